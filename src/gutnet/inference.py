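"""Compositional association-network inference.

Read counts only carry relative information, so ordinary correlations of
relative abundances are biased by the sum constraint.  This module estimates
the *latent* (log-scale) correlation structure from the centred log-ratio
(clr) transform of the counts with a lasso-penalised latent-variable fit:

    minimize over symmetric PSD Sigma:
        1/2 || S_hat - G Sigma G ||_F^2  +  lambda * sum_{i<j} |Sigma_ij|

where ``S_hat`` is the empirical covariance of the clr sample vectors and
``G = I - (1/p) 11'`` is the centring projector.  Because clr data identify
the latent covariance only up to row/column offsets (G annihilates them),
the L1 penalty resolves the indeterminacy and yields a sparse estimate.

The problem is solved by Davis-Yin three-operator splitting: a gradient step
on the smooth quadratic, a proximal step for the off-diagonal L1 penalty
(soft thresholding) and a projection onto the PSD cone (eigenvalue clipping).

Edge significance is assessed by a permutation test that shuffles each taxon
row of the clr matrix independently across samples — destroying all pairwise
association while preserving marginals — and refits the estimator at the
observed-data penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stream
from .core_io import CountMatrix, SampleDesign, filter_taxa
from .errors import ConvergenceError, UsageError
from .network import AssociationNetwork, sign_label

__all__ = [
    "ClrMatrix",
    "clr_transform",
    "CclassoFit",
    "cclasso_fit",
    "permutation_edge_pvalues",
    "build_network",
]

LAMBDA_GRID = np.logspace(-3, 0, 20)


# ---------------------------------------------------------------------------
# clr transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClrMatrix:
    """Centred log-ratio values (taxa x samples) and the pseudocount used."""

    values: pd.DataFrame
    pseudocount: float

    def __post_init__(self) -> None:
        col_sums = self.values.to_numpy().sum(axis=0)
        if not np.allclose(col_sums, 0.0, atol=1e-9):
            raise UsageError("clr columns must sum to 0")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise UsageError("clr values must be finite")

    @property
    def taxon_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def clr_transform(counts: CountMatrix, pseudocount: float = 0.5) -> ClrMatrix:
    """Per sample: x -> log(x + pseudocount) minus the sample's mean log."""
    if pseudocount <= 0:
        raise UsageError("pseudocount must be > 0")
    logs = np.log(counts.values.astype(float) + pseudocount)
    centred = logs - logs.mean(axis=0, keepdims=True)
    values = pd.DataFrame(centred, index=counts.table.index,
                          columns=counts.table.columns)
    return ClrMatrix(values, float(pseudocount))


# ---------------------------------------------------------------------------
# penalised latent-covariance fit
# ---------------------------------------------------------------------------

def _soft_threshold_offdiag(x: np.ndarray, t: float) -> np.ndarray:
    out = np.sign(x) * np.maximum(np.abs(x) - t, 0.0)
    np.fill_diagonal(out, np.diag(x))
    return out


def _project_psd(x: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh((x + x.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def _fit_cov(
    s_hat: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> tuple:
    """Solve the penalised PSD fit; returns (Sigma, n_iter, residual).

    Davis-Yin splitting with unit step (the quadratic's Lipschitz constant is
    ||G||^4 = 1).  The sparse copy (after soft thresholding) is returned, so
    entries killed by the penalty are exact zeros.
    """
    p = s_hat.shape[0]
    g = np.eye(p) - np.ones((p, p)) / p

    def grad(x):
        return g @ (g @ x @ g - s_hat) @ g

    z = s_hat.copy()
    x_sparse = z
    resid = np.inf
    for it in range(1, max_iter + 1):
        x_psd = _project_psd(z)
        # each unordered pair occupies two symmetric entries, so the prox of
        # lam * sum_{i<j} |Sigma_ij| thresholds entries at lam / 2
        x_sparse = _soft_threshold_offdiag(
            2.0 * x_psd - z - grad(x_psd), lam / 2.0
        )
        z = z + x_sparse - x_psd
        resid = np.linalg.norm(x_sparse - x_psd, "fro") / max(
            1.0, np.linalg.norm(x_psd, "fro")
        )
        if resid < tol:
            return (x_sparse + x_sparse.T) / 2.0, it, resid
    raise ConvergenceError(
        f"penalised fit did not converge in {max_iter} iterations "
        f"(residual {resid:.3e}, tol {tol:.1e})"
    )


def _cov_to_corr(sigma: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.clip(np.diag(sigma), 1e-12, None))
    corr = sigma / np.outer(d, d)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def _sample_cov(values: np.ndarray) -> np.ndarray:
    # observations are sample columns; covariance over the p taxa
    return np.cov(values, ddof=1)


def _cv_lambda(
    values: np.ndarray,
    grid: np.ndarray,
    k: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> float:
    """K-fold selection of lambda by held-out Frobenius loss on G Sigma G."""
    p, n = values.shape
    g = np.eye(p) - np.ones((p, p)) / p
    k = min(k, n)
    rng = stream(seed, "cclasso-cv")
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    losses = np.zeros(len(grid))
    for fold in folds:
        test = np.zeros(n, dtype=bool)
        test[fold] = True
        if test.sum() < 2 or (~test).sum() < 3:
            continue
        s_train = _sample_cov(values[:, ~test])
        s_test = _sample_cov(values[:, test])
        for gi, lam in enumerate(grid):
            try:
                sigma, _, _ = _fit_cov(s_train, lam, tol=tol, max_iter=max_iter)
            except ConvergenceError:
                # near-unpenalised fits are indeterminate and may stall;
                # such a lambda simply loses the cross-validation
                losses[gi] += np.inf
                continue
            losses[gi] += np.linalg.norm(s_test - g @ sigma @ g, "fro") ** 2
    return float(grid[int(np.argmin(losses))])


@dataclass(frozen=True)
class CclassoFit:
    """Result of the penalised latent-correlation fit."""

    corr: pd.DataFrame   # taxa x taxa, unit diagonal, entries in [-1, 1]
    cov: pd.DataFrame    # fitted latent covariance before rescaling
    lam: float
    n_iter: int
    residual: float


def cclasso_fit(
    clr: ClrMatrix,
    lam="cv",
    tol: float = 1e-6,
    max_iter: int = 5000,
    cv_folds: int = 5,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> CclassoFit:
    """Estimate the latent correlation matrix from clr data.

    ``lam`` is either a non-negative penalty or ``"cv"``, which selects the
    penalty on a log grid by ``cv_folds``-fold held-out Frobenius loss.
    """
    values = clr.values.to_numpy()
    p, n = values.shape
    if n < 3:
        raise UsageError("need at least 3 samples")
    if p < 2:
        raise UsageError("need at least 2 taxa")
    if isinstance(lam, str):
        if lam != "cv":
            raise UsageError(f"lam must be a number or 'cv', got {lam!r}")
        grid = LAMBDA_GRID if grid is None else np.asarray(grid, dtype=float)
        lam_val = _cv_lambda(values, grid, k=cv_folds, seed=seed,
                             tol=tol, max_iter=max_iter)
    else:
        lam_val = float(lam)
        if lam_val < 0:
            raise UsageError("lam must be >= 0")
    s_hat = _sample_cov(values)
    sigma, n_iter, resid = _fit_cov(s_hat, lam_val, tol=tol, max_iter=max_iter)
    corr = _cov_to_corr(sigma)
    ids = clr.taxon_ids
    return CclassoFit(
        corr=pd.DataFrame(corr, index=ids, columns=ids),
        cov=pd.DataFrame(sigma, index=ids, columns=ids),
        lam=lam_val,
        n_iter=n_iter,
        residual=resid,
    )


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def permutation_edge_pvalues(
    clr: ClrMatrix,
    fit_lambda: float,
    n_perm: int = 200,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> tuple:
    """Per-pair two-sided permutation p-values for the latent correlations.

    Every permutation shuffles each taxon row of the clr matrix independently
    across samples and refits the estimator at ``fit_lambda``.  The add-one
    convention ``p = (1 + #{|r_null| >= |r_obs|}) / (n_perm + 1)`` keeps
    p > 0; the smallest attainable value is ``1 / (n_perm + 1)``.

    Returns ``(pvalues, corr_obs)`` as taxa x taxa DataFrames.
    """
    if n_perm < 1:
        raise UsageError("n_perm must be >= 1")
    values = clr.values.to_numpy()
    p, n = values.shape
    sigma_obs, _, _ = _fit_cov(_sample_cov(values), fit_lambda,
                               tol=tol, max_iter=max_iter)
    corr_obs = _cov_to_corr(sigma_obs)
    abs_obs = np.abs(corr_obs)
    rng = stream(seed, "edge-permutation")
    exceed = np.zeros((p, p), dtype=np.int64)
    for _ in range(n_perm):
        perm = np.empty_like(values)
        for i in range(p):
            perm[i] = values[i, rng.permutation(n)]
        perm = perm - perm.mean(axis=0, keepdims=True)  # restore clr centring
        sigma_null, _, _ = _fit_cov(_sample_cov(perm), fit_lambda,
                                    tol=tol, max_iter=max_iter)
        exceed += np.abs(_cov_to_corr(sigma_null)) >= abs_obs
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    np.fill_diagonal(pvals, 1.0)
    ids = clr.taxon_ids
    return (
        pd.DataFrame(pvals, index=ids, columns=ids),
        pd.DataFrame(corr_obs, index=ids, columns=ids),
    )


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(
    counts: CountMatrix,
    design: SampleDesign | None = None,
    subset: tuple | None = None,
    p_threshold: float = 0.005,
    n_perm: int = 200,
    lam="cv",
    seed: int = 0,
    pseudocount: float = 0.5,
    filter_kwargs: dict | None = None,
) -> AssociationNetwork:
    """Infer the permutation-validated association network of a niche subset.

    ``subset`` is ``None`` for the full design or a ``(variable, level)``
    pair, e.g. ``("diet", "Ulva")``; the taxon pre-filter is re-applied
    within the subset.  Edges are the taxon pairs whose permutation p-value
    is below ``p_threshold``; edge sign follows the correlation sign.
    """
    if subset is None:
        sub_counts = counts
        provenance = "overall"
    else:
        if design is None:
            raise UsageError("a SampleDesign is required to select a subset")
        variable, level = subset
        samples = design.samples_in(variable, level)
        samples = [s for s in samples if s in set(counts.sample_ids)]
        if len(samples) < 3:
            raise UsageError(
                f"subset {variable}={level} selects {len(samples)} sample(s); "
                "need at least 3"
            )
        sub_counts = counts.select_samples(samples)
        provenance = f"{variable}={level}"
    sub_counts, _report = filter_taxa(sub_counts, **(filter_kwargs or {}))
    clr = clr_transform(sub_counts, pseudocount=pseudocount)
    fit = cclasso_fit(clr, lam=lam, seed=seed)
    pvals, corr = permutation_edge_pvalues(
        clr, fit_lambda=fit.lam, n_perm=n_perm, seed=seed
    )
    ids = clr.taxon_ids
    rows = []
    pv = pvals.to_numpy()
    cv = corr.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if pv[i, j] < p_threshold:
                w = float(cv[i, j])
                rows.append(
                    {
                        "source": ids[i],
                        "target": ids[j],
                        "weight": w,
                        "sign": sign_label(w),
                        "p_value": float(pv[i, j]),
                    }
                )
    edges = pd.DataFrame(rows, columns=["source", "target", "weight", "sign",
                                        "p_value"])
    params = {
        "lambda": fit.lam,
        "n_perm": n_perm,
        "p_threshold": p_threshold,
        "pseudocount": pseudocount,
        "seed": seed,
    }
    return AssociationNetwork(tuple(ids), edges, provenance, params)
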