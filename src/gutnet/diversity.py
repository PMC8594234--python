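"""Rarefaction, alpha/beta diversity and group-difference tests.

Samples are rarefied (subsampled without replacement) to a common sequencing
depth; samples below the depth are dropped, not scaled.  Alpha diversity is
the Shannon index in nats, beta diversity the Bray-Curtis dissimilarity.
Community-level differences are tested by one-factor PERMANOVA on the
dissimilarity matrix; univariate per-sample metrics by Kruskal-Wallis with
post hoc Dunn z-tests under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, norm, rankdata
from statsmodels.stats.multitest import multipletests

from ._rng import stream
from .core_io import CountMatrix
from .errors import DesignError, EmptyResultError, UndefinedIndexError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "rarefy",
    "shannon_alpha",
    "bray_curtis",
    "PermanovaResult",
    "permanova",
    "KruskalDunnResult",
    "kruskal_dunn",
]


def rarefy(counts: CountMatrix, depth: int = 10000, seed: int = 0) -> CountMatrix:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped (logged).  The draw is
    multivariate hypergeometric per sample, deterministic under ``seed``.
    """
    if depth < 1:
        raise UsageError("depth must be >= 1")
    rng = stream(seed, "rarefy")
    arr = counts.values
    totals = arr.sum(axis=0)
    keep = totals >= depth
    dropped = [s for s, k in zip(counts.sample_ids, keep) if not k]
    if dropped:
        logger.info("rarefy: dropping %d sample(s) below depth %d: %s",
                    len(dropped), depth, dropped)
    if not keep.any() or keep.sum() < 2:
        raise EmptyResultError(
            f"fewer than 2 samples reach rarefaction depth {depth}"
        )
    cols = []
    for j, k in enumerate(keep):
        if not k:
            continue
        col = arr[:, j]
        if totals[j] == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    out = pd.DataFrame(
        np.column_stack(cols).astype(np.int64),
        index=counts.table.index,
        columns=[s for s, k in zip(counts.sample_ids, keep) if k],
    )
    return CountMatrix(out)


def shannon_alpha(sample_counts) -> float:
    """Shannon diversity -sum(p ln p) of one sample, in nats."""
    v = np.asarray(sample_counts, dtype=float)
    s = v.sum()
    if s <= 0:
        raise UndefinedIndexError("Shannon index undefined for an empty sample")
    p = v[v > 0] / s
    return float(-np.sum(p * np.log(p)))


def bray_curtis(counts: CountMatrix) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity D = sum|u-v| / sum(u+v)."""
    arr = counts.values.T.astype(float)
    if (arr.sum(axis=1) <= 0).any():
        bad = [s for s, t in zip(counts.sample_ids, arr.sum(axis=1)) if t <= 0]
        raise UndefinedIndexError(
            f"Bray-Curtis undefined for all-zero sample(s): {bad}"
        )
    d = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(d, index=counts.sample_ids, columns=counts.sample_ids)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    n_groups: int
    n_samples: int


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple:
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for gidx in range(n_groups):
        members = np.flatnonzero(codes == gidx)
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
    return ss_total, ss_within


def permanova(
    dist: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    The pseudo-F statistic partitions the sum of squared dissimilarities
    into between- and within-group parts; the p-value permutes group labels
    with the add-one convention.  ``groups`` is a label per sample, aligned
    with the matrix order (or indexed like it, if a Series).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-10):
        raise UsageError("dist must be a symmetric square matrix")
    if isinstance(groups, pd.Series) and isinstance(dist, pd.DataFrame):
        groups = groups.loc[list(dist.index)]
    labels = pd.Categorical(np.asarray(groups))
    if len(labels) != n:
        raise UsageError("groups must have one label per sample")
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise DesignError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise DesignError(f"group(s) with a single sample: {small}")
    codes = labels.codes.astype(np.int64)
    a = len(counts)
    d2 = d**2

    def pseudo_f(perm_codes):
        ss_total, ss_within = _permanova_ss(d2, perm_codes, a)
        ss_between = ss_total - ss_within
        return (ss_between / (a - 1)) / (ss_within / (n - a)), ss_between, ss_total

    f_obs, ss_b, ss_t = pseudo_f(codes)
    rng = stream(seed, "permanova")
    exceed = 0
    for _ in range(n_perm):
        f_perm, _, _ = pseudo_f(rng.permutation(codes))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r2=float(ss_b / ss_t),
        p_value=float(p),
        n_permutations=n_perm,
        n_groups=a,
        n_samples=n,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KruskalDunnResult:
    h_statistic: float
    p_value: float
    dunn: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj, significant
    fdr_alpha: float


def kruskal_dunn(values, groups, fdr_alpha: float = 0.01) -> KruskalDunnResult:
    """Tie-corrected Kruskal-Wallis H with post hoc Dunn z-tests.

    Pairwise Dunn p-values are Benjamini-Hochberg adjusted and flagged at
    ``fdr_alpha``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if len(values) != len(labels):
        raise UsageError("values and groups must align")
    level_names = list(dict.fromkeys(labels))
    if len(level_names) < 2:
        raise DesignError("Kruskal-Wallis needs at least 2 groups")
    by_group = {g: values[labels == g] for g in level_names}
    if any(len(v) < 2 for v in by_group.values()):
        raise DesignError("each group needs at least 2 values")

    if np.all(values == values[0]):
        h, p = 0.0, 1.0  # scipy raises on all-identical input; H=0 by convention
    else:
        h, p = kruskal(*by_group.values())

    n = len(values)
    ranks = rankdata(values)
    mean_ranks = {g: ranks[labels == g].mean() for g in level_names}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    rows = []
    for ga, gb in itertools.combinations(level_names, 2):
        na, nb = len(by_group[ga]), len(by_group[gb])
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[ga] - mean_ranks[gb]) / se if se > 0 else 0.0
        p_raw = 2.0 * norm.sf(abs(z))
        rows.append({"group_a": ga, "group_b": gb, "z": z, "p_raw": p_raw})
    dunn = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(dunn["p_raw"], alpha=fdr_alpha,
                                        method="fdr_bh")
    dunn["p_adj"] = p_adj
    dunn["significant"] = reject
    return KruskalDunnResult(
        h_statistic=float(h),
        p_value=float(p),
        dunn=dunn,
        fdr_alpha=fdr_alpha,
    )
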