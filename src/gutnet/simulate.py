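"""Synthetic gut-microbiome communities with known ground truth.

The generator emulates the factorial feeding-trial design the analysis
assumes: three diets crossed with three gut regions, a handful of replicates
per cell, sparse overdispersed counts of 10-20k reads per sample, and taxa
planted from occurrence archetypes:

* **core** — high mean abundance in every habitat cell, no dropout;
* **generalist** — moderate abundance in every cell, light dropout;
* **specialist** — abundant in at most two habitat cells, absent elsewhere;
* **unique** — abundant in every region under one diet level, rare elsewhere;
* **background** — random sparse filler taxa.

Counts follow a logistic-normal-multinomial model: a latent Gaussian vector
per sample (with a user-specified correlation structure across taxa) is added
to the archetype log-mean, exponentiated, masked by per-taxon dropout,
normalised to a composition, and sampled with a multinomial at the requested
sequencing depth.  The latent log-scale correlation is exactly the quantity
the inference stage estimates, so parameter recovery is well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream
from .core_io import CountMatrix, SampleDesign
from .errors import UsageError

__all__ = [
    "DIETS",
    "REGIONS",
    "ArchetypeSpec",
    "CommunityTruth",
    "generate_design",
    "generate_counts",
    "generate_null_counts",
    "generate_correlated_counts",
]

DIETS = ("Ulva", "Gracilaria", "Pellet")
REGIONS = ("esophagus", "stomach", "intestine")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Planted community composition.

    ``base_abundance`` are mean log-abundances on the latent scale (unitless;
    the composition only depends on differences).  ``dropout`` is the
    probability that a taxon is structurally absent from a sample of a
    habitat where it is otherwise active.
    """

    n_core: int = 8
    n_generalist: int = 15
    n_specialist: int = 12
    n_unique_per_niche: int = 4
    n_background: int = 103
    specialist_cells: int = 2
    base_abundance: dict = field(
        default_factory=lambda: {
            "core": 4.0,
            "generalist": 2.5,
            "specialist": 3.0,
            "unique": 3.5,
            "background": 0.0,
        }
    )
    dropout: dict = field(
        default_factory=lambda: {
            "core": 0.0,
            "generalist": 0.25,
            "specialist": 0.10,
            "unique_home": 0.03,
            "unique_away": 0.95,
            "background": 0.60,
        }
    )
    latent_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_core", "n_generalist", "n_specialist",
                     "n_unique_per_niche", "n_background"):
            if getattr(self, name) < 0:
                raise UsageError(f"{name} must be >= 0")
        for k, v in self.dropout.items():
            if not 0.0 <= v <= 1.0:
                raise UsageError(f"dropout[{k!r}] outside [0, 1]")
        for k, v in self.base_abundance.items():
            if not np.isfinite(v):
                raise UsageError(f"base_abundance[{k!r}] not finite")

    def n_taxa(self, n_niches: int) -> int:
        return (
            self.n_core
            + self.n_generalist
            + self.n_specialist
            + self.n_unique_per_niche * n_niches
            + self.n_background
        )


@dataclass(frozen=True)
class CommunityTruth:
    """Ground truth of a generated community, for parameter-recovery tests."""

    labels: pd.DataFrame       # index taxon_id; columns: archetype, niche
    latent_corr: pd.DataFrame  # taxa x taxa planted latent correlation
    seed: int

    def taxa_with(self, archetype: str) -> list:
        return list(self.labels.index[self.labels["archetype"] == archetype])


def generate_design(
    n_per_cell: int,
    diets: tuple = DIETS,
    regions: tuple = REGIONS,
) -> SampleDesign:
    """Balanced factorial design with deterministic sample naming."""
    if n_per_cell < 1:
        raise UsageError("n_per_cell must be >= 1")
    if not diets or not regions:
        raise UsageError("diets and regions must be non-empty level lists")
    rows = []
    for diet in diets:
        for region in regions:
            for rep in range(1, n_per_cell + 1):
                rows.append((f"{diet}-{region}-{rep:03d}", diet, region))
    table = pd.DataFrame(rows, columns=["sample_id", "diet", "region"])
    return SampleDesign(table.set_index("sample_id"))


def _validate_corr(latent_corr: np.ndarray, p: int) -> np.ndarray:
    c = np.asarray(latent_corr, dtype=float)
    if c.shape != (p, p):
        raise UsageError(f"latent_corr must be {p}x{p}, got {c.shape}")
    if not np.allclose(c, c.T, atol=1e-10):
        raise UsageError("latent_corr must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-10):
        raise UsageError("latent_corr must have unit diagonal")
    w = np.linalg.eigvalsh(c)
    if w.min() < -1e-8:
        raise UsageError(f"latent_corr not positive semidefinite (min eig {w.min():.3g})")
    return c


def _correlated_normals(corr: np.ndarray | None, p: int, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal((p, n))
    if corr is None:
        return z
    # eigenvalue square root handles semidefinite matrices (Cholesky may not)
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    return root @ z


def generate_counts(
    design: SampleDesign,
    spec: ArchetypeSpec | None = None,
    latent_corr: np.ndarray | None = None,
    depth: int = 15000,
    seed: int = 0,
) -> tuple:
    """Draw a CountMatrix with planted archetypes and latent correlation.

    Returns ``(CountMatrix, CommunityTruth)``.  Identical seed gives
    bit-identical output.
    """
    if spec is None:
        spec = ArchetypeSpec()
    if depth < 1:
        raise UsageError("depth must be >= 1")
    diets = design.levels("diet")
    regions = design.levels("region")
    cells = [(d, r) for d in diets for r in regions]
    cell_index = {c: i for i, c in enumerate(cells)}
    n_cells = len(cells)
    p = spec.n_taxa(len(diets))
    samples = design.sample_ids
    n = len(samples)
    sample_cell = np.array(
        [cell_index[(design.diet[s], design.region[s])] for s in samples]
    )

    if latent_corr is not None:
        corr = _validate_corr(latent_corr, p)
    else:
        corr = None

    rng_means = stream(seed, "means")
    rng_drop = stream(seed, "dropout")
    rng_latent = stream(seed, "latent")
    rng_multi = stream(seed, "multinomial")

    taxon_ids: list = []
    archetypes: list = []
    niches: list = []
    mu = np.full((p, n_cells), -np.inf)  # -inf: structurally absent from cell
    drop = np.ones((p, n_cells))
    t = 0
    ba, do = spec.base_abundance, spec.dropout
    for i in range(spec.n_core):
        taxon_ids.append(f"core_{i + 1:03d}")
        archetypes.append("core")
        niches.append("")
        mu[t, :] = ba["core"]
        drop[t, :] = do["core"]
        t += 1
    for i in range(spec.n_generalist):
        taxon_ids.append(f"gen_{i + 1:03d}")
        archetypes.append("generalist")
        niches.append("")
        mu[t, :] = ba["generalist"]
        drop[t, :] = do["generalist"]
        t += 1
    for i in range(spec.n_specialist):
        taxon_ids.append(f"spec_{i + 1:03d}")
        archetypes.append("specialist")
        niches.append("")
        k = min(spec.specialist_cells, n_cells)
        chosen = rng_means.choice(n_cells, size=k, replace=False)
        mu[t, chosen] = ba["specialist"]
        drop[t, chosen] = do["specialist"]
        t += 1
    for diet in diets:
        for i in range(spec.n_unique_per_niche):
            taxon_ids.append(f"uniq_{diet}_{i + 1:03d}")
            archetypes.append("unique")
            niches.append(diet)
            for c, (d, _r) in enumerate(cells):
                mu[t, c] = ba["unique"]
                drop[t, c] = do["unique_home"] if d == diet else do["unique_away"]
            t += 1
    for i in range(spec.n_background):
        taxon_ids.append(f"bg_{i + 1:03d}")
        archetypes.append("background")
        niches.append("")
        mu[t, :] = ba["background"] + rng_means.standard_normal()
        drop[t, :] = do["background"]
        t += 1
    assert t == p

    z = _correlated_normals(corr, p, n, rng_latent)
    log_abund = mu[:, sample_cell] + spec.latent_sd * z
    keep = rng_drop.random((p, n)) >= drop[:, sample_cell]
    with np.errstate(over="ignore"):
        weights = np.where(keep, np.exp(log_abund), 0.0)
    weights[~np.isfinite(weights)] = 0.0

    counts = np.zeros((p, n), dtype=np.int64)
    for j in range(n):
        col = weights[:, j]
        tot = col.sum()
        if tot <= 0:  # pathological all-dropout column: put reads on max-mean taxon
            col = np.zeros(p)
            col[int(np.argmax(mu[:, sample_cell[j]]))] = 1.0
            tot = 1.0
        counts[:, j] = rng_multi.multinomial(depth, col / tot)

    table = pd.DataFrame(counts, index=pd.Index(taxon_ids, name="taxon_id"),
                         columns=samples)
    labels = pd.DataFrame(
        {"archetype": archetypes, "niche": niches},
        index=pd.Index(taxon_ids, name="taxon_id"),
    )
    corr_df = pd.DataFrame(
        corr if corr is not None else np.eye(p), index=taxon_ids, columns=taxon_ids
    )
    return CountMatrix(table), CommunityTruth(labels, corr_df, int(seed))


def generate_correlated_counts(
    n_samples: int,
    n_taxa: int,
    latent_corr: np.ndarray | None = None,
    depth: int = 15000,
    seed: int = 0,
    latent_sd: float = 1.0,
) -> CountMatrix:
    """Homogeneous (single-habitat) logistic-normal-multinomial counts.

    Per-taxon mean log-abundances are drawn N(0, 1) once from the seed; no
    dropout or archetype structure is planted.  Used for calibration nulls
    (identity correlation) and edge-recovery studies (planted correlation).
    """
    if n_samples < 1 or n_taxa < 1 or depth < 1:
        raise UsageError("n_samples, n_taxa and depth must be positive")
    corr = _validate_corr(latent_corr, n_taxa) if latent_corr is not None else None
    rng_means = stream(seed, "null-means")
    rng_latent = stream(seed, "null-latent")
    rng_multi = stream(seed, "null-multinomial")
    mu = rng_means.standard_normal(n_taxa)
    z = _correlated_normals(corr, n_taxa, n_samples, rng_latent)
    weights = np.exp(mu[:, None] + latent_sd * z)
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = rng_multi.multinomial(depth, weights[:, j] / weights[:, j].sum())
    taxa = [f"T{i + 1:04d}" for i in range(n_taxa)]
    samples = [f"S{j + 1:04d}" for j in range(n_samples)]
    table = pd.DataFrame(counts, index=pd.Index(taxa, name="taxon_id"),
                         columns=samples)
    return CountMatrix(table)


def generate_null_counts(
    n_samples: int, n_taxa: int, depth: int = 15000, seed: int = 0
) -> CountMatrix:
    """Counts with identity latent correlation and no planted structure."""
    return generate_correlated_counts(n_samples, n_taxa, None, depth, seed)


def generate_rewired_triple(
    seed: int,
    n_nodes: int = 30,
    edge_prob: float = 0.1,
    n_new_partners: int = 10,
):
    """A case/control network triple with one planted driver node.

    Two identical control networks are drawn as an Erdos-Renyi graph; the
    case network rewires one low-degree node: all its old edges are removed
    and ``n_new_partners`` exclusive new partners are attached, so the node
    shows complete neighbour turnover and a jump in betweenness — the
    signature the driver criteria (low JEI, high NESH, positive delta-B)
    are designed to detect.

    Returns ``({"A": net, "B": net, "C": rewired net}, planted_node)``.
    """
    import networkx as nx

    from .network import AssociationNetwork

    if n_new_partners >= n_nodes - 1:
        raise UsageError("n_new_partners must be < n_nodes - 1")
    rng = stream(seed, "rewired-triple")
    g = nx.gnp_random_graph(n_nodes, edge_prob, seed=int(seed) & 0x7FFFFFFF)
    nodes = [f"v{i}" for i in range(n_nodes)]
    g = nx.relabel_nodes(g, dict(enumerate(nodes)))
    degs = dict(g.degree())
    low = [u for u in nodes if degs[u] <= 2] or sorted(nodes, key=degs.get)[:1]
    v = low[int(rng.integers(len(low)))]
    gc = g.copy()
    old = set(gc[v])
    gc.remove_edges_from([(v, u) for u in old])
    candidates = [u for u in nodes if u != v and u not in old]
    new = rng.choice(candidates, size=min(n_new_partners, len(candidates)),
                     replace=False)
    gc.add_edges_from((v, u) for u in new)

    def mk(graph, name):
        return AssociationNetwork.from_edges(graph.edges(), nodes=nodes,
                                             provenance=name)

    return {"A": mk(g, "A"), "B": mk(g, "B"), "C": mk(gc, "C")}, v
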