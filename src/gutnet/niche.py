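"""Niche-breadth indices and taxon classification.

Each taxon's distribution of reads across habitat units is summarised by
three complementary indices:

* **Levin's index** ``B = 1 / sum(p_j^2)`` — the inverse Simpson
  concentration of the taxon's abundance shares ``p_j`` over habitat units;
  equals the number of habitats under perfectly even use.
* **Shannon-Weaver breadth** ``H = -sum(p_j ln p_j)`` (nats) — evenness of
  occurrence across habitats.
* **Occupancy** — the fraction of habitat units where the taxon is present.

These obey the Hill-number ordering ``exp(H) >= B >= 1``.

Classification then combines two rules.  Occurrence-based: a *core* taxon is
present in at least 85% of the samples of every level of the scoped design
variable(s); a *unique* taxon is present in at least 85% of the samples of
exactly one level but in no more than 25% of the samples of each other level
of the same variable.  Rank-based: taxa whose overall niche-breadth rank
(mean of the three per-index ranks) falls in the top or bottom decile are
*generalists* or *specialists*.  A taxon that is both core and generalist is
a *core generalist*; everything else is *not significant*.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import CountMatrix, SampleDesign
from .errors import UndefinedIndexError, UsageError

__all__ = [
    "levins_index",
    "shannon_breadth",
    "occupancy",
    "classify_occurrence",
    "rank_classify",
    "profile_all",
    "load_published_indices",
]


# ---------------------------------------------------------------------------
# per-taxon indices
# ---------------------------------------------------------------------------

def _shares(abundance_by_habitat) -> np.ndarray:
    v = np.asarray(abundance_by_habitat, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise UsageError("abundance vector must be 1-D and non-empty")
    if (v < 0).any():
        raise UsageError("abundances must be non-negative")
    s = v.sum()
    if s <= 0:
        raise UndefinedIndexError("niche index undefined for an all-zero vector")
    return v / s


def levins_index(abundance_by_habitat) -> float:
    """Levin's niche breadth B = 1 / sum(p_j^2)."""
    p = _shares(abundance_by_habitat)
    return float(1.0 / np.sum(p**2))


def shannon_breadth(abundance_by_habitat) -> float:
    """Shannon-Weaver niche breadth H = -sum(p_j ln p_j), with 0 ln 0 = 0."""
    p = _shares(abundance_by_habitat)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def occupancy(abundance_by_habitat) -> float:
    """Fraction of habitat units with abundance > 0."""
    v = np.asarray(abundance_by_habitat, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise UsageError("abundance vector must be 1-D and non-empty")
    return float(np.mean(v > 0))


# ---------------------------------------------------------------------------
# occurrence rule
# ---------------------------------------------------------------------------

def classify_occurrence(
    occurrence_by_level: dict,
    core_min: float = 0.85,
    unique_other_max: float = 0.25,
) -> str:
    """Apply the core / unique occurrence rule to one design variable.

    ``occurrence_by_level`` maps each level of the variable to the presence
    fraction of the taxon among that level's samples.  Returns ``"core"``,
    ``"unique:<level>"`` or ``"none"``.  Core (>= ``core_min`` in every
    level) takes precedence over unique (>= ``core_min`` in exactly one
    level and <= ``unique_other_max`` in each other level).
    """
    if len(occurrence_by_level) < 2:
        raise UsageError("need at least 2 levels per variable")
    vals = {k: float(v) for k, v in occurrence_by_level.items()}
    for k, v in vals.items():
        if not 0.0 <= v <= 1.0:
            raise UsageError(f"occurrence fraction for level {k!r} outside [0, 1]")
    if all(v >= core_min for v in vals.values()):
        return "core"
    high = [k for k, v in vals.items() if v >= core_min]
    if len(high) == 1:
        level = high[0]
        if all(v <= unique_other_max for k, v in vals.items() if k != level):
            return f"unique:{level}"
    return "none"


# ---------------------------------------------------------------------------
# rank rule
# ---------------------------------------------------------------------------

def rank_classify(
    levins,
    shannon,
    occ,
    decile: float = 0.10,
) -> tuple:
    """Decile rule on the mean of the three per-index ranks.

    Each index is ranked descending (broadest niche = rank 1) with average
    ranks for ties.  Taxa whose overall rank lies within the best
    ``ceil(decile * N)`` are generalists, within the worst ``ceil(decile *
    N)`` specialists, everything else not significant.  Returns
    ``(labels, overall_rank)`` as numpy arrays.
    """
    levins = np.asarray(levins, dtype=float)
    shannon = np.asarray(shannon, dtype=float)
    occ = np.asarray(occ, dtype=float)
    if not (len(levins) == len(shannon) == len(occ)):
        raise UsageError("index vectors must have equal length")
    n = len(levins)
    if n < 1:
        raise UsageError("empty index vectors")
    ranks = np.vstack(
        [rankdata(-v, method="average") for v in (levins, shannon, occ)]
    )
    overall = ranks.mean(axis=0)
    labels = np.full(n, "not_significant", dtype=object)
    if n * decile < 1.0:
        warnings.warn(
            f"decile set would contain < 1 taxon at N={n}; "
            "returning all not_significant",
            stacklevel=2,
        )
        return labels, overall
    k = int(np.ceil(decile * n))
    top_cut = np.sort(overall)[k - 1]
    bottom_cut = np.sort(overall)[n - k]
    is_gen = overall <= top_cut
    is_spec = overall >= bottom_cut
    clash = is_gen & is_spec
    if clash.any():
        warnings.warn(
            "taxa tied across both decile boundaries left not_significant",
            stacklevel=2,
        )
        is_gen &= ~clash
        is_spec &= ~clash
    labels[is_gen] = "generalist"
    labels[is_spec] = "specialist"
    return labels, overall


# ---------------------------------------------------------------------------
# full profile
# ---------------------------------------------------------------------------

def profile_all(
    counts: CountMatrix,
    design: SampleDesign,
    habitat_unit: str = "sample",
    scope: str = "both",
    core_min: float = 0.85,
    unique_other_max: float = 0.25,
    decile: float = 0.10,
    core_any_level: bool = False,
) -> pd.DataFrame:
    """Full per-taxon niche profile and final class label.

    ``habitat_unit`` chooses the units the three breadth indices are computed
    over: individual samples (default) or diet x region design cells.
    ``scope`` selects which design variables enter the occurrence rule
    (``"diet"``, ``"region"`` or ``"both"``).  With ``core_any_level=True``
    the core rule requires >= ``core_min`` presence in at least one level
    instead of every level (lenient reading; the strict reading is the
    default).

    Returns a DataFrame indexed by taxon with columns ``levins``,
    ``shannon_breadth``, ``occupancy``, ``overall_rank``, one
    ``occurrence_<variable>_<level>`` column per level, ``occurrence_overall``,
    ``cumulative_abundance``, ``abundance_occurrence_ratio`` and ``label``.
    """
    if habitat_unit not in ("sample", "cell"):
        raise UsageError(f"unknown habitat_unit {habitat_unit!r}")
    if scope not in ("diet", "region", "both"):
        raise UsageError(f"unknown scope {scope!r}")
    missing = set(counts.sample_ids) - set(design.sample_ids)
    if missing:
        raise UsageError(f"design does not cover samples: {sorted(missing)}")
    design = design.subset(counts.sample_ids)

    arr = counts.values.astype(float)
    if habitat_unit == "sample":
        units = arr
    else:
        cells = design.cells()
        groups = [np.asarray(cells == c) for c in dict.fromkeys(cells)]
        units = np.column_stack([arr[:, g].sum(axis=1) for g in groups])

    n_taxa = arr.shape[0]
    levins = np.empty(n_taxa)
    shannon = np.empty(n_taxa)
    occ = np.empty(n_taxa)
    for i in range(n_taxa):
        row = units[i]
        if row.sum() <= 0:
            # taxon absent everywhere (possible on unfiltered input)
            levins[i], shannon[i], occ[i] = 1.0, 0.0, 0.0
        else:
            levins[i] = levins_index(row)
            shannon[i] = shannon_breadth(row)
            occ[i] = occupancy(row)

    rank_labels, overall = rank_classify(levins, shannon, occ, decile=decile)

    variables = ["diet", "region"] if scope == "both" else [scope]
    presence = counts.values > 0
    occ_cols: dict = {}
    per_var_occ: dict = {}
    for var in variables:
        lv_occ = {}
        for level in design.levels(var):
            members = [s in set(design.samples_in(var, level))
                       for s in counts.sample_ids]
            members = np.asarray(members)
            frac = presence[:, members].mean(axis=1)
            lv_occ[level] = frac
            occ_cols[f"occurrence_{var}_{level}"] = frac
        per_var_occ[var] = lv_occ

    is_core = np.zeros(n_taxa, dtype=bool)
    unique_label = np.full(n_taxa, "", dtype=object)
    for i in range(n_taxa):
        verdicts = {}
        for var in variables:
            by_level = {lev: fr[i] for lev, fr in per_var_occ[var].items()}
            if len(by_level) < 2:
                continue  # degenerate single-level variable: no occurrence rule
            verdicts[var] = classify_occurrence(
                by_level, core_min=core_min, unique_other_max=unique_other_max
            )
        core_votes = [v == "core" for v in verdicts.values()]
        if not core_votes:
            is_core[i] = False
        else:
            is_core[i] = any(core_votes) if core_any_level else all(core_votes)
        if not is_core[i]:
            for var in variables:  # diet takes priority when both match
                if verdicts.get(var, "none").startswith("unique:"):
                    unique_label[i] = verdicts[var]
                    break

    labels = np.empty(n_taxa, dtype=object)
    for i in range(n_taxa):
        if is_core[i] and rank_labels[i] == "generalist":
            labels[i] = "core_generalist"
        elif is_core[i]:
            labels[i] = "core"
        elif unique_label[i]:
            labels[i] = unique_label[i]
        else:
            labels[i] = rank_labels[i]

    cumulative = counts.values.sum(axis=1)
    present_samples = presence.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(present_samples > 0, cumulative / present_samples, 0.0)

    out = pd.DataFrame(
        {
            "levins": levins,
            "shannon_breadth": shannon,
            "occupancy": occ,
            "overall_rank": overall,
            "occurrence_overall": presence.mean(axis=1),
            **occ_cols,
            "cumulative_abundance": cumulative,
            "abundance_occurrence_ratio": ratio,
            "label": labels,
        },
        index=pd.Index(counts.taxon_ids, name="taxon_id"),
    )
    return out


# ---------------------------------------------------------------------------
# published reference indices
# ---------------------------------------------------------------------------

def load_published_indices() -> pd.DataFrame:
    """Niche-breadth index triples published for the sea urchin gut survey.

    Columns: ``category`` (core / core_generalist / generalist / specialist /
    unique), ``levins``, ``shannon`` (nats) and ``occurrence``.  Used to audit
    the Hill-number ordering exp(H) >= B against independently computed
    values.
    """
    with resources.files("gutnet.data").joinpath(
        "published_niche_indices.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
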