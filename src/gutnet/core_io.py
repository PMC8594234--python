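"""Data containers, TSV readers/writers and the taxon pre-filters.

The pipeline's canonical in-memory objects are thin wrappers around pandas
DataFrames:

* :class:`CountMatrix` — integer taxa x samples read-count table;
* :class:`SampleDesign` — per-sample diet and gut-region factor levels, whose
  cross defines the habitat cells of the factorial design;
* :class:`TaxonomyTable` — optional ranked lineage per taxon;
* :class:`FilterReport` — bookkeeping of the abundance/occurrence pre-filter.

All on-disk formats are plain TSV (tab-separated, UTF-8, no quoting, "."
decimal separator).  The first header cell of a counts table is literally
``taxon_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    EmptyResultError,
    IdentifierError,
    ReconciliationError,
    TableFormatError,
    UsageError,
)
from .network import AssociationNetwork, EDGE_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "TaxonomyTable",
    "FilterReport",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_taxonomy",
    "filter_taxa",
    "write_network",
    "read_network",
]

TAXONOMY_RANKS = ["phylum", "class", "order", "family", "genus", "species"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    """Integer taxa x samples abundance table (units: reads)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate taxon ids: {dups}")
        if t.columns.has_duplicates:
            dups = t.columns[t.columns.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate sample ids: {dups}")
        if t.shape[0] < 1 or t.shape[1] < 2:
            raise UsageError(
                f"need at least 1 taxon and 2 samples, got shape {t.shape}"
            )
        arr = t.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise TableFormatError("counts must be integers")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative count at taxon {t.index[i]!r}, sample {t.columns[j]!r}"
            )

    @property
    def taxon_ids(self) -> list:
        return list(self.table.index)

    @property
    def sample_ids(self) -> list:
        return list(self.table.columns)

    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy()

    @property
    def shape(self) -> tuple:
        return self.table.shape

    def select_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise UsageError(f"unknown sample ids: {sorted(missing)}")
        return CountMatrix(self.table.loc[:, sample_ids].copy())

    def select_taxa(self, taxon_ids: Iterable[str]) -> "CountMatrix":
        taxon_ids = list(taxon_ids)
        missing = set(taxon_ids) - set(self.taxon_ids)
        if missing:
            raise UsageError(f"unknown taxon ids: {sorted(missing)}")
        return CountMatrix(self.table.loc[taxon_ids, :].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample factor assignment; ``diet`` x ``region`` defines habitats."""

    table: pd.DataFrame  # index: sample_id; columns: diet, region

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise IdentifierError("duplicate sample ids in design")
        for col in ("diet", "region"):
            if col not in t.columns:
                raise TableFormatError(f"design table lacks column {col!r}")
            vals = t[col].astype(str)
            if (vals.str.len() == 0).any() or vals.isna().any():
                raise TableFormatError(f"empty {col} level in design")

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    @property
    def diet(self) -> pd.Series:
        return self.table["diet"]

    @property
    def region(self) -> pd.Series:
        return self.table["region"]

    def levels(self, variable: str) -> list:
        """Distinct levels of ``diet`` or ``region``, in order of appearance."""
        if variable not in ("diet", "region"):
            raise UsageError(f"unknown design variable {variable!r}")
        return list(dict.fromkeys(self.table[variable]))

    def cells(self) -> pd.Series:
        """Habitat-cell label (diet x region) per sample."""
        return self.table["diet"].astype(str) + "|" + self.table["region"].astype(str)

    def samples_in(self, variable: str, level: str) -> list:
        lev = self.table[variable].astype(str)
        return list(self.table.index[lev == str(level)])

    def subset(self, sample_ids: Iterable[str]) -> "SampleDesign":
        return SampleDesign(self.table.loc[list(sample_ids)].copy())


@dataclass(frozen=True)
class TaxonomyTable:
    """Ranked lineage strings per taxon; any rank may be ``unassigned``."""

    table: pd.DataFrame  # index: taxon_id; columns: TAXONOMY_RANKS

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise IdentifierError("duplicate taxon ids in taxonomy")
        missing = [r for r in TAXONOMY_RANKS if r not in self.table.columns]
        if missing:
            raise TableFormatError(f"taxonomy lacks rank column(s): {missing}")

    def lineage(self, taxon_id: str) -> dict:
        return self.table.loc[taxon_id, TAXONOMY_RANKS].to_dict()


@dataclass(frozen=True)
class FilterReport:
    """Partition of the input taxa by the pre-filter rule that removed them."""

    taxa_removed_min_reads: int
    taxa_removed_prevalence: int
    taxa_removed_occurrence: int
    taxa_retained: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise UsageError(f"{name} negative")

    @property
    def taxa_input(self) -> int:
        return (
            self.taxa_removed_min_reads
            + self.taxa_removed_prevalence
            + self.taxa_removed_occurrence
            + self.taxa_retained
        )


# ---------------------------------------------------------------------------
# counts I/O
# ---------------------------------------------------------------------------

def read_counts(path) -> CountMatrix:
    """Read a taxa x samples TSV whose first column holds taxon ids."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
    header = header_line.split("\t")  # pandas would mangle duplicate headers
    if len(header) < 2:
        raise TableFormatError(f"{path}: expected taxon_id column plus samples")
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise IdentifierError(f"{path}: duplicated sample header(s): {dups}")
    taxa = raw.iloc[:, 0].tolist()
    if len(set(taxa)) != len(taxa):
        dups = sorted({t for t in taxa if taxa.count(t) > 1})
        raise IdentifierError(f"{path}: duplicated taxon id(s): {dups}")
    values = np.empty((len(taxa), len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        col = raw.iloc[:, j + 1]
        for i, cell in enumerate(col):
            try:
                v = int(cell)
            except ValueError:
                raise TableFormatError(
                    f"{path}: non-integer cell {cell!r} at taxon {taxa[i]!r}, "
                    f"sample {sid!r}"
                ) from None
            if v < 0:
                raise TableFormatError(
                    f"{path}: negative cell {cell!r} at taxon {taxa[i]!r}, "
                    f"sample {sid!r}"
                )
            values[i, j] = v
    table = pd.DataFrame(values, index=pd.Index(taxa, name="taxon_id"),
                         columns=sample_ids)
    return CountMatrix(table)


def write_counts(counts: CountMatrix, path) -> None:
    """Write a counts TSV that round-trips byte-identically via read_counts."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("taxon_id\t" + "\t".join(map(str, counts.sample_ids)) + "\n")
        for tid, row in zip(counts.taxon_ids, counts.values):
            fh.write(str(tid) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# design / taxonomy I/O
# ---------------------------------------------------------------------------

def read_design(path, counts: CountMatrix | None = None, strict: bool = True) -> SampleDesign:
    """Read sample metadata (columns ``sample_id, diet, region``).

    When ``counts`` is given the design is reconciled with its samples:
    a sample present in the counts but missing from the metadata is always an
    error; extra metadata rows are an error under ``strict`` and are silently
    subset (logged) otherwise.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "diet", "region"):
        if col not in raw.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    if raw["sample_id"].duplicated().any():
        dups = raw["sample_id"][raw["sample_id"].duplicated()].unique().tolist()
        raise IdentifierError(f"{path}: duplicated sample id(s): {dups}")
    table = raw.set_index("sample_id")[["diet", "region"]]
    design = SampleDesign(table)
    if counts is None:
        return design
    count_samples = list(counts.sample_ids)
    missing = sorted(set(count_samples) - set(design.sample_ids))
    extra = sorted(set(design.sample_ids) - set(count_samples))
    if missing:
        raise ReconciliationError(
            f"{path}: samples present in counts but absent from metadata: {missing}"
        )
    if extra:
        if strict:
            raise ReconciliationError(
                f"{path}: metadata rows without matching counts sample: {extra}"
            )
        logger.info("read_design: dropping %d unmatched metadata row(s): %s",
                    len(extra), extra)
    return SampleDesign(table.loc[count_samples].copy())


def write_design(design: SampleDesign, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tdiet\tregion\n")
        for sid, row in design.table.iterrows():
            fh.write(f"{sid}\t{row['diet']}\t{row['region']}\n")


def read_taxonomy(path) -> TaxonomyTable:
    """Read a taxonomy TSV (``taxon_id`` plus one column per rank)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "taxon_id" not in raw.columns:
        raise TableFormatError(f"{path}: missing column 'taxon_id'")
    if raw["taxon_id"].duplicated().any():
        raise IdentifierError(f"{path}: duplicated taxon ids")
    table = raw.set_index("taxon_id")
    for rank in TAXONOMY_RANKS:
        if rank not in table.columns:
            table[rank] = "unassigned"
    return TaxonomyTable(table[TAXONOMY_RANKS])


# ---------------------------------------------------------------------------
# taxon pre-filter
# ---------------------------------------------------------------------------

def filter_taxa(
    counts: CountMatrix,
    min_total_reads: int = 5,
    min_rel_abundance: float = 1e-5,
    min_occurrence: float = 0.10,
    prevalence_mode: str = "pooled",
) -> tuple:
    """Remove rare taxa before any downstream stage.

    A taxon is retained when its total reads are >= ``min_total_reads``, its
    relative abundance is >= ``min_rel_abundance`` and it is present
    (count > 0) in at least ``min_occurrence`` of the samples.  A removed
    taxon is counted once, in the first rule it fails (total reads, then
    prevalence, then occurrence), so the report categories partition the
    input.

    ``prevalence_mode`` selects how relative abundance is measured:
    ``"pooled"`` (taxon total / grand total, the default) or ``"mean"``
    (mean of per-sample relative abundances).
    """
    if prevalence_mode not in ("pooled", "mean"):
        raise UsageError(f"unknown prevalence_mode {prevalence_mode!r}")
    arr = counts.values
    totals = arr.sum(axis=1)
    grand = arr.sum()
    if prevalence_mode == "pooled":
        rel = totals / grand if grand > 0 else np.zeros_like(totals, dtype=float)
    else:
        col_tot = arr.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_sample = np.where(col_tot > 0, arr / col_tot, 0.0)
        rel = per_sample.mean(axis=1)
    occurrence = (arr > 0).mean(axis=1)

    fail_reads = totals < min_total_reads
    fail_prev = ~fail_reads & (rel < min_rel_abundance)
    fail_occ = ~fail_reads & ~fail_prev & (occurrence < min_occurrence)
    keep = ~(fail_reads | fail_prev | fail_occ)

    report = FilterReport(
        taxa_removed_min_reads=int(fail_reads.sum()),
        taxa_removed_prevalence=int(fail_prev.sum()),
        taxa_removed_occurrence=int(fail_occ.sum()),
        taxa_retained=int(keep.sum()),
    )
    if report.taxa_retained == 0:
        raise EmptyResultError(
            "all taxa removed by the pre-filter; relax min_total_reads/"
            "min_rel_abundance/min_occurrence"
        )
    kept = CountMatrix(counts.table.loc[np.asarray(keep)].copy())
    return kept, report


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------

def write_network(net: AssociationNetwork, path, format: str = "edgelist_tsv") -> None:
    """Write a network as edge-list TSV or GraphML.

    The edge-list columns are ``source, target, weight, sign, p_value``.
    Floats are written with ``repr`` so that reading back reproduces the
    network exactly.
    """
    path = Path(path)
    if format == "edgelist_tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("# nodes: " + ",".join(net.nodes) + "\n")
            fh.write("# provenance: " + net.provenance + "\n")
            fh.write("\t".join(EDGE_COLUMNS) + "\n")
            for row in net.edges.itertuples(index=False):
                fh.write(
                    f"{row.source}\t{row.target}\t{row.weight!r}\t{row.sign}\t"
                    f"{row.p_value!r}\n"
                )
    elif format == "graphml":
        g = net.to_networkx()
        g.graph["provenance"] = net.provenance
        nx.write_graphml(g, path)
    else:
        raise UsageError(f"unknown network format {format!r}")


def read_network(path, format: str = "edgelist_tsv") -> AssociationNetwork:
    path = Path(path)
    if format == "edgelist_tsv":
        nodes: list = []
        provenance = ""
        rows = []
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        body = []
        for line in lines:
            if line.startswith("# nodes:"):
                spec = line.split(":", 1)[1].strip()
                nodes = spec.split(",") if spec else []
            elif line.startswith("# provenance:"):
                provenance = line.split(":", 1)[1].strip()
            elif line and not line.startswith("#"):
                body.append(line)
        if not body or body[0].split("\t") != EDGE_COLUMNS:
            raise TableFormatError(f"{path}: missing edge-list header")
        for line in body[1:]:
            parts = line.split("\t")
            if len(parts) != 5:
                raise TableFormatError(f"{path}: malformed edge row {line!r}")
            rows.append(
                {
                    "source": parts[0],
                    "target": parts[1],
                    "weight": float(parts[2]),
                    "sign": parts[3],
                    "p_value": float(parts[4]),
                }
            )
        edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        if not nodes:
            nodes = sorted(set(edges["source"]) | set(edges["target"]))
        return AssociationNetwork(tuple(nodes), edges, provenance)
    elif format == "graphml":
        g = nx.read_graphml(path)
        provenance = g.graph.get("provenance", "")
        return AssociationNetwork.from_networkx(g, provenance=provenance)
    else:
        raise UsageError(f"unknown network format {format!r}")
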