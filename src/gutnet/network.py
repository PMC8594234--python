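"""The association-network container shared by inference, topology and comparison.

An :class:`AssociationNetwork` is an undirected, signed, weighted graph over
taxa.  Each edge carries the estimated latent correlation (``weight``), a sign
label (co-occurrence for positive, co-exclusion for negative association) and
the permutation p-value under which it was retained.  ``provenance`` records
which niche subset (diet level, gut region, or the full design) the network
was inferred from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import UsageError

__all__ = ["AssociationNetwork", "SIGN_POSITIVE", "SIGN_NEGATIVE", "sign_label"]

SIGN_POSITIVE = "co-occurrence"
SIGN_NEGATIVE = "co-exclusion"

EDGE_COLUMNS = ["source", "target", "weight", "sign", "p_value"]


def sign_label(weight: float) -> str:
    return SIGN_POSITIVE if weight > 0 else SIGN_NEGATIVE


@dataclass
class AssociationNetwork:
    """Undirected signed weighted graph over taxa.

    Parameters
    ----------
    nodes:
        Taxon identifiers, including nodes of degree zero.
    edges:
        DataFrame with columns ``source, target, weight, sign, p_value``;
        each unordered pair appears exactly once and self-edges are invalid.
    provenance:
        Label of the niche subset the network was inferred from.
    params:
        Free-form record of inference parameters (lambda, n_perm, p threshold).
    """

    nodes: tuple
    edges: pd.DataFrame
    provenance: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = tuple(str(n) for n in self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise UsageError("duplicate node identifiers")
        edges = pd.DataFrame(self.edges, columns=EDGE_COLUMNS).copy()
        edges["source"] = edges["source"].astype(str)
        edges["target"] = edges["target"].astype(str)
        node_set = set(self.nodes)
        for col in ("source", "target"):
            unknown = set(edges[col]) - node_set
            if unknown:
                raise UsageError(f"edge endpoint(s) not in node list: {sorted(unknown)}")
        if (edges["source"] == edges["target"]).any():
            raise UsageError("self-edges are not allowed")
        keys = [frozenset((s, t)) for s, t in zip(edges["source"], edges["target"])]
        if len(set(keys)) != len(keys):
            raise UsageError("duplicate edges (each unordered pair may appear once)")
        # sign labels produced by the inference stage must agree with the
        # weight sign; externally supplied labels (e.g. "+"/"-") pass through.
        for w, s in zip(edges["weight"], edges["sign"]):
            if s in (SIGN_POSITIVE, SIGN_NEGATIVE) and sign_label(float(w)) != s:
                raise UsageError(f"edge sign label {s!r} contradicts weight {w}")
        self.edges = edges.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_keys(self) -> set:
        """Unordered node-pair identity of every edge."""
        return {
            tuple(sorted((s, t)))
            for s, t in zip(self.edges["source"], self.edges["target"])
        }

    def edge_signs(self) -> Mapping[tuple, str]:
        return {
            tuple(sorted((s, t))): sign
            for s, t, sign in zip(
                self.edges["source"], self.edges["target"], self.edges["sign"]
            )
        }

    def neighbors(self, node: str) -> set:
        """Neighbor set of ``node``; empty if absent from the network."""
        out = set()
        for s, t in zip(self.edges["source"], self.edges["target"]):
            if s == node:
                out.add(t)
            elif t == node:
                out.add(s)
        return out

    # -- conversions -------------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.source,
                row.target,
                weight=float(row.weight),
                sign=str(row.sign),
                p_value=float(row.p_value),
            )
        return g

    @classmethod
    def from_networkx(
        cls, g: nx.Graph, provenance: str = "", params: dict | None = None
    ) -> "AssociationNetwork":
        rows = []
        for u, v, data in g.edges(data=True):
            w = float(data.get("weight", 1.0))
            rows.append(
                {
                    "source": str(u),
                    "target": str(v),
                    "weight": w,
                    "sign": str(data.get("sign", sign_label(w))),
                    "p_value": float(data.get("p_value", 1.0)),
                }
            )
        edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        return cls(tuple(g.nodes()), edges, provenance, params or {})

    @classmethod
    def from_edges(
        cls,
        pairs: Iterable[tuple],
        nodes: Iterable[str] | None = None,
        provenance: str = "",
        weight: float = 1.0,
        params: dict | None = None,
    ) -> "AssociationNetwork":
        """Build an unweighted network (weight 1, p-value 1) from node pairs."""
        pairs = [tuple(map(str, p)) for p in pairs]
        if nodes is None:
            nodes = sorted({n for p in pairs for n in p})
        rows = [
            {
                "source": u,
                "target": v,
                "weight": weight,
                "sign": sign_label(weight),
                "p_value": 1.0,
            }
            for u, v in pairs
        ]
        edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
        return cls(tuple(nodes), edges, provenance, params or {})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationNetwork):
            return NotImplemented
        if set(self.nodes) != set(other.nodes):
            return False
        def canon(net):
            return {
                tuple(sorted((r.source, r.target))): (r.weight, r.sign, r.p_value)
                for r in net.edges.itertuples(index=False)
            }
        return canon(self) == canon(other)
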