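"""Node-level centralities, hub identification and case-control driver detection.

Hubs are nodes that rank highly on several centrality measures at once:
degree, closeness (short distance to any other node), betweenness (how often
the node lies on shortest paths between other pairs) and Kleinberg's hub
score (the principal eigenvector of the adjacency matrix; for an undirected
graph hub and authority scores coincide).

Drivers are nodes whose *rewiring* explains the difference between a case
network (one niche) and control networks (the other niches).  A node is a
driver of niche X when, against each other niche taken as control, it shows

* a low Jaccard index of its neighbour sets (JEI < 0.3),
* a high neighbour-shift score — the gain of exclusive interaction
  partners — (NESH > 1.8), and
* an increase of path-length-normalised betweenness (delta-B > 0; the
  literal non-zero reading is available as a switch).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import UsageError
from .network import AssociationNetwork
from .topology import topology_indices

__all__ = [
    "centralities",
    "kleinberg_hub_scores",
    "identify_hubs",
    "node_jei",
    "nesh_score",
    "delta_betweenness",
    "DriverResult",
    "identify_drivers",
]

CENTRALITY_MEASURES = ("degree", "closeness", "betweenness", "kleinberg_hub")


def _as_graph(net) -> nx.Graph:
    if isinstance(net, AssociationNetwork):
        return net.to_networkx()
    if isinstance(net, nx.Graph):
        return net
    raise UsageError(f"expected AssociationNetwork or networkx Graph, got {type(net)}")


def kleinberg_hub_scores(g: nx.Graph, tol: float = 1e-10,
                         max_iter: int = 10000) -> dict:
    """Principal-eigenvector scores of the adjacency matrix, max-normalised.

    Computed by power iteration on the (symmetric, non-negative) adjacency
    matrix; the limit is the Perron eigenvector, so entries are non-negative
    and the best-connected node scores exactly 1.
    """
    nodes = list(g.nodes())
    n = len(nodes)
    if n == 0:
        return {}
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    if a.sum() == 0:
        return {v: 0.0 for v in nodes}
    # shift by I so the dominant eigenvalue is strictly largest in modulus
    # (a bipartite adjacency has a -lambda_max eigenvalue that would make
    # plain power iteration oscillate); eigenvectors are unchanged
    a = a + np.eye(n)
    x = np.ones(n) / np.sqrt(n)
    for _ in range(max_iter):
        y = a @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    return dict(zip(nodes, x / x.max()))


def centralities(net) -> pd.DataFrame:
    """Degree, closeness, raw betweenness and Kleinberg hub score per node.

    Closeness uses the component-scaled convention (reachable count over sum
    of distances, scaled by the reachable fraction); betweenness is the raw
    count of unordered node pairs whose shortest paths pass through the node,
    with fractional credit for tied paths.  A ``betweenness_normalized``
    column divides by ``(N-1)(N-2)/2``.
    """
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise UsageError("centralities need at least 2 nodes")
    degree = dict(g.degree())
    closeness = nx.closeness_centrality(g)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    hub = kleinberg_hub_scores(g)
    denom = (n - 1) * (n - 2) / 2.0
    df = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "closeness": pd.Series(closeness),
            "betweenness": pd.Series(betweenness),
            "betweenness_normalized": pd.Series(
                {v: (b / denom if denom > 0 else 0.0)
                 for v, b in betweenness.items()}
            ),
            "kleinberg_hub": pd.Series(hub),
        }
    )
    df.index.name = "node"
    return df.loc[list(g.nodes())]


def identify_hubs(
    net,
    top_fraction: float = 0.2,
    min_criteria: int = 3,
) -> set:
    """Nodes in the top ``ceil(top_fraction * N)`` on >= ``min_criteria``
    of the four centralities; ties at the cutoff are all included."""
    cent = centralities(net)
    n = len(cent)
    if n < 5:
        raise UsageError("hub identification needs at least 5 nodes")
    k = int(np.ceil(top_fraction * n))
    votes = pd.Series(0, index=cent.index)
    for measure in CENTRALITY_MEASURES:
        scores = cent[measure]
        cutoff = scores.sort_values(ascending=False).iloc[k - 1]
        top = scores >= cutoff
        if scores.nunique() > 1:
            # ties at the cutoff count, but the measure's global minimum
            # cannot be "top" (sparse graphs put most nodes at 0)
            top &= scores > scores.min()
        votes[top] += 1
    hubs = set(votes.index[votes >= min_criteria])
    if len(hubs) == n:
        warnings.warn(
            "every node ties on the hub criteria (regular graph?); "
            "all nodes flagged",
            stacklevel=2,
        )
    return hubs


# ---------------------------------------------------------------------------
# case-control node metrics
# ---------------------------------------------------------------------------

def node_jei(neigh_control: set, neigh_case: set) -> float:
    """Jaccard index of a node's neighbour sets; both empty -> 1 (no rewiring)."""
    a, b = set(neigh_control), set(neigh_case)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def nesh_score(neigh_control: set, neigh_case: set) -> float:
    """Neighbour-shift score: growth in exclusive case partners.

    NESH = |B\\A| / |A u B| + |B\\A| / |B| with A the control and B the
    case neighbour set; 0 when the case set is empty or contained in the
    control set, 2 at complete turnover.
    """
    a, b = set(neigh_control), set(neigh_case)
    if not b:
        return 0.0
    gained = b - a
    union = a | b
    return len(gained) / len(union) + len(gained) / len(b)


def _betweenness_and_apl(net: AssociationNetwork) -> tuple:
    g = net.to_networkx()
    bet = nx.betweenness_centrality(g, normalized=False) if g.number_of_nodes() else {}
    apl = topology_indices(net).avg_path_length if g.number_of_nodes() else 0.0
    return bet, apl


def delta_betweenness(
    net_control: AssociationNetwork,
    net_case: AssociationNetwork,
    node: str,
) -> float:
    """Change of betweenness normalised by each network's average path length.

    delta-B = B_case / APL_case - B_control / APL_control with raw
    betweenness; a node absent from a network contributes betweenness 0, and
    a network with no connected pair (APL undefined) contributes 0 to the
    difference (flagged with a warning).
    """
    bet_ctl, apl_ctl = _betweenness_and_apl(net_control)
    bet_case, apl_case = _betweenness_and_apl(net_case)
    return _delta_b(bet_ctl, apl_ctl, bet_case, apl_case, node)


def _delta_b(bet_ctl, apl_ctl, bet_case, apl_case, node) -> float:
    def term(bet, apl):
        b = float(bet.get(node, 0.0))
        if apl <= 0:
            if b > 0:
                warnings.warn(
                    "network has no connected pair; its delta-B term is 0",
                    stacklevel=3,
                )
            return 0.0
        return b / apl

    return term(bet_case, apl_case) - term(bet_ctl, apl_ctl)


@dataclass(frozen=True)
class DriverResult:
    """Per-comparison metric table and the aggregated driver verdicts."""

    comparisons: pd.DataFrame  # node, case, control, jei, nesh, delta_b, passes
    drivers: pd.DataFrame      # node, niche, driver (bool)

    def driver_nodes(self, niche: str | None = None) -> set:
        d = self.drivers[self.drivers["driver"]]
        if niche is not None:
            d = d[d["niche"] == niche]
        return set(d["node"])


def identify_drivers(
    nets: Mapping[str, AssociationNetwork],
    jei_max: float = 0.3,
    nesh_min: float = 1.8,
    require_positive_delta: bool = True,
) -> DriverResult:
    """Multi-network driver detection with pairwise validation.

    A node is a driver of niche X iff, with X as case against *each* other
    niche as control, JEI < ``jei_max``, NESH > ``nesh_min`` and delta-B is
    positive (or merely non-zero when ``require_positive_delta=False``).
    The full metric table is emitted for every node and ordered pair.
    """
    niches = list(nets)
    if len(niches) < 2:
        raise UsageError("driver detection needs at least 2 networks")
    usable = {}
    for name, net in nets.items():
        if net.n_nodes == 0:
            warnings.warn(f"niche {name!r} has an empty network; skipped",
                          stacklevel=2)
            continue
        usable[name] = net
    if len(usable) < 2:
        raise UsageError("fewer than 2 non-empty networks")

    neigh = {
        name: {v: net.neighbors(v) for v in net.nodes}
        for name, net in usable.items()
    }
    bet_apl = {name: _betweenness_and_apl(net) for name, net in usable.items()}
    all_nodes = sorted(set().union(*(set(net.nodes) for net in usable.values())))

    rows = []
    for case, control in itertools.permutations(usable, 2):
        bet_case, apl_case = bet_apl[case]
        bet_ctl, apl_ctl = bet_apl[control]
        for v in all_nodes:
            nb_case = neigh[case].get(v, set())
            nb_ctl = neigh[control].get(v, set())
            jei = node_jei(nb_ctl, nb_case)
            nesh = nesh_score(nb_ctl, nb_case)
            db = _delta_b(bet_ctl, apl_ctl, bet_case, apl_case, v)
            ok_delta = db > 0 if require_positive_delta else db != 0
            rows.append(
                {
                    "node": v,
                    "case": case,
                    "control": control,
                    "jei": jei,
                    "nesh": nesh,
                    "delta_b": db,
                    "passes": bool(jei < jei_max and nesh > nesh_min and ok_delta),
                }
            )
    comparisons = pd.DataFrame(rows)

    verdicts = []
    for case in usable:
        sub = comparisons[comparisons["case"] == case]
        passed = sub.groupby("node")["passes"].all()
        for v in all_nodes:
            verdicts.append(
                {"node": v, "niche": case, "driver": bool(passed.get(v, False))}
            )
    drivers = pd.DataFrame(verdicts)
    return DriverResult(comparisons=comparisons, drivers=drivers)
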