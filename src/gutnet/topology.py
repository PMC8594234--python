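"""Whole-network topology: global indices, edge-set overlap, degree model.

All metrics are computed on the unweighted skeleton of the association
network (edge weights are carried only as attributes).  For disconnected
graphs the diameter is the maximum finite eccentricity and the average path
length averages over connected pairs only; "sub-clusters" are connected
components with at least two nodes.

The randomness of a network is judged from its degree sequence: a random
(Erdos-Renyi-like) graph has approximately Poisson-distributed degrees,
whereas a scale-free graph shows a power-law tail.  Both models are fit by
maximum likelihood on nodes of degree >= 1 and compared by AIC (the models
are non-nested, so a likelihood-ratio test would not apply).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import optimize, special, stats

from .errors import UsageError
from .network import AssociationNetwork

__all__ = [
    "TopologyReport",
    "DegreeFitReport",
    "topology_indices",
    "jaccard_edges",
    "edge_overlap",
    "classify_degree_distribution",
]


@dataclass(frozen=True)
class TopologyReport:
    n_nodes: int
    n_edges: int
    density: float
    diameter: int
    avg_path_length: float
    clustering_coefficient: float
    n_clusters: int
    positive_edge_fraction: float
    degree_distribution_class: str | None
    degree_skewness: float


@dataclass(frozen=True)
class DegreeFitReport:
    classification: str          # "random" or "scale_free"
    poisson_rate: float
    powerlaw_exponent: float
    loglik_poisson: float
    loglik_powerlaw: float
    aic_poisson: float
    aic_powerlaw: float
    degree_skewness: float
    degenerate: bool


def _as_graph(net) -> nx.Graph:
    if isinstance(net, AssociationNetwork):
        return net.to_networkx()
    if isinstance(net, nx.Graph):
        return net
    raise UsageError(f"expected AssociationNetwork or networkx Graph, got {type(net)}")


def topology_indices(net) -> TopologyReport:
    """Global topology indices of an association network."""
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n == 0:
        raise UsageError("topology indices undefined on an empty graph")
    m = g.number_of_edges()
    density = nx.density(g) if n >= 2 else 0.0
    clustering = nx.average_clustering(g) if n > 0 else 0.0

    diameter = 0
    total_dist = 0.0
    total_pairs = 0
    n_clusters = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        n_clusters += 1
        sub = g.subgraph(comp)
        ecc = nx.eccentricity(sub)
        diameter = max(diameter, max(ecc.values()))
        k = len(comp)
        pairs = k * (k - 1) // 2
        total_pairs += pairs
        total_dist += nx.average_shortest_path_length(sub) * pairs
    apl = total_dist / total_pairs if total_pairs else 0.0

    if isinstance(net, AssociationNetwork) and net.n_edges > 0:
        pos_frac = float((net.edges["weight"] > 0).mean())
    elif m > 0:
        weights = [d.get("weight", 1.0) for _, _, d in g.edges(data=True)]
        pos_frac = float(np.mean(np.asarray(weights) > 0))
    else:
        pos_frac = float("nan")

    degrees = np.array([d for _, d in g.degree()])
    skew = _degree_skew(degrees)

    dd_class = None
    if int((degrees >= 1).sum()) >= 5:
        dd_class = classify_degree_distribution(g).classification

    return TopologyReport(
        n_nodes=n,
        n_edges=m,
        density=float(density),
        diameter=int(diameter),
        avg_path_length=float(apl),
        clustering_coefficient=float(clustering),
        n_clusters=n_clusters,
        positive_edge_fraction=pos_frac,
        degree_distribution_class=dd_class,
        degree_skewness=skew,
    )


def jaccard_edges(net_a: AssociationNetwork, net_b: AssociationNetwork) -> float:
    """Jaccard edge index |E_a & E_b| / |E_a | E_b| on node-pair identity."""
    ea, eb = net_a.edge_keys(), net_b.edge_keys()
    union = ea | eb
    if not union:
        warnings.warn("both edge sets empty; Jaccard edge index defined as 1.0",
                      stacklevel=2)
        return 1.0
    return len(ea & eb) / len(union)


def edge_overlap(net_a: AssociationNetwork, net_b: AssociationNetwork) -> dict:
    """Shared / exclusive edge counts, including sign-flipped shared edges."""
    ea, eb = net_a.edge_keys(), net_b.edge_keys()
    shared = ea & eb
    signs_a, signs_b = net_a.edge_signs(), net_b.edge_signs()
    flipped = sum(1 for e in shared if signs_a[e] != signs_b[e])
    union = ea | eb
    return {
        "shared": len(shared),
        "only_a": len(ea - eb),
        "only_b": len(eb - ea),
        "sign_flipped": flipped,
        "jaccard": len(shared) / len(union) if union else 1.0,
    }


# ---------------------------------------------------------------------------
# degree-distribution model comparison
# ---------------------------------------------------------------------------

def _degree_skew(degrees: np.ndarray) -> float:
    if len(degrees) < 3 or np.ptp(degrees) == 0:
        return 0.0
    return float(stats.skew(degrees))


def _poisson_loglik(degrees: np.ndarray) -> tuple:
    rate = degrees.mean()
    ll = float(np.sum(stats.poisson.logpmf(degrees, rate)))
    return rate, ll


def _powerlaw_loglik(degrees: np.ndarray, kmin: int = 1) -> tuple:
    """Discrete power law p(k) = k^-alpha / zeta(alpha, kmin); MLE over alpha."""
    logs = np.sum(np.log(degrees))
    n = len(degrees)

    def nll(alpha):
        return n * np.log(special.zeta(alpha, kmin)) + alpha * logs

    res = optimize.minimize_scalar(nll, bounds=(1.0001, 12.0), method="bounded")
    alpha = float(res.x)
    return alpha, float(-res.fun)


def classify_degree_distribution(net) -> DegreeFitReport:
    """Poisson vs discrete power-law fit of the degree sequence, by AIC.

    Fits both one-parameter models to the degrees of nodes with degree >= 1
    and returns the lower-AIC model; ties and degenerate (all-equal) degree
    sequences classify as random.
    """
    g = _as_graph(net)
    degrees = np.array([d for _, d in g.degree() if d >= 1])
    if len(degrees) < 5:
        raise UsageError("need at least 5 nodes with degree >= 1")
    skew = _degree_skew(degrees)
    if np.all(degrees == degrees[0]):
        rate, ll_p = _poisson_loglik(degrees)
        return DegreeFitReport(
            classification="random",
            poisson_rate=rate,
            powerlaw_exponent=float("nan"),
            loglik_poisson=ll_p,
            loglik_powerlaw=float("nan"),
            aic_poisson=2 - 2 * ll_p,
            aic_powerlaw=float("nan"),
            degree_skewness=skew,
            degenerate=True,
        )
    rate, ll_p = _poisson_loglik(degrees)
    alpha, ll_pl = _powerlaw_loglik(degrees)
    aic_p = 2.0 - 2.0 * ll_p
    aic_pl = 2.0 - 2.0 * ll_pl
    label = "scale_free" if aic_pl < aic_p else "random"
    return DegreeFitReport(
        classification=label,
        poisson_rate=float(rate),
        powerlaw_exponent=alpha,
        loglik_poisson=ll_p,
        loglik_powerlaw=ll_pl,
        aic_poisson=aic_p,
        aic_powerlaw=aic_pl,
        degree_skewness=skew,
        degenerate=False,
    )
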