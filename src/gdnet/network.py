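"""Directed dependency network: construction, topology, hubs, set overlap.

Edges point modulator -> target and carry the CMI score as ``weight`` plus
the permutation ``p_value``. A node's out-degree counts how many
phenotype-linked genes it modulates, which is why hub selection is by
out-degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .dependency import DependencyPair
from .io import GeneSet

__all__ = [
    "PowerLawFit",
    "HubParams",
    "OverlapResult",
    "build_network",
    "main_component",
    "degree_distribution",
    "fit_power_law",
    "select_hubs",
    "overlap_test",
    "write_network",
    "read_network",
]


@dataclass
class PowerLawFit:
    """Log-log least-squares fit of a degree distribution.

    ``exponent`` is the magnitude of the slope of log10(frequency) against
    log10(degree); ``correlation`` the magnitude of the Pearson correlation of
    the log-log points; ``r_square`` the coefficient of determination.
    """

    exponent: float
    correlation: float
    r_square: float
    n_points: int


@dataclass
class HubParams:
    hub_fraction: float = 0.20
    min_out_degree: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.hub_fraction <= 1:
            raise ValueError("hub_fraction must be in (0, 1]")
        if self.min_out_degree < 0:
            raise ValueError("min_out_degree must be >= 0")


@dataclass
class OverlapResult:
    overlap: int
    p_value: float
    universe_size: int
    set_a_size: int
    set_b_size: int


def build_network(pairs: list[DependencyPair]) -> nx.DiGraph:
    """One directed edge per significant pair; reciprocal edges are allowed."""
    net = nx.DiGraph()
    for p in pairs:
        if net.has_edge(p.modulator, p.target):
            raise ValueError(f"duplicate directed pair {p.modulator}->{p.target}")
        net.add_edge(p.modulator, p.target, weight=p.cmi, p_value=p.p_value)
    return net


def main_component(net: nx.DiGraph) -> nx.DiGraph:
    """Largest weakly connected component (direction ignored for connectivity).

    A tie in component size is broken toward the component containing the
    lexicographically smallest gene id, so the result is deterministic.
    """
    if net.number_of_nodes() == 0:
        return net.copy()
    comps = list(nx.weakly_connected_components(net))
    size = max(len(c) for c in comps)
    tied = [c for c in comps if len(c) == size]
    best = min(tied, key=lambda c: min(str(g) for g in c))
    return net.subgraph(best).copy()


def degree_distribution(net: nx.DiGraph, direction: str = "total") -> list[tuple[int, int]]:
    """(degree, number of nodes with that degree), zero-frequency degrees omitted."""
    if direction == "in":
        degs = [d for _, d in net.in_degree()]
    elif direction == "out":
        degs = [d for _, d in net.out_degree()]
    elif direction == "total":
        degs = [d for _, d in net.degree()]
    else:
        raise ValueError("direction must be 'in', 'out' or 'total'")
    if not degs:
        return []
    vals, counts = np.unique(degs, return_counts=True)
    return [(int(v), int(c)) for v, c in zip(vals, counts)]


def fit_power_law(dist: list[tuple[int, int]]) -> PowerLawFit:
    """Least-squares line on (log10 degree, log10 frequency) over degrees >= 1."""
    pts = [(k, f) for k, f in dist if k >= 1 and f >= 1]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 distinct positive degrees, got {len(pts)}")
    x = np.log10([k for k, _ in pts])
    y = np.log10([f for _, f in pts])
    if np.ptp(y) == 0:  # flat distribution: slope 0, no explainable variance
        return PowerLawFit(exponent=0.0, correlation=0.0, r_square=0.0, n_points=len(pts))
    res = stats.linregress(x, y)
    return PowerLawFit(
        exponent=float(abs(res.slope)),
        correlation=float(abs(res.rvalue)),
        r_square=float(res.rvalue**2),
        n_points=len(pts),
    )


def select_hubs(net: nx.DiGraph, params: HubParams = HubParams()) -> GeneSet:
    """Hubs = nodes above an out-degree cutoff.

    The cutoff d* is the smallest out-degree >= ``min_out_degree`` whose
    selection #{nodes with out-degree >= d*} does not exceed
    ``hub_fraction * N`` — i.e. the degree threshold whose yield is closest
    to the target fraction from below or equal. Selecting by cutoff (not by
    rank) means tied nodes are never split arbitrarily.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("cannot select hubs from an empty network")
    out_deg = dict(net.out_degree())
    target = params.hub_fraction * n
    degrees = np.array(sorted(out_deg.values()))
    # count of nodes with out-degree >= d is nonincreasing in d, so the first
    # d within budget is the closest-from-below threshold
    lo = max(params.min_out_degree, 1)
    cutoff = int(degrees.max()) + 1  # selects nobody; overwritten unless loop is empty
    for d in range(lo, max(int(degrees.max()) + 2, lo + 1)):
        count = int(np.sum(degrees >= d))
        if count <= target:
            cutoff = d
            break
    members = {g for g, dg in out_deg.items() if dg >= max(cutoff, params.min_out_degree)}
    return GeneSet(name=f"hubs_outdeg>={max(cutoff, params.min_out_degree)}", members=members)


def overlap_test(set_a: GeneSet, set_b: GeneSet, universe: GeneSet) -> OverlapResult:
    """Upper-tail hypergeometric test of |A ∩ B|.

    P(X >= overlap) with population ``|universe|``, ``|B|`` successes and
    ``|A|`` draws.
    """
    if not set_a.members <= universe.members:
        raise ValueError("set_a is not contained in the universe")
    if not set_b.members <= universe.members:
        raise ValueError("set_b is not contained in the universe")
    k = len(set_a.members & set_b.members)
    m, nb, na = len(universe), len(set_b), len(set_a)
    p = float(stats.hypergeom.sf(k - 1, m, nb, na))
    return OverlapResult(
        overlap=k, p_value=min(p, 1.0),
        universe_size=m, set_a_size=na, set_b_size=nb,
    )


def write_network(net: nx.DiGraph, edge_path, node_path, hubs: GeneSet | None = None) -> None:
    """Edge table (modulator, target, cmi, p_value) + node table with degrees."""
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("modulator\ttarget\tcmi\tp_value\n")
        for u, v, d in sorted(net.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['weight']:.6g}\t{d['p_value']:.6g}\n")
    hub_members = hubs.members if hubs is not None else set()
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("gene\tin_degree\tout_degree\tis_hub\n")
        for g in sorted(net.nodes()):
            fh.write(
                f"{g}\t{net.in_degree(g)}\t{net.out_degree(g)}\t{int(g in hub_members)}\n"
            )


def read_network(edge_path) -> nx.DiGraph:
    net = nx.DiGraph()
    with open(edge_path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("modulator\ttarget"):
            raise ValueError(f"{edge_path}: not an edge table")
        for line in fh:
            if not line.strip():
                continue
            u, v, w, p = line.rstrip("\n").split("\t")
            net.add_edge(u, v, weight=float(w), p_value=float(p))
    return net
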