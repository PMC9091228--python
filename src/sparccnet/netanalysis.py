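"""Co-occurrence network construction, topology, hubs, and robustness.

Group-level networks connect CAGs (or taxa) whose abundances show a
significant Spearman correlation (default p < 0.05, unadjusted); edges are
signed by the correlation's sign. Topology summaries cover edge counts,
average degree and the degree sequence; hubs ("keystone taxa") are nodes
holding more than a set share (default 4%) of all connections.

Robustness measures how gradually the network falls apart under random
node removal: nodes are deleted one by one in a random order, the fraction
of nodes in the largest connected component (LCC) is recorded after each
deletion, curves are aggregated across replicates by the pointwise median,
and R is the mean of the median curve. For a complete graph R is exactly
(N-1)/(2N) regardless of order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
from scipy import stats as sps

from .io import AbundanceTable

__all__ = [
    "MicrobialNetwork",
    "RobustnessResult",
    "HubReport",
    "cooccurrence_network",
    "network_stats",
    "find_hubs",
    "robustness",
    "degree_loglog_summary",
]


@dataclass
class MicrobialNetwork:
    """Undirected network over a fixed node set; edges carry Spearman rho,
    the p-value they passed, and a sign."""

    graph: nx.Graph = field(repr=False)
    p_thresh: float | None = None

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    @classmethod
    def from_edges(cls, nodes, edges) -> "MicrobialNetwork":
        """Build from explicit (u, v[, attrs]) pairs over a node list."""
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for e in edges:
            u, v = e[0], e[1]
            attrs = e[2] if len(e) > 2 else {}
            if u == v:
                raise ValueError("self-edges are not allowed")
            g.add_edge(u, v, **attrs)
        return cls(graph=g)


@dataclass
class RobustnessResult:
    """Median LCC-fraction curve sigma(i/N) for i = 1..N and its mean R."""

    fragility_curve: np.ndarray
    R: float
    n_reps: int
    seed: int | None

    @property
    def removal_fractions(self) -> np.ndarray:
        n = self.fragility_curve.size
        return np.arange(1, n + 1) / n


@dataclass
class HubReport:
    """Node degrees, degree shares, and which nodes exceed the hub share."""

    degrees: dict
    shares: dict
    hubs: list
    share_thresh: float


# ---------------------------------------------------------------------------
# Spearman edge significance


@lru_cache(maxsize=16)
def _exact_spearman_null(S: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of sum d^2 over all S! rank permutations (no ties).

    Returns (unique sum-d^2 values, counts). Cached; used for S < 10 where
    the t-approximation is unreliable.
    """
    base = np.arange(S)
    perms = np.array(list(itertools.permutations(range(S))), dtype=np.int64)
    d2 = ((perms - base) ** 2).sum(axis=1)
    return np.unique(d2, return_counts=True)


def _exact_spearman_p(rho: float, S: int) -> float:
    """Two-sided exact p for Spearman rho (no ties): P(|rho*| >= |rho|)."""
    vals, counts = _exact_spearman_null(S)
    scale = S * (S**2 - 1) / 6.0
    rho_null = 1.0 - vals / scale
    total = counts.sum()
    mask = np.abs(rho_null) >= abs(rho) - 1e-12
    return float(counts[mask].sum() / total)


def cooccurrence_network(
    cag_table: AbundanceTable, p_thresh: float = 0.05
) -> MicrobialNetwork:
    """Network over the table's columns with edges where Spearman p < p_thresh.

    No multiplicity adjustment is applied. For S >= 10 samples p-values use
    the asymptotic t-approximation; for smaller cohorts the exact
    permutation null is used (falling back to the approximation when ties
    make the tie-free exact null invalid). Constant columns have undefined
    correlation and receive no edges.
    """
    if not 0 < p_thresh < 1:
        raise ValueError("p_thresh must be in (0, 1)")
    S = cag_table.n_samples
    if S < 4:
        raise ValueError("Spearman edge significance needs S >= 4 samples")
    vals = cag_table.values
    ids = cag_table.taxon_ids
    D = len(ids)
    g = nx.Graph()
    g.add_nodes_from(ids)
    constant = vals.std(axis=0) == 0
    for i in range(D):
        for j in range(i + 1, D):
            if constant[i] or constant[j]:
                continue
            rho, p = sps.spearmanr(vals[:, i], vals[:, j])
            if not np.isfinite(rho):
                continue
            if S < 10:
                ties = (
                    len(np.unique(vals[:, i])) < S or len(np.unique(vals[:, j])) < S
                )
                if not ties:
                    p = _exact_spearman_p(rho, S)
            if p < p_thresh:
                g.add_edge(
                    ids[i],
                    ids[j],
                    rho=float(rho),
                    p=float(p),
                    sign="positive" if rho >= 0 else "negative",
                    weight=float(rho),
                )
    return MicrobialNetwork(graph=g, p_thresh=p_thresh)


# ---------------------------------------------------------------------------
# topology


def network_stats(net: MicrobialNetwork) -> dict:
    """Edge count, average degree 2E/N, and descending degree sequence."""
    N = net.n_nodes
    E = net.edge_count
    degs = sorted((d for _, d in net.graph.degree()), reverse=True)
    return {
        "edge_count": E,
        "average_degree": (2.0 * E / N) if N else 0.0,
        "degree_sequence": degs,
    }


def degree_loglog_summary(net: MicrobialNetwork) -> dict:
    """Degree-frequency pairs and a log-log OLS slope for scale-free
    inspection (no formal power-law fit is attempted)."""
    degs = np.array([d for _, d in net.graph.degree()])
    ks, counts = np.unique(degs[degs > 0], return_counts=True)
    out = {"degree": ks.tolist(), "count": counts.tolist(), "loglog_slope": None}
    if ks.size >= 3:
        slope, _, _, _, _ = sps.linregress(np.log(ks), np.log(counts))
        out["loglog_slope"] = float(slope)
    return out


def find_hubs(net: MicrobialNetwork, share_thresh: float = 0.04) -> HubReport:
    """Flag nodes holding more than ``share_thresh`` of all connections.

    Degree share is degree / sum of degrees; on a complete graph every node
    exceeds 4% once N <= 25 (degenerate but correct).
    """
    if net.edge_count == 0:
        raise ValueError("hub detection is undefined on an edgeless network")
    degrees = dict(net.graph.degree())
    total = sum(degrees.values())
    shares = {n: d / total for n, d in degrees.items()}
    hubs = [n for n, s in shares.items() if s > share_thresh]
    return HubReport(degrees=degrees, shares=shares, hubs=hubs, share_thresh=share_thresh)


# ---------------------------------------------------------------------------
# robustness under random node removal


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, x: int, y: int) -> int:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return self.size[rx]
        if self.size[rx] < self.size[ry]:
            rx, ry = ry, rx
        self.parent[ry] = rx
        self.size[rx] += self.size[ry]
        return self.size[rx]


def robustness(
    net: MicrobialNetwork, n_reps: int = 1000, seed: int | None = None
) -> RobustnessResult:
    """Random-removal robustness R of a network.

    Per replicate, nodes are removed in a uniformly random order and the
    LCC fraction sigma recorded after each removal (an empty graph has LCC
    0). The curve is the pointwise median over replicates and
    R = (1/N) * sum_i sigma(i/N). Computed by the reverse (percolation)
    process with union-find, which is exactly equivalent and O(N+E) per
    replicate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    N = net.n_nodes
    if N < 1:
        raise ValueError("network has no nodes")
    idx = {n: i for i, n in enumerate(net.nodes)}
    adj: list[list[int]] = [[] for _ in range(N)]
    for u, v in net.graph.edges():
        adj[idx[u]].append(idx[v])
        adj[idx[v]].append(idx[u])
    rng = np.random.default_rng(seed)
    curves = np.empty((n_reps, N))
    for r in range(n_reps):
        order = rng.permutation(N)
        # removal order = order; adding back in reverse, lcc_after[i] is the
        # LCC with nodes order[i:] present, for i = N-1 .. 1; after all N
        # removals the LCC is 0.
        uf = _UnionFind(N)
        present = np.zeros(N, dtype=bool)
        largest = 0
        lcc_after = np.empty(N)
        lcc_after[N - 1] = 0.0
        for pos in range(N - 1, 0, -1):
            node = order[pos]
            present[node] = True
            largest = max(largest, 1)
            for nb in adj[node]:
                if present[nb]:
                    largest = max(largest, uf.union(node, nb))
            lcc_after[pos - 1] = largest / N
        curves[r] = lcc_after
    curve = np.median(curves, axis=0)
    return RobustnessResult(
        fragility_curve=curve, R=float(curve.mean()), n_reps=n_reps, seed=seed
    )


# ---------------------------------------------------------------------------
# serialisation


def write_network(net: MicrobialNetwork, path, format: str = "tsv") -> None:
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "tsv":
        import pandas as pd

        rows = [
            (u, v, d.get("rho", d.get("weight", 1.0)), d.get("p", np.nan), d.get("sign", ""))
            for u, v, d in net.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["node_i", "node_j", "rho", "p", "sign"]).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def write_robustness_curve(res: RobustnessResult, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"removed_fraction": res.removal_fractions, "sigma_median": res.fragility_curve}
    ).to_csv(path, index=False, float_format="%.17g")
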