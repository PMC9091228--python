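"""Co-abundance groups (CAGs): null-calibrated SparCC edges and clustering.

Taxa whose abundances co-vary are grouped into CAGs and treated as single
ecological units downstream. Edges require both a correlation above a hard
threshold (default rho > 0.4, positive side only) and a pseudo p-value
below 0.05 from resampling. A plain bootstrap of rho-hat does not test a
null, so the default resampling scheme shuffles each taxon column
independently across samples (destroying all pairwise association while
preserving marginals) and compares |rho*| against |rho_obs|; a
sign-stability bootstrap is available behind ``method="bootstrap"``.

CAGs are the connected components of the kept-edge graph; components of 3+
taxa are refined by average-linkage clustering on distance 1 - rho cut at
1 - r_thresh, so every reported group keeps average within-group
correlation above the threshold. Taxa with no kept edge become singletons,
keeping downstream abundance tables total-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .io import AbundanceTable
from .sparcc import CorrelationMatrix, sparcc_correlation

__all__ = [
    "BootstrapResult",
    "CAGPartition",
    "bootstrap_sparcc",
    "cluster_cags",
    "cag_abundance",
]


@dataclass
class BootstrapResult:
    """Observed SparCC correlations with resampling pseudo p-values."""

    rho_obs: CorrelationMatrix
    pvals: np.ndarray
    n_boot: int
    seed: int | None
    method: str = "permutation"


@dataclass
class CAGPartition:
    """Taxon -> CAG assignment; CAG ids are contiguous integers from 1."""

    assignment: dict = field(repr=False)
    n_cags: int
    linkage_criterion: dict = None

    def members(self) -> dict:
        out: dict = {}
        for taxon, cid in self.assignment.items():
            out.setdefault(cid, []).append(taxon)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon_id": list(self.assignment), "cag_id": list(self.assignment.values())}
        )


def bootstrap_sparcc(
    table: AbundanceTable,
    n_boot: int = 100,
    seed: int | None = None,
    method: str = "permutation",
    pseudocount: float = 0.5,
) -> BootstrapResult:
    """SparCC correlations with resampling pseudo p-values.

    ``method="permutation"`` (default): each replicate shuffles every taxon
    column independently across samples and recomputes rho; the two-sided
    pseudo p-value is (1 + #{|rho*| >= |rho_obs|}) / (n_boot + 1), which
    floors p at 1/(n_boot+1).

    ``method="bootstrap"``: samples are resampled with replacement and the
    p-value is the two-sided sign-stability fraction of the bootstrap
    distribution (no true null; kept for parity with common pipelines).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if method not in ("permutation", "bootstrap"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    rho_obs = sparcc_correlation(table, pseudocount=pseudocount)
    vals = table.values
    S, D = vals.shape
    abs_obs = np.abs(rho_obs.rho)
    if method == "permutation":
        exceed = np.zeros((D, D))
        for _ in range(n_boot):
            shuf = np.empty_like(vals)
            for j in range(D):
                shuf[:, j] = vals[rng.permutation(S), j]
            rep = AbundanceTable(
                pd.DataFrame(shuf, index=table.data.index, columns=table.data.columns),
                kind="counts" if table.kind == "counts" else "relative",
            )
            rho_star = sparcc_correlation(rep, pseudocount=pseudocount)
            exceed += np.abs(rho_star.rho) >= abs_obs
        pvals = (exceed + 1.0) / (n_boot + 1.0)
    else:
        pos = np.zeros((D, D))
        neg = np.zeros((D, D))
        for _ in range(n_boot):
            idx = rng.integers(0, S, size=S)
            rep = AbundanceTable(
                pd.DataFrame(
                    vals[idx],
                    index=[f"b{i}" for i in range(S)],
                    columns=table.data.columns,
                ),
                kind=table.kind,
            )
            rho_star = sparcc_correlation(rep, pseudocount=pseudocount)
            pos += rho_star.rho >= 0
            neg += rho_star.rho <= 0
        tail = np.minimum(pos, neg) / n_boot
        pvals = np.minimum(2.0 * tail + 1.0 / (n_boot + 1.0), 1.0)
    pvals = 0.5 * (pvals + pvals.T)
    np.fill_diagonal(pvals, 0.0)
    return BootstrapResult(rho_obs=rho_obs, pvals=pvals, n_boot=n_boot, seed=seed, method=method)


def cluster_cags(
    result: BootstrapResult,
    r_thresh: float = 0.4,
    p_thresh: float = 0.05,
    use_absolute: bool = False,
    refine_min_size: int = 3,
) -> CAGPartition:
    """Partition taxa into CAGs from thresholded correlations.

    Edges: rho_obs > r_thresh (|rho_obs| > r_thresh with ``use_absolute``)
    and p < p_thresh. Connected components of the edge graph are the
    initial groups; components of at least ``refine_min_size`` taxa are
    refined by average linkage on 1 - rho cut at 1 - r_thresh. CAG ids are
    assigned contiguously in order of each group's first taxon.
    """
    if not (0 < r_thresh < 1) or not (0 < p_thresh < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    rho = result.rho_obs.rho
    taxa = result.rho_obs.taxon_ids
    D = len(taxa)
    score = np.abs(rho) if use_absolute else rho
    adj = (score > r_thresh) & (result.pvals < p_thresh)
    np.fill_diagonal(adj, False)
    adj = adj | adj.T
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)

    groups: list[list[int]] = []
    for c in range(n_comp):
        idx = np.flatnonzero(comp == c)
        if idx.size >= refine_min_size:
            sub = rho[np.ix_(idx, idx)]
            dist = 1.0 - (np.abs(sub) if use_absolute else sub)
            np.fill_diagonal(dist, 0.0)
            dist = np.maximum(0.5 * (dist + dist.T), 0.0)
            lab = fcluster(
                linkage(squareform(dist, checks=False), method="average"),
                t=1.0 - r_thresh,
                criterion="distance",
            )
            for sub_lab in np.unique(lab):
                groups.append(list(idx[lab == sub_lab]))
        else:
            groups.append(list(idx))

    groups.sort(key=lambda g: min(g))
    assignment = {}
    for cid, g in enumerate(groups, start=1):
        for i in g:
            assignment[taxa[i]] = cid
    return CAGPartition(
        assignment=assignment,
        n_cags=len(groups),
        linkage_criterion={
            "edges": "components",
            "refinement": "average-linkage, 1-rho distance",
            "cut": 1.0 - r_thresh,
            "r_thresh": r_thresh,
            "p_thresh": p_thresh,
            "use_absolute": use_absolute,
            "refine_min_size": refine_min_size,
        },
    )


def cag_abundance(table: AbundanceTable, partition: CAGPartition) -> AbundanceTable:
    """Aggregate member abundances per CAG (samples x CAGs).

    Sums preserve each sample's total abundance exactly, so a relative
    input stays relative.
    """
    missing = [t for t in table.taxon_ids if t not in partition.assignment]
    if missing:
        raise ValueError(f"taxa not covered by the partition: {missing[:5]}")
    cols = {}
    for cid, members in sorted(partition.members().items()):
        present = [m for m in members if m in table.data.columns]
        cols[f"CAG{cid}"] = table.data[present].sum(axis=1)
    out = pd.DataFrame(cols, index=table.data.index)
    kind = table.kind if out.shape[1] >= 2 else "counts"
    if out.shape[1] < 2:
        raise ValueError("fewer than 2 CAGs; downstream correlation undefined")
    return AbundanceTable(out, kind=kind)
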