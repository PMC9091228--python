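"""Single-sample SparCC networks (SSNs).

The closed-form SparCC correlation is a sum over samples; each summand,
built from one sample's log-ratios against the cohort mean log-ratios, is
that sample's specific correlation contribution rho_ij^(k):

    rho_ij^(k) = [ b(a+1) (r_i^(k) + r_j^(k)) - 2 b T^(k) - d_ij^(k) ]
                 / (2 S omega_i omega_j),

where d_ij^(k) = (log(x_i/x_j)^(k) - mu_ij)^2, r_i^(k) = sum_j d_ij^(k),
T^(k) = sum_ij d_ij^(k). The cohort statistics mu and omega come from all S
samples (no leave-one-out), so sum_k rho^(k) equals the unclipped
population rho exactly — the identity every build rests on.

Thresholding |rho_ij^(k)| yields one signed weighted network per
individual. No criterion for what counts as an edge is canonical; the edge
rule (magnitude threshold or top-quantile) is an explicit, recorded choice,
with a helper that picks a cohort-wide threshold from a target median
density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AbundanceTable, to_relative
from .sparcc import basis_variances, log_ratio_stats

__all__ = [
    "SampleCorrelationTensor",
    "SingleSampleNetwork",
    "decompose",
    "build_ssn",
    "build_all_ssns",
    "choose_tau",
    "ssn_attributes",
]


@dataclass
class SampleCorrelationTensor:
    """Per-sample correlation contributions rho_ij^(k), S x D x D.

    Slices are symmetric and sum over k to the unclipped population
    correlation. Unclipped values are used throughout so the identity is
    exact.
    """

    rho_k: np.ndarray
    sample_ids: list
    taxon_ids: list
    rho_total: np.ndarray = None  # unclipped population rho (= rho_k.sum(0))

    @property
    def n_samples(self) -> int:
        return self.rho_k.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.rho_k.shape[1]


@dataclass
class SingleSampleNetwork:
    """One individual's network: signed weighted edges over the taxon set."""

    sample_id: object
    taxon_ids: list
    edges: list = field(repr=False)  # (taxon_i, taxon_j, weight, sign)
    edge_rule: dict = None

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.edge_count / len(self.taxon_ids)


def decompose(table: AbundanceTable, pseudocount: float = 0.5) -> SampleCorrelationTensor:
    """Split the SparCC correlation into per-sample contributions.

    Step 1 estimates mu and omega from all S samples; Step 2 evaluates each
    sample's summand; Step 3 iterates over samples (vectorised here).
    """
    if table.n_samples < 2:
        raise ValueError("per-sample decomposition needs S >= 2 samples")
    if table.kind != "relative" or np.any(table.values <= 0):
        table = to_relative(table, pseudocount=pseudocount)
    stats = log_ratio_stats(table)
    basis = basis_variances(stats)
    z = stats.z  # S x D centred logs: (log x_i^(k) - mean log x_i), so
    # z_i^(k) - z_j^(k) = log(x_i/x_j)^(k) - mu_ij
    S, D = z.shape
    a, b = basis.a, basis.b
    w = np.sqrt(basis.omega_sq)

    d = (z[:, :, None] - z[:, None, :]) ** 2            # S x D x D
    row = d.sum(axis=2)                                  # S x D
    tot = d.sum(axis=(1, 2))                             # S
    denom = 2.0 * S * np.outer(w, w)
    rho_k = (
        b * (a + 1.0) * (row[:, :, None] + row[:, None, :])
        - 2.0 * b * tot[:, None, None]
        - d
    ) / denom
    return SampleCorrelationTensor(
        rho_k=rho_k,
        sample_ids=table.sample_ids,
        taxon_ids=table.taxon_ids,
        rho_total=rho_k.sum(axis=0),
    )


def _upper_pairs(D: int):
    iu = np.triu_indices(D, k=1)
    return iu


def choose_tau(tensor: SampleCorrelationTensor, target_density: float = 0.10) -> float:
    """Magnitude threshold giving a median SSN density near ``target_density``.

    For each sample the |rho^(k)| quantile that would retain the target
    fraction of candidate pairs is found; tau is the median of those
    per-sample thresholds, so edge counts stay comparable across
    individuals while tau remains a single reportable number.
    """
    if not 0 < target_density <= 1:
        raise ValueError("target_density must be in (0, 1]")
    iu = _upper_pairs(tensor.n_taxa)
    mags = np.abs(tensor.rho_k[:, iu[0], iu[1]])  # S x P
    per_sample = np.quantile(mags, 1.0 - target_density, axis=1)
    return float(np.median(per_sample))


def build_ssn(
    tensor: SampleCorrelationTensor,
    k: int,
    tau: float | None = None,
    top_q: float | None = None,
) -> SingleSampleNetwork:
    """Threshold sample k's correlation slice into a network.

    Exactly one of ``tau`` (keep pairs with |rho^(k)| >= tau) or ``top_q``
    (keep the top-q fraction of pairs by magnitude) must be given. Ties are
    broken lexicographically by pair index.
    """
    if not 0 <= k < tensor.n_samples:
        raise IndexError(f"sample index {k} out of range")
    if (tau is None) == (top_q is None):
        raise ValueError("specify exactly one of tau or top_q")
    D = tensor.n_taxa
    iu = _upper_pairs(D)
    wts = tensor.rho_k[k][iu]
    mags = np.abs(wts)
    if tau is not None:
        if tau < 0:
            raise ValueError("tau must be non-negative")
        keep = np.flatnonzero(mags >= tau)
        rule = {"rule": "magnitude", "tau": float(tau)}
    else:
        if not 0 < top_q <= 1:
            raise ValueError("top_q must be in (0, 1]")
        P = mags.size
        n_keep = int(np.ceil(top_q * P))
        # stable lexicographic tie-break: pairs are already in lex order
        order = np.argsort(-mags, kind="stable")
        keep = np.sort(order[:n_keep])
        rule = {"rule": "top_q", "q": float(top_q)}
    taxa = tensor.taxon_ids
    edges = [
        (taxa[iu[0][p]], taxa[iu[1][p]], float(wts[p]), "positive" if wts[p] >= 0 else "negative")
        for p in keep
    ]
    return SingleSampleNetwork(
        sample_id=tensor.sample_ids[k], taxon_ids=list(taxa), edges=edges, edge_rule=rule
    )


def build_all_ssns(
    tensor: SampleCorrelationTensor,
    tau: float | None = None,
    top_q: float | None = None,
    target_density: float = 0.10,
) -> list[SingleSampleNetwork]:
    """One SSN per individual under a shared edge rule.

    When neither ``tau`` nor ``top_q`` is given, tau is chosen by
    :func:`choose_tau` at ``target_density``.
    """
    if tau is None and top_q is None:
        tau = choose_tau(tensor, target_density)
    return [build_ssn(tensor, k, tau=tau, top_q=top_q) for k in range(tensor.n_samples)]


def ssn_attributes(net: SingleSampleNetwork) -> dict:
    """Scalar network attributes used downstream as predictors."""
    return {"edge_count": net.edge_count, "mean_degree": net.mean_degree}


def write_ssn(net: SingleSampleNetwork, path) -> None:
    """Edge-list TSV: taxon_i, taxon_j, weight, sign."""
    import pandas as pd

    pd.DataFrame(net.edges, columns=["taxon_i", "taxon_j", "weight", "sign"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def ssn_to_graphml(net: SingleSampleNetwork, path) -> None:
    import networkx as nx

    g = nx.Graph(sample_id=str(net.sample_id))
    g.add_nodes_from(net.taxon_ids)
    for i, j, wgt, sign in net.edges:
        g.add_edge(i, j, weight=wgt, sign=sign)
    nx.write_graphml(g, path)
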