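"""Closed-form SparCC estimation of basis correlations from compositions.

Compositional data (relative abundances summing to 1 per sample) induce
spurious correlations. SparCC works on log-ratios, which are invariant to
the normalisation: t_ij = Var[log(x_i/x_j)] equals the log-ratio variance
of the latent absolute ("basis") abundances w. Under a sparsity assumption
(average basis correlation ~ 0), the basis log-variances omega_i^2 have the
analytic solution

    omega_i^2 = b (a + 1) sum_j t_ij  -  b sum_ij t_ij,
    a = 2 D - 3,   b = 1 / (2 (D - 1) (D - 2)),

and the basis correlation follows by inverting
t_ij = omega_i^2 + omega_j^2 - 2 rho_ij omega_i omega_j.

Variances are population variances (divide by S): the per-sample
decomposition in :mod:`sparccnet.ssn` carries an explicit 1/S prefactor and
only sums back to rho under this convention. The classical iterative
strong-pair-exclusion refinement of SparCC is deliberately not applied; the
one-pass analytic solution is the estimator throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import AbundanceTable, to_relative

__all__ = [
    "LogRatioStats",
    "BasisVariances",
    "CorrelationMatrix",
    "log_ratio_stats",
    "basis_variances",
    "sparcc_correlation",
]

OMEGA_FLOOR = 1e-12


@dataclass
class LogRatioStats:
    """Pairwise log-ratio variances t_ij and mean log-ratios mu_ij."""

    t: np.ndarray          # D x D, symmetric, zero diagonal
    mu: np.ndarray         # D x D, antisymmetric: mean_k log(x_i/x_j)
    n_samples: int
    taxon_ids: list
    z: np.ndarray = None   # S x D centred log abundances (internal reuse)

    @property
    def n_taxa(self) -> int:
        return self.t.shape[0]


@dataclass
class BasisVariances:
    """Basis log-variances omega_i^2 with the analytic constants a, b.

    ``omega_sq`` is floored at a small positive epsilon so square roots stay
    real; ``omega_sq_raw`` keeps the unfloored closed-form values, which the
    correlation numerator uses so the per-sample decomposition identity
    stays exact even when flooring fires.
    """

    omega_sq: np.ndarray
    a: float
    b: float
    floored: np.ndarray = None       # bool mask of entries clamped to the floor
    omega_sq_raw: np.ndarray = None


@dataclass
class CorrelationMatrix:
    """SparCC correlation estimate; rho is clipped to [-1, 1], the raw
    closed-form values are kept in rho_unclipped for the exact
    decomposition identity."""

    rho: np.ndarray
    taxon_ids: list
    rho_unclipped: np.ndarray = None

    @property
    def n_taxa(self) -> int:
        return self.rho.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rho, index=self.taxon_ids, columns=self.taxon_ids)


def _require_positive_relative(table: AbundanceTable) -> np.ndarray:
    if table.kind != "relative":
        raise ValueError("expected a relative-abundance table (use to_relative)")
    x = table.values
    if np.any(x <= 0):
        raise ValueError(
            "zero abundances present; apply a pseudocount before log-ratios"
        )
    return x


def log_ratio_stats(table: AbundanceTable) -> LogRatioStats:
    """Compute t_ij = Var[log(x_i/x_j)] and mu_ij = mean[log(x_i/x_j)].

    Population variance (divide by S). With centred log abundances
    z = log x - mean_k log x, t_ij = mean_k (z_i - z_j)^2, computed via the
    covariance expansion t = v_i + v_j - 2 C_ij.
    """
    x = _require_positive_relative(table)
    y = np.log(x)
    ybar = y.mean(axis=0)
    z = y - ybar
    S = y.shape[0]
    C = (z.T @ z) / S
    v = np.diag(C)
    t = v[:, None] + v[None, :] - 2.0 * C
    np.fill_diagonal(t, 0.0)
    t = np.maximum(t, 0.0)  # guard tiny negative round-off
    t = 0.5 * (t + t.T)
    mu = ybar[:, None] - ybar[None, :]
    return LogRatioStats(t=t, mu=mu, n_samples=S, taxon_ids=table.taxon_ids, z=z)


def basis_variances(stats: LogRatioStats) -> BasisVariances:
    """Solve for the basis log-variances under the sparsity assumption.

    Requires D >= 4: with a = 2D-3 and b = 1/(2(D-1)(D-2)) the solution
    needs D - 2 > 1 independent pair equations per taxon to be meaningful.
    Negative estimates (possible under strong dense correlation) are floored
    at a small epsilon with a warning.
    """
    D = stats.n_taxa
    if D < 4:
        raise ValueError(
            f"basis variance estimation needs D >= 4 taxa (got D={D}); "
            "b = 1/(2(D-1)(D-2)) leaves too few equations"
        )
    a = 2.0 * D - 3.0
    b = 1.0 / (2.0 * (D - 1.0) * (D - 2.0))
    row = stats.t.sum(axis=1)
    total = stats.t.sum()
    raw = b * (a + 1.0) * row - b * total
    floored = raw <= 0
    omega_sq = raw
    if floored.any():
        warnings.warn(
            f"{int(floored.sum())} basis variance estimate(s) non-positive; "
            f"floored at {OMEGA_FLOOR:g} (sparsity assumption likely violated)",
            RuntimeWarning,
            stacklevel=2,
        )
        omega_sq = np.where(floored, OMEGA_FLOOR, raw)
    return BasisVariances(omega_sq=omega_sq, a=a, b=b, floored=floored, omega_sq_raw=raw)


def correlation_from_stats(
    stats: LogRatioStats, basis: BasisVariances | None = None
) -> CorrelationMatrix:
    """Invert t_ij = w_i^2 + w_j^2 - 2 rho w_i w_j for rho."""
    if basis is None:
        basis = basis_variances(stats)
    w = np.sqrt(basis.omega_sq)
    denom = 2.0 * np.outer(w, w)
    num_sq = basis.omega_sq_raw if basis.omega_sq_raw is not None else basis.omega_sq
    raw = (num_sq[:, None] + num_sq[None, :] - stats.t) / denom
    rho = np.clip(raw, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    if not np.all(np.isfinite(raw)):
        warnings.warn("non-finite correlation entries replaced by 0", RuntimeWarning)
        raw = np.nan_to_num(raw, nan=0.0, posinf=1.0, neginf=-1.0)
        rho = np.clip(raw, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(rho=rho, taxon_ids=stats.taxon_ids, rho_unclipped=raw)


def sparcc_correlation(
    table: AbundanceTable, pseudocount: float = 0.5
) -> CorrelationMatrix:
    """One-pass SparCC correlation estimate for an abundance table.

    Count tables (or relative tables containing zeros) are converted with
    :func:`sparccnet.io.to_relative` using ``pseudocount`` first.
    """
    if table.kind != "relative" or np.any(table.values <= 0):
        table = to_relative(table, pseudocount=pseudocount)
    stats = log_ratio_stats(table)
    return correlation_from_stats(stats)


def write_correlation(corr: CorrelationMatrix, path) -> None:
    corr.to_frame().rename_axis("taxon_id").to_csv(path, sep="\t", float_format="%.17g")
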