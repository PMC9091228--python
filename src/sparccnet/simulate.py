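"""Synthetic compositional count tables and cohorts with planted structure.

The generative model is the minimal one consistent with the log-ratio
correlation estimand: latent log basis abundances are multivariate normal
with a chosen (sparse) correlation structure, exponentiated, closed to
proportions, and observed as multinomial counts at a fixed sequencing
depth (default 10,000 reads per sample, the rarefaction depth typical of
16S workflows). There is no zero-inflation by default.

Cohort simulation additionally plants a per-sample latent "connectivity"
score that (a) scales that sample's deviation from the cohort mean
log-composition — inflating its single-sample network edge weights — and
(b) drives the hepatic-fat response: hfc_change = c0 - effect*score +
noise, with c0 calibrated analytically so the expected responder fraction
(hfc_change < -5) matches the spec. The coupling direction mirrors the
finding that responders tend to have denser baseline networks; it is a
testability device, not an empirical claim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import AbundanceTable, CohortMetadata

__all__ = [
    "BasisModel",
    "CohortSpec",
    "independent_model",
    "planted_pairs_model",
    "block_model",
    "simulate_counts",
    "simulate_cohort",
]

PSD_REPAIR_TOL = 0.1


@dataclass
class BasisModel:
    """Log-normal basis: log w ~ N(log_mean, diag(sd) corr diag(sd))."""

    log_mean: np.ndarray
    log_sd: np.ndarray
    corr: np.ndarray
    taxon_ids: list = None

    def __post_init__(self) -> None:
        self.log_mean = np.asarray(self.log_mean, dtype=float)
        self.log_sd = np.asarray(self.log_sd, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        D = self.log_mean.size
        if self.log_sd.size != D or self.corr.shape != (D, D):
            raise ValueError("inconsistent model dimensions")
        if np.any(self.log_sd <= 0):
            raise ValueError("log_sd must be positive")
        if not np.allclose(self.corr, self.corr.T) or not np.allclose(np.diag(self.corr), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        if self.taxon_ids is None:
            self.taxon_ids = [f"T{i + 1}" for i in range(D)]

    @property
    def n_taxa(self) -> int:
        return self.log_mean.size

    def covariance(self) -> np.ndarray:
        cov = np.outer(self.log_sd, self.log_sd) * self.corr
        return _nearest_psd(cov)


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipping PSD repair; errors if the repair is too large."""
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() >= -1e-12:
        return cov
    shift = -float(vals.min())
    if shift > PSD_REPAIR_TOL * float(vals.max()):
        raise ValueError(
            f"correlation matrix is far from PSD (min eigenvalue {vals.min():.3g})"
        )
    warnings.warn(
        f"correlation matrix repaired to PSD (eigenvalues clipped at 0, "
        f"largest adjustment {shift:.3g})",
        RuntimeWarning,
        stacklevel=2,
    )
    floor = 1e-8 * float(vals.max())  # keep strictly PD for Cholesky sampling
    repaired = (vecs * np.maximum(vals, floor)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    scale = np.sqrt(np.diag(cov)) / np.where(d > 0, d, 1.0)
    return repaired * np.outer(scale, scale)


def independent_model(D: int, log_sd: float = 1.0, mean_spread: float = 2.0) -> BasisModel:
    """Independent taxa with log-means spread over ``mean_spread`` units
    (abundance heterogeneity without rare taxa dropping out at default
    depth)."""
    log_mean = np.linspace(0.0, -mean_spread, D)
    return BasisModel(log_mean, np.full(D, log_sd), np.eye(D))


def planted_pairs_model(
    D: int, pairs: list[tuple[int, int, float]], log_sd: float = 1.0, mean_spread: float = 2.0
) -> BasisModel:
    """Independent taxa plus explicit (i, j, rho) planted correlations."""
    model = independent_model(D, log_sd=log_sd, mean_spread=mean_spread)
    for i, j, rho in pairs:
        model.corr[i, j] = model.corr[j, i] = rho
    return BasisModel(model.log_mean, model.log_sd, model.corr)


def sparse_random_pairs(
    D: int,
    n_pairs: int,
    rho_low: float = 0.5,
    rho_high: float = 0.8,
    signed: bool = True,
    seed: int | None = None,
) -> list[tuple[int, int, float]]:
    """Disjoint (i, j, rho) planted pairs — each taxon in at most one pair,
    so the planted matrix is guaranteed PSD and the structure sparse."""
    if 2 * n_pairs > D:
        raise ValueError("too many pairs for D taxa")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(D)[: 2 * n_pairs]
    out = []
    for p in range(n_pairs):
        i, j = sorted((int(idx[2 * p]), int(idx[2 * p + 1])))
        rho = float(rng.uniform(rho_low, rho_high))
        if signed and rng.random() < 0.5:
            rho = -rho
        out.append((i, j, rho))
    return out


def block_model(
    n_blocks: int,
    block_size: int,
    within_rho: float = 0.7,
    log_sd: float = 1.0,
    mean_spread: float = 2.0,
) -> tuple[BasisModel, np.ndarray]:
    """Block-diagonal basis correlation; returns (model, block labels)."""
    D = n_blocks * block_size
    corr = np.eye(D)
    labels = np.repeat(np.arange(n_blocks), block_size)
    for b in range(n_blocks):
        idx = np.flatnonzero(labels == b)
        for i in idx:
            for j in idx:
                if i != j:
                    corr[i, j] = within_rho
    model = independent_model(D, log_sd=log_sd, mean_spread=mean_spread)
    return BasisModel(model.log_mean, model.log_sd, corr), labels


@dataclass
class CohortSpec:
    """Trial-scale cohort conditions.

    effect is in HFC percentage points per SD of the latent connectivity
    score; noise_scale is the residual SD of hfc_change in the same units.
    deviation_coupling scales how strongly the score inflates a sample's
    compositional deviation (log scale). Defaults emulate an intervention
    arm of ~20 individuals rarefied to 10,000 reads with a moderate,
    detectable network-outcome link.
    """

    n_samples: int = 20
    depth: int = 10000
    responder_fraction: float = 0.5
    effect: float = 4.0
    noise_scale: float = 4.0
    deviation_coupling: float = 0.5
    hfc_baseline_range: tuple = (5.0, 35.0)
    cutoff: float = -5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 < self.responder_fraction < 1:
            raise ValueError("responder_fraction must be in (0, 1)")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


def simulate_counts(
    model: BasisModel,
    S: int,
    depth: int = 10000,
    seed: int | None = None,
    return_latent: bool = False,
):
    """Draw S samples: log-normal basis -> proportions -> multinomial counts.

    With ``return_latent`` the latent log-basis matrix is returned alongside
    the table (for generative-truth checks on the pre-compositional draw).
    """
    if S < 2:
        raise ValueError("need S >= 2 samples")
    rng = np.random.default_rng(seed)
    cov = model.covariance()
    y = rng.multivariate_normal(model.log_mean, cov, size=S, method="cholesky")
    counts = _counts_from_logs(y, depth, rng)
    table = AbundanceTable(
        pd.DataFrame(
            counts,
            index=[f"S{i + 1}" for i in range(S)],
            columns=model.taxon_ids,
        ),
        kind="counts",
    )
    return (table, y) if return_latent else table


def _counts_from_logs(y: np.ndarray, depth: int, rng) -> np.ndarray:
    w = np.exp(y)
    props = w / w.sum(axis=1, keepdims=True)
    return np.vstack([rng.multinomial(depth, p) for p in props])


def simulate_cohort(
    model: BasisModel, spec: CohortSpec, seed: int | None = None
) -> tuple[AbundanceTable, CohortMetadata]:
    """Cohort with a planted connectivity-outcome coupling.

    The latent score s_k ~ N(0,1) multiplies the sample's log-scale
    deviation from the cohort mean by exp(deviation_coupling * s_k) and
    enters hfc_change = c0 - effect*s_k + noise_scale*eps. c0 is chosen in
    closed form so P(hfc_change < cutoff) equals responder_fraction. The
    score is stored in the metadata column ``connectivity_score`` as the
    planted ground truth.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    S = spec.n_samples
    cov = model.covariance()
    score = rng.standard_normal(S)
    eps = rng.multivariate_normal(np.zeros(model.n_taxa), cov, size=S, method="cholesky")
    y = model.log_mean + np.exp(spec.deviation_coupling * score)[:, None] * eps
    counts = _counts_from_logs(y, spec.depth, rng)
    sample_ids = [f"S{i + 1}" for i in range(S)]
    table = AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=model.taxon_ids), kind="counts"
    )

    tau = float(np.hypot(spec.effect, spec.noise_scale))
    # P(c0 + X < cutoff) = responder_fraction with X ~ N(0, tau)
    c0 = spec.cutoff - tau * norm.ppf(spec.responder_fraction)
    hfc_change = c0 - spec.effect * score + spec.noise_scale * rng.standard_normal(S)
    lo, hi = spec.hfc_baseline_range
    baseline = rng.uniform(lo, hi, size=S)
    meta = CohortMetadata(
        pd.DataFrame(
            {
                "group": "intervention",
                "hfc_baseline": baseline,
                "hfc_followup": baseline + hfc_change,
                "hfc_change": hfc_change,
                "connectivity_score": score,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return table, meta
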