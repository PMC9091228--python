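"""Predicting intervention responders from single-sample network features.

A responder is an individual whose hepatic fat content (HFC, % liver fat)
dropped by more than 5 percentage points over the intervention
(hfc_change < -5, strict). Prediction uses baseline single-sample networks
two ways:

* unsupervised — a scalar network attribute (edge count or mean degree)
  is scored directly against the labels by ROC/AUC;
* supervised — the per-sample edge weights (one column per taxon pair) feed
  a penalized linear model (Elastic-Net default, LASSO optional) of the
  post-intervention HFC level; predicted change (predicted level minus
  baseline) is thresholded by the responder rule and scored by ROC.

An ordinary least-squares regression of hfc_change on a network attribute
quantifies the attribute–outcome association directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import ElasticNet, ElasticNetCV, Lasso, LassoCV
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import KFold, LeaveOneOut, cross_val_predict

from .io import CohortMetadata
from .ssn import SingleSampleNetwork

__all__ = [
    "ResponderLabels",
    "EdgeFeatureMatrix",
    "RocResult",
    "PenalizedFit",
    "label_responders",
    "edge_matrix",
    "unsupervised_roc",
    "fit_penalized",
    "regress_attribute",
]

DEFAULT_CUTOFF = -5.0

RESPONDER = "responder"
NON_RESPONDER = "low/non-responder"


@dataclass
class ResponderLabels:
    """Binary outcome labels with the HFC-change cutoff that defined them."""

    sample_ids: list
    labels: np.ndarray  # bool, True = responder
    cutoff: float = DEFAULT_CUTOFF

    @property
    def names(self) -> list:
        return [RESPONDER if r else NON_RESPONDER for r in self.labels]

    @property
    def n_responders(self) -> int:
        return int(self.labels.sum())


@dataclass
class EdgeFeatureMatrix:
    """Samples x taxon-pairs matrix of SSN edge weights (0 where no edge).

    Columns are all D(D-1)/2 candidate pairs in lexicographic order of the
    shared taxon indexing, identical for every sample.
    """

    data: pd.DataFrame = field(repr=False)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    higher_score_predicts_responder: bool = True

    def youden(self) -> dict:
        j = self.sensitivity + self.specificity - 1.0
        k = int(np.argmax(j))
        return {
            "threshold": float(self.thresholds[k]),
            "sensitivity": float(self.sensitivity[k]),
            "specificity": float(self.specificity[k]),
            "J": float(j[k]),
        }


@dataclass
class PenalizedFit:
    model: str
    alpha: float
    l1_ratio: float
    coef: pd.Series = field(repr=False)
    intercept: float = 0.0
    predictions_resub: pd.Series = field(default=None, repr=False)
    predictions_cv: pd.Series = field(default=None, repr=False)
    roc_resub: RocResult = None
    roc_cv: RocResult = None
    predicted_labels_resub: list = None
    predicted_labels_cv: list = None

    @property
    def selected_features(self) -> list:
        return list(self.coef.index[self.coef != 0])


def label_responders(meta: CohortMetadata, cutoff: float = DEFAULT_CUTOFF) -> ResponderLabels:
    """Responder iff hfc_change < cutoff (strict); default cutoff -5."""
    change = meta.hfc_change.to_numpy(dtype=float)
    if np.any(np.isnan(change)):
        bad = [s for s, c in zip(meta.sample_ids, change) if np.isnan(c)]
        raise ValueError(f"hfc_change missing for samples: {bad}")
    return ResponderLabels(
        sample_ids=meta.sample_ids, labels=change < cutoff, cutoff=cutoff
    )


def edge_matrix(ssns: list[SingleSampleNetwork]) -> EdgeFeatureMatrix:
    """Stack SSNs into the samples x pairs edge-weight feature matrix."""
    if not ssns:
        raise ValueError("no networks given")
    taxa = ssns[0].taxon_ids
    for net in ssns[1:]:
        if net.taxon_ids != taxa:
            raise ValueError("all networks must share an identical taxon set")
    D = len(taxa)
    pos = {t: i for i, t in enumerate(taxa)}
    pairs = [(i, j) for i in range(D) for j in range(i + 1, D)]
    col_of = {p: c for c, p in enumerate(pairs)}
    mat = np.zeros((len(ssns), len(pairs)))
    for r, net in enumerate(ssns):
        for ti, tj, w, _sign in net.edges:
            i, j = pos[ti], pos[tj]
            mat[r, col_of[(min(i, j), max(i, j))]] = w
    cols = [f"{taxa[i]}|{taxa[j]}" for i, j in pairs]
    return EdgeFeatureMatrix(
        pd.DataFrame(mat, index=[n.sample_id for n in ssns], columns=cols)
    )


def _roc_from_scores(labels: np.ndarray, scores: np.ndarray) -> RocResult:
    fpr, tpr, thr = roc_curve(labels.astype(int), scores)
    auc = float(roc_auc_score(labels.astype(int), scores))
    return RocResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        higher_score_predicts_responder=auc >= 0.5,
    )


def unsupervised_roc(attribute, labels: ResponderLabels) -> RocResult:
    """ROC of a raw per-sample attribute against the responder labels.

    The attribute is used as the score directly (responder = positive
    class); AUC equals the tie-corrected rank statistic U/(n1*n2), so a
    label flip maps AUC to 1-AUC and monotone transforms leave it
    unchanged. Orientation is reported rather than forced.
    """
    attr = np.asarray(attribute, dtype=float)
    y = labels.labels
    if attr.shape[0] != y.shape[0]:
        raise ValueError("attribute and labels differ in length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present for an ROC")
    return _roc_from_scores(y, attr)


def fit_penalized(
    features: EdgeFeatureMatrix,
    response,
    model: str = "elastic_net",
    l1_ratio: float = 0.5,
    cv: str | int = "loo",
    seed: int | None = None,
    baseline=None,
    labels: ResponderLabels | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> PenalizedFit:
    """Penalized regression of post-intervention HFC on edge features.

    The response is the post-intervention HFC level; the penalty strength
    is picked by cross-validation (leave-one-out by default, integer k for
    k-fold). Features are standardised internally. When ``baseline`` HFC is
    given, predicted change = prediction - baseline is thresholded at
    ``cutoff`` to produce predicted labels, and (when true ``labels`` are
    given) ROC curves are computed with score = -(predicted change), both
    in resubstitution and with held-out cross-validated predictions.
    """
    X = features.data.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    n = y.size
    if n < 6:
        raise ValueError("need at least 6 samples to fit a penalized model")
    if np.std(y) == 0:
        raise ValueError("degenerate (constant) response")
    if model not in ("elastic_net", "lasso"):
        raise ValueError(f"unknown model {model!r}")
    if model == "lasso":
        l1_ratio = 1.0

    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd_safe

    splitter = LeaveOneOut() if cv == "loo" else KFold(int(cv), shuffle=True, random_state=seed)

    if np.all(Xs == 0):
        alpha = 0.0
        coef = np.zeros(X.shape[1])
        intercept = float(y.mean())
        pred_resub = np.full(n, intercept)
        pred_cv = np.array(
            [y[np.arange(n) != i].mean() for i in range(n)]
        ) if cv == "loo" else np.full(n, intercept)
    else:
        cv_cls = LassoCV if model == "lasso" else ElasticNetCV
        kwargs = {} if model == "lasso" else {"l1_ratio": l1_ratio}
        cv_fit = cv_cls(cv=splitter, random_state=seed, max_iter=50000, **kwargs).fit(Xs, y)
        alpha = float(cv_fit.alpha_)
        coef = cv_fit.coef_
        intercept = float(cv_fit.intercept_)
        pred_resub = cv_fit.predict(Xs)
        est_cls = Lasso if model == "lasso" else ElasticNet
        est_kwargs = {"alpha": alpha, "max_iter": 50000}
        if model != "lasso":
            est_kwargs["l1_ratio"] = l1_ratio
        pred_cv = cross_val_predict(est_cls(**est_kwargs), Xs, y, cv=splitter)

    ids = features.sample_ids
    fit = PenalizedFit(
        model=model,
        alpha=alpha,
        l1_ratio=l1_ratio,
        coef=pd.Series(coef / sd_safe, index=features.data.columns),
        intercept=intercept,
        predictions_resub=pd.Series(pred_resub, index=ids),
        predictions_cv=pd.Series(pred_cv, index=ids),
    )
    if baseline is not None:
        base = np.asarray(baseline, dtype=float)
        chg_resub = pred_resub - base
        chg_cv = pred_cv - base
        fit.predicted_labels_resub = [
            RESPONDER if c < cutoff else NON_RESPONDER for c in chg_resub
        ]
        fit.predicted_labels_cv = [
            RESPONDER if c < cutoff else NON_RESPONDER for c in chg_cv
        ]
        if labels is not None and labels.labels.any() and not labels.labels.all():
            fit.roc_resub = _roc_from_scores(labels.labels, -chg_resub)
            fit.roc_cv = _roc_from_scores(labels.labels, -chg_cv)
    return fit


def regress_attribute(attribute, hfc_change) -> dict:
    """OLS of hfc_change on a network attribute with a two-sided slope test."""
    x = np.asarray(attribute, dtype=float)
    y = np.asarray(hfc_change, dtype=float)
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.std(x) == 0:
        raise ValueError("zero-variance attribute")
    res = sps.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
    }
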