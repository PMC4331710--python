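"""Logistic model over pair features, PR curves, and tiered III prediction.

The linear predictor is

    logit(y) = alpha0 + sum_k alpha_k * E_k + alpha_ddi * DDI

with one coefficient per expression dataset plus one for the DDI score.
Predictions are tiered by logit score: strictly above the high threshold
(default 2.575) -> high confidence; strictly above the low threshold
(default 1.692) -> low confidence.  Additionally, for every gene-level PPI
the best-scoring isoform pair is kept ("rescued") even below the low
threshold, so every PPI yields at least one predicted III.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from iiinet.data_io import IsoformCatalog, Pair, canonical_pair
from iiinet.errors import ContractViolation, FitError
from iiinet.features import PairFeatureVector

DEFAULT_HIGH_THRESHOLD = 2.575
DEFAULT_LOW_THRESHOLD = 1.692

TIER_HIGH = "high"
TIER_LOW = "low"
TIER_RESCUED = "rescued"


@dataclass(frozen=True)
class CoefficientVector:
    """Fitted coefficients: intercept, one per dataset, one for DDI."""

    alpha0: float
    alpha_corr: tuple[float, ...]
    alpha_ddi: float

    def __post_init__(self) -> None:
        values = (self.alpha0, *self.alpha_corr, self.alpha_ddi)
        if not all(np.isfinite(values)):
            raise ContractViolation("non-finite coefficient")

    @property
    def n_datasets(self) -> int:
        return len(self.alpha_corr)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha0, *self.alpha_corr, self.alpha_ddi])

    @classmethod
    def from_array(cls, beta: np.ndarray) -> "CoefficientVector":
        return cls(
            alpha0=float(beta[0]),
            alpha_corr=tuple(float(b) for b in beta[1:-1]),
            alpha_ddi=float(beta[-1]),
        )


@dataclass(frozen=True)
class IIIPrediction:
    pair: Pair
    gene_pair: Pair
    logit_score: float
    tier: str
    evidence: PairFeatureVector

    @property
    def probability(self) -> float:
        return float(_sigmoid(np.array([self.logit_score]))[0])


@dataclass(frozen=True)
class PRCurve:
    """Precision/recall at each distinct score threshold (strict >).

    ``n_called`` tracks how many items score above each threshold; the
    highest threshold always calls nothing (precision reported as 1.0 by
    the empty-call convention) and is ignored for operating-point search.
    """

    thresholds: tuple[float, ...]
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    n_called: tuple[int, ...] = ()

    def __iter__(self):
        return iter(zip(self.thresholds, self.precision, self.recall))

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class TestEvaluation:
    curve: PRCurve
    high_precision: float
    high_recall: float
    low_precision: float
    low_recall: float


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _design_matrix(features: Sequence[PairFeatureVector]) -> np.ndarray:
    rows = np.vstack([fv.as_model_row() for fv in features])
    return np.column_stack([np.ones(len(rows)), rows])


def fit_logistic(
    features: Sequence[PairFeatureVector],
    labels: Sequence[int],
    ridge: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoefficientVector:
    """Fit by Newton/IRLS, maximizing the ridge-penalized log-likelihood.

    The ridge term (on slopes only, not the intercept) keeps the problem
    well-posed under complete separation.  Missing correlations are already
    imputed as 0 inside the feature vectors.
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ContractViolation("labels must contain both classes (0 and 1)")
    if len(features) != len(y):
        raise ContractViolation("features and labels differ in length")
    if ridge < 0:
        raise ContractViolation("ridge must be non-negative")
    X = _design_matrix(features)
    n, p = X.shape
    penalty = np.full(p, ridge)
    penalty[0] = 0.0  # intercept unpenalized
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = _sigmoid(eta)
        grad = X.T @ (y - mu) - penalty * beta
        if np.linalg.norm(grad) < tol:
            return CoefficientVector.from_array(beta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        hessian = (X.T * w) @ X + np.diag(penalty)
        beta = beta + np.linalg.solve(hessian, grad)
    grad_norm = float(np.linalg.norm(X.T @ (y - _sigmoid(X @ beta)) - penalty * beta))
    if grad_norm < tol:
        return CoefficientVector.from_array(beta)
    raise FitError(
        f"IRLS did not converge in {max_iter} iterations "
        f"(gradient norm {grad_norm:.3e})"
    )


def standard_errors(
    coeffs: CoefficientVector, features: Sequence[PairFeatureVector]
) -> np.ndarray:
    """Asymptotic standard errors from the observed information matrix."""
    X = _design_matrix(features)
    mu = _sigmoid(X @ coeffs.as_array())
    w = mu * (1.0 - mu)
    info = (X.T * w) @ X
    return np.sqrt(np.diag(np.linalg.inv(info)))


def logit_score(coeffs: CoefficientVector, fv: PairFeatureVector) -> float:
    """Linear predictor for one pair; probability is its inverse logit."""
    row = fv.as_model_row()
    if row.size != coeffs.n_datasets + 1:
        raise ContractViolation(
            f"feature vector has {row.size - 1} datasets, "
            f"model expects {coeffs.n_datasets}"
        )
    return float(coeffs.alpha0 + row @ coeffs.as_array()[1:])


def score_many(
    coeffs: CoefficientVector, features: Sequence[PairFeatureVector]
) -> np.ndarray:
    if not features:
        return np.empty(0)
    X = _design_matrix(features)
    if X.shape[1] != coeffs.n_datasets + 2:
        raise ContractViolation("feature dimension mismatch")
    return X @ coeffs.as_array()


def precision_recall_curve(
    scores: Sequence[float], labels: Sequence[int]
) -> PRCurve:
    """Precision/recall over all distinct score thresholds, predicting
    positive iff score > threshold.  Precision is 1.0 when nothing is
    called positive (empty-call convention)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size != y.size or s.size == 0:
        raise ContractViolation("scores and labels must be non-empty, equal length")
    total_pos = int(y.sum())
    if total_pos == 0:
        raise ContractViolation("precision/recall undefined without positives")
    order = np.argsort(s)
    s_sorted = s[order]
    y_sorted = y[order]
    # suffix sums: counts of items and positives with score strictly > t
    thresholds = np.unique(s_sorted)
    cum_pos = np.cumsum(y_sorted[::-1])[::-1]
    precisions, recalls, called_counts = [], [], []
    for t in thresholds:
        i = np.searchsorted(s_sorted, t, side="right")
        called = s.size - i
        tp = int(cum_pos[i]) if i < s.size else 0
        precisions.append(tp / called if called > 0 else 1.0)
        recalls.append(tp / total_pos)
        called_counts.append(called)
    return PRCurve(
        thresholds=tuple(float(t) for t in thresholds),
        precision=tuple(precisions),
        recall=tuple(recalls),
        n_called=tuple(called_counts),
    )


def threshold_for_operating_point(curve: PRCurve, target_precision: float) -> float:
    """Smallest threshold whose precision meets the target (max recall).

    Knots calling no items are skipped: a precision achieved on an empty
    prediction set is not an operating point.
    """
    called = curve.n_called or tuple(1 for _ in curve.thresholds)
    best = None
    for (t, p, _r), c in zip(curve, called):
        if c > 0 and p >= target_precision:
            best = t if best is None else min(best, t)
    if best is None:
        raise ContractViolation(
            f"target precision {target_precision} unachievable; "
            f"maximum on curve is {max(curve.precision)}"
        )
    return best


def predict(
    candidate_features: Sequence[PairFeatureVector],
    coeffs: CoefficientVector,
    ppi_gene_pairs: Iterable[Pair],
    catalog: IsoformCatalog,
    high_threshold: float = DEFAULT_HIGH_THRESHOLD,
    low_threshold: float = DEFAULT_LOW_THRESHOLD,
) -> list[IIIPrediction]:
    """Score PPI-confirmed candidate pairs and assign confidence tiers.

    Candidates must be isoform pairs whose genes have a known PPI (the
    confirmation filter is applied up front by construction).  Tiers:
    score > high -> "high"; low < score <= high -> "low"; otherwise the
    pair is kept as "rescued" iff it is the best-scoring pair of its PPI
    (ties broken by canonical pair order), so each PPI has >= 1 prediction.
    """
    if high_threshold < low_threshold:
        raise ContractViolation("high threshold must be >= low threshold")
    ppi_set = {canonical_pair(*gp) for gp in ppi_gene_pairs}
    scores = score_many(coeffs, candidate_features)

    by_ppi: dict[Pair, list[int]] = {}
    gene_pairs: list[Pair] = []
    for i, fv in enumerate(candidate_features):
        gp = canonical_pair(catalog.gene_of(fv.isoform_a), catalog.gene_of(fv.isoform_b))
        if gp not in ppi_set:
            raise ContractViolation(
                f"candidate pair {fv.pair} has no gene-level PPI {gp}"
            )
        gene_pairs.append(gp)
        by_ppi.setdefault(gp, []).append(i)

    best_of_ppi: set[int] = set()
    for gp, idxs in by_ppi.items():
        best = min(idxs, key=lambda i: (-scores[i], candidate_features[i].pair))
        best_of_ppi.add(best)

    out: list[IIIPrediction] = []
    for i, fv in enumerate(candidate_features):
        s = float(scores[i])
        if s > high_threshold:
            tier = TIER_HIGH
        elif s > low_threshold:
            tier = TIER_LOW
        elif i in best_of_ppi:
            tier = TIER_RESCUED
        else:
            continue
        out.append(
            IIIPrediction(
                pair=fv.pair,
                gene_pair=gene_pairs[i],
                logit_score=s,
                tier=tier,
                evidence=fv,
            )
        )
    out.sort(key=lambda p: p.pair)
    return out


def _operating_point(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float]:
    called = scores > threshold
    tp = int((called & (labels == 1)).sum())
    fp = int((called & (labels == 0)).sum())
    pos = int((labels == 1).sum())
    precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    return precision, tp / pos


def evaluate_on_test(
    coeffs: CoefficientVector,
    test_features: Sequence[PairFeatureVector],
    test_labels: Sequence[int],
    high_threshold: float = DEFAULT_HIGH_THRESHOLD,
    low_threshold: float = DEFAULT_LOW_THRESHOLD,
) -> TestEvaluation:
    """Score the held-out mixture and report the curve plus both operating points."""
    y = np.asarray(test_labels, dtype=int)
    if y.size == 0 or y.sum() == 0 or y.sum() == y.size:
        raise ContractViolation("test set needs at least one positive and one negative")
    scores = score_many(coeffs, test_features)
    curve = precision_recall_curve(scores, y)
    hp, hr = _operating_point(scores, y, high_threshold)
    lp, lr = _operating_point(scores, y, low_threshold)
    return TestEvaluation(
        curve=curve,
        high_precision=hp,
        high_recall=hr,
        low_precision=lp,
        low_recall=lr,
    )
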