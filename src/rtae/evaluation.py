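"""ROC analysis and operating-point metrics shared by both predictive models.

AUC is the pairwise concordance probability (ties count 1/2), its 95% CI
comes from DeLong's placement-value variance estimator by default, and the
reported sensitivity/specificity/accuracy triple is taken at the threshold
maximizing Youden's J = sensitivity + specificity - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class ModelPerformance:
    """Performance summary for one model context (phase x endpoint x set).

    Percentages are on the 0-100 scale; ``auc`` and its CI on [0, 1].
    """

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    ci95: tuple[float, float]
    p_value: float
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (0.0 <= lo <= self.auc + 1e-12 and self.auc - 1e-12 <= hi <= 1.0):
            raise ValueError(f"CI {self.ci95} inconsistent with AUC {self.auc}")
        for name in ("sensitivity", "specificity", "accuracy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "context": self.context,
        }


def _check_two_class(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the (fpr, tpr) curve points.

    The AUC is computed as the Mann-Whitney concordance probability
    P(score+ > score-) + 0.5 P(score+ = score-), which equals the
    trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_class(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # rank-based concordance; ties get 1/2
    order = np.concatenate([neg, pos])
    ranks = stats.rankdata(order)
    auc = (ranks[len(neg):].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg)
    )
    # curve points: sweep thresholds at unique scores, descending
    thresholds = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(np.mean(pos >= t))
        fpr.append(np.mean(neg >= t))
    return float(auc), np.asarray(fpr), np.asarray(tpr)


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and DeLong variance from placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auc_ci(
    scores,
    labels,
    method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[tuple[float, float], float]:
    """95% CI for the AUC and a p-value against AUC = 0.5.

    ``method='delong'`` (default) uses the asymptotic placement-value
    variance; ``'bootstrap'`` a stratified percentile bootstrap. The
    p-value is always normal-theory on the DeLong scale. Degenerate
    (zero) variance clamps the CI to the point estimate within [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_class(labels)
    auc, var = _delong_variance(scores, labels)
    se = np.sqrt(var)
    if se == 0.0:
        p = 0.0 if auc != 0.5 else 1.0
    else:
        p = 2 * stats.norm.sf(abs(auc - 0.5) / se)
    if method == "delong":
        z = stats.norm.ppf(1 - alpha / 2)
        lo, hi = auc - z * se, auc + z * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(labels == 1)
        neg_idx = np.flatnonzero(labels == 0)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            bi = np.concatenate(
                [
                    rng.choice(pos_idx, len(pos_idx), replace=True),
                    rng.choice(neg_idx, len(neg_idx), replace=True),
                ]
            )
            reps[b], _ = _delong_variance(scores[bi], labels[bi])
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown method {method!r}")
    lo = float(min(max(lo, 0.0), auc))
    hi = float(max(min(hi, 1.0), auc))
    return (lo, hi), float(p)


def youden_threshold(scores, labels) -> float:
    """Threshold (predict positive when score >= t) maximizing Youden's J.

    Candidates are the observed scores plus +inf (predict all negative);
    ties in J are broken toward the LOWER threshold, i.e. higher
    sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_class(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best_t, best_j = np.inf, -np.inf
    for t in np.concatenate([np.sort(np.unique(scores)), [np.inf]]):
        j = np.mean(pos >= t) + np.mean(neg < t) - 1
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and t < best_t):
            best_j, best_t = j, t
    return float(best_t)


def metrics_at_threshold(scores, labels, threshold: float) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, accuracy %) predicting score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    sens = 100.0 * np.mean(pred[labels == 1]) if np.any(labels == 1) else np.nan
    spec = 100.0 * np.mean(~pred[labels == 0]) if np.any(labels == 0) else np.nan
    acc = 100.0 * np.mean(pred == labels)
    return float(sens), float(spec), float(acc)


def operating_point(scores, labels) -> tuple[float, float, float]:
    """Youden-optimal (sensitivity %, specificity %, accuracy %)."""
    t = youden_threshold(scores, labels)
    return metrics_at_threshold(scores, labels, t)


def performance(
    scores,
    labels,
    threshold: float | None = None,
    context: dict | None = None,
    ci_method: str = "delong",
    seed: int | None = None,
) -> ModelPerformance:
    """Full performance summary; threshold defaults to the Youden optimum
    of ``scores`` themselves (pass a training-derived threshold to avoid
    optimistic test-set operating points)."""
    auc, _, _ = roc_auc(scores, labels)
    (lo, hi), p = auc_ci(scores, labels, method=ci_method, seed=seed)
    if threshold is None:
        threshold = youden_threshold(scores, labels)
    sens, spec, acc = metrics_at_threshold(scores, labels, threshold)
    return ModelPerformance(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=auc,
        ci95=(lo, hi),
        p_value=p,
        context=context or {},
    )
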