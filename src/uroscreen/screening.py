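"""ROC analysis and screening cut-off selection for UF-5000 counts.

The screening question: can an instrument bacterial count exclude
culture-negative urines before plating? The machinery here is the standard
diagnostic-accuracy toolkit — empirical ROC with the "score >= cutoff calls
positive" convention, cut-offs chosen at fixed sensitivity floors, confusion
metrics, and the workload accounting (fraction of cultures avoided and the
false-negative rate among avoided cultures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._util import pct, round_half_up

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "RocCurve",
    "ThresholdRow",
    "WorkloadResult",
    "confusion_counts",
    "diagnostic_metrics",
    "empirical_roc",
    "auc_ci",
    "cutoff_at_sensitivity",
    "sensitivity_table",
    "workload_reduction",
    "combine_markers",
    "compare_groups",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/TN/FP at one operating point."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricSet:
    """SEN/SPE/PPV/NPV as unrounded percentages; ``None`` marks an undefined
    metric (zero denominator), never 0. The generating counts are retained so
    every figure can be traced back."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    counts: ConfusionCounts

    def rounded(self, ndigits: int = 1) -> dict[str, Optional[float]]:
        """Report-ready percentages, half-up to ``ndigits`` decimals."""
        return {
            k: (None if v is None else round_half_up(v, ndigits))
            for k, v in {
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "ppv": self.ppv,
                "npv": self.npv,
            }.items()
        }


def _validate_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.size == 0:
        raise ValueError("empty input")
    if s.shape != y.shape:
        raise ValueError(f"scores and labels differ in length: {s.shape} vs {y.shape}")
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1, False, True}:
        raise ValueError(f"labels must be binary 0/1, got values {sorted(uniq)}")
    return s, y.astype(int)


def confusion_counts(scores, labels, cutoff: float) -> ConfusionCounts:
    """Tabulate calls at a cutoff; a sample is called positive iff score >= cutoff."""
    s, y = _validate_scores_labels(scores, labels)
    call = s >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(call & (y == 1))),
        fn=int(np.sum(~call & (y == 1))),
        tn=int(np.sum(~call & (y == 0))),
        fp=int(np.sum(call & (y == 0))),
    )


def diagnostic_metrics(c: ConfusionCounts) -> MetricSet:
    return MetricSet(
        sensitivity=pct(c.tp, c.tp + c.fn),
        specificity=pct(c.tn, c.tn + c.fp),
        ppv=pct(c.tp, c.tp + c.fp),
        npv=pct(c.tn, c.tn + c.fn),
        counts=c,
    )


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: one point per distinct observed score plus +/-inf
    sentinels; ``points`` are (cutoff, sensitivity, 1 - specificity) with
    sensitivity non-increasing as the cutoff increases."""

    points: tuple[tuple[float, float, float], ...]
    auc: float
    auc_ci: Optional[tuple[float, float]] = None


def empirical_roc(scores, labels) -> RocCurve:
    """ROC over all distinct cutoffs; AUC by the trapezoidal rule, which for
    the empirical curve equals the Mann-Whitney concordance probability with
    ties counted half."""
    s, y = _validate_scores_labels(scores, labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")

    cutoffs = np.concatenate(([np.inf], np.unique(s)[::-1], [-np.inf]))
    pts = []
    for c in cutoffs:
        call = s >= c
        sens = float(np.sum(call & (y == 1))) / n_pos
        fpr = float(np.sum(call & (y == 0))) / n_neg
        pts.append((float(c), sens, fpr))

    fprs = np.array([p[2] for p in pts])
    senss = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(senss, fprs))
    # points listed with cutoff decreasing = ROC traversed left to right
    return RocCurve(points=tuple(pts[::-1]), auc=auc)


def _midrank_auc_components(s: np.ndarray, y: np.ndarray):
    """Placement values for the DeLong AUC variance (midranks handle ties)."""
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n          # P(neg < pos), per positive
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # per negative
    auc = float(v10.mean())
    return auc, v10, v01


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong 95% (by default) confidence interval for the empirical AUC.

    Deterministic; the interval is clipped to [0, 1]. Requires at least 10
    samples in each class for the normal approximation to be meaningful.
    """
    s, y = _validate_scores_labels(scores, labels)
    m, n = int(y.sum()), int((1 - y).sum())
    if m < 10 or n < 10:
        raise ValueError(f"need >= 10 samples per class for a DeLong CI, got {m} pos / {n} neg")
    auc, v10, v01 = _midrank_auc_components(s, y)
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


@dataclass(frozen=True)
class ThresholdRow:
    """One line of a cut-off table: the cutoff attaining a nominal
    sensitivity floor, with its achieved metrics and counts."""

    nominal_sensitivity: float
    cutoff: float
    metrics: MetricSet
    counts: ConfusionCounts


def cutoff_at_sensitivity(scores, labels, target: float) -> ThresholdRow:
    """Largest cutoff whose achieved sensitivity is >= ``target`` percent.

    Because sensitivity is non-increasing in the cutoff, this maximizes
    specificity subject to the sensitivity floor. The cutoff at the minimum
    observed score always reaches 100% sensitivity, so any target in (0, 100]
    is attainable whenever positives exist.
    """
    s, y = _validate_scores_labels(scores, labels)
    if not (0 < target <= 100):
        raise ValueError(f"target sensitivity must lie in (0, 100], got {target!r}")
    if y.sum() == 0:
        raise ValueError("no positive samples: sensitivity target unattainable")
    if (1 - y).sum() == 0:
        raise ValueError("no negative samples: both classes required")

    pos = s[y == 1]
    n_pos = len(pos)
    best = None
    for c in np.unique(s)[::-1]:  # largest first
        sens = float(np.sum(pos >= c)) / n_pos * 100.0
        if sens >= target:
            best = float(c)
            break
    assert best is not None  # cutoff = min(s) gives sens 100
    counts = confusion_counts(s, y, best)
    return ThresholdRow(
        nominal_sensitivity=float(target),
        cutoff=best,
        metrics=diagnostic_metrics(counts),
        counts=counts,
    )


def sensitivity_table(scores, labels, targets: Sequence[float]) -> list[ThresholdRow]:
    """One ThresholdRow per nominal sensitivity target, in the given order."""
    return [cutoff_at_sensitivity(scores, labels, t) for t in targets]


@dataclass(frozen=True)
class WorkloadResult:
    """Screening economics of a cut-off: cultures avoided and the price paid.

    ``culture_reduction`` is the fraction of all specimens called negative
    (and hence not cultured); ``false_negative_rate`` is the fraction of
    those avoided cultures that would have grown. Both are unrounded
    percentages; ``false_negative_rate`` is None when nothing is avoided.
    """

    culture_reduction: float
    false_negative_rate: Optional[float]
    counts: ConfusionCounts

    def rounded(self, ndigits: int = 1) -> tuple[float, Optional[float]]:
        fnr = self.false_negative_rate
        return (
            round_half_up(self.culture_reduction, ndigits),
            None if fnr is None else round_half_up(fnr, ndigits),
        )


def workload_reduction(c: ConfusionCounts) -> WorkloadResult:
    if c.total == 0:
        raise ValueError("empty confusion table")
    avoided = c.tn + c.fn
    return WorkloadResult(
        culture_reduction=100.0 * avoided / c.total,
        false_negative_rate=pct(c.fn, avoided),
        counts=c,
    )


def combine_markers(bact, wbc, labels) -> np.ndarray:
    """Joint BACT+WBC score: linear logistic predictor on log(count + 1).

    Fitted by maximum likelihood; zero-variance covariates are dropped
    (the score then degenerates to the remaining marker, preserving its ROC
    ordering). Returns one score per sample, suitable for empirical_roc.
    """
    import statsmodels.api as sm

    b = np.log1p(np.asarray(bact, dtype=float))
    w = np.log1p(np.asarray(wbc, dtype=float))
    _, y = _validate_scores_labels(b, labels)
    if len(w) != len(b):
        raise ValueError("bact and wbc differ in length")

    cols, names = [], []
    for arr, name in ((b, "log_bact"), (w, "log_wbc")):
        if np.ptp(arr) > 0:
            cols.append(arr)
            names.append(name)
    if not cols:
        raise ValueError("both markers are constant; no score can be fitted")
    X = sm.add_constant(np.column_stack(cols), has_constant="add")

    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation raises in statsmodels
        # fall back to a heavily-regularised fit only to order the samples
        fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-6, maxiter=500)
    if np.any(~np.isfinite(fit.params)):
        raise RuntimeError(f"logistic fit did not converge: params={fit.params}")
    return np.asarray(X @ fit.params, dtype=float)


def compare_groups(values, groups) -> tuple[float, float, float]:
    """Medians of the two groups and a two-sided Mann-Whitney U p-value.

    The rank test is used because instrument counts and channel features are
    right-skewed; scipy computes the exact null distribution for small
    tie-free samples, otherwise the tie-corrected normal approximation.
    Returns (median_group0, median_group1, p).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups).astype(int)
    a, b = v[g == 0], v[g == 1]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(np.median(a)), float(np.median(b)), float(res.pvalue)
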