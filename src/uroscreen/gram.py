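"""Gram-class prediction from the bacterial scattergram geometry.

On a UF-5000 scattergram with fluorescence (B_FLH) on the abscissa and
forward scatter (B_FSC) on the ordinate, a specimen's bacterial cloud sits
on a ray whose slope is the B_FSC/B_FLH ratio. Gram-negative rods stay in
suspension as small single cells (low forward scatter) and stain brightly
(high fluorescence), so their ray hugs the abscissa; Gram-positive cocci
aggregate into larger clumps and stain poorly through thick peptidoglycan,
steepening the ray. The classifier thresholds the ray's angle from the
abscissa: below the cut-off angle predicts Gram-negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .records import Gram, SampleRecord
from .screening import ConfusionCounts, MetricSet, compare_groups, diagnostic_metrics

__all__ = [
    "ScatterSummary",
    "AngleClassifier",
    "fsc_flh_ratio",
    "ratio_to_angle",
    "truncate_angle",
    "fit_ratio_cutoff",
    "classify_by_angle",
    "summarize_scattergram",
    "DEFAULT_BACT_CUTOFF",
]

logger = logging.getLogger(__name__)

# screening cut-off used to pre-filter specimens before Gram prediction
DEFAULT_BACT_CUTOFF = 42.2


def fsc_flh_ratio(b_fsc: float, b_flh: float) -> float:
    """Scattergram slope B_FSC / B_FLH (dimensionless)."""
    if b_flh <= 0:
        raise ValueError(f"b_flh must be positive, got {b_flh!r}")
    if b_fsc < 0:
        raise ValueError(f"b_fsc must be non-negative, got {b_fsc!r}")
    return b_fsc / b_flh


def ratio_to_angle(ratio: float) -> float:
    """Angle from the abscissa, in degrees, of the ray with the given slope.

    Strictly increasing, mapping [0, inf) into [0, 90). Full precision is
    returned; integer reporting truncates toward zero (see
    :func:`truncate_angle`), so a ratio of 0.55 reads as 28 degrees.
    """
    if ratio < 0:
        raise ValueError(f"ratio must be non-negative, got {ratio!r}")
    return math.degrees(math.atan(ratio))


def truncate_angle(angle_deg: float) -> int:
    """Integer angle for reporting: truncated toward zero, not rounded."""
    return math.trunc(angle_deg)


@dataclass(frozen=True)
class AngleClassifier:
    """A fitted ratio cut-off and its angle form.

    ``angle_cutoff_deg`` is the reported integer angle (truncated);
    ``angle_deg`` retains full precision. ``low_separability`` marks a fit
    whose best Youden index is not positive, i.e. the classes were
    indistinguishable in training.
    """

    ratio_cutoff: float
    angle_cutoff_deg: int
    angle_deg: float
    training_metrics: Optional[MetricSet] = None
    youden: Optional[float] = None
    low_separability: bool = False
    method: str = "youden_midpoint"


def _as_gn_indicator(gram_labels: Sequence) -> np.ndarray:
    out = []
    for g in gram_labels:
        if isinstance(g, Gram):
            out.append(1 if g is Gram.NEGATIVE else 0)
        elif g in ("GN", 1, True):
            out.append(1)
        elif g in ("GP", 0, False):
            out.append(0)
        else:
            raise ValueError(f"unrecognised Gram label {g!r}")
    return np.array(out, dtype=int)


def fit_ratio_cutoff(ratios: Sequence[float], gram_labels: Sequence) -> AngleClassifier:
    """Youden-optimal ratio cut-off for calling Gram-negative.

    Gram-negatives have the LOWER ratio, so a specimen is called GN when
    ratio <= cutoff. Candidate cut-offs are the midpoints between adjacent
    distinct observed ratios; the Youden index J = SEN + SPE - 1 is
    maximised, with ties broken toward higher sensitivity (the larger
    cutoff).
    """
    r = np.asarray(ratios, dtype=float)
    y = _as_gn_indicator(gram_labels)
    if len(r) != len(y):
        raise ValueError("ratios and labels differ in length")
    n_gn, n_gp = int(y.sum()), int((1 - y).sum())
    if n_gn == 0 or n_gp == 0:
        raise ValueError("both Gram classes must be present to fit a cut-off")

    distinct = np.unique(r)
    if len(distinct) == 1:
        candidates = distinct  # degenerate: single observed value
    else:
        candidates = (distinct[:-1] + distinct[1:]) / 2.0

    best = None  # (J, sens, cutoff)
    for c in candidates:
        call_gn = r <= c
        sens = float(np.sum(call_gn & (y == 1))) / n_gn
        spec = float(np.sum(~call_gn & (y == 0))) / n_gp
        j = sens + spec - 1.0
        if (
            best is None
            or j > best[0] + 1e-12
            or (abs(j - best[0]) <= 1e-12 and sens > best[1] + 1e-12)
        ):
            best = (j, sens, float(c))
    j, _, cutoff = best

    counts = ConfusionCounts(
        tp=int(np.sum((r <= cutoff) & (y == 1))),
        fn=int(np.sum((r > cutoff) & (y == 1))),
        tn=int(np.sum((r > cutoff) & (y == 0))),
        fp=int(np.sum((r <= cutoff) & (y == 0))),
    )
    angle = ratio_to_angle(cutoff)
    return AngleClassifier(
        ratio_cutoff=cutoff,
        angle_cutoff_deg=truncate_angle(angle),
        angle_deg=angle,
        training_metrics=diagnostic_metrics(counts),
        youden=j,
        low_separability=j <= 0.0,
    )


def classify_by_angle(
    samples: Sequence[SampleRecord],
    angle_cutoff_deg: float,
    gram_labels: Optional[Sequence] = None,
    bact_cutoff: Optional[float] = DEFAULT_BACT_CUTOFF,
) -> tuple[list[Optional[str]], Optional[ConfusionCounts], int]:
    """Apply the angle rule: scattergram angle < cutoff predicts GN, else GP.

    Only samples with BACT >= ``bact_cutoff`` are classified (pass None to
    disable the filter); excluded or channel-missing samples get a None
    prediction. Returns (predictions aligned to input, confusion counts
    against ``gram_labels`` with GN as the positive class when labels are
    given, number skipped for missing channels).
    """
    preds: list[Optional[str]] = []
    skipped = 0
    kept_idx = []
    for i, s in enumerate(samples):
        if bact_cutoff is not None and s.bact_per_ul < bact_cutoff:
            preds.append(None)
            continue
        if s.b_fsc_ch is None or s.b_flh_ch is None:
            logger.warning("sample %s lacks channel values; skipped", s.sample_id)
            skipped += 1
            preds.append(None)
            continue
        angle = ratio_to_angle(fsc_flh_ratio(s.b_fsc_ch, s.b_flh_ch))
        preds.append("GN" if angle < angle_cutoff_deg else "GP")
        kept_idx.append(i)

    counts = None
    if gram_labels is not None:
        y = _as_gn_indicator(gram_labels)
        if len(y) != len(samples):
            raise ValueError("gram_labels and samples differ in length")
        tp = sum(1 for i in kept_idx if preds[i] == "GN" and y[i] == 1)
        fn = sum(1 for i in kept_idx if preds[i] == "GP" and y[i] == 1)
        tn = sum(1 for i in kept_idx if preds[i] == "GP" and y[i] == 0)
        fp = sum(1 for i in kept_idx if preds[i] == "GN" and y[i] == 0)
        counts = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
    return preds, counts, skipped


@dataclass(frozen=True)
class ScatterSummary:
    """Per-Gram-class channel medians and the rank-test p-values.

    Ratio medians are medians of per-sample ratios (not ratios of medians).
    """

    median_fsc_gn: float
    median_fsc_gp: float
    median_flh_gn: float
    median_flh_gp: float
    median_ratio_gn: float
    median_ratio_gp: float
    p_fsc: float
    p_flh: float
    p_ratio: float
    n_gn: int
    n_gp: int


def summarize_scattergram(samples: Sequence[SampleRecord], gram_labels: Sequence) -> ScatterSummary:
    y = _as_gn_indicator(gram_labels)
    fsc = np.array([s.b_fsc_ch for s in samples], dtype=float)
    flh = np.array([s.b_flh_ch for s in samples], dtype=float)
    if np.any(~np.isfinite(fsc)) or np.any(~np.isfinite(flh)):
        raise ValueError("all samples need channel values for a scattergram summary")
    ratio = fsc / flh

    med_fsc_gp, med_fsc_gn, p_fsc = compare_groups(fsc, y)
    med_flh_gp, med_flh_gn, p_flh = compare_groups(flh, y)
    med_r_gp, med_r_gn, p_r = compare_groups(ratio, y)
    return ScatterSummary(
        median_fsc_gn=med_fsc_gn,
        median_fsc_gp=med_fsc_gp,
        median_flh_gn=med_flh_gn,
        median_flh_gp=med_flh_gp,
        median_ratio_gn=med_r_gn,
        median_ratio_gp=med_r_gp,
        p_fsc=p_fsc,
        p_flh=p_flh,
        p_ratio=p_r,
        n_gn=int(y.sum()),
        n_gp=int((1 - y).sum()),
    )
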