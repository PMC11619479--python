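"""Flag-vs-culture agreement: cross-tabulation, Cohen's kappa, Gram-flag accuracy.

The UF-5000 emits a categorical bacterial-information flag; culture gives a
categorical truth (Gram-positive / Gram-negative / mixed / no growth). The
cross-tab is built only over samples above a BACT cut-off (the screening
cut-off is applied first, mirroring how the flags would be used in practice).
Kappa requires a square table, and the instrument's six flag levels do not
match the four culture levels, so collapsing onto a shared category set is an
explicit, named parameter of the analysis — not a hidden constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import CULTURE_CLASS_ORDER, FLAG_ORDER, Flag
from .screening import ConfusionCounts, MetricSet, diagnostic_metrics

__all__ = [
    "AgreementTable",
    "KappaResult",
    "COLLAPSING_SCHEMES",
    "crosstab",
    "cohen_kappa",
    "gram_flag_metrics",
]

_FLAG_LABELS = [f.value for f in FLAG_ORDER]


@dataclass(frozen=True)
class AgreementTable:
    """Flags (rows) x culture classes (columns) contingency table."""

    table: pd.DataFrame  # index = flag labels, columns = culture classes, int cells
    bact_cutoff: Optional[float] = None

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())

    def with_margins(self) -> pd.DataFrame:
        out = self.table.copy()
        out["Total"] = out.sum(axis=1)
        out.loc["Total"] = out.sum(axis=0)
        return out


def crosstab(
    flags: Sequence,
    cultures: Sequence[str],
    bact: Optional[Sequence[float]] = None,
    bact_cutoff: Optional[float] = None,
) -> AgreementTable:
    """Cross-tabulate flags against culture classes.

    When ``bact`` and ``bact_cutoff`` are given, only samples with
    BACT >= cutoff enter the table (culture-negative exclusion step).
    Culture classes follow :meth:`CultureRecord.culture_class`: a mixed
    culture whose species share a Gram class is already folded into that
    class; "Mixed" means both classes present.
    """
    flag_labels = [f.value if isinstance(f, Flag) else str(f) for f in flags]
    culture_labels = [str(c) for c in cultures]
    if len(flag_labels) != len(culture_labels):
        raise ValueError("flags and cultures differ in length")

    bad = sorted(set(flag_labels) - set(_FLAG_LABELS))
    if bad:
        raise ValueError(f"unknown flag labels {bad}; valid: {_FLAG_LABELS}")
    bad = sorted(set(culture_labels) - set(CULTURE_CLASS_ORDER))
    if bad:
        raise ValueError(f"unknown culture classes {bad}; valid: {CULTURE_CLASS_ORDER}")

    if bact is not None and bact_cutoff is not None:
        b = np.asarray(bact, dtype=float)
        if len(b) != len(flag_labels):
            raise ValueError("bact and flags differ in length")
        keep = b >= bact_cutoff
        flag_labels = [f for f, k in zip(flag_labels, keep) if k]
        culture_labels = [c for c, k in zip(culture_labels, keep) if k]

    if flag_labels:
        tab = pd.crosstab(
            pd.Categorical(flag_labels, categories=_FLAG_LABELS),
            pd.Categorical(culture_labels, categories=CULTURE_CLASS_ORDER),
            dropna=False,
        )
        tab = tab.reindex(index=_FLAG_LABELS, columns=CULTURE_CLASS_ORDER, fill_value=0)
    else:
        tab = pd.DataFrame(0, index=_FLAG_LABELS, columns=CULTURE_CLASS_ORDER)
    tab = tab.astype(int)
    tab.index.name = "flag"
    tab.columns.name = "culture"
    return AgreementTable(table=tab, bact_cutoff=bact_cutoff)


# Each scheme maps both axes onto one shared category set.
COLLAPSING_SCHEMES: dict[str, dict[str, dict[str, str]]] = {
    # Gram calls only; everything non-informative is "Other"
    "three_class": {
        "flags": {
            Flag.GRAM_POS.value: "GP",
            Flag.GRAM_NEG.value: "GN",
            Flag.GRAM_POS_NEG.value: "Other",
            Flag.UNCLASSIFIED.value: "Other",
            Flag.UTI.value: "Other",
            Flag.NO_FLAG.value: "Other",
        },
        "cultures": {
            "Gram Pos": "GP",
            "Gram Neg": "GN",
            "Mixed": "Other",
            "Negative": "Other",
        },
        "order": ["GP", "GN", "Other"],
    },
    # Keeps mixed and negative as their own levels; the GP/GN flag plays
    # the mixed role and the non-informative flags play the negative role.
    "four_class": {
        "flags": {
            Flag.GRAM_POS.value: "GP",
            Flag.GRAM_NEG.value: "GN",
            Flag.GRAM_POS_NEG.value: "Mixed",
            Flag.UNCLASSIFIED.value: "Negative",
            Flag.UTI.value: "Negative",
            Flag.NO_FLAG.value: "Negative",
        },
        "cultures": {
            "Gram Pos": "GP",
            "Gram Neg": "GN",
            "Mixed": "Mixed",
            "Negative": "Negative",
        },
        "order": ["GP", "GN", "Mixed", "Negative"],
    },
}


@dataclass(frozen=True)
class KappaResult:
    """Unweighted Cohen's kappa on a collapsed square table.

    kappa = (Po - Pe) / (1 - Pe); ``None`` when expected agreement is 1
    (both raters constant), where chance correction is undefined.
    """

    kappa: Optional[float]
    observed_agreement: float
    expected_agreement: float
    collapsing: str
    collapsed: pd.DataFrame


def cohen_kappa(table: AgreementTable, collapsing: str = "three_class") -> KappaResult:
    if collapsing not in COLLAPSING_SCHEMES:
        raise ValueError(
            f"unknown collapsing scheme {collapsing!r}; valid: {sorted(COLLAPSING_SCHEMES)}"
        )
    scheme = COLLAPSING_SCHEMES[collapsing]
    order = scheme["order"]

    collapsed = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for flag_label, row in table.table.iterrows():
        r = scheme["flags"][flag_label]
        for culture_label, count in row.items():
            c = scheme["cultures"][culture_label]
            collapsed.loc[r, c] += int(count)

    m = collapsed.to_numpy(dtype=float)
    n = m.sum()
    if n == 0:
        raise ValueError("empty agreement table")
    po = np.trace(m) / n
    pe = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / n**2
    kappa = None if pe >= 1.0 else (po - pe) / (1.0 - pe)
    return KappaResult(
        kappa=kappa,
        observed_agreement=float(po),
        expected_agreement=float(pe),
        collapsing=collapsing,
        collapsed=collapsed,
    )


def gram_flag_metrics(table: AgreementTable, target: str = "GN") -> MetricSet:
    """Score one Gram flag as a binary test against culture.

    Flags binarize as "target flag vs any other flag"; cultures as "target
    Gram class vs anything else" (a both-class mixed culture is not a pure
    target and counts on the non-target side). PPV is then the flag's
    correct-call fraction.
    """
    if target not in ("GN", "GP"):
        raise ValueError(f"target must be 'GN' or 'GP', got {target!r}")
    flag_label = Flag.GRAM_NEG.value if target == "GN" else Flag.GRAM_POS.value
    culture_label = "Gram Neg" if target == "GN" else "Gram Pos"

    t = table.table
    tp = int(t.loc[flag_label, culture_label])
    fp = int(t.loc[flag_label].sum()) - tp
    fn = int(t[culture_label].sum()) - tp
    tn = table.total - tp - fp - fn
    return diagnostic_metrics(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))
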