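"""Core record types: one instrument readout and one culture result per specimen.

Units: all particle counts are per µL. The UF-5000 prints counts as ×10^6/L,
which is numerically identical to /µL; files and records here use /µL
throughout. Channel intensities (B_FSC, B_FLH) are in the instrument's
arbitrary channel units ("ch").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Flag(str, Enum):
    """UF-5000 bacterial-information flags.

    The instrument emits a Gram-class guess only when both screening
    thresholds are met (WBC >= 10/µL and BACT >= 100/µL); otherwise the
    sample carries no bacterial information ("No flag"). "UTI" is a
    WBC-driven flag without Gram information.
    """

    GRAM_NEG = "Gram Neg?"
    GRAM_POS = "Gram Pos?"
    GRAM_POS_NEG = "Gram Pos/Neg?"
    UNCLASSIFIED = "Unclassified"
    UTI = "UTI"
    NO_FLAG = "No flag"


class Gram(str, Enum):
    NEGATIVE = "GN"
    POSITIVE = "GP"


class CultureStatus(str, Enum):
    NEGATIVE = "negative"
    POSITIVE = "positive"
    YEAST = "yeast"
    CONTAMINATED = "contaminated"


class CfuCategory(str, Enum):
    """Colony-count stratum of the culture (CFU/mL)."""

    LT_1E4 = "lt1e4"
    BETWEEN_1E4_1E5 = "1e4_to_1e5"
    GE_1E5 = "ge1e5"


class Cohort(str, Enum):
    TRAINING = "training"
    VALIDATION = "validation"


# shared display order for flag / culture axes of the agreement table
FLAG_ORDER = [
    Flag.GRAM_POS,
    Flag.GRAM_NEG,
    Flag.GRAM_POS_NEG,
    Flag.UNCLASSIFIED,
    Flag.UTI,
    Flag.NO_FLAG,
]

CULTURE_CLASS_ORDER = ["Gram Pos", "Gram Neg", "Mixed", "Negative"]


@dataclass
class SampleRecord:
    """One urine specimen's UF-5000 readout."""

    sample_id: str
    bact_per_ul: float
    wbc_per_ul: float
    ylc_per_ul: float = 0.0
    ec_per_ul: float = 0.0
    b_fsc_ch: Optional[float] = None
    b_flh_ch: Optional[float] = None
    flag: Flag = Flag.NO_FLAG
    cohort: Cohort = Cohort.TRAINING

    def __post_init__(self) -> None:
        for name in ("bact_per_ul", "wbc_per_ul", "ylc_per_ul", "ec_per_ul"):
            v = getattr(self, name)
            if v is None or v < 0:
                raise ValueError(f"{name} must be a non-negative count, got {v!r}")
        for name in ("b_fsc_ch", "b_flh_ch"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present, got {v!r}")


@dataclass
class CultureRecord:
    """Gold-standard urine-culture outcome for one specimen.

    A positive culture carries a CFU/mL category of at least 10^4 and up to
    two identified organisms with Gram classes. More than two species means
    the culture is reported as contaminated, with no organism list.
    """

    sample_id: str
    status: CultureStatus
    cfu_category: CfuCategory = CfuCategory.LT_1E4
    organism_1: Optional[str] = None
    gram_1: Optional[Gram] = None
    organism_2: Optional[str] = None
    gram_2: Optional[Gram] = None

    def __post_init__(self) -> None:
        if self.status is CultureStatus.POSITIVE:
            if self.cfu_category is CfuCategory.LT_1E4:
                raise ValueError(
                    "positive culture requires cfu_category >= 1e4 "
                    f"(sample {self.sample_id})"
                )
            if self.gram_1 is None:
                raise ValueError(
                    f"positive bacterial culture needs a Gram class (sample {self.sample_id})"
                )
        if self.status in (CultureStatus.NEGATIVE, CultureStatus.YEAST, CultureStatus.CONTAMINATED):
            if self.gram_1 is not None or self.gram_2 is not None:
                raise ValueError(
                    f"non-bacterial-positive culture carries no Gram class (sample {self.sample_id})"
                )

    @property
    def gram_classes(self) -> tuple[Gram, ...]:
        return tuple(g for g in (self.gram_1, self.gram_2) if g is not None)

    def culture_class(self) -> str:
        """Four-level culture category for the agreement table.

        Two species of the same Gram class are regarded as that class; a
        culture containing both classes is "Mixed". Negative, yeast and
        contaminated cultures all fall in "Negative" for flag comparison
        (yeast/contaminated are normally excluded upstream).
        """
        grams = set(self.gram_classes)
        if grams == {Gram.NEGATIVE}:
            return "Gram Neg"
        if grams == {Gram.POSITIVE}:
            return "Gram Pos"
        if grams == {Gram.NEGATIVE, Gram.POSITIVE}:
            return "Mixed"
        return "Negative"
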