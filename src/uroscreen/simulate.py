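"""Synthetic UF-5000 cohort generator.

Emulates the joint structure a urine-flow-cytometry UTI screening study sees:
culture positivity around 31.8% of non-yeast specimens at >=10^4 CFU/mL with
88.5% of positives at >=10^5, Gram-negative predominance, right-skewed
(lognormal) BACT and WBC counts whose class separation gives a BACT AUC near
0.93, bivariate lognormal (B_FSC, B_FLH) channel features with Gram-class
medians (31.6, 101.2) ch for Gram-negatives and (59.8, 87.6) ch for
Gram-positives, and instrument flagging gated on WBC >= 10/µL and
BACT >= 100/µL.

The count and channel spreads are calibration parameters: the study this
emulates reports medians and AUCs but no distributional family, so the
lognormal scales here were fitted once to reproduce the published operating
points (see docs/methods.md) and are not meant to be re-tuned per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .records import (
    CfuCategory,
    Cohort,
    CultureRecord,
    CultureStatus,
    Flag,
    Gram,
    SampleRecord,
)

__all__ = [
    "LogNormalParams",
    "BivariateLogNormalParams",
    "GeneratorConfig",
    "SyntheticCohort",
    "ConfigError",
    "make_default_config",
    "generate_cohort",
    "simulate_flags",
    "write_cohort",
    "cohort_to_frames",
    "WBC_FLAG_THRESHOLD",
    "BACT_FLAG_THRESHOLD",
]

# instrument flagging eligibility thresholds (per µL)
WBC_FLAG_THRESHOLD = 10.0
BACT_FLAG_THRESHOLD = 100.0


class ConfigError(ValueError):
    """Raised when a GeneratorConfig field is out of its valid range."""


@dataclass(frozen=True)
class LogNormalParams:
    """Location/spread of a lognormal law on the natural-log scale."""

    mu: float
    sigma: float


@dataclass(frozen=True)
class BivariateLogNormalParams:
    """Bivariate lognormal for (B_FSC, B_FLH); medians are exp(mu) ch."""

    mu_fsc: float
    mu_flh: float
    sigma_fsc: float
    sigma_flh: float
    rho: float = 0.0

    @property
    def median_fsc(self) -> float:
        return math.exp(self.mu_fsc)

    @property
    def median_flh(self) -> float:
        return math.exp(self.mu_flh)


@dataclass(frozen=True)
class GeneratorConfig:
    n_samples: int
    seed: int
    prev_pos4: float = 0.318
    frac_pos5_given_pos4: float = 0.885
    frac_gram_negative: float = 0.76
    yeast_fraction: float = 31 / 823
    frac_two_species: float = 8 / 252
    frac_contaminated: float = 0.0
    validation_fraction: float = 699 / 1522
    bact_params: Mapping[str, LogNormalParams] = None  # type: ignore[assignment]
    wbc_params: Mapping[str, LogNormalParams] = None  # type: ignore[assignment]
    fsc_flh_params: Mapping[str, BivariateLogNormalParams] = None  # type: ignore[assignment]
    flag_noise: Mapping[str, Mapping[Flag, float]] = None  # type: ignore[assignment]

    def validate(self) -> None:
        for name in ("bact_params", "wbc_params", "fsc_flh_params", "flag_noise"):
            if getattr(self, name) is None:
                raise ConfigError(
                    f"{name} is unset; use make_default_config() or supply it explicitly"
                )
        for name in (
            "prev_pos4",
            "frac_pos5_given_pos4",
            "frac_gram_negative",
            "yeast_fraction",
            "frac_two_species",
            "frac_contaminated",
            "validation_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if self.n_samples <= 0:
            raise ConfigError(f"n_samples must be positive, got {self.n_samples!r}")
        for name in ("bact_params", "wbc_params"):
            params = getattr(self, name)
            for stratum in ("negative", "positive"):
                if stratum not in params:
                    raise ConfigError(f"{name} missing stratum {stratum!r}")
                if params[stratum].sigma <= 0:
                    raise ConfigError(f"{name}[{stratum!r}].sigma must be positive")
        for cls in ("GN", "GP", "background"):
            if cls not in self.fsc_flh_params:
                raise ConfigError(f"fsc_flh_params missing class {cls!r}")
            p = self.fsc_flh_params[cls]
            if not (-1.0 < p.rho < 1.0):
                raise ConfigError(f"fsc_flh_params[{cls!r}].rho must lie in (-1, 1)")
        for cls, noise in self.flag_noise.items():
            total = sum(noise.values())
            if any(p < 0 for p in noise.values()) or total > 1.0 + 1e-12:
                raise ConfigError(
                    f"flag_noise[{cls!r}] probabilities must be non-negative and sum to <= 1"
                )


# Misflag probabilities for flag-eligible samples, by true class. The
# remaining mass goes to the class's nominal flag (GN -> "Gram Neg?",
# GP -> "Gram Pos?", culture-negative -> "Unclassified"). Fitted once so a
# simulated flags-vs-culture cross-tab is qualitatively like the published
# one (Gram-negative column dominated by the Gram Neg? flag).
_DEFAULT_FLAG_NOISE: dict[str, dict[Flag, float]] = {
    "GN": {
        Flag.GRAM_POS: 0.06,
        Flag.GRAM_POS_NEG: 0.10,
        Flag.UNCLASSIFIED: 0.03,
        Flag.UTI: 0.01,
        Flag.NO_FLAG: 0.05,
    },
    "GP": {
        Flag.GRAM_NEG: 0.04,
        Flag.GRAM_POS_NEG: 0.08,
        Flag.UNCLASSIFIED: 0.02,
        Flag.UTI: 0.05,
        Flag.NO_FLAG: 0.26,
    },
    "negative": {
        Flag.GRAM_POS: 0.27,
        Flag.GRAM_NEG: 0.065,
        Flag.GRAM_POS_NEG: 0.03,
        Flag.UTI: 0.21,
        Flag.NO_FLAG: 0.33,
    },
}

_NOMINAL_FLAG = {
    "GN": Flag.GRAM_NEG,
    "GP": Flag.GRAM_POS,
    "negative": Flag.UNCLASSIFIED,
}

# Count spreads fitted by quantile-matching the published cutoff/SEN/SPE
# operating points; the implied BACT AUC is 0.926 and P(BACT >= 42.2 | pos)
# is 0.950.
_DEFAULT_BACT = {
    "negative": LogNormalParams(mu=3.14, sigma=2.34),
    "positive": LogNormalParams(mu=8.55, sigma=2.92),
}
_DEFAULT_WBC = {
    "negative": LogNormalParams(mu=2.08, sigma=1.5),
    "positive": LogNormalParams(mu=3.36, sigma=1.8),
}
# Channel-feature spreads chosen so the Gram-negative-vs-positive ratio rule
# at 0.55 operates at sensitivity 0.95 / specificity 0.933.
_DEFAULT_FSC_FLH = {
    "GN": BivariateLogNormalParams(
        mu_fsc=math.log(31.6), mu_flh=math.log(101.2), sigma_fsc=0.28, sigma_flh=0.20
    ),
    "GP": BivariateLogNormalParams(
        mu_fsc=math.log(59.8), mu_flh=math.log(87.6), sigma_fsc=0.12, sigma_flh=0.08
    ),
    # culture-negative / yeast background: low-grade debris signal
    "background": BivariateLogNormalParams(
        mu_fsc=math.log(45.0), mu_flh=math.log(70.0), sigma_fsc=0.5, sigma_flh=0.5
    ),
}


def make_default_config(seed: int, n_samples: int = 823) -> GeneratorConfig:
    """Calibrated default configuration; deterministic in its arguments."""
    cfg = GeneratorConfig(
        n_samples=n_samples,
        seed=seed,
        bact_params=dict(_DEFAULT_BACT),
        wbc_params=dict(_DEFAULT_WBC),
        fsc_flh_params=dict(_DEFAULT_FSC_FLH),
        flag_noise={k: dict(v) for k, v in _DEFAULT_FLAG_NOISE.items()},
    )
    cfg.validate()
    return cfg


@dataclass
class SyntheticCohort:
    samples: list[SampleRecord]
    cultures: list[CultureRecord]
    config_used: GeneratorConfig

    def __len__(self) -> int:
        return len(self.samples)


_GN_SPECIES = [
    ("Escherichia coli", 113),
    ("Klebsiella pneumoniae", 23),
    ("Klebsiella oxytoca", 9),
    ("Proteus mirabilis", 8),
    ("Pseudomonas aeruginosa", 7),
    ("Other Gram-negative", 26),
]
_GP_SPECIES = [
    ("Enterococcus faecium", 17),
    ("Enterococcus faecalis", 13),
    ("Streptococcus agalactiae", 6),
    ("Other Gram-positive", 22),
]


def _pick_species(rng: np.random.Generator, gram: Gram) -> str:
    table = _GN_SPECIES if gram is Gram.NEGATIVE else _GP_SPECIES
    names = [n for n, _ in table]
    weights = np.array([w for _, w in table], dtype=float)
    return rng.choice(names, p=weights / weights.sum())


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort (culture outcomes + instrument readouts).

    Reproducible: identical config (including seed) yields identical records.
    Flags are populated too, via :func:`simulate_flags`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    samples: list[SampleRecord] = []
    cultures: list[CultureRecord] = []
    width = max(4, len(str(n)))

    for i in range(n):
        sid = f"S{i + 1:0{width}d}"
        cohort = (
            Cohort.VALIDATION
            if rng.random() < config.validation_fraction
            else Cohort.TRAINING
        )

        u = rng.random()
        if u < config.yeast_fraction:
            status = CultureStatus.YEAST
        elif u < config.yeast_fraction + (1 - config.yeast_fraction) * config.frac_contaminated:
            status = CultureStatus.CONTAMINATED
        else:
            status = (
                CultureStatus.POSITIVE
                if rng.random() < config.prev_pos4
                else CultureStatus.NEGATIVE
            )

        if status is CultureStatus.POSITIVE:
            cfu = (
                CfuCategory.GE_1E5
                if rng.random() < config.frac_pos5_given_pos4
                else CfuCategory.BETWEEN_1E4_1E5
            )
            if rng.random() < config.frac_two_species:
                # two-species cultures: mostly concordant Gram classes
                kind = rng.choice(["GN-GN", "GP-GP", "GN-GP"], p=[0.5, 0.25, 0.25])
                g1, g2 = {
                    "GN-GN": (Gram.NEGATIVE, Gram.NEGATIVE),
                    "GP-GP": (Gram.POSITIVE, Gram.POSITIVE),
                    "GN-GP": (Gram.NEGATIVE, Gram.POSITIVE),
                }[kind]
            else:
                g1 = (
                    Gram.NEGATIVE
                    if rng.random() < config.frac_gram_negative
                    else Gram.POSITIVE
                )
                g2 = None
            culture = CultureRecord(
                sample_id=sid,
                status=status,
                cfu_category=cfu,
                organism_1=_pick_species(rng, g1),
                gram_1=g1,
                organism_2=_pick_species(rng, g2) if g2 is not None else None,
                gram_2=g2,
            )
            count_stratum = "positive"
            # channel features follow the dominant Gram class; for a mixed
            # GN+GP culture the Gram-negative morphology dominates
            feat_cls = "GN" if Gram.NEGATIVE in culture.gram_classes else "GP"
        else:
            culture = CultureRecord(sample_id=sid, status=status)
            count_stratum = "negative"
            feat_cls = "background"

        bp = config.bact_params[count_stratum]
        wp = config.wbc_params[count_stratum]
        bact = float(rng.lognormal(bp.mu, bp.sigma))
        wbc = float(rng.lognormal(wp.mu, wp.sigma))

        fp = config.fsc_flh_params[feat_cls]
        z1, z2 = rng.standard_normal(2)
        log_fsc = fp.mu_fsc + fp.sigma_fsc * z1
        log_flh = fp.mu_flh + fp.sigma_flh * (fp.rho * z1 + math.sqrt(1 - fp.rho**2) * z2)
        b_fsc, b_flh = math.exp(log_fsc), math.exp(log_flh)

        ylc = float(rng.lognormal(math.log(50.0), 1.0)) if status is CultureStatus.YEAST else 0.0
        ec = float(rng.lognormal(math.log(5.0), 1.0))

        samples.append(
            SampleRecord(
                sample_id=sid,
                bact_per_ul=bact,
                wbc_per_ul=wbc,
                ylc_per_ul=ylc,
                ec_per_ul=ec,
                b_fsc_ch=b_fsc,
                b_flh_ch=b_flh,
                cohort=cohort,
            )
        )
        cultures.append(culture)

    cohort_obj = SyntheticCohort(samples=samples, cultures=cultures, config_used=config)
    return simulate_flags(cohort_obj, config)


def simulate_flags(cohort: SyntheticCohort, config: Optional[GeneratorConfig] = None) -> SyntheticCohort:
    """Assign UF-5000 bacterial-information flags in place.

    A sample is flag-eligible only when WBC >= 10/µL and BACT >= 100/µL;
    otherwise it carries "No flag". Eligible samples receive their class's
    nominal flag, perturbed by the configured misflag probabilities. The
    flag stream is seeded independently of the count stream so re-flagging
    a cohort is itself reproducible.
    """
    config = config or cohort.config_used
    config.validate()
    rng = np.random.default_rng((config.seed, 0xF1A6))
    by_id = {c.sample_id: c for c in cohort.cultures}

    for s in cohort.samples:
        if s.wbc_per_ul < WBC_FLAG_THRESHOLD or s.bact_per_ul < BACT_FLAG_THRESHOLD:
            s.flag = Flag.NO_FLAG
            continue
        culture = by_id[s.sample_id]
        grams = set(culture.gram_classes)
        if Gram.NEGATIVE in grams:
            cls = "GN"
        elif Gram.POSITIVE in grams:
            cls = "GP"
        else:
            cls = "negative"
        noise = config.flag_noise[cls]
        flags = list(noise.keys()) + [_NOMINAL_FLAG[cls]]
        probs = np.array(list(noise.values()) + [1.0 - sum(noise.values())])
        s.flag = flags[int(rng.choice(len(flags), p=probs / probs.sum()))]
    return cohort


def cohort_to_frames(cohort: SyntheticCohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render a cohort as the two canonical tables (samples, cultures)."""
    samples = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cohort.samples],
            "bact_per_ul": [s.bact_per_ul for s in cohort.samples],
            "wbc_per_ul": [s.wbc_per_ul for s in cohort.samples],
            "ylc_per_ul": [s.ylc_per_ul for s in cohort.samples],
            "ec_per_ul": [s.ec_per_ul for s in cohort.samples],
            "b_fsc_ch": [s.b_fsc_ch for s in cohort.samples],
            "b_flh_ch": [s.b_flh_ch for s in cohort.samples],
            "flag": [s.flag.value for s in cohort.samples],
            "cohort": [s.cohort.value for s in cohort.samples],
        }
    )
    cultures = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in cohort.cultures],
            "status": [c.status.value for c in cohort.cultures],
            "cfu_category": [c.cfu_category.value for c in cohort.cultures],
            "organism_1": [c.organism_1 or "" for c in cohort.cultures],
            "gram_1": [c.gram_1.value if c.gram_1 else "none" for c in cohort.cultures],
            "organism_2": [c.organism_2 or "" for c in cohort.cultures],
            "gram_2": [c.gram_2.value if c.gram_2 else "none" for c in cohort.cultures],
        }
    )
    return samples, cultures


def write_cohort(cohort: SyntheticCohort, samples_path, cultures_path) -> None:
    """Write samples.csv / cultures.csv (RFC-4180, UTF-8)."""
    samples, cultures = cohort_to_frames(cohort)
    samples.to_csv(samples_path, index=False, encoding="utf-8", lineterminator="\n")
    cultures.to_csv(cultures_path, index=False, encoding="utf-8", lineterminator="\n")
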