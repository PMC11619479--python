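"""Reading, validating and joining the samples / cultures tables.

File dialect (RFC-4180 CSV, UTF-8):

samples.csv
    sample_id, bact_per_ul, wbc_per_ul, ylc_per_ul, ec_per_ul,
    b_fsc_ch, b_flh_ch, flag, cohort
cultures.csv
    sample_id, status {negative|positive|yeast|contaminated},
    cfu_category {lt1e4|1e4_to_1e5|ge1e5},
    organism_1, gram_1 {GN|GP|none}, organism_2, gram_2

Counts are per µL (numerically identical to the instrument's x10^6/L).
Empty channel cells mean the scattergram features were not exported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

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

__all__ = ["read_samples", "read_cultures", "join_cohort", "JoinedCohort", "SAMPLE_COLUMNS", "CULTURE_COLUMNS"]

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = [
    "sample_id",
    "bact_per_ul",
    "wbc_per_ul",
    "ylc_per_ul",
    "ec_per_ul",
    "b_fsc_ch",
    "b_flh_ch",
    "flag",
    "cohort",
]
CULTURE_COLUMNS = [
    "sample_id",
    "status",
    "cfu_category",
    "organism_1",
    "gram_1",
    "organism_2",
    "gram_2",
]


def _check_header(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _float_or_none(value, row_no: int, col: str, path):
    if pd.isna(value) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"{path}, line {row_no}: non-numeric {col}: {value!r}") from None


def read_samples(path) -> list[SampleRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df, SAMPLE_COLUMNS, path)
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        sid = row["sample_id"]
        if not sid:
            raise ValueError(f"{path}, line {line}: empty sample_id")
        if sid in seen:
            raise ValueError(f"{path}, line {line}: duplicate sample_id {sid!r}")
        seen.add(sid)
        vals = {}
        for col in ("bact_per_ul", "wbc_per_ul", "ylc_per_ul", "ec_per_ul"):
            v = _float_or_none(row[col], line, col, path)
            if v is None:
                raise ValueError(f"{path}, line {line}: missing count {col}")
            if v < 0:
                raise ValueError(f"{path}, line {line}: negative count {col}={v}")
            vals[col] = v
        for col in ("b_fsc_ch", "b_flh_ch"):
            vals[col] = _float_or_none(row[col], line, col, path)
        try:
            flag = Flag(row["flag"]) if row["flag"] else Flag.NO_FLAG
            cohort = Cohort(row["cohort"]) if row["cohort"] else Cohort.TRAINING
            records.append(SampleRecord(sample_id=sid, flag=flag, cohort=cohort, **vals))
        except ValueError as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from None
    return records


def read_cultures(path) -> list[CultureRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df, CULTURE_COLUMNS, path)
    records: list[CultureRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        line = idx + 2
        sid = row["sample_id"]
        if not sid:
            raise ValueError(f"{path}, line {line}: empty sample_id")
        if sid in seen:
            raise ValueError(f"{path}, line {line}: duplicate sample_id {sid!r}")
        seen.add(sid)
        try:
            status = CultureStatus(row["status"])
            cfu = CfuCategory(row["cfu_category"]) if row["cfu_category"] else CfuCategory.LT_1E4
            gram_1 = None if row["gram_1"] in ("", "none") else Gram(row["gram_1"])
            gram_2 = None if row["gram_2"] in ("", "none") else Gram(row["gram_2"])
            records.append(
                CultureRecord(
                    sample_id=sid,
                    status=status,
                    cfu_category=cfu,
                    organism_1=row["organism_1"] or None,
                    gram_1=gram_1,
                    organism_2=row["organism_2"] or None,
                    gram_2=gram_2,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from None
    return records


@dataclass
class JoinedCohort:
    """Inner join of instrument and culture records, with the bacterial-
    analysis subset (yeast and contaminated cultures excluded) split out."""

    pairs: list[tuple[SampleRecord, CultureRecord]]
    bacterial: list[tuple[SampleRecord, CultureRecord]]
    n_yeast_excluded: int
    n_contaminated_excluded: int
    unmatched_samples: list[str]
    unmatched_cultures: list[str]


def join_cohort(samples: list[SampleRecord], cultures: list[CultureRecord]) -> JoinedCohort:
    """Join on sample_id; exclude yeast/contaminated from bacterial analyses.

    Mirrors the usual denominator shift: a cohort of N specimens with k
    yeast-positive cultures analyses N - k specimens against bacterial
    culture. Unmatched ids on either side are reported, and zero overlap is
    an error. Duplicate culture ids are an error (one culture per specimen).
    """
    culture_by_id: dict[str, CultureRecord] = {}
    for c in cultures:
        if c.sample_id in culture_by_id:
            raise ValueError(f"duplicate culture for sample {c.sample_id!r}")
        culture_by_id[c.sample_id] = c

    pairs = [(s, culture_by_id[s.sample_id]) for s in samples if s.sample_id in culture_by_id]
    if not pairs:
        raise ValueError("no overlap between sample and culture ids")

    matched = {s.sample_id for s, _ in pairs}
    unmatched_samples = [s.sample_id for s in samples if s.sample_id not in matched]
    unmatched_cultures = [c.sample_id for c in cultures if c.sample_id not in matched]

    bacterial = [
        (s, c)
        for s, c in pairs
        if c.status in (CultureStatus.NEGATIVE, CultureStatus.POSITIVE)
    ]
    n_yeast = sum(1 for _, c in pairs if c.status is CultureStatus.YEAST)
    n_contam = sum(1 for _, c in pairs if c.status is CultureStatus.CONTAMINATED)
    logger.info(
        "joined %d pairs; excluded %d yeast and %d contaminated from bacterial analyses",
        len(pairs),
        n_yeast,
        n_contam,
    )
    return JoinedCohort(
        pairs=pairs,
        bacterial=bacterial,
        n_yeast_excluded=n_yeast,
        n_contaminated_excluded=n_contam,
        unmatched_samples=unmatched_samples,
        unmatched_cultures=unmatched_cultures,
    )
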