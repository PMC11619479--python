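import numpy as np
import pytest

from uroscreen import agreement, simulate
from uroscreen.records import Flag

# Flags-vs-culture contingency table of a published UF-5000 evaluation
# (455 specimens above the 42.2/µL screening cut-off); used as a fixed
# desk-scale input throughout the agreement tests.
TABLE3_CELLS = {
    Flag.GRAM_POS.value: {"Gram Pos": 26, "Gram Neg": 10, "Mixed": 2, "Negative": 58},
    Flag.GRAM_NEG.value: {"Gram Pos": 2, "Gram Neg": 109, "Mixed": 0, "Negative": 14},
    Flag.GRAM_POS_NEG.value: {"Gram Pos": 4, "Gram Neg": 17, "Mixed": 0, "Negative": 6},
    Flag.UNCLASSIFIED.value: {"Gram Pos": 0, "Gram Neg": 4, "Mixed": 0, "Negative": 22},
    Flag.UTI.value: {"Gram Pos": 2, "Gram Neg": 1, "Mixed": 0, "Negative": 45},
    Flag.NO_FLAG.value: {"Gram Pos": 17, "Gram Neg": 46, "Mixed": 0, "Negative": 70},
}


def expand_table(cells) -> tuple[list[str], list[str]]:
    """Per-sample (flag, culture) label pairs realising a contingency table."""
    flags, cultures = [], []
    for flag, row in cells.items():
        for culture, count in row.items():
            flags.extend([flag] * count)
            cultures.extend([culture] * count)
    return flags, cultures


@pytest.fixture(scope="session")
def table3() -> agreement.AgreementTable:
    flags, cultures = expand_table(TABLE3_CELLS)
    return agreement.crosstab(flags, cultures)


@pytest.fixture(scope="session")
def cohort10k() -> simulate.SyntheticCohort:
    """Large default-configured synthetic cohort, shared across tests."""
    cfg = simulate.make_default_config(seed=42, n_samples=10_000)
    return simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort() -> simulate.SyntheticCohort:
    cfg = simulate.make_default_config(seed=7, n_samples=600)
    return simulate.generate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
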