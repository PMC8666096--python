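import numpy as np
import pandas as pd
import pytest

from brainmark.identfilter import PSM
from brainmark.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def cohort() -> pd.DataFrame:
    """Default-size discovery cohort (7 SCI+ / 8 SCI- / 6 control)."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture
def annotations(cohort) -> pd.DataFrame:
    return cohort[["sample_id", "group"]]


def make_psm(
    sample="S1",
    accession="P1",
    peptide="ACDEFGHIKR",
    charge=2,
    probability=0.99,
    mowse=50.0,
    spectrum_id="sp1",
) -> PSM:
    return PSM(sample, accession, peptide, charge, probability, mowse, spectrum_id)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
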