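import numpy as np
import pytest

from apeqol.formants import FormantProfile, VowelMeasurement
from apeqol.synthetic import DEFAULT_TARGETS, CohortConfig, simulate_cohort


def make_profile(formants, speaker="s1", gender="male", timepoint="pre"):
    """Build a FormantProfile from {vowel: (F1, F2)} without audio."""
    measurements = {
        v: VowelMeasurement(vowel=v, f1=f1, f2=f2, method="given", quality=1.0)
        for v, (f1, f2) in formants.items()
    }
    return FormantProfile(
        speaker=speaker, gender=gender, timepoint=timepoint, measurements=measurements
    )


#: The textbook corner-vowel profile used for all hand-arithmetic oracles:
#: /i/ (270, 2290), /u/ (300, 870), /ɑ/ (730, 1090).
WORKED_FORMANTS = {"A": (730.0, 1090.0), "I": (270.0, 2290.0), "U": (300.0, 870.0)}


@pytest.fixture
def worked_profile():
    return make_profile(WORKED_FORMANTS)


@pytest.fixture(scope="session")
def default_cohort():
    """One default validation cohort, shared across tests (read-only)."""
    return simulate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def male_targets():
    return DEFAULT_TARGETS["male"]


@pytest.fixture(scope="session")
def female_targets():
    return DEFAULT_TARGETS["female"]
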