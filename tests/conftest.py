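import numpy as np
import pytest

from synthct import PhantomSpec, generate_paired_case, generate_dose, preprocess_case


@pytest.fixture(scope="session")
def small_case():
    """One 48³ paired phantom with dose, shared across tests."""
    case = generate_paired_case(PhantomSpec(seed=7, shape=(48, 48, 48), spacing=(6.0, 6.0, 4.0)))
    case.dose = generate_dose(case, prescription=36.25)
    return case


@pytest.fixture(scope="session")
def pre_case(small_case):
    """The same case preprocessed to normalized [-1, 1] intensities."""
    pre, _ = preprocess_case(small_case)
    return pre


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
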