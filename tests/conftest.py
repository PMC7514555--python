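import numpy as np
import pytest

from pffcens import IWDParams, PFFSample, load_dataset, parse_scheme, simulate_pff


@pytest.fixture(scope="session")
def std_params():
    return IWDParams(2.0, 1.0)


@pytest.fixture(scope="session")
def guinea_complete():
    return load_dataset("guinea_complete")


@pytest.fixture(scope="session")
def guinea_complete_sample(guinea_complete):
    scheme = parse_scheme("(0*72)", k=1, n=72)
    return PFFSample(scheme, np.sort(guinea_complete.times))


@pytest.fixture(scope="session")
def guinea_r1_sample():
    ds = load_dataset("guinea_R1")
    return PFFSample(ds.censoring, ds.times)


@pytest.fixture(scope="session")
def sim_sample_n50_m40(std_params):
    """Seeded simulated sample: k=1, n=50, m=40, R=(10, 0*39)."""
    scheme = parse_scheme("(10,0*39)", k=1, n=50)
    return simulate_pff(scheme, std_params, seed=42)


@pytest.fixture(scope="session")
def fit_r1(guinea_r1_sample):
    from pffcens import fit_mle

    return fit_mle(guinea_r1_sample)


@pytest.fixture(scope="session")
def fit_n50_m40(sim_sample_n50_m40):
    from pffcens import fit_mle

    return fit_mle(sim_sample_n50_m40)
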