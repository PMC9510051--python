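import pytest

from triphase.simgen import SampleDesign, SimParams, simulate_dataset


@pytest.fixture(scope="session")
def design():
    return SampleDesign.default()


@pytest.fixture(scope="session")
def small_dataset():
    """Error-free 2,000-site dataset shared across read-only tests."""
    params = SimParams(
        n_sites=2_000, chrom_length=400_000, seed=1234, error_rate=0.0
    )
    trio, dsg, sites = simulate_dataset(params)
    return params, trio, dsg, sites
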