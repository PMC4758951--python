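import numpy as np
import pytest

from pbmkit.fitting import FitConfig, fit_model
from pbmkit.simulate import SimSpec, example_symmetric_psam, simulate_dataset


@pytest.fixture(scope="session")
def sym_truth():
    return example_symmetric_psam()


@pytest.fixture(scope="session")
def small_sim(sym_truth):
    """A modest simulated PBM dataset shared across unit tests."""
    spec = SimSpec(
        n_probes=1200,
        probe_len=30,
        modes=[(sym_truth, 1.0)],
        noise_sd_frac=0.05,
        rng_seed=7,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A fitted state on the shared dataset (seed discovery skipped for
    speed; the seed stage has its own tests)."""
    table, _ = small_sim
    return fit_model(table, FitConfig(), seed_kmer="GCACGTGC")
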