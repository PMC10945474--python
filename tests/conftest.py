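import numpy as np
import pandas as pd
import pytest

from homeobias import PipelineConfig, SimConfig, run_all, simulate_experiment


@pytest.fixture(scope="session")
def small_config():
    """A small but complete experiment: 4 chromosomes x 80 genes."""
    return SimConfig(
        n_chromosomes=4,
        genes_per_chromosome=80,
        seed=7,
        library_size_mean=2e6,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def small_pipeline_result(small_config):
    return run_all(PipelineConfig(sim=small_config, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def nb_counts(rng, mean, dispersion, size):
    """Negative binomial draws via the gamma-Poisson mixture."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return rng.poisson(lam)


def toy_count_matrix(values, samples=None, groups=None):
    """Build a CountMatrix from a plain array."""
    from homeobias import CountMatrix

    values = np.asarray(values)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])], columns=samples)
    meta = pd.DataFrame(
        {"group": groups or ["A"] * len(samples)}, index=pd.Index(samples, name="sample")
    )
    return CountMatrix(frame, meta)
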