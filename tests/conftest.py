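import numpy as np
import pandas as pd
import pytest

import cellewas as ce


@pytest.fixture(scope="session")
def small_config():
    """A small mixed cohort with marker structure, M-scale mixing."""
    return ce.SimulationConfig(
        n_samples=60, n_probes=160, markers_per_type=20, cell_types=("A", "B", "C"),
        dirichlet_mean=(0.5, 0.3, 0.2), seed=11,
    )


@pytest.fixture(scope="session")
def small_profiles(small_config):
    return ce.simulate_pure_profiles(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_profiles):
    return ce.simulate_dataset(small_config, small_profiles)


@pytest.fixture(scope="session")
def cord_config():
    """Default 7-type cord-blood configuration at modest size."""
    return ce.SimulationConfig(n_samples=100, n_probes=760, seed=4)


def make_phenotypes(n, seed=0, continuous=True, covariates=2):
    """Hand-built phenotype table independent of the generator."""
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    data = {"phenotype": rng.standard_normal(n) if continuous
            else (rng.uniform(size=n) < 0.3).astype(float)}
    covs = []
    for j in range(covariates):
        name = f"z{j}"
        data[name] = rng.standard_normal(n)
        covs.append(name)
    return ce.PhenotypeTable(pd.DataFrame(data, index=idx), "phenotype", covs)


def make_proportions(n, k, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    frac = rng.dirichlet(np.full(k, 5.0), size=n)
    idx = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    cols = labels or [f"ct{j}" for j in range(k)]
    return ce.CellProportions(pd.DataFrame(frac, index=idx, columns=cols))


def make_matrix(values, scale="M", sample_ids=None):
    p, n = values.shape
    idx = pd.Index([f"cg{i:08d}" for i in range(p)], name="probe_id")
    cols = sample_ids if sample_ids is not None else [f"S{i:05d}" for i in range(n)]
    return ce.MethylationMatrix(pd.DataFrame(values, index=idx, columns=cols), scale=scale)
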