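import numpy as np
import pandas as pd
import pytest

from metabovar import (
    MCMCConfig,
    MetaboDataset,
    Schema,
    build_design,
    make_scenario,
    simulate_dataset,
)


@pytest.fixture
def toy_schema():
    return Schema(
        id_col="id", time_col="time",
        covariate_cols=("age", "bmi", "sex"),
        metabolite_cols=("metA", "metB"),
    )


@pytest.fixture
def toy_csv(tmp_path, toy_schema):
    """8-row CSV: 2 individuals x 4 timepoints, 2 metabolites, 3 covariates."""
    rng = np.random.default_rng(11)
    rows = []
    for ind, (age, bmi, sex) in zip("AB", [(30, 22.0, 0), (45, 27.5, 1)]):
        for t in range(1, 5):
            rows.append((ind, t, age, bmi, sex,
                         round(10 + rng.normal(), 3),
                         round(20 + rng.normal(), 3)))
    df = pd.DataFrame(rows, columns=["id", "time", "age", "bmi", "sex",
                                     "metA", "metB"])
    path = tmp_path / "toy.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def small_dataset():
    """Scenario-1 dataset small enough for fast fitting (N=30)."""
    return simulate_dataset(make_scenario(1, N=30, seed=42), 0)


@pytest.fixture
def small_design(small_dataset):
    return build_design(small_dataset)


@pytest.fixture
def fast_mcmc():
    return MCMCConfig(n_chains=2, n_iter=400, burn_in=100, thin=2, seed=5)


def make_dataset(df: pd.DataFrame, metabolites, covariates=()) -> MetaboDataset:
    """Wrap a hand-built frame (columns id, time, ...) as a MetaboDataset."""
    schema = Schema(id_col="id", time_col="time",
                    covariate_cols=tuple(covariates),
                    metabolite_cols=tuple(metabolites))
    return MetaboDataset(data=df, schema=schema)


def batch_mcse(x: np.ndarray, n_batches: int = 25) -> float:
    """Monte-Carlo standard error via batch means (autocorrelation-robust)."""
    x = np.asarray(x, dtype=float).ravel()
    size = len(x) // n_batches
    means = x[: size * n_batches].reshape(n_batches, size).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
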