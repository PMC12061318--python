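import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from autogs.envirotyping import RDEPMatrix, StageThresholdTable
from autogs.envparams import EP_NAMES
from autogs.genofeatures import GenotypeMatrix
from autogs.simdata import simulate_trial


@pytest.fixture(scope="session")
def small_trial():
    """One deterministic synthetic trial shared by read-only tests."""
    return simulate_trial(seed=11, n_genotypes=120, n_markers=400, n_envs=6)


@pytest.fixture()
def toy_weather():
    """Ten days of well-behaved weather for one environment."""
    n = 10
    return pd.DataFrame(
        {
            "env_id": "E1",
            "date": pd.date_range("2021-05-01", periods=n),
            "tmax": np.linspace(70, 90, n),
            "tmin": np.linspace(50, 62, n),
            "day_length": np.full(n, 13.5),
            "rh": np.full(n, 60.0),
            "pre": np.zeros(n),
            "par": np.full(n, 20.0),
        }
    )


def make_rdep(env_id, values, window_days=None, labels=None):
    """RDEPMatrix helper: values is (9, W) array-like."""
    values = np.asarray(values, float)
    w = values.shape[1]
    labels = labels or [f"S{i}" for i in range(w)]
    return RDEPMatrix(
        env_id=env_id,
        matrix=pd.DataFrame(values, index=list(EP_NAMES), columns=labels),
        window_days=np.asarray(window_days if window_days is not None else np.ones(w), int),
    )


def make_genotypes(dosages, chroms=None, positions=None, samples=None, multiallelic=None):
    """GenotypeMatrix helper from a plain (n_samples, n_markers) array."""
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    marker_map = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": positions if positions is not None else np.arange(1, m + 1) * 1000,
        },
        index=[f"m{i}" for i in range(m)],
    )
    if multiallelic is not None:
        marker_map["multiallelic"] = multiallelic
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(n)],
        dosages=dosages,
        marker_map=marker_map,
    )


@pytest.fixture()
def simple_stage_table():
    return StageThresholdTable(("A", "B", "C"), (25.0, 50.0, 100.0))
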