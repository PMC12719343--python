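import numpy as np
import pytest
from scipy.special import ndtri

from twinpath.model import VariableSpec, model_from_components
from twinpath.simulate import SimulationConfig, simulate_ace_cohort

UNIVARIATE = (VariableSpec("y", "binary_liability"),)

TRIVARIATE = (
    VariableSpec("prs", "continuous", components_allowed=("A",)),
    VariableSpec("mdd", "binary_liability"),
    VariableSpec("si", "binary_liability"),
)


def univariate_truth(A=0.4, C=0.0, prevalence=0.18):
    props = {"y": {k: v for k, v in
                   (("A", A), ("C", C), ("E", 1.0 - A - C)) if v > 0}}
    return model_from_components(
        UNIVARIATE, props, {},
        thresholds={"y": float(ndtri(1.0 - prevalence))})


def trivariate_truth():
    h2 = {"prs": 1.0, "mdd": 0.40, "si": 0.52}
    ra = np.array([[1.0, 0.25, 0.18],
                   [0.25, 1.0, 0.65],
                   [0.18, 0.65, 1.0]])
    re = np.array([[1.0, 0.0, 0.0],
                   [0.0, 1.0, 0.06],
                   [0.0, 0.06, 1.0]])
    return model_from_components(
        TRIVARIATE, {k: {"A": h2[k], "E": 1.0 - h2[k]} for k in h2},
        {"A": ra, "E": re},
        thresholds={"mdd": float(ndtri(0.82)), "si": 1.2})


def simulate(model, n_mz, n_dz, seed, **kw):
    ds, truth = simulate_ace_cohort(SimulationConfig(
        n_mz_pairs=n_mz, n_dz_pairs=n_dz, model=model, seed=seed, **kw))
    return ds, truth


@pytest.fixture(scope="session")
def univariate_ds():
    ds, _ = simulate(univariate_truth(), 2000, 2000, seed=101)
    return ds


@pytest.fixture(scope="session")
def trivariate_ds():
    ds, _ = simulate(trivariate_truth(), 250, 300, seed=202)
    return ds
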