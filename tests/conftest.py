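import numpy as np
import pandas as pd
import pytest

import tractsem as ts


@pytest.fixture(scope="session")
def study_table():
    """Moderate-size synthetic subject table with the default population."""
    table, truth = ts.simulate_subject_table(ts.SemSimConfig(n=400, seed=11))
    return table


@pytest.fixture(scope="session")
def two_factor_spec():
    return ts.build_watershed_spec({"FI": ["PO", "PS"], "CI": ["VC", "WM"]})


@pytest.fixture(scope="session")
def watershed_spec():
    return ts.build_watershed_spec({"FI": ["PO", "PS"], "CI": ["VC", "WM"]},
                                   ts.TRACTS + ("age",))


@pytest.fixture(scope="session")
def tiny_mimic():
    """Small MIMIC (2 latents, 2 predictors) with a known parameter set."""
    spec = ts.build_watershed_spec({"F1": ["a", "b"], "F2": ["c", "d"]},
                                   ("x1", "x2"))
    lam = np.array([[1.0, 0.0], [0.8, 0.0], [0.0, 1.0], [0.0, 0.6]])
    gamma = np.array([[0.5, 0.0], [0.0, -0.4]])
    psi = np.array([[0.6, 0.2], [0.2, 0.7]])
    theta = np.array([0.4, 0.5, 0.3, 0.6])
    phi = np.array([[1.0, 0.3], [0.3, 1.0]])
    params = ts.ParameterSet(lam, gamma, psi, theta, phi)
    return spec, params
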