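"""Shared fixtures: a small synthetic study and a cheap trained model.

The "tiny" study uses short holds (4 s, 3 s extracted) and two iterations
per class so that unit tests exercising the full pipeline stay fast; the
full-size study (10 s holds, six iterations) is built only where segment
bookkeeping itself is under test.
"""

import numpy as np
import pytest

import myowrist as mw


@pytest.fixture(scope="session")
def amap() -> mw.ActivationMap:
    return mw.ActivationMap()


@pytest.fixture(scope="session")
def config19() -> mw.ClassConfig:
    return mw.load_class_config("nineteen")


@pytest.fixture(scope="session")
def config13() -> mw.ClassConfig:
    return mw.load_class_config("thirteen")


@pytest.fixture(scope="session")
def tiny_study(amap, config13):
    """13-class study, 2 iterations/class, 4 s holds with 3 s excerpts."""
    return mw.synth_study(amap, config13, iterations_per_class=2,
                          hold_extract_s=3.0, hold_seconds=4.0, seed=7)


@pytest.fixture(scope="session")
def tiny_features(tiny_study):
    return mw.build_feature_matrix(tiny_study)


@pytest.fixture(scope="session")
def tiny_model(tiny_features):
    """Model fitted at one fixed (C, gamma); enough for streaming tests."""
    grid = mw.GridSpec(c_values=(50.0,), gamma_values=(0.7,))
    return mw.grid_search_train(tiny_features, grid=grid, seed=0)


@pytest.fixture(scope="session")
def tiny_study19(amap, config19):
    return mw.synth_study(amap, config19, iterations_per_class=3,
                          hold_extract_s=4.0, hold_seconds=5.0, seed=7)


@pytest.fixture(scope="session")
def tiny_model19(tiny_study19):
    """19-class model: every 10 % staircase plateau is a configured class."""
    grid = mw.GridSpec(c_values=(50.0,), gamma_values=(0.7,))
    return mw.grid_search_train(mw.build_feature_matrix(tiny_study19), grid=grid, seed=0)
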