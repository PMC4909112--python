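"""Shared fixtures: expensive simulation runs are computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

import glucoflow as gf


@pytest.fixture(scope="session")
def default_network():
    return gf.build_default_network()


@pytest.fixture(scope="session")
def fasting_state():
    """Equilibrated fasting state of the normal scenario."""
    return gf.equilibrate(gf.Scenario())


@pytest.fixture(scope="session")
def normal_run():
    """The normal-preset OGTT (50 g duodenal gavage at t=100 min)."""
    return gf.run_scenario(gf.Scenario())


@pytest.fixture(scope="session")
def low_glp1_run():
    """GLP-1-deficient secretion: glucose sensitivity at the sweep floor."""
    return gf.run_scenario(gf.Scenario(glp1_glucose_sensitivity=0.1))


@pytest.fixture(scope="session")
def open_shunt_run():
    """Portosystemic shunt wide open, normal presinusoidal resistance."""
    return gf.run_scenario(gf.Scenario(pss_resistance=0.005))


@pytest.fixture(scope="session")
def no_shunt_run():
    """Control for normalized ratios: shunt resistance 40 (shunt absent)."""
    return gf.run_scenario(gf.Scenario(pss_resistance=40.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20160412)
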