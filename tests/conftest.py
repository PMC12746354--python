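"""Shared fixtures: tissues, protocols, and cached component tables."""

import numpy as np
import pytest

from afisim import (AFIProtocol, InterferenceParams, SimSettings,
                    TissueComponent, TwoComponentSystem, tissue_for)
from afisim.fitting import component_table


@pytest.fixture(scope="session")
def w1_3t() -> TissueComponent:
    return tissue_for("W1", "3T")


@pytest.fixture(scope="session")
def w1_3t_nodiff() -> TissueComponent:
    """W1 relaxation without diffusion, for EPG-vs-isochromat comparisons."""
    return TissueComponent(t1_ms=1301.0, t2_ms=585.0, adc_um2_s=0.0)


@pytest.fixture(scope="session")
def pvp5_system() -> TwoComponentSystem:
    return TwoComponentSystem.build(tissue_for("PVP5", "3T"), 320.0)


@pytest.fixture(scope="session")
def pvp5_params() -> InterferenceParams:
    return InterferenceParams.from_pi_units(0.136, -0.18, 320.0)


@pytest.fixture(scope="session")
def protocol_3t() -> AFIProtocol:
    return AFIProtocol(te_ms=1.9, a_g1=117.5, a_g2=587.5)


@pytest.fixture(scope="session")
def coarse_phi0_grid() -> np.ndarray:
    """Six-point Φ0 grid for fast fitting tests."""
    return np.array([0.0, 40.0, 60.0, 100.0, 120.0, 160.0])


@pytest.fixture(scope="session")
def pvp5_components(protocol_3t, pvp5_system, coarse_phi0_grid):
    """Component signal table on the coarse grid, shared across fit tests."""
    return component_table(protocol_3t, pvp5_system, coarse_phi0_grid,
                           SimSettings(), alpha_true_deg=60.0)
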