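"""Shared fixtures: expensive simulations are session-scoped and reused."""

from __future__ import annotations

import numpy as np
import pytest

from atriasim.calibration import tune_sigma_longitudinal
from atriasim.cell import REGION_IDS, make_regional_cell, pace_to_steady_state
from atriasim.geometry import build_idealized_atria, AtriaConfig
from atriasim.monodomain import StimulusSet, run_monodomain
from atriasim.presets import default_cell_map, default_conductivity, san_stimulus


@pytest.fixture(scope="session")
def regional_apds():
    """Final-beat APD90 (and the stabilization trace) per regional model,
    paced at 1 Hz with the convergence-stopped stabilization protocol."""
    out = {}
    for region in REGION_IDS:
        trace, apds = pace_to_steady_state(make_regional_cell(region),
                                           max_beats=1200)
        out[region] = (float(apds[-1]), trace)
    return out


@pytest.fixture(scope="session")
def ra_la_calibration():
    """sigma_L calibrated for general RA/LA tissue (63.3 cm/s, ratio 0.35)."""
    return tune_sigma_longitudinal(63.3, 0.35, make_regional_cell("RA/PM"))


@pytest.fixture(scope="session")
def bundle_calibration():
    """sigma_L calibrated for bundle tissue (116.0 cm/s, ratio 0.15)."""
    return tune_sigma_longitudinal(116.0, 0.15, make_regional_cell("CT/BB"),
                                   sigma0=12.0)


def _run_atria(config=None, isotropic=False, duration=90.0):
    mesh, labels, fibres = build_idealized_atria(config)
    cond = default_conductivity(mesh, labels, fibres)
    if isotropic:
        cond.sigma_t = cond.sigma_l.copy()
    stim = StimulusSet([san_stimulus(mesh, labels)])
    vm = run_monodomain(mesh, labels, cond, default_cell_map(labels), stim,
                        duration=duration, output_dt=1.0)
    return mesh, labels, fibres, vm


@pytest.fixture(scope="session")
def atria_run():
    """Sinus-rhythm activation of the idealized atria (anisotropic)."""
    return _run_atria()


@pytest.fixture(scope="session")
def atria_run_isotropic():
    """Same geometry and longitudinal conductivities, anisotropy ratio 1."""
    return _run_atria(isotropic=True)


@pytest.fixture(scope="session")
def atria_run_coarse():
    """Coarser surrogate (600 um voxels) for refinement-stability checks."""
    cfg = AtriaConfig(spacing_um=600.0, wall_thickness_cm=0.12)
    return _run_atria(cfg)
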