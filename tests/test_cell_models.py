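"""Single-cell electrophysiology: regional variants, pacing, APD, stability."""

import numpy as np
import pytest

from atriasim.cell import (
    REGIONAL_SCALINGS,
    ActionPotentialTrace,
    CellParameterSet,
    PacingProtocol,
    check_steady_state,
    make_regional_cell,
    measure_apd,
    pace_single_cell,
)


@pytest.mark.parametrize("region,expected", list(REGIONAL_SCALINGS.items()))
def test_regional_scalings_match_table(region, expected):
    params = make_regional_cell(region)
    assert params.scalings == expected
    assert params.region_id == region


def test_ra_pm_is_unscaled_baseline():
    params = make_regional_cell("RA/PM")
    assert params.scalings == (1.0, 1.0, 1.0)


def test_unknown_region_error_lists_valid_labels():
    with pytest.raises(ValueError, match="RA/PM.*CT/BB"):
        make_regional_cell("VENTRICLE")


def test_nonpositive_scaling_rejected():
    with pytest.raises(ValueError, match="strictly positive"):
        CellParameterSet(region_id="RA/PM", scale_gKr=0.0)


def test_baseline_identity_bitwise():
    """A regional RA/PM run is bitwise identical to the unscaled model."""
    proto = PacingProtocol(n_beats=1, output_dt=1.0)
    a = pace_single_cell(make_regional_cell("RA/PM"), proto)
    b = pace_single_cell(CellParameterSet(region_id="RA/PM"), proto)
    assert np.array_equal(a.vm, b.vm)
    assert np.array_equal(a.concentrations, b.concentrations)


def test_unstimulated_cell_stays_at_rest():
    proto = PacingProtocol(n_beats=2, stim_amplitude=0.0, output_dt=1.0)
    trace = pace_single_cell(make_regional_cell("RA/PM"), proto)
    assert np.all(np.abs(trace.vm - trace.vm[0]) < 1.0)


def test_apd_on_synthetic_linear_beat():
    """Instant upstroke -80 -> +20 mV, linear return to -80 at 300 ms."""
    t = np.linspace(0.0, 300.0, 3001)
    vm = 20.0 - 100.0 * t / 300.0
    vm[0] = -80.0  # pre-stimulus diastolic sample
    trace = ActionPotentialTrace(time=t, vm=vm, concentrations=None,
                                 prestim_concentrations=None)
    apd = measure_apd(trace, repolarization_fraction=0.9)
    assert apd == pytest.approx(270.0, abs=0.2)


def test_apd_requires_a_beat():
    t = np.arange(0.0, 100.0)
    trace = ActionPotentialTrace(time=t, vm=np.full_like(t, -80.0),
                                 concentrations=None,
                                 prestim_concentrations=None)
    with pytest.raises(ValueError, match="no beat detected"):
        measure_apd(trace)


def test_apd_fraction_validated():
    t = np.arange(0.0, 10.0)
    trace = ActionPotentialTrace(time=t, vm=np.zeros_like(t),
                                 concentrations=None,
                                 prestim_concentrations=None)
    with pytest.raises(ValueError):
        measure_apd(trace, repolarization_fraction=1.5)


def test_apd_step_size_convergence():
    """Halving dt changes the measured APD90 by well under 0.5 ms."""
    apds = {}
    for dt in (0.02, 0.01):
        proto = PacingProtocol(n_beats=15, dt=dt, output_dt=0.5)
        trace = pace_single_cell(make_regional_cell("RA/PM"), proto)
        apds[dt] = measure_apd(trace)
    assert abs(apds[0.02] - apds[0.01]) < 0.5


def test_gkr_scaling_never_lengthens_apd():
    """I_Kr is repolarizing: increasing its conductance cannot raise APD90."""
    proto = PacingProtocol(n_beats=30, output_dt=0.5)
    apds = []
    for gkr in (0.5, 1.0, 1.6, 3.2):
        params = CellParameterSet(region_id="RA/PM", scale_gKr=gkr)
        apds.append(measure_apd(pace_single_cell(params, proto)))
    assert all(a >= b for a, b in zip(apds, apds[1:]))


def test_steady_state_zero_for_periodic_concentrations():
    pre = np.tile([8.5, 129.5, 6.5e-5], (80, 1))
    trace = ActionPotentialTrace(time=np.arange(2.0), vm=np.zeros(2),
                                 concentrations=None,
                                 prestim_concentrations=pre)
    assert check_steady_state(trace, window_beats=60) == 0.0


def test_steady_state_reports_injected_drift():
    """A linear 1% drift on one species over the window reads back as 1%."""
    pre = np.tile([8.5, 129.5, 6.5e-5], (60, 1))
    pre[:, 0] *= np.linspace(1.0, 1.01, 60)
    trace = ActionPotentialTrace(time=np.arange(2.0), vm=np.zeros(2),
                                 concentrations=None,
                                 prestim_concentrations=pre)
    assert check_steady_state(trace, window_beats=60) == pytest.approx(1.0, rel=1e-9)


def test_steady_state_requires_concentrations():
    trace = ActionPotentialTrace(time=np.arange(2.0), vm=np.zeros(2),
                                 concentrations=None,
                                 prestim_concentrations=None)
    with pytest.raises(ValueError, match="concentration"):
        check_steady_state(trace)


def test_protocol_validation():
    with pytest.raises(ValueError):
        PacingProtocol(n_beats=0)
    with pytest.raises(ValueError):
        PacingProtocol(dt=0.0)
    with pytest.raises(ValueError):
        PacingProtocol(stim_duration=1200.0, bcl=1000.0)


def test_table_ordering_of_regional_apds(regional_apds):
    """Regional APD90 ordering: CT/BB > RA/PM > LA > PV and TV > MV."""
    apd = {r: v[0] for r, v in regional_apds.items()}
    assert apd["CT/BB"] > apd["RA/PM"] > apd["LA"] > apd["PV"]
    assert apd["TV"] > apd["MV"]


def test_stabilization_converges_before_reference_protocol_end(regional_apds):
    """APD90 drift per 20 beats falls below 0.2 ms well before 3600 beats."""
    for region, (_, trace) in regional_apds.items():
        assert trace.metadata["beats_run"] < 3600
        hist = trace.metadata["apd_history"]
        assert abs(hist[-1] - hist[-2]) < 0.2
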