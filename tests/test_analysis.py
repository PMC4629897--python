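"""Activation/APD maps, B-RMS, P-wave features, region decomposition."""

import numpy as np
import pytest

from atriasim.analysis import (
    compute_apd_map,
    compute_brms_map,
    compute_lat_map,
    decompose_region_contributions,
    extract_pwave_features,
)
from atriasim.forward import ObservationPoints
from atriasim.geometry import RegionLabelField, build_slab
from atriasim.monodomain import VmSeries


def _plane_wave(cv_cm_s=100.0, nx=20, ny=4, nz=1):
    mesh = build_slab(nx, ny, nz, 300.0)
    times = np.arange(0.0, 30.0, 0.5)
    lat = mesh.nodes[:, 0] / cv_cm_s * 1e3
    vm = -80.0 + 100.0 * np.clip(times[:, None] - lat[None, :], 0.0, 1.0)
    return VmSeries(times=times, vm=vm, mesh=mesh)


def test_lat_linear_along_plane_wave():
    """A 100 cm/s wave gives LAT slope 1 ms per mm along the axis."""
    vm = _plane_wave(100.0)
    lat = compute_lat_map(vm, threshold=-40.0)
    x = vm.mesh.nodes[:, 0]
    fit = np.polyfit(x, lat.times, 1)
    assert fit[0] == pytest.approx(10.0, rel=0.02)  # ms per cm


def test_lat_unactivated_nodes_flagged():
    vm = _plane_wave()
    vm.vm[:] = -80.0
    lat = compute_lat_map(vm)
    assert not lat.activated.any()


def test_apd_map_homogeneous_slab_is_tight():
    """Synthetic homogeneous repolarization: per-node APD uniform."""
    mesh = build_slab(6, 6, 1, 300.0)
    times = np.arange(0.0, 300.0, 1.0)
    v = np.full((len(times), mesh.n_nodes), -80.0)
    v[(times >= 5) & (times < 205)] = 20.0  # 200 ms square AP everywhere
    vm = VmSeries(times=times, vm=v, mesh=mesh)
    labels = RegionLabelField(names=("CT",),
                              indices=np.zeros(mesh.n_elements, dtype=int))
    m = compute_apd_map(vm, labels)
    assert m.n_excluded == 0
    assert m.region_table.loc[0, "sd_ms"] < 1.0
    assert int(m.region_table.loc[0, "n_nodes"]) == int(np.isfinite(m.apd).sum())


def test_brms_closed_forms():
    with pytest.raises(ValueError, match="empty"):
        compute_brms_map(np.zeros((5, 3)), times=np.arange(5.0),
                         window=(10.0, 20.0))
    assert np.all(compute_brms_map(np.zeros((8, 4))).values == 0.0)
    t = np.linspace(0.0, 1.0, 2001)[:-1]  # integer number of periods
    sine = 3.0 * np.sin(2 * np.pi * 5 * t)
    rms = compute_brms_map(sine[:, None]).values[0]
    assert rms == pytest.approx(3.0 / np.sqrt(2.0), rel=1e-3)


def test_brms_homogeneity_under_scaling():
    rng = np.random.default_rng(0)
    tr = rng.normal(size=(50, 7))
    a = compute_brms_map(tr).values
    b = compute_brms_map(-2.5 * tr).values
    assert np.allclose(b, 2.5 * a)


def test_pwave_monophasic_positive():
    t = np.linspace(0.0, 120.0, 400)
    v = np.exp(-((t - 60.0) / 15.0) ** 2)
    f = extract_pwave_features(t, v)
    assert f.morphology == "monophasic+"
    assert f.duration > 0
    assert f.amplitude == pytest.approx(v.max() - v.min())


def test_pwave_biphasic():
    t = np.linspace(0.0, 120.0, 400)
    v = np.exp(-((t - 40.0) / 10.0) ** 2) - np.exp(-((t - 80.0) / 10.0) ** 2)
    assert extract_pwave_features(t, v).morphology == "biphasic"


def test_pwave_m_shaped():
    t = np.linspace(0.0, 120.0, 400)
    v = np.exp(-((t - 40.0) / 12.0) ** 2) + np.exp(-((t - 80.0) / 12.0) ** 2)
    f = extract_pwave_features(t, v)  # ~50% notch between equal peaks
    assert f.morphology == "M-shaped"


def test_pwave_negative_and_flat():
    t = np.linspace(0.0, 120.0, 400)
    v = -np.exp(-((t - 60.0) / 15.0) ** 2)
    assert extract_pwave_features(t, v).morphology == "monophasic-"
    flat = extract_pwave_features(t, np.zeros_like(t))
    assert flat.morphology == "indeterminate"
    assert flat.amplitude == 0.0


def test_single_region_decomposition_equals_total():
    vm = _plane_wave()
    labels = RegionLabelField(names=("CT",),
                              indices=np.zeros(vm.mesh.n_elements, dtype=int))
    pts = ObservationPoints(names=["P"], positions=[[3.0, 2.0, 2.0]])
    out = decompose_region_contributions(vm, labels, pts)
    assert np.array_equal(out.per_region["CT"].values, out.total.values)
    assert out.shares.sum() == pytest.approx(100.0, abs=1e-6)


def test_half_slab_contributions_sum_to_whole():
    vm = _plane_wave()
    cent = vm.mesh.element_centroids()
    idx = (cent[:, 0] >= cent[:, 0].mean()).astype(np.int64)
    labels = RegionLabelField(names=("RAS", "LAS"), indices=idx)
    pts = ObservationPoints(names=["P", "Q"],
                            positions=[[3.0, 2.0, 2.0], [-2.0, 0.0, 1.0]])
    out = decompose_region_contributions(vm, labels, pts)
    summed = out.per_region["RAS"].values + out.per_region["LAS"].values
    scale = np.abs(out.total.values).max()
    assert np.allclose(summed, out.total.values, rtol=0, atol=1e-12 * scale)
    assert out.shares.sum() == pytest.approx(100.0, abs=1e-6)


def test_decomposition_label_mismatch_raises():
    vm = _plane_wave()
    labels = RegionLabelField(names=("CT",), indices=np.zeros(3, dtype=int))
    pts = ObservationPoints(names=["P"], positions=[[3.0, 2.0, 2.0]])
    with pytest.raises(ValueError, match="label"):
        decompose_region_contributions(vm, labels, pts)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=30, derandomize=True, deadline=None)
@given(scale=st.floats(min_value=1e-3, max_value=1e3),
       centre=st.floats(min_value=30.0, max_value=90.0),
       width=st.floats(min_value=5.0, max_value=25.0))
def test_pwave_class_invariant_under_positive_scaling(scale, centre, width):
    """Positive rescaling preserves the morphology class and scales the
    amplitude linearly."""
    t = np.linspace(0.0, 120.0, 500)
    v = np.exp(-((t - centre) / width) ** 2)
    base = extract_pwave_features(t, v)
    scaled = extract_pwave_features(t, scale * v)
    assert scaled.morphology == base.morphology == "monophasic+"
    assert scaled.amplitude == pytest.approx(scale * base.amplitude, rel=1e-9)
    assert scaled.duration == pytest.approx(base.duration)
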