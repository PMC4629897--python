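"""Monodomain solver: operator properties, 0D equivalence, tissue behavior."""

import numpy as np
import pytest

from atriasim.cell import PacingProtocol, make_regional_cell, pace_single_cell
from atriasim.geometry import assign_fibres, build_slab, uniform_labels
from atriasim.monodomain import (
    ConductivityField,
    Stimulus,
    StimulusSet,
    assemble_diffusion,
    run_monodomain,
)


def _slab(nx=6, ny=5, nz=2, spacing=300.0):
    mesh = build_slab(nx, ny, nz, spacing)
    labels = uniform_labels(mesh)
    fibres = assign_fibres(mesh, labels, {"TISSUE": np.array([0.0, -1.0, 0.0])})
    return mesh, labels, fibres


def test_operator_annihilates_constants_and_is_symmetric():
    mesh, _, fibres = _slab()
    op = assemble_diffusion(mesh, ConductivityField.uniform(mesh, 3.0, 0.35,
                                                            fibres))
    K = op.stiffness
    assert np.max(np.abs(K @ np.ones(mesh.n_nodes))) < 1e-12
    assert abs(K - K.T).max() < 1e-12


def test_operator_zero_laplacian_for_linear_field():
    """div(D grad x) = 0: interior rows annihilate linear fields."""
    mesh, _, fibres = _slab(8, 8, 2)
    op = assemble_diffusion(mesh, ConductivityField.uniform(mesh, 3.0, 1.0,
                                                            fibres))
    resid = op.apply(mesh.nodes[:, 0])
    lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
    interior = np.all((mesh.nodes > lo + 1e-9) & (mesh.nodes < hi - 1e-9),
                      axis=1)
    assert interior.any()
    assert np.max(np.abs(resid[interior])) < 1e-10


def test_conductivity_requires_spd_ordering():
    mesh, _, fibres = _slab()
    with pytest.raises(ValueError, match="elements"):
        ConductivityField.uniform(mesh, 1.0, 2.0, fibres)  # sigma_t > sigma_l
    with pytest.raises(ValueError):
        ConductivityField.uniform(mesh, -1.0, 1.0, fibres)


def test_unstimulated_tissue_rests_for_one_second():
    mesh, labels, fibres = _slab(4, 3, 1)
    cond = ConductivityField.uniform(mesh, 3.0, 0.35, fibres)
    vm = run_monodomain(mesh, labels, cond,
                        {"TISSUE": make_regional_cell("RA/PM")},
                        StimulusSet([]), duration=1000.0, output_dt=10.0)
    assert np.max(np.abs(vm.vm - vm.vm[0, 0])) < 1.0


def test_single_element_matches_zero_dimensional_cell():
    """With vanishing conductivity a 1-element mesh reproduces the 0D AP."""
    mesh, labels, fibres = _slab(1, 1, 1)
    cond = ConductivityField.uniform(mesh, 1e-6, 1.0, fibres)
    params = make_regional_cell("RA/PM")
    stim = StimulusSet([Stimulus(nodes=np.arange(8), start=10.0, duration=1.0,
                                 amplitude=52.0)])
    vm = run_monodomain(mesh, labels, cond, {"TISSUE": params}, stim,
                        duration=400.0, output_dt=1.0)
    proto = PacingProtocol(n_beats=1, bcl=400.0, stim_amplitude=52.0,
                           stim_duration=1.0, output_dt=1.0)
    trace = pace_single_cell(params, proto)
    v0d = np.interp(vm.times - 10.0, trace.time, trace.vm, left=trace.vm[0])
    rms = np.sqrt(np.mean((vm.vm[:, 0] - v0d) ** 2))
    assert rms < 0.5


def test_missing_cell_model_raises():
    mesh, labels, fibres = _slab()
    cond = ConductivityField.uniform(mesh, 3.0, 0.35, fibres)
    with pytest.raises(ValueError, match="TISSUE"):
        run_monodomain(mesh, labels, cond, {}, StimulusSet([]), duration=1.0)


def test_mirrored_stimulus_gives_mirrored_field():
    mesh, labels, fibres = _slab(10, 4, 1)
    cond = ConductivityField.uniform(mesh, 3.0, 1.0, fibres)
    params = {"TISSUE": make_regional_cell("RA/PM")}
    xmax = mesh.nodes[:, 0].max()
    left = np.nonzero(mesh.nodes[:, 0] < 0.08)[0]
    right = np.nonzero(mesh.nodes[:, 0] > xmax - 0.08)[0]
    vm_l = run_monodomain(mesh, labels, cond, params,
                          StimulusSet([Stimulus(nodes=left, duration=2.0,
                                                amplitude=52.0)]),
                          duration=10.0, output_dt=1.0)
    vm_r = run_monodomain(mesh, labels, cond, params,
                          StimulusSet([Stimulus(nodes=right, duration=2.0,
                                                amplitude=52.0)]),
                          duration=10.0, output_dt=1.0)
    # mirror map: node at x -> node at xmax - x
    mirrored = mesh.nodes.copy()
    mirrored[:, 0] = xmax - mirrored[:, 0]
    order = np.lexsort(mesh.nodes.T)
    order_m = np.lexsort(mirrored.T)
    perm = np.empty(mesh.n_nodes, dtype=int)
    perm[order] = order_m
    assert np.allclose(vm_l.vm, vm_r.vm[:, perm], atol=1e-6)


def test_stimulus_activity_windows():
    s = Stimulus(nodes=np.array([0]), start=5.0, duration=2.0, period=100.0,
                 count=2)
    assert not s.active(4.9)
    assert s.active(5.0) and s.active(6.9)
    assert not s.active(7.1)
    assert s.active(105.5)
    assert not s.active(205.5)  # train exhausted
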