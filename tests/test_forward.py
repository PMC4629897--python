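"""Forward problem: pseudo-ECG integral and torso Laplace solver."""

import numpy as np
import pytest

from atriasim.forward import (
    ObservationPoints,
    TorsoConfig,
    TorsoLaplaceSolver,
    build_simplified_torso,
    compute_pseudo_ecg,
    extract_leads,
    solve_torso_laplace,
    standard_lead_positions,
)
from atriasim.geometry import build_slab
from atriasim.monodomain import VmSeries


def _series(mesh, vm):
    times = np.arange(vm.shape[0], dtype=float)
    return VmSeries(times=times, vm=vm, mesh=mesh)


@pytest.fixture(scope="module")
def slab_mesh():
    return build_slab(10, 10, 4, 300.0)


def test_uniform_vm_gives_zero_potential(slab_mesh):
    vm = _series(slab_mesh, np.full((4, slab_mesh.n_nodes), -62.0))
    pts = ObservationPoints(names=["P"], positions=[[4.0, 4.0, 4.0]])
    traces = compute_pseudo_ecg(vm, pts)
    assert np.max(np.abs(traces.values)) < 1e-12


def test_gamma_linearity(slab_mesh):
    rng = np.random.default_rng(3)
    vm = _series(slab_mesh, rng.normal(size=(5, slab_mesh.n_nodes)))
    pts = ObservationPoints(names=["P"], positions=[[4.0, 4.0, 4.0]])
    v1 = compute_pseudo_ecg(vm, pts, gamma=1.0).values
    v2 = compute_pseudo_ecg(vm, pts, gamma=2.0).values
    assert np.allclose(v2, 2.0 * v1)


def test_observation_point_inside_mesh_raises(slab_mesh):
    vm = _series(slab_mesh, np.zeros((2, slab_mesh.n_nodes)))
    pts = ObservationPoints(names=["inside"], positions=[[0.15, 0.15, 0.06]])
    with pytest.raises(ValueError, match="inside"):
        compute_pseudo_ecg(vm, pts)


def test_superposition_of_disjoint_sources(slab_mesh):
    """Masked sources over a partition sum to the total at machine precision."""
    rng = np.random.default_rng(5)
    vm = _series(slab_mesh, rng.normal(size=(3, slab_mesh.n_nodes)))
    pts = ObservationPoints(names=["P", "Q"],
                            positions=[[4.0, 4.0, 4.0], [-3.0, 1.0, 2.0]])
    cent = slab_mesh.element_centroids()
    mask_a = cent[:, 0] < cent[:, 0].mean()
    total = compute_pseudo_ecg(vm, pts).values
    va = compute_pseudo_ecg(vm, pts, element_mask=mask_a).values
    vb = compute_pseudo_ecg(vm, pts, element_mask=~mask_a).values
    assert np.allclose(va + vb, total, rtol=0, atol=1e-15 + 1e-12 * np.abs(total).max())


def test_far_field_dipole_decay(slab_mesh):
    """A compact uniform-gradient source decays as 1/r^2 along a ray."""
    x = slab_mesh.nodes[:, 0]
    vm = _series(slab_mesh, np.tile(x, (2, 1)))
    cent = slab_mesh.element_centroids()
    c0 = cent.mean(axis=0)
    ball = np.linalg.norm(cent - c0, axis=1) < 0.1
    assert ball.sum() > 5
    ray = np.array([1.0, 0.3, 0.2])
    ray /= np.linalg.norm(ray)
    r = 4.0
    pts = ObservationPoints(names=["near", "far"],
                            positions=[c0 + r * ray, c0 + 2 * r * ray])
    tr = compute_pseudo_ecg(vm, pts, element_mask=ball)
    ratio = tr["near"][0] / tr["far"][0]
    assert ratio == pytest.approx(4.0, rel=0.10)


def test_grid_convergence_of_pseudo_ecg():
    """One uniform refinement changes the potential of a fixed smooth
    (grid-resolved) source by < 2%."""
    pts = ObservationPoints(names=["P"], positions=[[5.0, 5.0, 5.0]])
    vals = []
    for n, h in ((10, 300.0), (20, 150.0)):
        mesh = build_slab(n, n, n // 2, h)
        xyz = mesh.nodes
        vm_field = np.sin(2 * np.pi * xyz[:, 0] / 0.6) * xyz[:, 1]
        vm = _series(mesh, vm_field[None, :])
        vals.append(compute_pseudo_ecg(vm, pts).values[0, 0])
    assert vals[1] == pytest.approx(vals[0], rel=0.02)


# ---------------------------------------------------------------------------
# torso
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def torso_and_table():
    return build_simplified_torso(TorsoConfig(spacing=1.5))


def test_torso_every_element_labeled_and_covered(torso_and_table):
    torso, table = torso_and_table
    assert set(torso.organ_labels()) <= set(table)
    assert len(torso.organ_indices) == len(torso.tets)
    assert {"chest", "lung", "bone", "liver", "blood", "myocardium"} == \
        set(torso.organ_labels())


def test_homogeneous_torso_is_all_chest():
    torso, table = build_simplified_torso(TorsoConfig(
        spacing=2.0, include_lungs=False, include_bone=False,
        include_liver=False, atrial_radius=0.0, myocardium_thickness=0.0,
        source_layer_offset=2.0))
    assert set(torso.organ_labels()) == {"chest"}
    assert table == {"chest": 2.390}


def test_source_layer_at_offset_within_element_size(torso_and_table):
    torso, _ = torso_and_table
    cfg = TorsoConfig(spacing=1.5)
    r = np.linalg.norm(torso.nodes[torso.inner_nodes]
                       - np.asarray(cfg.heart_center), axis=1)
    target = cfg.atrial_radius + cfg.myocardium_thickness + 0.08
    assert np.all(np.abs(r - target) <= cfg.spacing)


def test_laplace_constant_dirichlet_gives_constant_field(torso_and_table):
    torso, table = torso_and_table
    v = solve_torso_laplace(torso, table,
                            np.full(len(torso.inner_nodes), 7.25))
    assert np.max(np.abs(v - 7.25)) < 1e-9


def test_laplace_discrete_maximum_principle(torso_and_table):
    torso, table = torso_and_table
    rng = np.random.default_rng(11)
    inner = rng.uniform(-1.0, 1.0, len(torso.inner_nodes))
    v = solve_torso_laplace(torso, table, inner)
    assert v.min() >= inner.min() - 1e-9
    assert v.max() <= inner.max() + 1e-9


def test_laplace_two_layer_analytic_solution():
    """1D conductivity contrast 1:2 with Dirichlet plates: piecewise-linear
    solution with flux continuity, reproduced to solver accuracy."""
    torso, _ = build_simplified_torso(TorsoConfig(
        size=(6.0, 6.0, 12.0), spacing=1.0, include_lungs=False,
        include_bone=False, include_liver=False, atrial_radius=0.0,
        myocardium_thickness=0.0, source_layer_offset=2.0))
    z = torso.nodes[:, 2]
    zmin, zmax = z.min(), z.max()
    cent = torso.nodes[torso.tets].mean(axis=1)
    lab = np.where(cent[:, 2] < 0.0, 0, 1).astype(np.int64)
    torso.organ_names = ("lower", "upper")
    torso.organ_indices = lab
    plates = np.nonzero(np.isclose(z, zmin) | np.isclose(z, zmax))[0]
    torso.inner_nodes = plates
    bc = np.where(np.isclose(z[plates], zmin), 0.0, 1.0)
    v = solve_torso_laplace(torso, {"lower": 1.0, "upper": 2.0}, bc)
    # sigma1 g1 = sigma2 g2, V continuous, V(zmin)=0, V(zmax)=1
    L = zmax - zmin
    g1 = 1.0 / (L / 2 + (1.0 / 2.0) * L / 2)  # = 2/(3/2 L) with sigma ratio 2
    v_mid = g1 * (L / 2)
    expected = np.where(z < 0.0, g1 * (z - zmin),
                        v_mid + 0.5 * g1 * z)
    assert np.max(np.abs(v - expected)) < 1e-9


def test_laplace_requires_dirichlet_and_known_organs(torso_and_table):
    torso, table = torso_and_table
    import copy
    t2 = copy.copy(torso)
    t2.inner_nodes = np.array([], dtype=int)
    with pytest.raises(ValueError, match="Dirichlet"):
        TorsoLaplaceSolver(t2, table)
    with pytest.raises(ValueError, match="conductivity"):
        TorsoLaplaceSolver(torso, {"chest": 2.39})


def test_lead_extraction_nodal_and_constant(torso_and_table):
    torso, _ = torso_and_table
    rng = np.random.default_rng(2)
    field = rng.normal(size=(1, torso.n_nodes))
    node = torso.tets[100, 0]
    pts = ObservationPoints(names=["at_node"],
                            positions=[torso.nodes[node]])
    tr = extract_leads(torso, field, np.array([0.0]), pts)
    assert tr.values[0, 0] == pytest.approx(field[0, node], abs=1e-9)
    const = np.full((3, torso.n_nodes), 4.2)
    tr2 = extract_leads(torso, const, np.arange(3.0), pts)
    assert np.allclose(tr2.values, 4.2)


def test_lead_extraction_outside_hull_raises(torso_and_table):
    torso, _ = torso_and_table
    pts = ObservationPoints(names=["out"], positions=[[100.0, 0.0, 0.0]])
    with pytest.raises(ValueError, match="outside"):
        extract_leads(torso, np.zeros((1, torso.n_nodes)), np.array([0.0]), pts)


def test_bipolar_lead_is_pointwise_difference(torso_and_table):
    torso, _ = torso_and_table
    rng = np.random.default_rng(4)
    field = rng.normal(size=(5, torso.n_nodes))
    pts = standard_lead_positions(torso_radius=2.5)
    tr = extract_leads(torso, field, np.arange(5.0), pts)
    d1 = tr.bipolar("D1", "LA_e", "RA_e")
    assert np.allclose(d1.values[:, 0], tr["LA_e"] - tr["RA_e"])
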