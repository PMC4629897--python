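"""Forward computation of extracellular potentials.

Two torso representations are supported:

* infinite homogeneous medium ("pseudo-ECG"): the extracellular potential at
  an observation point r is the volume integral of the transmembrane
  potential gradient against the gradient of 1/|r' - r|,

      V(r) = -(gamma / 4 pi) (sigma_i / sigma_e)
             sum_e  grad Vm(e) . grad'(1/|r_e - r|)  vol(e),

  evaluated with constant-per-element trilinear gradients at centroids and
  the analytic kernel gradient. The potential is linear in Vm and in gamma,
  so per-region source masking decomposes the signal exactly.

* heterogeneous torso volume conductor: under the quasi-static assumption
  each output time step solves the Laplace equation
  div(D_T grad V_T) = 0 with organ-wise isotropic conductivities, Dirichlet
  values on an inner source layer offset 0.8 mm from the atrial boundary
  (fed by the infinite-medium integral) and zero flux on the skin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .geometry import HexMesh
from .monodomain import VmSeries, _DN

#: organ conductivities of the heterogeneous torso (mS/cm)
ORGAN_CONDUCTIVITIES: dict[str, float] = {
    "myocardium": 4.589,
    "bone": 0.200,
    "liver": 0.277,
    "lung": 0.389,
    "chest": 2.390,
    "blood": 7.0,
}


@dataclass
class ObservationPoints:
    """Named observation points (cm) for lead extraction."""

    names: list[str]
    positions: np.ndarray  # (n, 3)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if len(self.names) != len(self.positions):
            raise ValueError("names and positions length mismatch")


@dataclass
class LeadTraces:
    """V(lead, t) in mV on a common time grid (ms)."""

    times: np.ndarray
    names: list[str]
    values: np.ndarray  # (n_t, n_leads)

    def __post_init__(self):
        if self.values.shape != (len(self.times), len(self.names)):
            raise ValueError("values shape must be (n_times, n_leads)")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def bipolar(self, name: str, plus: str, minus: str) -> "LeadTraces":
        v = (self[plus] - self[minus])[:, None]
        return LeadTraces(times=self.times, names=[name], values=v)


def standard_lead_positions(
    heart_center: np.ndarray | tuple = (0.0, 0.0, 0.0),
    torso_radius: float = 8.0,
) -> ObservationPoints:
    """Surrogate electrode layout around a heart-centred frame (cm).

    Precordial V1-V6 sweep across the anterior chest (y < 0), limb
    equivalents (RA_e, LA_e, LL_e) sit at the shoulders/hip, and N1-N9 form
    a 3x3 grid on the back. Positions are desk-scale stand-ins for the
    clinical layout, not a torso registration.
    """
    c = np.asarray(heart_center, dtype=float)
    r = torso_radius
    pts: list[tuple[str, np.ndarray]] = []
    # precordials: arc from right parasternal to left midaxillary
    angles = np.deg2rad([105.0, 75.0, 55.0, 35.0, 10.0, -15.0])
    for i, a in enumerate(angles, start=1):
        pts.append((f"V{i}",
                    c + np.array([r * np.cos(a) * -1.0, -r * 0.8, 2.0 - 0.8 * i])))
    pts.append(("RA_e", c + np.array([-r, -2.0, r])))
    pts.append(("LA_e", c + np.array([r, -2.0, r])))
    pts.append(("LL_e", c + np.array([r * 0.4, -2.0, -r * 1.4])))
    k = 1
    for z in (4.0, 0.0, -4.0):
        for x in (-5.0, 0.0, 5.0):
            pts.append((f"N{k}", c + np.array([x, r * 0.8, z])))
            k += 1
    names = [n for n, _ in pts]
    pos = np.array([p for _, p in pts])
    return ObservationPoints(names=names, positions=pos)


def _element_gradient_operator(mesh: HexMesh):
    """Per-element (8,3) operator: nodal values -> centroid gradient, and
    element volumes."""
    X = mesh.nodes[mesh.elements]
    dN0 = np.zeros((8, 3))
    for g in range(8):
        dN0 += _DN[g] / 8.0  # average of Gauss-point gradients ~ centre value
    J = np.einsum("ai,eaj->eij", dN0, X)
    detJ = np.abs(np.linalg.det(J))
    # volume via full quadrature (exact for trilinear maps of parallelepipeds)
    vol = np.zeros(mesh.n_elements)
    for g in range(8):
        Jg = np.einsum("ai,eaj->eij", _DN[g], X)
        vol += np.abs(np.linalg.det(Jg))
    G = np.einsum("ai,eij->eaj", dN0, np.linalg.inv(J))
    return G, vol


def compute_pseudo_ecg(
    vm: VmSeries,
    points: ObservationPoints,
    gamma: float = 1.0,
    sigma_ratio: float = 1.0,
    element_mask: np.ndarray | None = None,
) -> LeadTraces:
    """Infinite-medium extracellular potentials at the observation points.

    ``element_mask`` restricts the source integral to a subset of elements
    (the basis of the per-region contribution decomposition); by linearity
    masked traces over a partition of the mesh sum exactly to the total.
    Raises if an observation point touches the source mesh (singular
    kernel).
    """
    mesh = vm.mesh
    G, vol = _element_gradient_operator(mesh)
    centroids = mesh.element_centroids()
    h = np.cbrt(vol)
    tree = cKDTree(centroids)
    d_min, _ = tree.query(points.positions, k=1)
    too_close = d_min < 1.5 * h.max()
    if too_close.any():
        bad = [points.names[i] for i in np.nonzero(too_close)[0]]
        raise ValueError(f"observation points inside/touching the mesh: {bad}")

    if element_mask is not None:
        sel = np.asarray(element_mask, dtype=bool)
        G = G[sel]
        vol = vol[sel]
        centroids = centroids[sel]
        elements = mesh.elements[sel]
    else:
        elements = mesh.elements

    # kernel gradient: grad'(1/|r'-r|) = -(r'-r)/|r'-r|^3 at element centroids
    diff = centroids[None, :, :] - points.positions[:, None, :]  # (p, e, 3)
    dist3 = np.linalg.norm(diff, axis=2) ** 3
    kernel = -diff / dist3[:, :, None] * vol[:, None]             # (p, e, 3)

    vm_nodes = vm.vm[:, elements]                                 # (t, e, 8)
    grad = np.einsum("tea,eaj->tej", vm_nodes, G)                 # (t, e, 3)
    coef = -(gamma / (4.0 * np.pi)) * sigma_ratio
    values = coef * np.einsum("tej,pej->tp", grad, kernel)
    return LeadTraces(times=vm.times, names=list(points.names), values=values)


# --------------------------------------------------------------------------
# Simplified torso volume conductor
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TorsoConfig:
    """Parametric desk-scale torso: a box with embedded simplified organs."""

    size: tuple[float, float, float] = (24.0, 18.0, 30.0)  # cm
    spacing: float = 1.0                                   # cm
    heart_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    atrial_radius: float = 1.6       # blood cavity radius (cm)
    myocardium_thickness: float = 0.8
    source_layer_offset: float = 0.08  # cm = 0.8 mm outside the atrial wall
    include_lungs: bool = True
    include_bone: bool = True
    include_liver: bool = True
    conductivities: dict = field(default_factory=lambda: dict(ORGAN_CONDUCTIVITIES))


@dataclass
class TorsoMesh:
    """Labeled tetrahedral torso mesh with the designated source layer."""

    nodes: np.ndarray                 # (n, 3) cm
    tets: np.ndarray                  # (m, 4) int
    organ_names: tuple[str, ...]
    organ_indices: np.ndarray         # (m,) int into organ_names
    inner_nodes: np.ndarray           # node ids of the 0.8 mm source layer
    surface_nodes: np.ndarray         # node ids on the outer skin

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def organ_labels(self) -> np.ndarray:
        return np.asarray(self.organ_names, dtype=object)[self.organ_indices]


# Kuhn decomposition of a cube into 6 tetrahedra sharing the main diagonal.
_KUHN_TETS = np.array([
    (0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
    (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7),
])
_CUBE_OFFSETS = np.array([
    (0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
    (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1),
])


def build_simplified_torso(config: TorsoConfig | None = None
                           ) -> tuple[TorsoMesh, dict[str, float]]:
    """Structured tetrahedral torso box with embedded simplified organs.

    Organs: two lung ellipsoids, a spherical blood pool wrapped in a
    myocardial shell at the heart centre, a spine column (bone) and a liver
    block; everything else is chest. The inner source layer is the set of
    mesh nodes nearest to the sphere offset ``source_layer_offset`` outside
    the myocardial boundary (within one element spacing). With all organ
    flags off the mesh is homogeneous chest.
    """
    cfg = config or TorsoConfig()
    sx, sy, sz = cfg.size
    h = cfg.spacing
    nx, ny, nz = (int(round(s / h)) for s in (sx, sy, sz))
    xs = np.linspace(-sx / 2, sx / 2, nx + 1)
    ys = np.linspace(-sy / 2, sy / 2, ny + 1)
    zs = np.linspace(-sz / 2, sz / 2, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    corners = np.stack([nid(ijk[:, 0] + di, ijk[:, 1] + dj, ijk[:, 2] + dk)
                        for di, dj, dk in _CUBE_OFFSETS], axis=1)
    tets = corners[:, _KUHN_TETS].reshape(-1, 4)

    centroids = nodes[tets].mean(axis=1)
    hc = np.asarray(cfg.heart_center)
    r = np.linalg.norm(centroids - hc, axis=1)
    r_myo = cfg.atrial_radius + cfg.myocardium_thickness

    organ_names = ("chest", "blood", "myocardium", "lung", "bone", "liver")
    name_to_i = {n: i for i, n in enumerate(organ_names)}
    lab = np.zeros(len(tets), dtype=np.int64)
    if cfg.include_liver:
        in_liver = ((centroids[:, 0] > 1.0) & (centroids[:, 0] < 9.0)
                    & (np.abs(centroids[:, 1]) < 6.0)
                    & (centroids[:, 2] > -12.0) & (centroids[:, 2] < -6.0))
        lab[in_liver] = name_to_i["liver"]
    if cfg.include_bone:
        spine = (np.linalg.norm(centroids[:, :2] - np.array([0.0, 6.5]),
                                axis=1) < 1.5)
        lab[spine] = name_to_i["bone"]
    if cfg.include_lungs:
        for cx in (-6.0, 6.0):
            lung_c = np.array([cx, 0.5, 2.0])
            lung_r = np.array([3.5, 5.0, 9.0])
            inside = (((centroids - lung_c) ** 2 / lung_r ** 2).sum(axis=1) < 1)
            lab[inside] = name_to_i["lung"]
    lab[r < r_myo] = name_to_i["myocardium"]
    lab[r < cfg.atrial_radius] = name_to_i["blood"]

    # inner source layer: nodes nearest the 0.8 mm offset sphere
    rn = np.linalg.norm(nodes - hc, axis=1)
    r_layer = r_myo + cfg.source_layer_offset
    inner = np.nonzero(np.abs(rn - r_layer) <= 0.75 * h)[0]
    if len(inner) == 0:
        raise RuntimeError("empty source layer; spacing too coarse")

    on_surf = (
        np.isclose(np.abs(nodes[:, 0]), sx / 2)
        | np.isclose(np.abs(nodes[:, 1]), sy / 2)
        | np.isclose(np.abs(nodes[:, 2]), sz / 2)
    )
    used = set(organ_names[i] for i in np.unique(lab))
    table = {k: cfg.conductivities[k] for k in used}
    torso = TorsoMesh(nodes=nodes, tets=tets, organ_names=organ_names,
                      organ_indices=lab, inner_nodes=inner,
                      surface_nodes=np.nonzero(on_surf)[0])
    return torso, table


def _tet_stiffness(nodes: np.ndarray, tets: np.ndarray,
                   sigma: np.ndarray) -> sp.csr_matrix:
    """P1 FEM stiffness for div(sigma grad .) on tetrahedra."""
    X = nodes[tets]  # (m, 4, 3)
    v0 = X[:, 0]
    E = X[:, 1:] - v0[:, None, :]             # (m, 3, 3) edge matrix
    detE = np.linalg.det(E)
    vol = np.abs(detE) / 6.0
    Einv = np.linalg.inv(E)                   # rows: grad of barycentric 1..3
    grads = np.empty((len(tets), 4, 3))
    grads[:, 1:, :] = np.transpose(Einv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    Ke = np.einsum("eai,ebi->eab", grads, grads) * (sigma * vol)[:, None, None]
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    n = len(nodes)
    return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


class TorsoLaplaceSolver:
    """Quasi-static heterogeneous Laplace solver, factorized once.

    Dirichlet data on the inner source layer, homogeneous Neumann on the
    rest; one ``solve`` per output time step.
    """

    def __init__(self, torso: TorsoMesh, conductivities: dict[str, float]):
        missing = set(torso.organ_labels()) - set(conductivities)
        if missing:
            raise ValueError(f"no conductivity for organs: {sorted(missing)}")
        sigma = np.array([conductivities[n] for n in torso.organ_labels()],
                         dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("organ conductivities must be positive")
        if len(torso.inner_nodes) == 0:
            raise ValueError("empty Dirichlet (source layer) set")
        self.torso = torso
        K = _tet_stiffness(torso.nodes, torso.tets, sigma)
        n = torso.n_nodes
        self.dirichlet = np.asarray(torso.inner_nodes, dtype=np.int64)
        free = np.setdiff1d(np.arange(n), self.dirichlet)
        self.free = free
        self._K_fd = K[free][:, self.dirichlet]
        self._solve_ff = spla.factorized(K[free][:, free].tocsc())

    def solve(self, inner_values: np.ndarray) -> np.ndarray:
        """Potential at every torso node given source-layer values (mV)."""
        inner_values = np.asarray(inner_values, dtype=float)
        if inner_values.shape != self.dirichlet.shape:
            raise ValueError("inner_values must match the source-layer nodes")
        out = np.empty(self.torso.n_nodes)
        out[self.dirichlet] = inner_values
        out[self.free] = self._solve_ff(-self._K_fd @ inner_values)
        return out


def solve_torso_laplace(torso: TorsoMesh, conductivities: dict[str, float],
                        inner_values: np.ndarray) -> np.ndarray:
    """One-off heterogeneous Laplace solve (see TorsoLaplaceSolver)."""
    return TorsoLaplaceSolver(torso, conductivities).solve(inner_values)


def compute_torso_potentials(
    vm: VmSeries,
    torso: TorsoMesh,
    conductivities: dict[str, float],
    gamma: float = 1.0,
    sigma_ratio: float = 1.0,
) -> np.ndarray:
    """Two-stage forward solve: infinite-medium potentials on the source
    layer drive per-time-step torso Laplace solves.

    Returns V_T with shape (n_times, n_torso_nodes) in mV.
    """
    layer = ObservationPoints(
        names=[f"src{i}" for i in range(len(torso.inner_nodes))],
        positions=torso.nodes[torso.inner_nodes],
    )
    inner = compute_pseudo_ecg(vm, layer, gamma=gamma, sigma_ratio=sigma_ratio)
    solver = TorsoLaplaceSolver(torso, conductivities)
    out = np.empty((len(vm.times), torso.n_nodes))
    for t in range(len(vm.times)):
        out[t] = solver.solve(inner.values[t])
    return out


def extract_leads(
    torso: TorsoMesh,
    potentials: np.ndarray,
    times: np.ndarray,
    points: ObservationPoints,
) -> LeadTraces:
    """Barycentric interpolation of torso potentials at lead positions.

    Raises if a point lies outside the torso mesh hull.
    """
    centroids = torso.nodes[torso.tets].mean(axis=1)
    tree = cKDTree(centroids)
    nq = min(64, len(centroids))
    _, cand = tree.query(points.positions, k=nq)
    cand = np.atleast_2d(cand)
    values = np.empty((len(times), len(points.names)))
    for p in range(len(points.names)):
        found = False
        for e in cand[p]:
            tet = torso.tets[e]
            X = torso.nodes[tet]
            T = (X[1:] - X[0]).T
            try:
                lam = np.linalg.solve(T, points.positions[p] - X[0])
            except np.linalg.LinAlgError:
                continue
            bary = np.concatenate([[1.0 - lam.sum()], lam])
            if np.all(bary >= -1e-9):
                values[:, p] = potentials[:, tet] @ bary
                found = True
                break
        if not found:
            raise ValueError(
                f"lead {points.names[p]} at {points.positions[p].tolist()} "
                "is outside the torso mesh"
            )
    return LeadTraces(times=np.asarray(times), names=list(points.names),
                      values=values)
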