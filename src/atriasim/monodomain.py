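"""Anisotropic monodomain reaction-diffusion on hexahedral meshes.

The transmembrane potential obeys

    Cm dVm/dt = div(D grad Vm) - I_ion + I_stim,        n . (D grad Vm) = 0

with a per-element equivalent conductivity tensor
D = sigma_T I + (sigma_L - sigma_T) f f^T built from the local fibre
direction f. Conductivities are "equivalent" values in mS/cm that absorb
the surface-to-volume ratio; they are converted to an effective diffusivity
in cm^2/ms by a fixed membrane factor (chi * Cm = 1400 uF/cm^3) and pinned
to physiology by conduction-velocity calibration, not by the factor itself.

Discretization: trilinear FEM stiffness on hexahedra with a lumped mass
matrix; Godunov operator splitting with forward-Euler/Rush-Larsen reaction
steps and an implicit (backward Euler) diffusion step solved by a sparse LU
factorization computed once per run. Default time step 0.02 ms; output
sampling every 1 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numba import njit

from .cell import maleckar
from .cell.regions import CellParameterSet
from .geometry import FibreField, HexMesh, RegionLabelField

#: chi * Cm in uF/cm^3: converts sigma (mS/cm) to diffusivity (cm^2/ms).
MEMBRANE_FACTOR = 1400.0

# 2x2x2 Gauss quadrature on [-1,1]^3 and trilinear shape gradients
_XI = np.array([
    (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
    (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
], dtype=float)
_GP = _XI / np.sqrt(3.0)


def _shape_grad(xi):
    """d N_a / d xi at one reference point: (8, 3)."""
    g = np.empty((8, 3))
    for a in range(8):
        sa = _XI[a]
        g[a, 0] = sa[0] * (1 + sa[1] * xi[1]) * (1 + sa[2] * xi[2]) / 8.0
        g[a, 1] = sa[1] * (1 + sa[0] * xi[0]) * (1 + sa[2] * xi[2]) / 8.0
        g[a, 2] = sa[2] * (1 + sa[0] * xi[0]) * (1 + sa[1] * xi[1]) / 8.0
    return g


_DN = np.stack([_shape_grad(gp) for gp in _GP])  # (8 gp, 8 nodes, 3)


def _element_jacobian_dets(mesh: HexMesh) -> np.ndarray:
    """Element volumes via the quadrature of the trilinear map."""
    X = mesh.nodes[mesh.elements]  # (ne, 8, 3)
    vols = np.zeros(mesh.n_elements)
    for g in range(8):
        J = np.einsum("ai,eaj->eij", _DN[g], X)
        vols += np.abs(np.linalg.det(J))
    return vols


@dataclass
class ConductivityField:
    """Per-element longitudinal/transverse equivalent conductivities (mS/cm)."""

    sigma_l: np.ndarray
    sigma_t: np.ndarray
    fibres: FibreField

    def __post_init__(self):
        self.sigma_l = np.atleast_1d(np.asarray(self.sigma_l, dtype=float))
        self.sigma_t = np.atleast_1d(np.asarray(self.sigma_t, dtype=float))
        bad = np.nonzero(~((self.sigma_t > 0) & (self.sigma_l >= self.sigma_t)))[0]
        if len(bad):
            raise ValueError(
                f"conductivity tensor not SPD with sigma_l >= sigma_t > 0 "
                f"on elements {bad[:10].tolist()}"
            )

    @classmethod
    def uniform(cls, mesh: HexMesh, sigma_l: float, anisotropy_ratio: float,
                fibres: FibreField) -> "ConductivityField":
        sl = np.full(mesh.n_elements, sigma_l)
        return cls(sigma_l=sl, sigma_t=sl * anisotropy_ratio, fibres=fibres)

    def tensors(self) -> np.ndarray:
        """(n_elem, 3, 3) conductivity tensors in mS/cm."""
        f = self.fibres.vectors
        eye = np.eye(3)
        return (self.sigma_t[:, None, None] * eye
                + (self.sigma_l - self.sigma_t)[:, None, None]
                * np.einsum("ei,ej->eij", f, f))


@dataclass
class DiffusionOperator:
    """Assembled FEM diffusion: stiffness K (cm^3/ms) and lumped mass (cm^3)."""

    stiffness: sp.csr_matrix
    lumped_mass: np.ndarray

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Action of div(D grad .) in mV/ms (mass-normalized)."""
        return -(self.stiffness @ v) / self.lumped_mass


def assemble_diffusion(mesh: HexMesh,
                       conductivity: ConductivityField) -> DiffusionOperator:
    """Assemble the symmetric Neumann diffusion operator.

    Constant fields lie in the null space of the stiffness (zero row sums),
    which encodes the no-flux boundary.
    """
    D = conductivity.tensors() / MEMBRANE_FACTOR  # cm^2/ms
    X = mesh.nodes[mesh.elements]
    ne = mesh.n_elements
    Ke = np.zeros((ne, 8, 8))
    Me = np.zeros(ne)
    for g in range(8):
        J = np.einsum("ai,eaj->eij", _DN[g], X)
        detJ = np.abs(np.linalg.det(J))
        Jinv = np.linalg.inv(J)
        gradN = np.einsum("ai,eij->eaj", _DN[g], Jinv)
        flux = np.einsum("eaj,ejk->eak", gradN, D)
        Ke += np.einsum("eak,ebk->eab", flux, gradN) * detJ[:, None, None]
        Me += detJ
    rows = np.repeat(mesh.elements, 8, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 8)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    M = np.zeros(mesh.n_nodes)
    np.add.at(M, mesh.elements.ravel(), np.repeat(Me / 8.0, 8))
    return DiffusionOperator(stiffness=K, lumped_mass=M)


@dataclass(frozen=True)
class Stimulus:
    """Periodic current-pulse train delivered to a node set (pA/pF)."""

    nodes: np.ndarray
    start: float = 0.0       # ms
    duration: float = 2.0    # ms
    amplitude: float = 30.0  # pA/pF, depolarizing
    period: float = 1000.0   # ms
    count: int = 1

    def active(self, t: float) -> bool:
        if t < self.start:
            return False
        k = int((t - self.start) // self.period) if self.period > 0 else 0
        if k >= self.count:
            return False
        phase = t - self.start - k * self.period
        return phase < self.duration


@dataclass
class StimulusSet:
    stimuli: list[Stimulus] = field(default_factory=list)

    def __iter__(self):
        return iter(self.stimuli)


@dataclass
class VmSeries:
    """Transmembrane potential sampled on the output grid."""

    times: np.ndarray            # (n_t,) ms
    vm: np.ndarray               # (n_t, n_nodes) mV
    mesh: HexMesh
    metadata: dict = field(default_factory=dict)


@njit(cache=False)
def _react(states, n_sub, dt_s, gto, gcal, gkr, stim):
    for i in range(states.shape[0]):
        y = states[i]
        for _ in range(n_sub):
            maleckar._step(y, dt_s, gto[i], gcal[i], gkr[i], stim[i])


def node_regions(mesh: HexMesh, labels: RegionLabelField) -> np.ndarray:
    """Per-node region index: each node takes the label of its lowest-index
    incident element (deterministic tie-break)."""
    out = np.full(mesh.n_nodes, -1, dtype=np.int64)
    rev = np.arange(mesh.n_elements)[::-1]
    out[mesh.elements[rev].ravel()] = np.repeat(labels.indices[rev], 8)
    return out


def run_monodomain(
    mesh: HexMesh,
    labels: RegionLabelField,
    conductivity: ConductivityField,
    cell_map: dict[str, CellParameterSet],
    stimuli: StimulusSet,
    duration: float,
    dt: float = 0.02,
    output_dt: float = 1.0,
    initial_states: dict[str, np.ndarray] | None = None,
) -> VmSeries:
    """Godunov-split monodomain integration.

    ``cell_map`` assigns a regional cell parameter set to every label name in
    ``labels``; ``initial_states`` optionally provides a stabilized state
    vector per label (default: the model's resting initial state).
    Returns Vm sampled every ``output_dt`` ms (including t = 0).
    """
    missing = labels.present() - set(cell_map)
    if missing:
        raise ValueError(f"no cell model for labels: {sorted(missing)}")
    nreg = node_regions(mesh, labels)
    n = mesh.n_nodes

    gto = np.empty(n)
    gcal = np.empty(n)
    gkr = np.empty(n)
    states = np.empty((n, maleckar.N_STATES))
    for i, name in enumerate(labels.names):
        sel = nreg == i
        if not sel.any():
            continue
        params = cell_map[name]
        gto[sel], gcal[sel], gkr[sel] = params.scalings
        y0 = (initial_states or {}).get(name)
        states[sel] = maleckar.initial_state_vector() if y0 is None else y0

    op = assemble_diffusion(mesh, conductivity)
    A = sp.diags(op.lumped_mass) + dt * op.stiffness
    solver = spla.factorized(A.tocsc())
    M = op.lumped_mass

    n_steps = int(round(duration / dt))
    out_stride = max(1, int(round(output_dt / dt)))
    n_out = n_steps // out_stride + 1
    times = np.arange(n_out) * dt * out_stride
    vm_out = np.empty((n_out, n))
    vm_out[0] = states[:, maleckar.IDX_V]

    stim = np.zeros(n)
    active_prev: tuple[bool, ...] | None = None
    k = 1
    dt_s = dt * 1e-3
    for step in range(n_steps):
        t = step * dt
        active = tuple(s.active(t) for s in stimuli)
        if active != active_prev:
            stim[:] = 0.0
            for s, a in zip(stimuli, active):
                if a:
                    stim[s.nodes] += s.amplitude
            active_prev = active
        _react(states, 1, dt_s, gto, gcal, gkr, stim)
        v = solver(M * states[:, maleckar.IDX_V])
        states[:, maleckar.IDX_V] = v
        if (step + 1) % out_stride == 0:
            if not np.all(np.isfinite(v)):
                raise RuntimeError(f"monodomain instability at t = {t + dt:.2f} ms")
            vm_out[k] = v
            k += 1
    return VmSeries(times=times, vm=vm_out[:k], mesh=mesh,
                    metadata={"dt": dt, "output_dt": output_dt,
                              "scheme": "godunov-splitting/backward-euler",
                              "final_states": states})
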