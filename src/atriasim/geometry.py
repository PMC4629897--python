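"""Hexahedral tissue geometry: slabs, the idealized bi-atrial surrogate,
region labelling and fibre-field construction.

Meshes are voxel-based linear hexahedral grids (coordinates in cm, spacing
stated in μm). Region labels live on elements and are drawn from the
21-region anatomical vocabulary of the human atria (plus the fossa ovalis
and its limb). Longitudinal fibre directions are constructed per element as
the normalized cross product between a region's principal defining vector
and the element's outward surface normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 21 anatomical atrial regions.
ATRIAL_REGIONS: tuple[str, ...] = (
    "SAN", "CT", "BBR", "BBL", "IB", "RAS", "RLW", "RAA", "PM", "IST",
    "SCV", "ICV", "TV", "LSW", "LAS", "LAA", "LPW", "MV", "RPV", "LPV", "CS",
)

#: Full label vocabulary: the 21 regions plus the fossa ovalis and its limb.
REGION_VOCABULARY: tuple[str, ...] = ATRIAL_REGIONS + ("FO", "LFO")

RIGHT_ATRIAL_REGIONS = ("SAN", "CT", "BBR", "IB", "RAS", "RLW", "RAA", "PM",
                        "IST", "SCV", "ICV", "TV")
LEFT_ATRIAL_REGIONS = ("BBL", "LSW", "LAS", "LAA", "LPW", "MV", "RPV",
                       "LPV", "CS")

# VTK_HEXAHEDRON local node ordering for a voxel (i,j,k):
# bottom face counter-clockwise, then top face.
_HEX_OFFSETS = np.array([
    (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
    (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
], dtype=np.int64)


@dataclass
class HexMesh:
    """Conforming 8-node hexahedral mesh (coordinates in cm)."""

    nodes: np.ndarray           # (n_nodes, 3) float, cm
    elements: np.ndarray        # (n_elem, 8) int, VTK hexahedron ordering
    spacing_um: float | None = None
    #: outward surface normal per element (unit), set by the generators
    surface_normals: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        """Volumes by 2x2x2 Gauss quadrature of the trilinear map (cm^3)."""
        from .monodomain import _element_jacobian_dets
        return _element_jacobian_dets(self)


@dataclass
class RegionLabelField:
    """Per-element region label, stored as indices into a name list."""

    names: tuple[str, ...]          # label vocabulary actually used
    indices: np.ndarray             # (n_elem,) int into names

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        bad = set(self.names) - set(REGION_VOCABULARY) - {"TISSUE"}
        if bad:
            raise ValueError(f"labels outside the region vocabulary: {sorted(bad)}")
        if self.indices.min(initial=0) < 0 or \
                self.indices.max(initial=0) >= len(self.names):
            raise ValueError("label index out of range")

    def labels(self) -> np.ndarray:
        """Per-element label names as an object array."""
        return np.asarray(self.names, dtype=object)[self.indices]

    def mask(self, name: str) -> np.ndarray:
        return self.indices == self.names.index(name)

    def present(self) -> set[str]:
        return {self.names[i] for i in np.unique(self.indices)}


@dataclass
class FibreField:
    """Per-element unit longitudinal fibre direction."""

    vectors: np.ndarray  # (n_elem, 3), unit norm

    def __post_init__(self):
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("fibre vectors must have unit norm")


def build_slab(nx: int, ny: int, nz: int, spacing_um: float = 300.0) -> HexMesh:
    """Axis-aligned regular hexahedral slab of nx*ny*nz elements.

    The reference tissue fixture is 50x50x3 elements at 300 μm, the slab
    used for conduction-velocity calibration. Outward surface normals are
    +z (slab top).
    """
    if nx < 1 or ny < 1 or nz < 1:
        raise ValueError("element counts must be >= 1")
    if not spacing_um > 0:
        raise ValueError("spacing must be positive")
    h = spacing_um * 1e-4  # cm
    xs = np.arange(nx + 1) * h
    ys = np.arange(ny + 1) * h
    zs = np.arange(nz + 1) * h
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    elems = np.empty((len(ijk), 8), dtype=np.int64)
    for a, (di, dj, dk) in enumerate(_HEX_OFFSETS):
        elems[:, a] = nid(ijk[:, 0] + di, ijk[:, 1] + dj, ijk[:, 2] + dk)
    normals = np.tile(np.array([0.0, 0.0, 1.0]), (len(elems), 1))
    return HexMesh(nodes=nodes, elements=elems, spacing_um=spacing_um,
                   surface_normals=normals)


def uniform_labels(mesh: HexMesh, name: str = "TISSUE") -> RegionLabelField:
    """Single-region label field covering the whole mesh."""
    return RegionLabelField(names=(name,),
                            indices=np.zeros(mesh.n_elements, dtype=np.int64))


def assign_fibres(
    mesh: HexMesh,
    labels: RegionLabelField,
    principal_vectors: dict[str, np.ndarray],
) -> FibreField:
    """Fibre directions from the per-region principal-vector cross rule.

    fibre(e) = normalize(principal(region(e)) x normal(e)). Raises if a
    region present in the labels has no principal vector, or if the cross
    product vanishes (principal parallel to the local normal).
    """
    if mesh.surface_normals is None:
        raise ValueError("mesh has no element surface normals")
    present = labels.present()
    missing = present - set(principal_vectors)
    if missing:
        raise ValueError(f"no principal vector for regions: {sorted(missing)}")
    principals = np.zeros((len(labels.names), 3))
    for i, name in enumerate(labels.names):
        if name in principal_vectors:
            principals[i] = np.asarray(principal_vectors[name], dtype=float)
    per_elem_principal = principals[labels.indices]
    cross = np.cross(per_elem_principal, mesh.surface_normals)
    norms = np.linalg.norm(cross, axis=1)
    degenerate = np.nonzero(norms < 1e-8)[0]
    if len(degenerate):
        raise ValueError(
            "principal vector parallel to surface normal on elements "
            f"{degenerate[:10].tolist()}{'...' if len(degenerate) > 10 else ''}"
        )
    return FibreField(vectors=cross / norms[:, None])


@dataclass(frozen=True)
class AtriaConfig:
    """Geometry of the idealized bi-atrial surrogate (two ellipsoidal shells).

    Dimensions are desk-scale stand-ins, not anatomical reconstructions;
    wall thickness defaults inside the physiological 600-900 μm band scaled
    to the chosen voxel size.
    """

    spacing_um: float = 500.0
    wall_thickness_cm: float = 0.10
    ra_center: tuple[float, float, float] = (-0.62, 0.0, 0.0)
    la_center: tuple[float, float, float] = (0.62, 0.0, 0.0)
    ra_radii: tuple[float, float, float] = (0.70, 0.58, 0.62)
    la_radii: tuple[float, float, float] = (0.64, 0.54, 0.58)

    def __post_init__(self):
        if self.wall_thickness_cm < self.spacing_um * 1e-4:
            raise ValueError("wall thickness must be at least one voxel")


# Surrogate principal region-defining vectors (global frame, unit scale not
# required). Chosen so that no region's patch contains a surface normal
# parallel to its principal vector.
DEFAULT_PRINCIPAL_VECTORS: dict[str, np.ndarray] = {
    "SAN": np.array([0.0, 0.0, 1.0]),
    "CT": np.array([0.0, 1.0, 0.3]),
    "BBR": np.array([0.0, 0.0, 1.0]),
    "BBL": np.array([0.0, 0.0, 1.0]),
    "IB": np.array([0.0, 0.0, 1.0]),
    "RAS": np.array([0.0, 0.0, 1.0]),
    "RLW": np.array([0.2, 0.0, 1.0]),
    "RAA": np.array([0.0, 0.5, 1.0]),
    "PM": np.array([0.0, 1.0, 0.3]),
    "IST": np.array([1.0, 0.0, 0.0]),
    "SCV": np.array([1.0, 0.0, 0.0]),
    "ICV": np.array([1.0, 0.0, 0.0]),
    "TV": np.array([0.0, 0.0, 1.0]),
    "LSW": np.array([1.0, 0.0, 0.0]),
    "LAS": np.array([0.0, 0.0, 1.0]),
    "LAA": np.array([0.0, 0.5, 1.0]),
    "LPW": np.array([0.0, 0.0, 1.0]),
    "MV": np.array([0.0, 0.0, 1.0]),
    "RPV": np.array([1.0, 0.0, 0.0]),
    "LPV": np.array([1.0, 0.0, 0.0]),
    "CS": np.array([0.0, 0.0, 1.0]),
    "FO": np.array([0.0, 0.0, 1.0]),
    "LFO": np.array([0.0, 0.0, 1.0]),
    "TISSUE": np.array([1.0, 0.0, 0.0]),
}


def _voxelize_shells(cfg: AtriaConfig):
    """Voxel occupancy + chamber membership for the two ellipsoidal shells."""
    h = cfg.spacing_um * 1e-4
    ra_c = np.asarray(cfg.ra_center)
    la_c = np.asarray(cfg.la_center)
    ra_r = np.asarray(cfg.ra_radii)
    la_r = np.asarray(cfg.la_radii)
    lo = np.minimum(ra_c - ra_r, la_c - la_r) - h
    hi = np.maximum(ra_c + ra_r, la_c + la_r) + h
    nvox = np.ceil((hi - lo) / h).astype(int)
    idx = np.indices(nvox).reshape(3, -1).T
    centers = lo + (idx + 0.5) * h

    def shell_depth(c, r):
        # approximate signed distance inward from the outer ellipsoid surface
        f = np.sqrt(((centers - c) ** 2 / r ** 2).sum(axis=1))
        r_local = np.linalg.norm((centers - c), axis=1) / np.maximum(f, 1e-12)
        return (1.0 - f) * r_local  # >0 inside, in cm

    d_ra = shell_depth(ra_c, ra_r)
    d_la = shell_depth(la_c, la_r)
    th = cfg.wall_thickness_cm
    in_ra = (d_ra >= 0) & (d_ra <= th)
    in_la = (d_la >= 0) & (d_la <= th)
    # keep LA-shell voxels out of the RA cavity and vice versa, but keep the
    # septal overlap where both shells intersect
    occupied = in_ra | in_la
    return idx[occupied], centers[occupied], in_ra[occupied], in_la[occupied], lo, h


def _angles(centers, c):
    v = centers - np.asarray(c)
    rho = np.linalg.norm(v, axis=1)
    theta = np.arccos(np.clip(v[:, 2] / np.maximum(rho, 1e-12), -1, 1))
    phi = np.arctan2(v[:, 1], v[:, 0])
    return theta, phi


def _paint_ra(theta, phi, toward_la):
    """Angular-sector painting of the 12 right atrial regions."""
    n = len(theta)
    lab = np.full(n, "RLW", dtype=object)
    lab[theta < 0.45] = "SCV"
    lab[theta > np.pi - 0.45] = "ICV"
    band = (theta >= np.pi - 0.80) & (theta <= np.pi - 0.45)
    lab[band] = "TV"
    mid = (theta > 0.45) & (theta < np.pi - 0.80)
    # intercaval bundle: ring just below the SCV ostium
    lab[mid & (theta < 0.65)] = "IB"
    # appendage: anterior patch
    raa = mid & (theta >= 0.65) & (theta < 1.8) & (np.abs(phi + np.pi / 2) < 0.6)
    lab[raa] = "RAA"
    # CT: posterior meridian strip running from below the SCV towards the ICV
    ct = mid & (np.abs(phi - np.pi / 2) < 0.35) & (theta > 0.70)
    lab[ct] = "CT"
    # SAN: patch carved from the top of the CT strip (face-adjacent to CT)
    san = mid & (np.abs(phi - np.pi / 2) < 0.35) & (theta <= 0.70)
    lab[san] = "SAN"
    # pectinate tract next to the CT on the free wall
    pm = mid & (phi > np.pi / 2 + 0.35) & (phi < np.pi / 2 + 0.95) & (theta > 0.8)
    lab[pm] = "PM"
    # isthmus: between ICV and TV on the CT side
    ist = band & (np.abs(phi - np.pi / 2) < 0.4)
    lab[ist] = "IST"
    # septal face towards the LA
    lab[toward_la & (theta > 1.2) & (theta < np.pi - 0.8)] = "RAS"
    # Bachmann bundle right limb: upper septal face
    lab[toward_la & (theta <= 1.2)] = "BBR"
    return lab


def _paint_la(theta, phi, toward_ra):
    """Angular-sector painting of the 9 left atrial regions."""
    n = len(theta)
    lab = np.full(n, "LPW", dtype=object)
    lab[theta < 0.55] = "LSW"
    band = theta > np.pi - 0.55
    lab[band] = "MV"
    mid = (theta >= 0.55) & (theta <= np.pi - 0.55)
    # pulmonary veins: two posterior ostia patches (y > 0 side)
    rpv = mid & (np.abs(phi - (np.pi / 2 - 0.55)) < 0.35) & (theta < 1.5)
    lpv = mid & (np.abs(phi - (np.pi / 2 + 0.55)) < 0.35) & (theta < 1.5)
    lab[rpv] = "RPV"
    lab[lpv] = "LPV"
    # coronary sinus: posterior band just above the MV ring
    cs = (theta > np.pi - 0.9) & (theta <= np.pi - 0.55) & \
        (phi > 0.6) & (phi < np.pi - 0.3)
    lab[cs] = "CS"
    # appendage: anterior patch
    laa = mid & (np.abs(phi + np.pi / 2) < 0.55) & (theta < 1.7)
    lab[laa] = "LAA"
    # septal face towards the RA
    lab[toward_ra & (theta > 1.2) & (theta < np.pi - 0.55)] = "LAS"
    # Bachmann bundle left limb: upper septal face
    lab[toward_ra & (theta <= 1.2)] = "BBL"
    return lab


def build_idealized_atria(
    config: AtriaConfig | None = None,
    principal_vectors: dict[str, np.ndarray] | None = None,
) -> tuple[HexMesh, RegionLabelField, FibreField]:
    """Desk-scale bi-atrial surrogate: two joined ellipsoidal shells.

    The 21 anatomical region labels are painted by angular sectors; the
    interatrial connection runs through the Bachmann bundle labels (BBR/BBL,
    upper septal contact) and the septal labels (RAS/LAS). SAN is carved out
    of the top of the CT strip so the two share element faces. Fibres follow
    the principal-vector cross rule with outward radial shell normals.
    """
    cfg = config or AtriaConfig()
    idx, centers, in_ra, in_la, lo, h = _voxelize_shells(cfg)

    # conforming mesh from occupied voxels
    key = idx[:, 0] * 10_000_000 + idx[:, 1] * 10_000 + idx[:, 2]
    order = np.argsort(key)
    idx, centers, in_ra, in_la = idx[order], centers[order], in_ra[order], in_la[order]
    corner_ids = {}
    elems = np.empty((len(idx), 8), dtype=np.int64)
    nodes = []
    for e, (i, j, k) in enumerate(idx):
        for a, (di, dj, dk) in enumerate(_HEX_OFFSETS):
            ck = (i + di, j + dj, k + dk)
            nid = corner_ids.get(ck)
            if nid is None:
                nid = len(nodes)
                corner_ids[ck] = nid
                nodes.append(lo + np.array(ck) * h)
            elems[e, a] = nid
    nodes = np.asarray(nodes)

    ra_c = np.asarray(cfg.ra_center)
    la_c = np.asarray(cfg.la_center)
    # chamber membership: overlap voxels belong to the nearer chamber
    d_ra = np.linalg.norm((centers - ra_c) / np.asarray(cfg.ra_radii), axis=1)
    d_la = np.linalg.norm((centers - la_c) / np.asarray(cfg.la_radii), axis=1)
    is_ra = in_ra & (~in_la | (d_ra <= d_la))

    labels = np.empty(len(centers), dtype=object)
    th_ra, ph_ra = _angles(centers[is_ra], ra_c)
    th_la, ph_la = _angles(centers[~is_ra], la_c)
    toward_la = centers[is_ra][:, 0] > ra_c[0] + 0.65 * cfg.ra_radii[0]
    toward_ra = centers[~is_ra][:, 0] < la_c[0] - 0.65 * cfg.la_radii[0]
    labels[is_ra] = _paint_ra(th_ra, ph_ra, toward_la)
    labels[~is_ra] = _paint_la(th_la, ph_la, toward_ra)

    names = tuple(n for n in ATRIAL_REGIONS)
    name_to_i = {n: i for i, n in enumerate(names)}
    indices = np.array([name_to_i[l] for l in labels], dtype=np.int64)
    label_field = RegionLabelField(names=names, indices=indices)

    # outward radial normal of the owning chamber's mid-surface
    normals = np.where(is_ra[:, None], centers - ra_c, centers - la_c)
    normals = normals / np.linalg.norm(normals, axis=1)[:, None]
    mesh = HexMesh(nodes=nodes, elements=elems, spacing_um=cfg.spacing_um,
                   surface_normals=normals)
    fibres = assign_fibres(mesh, label_field,
                           principal_vectors or DEFAULT_PRINCIPAL_VECTORS)
    return mesh, label_field, fibres


def element_face_adjacency(mesh: HexMesh, mask_a: np.ndarray,
                           mask_b: np.ndarray) -> bool:
    """True if any element in mask_a shares a quad face with one in mask_b."""
    faces_local = [(0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
                   (2, 3, 7, 6), (0, 3, 7, 4), (1, 2, 6, 5)]

    def face_set(mask):
        faces = set()
        for el in mesh.elements[mask]:
            for f in faces_local:
                faces.add(frozenset(int(el[i]) for i in f))
        return faces

    return bool(face_set(mask_a) & face_set(mask_b))
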