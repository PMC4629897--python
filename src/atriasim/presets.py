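"""Default physiological assignments for the 21 atrial regions.

Maps every anatomical region label to (a) one of the eight regional cell
phenotypes and (b) a conduction tissue class (target CV + anisotropy
ratio). Longitudinal conductivities are derived from the reference slab
calibration of general RA/LA tissue via the square-root CV-conductivity
law; regenerate them exactly with :func:`atriasim.calibration.calibrate_table`.
"""

from __future__ import annotations

import numpy as np

from .calibration import ANISOTROPY_RATIOS, TARGET_CV
from .cell.regions import CellParameterSet, make_regional_cell
from .geometry import FibreField, HexMesh, RegionLabelField
from .monodomain import ConductivityField

#: sigma_L (mS/cm) calibrated for 63.3 cm/s on the 300 um reference slab
REFERENCE_SIGMA_L = 3.742
REFERENCE_CV = 63.3

#: region -> cell phenotype (surrogate assignment at the 21-region level)
DEFAULT_CELL_ASSIGNMENT: dict[str, str] = {
    "SAN": "RA/PM", "CT": "CT/BB", "BBR": "CT/BB", "BBL": "CT/BB",
    "IB": "RA/PM", "RAS": "RA/PM", "RLW": "RA/PM", "RAA": "RAA",
    "PM": "RA/PM", "IST": "RA/PM", "SCV": "RA/PM", "ICV": "RA/PM",
    "TV": "TV", "LSW": "LA", "LAS": "LA", "LAA": "LAA", "LPW": "LA",
    "MV": "MV", "RPV": "PV", "LPV": "PV", "CS": "LA",
    "FO": "RA/PM", "LFO": "RA/PM", "TISSUE": "RA/PM",
}

#: region -> (target CV cm/s, anisotropy ratio). SAN is given a slow
#: surrogate CV (the node itself conducts slowly); bundles take the fast
#: class values.
REGION_CONDUCTION: dict[str, tuple[float, float]] = {
    "SAN": (40.0, 1.0),
    "CT": (TARGET_CV["CT"], ANISOTROPY_RATIOS["CT"]),
    "BBR": (116.0, 0.15), "BBL": (116.0, 0.15),
    "PM": (TARGET_CV["PM"], ANISOTROPY_RATIOS["PM"]),
    "IST": (TARGET_CV["IST"], ANISOTROPY_RATIOS["IST"]),
    "RPV": (TARGET_CV["PV"], ANISOTROPY_RATIOS["PV"]),
    "LPV": (TARGET_CV["PV"], ANISOTROPY_RATIOS["PV"]),
    "CS": (TARGET_CV["CS"], ANISOTROPY_RATIOS["CS"]),
    "FO": (63.3, 1.0),
    "LFO": (TARGET_CV["LFO"], ANISOTROPY_RATIOS["LFO"]),
}
_GENERAL = (TARGET_CV["RA/LA"], ANISOTROPY_RATIOS["RA/LA"])
for _r in ("IB", "RAS", "RLW", "RAA", "SCV", "ICV", "TV",
           "LSW", "LAS", "LAA", "LPW", "MV", "TISSUE"):
    REGION_CONDUCTION[_r] = _GENERAL


def sigma_from_cv(target_cv: float) -> float:
    """sigma_L from a target CV via the square-root scaling law around the
    calibrated reference point."""
    return REFERENCE_SIGMA_L * (target_cv / REFERENCE_CV) ** 2


def default_cell_map(labels: RegionLabelField) -> dict[str, CellParameterSet]:
    return {name: make_regional_cell(DEFAULT_CELL_ASSIGNMENT[name])
            for name in labels.names}


def default_conductivity(mesh: HexMesh, labels: RegionLabelField,
                         fibres: FibreField) -> ConductivityField:
    """Per-element conductivities from the regional conduction classes."""
    sigma_l = np.empty(mesh.n_elements)
    sigma_t = np.empty(mesh.n_elements)
    for i, name in enumerate(labels.names):
        cv, ratio = REGION_CONDUCTION[name]
        sel = labels.indices == i
        sigma_l[sel] = sigma_from_cv(cv)
        sigma_t[sel] = sigma_from_cv(cv) * ratio
    return ConductivityField(sigma_l=sigma_l, sigma_t=sigma_t, fibres=fibres)


def san_stimulus(mesh: HexMesh, labels: RegionLabelField,
                 amplitude: float = 52.0, duration: float = 2.0,
                 capture_radius: float = 0.25, start: float = 0.0,
                 period: float = 1000.0, count: int = 1):
    """Sinus-rhythm stimulus: a pulse train delivered around the SAN patch.

    At the surrogate's coarse resolution the bare SAN patch is too small a
    source to drive the fast bundles (source-sink mismatch), so the stimulus
    covers a ``capture_radius`` ball around the SAN centroid at the single-
    cell stimulus strength.
    """
    from .monodomain import Stimulus, node_regions

    nreg = node_regions(mesh, labels)
    san = np.nonzero(nreg == labels.names.index("SAN"))[0]
    if len(san) == 0:
        raise ValueError("label field has no SAN nodes")
    c = mesh.nodes[san].mean(axis=0)
    ball = np.nonzero(np.linalg.norm(mesh.nodes - c, axis=1) < capture_radius)[0]
    return Stimulus(nodes=ball, start=start, duration=duration,
                    amplitude=amplitude, period=period, count=count)
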