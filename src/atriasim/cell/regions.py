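"""Regional human atrial cell variants.

Eight regional electrophysiological phenotypes are defined by scaling the
maximum conductances of three currents (I_to, I_CaL, I_Kr) of the baseline
atrial myocyte model. The scalings encode the experimentally observed
action-potential heterogeneity across the atria: e.g. crista terminalis /
Bachmann-bundle cells (halved I_to and I_Kr) have long plateaus, while
pulmonary-vein and mitral-valve-ring cells (raised I_Kr, reduced I_CaL)
repolarize early.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import maleckar

#: (scale_gto, scale_gCaL, scale_gKr) per regional phenotype.
REGIONAL_SCALINGS: dict[str, tuple[float, float, float]] = {
    "RA/PM": (1.00, 1.00, 1.00),
    "CT/BB": (0.50, 1.00, 0.50),
    "RAA": (1.35, 1.00, 1.00),
    "TV": (1.35, 0.80, 2.00),
    "LA": (1.00, 0.67, 1.60),
    "PV": (1.35, 0.67, 3.20),
    "LAA": (1.35, 0.67, 1.60),
    "MV": (1.35, 0.53, 3.20),
}

REGION_IDS = tuple(REGIONAL_SCALINGS)


@dataclass(frozen=True)
class CellParameterSet:
    """Ionic parameters of one myocyte: baseline constants + regional scalings."""

    region_id: str
    scale_gto: float = 1.0
    scale_gCaL: float = 1.0
    scale_gKr: float = 1.0
    Cm: float = maleckar.CONSTANTS["Cm"]
    constants: dict = field(default_factory=lambda: dict(maleckar.CONSTANTS))

    def __post_init__(self):
        for name, v in (("scale_gto", self.scale_gto),
                        ("scale_gCaL", self.scale_gCaL),
                        ("scale_gKr", self.scale_gKr)):
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")

    @property
    def scalings(self) -> tuple[float, float, float]:
        return (self.scale_gto, self.scale_gCaL, self.scale_gKr)

    def initial_state(self) -> np.ndarray:
        return maleckar.initial_state_vector()


def make_regional_cell(region_id: str) -> CellParameterSet:
    """Build the parameter set of one of the eight regional cell phenotypes.

    ``region_id`` must be one of ``REGION_IDS``; "RA/PM" is the unscaled
    baseline model. Deterministic and idempotent.
    """
    if region_id not in REGIONAL_SCALINGS:
        raise ValueError(
            f"unknown region_id {region_id!r}; valid labels are "
            + ", ".join(REGION_IDS)
        )
    gto, gcal, gkr = REGIONAL_SCALINGS[region_id]
    return CellParameterSet(
        region_id=region_id, scale_gto=gto, scale_gCaL=gcal, scale_gKr=gkr
    )
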