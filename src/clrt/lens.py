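"""Convergent x-ray lens specifications and beams.

The lens focuses a quasi-monoenergetic ~60 keV photon beam through a hollow
conical shell onto a small focal volume.  Its dosimetric signature is an
anisotropic focal spot (full width at half maximum given separately along
and across the beam axis, as measured in water) surrounded by a much lower
entrance dose spread over the converging cone.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["LensSpec", "Beam", "builtin_lens", "BUILTIN_LENSES"]

#: Linear attenuation coefficient of water at 60 keV, per mm (NIST-derived).
MU_WATER_60KEV = 0.0206


@dataclass(frozen=True)
class LensSpec:
    """Geometric and dosimetric parameters of a converging lens.

    Parameters
    ----------
    fwhm_lateral, fwhm_longitudinal : float
        Focal-spot FWHM (mm) across and along the beam axis, in water.
    cone_inner_half_angle, cone_outer_half_angle : float
        Half-opening angles (degrees) bounding the hollow conical shell.
    energy : float
        Nominal photon energy in keV.
    source_focus_distance : float
        Distance (mm) from the treatment-head exit to the focal point.
    max_depth : float
        Maximum water-equivalent depth (mm) of the focal point below the
        body surface for a deliverable beam.
    peak_to_entrance_ratio : float
        Focal peak dose divided by the entrance (skin) dose; must exceed 1.
    mu_water : float
        Linear attenuation coefficient (per mm) at the beam energy.
    """

    fwhm_lateral: float
    fwhm_longitudinal: float
    cone_inner_half_angle: float = 20.0
    cone_outer_half_angle: float = 25.0
    energy: float = 60.0
    source_focus_distance: float = 300.0
    max_depth: float = 80.0
    peak_to_entrance_ratio: float = 20.0
    mu_water: float = MU_WATER_60KEV

    def __post_init__(self) -> None:
        if not (0.0 < self.cone_inner_half_angle < self.cone_outer_half_angle < 90.0):
            raise ValueError(
                "require 0 < inner < outer < 90 degrees, got "
                f"({self.cone_inner_half_angle}, {self.cone_outer_half_angle})"
            )
        if self.fwhm_lateral <= 0 or self.fwhm_longitudinal <= 0:
            raise ValueError("focal FWHMs must be positive")
        if self.peak_to_entrance_ratio <= 1:
            raise ValueError("peak_to_entrance_ratio must exceed 1")
        if self.max_depth <= 0 or self.mu_water <= 0 or self.energy <= 0:
            raise ValueError("energy, max_depth and mu_water must be positive")

    @property
    def sigma_lateral(self) -> float:
        return self.fwhm_lateral / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    @property
    def sigma_longitudinal(self) -> float:
        return self.fwhm_longitudinal / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LensSpec":
        return cls(**d)


#: Built-in prototype lenses (focal FWHMs measured in water).
BUILTIN_LENSES = {
    "A": LensSpec(fwhm_lateral=3.4, fwhm_longitudinal=22.5),
    "B": LensSpec(fwhm_lateral=1.3, fwhm_longitudinal=10.8),
}


def builtin_lens(name: str) -> LensSpec:
    """Return a built-in lens by name.

    Lens ``"A"`` has an elongated focal volume (22.5 mm longitudinal ×
    3.4 mm lateral FWHM in water); lens ``"B"`` is more compact
    (10.8 mm × 1.3 mm).
    """
    try:
        return BUILTIN_LENSES[name]
    except KeyError:
        raise ValueError(f"unknown lens {name!r}; available: {sorted(BUILTIN_LENSES)}")


@dataclass
class Beam:
    """One focal shot: a target point, an approach direction, and a weight.

    ``direction`` is the unit beam axis pointing from the entrance toward the
    focus; ``weight`` is the non-negative optimization variable scaling the
    per-unit-weight dose kernel.
    """

    target: tuple[float, float, float]
    direction: tuple[float, float, float]
    weight: float = 0.0

    def __post_init__(self) -> None:
        self.target = tuple(float(x) for x in self.target)
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError(f"direction must be a unit vector, |d| = {np.linalg.norm(d)!r}")
        self.direction = tuple(float(x) for x in d)
        if self.weight < 0:
            raise ValueError("beam weight must be non-negative")

    @classmethod
    def aimed(cls, target, direction, weight: float = 0.0) -> "Beam":
        """Construct a beam, normalizing ``direction``."""
        d = np.asarray(direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("direction must be non-zero")
        return cls(tuple(target), tuple(d / n), weight)
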