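"""Plan evaluation: DVHs, dose-volume queries, and plan-quality indices.

Cumulative dose-volume histograms use the "volume receiving at least"
convention with an inclusive (>=) threshold.  The plan-quality indices are

* CI  = V100_PTV / V100       (conformity: fraction of the prescription
  isodose volume inside the PTV),
* TCI = V100_PTV / V_PTV      (coverage: fraction of the PTV at or above
  prescription),
* CN  = CI × TCI              (conformal number),
* GI  = 50% / (R50_eff − R100_eff) in %/cm (dose-gradient steepness),

where Vx is the volume receiving at least x% of the prescribed dose,
taken over the whole dose grid for the denominators, and Rx_eff is the
radius (cm) of the sphere with volume Vx.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import VoxelGrid

__all__ = [
    "DVHCurve",
    "PlanIndices",
    "compute_dvh",
    "volume_at_dose",
    "effective_radius",
    "conformal_number",
    "plan_indices",
    "UndefinedIndexError",
]


class UndefinedIndexError(ValueError):
    """No voxel reaches the prescription: the conformity index is undefined."""


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of a structure receiving at least each dose."""

    structure: str
    dose_edges: np.ndarray  # Gy, ascending
    volume_fraction: np.ndarray  # of structure volume, at >= edge dose

    def at(self, dose_gy: float) -> float:
        """Volume fraction receiving at least ``dose_gy`` (step interpolation)."""
        i = np.searchsorted(self.dose_edges, dose_gy, side="right") - 1
        if i < 0:
            return 1.0
        return float(self.volume_fraction[min(i, len(self.volume_fraction) - 1)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "structure": self.structure,
                "dose_gy": self.dose_edges,
                "volume_fraction": self.volume_fraction,
            }
        )


@dataclass
class PlanIndices:
    """Conformity/coverage/gradient indices with their volume intermediates."""

    CI: float
    TCI: float
    CN: float
    GI: float  # %/cm; inf when the 50% and 100% effective radii coincide
    V100: float  # cc, whole grid
    V100_PTV: float  # cc, inside PTV
    V_PTV: float  # cc
    R100_eff: float  # cm
    R50_eff: float  # cm


def compute_dvh(
    dose: VoxelGrid, mask: np.ndarray, bin_width: float, structure: str = ""
) -> DVHCurve:
    """Cumulative DVH of ``dose`` over ``mask`` with the given bin width (Gy)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty structure mask")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = dose.values[mask]
    top = max(float(d.max()), bin_width)
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    frac = (d[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(structure=structure, dose_edges=edges, volume_fraction=frac)


def volume_at_dose(
    dose: VoxelGrid,
    prescription_gy: float,
    threshold_fraction: float,
    mask: np.ndarray | None = None,
) -> float:
    """Volume (cc) receiving at least ``threshold_fraction`` × prescription.

    Restricted to ``mask`` when given, else over the whole grid (as used for
    the conformity denominator V100).  The threshold is inclusive.
    """
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    sel = dose.values >= threshold_fraction * prescription_gy
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    return float(sel.sum()) * dose.voxel_volume_cc


def effective_radius(volume_cc: float) -> float:
    """Radius (cm) of the sphere with the given volume (cc)."""
    if volume_cc < 0:
        raise ValueError("volume must be non-negative")
    return float((3.0 * volume_cc / (4.0 * np.pi)) ** (1.0 / 3.0))


def conformal_number(ci: float, tci: float) -> float:
    """Conformal number CN = CI × TCI."""
    return ci * tci


def plan_indices(dose: VoxelGrid, ptv: np.ndarray, prescription_gy: float) -> PlanIndices:
    """Compute CI, TCI, CN and GI for a dose grid against a PTV mask.

    Raises
    ------
    UndefinedIndexError
        If no voxel reaches the prescription (V100 = 0).
    """
    ptv = np.asarray(ptv, dtype=bool)
    if not ptv.any():
        raise ValueError("PTV mask is empty")
    v100 = volume_at_dose(dose, prescription_gy, 1.0)
    if v100 == 0.0:
        raise UndefinedIndexError("no voxel reaches the prescription dose")
    v100_ptv = volume_at_dose(dose, prescription_gy, 1.0, mask=ptv)
    v50 = volume_at_dose(dose, prescription_gy, 0.5)
    v_ptv = float(ptv.sum()) * dose.voxel_volume_cc

    ci = v100_ptv / v100
    tci = v100_ptv / v_ptv
    r100 = effective_radius(v100)
    r50 = effective_radius(v50)
    gi = 50.0 / (r50 - r100) if r50 > r100 else np.inf

    return PlanIndices(
        CI=ci,
        TCI=tci,
        CN=conformal_number(ci, tci),
        GI=gi,
        V100=v100,
        V100_PTV=v100_ptv,
        V_PTV=v_ptv,
        R100_eff=r100,
        R50_eff=r50,
    )
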