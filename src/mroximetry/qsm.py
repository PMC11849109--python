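"""Venous oximetry from quantitative susceptibility maps.

Blood susceptibility relative to CSF depends linearly on the deoxygenated
fraction of haemoglobin:

    dchi_vein-CSF = (1 - SvO2) * dchi0 * Hct + dchi_HbH2O * Hct

where ``dchi0`` is the susceptibility difference per unit haematocrit between
fully deoxygenated and fully oxygenated red cells (0.27 ppm cgs) and
``dchi_HbH2O`` the difference between fully oxygenated cells and water
(-0.03 ppm cgs). The package works internally in SI ppm, where both constants
carry an extra factor of 4*pi; the 130-1000 ppb vein-inclusion window is only
consistent with SI-scaled venous susceptibilities, so SI is the default, with
cgs available throughout for maps reconstructed in that convention.

Vein ROIs supplied as seed label volumes are refined by susceptibility
thresholding; the vein value is the 90th percentile of the surviving
non-zero voxels, which suppresses residual partial-volume voxels at the
vessel edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import EmptyRegionError

__all__ = [
    "OximetryConstants",
    "VeinMeasurement",
    "Svo2Result",
    "erode_brain_mask",
    "refine_vein_roi",
    "vein_susceptibility",
    "svo2_from_susceptibility",
    "measure_vein",
    "VEIN_NAMES",
]

VEIN_NAMES = ("SSS V", "SSS H", "SS", "BVs", "ICVs")

_FOUR_PI = 4.0 * np.pi


@dataclass(frozen=True)
class OximetryConstants:
    """Susceptibility constants of the venous oximetry relation.

    ``dchi0_cgs`` and ``dchi_hb_h2o_cgs`` are stored in cgs ppm;
    the accessors return them in the map's unit system (SI = 4*pi * cgs).
    """

    dchi0_cgs: float = 0.27  # ppm per unit haematocrit
    dchi_hb_h2o_cgs: float = -0.03  # ppm
    unit_system: str = "SI"

    def __post_init__(self) -> None:
        if self.unit_system not in ("SI", "cgs"):
            raise ValueError("unit_system must be 'SI' or 'cgs'")

    @property
    def _scale(self) -> float:
        return _FOUR_PI if self.unit_system == "SI" else 1.0

    @property
    def dchi0(self) -> float:
        """ppm per unit haematocrit, in the selected unit system."""
        return self.dchi0_cgs * self._scale

    @property
    def dchi_hb_h2o(self) -> float:
        """ppm, in the selected unit system."""
        return self.dchi_hb_h2o_cgs * self._scale


class Svo2Result(NamedTuple):
    svo2: float
    clamped: bool


@dataclass(frozen=True)
class VeinMeasurement:
    """Refined-ROI susceptibility measurement for one vein."""

    vein: str
    dchi_ppm: float  # vein-minus-CSF susceptibility
    svo2: float
    n_voxels: int
    clamped: bool = False


def erode_brain_mask(mask) -> np.ndarray:
    """One 6-connected erosion pass, removing the outermost mask voxels.

    Strips the tissue-air boundary layer of a brain mask, where imperfect
    background-field removal corrupts the susceptibility values.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3-D volume")
    if not mask.any():
        raise ValueError("mask is empty")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    return ndimage.binary_erosion(mask, structure=structure, border_value=0)


def refine_vein_roi(seed_roi, chi_ppm, lower_ppb: float = 130.0,
                    upper_ppb: float = 1000.0) -> np.ndarray:
    """Keep seed voxels whose susceptibility falls in the venous window.

    Bounds are inclusive and given in ppb (ppm * 1000).
    """
    seed = np.asarray(seed_roi, dtype=bool)
    chi = np.asarray(chi_ppm, dtype=float)
    if not seed.any():
        raise ValueError("seed ROI is empty")
    if seed.shape != chi.shape:
        raise ValueError("seed ROI and susceptibility map shapes differ")
    ppb = chi * 1000.0
    refined = seed & (ppb >= lower_ppb) & (ppb <= upper_ppb)
    if not refined.any():
        raise EmptyRegionError(
            f"no seed voxel survives the [{lower_ppb}, {upper_ppb}] ppb window")
    return refined


def vein_susceptibility(refined_roi, chi_ppm, percentile: float = 90.0) -> float:
    """90th percentile of the non-zero in-ROI susceptibilities, in ppm.

    Percentiles interpolate linearly between order statistics.
    """
    roi = np.asarray(refined_roi, dtype=bool)
    chi = np.asarray(chi_ppm, dtype=float)
    if not roi.any():
        raise EmptyRegionError("refined ROI is empty")
    vals = chi[roi]
    vals = vals[vals != 0.0]
    if vals.size == 0:
        raise EmptyRegionError("refined ROI contains only zero voxels")
    return float(np.percentile(vals, percentile, method="linear"))


def svo2_from_susceptibility(dchi_ppm: float, hct: float,
                             constants: OximetryConstants | None = None
                             ) -> Svo2Result:
    """Invert the susceptibility relation for venous oxygen saturation.

    Solves ``dchi = (1 - SvO2) * dchi0 * Hct + dchi_HbH2O * Hct`` for SvO2.
    The result is clamped to [0, 1]; ``clamped`` records whether clamping
    occurred (a sign of unit mismatch or a corrupted ROI).
    """
    constants = constants or OximetryConstants()
    if not 0.0 < hct < 1.0:
        raise ValueError(f"haematocrit must lie in (0, 1), got {hct!r}")
    svo2 = 1.0 - (dchi_ppm - constants.dchi_hb_h2o * hct) / (constants.dchi0 * hct)
    clamped = not 0.0 <= svo2 <= 1.0
    return Svo2Result(svo2=float(np.clip(svo2, 0.0, 1.0)), clamped=clamped)


def susceptibility_from_svo2(svo2: float, hct: float,
                             constants: OximetryConstants | None = None) -> float:
    """Forward venous susceptibility (ppm) of blood at a given SvO2 and Hct."""
    constants = constants or OximetryConstants()
    if not 0.0 <= svo2 <= 1.0:
        raise ValueError("SvO2 must lie in [0, 1]")
    if not 0.0 < hct < 1.0:
        raise ValueError("haematocrit must lie in (0, 1)")
    return (1.0 - svo2) * constants.dchi0 * hct + constants.dchi_hb_h2o * hct


def measure_vein(vein: str, seed_roi, chi_ppm, hct: float,
                 constants: OximetryConstants | None = None,
                 lower_ppb: float = 130.0, upper_ppb: float = 1000.0,
                 percentile: float = 90.0) -> VeinMeasurement:
    """Full vein oximetry chain: refine ROI, extract percentile, invert."""
    refined = refine_vein_roi(seed_roi, chi_ppm, lower_ppb, upper_ppb)
    dchi = vein_susceptibility(refined, chi_ppm, percentile)
    res = svo2_from_susceptibility(dchi, hct, constants)
    return VeinMeasurement(vein=vein, dchi_ppm=dchi, svo2=res.svo2,
                           n_voxels=int(refined.sum()), clamped=res.clamped)
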