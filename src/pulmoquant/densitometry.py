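"""Per-subject parenchymal and vascular metrics.

Whole-lung densitometry (mean density, density percentiles such as p10,
low-attenuation fraction) is computed over the full lung mask, vessels
included, matching the whole-lung densitometry convention; a
vessels-excluded variant is available via ``exclude_vessels``. Derived
vascular metrics: vascular density (vessel volume / lung volume,
dimensionless) and the lobar vascular volume ratios RUL/RLL, LUL/LLL and
ULs/LLs = (RUL+LUL)/(RLL+LLL), the upper/lower redistribution index.
The middle lobe is excluded from ULs/LLs unless it has been merged into
RUL upstream. A zero denominator makes a ratio undefined: it is reported
as missing (None/NaN), never as infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .imaging import CTVolume, LobeLabelMap
from .lungs import LungMask
from .vessels import EmptyMaskError, PipelineConfig, VesselSegmentation, vessel_volume_per_lobe


def _mask_array(mask) -> np.ndarray:
    """Accept either a LungMask or a plain boolean array."""
    return mask.mask if isinstance(mask, LungMask) else np.asarray(mask, dtype=bool)


def lung_volume(mask, spacing_mm) -> float:
    """Lung volume in cm^3 (voxel count x voxel volume)."""
    return float(np.count_nonzero(_mask_array(mask))) * float(np.prod(spacing_mm)) / 1000.0


def mean_density(ct: CTVolume, mask) -> float:
    """Arithmetic mean HU over the mask."""
    vals = ct.voxels[_mask_array(mask)]
    if vals.size == 0:
        raise EmptyMaskError("mean density of an empty mask is undefined")
    return float(vals.mean())


def density_percentile(ct: CTVolume, mask, p: float) -> float:
    """The p-th percentile of lung attenuation, by linear interpolation
    between closest ranks.

    With sorted mask values v_1..v_n, the rank is r = 1 + (p/100)(n-1) and
    the result interpolates linearly between v_floor(r) and the next value.
    """
    if not 0.0 < p <= 100.0:
        raise ValueError("percentile p must lie in (0, 100]")
    vals = ct.voxels[_mask_array(mask)]
    if vals.size == 0:
        raise EmptyMaskError("percentile of an empty mask is undefined")
    v = np.sort(np.asarray(vals, dtype=np.float64))
    n = v.size
    r = 1.0 + (p / 100.0) * (n - 1)
    k = int(math.floor(r))
    if k >= n:
        return float(v[-1])
    frac = r - k
    return float(v[k - 1] + frac * (v[k] - v[k - 1]))


def low_attenuation_fraction(ct: CTVolume, mask,
                             threshold_hu: float = -950.0) -> float:
    """Fraction of lung voxels strictly below ``threshold_hu`` (LAA index)."""
    vals = ct.voxels[_mask_array(mask)]
    if vals.size == 0:
        raise EmptyMaskError("low-attenuation fraction of an empty mask is undefined")
    return float(np.count_nonzero(vals < threshold_hu)) / float(vals.size)


def _safe_ratio(num: float, den: float) -> Optional[float]:
    if num < 0 or den < 0:
        raise ValueError("lobar volumes must be nonnegative")
    if den == 0:
        return None
    return num / den


def lobar_ratios(volumes_cm3: dict[str, float]
                 ) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Upper/lower vascular volume ratios (RUL/RLL, LUL/LLL, ULs/LLs).

    ULs/LLs = (RUL + LUL) / (RLL + LLL); the middle lobe does not enter
    either side. Zero denominators yield ``None``.
    """
    v = {k: float(volumes_cm3.get(k, 0.0)) for k in ("RUL", "RLL", "LUL", "LLL")}
    r_rul_rll = _safe_ratio(v["RUL"], v["RLL"])
    r_lul_lll = _safe_ratio(v["LUL"], v["LLL"])
    r_uls_lls = _safe_ratio(v["RUL"] + v["LUL"], v["RLL"] + v["LLL"])
    return r_rul_rll, r_lul_lll, r_uls_lls


@dataclass
class SubjectMetrics:
    """One subject's quantitative CT readout (one cohort-table row)."""

    lung_volume_cm3: float
    mean_density_hu: float
    p10_hu: float
    vessel_volume_cm3: float
    vessel_volume_by_lobe_cm3: dict[str, float]
    vascular_density: float
    ratio_rul_rll: Optional[float]
    ratio_lul_lll: Optional[float]
    ratio_uls_lls: Optional[float]
    threshold_used_hu: float
    adaptive_applied: bool
    lobe_provenance: str
    correction_factor: float = 1.0
    p15_hu: Optional[float] = None
    laa950_fraction: Optional[float] = None


def compute_subject_metrics(ct: CTVolume, mask: LungMask, lobes: LobeLabelMap,
                            seg: VesselSegmentation,
                            correction_factor: float = 1.0,
                            cfg: PipelineConfig = PipelineConfig(),
                            exclude_vessels: bool = False,
                            include_optional: bool = True) -> SubjectMetrics:
    """Assemble the full per-subject metric set.

    Vessel volumes (total and per lobe) are multiplied by
    ``correction_factor``; vascular density is computed from the corrected
    vessel volume of this subject. With ``exclude_vessels`` the densitometry
    statistics ignore vessel voxels.
    """
    if exclude_vessels:
        dens_mask = LungMask(mask=mask.mask & ~seg.vessel_mask,
                             left=mask.left & ~seg.vessel_mask,
                             right=mask.right & ~seg.vessel_mask)
    else:
        dens_mask = mask
    lv = lung_volume(mask, ct.spacing_mm)
    by_lobe = vessel_volume_per_lobe(seg, lobes, ct.spacing_mm)
    by_lobe = {k: v * correction_factor for k, v in by_lobe.items()}
    vv = seg.total_volume_cm3 * correction_factor
    r1, r2, r3 = lobar_ratios(by_lobe)
    return SubjectMetrics(
        lung_volume_cm3=lv,
        mean_density_hu=mean_density(ct, dens_mask),
        p10_hu=density_percentile(ct, dens_mask, cfg.percentile_p),
        vessel_volume_cm3=vv,
        vessel_volume_by_lobe_cm3=by_lobe,
        vascular_density=(vv / lv) if lv > 0 else 0.0,
        ratio_rul_rll=r1,
        ratio_lul_lll=r2,
        ratio_uls_lls=r3,
        threshold_used_hu=seg.threshold_used_hu,
        adaptive_applied=seg.adaptive_applied,
        lobe_provenance=lobes.provenance,
        correction_factor=correction_factor,
        p15_hu=density_percentile(ct, dens_mask, 15.0) if include_optional else None,
        laa950_fraction=(low_attenuation_fraction(ct, dens_mask, cfg.low_attenuation_threshold_hu)
                         if include_optional else None),
    )
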