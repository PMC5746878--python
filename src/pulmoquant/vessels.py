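"""Intrapulmonary vessel detection and lobar vessel volumes.

Contrast-filled vessels are far denser than aerated parenchyma, so they
are detected by attenuation thresholding inside the lung mask. The
standard threshold is -500 HU; when the lung's mean attenuation is
abnormal (outside [-850, -600] HU), an adaptive threshold is derived from
the attenuation histogram instead: the parenchymal mode (1-HU binning,
ties broken toward the lower HU) plus a fixed offset of +360 HU, clamped
to [-650, -200] HU. The offset is calibrated so a normal parenchymal mode
near -860 HU reproduces the -500 standard.

Candidate voxels (HU >= threshold, inclusive, so integer-HU edge cases are
deterministic) are grouped into 3D connected components; components with
volume of 100 mm^3 or less are rejected outright and the survivors form
the vessel mask. Vessel volumes may finally be scaled by a body-size
correction factor (off by default; optionally BSA-normalized via the
DuBois formula against a 1.73 m^2 reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .imaging import LOBE_CODES, LOBE_NAMES, CTVolume, LobeLabelMap, SubjectRecord
from .lungs import LungMask

#: m^2; the adult reference body surface area used for BSA normalization.
REFERENCE_BSA_M2 = 1.73

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the vessel/densitometry pipeline."""

    standard_threshold_hu: float = -500.0
    min_component_mm3: float = 100.0
    connectivity: int = 26
    adaptive_trigger_hu: tuple[float, float] = (-850.0, -600.0)
    adaptive_offset_hu: float = 360.0
    adaptive_clamp_hu: tuple[float, float] = (-650.0, -200.0)
    low_attenuation_threshold_hu: float = -950.0
    percentile_p: float = 10.0
    body_size_correction: str = "none"  # none | bsa

    def __post_init__(self) -> None:
        if self.min_component_mm3 <= 0:
            raise ValueError("min_component_mm3 must be positive")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if not self.adaptive_clamp_hu[0] < self.adaptive_clamp_hu[1]:
            raise ValueError("adaptive_clamp_hu interval is degenerate")
        if not 0.0 < self.percentile_p < 100.0:
            raise ValueError("percentile_p must lie in (0, 100)")
        if self.body_size_correction not in ("none", "bsa"):
            raise ValueError("body_size_correction must be 'none' or 'bsa'")


@dataclass
class VesselComponent:
    """One retained 3D-connected vessel component."""

    component_id: int
    voxel_count: int
    volume_mm3: float
    lobe: Optional[str] = None  # majority-vote lobe, when a lobe map is given


@dataclass
class VesselSegmentation:
    """Binary vessel mask plus the component inventory that produced it."""

    vessel_mask: np.ndarray
    components: list[VesselComponent]
    threshold_used_hu: float
    adaptive_applied: bool
    spacing_mm: tuple[float, float, float]

    @property
    def total_volume_cm3(self) -> float:
        return float(np.count_nonzero(self.vessel_mask)) * float(np.prod(self.spacing_mm)) / 1000.0


class EmptyMaskError(ValueError):
    pass


def compute_threshold(ct: CTVolume, mask: LungMask,
                      cfg: PipelineConfig = PipelineConfig()) -> tuple[float, bool]:
    """Choose the vessel detection threshold for one subject.

    Returns ``(threshold_hu, adaptive_applied)``. Lungs whose mean HU lies
    within ``cfg.adaptive_trigger_hu`` (inclusive) use the standard
    threshold; otherwise the attenuation-histogram rule applies.
    """
    vals = ct.voxels[mask.mask]
    if vals.size == 0:
        raise EmptyMaskError("cannot compute a threshold over an empty lung mask")
    mean_hu = float(vals.mean())
    lo, hi = cfg.adaptive_trigger_hu
    if lo <= mean_hu <= hi:
        return float(cfg.standard_threshold_hu), False
    # histogram mode at 1-HU binning; ties break toward the lower HU
    ints = np.rint(vals).astype(np.int64)
    offset = int(ints.min())
    counts = np.bincount(ints - offset)
    mode = float(int(np.argmax(counts)) + offset)
    thr = float(np.clip(mode + cfg.adaptive_offset_hu, *cfg.adaptive_clamp_hu))
    return thr, True


def _majority_lobe(comp_labels: np.ndarray, comp_z: np.ndarray) -> Optional[str]:
    """Majority-vote lobe of a component; ties go to the lobe whose member
    voxels have the more cranial (larger z) centroid."""
    inside = comp_labels > 0
    if not np.any(inside):
        return None
    counts = np.bincount(comp_labels[inside], minlength=6)
    best = counts.max()
    tied = np.nonzero(counts == best)[0]
    if len(tied) == 1:
        return LOBE_NAMES[int(tied[0])]
    zmeans = {int(c): comp_z[comp_labels == c].mean() for c in tied}
    return LOBE_NAMES[max(zmeans, key=zmeans.get)]


def segment_vessels(ct: CTVolume, mask: LungMask,
                    cfg: PipelineConfig = PipelineConfig(),
                    lobes: Optional[LobeLabelMap] = None,
                    threshold_hu: Optional[float] = None) -> VesselSegmentation:
    """Detect vessels: threshold, 3D-connect, reject small components.

    Components whose volume does not exceed ``cfg.min_component_mm3``
    (100 mm^3 by default) are removed entirely. An empty result is valid
    and means zero vessel volume.
    """
    if threshold_hu is None:
        threshold_hu, adaptive = compute_threshold(ct, mask, cfg)
    else:
        adaptive = False
    candidates = mask.mask & (ct.voxels >= threshold_hu)
    lab, n = ndimage.label(candidates, structure=_STRUCTURES[cfg.connectivity])
    voxvol = ct.voxel_volume_mm3
    components: list[VesselComponent] = []
    if n == 0:
        vessel = np.zeros_like(candidates)
    else:
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        keep = counts * voxvol > cfg.min_component_mm3
        keep[0] = False
        vessel = keep[lab]
        zcoord = np.arange(ct.shape[2])[None, None, :]
        for cid in np.nonzero(keep)[0]:
            comp = lab == cid
            lobe = None
            if lobes is not None:
                comp_labels = np.asarray(lobes.labels)[comp]
                comp_z = np.broadcast_to(zcoord, ct.shape)[comp]
                lobe = _majority_lobe(comp_labels, comp_z)
            components.append(VesselComponent(
                component_id=int(cid),
                voxel_count=int(counts[cid]),
                volume_mm3=float(counts[cid] * voxvol),
                lobe=lobe,
            ))
    return VesselSegmentation(
        vessel_mask=vessel,
        components=components,
        threshold_used_hu=float(threshold_hu),
        adaptive_applied=adaptive,
        spacing_mm=ct.spacing_mm,
    )


def bsa_dubois_m2(weight_kg: float, height_cm: float) -> float:
    """DuBois & DuBois body surface area in m^2."""
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def body_size_correction_factor(rec: Optional[SubjectRecord],
                                cfg: PipelineConfig = PipelineConfig()) -> float:
    """Multiplicative body-size factor applied to vessel volumes.

    ``none`` mode, or missing biometrics, yields 1.0. ``bsa`` mode returns
    ``1.73 / BSA_DuBois`` so a reference-sized adult is unchanged.
    """
    if cfg.body_size_correction == "none" or rec is None:
        return 1.0
    if rec.height_cm is None or rec.weight_kg is None:
        return 1.0
    if rec.height_cm <= 0 or rec.weight_kg <= 0:
        raise ValueError("height and weight must be positive for BSA correction")
    return REFERENCE_BSA_M2 / bsa_dubois_m2(rec.weight_kg, rec.height_cm)


def vessel_volume_per_lobe(seg: VesselSegmentation, lobes: LobeLabelMap,
                           spacing_mm) -> dict[str, float]:
    """Integrate vessel volume per lobe, in cm^3.

    Each vessel voxel contributes its voxel volume to its own lobe label;
    voxels labeled none are reported under ``unassigned``. The per-lobe
    volumes plus ``unassigned`` sum exactly to the total vessel volume.
    """
    labels = np.asarray(lobes.labels)
    if labels.shape != seg.vessel_mask.shape:
        raise ValueError("vessel mask and lobe map are on different grids")
    voxvol_cm3 = float(np.prod(spacing_mm)) / 1000.0
    lab_in_vessel = labels[seg.vessel_mask]
    counts = np.bincount(lab_in_vessel, minlength=6)
    out = {name: float(counts[code]) * voxvol_cm3 for name, code in LOBE_CODES.items()}
    out["unassigned"] = float(counts[0]) * voxvol_cm3
    return out
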