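"""Lung extraction and lobar labeling.

The lung mask comes from a standard attenuation heuristic: air-like voxels
(HU < -320) not connected to the volume border, two largest components
kept, intrapulmonary holes (contrast-filled vessels) recovered by
morphological closing plus 3D hole filling. The trachea and main bronchi
are not explicitly removed; they are excluded only implicitly when they
connect to the border air.

Lobar labels are taken from an external map when one is supplied (clipped
to the lung mask). Without one, a deterministic geometric fallback splits
each lung at half its cranio-caudal extent into an upper and a lower lobe
(no middle lobe or lingula); the provenance flag records which route
produced the labels so downstream statistics can stratify.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import ball
from skimage.segmentation import clear_border

from .imaging import LOBE_CODES, CTVolume, LobeLabelMap

logger = logging.getLogger(__name__)

AIR_THRESHOLD_HU = -320.0
MIN_COMPONENT_CM3 = 1.0  # speckle guard before the two-largest rule


class NoLungFoundError(ValueError):
    """No candidate lung component in the volume."""


class LobeMapMisalignedError(ValueError):
    """External lobe map labels fall outside the lung mask."""


@dataclass
class LungMask:
    """Binary lung mask with a left/right laterality split."""

    mask: np.ndarray
    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        if not np.any(self.mask):
            raise NoLungFoundError("lung mask is empty")
        if np.any(self.left & self.right):
            raise ValueError("left and right sub-masks must be disjoint")


def segment_lungs(ct: CTVolume) -> LungMask:
    """Extract the lungs from a thoracic CT volume.

    Raises :class:`NoLungFoundError` when no air-like component survives
    border clearing; a single fused component is split at the mid-body
    sagittal plane with a logged warning.
    """
    air = ct.voxels < AIR_THRESHOLD_HU
    interior = clear_border(air)
    lab, n = ndimage.label(interior, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        raise NoLungFoundError("no air-like component away from the border")
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    min_vox = int(MIN_COMPONENT_CM3 * 1000.0 / ct.voxel_volume_mm3)
    candidates = [i for i in np.argsort(counts)[::-1] if counts[i] > max(min_vox, 0)]
    if not candidates:
        raise NoLungFoundError("no lung-sized air component found")

    if len(candidates) >= 2:
        # close/fill each lung separately so the closing cannot bridge the
        # narrow mediastinal gap and fuse the lungs
        comp_masks = [_fill_vessel_holes(lab == i) for i in candidates[:2]]
        cx = [ndimage.center_of_mass(m)[0] for m in comp_masks]
        # x increases toward the patient's right
        right = comp_masks[int(np.argmax(cx))]
        left = comp_masks[int(np.argmin(cx))] & ~right
    else:
        logger.warning("single fused lung component; splitting at the mid-body plane")
        fused = lab == candidates[0]
        fused = _fill_vessel_holes(fused)
        idx = np.nonzero(fused)
        xmid = 0.5 * (idx[0].min() + idx[0].max())
        xcoord = np.arange(ct.shape[0])[:, None, None]
        right = fused & (xcoord > xmid)
        left = fused & ~right
    mask = left | right
    return LungMask(mask=mask, left=left, right=right)


def _fill_vessel_holes(lungs: np.ndarray) -> np.ndarray:
    """Close small gaps, then fill 3D-enclosed cavities (vessels)."""
    closed = ndimage.binary_closing(lungs, structure=ball(2))
    return ndimage.binary_fill_holes(closed)


def assign_lobes(mask: LungMask,
                 external_map: Optional[LobeLabelMap] = None) -> LobeLabelMap:
    """Attach lobe labels to a lung mask.

    With an external map: labels are clipped to the mask (provenance
    ``external``); if more than 1% of labeled voxels fall outside the mask
    the map is considered misaligned and an error is raised. Without one: a
    geometric fallback splits each lung at half its cranio-caudal extent
    (voxels at or above the midpoint are upper), yielding RUL/RLL and
    LUL/LLL only (provenance ``fallback``).
    """
    if external_map is not None:
        labels = np.asarray(external_map.labels)
        if labels.shape != mask.mask.shape:
            raise LobeMapMisalignedError(
                f"label map shape {labels.shape} != mask shape {mask.mask.shape}")
        labeled = labels > 0
        n_labeled = int(labeled.sum())
        n_outside = int((labeled & ~mask.mask).sum())
        if n_labeled > 0 and n_outside > 0.01 * n_labeled:
            raise LobeMapMisalignedError(
                f"{n_outside}/{n_labeled} labeled voxels outside the lung mask "
                "(> 1%): external lobe map misaligned")
        clipped = np.where(mask.mask, labels, 0).astype(np.int16)
        return LobeLabelMap(labels=clipped, provenance="external")

    labels = np.zeros(mask.mask.shape, dtype=np.int16)
    z = np.arange(mask.mask.shape[2])[None, None, :]
    for sub, upper, lower in ((mask.right, "RUL", "RLL"),
                              (mask.left, "LUL", "LLL")):
        if not np.any(sub):
            continue
        zs = np.nonzero(sub)[2]
        zmid = 0.5 * (zs.min() + zs.max())
        labels[sub & (z >= zmid)] = LOBE_CODES[upper]
        labels[sub & (z < zmid)] = LOBE_CODES[lower]
    return LobeLabelMap(labels=labels, provenance="fallback")


def merge_problem_lobes(lobemap: LobeLabelMap) -> LobeLabelMap:
    """Fold the middle lobe into the right upper lobe (ML -> RUL).

    Mirrors the fallback used when lobar segmentation cannot separate the
    middle lobe; the left lung carries no separate lingula label, so it is
    untouched. Total labeled voxel count is conserved; provenance becomes
    ``merged``.
    """
    labels = np.asarray(lobemap.labels).copy()
    labels[labels == LOBE_CODES["ML"]] = LOBE_CODES["RUL"]
    return LobeLabelMap(labels=labels, provenance="merged")
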