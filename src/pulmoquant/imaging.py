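"""Volumes, label maps and subject tables: on-disk formats and conventions.

Conventions used throughout the package:

* Voxel arrays are indexed ``(x, y, z)`` with 0-based indices.
* ``x`` increases toward the patient's right, ``y`` toward anterior and
  ``z`` cranially (RAS+); apical/basal logic relies on the ``z`` direction.
* Physical coordinates and spacings are in millimetres; attenuation is in
  Hounsfield units (HU), assumed already calibrated.
* Volumes are stored as NIfTI (``.nii``/``.nii.gz``); lobe label maps as
  integer-coded NIfTI with a JSON sidecar giving the label dictionary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Integer codes used in lobe label maps (0 = unlabeled / outside lung).
LOBE_CODES = {"RUL": 1, "ML": 2, "RLL": 3, "LUL": 4, "LLL": 5}
LOBE_NAMES = {v: k for k, v in LOBE_CODES.items()}
UPPER_LOBES = ("RUL", "LUL")
LOWER_LOBES = ("RLL", "LLL")

GROUPS = ("control", "PH")

SUBJECT_COLUMNS = (
    "subject_id",
    "group",
    "nice_subgroup",
    "height_cm",
    "weight_kg",
    "sex",
    "mpap_mmhg",
)


class FormatError(ValueError):
    """Raised for malformed on-disk inputs."""


@dataclass
class CTVolume:
    """A 3D attenuation grid in HU with voxel spacing in mm."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise FormatError("CTVolume requires a non-empty 3D scalar grid")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise FormatError(f"spacings must be three positive reals, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class LobeLabelMap:
    """Voxelwise lobe labels (codes per :data:`LOBE_CODES`, 0 = none)."""

    labels: np.ndarray
    provenance: str = "external"  # external | fallback | merged

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("lobe label map must be 3D")
        if self.provenance not in ("external", "fallback", "merged"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def volume_cm3(self, lobe: str, spacing_mm) -> float:
        """Volume of one lobe's labeled voxels in cm^3."""
        code = LOBE_CODES[lobe]
        return float(np.count_nonzero(self.labels == code)) * float(np.prod(spacing_mm)) / 1000.0


@dataclass
class SubjectRecord:
    """Clinical metadata attached to one CT examination."""

    subject_id: str
    group: str
    nice_subgroup: Optional[int] = None
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    sex: Optional[str] = None
    mpap_mmhg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}; expected one of {GROUPS}")
        if self.mpap_mmhg is not None and self.mpap_mmhg <= 0:
            raise ValueError("mpap_mmhg must be positive when present")
        # PH is defined clinically as mPAP >= 25 mmHg at rest; not enforced here.


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def write_volume(path, volume: CTVolume) -> None:
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32),
                          _affine(volume.spacing_mm, volume.origin_mm))
    nib.save(img, str(path))


def read_volume(path) -> CTVolume:
    """Read a scalar 3D NIfTI volume, preserving HU values and spacing.

    The image is reoriented to the package's RAS+ axis convention.
    Raises :class:`FormatError` for non-3D or non-scalar input and for
    non-positive spacing (spacing is never silently assumed).
    """
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    if len(img.shape) != 3:
        raise FormatError(f"expected a 3D scalar volume, got shape {img.shape}")
    zooms = img.header.get_zooms()[:3]
    if any((not np.isfinite(z)) or z <= 0 for z in zooms):
        raise FormatError(f"volume at {path} has invalid voxel spacing {zooms}")
    data = np.asanyarray(img.dataobj).astype(np.float32)
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(voxels=data, spacing_mm=tuple(float(z) for z in zooms), origin_mm=origin)


def write_labelmap(path, labelmap: LobeLabelMap, spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> None:
    """Write an integer-coded lobe map plus a JSON sidecar with the label codes."""
    img = nib.Nifti1Image(np.asarray(labelmap.labels, dtype=np.int16),
                          _affine(spacing_mm, origin_mm))
    nib.save(img, str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
    sidecar = Path(str(sidecar) + ".labels.json")
    sidecar.write_text(json.dumps({"codes": LOBE_CODES, "provenance": labelmap.provenance}))


def read_labelmap(path) -> LobeLabelMap:
    img = nib.as_closest_canonical(nib.load(str(path)))
    if len(img.shape) != 3:
        raise FormatError(f"expected a 3D label map, got shape {img.shape}")
    labels = np.asanyarray(img.dataobj).astype(np.int16)
    provenance = "external"
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".labels.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        provenance = meta.get("provenance", "external")
    return LobeLabelMap(labels=labels, provenance=provenance)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def read_subject_table(path) -> list[SubjectRecord]:
    """Read a CSV subject table into :class:`SubjectRecord` rows.

    Unknown columns are ignored with a logged warning; missing optional
    fields stay absent (``None``), never zero. Duplicate subject ids and
    unknown group labels raise.
    """
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in SUBJECT_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown subject-table columns: %s", unknown)
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise FormatError("subject table requires 'subject_id' and 'group' columns")
    ids = df["subject_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate subject_id values: {dupes}")
    records = []
    for _, row in df.iterrows():
        nice = row.get("nice_subgroup")
        nice = None if nice is None or (isinstance(nice, float) and np.isnan(nice)) else int(nice)
        sex = row.get("sex")
        sex = None if sex is None or (isinstance(sex, float) and np.isnan(sex)) else str(sex)
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            nice_subgroup=nice,
            height_cm=_opt_float(row.get("height_cm")),
            weight_kg=_opt_float(row.get("weight_kg")),
            sex=sex,
            mpap_mmhg=_opt_float(row.get("mpap_mmhg")),
        ))
    return records


#: Units for the metrics-table columns written by :func:`write_metrics_table`.
METRIC_UNITS = {
    "lung_volume_cm3": "cm3",
    "mean_density_hu": "HU",
    "p10_hu": "HU",
    "p15_hu": "HU",
    "laa950_fraction": "fraction",
    "vessel_volume_cm3": "cm3",
    "vascular_density": "dimensionless",
    "ratio_rul_rll": "dimensionless",
    "ratio_lul_lll": "dimensionless",
    "ratio_uls_lls": "dimensionless",
    "threshold_used_hu": "HU",
}


def write_metrics_table(path, table: pd.DataFrame) -> None:
    """Write one row per subject as CSV with a units comment header."""
    units = ", ".join(f"{k}[{v}]" for k, v in METRIC_UNITS.items() if k in table.columns)
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        table.to_csv(fh, index=False)


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
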