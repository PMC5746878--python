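"""Digital thorax phantoms with known lung/lobe/vessel ground truth.

The phantom emulates a contrast-enhanced inspiratory chest CT: an air
background (about -1000 HU), a soft-tissue body shell (about +40 HU), two
ellipsoidal lungs filled with Gaussian parenchyma around -850 HU, and a
contrast-filled bifurcating vessel tree rasterized well above the vessel
detection threshold. Two disease-like controls are exposed:

* ``apical_fraction`` shifts vessel volume toward the upper lobes, the
  redistribution pattern reported in pulmonary hypertension (a fraction
  ``f`` yields a ground-truth upper/lower vascular volume ratio of
  ``f / (1 - f)``);
* ``oligemia_fraction`` carves ellipsoidal low-attenuation patches into the
  parenchyma (mean HU shifted down), mimicking regional oligemia and its
  depressive effect on low density percentiles such as p10.

Lobes are geometric partitions of each lung ellipsoid by axial
pseudo-fissure planes (two on the right: RUL/ML/RLL; one on the left:
LUL/LLL). Every phantom carries voxel-level truth masks and per-lobe vessel
volumes, so the measurement pipeline can be validated by parameter
recovery. All randomness flows from explicit seeds; identical spec + seed
reproduce the volume bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .imaging import LOBE_CODES, CTVolume, LobeLabelMap

LOBES = ("RUL", "ML", "RLL", "LUL", "LLL")
RIGHT_LOBES = ("RUL", "ML", "RLL")
LEFT_LOBES = ("LUL", "LLL")

# Pseudo-fissure planes as fractions of each lung's cranio-caudal extent,
# measured from the lung base. The right lung is cut twice (RLL below 0.45,
# ML in [0.45, 0.60), RUL above), the left lung once (LLL below 0.55).
RIGHT_FISSURES = (0.45, 0.60)
LEFT_FISSURE = 0.55

#: Radius ratio at each bifurcation, r_child = r_parent * 2**(-1/3)
#: (Murray's law for a symmetric bifurcation conserving r^3).
MURRAY_RATIO = 2.0 ** (-1.0 / 3.0)
LENGTH_RATIO = 0.72


class PhantomError(ValueError):
    """Invalid phantom specification or geometry."""


class InfeasibleVesselVolumeError(PhantomError):
    """The requested vessel volume cannot be realized by the tree."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject.

    HU defaults follow contrast-enhanced inspiratory CT: parenchyma near
    -850 HU, opacified vessels at +150 HU, additive Gaussian reconstruction
    noise of 20 HU.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (1.4, 1.4, 1.4)
    parenchyma_mean_hu: float = -850.0
    parenchyma_sd_hu: float = 40.0
    noise_sd_hu: float = 20.0
    vessel_hu: float = 150.0
    target_vessel_volume_cm3: float = 40.0
    apical_fraction: float = 0.35
    oligemia_fraction: float = 0.0
    oligemia_shift_hu: float = -80.0
    n_tree_generations: int = 4
    lung_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise PhantomError("grid_shape must be three positive integers")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise PhantomError("spacing_mm must be three positive reals")
        for name in ("apical_fraction", "oligemia_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PhantomError(f"{name} must lie in [0, 1], got {v}")
        if self.parenchyma_sd_hu < 0 or self.noise_sd_hu < 0:
            raise PhantomError("standard deviations must be nonnegative")
        if self.oligemia_shift_hu > 0:
            raise PhantomError("oligemia_shift_hu must be <= 0")
        if self.target_vessel_volume_cm3 <= 0:
            raise PhantomError("target_vessel_volume_cm3 must be positive")
        if self.n_tree_generations < 1:
            raise PhantomError("n_tree_generations must be >= 1")
        # above ~1.05 the lung ellipsoids breach the body shell
        if not 0.5 <= self.lung_scale <= 1.05:
            raise PhantomError("lung_scale must lie in [0.5, 1.05]")
        # Vessels must be separable from parenchyma by a threshold.
        if self.vessel_hu <= self.parenchyma_mean_hu + 5 * self.parenchyma_sd_hu:
            raise PhantomError(
                "vessel_hu must exceed parenchyma_mean_hu + 5*parenchyma_sd_hu")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, dtype=float) * np.asarray(self.spacing_mm)


@dataclass
class VesselTree:
    """Line-segment skeleton of the pulmonary vasculature.

    ``segments`` holds (start_mm, end_mm, radius_mm) triples;
    ``lobe_of_segment`` the lobe each segment was grown in. Segment
    midpoints always lie inside the lung region of their assigned lobe
    (lobe regions are convex, and all endpoints are kept inside them).
    """

    segments: list[tuple[np.ndarray, np.ndarray, float]]
    lobe_of_segment: list[str]

    def analytic_volume_mm3(self, lobe: Optional[str] = None) -> float:
        """Sum of cylinder volumes pi r^2 L, optionally for one lobe."""
        total = 0.0
        for (a, b, r), lb in zip(self.segments, self.lobe_of_segment):
            if lobe is not None and lb != lobe:
                continue
            total += math.pi * r * r * float(np.linalg.norm(b - a))
        return total


@dataclass
class PhantomTruth:
    """Ground-truth masks and per-lobe vessel volumes of one phantom."""

    lung_mask: np.ndarray
    lobe_labels: LobeLabelMap
    vessel_mask: np.ndarray
    vessel_volume_per_lobe_cm3: dict[str, float]
    oligemia_mask: np.ndarray

    @property
    def total_vessel_volume_cm3(self) -> float:
        return float(sum(self.vessel_volume_per_lobe_cm3.values()))


@dataclass(frozen=True)
class CohortSpec:
    """Two-arm study design: control-like vs PH-like phantom parameters.

    Apical-fraction means default to 0.35 (control) and 0.54 (PH), whose
    implied truth upper/lower ratios f/(1-f) are 0.54 and 1.17; the SDs are
    chosen so the between-subject spread of the simulated ratios matches a
    realistic clinical dispersion (narrow in controls, wide in PH).
    """

    n_control: int = 8
    n_ph: int = 8
    control_apical_fraction_dist: tuple[float, float] = (0.35, 0.065)
    ph_apical_fraction_dist: tuple[float, float] = (0.54, 0.20)
    ph_oligemia_fraction_dist: tuple[float, float] = (0.15, 0.05)
    control_oligemia_fraction_dist: tuple[float, float] = (0.0, 0.0)
    lung_scale_dist: tuple[float, float] = (0.95, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_ph < 0 or self.n_control + self.n_ph < 1:
            raise PhantomError("cohort needs n_control + n_ph >= 1, both nonnegative")


def _ellipsoid_interior_distance(y, axes) -> float:
    """Distance from an interior point to the surface of an axis-aligned
    ellipsoid centered at the origin.

    The nearest surface point x satisfies x_i = a_i^2 y_i / (a_i^2 + t)
    for the root t < 0 of g(t) = sum (a_i y_i / (a_i^2 + t))^2 - 1; the
    root is bracketed in (-a_min^2, 0] and found by bisection.
    """
    a0, a1, a2_ = (float(v) for v in axes)
    y0, y1, y2 = (float(v) if abs(float(v)) > 1e-9 else 1e-9 for v in y)
    s0, s1, s2 = a0 * a0, a1 * a1, a2_ * a2_

    def g(t: float) -> float:
        return ((a0 * y0 / (s0 + t)) ** 2 + (a1 * y1 / (s1 + t)) ** 2
                + (a2_ * y2 / (s2 + t)) ** 2 - 1.0)

    lo = -min(s0, s1, s2) * (1.0 - 1e-12)
    hi = 0.0
    if g(hi) >= 0.0:  # on (or numerically at) the surface
        return 0.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    return abs(t) * math.sqrt((y0 / (s0 + t)) ** 2 + (y1 / (s1 + t)) ** 2
                              + (y2 / (s2 + t)) ** 2)


class LungGeometry:
    """Analytic thorax geometry: body ellipse, lung ellipsoids, fissures.

    All proportions scale with the physical grid extent, so the same
    anatomy renders at any resolution. ``x`` increases toward the patient's
    right, ``z`` cranially; the right lung therefore sits at larger ``x``.
    Each lobe region (lung ellipsoid cut by axial fissure planes) is convex.
    """

    def __init__(self, extent_mm, lung_scale: float = 1.0) -> None:
        ext = np.asarray(extent_mm, dtype=float)
        self.extent = ext
        self.body_center = np.array([0.5 * ext[0], 0.5 * ext[1]])
        self.body_semiaxes = np.array([0.47 * ext[0], 0.42 * ext[1]])
        self.body_zrange = (0.02 * ext[2], 0.98 * ext[2])
        self.lung_semiaxes = lung_scale * np.array(
            [0.19 * ext[0], 0.32 * ext[1], 0.40 * ext[2]])
        dx = 0.22 * ext[0]
        self.lung_centers = {
            "right": np.array([0.5 * ext[0] + dx, 0.5 * ext[1], 0.52 * ext[2]]),
            "left": np.array([0.5 * ext[0] - dx, 0.5 * ext[1], 0.52 * ext[2]]),
        }

    def side_of_lobe(self, lobe: str) -> str:
        return "right" if lobe in RIGHT_LOBES else "left"

    def lung_zrange(self, side: str) -> tuple[float, float]:
        c = self.lung_centers[side]
        r = self.lung_semiaxes[2]
        return (c[2] - r, c[2] + r)

    def lobe_zband(self, lobe: str) -> tuple[float, float]:
        """Absolute z interval of one lobe's fissure band."""
        side = self.side_of_lobe(lobe)
        zlo, zhi = self.lung_zrange(side)
        span = zhi - zlo
        if side == "right":
            f1, f2 = RIGHT_FISSURES
            bands = {"RLL": (0.0, f1), "ML": (f1, f2), "RUL": (f2, 1.0)}
        else:
            bands = {"LLL": (0.0, LEFT_FISSURE), "LUL": (LEFT_FISSURE, 1.0)}
        lo, hi = bands[lobe]
        return (zlo + lo * span, zlo + hi * span)

    def in_lung(self, p, side: str) -> bool:
        c = self.lung_centers[side]
        q = (np.asarray(p, dtype=float) - c) / self.lung_semiaxes
        return float(q @ q) <= 1.0

    def in_lobe(self, p, lobe: str, margin: float = 0.0,
                band_margin: Optional[float] = None) -> bool:
        """Whether ``p`` lies in the lobe region with at least ``margin``
        mm of clearance to the pleural surface and ``band_margin`` mm
        (``margin`` when omitted) to the fissure planes.

        Clearance to the ellipsoid surface is evaluated exactly (not by
        axis-shrinking, which overestimates the lateral clearance near the
        apex of an elongated ellipsoid); the eroded region stays convex."""
        bm = margin if band_margin is None else band_margin
        zlo, zhi = self.lobe_zband(lobe)
        if not (zlo + bm <= p[2] <= zhi - bm):
            return False
        c = self.lung_centers[self.side_of_lobe(lobe)]
        y = np.asarray(p, dtype=float) - c
        q2 = float(np.sum((y / self.lung_semiaxes) ** 2))
        if q2 > 1.0:
            return False
        if margin <= 0.0:
            return True
        # cheap bounds first: (1-q)*a_min <= distance <= |y|(1/q - 1)
        q = math.sqrt(q2)
        a_min = float(self.lung_semiaxes.min())
        if (1.0 - q) * a_min >= margin:
            return True
        if q > 1e-9 and float(np.linalg.norm(y)) * (1.0 / q - 1.0) < margin:
            return False
        return _ellipsoid_interior_distance(y, self.lung_semiaxes) >= margin

    def lobe_seed_point(self, lobe: str) -> np.ndarray:
        """Hilar entry point of a lobe's subtree: medial, near the lobe's
        mediastinal edge closest to mid-lung."""
        side = self.side_of_lobe(lobe)
        c = self.lung_centers[side]
        zlo, zhi = self.lobe_zband(lobe)
        # step 15% into the band from the edge nearest the lung center
        if abs(zlo - c[2]) < abs(zhi - c[2]):
            z = zlo + 0.15 * (zhi - zlo)
        else:
            z = zhi - 0.15 * (zhi - zlo)
        sign = -1.0 if side == "right" else 1.0  # toward the mediastinum
        p = np.array([c[0] + sign * 0.45 * self.lung_semiaxes[0], c[1], z])
        if not self.in_lobe(p, lobe):  # fall back to the band center
            p = np.array([c[0], c[1], 0.5 * (zlo + zhi)])
        return p

    def lobe_centroid(self, lobe: str) -> np.ndarray:
        side = self.side_of_lobe(lobe)
        c = self.lung_centers[side]
        zlo, zhi = self.lobe_zband(lobe)
        return np.array([c[0], c[1], 0.5 * (zlo + zhi)])

    def voxel_masks(self, grid_shape, spacing_mm):
        """Rasterize body mask, lung mask and lobe labels on the grid."""
        nx, ny, nz = grid_shape
        sx, sy, sz = spacing_mm
        # voxel-center coordinates
        xs = (np.arange(nx) + 0.5) * sx
        ys = (np.arange(ny) + 0.5) * sy
        zs = (np.arange(nz) + 0.5) * sz
        X = xs[:, None, None]
        Y = ys[None, :, None]
        Z = zs[None, None, :]

        bc, ba = self.body_center, self.body_semiaxes
        body = ((X - bc[0]) ** 2 / ba[0] ** 2 + (Y - bc[1]) ** 2 / ba[1] ** 2 <= 1.0)
        body = body & (Z >= self.body_zrange[0]) & (Z <= self.body_zrange[1])

        labels = np.zeros(grid_shape, dtype=np.int16)
        lung = np.zeros(grid_shape, dtype=bool)
        a = self.lung_semiaxes
        for side, lobes in (("right", RIGHT_LOBES), ("left", LEFT_LOBES)):
            c = self.lung_centers[side]
            m = ((X - c[0]) ** 2 / a[0] ** 2 + (Y - c[1]) ** 2 / a[1] ** 2
                 + (Z - c[2]) ** 2 / a[2] ** 2 <= 1.0)
            lung |= m
            for lobe in lobes:
                zlo, zhi = self.lobe_zband(lobe)
                band = m & (Z >= zlo) & (Z <= zhi)
                labels[band] = LOBE_CODES[lobe]
        # guarantee a soft-tissue shell of >= 2 voxels around the lungs, so
        # lung air can never touch the outside air even at coarse spacing
        from scipy import ndimage
        shell = ndimage.binary_dilation(lung, iterations=2)
        body |= shell

        # fissure planes land between voxel centers; sweep up any lung voxel
        # left unlabeled by strict band edges
        unl = lung & (labels == 0)
        if np.any(unl):
            idx = np.argwhere(unl)
            pts = (idx + 0.5) * np.asarray(spacing_mm)
            for (i, j, k), p in zip(idx, pts):
                side = "right" if self.in_lung(p, "right") else "left"
                zlo, _ = self.lung_zrange(side)
                zhi_l = self.lung_zrange(side)[1]
                frac = (p[2] - zlo) / (zhi_l - zlo)
                if side == "right":
                    lobe = "RLL" if frac < RIGHT_FISSURES[0] else (
                        "ML" if frac < RIGHT_FISSURES[1] else "RUL")
                else:
                    lobe = "LLL" if frac < LEFT_FISSURE else "LUL"
                labels[i, j, k] = LOBE_CODES[lobe]
        return body, lung, labels


def _clamp_inside(geom: LungGeometry, lobe: str, start: np.ndarray,
                  end: np.ndarray, margin: float = 0.0,
                  band_margin: Optional[float] = None) -> np.ndarray:
    """Shrink ``end`` toward ``start`` until it lies inside the (convex)
    lobe region eroded by ``margin``; ``start`` is assumed inside."""
    if geom.in_lobe(end, lobe, margin, band_margin):
        return end
    lo, hi = 0.0, 1.0
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if geom.in_lobe(start + mid * (end - start), lobe, margin, band_margin):
            lo = mid
        else:
            hi = mid
    t = max(lo * 0.95, 0.02)  # stay strictly interior, keep nonzero length
    return start + t * (end - start)


def root_radius_estimate(geom: LungGeometry, lobe: str, generations: int,
                         target_mm3: float) -> float:
    """Provisional root radius from the analytic volume of an ideal tree."""
    zlo, zhi = geom.lobe_zband(lobe)
    root_len = float(np.clip(0.45 * (zhi - zlo), 8.0, 50.0))
    vol_factor = sum((2.0 * MURRAY_RATIO**2 * LENGTH_RATIO) ** g
                     for g in range(generations))
    return math.sqrt(target_mm3 / (math.pi * root_len * vol_factor))


def _grow_lobe_tree(geom: LungGeometry, lobe: str, generations: int,
                    rng: np.random.Generator, root_radius_mm: float,
                    slack_mm: float = 0.0):
    """Grow a bifurcating skeleton inside one lobe; radii are relative
    (root = 1) and rescaled later to meet the volume target.

    Segments are confined to the lobe eroded by their own expected radius
    (``root_radius_mm`` scaled down the generations) plus ``slack_mm``, so
    the rasterized vessel tapers off before reaching the pleura and the
    fissures (real vasculature does not breach the pleural surface).
    """
    zlo, zhi = geom.lobe_zband(lobe)
    band_height = zhi - zlo
    root_len = float(np.clip(0.45 * band_height, 8.0, 50.0))
    max_margin = 0.45 * min(float(geom.lung_semiaxes.min()), 0.5 * band_height)

    def margin_for(gen: int) -> float:
        return min(1.1 * root_radius_mm * MURRAY_RATIO**gen + slack_mm,
                   max_margin)

    # fissure planes need no radius clearance (crossing them is harmless
    # and real vessels do); only keep endpoints strictly inside the band
    band_margin = slack_mm

    start = geom.lobe_seed_point(lobe)
    if not geom.in_lobe(start, lobe, margin_for(0), band_margin):
        start = geom.lobe_centroid(lobe)
    centroid = geom.lobe_centroid(lobe)
    d0 = centroid - start
    n0 = np.linalg.norm(d0)
    d0 = d0 / n0 if n0 > 1e-9 else np.array([0.0, 0.0, 1.0])

    segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    stack = [(start, d0, root_len, 1.0, 0)]
    while stack:
        s, d, length, r_rel, gen = stack.pop()
        end = _clamp_inside(geom, lobe, s, s + length * d, margin_for(gen),
                            band_margin)
        segments.append((s, end, r_rel))
        if gen + 1 >= generations:
            continue
        # children: rotate away from the parent axis, biased back toward
        # the lobe interior so branches do not pile up on the boundary;
        # directions that would clamp to a stub are resampled
        child_len = length * LENGTH_RATIO
        child_margin = margin_for(gen + 1)
        first_perp = None
        for ci in range(2):
            best_dir, best_perp, best_frac = None, None, -1.0
            for _try in range(6):
                perp = rng.normal(size=3)
                perp -= perp @ d * d
                nrm = np.linalg.norm(perp)
                perp = perp / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
                # siblings leave on opposite sides of the parent axis, so
                # their cylinders separate instead of running together
                if first_perp is not None and perp @ first_perp > 0:
                    perp = -perp
                angle = math.radians(rng.normal(35.0, 8.0))
                cd = math.cos(angle) * d + math.sin(angle) * perp
                to_c = centroid - end
                ncc = np.linalg.norm(to_c)
                if ncc > 1e-9:
                    cd = 0.85 * cd + 0.15 * (to_c / ncc)
                cd /= np.linalg.norm(cd)
                trial_end = _clamp_inside(geom, lobe, end,
                                          end + child_len * cd, child_margin,
                                          band_margin)
                frac = float(np.linalg.norm(trial_end - end)) / child_len
                if frac > best_frac:
                    best_dir, best_perp, best_frac = cd, perp, frac
                if frac >= 0.7:
                    break
            if ci == 0:
                first_perp = best_perp
            stack.append((end, best_dir, child_len,
                          r_rel * MURRAY_RATIO, gen + 1))
    return segments


def _union_volume_mm3(segments, rng: np.random.Generator,
                      n_samples: int = 4000) -> float:
    """Monte-Carlo estimate of the union volume of a set of cylinders.

    Samples points uniformly within the cylinders (weighted by analytic
    volume) and divides each point by its multiplicity, correcting the
    double-counting of junction overlaps in the plain cylinder sum.
    """
    vols = np.array([math.pi * r * r * float(np.linalg.norm(b - a))
                     for a, b, r in segments])
    v_tot = float(vols.sum())
    if v_tot <= 0:
        return 0.0
    counts = rng.multinomial(n_samples, vols / v_tot)
    pts = []
    for (a, b, r), k in zip(segments, counts):
        if k == 0:
            continue
        u = b - a
        L = float(np.linalg.norm(u))
        u = u / L
        # orthonormal frame around the axis
        ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, ref); e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        t = rng.uniform(0.0, L, size=k)
        rad = r * np.sqrt(rng.uniform(0.0, 1.0, size=k))
        ang = rng.uniform(0.0, 2.0 * math.pi, size=k)
        pts.append(a + t[:, None] * u
                   + (rad * np.cos(ang))[:, None] * e1
                   + (rad * np.sin(ang))[:, None] * e2)
    P = np.concatenate(pts, axis=0)
    mult = np.zeros(len(P))
    for a, b, r in segments:
        u = b - a
        L = float(np.linalg.norm(u))
        u = u / L
        rel = P - a
        t = rel @ u
        radial2 = np.einsum("ij,ij->i", rel, rel) - t * t
        mult += (t >= 0.0) & (t <= L) & (radial2 <= r * r)
    return v_tot * float(np.mean(1.0 / np.maximum(mult, 1.0)))


def _lobe_volume_targets_mm3(spec: PhantomSpec) -> dict[str, float]:
    """Split the vessel-volume target across lobes: ``apical_fraction`` to
    the upper lobes (RUL/LUL equally), the rest to the lower lobes
    (RLL/LLL equally); the middle lobe carries no tree."""
    total = spec.target_vessel_volume_cm3 * 1000.0
    upper = spec.apical_fraction * total
    lower = (1.0 - spec.apical_fraction) * total
    return {"RUL": upper / 2, "LUL": upper / 2,
            "RLL": lower / 2, "LLL": lower / 2, "ML": 0.0}


def generate_vessel_tree(spec: PhantomSpec,
                         geom: Optional[LungGeometry] = None) -> VesselTree:
    """Build the phantom's vessel skeleton.

    One bifurcating subtree per lobe grows from a hilar seed point;
    child radii follow Murray's law (ratio 2^(-1/3)). After the geometry is
    fixed, each subtree's radii are rescaled so its expected occupied
    (union) volume matches the lobe's share of
    ``target_vessel_volume_cm3``, correcting for cylinder overlap at the
    bifurcations. Raises :class:`InfeasibleVesselVolumeError` if the
    required root radius would not fit the lobe.
    """
    if geom is None:
        geom = LungGeometry(spec.extent_mm, spec.lung_scale)
    targets = _lobe_volume_targets_mm3(spec)
    slack = float(max(spec.spacing_mm))
    segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    lobe_of: list[str] = []
    for li, lobe in enumerate(LOBES):  # fixed order for determinism
        target = targets[lobe]
        if target <= 0.0:
            continue
        zlo, zhi = geom.lobe_zband(lobe)
        max_root = 0.35 * min(float(geom.lung_semiaxes.min()), 0.5 * (zhi - zlo))
        r_margin = root_radius_estimate(geom, lobe, spec.n_tree_generations, target)
        mc_rng = np.random.default_rng((spec.seed, li, 1))
        rel, scale = [], r_margin
        # grow, calibrate the radius scale against the expected *union*
        # volume (cylinder sums double-count the junctions), and re-grow
        # with wider margins until they cover the calibrated radii
        for _ in range(4):
            grow_rng = np.random.default_rng((spec.seed, li))
            rel = _grow_lobe_tree(geom, lobe, spec.n_tree_generations,
                                  grow_rng, r_margin, slack)
            v_rel = sum(math.pi * r * r * float(np.linalg.norm(b - a))
                        for a, b, r in rel)
            scale = math.sqrt(target / v_rel)
            for _ in range(2):
                scaled = [(a, b, r * scale) for a, b, r in rel]
                union = _union_volume_mm3(scaled, mc_rng)
                scale *= math.sqrt(target / union)
            if scale > max_root:
                raise InfeasibleVesselVolumeError(
                    f"lobe {lobe}: volume target {target:.0f} mm3 needs root "
                    f"radius {scale:.1f} mm > {max_root:.1f} mm; increase "
                    "n_tree_generations or lower target_vessel_volume_cm3")
            if scale <= r_margin * 1.001:  # margins already cover the radii
                break
            r_margin = scale
        for a, b, r in rel:
            segments.append((a, b, r * scale))
            lobe_of.append(lobe)
    return VesselTree(segments=segments, lobe_of_segment=lobe_of)


def _rasterize_tree(tree: VesselTree, grid_shape, spacing_mm) -> np.ndarray:
    """Voxelize the tree: a voxel is vessel if its center lies within a
    segment's cylinder (flat caps)."""
    mask = np.zeros(grid_shape, dtype=bool)
    sp = np.asarray(spacing_mm, dtype=float)
    shape = np.asarray(grid_shape)
    for (a, b, r) in tree.segments:
        lo_mm = np.minimum(a, b) - r - sp
        hi_mm = np.maximum(a, b) + r + sp
        lo = np.maximum(np.floor(lo_mm / sp - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil(hi_mm / sp - 0.5).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        xs = (np.arange(lo[0], hi[0]) + 0.5) * sp[0]
        ys = (np.arange(lo[1], hi[1]) + 0.5) * sp[1]
        zs = (np.arange(lo[2], hi[2]) + 0.5) * sp[2]
        P = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
        u = b - a
        L = float(np.linalg.norm(u))
        if L < 1e-9:
            continue
        u = u / L
        rel = P - a
        t = rel @ u
        radial2 = np.sum(rel * rel, axis=-1) - t * t
        inside = (t >= 0.0) & (t <= L) & (radial2 <= r * r)
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= inside
    return mask


def _place_oligemia(spec: PhantomSpec, lung: np.ndarray, vessel: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Union of random ellipsoidal patches covering approximately
    ``oligemia_fraction`` of the parenchyma (lung minus vessels)."""
    olig = np.zeros_like(lung)
    if spec.oligemia_fraction <= 0.0:
        return olig
    parenchyma = lung & ~vessel
    target = spec.oligemia_fraction * int(parenchyma.sum())
    sp = np.asarray(spec.spacing_mm)
    shape = np.asarray(spec.grid_shape)
    lung_idx = np.argwhere(lung)
    for _ in range(2000):
        if olig.sum() >= target:
            break
        center = (lung_idx[rng.integers(len(lung_idx))] + 0.5) * sp
        semi = rng.uniform(6.0, 16.0, size=3)  # patch semi-axes in mm
        lo = np.maximum(np.floor((center - semi) / sp - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil((center + semi) / sp - 0.5).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        xs = (np.arange(lo[0], hi[0]) + 0.5) * sp[0]
        ys = (np.arange(lo[1], hi[1]) + 0.5) * sp[1]
        zs = (np.arange(lo[2], hi[2]) + 0.5) * sp[2]
        q = ((xs[:, None, None] - center[0]) ** 2 / semi[0] ** 2
             + (ys[None, :, None] - center[1]) ** 2 / semi[1] ** 2
             + (zs[None, None, :] - center[2]) ** 2 / semi[2] ** 2)
        patch = q <= 1.0
        sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        olig[sub] |= patch & parenchyma[sub]
    return olig


def rasterize_phantom(spec: PhantomSpec,
                      tree: Optional[VesselTree] = None
                      ) -> tuple[CTVolume, PhantomTruth]:
    """Render a phantom CT volume and its ground truth.

    Deterministic given ``spec.seed``: the same spec always yields a
    bit-identical volume and truth.
    """
    if min(spec.grid_shape) < 16:
        raise PhantomError("grid too small for the body geometry (min dim 16)")
    geom = LungGeometry(spec.extent_mm, spec.lung_scale)
    if tree is None:
        tree = generate_vessel_tree(spec, geom)
    body, lung, labels = geom.voxel_masks(spec.grid_shape, spec.spacing_mm)
    if not np.any(lung):
        raise PhantomError("grid too small: lungs rasterize to zero voxels")

    vessel = _rasterize_tree(tree, spec.grid_shape, spec.spacing_mm) & lung

    rng = np.random.default_rng(spec.seed)
    hu = np.full(spec.grid_shape, -1000.0, dtype=np.float64)
    hu[body] = 40.0
    n_lung = int(lung.sum())
    hu[lung] = rng.normal(spec.parenchyma_mean_hu, spec.parenchyma_sd_hu, size=n_lung)
    olig = _place_oligemia(spec, lung, vessel, rng)
    hu[olig] += spec.oligemia_shift_hu
    hu[vessel] = spec.vessel_hu
    if spec.noise_sd_hu > 0:
        hu += rng.normal(0.0, spec.noise_sd_hu, size=spec.grid_shape)

    voxvol_cm3 = float(np.prod(spec.spacing_mm)) / 1000.0
    per_lobe = {}
    for lobe in LOBES:
        per_lobe[lobe] = float(np.count_nonzero(vessel & (labels == LOBE_CODES[lobe]))) * voxvol_cm3
    truth = PhantomTruth(
        lung_mask=lung,
        lobe_labels=LobeLabelMap(labels=labels, provenance="external"),
        vessel_mask=vessel,
        vessel_volume_per_lobe_cm3=per_lobe,
        oligemia_mask=olig,
    )
    ct = CTVolume(voxels=hu.astype(np.float32), spacing_mm=spec.spacing_mm)
    return ct, truth


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd <= 0:
        return float(np.clip(mean, 0.0, 1.0))
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


def draw_cohort_specs(cspec: CohortSpec, base: PhantomSpec
                      ) -> list[tuple[PhantomSpec, str]]:
    """Draw per-subject phantom specs (without rendering them).

    Subject parameters come from the group distributions (truncated to
    [0, 1]); per-subject seeds derive deterministically from ``cspec.seed``.
    """
    rng = np.random.default_rng(cspec.seed)
    out: list[tuple[PhantomSpec, str]] = []
    for group, n in (("control", cspec.n_control), ("PH", cspec.n_ph)):
        if group == "control":
            af_dist, ol_dist = (cspec.control_apical_fraction_dist,
                                cspec.control_oligemia_fraction_dist)
        else:
            af_dist, ol_dist = (cspec.ph_apical_fraction_dist,
                                cspec.ph_oligemia_fraction_dist)
        for _ in range(n):
            af = _truncated_normal(rng, *af_dist)
            ol = _truncated_normal(rng, *ol_dist)
            ls = float(np.clip(rng.normal(*cspec.lung_scale_dist), 0.85, 1.05))
            seed = int(rng.integers(0, 2**31 - 1))
            out.append((replace(base, apical_fraction=af, oligemia_fraction=ol,
                                lung_scale=ls, seed=seed), group))
    return out


def generate_cohort(cspec: CohortSpec, base: PhantomSpec
                    ) -> list[tuple[CTVolume, PhantomTruth, str]]:
    """Render a two-arm cohort of phantoms with group labels attached."""
    cohort = []
    for sub_spec, group in draw_cohort_specs(cspec, base):
        ct, truth = rasterize_phantom(sub_spec)
        cohort.append((ct, truth, group))
    return cohort
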