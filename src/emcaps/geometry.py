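"""Radial profiles, outer-diameter estimation and linker-pattern distances.

The radial intensity profile about a particle center is the class
fingerprint: mean pixel intensity binned by Euclidean distance from the
center.  The outer diameter is read off the profile's contrast edge --
the outermost radius at which intensity climbs back through the
half-depth level between the deepest minimum and the asymptotic
background.  Pattern analysis measures center-to-center distances
between a central Qt particle and its Tm satellites, recovering the
cross-linker length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import BarcodeClass, Micrograph, PixelScale

__all__ = [
    "RadialProfile",
    "PatternMeasurement",
    "EstimationError",
    "radial_profile",
    "average_radial_profile",
    "estimate_outer_diameter",
    "pattern_distances",
]


class EstimationError(RuntimeError):
    """Raised when a profile carries no usable contrast edge."""


@dataclass(frozen=True)
class RadialProfile:
    """Mean intensity vs distance from a center, in fixed-width bins.

    Bins that received no pixels carry ``n_pixels`` 0 and NaN intensity.
    """

    radii_nm: np.ndarray  # bin centers
    mean_intensity: np.ndarray
    n_pixels: np.ndarray
    center: tuple[float, float]  # (row, col), px

    def __post_init__(self) -> None:
        if np.any(np.diff(self.radii_nm) <= 0):
            raise ValueError("bin centers must be strictly increasing")

    @property
    def bin_nm(self) -> float:
        return float(self.radii_nm[1] - self.radii_nm[0]) if len(self.radii_nm) > 1 \
            else float(2 * self.radii_nm[0])


def _profile_sums(raster: np.ndarray, center: tuple[float, float],
                  r_max_nm: float, bin_nm: float, scale: PixelScale
                  ) -> tuple[np.ndarray, np.ndarray]:
    h, w = raster.shape
    cr, cc = center
    if not (0 <= cr <= h - 1 and 0 <= cc <= w - 1):
        raise ValueError(f"center {center} outside frame {raster.shape}")
    ext = int(math.ceil(r_max_nm / scale.nm_per_pixel)) + 1
    r0, r1 = max(0, int(cr) - ext), min(h, int(cr) + ext + 1)
    c0, c1 = max(0, int(cc) - ext), min(w, int(cc) + ext + 1)
    rr = np.arange(r0, r1, dtype=float)[:, None] - cr
    cols = np.arange(c0, c1, dtype=float)[None, :] - cc
    d_nm = np.hypot(rr, cols) * scale.nm_per_pixel
    sel = d_nm < r_max_nm
    idx = (d_nm[sel] / bin_nm).astype(int)
    vals = raster[r0:r1, c0:c1][sel]
    n_bins = int(math.ceil(r_max_nm / bin_nm))
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    sums = np.bincount(idx, weights=vals, minlength=n_bins)[:n_bins]
    return sums, counts


def radial_profile(raster: np.ndarray | Micrograph, center: tuple[float, float],
                   r_max_nm: float, bin_nm: float | None = None,
                   scale: PixelScale | None = None) -> RadialProfile:
    """Bin pixel intensities by distance (nm) from a sub-pixel center.

    Distances are computed on pixel centers (row-major, 0-based), so a
    floating-point center is honored exactly.  Default bin width is one
    pixel (1.81 nm at the default scale).
    """
    if isinstance(raster, Micrograph):
        scale = scale or raster.scale
        raster = raster.pixels
    scale = scale or PixelScale()
    if r_max_nm <= 0:
        raise ValueError(f"r_max_nm must be positive, got {r_max_nm}")
    if bin_nm is None:
        bin_nm = scale.nm_per_pixel
    sums, counts = _profile_sums(np.asarray(raster, float), center,
                                 r_max_nm, bin_nm, scale)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    radii = (np.arange(len(counts)) + 0.5) * bin_nm
    return RadialProfile(radii, mean, counts, center)


def average_radial_profile(raster: np.ndarray | Micrograph,
                           centers: list[tuple[float, float]],
                           r_max_nm: float, bin_nm: float | None = None,
                           scale: PixelScale | None = None) -> RadialProfile:
    """Pixel-count-weighted mean profile over several centers."""
    if isinstance(raster, Micrograph):
        scale = scale or raster.scale
        raster = raster.pixels
    scale = scale or PixelScale()
    if not centers:
        raise ValueError("need at least one center")
    if r_max_nm <= 0:
        raise ValueError(f"r_max_nm must be positive, got {r_max_nm}")
    if bin_nm is None:
        bin_nm = scale.nm_per_pixel
    raster = np.asarray(raster, float)
    total_sums = total_counts = None
    for center in centers:
        sums, counts = _profile_sums(raster, center, r_max_nm, bin_nm, scale)
        if total_sums is None:
            total_sums, total_counts = sums, counts
        else:
            total_sums += sums
            total_counts += counts
    with np.errstate(invalid="ignore"):
        mean = np.where(total_counts > 0,
                        total_sums / np.maximum(total_counts, 1), np.nan)
    radii = (np.arange(len(total_counts)) + 0.5) * bin_nm
    return RadialProfile(radii, mean, total_counts,
                         (float("nan"), float("nan")))


def estimate_outer_diameter(profile: RadialProfile,
                            background_tail_fraction: float = 0.2,
                            min_depth: float = 0.05) -> float:
    """Outer diameter (nm) from the contrast edge of a radial profile.

    The background level is the mean intensity of the outermost
    ``background_tail_fraction`` of populated bins; the outer radius is
    the outermost radius at which intensity crosses the half-depth level
    between the deepest minimum and the background (linear interpolation
    between bins).  Invariant to affine intensity rescaling.  Profiles
    whose minimum is less than ``min_depth`` (as a fraction of the
    background level) below background raise :class:`EstimationError`.
    """
    ok = profile.n_pixels > 0
    if ok.sum() < 4:
        raise EstimationError("profile has too few populated bins")
    radii = profile.radii_nm[ok]
    intens = profile.mean_intensity[ok]
    n_tail = max(1, int(round(background_tail_fraction * len(intens))))
    background = float(intens[-n_tail:].mean())
    interior = intens[:-n_tail]
    if len(interior) == 0:
        raise EstimationError("profile entirely background")
    i_min = int(np.argmin(interior))
    depth = background - interior[i_min]
    if depth <= min_depth * abs(background) or depth <= 0:
        raise EstimationError("no contrast minimum below background")
    # a strictly rising profile has no particle, only a gradient
    diffs = np.diff(intens)
    if len(diffs) and np.all(diffs > 0.25 * depth / len(diffs)):
        raise EstimationError("monotone increasing profile: no particle")
    level = interior[i_min] + depth / 2.0
    below = intens < level
    crossings = np.flatnonzero(below[:-1] & ~below[1:])
    if len(crossings) == 0:
        raise EstimationError("profile never recrosses the half-depth level")
    j = int(crossings[-1])  # outermost upward crossing
    r0, r1 = radii[j], radii[j + 1]
    v0, v1 = intens[j], intens[j + 1]
    r_edge = r0 + (level - v0) / (v1 - v0) * (r1 - r0)
    return 2.0 * float(r_edge)


@dataclass(frozen=True)
class PatternMeasurement:
    """Distances from one pattern center to its surrounding satellites."""

    center_instance_id: int
    satellite_ids: tuple[int, ...]
    distances_nm: tuple[float, ...]
    mean_nm: float | None
    sd_nm: float | None  # defined only for >= 2 satellites


def pattern_distances(records, center_class: BarcodeClass = BarcodeClass.QT_1M,
                      satellite_class: BarcodeClass = BarcodeClass.TM_1M,
                      r_search_nm: float = 120.0,
                      scale: PixelScale | None = None
                      ) -> list[PatternMeasurement]:
    """Center-to-center distances from each center-class instance.

    ``records`` is any iterable of objects with ``id``, ``class_id`` and
    ``centroid``/``center_px`` (row, col in px) attributes -- instance
    records or simulator ground-truth instances both qualify.  Satellites
    are satellite-class instances within ``r_search_nm``.
    """
    scale = scale or PixelScale()

    def center_of(r):
        c = getattr(r, "centroid", None)
        if c is None:
            c = r.center_px
        return np.asarray(c, float)

    def cls_of(r):
        return int(r.class_id)

    centers = [r for r in records if cls_of(r) == int(center_class)]
    sats = [r for r in records if cls_of(r) == int(satellite_class)]
    out = []
    for c in centers:
        cpos = center_of(c)
        ids, dists = [], []
        for s in sats:
            d_nm = float(np.hypot(*(center_of(s) - cpos))) * scale.nm_per_pixel
            if 0 < d_nm <= r_search_nm:
                ids.append(s.id)
                dists.append(d_nm)
        mean = float(np.mean(dists)) if dists else None
        sd = float(np.std(dists, ddof=1)) if len(dists) >= 2 else None
        out.append(PatternMeasurement(c.id, tuple(ids), tuple(dists), mean, sd))
    return out
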