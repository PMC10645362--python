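"""Disc-diffusion image analysis: radial profiles, ZOI and formazan ring.

On an MTT-supplemented lawn, the tetrazolium dye is reduced to dark
insoluble formazan wherever cells respire hard. Around a bactericidal
antibiotic disk this produces a characteristic dark ring just outside the
zone of inhibition (ZOI) — the sub-MIC band where survivors upshift
respiration. The analysis isolates the green channel, removes smooth
background, applies a linear contrast stretch, and averages intensity
over 1-px annuli outward from the disk edge; the ZOI boundary is where
the profile first recovers toward the lawn plateau, and the formazan
ring is the deepest prominent minimum beyond it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .types import PlateImage

logger = logging.getLogger(__name__)

__all__ = ["RadialProfile", "radial_profile", "detect_zoi",
           "detect_formazan_ring", "find_disk"]


@dataclass
class RadialProfile:
    """Mean processed green-channel intensity vs distance from the disk edge.

    ``distances`` are annulus centers in pixels from the disk *edge*
    (``distances_cm`` available when ``px_per_cm`` is known);
    ``zoi_boundary`` and ``ring_distance`` are filled in by
    :func:`detect_zoi` / :func:`detect_formazan_ring`.
    """

    distances: np.ndarray
    intensity: np.ndarray
    disk_center: tuple[float, float]
    disk_radius_px: float
    px_per_cm: float | None = None
    zoi_boundary: float | None = None
    zoi_defined: bool = True
    ring_distance: float | None = None

    @property
    def distances_cm(self) -> np.ndarray:
        if not self.px_per_cm:
            raise ValueError("px_per_cm not set")
        return self.distances / self.px_per_cm

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"distance_px": self.distances,
                             "intensity": self.intensity})


def _subtract_background(green: np.ndarray, radius: int) -> np.ndarray:
    """Rolling-ball-style background removal via greyscale opening.

    The background is the morphological opening of the image with a flat
    structuring element of half-width ``radius`` (separable min-then-max
    filters) — the flat-ball analogue of the classic rolling-ball
    estimator. With ``radius`` much larger than the ring width this
    removes constant offsets and smooth illumination without touching
    the ring or the ZOI step.
    """
    size = 2 * radius + 1
    background = ndimage.maximum_filter(
        ndimage.minimum_filter(green, size=size), size=size)
    return green - background


def _enhance_contrast(img: np.ndarray, saturated: float = 0.35) -> np.ndarray:
    """Linear stretch saturating ``saturated`` percent of pixels total.

    Maps the (saturated/2)-th and (100 - saturated/2)-th percentiles to 0
    and 255, clipping beyond — the common default behaviour of
    histogram-based contrast enhancement.
    """
    lo, hi = np.percentile(img, [saturated / 2.0, 100.0 - saturated / 2.0])
    if hi <= lo:
        return np.zeros_like(img, dtype=float)
    return np.clip((img - lo) * (255.0 / (hi - lo)), 0.0, 255.0)


def find_disk(image: PlateImage, approx_radius: float | None = None
              ) -> tuple[tuple[float, float], float]:
    """Locate the antibiotic disk as the brightest compact blob.

    The paper disk scatters light and is the brightest object on the
    plate; its center is the intensity centroid of the top-percentile
    pixels and its radius follows from their area. Adequate for
    single-disk plates; pass an explicit annotation for anything else.
    """
    green = image.green
    blob = green >= np.percentile(green, 99.0)
    lab, n = ndimage.label(blob)
    if n == 0:
        raise ValueError("no disk-like bright region found")
    sizes = ndimage.sum_labels(blob, lab, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    ys, xs = np.nonzero(lab == biggest)
    cy, cx = float(ys.mean()), float(xs.mean())
    # refine the radius with a half-max threshold between the lawn level
    # (image median) and the disk plateau, which is unbiased unlike the
    # percentile cut used to find the blob
    half = 0.5 * (float(np.median(green)) + float(green[ys, xs].mean()))
    lab2, n2 = ndimage.label(green >= half)
    disk_label = lab2[int(round(cy)), int(round(cx))]
    area = int(np.sum(lab2 == disk_label)) if disk_label else len(ys)
    radius = float(np.sqrt(area / np.pi))
    if approx_radius is not None:
        radius = approx_radius
    return (cx, cy), radius


def radial_profile(image: PlateImage, disk_center: tuple[float, float],
                   disk_radius_px: float, max_dist: float | None = None,
                   *, background_radius: int = 150, saturated: float = 0.35,
                   mode: str = "annulus", ray_angle_deg: float = 0.0,
                   edge_margin: float = 2.0) -> RadialProfile:
    """Green-channel intensity vs distance from the antibiotic disk edge.

    The green channel is isolated, background-subtracted
    (:func:`_subtract_background`), contrast-stretched
    (:func:`_enhance_contrast`), and averaged over annuli of 1-px width
    from the disk edge outward to ``max_dist`` (default: the largest
    fully-sampled distance). The first ``edge_margin`` pixels are
    skipped so the paper disk's bright rim does not leak into the
    profile; distances remain measured from the disk edge.

    ``mode="ray"`` instead samples a single ray at ``ray_angle_deg`` —
    the direct analogue of a line-profile measurement — at the cost of
    azimuthal averaging.
    """
    h, w = image.pixels.shape[:2]
    cx, cy = disk_center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("disk center outside image")
    if (cx - disk_radius_px < 0 or cx + disk_radius_px >= w
            or cy - disk_radius_px < 0 or cy + disk_radius_px >= h):
        raise ValueError("disk not fully inside image")

    green = _subtract_background(image.green, background_radius)
    green = _enhance_contrast(green, saturated)

    if max_dist is None:
        max_dist = min(cx, cy, w - 1 - cx, h - 1 - cy) - disk_radius_px
    max_dist = float(max_dist)
    if max_dist < 2:
        raise ValueError("no room beyond the disk for a profile")

    if mode == "ray":
        ang = np.deg2rad(ray_angle_deg)
        d = np.arange(edge_margin, max_dist, 1.0)
        xs = cx + (disk_radius_px + d) * np.cos(ang)
        ys = cy + (disk_radius_px + d) * np.sin(ang)
        vals = ndimage.map_coordinates(green, [ys, xs], order=1)
        return RadialProfile(distances=d + 0.5, intensity=vals,
                             disk_center=(cx, cy), disk_radius_px=disk_radius_px,
                             px_per_cm=image.px_per_cm)
    if mode != "annulus":
        raise ValueError(f"unknown profile mode {mode!r}")

    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - cx, yy - cy) - disk_radius_px
    sel = (r >= edge_margin) & (r < max_dist)
    bins = np.floor(r[sel]).astype(int)
    sums = np.bincount(bins, weights=green[sel])
    counts = np.bincount(bins)
    valid = counts > 0
    intensity = sums[valid] / counts[valid]
    distances = np.arange(len(counts))[valid] + 0.5
    return RadialProfile(distances=distances.astype(float), intensity=intensity,
                         disk_center=(cx, cy), disk_radius_px=disk_radius_px,
                         px_per_cm=image.px_per_cm)


def detect_zoi(profile: RadialProfile, frac: float = 0.5,
               plateau_frac: float = 0.2, min_plateau: float = 1.0) -> float | None:
    """Distance (from the disk edge) where growth first becomes visible.

    The far-field plateau is the median of the outer ``plateau_frac`` of
    bins; the ZOI boundary is the smallest distance where intensity first
    exceeds ``frac`` times that plateau. Sets ``zoi_boundary`` and
    ``zoi_defined`` on the profile. A profile whose plateau is darker
    than ``min_plateau`` (no lawn grew, or inhibition everywhere) leaves
    the ZOI undefined.
    """
    n = profile.intensity.size
    if n < 10:
        raise ValueError("profile too short to locate a ZOI boundary")
    tail = profile.intensity[int(np.ceil(n * (1 - plateau_frac))):]
    plateau = float(np.median(tail))
    if plateau < min_plateau:
        profile.zoi_boundary = None
        profile.zoi_defined = False
        logger.warning("detect_zoi: plateau %.2f below %.2f; ZOI undefined",
                       plateau, min_plateau)
        return None
    above = profile.intensity > frac * plateau
    if not above.any():
        profile.zoi_boundary = None
        profile.zoi_defined = False
        return None
    first = int(np.argmax(above))
    # a profile already above threshold at the disk edge means no inhibition
    boundary = 0.0 if first == 0 else float(profile.distances[first])
    profile.zoi_boundary = boundary
    profile.zoi_defined = True
    return boundary


def detect_formazan_ring(profile: RadialProfile, min_depth: float = 10.0,
                         plateau_frac: float = 0.2) -> float | None:
    """Locate the formazan ring: deepest local minimum beyond the ZOI.

    Candidate minima are interior local minima of the beyond-ZOI
    profile; the ring is the one with the greatest depth below the
    far-field plateau (median of the outer ``plateau_frac`` of bins),
    provided that depth exceeds ``min_depth`` intensity units. Depth is
    measured against the plateau rather than as two-sided peak
    prominence because a ring hugging the ZOI periphery has its inner
    flank swallowed by the inhibition step while remaining a real,
    well-localized minimum. Returns ``None`` when no qualifying minimum
    exists (e.g. a bacteriostatic drug that never upshifts respiration).
    """
    if not profile.zoi_defined or profile.zoi_boundary is None:
        raise ValueError("detect_formazan_ring requires a detected ZOI")
    beyond = profile.distances > profile.zoi_boundary
    if beyond.sum() < 3:
        profile.ring_distance = None
        return None
    y = profile.intensity[beyond]
    d = profile.distances[beyond]
    n = profile.intensity.size
    plateau = float(np.median(
        profile.intensity[int(np.ceil(n * (1 - plateau_frac))):]))
    minima, _ = signal.find_peaks(-y)  # interior local minima, any size
    if minima.size == 0:
        profile.ring_distance = None
        return None
    depths = plateau - y[minima]
    best = int(np.argmax(depths))
    if depths[best] < min_depth:
        profile.ring_distance = None
        return None
    profile.ring_distance = float(d[minima[best]])
    return profile.ring_distance
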