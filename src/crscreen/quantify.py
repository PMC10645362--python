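"""Per-colony quantification of pinned-array plate scans.

The screen images a Congo Red agar plate carrying a regular grid of
pinned colonies (1536-density: 32 x 48). Two numbers are extracted per
position:

``growth``
    colony density — background-subtracted mean foreground intensity
    weighted by the colony's effective area relative to the nominal
    colony footprint, so the statistic is monotone in both colony size
    and opacity. Equivalently the integrated background-subtracted
    intensity over the measurement window divided by ``pi * r^2``.
``red_intensity``
    mean red-channel value inside the colony mask, background-subtracted
    — the Congo Red binding readout.

Grid finding projects foreground intensity onto the image axes and fits
a regular line spacing to the periodic peaks, so individual missing
colonies do not perturb their neighbours' centers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

from .types import GridGeometry, GridNotFound, PlateImage

logger = logging.getLogger(__name__)

__all__ = ["locate_grid", "measure_colonies", "estimate_background"]

# presence requires at least this fraction of the window above threshold
PRESENCE_MIN_FRACTION = 0.05
# minimum threshold offset above background, in intensity units
MIN_THRESHOLD_OFFSET = 8.0


def _density_channel(image: PlateImage) -> np.ndarray:
    """Channel used for grid finding and colony density (green).

    Congo Red staining moves colonies mainly in the red channel; green
    tracks biomass for stained and unstained colonies alike.
    """
    return image.green


def _fit_grid_lines(profile: np.ndarray, n_lines: int) -> np.ndarray:
    """Positions of ``n_lines`` equally spaced lines from a 1-D projection.

    Finds periodic peaks, fits position ~ offset + spacing * index by
    least squares (robust to a few missing peaks via rounding of the
    index), and returns the full line set.
    """
    if n_lines == 1:
        # single line: centroid of the profile
        w = profile - profile.min()
        if w.sum() <= 0:
            raise GridNotFound("no foreground signal in projection")
        return np.array([float(np.arange(profile.size) @ w / w.sum())])

    smooth = ndimage.uniform_filter1d(profile.astype(float), size=3)
    est_spacing = profile.size / (n_lines + 1)
    prominence = 0.05 * (smooth.max() - np.median(smooth))
    if prominence <= 0:
        raise GridNotFound("projection is flat; no colonies detected")
    peaks, props = signal.find_peaks(
        smooth, distance=max(2, int(0.6 * est_spacing)), prominence=prominence)
    if peaks.size < max(2, n_lines // 2):
        raise GridNotFound(
            f"only {peaks.size} projection peaks found for {n_lines} grid lines")
    if peaks.size > n_lines:
        keep = np.argsort(props["prominences"])[-n_lines:]
        peaks = np.sort(peaks[keep])

    # subpixel refinement: intensity centroid around each peak
    half = max(2, int(0.3 * est_spacing))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(profile.size, p + half + 1)
        seg = smooth[lo:hi] - smooth[lo:hi].min()
        if seg.sum() > 0:
            refined.append(lo + float(np.arange(hi - lo) @ seg / seg.sum()))
        else:
            refined.append(float(p))
    pk = np.asarray(refined)

    spacing = float(np.median(np.diff(pk)))
    if spacing <= 0:
        raise GridNotFound("could not estimate grid spacing")
    idx = np.round((pk - pk[0]) / spacing)
    A = np.vstack([np.ones_like(idx), idx]).T
    (offset, spacing), *_ = np.linalg.lstsq(A, pk, rcond=None)
    # anchor the full line set so detected peaks map inside [0, n_lines)
    start = int(np.round(-min(0, idx.min())))
    lines = offset + spacing * (np.arange(n_lines) - start)
    return lines


def locate_grid(image: PlateImage) -> GridGeometry:
    """Locate the colony grid by axis projections of foreground intensity.

    Returns one center per expected grid position (missing colonies get
    the position implied by the fitted line spacing). Raises
    :class:`GridNotFound` when fewer than the required periodic peaks are
    detectable, e.g. on a blank image.
    """
    gray = _density_channel(image)
    floor = np.percentile(gray, 20)
    fg = np.clip(gray - floor, 0, None)
    xs = _fit_grid_lines(fg.sum(axis=0), image.grid_cols)
    ys = _fit_grid_lines(fg.sum(axis=1), image.grid_rows)
    h, w = gray.shape
    if xs.min() < 0 or xs.max() >= w or ys.min() < 0 or ys.max() >= h:
        raise GridNotFound("fitted grid extends outside the image")

    spacings = []
    if len(xs) > 1:
        spacings.append(np.median(np.diff(xs)))
    if len(ys) > 1:
        spacings.append(np.median(np.diff(ys)))
    mean_spacing = float(np.mean(spacings)) if spacings else float(min(h, w))

    centers = {(i, j): (float(xs[j]), float(ys[i]))
               for i in range(image.grid_rows) for j in range(image.grid_cols)}
    radius = _estimate_colony_radius(gray, centers, mean_spacing)
    geom = GridGeometry(centers=centers, mean_spacing_px=mean_spacing,
                        colony_radius_px=radius,
                        n_rows=image.grid_rows, n_cols=image.grid_cols)
    geom.validate(image)
    return geom


def _estimate_colony_radius(gray: np.ndarray, centers: dict,
                            spacing: float) -> float:
    """Median per-position colony area, converted to a disk radius.

    The area of each colony is estimated coverage-weighted — integrated
    background-subtracted intensity divided by the colony's plateau
    level — which counts anti-aliased edge pixels fractionally and so
    recovers the true disk area, not the binary pixel count.
    """
    win = max(3, int(np.floor(spacing / 2)) - 1)
    bg = float(np.percentile(gray, 20))
    areas = []
    h, w = gray.shape
    for (cy, cx) in ((y, x) for (x, y) in centers.values()):
        y0, y1 = int(round(cy)) - win, int(round(cy)) + win + 1
        x0, x1 = int(round(cx)) - win, int(round(cx)) + win + 1
        if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
            continue
        window = gray[y0:y1, x0:x1].astype(float)
        t = bg + 0.5 * (window.max() - bg)
        fg = window[window > t]
        if fg.size < 4:
            continue  # likely a missing colony
        level = float(np.median(fg))
        if level <= bg:
            continue
        areas.append(np.clip(window - bg, 0, None).sum() / (level - bg))
    if not areas:
        raise GridNotFound("no in-bounds positions for radius estimation")
    area = float(np.median(areas))
    radius = float(np.sqrt(max(area, 1.0) / np.pi))
    return min(radius, 0.45 * spacing)


def estimate_background(image: PlateImage, grid: GridGeometry,
                        channel: str = "green") -> float:
    """Median pixel value of the inter-colony (agar) region, per channel."""
    return background_stats(image, grid, channel)[0]


def background_stats(image: PlateImage, grid: GridGeometry,
                     channel: str = "green") -> tuple[float, float]:
    """Median and robust (MAD-based) sd of the inter-colony agar region."""
    gray = getattr(image, channel)
    h, w = gray.shape
    occupied = np.zeros((h, w), dtype=bool)
    r = int(np.ceil(grid.colony_radius_px)) + 2
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (yy ** 2 + xx ** 2) <= r ** 2
    for (x, y) in grid.centers.values():
        cy, cx = int(round(y)), int(round(x))
        y0, y1 = max(0, cy - r), min(h, cy + r + 1)
        x0, x1 = max(0, cx - r), min(w, cx + r + 1)
        occupied[y0:y1, x0:x1] |= disk[(y0 - cy + r):(y1 - cy + r),
                                       (x0 - cx + r):(x1 - cx + r)]
    agar = gray[~occupied]
    if agar.size == 0:
        # dense grid with no agar left between windows; fall back
        agar = gray
    med = float(np.median(agar))
    mad = float(np.median(np.abs(agar - med)))
    return med, 1.4826 * mad


def measure_colonies(image: PlateImage, grid: GridGeometry,
                     layout: dict[tuple[int, int], str] | None = None,
                     *, window_margin: int = 2) -> pd.DataFrame:
    """Measure growth density and Congo Red intensity at every grid position.

    Parameters
    ----------
    image, grid
        The plate scan and its located grid.
    layout
        Optional ``(row, col) -> strain`` map; unmapped positions get a
        positional placeholder name.
    window_margin
        Extra pixels of the measurement window beyond the colony radius
        (the margin admits local agar so in-window thresholding sees both
        classes).

    Returns
    -------
    DataFrame
        One record per grid position with columns plate_id, condition,
        replicate, row, col, strain, growth, red_intensity, present.
        Absent positions have growth = red_intensity = 0.
    """
    gray = _density_channel(image)
    red = image.red
    bg_gray, noise_sd = background_stats(image, grid, "green")
    bg_red, _ = background_stats(image, grid, "red")
    threshold_floor = max(MIN_THRESHOLD_OFFSET, 4.0 * noise_sd)
    r_nominal = grid.colony_radius_px
    nominal_area = np.pi * r_nominal ** 2
    win_r = r_nominal + window_margin
    wi = int(np.ceil(win_r))
    yy, xx = np.mgrid[-wi:wi + 1, -wi:wi + 1]
    in_window = np.hypot(yy, xx) <= win_r
    h, w = gray.shape

    records = []
    for (i, j), (cx, cy) in sorted(grid.centers.items()):
        cyi, cxi = int(round(cy)), int(round(cx))
        y0, y1 = cyi - wi, cyi + wi + 1
        x0, x1 = cxi - wi, cxi + wi + 1
        strain = (layout or {}).get((i, j), f"pos_r{i:02d}c{j:02d}")
        rec = {"plate_id": image.plate_id, "condition": image.condition,
               "replicate": image.replicate_id, "row": i, "col": j,
               "strain": strain, "growth": 0.0, "red_intensity": 0.0,
               "present": False}
        if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
            records.append(rec)  # degenerate window at the image border
            continue
        gwin = gray[y0:y1, x0:x1][in_window]
        rwin = red[y0:y1, x0:x1][in_window]
        t = _local_threshold(gwin, bg_gray, threshold_floor)
        mask = gwin >= t
        frac = mask.mean()
        if frac < PRESENCE_MIN_FRACTION:
            records.append(rec)
            continue
        # interior (mask eroded by ~1 px) for unbiased intensity means
        mask2d = np.zeros_like(in_window)
        mask2d[in_window] = mask
        interior2d = ndimage.binary_erosion(mask2d)
        interior = interior2d[in_window]
        if not interior.any():
            interior = mask
        mean_gray = float(gwin[interior].mean())
        mean_red = float(rwin[interior].mean())
        # effective (coverage-weighted) colony area relative to the
        # nominal footprint; exact for anti-aliased flat-top colonies
        integrated = float(np.clip(gwin - bg_gray, 0, None).sum())
        area_fraction = integrated / max(mean_gray - bg_gray, 1e-9) / nominal_area
        rec["growth"] = max(mean_gray - bg_gray, 0.0) * area_fraction
        rec["red_intensity"] = max(mean_red - bg_red, 0.0)
        rec["present"] = True
        records.append(rec)
    return pd.DataFrame(records)


def _local_threshold(window: np.ndarray, background: float,
                     floor: float = MIN_THRESHOLD_OFFSET) -> float:
    """Foreground threshold for one measurement window.

    Otsu when the window shows real contrast (colony and agar both in
    view); otherwise the midpoint between the plate background and the
    window maximum — which classifies an all-colony window entirely as
    foreground and an all-agar window entirely as background. Always at
    least ``floor`` (several noise sigmas) above the plate background so
    pixel noise cannot fabricate colonies.
    """
    lo, hi = float(window.min()), float(window.max())
    t = None
    if hi - lo > 4 * floor:
        try:
            t = float(threshold_otsu(window))
        except ValueError:
            t = None
    if t is None or t <= background + floor:
        t = background + max(floor, 0.5 * (hi - background))
    return t
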