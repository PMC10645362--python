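"""Synthetic inputs with ground truth for every stage of the pipeline.

Four generators emulate the screen's data sources:

* :func:`generate_plate_image` — an RGB scan of a pinned colony array on
  Congo Red agar, with separable multiplicative row x column position
  effects, planted stimulation-deficient mutants (reduced red channel),
  missing colonies and pixel noise, plus a ground-truth table.
* :func:`generate_screen_pair` — two replicate plates sharing planted-hit
  identities but with independent noise and missing-colony draws, mirroring
  a duplicate screen pinned from two source plates.
* :func:`generate_screen_tables` — the same replicate structure at the
  colony-value level (no rendering), for large multi-plate screens.
* :func:`generate_dose_response` — a 96-well peg-lid table in which biofilm
  peaks at sub-MIC antibiotic concentrations while planktonic growth
  declines sigmoidally, optionally with nitrate suppression of the peak.
* :func:`generate_disc_image` — a disc-diffusion plate's green channel with
  a zone of inhibition and an optional dark formazan ring at its periphery.

Every generator is driven by a single integer seed and is bit-reproducible.

Closed forms (used verbatim by the noise-free re-evaluation tests)
------------------------------------------------------------------
Dose response, concentration ``c`` of a 2x dilution series::

    growth(c)  = g0 / (1 + (c / mic) ** hill_growth)
    biofilm(c) = b0 * (1 + A * exp(-(log2(c / (peak_frac * mic)))**2
                                   / (2 * stim_width**2)))
    A = stim_amplitude * (nitrate_suppression if nitrate else 1)

with ``growth(0) = g0`` and ``biofilm(0) = b0`` for vehicle wells; blank
(media) offsets are added to every well including sterility controls.

Disc image, radius ``r`` from the disk center::

    green(r) = disk_level                              r <  disk_radius
             = inhibition_level                        r <  zoi_radius
             = lawn_intensity                          r >= zoi_radius
    green(r) -= ring_depth * exp(-(r - ring_radius)**2 / (2 * ring_width**2))

with 1-px anti-aliasing at each boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .types import PlateImage

__all__ = [
    "PlateSpec", "DoseSpec", "DiscSpec",
    "generate_plate_image", "generate_screen_pair", "generate_screen_tables",
    "generate_dose_response", "generate_disc_image",
]

MAX_IMAGE_SIDE = 8192  # rendered plates larger than this are rejected


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class PlateSpec:
    """Parameters of a synthetic colony-array plate.

    Intensities are on the 8-bit scale: ``base_growth`` is the mean
    colony foreground level above background, ``base_redness`` the mean
    red-channel excess over background. ``row_gradient`` /
    ``col_gradient`` are per-line multiplicative position effects
    (length ``grid_rows`` / ``grid_cols``; ``None`` means flat).
    ``planted_hits`` maps a (row, col) position to a
    ``(redness_multiplier, growth_multiplier)`` pair — a
    stimulation-deficient mutant has redness_multiplier << 1 with
    growth_multiplier near 1.
    """

    grid_rows: int = 32
    grid_cols: int = 48
    spacing_px: int = 20
    colony_radius_px: float = 7.0
    base_growth: float = 150.0
    base_redness: float = 170.0
    background: float = 30.0
    row_gradient: np.ndarray | None = None
    col_gradient: np.ndarray | None = None
    planted_hits: dict = field(default_factory=dict)
    missing_prob: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows * self.grid_cols < 1:
            raise ValueError("grid must have at least one position")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError("missing_prob must lie in [0, 1]")
        for name in ("row_gradient", "col_gradient"):
            g = getattr(self, name)
            if g is not None:
                g = np.asarray(g, dtype=float)
                expected = self.grid_rows if name == "row_gradient" else self.grid_cols
                if g.shape != (expected,):
                    raise ValueError(f"{name} must have length {expected}")
                if not (g > 0).all():
                    raise ValueError(f"{name} factors must be > 0")
                setattr(self, name, g)
        for pos, (rm, gm) in dict(self.planted_hits).items():
            if rm <= 0 or gm <= 0:
                raise ValueError(f"planted multiplier at {pos} must be > 0")

    def margins(self) -> int:
        return int(self.spacing_px)

    def image_shape(self) -> tuple[int, int]:
        h = 2 * self.margins() + (self.grid_rows - 1) * self.spacing_px + 1
        w = 2 * self.margins() + (self.grid_cols - 1) * self.spacing_px + 1
        return h, w


@dataclass
class DoseSpec:
    """Parameters of a synthetic peg-lid dose-response experiment.

    ``mic`` sets the growth-inhibition midpoint; biofilm peaks at
    ``peak_frac * mic`` with fold increase ``stim_amplitude`` over the
    untreated baseline and log2-concentration width ``stim_width``.
    ``nitrate_suppression`` multiplies the stimulation amplitude when the
    nitrate flag is set (0.2 means the peak shrinks to 20%).
    """

    mic: float = 1.0
    hill_growth: float = 4.0
    peak_frac: float = 0.25
    stim_amplitude: float = 3.0
    stim_width: float = 1.0
    n_dilutions: int = 8
    replicate_cv: float = 0.05
    nitrate_suppression: float = 0.2
    n_replicates: int = 3
    top_dose_factor: float = 2.0
    baseline_od: float = 0.5
    baseline_biofilm: float = 0.25
    blank_od: float = 0.04
    blank_biofilm: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.mic <= 0:
            raise ValueError("mic must be > 0")
        if not 0.0 < self.peak_frac < 1.0:
            raise ValueError("peak_frac must lie in (0, 1)")
        if self.stim_amplitude < 0:
            raise ValueError("stim_amplitude must be >= 0")
        if self.n_dilutions < 2:
            raise ValueError("need at least 2 dilutions")

    def concentrations(self) -> np.ndarray:
        """The 2x serial dilution series, highest dose first."""
        top = self.top_dose_factor * self.mic
        return top * 2.0 ** (-np.arange(self.n_dilutions, dtype=float))

    def growth_curve(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.baseline_od / (1.0 + (c / self.mic) ** self.hill_growth)

    def biofilm_curve(self, c: np.ndarray, nitrate: bool = False) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        amp = self.stim_amplitude * (self.nitrate_suppression if nitrate else 1.0)
        out = np.full(c.shape, self.baseline_biofilm)
        pos = c > 0
        z = np.log2(c[pos] / (self.peak_frac * self.mic))
        out[pos] = self.baseline_biofilm * (
            1.0 + amp * np.exp(-z ** 2 / (2.0 * self.stim_width ** 2)))
        return out


@dataclass
class DiscSpec:
    """Parameters of a synthetic disc-diffusion plate (green channel).

    The zone of inhibition (near-zero lawn signal) extends from the disk
    out to ``zoi_radius_px``; a Gaussian dark ring of depth ``ring_depth``
    and width ``ring_width_px`` sits at ``ring_radius_px``, by
    construction at the ZOI periphery. ``ring_depth = 0`` disables the
    ring (a bacteriostatic-drug-like plate).
    """

    disk_radius_px: float = 25.0
    zoi_radius_px: float = 100.0
    ring_radius_px: float = 110.0
    ring_width_px: float = 6.0
    ring_depth: float = 60.0
    lawn_intensity: float = 150.0
    inhibition_level: float = 5.0
    disk_level: float = 220.0
    margin_px: int = 60
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.disk_radius_px >= self.ring_radius_px:
            raise ValueError("disk must be smaller than the ring radius")
        if self.zoi_radius_px <= self.disk_radius_px:
            raise ValueError("ZOI must extend beyond the disk")


# ---------------------------------------------------------------------------
# Colony-array plates
# ---------------------------------------------------------------------------

def _true_values(spec: PlateSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Per-position pre-noise ground truth (shared by image and table paths)."""
    rows = []
    rg = spec.row_gradient if spec.row_gradient is not None else np.ones(spec.grid_rows)
    cg = spec.col_gradient if spec.col_gradient is not None else np.ones(spec.grid_cols)
    present = rng.random((spec.grid_rows, spec.grid_cols)) >= spec.missing_prob
    for i in range(spec.grid_rows):
        for j in range(spec.grid_cols):
            rm, gm = spec.planted_hits.get((i, j), (1.0, 1.0))
            pos_factor = rg[i] * cg[j]
            rows.append({
                "row": i, "col": j,
                "strain_id": f"s{i * spec.grid_cols + j:05d}",
                "true_growth": spec.base_growth * pos_factor * gm,
                "true_redness": spec.base_redness * pos_factor * rm,
                "is_present": bool(present[i, j]),
                "is_planted_hit": (i, j) in spec.planted_hits,
                "true_enrichment": rm / gm,
            })
    return pd.DataFrame(rows)


def _disk_coverage(shape: tuple[int, int], cx: float, cy: float,
                   radius: float) -> np.ndarray:
    """Pixel coverage of a disk with a 1-px anti-aliased edge.

    coverage = clip(radius + 0.5 - dist, 0, 1); its integral equals the
    disk area pi r^2 to within a fraction of a percent, which is what
    makes integrated-intensity colony measurements exact.
    """
    h, w = shape
    y0 = max(0, int(np.floor(cy - radius - 2)))
    y1 = min(h, int(np.ceil(cy + radius + 3)))
    x0 = max(0, int(np.floor(cx - radius - 2)))
    x1 = min(w, int(np.ceil(cx + radius + 3)))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    cov = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    full = np.zeros(shape)
    full[y0:y1, x0:x1] = cov
    return full


def generate_plate_image(spec: PlateSpec, *, treated: bool = True,
                         plate_id: str = "synthetic", condition: str = "treated",
                         replicate_id: str = "rep1",
                         ) -> tuple[PlateImage, pd.DataFrame]:
    """Render a colony-array plate and return it with its ground truth.

    Each present position gets a flat-top disk whose red channel is
    ``background + true_redness`` and whose green/blue channels are
    ``background + true_growth`` (clipped to [0, 255]), with 1-px
    anti-aliased edges and optional additive Gaussian pixel noise.
    ``treated=False`` renders the vehicle plate: planted multipliers are
    ignored (an antibiotic-response mutant looks normal untreated) but
    remain flagged in the truth table.
    """
    h, w = spec.image_shape()
    if max(h, w) > MAX_IMAGE_SIDE:
        raise ValueError(f"rendered extent {h}x{w} exceeds {MAX_IMAGE_SIDE} px")
    rng = np.random.default_rng(spec.seed)
    truth = _true_values(spec, rng)
    if not treated:
        rg = spec.row_gradient if spec.row_gradient is not None else np.ones(spec.grid_rows)
        cg = spec.col_gradient if spec.col_gradient is not None else np.ones(spec.grid_cols)
        pos = rg[truth["row"].to_numpy()] * cg[truth["col"].to_numpy()]
        truth["true_growth"] = spec.base_growth * pos
        truth["true_redness"] = spec.base_redness * pos
        truth["true_enrichment"] = 1.0

    m = spec.margins()
    img = np.full((h, w, 3), spec.background, dtype=float)
    for rec in truth.itertuples():
        if not rec.is_present:
            continue
        cx = m + rec.col * spec.spacing_px
        cy = m + rec.row * spec.spacing_px
        cov = _disk_coverage((h, w), cx, cy, spec.colony_radius_px)
        img[..., 0] += rec.true_redness * cov
        img[..., 1] += rec.true_growth * cov
        img[..., 2] += rec.true_growth * cov
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    image = PlateImage(pixels=img, plate_id=plate_id, condition=condition,
                       replicate_id=replicate_id, grid_rows=spec.grid_rows,
                       grid_cols=spec.grid_cols)
    return image, truth


def generate_screen_pair(spec: PlateSpec, *, treated: bool = True,
                         plate_id: str = "synthetic", condition: str = "treated",
                         ) -> list[tuple[PlateImage, pd.DataFrame]]:
    """Two replicate plates with shared planted hits, independent noise.

    Replicate seeds are derived deterministically from ``spec.seed``
    (children of its SeedSequence), so the pair is reproducible as a
    unit while noise and missing-colony draws stay independent.
    """
    child_seeds = _child_seeds(spec.seed, 2)
    out = []
    for rep, s in enumerate(child_seeds, start=1):
        rspec = _with_seed(spec, s)
        out.append(generate_plate_image(
            rspec, treated=treated, plate_id=plate_id, condition=condition,
            replicate_id=f"rep{rep}"))
    return out


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def _with_seed(spec: PlateSpec, seed: int) -> PlateSpec:
    d = asdict(spec)
    d["seed"] = seed
    d["planted_hits"] = dict(spec.planted_hits)
    d["row_gradient"] = spec.row_gradient
    d["col_gradient"] = spec.col_gradient
    return PlateSpec(**d)


# ---------------------------------------------------------------------------
# Value-level replicate screens (no rendering)
# ---------------------------------------------------------------------------

def generate_screen_tables(n_strains: int = 3808, n_plants: int = 60,
                           plant_enrichment: float = 0.3,
                           plant_growth_multiplier: float = 1.0,
                           cv: float = 0.10, gradient_max: float = 1.5,
                           grid_rows: int = 32, grid_cols: int = 48,
                           base_growth: float = 150.0, base_redness: float = 170.0,
                           seed: int = 0,
                           ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two replicate ColonyTables for a multi-plate arrayed screen.

    Strains fill 1536-position plates row-major; each plate draws its own
    separable row x column gradients, with factors uniform in
    ``[1/gradient_max, gradient_max]``, shared between replicates (the
    position effect is a property of plate handling, not of the pinning
    draw). ``n_plants`` strains are planted with red intensity multiplied
    by ``plant_enrichment * plant_growth_multiplier`` and growth by
    ``plant_growth_multiplier``, so their true enrichment is
    ``plant_enrichment``. Measurement noise is multiplicative Gaussian
    with coefficient of variation ``cv``, independent per replicate.

    Returns ``(rep1, rep2, truth)`` where the replicate tables carry
    plate_id/row/col/strain/growth/red_intensity/present columns.
    """
    rng = np.random.default_rng(seed)
    per_plate = grid_rows * grid_cols
    n_plates = int(np.ceil(n_strains / per_plate))
    plant_idx = rng.choice(n_strains, size=n_plants, replace=False)
    is_plant = np.zeros(n_strains, dtype=bool)
    is_plant[plant_idx] = True

    reps: list[list[pd.DataFrame]] = [[], []]
    truth_rows = []
    for p in range(n_plates):
        lo, hi = p * per_plate, min((p + 1) * per_plate, n_strains)
        n_here = hi - lo
        row_g = rng.uniform(1.0 / gradient_max, gradient_max, size=grid_rows)
        col_g = rng.uniform(1.0 / gradient_max, gradient_max, size=grid_cols)
        idx = np.arange(per_plate)
        rows, cols = idx // grid_cols, idx % grid_cols
        present_strain = idx < n_here
        strain_ids = np.array([f"s{lo + k:05d}" if present_strain[k] else ""
                               for k in idx])
        plants_here = np.zeros(per_plate, dtype=bool)
        plants_here[:n_here] = is_plant[lo:hi]
        gm = np.where(plants_here, plant_growth_multiplier, 1.0)
        rm = np.where(plants_here, plant_enrichment * plant_growth_multiplier, 1.0)
        pos = row_g[rows] * col_g[cols]
        true_growth = np.where(present_strain, base_growth * pos * gm, np.nan)
        true_red = np.where(present_strain, base_redness * pos * rm, np.nan)
        for k in np.flatnonzero(present_strain):
            truth_rows.append({"strain_id": strain_ids[k],
                               "is_planted_hit": bool(plants_here[k]),
                               "true_enrichment": plant_enrichment if plants_here[k] else 1.0})
        for r in range(2):
            noise_g = 1.0 + cv * rng.standard_normal(per_plate)
            noise_r = 1.0 + cv * rng.standard_normal(per_plate)
            reps[r].append(pd.DataFrame({
                "plate_id": f"plate{p:02d}",
                "row": rows, "col": cols,
                "strain": strain_ids,
                "growth": np.where(present_strain, true_growth * noise_g, 0.0),
                "red_intensity": np.where(present_strain, true_red * noise_r, 0.0),
                "present": present_strain,
            }))
    rep1 = pd.concat(reps[0], ignore_index=True)
    rep2 = pd.concat(reps[1], ignore_index=True)
    return rep1, rep2, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Dose-response tables
# ---------------------------------------------------------------------------

def generate_dose_response(spec: DoseSpec, nitrate: bool = False,
                           strain: str = "WT", condition: str = "CEF",
                           ) -> pd.DataFrame:
    """A 96-well-style peg-lid plate-reader table for one dose response.

    Layout: ``n_replicates`` replicate rows (A, B, ...); the 2x dilution
    series across columns 1..n_dilutions, vehicle wells (concentration 0)
    in the next column, and a sterility-control row H holding blank media
    wells. OD600 carries the growth sigmoid, Abs600 (solubilized crystal
    violet) the biofilm stimulation curve; both include the media blank
    offsets that :func:`crscreen.assays.subtract_sterility` removes.
    """
    rng = np.random.default_rng(spec.seed)
    conc = spec.concentrations()
    cols = list(range(1, spec.n_dilutions + 2))  # last column = vehicle
    rows = [chr(ord("A") + i) for i in range(spec.n_replicates)]
    cond_label = f"{condition}+NO3" if nitrate else condition
    records = []
    for ri, rlab in enumerate(rows):
        for ci, cnum in enumerate(cols):
            c = conc[ci] if ci < spec.n_dilutions else 0.0
            od = spec.growth_curve(np.array([c]))[0]
            bf = spec.biofilm_curve(np.array([c]), nitrate=nitrate)[0]
            if spec.replicate_cv > 0:
                od *= 1.0 + spec.replicate_cv * rng.standard_normal()
                bf *= 1.0 + spec.replicate_cv * rng.standard_normal()
            records.append({
                "well_id": f"{rlab}{cnum}", "row": rlab, "col": cnum,
                "strain": strain, "condition": cond_label,
                "concentration": c,
                "od600": spec.blank_od + max(od, 0.0),
                "abs600_cv": spec.blank_biofilm + max(bf, 0.0),
                "gfp": np.nan, "mcherry": np.nan, "a546": np.nan,
                "is_sterility": False,
                "is_vehicle": ci >= spec.n_dilutions,
            })
    for cnum in cols:  # row H: sterile media + vehicle
        records.append({
            "well_id": f"H{cnum}", "row": "H", "col": cnum,
            "strain": "", "condition": cond_label, "concentration": 0.0,
            "od600": spec.blank_od, "abs600_cv": spec.blank_biofilm,
            "gfp": np.nan, "mcherry": np.nan, "a546": np.nan,
            "is_sterility": True, "is_vehicle": False,
        })
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Disc-diffusion images
# ---------------------------------------------------------------------------

def generate_disc_image(spec: DiscSpec) -> PlateImage:
    """Render a radially symmetric disc-diffusion plate.

    The green channel follows the closed form in the module docstring;
    red and blue are dimmed copies (the analysis uses green only). The
    disk center sits at the image center.
    """
    extent = int(np.ceil(max(spec.zoi_radius_px, spec.ring_radius_px)
                         + 4 * spec.ring_width_px + spec.margin_px))
    side = 2 * extent + 1
    c = float(extent)
    yy, xx = np.mgrid[0:side, 0:side]
    r = np.hypot(xx - c, yy - c)

    # anti-aliased radial steps: fraction of the pixel beyond each boundary
    beyond_zoi = np.clip(r - spec.zoi_radius_px + 0.5, 0.0, 1.0)
    on_disk = np.clip(spec.disk_radius_px + 0.5 - r, 0.0, 1.0)
    green = spec.inhibition_level + (spec.lawn_intensity - spec.inhibition_level) * beyond_zoi
    green = green * (1.0 - on_disk) + spec.disk_level * on_disk
    if spec.ring_depth > 0:
        green -= spec.ring_depth * np.exp(
            -(r - spec.ring_radius_px) ** 2 / (2.0 * spec.ring_width_px ** 2))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        green = green + rng.normal(0.0, spec.noise_sd, size=green.shape)
    green = np.clip(np.round(green), 0, 255)
    img = np.stack([0.6 * green, green, 0.5 * green], axis=-1)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return PlateImage(pixels=img, plate_id="disc", condition="disc",
                      grid_rows=1, grid_cols=1)
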