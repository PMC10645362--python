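"""Positional normalization, enrichment scoring, and replicate hit calling.

A pinned colony array carries strong positional artifacts: colonies near
plate edges see more nutrients and less competition, and pinning pressure
varies smoothly across the platen. Both growth and Congo Red (CR) binding
are therefore corrected per plate by dividing each colony's value by the
interquartile mean (IQM) of its column and then of its row, which exactly
cancels any separable multiplicative row x column effect while being robust
(the IQM trims the top and bottom quarters) to the very mutants the screen
is looking for.

The per-strain statistic is the *enrichment value*: normalized CR binding
divided by normalized growth. A typical colony sits near 1; a mutant that
grows normally but fails to produce dye-binding matrix falls well below 1.
Hits require concordance across two independent replicates, under either of
two rules:

``sd``
    enrichment at least ``k`` sample standard deviations below the replicate
    mean, in both replicates (default ``k = 2``).
``threshold``
    enrichment below ``enr_max`` in both replicates (default 0.5), with
    strains whose normalized growth falls below ``growth_min`` (default 0.2)
    excluded as likely small-colony false positives.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "iqm",
    "normalize_plate",
    "enrichment",
    "call_hits_sd",
    "call_hits_threshold",
    "intersect_hits",
    "export_replica_plot",
    "load_screen_table",
    "HitOverlap",
]


# ---------------------------------------------------------------------------
# Interquartile mean
# ---------------------------------------------------------------------------

def iqm(values, variant: str = "fractional") -> float:
    """Interquartile mean (25%-trimmed mean) of a sequence.

    Parameters
    ----------
    values
        Finite observations; must be non-empty. NaNs are rejected —
        exclude missing colonies before calling.
    variant
        ``"fractional"`` (default): sort, drop ``n/4`` observations from
        each end, giving fractional weight to the two boundary
        observations when ``n`` is not divisible by 4.  This is the
        standard IQM and the definition used throughout the package.
        ``"quartile_window"``: plain mean of the observations lying within
        ``[Q1, Q3]`` (linear-interpolation quartiles); differs from the
        fractional definition only at window boundaries.

    Returns
    -------
    float
        The trimmed mean. For a single observation this is the
        observation itself.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("iqm() of an empty sequence")
    if not np.isfinite(x).all():
        raise ValueError("iqm() requires finite values; drop missing colonies first")
    if variant == "quartile_window":
        q1, q3 = np.percentile(x, [25, 75])
        inside = x[(x >= q1) & (x <= q3)]
        # Degenerate only if floating-point puts every point outside; fall back.
        return float(inside.mean()) if inside.size else float(x.mean())
    if variant != "fractional":
        raise ValueError(f"unknown IQM variant: {variant!r}")

    n = x.size
    if n < 4:
        # Trimming n/4 < 1 from each end leaves fractional weights on the
        # extremes; the general formula below handles this, but for n < 4
        # it reduces to expressions dominated by the middle — compute it
        # through the same weighting for consistency.
        pass
    xs = np.sort(x)
    trim = n / 4.0
    g = int(np.floor(trim))
    frac = trim - g
    # Full-weight middle block xs[g+?]: indices g .. n-1-g carry weight 1,
    # except the two boundary points xs[g] and xs[n-1-g] which carry
    # weight (1 - frac).
    weights = np.zeros(n)
    weights[g : n - g] = 1.0
    if frac > 0:
        weights[g] = 1.0 - frac
        weights[n - 1 - g] = 1.0 - frac
    total = weights.sum()  # == n/2 for n >= 2
    return float(np.dot(weights, xs) / total)


# ---------------------------------------------------------------------------
# Plate normalization
# ---------------------------------------------------------------------------

MIN_PER_LINE = 4  # minimum present colonies for a row/column's own IQM


def _iqm_normalize_grid(values: np.ndarray, variant: str) -> tuple[np.ndarray, list[str]]:
    """Divide a 2-D value grid by column IQMs, then by row IQMs of the result.

    NaN entries (absent colonies) are ignored in every IQM and propagate
    unchanged. Rows/columns with fewer than MIN_PER_LINE present colonies
    fall back to the grid-wide IQM; each fallback is recorded.
    """
    vals = values.astype(float).copy()
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("normalize_plate: no present colonies on plate")
    flags: list[str] = []
    plate_iqm = iqm(vals[finite], variant=variant)

    col_factors = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        col = vals[:, j][finite[:, j]]
        if col.size >= MIN_PER_LINE:
            col_factors[j] = iqm(col, variant=variant)
        else:
            col_factors[j] = plate_iqm
            flags.append(f"col {j}: {col.size} present, plate-wide IQM used")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = vals / col_factors[np.newaxis, :]

    # Row IQMs of the column-normalized values; fallback re-derived on the
    # column-normalized grid so both passes live on the same scale.
    finite2 = np.isfinite(vals)
    plate_iqm2 = iqm(vals[finite2], variant=variant)
    row_factors = np.empty(vals.shape[0])
    for i in range(vals.shape[0]):
        row = vals[i, :][finite2[i, :]]
        if row.size >= MIN_PER_LINE:
            row_factors[i] = iqm(row, variant=variant)
        else:
            row_factors[i] = plate_iqm2
            flags.append(f"row {i}: {row.size} present, plate-wide IQM used")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = vals / row_factors[:, np.newaxis]
    return vals, flags


def normalize_plate(table: pd.DataFrame, variant: str = "fractional") -> pd.DataFrame:
    """Positionally normalize one plate's colony table and score enrichment.

    Parameters
    ----------
    table
        ColonyTable for a single plate: columns ``row``, ``col``,
        ``growth``, ``red_intensity``, ``present`` (and any identifier
        columns, which are carried through).
    variant
        IQM definition, see :func:`iqm`.

    Returns
    -------
    DataFrame
        Input columns plus ``norm_growth``, ``norm_cr`` and
        ``enrichment`` (= norm_cr / norm_growth; NaN where the colony is
        absent or normalized growth is not positive).

    Notes
    -----
    Each metric is divided by the IQM of its column and then by the row
    IQM of the column-normalized values. For a separable multiplicative
    position effect ``value(i, j) = r_i * c_j * v`` this cancels the
    gradients exactly, leaving a typical colony at 1.
    """
    required = {"row", "col", "growth", "red_intensity", "present"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ColonyTable missing columns: {sorted(missing)}")
    n_rows = int(table["row"].max()) + 1
    n_cols = int(table["col"].max()) + 1

    out = table.copy()
    grids = {}
    for metric in ("growth", "red_intensity"):
        grid = np.full((n_rows, n_cols), np.nan)
        r = table["row"].to_numpy(int)
        c = table["col"].to_numpy(int)
        v = table[metric].to_numpy(float)
        v = np.where(table["present"].to_numpy(bool), v, np.nan)
        grid[r, c] = v
        norm, flags = _iqm_normalize_grid(grid, variant)
        if flags:
            logger.warning("normalize_plate [%s]: plate-wide IQM fallback for %d "
                           "sparse rows/columns", metric, len(flags))
            for f in flags:
                logger.debug("normalize_plate [%s]: %s", metric, f)
        grids[metric] = norm

    r = out["row"].to_numpy(int)
    c = out["col"].to_numpy(int)
    out["norm_growth"] = grids["growth"][r, c]
    out["norm_cr"] = grids["red_intensity"][r, c]
    ng = out["norm_growth"].to_numpy(float)
    ncr = out["norm_cr"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        enr = np.where(ng > 0, ncr / ng, np.nan)
    n_bad = int(np.sum(~(ng > 0) & np.isfinite(ncr)))
    if n_bad:
        logger.warning("normalize_plate: %d colonies with non-positive normalized growth "
                       "flagged missing for enrichment", n_bad)
    out["enrichment"] = enr
    return out


def enrichment(norm_cr: float, norm_growth: float) -> float:
    """Enrichment value: normalized CR binding divided by normalized growth.

    Returns NaN (and logs) when normalized growth is not positive; such
    strains are dropped from hit calling.
    """
    if not norm_growth > 0:
        logger.warning("enrichment undefined for norm_growth=%r", norm_growth)
        return float("nan")
    return float(norm_cr) / float(norm_growth)


# ---------------------------------------------------------------------------
# Replicate merging and hit calling
# ---------------------------------------------------------------------------

_REP_COLS = ["enrichment_rep1", "enrichment_rep2", "norm_growth_rep1", "norm_growth_rep2"]


def pair_replicates(rep1: pd.DataFrame, rep2: pd.DataFrame) -> pd.DataFrame:
    """Merge two normalized colony tables into one strain-indexed table.

    Strains must appear once per replicate; absent colonies carry NaN and
    become "no-call" rows downstream.
    """
    def _strain_frame(t: pd.DataFrame, suffix: str) -> pd.DataFrame:
        f = t.set_index("strain")[["enrichment", "norm_growth"]]
        f.columns = [f"enrichment_{suffix}", f"norm_growth_{suffix}"]
        return f

    merged = _strain_frame(rep1, "rep1").join(_strain_frame(rep2, "rep2"), how="outer")
    return merged.reset_index()


def call_hits_sd(paired: pd.DataFrame, k: float = 2.0,
                 growth_min: float | None = None) -> pd.DataFrame:
    """Hit calling by the standard-deviation rule.

    A strain is a hit when its enrichment lies at least ``k`` sample
    standard deviations below the mean in *both* replicates. The mean and
    standard deviation are computed per replicate across all strains with
    finite enrichment (after any growth exclusion).

    Parameters
    ----------
    paired
        Output of :func:`pair_replicates` (columns ``strain`` plus the
        four replicate enrichment/growth columns).
    k
        Number of standard deviations; the screen used 2.
    growth_min
        Optional low-growth exclusion applied before computing the
        statistics (the threshold rule's ``growth_min``); ``None``
        disables it.

    Returns
    -------
    DataFrame
        ScreenResult: per strain, replicate values, ``excluded_low_growth``,
        ``no_call`` (missing in either replicate), ``is_hit`` and
        ``rule='sd'``.
    """
    out = paired.copy()
    e1 = out["enrichment_rep1"].to_numpy(float)
    e2 = out["enrichment_rep2"].to_numpy(float)
    g1 = out["norm_growth_rep1"].to_numpy(float)
    g2 = out["norm_growth_rep2"].to_numpy(float)

    no_call = ~(np.isfinite(e1) & np.isfinite(e2))
    if growth_min is not None:
        excluded = (g1 < growth_min) | (g2 < growth_min)
    else:
        excluded = np.zeros(len(out), dtype=bool)
    usable = ~no_call & ~excluded
    if usable.sum() < 3:
        raise ValueError("call_hits_sd: need >= 3 strains with finite enrichment "
                         "in both replicates")

    is_hit = np.zeros(len(out), dtype=bool)
    cuts = {}
    degenerate = False
    for rep, e in (("rep1", e1), ("rep2", e2)):
        mu = e[usable].mean()
        sd = e[usable].std(ddof=1)
        cuts[rep] = mu - k * sd
        if sd == 0:
            degenerate = True
    if degenerate:
        logger.warning("call_hits_sd: zero enrichment variance in a replicate; no hits called")
    else:
        is_hit = usable & (e1 <= cuts["rep1"]) & (e2 <= cuts["rep2"])

    out["excluded_low_growth"] = excluded
    out["no_call"] = no_call
    out["is_hit"] = is_hit
    out["rule"] = "sd"
    out.attrs["cutoffs"] = cuts
    return out


def call_hits_threshold(paired: pd.DataFrame, enr_max: float = 0.5,
                        growth_min: float = 0.2,
                        growth_rule: str = "either") -> pd.DataFrame:
    """Hit calling by fixed enrichment and growth thresholds.

    A strain is a hit when enrichment is below ``enr_max`` in both
    replicates and it is not excluded for low growth. ``growth_rule``
    selects the exclusion reading: ``"either"`` (default, conservative —
    excluded when normalized growth is below ``growth_min`` in either
    replicate) or ``"both"`` (excluded only when below in both).

    Strains missing from either replicate are "no-call", never hits.
    """
    if growth_rule not in ("either", "both"):
        raise ValueError(f"growth_rule must be 'either' or 'both', got {growth_rule!r}")
    out = paired.copy()
    e1 = out["enrichment_rep1"].to_numpy(float)
    e2 = out["enrichment_rep2"].to_numpy(float)
    g1 = out["norm_growth_rep1"].to_numpy(float)
    g2 = out["norm_growth_rep2"].to_numpy(float)

    no_call = ~(np.isfinite(e1) & np.isfinite(e2))
    low1 = g1 < growth_min
    low2 = g2 < growth_min
    excluded = (low1 | low2) if growth_rule == "either" else (low1 & low2)
    with np.errstate(invalid="ignore"):
        is_hit = ~no_call & ~excluded & (e1 < enr_max) & (e2 < enr_max)

    out["excluded_low_growth"] = excluded
    out["no_call"] = no_call
    out["is_hit"] = is_hit
    out["rule"] = "threshold"
    return out


# ---------------------------------------------------------------------------
# Hit-set intersection (Venn arithmetic)
# ---------------------------------------------------------------------------

@dataclass
class HitOverlap:
    """Exclusive Venn-region counts over per-antibiotic hit sets.

    ``regions`` maps each nonempty antibiotic subset (a sorted tuple) to
    the set of strains that are hits for exactly those antibiotics.
    """

    hit_sets: dict[str, set[str]]
    regions: dict[tuple[str, ...], set[str]] = field(default_factory=dict)

    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"antibiotics": "&".join(k), "n_strains": len(v),
             "strains": ";".join(sorted(v))}
            for k, v in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), kv[0]))
        ]
        return pd.DataFrame(rows, columns=["antibiotics", "n_strains", "strains"])


def intersect_hits(hit_sets: dict[str, set[str]]) -> HitOverlap:
    """Exclusive region counts for every nonempty subset of antibiotics.

    A strain in region ``(A, B)`` is a hit for A and B and for no other
    antibiotic in ``hit_sets`` (Venn semantics, so region counts sum to
    the size of the union of all hit sets).
    """
    if len(hit_sets) < 2:
        raise ValueError("intersect_hits requires >= 2 antibiotics")
    names = sorted(hit_sets)
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(names) + 1):
        for subset in itertools.combinations(names, r):
            inside = set.intersection(*(set(hit_sets[a]) for a in subset))
            outside = set.union(set(), *(set(hit_sets[a]) for a in names if a not in subset))
            regions[subset] = inside - outside
    return HitOverlap(hit_sets={k: set(v) for k, v in hit_sets.items()}, regions=regions)


# ---------------------------------------------------------------------------
# Replica plot
# ---------------------------------------------------------------------------

def export_replica_plot(result: pd.DataFrame, plot_path, table_path=None,
                        cap: float = 4.0, enr_max: float = 0.5):
    """Replica scatter of rep1 vs rep2 enrichment with marginal histograms.

    Points with enrichment above ``cap`` in either replicate are omitted
    from the *plot only* — the hit-region rectangle and the underlying
    table (written uncapped to ``table_path`` when given) always reflect
    the full data. Returns the number of plotted points.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    e1 = result["enrichment_rep1"].to_numpy(float)
    e2 = result["enrichment_rep2"].to_numpy(float)
    finite = np.isfinite(e1) & np.isfinite(e2)
    shown = finite & (e1 <= cap) & (e2 <= cap)

    fig = plt.figure(figsize=(6, 6))
    gs = fig.add_gridspec(2, 2, width_ratios=(4, 1), height_ratios=(1, 4),
                          wspace=0.05, hspace=0.05)
    ax = fig.add_subplot(gs[1, 0])
    ax_hx = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_hy = fig.add_subplot(gs[1, 1], sharey=ax)
    ax.scatter(e1[shown], e2[shown], s=6, alpha=0.5, color="0.2", linewidths=0)
    is_hit = result.get("is_hit")
    if is_hit is not None:
        h = is_hit.to_numpy(bool) & shown
        ax.scatter(e1[h], e2[h], s=10, color="crimson", linewidths=0)
    import matplotlib.patches as mpatches
    ax.add_patch(mpatches.Rectangle((0, 0), enr_max, enr_max, fill=False,
                                    edgecolor="red", linewidth=1.2))
    ax_hx.hist(e1[shown], bins=60, color="0.5")
    ax_hy.hist(e2[shown], bins=60, orientation="horizontal", color="0.5")
    ax_hx.tick_params(labelbottom=False)
    ax_hy.tick_params(labelleft=False)
    ax.set_xlabel("enrichment, replicate 1")
    ax.set_ylabel("enrichment, replicate 2")
    fig.savefig(plot_path, dpi=150)
    plt.close(fig)

    if table_path is not None:
        result.to_csv(table_path, index=False)
    return int(shown.sum())


# ---------------------------------------------------------------------------
# Pre-quantified screen-table import
# ---------------------------------------------------------------------------

def load_screen_table(path, antibiotic: str, *, strain_col: str = "strain",
                      sheet=0) -> pd.DataFrame:
    """Import a pre-quantified normalized screen table (CSV/TSV/XLSX).

    Expects, for the requested antibiotic ``AB``, columns
    ``AB_growth_rep1``, ``AB_growth_rep2``, ``AB_enrichment_rep1``,
    ``AB_enrichment_rep2`` (case-insensitive; separators ``_``, ``-`` or
    space), alongside a strain identifier column. Returns a paired table
    ready for :func:`call_hits_threshold` / :func:`call_hits_sd`.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        raw = pd.read_excel(path, sheet_name=sheet)
    else:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        raw = pd.read_csv(path, sep=sep)

    def canon(name: str) -> str:
        return "".join(ch if ch.isalnum() else "_" for ch in str(name).strip().lower())

    colmap = {canon(c): c for c in raw.columns}
    ab = canon(antibiotic)

    def find(metric: str, rep: int) -> str:
        for pattern in (f"{ab}_{metric}_rep{rep}", f"{ab}_{metric}{rep}",
                        f"{ab}_rep{rep}_{metric}", f"{metric}_{ab}_rep{rep}"):
            if pattern in colmap:
                return colmap[pattern]
        raise KeyError(f"no column for {antibiotic} {metric} replicate {rep}; "
                       f"available: {list(raw.columns)}")

    strain_key = canon(strain_col)
    if strain_key not in colmap:
        raise KeyError(f"no strain column {strain_col!r}")
    out = pd.DataFrame({
        "strain": raw[colmap[strain_key]].astype(str),
        "enrichment_rep1": pd.to_numeric(raw[find("enrichment", 1)], errors="coerce"),
        "enrichment_rep2": pd.to_numeric(raw[find("enrichment", 2)], errors="coerce"),
        "norm_growth_rep1": pd.to_numeric(raw[find("growth", 1)], errors="coerce"),
        "norm_growth_rep2": pd.to_numeric(raw[find("growth", 2)], errors="coerce"),
    })
    return out
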