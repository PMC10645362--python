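"""Plate-reader assay calculations for the screen's follow-up experiments.

All operations work on a long-format well table (one row per well) with
columns ``well_id, row, col, strain, condition, concentration, od600,
abs600_cv, gfp, mcherry, a546, is_sterility, is_vehicle``:

* :func:`subtract_sterility` — remove the uninoculated-media blank.
* :func:`percent_of_control` — peg-lid dose response as percent of the
  matched vehicle control (same strain, same condition), for planktonic
  growth (OD600) and biofilm (solubilized crystal violet A600).
* :func:`max_stimulation` — the concentration with the highest mean
  biofilm percent-of-control ("highest average at one concentration").
* :func:`nitrate_fold_change` — ratio of maximum biofilm stimulation with
  nitrate to the no-nitrate control.
* :func:`reporter_scores` — promoter-reporter RFU and relative change,
  ratiometric NADH-reporter signal, and the diazotization nitrate-
  reduction index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "subtract_sterility", "percent_of_control", "max_stimulation",
    "nitrate_fold_change", "reporter_scores", "DoseResponseSummary",
]

READOUTS = ["od600", "abs600_cv", "gfp", "mcherry", "a546"]
GROUP_COLS = ["strain", "condition"]


def subtract_sterility(table: pd.DataFrame,
                       readouts: list[str] | None = None) -> pd.DataFrame:
    """Subtract the mean sterility-control value from each readout.

    Sterility wells are matched within each (strain-agnostic) condition
    group when such wells exist there, else plate-wide. Negative
    corrected values are clamped to 0 with a warning. Raises when no
    sterility wells are present at all.
    """
    if "is_sterility" not in table.columns or not table["is_sterility"].any():
        raise ValueError("subtract_sterility: no sterility-control wells in table")
    readouts = readouts or [c for c in READOUTS if c in table.columns]
    out = table.copy()
    sterile = table[table["is_sterility"]]
    for col in readouts:
        vals = out[col].to_numpy(float)
        blank_by_cond = sterile.groupby("condition")[col].mean()
        blank_global = sterile[col].mean()
        blanks = out["condition"].map(blank_by_cond).fillna(blank_global).to_numpy(float)
        blanks = np.where(np.isfinite(blanks), blanks, 0.0)
        corrected = vals - blanks
        n_neg = int(np.sum(corrected < 0))
        if n_neg:
            logger.warning("subtract_sterility: clamped %d negative %s values to 0",
                           n_neg, col)
        out[col] = np.where(np.isfinite(vals), np.clip(corrected, 0.0, None), vals)
    return out


@dataclass
class DoseResponseSummary:
    """Percent-of-control dose response for one (strain, condition) group.

    ``table`` has one row per tested concentration with mean raw values
    and ``growth_pct`` / ``biofilm_pct`` relative to the matched vehicle
    control; vehicle means are kept for reference.
    """

    strain: str
    condition: str
    table: pd.DataFrame
    vehicle_growth: float
    vehicle_biofilm: float

    def max_stimulation(self) -> tuple[float, float]:
        return max_stimulation(self)


def percent_of_control(table: pd.DataFrame, growth_col: str = "od600",
                       biofilm_col: str = "abs600_cv") -> list[DoseResponseSummary]:
    """Percent-of-control summaries per (strain, condition) group.

    For each tested concentration, the mean readout divided by the mean
    of that group's vehicle wells, times 100 — separately for growth and
    biofilm. Sterility wells are ignored here (subtract the blank first
    with :func:`subtract_sterility` if desired; percent-of-control itself
    is ratio-based and scale-invariant).
    """
    data = table[~table["is_sterility"].astype(bool)]
    out = []
    for (strain, cond), grp in data.groupby(GROUP_COLS, sort=True):
        vehicle = grp[grp["is_vehicle"].astype(bool)]
        if vehicle.empty:
            raise ValueError(f"no vehicle wells for group ({strain!r}, {cond!r})")
        vg = float(vehicle[growth_col].mean())
        vb = float(vehicle[biofilm_col].mean())
        if vg <= 0 or vb <= 0:
            raise ValueError(f"non-positive vehicle mean for ({strain!r}, {cond!r})")
        treated = grp[~grp["is_vehicle"].astype(bool)]
        rows = []
        for conc, sub in treated.groupby("concentration", sort=True):
            g = float(sub[growth_col].mean())
            b = float(sub[biofilm_col].mean())
            rows.append({"concentration": float(conc),
                         "growth_mean": g, "biofilm_mean": b,
                         "growth_pct": 100.0 * g / vg,
                         "biofilm_pct": 100.0 * b / vb,
                         "n_wells": len(sub)})
        out.append(DoseResponseSummary(
            strain=strain, condition=cond,
            table=pd.DataFrame(rows).sort_values("concentration", ignore_index=True),
            vehicle_growth=vg, vehicle_biofilm=vb))
    return out


def max_stimulation(summary: DoseResponseSummary) -> tuple[float, float]:
    """The (concentration, biofilm_pct) of maximum mean biofilm stimulation.

    Ties break toward the lower concentration (the sub-MIC-conservative
    choice).
    """
    t = summary.table
    if t.empty:
        raise ValueError("max_stimulation: no tested concentrations")
    t = t.sort_values("concentration", kind="stable", ignore_index=True)
    best = int(np.argmax(t["biofilm_pct"].to_numpy()))  # first max = lowest conc
    return float(t.loc[best, "concentration"]), float(t.loc[best, "biofilm_pct"])


def nitrate_fold_change(max_nitrate_pct: float, max_control_pct: float) -> float:
    """Maximum biofilm stimulation with nitrate over the no-nitrate control."""
    if max_control_pct <= 0:
        raise ValueError("nitrate_fold_change: non-positive control maximum")
    return float(max_nitrate_pct) / float(max_control_pct)


def reporter_scores(table: pd.DataFrame, promoterless_strain: str | None = None,
                    sterility_subtract: bool = True,
                    nadh_sterility_subtract: bool = False) -> pd.DataFrame:
    """Per-well reporter normalizations.

    Adds, where the inputs exist and denominators are positive (NaN
    otherwise):

    ``rfu``
        GFP / OD600, after sterility subtraction of both when
        ``sterility_subtract`` (the promoter-reporter convention).
    ``relative_change``
        this well's RFU divided by the promoterless strain's RFU in the
        condition- and concentration-matched wells (mean over matches);
        requires ``promoterless_strain``. Unmatched wells stay NaN.
    ``nadh_signal``
        GFP / (mCherry * OD600) — the ratiometric NADH reporter; by
        default computed on raw values (``nadh_sterility_subtract``
        opts in to blank removal).
    ``nitrate_index``
        sterility-subtracted A546 divided by the well's growth.
    """
    raw = table.copy()
    corrected = subtract_sterility(raw) if (sterility_subtract and
                                            raw.get("is_sterility") is not None and
                                            raw["is_sterility"].any()) else raw
    out = raw.copy()
    wells = ~out["is_sterility"].astype(bool)

    def _ratio(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)

    gfp_c = corrected["gfp"].to_numpy(float)
    od_c = corrected["od600"].to_numpy(float)
    out["rfu"] = np.where(wells, _ratio(gfp_c, od_c), np.nan)

    nadh_src = corrected if nadh_sterility_subtract else raw
    out["nadh_signal"] = np.where(
        wells,
        _ratio(nadh_src["gfp"].to_numpy(float),
               nadh_src["mcherry"].to_numpy(float) * nadh_src["od600"].to_numpy(float)),
        np.nan)

    if "a546" in corrected.columns:
        out["nitrate_index"] = np.where(
            wells, _ratio(corrected["a546"].to_numpy(float), od_c), np.nan)

    out["relative_change"] = np.nan
    if promoterless_strain is not None:
        ref = out[(out["strain"] == promoterless_strain) & wells]
        ref_rfu = ref.groupby(["condition", "concentration"])["rfu"].mean()
        keys = list(zip(out["condition"], out["concentration"]))
        ref_vals = np.array([ref_rfu.get(k, np.nan) for k in keys], dtype=float)
        rel = _ratio(out["rfu"].to_numpy(float), ref_vals)
        unmatched = wells & ~np.isfinite(ref_vals) & (out["strain"] != promoterless_strain)
        if unmatched.any():
            logger.warning("reporter_scores: %d wells without a matched promoterless "
                           "reference", int(unmatched.sum()))
        out["relative_change"] = np.where(wells, rel, np.nan)
    return out
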