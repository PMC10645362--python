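"""Synthetic-data generators: determinism, closed forms, planted truth."""

import numpy as np
import pytest

from crscreen import simulate
from crscreen.simulate import (DiscSpec, DoseSpec, PlateSpec,
                               generate_disc_image, generate_dose_response,
                               generate_plate_image, generate_screen_pair,
                               generate_screen_tables)


# ---------------------------------------------------------------------------
# plate images
# ---------------------------------------------------------------------------

def test_plate_seeded_determinism():
    spec = PlateSpec(grid_rows=4, grid_cols=6, noise_sd=4.0, missing_prob=0.1,
                     seed=11)
    img1, t1 = generate_plate_image(spec)
    img2, t2 = generate_plate_image(spec)
    assert np.array_equal(img1.pixels, img2.pixels)
    assert t1.equals(t2)


def test_noise_free_colony_red_value_is_exact():
    """No noise, no gradients: every colony's red plateau equals
    background + base_redness at the colony center."""
    spec = PlateSpec(grid_rows=3, grid_cols=4, noise_sd=0.0, seed=0)
    img, truth = generate_plate_image(spec)
    m = spec.margins()
    for rec in truth.itertuples():
        cx, cy = m + rec.col * spec.spacing_px, m + rec.row * spec.spacing_px
        assert img.pixels[cy, cx, 0] == spec.background + spec.base_redness


def test_planted_hit_recorded_in_truth():
    spec = PlateSpec(grid_rows=3, grid_cols=4, noise_sd=0.0, seed=0,
                     planted_hits={(1, 2): (0.3, 1.0)})
    _, truth = generate_plate_image(spec)
    rec = truth[(truth["row"] == 1) & (truth["col"] == 2)].iloc[0]
    assert rec["is_planted_hit"]
    assert rec["true_enrichment"] == pytest.approx(0.3)
    assert truth["true_enrichment"].drop(rec.name).eq(1.0).all()
    assert (truth.loc[truth["is_present"], "true_enrichment"] > 0).all()


def test_vehicle_plate_ignores_planted_multipliers():
    spec = PlateSpec(grid_rows=3, grid_cols=4, noise_sd=0.0, seed=0,
                     planted_hits={(1, 2): (0.3, 1.0)})
    _, truth = generate_plate_image(spec, treated=False)
    assert truth["true_enrichment"].eq(1.0).all()
    assert truth[(truth["row"] == 1) & (truth["col"] == 2)]["is_planted_hit"].iloc[0]


def test_plate_rejects_invalid_specs():
    with pytest.raises(ValueError):
        PlateSpec(missing_prob=1.5)
    with pytest.raises(ValueError):
        PlateSpec(row_gradient=np.array([1.0, -1.0]), grid_rows=2)
    with pytest.raises(ValueError):
        generate_plate_image(PlateSpec(grid_rows=500, grid_cols=500, spacing_px=40))


def test_screen_pair_shares_plants_with_independent_noise():
    spec = PlateSpec(grid_rows=8, grid_cols=12, noise_sd=5.0, seed=21,
                     planted_hits={(2, 3): (0.3, 1.0), (5, 7): (0.4, 0.9)})
    (img1, t1), (img2, t2) = generate_screen_pair(spec)
    assert t1["is_planted_hit"].equals(t2["is_planted_hit"])
    # independent pixel noise: images correlated but not identical
    a = img1.pixels[..., 0].astype(float).ravel()
    b = img2.pixels[..., 0].astype(float).ravel()
    assert not np.array_equal(a, b)
    assert np.corrcoef(a, b)[0, 1] < 1.0


def test_screen_pair_noise_free_differs_only_by_missing_draws():
    spec = PlateSpec(grid_rows=8, grid_cols=12, noise_sd=0.0, missing_prob=0.2,
                     seed=5)
    (img1, t1), (img2, t2) = generate_screen_pair(spec)
    both = t1["is_present"].to_numpy() & t2["is_present"].to_numpy()
    # positions present in both replicates render identically
    m, sp = spec.margins(), spec.spacing_px
    for rec in t1[both].itertuples():
        cy, cx = m + rec.row * sp, m + rec.col * sp
        win = np.s_[cy - 10:cy + 10, cx - 10:cx + 10]
        assert np.array_equal(img1.pixels[win], img2.pixels[win])


def test_screen_tables_truth_and_shapes():
    rep1, rep2, truth = generate_screen_tables(n_strains=200, n_plants=10,
                                               grid_rows=8, grid_cols=12, seed=3)
    assert truth["is_planted_hit"].sum() == 10
    assert len(truth) == 200
    assert set(rep1.columns) == set(rep2.columns)
    # noisy replicates differ but correlate
    g1 = rep1.loc[rep1["present"], "growth"].to_numpy()
    g2 = rep2.loc[rep2["present"], "growth"].to_numpy()
    assert 0.5 < np.corrcoef(g1, g2)[0, 1] < 1.0


# ---------------------------------------------------------------------------
# dose-response tables
# ---------------------------------------------------------------------------

def test_dose_response_matches_closed_form_when_noise_free():
    """An independent re-evaluation of the documented growth/biofilm
    formulas reproduces every emitted well value to 1e-9."""
    spec = DoseSpec(replicate_cv=0.0, seed=0)
    tab = generate_dose_response(spec)
    for rec in tab[~tab["is_sterility"]].itertuples():
        c = rec.concentration
        od = spec.baseline_od / (1 + (c / spec.mic) ** spec.hill_growth)
        if c > 0:
            z = np.log2(c / (spec.peak_frac * spec.mic))
            bf = spec.baseline_biofilm * (
                1 + spec.stim_amplitude * np.exp(-z ** 2 / (2 * spec.stim_width ** 2)))
        else:
            bf = spec.baseline_biofilm
        assert rec.od600 == pytest.approx(spec.blank_od + od, abs=1e-9)
        assert rec.abs600_cv == pytest.approx(spec.blank_biofilm + bf, abs=1e-9)


def test_dose_response_argmax_at_dilution_nearest_peak():
    for peak_frac in (0.25, 0.5, 0.3):
        spec = DoseSpec(replicate_cv=0.0, peak_frac=peak_frac, seed=0)
        tab = generate_dose_response(spec)
        treated = tab[~tab["is_sterility"] & ~tab["is_vehicle"]]
        means = treated.groupby("concentration")["abs600_cv"].mean()
        conc = spec.concentrations()
        nearest = conc[np.argmin(np.abs(np.log2(conc / (peak_frac * spec.mic))))]
        assert means.idxmax() == pytest.approx(nearest)


def test_dose_response_degenerate_cases():
    flat = generate_dose_response(DoseSpec(replicate_cv=0.0, stim_amplitude=0.0))
    sub_mic = flat[~flat["is_sterility"] & (flat["concentration"] > 0)
                   & (flat["concentration"] < 1.0)]
    vehicle = flat[flat["is_vehicle"]]["abs600_cv"].mean()
    assert np.allclose(100 * sub_mic["abs600_cv"].mean() / vehicle, 100, atol=1e-6)

    # full suppression (nitrate_suppression=0) equals the no-stimulation curve
    supp = generate_dose_response(
        DoseSpec(replicate_cv=0.0, nitrate_suppression=0.0), nitrate=True)
    assert np.allclose(supp["abs600_cv"], flat["abs600_cv"])

    with pytest.raises(ValueError):
        DoseSpec(n_dilutions=1)
    with pytest.raises(ValueError):
        DoseSpec(peak_frac=1.5)


def test_dose_response_has_controls():
    tab = generate_dose_response(DoseSpec())
    assert tab["is_vehicle"].any()
    assert tab["is_sterility"].any()
    assert (tab.loc[tab["is_vehicle"], "concentration"] == 0).all()


# ---------------------------------------------------------------------------
# disc images
# ---------------------------------------------------------------------------

def test_disc_seeded_determinism():
    spec = DiscSpec(noise_sd=3.0, seed=9)
    assert np.array_equal(generate_disc_image(spec).pixels,
                          generate_disc_image(spec).pixels)


def test_disc_noise_free_minimum_at_planted_ring():
    spec = DiscSpec(noise_sd=0.0)
    img = generate_disc_image(spec)
    c = img.pixels.shape[0] // 2
    # radial green values along the +x ray beyond the ZOI
    xs = np.arange(int(spec.zoi_radius_px) + 3, img.pixels.shape[1] - c - 1)
    ray = img.pixels[c, c + xs, 1].astype(float)
    assert xs[np.argmin(ray)] == pytest.approx(spec.ring_radius_px, abs=1)


def test_disc_without_ring_is_a_single_step():
    spec = DiscSpec(ring_depth=0.0, noise_sd=0.0)
    img = generate_disc_image(spec)
    c = img.pixels.shape[0] // 2
    xs = np.arange(int(spec.disk_radius_px) + 2, img.pixels.shape[1] - c - 1)
    ray = img.pixels[c, c + xs, 1].astype(float)
    inside = ray[xs < spec.zoi_radius_px - 1]
    outside = ray[xs > spec.zoi_radius_px + 1]
    assert np.all(inside == spec.inhibition_level)
    assert np.all(outside == spec.lawn_intensity)


def test_disc_spec_validation():
    with pytest.raises(ValueError):
        DiscSpec(disk_radius_px=120, ring_radius_px=110)
    with pytest.raises(ValueError):
        DiscSpec(zoi_radius_px=10, disk_radius_px=25)
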