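"""Positional normalization, enrichment, hit calling, hit-set intersection."""

import numpy as np
import pandas as pd
import pytest

from crscreen import scoring
from crscreen.scoring import (call_hits_sd, call_hits_threshold, enrichment,
                              intersect_hits, load_screen_table,
                              normalize_plate, pair_replicates)

from conftest import make_colony_table


# ---------------------------------------------------------------------------
# normalize_plate
# ---------------------------------------------------------------------------

def test_uniform_plate_normalizes_to_one():
    t = make_colony_table(np.full((8, 12), 7.0))
    n = normalize_plate(t)
    assert np.allclose(n["norm_growth"], 1.0)
    assert np.allclose(n["norm_cr"], 1.0)
    assert np.allclose(n["enrichment"], 1.0)


def test_separable_gradients_cancel_exactly(rng):
    r = rng.uniform(0.6, 1.6, size=8)
    c = rng.uniform(0.6, 1.6, size=12)
    grid = 5.0 * np.outer(r, c)
    n = normalize_plate(make_colony_table(grid, red=3.0 * np.outer(r, c)))
    assert np.abs(n["norm_growth"] - 1).max() < 1e-9
    assert np.abs(n["norm_cr"] - 1).max() < 1e-9
    assert np.abs(n["enrichment"] - 1).max() < 1e-9


def test_single_outlier_untouched_on_full_density_plate():
    """On a 32x48 all-ones plate a lone 2x colony keeps its value: it is
    trimmed out of both its column and row IQMs, which stay at 1."""
    grid = np.ones((32, 48))
    grid[10, 20] = 2.0
    n = normalize_plate(make_colony_table(grid))
    at = n[(n["row"] == 10) & (n["col"] == 20)]["norm_growth"].iloc[0]
    others = n[(n["row"] != 10) | (n["col"] != 20)]["norm_growth"]
    assert at == pytest.approx(2.0, abs=1e-12)
    assert np.abs(others - 1).max() < 1e-12


def test_scale_invariance_of_normalization_and_hits(rng):
    grid = rng.lognormal(0, 0.2, size=(8, 12))
    red = rng.lognormal(0, 0.2, size=(8, 12))
    n1 = normalize_plate(make_colony_table(grid, red=red))
    n2 = normalize_plate(make_colony_table(grid * 137.0, red=red * 0.004))
    assert np.allclose(n1["norm_growth"], n2["norm_growth"])
    assert np.allclose(n1["norm_cr"], n2["norm_cr"])
    assert np.allclose(n1["enrichment"], n2["enrichment"])


def test_normalization_idempotent_on_position_free_plates(rng):
    """Once positional structure is removed the normalizer is a fixed
    point: a separable-gradient plate normalizes to all-ones, and
    re-normalizing the result changes nothing. (On plates with
    non-separable strain-level structure a second pass is not an exact
    no-op — the correction is defined as a single column-then-row pass —
    but it must perturb values far less than the first pass did.)"""
    r = rng.uniform(0.6, 1.6, size=8)
    c = rng.uniform(0.6, 1.6, size=12)
    n1 = normalize_plate(make_colony_table(4.0 * np.outer(r, c)))
    t2 = make_colony_table(
        n1["norm_growth"].to_numpy().reshape(8, 12),
        red=n1["norm_cr"].to_numpy().reshape(8, 12))
    n2 = normalize_plate(t2)
    assert np.abs(n2["norm_growth"] - n1["norm_growth"]).max() < 1e-9
    assert np.abs(n2["norm_cr"] - n1["norm_cr"]).max() < 1e-9

    grid = rng.lognormal(0, 0.3, size=(16, 24)) * np.outer(
        rng.uniform(0.7, 1.4, 16), rng.uniform(0.7, 1.4, 24))
    m1 = normalize_plate(make_colony_table(grid))
    v1 = m1["norm_growth"].to_numpy().reshape(16, 24)
    m2 = normalize_plate(make_colony_table(v1))
    v2 = m2["norm_growth"].to_numpy().reshape(16, 24)
    first_pass = np.abs(v1 * scoring.iqm(grid.ravel()) / grid - 1).max()
    second_pass = np.abs(v2 / v1 - 1).max()
    assert second_pass < 0.5 * first_pass


def test_absent_colonies_propagate_and_sparse_lines_fall_back(rng):
    present = np.ones((8, 12), dtype=bool)
    present[:, 3] = False          # a whole empty column
    present[0, 0] = False
    grid = rng.lognormal(0, 0.1, size=(8, 12))
    n = normalize_plate(make_colony_table(grid, present=present))
    absent = n[~n["present"]]
    assert absent["norm_growth"].isna().all()
    assert absent["enrichment"].isna().all()
    assert np.isfinite(n[n["present"]]["norm_growth"]).all()


def test_all_absent_plate_is_an_error():
    t = make_colony_table(np.ones((4, 4)), present=np.zeros((4, 4), dtype=bool))
    with pytest.raises(ValueError):
        normalize_plate(t)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cr, g, expected", [(1, 1, 1.0), (0.4, 0.8, 0.5),
                                             (2.0, 0.5, 4.0)])
def test_enrichment_arithmetic(cr, g, expected):
    assert enrichment(cr, g) == pytest.approx(expected)


def test_enrichment_nonpositive_growth_is_missing():
    assert np.isnan(enrichment(1.0, 0.0))
    assert np.isnan(enrichment(1.0, -0.2))


# ---------------------------------------------------------------------------
# hit calling
# ---------------------------------------------------------------------------

def _paired(e1, e2, g1=None, g2=None):
    n = len(e1)
    return pd.DataFrame({
        "strain": [f"s{i}" for i in range(n)],
        "enrichment_rep1": e1, "enrichment_rep2": e2,
        "norm_growth_rep1": g1 if g1 is not None else np.ones(n),
        "norm_growth_rep2": g2 if g2 is not None else np.ones(n),
    })


def test_sd_rule_single_low_strain():
    """Nine strains, eight at 1 and one at 0.2 in both replicates: the
    cutoff mu - 2*sigma is ~0.378 (computed by hand), so only the 0.2
    strain qualifies."""
    e = [1.0] * 8 + [0.2]
    res = call_hits_sd(_paired(e, e), k=2)
    mu, sd = np.mean(e), np.std(e, ddof=1)
    assert mu - 2 * sd == pytest.approx(0.37778, abs=1e-4)
    assert res["is_hit"].tolist() == [False] * 8 + [True]


def test_sd_rule_zero_variance_yields_no_hits():
    res = call_hits_sd(_paired([1.0] * 5, [1.0] * 5), k=2)
    assert not res["is_hit"].any()


def test_sd_rule_requires_both_replicates():
    e1 = [1.0] * 8 + [0.2]                              # clear outlier in rep1
    e2 = [0.9, 1.1, 1.0, 0.95, 1.05, 1.0, 0.98, 1.02, 0.97]  # unremarkable
    res = call_hits_sd(_paired(e1, e2), k=2)
    cut2 = np.mean(e2) - 2 * np.std(e2, ddof=1)
    assert e2[-1] > cut2       # genuinely not low in replicate 2
    assert not res["is_hit"].any()


def test_sd_rule_too_few_strains_errors():
    with pytest.raises(ValueError):
        call_hits_sd(_paired([1.0, 0.5], [1.0, 0.5]))


@pytest.mark.parametrize("e1, e2, g1, g2, hit, excluded", [
    (0.45, 0.48, 0.6, 0.7, True, False),   # below 0.5 in both -> hit
    (0.30, 0.30, 0.15, 0.6, False, True),  # low growth in one rep -> excluded
    (0.45, 0.55, 0.6, 0.7, False, False),  # misses in rep2 -> not a hit
])
def test_threshold_rule_examples(e1, e2, g1, g2, hit, excluded):
    res = call_hits_threshold(_paired([e1, 1, 1], [e2, 1, 1],
                                      [g1, 1, 1], [g2, 1, 1]))
    assert bool(res.loc[0, "is_hit"]) is hit
    assert bool(res.loc[0, "excluded_low_growth"]) is excluded


def test_threshold_growth_rule_readings_differ():
    paired = _paired([0.3], [0.3], [0.15], [0.6])
    either = call_hits_threshold(paired, growth_rule="either")
    both = call_hits_threshold(paired, growth_rule="both")
    assert bool(either.loc[0, "excluded_low_growth"])
    assert not bool(both.loc[0, "excluded_low_growth"])
    assert bool(both.loc[0, "is_hit"])


def test_missing_replicate_is_no_call_never_hit():
    paired = _paired([0.2, 1.0], [np.nan, 1.0])
    res = call_hits_threshold(paired)
    assert bool(res.loc[0, "no_call"])
    assert not bool(res.loc[0, "is_hit"])


def test_pair_replicates_outer_joins_strains():
    r1 = pd.DataFrame({"strain": ["a", "b"], "enrichment": [1.0, 0.4],
                       "norm_growth": [1.0, 1.0]})
    r2 = pd.DataFrame({"strain": ["b", "c"], "enrichment": [0.4, 1.0],
                       "norm_growth": [1.0, 1.0]})
    p = pair_replicates(r1, r2)
    assert set(p["strain"]) == {"a", "b", "c"}
    assert p.set_index("strain").loc["a", "enrichment_rep2"] != \
        p.set_index("strain").loc["a", "enrichment_rep2"]  # NaN


# ---------------------------------------------------------------------------
# intersect_hits
# ---------------------------------------------------------------------------

def test_intersect_two_sets():
    ov = intersect_hits({"A": {"x", "y"}, "B": {"y", "z"}})
    assert ov.counts() == {("A",): 1, ("B",): 1, ("A", "B"): 1}


def test_intersect_disjoint_sets():
    ov = intersect_hits({"A": {"x"}, "B": {"y"}, "C": {"z"}})
    counts = ov.counts()
    assert counts[("A",)] == counts[("B",)] == counts[("C",)] == 1
    assert all(v == 0 for k, v in counts.items() if len(k) > 1)


def test_intersect_region_counts_sum_to_union(rng):
    sets = {name: set(rng.choice(100, size=rng.integers(5, 40), replace=False))
            for name in "ABC"}
    sets = {k: {f"g{i}" for i in v} for k, v in sets.items()}
    ov = intersect_hits(sets)
    assert sum(ov.counts().values()) == len(set.union(*sets.values()))


def test_intersect_label_permutation_consistent(rng):
    sets = {"NOVO": {"a", "b", "c"}, "CEF": {"b", "c", "d"}, "TET": {"c", "e"}}
    ov1 = intersect_hits(sets)
    ov2 = intersect_hits({"TET": sets["TET"], "CEF": sets["CEF"],
                          "NOVO": sets["NOVO"]})
    assert ov1.counts() == ov2.counts()


def test_intersect_requires_two_sets():
    with pytest.raises(ValueError):
        intersect_hits({"A": {"x"}})


# ---------------------------------------------------------------------------
# replica plot and screen-table import
# ---------------------------------------------------------------------------

def test_replica_plot_caps_display_not_table(tmp_path, rng):
    e1 = np.concatenate([rng.uniform(0.3, 3, 50), [5.0, 6.0]])
    e2 = np.concatenate([rng.uniform(0.3, 3, 50), [5.0, 2.0]])
    res = call_hits_threshold(_paired(e1, e2))
    n_shown = scoring.export_replica_plot(res, tmp_path / "rp.png",
                                          tmp_path / "rp.csv", cap=4.0)
    over = np.sum((e1 > 4) | (e2 > 4))
    assert n_shown == len(e1) - over
    table = pd.read_csv(tmp_path / "rp.csv")
    assert len(table) == len(e1)                      # uncapped on disk
    assert table["enrichment_rep1"].max() > 4
    assert (tmp_path / "rp.png").stat().st_size > 0
    # cap=inf shows everything
    assert scoring.export_replica_plot(res, tmp_path / "rp2.png",
                                       cap=np.inf) == len(e1)


def test_load_screen_table_csv_layout(tmp_path):
    df = pd.DataFrame({
        "Strain": ["a", "b"],
        "NOVO_enrichment_rep1": [0.4, 1.1], "NOVO_enrichment_rep2": [0.45, 0.9],
        "NOVO_growth_rep1": [0.8, 1.0], "NOVO_growth_rep2": [0.9, 1.0],
    })
    p = tmp_path / "screen.csv"
    df.to_csv(p, index=False)
    t = load_screen_table(p, "NOVO")
    res = call_hits_threshold(t)
    assert res.set_index("strain")["is_hit"].to_dict() == {"a": True, "b": False}


def test_load_screen_table_missing_column_errors(tmp_path):
    p = tmp_path / "bad.csv"
    pd.DataFrame({"strain": ["a"], "NOVO_growth_rep1": [1.0]}).to_csv(p, index=False)
    with pytest.raises(KeyError):
        load_screen_table(p, "NOVO")
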