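"""ICERs, net monetary benefit and acceptability frontiers."""

import numpy as np
import pandas as pd
import pytest

from medretain import cea
from medretain.cea import (
    ceaf,
    icer,
    nmb,
    percent_gain,
    proportions_of_baseline,
    threshold_grid,
)
from medretain.uncertainty import PSADraws


def _summary(cost, dy, sy=0.0, name="x"):
    return pd.Series({"cost": cost, "doctor_years": dy,
                      "specialist_years": sy, "scenario": name})


BASE = _summary(100.0, 50.0, 5.0, "baseline")


def test_icer_ratio_and_dominance_classes():
    r = icer(_summary(110.0, 52.0), BASE, "doctor_years")
    assert r.icer == pytest.approx(5.0)
    assert r.dominance == cea.TRADEOFF

    r = icer(_summary(96.0, 52.0), BASE, "doctor_years")
    assert r.icer == pytest.approx(-2.0)
    assert r.dominance == cea.COST_SAVING

    r = icer(_summary(96.0, 48.0), BASE, "doctor_years")
    assert r.dominance == cea.LESS_EFFECTIVE_CHEAPER

    r = icer(_summary(110.0, 48.0), BASE, "doctor_years")
    assert r.dominance == cea.DOMINATED


def test_zero_incremental_effect_yields_an_undefined_marker():
    r = icer(_summary(103.0, 50.0), BASE, "doctor_years")
    assert r.icer is None
    assert r.dominance == cea.DOMINATED


def test_nmb_arithmetic():
    assert nmb(5.0, 2.0, 0.0) == -5.0
    assert nmb(5.0, 2.0, 10.0) == 15.0
    with pytest.raises(ValueError):
        nmb(1.0, 1.0, -1.0)


def test_nmb_ranking_agrees_with_icer_threshold_comparison():
    """For two options that both add effect, the one with the higher NMB at
    threshold lambda is the one whose ICER lies below lambda (when exactly
    one does) — checked by enumeration over random pairs."""
    rng = np.random.default_rng(4)
    for _ in range(200):
        dc1, dc2 = rng.uniform(1, 50, 2)
        de1, de2 = rng.uniform(0.1, 10, 2)
        lam = rng.uniform(0, 20)
        icer1, icer2 = dc1 / de1, dc2 / de2
        nmb1 = lam * de1 - dc1
        nmb2 = lam * de2 - dc2
        if icer1 < lam < icer2:
            assert nmb1 > 0 > nmb2
        elif icer2 < lam < icer1:
            assert nmb2 > 0 > nmb1


def test_threshold_grid_matches_the_reporting_convention():
    grid = threshold_grid(50_000_000, 100_000)
    assert len(grid) == 501
    assert grid[0] == 0.0 and grid[-1] == 50_000_000.0
    assert np.allclose(np.diff(grid), 100_000.0)


def _toy_draws(rng=None, identical=False):
    rng = rng or np.random.default_rng(0)
    n = 400
    cost = np.column_stack([
        rng.normal(100, 10, n), rng.normal(120, 10, n), rng.normal(90, 10, n)])
    eff = np.column_stack([
        rng.normal(10, 1, n), rng.normal(14, 1, n), rng.normal(8, 1, n)])
    if identical:
        cost[:, 1] = cost[:, 0]
        eff[:, 1] = eff[:, 0]
    return PSADraws(["a", "b", "c"], cost, eff, np.zeros_like(eff) + 0.1,
                    seed=0)


def test_ceaf_at_zero_threshold_picks_the_cheapest_option():
    draws = _toy_draws()
    frontier = ceaf(draws, np.array([0.0]), "doctor_years")
    assert frontier["optimal"].iloc[0] == "c"  # lowest mean cost


def test_ceaf_optimal_maximises_mean_nmb_everywhere():
    draws = _toy_draws()
    grid = threshold_grid(40, 2)
    frontier = ceaf(draws, grid, "doctor_years")
    mean_cost = draws.cost.mean(axis=0)
    mean_eff = draws.doctor_years.mean(axis=0)
    for _, row in frontier.iterrows():
        nmbs = row["lambda"] * mean_eff - mean_cost
        assert nmbs[draws.scenarios.index(row["optimal"])] == \
            pytest.approx(nmbs.max())


def test_ceaf_probability_equals_the_empirical_win_share():
    draws = _toy_draws()
    lam = 12.0
    frontier = ceaf(draws, np.array([lam]), "doctor_years")
    opt = frontier["optimal"].iloc[0]
    k = draws.scenarios.index(opt)
    nmbs = lam * draws.doctor_years - draws.cost
    wins = (nmbs.argmax(axis=1) == k).mean()
    assert frontier["probability"].iloc[0] == pytest.approx(wins)


def test_identical_options_split_ties_equally():
    draws = _toy_draws(identical=True)
    frontier = ceaf(draws, np.array([13.0]), "doctor_years")
    opt = frontier["optimal"].iloc[0]
    assert opt in ("a", "b")
    # a and b are duplicate columns: whenever one wins, both tie
    nmbs = 13.0 * draws.doctor_years - draws.cost
    p_ab_best = (nmbs[:, 0] >= nmbs[:, 2]).mean()
    assert frontier["probability"].iloc[0] == pytest.approx(p_ab_best / 2)


def test_percent_gain_reproduces_reported_conversions():
    assert percent_gain(1.17) == pytest.approx(17.0)
    assert percent_gain(6.16) == pytest.approx(516.0)
    assert percent_gain(1.00) == 0.0


def test_proportions_table_has_unit_baseline(frame_wp):
    props = proportions_of_baseline(frame_wp)
    assert props.loc["baseline", "doctor_years_prop"] == pytest.approx(1.0)
    assert props.loc["baseline", "specialist_years_prop"] == pytest.approx(1.0)
    assert props.loc["baseline", "doctor_years_gain_pct"] == pytest.approx(0.0)


def test_icer_table_covers_both_effects(frame_wp):
    table = cea.icer_table(frame_wp)
    assert len(table) == 15 * 2
    assert set(table["effect"]) == set(cea.EFFECTS)


def test_summarize_bundles_all_report_tables(frame_wp, psa_draws):
    tables = cea.summarize(frame_wp, psa_draws,
                           grid=threshold_grid(50_000_000, 1_000_000))
    assert {"proportions", "icers", "cost_shares",
            "ceaf_doctor_years", "ceaf_specialist_years"} <= set(tables)
    for effect in cea.EFFECTS:
        assert tables[f"ceaf_{effect}"]["probability"].between(0, 1).all()
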