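"""Rank tests, logistic selectivity, resampling, and geographic range."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from foramsize import (
    EventSimulationParams,
    assign_grid_cells,
    bonferroni_adjust,
    extinction_rate,
    fit_logistic_selectivity,
    generate_genus_table,
    mann_whitney_u,
    pooled_group_selectivity,
    proportion_large,
    resample_significance,
)

# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def test_mwu_fully_separated_small_sample():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.U == 0.0
    assert res.exact
    assert res.p_two_sided == pytest.approx(0.10, abs=1e-12)


def test_mwu_identical_groups():
    res = mann_whitney_u([5, 5, 5], [5, 5, 5])
    assert res.p_two_sided == 1.0
    assert res.median_ratio_linear == pytest.approx(1.0)


def test_mwu_median_ratio_anchor():
    """Victim/survivor medians of 7.69 and 7.15 log10 um^3 give a 3.47x
    linear median volume ratio."""
    res = mann_whitney_u([7.0, 7.69, 8.4], [6.9, 7.15, 7.4])
    assert res.median_victims == pytest.approx(7.69)
    assert res.median_survivors == pytest.approx(7.15)
    assert round(res.median_ratio_linear, 2) == 3.47


def test_mwu_exact_agrees_with_scipy(rng):
    """Independent cross-check of the enumeration path against scipy."""
    for _ in range(20):
        n1, n2 = rng.integers(2, 7, size=2)
        x = rng.normal(0, 1, n1)
        y = rng.normal(0.5, 1, n2)
        ours = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.exact
        assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)


def test_mwu_normal_approximation_agrees_with_scipy(rng):
    """Tie-corrected, continuity-corrected approximation vs scipy's."""
    for _ in range(10):
        x = rng.normal(7.4, 0.5, 30)
        y = rng.normal(7.2, 0.5, 40)
        ours = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert not ours.exact
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-8)
    # with heavy ties
    x = rng.integers(0, 4, 25).astype(float)
    y = rng.integers(1, 5, 25).astype(float)
    ours = mann_whitney_u(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-8)


@given(
    data=st.lists(st.integers(-1000, 1000), min_size=8, max_size=30, unique=True),
    shift=st.integers(-500, 500),
)
@settings(deadline=None, max_examples=40)
def test_mwu_invariant_under_monotone_transform(data, shift):
    """The rank test depends on the data only through ranks, so any strictly
    monotone transform of the pooled sample leaves U and p unchanged."""
    n1 = len(data) // 2
    x, y = np.array(data[:n1], dtype=float), np.array(data[n1:], dtype=float)

    def transform(v):
        return np.exp((v + shift) / 400.0)  # strictly increasing, tie-free

    a = mann_whitney_u(x, y)
    b = mann_whitney_u(transform(x), transform(y))
    assert a.U == b.U
    assert a.p_two_sided == pytest.approx(b.p_two_sided, rel=1e-9)


def test_mwu_empty_group_errors():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------


def _table_from_arrays(size, richness, cells, status, event="P-T"):
    n = len(size)
    return pd.DataFrame(
        {
            "genus": [f"g{i}" for i in range(n)],
            "event": event,
            "mean_log10_volume": size,
            "sd_log10_volume": 0.1,
            "n_specimens": 3,
            "species_richness": richness,
            "range_cells": cells,
            "status": status,
            "size_class": "small",
        }
    )


def test_logistic_2x2_closed_form(rng):
    """On a binary covariate the fitted slope must equal the log odds ratio
    ln(ad/bc) with SE sqrt(1/a+1/b+1/c+1/d)."""
    a, b, c, d = 30, 22, 14, 41  # victims@x1, survivors@x1, victims@x0, survivors@x0
    size = np.array([1.0] * (a + b) + [0.0] * (c + d))
    status = np.array([1] * a + [0] * b + [1] * c + [0] * d)
    table = _table_from_arrays(size, 1, 1, status)
    res = fit_logistic_selectivity(table, ["body_size"])
    est = res.estimate("body_size")
    assert est.coef == pytest.approx(math.log(a * d / (b * c)), abs=1e-6)
    assert est.se == pytest.approx(math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), abs=1e-6)
    assert est.ci95_lo == pytest.approx(est.coef - 1.959964 * est.se, abs=1e-9)


def test_logistic_symmetric_design_zero_coefficient():
    size = np.array([-1.0] * 40 + [1.0] * 40)
    status = np.array(([1] * 10 + [0] * 30) * 2)  # same victim fraction at both levels
    table = _table_from_arrays(size, 1, 1, status)
    res = fit_logistic_selectivity(table, ["body_size"])
    assert res.estimate("body_size").coef == pytest.approx(0.0, abs=1e-8)


def test_logistic_parameter_recovery():
    params = EventSimulationParams(
        "P-T", n_genera=2000, size_mean=7.5, size_sd=0.8, beta_size=1.2, seed=7,
    )
    table = generate_genus_table(params)
    res = fit_logistic_selectivity(table)
    assert res.converged
    assert abs(res.estimate("body_size").coef - 1.2) < 0.15


def test_logistic_null_covariate_ci_coverage():
    """When labels are independent of the covariate, the 95% CI should cover
    zero in at least ~90% of replicates."""
    cover = 0
    reps = 100
    for i in range(reps):
        rng = np.random.default_rng(1000 + i)
        size = rng.normal(7.5, 0.5, 500)
        status = rng.binomial(1, 0.5, 500)
        if status.min() == status.max():
            continue
        table = _table_from_arrays(size, 1, 1, status)
        est = fit_logistic_selectivity(table, ["body_size"]).estimate("body_size")
        cover += est.ci95_lo <= 0.0 <= est.ci95_hi
    assert cover >= 0.90 * reps


def test_logistic_requires_both_classes_and_variance(small_event_table):
    all_victims = small_event_table.assign(status=1)
    with pytest.raises(ValueError):
        fit_logistic_selectivity(all_victims)
    flat = small_event_table.assign(species_richness=2)
    with pytest.raises(ValueError):
        fit_logistic_selectivity(flat, ["species_richness"])


def test_logistic_separation_flagged():
    size = np.linspace(6.0, 9.0, 40)
    status = (size > 7.5).astype(int)  # perfectly separable
    table = _table_from_arrays(size, 1, 1, status)
    res = fit_logistic_selectivity(table, ["body_size"])
    assert res.separation
    assert not res.converged


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------


def test_bonferroni_adjust():
    assert bonferroni_adjust([0.01], 6) == [pytest.approx(0.06)]
    assert bonferroni_adjust([0.5], 6) == [1.0]
    assert bonferroni_adjust([0.0], 6) == [0.0]
    with pytest.raises(ValueError):
        bonferroni_adjust([1.5], 6)
    with pytest.raises(ValueError):
        bonferroni_adjust([0.1, 0.2, 0.3], 2)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def test_resample_deterministic(small_event_table):
    a = resample_significance(small_event_table, n_iter=200, seed=11)
    b = resample_significance(small_event_table, n_iter=200, seed=11)
    assert a == b
    c = resample_significance(small_event_table, n_iter=200, seed=12)
    assert a.fraction_nonsignificant != c.fraction_nonsignificant or a.seed != c.seed


def test_resample_degenerate_identical_sizes():
    table = _table_from_arrays(
        np.full(20, 5.0), 1, 1, np.array([1] * 10 + [0] * 10)
    )
    res = resample_significance(table, n_iter=50, seed=1)
    assert res.fraction_nonsignificant == 1.0


def test_resample_pooled_null_calibrated():
    """The pooled scheme breaks any group association, so null data stay
    nonsignificant in ~(1 - alpha) of iterations regardless of the draw."""
    rng = np.random.default_rng(5)
    for _ in range(5):
        size = rng.normal(7.5, 0.4, 40)
        status = np.array([1] * 20 + [0] * 20)
        table = _table_from_arrays(size, 1, 1, status)
        res = resample_significance(table, n_iter=500, alpha=0.05, seed=9,
                                    scheme="pooled")
        assert res.fraction_nonsignificant >= 0.90


def test_resample_stratified_inherits_observed_difference():
    """Stratified replicates preserve the observed group separation, so a
    clearly separated dataset stays significant while the pooled scheme
    destroys the association."""
    rng = np.random.default_rng(8)
    size = np.concatenate([rng.normal(8.2, 0.3, 30), rng.normal(7.2, 0.3, 30)])
    status = np.array([1] * 30 + [0] * 30)
    table = _table_from_arrays(size, 1, 1, status)
    strat = resample_significance(table, n_iter=300, seed=3)
    pooled = resample_significance(table, n_iter=300, seed=3, scheme="pooled")
    assert strat.fraction_nonsignificant <= 0.05
    assert pooled.fraction_nonsignificant >= 0.80
    with pytest.raises(ValueError):
        resample_significance(table, scheme="jackknife")


def test_resample_strong_separation_always_significant():
    rng = np.random.default_rng(6)
    size = np.concatenate([rng.normal(9, 0.1, 50), rng.normal(6, 0.1, 50)])
    status = np.array([1] * 50 + [0] * 50)
    table = _table_from_arrays(size, 1, 1, status)
    res = resample_significance(table, n_iter=500, alpha=0.05, seed=10)
    assert res.fraction_nonsignificant <= 0.01


# ---------------------------------------------------------------------------
# Pooled size classes, proportions, grid
# ---------------------------------------------------------------------------


def test_pooled_group_selectivity_contrast():
    """Selectivity constructed only above the threshold shows up in the large
    class and not in the small class."""
    rng = np.random.default_rng(3)
    tables = []
    for event in ("P-T", "K-Pg"):
        size = rng.uniform(6.0, 9.0, 300)
        logits = np.where(size >= 7.4, 1.5 * (size - 7.7), 0.0)
        status = rng.binomial(1, 1 / (1 + np.exp(-logits)))
        tables.append(
            _table_from_arrays(size, rng.poisson(2, 300) + 1, rng.poisson(2, 300) + 1,
                               status, event=event)
        )
    out = pooled_group_selectivity(tables)
    large = out["large"].estimate("body_size")
    small = out["small"].estimate("body_size")
    assert large.ci95_lo > 0.0
    assert small.ci95_lo <= 0.0 <= small.ci95_hi


def test_pooled_requires_two_events(small_event_table):
    with pytest.raises(ValueError):
        pooled_group_selectivity([small_event_table])


def test_pooled_single_outcome_class_flagged(small_event_table):
    # make the large class all victims -> not fittable there; keep both
    # outcomes among the small genera
    t1 = small_event_table.copy()
    t1.loc[t1["mean_log10_volume"] >= 7.4, "status"] = 1
    t1.loc[t1["mean_log10_volume"] < 7.4, "status"] = [0, 1, 0]
    t2 = t1.assign(event="K-Pg")
    out = pooled_group_selectivity([t1, t2])
    assert out["large"] is None
    assert out["small"] is not None


def test_proportion_large_and_threshold_inclusive():
    table = _table_from_arrays(
        np.array([7.4, 7.39, 8.0, 6.0]), 1, 1, np.array([1, 0, 1, 0])
    )
    n_large, n_total, pct = proportion_large(table)
    assert (n_large, n_total) == (2, 4)
    assert pct == 50.0
    # paper-style count anchors
    assert round(100 * 85 / 138, 2) == 61.59
    assert round(100 * 9 / 43, 2) == 20.93


def test_extinction_rate():
    table = _table_from_arrays(
        np.linspace(6, 8, 86), 1, 1, np.array([1] * 37 + [0] * 49)
    )
    assert extinction_rate(table) == 43.02
    assert extinction_rate(table.assign(status=0)) == 0.0
    assert extinction_rate(table.assign(status=1)) == 100.0


def test_grid_cells_dedup_and_bounds():
    assert assign_grid_cells([(10.0, 10.0)]) == 1
    assert assign_grid_cells([(10.0, 10.0), (10.1, 10.1)]) == 1  # same 5 deg cell
    assert assign_grid_cells([(10.0, 10.0), (-170.0, -10.0)]) == 2  # antipodal
    assert assign_grid_cells([(180.0, 90.0), (-180.0, -90.0)]) == 2  # edges ok
    with pytest.raises(ValueError):
        assign_grid_cells([(190.0, 0.0)])
    with pytest.raises(ValueError):
        assign_grid_cells([(0.0, 95.0)])


def test_grid_cells_equal_area_bands():
    # two points a fixed sin-latitude apart land in different bands even
    # near the pole where degree spacing shrinks
    near_equator = assign_grid_cells([(0.0, 0.0), (0.0, 4.0)])
    assert near_equator == 2
    # degree distance 4 near the pole spans less sin-lat -> same band
    near_pole = assign_grid_cells([(0.0, 80.0), (0.0, 84.0)])
    assert near_pole == 1
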