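"""Audit-module tests: discrepancy estimators, bootstrap, condition matching."""

import math

import numpy as np
import pandas as pd
import pytest

from ratersim.audit import (AISystemConfig, DiscrepancyStats, FixtureConfig,
                            bootstrap_audit, discrepancy_stats, human_reference,
                            make_fixture, match_condition, subgroup_deviations,
                            validate_scores)


def _table(rows):
    return pd.DataFrame(rows, columns=["unit_id", "rater_id", "rater_kind",
                                       "system_label", "familiarity_group",
                                       "score"])


def exact_fixture(n_units=6, slope=1.0, intercept=0.0):
    """Noise-free score table: teachers score the true value exactly,
    the AI applies a deterministic affine map."""
    true = np.linspace(30.0, 60.0, n_units)
    rows = []
    for u, t in enumerate(true):
        for g_idx, g in enumerate(("direct", "indirect", "unfamiliar")):
            rows.append((f"u{u}", f"t{g_idx}", "human", "", g, t))
        rows.append((f"u{u}", "ai", "ai", "sys", None, intercept + slope * t))
    return _table(rows)


def test_human_reference_mean_and_errors():
    t = _table([("e1", "t1", "human", "", "direct", 60),
                ("e1", "t2", "human", "", "indirect", 64),
                ("e1", "t3", "human", "", "unfamiliar", 68),
                ("e2", "t1", "human", "", "direct", 50),
                ("e1", "ai", "ai", "sys", None, 70)])
    ref = human_reference(t)
    assert ref["e1"] == pytest.approx(64.0)
    assert ref["e2"] == pytest.approx(50.0)  # single rater -> that score
    shuffled = human_reference(t.sample(frac=1, random_state=0))
    pd.testing.assert_series_equal(ref.sort_index(), shuffled.sort_index())
    with pytest.raises(ValueError, match="e3"):
        human_reference(_table([("e3", "ai", "ai", "s", None, 10.0),
                                ("e4", "t1", "human", "", None, 20.0)]))


def test_discrepancy_stats_identity_and_constant_shift():
    t = exact_fixture()
    s = discrepancy_stats(t, "sys")
    assert s.bias == pytest.approx(0.0)
    assert s.slope == pytest.approx(1.0)
    assert s.r_squared == pytest.approx(1.0)
    shifted = exact_fixture(intercept=-5.0)
    s2 = discrepancy_stats(shifted, "sys")
    assert s2.bias == pytest.approx(-5.0)
    assert s2.slope == pytest.approx(1.0)


def test_discrepancy_stats_recovers_configured_slope_exactly():
    t = exact_fixture(slope=0.5, intercept=10.0)
    s = discrepancy_stats(t, "sys")
    assert s.slope == pytest.approx(0.5, abs=1e-12)
    assert s.r_squared == pytest.approx(1.0, abs=1e-12)


def test_discrepancy_var_ratio_undefined_when_teachers_agree_exactly():
    s = discrepancy_stats(exact_fixture(), "sys")
    assert math.isnan(s.var_ratio)  # zero teacher-residual SD


def test_subgroup_deviations_recover_constructed_offsets():
    t = exact_fixture()
    # shift each group's teacher scores by a known offset: the AI-teacher
    # deviation then equals minus that offset
    offsets = {"direct": 2.0, "indirect": 0.0, "unfamiliar": -3.0}
    t = t.copy()
    for g, off in offsets.items():
        mask = (t["rater_kind"] == "human") & (t["familiarity_group"] == g)
        t.loc[mask, "score"] += off
    dev = subgroup_deviations(t, "sys")
    for g, off in offsets.items():
        # ref moved by mean(offsets)/1 too, but d_g compares AI to the
        # group's own scores: AI = true + mean_offset... recompute directly
        pass
    # direct construction: AI score is the ORIGINAL true value, so
    # d_g = true - (true + off) = -off up to the reference shift in AI? The
    # AI column was built from unshifted true values, hence exactly -off.
    assert dev["direct"] == pytest.approx(-2.0)
    assert dev["indirect"] == pytest.approx(0.0)
    assert dev["unfamiliar"] == pytest.approx(3.0)
    # invariant to row order
    dev2 = subgroup_deviations(t.sample(frac=1, random_state=1), "sys")
    assert dev2 == pytest.approx(dev)


def test_validate_scores_rejects_bad_tables():
    with pytest.raises(ValueError, match="missing columns"):
        validate_scores(pd.DataFrame({"unit_id": []}))
    bad_kind = exact_fixture().assign(rater_kind="robot")
    with pytest.raises(ValueError, match="rater_kind"):
        validate_scores(bad_kind)
    out_of_scale = exact_fixture()
    out_of_scale.loc[0, "score"] = 99.0
    with pytest.raises(ValueError, match="outside the declared scale"):
        validate_scores(out_of_scale)


# --------------------------------------------------------------- bootstrap


def noisy_fixture(rng, slope=0.5, noise=0.1):
    cfg = FixtureConfig(systems={"sys": AISystemConfig(
        intercept=45 * (1 - slope), slope=slope, noise_sd=noise)},
        teacher_sd=3.0)
    return make_fixture(cfg, rng=rng)


def test_bootstrap_is_seed_deterministic():
    t = noisy_fixture(np.random.default_rng(1))
    r1 = bootstrap_audit(t, "sys", B=200, rng=np.random.default_rng(9))
    r2 = bootstrap_audit(t, "sys", B=200, rng=np.random.default_rng(9))
    assert r1.bias_ci == r2.bias_ci
    assert r1.slope_ci == r2.slope_ci
    assert r1.p_compression == r2.p_compression


def test_bootstrap_ci_collapses_for_constant_shift():
    t = exact_fixture(intercept=-5.0)
    # add minute teacher noise so the variance ratio stays defined
    rng = np.random.default_rng(3)
    t = t.copy()
    human = t["rater_kind"] == "human"
    t.loc[human, "score"] += 1e-6 * rng.standard_normal(human.sum())
    res = bootstrap_audit(t, "sys", B=300, rng=np.random.default_rng(4))
    assert res.bias_ci[0] == pytest.approx(-5.0, abs=1e-4)
    assert res.bias_ci[1] == pytest.approx(-5.0, abs=1e-4)


def test_p_compression_near_one_for_strong_compression():
    t = noisy_fixture(np.random.default_rng(5), slope=0.5, noise=0.1)
    res = bootstrap_audit(t, "sys", B=500, rng=np.random.default_rng(6))
    assert res.p_compression > 0.95


def test_bootstrap_matches_tablewise_resampling_oracle():
    """The array fast path must equal recomputing discrepancy_stats on a
    materialised resampled table."""
    t = noisy_fixture(np.random.default_rng(7), slope=0.8, noise=2.0)
    units = sorted(t["unit_id"].unique())
    rng = np.random.default_rng(8)
    idx = rng.integers(0, len(units), size=len(units))
    parts = []
    for j, i in enumerate(idx):
        part = t[t["unit_id"] == units[i]].copy()
        part["unit_id"] = f"bs{j}"
        parts.append(part)
    resample = pd.concat(parts, ignore_index=True)
    want = discrepancy_stats(resample, "sys")
    # replay the fast path with the same draw
    res = bootstrap_audit(t, "sys", B=1,
                          rng=np.random.default_rng(8), match=False)
    assert res.bias_ci[0] == pytest.approx(want.bias, abs=1e-10)
    assert res.slope_ci[0] == pytest.approx(want.slope, abs=1e-10)
    assert res.var_ratio_ci[0] == pytest.approx(want.var_ratio, abs=1e-10)


def _coverage(n_units, n_draws, rng):
    true_bias, true_slope = -6.0, 0.7
    # fixture has true_mean 45: choose intercept so E[AI - true] = bias
    cfg = FixtureConfig(n_units=n_units, systems={"sys": AISystemConfig(
        intercept=true_bias + 45 * (1 - true_slope), slope=true_slope,
        noise_sd=2.0)}, teacher_sd=3.0)
    cover_bias = cover_slope = 0
    for _ in range(n_draws):
        t = make_fixture(cfg, rng=rng)
        res = bootstrap_audit(t, "sys", B=500, rng=rng, match=False)
        cover_bias += res.bias_ci[0] <= true_bias <= res.bias_ci[1]
        cover_slope += res.slope_ci[0] <= true_slope <= res.slope_ci[1]
    return cover_bias / n_draws, cover_slope / n_draws


def test_bootstrap_interval_coverage_on_fixture_draws():
    """Percentile CIs cover the configured bias and slope most of the
    time at the six-essay layout; unit-resampling percentile intervals
    are known to undercover the nominal 95% at n = 6, so the floor is
    0.80 there, and coverage must recover toward nominal at a larger
    unit count (the interval's validity regime)."""
    rng = np.random.default_rng(10)
    cb6, cs6 = _coverage(n_units=6, n_draws=200, rng=rng)
    assert cb6 >= 0.80 and cs6 >= 0.80
    cb24, cs24 = _coverage(n_units=24, n_draws=100, rng=rng)
    assert cb24 >= 0.90
    assert cs24 >= 0.80  # slope CI converges more slowly than the mean's
    assert cb24 > cb6 - 0.02  # calibration improves with units


# ---------------------------------------------------------------- matching


def test_match_condition_reproduces_reported_profiles():
    # strong negative bias, sub-unit variance ratio, compression and
    # fairness probabilities high -> (bias -0.5, mid variance, both flags)
    gpt_like = DiscrepancyStats(bias=-9.0, var_ratio=0.84, slope=0.50,
                                r_squared=0.79, pooled_teacher_sd=5.0,
                                n_units=6)
    cond = match_condition(gpt_like, p_compression=0.99, p_fairness=0.998)
    assert (cond.bias, cond.ai_var_level) == (-0.5, "mid")
    assert cond.compression and cond.fairness and not cond.imbalance
    assert cond.n == 100

    inflated = DiscrepancyStats(bias=-12.05, var_ratio=1.24, slope=0.67,
                                r_squared=0.48, pooled_teacher_sd=5.0,
                                n_units=6)
    cond2 = match_condition(inflated, p_compression=0.69, p_fairness=0.999)
    assert cond2.ai_var_level == "high"
    assert cond2.compression and cond2.fairness


def test_match_condition_identity_fixture_is_null_like():
    s = DiscrepancyStats(bias=0.0, var_ratio=0.0, slope=1.0, r_squared=1.0,
                         pooled_teacher_sd=3.0, n_units=6)
    cond = match_condition(s, p_compression=0.5, p_fairness=0.1)
    assert cond.bias == 0.0 and cond.ai_var_level == "low"
    assert not cond.compression and not cond.fairness


def test_match_condition_undefined_var_ratio_raises():
    s = DiscrepancyStats(bias=1.0, var_ratio=math.nan, slope=1.0,
                         r_squared=1.0, pooled_teacher_sd=0.0, n_units=6)
    with pytest.raises(ValueError, match="variance ratio undefined"):
        match_condition(s, 0.5, 0.5)


def test_match_recovers_clearly_separated_fixture_configs():
    """Fixture -> audit -> match recovers the configured regime when the
    configuration sits well inside a design cell."""
    rng = np.random.default_rng(12)
    cfg = FixtureConfig(n_units=6, teacher_sd=4.0, systems={"sys": AISystemConfig(
        intercept=-10.0 + 45 * (1 - 0.5), slope=0.5, noise_sd=1.0)})
    hits = 0
    for _ in range(20):
        t = make_fixture(cfg, rng=rng)
        res = bootstrap_audit(t, "sys", B=300, rng=rng)
        c = res.matched
        hits += (c is not None and c.bias == -0.5 and c.compression)
    assert hits >= 16  # small-n bootstrap noise allows a few misses


# ----------------------------------------------------------------- fixture


def test_default_fixture_shape_and_determinism():
    t1 = make_fixture(rng=np.random.default_rng(0))
    t2 = make_fixture(rng=np.random.default_rng(0))
    assert len(t1) == 30  # 6 units x (3 teachers + 2 systems)
    assert (t1["rater_kind"] == "human").sum() == 18
    assert (t1["rater_kind"] == "ai").sum() == 12
    pd.testing.assert_frame_equal(t1, t2)
    assert set(t1.loc[t1["rater_kind"] == "ai", "system_label"]) == {
        "gpt", "gemini"}


def test_zero_noise_fixture_recovers_configured_bias_and_slope():
    cfg = FixtureConfig(teacher_sd=0.0, systems={"sys": AISystemConfig(
        intercept=8.0, slope=0.9, noise_sd=0.0)})
    t = make_fixture(cfg, rng=np.random.default_rng(2))
    s = discrepancy_stats(t, "sys")
    assert s.slope == pytest.approx(0.9, abs=1e-9)
    # bias = intercept + (slope-1)*mean(true); compute from the table
    true = human_reference(t)
    want_bias = 8.0 + (0.9 - 1.0) * true.mean()
    assert s.bias == pytest.approx(want_bias, abs=1e-9)
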