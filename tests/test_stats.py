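"""Stage-2 statistics: ranges, repeated-measures ANOVA, post-hoc tests, regressions."""

import numpy as np
import pandas as pd
import pytest

from ictrack.stats import (
    delay_range,
    fit_rt2_regression,
    posthoc_by_isi,
    rm_anova,
    stage2_battery,
)


# ---------------------------------------------------------------------------
# percentile ranges
# ---------------------------------------------------------------------------

def test_delay_range_matches_percentile_oracle():
    vals = np.arange(0.1, 1.01, 0.1)  # ten points
    lo, hi = np.percentile(vals, [5, 95], method="linear")
    assert delay_range(vals) == pytest.approx(hi - lo, rel=1e-12)


def test_delay_range_degenerate_cases():
    assert delay_range([0.3, 0.3, 0.3]) == 0.0
    with pytest.raises(ValueError):
        delay_range([0.3])


def test_range_bounded_and_monotone_in_band():
    """Nested percentile bands give nested ranges, all within the full span."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        vals = rng.normal(size=12)
        r_5_95 = delay_range(vals)
        r_10_90 = delay_range(vals, lo=10, hi=90)
        full = vals.max() - vals.min()
        assert 0.0 <= r_10_90 <= r_5_95 <= full + 1e-12


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _random_table(rng, n_sub=6, n_a=2, n_b=4):
    rows = []
    for s in range(n_sub):
        base = rng.normal()
        for i in range(n_a):
            for j in range(n_b):
                rows.append(
                    {"participant": s, "A": i, "B": j,
                     "y": base + 0.4 * i + 0.15 * j + rng.normal() * 0.3}
                )
    return pd.DataFrame(rows)


def _brute_force_two_way(df):
    """Direct sums-of-squares oracle for a fully within 2-factor design."""
    Y = df.set_index(["participant", "A", "B"])["y"].unstack(["A", "B"])
    arr = Y.to_numpy().reshape(Y.shape[0], df["A"].nunique(), df["B"].nunique())
    S, a, b = arr.shape
    grand = arr.mean()
    m_s = arr.mean(axis=(1, 2))
    m_a = arr.mean(axis=(0, 2))
    m_b = arr.mean(axis=(0, 1))
    m_sa = arr.mean(axis=2)
    m_sb = arr.mean(axis=1)
    m_ab = arr.mean(axis=0)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_a = S * b * np.sum((m_a - grand) ** 2)
    ss_b = S * a * np.sum((m_b - grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_ab = S * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_tot = np.sum((arr - grand) ** 2)
    ss_sab = ss_tot - ss_s - ss_a - ss_b - ss_sa - ss_sb - ss_ab
    F_a = (ss_a / (a - 1)) / (ss_sa / ((a - 1) * (S - 1)))
    F_b = (ss_b / (b - 1)) / (ss_sb / ((b - 1) * (S - 1)))
    F_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_sab / ((a - 1) * (b - 1) * (S - 1)))
    return F_a, F_b, F_ab


def test_rm_anova_matches_brute_force_sums_of_squares():
    df = _random_table(np.random.default_rng(1))
    res = rm_anova(df, "y", within=["A", "B"])
    F_a, F_b, F_ab = _brute_force_two_way(df)
    assert res.loc["A", "F"] == pytest.approx(F_a, abs=1e-9)
    assert res.loc["B", "F"] == pytest.approx(F_b, abs=1e-9)
    assert res.loc["A * B", "F"] == pytest.approx(F_ab, abs=1e-9)


def test_rm_anova_matches_statsmodels_and_pingouin():
    from statsmodels.stats.anova import AnovaRM

    df = _random_table(np.random.default_rng(2))
    res = rm_anova(df, "y", within=["A", "B"])
    sm = AnovaRM(df, "y", "participant", within=["A", "B"]).fit().anova_table
    assert res.loc["A", "F"] == pytest.approx(sm.loc["A", "F Value"], rel=1e-9)
    assert res.loc["B", "F"] == pytest.approx(sm.loc["B", "F Value"], rel=1e-9)
    assert res.loc["A * B", "F"] == pytest.approx(sm.loc["A:B", "F Value"], rel=1e-9)

    import pingouin as pg

    wide = df.groupby(["participant", "B"])["y"].mean().unstack()
    assert res.loc["B", "eps_gg"] == pytest.approx(
        pg.epsilon(wide, correction="gg"), rel=1e-9
    )
    assert res.loc["B", "eps_hf"] == pytest.approx(
        pg.epsilon(wide, correction="hf"), rel=1e-9
    )


def test_zero_effect_gives_zero_f():
    """Identical RT1 and RT2 in every cell: Step effect F = 0, p = 1."""
    rng = np.random.default_rng(3)
    rows = []
    for s in range(5):
        for j, isi in enumerate([0.1, 0.2, 0.3]):
            val = rng.normal()
            for step in (1, 2):
                rows.append({"participant": s, "step": step, "isi_s": isi, "rt": val})
    res = rm_anova(pd.DataFrame(rows), "rt", within=["step", "isi_s"])
    assert res.loc["step", "F"] == 0.0
    assert res.loc["step", "p"] == 1.0


def test_two_level_factor_needs_no_correction():
    df = _random_table(np.random.default_rng(4))
    res = rm_anova(df, "y", within=["A", "B"])
    assert res.loc["A", "eps_used"] == 1.0
    assert res.loc["A", "df1_corr"] == res.loc["A", "df1"]


def test_incomplete_design_rejected_with_cells():
    df = _random_table(np.random.default_rng(5))
    df = df[~((df["participant"] == 0) & (df["A"] == 1) & (df["B"] == 2))]
    with pytest.raises(ValueError, match="missing cells"):
        rm_anova(df, "y", within=["A", "B"])


# ---------------------------------------------------------------------------
# post-hoc per ISI
# ---------------------------------------------------------------------------

def _delay_table(effects, n_sub=6, noise=0.005, seed=0):
    """Synthetic delay table: rt2 = rt1 + effect(isi)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        for isi, eff in effects.items():
            for rep in range(2):
                rt1 = 0.18 + rng.normal() * noise
                rows.append(
                    {"participant": s, "trial": rep, "pattern": "rev_RL",
                     "pattern_class": "reversed", "isi_s": isi,
                     "rt1_s": rt1, "rt2_s": rt1 + eff + rng.normal() * noise,
                     "residual": 0.0, "flags": ""}
                )
    return pd.DataFrame(rows)


ZERO_GRID = [0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.50, 1.00]


def test_metric_is_largest_contiguously_significant_isi():
    effects = {isi: (0.33 - isi if isi <= 0.25 else 0.0) for isi in ZERO_GRID}
    post = posthoc_by_isi(_delay_table(effects))
    assert post.anova_metric == pytest.approx(0.25)
    assert post.anova_metric_interp == pytest.approx((0.25 + 0.30) / 2)
    assert not post.unbounded
    assert post.interfered_isis == (0.05, 0.10, 0.15, 0.20, 0.25)


def test_metric_zero_when_nothing_significant():
    post = posthoc_by_isi(_delay_table({isi: 0.0 for isi in ZERO_GRID}))
    assert post.anova_metric == 0.0
    assert post.interfered_isis == ()


def test_metric_flags_unbounded_when_everything_significant():
    post = posthoc_by_isi(_delay_table({isi: 0.1 for isi in ZERO_GRID}))
    assert post.unbounded
    assert post.anova_metric == pytest.approx(1.0)


def test_posthoc_needs_three_participants():
    with pytest.raises(ValueError):
        posthoc_by_isi(_delay_table({0.1: 0.1, 0.2: 0.0}, n_sub=2))


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def test_max_increase_reproduces_first_order_arithmetic():
    """Intercept 434 ms minus mean RT1 230 ms gives a 204 ms maximum increase."""
    isis = np.array([0.10, 0.15, 0.20, 0.25, 0.35])
    rt2 = 0.434 - 1.0 * isis
    res = fit_rt2_regression(pd.Series(rt2, index=isis), isis, mean_rt1=0.230)
    assert res.intercept == pytest.approx(0.434, abs=1e-12)
    assert res.max_increase == pytest.approx(0.204, abs=1e-12)


def test_exact_line_gives_matching_constrained_fit():
    isis = np.array([0.05, 0.10, 0.20, 0.30])
    C = 0.49
    rt2 = C - isis
    res = fit_rt2_regression(pd.Series(rt2, index=isis), isis, mean_rt1=0.14)
    assert res.slope == pytest.approx(-1.0, abs=1e-12)
    assert res.intercept == pytest.approx(C, abs=1e-12)
    assert res.constrained_intercept == pytest.approx(C, abs=1e-12)
    assert res.constrained_duration == pytest.approx(C - 0.14, abs=1e-12)


def test_empty_interfered_set_reports_absent_metrics():
    res = fit_rt2_regression(pd.Series({0.1: 0.2}), [], mean_rt1=0.15)
    assert res.slope is None and res.max_increase is None
    assert res.constrained_duration is None


def test_single_interfered_isi_supports_only_constrained_fit():
    res = fit_rt2_regression(pd.Series({0.1: 0.4}), [0.1], mean_rt1=0.15)
    assert res.slope is None
    assert res.constrained_intercept == pytest.approx(0.5)
    assert res.constrained_duration == pytest.approx(0.35)


# ---------------------------------------------------------------------------
# the six-test battery
# ---------------------------------------------------------------------------

def test_battery_detects_simulated_refractoriness():
    effects = {isi: max(0.0, 0.35 - isi) for isi in ZERO_GRID}
    battery = stage2_battery(_delay_table(effects, noise=0.004))
    assert battery["any_refractoriness"]
    assert battery["step_isi_interaction"]["refractory"]
    assert battery["anova_metric"] > 0
    assert battery["regression"].slope == pytest.approx(-1.0, abs=0.05)


def test_battery_clean_on_null_data():
    battery = stage2_battery(_delay_table({isi: 0.0 for isi in ZERO_GRID}, noise=0.003))
    assert not battery["any_refractoriness"]
    assert battery["anova_metric"] == 0.0
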