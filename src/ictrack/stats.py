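"""Stage 2: distributions, repeated-measures ANOVA and RT2 regressions.

The unit of analysis is the delay table produced by stage 1: one row per
step pair with participant, pattern class, ISI and the reconstructed RT1
and RT2.  Repetitions are averaged within participant before testing, so
every test treats participants as the random factor.

The repeated-measures ANOVA is fully within-subject; every effect with
more than two levels has its degrees of freedom multiplied by the average
of the Greenhouse-Geisser and Huynh-Feldt sphericity estimates.  The
per-ISI post-hoc comparisons are uncorrected two-tailed paired t-tests,
mirroring the convention of reporting raw per-ISI p-values; a Holm option
is available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import null_space

__all__ = [
    "delay_range",
    "rm_anova",
    "posthoc_by_isi",
    "PosthocResult",
    "RegressionResult",
    "fit_rt2_regression",
    "participant_isi_means",
    "stage2_battery",
]

_ZERO_VAR_TOL = 1e-12


def delay_range(values, lo: float = 5.0, hi: float = 95.0) -> float:
    """Percentile range (default 5th to 95th, linear interpolation)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values for a percentile range")
    p_lo, p_hi = np.percentile(v, [lo, hi], method="linear")
    return float(p_hi - p_lo)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels x levels-1) orthonormal basis orthogonal to the constant."""
    return null_space(np.ones((1, levels)))


def _hf_epsilon(gg: float, n_subjects: int, d: int) -> float:
    num = n_subjects * d * gg - 2.0
    den = d * (n_subjects - 1 - d * gg)
    if den <= 0:
        return 1.0
    return min(1.0, num / den)


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "participant",
) -> pd.DataFrame:
    """Fully within-subject repeated-measures ANOVA.

    ``table`` is long-format; replicate rows per subject x cell are averaged
    first.  For every main effect and interaction the classical F is
    computed from contrast-projected scores (error term: effect x subject),
    and the averaged Greenhouse-Geisser / Huynh-Feldt epsilon is applied to
    both degrees of freedom for effects with more than two levels.

    Returns a data frame indexed by effect with columns ``F``, ``df1``,
    ``df2``, ``eps_gg``, ``eps_hf``, ``eps_used``, ``df1_corr``,
    ``df2_corr``, ``p_uncorrected`` and ``p``.
    """
    if len(within) == 0:
        raise ValueError("need at least one within factor")
    cell = table.groupby([subject] + within, sort=True)[dv].mean()
    wide = cell.unstack(within)  # subjects x full cell grid
    if wide.isna().any().any():
        missing = [
            tuple(col) if isinstance(col, tuple) else (col,)
            for col in wide.columns[wide.isna().any(axis=0)]
        ]
        raise ValueError(f"incomplete within-subject design; missing cells: {missing}")
    n = wide.shape[0]
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs at least two subjects")
    if len(within) > 1:
        levels = {f: list(dict.fromkeys(wide.columns.get_level_values(i)))
                  for i, f in enumerate(within)}
        full_cols = pd.MultiIndex.from_product([levels[f] for f in within],
                                               names=within)
        Y = wide.reindex(columns=full_cols).to_numpy()
    else:
        levels = {within[0]: list(wide.columns)}
        Y = wide.to_numpy()

    rows = []
    for r in range(1, len(within) + 1):
        for effect in itertools.combinations(within, r):
            mats = []
            m_rest = 1
            for f in within:
                lf = len(levels[f])
                if f in effect:
                    mats.append(_orthonormal_contrasts(lf))
                else:
                    mats.append(np.full((lf, 1), 1.0 / lf))
                    m_rest *= lf
            C = mats[0]
            for M in mats[1:]:
                C = np.kron(C, M)
            Z = math.sqrt(m_rest) * (Y @ C)  # subjects x d
            d = Z.shape[1]
            zbar = Z.mean(axis=0)
            ss_eff = n * float(zbar @ zbar)
            dev = Z - zbar
            ss_err = float((dev * dev).sum())
            df1 = d
            df2 = d * (n - 1)
            scale = max(float((Z * Z).sum()), 1.0)
            if ss_err <= _ZERO_VAR_TOL * scale:
                if ss_eff <= _ZERO_VAR_TOL * scale:
                    F, p_unc = 0.0, 1.0
                else:
                    F, p_unc = math.inf, 0.0
                gg = hf = eps = 1.0
                p = p_unc
            else:
                F = (ss_eff / df1) / (ss_err / df2)
                if d > 1:
                    S = (dev.T @ dev) / (n - 1)
                    tr = float(np.trace(S))
                    tr2 = float(np.trace(S @ S))
                    gg = (tr * tr) / (d * tr2) if tr2 > 0 else 1.0
                    hf = _hf_epsilon(gg, n, d)
                else:
                    gg = hf = 1.0
                eps = min(1.0, 0.5 * (gg + hf))
                p_unc = float(sps.f.sf(F, df1, df2))
                p = float(sps.f.sf(F, eps * df1, eps * df2))
            rows.append(
                {
                    "effect": " * ".join(effect),
                    "F": F,
                    "df1": df1,
                    "df2": df2,
                    "eps_gg": gg,
                    "eps_hf": hf,
                    "eps_used": eps,
                    "df1_corr": eps * df1,
                    "df2_corr": eps * df2,
                    "p_uncorrected": p_unc,
                    "p": p,
                }
            )
    return pd.DataFrame(rows).set_index("effect")


# ---------------------------------------------------------------------------
# per-ISI post-hoc tests
# ---------------------------------------------------------------------------

def participant_isi_means(
    table: pd.DataFrame,
    pattern_class: str | None = None,
) -> pd.DataFrame:
    """Average repetitions within participant x ISI (optionally one class).

    Returns a frame indexed by (participant, isi_s) with mean ``rt1_s`` and
    ``rt2_s`` columns.
    """
    t = table if pattern_class is None else table[table["pattern_class"] == pattern_class]
    if t.empty:
        raise ValueError("no rows for the requested pattern class")
    return t.groupby(["participant", "isi_s"])[["rt1_s", "rt2_s"]].mean()


@dataclass
class PosthocResult:
    """Per-ISI paired comparisons and the derived refractory-duration metric."""

    per_isi: pd.DataFrame        # indexed by isi_s: mean_rt1, mean_rt2, t, p, significant
    anova_metric: float          # s: largest ISI with contiguous significance from below
    anova_metric_interp: float   # s: midpoint interpolation variant
    unbounded: bool              # every ISI significant (metric hit the grid edge)
    interfered_isis: tuple[float, ...]


def _paired_p(diff: np.ndarray) -> tuple[float, float]:
    """Two-tailed paired t-test on difference scores, safe for zero variance."""
    n = diff.size
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd < _ZERO_VAR_TOL * max(1.0, abs(mean)):
        # all participants show the identical difference: degenerate t
        if abs(mean) > 1e-9:
            return math.inf, 0.0
        return 0.0, 1.0
    t = mean / (sd / math.sqrt(n))
    p = 2 * float(sps.t.sf(abs(t), n - 1))
    return t, p


def posthoc_by_isi(
    table: pd.DataFrame,
    pattern_class: str | None = None,
    alpha: float = 0.05,
    holm: bool = False,
) -> PosthocResult:
    """Paired RT2-vs-RT1 comparison at each ISI across participants.

    An ISI is *interfered* when the test is significant at ``alpha`` and RT2
    exceeds RT1.  The ANOVA metric is the largest ISI such that it and every
    smaller ISI are interfered (0 when none are); the interpolated variant
    places the refractory boundary midway between the last interfered and
    the first non-interfered ISI.
    """
    means = participant_isi_means(table, pattern_class)
    wide1 = means["rt1_s"].unstack("isi_s")
    wide2 = means["rt2_s"].unstack("isi_s")
    if wide1.shape[0] < 3:
        raise ValueError("per-ISI post-hoc tests need at least three participants")
    isis = np.array(sorted(wide1.columns))
    rows = []
    for isi in isis:
        diff = (wide2[isi] - wide1[isi]).to_numpy(dtype=float)
        t, p = _paired_p(diff)
        rows.append(
            {
                "isi_s": isi,
                "mean_rt1": float(wide1[isi].mean()),
                "mean_rt2": float(wide2[isi].mean()),
                "diff": float(diff.mean()),
                "t": t,
                "p": p,
            }
        )
    per = pd.DataFrame(rows).set_index("isi_s")
    if holm:
        order = np.argsort(per["p"].to_numpy())
        m = len(per)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * per["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        per["p"] = adj
    per["significant"] = (per["p"] < alpha) & (per["diff"] > 0)

    sig = per["significant"].to_numpy()
    metric = 0.0
    last_idx = -1
    for i, isi in enumerate(isis):
        if sig[i]:
            metric = float(isi)
            last_idx = i
        else:
            break
    unbounded = bool(sig.all())
    if last_idx < 0:
        interp = 0.0
    elif unbounded:
        interp = float(isis[-1])
    else:
        interp = float(0.5 * (isis[last_idx] + isis[last_idx + 1]))
    interfered = tuple(float(i) for i, s in zip(isis, sig) if s)
    return PosthocResult(
        per_isi=per,
        anova_metric=metric,
        anova_metric_interp=interp,
        unbounded=unbounded,
        interfered_isis=interfered,
    )


# ---------------------------------------------------------------------------
# RT2 regressions
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """RT2-vs-ISI regression over the interfered ISIs."""

    slope: float | None
    intercept: float | None          # value of the line at ISI = 0
    slope_se: float | None
    n_points: int
    max_increase: float | None       # unconstrained intercept minus mean RT1
    constrained_intercept: float | None
    constrained_duration: float | None  # ISI where the slope -1 line meets mean RT1


def fit_rt2_regression(
    mean_rt2_by_isi: "pd.Series | dict[float, float]",
    interfered_isis,
    mean_rt1: float,
    constrain_slope: float | None = None,
) -> RegressionResult:
    """Fit mean RT2 against ISI over the interfered ISIs.

    Unconstrained: ordinary least squares; the refractory extent is the
    intercept at ISI = 0 minus the mean RT1 baseline.  With
    ``constrain_slope = -1`` (the single-channel prediction) the least-
    squares intercept is ``mean(RT2 + ISI)`` and the refractory duration is
    that intercept minus mean RT1 (the ISI at which the line crosses the
    RT1 baseline).  Both variants are always reported when computable.
    """
    s = pd.Series(dict(mean_rt2_by_isi)) if not isinstance(mean_rt2_by_isi, pd.Series) \
        else mean_rt2_by_isi
    isis = np.array(sorted(float(i) for i in interfered_isis))
    isis = isis[np.isin(isis, np.asarray(s.index, dtype=float))]
    if isis.size == 0:
        return RegressionResult(None, None, None, 0, None, None, None)
    rt2 = s.loc[isis].to_numpy(dtype=float)

    c_int = float(np.mean(rt2 + isis))
    c_dur = c_int - mean_rt1

    slope = intercept = slope_se = max_inc = None
    if constrain_slope is not None and constrain_slope != -1:
        raise ValueError("only a slope constraint of -1 is supported")
    if isis.size >= 2:
        res = sps.linregress(isis, rt2)
        slope = float(res.slope)
        intercept = float(res.intercept)
        slope_se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        max_inc = intercept - mean_rt1
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        n_points=int(isis.size),
        max_increase=max_inc,
        constrained_intercept=c_int,
        constrained_duration=c_dur,
    )


# ---------------------------------------------------------------------------
# the six-test battery
# ---------------------------------------------------------------------------

def stage2_battery(
    table: pd.DataFrame,
    pattern_class: str | None = None,
    alpha: float = 0.05,
    grid_step: float = 0.01,
) -> dict:
    """The six refractoriness tests on one condition's delay table.

    1. Are the 5-95% ranges of RT1 and RT2 equal?
    2. Is RT2 greater than RT1 (Step Number main effect)?
    3. Is there a Step Number x ISI interaction?
    4. Is RT1 independent of ISI?
    5. Up to which ISI is RT2 significantly greater than RT1?
    6. What is the maximum increase in RT2 (unconstrained regression
       intercept minus mean RT1)?

    Returns a structured report; ``any_refractoriness`` summarises whether
    the battery rejects the continuous (zero-refractoriness) hypothesis.
    """
    t = table if pattern_class is None else table[table["pattern_class"] == pattern_class]
    if t.empty:
        raise ValueError("no rows for the requested pattern class")

    # 1: participant-wise 5-95% ranges, pooled over ISIs and repetitions
    by_p = t.groupby("participant")
    r1 = by_p["rt1_s"].apply(lambda v: delay_range(v.to_numpy()))
    r2 = by_p["rt2_s"].apply(lambda v: delay_range(v.to_numpy()))
    _, p_rng = _paired_p((r2 - r1).to_numpy(dtype=float))
    rng_diff = float((r2 - r1).mean())
    ranges_equal = abs(rng_diff) <= grid_step
    ranges = {
        "mean_range_rt1": float(r1.mean()),
        "mean_range_rt2": float(r2.mean()),
        "difference": rng_diff,
        "p": p_rng,
        "equal_within_grid_step": ranges_equal,
        "refractory": (not ranges_equal) and p_rng < alpha,
    }

    # 2 & 3: Step x ISI repeated-measures ANOVA
    means = participant_isi_means(t).reset_index()
    long = means.melt(
        id_vars=["participant", "isi_s"],
        value_vars=["rt1_s", "rt2_s"],
        var_name="step",
        value_name="rt",
    )
    long["step"] = long["step"].map({"rt1_s": 1, "rt2_s": 2})
    anova = rm_anova(long, dv="rt", within=["step", "isi_s"])
    step_p = float(anova.loc["step", "p"])
    inter_p = float(anova.loc["step * isi_s", "p"])
    mean_rt1 = float(t["rt1_s"].mean())
    mean_rt2 = float(t["rt2_s"].mean())
    step_effect = {
        "mean_rt1": mean_rt1,
        "mean_rt2": mean_rt2,
        "F": float(anova.loc["step", "F"]),
        "p": step_p,
        "refractory": step_p < alpha and mean_rt2 > mean_rt1,
    }
    interaction = {
        "F": float(anova.loc["step * isi_s", "F"]),
        "p": inter_p,
        "refractory": inter_p < alpha,
    }

    # 4: RT1 against ISI (one-way within)
    rt1_anova = rm_anova(means, dv="rt1_s", within=["isi_s"])
    rt1_p = float(rt1_anova.loc["isi_s", "p"])
    rt1_vs_isi = {
        "F": float(rt1_anova.loc["isi_s", "F"]),
        "p": rt1_p,
        "rt1_independent_of_isi": rt1_p >= alpha,
    }

    # 5: per-ISI post-hoc and the ANOVA metric
    post = posthoc_by_isi(t, alpha=alpha)

    # 6: regression over interfered ISIs
    reg = fit_rt2_regression(
        post.per_isi["mean_rt2"], post.interfered_isis, mean_rt1
    )

    any_refr = (
        ranges["refractory"]
        or step_effect["refractory"]
        or interaction["refractory"]
        or post.anova_metric > 0
    )
    return {
        "ranges": ranges,
        "step_effect": step_effect,
        "step_isi_interaction": interaction,
        "rt1_vs_isi": rt1_vs_isi,
        "posthoc": post,
        "anova": anova,
        "regression": reg,
        "anova_metric": post.anova_metric,
        "any_refractoriness": bool(any_refr),
    }
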