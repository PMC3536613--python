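"""Stage 3: refractory-duration metrics and triggering-regime classification.

Four estimates of the refractory duration are combined:

* the **ANOVA metric** -- the ISI up to which RT2 is significantly delayed
  relative to RT1;
* the intercept of the **unconstrained** RT2-vs-ISI regression (minus the
  mean RT1 baseline, the "maximum increase in RT2");
* the intercept of the **slope -1** constrained fit (minus mean RT1), the
  single-channel estimate of the open-loop interval;
* the 5-95% **range of RT2** pooled over the interfered ISIs.

The slope of the unconstrained regression classifies the event-triggering
regime: -1 for external triggering at one event per step, -1/2 for
internal triggering saturated at the maximal rate the open-loop interval
permits, 0 for continuous control, intermediate values for mixed regimes.
An interior peak of mean RT2 over ISI, when present, estimates a sampling
delay (responses to step pairs closer than it merge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import RegressionResult, delay_range, fit_rt2_regression, stage2_battery

__all__ = [
    "RefractoryReport",
    "classify_triggering",
    "estimate_sampling_delay",
    "refractory_estimates",
]

TRIGGERING_CLASSES = ("external", "internal_saturated", "mixed", "continuous")


@dataclass
class RefractoryReport:
    """Per-condition stage-3 summary."""

    condition: str
    mean_rt1: float
    mean_rt2_by_isi: dict[float, float]
    range_rt1: float
    range_rt2: float
    anova: "pd.DataFrame"
    metric_anova: float
    slope_unconstrained: float | None
    slope_se: float | None
    intercept_unconstrained: float | None
    max_increase: float | None
    intercept_constrained: float | None
    duration_constrained: float | None
    metric_range_rt2: float | None
    triggering_class: str
    sampling_delay_estimate: float | None
    battery: dict = field(repr=False, default_factory=dict)

    def metrics(self) -> dict[str, float | None]:
        """The four refractory-duration estimates (s)."""
        return {
            "anova_metric": self.metric_anova,
            "max_increase": self.max_increase,
            "duration_constrained": self.duration_constrained,
            "range_rt2": self.metric_range_rt2,
        }

    def to_markdown(self) -> str:
        lines = [
            f"## Refractory-duration report: {self.condition}",
            "",
            f"mean RT1 (baseline): {self.mean_rt1 * 1e3:.0f} ms",
            "",
            "| metric | value (ms) |",
            "|---|---|",
        ]
        for name, val in self.metrics().items():
            shown = "absent" if val is None else f"{val * 1e3:.0f}"
            lines.append(f"| {name} | {shown} |")
        lines += [
            "",
            f"unconstrained slope: "
            + ("absent" if self.slope_unconstrained is None
               else f"{self.slope_unconstrained:.3f}"),
            f"triggering class: {self.triggering_class}",
            f"sampling delay estimate: "
            + ("absent" if self.sampling_delay_estimate is None
               else f"{self.sampling_delay_estimate * 1e3:.0f} ms"),
        ]
        return "\n".join(lines)


def classify_triggering(
    slope: float | None,
    slope_se: float | None,
    dof: int | None = None,
    conf: float = 0.95,
) -> str:
    """Classify the triggering regime from the unconstrained slope.

    Uses the confidence interval of the slope: ``external`` when it covers
    -1 but not -1/2, ``internal_saturated`` when it covers -1/2 but not -1,
    ``continuous`` when it covers 0 but not -1/2, and ``mixed`` otherwise
    (including boundary overlaps).
    """
    if slope is None:
        return "continuous"
    se = slope_se or 0.0
    if dof is not None and dof > 0:
        crit = float(sps.t.ppf(0.5 + conf / 2, dof))
    else:
        crit = float(sps.norm.ppf(0.5 + conf / 2))
    lo, hi = slope - crit * se, slope + crit * se

    def covers(v: float) -> bool:
        return lo - 1e-12 <= v <= hi + 1e-12

    if covers(-1.0) and not covers(-0.5):
        return "external"
    if covers(-0.5) and not covers(-1.0):
        return "internal_saturated"
    if covers(0.0) and not covers(-0.5):
        return "continuous"
    return "mixed"


def estimate_sampling_delay(mean_rt2_by_isi) -> float | None:
    """Interior ISI at which mean RT2 peaks, or ``None`` when monotone.

    The peak must strictly exceed both neighbours (no plateau or boundary
    peaks); it estimates the sampling delay of the event trigger, below
    which responses to the two steps merge.
    """
    s = pd.Series(dict(mean_rt2_by_isi)) if not isinstance(mean_rt2_by_isi, pd.Series) \
        else mean_rt2_by_isi
    s = s.sort_index()
    if len(s) < 3:
        raise ValueError("peak detection needs at least three ISI levels")
    v = s.to_numpy(dtype=float)
    interior = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1
    if interior.size == 0:
        return None
    best = interior[np.argmax(v[interior])]
    return float(s.index[best])


def refractory_estimates(
    table: pd.DataFrame,
    pattern_class: str | None = "reversed",
    condition: str = "",
    alpha: float = 0.05,
    grid_step: float = 0.01,
) -> RefractoryReport:
    """Run stage 2 on one condition's delay table and assemble stage 3.

    ``pattern_class`` selects the reversed or unidirectional step pairs
    (``None`` pools both).  All four refractory-duration metrics are
    populated where defined; undefined metrics are reported as absent.
    """
    battery = stage2_battery(
        table, pattern_class=pattern_class, alpha=alpha, grid_step=grid_step
    )
    post = battery["posthoc"]
    reg: RegressionResult = battery["regression"]
    t = table if pattern_class is None else table[table["pattern_class"] == pattern_class]
    mean_rt1 = float(t["rt1_s"].mean())
    mean_rt2_by_isi = {float(i): float(v) for i, v in post.per_isi["mean_rt2"].items()}

    if post.interfered_isis:
        pooled_rt2 = t[t["isi_s"].isin(post.interfered_isis)]["rt2_s"].to_numpy()
        metric_range = delay_range(pooled_rt2) if pooled_rt2.size >= 2 else None
    else:
        metric_range = None

    dof = reg.n_points - 2 if reg.n_points >= 2 else None
    triggering = classify_triggering(reg.slope, reg.slope_se, dof)
    try:
        peak = estimate_sampling_delay(post.per_isi["mean_rt2"])
    except ValueError:
        peak = None

    return RefractoryReport(
        condition=condition,
        mean_rt1=mean_rt1,
        mean_rt2_by_isi=mean_rt2_by_isi,
        range_rt1=battery["ranges"]["mean_range_rt1"],
        range_rt2=battery["ranges"]["mean_range_rt2"],
        anova=battery["anova"],
        metric_anova=post.anova_metric,
        slope_unconstrained=reg.slope,
        slope_se=reg.slope_se,
        intercept_unconstrained=reg.intercept,
        max_increase=reg.max_increase,
        intercept_constrained=reg.constrained_intercept,
        duration_constrained=reg.constrained_duration,
        metric_range_rt2=metric_range,
        triggering_class=triggering,
        sampling_delay_estimate=peak,
        battery=battery,
    )
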