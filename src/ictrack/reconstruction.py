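"""Stage 1: response delays by set-point reconstruction.

The closed-loop relationship between the piecewise-constant target and the
recorded control (joystick) signal is modelled as a low-order, *zero
dead-time* linear time-invariant map.  Response delays are then estimated
by shifting the instants of the target steps and scoring each candidate
reconstruction by the residual of the LTI fit:

* the **time-invariant** stage shifts all steps equally (the common delay
  of the whole response);
* the **non-time-invariant** stage then adjusts each step instant
  individually, sequentially and in repeated passes, yielding one delay per
  step (RT1, RT2, ...).

Because the scoring model is all-pole with a direct feedthrough term
(``u[t] = sum a_i u[t-i] + b0 w[t] (+ c)``), it has no dead-time capacity
of its own: any latency in the data must be explained by the explicit step
shifts, which makes the delay estimates identifiable.  The general
rational-model fit (numerator of arbitrary span) is available through
:func:`fit_lti_map` for model-order diagnostics.

Signals are decimated from the simulation rate (1 kHz) to an
identification rate (default 100 Hz) by block averaging, which commutes
with shifts that are multiples of the identification step and attenuates
white measurement noise by the decimation factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stimulus import StepSequence, pattern_class

__all__ = [
    "LTIFit",
    "StepDelayEstimate",
    "TrialReconstruction",
    "block_decimate",
    "render_steps",
    "fit_lti_map",
    "aic_by_order",
    "estimate_common_delay",
    "reconstruct_step_delays",
    "reconstruct_trial",
    "extract_rt_pairs",
    "delay_table",
]

DEFAULT_DT_ID = 0.01       # s, identification sample step (100 Hz)
DEFAULT_MAX_DELAY = 1.5    # s, upper end of the delay search range
DEFAULT_ORDER = 10


@dataclass
class LTIFit:
    """Least-squares rational input-output model of one trial."""

    order: int
    a: np.ndarray               # denominator (AR) coefficients a[1..na]
    b: np.ndarray               # numerator (input) coefficients b[0..nb-1]
    intercept: float
    common_delay: float         # s, shift applied to all steps for this fit
    residual_variance: float
    aic: float
    n_samples: int


@dataclass
class StepDelayEstimate:
    """Reconstructed RT1/RT2 for one step pair of one trial."""

    participant: int | str
    trial: int
    pattern: str
    pattern_class: str
    isi: float
    rt1: float
    rt2: float
    residual: float
    flags: tuple[str, ...] = ()


@dataclass
class TrialReconstruction:
    """Per-step delays and diagnostics for one trial."""

    delays: np.ndarray          # s, one per target step
    residual: float
    common_delay: float
    converged: bool
    flags: tuple[str, ...] = ()
    fit: LTIFit | None = None


def block_decimate(x: np.ndarray, factor: int) -> np.ndarray:
    """Decimate by averaging consecutive blocks of ``factor`` samples."""
    x = np.asarray(x, dtype=float)
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if factor == 1:
        return x.copy()
    m = x.size // factor
    if m == 0:
        raise ValueError("series shorter than one decimation block")
    return x[: m * factor].reshape(m, factor).mean(axis=1)


def render_steps(times, levels, dt: float, n: int) -> np.ndarray:
    """Render a piecewise-constant target with steps at ``times`` (s).

    Steps are applied in chronological order (stable for coincident
    instants, so a reversal whose steps collapse onto the same sample
    renders flat).  Steps at or beyond the end of the window are ignored.
    """
    w = np.zeros(n)
    order = np.argsort(times, kind="stable")
    for idx in order:
        i = int(round(times[idx] / dt))
        if i < n:
            w[max(i, 0):] = levels[idx]
    return w


# ---------------------------------------------------------------------------
# LTI fitting
# ---------------------------------------------------------------------------

def _lag_matrix(y: np.ndarray, w: np.ndarray, na: int, nb: int,
                start: int, fit_intercept: bool) -> tuple[np.ndarray, np.ndarray]:
    """Regression target and design matrix for the ARX-style fit.

    Rows are samples ``t = start .. T-1``; columns are ``y[t-1..t-na]``,
    ``w[t..t-(nb-1)]`` and optionally a constant.
    """
    T = y.size
    if w.size != T:
        raise ValueError("target and response series must have equal length")
    if start < max(na, nb - 1):
        raise ValueError("start index must cover the longest lag")
    if T - start < na + nb + 2:
        raise ValueError("series too short for the requested model order")
    rows = T - start
    ncol = na + nb + (1 if fit_intercept else 0)
    X = np.empty((rows, ncol))
    for i in range(na):
        X[:, i] = y[start - 1 - i : T - 1 - i]
    for j in range(nb):
        X[:, na + j] = w[start - j : T - j]
    if fit_intercept:
        X[:, -1] = 1.0
    return y[start:], X


def fit_lti_map(
    target: np.ndarray,
    response: np.ndarray,
    order: int = DEFAULT_ORDER,
    nb: int | None = None,
    fit_intercept: bool = True,
    start: int | None = None,
    common_delay: float = 0.0,
) -> LTIFit:
    """Least-squares rational model from target to response (zero dead time).

    ``order`` is the denominator (AR) order; ``nb`` the number of numerator
    coefficients ``b[0..nb-1]`` (defaults to ``order + 1``, the full rational
    model).  Both series must already be at the identification rate.
    """
    y = np.asarray(response, dtype=float)
    w = np.asarray(target, dtype=float)
    na = int(order)
    nb = na + 1 if nb is None else int(nb)
    if na < 0 or nb < 1:
        raise ValueError("order must be >= 0 and nb >= 1")
    s = max(na, nb - 1) if start is None else int(start)
    yy, X = _lag_matrix(y, w, na, nb, s, fit_intercept)
    if not np.any(np.abs(X) > 0):
        raise ValueError("degenerate regression: all regressors are zero")
    theta, _, rank, sv = np.linalg.lstsq(X, yy, rcond=None)
    resid = yy - X @ theta
    m = yy.size
    ssr = float(resid @ resid)
    sigma2 = ssr / m
    k_par = X.shape[1]
    aic = m * math.log(max(sigma2, 1e-300)) + 2 * k_par
    return LTIFit(
        order=na,
        a=theta[:na].copy(),
        b=theta[na : na + nb].copy(),
        intercept=float(theta[-1]) if fit_intercept else 0.0,
        common_delay=common_delay,
        residual_variance=sigma2,
        aic=aic,
        n_samples=m,
    )


def aic_by_order(
    target: np.ndarray,
    response: np.ndarray,
    orders=range(1, 13),
    fit_intercept: bool = True,
) -> dict[int, float]:
    """AIC of the rational fit over candidate model orders (common support).

    Used as the working check that the default 10th-order model does not
    exceed the information-criterion optimum by a meaningful margin.
    """
    orders = list(orders)
    s = max(orders)  # common start so fits share their sample support
    out = {}
    for n in orders:
        out[n] = fit_lti_map(
            target, response, order=n, fit_intercept=fit_intercept, start=s
        ).aic
    return out


# ---------------------------------------------------------------------------
# delay optimization
# ---------------------------------------------------------------------------

class _DelayScorer:
    """Scores candidate step-shift configurations for one trial.

    The response is decimated once; the fixed (response-lag and intercept)
    Gram blocks are precomputed, and each candidate target only contributes
    its cross- and auto-products, so one score costs a small matrix solve.
    """

    def __init__(
        self,
        response: np.ndarray,
        seq: StepSequence,
        dt: float,
        dt_id: float = DEFAULT_DT_ID,
        order: int = DEFAULT_ORDER,
        fit_intercept: bool = True,
    ):
        factor = int(round(dt_id / dt))
        if not math.isclose(factor * dt, dt_id, rel_tol=1e-9):
            raise ValueError("dt_id must be an integer multiple of dt")
        self.dt = dt
        self.dt_id = dt_id
        self.factor = factor
        self.seq = seq
        self.na = int(order)
        self.nb = 1  # zero-dead-time scoring model: b0 only
        self.fit_intercept = fit_intercept
        self.u_sim_len = np.asarray(response).size
        self.u = block_decimate(response, factor)
        self.start = self.na
        T = self.u.size
        if T - self.start < self.na + 4:
            raise ValueError("trial too short for delay reconstruction")
        rows = T - self.start
        Xu = np.empty((rows, self.na + (1 if fit_intercept else 0)))
        for i in range(self.na):
            Xu[:, i] = self.u[self.start - 1 - i : T - 1 - i]
        if fit_intercept:
            Xu[:, -1] = 1.0
        self.Xu = Xu
        self.yy = self.u[self.start :]
        self.Guu = Xu.T @ Xu
        self.gu = Xu.T @ self.yy
        self.yty = float(self.yy @ self.yy)
        self.rows = rows

    def target_for(self, delays: np.ndarray) -> np.ndarray:
        """Decimated reconstructed target for per-step shifts ``delays``."""
        times = np.asarray(self.seq.step_times) + np.asarray(delays)
        w_sim = render_steps(times, self.seq.step_levels, self.dt, self.u_sim_len)
        return block_decimate(w_sim, self.factor)

    def ssr(self, delays: np.ndarray) -> float:
        """Sum of squared one-step residuals for a candidate configuration."""
        w = self.target_for(delays)
        wcol = w[self.start :]
        nfix = self.Xu.shape[1]
        G = np.empty((nfix + 1, nfix + 1))
        G[:nfix, :nfix] = self.Guu
        cross = self.Xu.T @ wcol
        G[:nfix, nfix] = cross
        G[nfix, :nfix] = cross
        G[nfix, nfix] = wcol @ wcol
        g = np.empty(nfix + 1)
        g[:nfix] = self.gu
        g[nfix] = wcol @ self.yy
        theta, *_ = np.linalg.lstsq(G, g, rcond=None)
        return max(self.yty - float(theta @ g), 0.0)

    def fit(self, delays: np.ndarray, common_delay: float = 0.0) -> LTIFit:
        """Full (lstsq-based) zero-dead-time fit at a given configuration."""
        return fit_lti_map(
            self.target_for(delays),
            self.u,
            order=self.na,
            nb=1,
            fit_intercept=self.fit_intercept,
            start=self.start,
            common_delay=common_delay,
        )


def _default_grid(dt_id: float, max_delay: float) -> np.ndarray:
    n = int(round(max_delay / dt_id))
    return np.arange(n + 1) * dt_id


def estimate_common_delay(
    response: np.ndarray,
    seq: StepSequence,
    dt: float,
    grid: np.ndarray | None = None,
    dt_id: float = DEFAULT_DT_ID,
    order: int = DEFAULT_ORDER,
    max_delay: float = DEFAULT_MAX_DELAY,
    scorer: _DelayScorer | None = None,
) -> tuple[float, LTIFit]:
    """Time-invariant stage: one delay applied to every step.

    Returns the grid point minimizing the fit residual (ties resolve to the
    smallest delay) together with the fit at that delay.
    """
    if scorer is None:
        scorer = _DelayScorer(response, seq, dt, dt_id=dt_id, order=order)
    if grid is None:
        grid = _default_grid(scorer.dt_id, max_delay)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("delay grid must not be empty")
    nsteps = len(seq.step_times)
    ssrs = np.array([scorer.ssr(np.full(nsteps, d)) for d in grid])
    best = int(np.argmin(ssrs))  # first minimum = smallest delay on ties
    delta = float(grid[best])
    return delta, scorer.fit(np.full(nsteps, delta), common_delay=delta)


def reconstruct_step_delays(
    response: np.ndarray,
    seq: StepSequence,
    dt: float,
    grid: np.ndarray | None = None,
    dt_id: float = DEFAULT_DT_ID,
    order: int = DEFAULT_ORDER,
    max_delay: float = DEFAULT_MAX_DELAY,
    max_passes: int = 6,
    init: float | np.ndarray | None = None,
    scorer: _DelayScorer | None = None,
) -> TrialReconstruction:
    """Non-time-invariant stage: optimize each step instant individually.

    Starting from the common-delay solution, each step's shift is scanned
    over the grid in temporal order (others held fixed), repeating passes
    until the residual stops improving or ``max_passes`` is reached.
    """
    if scorer is None:
        scorer = _DelayScorer(response, seq, dt, dt_id=dt_id, order=order)
    if grid is None:
        grid = _default_grid(scorer.dt_id, max_delay)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("delay grid must not be empty")
    nsteps = len(seq.step_times)
    common = None
    if init is None:
        common, _ = estimate_common_delay(response, seq, dt, grid=grid, scorer=scorer)
        delays = np.full(nsteps, common)
    else:
        delays = np.broadcast_to(np.asarray(init, dtype=float), (nsteps,)).copy()
    best_ssr = scorer.ssr(delays)
    converged = False
    for _ in range(max_passes):
        improved = False
        for step in range(nsteps):
            trial_delays = delays.copy()
            ssrs = np.empty(grid.size)
            for gi, d in enumerate(grid):
                trial_delays[step] = d
                ssrs[gi] = scorer.ssr(trial_delays)
            gi_best = int(np.argmin(ssrs))
            if ssrs[gi_best] < best_ssr - 1e-15 * max(best_ssr, 1.0):
                best_ssr = ssrs[gi_best]
                delays[step] = grid[gi_best]
                improved = True
            else:
                trial_delays[step] = delays[step]
        if not improved:
            converged = True
            break
    flags: list[str] = []
    if not converged:
        flags.append("not_converged")
    times = np.asarray(seq.step_times) + delays
    if nsteps >= 2 and np.any(np.diff(times[:2]) < scorer.dt_id / 2):
        flags.append("merged")
    fit = scorer.fit(delays, common_delay=common if common is not None else float("nan"))
    return TrialReconstruction(
        delays=delays,
        residual=fit.residual_variance,
        common_delay=common if common is not None else float("nan"),
        converged=converged,
        flags=tuple(flags),
        fit=fit,
    )


def reconstruct_trial(
    response: np.ndarray,
    seq: StepSequence,
    dt: float,
    dt_id: float = DEFAULT_DT_ID,
    order: int = DEFAULT_ORDER,
    max_delay: float = DEFAULT_MAX_DELAY,
    max_passes: int = 6,
    response_floor: float = 1e-6,
) -> TrialReconstruction | None:
    """Stage-1 wrapper for one trial with a no-response screen.

    Returns ``None`` when the control signal never moves (relative standard
    deviation below ``response_floor`` of the step amplitude) -- as happens
    when a saturated event train skips a brief reversal entirely -- so the
    trial can be dropped and logged rather than produce arbitrary delays.
    """
    response = np.asarray(response, dtype=float)
    if np.std(response) < response_floor * abs(seq.amplitude):
        return None
    scorer = _DelayScorer(response, seq, dt, dt_id=dt_id, order=order)
    return reconstruct_step_delays(
        response, seq, dt,
        dt_id=dt_id, order=order, max_delay=max_delay,
        max_passes=max_passes, scorer=scorer,
    )


# ---------------------------------------------------------------------------
# RT pair extraction
# ---------------------------------------------------------------------------

def extract_rt_pairs(
    reconstructions: list[TrialReconstruction | None],
    sequences: list[StepSequence],
    participant: int | str = 0,
    dropped_log: list | None = None,
) -> list[StepDelayEstimate]:
    """Pair (RT1, RT2) per trial, labelled by pattern class and ISI.

    Only the first two steps form the pair; the return-to-centre step of
    unidirectional trials is excluded.  Trials screened out in stage 1
    (``None`` entries) are dropped and logged.
    """
    if len(reconstructions) != len(sequences):
        raise ValueError("reconstructions and sequences must align")
    out: list[StepDelayEstimate] = []
    for trial_id, (rec, seq) in enumerate(zip(reconstructions, sequences)):
        if rec is None or len(rec.delays) < 2:
            if dropped_log is not None:
                dropped_log.append((participant, trial_id))
            continue
        out.append(
            StepDelayEstimate(
                participant=participant,
                trial=trial_id,
                pattern=seq.pattern,
                pattern_class=pattern_class(seq.pattern),
                isi=seq.isi,
                rt1=float(rec.delays[0]),
                rt2=float(rec.delays[1]),
                residual=rec.residual,
                flags=rec.flags,
            )
        )
    return out


def delay_table(estimates: list[StepDelayEstimate]) -> "pandas.DataFrame":
    """Long-format delay table (one row per step pair)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "participant": [e.participant for e in estimates],
            "trial": [e.trial for e in estimates],
            "pattern": [e.pattern for e in estimates],
            "pattern_class": [e.pattern_class for e in estimates],
            "isi_s": [e.isi for e in estimates],
            "rt1_s": [e.rt1 for e in estimates],
            "rt2_s": [e.rt2 for e in estimates],
            "residual": [e.residual for e in estimates],
            "flags": [";".join(e.flags) for e in estimates],
        }
    )
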