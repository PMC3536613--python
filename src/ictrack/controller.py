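"""Virtual participants: continuous and intermittent predictive controllers.

The synthetic "participant" closes the loop around a virtual system
(:mod:`ictrack.plants`) with a predictive state-feedback controller.  Two
regimes are simulated:

* **continuous** -- state feedback applied at every sample, with a pure
  feedback time delay ``t_d`` compensated by a model-based predictor
  (delay-free design, Smith-predictor style).
* **intermittent (serial ballistic)** -- the predicted state is used only at
  discrete events to refresh a *system-matched hold*: between events the
  control trajectory replays what the delay-free closed loop would do, so
  control is open loop for at least the minimum open-loop interval
  ``Delta_OL``.  An event fires when (i) it is a single detection (all
  triggers within the sampling delay ``Delta_s`` merge into one), (ii) at
  least ``Delta_OL`` has elapsed since the previous event, and (iii) an
  error signal exceeds a threshold ``q``.

Event triggering modes:

* ``external`` -- one event per target step (deferred to respect
  ``Delta_OL``), the construction that yields the RT2-vs-ISI slope of -1.
* ``internal`` -- events triggered by the prediction-error signal crossing
  ``q``.  With ``q = 0`` and a persistent error the event train runs at the
  maximal rate ``1/Delta_OL``.  Setting ``free_run_phase`` pins the
  saturated regime explicitly: events at ``phase + k*Delta_OL`` regardless
  of the error, the limit reached when noise drives a zero-threshold
  trigger.  With uniformly random phase this produces the slope of -1/2.

An isolated target step is answered ``t_d`` (plus ``Delta_s`` if set) after
the triggering event, which is the timing law the delay-reconstruction
stage is designed to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.linalg import matrix_power
from scipy.linalg import solve_continuous_are
from scipy.signal import place_poles

from .plants import ContinuousPlant, DiscretePlant, SystemSpec, discretize_plant, make_plant
from .stimulus import StepSequence, render_target

__all__ = [
    "ICParams",
    "TrialRecord",
    "design_controller",
    "event_trigger",
    "external_event_times",
    "simulate_continuous",
    "simulate_intermittent",
    "run_virtual_participant",
]

DEFAULT_DT = 0.001  # s, 1 kHz simulation rate


@dataclass(frozen=True)
class ICParams:
    """Intermittent-controller parameters.

    Times in seconds.  ``feedback_gain``/``observer_gain`` default to the
    LQR / pole-placement design of :func:`design_controller` when ``None``.
    """

    open_loop_interval: float = 0.35   # Delta_OL, minimum time between events
    sampling_delay: float = 0.0        # Delta_s, event-to-sample delay
    feedback_delay: float = 0.14       # t_d, pure loop delay
    event_threshold: float = 0.0       # q, trigger threshold (internal mode)
    trigger_mode: str = "external"     # "external" or "internal"
    feedback_gain: np.ndarray | None = None
    observer_gain: np.ndarray | None = None
    lp_cutoff: float = math.inf        # Hz; inf = low-pass filter off
    nms_time_constant: float = 0.0     # s; 0 = identity neuromuscular block
    observation_noise_sd: float = 0.0  # screen units, on the measured output
    free_run_phase: float | None = None  # s; saturated internal event train

    def __post_init__(self) -> None:
        if self.open_loop_interval < 0:
            raise ValueError("open_loop_interval must be >= 0")
        if self.sampling_delay < 0:
            raise ValueError("sampling_delay must be >= 0")
        if self.feedback_delay < 0:
            raise ValueError("feedback_delay must be >= 0")
        if self.event_threshold < 0:
            raise ValueError("event_threshold must be >= 0")
        if self.observation_noise_sd < 0:
            raise ValueError("observation_noise_sd must be >= 0")
        if self.trigger_mode not in ("external", "internal"):
            raise ValueError(f"unknown trigger_mode {self.trigger_mode!r}")


@dataclass
class TrialRecord:
    """Sampled signals and event log for one simulated (or recorded) trial."""

    dt: float
    w: np.ndarray            # target
    u: np.ndarray            # control (joystick) signal
    u_e: np.ndarray          # externally observed control signal
    y: np.ndarray            # system output
    d: np.ndarray            # disturbance
    event_times: list[float] = field(default_factory=list)
    reset_times: list[float] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.w)
        for name in ("u", "u_e", "y", "d"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name!r} length differs from target length {n}")

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.w)) * self.dt

    @property
    def seq(self) -> StepSequence | None:
        return self.metadata.get("sequence")


# ---------------------------------------------------------------------------
# controller design
# ---------------------------------------------------------------------------

def _augment_nms(plant: ContinuousPlant, time_constant: float) -> ContinuousPlant:
    """Append a first-order neuromuscular lag between command and plant input."""
    if time_constant <= 0:
        return plant
    n = plant.n_states
    T = time_constant
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = plant.A
    A[:n, n] = plant.B[:, 0]
    A[n, n] = -1.0 / T
    B = np.zeros((n + 1, 1))
    B[n, 0] = 1.0 / T
    C = np.zeros((1, n + 1))
    C[0, :n] = plant.C[0]
    C[0, n] = plant.D[0, 0]
    D = np.zeros((1, 1))
    return ContinuousPlant(spec=plant.spec, A=A, B=B, C=C, D=D)


def design_controller(
    plant: ContinuousPlant,
    nms_time_constant: float = 0.0,
    state_weight: float = 1.0,
    input_weight: float = 1.0,
    dt: float = DEFAULT_DT,
    observer_bandwidth: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """LQR state-feedback gain ``k`` and discrete observer gain ``L``.

    The delay-free closed loop ``x' = (A - B k) x`` is asymptotically stable
    by construction; observer poles are placed at ``exp(-dt * bandwidth * j)``
    for a fast (near-deadbeat at 1 kHz) estimate.  For the zero-order system
    both gains are empty: control reduces to the static tracking gain.
    """
    comp = _augment_nms(plant, nms_time_constant)
    n = comp.n_states
    if n == 0:
        return np.zeros(0), np.zeros((0, 1))
    Q = state_weight * np.eye(n)
    R = np.array([[input_weight]])
    try:
        P = solve_continuous_are(comp.A, comp.B, Q, R)
    except Exception as exc:  # pragma: no cover - defensive
        raise ValueError(f"controller design failed (unstabilizable?): {exc}") from exc
    k = (np.linalg.solve(R, comp.B.T @ P))[0]
    eig = np.linalg.eigvals(comp.A - comp.B @ k[None, :])
    if np.any(eig.real >= 0):
        raise ValueError("LQR design did not stabilize the plant")
    disc = discretize_plant(comp, dt)
    poles = [math.exp(-dt * observer_bandwidth * (1 + 0.2 * j)) for j in range(n)]
    placed = place_poles(disc.Ad.T, disc.Cd.T, poles)
    L = placed.gain_matrix.T
    return k, L


def _reference_maps(plant: ContinuousPlant) -> tuple[np.ndarray, float]:
    """Per-unit-target equilibrium state ``r_x`` and feedforward input ``r_u``.

    Solves ``A x + B u = 0, C x + D u = 1`` so that ``x_ref = w * r_x`` and
    ``u_ff = w * r_u`` hold the output at the target value ``w``.
    """
    n = plant.n_states
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = plant.A
    M[:n, n] = plant.B[:, 0]
    M[n, :n] = plant.C[0]
    M[n, n] = plant.D[0, 0]
    rhs = np.zeros(n + 1)
    rhs[n] = 1.0
    sol = np.linalg.solve(M, rhs)
    return sol[:n], float(sol[n])


# ---------------------------------------------------------------------------
# event triggering
# ---------------------------------------------------------------------------

def event_trigger(
    prediction_error: float,
    now: float,
    last_event_time: float,
    params: ICParams,
    pending_events: list[float] | None = None,
) -> bool:
    """Decide whether an event fires at time ``now``.

    Implements the three trigger conditions: single detection within the
    sampling delay (any candidate in ``pending_events`` closer than
    ``Delta_s`` to ``now``, or ``now`` within ``Delta_s`` of the last event,
    merges), a minimum open-loop interval since the previous event, and an
    error signal exceeding the threshold (strictly nonzero when ``q = 0``).
    """
    if now < last_event_time:
        raise ValueError("now must not precede last_event_time")
    elapsed = now - last_event_time
    if elapsed < params.open_loop_interval:
        return False
    if params.sampling_delay > 0:
        if elapsed < params.sampling_delay:
            return False  # merged with the previous event's sample
        if pending_events and any(
            0 <= now - t < params.sampling_delay for t in pending_events
        ):
            return False
    q = params.event_threshold
    err = abs(prediction_error)
    return err > q if q > 0 else err > 0


def external_event_times(step_times, params: ICParams) -> list[float]:
    """Event instants for the externally triggered mode (one per step).

    Each target step requests an event; events are deferred until the
    open-loop interval has elapsed since the previous event, and steps that
    fall inside a previous event's sampling window are absorbed into it.
    """
    events: list[float] = []
    last = -math.inf
    absorb_until = -math.inf
    for s in step_times:
        if s < absorb_until:
            continue
        t_ev = max(s, last + params.open_loop_interval)
        events.append(t_ev)
        last = t_ev
        absorb_until = t_ev + params.sampling_delay
    return events


def _free_run_event_times(phase: float, dol: float, duration: float) -> list[float]:
    if dol <= 0:
        raise ValueError("free-running events need open_loop_interval > 0")
    t = phase % dol
    out = []
    while t < duration:
        out.append(t)
        t += dol
    return out


# ---------------------------------------------------------------------------
# simulation engines
# ---------------------------------------------------------------------------

def _lp_alpha(cutoff: float, dt: float) -> float:
    """First-order low-pass pole; 0 disables filtering (pass-through)."""
    if not math.isfinite(cutoff):
        return 0.0
    return math.exp(-2 * math.pi * cutoff * dt)


class _Loop:
    """Shared closed-loop machinery: plant, observer, delay-line predictor."""

    def __init__(
        self,
        plant: ContinuousPlant,
        params: ICParams,
        dt: float,
        rng: np.random.Generator | None,
    ):
        comp = _augment_nms(plant, params.nms_time_constant)
        self.spec = plant.spec
        self.disc = discretize_plant(comp, dt)
        self.dt = dt
        self.n = self.disc.n_states
        self.n_d = int(round(params.feedback_delay / dt))
        if params.feedback_gain is not None:
            self.k = np.asarray(params.feedback_gain, dtype=float).ravel()
            if params.observer_gain is not None:
                self.L = np.asarray(params.observer_gain, dtype=float).reshape(self.n, 1)
            else:
                _, self.L = design_controller(
                    plant, params.nms_time_constant, dt=dt
                )
        else:
            self.k, self.L = design_controller(plant, params.nms_time_constant, dt=dt)
        if self.k.size != self.n:
            raise ValueError("feedback gain dimension does not match plant order")
        self.r_x, self.r_u = _reference_maps(comp)
        self.A_cl = self.disc.Ad - self.disc.Bd @ self.k[None, :] if self.n else None
        self.Ad_nd = matrix_power(self.disc.Ad, self.n_d) if self.n else None
        self.sigma = params.observation_noise_sd
        self.rng = rng
        self.params = params

    def noise(self) -> float:
        if self.sigma > 0:
            if self.rng is None:
                raise ValueError("observation noise requested but no rng supplied")
            return float(self.rng.normal(0.0, self.sigma))
        return 0.0


def _finalize(loop, w, u, y, d, events, metadata, dt) -> TrialRecord:
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(y))):
        metadata = dict(metadata, failed=True)
    return TrialRecord(
        dt=dt, w=w, u=u, u_e=u.copy(), y=y, d=d,
        event_times=list(events), metadata=metadata,
    )


def simulate_continuous(
    plant: ContinuousPlant,
    w: np.ndarray,
    params: ICParams | None = None,
    dt: float = DEFAULT_DT,
    rng: np.random.Generator | None = None,
    d: np.ndarray | None = None,
    metadata: dict | None = None,
) -> TrialRecord:
    """Continuous predictive control: state feedback at every sample.

    The controller acts on target and output information that is
    ``t_d = params.feedback_delay`` old; the predictor cancels the delay
    from the loop dynamics, so an isolated step is answered ``t_d`` later
    and the event log is empty.
    """
    params = params or ICParams(trigger_mode="external")
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("target series must not be empty")
    loop = _Loop(plant, params, dt, rng)
    nsmp, n, n_d = w.size, loop.n, loop.n_d
    d = np.zeros(nsmp) if d is None else np.asarray(d, dtype=float)
    u = np.zeros(nsmp)
    y = np.zeros(nsmp)
    alpha = _lp_alpha(params.lp_cutoff, dt)

    if n == 0:
        # static system: control is the delayed, optionally filtered target
        wf = w.copy()
        if alpha > 0:
            for i in range(1, nsmp):
                wf[i] = alpha * wf[i - 1] + (1 - alpha) * w[i]
        u[n_d:] = wf[: nsmp - n_d] * loop.r_u
        y = loop.disc.Dd[0, 0] * (u + d)
        return _finalize(loop, w, u, y, d, [], metadata or {}, dt)

    disc = loop.disc
    x = np.zeros(n)          # true plant state
    x_hat = np.zeros(n)      # observer estimate at the delayed instant
    x_pred = np.zeros(n)     # model prediction of the current state
    wf_d = 0.0               # filtered delayed target
    y_hist = np.zeros(nsmp)  # measured output history (with noise)
    for i in range(nsmp):
        j = i - n_d
        if j >= 0:
            # observer measurement/update at the delayed instant j
            innov = y_hist[j] - loop.disc.output(x_hat, u[j])
            x_hat = disc.step(x_hat, u[j] + d[j]) + (loop.L[:, 0] * innov)
            x_pred = x_pred + loop.Ad_nd @ (loop.L[:, 0] * innov)
            w_d = w[j]
        else:
            w_d = 0.0
        wf_d = alpha * wf_d + (1 - alpha) * w_d if alpha > 0 else w_d
        ui = wf_d * loop.r_u - float(loop.k @ (x_pred - wf_d * loop.r_x))
        u[i] = ui
        y[i] = disc.output(x, ui + d[i])
        y_hist[i] = y[i] + loop.noise()
        x = disc.step(x, ui + d[i])
        x_pred = disc.step(x_pred, ui + d[i])
    return _finalize(loop, w, u, y, d, [], metadata or {}, dt)


def simulate_intermittent(
    plant: ContinuousPlant,
    w: np.ndarray,
    params: ICParams,
    dt: float = DEFAULT_DT,
    rng: np.random.Generator | None = None,
    d: np.ndarray | None = None,
    step_times: tuple[float, ...] | None = None,
    metadata: dict | None = None,
) -> TrialRecord:
    """Intermittent (serial ballistic) control with a system-matched hold.

    Between events the hold state evolves under the delay-free closed-loop
    dynamics; at each event the delayed predicted state error reinitializes
    it.  ``step_times`` must be given in external trigger mode (the step
    onsets feed the trigger, one event per step).
    """
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("target series must not be empty")
    if params.trigger_mode == "external" and params.free_run_phase is None:
        if step_times is None:
            raise ValueError("external trigger mode requires the target step times")
    loop = _Loop(plant, params, dt, rng)
    nsmp, n, n_d = w.size, loop.n, loop.n_d
    duration = nsmp * dt
    d = np.zeros(nsmp) if d is None else np.asarray(d, dtype=float)
    u = np.zeros(nsmp)
    y = np.zeros(nsmp)
    alpha = _lp_alpha(params.lp_cutoff, dt)
    n_ds = int(round(params.sampling_delay / dt))

    # precomputed event trains (external / saturated-internal free run)
    if params.free_run_phase is not None:
        events = _free_run_event_times(
            params.free_run_phase, params.open_loop_interval, duration
        )
    elif params.trigger_mode == "external":
        events = external_event_times(step_times, params)
    else:
        events = None  # runtime threshold trigger

    # map event time -> control-update sample index (event + Ds + t_d)
    schedule: dict[int, float] = {}
    if events is not None:
        for t_ev in events:
            i_up = int(round(t_ev / dt)) + n_ds + n_d
            schedule[i_up] = t_ev

    event_log: list[float] = []
    last_event = -math.inf
    w_h = 0.0                              # target value held by the hold
    x_h = np.zeros(n)                      # hold state (error coordinates)
    x = np.zeros(n)
    x_hat = np.zeros(n)
    x_pred = np.zeros(n)
    wf_d = 0.0
    y_hist = np.zeros(nsmp)
    runtime_schedule: dict[int, float] = {}

    for i in range(nsmp):
        j = i - n_d
        if n and j >= 0:
            innov = y_hist[j] - loop.disc.output(x_hat, u[j])
            x_hat = loop.disc.step(x_hat, u[j] + d[j]) + loop.L[:, 0] * innov
            x_pred = x_pred + loop.Ad_nd @ (loop.L[:, 0] * innov)
        w_d = w[j] if j >= 0 else 0.0
        wf_d = alpha * wf_d + (1 - alpha) * w_d if alpha > 0 else w_d

        if events is None and j >= 0:
            now = j * dt
            if n:
                err = float(np.max(np.abs((x_pred - wf_d * loop.r_x) - x_h)))
            else:
                err = abs(wf_d - w_h)
            err += abs(loop.noise()) if loop.sigma > 0 else 0.0
            if now >= last_event and event_trigger(err, now, last_event, params):
                last_event = now
                event_log.append(now)
                runtime_schedule[i + n_ds] = now

        if events is not None and i in schedule:
            t_ev = schedule[i]
            event_log.append(t_ev)
            w_h = wf_d
            if n:
                x_h = x_pred - w_h * loop.r_x
        elif events is None and i in runtime_schedule:
            w_h = wf_d
            if n:
                x_h = x_pred - w_h * loop.r_x

        ui = w_h * loop.r_u - (float(loop.k @ x_h) if n else 0.0)
        u[i] = ui
        y[i] = loop.disc.output(x, ui + d[i]) if n else loop.disc.Dd[0, 0] * (ui + d[i])
        if n:
            y_hist[i] = y[i] + loop.noise()
            x = loop.disc.step(x, ui + d[i])
            x_pred = loop.disc.step(x_pred, ui + d[i])
            x_h = loop.A_cl @ x_h
    event_log.sort()
    md = dict(metadata or {})
    return _finalize(loop, w, u, y, d, event_log, md, dt)


# ---------------------------------------------------------------------------
# sessions of virtual participants
# ---------------------------------------------------------------------------

def run_virtual_participant(
    spec: SystemSpec,
    controller: str,
    params: ICParams,
    session: list[StepSequence],
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
    participant_id: int | str = 0,
    trail: float = 1.0,
) -> list[TrialRecord]:
    """Simulate one participant's whole session, one record per sequence.

    ``controller`` is ``"continuous"`` or ``"intermittent"``.  Each trial
    gets an independent noise stream spawned from ``rng``; runs are
    bit-reproducible under a fixed seed.  ``trail`` seconds are appended
    after the last step so late responses stay inside the record.
    """
    if controller not in ("continuous", "intermittent"):
        raise ValueError(f"unknown controller type {controller!r}")
    plant = make_plant(spec)
    records: list[TrialRecord] = []
    seeds = rng.spawn(len(session))
    for trial_id, (seq, trial_rng) in enumerate(zip(session, seeds)):
        duration = seq.step_times[-1] + max(trail, params.feedback_delay + 0.5)
        w = render_target(seq, dt, duration=duration)
        md = {
            "participant": participant_id,
            "trial": trial_id,
            "controller": controller,
            "sequence": seq,
            "system": spec.to_dict(),
        }
        p = params
        if (
            controller == "intermittent"
            and params.trigger_mode == "internal"
            and params.free_run_phase is None
            and params.event_threshold == 0.0
        ):
            # saturated regime: zero threshold under noise -> maximal-rate
            # event train with random phase
            p = replace(params, free_run_phase=float(
                trial_rng.uniform(0.0, params.open_loop_interval)
            ))
        if controller == "continuous":
            rec = simulate_continuous(plant, w, p, dt=dt, rng=trial_rng, metadata=md)
        else:
            rec = simulate_intermittent(
                plant, w, p, dt=dt, rng=trial_rng,
                step_times=seq.step_times, metadata=md,
            )
        records.append(rec)
    return records
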