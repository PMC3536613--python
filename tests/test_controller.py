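"""Continuous and intermittent controller simulations: design, triggering, timing."""

import numpy as np
import pytest

from ictrack import (
    ICParams,
    SystemSpec,
    design_controller,
    event_trigger,
    make_plant,
    make_step_sequence,
    render_target,
    simulate_continuous,
    simulate_intermittent,
    run_virtual_participant,
)
from ictrack.controller import external_event_times
from ictrack.stimulus import build_session

from conftest import reversal_trial


# ---------------------------------------------------------------------------
# controller design
# ---------------------------------------------------------------------------

def test_design_stabilizes_first_order():
    plant = make_plant(SystemSpec(order=1))
    k, L = design_controller(plant)
    pole = np.linalg.eigvals(plant.A - plant.B @ k[None, :])
    assert np.all(pole.real < 0)


def test_design_stabilizes_unstable_second_order():
    plant = make_plant(SystemSpec(order=2, stability="unstable"))
    k, _ = design_controller(plant)
    A_cl = plant.A - plant.B @ k[None, :]
    assert np.all(np.linalg.eigvals(A_cl).real < 0)
    # simulated delay-free closed loop decays from y(0) = 0.1
    from ictrack.plants import discretize_plant

    disc_cl = discretize_plant(plant, 0.001)
    x = np.array([0.1, 0.0])
    for _ in range(8000):
        x = disc_cl.step(x, float(-k @ x))
    assert abs(x[0]) < 0.01


def test_zero_order_design_reduces_to_static_gain():
    plant = make_plant(SystemSpec(order=0))
    k, L = design_controller(plant)
    assert k.size == 0 and L.size == 0
    # output follows target exactly t_d after each step
    seq, w = reversal_trial(isi=0.5)
    rec = simulate_continuous(plant, w, ICParams(feedback_delay=0.14))
    n_d = round(0.14 / 0.001)
    assert np.array_equal(rec.y[n_d:], w[:-n_d])


# ---------------------------------------------------------------------------
# event trigger
# ---------------------------------------------------------------------------

def test_trigger_fires_when_all_conditions_hold():
    p = ICParams(open_loop_interval=0.35, event_threshold=0.1)
    assert event_trigger(0.5, now=1.0, last_event_time=0.60, params=p)


def test_trigger_blocked_during_open_loop_interval():
    p = ICParams(open_loop_interval=0.35, event_threshold=0.1)
    assert not event_trigger(99.0, now=1.0, last_event_time=0.80, params=p)


def test_detections_within_sampling_delay_merge():
    p = ICParams(open_loop_interval=0.1, sampling_delay=0.05, event_threshold=0.0)
    events = external_event_times([1.0, 1.01], p)
    assert events == [1.0]


def test_zero_threshold_requires_nonzero_error():
    p = ICParams(open_loop_interval=0.1, event_threshold=0.0)
    assert not event_trigger(0.0, now=1.0, last_event_time=0.0, params=p)
    assert event_trigger(1e-6, now=1.0, last_event_time=0.0, params=p)


# ---------------------------------------------------------------------------
# intermittent timing laws
# ---------------------------------------------------------------------------

def _onsets(u, dt=0.001):
    return (np.flatnonzero(np.diff(u) != 0) + 1) * dt


@pytest.mark.parametrize(
    "isi,expected_second",
    [
        (0.50, 0.50 + 0.14),          # ISI >= open-loop interval: undelayed
        (0.20, 0.35 + 0.14),          # deferred: step1 + Delta_OL + t_d
    ],
)
def test_external_response_onsets(zero_order_plant, reference_params, isi, expected_second):
    seq, w = reversal_trial(isi=isi)
    rec = simulate_intermittent(
        zero_order_plant, w, reference_params, step_times=seq.step_times
    )
    onsets = _onsets(rec.u) - seq.first_step_time
    assert onsets[0] == pytest.approx(0.14, abs=1e-9)
    assert onsets[1] == pytest.approx(expected_second, abs=1e-9)


def test_inter_event_intervals_respect_open_loop_interval(zero_order_plant, reference_params):
    for isi in (0.05, 0.15, 0.30):
        seq, w = reversal_trial(isi=isi)
        rec = simulate_intermittent(
            zero_order_plant, w, reference_params, step_times=seq.step_times
        )
        gaps = np.diff(rec.event_times)
        assert np.all(gaps >= reference_params.open_loop_interval - 1e-12)


def test_zero_open_loop_interval_equals_continuous():
    """With a zero open-loop interval, intermittent control is continuous."""
    plant = make_plant(SystemSpec(order=1))
    seq, w = reversal_trial(isi=0.2)
    p = ICParams(open_loop_interval=0.0, feedback_delay=0.14,
                 trigger_mode="internal", event_threshold=0.0)
    y_int = simulate_intermittent(plant, w, p).y
    y_cont = simulate_continuous(plant, w, p).y
    assert np.max(np.abs(y_int - y_cont)) <= 1e-9


def test_internal_zero_threshold_saturates_at_open_loop_rate():
    """A persistent error drives the event train at rate 1/Delta_OL."""
    plant = make_plant(SystemSpec(order=0))
    dt = 0.001
    w = np.linspace(0, 2.0, 4000)  # ramp: the error never settles
    p = ICParams(open_loop_interval=0.25, feedback_delay=0.1,
                 trigger_mode="internal", event_threshold=0.0)
    rec = simulate_intermittent(plant, w, p)
    gaps = np.diff(rec.event_times)
    assert len(rec.event_times) >= 10
    assert np.allclose(gaps, 0.25, atol=2 * dt)


def test_convergence_to_continuous_as_interval_shrinks():
    """On a moving target the hold's open-loop segments shrink with the
    open-loop interval and the intermittent output approaches continuous."""
    plant = make_plant(SystemSpec(order=2, stability="marginally_stable"))
    w = 0.5 * np.arange(3000) * 0.001  # ramp keeps the trigger error alive
    p0 = ICParams(open_loop_interval=0.0, feedback_delay=0.1)
    y_cont = simulate_continuous(plant, w, p0).y
    sups = []
    for dol in (0.4, 0.1, 0.025):
        p = ICParams(open_loop_interval=dol, feedback_delay=0.1,
                     trigger_mode="internal", event_threshold=0.0)
        y = simulate_intermittent(plant, w, p).y
        sups.append(np.max(np.abs(y - y_cont)))
    assert sups[0] > sups[1] > sups[2]


# ---------------------------------------------------------------------------
# continuous control
# ---------------------------------------------------------------------------

def test_continuous_step_tracking_zero_order(zero_order_plant):
    seq, w = reversal_trial(isi=1.0, trail=1.5)
    rec = simulate_continuous(zero_order_plant, w, ICParams(feedback_delay=0.14))
    i = round((seq.first_step_time + 0.14 + 0.5) / 0.001)
    assert abs(rec.y[i] - w[i]) < 0.01


def test_unstable_plant_bounded_over_long_session():
    """Stabilizing feedback keeps the inverted-pendulum-like load on screen
    for a 200 s trial without any reset."""
    spec = SystemSpec(order=2, stability="unstable")
    plant = make_plant(spec)
    dt = 0.001
    n = 200_000
    w = np.zeros(n)
    rng = np.random.default_rng(4)
    for t0 in np.arange(2.0, 198.0, 5.0):
        w[int(t0 / dt):] = rng.choice([-1.0, 0.0, 1.0])
    rec = simulate_continuous(plant, w, ICParams(feedback_delay=0.14))
    assert np.all(np.abs(rec.y) < spec.display_limit * 2)
    assert not rec.metadata.get("failed", False)


def test_continuous_rt2_equals_rt1_after_reconstruction(zero_order_plant):
    from ictrack.reconstruction import reconstruct_trial

    for isi in (0.1, 0.3):
        seq, w = reversal_trial(isi=isi)
        rec = simulate_continuous(zero_order_plant, w, ICParams(feedback_delay=0.14))
        tr = reconstruct_trial(rec.u, seq, 0.001)
        assert tr.delays[0] == pytest.approx(tr.delays[1], abs=1e-12)


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def test_virtual_participant_reproducible_and_counted(reference_params):
    spec = SystemSpec(order=0)
    session = build_session(0, repetitions=1, rng=np.random.default_rng(11))
    recs1 = run_virtual_participant(
        spec, "intermittent", reference_params, session, np.random.default_rng(5)
    )
    recs2 = run_virtual_participant(
        spec, "intermittent", reference_params, session, np.random.default_rng(5)
    )
    assert len(recs1) == len(session) == 32
    for a, b in zip(recs1, recs2):
        assert np.array_equal(a.u, b.u) and np.array_equal(a.y, b.y)
    # noise-free external mode: every first response exactly t_d after step 1
    for rec, seq in zip(recs1, session):
        onset = _onsets(rec.u)[0]
        assert onset == pytest.approx(seq.first_step_time + 0.14, abs=1e-9)


def test_unknown_controller_rejected(reference_params):
    with pytest.raises(ValueError):
        run_virtual_participant(
            SystemSpec(order=0), "fuzzy", reference_params, [], np.random.default_rng(0)
        )
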