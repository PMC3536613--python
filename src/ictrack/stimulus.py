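"""Unpredictable double/triple-step pursuit targets and randomized sessions.

A trial's target is piecewise constant.  Four direction patterns are used:

* ``rev_LR`` -- step left then reverse back to centre (levels 0, -A, 0)
* ``rev_RL`` -- step right then reverse back to centre (levels 0, +A, 0)
* ``uni_LLc`` -- two steps left, then return to centre after the recovery
  period (levels 0, -A, -2A, 0)
* ``uni_RRc`` -- mirrored to the right (levels 0, +A, +2A, 0)

Left is negative in screen units.  The first and second steps are separated
by the inter-step interval (ISI); the recovery step of unidirectional trials
and the end of every trial are placed after a randomized approximate
recovery period (ARP) whose range depends on system order (0: 1-2 s,
1st: 2-3 s, 2nd: 4-5 s).  A session presents every combination of the eight
order-specific ISIs and four patterns in a seeded random order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StepSequence",
    "PATTERNS",
    "ISI_TABLE",
    "ARP_RANGES",
    "make_step_sequence",
    "sample_arp",
    "build_session",
    "render_target",
    "pattern_class",
]

PATTERNS = ("rev_LR", "rev_RL", "uni_LLc", "uni_RRc")

#: The eight inter-step intervals (s) used for each system order.
ISI_TABLE: dict[int, tuple[float, ...]] = {
    0: (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.50, 1.00),
    1: (0.10, 0.15, 0.20, 0.25, 0.35, 0.50, 1.00, 2.50),
    2: (0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 1.50, 4.00),
}

#: Approximate-recovery-period sampling range (s) per system order.
ARP_RANGES: dict[int, tuple[float, float]] = {
    0: (1.0, 2.0),
    1: (2.0, 3.0),
    2: (4.0, 5.0),
}

DEFAULT_FIRST_STEP_TIME = 0.6  # s of quiet baseline before the first step


@dataclass(frozen=True)
class StepSequence:
    """One trial's piecewise-constant target.

    ``step_times`` are the instants (s) at which the target jumps and
    ``step_levels`` the value it takes after each jump; before the first
    step the target sits at zero (screen centre).
    """

    pattern: str
    amplitude: float
    first_step_time: float
    isi: float
    arp: float
    step_times: tuple[float, ...]
    step_levels: tuple[float, ...]

    @property
    def pattern_class(self) -> str:
        return pattern_class(self.pattern)

    @property
    def duration_hint(self) -> float:
        """Earliest sensible end-of-trial time (last step + recovery)."""
        return self.step_times[-1] + self.arp


def pattern_class(pattern: str) -> str:
    """``"reversed"`` or ``"unidirectional"`` class of a pattern name."""
    if pattern.startswith("rev"):
        return "reversed"
    if pattern.startswith("uni"):
        return "unidirectional"
    raise ValueError(f"unknown pattern {pattern!r}")


def make_step_sequence(
    pattern: str,
    amplitude: float = 1.0,
    first_step_time: float = DEFAULT_FIRST_STEP_TIME,
    isi: float = 0.2,
    arp: float = 1.5,
) -> StepSequence:
    """Construct the step sequence for one trial.

    Reversed patterns have two steps (out by ``amplitude``, back to centre
    after ``isi``); unidirectional patterns have three (twice in the same
    direction, then back to centre ``arp`` after the second step).
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; expected one of {PATTERNS}")
    if not isi > 0:
        raise ValueError("isi must be positive")
    if not arp > 0:
        raise ValueError("arp must be positive")
    A = float(amplitude)
    t1 = float(first_step_time)
    if pattern == "rev_LR":
        times = (t1, t1 + isi)
        levels = (-A, 0.0)
    elif pattern == "rev_RL":
        times = (t1, t1 + isi)
        levels = (A, 0.0)
    elif pattern == "uni_LLc":
        times = (t1, t1 + isi, t1 + isi + arp)
        levels = (-A, -2 * A, 0.0)
    else:  # uni_RRc
        times = (t1, t1 + isi, t1 + isi + arp)
        levels = (A, 2 * A, 0.0)
    return StepSequence(
        pattern=pattern,
        amplitude=A,
        first_step_time=t1,
        isi=float(isi),
        arp=float(arp),
        step_times=times,
        step_levels=levels,
    )


def sample_arp(order: int, rng: np.random.Generator) -> float:
    """Draw an approximate recovery period for the given system order.

    Uniform in 1-2 s (order 0), 2-3 s (order 1) or 4-5 s (order 2).
    """
    if order not in ARP_RANGES:
        raise ValueError(f"system order must be 0, 1 or 2, got {order!r}")
    lo, hi = ARP_RANGES[order]
    return float(rng.uniform(lo, hi))


def build_session(
    order: int,
    amplitude: float = 1.0,
    repetitions: int = 4,
    rng: np.random.Generator | None = None,
    first_step_time: float = DEFAULT_FIRST_STEP_TIME,
    patterns: tuple[str, ...] = PATTERNS,
) -> list[StepSequence]:
    """Full randomized session for one participant and one system order.

    Every (ISI, pattern) combination appears exactly ``repetitions`` times,
    in a seeded random order, each with a freshly drawn ARP.
    """
    if order not in ISI_TABLE:
        raise ValueError(f"system order must be 0, 1 or 2, got {order!r}")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    combos = [
        (isi, pat)
        for _ in range(repetitions)
        for isi in ISI_TABLE[order]
        for pat in patterns
    ]
    perm = rng.permutation(len(combos))
    session = []
    for idx in perm:
        isi, pat = combos[idx]
        arp = sample_arp(order, rng)
        session.append(
            make_step_sequence(
                pat,
                amplitude=amplitude,
                first_step_time=first_step_time,
                isi=isi,
                arp=arp,
            )
        )
    return session


def render_target(seq: StepSequence, dt: float, duration: float | None = None) -> np.ndarray:
    """Sample the piecewise-constant target at step ``dt``.

    Step instants are aligned to the sampling grid by rounding.  ``duration``
    defaults to the last step plus the sequence's recovery period.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if duration is None:
        duration = seq.duration_hint
    if duration < seq.step_times[-1]:
        raise ValueError(
            f"duration {duration} s does not cover the last step at "
            f"{seq.step_times[-1]} s"
        )
    n = int(round(duration / dt))
    w = np.zeros(n)
    for t, level in zip(seq.step_times, seq.step_levels):
        i = int(round(t / dt))
        if i < n:
            w[i:] = level
    return w
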