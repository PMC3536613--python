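"""Virtual controlled systems driven through a joystick-like input.

The tracking experiments emulated here use one-dimensional linear "loads"
displayed as a dot on a screen.  The joystick signal ``u`` sets the system's
position (order 0), velocity (order 1) or acceleration (order 2).  The
second-order load comes in a marginally stable flavour (a pure mass,
``y'' = G u``) and an unstable flavour that mimics standing balance,
``y'' = y / tau**2 + G u`` with divergence time constant ``tau`` (default
0.92 s).

All systems are expressed in continuous-time state space and discretized
exactly with a zero-order hold at the 1 kHz simulation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import cont2discrete

__all__ = [
    "SystemSpec",
    "ContinuousPlant",
    "DiscretePlant",
    "make_plant",
    "discretize_plant",
    "simulate_plant",
]

#: Stability labels accepted for second-order systems.
STABILITIES = ("not_applicable", "marginally_stable", "unstable")

DEFAULT_TAU = 0.92  # s, standing-balance equivalent divergence time constant


@dataclass(frozen=True)
class SystemSpec:
    """Description of a virtual controlled system.

    Parameters
    ----------
    order:
        0, 1 or 2 -- the number of integrations between joystick and display.
    stability:
        ``"not_applicable"`` for orders 0 and 1; ``"marginally_stable"`` or
        ``"unstable"`` for order 2.
    tau:
        Unstable time constant in seconds (order-2 unstable only).
    gain:
        Input gain G in screen units per joystick unit per s**order.
    display_limit:
        Half-width of the visible screen range in screen units; exceeding it
        may trigger the reset-to-centre rule in :func:`simulate_plant`.
    """

    order: int
    stability: str = "not_applicable"
    tau: float = DEFAULT_TAU
    gain: float = 1.0
    display_limit: float = 1.5

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError(f"system order must be 0, 1 or 2, got {self.order!r}")
        if self.stability not in STABILITIES:
            raise ValueError(f"unknown stability {self.stability!r}")
        if self.order == 2:
            if self.stability == "not_applicable":
                raise ValueError(
                    "a second-order system must be declared 'marginally_stable' "
                    "or 'unstable'"
                )
        elif self.stability != "not_applicable":
            raise ValueError(
                f"stability {self.stability!r} is only meaningful for order 2; "
                f"use 'not_applicable' for order {self.order}"
            )
        if self.stability == "unstable" and not self.tau > 0:
            raise ValueError("unstable time constant tau must be positive")
        if self.gain == 0:
            raise ValueError("input gain must be nonzero")
        if not self.display_limit > 0:
            raise ValueError("display_limit must be positive")

    @property
    def n_states(self) -> int:
        return self.order

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "stability": self.stability,
            "tau": self.tau,
            "gain": self.gain,
            "display_limit": self.display_limit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SystemSpec":
        return cls(
            order=int(d["order"]),
            stability=d.get("stability", "not_applicable"),
            tau=float(d.get("tau", DEFAULT_TAU)),
            gain=float(d.get("gain", 1.0)),
            display_limit=float(d.get("display_limit", 1.5)),
        )


@dataclass(frozen=True)
class ContinuousPlant:
    """Continuous-time state-space realisation ``x' = A x + B u, y = C x + D u``."""

    spec: SystemSpec
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray

    @property
    def n_states(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class DiscretePlant:
    """Zero-order-hold discretization ``x+ = Ad x + Bd u, y = Cd x + Dd u``."""

    spec: SystemSpec
    dt: float
    Ad: np.ndarray
    Bd: np.ndarray
    Cd: np.ndarray
    Dd: np.ndarray

    @property
    def n_states(self) -> int:
        return self.Ad.shape[0]

    def output(self, x: np.ndarray, u: float) -> float:
        if self.n_states == 0:
            return float(self.Dd[0, 0] * u)
        return float(self.Cd[0] @ x + self.Dd[0, 0] * u)

    def step(self, x: np.ndarray, u: float) -> np.ndarray:
        if self.n_states == 0:
            return x
        return self.Ad @ x + self.Bd[:, 0] * u


def make_plant(spec: SystemSpec) -> ContinuousPlant:
    """Build the continuous-time system for ``spec``.

    Order 0 is pure feedthrough ``y = G u``; order 1 a single integrator
    ``y' = G u``; order 2 either a double integrator ``y'' = G u`` or the
    unstable load ``y'' = y / tau**2 + G u`` with one real pole at ``+1/tau``.
    """
    G = spec.gain
    if spec.order == 0:
        A = np.zeros((0, 0))
        B = np.zeros((0, 1))
        C = np.zeros((1, 0))
        D = np.array([[G]])
    elif spec.order == 1:
        A = np.zeros((1, 1))
        B = np.array([[G]])
        C = np.array([[1.0]])
        D = np.array([[0.0]])
    else:  # order 2; state = [position, velocity]
        a21 = 1.0 / spec.tau**2 if spec.stability == "unstable" else 0.0
        A = np.array([[0.0, 1.0], [a21, 0.0]])
        B = np.array([[0.0], [G]])
        C = np.array([[1.0, 0.0]])
        D = np.array([[0.0]])
    return ContinuousPlant(spec=spec, A=A, B=B, C=C, D=D)


def discretize_plant(plant: ContinuousPlant, dt: float) -> DiscretePlant:
    """Exact zero-order-hold discretization of ``plant`` at step ``dt``."""
    if not dt > 0:
        raise ValueError("dt must be positive")
    if plant.n_states == 0:
        Ad = np.zeros((0, 0))
        Bd = np.zeros((0, 1))
        Cd = plant.C.copy()
        Dd = plant.D.copy()
    else:
        Ad, Bd, Cd, Dd, _ = cont2discrete(
            (plant.A, plant.B, plant.C, plant.D), dt, method="zoh"
        )
    for M in (Ad, Bd, Cd, Dd):
        if not np.all(np.isfinite(M)):
            raise ValueError("discretization produced non-finite matrices")
    return DiscretePlant(spec=plant.spec, dt=dt, Ad=Ad, Bd=Bd, Cd=Cd, Dd=Dd)


def simulate_plant(
    plant: DiscretePlant,
    u: np.ndarray,
    display_limit: float | None = None,
    reset_enabled: bool = False,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Open-loop simulation of a discrete plant driven by input series ``u``.

    When ``reset_enabled`` and the output magnitude exceeds ``display_limit``,
    the full state is zeroed at that sample (position, velocity and
    acceleration reset, as when the dot leaves the screen and the system is
    returned to centre) and the instant is logged.

    Returns
    -------
    (y, reset_times):
        Output series of the same length as ``u`` and the list of reset
        instants in seconds.
    """
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        raise ValueError("input series must not be empty")
    if display_limit is None:
        display_limit = plant.spec.display_limit
    n = u.size
    y = np.empty(n)
    x = np.zeros(plant.n_states) if x0 is None else np.asarray(x0, dtype=float).copy()
    reset_times: list[float] = []
    for i in range(n):
        yi = plant.output(x, u[i])
        if reset_enabled and abs(yi) > display_limit:
            x = np.zeros(plant.n_states)
            yi = plant.output(x, u[i])
            reset_times.append(i * plant.dt)
        y[i] = yi
        x = plant.step(x, u[i])
    return y, reset_times
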