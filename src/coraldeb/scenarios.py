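"""Environmental forcings: constants, seasonal sinusoids, pulses, ramps and
42-day intervention windows.

All constructors are pure: the same parameters and time always give the same
value, and every forcing is defined on the whole burn-in-to-horizon interval
(nominally day -100 to day 1500).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Literal

__all__ = [
    "Forcing",
    "seasonal_temperature",
    "heat_pulse",
    "linear_ramp",
    "intervention",
    "DEFAULT_ENVIRONMENT",
    "preset",
    "PRESETS",
]

#: Default constant environment used by the seasonal experiments:
#: light 30 mol photons m^-2 d^-1, DIN 2e-7 mol N L^-1, prey 2e-7 mol C L^-1.
DEFAULT_ENVIRONMENT = {"L": 30.0, "N": 2e-7, "X": 2e-7}

TimeFunc = Callable[[float], float]


def _const(v: float) -> TimeFunc:
    return lambda t: v


@dataclass(frozen=True)
class Forcing:
    """Time-dependent environment: four functions of time in days."""

    T: TimeFunc
    L: TimeFunc
    N: TimeFunc
    X: TimeFunc
    name: str = "custom"

    @classmethod
    def constant(cls, T: float, L: float | None = None, N: float | None = None,
                 X: float | None = None, name: str = "constant") -> "Forcing":
        env = {**DEFAULT_ENVIRONMENT}
        if L is not None:
            env["L"] = L
        if N is not None:
            env["N"] = N
        if X is not None:
            env["X"] = X
        return cls(T=_const(T), L=_const(env["L"]), N=_const(env["N"]),
                   X=_const(env["X"]), name=name)

    @classmethod
    def seasonal(cls, T_min: float, T_max: float, *, L: float | None = None,
                 N: float | None = None, X: float | None = None,
                 name: str = "seasonal") -> "Forcing":
        base = cls.constant(0.0, L, N, X, name=name)
        return replace(base, T=lambda t: seasonal_temperature(T_min, T_max, t))

    @classmethod
    def pulse(cls, T_base: float, T_peak: float, start: float, duration: float,
              *, L: float | None = None, N: float | None = None,
              X: float | None = None, name: str = "pulse") -> "Forcing":
        base = cls.constant(0.0, L, N, X, name=name)
        return replace(base, T=lambda t: heat_pulse(T_base, T_peak, start, duration, t))

    @classmethod
    def ramp(cls, T_start: float, rate: float, *, t0: float = 0.0,
             L: float | None = None, N: float | None = None,
             X: float | None = None, name: str = "ramp") -> "Forcing":
        base = cls.constant(0.0, L, N, X, name=name)
        return replace(base, T=lambda t: linear_ramp(T_start, rate, t0, t))

    def at(self, t: float) -> tuple[float, float, float, float]:
        return self.T(t), self.L(t), self.N(t), self.X(t)


def seasonal_temperature(T_min: float, T_max: float, t: float) -> float:
    """Sinusoidal annual temperature: period 365 d, minimum ``T_min`` at
    day 0 and maximum ``T_max`` at midsummer (day 182.5)."""
    if T_max < T_min:
        raise ValueError("T_max must be >= T_min")
    mid = 0.5 * (T_min + T_max)
    amp = 0.5 * (T_max - T_min)
    return mid - amp * math.cos(2.0 * math.pi * t / 365.0)


def heat_pulse(T_base: float, T_peak: float, start: float, duration: float,
               t: float) -> float:
    """Square heat pulse: ``T_peak`` on ``[start, start + duration)``,
    ``T_base`` elsewhere."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return T_peak if start <= t < start + duration else T_base


def linear_ramp(T_start: float, rate: float, t0: float, t: float) -> float:
    """Gradual warming: ``T_start`` until ``t0``, then linear at ``rate``
    degree C per day."""
    return T_start + rate * max(t - t0, 0.0)


InterventionKind = Literal["shade", "low_DIN", "feed"]


def intervention(base: Forcing, peak_day: float, half_width: float = 42.0,
                 kind: InterventionKind = "shade") -> Forcing:
    """Apply a mitigation measure for ``half_width`` days before and after
    the seasonal temperature peak.

    ``shade`` reduces light by 20% (L -> 0.8 L), ``low_DIN`` removes DIN
    entirely, and ``feed`` raises prey availability by 200% (X -> 3 X).
    """
    if kind not in ("shade", "low_DIN", "feed"):
        raise ValueError(f"unknown intervention kind {kind!r}")
    lo, hi = peak_day - half_width, peak_day + half_width

    def window(t: float) -> bool:
        return lo <= t <= hi

    if kind == "shade":
        L = lambda t: base.L(t) * 0.8 if window(t) else base.L(t)
        return replace(base, L=L, name=f"{base.name}+shade")
    if kind == "low_DIN":
        N = lambda t: 0.0 if window(t) else base.N(t)
        return replace(base, N=N, name=f"{base.name}+low_DIN")
    X = lambda t: base.X(t) * 3.0 if window(t) else base.X(t)
    return replace(base, X=X, name=f"{base.name}+feed")


def preset(name: str, **overrides) -> Forcing:
    """Named scenario constructors used across the simulation battery.

    ``heat_pulse_30d`` / ``heat_pulse_5d`` require explicit ``T_base`` and
    ``T_peak`` (no silent default), with the pulse starting at day 0.
    """
    if name == "moderate_summer":
        return Forcing.seasonal(20.0, 30.0, name=name, **overrides)
    if name == "extreme_summer":
        return Forcing.seasonal(20.0, 34.0, name=name, **overrides)
    if name in ("heat_pulse_30d", "heat_pulse_5d"):
        if "T_base" not in overrides or "T_peak" not in overrides:
            raise ValueError(f"{name} requires explicit T_base and T_peak")
        duration = 30.0 if name == "heat_pulse_30d" else 5.0
        T_base = overrides.pop("T_base")
        T_peak = overrides.pop("T_peak")
        start = overrides.pop("start", 0.0)
        return Forcing.pulse(T_base, T_peak, start, duration, name=name, **overrides)
    if name.startswith("intervention_"):
        kind = {"intervention_shade": "shade", "intervention_low_din": "low_DIN",
                "intervention_feed": "feed"}.get(name)
        if kind is None:
            raise ValueError(f"unknown preset {name!r}")
        base = Forcing.seasonal(20.0, 34.0, name="extreme_summer", **overrides)
        return intervention(base, peak_day=182.5, kind=kind)
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("moderate_summer", "extreme_summer", "heat_pulse_30d", "heat_pulse_5d",
           "intervention_shade", "intervention_low_din", "intervention_feed")
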