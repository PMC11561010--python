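"""Long-run classification and parameter-space exploration.

A coral in a constant environment is integrated for 1500 days from the
standard functional-symbiosis initial conditions and classified by two
booleans: *bleached* (final S/H <= 0.05) and *growing* (dH/dt > 0 at the
final time).  Sweeps, 2-D phase diagrams, bisection of the bleaching
threshold and one-at-a-time sensitivity scans are built on that primitive.

Because the system can have multiple steady states, every record documents
the outcome from one initial condition, not a global attractor analysis.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import STANDARD_INIT, HolobiontState, ModelParameters
from .scenarios import DEFAULT_ENVIRONMENT, Forcing
from .simulate import SimulationError, simulate

__all__ = [
    "BLEACHING_RATIO", "OutcomeRecord", "steady_state", "sweep", "grid2d",
    "bleaching_threshold", "sensitivity_scan", "CATEGORIES",
]

#: S/H at or below which a coral counts as bleached (threshold exclusive for
#: "not bleached": a coral must *exceed* it to escape the label).
BLEACHING_RATIO = 0.05

CATEGORIES = ("growing & not bleached", "bleached & dying",
              "bleached & growing", "not bleached & dying")


@dataclass(frozen=True)
class OutcomeRecord:
    """Steady-state classification for one constant environment."""

    T: float
    L: float
    N: float
    X: float
    ratio: float            # final S/H
    net_S: float            # final S'/S
    net_H: float            # final H'/H
    bleached: bool
    growing: bool
    category: str
    su_HG_C: float          # SU substrate inputs at the final state:
    su_HG_N: float          # the lowest one is the most limiting factor
    su_SG_C: float
    su_SG_N: float
    su_CP_L: float
    su_CP_C: float
    valid: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def _categorize(bleached: bool, growing: bool) -> str:
    if growing and not bleached:
        return "growing & not bleached"
    if bleached and not growing:
        return "bleached & dying"
    if bleached and growing:
        return "bleached & growing"
    return "not bleached & dying"


def steady_state(p: ModelParameters, env: dict | None = None, *,
                 T: float | None = None, horizon: float = 1500.0,
                 init: HolobiontState = STANDARD_INIT,
                 **sim_kwargs) -> OutcomeRecord:
    """Classify the long-run outcome in a constant environment.

    ``env`` maps any of T/L/N/X; unspecified entries fall back to the default
    constant environment (L=30, N=2e-7, X=2e-7).  The outcome depends on the
    initial condition; the standard one corresponds to a functional symbiosis.
    """
    e = {**DEFAULT_ENVIRONMENT, **(env or {})}
    if T is not None:
        e["T"] = T
    if "T" not in e:
        raise ValueError("a temperature is required")
    forcing = Forcing.constant(e["T"], e["L"], e["N"], e["X"], name="steady")
    try:
        traj = simulate(p, forcing, t_start=0.0, t_end=horizon, init=init,
                        output_dt=horizon / 10.0, **sim_kwargs)
    except SimulationError:
        return OutcomeRecord(T=e["T"], L=e["L"], N=e["N"], X=e["X"],
                             ratio=float("nan"), net_S=float("nan"),
                             net_H=float("nan"), bleached=True, growing=False,
                             category="bleached & dying",
                             su_HG_C=float("nan"), su_HG_N=float("nan"),
                             su_SG_C=float("nan"), su_SG_N=float("nan"),
                             su_CP_L=float("nan"), su_CP_C=float("nan"),
                             valid=False)
    f = traj.fluxes[-1]
    ratio = float(traj.ratio[-1])
    bleached = ratio <= BLEACHING_RATIO
    growing = f.net_H > 0.0
    return OutcomeRecord(T=e["T"], L=e["L"], N=e["N"], X=e["X"], ratio=ratio,
                         net_S=f.net_S, net_H=f.net_H, bleached=bleached,
                         growing=growing, category=_categorize(bleached, growing),
                         su_HG_C=f.su_HG_C, su_HG_N=f.su_HG_N,
                         su_SG_C=f.su_SG_C, su_SG_N=f.su_SG_N,
                         su_CP_L=f.su_CP_L, su_CP_C=f.su_CP_C)


def sweep(p: ModelParameters, axis: str, grid: Sequence[float],
          fixed_env: dict | None = None, **kwargs) -> pd.DataFrame:
    """One-dimensional steady-state sweep along temperature or DIN.

    Per-point failures are recorded (``valid=False``) without aborting the
    sweep.  SU substrate inputs are emitted per record so limitation can be
    diagnosed along the axis.
    """
    if axis not in ("T", "N", "L", "X"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    rows = []
    for v in grid:
        env = {**(fixed_env or {}), axis: float(v)}
        rows.append(steady_state(p, env, **kwargs).as_dict())
    return pd.DataFrame(rows)


def grid2d(p: ModelParameters, y_axis: str, T_grid: Sequence[float],
           y_grid: Sequence[float], fixed_env: dict | None = None,
           **kwargs) -> pd.DataFrame:
    """Temperature-by-environment phase diagram.

    ``y_axis`` is one of L, N, X.  Returns a tidy frame with one row per
    (T, y) cell; the safe region is the ``growing & not bleached`` category.
    """
    if y_axis not in ("L", "N", "X"):
        raise ValueError(f"y_axis must be one of L, N, X, got {y_axis!r}")
    rows = []
    for yv in y_grid:
        for Tv in T_grid:
            env = {**(fixed_env or {}), "T": float(Tv), y_axis: float(yv)}
            rows.append(steady_state(p, env, **kwargs).as_dict())
    return pd.DataFrame(rows)


def bleaching_threshold(p: ModelParameters, env: dict | None = None,
                        T_lo: float = 25.0, T_hi: float = 40.0,
                        resolution: float = 0.05, **kwargs) -> float:
    """Bisect the sharp temperature above which the steady state bleaches.

    Requires the classification to differ between the brackets; returns the
    midpoint of the final bracket, accurate to ``resolution`` degree C.
    """
    lo = steady_state(p, env, T=T_lo, **kwargs).bleached
    hi = steady_state(p, env, T=T_hi, **kwargs).bleached
    if lo == hi:
        raise ValueError(
            f"classification identical at both brackets ({T_lo}, {T_hi}): "
            "no threshold to bisect")
    while T_hi - T_lo > resolution:
        mid = 0.5 * (T_lo + T_hi)
        if steady_state(p, env, T=mid, **kwargs).bleached == hi:
            T_hi = mid
        else:
            T_lo = mid
    return 0.5 * (T_lo + T_hi)


def sensitivity_scan(p: ModelParameters, parameter: str,
                     factors: Sequence[float] = (0.5, 1.0, 2.0),
                     env: dict | None = None, **kwargs) -> pd.DataFrame:
    """Bleaching threshold as one parameter is scaled 0.5x-2x, all else fixed.

    Returns a frame (parameter, factor, threshold_C); a NaN threshold means
    no bleaching transition exists in the bracket at that scaling.
    """
    rows = []
    for f in factors:
        q = p.scaled(parameter, float(f))
        try:
            thr = bleaching_threshold(q, env, **kwargs)
        except ValueError:
            thr = float("nan")
        rows.append({"parameter": parameter, "factor": float(f),
                     "threshold_C": thr})
    return pd.DataFrame(rows)
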