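"""Direct temperature effects on holobiont metabolism and photosynthesis.

Two factors carry the whole thermal response of the model:

* a metabolic speed factor ``alpha(T)`` — an Arrhenius acceleration, shared by
  all enzymatic rates, parameterised through a Q10 anchor (the factor ratio
  across a 10 degree C interval above the reference temperature);
* a damage factor ``damage(T)`` — a decreasing logistic in temperature that
  represents heat damage to the photosynthetic machinery.

Their product, rescaled to equal the base-model maximal photosynthesis rate at
the reference temperature, gives the unimodal thermal performance curve of
maximal photosynthesis.  The damage parameters can be recalibrated from
Fv/Fm-style data (temperature, quantum-yield pairs) by least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ThermalParams",
    "ThermalFitError",
    "metabolic_speed",
    "damage_factor",
    "max_photosynthesis_rate",
    "arrhenius_temperature",
    "fit_thermal_curve",
    "shift_tolerance",
]

_KELVIN = 273.15


class ThermalFitError(ValueError):
    """Raised when a thermal-curve fit is infeasible or non-identifiable."""


@dataclass(frozen=True)
class ThermalParams:
    """Constants of the thermal response.

    Parameters
    ----------
    T_ref:
        Reference temperature (degree C) at which all base rates hold and the
        metabolic speed factor equals 1.
    Q10:
        Factor by which metabolic rates accelerate over ``[T_ref, T_ref+10]``.
    T_tol:
        Heat-tolerance location (degree C): midpoint of the logistic damage
        factor.
    damage_steepness:
        Logistic slope of the damage factor (1/degree C).
    jCPm_ref:
        Maximal photosynthesis rate at ``T_ref``
        (mol C per C-mol symbiont per day).
    """

    T_ref: float = 28.0
    Q10: float = 1.88
    T_tol: float = 31.0
    damage_steepness: float = 1.0
    jCPm_ref: float = 2.8

    def __post_init__(self) -> None:
        if not (self.Q10 > 1.0):
            raise ValueError(f"Q10 must exceed 1, got {self.Q10}")
        if not (self.damage_steepness > 0.0):
            raise ValueError("damage_steepness must be positive")
        if not (self.jCPm_ref > 0.0):
            raise ValueError("jCPm_ref must be positive")


def arrhenius_temperature(p: ThermalParams) -> float:
    """Arrhenius temperature T_A (Kelvin) implied by the Q10 anchor.

    T_A is fixed once so that ``alpha(T_ref + 10) / alpha(T_ref) = Q10`` with
    ``alpha(T) = exp(T_A (1/T_ref_K - 1/T_K))``.
    """
    t0 = p.T_ref + _KELVIN
    t1 = p.T_ref + 10.0 + _KELVIN
    return math.log(p.Q10) / (1.0 / t0 - 1.0 / t1)


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature must be finite")
    return T


def metabolic_speed(T, p: ThermalParams):
    """Arrhenius acceleration factor alpha(T), equal to 1 at ``p.T_ref``.

    Accepts scalars or arrays of temperature in degree C.
    """
    T = _check_temperature(T)
    TA = arrhenius_temperature(p)
    out = np.exp(TA * (1.0 / (p.T_ref + _KELVIN) - 1.0 / (T + _KELVIN)))
    return out if out.ndim else float(out)


def damage_factor(T, p: ThermalParams):
    """Decreasing logistic damage factor in (0, 1]; 1/2 at ``p.T_tol``."""
    T = _check_temperature(T)
    out = 1.0 / (1.0 + np.exp(p.damage_steepness * (T - p.T_tol)))
    return out if out.ndim else float(out)


def max_photosynthesis_rate(T, p: ThermalParams):
    """Thermally modulated maximal photosynthesis rate j_CPm(T).

    Product of the Arrhenius acceleration and the logistic damage factor,
    rescaled by its value at the reference temperature so that
    ``j_CPm(T_ref) == jCPm_ref`` exactly and the base model is recovered
    at the reference temperature.  The curve is unimodal: Arrhenius
    acceleration dominates below the tolerance region, damage above it.
    """
    T = _check_temperature(T)
    norm = damage_factor(p.T_ref, p)  # alpha(T_ref) = 1 by construction
    out = p.jCPm_ref * metabolic_speed(T, p) * np.asarray(damage_factor(T, p)) / norm
    return out if out.ndim else float(out)


def shift_tolerance(p: ThermalParams, delta: float) -> ThermalParams:
    """Translate the damage curve along the temperature axis by ``delta``.

    ``damage_factor(T + delta, shifted) == damage_factor(T, p)`` pointwise;
    all other constants are untouched.  ``delta = -4`` reproduces the
    four-degree reduction of heat tolerance used to move a fit on
    heat-adapted corals to a more typical bleaching threshold.
    """
    return replace(p, T_tol=p.T_tol + delta)


def _scaled_curve(T: np.ndarray, scale: float, p: ThermalParams) -> np.ndarray:
    return scale * metabolic_speed(T, p) * np.asarray(damage_factor(T, p))


def fit_thermal_curve(
    points: Sequence[tuple[float, float]],
    p0: ThermalParams | None = None,
    *,
    rescale_to_reference: bool = True,
    grid_T_tol: Sequence[float] | None = None,
    grid_steepness: Sequence[float] | None = None,
) -> ThermalParams:
    """Fit the unimodal thermal curve to (temperature, yield) points.

    Free parameters are an overall scale, the damage location ``T_tol`` and
    the damage steepness; the Arrhenius acceleration is held at the metabolic
    Q10, mirroring the assumption that photosynthesis accelerates like every
    other rate before damage takes over.  The sum of squared residuals is
    minimised, starting local optimisation from the best point of a coarse
    (T_tol, steepness) grid to sidestep the local minima typical of unimodal
    fits.

    With ``rescale_to_reference`` (default) the returned parameters keep
    ``jCPm_ref`` from ``p0`` — i.e. only the *shape* (T_tol, steepness) is
    taken from the data, and the curve maximum is pinned back to the
    base-model reference value by the model-side normalisation.

    Raises
    ------
    ThermalFitError
        For fewer than 4 points, points on one side of the peak only being
        degenerate (zero spread), or flat/non-identifiable data.
    """
    p0 = p0 or ThermalParams()
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ThermalFitError("points must be an (n, 2) table of (T, value)")
    if pts.shape[0] < 4:
        raise ThermalFitError(f"need at least 4 points, got {pts.shape[0]}")
    T, y = pts[:, 0], pts[:, 1]
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(y))):
        raise ThermalFitError("non-finite values in fit points")
    if np.ptp(y) < 1e-12 * max(1.0, float(np.max(np.abs(y)))):
        raise ThermalFitError("flat data: thermal curve is non-identifiable")

    if grid_T_tol is None:
        grid_T_tol = np.linspace(T.min() - 2.0, T.max() + 5.0, 25)
    if grid_steepness is None:
        grid_steepness = np.geomspace(0.1, 5.0, 12)

    def residuals(theta: np.ndarray) -> np.ndarray:
        scale, t_tol, steep = theta
        q = replace(p0, T_tol=t_tol, damage_steepness=abs(steep))
        return _scaled_curve(T, scale, q) - y

    best = None
    for tt in grid_T_tol:
        for ss in grid_steepness:
            q = replace(p0, T_tol=float(tt), damage_steepness=float(ss))
            base = metabolic_speed(T, q) * np.asarray(damage_factor(T, q))
            denom = float(base @ base)
            scale = float(base @ y) / denom if denom > 0 else 0.0
            ssr = float(np.sum((scale * base - y) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, np.array([scale, tt, ss]))
    assert best is not None

    sol = least_squares(residuals, best[1], method="lm", xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise ThermalFitError(f"thermal-curve fit did not converge: {sol.message}")
    scale, t_tol, steep = sol.x
    if scale <= 0:
        raise ThermalFitError("fit produced a non-positive curve scale")

    fitted = replace(p0, T_tol=float(t_tol), damage_steepness=float(abs(steep)))
    if not rescale_to_reference:
        # keep the fitted amplitude: express it as jCPm at T_ref
        fitted = replace(
            fitted,
            jCPm_ref=float(scale * metabolic_speed(p0.T_ref, fitted)
                           * damage_factor(p0.T_ref, fitted)),
        )
    return fitted
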