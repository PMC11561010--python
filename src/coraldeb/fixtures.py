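"""Synthetic Fv/Fm-style calibration data.

The thermal damage curve is calibrated against (temperature, maximum quantum
yield) points.  The published measurements exist only as figure points, so
this generator emulates such a dataset: a unimodal curve — Arrhenius rise
times logistic damage, scaled to a typical healthy Fv/Fm maximum — plus
additive Gaussian noise on a temperature grid spanning both limbs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .thermal import ThermalParams, damage_factor, metabolic_speed

__all__ = ["generate_fvfm_fixture", "FVFM_HEALTHY_MAX"]

#: Typical maximum quantum yield of a healthy symbiont, used as curve scale.
FVFM_HEALTHY_MAX = 0.6


def generate_fvfm_fixture(truth: ThermalParams, n: int = 30,
                          noise_sd: float = 0.02, seed: int | None = 0,
                          T_min: float = 16.0, T_max: float = 40.0,
                          scale: float = FVFM_HEALTHY_MAX) -> pd.DataFrame:
    """Sample ``n`` noisy quantum-yield points from a known thermal curve.

    The curve is ``scale * alpha(T) * damage(T)``, normalised so its maximum
    over the sampled range equals ``scale``.  Reproducible by ``seed``.

    Returns a two-column frame (temperature_C, fvfm).
    """
    if n < 4:
        raise ValueError("need n >= 4 points to span a unimodal curve")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    T = np.linspace(T_min, T_max, n)
    curve = metabolic_speed(T, truth) * np.asarray(damage_factor(T, truth))
    curve = scale * curve / curve.max()
    y = curve + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"temperature_C": T, "fvfm": y})
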