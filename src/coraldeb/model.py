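"""Bioenergetic core of the coral holobiont: states, parameters and fluxes.

The model tracks host biomass ``H`` and symbiont biomass ``S`` (both in
C-mol), coupled through surplus-nutrient exchange:

* the symbiont photosynthesises (an SU of captured light and inorganic
  carbon, capped by the thermally modulated maximum ``j_CPm``) and shares its
  surplus fixed carbon ``rho_C`` with the host;
* the host feeds and takes up dissolved inorganic nitrogen (DIN), grows (an
  SU of carbon and nitrogen), shares its surplus nitrogen ``rho_N`` with the
  symbiont, and spends its surplus *carbon* on carbon concentration
  mechanisms (CCMs) that deliver CO2 back to the symbiont;
* captured light that photosynthesis cannot use is excess light; up to the
  non-photochemical-quenching capacity ``k_NPQ`` is dissipated harmlessly,
  the remainder produces reactive oxygen species (ROS).  Elevated ROS both
  depress realised photosynthesis (photoinhibition) and trigger symbiont
  expulsion in proportion to ``b (c_ROS - 1) j_ST0``.

Temperature enters in exactly two places: the Arrhenius metabolic speed
factor ``alpha`` multiplying the six rate constants (maximal symbiont/host
growth, symbiont/host turnover, maximal feeding, maximal DIN uptake), and
the unimodal maximal photosynthesis rate.  Two single-effect variants switch
one of the mechanisms off; at the reference temperature all variants reduce
exactly to the base model.

The two flux variables ``j_CP`` and ``j_SG`` are themselves state variables
relaxing toward their instantaneous SU targets on a fast timescale, which
resolves the circular dependencies of the flux network (photosynthesis needs
the CCM flux, which needs host surplus carbon, which needs the carbon the
symbiont shares, which needs photosynthesis).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from typing import Literal

import numpy as np

from .thermal import ThermalParams, damage_factor, max_photosynthesis_rate, metabolic_speed

__all__ = [
    "HolobiontState",
    "ModelParameters",
    "EnvironmentState",
    "FluxSet",
    "su_rate",
    "light_capture",
    "photoinhibition",
    "compute_fluxes",
    "rhs",
    "rhs_log",
    "STANDARD_INIT",
]

Variant = Literal["full", "acceleration", "damage", "base"]

PARAMS_VERSION = "base-table-28C/v1"


@dataclass(frozen=True)
class HolobiontState:
    """Dynamic state: biomasses plus the two relaxed fluxes."""

    H: float        # host biomass, C-mol
    S: float        # symbiont biomass, C-mol
    j_CP: float     # effective photosynthesis rate, mol C / C-mol S / d
    j_SG: float     # symbiont gross growth rate, mol C / C-mol S / d

    def __post_init__(self) -> None:
        if not (self.H > 0):
            raise ValueError("host biomass H must be positive")
        if self.S < 0 or self.j_CP < 0 or self.j_SG < 0:
            raise ValueError("S, j_CP and j_SG must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.H, self.S, self.j_CP, self.j_SG])

    @property
    def ratio(self) -> float:
        """Symbiont-to-host biomass ratio S/H."""
        return self.S / self.H


#: Standard initial conditions used by every simulation experiment.
STANDARD_INIT = HolobiontState(H=1.0, S=0.1, j_CP=2.8, j_SG=1.0)


@dataclass(frozen=True)
class EnvironmentState:
    """Instantaneous environment."""

    T: float    # temperature, degree C
    L: float    # light, mol photons / m^2 / d
    N: float    # DIN, mol N / L
    X: float    # prey, mol C / L

    def __post_init__(self) -> None:
        if self.L < 0 or self.N < 0 or self.X < 0:
            raise ValueError("L, N and X must be non-negative")


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants of the holobiont model, valid at the 28 degree C
    reference temperature, plus the thermal response and the variant switch.

    Rates are per C-mol biomass per day unless noted.
    """

    # --- host ---
    j_HGm: float = 1.0          # maximal host growth rate
    j_HT0: float = 0.03         # host biomass turnover
    j_Xm: float = 0.13          # maximal feeding rate, mol C prey / C-mol H / d
    K_X: float = 1e-6           # feeding half-saturation, mol C / L
    j_Nm: float = 0.035         # maximal DIN uptake, mol N / C-mol H / d
    K_N: float = 1.5e-6         # DIN half-saturation, mol N / L
    n_NH: float = 0.18          # N:C ratio of host biomass
    n_NX: float = 0.2           # N:C ratio of prey
    sigma_NH: float = 0.9       # fraction of host turnover N recycled
    sigma_CH: float = 0.1       # fraction of host respiration C recycled
    k_CO2: float = 10.0         # CCM efficiency, mol CO2 delivered / mol C spent
    # --- symbiont ---
    j_SGm: float = 0.25         # maximal symbiont growth rate
    j_ST0: float = 0.03         # symbiont biomass turnover (baseline)
    n_NS: float = 0.13          # N:C ratio of symbiont biomass
    sigma_NS: float = 0.9       # fraction of symbiont turnover N recycled
    sigma_CS: float = 0.9       # fraction of symbiont respiration C recycled
    y_C: float = 0.8            # carbon yield of biomass formation
    y_CL: float = 0.1           # quantum yield, mol C fixed / mol photons
    astar: float = 1.34         # light-absorbing cross-section, m^2 / C-mol S
    k_NPQ: float = 112.0        # NPQ capacity, mol photons / C-mol S / d
    k_ROS: float = 80.0         # excess light that doubles ROS, mol photons / C-mol S / d
    ros_exponent: float = 1.0   # exponent on ROS production
    b: float = 5.0              # bleaching-response scale
    # --- numerics / thermal / variant ---
    tau_flux: float = 0.01      # relaxation timescale of j_CP, j_SG (d)
    expulsion_scales_with_alpha: bool = True
    thermal: ThermalParams = field(default_factory=ThermalParams)
    variant: Variant = "full"
    version: str = PARAMS_VERSION

    def __post_init__(self) -> None:
        positive = (
            "j_HGm j_HT0 j_Xm K_X j_Nm K_N n_NH n_NX j_SGm j_ST0 n_NS "
            "y_C y_CL astar k_NPQ k_ROS b tau_flux"
        ).split()
        for name in positive:
            if not (getattr(self, name) > 0):
                raise ValueError(f"parameter {name} must be strictly positive")
        if not (0 < self.y_C <= 1):
            raise ValueError("y_C must lie in (0, 1]")
        for name in ("sigma_NH", "sigma_CH", "sigma_NS", "sigma_CS"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.variant not in ("full", "acceleration", "damage", "base"):
            raise ValueError(f"unknown variant {self.variant!r}")

    def with_variant(self, variant: Variant) -> "ModelParameters":
        return replace(self, variant=variant)

    def scaled(self, name: str, factor: float) -> "ModelParameters":
        """Return a copy with one base parameter multiplied by ``factor``."""
        if name == "jCPm_ref":
            return replace(self, thermal=replace(self.thermal,
                                                 jCPm_ref=self.thermal.jCPm_ref * factor))
        if name not in {f.name for f in fields(self)}:
            raise KeyError(f"unknown parameter {name!r}")
        value = getattr(self, name)
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise KeyError(f"parameter {name!r} is not a scalar rate")
        return replace(self, **{name: value * factor})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thermal"] = asdict(self.thermal)
        return d


@dataclass(frozen=True)
class FluxSet:
    """Every derived per-biomass flux at one instant.

    Per-symbiont fluxes are per C-mol S, per-host fluxes per C-mol H.
    SU input fields give the two substrate fluxes entering each synthesizing
    unit, in units of producible biomass, so the lowest one is the most
    limiting factor.
    """

    alpha: float                # metabolic speed factor
    j_CPm: float                # thermal maximal photosynthesis rate
    j_L: float                  # captured light, mol photons / C-mol S / d
    j_CP: float                 # realised photosynthesis (relaxed state)
    j_CP_target: float          # instantaneous SU target for j_CP
    j_eL: float                 # excess light
    j_NPQ: float                # quenched excess light
    c_ROS: float                # ROS level, baseline 1
    expulsion: float            # b (c_ROS - 1) j_ST0 [alpha]
    j_X: float                  # feeding, mol C prey / C-mol H / d
    j_N: float                  # DIN uptake, mol N / C-mol H / d
    j_CO2: float                # CCM-delivered CO2, mol C / C-mol H / d
    j_eC: float                 # host surplus carbon spent on CCMs
    rho_C: float                # carbon shared symbiont -> host, / C-mol S
    rho_N: float                # nitrogen shared host -> symbiont, / C-mol H
    j_HG: float                 # host gross growth
    j_SG: float                 # symbiont gross growth (relaxed state)
    j_SG_target: float          # instantaneous SU target for j_SG
    j_HT: float                 # host turnover
    j_ST: float                 # total symbiont turnover incl. expulsion
    # SU substrate inputs (producible-biomass units)
    su_HG_C: float
    su_HG_N: float
    su_SG_C: float
    su_SG_N: float
    su_CP_L: float              # light input to photosynthesis SU (mol C units)
    su_CP_C: float              # inorganic carbon input (mol C units)
    # recycled flows
    r_CH: float                 # host respiration CO2 recycled, / C-mol H
    r_CS: float                 # symbiont respiration CO2 recycled, / C-mol S
    r_NH: float                 # host turnover N recycled, / C-mol H
    r_NS: float                 # symbiont turnover N recycled, / C-mol S
    net_S: float                # specific symbiont net growth S'/S
    net_H: float                # specific host net growth H'/H

    def as_dict(self) -> dict:
        return asdict(self)


def su_rate(j_max: float, A: float, B: float) -> float:
    """Parallel-complementary synthesizing-unit rate.

    ``1 / (1/j_max + 1/A + 1/B - 1/(A+B))`` — bounded above by each substrate
    flux and by the capacity ``j_max``; zero whenever a substrate is missing.
    """
    if j_max <= 0:
        raise ValueError("j_max must be positive")
    if A < 0 or B < 0:
        raise ValueError("substrate fluxes must be non-negative")
    if A == 0.0 or B == 0.0:
        return 0.0
    return 1.0 / (1.0 / j_max + 1.0 / A + 1.0 / B - 1.0 / (A + B))


def light_capture(L: float, ratio: float, p: ModelParameters) -> float:
    """Per-symbiont light capture ``j_L`` with self-shading.

    The spectral amplification factor ``1.26 + 1.39 exp(-6.48 S/H)`` makes
    per-symbiont capture decrease as symbiont density rises (self-shading)
    while remaining proportional to irradiance.
    """
    if L < 0 or ratio < 0:
        raise ValueError("L and S/H ratio must be non-negative")
    return (1.26 + 1.39 * np.exp(-6.48 * ratio)) * p.astar * L


def photoinhibition(j_CP_potential: float, c_ROS: float) -> float:
    """ROS feedback on realised photosynthesis: division by the ROS level."""
    return j_CP_potential / c_ROS


def _thermal_factors(T: float, p: ModelParameters) -> tuple[float, float]:
    """(alpha, j_CPm) under the active variant."""
    th = p.thermal
    if p.variant == "base":
        return 1.0, th.jCPm_ref
    alpha = float(metabolic_speed(T, th))
    if p.variant == "acceleration":
        # damage switched off: photosynthesis accelerates like everything else
        return alpha, th.jCPm_ref * alpha
    if p.variant == "damage":
        # temperature affects only the photosynthetic machinery: j_CPm keeps
        # its full unimodal curve, the six metabolic rates stay at base speed
        return 1.0, float(max_photosynthesis_rate(T, th))
    return alpha, float(max_photosynthesis_rate(T, th))


def _core(H, S, j_CP, j_SG, T, L, N, X, p: ModelParameters):
    """Algebraic flux network; returns the tuple used by rhs and FluxSet."""
    ratio = max(S, 1e-12 * H) / H   # guard: expulsion may drive S to 0
    return _core_ratio(ratio, j_CP, j_SG, T, L, N, X, p)


def _core_ratio(ratio, j_CP, j_SG, T, L, N, X, p: ModelParameters):
    """Flux network in terms of the ratio S/H only (scale invariance)."""
    alpha, j_CPm = _thermal_factors(T, p)

    # host acquisition (alpha scales the maxima)
    j_X = alpha * p.j_Xm * X / (X + p.K_X) if X > 0 else 0.0
    j_N = alpha * p.j_Nm * N / (N + p.K_N) if N > 0 else 0.0

    # turnover and recycled flows
    j_HT = alpha * p.j_HT0
    j_ST0_T = alpha * p.j_ST0
    r_NH = p.sigma_NH * p.n_NH * j_HT
    r_NS = p.sigma_NS * p.n_NS * j_ST0_T
    r_CS = p.sigma_CS * (j_ST0_T + (1.0 - p.y_C) / p.y_C * j_SG)

    # symbiont surplus carbon shared with host
    rho_C = max(j_CP - j_SG / p.y_C, 0.0)

    # host growth SU: carbon vs nitrogen, in producible-biomass units
    su_HG_C = p.y_C * (j_X + rho_C * ratio)
    su_HG_N = (j_N + p.n_NX * j_X + r_NH) / p.n_NH
    j_HG = su_rate(alpha * p.j_HGm, su_HG_C, su_HG_N)

    # host surpluses: nitrogen shared, carbon fuels the CCMs
    rho_N = max(j_N + p.n_NX * j_X + r_NH - p.n_NH * j_HG, 0.0)
    j_eC = max(j_X + rho_C * ratio - j_HG / p.y_C, 0.0)
    j_CO2 = p.k_CO2 * j_eC
    r_CH = p.sigma_CH * (j_HT + (1.0 - p.y_C) / p.y_C * j_HG)

    # photosynthesis SU: captured light vs inorganic carbon (per symbiont)
    j_L = light_capture(L, ratio, p)
    su_CP_L = p.y_CL * j_L
    su_CP_C = (j_CO2 + r_CH) / ratio + r_CS
    j_CP_potential = su_rate(j_CPm, su_CP_L, su_CP_C) if su_CP_L > 0 and su_CP_C > 0 else 0.0

    # excess light, NPQ, ROS
    j_eL = max(j_L - j_CP / p.y_CL, 0.0)
    j_NPQ = 0.0 if j_eL == 0.0 else 1.0 / (1.0 / p.k_NPQ + 1.0 / j_eL)
    surplus_light = max(j_eL - j_NPQ, 0.0)
    c_ROS = 1.0 + (surplus_light / p.k_ROS) ** p.ros_exponent
    j_CP_target = photoinhibition(j_CP_potential, c_ROS)

    # symbiont growth SU and turnover with ROS-triggered expulsion
    su_SG_C = p.y_C * j_CP
    su_SG_N = (rho_N / ratio + r_NS) / p.n_NS
    j_SG_target = su_rate(alpha * p.j_SGm, su_SG_C, su_SG_N)
    expulsion_base = j_ST0_T if p.expulsion_scales_with_alpha else p.j_ST0
    expulsion = p.b * (c_ROS - 1.0) * expulsion_base
    j_ST = j_ST0_T + expulsion

    net_H = j_HG - j_HT
    net_S = j_SG - j_ST

    return (alpha, j_CPm, j_L, j_CP_target, j_eL, j_NPQ, c_ROS, expulsion,
            j_X, j_N, j_CO2, j_eC, rho_C, rho_N, j_HG, j_SG_target, j_HT, j_ST,
            su_HG_C, su_HG_N, su_SG_C, su_SG_N, su_CP_L, su_CP_C,
            r_CH, r_CS, r_NH, r_NS, net_S, net_H)


def compute_fluxes(state: HolobiontState, env: EnvironmentState,
                   p: ModelParameters) -> FluxSet:
    """Evaluate the complete flux network at one instant."""
    (alpha, j_CPm, j_L, j_CP_target, j_eL, j_NPQ, c_ROS, expulsion,
     j_X, j_N, j_CO2, j_eC, rho_C, rho_N, j_HG, j_SG_target, j_HT, j_ST,
     su_HG_C, su_HG_N, su_SG_C, su_SG_N, su_CP_L, su_CP_C,
     r_CH, r_CS, r_NH, r_NS, net_S, net_H) = _core(
        state.H, state.S, state.j_CP, state.j_SG,
        env.T, env.L, env.N, env.X, p)
    return FluxSet(
        alpha=alpha, j_CPm=j_CPm, j_L=j_L, j_CP=state.j_CP,
        j_CP_target=j_CP_target, j_eL=j_eL, j_NPQ=j_NPQ, c_ROS=c_ROS,
        expulsion=expulsion, j_X=j_X, j_N=j_N, j_CO2=j_CO2, j_eC=j_eC,
        rho_C=rho_C, rho_N=rho_N, j_HG=j_HG, j_SG=state.j_SG,
        j_SG_target=j_SG_target, j_HT=j_HT, j_ST=j_ST,
        su_HG_C=su_HG_C, su_HG_N=su_HG_N, su_SG_C=su_SG_C, su_SG_N=su_SG_N,
        su_CP_L=su_CP_L, su_CP_C=su_CP_C,
        r_CH=r_CH, r_CS=r_CS, r_NH=r_NH, r_NS=r_NS,
        net_S=net_S, net_H=net_H,
    )


def rhs(t: float, y: np.ndarray, forcing, p: ModelParameters) -> np.ndarray:
    """ODE right-hand side over the packed state ``[H, S, j_CP, j_SG]``.

    Growth depends on the ratio S/H only, so the biomass dynamics are
    exponential; ``j_CP`` and ``j_SG`` relax toward their SU targets on the
    fast timescale ``tau_flux``.
    """
    H, S, j_CP, j_SG = y
    H = max(H, 1e-300)
    S = max(S, 0.0)
    j_CP = max(j_CP, 0.0)
    j_SG = max(j_SG, 0.0)
    out = _core(H, S, j_CP, j_SG,
                forcing.T(t), forcing.L(t), forcing.N(t), forcing.X(t), p)
    j_CP_target, j_HG, j_SG_target, j_HT, j_ST = out[3], out[14], out[15], out[16], out[17]
    return np.array([
        (j_HG - j_HT) * H,
        (j_SG - j_ST) * S,
        (j_CP_target - j_CP) / p.tau_flux,
        (j_SG_target - j_SG) / p.tau_flux,
    ])


_LOG_RATIO_MIN = np.log(1e-12)
_LOG_RATIO_MAX = np.log(1e12)


def rhs_log(t: float, y: np.ndarray, forcing, p: ModelParameters) -> np.ndarray:
    """Right-hand side over ``[ln H, ln S, j_CP, j_SG]``.

    Equivalent to :func:`rhs` but robust to the exponential growth or decay
    of the biomasses over long horizons (the dynamics depend on S/H only).
    """
    ln_H, ln_S, j_CP, j_SG = y
    ratio = float(np.exp(np.clip(ln_S - ln_H, _LOG_RATIO_MIN, _LOG_RATIO_MAX)))
    out = _core_ratio(ratio, max(j_CP, 0.0), max(j_SG, 0.0),
                      forcing.T(t), forcing.L(t), forcing.N(t), forcing.X(t), p)
    j_CP_target, j_HG, j_SG_target, j_HT, j_ST = out[3], out[14], out[15], out[16], out[17]
    return np.array([
        j_HG - j_HT,
        j_SG - j_ST,
        (j_CP_target - max(j_CP, 0.0)) / p.tau_flux,
        (j_SG_target - max(j_SG, 0.0)) / p.tau_flux,
    ])
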