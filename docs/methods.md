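# Methods

## Model structure

The model tracks four dynamic quantities: host biomass H (C-mol), symbiont
biomass S (C-mol), and two flux variables — the effective photosynthesis
rate j_CP and the symbiont gross growth rate j_SG (both mol C · C-mol S⁻¹ ·
d⁻¹). Growth rates depend on the ratio S/H only, never on absolute sizes, so
the biomass dynamics are exponential: the model describes a colony growing
or shrinking without density dependence. Internally the integrator therefore
works with ln H and ln S, which keeps 1500-day runs of strongly declining
(or growing) colonies inside floating-point range without changing the
dynamics; public interfaces expose linear biomasses and the ratio.

All per-biomass fluxes at an instant are algebraic functions of
(S/H, j_CP, j_SG) and the environment (T, L, N, X):

* Host feeding j_X = α j_Xm X/(X+K_X) and DIN uptake j_N = α j_Nm N/(N+K_N).
* Host growth is an SU of carbon y_C(j_X + ρ_C·S/H) and nitrogen
  (j_N + n_NX j_X + r_NH)/n_NH with capacity α j_HGm; r_NH is recycled
  turnover nitrogen (σ_NH n_NH j_HT).
* Surplus host nitrogen is shared: ρ_N = max(0, N-input − n_NH j_HG).
  Surplus host carbon fuels the CCMs: j_eC = max(0, j_X + ρ_C·S/H −
  j_HG/y_C), delivering j_CO2 = k_CO2 · j_eC of inorganic carbon.
* Light capture per symbiont is j_L = (1.26 + 1.39 e^(−6.48 S/H)) ā* L; the
  spectral amplification factor encodes self-shading — denser symbiont
  populations receive less light per cell.
* Photosynthesis is an SU of captured light (y_CL j_L) and inorganic carbon
  ((j_CO2 + r_CH) H/S + r_CS; CCM delivery plus respiratory recycling),
  capped by the thermal maximum j_CPm(T), then divided by c_ROS
  (photoinhibition). j_CP relaxes toward this target.
* Excess light j_eL = max(0, j_L − j_CP/y_CL) is quenched through a
  single-substrate SU with capacity k_NPQ (a smooth saturating form rather
  than a hard min); the residual sets c_ROS = 1 + (residual/k_ROS)^k, k = 1.
* Symbiont growth is an SU of carbon y_C j_CP and nitrogen (ρ_N H/S +
  r_NS)/n_NS with capacity α j_SGm; its carbon surplus is the translocation
  ρ_C = max(0, j_CP − j_SG/y_C). j_SG relaxes toward the SU target.
* Turnover: j_HT = α j_HT0; j_ST = α j_ST0 (1 + b (c_ROS − 1)), i.e. ROS add
  expulsion proportional to the α-scaled baseline maintenance (the baseline
  inside the expulsion term carries α; configurable via
  `expulsion_scales_with_alpha`).

The circular dependencies of this network (photosynthesis needs CCM carbon,
which needs host surplus carbon, which needs shared photosynthate) are
resolved by treating j_CP and j_SG as state variables relaxing toward their
instantaneous targets with timescale τ = 0.01 d — fast against biomass
dynamics, slow enough to integrate. The max(·,0) surplus terms are kept
exact (no smoothing).

## Temperature response

α(T) = exp(T_A (1/T_ref,K − 1/T_K)) with T_A ≈ 5915 K fixed once so that
α(T_ref+10)/α(T_ref) = Q10 = 1.88 (T_ref = 28 °C). The damage factor is a
decreasing logistic 1/(1 + e^{s(T − T_tol)}). j_CPm(T) = j_CPm,ref ·
α(T) · damage(T)/damage(T_ref): the normalisation is by the curve's value at
28 °C — not its maximum — so the reference-temperature identity with the
base model is exact; maximum-normalisation is used only when displaying or
fitting the curve against quantum-yield data. For a single-substrate SU the
half-saturation equals the capacity, so scaling j_CPm automatically scales
the light half-saturation proportionally.

Variants: `acceleration` keeps α and replaces the damage factor by 1 (j_CPm
= ref · α); `damage` keeps the full unimodal j_CPm(T) curve — the curve is
the photosynthesis temperature effect as a whole — and sets α = 1 for the
six metabolic rates; `base` removes both. All variants coincide exactly at
28 °C. Defining the damage variant this way (rather than also stripping the
Arrhenius rise out of j_CPm) is what makes the comparison "full vs damage"
isolate metabolic acceleration; acceleration then lowers the bleaching
threshold (32.28 vs 32.60 °C at defaults) by raising carbon demand.

## Parameters

Base rates are valid at 28 °C and follow the published parameter table of
the underlying base model: j_HGm = 1, j_HT0 = j_ST0 = 0.03, j_Xm = 0.13
(K_X = 1e-6), j_Nm = 0.035 (K_N = 1.5e-6), j_SGm = 0.25, j_CPm,ref = 2.8,
n_NH = 0.18, n_NX = 0.2, n_NS = 0.13, σ_NH = σ_NS = σ_CS = 0.9, σ_CH = 0.1,
y_C = 0.8, y_CL = 0.1, ā* = 1.34, k_CO2 = 10, k_NPQ = 112, k_ROS = 80,
b = 5. Damage-curve defaults T_tol = 31.0 °C, s = 1.0 °C⁻¹ represent the
post-fit, −4 °C-shifted calibration: they are chosen once so that the
package's default conditions express the documented qualitative regime —
j_CPm unimodal with its peak just above 28 °C, a moderate summer (peak
30 °C) that never bleaches, an extreme summer (peak 34 °C) that does, a
damage-only variant that also bleaches while the acceleration-only variant
does not. The shipped defaults give a constant-environment bleaching
threshold of 32.3 °C.

Standard initial conditions for every experiment are H = 1, S = 0.1,
j_SG = 1, j_CP = 2.8; seasonal runs start at day −100 so the system reaches
a quasi-steady state before the plotted year.

## Numerics

Stiff BDF integration with rtol = 1e-8, atol = 1e-10 (the relaxation states
and surplus kinks demand tight control); output cadence 1 d, configurable.
Per-symbiont fluxes guard S from below at 1e-12·H so ROS-driven expulsion
can empty the symbiont pool without breaking integrability; the log-state
ratio is clipped to [1e-12, 1e12] inside the right-hand side. Steady-state
classification integrates 1500 d and evaluates at the final time: bleached
iff S/H ≤ 0.05 (the tie counts as bleached), growing iff dH/dt > 0 — the
final-time sign, not an average, to avoid transient ambiguity. Threshold
bisection runs to 0.05 °C. Because the system can be bistable, all steady
states are reported for the standard (functional-symbiosis) initial
condition only.

Default exploration sizes are desk-scale: 8×8 phase-diagram grids over
T ∈ [29, 34] °C with L ∈ [10, 60], N ∈ [0, 1e-6], X ∈ [5e-8, 1e-6];
denser grids are a parameter away. The documented boundary monotonicities
(safe temperature falling with L and N, rising with X) hold on these
ranges; at much higher prey levels the feeding benefit reverses because
prey nitrogen pushes the host into the carbon-limited state — the same
mechanism that makes high DIN harmful at the default maximal host growth
rate and benign at j_HGm = 0.2.

## Scenarios

Seasonal forcing is a 365-day sinusoid with minimum at day 0 ("temperatures
start at 20 °C") and maximum at day 182.5; moderate/extreme presets peak at
30/34 °C. Heat-pulse experiments take explicit base and peak temperatures
(none are printed in the source material, so none are defaulted); the
hysteresis tests use 28 → 34 °C for 30 d. The post-pulse environment at the
default food level (X = 2e-7) is not bistable — the CCMs restart on feeding
carbon and the symbiosis always recovers — so the food contrast uses
X = 1e-8 ("low food": bleached state persists and S/H keeps declining after
the stressor is removed) against X = 2e-7 ("high food": full recovery).
Recovery means returning within 10% of the pre-pulse S/H within 365 d of
pulse end; both knobs are exposed. Interventions modify the environment for
42 d on each side of the seasonal peak: shading (L × 0.8), DIN removal
(N = 0), feeding (X × 3 — an increase *by* 200%). Under the extreme summer
all three raise the annual S/H minimum (0.116, 0.022, 0.007 vs control
0.006); shading prevents bleaching outright.

## Synthetic calibration data

The Fv/Fm generator emulates thermal-performance measurements: n points on
a uniform grid over [16, 40] °C, values on the unimodal curve scaled to a
healthy-yield maximum of 0.6, plus i.i.d. Gaussian noise (default σ = 0.02),
seeded. It mimics the shape information real quantum-yield data carry, not
their heteroscedasticity, species mixture, or uneven temperature coverage —
so calibration tests demonstrate parameter recoverability under clean
conditions, not field robustness. Fitting holds the Arrhenius side fixed
(photosynthesis accelerates like every other rate) and estimates scale,
T_tol and steepness by least squares from a coarse (T_tol, s) grid start;
the amplitude is then discarded in favour of the base-model reference value.
Flat or too-few points are rejected as non-identifiable.

## Limitations

No explicit reserves or damage-state dynamics (stress responses are
effectively instantaneous, which makes the onset of hysteresis immediate);
no diurnal light cycle; a single symbiont taxon; no density dependence; no
direct cost of symbiosis to the host; the CCM allocation rule is fixed
(growth first, surplus to CCMs). Extremely high S/H in the
hot-and-dim regime ("not bleached but dying") should be read qualitatively.
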