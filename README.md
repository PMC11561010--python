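# coraldeb

Bioenergetic simulation of coral–algal symbiosis under heat stress.

`coraldeb` implements a Dynamic Energy Budget (DEB)-style model of a coral
holobiont — host biomass *H* and symbiont biomass *S*, in C-mol — whose
partners exchange surplus nutrients: the symbiont shares surplus fixed carbon
(ρ_C) from photosynthesis, the host shares surplus nitrogen (ρ_N) and spends
its surplus carbon on carbon concentration mechanisms (CCMs) that deliver
CO₂ back to the symbiont. Production steps are synthesizing units (SUs),

    j = ( 1/j_max + 1/A + 1/B − 1/(A+B) )⁻¹ ,

which blend two parallel complementary substrate fluxes *A*, *B* under a
capacity j_max, so the lowest input is the most limiting factor. Captured
light that photosynthesis cannot use is excess light j_eL; non-photochemical
quenching dissipates part of it (capacity k_NPQ), the remainder raises the
reactive-oxygen-species level c_ROS above its baseline of 1. Elevated ROS
depress realised photosynthesis (photoinhibition) and expel symbionts at
rate b·(c_ROS − 1)·j_ST,0 — the model's mechanism of coral bleaching,
operationally defined as the ratio S/H falling to 0.05 or below.

Temperature enters in exactly two places:

1. **Metabolic acceleration** — an Arrhenius factor α(T) (Q10 = 1.88,
   α(28 °C) = 1) multiplying the six rate constants: maximal symbiont/host
   growth, symbiont/host turnover, maximal feeding, maximal DIN uptake.
2. **Photosynthetic damage** — the maximal photosynthesis rate j_CPm(T)
   follows a unimodal curve: the same Arrhenius rise times a steeply
   decreasing logistic damage factor, normalised so the base model is
   recovered exactly at the 28 °C reference. The damage curve can be
   recalibrated from Fv/Fm-style data and translated along the temperature
   axis (e.g. −4 °C) to represent less heat-adapted corals.

Single-mechanism variants (`acceleration`, `damage`) isolate each effect;
`base` removes all thermal terms. The package reproduces the full
simulation battery around the model: seasonal bleaching time courses,
variant dissection, 1500-day steady-state classification, temperature ×
environment phase diagrams, heat-pulse hysteresis experiments, mitigation
interventions, and one-at-a-time parameter sensitivity of the bleaching
threshold.

## Worked example

```python
import coraldeb as cd

p = cd.ModelParameters()                 # 28 °C reference parameter table

# a moderate (peak 30 °C) and an extreme (peak 34 °C) summer, with
# L = 30 mol photons m⁻² d⁻¹, N = X = 2e-7 mol L⁻¹ held constant
for name in ("moderate_summer", "extreme_summer"):
    traj = cd.simulate(p, cd.preset(name))          # days −100 … 365
    print(name, round(traj.min_ratio(0, 365), 4))

print("threshold", cd.bleaching_threshold(p))       # constant-T bisection
```

prints

```
moderate_summer 0.1156
extreme_summer 0.0061
threshold 32.2802734375
```

Under the moderate summer the symbiont-to-host ratio never leaves the
functional range (annual minimum 0.116 > 0.05; it actually *rises* during
the warm months). Under the extreme summer the ratio first rises, then the
CCM feedback collapses photosynthesis and ROS-driven expulsion crashes S/H
to 0.006 — bleaching. The constant-environment bleaching threshold sits at
32.3 °C, between the two seasonal peaks.

A command-line interface mirrors the library
(`coraldeb simulate|variants|steady|sweep|grid|threshold|sensitivity|calibrate|fixture`),
reading a YAML run configuration and writing tidy CSV with a JSON
provenance sidecar keyed by the configuration hash.

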