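# flowpet

Blood-flow quantification from **early-dynamic PET** with
**high-temporal-resolution (HTR) distributed kinetic modeling**.

## The problem

PET blood-flow imaging normally requires a flow-specific tracer
(¹⁵O-water, ¹¹C-butanol) whose short-lived isotopes demand an on-site
cyclotron. With a widely available metabolic tracer such as ¹⁸F-FDG, the
classical surrogate for flow is the blood-to-tissue transport rate

&nbsp;&nbsp;&nbsp;&nbsp; *K*₁ = *F·E*,

which approximates the blood flow *F* only where the extraction fraction *E*
is near 1 — true for few tissues. When the first two minutes of a dynamic
scan are reconstructed at 1–2 s frames, however, the *vascular transit* of
the bolus becomes visible, and a distributed kinetic model can estimate *F*
directly in any tissue.

## The model

`flowpet` implements two tissue impulse responses:

* **S1TC** (standard one-tissue compartment, instantaneous vascular mixing):
  *R*(t) = *v*<sub>b</sub> at t = 0, *K*₁·e^(−*k*₂t) for t > 0.
* **AATH** (adiabatic approximation to tissue homogeneity, plug-flow
  vascular phase):
  *R*(t) = *F* for 0 ≤ t < *T*<sub>c</sub>, and
  *K*₁·e^(−*k*₂(t−*T*<sub>c</sub>)) for t ≥ *T*<sub>c</sub>,
  with *T*<sub>c</sub> = *v*<sub>b</sub>/*F* the mean vascular transit time.

The measured curve is *Q*(t) = *C*<sub>a</sub>(t − t<sub>d</sub>) ⊗ *R*(t),
frame-averaged over the acquisition schedule (the HTR protocol is
60 × 1 s + 30 × 2 s frames). Fitting uses a **basis-function method with
time-delay correction**: an exhaustive grid search over (*k*₂, *T*<sub>c</sub>,
t<sub>d</sub>) with a constrained 2-coefficient weighted linear solve at each
node, guaranteeing 0 ≤ *E* ≤ 1 and 0 ≤ *v*<sub>b</sub> ≤ 1. AIC comparison
across frame-averaging intervals (1/2/3/5/10 s) shows when the distributed
model is supported; a kernel (nonlocal-means-like) smoother built from
composite frames supports voxelwise parametric imaging; and a synthetic-data
engine (regional presets, count-scaled Gaussian TAC noise, digital 4D
phantoms) drives practical-identifiability analysis.

## Worked example

```python
import flowpet as fp

schedule = fp.FrameSchedule.htr_early_dynamic()      # 60 x 1 s + 30 x 2 s
aif = fp.generate_aif(fp.AIFModelParams())           # parametric aortic input

# simulate a noisy cortical gray-matter curve at its preset kinetics
gm = fp.region_presets()[0]
tac = fp.simulate_tac(gm.to_aath_params(), aif, schedule,
                      fp.NoiseConfig(peak_snr=25.0, seed=0), label=gm.label)

# fit the distributed (AATH) model by basis-function least squares
basis = fp.build_basis(aif, schedule, fp.GridConfig.default(), "aath")
fit = fp.fit_tac(tac, basis)
p = fit.params
print(f"blood flow F    : {p.F:.3f} mL/min/cm^3   (truth {gm.F})")
print(f"transport K1    : {p.K1:.3f} mL/min/cm^3   (truth {gm.K1})")
print(f"extraction E    : {p.E:.3f}")
print(f"transit time Tc : {p.Tc:.1f} s            (truth {gm.Tc})")
cmp, = fp.temporal_resolution_study(tac, aif, [1])
print(f"delta AIC       : {cmp.delta_aic:.1f}")
```

prints

```
blood flow F    : 0.543 mL/min/cm^3   (truth 0.507)
transport K1    : 0.139 mL/min/cm^3   (truth 0.136)
extraction E    : 0.256
transit time Tc : 4.0 s            (truth 4.4)
delta AIC       : -20.7
```

— the flow estimate recovers the simulated truth to ~7% under peak-SNR-25
noise, and the negative AIC difference (AATH − S1TC) shows the distributed
model is preferred at native 1-s resolution.

A `flowpet` command-line interface wraps the same machinery
(`flowpet simulate`, `fit-roi`, `model-select`, `identifiability`,
`fit-image`); see `flowpet --help`.

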