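# Methods

## Models and conventions

Two tissue impulse responses are implemented. The standard one-tissue
compartment (S1TC) model assumes the tracer mixes instantaneously in the
regional vascular volume:

    R_S1TC(t) = vb            at t = 0
                K1 e^{-k2 t}  for t > 0

The adiabatic approximation to tissue homogeneity (AATH) is a distributed
model with an explicit plug-flow vascular phase of duration Tc, the mean
transit time of the tracer through the voxel's entire vascular volume:

    R_AATH(t) = F                     for 0 <= t < Tc
                K1 e^{-k2 (t - Tc)}   for t >= Tc

with the identities K1 = F·E (E the first-pass extraction fraction) and
Tc = vb/F. The response is right-continuous at t = Tc with value K1: the
case split assigns the transition instant to the tissue phase. The measured
curve is Q(t) = Ca(t − td) ⊗ R(t), frame-averaged over the acquisition
schedule; Ca(t) = 0 for t < 0.

Units follow the field's tabulated convention: F and K1 in mL/min/cm³, k2 in
1/min, vb in mL/cm³, while all time axes (frames, Tc, td) are in seconds.
Every exponential and convolution integral therefore carries an explicit
1/60 conversion.

The S1TC "vb at t = 0" point value is realized in the forward model as the
additive intravascular term vb·Ca(t − td) — a scaled copy of the input — not
as a convolution-kernel point value, which would have measure zero under the
integral. The AATH intravascular term is the boxcar integral
(F/60)·∫₀^Tc Ca(t − td − s) ds, a smoothed and widened copy of the input.

## Numerics

All continuous operations run on a uniform 0.1 s fine grid (≥10× finer than
the shortest 1 s frame): the input function is linearly interpolated onto the
grid, the time delay td is applied as a continuous shift by linear
interpolation, convolutions with the exponential kernel use an
endpoint-corrected (trapezoid-accurate) discrete convolution, and frame
averages are taken through the running trapezoidal integral. The forward
model and the estimator's basis regressors are built from the *same*
primitives, so a noiseless on-grid truth is recovered to machine precision
(checked to 1e−6 relative, with relative residuals below 1e−10).

Known discretization behavior: as Tc → 0 at fixed vb, the AATH curve
converges to the S1TC curve only first-order in Tc (error ≈ vb·Tc/2·max|Ca′|),
and a constant input reaches its analytic plateau c·(vb + K1/k2) within 0.1%.

## Estimation

Both models are linear in two coefficients once the nonlinear parameters are
fixed — AATH in (F, K1) given (k2, Tc, td), S1TC in (vb, K1) given (k2, td).
Fitting is an exhaustive, deterministic, seed-free search over a
nonlinear-parameter grid with a weighted 2-coefficient linear solve per node.
Physical constraints (coefficients ≥ 0, K1 ≤ F so E ≤ 1, vb ≤ 1) are enforced
exactly by evaluating the unconstrained stationary point and every active
constraint edge of the convex quadratic and keeping the feasible minimum.
Ties in the weighted residual sum of squares are broken toward smaller td,
then smaller Tc, then smaller k2.

Default grids: k2 ∈ [0.01, 3] 1/min on 50 geometric nodes; Tc ∈ [0, 40] s in
0.5 s steps; td ∈ [0, 30] s in 0.5 s steps — spanning the tabulated regional
transit times (4.4–29.1 s) with margin. Default weights are the frame
durations, equalizing the information content of 1 s and 2 s frames; uniform
and inverse-variance (Δt/max(value, floor)) schemes are available.

Regressors are precomputed once per input function: frame averages of the
shifted running integral (vascular phase) and of the shifted exponential
convolutions (tissue phase, one per k2 node), with normal-equation cross
products cached per weight vector. Repeated fits against a shared basis —
replicate simulations, voxelwise maps — then cost only two small
matrix-vector products and a vectorized sweep (~30 ms per curve on the full
default grid).

## Model comparison

The Akaike information criterion uses the Gaussian-likelihood form
AIC = n·ln(RSS/n) + 2k with k = 5 for AATH (F, K1, k2, Tc, td) and k = 4 for
S1TC (vb, K1, k2, td); a positive floor (1e−30) guards exactly-zero
residuals. The small-sample correction AICc = AIC + 2k(k+1)/(n−k−1) is
exposed as an option and off by default.

Frame averaging rebins the 2-min HTR curve into fixed bins of 1/2/3/5/10 s
with duration-weighted overlap. Averaging may merge but never split measured
frames: bin edges that would cut a single measured frame into sub-frames
(the 1 s interval against native 2 s frames) are dropped, so the 1 s interval
is the identity. The duration-weighted time integral is conserved exactly.

On simulated distributed-model data with peak-SNR-25 noise the AIC strongly
prefers AATH at 1 s and 2 s frames (median ΔAIC ≈ −28 and −23 for the
cortical gray-matter preset). At the 10 s interval only 12 frames remain to
support 5 parameters (n/k = 2.4), a regime where the uncorrected AIC is
known to under-penalize; there the uncorrected median ΔAIC stays marginally
negative (≈ −1.6) because, in a simulation whose generator *is* the fitted
model, a residual transit signature survives coarse binning, while the
small-sample-corrected criterion prefers the compartment model (median
ΔAICc ≈ +2.7). The package's coarse-interval comparison test therefore uses
the corrected criterion; this is a property of clean desk-scale simulations
and real data, with unmodeled dispersion and motion, lose the distributed
signature at coarse frames more completely.

Agreement between two paired measurement series (e.g. flow estimates from
two tracers) is summarized by mean difference, 95% limits of agreement
(mean ± 1.96 SD of differences), Pearson correlation, and the least-squares
slope/intercept; zero-variance inputs raise rather than returning a
conventional value, since silent conventions hide upstream bugs.

## Synthetic study conditions

The simulation engine emulates the HTR early-dynamic protocol — 60 × 1 s
plus 30 × 2 s frames over 2 min — for ten tissue regions at their
cohort-mean kinetics (cortical and subcortical gray matter, white matter,
brain stem, cerebellum, spleen, renal cortex, skeletal muscle, bone marrow,
lungs; the lung transport rate uses the cohort median). The clearance rate
k2 is not part of that summary and is derived as k2 = K1/vd with a
per-tissue-class distribution volume: 0.3 mL/cm³ by default, 0.6 for the
spleen and 0.4 for the renal cortex so that every derived rate (0.11–2.0
1/min) lies inside the default search grid. vd is an explicit simulation
knob, not an estimated quantity.

The parametric arterial input is a gamma-variate first pass (arrival 15 s,
peak 150 kBq/mL at 20 s, ~7 s full width at half maximum — sharp enough to
exercise sub-5-s transit times) plus two washed-in exponential recirculation
tails (fractions 0.15/0.05, time constants 40/400 s). By protocol convention
the ascending aorta drives all tissues except the lungs, which use a
right-ventricle input; the simulation uses a single input for all regions.

TAC noise is zero-mean Gaussian with per-frame SD = scale·sqrt(max(Q, floor)
/Δt), the standard count-scaled PET approximation (decay-correction
inflation is negligible over a 2-min scan and omitted). The scale is
calibrated per curve so the peak-frame SNR is 25, typical of kernel-smoothed
HTR regional curves. Replicates and phantom voxels draw independent noise
from a seeded generator; every stochastic operation is reproducible from its
seed.

What these conditions do not emulate: reconstruction-correlated noise,
partial-volume and spillover effects, motion, input-function dispersion,
dual-input organs (liver, lung tumors), and FDG phosphorylation (k3/k4 are
not identifiable in the first minutes and are excluded by design). Passing
recovery bounds here demonstrates the estimator's practical identifiability
under the stated noise model, not clinical accuracy.

## Practical identifiability

For each region, 100 replicate noisy curves are simulated at the preset
truth and fitted; percent errors of F, K1, k2, Tc and vb are summarized as
mean (bias) and SD (variability). At peak SNR 25 with the default grid, the
blood-flow bias stays within 5% and the SD within 15% for every region
except skeletal muscle — whose very low flow (0.039 mL/min/cm³) and long
transit (29.1 s) make it the known hard case, with mean overestimation of a
few percent and SD near 15–27% depending on the seed. Part of the small
regional biases (~2%) is Tc/k2 grid discretization, since the preset transit
times do not all lie on the 0.5 s grid.

## Parametric imaging and kernel smoothing

Voxelwise fitting reuses one precomputed basis for all masked voxels, so a
voxel's map values equal a regional fit of its curve. Maps are produced for
F, K1, k2, Tc, td, vb, E and RSS (NaN outside the mask; the S1TC-specific
subset when that model is selected).

The kernel smoother builds, per masked voxel, a feature vector of z-scored
composite-frame intensities (defaults 0–30, 30–60, 60–120 s — composites
adapted to the 2-min early-dynamic window), selects the k = 49 most
feature-similar masked voxels inside a 9 × 9 × 9 spatial window (self always
included; fewer where the window holds fewer masked voxels), and assigns
Gaussian weights in feature distance with a per-voxel bandwidth equal to the
median neighbor distance (uniform weights when all distances vanish), row
normalized. Spatial coordinates are deliberately excluded from the feature
vector; locality comes only from the window. Rows sum to 1, so uniform
images are invariant; with well-separated region intensities neighbors never
cross boundaries and piecewise-constant images are preserved exactly.
Parametric maps are smoothed with the same operator built from the
composites, not rebuilt from the maps.

The default digital phantom is a 24³ volume with ten cuboid regions and a
blood-pool or zero background; tests use 12³ phantoms with three regions and
grids containing the preset values exactly, keeping voxelwise runs to
seconds while exercising the full mechanism.

## Problem sizes

Suite and reproduction-script sizes were chosen at desk scale: 100
replicates per region for identifiability (~35 s), 20 replicates for the
temporal-resolution comparison, 20 random curves for the
independent-optimizer cross-check, and 12³ phantoms for imaging round
trips.
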