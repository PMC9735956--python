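# Methods

This note documents the models implemented in `thzcornea`, the choices
made where the design was genuinely open, and what the synthetic data
can and cannot say about real measurements.

## Conventions

All frequency-domain physics uses the `e^(-iωt)` time convention: lossy
media have `Im ε ≥ 0` and `Im n ≥ 0`, and a forward wave
`e^(i(kz−ωt))` decays in an absorbing layer. NumPy's inverse DFT
synthesises signals with the conjugate kernel, so a physics reflectance
is conjugated exactly once — inside `simulate.synthesize_trace` — when
it is imposed on a sampled pulse. Keeping the sign rule in one place is
deliberate: mixed conventions are the dominant failure mode of layered-
media code, and every oracle test in the suite would catch a violation.

Units: time in ps, frequency in THz (their product is dimensionless),
depth in µm, diffusion in µm²/min, pressure in mmHg. The spectral slope
is d|H|/df with |H| dimensionless and f in THz, hence ps.

## Tissue optics

**Water permittivity.** Double-Debye relaxation with the widely used
liquid-water parameter set ε∞ = 3.48, Δε₁ = 73.43, τ₁ = 8.24 ps,
Δε₂ = 1.45, τ₂ = 0.18 ps (static permittivity 78.36). The model class
is standard for this band; the specific values are a configurable
choice, not a fit.

**Composite tissue.** The symmetric Bruggeman rule mixes water with a
non-dispersive tissue background (ε_b = 4.0, configurable). The mixing
equation is quadratic in the effective permittivity; the closed-form
root with positive real part and non-negative imaginary part is
returned, endpoint fractions (0 and 1) are returned exactly, and the
residual of the mixing equation at the returned root is below 10⁻¹²
(property-tested over random lossy inputs).

**Stratified reflectance.** Characteristic 2×2 transfer matrices at
normal incidence, validated against an independently coded Airy
multiple-reflection series to 10⁻¹⁰ on one- and two-layer stacks.
Oblique incidence, scattering and polarization are out of scope. The
matrix product grows like `e^(Σ Im δ)`; for the stacks generated here
(≤ 300 µm of hydrated tissue below 15 THz) the exponent stays below ~5,
far from overflow.

## Hydration model

**Depth profile.** The erfc solution of Fick's second law for a
semi-infinite medium with fixed boundary concentration,
`C(z,t) = C0 + (C1−C0)·erfc(z/(2√(Dt)))`, with D = 40 µm²/min — a
diffusion length of roughly 200 µm over the 4 h pressure step, i.e. the
gradient penetrates a meaningful fraction of the stroma without
equilibrating it. The profile is evaluated quasi-statically with the
current boundary fraction C1(t) and elapsed time, and discretised into
20 equal layers over 300 µm on a bulk half-space; the bulk water
fraction is C0 = 0.75, a standard stromal value.

**Boundary dynamics.** The study protocol gives no quantitative link
between IOP and water influx, so the boundary fraction follows a
deliberately minimal two-rate balance:

    dC1/dt = k_in·(1 − e^(−ΔIOP/s)) − k_out·p·(C1 − C0),  C1 ∈ [0.60, 0.95]

with k_in = 8·10⁻⁴ /min, s = 10 mmHg, k_out = 0.05 /min, and p the
pump efficacy. The influx saturates in the overpressure so the 25, 35
and 45 mmHg groups produce comparable (not proportional) hydration
loads — consistent with the observation that damage state, not insult
magnitude, dominates the response. With p ≈ 1 the equilibrium excess is
k_in/k_out ≈ 1.5% water fraction, reached with a 20 min time constant
and pumped back out promptly after the pressure drops (the intact,
reversible archetype); with p ≈ 0 the load accumulates to ~0.15 over
4 h and persists through recovery (the damaged archetype). These rates
are free parameters of the generator, not estimates of the real system.

**Cell density and pump.** ECD is drawn from a two-component lognormal
mixture: intact mode median 5500 cells/mm², σ_log = 0.15 (within the
healthy porcine range of roughly 3500–6500, where SEM-based counts can
run higher); damaged mode median 1500, σ_log = 0.20; mixture weight
0.5. Pump efficacy is logistic in ECD with midpoint 3000 (the
intactness threshold) and scale 300, so the two modes map to p ≈ 1 and
p ≈ 0 with a narrow crossover. The default mixture deliberately avoids
placing samples on the threshold: the generator's purpose is a cohort
whose label structure is known, and its measured S_Elev class
separation (≈ 7–9 pooled SDs, seed-dependent) is a design property,
not a biological claim.

**Reference pulse and scan geometry.** The emitted pulse is a
third-derivative-of-Gaussian wavelet (σ = 0.46 ps, peak near 0.6 THz,
>99% of its energy in 0.1–2 THz), sampled at 0.0333 ps over 2048
points. The reference scan is the pulse off a perfect conductor
(r = −1). Sphere curvature and alignment are not modelled: the
deconvolution divides them out to first order in the real instrument,
so all 81 pixels are statistically exchangeable up to additive white
detector noise (σ = 0.01 of the unit pulse peak). Archives store traces
as float32 — the noise floor makes the extra mantissa meaningless — in
HDF5 with timestamp tracking disabled, so identical seeds give
byte-identical files.

## Signal processing

The high-pass filter is parameterised by its half-gain point: gain
`1 − e^(−f²/2σ_f²)` with σ_f chosen so the gain at the 0.1 THz cutoff
is exactly 0.5. Deconvolution is Wiener-regularised with λ = 10⁻³ of
the reference peak magnitude (bare division would amplify out-of-band
noise); both sample and reference pass through the same filter, so the
filter cancels in-band. The FFT length equals the trace length (no
zero-padding), giving a bin spacing of 0.01466 THz and 27 bins inside
the 0.4–0.8 THz band. The band is inclusive on both edges and the
slope is fitted on linear amplitude, not dB — that is what makes its
units ps. On a noiseless synthetic half-space the full
trace-level pipeline reproduces the slope computed directly from the
model |r(f)| to better than 0.1% (tested at 1%).

One figure of the source protocol quotes a 0.4–1 THz band where the
text uses 0.4–0.8 THz; the band is a configuration parameter and the
default follows the text.

## Features

Each frame is reduced to the mean of the central 5×5 pixel block
(rows/columns 2–6 of the 9×9 grid). NaN pixels are excluded up to 20%
of the block, beyond which the frame errors out. Averaging windows are
the last 30 min of each period, half-open `(T_end−30, T_end]`: with
4 min sampling each window holds exactly 8 frames and the frame at
`T_end−30` is excluded — an explicit convention, since the protocol
wording does not settle the boundary frame. A scan taken exactly at a
pressure-step instant is annotated with the pressure of the period it
concludes.

## Classification

"Bootstrapping" at n = 19 is implemented operationally as Monte Carlo
cross-validation: 300 independent 70/30 splits, stratified by class
(a plain random split with bounded redraws of single-class test sets is
available by flag). Per split, predictors are z-scored with
training-split statistics, the SVM margin penalty is grid-searched over
{10⁻³…10³} by stratified k-fold cross-validation (k = min(5, smallest
class count)) on the training split scored by accuracy with ties to the
smaller C, and the test ROC comes from the decision function. The grid
search runs inside every iteration — nesting it avoids selection leaking
across splits. The CV loop is a small explicit loop over scikit-learn
primitives rather than `GridSearchCV`; at 13 training samples the
framework overhead dominates the fit, and the loop keeps every RNG
draw seeded. Mean ROC curves are vertical averages on a fixed 101-point
FPR grid with the endpoints pinned to (0,0) and (1,1), the usual
convention for averaged empirical ROCs. No multiple-testing correction
is applied across the four predictor sets; raw AUCs are reported.

Split randomness is keyed per class by the class's *smallest member
index*, not its label, so relabelling samples cannot change the
partition. AUC label-flip antisymmetry (AUC → 1−AUC) holds at the
scoring level — retraining on flipped labels negates the decision
function and leaves AUC invariant, which is why the identity is tested
on scores, not on retrained models.

The kernel is linear by default; other scikit-learn kernels pass
through unchanged but are not part of the evaluated configurations.

## Determinism

Every stochastic component draws from `numpy.random.SeedSequence` keys
derived from one master seed: cohort-level draws from `(seed, 0)`,
per-sample noise streams from `(seed, 1, sample_index)`, split i of an
evaluation from `(seed, i)` plus the class key, its CV fold shuffle
from `(seed, i, 10⁶)`. Rerunning any stage with the same configuration
and seed reproduces every output byte for byte, archives included.

## Problem sizes

Default study conditions: 19 samples (7/6/6 across 25/35/45 mmHg),
136 frames of 9×9 traces of 2048 points, 300 SVM iterations per
predictor set. A full end-to-end run produces a ~1.7 GB archive and
takes on the order of 1–2 min on one CPU; unit tests run on reduced
cohorts (512-point traces, shortened protocols) chosen so every code
path is still exercised.

## What the synthetic data does not show

The generator realises the *assumed* statistical structure — monotone
hydration/reflectance physics, exchangeable pixels, class-separated
hydration dynamics — so green tests demonstrate that the pipeline
recovers structure that is present, not that real corneas possess it.
Omitted features of real scans include curvature and alignment
residuals, time-of-arrival jitter, drift and 1/f detector noise,
epithelium/tear-film layering, inter-sample variation in stromal
thickness and baseline hydration, and any coupling between IOP and
geometry. Headline numbers from the original ex vivo experiment
(e.g. an AUC of 0.91 ± 0.12 on 19 real globes) are therefore not
reproduction targets for this package; on the synthetic defaults the
two-feature model separates the classes essentially perfectly, because
the generator was designed to make the label structure recoverable.
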