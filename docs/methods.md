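# Methods

This note records the models, estimators and numerical choices behind
cardioflux, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one defensible option existed.

## Signals and conventions

Time is 0-based from the first sample; all windows are half-open
`[start, end)`. Acquisition grids must be strictly increasing and uniform
to 1 part in 10⁶; non-finite samples are rejected at read time rather than
imputed, because silent interpolation corrupts kinetics. The 340/380 nm
excitation pair is represented as two already-aligned columns on one grid
(de-interleaving of raw photomultiplier streams is upstream of this
package). An optional per-channel constant dark background (default 0) can
be subtracted before ratioing. ΔF/F0 uses the mean F over a caller-chosen
baseline window (≥ 10 samples) as F0.

## Transient waveform model

A beat is modelled as `amplitude · g(t − t_stim)` on top of the diastolic
level, where `g` rises as a product of exponentials and decays exactly
monoexponentially:

    g(t) = (1 − e^(−t/τ_r)) e^(−t/τ_d) / g_peak    0 ≤ t ≤ t*
    g(t) = e^(−(t − t*)/τ_d)                        t > t*
    t*   = τ_r ln(1 + τ_d/τ_r)

The rise constant τ_r is solved from a requested time-to-peak through the
closed peak-time relation (Brent's method on a bracketing interval; a
solution exists iff TTP < τ_d). The decay limb being *exactly*
exponential is deliberate: with the plain product kernel, a monoexponential
fit started at the peak is contaminated by the residual rise term and
overestimates τ by 10–30 % even on noiseless data (worst for slow,
mitochondrial-like rise times). With the piecewise kernel, amplitude,
time-to-peak and τ are independent, analytically defined parameters, and
superposed tails of previous beats share the same τ, so incomplete decay
between beats (e.g. τ 0.27 s at 1 Hz) cannot bias the fitted τ either —
only the measured diastolic level and amplitude shift by the residual tail
(≈ 3–4 % under that protocol), which is a property of the pacing protocol
itself. The price is a slope discontinuity of size 1/τ_d at the peak;
noiseless recovery tests therefore pin amplitude/τ/diastolic to ≤ 0.5 %
and time-to-peak to one sample (2.5 ms at 400 Hz) rather than to machine
precision.

## Per-beat estimators

* **Beat windows**: one window `[stim, stim + 1/f)` per stimulus; explicit
  stimulus times override the frequency-derived train; a final window not
  fully covered by the recording is dropped.
* **Diastolic**: mean of the 50 ms (configurable) immediately *preceding*
  the stimulus — the field convention, and necessary because transients
  with slow rise begin moving within milliseconds of the stimulus, so a
  post-stimulus "baseline" would be contaminated by up to half the
  amplitude for mitochondrial kinetics. For a first beat without
  pre-stimulus samples the first 50 ms of the window is used instead. The
  generators emit a quiet pre-stimulus lead-in (default 1 s) so this
  fallback is rarely exercised.
* **Noise floor**: beats with amplitude ≤ k·SD(baseline) (k = 3) are
  rejected with a reason rather than fitted.
* **Smoothing**: a 5-sample moving average (12.5 ms at 400 Hz) is applied
  only for the noise screen and the derivative estimate; the maximum rate
  of rise is the maximum central-difference derivative of the smoothed
  signal between stimulus and peak, reported per ms. Because the kernel's
  true derivative maximum sits at the onset, discretisation plus smoothing
  understate it systematically (up to ~25–35 % for fast rises at 400 Hz);
  the bias is consistent across conditions, so group contrasts are
  preserved, and tests bound it rather than pretending it away.
* **Peak and amplitude**: the raw argmax locates the peak (exact on
  noiseless data, free of the early shift a moving average imposes on an
  asymmetric peak). The peak *value* is then denoised: with the default
  peak-anchored decay fit, peak = A + C from the fit, which averages the
  whole decay limb instead of trusting one noisy sample. A single-sample
  or smoothed maximum is an extreme-value statistic and overestimates the
  amplitude by ~7–10 % at mitochondrial SNR (amplitude 0.033, noise 0.005).
* **SNR-gated waveform fit**: below a beat SNR of 20 (configurable;
  "always"/"never" available) even the fit-anchored estimate retains a
  few-percent convex bias from anchor-time jitter, so amplitude and
  time-to-peak are refined by a least-squares fit of the full
  rise-and-decay template to the beat. At the mitochondrial settings this
  reduces the amplitude bias to ≈ 0.3 % (per-seed spread −0.8…+1.3 %
  over 30 seeds). τ always keeps its tail-fit definition.
* **Decay fit**: `A·exp(−(t−t_p)/τ) + C` by trust-region least squares
  (`scipy.optimize.curve_fit`, τ > 0 bound), seeded by a log-linear
  regression on the early decay; C is free so residual drift does not bias
  τ; RMSE and R² are reported so callers can filter. The fit may
  alternatively start where the signal has fallen to 90 % of amplitude.
  Non-convergence marks τ invalid with a reason instead of raising.
* **Steady state**: mean ± SEM (SD/√n, 0 for n = 1) of each parameter over
  the last n accepted beats; rejected beats are listed with reasons.

## Caffeine assay

Diastolic comes from the 2 s before the bolus; the peak is sought within
10 s after it (raw argmax, screened by the smoothed maximum against
3·SD(baseline) — "no caffeine response" otherwise). The efflux fit runs
from the peak to the earlier of the first return to within 5 % of
amplitude or the end of record, and the store amplitude is the fitted
A + C minus diastolic, as above. The bolus time comes from the event
annotation; for unannotated traces an onset detector (first smoothed
excursion above diastolic + 5·SD) is provided. The generator uses a fixed
0.5 s linear rise so that the decay is exactly exponential from the peak;
a post-event record shorter than 3τ triggers a truncation warning.

## Respirometry and membrane potential

States start a settle time (default 60 s) after their event and end at the
next event. Flux is −slope([O₂]) × chamber volume × 1000 / mass
(µM s⁻¹ · mL → pmol s⁻¹, per mg), least-squares over the state window; a
positive slope beyond tolerance flags the state but still returns the
value. The steady flag bounds the flux drift (quadratic term of the tail
O₂ course) by 0.1 pmol s⁻² mg⁻¹.

Membrane potential uses Nernstian partitioning of safranine-O (z = +1):

    ΔΨ = (RT/zF) ln(C_out/C_in),  C_out = C_RB,
    C_in = (C_FCCP − C_RB) · V_RB / V_mito

with R = 8.314 J mol⁻¹ K⁻¹, F = 96485 C mol⁻¹, T defaulting to 310.15 K
(37 °C assay), V_RB = 2 mL and V_mito = 3.1 µL per mg of tissue. C_FCCP —
the signal after uncoupling — already excludes non-mitochondrial dye
uptake (C_total − C_FCCP), which is why it, not C_total, enters C_in. The
subtraction is read as (C_FCCP − C_RB)·V_RB/V_mito; the alternative
reading C_FCCP − (C_RB·V_RB/V_mito) is dimensionally inconsistent with a
concentration subtraction and incompatible with ΔΨ → 0 at C_in = C_out.
ΔΨ is evaluated on the mean safranine signal over the last third of each
state; the FCCP state is 0 mV by definition. The closed-form inverse
(used by the generator) is C_RB = C_FCCP·kr/(1+kr) with
k = exp(ΔΨ·zF/RT), r = V_RB/V_mito. Useful identities: 61.5 mV per
tenfold concentration ratio at 310.15 K; ΔΨ = 0 at C_RB = C_FCCP·r/(1+r).
The safranine channel is assumed pre-calibrated to µM; a two-point linear
helper (0 and C_total) is provided. mPTP opening during Ca²⁺ titration is
detected as a sustained safranine rise (> 10⁻³ µM s⁻¹ by default) —
detection only, no modelling. Free [Ca²⁺] after CaCl₂ additions is looked
up in an externally supplied ladder (e.g. 0.3 mM cumulative → 0.39 µM);
speciation is never computed here.

## Cluster analysis

Segmentation: optional rolling-ball background subtraction (off by
default), a global threshold (Otsu by default, or a fixed value — the
method and value are recorded in every output), 8-connected components,
then a marker-controlled watershed (markers = local maxima of the
2-px-Gaussian-smoothed intensity, minimum separation 5 px; any component
without a detected maximum keeps its brightest pixel) that splits touching
clusters and reduces exactly to connected components when spots are
separated. Plain thresholding cannot work at realistic STED densities: at
≈ 15 clusters/µm² with mean area 0.027 µm² (≈ 40 % coverage) half-max
contours nearly touch, and components merge whenever centres are closer
than ~1.4 spot widths. Clusters under 4 px (≈ 0.0009 µm² at 15 nm — shot
noise, two orders below the smallest reported clusters) are discarded;
frame-edge clusters are kept but flagged so callers can exclude their
clipped areas (`ClusterSet.interior()`). Pixel (0,0) is top-left;
physical coordinates are (col, row)·pixel size; areas are
pixel-count·pixel-size² exactly.

Density tiles the frame from the origin with 1 µm² squares (partial edge
tiles excluded) and assigns each cluster to the tile containing its
centroid. Fractional area is the percentage of ROI pixels above threshold
(polygon ROI in µm, full frame by default). Nearest-neighbour distances
are KD-tree queries between centroid sets, with self-exclusion when a set
is compared against itself; colocalization is expressed only through these
distances, not through intensity-correlation coefficients.

## Synthetic generators

Every generator is a deterministic function of a mandatory seed, and every
generator/analyzer pair closes a round trip (noiseless recovery to solver
tolerance; unbiased noisy recovery at the documented SNRs). Noise is
additive white Gaussian; photobleaching is a linear drift term.

* **Traces**: ratiometric mode constructs F380 = B·(1 − s·ĝ(t)) and
  F340 = R(t)·F380, so the computed ratio reproduces the (noisy) target
  signal exactly while the two channels move anti-correlated with
  modulation depth s (default 0.3). Single mode emits
  F = F0·(1 + signal), so ΔF/F0 against the quiet lead-in recovers the
  target exactly.
* **Oxygraph**: piecewise-linear O₂ per state and a per-state constant
  safranine level from the closed-form Nernst inverse (C_FCCP for the
  FCCP state); event markers at state boundaries; protocol order
  GMP → ADP_HEX → CACL2… → FCCP enforced.
* **Cluster images**: spot count Poisson(density × area) or fixed; areas
  lognormal with the requested mean and log-sigma 0.5 (chosen because it
  reproduces the published per-cluster SD of ≈ 0.01 µm² at means
  0.027–0.034 µm²); positions by random sequential adsorption,
  largest-first, with per-pair minimum separation factor × (r_i + r_j)
  (factor 1.0 = contact) and a bounded attempt budget (error if the
  density is geometrically infeasible). Each spot is rendered as a uniform
  disk of its ground-truth area blurred by a Gaussian PSF (σ 20 nm), the
  physically appropriate model for STED imaging of structures much larger
  than the PSF: its half-maximum contour encloses exactly the ground-truth
  area, Otsu lands near half-max on such images, and near-contact disks
  produce negligible bridge area — which is what makes count and area
  recovery possible at 40 % coverage. A pure Gaussian profile
  (FWHM = 2√(area/π)) is available for sparse fields but cannot realise
  the dense published settings, since separating Gaussians by thresholding
  requires ≈ 1.4 FWHM spacing, capping density near 9 µm⁻².
* **Group study**: per-cell parameters are drawn around the published
  CON/MCT group means. Printed dispersions are interpreted as SEM and
  scaled by √n where that is consistent with the printed significance
  levels, and as per-cell/per-section SDs where SEM×√n would exceed the
  mean (cytosolic amplitudes and rates of rise) or where an SEM over
  N = 3 hearts cannot reproduce the reported p-values (cluster metrics) —
  per-section SDs with ~15 sections/group do. Non-positive draws are
  redrawn (counted in the manifest), time-to-peak draws are constrained
  below 0.9·τ, and image parameter pairs are redrawn while
  density × area > 0.45 (the generator's packing-feasibility cap; this
  shifts the realized per-image densities below the configured means but
  leaves every recorded ground truth and both group contrasts intact).
  Mitochondrial noise scales with the drawn amplitude (10 %) so that weak
  cells remain above the analyzer's own rejection floor, as usable
  recordings must be. The manifest records every drawn value, the
  configured group tables and the expected effect directions.

## What the generators do not emulate

Photon (Poisson) noise, dye photophysics and compartmentalisation,
movement artefacts, de-interleaving of excitation streams, real STED PSF
shape and depletion-power effects, anisotropic or clustered-beyond-Poisson
spot placement, instrument drift in the oxygraph, and biophysical
EC-coupling (no LTCC/RyR2/SERCA fluxes — the kernel is phenomenological).
Passing the recovery suites therefore demonstrates correctness of the
estimators under the stated noise model, not robustness to every
real-world artefact.

## Problem sizes

The recovery suites use 100 seeds × 20 beats for the paced-τ check, 50
seeds for the caffeine medians, 60 replicate cohorts for the caffeine
effect-direction check, single 15 × 15 µm frames (1000 × 1000 px) per
TOM20 setting, and a full two-group cohort (12 cytosolic, 37 caffeine,
20 mitochondrial cells; 30 TOM20 + 30 RyR2 frames; 4 oxygraph chambers)
for the end-to-end run — sizes at which each statistic is stable at its
stated tolerance.

## Known limitations

Time-to-peak is grid-quantised at high SNR (±2.5 ms at 400 Hz) and
model-refined only below the SNR gate; the maximum rate of rise is
systematically understated as described; diastolic and amplitude inherit
the residual-tail offset under pacing faster than ~5τ; per-state flux
assumes linear O₂ consumption within a state; the watershed cannot split
clusters whose intensity maxima merge (centre distance below ~2 smoothing
sigmas); and the fixed-threshold fractional area is as good as the chosen
threshold — Otsu is a convention, recorded in every output, not a claim.
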