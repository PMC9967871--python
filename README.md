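# cardioflux

Quantification of cardiomyocyte Ca²⁺ handling and mitochondrial function,
built for studies of right-ventricular hypertrophy (e.g. the monocrotaline
rat model of pulmonary artery hypertension, MCT vs saline controls) but
applicable to any paced-myocyte fluorescence, respirometry, or
super-resolution cluster data in the same formats.

The package covers four measurement classes, each with a matching
synthetic-data generator so that every stage can be validated by parameter
recovery without any external data:

1. **Beat-wise Ca²⁺ transients** — two-channel Fura-2 (340/380 nm ratio,
   cytosolic) or single-channel Rhod-2 (ΔF/F0, mitochondrial) recordings
   sampled at 400 Hz are segmented into stimulus-aligned beats and reduced
   to the kinetic quintet: diastolic level, amplitude, maximum rate of rise
   (a.u. ms⁻¹), time to peak, and the decay time constant τ from a
   least-squares monoexponential fit
   `y(t) = A·exp(−(t−t_p)/τ) + C` with free offset.
2. **Caffeine-bolus SR-store assay** — with pacing stopped, a 20 mM
   caffeine bolus empties the sarcoplasmic reticulum: the transient's
   amplitude measures total SR Ca²⁺ content and its decay τ in the
   continued presence of caffeine measures trans-sarcolemmal efflux
   (predominantly NCX).
3. **Respirometry + membrane potential** — event-marked oxygraph
   recordings are segmented into respiratory states (CI Leak, CI OXPHOS,
   Ca²⁺ titration, FCCP); O₂ flux is the per-state slope scaled to
   pmol s⁻¹ mg⁻¹, and the safranine-O signal is converted to the
   mitochondrial membrane potential via Nernstian dye partitioning:
   ΔΨ = (RT/zF)·ln(C_out/C_in) with C_out = C_RB and
   C_in = (C_FCCP − C_RB)·V_RB/V_mito (V_mito = 3.1 µL per mg tissue).
4. **STED/confocal cluster analysis** — immunolabel clusters (TOM20, RyR2,
   phalloidin) are segmented by thresholding, connected components and a
   marker-controlled watershed for touching spots; outputs are per-cluster
   areas (µm²), cluster density per 1 µm² tile, fractional labelled area
   (%), and centroid nearest-neighbour distances.

All inputs are plain text or TIFF: CSV traces with a JSON metadata sidecar,
CSV oxygraph records, TIFF frames with the pixel size in a sidecar.

## Worked example

Generate a paced recording with known ground truth (amplitude 0.5,
τ = 0.27 s, 1 Hz, Gaussian noise at 2 % of amplitude) and recover the
kinetics:

```python
import cardioflux as cf

spec = cf.TransientGenSpec(seed=42, diastolic=1.0, amplitude=0.5,
                           time_to_peak_s=0.08, tau_decay_s=0.27,
                           stim_freq_hz=1.0, n_beats=20, noise_sd=0.01)
trace, truth = cf.gen_transient_trace(spec)
ratio = cf.compute_ratio(trace)                  # 340/380 ratio signal
params = cf.analyze_trace(ratio)                 # one record per beat
summary = cf.steady_state_summary(params, n_last=10)
for k in ("diastolic", "amplitude", "time_to_peak", "tau_decay", "max_rate_of_rise"):
    print(f"{k:18s} {summary.mean[k]:8.4f} +/- {summary.sem[k]:.4f}")
```

prints

```
diastolic            1.0182 +/- 0.0004
amplitude            0.4979 +/- 0.0021
time_to_peak         0.0783 +/- 0.0015
tau_decay            0.2699 +/- 0.0011
max_rate_of_rise     0.0153 +/- 0.0002
```

i.e. amplitude and τ are recovered within 0.5 % of the configured values
(diastolic sits 1.8 % above 1.0 because at 1 Hz the previous beat has not
fully decayed — a property of the pacing protocol, not of the fit; see
`docs/methods.md`). The same round trip for the caffeine assay:

```python
trace, _ = cf.gen_caffeine_trace(store_amplitude=0.59, tau_efflux_s=6.07,
                                 seed=7, noise_sd=0.02)
res = cf.analyze_caffeine(cf.compute_ratio(trace))
print(f"store {res.store_amplitude:.3f} a.u., tau_efflux {res.tau_efflux:.2f} s")
# store 0.575 a.u., tau_efflux 6.03 s
```

A command-line interface mirrors the library:

```sh
cardioflux simulate transients --seed 3 --out sim/
cardioflux transients sim/transients.csv beats.csv --n-last 10
cardioflux caffeine trace.csv result.json --event-time 30
cardioflux oxygraph oxy.csv states.json --mass-mg 2 --ladder ladder.json
cardioflux clusters image.tif clusters.csv --pixel-size-nm 15
cardioflux simulate study --seed 42 --out study/
```

## Layout

```
src/cardioflux/
  io.py         readers/writers + ratio and dF/F0 derivation
  transients.py beat segmentation and kinetic parameters
  caffeine.py   SR-store / efflux assay
  oxygraph.py   respiratory states, O2 flux, safranine-O Nernst calibration
  clusters.py   cluster segmentation, density, fractional area, NND
  waveform.py   the shared transient waveform template
  synth.py      synthetic generators with ground truth
  study.py      two-group synthetic cohort + end-to-end pipeline
  cli.py        the `cardioflux` command
docs/methods.md model assumptions, estimator choices, limitations
```
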