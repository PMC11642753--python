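# triphasic

Analysis of cortical spiking evoked by brief optogenetic photostimulation of
the mouse hand, recorded simultaneously in hand/forelimb primary
somatosensory (S1) and motor (M1) cortex — packaged with a synthetic-cohort
generator so that every stage of the pipeline can be validated by parameter
recovery without any recorded data.

## Who this is for

Systems neurophysiologists analyzing stimulus-aligned extracellular
recordings (sorted single- and multi-units from linear probes) who need a
tested, reproducible implementation of the standard evoked-response
workflow: peristimulus time histograms, z-score responsiveness detection,
triphasic peak–suppression–rebound parameterization, laminar profiles,
PV-interneuron opto-tagging, paired-pulse excitability, propagation-speed
morphometry, and partial-silencing quantification.

## The model

Each unit's spiking is treated as an inhomogeneous Poisson process whose
peristimulus rate r(t) is

  r(t) = λ₀ + K(t) + S(t) + R(t)

with baseline λ₀ (Hz); a triangular peak kernel K(t) rising from an onset
near 15 ms (S1) / 24 ms (M1) to an amplitude of tens of Hz and
self-terminating within ~25 ms; a suppression step S(t) = (f − 1)·λ₀ on
110–170 ms (f ≈ 0.08, i.e. firing drops to ~8% of baseline in affected
units); and a Gaussian rebound bump R(t) centered near 280–290 ms within
190–400 ms. Analysis mirrors the standard measurement conventions:

- PSTHs: 5-ms bins, −0.5 to +0.5 s around stimulus onset, trial-averaged
  (25 trials), z-scored against the 250-ms pre-stimulus baseline.
- A unit is **stimulus responsive** when max post-stimulus z > 2.5. The
  baseline s.d. is floored at the single-spike rate quantum 1/(NΔ) so the
  threshold stays meaningful at ~1-Hz baselines (see `docs/methods.md`).
- **Peak metrics**: onset = first bin exceeding 2.5 s.d. (bin centers),
  amplitude = max baseline-subtracted rate within 100 ms, duration = time
  until the rate first falls below 1 s.d. above baseline.
- **Suppression / rebound**: per-trial window rates vs per-trial baseline
  rates, exact paired Wilcoxon signed-rank at α = 0.05.
- **Propagation speeds**: pathway distance / latency per recording, averaged
  as a mean of ratios (44.3 mm hand→S1; per-recording probe distance S1→M1).
- Population statistics: two-level pooling (units → recording means →
  grand mean ± s.d.), paired signed-rank area comparisons, Spearman ρ with
  t-transform p-values, Benjamini–Hochberg FDR, Friedman + Dunn–Šidák for
  paired-pulse lags.

## Worked example

Generate the default 13-recording synthetic cohort and analyze it:

```bash
triphasic synth   --out cohort --seed 7 --n-recordings 13
triphasic analyze --spikes cohort/spikes.csv --units cohort/units.csv \
                  --trials cohort/trials.csv --manifest cohort/manifest.json \
                  --out analysis
triphasic report  --analysis analysis --spikes cohort/spikes.csv \
                  --units cohort/units.csv --trials cohort/trials.csv \
                  --out report
```

`analysis/summary.csv` then contains (mean ± s.d. across 13 recordings,
paired signed-rank p):

```
         parameter  s1_mean  s1_sd  m1_mean  m1_sd  p_value
       baseline_hz    1.217  0.138    0.577  0.078    0.000
    responsive_pct   40.000  8.036   20.385  8.345    0.001
          onset_ms   15.872  1.814   26.857  3.345    0.000
           peak_ms   22.595  1.508   30.640  2.200    0.000
      amplitude_hz   76.260  9.172   40.240  5.093    0.000
    suppressed_pct   17.581  6.833    5.287  7.186    0.000
       rebound_pct   26.199  6.896   16.141 17.914    0.057
rebound_latency_ms  282.368 11.888  276.375 25.334    0.375
```

Reading it: responsive units are about twice as common in S1 as in M1;
S1 responses begin ~16 ms after the stimulus and M1 ~11 ms later; S1
amplitudes are roughly double M1's; suppression and rebound are S1-dominant.
These recover the generator's ground truth (baseline 1.2/0.6 Hz, onset
targets 14.7/24.3 ms, 36.7%/25.6% responsive) up to the detection and test
biases quantified in `docs/methods.md`. `analysis/speeds_summary.csv` gives
the propagation speeds (hand→S1 2.8 ± 0.3 m/s onset-based; S1→M1
0.10 ± 0.04 m/s — a ~20-fold drop from the subcortical to the
corticocortical leg), and `analysis/tags.csv`, `paired_pulse.csv` and
`silencing.csv` the opto-tag, excitability-recovery and partial-silencing
results.

## Layout

```
src/triphasic/
  synth.py     synthetic cohort generator (presets, rate profiles, thinning)
  psth.py      binning, averaging, z-scoring, responsiveness, pooling
  metrics.py   peak/suppression/rebound metrics, summaries, Spearman, BH
  laminar.py   depth binning and laminar amplitude profiles
  optotag.py   PV classification from laser/sham trials, PV partitions
  pathways.py  propagation speeds, paired pulse, silencing integrals
  pipeline.py  orchestration; cli.py + report.py  command-line front end
docs/methods.md  model, conventions, calibrations, known limitations
```
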