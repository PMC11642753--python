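# Methods

## Scope

The package has two halves that validate each other. The *generator*
(`synth.py`) produces spike tables for a cohort of paired S1+M1 recordings
whose underlying rate structure follows the triphasic evoked-response
pattern (short-latency peak, 110–170 ms suppression, 190–400 ms rebound),
with opto-taggable PV interneurons, laminar amplitude structure, paired-pulse
recovery and partial-silencing conditions. The *pipeline* (`psth.py` →
`metrics.py` → `laminar.py` / `optotag.py` / `pathways.py`) implements the
standard stimulus-aligned analysis. Because the generator retains every
unit's ground truth in a manifest, the pipeline is tested end-to-end by
parameter recovery.

## Generative model

Spiking is an inhomogeneous Poisson process sampled per 1-s trial window by
Lewis–Shedler thinning. The peristimulus rate is baseline plus, for
responsive units on hand-stimulation trials:

- **Peak kernel** — piecewise linear: zero at the kernel onset, maximal
  (baseline + amplitude) at the kernel peak, back to baseline at
  onset + duration. The triangular shape was chosen so the
  threshold-crossing measurements map analytically onto the kernel anchors.
- **Suppression** — rate multiplied by `supp_frac` (mean 0.082 in S1,
  0.056 in M1) on 110–170 ms, in the `suppressed_prob` subset of responsive
  units.
- **Rebound** — Gaussian bump, σ = 40 ms, truncated to 190–400 ms, centered
  at the unit's rebound latency (mean 289 ms S1 / 275 ms M1), in the
  `rebound_prob` subset. σ is a modeling choice; only the window and the
  peak statistics are constrained by the emulation targets.
- **Protocols** — `hand_off` trials are pure baseline; paired-pulse trials
  add a second kernel scaled by the recovery map {150 ms: 0.5, 250 ms: 1.0,
  350 ms: 1.0}; cortical-laser trials drive PV units at a 100-Hz plateau for
  the 20-ms pulse (an arbitrary value chosen well above any baseline so
  tagging is unambiguous) and put all units through the suppression+rebound
  sequence scaled by laser intensity; hand+cortex trials multiply the hand
  response by per-population silencing factors (S1 PV 0.742, S1 non-PV
  0.588, M1 0.762). By convention the laser targets the S1 probe.
- **Distributions** — positive skewed quantities (baseline rate,
  amplitudes) are log-normal; latencies, durations and fractions are
  truncated normal. Spreads reuse the across-recording s.d. of the target
  statistics as between-unit variability; all variability is between units
  (no trial-to-trial latency jitter), a deliberate simplification.
- **Laminar structure** — peak and rebound amplitudes share a smooth depth
  weighting `0.4 + 0.6·exp(−(d−d₀)²/2·0.18²)`, d₀ = 0.45 (S1) / 0.25 (M1),
  normalized to preserve the mean amplitude; depths are uniform on [0, 1].
- **PV structure** — a unit is PV with probability 0.47. PV units respond
  5 ms earlier, with 2× amplitude, and are ~2.06× as likely to be
  responsive (with suppression/rebound incidence ratios 1.69/1.38). Group
  means are decomposed so the pooled means still equal the per-area targets;
  with these settings PV units carry ~75% of the evoked spikes.
- **Seeding** — a master seed spawns per-recording, per-unit, per-block
  streams (`numpy` `SeedSequence` spawn keys), so regeneration is
  bit-identical and adding units does not perturb existing ones.

### Kernel calibration to the measurement conventions

The emulation targets are *measured* quantities: the onset reported by the
pipeline is the center of the first 5-ms bin whose trial-averaged rate
exceeds 2.5 baseline s.d., which for a kernel that starts rising at time t
is systematically t + 3–4 ms (threshold crossing plus bin quantization). If
the preset means were used directly as kernel anchors, the recovered onset
would therefore miss the target by more than its own spread. Each unit's
drawn (onset, peak latency, duration) targets are instead mapped to kernel
anchors by a fixed-point calibration: the noise-free binned readout,
averaged over bin phases, is computed analytically for the candidate kernel
and the anchors shifted until the readout equals the targets (4 iterations;
the phase-averaged readout is shift-equivariant, so this converges).
Amplitude is *not* calibrated: the kernel maximum is exactly baseline +
drawn amplitude, and the measured amplitude carries the two opposing biases
discussed below. Kernels too weak to clear 1.2× the onset threshold are
left uncalibrated. Both the anchors and the targets are stored in the
manifest.

## Analysis conventions

- Bins are half-open and left-inclusive, anchored at stimulus onset; a
  spike exactly at the event time falls in the first post-stimulus bin.
  The suppression, rebound and silencing windows select bins by their left
  edge, making them effectively half-open (lo, hi].
- Baseline statistics are taken across the 50 baseline bins of the
  trial-averaged PSTH. **The s.d. is floored at the single-spike rate
  quantum 1/(N·Δ)** (8 Hz for 25 trials × 5 ms). Without the floor the
  empirical s.d. at a 1-Hz baseline is ~3 Hz, so any 2-spike coincidence
  (16 Hz) clears 2.5 s.d. and the max-over-100-bins detection rule flags
  75–90% of pure-Poisson units; with the floor, detection requires ≥3
  coincident spikes and the false-positive rate drops to ~5% (S1) / ~1%
  (M1) while sensitivity for real peaks stays ≳0.85. The floor only acts in
  the sparse regime — at rates where the empirical s.d. exceeds one quantum
  it is inert. The flat-baseline special case follows: a silent baseline
  with a strong evoked peak is responsive, a single stray spike is not.
- Responsiveness searches the full post-stimulus half (0–500 ms); peak
  metrics then restrict to 0–100 ms. Onset/duration thresholds use strict
  inequalities; latencies are reported at bin centers; maxima tie-break to
  the earliest bin. A responsive unit with no crossing inside the peak
  window is excluded from peak summaries but retained for
  suppression/rebound.
- Suppression and rebound use per-trial window rates paired with per-trial
  250-ms baseline rates, Wilcoxon signed rank, zeros dropped. The p-value
  uses the **exact sign-flip null** (dynamic programming over doubled
  midranks, up to 30 non-zero differences) because the tie-corrected normal
  approximation declares as few as four all-positive differences
  significant. All-zero differences leave the test undefined (not
  suppressed). The rebound averaging span (max bin ± 20 ms) is truncated at
  the 190–400 ms window edges. Suppression depth (% of baseline) is
  undefined when the unit's baseline rate is zero.
- Units flagged suppressed-only do not count as stimulus responsive;
  responsiveness is defined solely by the positive z-threshold.
- Two-level pooling everywhere: unit values → per-recording means →
  grand mean ± s.d.; recordings weigh equally regardless of unit count.
  Between-area differences are computed on recordings contributing both
  areas. Paired comparisons use the signed rank for n ≥ 6 recordings,
  paired t below that. Spearman p-values use t = ρ√((n−2)/(1−ρ²)) on n−2
  d.f. FDR control is Benjamini–Hochberg step-up at q = 0.05.
- Opto-tagging: PV iff (a) first significant elevation of 1-ms sub-bin
  counts (above the 97.5% Poisson tail of the baseline expectation) within
  5 ms of laser onset, (b) elevation in ≥50% of the 20 pulse sub-bins, and
  (c) laser-window rate above matched sham-window rate (signed rank,
  p < 0.05). All three criteria and the sub-bin width are configurable.
  Sham trials are encoded as laser trials with intensity 0.
- Propagation speeds are means of per-recording distance/latency ratios;
  recordings with non-positive M1−S1 latency differences are excluded from
  the corticocortical speed and logged. The hand→S1 distance (44.3 mm) is
  a morphometric constant.
- Silencing integrals are baseline-subtracted rate integrals over
  (15, 50] ms in Hz·s (evoked spikes per trial); baseline subtraction is a
  toggle. The hand-alone comparator is the 25-trial hand block; the
  cortex and hand+cortex conditions use 27 trials at 0.25 intensity.

## What the generator does and does not emulate

Passing recovery tests shows the pipeline correctly measures data whose
variability is Poisson spiking around piecewise-deterministic rates with
between-unit parameter spread. Real recordings additionally have
trial-to-trial latency jitter and gain fluctuations, bursting and
refractoriness, correlated noise across units, spike-sorting contamination,
and multi-unit pooling — none of which are modeled. Absolute firing-rate
calibration is out of scope (multi-unit pooling makes absolute rates
unreliable in the source workflow too); waveform-based cell typing, raw
voltage, LFP and behavior are not modeled.

## Known quantitative limitations (all measured, none hidden)

These are properties of the *measurement conventions at study scale*
(1.2/0.6-Hz baselines, 25 trials), not implementation defects; each is
asserted at its stated tolerance in the acceptance tests and left failing
where the target is unreachable:

1. **Responsive fraction** runs ~3 points above the true probability
   (false positives from 3-spike coincidences); still inside the binomial
   3-s.e. band.
2. **Suppression test calibration** — pairing a 60-ms window rate with a
   250-ms baseline rate gives the signed rank an asymmetric null (window
   rates move in 16.7-Hz quanta, baseline in 4-Hz quanta): ~11–13% of null
   units are flagged at α = 0.05. Its power on truly suppressed ~1-Hz units
   is ~60%; miscalibration and missed detections partially offset, so the
   recovered suppressed *fraction* lands near the target.
3. **Suppression depth is not identifiable per unit** at these rates: a
   92%-suppressed 1.2-Hz unit emits ~0.15 window spikes over the whole
   block, and flagging selects the all-zero-window cases, so the measured
   depth among flagged units is ~0–2% of baseline rather than ~8%.
4. **M1 duration and amplitude** are biased (short and high respectively):
   the 1-s.d. fall threshold is large relative to ~26-Hz peaks, and max-bin
   readouts of noisy PSTHs are upward biased with detection favoring
   larger-amplitude units.
5. **Paired-pulse ratios at 250 ms in M1** run ~0.1 high: the second-pulse
   window superimposes the first response's rebound bump.
6. The cohort-scale laminar peak–rebound profile correlation is weakly
   positive (~0.3), not the noise-free ~1: the rebound adds only ~3 Hz per
   depth bin against comparable bin noise at 13 recordings.

## Problem sizes

Defaults chosen for desk-scale validation: 13 recordings × 40 units per
area, 25 trials per protocol block (27 for the silencing conditions), full
protocol suite per recording. Generation takes ~1 s and the full pipeline a
few seconds on one core; the complete test suite, including the cohort
fixture, runs in well under a minute.
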