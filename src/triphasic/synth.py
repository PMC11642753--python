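"""Synthetic cohort generator for evoked-spiking experiments in S1 and M1.

Produces multi-recording datasets of spike trains whose underlying rate
structure follows the triphasic response pattern seen with brief
photostimulation of the hand: a short-latency peak, a post-peak suppression
(110-170 ms) and a late rebound (190-400 ms), with PV interneurons responding
earlier and more strongly than other units, depth-dependent amplitudes, and
the full set of stimulation protocols (hand on/off, paired pulses, cortical
laser with sham, and hand stimulation paired with partial cortical silencing).

Ground truth for every unit is retained in a :class:`CohortManifest` so that
the analysis pipeline can be validated by parameter recovery.

Spikes are sampled from an inhomogeneous Poisson process by thinning
(Lewis & Shedler). Each trial occupies a 1-s window tiled around its event,
so trains are reproducible per (config, seed) and trials are independent.

A note on latency parameters: preset distributions describe the *measured*
quantities (onset, peak latency, duration as read off a binned PSTH by
threshold crossing at the default analysis parameters). Because a
threshold-crossing readout of a kernel that starts rising at time t reports a
value a few milliseconds later than t, the generator calibrates each unit's
kernel anchors so that the noise-free measurement returns the drawn target.
Both the anchors and the targets are stored in the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .params import AnalysisParams

PROTOCOL_KINDS = ("hand", "hand_off", "paired_pulse", "cortex_laser", "hand_plus_cortex")
PAIRED_PULSE_LAGS_MS = (150.0, 250.0, 350.0)

# Stereotaxic probe targets (AP, ML) in mm.
S1_PROBE_TARGET = (0.0, 2.4)
M1_PROBE_TARGET = (0.25, 1.35)

_REBOUND_SIGMA_MS = 40.0
_PV_PLATEAU_HZ = 100.0


@dataclass(frozen=True)
class StimulusProtocol:
    """One block of identical stimulation trials.

    kind
        ``hand``: 5-ms photostimulus to the palm. ``hand_off``: identical
        timing with the hand off the light bar (pure baseline control).
        ``paired_pulse``: two hand pulses separated by ``lag_ms``.
        ``cortex_laser``: 20-ms laser pulse at the probe driving PV units
        (``intensity_frac == 0`` encodes the sham condition, laser off).
        ``hand_plus_cortex``: simultaneous hand pulse and low-intensity
        cortical laser (partial silencing).
    """

    kind: str
    n_trials: int = 25
    inter_trial_s: float = 1.0
    pulse_ms: float = 5.0
    lag_ms: float | None = None
    intensity_frac: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.inter_trial_s < 1.0:
            raise ValueError("inter-trial period must cover the 1-s response window")
        if (self.lag_ms is not None) != (self.kind == "paired_pulse"):
            raise ValueError("lag_ms must be present iff kind='paired_pulse'")
        if self.kind == "paired_pulse" and self.lag_ms not in PAIRED_PULSE_LAGS_MS:
            raise ValueError(f"paired-pulse lag must be one of {PAIRED_PULSE_LAGS_MS}")
        if not (0.0 <= self.intensity_frac <= 1.0):
            raise ValueError("intensity_frac must lie in [0, 1]")

    @property
    def hand_on(self) -> bool:
        return self.kind in ("hand", "paired_pulse", "hand_plus_cortex")


def default_protocol_suite() -> tuple[StimulusProtocol, ...]:
    """Protocol blocks simulated for every recording of the default cohort.

    Covers the hand response (25 trials), the hand-off control, opto-tagging
    (full-intensity laser plus an equal sham block), the three paired-pulse
    lags, and the partial-silencing pair (27 trials each, 0.25 intensity).
    The 25-trial hand block doubles as the hand-alone silencing comparator.
    """
    return (
        StimulusProtocol("hand"),
        StimulusProtocol("hand_off"),
        StimulusProtocol("cortex_laser", pulse_ms=20.0, intensity_frac=1.0),
        StimulusProtocol("cortex_laser", pulse_ms=20.0, intensity_frac=0.0),
        StimulusProtocol("paired_pulse", lag_ms=150.0),
        StimulusProtocol("paired_pulse", lag_ms=250.0),
        StimulusProtocol("paired_pulse", lag_ms=350.0),
        StimulusProtocol("cortex_laser", n_trials=27, pulse_ms=20.0, intensity_frac=0.25),
        StimulusProtocol("hand_plus_cortex", n_trials=27, intensity_frac=0.25),
    )


@dataclass
class UnitGroundTruth:
    """Generative parameters for one unit.

    ``onset_ms``/``peak_ms``/``dur_ms`` anchor the piecewise-linear peak
    kernel (rise starts at onset_ms, apex at peak_ms, back to baseline at
    onset_ms + dur_ms). ``target_*`` hold the intended *measured* values the
    kernel was calibrated to; for uncalibrated (weak or non-responsive) units
    they equal the anchors.
    """

    unit_id: str
    area: str
    is_pv: bool
    is_single: bool
    depth_frac: float
    baseline_hz: float
    responsive: bool
    onset_ms: float = np.nan
    peak_ms: float = np.nan
    dur_ms: float = np.nan
    peak_hz: float = 0.0
    suppressed: bool = False
    supp_frac: float = 1.0
    rebound: bool = False
    rebound_peak_ms: float = np.nan
    rebound_hz: float = 0.0
    target_onset_ms: float = np.nan
    target_peak_ms: float = np.nan
    target_dur_ms: float = np.nan

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth_frac <= 1.0:
            raise ValueError("depth_frac must lie in [0, 1]")
        if self.baseline_hz < 0 or self.peak_hz < 0 or self.rebound_hz < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.supp_frac <= 1.0:
            raise ValueError("supp_frac must lie in [0, 1]")
        if self.responsive and not (self.onset_ms < self.peak_ms < self.onset_ms + self.dur_ms):
            raise ValueError("require onset_ms < peak_ms < onset_ms + dur_ms")


@dataclass(frozen=True)
class AreaPreset:
    """Distribution parameters for the units of one cortical area.

    Means follow the published per-area response statistics; spreads are the
    corresponding across-recording s.d. reused as between-unit variability.
    Positive skewed quantities (baseline, amplitudes) are log-normal;
    latencies and fractions are truncated normal.
    """

    area: str
    baseline_mean_hz: float
    baseline_sd_hz: float
    responsive_prob: float
    onset_mean_ms: float
    onset_sd_ms: float
    peak_mean_ms: float
    dur_mean_ms: float
    dur_sd_ms: float
    amp_mean_hz: float
    amp_sd_hz: float
    suppressed_prob: float
    supp_frac_mean: float
    supp_frac_sd: float
    rebound_prob: float
    rebound_peak_mean_ms: float
    rebound_peak_sd_ms: float
    rebound_amp_mean_hz: float
    rebound_amp_sd_hz: float
    depth_peak_frac: float  # depth of maximal laminar amplitude weighting

    def __post_init__(self) -> None:
        for p in (self.responsive_prob, self.suppressed_prob, self.rebound_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


_PRESETS: dict[str, AreaPreset] = {
    "S1_default": AreaPreset(
        area="S1", baseline_mean_hz=1.2, baseline_sd_hz=0.7, responsive_prob=0.367,
        onset_mean_ms=14.7, onset_sd_ms=2.5, peak_mean_ms=21.4,
        dur_mean_ms=27.0, dur_sd_ms=4.0, amp_mean_hz=83.0, amp_sd_hz=43.1,
        suppressed_prob=0.223, supp_frac_mean=0.082, supp_frac_sd=0.063,
        rebound_prob=0.309, rebound_peak_mean_ms=289.0, rebound_peak_sd_ms=31.9,
        rebound_amp_mean_hz=31.4, rebound_amp_sd_hz=13.6, depth_peak_frac=0.45,
    ),
    "M1_default": AreaPreset(
        area="M1", baseline_mean_hz=0.6, baseline_sd_hz=0.2, responsive_prob=0.256,
        onset_mean_ms=24.3, onset_sd_ms=4.3, peak_mean_ms=31.2,
        dur_mean_ms=22.4, dur_sd_ms=3.2, amp_mean_hz=25.8, amp_sd_hz=8.9,
        suppressed_prob=0.084, supp_frac_mean=0.056, supp_frac_sd=0.075,
        rebound_prob=0.081, rebound_peak_mean_ms=274.7, rebound_peak_sd_ms=36.2,
        rebound_amp_mean_hz=20.2, rebound_amp_sd_hz=5.3, depth_peak_frac=0.25,
    ),
}


def make_preset(name: str) -> AreaPreset:
    """Return the fully populated per-area preset ``S1_default`` or ``M1_default``."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None


@dataclass(frozen=True)
class PVModifiers:
    """How opto-tagged PV units differ from non-PV units.

    PV units respond ~5 ms earlier with ~2x amplitude and are about twice as
    likely to be stimulus responsive; suppression/rebound incidence ratios
    follow the tagged-population comparisons. Group means are decomposed so
    that the pooled (PV + non-PV) means still equal the preset values.
    """

    onset_shift_ms: float = -5.0
    amplitude_mult: float = 2.0
    responsive_prob_mult: float = 2.06
    suppressed_prob_mult: float = 1.69
    rebound_prob_mult: float = 1.38


@dataclass(frozen=True)
class SilencingFactors:
    """Multiplier on the hand-evoked response under simultaneous PV activation."""

    s1_pv: float = 0.742
    s1_non_pv: float = 0.588
    m1: float = 0.762

    def factor(self, area: str, is_pv: bool) -> float:
        if area == "M1":
            return self.m1
        return self.s1_pv if is_pv else self.s1_non_pv


@dataclass(frozen=True)
class RecordingConfig:
    """One paired S1+M1 recording: presets, unit counts, and protocol suite."""

    recording_id: str
    s1: AreaPreset = field(default_factory=lambda: make_preset("S1_default"))
    m1: AreaPreset = field(default_factory=lambda: make_preset("M1_default"))
    n_units_per_area: int = 40
    pv_frac: float = 0.47
    single_frac: float = 0.30
    pv_modifiers: PVModifiers = field(default_factory=PVModifiers)
    silencing: SilencingFactors = field(default_factory=SilencingFactors)
    paired_pulse_recovery: dict = field(
        default_factory=lambda: {150.0: 0.5, 250.0: 1.0, 350.0: 1.0})
    s1_m1_distance_mean_mm: float = 0.92
    s1_m1_distance_sd_mm: float = 0.12
    protocols: tuple[StimulusProtocol, ...] = field(default_factory=default_protocol_suite)
    calibrate_kernels: bool = True

    def __post_init__(self) -> None:
        if self.n_units_per_area < 15:
            raise ValueError("n_units_per_area must be >= 15 (analysis inclusion rule)")
        if not 0.0 <= self.pv_frac <= 1.0:
            raise ValueError("pv_frac must lie in [0, 1]")

    def area_preset(self, area: str) -> AreaPreset:
        return self.s1 if area == "S1" else self.m1


def default_cohort_configs(n_recordings: int = 13) -> list[RecordingConfig]:
    """Configs for the default cohort: paired S1+M1 default presets."""
    return [RecordingConfig(recording_id=f"rec{i + 1:02d}") for i in range(n_recordings)]


# ---------------------------------------------------------------------------
# Rate profiles
# ---------------------------------------------------------------------------

def _tri_kernel(t_ms: np.ndarray, t0: float, tp: float, t1: float, amp: float) -> np.ndarray:
    """Piecewise-linear peak kernel: 0 at t0, amp at tp, 0 at t1 (ms domain)."""
    out = np.zeros_like(t_ms, dtype=float)
    rise = (t_ms >= t0) & (t_ms < tp)
    fall = (t_ms >= tp) & (t_ms < t1)
    out[rise] = amp * (t_ms[rise] - t0) / (tp - t0)
    out[fall] = amp * (t1 - t_ms[fall]) / (t1 - tp)
    return out


def _tri_area_hz_s(t0: float, t1: float, amp: float) -> float:
    return 0.5 * amp * (t1 - t0) / 1000.0


class RateProfile:
    """Peristimulus firing-rate function r(t) in Hz for one unit and protocol.

    Valid on the trial window [-0.5, +0.5) s around the stimulus event.
    Piecewise construction: constant baseline, triangular peak kernel(s),
    a multiplicative suppression step on the suppression window, a truncated
    Gaussian rebound bump, and (for cortical-laser protocols) a plateau drive
    of PV units during the light pulse.
    """

    def __init__(self, unit: UnitGroundTruth, protocol: StimulusProtocol,
                 recovery: dict | None = None,
                 silencing: SilencingFactors | None = None):
        self.unit = unit
        self.protocol = protocol
        self._kernels: list[tuple[float, float, float, float]] = []  # (t0,tp,t1,amp) ms
        self._supp: tuple[float, float, float] | None = None  # (lo_ms, hi_ms, rate_delta)
        self._rebound: tuple[float, float, float, float] | None = None  # (lo,hi,center,amp)
        self._plateau: tuple[float, float, float] | None = None  # (lo_ms, hi_ms, rate)
        base = unit.baseline_hz
        kind = protocol.kind

        evoked_scale = 0.0
        if kind in ("hand", "paired_pulse", "hand_plus_cortex") and unit.responsive:
            evoked_scale = 1.0
        if kind == "hand_plus_cortex":
            evoked_scale *= (silencing or SilencingFactors()).factor(unit.area, unit.is_pv)
        laser = kind in ("cortex_laser", "hand_plus_cortex") and protocol.intensity_frac > 0
        phase_scale = evoked_scale
        if kind == "cortex_laser":
            # PV activation alone drives the suppression/rebound sequence in
            # all units, scaled with the light intensity.
            phase_scale = protocol.intensity_frac

        if evoked_scale > 0:
            k = (unit.onset_ms, unit.peak_ms, unit.onset_ms + unit.dur_ms,
                 evoked_scale * unit.peak_hz)
            self._kernels.append(k)
            if kind == "paired_pulse":
                lag = float(protocol.lag_ms)
                scale = float((recovery or {}).get(lag, 1.0))
                self._kernels.append((k[0] + lag, k[1] + lag, k[2] + lag, k[3] * scale))
        if laser and unit.is_pv:
            self._plateau = (0.0, protocol.pulse_ms, _PV_PLATEAU_HZ * protocol.intensity_frac)
        if phase_scale > 0:
            if unit.suppressed:
                delta = phase_scale * (unit.supp_frac - 1.0) * base
                self._supp = (110.0, 170.0, delta)
            if unit.rebound:
                self._rebound = (190.0, 400.0, unit.rebound_peak_ms,
                                 phase_scale * unit.rebound_hz)

        if base + (self._supp[2] if self._supp else 0.0) < 0:
            raise ValueError("rate profile would be negative in the suppression window")

    # -- evaluation ---------------------------------------------------------
    def __call__(self, t_s: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t_s, dtype=float)) * 1000.0  # ms
        r = np.full(t.shape, self.unit.baseline_hz)
        for t0, tp, t1, amp in self._kernels:
            r += _tri_kernel(t, t0, tp, t1, amp)
        if self._plateau is not None:
            lo, hi, rate = self._plateau
            r[(t >= lo) & (t < hi)] += rate
        if self._supp is not None:
            lo, hi, delta = self._supp
            r[(t >= lo) & (t < hi)] += delta
        if self._rebound is not None:
            lo, hi, c, amp = self._rebound
            m = (t >= lo) & (t < hi)
            r[m] += amp * np.exp(-0.5 * ((t[m] - c) / _REBOUND_SIGMA_MS) ** 2)
        if np.any(r < 0):
            raise ValueError("negative firing rate; mis-specified configuration")
        return r if np.ndim(t_s) else float(r[0])

    @property
    def max_rate_hz(self) -> float:
        m = self.unit.baseline_hz
        peak = m + sum(a for *_, a in self._kernels)  # upper bound if kernels overlap
        if self._plateau is not None:
            peak = max(peak, m + self._plateau[2] + sum(a for *_, a in self._kernels))
        if self._rebound is not None:
            peak = max(peak, m + self._rebound[3] + sum(a for *_, a in self._kernels))
        return peak

    def integral_hz_s(self, a_s: float = -0.5, b_s: float = 0.5) -> float:
        """Closed-form integral of r over [a_s, b_s] in expected spikes."""
        from scipy.stats import norm

        a, b = a_s * 1000.0, b_s * 1000.0
        total = self.unit.baseline_hz * (b - a) / 1000.0

        def clip_lin(t0, tp, t1, amp):
            # integral of the triangle restricted to [a, b]
            tt = np.linspace(max(t0, a), min(t1, b), 2001)
            if tt[-1] <= tt[0]:
                return 0.0
            return float(np.trapezoid(_tri_kernel(tt, t0, tp, t1, amp), tt)) / 1000.0

        for t0, tp, t1, amp in self._kernels:
            if t1 - t0 <= b - a and t0 >= a and t1 <= b:
                total += _tri_area_hz_s(t0, t1, amp)
            else:
                total += clip_lin(t0, tp, t1, amp)
        if self._plateau is not None:
            lo, hi, rate = self._plateau
            total += rate * max(0.0, min(hi, b) - max(lo, a)) / 1000.0
        if self._supp is not None:
            lo, hi, delta = self._supp
            total += delta * max(0.0, min(hi, b) - max(lo, a)) / 1000.0
        if self._rebound is not None:
            lo, hi, c, amp = self._rebound
            lo, hi = max(lo, a), min(hi, b)
            if hi > lo:
                s = _REBOUND_SIGMA_MS
                total += amp * s * np.sqrt(2 * np.pi) * (
                    norm.cdf((hi - c) / s) - norm.cdf((lo - c) / s)) / 1000.0
        return total


def rate_profile(unit: UnitGroundTruth, protocol: StimulusProtocol,
                 recovery: dict | None = None,
                 silencing: SilencingFactors | None = None) -> RateProfile:
    """Build the peristimulus rate function for a unit under a protocol."""
    return RateProfile(unit, protocol, recovery=recovery, silencing=silencing)


# ---------------------------------------------------------------------------
# Kernel calibration: anchors -> measured values
# ---------------------------------------------------------------------------

def _measure_binned(t0: float, tp: float, t1: float, amp: float,
                    thr_on: float, thr_fall: float, bin_ms: float = 5.0,
                    n_phases: int = 10) -> tuple[float, float, float]:
    """Noise-free binned readout of a triangular kernel, averaged over bin phases.

    Returns (onset, peak latency, duration): onset = center of the first bin
    whose mean rate exceeds thr_on; peak = center of the max bin; duration =
    left edge of the first later bin below thr_fall minus the onset bin's
    left edge. NaN-free only when the kernel clears thr_on.
    """
    dt = 0.1
    grid = np.arange(0.0, 200.0, dt)
    kern = _tri_kernel(grid, t0, tp, t1, amp)
    per_bin = int(round(bin_ms / dt))
    ons, pks, durs = [], [], []
    for i in range(n_phases):
        phase = i * bin_ms / n_phases
        start = int(round(phase / dt))
        n_bins = (len(grid) - start) // per_bin
        avg = kern[start:start + n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
        lefts = phase + bin_ms * np.arange(n_bins)
        above = np.nonzero(avg > thr_on)[0]
        if len(above) == 0:
            continue
        b_on = above[0]
        ons.append(lefts[b_on] + bin_ms / 2.0)
        b_pk = int(np.argmax(avg))
        pks.append(lefts[b_pk] + bin_ms / 2.0)
        below = np.nonzero(avg[b_on + 1:] < thr_fall)[0]
        b_end = b_on + 1 + below[0] if len(below) else n_bins - 1
        durs.append(lefts[b_end] - lefts[b_on])
    if not ons:
        return (np.nan, np.nan, np.nan)
    return float(np.mean(ons)), float(np.mean(pks)), float(np.mean(durs))


def calibrate_kernel(target_onset: float, target_peak: float, target_dur: float,
                     amp: float, thr_on: float, thr_fall: float,
                     bin_ms: float = 5.0, n_iter: int = 4) -> tuple[float, float, float]:
    """Find kernel anchors (t0, tp, t1) whose binned readout matches the targets.

    Fixed-point iteration exploiting that the phase-averaged readout is
    shift-equivariant. If the kernel amplitude does not comfortably clear the
    onset threshold the targets are returned unchanged (no calibration).
    """
    if amp <= 1.2 * thr_on:
        return (target_onset, target_peak, target_onset + target_dur)
    t0, tp, t1 = target_onset, target_peak, target_onset + target_dur
    for _ in range(n_iter):
        m_on, m_pk, m_du = _measure_binned(t0, tp, t1, amp, thr_on, thr_fall, bin_ms)
        if np.isnan(m_on):
            break
        t0 += target_onset - m_on
        tp += target_peak - m_pk
        t1 += (target_onset + target_dur) - (m_on + m_du)
        t0 = max(t0, 0.5)
        tp = max(tp, t0 + 0.5)
        t1 = max(t1, tp + 0.5)
    return (t0, tp, t1)


# ---------------------------------------------------------------------------
# Spike sampling
# ---------------------------------------------------------------------------

def sample_spikes(rate: Callable[[np.ndarray], np.ndarray], protocol: StimulusProtocol,
                  seed, block_start_s: float = 0.0,
                  max_rate_hz: float | None = None) -> np.ndarray:
    """Sample spike times for one unit over one protocol block by thinning.

    ``rate`` maps peristimulus time (s, on [-0.5, 0.5)) to Hz; the same
    profile applies to every trial of the block. Events are spaced
    ``inter_trial_s`` apart starting 0.5 s into the block. Returns absolute
    spike times, sorted.
    """
    rng = np.random.default_rng(seed)
    if max_rate_hz is None:
        max_rate_hz = getattr(rate, "max_rate_hz", None)
        if max_rate_hz is None:
            tt = np.linspace(-0.5, 0.5, 4001)
            max_rate_hz = float(np.max(rate(tt))) * 1.05
    if not np.isfinite(max_rate_hz):
        raise ValueError("rate function must be bounded")
    if max_rate_hz <= 0:
        return np.empty(0)
    events = block_start_s + 0.5 + protocol.inter_trial_s * np.arange(protocol.n_trials)
    n_cand = rng.poisson(max_rate_hz, size=protocol.n_trials)  # per 1-s trial window
    total = int(n_cand.sum())
    t_rel = rng.uniform(-0.5, 0.5, size=total)
    u = rng.uniform(0.0, max_rate_hz, size=total)
    keep = u < rate(t_rel)
    t_abs = np.repeat(events, n_cand) + t_rel
    return np.sort(t_abs[keep])


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _draw_lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    if mean <= 0:
        raise ValueError("log-normal mean must be positive")
    if sd <= 0:
        return np.full(size, mean) if size is not None else mean
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _draw_truncnorm(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _laminar_weight(depth: float, peak_depth: float, width: float = 0.18) -> float:
    """Smooth amplitude weighting across normalized depth, maximal at peak_depth."""
    return 0.4 + 0.6 * np.exp(-0.5 * ((depth - peak_depth) / width) ** 2)


def _laminar_norm(peak_depth: float) -> float:
    d = np.linspace(0.0, 1.0, 501)
    return float(np.mean(_laminar_weight(d, peak_depth)))


def sample_unit(rng: np.random.Generator, preset: AreaPreset, cfg: RecordingConfig,
                unit_id: str, thr_on: float, thr_fall: float) -> UnitGroundTruth:
    """Draw one unit's ground truth from the preset distributions."""
    mods = cfg.pv_modifiers
    is_pv = bool(rng.random() < cfg.pv_frac)
    is_single = bool(rng.random() < cfg.single_frac)
    depth = float(rng.uniform(0.0, 1.0))
    baseline = float(_draw_lognormal(rng, preset.baseline_mean_hz, preset.baseline_sd_hz))

    # Decompose group probabilities/means so the pooled values match the preset.
    r_np = preset.responsive_prob / (cfg.pv_frac * mods.responsive_prob_mult
                                     + (1.0 - cfg.pv_frac))
    r_pv = min(1.0, mods.responsive_prob_mult * r_np)
    p_resp = r_pv if is_pv else r_np
    responsive = bool(rng.random() < p_resp)
    # PV weight among responsive units, used to recentre group means.
    w_pv = cfg.pv_frac * r_pv / max(preset.responsive_prob, 1e-12)

    if not responsive:
        return UnitGroundTruth(
            unit_id=unit_id, area=preset.area, is_pv=is_pv, is_single=is_single,
            depth_frac=depth, baseline_hz=baseline, responsive=False)

    shift = mods.onset_shift_ms
    onset_np = preset.onset_mean_ms - shift * w_pv
    onset_mean = onset_np + (shift if is_pv else 0.0)
    onset = _draw_truncnorm(rng, onset_mean, preset.onset_sd_ms, 2.0, 95.0)
    rise = preset.peak_mean_ms - preset.onset_mean_ms
    dur = _draw_truncnorm(rng, preset.dur_mean_ms, preset.dur_sd_ms, rise + 2.0, 98.0)

    amp_mult = mods.amplitude_mult
    amp_np = preset.amp_mean_hz / (1.0 + w_pv * (amp_mult - 1.0))
    amp_mean = amp_np * (amp_mult if is_pv else 1.0)
    lam = _laminar_weight(depth, preset.depth_peak_frac) / _laminar_norm(preset.depth_peak_frac)
    amp = float(_draw_lognormal(rng, amp_mean, preset.amp_sd_hz * amp_mean
                                / preset.amp_mean_hz)) * lam

    s_np = preset.suppressed_prob / (cfg.pv_frac * mods.suppressed_prob_mult
                                     + (1.0 - cfg.pv_frac))
    p_supp = min(1.0, (mods.suppressed_prob_mult if is_pv else 1.0) * s_np)
    suppressed = bool(rng.random() < p_supp)
    supp_frac = (_draw_truncnorm(rng, preset.supp_frac_mean, preset.supp_frac_sd, 0.0, 1.0)
                 if suppressed else 1.0)

    b_np = preset.rebound_prob / (cfg.pv_frac * mods.rebound_prob_mult
                                  + (1.0 - cfg.pv_frac))
    p_reb = min(1.0, (mods.rebound_prob_mult if is_pv else 1.0) * b_np)
    rebound = bool(rng.random() < p_reb)
    reb_peak = _draw_truncnorm(rng, preset.rebound_peak_mean_ms, preset.rebound_peak_sd_ms,
                               190.0, 400.0)
    reb_amp = float(_draw_lognormal(rng, preset.rebound_amp_mean_hz,
                                    preset.rebound_amp_sd_hz)) * lam if rebound else 0.0

    if cfg.calibrate_kernels:
        t0, tp, t1 = calibrate_kernel(onset, onset + rise, dur, amp, thr_on, thr_fall)
    else:
        t0, tp, t1 = onset, onset + rise, onset + dur

    return UnitGroundTruth(
        unit_id=unit_id, area=preset.area, is_pv=is_pv, is_single=is_single,
        depth_frac=depth, baseline_hz=baseline, responsive=True,
        onset_ms=t0, peak_ms=tp, dur_ms=t1 - t0, peak_hz=amp,
        suppressed=suppressed, supp_frac=supp_frac, rebound=rebound,
        rebound_peak_ms=reb_peak if rebound else np.nan, rebound_hz=reb_amp,
        target_onset_ms=onset, target_peak_ms=onset + rise, target_dur_ms=dur)


@dataclass
class CohortManifest:
    """Ground truth and layout of one generated cohort."""

    seed: int
    configs: list[RecordingConfig]
    units: dict[str, list[UnitGroundTruth]]  # recording_id -> units
    probe_coords: dict[str, dict[str, tuple[float, float]]]  # rec -> area -> (AP, ML)
    block_layout: dict[str, list[dict]]  # rec -> [{protocol fields, start_s}]

    def unit_table(self) -> pd.DataFrame:
        rows = []
        for rec, units in self.units.items():
            for u in units:
                d = asdict(u)
                d["recording_id"] = rec
                rows.append(d)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {str(k): clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                o = o.item()
            if isinstance(o, float) and not np.isfinite(o):
                return None
            return o

        payload = clean({
            "seed": self.seed,
            "configs": [asdict(c) for c in self.configs],
            "units": {r: [asdict(u) for u in us] for r, us in self.units.items()},
            "probe_coords": self.probe_coords,
            "block_layout": self.block_layout,
        })
        return json.dumps(payload, indent=1, sort_keys=True)


def simulate_cohort(configs: Sequence[RecordingConfig], seed: int,
                    params: AnalysisParams | None = None
                    ) -> tuple[CohortManifest, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of paired S1+M1 recordings.

    Returns ``(manifest, spikes, trials, units)`` where ``spikes`` has columns
    (recording_id, unit_id, spike_time_s), ``trials`` has (recording_id,
    event_time_s, protocol, lag_ms, hand_on, intensity_frac) and ``units`` has
    (recording_id, unit_id, area, depth_frac, is_single, is_pv_true).

    Randomness uses per-recording, per-unit seed streams spawned from the
    master seed, so regeneration is bit-identical and adding units to one
    recording does not perturb the others.
    """
    if len(configs) == 0:
        raise ValueError("need at least one recording config")
    params = params or AnalysisParams()
    thr_on = params.z_thresh * params.sd_floor_hz(25)
    thr_fall = params.fall_thresh_sd * params.sd_floor_hz(25)

    root = np.random.SeedSequence(seed)
    spike_rows: list[pd.DataFrame] = []
    trial_rows: list[dict] = []
    unit_rows: list[dict] = []
    manifest_units: dict[str, list[UnitGroundTruth]] = {}
    coords: dict[str, dict[str, tuple[float, float]]] = {}
    layout: dict[str, list[dict]] = {}

    for i_rec, cfg in enumerate(configs):
        rec_ss = np.random.SeedSequence(seed, spawn_key=(i_rec,))
        rec_rng = np.random.default_rng(rec_ss)
        rec = cfg.recording_id

        # Probe coordinates: S1 at target with jitter; M1 placed so the
        # inter-probe Euclidean distance follows the configured distribution.
        s1_xy = np.array(S1_PROBE_TARGET) + rec_rng.normal(0.0, 0.05, size=2)
        d = max(0.3, rec_rng.normal(cfg.s1_m1_distance_mean_mm, cfg.s1_m1_distance_sd_mm))
        direction = np.array(M1_PROBE_TARGET) - np.array(S1_PROBE_TARGET)
        direction = direction / np.linalg.norm(direction)
        m1_xy = s1_xy + d * direction
        coords[rec] = {"S1": tuple(np.round(s1_xy, 4)), "M1": tuple(np.round(m1_xy, 4))}

        # Protocol block layout: blocks laid out sequentially with 2-s gaps.
        t_cursor = 0.0
        blocks = []
        for proto in cfg.protocols:
            blocks.append((proto, t_cursor))
            t_cursor += 0.5 + proto.n_trials * proto.inter_trial_s + 2.0
        layout[rec] = [
            {**{k: (v if not isinstance(v, tuple) else list(v))
                for k, v in asdict(p).items()}, "start_s": start}
            for p, start in blocks
        ]
        for proto, start in blocks:
            events = start + 0.5 + proto.inter_trial_s * np.arange(proto.n_trials)
            for ev in events:
                trial_rows.append({
                    "recording_id": rec, "event_time_s": round(float(ev), 6),
                    "protocol": proto.kind,
                    "lag_ms": proto.lag_ms if proto.lag_ms is not None else np.nan,
                    "hand_on": int(proto.hand_on),
                    "intensity_frac": proto.intensity_frac,
                })

        units: list[UnitGroundTruth] = []
        for area in ("S1", "M1"):
            preset = cfg.area_preset(area)
            for j in range(cfg.n_units_per_area):
                unit_ss = np.random.SeedSequence(
                    seed, spawn_key=(i_rec, 0 if area == "S1" else 1, j))
                unit_rng = np.random.default_rng(unit_ss)
                uid = f"{rec}_{area}_{j:03d}"
                u = sample_unit(unit_rng, preset, cfg, uid, thr_on, thr_fall)
                units.append(u)
                unit_rows.append({
                    "recording_id": rec, "unit_id": uid, "area": area,
                    "depth_frac": round(u.depth_frac, 4),
                    "is_single": int(u.is_single), "is_pv_true": int(u.is_pv),
                })
                times = []
                for k_blk, (proto, start) in enumerate(blocks):
                    prof = rate_profile(u, proto, recovery=cfg.paired_pulse_recovery,
                                        silencing=cfg.silencing)
                    blk_seed = np.random.SeedSequence(
                        seed, spawn_key=(i_rec, 0 if area == "S1" else 1, j, 10 + k_blk))
                    times.append(sample_spikes(prof, proto, blk_seed, block_start_s=start,
                                               max_rate_hz=prof.max_rate_hz))
                t_all = np.sort(np.concatenate(times)) if times else np.empty(0)
                if len(t_all):
                    spike_rows.append(pd.DataFrame({
                        "recording_id": rec, "unit_id": uid,
                        "spike_time_s": np.round(t_all, 6)}))
        manifest_units[rec] = units

    spikes = (pd.concat(spike_rows, ignore_index=True) if spike_rows
              else pd.DataFrame(columns=["recording_id", "unit_id", "spike_time_s"]))
    trials = pd.DataFrame(trial_rows)
    units_df = pd.DataFrame(unit_rows)
    manifest = CohortManifest(seed=seed, configs=list(configs), units=manifest_units,
                              probe_coords=coords, block_layout=layout)
    return manifest, spikes, trials, units_df


def write_cohort(outdir, manifest: CohortManifest, spikes: pd.DataFrame,
                 trials: pd.DataFrame, units: pd.DataFrame) -> dict:
    """Write spikes.csv / units.csv / trials.csv / manifest.json to ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "spikes": out / "spikes.csv",
        "units": out / "units.csv",
        "trials": out / "trials.csv",
        "manifest": out / "manifest.json",
    }
    spikes.to_csv(paths["spikes"], index=False)
    units.to_csv(paths["units"], index=False)
    trials.to_csv(paths["trials"], index=False)
    paths["manifest"].write_text(manifest.to_json())
    return {k: str(v) for k, v in paths.items()}
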