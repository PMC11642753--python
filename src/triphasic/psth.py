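"""Peristimulus time histograms: binning, averaging, z-scoring, responsiveness.

The analysis object is the per-unit trial-averaged PSTH: spikes are binned in
5-ms bins aligned to stimulus onset over a window spanning 0.5 s before to
0.5 s after the stimulus, averaged across trials (generally 25), and z-scored
against the 250-ms pre-stimulus baseline. A unit is stimulus responsive when
its z-scored rate exceeds 2.5 baseline s.d. anywhere post-stimulus.

Bin convention: half-open, left-inclusive, anchored at stimulus onset; a
spike exactly at the event time falls in the first post-stimulus bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import AnalysisParams

__all__ = ["UnitPSTH", "bin_spikes", "average_psth", "detect_responsive",
           "filter_recordings", "grand_average", "build_unit_psths"]


@dataclass
class UnitPSTH:
    """Trial-aligned binned activity of one unit.

    ``rate_hz`` is the trial-mean rate per bin, ``rate_sd`` the across-trial
    s.d. per bin. ``baseline_mean_hz``/``baseline_sd_hz`` are computed across
    the baseline bins of the trial-averaged rate vector; ``baseline_sd_eff_hz``
    is the s.d. actually used for z-scoring (floored at the single-spike rate
    quantum, see :class:`AnalysisParams`). ``z`` and ``responsive`` are filled
    by :func:`detect_responsive`.
    """

    unit_id: str
    counts: np.ndarray  # trials x bins
    params: AnalysisParams
    rate_hz: np.ndarray = field(init=False)
    rate_sd: np.ndarray = field(init=False)
    baseline_mean_hz: float = field(init=False)
    baseline_sd_hz: float = field(init=False)
    baseline_sd_eff_hz: float = field(init=False)
    z: np.ndarray | None = None
    responsive: bool | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] < 1 or c.shape[1] != self.params.n_bins:
            raise ValueError("counts must be a (trials x n_bins) matrix")
        self.counts = c
        self.rate_hz = c.mean(axis=0) / self.params.bin_s
        self.rate_sd = c.std(axis=0, ddof=0) / self.params.bin_s
        base = self.rate_hz[self.params.baseline_slice()]
        self.baseline_mean_hz = float(base.mean())
        self.baseline_sd_hz = float(base.std(ddof=1)) if len(base) > 1 else 0.0
        self.baseline_sd_eff_hz = max(self.baseline_sd_hz,
                                      self.params.sd_floor_hz(self.n_trials))

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    def baseline_subtracted(self) -> np.ndarray:
        return self.rate_hz - self.baseline_mean_hz

    def trial_rates(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        """Per-trial mean firing rate (Hz) over the window [lo_ms, hi_ms) ."""
        edges = self.params.bin_edges_ms
        sel = (edges[:-1] >= lo_ms) & (edges[:-1] < hi_ms)
        if not sel.any():
            raise ValueError("window does not cover any bin")
        dur_s = sel.sum() * self.params.bin_s
        return self.counts[:, sel].sum(axis=1) / dur_s


def bin_spikes(spike_times: np.ndarray, event_times: np.ndarray,
               params: AnalysisParams | None = None) -> np.ndarray:
    """Bin one unit's spike times around stimulus events.

    Returns a (n_events x n_bins) count matrix. Bin b covers
    ``[w0 + b*bin, w0 + (b+1)*bin)`` ms relative to the event (half-open,
    left-inclusive). Raises if consecutive events are closer than the
    analysis window, which would assign spikes ambiguously.
    """
    params = params or AnalysisParams()
    events = np.asarray(event_times, dtype=float)
    if len(events) == 0:
        raise ValueError("need at least one event")
    if np.any(np.diff(events) < 0):
        raise ValueError("events must be sorted")
    w0, w1 = params.window_s
    if np.any(np.diff(events) < (w1 - w0) - 1e-9):
        raise ValueError("analysis windows of consecutive events overlap")
    times = np.asarray(spike_times, dtype=float)
    counts = np.zeros((len(events), params.n_bins))
    if len(times) == 0:
        return counts
    idx = np.searchsorted(events + w0, times, side="right") - 1
    valid = idx >= 0
    rel = np.where(valid, times - events[np.clip(idx, 0, None)], np.nan)
    valid &= (rel >= w0) & (rel < w1)
    # epsilon guards against ties at bin edges landing one bin low after
    # inexact division (tolerance ~1e-9 of a bin width)
    b = np.floor((rel[valid] - w0) / params.bin_s + 1e-9).astype(int)
    np.add.at(counts, (idx[valid], np.clip(b, 0, params.n_bins - 1)), 1.0)
    return counts


def average_psth(counts: np.ndarray, params: AnalysisParams | None = None,
                 unit_id: str = "") -> UnitPSTH:
    """Construct the trial-averaged PSTH with baseline statistics."""
    return UnitPSTH(unit_id=unit_id, counts=np.asarray(counts, dtype=float),
                    params=params or AnalysisParams())


def detect_responsive(psth: UnitPSTH, params: AnalysisParams | None = None
                      ) -> tuple[bool, np.ndarray]:
    """Classify a unit as stimulus responsive and fill its z-scored PSTH.

    z = (rate - baseline mean) / baseline s.d. per bin; responsive when the
    maximum z over the post-stimulus bins exceeds ``z_thresh``. With the s.d.
    floor disabled and a perfectly flat baseline, any post-stimulus spiking
    counts as responsive (z marked infinite above baseline).
    """
    params = params or psth.params
    bm = psth.baseline_mean_hz
    bs = max(psth.baseline_sd_hz, params.sd_floor_hz(psth.n_trials)) \
        if params.sd_floor_spikes > 0 else psth.baseline_sd_hz
    post = params.post_slice()
    if bs > 0:
        z = (psth.rate_hz - bm) / bs
        responsive = bool(np.max(z[post]) > params.z_thresh)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(psth.rate_hz > bm, np.inf,
                         np.where(psth.rate_hz < bm, -np.inf, 0.0))
        responsive = bool(np.any(psth.rate_hz[post] > 0))
    psth.z = z
    psth.responsive = responsive
    return responsive, z


def filter_recordings(units: pd.DataFrame, params: AnalysisParams | None = None
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Apply the minimum-active-unit inclusion rule per probe.

    ``units`` must carry (recording_id, area, unit_id). Probes (one per
    recording x area) with fewer than ``min_active_units`` units are dropped.
    Returns the retained unit rows and a log of exclusions.
    """
    params = params or AnalysisParams()
    log: list[str] = []
    if len(units) == 0:
        return units, log
    keep = []
    for (rec, area), grp in units.groupby(["recording_id", "area"], sort=True):
        if len(grp) >= params.min_active_units:
            keep.append(grp)
        else:
            log.append(f"excluded probe {rec}/{area}: {len(grp)} active units "
                       f"< {params.min_active_units}")
    kept = pd.concat(keep, ignore_index=True) if keep else units.iloc[0:0]
    return kept, log


def grand_average(psths_by_recording: dict[str, list[np.ndarray]]
                  ) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Two-level pooling: units -> recording mean, recordings -> grand mean.

    Input maps recording id to a list of per-unit rate vectors (any common
    length). Returns (per-recording means, grand mean, across-recording s.d.).
    The grand mean weights recordings equally regardless of unit count.
    """
    if not psths_by_recording:
        raise ValueError("need at least one recording")
    rec_means = {rec: np.mean(np.vstack(vs), axis=0)
                 for rec, vs in psths_by_recording.items() if len(vs) > 0}
    if not rec_means:
        raise ValueError("no units in any recording")
    stack = np.vstack(list(rec_means.values()))
    grand = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(grand)
    return rec_means, grand, sd


def build_unit_psths(spikes: pd.DataFrame, events: np.ndarray, unit_ids,
                     params: AnalysisParams | None = None) -> dict[str, UnitPSTH]:
    """Bin, average and z-score every unit of one recording for one event set.

    ``unit_ids`` lists the units to build (units with no spikes get all-zero
    count matrices). ``spikes`` needs columns (unit_id, spike_time_s).
    """
    params = params or AnalysisParams()
    by_unit = {uid: grp["spike_time_s"].to_numpy()
               for uid, grp in spikes.groupby("unit_id", sort=False)}
    out: dict[str, UnitPSTH] = {}
    for uid in unit_ids:
        counts = bin_spikes(by_unit.get(uid, np.empty(0)), events, params)
        p = average_psth(counts, params, unit_id=uid)
        detect_responsive(p, params)
        out[uid] = p
    return out
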