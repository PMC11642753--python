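"""Laminar profiles: depth-binned PSTHs and evoked-amplitude-by-depth curves.

Units are sorted into 20 bins of 5% normalized cortical depth (0 = pia,
1 = white-matter boundary; last bin closed above). Per depth bin, unit PSTHs
are averaged within each recording and then across recordings, and the
evoked amplitude is read out in a window centered on the area's
grand-average peak latency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import AnalysisParams
from .metrics import spearman_with_t

__all__ = ["LaminarProfile", "depth_bin_index", "bin_by_depth",
           "laminar_amplitude", "profile_correlation"]


@dataclass
class LaminarProfile:
    """Evoked amplitude by normalized depth bin.

    ``amplitude_hz``/``sem_hz`` are NaN for bins without units in any
    recording (empty bins are flagged, not zero-filled).
    """

    bin_edges: np.ndarray  # length n_bins + 1
    amplitude_hz: np.ndarray
    sem_hz: np.ndarray
    unit_counts: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "depth_bin_lo": self.bin_edges[:-1], "depth_bin_hi": self.bin_edges[1:],
            "amplitude_hz": self.amplitude_hz, "sem_hz": self.sem_hz,
            "n_units": self.unit_counts,
        })


def depth_bin_index(depth_frac: float | np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Depth bin k covers [k/n, (k+1)/n), with the last bin closed at 1.0."""
    d = np.asarray(depth_frac, dtype=float)
    if np.any((d < 0.0) | (d > 1.0)):
        raise ValueError("depth_frac must lie in [0, 1]")
    return np.minimum((d * n_bins).astype(int), n_bins - 1)


def bin_by_depth(units: pd.DataFrame, rates: dict[str, np.ndarray],
                 params: AnalysisParams | None = None
                 ) -> dict[int, dict[str, np.ndarray]]:
    """Average unit rate vectors into depth bins, per recording.

    ``units`` needs (recording_id, unit_id, depth_frac); ``rates`` maps
    unit_id to a rate vector. Returns {depth_bin: {recording_id: mean rate}}.
    """
    params = params or AnalysisParams()
    n_bins = params.laminar_n_bins
    out: dict[int, dict[str, list[np.ndarray]]] = {}
    for row in units.itertuples(index=False):
        if row.unit_id not in rates:
            continue
        k = int(depth_bin_index(row.depth_frac, n_bins))
        out.setdefault(k, {}).setdefault(row.recording_id, []).append(rates[row.unit_id])
    return {k: {rec: np.mean(np.vstack(vs), axis=0) for rec, vs in per_rec.items()}
            for k, per_rec in out.items()}


def laminar_amplitude(units: pd.DataFrame, psths: dict[str, "UnitPSTH"],
                      params: AnalysisParams | None = None,
                      peak_ms: float | None = None) -> LaminarProfile:
    """Grand-average evoked amplitude per depth bin (mean ± s.e.m. across recordings).

    Amplitude is the mean baseline-subtracted rate in a window of
    ±``laminar_peak_halfwidth_ms`` around the grand-average peak latency
    (computed from the pooled units when ``peak_ms`` is not given).
    """
    params = params or AnalysisParams()
    sub_rates = {uid: p.baseline_subtracted() for uid, p in psths.items()}
    centers = params.bin_centers_ms
    if peak_ms is None:
        pooled = np.mean(np.vstack(list(sub_rates.values())), axis=0)
        lo, hi = params.peak_search_ms
        win = (centers >= lo) & (centers < hi)
        peak_ms = float(centers[win][np.argmax(pooled[win])])
    half = params.laminar_peak_halfwidth_ms
    sel = (centers >= peak_ms - half) & (centers <= peak_ms + half)

    binned = bin_by_depth(units, sub_rates, params)
    n_bins = params.laminar_n_bins
    amp = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for k in range(n_bins):
        per_rec = binned.get(k)
        if not per_rec:
            continue
        vals = np.array([v[sel].mean() for v in per_rec.values()])
        amp[k] = vals.mean()
        sem[k] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        counts[k] = sum((units["unit_id"].isin(psths)
                         & (depth_bin_index(units["depth_frac"], n_bins) == k)).tolist())
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return LaminarProfile(bin_edges=edges, amplitude_hz=amp, sem_hz=sem,
                          unit_counts=counts)


def profile_correlation(profile_a: LaminarProfile, profile_b: LaminarProfile
                        ) -> tuple[float, float]:
    """Spearman correlation between two laminar profiles over shared non-empty bins."""
    if len(profile_a.amplitude_hz) != len(profile_b.amplitude_hz):
        raise ValueError("profiles must share their depth binning")
    ok = np.isfinite(profile_a.amplitude_hz) & np.isfinite(profile_b.amplitude_hz)
    if ok.sum() < 4:
        raise ValueError("need at least 4 shared non-empty depth bins")
    return spearman_with_t(profile_a.amplitude_hz[ok], profile_b.amplitude_hz[ok])
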