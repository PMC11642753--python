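"""Protocol-level analyses: propagation speeds, paired-pulse recovery,
and partial-silencing effects.

Propagation speeds divide pathway distances by response latencies: the
hand-to-S1 distance is a morphometric constant (44.3 mm), the S1-to-M1
distance is the per-recording Euclidean distance between the probes, and
cohort speeds are means of per-recording speeds (mean of ratios, not ratio
of means). Paired-pulse recovery compares the second-pulse peak amplitude to
the first across lags (Friedman + Dunn-Sidak post hoc). Silencing effects
integrate the evoked firing rate 15-50 ms post-stimulus per condition and
report the (hand + cortex) / hand ratio per population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .params import AnalysisParams
from .psth import UnitPSTH
from .metrics import adjust_bh, paired_wilcoxon

__all__ = ["PathwayGeometry", "propagation_speeds", "paired_pulse_analysis",
           "dunn_sidak_vs_control", "evoked_integral", "silencing_effect"]

HAND_TO_S1_MM = 44.3
HAND_TO_S1_SD_MM = 1.1


@dataclass(frozen=True)
class PathwayGeometry:
    """Pathway distances used for propagation-speed estimates (mm)."""

    hand_to_s1_mm: float = HAND_TO_S1_MM
    hand_to_s1_sd_mm: float = HAND_TO_S1_SD_MM
    probe_coords: dict = field(default_factory=dict)  # rec -> {"S1": (AP, ML), "M1": ...}

    def s1_to_m1_mm(self, recording_id: str) -> float:
        c = self.probe_coords[recording_id]
        d = float(np.linalg.norm(np.asarray(c["M1"]) - np.asarray(c["S1"])))
        if d <= 0:
            raise ValueError(f"non-positive probe distance for {recording_id}")
        return d


def propagation_speeds(geometry: PathwayGeometry, latencies: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-recording and cohort propagation speeds in m/s.

    ``latencies`` has one row per recording with columns s1_onset_ms,
    m1_onset_ms, s1_peak_ms, m1_peak_ms (per-recording means over responsive
    units). mm/ms equals m/s, so speeds are distance_mm / latency_ms.
    Recordings whose M1 latency does not exceed S1 are excluded from the
    S1->M1 speed and logged.
    """
    log: list[str] = []
    rows = []
    for row in latencies.itertuples(index=False):
        rec = row.recording_id
        entry = {"recording_id": rec}
        for kind in ("onset", "peak"):
            s1_lat = getattr(row, f"s1_{kind}_ms")
            m1_lat = getattr(row, f"m1_{kind}_ms")
            entry[f"hand_s1_{kind}_mps"] = (geometry.hand_to_s1_mm / s1_lat
                                            if s1_lat and s1_lat > 0 else np.nan)
            lag = m1_lat - s1_lat if np.isfinite(m1_lat) and np.isfinite(s1_lat) else np.nan
            if np.isfinite(lag) and lag > 0 and rec in geometry.probe_coords:
                entry[f"s1_m1_{kind}_mps"] = geometry.s1_to_m1_mm(rec) / lag
            else:
                entry[f"s1_m1_{kind}_mps"] = np.nan
                if np.isfinite(lag) and lag <= 0:
                    log.append(f"excluded {rec} from S1->M1 {kind} speed: "
                               f"non-positive latency difference ({lag:.1f} ms)")
        rows.append(entry)
    per_rec = pd.DataFrame(rows)
    summary = []
    for col in ("hand_s1_onset_mps", "hand_s1_peak_mps",
                "s1_m1_onset_mps", "s1_m1_peak_mps"):
        v = per_rec[col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        summary.append({"speed": col, "mean_mps": v.mean() if len(v) else np.nan,
                        "sd_mps": v.std(ddof=1) if len(v) > 1 else np.nan,
                        "n": len(v)})
    return per_rec, pd.DataFrame(summary), log


# ---------------------------------------------------------------------------
# Paired pulse
# ---------------------------------------------------------------------------

def _window_peak_amp(rate_hz: np.ndarray, baseline_mean: float,
                     params: AnalysisParams, lo_ms: float, hi_ms: float) -> float:
    edges = params.bin_edges_ms
    sel = (edges[:-1] >= lo_ms) & (edges[:-1] < hi_ms)
    if not sel.any():
        raise ValueError("peak window covers no bins")
    return float(np.max(rate_hz[sel] - baseline_mean))


def dunn_sidak_vs_control(data: np.ndarray) -> pd.DataFrame:
    """Dunn's multiple-comparison test vs the first (control) column,
    with Sidak adjustment.

    ``data`` is (n subjects x k conditions); within-subject ranks feed the
    standard normal statistic z = (Rbar_i - Rbar_0) / sqrt(k(k+1)/(6n)).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    m = k - 1
    rows = []
    for i in range(1, k):
        z = (mean_ranks[i] - mean_ranks[0]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"condition": i, "z": z, "p_raw": p,
                     "p_sidak": 1.0 - (1.0 - min(p, 1.0)) ** m})
    return pd.DataFrame(rows)


def paired_pulse_analysis(psths_by_lag: dict[str, dict[float, "RecordingPSTH"]],
                          params: AnalysisParams | None = None) -> dict:
    """Second/first pulse amplitude ratios across paired-pulse lags.

    ``psths_by_lag`` maps recording_id -> {lag_ms: object with ``rate_hz``
    and ``baseline_mean_hz``} (typically the recording-average PSTH over
    responsive units). Peak amplitudes are read in 100-ms windows anchored
    at each pulse. Returns per-recording ratios, the Friedman test across
    conditions (first pulse + each lag) and the Dunn-Sidak post hoc vs the
    first pulse.
    """
    params = params or AnalysisParams()
    lags = sorted({lag for per in psths_by_lag.values() for lag in per})
    rows = []
    for rec, per_lag in sorted(psths_by_lag.items()):
        if set(per_lag) != set(lags):
            continue  # missing lag condition: excluded from the paired design
        entry = {"recording_id": rec}
        first_amps = []
        for lag in lags:
            p = per_lag[lag]
            a1 = _window_peak_amp(p.rate_hz, p.baseline_mean_hz, params,
                                  *params.peak_search_ms)
            a2 = _window_peak_amp(p.rate_hz, p.baseline_mean_hz, params,
                                  lag, lag + (params.peak_search_ms[1]
                                              - params.peak_search_ms[0]))
            first_amps.append(a1)
            entry[f"amp2_{int(lag)}"] = a2
            entry[f"ratio_{int(lag)}"] = a2 / a1 if a1 > 0 else np.nan
        entry["amp1"] = float(np.mean(first_amps))
        rows.append(entry)
    per_rec = pd.DataFrame(rows)
    result = {"per_recording": per_rec, "lags_ms": lags,
              "friedman_chi2": np.nan, "friedman_p": np.nan, "posthoc": None}
    if len(per_rec) >= 4 and lags:
        cols = ["amp1"] + [f"amp2_{int(l)}" for l in lags]
        mat = per_rec[cols].to_numpy(dtype=float)
        if np.all(np.isfinite(mat)):
            with np.errstate(invalid="ignore"):
                chi2, p = stats.friedmanchisquare(
                    *[mat[:, j] for j in range(mat.shape[1])])
            result["friedman_chi2"] = float(chi2)
            result["friedman_p"] = float(p)
            result["posthoc"] = dunn_sidak_vs_control(mat)
    return result


# ---------------------------------------------------------------------------
# Silencing
# ---------------------------------------------------------------------------

def evoked_integral(psth: UnitPSTH, params: AnalysisParams | None = None,
                    lo_ms: float = 15.0, hi_ms: float = 50.0,
                    subtract_baseline: bool = True) -> float:
    """Integral of (baseline-subtracted) firing rate over (lo, hi] ms.

    Returned in Hz*s, i.e. expected evoked spikes per trial in the window.
    """
    params = params or psth.params
    edges = psth.params.bin_edges_ms
    sel = (edges[:-1] >= lo_ms) & (edges[:-1] < hi_ms)
    r = psth.rate_hz[sel]
    if subtract_baseline:
        r = r - psth.baseline_mean_hz
    return float(r.sum() * params.bin_s)


def silencing_effect(integrals: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Population silencing summary from per-unit condition integrals.

    ``integrals`` holds one row per hand-responsive unit with columns
    recording_id, population (e.g. "S1_all", "S1_PV", "S1_nonPV", "M1_all";
    a unit may appear under several populations), int_hand, int_cortex,
    int_hand_cortex. Per recording x population: mean integrals, the
    (hand+cortex)/hand ratio in percent (flagged undefined when the hand
    integral is not positive), a within-recording signed-rank test across
    units (hand vs hand+cortex), and BH-adjusted significance across all
    recording x population cells.
    """
    rows = []
    for (rec, pop), grp in integrals.groupby(["recording_id", "population"], sort=True):
        hand = grp["int_hand"].to_numpy(dtype=float)
        combo = grp["int_hand_cortex"].to_numpy(dtype=float)
        cortex = grp["int_cortex"].to_numpy(dtype=float)
        mean_hand = float(hand.mean())
        mean_combo = float(combo.mean())
        ratio = 100.0 * mean_combo / mean_hand if mean_hand > 0 else np.nan
        p = paired_wilcoxon(hand, combo) if len(grp) >= 2 else np.nan
        rows.append({
            "recording_id": rec, "population": pop, "n_units": len(grp),
            "int_hand": mean_hand, "int_cortex": float(cortex.mean()),
            "int_hand_cortex": mean_combo, "ratio_pct": ratio, "p_value": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        reject, adj = adjust_bh(out["p_value"].to_numpy(), q=q)
        out["p_bh"] = adj
        out["significant_bh"] = reject
    return out
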