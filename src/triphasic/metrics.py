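"""Per-unit triphasic response metrics and population summaries.

For each stimulus-responsive unit the initial peak is parameterized on the
baseline-subtracted trial-averaged PSTH (onset = first bin above the
2.5-s.d. threshold, peak = maximal bin within 100 ms, duration = time until
the rate first falls below 1 s.d. above baseline). Post-peak suppression
(110-170 ms) and rebound (190-400 ms) are tested per unit with paired
Wilcoxon signed-rank tests of per-trial window rates against per-trial
baseline rates. Population summaries pool unit values to per-recording means
and then to grand averages across recordings, with paired between-area
comparisons, Spearman correlations (t-tested), and Benjamini-Hochberg FDR
control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .params import AnalysisParams
from .psth import UnitPSTH

__all__ = ["PeakMetrics", "SuppressionResult", "ReboundResult", "peak_metrics",
           "suppression_test", "rebound_test", "summarize",
           "correlate_properties", "adjust_bh", "paired_wilcoxon"]


@dataclass(frozen=True)
class PeakMetrics:
    onset_ms: float
    peak_ms: float
    peak_amp_hz: float  # baseline-subtracted
    duration_ms: float

    def __post_init__(self) -> None:
        if not (self.onset_ms <= self.peak_ms and self.duration_ms > 0
                and self.peak_amp_hz > 0):
            raise ValueError("inconsistent peak metrics")


@dataclass(frozen=True)
class SuppressionResult:
    is_suppressed: bool
    supp_rate_hz: float
    supp_pct_baseline: float  # NaN when the baseline rate is 0
    p_value: float


@dataclass(frozen=True)
class ReboundResult:
    has_rebound: bool
    rebound_amp_hz: float
    rebound_latency_ms: float
    p_value: float


def _effective_sd(psth: UnitPSTH, params: AnalysisParams) -> float:
    if params.sd_floor_spikes > 0:
        return max(psth.baseline_sd_hz, params.sd_floor_hz(psth.n_trials))
    return psth.baseline_sd_hz


def peak_metrics(psth: UnitPSTH, params: AnalysisParams | None = None
                 ) -> PeakMetrics | None:
    """Extract onset/peak/duration of the initial response.

    Works on the baseline-subtracted average PSTH within the peak-search
    window. Returns None when no bin strictly exceeds the onset threshold
    there (the unit is kept for suppression/rebound analyses but excluded
    from peak summaries). Ties in the maximum break toward the earliest bin;
    latencies are reported at bin centers.
    """
    params = params or psth.params
    bs = _effective_sd(psth, params)
    sub = psth.baseline_subtracted()
    edges = psth.params.bin_edges_ms
    lo, hi = params.peak_search_ms
    win = np.nonzero((edges[:-1] >= lo) & (edges[:-1] < hi))[0]
    thr_on = params.z_thresh * bs
    above = win[sub[win] > thr_on]
    if len(above) == 0 or bs == 0:
        return None
    b_on = int(above[0])
    b_pk = int(win[np.argmax(sub[win])])  # argmax returns first max: earliest
    amp = float(sub[b_pk])
    thr_fall = params.fall_thresh_sd * bs
    later = np.arange(b_on + 1, psth.params.n_bins)
    below = later[sub[later] < thr_fall]
    b_end = int(below[0]) if len(below) else psth.params.n_bins - 1
    duration = float(edges[b_end] - edges[b_on])
    return PeakMetrics(
        onset_ms=float(edges[b_on] + params.bin_ms / 2.0),
        peak_ms=float(edges[b_pk] + params.bin_ms / 2.0),
        peak_amp_hz=amp,
        duration_ms=duration,
    )


def _exact_signed_rank_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p over all sign flips (midranks for ties).

    The full null distribution of W+ is built by dynamic programming over
    doubled midranks (integers), so tied |differences| are handled exactly
    instead of by the anticonservative tie-corrected normal approximation.
    """
    ranks = stats.rankdata(np.abs(d))
    r2 = np.round(2.0 * ranks).astype(int)
    w_plus = int(np.round(r2[d > 0].sum()))
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    cdf = float(dist[:w_plus + 1].sum())
    sf = float(dist[w_plus:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples, zeros dropped.

    Exact null distribution for up to 30 non-zero differences (see
    :func:`_exact_signed_rank_p`); the normal approximation beyond that.
    Returns NaN when every paired difference is zero (test undefined).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return float("nan")
    if len(d) <= 30:
        return _exact_signed_rank_p(d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return float(stats.wilcoxon(d, zero_method="wilcox",
                                        alternative="two-sided").pvalue)
        except ValueError:
            return float("nan")


def suppression_test(psth: UnitPSTH, params: AnalysisParams | None = None
                     ) -> SuppressionResult:
    """Test post-peak suppression against the pre-stimulus baseline.

    Per-trial mean rates in the suppression window are paired with per-trial
    baseline rates (Wilcoxon signed rank). Suppressed requires p < alpha and
    a window mean below the baseline mean.
    """
    params = params or psth.params
    if psth.n_trials < params.min_trials_test:
        raise ValueError(f"need >= {params.min_trials_test} trials for the signed-rank test")
    lo, hi = params.supp_window_ms
    win = psth.trial_rates(lo, hi)
    base = psth.trial_rates(params.baseline_s[0] * 1000.0, params.baseline_s[1] * 1000.0)
    p = paired_wilcoxon(win, base)
    supp_rate = float(win.mean())
    base_rate = float(base.mean())
    is_supp = bool(np.isfinite(p) and p < params.alpha and supp_rate < base_rate)
    pct = 100.0 * supp_rate / base_rate if base_rate > 0 else float("nan")
    return SuppressionResult(is_suppressed=is_supp, supp_rate_hz=supp_rate,
                             supp_pct_baseline=pct, p_value=p)


def rebound_test(psth: UnitPSTH, params: AnalysisParams | None = None
                 ) -> ReboundResult:
    """Test post-suppression rebound against the pre-stimulus baseline.

    The rebound is located at the maximal PSTH bin within the rebound window;
    its amplitude is the mean rate from 20 ms before to 20 ms after that bin
    (span truncated at the window edges). Per-trial rates over the span are
    paired with per-trial baseline rates (Wilcoxon signed rank).
    """
    params = params or psth.params
    if psth.n_trials < params.min_trials_test:
        raise ValueError(f"need >= {params.min_trials_test} trials for the signed-rank test")
    lo, hi = params.rebound_window_ms
    edges = psth.params.bin_edges_ms
    win = np.nonzero((edges[:-1] >= lo) & (edges[:-1] < hi))[0]
    b_max = int(win[np.argmax(psth.rate_hz[win])])
    latency = float(edges[b_max] + params.bin_ms / 2.0)
    half = params.rebound_halfwidth_ms
    span_lo = max(lo, edges[b_max] - half)
    span_hi = min(hi, edges[b_max + 1] + half)
    span = psth.trial_rates(span_lo, span_hi)
    base = psth.trial_rates(params.baseline_s[0] * 1000.0, params.baseline_s[1] * 1000.0)
    p = paired_wilcoxon(span, base)
    amp = float(span.mean())
    has = bool(np.isfinite(p) and p < params.alpha and amp > psth.baseline_mean_hz)
    return ReboundResult(has_rebound=has, rebound_amp_hz=amp,
                         rebound_latency_ms=latency, p_value=p)


# ---------------------------------------------------------------------------
# Population summaries
# ---------------------------------------------------------------------------

# (row label, unit-table column, restrict to responsive units, is a fraction)
SUMMARY_ROWS = [
    ("baseline_hz", "baseline_hz", True, False),
    ("responsive_pct", "responsive", False, True),
    ("onset_ms", "onset_ms", True, False),
    ("peak_ms", "peak_ms", True, False),
    ("duration_ms", "duration_ms", True, False),
    ("amplitude_hz", "peak_amp_hz", True, False),
    ("suppressed_pct", "is_suppressed", True, True),
    ("supp_pct_baseline", "supp_pct_baseline_flagged", True, False),
    ("rebound_pct", "has_rebound", True, True),
    ("rebound_latency_ms", "rebound_latency_flagged_ms", True, False),
    ("rebound_amp_hz", "rebound_amp_flagged_hz", True, False),
]


def _paired_area_test(s1: np.ndarray, m1: np.ndarray, min_wilcoxon: int = 6) -> float:
    """Paired S1-vs-M1 comparison: signed rank for n >= 6, else paired t."""
    ok = np.isfinite(s1) & np.isfinite(m1)
    s1, m1 = s1[ok], m1[ok]
    if len(s1) < 2:
        return float("nan")
    if len(s1) >= min_wilcoxon:
        return paired_wilcoxon(m1, s1)
    if np.allclose(m1, s1):
        return 1.0
    return float(stats.ttest_rel(m1, s1).pvalue)


def summarize(unit_table: pd.DataFrame) -> pd.DataFrame:
    """Build the per-area response-property summary.

    ``unit_table`` holds one row per active unit with recording_id, area,
    responsive flag and the per-unit metric columns (missing metrics as NaN).
    Unit values are pooled to per-recording means, then averaged across
    recordings (mean ± s.d.); each parameter gets the paired between-area
    test and the per-recording M1 − S1 difference computed over recordings
    contributing both areas.
    """
    rows = []
    for label, col, resp_only, is_frac in SUMMARY_ROWS:
        if col not in unit_table.columns:
            continue
        rec_means: dict[str, pd.Series] = {}
        for area in ("S1", "M1"):
            sub = unit_table[unit_table["area"] == area]
            if resp_only and not is_frac:
                sub = sub[sub["responsive"].astype(bool)]
            if is_frac:
                if resp_only:
                    sub = sub[sub["responsive"].astype(bool)]
                vals = sub.groupby("recording_id")[col].apply(
                    lambda s: 100.0 * np.nanmean(s.astype(float)))
            else:
                vals = sub.groupby("recording_id")[col].apply(
                    lambda s: np.nanmean(s.astype(float))
                    if np.isfinite(s.astype(float)).any() else np.nan)
            rec_means[area] = vals
        s1, m1 = rec_means["S1"], rec_means["M1"]
        both = s1.index.intersection(m1.index)
        s1b = s1.loc[both].to_numpy(dtype=float)
        m1b = m1.loc[both].to_numpy(dtype=float)
        ok = np.isfinite(s1b) & np.isfinite(m1b)
        diff = m1b[ok] - s1b[ok]
        def _mean(v):
            v = np.asarray(v, dtype=float)
            v = v[np.isfinite(v)]
            return float(v.mean()) if len(v) else np.nan

        def _sd(v):
            v = np.asarray(v, dtype=float)
            v = v[np.isfinite(v)]
            return float(v.std(ddof=1)) if len(v) > 1 else np.nan

        rows.append({
            "parameter": label,
            "s1_mean": _mean(s1), "s1_sd": _sd(s1),
            "m1_mean": _mean(m1), "m1_sd": _sd(m1),
            "p_value": _paired_area_test(s1b, m1b),
            "diff_mean": float(diff.mean()) if len(diff) else np.nan,
            "diff_sd": float(diff.std(ddof=1)) if len(diff) > 1 else np.nan,
            "n_recordings": int(ok.sum()),
        })
    return pd.DataFrame(rows)


def spearman_with_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with p from the t transform.

    t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom. Returns
    (NaN, NaN) for constant input or n < 4.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def correlate_properties(rec_means: pd.DataFrame,
                         pairs: list[tuple[str, str]] | None = None
                         ) -> pd.DataFrame:
    """Spearman correlation matrix across per-recording mean properties.

    ``rec_means`` has one row per recording, one column per property.
    Returns a long table (prop_a, prop_b, rho, p_value, significant) for
    each requested pair (all unordered pairs by default). Constant columns
    yield NaN rho and are flagged non-significant.
    """
    cols = list(rec_means.columns)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    out = []
    for a, b in pairs:
        rho, p = spearman_with_t(rec_means[a].to_numpy(), rec_means[b].to_numpy())
        out.append({"prop_a": a, "prop_b": b, "rho": rho, "p_value": p,
                    "significant": bool(np.isfinite(p) and p < 0.05)})
    return pd.DataFrame(out)


def adjust_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject flags, adjusted p-values). NaN p-values are passed
    through unrejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject = np.zeros(p.shape, dtype=bool)
    adj = np.full(p.shape, np.nan)
    if ok.any():
        r, a, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
        reject[ok] = r
        adj[ok] = a
    return reject, adj
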