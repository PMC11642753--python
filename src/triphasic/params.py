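"""Analysis parameters shared across the pipeline.

All windows are expressed relative to stimulus onset. The defaults implement
the standard configuration used throughout: 5-ms bins spanning 0.5 s before to
0.5 s after the stimulus, a 250-ms pre-stimulus baseline, a 2.5-s.d. z-score
threshold for responsiveness, and the canonical suppression (110-170 ms) and
rebound (190-400 ms) windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class AnalysisParams:
    """Configuration for PSTH construction and response-metric extraction.

    Attributes
    ----------
    bin_ms :
        PSTH bin width in milliseconds. Must divide every window extent.
    window_s :
        Peristimulus window (start, stop) in seconds relative to stimulus
        onset. Bins are half-open, left-inclusive, anchored at onset.
    baseline_s :
        Pre-stimulus baseline window in seconds; baseline mean/s.d. are
        computed from the trial-averaged rate in these bins.
    z_thresh :
        Responsiveness / onset threshold in baseline standard deviations.
    fall_thresh_sd :
        Duration endpoint: the rate must fall below this many baseline s.d.
        above baseline.
    peak_search_ms :
        Window for peak-amplitude/latency/onset/duration extraction.
    supp_window_ms :
        Post-peak suppression test window.
    rebound_window_ms :
        Rebound search window.
    rebound_halfwidth_ms :
        Half-width of the averaging span around the rebound maximum.
    min_active_units :
        Probes with fewer active units than this are excluded.
    alpha :
        Significance level for all per-unit statistical tests.
    sd_floor_spikes :
        Floor on the baseline s.d. expressed in single-spike rate quanta
        ``1 / (n_trials * bin_s)``. With sparse discrete counts the empirical
        s.d. across baseline bins can fall below the resolution of the rate
        estimate itself, in which case one or two coincident spikes in a bin
        would clear any multiple of it; flooring at one quantum makes the
        z-threshold meaningful at low firing rates. Set to 0 to disable.
    """

    bin_ms: float = 5.0
    window_s: tuple[float, float] = (-0.5, 0.5)
    baseline_s: tuple[float, float] = (-0.25, 0.0)
    z_thresh: float = 2.5
    fall_thresh_sd: float = 1.0
    peak_search_ms: tuple[float, float] = (0.0, 100.0)
    supp_window_ms: tuple[float, float] = (110.0, 170.0)
    rebound_window_ms: tuple[float, float] = (190.0, 400.0)
    rebound_halfwidth_ms: float = 20.0
    min_active_units: int = 15
    alpha: float = 0.05
    sd_floor_spikes: float = 1.0
    laminar_n_bins: int = 20
    laminar_peak_halfwidth_ms: float = 10.0
    min_trials_test: int = 6

    def __post_init__(self) -> None:
        w0, w1 = self.window_s
        b0, b1 = self.baseline_s
        if not (w0 < w1 and w0 <= b0 < b1 <= 0.0):
            raise ValueError("windows must be ordered with baseline pre-stimulus")
        span_ms = (w1 - w0) * 1000.0
        if abs(span_ms / self.bin_ms - round(span_ms / self.bin_ms)) > 1e-9:
            raise ValueError("bin_ms must divide the analysis window")

    @property
    def n_bins(self) -> int:
        return int(round((self.window_s[1] - self.window_s[0]) * 1000.0 / self.bin_ms))

    @property
    def bin_s(self) -> float:
        return self.bin_ms / 1000.0

    @property
    def bin_edges_ms(self) -> "np.ndarray":
        import numpy as np

        return self.window_s[0] * 1000.0 + self.bin_ms * np.arange(self.n_bins + 1)

    @property
    def bin_centers_ms(self) -> "np.ndarray":
        edges = self.bin_edges_ms
        return (edges[:-1] + edges[1:]) / 2.0

    def baseline_slice(self) -> slice:
        """Index slice of the baseline bins within the PSTH."""
        lo = int(round((self.baseline_s[0] - self.window_s[0]) * 1000.0 / self.bin_ms))
        hi = int(round((self.baseline_s[1] - self.window_s[0]) * 1000.0 / self.bin_ms))
        return slice(lo, hi)

    def post_slice(self) -> slice:
        """Index slice of the post-stimulus bins (0 to window end)."""
        lo = int(round((0.0 - self.window_s[0]) * 1000.0 / self.bin_ms))
        return slice(lo, self.n_bins)

    def sd_floor_hz(self, n_trials: int) -> float:
        """Baseline-s.d. floor in Hz for a PSTH built from ``n_trials`` trials."""
        if self.sd_floor_spikes <= 0 or n_trials <= 0:
            return 0.0
        return self.sd_floor_spikes / (n_trials * self.bin_s)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        d = dict(d)
        for key in ("window_s", "baseline_s", "peak_search_ms", "supp_window_ms",
                    "rebound_window_ms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)
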