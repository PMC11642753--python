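import numpy as np
import pandas as pd
import pytest

import triphasic as tp

# Cohort-level study conditions: 13 paired recordings, default presets,
# fixed seed chosen up front for reproducibility.
COHORT_SEED = 7
N_RECORDINGS = 13


@pytest.fixture(scope="session")
def default_cohort():
    """The 13-recording default synthetic cohort (simulated once per session)."""
    configs = tp.default_cohort_configs(N_RECORDINGS)
    manifest, spikes, trials, units = tp.simulate_cohort(configs, seed=COHORT_SEED)
    return manifest, spikes, trials, units


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """Full pipeline output on the default cohort."""
    manifest, spikes, trials, units = default_cohort
    return tp.run_analysis(spikes, trials, units, probe_coords=manifest.probe_coords)


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-recording cohort for cheaper end-to-end checks."""
    configs = tp.default_cohort_configs(2)
    return tp.simulate_cohort(configs, seed=11)


def make_psth_from_rates(rate_hz, n_trials=200, params=None):
    """UnitPSTH whose trial-averaged rate equals ``rate_hz`` exactly.

    Places the per-bin totals in a single trial; with n_trials chosen so that
    rate values are integer multiples of 1/(n_trials*bin_s) the average
    reproduces the requested vector.
    """
    params = params or tp.AnalysisParams()
    rate_hz = np.asarray(rate_hz, dtype=float)
    counts = np.zeros((n_trials, params.n_bins))
    counts[0, :] = rate_hz * params.bin_s * n_trials
    return tp.average_psth(counts, params)
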