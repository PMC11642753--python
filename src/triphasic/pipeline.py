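"""Full analysis pipeline: from spike/trial/unit tables to all result tables.

Stages (each skipped gracefully when its trials are absent): probe-level
inclusion filter -> hand-stimulation PSTHs, responsiveness and triphasic
metrics -> per-area summaries -> laminar profiles -> opto-tag PV parsing ->
propagation speeds -> paired-pulse recovery -> partial-silencing effects.
Every exclusion is recorded in ``result.log``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import AnalysisParams
from . import psth as _psth
from . import metrics as _metrics
from . import laminar as _laminar
from . import optotag as _optotag
from . import pathways as _pathways

__all__ = ["AnalysisResult", "run_analysis"]

# By experimental convention the cortical laser targets the S1 probe; only
# S1 units are opto-tagged and M1 units enter the silencing analysis untagged.
LASER_AREA = "S1"


@dataclass
class AnalysisResult:
    params: AnalysisParams
    unit_table: pd.DataFrame
    summary: pd.DataFrame
    laminar: pd.DataFrame
    tags: pd.DataFrame
    partition: dict
    speeds_per_recording: pd.DataFrame
    speeds_summary: pd.DataFrame
    paired_pulse: dict
    silencing: pd.DataFrame
    correlations: pd.DataFrame
    grand_psth: dict  # area -> (centers_ms, mean, sd)
    laminar_corr: dict  # area -> (rho, p)
    log: list[str] = field(default_factory=list)

    def write(self, outdir) -> dict:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        def save(df: pd.DataFrame | None, name: str):
            if df is None or len(df) == 0:
                return
            df.to_csv(out / f"{name}.csv", index=False)
            paths[name] = str(out / f"{name}.csv")

        save(self.unit_table, "metrics")
        save(self.summary, "summary")
        save(self.laminar, "laminar")
        save(self.tags, "tags")
        save(self.speeds_per_recording, "speeds")
        save(self.speeds_summary, "speeds_summary")
        save(self.silencing, "silencing")
        save(self.correlations, "correlations")
        pp_frames = []
        for area, res in self.paired_pulse.items():
            df = res.get("per_recording")
            if df is not None and len(df):
                df = df.copy()
                df.insert(0, "area", area)
                pp_frames.append(df)
        if pp_frames:
            save(pd.concat(pp_frames, ignore_index=True), "paired_pulse")
        if self.partition:
            save(self.partition.get("per_recording"), "pv_partition")
            save(self.partition.get("comparisons"), "pv_comparisons")
        (out / "exclusions.log").write_text("\n".join(self.log) + "\n")
        return paths


def _events(trials: pd.DataFrame, rec: str, **where) -> np.ndarray:
    sel = trials["recording_id"] == rec
    for col, val in where.items():
        if val is None:
            sel &= trials[col].isna()
        else:
            sel &= trials[col] == val
    return np.sort(trials.loc[sel, "event_time_s"].to_numpy(dtype=float))


def run_analysis(spikes: pd.DataFrame, trials: pd.DataFrame, units: pd.DataFrame,
                 params: AnalysisParams | None = None,
                 probe_coords: dict | None = None) -> AnalysisResult:
    """Run every analysis stage supported by the supplied trial protocols."""
    params = params or AnalysisParams()
    units_kept, log = _psth.filter_recordings(units, params)
    spikes = spikes[spikes["unit_id"].isin(units_kept["unit_id"])]

    unit_rows: list[dict] = []
    hand_psths: dict[str, _psth.UnitPSTH] = {}
    recs = sorted(units_kept["recording_id"].unique())
    spk_by_rec = dict(tuple(spikes.groupby("recording_id", sort=False))) if len(spikes) else {}

    for rec in recs:
        ev = _events(trials, rec, protocol="hand")
        if len(ev) == 0:
            log.append(f"{rec}: no hand-stimulation trials; unit metrics skipped")
            continue
        rec_units = units_kept[units_kept["recording_id"] == rec]
        rec_spikes = spk_by_rec.get(rec, spikes.iloc[0:0])
        psths = _psth.build_unit_psths(rec_spikes, ev, rec_units["unit_id"], params)
        hand_psths.update(psths)
        for row in rec_units.itertuples(index=False):
            p = psths[row.unit_id]
            entry = {
                "recording_id": rec, "unit_id": row.unit_id, "area": row.area,
                "depth_frac": row.depth_frac,
                "is_single": bool(getattr(row, "is_single", True)),
                "n_trials": p.n_trials,
                "baseline_hz": p.baseline_mean_hz, "baseline_sd_hz": p.baseline_sd_hz,
                "responsive": bool(p.responsive),
                "onset_ms": np.nan, "peak_ms": np.nan, "peak_amp_hz": np.nan,
                "duration_ms": np.nan, "evoked_spikes": np.nan,
                "is_suppressed": np.nan, "supp_pct_baseline_flagged": np.nan,
                "supp_p": np.nan, "has_rebound": np.nan,
                "rebound_latency_flagged_ms": np.nan,
                "rebound_amp_flagged_hz": np.nan, "rebound_p": np.nan,
            }
            if p.responsive:
                pk = _metrics.peak_metrics(p, params)
                if pk is not None:
                    entry.update(onset_ms=pk.onset_ms, peak_ms=pk.peak_ms,
                                 peak_amp_hz=pk.peak_amp_hz, duration_ms=pk.duration_ms)
                else:
                    log.append(f"{rec}/{row.unit_id}: responsive but no peak-window "
                               "threshold crossing; excluded from peak summaries")
                edges = params.bin_edges_ms
                sel = (edges[:-1] >= params.peak_search_ms[0]) & \
                      (edges[:-1] < params.peak_search_ms[1])
                entry["evoked_spikes"] = float(
                    (p.baseline_subtracted()[sel]).sum() * params.bin_s)
                if p.n_trials >= params.min_trials_test:
                    sup = _metrics.suppression_test(p, params)
                    entry.update(is_suppressed=sup.is_suppressed, supp_p=sup.p_value)
                    if sup.is_suppressed:
                        entry["supp_pct_baseline_flagged"] = sup.supp_pct_baseline
                    reb = _metrics.rebound_test(p, params)
                    entry.update(has_rebound=reb.has_rebound, rebound_p=reb.p_value)
                    if reb.has_rebound:
                        entry["rebound_latency_flagged_ms"] = reb.rebound_latency_ms
                        entry["rebound_amp_flagged_hz"] = reb.rebound_amp_hz
            unit_rows.append(entry)

    unit_columns = [
        "recording_id", "unit_id", "area", "depth_frac", "is_single", "n_trials",
        "baseline_hz", "baseline_sd_hz", "responsive", "onset_ms", "peak_ms",
        "peak_amp_hz", "duration_ms", "evoked_spikes", "is_suppressed",
        "supp_pct_baseline_flagged", "supp_p", "has_rebound",
        "rebound_latency_flagged_ms", "rebound_amp_flagged_hz", "rebound_p"]
    unit_table = pd.DataFrame(unit_rows, columns=unit_columns)
    summary = _metrics.summarize(unit_table) if len(unit_table) else pd.DataFrame()

    # Spearman correlations among per-recording mean response properties.
    corr_frames = []
    for area in ("S1", "M1"):
        resp = unit_table[(unit_table["area"] == area) & unit_table["responsive"]] \
            if len(unit_table) else unit_table
        if len(resp) == 0:
            continue
        rec_means = resp.groupby("recording_id")[
            ["baseline_hz", "onset_ms", "peak_ms", "duration_ms", "peak_amp_hz"]
        ].mean()
        if len(rec_means) >= 4:
            c = _metrics.correlate_properties(rec_means)
            c.insert(0, "area", area)
            corr_frames.append(c)
    correlations = (pd.concat(corr_frames, ignore_index=True)
                    if corr_frames else pd.DataFrame())

    # Grand-average PSTHs (responsive units, two-level pooling) per area.
    grand = {}
    for area in ("S1", "M1"):
        per_rec: dict[str, list[np.ndarray]] = {}
        for row in unit_table[(unit_table["area"] == area)
                              & unit_table["responsive"]].itertuples(index=False):
            per_rec.setdefault(row.recording_id, []).append(
                hand_psths[row.unit_id].rate_hz)
        if per_rec:
            _, mean, sd = _psth.grand_average(per_rec)
            grand[area] = (params.bin_centers_ms, mean, sd)

    # Laminar profiles over all active units, peak- and rebound-centred.
    laminar_frames = []
    laminar_corr = {}
    for area in ("S1", "M1"):
        area_units = units_kept[units_kept["area"] == area]
        area_psths = {u: hand_psths[u] for u in area_units["unit_id"] if u in hand_psths}
        if not area_psths:
            continue
        prof_peak = _laminar.laminar_amplitude(area_units, area_psths, params)
        df = prof_peak.to_frame()
        df.insert(0, "area", area)
        df.insert(1, "phase", "peak")
        laminar_frames.append(df)
        # rebound-centred profile: window around the grand rebound maximum
        pooled = np.mean(np.vstack([p.baseline_subtracted()
                                    for p in area_psths.values()]), axis=0)
        centers = params.bin_centers_ms
        lo, hi = params.rebound_window_ms
        win = (centers >= lo) & (centers < hi)
        reb_peak_ms = float(centers[win][np.argmax(pooled[win])])
        prof_reb = _laminar.laminar_amplitude(area_units, area_psths, params,
                                              peak_ms=reb_peak_ms)
        df = prof_reb.to_frame()
        df.insert(0, "area", area)
        df.insert(1, "phase", "rebound")
        laminar_frames.append(df)
        try:
            laminar_corr[area] = _laminar.profile_correlation(prof_peak, prof_reb)
        except ValueError as e:
            log.append(f"laminar correlation skipped for {area}: {e}")
    laminar_df = (pd.concat(laminar_frames, ignore_index=True)
                  if laminar_frames else pd.DataFrame())

    # Opto-tagging from full-intensity laser + sham trials (S1 probe).
    tag_rows = []
    for rec in recs:
        laser_ev = _events(trials, rec, protocol="cortex_laser", intensity_frac=1.0)
        sham_ev = _events(trials, rec, protocol="cortex_laser", intensity_frac=0.0)
        if len(laser_ev) == 0 or len(sham_ev) == 0:
            log.append(f"{rec}: no laser/sham trials; units untagged")
            continue
        rec_units = units_kept[(units_kept["recording_id"] == rec)
                               & (units_kept["area"] == LASER_AREA)]
        rec_spikes = spk_by_rec.get(rec, spikes.iloc[0:0])
        by_unit = {uid: grp["spike_time_s"].to_numpy()
                   for uid, grp in rec_spikes.groupby("unit_id", sort=False)}
        for uid in rec_units["unit_id"]:
            t = _optotag.classify_pv(by_unit.get(uid, np.empty(0)), laser_ev, sham_ev,
                                     unit_id=uid)
            tag_rows.append({"recording_id": rec, "unit_id": uid, "is_pv_tagged": t.is_pv,
                             "laser_latency_ms": t.laser_latency_ms,
                             "laser_rate_hz": t.laser_rate_hz,
                             "sham_rate_hz": t.sham_rate_hz,
                             "sustained_frac": t.sustained_frac, "tag_p": t.p_value})
    tags = pd.DataFrame(tag_rows)

    partition = {}
    if len(tags) and len(unit_table):
        tagged = unit_table.merge(tags[["unit_id", "is_pv_tagged"]], on="unit_id",
                                  how="inner")
        if len(tagged):
            partition = _optotag.partition_metrics(tagged)

    # Propagation speeds from per-recording mean latencies + probe geometry.
    speeds_rec = speeds_sum = pd.DataFrame()
    if len(unit_table):
        lat_rows = []
        for rec in recs:
            entry = {"recording_id": rec}
            for area in ("S1", "M1"):
                sub = unit_table[(unit_table["recording_id"] == rec)
                                 & (unit_table["area"] == area)
                                 & unit_table["responsive"]]
                entry[f"{area.lower()}_onset_ms"] = float(np.nanmean(sub["onset_ms"])) \
                    if sub["onset_ms"].notna().any() else np.nan
                entry[f"{area.lower()}_peak_ms"] = float(np.nanmean(sub["peak_ms"])) \
                    if sub["peak_ms"].notna().any() else np.nan
            lat_rows.append(entry)
        geometry = _pathways.PathwayGeometry(probe_coords=probe_coords or {})
        speeds_rec, speeds_sum, sp_log = _pathways.propagation_speeds(
            geometry, pd.DataFrame(lat_rows))
        log.extend(sp_log)

    # Paired-pulse recovery per area, on recording-average responsive PSTHs.
    paired_pulse = {}
    lags = sorted(trials.loc[trials["protocol"] == "paired_pulse", "lag_ms"].dropna()
                  .unique())
    if lags:
        for area in ("S1", "M1"):
            by_rec: dict[str, dict[float, object]] = {}
            for rec in recs:
                resp_units = unit_table[(unit_table["recording_id"] == rec)
                                        & (unit_table["area"] == area)
                                        & unit_table["responsive"]]["unit_id"]
                if len(resp_units) == 0:
                    continue
                rec_spikes = spk_by_rec.get(rec, spikes.iloc[0:0])
                for lag in lags:
                    ev = _events(trials, rec, protocol="paired_pulse", lag_ms=lag)
                    if len(ev) == 0:
                        log.append(f"{rec}/{area}: missing paired-pulse lag {lag}")
                        continue
                    pp = _psth.build_unit_psths(rec_spikes, ev, resp_units, params)
                    mean_rate = np.mean(np.vstack([p.rate_hz for p in pp.values()]),
                                        axis=0)
                    base = float(np.mean([p.baseline_mean_hz for p in pp.values()]))
                    rec_obj = type("RecPSTH", (), {})()
                    rec_obj.rate_hz = mean_rate
                    rec_obj.baseline_mean_hz = base
                    by_rec.setdefault(rec, {})[float(lag)] = rec_obj
            if by_rec:
                paired_pulse[area] = _pathways.paired_pulse_analysis(by_rec, params)

    # Partial silencing: hand vs cortex vs hand+cortex integrals, 15-50 ms.
    silencing = pd.DataFrame()
    sil_rows = []
    has_combo = (trials["protocol"] == "hand_plus_cortex").any()
    if has_combo:
        tag_map = dict(zip(tags["unit_id"], tags["is_pv_tagged"])) if len(tags) else {}
        for rec in recs:
            ev_hand = _events(trials, rec, protocol="hand")
            ev_combo = _events(trials, rec, protocol="hand_plus_cortex")
            combo_int = trials.loc[(trials["recording_id"] == rec)
                                   & (trials["protocol"] == "hand_plus_cortex"),
                                   "intensity_frac"]
            intensity = float(combo_int.iloc[0]) if len(combo_int) else np.nan
            ev_cortex = _events(trials, rec, protocol="cortex_laser",
                                intensity_frac=intensity)
            if len(ev_hand) == 0 or len(ev_combo) == 0:
                continue
            rec_spikes = spk_by_rec.get(rec, spikes.iloc[0:0])
            resp = unit_table[(unit_table["recording_id"] == rec)
                              & unit_table["responsive"]]
            if len(resp) == 0:
                continue
            psth_hand = _psth.build_unit_psths(rec_spikes, ev_hand, resp["unit_id"], params)
            psth_combo = _psth.build_unit_psths(rec_spikes, ev_combo, resp["unit_id"], params)
            psth_cortex = (_psth.build_unit_psths(rec_spikes, ev_cortex, resp["unit_id"],
                                                  params) if len(ev_cortex) else {})
            for row in resp.itertuples(index=False):
                uid = row.unit_id
                ints = {
                    "int_hand": _pathways.evoked_integral(psth_hand[uid], params),
                    "int_hand_cortex": _pathways.evoked_integral(psth_combo[uid], params),
                    "int_cortex": (_pathways.evoked_integral(psth_cortex[uid], params)
                                   if uid in psth_cortex else np.nan),
                }
                pops = []
                if row.area == "M1":
                    pops.append("M1_all")
                else:
                    pops.append("S1_all")
                    if uid in tag_map:
                        pops.append("S1_PV" if tag_map[uid] else "S1_nonPV")
                for pop in pops:
                    sil_rows.append({"recording_id": rec, "population": pop,
                                     "unit_id": uid, **ints})
        if sil_rows:
            silencing = _pathways.silencing_effect(pd.DataFrame(sil_rows))

    return AnalysisResult(
        params=params, unit_table=unit_table, summary=summary, laminar=laminar_df,
        tags=tags, partition=partition, speeds_per_recording=speeds_rec,
        speeds_summary=speeds_sum, paired_pulse=paired_pulse, silencing=silencing,
        correlations=correlations, grand_psth=grand, laminar_corr=laminar_corr, log=log)
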