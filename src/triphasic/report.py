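"""Human-readable markdown report with summary figures.

The report is deterministic for fixed inputs: grand-average PSTH panels per
area, laminar amplitude profiles, the per-area response-property table, and
(when available) opto-tag, paired-pulse and silencing summaries. Sections
whose inputs are missing are marked as such rather than failing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .pipeline import AnalysisResult


def _table_md(df: pd.DataFrame, floatfmt: str = "{:.2f}") -> str:
    if df is None or len(df) == 0:
        return "_missing_\n"
    show = df.copy()
    for col in show.columns:
        if pd.api.types.is_float_dtype(show[col]):
            show[col] = show[col].map(lambda v: floatfmt.format(v)
                                      if np.isfinite(v) else "n/a")
    lines = ["| " + " | ".join(map(str, show.columns)) + " |",
             "| " + " | ".join("---" for _ in show.columns) + " |"]
    for _, row in show.iterrows():
        lines.append("| " + " | ".join(map(str, row.tolist())) + " |")
    return "\n".join(lines) + "\n"


def _plot_grand_psth(result: AnalysisResult, outdir: Path) -> str | None:
    if not result.grand_psth:
        return None
    fig, axes = plt.subplots(1, len(result.grand_psth), figsize=(10, 3.2),
                             sharey=False, squeeze=False)
    for ax, (area, (centers, mean, sd)) in zip(axes[0], sorted(result.grand_psth.items())):
        ax.fill_between(centers, mean - sd, mean + sd, alpha=0.3, lw=0)
        ax.plot(centers, mean, lw=1.2)
        ax.axvline(0.0, color="k", ls="--", lw=0.7)
        ax.set_title(f"{area} grand-average PSTH")
        ax.set_xlabel("time from stimulus (ms)")
        ax.set_ylabel("rate (Hz)")
    fig.tight_layout()
    path = outdir / "grand_psth.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path.name


def _plot_laminar(result: AnalysisResult, outdir: Path) -> str | None:
    lam = result.laminar
    if lam is None or len(lam) == 0:
        return None
    areas = sorted(lam["area"].unique())
    fig, axes = plt.subplots(1, len(areas), figsize=(8, 3.4), squeeze=False)
    for ax, area in zip(axes[0], areas):
        sub = lam[(lam["area"] == area) & (lam["phase"] == "peak")]
        depth = (sub["depth_bin_lo"] + sub["depth_bin_hi"]) / 2.0
        ax.errorbar(sub["amplitude_hz"], depth, xerr=sub["sem_hz"], fmt="o-", ms=3)
        ax.invert_yaxis()
        ax.set_title(f"{area} laminar profile")
        ax.set_xlabel("evoked amplitude (Hz)")
        ax.set_ylabel("normalized depth")
    fig.tight_layout()
    path = outdir / "laminar.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path.name


def render_report(result: AnalysisResult, outdir) -> str:
    """Write report.md (+ PNG figures) into ``outdir``; returns the report path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    parts: list[str] = ["# Evoked-spiking analysis report\n"]

    n_resp = int(result.unit_table["responsive"].sum()) if len(result.unit_table) else 0
    if n_resp == 0:
        parts.append("**No responsive units** were found in this cohort.\n")
    else:
        parts.append(f"Responsive units: {n_resp} of {len(result.unit_table)} active.\n")

    psth_png = _plot_grand_psth(result, out)
    parts.append("## Grand-average PSTHs\n")
    parts.append(f"![grand PSTH]({psth_png})\n" if psth_png else "_missing_\n")

    parts.append("## Response properties (per area, mean across recordings)\n")
    parts.append(_table_md(result.summary))

    lam_png = _plot_laminar(result, out)
    parts.append("## Laminar profiles\n")
    parts.append(f"![laminar]({lam_png})\n" if lam_png else "_missing_\n")

    parts.append("## Propagation speeds\n")
    parts.append(_table_md(result.speeds_summary, "{:.3f}"))

    parts.append("## PV opto-tag partition\n")
    parts.append(_table_md(result.partition.get("per_recording"))
                 if result.partition else "_missing_\n")

    parts.append("## Paired-pulse recovery\n")
    if result.paired_pulse:
        for area, res in sorted(result.paired_pulse.items()):
            parts.append(f"### {area} (Friedman chi2={res['friedman_chi2']:.2f}, "
                         f"p={res['friedman_p']:.3g})\n"
                         if np.isfinite(res["friedman_chi2"]) else f"### {area}\n")
            parts.append(_table_md(res["per_recording"]))
    else:
        parts.append("_missing_\n")

    parts.append("## Partial-silencing effects (Int. FR 15-50 ms)\n")
    parts.append(_table_md(result.silencing, "{:.3f}"))

    if result.log:
        parts.append("## Exclusions\n")
        parts.extend(f"- {line}\n" for line in result.log)

    report = out / "report.md"
    report.write_text("".join(parts))
    return str(report)
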