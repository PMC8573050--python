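"""Human-readable report generation from an analysis results directory.

The report renders tables and figures from the analysis outputs only; no
computation happens here. Missing inputs produce warnings and a partial
report rather than a failure.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _fig_trace_gallery(results: Path, fig_dir: Path, max_rois: int = 8) -> str | None:
    path = results / "traces.csv"
    if not path.exists():
        return None
    df = pd.read_csv(path)
    roi_ids = sorted(df["roi_id"].unique())[:max_rois]
    fig, axes = plt.subplots(len(roi_ids), 1, figsize=(8, 1.2 * len(roi_ids)),
                             sharex=True, squeeze=False)
    for ax, roi in zip(axes[:, 0], roi_ids):
        sub = df[df["roi_id"] == roi]
        ax.plot(sub["t_s"] / 3600.0, sub["dI_over_I0"], lw=0.5)
        ax.set_ylabel(f"ROI {roi}", fontsize=7)
    axes[-1, 0].set_xlabel("time (h)")
    fig.suptitle("dI/I0 traces")
    out = fig_dir / "traces.png"
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return out.name


def _fig_hourly(results: Path, fig_dir: Path) -> str | None:
    path = results / "hourly_summary.csv"
    if not path.exists():
        return None
    df = pd.read_csv(path)
    fig, axes = plt.subplots(1, 3, figsize=(10, 3))
    h = df["window_start_h"]
    axes[0].bar(h, df["mean_primary_dff"], color="tab:blue")
    axes[0].set_title("mean primary dI/I0")
    axes[1].bar(h, df["mean_fidelity"], color="tab:green")
    axes[1].axhline(0.6, color="k", ls="--", lw=0.8)
    axes[1].set_title("fidelity")
    axes[2].bar(h, df["n_secondary"], color="tab:orange")
    axes[2].set_title("secondary responses")
    for ax in axes:
        ax.set_xlabel("recording hour")
    fig.tight_layout()
    out = fig_dir / "hourly.png"
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return out.name


def _fig_nap(results: Path, fig_dir: Path) -> str | None:
    path = results / "nap.csv"
    if not path.exists():
        return None
    df = pd.read_csv(path)
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(df["window_start_h"], df["nap"], color="tab:purple")
    ax.set_xlabel("recording hour")
    ax.set_ylabel("NAP")
    fig.tight_layout()
    out = fig_dir / "nap.png"
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return out.name


def _table(df: pd.DataFrame, max_rows: int = 30) -> str:
    return df.head(max_rows).to_markdown(index=False, floatfmt=".3f")


def run_report(results_dir: str | Path, out_path: str | Path) -> Path:
    """Render a markdown report (with figures) from analysis outputs."""
    results = Path(results_dir)
    out_path = Path(out_path)
    fig_dir = out_path.parent / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    lines = ["# Ca2+ bioluminescence analysis report", ""]

    summary_path = results / "summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        lines += [
            f"* assigned ROIs: **{summary.get('n_rois')}**",
            f"* detected events: **{summary.get('n_events')}** "
            f"({summary.get('event_classes')})",
            "",
        ]
    else:
        warnings.warn("summary.json missing; partial report", stacklevel=2)
        summary = {}

    for name, title in [("hourly_summary.csv", "Per-hour summary"),
                        ("nap.csv", "Neuronal activation parameter (NAP)"),
                        ("fidelity.csv", "Fidelity per ROI per hour")]:
        path = results / name
        if path.exists():
            lines += [f"## {title}", "", _table(pd.read_csv(path)), ""]
        else:
            warnings.warn(f"{name} missing; section skipped", stacklevel=2)

    corr_path = results / "correlation.json"
    if corr_path.exists():
        corr = json.loads(corr_path.read_text())["temporal"]
        lines += ["## Optical-electrical correlation", "",
                  f"R^2 = {corr['r2']:.3f}, slope = {corr['slope']:.3f} uV/% "
                  f"(n = {corr['n']})", ""]

    kin_path = results / "kinetics.json"
    if kin_path.exists():
        kin = json.loads(kin_path.read_text()).get("decay")
        if kin and kin.get("t_half_ms_mean"):
            lines += ["## Decay kinetics", "",
                      f"mean half-life {kin['t_half_ms_mean']:.0f} ms over "
                      f"{kin['n_fits']} transients (ROI {kin['roi_id']})", ""]

    if summary.get("n_events") == 0:
        lines += ["*No events were detected in this session.*", ""]

    figs = [f for f in (_fig_trace_gallery(results, fig_dir),
                        _fig_hourly(results, fig_dir),
                        _fig_nap(results, fig_dir)) if f]
    if figs:
        lines += ["## Figures", ""]
        lines += [f"![{f}](figures/{f})" for f in figs] + [""]

    out_path.write_text("\n".join(lines))
    return out_path
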