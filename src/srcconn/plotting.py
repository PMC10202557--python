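"""Static summary figures for pipeline results."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

GROUP_ORDER = ("control", "tinnitus", "pain")
GROUP_COLORS = {"control": "0.6", "tinnitus": "tab:orange", "pain": "tab:red"}


def _grouped_bars(ax, table: pd.DataFrame, value: str, feature: str) -> None:
    feats = table[feature].unique()
    width = 0.8 / len(GROUP_ORDER)
    for gi, grp in enumerate(GROUP_ORDER):
        sub = table[table.group == grp]
        means = [sub.loc[sub[feature] == f, value].mean() for f in feats]
        sems = [sub.loc[sub[feature] == f, value].sem() for f in feats]
        x = np.arange(len(feats)) + (gi - 1) * width
        ax.bar(x, means, width=width, yerr=sems, capsize=2,
               color=GROUP_COLORS[grp], label=grp)
    ax.set_xticks(np.arange(len(feats)))
    ax.set_xticklabels(feats, rotation=60, ha="right", fontsize=7)
    ax.legend(fontsize=7)


def plot_roi_band_power(roi_power: pd.DataFrame, band: str, path: str | Path) -> None:
    """Group-mean ROI log relative power in one band, with SEM bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.2), constrained_layout=True)
    sub = roi_power[roi_power.band == band].rename(columns={"roi": "feature"})
    _grouped_bars(ax, sub, "log_rel_power", "feature")
    ax.set_ylabel(f"log relative {band} power")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gc_links(gc: pd.DataFrame, path: str | Path,
                  links: list[str] | None = None) -> None:
    """Group-mean directed theta coupling per link, with SEM bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gc = gc.assign(feature=gc.source_roi + "→" + gc.target_roi)
    if links is not None:
        gc = gc[gc.feature.isin(links)]
    fig, ax = plt.subplots(figsize=(8, 3.2), constrained_layout=True)
    _grouped_bars(ax, gc, "gc", "feature")
    ax.set_ylabel("Granger causality (theta)")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pac(pac: pd.DataFrame, path: str | Path) -> None:
    """Group-mean theta-gamma mean vector length per ROI."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2), constrained_layout=True)
    _grouped_bars(ax, pac.rename(columns={"roi": "feature"}), "mvl", "feature")
    ax.set_ylabel("theta-gamma MVL")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_summary_figures(result, out_dir: str | Path | None = None) -> list[Path]:
    """Write the standard figure set for a PipelineResult; returns the paths."""
    out = Path(out_dir) if out_dir is not None else result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for band in ("theta", "gamma"):
        p = out / f"roi_power_{band}.png"
        plot_roi_band_power(result.roi_power, band, p)
        paths.append(p)
    p = out / "gc_links.png"
    plot_gc_links(result.gc, p)
    paths.append(p)
    p = out / "pac_mvl.png"
    plot_pac(result.pac, p)
    paths.append(p)
    return paths
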