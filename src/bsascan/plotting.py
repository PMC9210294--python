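"""Track plots: per-chromosome window statistics with threshold overlays."""

from __future__ import annotations

import re
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def _natural_key(name: str):
    return [int(t) if t.isdigit() else t.lower() for t in re.split(r"(\d+)", str(name))]


_TRACKS = {
    "ratio": ("ratio", "sSNP/totalSNP ratio"),
    "g": ("mean_g", "G-statistic"),
    "delta_af": ("mean_delta_af", "ΔAF"),
}


def plot_tracks(
    windows: pd.DataFrame,
    out_dir: str | Path,
    *,
    genome_ratio_threshold: float | None = None,
    statistics: tuple[str, ...] = ("ratio",),
) -> list[Path]:
    """One multi-panel figure per statistic (panels = chromosomes, natural order).

    Ratio panels draw the genome-wide threshold as a horizontal line; G panels
    overlay the averaged simulated threshold curve; ΔAF panels draw the
    simulated confidence band symmetrically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(windows) == 0:
        import warnings

        warnings.warn("empty window table; nothing to plot")
        return []
    chroms = sorted(windows["chrom"].unique(), key=_natural_key)
    written = []
    for stat in statistics:
        col, label = _TRACKS[stat]
        if col not in windows:
            continue
        fig, axes = plt.subplots(
            1, len(chroms), figsize=(3 * len(chroms), 2.8), sharey=True, squeeze=False
        )
        for ax, chrom in zip(axes[0], chroms):
            grp = windows[windows["chrom"] == chrom]
            x = grp["start"].to_numpy() / 1e6
            ax.plot(x, grp[col], lw=0.8, color="black")
            if stat == "ratio" and genome_ratio_threshold is not None:
                ax.axhline(genome_ratio_threshold, color="red", lw=0.8)
            elif stat == "g" and "mean_g_thr" in grp:
                ax.plot(x, grp["mean_g_thr"], color="red", lw=0.8)
            elif stat == "delta_af" and "mean_delta_af_hi" in grp:
                ax.plot(x, grp["mean_delta_af_hi"], color="red", lw=0.8)
                ax.plot(x, grp["mean_delta_af_lo"], color="red", lw=0.8)
            ax.set_title(str(chrom), fontsize=9)
            ax.set_xlabel("Mb", fontsize=8)
        axes[0][0].set_ylabel(label, fontsize=9)
        fig.tight_layout()
        path = out_dir / f"track_{stat}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
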