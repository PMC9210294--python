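"""Sliding-window aggregation, peak calling and verification.

Per-SNP statistics are aggregated into overlapping windows (default 2 Mb
advancing by 10 kb; a 5 Mb "maize" preset ships for larger genomes).  The
window-level statistic of the ratio method is sSNP count / total SNP count —
an enrichment measure robust to uneven SNP density — while the ΔAF and G
tracks use the window mean of the smoothed per-SNP values.

Peak calling is two-stage for the ratio method: windows above the genome-wide
null threshold form candidate runs, the extreme window of each run is the
candidate peak, and each peak is then verified against its own window-specific
simulated threshold (typically a little higher than the genome-wide one in
SNP-poor windows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractViolation
from .thresholds import NullModel, ThresholdEstimate, window_ratio_threshold

#: window aggregation: stats column -> (windows column, how)
_AGG_COLUMNS = {
    "delta_af_sm": ("mean_delta_af", "mean"),
    "g_stat_sm": ("mean_g", "mean"),
    "delta_af_lo_sm": ("mean_delta_af_lo", "mean"),
    "delta_af_hi_sm": ("mean_delta_af_hi", "mean"),
    "g_thr_sm": ("mean_g_thr", "mean"),
}


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry (1-based half-open intervals)."""

    window_size: int = 2_000_000
    step: int = 10_000

    def __post_init__(self):
        if self.window_size <= 0 or self.step <= 0:
            raise ContractViolation("window_size and step must be positive")
        if self.step > self.window_size:
            raise ContractViolation("step must not exceed window_size")


#: preset for large-genome crops (maize-scale chromosomes)
MAIZE_PRESET = WindowConfig(window_size=5_000_000, step=10_000)


@dataclass(frozen=True)
class PeakCall:
    """A candidate or verified significant region."""

    chrom: str
    position: int
    statistic: str
    value: float
    genome_threshold: float | None = None
    window_threshold: float | None = None
    verified: bool = False
    start: int | None = None
    end: int | None = None


def build_windows(stats: pd.DataFrame, cfg: WindowConfig) -> pd.DataFrame:
    """Aggregate per-SNP statistics into sliding windows.

    Windows start at position 1 on each chromosome and advance by ``step``
    until the last SNP is covered; trailing SNP-free windows are not emitted
    but interior empty windows are kept with an undefined (NaN) ratio.
    Requires ``stats`` sorted by position within each chromosome.
    """
    frames = []
    for chrom, grp in stats.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ContractViolation(f"SNPs on {chrom} are not sorted by position")
        starts = np.arange(1, pos[-1] + 1, cfg.step, dtype=np.int64)
        ends = starts + cfg.window_size
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        total = hi - lo

        def _window_sum(col: np.ndarray) -> np.ndarray:
            cs = np.concatenate([[0.0], np.cumsum(col, dtype=float)])
            return cs[hi] - cs[lo]

        out = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": ends,
                "total_snps": total,
                "ssnps": _window_sum(grp["is_ssnp"].to_numpy()).astype(np.int64)
                if "is_ssnp" in grp
                else 0,
            }
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            out["ratio"] = np.where(total > 0, out["ssnps"] / np.maximum(total, 1), np.nan)
            for col, (name, _) in _AGG_COLUMNS.items():
                if col in grp:
                    out[name] = np.where(
                        total > 0, _window_sum(grp[col].to_numpy()) / np.maximum(total, 1), np.nan
                    )
        frames.append(out)
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "total_snps", "ssnps", "ratio"]
        )
    return pd.concat(frames, ignore_index=True)


def mean_snp_count_per_window(windows: pd.DataFrame) -> float:
    """Average total SNP count per window (empty windows count as zero)."""
    if len(windows) == 0:
        raise ContractViolation("no windows")
    return float(windows["total_snps"].mean())


def _candidate_runs(sig: np.ndarray, chroms: np.ndarray):
    """Yield (start_idx, end_idx) of maximal runs of True within a chromosome."""
    n = len(sig)
    i = 0
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        yield i, j + 1
        i = j + 1


def call_peaks(
    windows: pd.DataFrame,
    statistic: str,
    *,
    genome_threshold: ThresholdEstimate | float | None = None,
    stats: pd.DataFrame | None = None,
    model: NullModel | None = None,
    position: str = "start",
    rng_stream: int = 100,
) -> list[PeakCall]:
    """Call peaks for one statistic from the window table.

    ``statistic`` is ``"ratio"`` (needs ``genome_threshold`` plus ``stats``
    and ``model`` for per-window verification), ``"g"`` (windows above their
    averaged simulated G threshold) or ``"delta_af"`` (windows outside their
    averaged simulated confidence band, in either direction).  Consecutive
    significant windows form one candidate region whose extreme window is the
    peak.  ``position`` reports the peak at the window ``"start"`` (default)
    or ``"midpoint"``.
    """
    if len(windows) == 0:
        return []
    chroms = windows["chrom"].to_numpy()
    if statistic == "ratio":
        thr = (
            genome_threshold.upper
            if isinstance(genome_threshold, ThresholdEstimate)
            else genome_threshold
        )
        if thr is None:
            raise ContractViolation("ratio peaks require a genome-wide threshold")
        values = windows["ratio"].to_numpy()
        sig = np.nan_to_num(values, nan=-np.inf) > thr
        extreme = values
    elif statistic == "g":
        values = windows["mean_g"].to_numpy()
        thr_col = windows["mean_g_thr"].to_numpy()
        sig = np.nan_to_num(values, nan=-np.inf) > thr_col
        extreme = values
    elif statistic == "delta_af":
        values = windows["mean_delta_af"].to_numpy()
        lo = windows["mean_delta_af_lo"].to_numpy()
        hi = windows["mean_delta_af_hi"].to_numpy()
        sig = (np.nan_to_num(values, nan=0.0) > hi) | (np.nan_to_num(values, nan=0.0) < lo)
        extreme = np.abs(values)
    else:
        raise ContractViolation(f"unknown statistic {statistic!r}")

    peaks: list[PeakCall] = []
    for k, (i, j) in enumerate(_candidate_runs(sig, chroms)):
        # extreme window of the run; the ratio saturates (plateaus at 1.0)
        # around strong loci, so ties are broken by the window mean G, which
        # keeps decaying with distance — else by the plateau's central window
        seg = extreme[i:j]
        tied = np.flatnonzero(seg == np.nanmax(seg))
        if len(tied) > 1 and statistic == "ratio" and "mean_g" in windows:
            gseg = windows["mean_g"].to_numpy()[i:j][tied]
            idx = i + int(tied[int(np.nanargmax(gseg))])
        else:
            idx = i + int(tied[len(tied) // 2])
        row = windows.iloc[idx]
        pos = int(row["start"]) if position == "start" else int(
            row["start"] + (row["end"] - row["start"]) // 2
        )
        if statistic == "ratio":
            window_thr = None
            verified = False
            if stats is not None and model is not None:
                snps = stats[
                    (stats["chrom"] == row["chrom"])
                    & (stats["pos"] >= row["start"])
                    & (stats["pos"] < row["end"])
                ]
                est = window_ratio_threshold(
                    snps, model, rng=model.rng(stream=rng_stream + k)
                )
                window_thr = float(est.upper)
                verified = bool(row["ratio"] > window_thr)
            peaks.append(
                PeakCall(
                    chrom=str(row["chrom"]),
                    position=pos,
                    statistic="ratio",
                    value=float(row["ratio"]),
                    genome_threshold=float(thr),
                    window_threshold=window_thr,
                    verified=verified,
                    start=int(row["start"]),
                    end=int(row["end"]),
                )
            )
        elif statistic == "g":
            peaks.append(
                PeakCall(
                    chrom=str(row["chrom"]),
                    position=pos,
                    statistic="g",
                    value=float(row["mean_g"]),
                    window_threshold=float(row["mean_g_thr"]),
                    verified=True,
                    start=int(row["start"]),
                    end=int(row["end"]),
                )
            )
        else:
            val = float(row["mean_delta_af"])
            bound = float(row["mean_delta_af_hi"] if val > 0 else row["mean_delta_af_lo"])
            peaks.append(
                PeakCall(
                    chrom=str(row["chrom"]),
                    position=pos,
                    statistic="delta_af",
                    value=val,
                    window_threshold=bound,
                    verified=True,
                    start=int(row["start"]),
                    end=int(row["end"]),
                )
            )
    return peaks


def heterozygosity_track(
    classified: pd.DataFrame, cfg: WindowConfig
) -> pd.DataFrame:
    """Per-window composition of a bulks-only SNP set by parental origin.

    ``classified`` needs ``chrom``, ``pos``, an ``origin`` column with values
    ``shared`` / ``htSNP`` / ``bsSNP`` and (optionally) ``is_ssnp``.  Returns
    per window: heterozygosity (htSNP fraction), bsSNP count, and the ratios
    of sSNPs-within-htSNPs and sSNPs-within-bsSNPs to total SNPs.
    """
    df = classified.copy()
    df["_ht"] = (df["origin"] == "htSNP").astype(float)
    df["_bs"] = (df["origin"] == "bsSNP").astype(float)
    df["_sh"] = (df["origin"] == "shared").astype(float)
    ssnp = df["is_ssnp"].astype(float) if "is_ssnp" in df else 0.0
    df["is_ssnp"] = ssnp
    df["_ht_ssnp"] = df["_ht"] * df["is_ssnp"]
    df["_bs_ssnp"] = df["_bs"] * df["is_ssnp"]
    frames = []
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        starts = np.arange(1, pos[-1] + 1, cfg.step, dtype=np.int64)
        ends = starts + cfg.window_size
        lo = np.searchsorted(pos, starts, "left")
        hi = np.searchsorted(pos, ends, "left")
        total = (hi - lo).astype(float)

        def _s(col):
            cs = np.concatenate([[0.0], np.cumsum(grp[col].to_numpy(), dtype=float)])
            return cs[hi] - cs[lo]

        with np.errstate(invalid="ignore", divide="ignore"):
            safe = np.maximum(total, 1.0)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": ends,
                        "total_snps": total.astype(np.int64),
                        "heterozygosity": np.where(total > 0, _s("_ht") / safe, np.nan),
                        "bs_snps": _s("_bs").astype(np.int64),
                        "shared_fraction": np.where(total > 0, _s("_sh") / safe, np.nan),
                        "bs_fraction": np.where(total > 0, _s("_bs") / safe, np.nan),
                        "ht_ssnp_ratio": np.where(total > 0, _s("_ht_ssnp") / safe, np.nan),
                        "bs_ssnp_ratio": np.where(total > 0, _s("_bs_ssnp") / safe, np.nan),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
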