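"""Monte-Carlo significance thresholds under the null segregation model.

Every threshold in the scan is simulation-based: for each SNP the observed
per-bulk sequencing depths are kept and the ALT read count is redrawn
binomially at the population's null ALT frequency (0.5 for an F2).  From
those null tables we derive

* per-SNP ΔAF confidence bands (default 99%) and G percentiles (default
  99.5th), smoothed per chromosome like the real series;
* a genome-wide sSNP/totalSNP-ratio threshold: each replicate draws as many
  SNPs (with replacement) as the average sliding window holds, simulates
  them under the null, calls sSNPs at the simulation α (default 0.10 —
  deliberately looser than the real-data α so the threshold is conservative)
  and records the replicate's ratio; the threshold is the 99.5th percentile;
* per-window ratio thresholds for verifying candidate peaks, identical but
  using exactly the window's own SNPs.

The null distribution of any of these statistics depends on a SNP only
through its depth pair, so simulations are grouped by unique (depth1,
depth2) pairs; this is distributionally exact and dramatically faster.
Percentiles are nearest-rank order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association_stats import SmoothingParams, g_values, smooth_by_chromosome
from .errors import ContractViolation
from .exact import SignificanceLookup

_CHUNK_CELLS = 4_000_000  # max simulated tables held in memory at once


@dataclass(frozen=True)
class NullModel:
    """Null-hypothesis simulation settings.

    ``alt_freq`` is the theoretical ALT frequency of the segregating
    population (0.5 for an F2; e.g. 0.25/0.75 for a backcross).
    """

    alt_freq: float = 0.5
    replicates: int = 10_000
    alpha_sim: float = 0.10
    ratio_percentile: float = 99.5
    delta_af_ci: float = 99.0
    g_percentile: float = 99.5
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.alt_freq < 1:
            raise ContractViolation("alt_freq must lie strictly between 0 and 1")
        if self.replicates < 1:
            raise ContractViolation("replicates must be >= 1")
        for p in (self.ratio_percentile, self.g_percentile):
            if not 0 < p < 100:
                raise ContractViolation("percentiles must lie in (0, 100)")
        if not 0 < self.delta_af_ci < 100:
            raise ContractViolation("delta_af_ci must lie in (0, 100)")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Deterministic per-purpose stream derived from the root seed."""
        if self.seed is None:
            return np.random.default_rng()
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class ThresholdEstimate:
    """A simulated significance bound for one statistic at one scope."""

    statistic: str            # "ratio" | "delta_af" | "g"
    scope: str                # "genome" | "window" | "snp"
    lower: float | None
    upper: float | None
    replicates: int
    seed: int | None = None

    def __post_init__(self):
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ContractViolation("lower bound exceeds upper bound")


def _nearest_rank(values: np.ndarray, q: float) -> float:
    return float(np.percentile(values, q, method="inverted_cdf"))


def simulate_allele_depths(
    total_depth: int, alt_freq: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw one null (REF, ALT) read split at the given total depth."""
    if total_depth < 1:
        raise ContractViolation("total_depth must be >= 1")
    alt = int(rng.binomial(total_depth, alt_freq))
    return total_depth - alt, alt


def _depths(stats: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    n1 = (stats["ad_ref1"] + stats["ad_alt1"]).to_numpy(dtype=np.int64)
    n2 = (stats["ad_ref2"] + stats["ad_alt2"]).to_numpy(dtype=np.int64)
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ContractViolation("every SNP needs at least one read per bulk")
    return n1, n2


def _warn_if_few(replicates: int) -> None:
    if replicates < 100:
        warnings.warn(
            f"only {replicates} replicates: percentile thresholds will be unstable",
            stacklevel=3,
        )


def snp_level_thresholds(
    stats: pd.DataFrame,
    model: NullModel,
    *,
    smoothing: SmoothingParams = SmoothingParams(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-SNP ΔAF confidence bands and G percentiles under the null.

    Returns ``stats`` with ``delta_af_lo/hi``, ``g_thr`` and their smoothed
    ``*_sm`` companions appended.  SNPs sharing a depth pair share the same
    simulated null distribution, so thresholds are computed once per unique
    pair.
    """
    _warn_if_few(model.replicates)
    if rng is None:
        rng = model.rng(stream=1)
    n1, n2 = _depths(stats)
    pairs = np.stack([n1, n2], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    q_lo = (100.0 - model.delta_af_ci) / 2.0
    q_hi = 100.0 - q_lo
    lo = np.empty(len(uniq))
    hi = np.empty(len(uniq))
    g_thr = np.empty(len(uniq))
    reps = model.replicates
    for i, (d1, d2) in enumerate(uniq):
        a1 = rng.binomial(int(d1), model.alt_freq, size=reps)
        a2 = rng.binomial(int(d2), model.alt_freq, size=reps)
        daf = a2 / d2 - a1 / d1
        lo[i] = _nearest_rank(daf, q_lo)
        hi[i] = _nearest_rank(daf, q_hi)
        g_vals = g_values(d1 - a1, a1, d2 - a2, a2)
        g_thr[i] = _nearest_rank(g_vals, model.g_percentile)
    out = stats.copy()
    out["delta_af_lo"] = lo[inverse]
    out["delta_af_hi"] = hi[inverse]
    out["g_thr"] = g_thr[inverse]
    chroms = out["chrom"].to_numpy()
    for col in ("delta_af_lo", "delta_af_hi", "g_thr"):
        out[col + "_sm"] = smooth_by_chromosome(out[col].to_numpy(), chroms, smoothing)
    return out


def _simulate_ratios(
    lookup: SignificanceLookup,
    snp_idx_fn,
    m: int,
    model: NullModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replicate sSNP/totalSNP ratios for null-simulated SNP sets of size m.

    ``snp_idx_fn(rng, chunk)`` yields a (chunk, m) array of SNP indices.
    """
    reps = model.replicates
    ratios = np.empty(reps)
    chunk = max(1, _CHUNK_CELLS // m)
    done = 0
    while done < reps:
        c = min(chunk, reps - done)
        idx = snp_idx_fn(rng, c)
        a1 = rng.binomial(lookup.n1[idx], model.alt_freq)
        a2 = rng.binomial(lookup.n2[idx], model.alt_freq)
        sig = lookup.significant(idx, a1, a2)
        ratios[done : done + c] = sig.mean(axis=1)
        done += c
    return ratios


def genome_wide_ratio_threshold(
    stats: pd.DataFrame,
    mean_window_snp_count: float,
    model: NullModel,
    *,
    rng: np.random.Generator | None = None,
) -> ThresholdEstimate:
    """Genome-wide null threshold for the window sSNP/totalSNP ratio.

    Each replicate samples ``mean_window_snp_count`` SNPs with replacement
    from the whole dataset, redraws their allele depths under the null, calls
    sSNPs at ``alpha_sim`` and records the ratio; the threshold is the
    ``ratio_percentile`` nearest-rank percentile of the replicate ratios.
    """
    if len(stats) == 0:
        raise ContractViolation("empty SNP dataset")
    m = int(round(mean_window_snp_count))
    if m < 1:
        raise ContractViolation("mean_window_snp_count must be >= 1")
    _warn_if_few(model.replicates)
    if rng is None:
        rng = model.rng(stream=2)
    n1, n2 = _depths(stats)
    lookup = SignificanceLookup(n1, n2, model.alpha_sim)
    n = len(stats)
    ratios = _simulate_ratios(
        lookup, lambda r, c: r.integers(0, n, size=(c, m)), m, model, rng
    )
    return ThresholdEstimate(
        statistic="ratio",
        scope="genome",
        lower=None,
        upper=_nearest_rank(ratios, model.ratio_percentile),
        replicates=model.replicates,
        seed=model.seed,
    )


def window_ratio_threshold(
    window_snps: pd.DataFrame,
    model: NullModel,
    *,
    rng: np.random.Generator | None = None,
) -> ThresholdEstimate:
    """Null ratio threshold for one window, simulating exactly its own SNPs."""
    if len(window_snps) == 0:
        raise ContractViolation("window contains no SNPs")
    _warn_if_few(model.replicates)
    if rng is None:
        rng = model.rng(stream=3)
    n1, n2 = _depths(window_snps)
    lookup = SignificanceLookup(n1, n2, model.alpha_sim)
    m = len(window_snps)
    base = np.arange(m)
    ratios = _simulate_ratios(
        lookup, lambda r, c: np.broadcast_to(base, (c, m)), m, model, rng
    )
    return ThresholdEstimate(
        statistic="ratio",
        scope="window",
        lower=None,
        upper=_nearest_rank(ratios, model.ratio_percentile),
        replicates=model.replicates,
        seed=model.seed,
    )
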