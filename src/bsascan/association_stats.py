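"""Per-SNP association statistics: Fisher's exact P, ΔAF, G, smoothing, sSNP flags.

Every statistic is a function of the 2x2 allele-depth table of one SNP across
the two bulks.  Under the null (no association) the ALT allele segregates
identically in both bulks; phenotypic selection enriches opposite alleles in
opposite bulks, which shows up as a small exact-test P-value, a large |ΔAF|
(difference in ALT-allele frequency between bulks) and a large likelihood-
ratio G = 2 Σ O ln(O/E).

Raw per-SNP series are noisy at typical (<100x) depths, so each series is
smoothed along the SNP index within each chromosome with a Savitzky–Golay
filter before sSNPs (smoothed P < α) are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import ConfigurationError, ContractViolation
from .exact import fisher_pvalues
from .variant_io import SnpRecord


class AdTable(NamedTuple):
    """The 2x2 allele-depth table of one SNP: (REF, ALT) reads per bulk."""

    ad_ref1: int
    ad_alt1: int
    ad_ref2: int
    ad_alt2: int


@dataclass(frozen=True)
class SmoothingParams:
    """Savitzky–Golay settings applied per chromosome over SNP index order."""

    window_length: int = 51
    polyorder: int = 3

    def __post_init__(self):
        if self.window_length <= 0 or self.window_length % 2 == 0:
            raise ConfigurationError("window_length must be a positive odd integer")
        if not 0 <= self.polyorder < self.window_length:
            raise ConfigurationError("polyorder must satisfy 0 <= order < window_length")


def _validate(t: AdTable) -> AdTable:
    t = AdTable(*(int(x) for x in t))
    if any(x < 0 for x in t):
        raise ContractViolation("allele depths must be non-negative")
    if t.ad_ref1 + t.ad_alt1 < 1 or t.ad_ref2 + t.ad_alt2 < 1:
        raise ContractViolation("each bulk needs at least one read")
    return t


def fisher_pvalue(t: AdTable) -> float:
    """Two-sided Fisher's exact test P-value of the allele-depth table.

    Invariant under swapping REF and ALT simultaneously in both bulks.
    """
    t = _validate(t)
    return float(
        fisher_pvalues(
            np.array([t.ad_ref1]),
            np.array([t.ad_alt1]),
            np.array([t.ad_ref2]),
            np.array([t.ad_alt2]),
        )[0]
    )


def delta_af(t: AdTable) -> float:
    """ALT-frequency difference bulk2 − bulk1; sign flips under a REF/ALT swap."""
    t = _validate(t)
    return t.ad_alt2 / (t.ad_ref2 + t.ad_alt2) - t.ad_alt1 / (t.ad_ref1 + t.ad_alt1)


def g_statistic(t: AdTable) -> float:
    """Likelihood-ratio statistic G = 2 Σ O ln(O/E) of the 2x2 table.

    E is the usual independence expectation (row total x column total / grand
    total); empty cells contribute zero.  Invariant under a simultaneous
    REF/ALT swap.
    """
    t = _validate(t)
    return float(
        g_values(
            np.array([t.ad_ref1]),
            np.array([t.ad_alt1]),
            np.array([t.ad_ref2]),
            np.array([t.ad_alt2]),
        )[0]
    )


def delta_af_values(ad_ref1, ad_alt1, ad_ref2, ad_alt2) -> np.ndarray:
    ad_ref1, ad_alt1, ad_ref2, ad_alt2 = (
        np.asarray(a, dtype=float) for a in (ad_ref1, ad_alt1, ad_ref2, ad_alt2)
    )
    return ad_alt2 / (ad_ref2 + ad_alt2) - ad_alt1 / (ad_ref1 + ad_alt1)


def g_values(ad_ref1, ad_alt1, ad_ref2, ad_alt2) -> np.ndarray:
    O = np.stack(
        [np.asarray(a, dtype=float) for a in (ad_ref1, ad_alt1, ad_ref2, ad_alt2)],
        axis=0,
    )
    n1 = O[0] + O[1]
    n2 = O[2] + O[3]
    ref_total = O[0] + O[2]
    alt_total = O[1] + O[3]
    grand = n1 + n2
    E = np.stack([n1 * ref_total, n1 * alt_total, n2 * ref_total, n2 * alt_total]) / grand
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(np.where(O > 0, O / np.where(E > 0, E, 1.0), 1.0)), 0.0)
    return 2.0 * terms.sum(axis=0)


def smooth_by_chromosome(
    values: np.ndarray,
    chroms: Iterable[str],
    params: SmoothingParams = SmoothingParams(),
) -> np.ndarray:
    """Savitzky–Golay smoothing applied independently within each chromosome.

    Values must already be in ascending-position order within each
    chromosome.  A chromosome with fewer points than the window is returned
    unchanged.
    """
    values = np.asarray(values, dtype=float)
    chroms = np.asarray(list(chroms))
    if values.shape[0] != chroms.shape[0]:
        raise ConfigurationError("values and chromosome labels differ in length")
    out = values.copy()
    # contiguous runs of equal chromosome label
    boundaries = np.flatnonzero(np.concatenate([[True], chroms[1:] != chroms[:-1], [True]]))
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        if hi - lo >= params.window_length:
            out[lo:hi] = savgol_filter(values[lo:hi], params.window_length, params.polyorder)
    return out


def records_to_frame(records: Iterable[SnpRecord]) -> pd.DataFrame:
    """Extract the per-bulk biallelic allele depths into a DataFrame.

    Requires filtered records (biallelic, AD present in both bulks, at least
    one read per bulk).
    """
    rows = []
    for rec in records:
        if len(rec.alt_alleles) != 1:
            raise ContractViolation(
                f"record {rec.chrom}:{rec.pos} is not biallelic; filter first"
            )
        b1 = rec.samples.get("bulk1")
        b2 = rec.samples.get("bulk2")
        if b1 is None or b2 is None or b1.allele_depths is None or b2.allele_depths is None:
            raise ContractViolation(
                f"record {rec.chrom}:{rec.pos} lacks bulk allele depths; filter first"
            )
        rows.append(
            (
                rec.chrom,
                rec.pos,
                b1.allele_depths[0],
                b1.allele_depths[1],
                b2.allele_depths[0],
                b2.allele_depths[1],
            )
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ad_ref1", "ad_alt1", "ad_ref2", "ad_alt2"]
    )
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def compute_stats(
    snps: pd.DataFrame | Iterable[SnpRecord],
    *,
    alpha: float = 0.01,
    smoothing: SmoothingParams = SmoothingParams(),
) -> pd.DataFrame:
    """Compute raw and smoothed per-SNP statistics and flag sSNPs.

    Accepts filtered records or a DataFrame with columns
    ``chrom, pos, ad_ref1, ad_alt1, ad_ref2, ad_alt2`` (sorted by position
    within chromosome).  Returns the frame with ``fisher_p``, ``delta_af``,
    ``g_stat``, their ``*_sm`` smoothed companions and ``is_ssnp`` appended.
    """
    if not isinstance(snps, pd.DataFrame):
        df = records_to_frame(snps)
    else:
        df = snps.copy().reset_index(drop=True)
    r1, a1 = df["ad_ref1"].to_numpy(), df["ad_alt1"].to_numpy()
    r2, a2 = df["ad_ref2"].to_numpy(), df["ad_alt2"].to_numpy()
    df["fisher_p"] = fisher_pvalues(r1, a1, r2, a2)
    df["delta_af"] = delta_af_values(r1, a1, r2, a2)
    df["g_stat"] = g_values(r1, a1, r2, a2)
    chroms = df["chrom"].to_numpy()
    for col in ("fisher_p", "delta_af", "g_stat"):
        df[col + "_sm"] = smooth_by_chromosome(df[col].to_numpy(), chroms, smoothing)
    return flag_ssnps(df, alpha)


def flag_ssnps(stats: pd.DataFrame, alpha_real: float) -> pd.DataFrame:
    """Flag sSNPs: smoothed exact-test P strictly below ``alpha_real``."""
    if not 0 < alpha_real < 1:
        raise ConfigurationError("alpha must lie strictly between 0 and 1")
    stats = stats.copy()
    stats["is_ssnp"] = stats["fisher_p_sm"].to_numpy() < alpha_real
    return stats
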