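"""Synthetic BSA-Seq data with known truth.

The generator emulates the canonical BSA-Seq design: an F2 population from
two inbred (fully homozygous, maximally divergent) parents, two phenotypic-
tail bulks, and shotgun sequencing of the pooled DNA.  Meiosis is modelled
with a Poisson crossover count per chromosome (uniform crossover positions,
no interference), so the marginal genotype ratio at every locus is 1:2:1 and
linkage decays with distance.  Phenotypes are a sum of QTL effects — each QTL
has an additive effect ``a`` and a dominance degree ``d`` (genotypic values
−a, d·a, +a for 0/1/2 copies of the ALT allele) — plus Gaussian noise.

Sequencing emits the same table dialect the pipeline consumes: per bulk, the
total depth at a SNP is Poisson around the design's mean coverage (zero
redrawn as one read) and the ALT read count is binomial at the bulk's true
allele frequency.  Realism knobs the with/without-parents comparison needs:

* REF/ALT orientation is random per SNP (a real reference genome agrees with
  either parent at random), which is exactly what breaks the unswapped ΔAF
  track;
* a configurable fraction of loci are heterozygous in one parent (htSNPs,
  segregating trait-independently) or missing from the parental data
  entirely (bsSNPs, with uniform(0,1) allele frequency), the two
  contamination classes a bulks-only analysis cannot fully remove.

Every emitted SNP carries a truth label so end-to-end recovery is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractViolation
from .variant_io import SampleCall, SnpRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Qtl:
    """One trait locus: position, additive effect and dominance degree.

    ``dominance`` 0 gives an incomplete-dominant (additive) locus, 1 a fully
    dominant one.
    """

    chrom: str
    pos: int
    effect: float = 1.0
    dominance: float = 0.0


@dataclass(frozen=True)
class SimDesign:
    """Study design for the generator.

    Defaults mirror a small-genome (rice-like) F2 study: 178 plants, tail
    bulks of 23, ~8x coverage per bulk, ~4 cM/Mb.  SNP density is kept at a
    desk-scale 100 SNPs/Mb; real shotgun datasets are denser but the density
    only rescales window SNP counts.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"Chr1": 30_000_000, "Chr2": 30_000_000}
    )
    snp_density: float = 100.0  # SNPs per Mb
    population: str = "F2"
    population_size: int = 178
    bulk_size: int = 23
    qtls: tuple[Qtl, ...] = ()
    noise_sd: float = 0.0
    mean_depth: float = 8.0
    recomb_cm_per_mb: float = 4.0
    parent_het_rate: float = 0.0
    bs_snp_rate: float = 0.0
    contamination_tract_snps: float = 30.0

    def __post_init__(self):
        if self.population != "F2":
            raise ConfigurationError("only F2 populations are implemented")
        if self.bulk_size > self.population_size // 2:
            raise ContractViolation("bulk_size must not exceed population_size / 2")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be positive")
        for rate in (self.parent_het_rate, self.bs_snp_rate):
            if not 0 <= rate <= 1:
                raise ContractViolation("rates must lie in [0, 1]")
        if self.contamination_tract_snps < 1:
            raise ContractViolation("contamination_tract_snps must be >= 1")
        if self.parent_het_rate + self.bs_snp_rate > 1:
            raise ContractViolation("parent_het_rate + bs_snp_rate must not exceed 1")
        for q in self.qtls:
            if q.chrom not in self.chrom_lengths:
                raise ConfigurationError(f"QTL on unknown chromosome {q.chrom!r}")
            if not np.isfinite(q.effect):
                raise ContractViolation("QTL effects must be finite")


@dataclass
class SimPopulation:
    """Genotypes (ALT-dosage 0/1/2) of every individual at every locus.

    ALT is, by convention, the allele of parent 2.  ``qtl_dosage`` holds the
    dosage at each QTL (columns follow ``design.qtls`` order).
    """

    design: SimDesign
    snp_positions: dict[str, np.ndarray]
    dosage: dict[str, np.ndarray]  # chrom -> (n_individuals, n_snps) int8
    qtl_dosage: np.ndarray  # (n_individuals, n_qtls) int8

    @property
    def n_individuals(self) -> int:
        return self.design.population_size


def _gametes(
    length: int,
    positions: np.ndarray,
    cm_per_mb: float,
    n_gametes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw recombinant F1 gametes; entry 1 = allele from parent 2."""
    morgans = length / 1e6 * cm_per_mb / 100.0
    out = np.empty((n_gametes, len(positions)), dtype=np.int8)
    n_xo = rng.poisson(morgans, size=n_gametes)
    phases = rng.integers(0, 2, size=n_gametes)
    for g in range(n_gametes):
        if n_xo[g] == 0:
            out[g] = phases[g]
        else:
            xo = np.sort(rng.uniform(0, length, n_xo[g]))
            out[g] = (phases[g] + np.searchsorted(xo, positions)) % 2
    return out


def simulate_population(design: SimDesign, rng: np.random.Generator) -> SimPopulation:
    """Simulate F2 genotypes at all SNP loci (and at the QTLs)."""
    n = design.population_size
    snp_positions: dict[str, np.ndarray] = {}
    dosage: dict[str, np.ndarray] = {}
    qtl_cols: dict[int, np.ndarray] = {}
    qtl_by_chrom: dict[str, list[int]] = {}
    for i, q in enumerate(design.qtls):
        qtl_by_chrom.setdefault(q.chrom, []).append(i)
    for chrom, length in design.chrom_lengths.items():
        n_snps = max(1, int(round(design.snp_density * length / 1e6)))
        pos = np.unique(rng.integers(1, length + 1, size=n_snps))
        snp_positions[chrom] = pos
        qidx = qtl_by_chrom.get(chrom, [])
        query = np.concatenate([pos, [design.qtls[i].pos for i in qidx]])
        gam = _gametes(length, query, design.recomb_cm_per_mb, 2 * n, rng)
        dos = (gam[0::2] + gam[1::2]).astype(np.int8)
        dosage[chrom] = dos[:, : len(pos)]
        for j, i in enumerate(qidx):
            qtl_cols[i] = dos[:, len(pos) + j]
    qtl_dosage = (
        np.stack([qtl_cols[i] for i in range(len(design.qtls))], axis=1)
        if design.qtls
        else np.zeros((n, 0), dtype=np.int8)
    )
    return SimPopulation(design, snp_positions, dosage, qtl_dosage)


def phenotypes(pop: SimPopulation, rng: np.random.Generator) -> np.ndarray:
    """Additive-plus-dominance phenotype with Gaussian noise."""
    design = pop.design
    phen = np.zeros(pop.n_individuals)
    for i, q in enumerate(design.qtls):
        g = pop.qtl_dosage[:, i].astype(float)
        phen += q.effect * (g - 1.0) + q.dominance * q.effect * (g == 1)
    if design.noise_sd > 0:
        phen = phen + rng.normal(0.0, design.noise_sd, size=pop.n_individuals)
    return phen


def select_bulks(
    pop: SimPopulation, rng: np.random.Generator, *, bulk_size: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Select the two phenotypic tails (bulk1 = high, bulk2 = low).

    Phenotype ties (e.g. a single dominant locus with zero noise) are broken
    uniformly at random so the selected subset is exchangeable within a
    phenotype class.
    """
    design = pop.design
    k = design.bulk_size if bulk_size is None else bulk_size
    n = pop.n_individuals
    if k > n // 2:
        raise ContractViolation("bulk size exceeds half the population")
    phen = phenotypes(pop, rng)
    order = rng.permutation(n)
    ranked = order[np.argsort(phen[order], kind="stable")]
    return ranked[-k:], ranked[:k]


_ORIGIN_STATES = np.array(["shared", "htSNP", "bsSNP"])


def _sample_origins(
    n: int, ht_rate: float, bs_rate: float, mean_tract: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-SNP origin labels in sticky tracts.

    Residual parental heterozygosity and regions unsequenced in the parents
    are block-like in real data, so contaminant classes are drawn from a
    Markov chain along the SNP index whose stationary distribution equals the
    configured rates and whose tracts have mean length ``mean_tract`` SNPs
    (1 = independent per-SNP draws).
    """
    probs = np.array([1.0 - ht_rate - bs_rate, ht_rate, bs_rate])
    draws = rng.choice(3, size=n, p=probs)
    if mean_tract <= 1:
        return _ORIGIN_STATES[draws]
    redraw = rng.random(n) < 1.0 / mean_tract
    states = np.empty(n, dtype=np.int8)
    states[0] = draws[0]
    for i in range(1, n):
        states[i] = draws[i] if redraw[i] else states[i - 1]
    return _ORIGIN_STATES[states]


def _bulk_freqs(pop: SimPopulation, idx: np.ndarray) -> dict[str, np.ndarray]:
    return {c: pop.dosage[c][idx].mean(axis=0) / 2.0 for c in pop.dosage}


def _call_genotype(ref: str, alt: str, ad: tuple[int, int]) -> tuple[str, str]:
    if ad[1] == 0:
        return (ref, ref)
    if ad[0] == 0:
        return (alt, alt)
    return (ref, alt)


def _read_depths(n: int, mean_depth: float, rng: np.random.Generator) -> np.ndarray:
    d = rng.poisson(mean_depth, size=n)
    d[d == 0] = 1
    return d


def sequence_bulks(
    pop: SimPopulation,
    bulks: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
    *,
    with_parents: bool = True,
) -> tuple[list[SnpRecord], pd.DataFrame]:
    """Emit SNP records (and a truth table) for the two bulks.

    When ``with_parents`` the parental calls are emitted too, including the
    injected htSNP loci (heterozygous in one parent) whereas bsSNP loci get
    no parental call at all.  The truth table records each SNP's origin
    class, its REF/ALT orientation and its true per-bulk emitted ALT
    frequencies.
    """
    design = pop.design
    b1, b2 = bulks
    freq1 = _bulk_freqs(pop, b1)
    freq2 = _bulk_freqs(pop, b2)
    records: list[SnpRecord] = []
    truth_rows = []
    gq = 40
    for chrom in pop.snp_positions:
        pos = pop.snp_positions[chrom]
        L = len(pos)
        f1 = freq1[chrom].copy()
        f2 = freq2[chrom].copy()
        origin = _sample_origins(
            L,
            design.parent_het_rate,
            design.bs_snp_rate,
            design.contamination_tract_snps,
            rng,
        )
        # htSNPs segregate trait-independently from the heterozygous parent
        ht = origin == "htSNP"
        het_parent = rng.integers(1, 3, size=L)  # which parent is heterozygous
        f_ht = np.where(het_parent == 2, 0.75, 0.25)
        f1[ht] = f_ht[ht]
        f2[ht] = f_ht[ht]
        # bsSNPs: artifacts / regions unsequenced in the parents
        bs = origin == "bsSNP"
        f_bs = rng.uniform(0, 1, size=L)
        f1[bs] = f_bs[bs]
        f2[bs] = f_bs[bs]
        # random reference-genome orientation: ori=1 means the emitted REF
        # allele is parent 2's allele
        ori = rng.integers(0, 2, size=L)
        e1 = np.where(ori == 1, 1.0 - f1, f1)
        e2 = np.where(ori == 1, 1.0 - f2, f2)
        d1 = _read_depths(L, design.mean_depth, rng)
        d2 = _read_depths(L, design.mean_depth, rng)
        alt1 = rng.binomial(d1, e1)
        alt2 = rng.binomial(d2, e2)
        ref_base = rng.integers(0, 4, size=L)
        alt_base = (ref_base + rng.integers(1, 4, size=L)) % 4
        dp1 = _read_depths(L, design.mean_depth, rng)
        dp2 = _read_depths(L, design.mean_depth, rng)
        ht_split = rng.binomial(dp1, 0.5)  # het parent's REF-read split
        for i in range(L):
            ref = str(_BASES[ref_base[i]])
            alt = str(_BASES[alt_base[i]])
            ad1 = (int(d1[i] - alt1[i]), int(alt1[i]))
            ad2 = (int(d2[i] - alt2[i]), int(alt2[i]))
            samples = {
                "bulk1": SampleCall(_call_genotype(ref, alt, ad1), ad1, gq),
                "bulk2": SampleCall(_call_genotype(ref, alt, ad2), ad2, gq),
            }
            if with_parents and origin[i] != "bsSNP":
                # parent 1 carries the REF allele when ori == 0
                p_ref_is = {1: ori[i] == 0, 2: ori[i] == 1}
                for pnum, role in ((1, "parent1"), (2, "parent2")):
                    depth = int(dp1[i]) if pnum == 1 else int(dp2[i])
                    if origin[i] == "htSNP" and het_parent[i] == pnum:
                        split = int(ht_split[i]) if pnum == 1 else int(
                            rng.binomial(depth, 0.5)
                        )
                        samples[role] = SampleCall((ref, alt), (split, depth - split), gq)
                    elif p_ref_is[pnum]:
                        samples[role] = SampleCall((ref, ref), (depth, 0), gq)
                    else:
                        samples[role] = SampleCall((alt, alt), (0, depth), gq)
            records.append(
                SnpRecord(
                    chrom=chrom,
                    pos=int(pos[i]),
                    ref_allele=ref,
                    alt_alleles=(alt,),
                    qual=1000.0,
                    samples=samples,
                )
            )
            truth_rows.append(
                (chrom, int(pos[i]), origin[i], int(ori[i]), float(e1[i]), float(e2[i]))
            )
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "origin", "ref_is_parent2", "freq1", "freq2"]
    )
    return records, truth


def simulate_dataset(
    design: SimDesign,
    seed: int | np.random.Generator | None = None,
    *,
    with_parents: bool = True,
) -> tuple[list[SnpRecord], pd.DataFrame]:
    """Population -> bulks -> sequenced SNP table, in one call."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = simulate_population(design, rng)
    bulks = select_bulks(pop, rng)
    return sequence_bulks(pop, bulks, rng, with_parents=with_parents)


def write_truth(truth: pd.DataFrame, qtls: Sequence[Qtl], path) -> None:
    """Write the truth table with the QTL list as commented header lines."""
    with open(path, "w") as fh:
        for q in qtls:
            fh.write(f"# QTL\t{q.chrom}\t{q.pos}\t{q.effect}\t{q.dominance}\n")
        truth.to_csv(fh, sep="\t", index=False)
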