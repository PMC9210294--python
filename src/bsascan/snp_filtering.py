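"""SNP hygiene filters, two-ALT normalization, parent intersection and AD/GT swapping.

Bulk-sequencing SNP sets called against a reference genome that is *not* one
of the cross parents contain two classes of junk: loci where both parents
(hence both bulks) are identically homozygous for a non-reference allele
(false positives for the cross), and loci heterozygous in a parent, which
violate the homozygous-parents assumption every downstream statistic relies
on.  The rules below remove those plus ordinary technical failures (missing
values, genotype/depth disagreements, low genotype quality, excessive depth).

Rule order is fixed; each removed record is attributed to the *first* rule it
fails, so the removal report is deterministic and conserves counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, ContractViolation, EstimationError
from .variant_io import BULK_ROLES, PARENT_ROLES, SampleCall, SnpRecord

DEFAULT_EXCLUDE_PATTERNS = ("Mt", "Pt", "chloroplast", "mitochond")

RULE_NAMES = (
    "excluded_chromosome",      # 1
    "missing_value",            # 2
    "alt_fixed_in_all",         # 3  zero REF reads, single ALT everywhere
    "three_plus_alt",           # 4
    "two_alt_with_ref_reads",   # 5
    "genotype_allele_mismatch", # 6
    "genotype_ad_mismatch",     # 7
    "low_gq",                   # 8
    "depth_above_cap",          # 9
    "heterozygous_parent",      # 10
)


@dataclass(frozen=True)
class FilterConfig:
    """Knobs for the hygiene filter.

    ``mean_coverage`` is the run-level average sequencing coverage (X-fold)
    used by the depth cap; when ``None`` it is estimated per bulk as the
    median pre-filter total depth.  ``exclude_chroms`` entries are matched as
    case-insensitive substrings of the chromosome name (organellar/unplaced
    contigs).
    """

    gq_min: int = 20
    depth_cap_multiplier: float = 6.0
    mean_coverage: float | None = None
    exclude_chroms: tuple[str, ...] = DEFAULT_EXCLUDE_PATTERNS

    def __post_init__(self):
        if self.gq_min < 0:
            raise ConfigurationError("gq_min must be >= 0")
        if self.depth_cap_multiplier <= 0:
            raise ConfigurationError("depth_cap_multiplier must be > 0")


@dataclass
class FilterReport:
    """Per-rule removal counts; removals + survivors always equal inputs."""

    input_count: int = 0
    output_count: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULE_NAMES})

    def as_text(self) -> str:
        lines = [f"input:{self.input_count}"]
        lines += [f"{rule}:{n}" for rule, n in self.removed.items()]
        lines.append(f"output:{self.output_count}")
        return "\n".join(lines)


def _is_excluded_chrom(chrom: str, patterns: Sequence[str]) -> bool:
    low = chrom.lower()
    return any(p.lower() in low for p in patterns)


def _two_alt_zero_ref(record: SnpRecord, roles: Sequence[str]) -> bool:
    """Eligibility for two-ALT normalization: 2 ALTs and zero REF reads in all
    mapped samples (missing depths make the record ineligible)."""
    if len(record.alt_alleles) != 2:
        return False
    for role in roles:
        call = record.samples.get(role)
        if call is None or call.allele_depths is None:
            return False
        if call.allele_depths[0] != 0:
            return False
    return True


def normalize_two_alt(record: SnpRecord, roles: Sequence[str] | None = None) -> SnpRecord:
    """Re-anchor a two-ALT, zero-REF-read record on its first ALT allele.

    The REF allele (unobserved in every sample) is replaced by the first ALT,
    the second ALT becomes the single ALT, and the leading REF count is
    dropped from every AD list.  Genotype strings are untouched (they already
    name the observed alleles).  Must run before genotype-agreement checks.
    """
    roles = list(roles) if roles is not None else list(record.samples)
    if not _two_alt_zero_ref(record, roles):
        raise ContractViolation(
            "normalize_two_alt requires exactly two ALT alleles and zero REF "
            "reads in every mapped sample"
        )
    samples = {}
    for role, call in record.samples.items():
        ad = call.allele_depths
        samples[role] = replace(call, allele_depths=ad[1:] if ad is not None else None)
    return replace(
        record,
        ref_allele=record.alt_alleles[0],
        alt_alleles=(record.alt_alleles[1],),
        samples=samples,
    )


def _genotype_matches_alleles(record: SnpRecord, roles: Sequence[str]) -> bool:
    valid = set(record.alleles)
    for role in roles:
        gt = record.samples[role].genotype
        if gt is not None and any(a not in valid for a in gt):
            return False
    return True


def _genotype_consistent_with_ad(record: SnpRecord, roles: Sequence[str]) -> bool:
    """Homozygous calls must have zero reads for every non-called allele;
    heterozygous calls must have reads for both called alleles."""
    alleles = record.alleles
    for role in roles:
        call = record.samples[role]
        gt, ad = call.genotype, call.allele_depths
        if gt is None or ad is None or len(ad) != len(alleles):
            continue  # handled by the NA / allele-count rules
        depth = {a: ad[i] for i, a in enumerate(alleles)}
        if gt[0] == gt[1]:
            if any(d > 0 for a, d in depth.items() if a != gt[0]):
                return False
        else:
            if depth.get(gt[0], 0) == 0 or depth.get(gt[1], 0) == 0:
                return False
    return True


def estimate_mean_coverage(records: Iterable[SnpRecord], role: str) -> float:
    """Median total read depth for ``role`` across pre-filter records."""
    totals = [
        sum(rec.samples[role].allele_depths)
        for rec in records
        if role in rec.samples and rec.samples[role].allele_depths is not None
    ]
    if not totals:
        raise EstimationError(f"no records with AD values for role {role!r}")
    return float(np.median(totals))


def _first_failed_rule(
    record: SnpRecord,
    cfg: FilterConfig,
    roles: Sequence[str],
    bulk_roles: Sequence[str],
    gq_roles: Sequence[str],
    depth_caps: dict[str, float],
    check_het_parents: bool,
) -> tuple[str | None, SnpRecord]:
    """Return (name of first failed rule or None, possibly normalized record)."""
    # 1. organellar / unplaced chromosomes
    if _is_excluded_chrom(record.chrom, cfg.exclude_chroms):
        return "excluded_chromosome", record
    # 2. missing value in any used field
    for role in roles:
        call = record.samples.get(role)
        if call is None or call.genotype is None or call.allele_depths is None or call.gq is None:
            return "missing_value", record
    # two-ALT normalization precedes the genotype-agreement rules
    if _two_alt_zero_ref(record, roles):
        record = normalize_two_alt(record, roles)
    # 3. fixed non-reference allele: zero REF reads, single ALT, all samples
    if len(record.alt_alleles) == 1 and all(
        record.samples[r].allele_depths[0] == 0 for r in roles
    ):
        return "alt_fixed_in_all", record
    # 4. three or more ALT alleles
    if len(record.alt_alleles) >= 3:
        return "three_plus_alt", record
    # 5. two ALT alleles with REF reads somewhere (normalization ineligible)
    if len(record.alt_alleles) == 2:
        return "two_alt_with_ref_reads", record
    # 6. genotypes disagree with REF/ALT bases
    if not _genotype_matches_alleles(record, roles):
        return "genotype_allele_mismatch", record
    # 7. genotypes inconsistent with AD values
    if not _genotype_consistent_with_ad(record, roles):
        return "genotype_ad_mismatch", record
    # 8. low genotype quality
    for role in gq_roles:
        if record.samples[role].gq < cfg.gq_min:
            return "low_gq", record
    # 9. total depth above the coverage cap (bulks only)
    for role in bulk_roles:
        cap = depth_caps[role]
        if sum(record.samples[role].allele_depths) > cap:
            return "depth_above_cap", record
    # 10. heterozygous parent
    if check_het_parents:
        for role in PARENT_ROLES:
            call = record.samples.get(role)
            if call is not None and call.is_het:
                return "heterozygous_parent", record
    return None, record


def filter_snps(
    records: Iterable[SnpRecord],
    cfg: FilterConfig,
    use_parents: bool = False,
    *,
    parent_table: bool = False,
) -> tuple[list[SnpRecord], FilterReport]:
    """Apply the hygiene rules in order; each removal attributed to its first rule.

    ``use_parents`` additionally filters on parental genotype quality and
    removes loci heterozygous in a parent.  ``parent_table=True`` marks a
    parents-only table (separate-file workflow): the bulk-specific rules (GQ,
    depth cap) are skipped — parental GQ is filtered only after intersection
    with the bulk set — but heterozygous parents are still removed.
    """
    records = list(records)
    report = FilterReport(input_count=len(records))
    if not records:
        return [], report

    present = set().union(*(set(r.samples) for r in records))
    if parent_table:
        roles = [r for r in PARENT_ROLES if r in present]
        bulk_roles: list[str] = []
        gq_roles: list[str] = []
        check_het = True
        if not roles:
            raise ConfigurationError("parent_table=True but no parent samples present")
    else:
        bulk_roles = [r for r in BULK_ROLES if r in present]
        roles = list(bulk_roles)
        if use_parents:
            parents = [r for r in PARENT_ROLES if r in present]
            if not parents:
                raise ConfigurationError("use_parents=True but no parent samples present")
            roles += parents
            gq_roles = bulk_roles + parents
        else:
            gq_roles = list(bulk_roles)
        check_het = use_parents

    depth_caps: dict[str, float] = {}
    for role in bulk_roles:
        cov = cfg.mean_coverage
        if cov is None:
            cov = estimate_mean_coverage(records, role)
        depth_caps[role] = cfg.depth_cap_multiplier * cov

    kept = []
    for rec in records:
        rule, rec = _first_failed_rule(
            rec, cfg, roles, bulk_roles, gq_roles, depth_caps, check_het
        )
        if rule is None:
            kept.append(rec)
        else:
            report.removed[rule] += 1
    report.output_count = len(kept)
    return kept, report


def intersect_with_parents(
    bulk_records: Iterable[SnpRecord],
    parent_records: Iterable[SnpRecord],
) -> list[SnpRecord]:
    """Keep bulk records whose (chrom, pos, allele set) matches a parent record.

    Matching parent calls are attached to the returned bulk records so the
    reference-parent swap (and the deferred parental GQ filter) can run on
    them.  Bulk-only positions (bsSNPs) are dropped.
    """
    parent_by_key = {rec.key: rec for rec in parent_records}
    out = []
    for rec in bulk_records:
        match = parent_by_key.get(rec.key)
        if match is None:
            continue
        samples = dict(rec.samples)
        for role in PARENT_ROLES:
            if role in match.samples:
                samples[role] = match.samples[role]
        out.append(rec.with_samples(samples))
    return out


def filter_parent_gq(
    records: Iterable[SnpRecord], cfg: FilterConfig
) -> tuple[list[SnpRecord], int]:
    """Deferred parental GQ floor (applied after intersection)."""
    kept, removed = [], 0
    for rec in records:
        ok = True
        for role in PARENT_ROLES:
            call = rec.samples.get(role)
            if call is not None and (call.gq is None or call.gq < cfg.gq_min):
                ok = False
                break
        if ok:
            kept.append(rec)
        else:
            removed += 1
    return kept, removed


def swap_ref_alt(record: SnpRecord, reference_parent_genotype: tuple[str, str]) -> SnpRecord:
    """Re-orient a biallelic record so the reference parent's allele is REF.

    When the reference parent carries the ALT allele, the REF/ALT labels, the
    genotype pair and the AD pair of *every* sample are reversed ("G/A" ->
    "A/G", "19,9" -> "9,19"); otherwise the record is returned unchanged.
    Swapping twice is the identity and total depth is never altered.
    """
    if len(record.alt_alleles) != 1:
        raise ContractViolation("swap_ref_alt requires a biallelic record")
    a, b = reference_parent_genotype
    if a != b:
        raise ContractViolation(
            "reference parent is heterozygous; such records must be filtered out"
        )
    if a == record.ref_allele:
        return record
    if a != record.alt_alleles[0]:
        raise ContractViolation(
            f"reference parent allele {a!r} matches neither REF nor ALT"
        )
    samples = {}
    for role, call in record.samples.items():
        gt = call.genotype
        ad = call.allele_depths
        samples[role] = replace(
            call,
            genotype=(gt[1], gt[0]) if gt is not None else None,
            allele_depths=ad[::-1] if ad is not None else None,
        )
    return replace(
        record,
        ref_allele=record.alt_alleles[0],
        alt_alleles=(record.ref_allele,),
        samples=samples,
    )


def swap_to_reference_parent(
    records: Iterable[SnpRecord], reference_parent: str = "parent1"
) -> list[SnpRecord]:
    """Apply :func:`swap_ref_alt` across a filtered, parent-annotated set."""
    out = []
    for rec in records:
        call = rec.samples.get(reference_parent)
        if call is None or call.genotype is None:
            raise ContractViolation(
                f"record {rec.chrom}:{rec.pos} lacks a genotype for {reference_parent}"
            )
        out.append(swap_ref_alt(rec, call.genotype))
    return out


def classify_parent_origin(
    bulk_records: Iterable[SnpRecord],
    parent_records: Iterable[SnpRecord],
) -> dict[str, list[SnpRecord]]:
    """Partition a bulks-only SNP set by its status in the parental data.

    ``shared``: position present in the parents with the same allele
    composition and homozygous in both parents; ``htSNP``: heterozygous in at
    least one parent at that position; ``bsSNP``: absent from the parental
    data (or present with an incompatible allele set).  The partition is
    exhaustive and disjoint.
    """
    by_pos: dict[tuple[str, int], SnpRecord] = {}
    for rec in parent_records:
        by_pos[(rec.chrom, rec.pos)] = rec
    out: dict[str, list[SnpRecord]] = {"shared": [], "htSNP": [], "bsSNP": []}
    for rec in bulk_records:
        match = by_pos.get((rec.chrom, rec.pos))
        if match is None:
            out["bsSNP"].append(rec)
            continue
        het = any(
            match.samples[r].is_het
            for r in PARENT_ROLES
            if r in match.samples and match.samples[r].is_het is not None
        )
        if het:
            out["htSNP"].append(rec)
        elif frozenset(match.alleles) == frozenset(rec.alleles):
            out["shared"].append(rec)
        else:
            out["bsSNP"].append(rec)
    return out
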