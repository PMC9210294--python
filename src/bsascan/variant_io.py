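"""Reading and writing SNP tables (VariantsToTable TSV dialect) and VCF.

The on-disk table is the tab-separated layout produced by GATK4
``VariantsToTable``: one variant per row with ``CHROM``, ``POS``, ``QUAL``,
``REF``, ``ALT`` columns plus per-sample ``GT``/``AD``/``GQ`` columns named
either ``<sample>.GT`` or ``<sample>_GT``.  Samples are bound to pipeline
roles (bulk1/bulk2 and optionally parent1/parent2) explicitly through a
:class:`SampleRoleMap`; nothing is ever inferred from column order.

Coordinates are 1-based as in VCF.  Missing values ("NA", ".", "./.") are
kept as missing, never silently zeroed, so the downstream NA filter can
count them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, ParseError

ROLES = ("bulk1", "bulk2", "parent1", "parent2")
BULK_ROLES = ("bulk1", "bulk2")
PARENT_ROLES = ("parent1", "parent2")

_MISSING_TOKENS = {"", "NA", ".", "./.", ".|."}


@dataclass(frozen=True)
class SampleCall:
    """One sample's call at one variant site.

    ``genotype`` is a pair of allele strings (e.g. ``("G", "A")``) or ``None``
    when missing.  ``allele_depths`` is the read count per allele in REF-first
    order (length = 1 + number of ALT alleles) or ``None``.  ``gq`` is the
    Phred-scaled genotype quality or ``None``.
    """

    genotype: tuple[str, str] | None = None
    allele_depths: tuple[int, ...] | None = None
    gq: int | None = None

    @property
    def is_het(self) -> bool | None:
        if self.genotype is None:
            return None
        return self.genotype[0] != self.genotype[1]


@dataclass(frozen=True)
class SnpRecord:
    """A single variant row: position, alleles, and per-role sample calls."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qual: float | None = None
    samples: dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.alt_alleles:
            raise ValueError("alt_alleles must be non-empty")
        if self.ref_allele in self.alt_alleles:
            raise ValueError("ref_allele must not appear among alt_alleles")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele,) + self.alt_alleles

    @property
    def key(self) -> tuple[str, int, frozenset[str]]:
        """Identity used for parent/bulk intersection: position + allele set."""
        return (self.chrom, self.pos, frozenset(self.alleles))

    def with_samples(self, samples: dict[str, SampleCall]) -> "SnpRecord":
        return replace(self, samples=dict(samples))


@dataclass(frozen=True)
class SampleRoleMap:
    """Binding of sample column names to pipeline roles.

    ``reference_parent`` names the parent role whose allele anchors the REF
    position during AD/GT swapping (e.g. the parent whose genome would have
    served as the reference).
    """

    bulk1: str
    bulk2: str
    parent1: str | None = None
    parent2: str | None = None
    reference_parent: str | None = None

    def __post_init__(self):
        if self.bulk1 == self.bulk2:
            raise ConfigurationError("bulk1 and bulk2 must name different samples")
        if self.reference_parent is not None:
            if self.reference_parent not in PARENT_ROLES:
                raise ConfigurationError(
                    "reference_parent must be 'parent1' or 'parent2', got "
                    f"{self.reference_parent!r}"
                )
            if getattr(self, self.reference_parent) is None:
                raise ConfigurationError(
                    f"reference_parent={self.reference_parent!r} but that parent "
                    "has no sample bound"
                )

    @property
    def mapped(self) -> dict[str, str]:
        """role -> sample name for all bound roles, in canonical order."""
        out = {}
        for role in ROLES:
            name = getattr(self, role)
            if name is not None:
                out[role] = name
        return out

    @property
    def has_parents(self) -> bool:
        return self.parent1 is not None or self.parent2 is not None


def _parse_gt(token: str) -> tuple[str, str] | None:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return None
    sep = "/" if "/" in token else ("|" if "|" in token else None)
    alleles = token.split(sep) if sep else [token, token]
    if len(alleles) != 2 or any(a in ("", ".") for a in alleles):
        return None
    return (alleles[0], alleles[1])


def _parse_ad(token: str, line_number: int) -> tuple[int, ...] | None:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return None
    try:
        return tuple(int(x) for x in token.split(","))
    except ValueError:
        raise ParseError(f"unparsable AD value {token!r}", line_number) from None


def _parse_gq(token: str, line_number: int) -> int | None:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return None
    try:
        return int(float(token))
    except ValueError:
        raise ParseError(f"unparsable GQ value {token!r}", line_number) from None


def _sample_columns(header: Sequence[str], sample: str) -> dict[str, str]:
    """Resolve GT/AD/GQ column names for ``sample``, accepting '.'/'_' dialects."""
    cols = {}
    for fld in ("GT", "AD", "GQ"):
        for cand in (f"{sample}.{fld}", f"{sample}_{fld}"):
            if cand in header:
                cols[fld] = cand
                break
        else:
            raise ConfigurationError(
                f"missing column for sample {sample!r}: expected "
                f"'{sample}.{fld}' or '{sample}_{fld}'"
            )
    return cols


def read_variants_table(path: str | Path, roles: SampleRoleMap) -> list[SnpRecord]:
    """Read a VariantsToTable-style TSV into records, in file order."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    header = list(df.columns)
    for col in ("CHROM", "POS", "REF", "ALT"):
        if col not in header:
            raise ConfigurationError(f"missing mandatory column {col!r} in {path}")
    colmap = {role: _sample_columns(header, name) for role, name in roles.mapped.items()}
    has_qual = "QUAL" in header

    records: list[SnpRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        row = dict(zip(header, row))
        try:
            pos = int(row["POS"])
        except ValueError:
            raise ParseError(f"unparsable POS value {row['POS']!r}", i) from None
        alt = tuple(a for a in row["ALT"].split(",") if a)
        qual = None
        if has_qual and row["QUAL"].strip() not in _MISSING_TOKENS:
            try:
                qual = float(row["QUAL"])
            except ValueError:
                raise ParseError(f"unparsable QUAL value {row['QUAL']!r}", i) from None
        samples = {}
        for role, cols in colmap.items():
            samples[role] = SampleCall(
                genotype=_parse_gt(row[cols["GT"]]),
                allele_depths=_parse_ad(row[cols["AD"]], i),
                gq=_parse_gq(row[cols["GQ"]], i),
            )
        records.append(
            SnpRecord(
                chrom=row["CHROM"],
                pos=pos,
                ref_allele=row["REF"],
                alt_alleles=alt,
                qual=qual,
                samples=samples,
            )
        )
    return records


def read_vcf(path: str | Path, roles: SampleRoleMap) -> list[SnpRecord]:
    """Read a VCF with GT/AD/GQ FORMAT fields; same record semantics as the TSV."""
    import pysam

    mapped = roles.mapped
    if not mapped:
        raise ConfigurationError("no samples mapped to roles")
    with pysam.VariantFile(str(path)) as vcf:
        for fld in ("GT", "AD", "GQ"):
            if fld not in vcf.header.formats:
                raise ConfigurationError(f"VCF {path} lacks FORMAT field {fld!r}")
        vcf_samples = set(vcf.header.samples)
        for role, name in mapped.items():
            if name not in vcf_samples:
                raise ConfigurationError(
                    f"sample {name!r} (role {role}) not present in VCF {path}"
                )
        records = []
        for var in vcf:
            alts = tuple(var.alts or ())
            if not alts:
                continue
            alleles = (var.ref,) + alts
            samples = {}
            for role, name in mapped.items():
                call = var.samples[name]
                gt_idx = call.get("GT")
                genotype = None
                if gt_idx is not None and len(gt_idx) == 2 and None not in gt_idx:
                    genotype = (alleles[gt_idx[0]], alleles[gt_idx[1]])
                ad = call.get("AD")
                allele_depths = None
                if ad is not None and not all(a is None for a in ad):
                    allele_depths = tuple(int(a) if a is not None else 0 for a in ad)
                gq = call.get("GQ")
                samples[role] = SampleCall(
                    genotype=genotype,
                    allele_depths=allele_depths,
                    gq=int(gq) if gq is not None else None,
                )
            records.append(
                SnpRecord(
                    chrom=var.chrom,
                    pos=var.pos,
                    ref_allele=var.ref,
                    alt_alleles=alts,
                    qual=float(var.qual) if var.qual is not None else None,
                    samples=samples,
                )
            )
    return records


def _format_call(call: SampleCall) -> tuple[str, str, str]:
    gt = "/".join(call.genotype) if call.genotype is not None else "NA"
    ad = ",".join(str(d) for d in call.allele_depths) if call.allele_depths is not None else "NA"
    gq = str(call.gq) if call.gq is not None else "NA"
    return gt, ad, gq


def write_snp_table(records, path: str | Path) -> None:
    """Write records (or a statistics DataFrame) as a VariantsToTable-style TSV.

    A round trip through :func:`read_variants_table` (binding each role to a
    column of its own name) reproduces the records field-for-field.
    """
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, sep="\t", index=False)
        return
    records = list(records)
    present_roles = [r for r in ROLES if any(r in rec.samples for rec in records)]
    if not records:
        present_roles = list(BULK_ROLES)
    cols = ["CHROM", "POS", "QUAL", "REF", "ALT"]
    for role in present_roles:
        cols += [f"{role}.GT", f"{role}.AD", f"{role}.GQ"]
    rows = []
    for rec in records:
        row = {
            "CHROM": rec.chrom,
            "POS": rec.pos,
            "QUAL": rec.qual if rec.qual is not None else "NA",
            "REF": rec.ref_allele,
            "ALT": ",".join(rec.alt_alleles),
        }
        for role in present_roles:
            gt, ad, gq = _format_call(rec.samples.get(role, SampleCall()))
            row[f"{role}.GT"] = gt
            row[f"{role}.AD"] = ad
            row[f"{role}.GQ"] = gq
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def roles_for_roundtrip(records: Iterable[SnpRecord]) -> SampleRoleMap:
    """RoleMap binding each role present in ``records`` to a column of its name."""
    records = list(records)
    present = {r for rec in records for r in rec.samples}
    return SampleRoleMap(
        bulk1="bulk1",
        bulk2="bulk2",
        parent1="parent1" if "parent1" in present else None,
        parent2="parent2" if "parent2" in present else None,
    )
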