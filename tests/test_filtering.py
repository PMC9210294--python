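"""Hygiene rules, two-ALT normalization, intersection, swapping, origin classes."""

import pytest
from hypothesis import given, strategies as st

from bsascan import (
    FilterConfig,
    classify_parent_origin,
    estimate_mean_coverage,
    filter_snps,
    intersect_with_parents,
    normalize_two_alt,
    swap_ref_alt,
)
from bsascan.errors import ContractViolation, EstimationError
from bsascan.snp_filtering import filter_parent_gq, swap_to_reference_parent

from conftest import make_record

CFG = FilterConfig(mean_coverage=8.0)  # depth cap = 48


def good_record(**kw):
    return make_record(
        bulk1=kw.pop("bulk1", ((19, 9), ("G", "A"), 40)),
        bulk2=kw.pop("bulk2", ((9, 19), ("G", "A"), 40)),
        **kw,
    )


class TestNormalizeTwoAlt:
    def test_reanchors_on_first_alt(self):
        rec = make_record(
            ref="A",
            alts=("T", "G"),
            bulk1=((0, 12, 8), ("T", "G"), 40),
            bulk2=((0, 7, 9), ("T", "G"), 40),
        )
        out = normalize_two_alt(rec)
        assert out.ref_allele == "T" and out.alt_alleles == ("G",)
        assert out.samples["bulk1"].allele_depths == (12, 8)
        assert out.samples["bulk2"].allele_depths == (7, 9)
        # genotype strings untouched: they already span the new REF/ALT
        assert out.samples["bulk1"].genotype == ("T", "G")

    def test_nonzero_ref_reads_violate_precondition(self):
        rec = make_record(
            ref="A", alts=("T", "G"),
            bulk1=((3, 12, 8), ("T", "G"), 40), bulk2=((0, 7, 9), ("T", "G"), 40),
        )
        with pytest.raises(ContractViolation):
            normalize_two_alt(rec)


class TestFilterRules:
    @pytest.mark.parametrize(
        "record,rule",
        [
            (good_record(chrom="ChrMt"), "excluded_chromosome"),
            (good_record(bulk1=(None, ("G", "A"), 40)), "missing_value"),
            (
                make_record(ref="A", bulk1=((0, 20), ("G", "G"), 40), bulk2=((0, 18), ("G", "G"), 40), alts=("G",)),
                "alt_fixed_in_all",
            ),
            (
                make_record(ref="A", alts=("T", "G", "C"),
                            bulk1=((2, 4, 4, 4), ("T", "G"), 40), bulk2=((2, 4, 4, 4), ("T", "G"), 40)),
                "three_plus_alt",
            ),
            (
                make_record(ref="A", alts=("T", "G"),
                            bulk1=((3, 12, 8), ("T", "G"), 40), bulk2=((0, 7, 9), ("T", "G"), 40)),
                "two_alt_with_ref_reads",
            ),
            (good_record(bulk1=((19, 9), ("T", "A"), 40)), "genotype_allele_mismatch"),
            (good_record(bulk1=((19, 9), ("G", "G"), 40)), "genotype_ad_mismatch"),
            (good_record(bulk1=((19, 0), ("G", "A"), 40)), "genotype_ad_mismatch"),
            (good_record(bulk1=((19, 9), ("G", "A"), 19)), "low_gq"),
            (good_record(bulk2=((30, 30), ("G", "A"), 40)), "depth_above_cap"),
        ],
    )
    def test_record_attributed_to_first_failed_rule(self, record, rule):
        kept, report = filter_snps([record], CFG)
        assert kept == []
        assert report.removed[rule] == 1
        assert sum(report.removed.values()) == 1

    def test_clean_biallelic_record_retained(self):
        kept, report = filter_snps([good_record()], CFG)
        assert len(kept) == 1 and report.output_count == 1

    def test_two_alt_zero_ref_normalized_then_kept(self):
        rec = make_record(
            ref="A", alts=("T", "G"),
            bulk1=((0, 12, 8), ("T", "G"), 40), bulk2=((0, 7, 9), ("T", "G"), 40),
        )
        kept, _ = filter_snps([rec], CFG)
        assert len(kept) == 1
        assert kept[0].ref_allele == "T" and kept[0].alt_alleles == ("G",)

    def test_heterozygous_parent_removed_only_with_parents(self):
        rec = good_record(
            parent1=((5, 4), ("G", "A"), 40), parent2=((0, 9), ("A", "A"), 40)
        )
        kept, _ = filter_snps([rec], CFG, use_parents=False)
        assert len(kept) == 1
        kept, report = filter_snps([rec], CFG, use_parents=True)
        assert kept == [] and report.removed["heterozygous_parent"] == 1

    def test_conservation_and_idempotence(self):
        batch = [
            good_record(pos=p) for p in range(1, 30)
        ] + [
            good_record(pos=100, bulk1=((19, 9), ("G", "A"), 10)),
            good_record(pos=101, chrom="ChrPt"),
            good_record(pos=102, bulk2=(None, None, None)),
        ]
        kept, report = filter_snps(batch, CFG)
        assert report.input_count == len(batch)
        assert report.output_count + sum(report.removed.values()) == report.input_count
        kept2, report2 = filter_snps(kept, CFG)
        assert kept2 == kept and sum(report2.removed.values()) == 0


class TestMeanCoverage:
    def test_median_of_totals(self):
        recs = [good_record(pos=p, bulk1=((d, d), ("G", "A"), 40)) for p, d in ((1, 4), (2, 4), (3, 4))]
        assert estimate_mean_coverage(recs, "bulk1") == 8.0

    def test_median_robust_to_outliers(self):
        depths = [(1, 1), (4, 4), (50, 50)]
        recs = [good_record(pos=p, bulk1=((a, b), ("G", "A"), 40)) for p, (a, b) in enumerate(depths, 1)]
        assert estimate_mean_coverage(recs, "bulk1") == 8.0

    def test_empty_errors(self):
        with pytest.raises(EstimationError):
            estimate_mean_coverage([], "bulk1")


class TestIntersection:
    def parent(self, pos=100, ref="G", alts=("A",), gt1=("G", "G"), gt2=("A", "A")):
        return make_record(
            pos=pos, ref=ref, alts=alts, bulk1=None, bulk2=None,
            parent1=((8, 0), gt1, 40), parent2=((0, 7), gt2, 40),
        )

    def test_matching_key_kept_with_parent_calls_attached(self):
        out = intersect_with_parents([good_record()], [self.parent()])
        assert len(out) == 1
        assert out[0].samples["parent1"].genotype == ("G", "G")

    def test_same_position_different_alt_dropped(self):
        out = intersect_with_parents([good_record()], [self.parent(alts=("T",))])
        assert out == []

    def test_bulk_only_position_dropped(self):
        assert intersect_with_parents([good_record()], []) == []

    def test_parent_gq_filtered_after_intersection(self):
        par = make_record(
            bulk1=None, bulk2=None,
            parent1=((8, 0), ("G", "G"), 12), parent2=((0, 7), ("A", "A"), 40),
        )
        merged = intersect_with_parents([good_record()], [par])
        assert len(merged) == 1  # intersection keeps it...
        kept, removed = filter_parent_gq(merged, CFG)
        assert kept == [] and removed == 1  # ...the deferred GQ floor removes it


class TestSwap:
    def test_reference_parent_alt_swaps_both_bulks(self):
        rec = good_record(parent1=((0, 8), ("A", "A"), 40))
        out = swap_ref_alt(rec, ("A", "A"))
        assert out.ref_allele == "A" and out.alt_alleles == ("G",)
        assert out.samples["bulk1"].allele_depths == (9, 19)
        assert out.samples["bulk2"].allele_depths == (19, 9)
        assert out.samples["bulk1"].genotype == ("A", "G")

    def test_reference_parent_ref_is_identity(self):
        rec = good_record()
        assert swap_ref_alt(rec, ("G", "G")) is rec

    def test_double_swap_restores_original(self):
        rec = good_record()
        once = swap_ref_alt(rec, ("A", "A"))
        again = swap_ref_alt(once, ("G", "G"))  # anchor back on the old REF
        assert again == rec

    def test_heterozygous_reference_parent_rejected(self):
        with pytest.raises(ContractViolation):
            swap_ref_alt(good_record(), ("G", "A"))

    @given(
        ad1=st.tuples(st.integers(0, 40), st.integers(0, 40)),
        ad2=st.tuples(st.integers(0, 40), st.integers(0, 40)),
        parent_has_alt=st.booleans(),
    )
    def test_swap_preserves_total_depth_and_anchors_ref(self, ad1, ad2, parent_has_alt):
        rec = make_record(bulk1=(ad1, ("G", "A"), 40), bulk2=(ad2, ("G", "A"), 40))
        gt = ("A", "A") if parent_has_alt else ("G", "G")
        out = swap_ref_alt(rec, gt)
        assert out.ref_allele == gt[0]
        for role in ("bulk1", "bulk2"):
            assert sum(out.samples[role].allele_depths) == sum(rec.samples[role].allele_depths)

    def test_swap_to_reference_parent_across_set(self):
        recs = [
            good_record(pos=1, parent1=((7, 0), ("G", "G"), 40)),
            good_record(pos=2, parent1=((0, 7), ("A", "A"), 40)),
        ]
        out = swap_to_reference_parent(recs, "parent1")
        assert [r.ref_allele for r in out] == ["G", "A"]
        assert all(r.ref_allele == r.samples["parent1"].genotype[0] for r in out)


class TestClassifyParentOrigin:
    def test_partition_exhaustive_and_disjoint(self):
        bulk = [good_record(pos=p) for p in (1, 2, 3)]
        parents = [
            make_record(pos=1, bulk1=None, bulk2=None,
                        parent1=((8, 0), ("G", "G"), 40), parent2=((0, 7), ("A", "A"), 40)),
            make_record(pos=2, bulk1=None, bulk2=None,
                        parent1=((8, 0), ("G", "G"), 40), parent2=((4, 4), ("G", "A"), 40)),
        ]
        part = classify_parent_origin(bulk, parents)
        assert sum(len(v) for v in part.values()) == len(bulk)
        assert [r.pos for r in part["shared"]] == [1]
        assert [r.pos for r in part["htSNP"]] == [2]  # heterozygous in parent 2
        assert [r.pos for r in part["bsSNP"]] == [3]  # absent from the parents
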