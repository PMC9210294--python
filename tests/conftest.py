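import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from bsascan import SampleCall, SampleRoleMap, SnpRecord


@pytest.fixture
def bulk_roles() -> SampleRoleMap:
    return SampleRoleMap(bulk1="bulk1", bulk2="bulk2")


@pytest.fixture
def full_roles() -> SampleRoleMap:
    return SampleRoleMap(
        bulk1="bulk1",
        bulk2="bulk2",
        parent1="parent1",
        parent2="parent2",
        reference_parent="parent1",
    )


def make_record(
    chrom="Chr1",
    pos=100,
    ref="G",
    alts=("A",),
    qual=500.0,
    bulk1=((19, 9), ("G", "A"), 40),
    bulk2=((9, 19), ("G", "A"), 40),
    parent1=None,
    parent2=None,
) -> SnpRecord:
    """Small-fixture helper: each sample spec is (AD, GT, GQ) or None."""
    samples = {}
    for role, spec in (
        ("bulk1", bulk1),
        ("bulk2", bulk2),
        ("parent1", parent1),
        ("parent2", parent2),
    ):
        if spec is None:
            continue
        ad, gt, gq = spec
        samples[role] = SampleCall(
            genotype=tuple(gt) if gt is not None else None,
            allele_depths=tuple(ad) if ad is not None else None,
            gq=gq,
        )
    return SnpRecord(
        chrom=chrom, pos=pos, ref_allele=ref, alt_alleles=tuple(alts), qual=qual, samples=samples
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
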