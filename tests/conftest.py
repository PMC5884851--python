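import pytest
from hypothesis import HealthCheck, settings

from numtscan.alignio import AlignedRecord, AlignedSeqSet
from numtscan.codon import FrameSpec, GeneticCode

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def code5() -> GeneticCode:
    return GeneticCode.from_ncbi_id(5)


@pytest.fixture(scope="session")
def code1() -> GeneticCode:
    return GeneticCode.from_ncbi_id(1)


@pytest.fixture()
def frame0():
    def make(length: int) -> FrameSpec:
        return FrameSpec.for_length(length, offset=0)

    return make


def make_alignment(seqs, sites=None, ids=None) -> AlignedSeqSet:
    """Small helper used across test modules."""
    n = len(seqs)
    ids = ids or [f"s{i + 1}" for i in range(n)]
    sites = sites or [None] * n
    return AlignedSeqSet(
        records=tuple(
            AlignedRecord(id=i, seq=s, site_label=lab)
            for i, s, lab in zip(ids, seqs, sites)
        )
    )
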