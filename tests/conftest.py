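import pytest

from mtexpand.hapio import HaplotypeTable, expand_table, haplotype_alignment
from mtexpand.tables import (
    CR_LENGTH,
    EUROPE_LOCALITIES,
    INDIA_LOCALITIES,
    jackal_cr_table,
    jackal_cytb_table,
)

ISRAEL_EUROPE = frozenset({"Israel"}) | EUROPE_LOCALITIES


@pytest.fixture(scope="session")
def cr_table() -> HaplotypeTable:
    return jackal_cr_table()


@pytest.fixture(scope="session")
def cytb_table() -> HaplotypeTable:
    return jackal_cytb_table()


@pytest.fixture(scope="session")
def india_aln(cr_table):
    """Per-individual Indian control-region alignment (printed counts, n=52)."""
    return expand_table(cr_table, set(INDIA_LOCALITIES), length=CR_LENGTH)


@pytest.fixture(scope="session")
def india_hap_aln(cr_table):
    """One row per distinct Indian CR haplotype (16 rows)."""
    return haplotype_alignment(cr_table, set(INDIA_LOCALITIES), length=CR_LENGTH)


@pytest.fixture(scope="session")
def israel_europe_aln(cr_table):
    """Pooled Israel + Europe individuals (n = 249, two haplotypes)."""
    return expand_table(cr_table, set(ISRAEL_EUROPE), length=CR_LENGTH)


def make_table(states, counts=None, localities=("x",), ids=None, sites=None):
    """Small ad-hoc haplotype table for unit tests."""
    n = len(states)
    width = len(states[0]) if states else 0
    return HaplotypeTable(
        haplotype_ids=tuple(ids or (f"h{i}" for i in range(n))),
        sites=tuple(sites or range(1, width + 1)),
        states=tuple(states),
        localities=tuple(localities),
        counts=tuple(counts or ((1,) * len(localities) for _ in range(n))),
    )
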