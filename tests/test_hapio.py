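"""Alignment / haplotype-table containers, conversions and I/O."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

from mtexpand.hapio import (
    Alignment,
    AlignmentError,
    classify_sites,
    collapse_haplotypes,
    expand_table,
    haplotype_alignment,
    read_alignment,
    read_haplotype_table,
    write_haplotype_table,
)
from mtexpand.tables import INDIA_LOCALITIES

from conftest import ISRAEL_EUROPE, make_table


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


class TestReadAlignment:
    def test_identical_records_have_no_variable_sites(self, tmp_path):
        p = write_fasta(tmp_path / "a.fa", [("s1", "ACGTACGTAA"), ("s2", "ACGTACGTAA")])
        aln = read_alignment(p)
        assert aln.n == 2 and aln.length == 10
        assert not classify_sites(aln).substitution_variable

    def test_ambiguity_codes_become_missing(self, tmp_path, caplog):
        p = write_fasta(tmp_path / "a.fa", [("s1", "ACGN"), ("s2", "ACGT")])
        with caplog.at_level(logging.WARNING):
            aln = read_alignment(p)
        assert aln.matrix[0] == "ACG?"
        assert any("ambiguity" in r.message for r in caplog.records)

    def test_ragged_alignment_names_offender(self, tmp_path):
        p = write_fasta(tmp_path / "a.fa", [("ok", "ACGT"), ("bad", "ACG")])
        with pytest.raises(AlignmentError, match="bad"):
            read_alignment(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.raises(AlignmentError):
            read_alignment(p)

    def test_sample_order_follows_file(self, tmp_path):
        p = write_fasta(tmp_path / "a.fa", [("z", "AA"), ("a", "AA"), ("m", "AT")])
        assert read_alignment(p).sample_ids == ("z", "a", "m")


class TestCollapse:
    def test_cr_fixture_haplotype_accounting(self, cr_table):
        aln = expand_table(cr_table, length=440)
        tbl = collapse_haplotypes(aln)
        assert tbl.n_haplotypes == 18
        indian = [
            i
            for i in range(tbl.n_haplotypes)
            if any(
                tbl.counts[i][j] > 0
                for j, l in enumerate(tbl.localities)
                if l in INDIA_LOCALITIES
            )
        ]
        assert len(indian) == 16

    def test_cytb_fixture_haplotype_accounting(self, cytb_table):
        aln = expand_table(cytb_table, length=412)
        assert aln.n == 40
        assert collapse_haplotypes(aln).n_haplotypes == 9

    def test_identical_sequences_collapse_to_one(self):
        aln = expand_table(make_table(["ACGT"], counts=[(7,)]))
        tbl = collapse_haplotypes(aln)
        assert tbl.n_haplotypes == 1 and tbl.total_counts == (7,)

    def test_ignore_missing_merges_compatible_rows(self):
        aln = Alignment(
            sample_ids=("a", "b", "c"),
            localities=("x", "x", "x"),
            sites=(1, 2, 3),
            matrix=("AC?", "ACG", "ACT"),
        )
        strict = collapse_haplotypes(aln, "strict")
        merged = collapse_haplotypes(aln, "ignore_missing")
        assert strict.n_haplotypes == 3
        assert merged.n_haplotypes == 2
        # representative resolves '?' from the member that merged into it
        assert "ACG" in merged.states

    def test_counts_conserved(self, cr_table):
        aln = expand_table(cr_table, length=440)
        assert sum(collapse_haplotypes(aln).total_counts) == aln.n


class TestExpand:
    def test_india_filter_row_count(self, cr_table):
        assert expand_table(cr_table, set(INDIA_LOCALITIES)).n == 52

    def test_israel_europe_filter_row_count(self, cr_table):
        assert expand_table(cr_table, set(ISRAEL_EUROPE)).n == 249

    def test_single_haplotype_single_row(self):
        assert expand_table(make_table(["ACGT"])).n == 1

    def test_unknown_locality_errors(self, cr_table):
        with pytest.raises(AlignmentError, match="Atlantis"):
            expand_table(cr_table, {"Atlantis"})

    def test_haplotype_alignment_is_unweighted(self, cr_table):
        hap = haplotype_alignment(cr_table, set(INDIA_LOCALITIES))
        assert hap.n == 16
        assert len(set(hap.matrix)) == 16


@st.composite
def haplotype_tables(draw):
    n_sites = draw(st.integers(1, 6))
    n_loc = draw(st.integers(1, 3))
    states = draw(
        st.lists(
            st.text(alphabet="ACGT-", min_size=n_sites, max_size=n_sites),
            min_size=1,
            max_size=6,
            unique=True,
        )
    )
    counts = [
        tuple(draw(st.integers(0, 4)) for _ in range(n_loc)) for _ in states
    ]
    counts = [c if sum(c) else (1,) + c[1:] for c in counts]
    return make_table(states, counts=counts, localities=[f"L{i}" for i in range(n_loc)])


class TestRoundTrips:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(haplotype_tables())
    def test_collapse_of_expand_is_identity(self, tbl):
        back = collapse_haplotypes(expand_table(tbl))
        # identity up to haplotype naming and locality-column order
        def key(t):
            return sorted(
                (t.states[i], tuple(sorted(zip(t.localities, t.counts[i]))))
                for i in range(t.n_haplotypes)
            )

        def nonzero(k):
            return [(s, tuple((l, c) for l, c in loc if c)) for s, loc in k]

        assert nonzero(key(back)) == nonzero(key(tbl))

    def test_tsv_round_trip(self, cr_table, tmp_path):
        p = tmp_path / "t.tsv"
        write_haplotype_table(cr_table, p)
        assert read_haplotype_table(p) == cr_table

    def test_duplicate_id_errors_with_name(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "haplotype_id\tsite:1\tcount:x\nH1\tA\t1\nH1\tC\t2\n", encoding="utf-8"
        )
        with pytest.raises(AlignmentError, match="H1"):
            read_haplotype_table(p)

    def test_non_integer_count_errors_with_line(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("haplotype_id\tsite:1\tcount:x\nH1\tA\t\n", encoding="utf-8")
        with pytest.raises(AlignmentError, match=":2"):
            read_haplotype_table(p)

    def test_missing_count_columns_errors(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("haplotype_id\tsite:1\nH1\tA\n", encoding="utf-8")
        with pytest.raises(AlignmentError, match="count"):
            read_haplotype_table(p)


class TestClassifySites:
    def test_cr_fixture_indel_columns(self, cr_table):
        aln = expand_table(cr_table, length=440)
        cls = classify_sites(aln)
        assert sorted(cls.indel_containing) == [15465, 15466, 15518, 15528, 15529]

    def test_cr_fixture_substitution_columns_after_indel_removal(self, cr_table):
        aln = expand_table(cr_table, length=440)
        cls = classify_sites(aln)
        assert len(cls.substitution_variable - cls.indel_containing) == 22

    def test_monomorphic_all_invariant(self):
        aln = expand_table(make_table(["ACGT"], counts=[(4,)]))
        cls = classify_sites(aln)
        assert cls.invariant == frozenset(aln.sites)

    def test_missing_alone_never_variable(self):
        aln = Alignment(
            sample_ids=("a", "b"),
            localities=("x", "x"),
            sites=(1,),
            matrix=("A", "?"),
        )
        assert not classify_sites(aln).substitution_variable

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(haplotype_tables(), st.randoms(use_true_random=False))
    def test_invariant_under_row_permutation(self, tbl, rnd):
        aln = expand_table(tbl)
        order = list(range(aln.n))
        rnd.shuffle(order)
        assert classify_sites(aln) == classify_sites(aln.subset(order))
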