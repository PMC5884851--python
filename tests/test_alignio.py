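"""Alignment reading, trimming, haplotype collapsing and the prevalence test."""

import random
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from numtscan.alignio import (
    AlignedRecord,
    AlignedSeqSet,
    Haplotype,
    collapse_haplotypes,
    prevalence_test,
    read_alignment,
    trim_alignment,
    write_alignment,
)
from numtscan.errors import AlignmentError, DegenerateTableError, InputError

from conftest import make_alignment


class TestReadWrite:
    def test_parse_and_roundtrip(self, tmp_path):
        path = tmp_path / "aln.fasta"
        path.write_text(">a|site1\nacgtacgt\n>b|site2\nACGTACGA\n>c\nACGTACGT\n")
        aln = read_alignment(path)
        assert len(aln) == 3 and aln.length == 8
        assert aln.get("a").seq == "ACGTACGT"  # uppercased
        assert aln.get("a").site_label == "site1"
        assert aln.get("c").site_label is None
        out = tmp_path / "roundtrip.fasta"
        write_alignment(aln, out)
        again = read_alignment(out)
        assert again.records == aln.records

    def test_unequal_lengths_is_alignment_error(self, tmp_path):
        path = tmp_path / "ragged.fasta"
        path.write_text(">a\n" + "A" * 275 + "\n>b\n" + "A" * 274 + "\n")
        with pytest.raises(AlignmentError, match="b"):
            read_alignment(path)

    def test_empty_file_is_input_error(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(InputError):
            read_alignment(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentError, match="duplicate"):
            make_alignment(["ACGT", "ACGT"], ids=["x", "x"])


class TestTrim:
    def test_flush_alignment_unchanged(self):
        aln = make_alignment(["ACGTAC", "ACGTAA"])
        assert trim_alignment(aln) is aln

    def test_leading_gaps_dropped(self):
        aln = make_alignment(["--GTAC", "ACGTAA"])
        trimmed = trim_alignment(aln)
        assert trimmed.length == 4
        assert [r.seq for r in trimmed.records] == ["GTAC", "GTAA"]

    def test_trailing_n_dropped(self):
        aln = make_alignment(["ACGTNN", "ACGTAA"])
        assert trim_alignment(aln).length == 4

    def test_interior_gaps_untouched(self):
        aln = make_alignment(["AC-TAC", "ACGTAA"])
        assert trim_alignment(aln).length == 6

    def test_all_columns_removed_raises(self):
        aln = make_alignment(["A-", "-A"])
        with pytest.raises(AlignmentError):
            trim_alignment(aln)

    def test_matches_bruteforce_column_scan_and_is_idempotent(self):
        rng = random.Random(42)
        for _ in range(50):
            ncol, nrow = rng.randint(3, 30), rng.randint(2, 5)
            cols = []
            for _c in range(ncol):
                cols.append(
                    [rng.choice("ACGT" if rng.random() < 0.7 else "-N") for _ in range(nrow)]
                )
            seqs = ["".join(cols[c][r] for c in range(ncol)) for r in range(nrow)]
            aln = make_alignment(seqs)
            clean = [all(ch not in "-N" for ch in col) for col in cols]
            # brute force: first/last clean-run boundaries scanned from both ends
            try:
                start = next(i for i, ok in enumerate(clean) if ok)
                end = ncol - next(i for i, ok in enumerate(reversed(clean)) if ok)
            except StopIteration:
                with pytest.raises(AlignmentError):
                    trim_alignment(aln)
                continue
            trimmed = trim_alignment(aln)
            assert [r.seq for r in trimmed.records] == [s[start:end] for s in seqs]
            assert trim_alignment(trimmed).records == trimmed.records  # idempotent


class TestCollapse:
    def test_population_sample_18_vs_6_over_three_sites(self):
        x = "ACGTACGTACGT"
        y = "ACGTACGTACGA"
        seqs, sites = [], []
        for site in ("site1", "site2", "site3"):
            seqs += [x] * 6 + [y] * 2
            sites += [site] * 8
        aln = make_alignment(seqs, sites=sites)
        haps = collapse_haplotypes(aln)
        assert [h.hap_id for h in haps] == ["H1", "H2"]
        assert [h.total_count for h in haps] == [18, 6]
        assert haps[0].counts_by_site == {"site1": 6, "site2": 6, "site3": 6}
        assert haps[1].counts_by_site == {"site1": 2, "site2": 2, "site3": 2}
        assert sum(h.total_count for h in haps) == len(aln)

    def test_all_identical_is_one_haplotype(self):
        aln = make_alignment(["ACGT"] * 5)
        haps = collapse_haplotypes(aln)
        assert len(haps) == 1 and haps[0].total_count == 5
        assert haps[0].members == ("s1", "s2", "s3", "s4", "s5")

    def test_n_is_an_ordinary_mismatch_by_default(self):
        aln = make_alignment(["ACGT", "ACGN"])
        assert len(collapse_haplotypes(aln)) == 2
        assert len(collapse_haplotypes(aln, n_matches_any=True)) == 1

    @given(
        st.lists(
            st.text(alphabet="AC", min_size=3, max_size=3), min_size=1, max_size=30
        )
    )
    def test_counts_match_multiset_of_strings(self, seqs):
        aln = make_alignment(seqs)
        haps = collapse_haplotypes(aln)
        expected = Counter(seqs)
        assert len(haps) == len(expected)
        assert Counter({h.seq: h.total_count for h in haps}) == expected
        assert sum(h.total_count for h in haps) == len(seqs)  # conservation
        counts = [h.total_count for h in haps]
        assert counts == sorted(counts, reverse=True)  # descending order


def _hap(hap_id, counts):
    return Haplotype(
        hap_id=hap_id,
        seq="A" * 4,
        members=tuple(f"{hap_id}m{i}" for i in range(sum(counts.values()))),
        counts_by_site=counts,
    )


class TestPrevalence:
    def test_observed_equals_expected(self):
        haps = [
            _hap("H1", {"s1": 6, "s2": 6, "s3": 6}),
            _hap("H2", {"s1": 2, "s2": 2, "s3": 2}),
        ]
        res = prevalence_test(haps)
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 2
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association_2x2(self):
        haps = [_hap("H1", {"s1": 10, "s2": 0}), _hap("H2", {"s1": 0, "s2": 10})]
        res = prevalence_test(haps)
        assert res.statistic == pytest.approx(20.0)  # sum of (10-5)^2/5 over 4 cells
        assert res.df == 1

    def test_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            table = rng.integers(1, 20, size=(2, 3)).astype(float)
            haps = [
                _hap("H1", {f"s{j}": int(table[0, j]) for j in range(3)}),
                _hap("H2", {f"s{j}": int(table[1, j]) for j in range(3)}),
            ]
            res = prevalence_test(haps)
            # independent direct summation of Pearson's statistic
            n = table.sum()
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
            stat = ((table - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(stat, abs=1e-10)
            assert res.df == 2

    def test_statistic_invariant_to_permutation(self):
        haps = [
            _hap("H1", {"s1": 7, "s2": 3, "s3": 5}),
            _hap("H2", {"s1": 2, "s2": 6, "s3": 4}),
        ]
        base = prevalence_test(haps).statistic
        swapped_rows = prevalence_test(haps[::-1]).statistic
        relabeled = prevalence_test(
            [
                _hap("H1", {"s3": 7, "s1": 3, "s2": 5}),
                _hap("H2", {"s3": 2, "s1": 6, "s2": 4}),
            ]
        ).statistic
        assert swapped_rows == pytest.approx(base)
        assert relabeled == pytest.approx(base)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateTableError):
            prevalence_test([_hap("H1", {"s1": 5, "s2": 5})])  # single haplotype
        with pytest.raises(DegenerateTableError):
            prevalence_test([_hap("H1", {"s1": 5}), _hap("H2", {"s1": 3})])  # single site
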