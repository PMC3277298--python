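"""ITS2 barcode machinery: difference classification, indel coding, anchor
trimming, the constrained strain tree and the barcode-gap report."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caenophylo.barcode import (
    Alignment,
    all_pairwise,
    barcode_gap_report,
    indel_characters,
    pairwise_differences,
    strain_tree_branch_lengths,
    trim_to_marker,
)
from caenophylo.charmap import MISSING, fitch_length
from caenophylo.trees import parse_newick


class TestPairwiseDifferences:
    def test_identical(self):
        d = pairwise_differences("ACGT", "ACGT")
        assert (d.transitions, d.transversions, d.indel_events) == (0, 0, 0)

    def test_transition_and_transversion(self):
        d = pairwise_differences("ACGTT", "GCGTA")
        assert d.transitions == 1  # A<->G
        assert d.transversions == 1  # T<->A

    def test_gap_run_is_single_event(self):
        d = pairwise_differences("AC--GT", "ACTAGT")
        assert d.indel_events == 1
        assert d.substitutions == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pairwise_differences("ACGT", "ACG")

    def test_both_gap_columns_dropped_before_run_detection(self):
        # a's gap run interrupted only by a shared gap column: one event
        d = pairwise_differences("A--" + "-" + "-G", "ATT" + "-" + "CG")
        assert d.indel_events == 1
        assert d.both_gap_columns == 1

    def test_opposite_adjacent_runs_are_two_events(self):
        d = pairwise_differences("A--TTG", "ATT--G")
        assert d.indel_events == 2

    def test_ambiguity_skipped_not_guessed(self):
        d = pairwise_differences("ARGT", "AGGT")
        assert d.substitutions == 0
        assert d.ambiguous_columns == 1

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        chars = np.array(list("ACGT-N"))
        for _ in range(50):
            a = "".join(rng.choice(chars, size=40))
            b = "".join(rng.choice(chars, size=40))
            assert pairwise_differences(a, b) == pairwise_differences(b, a)

    def test_appending_both_gap_columns_changes_nothing(self):
        a, b = "ACGT-TAG", "ACTTATAG"
        d1 = pairwise_differences(a, b)
        d2 = pairwise_differences(a + "---", b + "---")
        assert (d1.transitions, d1.transversions, d1.indel_events) == (
            d2.transitions, d2.transversions, d2.indel_events
        )

    aligned_pair = st.integers(5, 60).flatmap(
        lambda n: st.tuples(
            st.text(alphabet="ACGT-RY", min_size=n, max_size=n),
            st.text(alphabet="ACGT-RY", min_size=n, max_size=n),
        )
    )

    @settings(max_examples=200, derandomize=True)
    @given(aligned_pair)
    def test_invariants_hold_for_arbitrary_pairs(self, pair):
        """Symmetry, column accounting and count bounds on arbitrary input."""
        a, b = pair
        d = pairwise_differences(a, b)
        assert d == pairwise_differences(b, a)
        assert d.compared_columns + d.both_gap_columns == len(a)
        assert d.transitions + d.transversions + d.ambiguous_columns <= d.compared_columns
        assert d.indel_events <= d.compared_columns

    def test_indel_events_bounded_by_gap_runs(self):
        rng = np.random.default_rng(12)
        chars = np.array(list("ACGT--"))
        for _ in range(50):
            a = "".join(rng.choice(chars, size=30))
            b = "".join(rng.choice(chars, size=30))
            runs = lambda s: len(
                [1 for k, g in itertools.groupby(s, key=lambda c: c == "-") if k]
            )
            d = pairwise_differences(a, b)
            assert d.indel_events <= runs(a) + runs(b)


class TestAllPairwise:
    def test_three_identical(self):
        aln = Alignment(["a", "b", "c"], {x: "ACGTACGT" for x in "abc"})
        df = all_pairwise(aln)
        assert len(df) == 3
        assert (df.substitutions == 0).all()
        assert (df.indel_events == 0).all()

    def test_matches_per_pair_recomputation(self):
        rng = np.random.default_rng(4)
        chars = np.array(list("ACGT-"))
        labels = [f"s{i}" for i in range(5)]
        aln = Alignment(
            labels, {l: "".join(rng.choice(chars, size=60)) for l in labels}
        )
        df = all_pairwise(aln).set_index(["strain_a", "strain_b"])
        assert len(df) == 10
        for la, lb in itertools.combinations(labels, 2):
            d = pairwise_differences(aln.rows[la], aln.rows[lb])
            row = df.loc[(la, lb)]
            assert row.substitutions == d.substitutions
            assert row.indel_events == d.indel_events


class TestIndelCharacters:
    def test_shared_run(self):
        aln = Alignment(
            ["a", "b", "c", "d"],
            {"a": "AAA---TT", "b": "AAA---TT", "c": "AAATTTTT", "d": "AAATCTTT"},
        )
        m = indel_characters(aln)
        assert m.characters == ["indel_3_6"]
        assert m.cells[("a", "indel_3_6")] == "present"
        assert m.cells[("b", "indel_3_6")] == "present"
        assert m.cells[("c", "indel_3_6")] == "absent"

    def test_gap_free_alignment(self):
        aln = Alignment(["a", "b"], {"a": "ACGT", "b": "ACGA"})
        assert indel_characters(aln).characters == []

    def test_distinct_coordinates_distinct_characters(self):
        aln = Alignment(
            ["a", "b", "c"],
            {"a": "AAA--CTT", "b": "AAA---TT", "c": "AAACCCTT"},
        )
        m = indel_characters(aln)
        assert m.characters == ["indel_3_5", "indel_3_6"]
        assert m.cells[("a", "indel_3_5")] == "present"
        assert m.cells[("a", "indel_3_6")] == "absent"


class TestTrim:
    def test_core_extracted(self):
        ref = "TTT" + "ACGTAC" + "GGGG" + "TCTCTC" + "AAA"
        other = "TTT" + "ACGTAC" + "CCCC" + "TCTCTC" + "AAA"
        aln = Alignment(["ref", "x"], {"ref": ref, "x": other})
        out = trim_to_marker(aln, "ACGTAC", "TCTCTC", max_mismatch=0)
        assert out.rows["ref"] == "GGGG"
        assert out.rows["x"] == "CCCC"

    def test_anchor_absent_errors(self):
        aln = Alignment(["r"], {"r": "AAAAAAAA"})
        with pytest.raises(ValueError, match="not found"):
            trim_to_marker(aln, "ACGTAC", "TCTCTC", max_mismatch=0)

    def test_gaps_in_reference_skipped(self):
        aln = Alignment(
            ["ref", "x"],
            {"ref": "AC--GTAC" + "GG" + "TCTCTC", "x": "ACTTGTAC" + "GG" + "TCTCTC"},
        )
        out = trim_to_marker(aln, "ACGTAC", "TCTCTC", max_mismatch=0)
        assert out.rows["ref"] == "GG"

    def test_mismatch_tolerance_matches_naive_scan(self):
        rng = np.random.default_rng(10)
        bases = np.array(list("ACGT"))
        for _ in range(25):
            seq = "".join(rng.choice(bases, size=80))
            anchor = seq[20:32]
            mutated = list(anchor)
            mutated[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[5]]
            mutated = "".join(mutated)
            # naive scan oracle: first window with <=1 mismatch
            naive = next(
                i for i in range(len(seq) - len(mutated) + 1)
                if sum(x != y for x, y in zip(seq[i:i + len(mutated)], mutated)) <= 1
            )
            from caenophylo.barcode import _find_motif

            assert _find_motif(seq, mutated, 1) == naive


def _aln(rows):
    return Alignment(list(rows), dict(rows))


class TestStrainTree:
    def test_one_strain_per_species_total_equals_column_fitch_sum(self):
        sp_tree = parse_newick("((S1,S2),S3);")
        aln = _aln({"a": "AACGT", "b": "AACTT", "c": "GACTA"})
        smap = {"a": "S1", "b": "S2", "c": "S3"}
        out = strain_tree_branch_lengths(sp_tree, smap, aln)
        total = sum(n.length for n in out.nodes if not n.is_root)
        expect = 0
        for i in range(5):
            col = {l: aln.rows[l][i] for l in aln.labels}
            if len(set(col.values())) > 1:
                expect += fitch_length(out, col)
        assert total == expect

    def test_identical_strains_have_zero_terminal_branches(self):
        sp_tree = parse_newick("(S1,S2);")
        aln = _aln({"s1a": "ACGTACGT", "s1b": "ACGTACGT", "s2a": "TTTTACGT"})
        smap = {"s1a": "S1", "s1b": "S1", "s2a": "S2"}
        out = strain_tree_branch_lengths(sp_tree, smap, aln)
        assert out.tip("s1a").length == 0
        assert out.tip("s1b").length == 0

    def test_hand_counted_two_by_two(self):
        # S1: strains p,q differ by one substitution; S2: strains u,v identical;
        # species separated by 3 substitutions and one 2-column indel
        sp_tree = parse_newick("(S1,S2);")
        aln = _aln({
            "p": "AAACGTAA",
            "q": "AAACGTAT",
            "u": "CCAC--AA",
            "v": "CCAC--AA",
        })
        smap = {"p": "S1", "q": "S1", "u": "S2", "v": "S2"}
        out = strain_tree_branch_lengths(sp_tree, smap, aln)
        assert out.tip("q").length == 1  # the private substitution
        assert out.tip("p").length == 0
        assert out.tip("u").length == 0
        assert out.tip("v").length == 0
        total = sum(n.length for n in out.nodes if not n.is_root)
        # 1 private + 2 fixed subs (cols 0,1) + 1 sub (col 6->A/T? none) + indel
        d = pairwise_differences(aln.rows["p"], aln.rows["u"])
        assert total == 1 + d.substitutions + d.indel_events

    def test_unmapped_strain_errors(self):
        sp_tree = parse_newick("(S1,S2);")
        aln = _aln({"a": "ACGT", "b": "ACGT"})
        with pytest.raises(KeyError):
            strain_tree_branch_lengths(sp_tree, {"a": "S1"}, aln)

    def test_species_without_strain_errors(self):
        sp_tree = parse_newick("(S1,S2);")
        aln = _aln({"a": "ACGT"})
        with pytest.raises(ValueError, match="without strains"):
            strain_tree_branch_lengths(sp_tree, {"a": "S1"}, aln)

    def test_gap_free_total_has_no_indel_component(self):
        rng = np.random.default_rng(21)
        bases = np.array(list("ACGT"))
        labels = ["x1", "x2", "y1", "y2"]
        aln = _aln({l: "".join(rng.choice(bases, size=30)) for l in labels})
        smap = {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}
        out = strain_tree_branch_lengths(parse_newick("(X,Y);"), smap, aln)
        total = sum(n.length for n in out.nodes if not n.is_root)
        expect = 0
        for i in range(30):
            col = {l: aln.rows[l][i] for l in labels}
            if len(set(col.values())) > 1:
                expect += fitch_length(out, col)
        assert total == expect


class TestBarcodeGap:
    def _diffs(self, rows):
        return all_pairwise(_aln(rows))

    def test_clean_gap_has_no_violations(self):
        rows = {
            "A1": "AAAAAAAAAA", "A2": "AAAAAAAAAT",
            "B1": "CCCCCCCCCC", "B2": "CCCCCCCCCG",
        }
        rep = barcode_gap_report(
            self._diffs(rows), {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        )
        assert rep.violations == []
        assert rep.intra.set_index("species").loc["A", "max_total"] == 1
        assert rep.inter.iloc[0].min_total >= 9

    def test_deep_split_flagged(self):
        rows = {
            "A1": "AAAAAAAAAA", "A2": "CCCCCAAAAA",  # deeply split species
            "B1": "AAAAAAAAAC", "B2": "AAAAAAAAAC",
        }
        rep = barcode_gap_report(
            self._diffs(rows), {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        )
        assert "A" in rep.violations
        assert "B" not in rep.violations

    def test_unmapped_strain_errors(self):
        with pytest.raises(KeyError):
            barcode_gap_report(
                self._diffs({"a": "AC", "b": "AG"}), {"a": "X"}
            )

    def test_singleton_species_never_in_intra_table(self):
        rows = {"A1": "AAAA", "B1": "CCCC", "B2": "CCCA"}
        rep = barcode_gap_report(
            self._diffs(rows), {"A1": "A", "B1": "B", "B2": "B"}
        )
        assert list(rep.intra.species) == ["B"]
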