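"""Reads -> genotypes: references, calling, counting, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribofitscape import (
    CallParams,
    Genotype,
    GenotypeCaller,
    Mutation,
    Reference,
    Reject,
    RejectReason,
    call_genotype,
    filter_genotypes,
    read_reference,
    read_references,
    tabulate_counts,
)
from ribofitscape.genotype_calling import DELETION, parse_genotype_label

from conftest import build_count_table


# ---------------------------------------------------------------------------
# references


class TestReadReference:
    def test_basic_parse_normalizes_u_to_t(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">t1\nGGACU\n")
        ref = read_reference(p)
        assert ref.subunit_id == "t1"
        assert ref.sequence == "GGACT"
        assert ref.length == 5

    def test_lowercase_equals_uppercase(self, tmp_path):
        up, low = tmp_path / "u.fa", tmp_path / "l.fa"
        up.write_text(">x\nGGACU\n")
        low.write_text(">x\nggacu\n")
        assert read_reference(up).sequence == read_reference(low).sequence

    def test_ambiguous_base_rejected(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">x\nGGANU\n")
        with pytest.raises(ValueError, match="non-nucleotide"):
            read_reference(p)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_reference(p)

    def test_multi_record_needs_subunit_tag(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">5TU\nGGG\n>t1\nCCC\n")
        with pytest.raises(ValueError, match="subunit_id"):
            read_reference(p)
        assert read_reference(p, "t1").sequence == "CCC"
        assert set(read_references(p)) == {"5TU", "t1"}

    def test_positions_are_one_based(self):
        ref = Reference("5TU", "GAC")
        assert ref.base(1) == "G" and ref.base(3) == "C"


# ---------------------------------------------------------------------------
# labels


def test_mutation_labels_follow_field_convention():
    assert Mutation(110, "C", "T").label == "C110U"
    assert Mutation(38, "T", DELETION).label == "ΔU38"
    g = Genotype("t1", (Mutation(110, "C", "T"), Mutation(38, "T", DELETION)))
    assert g.label == "ΔU38,C110U"  # sorted by position
    assert parse_genotype_label(g.label, "t1") == g
    assert parse_genotype_label("wt", "t1").is_wildtype


# ---------------------------------------------------------------------------
# calling


class TestCallGenotype:
    def test_identical_read_is_wildtype(self, ref120):
        g = call_genotype(ref120.sequence, ref120)
        assert g.is_wildtype and g.hamming == 0

    def test_single_substitution_c110u(self, ref120):
        read = list(ref120.sequence)
        read[109] = "T"
        g = call_genotype("".join(read), ref120)
        assert g.label == "C110U"

    def test_single_deletion_du38(self, ref120):
        read = ref120.sequence[:37] + ref120.sequence[38:]
        g = call_genotype(read, ref120)
        assert g.label == "ΔU38"

    def test_insertion_rejected(self, ref120):
        read = ref120.sequence[:50] + "AG" + ref120.sequence[50:]
        res = call_genotype(read, ref120)
        assert isinstance(res, Reject) and res.reason == RejectReason.INSERTION

    def test_multi_nt_deletion_rejected(self, ref120):
        read = ref120.sequence[:50] + ref120.sequence[53:]
        res = call_genotype(read, ref120)
        assert isinstance(res, Reject) and res.reason == RejectReason.LONG_DELETION

    def test_truncated_read_rejected_as_incomplete(self, ref120):
        res = call_genotype(ref120.sequence[:60], ref120)
        assert isinstance(res, Reject)
        assert res.reason == RejectReason.INCOMPLETE_COVERAGE

    def test_empty_read_rejected(self, ref120):
        res = call_genotype("", ref120)
        assert isinstance(res, Reject) and res.reason == RejectReason.EMPTY_READ

    def test_ambiguous_base_rejected(self, ref120):
        read = "N" + ref120.sequence[1:]
        res = call_genotype(read, ref120)
        assert isinstance(res, Reject) and res.reason == RejectReason.AMBIGUOUS_BASE

    def test_too_many_mutations_rejected(self, ref120):
        read = list(ref120.sequence)
        for i in (10, 20, 30):
            read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
        res = call_genotype("".join(read), ref120, CallParams(max_mutations=2))
        assert isinstance(res, Reject) and res.reason == RejectReason.TOO_MANY_MUTATIONS

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_substitution_calls_are_idempotent(self, ref120, data):
        """Render a random substitution genotype, call it, get it back."""
        n_mut = data.draw(st.integers(0, 4))
        positions = data.draw(
            st.lists(st.integers(1, ref120.length), min_size=n_mut, max_size=n_mut, unique=True)
        )
        muts = []
        for pos in positions:
            ref_base = ref120.base(pos)
            alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref_base]))
            muts.append(Mutation(pos, ref_base, alt))
        g = Genotype(ref120.subunit_id, tuple(muts))
        called = call_genotype(g.sequence(ref120), ref120)
        assert called == g

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_deletion_calls_reach_a_fixed_point(self, ref120, data):
        """A deletion in a homopolymer run may canonicalize to a different
        position, but re-calling the called genotype is stable."""
        pos = data.draw(st.integers(1, ref120.length))
        g = Genotype(ref120.subunit_id, (Mutation(pos, ref120.base(pos), DELETION),))
        first = call_genotype(g.sequence(ref120), ref120)
        assert isinstance(first, Genotype) and first.hamming == 1
        second = call_genotype(first.sequence(ref120), ref120)
        assert second == first


# ---------------------------------------------------------------------------
# counting


class TestTabulateCounts:
    def test_counts_and_depth(self, ref120):
        wt = Genotype("t1")
        mut = parse_genotype_label("C110U", "t1")
        stream = [(wt, "rep1", "pre")] * 3 + [(mut, "rep1", "pre")]
        table = tabulate_counts(stream, ["rep1"])
        assert table.counts.loc["wt", ("rep1", "pre")] == 3
        assert table.counts.loc["C110U", ("rep1", "pre")] == 1
        assert table.depth[("rep1", "pre")] == 4

    def test_order_invariance(self):
        wt = Genotype("t1")
        mut = parse_genotype_label("A5G", "t1")
        stream = [(wt, "r1", "pre"), (mut, "r1", "post"), (wt, "r1", "pre"), (mut, "r1", "pre")]
        t1 = tabulate_counts(stream, ["r1"])
        t2 = tabulate_counts(stream[::-1], ["r1"])
        assert t1.counts.equals(t2.counts)

    def test_empty_stream(self):
        table = tabulate_counts([], ["r1"])
        assert len(table.counts) == 0
        assert (table.depth == 0).all()

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            tabulate_counts([(Genotype("t1"), "weird", "pre")], ["r1"])


# ---------------------------------------------------------------------------
# filtering


class TestFilterGenotypes:
    def _toy(self):
        return build_count_table(
            "t1",
            {
                "wt": {(r, p): 100 for r in ("r1", "r2", "r3") for p in ("pre", "post")},
                "A5G": {("r1", "pre"): 12, ("r2", "pre"): 0, ("r3", "pre"): 15},
                "C7U": {("r1", "pre"): 3, ("r2", "pre"): 2, ("r3", "pre"): 1},
            },
            ["r1", "r2", "r3"],
        )

    def test_threshold_rule_keeps_wt_and_passing(self):
        # enumerated by hand: A5G has >=10 pre reads in 2 of 3 replicates,
        # C7U in none; wt always kept
        table, report = filter_genotypes(self._toy(), min_pre=10, min_replicates=2)
        assert set(table.counts.index) == {"wt", "A5G"}
        assert report.n_kept == 2 and report.n_dropped_low_pre == 1

    def test_permissive_threshold_is_noop(self):
        toy = build_count_table(
            "t1",
            {
                "wt": {("r1", "pre"): 5, ("r1", "post"): 5},
                "A5G": {("r1", "pre"): 1, ("r1", "post"): 0},
            },
            ["r1"],
        )
        table, _ = filter_genotypes(toy, min_pre=1, min_replicates=1)
        assert set(table.counts.index) == {"wt", "A5G"}

    def test_missing_wildtype_is_hard_error(self):
        toy = build_count_table("t1", {"A5G": {("r1", "pre"): 50}}, ["r1"])
        with pytest.raises(ValueError, match="wild type"):
            filter_genotypes(toy, min_pre=1)

    def test_default_requires_all_replicates(self):
        table, _ = filter_genotypes(self._toy(), min_pre=10)
        assert set(table.counts.index) == {"wt"}


# ---------------------------------------------------------------------------
# conservation through the pipeline


def test_accepted_reads_are_conserved_in_counts(small_pipeline):
    """Sum of counts per (replicate, phase) equals reads accepted there
    (error-free simulation: every read should be accepted)."""
    table = small_pipeline["counts"]
    depth = table.depth
    assert (depth == 100_000).all()


def test_tsv_round_trip(small_pipeline, tmp_path):
    table = small_pipeline["filtered"]
    path = tmp_path / "counts.tsv"
    table.to_tsv(path)
    back = type(table).from_tsv(path)
    assert back.counts.astype(int).equals(table.counts.astype(int))
    assert back.subunit_id == table.subunit_id
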