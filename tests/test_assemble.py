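"""Conserved-block trimming, intron excision, occupancy, concatenation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import random_alignment
from ucekit.alignment import LocusAlignment
from ucekit.assemble import (
    CONSERVED,
    GAP,
    HIGHLY_CONSERVED,
    NONCONSERVED,
    AssembleConfig,
    SuperMatrix,
    TrimSettings,
    classify_columns,
    concatenate,
    excise_introns,
    filter_by_occupancy,
    occupancy,
    trim_conserved_blocks,
)


def _aln_from_cols(cols, lid="x"):
    n = len(cols[0])
    taxa = [f"s{i}" for i in range(n)]
    return LocusAlignment(lid, taxa, {t: "".join(c[i] for c in cols) for i, t in enumerate(taxa)})


def _aln_with_labels(pattern):
    """Build a 4-taxon alignment whose column labels under b1=0.5, b2=0.5
    spell out ``pattern`` (H = all-identical, N = all-different, G = 3/4 gap)."""
    col = {"H": "AAAA", "N": "ACGT", "G": "A---", "C": "AACG"}
    return _aln_from_cols([col[c] for c in pattern])


class TestClassifyColumns:
    def test_threshold_arithmetic_conserved(self):
        aln = _aln_from_cols(["AACT"])
        labels = classify_columns(aln, TrimSettings(b1=0.5, b2=0.85, b3=6, b4=6))
        assert labels == [CONSERVED]  # count 2 >= ceil(0.5*4)=2, < ceil(0.85*4)=4

    def test_threshold_arithmetic_not_highly(self):
        aln = _aln_from_cols(["AAAC"])
        labels = classify_columns(aln, TrimSettings(b1=0.5, b2=0.85, b3=6, b4=6))
        assert labels == [CONSERVED]  # count 3 < ceil(3.4)=4

    def test_highly_conserved(self):
        aln = _aln_from_cols(["AAAA"])
        labels = classify_columns(aln, TrimSettings(b1=0.5, b2=0.85, b3=6, b4=6))
        assert labels == [HIGHLY_CONSERVED]

    def test_gap_policy_half(self):
        aln = _aln_from_cols(["A---"])
        assert classify_columns(aln, TrimSettings()) == [GAP]

    def test_gap_policy_none_ignores_gaps(self):
        aln = _aln_from_cols(["A---"])
        labels = classify_columns(aln, TrimSettings(gap_policy="none"))
        assert labels != [GAP]

    def test_nonconserved(self):
        aln = _aln_from_cols(["ACGT"])
        assert classify_columns(aln, TrimSettings()) == [NONCONSERVED]


class TestTrimConservedBlocks:
    def test_hand_worked_example_empty(self):
        """H H N*7 H H H with b3=6, b4=4: the 7-long nonconserved run splits
        the alignment into flanks of length 2 and 3, both below b4."""
        aln = _aln_with_labels("HH" + "N" * 7 + "HHH")
        trimmed, spans = trim_conserved_blocks(aln, TrimSettings(0.5, 0.5, 6, 4))
        assert trimmed.n_cols == 0 and spans == []

    def test_short_nonconserved_run_survives(self):
        aln = _aln_with_labels("HHHH" + "N" * 6 + "HHHH")
        trimmed, spans = trim_conserved_blocks(aln, TrimSettings(0.5, 0.5, 6, 4))
        assert spans == [(1, 14)] and trimmed.n_cols == 14

    def test_all_highly_conserved_kept(self):
        aln = _aln_with_labels("H" * 100)
        trimmed, spans = trim_conserved_blocks(aln, TrimSettings())
        assert trimmed.n_cols == 100 and spans == [(1, 100)]

    def test_gap_column_and_adjacent_nonconserved_removed(self):
        aln = _aln_with_labels("HHHHHH" + "NGN" + "HHHHHH")
        trimmed, spans = trim_conserved_blocks(aln, TrimSettings(0.5, 0.5, 6, 4))
        assert spans == [(1, 6), (10, 15)]

    def test_blocks_end_on_highly_conserved(self):
        aln = _aln_with_labels("CHHHHHHC")
        _, spans = trim_conserved_blocks(aln, TrimSettings(0.5, 0.9, 6, 4))
        assert spans == [(2, 7)]

    @given(st.integers(0, 10_000))
    def test_idempotent_and_subset(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n_taxa=6, n_cols=80, gap_p=0.08)
        settings = TrimSettings()
        once, spans = trim_conserved_blocks(aln, settings)
        # subset property: every kept column is an input column, in order
        cols = [c for s, e in spans for c in range(s - 1, e)]
        assert cols == sorted(cols)
        for i, t in enumerate(once.taxa):
            assert once.rows[t] == "".join(aln.rows[t][c] for c in cols)
        twice, spans2 = trim_conserved_blocks(once, settings)
        assert twice.rows == once.rows


class TestExciseIntrons:
    def _aln(self, n_cols=400):
        return _aln_with_labels("H" * n_cols)

    def test_single_span(self):
        out = excise_introns(self._aln(400), [(101, 250)])
        assert out.n_cols == 150

    def test_two_spans_preserve_order(self):
        aln = _aln_from_cols([f"{b}{b}{b}{b}" for b in "ACGTACGTAC" * 3])
        out = excise_introns(aln, [(1, 10), (21, 30)])
        assert out.n_cols == 20
        assert out.rows["s0"] == aln.rows["s0"][:10] + aln.rows["s0"][20:30]

    def test_full_span_identity(self):
        aln = self._aln(50)
        assert excise_introns(aln, [(1, 50)]).rows == aln.rows

    def test_empty_spans_give_empty_alignment(self):
        assert excise_introns(self._aln(10), []).n_cols == 0

    def test_bad_span_rejected(self):
        with pytest.raises(IndexError):
            excise_introns(self._aln(10), [(5, 11)])


class TestOccupancy:
    def _locus(self, present, n=20, cols=10):
        taxa = [f"t{i}" for i in range(present)]
        return LocusAlignment("L", taxa, {t: "A" * cols for t in taxa})

    def test_fraction(self):
        full = [f"t{i}" for i in range(20)]
        assert occupancy(self._locus(14), full) == pytest.approx(0.70)

    def test_complete(self):
        full = [f"t{i}" for i in range(20)]
        assert occupancy(self._locus(20), full) == 1.0

    def test_all_missing_row_not_counted(self):
        full = ["a", "b"]
        aln = LocusAlignment("L", ["a", "b"], {"a": "ACGT", "b": "????"})
        assert occupancy(aln, full) == 0.5

    def test_empty_full_set_rejected(self):
        with pytest.raises(ValueError):
            occupancy(self._locus(3), [])

    def test_boundary_locus_kept(self):
        full = [f"t{i}" for i in range(20)]
        loci = {"L": self._locus(14)}
        assert filter_by_occupancy(loci, full, AssembleConfig(min_occupancy=0.70))

    def test_threshold_sweep_monotone(self, small_ds):
        full = sorted(small_ds.genus_map)
        counts = [
            len(filter_by_occupancy(small_ds.loci, full, AssembleConfig(min_occupancy=x)))
            for x in (0.5, 0.6, 0.7, 0.8, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


class TestConcatenate:
    def test_partitions_and_padding(self):
        l1 = LocusAlignment("l1", ["a", "b"], {"a": "A" * 100, "b": "C" * 100})
        l2 = LocusAlignment("l2", ["a"], {"a": "G" * 150})
        sm = concatenate({"l1": l1, "l2": l2}, ["a", "b"])
        assert sm.n_sites == 250
        assert sm.partitions == [("l1", 1, 100), ("l2", 101, 250)]
        assert sm.rows["b"][100:] == "?" * 150

    def test_duplicate_taxa_rejected(self):
        l1 = LocusAlignment("l1", ["a"], {"a": "A"})
        with pytest.raises(ValueError):
            concatenate({"l1": l1}, ["a", "a"])

    def test_empty_locus_list_rejected(self):
        with pytest.raises(ValueError):
            concatenate({}, ["a"])

    def test_partition_extraction_round_trip(self):
        rng = np.random.default_rng(3)
        loci = {}
        for i in range(4):
            aln = random_alignment(rng, n_taxa=5, n_cols=30)
            loci[f"l{i}"] = LocusAlignment(f"l{i}", aln.taxa, aln.rows)
        sm = concatenate(loci, [f"s{i}" for i in range(5)])
        for lid, aln in loci.items():
            block = sm.extract(lid)
            for t in aln.taxa:
                assert block[t] == aln.rows[t]


@pytest.fixture(scope="module")
def built(small_ds):
    from ucekit.annotate import annotate_all
    from ucekit.assemble import build_matrices
    from ucekit.curate import curate_all

    hits = small_ds.hits[small_ds.hits.evalue <= 1e-10].reset_index(drop=True)
    ann = annotate_all(small_ds.loci, hits)
    kept, groups, reports = curate_all(ann, small_ds.loci, small_ds.genus_map)
    full = sorted(small_ds.genus_map)
    matrices, summary, cols = build_matrices(small_ds.loci, kept, ann, full)
    return matrices, summary, cols


class TestBuildMatrices:
    def test_variant_locus_ordering(self, built):
        _, summary, _ = built
        assert summary["filtered_exon_intron"]["n_loci"] <= summary["unfiltered"]["n_loci"]

    def test_exon_only_is_smaller(self, built):
        _, summary, _ = built
        assert (
            summary["filtered_exon_only"]["n_sites"]
            < summary["filtered_exon_intron"]["n_sites"]
        )

    def test_row_lengths_equal(self, built):
        matrices, _, _ = built
        for sm in matrices.values():
            lengths = {len(s) for s in sm.rows.values()}
            assert lengths == {sm.n_sites}

    def test_exon_purity_of_exon_only_variant(self, built, small_ds):
        """Nearly every column surviving variant 3 comes from a true exon."""
        _, _, cols = built
        truth = small_ds.truth_by_locus()
        good = total = 0
        for lid, kept_cols in cols["filtered_exon_only"].items():
            s, e = truth[lid].exon_span
            exon = set(range(s - 1, e))
            good += sum(1 for c in kept_cols if c in exon)
            total += len(kept_cols)
        assert total > 0 and good / total >= 0.95

    def test_no_dup_no_paralog_variants_equal(self):
        from ucekit.annotate import annotate_all
        from ucekit.assemble import build_matrices
        from ucekit.curate import curate_all
        from ucekit.synth import SimConfig, generate_dataset

        ds = generate_dataset(
            SimConfig(seed=21, n_proteins=25, dup_fraction=0.0, paralog_fraction=0.0)
        )
        hits = ds.hits[ds.hits.evalue <= 1e-10].reset_index(drop=True)
        ann = annotate_all(ds.loci, hits)
        kept, _, _ = curate_all(ann, ds.loci, ds.genus_map)
        _, summary, _ = build_matrices(ds.loci, kept, ann, sorted(ds.genus_map))
        assert summary["unfiltered"]["n_loci"] == summary["filtered_exon_intron"]["n_loci"]
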