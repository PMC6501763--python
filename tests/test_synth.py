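"""Synthetic-data generator: tree shape, sequence evolution, truth labels."""

import math
import os

import numpy as np
import pytest

from ucekit.alignment import pdistance_matrix, read_fasta_alignment
from ucekit.synth import (
    SimConfig,
    emit_hits,
    evalue_from_bitscore,
    evolve_sequences,
    generate_dataset,
    inject_paralog,
    make_locus,
    simulate_discrete,
    simulate_tree,
    write_dataset,
)


class TestSimulateTree:
    def test_smallest_tree(self):
        tree = simulate_tree(2, 1.0, seed=1)
        tips = list(tree.leaf_node_iter())
        internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(tips) == 2 and len(internals) == 1

    def test_rejects_single_taxon(self):
        with pytest.raises(ValueError):
            simulate_tree(1, 1.0, seed=1)

    def test_internal_node_count(self):
        tree = simulate_tree(20, 1.0, seed=3)
        internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internals) == 19
        assert all(len(n.child_nodes()) == 2 for n in internals)

    def test_determinism(self):
        a = simulate_tree(12, 2.0, seed=42).as_string(schema="newick")
        b = simulate_tree(12, 2.0, seed=42).as_string(schema="newick")
        assert a == b

    @pytest.mark.parametrize("n", [6, 11, 20])
    def test_congeneric_pairs_exist(self, n):
        tree = simulate_tree(n, 1.5, seed=5)
        genera = {}
        for lf in tree.leaf_node_iter():
            g = lf.taxon.label.rsplit("_", 1)[0]
            genera[g] = genera.get(g, 0) + 1
        assert sum(1 for c in genera.values() if c >= 2) >= 2


class TestEvolveSequences:
    def test_zero_rate_copies_root(self):
        tree = simulate_tree(6, 1.0, seed=2)
        tips = evolve_sequences(tree, "ACGT" * 25, 0.0, seed=2)
        assert all(s == "ACGT" * 25 for s in tips.values())

    def test_length_preserved(self):
        tree = simulate_tree(5, 1.0, seed=2)
        tips = evolve_sequences(tree, "A" * 300, 0.1, seed=2)
        assert all(len(s) == 300 for s in tips.values())

    def test_negative_rate_rejected(self):
        tree = simulate_tree(4, 1.0, seed=2)
        with pytest.raises(ValueError):
            evolve_sequences(tree, "ACGT", -0.1, seed=2)

    def test_jukes_cantor_expected_pdistance(self):
        """Two tips at path distance d: mean p-distance matches the
        closed form 3/4(1 - exp(-4d/3)) within 3 Monte-Carlo SEs."""
        from ucekit.mkasr import read_newick

        d = 0.3
        tree = read_newick(f"(A:{d / 2},B:{d / 2});")
        L = 30000
        rng = np.random.default_rng(9)
        root = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
        tips = evolve_sequences(tree, root, 1.0, seed=9)
        p_obs = sum(a != b for a, b in zip(tips["A"], tips["B"])) / L
        p_exp = 0.75 * (1 - math.exp(-4 * d / 3))
        se = math.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) < 3 * se


class TestMakeLocus:
    def test_duplicate_group_shared(self):
        tree = simulate_tree(10, 1.5, seed=4)
        cfg = SimConfig(n_taxa=10, seed=4)
        _, t1 = make_locus("protX", 1, tree, cfg, 1, duplicate_group_id="dup-protX")
        _, t2 = make_locus("protX", 2, tree, cfg, 2, duplicate_group_id="dup-protX")
        assert t1.duplicate_group_id == t2.duplicate_group_id == "dup-protX"

    def test_full_occupancy(self):
        tree = simulate_tree(10, 1.5, seed=4)
        cfg = SimConfig(n_taxa=10, occupancy_mean=1.0, seed=4)
        aln, truth = make_locus("protX", 1, tree, cfg, 3)
        assert aln.n_taxa == 10 and len(truth.present_taxa) == 10

    def test_exon_span_within_alignment(self):
        tree = simulate_tree(8, 1.5, seed=4)
        cfg = SimConfig(n_taxa=8, seed=4)
        aln, truth = make_locus("protX", 1, tree, cfg, 5)
        s, e = truth.exon_span
        assert 1 <= s <= e <= aln.n_cols
        assert (e - s + 1) % 3 == 0

    def test_exon_less_diverged_than_introns(self, default_ds):
        """Conserved cores: per-locus mean column diversity is lower in
        exon than intron columns for the vast majority of loci (sign
        test, p < 0.01)."""
        from scipy.stats import binomtest

        wins = total = 0
        for row in default_ds.truth[:100]:
            aln = default_ds.loci[row.locus_id]
            arr = aln.to_array()
            div = []
            for cols in (
                np.arange(row.exon_span[0] - 1, row.exon_span[1]),
                np.r_[np.arange(row.exon_span[0] - 1), np.arange(row.exon_span[1], aln.n_cols)],
            ):
                sub = arr[:, cols]
                counts = np.stack([(sub == b).sum(axis=0) for b in range(4)])
                nongap = counts.sum(axis=0)
                ok = nongap > 0
                div.append(float(np.mean(1 - counts.max(axis=0)[ok] / nongap[ok])))
            total += 1
            if div[1] > div[0]:
                wins += 1
        assert binomtest(wins, total, 0.5, alternative="greater").pvalue < 0.01


class TestInjectParalog:
    def _locus(self, seed=6):
        tree = simulate_tree(12, 2.5, seed=seed)
        cfg = SimConfig(n_taxa=12, occupancy_mean=1.0, seed=seed)
        rng = np.random.default_rng(seed)
        from ucekit.synth import _simulate_locus

        aln, truth, meta = _simulate_locus("uce-x", "protX", 1, tree, cfg, rng, None)
        return tree, cfg, aln, truth, meta

    def test_empty_taxa_is_identity(self):
        tree, cfg, aln, _, meta = self._locus()
        out = inject_paralog(
            aln, tree, [], 0.5, 1, root_seq=meta["root"],
            site_rates=meta["site_rates"], exon_sub_rate=cfg.exon_sub_rate,
        )
        assert out.rows == aln.rows

    def test_unknown_taxon_rejected(self):
        tree, cfg, aln, _, meta = self._locus()
        with pytest.raises(ValueError):
            inject_paralog(
                aln, tree, ["nosuch"], 0.5, 1, root_seq=meta["root"],
                site_rates=meta["site_rates"], exon_sub_rate=cfg.exon_sub_rate,
            )

    def test_deep_paralog_inflates_congeneric_distance(self):
        """A paralog at depth 0.5 in one congener pushes that pair's
        p-distance above the locus median in nearly all replicates."""
        hits = 0
        for seed in range(30):
            tree, cfg, aln, truth, meta = self._locus(seed)
            pair = [t for t in aln.taxa if t.startswith("gen01")]
            out = inject_paralog(
                aln, tree, [pair[0]], 0.5, seed + 1000, root_seq=meta["root"],
                site_rates=meta["site_rates"], exon_sub_rate=cfg.exon_sub_rate,
            )
            d = pdistance_matrix(out)
            i, j = out.taxa.index(pair[0]), out.taxa.index(pair[1])
            tri = d[np.triu_indices(out.n_taxa, k=1)]
            if d[i, j] > np.median(tri[np.isfinite(tri)]):
                hits += 1
        assert hits >= 29  # >= 95% of replicates


class TestEmitHits:
    def test_evalue_model(self):
        assert evalue_from_bitscore(30, 1e9) == pytest.approx(0.93132257, abs=1e-6)

    def test_one_hit_per_clean_locus(self, small_ds):
        clean = {r.locus_id for r in small_ds.truth if not r.contaminated_taxa}
        strong = small_ds.hits[small_ds.hits.bitscore > 0]
        for lid in clean:
            rows = strong[strong.qseqid == lid]
            if len(rows) > 1:  # decoy hits must stay below the ratio bar
                top = rows.bitscore.max()
                second = sorted(rows.bitscore)[-2]
                assert second / top < 0.9

    def test_contaminated_get_similar_second_hit(self, small_ds):
        contam = {r.locus_id for r in small_ds.truth if r.contaminated_taxa}
        assert contam
        for lid in contam:
            rows = small_ds.hits[small_ds.hits.qseqid == lid]
            assert rows.sseqid.nunique() >= 2
            scores = rows.groupby("sseqid").bitscore.max().sort_values()
            assert scores.iloc[-2] / scores.iloc[-1] >= 0.9

    def test_duplicates_share_subject_distinct_coords(self, small_ds):
        truth = small_ds.truth_by_locus()
        groups = {}
        for r in truth.values():
            if r.duplicate_group_id:
                groups.setdefault(r.duplicate_group_id, []).append(r)
        assert groups
        for rows in groups.values():
            coords = set()
            for r in rows:
                hit = small_ds.hits[
                    (small_ds.hits.qseqid == r.locus_id)
                    & (small_ds.hits.sseqid == r.source_protein_id)
                ].iloc[0]
                coords.add((int(hit.sstart), int(hit.send)))
            assert len(coords) == len(rows)

    def test_no_strong_second_hits_without_paralogs(self):
        ds = generate_dataset(SimConfig(seed=13, n_proteins=40, paralog_fraction=0.0))
        for lid, rows in ds.hits.groupby("qseqid"):
            if len(rows) > 1:
                scores = sorted(rows.bitscore)
                assert scores[-2] / scores[-1] < 0.9


class TestDatasetAndIO:
    def test_loci_count_equals_total_exons(self, small_ds):
        assert len(small_ds.loci) == len(small_ds.truth)
        by_group = {}
        for r in small_ds.truth:
            if r.duplicate_group_id:
                by_group.setdefault(r.duplicate_group_id, set()).add(r.source_protein_id)
        # duplicate groups partition multi-exon proteins' loci
        assert all(len(p) == 1 for p in by_group.values())

    def test_contaminated_subset_present(self, small_ds):
        for r in small_ds.truth:
            assert set(r.contaminated_taxa) <= set(r.present_taxa)

    def test_traits_one_state_per_tip(self, small_ds):
        tips = {lf.taxon.label for lf in small_ds.tree.leaf_node_iter()}
        assert set(small_ds.traits) == tips
        assert all(0 <= s < small_ds.config.n_states for s in small_ds.traits.values())

    def test_simulate_discrete_zero_rate_constant(self):
        tree = simulate_tree(8, 1.0, seed=3)
        tips = simulate_discrete(tree, 5, 0.0, seed=3, n_chars=4)
        vals = np.stack(list(tips.values()))
        assert (vals == vals[0]).all()

    def test_write_dataset_round_trip(self, tmp_path, small_ds):
        write_dataset(small_ds, tmp_path)
        for lid, aln in list(small_ds.loci.items())[:10]:
            back = read_fasta_alignment(tmp_path / "loci" / f"{lid}.fasta")
            assert back.rows == aln.rows and back.taxa == aln.taxa

    def test_seed_determinism_checksums(self, tmp_path):
        import hashlib

        sums = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            write_dataset(generate_dataset(SimConfig(seed=5, n_proteins=20)), out)
            digest = {}
            for dirpath, _, files in os.walk(out):
                for f in sorted(files):
                    p = os.path.join(dirpath, f)
                    digest[os.path.relpath(p, out)] = hashlib.sha256(
                        open(p, "rb").read()
                    ).hexdigest()
            sums.append(digest)
        assert sums[0] == sums[1]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(intron_sub_rate=0.01, exon_sub_rate=0.05).validate()
        with pytest.raises(ValueError):
            SimConfig(exon_len=(100, 200)).validate()
        with pytest.raises(ValueError):
            SimConfig(occupancy_mean=1.5).validate()
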