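"""The synthetic-data generator: species trees, gene families, sequence
evolution, isoforms, dropout, similarity."""

import math

import numpy as np
import pytest

from phylotrx.simulate import (SimulationConfig, apply_tissue_dropout,
                               evolve_sequences, make_isoforms, mammal_like,
                               plant_like, similarity_from_sequences,
                               simulate_dataset, simulate_gene_family,
                               simulate_species_tree)
from phylotrx.supermatrix import Alignment
from phylotrx.trees import (PhyloTree, parse_newick, robinson_foulds,
                            write_newick)


class TestSpeciesTree:
    def test_four_species_one_internal_edge(self):
        from phylotrx.trees import bipartitions

        tree = simulate_species_tree(4, 0.3, seed=0)
        assert len(bipartitions(tree)) == 1

    def test_ultrametric_at_requested_height(self):
        tree = simulate_species_tree(12, 0.37, seed=5)

        depths = []

        def walk(node, depth):
            depth += node.length or 0.0
            if node.is_tip:
                depths.append(depth)
            for c in node.children:
                walk(c, depth)

        walk(tree.root, 0.0)
        assert np.mean(depths) == pytest.approx(0.37, abs=1e-9)
        assert max(depths) - min(depths) < 1e-9

    def test_seed_determinism(self):
        a = simulate_species_tree(10, 0.4, seed=42)
        b = simulate_species_tree(10, 0.4, seed=42)
        assert write_newick(a) == write_newick(b)


class TestGeneFamily:
    def test_no_events_congruent_with_species_tree(self):
        sp = simulate_species_tree(8, 0.4, seed=1)
        gene, info, redraws = simulate_gene_family(sp, 0.0, 0.0, seed=2)
        assert redraws == 0
        labels = gene.tip_labels()
        assert len(labels) == 8
        # relabel gene tips by species and compare topologies
        relabeled = gene.copy()
        for tip in relabeled.tips():
            tip.label = info[tip.label][0]
        assert robinson_foulds(relabeled, sp) == 0

    def test_high_duplication_produces_multicopy_species(self):
        sp = simulate_species_tree(6, 0.5, seed=3)
        multi = 0
        for seed in range(30):
            gene, info, _ = simulate_gene_family(sp, 3.0, 0.0, seed=seed)
            species = [info[l][0] for l in gene.tip_labels()]
            if len(species) > len(set(species)):
                multi += 1
        assert multi >= 28  # duplication at rate 3 almost always visible

    def test_duplication_yield_matches_birth_process_mean(self):
        """With zero loss, a gene lineage duplicating at rate d along an
        ultrametric tree of height h leaves e^(d h) expected copies per
        species, so E[tips] = n e^(d h); check within 3 empirical SE."""
        height = 0.5
        sp = simulate_species_tree(6, height, seed=4)
        rate = 0.4
        n_sims = 400
        extra = []
        for seed in range(n_sims):
            gene, info, _ = simulate_gene_family(sp, rate, 0.0, seed=seed)
            extra.append(gene.n_tips() - 6)
        expected = 6 * (math.exp(rate * height) - 1)
        se = np.std(extra) / math.sqrt(n_sims)
        assert abs(np.mean(extra) - expected) <= 3 * se

    def test_ancient_duplication_doubles_lineages(self):
        sp = simulate_species_tree(6, 0.5, seed=5)
        gene, info, _ = simulate_gene_family(
            sp, 0.0, 0.0, seed=6, ancient_dup_prob=1.0,
            ancient_dup_depth=0.4)
        lineages = {info[l][1] for l in gene.tip_labels()}
        assert lineages == {"a0", "a1"}
        assert gene.n_tips() == 12

    def test_all_loss_raises_after_redraws(self):
        sp = simulate_species_tree(4, 0.5, seed=7)
        with pytest.raises(RuntimeError):
            simulate_gene_family(sp, 0.0, 500.0, seed=8, max_redraws=5)


class TestEvolveSequences:
    def test_zero_branch_lengths_identical_rows(self):
        tree = parse_newick("((A:0.0,B:0.0):0.0,(C:0.0,D:0.0):0.0);")
        aln = evolve_sequences(tree, 50, indel_rate=0.0, x_rate=0.0, seed=0)
        rows = set(aln.rows.values())
        assert len(rows) == 1 and "-" not in rows.pop()

    def test_p_distance_matches_closed_form(self):
        """Two tips at path 2b: E[p] = (19/20)(1 - exp(-20*2b/19))."""
        b = 0.25
        tree = parse_newick(f"(A:{b},B:{b});")
        aln = evolve_sequences(tree, 10_000, indel_rate=0.0, x_rate=0.0,
                               seed=11)
        a, z = aln.rows["A"], aln.rows["B"]
        p_hat = sum(1 for x, y in zip(a, z) if x != y) / len(a)
        p_exp = (19 / 20) * (1 - math.exp(-20 * 2 * b / 19))
        se = math.sqrt(p_exp * (1 - p_exp) / 10_000)
        assert abs(p_hat - p_exp) <= 3 * se

    def test_no_x_means_unambiguous_equals_nongap(self):
        tree = parse_newick("((A:0.1,B:0.1):0.1,C:0.1);")
        aln = evolve_sequences(tree, 200, indel_rate=0.05, x_rate=0.0, seed=1)
        for sid in aln.rows:
            row = aln.rows[sid]
            assert aln.unambiguous_count(sid) == len(row) - row.count("-")

    def test_indels_produce_gap_blocks(self):
        tree = parse_newick("((A:0.3,B:0.3):0.1,C:0.3);")
        aln = evolve_sequences(tree, 300, indel_rate=0.1, x_rate=0.0, seed=2)
        assert any("-" in r for r in aln.rows.values())


class TestIsoforms:
    def fam(self, seed=0):
        tree = parse_newick("((spA|f|g1:0.1,spB|f|g2:0.1):0.1,spC|f|g3:0.1);")
        aln = evolve_sequences(tree, 120, 0.0, 0.0, seed=seed)
        info = {l: (l.split("|")[0], "a0") for l in aln.rows}
        return aln, info

    def test_mean_one_gives_single_isoform(self):
        aln, info = self.fam()
        recs = make_isoforms(aln, info, 1.0, seed=0, family_id="f")
        assert len(recs) == 3
        assert all(r.isoform_id == "i0" for r in recs)

    def test_untruncated_isoform_has_max_unambiguous(self):
        aln, info = self.fam()
        recs = make_isoforms(aln, info, 3.0, seed=1, family_id="f")
        by_gene = {}
        for r in recs:
            by_gene.setdefault(r.gene_id, []).append(r)
        assert any(len(v) > 1 for v in by_gene.values())
        for gene, isoforms in by_gene.items():
            best = max(isoforms, key=lambda r: len(r.residues))
            assert best.isoform_id == "i0"

    def test_isoform_count_mean(self):
        aln, info = self.fam()
        mean = 2.5
        counts = []
        for seed in range(400):
            recs = make_isoforms(aln, info, mean, seed=seed, family_id="f")
            counts.append(len(recs) / 3)
        se = math.sqrt((mean - 1) / (400 * 3))
        assert abs(np.mean(counts) - mean) <= 3 * se


class TestDropout:
    def records(self):
        aln, info = TestIsoforms().fam()
        return make_isoforms(aln, info, 1.0, seed=0, family_id="f")

    def test_zero_dropout_keeps_everything(self):
        recs = self.records()
        out = apply_tissue_dropout(recs, ["t1", "t2"], 0.0, seed=0)
        assert all(len(v) == len(recs) for v in out.values())

    def test_full_dropout_empties_transcriptomes(self):
        recs = self.records()
        out = apply_tissue_dropout(recs, ["t1"], 1.0, seed=0)
        assert out == {"t1": {}}

    def test_retention_rate(self):
        rng = np.random.default_rng(0)
        recs = self.records()
        keep = []
        for seed in range(2000):
            out = apply_tissue_dropout(recs, ["t"], 0.3, seed=seed)
            keep.append(len(out["t"]) / len(recs))
        se = math.sqrt(0.3 * 0.7 / (2000 * 3))
        assert abs(np.mean(keep) - 0.7) <= 3 * se


class TestSimilarity:
    def test_identical_sequences_full_identity(self):
        from phylotrx.orthology import SequenceRecord

        a = SequenceRecord("a", "sp1", "a", "i0", "ACDEF", aligned="ACDEF",
                           frame_id="f")
        b = SequenceRecord("b", "sp2", "b", "i0", "ACDEF", aligned="ACDEF",
                           frame_id="f")
        (e, *_rest) = similarity_from_sequences([a, b])
        assert e.identity_fraction == 1.0
        assert e.aligned_fraction == 1.0

    def test_non_overlapping_truncations_no_edge(self):
        from phylotrx.orthology import SequenceRecord

        a = SequenceRecord("a", "sp1", "a", "i0", "ACD", aligned="ACD-----",
                           frame_id="f")
        b = SequenceRecord("b", "sp2", "b", "i0", "EFGHI", aligned="---EFGHI",
                           frame_id="f")
        assert similarity_from_sequences([a, b]) == []

    def test_identity_complements_p_distance(self):
        tree = parse_newick("(A:0.1,B:0.1);")
        aln = evolve_sequences(tree, 500, 0.0, 0.0, seed=3)
        from phylotrx.orthology import SequenceRecord

        recs = [SequenceRecord(l, l, l, "i0", aln.rows[l].replace("-", ""),
                               aligned=aln.rows[l], frame_id="f")
                for l in aln.rows]
        e = similarity_from_sequences(recs)[0]
        p = sum(1 for x, y in zip(*aln.rows.values()) if x != y) / 500
        assert e.identity_fraction == pytest.approx(1 - p)

    def test_cross_frame_pairs_produce_no_edges(self):
        from phylotrx.orthology import SequenceRecord

        a = SequenceRecord("a", "sp1", "a", "i0", "ACDEF", aligned="ACDEF",
                           frame_id="f1")
        b = SequenceRecord("b", "sp2", "b", "i0", "ACDEF", aligned="ACDEF",
                           frame_id="f2")
        assert similarity_from_sequences([a, b]) == []


class TestWholeDataset:
    def test_same_seed_same_bytes(self):
        cfg = mammal_like(n_families=5, n_species=6, seed=9)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        assert write_newick(a.species_tree) == write_newick(b.species_tree)
        assert a.gold.lineage_labels == b.gold.lineage_labels
        ta = {t: sorted(r.keys()) for t, r in a.transcriptomes.items()}
        tb = {t: sorted(r.keys()) for t, r in b.transcriptomes.items()}
        assert ta == tb
        sa = {sid: r.residues for sid, r in a.genome_records.items()}
        sb = {sid: r.residues for sid, r in b.genome_records.items()}
        assert sa == sb

    def test_every_sequence_labelled(self, small_dataset):
        ds = small_dataset
        for records in ds.transcriptomes.values():
            for sid in records:
                assert sid in ds.gold.labels
                assert sid in ds.gold.lineage_labels
        for sid in ds.genome_records:
            assert sid in ds.gold.labels

    def test_presets(self):
        m, p = mammal_like(), plant_like()
        assert m.n_species == 22 and len(m.tissues) == 7
        assert p.n_species == 15 and len(p.tissues) == 3
        assert p.ancient_dup_prob > m.ancient_dup_prob

    def test_parameter_recovery_from_clean_supermatrix(self, clean_dataset):
        """With ample signal and no noise the NJ tree from the genome
        supermatrix equals the generating species tree."""
        from phylotrx import pipeline as pl

        ds = clean_dataset
        groups = pl.genome_groups(ds)
        assert len(groups) == ds.config.n_families
        _, tree, _, _ = pl.species_tree_from_groups(
            groups, ds.genome_records, min_codons=150)
        assert robinson_foulds(tree, ds.species_tree) == 0
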