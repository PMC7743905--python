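"""Similarity filtering, Markov clustering, RBH assignment, and
gene-tree pruning to one-to-one orthologs."""

import numpy as np
import pytest

from phylotrx.orthology import (CoreOrthologSet, HomologCluster,
                                OrthologGroup, SequenceRecord, SimilarityEdge,
                                cut_deep_branches, extract_one_to_one,
                                filter_clusters, filter_similarity_edges,
                                mask_isoforms, mcl_cluster,
                                prune_spurious_terminals, rbh_assign,
                                strict_single_copy_groups,
                                tree_based_pipeline)
from phylotrx.supermatrix import Alignment
from phylotrx.trees import parse_newick, robinson_foulds, write_newick


def edge(q, s, aligned=0.9, identity=0.9, hit=0.9, score=100.0):
    return SimilarityEdge(query=q, subject=s, aligned_fraction=aligned,
                          identity_fraction=identity, hit_fraction=hit,
                          bitscore_like=score)


def rec(seq_id, species, length=100):
    return SequenceRecord(seq_id=seq_id, species_id=species,
                          gene_id=seq_id, isoform_id="i0",
                          residues="A" * length)


class TestFilterEdges:
    @pytest.mark.parametrize("a,i,h,kept", [
        (0.5, 0.4, 0.6, True),
        (0.29, 0.9, 0.9, False),
        (0.30, 0.30, 0.30, True),   # inclusive boundary ("at least")
        (0.9, 0.29, 0.9, False),
        (0.9, 0.9, 0.29, False),
    ])
    def test_threshold_combinations(self, a, i, h, kept):
        edges = filter_similarity_edges([edge("x", "y", a, i, h)])
        assert bool(edges) is kept


def reference_mcl(names, W, inflation, n_iter=300):
    """Independently coded dense MCL used as an oracle."""
    M = W.astype(float).copy()
    for k in range(len(names)):
        mx = M[k].max()
        M[k, k] = mx if mx > 0 else 1.0
    M = M / M.sum(axis=0)
    for _ in range(n_iter):
        M = np.linalg.matrix_power(M, 2)
        M = M ** inflation
        M = M / M.sum(axis=0)
    members = [set() for _ in names]
    labels = {}
    for i in range(len(names)):
        for j in range(len(names)):
            if M[i, j] > 1e-9 or M[j, i] > 1e-9:
                ri = labels.setdefault(i, i)
                labels[j] = ri
    # transitive closure via union-find-ish sweep
    groups = {}
    for j, r in sorted(labels.items()):
        while labels[r] != r:
            r = labels[r]
        groups.setdefault(r, set()).add(names[j])
    return {frozenset(g) for g in groups.values()}


class TestMCL:
    def test_disconnected_cliques_are_separate_clusters(self):
        edges = []
        for grp in (["a1", "a2", "a3"], ["b1", "b2", "b3"]):
            for x in grp:
                for y in grp:
                    if x != y:
                        edges.append(edge(x, y))
        clusters = mcl_cluster(edges)
        assert {frozenset(c.members) for c in clusters} == {
            frozenset({"a1", "a2", "a3"}), frozenset({"b1", "b2", "b3"})}

    def test_isolated_node_is_singleton(self):
        clusters = mcl_cluster([edge("a", "b")], nodes=["a", "b", "lonely"])
        assert {frozenset(c.members) for c in clusters} == {
            frozenset({"a", "b"}), frozenset({"lonely"})}

    def test_barbell_matches_reference_implementation(self):
        """Two tight triangles joined by a weak bridge: MCL at inflation
        1.4 must agree with an independently coded dense-matrix MCL."""
        names = ["a1", "a2", "a3", "b1", "b2", "b3", "hub"]
        idx = {n: i for i, n in enumerate(names)}
        W = np.zeros((7, 7))
        for grp in (["a1", "a2", "a3"], ["b1", "b2", "b3"]):
            for x in grp:
                for y in grp:
                    if x != y:
                        W[idx[x], idx[y]] = 10.0
        W[idx["a1"], idx["hub"]] = W[idx["hub"], idx["a1"]] = 1.0
        W[idx["b1"], idx["hub"]] = W[idx["hub"], idx["b1"]] = 0.5
        edges = [edge(x, y, score=W[idx[x], idx[y]])
                 for x in names for y in names if W[idx[x], idx[y]] > 0]
        got = {frozenset(c.members) for c in mcl_cluster(edges)}
        expected = reference_mcl(names, W, inflation=1.4)
        assert got == expected


class TestFilterClusters:
    def test_length_boundary(self):
        records = {"short": rec("short", "sp1", 29),
                   "ok": rec("ok", "sp2", 30),
                   "long": rec("long", "sp3", 80)}
        clusters = [HomologCluster(members={"short", "ok", "long"})]
        out = filter_clusters(clusters, records, ["sp1", "sp2", "sp3"],
                              min_species_fraction=0.5)
        assert out[0].members == {"ok", "long"}

    def test_half_of_22_species_rule(self):
        all_species = [f"sp{i:02d}" for i in range(22)]
        records = {f"s{i}": rec(f"s{i}", all_species[i]) for i in range(22)}
        eleven = HomologCluster(members={f"s{i}" for i in range(11)})
        ten = HomologCluster(members={f"s{i}" for i in range(10)})
        out = filter_clusters([eleven, ten], records, all_species)
        assert len(out) == 1 and out[0].members == eleven.members

    def test_species_counted_after_length_filter(self):
        """A cluster that loses its only member of a species to the length
        cutoff is judged on the reduced species set."""
        records = {"a": rec("a", "sp1", 29), "b": rec("b", "sp2", 50),
                   "c": rec("c", "sp3", 50), "d": rec("d", "sp4", 50)}
        cluster = HomologCluster(members={"a", "b", "c", "d"})
        # 4 species, need ceil(0.75*4)=3: survives only because sp2-4 remain
        out = filter_clusters([cluster], records,
                              ["sp1", "sp2", "sp3", "sp4"],
                              min_species_fraction=0.75)
        assert out and out[0].members == {"b", "c", "d"}
        # at a stricter fraction the same cluster dies
        out = filter_clusters([cluster], records,
                              ["sp1", "sp2", "sp3", "sp4"],
                              min_species_fraction=1.0)
        assert not out


class TestStrictSingleCopy:
    def test_rules(self):
        species = ["hum", "mou", "dog"]
        records = {"h1": rec("h1", "hum"), "h2": rec("h2", "hum"),
                   "m1": rec("m1", "mou"), "d1": rec("d1", "dog"),
                   "h3": rec("h3", "hum"), "m2": rec("m2", "mou")}
        two_human = HomologCluster(members={"h1", "h2", "m1", "d1"})
        complete = HomologCluster(members={"h3", "m2", "d1"})
        missing = HomologCluster(members={"h3", "m2"})
        groups = strict_single_copy_groups([two_human, complete, missing],
                                           records, species)
        assert len(groups) == 1
        assert groups[0].method_tag == "genome_mcl"
        assert set(groups[0].members.values()) == {"h3", "m2", "d1"}


class TestRBH:
    def make_core(self):
        group = OrthologGroup(group_id="g1", members={"ref": "refP"},
                              method_tag="core")
        return CoreOrthologSet(groups=[group], reference_species="ref")

    def txs(self, *ids, species="spA"):
        return {i: rec(i, species) for i in ids}

    def test_symmetric_best_hits_assigned(self):
        core = self.make_core()
        tx = self.txs("t1")
        edges = [edge("t1", "refP", score=50), edge("refP", "t1", score=50)]
        groups = rbh_assign(tx, core, edges, min_species_fraction=0.0)
        assert groups and groups[0].members == {"spA": "t1"}

    def test_reciprocity_failure_not_assigned(self):
        core = self.make_core()
        tx = self.txs("t1", "t2")
        edges = [edge("t1", "refP", score=50),
                 edge("refP", "t1", score=50), edge("refP", "t2", score=80)]
        groups = rbh_assign(tx, core, edges, min_species_fraction=0.0)
        # t1's best is refP but refP's best is t2, and t2 never hits refP
        assert not groups or "t1" not in groups[0].members.values()

    def test_two_reciprocal_transcripts_drop_the_species(self):
        """Two same-species transcripts tied reciprocally to one group
        violate single copy: the species is dropped from the group."""
        group = OrthologGroup(group_id="g1",
                              members={"ref": "refP", "spB": "b1"},
                              method_tag="core")
        core = CoreOrthologSet(groups=[group], reference_species="ref")
        tx = self.txs("t1", "t2")
        tx["b_t"] = rec("b_t", "spB")
        edges = [
            edge("t1", "refP", score=50), edge("t2", "refP", score=50),
            edge("refP", "t1", score=50), edge("refP", "t2", score=50),
            edge("b_t", "refP", score=40), edge("refP", "b_t", score=40),
        ]
        groups = rbh_assign(tx, core, edges, min_species_fraction=0.0)
        # deterministic tie-break sends refP's best hit to t1 only, so spA
        # keeps exactly one transcript; spB keeps its single transcript
        assert groups
        members = groups[0].members
        assert list(members.values()).count("t2") == 0


class TestTerminalPruning:
    def test_both_conditions_met_removed(self):
        tree = parse_newick("((A:0.7,B:0.05):0.1,(C:0.1,D:0.1):0.1);")
        pruned = prune_spurious_terminals(tree)
        assert "A" not in pruned.taxa()

    def test_ratio_fails_kept(self):
        tree = parse_newick("((A:0.7,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        assert "A" in prune_spurious_terminals(tree).taxa()

    def test_length_fails_kept(self):
        tree = parse_newick("((A:0.5,B:0.01):0.1,(C:0.1,D:0.1):0.1);")
        assert "A" in prune_spurious_terminals(tree).taxa()

    def test_iterates_to_fixpoint(self):
        # A (7.0 > 10 x 0.65, > 0.6) goes first; suppressing its parent
        # folds the 0.2 internal edge onto B (0.65 + 0.2 = 0.85), which now
        # violates the rule against sister C (0.05) and goes too
        tree = parse_newick(
            "(((A:7.0,B:0.65):0.2,C:0.05):0.1,(D:0.1,E:0.1):0.1);")
        pruned = prune_spurious_terminals(tree)
        assert "A" not in pruned.taxa() and "B" not in pruned.taxa()
        assert {"C", "D", "E"} <= pruned.taxa()


class TestDeepBranchCut:
    def test_no_long_edge_returns_original(self):
        tree = parse_newick("((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2);")
        frags = cut_deep_branches(tree)
        assert len(frags) == 1
        assert frags[0].taxa() == frozenset("ABCD")

    def test_central_long_edge_splits_in_two(self):
        tree = parse_newick(
            "((A:0.1,B:0.1,C:0.1):0.6,(D:0.1,E:0.1,F:0.1):0.1);")
        frags = cut_deep_branches(tree)
        assert {f.taxa() for f in frags} == {frozenset("ABC"),
                                             frozenset("DEF")}

    def test_chained_cuts_match_manual_enumeration(self):
        # caterpillar with long edges isolating {A,B} and {E,F}
        tree = parse_newick(
            "((A:0.1,B:0.1):0.6,((C:0.1,D:0.1):0.6,(E:0.1,F:0.1):0.1):0.1);")
        frags = cut_deep_branches(tree)
        assert {f.taxa() for f in frags} == {
            frozenset("AB"), frozenset("CD"), frozenset("EF")}

    def test_terminal_edges_never_cut(self):
        tree = parse_newick("((A:0.9,B:0.1):0.1,(C:0.1,D:0.9):0.1);")
        frags = cut_deep_branches(tree)
        assert len(frags) == 1 and frags[0].taxa() == frozenset("ABCD")


def _aln(rows):
    return Alignment(rows)


class TestMaskIsoforms:
    species_of = staticmethod(lambda sid: sid.split("_")[0])

    def test_sister_isoforms_keep_most_unambiguous(self):
        tree = parse_newick("((hum_i1:0.0,hum_i2:0.0):0.1,(mou_a:0.1,dog_a:0.1):0.1);")
        aln = _aln({"hum_i1": "ACDEFGHIKL", "hum_i2": "ACDEF-----",
                    "mou_a": "ACDEFGHIKL", "dog_a": "ACDEFGHIKL"})
        masked = mask_isoforms(tree, aln, self.species_of)
        assert masked.taxa() == {"hum_i1", "mou_a", "dog_a"}

    def test_paraphyletic_grade_one_survivor(self):
        """A basal grade of three same-species tips (paraphyletic on the
        rooted tree, successively adjacent on the unrooted one) collapses
        to the single best-covered tip."""
        tree = parse_newick(
            "(((mou_a:0.1,dog_a:0.1):0.1,hum_i1:0.0):0.05,"
            "hum_i2:0.0,hum_i3:0.0);")
        aln = _aln({"hum_i1": "ACDEFGHIKL", "hum_i2": "ACDEFG----",
                    "hum_i3": "ACD-------", "mou_a": "ACDEFGHIKL",
                    "dog_a": "ACDEFGHIKL"})
        masked = mask_isoforms(tree, aln, self.species_of)
        humans = [t for t in masked.tip_labels() if t.startswith("hum")]
        assert humans == ["hum_i1"]

    def test_tips_separated_by_other_species_not_merged(self):
        """Same-species tips on opposite sides of another species' tip are
        genuinely duplicated genes, not redundant isoforms."""
        tree = parse_newick(
            "((hum_a:0.1,mou_a:0.1):0.1,(hum_b:0.1,(dog_a:0.1,cat_a:0.1):0.1):0.1);")
        aln = _aln({k: "ACDEFGHIKL" for k in
                    ["hum_a", "hum_b", "mou_a", "dog_a", "cat_a"]})
        masked = mask_isoforms(tree, aln, self.species_of)
        assert {"hum_a", "hum_b"} <= masked.taxa()

    def test_missing_alignment_row_is_an_error(self):
        tree = parse_newick("((hum_a:0.1,mou_a:0.1):0.1,(dog_a:0.1,cat_a:0.1):0.1);")
        aln = _aln({"hum_a": "AC", "mou_a": "AC", "dog_a": "AC"})
        with pytest.raises(KeyError):
            mask_isoforms(tree, aln, self.species_of)


class TestExtractOneToOne:
    def records_for(self, labels):
        return {l: rec(l, l.split("_")[0]) for l in labels}

    def test_accepts_single_copy_above_half(self):
        labels = [f"sp{i:02d}_g" for i in range(12)]
        tree_src = "(" + ",".join(f"{l}:0.1" for l in labels) + ");"
        group = extract_one_to_one(parse_newick(tree_src),
                                   self.records_for(labels),
                                   [f"sp{i:02d}" for i in range(22)])
        assert group is not None and group.method_tag == "tree_based"
        assert len(group.members) == 12

    def test_rejects_duplicated_species(self):
        labels = ["spA_g1", "spA_g2", "spB_g", "spC_g"]
        tree_src = "(" + ",".join(f"{l}:0.1" for l in labels) + ");"
        assert extract_one_to_one(parse_newick(tree_src),
                                  self.records_for(labels),
                                  ["spA", "spB", "spC"]) is None

    def test_rejects_below_half_species(self):
        labels = [f"sp{i:02d}_g" for i in range(10)]
        tree_src = "(" + ",".join(f"{l}:0.1" for l in labels) + ");"
        assert extract_one_to_one(parse_newick(tree_src),
                                  self.records_for(labels),
                                  [f"sp{i:02d}" for i in range(22)]) is None


class TestTreeBasedPipeline:
    def test_clean_data_recovers_every_family(self, clean_dataset):
        ds = clean_dataset
        from phylotrx.simulate import similarity_from_sequences

        tissue = ds.config.tissues[0]
        tx = ds.transcripts_for(tissue)
        groups, log = tree_based_pipeline(
            tx, similarity_from_sequences(tx), ds.species)
        assert len(groups) == ds.config.n_families
        for g in groups:
            assert len(g.members) == ds.config.n_species

    def test_no_group_mixes_gold_families(self, small_dataset):
        ds = small_dataset
        from phylotrx.simulate import similarity_from_sequences

        tx = ds.transcripts_for("brain")
        groups, log = tree_based_pipeline(
            tx, similarity_from_sequences(tx), ds.species)
        assert groups
        for g in groups:
            fams = {ds.gold.labels[sid][0] for sid in g.members.values()}
            assert len(fams) == 1

    def test_every_group_single_copy(self, small_dataset):
        ds = small_dataset
        from phylotrx.simulate import similarity_from_sequences

        tx = ds.transcripts_for("kidney")
        groups, _ = tree_based_pipeline(
            tx, similarity_from_sequences(tx), ds.species)
        for g in groups:
            species = [ds.gold.labels[sid][1] for sid in g.members.values()]
            assert len(species) == len(set(species))

    def test_stage_log_reconciles(self, small_dataset):
        ds = small_dataset
        from phylotrx.simulate import similarity_from_sequences

        tx = ds.transcripts_for("liver")
        _, log = tree_based_pipeline(
            tx, similarity_from_sequences(tx), ds.species)
        assert log["clusters_initial"] == (log["clusters_after_filter"]
                                           + log["clusters_discarded_filter"])
        assert log["fragments"] == (log["groups_emitted"]
                                    + log["fragments_rejected"])
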