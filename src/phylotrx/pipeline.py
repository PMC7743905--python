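"""End-to-end orchestration: simulate -> identify orthologs -> build
supermatrix and tree -> compare topologies against the genome tree and
its nulls -> benchmark ortholog correctness.

The genome-based ("PG") route clusters complete proteomes and keeps
strictly single-copy, all-species clusters.  The transcriptome ("PT")
routes run either the gene-tree-based pipeline or reciprocal-best-hit
assignment against a core ortholog set built from a few reference
genomes.  All stage seeds derive from one master seed by fixed offsets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import benchmark as bench
from . import nulls as nulls_mod
from . import orthology as orth
from . import supermatrix as sm
from .simulate import (SimulationConfig, SyntheticDataset, _stage_seed,
                       mammal_like, plant_like, similarity_from_sequences,
                       simulate_dataset)
from .trees import PhyloTree, robinson_foulds, write_newick

REPORT_SCHEMA_VERSION = 1

PROFILES = {
    # length cutoff conventions for trimmed alignments
    "mammal_rbh": {"min_codons": 500},
    "mammal_tree": {"min_codons": 150},
    "plant": {"min_codons": 150},
}


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    tissue: str = "brain"
    method: str = "tree_based"       # tree_based | rbh
    profile: str = "mammal_tree"
    min_codons: Optional[int] = None  # overrides the profile cutoff
    trim_occupancy: float = 0.3       # supermatrix-stage column trimming
    gene_trim_occupancy: float = 0.1  # gene-tree-stage column trimming
    n_reference_species: int = 5
    min_species_fraction: float = 0.5
    n_null_samples: int = 1000
    n_bootstrap: int = 200
    seed: int = 0

    @property
    def length_cutoff(self) -> int:
        if self.min_codons is not None:
            return self.min_codons
        return PROFILES[self.profile]["min_codons"]


# ---------------------------------------------------------------------------
# Orthology stages
# ---------------------------------------------------------------------------

def genome_groups(dataset: SyntheticDataset,
                  inflation: float = 1.4) -> list[orth.OrthologGroup]:
    """Genome-mode orthology: cluster all annotated proteins and keep
    clusters single-copy in every species."""
    edges = orth.filter_similarity_edges(
        similarity_from_sequences(dataset.genome_records))
    clusters = orth.mcl_cluster(edges, inflation=inflation,
                                nodes=dataset.genome_records.keys())
    return orth.strict_single_copy_groups(clusters, dataset.genome_records,
                                          dataset.species)


def reference_core_set(dataset: SyntheticDataset,
                       n_refs: int = 5) -> orth.CoreOrthologSet:
    """Core ortholog groups from a handful of reference genomes (spread
    across the species list), single-copy across those references."""
    step = max(1, len(dataset.species) // n_refs)
    refs = dataset.species[::step][:n_refs]
    ref_records = {sid: r for sid, r in dataset.genome_records.items()
                   if r.species_id in refs}
    edges = orth.filter_similarity_edges(similarity_from_sequences(ref_records))
    clusters = orth.mcl_cluster(edges, nodes=ref_records.keys())
    groups = orth.strict_single_copy_groups(clusters, ref_records, refs)
    for g in groups:
        g.method_tag = "core"
    return orth.CoreOrthologSet(groups=groups, reference_species=refs[0])


def identify_orthologs(dataset: SyntheticDataset, tissue: str, method: str,
                       config: Optional[PipelineConfig] = None
                       ) -> tuple[list[orth.OrthologGroup], dict]:
    """Run one ortholog-identification method on one tissue's
    transcriptome.  Returns (groups, stage log)."""
    config = config or PipelineConfig()
    transcripts = dataset.transcripts_for(tissue)
    if method == "tree_based":
        edges = similarity_from_sequences(transcripts)
        groups, log = orth.tree_based_pipeline(
            transcripts, edges, dataset.species,
            min_species_fraction=config.min_species_fraction,
            trim_occupancy=config.gene_trim_occupancy)
        return groups, log
    if method == "rbh":
        core = reference_core_set(dataset, config.n_reference_species)
        ref_species_records = {
            sid: r for sid, r in dataset.genome_records.items()
            if r.species_id == core.reference_species}
        combined = dict(transcripts)
        combined.update(ref_species_records)
        edges = similarity_from_sequences(combined)
        groups = orth.rbh_assign(
            transcripts, core, edges,
            min_species_fraction=config.min_species_fraction,
            all_species=dataset.species)
        return groups, {"core_groups": len(core.groups),
                        "groups_emitted": len(groups)}
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Supermatrix and trees
# ---------------------------------------------------------------------------

def groups_supermatrix(groups: Sequence[orth.OrthologGroup],
                       records: dict[str, orth.SequenceRecord],
                       min_codons: int = 150,
                       trim_occupancy: float = 0.3) -> sm.Supermatrix:
    """Per-group alignments keyed by species, trimmed and length-filtered,
    then concatenated with gap fill for missing species."""
    alignments = {}
    for g in groups:
        rows = {}
        for sp, sid in g.members.items():
            rec = records[sid]
            rows[sp] = rec.aligned if rec.aligned is not None else rec.residues
        widths = {len(r) for r in rows.values()}
        if len(widths) != 1:
            raise ValueError(f"group {g.group_id}: inconsistent row widths")
        alignments[g.group_id] = sm.trim_columns(sm.Alignment(rows),
                                                 trim_occupancy)
    alignments = sm.filter_by_length(alignments, min_codons)
    if not alignments:
        raise ValueError("no alignment survived the length cutoff")
    species = sorted({sp for gid in alignments
                      for sp in alignments[gid].rows})
    ordered = sorted(alignments.items())
    return sm.concatenate(ordered, species)


def species_tree_from_groups(groups, records, min_codons=150,
                             trim_occupancy=0.3, n_bootstrap=0, seed=0):
    """NJ species tree (plus optional bootstrap) from ortholog groups."""
    matrix = groups_supermatrix(groups, records, min_codons, trim_occupancy)
    if n_bootstrap > 0:
        tree, reps, support = sm.bootstrap_trees(matrix, n_reps=n_bootstrap,
                                                 seed=seed)
        return matrix, tree, reps, support
    taxa, D = sm.pairwise_distance(matrix)
    return matrix, sm.neighbor_joining(taxa, D), [], {}


# ---------------------------------------------------------------------------
# Comparison and benchmark
# ---------------------------------------------------------------------------

def compare_trees(pt_tree: PhyloTree, pg_tree: PhyloTree, seed: int,
                  n_null_samples: int = 1000,
                  bootstrap_trees: Sequence[PhyloTree] = ()) -> dict:
    """d_T between a transcriptome tree and the genome reference, with the
    random-tree null and one/two/three-pair tip-swap nulls and their
    inclusive P-values; restricted to the common species throughout."""
    common = pt_tree.taxa() & pg_tree.taxa()
    from .trees import restrict_to_taxa
    ref = pg_tree if pg_tree.taxa() == common else restrict_to_taxa(pg_tree, common)
    d_obs = robinson_foulds(pt_tree, pg_tree)
    out = {"d_T": d_obs, "n_common_taxa": len(common)}
    rand = nulls_mod.build_null(ref, "random_tree", n_null_samples,
                                _stage_seed(seed, 71))
    out["random_null_min"] = int(min(rand.samples))
    out["p_random"] = nulls_mod.tip_swap_pvalue(rand, d_obs).p
    for k, name in ((1, "p_two_tips"), (2, "p_four_tips"), (3, "p_six_tips")):
        null = nulls_mod.build_null(ref, "tip_swap", n_null_samples,
                                    _stage_seed(seed, 80 + k),
                                    n_pairs_swapped=k)
        out[name] = nulls_mod.tip_swap_pvalue(null, d_obs).p
    if bootstrap_trees:
        dts = nulls_mod.bootstrap_dt_distribution(pg_tree, bootstrap_trees)
        out["bootstrap_d_T_mean"] = float(np.mean(dts))
        out["bootstrap_d_T_max"] = int(max(dts))
    return out


def benchmark_groups(groups: Sequence[orth.OrthologGroup],
                     dataset: SyntheticDataset,
                     counts_by_condition: Optional[Sequence[int]] = None
                     ) -> bench.BenchmarkSummary:
    verdicts = [bench.classify_group(g, dataset.gold.lineage_labels)
                for g in groups]
    return bench.summarize(verdicts, counts_by_condition)


# ---------------------------------------------------------------------------
# Whole-run driver
# ---------------------------------------------------------------------------

def _round_floats(obj, sig: int = 12):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig,
                 out_dir: Optional[Path | str] = None,
                 dataset: Optional[SyntheticDataset] = None) -> dict:
    """Execute every stage and return (optionally write) the JSON report."""
    dataset = dataset or simulate_dataset(config.sim)
    all_records = dict(dataset.genome_records)
    for tissue_records in dataset.transcriptomes.values():
        all_records.update(tissue_records)

    pg = genome_groups(dataset)
    if not pg:
        raise RuntimeError("genome stage produced no single-copy groups")
    _, pg_tree, _, _ = species_tree_from_groups(
        pg, dataset.genome_records, min_codons=config.length_cutoff,
        trim_occupancy=config.trim_occupancy)

    pt_groups, log = identify_orthologs(dataset, config.tissue, config.method,
                                        config)
    if not pt_groups:
        raise RuntimeError(f"{config.method}: no ortholog groups emitted")
    matrix, pt_tree, reps, support = species_tree_from_groups(
        pt_groups, all_records, min_codons=config.length_cutoff,
        trim_occupancy=config.trim_occupancy,
        n_bootstrap=config.n_bootstrap, seed=_stage_seed(config.seed, 61))

    comparison = compare_trees(pt_tree, pg_tree, config.seed,
                               n_null_samples=config.n_null_samples,
                               bootstrap_trees=reps)
    summary = benchmark_groups(pt_groups, dataset)
    pg_summary = benchmark_groups(pg, dataset)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config": {
            "method": config.method, "tissue": config.tissue,
            "profile": config.profile, "length_cutoff": config.length_cutoff,
            "sim": dataclasses.asdict(dataset.config),
        },
        "stage_log": log,
        "n_pg_groups": len(pg),
        "n_pt_groups": len(pt_groups),
        "supermatrix": {
            "n_columns": matrix.alignment.n_columns,
            "n_partitions": len(matrix.partitions),
            "gap_fraction": matrix.gap_fraction,
        },
        "pg_tree": write_newick(pg_tree),
        "pt_tree": write_newick(pt_tree),
        "d_T_true_vs_pg": robinson_foulds(pg_tree, dataset.species_tree),
        "comparison": comparison,
        "benchmark": {
            "pt": dataclasses.asdict(summary),
            "pg": dataclasses.asdict(pg_summary),
        },
    }
    report = _round_floats(report)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        (out_dir / "pt_tree.nwk").write_text(write_newick(pt_tree) + "\n")
        (out_dir / "pg_tree.nwk").write_text(write_newick(pg_tree) + "\n")
    return report
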