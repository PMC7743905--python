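"""Synthetic proteome/transcriptome generator with gold-standard labels.

The generator emulates the data regime that makes transcriptome-based
orthology hard:

* a bifurcating species tree (pure-birth topology, ultrametric, rescaled
  to a chosen root-to-tip height in substitutions/site);
* gene families evolving along it with birth-death duplication and loss,
  optionally seeded by an *ancient* duplication on the family stem — the
  deep paralogy that, combined with differential loss, defeats
  reciprocal-best-hit orthology;
* amino-acid sequences under the 20-state uniform-exchange (Poisson)
  substitution model, with deletion blocks so outputs are true alignments
  with explicit gaps, and a sprinkling of ambiguous ``X`` residues;
* per-gene isoform redundancy (each extra isoform a contiguous
  truncation, so the best representative is well defined);
* per-tissue expression dropout removing whole genes from a species'
  transcriptome (genomes see no dropout).

Every stage is seeded from the master seed by fixed offsets, so a config
fixes every emitted byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .orthology import SequenceRecord, SimilarityEdge
from .supermatrix import Alignment, GAP
from .trees import Node, PhyloTree

AA = "ACDEFGHIKLMNPQRSTVWY"
MAMMAL_TISSUES = ["brain", "kidney", "liver", "heart", "testis", "muscle", "lung"]
PLANT_TISSUES = ["leaf", "root", "stem"]

__all__ = [
    "SimulationConfig",
    "GoldStandard",
    "SyntheticDataset",
    "mammal_like",
    "plant_like",
    "simulate_species_tree",
    "simulate_gene_family",
    "evolve_sequences",
    "make_isoforms",
    "apply_tissue_dropout",
    "similarity_from_sequences",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 22
    tree_height: float = 0.4          # mean root-to-tip substitutions/site
    n_families: int = 200
    dup_rate: float = 0.1             # duplications per unit branch length
    loss_rate: float = 0.15           # losses per unit branch length
    ancient_dup_prob: float = 0.25    # families starting as two deep paralogs
    ancient_dup_depth: float = 0.4    # stem length above the root, per copy
    n_isoforms_mean: float = 1.5
    seq_length: int = 250             # residues (codons) at the root
    indel_rate: float = 0.02          # deletion events per site per unit length
    x_rate: float = 0.01              # ambiguous-residue rate at the tips
    tissues: tuple[str, ...] = tuple(MAMMAL_TISSUES)
    dropout_prob: float = 0.3         # per gene per tissue
    truncation_max: float = 0.4       # max fraction removed from an isoform end
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        for name in ("dup_rate", "loss_rate", "indel_rate", "x_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def mammal_like(**overrides) -> SimulationConfig:
    """22 species, 7 tissues, moderate duplication."""
    return replace(SimulationConfig(), **overrides)


def plant_like(**overrides) -> SimulationConfig:
    """15 species, 3 tissues, heavy ancient duplication (polyploidy-rich
    genomes)."""
    base = SimulationConfig(n_species=15, tree_height=0.5, dup_rate=0.2,
                            ancient_dup_prob=0.5,
                            tissues=tuple(PLANT_TISSUES))
    return replace(base, **overrides)


@dataclass
class GoldStandard:
    """True labels for every emitted sequence.

    ``labels`` maps seq_id -> (family_id, species_id, gene_copy_id,
    isoform_id).  ``lineage_labels`` maps seq_id to the ancestral-lineage
    id (family plus which stem copy the gene descends from) — the
    orthology-database-style label the benchmark classifies against.
    """

    true_species_tree: PhyloTree
    family_trees: list[PhyloTree]
    labels: dict[str, tuple[str, str, str, str]] = field(default_factory=dict)
    lineage_labels: dict[str, str] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    species: list[str]
    species_tree: PhyloTree
    genome_records: dict[str, SequenceRecord]           # no dropout, one per gene
    transcriptomes: dict[str, dict[str, SequenceRecord]]  # tissue -> records
    family_alignments: dict[str, Alignment]             # family -> gene alignment
    gold: GoldStandard
    n_redrawn_families: int = 0

    def transcripts_for(self, tissue: str) -> dict[str, SequenceRecord]:
        return self.transcriptomes[tissue]

    def heterogeneous_sample(self, seed: int) -> dict[str, SequenceRecord]:
        """One randomly chosen tissue per species, pooled — the
        mixed-tissue sampling experiment."""
        rng = np.random.default_rng(seed)
        choice = {sp: self.config.tissues[int(rng.integers(len(self.config.tissues)))]
                  for sp in self.species}
        out: dict[str, SequenceRecord] = {}
        for tissue, records in self.transcriptomes.items():
            for sid, rec in records.items():
                if choice[rec.species_id] == tissue:
                    out[sid] = rec
        return out


def _stage_seed(master: int, offset: int) -> int:
    return (int(master) * 100003 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(n_species: int, tree_height: float,
                          seed: int) -> PhyloTree:
    """Pure-birth (Yule) topology, ultrametric, rescaled so every
    root-to-tip path (hence the mean) equals ``tree_height``."""
    if n_species < 4:
        raise ValueError("n_species must be >= 4")
    rng = np.random.default_rng(seed)
    # (node, birth_time) for active lineages; root splits at t=0
    t = 0.0
    left, right = Node(), Node()
    root = Node(children=[left, right])
    active: list[tuple[Node, float]] = [(left, 0.0), (right, 0.0)]
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.length = t - born
        a, b = Node(), Node()
        node.children = [a, b]
        active.append((a, t))
        active.append((b, t))
    t += rng.exponential(1.0 / len(active))  # time to the present
    order = rng.permutation(len(active))
    width = len(str(n_species))
    for k, idx in enumerate(order):
        node, born = active[int(idx)]
        node.label = f"sp{k + 1:0{width}d}"
        node.length = t - born
    scale = tree_height / t
    for node in root.walk():
        if node.length is not None:
            node.length *= scale
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Gene families (duplication-loss along the species tree)
# ---------------------------------------------------------------------------

def simulate_gene_family(species_tree: PhyloTree, dup_rate: float,
                         loss_rate: float, seed: int,
                         family_id: str = "fam0",
                         ancient_dup_prob: float = 0.0,
                         ancient_dup_depth: float = 0.0,
                         max_redraws: int = 200
                         ) -> tuple[PhyloTree, dict[str, tuple[str, str]], int]:
    """Evolve one gene family along the species tree.

    Gene copies duplicate and are lost at the given rates per unit branch
    length; with probability ``ancient_dup_prob`` the family enters the
    species root as two paralogous copies that diverged
    ``2 * ancient_dup_depth`` earlier on the family stem.  Branch lengths
    of the gene tree inherit the species-tree path lengths.

    Returns ``(gene_tree, tip_info, n_redraws)`` where ``tip_info`` maps
    each tip label to ``(species_id, root_lineage_id)``.  Families
    surviving in fewer than 2 species are redrawn (counted, never
    returned).
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    total_rate = dup_rate + loss_rate

    def evolve(species_node: Node, branch_length: float, lineage: str,
               counter: list[int]) -> Optional[Node]:
        """One gene lineage entering the top of a species branch."""
        consumed = 0.0
        remaining = branch_length
        while total_rate > 0:
            wait = rng.exponential(1.0 / total_rate)
            if wait >= remaining:
                break
            consumed += wait
            remaining -= wait
            if rng.random() < loss_rate / total_rate:
                return None
            # duplication: two lineages continue down the same branch
            a = evolve(species_node, remaining, lineage, counter)
            b = evolve(species_node, remaining, lineage, counter)
            if a is None and b is None:
                return None
            if a is None or b is None:
                survivor = a if a is not None else b
                survivor.length = (survivor.length or 0.0) + consumed
                return survivor
            return Node(children=[a, b], length=consumed)
        # survived the branch
        if species_node.is_tip:
            counter[0] += 1
            label = f"{species_node.label}|{family_id}|g{counter[0]:03d}"
            return Node(label=label, length=branch_length)
        kids = []
        for child in species_node.children:
            sub = evolve(child, child.length or 0.0, lineage, counter)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length = (kids[0].length or 0.0) + branch_length
            return kids[0]
        return Node(children=kids, length=branch_length)

    n_redraws = 0
    for _ in range(max_redraws):
        counter = [0]
        lineage_of_tip: dict[str, str] = {}
        roots: list[tuple[str, Optional[Node]]] = []
        n_lineages = 2 if rng.random() < ancient_dup_prob else 1
        stem = ancient_dup_depth if n_lineages == 2 else 0.0
        for li in range(n_lineages):
            lineage = f"a{li}"
            sub = evolve(species_tree.root, stem, lineage, counter)
            if sub is not None:
                for node in sub.walk():
                    if node.is_tip:
                        lineage_of_tip[node.label] = lineage
            roots.append((lineage, sub))
        alive = [s for _, s in roots if s is not None]
        if not alive:
            n_redraws += 1
            continue
        root = alive[0] if len(alive) == 1 else Node(children=alive)
        if root.is_tip:
            n_redraws += 1
            continue
        if len(alive) == 1:
            root.length = None
        tree = PhyloTree(root)
        species_seen = {lab.split("|")[0] for lab in tree.tip_labels()}
        if len(species_seen) < 2:
            n_redraws += 1
            continue
        tip_info = {lab: (lab.split("|")[0], lineage_of_tip[lab])
                    for lab in tree.tip_labels()}
        return tree, tip_info, n_redraws
    raise RuntimeError(
        f"family {family_id}: no surviving family in {max_redraws} draws "
        "(loss rate too high?)")


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def evolve_sequences(gene_tree: PhyloTree, seq_length: int,
                     indel_rate: float, x_rate: float, seed: int) -> Alignment:
    """Evolve amino-acid sequences down the gene tree.

    Substitutions are Poisson with mean = branch length per site, each
    event jumping to one of the other 19 residues uniformly, so the
    expected proportion of differing sites between two rows at path
    distance b is ``(19/20)(1 - exp(-20 b / 19))`` — exactly inverted by
    the Poisson distance correction.  Indels are modelled as deletion
    blocks (geometric length, mean 3), which keeps all rows in the root
    coordinate frame: the output is a true alignment.  ``X`` is sprinkled
    on tip rows at ``x_rate``.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 20, size=seq_length).astype(np.int16)

    rows: dict[str, np.ndarray] = {}

    def descend(node: Node, seq: np.ndarray) -> None:
        for child in node.children:
            b = child.length or 0.0
            s = seq.copy()
            live = s >= 0
            if b > 0:
                # deletion blocks
                n_del = rng.poisson(indel_rate * b * seq_length)
                for _ in range(n_del):
                    start = int(rng.integers(seq_length))
                    size = int(rng.geometric(1 / 3))
                    s[start:start + size] = -1
                live = s >= 0
                # substitutions: m jumps per site, each to another residue
                m = rng.poisson(b, size=seq_length)
                m[~live] = 0
                while True:
                    hot = m > 0
                    if not hot.any():
                        break
                    jump = rng.integers(1, 20, size=int(hot.sum()))
                    s[hot] = (s[hot] + jump) % 20
                    m[hot] -= 1
            if child.is_tip:
                rows[child.label] = s
            else:
                descend(child, s)

    descend(gene_tree.root, root_seq)
    if not rows:
        raise ValueError("gene tree has no tips below the root")

    out: dict[str, str] = {}
    for label, s in rows.items():
        chars = []
        for v in s:
            if v < 0:
                chars.append(GAP)
            elif x_rate > 0 and rng.random() < x_rate:
                chars.append("X")
            else:
                chars.append(AA[int(v)])
        out[label] = "".join(chars)
    return Alignment(out)


# ---------------------------------------------------------------------------
# Isoforms, dropout, similarity
# ---------------------------------------------------------------------------

def make_isoforms(family_alignment: Alignment,
                  tip_info: dict[str, tuple[str, str]],
                  n_isoforms_mean: float, seed: int,
                  family_id: str,
                  truncation_max: float = 0.4) -> list[SequenceRecord]:
    """Expand each gene copy into >= 1 isoform records.

    Isoform counts are shifted Poisson (1 + Poisson(mean - 1)).  Isoform 0
    is the full gene product; each further isoform removes a contiguous
    block from one end (uniform fraction up to ``truncation_max``), so the
    untruncated isoform always carries the most unambiguous characters.
    """
    if n_isoforms_mean < 1:
        raise ValueError("n_isoforms_mean must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    for tip in sorted(family_alignment.rows):
        row = family_alignment.rows[tip]
        species, _lineage = tip_info[tip]
        n_iso = 1 + int(rng.poisson(n_isoforms_mean - 1))
        residue_positions = [i for i, c in enumerate(row) if c != GAP]
        for k in range(n_iso):
            iso_row = row
            if k > 0 and len(residue_positions) > 2:
                frac = rng.uniform(0.05, truncation_max)
                cut = max(1, int(frac * len(residue_positions)))
                cut = min(cut, len(residue_positions) - 1)
                if rng.random() < 0.5:  # truncate the N-terminal end
                    upto = residue_positions[cut - 1] + 1
                    iso_row = GAP * upto + row[upto:]
                else:
                    from_ = residue_positions[-cut]
                    iso_row = row[:from_] + GAP * (len(row) - from_)
            seq = iso_row.replace(GAP, "")
            if not seq:
                continue
            records.append(SequenceRecord(
                seq_id=f"{tip}|i{k}", species_id=species,
                gene_id=tip, isoform_id=f"i{k}",
                residues=seq, aligned=iso_row, frame_id=family_id))
    return records


def apply_tissue_dropout(records: list[SequenceRecord],
                         tissues: list[str] | tuple[str, ...],
                         dropout_prob: float,
                         seed: int) -> dict[str, dict[str, SequenceRecord]]:
    """Per-tissue transcriptomes: each gene (all its isoforms together) is
    expressed in a tissue independently with probability
    ``1 - dropout_prob``."""
    if not 0 <= dropout_prob <= 1:
        raise ValueError("dropout_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = sorted({r.gene_id for r in records})
    expressed = {g: {t for t in tissues if rng.random() >= dropout_prob}
                 for g in genes}
    out: dict[str, dict[str, SequenceRecord]] = {t: {} for t in tissues}
    for rec in records:
        for t in expressed[rec.gene_id]:
            out[t][rec.seq_id] = rec
    return out


def similarity_from_sequences(records: list[SequenceRecord] | dict[str, SequenceRecord],
                              hit_fraction_denominator: str = "shorter"
                              ) -> list[SimilarityEdge]:
    """All-against-all similarity edges computed from the known alignment
    coordinates (a noiseless stand-in for a BLAST search).

    Only pairs sharing an alignment coordinate frame (``frame_id``, the
    family) are compared; unrelated sequences — whose real BLAST hits
    would fall below any sensible threshold — produce no edge.  For an overlapping pair:
    aligned columns are those where both rows have a residue;
    ``identity_fraction`` is exact matches (X never matches) over aligned
    columns; ``aligned_fraction`` is aligned columns over the query
    length; ``hit_fraction`` divides by the shorter (default) or the query
    sequence length; ``bitscore_like`` is the identity count.
    """
    if hit_fraction_denominator not in ("shorter", "query"):
        raise ValueError("hit_fraction_denominator must be 'shorter' or 'query'")
    recs = list(records.values()) if isinstance(records, dict) else list(records)
    if len(recs) < 2:
        raise ValueError("need at least 2 records")

    frames: dict[object, list[SequenceRecord]] = {}
    for r in recs:
        row = r.aligned if r.aligned is not None else r.residues
        key = r.frame_id if r.frame_id is not None else ("w", len(row))
        frames.setdefault(key, []).append(r)

    edges: list[SimilarityEdge] = []
    for _frame, group in frames.items():
        if len(group) < 2:
            continue
        group = sorted(group, key=lambda r: r.seq_id)
        enc = np.array([np.frombuffer((r.aligned or r.residues).encode(),
                                      dtype=np.uint8) for r in group])
        residue = enc != ord(GAP)
        ambig = enc == ord("X")
        lengths = residue.sum(axis=1)
        for i in range(len(group)):
            for j in range(len(group)):
                if i == j:
                    continue
                both = residue[i] & residue[j]
                overlap = int(both.sum())
                if overlap == 0:
                    continue
                matches = int(((enc[i] == enc[j]) & both
                               & ~ambig[i] & ~ambig[j]).sum())
                qlen = int(lengths[i])
                denom = (min(qlen, int(lengths[j]))
                         if hit_fraction_denominator == "shorter" else qlen)
                edges.append(SimilarityEdge(
                    query=group[i].seq_id, subject=group[j].seq_id,
                    aligned_fraction=overlap / qlen,
                    identity_fraction=matches / overlap,
                    hit_fraction=overlap / denom,
                    bitscore_like=float(matches)))
    return edges


# ---------------------------------------------------------------------------
# Whole-dataset driver
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the whole generator: species tree, families, sequences,
    isoforms, tissue dropout, gold-standard labels."""
    seed = config.seed
    species_tree = simulate_species_tree(
        config.n_species, config.tree_height, _stage_seed(seed, 1))
    species = sorted(species_tree.tip_labels())

    gold = GoldStandard(true_species_tree=species_tree, family_trees=[])
    genome_records: dict[str, SequenceRecord] = {}
    all_transcript_records: list[SequenceRecord] = []
    family_alignments: dict[str, Alignment] = {}
    n_redrawn = 0

    width = len(str(max(config.n_families - 1, 1)))
    for fi in range(config.n_families):
        fam = f"f{fi:0{width}d}"
        tree, tip_info, redraws = simulate_gene_family(
            species_tree, config.dup_rate, config.loss_rate,
            _stage_seed(seed, 1000 + fi), family_id=fam,
            ancient_dup_prob=config.ancient_dup_prob,
            ancient_dup_depth=config.ancient_dup_depth)
        n_redrawn += redraws
        aln = evolve_sequences(tree, config.seq_length, config.indel_rate,
                               config.x_rate, _stage_seed(seed, 200000 + fi))
        gold.family_trees.append(tree)
        family_alignments[fam] = aln
        iso_records = make_isoforms(
            aln, tip_info, config.n_isoforms_mean,
            _stage_seed(seed, 400000 + fi), family_id=fam,
            truncation_max=config.truncation_max)
        all_transcript_records.extend(iso_records)
        for rec in iso_records:
            sp, lineage = tip_info[rec.gene_id]
            gold.labels[rec.seq_id] = (fam, sp, rec.gene_id, rec.isoform_id)
            gold.lineage_labels[rec.seq_id] = f"{fam}.{lineage}"
            if rec.isoform_id == "i0":  # the genome's annotated protein
                gid = f"{rec.gene_id}|p"
                prot = SequenceRecord(
                    seq_id=gid, species_id=sp, gene_id=rec.gene_id,
                    isoform_id="p", residues=rec.residues,
                    aligned=rec.aligned, frame_id=fam)
                genome_records[gid] = prot
                gold.labels[gid] = (fam, sp, rec.gene_id, "p")
                gold.lineage_labels[gid] = f"{fam}.{lineage}"

    transcriptomes = apply_tissue_dropout(
        all_transcript_records, list(config.tissues), config.dropout_prob,
        _stage_seed(seed, 3))

    return SyntheticDataset(
        config=config, species=species, species_tree=species_tree,
        genome_records=genome_records, transcriptomes=transcriptomes,
        family_alignments=family_alignments, gold=gold,
        n_redrawn_families=n_redrawn)
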