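"""Ortholog identification from proteomes and transcriptomes.

Two philosophies are implemented:

* A gene-tree-based pipeline ("tree-based"): all-against-all similarity
  edges are filtered on alignment coverage and identity, Markov clustering
  yields putative homolog groups, per-group gene trees are built, and the
  trees are pruned — spuriously long terminal branches removed, redundant
  same-species isoform tips masked down to their best representative, deep
  paralog clades severed at long internal branches — until what remains is
  a clean one-to-one ortholog group or nothing.  Stringent, so it emits
  fewer groups, but those groups rarely mix paralogs.

* A reciprocal-best-hit pipeline ("rbh"): transcripts are assigned to
  pre-built core ortholog groups when the transcript and the reference
  species' member of the group are each other's best-scoring hit.  Fast
  and permissive, but hidden paralogy — the reference species having lost
  one ancient gene copy while a query species expresses only the other —
  silently produces mixed groups.

Genome-mode orthology (``strict_single_copy_groups``) keeps only clusters
with exactly one member in every species, the conservative route available
when complete gene catalogues exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np

from .supermatrix import Alignment, GAP, neighbor_joining, pairwise_distance, trim_columns
from .trees import Node, PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "SimilarityEdge",
    "HomologCluster",
    "OrthologGroup",
    "CoreOrthologSet",
    "filter_similarity_edges",
    "mcl_cluster",
    "filter_clusters",
    "strict_single_copy_groups",
    "rbh_assign",
    "prune_spurious_terminals",
    "cut_deep_branches",
    "mask_isoforms",
    "extract_one_to_one",
    "tree_based_pipeline",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: a translated transcript or a genome-annotated
    protein.  ``aligned`` optionally carries the gapped row of the record in
    its family's alignment coordinates (the simulator provides it; real
    pipelines would realign instead)."""

    seq_id: str
    species_id: str
    gene_id: str
    isoform_id: str
    residues: str
    aligned: Optional[str] = None
    frame_id: Optional[str] = None  # alignment coordinate frame (family)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.seq_id}: empty sequence")


@dataclass(frozen=True)
class SimilarityEdge:
    """A directed pairwise-similarity hit (BLAST-like)."""

    query: str
    subject: str
    aligned_fraction: float
    identity_fraction: float
    hit_fraction: float
    bitscore_like: float


@dataclass
class HomologCluster:
    members: set[str]

    def species_represented(self, records: dict[str, SequenceRecord]) -> set[str]:
        return {records[m].species_id for m in self.members}


@dataclass
class OrthologGroup:
    """A single-copy (at most one sequence per species) ortholog group."""

    group_id: str
    members: dict[str, str]  # species_id -> seq_id
    method_tag: str  # tree_based | rbh | genome_mcl
    source_cluster: Optional[int] = None

    def __post_init__(self) -> None:
        if len(set(self.members.values())) != len(self.members):
            raise ValueError(f"{self.group_id}: duplicate sequence ids")


@dataclass
class CoreOrthologSet:
    """Reference ortholog groups built from a few well-annotated genomes,
    used to seed reciprocal-best-hit transcript assignment."""

    groups: list[OrthologGroup]
    reference_species: str

    def __post_init__(self) -> None:
        for g in self.groups:
            if self.reference_species not in g.members:
                raise ValueError(
                    f"core group {g.group_id} lacks reference species "
                    f"{self.reference_species}")


# ---------------------------------------------------------------------------
# Similarity filtering and Markov clustering
# ---------------------------------------------------------------------------

def filter_similarity_edges(edges: Iterable[SimilarityEdge],
                            min_aligned: float = 0.3,
                            min_identity: float = 0.3,
                            min_hit_fraction: float = 0.3) -> list[SimilarityEdge]:
    """Keep edges meeting all three inclusive thresholds: aligned-region
    fraction, identity within the aligned region, and hit fraction."""
    return [e for e in edges
            if e.aligned_fraction >= min_aligned
            and e.identity_fraction >= min_identity
            and e.hit_fraction >= min_hit_fraction]


def _connected_components(nodes: list[str],
                          adjacency: dict[str, set[str]]) -> list[list[str]]:
    seen: set[str] = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adjacency.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def _mcl_dense(names: list[str], W: np.ndarray, inflation: float,
               tolerance: float, max_iter: int) -> list[set[str]]:
    """Dense-matrix Markov clustering on one connected component.

    Self-loops are set to each node's maximum edge weight before the first
    normalization; iteration alternates expansion (matrix square) and
    inflation (element-wise power, column renormalize) until the largest
    column change falls below ``tolerance``.
    """
    M = W.astype(float).copy()
    loops = M.max(axis=1)
    loops[loops <= 0] = 1.0
    np.fill_diagonal(M, loops)
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = np.power(M, inflation)
        M[M < 1e-300] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tolerance:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {max_iter} iterations "
            f"(residual {np.abs(M - prev).max():.2e})")
    support = M > 1e-9
    adj = {names[i]: {names[j] for j in np.nonzero(support[i] | support[:, i])[0]}
           for i in range(len(names))}
    return [set(c) for c in _connected_components(names, adj)]


def mcl_cluster(edges: Iterable[SimilarityEdge], inflation: float = 1.4,
                tolerance: float = 1e-9, max_iter: int = 200,
                nodes: Optional[Iterable[str]] = None) -> list[HomologCluster]:
    """Markov clustering of the similarity graph into putative homolog
    clusters.

    Edge weights are ``bitscore_like`` symmetrized by max.  The graph is
    first split into connected components (clusters never span them), and
    dense MCL runs per component.  ``nodes`` may add isolated sequences,
    which come back as singleton clusters.
    """
    weights: dict[tuple[str, str], float] = {}
    adjacency: dict[str, set[str]] = {}
    names: set[str] = set(nodes) if nodes else set()
    for e in edges:
        if e.query == e.subject:
            continue
        a, b = sorted((e.query, e.subject))
        key = (a, b)
        weights[key] = max(weights.get(key, 0.0), float(e.bitscore_like))
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
        names.update(key)

    clusters: list[HomologCluster] = []
    for comp in _connected_components(sorted(names), adjacency):
        if len(comp) == 1:
            clusters.append(HomologCluster(members=set(comp)))
            continue
        idx = {n: i for i, n in enumerate(comp)}
        W = np.zeros((len(comp), len(comp)))
        for (a, b), w in weights.items():
            if a in idx and b in idx:
                W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
        for part in _mcl_dense(comp, W, inflation, tolerance, max_iter):
            clusters.append(HomologCluster(members=part))
    clusters.sort(key=lambda c: min(c.members))
    return clusters


def filter_clusters(clusters: list[HomologCluster],
                    records: dict[str, SequenceRecord],
                    all_species: Iterable[str],
                    min_length: int = 30,
                    min_species_fraction: float = 0.5) -> list[HomologCluster]:
    """Drop members shorter than ``min_length`` residues first, then drop
    clusters representing fewer than ``ceil(fraction * n_species)`` species
    — evaluated on the post-length-filter membership."""
    n_all = len(set(all_species))
    need = int(np.ceil(min_species_fraction * n_all))
    out = []
    for c in clusters:
        kept = {m for m in c.members if records[m].length >= min_length}
        if not kept:
            continue
        species = {records[m].species_id for m in kept}
        if len(species) >= need:
            out.append(HomologCluster(members=kept))
    return out


def strict_single_copy_groups(clusters: list[HomologCluster],
                              records: dict[str, SequenceRecord],
                              all_species: Iterable[str]) -> list[OrthologGroup]:
    """Genome-mode orthology: keep clusters with exactly one member in
    every species; anything with a missing species or an extra copy is
    discarded."""
    all_species = set(all_species)
    groups = []
    for i, c in enumerate(sorted(clusters, key=lambda c: min(c.members))):
        by_species: dict[str, list[str]] = {}
        for m in sorted(c.members):
            by_species.setdefault(records[m].species_id, []).append(m)
        if set(by_species) != all_species:
            continue
        if any(len(v) > 1 for v in by_species.values()):
            continue
        groups.append(OrthologGroup(
            group_id=f"pg{len(groups):05d}",
            members={s: v[0] for s, v in by_species.items()},
            method_tag="genome_mcl", source_cluster=i))
    return groups


# ---------------------------------------------------------------------------
# Reciprocal-best-hit assignment
# ---------------------------------------------------------------------------

def _best_hit(candidates: list[tuple[float, str]]) -> Optional[str]:
    """Highest score wins; ties break to the lexicographically smallest id."""
    if not candidates:
        return None
    return min(candidates, key=lambda t: (-t[0], t[1]))[1]


def rbh_assign(transcripts: dict[str, SequenceRecord],
               core: CoreOrthologSet,
               edges: Iterable[SimilarityEdge],
               min_species_fraction: float = 0.5,
               all_species: Optional[Iterable[str]] = None) -> list[OrthologGroup]:
    """Assign transcripts to core ortholog groups by reciprocal best hit
    against the reference species.

    A transcript ``t`` of species ``s`` joins core group ``g`` iff the
    best-scoring reference-species protein hit of ``t`` is ``g``'s
    reference member ``r``, and the best hit of ``r`` among species ``s``
    transcripts is ``t``.  A species claimed twice within one group is
    dropped from it (single-copy rule), and groups below the species
    threshold are discarded.
    """
    ref_members = {g.members[core.reference_species]: g for g in core.groups}

    best_ref_of: dict[str, list[tuple[float, str]]] = {}
    best_tx_of: dict[tuple[str, str], list[tuple[float, str]]] = {}
    for e in edges:
        if e.query in transcripts and e.subject in ref_members:
            best_ref_of.setdefault(e.query, []).append(
                (e.bitscore_like, e.subject))
        if e.query in ref_members and e.subject in transcripts:
            sp = transcripts[e.subject].species_id
            best_tx_of.setdefault((e.query, sp), []).append(
                (e.bitscore_like, e.subject))

    assigned: dict[str, dict[str, list[str]]] = {}  # group_id -> species -> txs
    for t in sorted(transcripts):
        r = _best_hit(best_ref_of.get(t, []))
        if r is None:
            continue
        sp = transcripts[t].species_id
        if _best_hit(best_tx_of.get((r, sp), [])) != t:
            continue
        g = ref_members[r]
        assigned.setdefault(g.group_id, {}).setdefault(sp, []).append(t)

    species_pool = (set(all_species) if all_species is not None
                    else {rec.species_id for rec in transcripts.values()})
    need = int(np.ceil(min_species_fraction * len(species_pool)))
    out = []
    for g in core.groups:
        by_species = assigned.get(g.group_id, {})
        members = {sp: txs[0] for sp, txs in by_species.items()
                   if len(txs) == 1}  # species with >1 reciprocal tx dropped
        if len(members) >= need:
            out.append(OrthologGroup(group_id=f"rbh_{g.group_id}",
                                     members=members, method_tag="rbh"))
    return out


# ---------------------------------------------------------------------------
# Gene-tree pruning (tree-based method)
# ---------------------------------------------------------------------------

def _suppress_unary(node: Node) -> Node:
    """Collapse degree-2 nodes created by pruning, summing edge lengths."""
    node.children = [_suppress_unary(c) for c in node.children]
    if len(node.children) == 1:
        child = node.children[0]
        if node.length is not None or child.length is not None:
            child.length = (node.length or 0.0) + (child.length or 0.0)
        else:
            child.length = node.length
        return child
    return node


def _remove_tips(tree: PhyloTree, drop: set[str]) -> Optional[PhyloTree]:
    def prune(node: Node) -> Optional[Node]:
        if node.is_tip:
            return None if node.label in drop else node
        kids = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kids:
            return None
        node.children = kids
        return node

    root = prune(tree.root.copy())
    if root is None or root.is_tip:
        return None
    root = _suppress_unary(root)
    if root.is_tip:
        return None
    if len(root.children) == 1:  # pragma: no cover - suppressed above
        root = root.children[0]
    return PhyloTree(root)


def prune_spurious_terminals(gene_tree: PhyloTree, ratio: float = 10.0,
                             min_length: float = 0.6) -> PhyloTree:
    """Remove terminal branches that are both longer than ``min_length``
    and more than ``ratio`` times their sister branch (strict inequalities,
    matching "more than ten times ... and longer than 0.6").

    Applied to fixpoint: removing a tip can expose a new violator once the
    intervening node is suppressed.  With several sisters the longest
    sister branch is the comparator, the conservative choice.
    """
    tree = gene_tree.copy()
    while True:
        drop: set[str] = set()
        parents: dict[int, Node] = {}
        for node in tree.root.walk():
            for c in node.children:
                parents[id(c)] = node
        for tip in tree.tips():
            if tip.length is None or tip.length <= min_length:
                continue
            parent = parents.get(id(tip))
            if parent is None:
                continue
            sisters = [c for c in parent.children if c is not tip]
            sister_lengths = [c.length for c in sisters if c.length is not None]
            if not sister_lengths:
                continue
            if tip.length > ratio * max(sister_lengths):
                drop.add(tip.label)
        if not drop:
            return tree
        pruned = _remove_tips(tree, drop)
        if pruned is None or pruned.n_tips() < 2:
            return tree if pruned is None else pruned
        tree = pruned


def cut_deep_branches(gene_tree: PhyloTree,
                      max_internal: float = 0.5) -> list[PhyloTree]:
    """Sever every internal edge longer than ``max_internal`` (removing
    deep paralog connections) and return the resulting subtrees, each with
    at least 2 tips; singletons are discarded."""
    tree = gene_tree.copy()
    fragments: list[PhyloTree] = []

    def collect(node: Node) -> Node:
        """Detach over-long internal child edges, queueing the subtrees."""
        kept = []
        for c in node.children:
            c = collect(c)
            if (not c.is_tip and c.length is not None
                    and c.length > max_internal):
                c.length = None
                fragments.append(PhyloTree(_suppress_unary(c.copy())
                                           if len(c.children) == 1 else c))
            else:
                kept.append(c)
        node.children = kept
        return node

    root = collect(tree.root)
    root = _suppress_unary(root)
    if not root.is_tip:
        fragments.append(PhyloTree(root))
    out = []
    for frag in fragments:
        frag = PhyloTree(_suppress_unary(frag.root))
        if frag.n_tips() >= 2:
            out.append(frag)
    out.sort(key=lambda t: min(t.tip_labels()))
    return out


def mask_isoforms(gene_tree: PhyloTree, alignment: Alignment,
                  species_of: Callable[[str], str]) -> PhyloTree:
    """Collapse monophyletic or paraphyletic runs of same-species tips to
    the single tip with the most unambiguous (non-gap, non-X) characters.

    Operationally, on the unrooted adjacency (a bifurcating root is
    spliced out): wherever an internal node touches two or more tips of
    the same species, keep the best one; suppress the degree-2 nodes this
    creates and repeat until stable.  Iterated collapse resolves
    paraphyletic grades too, while same-species tips separated by another
    species' tip never merge.  Ties break to the smaller sequence id.
    """
    for label in gene_tree.tip_labels():
        if label not in alignment.rows:
            raise KeyError(f"tip {label} missing from alignment")
    counts = {label: alignment.unambiguous_count(label)
              for label in gene_tree.tip_labels()}

    tree = gene_tree.copy()
    while True:
        # unrooted adjacency: each internal node's adjacent tips
        adjacent_tips: dict[int, list[Node]] = {}
        for node in tree.root.walk():
            for c in node.children:
                if c.is_tip:
                    adjacent_tips.setdefault(id(node), []).append(c)
        if len(tree.root.children) == 2:
            a, b = tree.root.children
            if a.is_tip and not b.is_tip:
                adjacent_tips.setdefault(id(b), []).append(a)
            elif b.is_tip and not a.is_tip:
                adjacent_tips.setdefault(id(a), []).append(b)

        drop: set[str] = set()
        for tips in adjacent_tips.values():
            by_species: dict[str, list[Node]] = {}
            for t in tips:
                by_species.setdefault(species_of(t.label), []).append(t)
            for sp, group in by_species.items():
                if len(group) < 2:
                    continue
                best = min(group, key=lambda t: (-counts[t.label], t.label))
                drop.update(t.label for t in group if t is not best)
        if not drop:
            return tree
        pruned = _remove_tips(tree, drop)
        if pruned is None:
            return tree
        tree = pruned


def extract_one_to_one(gene_tree: PhyloTree,
                       records: dict[str, SequenceRecord],
                       all_species: Iterable[str],
                       min_species_fraction: float = 0.5,
                       group_id: str = "grp",
                       source_cluster: Optional[int] = None) -> Optional[OrthologGroup]:
    """Accept a pruned gene tree as a one-to-one ortholog group iff no
    species appears twice and the species count clears the threshold."""
    all_species = set(all_species)
    need = int(np.ceil(min_species_fraction * len(all_species)))
    members: dict[str, str] = {}
    for label in gene_tree.tip_labels():
        sp = records[label].species_id
        if sp in members:
            return None
        members[sp] = label
    if len(members) < need:
        return None
    return OrthologGroup(group_id=group_id, members=members,
                         method_tag="tree_based", source_cluster=source_cluster)


# ---------------------------------------------------------------------------
# End-to-end tree-based pipeline
# ---------------------------------------------------------------------------

def _default_gene_tree_builder(alignment: Alignment) -> PhyloTree:
    taxa, D = pairwise_distance(alignment, correction="poisson")
    return neighbor_joining(taxa, D)


def _cluster_alignment(members: list[str],
                       records: dict[str, SequenceRecord]) -> Alignment:
    """Alignment of a cluster from the records' stored gapped rows.

    Rows sharing a coordinate system (same row length) stack directly;
    in the rare case of mixed systems the blocks are laid out diagonally
    with gap padding, which keeps downstream arithmetic well defined while
    contributing no cross-block signal.
    """
    by_width: dict[int, list[str]] = {}
    for m in members:
        rec = records[m]
        row = rec.aligned if rec.aligned is not None else rec.residues
        by_width.setdefault(len(row), []).append(m)
    if len(by_width) == 1:
        return Alignment({m: (records[m].aligned or records[m].residues)
                          for m in members})
    widths = sorted(by_width)
    total = sum(widths)
    rows = {}
    offset = 0
    for w in widths:
        for m in by_width[w]:
            row = records[m].aligned or records[m].residues
            rows[m] = GAP * offset + row + GAP * (total - offset - w)
        offset += w
    return Alignment(rows)


def tree_based_pipeline(transcripts: dict[str, SequenceRecord],
                        edges: Iterable[SimilarityEdge],
                        all_species: Iterable[str],
                        gene_tree_builder: Callable[[Alignment], PhyloTree] = _default_gene_tree_builder,
                        min_aligned: float = 0.3,
                        min_identity: float = 0.3,
                        min_hit_fraction: float = 0.3,
                        inflation: float = 1.4,
                        min_member_length: int = 30,
                        min_species_fraction: float = 0.5,
                        trim_occupancy: float = 0.1,
                        terminal_ratio: float = 10.0,
                        terminal_min_length: float = 0.6,
                        deep_branch_cutoff: float = 0.5,
                        gene_trees: Optional[dict[int, PhyloTree]] = None
                        ) -> tuple[list[OrthologGroup], dict[str, int]]:
    """The gene-tree-based ortholog identification pipeline, end to end.

    Stages: similarity-edge filtering -> Markov clustering -> cluster
    filtering -> per-cluster alignment trimming -> gene tree (built by
    ``gene_tree_builder`` or looked up in ``gene_trees`` by cluster index,
    so externally inferred trees can be dropped in) -> spurious-terminal
    pruning -> isoform masking -> deep-branch cutting -> one-to-one
    extraction.  Returns the groups and a per-stage accounting log.
    """
    all_species = sorted(set(all_species))
    species_of = lambda seq_id: transcripts[seq_id].species_id

    kept_edges = filter_similarity_edges(
        list(edges), min_aligned, min_identity, min_hit_fraction)
    clusters = mcl_cluster(kept_edges, inflation=inflation,
                           nodes=transcripts.keys())
    log = {"clusters_initial": len(clusters)}
    clusters = filter_clusters(clusters, transcripts, all_species,
                               min_length=min_member_length,
                               min_species_fraction=min_species_fraction)
    log["clusters_after_filter"] = len(clusters)
    log["clusters_discarded_filter"] = log["clusters_initial"] - len(clusters)

    groups: list[OrthologGroup] = []
    n_fragments = 0
    discarded_small = discarded_extract = 0
    for ci, cluster in enumerate(clusters):
        members = sorted(cluster.members)
        aln = trim_columns(_cluster_alignment(members, transcripts),
                           trim_occupancy)
        if gene_trees is not None and ci in gene_trees:
            tree = gene_trees[ci]
        else:
            if len(members) < 3:
                discarded_small += 1
                continue
            try:
                tree = gene_tree_builder(aln)
            except ValueError as exc:
                logger.warning("cluster %d: gene tree failed (%s)", ci, exc)
                discarded_small += 1
                continue
        tree = prune_spurious_terminals(tree, ratio=terminal_ratio,
                                        min_length=terminal_min_length)
        tree = mask_isoforms(tree, aln, species_of)
        fragments = cut_deep_branches(tree, max_internal=deep_branch_cutoff)
        n_fragments += len(fragments)
        for fi, frag in enumerate(fragments):
            group = extract_one_to_one(
                frag, transcripts, all_species,
                min_species_fraction=min_species_fraction,
                group_id=f"tb{ci:05d}_{fi}", source_cluster=ci)
            if group is None:
                discarded_extract += 1
            else:
                groups.append(group)
    log["clusters_too_small"] = discarded_small
    log["fragments"] = n_fragments
    log["fragments_rejected"] = discarded_extract
    log["groups_emitted"] = len(groups)
    return groups, log
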