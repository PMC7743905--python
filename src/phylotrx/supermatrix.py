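"""Alignment handling, concatenation, distances, neighbor joining, and
column bootstrap.

Alignments are gapped amino-acid matrices.  ``-`` is a gap and ``X`` an
ambiguous residue; both are excluded from a row's "unambiguous" count and
from pairwise distance comparisons (pairwise deletion).  Distances use the
20-state uniform-exchange (Poisson) correction
``d = -(19/20) ln(1 - 20 p / 19)``, whose inverse is the expected
p-distance of the same substitution model the simulator uses, so
noise-free simulated data yields additive distances and neighbor joining
provably recovers the generating topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trees import Node, PhyloTree

GAP = "-"
AMBIG = "X"

__all__ = [
    "Alignment",
    "Supermatrix",
    "trim_columns",
    "filter_by_length",
    "concatenate",
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap_trees",
]


class Alignment:
    """A gapped residue matrix keyed by sequence id."""

    def __init__(self, rows: dict[str, str]):
        if not rows:
            raise ValueError("alignment needs at least one row")
        lengths = {len(r) for r in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.rows = dict(rows)
        self.n_columns = lengths.pop()

    def unambiguous_count(self, seq_id: str) -> int:
        """Residues that are neither gap nor X."""
        row = self.rows[seq_id]
        return sum(1 for c in row if c != GAP and c != AMBIG)

    def subset(self, seq_ids) -> "Alignment":
        return Alignment({s: self.rows[s] for s in seq_ids})

    def select_columns(self, cols) -> "Alignment":
        return Alignment(
            {s: "".join(row[c] for c in cols) for s, row in self.rows.items()})

    @property
    def gap_fraction(self) -> float:
        total = len(self.rows) * self.n_columns
        gaps = sum(row.count(GAP) for row in self.rows.values())
        return gaps / total if total else 0.0

    def __len__(self) -> int:
        return len(self.rows)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({len(self.rows)} rows x {self.n_columns} cols)"


@dataclass
class Supermatrix:
    """Concatenation of per-group alignments keyed by species, with the
    0-based half-open column range of each source group recorded."""

    alignment: Alignment
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def gap_fraction(self) -> float:
        return self.alignment.gap_fraction


def trim_columns(alignment: Alignment, min_occupancy: float) -> Alignment:
    """Keep a column iff its fraction of non-gap characters is at least
    ``min_occupancy`` (the Phyutility ``-clean`` rule).  Idempotent; the
    row set never changes."""
    if not 0 < min_occupancy <= 1:
        raise ValueError("min_occupancy must be in (0, 1]")
    n_rows = len(alignment.rows)
    rows = list(alignment.rows.values())
    keep = [c for c in range(alignment.n_columns)
            if sum(1 for r in rows if r[c] != GAP) / n_rows >= min_occupancy]
    return alignment.select_columns(keep)


def filter_by_length(alignments: dict, min_codons: int) -> dict:
    """Drop alignments shorter than ``min_codons`` columns (inclusive keep).

    The profile conventions: 500 for the permissive reciprocal-best-hit
    mammal analysis, 150 for tree-based mammal and all plant analyses.
    """
    return {k: a for k, a in alignments.items() if a.n_columns >= min_codons}


def concatenate(groups, all_species) -> Supermatrix:
    """Concatenate per-group alignments keyed by species into one
    supermatrix; a species missing from a group is gap-filled over that
    group's partition.

    ``groups`` is an iterable of ``(group_id, {species_id: row})`` or
    ``(group_id, Alignment)`` with species ids as row keys.
    """
    all_species = sorted(all_species)
    chunks: dict[str, list[str]] = {s: [] for s in all_species}
    partitions: list[tuple[str, int, int]] = []
    start = 0
    for group_id, aln in groups:
        rows = aln.rows if isinstance(aln, Alignment) else dict(aln)
        if not rows:
            continue
        widths = {len(r) for r in rows.values()}
        if len(widths) != 1:
            raise ValueError(f"group {group_id}: ragged rows")
        width = widths.pop()
        unknown = set(rows) - set(all_species)
        if unknown:
            raise ValueError(f"group {group_id}: rows for unknown species {sorted(unknown)}")
        for s in all_species:
            chunks[s].append(rows.get(s, GAP * width))
        partitions.append((group_id, start, start + width))
        start += width
    if start == 0:
        raise ValueError("nothing to concatenate")
    alignment = Alignment({s: "".join(parts) for s, parts in chunks.items()})
    return Supermatrix(alignment=alignment, partitions=partitions)


def pairwise_distance(matrix, correction: str = "poisson") -> tuple[list[str], np.ndarray]:
    """Pairwise distances under pairwise deletion of gap/X sites.

    ``correction="p"`` returns raw mismatch proportions;
    ``correction="poisson"`` applies the 20-state correction
    ``d = -(19/20) ln(1 - 20p/19)`` and raises on saturation (p >= 19/20).
    Returns ``(taxa, D)`` with a symmetric zero-diagonal matrix.
    """
    aln = matrix.alignment if isinstance(matrix, Supermatrix) else matrix
    taxa = sorted(aln.rows)
    if len(taxa) < 2:
        raise ValueError("need at least 2 sequences")
    if correction not in ("p", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")

    enc = np.array([np.frombuffer(aln.rows[t].encode(), dtype=np.uint8)
                    for t in taxa])
    valid = (enc != ord(GAP)) & (enc != ord(AMBIG))
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {taxa[i]} and {taxa[j]}")
            p = float((enc[i][both] != enc[j][both]).sum()) / compared
            if correction == "poisson":
                if p >= 19 / 20:
                    raise ValueError(
                        f"saturated distance (p={p:.3f}) between "
                        f"{taxa[i]} and {taxa[j]}")
                d = -(19 / 20) * math.log(1 - 20 * p / 19)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return taxa, D


def neighbor_joining(taxa, distances: np.ndarray) -> PhyloTree:
    """Standard neighbor joining.

    Exact on additive inputs (recovers the generating tree's topology and
    branch lengths).  Negative branch-length estimates are clamped to zero
    with the deficit shifted onto the sister branch, preserving the pair's
    summed length.  Output is an unrooted binary tree represented with a
    trifurcating root.
    """
    D = np.asarray(distances, dtype=float)
    n = len(taxa)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match taxa")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0, atol=1e-8):
        raise ValueError("distance matrix diagonal must be zero")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes = [Node(label=str(t)) for t in taxa]
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_s, j_s = divmod(int(np.argmin(Q)), m)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        i, j = active[i_s], active[j_s]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_s] - r[j_s]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length, nodes[j].length = li, lj
        parent = Node(children=[nodes[i], nodes[j]])
        # distances from the new node to the remaining ones
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    # three-point formulas for the final star
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(length, 0.0)
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root, rooted=False)


def bootstrap_trees(matrix, n_reps: int = 200, seed: int = 0,
                    builder=None, correction: str = "poisson"):
    """Nonparametric column bootstrap.

    Each replicate resamples all columns with replacement and rebuilds a
    tree (default: neighbor joining on corrected distances).  Returns
    ``(replicate_trees, support)`` where ``support`` maps each bipartition
    of the main tree to the percentage of replicates containing it.
    """
    from .trees import bipartitions as _bip

    aln = matrix.alignment if isinstance(matrix, Supermatrix) else matrix
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    def default_builder(a: Alignment) -> PhyloTree:
        taxa, D = pairwise_distance(a, correction=correction)
        return neighbor_joining(taxa, D)

    build = builder or default_builder
    main_tree = build(aln)
    rng = np.random.default_rng(seed)
    reps = []
    failures = 0
    while len(reps) < n_reps:
        cols = rng.integers(0, aln.n_columns, size=aln.n_columns)
        try:
            reps.append(build(aln.select_columns([int(c) for c in cols])))
        except ValueError:
            # a resample can leave a species pair with no shared sites (or
            # a saturated distance) on gap-rich matrices; redraw
            failures += 1
            if failures > 10 * n_reps:
                raise
    if failures:
        import warnings

        warnings.warn(f"{failures} bootstrap resamples were not buildable "
                      "and were redrawn", stacklevel=2)

    main_splits = _bip(main_tree)
    counts = {bp: 0 for bp in main_splits}
    for t in reps:
        found = _bip(t)
        for bp in main_splits:
            if bp in found:
                counts[bp] += 1
    support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return main_tree, reps, support
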