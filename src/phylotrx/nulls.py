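"""Null distributions for the topological distance d_T.

Two calibration schemes for an observed distance between a transcriptome
tree and its genome-based reference:

* ``random_tree`` — d_T between the reference and fully random topologies
  on the same taxa.  Random trees are built by recursive random splitting
  of the taxon set (the classic ``rtree``-style generator); this is NOT
  uniform over labelled topologies, and a uniform-coalescent alternative is
  available via ``method="coalescent"``.
* ``tip_swap`` — d_T between the reference and copies of it in which k
  randomly chosen tip pairs have been exchanged, giving a graded null
  ("how many tip swaps away is the observed tree?").

P-values are one-sided and inclusive: the probability that a null draw is
less than or equal to the observed d_T.

The module also carries the exact two-tailed sign test used to compare two
ortholog-identification methods across paired per-tissue distances, and the
per-replicate d_T distribution for bootstrap tree sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .trees import PhyloTree, Node, bipartitions, rf_from_splits, robinson_foulds

__all__ = [
    "NullScheme",
    "NullDistribution",
    "PValueResult",
    "random_tree",
    "swap_tips",
    "build_null",
    "tip_swap_pvalue",
    "exact_sign_test",
    "bootstrap_dt_distribution",
]


class NullScheme(str, Enum):
    random_tree = "random_tree"
    tip_swap = "tip_swap"


@dataclass
class NullDistribution:
    scheme: NullScheme
    reference_tree: PhyloTree
    samples: list[int]
    seed: int
    n_pairs_swapped: Optional[int] = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class PValueResult:
    p: float
    d_obs: int
    scheme: NullScheme
    n_samples: int
    n_pairs_swapped: Optional[int] = None


def random_tree(taxa: Sequence[str], seed=None,
                method: str = "splitting") -> PhyloTree:
    """Random fully resolved binary topology on the given taxa.

    ``method="splitting"`` recursively splits each taxon subset at a
    uniformly chosen size into two random parts.  ``method="coalescent"``
    joins uniformly chosen lineage pairs instead, which is uniform over
    labelled rooted topologies.  No branch lengths are assigned.
    """
    taxa = sorted(set(taxa))
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa for a random tree")
    rng = np.random.default_rng(seed)

    if method == "splitting":
        pool = list(taxa)
        rng.shuffle(pool)

        def split(names: list[str]) -> Node:
            if len(names) == 1:
                return Node(label=names[0])
            k = int(rng.integers(1, len(names)))
            idx = rng.permutation(len(names))
            left = [names[i] for i in idx[:k]]
            right = [names[i] for i in idx[k:]]
            return Node(children=[split(left), split(right)])

        return PhyloTree(split(pool))

    if method == "coalescent":
        nodes = [Node(label=t) for t in taxa]
        while len(nodes) > 1:
            i, j = rng.choice(len(nodes), size=2, replace=False)
            i, j = int(i), int(j)
            merged = Node(children=[nodes[i], nodes[j]])
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
            nodes.append(merged)
        return PhyloTree(nodes[0])

    raise ValueError(f"unknown method {method!r}")


def swap_tips(tree: PhyloTree, n_pairs: int, seed=None,
              allow_reuse: bool = True) -> PhyloTree:
    """Exchange the labels of ``n_pairs`` sequentially drawn random tip
    pairs; the tree shape and taxon set are untouched.

    Each swap picks two distinct tips uniformly.  By default a tip may be
    picked again in a later pair (sequential swaps are independent); set
    ``allow_reuse=False`` to force the 2*n_pairs tips to be distinct.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    out = tree.copy()
    tips = out.tips()
    if len(tips) < 4:
        raise ValueError("need at least 4 tips to swap")
    rng = np.random.default_rng(seed)
    if allow_reuse:
        for _ in range(n_pairs):
            i, j = rng.choice(len(tips), size=2, replace=False)
            tips[int(i)].label, tips[int(j)].label = (
                tips[int(j)].label, tips[int(i)].label)
    else:
        if 2 * n_pairs > len(tips):
            raise ValueError("not enough tips for disjoint pairs")
        chosen = rng.choice(len(tips), size=2 * n_pairs, replace=False)
        for k in range(n_pairs):
            i, j = int(chosen[2 * k]), int(chosen[2 * k + 1])
            tips[i].label, tips[j].label = tips[j].label, tips[i].label
    return out


def build_null(reference: PhyloTree, scheme: NullScheme | str,
               n_samples: int, seed: int,
               n_pairs_swapped: Optional[int] = None,
               allow_reuse: bool = True) -> NullDistribution:
    """Sample a d_T null distribution against ``reference``.

    Each sample is d_T(reference, T_i) where T_i is drawn per ``scheme``.
    Fully deterministic given ``seed``.
    """
    scheme = NullScheme(scheme)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if scheme is NullScheme.tip_swap and not n_pairs_swapped:
        raise ValueError("tip_swap scheme needs n_pairs_swapped >= 1")
    taxa = sorted(reference.taxa())
    ref_splits = bipartitions(reference)
    rng = np.random.default_rng(seed)
    samples: list[int] = []
    for _ in range(n_samples):
        child_seed = int(rng.integers(0, 2**31 - 1))
        if scheme is NullScheme.random_tree:
            t = random_tree(taxa, seed=child_seed)
        else:
            t = swap_tips(reference, n_pairs_swapped, seed=child_seed,
                          allow_reuse=allow_reuse)
        samples.append(rf_from_splits(ref_splits, bipartitions(t)))
    return NullDistribution(scheme=scheme, reference_tree=reference,
                            samples=samples, seed=seed,
                            n_pairs_swapped=n_pairs_swapped)


def tip_swap_pvalue(null: NullDistribution, d_obs: int) -> PValueResult:
    """P(null d_T <= d_obs), the inclusive one-sided tail probability.

    Under a tip-swap null, a small p says the observed tree is closer to
    the reference than trees a few label swaps away, i.e. the disagreement
    is milder than the corresponding amount of tip shuffling.
    """
    if d_obs < 0:
        raise ValueError("d_obs must be >= 0")
    if null.n_samples == 0:
        raise ValueError("empty null distribution")
    count = sum(1 for s in null.samples if s <= d_obs)
    return PValueResult(p=count / null.n_samples, d_obs=d_obs,
                        scheme=null.scheme, n_samples=null.n_samples,
                        n_pairs_swapped=null.n_pairs_swapped)


def exact_sign_test(n_positive: int, n_negative: int) -> float:
    """Two-tailed exact sign test (binomial with success probability 1/2).

    Ties are expected to have been dropped by the caller.  Returns
    ``min(1, 2 * sum_{i<=min(n+, n-)} C(n, i) / 2^n)``.
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("counts must be non-negative")
    n = n_positive + n_negative
    if n < 1:
        raise ValueError("need at least one untied pair")
    k = min(n_positive, n_negative)
    tail = sum(math.comb(n, i) for i in range(k + 1)) / 2 ** n
    return min(1.0, 2.0 * tail)


def bootstrap_dt_distribution(reference: PhyloTree,
                              bootstrap_trees: Sequence[PhyloTree]) -> list[int]:
    """d_T from ``reference`` to each bootstrap replicate tree, in order."""
    if not bootstrap_trees:
        raise ValueError("need at least one bootstrap tree")
    return [robinson_foulds(reference, t) for t in bootstrap_trees]
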