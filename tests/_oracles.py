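"""Independent oracle implementations shared across test modules.

These deliberately avoid the production code paths they are used to
check: splits are enumerated by explicit edge deletion on an adjacency
graph, and additive distances are read off tree paths directly.
"""

import numpy as np

from phylotrx.trees import PhyloTree


def oracle_splits(tree: PhyloTree) -> set[frozenset]:
    """Brute-force split enumeration by edge deletion on the unrooted
    adjacency graph."""
    adj: dict[int, set[int]] = {}
    label_of: dict[int, str] = {}
    for node in tree.root.walk():
        adj.setdefault(id(node), set())
        if node.is_tip:
            label_of[id(node)] = node.label
        for c in node.children:
            adj[id(node)].add(id(c))
            adj.setdefault(id(c), set()).add(id(node))
    root = id(tree.root)
    if len(tree.root.children) == 2:  # splice out a bifurcating root
        a, b = (id(c) for c in tree.root.children)
        adj[a].discard(root)
        adj[b].discard(root)
        adj[a].add(b)
        adj[b].add(a)
        del adj[root]
    all_tips = frozenset(label_of.values())
    splits = set()
    edges = {tuple(sorted((u, v))) for u in adj for v in adj[u]}
    for u, v in edges:
        seen, stack = {u}, [u]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if (x, y) in ((u, v), (v, u)) or y in seen:
                    continue
                seen.add(y)
                stack.append(y)
        side = frozenset(label_of[n] for n in seen if n in label_of)
        if 2 <= len(side) <= len(all_tips) - 2:
            splits.add(frozenset((side, all_tips - side)))
    return splits


def as_pairs(splits) -> set[frozenset]:
    """Production Bipartition objects as orientation-free side pairs."""
    return {frozenset((bp.side_a, bp.side_b)) for bp in splits}


def tree_distances(tree: PhyloTree):
    """Path-length (additive) distances between the tips of a tree."""
    taxa = sorted(tree.tip_labels())
    paths = {}

    def collect(node, depth):
        depth = depth + (node.length or 0.0)
        if node.is_tip:
            return {node.label: depth}
        merged = {}
        for c in node.children:
            sub = collect(c, depth)
            for known_tip, d1 in merged.items():
                for new_tip, d2 in sub.items():
                    paths[frozenset((known_tip, new_tip))] = d1 + d2 - 2 * depth
            merged.update(sub)
        return merged

    collect(tree.root, 0.0)
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = paths[frozenset((taxa[i], taxa[j]))]
    return taxa, D
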