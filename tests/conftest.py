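"""Shared fixtures: scoring schemes, a small simulated cohort, tree helpers."""

from __future__ import annotations

import numpy as np
import pytest

import panstrain as ps


@pytest.fixture(scope="session")
def dna_scheme():
    return ps.ScoringScheme.dna_default()


@pytest.fixture(scope="session")
def protein_scheme():
    return ps.ScoringScheme.protein_default()


@pytest.fixture(scope="session")
def small_cfg():
    """A quick 3+4-genome collection: long enough genes that families stay
    intact at the 0.95 identity threshold, no MAG degradation."""
    return ps.SimConfig(
        n_group1=3, n_group2=4, n_core_families=25, core_gene_len_aa=180,
        accessory_novel_per_genome=3, shared_accessory=10,
        n_planted_group_genes=4, n_planted_variants=10,
        presence_flip_noise=0.0, mag_fraction=0.0, seed=42)


@pytest.fixture(scope="session")
def small_collection(small_cfg):
    return ps.simulate_collection(small_cfg)


# ---------------------------------------------------------------------------
# random additive trees (oracle for neighbor joining)
# ---------------------------------------------------------------------------

class _Edge:
    __slots__ = ("a", "b", "length")

    def __init__(self, a, b, length):
        self.a, self.b, self.length = a, b, length


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree built by sequential leaf insertion.

    Returns (adjacency dict node -> [(neighbor, length)], taxa names).
    Branch lengths are uniform in [0.1, 2.0], so the induced leaf-to-leaf
    distance matrix is strictly additive.
    """
    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    adj: dict = {t: [] for t in taxa[:2]}
    next_internal = [0]

    def connect(a, b, ln):
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))

    def disconnect(a, b):
        adj[a] = [(x, l) for x, l in adj[a] if x != b]
        adj[b] = [(x, l) for x, l in adj[b] if x != a]

    connect(taxa[0], taxa[1], float(rng.uniform(0.1, 2.0)))
    for leaf in taxa[2:]:
        edges = [(a, b, l) for a in adj for b, l in adj[a] if str(a) < str(b)]
        a, b, l = edges[rng.integers(0, len(edges))]
        mid = f"__i{next_internal[0]}"
        next_internal[0] += 1
        split = float(rng.uniform(0.2, 0.8))
        disconnect(a, b)
        connect(a, mid, l * split)
        connect(mid, b, l * (1 - split))
        connect(mid, leaf, float(rng.uniform(0.1, 2.0)))
    return adj, taxa


def tree_distances(adj, taxa):
    """Leaf-to-leaf path-length matrix of an adjacency-list tree."""
    import collections

    n = len(taxa)
    d = np.zeros((n, n))
    for i, t in enumerate(taxa):
        dist = {t: 0.0}
        queue = collections.deque([t])
        while queue:
            u = queue.popleft()
            for v, l in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + l
                    queue.append(v)
        for j, s in enumerate(taxa):
            d[i, j] = dist[s]
    return d


def tree_edge_lengths(adj, taxa):
    """Map canonical-split -> branch length for every edge of the true tree.

    Leaf edges are keyed by ``frozenset({leaf})``; internal edges by the
    side of the split not containing the lexicographically smallest taxon.
    """
    ref = min(taxa)
    all_taxa = set(taxa)

    def leaves_beyond(a, b):  # leaves reachable from b without crossing a
        seen = {a, b}
        stack = [b]
        out = set()
        while stack:
            u = stack.pop()
            if u in all_taxa:
                out.add(u)
            for v, _ in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return out

    lengths = {}
    for a in adj:
        for b, l in adj[a]:
            if str(a) > str(b):
                continue
            side = leaves_beyond(a, b)
            if len(side) == 1:
                key = frozenset(side)
            elif len(all_taxa - side) == 1:
                key = frozenset(all_taxa - side)
            else:
                key = frozenset(side if ref not in side else all_taxa - side)
            lengths[key] = l
    return lengths


def nj_edge_lengths(tree: "ps.Tree"):
    """Same canonical-split keying for an inferred tree's edges.

    At the trifurcating root the three child edges correspond to genuine
    edges only for leaf children; an internal child's edge is the split
    edge itself.
    """
    taxa = set(tree.leaf_names())
    ref = min(taxa)
    lengths = {}

    def walk(node):
        below = set()
        if node.is_leaf:
            below = {node.name}
        for c in node.children:
            below |= walk(c)
        if node is not tree.root:
            if len(below) == 1:
                key = frozenset(below)
            elif len(taxa - below) == 1:
                key = frozenset(taxa - below)
            else:
                key = frozenset(below if ref not in below else taxa - below)
            lengths[key] = lengths.get(key, 0.0) + node.length
        return below

    walk(tree.root)
    return lengths
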