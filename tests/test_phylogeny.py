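"""Core alignment handling, distances, neighbor joining, bootstrap and ANI."""

from __future__ import annotations

import numpy as np
import pytest

import panstrain as ps
from conftest import (nj_edge_lengths, random_additive_tree, tree_distances,
                      tree_edge_lengths)
from panstrain.phylogeny import Model, variant_columns


# ---------------------------------------------------------------------------
# concatenation and column reduction
# ---------------------------------------------------------------------------

def test_concatenation_length_additive_and_provenance():
    m1 = ps.Msa({"a": "MKVLWAARRT", "b": "MKVLWAARRT"})
    m2 = ps.Msa({"a": "DDEEGGSSTTDDEEGGSSTT", "b": "DDEEGGSSTTDDEEGGSSTT"})
    cat = ps.concatenate_core_alignment({"f2": m2, "f1": m1}, ["a", "b"])
    assert cat.length == 30
    assert cat.provenance(1) == ("f1", 1)
    assert cat.provenance(10) == ("f1", 10)
    assert cat.provenance(11) == ("f2", 1)
    assert cat.provenance(30) == ("f2", 20)
    with pytest.raises(IndexError):
        cat.provenance(31)


def test_concatenation_identical_genomes_identical_rows():
    m = ps.Msa({"a": "MKV", "b": "MKV"})
    cat = ps.concatenate_core_alignment({"f1": m}, ["a", "b"])
    assert cat.rows["a"] == cat.rows["b"]


def test_concatenation_rejects_partial_family():
    m = ps.Msa({"a": "MKV"})
    with pytest.raises(ps.ConsistencyError):
        ps.concatenate_core_alignment({"f1": m}, ["a", "b"])


def test_variant_columns_reduction():
    msa = ps.Msa({"a": "MKVA", "b": "MRVA", "c": "MRVA"})
    red = variant_columns(msa)
    assert red.length == 1
    assert red.source_columns == [2]
    # all-identical alignment reduces to nothing
    same = variant_columns(ps.Msa({"a": "MKV", "b": "MKV"}))
    assert same.length == 0


def test_variant_columns_matches_naive_scan():
    rng = np.random.default_rng(8)
    rows = {f"s{i}": "".join("ACGT-"[j] for j in rng.integers(0, 5, 60))
            for i in range(5)}
    msa = ps.Msa(rows)
    red = variant_columns(msa)
    expected = []
    for j in range(60):
        col = {r[j] for r in rows.values()} - {"-"}
        if len(col) >= 2:
            expected.append(j + 1)
    assert red.source_columns == expected


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_p_distance_examples():
    msa = ps.Msa({"a": "ACGT", "b": "ACGA", "c": "ACGT"})
    D = ps.distance_matrix(msa, Model.P_DISTANCE)
    assert D.value("a", "c") == 0.0
    assert D.value("a", "b") == pytest.approx(0.25)


def test_jc_correction_value():
    msa = ps.Msa({"a": "ACGT", "b": "ACGA"})
    D = ps.distance_matrix(msa, Model.JC)
    assert D.value("a", "b") == pytest.approx(-0.75 * np.log(1 - 4 * 0.25 / 3))


def test_jc_saturation_raises():
    msa = ps.Msa({"a": "ACGT", "b": "CAAC"})  # p = 1.0
    with pytest.raises(ps.SaturationError):
        ps.distance_matrix(msa, Model.JC)


def test_protein_poisson_correction():
    msa = ps.Msa({"a": "MKVW", "b": "MKVF"})
    D = ps.distance_matrix(msa, Model.JC)
    assert D.value("a", "b") == pytest.approx(-np.log(1 - 0.25))


def test_gap_columns_excluded_from_distance():
    msa = ps.Msa({"a": "AC-T", "b": "ACGT"})
    D = ps.distance_matrix(msa)
    assert D.value("a", "b") == 0.0  # only the 3 shared columns counted


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_nj_three_taxon_formulas():
    D = ps.DistanceMatrix(["a", "b", "c"],
                          np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
    tree = ps.neighbor_joining(D)
    lengths = {n.name: n.length for n in tree.root.children}
    assert lengths == pytest.approx({"a": 0.5, "b": 1.5, "c": 2.5})


def test_nj_recovers_known_four_taxon_tree():
    # ((a:1,b:2):1,(c:3,d:4)) as an unrooted additive metric
    d = {("a", "b"): 3, ("a", "c"): 5, ("a", "d"): 6,
         ("b", "c"): 6, ("b", "d"): 7, ("c", "d"): 7}
    ids = ["a", "b", "c", "d"]
    arr = np.zeros((4, 4))
    for (x, y), v in d.items():
        i, j = ids.index(x), ids.index(y)
        arr[i, j] = arr[j, i] = v
    tree = ps.neighbor_joining(ps.DistanceMatrix(ids, arr))
    assert tree.bipartitions() == {frozenset({"c", "d"})}
    found = nj_edge_lengths(tree)
    assert found[frozenset({"a"})] == pytest.approx(1.0)
    assert found[frozenset({"b"})] == pytest.approx(2.0)
    assert found[frozenset({"c"})] == pytest.approx(3.0)
    assert found[frozenset({"d"})] == pytest.approx(4.0)
    assert found[frozenset({"c", "d"})] == pytest.approx(1.0)


def test_nj_exact_on_random_additive_trees():
    """Topology and branch lengths of random additive trees are recovered
    exactly (this is NJ's defining guarantee)."""
    rng = np.random.default_rng(11)
    for rep in range(10):
        n = int(rng.integers(5, 13))
        adj, taxa = random_additive_tree(n, rng)
        D = ps.DistanceMatrix(taxa, tree_distances(adj, taxa))
        tree = ps.neighbor_joining(D)
        truth = tree_edge_lengths(adj, taxa)
        found = nj_edge_lengths(tree)
        assert set(found) == set(truth)
        for key in truth:
            assert found[key] == pytest.approx(truth[key], abs=1e-9), key


def test_nj_agrees_with_independent_implementation():
    """Cross-check topology against scikit-bio's neighbor joining."""
    import io

    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(13)
    adj, taxa = random_additive_tree(8, rng)
    d = tree_distances(adj, taxa)
    noise = rng.uniform(0, 0.01, size=d.shape)
    noise = (noise + noise.T) / 2
    np.fill_diagonal(noise, 0)
    d = (d + d.T) / 2 + noise  # exact float symmetry for both consumers
    ours = ps.neighbor_joining(ps.DistanceMatrix(taxa, d))
    theirs = skbio_nj(SkbioDM(d, ids=taxa))
    their_bips = set()
    all_taxa = set(taxa)
    ref = min(all_taxa)
    for node in theirs.non_tips():
        side = {t.name for t in node.tips()}
        if ref in side:
            side = all_taxa - side
        if 1 < len(side) < len(all_taxa) - 1:
            their_bips.add(frozenset(side))
    assert ours.bipartitions() == their_bips


def test_nj_degenerate_all_zero_distances():
    D = ps.DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4)))
    tree = ps.neighbor_joining(D)
    assert sorted(tree.leaf_names()) == ["a", "b", "c", "d"]
    assert all(n.length == 0.0 for n in tree.leaves())


def test_nj_needs_three_taxa():
    with pytest.raises(ValueError):
        ps.neighbor_joining(ps.DistanceMatrix(["a", "b"], np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _two_clade_msa(n_cols=100):
    left = "A" * n_cols + "C" * n_cols
    right = "G" * n_cols + "C" * n_cols
    return ps.Msa({"a1": left, "a2": left, "a3": left,
                   "b1": right, "b2": right, "b3": right})


def test_bootstrap_full_support_on_separating_edge():
    """The clade-separating edge (backed by 100 diagnostic columns) gets
    support 100; edges inside the zero-distance clades may not."""
    tree = ps.bootstrap_supports(_two_clade_msa(), 50, seed=3)
    separating = {frozenset({"b1", "b2", "b3"}), frozenset({"a1", "a2", "a3"})}
    taxa = frozenset(tree.leaf_names())
    hit = [n for n in _internal_nodes(tree)
           if _below(n) in separating or (taxa - _below(n)) in separating]
    assert hit
    assert all(n.support == 100.0 for n in hit)


def _below(node):
    return frozenset(l.name for l in _leaves_of(node))


def _leaves_of(node):
    if node.is_leaf:
        return [node]
    out = []
    for c in node.children:
        out.extend(_leaves_of(c))
    return out


def _internal_nodes(tree):
    out = []

    def walk(n):
        if not n.is_leaf and n is not tree.root:
            out.append(n)
        for c in n.children:
            walk(c)

    walk(tree.root)
    return out


def test_bootstrap_single_replicate_supports_binary():
    tree = ps.bootstrap_supports(_two_clade_msa(20), 1, seed=5)
    for n in _internal_nodes(tree):
        if n.support is not None:
            assert n.support in (0.0, 100.0)


def test_bootstrap_seeded_determinism_and_leaf_order_invariance():
    msa = _two_clade_msa(30)
    t1 = ps.bootstrap_supports(msa, 20, seed=7)
    t2 = ps.bootstrap_supports(msa, 20, seed=7)
    assert t1.to_newick() == t2.to_newick()
    shuffled = ps.Msa(dict(reversed(list(msa.rows.items()))))
    t3 = ps.bootstrap_supports(shuffled, 20, seed=7)
    assert t3.to_newick() == t1.to_newick()


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def ani_genomes():
    rng = np.random.default_rng(17)
    base = ps.random_dna(rng, 20000)
    return {
        "self": ps.GenomeRecord("self", {"c1": base}),
        "mut1": ps.GenomeRecord("mut1", {"c1": ps.mutate_dna(base, 200, rng)}),
        "mut10": ps.GenomeRecord("mut10", {"c1": ps.mutate_dna(base, 2000, rng)}),
        "unrelated": ps.GenomeRecord("unrelated", {"c1": ps.random_dna(rng, 4000)}),
    }


def test_ani_self_is_hundred(ani_genomes):
    res = ps.fragment_ani(ani_genomes["self"], ani_genomes["self"])
    assert res.ani == 100.0
    assert res.fragments_used == res.fragments_total == 20


def test_ani_one_percent_mutation(ani_genomes):
    res = ps.fragment_ani(ani_genomes["self"], ani_genomes["mut1"])
    assert res.ani == pytest.approx(99.0, abs=0.3)
    assert res.fragments_used == res.fragments_total


def test_ani_unrelated_genome_undefined(ani_genomes):
    small = ps.GenomeRecord("q", {"c1": ani_genomes["self"].contigs["c1"][:3000]})
    res = ps.fragment_ani(small, ani_genomes["unrelated"])
    assert res.ani is None
    assert res.fragments_used == 0


def test_ani_approximately_symmetric(ani_genomes):
    ab = ps.fragment_ani(ani_genomes["self"], ani_genomes["mut1"]).ani
    ba = ps.fragment_ani(ani_genomes["mut1"], ani_genomes["self"]).ani
    assert abs(ab - ba) < 0.2


def test_species_gate(ani_genomes):
    refs = [("species_a", ani_genomes["self"])]
    # ~99 % ANI genome assigned, ~90 % genome rejected at the 95 % gate
    assert ps.assign_species_by_ani(ani_genomes["mut1"], refs) == "species_a"
    assert ps.assign_species_by_ani(ani_genomes["mut10"], refs) == ps.UNASSIGNED


def test_species_gate_prefers_closest_reference(ani_genomes):
    refs = [("far", ani_genomes["mut10"]), ("near", ani_genomes["self"])]
    assert ps.assign_species_by_ani(ani_genomes["mut1"], refs) == "near"


def test_ani_requires_minimum_length():
    g = ps.GenomeRecord("g", {"c1": "ACGT" * 50})
    with pytest.raises(ValueError):
        ps.fragment_ani(g, g, frag_len=1000)
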