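"""Fisher association and group-exclusive variant scanning."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import panstrain as ps
from panstrain.signatures import association_frame, variants_frame


# ---------------------------------------------------------------------------
# exact-fraction enumeration oracle for the two-sided Fisher test
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d) -> Fraction:
    """Two-sided p by exhaustive enumeration with exact rational arithmetic."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return Fraction(1)
    denom = math.comb(n, c1)

    def prob(k):
        return Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        if prob(k) <= p_obs:
            total += prob(k)
    return total


@pytest.mark.parametrize("table,expected", [
    ([[1, 1], [1, 1]], 1.0),
    ([[6, 0], [0, 9]], 1 / 5005),
    ([[3, 1], [1, 3]], 34 / 70),
])
def test_fisher_known_tables(table, expected):
    assert ps.fisher_exact_two_sided(table) == pytest.approx(expected, rel=1e-9)


def test_fisher_degenerate_margin_is_one():
    assert ps.fisher_exact_two_sided([[0, 0], [3, 4]]) == 1.0
    assert ps.fisher_exact_two_sided([[2, 0], [3, 0]]) == 1.0


def test_fisher_matches_enumeration_on_moderate_tables():
    """Spot-check against the exact-fraction oracle and scipy for a grid of
    tables with margins up to 8 (the acceptance suite sweeps up to 12)."""
    from scipy.stats import fisher_exact

    for a in range(0, 5):
        for b in range(0, 5):
            for c in range(0, 5):
                for d in range(0, 5):
                    p = ps.fisher_exact_two_sided([[a, b], [c, d]])
                    assert p == pytest.approx(float(fisher_oracle(a, b, c, d)),
                                              rel=1e-9, abs=1e-12), (a, b, c, d)
                    if min(a + b, c + d, a + c, b + d) > 0:
                        assert p == pytest.approx(
                            fisher_exact([[a, b], [c, d]])[1], rel=1e-6)


# ---------------------------------------------------------------------------
# family association
# ---------------------------------------------------------------------------

def _meta(groups: dict[str, str]) -> ps.MetadataTable:
    return ps.MetadataTable.from_rows([
        {"genome_id": g, "group": grp, "source": "ISOLATE",
         "completeness": 100.0, "contamination": 0.0}
        for g, grp in groups.items()])


def _matrix(rows: dict[str, list[int]], genomes: list[str]) -> ps.PresenceAbsenceMatrix:
    return ps.PresenceAbsenceMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=genomes))


def test_perfectly_separating_family_hits_floor_p():
    g1 = [f"p{i}" for i in range(6)]
    g2 = [f"f{i}" for i in range(9)]
    meta = _meta({**{g: "PTB" for g in g1}, **{g: "FTB" for g in g2}})
    M = _matrix({"famA": [1] * 6 + [0] * 9, "famB": [1] * 6 + [1] * 8 + [0]},
                g1 + g2)
    res = ps.associate_families(M, meta)
    assert res[0].family_id == "famA"
    assert res[0].p_value == pytest.approx(1 / 5005)
    assert res[0].direction == ps.Direction.GROUP1_ENRICHED


def test_invariant_families_not_tested():
    meta = _meta({"a": "PTB", "b": "PTB", "c": "FTB", "d": "FTB"})
    M = _matrix({"all": [1, 1, 1, 1], "none": [0, 0, 0, 0],
                 "var": [1, 1, 0, 0]}, ["a", "b", "c", "d"])
    res = ps.associate_families(M, meta)
    assert [r.family_id for r in res] == ["var"]


def test_unknown_group_genomes_excluded():
    meta = _meta({"a": "PTB", "b": "PTB", "c": "FTB", "d": "FTB", "e": "UNKNOWN"})
    M = _matrix({"var": [1, 1, 0, 0, 1]}, ["a", "b", "c", "d", "e"])
    (res,) = ps.associate_families(M, meta)
    assert res.table == ((2, 0), (0, 2))  # genome e ignored


def test_bonferroni_and_bh_on_tied_pvalues():
    """m identical tests: Bonferroni multiplies by m, BH leaves ties at p."""
    g = {f"p{i}": "PTB" for i in range(3)} | {f"f{i}": "FTB" for i in range(3)}
    genomes = list(g)
    rows = {f"fam{i}": [1, 1, 1, 0, 0, 0] for i in range(10)}
    M = _matrix(rows, genomes)
    res = ps.associate_families(M, _meta(g))
    p = res[0].p_value
    for r in res:
        assert r.p_value == pytest.approx(p)
        assert r.p_bonferroni == pytest.approx(min(1.0, p * 10))
        assert r.q_bh == pytest.approx(p)
        assert r.p_bonferroni >= r.p_value


def test_swapping_group_labels_flips_direction_not_p():
    g = {f"p{i}": "PTB" for i in range(4)} | {f"f{i}": "FTB" for i in range(5)}
    genomes = list(g)
    rng = np.random.default_rng(0)
    rows = {f"fam{i}": list(rng.integers(0, 2, len(genomes))) for i in range(12)}
    rows = {k: v for k, v in rows.items() if 0 < sum(v) < len(genomes)}
    M = _matrix(rows, genomes)
    meta = _meta(g)
    fwd = ps.associate_families(M, meta, ps.Group.PTB, ps.Group.FTB)
    rev = ps.associate_families(M, meta, ps.Group.FTB, ps.Group.PTB)
    flip = {ps.Direction.GROUP1_ENRICHED: ps.Direction.GROUP2_ENRICHED,
            ps.Direction.GROUP2_ENRICHED: ps.Direction.GROUP1_ENRICHED,
            ps.Direction.NONE: ps.Direction.NONE}
    rev_by_fam = {r.family_id: r for r in rev}
    for r in fwd:
        assert rev_by_fam[r.family_id].p_value == pytest.approx(r.p_value)
        assert rev_by_fam[r.family_id].direction == flip[r.direction]


def test_association_requires_both_groups():
    meta = _meta({"a": "PTB", "b": "PTB"})
    M = _matrix({"var": [1, 0]}, ["a", "b"])
    with pytest.raises(ValueError):
        ps.associate_families(M, meta)


# ---------------------------------------------------------------------------
# variant scanning
# ---------------------------------------------------------------------------

_META_22 = _meta({"t1": "PTB", "t2": "PTB", "o1": "FTB", "o2": "FTB"})


def test_scan_no_variation_reports_nothing():
    msa = ps.Msa({"t1": "MKV", "t2": "MKV", "o1": "MKV", "o2": "MKV"})
    assert ps.scan_group_variants(msa, _META_22, ps.Group.PTB) == []


def test_scan_fixed_difference_reported_with_residue_sets():
    msa = ps.Msa({"t1": "MKV", "t2": "MKV", "o1": "MRV", "o2": "MRV"})
    (v,) = ps.scan_group_variants(msa, _META_22, ps.Group.PTB)
    assert v.column == 2
    assert v.target_residues == frozenset("K")
    assert v.other_residues == frozenset("R")


def test_scan_gap_in_target_strict_vs_lenient():
    """A target-side gap disqualifies the column in strict mode; lenient
    mode ignores the gap row and reports the disjoint sets."""
    msa = ps.Msa({"t1": "MKV", "t2": "M-V", "o1": "MRV", "o2": "MRV"})
    assert ps.scan_group_variants(msa, _META_22, ps.Group.PTB, strict=True) == []
    (v,) = ps.scan_group_variants(msa, _META_22, ps.Group.PTB, strict=False)
    assert v.column == 2
    assert v.target_residues == frozenset("K")


def test_scan_target_residue_present_in_other_group_not_reported():
    msa = ps.Msa({"t1": "MKV", "t2": "MKV", "o1": "MKV", "o2": "MRV"})
    assert ps.scan_group_variants(msa, _META_22, ps.Group.PTB, strict=True) == []


def test_scan_polymorphic_target_not_reported_in_strict_mode():
    msa = ps.Msa({"t1": "MKV", "t2": "MQV", "o1": "MRV", "o2": "MRV"})
    assert ps.scan_group_variants(msa, _META_22, ps.Group.PTB, strict=True) == []
    # lenient: {K,Q} and {R} are disjoint
    (v,) = ps.scan_group_variants(msa, _META_22, ps.Group.PTB, strict=False)
    assert v.target_residues == frozenset("KQ")


def test_scan_unlabeled_row_raises():
    msa = ps.Msa({"t1": "MKV", "t2": "MKV", "zz": "MRV"})
    with pytest.raises(ps.LabelingError):
        ps.scan_group_variants(msa, _META_22, ps.Group.PTB)


def test_scan_recovers_planted_variants(small_collection):
    collection, meta, truth = small_collection
    fams = ps.cluster_gene_families(collection)
    g2f = truth.gene_to_family
    found = []
    for fid, members in fams.families.items():
        rows = {}
        for g in sorted(members, key=lambda g: g.gene_id):
            rows.setdefault(g.genome_id, g.aa_seq)
        if len(rows) < len(collection):
            continue
        msa = ps.center_star_msa(rows)
        for v in ps.scan_group_variants(msa, meta, ps.Group.PTB, family_id=fid):
            found.append((g2f[members[0].gene_id], v.column))
    planted = [(f, pos) for f, pos, _x, _y in truth.planted_variants]
    assert sorted(found) == sorted(planted)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _gv(fam, col):
    return ps.GroupVariant(fam, col, frozenset("K"), frozenset("R"), True)


def test_summarize_counts_and_min_count_filter():
    per_fam = {"f1": [_gv("f1", 1), _gv("f1", 2), _gv("f1", 3)],
               "f2": [_gv("f2", 1)],
               "f3": [_gv("f3", 1), _gv("f3", 2)]}
    s = ps.summarize_variants(per_fam, min_count=2)
    assert s.reported == {"f1": 3, "f3": 2}
    assert s.total_variants == 6
    assert s.total_families_with_variants == 3


def test_summarize_empty_input():
    s = ps.summarize_variants({})
    assert s.total_variants == 0
    assert s.reported == {}


def test_summary_conserves_total_counts():
    rng = np.random.default_rng(2)
    per_fam = {f"f{i}": [_gv(f"f{i}", j + 1) for j in range(int(rng.integers(0, 5)))]
               for i in range(10)}
    s = ps.summarize_variants(per_fam, min_count=2)
    unreported = {f: c for f, c in s.counts.items() if f not in s.reported}
    assert sum(s.reported.values()) + sum(unreported.values()) == s.total_variants


def test_output_frames_are_deterministic():
    per_fam = {"f2": [_gv("f2", 3), _gv("f2", 1)], "f1": [_gv("f1", 2)]}
    df = variants_frame(per_fam)
    assert list(df["family_id"]) == ["f1", "f2", "f2"]
    assert list(df["column"]) == [2, 1, 3]
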