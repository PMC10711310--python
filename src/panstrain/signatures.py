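"""Phenotype-group discriminative analyses.

Two analyses distinguish the strain groups:

* pan-GWAS style association of gene-family presence/absence with the
  phenotype group, using a two-sided Fisher exact test per family with
  Bonferroni and Benjamini-Hochberg corrections (no phylogenetic pairing);
* a scanner for group-exclusive amino-acid variants in per-family multiple
  alignments: columns where the target group's residues are disjoint from
  the other group's.  Differing aligned amino acids are non-synonymous by
  construction, so scanning happens at the protein level.

Strict mode (the default) requires the target group to be fixed for a single
residue with no gaps, and that residue absent from the other group; lenient
mode only requires disjoint residue sets after dropping gap-carrying rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .alignment import Msa
from .errors import LabelingError
from .io_formats import Group, MetadataTable
from .pangenome import PresenceAbsenceMatrix

__all__ = [
    "Direction",
    "AssociationResult",
    "GroupVariant",
    "VariantSummary",
    "fisher_exact_two_sided",
    "associate_families",
    "scan_group_variants",
    "summarize_variants",
    "association_frame",
    "variants_frame",
]

_TIE_RTOL = 1e-7


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table ``[[a, b], [c, d]]``.

    The p-value sums hypergeometric probabilities of every table with the
    same margins whose probability is <= the observed one (ties within
    relative tolerance 1e-7).  A zero margin is degenerate and returns 1.0.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0 or any(x != int(x) for x in (a, b, c, d)):
        raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    dist = hypergeom(n, c1, r1)  # X = top-left cell over draws of row 1
    k_lo = max(0, r1 - (n - c1))
    k_hi = min(r1, c1)
    ks = np.arange(k_lo, k_hi + 1)
    pmf = dist.pmf(ks)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + _TIE_RTOL)].sum())
    return min(p, 1.0)


class Direction(str, Enum):
    GROUP1_ENRICHED = "GROUP1_ENRICHED"
    GROUP2_ENRICHED = "GROUP2_ENRICHED"
    NONE = "NONE"


@dataclass
class AssociationResult:
    """One family's 2x2 presence-by-group test with corrected p-values."""

    family_id: str
    table: tuple[tuple[int, int], tuple[int, int]]  # (g1 present, g1 absent), (g2 ...)
    p_value: float
    odds_ratio: float
    p_bonferroni: float
    q_bh: float
    direction: Direction


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else 0.0
    return (a * d) / (b * c)


def associate_families(
    matrix: PresenceAbsenceMatrix,
    metadata: MetadataTable,
    group1: Group = Group.PTB,
    group2: Group = Group.FTB,
) -> list[AssociationResult]:
    """Fisher-test every variable family against the phenotype grouping.

    Genomes with group UNKNOWN are excluded; families present in every
    labeled genome or in none are skipped (no test).  Bonferroni and BH
    corrections run over the set of tested families; results are sorted by
    ascending p (ties by family id).
    """
    groups = metadata.groups()
    g1 = [g for g in matrix.genome_ids if groups.get(g) == group1]
    g2 = [g for g in matrix.genome_ids if groups.get(g) == group2]
    if not g1 or not g2:
        raise ValueError("both groups need at least one genome in the matrix")
    sub1 = matrix.df[g1].to_numpy()
    sub2 = matrix.df[g2].to_numpy()
    n1, n2 = len(g1), len(g2)
    results: list[AssociationResult] = []
    for ri, fid in enumerate(matrix.family_ids):
        a = int(sub1[ri].sum())
        c = int(sub2[ri].sum())
        present = a + c
        if present == 0 or present == n1 + n2:
            continue  # invariant among labeled genomes: no signal to test
        b, d = n1 - a, n2 - c
        p = fisher_exact_two_sided([[a, b], [c, d]])
        if a / n1 > c / n2:
            direction = Direction.GROUP1_ENRICHED
        elif a / n1 < c / n2:
            direction = Direction.GROUP2_ENRICHED
        else:
            direction = Direction.NONE
        results.append(AssociationResult(
            family_id=fid, table=((a, b), (c, d)), p_value=p,
            odds_ratio=_odds_ratio(a, b, c, d),
            p_bonferroni=np.nan, q_bh=np.nan, direction=direction))
    if results:
        pvals = np.array([r.p_value for r in results])
        bonf = np.minimum(pvals * len(results), 1.0)
        _, q_bh, _, _ = multipletests(pvals, method="fdr_bh")
        for r, pb, q in zip(results, bonf, q_bh):
            r.p_bonferroni = float(pb)
            r.q_bh = float(q)
    results.sort(key=lambda r: (r.p_value, r.family_id))
    return results


# ---------------------------------------------------------------------------
# group-exclusive variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupVariant:
    """An alignment column whose target-group residues exclude the others'."""

    family_id: str
    column: int  # 1-based Msa column
    target_residues: frozenset[str]
    other_residues: frozenset[str]
    strict: bool


def scan_group_variants(
    msa: Msa,
    metadata: MetadataTable,
    target_group: Group = Group.PTB,
    strict: bool = True,
    family_id: str = "",
) -> list[GroupVariant]:
    """Find group-exclusive columns in a per-family protein alignment.

    Strict mode reports column j iff every target-group row carries one and
    the same residue (no gaps) and that residue is absent from all
    other-group rows (other-group gaps permitted).  Lenient mode drops
    gap-carrying rows at j and reports columns whose residue sets are
    disjoint and both non-empty.
    """
    groups = metadata.groups()
    target_ids, other_ids = [], []
    for sid in msa.ids:
        if sid not in groups:
            raise LabelingError(f"alignment row {sid!r} is not in the metadata")
        grp = groups[sid]
        if grp == target_group:
            target_ids.append(sid)
        elif grp != Group.UNKNOWN:
            other_ids.append(sid)
    if not target_ids or not other_ids:
        raise LabelingError("both phenotype groups must be represented in the alignment")
    t_rows = [msa.rows[i] for i in target_ids]
    o_rows = [msa.rows[i] for i in other_ids]
    out: list[GroupVariant] = []
    for j in range(msa.length):
        t_res = {r[j] for r in t_rows}
        o_res = {r[j] for r in o_rows}
        if strict:
            if "-" in t_res or len(t_res) != 1:
                continue
            a = next(iter(t_res))
            o_nongap = o_res - {"-"}
            if a in o_nongap:
                continue
            out.append(GroupVariant(family_id, j + 1, frozenset(t_res),
                                    frozenset(o_nongap), True))
        else:
            t_nongap = t_res - {"-"}
            o_nongap = o_res - {"-"}
            if not t_nongap or not o_nongap:
                continue
            if t_nongap & o_nongap:
                continue
            out.append(GroupVariant(family_id, j + 1, frozenset(t_nongap),
                                    frozenset(o_nongap), False))
    return out


@dataclass
class VariantSummary:
    """Per-family variant counts with a minimum-count report filter."""

    counts: dict[str, int]
    reported: dict[str, int]
    min_count: int
    total_variants: int
    total_families_with_variants: int


def summarize_variants(
    per_family_variants: dict[str, list[GroupVariant]],
    min_count: int = 2,
) -> VariantSummary:
    """Count variants per family; the report keeps families with >= min_count."""
    counts = {fid: len(v) for fid, v in per_family_variants.items() if v}
    reported = {fid: c for fid, c in counts.items() if c >= min_count}
    return VariantSummary(
        counts=counts,
        reported=reported,
        min_count=min_count,
        total_variants=sum(counts.values()),
        total_families_with_variants=len(counts),
    )


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "family_id": r.family_id,
        "group1_present": r.table[0][0],
        "group1_absent": r.table[0][1],
        "group2_present": r.table[1][0],
        "group2_absent": r.table[1][1],
        "p_value": r.p_value,
        "odds_ratio": r.odds_ratio,
        "p_bonferroni": r.p_bonferroni,
        "q_bh": r.q_bh,
        "direction": r.direction.value,
    } for r in results])


def variants_frame(per_family_variants: dict[str, list[GroupVariant]]) -> pd.DataFrame:
    rows = []
    for fid in sorted(per_family_variants):
        for v in sorted(per_family_variants[fid], key=lambda v: v.column):
            rows.append({
                "family_id": fid,
                "column": v.column,
                "target_residues": "".join(sorted(v.target_residues)),
                "other_residues": "".join(sorted(v.other_residues)),
                "strict": v.strict,
            })
    return pd.DataFrame(rows, columns=["family_id", "column", "target_residues",
                                       "other_residues", "strict"])


def write_association_tsv(results: list[AssociationResult], path: str | Path) -> None:
    association_frame(results).to_csv(path, sep="\t", index=False)


def write_variants_tsv(per_family_variants: dict[str, list[GroupVariant]],
                       path: str | Path) -> None:
    variants_frame(per_family_variants).to_csv(path, sep="\t", index=False)
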