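"""Genome quality gating and marker-gene-cluster profiling.

Quality gating keeps genomes with completeness >= 90 % and contamination
strictly < 5 % (the conventional high-quality MAG bar).  Marker profiling
asks, for each protein of a marker gene cluster and each genome, whether the
genome carries a gene matching it — best local alignment over all genes,
presence gated on identity and query (marker) coverage.  Coverage is
measured on the marker so fused or split genes in MAGs still register.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .alignment import ScoringScheme, align_local, default_protein_scheme
from .io_formats import Gene, GenomeRecord, MetadataTable, read_fasta
from .errors import MetadataError

__all__ = [
    "MarkerSet",
    "MarkerProfile",
    "filter_genomes",
    "profile_markers",
    "clade_concordance",
]


def filter_genomes(
    metadata: MetadataTable,
    min_completeness: float = 90.0,
    max_contamination: float = 5.0,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Quality-gate genomes: keep iff completeness >= min AND contamination < max.

    The contamination bound is strict.  Returns (kept ids, [(dropped id,
    reason), ...]); idempotent and order-independent.
    """
    df = metadata.df
    for col in ("completeness", "contamination"):
        if df[col].isna().any():
            bad = df.loc[df[col].isna(), "genome_id"].iloc[0]
            raise MetadataError(f"genome {bad!r} is missing {col}")
    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    for row in df.itertuples():
        reasons = []
        if row.completeness < min_completeness:
            reasons.append(f"completeness {row.completeness:.1f} < {min_completeness:.1f}")
        if row.contamination >= max_contamination:
            reasons.append(f"contamination {row.contamination:.1f} >= {max_contamination:.1f}")
        if reasons:
            dropped.append((row.genome_id, "; ".join(reasons)))
        else:
            kept.append(row.genome_id)
    return kept, dropped


@dataclass
class MarkerSet:
    """Marker proteins with the identity/coverage floors for presence calls."""

    markers: dict[str, str]
    min_identity: float = 0.7
    min_coverage: float = 0.8

    def __post_init__(self):
        if not self.markers:
            raise ValueError("marker set must be non-empty")
        for mid, seq in self.markers.items():
            if not seq:
                raise ValueError(f"marker {mid!r} has an empty sequence")
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    @classmethod
    def from_fasta(cls, path: str | Path, min_identity: float = 0.7,
                   min_coverage: float = 0.8) -> "MarkerSet":
        return cls(dict(read_fasta(path)), min_identity, min_coverage)


@dataclass
class MarkerProfile:
    """Presence matrix (markers x genomes) plus the best hit behind each call."""

    matrix: pd.DataFrame = field(repr=False)
    best_hit: dict[tuple[str, str], tuple[str, float, float]] = field(repr=False)
    min_identity: float = 0.7
    min_coverage: float = 0.8

    def presence(self, marker_id: str, genome_id: str) -> int:
        return int(self.matrix.loc[marker_id, genome_id])

    def hits_frame(self) -> pd.DataFrame:
        rows = [{
            "marker_id": m, "genome_id": g, "gene_id": hit[0],
            "identity": hit[1], "coverage": hit[2],
        } for (m, g), hit in sorted(self.best_hit.items())]
        return pd.DataFrame(rows, columns=["marker_id", "genome_id", "gene_id",
                                           "identity", "coverage"])


_SCREEN_K = 4


def _marker_best_hit(
    marker_seq: str,
    genes: list[Gene],
    scheme: ScoringScheme,
) -> tuple[str, float, float, float] | None:
    """Best local alignment of the marker over a genome's genes.

    Candidate genes are pre-screened for a shared 4-mer (word seeding, as in
    BLASTp); among candidates the highest score wins, ties by gene id.
    """
    marker_kmers = {marker_seq[i:i + _SCREEN_K]
                    for i in range(len(marker_seq) - _SCREEN_K + 1)}
    best = None  # (score, gene_id, identity, coverage)
    for gene in sorted(genes, key=lambda g: g.gene_id):
        seq = gene.aa_seq
        if marker_kmers and not any(seq[i:i + _SCREEN_K] in marker_kmers
                                    for i in range(len(seq) - _SCREEN_K + 1)):
            continue
        aln = align_local(marker_seq, seq, scheme)
        if aln.score <= 0:
            continue
        cand = (aln.score, gene.gene_id, aln.identity, aln.coverage_a)
        if best is None or aln.score > best[0]:
            best = cand
    if best is None:
        return None
    score, gene_id, identity, coverage = best
    return gene_id, identity, coverage, score


def profile_markers(
    markers: MarkerSet,
    genomes: list[tuple[GenomeRecord, list[Gene]]],
    scheme: ScoringScheme | None = None,
) -> MarkerProfile:
    """Profile every marker against every genome's gene complement."""
    if scheme is None:
        scheme = default_protein_scheme()
    marker_ids = sorted(markers.markers)
    genome_ids = [g.genome_id for g, _ in genomes]
    matrix = pd.DataFrame(0, index=marker_ids, columns=genome_ids, dtype="int8")
    best_hit: dict[tuple[str, str], tuple[str, float, float]] = {}
    for genome, genes in genomes:
        for mid in marker_ids:
            hit = _marker_best_hit(markers.markers[mid], genes, scheme)
            if hit is None:
                continue
            gene_id, identity, coverage, _score = hit
            best_hit[(mid, genome.genome_id)] = (gene_id, identity, coverage)
            if identity >= markers.min_identity and coverage >= markers.min_coverage:
                matrix.loc[mid, genome.genome_id] = 1
    return MarkerProfile(matrix, best_hit, markers.min_identity, markers.min_coverage)


def clade_concordance(
    profile: MarkerProfile,
    clades: dict[str, str],
) -> pd.DataFrame:
    """Per-clade presence fractions and a per-marker concordance score.

    Concordance is the spread between the most- and least-saturated clade
    (equal to |fraction(clade I) - fraction(clade II)| for two clades).
    """
    genome_ids = list(profile.matrix.columns)
    missing = [g for g in genome_ids if g not in clades]
    if missing:
        raise ValueError(f"genomes without a clade assignment: {missing}")
    by_clade: dict[str, list[str]] = {}
    for g in genome_ids:
        by_clade.setdefault(clades[g], []).append(g)
    for clade, members in by_clade.items():
        if not members:
            raise ValueError(f"clade {clade!r} has no genomes")
    clade_names = sorted(by_clade)
    rows = []
    for mid in profile.matrix.index:
        fracs = {c: float(profile.matrix.loc[mid, by_clade[c]].mean())
                 for c in clade_names}
        rows.append({
            "marker_id": mid,
            **{f"fraction_{c}": fracs[c] for c in clade_names},
            "concordance": max(fracs.values()) - min(fracs.values()),
        })
    return pd.DataFrame(rows)
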