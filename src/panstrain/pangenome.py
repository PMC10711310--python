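"""Gene-family clustering, presence/absence, pangenome partitioning and
Heaps'-law openness.

Clustering is greedy and representative-based (CD-HIT style): proteins are
visited in order of decreasing length and each either joins the first
existing family whose representative it matches at >= the identity threshold
under global alignment, or founds a new family.  A k-mer count screen with a
provable bound skips hopeless alignments without ever changing the result.

The pangenome is partitioned by presence fraction into core (>= 95 % of
genomes by default), shell and cloud, and openness is classified by fitting
Heaps' law P(N) = kappa * N**gamma to the permutation-averaged rarefaction
curve: gamma > 0 means an open pangenome that keeps gaining families.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .alignment import ScoringScheme, align_global, default_protein_scheme
from .errors import ConsistencyError
from .io_formats import Gene, GenomeRecord

logger = logging.getLogger("panstrain.pangenome")

__all__ = [
    "GeneFamilySet",
    "PresenceAbsenceMatrix",
    "PangenomePartition",
    "Openness",
    "HeapsFit",
    "cluster_gene_families",
    "build_matrix",
    "partition_pangenome",
    "rarefaction_curve",
    "fit_heaps",
]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class GeneFamilySet:
    """Gene families: family id -> member genes, with one representative each."""

    families: dict[str, list[Gene]]
    representative: dict[str, str]
    identity_threshold: float = 0.95

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.families.values())

    def family_of_gene(self) -> dict[str, str]:
        return {g.gene_id: fid for fid, members in self.families.items() for g in members}

    def paralog_report(self) -> dict[str, dict[str, int]]:
        """Families with >1 member from one genome: family -> genome -> count."""
        out: dict[str, dict[str, int]] = {}
        for fid, members in self.families.items():
            counts: dict[str, int] = {}
            for g in members:
                counts[g.genome_id] = counts.get(g.genome_id, 0) + 1
            multi = {gid: c for gid, c in counts.items() if c > 1}
            if multi:
                out[fid] = multi
        return out


_KMER = 4


def _kmer_bound(la: int, lb: int, threshold: float, k: int = _KMER) -> float:
    """Minimum k-mer position hits compatible with identity >= threshold.

    If the alignment reaches identity t over C columns, matches m = t*C with
    C >= max(la, lb) and mismatch/gap events e = C - m <= (1-t)*(la+lb).  The
    matched positions form <= e+1 exact runs shared verbatim by both
    sequences, so at least m - (e+1)*(k-1) k-mer positions of the query must
    occur in the representative.  A count below this bound proves the pair
    cannot reach the threshold; the screen can never reject a true match.
    """
    return threshold * max(la, lb) - ((1 - threshold) * (la + lb) + 1) * (k - 1)


def cluster_gene_families(
    genomes: list[tuple[GenomeRecord, list[Gene]]],
    threshold: float = 0.95,
    scheme: ScoringScheme | None = None,
) -> GeneFamilySet:
    """Cluster all proteins of a genome collection into gene families.

    Deterministic: proteins are sorted by descending length (ties by gene
    id), and each joins the first family, in founding order, whose
    representative it matches at identity >= ``threshold`` under global
    alignment; otherwise it founds a new family.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    genes = [g for _, gs in genomes for g in gs]
    if not genes:
        raise ValueError("no genes to cluster")
    for g in genes:
        if not g.aa_seq:
            raise ValueError(f"gene {g.gene_id} has an empty protein sequence")
    if scheme is None:
        scheme = default_protein_scheme()
    order = sorted(genes, key=lambda g: (-len(g.aa_seq), g.gene_id))

    fam_members: list[list[Gene]] = []
    reps: list[Gene] = []
    kmer_to_fams: dict[str, list[int]] = {}  # inverted index over representatives
    for gene in order:
        seq = gene.aa_seq
        la = len(seq)
        gene_kmers = [seq[i:i + _KMER] for i in range(la - _KMER + 1)]
        hits = np.zeros(len(reps))
        for km in gene_kmers:
            for fi in kmer_to_fams.get(km, ()):
                hits[fi] += 1
        placed = False
        for fi in range(len(reps)):
            lb = len(reps[fi].aa_seq)
            # identity <= min/max length ratio: columns >= max, matches <= min
            if min(la, lb) / max(la, lb) < threshold:
                continue
            bound = _kmer_bound(la, lb, threshold)
            if bound > 0 and la >= _KMER and hits[fi] < bound:
                continue
            aln = align_global(seq, reps[fi].aa_seq, scheme)
            if aln.identity >= threshold:
                fam_members[fi].append(gene)
                placed = True
                break
        if not placed:
            fi = len(reps)
            fam_members.append([gene])
            reps.append(gene)
            for km in set(gene_kmers):
                kmer_to_fams.setdefault(km, []).append(fi)
    width = max(5, len(str(len(reps))))
    families = {f"fam_{i + 1:0{width}d}": members for i, members in enumerate(fam_members)}
    representative = {fid: reps[i].gene_id for i, fid in enumerate(families)}
    logger.info("clustered %d genes into %d families at identity >= %.2f",
                len(genes), len(families), threshold)
    return GeneFamilySet(families, representative, threshold)


# ---------------------------------------------------------------------------
# presence/absence
# ---------------------------------------------------------------------------

@dataclass
class PresenceAbsenceMatrix:
    """Binary families x genomes matrix (paralogs collapse to presence)."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        values = self.df.to_numpy()
        if not ((values == 0) | (values == 1)).all():
            raise ValueError("presence/absence entries must be 0/1")
        self.df = self.df.astype("int8")

    @property
    def family_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_genomes(self) -> int:
        return self.df.shape[1]

    def presence_counts(self) -> pd.Series:
        return self.df.sum(axis=1)

    def subset_genomes(self, genome_ids: list[str]) -> "PresenceAbsenceMatrix":
        return PresenceAbsenceMatrix(self.df[genome_ids].copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, PresenceAbsenceMatrix) and self.df.equals(other.df)


def build_matrix(fams: GeneFamilySet, genome_ids: list[str]) -> PresenceAbsenceMatrix:
    """Binary matrix: cell 1 iff the family has >= 1 member in the genome."""
    known = set(genome_ids)
    data = np.zeros((len(fams.families), len(genome_ids)), dtype="int8")
    col = {g: i for i, g in enumerate(genome_ids)}
    for ri, (fid, members) in enumerate(fams.families.items()):
        for gene in members:
            if gene.genome_id not in known:
                raise ConsistencyError(
                    f"family {fid} references unknown genome {gene.genome_id!r}")
            data[ri, col[gene.genome_id]] = 1
    df = pd.DataFrame(data, index=list(fams.families), columns=list(genome_ids))
    return PresenceAbsenceMatrix(df)


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------

@dataclass
class PangenomePartition:
    """Core/shell/cloud family id sets (disjoint, jointly exhaustive)."""

    core_ids: list[str]
    shell_ids: list[str]
    cloud_ids: list[str]
    core_frac: float = 0.95
    shell_min_frac: float = 0.15

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.core_ids), len(self.shell_ids), len(self.cloud_ids)

    def summary_frame(self, matrix: PresenceAbsenceMatrix) -> pd.DataFrame:
        counts = matrix.presence_counts()
        cls = {fid: "core" for fid in self.core_ids}
        cls.update({fid: "shell" for fid in self.shell_ids})
        cls.update({fid: "cloud" for fid in self.cloud_ids})
        return pd.DataFrame({
            "family_id": matrix.family_ids,
            "presence_count": [int(counts[f]) for f in matrix.family_ids],
            "class": [cls[f] for f in matrix.family_ids],
        })


def partition_pangenome(
    matrix: PresenceAbsenceMatrix,
    core_frac: float = 0.95,
    shell_min_frac: float = 0.15,
) -> PangenomePartition:
    """Partition families by presence fraction c/G.

    core: c/G >= core_frac; shell: shell_min_frac <= c/G < core_frac;
    cloud: c/G < shell_min_frac.  The fraction rule is applied directly
    (no integer rounding), so with 15 genomes "core" means all 15.
    """
    G = matrix.n_genomes
    if G < 1:
        raise ValueError("matrix has no genomes")
    counts = matrix.presence_counts()
    core, shell, cloud = [], [], []
    for fid in matrix.family_ids:
        frac = counts[fid] / G
        if frac >= core_frac:
            core.append(fid)
        elif frac >= shell_min_frac:
            shell.append(fid)
        else:
            cloud.append(fid)
    return PangenomePartition(core, shell, cloud, core_frac, shell_min_frac)


# ---------------------------------------------------------------------------
# rarefaction + Heaps' law
# ---------------------------------------------------------------------------

def rarefaction_curve(
    matrix: PresenceAbsenceMatrix,
    n_permutations: int,
    seed: int,
) -> list[tuple[int, float, float]]:
    """Permutation-averaged pangenome accumulation curve.

    For each random genome ordering the cumulative number of distinct
    families at N = 1..G is recorded; returns per-N means of the pangenome
    size and of the number of newly gained families.  When G! does not
    exceed ``n_permutations`` every ordering is enumerated exactly once, so
    the means are exact rather than sampled.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    G = matrix.n_genomes
    if G < 2:
        raise ValueError("rarefaction needs at least 2 genomes")
    rng = np.random.default_rng(seed)
    pres = matrix.df.to_numpy(dtype=bool)  # families x genomes
    if math.factorial(G) <= n_permutations:
        orders = [np.array(p) for p in itertools.permutations(range(G))]
    else:
        orders = [rng.permutation(G) for _ in range(n_permutations)]
    sizes = np.zeros((len(orders), G))
    for p, order in enumerate(orders):
        cum = np.logical_or.accumulate(pres[:, order], axis=1)
        sizes[p] = cum.sum(axis=0)
    mean_sizes = sizes.mean(axis=0)
    new = np.diff(sizes, axis=1, prepend=0.0).mean(axis=0)
    return [(N + 1, float(mean_sizes[N]), float(new[N])) for N in range(G)]


class Openness(str, Enum):
    OPEN = "OPEN"
    CLOSED = "CLOSED"


@dataclass
class HeapsFit:
    """Heaps'-law fit P(N) = kappa * N**gamma and the openness verdict."""

    kappa: float
    gamma: float
    openness: Openness
    n_permutations: int
    curve: list[tuple[int, float]]


_GAMMA_TOL = 1e-6


def fit_heaps(curve: list[tuple[int, float, float]] | list[tuple[int, float]],
              n_permutations: int = 0) -> HeapsFit:
    """Fit Heaps' law by least squares on log P(N) vs log N.

    OPEN iff gamma > 0; |gamma| <= 1e-6 counts as CLOSED (flat curve).
    """
    pts = [(p[0], p[1]) for p in curve]
    if len(pts) < 3:
        raise ValueError("Heaps fit needs at least 3 curve points")
    N = np.array([p[0] for p in pts], dtype=float)
    P = np.array([p[1] for p in pts], dtype=float)
    if (P <= 0).any():
        raise ValueError("curve sizes must be positive")
    gamma, log_kappa = np.polyfit(np.log(N), np.log(P), 1)
    kappa = float(np.exp(log_kappa))
    openness = Openness.OPEN if gamma > _GAMMA_TOL else Openness.CLOSED
    return HeapsFit(kappa, float(gamma), openness, n_permutations, pts)
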