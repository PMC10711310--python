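"""Core-genome phylogeny and average nucleotide identity.

The tree is a neighbor-joining (Saitou-Nei, with the Studier-Keppler
Q-matrix) phylogeny on distances from the concatenated core alignment, with
column-bootstrap supports.  NJ recovers additive distance matrices exactly,
which is what matters for clade recovery within a species at > 99 % ANI.
Negative NJ branch-length estimates are clamped to zero with the deficit
shifted onto the sibling edge, so Newick output is non-negative.

ANI is fragment-based: the query is cut into fixed-length windows, each is
locally aligned to the reference (seeded by shared 16-mers), and the ANI is
the mean identity of fragments passing the acceptance floor.  Unaligned
fragment tails count against identity, so spurious short local hits between
unrelated genomes do not pass the floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .alignment import Msa, ScoringScheme, align_local, default_dna_scheme
from .errors import ConsistencyError, SaturationError
from .io_formats import GenomeRecord

logger = logging.getLogger("panstrain.phylogeny")

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "Model",
    "AniResult",
    "concatenate_core_alignment",
    "variant_columns",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_supports",
    "fragment_ani",
    "assign_species_by_ani",
    "UNASSIGNED",
]


# ---------------------------------------------------------------------------
# distance matrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over an ordered id list."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")

    def value(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted phylogeny stored with a trifurcating root node."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode):
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the leaf set not containing the
        lexicographically smallest taxon (a canonical representation)."""
        taxa = set(self.leaf_names())
        ref = min(taxa)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}
            below = set()
            for c in node.children:
                below |= walk(c)
            if node is not self.root:
                side = below if ref not in below else taxa - below
                if 1 < len(side) < len(taxa) - 1:
                    out.add(frozenset(side))
            return below

        walk(self.root)
        return out

    def to_newick(self) -> str:
        seen: set[int] = set()

        def fmt(node: TreeNode, top: bool) -> str:
            if id(node) in seen:
                raise ValueError("cyclic tree structure")
            seen.add(id(node))
            if node.is_leaf:
                core = node.name or ""
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = ""
                if not top and node.support is not None:
                    label = ("%g" % node.support)
                core = f"({inner}){label}"
            if top:
                return core
            return f"{core}:{node.length:.10g}"

        return fmt(self.root, True) + ";"


class Model(str, Enum):
    P_DISTANCE = "P_DISTANCE"
    JC = "JC"


# ---------------------------------------------------------------------------
# core alignment handling
# ---------------------------------------------------------------------------

class ConcatenatedAlignment(Msa):
    """Concatenation of per-family alignments with column provenance."""

    def __init__(self, rows: dict[str, str], blocks: list[tuple[str, int]]):
        super().__init__(rows)
        self._blocks = blocks  # (family_id, aligned length) in concatenation order

    def provenance(self, global_col: int) -> tuple[str, int]:
        """Map a 1-based concatenated column to (family_id, 1-based local column)."""
        if not 1 <= global_col <= self.length:
            raise IndexError(f"column {global_col} outside 1..{self.length}")
        offset = 0
        for fid, ln in self._blocks:
            if global_col <= offset + ln:
                return fid, global_col - offset
            offset += ln
        raise AssertionError("unreachable")


def concatenate_core_alignment(
    msas: dict[str, Msa],
    genome_ids: list[str],
) -> ConcatenatedAlignment:
    """Concatenate strict-core family alignments in sorted family-id order.

    Every family alignment must cover every genome (strict core only);
    total length is the sum of the family alignment lengths.
    """
    rows = {g: [] for g in genome_ids}
    blocks: list[tuple[str, int]] = []
    for fid in sorted(msas):
        msa = msas[fid]
        missing = set(genome_ids) - set(msa.ids)
        if missing:
            raise ConsistencyError(
                f"family {fid} is missing genomes {sorted(missing)}; "
                "only strict-core families can be concatenated")
        for g in genome_ids:
            rows[g].append(msa.rows[g])
        blocks.append((fid, msa.length))
    return ConcatenatedAlignment({g: "".join(parts) for g, parts in rows.items()}, blocks)


class VariantColumnsMsa(Msa):
    """A column-reduced alignment remembering original 1-based column indices."""

    def __init__(self, rows: dict[str, str], source_columns: list[int]):
        super().__init__(rows)
        self.source_columns = source_columns


def variant_columns(msa: Msa) -> VariantColumnsMsa:
    """Keep columns with >= 2 distinct non-gap residues (SNP-style reduction)."""
    if len(msa.rows) < 2:
        raise ValueError("need at least 2 rows")
    ids = msa.ids
    arr = np.array([list(msa.rows[i]) for i in ids])
    keep: list[int] = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        residues = set(col[col != "-"])
        if len(residues) >= 2:
            keep.append(j)
    rows = {i: "".join(arr[k, keep]) for k, i in enumerate(ids)}
    if not keep:
        rows = {i: "" for i in ids}
    return VariantColumnsMsa(rows, [j + 1 for j in keep])


_NT = set("ACGTN-")


def _encode_rows(msa: Msa, ids: list[str]) -> np.ndarray:
    return np.array([np.frombuffer(msa.rows[i].encode(), dtype=np.uint8) for i in ids])


def distance_matrix(msa: Msa, model: Model = Model.P_DISTANCE) -> DistanceMatrix:
    """Pairwise distances over columns where both rows are non-gap.

    p-distance is the mismatch fraction; the JC model applies
    -(3/4)ln(1 - 4p/3) for nucleotide rows and the Poisson correction
    -ln(1-p) for protein rows.  Saturated pairs (p >= 3/4 nucleotide) raise
    :class:`SaturationError`.
    """
    ids = sorted(msa.rows)
    if len(ids) < 2:
        raise ValueError("need at least 2 rows")
    arr = _encode_rows(msa, ids)
    gap = ord("-")
    is_nt = set("".join(msa.rows.values())) <= _NT
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (arr[i] != gap) & (arr[j] != gap)
            shared = int(both.sum())
            if shared == 0:
                raise SaturationError(
                    f"rows {ids[i]!r} and {ids[j]!r} share no aligned columns")
            p = float((arr[i][both] != arr[j][both]).sum() / shared)
            if model == Model.JC:
                if is_nt:
                    if p >= 0.75:
                        raise SaturationError(
                            f"JC undefined for p={p:.3f} >= 0.75 "
                            f"({ids[i]!r} vs {ids[j]!r})")
                    p = -0.75 * np.log(1 - 4 * p / 3)
                else:
                    if p >= 1.0:
                        raise SaturationError(
                            f"Poisson correction undefined for p={p:.3f} "
                            f"({ids[i]!r} vs {ids[j]!r})")
                    p = -np.log(1 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # negative estimate -> zero, deficit moved to the sibling edge
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Studier-Keppler Q criterion is joined at each
    step; ties go to the smallest (i, j) index pair in the current matrix
    order.  Additive matrices are recovered exactly (topology and lengths).
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in D.ids]
    d = D.d.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = np.argmin(q)  # row-major argmin = smallest (i, j) among ties
        bi, bj = divmod(int(best), m)
        if bi > bj:
            bi, bj = bj, bi
        i_idx, j_idx = active[bi], active[bj]
        dij = sub[bi, bj]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        node_i, node_j = nodes[i_idx], nodes[j_idx]
        node_i.length, node_j.length = li, lj
        parent = TreeNode(children=[node_i, node_j])
        new_idx = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i_idx, j_idx):
                continue
            dk = 0.5 * (d[i_idx, k] + d[j_idx, k] - dij)
            d[new_idx, k] = d[k, new_idx] = max(dk, 0.0)
        active = [k for k in active if k not in (i_idx, j_idx)] + [new_idx]
    # final trifurcation via the three-point formulas
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = max(ln, 0.0)
    return Tree(TreeNode(children=[nodes[a], nodes[b], nodes[c]]))


def bootstrap_supports(
    msa: Msa,
    n_replicates: int,
    seed: int,
    model: Model = Model.P_DISTANCE,
) -> Tree:
    """NJ tree with column-bootstrap supports (percent of replicates).

    Alignment columns are resampled with replacement per replicate, a NJ
    tree built from each, and every internal bipartition of the full-data
    tree scored by the percentage of replicate trees containing it.
    Reproducible for a fixed seed; invariant to leaf input order (ids are
    sorted internally).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base = neighbor_joining(distance_matrix(msa, model))
    ids = sorted(msa.rows)
    arr = _encode_rows(msa, ids)
    L = arr.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_rows = {ids[k]: arr[k, cols].tobytes().decode() for k in range(len(ids))}
        rep_tree = neighbor_joining(distance_matrix(Msa(rep_rows), model))
        for bp in rep_tree.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    taxa = set(ids)
    ref = min(taxa)

    def annotate(node: TreeNode) -> set[str]:
        if node.is_leaf:
            return {node.name}
        below = set()
        for ch in node.children:
            below |= annotate(ch)
        if node is not base.root:
            side = below if ref not in below else taxa - below
            if 1 < len(side) < len(taxa) - 1:
                node.support = 100.0 * counts.get(frozenset(side), 0) / n_replicates
        return below

    annotate(base.root)
    return base


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------

@dataclass
class AniResult:
    """Fragment-based ANI between a query and a reference genome.

    ``ani`` is ``None`` when no fragment passes the acceptance floor
    (undefined, which is not the same as 0).
    """

    query_id: str
    ref_id: str
    ani: float | None
    fragments_used: int
    fragments_total: int


_SEED_K = 16


def _kmer_index(genome: GenomeRecord, k: int = _SEED_K) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for cid, seq in genome.contigs.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((cid, i))
    return index


def _fragment_identity(fragment: str, target: str, scheme: ScoringScheme) -> float:
    """Local-alignment identity with unaligned fragment tails counted as
    mismatch columns, so the fragment must be covered to score well."""
    aln = align_local(fragment, target, scheme)
    if aln.n_columns == 0:
        return 0.0
    matches = sum(1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x != "-")
    eff_cols = aln.n_columns + (len(fragment) - (aln.a_end - aln.a_start))
    return matches / eff_cols


def fragment_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    frag_len: int = 1000,
    min_frag_identity: float = 0.8,
    scheme: ScoringScheme | None = None,
    max_fragments: int | None = None,
) -> AniResult:
    """Fragment-based average nucleotide identity of ``a`` against ``b``.

    The query's contigs are cut into consecutive ``frag_len`` windows (the
    tail shorter than ``frag_len`` is discarded).  Each fragment is locally
    aligned to the best-seeded candidate window of the reference (located by
    shared 16-mers; seedless fragments are unalignable) and fragments
    reaching ``min_frag_identity`` contribute to the mean.  With
    ``max_fragments`` set, an evenly spaced deterministic subset of windows
    is evaluated instead of all of them.
    """
    if scheme is None:
        scheme = default_dna_scheme()
    if a.total_length < frag_len or b.total_length < frag_len:
        raise ValueError(f"both genomes must have total length >= {frag_len}")
    index = _kmer_index(b)
    pad = 150
    identities: list[float] = []
    fragments_total = 0
    windows: list[str] = []
    for _cid, seq in sorted(a.contigs.items()):
        for start in range(0, len(seq) - frag_len + 1, frag_len):
            windows.append(seq[start:start + frag_len])
    if max_fragments is not None and len(windows) > max_fragments:
        picks = np.unique(np.linspace(0, len(windows) - 1, max_fragments).astype(int))
        windows = [windows[i] for i in picks]
    for fragment in windows:
        fragments_total += 1
        hits: dict[str, list[int]] = {}
        for i in range(0, frag_len - _SEED_K + 1):
            for cid, pos in index.get(fragment[i:i + _SEED_K], ()):
                hits.setdefault(cid, []).append(pos - i)
        if hits:
            cid = max(hits, key=lambda c: (len(hits[c]), c))
            offset = int(np.median(hits[cid]))
            contig = b.contigs[cid]
            lo = max(0, offset - pad)
            hi = min(len(contig), offset + frag_len + pad)
            ident = _fragment_identity(fragment, contig[lo:hi], scheme)
        else:
            # no shared 16-mer: at >= 80 % identity a 1 kb fragment carries
            # ~28 intact 16-mers in expectation, so a seedless fragment is
            # treated as unalignable (excluded, like an unmapped fragment)
            ident = 0.0
        if ident >= min_frag_identity:
            identities.append(ident)
    if not identities:
        return AniResult(a.genome_id, b.genome_id, None, 0, fragments_total)
    return AniResult(a.genome_id, b.genome_id, 100.0 * float(np.mean(identities)),
                     len(identities), fragments_total)


UNASSIGNED = "UNASSIGNED"


def assign_species_by_ani(
    genome: GenomeRecord,
    refs: list[tuple[str, GenomeRecord]],
    threshold: float = 95.0,
    frag_len: int = 1000,
    min_frag_identity: float = 0.8,
) -> str:
    """Assign the species of the best-ANI reference, gated at ``threshold`` %.

    Returns ``UNASSIGNED`` when no reference reaches the threshold or every
    ANI is undefined.  Ties go to the lexicographically smallest species.
    """
    if not refs:
        raise ValueError("at least one reference is required")
    best_species, best_ani = None, -1.0
    for species, ref in sorted(refs, key=lambda r: r[0]):
        res = fragment_ani(genome, ref, frag_len, min_frag_identity)
        if res.ani is not None and res.ani > best_ani:
            best_species, best_ani = species, res.ani
    if best_species is None or best_ani < threshold:
        return UNASSIGNED
    return best_species
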