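"""Pairwise affine-gap alignment and center-star multiple alignment.

This module is the computational engine beneath gene-family clustering,
group-variant scanning, fragment ANI and marker profiling.  It provides

* Needleman-Wunsch global alignment with affine gaps (Gotoh's algorithm),
* Smith-Waterman local alignment with affine gaps,
* a center-star multiple sequence aligner for intra-species gene families.

Gap model: a run of L gap columns scores ``gap_open + (L - 1) * gap_extend``
(the first gap column pays the opening penalty).  Percent identity is defined
project-wide as matches divided by alignment columns excluding dual-gap
columns, so gap columns count against identity; this pins down the meaning of
the 95 % clustering threshold.

Traceback tie-breaking is fixed (diagonal > up > left, and within each state
match > gap-in-b > gap-in-a) so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .errors import AlphabetError

__all__ = [
    "ScoringScheme",
    "PairwiseAlignment",
    "Msa",
    "align_global",
    "align_local",
    "center_star_msa",
]

_NEG = -1.0e30  # effective -infinity that stays finite under addition

# traceback states
_M, _X, _Y = 0, 1, 2  # match/mismatch, gap in b (consume a), gap in a
_STOP = 3


# ---------------------------------------------------------------------------
# scoring schemes
# ---------------------------------------------------------------------------

def _blosum62() -> tuple[str, np.ndarray]:
    m = substitution_matrices.load("BLOSUM62")
    alphabet = str(m.alphabet)
    arr = np.array(m, dtype=np.float64)
    return alphabet, arr


def _dna_matrix(match: float = 1.0, mismatch: float = -1.0) -> tuple[str, np.ndarray]:
    alphabet = "ACGTN"
    n = len(alphabet)
    arr = np.full((n, n), mismatch, dtype=np.float64)
    np.fill_diagonal(arr, match)
    # N is ambiguous: never rewarded, penalized like a mismatch (incl. N/N)
    arr[4, :] = mismatch
    arr[:, 4] = mismatch
    return alphabet, arr


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``gap_open`` is the score of the first column of a gap run and
    ``gap_extend`` of each subsequent column; both are negative and
    ``gap_open <= gap_extend``.
    """

    alphabet: str
    matrix: np.ndarray
    gap_open: float
    gap_extend: float
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")
        if self.matrix.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("matrix shape does not match alphabet")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.alphabet)})

    @classmethod
    def protein_default(cls, gap_open: float = -11.0, gap_extend: float = -1.0) -> "ScoringScheme":
        """BLOSUM62 with BLASTp-style gap penalties."""
        alphabet, arr = _blosum62()
        return cls(alphabet, arr, gap_open, gap_extend)

    @classmethod
    def dna_default(cls, gap_open: float = -5.0, gap_extend: float = -2.0) -> "ScoringScheme":
        """+1/-1 match/mismatch nucleotide scheme."""
        alphabet, arr = _dna_matrix()
        return cls(alphabet, arr, gap_open, gap_extend)

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.fromiter((self._index[c] for c in seq), dtype=np.int64, count=len(seq))
        except KeyError as e:
            raise AlphabetError(f"residue {e.args[0]!r} not in scheme alphabet") from None


_PROTEIN_DEFAULT: ScoringScheme | None = None
_DNA_DEFAULT: ScoringScheme | None = None


def default_protein_scheme() -> ScoringScheme:
    global _PROTEIN_DEFAULT
    if _PROTEIN_DEFAULT is None:
        _PROTEIN_DEFAULT = ScoringScheme.protein_default()
    return _PROTEIN_DEFAULT


def default_dna_scheme() -> ScoringScheme:
    global _DNA_DEFAULT
    if _DNA_DEFAULT is None:
        _DNA_DEFAULT = ScoringScheme.dna_default()
    return _DNA_DEFAULT


# ---------------------------------------------------------------------------
# numba DP kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nw_fill(sub, a, b, go, ge):  # pragma: no cover - exercised via align_global
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    pM = np.full((n + 1, m + 1), _STOP, dtype=np.uint8)
    pX = np.full((n + 1, m + 1), _STOP, dtype=np.uint8)
    pY = np.full((n + 1, m + 1), _STOP, dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
        pX[i, 0] = _M if i == 1 else _X
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge
        pY[0, j] = _M if j == 1 else _Y
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub[ai, b[j - 1]]
            # M: diagonal move, predecessor preference M > X > Y
            best = M[i - 1, j - 1]
            ptr = _M
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = _X
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = _Y
            M[i, j] = best + s
            pM[i, j] = ptr
            # X: gap in b (vertical), open from M/Y, extend from X
            best = M[i - 1, j] + go
            ptr = _M
            if X[i - 1, j] + ge > best:
                best = X[i - 1, j] + ge
                ptr = _X
            if Y[i - 1, j] + go > best:
                best = Y[i - 1, j] + go
                ptr = _Y
            X[i, j] = best
            pX[i, j] = ptr
            # Y: gap in a (horizontal)
            best = M[i, j - 1] + go
            ptr = _M
            if X[i, j - 1] + go > best:
                best = X[i, j - 1] + go
                ptr = _X
            if Y[i, j - 1] + ge > best:
                best = Y[i, j - 1] + ge
                ptr = _Y
            Y[i, j] = best
            pY[i, j] = ptr
    return M, X, Y, pM, pX, pY


@njit(cache=True)
def _nw_score(sub, a, b, go, ge):  # pragma: no cover
    """Score-only Gotoh with two rolling rows (used for center selection)."""
    n, m = a.shape[0], b.shape[0]
    Mp = np.full(m + 1, _NEG)
    Xp = np.full(m + 1, _NEG)
    Yp = np.full(m + 1, _NEG)
    Mp[0] = 0.0
    for j in range(1, m + 1):
        Yp[j] = go + (j - 1) * ge
    Mc = np.empty(m + 1)
    Xc = np.empty(m + 1)
    Yc = np.empty(m + 1)
    for i in range(1, n + 1):
        Mc[0] = _NEG
        Yc[0] = _NEG
        Xc[0] = go + (i - 1) * ge
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub[ai, b[j - 1]]
            Mc[j] = s + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xc[j] = max(Mp[j] + go, Xp[j] + ge, Yp[j] + go)
            Yc[j] = max(Mc[j - 1] + go, Xc[j - 1] + go, Yc[j - 1] + ge)
        Mp, Mc = Mc, Mp
        Xp, Xc = Xc, Xp
        Yp, Yc = Yc, Yp
    return max(Mp[m], Xp[m], Yp[m])


@njit(cache=True)
def _sw_fill(sub, a, b, go, ge):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    pM = np.full((n + 1, m + 1), _STOP, dtype=np.uint8)
    pX = np.full((n + 1, m + 1), _STOP, dtype=np.uint8)
    pY = np.full((n + 1, m + 1), _STOP, dtype=np.uint8)
    best_score = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub[ai, b[j - 1]]
            best = M[i - 1, j - 1]
            ptr = _M
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = _X
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = _Y
            if best <= 0.0:
                best = 0.0
                ptr = _STOP  # fresh start: this cell opens the local path
            v = best + s
            if v < 0.0:
                v = 0.0
                ptr = _STOP  # dead cell
            M[i, j] = v
            pM[i, j] = ptr
            best = M[i - 1, j] + go
            ptr = _M
            if X[i - 1, j] + ge > best:
                best = X[i - 1, j] + ge
                ptr = _X
            if Y[i - 1, j] + go > best:
                best = Y[i - 1, j] + go
                ptr = _Y
            X[i, j] = best
            pX[i, j] = ptr
            best = M[i, j - 1] + go
            ptr = _M
            if X[i, j - 1] + go > best:
                best = X[i, j - 1] + go
                ptr = _X
            if Y[i, j - 1] + ge > best:
                best = Y[i, j - 1] + ge
                ptr = _Y
            Y[i, j] = best
            pY[i, j] = ptr
            if M[i, j] > best_score:
                best_score = M[i, j]
                bi = i
                bj = j
    return M, pM, pX, pY, best_score, bi, bj


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseAlignment:
    """An aligned sequence pair with identity and coverage statistics.

    ``identity`` is matches over alignment columns (dual-gap columns cannot
    occur in a pairwise alignment).  ``coverage_a``/``coverage_b`` are the
    aligned span of each sequence divided by its full length; both are 1.0
    for global alignments.  ``a_start``/``a_end`` (0-based, half-open) locate
    the aligned span, which for local alignments may be a proper substring.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    coverage_a: float
    coverage_b: float
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def _identity(aligned_a: str, aligned_b: str) -> float:
    cols = len(aligned_a)
    if cols == 0:
        return 0.0
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    return matches / cols


def align_global(a: str, b: str, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch alignment under affine gaps (Gotoh).

    End gaps are penalized.  Deterministic traceback: at equal score the
    diagonal move is preferred over a gap in ``b`` over a gap in ``a``.
    """
    if scheme is None:
        scheme = default_protein_scheme()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea, eb = scheme.encode(a), scheme.encode(b)
    M, X, Y, pM, pX, pY = _nw_fill(scheme.matrix, ea, eb, scheme.gap_open, scheme.gap_extend)
    n, m = len(a), len(b)
    state = _M
    score = M[n, m]
    if X[n, m] > score:
        score, state = X[n, m], _X
    if Y[n, m] > score:
        score, state = Y[n, m], _Y
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    ptrs = (pM, pX, pY)
    while i > 0 or j > 0:
        prev = ptrs[state][i, j]
        if state == _M:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == _X:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        state = prev
    aa = "".join(reversed(out_a))
    ab = "".join(reversed(out_b))
    return PairwiseAlignment(
        aligned_a=aa, aligned_b=ab, score=float(score),
        identity=_identity(aa, ab), coverage_a=1.0, coverage_b=1.0,
        a_start=0, a_end=n, b_start=0, b_end=m,
    )


def align_global_score(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Global alignment score without traceback (rolling-row Gotoh)."""
    if scheme is None:
        scheme = default_protein_scheme()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return float(_nw_score(scheme.matrix, scheme.encode(a), scheme.encode(b),
                           scheme.gap_open, scheme.gap_extend))


def align_local(a: str, b: str, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal Smith-Waterman local alignment under affine gaps.

    The empty alignment (score 0) is a legal result when no positive-scoring
    pairing exists.  Among equal-scoring cells the first in row-major order
    wins, making the result deterministic.
    """
    if scheme is None:
        scheme = default_protein_scheme()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea, eb = scheme.encode(a), scheme.encode(b)
    M, pM, pX, pY, best, bi, bj = _sw_fill(scheme.matrix, ea, eb, scheme.gap_open, scheme.gap_extend)
    if best <= 0.0:
        return PairwiseAlignment("", "", 0.0, 0.0, 0.0, 0.0, 0, 0, 0, 0)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = bi, bj
    state = _M
    ptrs = (pM, pX, pY)
    while True:
        prev = ptrs[state][i, j]
        if state == _M:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
            if prev == _STOP:
                break
        elif state == _X:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        state = prev
    aa = "".join(reversed(out_a))
    ab = "".join(reversed(out_b))
    a_start, a_end = i, bi
    b_start, b_end = j, bj
    return PairwiseAlignment(
        aligned_a=aa, aligned_b=ab, score=float(best),
        identity=_identity(aa, ab),
        coverage_a=(a_end - a_start) / len(a),
        coverage_b=(b_end - b_start) / len(b),
        a_start=a_start, a_end=a_end, b_start=b_start, b_end=b_end,
    )


# ---------------------------------------------------------------------------
# center-star multiple alignment
# ---------------------------------------------------------------------------

@dataclass
class Msa:
    """A multiple sequence alignment: id -> equal-length gapped row."""

    rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("Msa rows must have equal length")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def degapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace("-", "")

    def column(self, j: int) -> dict[str, str]:
        """Residues at 1-based column ``j``."""
        return {sid: row[j - 1] for sid, row in self.rows.items()}

    def subset(self, ids) -> "Msa":
        return Msa({i: self.rows[i] for i in ids})


def center_star_msa(seqs: dict[str, str], scheme: ScoringScheme | None = None) -> Msa:
    """Center-star multiple alignment.

    The center is the sequence maximizing the summed global alignment score
    to all others (ties broken by lexicographically smallest id); the other
    sequences are merged against it under "once a gap, always a gap".
    De-gapping any output row reproduces its input sequence exactly.
    """
    if not seqs:
        raise ValueError("center_star_msa requires at least one sequence")
    if scheme is None:
        scheme = default_protein_scheme()
    ids = sorted(seqs)
    if len(ids) == 1:
        return Msa({ids[0]: seqs[ids[0]]})
    enc = {i: scheme.encode(seqs[i]) for i in ids}
    total = {i: 0.0 for i in ids}
    for ix in range(len(ids)):
        for jx in range(ix + 1, len(ids)):
            s = float(_nw_score(scheme.matrix, enc[ids[ix]], enc[ids[jx]],
                                scheme.gap_open, scheme.gap_extend))
            total[ids[ix]] += s
            total[ids[jx]] += s
    center = min(ids, key=lambda i: (-total[i], i))
    center_seq = seqs[center]

    master = list(center_seq)  # center row with accumulated gaps
    merged: dict[str, list[str]] = {center: list(center_seq)}
    for sid in ids:
        if sid == center:
            continue
        pw = align_global(center_seq, seqs[sid], scheme)
        ac, as_ = pw.aligned_a, pw.aligned_b
        new_master: list[str] = []
        new_row: list[str] = []
        inserts: list[int] = []  # columns (in new master) where old rows need a gap
        i = j = 0
        while i < len(master) or j < len(ac):
            mi = master[i] if i < len(master) else None
            cj = ac[j] if j < len(ac) else None
            if mi == "-" and cj == "-":
                new_master.append("-")
                new_row.append(as_[j])
                i += 1
                j += 1
            elif mi == "-":
                new_master.append("-")
                new_row.append("-")
                i += 1
            elif cj == "-":
                new_master.append("-")
                new_row.append(as_[j])
                inserts.append(len(new_master) - 1)
                j += 1
            else:
                new_master.append(mi)
                new_row.append(as_[j])
                i += 1
                j += 1
        if inserts:
            for rid, row in merged.items():
                for col in inserts:
                    row.insert(col, "-")
                # note: inserts are ascending positions in the NEW master, so
                # inserting in order keeps subsequent indices valid
        master = new_master
        merged[sid] = new_row
    return Msa({i: "".join(merged[i]) for i in sorted(merged)})
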