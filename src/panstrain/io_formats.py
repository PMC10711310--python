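"""File formats and domain records: FASTA, GFF3 CDS extraction, metadata
tables, Rtab-style presence/absence matrices and Newick output.

Coordinates follow the GFF3 convention: 1-based, inclusive on both ends, so
an extracted CDS always has length ``end - start + 1``.  Translation uses the
bacterial genetic code (NCBI table 11); the terminal stop is removed and
internal stops are kept but flagged (metagenome-assembled genomes carry
pseudogenized fragments).  Ambiguous codons translate to ``X``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import ConsistencyError, CoordinateError, FormatError, MetadataError

logger = logging.getLogger("panstrain.io")

__all__ = [
    "Group",
    "Source",
    "GenomeRecord",
    "Gene",
    "MetadataTable",
    "read_fasta",
    "write_fasta",
    "read_gff_genes",
    "write_gff",
    "read_presence_absence",
    "write_presence_absence",
    "write_newick",
    "write_aligned_fasta",
]


class Group(str, Enum):
    """Phenotype label of the source pregnancy: preterm or full-term birth."""

    PTB = "PTB"
    FTB = "FTB"
    UNKNOWN = "UNKNOWN"


class Source(str, Enum):
    ISOLATE = "ISOLATE"
    MAG = "MAG"


@dataclass
class GenomeRecord:
    """One genome: contig sequences plus its sample-level annotations."""

    genome_id: str
    contigs: dict[str, str]
    group: Group = Group.UNKNOWN
    source: Source = Source.ISOLATE
    completeness: float = 100.0
    contamination: float = 0.0

    def __post_init__(self):
        if isinstance(self.group, str):
            self.group = Group(self.group)
        if isinstance(self.source, str):
            self.source = Source(self.source)
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {cid!r} of {self.genome_id} is empty")
        self.contigs = {cid: seq.upper() for cid, seq in self.contigs.items()}
        if not (0 <= self.completeness <= 100):
            raise ValueError("completeness must be in [0, 100]")
        if self.contamination < 0:
            raise ValueError("contamination must be >= 0")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class Gene:
    """A CDS with its coordinates, nucleotide sequence and translation."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    nt_seq: str
    aa_seq: str
    has_internal_stop: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if len(self.nt_seq) != self.end - self.start + 1:
            raise ValueError(f"gene {self.gene_id}: nt length != end - start + 1")


_BACTERIAL_TABLE = 11


def translate_cds(nt_seq: str) -> tuple[str, bool]:
    """Translate a complete CDS under the bacterial code.

    Returns the protein without the terminal stop, plus a flag marking
    internal stop codons (kept as ``*`` in the returned string).
    """
    if len(nt_seq) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    aa = str(Seq(nt_seq).translate(table=_BACTERIAL_TABLE))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa, "*" in aa


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA file into ``[(id, SEQUENCE), ...]``.

    The id is the header token before the first whitespace; the remainder of
    the header is ignored.  Sequences are uppercased and order is preserved.
    """
    with _open_text(path) as fh:
        first = None
        for line in fh:
            if line.strip():
                first = line
                break
        if first is None:
            return []
        if not first.startswith(">"):
            raise FormatError(f"{path}: first non-blank line does not start with '>'")
    out: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            if not seq:
                raise FormatError(f"{path}: empty sequence under header {header!r}")
            out.append((header.split()[0], seq.upper()))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_aligned_fasta(msa, path: str | Path) -> None:
    """Write an Msa as aligned FASTA (gap character '-')."""
    write_fasta(((sid, msa.rows[sid]) for sid in msa.ids), path)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_gff_genes(gff_path: str | Path, genome: GenomeRecord) -> list[Gene]:
    """Extract CDS features from a GFF3 file as :class:`Gene` records.

    Minus-strand CDS are reverse-complemented before translation.  CDS whose
    length is not a multiple of three (broken MAG fragments) are skipped with
    a logged warning; coordinates beyond the contig raise
    :class:`CoordinateError`.
    """
    genes: list[Gene] = []
    counter = 0
    with _open_text(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line == "##FASTA":
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{gff_path}:{lineno}: expected 9 tab-separated columns")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            if seqid not in genome.contigs:
                raise ConsistencyError(
                    f"{gff_path}:{lineno}: seqid {seqid!r} is not a contig of {genome.genome_id}")
            start, end = int(start_s), int(end_s)
            contig = genome.contigs[seqid]
            if start < 1 or end > len(contig):
                raise CoordinateError(
                    f"{gff_path}:{lineno}: CDS {start}..{end} exceeds contig "
                    f"{seqid} (length {len(contig)})")
            counter += 1
            gene_id = None
            for part in attrs.split(";"):
                if part.startswith("ID="):
                    gene_id = part[3:]
                    break
            if gene_id is None:
                gene_id = f"{genome.genome_id}_{counter:05d}"
            nt = contig[start - 1:end]
            if strand == "-":
                nt = revcomp(nt)
            if len(nt) % 3 != 0:
                logger.warning(
                    "skipping CDS %s (%s:%d..%d): length %d not divisible by 3",
                    gene_id, seqid, start, end, len(nt))
                continue
            aa, internal_stop = translate_cds(nt)
            genes.append(Gene(
                gene_id=gene_id, genome_id=genome.genome_id, contig_id=seqid,
                start=start, end=end, strand=strand, nt_seq=nt, aa_seq=aa,
                has_internal_stop=internal_stop))
    return genes


def write_gff(genes: Iterable[Gene], path: str | Path, source: str = "panstrain") -> None:
    """Write CDS features as GFF3 (one line per gene)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([
                g.contig_id, source, "CDS", str(g.start), str(g.end), ".",
                g.strand, "0", f"ID={g.gene_id}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

_REQUIRED_META = ["genome_id", "group", "source", "completeness", "contamination"]


@dataclass
class MetadataTable:
    """Per-genome sample metadata (one row per genome id).

    Required columns: genome_id, group (PTB/FTB/UNKNOWN), source
    (ISOLATE/MAG), completeness, contamination.  Additional columns
    (gestation weeks, birthweight, CST, ...) are carried through untouched.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        for col in _REQUIRED_META:
            if col not in self.df.columns:
                raise MetadataError(f"metadata is missing required column {col!r}")
        if self.df["genome_id"].duplicated().any():
            dup = self.df.loc[self.df["genome_id"].duplicated(), "genome_id"].iloc[0]
            raise MetadataError(f"duplicate genome_id {dup!r} in metadata")
        bad = set(self.df["group"]) - {g.value for g in Group}
        if bad:
            raise MetadataError(f"unknown group labels: {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows: Iterable[dict]) -> "MetadataTable":
        return cls(pd.DataFrame(list(rows)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MetadataTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"genome_id": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df["genome_id"])

    def group_of(self, genome_id: str) -> Group:
        sel = self.df.loc[self.df["genome_id"] == genome_id, "group"]
        if sel.empty:
            raise MetadataError(f"genome {genome_id!r} not in metadata")
        return Group(sel.iloc[0])

    def groups(self) -> dict[str, Group]:
        return {r.genome_id: Group(r.group) for r in self.df.itertuples()}

    def ids_in_group(self, group: Group) -> list[str]:
        return [g for g, grp in self.groups().items() if grp == group]


# ---------------------------------------------------------------------------
# presence/absence (Rtab-style)
# ---------------------------------------------------------------------------

def write_presence_absence(matrix, path: str | Path) -> None:
    """Write a presence/absence matrix as a tab-separated Rtab-style table."""
    df = matrix.df if hasattr(matrix, "df") else matrix
    out = df.copy()
    out.index.name = "Gene"
    out.to_csv(path, sep="\t")


def read_presence_absence(path: str | Path):
    """Read an Rtab-style table back into a :class:`PresenceAbsenceMatrix`."""
    from .pangenome import PresenceAbsenceMatrix  # deferred to avoid a cycle

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    values = df.to_numpy()
    if not ((values == 0) | (values == 1)).all():
        raise FormatError(f"{path}: presence/absence cells must be 0 or 1")
    return PresenceAbsenceMatrix(df.astype("int8"))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Serialize a tree (with branch lengths and optional supports) to Newick."""
    Path(path).write_text(tree.to_newick() + "\n")
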