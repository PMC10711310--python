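"""Synthetic pangenome collections with known ground truth.

The generator emulates a small cohort of closely related strains of one
bacterial species split into two phenotype groups (preterm- and
full-term-associated), the regime of the real data this package targets:

* a shared core genome of protein-coding families, each genome's copy
  diverged from the ancestor at a small per-site amino-acid rate;
* planted group-fixed amino-acid differences in core genes (group 1 carries
  one residue at a chosen position, group 2 a different one; these positions
  are protected from background mutation so the truth is exact);
* planted group-specific accessory genes (present in all of group 1, absent
  from group 2, optionally flipped with a noise probability);
* a shared accessory pool at 50 % presence plus Poisson-distributed novel
  families per genome (an infinitely-many-genes accessory model: a positive
  novel-gene rate yields an open pangenome);
* MAG-style degradation: a fraction of genomes lose genes at random
  (completeness) and gain contaminating genes copied from another genome.

Proteins are reverse-translated with uniform synonymous codons (bacterial
code), concatenated with random spacers into contigs, and emitted as
standard FASTA + GFF3 + metadata + a ground-truth JSON, so the synthetic
collections are consumed exactly like real annotated assemblies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import ConfigError
from .io_formats import (Gene, GenomeRecord, Group, MetadataTable, Source,
                         revcomp, write_fasta, write_gff)
from .pangenome import PresenceAbsenceMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_collection",
    "degrade_to_mag",
    "img_presence_matrix",
    "write_collection",
    "random_dna",
    "mutate_dna",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"

_table = CodonTable.unambiguous_dna_by_id[11]
_CODONS: dict[str, list[str]] = {}
for codon, aa in _table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
_STOPS = sorted(_table.stop_codons)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic collection.

    Defaults mirror a 15-genome cohort: 6 group-1 (preterm) and 9 group-2
    (full-term) genomes, 500 core families of 300 aa, 14 planted
    group-specific genes, 185 planted group-fixed variants, 0.5 % background
    amino-acid divergence (the intra-species regime around 99.3-99.9 % ANI),
    an open accessory genome, and 40 % of genomes degraded to MAG quality.
    """

    n_group1: int = 6
    n_group2: int = 9
    n_core_families: int = 500
    core_gene_len_aa: int = 300
    accessory_novel_per_genome: float = 15.0
    shared_accessory: int = 120
    n_planted_group_genes: int = 14
    n_planted_variants: int = 185
    background_aa_divergence: float = 0.005
    presence_flip_noise: float = 0.0
    mag_fraction: float = 0.4
    mag_completeness_range: tuple[float, float] = (90.0, 100.0)
    mag_contamination_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_group1, self.n_group2, self.n_core_families,
                  self.core_gene_len_aa, self.shared_accessory,
                  self.n_planted_group_genes, self.n_planted_variants)
        if any(c < 0 for c in counts):
            raise ConfigError("all counts must be >= 0")
        if self.n_group1 + self.n_group2 < 4:
            raise ConfigError("need at least 4 genomes in total")
        for name in ("background_aa_divergence", "presence_flip_noise", "mag_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.accessory_novel_per_genome < 0:
            raise ConfigError("accessory_novel_per_genome must be >= 0")
        if self.n_planted_variants > self.n_core_families * self.core_gene_len_aa:
            raise ConfigError("more planted variants than core positions")


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery tests.

    ``planted_variants`` positions are 1-based within the core protein.
    ``genome_content`` maps genome id -> sorted synthetic family names;
    ``gene_to_family`` maps every emitted gene id to its synthetic family.
    """

    planted_group_family_ids: list[str]
    planted_variants: list[tuple[str, int, str, str]]  # (family, pos, g1 res, g2 res)
    genome_content: dict[str, list[str]]
    gene_to_family: dict[str, str]
    gamma_regime: str  # OPEN or CLOSED

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        data["planted_variants"] = [tuple(v) for v in data["planted_variants"]]
        return cls(**data)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def mutate_dna(seq: str, n_substitutions: int, rng: np.random.Generator) -> str:
    """Substitute exactly ``n_substitutions`` uniformly chosen positions.

    Each hit position is replaced by a different base, so the realized
    divergence is exactly ``n_substitutions / len(seq)``.
    """
    out = list(seq)
    for i in rng.choice(len(seq), size=n_substitutions, replace=False):
        out[i] = "ACGT".replace(out[i], "")[rng.integers(0, 3)]
    return "".join(out)


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            protected: set[int]) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if int(i) in protected:
            continue
        alt = _AA.replace(out[i], "")
        out[i] = alt[rng.integers(0, len(alt))]
    return "".join(out)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [_CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein]
    codons.append(_STOPS[rng.integers(0, len(_STOPS))])
    return "".join(codons)


def _descend_dna(rng: np.random.Generator, ancestral_dna: str,
                 ancestral_aa: str, derived_aa: str) -> str:
    """DNA of a descendant protein: ancestral codons are inherited at
    unchanged positions; a changed residue redraws a uniform synonymous
    codon.  Synonymous sites are therefore shared by descent, as in real
    conspecific strains."""
    if ancestral_aa == derived_aa:
        return ancestral_dna
    codons = [ancestral_dna[3 * i:3 * i + 3] for i in range(len(ancestral_aa))]
    for i, (x, y) in enumerate(zip(ancestral_aa, derived_aa)):
        if x != y:
            codons[i] = _CODONS[y][rng.integers(0, len(_CODONS[y]))]
    return "".join(codons) + ancestral_dna[-3:]


def _spacer(rng: np.random.Generator) -> str:
    n = int(rng.integers(50, 151))
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# content model (fast path shared with the full generator)
# ---------------------------------------------------------------------------

def img_presence_matrix(
    n_genomes: int,
    n_core: int,
    novel_per_genome: float,
    seed: int,
    shared_accessory: int = 0,
) -> PresenceAbsenceMatrix:
    """Presence/absence matrix of an infinitely-many-genes accessory model.

    Every genome carries all ``n_core`` core families, a 50 % random draw of
    the shared accessory pool, and Poisson(``novel_per_genome``) private
    novel families.  A positive novel-gene rate is the open-pangenome
    regime; zero with no shared accessory gives a flat accumulation curve.
    """
    rng = np.random.default_rng(seed)
    genomes = [f"g{i + 1:02d}" for i in range(n_genomes)]
    rows: dict[str, np.ndarray] = {}
    for f in range(n_core):
        rows[f"core_{f + 1:04d}"] = np.ones(n_genomes, dtype="int8")
    for f in range(shared_accessory):
        rows[f"acc_{f + 1:04d}"] = (rng.random(n_genomes) < 0.5).astype("int8")
    for gi in range(n_genomes):
        for k in range(rng.poisson(novel_per_genome)):
            row = np.zeros(n_genomes, dtype="int8")
            row[gi] = 1
            rows[f"novel_{genomes[gi]}_{k + 1:03d}"] = row
    df = pd.DataFrame(np.array(list(rows.values()), dtype="int8"),
                      index=list(rows), columns=genomes)
    return PresenceAbsenceMatrix(df)


# ---------------------------------------------------------------------------
# full generator
# ---------------------------------------------------------------------------

def simulate_collection(
    cfg: SimConfig,
) -> tuple[list[tuple[GenomeRecord, list[Gene]]], MetadataTable, GroundTruth]:
    """Generate a genome collection with known planted signal.

    Reproducible: every random draw comes from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    g1_ids = [f"PTB{i + 1:02d}" for i in range(cfg.n_group1)]
    g2_ids = [f"FTB{i + 1:02d}" for i in range(cfg.n_group2)]
    genome_ids = g1_ids + g2_ids
    group_of = {g: Group.PTB for g in g1_ids}
    group_of.update({g: Group.FTB for g in g2_ids})

    # --- core families with planted group-fixed variants
    core_names = [f"core_{i + 1:04d}" for i in range(cfg.n_core_families)]
    ancestors = {name: _random_protein(rng, cfg.core_gene_len_aa) for name in core_names}
    flat = rng.choice(cfg.n_core_families * cfg.core_gene_len_aa,
                      size=cfg.n_planted_variants, replace=False)
    planted_variants: list[tuple[str, int, str, str]] = []
    protected: dict[str, set[int]] = {name: set() for name in core_names}
    for idx in sorted(int(x) for x in flat):
        fam = core_names[idx // cfg.core_gene_len_aa]
        pos = idx % cfg.core_gene_len_aa  # 0-based
        x = _AA[rng.integers(0, len(_AA))]
        y = _AA.replace(x, "")[rng.integers(0, len(_AA) - 1)]
        anc = ancestors[fam]
        ancestors[fam] = anc[:pos] + y + anc[pos + 1:]
        protected[fam].add(pos)
        planted_variants.append((fam, pos + 1, x, y))

    # --- accessory pools
    group_gene_names = [f"ptbgene_{i + 1:03d}" for i in range(cfg.n_planted_group_genes)]
    group_gene_seqs = {n: _random_protein(rng, cfg.core_gene_len_aa) for n in group_gene_names}
    shared_names = [f"shared_{i + 1:04d}" for i in range(cfg.shared_accessory)]
    shared_seqs = {n: _random_protein(rng, cfg.core_gene_len_aa) for n in shared_names}

    # ancestral DNA, orientation, gene order and flanking spacers are drawn
    # once and inherited, so conspecific genomes share synonymous sites,
    # strand and synteny; accessory differences appear as indels
    anc_aa = dict(ancestors) | group_gene_seqs | shared_seqs
    anc_dna = {name: _reverse_translate(rng, aa) for name, aa in anc_aa.items()}
    anc_strand = {name: ("+" if rng.random() < 0.5 else "-") for name in anc_aa}
    anc_spacer = {name: _spacer(rng) for name in anc_aa}
    anc_order = [sorted(anc_aa)[i] for i in rng.permutation(len(anc_aa))]

    # --- per-genome content and sequences
    collection: list[tuple[GenomeRecord, list[Gene]]] = []
    genome_content: dict[str, list[str]] = {}
    gene_to_family: dict[str, str] = {}
    for gid in genome_ids:
        is_g1 = group_of[gid] == Group.PTB
        fam_seqs: dict[str, str] = {}
        for name in core_names:
            seq = _mutate(rng, ancestors[name], cfg.background_aa_divergence,
                          protected[name])
            if is_g1 and protected[name]:
                out = list(seq)
                for fam, pos, x, _y in planted_variants:
                    if fam == name:
                        out[pos - 1] = x
                seq = "".join(out)
            fam_seqs[name] = seq
        for name in group_gene_names:
            present = is_g1
            if rng.random() < cfg.presence_flip_noise:
                present = not present
            if present:
                fam_seqs[name] = group_gene_seqs[name]
        for name in shared_names:
            if rng.random() < 0.5:
                fam_seqs[name] = shared_seqs[name]
        for k in range(rng.poisson(cfg.accessory_novel_per_genome)):
            name = f"novel_{gid}_{k + 1:03d}"
            fam_seqs[name] = _random_protein(rng, cfg.core_gene_len_aa)

        order = [name for name in anc_order if name in fam_seqs]
        for name in sorted(fam_seqs):
            if name not in anc_aa:  # genome-private novel family
                order.insert(int(rng.integers(0, len(order) + 1)), name)
        contig_id = f"{gid}_c1"
        parts: list[str] = []
        pos = 0
        genes: list[Gene] = []
        for gi, name in enumerate(order):
            sp = anc_spacer.get(name)
            if sp is None:
                sp = _spacer(rng)
            parts.append(sp)
            pos += len(sp)
            if name in anc_dna:
                nt = _descend_dna(rng, anc_dna[name], anc_aa[name], fam_seqs[name])
                strand = anc_strand[name]
            else:
                nt = _reverse_translate(rng, fam_seqs[name])
                strand = "+" if rng.random() < 0.5 else "-"
            parts.append(nt if strand == "+" else revcomp(nt))
            gene_id = f"{gid}_{gi + 1:05d}"
            genes.append(Gene(
                gene_id=gene_id, genome_id=gid, contig_id=contig_id,
                start=pos + 1, end=pos + len(nt), strand=strand,
                nt_seq=nt, aa_seq=fam_seqs[name]))
            gene_to_family[gene_id] = name
            pos += len(nt)
        parts.append(_spacer(rng))
        genome = GenomeRecord(gid, {contig_id: "".join(parts)},
                              group=group_of[gid], source=Source.ISOLATE,
                              completeness=100.0, contamination=0.0)
        genome_content[gid] = sorted(fam_seqs)
        collection.append((genome, genes))

    # --- MAG degradation
    n_mag = int(round(cfg.mag_fraction * len(genome_ids)))
    if n_mag > 0:
        mag_idx = sorted(int(i) for i in
                         rng.choice(len(genome_ids), size=n_mag, replace=False))
        lo, hi = cfg.mag_completeness_range
        for mi in mag_idx:
            donor_choices = [i for i in range(len(genome_ids)) if i != mi]
            di = donor_choices[rng.integers(0, len(donor_choices))]
            completeness = float(lo + (hi - lo) * rng.random())
            genome, genes = collection[mi]
            donor_genome, donor_genes = collection[di]
            new_genome, new_genes = degrade_to_mag(
                genome, genes, completeness, cfg.mag_contamination_rate,
                donor_genome, donor_genes, rng)
            collection[mi] = (new_genome, new_genes)
            kept_fams = {gene_to_family[g.gene_id] for g in new_genes
                         if g.gene_id in gene_to_family}
            for g in new_genes:
                if g.gene_id not in gene_to_family:
                    src = g.gene_id.split("~", 1)[1]
                    gene_to_family[g.gene_id] = gene_to_family[src]
                    kept_fams.add(gene_to_family[src])
            genome_content[genome.genome_id] = sorted(kept_fams)

    metadata = MetadataTable.from_rows([{
        "genome_id": g.genome_id,
        "group": g.group.value,
        "source": g.source.value,
        "completeness": g.completeness,
        "contamination": g.contamination,
    } for g, _ in collection])
    truth = GroundTruth(
        planted_group_family_ids=list(group_gene_names),
        planted_variants=planted_variants,
        genome_content=genome_content,
        gene_to_family=gene_to_family,
        gamma_regime="OPEN" if cfg.accessory_novel_per_genome > 0 else "CLOSED",
    )
    return collection, metadata, truth


def degrade_to_mag(
    genome: GenomeRecord,
    genes: list[Gene],
    completeness: float,
    contamination_rate: float,
    donor: GenomeRecord,
    donor_genes: list[Gene],
    rng: np.random.Generator,
) -> tuple[GenomeRecord, list[Gene]]:
    """Degrade a genome to MAG quality: random gene loss plus contamination.

    Each gene is kept independently with probability ``completeness / 100``
    (dropped genes are excised from the contig, spacers retained); each donor
    gene is copied in with probability ``contamination_rate`` and appended.
    The returned record carries the *realized* completeness and contamination
    percentages.  With completeness 100 and rate 0 the genome is unchanged.
    """
    if not 0 < completeness <= 100:
        raise ValueError("completeness must be in (0, 100]")
    if donor.genome_id == genome.genome_id:
        raise ValueError("donor must differ from the degraded genome")
    keep = rng.random(len(genes)) < completeness / 100.0
    kept_by_contig: dict[str, list[Gene]] = {}
    keep_flag = {g.gene_id: bool(k) for g, k in zip(genes, keep)}
    by_contig: dict[str, list[Gene]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    new_contigs: dict[str, str] = {}
    new_genes: list[Gene] = []
    for cid, contig in genome.contigs.items():
        placed = sorted(by_contig.get(cid, []), key=lambda g: g.start)
        parts: list[str] = []
        new_len = 0
        last_end = 0  # 0-based exclusive
        for g in placed:
            spacer = contig[last_end:g.start - 1]
            parts.append(spacer)
            new_len += len(spacer)
            if keep_flag[g.gene_id]:
                span = contig[g.start - 1:g.end]
                parts.append(span)
                new_genes.append(dataclasses.replace(
                    g, start=new_len + 1, end=new_len + len(span)))
                new_len += len(span)
            last_end = g.end
        parts.append(contig[last_end:])
        new_contigs[cid] = "".join(parts)
        kept_by_contig[cid] = placed
    # contamination: copy donor genes onto the first contig
    first_cid = next(iter(new_contigs))
    contam = [g for g in sorted(donor_genes, key=lambda g: g.gene_id)
              if rng.random() < contamination_rate]
    added = 0
    for g in contam:
        sp = _spacer(rng)
        base = new_contigs[first_cid] + sp
        start = len(base) + 1
        seg = g.nt_seq if g.strand == "+" else revcomp(g.nt_seq)
        new_contigs[first_cid] = base + seg
        new_genes.append(dataclasses.replace(
            g, gene_id=f"{genome.genome_id}~{g.gene_id}",
            genome_id=genome.genome_id, contig_id=first_cid,
            start=start, end=start + len(g.nt_seq) - 1))
        added += 1
    n_total = len(genes) if genes else 1
    realized_completeness = 100.0 * int(keep.sum()) / n_total
    realized_contamination = 100.0 * added / n_total
    new_genome = GenomeRecord(
        genome.genome_id, new_contigs, group=genome.group, source=Source.MAG,
        completeness=realized_completeness, contamination=realized_contamination)
    return new_genome, new_genes


def write_collection(
    outdir: str | Path,
    collection: list[tuple[GenomeRecord, list[Gene]]],
    metadata: MetadataTable,
    truth: GroundTruth | None = None,
) -> None:
    """Write a collection as per-genome FASTA + GFF3, metadata TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome, genes in collection:
        write_fasta(genome.contigs.items(), outdir / f"{genome.genome_id}.fna")
        write_gff(genes, outdir / f"{genome.genome_id}.gff")
    metadata.to_tsv(outdir / "metadata.tsv")
    if truth is not None:
        truth.to_json(outdir / "truth.json")
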