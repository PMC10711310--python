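# panstrain

Comparative pangenomics for collections of closely related bacterial strains
(pairwise ANI around 99–99.9 %) split into two phenotype groups — the setting
of strain-level vaginal-microbiome studies that ask which genes and which
amino-acid changes distinguish, say, preterm-birth-associated from
full-term-associated *Lactobacillus* strains. The package takes annotated
assemblies (nucleotide FASTA + GFF3 CDS coordinates) with a per-genome
metadata table and produces, end to end:

1. **Gene families** — greedy representative-based protein clustering at a
   configurable identity threshold (default 95 %), with a provably safe
   k-mer screen so only plausible pairs are aligned.
2. **Pangenome structure** — the families × genomes presence/absence matrix
   (Rtab), its core/shell/cloud partition (presence fraction ≥ 0.95 /
   ≥ 0.15 / below), and openness via Heaps' law: the permutation-averaged
   accumulation curve is fit as P(N) = κ·N^γ by log–log least squares;
   γ > 0 means an open pangenome.
3. **Group association** — a two-sided Fisher exact test of each variable
   family's presence against the phenotype grouping, with Bonferroni and
   Benjamini–Hochberg corrections.
4. **Group-exclusive variants** — per-family center-star protein alignments
   scanned for columns where the target group is fixed for a residue never
   seen in the other group (differing aligned amino acids are
   non-synonymous by construction).
5. **Core-genome phylogeny** — neighbor joining (Saitou–Nei with the
   Studier–Keppler criterion) on distances from the concatenated core
   alignment, with column-bootstrap supports; exact on additive matrices.
6. **ANI and species gating** — fragment-based average nucleotide identity
   (1 kb windows, 16-mer seeding, affine-gap local alignment) and
   assignment to the best reference species at the conventional 95 % gate.
7. **Marker profiling** — presence/absence of a marker gene cluster across
   genomes by best local alignment, gated on identity and marker coverage,
   with per-clade concordance.

A synthetic-pangenome generator produces cohorts with planted group-specific
genes, planted group-fixed variants, an open accessory genome and MAG-style
degradation, so every stage has a parameter-recovery test against known
ground truth.

## Worked example

```python
import panstrain as ps

cfg = ps.SimConfig(n_group1=6, n_group2=9, n_core_families=120,
                   core_gene_len_aa=250, n_planted_group_genes=5,
                   n_planted_variants=40, mag_fraction=0.0, seed=7)
collection, metadata, truth = ps.simulate_collection(cfg)

fams = ps.cluster_gene_families(collection, threshold=0.95)
matrix = ps.build_matrix(fams, [g.genome_id for g, _ in collection])
part = ps.partition_pangenome(matrix)
print(f"{fams.n_genes} genes -> {fams.n_families} families "
      f"(core {part.sizes[0]}, shell {part.sizes[1]}, cloud {part.sizes[2]})")

curve = ps.rarefaction_curve(matrix, n_permutations=100, seed=1)
fit = ps.fit_heaps(curve, 100)
print(f"Heaps fit: kappa={fit.kappa:.1f} gamma={fit.gamma:.3f} -> {fit.openness.value}")

results = ps.associate_families(matrix, metadata)
best = results[0]
print(f"top family {best.family_id}: p={best.p_value:.2e} "
      f"bonferroni={best.p_bonferroni:.2e} ({best.direction.value})")

n_var, msas = 0, {}
for fid in part.core_ids:
    rows = {}
    for g in sorted(fams.families[fid], key=lambda g: g.gene_id):
        rows.setdefault(g.genome_id, g.aa_seq)
    msas[fid] = ps.center_star_msa(rows)
    n_var += len(ps.scan_group_variants(msas[fid], metadata, ps.Group.PTB))
print(f"group-exclusive variants in core genes: {n_var}")

concat = ps.concatenate_core_alignment(msas, sorted(matrix.genome_ids))
tree = ps.bootstrap_supports(concat, n_replicates=100, seed=2)
groups = metadata.groups()
ptb = frozenset(g for g in matrix.genome_ids if groups[g] == ps.Group.PTB)
print("groups form two clades:", ptb in tree.bipartitions())
```

prints

```
2964 genes -> 480 families (core 120, shell 124, cloud 236)
Heaps fit: kappa=192.9 gamma=0.323 -> OPEN
top family fam_00383: p=2.00e-04 bonferroni=7.19e-02 (GROUP1_ENRICHED)
group-exclusive variants in core genes: 40
groups form two clades: True
```

The 15 genomes carry 120 shared core families plus planted and random
accessory content. The positive γ classifies the accessory influx as an
open pangenome. The top-ranked family is one of the five planted group-1
genes: present in all six group-1 and no group-2 genomes, its 2×2 table is
the perfect 6-vs-9 separation whose exact two-sided Fisher p is
1/5005 ≈ 2.0·10⁻⁴. The strict scanner finds exactly the 40 planted
group-fixed amino-acid variants, and the bootstrap NJ tree on the
concatenated core alignment splits the two phenotype groups into two clades.

## Command line

Every stage is also a subcommand of the `panstrain` console script
(`simulate`, `qc`, `cluster`, `matrix`, `pangenome`, `associate`,
`variants`, `tree`, `ani`, `profile`, `run-all`), reading fixed-name
artifacts under `--out-dir` so any stage can be re-run from its
predecessors' outputs:

```bash
panstrain simulate --out data/ --seed 1
panstrain run-all --input-dir data/ --out-dir out/ --seed 1
```

`out/manifest.json` records the configuration echo, per-stage derived
seeds, wall times, record counts and sha256 hashes of every artifact; two
runs with the same seed produce identical hashes.

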