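# Methods

This note documents the models, algorithms and numerical choices behind
panstrain, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Alignment engine

All sequence comparison is built on affine-gap dynamic programming:
Needleman–Wunsch global alignment via Gotoh's three-matrix recursion and
Smith–Waterman local alignment, both with numba-compiled kernels.

* **Gap model.** A gap run of length L scores `gap_open + (L−1)·gap_extend`;
  defaults are BLOSUM62 with −11/−1 for protein (the familiar BLASTp
  setting) and +1/−1 match/mismatch with −5/−2 for DNA. `N` is never
  rewarded and `X` behaves as BLOSUM62 defines. All scheme parameters are
  configurable; none of the downstream defaults depend on a particular
  scheme being "correct", only on being fixed.
* **Identity.** Percent identity is defined project-wide as matches divided
  by alignment columns excluding dual-gap columns, i.e. gap columns count
  against identity. Tool dialects differ here; fixing one definition makes
  the 95 % clustering threshold unambiguous.
* **Determinism.** Traceback tie-breaking is fixed (diagonal over gap-in-b
  over gap-in-a; within a gap state, open-from-match preferred) so outputs
  are byte-identical across runs and platforms.
* **Multiple alignment** is center-star: the sequence maximizing the summed
  global score to all others (ties to the smallest id) is the center, and
  the rest are merged under "once a gap, always a gap". For intra-species
  gene families at ≥ 99 % ANI the star topology is essentially exact, the
  cost is O(k²) pairwise alignments per family, and the invariant that
  de-gapping any row reproduces its input is testable. A
  progressive-guide-tree aligner would add complexity without measurable
  benefit in this divergence regime.

## Gene families

Clustering is greedy and representative-based, in the CD-HIT tradition:
proteins sorted by decreasing length (ties by gene id) either join the
first existing family, in founding order, whose representative they match
at ≥ the identity threshold (default 0.95) under global alignment, or found
a new family. Two exact screens skip hopeless alignments without ever
changing the result: a length-ratio bound (identity ≤ min/max length) and a
k-mer count bound — if identity t is attainable over C ≥ max(la, lb)
columns, the matched positions form at most (1−t)(la+lb)+1 exact runs, so
at least t·max(la,lb) − ((1−t)(la+lb)+1)(k−1) k-mer positions of the query
must occur in the representative (k = 4). Candidates are located through an
inverted k-mer → family index. Paralogs stay in one family and collapse to
presence in the matrix; a side report lists multi-copy families.

This is a reimplementation of the gene-family step usually delegated to a
CD-HIT + all-vs-all BLAST + MCL stack. On conspecific genomes the greedy
single-pass rule recovers the same partition whenever within-family
divergence stays clearly below the threshold and between-family identity
stays clearly above it; counts on real data are expected to agree
approximately, not bit-exactly.

## Pangenome structure and openness

With G genomes and a family present in c of them, the partition is by
fraction: core if c/G ≥ 0.95, shell if 0.15 ≤ c/G < 0.95, cloud otherwise.
The fraction rule is applied directly with no integer rounding; at G = 15,
0.95·15 = 14.25 makes "core" mean presence in all 15 genomes.

The accumulation curve records, for random genome orderings, the cumulative
number of distinct families after N = 1..G genomes; means are taken over
permutations (all G! orderings are enumerated exactly when G! does not
exceed the requested permutation count). Heaps' law P(N) = κ·N^γ is fit by
least squares on log P against log N; γ > 10⁻⁶ is called OPEN, anything
else CLOSED (the tolerance absorbs float noise on flat curves). The
total-pangenome-size form of Heaps' law is used because the openness
criterion is the sign of γ, which this form exposes directly.

## Group association

Each family present in some but not all labeled genomes yields a 2×2 table
(group-1 present/absent × group-2 present/absent). The two-sided Fisher
exact p sums hypergeometric probabilities of all tables with the observed
margins whose probability does not exceed the observed table's (ties within
relative tolerance 10⁻⁷); degenerate margins give p = 1. Bonferroni and
Benjamini–Hochberg corrections run over the tested families only.
Genomes labeled UNKNOWN are excluded. Phylogenetically aware pan-GWAS
corrections (pairwise-comparison algorithms) are deliberately out of scope:
with cohorts of ~15 genomes the plain exact test plus corrections is the
transparent choice, and no significance threshold is hard-coded.

## Group-exclusive variants

Core families are individually aligned and scanned column by column.
Strict mode (default) reports a column iff every target-group row carries
one and the same residue (gaps disqualify — a fixed residue cannot be
asserted from a gap) and that residue appears in no other-group row;
lenient mode drops gap rows and requires disjoint, non-empty residue sets
on both sides. Both modes are exposed because reasonable gap policies
differ; strict matches the notion of "mutations specific to" a group.
Scanning at the protein level suffices for non-synonymous variation:
differing aligned amino acids are non-synonymous by construction, so no
codon back-mapping is performed. The summary filter defaults to families
with ≥ 2 variants.

## Core-genome phylogeny

Strict-core family alignments (one gene per genome; the lexicographically
smallest gene id when a genome has paralogs) are concatenated in sorted
family order, with a provenance map from any concatenated column back to
(family, local column). Distances are p-distances over columns where both
rows are ungapped, optionally Jukes–Cantor corrected (−¾ ln(1−4p/3)) for
nucleotides or Poisson corrected (−ln(1−p)) for proteins; saturated pairs
raise an error rather than returning silently clipped values.

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q-matrix and a
deterministic smallest-index tie-break. Additive matrices are recovered
exactly (topology and branch lengths), which is the guarantee the tests
pin. Negative branch-length estimates are clamped to zero with the deficit
moved to the sibling edge, so Newick output is non-negative. Supports come
from column bootstrap: resample alignment columns with replacement, rebuild
the tree, and score each internal bipartition of the full-data tree by the
percentage of replicates containing it. The default is 100 replicates
(tunable; classical practice for publication trees is 10–30× that). A
distance tree with bootstrap stands in for maximum-likelihood inference by
design: at intra-species divergence the question answered — do the
phenotype groups form two clades — is topological, and NJ answers it
exactly on clean signal while remaining dependency-free and fast.

## ANI and species gating

The query is cut into consecutive 1000-bp windows (the short tail is
discarded). For each fragment, shared 16-mers against an index of the
reference locate the best-supported contig and offset; the fragment is then
locally aligned to that window (±150 bp padding). Fragment identity counts
unaligned fragment tails as mismatch columns, so a short spurious local hit
cannot masquerade as a matching fragment. Fragments reaching the
acceptance floor (default 0.8) are averaged into the ANI; if none passes,
the ANI is reported as undefined, never as 0. A fragment with no shared
16-mer is treated as unalignable: at ≥ 80 % identity a 1 kb fragment
carries ~28 intact 16-mers in expectation (0.8¹⁶ ≈ 0.028 per position), so
seedless fragments are overwhelmingly true non-matches, and skipping them
bounds memory and time on large references. Species assignment takes the
reference with the highest defined ANI, gated at 95 % (the conventional
species boundary), with ties to the smallest species name.

The fragment length and acceptance floor are this package's own defaults;
sketching-based tools keep their internal cutoffs undocumented, so
reproductions of published ANI ranges should be read as approximate.

## Marker profiling and quality gating

Genomes pass the quality gate iff completeness ≥ 90 % and contamination
strictly < 5 %. Marker profiling aligns each marker protein locally
against every gene of a genome (candidates pre-screened by a shared 4-mer,
the word-seeding idea of BLASTp); the best-scoring gene (ties by gene id)
is the hit, and presence requires identity ≥ 0.7 and marker coverage ≥ 0.8
by default. Coverage is measured on the marker because the biological
question is whether the genome contains the marker, which stays answerable
when MAG genes are fused or split. Both thresholds are mandatory knobs and
are echoed into outputs. Clade concordance is the spread of per-clade
presence fractions (|f(clade I) − f(clade II)| for two clades).

## Synthetic cohorts

`simulate_collection` emulates a two-group cohort of conspecific genomes.
Defaults mirror the study conditions the package targets: 6 + 9 genomes,
500 core families of 300 aa, 14 planted group-1-specific genes, 185
planted group-fixed variants, 0.5 % background amino-acid divergence per
genome (the intra-species regime around 99.3–99.9 % ANI), a 120-family
shared accessory pool at 50 % presence, Poisson(15) private novel families
per genome (an infinitely-many-genes accessory model, hence an open
pangenome), and 40 % of genomes degraded to MAG quality with completeness
drawn from 90–100 % and a 2 % contamination rate.

Mechanics worth knowing:

* Planted variant positions are protected from background mutation, so the
  ground truth is exact rather than probabilistic, and planted group genes
  can be presence-flipped with a configurable noise rate ε.
* Ancestral DNA (uniform synonymous codons, bacterial code), gene strand,
  gene order and inter-gene spacers are drawn once and inherited; a
  descendant re-draws only the codons of residues it mutated. Conspecific
  genomes therefore share synonymous sites and synteny, as real strains do,
  and accessory differences appear as indels.
* MAG degradation excises lost genes from the contig (spacers retained,
  coordinates recomputed) and appends contamination genes copied from a
  donor genome; realized completeness/contamination percentages are
  recorded in the metadata.

What the generator does **not** emulate: recombination and HGT within
families, indel evolution inside genes, operon structure and expression
strand bias, GC skew, sequencing error, and assembly fragmentation beyond
whole-gene loss. Passing recovery tests therefore demonstrate algorithmic
correctness under clean, well-specified signal — not robustness to every
artifact of real MAGs.

## Pipeline

Stages run in a fixed order (qc → cluster → matrix → pangenome → associate
→ core_msa → variants → tree → ani → profile) and communicate only through
serialized artifacts with fixed names, so any stage can be re-run alone.
Stage seeds derive from the single configured seed XORed with a CRC32 hash
of the stage name, so adding a stage never perturbs another's random
stream. The manifest records a config echo, per-stage seeds, wall times,
record counts and sha256 hashes of every output. The pipeline's pairwise
ANI stage evaluates an evenly spaced subsample of fragments (default 50
per ordered pair) to keep all-vs-all matrices affordable; the subsample is
deterministic, and the full-fragment computation remains available through
the library call.

## Problem sizes

The shipped tests and the acceptance script run entirely on generated
data: the recovery cohort is 15 genomes × ~580 genes of 300 aa
(~8 700 proteins, ~590 kb per genome); Heaps classification uses 20
replicates of a 10-genome, 800-core-family content model; NJ recovery uses
50 random additive trees of 5–12 taxa; ANI calibration uses 30 kb genomes
with exact planted substitution counts. These sizes were chosen so the
whole verification cycle completes in a few minutes on one CPU while
keeping every statistical check at the cohort's true shape (6 + 9 genomes,
500 core families, 14 planted genes, 185 planted variants).

## Known limitations

* Clustering quality degrades when within-family divergence approaches the
  identity threshold; families whose members differ by more than ~5 % from
  the representative will split (by design — the threshold is the
  definition).
* The Fisher test ignores phylogenetic structure; strongly clonal cohorts
  inflate significance, which is why no significance cutoff is baked in.
* Fragment ANI is asymmetric in principle (query windows against a
  reference index); the asymmetry is reported, never silently averaged.
* Center-star MSA is not guaranteed optimal for divergent families; it is
  used only where the intra-species assumption holds.
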