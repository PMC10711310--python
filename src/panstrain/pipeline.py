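"""End-to-end pipeline: quality gate -> gene families -> presence/absence ->
partition + Heaps -> association -> core alignments -> variant scan -> core
phylogeny -> ANI -> marker profile.

Stages communicate only through serialized artifacts under
``out/<stage>/`` with fixed filenames, so any stage can be re-run from the
artifacts of its predecessors.  All randomness flows from the single
configured seed through per-stage substreams derived by hashing the stage
name, so adding a stage never perturbs another stage's stream.  A manifest
records the configuration echo, per-stage seeds, wall times, record counts
and output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io_formats as iof
from .alignment import center_star_msa
from .errors import ConfigError, PanstrainError, StageError
from .io_formats import Gene, GenomeRecord, Group, MetadataTable
from .pangenome import (build_matrix, cluster_gene_families, fit_heaps,
                        partition_pangenome, rarefaction_curve)
from .phylogeny import (Model, bootstrap_supports, concatenate_core_alignment,
                        fragment_ani)
from .profiling import MarkerSet, clade_concordance, filter_genomes, profile_markers
from .signatures import (associate_families, scan_group_variants,
                         summarize_variants, write_association_tsv,
                         write_variants_tsv)

logger = logging.getLogger("panstrain.pipeline")

STAGES = ["qc", "cluster", "matrix", "pangenome", "associate", "core_msa",
          "variants", "tree", "ani", "profile"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; the seed is mandatory for stochastic stages."""

    input_dir: Path
    out_dir: Path
    seed: int
    identity_threshold: float = 0.95
    core_frac: float = 0.95
    shell_min_frac: float = 0.15
    min_completeness: float = 90.0
    max_contamination: float = 5.0
    marker_fasta: Path | None = None
    marker_min_identity: float = 0.7
    marker_min_coverage: float = 0.8
    ani_frag_len: int = 1000
    ani_min_frag_identity: float = 0.8
    ani_max_fragments: int = 50
    n_permutations: int = 100
    n_bootstrap: int = 100
    skip: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.input_dir = Path(self.input_dir)
        self.out_dir = Path(self.out_dir)
        if self.marker_fasta is not None:
            self.marker_fasta = Path(self.marker_fasta)
        for name, lo, hi in [("identity_threshold", 0, 1), ("core_frac", 0, 1),
                             ("shell_min_frac", 0, 1),
                             ("marker_min_identity", 0, 1),
                             ("marker_min_coverage", 0, 1),
                             ("ani_min_frag_identity", 0, 1),
                             ("min_completeness", 0, 100),
                             ("max_contamination", 0, 100)]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigError(f"{name}={v} outside [{lo}, {hi}]")
        unknown = set(self.skip) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages in skip: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key=value config file (``#`` comments allowed)."""
        values: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key=value")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = val
        values.update(overrides)
        return cls(**_coerce(values))


def _coerce(values: dict) -> dict:
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    out: dict = {}
    for key, val in values.items():
        if key not in fields:
            raise ConfigError(f"unknown config key {key!r}")
        if not isinstance(val, str):
            out[key] = val
            continue
        typ = fields[key].type
        if key == "skip":
            out[key] = [s for s in val.split(",") if s]
        elif typ.startswith("int"):
            out[key] = int(val)
        elif typ.startswith("float"):
            out[key] = float(val)
        elif "Path" in typ:
            out[key] = Path(val)
        else:
            out[key] = val
    return out


def stage_seed(base_seed: int, stage: str) -> int:
    """Per-stage substream seed: base seed hashed with the stage name."""
    return (int(base_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


# ---------------------------------------------------------------------------
# input loading
# ---------------------------------------------------------------------------

def load_collection(
    input_dir: str | Path,
    metadata: MetadataTable,
    genome_ids: list[str] | None = None,
) -> list[tuple[GenomeRecord, list[Gene]]]:
    """Load ``<genome>.fna`` + ``<genome>.gff`` pairs for the given genomes."""
    input_dir = Path(input_dir)
    ids = genome_ids if genome_ids is not None else metadata.genome_ids
    collection = []
    meta = {r.genome_id: r for r in metadata.df.itertuples()}
    for gid in ids:
        row = meta[gid]
        contigs = dict(iof.read_fasta(input_dir / f"{gid}.fna"))
        genome = GenomeRecord(gid, contigs, group=Group(row.group),
                              source=row.source, completeness=row.completeness,
                              contamination=row.contamination)
        genes = iof.read_gff_genes(input_dir / f"{gid}.gff", genome)
        collection.append((genome, genes))
    return collection


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all (non-skipped) stages in order and return the manifest."""
    from . import __version__

    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in dataclasses.asdict(cfg).items()},
        "stages": {},
    }
    metadata = MetadataTable.from_tsv(cfg.input_dir / "metadata.tsv")

    def record(stage: str, outputs: list[Path], counts: dict, seed: int | None,
               t0: float) -> None:
        manifest["stages"][stage] = {
            "status": "ok",
            "seed": seed,
            "wall_time_s": round(time.monotonic() - t0, 3),
            "counts": counts,
            "outputs": {p.name: _hash_file(p) for p in outputs},
        }
        logger.info("stage %s done in %.2fs: %s", stage,
                    manifest["stages"][stage]["wall_time_s"], counts)

    def skipped(stage: str, reason: str = "skipped by configuration") -> bool:
        if stage in cfg.skip:
            manifest["stages"][stage] = {"status": "skipped", "reason": reason}
            logger.info("stage %s skipped", stage)
            return True
        return False

    def run_stage(stage: str, fn) -> None:
        if skipped(stage):
            return
        t0 = time.monotonic()
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        try:
            outputs, counts, seed = fn(sdir)
        except (PanstrainError, OSError, ValueError) as e:
            manifest["stages"][stage] = {"status": "failed", "error": str(e)}
            _write_manifest(out, manifest)
            raise StageError(stage, str(e)) from e
        record(stage, outputs, counts, seed, t0)
        _write_manifest(out, manifest)

    # --- qc -----------------------------------------------------------------
    def st_qc(sdir: Path):
        kept, dropped = filter_genomes(metadata, cfg.min_completeness,
                                       cfg.max_contamination)
        (sdir / "kept.txt").write_text("".join(g + "\n" for g in kept))
        pd.DataFrame(dropped, columns=["genome_id", "reason"]).to_csv(
            sdir / "dropped.tsv", sep="\t", index=False)
        return ([sdir / "kept.txt", sdir / "dropped.tsv"],
                {"kept": len(kept), "dropped": len(dropped)}, None)

    run_stage("qc", st_qc)

    def kept_ids() -> list[str]:
        path = out / "qc" / "kept.txt"
        if path.exists():
            return path.read_text().split()
        return metadata.genome_ids

    # --- cluster ------------------------------------------------------------
    def st_cluster(sdir: Path):
        ids = kept_ids()
        collection = load_collection(cfg.input_dir, metadata, ids)
        fams = cluster_gene_families(collection, cfg.identity_threshold)
        rows = []
        for fid, members in fams.families.items():
            rep = fams.representative[fid]
            for g in members:
                rows.append({"gene_id": g.gene_id, "genome_id": g.genome_id,
                             "family_id": fid,
                             "is_representative": int(g.gene_id == rep)})
        pd.DataFrame(rows).to_csv(sdir / "families.tsv", sep="\t", index=False)
        reps = {fams.representative[fid]: next(
            g.aa_seq for g in members if g.gene_id == fams.representative[fid])
            for fid, members in fams.families.items()}
        iof.write_fasta(reps.items(), sdir / "representatives.faa")
        return ([sdir / "families.tsv", sdir / "representatives.faa"],
                {"genes": fams.n_genes, "families": fams.n_families}, None)

    run_stage("cluster", st_cluster)

    def families_table() -> pd.DataFrame:
        return pd.read_csv(out / "cluster" / "families.tsv", sep="\t")

    # --- matrix -------------------------------------------------------------
    def st_matrix(sdir: Path):
        fam = families_table()
        ids = kept_ids()
        pres = (fam.groupby(["family_id", "genome_id"]).size().unstack(fill_value=0) > 0)
        pres = pres.reindex(columns=ids, fill_value=False).astype("int8")
        from .pangenome import PresenceAbsenceMatrix
        matrix = PresenceAbsenceMatrix(pres)
        iof.write_presence_absence(matrix, sdir / "gene_presence_absence.Rtab")
        return ([sdir / "gene_presence_absence.Rtab"],
                {"families": len(matrix.family_ids), "genomes": len(ids)}, None)

    run_stage("matrix", st_matrix)

    def matrix_artifact():
        return iof.read_presence_absence(out / "matrix" / "gene_presence_absence.Rtab")

    # --- pangenome ----------------------------------------------------------
    def st_pangenome(sdir: Path):
        matrix = matrix_artifact()
        part = partition_pangenome(matrix, cfg.core_frac, cfg.shell_min_frac)
        part.summary_frame(matrix).to_csv(sdir / "partition.tsv", sep="\t", index=False)
        seed = stage_seed(cfg.seed, "pangenome")
        curve = rarefaction_curve(matrix, cfg.n_permutations, seed)
        pd.DataFrame(curve, columns=["n_genomes", "mean_pangenome_size",
                                     "mean_new_genes"]).to_csv(
            sdir / "rarefaction.tsv", sep="\t", index=False)
        fit = fit_heaps(curve, cfg.n_permutations)
        (sdir / "heaps.json").write_text(json.dumps({
            "kappa": fit.kappa, "gamma": fit.gamma,
            "openness": fit.openness.value,
            "n_permutations": cfg.n_permutations}, indent=1))
        core, shell, cloud = part.sizes
        return ([sdir / "partition.tsv", sdir / "rarefaction.tsv", sdir / "heaps.json"],
                {"core": core, "shell": shell, "cloud": cloud,
                 "gamma": round(fit.gamma, 4)}, seed)

    run_stage("pangenome", st_pangenome)

    # --- associate ----------------------------------------------------------
    def st_associate(sdir: Path):
        matrix = matrix_artifact()
        results = associate_families(matrix, metadata)
        write_association_tsv(results, sdir / "association.tsv")
        return ([sdir / "association.tsv"], {"tested": len(results)}, None)

    run_stage("associate", st_associate)

    # --- core_msa -----------------------------------------------------------
    def st_core_msa(sdir: Path):
        fam = families_table()
        part = pd.read_csv(out / "pangenome" / "partition.tsv", sep="\t")
        core_fams = sorted(part.loc[part["class"] == "core", "family_id"])
        ids = kept_ids()
        collection = load_collection(cfg.input_dir, metadata, ids)
        seq_of = {g.gene_id: g.aa_seq for _, gs in collection for g in gs}
        outputs = []
        n_strict = 0
        for fid in core_fams:
            members = fam[fam["family_id"] == fid]
            # one gene per genome (smallest gene id); strict core only
            per_genome = (members.sort_values("gene_id")
                          .drop_duplicates("genome_id"))
            if set(per_genome["genome_id"]) != set(ids):
                continue
            msa = center_star_msa({r.genome_id: seq_of[r.gene_id]
                                   for r in per_genome.itertuples()})
            path = sdir / f"{fid}.afa"
            iof.write_aligned_fasta(msa, path)
            outputs.append(path)
            n_strict += 1
        return (outputs, {"strict_core_families": n_strict}, None)

    run_stage("core_msa", st_core_msa)

    def core_msas() -> dict:
        from .alignment import Msa
        msas = {}
        for path in sorted((out / "core_msa").glob("*.afa")):
            msas[path.stem] = Msa(dict(iof.read_fasta(path)))
        return msas

    # --- variants -----------------------------------------------------------
    def st_variants(sdir: Path):
        msas = core_msas()
        per_family = {fid: scan_group_variants(msa, metadata, Group.PTB,
                                               strict=True, family_id=fid)
                      for fid, msa in msas.items()}
        write_variants_tsv(per_family, sdir / "variants.tsv")
        summary = summarize_variants(per_family)
        pd.DataFrame(sorted(summary.reported.items()),
                     columns=["family_id", "n_variants"]).to_csv(
            sdir / "variant_summary.tsv", sep="\t", index=False)
        return ([sdir / "variants.tsv", sdir / "variant_summary.tsv"],
                {"variants": summary.total_variants,
                 "families_with_variants": summary.total_families_with_variants},
                None)

    run_stage("variants", st_variants)

    # --- tree ---------------------------------------------------------------
    def st_tree(sdir: Path):
        msas = core_msas()
        if not msas:
            raise StageError("tree", "no strict-core alignments available")
        concat = concatenate_core_alignment(msas, sorted(kept_ids()))
        seed = stage_seed(cfg.seed, "tree")
        tree = bootstrap_supports(concat, cfg.n_bootstrap, seed, Model.P_DISTANCE)
        iof.write_newick(tree, sdir / "core_tree.nwk")
        return ([sdir / "core_tree.nwk"],
                {"alignment_length": concat.length, "taxa": len(concat.ids),
                 "bootstrap": cfg.n_bootstrap}, seed)

    run_stage("tree", st_tree)

    # --- ani ----------------------------------------------------------------
    def st_ani(sdir: Path):
        ids = kept_ids()
        collection = load_collection(cfg.input_dir, metadata, ids)
        genomes = {g.genome_id: g for g, _ in collection}
        rows = []
        for qid in ids:
            for rid in ids:
                if qid == rid:
                    continue
                res = fragment_ani(genomes[qid], genomes[rid],
                                   cfg.ani_frag_len, cfg.ani_min_frag_identity,
                                   max_fragments=cfg.ani_max_fragments)
                rows.append({"query": qid, "reference": rid,
                             "ani": res.ani if res.ani is not None else "NA",
                             "fragments_used": res.fragments_used,
                             "fragments_total": res.fragments_total})
        pd.DataFrame(rows).to_csv(sdir / "ani_matrix.tsv", sep="\t", index=False)
        return ([sdir / "ani_matrix.tsv"], {"pairs": len(rows)}, None)

    run_stage("ani", st_ani)

    # --- profile ------------------------------------------------------------
    if cfg.marker_fasta is None:
        manifest["stages"]["profile"] = {"status": "skipped",
                                         "reason": "no marker FASTA configured"}
    else:
        def st_profile(sdir: Path):
            markers = MarkerSet.from_fasta(cfg.marker_fasta,
                                           cfg.marker_min_identity,
                                           cfg.marker_min_coverage)
            ids = kept_ids()
            collection = load_collection(cfg.input_dir, metadata, ids)
            profile = profile_markers(markers, collection)
            matrix = profile.matrix.copy()
            matrix.index.name = "Marker"
            matrix.to_csv(sdir / "marker_profile.tsv", sep="\t")
            profile.hits_frame().to_csv(sdir / "marker_hits.tsv", sep="\t",
                                        index=False)
            groups = metadata.groups()
            clades = {g: groups[g].value for g in ids}
            clade_concordance(profile, clades).to_csv(
                sdir / "clade_concordance.tsv", sep="\t", index=False)
            return ([sdir / "marker_profile.tsv", sdir / "marker_hits.tsv",
                     sdir / "clade_concordance.tsv"],
                    {"markers": len(markers.markers), "genomes": len(ids)}, None)

        run_stage("profile", st_profile)

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
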