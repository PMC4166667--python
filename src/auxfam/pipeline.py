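"""End-to-end orchestration: simulate and/or run every analysis stage.

A :class:`PipelineConfig` either names real input files (genome + GFF3,
proteome FASTA, aligned FASTA, Ct TSV) or carries synthetic-generation
parameters; ``run_pipeline`` executes whichever stages have inputs,
writes one output directory, and records a manifest (seed, config echo,
config hash, stage timings).  Stages with absent inputs are skipped with
a warning; a failing stage aborts with the stage name in the log while
earlier outputs are left in place.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import expression, family_identify, gene_structure, io_core
from . import phylogeny, promoter_scan, synthetic_data
from .domain_grammar import ANNOTATION_HEADER, annotate, annotation_rows

log = logging.getLogger("auxfam.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run.

    Input paths may be absent when ``simulate`` is true (they are then
    produced in the output directory).  Thresholds are validated up
    front so misconfiguration fails before any stage runs.
    """

    out_dir: str = "auxfam_run"
    seed: int = 0

    # real inputs (any may be None)
    genome: str | None = None
    gff: str | None = None
    proteome: str | None = None
    alignment: str | None = None
    ct_table: str | None = None

    # synthetic generation
    simulate: bool = False
    n_chrom: int = 8
    genes_per_chrom: list[int] = field(
        default_factory=lambda: [3, 3, 1, 4, 2, 0, 1, 3]
    )
    alignment_length: int = 120
    n_sister_pairs: int = 3
    noise_sd: float = 0.3
    effect_magnitude: float = 2.0
    attenuation: float = 0.25

    # analysis parameters
    promoter_window: int = 1000
    motifs: list[str] = field(
        default_factory=lambda: [m.name for m in promoter_scan.DEFAULT_MOTIFS]
    )
    bootstrap_reps: int = 1000
    sister_threshold: float = 99.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.promoter_window < 1:
            raise PipelineError("promoter_window must be >= 1")
        if not 0 < self.alpha < 1:
            raise PipelineError("alpha must be in (0, 1)")
        if not 0 <= self.sister_threshold <= 100:
            raise PipelineError("sister_threshold must be in [0, 100]")
        if self.bootstrap_reps < 1:
            raise PipelineError("bootstrap_reps must be >= 1")
        unknown = set(self.motifs) - set(promoter_scan.MOTIFS_BY_NAME)
        if unknown:
            raise PipelineError(f"unknown motifs {sorted(unknown)}")
        if not self.simulate and not any(
            (self.genome, self.gff, self.proteome, self.alignment,
             self.ct_table)
        ):
            raise PipelineError(
                "either real inputs or simulate=true must be configured"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError(f"unknown config keys {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _simulate(cfg: PipelineConfig, out: Path) -> dict:
    """Generate the full synthetic dataset into ``out`` and return paths."""
    genome, annotation, truth_g = synthetic_data.generate_genome(
        cfg.n_chrom, cfg.genes_per_chrom, cfg.seed
    )
    genes = [g.name for g in annotation.genes]
    # a modest default planting plan: one AUX1 and one TGA per gene,
    # alternating strands, plus a GRE on every third promoter
    plan = []
    for i, g in enumerate(genes):
        plan.append((g, "AUX1", -500 - 7 * i, "+" if i % 2 == 0 else "-"))
        plan.append((g, "TGA", -200 - 5 * i, "-" if i % 2 == 0 else "+"))
        if i % 3 == 0:
            plan.append((g, "GRE", -800 - 3 * i, "+"))
    genome, truth_m = synthetic_data.plant_motifs(
        annotation, genome, plan, cfg.seed, window=cfg.promoter_window
    )
    archs = synthetic_data.canonical_family_architectures(len(genes))
    for arch, g in zip(archs, genes):
        arch.name = g
    proteins, truth_p = synthetic_data.generate_proteins(archs, cfg.seed)
    n_pairs = min(cfg.n_sister_pairs, len(genes) // 2)
    if n_pairs < cfg.n_sister_pairs:
        log.warning("only %d sister pairs fit %d genes", n_pairs, len(genes))
    alignment, truth_a = synthetic_data.generate_alignment(
        n_taxa=len(genes), length=cfg.alignment_length,
        n_pairs=n_pairs, seed=cfg.seed, names=genes,
    )
    design = synthetic_data.ExperimentDesign(
        conditions=synthetic_data.FOUR_CONDITIONS,
        timepoints=synthetic_data.INFECTION_TIMEPOINTS,
    )
    effects = synthetic_data.plant_infection_effects(
        genes, magnitude=cfg.effect_magnitude, attenuation=cfg.attenuation
    )
    ct = synthetic_data.generate_ct_table(
        genes, design, effects, cfg.noise_sd, cfg.seed
    )
    paths = {
        "genome": out / "genome.fasta",
        "gff": out / "genes.gff3",
        "proteome": out / "proteome.fasta",
        "alignment": out / "alignment.fasta",
        "ct_table": out / "ct_table.tsv",
    }
    io_core.write_fasta(genome, paths["genome"])
    io_core.write_gff3(annotation, paths["gff"])
    io_core.write_fasta(proteins, paths["proteome"])
    io_core.write_fasta(alignment, paths["alignment"])
    ct.to_csv(paths["ct_table"], sep="\t", index=False)
    truth = synthetic_data.SyntheticTruth(
        seed=cfg.seed,
        planted_genes=truth_g.planted_genes,
        planted_motifs=truth_m.planted_motifs,
        planted_architectures=truth_p.planted_architectures,
        planted_effects=effects,
        noise_sd=cfg.noise_sd,
        planted_pairs=truth_a.planted_pairs,
    )
    synthetic_data.write_truth(truth, out / "truth.json")
    return {k: str(v) for k, v in paths.items()}


ANALYSIS_STAGES = (
    "identify", "domains", "structure", "promoters", "tree", "express",
)


def run_pipeline(cfg: PipelineConfig,
                 stages: set[str] | None = None) -> Path:
    """Run every stage with available inputs; returns the run directory.

    ``stages`` restricts which analysis stages execute (simulation and
    input loading always happen as needed); ``set()`` simulates only.
    """
    if stages is None:
        stages = set(ANALYSIS_STAGES)
    unknown = stages - set(ANALYSIS_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("auxfam")
    root.addHandler(fh)
    timings: dict[str, float] = {}
    skipped: list[str] = []

    def _stage(name, func, *args, **kwargs):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            result = func(*args, **kwargs)
        except Exception as exc:
            log.error("stage %s: FAILED: %s", name, exc)
            raise PipelineError(f"stage {name} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.3fs", name, timings[name])
        return result

    try:
        cfg_paths = dict(
            genome=cfg.genome, gff=cfg.gff, proteome=cfg.proteome,
            alignment=cfg.alignment, ct_table=cfg.ct_table,
        )
        if cfg.simulate:
            cfg_paths.update(_stage("simulate", _simulate, cfg, out))

        def _want(name: str, *inputs) -> bool:
            if name not in stages:
                return False
            if not all(inputs):
                skipped.append(name)
                return False
            return True

        annotation = proteins = genome = None
        if cfg_paths["gff"] and stages & {"structure", "promoters"}:
            annotation = _stage("load-gff", io_core.read_gff3,
                                cfg_paths["gff"])
        if cfg_paths["genome"] and stages & {"structure", "promoters"}:
            genome = _stage("load-genome", io_core.read_fasta,
                            cfg_paths["genome"], "dna")
        if cfg_paths["proteome"] and stages & {"identify", "domains",
                                               "structure"}:
            proteins = _stage(
                "load-proteome", io_core.read_fasta,
                cfg_paths["proteome"], "protein",
            )

        members = None
        if _want("identify", proteins):
            def _identify():
                ids = family_identify.scan_proteome(proteins)
                io_core.write_table(
                    [(i,) for i in ids], out / "family_members.tsv", ("id",)
                )
                return ids
            members = _stage("identify", _identify)

        if _want("domains", proteins):
            def _domains():
                annos = [annotate(rid, seq) for rid, seq in proteins.records]
                io_core.write_table(
                    annotation_rows(annos), out / "domain_annotations.tsv",
                    ANNOTATION_HEADER,
                )
            _stage("domains", _domains)

        if _want("structure", annotation):
            def _structure():
                rows = gene_structure.structure_diagram_table(annotation)
                io_core.write_table(
                    rows, out / "structure_diagram.tsv",
                    gene_structure.DIAGRAM_HEADER,
                )
                if genome is not None:
                    lengths = {r: len(s) for r, s in genome.records}
                    dist = gene_structure.distribution_map(
                        annotation, lengths
                    )
                    io_core.write_table(
                        [
                            (c, g.name, g.start, g.end, g.strand)
                            for c, gs in dist.items() for g in gs
                        ],
                        out / "distribution.tsv",
                        ("chromosome", "gene", "start", "end", "strand"),
                    )
            _stage("structure", _structure)
            if proteins is not None and annotation is not None:
                def _family_table():
                    names = set(proteins.ids)
                    table = family_identify.build_family_table(
                        annotation, proteins,
                        members=[m for m in (members or []) if m in names],
                    )
                    table.df.to_csv(
                        out / "family_table.tsv", sep="\t", index=False
                    )
                _stage("family-table", _family_table)

        if _want("promoters", genome, annotation):
            def _promoters():
                proms = promoter_scan.extract_promoters(
                    genome, annotation, cfg.promoter_window
                )
                motifs = tuple(
                    promoter_scan.MOTIFS_BY_NAME[m] for m in cfg.motifs
                )
                hits = promoter_scan.scan_promoters(proms, motifs)
                io_core.write_bedlike_hits(hits, out / "promoter_hits.tsv")
                counts = promoter_scan.count_table(hits, motifs=motifs)
                io_core.write_table(
                    sorted(counts.items()), out / "motif_counts.tsv",
                    ("motif", "count"),
                )
            _stage("promoters", _promoters)

        if _want("tree", cfg_paths["alignment"]):
            def _tree():
                aln = io_core.read_fasta(
                    cfg_paths["alignment"], "aligned-protein"
                )
                tree = phylogeny.bootstrap_supports(
                    aln, n_reps=cfg.bootstrap_reps, seed=cfg.seed
                )
                io_core.write_newick(tree, out / "tree.nwk")
                pairs = phylogeny.sister_pairs(tree, cfg.sister_threshold)
                io_core.write_table(
                    [(p.taxa[0], p.taxa[1], p.support) for p in pairs],
                    out / "sister_pairs.tsv",
                    ("taxon_a", "taxon_b", "support"),
                )
            _stage("tree", _tree)

        if _want("express", cfg_paths["ct_table"]):
            def _express():
                ct = expression.read_ct_table(cfg_paths["ct_table"])
                conditions = sorted(ct["condition"].unique())
                mock = synthetic_data.MOCK_CONDITION
                if mock not in conditions:
                    mock = conditions[0]
                fcms = {}
                for cond in conditions:
                    if cond == mock:
                        continue
                    fcm = expression.timecourse_contrast(
                        ct, cond, mock, alpha=cfg.alpha
                    )
                    fcms[cond] = fcm
                    safe = cond.replace("/", "_").replace("+", "p").replace(
                        "-", "m"
                    )
                    fcm.to_csv(
                        out / f"expression_{safe}.tsv", sep="\t", index=False
                    )
                    expression.heatmap_matrix(fcm).to_csv(
                        out / f"heatmap_{safe}.tsv", sep="\t"
                    )
                if {"+Sin/-NOA", "+Sin/+NOA"} <= set(fcms):
                    expression.alleviation_score(
                        fcms["+Sin/-NOA"], fcms["+Sin/+NOA"]
                    ).to_csv(out / "alleviation.tsv", sep="\t", index=False)
            _stage("express", _express)

        for name in skipped:
            log.warning("stage %s skipped: inputs absent", name)
        manifest = {
            "package": "auxfam",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": cfg.to_dict(),
            "stages_run": sorted(timings),
            "stages_skipped": sorted(skipped),
            "timings_s": timings,
        }
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=1)
        return out
    finally:
        root.removeHandler(fh)
        fh.close()
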