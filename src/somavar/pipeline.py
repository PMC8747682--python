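"""Pipeline orchestration: simulate -> qc -> classify -> annotate -> stats
-> spectrum -> expression -> report.

Every stage persists plain-text tabular outputs under its own
subdirectory and can be rerun from those alone; a run log records each
stage's parameters, input digests and row counts.  Two runs with
identical inputs and seeds produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import pandas as pd

from . import cross_sample, diversity, expression, qc, simulate, spectrum
from .config import SimulationConfig
from .effects import annotate_all, load_annotation, tag_genes

ALL_STAGES = (
    "simulate", "qc", "classify", "annotate", "stats", "spectrum",
    "expression", "report",
)

SPECTRUM_CLASSES = ("all", "denovo", "Ss", "Sn")


class StageError(RuntimeError):
    """A pipeline stage failed; downstream stages were not run."""


@dataclasses.dataclass
class PipelineConfig:
    out_dir: Path
    sim: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    stages: tuple[str, ...] = ALL_STAGES
    window_bp: int | None = None  # None -> 1% of chromosome, min 10 kb
    cluster_k: float = spectrum.DEFAULT_K
    min_cluster_windows: int = 1
    distal_fraction: float = spectrum.DISTAL_FRACTION
    min_qual: float = qc.MIN_QUAL
    min_mapq: float = qc.MIN_MAPQ
    ht_allele_depth_gt: int = qc.HT_ALLELE_DEPTH_GT
    ho_depth_ge: int = qc.HO_DEPTH_GE

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _log(cfg: PipelineConfig, stage: str, params: str, inputs: list[Path], note: str) -> None:
    log = cfg.out_dir / "pipeline_log.tsv"
    if not log.exists():
        log.write_text("stage\tparams\tinput_digests\tnote\n")
    digests = ";".join(f"{p.name}:{_sha256(p)}" for p in inputs if p.exists())
    with open(log, "a") as fh:
        fh.write(f"{stage}\t{params}\t{digests}\t{note}\n")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the requested stages in dependency order; return output dirs."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    produced: dict[str, Path] = {}
    runners = {
        "simulate": stage_simulate,
        "qc": stage_qc,
        "classify": stage_classify,
        "annotate": stage_annotate,
        "stats": stage_stats,
        "spectrum": stage_spectrum,
        "expression": stage_expression,
        "report": stage_report,
    }
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        try:
            produced[stage] = runners[stage](cfg)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return produced


def stage_simulate(cfg: PipelineConfig) -> Path:
    outdir = cfg.out_dir / "sim"
    simulate.generate_study(cfg.sim, outdir)
    _log(cfg, "simulate", f"seed={cfg.sim.seed}", [outdir / "truth.tsv"],
         f"variants={sum(1 for _ in open(outdir / 'truth.tsv')) - 1}")
    return outdir


def stage_qc(cfg: PipelineConfig) -> Path:
    simdir = cfg.out_dir / "sim"
    outdir = cfg.out_dir / "qc"
    outdir.mkdir(exist_ok=True)
    thresholds = dict(
        min_qual=cfg.min_qual, min_mapq=cfg.min_mapq,
        ht_allele_depth_gt=cfg.ht_allele_depth_gt, ho_depth_ge=cfg.ho_depth_ge,
    )
    for sample in cfg.sim.sample_ids:
        vcf_path = simdir / f"{sample}.vcf"
        calls = qc.read_vcf(vcf_path, sample_id=sample)
        callset = qc.apply_qc(calls, sample_id=sample, **thresholds)
        qc.write_callset(callset, outdir, header=qc.vcf_header(vcf_path))
        _log(cfg, "qc", ";".join(f"{k}={v}" for k, v in thresholds.items()),
             [vcf_path],
             f"sample={sample} in={len(calls)} retained={len(callset.retained)} "
             f"rejected={len(callset.rejected)}")
    return outdir


def _load_callsets(cfg: PipelineConfig) -> list[qc.CallSet]:
    qcdir = cfg.out_dir / "qc"
    callsets = []
    for sample in cfg.sim.sample_ids:
        calls = qc.read_vcf(qcdir / f"{sample}.filtered.vcf", sample_id=sample)
        callsets.append(qc.apply_qc(calls, sample_id=sample))
    return callsets


def stage_classify(cfg: PipelineConfig) -> Path:
    outdir = cfg.out_dir / "classify"
    callsets = _load_callsets(cfg)
    classified = cross_sample.classify(callsets)
    cross_sample.write_classification(classified, list(cfg.sim.sample_ids), outdir)
    counts = cross_sample.summarize_counts(classified, list(cfg.sim.sample_ids))
    _log(cfg, "classify", "key=chrom,pos,ref,alt",
         [cfg.out_dir / "qc" / f"{s}.filtered.vcf" for s in cfg.sim.sample_ids],
         f"union={counts['union']} shared={counts['shared']} denovo={counts['denovo']}")
    return outdir


def _load_classified(cfg: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(
        cfg.out_dir / "classify" / "classified_variants.tsv", sep="\t",
        dtype={"membership": str, "bitmask": str},
    )


def _load_study_annotation(cfg: PipelineConfig):
    simdir = cfg.out_dir / "sim"
    return load_annotation(simdir / "genes.gff3", simdir / "genome.fa")


def stage_annotate(cfg: PipelineConfig) -> Path:
    outdir = cfg.out_dir / "effects"
    outdir.mkdir(exist_ok=True)
    annotation = _load_study_annotation(cfg)
    classified = _load_classified(cfg)
    effects = annotate_all(classified[["chrom", "pos", "ref", "alt"]], annotation)
    effects.to_csv(outdir / "effects.tsv", sep="\t", index=False)
    gene_classes = tag_genes(effects, annotation)
    gene_classes.to_csv(outdir / "gene_classes.tsv", sep="\t", index=False)
    _log(cfg, "annotate", "code=standard",
         [cfg.out_dir / "classify" / "classified_variants.tsv"],
         f"effects={len(effects)} cds={int((effects['placement'] == 'CDS').sum())}")
    return outdir


def stage_stats(cfg: PipelineConfig) -> Path:
    outdir = cfg.out_dir / "stats"
    outdir.mkdir(exist_ok=True)
    simdir = cfg.out_dir / "sim"
    annotation = _load_study_annotation(cfg)
    named = {
        "totipotency": diversity.load_gene_list(simdir / "totipotency_genes.tsv"),
        "stability": diversity.load_gene_list(simdir / "stability_genes.tsv"),
    }
    categories = diversity.make_categories(annotation, named)
    classified = _load_classified(cfg)
    effects = pd.read_csv(cfg.out_dir / "effects" / "effects.tsv", sep="\t",
                          keep_default_na=False)
    report = diversity.build_report(
        classified, effects, categories, list(cfg.sim.sample_ids), annotation
    )
    report.to_csv(outdir / "diversity_report.tsv", sep="\t")
    _log(cfg, "stats", f"categories={','.join(c.name for c in categories)}",
         [cfg.out_dir / "effects" / "effects.tsv"], f"rows={len(report)}")
    return outdir


def stage_spectrum(cfg: PipelineConfig) -> Path:
    outdir = cfg.out_dir / "spectrum"
    outdir.mkdir(exist_ok=True)
    classified = _load_classified(cfg)
    effects = pd.read_csv(cfg.out_dir / "effects" / "effects.tsv", sep="\t",
                          keep_default_na=False)
    lengths = _chromosome_lengths(cfg)
    trends = []
    subsets = {
        "all": classified,
        "denovo": classified[classified["status"] == "denovo"],
        "Ss": effects[effects["effect"] == "Ss"],
        "Sn": effects[effects["effect"] == "Sn"],
    }
    for sample in cfg.sim.sample_ids:
        subsets[sample] = classified[
            classified["membership"].str.split(",").apply(lambda m: sample in m)
        ]
    for cls, sub in subsets.items():
        tracks = spectrum.windowed_density(sub, lengths, cfg.window_bp, cls)
        clusters = {
            c: spectrum.call_clusters(t, cfg.cluster_k, cfg.min_cluster_windows)
            for c, t in tracks.items()
        }
        spectrum.write_tracks(tracks, outdir / f"tracks_{cls}.tsv")
        spectrum.write_clusters(clusters, outdir / f"clusters_{cls}.bed")
        trend = spectrum.positional_trend(tracks, clusters, cfg.distal_fraction)
        trend.insert(0, "variant_class", cls)
        trends.append(trend)
    pd.concat(trends, ignore_index=True).to_csv(
        outdir / "positional_trend.tsv", sep="\t", index=False, float_format="%.6g"
    )
    _log(cfg, "spectrum",
         f"w={cfg.window_bp or 'auto'};k={cfg.cluster_k}",
         [cfg.out_dir / "classify" / "classified_variants.tsv"],
         f"classes={','.join(subsets)}")
    return outdir


def stage_expression(cfg: PipelineConfig) -> Path:
    outdir = cfg.out_dir / "expression"
    outdir.mkdir(exist_ok=True)
    expr = pd.read_csv(cfg.out_dir / "sim" / "expression.tsv", sep="\t")
    gene_classes = pd.read_csv(
        cfg.out_dir / "effects" / "gene_classes.tsv", sep="\t"
    )
    for grouping in ("two-way", "three-way"):
        comparisons = expression.compare_groups(expr, gene_classes, grouping)
        expression.comparisons_frame(comparisons).to_csv(
            outdir / f"comparisons_{grouping.replace('-', '_')}.tsv",
            sep="\t", index=False, float_format="%.6g",
        )
    annotation = _load_study_annotation(cfg)
    positions = pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chromosome, "start": g.start, "end": g.end}
            for g in annotation.genes.values()
        ]
    )
    lengths = _chromosome_lengths(cfg)
    w = cfg.window_bp or spectrum.default_window(next(iter(lengths.values())))
    track = expression.expression_track(expr, positions, lengths, w)
    with open(outdir / "expression_track.tsv", "w") as fh:
        fh.write("chrom\twindow\tmean_expression\n")
        for chrom in sorted(track):
            for i, v in enumerate(track[chrom]):
                fh.write(f"{chrom}\t{i}\t{'' if pd.isna(v) else f'{v:.6g}'}\n")
    _log(cfg, "expression", "test=mannwhitneyu;adjust=holm",
         [cfg.out_dir / "sim" / "expression.tsv"], "groupings=two-way,three-way")
    return outdir


def stage_report(cfg: PipelineConfig) -> Path:
    """Consolidated bundle: diversity table, cluster BEDs, comparisons."""
    outdir = cfg.out_dir / "report"
    outdir.mkdir(exist_ok=True)
    wanted = [
        cfg.out_dir / "stats" / "diversity_report.tsv",
        cfg.out_dir / "classify" / "count_summary.tsv",
        cfg.out_dir / "expression" / "comparisons_two_way.tsv",
        cfg.out_dir / "expression" / "comparisons_three_way.tsv",
    ] + sorted((cfg.out_dir / "spectrum").glob("clusters_*.bed"))
    for src in wanted:
        if src.exists():
            (outdir / src.name).write_bytes(src.read_bytes())
    _log(cfg, "report", "-", wanted, f"files={len(wanted)}")
    return outdir


def _chromosome_lengths(cfg: PipelineConfig) -> dict[str, int]:
    df = pd.read_csv(cfg.out_dir / "sim" / "genome_lengths.tsv", sep="\t")
    return dict(zip(df["chrom"], df["length"].astype(int)))
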