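"""Synthetic study generator with planted truth.

Emulates the design of a pooled-regenerant resequencing study: one
reference genome, three pooled samples whose call sets contain standing
heterozygous variants (shared by every sample) plus sample-private and
pairwise-shared de novo variants, spatial clustering of variants in
hotspot windows, coding/non-coding placement with known synonymous /
non-synonymous truth, and a per-gene expression table in which mutated
genes are shifted upward on the log scale.

Every output is plain text (FASTA, GFF3, VCF v4.2, TSV) and the whole
study is a deterministic function of the configuration, seed included.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .config import ConfigError, SimulationConfig

TRUTH_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "status",
    "membership",
    "genotype_class",
    "placement",
    "gene_id",
    "effect",
    "in_hotspot",
    "passes_qc",
    "qc_rule",
]

#: QC rules the failure injector can plant, keyed by genotype class.
INJECTABLE_RULES = {
    "Ht": ("quality", "multi-allelic", "indel", "ht-allele-depth"),
    "Ho": ("quality", "multi-allelic", "indel", "ho-depth"),
}

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclasses.dataclass(frozen=True)
class GeneSpec:
    """A planted gene: span, strand, and ordered CDS segments (genomic order)."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    cds_segments: tuple[tuple[int, int], ...]  # 1-based inclusive, ascending
    category: str  # totipotency | stability | none


def generate_study(config: SimulationConfig, output_directory: str | Path) -> pd.DataFrame:
    """Write a complete synthetic study and return its truth table.

    Files written under *output_directory*: ``genome.fa``, ``genes.gff3``,
    ``genome_lengths.tsv``, ``totipotency_genes.tsv``,
    ``stability_genes.tsv``, one ``<sample>.vcf`` per sample,
    ``expression.tsv`` and ``truth.tsv``.  Identical config (seed
    included) reproduces byte-identical files.
    """
    config.validate()
    outdir = Path(output_directory)
    outdir.mkdir(parents=True, exist_ok=True)
    if not outdir.is_dir():
        raise NotADirectoryError(str(outdir))

    rng = np.random.default_rng(config.seed)

    genome = _make_genome(rng, config)
    genes = _make_genes(rng, config)
    hotspots = _make_hotspots(rng, config)
    truth = _plant_variants(rng, config, genome, genes, hotspots)
    truth = inject_qc_failures(truth, config, rng)

    _write_fasta(outdir / "genome.fa", genome)
    _write_gff3(outdir / "genes.gff3", genes, config)
    _write_lengths(outdir / "genome_lengths.tsv", config)
    _write_categories(outdir, genes)
    for sample in config.sample_ids:
        _write_vcf(outdir / f"{sample}.vcf", sample, truth, config, rng)
    expression = _draw_expression(rng, config, genes, truth)
    expression.to_csv(outdir / "expression.tsv", sep="\t", index=False, float_format="%.4f")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    config.to_file(outdir / "config.txt")
    return truth


def inject_qc_failures(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Flag a fraction of planted variants to violate exactly one QC rule.

    ``round(qc_violation_fraction * n)`` records are marked
    ``passes_qc = False`` with the violated rule recorded in ``qc_rule``;
    the VCF writer materializes the violation in every member sample's
    record.  With a zero fraction the table is returned unchanged.
    """
    if config.qc_violation_fraction == 0 or truth.empty:
        return truth
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    truth = truth.copy()
    n_flag = int(round(config.qc_violation_fraction * len(truth)))
    flagged = rng.choice(len(truth), size=n_flag, replace=False)
    rules = []
    for idx in flagged:
        gt = truth.iloc[idx]["genotype_class"]
        rules.append(rng.choice(INJECTABLE_RULES[gt]))
    truth.iloc[flagged, truth.columns.get_loc("passes_qc")] = False
    truth.iloc[flagged, truth.columns.get_loc("qc_rule")] = rules
    return truth


# ---------------------------------------------------------------------------
# genome, genes, hotspots

def _make_genome(rng: np.random.Generator, cfg: SimulationConfig) -> dict[str, str]:
    # uniform A/C/G/T composition
    return {
        name: "".join(rng.choice(_BASES, size=cfg.chromosome_length_bp))
        for name in cfg.chromosome_names()
    }


def _gene_structure(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[list[int], list[int]]:
    """Segment and intron lengths for one gene; total CDS length % 3 == 0.

    Individual segments need not be codon-aligned, so codons may span
    segment boundaries — deliberately, to exercise split-codon handling.
    """
    n_seg = max(1, int(rng.poisson(cfg.mean_cds_segments_per_gene)))
    seg_lengths = [int(rng.integers(60, 301)) for _ in range(n_seg)]
    remainder = sum(seg_lengths) % 3
    if remainder:
        seg_lengths[-1] += 3 - remainder
    introns = [int(rng.integers(50, 401)) for _ in range(n_seg - 1)]
    return seg_lengths, introns


def _make_genes(rng: np.random.Generator, cfg: SimulationConfig) -> list[GeneSpec]:
    chrom_names = cfg.chromosome_names()
    per_chrom = [
        cfg.n_genes // cfg.n_chromosomes + (i < cfg.n_genes % cfg.n_chromosomes)
        for i in range(cfg.n_chromosomes)
    ]
    specs: list[tuple[str, int, int, str, tuple[tuple[int, int], ...]]] = []
    for chrom, n_here in zip(chrom_names, per_chrom):
        structures = [_gene_structure(rng, cfg) for _ in range(n_here)]
        spans = [sum(s) + sum(i) for s, i in structures]
        slack = cfg.chromosome_length_bp - sum(spans)
        if slack <= 0:
            raise ConfigError(
                f"chromosome_length_bp too small to place {n_here} genes on {chrom}"
            )
        offsets = np.sort(rng.integers(0, slack, size=n_here))
        cursor_extra = 0
        for (segs, introns), span, off in zip(structures, spans, offsets):
            start = 1 + int(off) + cursor_extra
            cds = []
            pos = start
            for i, seg_len in enumerate(segs):
                cds.append((pos, pos + seg_len - 1))
                pos += seg_len
                if i < len(introns):
                    pos += introns[i]
            strand = "+" if rng.random() < 0.5 else "-"
            specs.append((chrom, start, start + span - 1, strand, tuple(cds)))
            cursor_extra += span
    # categories: a random disjoint split of the gene universe
    n_tot = int(round(cfg.fraction_genes_totipotency * len(specs)))
    n_stab = int(round(cfg.fraction_genes_stability * len(specs)))
    order = rng.permutation(len(specs))
    categories = ["none"] * len(specs)
    for i in order[:n_tot]:
        categories[i] = "totipotency"
    for i in order[n_tot : n_tot + n_stab]:
        categories[i] = "stability"
    return [
        GeneSpec(f"gene{i + 1:04d}", chrom, start, end, strand, cds, cat)
        for i, ((chrom, start, end, strand, cds), cat) in enumerate(zip(specs, categories))
    ]


def _make_hotspots(
    rng: np.random.Generator, cfg: SimulationConfig
) -> dict[str, list[tuple[int, int]]]:
    """Half-open 0-based hotspot windows per chromosome, on the window grid."""
    hw = cfg.hotspot_window_bp
    n_windows = cfg.chromosome_length_bp // hw
    hotspots: dict[str, list[tuple[int, int]]] = {}
    for chrom in cfg.chromosome_names():
        k = min(cfg.hotspot_windows_per_chromosome, n_windows)
        idx = sorted(rng.choice(n_windows, size=k, replace=False)) if k else []
        hotspots[chrom] = [(int(i) * hw, (int(i) + 1) * hw) for i in idx]
    return hotspots


# ---------------------------------------------------------------------------
# variant planting

def _plant_variants(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    genome: dict[str, str],
    genes: list[GeneSpec],
    hotspots: dict[str, list[tuple[int, int]]],
) -> pd.DataFrame:
    chrom_names = cfg.chromosome_names()
    hot_len = {c: sum(e - s for s, e in spots) for c, spots in hotspots.items()}
    used: set[tuple[str, int]] = set()

    def sample_site() -> tuple[str, int]:
        while True:
            chrom = chrom_names[int(rng.integers(cfg.n_chromosomes))]
            H = hot_len[chrom]
            B = cfg.chromosome_length_bp - H
            f = cfg.hotspot_enrichment_factor
            p_hot = (f * H) / (f * H + B) if H else 0.0
            if rng.random() < p_hot:
                s, e = hotspots[chrom][int(rng.integers(len(hotspots[chrom])))]
                pos0 = int(rng.integers(s, e))
            else:
                while True:
                    pos0 = int(rng.integers(cfg.chromosome_length_bp))
                    if not _in_hotspot(pos0, hotspots[chrom]):
                        break
            if (chrom, pos0 + 1) not in used:
                used.add((chrom, pos0 + 1))
                return chrom, pos0 + 1

    memberships = [tuple(cfg.sample_ids)] * cfg.n_shared_variants
    memberships += _denovo_memberships(rng, cfg)

    genes_by_chrom: dict[str, list[GeneSpec]] = {c: [] for c in chrom_names}
    for g in genes:
        genes_by_chrom[g.chrom].append(g)
    starts_by_chrom = {c: [g.start for g in gs] for c, gs in genes_by_chrom.items()}

    rows = []
    for membership in memberships:
        chrom, pos = sample_site()
        ref = genome[chrom][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        gene = _containing_gene(genes_by_chrom[chrom], starts_by_chrom[chrom], pos)
        if gene is None:
            placement, gene_id, effect = "intergenic", "", "NA"
        elif _in_cds(gene, pos):
            placement, gene_id = "CDS", gene.gene_id
            effect = _true_effect(genome[chrom], gene, pos, alt)
        else:
            placement, gene_id, effect = "genic", gene.gene_id, "NA"
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "status": "shared" if len(membership) == len(cfg.sample_ids) else "denovo",
                "membership": ",".join(membership),
                "genotype_class": "Ht" if rng.random() < cfg.ht_fraction else "Ho",
                "placement": placement,
                "gene_id": gene_id,
                "effect": effect,
                "in_hotspot": _in_hotspot(pos - 1, hotspots[chrom]),
                "passes_qc": True,
                "qc_rule": "",
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    if not truth.empty:
        order = truth["chrom"].map({c: i for i, c in enumerate(chrom_names)})
        truth = (
            truth.assign(_o=order)
            .sort_values(["_o", "pos"], kind="mergesort")
            .drop(columns="_o")
            .reset_index(drop=True)
        )
    return truth


def _denovo_memberships(
    rng: np.random.Generator, cfg: SimulationConfig
) -> list[tuple[str, ...]]:
    """Sample memberships for de novo variants.

    Honors the exact per-sample call counts in ``n_denovo_per_sample``;
    ``pairwise_shared_fraction`` of the distinct de novo keys belong to
    exactly two samples (in expectation, subject to count feasibility).
    """
    n = list(cfg.n_denovo_per_sample)
    samples = list(cfg.sample_ids)
    total = sum(n)
    if total == 0:
        return []
    frac = cfg.pairwise_shared_fraction
    n_keys = int(round(total / (1.0 + frac)))
    n_pairs_target = total - n_keys

    pairs = [(i, j) for i in range(len(n)) for j in range(i + 1, len(n))]
    weights = np.array([min(n[i], n[j]) for i, j in pairs], dtype=float)
    remaining = n.copy()
    pair_counts = [0] * len(pairs)
    if weights.sum() > 0 and n_pairs_target > 0:
        alloc = np.floor(n_pairs_target * weights / weights.sum()).astype(int)
        for k, (i, j) in enumerate(pairs):
            take = min(int(alloc[k]), remaining[i], remaining[j])
            pair_counts[k] = take
            remaining[i] -= take
            remaining[j] -= take
    out: list[tuple[str, ...]] = []
    for k, (i, j) in enumerate(pairs):
        out += [(samples[i], samples[j])] * pair_counts[k]
    for i, left in enumerate(remaining):
        out += [(samples[i],)] * left
    perm = rng.permutation(len(out))
    return [out[i] for i in perm]


def _in_hotspot(pos0: int, spots: list[tuple[int, int]]) -> bool:
    return any(s <= pos0 < e for s, e in spots)


def _containing_gene(
    genes: list[GeneSpec], starts: list[int], pos: int
) -> GeneSpec | None:
    i = bisect_right(starts, pos) - 1
    if i >= 0 and genes[i].start <= pos <= genes[i].end:
        return genes[i]
    return None


def _in_cds(gene: GeneSpec, pos: int) -> bool:
    return any(s <= pos <= e for s, e in gene.cds_segments)


def _extract_cds(chrom_seq: str, gene: GeneSpec, mutate: tuple[int, str] | None = None) -> str:
    """CDS in transcript orientation, optionally with one base substituted.

    The substitution is applied on the genomic strand before any reverse
    complementing, i.e. it mimics editing the chromosome and re-extracting.
    """
    parts = []
    for s, e in gene.cds_segments:
        seg = chrom_seq[s - 1 : e]
        if mutate is not None and s <= mutate[0] <= e:
            k = mutate[0] - s
            seg = seg[:k] + mutate[1] + seg[k + 1 :]
        parts.append(seg)
    cds = "".join(parts)
    if gene.strand == "-":
        cds = cds.translate(_COMPLEMENT)[::-1]
    return cds


def _true_effect(chrom_seq: str, gene: GeneSpec, pos: int, alt: str) -> str:
    """Synonymous/non-synonymous truth by whole-protein comparison."""
    prot_ref = str(Seq(_extract_cds(chrom_seq, gene)).translate())
    prot_alt = str(Seq(_extract_cds(chrom_seq, gene, mutate=(pos, alt))).translate())
    return "Ss" if prot_ref == prot_alt else "Sn"


# ---------------------------------------------------------------------------
# writers

def _write_fasta(path: Path, genome: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_gff3(path: Path, genes: list[GeneSpec], cfg: SimulationConfig) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in cfg.chromosome_names():
            fh.write(f"##sequence-region {chrom} 1 {cfg.chromosome_length_bp}\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsomavar\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            segments = list(g.cds_segments)
            transcript_order = segments if g.strand == "+" else segments[::-1]
            phase, phased = 0, {}
            for s, e in transcript_order:
                phased[(s, e)] = phase
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for i, (s, e) in enumerate(segments):
                fh.write(
                    f"{g.chrom}\tsomavar\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phased[(s, e)]}\t"
                    f"ID={g.gene_id}.cds{i + 1};Parent={g.gene_id}\n"
                )


def _write_lengths(path: Path, cfg: SimulationConfig) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom in cfg.chromosome_names():
            fh.write(f"{chrom}\t{cfg.chromosome_length_bp}\n")


def _write_categories(outdir: Path, genes: list[GeneSpec]) -> None:
    for cat, fname in (("totipotency", "totipotency_genes.tsv"), ("stability", "stability_genes.tsv")):
        with open(outdir / fname, "w") as fh:
            fh.write("gene_id\tcategory\n")
            for g in genes:
                if g.category == cat:
                    fh.write(f"{g.gene_id}\t{cat}\n")


def _draw_depths_ht(rng: np.random.Generator, mean: float) -> tuple[int, int]:
    # resample until QC-passing so truth labels stay exact
    while True:
        d1, d2 = rng.poisson(mean / 2, size=2)
        if d1 >= 6 and d2 >= 6:
            return int(d1), int(d2)


def _draw_depths_ho(rng: np.random.Generator, mean: float) -> int:
    while True:
        d = rng.poisson(mean)
        if d >= 5:
            return int(d)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=somavar-simulate
{contigs}##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref first)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _write_vcf(
    path: Path,
    sample: str,
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    contigs = "".join(
        f"##contig=<ID={c},length={cfg.chromosome_length_bp}>\n" for c in cfg.chromosome_names()
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, sample=sample))
        for row in truth.itertuples(index=False):
            if sample not in row.membership.split(","):
                continue
            fh.write(_vcf_record(row, cfg, rng) + "\n")


def _vcf_record(row, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    ref, alt = row.ref, row.alt
    qual = int(rng.integers(30, 61))
    mq = int(rng.integers(30, 61))
    gt_class = row.genotype_class
    rule = row.qc_rule if not row.passes_qc else ""

    if gt_class == "Ht":
        gt = "0/1"
        ad = list(_draw_depths_ht(rng, cfg.allele_depth_mean))
    else:
        gt = "1/1"
        ad = [0, _draw_depths_ho(rng, cfg.allele_depth_mean)]

    if rule == "quality":
        qual = int(rng.integers(0, 30))
    elif rule == "multi-allelic":
        extra = next(b for b in "ACGT" if b not in (ref, alt))
        alt = f"{alt},{extra}"
        gt = "1/2"
        ad = [int(d) for d in (_draw_depths_ht(rng, cfg.allele_depth_mean) + (6,))]
    elif rule == "indel":
        alt = alt + str(rng.choice(list("ACGT")))
    elif rule == "ht-allele-depth":
        ad[int(rng.integers(2))] = int(rng.integers(0, 6))
    elif rule == "ho-depth":
        ad = [0, int(rng.integers(0, 5))]

    ad_str = ",".join(str(d) for d in ad)
    return (
        f"{row.chrom}\t{row.pos}\t.\t{ref}\t{alt}\t{qual}\tPASS\tMQ={mq}\t"
        f"GT:AD\t{gt}:{ad_str}"
    )


# ---------------------------------------------------------------------------
# expression

def _draw_expression(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    genes: list[GeneSpec],
    truth: pd.DataFrame,
) -> pd.DataFrame:
    """Log-normal expression per gene x sample.

    Mutated genes (any planted variant in span) get a log-mean shift;
    genes additionally carrying a non-synonymous variant get a further
    shift, producing the Sn > Ss-only > wild-type ordering.
    """
    genic = truth[truth["gene_id"] != ""] if not truth.empty else truth
    mutated = set(genic["gene_id"]) if not genic.empty else set()
    sn_genes = set(genic.loc[genic["effect"] == "Sn", "gene_id"]) if not genic.empty else set()
    base_mu, sigma = 2.0, 0.5
    rows = []
    for g in genes:
        mu = base_mu
        if g.gene_id in mutated:
            mu += cfg.expression_lognormal_mu_shift_mutated
        if g.gene_id in sn_genes:
            mu += cfg.expression_lognormal_mu_extra_shift_sn
        for sample in cfg.sample_ids:
            rows.append(
                {"gene_id": g.gene_id, "sample": sample, "value": float(rng.lognormal(mu, sigma))}
            )
    return pd.DataFrame(rows, columns=["gene_id", "sample", "value"])
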