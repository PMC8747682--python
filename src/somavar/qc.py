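"""Per-sample VCF parsing and high-confidence SNP filtering.

The retained set is the intersection of: site quality Q >= 30 and mapping
quality q >= 30; at most two distinct alleles at the site; ref and alt
both single bases (SNV, no indels); heterozygous calls with every allele
covered by more than five reads; homozygous calls with total depth >= 5.
Rules are evaluated in a fixed order (quality -> allelicity -> SNV ->
depth) and the rejection log records the first violated rule per call.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from cyvcf2 import VCF

MIN_QUAL = 30.0
MIN_MAPQ = 30.0
HT_ALLELE_DEPTH_GT = 5  # per-allele depth must exceed this for Ht calls
HO_DEPTH_GE = 5  # total depth must reach this for Ho calls

_SNV_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised for a structurally malformed VCF, naming the offending line."""


@dataclasses.dataclass(frozen=True)
class VariantCall:
    """One site-level call in one sample, as parsed (pre-filter).

    ``genotype_class`` is Ht/Ho for het / hom-alt, ``HomRef`` for 0/0
    records and ``Missing`` for uncalled genotypes.  Absent quality or
    depth fields are carried as None, never as zero.
    """

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotype_class: str
    allele_depths: tuple[int, ...] | None  # ref first; None if AD absent
    site_quality: float | None
    mapping_quality: float | None
    sample_id: str
    raw: str = dataclasses.field(default="", repr=False, compare=False)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, first alt) — the cross-sample identity."""
        return (self.chromosome, self.position, self.ref_allele, self.alt_alleles[0])


@dataclasses.dataclass
class CallSet:
    sample_id: str
    retained: list[VariantCall]
    rejected: list[tuple[VariantCall, str]]  # call -> first violated rule


def read_vcf(path: str | Path, sample_id: str | None = None) -> list[VariantCall]:
    """Parse every record of a single-sample VCF, unfiltered.

    Multi-allelic records are kept intact for the filter to reject;
    missing fields become ``None``.
    """
    path = Path(path)
    _prevalidate(path)
    vcf = VCF(str(path))
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else path.stem
    calls = []
    for rec in vcf:
        gt_type = rec.gt_types[0] if len(rec.gt_types) else 2
        genotype_class = {0: "HomRef", 1: "Ht", 2: "Missing", 3: "Ho"}[int(gt_type)]
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        depths = None
        if ad is not None:
            depths = tuple(int(d) for d in ad[0] if d >= 0)
            if len(depths) != 1 + len(rec.ALT):
                depths = None
        mq = rec.INFO.get("MQ")
        calls.append(
            VariantCall(
                chromosome=rec.CHROM,
                position=rec.POS,
                ref_allele=rec.REF,
                alt_alleles=tuple(rec.ALT),
                genotype_class=genotype_class,
                allele_depths=depths,
                site_quality=None if rec.QUAL is None else float(rec.QUAL),
                mapping_quality=None if mq is None else float(mq),
                sample_id=sample_id,
                raw=str(rec).rstrip("\n"),
            )
        )
    return calls


def _prevalidate(path: Path) -> None:
    """Cheap structural scan so malformed lines are reported by number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise VcfParseError(
                    f"{path}: line {lineno}: expected >= 8 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if not fields[1].isdigit():
                raise VcfParseError(
                    f"{path}: line {lineno}: POS is not a positive integer: {fields[1]!r}"
                )


def first_violated_rule(
    call: VariantCall,
    min_qual: float = MIN_QUAL,
    min_mapq: float = MIN_MAPQ,
    ht_allele_depth_gt: int = HT_ALLELE_DEPTH_GT,
    ho_depth_ge: int = HO_DEPTH_GE,
) -> str | None:
    """The first QC rule a call violates, or None if it is retained.

    Evaluation order: quality -> allelicity -> SNV -> depth; absent
    required fields reject with "missing-field" at the step that needs
    them.
    """
    if call.site_quality is None or call.mapping_quality is None:
        return "missing-field"
    if call.site_quality < min_qual or call.mapping_quality < min_mapq:
        return "quality"
    if 1 + len(call.alt_alleles) > 2:
        return "multi-allelic"
    if any(
        len(a) != 1 or a not in _SNV_BASES
        for a in (call.ref_allele, *call.alt_alleles)
    ):
        return "indel"
    if call.allele_depths is None:
        return "missing-field"
    if call.genotype_class == "Ht":
        if any(d <= ht_allele_depth_gt for d in call.allele_depths):
            return "ht-allele-depth"
    elif call.genotype_class == "Ho":
        if sum(call.allele_depths) < ho_depth_ge:
            return "ho-depth"
    else:
        return "missing-field"  # uncalled genotype
    return None


def apply_qc(
    calls: list[VariantCall],
    sample_id: str | None = None,
    **thresholds: float,
) -> CallSet:
    """Partition parsed calls into retained and rejected (with rule).

    Homozygous-reference records are not variants and are dropped
    silently; everything else lands in exactly one of the two sets.
    """
    if sample_id is None:
        sample_id = calls[0].sample_id if calls else ""
    retained: list[VariantCall] = []
    rejected: list[tuple[VariantCall, str]] = []
    for call in calls:
        if call.genotype_class == "HomRef":
            continue
        rule = first_violated_rule(call, **thresholds)
        if rule is None:
            retained.append(call)
        else:
            rejected.append((call, rule))
    return CallSet(sample_id=sample_id, retained=retained, rejected=rejected)


def write_callset(callset: CallSet, outdir: str | Path, header: str | None = None) -> None:
    """Write the filtered VCF (original record lines) and a rejection log TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{callset.sample_id}.filtered.vcf", "w") as fh:
        if header:
            fh.write(header if header.endswith("\n") else header + "\n")
        for call in callset.retained:
            fh.write(call.raw + "\n")
    with open(outdir / f"{callset.sample_id}.rejections.tsv", "w") as fh:
        fh.write("chrom\tpos\tsample\trule\n")
        for call, rule in callset.rejected:
            fh.write(f"{call.chromosome}\t{call.position}\t{callset.sample_id}\t{rule}\n")


def vcf_header(path: str | Path) -> str:
    return VCF(str(path)).raw_header
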