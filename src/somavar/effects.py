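"""Minimal coding-effect annotation from gene models and reference sequence.

Each biallelic SNV is placed by interval containment (CDS segment >
gene span > intergenic).  For CDS variants the containing codon is
located by in-frame offset along the transcript-ordered CDS (codons may
span segment boundaries), the alternate base is substituted —
complemented first on the minus strand — and both codons are translated
with the standard nuclear genetic code.  The change is synonymous (Ss)
iff the residue is unchanged; stop counts as a residue, so gain or loss
of a stop is non-synonymous (Sn).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gffutils
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from intervaltree import IntervalTree
from pyfaidx import Fasta

PLACEMENT_CDS = "CDS"
PLACEMENT_GENIC = "genic"
PLACEMENT_INTERGENIC = "intergenic"

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AnnotationError(ValueError):
    pass


class RefMismatchError(ValueError):
    """The variant's ref allele disagrees with the reference FASTA."""


@dataclasses.dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    cds_segments: tuple[tuple[int, int], ...]  # ascending genomic order
    categories: frozenset[str] = frozenset()

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    def transcript_segments(self) -> tuple[tuple[int, int], ...]:
        """CDS segments in translation order (descending on minus strand)."""
        return self.cds_segments if self.strand == "+" else self.cds_segments[::-1]


@dataclasses.dataclass(frozen=True)
class EffectCall:
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    gene_id: str  # "" for intergenic
    placement: str
    effect: str  # Ss | Sn | none
    codon_before: str = ""
    codon_after: str = ""
    residue_before: str = ""
    residue_after: str = ""


class GenomeAnnotation:
    """Gene models indexed for interval lookup, plus the reference sequence."""

    def __init__(self, genes: list[GeneModel], fasta: Fasta):
        self.genes = {g.gene_id: g for g in genes}
        self.fasta = fasta
        self.chromosome_lengths = {name: len(fasta[name]) for name in fasta.keys()}
        self._span_trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._span_trees.setdefault(g.chromosome, IntervalTree())
            tree.addi(g.start, g.end + 1, g.gene_id)  # half-open
        self._cds_cache: dict[str, str] = {}

    def genes_at(self, chromosome: str, position: int) -> list[GeneModel]:
        tree = self._span_trees.get(chromosome)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.at(position))
        return [self.genes[g] for g in hits]

    def reference_base(self, chromosome: str, position: int) -> str:
        return str(self.fasta[chromosome][position - 1 : position]).upper()

    def cds_sequence(self, gene_id: str) -> str:
        """Strand-corrected CDS in translation order, cached."""
        if gene_id not in self._cds_cache:
            gene = self.genes[gene_id]
            parts = [
                str(self.fasta[gene.chromosome][s - 1 : e]).upper()
                for s, e in gene.cds_segments
            ]
            cds = "".join(parts)
            if gene.strand == "-":
                cds = cds.translate(_COMPLEMENT)[::-1]
            self._cds_cache[gene_id] = cds
        return self._cds_cache[gene_id]


def load_annotation(
    gff3: str | Path,
    fasta: str | Path,
    categories: dict[str, str] | None = None,
) -> GenomeAnnotation:
    """Build a GenomeAnnotation from GFF3 gene/CDS features and a FASTA.

    *categories* optionally maps gene_id -> category name.  Raises
    AnnotationError (naming the gene) for CDS outside the chromosome or
    a total CDS length not divisible by 3.
    """
    ref = Fasta(str(fasta), sequence_always_upper=True)
    try:
        db = gffutils.create_db(
            str(gff3), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return GenomeAnnotation([], ref)  # feature-free annotation
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.id
        if feat.seqid not in ref:
            raise AnnotationError(f"gene {gene_id}: unknown sequence {feat.seqid}")
        chrom_len = len(ref[feat.seqid])
        segments = sorted(
            (c.start, c.end) for c in db.children(feat, featuretype="CDS")
        )
        for s, e in segments:
            if s < 1 or e > chrom_len:
                raise AnnotationError(
                    f"gene {gene_id}: CDS {s}..{e} outside {feat.seqid} (len {chrom_len})"
                )
            if not (feat.start <= s <= e <= feat.end):
                raise AnnotationError(f"gene {gene_id}: CDS {s}..{e} outside gene span")
        total = sum(e - s + 1 for s, e in segments)
        if segments and total % 3:
            raise AnnotationError(
                f"gene {gene_id}: CDS length {total} not divisible by 3"
            )
        cats = frozenset([categories[gene_id]]) if categories and gene_id in categories else frozenset()
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                cds_segments=tuple(segments),
                categories=cats,
            )
        )
    return GenomeAnnotation(genes, ref)


def _cds_offset(gene: GeneModel, position: int) -> int | None:
    """0-based offset of a genomic position along the translated CDS."""
    prior = 0
    for s, e in gene.transcript_segments():
        if s <= position <= e:
            return prior + (position - s if gene.strand == "+" else e - position)
        prior += e - s + 1
    return None


def annotate(
    chromosome: str,
    position: int,
    ref_allele: str,
    alt_allele: str,
    annotation: GenomeAnnotation,
) -> list[EffectCall]:
    """Annotate one SNV; one EffectCall per overlapping gene.

    A variant contained in no gene span yields a single intergenic call.
    """
    ref_base = annotation.reference_base(chromosome, position)
    if ref_base != ref_allele:
        raise RefMismatchError(
            f"{chromosome}:{position} ref allele {ref_allele} != reference base {ref_base}"
        )
    genes = annotation.genes_at(chromosome, position)
    if not genes:
        return [
            EffectCall(chromosome, position, ref_allele, alt_allele, "",
                       PLACEMENT_INTERGENIC, "none")
        ]
    calls = []
    for gene in genes:
        offset = _cds_offset(gene, position)
        if offset is None:
            calls.append(
                EffectCall(chromosome, position, ref_allele, alt_allele,
                           gene.gene_id, PLACEMENT_GENIC, "none")
            )
            continue
        cds = annotation.cds_sequence(gene.gene_id)
        codon_idx, within = divmod(offset, 3)
        codon_before = cds[codon_idx * 3 : codon_idx * 3 + 3]
        sub = alt_allele if gene.strand == "+" else alt_allele.translate(_COMPLEMENT)
        codon_after = codon_before[:within] + sub + codon_before[within + 1 :]
        res_before = _CODON_TABLE[codon_before]
        res_after = _CODON_TABLE[codon_after]
        calls.append(
            EffectCall(
                chromosome, position, ref_allele, alt_allele, gene.gene_id,
                PLACEMENT_CDS,
                "Ss" if res_before == res_after else "Sn",
                codon_before, codon_after, res_before, res_after,
            )
        )
    return calls


def annotate_all(
    variants: pd.DataFrame, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Annotate a table of variants (columns chrom, pos, ref, alt).

    Returns one row per (variant, overlapping gene) — or per variant for
    intergenic ones — preserving any extra input columns.
    """
    extra = [c for c in variants.columns if c not in ("chrom", "pos", "ref", "alt")]
    rename = {
        "chromosome": "chrom", "position": "pos",
        "ref_allele": "ref", "alt_allele": "alt",
    }
    rows = []
    for rec in variants.itertuples(index=False):
        for call in annotate(rec.chrom, int(rec.pos), rec.ref, rec.alt, annotation):
            row = {rename.get(k, k): v for k, v in dataclasses.asdict(call).items()}
            for c in extra:
                row[c] = getattr(rec, c)
            rows.append(row)
    columns = [rename.get(f.name, f.name) for f in dataclasses.fields(EffectCall)] + extra
    return pd.DataFrame(rows, columns=columns)


NON_MUTATED = "non-mutated"
MUTATED_SN = "mutated-Sn"
MUTATED_NO_SN = "mutated-no-Sn"


def tag_genes(effects: pd.DataFrame, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Per-gene mutation summary over the whole gene universe.

    Classes: non-mutated (no SNP in span), mutated-Sn (>= 1 Sn),
    mutated-no-Sn (>= 1 SNP in span, 0 Sn).  Ss/Sn counts are per gene.
    """
    genic = effects[effects["gene_id"] != ""]
    ss = genic[genic["effect"] == "Ss"].groupby("gene_id").size()
    sn = genic[genic["effect"] == "Sn"].groupby("gene_id").size()
    hit = set(genic["gene_id"])
    rows = []
    for gene_id in sorted(annotation.genes):
        n_sn = int(sn.get(gene_id, 0))
        n_ss = int(ss.get(gene_id, 0))
        if gene_id not in hit:
            cls = NON_MUTATED
        elif n_sn > 0:
            cls = MUTATED_SN
        else:
            cls = MUTATED_NO_SN
        rows.append(
            {"gene_id": gene_id, "gene_class": cls, "ss_count": n_ss, "sn_count": n_sn}
        )
    return pd.DataFrame(rows, columns=["gene_id", "gene_class", "ss_count", "sn_count"])
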