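"""Coding-effect annotation against hand-built genes and a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from somavar.config import SimulationConfig
from somavar.effects import (
    MUTATED_NO_SN,
    MUTATED_SN,
    NON_MUTATED,
    AnnotationError,
    RefMismatchError,
    annotate,
    annotate_all,
    load_annotation,
    tag_genes,
)
from somavar.simulate import generate_study

COMPLEMENT = str.maketrans("ACGT", "TGCA")


@pytest.fixture(scope="module")
def tiny(tiny_annotation_files):
    fasta, gff, seq = tiny_annotation_files
    return load_annotation(gff, fasta), seq


class TestLoadAnnotation:
    def test_cds_extracted_by_direct_slice(self, tiny):
        ann, seq = tiny
        expected = seq[10:22] + seq[30:39]
        assert ann.cds_sequence("gene_plus") == expected

    def test_minus_strand_cds_is_reverse_complement(self, tmp_path, tiny_annotation_files):
        fasta, _, seq = tiny_annotation_files
        gff = tmp_path / "minus.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\ttest\tgene\t8\t45\t.\t-\t.\tID=gene_minus\n"
            "chr1\ttest\tCDS\t11\t22\t.\t-\t0\tID=c1;Parent=gene_minus\n"
            "chr1\ttest\tCDS\t31\t39\t.\t-\t0\tID=c2;Parent=gene_minus\n"
        )
        ann = load_annotation(gff, fasta)
        genomic = seq[10:22] + seq[30:39]
        assert ann.cds_sequence("gene_minus") == genomic.translate(COMPLEMENT)[::-1]

    def test_empty_gff_yields_zero_genes(self, tmp_path, tiny_annotation_files):
        fasta, _, _ = tiny_annotation_files
        gff = tmp_path / "empty.gff3"
        gff.write_text("##gff-version 3\n")
        ann = load_annotation(gff, fasta)
        assert ann.genes == {}
        (call,) = annotate("chr1", 5, "T", "A", ann)
        assert call.placement == "intergenic"

    def test_cds_length_not_multiple_of_three_names_gene(self, tmp_path, tiny_annotation_files):
        fasta, _, _ = tiny_annotation_files
        gff = tmp_path / "bad.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\ttest\tgene\t11\t20\t.\t+\t.\tID=broken\n"
            "chr1\ttest\tCDS\t11\t20\t.\t+\t0\tID=c;Parent=broken\n"
        )
        with pytest.raises(AnnotationError, match="broken"):
            load_annotation(gff, fasta)


class TestAnnotate:
    def test_third_position_synonymous(self, tiny):
        # codon 2 is GGA (Gly) at CDS offsets 3..5 = positions 14..16;
        # GGA -> GGG is still Gly
        ann, _ = tiny
        (call,) = annotate("chr1", 16, "A", "G", ann)
        assert (call.codon_before, call.codon_after) == ("GGA", "GGG")
        assert call.effect == "Ss"

    def test_start_codon_nonsynonymous(self, tiny):
        # ATG -> ATA is Met -> Ile
        ann, _ = tiny
        (call,) = annotate("chr1", 13, "G", "A", ann)
        assert (call.codon_before, call.codon_after) == ("ATG", "ATA")
        assert call.effect == "Sn"
        assert (call.residue_before, call.residue_after) == ("M", "I")

    def test_split_codon_assembled_across_segments(self, tiny):
        # codon 4 = ACC from CDS offsets 9..11: positions 20,21,22 hold A,C,C
        ann, _ = tiny
        (call,) = annotate("chr1", 22, "C", "T", ann)
        assert call.codon_before == "ACC"
        assert call.placement == "CDS"

    def test_stop_gain_is_nonsynonymous(self, tiny):
        # codon 5 GGA spans the gap: offset 12 at pos 31 (G); GGA->TGA = stop
        ann, _ = tiny
        (call,) = annotate("chr1", 31, "G", "T", ann)
        assert call.codon_after == "TGA"
        assert call.residue_after == "*"
        assert call.effect == "Sn"

    def test_genic_non_cds_placement(self, tiny):
        ann, _ = tiny
        (call,) = annotate("chr1", 25, "C", "A", ann)  # intron between segments
        assert call.placement == "genic"
        assert call.effect == "none"

    def test_ref_mismatch_raises(self, tiny):
        ann, _ = tiny
        with pytest.raises(RefMismatchError):
            annotate("chr1", 16, "C", "G", ann)  # reference base there is A


def test_strand_symmetry(tmp_path, tiny_annotation_files):
    """Annotating on a minus-strand gene equals annotating the complement
    variant on the reverse-complemented chromosome with a plus-strand copy."""
    fasta, _, seq = tiny_annotation_files
    L = len(seq)
    gff_minus = tmp_path / "m.gff3"
    gff_minus.write_text(
        "##gff-version 3\n"
        "chr1\ttest\tgene\t8\t45\t.\t-\t.\tID=g\n"
        "chr1\ttest\tCDS\t11\t22\t.\t-\t0\tID=c1;Parent=g\n"
        "chr1\ttest\tCDS\t31\t39\t.\t-\t0\tID=c2;Parent=g\n"
    )
    ann_minus = load_annotation(gff_minus, fasta)

    rc = seq.translate(COMPLEMENT)[::-1]
    fasta_rc = tmp_path / "rc.fa"
    fasta_rc.write_text(">chr1\n" + rc + "\n")
    # segment 11..22 maps to L-22+1 .. L-11+1 on the flipped chromosome
    gff_plus = tmp_path / "p.gff3"
    gff_plus.write_text(
        "##gff-version 3\n"
        f"chr1\ttest\tgene\t{L - 45 + 1}\t{L - 8 + 1}\t.\t+\t.\tID=g\n"
        f"chr1\ttest\tCDS\t{L - 39 + 1}\t{L - 31 + 1}\t.\t+\t0\tID=c2;Parent=g\n"
        f"chr1\ttest\tCDS\t{L - 22 + 1}\t{L - 11 + 1}\t.\t+\t0\tID=c1;Parent=g\n"
    )
    ann_plus = load_annotation(gff_plus, fasta_rc)

    for pos in [11, 14, 20, 22, 31, 35, 39]:
        ref = seq[pos - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            (minus_call,) = annotate("chr1", pos, ref, alt, ann_minus)
            (plus_call,) = annotate(
                "chr1", L - pos + 1,
                ref.translate(COMPLEMENT), alt.translate(COMPLEMENT),
                ann_plus,
            )
            assert minus_call.effect == plus_call.effect
            assert minus_call.codon_before == plus_call.codon_before
            assert minus_call.codon_after == plus_call.codon_after


def oracle_effect(annotation, gene, pos, alt):
    """Brute force: substitute on the chromosome, re-extract the whole CDS,
    translate both proteins end to end and compare."""
    chrom = str(annotation.fasta[gene.chromosome][:])
    mutant = chrom[: pos - 1] + alt + chrom[pos:]
    def protein(chrom_seq):
        parts = [chrom_seq[s - 1 : e] for s, e in gene.cds_segments]
        cds = "".join(parts)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return str(Seq(cds).translate())
    return "Ss" if protein(chrom) == protein(mutant) else "Sn"


def test_annotator_agrees_with_mutate_and_translate_oracle(tmp_path):
    """Random CDS SNPs on a synthetic gene set, both strands, split codons."""
    cfg = SimulationConfig(seed=21, n_chromosomes=1, chromosome_length_bp=60_000,
                           n_genes=30, n_shared_variants=0,
                           n_denovo_per_sample=(0, 0, 0))
    generate_study(cfg, tmp_path)
    ann = load_annotation(tmp_path / "genes.gff3", tmp_path / "genome.fa")
    rng = np.random.default_rng(0)
    checked = 0
    genes = list(ann.genes.values())
    while checked < 400:
        gene = genes[rng.integers(len(genes))]
        seg = gene.cds_segments[rng.integers(len(gene.cds_segments))]
        pos = int(rng.integers(seg[0], seg[1] + 1))
        ref = ann.reference_base(gene.chromosome, pos)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        (call,) = annotate(gene.chromosome, pos, ref, alt, ann)
        assert call.placement == "CDS"
        assert call.effect == oracle_effect(ann, gene, pos, alt), (
            gene.gene_id, gene.strand, pos, ref, alt,
        )
        checked += 1


def test_truth_table_effects_match_annotator(default_study):
    """The generator's planted Ss/Sn labels re-derive from the written files."""
    cfg, outdir, truth = default_study
    ann = load_annotation(outdir / "genes.gff3", outdir / "genome.fa")
    cds = truth[truth["placement"] == "CDS"]
    assert len(cds) > 50
    for rec in cds.itertuples():
        (call,) = annotate(rec.chrom, rec.pos, rec.ref, rec.alt, ann)
        assert call.placement == "CDS"
        assert call.effect == rec.effect
        assert call.gene_id == rec.gene_id


class TestTagGenes:
    def test_gene_classes_from_counts(self, tiny):
        ann, _ = tiny
        effects = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [13, 16, 25],
                "ref": ["G", "A", "C"],
                "alt": ["A", "G", "A"],
                "gene_id": ["gene_plus"] * 3,
                "placement": ["CDS", "CDS", "genic"],
                "effect": ["Sn", "Ss", "none"],
            }
        )
        tags = tag_genes(effects, ann)
        row = tags.set_index("gene_id").loc["gene_plus"]
        assert row["gene_class"] == MUTATED_SN
        assert (row["ss_count"], row["sn_count"]) == (1, 1)

    def test_untouched_gene_is_non_mutated(self, tiny):
        ann, _ = tiny
        empty = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "gene_id", "placement", "effect"]
        )
        tags = tag_genes(empty, ann)
        assert (tags["gene_class"] == NON_MUTATED).all()

    def test_labels_match_planted_truth(self, default_study):
        cfg, outdir, truth = default_study
        ann = load_annotation(outdir / "genes.gff3", outdir / "genome.fa")
        effects = annotate_all(truth[["chrom", "pos", "ref", "alt"]], ann)
        tags = tag_genes(effects, ann).set_index("gene_id")
        genic = truth[truth["gene_id"] != ""]
        mutated = set(genic["gene_id"])
        sn_genes = set(genic.loc[genic["effect"] == "Sn", "gene_id"])
        for gene_id, row in tags.iterrows():
            if gene_id in sn_genes:
                assert row["gene_class"] == MUTATED_SN
            elif gene_id in mutated:
                assert row["gene_class"] == MUTATED_NO_SN
            else:
                assert row["gene_class"] == NON_MUTATED
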