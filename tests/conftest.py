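import pandas as pd
import pytest

from somavar.config import SimulationConfig
from somavar.simulate import generate_study


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """The default noiseless synthetic study, generated once per session."""
    outdir = tmp_path_factory.mktemp("study")
    cfg = SimulationConfig(seed=11)
    truth = generate_study(cfg, outdir)
    return cfg, outdir, truth


@pytest.fixture(scope="session")
def tiny_annotation_files(tmp_path_factory):
    """A hand-written one-gene genome small enough to reason about.

    chr1 (60 bp): gene_plus spans 8..45 with CDS segments 11..22 and
    31..39 (21 bp, 7 codons); codon 4 (ACC) straddles the segment gap.
    CDS = ATG GGA CTG ACC GGA TAA GTA -> protein M G L T G * V.
    """
    outdir = tmp_path_factory.mktemp("tiny")
    #            1         2         3         4         5         6
    #   123456789012345678901234567890123456789012345678901234567890
    seq = "TTTTTTTTTTATGGGACTGACCCCCCCCCCGGATAAGTAATTTTTTTTTTTTTTTTTTTT"[:60]
    fasta = outdir / "tiny.fa"
    fasta.write_text(">chr1\n" + seq + "\n")
    # gene_plus: CDS 11..22 and 31..39 => 12 + 9 = 21 bp, 7 codons,
    # a codon (#4) split across the two segments.
    gff = outdir / "tiny.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "##sequence-region chr1 1 60\n"
        "chr1\ttest\tgene\t8\t45\t.\t+\t.\tID=gene_plus\n"
        "chr1\ttest\tCDS\t11\t22\t.\t+\t0\tID=gene_plus.cds1;Parent=gene_plus\n"
        "chr1\ttest\tCDS\t31\t39\t.\t+\t0\tID=gene_plus.cds2;Parent=gene_plus\n"
    )
    return fasta, gff, seq


def truth_member_mask(truth: pd.DataFrame, sample: str) -> pd.Series:
    return truth["membership"].str.split(",").apply(lambda m: sample in m)
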