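"""Annotate coding effects and tag genes by mutation class.

Each SNP is placed against the gene models (CDS / genic / intergenic);
CDS changes are called synonymous (Ss) or non-synonymous (Sn) by codon
substitution and translation.  Genes are then classed as non-mutated,
mutated-with-Sn or mutated-without-Sn.
"""

from pathlib import Path

import pandas as pd

from somavar.config import SimulationConfig
from somavar.pipeline import PipelineConfig, run_pipeline

OUT = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    cfg = PipelineConfig(out_dir=OUT, sim=SimulationConfig(seed=11),
                         stages=("annotate",))
    run_pipeline(cfg)
    effects = pd.read_csv(OUT / "effects" / "effects.tsv", sep="\t",
                          keep_default_na=False)
    classes = pd.read_csv(OUT / "effects" / "gene_classes.tsv", sep="\t")
    placement = effects["placement"].value_counts()
    effect = effects.loc[effects["placement"] == "CDS", "effect"].value_counts()
    class_counts = classes["gene_class"].value_counts()

    RESULTS.mkdir(exist_ok=True)
    class_counts.rename_axis("gene_class").to_frame("n_genes").to_csv(
        RESULTS / "04_gene_class_counts.tsv", sep="\t"
    )
    print("variant placement:")
    print(placement.to_string())
    print("\ncoding effects (Sn/Ss ratio reflects ~3:1 codon degeneracy odds):")
    print(effect.to_string())
    print("\ngene classes:")
    print(class_counts.to_string())


if __name__ == "__main__":
    main()
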