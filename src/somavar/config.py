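"""Configuration for the synthetic study generator.

The defaults describe the toy study the pipeline ships with: a diploid-like
genome of 4 chromosomes x 500 kb carrying 200 genes, three pooled regenerant
call sets with standing (shared-by-all) heterozygous variants plus
sample-private and pairwise-shared de novo variants, spatial hotspot
enrichment, and an expression table in which mutated genes are shifted
upward on the log scale.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path


class ConfigError(ValueError):
    """A SimulationConfig invariant is violated."""


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Counts are per study; proportions are in [0, 1]; the hotspot
    enrichment factor is the ratio of per-bp variant density inside
    hotspot windows to the background per-bp density.
    """

    seed: int = 1
    n_chromosomes: int = 4
    chromosome_length_bp: int = 500_000
    n_genes: int = 200
    mean_cds_segments_per_gene: int = 3
    fraction_genes_totipotency: float = 0.15
    fraction_genes_stability: float = 0.20
    n_shared_variants: int = 1_000
    n_denovo_per_sample: tuple[int, ...] = (1_000, 600, 2_000)
    pairwise_shared_fraction: float = 0.10
    hotspot_windows_per_chromosome: int = 2
    hotspot_enrichment_factor: float = 10.0
    ht_fraction: float = 0.90
    allele_depth_mean: float = 30.0
    expression_lognormal_mu_shift_mutated: float = 0.5
    # extra log-mean shift for genes carrying >=1 non-synonymous variant,
    # on top of the mutated-gene shift; gives the Sn > Ss-only > wild-type
    # expression ordering the analysis is meant to detect
    expression_lognormal_mu_extra_shift_sn: float = 0.25
    qc_violation_fraction: float = 0.0
    sample_ids: tuple[str, ...] = ("s1", "s2", "s3")

    @property
    def hotspot_window_bp(self) -> int:
        """Width of one hotspot window: 1% of the chromosome, min 10 kb.

        Matches the default analysis window of the mutation-spectrum
        module so planted hotspots align with the calling grid.
        """
        return max(10_000, self.chromosome_length_bp // 100)

    @property
    def genome_length_bp(self) -> int:
        return self.n_chromosomes * self.chromosome_length_bp

    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length_bp": self.chromosome_length_bp,
            "n_genes": self.n_genes,
            "mean_cds_segments_per_gene": self.mean_cds_segments_per_gene,
            "n_shared_variants": self.n_shared_variants,
            "hotspot_windows_per_chromosome": self.hotspot_windows_per_chromosome,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        if len(self.n_denovo_per_sample) != len(self.sample_ids):
            raise ConfigError(
                "n_denovo_per_sample must have one entry per sample "
                f"({len(self.sample_ids)}), got {len(self.n_denovo_per_sample)}"
            )
        if any(n < 0 for n in self.n_denovo_per_sample):
            raise ConfigError("n_denovo_per_sample entries must be >= 0")
        proportions = {
            "fraction_genes_totipotency": self.fraction_genes_totipotency,
            "fraction_genes_stability": self.fraction_genes_stability,
            "pairwise_shared_fraction": self.pairwise_shared_fraction,
            "ht_fraction": self.ht_fraction,
            "qc_violation_fraction": self.qc_violation_fraction,
        }
        for name, value in proportions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.fraction_genes_totipotency + self.fraction_genes_stability > 1.0:
            raise ConfigError(
                "fraction_genes_totipotency + fraction_genes_stability must be <= 1"
            )
        if self.hotspot_enrichment_factor < 1.0:
            raise ConfigError(
                "hotspot_enrichment_factor must be >= 1, "
                f"got {self.hotspot_enrichment_factor}"
            )
        if self.allele_depth_mean <= 0:
            raise ConfigError("allele_depth_mean must be > 0")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConfigError("sample_ids must be distinct")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Read a flat ``key = value`` config file.

        Blank lines and ``#`` comments are ignored.  List-valued fields
        (``n_denovo_per_sample``, ``sample_ids``) take comma-separated
        values.
        """
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict[str, object] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ConfigError(f"unknown config key {key!r}")
            kwargs[key] = _coerce(key, value)
        cfg = cls(**kwargs)  # type: ignore[arg-type]
        cfg.validate()
        return cfg

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{f.name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")


_INT_FIELDS = {
    "seed",
    "n_chromosomes",
    "chromosome_length_bp",
    "n_genes",
    "mean_cds_segments_per_gene",
    "n_shared_variants",
    "hotspot_windows_per_chromosome",
}
_FLOAT_FIELDS = {
    "fraction_genes_totipotency",
    "fraction_genes_stability",
    "pairwise_shared_fraction",
    "hotspot_enrichment_factor",
    "ht_fraction",
    "allele_depth_mean",
    "expression_lognormal_mu_shift_mutated",
    "expression_lognormal_mu_extra_shift_sn",
    "qc_violation_fraction",
}


def _coerce(key: str, value: str) -> object:
    if key in _INT_FIELDS:
        return int(value)
    if key in _FLOAT_FIELDS:
        return float(value)
    if key == "n_denovo_per_sample":
        return tuple(int(v) for v in value.split(","))
    if key == "sample_ids":
        return tuple(v.strip() for v in value.split(","))
    raise ConfigError(f"unknown config key {key!r}")
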