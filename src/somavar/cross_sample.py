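"""Cross-sample variant set logic: standing vs de novo.

A variant is identified by (chromosome, position, ref, alt).  Variants
present in every sample are standing differences between the donor and
the reference genome; variants present in a strict non-empty subset of
samples — including exactly two of three — are de novo, attributed to
mutation during tissue culture.  Consequently
``de novo = union - shared-by-all`` for any collection of samples.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from .qc import CallSet

SHARED = "shared"
DENOVO = "denovo"


class VariantKey(NamedTuple):
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str


@dataclasses.dataclass(frozen=True)
class ClassifiedVariant:
    key: VariantKey
    membership: frozenset[str]
    status: str  # SHARED | DENOVO


class DuplicateKeyError(ValueError):
    """The same variant key occurs twice within one sample's call set."""


def classify(callsets: list[CallSet]) -> list[ClassifiedVariant]:
    """Classify every variant in the union of >= 2 call sets.

    Output is sorted by key; each key appears once, with its sample
    membership and shared/de novo status.
    """
    if len(callsets) < 2:
        raise ValueError("classification needs at least two call sets")
    sample_ids = [cs.sample_id for cs in callsets]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"sample ids are not distinct: {sample_ids}")
    return classify_keys({cs.sample_id: [c.key for c in cs.retained] for cs in callsets})


def classify_keys(keys_by_sample: dict[str, Iterable[tuple]]) -> list[ClassifiedVariant]:
    """Set-logic core, usable on bare key tuples (chrom, pos, ref, alt)."""
    full = frozenset(keys_by_sample)
    membership: dict[VariantKey, set[str]] = {}
    for sample, keys in keys_by_sample.items():
        seen: set[VariantKey] = set()
        for key in keys:
            vk = VariantKey(*key)
            if vk in seen:
                raise DuplicateKeyError(f"duplicate key {vk} in sample {sample}")
            seen.add(vk)
            membership.setdefault(vk, set()).add(sample)
    return [
        ClassifiedVariant(
            key=vk,
            membership=frozenset(members),
            status=SHARED if frozenset(members) == full else DENOVO,
        )
        for vk, members in sorted(membership.items())
    ]


def summarize_counts(
    classified: list[ClassifiedVariant], sample_ids: list[str]
) -> pd.Series:
    """Per-sample, union, shared-by-all and de novo counts.

    Satisfies de novo = union - shared and
    max(per-sample) <= union <= sum(per-sample).
    """
    counts = {
        sample: sum(1 for v in classified if sample in v.membership)
        for sample in sample_ids
    }
    counts["union"] = len(classified)
    counts["shared"] = sum(1 for v in classified if v.status == SHARED)
    counts["denovo"] = counts["union"] - counts["shared"]
    return pd.Series(counts, name="heterozygote_count")


def to_frame(classified: list[ClassifiedVariant], sample_ids: list[str]) -> pd.DataFrame:
    """Tabular form: one row per variant, membership as a bitmask string."""
    rows = [
        {
            "chrom": v.key.chromosome,
            "pos": v.key.position,
            "ref": v.key.ref_allele,
            "alt": v.key.alt_allele,
            "membership": ",".join(s for s in sample_ids if s in v.membership),
            "bitmask": "".join("1" if s in v.membership else "0" for s in sample_ids),
            "status": v.status,
        }
        for v in classified
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "membership", "bitmask", "status"]
    )


def write_classification(
    classified: list[ClassifiedVariant],
    sample_ids: list[str],
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    to_frame(classified, sample_ids).to_csv(
        outdir / "classified_variants.tsv", sep="\t", index=False
    )
    summarize_counts(classified, sample_ids).to_csv(
        outdir / "count_summary.tsv", sep="\t", header=True
    )
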