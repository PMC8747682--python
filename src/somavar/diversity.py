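"""Nucleotide-diversity and mutation-rate statistics per region category.

"Ht per Kb" — the heterozygote count over the region length in kb — is
the study's nucleotide-diversity measure; Ss/Sn rates are per Mb of the
same region.  Categories are the whole genome, all genes, and any named
gene lists (e.g. cell-totipotency or chromosome-stability genes); a
category's length is the merged union of its member gene spans, introns
included, and each variant counts at most once per category.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .effects import GenomeAnnotation

WHOLE_GENOME = "whole-genome"
ALL_GENES = "all-genes"

#: column blocks a report carries beyond the per-sample ones
DERIVED_COLUMNS = ("union", "shared", "denovo")

METRICS = ("ht_count", "length_bp", "ht_per_kb", "ss_count", "sn_count",
           "ss_per_mb", "sn_per_mb")


def ht_per_kb(n: int, length_bp: float) -> float:
    """Heterozygotes per kilobase, rounded half-up to 2 decimals."""
    if length_bp <= 0:
        raise ValueError(f"region length must be > 0, got {length_bp}")
    if n < 0:
        raise ValueError(f"count must be >= 0, got {n}")
    value = Decimal(n) * 1000 / Decimal(str(length_bp))
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def rate_per_mb(n: int, length_bp: float) -> float:
    """Mutations per megabase, to 3 significant figures."""
    if length_bp <= 0:
        raise ValueError(f"region length must be > 0, got {length_bp}")
    if n == 0:
        return 0.0
    value = n / length_bp * 1e6
    return float(f"{value:.3g}")


@dataclasses.dataclass(frozen=True)
class RegionCategory:
    """A named region: a gene set (empty = whole genome) with its length."""

    name: str
    gene_ids: frozenset[str]
    length_bp: int

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError(f"category {self.name}: length must be > 0")


def merged_span_length(annotation: GenomeAnnotation, gene_ids: frozenset[str]) -> int:
    """Total bp covered by the union of the given gene spans."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gid in gene_ids:
        if gid not in annotation.genes:
            raise KeyError(f"category references unknown gene {gid}")
        g = annotation.genes[gid]
        by_chrom.setdefault(g.chromosome, []).append((g.start, g.end))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
    return total


def make_categories(
    annotation: GenomeAnnotation,
    named_gene_lists: dict[str, list[str]] | None = None,
) -> list[RegionCategory]:
    """Whole-genome + all-genes + one category per named gene list."""
    genome_len = sum(annotation.chromosome_lengths.values())
    all_ids = frozenset(annotation.genes)
    cats = [RegionCategory(WHOLE_GENOME, frozenset(), genome_len)]
    if all_ids:
        cats.append(RegionCategory(ALL_GENES, all_ids, merged_span_length(annotation, all_ids)))
    for name, ids in (named_gene_lists or {}).items():
        fids = frozenset(ids)
        cats.append(RegionCategory(name, fids, merged_span_length(annotation, fids)))
    return cats


def load_gene_list(path: str | Path) -> list[str]:
    """Read a gene-category TSV (column ``gene_id``, header optional)."""
    df = pd.read_csv(path, sep="\t")
    col = "gene_id" if "gene_id" in df.columns else df.columns[0]
    return df[col].astype(str).tolist()


def _category_intervals(
    annotation: GenomeAnnotation, cat: RegionCategory
) -> dict[str, tuple[np.ndarray, np.ndarray]] | None:
    """Merged (starts, ends) arrays per chromosome; None = whole genome."""
    if not cat.gene_ids:
        return None
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gid in cat.gene_ids:
        g = annotation.genes[gid]
        by_chrom.setdefault(g.chromosome, []).append((g.start, g.end))
    out = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        merged = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = (
            np.array([m[0] for m in merged]),
            np.array([m[1] for m in merged]),
        )
    return out


def _in_category(
    chroms: pd.Series, positions: pd.Series,
    intervals: dict[str, tuple[np.ndarray, np.ndarray]] | None,
) -> np.ndarray:
    if intervals is None:
        return np.ones(len(chroms), dtype=bool)
    mask = np.zeros(len(chroms), dtype=bool)
    pos = positions.to_numpy()
    for chrom, (starts, ends) in intervals.items():
        sel = (chroms == chrom).to_numpy()
        if not sel.any():
            continue
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = (idx >= 0) & (pos[sel] <= ends[np.clip(idx, 0, len(ends) - 1)])
        mask[sel] = ok
    return mask


def build_report(
    classified: pd.DataFrame,
    effects: pd.DataFrame,
    categories: list[RegionCategory],
    sample_ids: list[str],
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """The diversity report: one metric block per category.

    *classified* needs columns chrom, pos, ref, alt, membership, status;
    *effects* needs chrom, pos, ref, alt, gene_id, placement, effect.
    Columns are the samples plus union / shared-by-all / de novo; the
    identity denovo = union - shared holds per category by construction
    and is re-checked here.
    """
    member_sets = classified["membership"].str.split(",").apply(frozenset)
    is_shared = (classified["status"] == "shared").to_numpy()

    cds = effects[effects["placement"] == "CDS"].drop_duplicates(
        subset=["chrom", "pos", "ref", "alt", "effect"]
    )
    cds = cds.merge(
        classified[["chrom", "pos", "ref", "alt", "membership", "status"]],
        on=["chrom", "pos", "ref", "alt"],
        how="inner",
    )
    cds_members = cds["membership"].str.split(",").apply(frozenset)

    columns = list(sample_ids) + list(DERIVED_COLUMNS)
    rows = []
    for cat in categories:
        intervals = _category_intervals(annotation, cat)
        in_cat = _in_category(classified["chrom"], classified["pos"], intervals)
        cds_in_cat = _in_category(cds["chrom"], cds["pos"], intervals)
        if intervals is not None:
            # restrict Ss/Sn to effects on member genes (a variant inside a
            # member gene's span but annotated to a different gene is rare
            # here since spans are merged per category)
            cds_in_cat &= cds["gene_id"].isin(cat.gene_ids).to_numpy()

        def col_mask(column: str) -> np.ndarray:
            if column == "union":
                return np.ones(len(classified), dtype=bool)
            if column == "shared":
                return is_shared
            if column == "denovo":
                return ~is_shared
            return member_sets.apply(lambda m: column in m).to_numpy()

        def cds_col_mask(column: str) -> np.ndarray:
            if column == "union":
                return np.ones(len(cds), dtype=bool)
            if column == "shared":
                return (cds["status"] == "shared").to_numpy()
            if column == "denovo":
                return (cds["status"] != "shared").to_numpy()
            return cds_members.apply(lambda m: column in m).to_numpy()

        block = {m: {} for m in METRICS}
        for column in columns:
            n = int((in_cat & col_mask(column)).sum())
            ss = int((cds_in_cat & cds_col_mask(column) & (cds["effect"] == "Ss")).sum())
            sn = int((cds_in_cat & cds_col_mask(column) & (cds["effect"] == "Sn")).sum())
            block["ht_count"][column] = n
            block["length_bp"][column] = cat.length_bp
            block["ht_per_kb"][column] = ht_per_kb(n, cat.length_bp)
            block["ss_count"][column] = ss
            block["sn_count"][column] = sn
            block["ss_per_mb"][column] = rate_per_mb(ss, cat.length_bp)
            block["sn_per_mb"][column] = rate_per_mb(sn, cat.length_bp)
        assert (
            block["ht_count"]["denovo"]
            == block["ht_count"]["union"] - block["ht_count"]["shared"]
        )
        for metric in METRICS:
            rows.append({"category": cat.name, "metric": metric, **block[metric]})
    return pd.DataFrame(rows, columns=["category", "metric", *columns]).set_index(
        ["category", "metric"]
    )


def recompute_from_printed(printed: pd.DataFrame) -> pd.DataFrame:
    """Re-derive the computed cells of a printed summary table.

    Input: one row per category with count columns (each sample plus
    ``union`` and ``shared``) and a ``length_bp`` column.  Output: the
    de novo count (union - shared) and the Ht-per-Kb value for every
    count column, at 2-decimal half-up rounding.
    """
    out = {}
    count_cols = [c for c in printed.columns if c != "length_bp"]
    for cat, row in printed.iterrows():
        denovo = int(row["union"]) - int(row["shared"])
        cells = {"denovo_count": denovo}
        for col in count_cols:
            cells[f"ht_per_kb_{col}"] = ht_per_kb(int(row[col]), row["length_bp"])
        cells["ht_per_kb_denovo"] = ht_per_kb(denovo, row["length_bp"])
        out[cat] = cells
    return pd.DataFrame(out).T
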