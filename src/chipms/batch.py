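"""Batch enrichment of an annotation catalog against one query peak set.

Runs the shuffle z-score for every catalog family (repeat classes, repeat
families, or one file per family in a peak-file-directory screen) and emits
a ranked, diff-stable results table. Each family draws from its own seed
substream derived from the master seed and the family name, so the table is
bit-identical regardless of family processing order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .enrichment import (
    EnrichmentResult,
    ShuffleParams,
    compute_enrichment,
    family_seed_sequence,
)
from .intervals import AnnotationCatalog, GenomeLayout, IntervalSet, merge_intervals

__all__ = ["EnrichmentTable", "enrich_catalog", "write_enrichment_table", "read_enrichment_table"]

TABLE_COLUMNS = [
    "family",
    "n_elements",
    "total_annotation_bp",
    "observed_bp",
    "null_mean",
    "null_sd",
    "z",
    "n_shuffles",
    "seed",
    "degenerate",
]


@dataclass
class EnrichmentTable:
    """Per-family enrichment results, sorted by descending z (NaN z last)."""

    rows: list[EnrichmentResult]
    genome_id: str = ""
    peaks_id: str = ""
    params_echo: ShuffleParams = field(default_factory=ShuffleParams)

    def to_dataframe(self) -> pd.DataFrame:
        records = [
            {
                "family": r.family_name,
                "n_elements": r.n_elements,
                "total_annotation_bp": r.total_annotation_bp,
                "observed_bp": r.observed_bp,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "z": r.z,
                "n_shuffles": r.n_shuffles,
                "seed": r.seed,
                "degenerate": r.degenerate,
            }
            for r in self.rows
        ]
        return pd.DataFrame(records, columns=TABLE_COLUMNS)


def _sort_key(r: EnrichmentResult) -> tuple:
    # descending z, NaN (degenerate) rows last; family name breaks ties
    nan_last = 1 if math.isnan(r.z) else 0
    return (nan_last, -(r.z if not math.isnan(r.z) else 0.0), r.family_name)


def enrich_catalog(
    peaks: IntervalSet,
    catalog: AnnotationCatalog,
    genome: GenomeLayout,
    params: ShuffleParams,
    genome_id: str = "",
    peaks_id: str = "",
) -> EnrichmentTable:
    """One EnrichmentResult per catalog family against the same peak set.

    No family is silently skipped: empty families yield observed = 0 and a
    degenerate flag per the shuffle-null rules; results carry the master
    seed. Rerunning with the same master seed is bit-identical regardless of
    the order families are supplied in.
    """
    peaks_merged = merge_intervals(peaks)
    rows: list[EnrichmentResult] = []
    for fam_name, fam_set in catalog.families.items():
        ss = family_seed_sequence(params.seed, fam_name)
        rows.append(
            compute_enrichment(
                fam_set,
                peaks_merged,
                genome,
                params,
                family_name=fam_name,
                seed_sequence=ss,
            )
        )
    rows.sort(key=_sort_key)
    return EnrichmentTable(
        rows=rows,
        genome_id=genome_id,
        peaks_id=peaks_id or peaks.name,
        params_echo=params,
    )


def write_enrichment_table(t: EnrichmentTable, path: str | Path) -> None:
    """Write the table as TSV with fixed numeric formatting (diff-stable).

    z and the null moments are printed to 4 decimals; NaN z is written as
    the literal ``NA``.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for r in t.rows:
            z_str = "NA" if math.isnan(r.z) else f"{r.z:.4f}"
            fh.write(
                f"{r.family_name}\t{r.n_elements}\t{r.total_annotation_bp}\t{r.observed_bp}\t"
                f"{r.null_mean:.4f}\t{r.null_sd:.4f}\t{z_str}\t{r.n_shuffles}\t{r.seed}\t"
                f"{str(r.degenerate).lower()}\n"
            )


def read_enrichment_table(path: str | Path) -> pd.DataFrame:
    """Re-parse a written enrichment table (round-trip helper)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["degenerate"] = df["degenerate"].astype(bool)
    return df
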