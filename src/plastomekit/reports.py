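"""Cross-genome comparison reports.

Assembles the per-genome module outputs (composition, census, repeat and SSR
summaries) side by side and appends min/max range rows with species
attribution, the standard way comparative plastome tables report e.g.
"total length ranged from 155,590 bp (S. purpurea) to 163,161 bp
(R. communis)".
"""

from __future__ import annotations

import pandas as pd

from .composition import composition_summary, gene_census
from .junctions import NoIRDetected, detect_ir, partition_from_ir
from .records import PlastomeRecord
from .repeats import find_long_repeats, find_ssrs

__all__ = ["compare_genomes", "range_rows"]


def range_rows(values: dict[str, float | int]) -> dict[str, object]:
    """Min/max with attribution over a species -> value mapping."""
    lo = min(values, key=lambda k: (values[k], k))
    hi = max(values, key=lambda k: (values[k], k))
    return {
        "min": values[lo],
        "min_species": lo,
        "max": values[hi],
        "max_species": hi,
    }


def compare_genomes(
    records: list[PlastomeRecord], min_ir_length: int = 1000
) -> pd.DataFrame:
    """Side-by-side summary of two or more annotated genomes.

    One column per genome, one row per statistic; a genome in which no IR
    can be detected keeps blank partition-dependent cells.  The final two
    columns attribute the min and max of each numeric row.
    """
    if len(records) < 2:
        raise ValueError("compare_genomes needs at least two records")
    columns: dict[str, dict[str, object]] = {}
    for record in records:
        cells: dict[str, object] = {"total_length_bp": len(record)}
        try:
            partition = partition_from_ir(
                record, detect_ir(record, min_ir_length=min_ir_length)
            )
        except (NoIRDetected, Exception) as exc:  # noqa: BLE001
            if not isinstance(exc, NoIRDetected):
                raise
            partition = None
        if partition is not None:
            comp = composition_summary(record, partition)
            for _, row in comp.regions.iterrows():
                cells[f"{row['region']}_length_bp"] = int(row["length_bp"])
                cells[f"{row['region']}_gc_percent"] = row["gc_percent"]
            for _, row in comp.classes.iterrows():
                cells[f"{row['class']}_length_bp"] = int(row["length_bp"])
            if record.annotations:
                census = gene_census(record.annotations, partition)
                cells["gene_copies"] = census.total_copies
                cells["distinct_genes"] = census.distinct_names
                cells["duplicated_genes"] = census.duplicated_names
            cells["n_ssrs"] = len(
                find_ssrs(record, partition=partition, collapse_ir=True)
            )
            cells["n_long_repeats"] = len(
                find_long_repeats(record, partition=partition)
            )
        columns[record.id] = cells
    df = pd.DataFrame(columns)
    mins, maxs = [], []
    for stat, row in df.iterrows():
        numeric = {k: v for k, v in row.items() if pd.notna(v)}
        if numeric:
            rng = range_rows(numeric)
            mins.append(f"{rng['min']} ({rng['min_species']})")
            maxs.append(f"{rng['max']} ({rng['max_species']})")
        else:
            mins.append("")
            maxs.append("")
    df["min"] = mins
    df["max"] = maxs
    df.index.name = "statistic"
    return df.reset_index()
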