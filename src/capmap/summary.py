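"""Per-chromosome genetic-map summaries and genome-level aggregates.

Mirrors the conventional map-description table: SNP count, map length,
mean inter-marker distance (length / marker count), biggest adjacent gap
and number of unique positions per chromosome, with means and totals
overall and per subgenome (A and B).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def summarize_map(genetic_map: pd.DataFrame) -> pd.DataFrame:
    """Summarise a marker-level map into per-chromosome feature rows.

    ``genetic_map`` needs marker/chromosome/position_cM columns. Chromosomes
    with no marker are omitted with a warning. Lengths and distances are
    reported to one decimal, mean distances to two.
    """
    if genetic_map.empty:
        raise ValueError("cannot summarise an empty map")
    rows = []
    for chrom, sub in genetic_map.groupby("chromosome"):
        if sub.empty:
            logger.warning("chromosome %s has no markers; omitted from the summary", chrom)
            continue
        unique_pos = np.sort(sub["position_cM"].unique())
        length = float(unique_pos.max() - unique_pos.min())
        n = len(sub)
        gap = float(np.diff(unique_pos).max()) if len(unique_pos) > 1 else 0.0
        rows.append(
            {
                "chromosome": chrom,
                "n_snps": n,
                "length_cM": round(length, 1),
                "mean_distance_cM": round(length / n, 2),
                "biggest_gap_cM": round(gap, 1),
                "unique_positions": len(unique_pos),
            }
        )
    return pd.DataFrame(rows)


def aggregate_chromosome_summary(per_chromosome: pd.DataFrame) -> pd.DataFrame:
    """Append Mean/Total rows, overall and per subgenome, to a summary table.

    The subgenome of a chromosome is its trailing letter (1A...7A -> A,
    1B...7B -> B). Means are reported to one decimal; totals are sums of
    counts and lengths (mean distance and gap are not summable and left
    blank on total rows).
    """
    df = per_chromosome.copy()
    required = {"chromosome", "n_snps", "length_cM"}
    if not required <= set(df.columns):
        raise ValueError(f"summary table must have columns {sorted(required)}")

    def mean_row(sub: pd.DataFrame, label: str) -> dict:
        row = {"chromosome": label}
        for col in df.columns:
            if col == "chromosome":
                continue
            row[col] = round(float(sub[col].mean()), 1)
        return row

    def total_row(sub: pd.DataFrame, label: str) -> dict:
        row = {"chromosome": label}
        for col in df.columns:
            if col == "chromosome":
                continue
            if col in ("n_snps", "unique_positions"):
                row[col] = int(sub[col].sum())
            elif col == "length_cM":
                row[col] = round(float(sub[col].sum()), 1)
            else:
                row[col] = np.nan
        return row

    genome = df["chromosome"].astype(str).str[-1]
    out_rows = [mean_row(df, "Mean"), total_row(df, "Total")]
    # subgenome blocks only for proper chromosome names (1A...7B); unassigned
    # linkage groups (LGxx) stay out of the genome subtotals
    for g in sorted(g for g in genome.unique() if g.isalpha()):
        sub = df[genome == g]
        out_rows.append(mean_row(sub, f"Mean {g}"))
        out_rows.append(total_row(sub, f"Total {g}"))
    return pd.concat([df, pd.DataFrame(out_rows)], ignore_index=True)
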