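"""Genetic-map validation against external putative positions.

Quantifies map quality by per-chromosome Spearman rank correlations with
putative physical and genetic coordinates, a cubic polynomial regression of
genetic on physical position with 95% prediction-band outlier tagging, the
detection of translocation blocks (runs of co-mapped markers whose putative
assignment points to one non-homeologous chromosome), and local
recombination rates (cM/Mb) over physical segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from capmap.mapping import _homeolog_name


def spearman_by_chromosome(
    genetic_map: pd.DataFrame,
    positions: pd.DataFrame,
    value_column: str = "putative_bp",
    min_markers: int = 3,
) -> pd.DataFrame:
    """Per-chromosome Spearman rank correlation of map cM vs external positions.

    ``genetic_map`` needs marker/chromosome/position_cM columns; ``positions``
    is indexed by marker (or has a ``marker`` column) with ``value_column``.
    Markers missing either coordinate are excluded; chromosomes with fewer
    than ``min_markers`` usable markers are reported with a NaN rho and
    flagged.
    """
    pos = positions.set_index("marker") if "marker" in positions.columns else positions
    rows = []
    for chrom, sub in genetic_map.groupby("chromosome"):
        merged = sub.set_index("marker").join(pos[[value_column]], how="inner").dropna(
            subset=["position_cM", value_column]
        )
        if len(merged) < min_markers:
            rows.append((chrom, np.nan, len(merged), True))
            continue
        rho = sps.spearmanr(merged["position_cM"], merged[value_column]).statistic
        rows.append((chrom, float(rho), len(merged), False))
    return pd.DataFrame(rows, columns=["chromosome", "spearman_rho", "n_markers", "too_few"])


@dataclass
class PolyfitResult:
    coefficients: np.ndarray  # highest degree first, on centred/scaled x
    adjusted_r2: float
    outlier: pd.Series  # boolean per marker
    fitted: pd.Series
    band_lower: pd.Series
    band_upper: pd.Series
    x_center: float
    x_scale: float


def polyfit_outliers(
    genetic_cM,
    physical_bp,
    degree: int = 3,
    level: float = 0.95,
    band: str = "prediction",
) -> PolyfitResult:
    """Cubic regression of genetic on physical position with outlier tagging.

    Fits a least-squares polynomial of ``genetic_cM`` on (centred, scaled)
    ``physical_bp`` and tags markers whose genetic position falls outside
    the pointwise ``level`` prediction band (``band="mean"`` switches to the
    narrower mean-response confidence band). Requires at least degree+2
    points so a residual degree of freedom remains.
    """
    y = pd.Series(genetic_cM).astype(float)
    x = pd.Series(physical_bp).astype(float)
    if len(y) != len(x):
        raise ValueError("genetic and physical vectors differ in length")
    if len(y) < degree + 2:
        raise ValueError(f"need at least {degree + 2} markers for a degree-{degree} fit")
    if band not in ("prediction", "mean"):
        raise ValueError("band must be 'prediction' or 'mean'")
    center, scale = float(x.mean()), float(x.std(ddof=0))
    if scale == 0:
        raise ValueError("degenerate design: all physical positions identical")
    xs = (x - center) / scale
    X = np.vander(xs.to_numpy(), degree + 1)
    model = sm.OLS(y.to_numpy(), X).fit()
    pred = model.get_prediction(X)
    frame = pred.summary_frame(alpha=1.0 - level)
    lower_col, upper_col = (
        ("obs_ci_lower", "obs_ci_upper") if band == "prediction" else ("mean_ci_lower", "mean_ci_upper")
    )
    lower = pd.Series(frame[lower_col].to_numpy(), index=y.index)
    upper = pd.Series(frame[upper_col].to_numpy(), index=y.index)
    # scale-relative tolerance so an exact (zero-residual) fit tags nothing
    eps = 1e-8 * max(1.0, float(y.abs().max()))
    outlier = (y < lower - eps) | (y > upper + eps)
    return PolyfitResult(
        coefficients=model.params,
        adjusted_r2=float(model.rsquared_adj),
        outlier=outlier,
        fitted=pd.Series(model.fittedvalues, index=y.index),
        band_lower=lower,
        band_upper=upper,
        x_center=center,
        x_scale=scale,
    )


def detect_translocation_blocks(
    genetic_map: pd.DataFrame,
    putative: pd.DataFrame,
    min_block: int = 3,
    max_gap_cM: float = 10.0,
) -> pd.DataFrame:
    """Runs of co-mapped markers putatively assigned to one alien chromosome.

    A block is a maximal run of >= ``min_block`` consecutive markers (in map
    order, adjacent cM gaps <= ``max_gap_cM``) whose putative chromosome is
    identical and neither the mapped chromosome nor its homeolog. Output is
    deterministic and depends only on the map order.
    """
    pos = putative.set_index("marker") if "marker" in putative.columns else putative
    blocks = []
    for chrom, sub in genetic_map.groupby("chromosome"):
        sub = sub.sort_values(["position_cM", "marker"])
        homeolog = _homeolog_name(chrom)
        run: list[tuple[str, float, str]] = []

        def flush(run: list) -> None:
            if len(run) >= min_block:
                blocks.append(
                    {
                        "mapped_chromosome": chrom,
                        "putative_chromosome": run[0][2],
                        "n_markers": len(run),
                        "start_cM": run[0][1],
                        "end_cM": run[-1][1],
                        "markers": ";".join(m for m, _, _ in run),
                    }
                )

        for _, row in sub.iterrows():
            marker, cm = row["marker"], float(row["position_cM"])
            pchrom = pos["putative_chromosome"].get(marker) if marker in pos.index else None
            alien = pchrom is not None and pd.notna(pchrom) and pchrom not in (chrom, homeolog)
            if alien and run and run[-1][2] == pchrom and cm - run[-1][1] <= max_gap_cM:
                run.append((marker, cm, pchrom))
            else:
                flush(run)
                run = [(marker, cm, pchrom)] if alien else []
        flush(run)
    return pd.DataFrame(
        blocks,
        columns=["mapped_chromosome", "putative_chromosome", "n_markers", "start_cM", "end_cM", "markers"],
    )


def segment_recomb_rate(
    genetic_map: pd.DataFrame,
    positions: pd.DataFrame,
    chromosome: str,
    bp_interval: tuple[float, float],
) -> float | None:
    """Local recombination rate over a physical segment, in cM/Mb.

    Computed as (genetic span of the segment's markers in cM) / (their
    physical span in Mb). Returns None with fewer than two usable markers;
    a zero genetic span gives 0.0.
    """
    pos = positions.set_index("marker") if "marker" in positions.columns else positions
    sub = genetic_map[genetic_map["chromosome"] == chromosome].set_index("marker")
    merged = sub.join(pos[["putative_bp"]], how="inner").dropna(subset=["position_cM", "putative_bp"])
    lo, hi = bp_interval
    inside = merged[(merged["putative_bp"] >= lo) & (merged["putative_bp"] <= hi)]
    if len(inside) < 2:
        return None
    cm_span = float(inside["position_cM"].max() - inside["position_cM"].min())
    mb_span = float(inside["putative_bp"].max() - inside["putative_bp"].min()) / 1e6
    if mb_span == 0:
        return None
    return cm_span / mb_span


def assignment_consistency(groups: pd.DataFrame) -> dict:
    """Genome-wide marker-weighted assignment consistency fractions."""
    usable = groups.dropna(subset=["chromosome"])
    usable = usable[usable["n_assigned"] > 0]
    if usable.empty:
        return {"fraction_consistent": np.nan, "fraction_homeolog": np.nan, "fraction_other": np.nan}
    weights = usable["n_assigned"].to_numpy(float)
    out = {}
    for key in ("fraction_consistent", "fraction_homeolog", "fraction_other"):
        out[key] = float(np.average(usable[key].to_numpy(float), weights=weights))
    return out
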