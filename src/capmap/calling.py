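"""Threshold-based genotype calling from capture allele read counts.

Calls are made per individual and per locus from the two allele counts with
a transparent depth rule: targeted loci accept calls from as few as two
reads (the polymorphism is already known to exist in the parents), whereas
newly discovered untargeted ("bonus") positions require four. Heterozygotes
need both alleles supported by a minimum read count and minor-allele
fraction. Loci are then classified for the capture-efficiency accounting:
``ER`` (expected-recovered, i.e. segregating), ``monomorphic``, ``het_only``
or ``not_captured``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CALL_A = "A"  # Dic2 homozygote
CALL_B = "B"  # Silur homozygote
CALL_H = "H"  # heterozygote
MISSING = "-"

DEPTH_TARGETED = 2
DEPTH_BONUS = 4


@dataclass(frozen=True)
class GenotypeCall:
    call: str  # A | B | H | -
    depth: int


@dataclass(frozen=True)
class LocusClassification:
    status: str  # ER | monomorphic | het_only | not_captured
    n_genotyped: int


def call_genotype(
    reads_a: int,
    reads_b: int,
    min_depth: int = DEPTH_TARGETED,
    het_minor_fraction: float = 0.2,
    het_minor_reads: int = 2,
) -> GenotypeCall:
    """Call one genotype from the two allele read counts.

    Missing below ``min_depth`` total reads; heterozygous when both alleles
    have >= ``het_minor_reads`` reads and the minor allele holds >=
    ``het_minor_fraction`` of the depth; otherwise homozygous for the
    majority allele. An exact tie that fails the heterozygote rule has no
    majority allele and is returned as missing.
    """
    if reads_a < 0 or reads_b < 0:
        raise ValueError("read counts must be non-negative")
    depth = reads_a + reads_b
    if depth < min_depth:
        return GenotypeCall(MISSING, depth)
    minor = min(reads_a, reads_b)
    if minor >= het_minor_reads and minor / depth >= het_minor_fraction:
        return GenotypeCall(CALL_H, depth)
    if reads_a > reads_b:
        return GenotypeCall(CALL_A, depth)
    if reads_b > reads_a:
        return GenotypeCall(CALL_B, depth)
    return GenotypeCall(MISSING, depth)


def _call_array(
    reads_a: np.ndarray,
    reads_b: np.ndarray,
    min_depth: int,
    het_minor_fraction: float,
    het_minor_reads: int,
) -> np.ndarray:
    depth = reads_a + reads_b
    minor = np.minimum(reads_a, reads_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_frac = np.where(depth > 0, minor / np.maximum(depth, 1), 0.0)
    het = (minor >= het_minor_reads) & (minor_frac >= het_minor_fraction)
    calls = np.full(depth.shape, MISSING, dtype="<U1")
    calls[(depth >= min_depth) & het] = CALL_H
    hom = (depth >= min_depth) & ~het
    calls[hom & (reads_a > reads_b)] = CALL_A
    calls[hom & (reads_b > reads_a)] = CALL_B
    return calls


def call_genotype_table(
    readcounts: pd.DataFrame,
    min_depth: int = DEPTH_TARGETED,
    het_minor_fraction: float = 0.2,
    het_minor_reads: int = 2,
) -> pd.DataFrame:
    """Vectorised calling over a long-format read-count table.

    ``readcounts`` needs columns ``locus_id``, ``individual``, ``reads_a``,
    ``reads_b``. Returns a loci x individuals matrix of A/B/H/-.
    """
    calls = _call_array(
        readcounts["reads_a"].to_numpy(),
        readcounts["reads_b"].to_numpy(),
        min_depth,
        het_minor_fraction,
        het_minor_reads,
    )
    frame = readcounts[["locus_id", "individual"]].copy()
    frame["call"] = calls
    matrix = frame.pivot(index="locus_id", columns="individual", values="call").fillna(MISSING)
    matrix = matrix.reindex(pd.unique(readcounts["locus_id"]))  # preserve input locus order
    matrix.columns.name = None
    matrix.index.name = "marker"
    return matrix


def classify_locus(
    calls: "np.ndarray | list[str] | pd.Series",
    is_targeted: bool = True,
    het_tolerance: int = 0,
) -> LocusClassification:
    """Classify a locus from its call vector.

    ``not_captured``: no non-missing call; ``het_only``: only heterozygote
    calls; ``monomorphic``: a single homozygote class (tolerating up to
    ``het_tolerance`` stray H calls); otherwise ``ER``. Untargeted loci use
    the same partition (``is_targeted`` is carried for bookkeeping only).
    """
    arr = np.asarray(list(calls), dtype="<U1")
    n_a = int((arr == CALL_A).sum())
    n_b = int((arr == CALL_B).sum())
    n_h = int((arr == CALL_H).sum())
    n_genotyped = n_a + n_b + n_h
    if n_genotyped == 0:
        status = "not_captured"
    elif n_a == 0 and n_b == 0:
        status = "het_only"
    elif (n_a == 0 or n_b == 0) and n_h <= het_tolerance:
        status = "monomorphic"
    else:
        status = "ER"
    return LocusClassification(status=status, n_genotyped=n_genotyped)


def classify_table(
    genotypes: pd.DataFrame, is_targeted: bool = True, het_tolerance: int = 0
) -> pd.DataFrame:
    """Per-locus classification of a genotype matrix (rows = loci)."""
    rows = []
    for marker, calls in genotypes.iterrows():
        cls = classify_locus(calls.to_numpy(), is_targeted, het_tolerance)
        rows.append((marker, cls.status, cls.n_genotyped))
    out = pd.DataFrame(rows, columns=["marker", "status", "n_genotyped"])
    return out.set_index("marker")


def discover_bonus_snps(
    readcounts: pd.DataFrame,
    min_depth: int = DEPTH_BONUS,
    het_minor_fraction: float = 0.2,
    het_minor_reads: int = 2,
    targeted_contigs: "set[str] | None" = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Find segregating loci among untargeted sequenced positions.

    Genotypes are called at the stricter bonus depth threshold; a position is
    emitted when its calls exhibit both parental alleles (an H call carries
    both). Each record is flagged ``on_targeted_contig`` for downstream
    de-duplication against the targeted marker of the same contig.

    Returns (records, genotype matrix of the emitted loci).
    """
    untargeted = readcounts
    if "is_targeted" in readcounts.columns:
        untargeted = readcounts[~readcounts["is_targeted"].astype(bool)]
    if untargeted.empty:
        empty = pd.DataFrame(columns=["marker", "contig", "pos", "on_targeted_contig", "n_genotyped"])
        return empty.set_index("marker"), pd.DataFrame()
    genotypes = call_genotype_table(untargeted, min_depth, het_minor_fraction, het_minor_reads)
    meta = untargeted[["locus_id", "contig", "pos"]].drop_duplicates().set_index("locus_id")
    targeted_contigs = targeted_contigs or set()

    values = genotypes.to_numpy()
    has_a = ((values == CALL_A) | (values == CALL_H)).any(axis=1)
    has_b = ((values == CALL_B) | (values == CALL_H)).any(axis=1)
    segregating = has_a & has_b
    n_genotyped = (values != MISSING).sum(axis=1)

    records = pd.DataFrame(
        {
            "marker": genotypes.index,
            "contig": meta.loc[genotypes.index, "contig"].to_numpy(),
            "pos": meta.loc[genotypes.index, "pos"].to_numpy(),
            "on_targeted_contig": [c in targeted_contigs for c in meta.loc[genotypes.index, "contig"]],
            "n_genotyped": n_genotyped,
        }
    )
    records = records[segregating].set_index("marker")
    return records, genotypes.loc[records.index]
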