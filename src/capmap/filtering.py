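"""SNP quality filtering (Fis, completeness, Nei's He) with full accounting.

Highly selfed RIL lines are expected to be almost fully homozygous (1.5%
residual heterozygosity after six selfing generations), so a locus with many
heterozygote calls betrays collapsed homeologs or paralogs: the inbreeding
coefficient Fis = 1 - Ho/He must exceed 0.8. Segregation distortion is
screened through a minimum expected heterozygosity (Nei's He = 2pq >= 0.34,
i.e. allele frequencies within ~[0.22, 0.78]), and unreliable loci through a
completeness floor (>= 100 genotyped individuals out of 135). The cascade
yields the "ER-clean" (targeted) and "bonus-clean" (untargeted) marker sets
and an accounting table whose categories reconcile exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from capmap.calling import CALL_A, CALL_B, CALL_H, MISSING


@dataclass(frozen=True)
class FilterThresholds:
    """Quality cascade thresholds (defaults are the study's)."""

    fis_min: float = 0.8  # strict: Fis must be > fis_min
    n_genotyped_min: int = 100
    he_min: float = 0.34  # inclusive: He >= he_min
    depth_targeted: int = 2
    depth_bonus: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.he_min <= 0.5:
            raise ValueError("he_min must be in [0, 0.5]")
        if not 0.0 <= self.fis_min <= 1.0:
            raise ValueError("fis_min must be in [0, 1]")


def _allele_counts(calls: np.ndarray) -> tuple[int, int, int]:
    arr = np.asarray(list(calls), dtype="<U1")
    return int((arr == CALL_A).sum()), int((arr == CALL_B).sum()), int((arr == CALL_H).sum())


def nei_he(calls) -> float:
    """Nei's expected heterozygosity 2pq from a call vector.

    p is the Dic2-allele frequency among non-missing calls; a heterozygote
    contributes half an allele to each class. Standard estimator without
    small-sample correction.
    """
    n_a, n_b, n_h = _allele_counts(calls)
    total = 2 * (n_a + n_b + n_h)
    if total == 0:
        raise ValueError("He undefined: all calls missing")
    p = (2 * n_a + n_h) / total
    return 2.0 * p * (1.0 - p)


def fis(calls) -> float:
    """Inbreeding coefficient 1 - Ho/He; near 1 in highly selfed lines.

    Undefined (raises) when He = 0 — such a locus is monomorphic and never
    reaches this filter.
    """
    n_a, n_b, n_h = _allele_counts(calls)
    n = n_a + n_b + n_h
    he = nei_he(calls)
    if he == 0.0:
        raise ValueError("Fis undefined: He = 0 (monomorphic locus)")
    ho = n_h / n
    return 1.0 - ho / he


def locus_stats(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per-locus n_genotyped, p, Ho, He and Fis (NaN where He=0)."""
    values = genotypes.to_numpy(dtype="<U1")
    n_a = (values == CALL_A).sum(axis=1)
    n_b = (values == CALL_B).sum(axis=1)
    n_h = (values == CALL_H).sum(axis=1)
    n = n_a + n_b + n_h
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, (2 * n_a + n_h) / np.maximum(2 * n, 1), np.nan)
        he = 2.0 * p * (1.0 - p)
        ho = np.where(n > 0, n_h / np.maximum(n, 1), np.nan)
        fis_v = np.where(he > 0, 1.0 - ho / np.where(he > 0, he, 1.0), np.nan)
    return pd.DataFrame(
        {"n_genotyped": n, "p": p, "ho": ho, "he": he, "fis": fis_v}, index=genotypes.index
    )


@dataclass
class CaptureAccounting:
    """Capture-efficiency bookkeeping; all identities checked in validate().

    ``targeted = not_captured + monomorphic + het_only + er``;
    ``bonus_untargeted = bonus_clean - bonus_on_targeted_contig``;
    ``total_clean = er_clean + bonus_clean``;
    ``total_for_map = er_clean + bonus_one_per_contig``.
    """

    targeted: int
    not_captured: int
    monomorphic: int
    het_only: int
    er_clean: int
    bonus_clean: int = 0
    bonus_on_targeted_contig: int = 0
    bonus_one_per_contig: int = 0
    targeted_ds: int | None = None  # DS-origin subset, for the polymorphic recovery ratio

    @property
    def er(self) -> int:
        return self.targeted - self.not_captured - self.monomorphic - self.het_only

    @property
    def bonus_untargeted(self) -> int:
        return self.bonus_clean - self.bonus_on_targeted_contig

    @property
    def total_clean(self) -> int:
        return self.er_clean + self.bonus_clean

    @property
    def total_for_map(self) -> int:
        return self.er_clean + self.bonus_one_per_contig

    @property
    def pct_not_captured(self) -> float:
        return 100.0 * self.not_captured / self.targeted

    @property
    def pct_recovered(self) -> float:
        """Clean targeted markers as a share of all targets."""
        return 100.0 * self.er_clean / self.targeted

    @property
    def pct_recovered_polymorphic_ds(self) -> float:
        """Clean targeted markers as a share of the DS-origin (known
        polymorphic) targets."""
        if not self.targeted_ds:
            raise ValueError("targeted_ds not set")
        return 100.0 * self.er_clean / self.targeted_ds

    def validate(self) -> None:
        if self.er < 0:
            raise ValueError("classification counts exceed the number of targets")
        if self.er_clean > self.er:
            raise ValueError("er_clean cannot exceed the ER count")
        if self.bonus_on_targeted_contig > self.bonus_clean:
            raise ValueError("bonus_on_targeted_contig cannot exceed bonus_clean")
        if self.bonus_one_per_contig > self.bonus_untargeted:
            raise ValueError("bonus_one_per_contig cannot exceed bonus_untargeted")

    def to_frame(self) -> pd.DataFrame:
        """Accounting rows under the published category names."""
        rows = [
            ("Number of targeted SNPs", self.targeted),
            ("Not captured", self.not_captured),
            ("Captured but monomorphic", self.monomorphic),
            ("Heterozygote state only", self.het_only),
            ("ER-SNPs", self.er),
            ("ER-clean SNPs (targeted and clean)", self.er_clean),
            ("Clean bonus SNPs", self.bonus_clean),
            ("On targeted contig (discarded)", self.bonus_on_targeted_contig),
            ("On untargeted contig", self.bonus_untargeted),
            ("Keeping only one SNP per contig", self.bonus_one_per_contig),
            ("Clean SNPs available", self.total_clean),
            ("SNP used for the genetic map (one per contig)", self.total_for_map),
        ]
        return pd.DataFrame(rows, columns=["category", "count"])


@dataclass
class FilterResult:
    er_clean: list[str]
    bonus_clean: list[str]
    bonus_deduped: list[str]
    accounting: CaptureAccounting
    stats: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def passes_filters(stats: pd.DataFrame, thresholds: FilterThresholds) -> pd.Series:
    """Conjunction of the three quality filters on a locus-stats frame."""
    return (
        (stats["fis"] > thresholds.fis_min)
        & (stats["he"] >= thresholds.he_min)
        & (stats["n_genotyped"] >= thresholds.n_genotyped_min)
    ).fillna(False)


def dedupe_per_contig(bonus_records: pd.DataFrame) -> list[str]:
    """Keep one bonus marker per untargeted contig.

    Markers on targeted contigs are removed outright (the targeted marker of
    the contig already represents it). Among the rest, ties break toward the
    most genotyped marker, then the highest He, then the smallest position.
    ``bonus_records`` is indexed by marker with columns ``contig``, ``pos``,
    ``on_targeted_contig`` and (optionally) ``n_genotyped``, ``he``.
    """
    if bonus_records.empty:
        return []
    off_target = bonus_records[~bonus_records["on_targeted_contig"].astype(bool)].copy()
    if off_target.empty:
        return []
    off_target["n_genotyped"] = off_target.get("n_genotyped", 0)
    off_target["he"] = off_target.get("he", 0.0)
    off_target = off_target.sort_values(
        by=["contig", "n_genotyped", "he", "pos"], ascending=[True, False, False, True]
    )
    kept = off_target.groupby("contig", sort=True).head(1)
    return list(kept.index)


def apply_filters(
    genotypes: pd.DataFrame,
    classifications: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
    bonus_genotypes: pd.DataFrame | None = None,
    bonus_records: pd.DataFrame | None = None,
    targeted_ds: int | None = None,
) -> FilterResult:
    """Apply the quality cascade and assemble the accounting table.

    ``genotypes``/``classifications`` cover the targeted loci;
    ``bonus_genotypes``/``bonus_records`` the discovered untargeted ones.
    The clean sets are the conjunction of the Fis, He and completeness
    filters (order-independent); bonus markers are additionally de-duplicated
    to one per untargeted contig.
    """
    stats = locus_stats(genotypes)
    er_mask = classifications["status"] == "ER"
    er_markers = classifications.index[er_mask]
    ok = passes_filters(stats.loc[er_markers], thresholds)
    er_clean = list(er_markers[ok.to_numpy(bool)])

    counts = classifications["status"].value_counts()
    bonus_clean: list[str] = []
    bonus_deduped: list[str] = []
    n_bonus_on_targeted = 0
    if bonus_genotypes is not None and len(bonus_genotypes):
        if bonus_records is None:
            raise ValueError("bonus_records required alongside bonus_genotypes")
        bstats = locus_stats(bonus_genotypes)
        bok = passes_filters(bstats, thresholds)
        bonus_clean = list(bonus_genotypes.index[bok.to_numpy(bool)])
        clean_records = bonus_records.loc[bonus_clean].copy()
        clean_records["n_genotyped"] = bstats.loc[bonus_clean, "n_genotyped"]
        clean_records["he"] = bstats.loc[bonus_clean, "he"]
        n_bonus_on_targeted = int(clean_records["on_targeted_contig"].astype(bool).sum())
        bonus_deduped = dedupe_per_contig(clean_records)
        stats = pd.concat([stats, bstats])

    accounting = CaptureAccounting(
        targeted=len(genotypes),
        not_captured=int(counts.get("not_captured", 0)),
        monomorphic=int(counts.get("monomorphic", 0)),
        het_only=int(counts.get("het_only", 0)),
        er_clean=len(er_clean),
        bonus_clean=len(bonus_clean),
        bonus_on_targeted_contig=n_bonus_on_targeted,
        bonus_one_per_contig=len(bonus_deduped),
        targeted_ds=targeted_ds,
    )
    accounting.validate()
    return FilterResult(
        er_clean=er_clean,
        bonus_clean=bonus_clean,
        bonus_deduped=bonus_deduped,
        accounting=accounting,
        stats=stats,
    )
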