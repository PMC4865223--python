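"""Synthetic study generation for a capture-genotyped RIL population.

This module creates every input the downstream pipeline consumes, with the
statistical structure of a real targeted-capture experiment on a selfed
recombinant inbred line (RIL) population of an allotetraploid wheat:

* a reference transcriptome (contigs with exon annotation and one candidate
  parental SNP per contig, a fraction of contigs with a homeologous
  near-copy on the other subgenome, and a fraction with an embedded tandem
  microsatellite),
* an F_g RIL population produced by single-seed descent from an F1, with
  crossovers modelled as a no-interference (Poisson) process on the cM scale
  (Haldane model),
* per-individual, per-locus allele read counts with bait-stoichiometry
  coverage (4-bait loci sequenced ~2x deeper than 2-bait loci), lognormal
  locus effects, negative-binomial individual depths, whole-locus capture
  failures, sequencing-error cross-talk, and a small set of microsatellite
  "sink" contigs absorbing a large share of the total read budget.

Defaults reproduce the study conditions the pipeline is meant for:
135 F6 RILs, median target depth 11.4 reads/locus/individual, 6% capture
failure, 20 sink contigs holding 42% of mapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NUCLEOTIDES = np.array(list("ACGT"))

#: Standard chromosome names of the two subgenomes (A and B) of tetraploid wheat.
WHEAT_CHROMOSOMES = [f"{num}{genome}" for num in range(1, 8) for genome in "AB"]


def expected_residual_heterozygosity(generations: int) -> float:
    """Expected heterozygote frequency after ``generations`` rounds of selfing.

    Each selfing generation halves the heterozygous fraction, so an F1-derived
    line carries (1/2)^g residual heterozygosity (0.015625 for g=6, the
    classic "1.5%" of an F6 RIL).
    """
    if generations < 0:
        raise ValueError("generations must be non-negative")
    return 0.5**generations


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoverageModel:
    """Stochastic model of capture sequencing depth.

    Parameters
    ----------
    mean_depth
        Mean reads per targeted 2-bait locus per individual; 4-bait loci
        receive twice this, matching bait stoichiometry. Because the depth
        distribution is overdispersed and right-skewed, the realized median
        sits somewhat below this value, as in real capture data.
    bait_count_per_locus
        Default bait count (2 or 4) used when no per-locus counts are given.
    capture_failure_rate
        Probability that a locus receives zero reads in every individual.
    sink_contig_count, sink_read_fraction
        Number of microsatellite "sink" contigs and the fraction of the total
        read budget they absorb (daisy-chain off-target capture).
    sequencing_error
        Per-read probability of reporting the wrong allele.
    overdispersion
        Negative-binomial size parameter k (variance = m + m^2/k).
    depth_lognorm_sigma
        Standard deviation of the lognormal per-locus depth multiplier.
    """

    mean_depth: float = 11.4
    bait_count_per_locus: int = 4
    capture_failure_rate: float = 0.06
    sink_contig_count: int = 20
    sink_read_fraction: float = 0.42
    sequencing_error: float = 0.01
    overdispersion: float = 1.0
    depth_lognorm_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        if self.bait_count_per_locus not in (2, 4):
            raise ValueError("bait_count_per_locus must be 2 or 4")
        for name in ("capture_failure_rate", "sink_read_fraction", "sequencing_error"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.sink_contig_count < 0:
            raise ValueError("sink_contig_count must be non-negative")


@dataclass
class MapSpec:
    """A true genetic map: chromosomes and one locus per contig.

    ``loci`` must contain columns ``contig_id``, ``chromosome``,
    ``position_cM`` and ``position_bp``; extra columns (origin, targeted
    status, ...) are carried through untouched.
    """

    chromosomes: list[tuple[str, float]]
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if any(length < 0 for length in lengths.values()):
            raise ValueError("chromosome lengths must be non-negative")
        required = {"contig_id", "chromosome", "position_cM", "position_bp"}
        missing = required - set(self.loci.columns)
        if missing:
            raise ValueError(f"loci table missing columns: {sorted(missing)}")
        if self.loci["contig_id"].duplicated().any():
            raise ValueError("contig_ids must be unique (one locus per contig)")
        unknown = set(self.loci["chromosome"]) - set(lengths)
        if unknown:
            raise ValueError(f"loci reference unknown chromosomes: {sorted(unknown)}")
        for chrom, sub in self.loci.groupby("chromosome"):
            if (sub["position_cM"] < 0).any() or (sub["position_cM"] > lengths[chrom]).any():
                raise ValueError(f"locus position outside chromosome {chrom} length")
            ordered = sub.sort_values("position_cM")
            d_cm = np.diff(ordered["position_cM"].to_numpy())
            d_bp = np.diff(ordered["position_bp"].to_numpy())
            if np.any(d_bp[d_cm > 0] <= 0):
                raise ValueError(f"bp positions must increase with cM on chromosome {chrom}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def loci_sorted(self) -> pd.DataFrame:
        """Loci ordered by chromosome then cM position."""
        chrom_order = {name: i for i, (name, _) in enumerate(self.chromosomes)}
        out = self.loci.copy()
        out["_order"] = out["chromosome"].map(chrom_order)
        out = out.sort_values(["_order", "position_cM", "contig_id"]).drop(columns="_order")
        return out.reset_index(drop=True)


@dataclass
class SimTruth:
    """True parental origin of every RIL at every locus, plus the true map.

    ``genotypes`` is a loci x individuals frame of ``A`` (Dic2 homozygote),
    ``B`` (Silur homozygote) or ``H`` (residual heterozygote), indexed by
    contig_id in map order.
    """

    genotypes: pd.DataFrame
    generations: int
    map_spec: MapSpec

    @property
    def individuals(self) -> list[str]:
        return list(self.genotypes.columns)

    def heterozygote_frequency(self) -> float:
        values = self.genotypes.to_numpy()
        return float((values == "H").mean())


@dataclass
class Reference:
    """Synthetic reference: contig sequences, exon annotation and SNP tables."""

    contigs: dict[str, str]
    exons: pd.DataFrame  # contig, exon_id, exon_start, exon_end (1-based inclusive)
    snps: pd.DataFrame  # contig, pos_1based, allele_dic2, allele_silur, origin, polymorphic
    homeologs: pd.DataFrame  # contig, parent_contig, bonus_pos, bonus_allele_dic2, bonus_allele_silur
    extra_sites: pd.DataFrame  # contig, pos_1based, allele_dic2, allele_silur (linked second site)
    microsat_contigs: list[str] = field(default_factory=list)


@dataclass
class ReadcountSet:
    """Simulated capture read counts with an exact read-budget accounting."""

    counts: pd.DataFrame  # locus_id, contig, pos, is_targeted, individual, reads_a, reads_b
    sink: pd.DataFrame  # contig, reads
    targeted_reads: int
    sink_reads: int

    @property
    def total_reads(self) -> int:
        return self.targeted_reads + self.sink_reads


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

_DEFAULT_EXON_DIST = {"kind": "uniform", "low": 130, "high": 400}

_DI_UNITS = ["AC", "AG", "AT", "CT", "GT"]
_TRI_UNITS = ["ACG", "AAT", "AGG", "CTT", "ATC"]


def _draw_exon_lengths(spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ValueError("exon_length_distribution must be a dict with a 'kind' key")
    kind = spec["kind"]
    if kind == "uniform":
        try:
            low, high = int(spec["low"]), int(spec["high"])
        except KeyError as exc:
            raise ValueError("uniform exon distribution requires 'low' and 'high'") from exc
        if not 1 <= low <= high:
            raise ValueError("uniform exon distribution requires 1 <= low <= high")
        return rng.integers(low, high + 1, size=n)
    if kind == "constant":
        try:
            length = int(spec["length"])
        except KeyError as exc:
            raise ValueError("constant exon distribution requires 'length'") from exc
        if length < 1:
            raise ValueError("constant exon length must be >= 1")
        return np.full(n, length)
    raise ValueError(f"unknown exon_length_distribution kind: {kind!r}")


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return NUCLEOTIDES[rng.integers(0, 4, size=length)]


def generate_reference(
    n_contigs: int,
    exon_length_distribution: dict | None = None,
    seed: int = 0,
    *,
    homeolog_fraction: float = 0.23,
    microsat_fraction: float = 0.003,
    epo_fraction: float = 0.30,
    epo_monomorphic_fraction: float = 0.41,
    second_snp_fraction: float = 0.15,
    homeolog_divergence: float = 0.03,
    mean_extra_exons: float = 1.0,
) -> Reference:
    """Generate a synthetic reference with one candidate SNP per contig.

    Each contig carries one or more exons (lengths from
    ``exon_length_distribution``, default uniform 130-400 bp) separated by
    short spacers, and exactly one candidate biallelic SNP placed in its
    longest exon. A ``homeolog_fraction`` of contigs receive a near-copy on
    the other subgenome carrying its own segregating "bonus" site; a
    ``microsat_fraction`` receive an embedded tandem microsatellite near the
    SNP; a ``second_snp_fraction`` receive a second, untargeted segregating
    position (perfectly linked to the primary SNP). EPO-origin SNPs are
    truly monomorphic between the cross parents with probability
    ``epo_monomorphic_fraction``.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    dist = exon_length_distribution if exon_length_distribution is not None else _DEFAULT_EXON_DIST
    rng = np.random.default_rng(seed)

    contigs: dict[str, str] = {}
    exon_rows: list[tuple] = []
    snp_rows: list[tuple] = []
    homeolog_rows: list[tuple] = []
    extra_rows: list[tuple] = []
    microsat_contigs: list[str] = []

    for i in range(n_contigs):
        name = f"contig{i:05d}"
        n_exons = 1 + rng.poisson(mean_extra_exons)
        lengths = _draw_exon_lengths(dist, n_exons, rng)
        gaps = rng.integers(20, 61, size=n_exons)  # leading spacer before each exon
        seq_parts: list[np.ndarray] = []
        exons: list[tuple[int, int]] = []
        cursor = 0
        for length, gap in zip(lengths, gaps):
            seq_parts.append(_random_sequence(int(gap), rng))
            cursor += int(gap)
            start = cursor + 1  # 1-based inclusive
            seq_parts.append(_random_sequence(int(length), rng))
            cursor += int(length)
            exons.append((start, cursor))
        seq = np.concatenate(seq_parts)

        for j, (start, end) in enumerate(exons):
            exon_rows.append((name, f"{name}.e{j+1}", start, end))

        # Candidate SNP in the longest exon (ties: first).
        longest = max(exons, key=lambda iv: (iv[1] - iv[0], -iv[0]))
        snp_pos = int(rng.integers(longest[0], longest[1] + 1))  # 1-based
        ref_base = seq[snp_pos - 1]
        alt_base = rng.choice(NUCLEOTIDES[NUCLEOTIDES != ref_base])
        origin = "EPO" if rng.random() < epo_fraction else "DS"
        polymorphic = not (origin == "EPO" and rng.random() < epo_monomorphic_fraction)
        snp_rows.append((name, snp_pos, str(ref_base), str(alt_base), origin, polymorphic))

        # Embedded tandem microsatellite near the SNP (daisy-chain sink material).
        if rng.random() < microsat_fraction:
            if rng.random() < 0.5:
                unit, reps = _DI_UNITS[rng.integers(len(_DI_UNITS))], 8
            else:
                unit, reps = _TRI_UNITS[rng.integers(len(_TRI_UNITS))], 6
            motif = np.array(list(unit * reps))
            lo, hi = longest[0] - 1, longest[1]  # 0-based slice bounds of exon
            start0 = snp_pos + 4  # 0-based start just downstream of the SNP
            if start0 + len(motif) > hi:
                start0 = snp_pos - 1 - 5 - len(motif)
            if start0 >= lo and start0 + len(motif) <= hi and not (start0 <= snp_pos - 1 < start0 + len(motif)):
                seq[start0 : start0 + len(motif)] = motif
                microsat_contigs.append(name)

        # Second, untargeted segregating position on the same contig.
        if rng.random() < second_snp_fraction:
            candidates = [p for p in range(longest[0], longest[1] + 1) if p != snp_pos]
            extra_pos = int(candidates[rng.integers(len(candidates))])
            base = seq[extra_pos - 1]
            alt = rng.choice(NUCLEOTIDES[NUCLEOTIDES != base])
            extra_rows.append((name, extra_pos, str(base), str(alt)))

        contigs[name] = "".join(seq)

        # Homeologous near-copy on the other subgenome, with its own bonus site.
        if rng.random() < homeolog_fraction:
            hname = f"{name}_h"
            hseq = seq.copy()
            mutate = rng.random(len(hseq)) < homeolog_divergence
            for k in np.flatnonzero(mutate):
                hseq[k] = rng.choice(NUCLEOTIDES[NUCLEOTIDES != hseq[k]])
            candidates = [p for p in range(longest[0], longest[1] + 1) if p != snp_pos]
            bonus_pos = int(candidates[rng.integers(len(candidates))])
            base = hseq[bonus_pos - 1]
            alt = rng.choice(NUCLEOTIDES[NUCLEOTIDES != base])
            contigs[hname] = "".join(hseq)
            for j, (start, end) in enumerate(exons):
                exon_rows.append((hname, f"{hname}.e{j+1}", start, end))
            homeolog_rows.append((hname, name, bonus_pos, str(base), str(alt)))

    return Reference(
        contigs=contigs,
        exons=pd.DataFrame(exon_rows, columns=["contig", "exon_id", "exon_start", "exon_end"]),
        snps=pd.DataFrame(
            snp_rows,
            columns=["contig", "pos_1based", "allele_dic2", "allele_silur", "origin", "polymorphic"],
        ),
        homeologs=pd.DataFrame(
            homeolog_rows,
            columns=["contig", "parent_contig", "bonus_pos", "bonus_allele_dic2", "bonus_allele_silur"],
        ),
        extra_sites=pd.DataFrame(
            extra_rows, columns=["contig", "pos_1based", "allele_dic2", "allele_silur"]
        ),
        microsat_contigs=microsat_contigs,
    )


# ---------------------------------------------------------------------------
# Map specification
# ---------------------------------------------------------------------------


def build_map_spec(
    reference: Reference,
    *,
    chromosomes: list[str] | None = None,
    chr_length_cM: float = 200.0,
    cm_per_mb: float = 1.0,
    jitter: float = 0.4,
    homeolog_offset_sd_cM: float = 5.0,
    seed: int = 0,
) -> MapSpec:
    """Place every reference locus on a true genetic map.

    Targeted contigs are spread over the chromosomes in round-robin order at
    roughly even cM spacing with multiplicative jitter; physical positions
    follow a uniform ``cm_per_mb`` recombination rate. Homeolog contigs are
    placed on the homeologous chromosome (A<->B) near their parent's
    position, emulating subgenome synteny.
    """
    chrom_names = list(chromosomes) if chromosomes is not None else list(WHEAT_CHROMOSOMES)
    rng = np.random.default_rng(seed)
    targets = reference.snps["contig"].tolist()
    n_chrom = len(chrom_names)

    per_chrom: dict[str, list[str]] = {name: [] for name in chrom_names}
    for i, contig in enumerate(targets):
        per_chrom[chrom_names[i % n_chrom]].append(contig)

    rows: list[tuple] = []
    placement: dict[str, tuple[str, float]] = {}
    for chrom in chrom_names:
        members = per_chrom[chrom]
        k = len(members)
        if k == 0:
            continue
        spacing = chr_length_cM / k
        base = (np.arange(k) + 0.5) * spacing
        pos = base + rng.uniform(-jitter, jitter, size=k) * spacing * 0.5
        pos = np.sort(np.clip(pos, 0.0, chr_length_cM))
        for contig, cm in zip(members, pos):
            placement[contig] = (chrom, float(cm))

    homeolog_of = {c: _homeolog_chromosome(c) or c for c in chrom_names}
    for _, row in reference.homeologs.iterrows():
        parent_chrom, parent_cm = placement[row["parent_contig"]]
        chrom = homeolog_of[parent_chrom]
        cm = float(np.clip(parent_cm + rng.normal(0, homeolog_offset_sd_cM), 0.0, chr_length_cM))
        placement[row["contig"]] = (chrom, cm)

    meta = reference.snps.set_index("contig")
    homeo_parents = reference.homeologs.set_index("contig")["parent_contig"].to_dict()
    for contig, (chrom, cm) in placement.items():
        is_target = contig in meta.index
        rows.append(
            (
                contig,
                chrom,
                cm,
                0,  # bp filled below, strictly increasing with cM
                is_target,
                meta.loc[contig, "origin"] if is_target else "bonus",
                bool(meta.loc[contig, "polymorphic"]) if is_target else True,
                homeo_parents.get(contig, ""),
            )
        )

    loci = pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "chromosome",
            "position_cM",
            "position_bp",
            "is_targeted",
            "origin",
            "polymorphic",
            "homeolog_parent",
        ],
    )
    # Physical positions: uniform cM/Mb rate; rank breaks cM ties so bp stays
    # strictly increasing wherever cM increases.
    for chrom, sub in loci.groupby("chromosome"):
        order = sub.sort_values("position_cM").index
        bp = np.round(sub.loc[order, "position_cM"].to_numpy() / cm_per_mb * 1e6).astype(np.int64)
        bp = bp + np.arange(len(bp))
        loci.loc[order, "position_bp"] = bp
    loci["position_bp"] = loci["position_bp"].astype(np.int64)

    return MapSpec(chromosomes=[(name, chr_length_cM) for name in chrom_names], loci=loci)


def _homeolog_chromosome(name: str) -> str | None:
    """'2A' -> '2B' and vice versa; None when the name has no A/B genome letter."""
    if len(name) >= 2 and name[:-1].isdigit() and name[-1] in "AB":
        return name[:-1] + ("B" if name[-1] == "A" else "A")
    return None


# ---------------------------------------------------------------------------
# RIL population
# ---------------------------------------------------------------------------


def _meiosis(
    haplotypes: tuple[np.ndarray, np.ndarray],
    chrom_layout: list[tuple[slice, np.ndarray, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a pair of haplotypes (Poisson crossovers per Haldane)."""
    gamete = np.empty_like(haplotypes[0])
    for sl, positions, length in chrom_layout:
        n_cross = rng.poisson(length / 100.0)
        if n_cross:
            cuts = np.sort(rng.uniform(0.0, length, size=n_cross))
            phase = (rng.integers(2) + np.searchsorted(cuts, positions)) % 2
        else:
            phase = np.full(len(positions), rng.integers(2))
        gamete[sl] = np.where(phase == 0, haplotypes[0][sl], haplotypes[1][sl])
    return gamete


def simulate_ril_population(
    map_spec: MapSpec,
    n_individuals: int = 135,
    generations: int = 6,
    seed: int = 0,
) -> SimTruth:
    """Simulate an F1-derived selfing series by single-seed descent.

    Every individual starts as an F1 (one haplotype from each parent) and is
    selfed for ``generations`` rounds; each selfing draws two independent
    gametes with crossovers as a Poisson process on the cM scale (no
    interference). The residual heterozygote frequency is (1/2)^generations
    in expectation.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)

    loci = map_spec.loci_sorted()
    chrom_layout: list[tuple[slice, np.ndarray, float]] = []
    lengths = dict(map_spec.chromosomes)
    start = 0
    for chrom, sub in loci.groupby("chromosome", sort=False):
        sl = slice(start, start + len(sub))
        chrom_layout.append((sl, sub["position_cM"].to_numpy(), lengths[chrom]))
        start += len(sub)

    n_loci = len(loci)
    individuals = [f"RIL{i+1:03d}" for i in range(n_individuals)]
    geno = np.empty((n_loci, n_individuals), dtype="<U1")
    h_dic2 = np.zeros(n_loci, dtype=np.int8)
    h_silur = np.ones(n_loci, dtype=np.int8)
    for j in range(n_individuals):
        pair = (h_dic2, h_silur)  # the F1
        for _ in range(generations):
            g1 = _meiosis(pair, chrom_layout, rng)
            g2 = _meiosis(pair, chrom_layout, rng)
            pair = (g1, g2)
        hom = pair[0] == pair[1]
        geno[:, j] = np.where(hom, np.where(pair[0] == 0, "A", "B"), "H")

    genotypes = pd.DataFrame(geno, index=loci["contig_id"].tolist(), columns=individuals)
    genotypes.index.name = "contig_id"
    return SimTruth(genotypes=genotypes, generations=generations, map_spec=map_spec)


# ---------------------------------------------------------------------------
# Capture read counts
# ---------------------------------------------------------------------------


def default_locus_table(truth: SimTruth, reference: Reference | None = None) -> pd.DataFrame:
    """Per-sequenced-position table driving the read-count simulation.

    Columns: ``locus_id`` (contig@pos), ``contig``, ``pos``, ``is_targeted``,
    ``polymorphic``, ``truth_contig`` (the map locus whose genotype the
    position carries). With a reference, targeted SNP positions are taken
    from the SNP table, homeolog bonus sites become untargeted positions on
    their own (mapped) contig, and linked second sites become untargeted
    positions on targeted contigs; without one, each map locus is sequenced
    at a nominal position 1.
    """
    loci = truth.map_spec.loci_sorted()
    rows: list[tuple] = []
    if reference is None:
        for _, row in loci.iterrows():
            contig = row["contig_id"]
            rows.append((f"{contig}@1", contig, 1, bool(row.get("is_targeted", True)),
                         bool(row.get("polymorphic", True)), contig))
    else:
        snp_pos = reference.snps.set_index("contig")["pos_1based"].to_dict()
        bonus_pos = reference.homeologs.set_index("contig")["bonus_pos"].to_dict()
        for _, row in loci.iterrows():
            contig = row["contig_id"]
            targeted = bool(row.get("is_targeted", True))
            pos = int(snp_pos[contig]) if targeted else int(bonus_pos[contig])
            rows.append((f"{contig}@{pos}", contig, pos, targeted,
                         bool(row.get("polymorphic", True)), contig))
        for _, row in reference.extra_sites.iterrows():
            contig, pos = row["contig"], int(row["pos_1based"])
            if contig in truth.genotypes.index:
                rows.append((f"{contig}@{pos}", contig, pos, False, True, contig))
    return pd.DataFrame(
        rows, columns=["locus_id", "contig", "pos", "is_targeted", "polymorphic", "truth_contig"]
    )


def simulate_capture_readcounts(
    truth: SimTruth,
    model: CoverageModel,
    seed: int = 0,
    *,
    bait_counts: dict[str, int] | pd.Series | None = None,
    locus_table: pd.DataFrame | None = None,
    sink_contigs: list[str] | None = None,
) -> ReadcountSet:
    """Draw per-individual allele read counts for every sequenced position.

    Depth at a locus is negative-binomial around ``mean_depth *
    (bait_count/2) * lognormal locus effect``; a ``capture_failure_rate``
    fraction of loci receive zero reads everywhere. Allele counts split
    binomially by the true genotype with ``sequencing_error`` cross-talk
    (monomorphic targets always emit the Dic2 allele). Sink contigs then
    absorb ``sink_read_fraction`` of the grand total, so the read budget
    reconciles exactly: total = targeted + sink.
    """
    table = locus_table if locus_table is not None else default_locus_table(truth)
    missing = set(table["truth_contig"]) - set(truth.genotypes.index)
    if missing:
        raise ValueError(f"locus_table references unknown truth loci: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)

    n_loci = len(table)
    individuals = truth.individuals
    n_ind = len(individuals)

    if bait_counts is None:
        bc = np.full(n_loci, model.bait_count_per_locus, dtype=float)
    else:
        mapping = dict(bait_counts) if not isinstance(bait_counts, dict) else bait_counts
        bc = table["contig"].map(lambda c: mapping.get(c, model.bait_count_per_locus)).to_numpy(float)
    if not np.all(np.isin(bc, (2, 4))):
        raise ValueError("bait counts must be 2 or 4")

    captured = rng.random(n_loci) >= model.capture_failure_rate
    locus_mult = np.exp(rng.normal(0.0, model.depth_lognorm_sigma, size=n_loci))
    mean = model.mean_depth * (bc / 2.0) * locus_mult
    k = model.overdispersion
    p = k / (k + mean)
    depth = rng.negative_binomial(k, p[:, None], size=(n_loci, n_ind))
    depth[~captured, :] = 0

    geno = truth.genotypes.loc[table["truth_contig"]].to_numpy()
    err = model.sequencing_error
    p_a = np.where(geno == "A", 1.0 - err, np.where(geno == "B", err, 0.5))
    p_a[~table["polymorphic"].to_numpy(bool), :] = 1.0 - err  # monomorphic targets: all Dic2
    reads_a = rng.binomial(depth, p_a)
    reads_b = depth - reads_a

    counts = pd.DataFrame(
        {
            "locus_id": np.repeat(table["locus_id"].to_numpy(), n_ind),
            "contig": np.repeat(table["contig"].to_numpy(), n_ind),
            "pos": np.repeat(table["pos"].to_numpy(), n_ind),
            "is_targeted": np.repeat(table["is_targeted"].to_numpy(), n_ind),
            "individual": np.tile(np.array(individuals), n_loci),
            "reads_a": reads_a.ravel(),
            "reads_b": reads_b.ravel(),
        }
    )

    targeted_total = int(depth.sum())
    f = model.sink_read_fraction
    if model.sink_contig_count > 0 and f > 0 and targeted_total > 0:
        sink_total = int(round(targeted_total * f / (1.0 - f)))
        names = list(sink_contigs) if sink_contigs else []
        names = names[: model.sink_contig_count]
        names += [f"sink{i:03d}" for i in range(len(names), model.sink_contig_count)]
        weights = rng.dirichlet(np.full(model.sink_contig_count, 0.5))
        sink_reads = rng.multinomial(sink_total, weights)
        sink = pd.DataFrame({"contig": names, "reads": sink_reads})
    else:
        sink_total = 0
        sink = pd.DataFrame(columns=["contig", "reads"])

    return ReadcountSet(counts=counts, sink=sink, targeted_reads=targeted_total, sink_reads=sink_total)


# ---------------------------------------------------------------------------
# Putative (external) positions
# ---------------------------------------------------------------------------


def make_putative_positions(
    map_spec: MapSpec,
    *,
    swap_prob: float = 0.10,
    other_prob: float = 0.02,
    missing_prob: float = 0.30,
    cm_noise_sd: float = 2.0,
    bp_noise_sd: float = 2.0e6,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy per-contig chromosome assignments and positions.

    Emulates assignments obtained by sequence similarity against an external
    reference: a ``missing_prob`` fraction of contigs get no hit, a
    ``swap_prob`` fraction are attributed to the homeologous chromosome (the
    dominant error mode in an allopolyploid) and an ``other_prob`` fraction
    to an unrelated chromosome. Positions carry Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [name for name, _ in map_spec.chromosomes]
    rows = []
    for _, row in map_spec.loci_sorted().iterrows():
        if rng.random() < missing_prob:
            continue
        chrom = row["chromosome"]
        u = rng.random()
        if u < swap_prob:
            chrom = _homeolog_chromosome(chrom) or chrom
        elif u < swap_prob + other_prob:
            others = [c for c in chrom_names if c != chrom and c != _homeolog_chromosome(chrom)]
            if others:
                chrom = others[rng.integers(len(others))]
        cm = max(0.0, row["position_cM"] + rng.normal(0.0, cm_noise_sd))
        bp = max(1, int(round(row["position_bp"] + rng.normal(0.0, bp_noise_sd))))
        rows.append((row["contig_id"], chrom, bp, cm))
    return pd.DataFrame(rows, columns=["contig", "putative_chromosome", "putative_bp", "putative_cM"])
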