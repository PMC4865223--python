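"""Allele-specific 120-mer bait design with a tandem-microsatellite screen.

One SNP per contig is selected under exon constraints and emitted as a small
set of 120 bp capture baits in one of three layouts:

* type 1 (exon >= 200 bp): four baits — two centered on the SNP (one per
  parental allele) plus two allele-invariant flanking baits that together
  tile a 200 bp window around the SNP;
* type 2 (exon >= 200 bp): two shifted baits, each containing the SNP (one
  per allele) at different offsets;
* type 3 (120 <= exon < 200 bp): two baits at identical coordinates, one per
  allele.

Baits never cross exon boundaries. Every bait is screened for tandem
microsatellites (a dinucleotide unit repeated >= 7 times or a trinucleotide
unit repeated >= 5 times), the repeat structure implicated in daisy-chain
off-target capture.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

BAIT_LENGTH = 120
TYPE1_SPAN = 200

#: Tandem repeats: any 2 bp unit x7 (>=14 bp) or 3 bp unit x5 (>=15 bp).
_DI_RUN = re.compile(r"(..)\1{6}")
_TRI_RUN = re.compile(r"(...)\1{4}")
_VALID = re.compile(r"^[ACGT]*$")


@dataclass(frozen=True)
class SnpTarget:
    """One targeted parental polymorphism with its exon context."""

    contig_id: str
    pos_1based: int
    allele_dic2: str
    allele_silur: str
    exon_start: int  # 1-based inclusive
    exon_end: int
    origin: str  # DS | EPO
    layout_type: int  # 1 | 2 | 3

    def __post_init__(self) -> None:
        if self.allele_dic2 == self.allele_silur:
            raise ValueError("parental alleles must differ")
        if not self.exon_start <= self.pos_1based <= self.exon_end:
            raise ValueError("SNP position must lie inside its exon")
        if self.layout_type not in (1, 2, 3):
            raise ValueError("layout_type must be 1, 2 or 3")

    @property
    def exon_length(self) -> int:
        return self.exon_end - self.exon_start + 1


@dataclass(frozen=True)
class Bait:
    """A 120-mer capture bait.

    ``name`` follows the ``A@pos|B|C|D|E`` convention: contig@SNP-position,
    parental allelic status (Dic2 | Silur | flanking), 1-based SNP offset in
    the bait (NA for flanking baits), layout type, SNP origin.
    """

    name: str
    sequence: str
    allele_status: str  # Dic2 | Silur | flanking
    snp_offset_in_bait: int | None  # 1-based; None for flanking baits
    layout_type: int
    repeat_flagged: bool

    def __post_init__(self) -> None:
        if len(self.sequence) != BAIT_LENGTH:
            raise ValueError(f"bait must be {BAIT_LENGTH} bp, got {len(self.sequence)}")
        if self.allele_status == "flanking" and self.snp_offset_in_bait is not None:
            raise ValueError("flanking baits carry no SNP allele")


def screen_microsatellite(sequence: str) -> bool:
    """True iff the sequence contains a tandem microsatellite run.

    A run is a dinucleotide motif repeated >= 7 times head-to-tail (>= 14 bp)
    or a trinucleotide motif repeated >= 5 times (>= 15 bp). Homopolymer
    stretches count only through the dinucleotide rule (an AA unit is itself
    a tandem dinucleotide, so 14 consecutive identical bases qualify).
    """
    seq = sequence.upper()
    if not _VALID.match(seq):
        raise ValueError("sequence must contain only A/C/G/T characters")
    return bool(_DI_RUN.search(seq) or _TRI_RUN.search(seq))


def select_targets(
    snp_table: pd.DataFrame,
    exon_annotation: pd.DataFrame,
    contig_lengths: dict[str, int] | None = None,
    *,
    max_per_contig: int = 1,
    min_exon: int = BAIT_LENGTH,
    long_exon: int = TYPE1_SPAN,
    type1_fraction: float = 3625 / (3625 + 508),
) -> tuple[list[SnpTarget], pd.DataFrame]:
    """Select at most ``max_per_contig`` designable SNPs per contig.

    A SNP is designable when it lies inside a single exon of length >=
    ``min_exon``. SNPs in exons >= ``long_exon`` are split between layout
    types 1 and 2 by a deterministic quota (``type1_fraction`` of them, in
    sorted contig order, become type 1); shorter eligible exons give type 3.
    Ties within a contig are broken toward the longest exon, then the
    smallest position.

    Returns the targets plus a per-row report (kept/dropped with reasons).
    """
    if not 0.0 <= type1_fraction <= 1.0:
        raise ValueError("type1_fraction must be in [0, 1]")
    exons = exon_annotation.rename(columns={"start": "exon_start", "end": "exon_end"})
    report_rows: list[tuple] = []
    candidates: list[dict] = []

    exon_by_contig: dict[str, pd.DataFrame] = {c: sub for c, sub in exons.groupby("contig")}
    for _, row in snp_table.iterrows():
        contig, pos = row["contig"], int(row["pos_1based"])
        length = contig_lengths.get(contig) if contig_lengths else None
        if pos < 1 or (length is not None and pos > length):
            report_rows.append((contig, pos, "dropped", "position_outside_contig"))
            continue
        sub = exon_by_contig.get(contig)
        hit = None
        if sub is not None:
            inside = sub[(sub["exon_start"] <= pos) & (pos <= sub["exon_end"])]
            if len(inside):
                hit = inside.iloc[0]
        if hit is None:
            report_rows.append((contig, pos, "dropped", "not_in_exon"))
            continue
        exon_len = int(hit["exon_end"]) - int(hit["exon_start"]) + 1
        if exon_len < min_exon:
            report_rows.append((contig, pos, "dropped", "exon_too_short"))
            continue
        candidates.append(
            {
                "contig": contig,
                "pos": pos,
                "allele_dic2": row["allele_dic2"],
                "allele_silur": row["allele_silur"],
                "origin": row.get("origin", "DS"),
                "exon_start": int(hit["exon_start"]),
                "exon_end": int(hit["exon_end"]),
                "exon_len": exon_len,
            }
        )

    # One SNP per contig: longest exon, then smallest position.
    chosen: list[dict] = []
    by_contig: dict[str, list[dict]] = {}
    for cand in candidates:
        by_contig.setdefault(cand["contig"], []).append(cand)
    for contig in sorted(by_contig):
        ranked = sorted(by_contig[contig], key=lambda c: (-c["exon_len"], c["pos"]))
        for cand in ranked[:max_per_contig]:
            chosen.append(cand)
        for cand in ranked[max_per_contig:]:
            report_rows.append((cand["contig"], cand["pos"], "dropped", "extra_snp_on_contig"))

    # Deterministic type-1 quota among long-exon targets, in sorted order.
    long_targets = [c for c in chosen if c["exon_len"] >= long_exon]
    n_type1 = round(type1_fraction * len(long_targets))
    type_of: dict[tuple[str, int], int] = {}
    for i, cand in enumerate(long_targets):
        type_of[(cand["contig"], cand["pos"])] = 1 if i < n_type1 else 2
    targets: list[SnpTarget] = []
    for cand in chosen:
        layout = type_of.get((cand["contig"], cand["pos"]), 3)
        targets.append(
            SnpTarget(
                contig_id=cand["contig"],
                pos_1based=cand["pos"],
                allele_dic2=cand["allele_dic2"],
                allele_silur=cand["allele_silur"],
                exon_start=cand["exon_start"],
                exon_end=cand["exon_end"],
                origin=cand["origin"],
                layout_type=layout,
            )
        )
        report_rows.append((cand["contig"], cand["pos"], "kept", f"type{layout}"))

    report = pd.DataFrame(report_rows, columns=["contig", "pos_1based", "status", "reason"])
    return targets, report


def _clamp(value: int, low: int, high: int) -> int:
    return max(low, min(value, high))


def _bait_sequence(contig_seq: str, start0: int, allele_pos0: int | None, allele: str | None) -> str:
    seq = contig_seq[start0 : start0 + BAIT_LENGTH]
    if allele_pos0 is not None:
        offset = allele_pos0 - start0
        seq = seq[:offset] + allele + seq[offset + 1 :]
    return seq


def design_baits(
    target: SnpTarget,
    contig_sequence: str,
    *,
    type2_offsets: tuple[int, int] = (40, 80),
) -> list[Bait]:
    """Emit the 120-mer baits for one target in its layout.

    Flanking baits (type 1) carry the reference (Dic2) haplotype and no SNP
    allele annotation. ``type2_offsets`` are the preferred 0-based SNP
    offsets of the two shifted type-2 baits (defaults put the SNP at 1/3 and
    2/3 of the bait).
    """
    seq = contig_sequence.upper()
    snp0 = target.pos_1based - 1
    ex0, ex1 = target.exon_start - 1, target.exon_end - 1
    if ex1 >= len(seq):
        raise ValueError("exon interval exceeds contig length")
    if seq[snp0] != target.allele_dic2:
        raise ValueError(
            f"contig {target.contig_id} position {target.pos_1based}: reference base "
            f"{seq[snp0]} does not match Dic2 allele {target.allele_dic2}"
        )
    exon_len = target.exon_length
    if exon_len < BAIT_LENGTH:
        raise ValueError("layout impossible: exon shorter than the bait length")

    def make(start0: int, status: str, allele: str | None) -> Bait:
        if status == "flanking":
            bait_seq = _bait_sequence(seq, start0, None, None)
            offset1 = None
            offset_field = "NA"
        else:
            bait_seq = _bait_sequence(seq, start0, snp0, allele)
            offset1 = snp0 - start0 + 1
            offset_field = str(offset1)
        name = (
            f"{target.contig_id}@{target.pos_1based}|{status}|{offset_field}"
            f"|{target.layout_type}|{target.origin}"
        )
        return Bait(
            name=name,
            sequence=bait_seq,
            allele_status=status,
            snp_offset_in_bait=offset1,
            layout_type=target.layout_type,
            repeat_flagged=screen_microsatellite(bait_seq),
        )

    baits: list[Bait] = []
    if target.layout_type == 1:
        if exon_len < TYPE1_SPAN:
            raise ValueError("layout impossible: type 1 requires an exon of at least 200 bp")
        center = _clamp(snp0 - BAIT_LENGTH // 2, ex0, ex1 - BAIT_LENGTH + 1)
        window = _clamp(snp0 - TYPE1_SPAN // 2, ex0, ex1 - TYPE1_SPAN + 1)
        baits.append(make(center, "Dic2", target.allele_dic2))
        baits.append(make(center, "Silur", target.allele_silur))
        baits.append(make(window, "flanking", None))  # 5' half of the 200 bp window
        baits.append(make(window + TYPE1_SPAN - BAIT_LENGTH, "flanking", None))  # 3' half
    elif target.layout_type == 2:
        o1, o2 = type2_offsets
        if not (0 <= o1 < BAIT_LENGTH and 0 <= o2 < BAIT_LENGTH):
            raise ValueError("type2_offsets must be valid 0-based bait offsets")
        start1 = _clamp(snp0 - o1, ex0, ex1 - BAIT_LENGTH + 1)
        start2 = _clamp(snp0 - o2, ex0, ex1 - BAIT_LENGTH + 1)
        baits.append(make(start1, "Dic2", target.allele_dic2))
        baits.append(make(start2, "Silur", target.allele_silur))
    else:  # type 3: two aligned baits at identical coordinates
        start = _clamp(snp0 - BAIT_LENGTH // 2, ex0, ex1 - BAIT_LENGTH + 1)
        baits.append(make(start, "Dic2", target.allele_dic2))
        baits.append(make(start, "Silur", target.allele_silur))
    return baits


def design_all(
    targets: list[SnpTarget],
    contigs: dict[str, str],
    *,
    type2_offsets: tuple[int, int] = (40, 80),
) -> tuple[list[Bait], pd.DataFrame]:
    """Design baits for every target; returns baits plus a design report."""
    baits: list[Bait] = []
    rows: list[tuple] = []
    for target in targets:
        try:
            emitted = design_baits(target, contigs[target.contig_id], type2_offsets=type2_offsets)
        except (ValueError, KeyError) as exc:
            rows.append((target.contig_id, target.pos_1based, target.layout_type, 0, False, str(exc)))
            continue
        baits.extend(emitted)
        flagged = any(b.repeat_flagged for b in emitted)
        rows.append((target.contig_id, target.pos_1based, target.layout_type, len(emitted), flagged, ""))
    report = pd.DataFrame(
        rows, columns=["contig", "pos_1based", "layout_type", "n_baits", "repeat_flagged", "error"]
    )
    return baits, report


def bait_counts_by_contig(targets: list[SnpTarget]) -> dict[str, int]:
    """Baits per targeted contig under the layout rules (type 1 -> 4, else 2)."""
    return {t.contig_id: (4 if t.layout_type == 1 else 2) for t in targets}
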