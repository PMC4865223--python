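"""Bait design: target selection, layout geometry and the microsatellite screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from capmap.baits import (
    BAIT_LENGTH,
    SnpTarget,
    design_all,
    design_baits,
    screen_microsatellite,
    select_targets,
)

RNG = np.random.default_rng(123)


def random_seq(n: int, rng=RNG) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_contig(exon_len: int, snp_offset: int, lead: int = 30):
    """Contig with one exon of ``exon_len`` and a SNP at ``snp_offset`` within it."""
    seq = random_seq(lead + exon_len + 30)
    exon_start, exon_end = lead + 1, lead + exon_len
    pos = lead + snp_offset  # 1-based
    return seq, exon_start, exon_end, pos


def brute_force_tandem(seq: str) -> bool:
    """Independent oracle: scan every phase for k-mer tandem runs."""
    for k, min_reps in ((2, 7), (3, 5)):
        for i in range(len(seq) - k * min_reps + 1):
            unit = seq[i : i + k]
            if all(seq[i + j * k : i + (j + 1) * k] == unit for j in range(min_reps)):
                return True
    return False


class TestSelectTargets:
    def _tables(self, rows):
        snps = pd.DataFrame(rows, columns=["contig", "pos_1based", "allele_dic2", "allele_silur", "origin"])
        return snps

    def test_exon_length_boundaries(self):
        exons = pd.DataFrame(
            [
                ("c119", "e1", 10, 128),  # 119 bp -> too short
                ("c150", "e1", 10, 159),  # 150 bp -> type 3
                ("c250", "e1", 10, 259),  # 250 bp -> type 1/2
            ],
            columns=["contig", "exon_id", "exon_start", "exon_end"],
        )
        snps = self._tables(
            [("c119", 60, "A", "G", "DS"), ("c150", 60, "A", "G", "DS"), ("c250", 60, "A", "G", "DS")]
        )
        targets, report = select_targets(snps, exons, type1_fraction=1.0)
        by_contig = {t.contig_id: t for t in targets}
        assert "c119" not in by_contig
        assert by_contig["c150"].layout_type == 3
        assert by_contig["c250"].layout_type == 1
        dropped = report[report["status"] == "dropped"]
        assert dropped.iloc[0]["reason"] == "exon_too_short"

    def test_one_snp_per_contig_longest_exon_then_position(self):
        exons = pd.DataFrame(
            [("c1", "e1", 1, 150), ("c1", "e2", 200, 500)],
            columns=["contig", "exon_id", "exon_start", "exon_end"],
        )
        snps = self._tables(
            [("c1", 50, "A", "G", "DS"), ("c1", 300, "C", "T", "DS"), ("c1", 250, "A", "C", "DS")]
        )
        targets, _ = select_targets(snps, exons)
        assert len(targets) == 1
        assert targets[0].pos_1based == 250  # longest exon wins, then smallest position

    def test_position_outside_contig_rejected_and_logged(self):
        exons = pd.DataFrame([("c1", "e1", 1, 300)], columns=["contig", "exon_id", "exon_start", "exon_end"])
        snps = self._tables([("c1", 999, "A", "G", "DS")])
        targets, report = select_targets(snps, exons, contig_lengths={"c1": 330})
        assert targets == []
        assert (report["reason"] == "position_outside_contig").any()

    def test_type_split_fraction(self):
        exons = pd.DataFrame(
            [(f"c{i}", "e1", 1, 300) for i in range(10)],
            columns=["contig", "exon_id", "exon_start", "exon_end"],
        )
        snps = self._tables([(f"c{i}", 150, "A", "G", "DS") for i in range(10)])
        targets, _ = select_targets(snps, exons, type1_fraction=0.6)
        types = [t.layout_type for t in targets]
        assert types.count(1) == 6 and types.count(2) == 4


class TestDesignBaits:
    def _target(self, exon_len, snp_offset, layout):
        seq, es, ee, pos = make_contig(exon_len, snp_offset)
        target = SnpTarget(
            contig_id="c1",
            pos_1based=pos,
            allele_dic2=seq[pos - 1],
            allele_silur="A" if seq[pos - 1] != "A" else "G",
            exon_start=es,
            exon_end=ee,
            origin="DS",
            layout_type=layout,
        )
        return target, seq

    @pytest.mark.parametrize("layout,expected_n,expected_with_snp", [(1, 4, 2), (2, 2, 2), (3, 2, 2)])
    def test_bait_counts_per_layout(self, layout, expected_n, expected_with_snp):
        target, seq = self._target(320, 160, layout)
        baits = design_baits(target, seq)
        assert len(baits) == expected_n
        with_snp = [b for b in baits if b.snp_offset_in_bait is not None]
        assert len(with_snp) == expected_with_snp
        for bait in baits:
            assert len(bait.sequence) == BAIT_LENGTH

    def test_sequences_match_contig_except_allele(self):
        target, seq = self._target(320, 160, 1)
        for bait in design_baits(target, seq):
            # locate the bait on the contig via its invariant flanks
            if bait.allele_status == "flanking":
                assert bait.sequence in seq
                continue
            allele = target.allele_dic2 if bait.allele_status == "Dic2" else bait.sequence[bait.snp_offset_in_bait - 1]
            offset0 = bait.snp_offset_in_bait - 1
            start0 = target.pos_1based - 1 - offset0
            reference = seq[start0 : start0 + BAIT_LENGTH]
            diffs = [i for i in range(BAIT_LENGTH) if reference[i] != bait.sequence[i]]
            if bait.allele_status == "Dic2":
                assert diffs == []
            else:
                assert diffs == [offset0]
                assert bait.sequence[offset0] == target.allele_silur

    def test_allele_pair_differs_at_exactly_one_position(self):
        for layout in (1, 2, 3):
            target, seq = self._target(320, 100, layout)
            baits = [b for b in design_baits(target, seq) if b.snp_offset_in_bait is not None]
            d2 = next(b for b in baits if b.allele_status == "Dic2")
            si = next(b for b in baits if b.allele_status == "Silur")
            if layout == 3:
                diffs = [i for i in range(BAIT_LENGTH) if d2.sequence[i] != si.sequence[i]]
                assert len(diffs) == 1
            assert d2.sequence[d2.snp_offset_in_bait - 1] == target.allele_dic2
            assert si.sequence[si.snp_offset_in_bait - 1] == target.allele_silur

    def test_type3_exon_exactly_120_forced_placement(self):
        target, seq = self._target(120, 60, 3)
        baits = design_baits(target, seq)
        exon_seq = seq[target.exon_start - 1 : target.exon_end]
        assert len(baits) == 2
        d2, si = baits
        assert d2.sequence == exon_seq  # Dic2 bait equals the whole exon
        assert d2.snp_offset_in_bait == si.snp_offset_in_bait
        diffs = [i for i in range(BAIT_LENGTH) if d2.sequence[i] != si.sequence[i]]
        assert len(diffs) == 1

    def test_type1_tiles_200bp_window_inside_exon(self):
        target, seq = self._target(260, 130, 1)
        flanks = [b for b in design_baits(target, seq) if b.allele_status == "flanking"]
        starts = sorted(seq.index(b.sequence) for b in flanks)
        assert starts[1] - starts[0] == 200 - BAIT_LENGTH  # the two flanks tile 200 bp
        assert starts[0] >= target.exon_start - 1
        assert starts[1] + BAIT_LENGTH <= target.exon_end

    def test_impossible_layout_raises_naming_constraint(self):
        target, seq = self._target(150, 75, 1)  # type 1 needs >= 200 bp
        with pytest.raises(ValueError, match="200"):
            design_baits(target, seq)

    def test_bait_totals_reconcile_over_target_set(self):
        rows, exon_rows, contigs = [], [], {}
        rng = np.random.default_rng(7)
        for i in range(40):
            exon_len = int(rng.integers(130, 400))
            seq, es, ee, pos = make_contig(exon_len, exon_len // 2)
            name = f"c{i:03d}"
            contigs[name] = seq
            exon_rows.append((name, "e1", es, ee))
            alt = "A" if seq[pos - 1] != "A" else "G"
            rows.append((name, pos, seq[pos - 1], alt, "DS"))
        snps = pd.DataFrame(rows, columns=["contig", "pos_1based", "allele_dic2", "allele_silur", "origin"])
        exons = pd.DataFrame(exon_rows, columns=["contig", "exon_id", "exon_start", "exon_end"])
        targets, _ = select_targets(snps, exons)
        baits, report = design_all(targets, contigs)
        counts = {1: 0, 2: 0, 3: 0}
        for t in targets:
            counts[t.layout_type] += 1
        assert len(baits) == 4 * counts[1] + 2 * counts[2] + 2 * counts[3]
        assert (report["error"] == "").all()


class TestMicrosatelliteScreen:
    def test_positive_controls_and_boundary(self):
        pad = random_seq(50)
        tail = random_seq(120 - 50 - 14)
        assert screen_microsatellite(pad + "AC" * 7 + tail)
        assert screen_microsatellite(random_seq(40) + "ACG" * 5 + random_seq(65))
        base = "GATTTCGGCGAT" * 12
        assert not screen_microsatellite(base[:50] + "ACACACACACAC" + base[50:58])  # AC x6 only

    def test_homopolymer_counts_as_tandem_dinucleotide(self):
        assert screen_microsatellite("A" * 14 + random_seq(106))
        assert not screen_microsatellite("GACTC" * 24)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            screen_microsatellite("ACGTN" * 24)

    def test_matches_bruteforce_on_random_and_planted(self):
        rng = np.random.default_rng(99)
        n_flagged = 0
        for i in range(1000):
            seq = random_seq(120, rng)
            if i % 3 == 0:  # plant a repeat of random unit/length
                k = int(rng.integers(2, 4))
                reps = int(rng.integers(3, 10))
                unit = random_seq(k, rng)
                start = int(rng.integers(0, 120 - k * reps))
                seq = seq[:start] + unit * reps + seq[start + k * reps :]
            expected = brute_force_tandem(seq)
            assert screen_microsatellite(seq) == expected
            n_flagged += expected
        assert n_flagged > 20  # the planted repeats exercised the positive path

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_reverse_complement_invariance(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(120, rng)
        if seed % 2:
            unit = random_seq(int(rng.integers(2, 4)), rng)
            reps = 8
            start = int(rng.integers(0, 120 - len(unit) * reps))
            seq = seq[:start] + unit * reps + seq[start + len(unit) * reps :]
        complement = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(complement)[::-1]
        assert screen_microsatellite(seq) == screen_microsatellite(rc)
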