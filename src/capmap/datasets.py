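"""Published reference tables from the Dic2 x Silur durum wheat capture study.

These are the printed bookkeeping inputs of the experiment this package
models: the SNP panel available for bait design, the capture-efficiency
category counts, the bait-design mix and the per-chromosome features of the
resulting genetic map. They serve as fixed inputs for arithmetic
reproduction checks and as the default "realistic scale" for simulations.
"""

from __future__ import annotations

import pandas as pd

from capmap.filtering import CaptureAccounting

#: SNPs available for bait design, by discovery panel.
DESIGN_PANEL = {
    "ds_snps_on_dwr": 17_543,  # Dic2 x Silur SNPs on the durum transcriptome
    "ds_snps_on_bwr": 1_356,  # Dic2 x Silur SNPs on the bread wheat reference
    "ds_targeted": 4_352,  # Dic2 x Silur SNPs targeted by baits
    "epo_available": 84_710,  # pre-breeding population panel
    "epo_targeted": 1_888,
}

#: Bait-design mix: number of targets per layout type.
BAIT_MIX = {1: 3_625, 2: 508, 3: 2_107}

#: Capture-efficiency category counts (targeted loci and bonus discoveries).
CAPTURE_COUNTS = {
    "targeted": 6_240,
    "not_captured": 939,
    "monomorphic": 768,
    "het_only": 160,
    "er_clean": 2_822,
    "bonus_clean": 2_305,
    "bonus_on_targeted_contig": 895,
    "bonus_one_per_contig": 968,
}

#: Baits flagged by the tandem-microsatellite screen.
MICROSAT_FLAGGED_BAITS = 96

#: Per-chromosome features of the published genetic map.
_MAP_ROWS = [
    # chromosome, n_snps, length_cM, mean_distance_cM, biggest_gap_cM, unique_positions
    ("1A", 231, 175.5, 0.76, 18.2, 90),
    ("1B", 298, 181.4, 0.61, 11.9, 121),
    ("2A", 403, 218.3, 0.54, 12.6, 132),
    ("2B", 324, 234.9, 0.73, 13.0, 141),
    ("3A", 204, 199.6, 0.98, 13.6, 97),
    ("3B", 337, 229.7, 0.68, 14.2, 142),
    ("4A", 231, 229.3, 1.00, 21.1, 115),
    ("4B", 281, 163.7, 0.58, 18.8, 100),
    ("5A", 279, 288.2, 1.04, 15.5, 134),
    ("5B", 280, 246.4, 0.88, 12.1, 134),
    ("6A", 172, 178.2, 1.04, 11.1, 96),
    ("6B", 253, 183.4, 0.73, 20.8, 114),
    ("7A", 292, 237.6, 0.82, 12.2, 135),
    ("7B", 144, 197.3, 1.38, 20.9, 73),
]


def published_map_summary() -> pd.DataFrame:
    """The published per-chromosome map feature rows (one row per chromosome)."""
    return pd.DataFrame(
        _MAP_ROWS,
        columns=[
            "chromosome",
            "n_snps",
            "length_cM",
            "mean_distance_cM",
            "biggest_gap_cM",
            "unique_positions",
        ],
    )


def published_accounting() -> CaptureAccounting:
    """The published capture-efficiency counts as an accounting object."""
    acct = CaptureAccounting(
        targeted=CAPTURE_COUNTS["targeted"],
        not_captured=CAPTURE_COUNTS["not_captured"],
        monomorphic=CAPTURE_COUNTS["monomorphic"],
        het_only=CAPTURE_COUNTS["het_only"],
        er_clean=CAPTURE_COUNTS["er_clean"],
        bonus_clean=CAPTURE_COUNTS["bonus_clean"],
        bonus_on_targeted_contig=CAPTURE_COUNTS["bonus_on_targeted_contig"],
        bonus_one_per_contig=CAPTURE_COUNTS["bonus_one_per_contig"],
        targeted_ds=DESIGN_PANEL["ds_targeted"],
    )
    acct.validate()
    return acct


def snps_available_for_design() -> int:
    """Total SNP panel available for bait design across discovery sources."""
    return DESIGN_PANEL["ds_snps_on_dwr"] + DESIGN_PANEL["ds_snps_on_bwr"]


def snps_targeted() -> int:
    """Total targeted SNPs (= targeted contigs, one SNP per contig)."""
    return DESIGN_PANEL["ds_targeted"] + DESIGN_PANEL["epo_targeted"]
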