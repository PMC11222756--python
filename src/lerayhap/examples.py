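"""Bundled worked-example count tables.

A two-tank mock-community COI Leray metabarcoding experiment over three
hydrobiont species (the masked greenling *Hexagrammos octogrammus*, the
prickleback *Pholidapus dybowskii*, and the shrimp *Pandalus latirostris*):
per-sample sequencing totals and the ASV x sample count table produced by
reference classification + closed-reference clustering. The validation suite
recomputes this table's arithmetic (totals, species subtotals, shares)
through the same code paths used for fresh data.
"""

from __future__ import annotations

import pandas as pd

from .classify import AsvTable

# per-sample totals: sample -> (total reads, reads assigned to reference haplotypes)
SAMPLE_READ_COUNTS: dict[str, tuple[int, int]] = {
    "PD20-1": (72_592, 22_928),
    "PD20-3": (103_077, 19_395),
    "PL20-1": (100_536, 177),
    "PL20-2": (174_597, 719),
    "HO20-4": (120_273, 34_996),
    "HO20-6": (117_520, 34_129),
    "HO20-7": (91_637, 36_411),
    "RA": (198_507, 1_288),       # mock community, Vostok Bay tank
    "LA": (217_846, 10_753),      # mock community, Vityaz Bay tank
    "NEG": (1_308, 0),            # negative PCR control
}

_SAMPLES = ["PD_hap1", "PD_hap2", "HO_hap2", "HO_hap3", "PL_hap2", "HO_hap1", "PL_hap1", "LA", "RA"]

# rows: (label, species, counts over the 9 sample columns)
_ASV_ROWS: list[tuple[str, str, list[int]]] = [
    ("PD20-1 Hap-1", "P. dybowskii", [22928, 6, 0, 0, 5, 0, 0, 156, 44]),
    ("PD20-3 Hap-2", "P. dybowskii", [0, 19389, 0, 0, 0, 0, 0, 459, 336]),
    ("HO20-4 Hap-1", "H. octogrammus", [0, 0, 24, 7, 0, 34201, 23, 4252, 0]),
    ("HO20-6 Hap-2", "H. octogrammus", [0, 0, 33023, 0, 0, 19, 0, 0, 313]),
    ("HO20-7 Hap-3", "H. octogrammus", [0, 0, 0, 36392, 0, 0, 0, 0, 489]),
    ("DENOVO506", "H. octogrammus", [0, 0, 592, 0, 0, 0, 0, 0, 0]),
    ("DENOVO152", "H. octogrammus", [0, 0, 490, 0, 0, 497, 0, 9, 0]),
    ("DENOVO622", "H. octogrammus", [0, 0, 0, 5, 0, 0, 0, 0, 0]),
    ("DENOVO373", "H. octogrammus", [0, 0, 0, 0, 0, 279, 0, 6, 0]),
    ("DENOVO625", "H. octogrammus", [0, 0, 0, 7, 0, 0, 0, 0, 0]),
    ("PL20-1 Hap-1", "P. latirostris", [0, 0, 0, 0, 0, 0, 154, 7, 0]),
    ("PL20-2 Hap-2", "P. latirostris", [0, 0, 0, 0, 714, 0, 0, 5773, 106]),
    ("DENOVO1386", "P. latirostris", [0, 0, 0, 0, 0, 0, 0, 21, 0]),
    ("DENOVO3056", "P. latirostris", [0, 0, 0, 0, 0, 0, 0, 6, 0]),
    ("DENOVO3088", "P. latirostris", [0, 0, 0, 0, 0, 0, 0, 15, 0]),
    ("DENOVO3101", "P. latirostris", [0, 0, 0, 0, 0, 0, 0, 9, 0]),
    ("DENOVO3138", "P. latirostris", [0, 0, 0, 0, 0, 0, 0, 10, 0]),
    ("DENOVO3142", "P. latirostris", [0, 0, 0, 0, 0, 0, 0, 22, 0]),
    ("DENOVO3143", "P. latirostris", [0, 0, 0, 0, 0, 0, 0, 8, 0]),
]


def example_asv_table() -> AsvTable:
    """The worked-example ASV x sample table as an AsvTable."""
    df = pd.DataFrame(
        {label: dict(zip(_SAMPLES, row)) for label, _, row in _ASV_ROWS}
    ).T.astype(int)
    df.insert(0, "species", [sp for _, sp, _ in _ASV_ROWS])
    return AsvTable(df)


def total_reads() -> int:
    return sum(t for t, _ in SAMPLE_READ_COUNTS.values())


def negative_control_share_pct() -> float:
    return round(100 * SAMPLE_READ_COUNTS["NEG"][0] / total_reads(), 1)
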