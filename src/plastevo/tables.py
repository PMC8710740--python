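"""Packaged reference tables for the monogenomic Triticeae plastome set.

Two small published summary tables ship with the package so the statistical
battery can run without any sequence download:

* a genome-size table for 33 monogenomic Triticeae chloroplast genomes
  (total / non-protein-coding / protein-coding bp, grouped into the four
  maternal clades), and
* a per-node table for the 33 divergence nodes of the corresponding
  time-calibrated phylogeny (node age in MYA, cumulative indel count, and a
  node-associated genome size in bp; two nodes have no indel count).
"""

from __future__ import annotations

import math

from .plastome import SizeRecord

# species, clade, total_bp, noncoding_bp, coding_bp
_SIZE_ROWS = [
    ("Aegilops_bicornis", "I", 136861, 77543, 59318),
    ("Aegilops_longissima", "I", 136875, 77557, 59318),
    ("Aegilops_markgrafii", "I", 136063, 76745, 59318),
    ("Aegilops_searsii", "I", 136870, 77552, 59318),
    ("Aegilops_sharonensis", "I", 136867, 77549, 59318),
    ("Aegilops_speltoides", "I", 135652, 76334, 59318),
    ("Aegilops_speltoides_ligustica", "I", 135660, 76343, 59317),
    ("Aegilops_tauschii", "I", 135568, 76250, 59318),
    ("Aegilops_umbellulata", "I", 136028, 76710, 59318),
    ("Aegilops_umbellulata_transcaucasica", "I", 136031, 76713, 59318),
    ("Amblyopyrum_muticum", "I", 135787, 77485, 58302),
    ("Secale_cereale", "I", 135564, 77109, 58455),
    ("Taeniatherum_caput-medusae", "I", 136861, 77537, 59324),
    ("Triticum_monococcum", "I", 136886, 77568, 59318),
    ("Triticum_monococcum_aegilopoides", "I", 136870, 75821, 61049),
    ("Triticum_urartu", "I", 136865, 77547, 59318),
    ("Crithopsis_delileana", "I", 136436, 77109, 59327),
    ("Heteranthelium_piliferum", "I", 136768, 77490, 59278),
    ("Pseudoroegneria_libanotica", "II", 135026, 75711, 59315),
    ("Pseudoroegneria_spicata", "II", 135165, 75854, 59311),
    ("Dasypyrum_villosum", "II", 135249, 75877, 59372),
    ("Lophopyrum_elongatum", "II", 135020, 75707, 59313),
    ("Thinopyrum_bessarabicum", "II", 135003, 75694, 59309),
    ("Agropyron_cristatum", "III", 135554, 76251, 59303),
    ("Agropyron_mongolicum", "III", 135547, 76244, 59303),
    ("Australopyrum_retrofractum", "III", 135417, 76114, 59303),
    ("Eremopyrum_distans", "III", 135589, 76248, 59341),
    ("Eremopyrum_tririceum", "III", 135554, 76283, 59271),
    ("Henradia_persica", "III", 135659, 76353, 59306),
    ("Hordeum_bogdanii", "IV", 136968, 77672, 59296),
    ("Hordeum_jubatum", "IV", 136826, 77466, 59360),
    ("Hordeum_vulgare", "IV", 136462, 77153, 59309),
    ("Hordeum_vulgare_spontaneum", "IV", 136043, 76945, 59098),
]

# node, divergence_time (MYA), indel_count (None = not reported), cp_size (bp)
_NODE_ROWS = [
    (1, 0.66, 28, 136030),
    (2, 0.65, 77, 135925),
    (3, 0.84, 115, 135977),
    (4, 1.67, 182, 136423),
    (5, 0.03, None, 136873),
    (6, 0.33, 14, 136871),
    (7, 1.12, 20, 136868),
    (8, 2.10, 258, 136328),
    (9, 7.85, 413, 136464),
    (10, 0.13, 122, 136878),
    (11, 0.41, 156, 136874),
    (12, 8.12, 513, 136383),
    (13, 0.12, None, 135656),
    (14, 2.22, 143, 136058),
    (15, 8.98, 625, 136332),
    (16, 12.40, 656, 136338),
    (17, 12.71, 780, 136362),
    (18, 2.27, 71, 135012),
    (19, 3.19, 178, 135091),
    (20, 3.89, 190, 135075),
    (21, 12.62, 226, 135093),
    (22, 20.49, 977, 136086),
    (23, 0.85, 39, 135551),
    (24, 13.00, 190, 135561),
    (25, 4.70, 101, 135572),
    (26, 13.29, 269, 135532),
    (27, 17.16, 360, 135553),
    (28, 21.18, 1239, 135976),
    (29, 8.70, 51, 136253),
    (30, 6.37, 139, 136804),
    (31, 15.09, 343, 136528),
    (32, 27.03, 1568, 136043),
    (33, 27.63, 1702, 136059),
]

OUTGROUP_SPECIES = "Brachypodium_distachyon"
OUTGROUP_SIZE_BP = 135199
CROWN_AGE_MYA = 27.63


def triticeae_size_table() -> list[SizeRecord]:
    """The 33-genome Triticeae size table as SizeRecord objects."""
    return [
        SizeRecord(species=sp, clade=cl, total_bp=t, coding_bp=c, noncoding_bp=n)
        for sp, cl, t, n, c in _SIZE_ROWS
    ]


def triticeae_node_table():
    """The 33-node divergence table as a DataFrame.

    Columns: node, divergence_time (MYA), indel_count (NaN where not
    reported), cp_size (bp).
    """
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "node": n,
                "divergence_time": t,
                "indel_count": float("nan") if c is None else float(c),
                "cp_size": s,
            }
            for n, t, c, s in _NODE_ROWS
        ]
    )


def table_fixtures():
    """(size table, node table) in one call."""
    return triticeae_size_table(), triticeae_node_table()
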