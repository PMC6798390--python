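"""Published summary statistics for the seven i5k pilot insect species.

These are the printed per-species gene-set sizes and set-wide medians of
the i5k pilot-project annotation comparison (automatic MAKER sets vs.
official gene sets): assembly sizes, AUTO/OGS/AUTO-SUB/MAN-SUB/MAN-ADD
counts, and the AUTO-SUB/MAN-SUB medians of transcript length, protein
length, exon count, and per-transcript exon/intron-length medians.  They
serve as worked-example inputs for the accounting and differencing
operations; they are inputs, not values this package computes.
"""

from __future__ import annotations

import pandas as pd

SPECIES = [
    "A_glabripennis",
    "L_decemlineata",
    "A_rosae",
    "O_abietinus",
    "C_lectularius",
    "O_fasciatus",
    "F_occidentalis",
]

# columns follow SPECIES order
GENE_SET_COUNTS = pd.DataFrame(
    {
        "A_glabripennis": {"AUTO": 22253, "OGS": 22035, "AUTO-SUB": 749, "MAN-SUB": 770, "MAN-ADD": 216},
        "L_decemlineata": {"AUTO": 24732, "OGS": 24671, "AUTO-SUB": 972, "MAN-SUB": 933, "MAN-ADD": 98},
        "A_rosae": {"AUTO": 11956, "OGS": 11894, "AUTO-SUB": 805, "MAN-SUB": 825, "MAN-ADD": 50},
        "O_abietinus": {"AUTO": 10966, "OGS": 10959, "AUTO-SUB": 659, "MAN-SUB": 670, "MAN-ADD": 30},
        "C_lectularius": {"AUTO": 14085, "OGS": 13953, "AUTO-SUB": 795, "MAN-SUB": 778, "MAN-ADD": 221},
        "O_fasciatus": {"AUTO": 19587, "OGS": 19615, "AUTO-SUB": 1013, "MAN-SUB": 945, "MAN-ADD": 161},
        "F_occidentalis": {"AUTO": 18021, "OGS": 17553, "AUTO-SUB": 1118, "MAN-SUB": 1127, "MAN-ADD": 381},
    }
)[SPECIES]

# set-wide medians per species: {property: {subset: {species: value}}}
SUBSET_MEDIANS = {
    "median_transcript_length_bp": {
        "AUTO-SUB": {
            "A_glabripennis": 6183.0,
            "L_decemlineata": 8562.5,
            "A_rosae": 4340.0,
            "O_abietinus": 5200.0,
            "C_lectularius": 4362.0,
            "O_fasciatus": 9324.0,
            "F_occidentalis": 5001.5,
        },
        "MAN-SUB": {
            "A_glabripennis": 5789.5,
            "L_decemlineata": 9280.0,
            "A_rosae": 3208.0,
            "O_abietinus": 3996.0,
            "C_lectularius": 4360.0,
            "O_fasciatus": 11244.0,
            "F_occidentalis": 4064.0,
        },
    },
    "median_protein_length_aa": {
        "AUTO-SUB": {
            "A_glabripennis": 358.0,
            "L_decemlineata": 255.0,
            "A_rosae": 445.0,
            "O_abietinus": 430.0,
            "C_lectularius": 358.0,
            "O_fasciatus": 257.0,
            "F_occidentalis": 419.5,
        },
        "MAN-SUB": {
            "A_glabripennis": 389.0,
            "L_decemlineata": 300.0,
            "A_rosae": 423.0,
            "O_abietinus": 419.0,
            "C_lectularius": 372.5,
            "O_fasciatus": 320.0,
            "F_occidentalis": 419.0,
        },
    },
    "median_exon_count": {
        "AUTO-SUB": {
            "A_glabripennis": 4.0,
            "L_decemlineata": 4.0,
            "A_rosae": 6.0,
            "O_abietinus": 5.0,
            "C_lectularius": 5.0,
            "O_fasciatus": 4.0,
            "F_occidentalis": 6.0,
        },
        "MAN-SUB": {
            "A_glabripennis": 4.0,
            "L_decemlineata": 4.0,
            "A_rosae": 5.0,
            "O_abietinus": 5.5,
            "C_lectularius": 5.0,
            "O_fasciatus": 4.0,
            "F_occidentalis": 6.0,
        },
    },
    "median_median_exon_length_bp": {
        "AUTO-SUB": {
            "A_glabripennis": 1210.0,
            "L_decemlineata": 984.0,
            "A_rosae": 2220.0,
            "O_abietinus": 2151.0,
            "C_lectularius": 1200.0,
            "O_fasciatus": 1086.0,
            "F_occidentalis": 1807.5,
        },
        "MAN-SUB": {
            "A_glabripennis": 1345.5,
            "L_decemlineata": 1127.0,
            "A_rosae": 1786.0,
            "O_abietinus": 1828.0,
            "C_lectularius": 1194.5,
            "O_fasciatus": 1347.0,
            "F_occidentalis": 1755.0,
        },
    },
    "median_median_intron_length_bp": {
        "AUTO-SUB": {
            "A_glabripennis": 354.75,
            "L_decemlineata": 1192.0,
            "A_rosae": 107.5,
            "O_abietinus": 1278.25,
            "C_lectularius": 75.0,
            "O_fasciatus": 126.75,
            "F_occidentalis": 108.0,
        },
        "MAN-SUB": {
            "A_glabripennis": 359.0,
            "L_decemlineata": 1363.0,
            "A_rosae": 100.5,
            "O_abietinus": 1434.0,
            "C_lectularius": 74.0,
            "O_fasciatus": 123.0,
            "F_occidentalis": 100.75,
        },
    },
}


def subset_median_series(property_name: str, subset: str) -> pd.Series:
    return pd.Series(SUBSET_MEDIANS[property_name][subset], name=f"{subset}:{property_name}")
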