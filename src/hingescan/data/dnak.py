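"""Literature reference values for E. coli DnaK's nucleotide-binding domain.

These are published survey numbers for DnaK/Hsp70, shipped as inputs for the
filtering stages (the conservation filter and candidate selection operate on
printed percentages, not on raw databases) and as oracles for tests.
"""

# Residue name by number for the II-A/II-B hinge-region table below.
DNAK_HINGE_REGION_NAMES = {
    202: "I", 203: "S", 217: "E", 220: "A", 221: "T", 222: "N", 223: "G",
    224: "D", 225: "T", 226: "H", 227: "L", 228: "G", 229: "G", 230: "E",
}

# Per-residue (identity %, conservative-substitution %) by taxon group from a
# published Hsp70 ortholog survey (1714 bacterial, 1388 animal, 597 plant
# sequences), for the II-A/II-B hinge region of DnaK.
DNAK_HINGE_CONSERVATION: dict[int, dict[str, tuple[float, float]]] = {
    202: {"bacteria": (31, 64), "animals": (5, 90), "plants": (5, 83)},
    203: {"bacteria": (90, 9), "animals": (92, 7), "plants": (86, 10)},
    217: {"bacteria": (77, 16), "animals": (87, 9), "plants": (79, 12)},
    220: {"bacteria": (55, 41), "animals": (48, 51), "plants": (59, 39)},
    221: {"bacteria": (83, 13), "animals": (94, 4), "plants": (88, 5)},
    222: {"bacteria": (41, 41), "animals": (14, 11), "plants": (17, 22)},
    223: {"bacteria": (98, 1), "animals": (91, 1), "plants": (83, 1)},
    224: {"bacteria": (83, 11), "animals": (94, 4), "plants": (91, 5)},
    225: {"bacteria": (50, 41), "animals": (89, 2), "plants": (82, 3)},
    226: {"bacteria": (36, 18), "animals": (83, 4), "plants": (82, 4)},
    227: {"bacteria": (97, 2), "animals": (96, 3), "plants": (92, 7)},
    228: {"bacteria": (99, 1), "animals": (99, 0), "plants": (98, 1)},
    229: {"bacteria": (100, 0), "animals": (99, 0), "plants": (99, 1)},
    230: {"bacteria": (30, 64), "animals": (87, 8), "plants": (68, 27)},
}

# Residues with multiple phi-psi clusters reported for DnaK NBD Langevin
# dynamics ensembles, by subdomain.
DNAK_MULTIMODAL_RESIDUES: dict[str, tuple[int, ...]] = {
    "I-A": (13, 14, 20),
    "I-B": (51, 67, 68, 73, 74, 83, 84, 85, 104, 105),
    "II-A": (183, 184, 185, 186, 195, 198, 199, 202, 203, 222, 223, 227,
             228, 229, 340, 341, 342, 363),
    "II-B": (281, 288, 289),
}

# Residues reported significantly correlated to nucleotide motion (top-60 by
# |correlation| in at least 4 of 10 nucleotide-bound trajectories).
DNAK_TALLY_SIGNIFICANT: dict[str, tuple[int, ...]] = {
    "I-A": (8, 15, 33, 37, 38, 143, 144, 145),
    "I-B": (39, 51, 66, 68, 72),
    "II-A": (194, 195, 200, 223, 225, 228, 229, 230, 339, 344, 346, 347, 349),
    "II-B": (265, 268, 269, 274),
}

# Published per-state ensemble means of the II-B <-> I-A/B + II-A CA COM
# distance (Angstrom), used to seed the synthetic openness defaults and to
# check the open/closed classifier.
DNAK_OPENNESS_MEANS = {"apo": 31.9, "ATP": 27.3, "ADP_Pi": 26.1}


def all_multimodal() -> set[int]:
    return {r for rs in DNAK_MULTIMODAL_RESIDUES.values() for r in rs}


def all_tally_significant() -> set[int]:
    return {r for rs in DNAK_TALLY_SIGNIFICANT.values() for r in rs}
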