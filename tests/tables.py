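"""Replay fixtures: the three published per-family top-five tables.

Scores are synthetic stand-ins chosen only to reproduce the printed gene
ORDER and tie pattern (the published connection/likelihood scores themselves
are not needed: the scoring arithmetic consumes ranks, not raw scores).
Carrier lists and expected totals are the published ones.
"""

# family 1: five children 25-29; ranks 1,2,3,3(tie),5
FAMILY1_SCORES = [
    ("FAM8A1", 100.0, 100.0),
    ("ACADS", 90.0, 90.0),
    ("KRT76", 80.0, 80.0),
    ("HLA-DRB1", 80.0, 80.0),
    ("TTBK2", 70.0, 70.0),
]
FAMILY1_CARRIERS = [
    ("FAM8A1", "26"), ("FAM8A1", "28"),
    ("ACADS", "26"),
    ("KRT76", "29"),
    ("HLA-DRB1", "25"),
    ("TTBK2", "27"), ("TTBK2", "29"),
]
FAMILY1_CHILDREN = ("25", "26", "27", "28", "29")
FAMILY1_EXPECTED_TOTALS = {"25": 3.0, "26": 6.5, "27": 0.5, "28": 2.5, "29": 3.5}

# family 2: four children 32-35; ranks 1,2,3,3(tie),5
FAMILY2_SCORES = [
    ("FAM8A1", 100.0, 100.0),
    ("TRPM3", 90.0, 90.0),
    ("PAH", 80.0, 80.0),
    ("PCK1", 80.0, 80.0),
    ("PCK2", 70.0, 70.0),
]
FAMILY2_CARRIERS = [
    ("FAM8A1", "35"),
    ("TRPM3", "35"),
    ("PAH", "34"), ("PAH", "35"),
    ("PCK1", "33"),
    ("PCK2", "33"),
]
FAMILY2_CHILDREN = ("32", "33", "34", "35")
FAMILY2_EXPECTED_TOTALS = {"32": 0.0, "33": 4.0, "34": 1.5, "35": 10.5}

# family 3: seven children 38-44; ranks 1..5, no ties
FAMILY3_SCORES = [
    ("TNNT3", 100.0, 100.0),
    ("SIRPB1", 90.0, 90.0),
    ("TRMT1", 80.0, 80.0),
    ("ITGB4", 70.0, 70.0),
    ("DCHS1", 60.0, 60.0),
]
FAMILY3_CARRIERS = [
    ("TNNT3", "43"),
    ("SIRPB1", "41"),
    ("TRMT1", "44"),
    ("ITGB4", "43"),
    ("DCHS1", "42"),
]
FAMILY3_CHILDREN = ("38", "39", "40", "41", "42", "43", "44")
FAMILY3_EXPECTED_TOTALS = {
    "38": 0.0, "39": 0.0, "40": 0.0, "41": 4.0, "42": 1.0, "43": 7.0, "44": 3.0,
}

# blinded-evaluation truth: the child actually diagnosed, per family
REVEALED_DIAGNOSES = {"family1": "25", "family2": "35", "family3": "41"}
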