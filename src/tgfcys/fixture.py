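"""Packaged study fixture: the 33-protein human family plus GDNF outgroup.

The fixture transcribes the published coordinates of the conserved-cysteine
census, the cysteine disease-mutation catalog, and the partner-protein
domain facts into machine-readable tables, and embeds them in *synthetic*
scaffold sequences: real precursor sequences are not redistributed here, so
each precursor is a deterministic pseudo-random non-cysteine background with
cysteines (and mutation reference residues) planted at the documented
precursor positions, and the prodomain alignment is laid out so that every
documented position falls in the correct region column.  Quantities the
pipeline computes from the fixture — census counts, mutated-position counts,
heterodimer and partner-edge counts, cysteine spacings — therefore rest on
the transcribed coordinates, not on the scaffold filler.

Rows whose positions are documented verbatim carry provenance
``results-text``; rows that are only constrained by table-level totals
(per-subfamily census membership, unnamed partner mutations) carry
``table-transcription`` and are auditable as reconstructions.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .conservation import GAP, Alignment, RegionWindow, SimilarityScheme
from .mutation_catalog import MutationRecord, records_from_frame
from .partner_domains import PartnerDomain
from .sequence_prep import ProteinRecord, extract_prodomain

__all__ = ["StudyFixture", "load_study_fixture", "build_fixture", "fixture_dir"]

# ---------------------------------------------------------------------------
# Alignment geometry.  The Association (Assn) block occupies columns
# CA..CA+3 and the beta-8 block columns CB..CB+3; each row right-aligns its
# amino-terminal segment against the Assn block and left-aligns the rest, so
# every documented precursor position lands in its region column.
CA = 70
CB = 305
WIDTH = 370
ASSN_WINDOW = (CA, CA + 3)
B8_WINDOW = (CB, CB + 3)

N_FAMILY = 33

# Label -> (block, offset) in alignment columns.
_SLOTS = {"A1": ("A", 0), "A4": ("A", 3), "B1": ("B", 0), "B3": ("B", 2), "B4": ("B", 3)}
_LABEL_NAME = {"A1": "CYS@1", "A4": "CYS@4", "B1": "CYS@1", "B3": "CYS@3", "B4": "CYS@4"}
_REGION = {"A": "ASSN", "B": "B8"}

# ---------------------------------------------------------------------------
# Family table: id, subfamily, signal length, Assn anchor position (precursor
# position of the residue in column CA), beta-8 anchor position (column CB),
# cleavage position, precursor length, conserved-cysteine slots held, and
# additional planted residues (documented mutation reference residues).
#
# Census constraints honoured exactly: 21 proteins with >=1 beta-8 cysteine
# (13 BMP / 4 Activin / 4 TGF-beta), 16 with >=1 Assn cysteine (5 / 6 / 5),
# 24 distinct proteins overall (13 / 6 / 5 per subfamily); AssnCys@4 is
# carried by the four INHBs plus MSTN and GDF11; GDNF is an outgroup row.
_FAM = [
    # id        subfam      s   posA posB cleav len  slots                     extras
    ("TGFB1", "TGF-beta", 29, 33, 223, 278, 390, ("A1", "B1", "B3"), {}),
    ("TGFB2", "TGF-beta", 20, 24, 254, 302, 442, ("A1", "B1", "B3", "B4"),
     {246: "C", 378: "C", 407: "C", 439: "C"}),
    ("TGFB3", "TGF-beta", 23, 27, 226, 280, 412, ("A1", "B1", "B3"), {409: "C"}),
    ("AMH", "TGF-beta", 18, 22, 208, 250, 360, ("A1", "B1"), {}),
    ("NODAL", "TGF-beta", 26, 30, 240, 280, 347, ("A1",), {}),
    ("GDF15", "TGF-beta", 29, 35, 200, 240, 308, (), {}),
    ("LEFTY1", "TGF-beta", 21, 26, 230, 270, 366, (), {}),
    ("LEFTY2", "TGF-beta", 21, 26, 232, 272, 366, (), {}),
    ("INHA", "Activin", 24, 30, 230, 260, 366, (), {291: "C"}),
    ("INHBA", "Activin", 28, 41, 244, 300, 426, ("A1", "A4", "B1", "B4"), {}),
    ("INHBB", "Activin", 28, 92, 241, 292, 407, ("A1", "A4", "B1", "B4"),
     {154: "S", 223: "R"}),
    ("INHBC", "Activin", 22, 28, 236, 280, 352, ("A1", "A4", "B1", "B4"), {}),
    ("INHBE", "Activin", 22, 26, 232, 278, 350, ("A1", "A4", "B1", "B4"), {}),
    ("MSTN", "Activin", 23, 40, 235, 266, 375, ("A1", "A4"), {}),
    ("GDF11", "Activin", 24, 76, 240, 298, 407, ("A1", "A4"), {}),
    ("GDF3", "Activin", 23, 29, 238, 250, 364, (), {}),
    ("BMP2", "BMP", 23, 30, 246, 282, 396, ("A1", "B3"), {}),
    ("BMP3", "BMP", 24, 30, 238, 270, 384, (), {}),
    ("BMP4", "BMP", 24, 32, 248, 292, 408, ("A1", "B3"), {}),
    ("BMP5", "BMP", 28, 36, 239, 280, 420, ("B3",), {}),
    ("BMP6", "BMP", 26, 34, 251, 296, 420, ("A1", "B3"), {}),
    ("BMP7", "BMP", 29, 31, 249, 292, 431, ("A1", "B1"), {}),
    ("BMP8A", "BMP", 27, 33, 244, 280, 402, (), {}),
    ("BMP8B", "BMP", 27, 33, 245, 281, 402, (), {}),
    ("BMP10", "BMP", 21, 27, 245, 290, 424, ("B1",), {}),
    ("BMP15", "BMP", 25, 31, 206, 268, 392, ("B4",), {}),
    ("GDF1", "BMP", 26, 32, 224, 252, 372, ("B4",), {}),
    ("GDF2", "BMP", 22, 25, 234, 274, 390, ("A1", "B4"), {}),
    ("GDF5", "BMP", 27, 33, 252, 300, 460, ("B4",), {438: "R"}),
    ("GDF6", "BMP", 22, 28, 227, 280, 455, ("B4",), {419: "C"}),
    ("GDF7", "BMP", 28, 34, 256, 298, 450, ("B4",), {}),
    ("GDF9", "BMP", 29, 35, 242, 303, 360, ("B1",), {}),
    ("GDF10", "BMP", 25, 31, 240, 276, 388, (), {}),
    ("GDNF", "outgroup", 19, 35, 200, 230, 300, ("A1", "A4"), {}),
]

# ---------------------------------------------------------------------------
# Family mutation catalog (protein, position, ref, alt, phenotype, source,
# near_region, provenance).  near_region flags cysteine gains judged
# structurally close to a conserved region.
_FAMILY_MUTATIONS = [
    ("BMP15", 209, "C", "G", "Lung squamous cell neoplasms", "GDC", 0, "results-text"),
    ("GDF1", 227, "C", "del:145", "Right atrial isomerism", "GDC", 0, "results-text"),
    ("GDF6", 230, "C", "R", "Colon adenocarcinoma", "GDC", 0, "results-text"),
    ("GDF6", 419, "C", "Y", "Colon adenocarcinoma", "GDC", 0, "results-text"),
    ("GDF5", 438, "R", "C", "colon adenocarcinoma", "GDC", 1, "results-text"),
    ("INHBA", 244, "C", "Y", "Lung adenocarcinoma", "GDC", 0, "results-text"),
    ("TGFB1", 223, "C", "R", "Camurati-Engelmann disease", "MalaCards", 0, "results-text"),
    ("TGFB1", 223, "C", "G", "Camurati-Engelmann disease", "MalaCards", 0, "results-text"),
    ("TGFB1", 223, "C", "S", "Camurati-Engelmann disease", "MalaCards", 0, "results-text"),
    ("TGFB1", 225, "C", "R", "Camurati-Engelmann disease", "MalaCards", 0, "results-text"),
    ("TGFB1", 225, "C", "Y", "Camurati-Engelmann disease", "MalaCards", 0, "results-text"),
    ("INHBE", 29, "C", "Y", "Plasma cell tumors", "GDC", 0, "results-text"),
    ("INHBB", 154, "S", "C", "plasma cell tumors", "GDC", 1, "results-text"),
    ("TGFB2", 256, "C", "*", "Endometrial adenocarcinoma", "GDC", 0, "results-text"),
    ("INHA", 291, "C", "W", "endometrial adenocarcinoma", "GDC", 0, "results-text"),
    ("INHBB", 223, "R", "C", "endometrial adenomas", "GDC", 1, "results-text"),
    ("TGFB2", 257, "C", "F", "Holt-Oram syndrome", "GDC", 0, "results-text"),
    ("TGFB2", 378, "C", "Y", "Holt-Oram syndrome", "GDC", 0, "results-text"),
    ("TGFB2", 257, "C", "*", "Loeys-Dietz syndrome", "GDC", 0, "results-text"),
    ("TGFB2", 439, "C", "S", "Loeys-Dietz syndrome", "GDC", 0, "results-text"),
    ("TGFB3", 409, "C", "Y", "Loeys-Dietz syndrome", "GDC", 0, "results-text"),
    ("TGFB2", 246, "C", "Y", "Lung adenocarcinoma", "GDC", 0, "results-text"),
    ("TGFB2", 407, "C", "S", "Lung adenocarcinoma", "GDC", 0, "results-text"),
]

# ---------------------------------------------------------------------------
# Partner proteins: id, length, domains (kind, ordinal, start, end),
# cysteine positions to plant (documented ones plus canonical domain fills).
_PARTNERS = [
    ("LTBP1", 1450,
     [("TB8CYS", 1, 540, 600), ("EGF", 7, 1000, 1040), ("TB8CYS", 3, 1330, 1392)],
     # TB1: mutated cysteines 559 (1st) and 594 (6th); TB3: the TGFB1-binding
     # pair 1359 (2nd) and 1384 (6th), 25 residues apart.
     [559, 566, 571, 577, 586, 594, 597, 599,
      1005, 1012, 1018, 1022, 1029, 1036,
      1337, 1359, 1366, 1371, 1377, 1384, 1388, 1390]),
    ("LTBP2", 1200,
     [("TB8CYS", 1, 300, 360), ("EGF", 5, 400, 440), ("EGF", 9, 600, 640),
      ("EGF", 14, 830, 870), ("TB8CYS", 3, 990, 1050)],
     [305, 312, 318, 330, 336, 342, 350, 356,
      404, 410, 416, 422, 428, 434,
      604, 612, 618, 624, 630, 636,
      834, 840, 845, 852, 858, 864,
      995, 1002, 1010, 1018, 1026, 1034, 1042, 1048]),
    ("LTBP3", 1300,
     [("TB8CYS", 3, 1200, 1260)],
     [1205, 1212, 1215, 1222, 1230, 1238, 1246, 1254]),
    ("LTBP4", 1400,
     [("TB8CYS", 3, 1290, 1350)],
     [1295, 1302, 1308, 1315, 1323, 1331, 1339, 1346]),
    ("FBN1", 2000,
     [("EGF", 8, 470, 510), ("EGF", 24, 1410, 1450), ("EGF", 28, 1670, 1710),
      ("TB8CYS", 6, 1830, 1890)],
     [474, 480, 487, 493, 499, 505,
      1414, 1420, 1426, 1431, 1438, 1444,
      1674, 1680, 1687, 1693, 1699, 1705,
      1835, 1842, 1849, 1856, 1863, 1870, 1877, 1884,
      720, 1120, 1530, 1760, 1900, 1950]),
    ("FBN2", 1700,
     [("EGF", 16, 1180, 1220), ("EGF", 22, 1370, 1410), ("TB8CYS", 6, 1560, 1620)],
     # EGF-22 mutated cysteines 1378/1406 are 28 apart; TB6 mutated
     # cysteines 1579/1608 are 29 apart.
     [1184, 1193, 1199, 1205, 1211, 1217,
      1374, 1378, 1385, 1392, 1399, 1406,
      1565, 1572, 1579, 1587, 1595, 1601, 1608, 1615,
      602, 890, 1240, 1335]),
    ("FBN3", 1620,
     [("EGF", 2, 130, 170), ("EGF", 20, 1080, 1120), ("TB8CYS", 6, 1490, 1550)],
     [134, 142, 148, 154, 160, 166,
      1084, 1090, 1096, 1101, 1108, 1114,
      1495, 1502, 1510, 1519, 1527, 1534, 1541, 1548,
      260, 770, 950, 1450, 1575]),
    ("LRC32", 420,
     [("LRR", 7, 205, 230), ("LRR", 12, 330, 355)],
     # The TGFB1-binding cysteines 211/350 are 139 residues apart; LRR-12
     # holds only Cys342 and Cys350.
     [211, 342, 350]),
    ("LRC33", 400, [("LRR", 10, 280, 305)], [290]),
    ("SELE", 610, [("SUSHI", 5, 500, 560)], [505, 512, 520, 528, 536, 544]),
]

_PARTNER_MUTATIONS = [
    # plasma-cell tumors: 11 cysteine losses across LTBP1 + FBN1-3
    ("LTBP1", 1022, "C", "Y", "plasma cell tumors", "GDC", "results-text"),
    ("FBN1", 1431, "C", "Y", "plasma cell tumors", "GDC", "results-text"),
    ("FBN1", 1687, "C", "F", "plasma cell tumors", "GDC", "results-text"),
    ("FBN2", 1193, "C", "S", "plasma cell tumors", "GDC", "table-transcription"),
    ("FBN2", 1378, "C", "S", "plasma cell tumors", "GDC", "table-transcription"),
    ("FBN2", 1406, "C", "F", "plasma cell tumors", "GDC", "results-text"),
    ("FBN2", 1579, "C", "G", "plasma cell tumors", "GDC", "results-text"),
    ("FBN2", 1608, "C", "Y", "plasma cell tumors", "GDC", "results-text"),
    ("FBN3", 142, "C", "R", "plasma cell tumors", "GDC", "table-transcription"),
    ("FBN3", 1101, "C", "Y", "plasma cell tumors", "GDC", "table-transcription"),
    ("FBN3", 1519, "C", "R", "plasma cell tumors", "GDC", "results-text"),
    # colon adenocarcinoma: 5 partner proteins
    ("LTBP1", 559, "C", "Y", "colon adenocarcinoma", "GDC", "results-text"),
    ("LTBP1", 594, "C", "W", "colon adenocarcinoma", "GDC", "results-text"),
    ("LTBP2", 330, "C", "R", "colon adenocarcinoma", "GDC", "table-transcription"),
    ("FBN1", 480, "C", "Y", "colon adenocarcinoma", "GDC", "table-transcription"),
    ("FBN1", 1120, "C", "S", "colon adenocarcinoma", "GDC", "table-transcription"),
    ("FBN1", 1900, "C", "F", "colon adenocarcinoma", "GDC", "table-transcription"),
    ("FBN2", 602, "C", "W", "colon adenocarcinoma", "GDC", "table-transcription"),
    ("FBN2", 890, "C", "Y", "colon adenocarcinoma", "GDC", "table-transcription"),
    ("FBN2", 1406, "C", "S", "colon adenocarcinoma", "GDC", "results-text"),
    ("FBN3", 260, "C", "Y", "colon adenocarcinoma", "GDC", "table-transcription"),
    ("FBN3", 770, "C", "S", "colon adenocarcinoma", "GDC", "table-transcription"),
    ("FBN3", 1450, "C", "R", "colon adenocarcinoma", "GDC", "table-transcription"),
    # endometrial adenocarcinoma: 8 partner proteins
    ("LTBP1", 1337, "C", "R", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    ("LTBP2", 410, "C", "Y", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    ("LTBP2", 612, "C", "S", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    ("LTBP2", 845, "C", "F", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    ("LTBP2", 1010, "C", "R", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    ("LTBP3", 1215, "C", "S", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    ("LRC32", 342, "C", "R", "endometrial adenocarcinoma", "GDC", "results-text"),
    ("SELE", 520, "C", "G", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    ("FBN1", 720, "C", "Y", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    ("FBN1", 1530, "C", "S", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    ("FBN1", 1760, "C", "W", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    ("FBN1", 1950, "C", "R", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    ("FBN2", 1240, "C", "Y", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    ("FBN2", 1335, "C", "S", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    ("FBN3", 950, "C", "F", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    ("FBN3", 1575, "C", "Y", "endometrial adenocarcinoma", "GDC", "table-transcription"),
    # Loeys-Dietz: one fibrillin cysteine shared with the TGFB2/TGFB3 group
    ("FBN1", 1431, "C", "W", "Loeys-Dietz syndrome", "GDC", "results-text"),
]

_SYNONYMS = {
    "endometrial adenomas": "endometrial adenocarcinoma",
    "endometrial adenocarcinomas": "endometrial adenocarcinoma",
    "colon adenocarcinomas": "colon adenocarcinoma",
    "plasma cell tumor": "plasma cell tumors",
}

#: Previously demonstrated interactions (suppressed from "novel" counts).
_KNOWN_INTERACTIONS = [
    ("TGFB1", "TGFB1"),
    ("INHA", "INHBB"),
    ("TGFB1", "LTBP1"),
    ("TGFB1", "LTBP3"),
    ("TGFB1", "LTBP4"),
    ("TGFB1", "LRC32"),
    ("TGFB1", "LRC33"),
]

#: Documented reference cysteine pairs for spacing comparisons.
_REFERENCE_PAIRS = {
    "LTBP1_TB3_TGFB1_binding": (1359, 1384),  # 25 residues apart
    "LTBP1_TB1_mutated": (559, 594),  # 35 residues apart
    "LRC32_TGFB1_binding": (211, 350),  # 139 residues apart
    "FBN2_TB6_mutated": (1579, 1608),
    "FBN2_EGF22_mutated": (1378, 1406),  # 28 residues apart
}


# ---------------------------------------------------------------------------
# Domain alignments for the docking-site comparison.  Column plan for the
# TB alignment (LTBP1 TB3 as reference vs FBN1-3 TB6): eight shared cysteine
# columns; a two-residue FP insertion unique to LTBP1 between cysteines 6
# and 7; two acidic columns conserved in all rows, three acidic in LTBP1
# only, three acidic in all fibrillins only.
def _build_tb_dock_rows() -> list[tuple[str, str]]:
    width = 48
    cys_cols = [2, 7, 13, 18, 23, 33, 40, 46]
    green = {12: "D", 42: "E"}  # acidic in all four rows
    purple = {5: "E", 17: "D", 39: "D"}  # acidic in LTBP1 only
    blue = {8: "D", 20: "E", 36: "D"}  # acidic in fibrillins only
    fp = {34: "F", 35: "P"}
    fillers = {"LTBP1_TB3": "G", "FBN1_TB6": "S", "FBN2_TB6": "T", "FBN3_TB6": "N"}
    rows = []
    for rid, filler in fillers.items():
        chars = []
        for col in range(1, width + 1):
            if col in fp:
                chars.append(fp[col] if rid == "LTBP1_TB3" else GAP)
            elif col in cys_cols:
                chars.append("C")
            elif col in green:
                chars.append(green[col])
            elif col in purple:
                chars.append(purple[col] if rid == "LTBP1_TB3" else filler)
            elif col in blue:
                chars.append(filler if rid == "LTBP1_TB3" else blue[col])
            else:
                chars.append(filler)
        rows.append((rid, "".join(chars)))
    return rows


def _build_egf_dock_rows() -> list[tuple[str, str]]:
    """EGF-repeat alignment: six shared cysteines flanked by three acidic
    residues upstream of Cys1 and three downstream of Cys6 in all rows."""
    width = 42
    cys_cols = [4, 9, 15, 21, 28, 36]
    acidic = {1: "D", 2: "E", 3: "D", 37: "E", 38: "D", 39: "E"}
    fillers = {"LTBP1_EGF7": "G", "FBN1_EGF28": "S", "FBN2_EGF22": "T", "FBN3_EGF20": "N"}
    rows = []
    for rid, filler in fillers.items():
        chars = []
        for col in range(1, width + 1):
            if col in cys_cols:
                chars.append("C")
            elif col in acidic:
                chars.append(acidic[col])
            else:
                chars.append(filler)
        rows.append((rid, "".join(chars)))
    return rows


# ---------------------------------------------------------------------------
# Sequence and alignment construction.

_BACKGROUND = np.array(list("ADEFGHIKLMNPQRSTVWY"))  # no cysteine


def _filler_seq(tag: str, n: int) -> np.ndarray:
    """Deterministic non-cysteine filler (stable across runs/platforms)."""
    rng = np.random.default_rng(zlib.crc32(tag.encode()) & 0x7FFFFFFF)
    return rng.choice(_BACKGROUND, n)


def _family_slots(slots: tuple[str, ...], pos_a: int, pos_b: int) -> dict[int, str]:
    out = {}
    for slot in slots:
        block, offset = _SLOTS[slot]
        out[(pos_a if block == "A" else pos_b) + offset] = "C"
    return out


def _family_precursor(pid, s, pos_a, pos_b, cleav, length, slots, extras) -> str:
    seq = _filler_seq("fixture:" + pid, length)
    seq[0] = "M"
    for pos, aa in {**_family_slots(slots, pos_a, pos_b), **extras}.items():
        seq[pos - 1] = aa
    return "".join(seq)


def _family_row(precursor: str, s: int, pos_a: int, pos_b: int, cleav: int) -> str:
    """Lay a prodomain into the fixed-geometry gapped row."""
    start = s + 1
    res = lambda lo, hi: precursor[lo - 1 : hi]  # inclusive precursor slice
    n1 = pos_a - start
    n2 = pos_b - pos_a - 4
    n3 = cleav - pos_b - 3
    pre_cap, mid_cap, tail_cap = CA - 1, CB - CA - 4, WIDTH - CB - 3
    if not (0 <= n1 <= pre_cap and 0 <= n2 <= mid_cap and 0 <= n3 <= tail_cap):
        raise ValueError("prodomain does not fit the fixture alignment geometry")
    return (
        GAP * (pre_cap - n1)
        + res(start, pos_a - 1)
        + res(pos_a, pos_a + 3)
        + res(pos_a + 4, pos_b - 1)
        + GAP * (mid_cap - n2)
        + res(pos_b, pos_b + 3)
        + res(pos_b + 4, cleav)
        + GAP * (tail_cap - n3)
    )


def _partner_precursor(pid: str, length: int, cys_positions: list[int]) -> str:
    seq = _filler_seq("fixture-partner:" + pid, length)
    seq[0] = "M"
    for pos in cys_positions:
        seq[pos - 1] = "C"
    return "".join(seq)


def _conserved_table_rows() -> list[dict]:
    rows = []
    for pid, _sub, _s, pos_a, pos_b, _cleav, _len, slots, _extras in _FAM:
        for slot in slots:
            block, offset = _SLOTS[slot]
            rows.append(
                {
                    "protein": pid,
                    "region": _REGION[block],
                    "position": (pos_a if block == "A" else pos_b) + offset,
                    "label": _LABEL_NAME[slot],
                }
            )
    return rows


def _write_fasta(path: Path, items: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in items:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _config_dict() -> dict:
    return {
        "cutoff": 0.2,
        "threshold": 0.2,
        "n_family": N_FAMILY,
        "windows": {"assn": list(ASSN_WINDOW), "b8": list(B8_WINDOW)},
        "similarity_scheme": ["FYW", "ILVM", "RK", "DE", "ST", "NQ", "A", "G", "P", "C", "H"],
        "spacing_tolerance": 5,
        "partners": [p[0] for p in _PARTNERS],
        "known_interactions": [list(p) for p in _KNOWN_INTERACTIONS],
        "synonyms": dict(_SYNONYMS),
        "reference_pairs": {k: list(v) for k, v in _REFERENCE_PAIRS.items()},
    }


def build_fixture(outdir: str | Path) -> list[Path]:
    """Write all fixture files plus a MANIFEST of sha256 checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    precursors = []
    ann_rows = []
    aln_rows = []
    for pid, sub, s, pos_a, pos_b, cleav, length, slots, extras in _FAM:
        prec = _family_precursor(pid, s, pos_a, pos_b, cleav, length, slots, extras)
        precursors.append((pid, prec))
        ann_rows.append(
            {
                "id": pid,
                "accession": f"SYN-{pid}",
                "subfamily": sub,
                "signal_start": 1,
                "signal_end": s,
                "cleavage_pos": cleav,
            }
        )
        aln_rows.append((f"{pid}|{s + 1}-{cleav}", _family_row(prec, s, pos_a, pos_b, cleav)))

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        written.append(path)

    emit("family_precursors.synthetic.fasta", lambda p: _write_fasta(p, precursors))
    emit("annotations.tsv", lambda p: pd.DataFrame(ann_rows).to_csv(p, sep="\t", index=False))
    emit("prodomain_alignment.synthetic.afa", lambda p: _write_fasta(p, aln_rows))
    emit(
        "conserved_cys.tsv",
        lambda p: pd.DataFrame(_conserved_table_rows())
        .sort_values(["region", "protein", "position"])
        .to_csv(p, sep="\t", index=False),
    )
    fam_mut = pd.DataFrame(
        _FAMILY_MUTATIONS,
        columns=["protein", "position", "ref", "alt", "phenotype", "source",
                 "near_region", "provenance"],
    )
    part_mut = pd.DataFrame(
        _PARTNER_MUTATIONS,
        columns=["protein", "position", "ref", "alt", "phenotype", "source", "provenance"],
    )
    part_mut.insert(6, "near_region", 0)
    emit(
        "mutations.tsv",
        lambda p: pd.concat([fam_mut, part_mut], ignore_index=True).to_csv(
            p, sep="\t", index=False
        ),
    )
    emit(
        "partner_domains.tsv",
        lambda p: pd.DataFrame(
            [
                {"partner": pid, "kind": kind, "ordinal": ordinal, "start": a, "end": b}
                for pid, _len, domains, _cys in _PARTNERS
                for kind, ordinal, a, b in domains
            ]
        ).to_csv(p, sep="\t", index=False),
    )
    emit(
        "partner_precursors.synthetic.fasta",
        lambda p: _write_fasta(
            p, [(pid, _partner_precursor(pid, ln, cys)) for pid, ln, _d, cys in _PARTNERS]
        ),
    )
    emit("tb_docking_alignment.synthetic.afa", lambda p: _write_fasta(p, _build_tb_dock_rows()))
    emit("egf_alignment.synthetic.afa", lambda p: _write_fasta(p, _build_egf_dock_rows()))
    emit(
        "config.yaml",
        lambda p: p.write_text(yaml.safe_dump(_config_dict(), sort_keys=True)),
    )

    manifest = outdir / "MANIFEST.sha256"
    with open(manifest, "w") as fh:
        for path in sorted(written):
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            fh.write(f"{digest}  {path.name}\n")
    written.append(manifest)
    return written


def fixture_dir() -> Path:
    """Directory of the packaged fixture files."""
    return Path(resources.files("tgfcys").joinpath("data/fixture"))


def verify_manifest(directory: Path) -> None:
    manifest = directory / "MANIFEST.sha256"
    if not manifest.exists():
        raise FileNotFoundError(f"missing fixture manifest {manifest}")
    for line in manifest.read_text().splitlines():
        digest, name = line.split()
        path = directory / name
        if not path.exists():
            raise FileNotFoundError(f"fixture file {name} missing")
        actual = hashlib.sha256(path.read_bytes()).hexdigest()
        if actual != digest:
            raise ValueError(f"fixture checksum mismatch for {name}")


@dataclass
class StudyFixture:
    """Everything the pipeline needs, loaded from the packaged fixture."""

    records: list[ProteinRecord]  # family + outgroup
    alignment: Alignment
    conserved: pd.DataFrame  # transcribed conservation table
    mutation_records: list[MutationRecord]
    partner_domains: list[PartnerDomain]
    partner_sequences: dict[str, str]
    tb_dock_rows: list[tuple[str, str]]
    egf_dock_rows: list[tuple[str, str]]
    config: dict

    @property
    def subfamilies(self) -> dict[str, str]:
        return {r.id: r.subfamily for r in self.records}

    @property
    def family_ids(self) -> list[str]:
        return [r.id for r in self.records if r.subfamily != "outgroup"]

    @property
    def partner_ids(self) -> list[str]:
        return list(self.config["partners"])

    @property
    def windows(self) -> dict[str, RegionWindow]:
        w = self.config["windows"]
        return {
            "ASSN": RegionWindow("ASSN", *w["assn"]),
            "B8": RegionWindow("B8", *w["b8"]),
        }

    @property
    def scheme(self) -> SimilarityScheme:
        return SimilarityScheme(self.config["similarity_scheme"])

    @property
    def synonyms(self) -> dict[str, str]:
        return dict(self.config["synonyms"])

    def records_by_id(self) -> Mapping[str, ProteinRecord]:
        return {r.id: r for r in self.records}


def load_study_fixture(verify: bool = True) -> StudyFixture:
    """Load (and checksum-verify) the packaged fixture."""
    from . import sequence_prep
    from .conservation import read_alignment, read_conserved_table
    from .partner_domains import read_partner_domains

    d = fixture_dir()
    if verify:
        verify_manifest(d)
    with open(d / "config.yaml") as fh:
        config = yaml.safe_load(fh)
    sequences = sequence_prep.read_fasta(d / "family_precursors.synthetic.fasta")
    annotations = sequence_prep.read_annotation_table(d / "annotations.tsv")
    records = sequence_prep.apply_annotations(sequences, annotations)
    alignment = read_alignment(d / "prodomain_alignment.synthetic.afa")
    alignment.validate_against(
        {r.id: extract_prodomain(r) for r in records}
    )
    conserved = read_conserved_table(d / "conserved_cys.tsv")
    mut_df = pd.read_csv(d / "mutations.tsv", sep="\t", dtype=str, keep_default_na=False)
    mut_records, errors = records_from_frame(mut_df)
    if errors:
        raise ValueError(f"fixture mutation table has malformed rows: {errors}")
    partner_domains = read_partner_domains(d / "partner_domains.tsv")
    partner_sequences = dict(
        sequence_prep.read_fasta(d / "partner_precursors.synthetic.fasta")
    )
    tb_rows = sequence_prep.read_fasta(d / "tb_docking_alignment.synthetic.afa")
    egf_rows = sequence_prep.read_fasta(d / "egf_alignment.synthetic.afa")
    return StudyFixture(
        records=records,
        alignment=alignment,
        conserved=conserved,
        mutation_records=mut_records,
        partner_domains=partner_domains,
        partner_sequences=partner_sequences,
        tb_dock_rows=tb_rows,
        egf_dock_rows=egf_rows,
        config=config,
    )


if __name__ == "__main__":  # pragma: no cover - maintenance entry point
    import sys

    target = sys.argv[1] if len(sys.argv) > 1 else str(fixture_dir())
    for p in build_fixture(target):
        print(p)
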