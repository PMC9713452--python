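"""Binding-partner domain architecture, cysteine spacing, docking-site logic.

The ten candidate TGF-beta binding partners fall into four families: LTBP1-4
and FBN1-3 built from 8-cysteine TGF-beta-binding (TB) domains and
6-cysteine EGF-like repeats, the leucine-rich-repeat proteins LRC32 (GARP)
and LRC33, and the Sushi-domain protein SELE.  Latency works through
disulfide bonds: in LTBP1, a pair of TB-domain cysteines 25 residues apart
each bond one monomer of a TGFB1 dimer.  Two comparisons drive the analysis
here: the *spacing* between candidate cysteine pairs versus that reference
pair, and the column-wise conservation of acidic (D/E) docking-site residues
in an alignment of TB or EGF domains against the LTBP1 reference row.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DOMAIN_KINDS",
    "CANONICAL_CYS_COUNT",
    "PartnerDomain",
    "read_partner_domains",
    "write_partner_domains",
    "find_domain",
    "cys_spacing",
    "scan_domain_cys",
    "spacing_similarity",
    "DockingComparison",
    "docking_site_compare",
    "reference_insertion_columns",
    "check_domain_cys_counts",
    "render_docking_html",
]

DOMAIN_KINDS = ("TB8CYS", "EGF", "LRR", "SUSHI")

#: Canonical cysteine counts for fully annotated domains (checked as
#: warnings, not errors: many spans are partial transcriptions).
CANONICAL_CYS_COUNT = {"TB8CYS": 8, "EGF": 6}

GAP = "-"
ACIDIC = {"D", "E"}

# Docking-site column classes.
CONSERVED_ACIDIC_ALL = "CONSERVED_ACIDIC_ALL"
REFERENCE_ONLY = "REFERENCE_ONLY"
NONREFERENCE_ONLY = "NONREFERENCE_ONLY"
NONE = "NONE"


@dataclass(frozen=True)
class PartnerDomain:
    """One annotated domain of a partner protein (inclusive precursor span)."""

    partner: str
    kind: str
    ordinal: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.partner} {self.kind}-{self.ordinal}: bad span")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def read_partner_domains(path: str | Path) -> list[PartnerDomain]:
    """Read domain annotations from TSV ``partner kind ordinal start end``."""
    df = pd.read_csv(path, sep="\t", dtype={"partner": str, "kind": str})
    missing = {"partner", "kind", "ordinal", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"partner domain table missing columns: {sorted(missing)}")
    return [
        PartnerDomain(
            partner=row["partner"],
            kind=row["kind"],
            ordinal=int(row["ordinal"]),
            start=int(row["start"]),
            end=int(row["end"]),
        )
        for _, row in df.iterrows()
    ]


def write_partner_domains(domains: Sequence[PartnerDomain], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"partner": d.partner, "kind": d.kind, "ordinal": d.ordinal,
             "start": d.start, "end": d.end}
            for d in domains
        ]
    ).to_csv(path, sep="\t", index=False)


def find_domain(
    domains: Iterable[PartnerDomain], partner: str, position: int
) -> PartnerDomain | None:
    """First annotated domain of ``partner`` containing ``position``."""
    for d in domains:
        if d.partner == partner and d.contains(position):
            return d
    return None


def cys_spacing(pos_a: int, pos_b: int) -> int:
    """Residue distance between two cysteines: |pos_b - pos_a|.

    This convention reproduces the quoted reference spacings (e.g. 25 for
    the LTBP1 TGFB1-binding pair Cys1359/Cys1384).
    """
    if pos_a < 1 or pos_b < 1:
        raise ValueError("positions must be >= 1")
    return abs(pos_b - pos_a)


def scan_domain_cys(sequence: str, domain: PartnerDomain) -> list[int]:
    """Precursor positions of 'C' inside the domain span, ascending."""
    if domain.end > len(sequence):
        raise ValueError(
            f"{domain.partner} {domain.kind}-{domain.ordinal}: span exceeds sequence"
        )
    seq = sequence.upper()
    return [
        pos for pos in range(domain.start, domain.end + 1) if seq[pos - 1] == "C"
    ]


def spacing_similarity(
    candidate: tuple[int, int],
    reference: tuple[int, int],
    tolerance: int = 5,
) -> tuple[bool, int]:
    """Compare a candidate cysteine pair's spacing with a reference pair's.

    Returns ``(similar, delta)`` where delta = |spacing(candidate) -
    spacing(reference)| and similar means delta <= tolerance.  The default
    tolerance of 5 classifies 27 vs 25 as similar and 35 or 139 vs 25 as not.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    delta = abs(cys_spacing(*candidate) - cys_spacing(*reference))
    return delta <= tolerance, delta


@dataclass(frozen=True)
class DockingComparison:
    """Per-column acidic-residue classification of a domain alignment."""

    reference_id: str
    classes: tuple[str, ...]

    @property
    def counts(self) -> dict[str, int]:
        return dict(Counter(self.classes))

    def columns_of(self, cls: str) -> list[int]:
        return [i + 1 for i, c in enumerate(self.classes) if c == cls]


def docking_site_compare(
    rows: Sequence[tuple[str, str]], reference_id: str
) -> DockingComparison:
    """Classify each column of a domain alignment by acidic conservation.

    CONSERVED_ACIDIC_ALL: every non-gap cell is D/E (and at least one cell is
    non-gap); REFERENCE_ONLY: the reference cell is D/E but some non-reference
    cell is not; NONREFERENCE_ONLY: the reference cell is not D/E but every
    non-reference cell is; NONE otherwise.  Requires >= 2 rows of equal width.
    """
    if len(rows) < 2:
        raise ValueError("docking comparison needs at least 2 rows")
    width = len(rows[0][1])
    for rid, s in rows:
        if len(s) != width:
            raise ValueError(f"row {rid!r} width {len(s)} != {width}")
    ids = [rid for rid, _ in rows]
    if reference_id not in ids:
        raise ValueError(f"reference row {reference_id!r} not in alignment")
    ref_seq = dict(rows)[reference_id].upper()
    others = [s.upper() for rid, s in rows if rid != reference_id]
    classes: list[str] = []
    for c in range(width):
        ref = ref_seq[c]
        oth = [s[c] for s in others]
        cells = [ref] + oth
        nongap = [aa for aa in cells if aa != GAP]
        if nongap and all(aa in ACIDIC for aa in nongap):
            classes.append(CONSERVED_ACIDIC_ALL)
        elif ref in ACIDIC and any(aa not in ACIDIC for aa in oth):
            classes.append(REFERENCE_ONLY)
        elif ref not in ACIDIC and oth and all(aa in ACIDIC for aa in oth):
            classes.append(NONREFERENCE_ONLY)
        else:
            classes.append(NONE)
    return DockingComparison(reference_id=reference_id, classes=tuple(classes))


def reference_insertion_columns(
    rows: Sequence[tuple[str, str]], reference_id: str
) -> list[int]:
    """Columns where the reference has a residue and every other row a gap.

    Used descriptively for the LTBP1 two-residue (FP) insertion between TB
    cysteines 6 and 7, which is unique to TGFB1 binding and absent from all
    fibrillin TB domains.
    """
    ref_seq = dict(rows)[reference_id]
    others = [s for rid, s in rows if rid != reference_id]
    return [
        c + 1
        for c in range(len(ref_seq))
        if ref_seq[c] != GAP and all(s[c] == GAP for s in others)
    ]


def check_domain_cys_counts(
    domains: Sequence[PartnerDomain], sequences: Mapping[str, str]
) -> list[str]:
    """Warnings for domains whose cysteine count deviates from canonical."""
    warnings = []
    for d in domains:
        want = CANONICAL_CYS_COUNT.get(d.kind)
        if want is None or d.partner not in sequences:
            continue
        got = len(scan_domain_cys(sequences[d.partner], d))
        if got != want:
            warnings.append(
                f"{d.partner} {d.kind}-{d.ordinal}: {got} cysteines "
                f"(canonical {want})"
            )
    return warnings


_DOCK_CSS = {
    CONSERVED_ACIDIC_ALL: "background:#2e8b57;color:#fff",  # green
    REFERENCE_ONLY: "background:#800080;color:#fff",  # purple
    NONREFERENCE_ONLY: "background:#1e60c8;color:#fff",  # blue
}


def render_docking_html(
    rows: Sequence[tuple[str, str]], comparison: DockingComparison
) -> str:
    """Color-coded HTML of a docking-site comparison (one row per sequence)."""
    name_w = max(len(r) for r, _ in rows) + 2
    out = ["<!DOCTYPE html>\n<html><head><meta charset='utf-8'></head>"
           "<body style='font-family:monospace;white-space:pre'>\n"]
    for rid, seq in rows:
        out.append(rid.ljust(name_w))
        for c, aa in enumerate(seq):
            style = _DOCK_CSS.get(comparison.classes[c])
            if style and aa != GAP:
                out.append(f"<span style='{style}'>{aa}</span>")
            else:
                out.append(aa)
        out.append("\n")
    out.append("</body></html>\n")
    return "".join(out)
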