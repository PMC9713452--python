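"""Alignment conservation shading, conserved-cysteine detection, Cys@ labels.

The conservation model follows the consensus-shading convention of BoxShade:
for each alignment column, residues are grouped by a biochemical similarity
partition; a residue is shaded as *identity* when its similarity group
reaches the cutoff fraction of rows and it is the plurality residue of that
group, and as *similar* when the group reaches the cutoff but the residue is
not the plurality.  Gaps always count in the denominator (so proteins absent
from a region dilute conservation) and are never shaded.

Conserved cysteine columns inside the two structure-anchored region windows
(the amino-terminal Association region and the carboxy-terminal beta-8
region) are named positionally: the first conserved-cysteine column of a
window is the anchor, Cys@1; a cysteine two columns downstream is Cys@3 (the
middle, third residue of the four-residue region) and three columns
downstream is Cys@4.  Offsets are alignment columns, not ungapped residues,
so proteins with local indels still receive comparable labels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import AlignIO

from .sequence_prep import ProdomainSeq

__all__ = [
    "GAP",
    "IDENTITY",
    "SIMILAR",
    "UNSHADED",
    "DEFAULT_SIMILARITY_GROUPS",
    "SimilarityScheme",
    "RegionWindow",
    "Alignment",
    "read_alignment",
    "shade_cells",
    "shade_alignment",
    "conserved_cys_columns",
    "assign_cys_labels",
    "summarize_conservation",
    "read_conserved_table",
    "write_conserved_table",
    "render_shaded_text",
    "render_shaded_html",
]

GAP = "-"

# Shading classes.
IDENTITY = "IDENTITY"
SIMILAR = "SIMILAR"
UNSHADED = "UNSHADED"

#: Biochemical similarity partition of the 20 standard residues.  Cysteine is
#: deliberately its own group: a C column is only "similar" to other C's.
DEFAULT_SIMILARITY_GROUPS: tuple[str, ...] = (
    "FYW", "ILVM", "RK", "DE", "ST", "NQ", "A", "G", "P", "C", "H",
)

REGION_NAMES = ("ASSN", "B8")
CYS_LABELS = {0: "CYS@1", 2: "CYS@3", 3: "CYS@4"}

TABLE_COLUMNS = ["protein", "region", "position", "label"]


class SimilarityScheme:
    """A named partition of the 20 standard residues into similarity groups.

    'X' belongs to no group and never matches anything.
    """

    def __init__(self, groups: Sequence[str] = DEFAULT_SIMILARITY_GROUPS):
        self.groups = tuple(g.upper() for g in groups)
        self._group_of: dict[str, int] = {}
        for gi, g in enumerate(self.groups):
            for aa in g:
                if aa in self._group_of:
                    raise ValueError(f"residue {aa} in more than one group")
                self._group_of[aa] = gi
        covered = set(self._group_of)
        missing = set("ACDEFGHIKLMNPQRSTVWY") - covered
        if missing:
            raise ValueError(f"similarity groups do not cover {sorted(missing)}")

    def group_of(self, aa: str) -> int | None:
        return self._group_of.get(aa)

    def same_group(self, a: str, b: str) -> bool:
        ga, gb = self.group_of(a), self.group_of(b)
        return ga is not None and ga == gb


@dataclass(frozen=True)
class RegionWindow:
    """An inclusive 1-based alignment-column span naming a prodomain region."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise ValueError(f"region name must be one of {REGION_NAMES}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid window span {self.start}-{self.end}")

    @property
    def columns(self) -> range:
        return range(self.start, self.end + 1)


class Alignment:
    """An ordered multiple alignment of prodomains with coordinate mapping.

    Rows are ``(protein_id, gapped_string)``; ``starts`` maps each protein to
    the precursor position of its first (ungapped) prodomain residue, which
    is what makes column<->precursor translation possible.
    """

    def __init__(
        self,
        rows: Sequence[tuple[str, str]],
        starts: Mapping[str, int] | None = None,
    ):
        if not rows:
            raise ValueError("alignment has no rows")
        width = len(rows[0][1])
        for rid, gapped in rows:
            if len(gapped) != width:
                raise ValueError(f"row {rid!r} has length {len(gapped)} != {width}")
        ids = [rid for rid, _ in rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")
        self.rows: list[tuple[str, str]] = [(r, s.upper()) for r, s in rows]
        self.starts: dict[str, int] = dict(starts or {})
        self._index = {rid: i for i, (rid, _) in enumerate(self.rows)}

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, protein_id: str) -> str:
        try:
            return self.rows[self._index[protein_id]][1]
        except KeyError:
            raise KeyError(f"unknown protein {protein_id!r}") from None

    def column(self, col: int) -> list[str]:
        """Residue-or-gap per row at 1-based column ``col``."""
        if not (1 <= col <= self.width):
            raise IndexError(f"column {col} outside 1..{self.width}")
        return [s[col - 1] for _, s in self.rows]

    def column_to_residue(self, protein_id: str, col: int) -> int | None:
        """Precursor position of the residue at ``col`` or None for a gap."""
        gapped = self.row(protein_id)
        if not (1 <= col <= self.width):
            raise IndexError(f"column {col} outside 1..{self.width}")
        if gapped[col - 1] == GAP:
            return None
        if protein_id not in self.starts:
            raise KeyError(f"no start coordinate for {protein_id!r}")
        offset = sum(1 for ch in gapped[: col - 1] if ch != GAP)
        return self.starts[protein_id] + offset

    def residue_to_column(self, protein_id: str, position: int) -> int:
        """Alignment column of precursor ``position`` (inverse of above)."""
        gapped = self.row(protein_id)
        if protein_id not in self.starts:
            raise KeyError(f"no start coordinate for {protein_id!r}")
        target = position - self.starts[protein_id]
        if target < 0:
            raise ValueError(f"{protein_id}: position {position} precedes prodomain")
        seen = -1
        for ci, ch in enumerate(gapped, start=1):
            if ch != GAP:
                seen += 1
                if seen == target:
                    return ci
        raise ValueError(f"{protein_id}: position {position} beyond prodomain")

    def validate_against(self, prodomains: Mapping[str, ProdomainSeq]) -> None:
        """Check each row's ungapped content equals that protein's prodomain."""
        for rid, gapped in self.rows:
            if rid not in prodomains:
                continue
            got = gapped.replace(GAP, "")
            want = prodomains[rid].sequence
            if got != want:
                raise ValueError(
                    f"alignment row {rid!r} does not match its prodomain sequence"
                )


def read_alignment(
    path: str | Path,
    fmt: str = "fasta",
    starts: Mapping[str, int] | None = None,
) -> Alignment:
    """Read an aligned FASTA or Clustal file.

    FASTA headers may carry a ``|start-end`` coordinate suffix (as written by
    :func:`tgfcys.sequence_prep.write_prodomain_fasta`); if present and no
    explicit ``starts`` mapping is given, start coordinates are taken from it.
    """
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    msa = AlignIO.read(str(path), fmt)
    rows: list[tuple[str, str]] = []
    inferred: dict[str, int] = {}
    for rec in msa:
        rid = rec.id
        if "|" in rid:
            rid, _, coord = rid.partition("|")
            if "-" in coord:
                try:
                    inferred[rid] = int(coord.split("-")[0])
                except ValueError:
                    pass
        rows.append((rid, str(rec.seq).upper()))
    return Alignment(rows, starts=starts if starts is not None else inferred)


def shade_cells(
    column: Sequence[str],
    scheme: SimilarityScheme,
    cutoff: float = 0.2,
) -> list[str]:
    """BoxShade-style shading for one alignment column.

    With ``n`` rows (gaps included in the denominator), a residue ``r`` whose
    similarity group reaches ``cutoff`` of the rows is shaded: IDENTITY if
    ``r`` is the plurality residue of its group (ties broken by count then
    alphabetically), SIMILAR otherwise.  Gaps and 'X' are always UNSHADED.
    """
    if not (0 < cutoff <= 1):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    n = len(column)
    counts = Counter(aa for aa in column if aa != GAP)
    group_freq: dict[int, int] = {}
    for aa, c in counts.items():
        gi = scheme.group_of(aa)
        if gi is not None:
            group_freq[gi] = group_freq.get(gi, 0) + c
    # plurality residue per group: max count, alphabetical tie-break
    plurality: dict[int, str] = {}
    for aa in sorted(counts):
        gi = scheme.group_of(aa)
        if gi is None:
            continue
        best = plurality.get(gi)
        if best is None or counts[aa] > counts[best]:
            plurality[gi] = aa
    out: list[str] = []
    for aa in column:
        gi = scheme.group_of(aa) if aa != GAP else None
        if gi is None or group_freq.get(gi, 0) / n < cutoff:
            out.append(UNSHADED)
        elif plurality[gi] == aa:
            out.append(IDENTITY)
        else:
            out.append(SIMILAR)
    return out


def shade_alignment(
    aln: Alignment, scheme: SimilarityScheme | None = None, cutoff: float = 0.2
) -> list[list[str]]:
    """Shading classes for every cell; ``result[row][col0]`` indexing."""
    scheme = scheme or SimilarityScheme()
    per_col = [shade_cells(aln.column(c), scheme, cutoff) for c in range(1, aln.width + 1)]
    return [[per_col[c][r] for c in range(aln.width)] for r in range(aln.n_rows)]


def conserved_cys_columns(
    aln: Alignment, window: RegionWindow, threshold: float = 0.2
) -> list[int]:
    """Columns in ``window`` where the cysteine fraction reaches ``threshold``.

    The denominator is the full row count (gaps dilute conservation); the
    comparison is closed (>=).
    """
    if window.end > aln.width:
        raise ValueError(
            f"window {window.name} ({window.start}-{window.end}) exceeds "
            f"alignment width {aln.width}"
        )
    n = aln.n_rows
    out = []
    for col in window.columns:
        if sum(1 for aa in aln.column(col) if aa == "C") / n >= threshold:
            out.append(col)
    return out


def assign_cys_labels(
    aln: Alignment,
    window: RegionWindow,
    columns: Sequence[int],
) -> pd.DataFrame:
    """Assign Cys@ labels relative to the window's anchor column.

    The anchor is the first conserved-cysteine column of the window; any
    protein with 'C' at the anchor gets CYS@1, at anchor+2 CYS@3, and at
    anchor+3 CYS@4.  Positions are reported in precursor coordinates.  With
    no conserved columns an empty table is returned.
    """
    rows: list[dict] = []
    if columns:
        anchor = min(columns)
        for offset, label in CYS_LABELS.items():
            col = anchor + offset
            if col > aln.width:
                continue
            for rid in aln.ids:
                if aln.row(rid)[col - 1] == "C":
                    rows.append(
                        {
                            "protein": rid,
                            "region": window.name,
                            "position": aln.column_to_residue(rid, col),
                            "label": label,
                        }
                    )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return df.sort_values(["region", "protein", "position"]).reset_index(drop=True)


def summarize_conservation(
    table: pd.DataFrame,
    subfamilies: Mapping[str, str],
    n_family: int = 33,
) -> dict:
    """Per-region and overall census of proteins with conserved cysteines.

    Proteins labelled ``outgroup`` are excluded everywhere; percentages are
    100 * count / n_family rounded to the nearest integer.
    """
    if n_family <= 0:
        raise ValueError("n_family must be positive")

    def fam(proteins: Iterable[str]) -> set[str]:
        return {p for p in proteins if subfamilies.get(p) != "outgroup"}

    summary: dict = {"regions": {}, "n_family": n_family}
    for region in REGION_NAMES:
        prots = fam(table.loc[table["region"] == region, "protein"])
        by_sub: dict[str, int] = {}
        for p in prots:
            sub = subfamilies.get(p, "?")
            by_sub[sub] = by_sub.get(sub, 0) + 1
        summary["regions"][region] = {
            "n_proteins": len(prots),
            "by_subfamily": dict(sorted(by_sub.items())),
            "pct_of_family": round(100 * len(prots) / n_family),
        }
    overall = fam(table["protein"])
    summary["overall"] = {
        "n_proteins": len(overall),
        "pct_of_family": round(100 * len(overall) / n_family),
    }
    return summary


def write_conserved_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_conserved_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "region": str, "label": str})
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"conserved table missing columns: {sorted(missing)}")
    return df[TABLE_COLUMNS]


def render_shaded_text(
    aln: Alignment,
    shading: Sequence[Sequence[str]],
    block: int = 60,
) -> str:
    """Plain-text rendering: identity uppercase, similar lowercase, other '.'.

    Gaps stay '-'.  Rows are wrapped in blocks with the last alignment column
    of each block noted at the end of the line.
    """
    name_w = max(len(r) for r in aln.ids) + 2
    lines: list[str] = []
    for begin in range(0, aln.width, block):
        end = min(begin + block, aln.width)
        for ri, (rid, gapped) in enumerate(aln.rows):
            cells = []
            for ci in range(begin, end):
                aa = gapped[ci]
                cls = shading[ri][ci]
                if aa == GAP:
                    cells.append(GAP)
                elif cls == IDENTITY:
                    cells.append(aa.upper())
                elif cls == SIMILAR:
                    cells.append(aa.lower())
                else:
                    cells.append(".")
            lines.append(f"{rid:<{name_w}}{''.join(cells)}  {end}")
        lines.append("")
    return "\n".join(lines)


_HTML_HEAD = (
    "<!DOCTYPE html>\n<html><head><meta charset='utf-8'><style>\n"
    "body{font-family:monospace;white-space:pre}\n"
    ".id{background:#000;color:#fff}\n"
    ".sim{background:#bbb;color:#000}\n"
    "</style></head><body>\n"
)


def render_shaded_html(
    aln: Alignment,
    shading: Sequence[Sequence[str]],
    block: int = 60,
) -> str:
    """Two-class HTML rendering (identity black, similar grey)."""
    name_w = max(len(r) for r in aln.ids) + 2
    parts: list[str] = [_HTML_HEAD]
    for begin in range(0, aln.width, block):
        end = min(begin + block, aln.width)
        for ri, (rid, gapped) in enumerate(aln.rows):
            parts.append(rid.ljust(name_w))
            for ci in range(begin, end):
                aa = gapped[ci]
                cls = shading[ri][ci]
                if aa != GAP and cls == IDENTITY:
                    parts.append(f"<span class='id'>{aa}</span>")
                elif aa != GAP and cls == SIMILAR:
                    parts.append(f"<span class='sim'>{aa}</span>")
                else:
                    parts.append(aa)
            parts.append(f"  {end}\n")
        parts.append("\n")
    parts.append("</body></html>\n")
    return "".join(parts)
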