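"""Precursor sequences, signal/cleavage annotation, and prodomain extraction.

TGF-beta family members are synthesized as three-part precursors: an
amino-terminal signal sequence, a ~250-residue prodomain, and a
carboxy-terminal ligand domain.  The analyses in this package operate on the
prodomain but report every residue in *precursor* coordinates (Met1 = 1),
so that positions agree with the mutation databases and the structural
literature even though the signal sequence and ligand are trimmed away
before alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "STANDARD_AA",
    "SUBFAMILIES",
    "ProteinRecord",
    "ProdomainSeq",
    "read_fasta",
    "read_annotation_table",
    "apply_annotations",
    "extract_prodomain",
    "write_prodomain_fasta",
]

#: The 20 standard residues; 'X' is tolerated as an unknown residue.
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Valid subfamily tags.  "outgroup" marks comparator rows (GDNF) that are
#: carried in the alignment but excluded from family denominators.
SUBFAMILIES = ("TGF-beta", "Activin", "BMP", "outgroup")


@dataclass(frozen=True)
class ProteinRecord:
    """A precursor sequence with its trimming annotations.

    Parameters
    ----------
    id:
        Gene symbol (e.g. ``"TGFB1"``).
    accession:
        Free-text accession; informational only.
    subfamily:
        One of :data:`SUBFAMILIES`.
    precursor:
        Full precursor amino-acid sequence, Met1 first.
    signal_span:
        Inclusive 1-based span of the signal sequence, or ``None`` if the
        protein has no signal peptide.  When present it must start at 1.
    cleavage_pos:
        1-based position of the *last* prodomain residue; everything
        downstream is the ligand domain.
    """

    id: str
    accession: str
    subfamily: str
    precursor: str
    signal_span: tuple[int, int] | None
    cleavage_pos: int

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(
                f"{self.id}: unknown subfamily {self.subfamily!r}; "
                f"expected one of {SUBFAMILIES}"
            )
        bad = set(self.precursor) - STANDARD_AA - {"X"}
        if bad:
            raise ValueError(f"{self.id}: non-standard residues {sorted(bad)}")
        if self.signal_span is not None:
            start, end = self.signal_span
            if start != 1:
                raise ValueError(f"{self.id}: signal span must start at residue 1")
            if not (start <= end):
                raise ValueError(f"{self.id}: empty/inverted signal span")
            if not end < self.cleavage_pos:
                raise ValueError(
                    f"{self.id}: signal end {end} must precede cleavage "
                    f"{self.cleavage_pos}"
                )
        if not (1 <= self.cleavage_pos < len(self.precursor)):
            raise ValueError(
                f"{self.id}: cleavage_pos {self.cleavage_pos} outside precursor "
                f"(length {len(self.precursor)})"
            )

    @property
    def prodomain_start(self) -> int:
        """First prodomain residue in precursor coordinates."""
        return 1 if self.signal_span is None else self.signal_span[1] + 1


@dataclass(frozen=True)
class ProdomainSeq:
    """A trimmed prodomain that remembers precursor numbering.

    ``residues`` is an ascending, contiguous list of
    ``(precursor_position, amino_acid)`` pairs running from the residue
    after the signal sequence through the cleavage position.
    """

    protein_id: str
    residues: tuple[tuple[int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for (p0, _), (p1, _) in zip(self.residues, self.residues[1:]):
            if p1 != p0 + 1:
                raise ValueError(
                    f"{self.protein_id}: prodomain positions not contiguous "
                    f"({p0} -> {p1})"
                )

    @property
    def start(self) -> int:
        return self.residues[0][0]

    @property
    def end(self) -> int:
        return self.residues[-1][0]

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)

    def position_of_index(self, i: int) -> int:
        """Precursor position of the i-th (0-based) prodomain residue."""
        return self.residues[i][0]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are uppercased and whitespace-stripped.  Raises on an empty
    file and on duplicate record ids.
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id.split("|")[0]
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r} in {path}")
        seen.add(rid)
        out.append((rid, str(rec.seq).upper().replace(" ", "")))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


ANNOTATION_COLUMNS = [
    "id",
    "accession",
    "subfamily",
    "signal_start",
    "signal_end",
    "cleavage_pos",
]


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read the trimming-annotation TSV.

    Header: ``id accession subfamily signal_start signal_end cleavage_pos``.
    Empty signal fields mean "no signal peptide".
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "accession": str, "subfamily": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def apply_annotations(
    sequences: Sequence[tuple[str, str]], annotations: pd.DataFrame
) -> list[ProteinRecord]:
    """Join sequences with their annotation rows into :class:`ProteinRecord`.

    Every sequence id must appear exactly once in the annotation table;
    record invariants are checked on construction.
    """
    by_id = {}
    for _, row in annotations.iterrows():
        rid = str(row["id"])
        if rid in by_id:
            raise ValueError(f"duplicate annotation row for {rid!r}")
        by_id[rid] = row
    records: list[ProteinRecord] = []
    for rid, seq in sequences:
        if rid not in by_id:
            raise ValueError(f"no annotation row for sequence {rid!r}")
        row = by_id[rid]
        if pd.isna(row["signal_start"]) or pd.isna(row["signal_end"]):
            span = None
        else:
            span = (int(row["signal_start"]), int(row["signal_end"]))
        records.append(
            ProteinRecord(
                id=rid,
                accession="" if pd.isna(row["accession"]) else str(row["accession"]),
                subfamily=str(row["subfamily"]),
                precursor=seq,
                signal_span=span,
                cleavage_pos=int(row["cleavage_pos"]),
            )
        )
    return records


def extract_prodomain(record: ProteinRecord) -> ProdomainSeq:
    """Trim signal sequence and ligand, keeping precursor numbering.

    The result spans ``signal_end + 1 .. cleavage_pos`` (or ``1 ..
    cleavage_pos`` without a signal peptide), so a residue reported at
    position 33 is precursor residue 33.
    """
    start = record.prodomain_start
    residues = tuple(
        (pos, record.precursor[pos - 1])
        for pos in range(start, record.cleavage_pos + 1)
    )
    return ProdomainSeq(protein_id=record.id, residues=residues)


def write_prodomain_fasta(prodomains: Iterable[ProdomainSeq], path: str | Path) -> None:
    """Write prodomains as FASTA with a ``|start-end`` coordinate suffix."""
    with open(path, "w") as fh:
        for pro in prodomains:
            fh.write(f">{pro.protein_id}|{pro.start}-{pro.end}\n")
            seq = pro.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
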