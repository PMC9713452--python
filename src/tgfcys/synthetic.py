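"""Synthetic protein families with planted ground truth.

The generator builds a family of precursor sequences, a gap-free (or
optionally gapped) prodomain alignment, and a mutation table in which
conserved-cysteine columns and phenotype-sharing mutation sets are *planted*
by construction, together with a :class:`TruthBundle` holding the conserved
table and interaction pairs the pipeline must recover.  The background
residue distribution excludes cysteine outside planted columns, so planted
conservation is unambiguous in small tests; a ``background_cys_rate`` flag
re-enables stray cysteines for stress testing.  All randomness flows from a
single integer seed, and the same configuration and seed produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import GAP, Alignment, RegionWindow
from .sequence_prep import ProteinRecord, write_prodomain_fasta, extract_prodomain

__all__ = ["SyntheticConfig", "TruthBundle", "SyntheticFamily", "generate_family", "write_family"]

#: Background alphabet: the 19 standard residues other than cysteine.
BACKGROUND_AA = np.array(list("ADEFGHIKLMNPQRSTVWY"))

#: Label offsets (alignment columns from the region anchor) that carry names.
LABEL_OFFSETS = {0: "CYS@1", 2: "CYS@3", 3: "CYS@4"}

SUBFAMILY_CYCLE = ("TGF-beta", "Activin", "BMP")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic family.

    ``planted_columns`` maps region name -> alignment column -> tuple of
    protein ids carrying a planted cysteine there; column offsets within a
    region must be 0/2/3 relative to the region's first planted column so
    that every planted cysteine receives a Cys@ label.  ``planted_pairs``
    are (protein_a, protein_b, phenotype) triples; a == b plants a homotypic
    dimer (the protein then needs >= 2 planted positions).  Noise mutations
    get unique singleton phenotypes and can never create a pair.
    """

    n_proteins: int
    width: int = 120
    signal_length: int = 20
    ligand_length: int = 30
    assn_window: tuple[int, int] = (10, 13)
    b8_window: tuple[int, int] = (90, 93)
    planted_columns: Mapping[str, Mapping[int, tuple[str, ...]]] = field(
        default_factory=dict
    )
    planted_pairs: tuple[tuple[str, str, str], ...] = ()
    n_noise: int = 0
    seed: int = 0
    threshold: float = 0.2
    indel: bool = False
    background_cys_rate: float = 0.0

    def protein_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_proteins)]

    def subfamily_of(self, pid: str) -> str:
        i = int(pid[1:]) - 1
        return SUBFAMILY_CYCLE[i % len(SUBFAMILY_CYCLE)]

    def windows(self) -> dict[str, RegionWindow]:
        return {
            "ASSN": RegionWindow("ASSN", *self.assn_window),
            "B8": RegionWindow("B8", *self.b8_window),
        }

    def validate(self) -> None:
        ids = set(self.protein_ids())
        windows = self.windows()
        for region, cols in self.planted_columns.items():
            if region not in windows:
                raise ValueError(f"unknown region {region!r}")
            w = windows[region]
            anchor = min(cols)
            for col, holders in cols.items():
                if not (w.start <= col <= w.end):
                    raise ValueError(
                        f"planted column {col} outside {region} window "
                        f"{w.start}-{w.end}"
                    )
                if col - anchor not in LABEL_OFFSETS:
                    raise ValueError(
                        f"planted column {col} at unlabeled offset "
                        f"{col - anchor} from anchor {anchor}"
                    )
                unknown = set(holders) - ids
                if unknown:
                    raise ValueError(f"planted holders not in family: {sorted(unknown)}")
                if self.n_proteins and len(holders) / self.n_proteins < self.threshold:
                    raise ValueError(
                        f"column {col}: {len(holders)}/{self.n_proteins} holders "
                        f"below detection threshold {self.threshold}"
                    )
        for a, b, phen in self.planted_pairs:
            for p in (a, b):
                if p not in ids:
                    raise ValueError(f"planted pair protein {p!r} not in family")
            if a == b and len(self._positions_of(a)) < 2:
                raise ValueError(
                    f"homotypic pair for {a} needs >= 2 planted positions"
                )
            if not phen:
                raise ValueError("planted pair needs a phenotype label")

    def _positions_of(self, pid: str) -> list[int]:
        """Planted alignment columns held by ``pid`` (ascending)."""
        cols = []
        for region_cols in self.planted_columns.values():
            for col, holders in region_cols.items():
                if pid in holders:
                    cols.append(col)
        return sorted(cols)


@dataclass(frozen=True)
class TruthBundle:
    """Ground truth derivable from the config without running the pipeline."""

    conserved: pd.DataFrame  # columns: protein region position label
    pairs: tuple[tuple[str, str, str], ...]  # sorted (a, b, phenotype), a <= b

    def pair_set(self) -> set[tuple[str, str, str]]:
        return set(self.pairs)


@dataclass
class SyntheticFamily:
    records: list[ProteinRecord]
    alignment: Alignment | None
    mutations: pd.DataFrame
    truth: TruthBundle


def _row_gap_plan(cfg: SyntheticConfig, rng: np.random.Generator) -> dict[str, tuple[int, int]]:
    """In indel mode, choose a per-protein gap block away from the windows."""
    if not cfg.indel:
        return {}
    lo = cfg.assn_window[1] + 5
    hi = cfg.b8_window[0] - 10
    if hi <= lo:
        raise ValueError("alignment too narrow for indel mode")
    plan: dict[str, tuple[int, int]] = {}
    for i, pid in enumerate(cfg.protein_ids()):
        if i % 3 == 2:  # every third row carries a deletion
            length = int(rng.integers(2, 6))
            start = int(rng.integers(lo, hi - length))
            plan[pid] = (start, length)
    return plan


def generate_family(cfg: SyntheticConfig) -> SyntheticFamily:
    """Generate sequences, alignment, mutations and ground truth.

    Sequences are drawn uniformly over the non-cysteine background except at
    planted columns; planted interaction pairs receive qualifying
    cysteine-loss mutations sharing their phenotype label; noise mutations
    receive unique singleton phenotypes.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    empty_truth = TruthBundle(
        conserved=pd.DataFrame(columns=["protein", "region", "position", "label"]),
        pairs=(),
    )
    if cfg.n_proteins == 0:
        return SyntheticFamily([], None, pd.DataFrame(
            columns=["protein", "position", "ref", "alt", "phenotype", "source", "near_region"]
        ), empty_truth)

    ids = cfg.protein_ids()
    planted_at: dict[tuple[str, int], bool] = {}
    for region_cols in cfg.planted_columns.values():
        for col, holders in region_cols.items():
            for pid in holders:
                planted_at[(pid, col)] = True

    gap_plan = _row_gap_plan(cfg, rng)
    rows: list[tuple[str, str]] = []
    starts: dict[str, int] = {}
    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    position_of: dict[tuple[str, int], int] = {}  # (pid, column) -> precursor pos

    for pid in ids:
        gap = gap_plan.get(pid)
        row_chars: list[str] = []
        prodomain_chars: list[str] = []
        start = cfg.signal_length + 1
        pos = start
        for col in range(1, cfg.width + 1):
            if gap and gap[0] <= col < gap[0] + gap[1]:
                row_chars.append(GAP)
                continue
            if planted_at.get((pid, col)):
                aa = "C"
            elif cfg.background_cys_rate > 0 and rng.random() < cfg.background_cys_rate:
                aa = "C"
            else:
                aa = str(rng.choice(BACKGROUND_AA))
            row_chars.append(aa)
            prodomain_chars.append(aa)
            position_of[(pid, col)] = pos
            pos += 1
        rows.append((pid, "".join(row_chars)))
        starts[pid] = start
        signal = "M" + "".join(rng.choice(BACKGROUND_AA, cfg.signal_length - 1))
        ligand = "".join(rng.choice(BACKGROUND_AA, cfg.ligand_length))
        precursor = signal + "".join(prodomain_chars) + ligand
        cleavage = cfg.signal_length + len(prodomain_chars)
        records.append(
            ProteinRecord(
                id=pid,
                accession=f"SYN-{pid}",
                subfamily=cfg.subfamily_of(pid),
                precursor=precursor,
                signal_span=(1, cfg.signal_length),
                cleavage_pos=cleavage,
            )
        )

    for region, cols in cfg.planted_columns.items():
        anchor = min(cols)
        for col, holders in cols.items():
            label = LABEL_OFFSETS[col - anchor]
            for pid in holders:
                truth_rows.append(
                    {
                        "protein": pid,
                        "region": region,
                        "position": position_of[(pid, col)],
                        "label": label,
                    }
                )
    truth_table = (
        pd.DataFrame(truth_rows, columns=["protein", "region", "position", "label"])
        .sort_values(["region", "protein", "position"])
        .reset_index(drop=True)
    )

    mut_rows: list[dict] = []

    def plant_loss(pid: str, col: int, phenotype: str) -> None:
        pos = position_of[(pid, col)]
        mut_rows.append(
            {
                "protein": pid,
                "position": pos,
                "ref": "C",
                "alt": "R",
                "phenotype": phenotype,
                "source": "synthetic",
                "near_region": 0,
            }
        )

    truth_pairs: list[tuple[str, str, str]] = []
    for a, b, phen in cfg.planted_pairs:
        cols_a = cfg._positions_of(a)
        if a == b:
            plant_loss(a, cols_a[0], phen)
            plant_loss(a, cols_a[1], phen)
        else:
            plant_loss(a, cols_a[0], phen)
            plant_loss(b, cfg._positions_of(b)[0], phen)
        truth_pairs.append((*sorted((a, b)), phen))

    planted_cols_by_pid: dict[str, set[int]] = {}
    for (pid, col) in planted_at:
        planted_cols_by_pid.setdefault(pid, set()).add(col)
    for i in range(cfg.n_noise):
        pid = ids[int(rng.integers(0, len(ids)))]
        rec = next(r for r in records if r.id == pid)
        taken = {position_of[(pid, c)] for c in planted_cols_by_pid.get(pid, ())}
        while True:
            pos = int(rng.integers(rec.prodomain_start, rec.cleavage_pos + 1))
            if pos not in taken:
                break
        ref = rec.precursor[pos - 1]
        alt = str(rng.choice(BACKGROUND_AA))
        while alt == ref:
            alt = str(rng.choice(BACKGROUND_AA))
        mut_rows.append(
            {
                "protein": pid,
                "position": pos,
                "ref": ref,
                "alt": alt,
                "phenotype": f"noise phenotype {i + 1}",
                "source": "synthetic",
                "near_region": 0,
            }
        )

    mutations = pd.DataFrame(
        mut_rows,
        columns=["protein", "position", "ref", "alt", "phenotype", "source", "near_region"],
    )
    truth = TruthBundle(conserved=truth_table, pairs=tuple(sorted(truth_pairs)))
    return SyntheticFamily(records, Alignment(rows, starts=starts), mutations, truth)


def write_family(family: SyntheticFamily, outdir: str | Path) -> None:
    """Write a generated family in the standard fixture layout (text files)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "family_precursors.synthetic.fasta", "w") as fh:
        for rec in family.records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.precursor), 60):
                fh.write(rec.precursor[i : i + 60] + "\n")
    pd.DataFrame(
        [
            {
                "id": r.id,
                "accession": r.accession,
                "subfamily": r.subfamily,
                "signal_start": r.signal_span[0] if r.signal_span else "",
                "signal_end": r.signal_span[1] if r.signal_span else "",
                "cleavage_pos": r.cleavage_pos,
            }
            for r in family.records
        ]
    ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    if family.alignment is not None:
        prodomains = [extract_prodomain(r) for r in family.records]
        with open(outdir / "prodomain_alignment.synthetic.afa", "w") as fh:
            for (rid, gapped), pro in zip(family.alignment.rows, prodomains):
                fh.write(f">{rid}|{pro.start}-{pro.end}\n{gapped}\n")
        write_prodomain_fasta(prodomains, outdir / "prodomains.synthetic.fasta")
    family.mutations.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    family.truth.conserved.to_csv(outdir / "truth_conserved.tsv", sep="\t", index=False)
    pd.DataFrame(family.truth.pairs, columns=["member_a", "member_b", "phenotype"]).to_csv(
        outdir / "truth_pairs.tsv", sep="\t", index=False
    )
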