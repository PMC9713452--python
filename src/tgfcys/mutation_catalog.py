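"""Disease-mutation ingestion, cysteine loss/gain classification, context.

Mutation records emulate what is mined by hand from GeneCards, MalaCards and
the NCI Genome Data Commons: a protein, a precursor position, reference and
alternate residues (the alternate may be a stop or an in-frame deletion) and
a free-text disease phenotype.  Records are classified by their effect on
cysteine content and annotated with the feature they hit: a conserved
prodomain cysteine, another prodomain site, the ligand domain, or an
annotated domain of a binding-partner protein.

Phenotype strings are normalized conservatively (lowercase, collapsed
whitespace, optional curated synonym map).  Distinct strings stay distinct:
the downstream inference hinges on *exact* phenotype sharing, and the source
databases distinguish, e.g., squamous-cell from adenocarcinoma lung tumors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .partner_domains import PartnerDomain, find_domain
from .sequence_prep import ProteinRecord

__all__ = [
    "CYS_LOSS",
    "CYS_GAIN",
    "OTHER",
    "Context",
    "MutationRecord",
    "classify_effect",
    "normalize_phenotype",
    "load_synonym_map",
    "parse_mutation_table",
    "records_from_frame",
    "annotate_context",
    "annotate_catalog",
    "write_catalog",
    "count_mutated_conserved_positions",
]

# Effects
CYS_LOSS = "CYS_LOSS"
CYS_GAIN = "CYS_GAIN"
OTHER = "OTHER"

# Context kinds
PRODOMAIN_CONSERVED = "PRODOMAIN_CONSERVED"
PRODOMAIN_OTHER = "PRODOMAIN_OTHER"
LIGAND = "LIGAND"
PARTNER_DOMAIN = "PARTNER_DOMAIN"
UNMAPPED = "UNMAPPED"

MUTATION_COLUMNS = ["protein", "position", "ref", "alt", "phenotype", "source"]

_ALT_DEL = re.compile(r"^del:(\d+)$", re.IGNORECASE)


@dataclass(frozen=True)
class Context:
    """Feature context of a mutation after annotation."""

    kind: str
    region: str | None = None  # PRODOMAIN_CONSERVED: ASSN or B8
    label: str | None = None  # PRODOMAIN_CONSERVED: CYS@1/3/4
    domain_kind: str | None = None  # PARTNER_DOMAIN
    domain_ordinal: int | None = None  # PARTNER_DOMAIN

    def __str__(self) -> str:
        if self.kind == PRODOMAIN_CONSERVED:
            return f"{self.kind}({self.region},{self.label})"
        if self.kind == PARTNER_DOMAIN:
            return f"{self.kind}({self.domain_kind},{self.domain_ordinal})"
        return self.kind


@dataclass(frozen=True)
class MutationRecord:
    """One cysteine-affecting (or other) variant at a precursor position.

    ``alt`` is a one-letter residue, ``"*"`` for a stop, or ``"del:<n>"``
    for an in-frame deletion of n residues starting at ``position``.
    """

    id: str
    protein: str
    position: int
    ref: str
    alt: str
    phenotype_raw: str
    source: str
    near_region: bool = False
    phenotype_key: str | None = None
    effect: str | None = None
    context: Context | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.id}: position must be >= 1")
        if len(self.ref) != 1 or not self.ref.isalpha():
            raise ValueError(f"{self.id}: bad ref residue {self.ref!r}")
        if not (len(self.alt) == 1 and (self.alt.isalpha() or self.alt == "*")) and not _ALT_DEL.match(self.alt):
            raise ValueError(f"{self.id}: bad alt {self.alt!r}")


def classify_effect(ref: str, alt: str) -> str:
    """CYS_LOSS for C->anything-else (stop and deletion included),
    CYS_GAIN for non-C->C, OTHER otherwise."""
    ref = ref.upper()
    is_del = bool(_ALT_DEL.match(alt))
    alt_aa = alt.upper() if len(alt) == 1 else None
    if ref == "C" and (is_del or alt_aa != "C"):
        return CYS_LOSS
    if ref != "C" and alt_aa == "C":
        return CYS_GAIN
    return OTHER


def normalize_phenotype(
    raw: str | None, synonyms: Mapping[str, str] | None = None
) -> str | None:
    """Lowercase, trim, collapse whitespace; then apply the synonym map.

    Returns None for absent/blank phenotypes.  No fuzzy matching: merging
    happens only through the explicit, curated synonym map.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    key = re.sub(r"\s+", " ", str(raw).strip().lower())
    if not key:
        return None
    if synonyms:
        key = synonyms.get(key, key)
    return key


def load_synonym_map(path: str | Path) -> dict[str, str]:
    """Load the curated phenotype synonym map (YAML mapping raw -> canonical).

    Both sides are normalized so lookups are case/whitespace insensitive.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return {
        normalize_phenotype(k): normalize_phenotype(v) for k, v in data.items()
    }


def parse_mutation_table(
    path: str | Path,
) -> tuple[list[MutationRecord], list[str]]:
    """Parse the mutation TSV into records plus a row-level error report.

    Header: ``protein position ref alt phenotype source`` with an optional
    ``near_region`` 0/1 column (a curated structural-proximity flag used for
    cysteine-gain evidence).  Malformed rows are reported, not fatal; an
    empty file is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"mutation table {path} has no rows")
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> tuple[list[MutationRecord], list[str]]:
    """Build records from an in-memory mutation table (all-string columns)."""
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    records: list[MutationRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            pos = int(row["position"])
        except ValueError:
            errors.append(f"line {line}: unparseable position {row['position']!r}")
            continue
        near = str(row.get("near_region", "") or "0").strip() in ("1", "true", "True")
        try:
            rec = MutationRecord(
                id=f"{row['protein']}:{row['ref']}{pos}{row['alt']}:{row['source']}:{line}",
                protein=row["protein"],
                position=pos,
                ref=row["ref"].strip().upper(),
                alt=row["alt"].strip(),
                phenotype_raw=row["phenotype"],
                source=row["source"],
                near_region=near,
            )
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
            continue
        records.append(rec)
    return records, errors


def annotate_context(
    record: MutationRecord,
    conserved: pd.DataFrame,
    protein_records: Mapping[str, ProteinRecord],
    partner_domains: Sequence[PartnerDomain] = (),
    partner_ids: Iterable[str] = (),
) -> Context:
    """Resolve the feature context of one record.

    Family proteins: a (protein, position) hit in the conserved-cysteine
    table wins; otherwise positions up to the cleavage site are
    PRODOMAIN_OTHER and positions beyond it are LIGAND.  Partner proteins:
    a position inside an annotated domain is PARTNER_DOMAIN; anything else
    (including unknown proteins) is UNMAPPED.
    """
    hit = conserved[
        (conserved["protein"] == record.protein)
        & (conserved["position"] == record.position)
    ]
    if len(hit):
        row = hit.iloc[0]
        return Context(PRODOMAIN_CONSERVED, region=row["region"], label=row["label"])
    if record.protein in protein_records:
        if record.position <= protein_records[record.protein].cleavage_pos:
            return Context(PRODOMAIN_OTHER)
        return Context(LIGAND)
    if record.protein in set(partner_ids):
        dom = find_domain(partner_domains, record.protein, record.position)
        if dom is not None:
            return Context(PARTNER_DOMAIN, domain_kind=dom.kind, domain_ordinal=dom.ordinal)
        return Context(UNMAPPED)
    return Context(UNMAPPED)


def annotate_catalog(
    records: Sequence[MutationRecord],
    conserved: pd.DataFrame,
    protein_records: Mapping[str, ProteinRecord],
    partner_domains: Sequence[PartnerDomain] = (),
    partner_ids: Iterable[str] = (),
    synonyms: Mapping[str, str] | None = None,
) -> list[MutationRecord]:
    """Classify effect, normalize phenotype, and set context for each record."""
    partner_ids = set(partner_ids)
    out: list[MutationRecord] = []
    for rec in records:
        out.append(
            replace(
                rec,
                effect=classify_effect(rec.ref, rec.alt),
                phenotype_key=normalize_phenotype(rec.phenotype_raw, synonyms),
                context=annotate_context(
                    rec, conserved, protein_records, partner_domains, partner_ids
                ),
            )
        )
    return out


def write_catalog(records: Sequence[MutationRecord], path: str | Path) -> None:
    """Write the annotated catalog as TSV with effect/context/phenotype_key."""
    rows = [
        {
            "protein": r.protein,
            "position": r.position,
            "ref": r.ref,
            "alt": r.alt,
            "phenotype": r.phenotype_raw,
            "source": r.source,
            "near_region": int(r.near_region),
            "effect": r.effect or "",
            "context": str(r.context) if r.context else "",
            "phenotype_key": r.phenotype_key or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def count_mutated_conserved_positions(
    records: Sequence[MutationRecord],
) -> tuple[int, int]:
    """Distinct conserved prodomain cysteine positions with >=1 cysteine-loss
    mutation, and the number of proteins carrying them.

    Multiple substitutions at one position (e.g. three different changes of
    one cysteine) collapse to a single mutated position.
    """
    positions = {
        (r.protein, r.position)
        for r in records
        if r.effect == CYS_LOSS
        and r.context is not None
        and r.context.kind == PRODOMAIN_CONSERVED
    }
    proteins = {p for p, _ in positions}
    return len(positions), len(proteins)
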