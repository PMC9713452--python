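"""Common-mutant-phenotype inference of heterodimers and partner binding.

The inference principle: mutations in two proteins that produce the same
disease phenotype point to a lost biochemical interaction that normally
achieves a shared function.  Applied to cysteine variants it yields two kinds
of hypotheses:

* **Heterodimers** — two TGF-beta family proteins whose qualifying cysteine
  evidence shares a phenotype.  Qualifying evidence for a protein is a
  cysteine loss at a conserved prodomain position, a cysteine loss in the
  ligand domain, or a curated cysteine *gain* structurally near a conserved
  region.  A homotypic (same-protein) dimer hypothesis is emitted only when
  a protein is the sole holder of qualifying evidence for a phenotype and
  that evidence spans at least two distinct positions (e.g. prodomain plus
  ligand); when other proteins share the phenotype, same-protein multi-site
  evidence is read as confidence in the cross-protein pairs instead.
* **Partner binding** — a cysteine loss at a conserved prodomain position
  whose phenotype is shared by at least one cysteine-loss record on a
  binding-partner protein yields a (family protein, partner) edge.

Hypotheses are flagged novel unless the pair is in the curated
known-interaction set; ordering is lexicographic by (phenotype, members) so
output files are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .mutation_catalog import (
    CYS_GAIN,
    CYS_LOSS,
    LIGAND,
    PRODOMAIN_CONSERVED,
    MutationRecord,
)

__all__ = [
    "HETERODIMER",
    "PARTNER_BINDING",
    "InteractionHypothesis",
    "KnownInteractionSet",
    "qualifying_heterodimer_evidence",
    "propose_heterodimers",
    "propose_partner_interactions",
    "summarize_hypotheses",
    "count_potential_tb_partnerships",
    "write_hypotheses_json",
    "write_hypotheses_tsv",
]

HETERODIMER = "HETERODIMER"
PARTNER_BINDING = "PARTNER_BINDING"

WITHIN_SUBFAMILY = "WITHIN_SUBFAMILY"
ACROSS_SUBFAMILY = "ACROSS_SUBFAMILY"
SCOPE_NA = "NA"


@dataclass(frozen=True)
class InteractionHypothesis:
    """A proposed interaction supported by a shared mutant phenotype.

    ``members`` is sorted; for HETERODIMER both members are family proteins
    (equal ids denote a homotypic dimer), for PARTNER_BINDING exactly one is
    a family protein and one a partner.
    """

    kind: str
    members: tuple[str, str]
    phenotype_key: str
    supporting_mutation_ids: tuple[str, ...]
    scope: str
    novel: bool

    @property
    def pair(self) -> frozenset[str]:
        return frozenset(self.members)

    def sort_key(self) -> tuple:
        return (self.phenotype_key, self.members)


class KnownInteractionSet:
    """Unordered protein pairs previously demonstrated to interact."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._pairs: set[frozenset[str]] = set()
        for a, b in pairs:
            p = frozenset((a, b))
            self._pairs.add(p)

    def __contains__(self, pair: Iterable[str]) -> bool:
        return frozenset(pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KnownInteractionSet":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(tuple(p) for p in data.get("known_interactions", []))


def _is_qualifying(rec: MutationRecord) -> bool:
    if rec.effect == CYS_LOSS and rec.context is not None and rec.context.kind in (
        PRODOMAIN_CONSERVED,
        LIGAND,
    ):
        return True
    if rec.effect == CYS_GAIN and rec.near_region:
        return True
    return False


def qualifying_heterodimer_evidence(
    catalog: Sequence[MutationRecord], family_ids: Iterable[str]
) -> dict[str, dict[str, list[MutationRecord]]]:
    """phenotype_key -> protein -> qualifying records (family proteins only)."""
    family = set(family_ids)
    out: dict[str, dict[str, list[MutationRecord]]] = {}
    for rec in catalog:
        if rec.protein not in family or rec.phenotype_key is None:
            continue
        if _is_qualifying(rec):
            out.setdefault(rec.phenotype_key, {}).setdefault(rec.protein, []).append(rec)
    return out


def _scope(a: str, b: str, subfamilies: Mapping[str, str]) -> str:
    return (
        WITHIN_SUBFAMILY
        if subfamilies.get(a) == subfamilies.get(b)
        else ACROSS_SUBFAMILY
    )


def propose_heterodimers(
    catalog: Sequence[MutationRecord],
    family_ids: Iterable[str],
    subfamilies: Mapping[str, str],
    known: KnownInteractionSet,
) -> list[InteractionHypothesis]:
    """Propose heterodimer pairs from shared qualifying phenotypes.

    For each phenotype, one hypothesis per unordered pair of distinct family
    proteins with qualifying evidence.  When exactly one protein holds the
    phenotype's qualifying evidence and it spans >= 2 distinct precursor
    positions, a homotypic dimer hypothesis is emitted instead.  Output is
    deduplicated and sorted by (phenotype, members).
    """
    evidence = qualifying_heterodimer_evidence(catalog, family_ids)
    hyps: dict[tuple[str, tuple[str, str]], InteractionHypothesis] = {}
    for phen in sorted(evidence):
        by_protein = evidence[phen]
        proteins = sorted(by_protein)
        if len(proteins) == 1:
            (p,) = proteins
            positions = {r.position for r in by_protein[p]}
            if len(positions) >= 2:
                members = (p, p)
                hyps[(phen, members)] = InteractionHypothesis(
                    kind=HETERODIMER,
                    members=members,
                    phenotype_key=phen,
                    supporting_mutation_ids=tuple(r.id for r in by_protein[p]),
                    scope=WITHIN_SUBFAMILY,
                    novel=(p, p) not in known,
                )
            continue
        for a, b in combinations(proteins, 2):
            members = tuple(sorted((a, b)))
            support = tuple(r.id for p in members for r in by_protein[p])
            hyps[(phen, members)] = InteractionHypothesis(
                kind=HETERODIMER,
                members=members,
                phenotype_key=phen,
                supporting_mutation_ids=support,
                scope=_scope(a, b, subfamilies),
                novel=members not in known,
            )
    return sorted(hyps.values(), key=InteractionHypothesis.sort_key)


def propose_partner_interactions(
    catalog: Sequence[MutationRecord],
    family_ids: Iterable[str],
    partner_ids: Iterable[str],
    known: KnownInteractionSet,
) -> list[InteractionHypothesis]:
    """Propose (family protein, partner) edges from shared phenotypes.

    Anchors are cysteine losses at conserved prodomain positions; for each
    anchor phenotype, every partner with >= 1 cysteine-loss record sharing it
    yields one edge carrying all supporting mutations.  Edges are
    deduplicated per (phenotype, family, partner) and sorted.
    """
    family = set(family_ids)
    partners = set(partner_ids)
    anchors: dict[str, dict[str, list[MutationRecord]]] = {}
    for rec in catalog:
        if (
            rec.protein in family
            and rec.phenotype_key is not None
            and rec.effect == CYS_LOSS
            and rec.context is not None
            and rec.context.kind == PRODOMAIN_CONSERVED
        ):
            anchors.setdefault(rec.phenotype_key, {}).setdefault(rec.protein, []).append(rec)
    partner_loss: dict[str, dict[str, list[MutationRecord]]] = {}
    for rec in catalog:
        if rec.protein in partners and rec.phenotype_key and rec.effect == CYS_LOSS:
            partner_loss.setdefault(rec.phenotype_key, {}).setdefault(rec.protein, []).append(rec)
    hyps: dict[tuple[str, tuple[str, str]], InteractionHypothesis] = {}
    for phen in sorted(anchors):
        if phen not in partner_loss:
            continue
        for fam_protein in sorted(anchors[phen]):
            for partner in sorted(partner_loss[phen]):
                members = tuple(sorted((fam_protein, partner)))
                support = tuple(
                    r.id for r in anchors[phen][fam_protein]
                ) + tuple(r.id for r in partner_loss[phen][partner])
                hyps[(phen, members)] = InteractionHypothesis(
                    kind=PARTNER_BINDING,
                    members=members,
                    phenotype_key=phen,
                    supporting_mutation_ids=support,
                    scope=SCOPE_NA,
                    novel=members not in known,
                )
    return sorted(hyps.values(), key=InteractionHypothesis.sort_key)


def summarize_hypotheses(
    hypotheses: Sequence[InteractionHypothesis],
    subfamilies: Mapping[str, str] | None = None,
    family_ids: Iterable[str] = (),
) -> dict:
    """Deterministic headline counts over distinct novel pairs.

    Heterodimers: distinct novel pairs, split within/across subfamily (a
    homotypic pair counts as within, credited to its subfamily).  Partner
    edges: distinct novel (family, partner) pairs and distinct partners.
    """
    subfamilies = subfamilies or {}
    family = set(family_ids)
    het_pairs: dict[frozenset, InteractionHypothesis] = {}
    edge_pairs: dict[frozenset, InteractionHypothesis] = {}
    for h in hypotheses:
        if not h.novel:
            continue
        target = het_pairs if h.kind == HETERODIMER else edge_pairs
        target.setdefault(h.pair, h)
    within_by_sub: dict[str, int] = {}
    across = 0
    for h in het_pairs.values():
        if h.scope == WITHIN_SUBFAMILY:
            sub = subfamilies.get(h.members[0], "?")
            within_by_sub[sub] = within_by_sub.get(sub, 0) + 1
        else:
            across += 1
    partners = set()
    for h in edge_pairs.values():
        for m in h.members:
            if m not in family:
                partners.add(m)
    return {
        "heterodimers": {
            "novel_pairs": len(het_pairs),
            "within_subfamily": sum(within_by_sub.values()),
            "within_by_subfamily": dict(sorted(within_by_sub.items())),
            "across_subfamily": across,
        },
        "partner_edges": {
            "novel_edges": len(edge_pairs),
            "distinct_partners": len(partners),
        },
    }


def count_potential_tb_partnerships(
    conserved: pd.DataFrame,
    subfamilies: Mapping[str, str],
    partner_domains: Sequence,
    exclude: Iterable[str] = ("TGFB1",),
) -> int:
    """Potential pairings of AssnCys@1 family proteins with TB-domain partners.

    Counts family proteins (outgroup excluded) carrying an Association-region
    CYS@1, minus the excluded established case (TGFB1), times the number of
    partner proteins annotated with at least one 8-cysteine TB domain.
    """
    holders = {
        row["protein"]
        for _, row in conserved.iterrows()
        if row["region"] == "ASSN"
        and row["label"] == "CYS@1"
        and subfamilies.get(row["protein"]) not in (None, "outgroup")
    } - set(exclude)
    tb_partners = {d.partner for d in partner_domains if d.kind == "TB8CYS"}
    return len(holders) * len(tb_partners)


def _as_dict(h: InteractionHypothesis) -> dict:
    return {
        "kind": h.kind,
        "members": list(h.members),
        "phenotype_key": h.phenotype_key,
        "supporting_mutation_ids": list(h.supporting_mutation_ids),
        "scope": h.scope,
        "novel": h.novel,
    }


def write_hypotheses_json(
    hypotheses: Sequence[InteractionHypothesis], path: str | Path
) -> None:
    with open(path, "w") as fh:
        json.dump([_as_dict(h) for h in hypotheses], fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_hypotheses_tsv(
    hypotheses: Sequence[InteractionHypothesis], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "kind": h.kind,
                "member_a": h.members[0],
                "member_b": h.members[1],
                "phenotype_key": h.phenotype_key,
                "scope": h.scope,
                "novel": int(h.novel),
                "n_support": len(h.supporting_mutation_ids),
            }
            for h in hypotheses
        ]
    ).to_csv(path, sep="\t", index=False)
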