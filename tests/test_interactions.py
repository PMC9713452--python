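"""Common-phenotype inference versus a brute-force oracle, plus fixture cases."""

import random

import pytest

from tgfcys.interactions import (
    KnownInteractionSet,
    propose_heterodimers,
    propose_partner_interactions,
    summarize_hypotheses,
)
from tgfcys.mutation_catalog import (
    CYS_GAIN,
    CYS_LOSS,
    Context,
    MutationRecord,
)

# ---------------------------------------------------------------------------
# Brute-force oracle: an independent double loop over phenotypes and protein
# pairs, re-deriving qualification from raw record fields.


def oracle_heterodimers(catalog, family_ids, known):
    def qualifies(r):
        if r.phenotype_key is None or r.protein not in set(family_ids):
            return False
        if r.effect == CYS_LOSS and r.context.kind in ("PRODOMAIN_CONSERVED", "LIGAND"):
            return True
        return r.effect == CYS_GAIN and r.near_region

    phenotypes = sorted({r.phenotype_key for r in catalog if qualifies(r)})
    out = set()
    for phen in phenotypes:
        holders = sorted(
            {r.protein for r in catalog if qualifies(r) and r.phenotype_key == phen}
        )
        if len(holders) == 1:
            p = holders[0]
            positions = {
                r.position
                for r in catalog
                if qualifies(r) and r.phenotype_key == phen and r.protein == p
            }
            if len(positions) >= 2:
                out.add((phen, (p, p), (p, p) not in known))
        else:
            for i, a in enumerate(holders):
                for b in holders[i + 1 :]:
                    out.add((phen, tuple(sorted((a, b))), (a, b) not in known))
    return out


def oracle_partner_edges(catalog, family_ids, partner_ids, known):
    family, partners = set(family_ids), set(partner_ids)
    out = set()
    for anchor in catalog:
        if (
            anchor.protein not in family
            or anchor.phenotype_key is None
            or anchor.effect != CYS_LOSS
            or anchor.context.kind != "PRODOMAIN_CONSERVED"
        ):
            continue
        for rec in catalog:
            if (
                rec.protein in partners
                and rec.effect == CYS_LOSS
                and rec.phenotype_key == anchor.phenotype_key
            ):
                members = tuple(sorted((anchor.protein, rec.protein)))
                out.add((anchor.phenotype_key, members, members not in known))
    return out


def _record(i, protein, position, effect, context_kind, phenotype, near=False):
    ref, alt = ("C", "R") if effect == CYS_LOSS else ("R", "C")
    if effect == "OTHER":
        ref, alt = "A", "V"
    return MutationRecord(
        id=f"m{i}",
        protein=protein,
        position=position,
        ref=ref,
        alt=alt,
        phenotype_raw=phenotype,
        source="synthetic",
        near_region=near,
        phenotype_key=phenotype,
        effect=effect if effect != "OTHER" else "OTHER",
        context=Context(context_kind),
    )


def _random_catalog(rng, n_family, n_partners):
    family = [f"F{i}" for i in range(n_family)]
    partners = [f"X{i}" for i in range(n_partners)]
    phenotypes = ["alpha", "beta", "gamma", "delta"]
    contexts_family = ["PRODOMAIN_CONSERVED", "LIGAND", "PRODOMAIN_OTHER"]
    catalog = []
    for i in range(rng.randint(5, 40)):
        if rng.random() < 0.7:
            protein = rng.choice(family)
            kind = rng.choice(contexts_family)
        else:
            protein = rng.choice(partners)
            kind = rng.choice(["PARTNER_DOMAIN", "UNMAPPED"])
        effect = rng.choice([CYS_LOSS, CYS_LOSS, CYS_GAIN, "OTHER"])
        catalog.append(
            _record(
                i,
                protein,
                rng.randint(1, 60),
                effect,
                kind,
                rng.choice(phenotypes),
                near=rng.random() < 0.3,
            )
        )
    return catalog, family, partners


@pytest.mark.parametrize("seed", range(25))
def test_heterodimers_match_bruteforce_oracle(seed):
    rng = random.Random(seed)
    catalog, family, partners = _random_catalog(rng, rng.randint(2, 20), 4)
    known = KnownInteractionSet([(family[0], family[1])])
    subfamilies = {p: ("TGF-beta" if i % 2 else "BMP") for i, p in enumerate(family)}
    got = {
        (h.phenotype_key, h.members, h.novel)
        for h in propose_heterodimers(catalog, family, subfamilies, known)
    }
    assert got == oracle_heterodimers(catalog, family, known)


@pytest.mark.parametrize("seed", range(25))
def test_partner_edges_match_bruteforce_oracle(seed):
    rng = random.Random(seed + 1000)
    catalog, family, partners = _random_catalog(rng, rng.randint(2, 20), 5)
    known = KnownInteractionSet([(family[0], partners[0])])
    got = {
        (h.phenotype_key, h.members, h.novel)
        for h in propose_partner_interactions(catalog, family, partners, known)
    }
    assert got == oracle_partner_edges(catalog, family, partners, known)


def test_three_holders_give_three_pairs():
    catalog = [
        _record(i, p, 10 + i, CYS_LOSS, "PRODOMAIN_CONSERVED", "shared")
        for i, p in enumerate(["F0", "F1", "F2"])
    ]
    hyps = propose_heterodimers(
        catalog, ["F0", "F1", "F2", "F3"], {}, KnownInteractionSet()
    )
    assert len(hyps) == 3  # C(3,2)


def test_catalog_row_order_invariance(catalog, fx, known):
    forward = propose_heterodimers(catalog, fx.family_ids, fx.subfamilies, known)
    backward = propose_heterodimers(
        list(reversed(catalog)), fx.family_ids, fx.subfamilies, known
    )
    assert [(h.members, h.phenotype_key, h.novel) for h in forward] == [
        (h.members, h.phenotype_key, h.novel) for h in backward
    ]


def test_phenotype_removal_locality(catalog, fx, known):
    # dropping one phenotype's records removes exactly its hypotheses
    full = propose_heterodimers(catalog, fx.family_ids, fx.subfamilies, known)
    target = "colon adenocarcinoma"
    reduced_catalog = [r for r in catalog if r.phenotype_key != target]
    reduced = propose_heterodimers(reduced_catalog, fx.family_ids, fx.subfamilies, known)
    kept = [h for h in full if h.phenotype_key != target]
    assert [(h.members, h.phenotype_key) for h in reduced] == [
        (h.members, h.phenotype_key) for h in kept
    ]
    assert any(h.phenotype_key == target for h in full)


class TestFixtureHeterodimers:
    def _by_phen(self, catalog, fx, known, phen):
        return [
            h
            for h in propose_heterodimers(catalog, fx.family_ids, fx.subfamilies, known)
            if h.phenotype_key == phen
        ]

    def test_colon_adenocarcinoma_pairs_gdf5_gdf6(self, catalog, fx, known):
        hyps = self._by_phen(catalog, fx, known, "colon adenocarcinoma")
        assert [(h.members, h.novel) for h in hyps] == [(("GDF5", "GDF6"), True)]

    def test_endometrial_group_keeps_known_pair_non_novel(self, catalog, fx, known):
        hyps = self._by_phen(catalog, fx, known, "endometrial adenocarcinoma")
        got = {h.members: h.novel for h in hyps}
        assert got == {
            ("INHA", "INHBB"): False,
            ("INHA", "TGFB2"): True,
            ("INHBB", "TGFB2"): True,
        }

    def test_holt_oram_sole_holder_yields_homotypic(self, catalog, fx, known):
        hyps = self._by_phen(catalog, fx, known, "holt-oram syndrome")
        assert [(h.members, h.novel, h.scope) for h in hyps] == [
            (("TGFB2", "TGFB2"), True, "WITHIN_SUBFAMILY")
        ]

    def test_camurati_homotypic_suppressed_as_known(self, catalog, fx, known):
        hyps = self._by_phen(catalog, fx, known, "camurati-engelmann disease")
        assert [(h.members, h.novel) for h in hyps] == [(("TGFB1", "TGFB1"), False)]

    def test_summary_headline_counts(self, catalog, fx, known):
        hets = propose_heterodimers(catalog, fx.family_ids, fx.subfamilies, known)
        edges = propose_partner_interactions(catalog, fx.family_ids, fx.partner_ids, known)
        s = summarize_hypotheses(hets + edges, fx.subfamilies, fx.family_ids)
        assert s["heterodimers"]["novel_pairs"] == 7
        assert s["heterodimers"]["within_by_subfamily"] == {
            "Activin": 1,
            "BMP": 1,
            "TGF-beta": 2,
        }
        assert s["heterodimers"]["across_subfamily"] == 3
        assert s["partner_edges"] == {"novel_edges": 17, "distinct_partners": 8}

    def test_empty_catalog_gives_zero_counts(self, fx, known):
        s = summarize_hypotheses([], fx.subfamilies, fx.family_ids)
        assert s["heterodimers"]["novel_pairs"] == 0
        assert s["partner_edges"]["novel_edges"] == 0


class TestFixturePartnerEdges:
    def test_inhbe_plasma_cell_partners(self, catalog, fx, known):
        edges = propose_partner_interactions(catalog, fx.family_ids, fx.partner_ids, known)
        inhbe = sorted(
            {m for h in edges if "INHBE" in h.members for m in h.members} - {"INHBE"}
        )
        assert inhbe == ["FBN1", "FBN2", "FBN3", "LTBP1"]

    def test_tgfb2_endometrial_partner_count(self, catalog, fx, known):
        edges = propose_partner_interactions(catalog, fx.family_ids, fx.partner_ids, known)
        tgfb2 = {
            m
            for h in edges
            if "TGFB2" in h.members and h.phenotype_key == "endometrial adenocarcinoma"
            for m in h.members
        } - {"TGFB2"}
        assert len(tgfb2) == 8

    def test_no_phenotype_overlap_gives_no_edges(self, fx, known):
        catalog = [
            _record(0, "INHBE", 29, CYS_LOSS, "PRODOMAIN_CONSERVED", "unique-a"),
            _record(1, "LTBP1", 1022, CYS_LOSS, "PARTNER_DOMAIN", "unique-b"),
        ]
        assert (
            propose_partner_interactions(catalog, fx.family_ids, fx.partner_ids, known)
            == []
        )
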