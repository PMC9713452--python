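"""Consensus shading, conserved-column detection, and Cys@ labelling."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tgfcys.conservation import (
    GAP,
    IDENTITY,
    SIMILAR,
    UNSHADED,
    Alignment,
    RegionWindow,
    SimilarityScheme,
    assign_cys_labels,
    conserved_cys_columns,
    render_shaded_html,
    render_shaded_text,
    shade_alignment,
    shade_cells,
    summarize_conservation,
)

SCHEME = SimilarityScheme()


class TestShadeCells:
    def test_unanimous_column_is_identity(self):
        assert shade_cells(["C"] * 10, SCHEME, 0.2) == [IDENTITY] * 10

    def test_all_gaps_unshaded(self):
        assert shade_cells([GAP] * 5, SCHEME, 0.2) == [UNSHADED] * 5

    def test_group_plurality_split(self):
        # 3 D + 2 E + 5 G at cutoff 0.5: the D/E group reaches 5/10 with D the
        # plurality residue, so D is identity-shaded and E similarity-shaded;
        # G reaches 5/10 on its own. (Hand enumeration of the counts.)
        column = ["D"] * 3 + ["E"] * 2 + ["G"] * 5
        got = shade_cells(column, SCHEME, 0.5)
        assert got == [IDENTITY] * 3 + [SIMILAR] * 2 + [IDENTITY] * 5

    def test_below_cutoff_unshaded(self):
        column = ["D"] * 3 + ["E"] * 2 + ["G"] * 5
        assert shade_cells(column, SCHEME, 0.6) == [UNSHADED] * 10

    def test_gaps_dilute_denominator(self):
        # 2 C out of 10 rows is 0.2 with gaps counted; at 0.25 it fails
        column = ["C", "C"] + [GAP] * 8
        assert shade_cells(column, SCHEME, 0.2)[:2] == [IDENTITY, IDENTITY]
        assert shade_cells(column, SCHEME, 0.25)[:2] == [UNSHADED, UNSHADED]

    def test_x_never_matches(self):
        assert shade_cells(["X"] * 10, SCHEME, 0.2) == [UNSHADED] * 10

    @pytest.mark.parametrize("cutoff", [0, -0.1, 1.5])
    def test_invalid_cutoff_errors(self, cutoff):
        with pytest.raises(ValueError):
            shade_cells(["A"], SCHEME, cutoff)

    def test_row_permutation_equivariance(self):
        import random

        rng = random.Random(7)
        column = ["D", "E", "G", GAP, "C", "D", "K", "R", "S", "T"]
        base = shade_cells(column, SCHEME, 0.2)
        for _ in range(5):
            perm = list(range(len(column)))
            rng.shuffle(perm)
            shuffled = shade_cells([column[i] for i in perm], SCHEME, 0.2)
            assert shuffled == [base[i] for i in perm]


def _toy_alignment(rows, starts=None):
    return Alignment(rows, starts=starts or {rid: 1 for rid, _ in rows})


class TestConservedColumns:
    def test_unanimous_column_included_at_any_threshold(self):
        rows = [(f"P{i}", "CA") for i in range(33)]
        aln = _toy_alignment(rows)
        win = RegionWindow("B8", 1, 2)
        assert conserved_cys_columns(aln, win, 1.0) == [1]

    def test_fractional_threshold_boundary(self):
        # 7 of 33 rows (0.212) passes a 0.2 threshold, 6 of 33 (0.182) fails
        for n_cys, expected in [(7, [1]), (6, [])]:
            rows = [(f"P{i}", "C" if i < n_cys else "A") for i in range(33)]
            aln = _toy_alignment(rows)
            assert conserved_cys_columns(aln, RegionWindow("B8", 1, 1), 0.2) == expected

    def test_window_without_cysteines_is_empty(self):
        aln = _toy_alignment([("A", "ADE"), ("B", "ADE")])
        assert conserved_cys_columns(aln, RegionWindow("ASSN", 1, 3), 0.2) == []

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_threshold_monotonicity(self, data):
        # raising the threshold can only shrink the conserved-column set
        n_rows = data.draw(st.integers(2, 12))
        width = data.draw(st.integers(1, 15))
        rows = [
            (
                f"P{i}",
                "".join(
                    data.draw(st.sampled_from("CCAG-")) for _ in range(width)
                ),
            )
            for i in range(n_rows)
        ]
        aln = _toy_alignment(rows)
        win = RegionWindow("B8", 1, width)
        t1 = data.draw(st.floats(0.05, 1.0))
        t2 = data.draw(st.floats(t1, 1.0))
        assert set(conserved_cys_columns(aln, win, t2)) <= set(
            conserved_cys_columns(aln, win, t1)
        )


class TestCoordinateMapping:
    def test_gap_aware_mapping(self):
        aln = _toy_alignment([("P", "A-C")], starts={"P": 30})
        assert aln.column_to_residue("P", 1) == 30
        assert aln.column_to_residue("P", 2) is None
        assert aln.column_to_residue("P", 3) == 31

    def test_unknown_protein_errors(self):
        aln = _toy_alignment([("P", "AC")])
        with pytest.raises(KeyError):
            aln.column_to_residue("Q", 1)

    def test_round_trip_on_fixture(self, fx):
        # residue_to_column(column_to_residue(c)) == c for all non-gap cells
        aln = fx.alignment
        for rid in aln.ids[::5]:
            row = aln.row(rid)
            for col in range(1, aln.width + 1, 7):
                if row[col - 1] == GAP:
                    continue
                pos = aln.column_to_residue(rid, col)
                assert aln.residue_to_column(rid, pos) == col

    def test_mapped_positions_are_cysteines(self, fx, conserved):
        # every conserved-table position is 'C' in both alignment and precursor
        records = fx.records_by_id()
        for _, row in conserved.iterrows():
            rec = records[row["protein"]]
            assert rec.precursor[row["position"] - 1] == "C"
            col = fx.alignment.residue_to_column(row["protein"], row["position"])
            assert fx.alignment.row(row["protein"])[col - 1] == "C"


class TestAssignLabels:
    def _labels(self, fx, conserved, protein, region):
        sub = conserved[
            (conserved["protein"] == protein) & (conserved["region"] == region)
        ]
        return dict(zip(sub["label"], sub["position"]))

    def test_tgfb1_beta8_pair(self, fx, conserved):
        assert self._labels(fx, conserved, "TGFB1", "B8") == {
            "CYS@1": 223,
            "CYS@3": 225,
        }

    def test_inhba_beta8_pair(self, fx, conserved):
        assert self._labels(fx, conserved, "INHBA", "B8") == {
            "CYS@1": 244,
            "CYS@4": 247,
        }

    def test_tgfb2_beta8_triplet(self, fx, conserved):
        assert self._labels(fx, conserved, "TGFB2", "B8") == {
            "CYS@1": 254,
            "CYS@3": 256,
            "CYS@4": 257,
        }

    def test_assn_anchor_positions(self, fx, conserved):
        assert self._labels(fx, conserved, "TGFB1", "ASSN") == {"CYS@1": 33}
        assert self._labels(fx, conserved, "INHBE", "ASSN") == {
            "CYS@1": 26,
            "CYS@4": 29,
        }

    def test_no_conserved_columns_gives_empty_table(self):
        aln = _toy_alignment([("A", "ADE"), ("B", "ADE")])
        table = assign_cys_labels(aln, RegionWindow("ASSN", 1, 3), [])
        assert table.empty

    def test_label_uniqueness_invariant(self, conserved):
        assert not conserved.duplicated(["protein", "region", "label"]).any()


class TestSummarize:
    def test_census_counts(self, fx, conserved):
        s = summarize_conservation(conserved, fx.subfamilies, fx.config["n_family"])
        assert s["regions"]["B8"]["n_proteins"] == 21
        assert s["regions"]["B8"]["by_subfamily"] == {
            "Activin": 4,
            "BMP": 13,
            "TGF-beta": 4,
        }
        assert s["regions"]["ASSN"]["n_proteins"] == 16
        assert s["regions"]["ASSN"]["by_subfamily"] == {
            "Activin": 6,
            "BMP": 5,
            "TGF-beta": 5,
        }
        assert s["regions"]["B8"]["pct_of_family"] == 64
        assert s["regions"]["ASSN"]["pct_of_family"] == 48
        assert s["overall"]["n_proteins"] == 24

    def test_outgroup_excluded(self, fx, conserved):
        assert "GDNF" in set(conserved["protein"])  # present in the table
        s = summarize_conservation(conserved, fx.subfamilies, 33)
        total = sum(
            s["regions"][r]["by_subfamily"].get(sub, 0)
            for r in ("ASSN", "B8")
            for sub in ("TGF-beta", "Activin", "BMP")
        )
        assert total == 16 + 21  # outgroup contributes nowhere

    def test_empty_table_gives_zeros(self, fx):
        empty = pd.DataFrame(columns=["protein", "region", "position", "label"])
        s = summarize_conservation(empty, fx.subfamilies, 33)
        assert s["overall"]["n_proteins"] == 0
        assert s["regions"]["B8"]["n_proteins"] == 0


class TestRenderers:
    def test_text_rendering_case_encoding(self):
        aln = _toy_alignment([("A", "DG"), ("B", "EG"), ("C", "D-")])
        shading = shade_alignment(aln, SCHEME, 0.5)
        text = render_shaded_text(aln, shading)
        lines = [l for l in text.splitlines() if l.strip()]
        assert lines[0].split()[1] == "DG"  # D identity-upper, G identity
        assert lines[1].split()[1] == "eG"  # E similar-lower
        assert lines[2].split()[1] == "D-"  # gap kept

    def test_html_contains_both_classes(self):
        aln = _toy_alignment([("A", "DG"), ("B", "EG"), ("C", "DA")])
        html = render_shaded_html(aln, shade_alignment(aln, SCHEME, 0.5))
        assert "class='id'" in html and "class='sim'" in html
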