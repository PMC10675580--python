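"""Digest conversion, table I/O, non-detect policies and summaries."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ovorisk import (
    DEFAULT_PANEL, DigestionRecord, convert_concentration, read_element_table,
    substitute_nondetects, summarize_elements, write_element_table,
)
from ovorisk.panel import ElementPanel

from conftest import make_table


class TestConvertConcentration:
    @pytest.mark.parametrize(
        "cs, vs, wt, expected",
        [
            (500.0, 0.05, 0.5, 50.0),
            (0.0, 0.05, 0.5, 0.0),
            (1000.0, 0.05, 0.5, 100.0),  # the 50 mL / 0.5 g digest prep
        ],
    )
    def test_direct_evaluation(self, cs, vs, wt, expected):
        rec = DigestionRecord("s", solution_conc=cs, volume=vs, dry_mass=wt)
        assert convert_concentration(rec) == pytest.approx(expected)

    def test_nondetect_propagates(self):
        rec = DigestionRecord("s", math.nan, 0.05, 0.5, nondetect=True)
        assert math.isnan(convert_concentration(rec))

    @pytest.mark.parametrize("field", ["volume", "dry_mass"])
    def test_nonpositive_inputs_name_the_field(self, field):
        kwargs = {"volume": 0.05, "dry_mass": 0.5}
        kwargs[field] = 0.0
        with pytest.raises(ValueError, match=field):
            convert_concentration(DigestionRecord("s", 10.0, **kwargs))

    @given(
        cs=st.floats(0.01, 1e5), vs=st.floats(1e-3, 1.0),
        wt=st.floats(1e-3, 10.0), k=st.floats(0.1, 10.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_linear_in_cs_inverse_in_wt(self, cs, vs, wt, k):
        base = convert_concentration(DigestionRecord("s", cs, vs, wt))
        scaled = convert_concentration(DigestionRecord("s", k * cs, vs, wt))
        heavier = convert_concentration(DigestionRecord("s", cs, vs, k * wt))
        assert scaled == pytest.approx(k * base, rel=1e-12)
        assert heavier == pytest.approx(base / k, rel=1e-12)


class TestElementTableInvariants:
    def test_duplicate_sample_part_rejected(self):
        t = make_table({("E1", "white"): {"Na": 1.0}, ("E2", "white"): {"Na": 2.0}})
        t.data.loc[1, "sample_id"] = "E1"
        with pytest.raises(ValueError, match="duplicated"):
            t.validate()

    def test_negative_concentration_rejected(self):
        t = make_table({("E1", "white"): {"Na": 1.0}, ("E2", "white"): {"Na": 2.0}})
        t.data.loc[0, "Na"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            t.validate()

    def test_unknown_part_rejected(self):
        t = make_table({("E1", "white"): {"Na": 1.0}})
        t.data.loc[0, "egg_part"] = "membrane"
        with pytest.raises(ValueError, match="egg_part"):
            t.validate()


class TestCsvRoundTrip:
    def test_bit_exact_values_and_flags(self, tmp_path, default_table):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_element_table(default_table, p1)
        back = read_element_table(p1)
        write_element_table(back, p2)
        again = read_element_table(p2)
        a = back.data[back.elements].to_numpy()
        b = again.data[again.elements].to_numpy()
        assert np.array_equal(a, b, equal_nan=True)
        assert back.nd.equals(again.nd)
        # values survive the first write too
        orig = default_table.data[default_table.elements].to_numpy()
        assert np.array_equal(orig, a, equal_nan=True)
        assert default_table.nd.to_numpy().sum() == back.nd.to_numpy().sum()

    def test_nd_cells_parsed_and_excluded_from_means(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "sample_id,egg_part,system,Na\n"
            "E1,white,home,10.0\nE2,white,home,ND\nE3,white,home,30.0\n"
        )
        t = read_element_table(p)
        assert t.nd["Na"].tolist() == [False, True, False]
        s = summarize_elements(t, by=None)
        row = s[s.element == "Na"].iloc[0]
        assert row["mean"] == pytest.approx(20.0)  # not (10+0+30)/3
        assert row["n"] == 2

    def test_unknown_element_column_warns_and_drops(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("sample_id,egg_part,system,Na,Xx\nE1,white,home,1.0,2.0\n")
        with pytest.warns(UserWarning, match="Xx"):
            t = read_element_table(p)
        assert t.elements == ["Na"]

    def test_missing_metadata_is_an_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("sample_id,egg_part,Na\nE1,white,1.0\n")
        with pytest.raises(ValueError, match="system"):
            read_element_table(p)

    def test_thousands_separators_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text('sample_id,egg_part,system,Na\nE1,white,home,"15,373.56"\n')
        with pytest.raises(ValueError):
            read_element_table(p)

    def test_duplicated_pair_in_file_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "sample_id,egg_part,system,Na\n"
            "E1,white,home,1.0\nE1,white,home,2.0\n"
        )
        with pytest.raises(ValueError, match="duplicated"):
            read_element_table(p)


class TestNondetectPolicies:
    @pytest.fixture
    def nd_table(self):
        return make_table({
            ("E1", "white"): {"Cd": "ND", "Pb": 1.0},
            ("E2", "white"): {"Cd": 0.02, "Pb": 2.0},
            ("E3", "white"): {"Cd": 0.04, "Pb": "ND"},
            ("E4", "white"): {"Cd": 0.06, "Pb": 4.0},
            ("E5", "white"): {"Cd": "ND", "Pb": 5.0},
        })

    def test_zero_policy(self, nd_table):
        out = substitute_nondetects(nd_table, "zero")
        assert not out.has_nondetects()
        assert out.data["Cd"].tolist()[0] == 0.0

    def test_half_lod_policy(self, nd_table):
        out = substitute_nondetects(nd_table, "half_lod", lod={"Cd": 0.01, "Pb": 0.5})
        assert out.data["Cd"].iloc[0] == pytest.approx(0.005)
        assert out.data["Pb"].iloc[2] == pytest.approx(0.25)

    def test_half_lod_without_lod_errors(self, nd_table):
        with pytest.raises(ValueError, match="LOD"):
            substitute_nondetects(nd_table, "half_lod")

    def test_drop_policy_shrinks_n(self, nd_table):
        out = substitute_nondetects(nd_table, "drop")
        s = summarize_elements(out, by=None)
        assert s.set_index("element").loc["Cd", "n"] == 3  # 5 rows - 2 ND
        assert s.set_index("element").loc["Pb", "n"] == 4

    def test_unknown_policy(self, nd_table):
        with pytest.raises(ValueError, match="policy"):
            substitute_nondetects(nd_table, "impute")


class TestSummaries:
    def test_hand_built_min_mean_max(self):
        t = make_table({
            ("E1", "white"): {"Na": 1.0},
            ("E2", "white"): {"Na": 2.0},
            ("E3", "white"): {"Na": 3.0},
        })
        row = summarize_elements(t).iloc[0]
        assert (row["min"], row["max"], row["mean"]) == (1.0, 3.0, 2.0)

    def test_single_row_group(self):
        t = make_table({("E1", "yolk"): {"Zn": 33.0}})
        row = summarize_elements(t).iloc[0]
        assert row["min"] == row["max"] == row["mean"] == 33.0

    def test_min_le_mean_le_max_everywhere(self, default_table):
        s = summarize_elements(default_table, by=("egg_part", "system"))
        ok = s.dropna(subset=["mean"])
        assert (ok["min"] <= ok["mean"] + 1e-12).all()
        assert (ok["mean"] <= ok["max"] + 1e-12).all()


class TestPanel:
    def test_default_panel_has_64_disjoint_symbols(self):
        assert len(DEFAULT_PANEL) == 64
        assert len(set(DEFAULT_PANEL.symbols)) == 64

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            ElementPanel(groups={"a": ("Na", "K"), "b": ("K",)})

    def test_json_round_trip(self, tmp_path):
        p = tmp_path / "panel.json"
        DEFAULT_PANEL.to_json(p)
        assert ElementPanel.from_json(p).symbols == DEFAULT_PANEL.symbols
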