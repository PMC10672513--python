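"""Concentration-table IO, relative abundance and class-level accounting."""

import numpy as np
import pandas as pd
import pytest

from lipidchains.lipidome import (
    ClassSummary,
    OverlapCounts,
    aggregate_categories,
    class_summary,
    detection_overlap,
    diversity_abundance_correlation,
    pe_pc_ratio,
    read_table,
    relative_abundance,
    to_long_csv,
)
from lipidchains.reference import reference_class_summaries

from conftest import make_table


class TestReadTable:
    def _long_df(self):
        return pd.DataFrame(
            {
                "sample_id": ["s1", "s1", "s2", "s2"],
                "group": ["Day1", "Day1", "Day19", "Day19"],
                "lipid_name": ["PC(16:0_18:1)", "TG(16:0_16:0_16:0)"] * 2,
                "concentration": [1.0, 3.0, 2.0, 6.0],
            }
        )

    def test_long_layout_round_trip(self, tmp_path):
        path = tmp_path / "t.csv"
        self._long_df().to_csv(path, index=False)
        table = read_table(str(path), "long")
        assert len(table.samples) == 2
        assert set(table.species) == {"PC(16:0_18:1)", "TG(16:0_16:0_16:0)"}
        assert table.values.loc["s2", "TG(16:0_16:0_16:0)"] == 6.0

    def test_wide_and_long_layouts_agree(self, tmp_path):
        lpath = tmp_path / "l.csv"
        self._long_df().to_csv(lpath, index=False)
        wide = pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "group": ["Day1", "Day19"],
                "PC(16:0_18:1)": [1.0, 2.0],
                "TG(16:0_16:0_16:0)": [3.0, 6.0],
            }
        )
        wpath = tmp_path / "w.csv"
        wide.to_csv(wpath, index=False)
        t_long = read_table(str(lpath), "long")
        t_wide = read_table(str(wpath), "wide")
        pd.testing.assert_frame_equal(
            t_long.values.sort_index(axis=1), t_wide.values.sort_index(axis=1)
        )
        assert [s.group for s in t_long.samples] == [s.group for s in t_wide.samples]

    def test_duplicate_cell_rejected(self, tmp_path):
        df = self._long_df()
        df.loc[len(df)] = ["s1", "Day1", "PC(16:0_18:1)", 5.0]
        path = tmp_path / "d.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_table(str(path), "long")

    def test_alias_spellings_of_same_species_rejected(self, tmp_path):
        df = self._long_df()
        df.loc[len(df)] = ["s1", "Day1", "PC(16:0/18:1)", 5.0]
        path = tmp_path / "a.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="same species"):
            read_table(str(path), "long")

    def test_negative_concentration_rejected(self, tmp_path):
        df = self._long_df()
        df.loc[0, "concentration"] = -1.0
        path = tmp_path / "n.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="negative|non-finite"):
            read_table(str(path), "long")

    def test_unparseable_name_reported(self, tmp_path):
        df = self._long_df()
        df.loc[0, "lipid_name"] = "PC(16:0_xx)"
        path = tmp_path / "u.csv"
        df.to_csv(path, index=False)
        with pytest.raises(Exception, match="16:0_xx|malformed"):
            read_table(str(path), "long")

    def test_synthetic_round_trip_through_csv(self, synthetic_table, tmp_path):
        table, _ = synthetic_table
        path = tmp_path / "synth.csv"
        to_long_csv(table, str(path))
        again = read_table(str(path), "long")
        assert len(again.samples) == 32
        assert set(again.species) == set(table.species)
        classes = {sp.class_code for sp in again.species.values()}
        assert len(classes) == 15


class TestRelativeAbundance:
    def test_single_species_is_hundred_percent(self):
        t = make_table({"s1": "Day1"}, {"LPC(16:0)": [4.2]})
        assert relative_abundance(t).iloc[0, 0] == pytest.approx(100.0)

    def test_two_species_split(self):
        t = make_table(
            {"s1": "Day1"}, {"LPC(16:0)": [1.0], "LPC(18:1)": [3.0]}
        )
        rel = relative_abundance(t)
        assert rel.loc["s1", "LPC(16:0)"] == pytest.approx(25.0)
        assert rel.loc["s1", "LPC(18:1)"] == pytest.approx(75.0)

    def test_rows_sum_to_hundred_on_synthetic(self, synthetic_table):
        table, _ = synthetic_table
        sums = relative_abundance(table).sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_all_zero_sample_named_in_error(self):
        t = make_table(
            {"s1": "Day1", "s2": "Day1"},
            {"LPC(16:0)": [1.0, 0.0], "LPC(18:1)": [1.0, 0.0]},
        )
        with pytest.raises(ValueError, match="s2"):
            relative_abundance(t)


class TestClassSummary:
    def test_diversity_and_abundance_by_hand(self):
        t = make_table(
            {"a1": "Day1", "a2": "Day1", "b1": "Day19"},
            {
                "PC(16:0_18:1)": [1.0, 3.0, 2.0],
                "PC(16:0_18:2)": [1.0, 1.0, 0.0],
                "PE(16:0_18:1)": [2.0, 4.0, 2.0],
            },
        )
        rows = {(s.class_code, s.group): s for s in class_summary(t)}
        assert rows[("PC", "Day1")].diversity == 2
        assert rows[("PC", "Day19")].diversity == 1
        assert rows[("PE", "Day19")].diversity == 1
        # sample a1: PC 50%, a2: PC 50% -> mean 50, sd 0
        assert rows[("PC", "Day1")].abundance_pct == pytest.approx(50.0)
        assert rows[("PC", "Day1")].abundance_se == pytest.approx(0.0)
        assert rows[("TG", "Day1")].diversity == 0
        assert rows[("TG", "Day1")].abundance_pct == 0.0

    def test_abundances_sum_to_hundred_per_group(self, synthetic_table):
        table, _ = synthetic_table
        summaries = class_summary(table)
        for group in table.groups:
            total = sum(s.abundance_pct for s in summaries if s.group == group)
            assert total == pytest.approx(100.0, abs=1e-9)

    def test_min_replicate_threshold_reduces_diversity(self):
        t = make_table(
            {"a1": "Day1", "a2": "Day1"},
            {"PC(16:0_18:1)": [1.0, 0.0], "PE(16:0_18:1)": [1.0, 1.0]},
        )
        one = {s.class_code: s.diversity for s in class_summary(t, 1) if s.group == "Day1"}
        two = {s.class_code: s.diversity for s in class_summary(t, 2) if s.group == "Day1"}
        assert one["PC"] == 1 and two["PC"] == 0
        assert one["PE"] == two["PE"] == 1

    def test_diversity_invariant_to_sample_rescaling(self, synthetic_table):
        table, _ = synthetic_table
        scaled = make_table(
            {s.sample_id: s.group for s in table.samples},
            {
                name: (table.values[name] * np.linspace(1, 7, len(table.samples))).tolist()
                for name in list(table.species)[:50]
            },
        )
        base = make_table(
            {s.sample_id: s.group for s in table.samples},
            {name: table.values[name].tolist() for name in list(table.species)[:50]},
        )
        d_scaled = {(s.class_code, s.group): s.diversity for s in class_summary(scaled)}
        d_base = {(s.class_code, s.group): s.diversity for s in class_summary(base)}
        assert d_scaled == d_base


class TestAggregation:
    def test_category_rows_are_sums_of_member_classes(self):
        cats = {
            (c.category, c.group): c
            for c in aggregate_categories(reference_class_summaries())
        }
        assert cats[("Neutral lipids", "Day1")].diversity == 213
        assert cats[("Neutral lipids", "Day1")].abundance_pct == pytest.approx(36.5)
        assert cats[("Phospholipids", "Day19")].diversity == 148
        assert cats[("Ether phospholipids", "Day19")].abundance_pct == pytest.approx(
            3.47
        )

    def test_empty_input_gives_no_rows(self):
        assert aggregate_categories([]) == []


class TestOverlap:
    def test_union_is_sum_of_parts(self):
        assert OverlapCounts(332, 43, 46).union == 421

    def test_disjoint_and_identical_groups(self):
        t = make_table(
            {"a": "Day1", "b": "Day19"},
            {"PC(16:0_18:1)": [1.0, 0.0], "PE(16:0_18:1)": [0.0, 1.0]},
        )
        ov = detection_overlap(t, "Day1", "Day19")
        assert (ov.shared, ov.only_a, ov.only_b) == (0, 1, 1)
        t2 = make_table(
            {"a": "Day1", "b": "Day19"},
            {"PC(16:0_18:1)": [1.0, 2.0]},
        )
        ov2 = detection_overlap(t2, "Day1", "Day19")
        assert (ov2.shared, ov2.only_a, ov2.only_b) == (1, 0, 0)

    def test_symmetric_under_group_swap(self, synthetic_table):
        table, _ = synthetic_table
        ab = detection_overlap(table, "Day1", "Day19")
        ba = detection_overlap(table, "Day19", "Day1")
        assert ab.shared == ba.shared and ab.union == ba.union
        assert (ab.only_a, ab.only_b) == (ba.only_b, ba.only_a)

    def test_unknown_group_rejected(self, synthetic_table):
        table, _ = synthetic_table
        with pytest.raises(ValueError, match="unknown group"):
            detection_overlap(table, "Day1", "Day99")


class TestRatiosAndCorrelation:
    def test_equal_pe_pc_gives_unity(self):
        rows = [
            ClassSummary("PE", "Day1", 5, 10.0, 0.1),
            ClassSummary("PC", "Day1", 5, 10.0, 0.1),
        ]
        assert pe_pc_ratio(rows, "Day1") == pytest.approx(1.0)

    def test_zero_pc_rejected(self):
        rows = [
            ClassSummary("PE", "Day1", 5, 10.0, 0.1),
            ClassSummary("PC", "Day1", 0, 0.0, 0.0),
        ]
        with pytest.raises(ValueError, match="PC abundance"):
            pe_pc_ratio(rows, "Day1")

    def test_proportional_abundance_gives_perfect_correlation(self):
        rows = [
            ClassSummary(c, "Day1", d, 2.5 * d, 0.0)
            for c, d in [("PC", 10), ("PE", 20), ("TG", 40), ("CL", 5)]
        ]
        assert diversity_abundance_correlation(rows, "Day1") == pytest.approx(1.0)
        assert diversity_abundance_correlation(
            rows, "Day1", transform="identity"
        ) == pytest.approx(1.0)

    def test_too_few_positive_classes_rejected(self):
        rows = [
            ClassSummary("PC", "Day1", 10, 5.0, 0.1),
            ClassSummary("PE", "Day1", 0, 0.0, 0.0),
            ClassSummary("TG", "Day1", 3, 1.0, 0.1),
        ]
        with pytest.raises(ValueError, match=">=3 classes"):
            diversity_abundance_correlation(rows, "Day1")

    def test_zero_variance_rejected(self):
        rows = [
            ClassSummary(c, "Day1", 10, a, 0.0)
            for c, a in [("PC", 1.0), ("PE", 2.0), ("TG", 3.0)]
        ]
        with pytest.raises(ValueError, match="zero variance"):
            diversity_abundance_correlation(rows, "Day1")
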