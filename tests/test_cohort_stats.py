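import numpy as np
import pandas as pd
import pytest

from immunoprofile.cohort_stats import (
    aa_composition,
    apply_filters,
    chi_squared,
    compare_aa_composition,
    coverage_summary,
    disorder_by_position,
    length_bin_analysis,
    length_bin_label,
    mann_whitney,
    success_rate_by_group,
    wb_specificity_by_length,
)

from .oracles import exact_mannwhitney_p, textbook_chi2


def records_frame(**overrides):
    base = dict(label=["successful"] * 4 + ["unsuccessful"] * 2,
                immunogen_length=[30, 40, 50, 25, 45, 35],
                protein_length=[300, 500, 1000, 150, 800, 400])
    base.update(overrides)
    return pd.DataFrame(base)


class TestFilters:
    def test_boundaries(self):
        df = records_frame(
            immunogen_length=[50, 51, 30, 30, 30, 30],
            protein_length=[500, 500, 99, 100, 2000, 2001])
        kept, reasons = apply_filters(df)
        assert list(kept.index) == [0, 3, 4]
        assert reasons["immunogen_too_long"] == 1
        assert reasons["protein_length_out_of_range"] == 2

    def test_unclassified_excluded(self):
        df = records_frame(label=["successful", "unclassified", "unsuccessful",
                                  "successful", "unclassified", "successful"])
        kept, reasons = apply_filters(df)
        assert reasons["unclassified_label"] == 2
        assert set(kept["label"]) == {"successful", "unsuccessful"}

    def test_idempotent(self):
        df = records_frame()
        once, _ = apply_filters(df)
        twice, reasons = apply_filters(once)
        pd.testing.assert_frame_equal(once, twice)
        assert all(v == 0 for v in reasons.values())


class TestChiSquared:
    def test_closed_form_2x2(self):
        stat, p = chi_squared([[30, 10], [10, 30]])
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 80*640000/2560000
        assert stat == pytest.approx(20.0, abs=1e-12)

    def test_identical_rows(self):
        stat, p = chi_squared([[20, 20], [20, 20]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_random_tables_match_textbook_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            table = rng.integers(1, 60, size=(2, 3))
            stat, p = chi_squared(table)
            ref_stat, ref_p = textbook_chi2(table)
            assert stat == pytest.approx(ref_stat, abs=1e-10)
            assert p == pytest.approx(ref_p, abs=1e-10)

    def test_zero_marginal_is_error(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_squared([[0, 0], [5, 3]])


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_samples(self):
        u, p = mann_whitney([1.5, 2.5, 3.5], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.5

    def test_matches_exact_enumeration(self):
        # continuous samples: tie-free, so the exact branch applies
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.normal(size=rng.integers(3, 8))
            y = rng.normal(size=rng.integers(3, 8))
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(exact_mannwhitney_p(x, y), abs=1e-9)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestGroupedRates:
    def test_example_rates_and_statistic(self):
        df = pd.DataFrame({
            "label": ["successful"] * 30 + ["unsuccessful"] * 10
            + ["successful"] * 10 + ["unsuccessful"] * 30,
            "group": ["A"] * 40 + ["B"] * 40,
        })
        table = success_rate_by_group(df, "group")
        assert table.rate("A") == 0.75
        assert table.rate("B") == 0.25
        assert table.statistic == pytest.approx(20.0)

    def test_single_group_skips_test(self):
        df = pd.DataFrame({"label": ["successful"] * 5, "group": ["A"] * 5})
        table = success_rate_by_group(df, "group")
        assert table.rate("A") == 1.0
        assert table.test_name is None

    def test_rates_reproduce_from_raw_labels(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "label": rng.choice(["successful", "unsuccessful"], 200),
            "group": rng.choice(["x", "y", "z"], 200),
        })
        table = success_rate_by_group(df, "group")
        for row in table.rows:
            sub = df[df["group"] == row.group_label]
            assert row.n_total == len(sub)
            assert row.n_success == (sub["label"] == "successful").sum()
            assert 0.0 <= row.success_rate <= 1.0

    def test_unclassified_records_rejected(self):
        df = pd.DataFrame({"label": ["successful", "unclassified"],
                           "group": ["A", "B"]})
        with pytest.raises(ValueError):
            success_rate_by_group(df, "group")

    def test_disorder_by_position_excludes_unavailable(self):
        df = pd.DataFrame({
            "label": ["successful"] * 6 + ["unsuccessful"] * 2,
            "disorder_class": ["high", "low", "medium", "unavailable",
                               "high", "low", "medium", "low"],
            "position_class": ["terminus", "center"] * 4,
        })
        tables = disorder_by_position(df)
        assert set(tables) == {"all", "terminus", "center"}
        assert sum(r.n_total for r in tables["all"].rows) == 7


class TestLengthBins:
    def test_default_bin_labels(self):
        assert length_bin_label(19) == "<30"
        assert length_bin_label(29) == "<30"
        assert length_bin_label(30) == "30-49"
        assert length_bin_label(109) == "90-109"
        assert length_bin_label(110) == ">=110"
        assert length_bin_label(202) == ">=110"

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            length_bin_label(210)
        with pytest.raises(ValueError):
            length_bin_label(10)

    def test_single_populated_bin(self):
        df = pd.DataFrame({"label": ["successful"] * 4,
                           "immunogen_length": [25] * 4})
        table = length_bin_analysis(df)
        assert [r.group_label for r in table.rows] == ["<30"]

    def test_strong_length_effect_gives_monotone_rates(self):
        rng = np.random.default_rng(4)
        lengths = rng.integers(19, 203, size=4000)
        p = 1 / (1 + np.exp(-(-1.0 + 0.03 * (lengths - 19))))
        labels = np.where(rng.random(4000) < p, "successful", "unsuccessful")
        df = pd.DataFrame({"label": labels, "immunogen_length": lengths})
        rates = [r.success_rate for r in length_bin_analysis(df).rows]
        assert rates == sorted(rates)

    def test_wb_specificity_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "immunogen_length": rng.integers(19, 203, size=300),
            "wb_specificity": rng.choice(
                ["specific", "unspecific", "no_binding", "untested"], 300),
        })
        out = wb_specificity_by_length(df)
        np.testing.assert_allclose(
            out[["specific", "unspecific", "no_binding"]].sum(axis=1), 1.0)


class TestCoverage:
    PROTEOME = pd.DataFrame({
        "protein_id": ["P1", "P2", "P3"],
        "protein_length": [300, 500, 200],
        "localization": ["cytoplasm", "membrane", "nucleus"],
    })

    def test_counting_example(self):
        records = pd.DataFrame({
            "protein_id": ["P1", "P1", "P2"],
            "outcome_wb": ["approved", "untested", "uncertain"],
            "outcome_ihc": ["approved", "approved", "approved"],
            "outcome_icc": ["untested", "untested", "supported"],
        })
        out = coverage_summary(records, self.PROTEOME)
        assert out["covered_fraction"] == pytest.approx(2 / 3)
        assert out["multi_antibody_fraction"] == pytest.approx(1 / 3)
        assert out["single_antibody_fraction"] == pytest.approx(1 / 3)
        assert out["technologies"]["ihc"]["tested_fraction"] == 1.0

    def test_no_antibodies(self):
        records = pd.DataFrame({"protein_id": [], "outcome_wb": [],
                                "outcome_ihc": [], "outcome_icc": []})
        assert coverage_summary(records, self.PROTEOME)["covered_fraction"] == 0

    def test_unknown_protein_is_error(self):
        records = pd.DataFrame({
            "protein_id": ["P9"], "outcome_wb": ["approved"],
            "outcome_ihc": ["untested"], "outcome_icc": ["untested"]})
        with pytest.raises(ValueError, match="unknown"):
            coverage_summary(records, self.PROTEOME)


class TestComposition:
    def test_frequencies(self):
        freq = aa_composition(["AAG"])
        assert freq.sum() == pytest.approx(1.0)
        idx = {aa: i for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}
        assert freq[idx["A"]] == pytest.approx(2 / 3)
        assert freq[idx["G"]] == pytest.approx(1 / 3)

    def test_identical_sets_have_zero_statistic(self):
        stat, p = compare_aa_composition(["MKLV", "AAG"], ["MKLV", "AAG"])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            aa_composition([])
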