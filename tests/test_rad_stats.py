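import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import vagidyn as v
from vagidyn.errors import UsageError, ValidationError

from conftest import make_design


def _paired_table(values_by_sample, taxa=("Lactobacillus", "other")):
    """Two-taxon relative table from {sample: lactobacillus abundance}."""
    data = {
        sid: [p, 1 - p] for sid, p in values_by_sample.items()
    }
    return v.AbundanceTable(
        pd.DataFrame(data, index=list(taxa)), mode="relative"
    )


class TestComputeRads:
    def test_simple_subtraction(self):
        design = make_design([
            ("S1", "P1", "placebo", "V1"), ("S2", "P1", "placebo", "D7"),
        ])
        table = _paired_table({"S1": 0.80, "S2": 0.95})
        rads = v.compute_rads(table, design, "Lactobacillus", "V1", "D7")
        assert rads["rad"].tolist() == pytest.approx([0.15])

    def test_missing_sample_omits_participant(self):
        design = make_design([
            ("S1", "P1", "placebo", "V1"), ("S2", "P1", "placebo", "D7"),
            ("S3", "P2", "placebo", "V1"),
        ])
        table = _paired_table({"S1": 0.8, "S2": 0.9, "S3": 0.7})
        rads = v.compute_rads(table, design, "Lactobacillus", "V1", "D7")
        assert rads["participant_id"].tolist() == ["P1"]

    def test_taxon_absent_in_both_yields_zero(self):
        design = make_design([
            ("S1", "P1", "placebo", "V1"), ("S2", "P1", "placebo", "D7"),
        ])
        table = v.AbundanceTable(
            pd.DataFrame({"S1": [0.0, 1.0], "S2": [0.0, 1.0]},
                         index=["Lactobacillus", "other"]),
            mode="relative",
        )
        rads = v.compute_rads(table, design, "Lactobacillus", "V1", "D7")
        assert rads["rad"].tolist() == [0.0]

    def test_equal_timepoints_rejected(self):
        design = make_design([("S1", "P1", "placebo", "V1")])
        table = _paired_table({"S1": 0.5})
        with pytest.raises(UsageError):
            v.compute_rads(table, design, "Lactobacillus", "V1", "V1")

    def test_rads_bounded(self, default_cohort):
        sub = v.aggregate_taxa(v.to_relative(default_cohort.counts), "subgenus_group")
        rads = v.compute_rads(sub, default_cohort.design, "L_iners_group", "V1", "V3")
        assert rads["rad"].between(-1, 1).all()


class TestSignedRank:
    def test_five_uniform_signs_exact_p(self):
        # 2 * P(all 5 positive) = 2/32
        assert v.signed_rank_test([0.1, 0.2, 0.3, 0.4, 0.5]) == pytest.approx(0.0625)

    def test_all_zero_differences(self):
        assert v.signed_rank_test([0.0, 0.0, 0.0]) == 1.0

    def test_paired_consistency_with_abundance_columns(self, default_cohort):
        """p computed on RADs equals p computed from the paired columns."""
        gen = v.aggregate_taxa(v.to_relative(default_cohort.counts), "genus")
        rads = v.compute_rads(gen, default_cohort.design, "Lactobacillus", "D7", "V2")
        pairs = default_cohort.design.paired_samples("D7", "V2")
        lacto = gen.values.loc["Lactobacillus"]
        x = lacto[pairs["sample2"]].to_numpy()
        y = lacto[pairs["sample1"]].to_numpy()
        assert v.signed_rank_test(rads["rad"].to_numpy()) == pytest.approx(
            v.signed_rank_test(x - y)
        )


class TestHodgesLehmann:
    def test_hand_example(self):
        assert v.hodges_lehmann([1, 2, 3], [0, 1]) == pytest.approx(1.5)

    def test_identical_singletons(self):
        assert v.hodges_lehmann([3.0], [3.0]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            v.hodges_lehmann([], [1.0])

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=30),
        st.lists(st.floats(-5, 5), min_size=1, max_size=30),
        st.floats(-3, 3),
    )
    def test_matches_brute_force_and_translation(self, x, y, delta):
        brute = float(np.median([xi - yi for xi in x for yi in y]))
        est = v.hodges_lehmann(x, y)
        assert est == pytest.approx(brute, abs=1e-12)
        assert v.hodges_lehmann(np.array(x) + delta, y) == pytest.approx(
            est + delta, abs=1e-9
        )


class TestByAdjust:
    def test_hand_computed_example(self):
        # c(3) = 11/6; adjusted = {0.0550, 0.0550, 0.0917} after step-up
        adj = v.by_adjust([0.01, 0.02, 0.05])
        assert adj == pytest.approx([0.055, 0.055, 0.0916667], abs=5e-5)

    def test_single_p_scaled_by_c1_only(self):
        assert v.by_adjust([0.04]) == pytest.approx([0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            v.by_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_dominates_input_and_capped(self, p):
        adj = v.by_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.randoms())
    def test_permutation_invariant(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        adj = v.by_adjust(p)
        adj_perm = v.by_adjust([p[i] for i in perm])
        assert np.allclose([adj[i] for i in perm], adj_perm, atol=1e-12)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.random(rng.integers(1, 30))
            ours = v.by_adjust(p)
            ref = multipletests(p, method="fdr_by")[1]
            assert np.allclose(ours, ref, atol=1e-12)


class TestMedianRadMatrix:
    def test_median_of_three(self):
        design = make_design([
            ("A1", "P1", "placebo", "V1"), ("A2", "P1", "placebo", "D7"),
            ("B1", "P2", "placebo", "V1"), ("B2", "P2", "placebo", "D7"),
            ("C1", "P3", "placebo", "V1"), ("C2", "P3", "placebo", "D7"),
        ])
        table = _paired_table({
            "A1": 0.50, "A2": 0.60,   # +0.10
            "B1": 0.50, "B2": 0.55,   # +0.05
            "C1": 0.50, "C2": 0.70,   # +0.20
        })
        mat = v.median_rad_matrix(table, design, "Lactobacillus")
        assert mat.cell("V1", "D7")["median_rad"] == pytest.approx(0.10)
        assert mat.cell("V1", "D7")["n"] == 3

    def test_untested_cells_excluded_from_by_family(self):
        design = make_design([
            ("A1", "P1", "placebo", "V1"), ("A2", "P1", "placebo", "D7"),
            ("B1", "P2", "placebo", "V1"), ("B2", "P2", "placebo", "D7"),
        ])
        table = _paired_table({"A1": 0.5, "A2": 0.6, "B1": 0.5, "B2": 0.7})
        mat = v.median_rad_matrix(table, design, "Lactobacillus")
        tested = mat.cells[mat.cells["tested"]]
        assert len(tested) == 1  # only (V1, D7) has >= 2 pairs
        assert np.isnan(mat.cell("V1", "D14")["p_adj"])

    def test_antisymmetry_under_reversed_orientation(self, default_cohort):
        sub = v.aggregate_taxa(v.to_relative(default_cohort.counts), "subgenus_group")
        rads = v.compute_rads(sub, default_cohort.design, "L_crispatus_group", "D7", "V2")
        lacto = sub.values.loc["L_crispatus_group"]
        pairs = default_cohort.design.paired_samples("D7", "V2")
        reversed_rads = lacto[pairs["sample1"]].to_numpy() - lacto[pairs["sample2"]].to_numpy()
        assert np.median(reversed_rads) == pytest.approx(-np.median(rads["rad"]), abs=1e-12)

    def test_p_adj_dominates_p_raw(self, default_cohort):
        sub = v.aggregate_taxa(v.to_relative(default_cohort.counts), "subgenus_group")
        mat = v.median_rad_matrix(sub, default_cohort.design, "L_iners_group")
        tested = mat.cells[mat.cells["tested"]]
        assert (tested["p_adj"] >= tested["p_raw"] - 1e-12).all()
        assert tested["p_raw"].between(0, 1).all()


class TestDifferentialRad:
    def test_identical_arms_give_zero_shift(self):
        rows, values = [], {}
        for i in range(4):
            arm = "placebo" if i < 2 else "treatment"
            rows += [(f"S{i}a", f"P{i}", arm, "V1"), (f"S{i}b", f"P{i}", arm, "D7")]
            values[f"S{i}a"] = 0.5
            values[f"S{i}b"] = 0.5 + [0.1, 0.2][i % 2]  # same RADs in both arms
        mat = v.differential_rad_matrix(
            _paired_table(values), make_design(rows), "Lactobacillus"
        )
        cell = mat.cell("V1", "D7")
        assert cell["hl_estimate"] == 0.0
        assert cell["p_raw"] == pytest.approx(1.0)

    def test_hl_example_with_convention(self):
        rows, values = [], {}
        rads_t, rads_p = [1, 2, 3], [0, 1]
        for i, r in enumerate(rads_t):
            rows += [(f"T{i}a", f"T{i}", "treatment", "V1"), (f"T{i}b", f"T{i}", "treatment", "D7")]
            values[f"T{i}a"] = 0.1
            values[f"T{i}b"] = 0.1 + r / 10
        for i, r in enumerate(rads_p):
            rows += [(f"Q{i}a", f"Q{i}", "placebo", "V1"), (f"Q{i}b", f"Q{i}", "placebo", "D7")]
            values[f"Q{i}a"] = 0.1
            values[f"Q{i}b"] = 0.1 + r / 10
        table = _paired_table(values)
        design = make_design(rows)
        mat = v.differential_rad_matrix(table, design, "Lactobacillus")
        assert mat.cell("V1", "D7")["hl_estimate"] == pytest.approx(0.15)
        flipped = v.differential_rad_matrix(
            table, design, "Lactobacillus", convention="placebo_minus_treatment"
        )
        assert flipped.cell("V1", "D7")["hl_estimate"] == pytest.approx(-0.15)
        assert flipped.cell("V1", "D7")["p_raw"] == mat.cell("V1", "D7")["p_raw"]

    def test_unknown_convention_rejected(self, default_cohort):
        gen = v.aggregate_taxa(v.to_relative(default_cohort.counts), "genus")
        with pytest.raises(UsageError):
            v.differential_rad_matrix(
                gen, default_cohort.design, "Lactobacillus", convention="sideways"
            )


class TestCrossSectional:
    def test_closed_form_h(self):
        design = make_design([
            ("S1", "P1", "placebo", "V1"), ("S2", "P2", "placebo", "V1"),
            ("S3", "P3", "placebo", "V1"), ("S4", "P4", "treatment", "V1"),
            ("S5", "P5", "treatment", "V1"), ("S6", "P6", "treatment", "V1"),
        ])
        values = pd.Series(
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
            index=["S1", "S2", "S3", "S4", "S5", "S6"],
        )
        h, p = v.cross_sectional_test(None, design, None, "V1", values=values)
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_identical_groups(self):
        design = make_design([
            ("S1", "P1", "placebo", "V1"), ("S2", "P2", "placebo", "V1"),
            ("S3", "P3", "placebo", "V1"), ("S4", "P4", "treatment", "V1"),
            ("S5", "P5", "treatment", "V1"), ("S6", "P6", "treatment", "V1"),
        ])
        values = pd.Series(
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            index=["S1", "S2", "S3", "S4", "S5", "S6"],
        )
        h, p = v.cross_sectional_test(None, design, None, "V1", values=values)
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_group_kw_equals_ranksums(self):
        """Tie-free two-group Kruskal-Wallis equals the (uncorrected) normal
        rank-sum test asymptotically: H = z^2."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        y = rng.normal(0.5, size=15)
        h, p_kw = stats.kruskal(x, y)
        p_rs = stats.ranksums(x, y).pvalue
        assert p_kw == pytest.approx(p_rs, abs=1e-6)

    def test_metric_option_on_qpcr_log10(self, default_cohort):
        conc = default_cohort.qpcr.concentrations["L_crispatus"]
        log10 = np.log10(conc[conc > 0])
        mat = v.median_rad_matrix(None, default_cohort.design, None, values=log10)
        assert mat.cells["tested"].any()
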