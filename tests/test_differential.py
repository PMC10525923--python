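"""Welch and Student t-tests, BH adjustment, volcano and class-level analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from csflipidomics import (
    PipelineConfig,
    SimulationSpec,
    bh_adjust,
    class_total_comparison,
    curate_classes,
    demographics_test,
    generate,
    overall_abundance_comparison,
    qc_geomean_normalize,
    subject_group_totals,
    volcano_table,
    welch_t,
    within_class_tests,
)


def brute_force_bh(p):
    """Step-up definition computed literally: p_adj(i) = min_{j>=i} m*p(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestWelch:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_equal_variance_case(self):
        # s^2 = 5/3 on both sides, se = sqrt(2 * (5/3)/4), t = -1/se
        res = welch_t([1, 2, 3, 4], [2, 3, 4, 5])
        assert res.t_stat == pytest.approx(-1.0954451, abs=1e-6)
        assert res.df == pytest.approx(6.0)
        assert res.p_value == pytest.approx(0.3153336, abs=1e-6)

    def test_antisymmetric_under_swap(self):
        a, b = [1.0, 2.5, 3.1, 4.0], [2.0, 4.5, 5.5]
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.t_stat == pytest.approx(-r2.t_stat)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_missing_values_dropped(self):
        res = welch_t([1, 2, 3, 4, np.nan], [2, 3, 4, 5])
        assert res.t_stat == pytest.approx(-1.0954451, abs=1e-6)

    def test_degenerate_zero_variance(self):
        assert welch_t([2.0, 2.0], [2.0, 2.0]).p_value == 1.0
        with pytest.warns(UserWarning):
            assert welch_t([2.0, 2.0], [3.0, 3.0]).p_value == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestDemographics:
    def test_equal_samples(self):
        assert demographics_test([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_case(self):
        # pooled sd = 1, se = sqrt(2/3), t = -3/se = -3.674, df = 4
        res = demographics_test([1, 2, 3], [4, 5, 6])
        assert res.t_stat == pytest.approx(-3.6742346, abs=1e-6)
        assert res.df == pytest.approx(4.0)
        assert res.p_value == pytest.approx(0.02131, abs=1e-4)

    def test_agrees_with_welch_for_equal_n_equal_variance(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        assert demographics_test(a, b).p_value == pytest.approx(welch_t(a, b).p_value)


class TestBHAdjust:
    def test_stepup_arithmetic_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.037]), [0.037])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_preserved_and_excluded_from_family(self):
        out = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_adjust([0.01, 0.02]))

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(5)
        p = rng.random(40)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_equals_brute_force_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_equals_oracle_on_thousand_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            m = int(rng.integers(1, 60))
            p = rng.random(m)
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


def _filtered_normalized(seed, **spec_kwargs):
    from csflipidomics import descriptive_power, filter_by_dp

    table, truth = generate(SimulationSpec(seed=seed, **spec_kwargs))
    scheme = curate_classes(table.compounds)
    norm = qc_geomean_normalize(table.subset_compounds(scheme.retained_compounds))
    descriptive_power(norm)
    return filter_by_dp(norm, 2.5), scheme, truth


class TestVolcano:
    def test_doubled_mean_gives_log2fc_one(self, tiny_table):
        norm = qc_geomean_normalize(tiny_table)
        norm.intensities.loc["C1"] = [1.0, 3.0, 2.0, 6.0, 1.0, 1.0]  # case = 2x control
        out = volcano_table(norm)
        assert out.at["C1", "log2fc"] == pytest.approx(1.0)

    def test_matches_scalar_welch_per_lipid(self):
        norm, _, _ = _filtered_normalized(2, n_compounds=40)
        out = volcano_table(norm)
        for cid in norm.compound_ids[:10]:
            ref = welch_t(norm.intensities.loc[cid, norm.case_ids],
                          norm.intensities.loc[cid, norm.control_ids])
            assert out.at[cid, "t_stat"] == pytest.approx(ref.t_stat, rel=1e-9)
            assert out.at[cid, "p_raw"] == pytest.approx(ref.p_value, rel=1e-9)
            assert out.at[cid, "df_welch"] == pytest.approx(ref.df, rel=1e-9)

    def test_invariant_to_lipid_order(self):
        norm, _, _ = _filtered_normalized(3, n_compounds=40)
        shuffled = norm.copy()
        rng = np.random.default_rng(1)
        rows = list(shuffled.intensities.index)
        rng.shuffle(rows)
        shuffled.intensities = shuffled.intensities.loc[rows]
        shuffled.compounds = shuffled.compounds.loc[rows]
        shuffled.descriptive_power = shuffled.descriptive_power.loc[rows]
        a = volcano_table(norm).sort_index()
        b = volcano_table(shuffled).sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_log2fc_antisymmetric_under_cohort_swap(self):
        norm, _, _ = _filtered_normalized(4, n_compounds=30)
        swapped = norm.copy()
        roles = swapped.samples["role"].map(
            {"control": "case", "case": "control", "qc": "qc"})
        swapped.samples["role"] = roles
        a = volcano_table(norm)
        b = volcano_table(swapped)
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], rtol=1e-9)
        np.testing.assert_allclose(a["p_raw"], b["p_raw"], rtol=1e-9)

    def test_injected_effects_recovered(self):
        norm, _, truth = _filtered_normalized(
            6, n_differential=10, fold_changes=(8.0,))
        out = volcano_table(norm)
        hits = set(out.index[out["significant"]]) & set(truth.differential_compounds)
        assert len(hits) >= 8
        est = out.loc[[c for c in truth.differential_compounds if c in out.index],
                      "log2fc"]
        assert abs(float(np.median(est)) - 3.0) <= 0.5

    def test_null_rarely_declares_discoveries(self):
        zero = 0
        n_rep = 40
        for seed in range(n_rep):
            norm, _, _ = _filtered_normalized(1000 + seed, n_compounds=120)
            out = volcano_table(norm)
            zero += int(out["significant"].sum() == 0)
        assert zero >= 0.70 * n_rep


class TestClassLevel:
    def test_identical_cohort_totals_give_p_one(self):
        totals = pd.DataFrame(
            {"g1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
             "g2": [5.0, 6.0, 7.0, 5.0, 6.0, 7.0]},
            index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"),
        )
        samples = pd.DataFrame({"role": ["control"] * 3 + ["case"] * 3},
                               index=totals.index)
        out = class_total_comparison(totals, samples)
        np.testing.assert_allclose(out["p_raw"], 1.0)

    def test_shifted_group_flagged(self):
        norm, scheme, _ = _filtered_normalized(8, n_compounds=150)
        totals = subject_group_totals(norm, scheme)
        group = totals.columns[0]
        roles = norm.samples.loc[totals.index, "role"]
        totals.loc[roles == "case", group] *= 4.0
        out = class_total_comparison(totals, norm.samples)
        assert bool(out.at[group, "significant"])

    def test_within_class_single_lipid_padj_equals_praw(self):
        norm, scheme, _ = _filtered_normalized(9, n_compounds=100)
        out = within_class_tests(norm, scheme)
        singles = out.groupby("group").size()
        for group in singles.index[singles == 1]:
            row = out[out["group"] == group].iloc[0]
            assert row["p_adj"] == pytest.approx(row["p_raw"])

    def test_within_class_adjustment_uses_class_family_only(self):
        """Each class's adjusted p-values equal the step-up definition applied
        to that class's raw p-vector alone, and raw p-values match the global
        analysis (only the BH family differs)."""
        norm, scheme, _ = _filtered_normalized(10, n_compounds=120)
        within = within_class_tests(norm, scheme)
        global_out = volcano_table(norm)
        np.testing.assert_allclose(
            within["p_raw"].sort_index().to_numpy(),
            global_out["p_raw"].sort_index().to_numpy(), rtol=1e-12)
        for group, sub in within.groupby("group"):
            ok = sub["p_raw"].notna()
            np.testing.assert_allclose(
                sub.loc[ok, "p_adj"].to_numpy(),
                brute_force_bh(sub.loc[ok, "p_raw"].to_numpy()), atol=1e-12)


class TestOverall:
    def test_identical_cohorts_p_one(self, tiny_table):
        norm = qc_geomean_normalize(tiny_table)
        norm.intensities.loc[:, ["S3", "S4"]] = \
            norm.intensities.loc[:, ["S1", "S2"]].to_numpy()
        res = overall_abundance_comparison(norm)
        assert res.p_value == pytest.approx(1.0)

    def test_doubling_a_cohort_doubles_its_mean(self):
        norm, _, _ = _filtered_normalized(12, n_compounds=60)
        base = overall_abundance_comparison(norm)
        doubled = norm.copy()
        doubled.intensities[doubled.case_ids] *= 2.0
        res = overall_abundance_comparison(doubled)
        assert res.mean_case == pytest.approx(2 * base.mean_case)
        assert res.mean_control == pytest.approx(base.mean_control)

    def test_null_mean_difference_within_three_standard_errors(self):
        ok = 0
        n_rep = 30
        for seed in range(n_rep):
            norm, _, _ = _filtered_normalized(200 + seed, n_compounds=60)
            res = overall_abundance_comparison(norm)
            se = np.sqrt(res.sd_case**2 / len(norm.case_ids)
                         + res.sd_control**2 / len(norm.control_ids))
            ok += int(abs(res.mean_case - res.mean_control) <= 3 * se)
        assert ok >= 0.9 * n_rep
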