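"""Grubbs screening: critical values, iterated flagging, sample exclusion."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from csflipidomics import (
    PipelineConfig,
    SimulationSpec,
    apply_exclusions,
    generate,
    grubbs_critical_value,
    grubbs_flag,
    screen_table,
    seed_sample_outlier_burden,
)

# Published two-sided Grubbs critical values at alpha = 0.05.
PUBLISHED_G_CRIT_05 = {
    3: 1.1543, 4: 1.4812, 5: 1.7150, 6: 1.8871, 7: 2.0200, 8: 2.1266,
    9: 2.2150, 10: 2.2900, 12: 2.4116, 15: 2.5483, 20: 2.7082,
    25: 2.8217, 30: 2.9085,
}


def brute_force_grubbs(values, alpha):
    """Independent oracle: recompute everything from scratch each round."""
    vals = {i: v for i, v in enumerate(values) if np.isfinite(v)}
    flagged = set()
    while len(vals) >= 3:
        idx = list(vals)
        arr = np.array([vals[i] for i in idx])
        mean = sum(arr) / len(arr)
        sd = math.sqrt(sum((v - mean) ** 2 for v in arr) / (len(arr) - 1))
        if sd == 0:
            break
        n = len(arr)
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
        devs = [abs(v - mean) for v in arr]
        j = devs.index(max(devs))
        if devs[j] / sd > crit:
            flagged.add(idx[j])
            del vals[idx[j]]
        else:
            break
    return flagged


class TestCriticalValue:
    def test_matches_published_tables(self):
        for n, expected in PUBLISHED_G_CRIT_05.items():
            assert grubbs_critical_value(n, 0.05) == pytest.approx(expected, abs=5e-3)

    def test_n3_approaches_geometric_bound(self):
        # as n -> 3 the statistic's hard bound is (n-1)/sqrt(n) = 2/sqrt(3)
        assert grubbs_critical_value(3, 0.05) == pytest.approx(1.155, abs=5e-3)
        assert grubbs_critical_value(3, 0.05) < 2 / math.sqrt(3)

    def test_monotone_in_n(self):
        crits = [grubbs_critical_value(n, 0.05) for n in range(3, 51)]
        assert all(a < b for a, b in zip(crits, crits[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            grubbs_critical_value(2, 0.05)


class TestGrubbsFlag:
    def test_constant_data_has_no_outliers(self):
        assert grubbs_flag([1.0] * 5) == set()

    def test_single_gross_outlier_flagged(self):
        # G = (245.57 - mean)/sd ~ 2.47 > 2.127; the remainder is clean
        vals = [199.31, 199.53, 200.19, 200.82, 201.92, 201.95, 202.18, 245.57]
        assert grubbs_flag(vals, 0.05) == {7}

    def test_injected_ten_sigma_value_always_caught(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            x = rng.normal(0, 1, size=21)
            x[7] = 10.0
            assert 7 in grubbs_flag(x, 0.05)

    def test_fewer_than_three_values_returns_empty(self):
        assert grubbs_flag([1.0, 2.0]) == set()
        assert grubbs_flag([1.0, np.nan, 2.0]) == set()

    def test_max_outliers_cap(self):
        # two same-side gross outliers: iterated flags both, the cap stops at one
        x = list(np.linspace(0, 1, 18)) + [50.0, 40.0]
        assert grubbs_flag(x, 0.05) == {18, 19}
        assert grubbs_flag(x, 0.05, max_outliers=1) == {18}

    def test_symmetric_outliers_can_mask_each_other(self):
        # a known Grubbs limitation: equal-and-opposite extremes inflate the
        # sd enough that neither exceeds the bound
        x = list(np.linspace(0, 1, 10)) + [50.0, -50.0]
        assert grubbs_flag(x, 0.05) == brute_force_grubbs(x, 0.05) == set()

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=30),
           st.sampled_from([0.01, 0.05, 0.10]))
    def test_equals_brute_force_oracle(self, values, alpha):
        assert grubbs_flag(values, alpha) == brute_force_grubbs(values, alpha)

    def test_equals_oracle_on_thousand_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(3, 31))
            x = rng.normal(0, 1, size=n)
            if rng.random() < 0.5:  # sprinkle gross outliers
                k = int(rng.integers(1, 3))
                x[rng.choice(n, k, replace=False)] += rng.choice([-1, 1], k) * 8
            assert grubbs_flag(x, 0.05) == brute_force_grubbs(x, 0.05)


class TestScreenTable:
    def test_null_flag_rate_is_small(self):
        table, _ = generate(SimulationSpec(seed=3, n_compounds=200,
                                           n_control=10, n_case=10))
        report = screen_table(table, PipelineConfig())
        fracs = list(report.per_sample_fraction.values())
        assert np.mean(fracs) <= 0.08
        assert not report.excluded_samples

    def test_null_compound_flag_rate_brackets_alpha(self):
        """Fraction of (compound, group) screens with >= 1 flag sits near the
        nominal level under normal data (iterated Grubbs is not exactly
        alpha-level, so only an order-of-magnitude bracket is asserted)."""
        spec = SimulationSpec(seed=17, n_compounds=300)
        table, _ = generate(spec)
        report = screen_table(table, PipelineConfig())
        n_screens = 2 * spec.n_compounds
        rate = len({(c, s) for c, s in report.flags}) / n_screens
        assert 0.5 * 0.025 <= rate <= 2 * 0.10

    def test_qc_samples_never_flagged(self):
        table, _ = generate(SimulationSpec(seed=3))
        report = screen_table(table)
        qc = set(table.qc_ids)
        assert not {s for _, s in report.flags} & qc
        assert not set(report.per_sample_fraction) & qc

    def test_seeded_burden_sample_excluded(self):
        spec = SimulationSpec(seed=8)
        table, _ = generate(spec)
        seeded, _ = seed_sample_outlier_burden(table, "CASE05", 0.25, spec)
        report = screen_table(seeded)
        assert "CASE05" in report.excluded_samples
        assert report.per_sample_fraction["CASE05"] > 0.20

    def test_exclusion_monotone_in_threshold(self):
        spec = SimulationSpec(seed=15)
        table, _ = generate(spec)
        seeded, _ = seed_sample_outlier_burden(table, "CTRL02", 0.25, spec)
        excluded = []
        for frac in (0.05, 0.20, 0.50):
            cfg = PipelineConfig(sample_exclusion_fraction=frac)
            excluded.append(screen_table(seeded, cfg).excluded_samples)
        assert excluded[0] >= excluded[1] >= excluded[2]

    def test_tiny_cohort_rejected(self, tiny_table):
        with pytest.raises(ValueError, match=">= 3"):
            screen_table(tiny_table)


class TestApplyExclusions:
    def test_empty_report_is_identity(self, default_table):
        table, _ = default_table
        report = screen_table(table)
        report.excluded_samples = set()
        report.flags = set()
        out = apply_exclusions(table, report, mode="drop_samples")
        assert out.intensities.equals(table.intensities)

    def test_drop_samples_keeps_flagged_cells_of_retained_samples(self):
        spec = SimulationSpec(seed=8)
        table, _ = generate(spec)
        seeded, _ = seed_sample_outlier_burden(table, "CASE05", 0.25, spec)
        report = screen_table(seeded)
        out = apply_exclusions(seeded, report, mode="drop_samples")
        assert out.n_samples == seeded.n_samples - len(report.excluded_samples)
        retained_flags = [(c, s) for c, s in report.flags
                          if s not in report.excluded_samples]
        if retained_flags:
            c, s = retained_flags[0]
            assert np.isfinite(out.intensities.at[c, s])

    def test_mask_cells_removes_all_flags(self):
        table, _ = generate(SimulationSpec(seed=10, outlier_rate=0.01))
        report = screen_table(table)
        out = apply_exclusions(table, report, mode="mask_cells")
        kept = set(out.samples.index)
        for c, s in report.flags:
            if s in kept:
                assert np.isnan(out.intensities.at[c, s])
        # re-screen finds nothing it already masked
        report2 = screen_table(out)
        assert not {f for f in report2.flags if f in report.flags}

    def test_excluding_whole_cohort_errors(self, default_table):
        table, _ = default_table
        report = screen_table(table)
        report.excluded_samples = set(table.control_ids)
        with pytest.raises(ValueError, match="cohort"):
            apply_exclusions(table, report, mode="drop_samples")

    def test_unknown_mode_rejected(self, default_table):
        table, _ = default_table
        report = screen_table(table)
        with pytest.raises(ValueError):
            apply_exclusions(table, report, mode="nope")
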