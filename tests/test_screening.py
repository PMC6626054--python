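import random

import numpy as np
import pytest

from wormscreen import (
    GroupSummary,
    SpeedRecord,
    call_hits,
    compare_groups,
    dose_response,
    hill_multiplier,
    load_table1,
    ratio_to_control,
    zprime,
)


def summary(mean, sd=0.0, label="g", n=10):
    return GroupSummary(
        label=label, n=n, mean_mm_s=mean, sd_mm_s=sd, sem_mm_s=sd / np.sqrt(n),
        median_mm_s=mean, unweighted_mean_mm_s=mean,
        hist_counts=np.array([n]), hist_edges=np.array([0.0, 1.0]),
    )


class TestZPrime:
    def test_perfect_assay_limit(self):
        assert zprime(summary(0.14), summary(0.042)).zprime == pytest.approx(1.0)

    def test_hand_computed_value(self):
        res = zprime(summary(0.14, 0.014), summary(0.042, 0.0042))
        assert res.zprime == pytest.approx(1.0 - 3.0 * 0.0182 / 0.098, rel=1e-9)
        assert res.zprime == pytest.approx(0.4429, abs=5e-5)

    def test_equal_means_raise(self):
        with pytest.raises(ValueError):
            zprime(summary(0.1, 0.01), summary(0.1, 0.02))

    def test_symmetric_in_group_order_and_decreasing_in_sd(self):
        a, b = summary(0.14, 0.01), summary(0.042, 0.005)
        assert zprime(a, b).zprime == pytest.approx(zprime(b, a).zprime)
        worse = zprime(summary(0.14, 0.02), b).zprime
        assert worse < zprime(a, b).zprime


class TestRatioToControl:
    def test_identity(self):
        g = summary(0.043, 0.01)
        assert ratio_to_control(g, g) == pytest.approx(1.0)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError):
            ratio_to_control(summary(0.05), summary(0.0))

    def test_scale_invariance(self):
        t, c = summary(0.06), summary(0.04)
        t2, c2 = summary(0.6), summary(0.4)
        assert ratio_to_control(t, c) == pytest.approx(ratio_to_control(t2, c2))


@pytest.fixture(scope="module")
def table1():
    return load_table1()


class TestCallHits:
    def test_reference_screen_yields_twelve_hits_topped_by_nifedipine(self, table1):
        compounds = table1[table1["role"] == "treated"]
        pos = float(table1.loc[table1["role"] == "positive_control", "ratio"].iloc[0])
        assert pos == 1.22
        results = call_hits(list(zip(compounds["label"], compounds["ratio"])), pos)
        assert len(results) == 38
        hits = [r for r in results if r.is_hit]
        assert len(hits) == 12
        assert results[0].compound == "Nifedipine"
        assert results[0].ratio == pytest.approx(1.69)
        assert results[0].rank == 1 and results[0].is_hit

    def test_hit_count_invariant_to_input_order(self, table1):
        compounds = list(
            zip(table1[table1["role"] == "treated"]["label"],
                table1[table1["role"] == "treated"]["ratio"])
        )
        random.Random(0).shuffle(compounds)
        results = call_hits(compounds, 1.22)
        assert sum(r.is_hit for r in results) == 12
        assert results[0].compound == "Nifedipine"
        assert sorted(r.rank for r in results) == list(range(1, 39))

    def test_all_below_threshold_gives_no_hits(self):
        results = call_hits([("a", 0.9), ("b", 1.1)], 1.22)
        assert not any(r.is_hit for r in results)

    def test_printed_tie_counts_as_hit(self):
        # "as effective as": equality after rounding to table precision
        results = call_hits([("tie", 1.2249)], 1.2151)
        assert results[0].is_hit

    def test_ratio_one_never_hit_when_control_exceeds_one(self):
        results = call_hits([("inert", 1.0)], 1.22)
        assert not results[0].is_hit

    def test_empty_screen_rejected(self):
        with pytest.raises(ValueError):
            call_hits([], 1.22)


class TestDoseResponse:
    def test_increasing_series_flagged_monotone(self):
        t = dose_response([summary(0.04), summary(0.05), summary(0.06)],
                          [0.0, 10.0, 100.0], "rescue")
        assert t.monotone_increasing and not t.monotone_decreasing

    def test_flat_series_is_monotone_both_ways(self):
        t = dose_response([summary(0.05), summary(0.05)], [0.0, 10.0])
        assert t.monotone_increasing and t.monotone_decreasing

    def test_paralytic_series_flagged_decreasing(self):
        t = dose_response([summary(0.14), summary(0.05), summary(0.01)],
                          [0.0, 100.0, 1000.0], "paralytic")
        assert t.monotone_decreasing and not t.monotone_increasing

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            dose_response([summary(0.05)], [0.0, 1.0])


class TestCompareGroups:
    @staticmethod
    def records(values):
        return [SpeedRecord(i, 0, v, 120.0) for i, v in enumerate(values)]

    def test_identical_groups_give_statistic_zero_p_one(self):
        a = self.records([0.02, 0.04, 0.06, 0.08])
        stat, p = compare_groups(a, a)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_large_separation_is_highly_significant(self):
        rng = np.random.default_rng(2)
        a = self.records(rng.normal(0.043, 0.005, 100))
        b = self.records(rng.normal(0.061, 0.005, 100))
        _, p = compare_groups(a, b)
        assert p < 1e-3

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(self.records([0.1]), self.records([0.1, 0.2]))


class TestHillMultiplier:
    def test_anchors_and_monotonicity(self):
        assert hill_multiplier(0.0, emax=1.7, ec50_um=30.0) == 1.0
        assert hill_multiplier(30.0, emax=1.7, ec50_um=30.0) == pytest.approx(1.35)
        doses = [0.0, 1.0, 10.0, 30.0, 100.0, 1000.0]
        vals = [hill_multiplier(d, 1.7, 30.0) for d in doses]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.7

    def test_paralytic_direction(self):
        vals = [hill_multiplier(d, 0.1, 50.0) for d in [0.0, 10.0, 100.0, 1000.0]]
        assert all(b <= a for a, b in zip(vals, vals[1:]))
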