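"""Rank statistics for the stress time course, checked against brute force."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu as scipy_mwu

from cellcount.timecourse_stats import (
    PairwiseTest,
    TimepointRecord,
    assemble_records,
    baseline_subtract,
    bonferroni,
    endpoint_comparison,
    mann_whitney_u,
    records_to_frame,
    tests_to_frame as pairwise_tests_frame,
)
import pandas as pd


def brute_force_mwu(a, b):
    """Independent oracle: U from pairwise comparisons, p from exhaustive
    enumeration of group assignments of the pooled values."""
    a, b = list(a), list(b)
    u_a = sum(0.5 if x == y else float(x > y) for x in a for y in b)
    u_b = len(a) * len(b) - u_a
    u_obs = min(u_a, u_b)
    pooled = a + b
    n, n_a = len(pooled), len(a)
    hits = total = 0
    for combo in itertools.combinations(range(n), n_a):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(n) if i not in combo]
        ua = sum(0.5 if x == y else float(x > y) for x in ga for y in gb)
        if min(ua, n_a * (n - n_a) - ua) <= u_obs + 1e-12:
            hits += 1
        total += 1
    return u_obs, hits / total


class TestBaselineSubtract:
    def test_simple_series(self):
        assert baseline_subtract([5, 7, 9]) == [0, 2, 4]

    def test_constant_series(self):
        assert baseline_subtract([3.5] * 4) == [0, 0, 0, 0]

    def test_first_element_always_zero(self):
        assert baseline_subtract([-2.0, 11.0, 0.0])[0] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            baseline_subtract([])

    def test_endpoint_telescoping(self):
        series = [4.0, 9.0, 1.0, 12.0]
        d = baseline_subtract(series)
        assert d[-1] - d[0] == series[-1] - series[0]


class TestMannWhitney:
    def test_fully_separated_pairs(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_give_max_u(self):
        for n in (2, 4, 6):
            u, _ = mann_whitney_u(list(range(n)), list(range(n)))
            assert u == n * n / 2

    def test_three_vs_three_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        bu, bp = brute_force_mwu([1, 2, 3], [4, 5, 6])
        assert u == bu == 0.0
        assert p == pytest.approx(bp)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_regime_matches_enumeration(self, seed):
        """All combined sizes up to 10, with ties, against the oracle."""
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(1, 6))
        n_b = int(rng.integers(1, min(6, 11 - n_a)))
        a = rng.integers(0, 5, n_a).astype(float).tolist()  # ties likely
        b = rng.integers(0, 5, n_b).astype(float).tolist()
        u, p = mann_whitney_u(a, b)
        bu, bp = brute_force_mwu(a, b)
        assert u == pytest.approx(bu)
        assert p == pytest.approx(bp)

    def test_u_statistics_are_complementary(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=8).tolist()
        b = rng.normal(size=13).tolist()
        u_min, _ = mann_whitney_u(a, b)
        u_a = sum(0.5 if x == y else float(x > y) for x in a for y in b)
        assert u_min == min(u_a, len(a) * len(b) - u_a)

    def test_large_sample_path_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 10).tolist()
        b = rng.normal(0.8, 1, 10).tolist()
        u, p = mann_whitney_u(a, b)
        ref = scipy_mwu(a, b, method="asymptotic", use_continuity=True)
        assert min(ref.statistic, 100 - ref.statistic) == pytest.approx(u)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_tie_correction_in_large_samples(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 4, 12).astype(float).tolist()
        b = rng.integers(1, 5, 9).astype(float).tolist()
        _, p = mann_whitney_u(a, b)
        ref = scipy_mwu(a, b, method="asymptotic", use_continuity=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestBonferroni:
    def test_explicit_m(self):
        assert bonferroni([0.02], m=6) == [0.12]

    def test_cap_at_one(self):
        assert bonferroni([0.3, 0.9]) == [0.6, 1.0]

    def test_number_of_pairs_of_four_groups(self):
        from math import comb
        assert comb(4, 2) == 6  # endpoint_comparison tests exactly this many

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


def _records_for(groups: dict[str, list[list[float]]]) -> list[TimepointRecord]:
    """Build records from {group: per-field [red_pct at t0, t1, ...]}
    with a constant total of 100 cells (red_count == red_pct)."""
    out = []
    for group, fields in groups.items():
        for fov, series in enumerate(fields):
            for t, red in enumerate(series):
                out.append(
                    TimepointRecord(
                        group=group, dose=0.0, field_of_view=fov, time_index=t,
                        total_count=100.0, red_count=red,
                    )
                )
    return out


class TestEndpointComparison:
    def test_four_groups_give_six_corrected_tests(self):
        rng = np.random.default_rng(0)
        groups = {
            g: [[rng.uniform(0, 5), rng.uniform(0, 5)] for _ in range(5)]
            for g in ("Tu", "TagRFP+", "DMSO", "Int")
        }
        tests = endpoint_comparison(_records_for(groups))
        assert len(tests) == 6
        assert all(isinstance(t, PairwiseTest) for t in tests)
        assert all(t.p_corrected >= t.p_value for t in tests)

    def test_copied_group_is_fully_nonsignificant(self):
        fields = [[1.0, float(i)] for i in range(6)]
        tests = endpoint_comparison(_records_for({"a": fields, "b": list(fields)}))
        assert tests[0].p_corrected == 1.0

    def test_planted_shift_reaches_significance(self):
        rng = np.random.default_rng(42)
        null = lambda: [[rng.normal(10, 3), rng.normal(10, 3)] for _ in range(10)]
        shifted = [[rng.normal(10, 3), rng.normal(30, 3)] for _ in range(10)]
        groups = {"a": null(), "b": null(), "c": null(), "d": shifted}
        tests = endpoint_comparison(_records_for(groups))
        assert len(tests) == 6
        for t in tests:
            involved = "d" in (t.group_a, t.group_b)
            if involved:
                assert t.p_corrected < 0.05
            else:
                assert t.p_corrected > 0.05

    def test_missing_endpoint_is_data_error(self):
        recs = _records_for({"a": [[1, 2]], "b": [[3, 4]]})
        recs = [r for r in recs if not (r.group == "b" and r.time_index == 1)]
        with pytest.raises(ValueError, match="lacks time index"):
            endpoint_comparison(recs)


def test_assemble_and_export_round_trip():
    counts = pd.DataFrame(
        {"path": ["a.tif", "b.tif"], "cell_count": [200.0, 250.0],
         "red_count": [50.0, 100.0]}
    )
    sheet = pd.DataFrame(
        {"path": ["a.tif", "b.tif"], "group": ["Tu", "Tu"], "dose": [10.0, 10.0],
         "field_of_view": [0, 0], "time_index": [0, 1]}
    )
    records = assemble_records(counts, sheet)
    assert [r.red_pct for r in records] == [25.0, 40.0]
    df = records_to_frame(records)
    assert df["red_pct"].tolist() == [25.0, 40.0]
    tests = endpoint_comparison(records + [
        TimepointRecord("Int", 0.0, 0, t, 100.0, v) for t, v in ((0, 5.0), (1, 6.0))
    ])
    out = pairwise_tests_frame(tests)
    assert list(out.columns) == [
        "group_1", "group_2", "u_statistic", "p_value", "corrected_p_value"
    ]
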