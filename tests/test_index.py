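"""MPMI computation, outlier fencing, group tests, cohort labels."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpmi import catalog, index, profiles, simulate as sim
from mpmi.profiles import ECAbundanceMatrix

from conftest import balanced_matrix


class TestComputeMpmi:
    def test_balance_is_100(self, markers):
        results, _ = index.compute_mpmi(balanced_matrix(markers), markers, a=1.0)
        assert results[0].mpmi_value == pytest.approx(100.0)

    def test_linearity(self, markers):
        m = balanced_matrix(markers, n_weight=2.0 / 12, d_weight=1.0 / 10)
        results, _ = index.compute_mpmi(m, markers, a=1.0)
        assert results[0].mpmi_value == pytest.approx(200.0)

    def test_a_scales_index(self, markers):
        results, _ = index.compute_mpmi(balanced_matrix(markers), markers, a=2.5)
        assert results[0].mpmi_value == pytest.approx(250.0)

    def test_toy_matrix_matches_brute_force(self, markers, rng):
        # spreadsheet-style oracle: explicit per-sample sums over roles
        ecs = [m.ec_number for m in markers]
        ab = pd.DataFrame(
            rng.uniform(0.1, 2.0, size=(3, len(ecs))),
            index=["s1", "s2", "s3"],
            columns=ecs,
        )
        roles = {m.ec_number: m.role for m in markers}
        weights = {m.ec_number: m.stoich_weight for m in markers}
        results, _ = index.compute_mpmi(ECAbundanceMatrix(abundance=ab), markers)
        for r in results:
            num = sum(weights[e] * ab.loc[r.sample_id, e] for e in ecs if roles[e] == "N")
            den = sum(weights[e] * ab.loc[r.sample_id, e] for e in ecs if roles[e] == "D")
            assert r.mpmi_value == pytest.approx(100.0 * num / den)
            assert r.numerator_sum == pytest.approx(num)
            assert r.denominator_sum == pytest.approx(den)

    def test_stoich_weights_enter_sums(self, markers):
        reweighted = [
            catalog.MarkerReaction(
                m.ec_number, m.kegg_ids, m.role,
                stoich_weight=3.0 if m.ec_number == "1.2.1.5" else 1.0,
            )
            for m in markers
        ]
        m1 = balanced_matrix(markers)
        base, _ = index.compute_mpmi(m1, markers)
        rew, _ = index.compute_mpmi(m1, reweighted)
        assert rew[0].numerator_sum == pytest.approx(
            base[0].numerator_sum + 2.0 / 12
        )

    def test_zero_denominator_flagged_not_dropped(self, markers):
        num = sorted(m.ec_number for m in markers if m.role == "N")
        ab = pd.DataFrame([{ec: 1.0 for ec in num}], index=["s"])
        results, coverage = index.compute_mpmi(ECAbundanceMatrix(abundance=ab), markers)
        assert len(results) == 1
        assert math.isnan(results[0].mpmi_value)
        assert len(coverage["missing_denominator"]) == 10

    def test_missing_ecs_reported(self, markers):
        ab = pd.DataFrame([{"1.2.1.5": 1.0, "3.5.3.9": 1.0}], index=["s"])
        results, coverage = index.compute_mpmi(ECAbundanceMatrix(abundance=ab), markers)
        assert results[0].mpmi_value == pytest.approx(100.0)
        assert len(coverage["missing_numerator"]) == 11
        assert len(coverage["missing_denominator"]) == 9

    def test_scale_invariance_per_sample(self, markers, rng):
        ecs = [m.ec_number for m in markers]
        row = rng.uniform(0.1, 2.0, size=len(ecs))
        ab = pd.DataFrame([row, row * 7.3], index=["s1", "s2"], columns=ecs)
        results, _ = index.compute_mpmi(ECAbundanceMatrix(abundance=ab), markers)
        assert results[0].mpmi_value == pytest.approx(results[1].mpmi_value)

    def test_monotonicity(self, markers, rng):
        ecs = [m.ec_number for m in markers]
        roles = {m.ec_number: m.role for m in markers}
        ab = pd.DataFrame([rng.uniform(0.5, 1.5, size=len(ecs))], index=["s"], columns=ecs)
        base, _ = index.compute_mpmi(ECAbundanceMatrix(abundance=ab), markers)
        for ec in rng.choice(ecs, size=6, replace=False):
            bumped = ab.copy()
            bumped[ec] += 0.25
            res, _ = index.compute_mpmi(ECAbundanceMatrix(abundance=bumped), markers)
            if roles[ec] == "N":
                assert res[0].mpmi_value > base[0].mpmi_value
            else:
                assert res[0].mpmi_value < base[0].mpmi_value

    def test_fold_recovery_on_synthetic_data(self, sim_counts, sim_matrix, markers):
        # treated/control median MPMI ratio recovers the generating fold
        results, _ = index.compute_mpmi(sim_matrix, markers)
        frame = index.results_frame(results).join(sim_counts.labels)
        ratio = (
            frame.loc[frame["treatment"] == "pb", "mpmi"].median()
            / frame.loc[frame["treatment"] == "control", "mpmi"].median()
        )
        assert ratio == pytest.approx(sim_counts.true_mpmi_ratio, rel=0.10)


class TestOutliers:
    def test_obvious_outlier_excluded(self):
        values = list(range(1, 11)) + [1000]
        kept, excluded = index.exclude_outliers(values, k=2.0)
        # brute-force fence oracle
        q1, q3 = np.percentile(values, [25, 75])
        fence = (q1 - 2 * (q3 - q1), q3 + 2 * (q3 - q1))
        assert excluded == [v for v in values if not fence[0] <= v <= fence[1]]
        assert excluded == [1000]
        assert kept == list(range(1, 11))

    def test_all_equal_none_excluded(self):
        kept, excluded = index.exclude_outliers([5.0] * 6)
        assert kept == [5.0] * 6 and excluded == []

    def test_infinite_k_excludes_nothing(self):
        kept, excluded = index.exclude_outliers([1, 2, 3, 1e9], k=math.inf)
        assert excluded == []

    def test_fewer_than_four_untouched(self):
        kept, excluded = index.exclude_outliers([1, 2, 1000])
        assert kept == [1, 2, 1000] and excluded == []

    def test_median_mode(self):
        values = [1, 2, 3, 4, 5, 100]
        _, excl_tukey = index.exclude_outliers(values, k=2.0, mode="tukey")
        _, excl_median = index.exclude_outliers(values, k=2.0, mode="median")
        assert excl_tukey == [100] and excl_median == [100]

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=4, max_size=30),
        st.floats(min_value=0.5, max_value=5.0),
    )
    def test_kept_values_respect_fences(self, values, k):
        kept, excluded = index.exclude_outliers(values, k=k)
        q1, q3 = np.percentile(values, [25, 75])
        iqr = q3 - q1
        assert all(q1 - k * iqr <= v <= q3 + k * iqr for v in kept)
        assert sorted(kept + excluded) == sorted(values)


class TestCompareGroups:
    def test_exact_p_for_separated_triples(self):
        # enumeration oracle: all C(6,3) = 20 rank assignments; the observed
        # rank sum is one of the 2 most extreme -> two-sided p = 2/20
        a, b = [1, 2, 3], [10, 11, 12]
        pooled = sorted(a + b)
        observed = sum(pooled.index(v) + 1 for v in a)
        sums = [sum(c) for c in itertools.combinations(range(1, 7), 3)]
        lo = sum(1 for s in sums if s <= observed)
        hi = sum(1 for s in sums if s >= observed)
        expected = 2 * min(lo, hi) / len(sums)
        assert expected == pytest.approx(0.1)
        comp = index.compare_groups(a, b)
        assert comp.test_name == "mann_whitney"
        assert comp.p_value == pytest.approx(expected)

    def test_identical_groups_p_near_one(self):
        comp = index.compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert comp.p_value > 0.9

    def test_three_identical_groups_kruskal_h_zero(self):
        g = [1.0, 2.0, 3.0]
        comp = index.compare_groups(g, g, g)
        assert comp.test_name == "kruskal_wallis"
        assert comp.statistic == pytest.approx(0.0)

    def test_large_groups_use_asymptotic(self, rng):
        a = list(rng.normal(0, 1, 30))
        b = list(rng.normal(2, 1, 30))
        comp = index.compare_groups(a, b)
        assert comp.p_value < 0.001

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            index.compare_groups([1.0], [2.0, 3.0])


class TestCohortSplit:
    def test_mean_split(self):
        labels = index.cohort_split(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert labels["a"] == "Low" and labels["c"] == "High"
        assert labels["b"] == "Low"  # exactly at the mean -> tie rule

    def test_mean_split_tie_high(self):
        labels = index.cohort_split(
            pd.Series([1.0, 2.0, 3.0], index=list("abc")), tie="high"
        )
        assert labels["b"] == "High"

    def test_10pct_band(self):
        labels = index.cohort_split(
            pd.Series([89.0, 100.0, 111.0], index=list("abc")), mode="10pct"
        )
        assert labels["a"] == "Low"
        assert labels["b"] is None
        assert labels["c"] == "High"

    def test_10pct_all_equal_unlabeled(self):
        labels = index.cohort_split(pd.Series([5.0, 5.0, 5.0]), mode="10pct")
        assert labels.isna().all() or (labels == None).all()  # noqa: E711

    def test_empty_weights_error(self):
        with pytest.raises(ValueError):
            index.cohort_split(pd.Series(dtype=float))


def test_flag_outliers_marks_but_keeps(markers, rng):
    ecs = [m.ec_number for m in markers]
    rows = [rng.uniform(0.9, 1.1, size=len(ecs)) for _ in range(9)]
    ab = pd.DataFrame(rows, index=[f"s{i}" for i in range(9)], columns=ecs)
    ab.iloc[0] = ab.iloc[0] * 0  # zero out sample s0...
    ab.iloc[0, :12] = 100.0  # ...then give it a huge numerator
    results, _ = index.compute_mpmi(ECAbundanceMatrix(abundance=ab), markers)
    flagged = index.flag_outliers(results)
    assert len(flagged) == len(results)
    by_id = {r.sample_id: r for r in flagged}
    assert any(r.excluded_as_outlier for r in flagged)
    assert not by_id["s1"].excluded_as_outlier
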