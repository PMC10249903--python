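"""Unit and property tests for the diagnostic workflows."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import gaode as g
from gaode.errors import ComparabilityError, DegenerateDataError, ValidationError

from conftest import unlabeled


def brute_force_mw_p(a, b):
    """Independent oracle: enumerate every labeling of the pooled sample."""
    pooled = np.concatenate([a, b])
    n = len(a)
    nm = n * len(b)

    def u_of(idx):
        aa = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        gt = sum((x > y) + 0.5 * (x == y) for x in aa for y in rest)
        return gt

    u_obs = u_of(range(n))
    dev = abs(u_obs - nm / 2)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        total += 1
        if abs(u_of(idx) - nm / 2) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_perfect_separation_exact(self):
        rep = g.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert rep.statistic == 0.0
        assert rep.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples(self):
        rep = g.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert rep.p_value == pytest.approx(1.0)

    def test_complete_ties(self):
        rep = g.mann_whitney_u([1, 1], [1, 1])
        assert rep.statistic == 2.0
        assert rep.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 6, size=2)
        # integer values force ties with positive probability
        a = rng.integers(0, 4, size=n).astype(float)
        b = rng.integers(0, 4, size=m).astype(float)
        u_obs, p_oracle = brute_force_mw_p(a, b)
        rep = g.mann_whitney_u(a, b)
        assert rep.statistic == pytest.approx(u_obs)
        assert rep.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 60)
        b = rng.normal(1, 1, 60)
        rep = g.mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert rep.p_value == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            g.mann_whitney_u([], [1.0, 2.0])


class TestWelch:
    def test_identical_samples_p_one(self):
        rep = g.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.statistic == 0.0
        assert rep.p_value == 1.0

    def test_zero_variance_both_degenerate(self):
        with pytest.raises(DegenerateDataError):
            g.welch_t([0.0] * 4, [1.0] * 4)

    def test_power_at_unit_separation(self):
        rng = np.random.default_rng(1)
        rep = g.welch_t(rng.normal(0, 1, 1000), rng.normal(1, 1, 1000))
        assert rep.p_value < 1e-10
        assert rep.direction == "a_lower"

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 30), rng.normal(0.3, 2, 40)
        rep = g.welch_t(a, b)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert rep.statistic == pytest.approx(float(t))
        assert rep.p_value == pytest.approx(float(p))


class TestShiftTest:
    def test_cohort_against_itself(self, wheat_like_model_and_tables):
        model, _, test = wheat_like_model_and_tables
        records = g.classify_table(model, unlabeled(test))
        rep = g.srs_shift_test(records, records, method="welch_t")
        assert rep.p_value == 1.0

    def test_different_models_rejected(self, wheat_like_model_and_tables, fig1a_exact_model):
        model, _, test = wheat_like_model_and_tables
        rec_a = g.classify_table(model, unlabeled(test))
        tab = g.AttributeTable(data=pd.DataFrame({"x": np.linspace(-1, 1, 20)}))
        rec_b = g.classify_table(fig1a_exact_model, tab)
        with pytest.raises(ComparabilityError):
            g.srs_shift_test(rec_a, rec_b)

    def test_detects_mean_shift(self):
        train, matched, mismatched = g.gen_cohort_shift(
            n_per_cohort=400, n_attributes=8, shift=1.0, seed=0
        )
        model = g.train_model(train, g.TrainingConfig(seed=0, max_components=1))
        rec_m = g.classify_table(model, unlabeled(matched))
        rec_x = g.classify_table(model, unlabeled(mismatched))
        rep = g.srs_shift_test(rec_x, rec_m, method="welch_t")
        assert rep.direction == "a_lower"
        assert rep.p_value < 1e-3


class TestRoc:
    def test_perfect_separation(self):
        roc = g.srs_roc_auc([0.9, 0.8, 0.7], [0.1, 0.2])
        assert roc.auc == pytest.approx(1.0)

    def test_identical_scores_chance(self):
        roc = g.srs_roc_auc([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert roc.auc == pytest.approx(0.5)

    def test_curve_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        roc = g.srs_roc_auc(rng.normal(1, 1, 40), rng.normal(0, 1, 30))
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all((roc.tpr >= 0) & (roc.tpr <= 1))
        assert np.all((roc.fpr >= 0) & (roc.fpr <= 1))
        assert 0.0 <= roc.auc <= 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_mann_whitney_identity(self, seed):
        rng = np.random.default_rng(seed)
        known = np.round(rng.normal(0.5, 1, 37), 1)  # rounding forces ties
        unknown = np.round(rng.normal(0, 1, 23), 1)
        roc = g.srs_roc_auc(known, unknown)
        ranks = stats.rankdata(np.concatenate([known, unknown]))
        u = ranks[: known.size].sum() - known.size * (known.size + 1) / 2
        assert roc.auc == pytest.approx(u / (known.size * unknown.size), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            g.srs_roc_auc([], [1.0])


class TestMissingnessProfile:
    def test_complete_table_single_group(self, wheat_like_model_and_tables):
        model, _, test = wheat_like_model_and_tables
        tab = unlabeled(test)
        records = g.classify_table(model, tab)
        report = g.missingness_profile(tab, records)
        assert len(report.groups) == 1
        assert report.groups[0]["count"] == tab.n_rows
        assert report.groups[0]["missing_set"] == ()

    def test_partition_counts(self, fig1a_exact_model):
        # build a 2-attribute model table via a small trained model instead
        train = g.gen_informative_noise(n_per_class=100, seed=0)
        model = g.train_model(train, g.TrainingConfig(seed=0, max_components=1))
        test = g.gen_informative_noise(n_per_class=50, seed=1)
        part_a = g.inject_missingness(test.subset(np.arange(40)), remove=["noise1"], seed=0)
        part_b = test.subset(np.arange(40, 100))
        tab = g.AttributeTable(
            data=pd.concat([part_a.data, part_b.data], ignore_index=True)
        )
        records = g.classify_table(model, tab)
        report = g.missingness_profile(tab, records)
        assert sorted(grp["count"] for grp in report.groups) == [40, 60]
        assert sum(grp["count"] for grp in report.groups) == report.n_rows

    def test_groups_sorted_by_mean_srs(self):
        train = g.gen_informative_noise(n_per_class=100, seed=2)
        model = g.train_model(train, g.TrainingConfig(seed=2, max_components=1))
        test = g.gen_informative_noise(n_per_class=60, seed=3)
        inf_names = [n for n in test.attribute_names if n.startswith("inf")]
        noise_names = [n for n in test.attribute_names if n.startswith("noise")]
        tab_inf = g.inject_missingness(test, remove=inf_names[:3], seed=0)
        tab_noise = g.inject_missingness(test, remove=noise_names, seed=0)
        tab = g.AttributeTable(
            data=pd.concat([tab_inf.data, tab_noise.data], ignore_index=True)
        )
        records = g.classify_table(model, tab)
        report = g.missingness_profile(tab, records)
        means = [grp["mean_srs"] for grp in report.groups]
        assert means == sorted(means)
        # informative-removed pattern scores lower on average
        by_set = {grp["missing_set"]: grp["mean_srs"] for grp in report.groups}
        assert by_set[tuple(inf_names[:3])] < by_set[tuple(noise_names)]

    def test_misaligned_inputs_rejected(self, wheat_like_model_and_tables):
        model, _, test = wheat_like_model_and_tables
        tab = unlabeled(test)
        records = g.classify_table(model, tab)
        with pytest.raises(ValidationError):
            g.missingness_profile(tab, records[:-1])


class TestAbstention:
    def _records(self, model, values):
        tab = g.AttributeTable(data=pd.DataFrame({"x": values}))
        return g.classify_table(model, tab)

    def test_extreme_thresholds(self, fig1a_exact_model):
        records = self._records(fig1a_exact_model, np.linspace(-2, 2, 10))
        none_new, n0 = g.apply_abstention(records, -np.inf)
        all_new, n1 = g.apply_abstention(records, np.inf)
        assert n0 == 0 and not any(r.abstained for r in none_new)
        assert n1 == 10 and all(r.abstained for r in all_new)

    def test_median_threshold_splits_in_half(self, fig1a_exact_model):
        values = np.linspace(-1.0, 0.0, 10)  # 10 distinct SRS values
        records = self._records(fig1a_exact_model, values)
        scores = sorted(r.srs for r in records)
        assert len(set(scores)) == 10
        threshold = 0.5 * (scores[4] + scores[5])
        updated, newly = g.apply_abstention(records, threshold)
        assert newly == 5
        assert sum(r.abstained for r in updated) == 5

    def test_abstention_is_sticky(self, fig1a_exact_model):
        records = self._records(fig1a_exact_model, np.linspace(-2, 2, 6))
        flagged, _ = g.apply_abstention(records, np.inf)
        still, newly = g.apply_abstention(flagged, -np.inf)
        assert newly == 0
        assert all(r.abstained for r in still)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    data=st.lists(st.integers(0, 5), min_size=4, max_size=10),
    split=st.integers(2, 8),
)
def test_exact_mw_agrees_with_enumeration(data, split):
    """Property: the exact Mann-Whitney p matches brute-force enumeration."""
    split = min(split, len(data) - 2)
    a = np.array(data[:split], dtype=float)
    b = np.array(data[split:], dtype=float)
    if len(a) < 2 or len(b) < 2:
        return
    u_obs, p_oracle = brute_force_mw_p(a, b)
    rep = g.mann_whitney_u(a, b)
    assert rep.statistic == pytest.approx(u_obs)
    assert rep.p_value == pytest.approx(p_oracle, abs=1e-12)
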