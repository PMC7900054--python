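"""Domain types, Fisher's exact test and the pooling engines."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import metafragility as mf
from metafragility.meta_model import _fisher_p_counts

from conftest import random_meta


class TestTwoByTwoTrial:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(events_t=-1, size_t=10, events_c=0, size_c=10),
            dict(events_t=11, size_t=10, events_c=0, size_c=10),
            dict(events_t=0, size_t=0, events_c=0, size_c=10),
            dict(events_t=0, size_t=10, events_c=5, size_c=4),
        ],
    )
    def test_invalid_counts_rejected(self, kwargs):
        with pytest.raises(mf.InvalidTableError):
            mf.TwoByTwoTrial("t", **kwargs)

    def test_sample_size_is_sum_of_arms(self):
        t = mf.TwoByTwoTrial("t", 3, 25, 4, 30)
        assert t.sample_size == 55
        assert t.nonevents_t == 22 and t.nonevents_c == 26

    def test_meta_requires_unique_trial_ids(self):
        t = mf.TwoByTwoTrial("t", 1, 10, 2, 10)
        with pytest.raises(ValueError, match="duplicate"):
            mf.MetaAnalysisSpec("m", (t, t))
        with pytest.raises(ValueError, match="no trials"):
            mf.MetaAnalysisSpec("m", ())

    def test_meta_sample_size_sums_all_trials(self, three_trial_spec):
        assert three_trial_spec.sample_size == 238 + 121 + 595

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            mf.PoolingConfig(alpha=0.0)
        with pytest.raises(ValueError):
            mf.PoolingConfig(alpha=1.0)


class TestFisherExact:
    def test_identical_arms_give_p_one(self):
        assert mf.fisher_exact_two_sided(mf.TwoByTwoTrial("t", 5, 10, 5, 10)) == 1.0

    def test_all_zero_table_gives_p_one(self):
        assert mf.fisher_exact_two_sided(mf.TwoByTwoTrial("t", 0, 10, 0, 10)) == 1.0

    def test_frozen_example_one_vs_nine_per_hundred(self):
        # value frozen from an exact rational full-enumeration oracle
        p = mf.fisher_exact_two_sided(mf.TwoByTwoTrial("t", 1, 100, 9, 100))
        assert p == pytest.approx(0.018487679877476366, abs=1e-14)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n1 = int(rng.integers(1, 40))
            n2 = int(rng.integers(1, 40))
            a = int(rng.integers(0, n1 + 1))
            c = int(rng.integers(0, n2 + 1))
            ours = _fisher_p_counts(a, n1, c, n2)
            table = [[a, n1 - a], [c, n2 - c]]
            theirs = scipy.stats.fisher_exact(table, alternative="two-sided")[1]
            assert ours == pytest.approx(theirs, abs=1e-11), (a, n1, c, n2)

    @settings(max_examples=200, derandomize=True)
    @given(
        n1=st.integers(1, 30),
        n2=st.integers(1, 30),
        fa=st.floats(0, 1),
        fc=st.floats(0, 1),
    )
    def test_invariant_under_arm_and_outcome_swaps(self, n1, n2, fa, fc):
        a = round(fa * n1)
        c = round(fc * n2)
        p = _fisher_p_counts(a, n1, c, n2)
        assert p == pytest.approx(_fisher_p_counts(c, n2, a, n1), abs=1e-12)
        # swapping event/non-event columns
        assert p == pytest.approx(_fisher_p_counts(n1 - a, n1, n2 - c, n2), abs=1e-12)
        assert 0.0 < p <= 1.0


class TestPooling:
    def test_single_trial_fixed_rr_equals_trial_rr(self):
        spec = mf.MetaAnalysisSpec(
            "m", (mf.TwoByTwoTrial("t", 10, 100, 20, 100),), mf.PoolingConfig(model="fixed")
        )
        assert mf.pool(spec).effect == pytest.approx(0.5, rel=1e-12)

    def test_duplicating_trials_keeps_estimate_reduces_se(self):
        t = mf.TwoByTwoTrial("t1", 10, 100, 20, 100)
        one = mf.MetaAnalysisSpec("m", (t,), mf.PoolingConfig(model="fixed"))
        t2 = mf.TwoByTwoTrial("t2", 10, 100, 20, 100)
        two = mf.MetaAnalysisSpec("m", (t, t2), mf.PoolingConfig(model="fixed"))
        r1, r2 = mf.pool(one), mf.pool(two)
        assert r2.effect == pytest.approx(r1.effect, rel=1e-12)
        assert r2.se < r1.se

    def test_three_trial_fixture_matches_frozen_oracle(self, three_trial_spec):
        # values frozen from an independent implementation of the
        # Greenland-Robins and DerSimonian-Laird formulas (R metafor 4.8-0)
        fixed = mf.pool(three_trial_spec)
        assert fixed.log_effect == pytest.approx(-0.466925709014, abs=1e-9)
        assert fixed.se == pytest.approx(0.174928040522, abs=1e-9)
        random = mf.pool(
            mf.MetaAnalysisSpec(
                "m", three_trial_spec.trials, mf.PoolingConfig(model="random")
            )
        )
        assert random.log_effect == pytest.approx(-0.464480344843, abs=1e-9)
        assert random.se == pytest.approx(0.175554897471, abs=1e-9)
        assert random.tau2 == 0.0
        assert random.q_stat == pytest.approx(0.956885621063, abs=1e-9)
        odds = mf.pool(
            mf.MetaAnalysisSpec(
                "m", three_trial_spec.trials, mf.PoolingConfig(measure="or", model="fixed")
            )
        )
        assert odds.log_effect == pytest.approx(-0.533766654984, abs=1e-9)
        assert odds.se == pytest.approx(0.198979902494, abs=1e-9)

    def test_all_double_zero_is_inestimable(self):
        trials = (
            mf.TwoByTwoTrial("t1", 0, 10, 0, 10),
            mf.TwoByTwoTrial("t2", 0, 20, 0, 20),
        )
        with pytest.raises(mf.InestimableError):
            mf.pool(mf.MetaAnalysisSpec("m", trials))

    def test_double_zero_trial_excluded_from_k_but_not_sample_size(self):
        trials = (
            mf.TwoByTwoTrial("t1", 10, 100, 20, 100),
            mf.TwoByTwoTrial("t2", 0, 50, 0, 50),
        )
        spec = mf.MetaAnalysisSpec("m", trials, mf.PoolingConfig(model="fixed"))
        res = mf.pool(spec)
        assert res.k == 1
        assert res.effect == pytest.approx(0.5, rel=1e-12)
        assert spec.sample_size == 300

    @staticmethod
    def _iv_fixed_se(spec):
        """Inverse-variance fixed-effect SE, reimplemented independently."""
        weights = []
        for t in spec.trials:
            a, b = t.events_t, t.nonevents_t
            c, d = t.events_c, t.nonevents_c
            if a == 0 and c == 0:
                continue
            if 0 in (a, b, c, d):
                a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            v = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
            weights.append(1 / v)
        return 1.0 / math.sqrt(sum(weights))

    def test_tau2_zero_when_q_small_and_random_se_never_smaller(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            spec = random_meta(rng, k_max=4, model="random")
            try:
                random = mf.pool(spec)
            except mf.InestimableError:
                continue
            assert random.tau2 >= 0.0
            if random.q_stat <= random.k - 1:
                assert random.tau2 == 0.0
            # heterogeneity can only widen the interval relative to the
            # inverse-variance fixed-effect analysis of the same data
            se_iv = self._iv_fixed_se(spec)
            assert random.se >= se_iv - 1e-12
            if random.tau2 == 0.0:
                assert random.se == pytest.approx(se_iv, rel=1e-12)

    def test_ci_brackets_point_estimate(self, three_trial_spec):
        res = mf.pool(three_trial_spec)
        assert res.ci_low <= res.effect <= res.ci_high
        assert 0.0 < res.p_value <= 1.0


class TestSignificance:
    def test_ci_excluding_one_is_significant(self):
        res = mf.PooledResult(
            log_effect=math.log(1.6), se=0.1, ci_low=1.10, ci_high=2.50,
            p_value=0.001, tau2=0.0, q_stat=0.0, k=1,
        )
        assert mf.is_significant(res, mf.PoolingConfig())

    def test_ci_including_one_is_not_significant(self):
        res = mf.PooledResult(
            log_effect=math.log(1.08), se=0.1, ci_low=0.90, ci_high=1.30,
            p_value=0.4, tau2=0.0, q_stat=0.0, k=1,
        )
        assert not mf.is_significant(res, mf.PoolingConfig())

    def test_boundary_ci_touching_one_counts_as_null(self):
        res = mf.PooledResult(
            log_effect=math.log(1.34), se=0.15, ci_low=1.00, ci_high=1.80,
            p_value=0.05, tau2=0.0, q_stat=0.0, k=1,
        )
        assert not mf.is_significant(res, mf.PoolingConfig())

    def test_wald_equivalence_on_random_meta_analyses(self):
        # CI excluding 1 must agree with p < alpha: same Wald construction
        rng = np.random.default_rng(17)
        n_checked = 0
        while n_checked < 10_000:
            model = "fixed" if n_checked % 2 else "random"
            spec = random_meta(rng, k_max=4, model=model)
            try:
                res = mf.pool(spec)
            except mf.InestimableError:
                continue
            n_checked += 1
            assert mf.is_significant(res, spec.config) == (
                res.p_value < spec.config.alpha
            ), (res, spec)
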