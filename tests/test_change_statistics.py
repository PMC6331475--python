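"""Change statistics: d, omega-squared, SID, RCI, classification, percentages."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import prepost_change as pc
from prepost_change import change_statistics as cs
from prepost_change.synthetic_cohorts import PairedSample, TwoGroupSample


def sample_from_diffs(diffs, pre=None):
    diffs = np.asarray(diffs, dtype=float)
    pre = np.zeros_like(diffs) if pre is None else np.asarray(pre, dtype=float)
    return PairedSample(pre=pre, post=pre + diffs)


class TestCohensD:
    def test_hand_computed_example(self):
        s = PairedSample(pre=[0, 1, 2], post=[1, 2, 4])
        est = cs.cohens_d_dif(s)
        assert est.value == pytest.approx(2.3094, abs=1e-4)
        assert est.components["S_dif"] == pytest.approx(0.5774, abs=1e-4)

    def test_zero_variance_differences_error(self):
        with pytest.raises(pc.DegenerateSampleError):
            cs.cohens_d_dif(PairedSample(pre=[1, 2, 3], post=[1, 2, 3]))

    def test_symmetric_differences_give_zero(self):
        s = sample_from_diffs([-2, -1, 0, 1, 2])
        assert cs.cohens_d_dif(s).value == pytest.approx(0.0, abs=1e-12)


def brute_force_interaction_f(two: TwoGroupSample) -> float:
    """Full 2x2 mixed-ANOVA decomposition: SS_AB / MS(B x subjects within A)."""
    groups = [two.experimental, two.control]
    ns = [g.n for g in groups]
    scores = {
        (gi, si, ti): (g.pre[si] if ti == 0 else g.post[si])
        for gi, g in enumerate(groups)
        for si in range(g.n)
        for ti in (0, 1)
    }
    grand = np.mean(list(scores.values()))
    m_g = {gi: np.mean([v for k, v in scores.items() if k[0] == gi]) for gi in (0, 1)}
    m_t = {ti: np.mean([v for k, v in scores.items() if k[2] == ti]) for ti in (0, 1)}
    m_gt = {
        (gi, ti): np.mean(
            [v for k, v in scores.items() if k[0] == gi and k[2] == ti]
        )
        for gi in (0, 1)
        for ti in (0, 1)
    }
    m_gs = {
        (gi, si): np.mean([scores[gi, si, 0], scores[gi, si, 1]])
        for gi in (0, 1)
        for si in range(ns[gi])
    }
    ss_ab = sum(
        ns[gi] * (m_gt[gi, ti] - m_g[gi] - m_t[ti] + grand) ** 2
        for gi in (0, 1)
        for ti in (0, 1)
    )
    ss_err = sum(
        (scores[gi, si, ti] - m_gs[gi, si] - m_gt[gi, ti] + m_g[gi]) ** 2
        for gi in (0, 1)
        for si in range(ns[gi])
        for ti in (0, 1)
    )
    df_err = sum(ns) - 2
    return ss_ab / (ss_err / df_err)


class TestOmegaSquared:
    def test_f_equal_one_gives_zero(self):
        # engineered so the between-groups difference-score F is exactly 1
        exp = sample_from_diffs([1.0, -1.0, 0.5, -0.5])
        # choose ctrl mean offset m so that SS_between == MS_within
        n = 4
        ms_within = (2.5 + 2.5) / 6  # pooled variance of diffs
        m = np.sqrt(ms_within * (1 / n + 1 / n))
        ctrl = sample_from_diffs(np.array([1.0, -1.0, 0.5, -0.5]) + m)
        est = cs.interaction_omega_squared(TwoGroupSample(exp, ctrl))
        assert est.components["F_AB"] == pytest.approx(1.0, abs=1e-12)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_limit_near_one_for_separated_groups(self):
        jit = np.array([1e-6, -1e-6, 2e-6, -2e-6])
        exp = sample_from_diffs(2.0 + jit)
        ctrl = sample_from_diffs(0.0 + jit)
        est = cs.interaction_omega_squared(TwoGroupSample(exp, ctrl))
        f = est.components["F_AB"]
        assert f > 1e6
        assert est.value == pytest.approx((f - 1) / ((f - 1) + 16), rel=1e-9)

    def test_negative_omega_not_truncated(self):
        exp = sample_from_diffs([1.0, -1.0, 0.5, -0.5])
        ctrl = sample_from_diffs([1.01, -1.0, 0.5, -0.5])
        est = cs.interaction_omega_squared(TwoGroupSample(exp, ctrl))
        assert est.components["F_AB"] < 1
        assert est.value < 0

    def test_matches_brute_force_anova_and_t_squared(self, rng):
        from scipy import stats as sps

        for _ in range(25):
            n1, n2 = rng.integers(2, 8, size=2)
            exp = PairedSample(pre=rng.normal(size=n1), post=rng.normal(1, 2, n1))
            ctrl = PairedSample(pre=rng.normal(size=n2), post=rng.normal(0, 1, n2))
            two = TwoGroupSample(exp, ctrl)
            est = cs.interaction_omega_squared(two)
            f_brute = brute_force_interaction_f(two)
            t = sps.ttest_ind(exp.differences, ctrl.differences, equal_var=True)
            assert est.components["F_AB"] == pytest.approx(f_brute, rel=1e-9)
            assert est.components["F_AB"] == pytest.approx(t.statistic**2, rel=1e-9)
            assert est.components["N"] == 2 * (n1 + n2)

    def test_degenerate_error(self):
        exp = sample_from_diffs([1.0, 1.0, 1.0])
        ctrl = sample_from_diffs([0.0, 0.0, 0.0])
        with pytest.raises(pc.DegenerateSampleError):
            cs.interaction_omega_squared(TwoGroupSample(exp, ctrl))


class TestIndividualIndices:
    def test_sid_hand_computed(self):
        s = sample_from_diffs([1, 1, 2])
        np.testing.assert_allclose(
            cs.sid_scores(s), [1.7321, 1.7321, 3.4641], atol=1e-4
        )

    def test_mean_sid_equals_d(self, rng):
        s = PairedSample(pre=rng.normal(size=30), post=rng.normal(0.5, 1.2, 30))
        assert np.mean(cs.sid_scores(s)) == pytest.approx(
            cs.cohens_d_dif(s).value, rel=1e-12
        )

    def test_rci_unit_denominator_closed_form(self):
        # S_pre = S_post = 1 and r = 0.5 make the standard error exactly 1
        pre = np.array([-1.5, -0.5, 0.5, 1.5]) / np.std(
            [-1.5, -0.5, 0.5, 1.5], ddof=1
        )
        post = pre.copy()
        post[0], post[1] = post[1], post[0]  # permute to lower the correlation
        s = PairedSample(pre=pre, post=post)
        rci = cs.rci_scores(s, reliability=0.5)
        np.testing.assert_allclose(rci, s.differences, atol=1e-12)

    def test_rci_zero_reliability(self):
        s = PairedSample(pre=[0.0, 1.0, 2.0], post=[2.0, 1.0, 0.0])
        # here S_pre = S_post = 1 exactly, so the denominator is sqrt(2)
        rci = cs.rci_scores(s, reliability=0.0)
        np.testing.assert_allclose(rci, s.differences / np.sqrt(2.0), atol=1e-12)

    def test_rci_reliability_validation_and_degenerate(self):
        s = PairedSample(pre=[0.0, 1.0, 2.0], post=[2.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            cs.rci_scores(s, reliability=1.0)
        flat = PairedSample(pre=[1.0, 1.0, 1.0], post=[0.0, 1.0, 2.0])
        with pytest.raises(pc.DegenerateSampleError):
            cs.rci_scores(flat)

    def test_rci_defaults_to_sample_correlation(self, rng):
        s = PairedSample(pre=rng.normal(size=50), post=rng.normal(size=50))
        r = float(np.corrcoef(s.pre, s.post)[0, 1])
        np.testing.assert_allclose(cs.rci_scores(s), cs.rci_scores(s, reliability=r))


class TestClassification:
    @pytest.mark.parametrize(
        "value,cutoff,tails,expected",
        [
            (1.7, 1.645, "one", cs.ChangeLabel.IMPROVEMENT),
            (-2.1, 1.96, "two", cs.ChangeLabel.WORSENING),
            (-2.1, 1.645, "one", cs.ChangeLabel.NO_CHANGE),  # one-tailed ignores drops
            (1.645, 1.645, "one", cs.ChangeLabel.NO_CHANGE),  # ties are not changes
            (1.96, 1.96, "two", cs.ChangeLabel.NO_CHANGE),
            (0.0, 1.96, "two", cs.ChangeLabel.NO_CHANGE),
        ],
    )
    def test_cutoff_rules(self, value, cutoff, tails, expected):
        assert cs.classify_reliable_change([value], cutoff, tails)[0] is expected

    def test_validation(self):
        with pytest.raises(ValueError):
            cs.classify_reliable_change([1.0], 0.0, "one")
        with pytest.raises(ValueError):
            cs.classify_reliable_change([1.0], 1.96, "both")


class TestPercentages:
    def test_percent_reliable_counts(self):
        labels = cs.classify_reliable_change(
            [2.0] + [0.0] * 24, 1.645, "one"
        )
        assert cs.percent_reliable(labels).value == pytest.approx(4.0)

    def test_percent_all_null(self):
        labels = cs.classify_reliable_change([0.0, 0.1], 1.645, "one")
        assert cs.percent_reliable(labels).value == 0.0

    def test_net_percent_arithmetic(self):
        est = cs.net_percent(
            cs.classify_reliable_change([2.0] * 40 + [-2.0] * 5 + [0.0] * 55, 1.96, "two"),
            cs.classify_reliable_change([2.0] * 10 + [-2.0] * 5 + [0.0] * 85, 1.96, "two"),
        )
        assert est.value == pytest.approx(30.0)
        assert est.components["P+_exp"] == pytest.approx(40.0)

    def test_net_percent_identical_groups_zero(self):
        labels = cs.classify_reliable_change([2.5, -2.5, 0.0, 1.0], 1.96, "two")
        assert cs.net_percent(labels, labels.copy()).value == 0.0

    def test_net_percent_full_range(self):
        up = cs.classify_reliable_change([3.0] * 4, 1.96, "two")
        down = cs.classify_reliable_change([-3.0] * 4, 1.96, "two")
        assert cs.net_percent(up, down).value == pytest.approx(200.0)
        assert cs.net_percent(down, up).value == pytest.approx(-200.0)

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            cs.percent_reliable(np.array([], dtype=object))


class TestAnalyticNormalPercentage:
    def test_known_tail_probabilities(self):
        assert cs.analytic_percentage_normal(0.0, 1.645) == pytest.approx(5.0, abs=0.01)
        assert cs.analytic_percentage_normal(0.5, 1.645) == pytest.approx(13.0, abs=0.5)

    def test_delta_at_cutoff_gives_half(self):
        assert cs.analytic_percentage_normal(1.645, 1.645) == pytest.approx(50.0)

    def test_monte_carlo_agreement_known_sigma(self, rng):
        # known-sigma normal differences: empirical tail within 3 MC SEs
        delta, n = 0.9, 200_000
        sid_known_sigma = rng.standard_normal(n) + delta
        labels = cs.classify_reliable_change(sid_known_sigma, 1.645, "one")
        p = cs.percent_reliable(labels).value
        expected = cs.analytic_percentage_normal(delta, 1.645)
        se = np.sqrt(expected * (100 - expected) / n)
        assert abs(p - expected) < 3 * se

    def test_expected_percent_monotone_in_delta(self, rng):
        # expected percentage of reliable changes rises with the true effect
        means = []
        for delta in (0.0, 0.6, 1.2, 1.8, 2.4):
            cond = pc.DesignCondition(delta, 50, 0.7)
            vals = [
                cs.percent_reliable(
                    cs.classify_reliable_change(
                        cs.sid_scores(pc.simulate_paired_sample(cond, rng)),
                        1.645,
                        "one",
                    )
                ).value
                for _ in range(200)
            ]
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))


@st.composite
def paired_samples(draw):
    n = draw(st.integers(min_value=3, max_value=30))
    pre = draw(
        st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=n, max_size=n
        )
    )
    diffs = draw(
        st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=n, max_size=n
        )
    )
    pre = np.asarray(pre)
    post = pre + np.asarray(diffs)
    if np.std(post - pre, ddof=1) < 1e-6:
        post = post + np.arange(n) * 0.5  # avoid the degenerate branch
    return PairedSample(pre=pre, post=post)


class TestInvariances:
    @given(paired_samples(), st.floats(0.1, 20))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, s, c):
        scaled = PairedSample(pre=c * s.pre, post=c * s.post)
        assert cs.cohens_d_dif(scaled).value == pytest.approx(
            cs.cohens_d_dif(s).value, rel=1e-6, abs=1e-9
        )
        np.testing.assert_allclose(
            cs.sid_scores(scaled), cs.sid_scores(s), rtol=1e-6, atol=1e-9
        )

    @given(paired_samples(), st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance(self, s, c):
        shifted = PairedSample(pre=s.pre + c, post=s.post + c)
        assert cs.cohens_d_dif(shifted).value == pytest.approx(
            cs.cohens_d_dif(s).value, rel=1e-6, abs=1e-9
        )
        np.testing.assert_allclose(
            cs.sid_scores(shifted), cs.sid_scores(s), rtol=1e-6, atol=1e-9
        )

    @given(paired_samples())
    @settings(max_examples=50, deadline=None)
    def test_mean_sid_is_d(self, s):
        assert np.mean(cs.sid_scores(s)) == pytest.approx(
            cs.cohens_d_dif(s).value, rel=1e-9, abs=1e-12
        )


class TestCaseChanges:
    def test_table_columns_and_labels(self, rng):
        cond = pc.DesignCondition(1.2, 25, 0.7)
        s = pc.simulate_paired_sample(cond, rng)
        table = cs.case_changes(s, index="sid", cutoff=1.645, tails="one")
        assert list(table.columns) == [
            "case_id", "pre", "post", "difference", "sid", "rci", "label",
        ]
        reliable = table["sid"] > 1.645
        assert (
            (table["label"] == cs.ChangeLabel.IMPROVEMENT.value) == reliable
        ).all()

    def test_unknown_index_rejected(self, rng):
        s = pc.simulate_paired_sample(pc.DesignCondition(0.0, 10, 0.5), rng)
        with pytest.raises(ValueError):
            cs.case_changes(s, index="zscore")
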