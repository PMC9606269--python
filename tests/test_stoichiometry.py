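"""Binomial labeling model, histogram inversion, and downstream arithmetic."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smbleach.steps import ObservedStepHistogram
from smbleach.stoichiometry import (
    LabelingModel,
    OligomerDistribution,
    binomial_label_prob,
    bootstrap_ci,
    build_observation_matrix,
    fold_over_reference,
    forward_observe,
    group_fractions,
    particle_to_entity,
    receptors_per_cell,
    solve_corrected_fractions,
)


def enumerate_label_prob(order: int, m: int, p_f: float) -> float:
    """Oracle: exhaustive enumeration of all 2^order labeling outcomes."""
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=order):
        if sum(outcome) == m:
            prob = 1.0
            for bit in outcome:
                prob *= p_f if bit else (1.0 - p_f)
            total += prob
    return total


class TestBinomialLabelProb:
    def test_dimer_fully_labeled_at_80_percent(self):
        assert binomial_label_prob(2, 2, 0.8) == pytest.approx(0.64, abs=1e-12)

    @pytest.mark.parametrize("order", [1, 2, 3, 4, 5])
    def test_certainty_under_full_labeling(self, order):
        assert binomial_label_prob(order, order, 1.0) == 1.0

    def test_trimer_single_label(self):
        assert binomial_label_prob(3, 1, 0.8) == pytest.approx(0.096, abs=1e-12)

    @pytest.mark.parametrize("order,m", [(o, m) for o in range(1, 6)
                                         for m in range(o + 1)])
    def test_matches_enumeration_oracle(self, order, m):
        for p_f in (0.3, 0.5, 0.8, 1.0):
            assert binomial_label_prob(order, m, p_f) == pytest.approx(
                enumerate_label_prob(order, m, p_f), abs=1e-12)

    def test_m_above_order_rejected(self):
        with pytest.raises(ValueError):
            binomial_label_prob(2, 3, 0.8)


class TestObservationMatrix:
    def test_full_labeling_gives_identity(self):
        a = build_observation_matrix(LabelingModel(1.0, 5)).entries
        assert np.allclose(a, np.eye(5))

    def test_dimer_column_at_80_percent(self):
        a = build_observation_matrix(LabelingModel(0.8, 2)).entries
        assert np.allclose(a[:, 1], [1 / 3, 2 / 3])

    @given(p_f=st.floats(0.05, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_columns_sum_to_one(self, p_f):
        a = build_observation_matrix(LabelingModel(p_f, 5)).entries
        assert np.allclose(a.sum(axis=0), 1.0, atol=1e-12)
        assert np.allclose(a, np.triu(a))  # zero below the visible diagonal

    def test_matches_enumeration_oracle(self):
        p_f = 0.8
        a = build_observation_matrix(LabelingModel(p_f, 5)).entries
        for i in range(1, 6):
            visible = 1.0 - (1.0 - p_f) ** i
            for m in range(1, i + 1):
                expected = enumerate_label_prob(i, m, p_f) / visible
                assert a[m - 1, i - 1] == pytest.approx(expected, abs=1e-12)


class TestForwardObserve:
    def test_pure_dimer_at_80_percent(self):
        r = forward_observe(np.array([0, 1, 0, 0, 0.0]), LabelingModel(0.8, 5))
        assert np.allclose(r, [1 / 3, 2 / 3, 0, 0, 0], atol=1e-12)

    def test_full_labeling_is_identity(self):
        x = np.array([0.2, 0.3, 0.25, 0.15, 0.1])
        r = forward_observe(x, LabelingModel(1.0, 5))
        assert np.allclose(r, x, atol=1e-12)

    def test_low_density_fractions_give_56_percent_one_step(self):
        r = forward_observe(np.array([0.435, 0.467, 0.098, 0, 0]),
                            LabelingModel(0.8, 5))
        assert 0.56 <= r[0] <= 0.57

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_mean_step_count_monotone_in_labeling_efficiency(self, data):
        x = np.array(data.draw(st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5)))
        if x.sum() <= 0:
            return
        x = x / x.sum()
        ms = np.arange(1, 6)
        means = [ms @ forward_observe(x, LabelingModel(p, 5))
                 for p in (0.3, 0.5, 0.7, 0.9, 1.0)]
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))


class TestSolveCorrectedFractions:
    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_round_trip_identity(self, data):
        raw = np.array(data.draw(
            st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5)))
        if raw.sum() <= 1e-6:
            return
        x = raw / raw.sum()
        p_f = data.draw(st.floats(0.3, 1.0))
        model = LabelingModel(p_f, 5)
        result = solve_corrected_fractions(forward_observe(x, model), model)
        assert result.residual_norm < 1e-9
        assert np.allclose(result.corrected.fractions, x, atol=1e-8)

    def test_pure_monomer_trivial(self):
        result = solve_corrected_fractions(np.array([1.0, 0, 0, 0, 0]),
                                           LabelingModel(1.0, 5))
        assert np.allclose(result.corrected.fractions, [1, 0, 0, 0, 0])

    def test_high_density_printed_fractions_round_trip(self):
        x = np.array([0.133, 0.560, 0.135, 0.172, 0.0])
        x = x / x.sum()
        model = LabelingModel(0.8, 5)
        result = solve_corrected_fractions(forward_observe(x, model), model)
        assert np.allclose(result.corrected.fractions, x, atol=1e-9)

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(ValueError):
            solve_corrected_fractions(ObservedStepHistogram(np.zeros(5, int)),
                                      LabelingModel(0.8, 5))

    def test_ill_conditioned_model_warns(self):
        hist = ObservedStepHistogram(np.array([80, 15, 4, 1, 0]))
        with pytest.warns(UserWarning, match="ill-conditioned"):
            result = solve_corrected_fractions(hist, LabelingModel(0.05, 5))
        assert result.warnings

    def test_condition_tends_to_one_as_labeling_completes(self):
        conds = [solve_corrected_fractions(
            forward_observe(np.array([0.4, 0.4, 0.2, 0, 0]), LabelingModel(p, 5)),
            LabelingModel(p, 5)).condition_indicator for p in (0.8, 0.95, 0.999)]
        assert conds[0] > conds[1] > conds[2]
        assert conds[2] == pytest.approx(1.0, abs=1e-2)

    def test_parameter_recovery_is_unbiased(self):
        # labeling + perfect step counting on 10,000 particles: the mean of
        # ten replicate estimates recovers the truth well within 2 pp
        from smbleach.simulate import apply_labeling, sample_orders
        truth = np.array([0.13, 0.56, 0.14, 0.17, 0.0])
        model = LabelingModel(0.8, 5)
        estimates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            orders = sample_orders(truth, 10_000, seed=rng)
            labels = apply_labeling(orders, 0.8, seed=rng)
            counts = np.bincount(labels[labels > 0], minlength=6)[1:6]
            result = solve_corrected_fractions(ObservedStepHistogram(counts), model)
            estimates.append(result.corrected.fractions)
        assert np.all(np.abs(np.mean(estimates, axis=0) - truth) <= 0.02)


class TestEntityAndGrouping:
    def test_pure_monomer_unchanged(self):
        e = particle_to_entity(OligomerDistribution(np.array([1.0, 0, 0, 0, 0])))
        assert np.allclose(e.fractions, [1, 0, 0, 0, 0])

    def test_equal_monomer_dimer_weighting(self):
        e = particle_to_entity(OligomerDistribution(np.array([0.5, 0.5, 0, 0, 0])))
        assert np.allclose(e.fractions, [1 / 3, 2 / 3, 0, 0, 0])

    def test_high_density_entity_shares(self):
        x = np.array([0.133, 0.560, 0.135, 0.172, 0.0]) / 1.0
        e = particle_to_entity(OligomerDistribution(x / x.sum()))
        grouped = group_fractions(e)
        assert grouped["monomer"] == pytest.approx(0.05, abs=0.03)
        assert grouped["dimer"] == pytest.approx(0.46, abs=0.03)
        assert grouped["oligomer"] == pytest.approx(0.49, abs=0.03)

    def test_grouping_oligomer_sum(self):
        g = group_fractions(OligomerDistribution(
            np.array([0.133, 0.560, 0.135, 0.172, 0.0])))
        assert g["oligomer"] == pytest.approx(0.307, abs=1e-12)

    def test_identity_grouping_preserves(self):
        x = np.array([0.2, 0.3, 0.25, 0.15, 0.1])
        g = group_fractions(OligomerDistribution(x),
                            {i: str(i) for i in range(1, 6)})
        assert np.allclose([g[str(i)] for i in range(1, 6)], x)

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_group_sums_conserve_total(self, data):
        raw = np.array(data.draw(st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5)))
        x = raw / raw.sum()
        g = group_fractions(OligomerDistribution(x))
        assert sum(g.values()) == pytest.approx(1.0, abs=1e-12)

    def test_incomplete_grouping_rejected(self):
        with pytest.raises(ValueError):
            group_fractions(OligomerDistribution(np.array([0.5, 0.5, 0, 0, 0])),
                            {1: "monomer"})


class TestBootstrap:
    def test_narrow_intervals_at_large_n(self):
        model = LabelingModel(0.8, 5)
        r = forward_observe(np.array([0.4, 0.4, 0.2, 0, 0]), model)
        counts = np.round(r * 1_000_000).astype(int)
        ci = bootstrap_ci(ObservedStepHistogram(counts), model, b=200, seed=0)
        assert np.all(ci["ci_high"] - ci["ci_low"] < 0.01)

    def test_degenerate_monomer_zero_width(self):
        hist = ObservedStepHistogram(np.array([500, 0, 0, 0, 0]))
        ci = bootstrap_ci(hist, LabelingModel(1.0, 5), b=100, seed=1)
        assert np.allclose(ci["ci_low"], [1, 0, 0, 0, 0])
        assert np.allclose(ci["ci_high"], [1, 0, 0, 0, 0])

    def test_same_seed_identical(self):
        hist = ObservedStepHistogram(np.array([300, 150, 40, 10, 0]))
        model = LabelingModel(0.8, 5)
        a = bootstrap_ci(hist, model, b=100, seed=5)
        b = bootstrap_ci(hist, model, b=100, seed=5)
        assert a.equals(b)


class TestDensityArithmetic:
    @pytest.mark.parametrize("density,area,expected", [
        (0.22, 1200.0, 260),
        (1.0, 100.0, 100),
        (0.76, 1200.0, 910),
    ])
    def test_receptors_per_cell(self, density, area, expected):
        assert receptors_per_cell(density, area) == expected

    def test_raw_product_before_rounding(self):
        assert 0.76 * 1200 == pytest.approx(912.0)

    @pytest.mark.parametrize("bmax,ref,expected", [
        (7.0, 0.5, 14.0),
        (7.0, 3.06, 7.0 / 3.06),
        (3.3, 3.3, 1.0),
    ])
    def test_fold_over_reference(self, bmax, ref, expected):
        assert fold_over_reference(bmax, ref) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            fold_over_reference(1.0, 0.0)
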