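"""Ground-truth generator: order sampling, binomial labeling, traces, movies."""
import numpy as np
import pytest
from scipy import stats

from smbleach.simulate import (
    SimulationConfig,
    apply_labeling,
    render_movie,
    sample_bleach_frames,
    sample_orders,
    simulate_trace,
)


class TestSampleOrders:
    @pytest.mark.parametrize("fractions,expected", [
        ((1, 0, 0, 0, 0), 1),
        ((0, 1, 0, 0, 0), 2),
    ])
    def test_degenerate_distribution(self, fractions, expected):
        orders = sample_orders(fractions, 100, seed=0)
        assert np.all(orders == expected)

    def test_mean_order_within_sampling_error(self):
        n = 100_000
        orders = sample_orders((0.5, 0.5, 0, 0, 0), n, seed=1)
        se = 0.5 / np.sqrt(n)
        assert abs(orders.mean() - 1.5) < 3 * se

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            sample_orders((0.5, 0.6), 10, seed=0)
        with pytest.raises(ValueError):
            sample_orders((-0.1, 1.1), 10, seed=0)

    def test_reproducible_given_seed(self):
        a = sample_orders((0.3, 0.3, 0.4), 1000, seed=7)
        b = sample_orders((0.3, 0.3, 0.4), 1000, seed=7)
        assert np.array_equal(a, b)


class TestApplyLabeling:
    def test_full_labeling_is_identity(self):
        labeled = apply_labeling(np.full(100, 2), 1.0, seed=0)
        assert np.all(labeled == 2)

    def test_dimer_double_label_fraction(self):
        # both subunits of a dimer labeled with probability 0.8^2 = 64%
        n = 100_000
        labeled = apply_labeling(np.full(n, 2), 0.8, seed=2)
        frac = np.mean(labeled == 2)
        se = np.sqrt(0.64 * 0.36 / n)
        assert abs(frac - 0.64) < 3 * se

    def test_trimer_single_label_fraction(self):
        # 3 * 0.8 * 0.2^2 = 0.096
        n = 100_000
        labeled = apply_labeling(np.full(n, 3), 0.8, seed=3)
        frac = np.mean(labeled == 1)
        se = np.sqrt(0.096 * 0.904 / n)
        assert abs(frac - 0.096) < 3 * se

    @pytest.mark.parametrize("order", [1, 2, 3, 4, 5])
    def test_binomial_goodness_of_fit(self, order):
        n = 100_000
        labeled = apply_labeling(np.full(n, order), 0.8, seed=10 + order)
        observed = np.bincount(labeled, minlength=order + 1)
        expected = n * stats.binom.pmf(np.arange(order + 1), order, 0.8)
        _, p = stats.chisquare(observed, expected)
        assert p > 0.001

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError):
            apply_labeling([2, 2], 0.0, seed=0)
        with pytest.raises(ValueError):
            apply_labeling([2, 2], 1.2, seed=0)


class TestSimulateTrace:
    def test_unlabeled_particle_gives_flat_background(self):
        cfg = SimulationConfig(n_particles=1, shot_noise=False, read_noise_sd=0.0,
                               background_level=150.0, n_frames=50)
        trace = simulate_trace(0, cfg, seed=0)
        assert np.all(trace.intensity == 150.0)

    def test_noiseless_two_fluorophores_two_unit_steps(self):
        cfg = SimulationConfig(n_particles=1, shot_noise=False, read_noise_sd=0.0,
                               unit_intensity=300.0, background_level=100.0,
                               n_frames=200, mean_bleach_time=30.0)
        trace = simulate_trace(2, cfg, seed=4)
        drops = np.diff(trace.intensity)
        down = drops[drops < 0]
        assert len(down) == 2
        assert np.allclose(down, -300.0)
        assert trace.intensity[-1] == 100.0

    def test_first_bleach_time_of_three_fluorophores(self):
        # minimum of 3 exponentials with mean 100 frames has mean 100/3;
        # the recorded frame index is ceil(t), offset by +0.5 on average
        cfg = SimulationConfig(n_particles=1, n_frames=1000, mean_bleach_time=100.0)
        rng = np.random.default_rng(5)
        firsts = [sample_bleach_frames(3, 100.0, rng).min() for _ in range(10_000)]
        mean_first = np.mean(firsts) - 0.5
        se = (100 / 3) / np.sqrt(len(firsts))
        assert abs(mean_first - 100 / 3) < 3 * se

    def test_preacquisition_upstroke(self):
        cfg = SimulationConfig(n_particles=1, shot_noise=False, read_noise_sd=0.0,
                               unit_intensity=300.0, background_level=100.0,
                               n_frames=100, preacq_frames=20, preacq_scale=0.05,
                               mean_bleach_time=1000.0)
        trace = simulate_trace(1, cfg, seed=6)
        assert np.all(trace.intensity[:20] == pytest.approx(0.05 * 400.0))
        assert trace.intensity[20] == pytest.approx(400.0)  # the upstroke


class TestRenderMovie:
    def test_empty_population_gives_pure_background(self):
        cfg = SimulationConfig(n_particles=0, image_shape=(32, 32), n_frames=5,
                               shot_noise=False, read_noise_sd=0.0,
                               background_level=100.0)
        movie, truth = render_movie(cfg, seed=0)
        assert len(truth) == 0
        assert np.all(movie.data == 100.0)

    def test_single_spot_peaks_then_decays(self):
        cfg = SimulationConfig(
            true_fractions=(1.0,), n_particles=1, image_shape=(32, 32),
            shot_noise=False, read_noise_sd=0.0, labeling_efficiency=1.0,
            n_frames=60, mean_bleach_time=20.0, background_level=100.0, seed=1)
        movie, truth = render_movie(cfg)
        p = truth.particles[0]
        assert p.labeled_count == 1
        peak = np.unravel_index(np.argmax(movie.data[0]), movie.data[0].shape)
        assert peak == (round(p.position[0]), round(p.position[1]))
        b = p.bleach_frames[0]
        if b < cfg.n_frames:
            assert np.all(movie.data[b] == pytest.approx(100.0, abs=1e-3))

    def test_poisson_placement_density(self):
        cfg = SimulationConfig(particle_density=0.22, n_particles=None,
                               image_shape=(512, 512), n_frames=1,
                               shot_noise=False, read_noise_sd=0.0)
        movie, truth = render_movie(cfg, seed=42)
        assert truth.realized_density == pytest.approx(0.22, rel=0.10)

    def test_integrated_intensity_matches_gaussian_flux(self):
        # noiseless: total counts above background = sum(labeled) * unit * 2*pi*sigma^2
        cfg = SimulationConfig(true_fractions=(0.5, 0.5, 0, 0, 0), n_particles=10,
                               image_shape=(128, 128), n_frames=1,
                               shot_noise=False, read_noise_sd=0.0,
                               background_level=0.0, min_separation=10.0, seed=2)
        movie, truth = render_movie(cfg)
        total_labels = sum(p.labeled_count for p in truth.particles)
        expected = total_labels * cfg.unit_intensity * 2 * np.pi * cfg.psf_sigma**2
        assert movie.data[0].sum() == pytest.approx(expected, rel=0.01)

    def test_summary_consistent_with_particles(self, noiseless_cfg):
        _, truth = render_movie(noiseless_cfg)
        counts = np.zeros(5)
        for p in truth.particles:
            counts[p.true_order - 1] += 1
        assert np.allclose(truth.summary, counts / counts.sum())

    def test_same_seed_bit_identical(self, noiseless_cfg):
        m1, t1 = render_movie(noiseless_cfg, seed=9)
        m2, t2 = render_movie(noiseless_cfg, seed=9)
        assert np.array_equal(m1.data, m2.data)
        assert t1.to_dataframe().equals(t2.to_dataframe())

    def test_ground_truth_fractions_converge(self):
        cfg = SimulationConfig(true_fractions=(0.4, 0.4, 0.2, 0, 0),
                               n_particles=20_000, image_shape=(64, 64),
                               n_frames=1, shot_noise=False, read_noise_sd=0.0,
                               unit_intensity=0.0, seed=3)
        _, truth = render_movie(cfg)
        p = np.array([0.4, 0.4, 0.2, 0, 0])
        bound = 3 * np.sqrt(p * (1 - p) / len(truth))
        assert np.all(np.abs(truth.summary - p) <= np.maximum(bound, 1e-12))
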