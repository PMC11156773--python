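"""Projection components: SSIM, initialization, schedules, noise regularizer, recovery."""

import numpy as np
import pytest

from latentmorph import projection as pj
from latentmorph import stylegan as sg


@pytest.fixture(scope="module")
def toy_model():
    return sg.GeneratorModel(sg.GeneratorConfig(resolution=32, latent_dim=64, seed=3))


@pytest.fixture(scope="module")
def small_cfg():
    return pj.ProjectionConfig(iterations=40, init_samples=64, init_top_k=8,
                               lr_rampup_iters=5, lr_rampdown_iters=10,
                               noise_ramp_iters=20, seed=0)


class TestSsim:
    def test_self_similarity_is_one(self):
        x = np.random.default_rng(0).random((3, 32, 32))
        assert pj.ssim(x, x) == pytest.approx(1.0)

    def test_inverted_binary_image_scores_below_one(self):
        x = np.zeros((32, 32))
        x[8:24, 8:24] = 1.0
        assert pj.ssim(x, 1 - x) < 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((3, 32, 32)), rng.random((3, 32, 32))
        assert pj.ssim(a, b) == pytest.approx(pj.ssim(b, a))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            pj.ssim(np.zeros((16, 16)), np.zeros((32, 32)))


class TestInitLatent:
    def test_fixed_seed_reproducible(self, toy_model, small_cfg):
        target = sg.synthesize(toy_model, sg.map_latent(
            toy_model, np.random.default_rng(2).standard_normal(64)))
        a = pj.init_latent(toy_model, target, small_cfg)
        b = pj.init_latent(toy_model, target, small_cfg)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_top_k_equal_n_reduces_to_plain_mean(self, toy_model):
        cfg = pj.ProjectionConfig(iterations=10, init_samples=32, init_top_k=32,
                                  lr_rampup_iters=2, lr_rampdown_iters=2,
                                  noise_ramp_iters=5, seed=4)
        target = sg.synthesize(toy_model, sg.map_latent(
            toy_model, np.random.default_rng(5).standard_normal(64)))
        init_w, sigma_w = pj.init_latent(toy_model, target, cfg)
        # recompute the plain mean with the same draw stream
        rng = np.random.default_rng(cfg.seed)
        z = rng.standard_normal((32, 64)).astype(np.float32)
        w = sg.map_latent(toy_model, z)
        np.testing.assert_allclose(init_w, w.mean(axis=0), rtol=1e-5)
        assert sigma_w == pytest.approx(np.sqrt(w.var(axis=0).mean()), rel=1e-5)

    def test_sample_count_below_top_k_rejected(self):
        with pytest.raises(ValueError, match="init_samples"):
            pj.ProjectionConfig(init_samples=10, init_top_k=100)


class TestPerceptual:
    def test_zero_on_identical_and_symmetric(self):
        rng = np.random.default_rng(6)
        a, b = rng.random((3, 32, 32)), rng.random((3, 32, 32))
        emb = sg.RandomConvEmbedder()
        assert pj.perceptual_distance(a, a, emb) == pytest.approx(0.0)
        assert pj.perceptual_distance(a, b, emb) == pytest.approx(
            pj.perceptual_distance(b, a, emb), rel=1e-6)

    def test_increases_with_noise_level_on_average(self):
        rng = np.random.default_rng(7)
        base = rng.random((3, 32, 32))
        emb = sg.RandomConvEmbedder()
        levels = np.linspace(0.01, 0.5, 20)
        dists = [np.mean([pj.perceptual_distance(
            base, base + rng.normal(0, s, base.shape), emb) for _ in range(3)])
            for s in levels]
        assert np.corrcoef(levels, dists)[0, 1] > 0.9


def brute_force_noise_reg(m: np.ndarray) -> float:
    """Direct-summation oracle for the autocorrelation penalty of one map."""
    total = 0.0
    p = m.astype(np.float64)
    while True:
        r = p.shape[-1]
        sx = sum(p[y, x] * p[y, (x - 1) % r] for y in range(r) for x in range(r))
        sy = sum(p[y, x] * p[(y - 1) % r, x] for y in range(r) for x in range(r))
        total += (sx**2 + sy**2) / r**2
        if r <= 8:
            break
        p = 2.0 * p.reshape(r // 2, 2, r // 2, 2).mean(axis=(1, 3))
    return total


class TestNoiseReg:
    def test_zero_map_gives_zero(self):
        assert pj.noise_reg([np.zeros((8, 8))]) == 0.0

    def test_all_ones_8x8_gives_128(self):
        assert pj.noise_reg([np.ones((8, 8))]) == pytest.approx(128.0)
        assert brute_force_noise_reg(np.ones((8, 8))) == pytest.approx(128.0)

    def test_checkerboard_8x8_gives_128(self):
        cb = (-1.0) ** (np.add.outer(np.arange(8), np.arange(8)))
        assert pj.noise_reg([cb]) == pytest.approx(128.0)
        assert brute_force_noise_reg(cb) == pytest.approx(128.0)

    def test_matches_brute_force_on_random_pyramid(self):
        m = np.random.default_rng(8).standard_normal((16, 16))
        assert pj.noise_reg([m]) == pytest.approx(brute_force_noise_reg(m), rel=1e-4)

    def test_white_noise_penalty_far_below_structured(self):
        rng = np.random.default_rng(9)
        white = rng.standard_normal((16, 16))
        assert pj.noise_reg([np.ones((16, 16))]) / pj.noise_reg([white]) > 10

    def test_small_map_rejected(self):
        with pytest.raises(ValueError, match="8x8"):
            pj.noise_reg([np.ones((4, 4))])


class TestSchedules:
    def test_lr_endpoints_and_plateau(self):
        cfg = pj.ProjectionConfig()
        assert pj.lr_schedule(0, cfg) == 0.0
        assert pj.lr_schedule(50, cfg) == pytest.approx(0.1)
        assert pj.lr_schedule(1500, cfg) == pytest.approx(0.1)
        assert pj.lr_schedule(cfg.iterations - 1, cfg) == 0.0

    def test_lr_is_continuous_at_unit_steps(self):
        cfg = pj.ProjectionConfig()
        lrs = [pj.lr_schedule(i, cfg) for i in range(cfg.iterations)]
        assert np.abs(np.diff(lrs)).max() < cfg.lr_max / 10

    def test_lr_out_of_range_rejected(self):
        cfg = pj.ProjectionConfig()
        with pytest.raises(ValueError):
            pj.lr_schedule(-1, cfg)
        with pytest.raises(ValueError):
            pj.lr_schedule(cfg.iterations, cfg)

    def test_latent_noise_ramp_values(self):
        cfg = pj.ProjectionConfig()
        assert pj.latent_noise_std(750, 1.0, cfg) == 0.0
        assert pj.latent_noise_std(3000, 1.0, cfg) == 0.0
        assert pj.latent_noise_std(0, 1.0, cfg) == pytest.approx(0.05)
        assert pj.latent_noise_std(375, 1.0, cfg) == pytest.approx(0.0125)


class TestProject:
    def test_single_iteration_trace_and_shapes(self, toy_model):
        cfg = pj.ProjectionConfig(iterations=1, lr_rampup_iters=1, lr_rampdown_iters=1,
                                  noise_ramp_iters=1, init_samples=16, init_top_k=4, seed=1)
        target = sg.synthesize(toy_model, sg.map_latent(
            toy_model, np.random.default_rng(10).standard_normal(64)))
        res = pj.project(toy_model, target, cfg)
        assert res.loss_trace.shape == (1, 3)
        assert res.wplus.shape == (toy_model.num_style_layers, 64)
        assert len(res.noise_maps) == len(toy_model.synthesis.noise_shapes)

    def test_noise_maps_normalized_each_iteration(self, toy_model, small_cfg):
        target = sg.synthesize(toy_model, sg.map_latent(
            toy_model, np.random.default_rng(11).standard_normal(64)))
        res = pj.project(toy_model, target, small_cfg)
        for m in res.noise_maps:
            assert abs(m.mean()) < 1e-6
            assert m.std() == pytest.approx(1.0, abs=1e-5)

    def test_same_seed_gives_identical_traces(self, toy_model, small_cfg):
        target = sg.synthesize(toy_model, sg.map_latent(
            toy_model, np.random.default_rng(12).standard_normal(64)))
        a = pj.project(toy_model, target, small_cfg)
        b = pj.project(toy_model, target, small_cfg)
        np.testing.assert_array_equal(a.loss_trace, b.loss_trace)

    def test_loss_decreases_on_generator_produced_target(self, toy_model):
        cfg = pj.ProjectionConfig(iterations=120, init_samples=128, init_top_k=16,
                                  lr_rampup_iters=10, lr_rampdown_iters=30,
                                  noise_ramp_iters=30, seed=2)
        w_true = sg.map_latent(toy_model, np.random.default_rng(13).standard_normal(64))
        target = sg.synthesize(toy_model, w_true, noise="zero")
        res = pj.project(toy_model, target, cfg)
        assert res.loss_trace[-1, 0] <= res.loss_trace[0, 0]
        assert res.loss_trace[-1, 1] < 0.5 * res.loss_trace[0, 1]
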