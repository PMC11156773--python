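"""Generator/discriminator mechanics, training losses, ADA, and the Fréchet metric."""

import numpy as np
import pytest

from latentmorph import stylegan as sg
from latentmorph import tensor as T


@pytest.fixture(scope="module")
def toy_model():
    return sg.GeneratorModel(sg.GeneratorConfig(resolution=32, latent_dim=64, seed=0))


class TestMapping:
    def test_map_latent_deterministic(self, toy_model):
        z = np.random.default_rng(0).standard_normal(64)
        np.testing.assert_array_equal(sg.map_latent(toy_model, z), sg.map_latent(toy_model, z))

    def test_distinct_latents_map_to_distinct_styles(self, toy_model):
        rng = np.random.default_rng(1)
        w1 = sg.map_latent(toy_model, rng.standard_normal(64))
        w2 = sg.map_latent(toy_model, rng.standard_normal(64))
        assert not np.allclose(w1, w2)

    def test_mapped_population_has_finite_positive_spread(self, toy_model):
        z = np.random.default_rng(2).standard_normal((2000, 64)).astype(np.float32)
        w = sg.map_latent(toy_model, z)
        std = w.std(axis=0)
        assert np.all(np.isfinite(std)) and np.all(std > 0)

    def test_dimension_mismatch_rejected(self, toy_model):
        with pytest.raises(ValueError, match="latent dim"):
            sg.map_latent(toy_model, np.zeros(13))
        with pytest.raises(ValueError, match="finite"):
            sg.map_latent(toy_model, np.full(64, np.nan))


class TestSynthesis:
    def test_zero_noise_synthesis_is_pure_function(self, toy_model):
        w = sg.map_latent(toy_model, np.random.default_rng(3).standard_normal(64))
        a = sg.synthesize(toy_model, w, noise="zero")
        b = sg.synthesize(toy_model, w, noise="zero")
        np.testing.assert_array_equal(a, b)
        assert a.shape == (3, 32, 32)

    def test_broadcast_equals_explicit_wplus(self, toy_model):
        w = sg.map_latent(toy_model, np.random.default_rng(4).standard_normal(64))
        L = toy_model.num_style_layers
        assert L == 8
        explicit = np.repeat(w[None], L, axis=0)
        np.testing.assert_array_equal(sg.synthesize(toy_model, w),
                                      sg.synthesize(toy_model, explicit))

    def test_fixed_noise_stack_reproducible(self, toy_model):
        w = sg.map_latent(toy_model, np.random.default_rng(5).standard_normal(64))
        noise = [m.data for m in toy_model.make_noise(1, "random", np.random.default_rng(6))]
        a = sg.synthesize(toy_model, w, noise=noise)
        b = sg.synthesize(toy_model, w, noise=noise)
        np.testing.assert_array_equal(a, b)

    def test_wrong_layer_count_rejected(self, toy_model):
        with pytest.raises(ValueError, match="wplus"):
            sg.synthesize(toy_model, np.zeros((3, 64)))


class TestR1:
    def test_constant_discriminator_has_zero_penalty(self):
        class Const:
            def __call__(self, x):
                return T.tsum(x * np.float32(0.0)) + np.float32(1.0)

        pen = sg.r1_penalty(Const(), np.random.default_rng(0).standard_normal((4, 3, 8, 8)))
        assert pen.item() == pytest.approx(0.0)

    def test_linear_discriminator_matches_analytic_value(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((3, 8, 8)).astype(np.float32)

        class Linear:
            def __call__(self, x):
                return T.tsum(x * T.tensor(a), axis=(1, 2, 3))

        x = rng.standard_normal((5, 3, 8, 8))
        gamma = 2.0
        pen = sg.r1_penalty(Linear(), x, gamma)
        assert pen.item() == pytest.approx(gamma / 2 * (a.astype(np.float64) ** 2).sum(), rel=1e-5)

        class Doubled:
            def __call__(self, x):
                return T.tsum(x * T.tensor(2 * a), axis=(1, 2, 3))

        pen4 = sg.r1_penalty(Doubled(), x, gamma)
        assert pen4.item() == pytest.approx(4 * pen.item(), rel=1e-5)


class TestAda:
    @pytest.mark.parametrize(
        "p,rt,expected",
        [(1.0, 0.9, 1.0), (0.0, 0.1, 0.0), (0.5, 0.9, 0.55), (0.5, 0.1, 0.45)],
    )
    def test_controller_step_and_clamping(self, p, rt, expected):
        cfg = sg.TrainConfig(ada_target=0.6, ada_step=0.05)
        assert sg.ada_controller_step(p, rt, cfg) == pytest.approx(expected)


class TestFrechet:
    def test_identical_gaussians_give_zero(self):
        mu = np.array([1.0, 2.0])
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert sg.frechet_distance(mu, cov, mu, cov) == pytest.approx(0.0, abs=1e-8)

    def test_mean_shift_closed_form(self):
        mu1 = np.zeros(3)
        mu2 = np.array([2.0, 0.0, 0.0])
        eye = np.eye(3)
        assert sg.frechet_distance(mu1, eye, mu2, eye) == pytest.approx(4.0)

    def test_1d_variance_difference_closed_form(self):
        # N(0,1) vs N(0,4): (sigma1 - sigma2)^2 = 1
        assert sg.frechet_distance([0.0], [[1.0]], [0.0], [[4.0]]) == pytest.approx(1.0)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((50, 4))
        b = rng.standard_normal((50, 4)) + 1.0
        m1, s1 = sg.gaussian_stats(a)
        m2, s2 = sg.gaussian_stats(b)
        d12 = sg.frechet_distance(m1, s1, m2, s2)
        d21 = sg.frechet_distance(m2, s2, m1, s1)
        assert d12 >= 0 and d12 == pytest.approx(d21, rel=1e-6)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError, match="semidefinite"):
            sg.frechet_distance([0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]],
                                [0.0, 0.0], np.eye(2))


class TestTraining:
    def test_two_steps_smoke_finite_losses(self):
        rng = np.random.default_rng(0)
        data = rng.random((8, 3, 16, 16)).astype(np.float32)
        cfg = sg.TrainConfig(kimg_budget=0.016, batch_size=8, metric_interval=1000)
        gcfg = sg.GeneratorConfig(resolution=16, seed=0)
        res = sg.train(data, cfg, gcfg)
        assert len(res.history["loss_g"]) == 2
        assert np.all(np.isfinite(res.history["loss_g"]))
        assert np.all(np.isfinite(res.history["loss_d"]))
        for p in res.model.parameters():
            assert np.all(np.isfinite(p.data))
        assert all(0.0 <= p <= 1.0 for p in res.history["ada_p"])

    def test_same_seed_reproduces_first_step_losses(self):
        rng = np.random.default_rng(1)
        data = rng.random((8, 3, 16, 16)).astype(np.float32)
        cfg = sg.TrainConfig(kimg_budget=0.008, batch_size=8, metric_interval=1000, seed=5)
        a = sg.train(data, cfg, sg.GeneratorConfig(resolution=16, seed=5))
        b = sg.train(data, cfg, sg.GeneratorConfig(resolution=16, seed=5))
        assert a.history["loss_g"] == b.history["loss_g"]
        assert a.history["loss_d"] == b.history["loss_d"]

    def test_empty_or_mixed_input_rejected(self):
        with pytest.raises(ValueError):
            sg.train(np.empty((0, 3, 16, 16)))
        with pytest.raises(ValueError):
            sg.train(np.zeros((4, 3, 16, 24)))


class TestCheckpoint:
    def test_roundtrip_preserves_synthesis(self, toy_model, tmp_path):
        path = tmp_path / "model.npz"
        sg.save_checkpoint(path, toy_model, extra={"note": "test"})
        loaded, disc, extra = sg.load_checkpoint(path)
        assert disc is None and extra == {"note": "test"}
        w = sg.map_latent(toy_model, np.random.default_rng(8).standard_normal(64))
        np.testing.assert_array_equal(sg.synthesize(toy_model, w), sg.synthesize(loaded, w))
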