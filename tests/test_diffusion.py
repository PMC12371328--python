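"""Diffusion schedule, forward corruption, denoiser contracts, training
objective and the conditional reverse sampler."""

import numpy as np
import pytest

from phylodiff.diffusion import (
    DenoiserConfig,
    PhylumDenoiser,
    TrainConfig,
    forward_diffuse,
    impute,
    make_schedule,
    train,
    training_loss,
)
from phylodiff.missingness import TimepointMask
from phylodiff.nn import Tensor


def small_denoiser(blocks=((0, 3), (3, 6)), K=6, L=4, **kwargs):
    defaults = dict(channels=16, residual_layers=1, heads=4,
                    diffusion_embedding_dim=32)
    defaults.update(kwargs)
    cfg = DenoiserConfig(**defaults)
    return PhylumDenoiser(cfg, list(blocks), K, L,
                          rng=np.random.default_rng(0)), cfg


class TestSchedule:
    def test_linear_hand_product(self):
        s = make_schedule(T=2, beta_start=0.1, beta_end=0.2, kind="linear")
        np.testing.assert_allclose(s.beta, [0.1, 0.2])
        np.testing.assert_allclose(s.alpha_bar, [0.9, 0.72])

    def test_default_quadratic_terminal_alpha_bar(self):
        s = make_schedule()   # T=50, quadratic, 1e-4 -> 0.5
        assert s.T == 50
        assert s.alpha_bar[-1] < 0.01
        # independent cumulative product
        grid = np.arange(50) / 49
        beta = (np.sqrt(1e-4) + grid * (np.sqrt(0.5) - np.sqrt(1e-4))) ** 2
        np.testing.assert_allclose(s.alpha_bar, np.cumprod(1 - beta), rtol=1e-12)

    def test_alpha_bar_strictly_decreasing(self):
        for kind in ("linear", "quadratic"):
            s = make_schedule(T=30, beta_start=1e-3, beta_end=0.4, kind=kind)
            assert np.all(np.diff(s.alpha_bar) < 0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(T=10, beta_start=0.5, beta_end=0.1)
        with pytest.raises(ValueError):
            make_schedule(T=1)


class TestForwardDiffuse:
    def test_closed_form_limits(self):
        s = make_schedule(T=10, beta_start=1e-4, beta_end=0.5)
        x0 = np.full((2, 3), 1.0)
        # eps = 0 keeps sqrt(alpha_bar)*x0
        xt = forward_diffuse(x0, 10, np.zeros_like(x0), s)
        np.testing.assert_allclose(xt, np.sqrt(s.alpha_bar[-1]) * x0)

    def test_scalar_analytic_case(self):
        s = make_schedule(T=2, beta_start=0.5, beta_end=0.75, kind="linear")
        # alpha_bar_2 = 0.5*0.25 = 0.125; pick t where values known
        np.testing.assert_allclose(
            forward_diffuse(np.array([1.0]), 1, np.array([0.0]), s),
            [np.sqrt(0.5)])

    def test_out_of_range_step_rejected(self):
        s = make_schedule(T=5)
        with pytest.raises(ValueError):
            forward_diffuse(np.zeros(3), 0, np.zeros(3), s)
        with pytest.raises(ValueError):
            forward_diffuse(np.zeros(3), 6, np.zeros(3), s)

    def test_marginal_moments_match_closed_form(self):
        s = make_schedule(T=25)
        rng = np.random.default_rng(0)
        x0 = 1.7
        t = 12
        draws = forward_diffuse(
            np.full(10_000, x0), t, rng.standard_normal(10_000), s)
        abar = s.alpha_bar[t - 1]
        assert draws.mean() == pytest.approx(np.sqrt(abar) * x0, abs=0.03)
        assert draws.var() == pytest.approx(1 - abar, rel=0.05)


class TestDenoiser:
    def test_output_shape_matches_input(self):
        den, _ = small_denoiser()
        out = den(np.zeros((2, 4, 6)), np.zeros((2, 4, 6)),
                  np.ones((2, 4)), np.array([1, 2]))
        assert out.shape == (2, 4, 6)

    def test_non_contiguous_blocks_rejected(self):
        with pytest.raises(ValueError, match="not contiguous"):
            small_denoiser(blocks=((0, 3), (4, 6)))

    def test_parameter_count_grows_with_depth(self):
        d1, _ = small_denoiser(residual_layers=1)
        d2, _ = small_denoiser(residual_layers=2)
        assert d2.n_parameters() > d1.n_parameters()

    def test_spatial_metadata_widens_internal_width(self):
        cfg = DenoiserConfig(channels=16, residual_layers=1, heads=4,
                             metadata_strategy="spatial")
        den = PhylumDenoiser(cfg, [(0, 6)], 6, 4, vocab_sizes=[3, 4],
                             rng=np.random.default_rng(0))
        assert den.width == 6 + 2 * 8    # K + n·d with d = 8
        out = den(np.zeros((2, 4, 6)), np.zeros((2, 4, 6)),
                  np.ones((2, 4)), np.array([1, 1]),
                  metadata_codes=np.zeros((2, 2), dtype=int))
        assert out.shape == (2, 4, 6)

    def test_channel_metadata_widens_model_dim(self):
        cfg = DenoiserConfig(channels=16, residual_layers=1, heads=4,
                             metadata_strategy="channel")
        den = PhylumDenoiser(cfg, [(0, 6)], 6, 4, vocab_sizes=[3, 4],
                             rng=np.random.default_rng(0))
        assert den.d_model == 16 + 2 * 8   # C + n·d channels


class TestTrainingLoss:
    def setup_method(self):
        self.sched = make_schedule(T=8, beta_start=1e-3, beta_end=0.3)
        self.x0 = np.random.default_rng(0).normal(size=(3, 4, 6))
        target = np.array([[0, 1, 0, 1]] * 3, dtype=np.int8)
        cond = 1 - target
        self.split = TimepointMask(target, cond, 0.5)

    def test_zero_for_oracle_denoiser(self):
        injected = {}

        class Oracle:
            def __call__(self, noisy, cond_plane, cond_mask, t, codes=None):
                return Tensor(injected["eps"])

        rng = np.random.default_rng(1)
        # capture the noise the loss will draw by mirroring its rng stream
        rng_probe = np.random.default_rng(1)
        rng_probe.integers(1, self.sched.T + 1, size=3)
        injected["eps"] = rng_probe.standard_normal(self.x0.shape)
        loss = training_loss(Oracle(), self.x0, self.split, self.sched, rng)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_zero_predictor_loss_near_one(self):
        class Zero:
            def __call__(self, noisy, cond_plane, cond_mask, t, codes=None):
                return Tensor(np.zeros(noisy.shape))

        rng = np.random.default_rng(2)
        losses = [
            float(training_loss(Zero(), self.x0, self.split, self.sched, rng).data)
            for _ in range(300)
        ]
        # E[eps^2] = 1 for standard normal noise
        assert np.mean(losses) == pytest.approx(1.0, abs=0.05)

    def test_loss_averages_only_target_entries(self):
        """With a prediction that does not depend on its inputs, changing
        the conditional timepoints' values cannot move the loss — the
        average runs over target entries only."""

        class Zero:
            def __call__(self, noisy, cond_plane, cond_mask, t, codes=None):
                return Tensor(np.zeros(noisy.shape))

        x_alt = self.x0.copy()
        x_alt[self.split.cond.astype(bool)] += 123.0   # only cond timepoints
        l1 = training_loss(Zero(), self.x0, self.split, self.sched,
                           np.random.default_rng(3))
        l2 = training_loss(Zero(), x_alt, self.split, self.sched,
                           np.random.default_rng(3))
        assert float(l1.data) == pytest.approx(float(l2.data), rel=1e-12)

    def test_empty_target_rejected(self):
        empty = TimepointMask(np.zeros((3, 4), dtype=np.int8),
                              np.ones((3, 4), dtype=np.int8), 0.0)
        den, _ = small_denoiser(K=6, L=4)
        with pytest.raises(ValueError, match="empty target"):
            training_loss(den, self.x0, empty, self.sched,
                          np.random.default_rng(0))


class TestTrain:
    def test_same_seed_reproduces_history(self):
        rng = np.random.default_rng(0)
        x0 = rng.normal(size=(6, 4, 6)).astype(np.float32)
        observed = np.ones((6, 4), dtype=np.int8)
        sched = make_schedule(T=6, beta_start=1e-3, beta_end=0.3)
        histories = []
        for _ in range(2):
            den, _ = small_denoiser(K=6, L=4)
            histories.append(train(x0, observed, den, sched,
                                   TrainConfig(epochs=3, batch=4, seed=11)))
        np.testing.assert_allclose(histories[0], histories[1], rtol=1e-6)

    def test_zero_epochs_returns_empty_history(self):
        den, _ = small_denoiser(K=6, L=4)
        sched = make_schedule(T=6, beta_start=1e-3, beta_end=0.3)
        hist = train(np.zeros((4, 4, 6)), np.ones((4, 4), dtype=np.int8),
                     den, sched, TrainConfig(epochs=0, seed=0))
        assert hist == []


class TestImpute:
    def make_mask(self, S=3, L=4):
        target = np.zeros((S, L), dtype=np.int8)
        target[:, 1] = 1
        cond = 1 - target
        return TimepointMask(target, cond, 0.25)

    def test_conditional_entries_bitwise_preserved(self):
        den, _ = small_denoiser(K=6, L=4)
        sched = make_schedule(T=6, beta_start=1e-3, beta_end=0.3)
        x = np.random.default_rng(0).normal(size=(3, 4, 6)).astype(np.float32)
        mask = self.make_mask()
        res = impute(den, x, mask, sched, n_draws=4, seed=1)
        co = mask.cond.astype(bool)
        np.testing.assert_array_equal(res.point[co], x[co])
        for d in range(4):
            np.testing.assert_array_equal(res.draws[d][co], x[co])

    def test_draws_vary_but_point_is_stable(self):
        den, _ = small_denoiser(K=6, L=4)
        sched = make_schedule(T=6, beta_start=1e-3, beta_end=0.3)
        x = np.random.default_rng(0).normal(size=(3, 4, 6)).astype(np.float32)
        mask = self.make_mask()
        a = impute(den, x, mask, sched, n_draws=40, seed=1)
        b = impute(den, x, mask, sched, n_draws=40, seed=2)
        ta = mask.target.astype(bool)
        assert not np.array_equal(a.draws[0][ta], b.draws[0][ta])
        # Monte-Carlo stability of the median point estimate
        spread = np.abs(a.point[ta] - b.point[ta]).mean()
        draw_sd = a.draws.std(axis=0)[ta].mean()
        assert spread < draw_sd

    def test_single_step_zero_denoiser_closed_form(self):
        """With T=1 and a zero-output denoiser the reverse step is the
        deterministic map x0 = x_1 / sqrt(alpha_1)."""

        class Zero:
            def __call__(self, noisy, cond_plane, cond_mask, t, codes=None):
                return Tensor(np.zeros(noisy.shape))

        from phylodiff.diffusion import NoiseSchedule
        beta = np.array([0.36])
        sched = NoiseSchedule(1, beta, 1 - beta, np.array([0.64]))
        x = np.zeros((1, 4, 6))
        mask = self.make_mask(S=1)
        res = impute(Zero(), x, mask, sched, n_draws=1, seed=5)
        # replicate: initial noise for targets, one step mean, no sigma term
        rng = np.random.default_rng(5)
        ta = np.repeat(mask.target[:, :, None], 6, axis=2).astype(float)
        init = ta * rng.standard_normal((1, 4, 6))
        expected = ta * (init / np.sqrt(0.64))
        np.testing.assert_allclose(res.draws[0], expected, rtol=1e-6)

    def test_invalid_draw_count(self):
        den, _ = small_denoiser(K=6, L=4)
        sched = make_schedule(T=4, beta_start=1e-3, beta_end=0.3)
        with pytest.raises(ValueError):
            impute(den, np.zeros((3, 4, 6)), self.make_mask(), sched, n_draws=0)
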