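"""Training loop: loss, clipping, AdaBelief, gradients, parameter recovery."""

import numpy as np
import pytest

import kinfit as kf
from kinfit.errors import NonFiniteGradientError, ZeroMeanSpeciesError
from kinfit.training import (
    AdaBeliefState,
    TrainerConfig,
    _train_batch,
    clip_by_global_norm,
    global_norm,
    mean_centered_loss,
)


class TestMeanCenteredLoss:
    def test_zero_on_identical_inputs(self, f2_dataset):
        assert mean_centered_loss(f2_dataset.values, f2_dataset) == 0.0

    def test_hand_case(self):
        # one species, obs (1, 3): mean 2; pred (2, 4): J = (0.5^2 + 0.5^2)/2
        obs = kf.TimeSeriesDataset(times=[0, 1], species=["A"], values=[[1.0, 3.0]])
        assert mean_centered_loss(np.array([[2.0, 4.0]]), obs) == pytest.approx(0.25)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.5, 2.0, (2, 5))
        pred = vals + rng.normal(0, 0.1, vals.shape)
        obs = kf.TimeSeriesDataset(times=np.arange(5.0), species=["A", "B"], values=vals)
        J1 = mean_centered_loss(pred, obs)
        c = 37.5
        obs_scaled = kf.TimeSeriesDataset(
            times=np.arange(5.0), species=["A", "B"], values=vals * c
        )
        assert mean_centered_loss(pred * c, obs_scaled) == pytest.approx(J1, rel=1e-12)

    def test_missing_values_excluded(self):
        obs = kf.TimeSeriesDataset(
            times=[0, 1, 2], species=["A"], values=[[1.0, np.nan, 3.0]]
        )
        # only the two observed points count; mean is 2, N = 2
        J = mean_centered_loss(np.array([[2.0, 99.0, 4.0]]), obs)
        assert J == pytest.approx(0.25)

    def test_zero_mean_species_raises(self):
        obs = kf.TimeSeriesDataset(times=[0, 1], species=["A"], values=[[1.0, -1.0]])
        with pytest.raises(ZeroMeanSpeciesError):
            mean_centered_loss(np.array([[1.0, -1.0]]), obs)


class TestNormAndClip:
    def test_global_norm_cases(self):
        assert global_norm(np.zeros(4)) == 0.0
        assert global_norm(np.array([3.0, 4.0])) == pytest.approx(5.0)
        rng = np.random.default_rng(5)
        g = rng.normal(size=100)
        acc = 0.0
        for x in g:  # independent elementwise accumulation
            acc += x * x
        assert global_norm(g) == pytest.approx(np.sqrt(acc), rel=1e-12)

    def test_non_finite_gradient_rejected(self):
        with pytest.raises(NonFiniteGradientError):
            global_norm(np.array([1.0, np.nan]))

    def test_clip_within_bound_unchanged(self):
        g = np.array([1.0, 1.0])
        np.testing.assert_array_equal(clip_by_global_norm(g, 4.0), g)

    def test_clip_rescales_exactly(self):
        clipped = clip_by_global_norm(np.array([3.0, 4.0]), 4.0)
        np.testing.assert_allclose(clipped, [2.4, 3.2], rtol=1e-12)
        assert global_norm(clipped) <= 4.0 + 1e-12

    def test_clip_zero_vector(self):
        np.testing.assert_array_equal(clip_by_global_norm(np.zeros(3), 4.0), np.zeros(3))

    @pytest.mark.parametrize("scale", [0.1, 10.0, 1e4])
    def test_post_clip_norm_never_exceeds_cap(self, scale):
        rng = np.random.default_rng(int(scale))
        for _ in range(20):
            g = rng.normal(size=7) * scale
            assert global_norm(clip_by_global_norm(g, 4.0)) <= 4.0 * (1 + 1e-12)


class TestAdaBelief:
    def test_zero_gradient_is_fixpoint(self):
        state = AdaBeliefState.zeros(3)
        delta = state.step(np.zeros(3), TrainerConfig())
        np.testing.assert_array_equal(delta, np.zeros(3))

    def test_first_step_hand_value(self):
        # fresh state, scalar g=1: m̂=1, √ŝ=0.9 -> Δ = -lr/0.9 = -1.111e-3
        state = AdaBeliefState.zeros(1)
        delta = state.step(np.ones(1), TrainerConfig())
        assert delta[0] == pytest.approx(-1.1111111e-3, rel=1e-4)

    def test_matches_independent_reimplementation(self):
        cfg = TrainerConfig()
        state = AdaBeliefState.zeros(4)
        rng = np.random.default_rng(2)
        g = rng.normal(size=4)
        # independent loop following the published update equations
        m = np.zeros(4)
        s = np.zeros(4)
        phi_ref = np.zeros(4)
        phi = np.zeros(4)
        for t in range(1, 11):
            m = cfg.beta1 * m + (1 - cfg.beta1) * g
            s = cfg.beta2 * s + (1 - cfg.beta2) * (g - m) ** 2 + cfg.eps
            mhat = m / (1 - cfg.beta1**t)
            shat = s / (1 - cfg.beta2**t)
            phi_ref -= cfg.learning_rate * mhat / (np.sqrt(shat) + cfg.eps)
            phi += state.step(g, cfg)
        np.testing.assert_allclose(phi, phi_ref, atol=1e-10)


class TestLossGradient:
    def test_zero_gradient_at_truth_on_noiseless_data(self, f2, f2_dataset):
        model, _, _ = f2
        J, g = kf.loss_gradient(model, None, f2_dataset)
        assert J < 1e-12
        assert np.linalg.norm(g) < 1e-4

    def test_decay_gradient_sign(self, f1, f1_dataset):
        # data from k=0.5; at k/3 the loss decreases as k grows
        model, _, _ = f1
        _, g = kf.loss_gradient(model, np.array([0.5 / 3]), f1_dataset)
        assert g[0] < 0

    def test_matches_finite_differences_in_log_space(self, chain3):
        model, theta_true, t_end = chain3
        ds = kf.generate_synthetic_dataset(model, None, t_end)
        cfg = TrainerConfig()
        from kinfit.training import _make_engines

        engine = _make_engines(model, [ds], cfg)[0]
        rng = np.random.default_rng(123)
        h = 1e-4
        for _ in range(10):
            theta = theta_true * np.exp(rng.uniform(-1.0, 1.0, 3))
            _, g = kf.loss_gradient(model, theta, ds)
            for j in range(3):
                step = np.zeros(3)
                step[j] = h
                up = engine.loss_value((theta * np.exp(step))[None, :])[0][0]
                dn = engine.loss_value((theta * np.exp(-step))[None, :])[0][0]
                fd = (up - dn) / (2 * h)
                assert g[j] == pytest.approx(fd, rel=1e-3, abs=1e-10)

    def test_failure_raises_gradient_unavailable(self):
        import sympy

        from kinfit.errors import GradientUnavailableError
        from kinfit.sbml import ModelSpec, Reaction, Species

        spec = ModelSpec(
            species=[Species("A", 1.0, "cell")],
            compartments={"cell": 1.0},
            global_params={"k": 50.0},
            reactions=[Reaction("r", {}, {"A": 1.0}, rate=sympy.sympify("k*A**2"))],
            flattened=True,
        )
        model = kf.KineticModel(spec)
        ds = kf.TimeSeriesDataset(times=[0.0, 1.0], species=["A"], values=[[1.0, 1.0]])
        with pytest.raises(GradientUnavailableError):
            kf.loss_gradient(model, None, ds)


class TestTrain:
    def test_start_at_truth_converges_immediately(self, f1, f1_dataset):
        model, _, _ = f1
        res = kf.train(model, None, f1_dataset)
        assert res.status == "converged-early"
        assert res.n_iter <= 1

    def test_decay_parameter_recovery(self, f1, f1_dataset):
        model, theta_true, _ = f1
        res = kf.train(model, np.array([3 * theta_true["k"]]), f1_dataset)
        assert res.final_loss < 1e-6
        assert res.params["k"] == pytest.approx(theta_true["k"], rel=0.01)

    def test_trace_bookkeeping_and_descent(self, f1, f1_dataset):
        model, theta_true, _ = f1
        cfg = TrainerConfig(max_iter=200)
        res = kf.train(model, np.array([3 * theta_true["k"]]), f1_dataset, config=cfg)
        assert len(res.trace.loss) <= cfg.max_iter
        assert res.final_loss <= res.initial_loss
        # descent sanity: non-increasing over any 50-iteration window
        loss = res.trace.loss
        for i in range(0, len(loss) - 50):
            assert loss[i + 50] <= loss[i] + 1e-15

    def test_positivity_preserved_along_iterates(self, f1, f1_dataset):
        model, _, _ = f1
        cfg = TrainerConfig(max_iter=50, snapshot_stride=1)
        res = kf.train(model, np.array([1.4]), f1_dataset, config=cfg)
        for _, theta in res.trace.snapshots:
            assert np.all(theta > 0)

    def test_clipped_norms_respect_cap(self, f2, f2_dataset):
        model, _, _ = f2
        cfg = TrainerConfig(max_iter=30)
        res = kf.train(model, np.array([7.0, 0.03]), f2_dataset, config=cfg)
        assert np.all(res.trace.clipped_norm <= cfg.clip_norm * (1 + 1e-12))

    def test_summary_mentions_parameters(self, f1, f1_dataset):
        model, _, _ = f1
        res = kf.train(model, np.array([1.0]), f1_dataset,
                       config=TrainerConfig(max_iter=5))
        text = res.summary()
        assert "k" in text and "final loss" in text


class TestTrainMulti:
    def test_single_dataset_list_bitwise_equals_train(self, f1, f1_dataset):
        model, _, _ = f1
        cfg = TrainerConfig(max_iter=40)
        a = kf.train(model, np.array([1.2]), f1_dataset, config=cfg)
        b = kf.train_multi(model, np.array([1.2]), [f1_dataset], config=cfg)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.trace.loss, b.trace.loss)

    def test_duplicate_datasets_match_single(self, f1, f1_dataset):
        model, _, _ = f1
        cfg = TrainerConfig(max_iter=40)
        a = kf.train(model, np.array([1.2]), f1_dataset, config=cfg)
        b = kf.train_multi(model, np.array([1.2]), [f1_dataset, f1_dataset], config=cfg)
        np.testing.assert_allclose(a.theta, b.theta, rtol=1e-12)

    def test_first_update_equals_hand_averaged_gradients(self, f2):
        model, _, t_end = f2
        ds1 = kf.generate_synthetic_dataset(model, None, t_end)
        ds2 = kf.generate_synthetic_dataset(
            model, None, t_end, noise_pct=5.0, seed=99
        )
        theta0 = np.array([1.4, 0.2])
        cfg = TrainerConfig(max_iter=1)
        _, g1 = kf.loss_gradient(model, theta0, ds1)
        _, g2 = kf.loss_gradient(model, theta0, ds2)
        g_mean = clip_by_global_norm((g1 + g2) / 2, cfg.clip_norm)
        state = AdaBeliefState.zeros(2)
        delta = state.step(g_mean, cfg)
        expected = theta0 * np.exp(delta)
        res = kf.train_multi(model, theta0, [ds1, ds2], config=cfg)
        np.testing.assert_allclose(res.theta, expected, rtol=1e-12)


def test_batch_training_matches_sequential(f2, f2_dataset):
    """Vectorized multi-start training equals run-by-run training."""
    model, _, _ = f2
    cfg = TrainerConfig(max_iter=25)
    starts = np.array([[1.4, 0.2], [0.3, 0.9]])
    batch = _train_batch(model, starts, [f2_dataset], cfg)
    for i, row in enumerate(starts):
        single = kf.train(model, row, f2_dataset, config=cfg)
        np.testing.assert_allclose(batch[i].theta, single.theta, rtol=1e-10)
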