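import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexcompnet.grunet import (
    WEIGHT_NAMES,
    GRUParams,
    GRUWordRecognizer,
    batch_backward,
    batch_forward,
    batch_loss_and_dLdh,
    forward,
    gru_step,
    init_params,
    trial_loss,
)


def finite_difference_grads(p, X, Y, eps=1e-6):
    def loss_of():
        hs, _ = batch_forward(p, X)
        return batch_loss_and_dLdh(hs, Y)[0]

    out = {}
    for name in WEIGHT_NAMES:
        W = getattr(p, name)
        g = np.zeros_like(W)
        for i in range(W.shape[0]):
            for j in range(W.shape[1]):
                orig = W[i, j]
                W[i, j] = orig + eps
                lp = loss_of()
                W[i, j] = orig - eps
                lm = loss_of()
                W[i, j] = orig
                g[i, j] = (lp - lm) / (2 * eps)
        out[name] = g
    return out


class TestInit:
    def test_same_seed_identical(self):
        a = init_params(5, 7, 42)
        b = init_params(5, 7, 42)
        for n in WEIGHT_NAMES:
            np.testing.assert_array_equal(getattr(a, n), getattr(b, n))

    def test_different_seeds_differ(self):
        a = init_params(5, 7, 1)
        b = init_params(5, 7, 2)
        assert not np.array_equal(a.W, b.W)

    def test_full_scale_shapes(self):
        p = init_params(20, 450, 0)
        assert p.W.shape == (450, 20)
        assert p.U.shape == (450, 450)


class TestGruStep:
    def test_zero_weights_halve_previous_state(self):
        p = GRUParams(*[np.zeros(s) for s in
                        [(4, 3), (4, 4), (4, 3), (4, 4), (4, 3), (4, 4)]])
        h_prev = np.array([0.2, -0.4, 0.6, 0.0])
        s = gru_step(p, np.ones(3), h_prev)
        np.testing.assert_allclose(s.u, 0.5)
        np.testing.assert_allclose(s.r, 0.5)
        np.testing.assert_allclose(s.h_cand, 0.0)
        np.testing.assert_allclose(s.h, 0.5 * h_prev)

    def test_zero_input_zero_state_stays_zero(self):
        p = init_params(3, 4, 9)
        s = gru_step(p, np.zeros(3), np.zeros(4))
        np.testing.assert_allclose(s.h, 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_state_remains_in_open_unit_ball(self, seed):
        rng = np.random.default_rng(seed)
        p = init_params(3, 4, seed % 1000)
        h = rng.uniform(-0.999, 0.999, 4)
        x = rng.uniform(-2, 2, 3)
        for _ in range(5):
            h = gru_step(p, x, h).h
            assert np.all(np.abs(h) < 1.0)

    def test_dimension_mismatch_raises(self):
        p = init_params(3, 4, 0)
        with pytest.raises(ValueError):
            gru_step(p, np.zeros(5), np.zeros(4))


class TestForward:
    def test_full_scale_output_shape(self):
        p = init_params(20, 450, 0)
        states = forward(p, np.zeros((32, 20)))
        assert states.shape == (32, 450)

    def test_empty_sequence(self):
        p = init_params(3, 4, 0)
        assert forward(p, np.zeros((0, 3))).shape == (0, 4)

    def test_composition_equals_stepwise(self):
        rng = np.random.default_rng(0)
        p = init_params(3, 4, 1)
        X = rng.random((6, 3))
        full = forward(p, X)
        h = np.zeros(4)
        for t in range(6):
            h = gru_step(p, X[t], h).h
            np.testing.assert_allclose(full[t], h)

    def test_batch_forward_agrees_with_single(self):
        rng = np.random.default_rng(1)
        p = init_params(3, 5, 2)
        X = rng.random((4, 7, 3))
        hs, _ = batch_forward(p, X)
        for i in range(4):
            np.testing.assert_allclose(hs[i], forward(p, X[i]), atol=1e-12)


class TestTrialLoss:
    def test_perfect_outputs_zero_loss(self):
        target = np.array([1.0, 0.0, 1.0])
        outputs = np.tile(target, (5, 1))
        assert trial_loss(outputs, target) == 0.0

    def test_constant_zero_output_gives_fraction_of_ones(self):
        target = np.array([1, 1, 0, 0, 0], dtype=float)  # q = 0.4
        outputs = np.zeros((7, 5))
        assert trial_loss(outputs, target) == pytest.approx(0.4)

    def test_nonnegative(self):
        rng = np.random.default_rng(3)
        assert trial_loss(rng.normal(size=(4, 6)), rng.integers(0, 2, 6)) >= 0.0

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            trial_loss(np.zeros((0, 3)), np.zeros(3))


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        p = init_params(3, 4, 1)
        X = rng.random((2, 5, 3))
        Y = rng.integers(0, 2, (2, 4)).astype(float)
        hs, cache = batch_forward(p, X)
        _, dLdh = batch_loss_and_dLdh(hs, Y)
        grads = batch_backward(p, X, cache, dLdh)
        numeric = finite_difference_grads(p, X, Y)
        for name in WEIGHT_NAMES:
            rel = np.abs(grads[name] - numeric[name]) / np.maximum(
                np.abs(numeric[name]), 1e-8
            )
            assert rel.max() < 1e-5, name

    def test_bce_gradients_match_finite_differences(self):
        rng = np.random.default_rng(5)
        p = init_params(2, 3, 7)
        X = rng.random((2, 4, 2))
        Y = rng.integers(0, 2, (2, 3)).astype(float)
        hs, cache = batch_forward(p, X)
        _, dLdh = batch_loss_and_dLdh(hs, Y, "bce")
        grads = batch_backward(p, X, cache, dLdh)

        def loss_of():
            h, _ = batch_forward(p, X)
            return batch_loss_and_dLdh(h, Y, "bce")[0]

        eps = 1e-6
        W = p.W_u
        num = np.zeros_like(W)
        for i in range(W.shape[0]):
            for j in range(W.shape[1]):
                orig = W[i, j]
                W[i, j] = orig + eps
                lp = loss_of()
                W[i, j] = orig - eps
                lm = loss_of()
                W[i, j] = orig
                num[i, j] = (lp - lm) / (2 * eps)
        rel = np.abs(grads["W_u"] - num) / np.maximum(np.abs(num), 1e-8)
        assert rel.max() < 1e-5


class TestTraining:
    def _toy(self, n=3, T=6, din=4, dout=5, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((n, T, din))
        Y = rng.integers(0, 2, (n, dout)).astype(float)
        return X, Y

    def test_first_update_descends_at_small_step(self):
        X, Y = self._toy()
        m0 = GRUWordRecognizer(hidden_dim=5, learning_rate=1e-3, momentum=0.0,
                               nesterov=False, epochs=1, eval_every=1,
                               random_state=3, dtype="float64")
        m0.fit(X, Y)
        hs, _ = batch_forward(m0.params_, X)
        after, _ = batch_loss_and_dLdh(hs, Y)
        before, _ = batch_loss_and_dLdh(batch_forward(init_params(4, 5, 3), X)[0], Y)
        assert after <= before

    def test_fixed_seed_reproducible_log(self):
        X, Y = self._toy()
        runs = []
        for _ in range(2):
            m = GRUWordRecognizer(hidden_dim=5, epochs=20, eval_every=5,
                                  random_state=11)
            m.fit(X, Y, eval_fn=lambda p, e: {"w_sum": float(p.W.sum())})
            runs.append(m.log_)
        assert runs[0] == runs[1]

    def test_minibatch_option_runs(self):
        X, Y = self._toy(n=4)
        m = GRUWordRecognizer(hidden_dim=5, epochs=3, eval_every=3,
                              batch_size=2, random_state=0)
        m.fit(X, Y)
        assert m.n_epochs_ == 3

    def test_inconsistent_dimensions_rejected(self):
        X, Y = self._toy()
        with pytest.raises(ValueError):
            GRUWordRecognizer(hidden_dim=9).fit(X, Y)
        with pytest.raises(ValueError):
            GRUWordRecognizer(hidden_dim=5).fit(X[0], Y)

    def test_sklearn_param_interface(self):
        m = GRUWordRecognizer(learning_rate=0.1)
        assert m.get_params()["learning_rate"] == 0.1
        m.set_params(momentum=0.9)
        assert m.momentum == 0.9


class TestConvergenceOnTenItems:
    def test_ten_item_vocabulary_is_fully_learned(self):
        """Trained long enough, a 10-item vocabulary is fully mastered:
        both constituents recognized for every item, each item's binarized
        target reproduced exactly at word offset, and the loss falls far
        below its starting value (an irreducible floor remains from the
        pre-onset timesteps, where the word is not yet identifiable)."""
        from lexcompnet.evaluation import TrainingMonitor
        from lexcompnet.phonology import VocabularyItem
        from lexcompnet.pipeline import assemble
        from lexcompnet.synth import _fixture_inventory

        inv = _fixture_inventory()
        cons = inv.consonants()
        vows = inv.vowels()
        vocab = [
            VocabularyItem(f"w{i}", (cons[i], vows[i % 5], cons[(i + 3) % 10]),
                           f"cat{i % 3}")
            for i in range(10)
        ]
        rng = np.random.default_rng(0)
        sem = rng.integers(0, 2, (10, 20)).astype(float)
        vis = rng.integers(0, 2, (10, 20)).astype(float)
        ds = assemble(vocab, inv, sem, vis, n_slots=4)
        monitor = TrainingMonitor(
            X=ds.X, offsets=ds.offsets, semvis_targets=ds.semvis_targets,
            lexical_targets=ds.lexical_targets, item_ids=ds.item_ids,
            spec=ds.spec,
        )
        model = GRUWordRecognizer(hidden_dim=ds.spec.total_dim, epochs=30000,
                                  eval_every=1000, convergence_patience=0,
                                  random_state=1)
        model.fit(ds.X, ds.Y, eval_fn=monitor)
        assert model.log_[-1]["pct_both"] == 100.0
        hs = model.forward_states(ds.X)
        h_off = hs[np.arange(10), ds.offsets]
        assert (((h_off > 0.5).astype(float) == ds.Y).all(axis=1)).all()
        assert model.loss_curve_[-1][1] < 0.5 * model.loss_curve_[0][1]
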