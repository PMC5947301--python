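"""Network propagation and online backprop: oracles, isolation, descent."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import babblereach as br

TOY_SIZES = br.LayerSizes(motor=3, visual=2, hidden=4)


def _snapshot(params):
    return {
        name: getattr(params, name).copy()
        for name in br.ModelParams.FORWARD_FIELDS + br.ModelParams.INVERSE_FIELDS
    }


def loop_forward_step(params, u, y, h):
    """Matrix-free reimplementation of the forward propagation."""
    H = params.W_hh.shape[0]
    V = params.W_hy.shape[0]
    y = np.zeros(params.W_vy.shape[1]) if y is None else y
    h_new = np.empty(H)
    for i in range(H):
        s = 0.0
        for j in range(len(u)):
            s += params.W_mu[i, j] * u[j]
        for j in range(len(y)):
            s += params.W_vy[i, j] * y[j]
        for j in range(H):
            s += params.W_hh[i, j] * h[j]
        h_new[i] = 1.0 / (1.0 + np.exp(-s))
    y_pred = np.empty(V)
    for i in range(V):
        s = 0.0
        for j in range(H):
            s += params.W_hy[i, j] * h_new[j]
        y_pred[i] = 1.0 / (1.0 + np.exp(-s))
    return h_new, y_pred


def loop_inverse_step(params, y_next, h):
    H = params.V_h.shape[0]
    M = params.V_u.shape[0]
    h_inv = np.empty(H)
    for i in range(H):
        s = 0.0
        for j in range(len(y_next)):
            s += params.V_y[i, j] * y_next[j]
        for j in range(H):
            s += params.V_h[i, j] * h[j]
        h_inv[i] = 1.0 / (1.0 + np.exp(-s))
    u_post = np.empty(M)
    for i in range(M):
        s = 0.0
        for j in range(H):
            s += params.V_u[i, j] * h_inv[j]
        u_post[i] = 1.0 / (1.0 + np.exp(-s))
    return u_post


class TestLogistic:
    def test_zero_maps_to_half(self):
        assert br.logistic(np.array([0.0]))[0] == pytest.approx(0.5)

    @given(arrays(np.float64, 5, elements=st.floats(-30, 30)))
    @settings(max_examples=100, derandomize=True)
    def test_symmetry_and_open_range(self, x):
        y = br.logistic(x)
        assert np.allclose(y + br.logistic(-x), 1.0)
        assert np.all(y > 0.0) and np.all(y < 1.0)


class TestPropagation:
    def test_zero_weights_give_half_everywhere(self):
        sizes = TOY_SIZES
        params = br.ModelParams.initialize(
            sizes, np.random.default_rng(0), scale=0.0
        )
        h = br.initial_state(sizes)
        h_new, y_pred = br.forward_step(
            params, np.ones(sizes.motor), np.ones(sizes.visual), h
        )
        assert np.allclose(h_new, 0.5) and np.allclose(y_pred, 0.5)
        u_post = br.inverse_step(params, np.ones(sizes.visual), h)
        assert np.allclose(u_post, 0.5)

    def test_matches_matrix_free_oracle(self, toy_params):
        rng = np.random.default_rng(1)
        u = rng.random(TOY_SIZES.motor)
        y = rng.random(TOY_SIZES.visual)
        h = rng.random(TOY_SIZES.hidden)
        h_new, y_pred = br.forward_step(toy_params, u, y, h)
        h_ref, y_ref = loop_forward_step(toy_params, u, y, h)
        assert np.max(np.abs(h_new - h_ref)) < 1e-12
        assert np.max(np.abs(y_pred - y_ref)) < 1e-12
        # absent vision contributes a zero vector
        h_new0, _ = br.forward_step(toy_params, u, None, h)
        h_ref0, _ = loop_forward_step(toy_params, u, None, h)
        assert np.max(np.abs(h_new0 - h_ref0)) < 1e-12
        u_post = br.inverse_step(toy_params, y, h)
        assert np.max(np.abs(u_post - loop_inverse_step(toy_params, y, h))) < 1e-12

    def test_shape_mismatch_raises(self, toy_params):
        with pytest.raises(br.ModelShapeError):
            br.forward_step(
                toy_params,
                np.ones(TOY_SIZES.motor + 1),
                None,
                np.full(TOY_SIZES.hidden, 0.5),
            )


class TestUpdates:
    def _inputs(self, seed=2):
        rng = np.random.default_rng(seed)
        return (
            rng.random(TOY_SIZES.motor),
            rng.random(TOY_SIZES.visual),
            rng.random(TOY_SIZES.hidden),
        )

    def test_teacher_equal_to_output_changes_nothing(self, toy_params):
        u, y, h = self._inputs()
        h_new, y_pred = br.forward_step(toy_params, u, y, h)
        before = _snapshot(toy_params)
        br.update_forward(toy_params, u, y, h, y_pred, eta=0.05)
        for name, w in before.items():
            assert np.array_equal(w, getattr(toy_params, name))
        u_post = br.inverse_step(toy_params, y, h)
        br.update_inverse(toy_params, y, h, u_post, eta=0.05)
        for name, w in before.items():
            assert np.array_equal(w, getattr(toy_params, name))

    def test_update_decreases_loss(self, toy_params):
        u, y, h = self._inputs()
        rng = np.random.default_rng(5)
        teacher_y = rng.random(TOY_SIZES.visual)
        _, y_pred0 = br.forward_step(toy_params, u, y, h)
        loss0 = 0.5 * np.sum((y_pred0 - teacher_y) ** 2)
        br.update_forward(toy_params, u, y, h, teacher_y, eta=1e-3)
        _, y_pred1 = br.forward_step(toy_params, u, y, h)
        assert 0.5 * np.sum((y_pred1 - teacher_y) ** 2) < loss0

        teacher_u = rng.random(TOY_SIZES.motor)
        u0 = br.inverse_step(toy_params, y, h)
        loss0 = 0.5 * np.sum((u0 - teacher_u) ** 2)
        br.update_inverse(toy_params, y, h, teacher_u, eta=1e-3)
        u1 = br.inverse_step(toy_params, y, h)
        assert 0.5 * np.sum((u1 - teacher_u) ** 2) < loss0

    def test_weight_isolation(self, toy_params):
        u, y, h = self._inputs()
        rng = np.random.default_rng(6)
        before = _snapshot(toy_params)
        br.update_inverse(toy_params, y, h, rng.random(TOY_SIZES.motor), eta=0.1)
        for name in br.ModelParams.FORWARD_FIELDS:
            assert np.array_equal(before[name], getattr(toy_params, name))
        for name in br.ModelParams.INVERSE_FIELDS:
            assert not np.array_equal(before[name], getattr(toy_params, name))

        before = _snapshot(toy_params)
        br.update_forward(toy_params, u, y, h, rng.random(TOY_SIZES.visual), eta=0.1)
        for name in br.ModelParams.INVERSE_FIELDS:
            assert np.array_equal(before[name], getattr(toy_params, name))
        for name in br.ModelParams.FORWARD_FIELDS:
            assert not np.array_equal(before[name], getattr(toy_params, name))

    def test_updates_are_in_place(self, toy_params):
        # the online loop relies on BLAS writing into the same buffers
        u, y, h = self._inputs()
        buf = toy_params.W_hy
        br.update_forward(
            toy_params, u, y, h, np.zeros(TOY_SIZES.visual), eta=0.1
        )
        assert toy_params.W_hy is buf

    def test_nonpositive_eta_rejected(self, toy_params):
        u, y, h = self._inputs()
        with pytest.raises(ValueError):
            br.update_forward(toy_params, u, y, h, np.zeros(TOY_SIZES.visual), eta=0.0)

    def test_float32_update_matches_float64_to_single_precision(self):
        rng = np.random.default_rng(9)
        p64 = br.ModelParams.initialize(TOY_SIZES, rng, scale=0.5, dtype=np.float64)
        p32 = br.ModelParams(
            **{
                n: getattr(p64, n).astype(np.float32)
                for n in br.ModelParams.FORWARD_FIELDS + br.ModelParams.INVERSE_FIELDS
            }
        )
        u, y, h = (
            rng.random(TOY_SIZES.motor),
            rng.random(TOY_SIZES.visual),
            rng.random(TOY_SIZES.hidden),
        )
        t = rng.random(TOY_SIZES.visual)
        br.update_forward(p64, u, y, h, t, eta=0.05)
        br.update_forward(p32, u, y, h, t, eta=0.05)
        assert np.allclose(p32.W_hh, p64.W_hh, atol=1e-5)
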