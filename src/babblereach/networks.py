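"""Forward and inverse transformation networks.

Two three-layered networks of logistic units, with no bias nodes, momentum
or Fahlman offset:

* the *forward* network is a simple recurrent network (Elman-style): its
  hidden layer receives the population-coded motor command u~(t), the
  population-coded visual hand position y~(t) (a zero vector when vision is
  unavailable), and its own previous activation h_f(t-1) as a frozen context;
  the output layer predicts the next visual population y*(t+1);

* the *inverse* network receives the population-coded visual position
  y~(t+1) together with the forward hidden state h_f(t) — the internal
  representation of where the hand was — and outputs the "postdiction"
  u*(t) of the motor command that produced the movement.

Learning is one online gradient step of the summed squared error between the
output population and its teacher population, through logistic derivatives.
The recurrent context is treated as a constant input (no unrolling through
time), and inverse-error gradients stop at the forward-hidden boundary: the
two networks' weights are strictly isolated.

Weights are kept Fortran-ordered so the rank-1 online updates run in place
through BLAS ``ger``; float32 and float64 are both supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import blas
from scipy.special import expit

from .coding import PopulationCode

__all__ = [
    "LayerSizes",
    "ModelParams",
    "ModelShapeError",
    "logistic",
    "initial_state",
    "forward_step",
    "inverse_step",
    "update_forward",
    "update_inverse",
]


class ModelShapeError(ValueError):
    """Raised when an input population does not match the model's layers."""


def logistic(x: np.ndarray) -> np.ndarray:
    """Componentwise 1 / (1 + exp(-x)) (numerically stable)."""
    return expit(x)


@dataclass(frozen=True)
class LayerSizes:
    """Unit counts: motor and visual populations, hidden layer per network."""

    motor: int = 100
    visual: int = 200
    hidden: int = 400


@dataclass(eq=False)
class ModelParams:
    """All connection weights of the forward and inverse networks.

    Forward network: ``W_mu`` (hidden x motor), ``W_vy`` (hidden x visual),
    ``W_hh`` (hidden x hidden, recurrent), ``W_hy`` (visual x hidden).
    Inverse network: ``V_y`` (hidden x visual), ``V_h`` (hidden x hidden,
    from the forward hidden layer), ``V_u`` (motor x hidden).
    There are no bias parameters.
    """

    W_mu: np.ndarray
    W_vy: np.ndarray
    W_hh: np.ndarray
    W_hy: np.ndarray
    V_y: np.ndarray
    V_h: np.ndarray
    V_u: np.ndarray

    FORWARD_FIELDS = ("W_mu", "W_vy", "W_hh", "W_hy")
    INVERSE_FIELDS = ("V_y", "V_h", "V_u")

    def __post_init__(self) -> None:
        # F-contiguity is required for the in-place BLAS rank-1 updates.
        for name in self.FORWARD_FIELDS + self.INVERSE_FIELDS:
            w = getattr(self, name)
            if not w.flags.f_contiguous:
                setattr(self, name, np.asfortranarray(w))

    @property
    def sizes(self) -> LayerSizes:
        return LayerSizes(
            motor=self.W_mu.shape[1],
            visual=self.W_vy.shape[1],
            hidden=self.W_hh.shape[0],
        )

    @property
    def dtype(self) -> np.dtype:
        return self.W_mu.dtype

    @classmethod
    def initialize(
        cls,
        sizes: LayerSizes,
        rng: np.random.Generator,
        scale: float = 0.1,
        dtype: np.dtype | str = np.float64,
    ) -> "ModelParams":
        """Independent Uniform(-scale, scale) weights, no biases."""
        dt = np.dtype(dtype)
        M, V, H = sizes.motor, sizes.visual, sizes.hidden

        def w(rows: int, cols: int) -> np.ndarray:
            return np.asfortranarray(
                rng.uniform(-scale, scale, size=(rows, cols)).astype(dt)
            )

        return cls(
            W_mu=w(H, M), W_vy=w(H, V), W_hh=w(H, H), W_hy=w(V, H),
            V_y=w(H, V), V_h=w(H, H), V_u=w(M, H),
        )

    def copy(self) -> "ModelParams":
        return ModelParams(
            **{
                name: getattr(self, name).copy(order="F")
                for name in self.FORWARD_FIELDS + self.INVERSE_FIELDS
            }
        )


def initial_state(sizes: LayerSizes, dtype: np.dtype | str = np.float64) -> np.ndarray:
    """Resting forward hidden state: all 0.5 (logistic of zero input)."""
    return np.full(sizes.hidden, 0.5, dtype=np.dtype(dtype))


def _blas_for(dtype: np.dtype):
    if dtype == np.float32:
        return blas.sger, blas.sgemv
    return blas.dger, blas.dgemv


def _acts(x, params: ModelParams, n: int, what: str) -> np.ndarray:
    """Accept a PopulationCode or raw activation array; check its length."""
    a = x.activations if isinstance(x, PopulationCode) else np.asarray(x)
    if a.shape != (n,):
        raise ModelShapeError(f"{what} population has shape {a.shape}, expected ({n},)")
    return np.asarray(a, dtype=params.dtype)


def forward_step(params: ModelParams, u_code, y_code, state: np.ndarray):
    """One propagation of the forward network.

    Returns ``(h_new, y_pred)``: the new hidden state
    ``logistic(W_mu u + W_vy y + W_hh h)`` and the predicted visual
    population ``logistic(W_hy h_new)``.  ``y_code=None`` means vision is
    absent and contributes a zero vector.
    """
    sz = params.sizes
    u = _acts(u_code, params, sz.motor, "motor")
    h = _acts(state, params, sz.hidden, "hidden state")
    pre = params.W_mu @ u
    pre += params.W_hh @ h
    if y_code is not None:
        pre += params.W_vy @ _acts(y_code, params, sz.visual, "visual")
    h_new = logistic(pre)
    y_pred = logistic(params.W_hy @ h_new)
    return h_new, y_pred


def inverse_step(params: ModelParams, y_next_code, state: np.ndarray) -> np.ndarray:
    """One propagation of the inverse network.

    ``logistic(V_u logistic(V_y y_next + V_h h_f))`` — the postdicted motor
    population for the movement ending at ``y_next`` given that the forward
    hidden state ``h_f`` represents where the hand was.
    """
    sz = params.sizes
    y = _acts(y_next_code, params, sz.visual, "visual")
    h = _acts(state, params, sz.hidden, "hidden state")
    h_inv = logistic(params.V_y @ y + params.V_h @ h)
    return logistic(params.V_u @ h_inv)


def update_forward(
    params: ModelParams,
    u_code,
    y_code,
    state: np.ndarray,
    teacher,
    eta: float,
    cache: tuple[np.ndarray, np.ndarray] | None = None,
) -> ModelParams:
    """One online backprop step of the forward network.

    Minimizes ``0.5 * sum((y_pred - teacher)^2)`` where ``teacher`` is the
    population-coded actual post-movement hand position.  Updates W_hy,
    W_mu, W_vy, W_hh in place (the recurrent context ``state`` is a constant
    input; no unrolling) and returns ``params``.  ``cache`` may carry the
    ``(h_new, y_pred)`` pair already computed by :func:`forward_step` for
    these exact inputs.
    """
    if not eta > 0:
        raise ValueError(f"learning rate must be positive, got {eta}")
    sz = params.sizes
    u = _acts(u_code, params, sz.motor, "motor")
    h = _acts(state, params, sz.hidden, "hidden state")
    y = None if y_code is None else _acts(y_code, params, sz.visual, "visual")
    t = _acts(teacher, params, sz.visual, "teacher")
    if cache is None:
        h_new, y_pred = forward_step(params, u, y, h)
    else:
        h_new, y_pred = cache

    ger, gemv = _blas_for(params.dtype)
    neta = params.dtype.type(-eta)
    one = params.dtype.type(1.0)
    # output delta, then hidden delta through the pre-update W_hy
    d_out = (y_pred - t) * y_pred * (one - y_pred)
    d_hid = gemv(one, params.W_hy, d_out, trans=1) * h_new * (one - h_new)
    ger(neta, d_out, h_new, a=params.W_hy, overwrite_a=1)
    ger(neta, d_hid, u, a=params.W_mu, overwrite_a=1)
    if y is not None:
        ger(neta, d_hid, y, a=params.W_vy, overwrite_a=1)
    ger(neta, d_hid, h, a=params.W_hh, overwrite_a=1)
    return params


def update_inverse(
    params: ModelParams,
    y_next_code,
    state: np.ndarray,
    teacher,
    eta: float,
) -> ModelParams:
    """One online backprop step of the inverse network.

    ``teacher`` is the population-coded babbled command u~(t).  Updates V_u,
    V_y, V_h in place and returns ``params``; gradients stop at the forward
    hidden boundary, so the forward network's weights are never touched.
    """
    if not eta > 0:
        raise ValueError(f"learning rate must be positive, got {eta}")
    sz = params.sizes
    y = _acts(y_next_code, params, sz.visual, "visual")
    h = _acts(state, params, sz.hidden, "hidden state")
    t = _acts(teacher, params, sz.motor, "teacher")

    ger, gemv = _blas_for(params.dtype)
    neta = params.dtype.type(-eta)
    one = params.dtype.type(1.0)
    h_inv = logistic(params.V_y @ y + params.V_h @ h)
    u_post = logistic(params.V_u @ h_inv)
    d_out = (u_post - t) * u_post * (one - u_post)
    d_hid = gemv(one, params.V_u, d_out, trans=1) * h_inv * (one - h_inv)
    ger(neta, d_out, h_inv, a=params.V_u, overwrite_a=1)
    ger(neta, d_hid, y, a=params.V_y, overwrite_a=1)
    ger(neta, d_hid, h, a=params.V_h, overwrite_a=1)
    return params
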