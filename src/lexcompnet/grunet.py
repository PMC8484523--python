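"""Gated recurrent unit mapping unfolding phonological input to static targets.

The cell follows the standard GRU equations.  With input x_t and previous
output h_{t-1}:

    u_t = sigma(W_u x_t + H_u h_{t-1})          (update gate)
    r_t = sigma(W_r x_t + H_r h_{t-1})          (reset gate)
    h'_t = tanh(W x_t + r_t * (U h_{t-1}))      (candidate)
    h_t = u_t * h_{t-1} + (1 - u_t) * h'_t

There is no separate readout layer: the hidden state *is* the model
output, so the hidden dimension equals the length of the aggregated
static target (450 at full scale).  Training is full-batch gradient
descent with Nesterov momentum on the mean pointwise loss between the
hidden state and the constant target, accumulated over every timestep of
every trial (including the zero-padded tail).  Gradients are computed by
backpropagation through time in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

WEIGHT_NAMES = ("W_u", "H_u", "W_r", "H_r", "W", "U")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GRUParams:
    """The six weight matrices of the GRU cell."""

    W_u: np.ndarray  # (hidden, input)
    H_u: np.ndarray  # (hidden, hidden)
    W_r: np.ndarray
    H_r: np.ndarray
    W: np.ndarray
    U: np.ndarray

    @property
    def input_dim(self) -> int:
        return self.W.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.W.shape[0]

    def __post_init__(self) -> None:
        h, i = self.W.shape
        for name in ("W_u", "W_r", "W"):
            if getattr(self, name).shape != (h, i):
                raise ValueError(f"{name} must have shape ({h}, {i})")
        for name in ("H_u", "H_r", "U"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} must have shape ({h}, {h})")

    def copy(self) -> "GRUParams":
        return GRUParams(**{n: getattr(self, n).copy() for n in WEIGHT_NAMES})


@dataclass
class GRUState:
    """Hidden state plus gate/candidate diagnostics for a single step."""

    h: np.ndarray
    u: np.ndarray
    r: np.ndarray
    h_cand: np.ndarray


def init_params(input_dim: int, hidden_dim: int, seed: int) -> GRUParams:
    """Draw all six weight matrices uniformly in ±1/sqrt(hidden_dim)."""
    if input_dim < 1 or hidden_dim < 1:
        raise ValueError("dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    bound = 1.0 / np.sqrt(hidden_dim)
    shapes = {
        "W_u": (hidden_dim, input_dim),
        "H_u": (hidden_dim, hidden_dim),
        "W_r": (hidden_dim, input_dim),
        "H_r": (hidden_dim, hidden_dim),
        "W": (hidden_dim, input_dim),
        "U": (hidden_dim, hidden_dim),
    }
    return GRUParams(**{k: rng.uniform(-bound, bound, s) for k, s in shapes.items()})


def gru_step(p: GRUParams, x_t: np.ndarray, h_prev: np.ndarray) -> GRUState:
    """One application of the GRU cell (single vector or batch of rows)."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    if x_t.shape[-1] != p.input_dim or h_prev.shape[-1] != p.hidden_dim:
        raise ValueError(
            f"expected input dim {p.input_dim} and hidden dim {p.hidden_dim}, "
            f"got {x_t.shape[-1]} and {h_prev.shape[-1]}"
        )
    u = _sigmoid(x_t @ p.W_u.T + h_prev @ p.H_u.T)
    r = _sigmoid(x_t @ p.W_r.T + h_prev @ p.H_r.T)
    h_cand = np.tanh(x_t @ p.W.T + r * (h_prev @ p.U.T))
    h = u * h_prev + (1.0 - u) * h_cand
    return GRUState(h=h, u=u, r=r, h_cand=h_cand)


def forward(p: GRUParams, inputs: np.ndarray, h0: np.ndarray | None = None) -> np.ndarray:
    """Iterate the cell over the rows of one unfolding matrix.

    Returns a (timesteps, hidden_dim) array of hidden states; ``h0``
    defaults to all zeros (silence) and no state carries between trials.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 2 or inputs.shape[1] != p.input_dim:
        raise ValueError(f"inputs must be (T, {p.input_dim})")
    h = np.zeros(p.hidden_dim) if h0 is None else np.asarray(h0, dtype=float)
    states = np.empty((inputs.shape[0], p.hidden_dim))
    for t, x_t in enumerate(inputs):
        h = gru_step(p, x_t, h).h
        states[t] = h
    return states


def trial_loss(outputs: np.ndarray, target: np.ndarray, loss_kind: str = "mse") -> float:
    """Mean pointwise loss between every timestep's output and the constant target."""
    outputs = np.asarray(outputs, dtype=float)
    target = np.asarray(target, dtype=float)
    if outputs.size == 0:
        raise ValueError("empty output sequence")
    if outputs.shape[-1] != target.shape[-1]:
        raise ValueError("output/target length mismatch")
    if loss_kind == "mse":
        return float(np.mean((outputs - target) ** 2))
    if loss_kind == "bce":
        p = _sigmoid(outputs)
        eps = 1e-12
        return float(-np.mean(target * np.log(p + eps) + (1 - target) * np.log(1 - p + eps)))
    raise ValueError(f"unknown loss kind {loss_kind!r}")


# ---------------------------------------------------------------------------
# batched forward / backward for training


def batch_forward(p: GRUParams, X: np.ndarray):
    """Run all sequences at once. X: (n, T, input_dim) -> states (n, T, hidden).

    The three input projections are computed for all timesteps in single
    matmuls; only the recurrent projections run inside the time loop.
    """
    n, T, _ = X.shape
    H = p.hidden_dim
    dt = np.result_type(X.dtype, p.W.dtype)
    proj_u = X @ p.W_u.T
    proj_r = X @ p.W_r.T
    proj_c = X @ p.W.T
    hs = np.empty((n, T, H), dtype=dt)
    us = np.empty_like(hs)
    rs = np.empty_like(hs)
    Uhs = np.empty_like(hs)
    cs = np.empty_like(hs)
    h = np.zeros((n, H), dtype=dt)
    for t in range(T):
        u = _sigmoid(proj_u[:, t] + h @ p.H_u.T)
        r = _sigmoid(proj_r[:, t] + h @ p.H_r.T)
        Uh = h @ p.U.T
        c = np.tanh(proj_c[:, t] + r * Uh)
        h = u * h + (1.0 - u) * c
        us[:, t], rs[:, t], Uhs[:, t], cs[:, t], hs[:, t] = u, r, Uh, c, h
    return hs, (hs, us, rs, Uhs, cs)


def batch_backward(p: GRUParams, X: np.ndarray, cache, dLdh: np.ndarray) -> dict:
    """BPTT gradients of a loss whose per-timestep derivative w.r.t. h_t is dLdh."""
    hs, us, rs, Uhs, cs = cache
    n, T, H = hs.shape
    # h_{t-1} for every t, with h_0-previous = zeros
    h_prev = np.concatenate([np.zeros((n, 1, H), dtype=hs.dtype), hs[:, :-1]], axis=1)
    dAu = np.empty_like(hs)
    dAr = np.empty_like(hs)
    dAc = np.empty_like(hs)
    dh_next = np.zeros((n, H), dtype=hs.dtype)
    for t in range(T - 1, -1, -1):
        u, r, Uh, c, hp = us[:, t], rs[:, t], Uhs[:, t], cs[:, t], h_prev[:, t]
        dh = dh_next + dLdh[:, t, :]
        da_c = dh * (1.0 - u) * (1.0 - c * c)
        da_u = dh * (hp - c) * u * (1.0 - u)
        da_r = da_c * Uh * r * (1.0 - r)
        dAc[:, t], dAu[:, t], dAr[:, t] = da_c, da_u, da_r
        dh_next = dh * u + (da_c * r) @ p.U + da_u @ p.H_u + da_r @ p.H_r
    Xf = X.reshape(n * T, -1)
    hf = h_prev.reshape(n * T, H)
    dAcf, dAuf, dArf = (a.reshape(n * T, H) for a in (dAc, dAu, dAr))
    return {
        "W": dAcf.T @ Xf,
        "U": (dAc * rs).reshape(n * T, H).T @ hf,
        "W_u": dAuf.T @ Xf,
        "H_u": dAuf.T @ hf,
        "W_r": dArf.T @ Xf,
        "H_r": dArf.T @ hf,
    }


def batch_loss_and_dLdh(
    hs: np.ndarray, Y: np.ndarray, loss_kind: str = "mse"
) -> tuple[float, np.ndarray]:
    """Loss (mean over items, timesteps and dimensions) and its gradient w.r.t. hs."""
    n, T, D = hs.shape
    target = Y[:, None, :]
    N = n * T * D
    if loss_kind == "mse":
        diff = hs - target
        return float(np.mean(diff**2)), 2.0 * diff / N
    if loss_kind == "bce":
        prob = _sigmoid(hs)
        eps = 1e-12
        loss = -np.mean(target * np.log(prob + eps) + (1 - target) * np.log(1 - prob + eps))
        return float(loss), (prob - target) / N
    raise ValueError(f"unknown loss kind {loss_kind!r}")


class GRUWordRecognizer(BaseEstimator):
    """Sequence-to-static-target GRU trained with full-batch Nesterov momentum.

    Parameters
    ----------
    hidden_dim : size of the hidden state; equals the target length
        because the hidden state is the model output (450 at full scale).
    learning_rate, momentum, nesterov : optimiser hyperparameters
        (defaults 0.4 / 0.4 / True).
    epochs : epoch budget; one epoch is one full-batch update over all
        training trials.
    eval_every : cadence (in epochs) of the evaluation callback and of
        entries in the training log.
    batch_size : None for full batch (default); otherwise deterministic
        contiguous mini-batches.
    loss : "mse" (default) or "bce" (cross-entropy over a sigmoid readout).
    convergence_patience : stop early once the evaluation callback has
        reported ``converged=True`` this many consecutive times (0
        disables early stopping).
    random_state : seed for weight initialisation.

    Attributes
    ----------
    params_ : GRUParams, the trained weights.
    loss_curve_ : list of (epoch, loss) pairs at the evaluation cadence.
    log_ : list of dicts emitted by the evaluation callback.
    n_epochs_ : number of epochs actually run.
    """

    def __init__(
        self,
        hidden_dim: int = 450,
        learning_rate: float = 0.4,
        momentum: float = 0.4,
        nesterov: bool = True,
        epochs: int = 5000,
        eval_every: int = 100,
        batch_size: int | None = None,
        loss: str = "mse",
        convergence_patience: int = 2,
        random_state: int = 0,
        dtype: str = "float32",
    ):
        self.hidden_dim = hidden_dim
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.nesterov = nesterov
        self.epochs = epochs
        self.eval_every = eval_every
        self.batch_size = batch_size
        self.loss = loss
        self.convergence_patience = convergence_patience
        self.random_state = random_state
        self.dtype = dtype

    def _validate_fit_inputs(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_items, timesteps, input_dim); pad all "
                             "unfolding matrices to a common trial length")
        if Y.ndim != 2 or Y.shape[0] != X.shape[0]:
            raise ValueError("Y must be (n_items, hidden_dim)")
        if Y.shape[1] != self.hidden_dim:
            raise ValueError(
                f"target length {Y.shape[1]} != hidden_dim {self.hidden_dim}"
            )
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        return X, Y

    def fit(self, X, Y, eval_fn: Callable[[GRUParams, int], dict] | None = None):
        """Train on padded unfolding matrices X (n, T, input) and targets Y (n, hidden)."""
        X, Y = self._validate_fit_inputs(X, Y)
        # single-precision training roughly halves wall time; gradients are
        # verified in double precision against finite differences
        dt = np.dtype(self.dtype)
        X = X.astype(dt)
        Y = Y.astype(dt)
        p = init_params(X.shape[2], self.hidden_dim, self.random_state)
        for name in WEIGHT_NAMES:
            setattr(p, name, getattr(p, name).astype(dt))
        velocity = {n: np.zeros_like(getattr(p, n)) for n in WEIGHT_NAMES}
        self.loss_curve_ = []
        self.log_ = []
        n = X.shape[0]
        bs = self.batch_size or n
        lr, mu = self.learning_rate, self.momentum
        streak = 0
        epoch = 0
        for epoch in range(1, self.epochs + 1):
            epoch_loss = 0.0
            for start in range(0, n, bs):
                xb, yb = X[start : start + bs], Y[start : start + bs]
                hs, cache = batch_forward(p, xb)
                loss, dLdh = batch_loss_and_dLdh(hs, yb, self.loss)
                grads = batch_backward(p, xb, cache, dLdh)
                epoch_loss += loss * xb.shape[0] / n
                for name in WEIGHT_NAMES:
                    g = grads[name]
                    v = velocity[name]
                    v *= mu
                    v += g
                    step = g + mu * v if self.nesterov else v
                    getattr(p, name)[...] -= lr * step
            if epoch % self.eval_every == 0 or epoch == self.epochs:
                self.loss_curve_.append((epoch, epoch_loss))
                if eval_fn is not None:
                    entry = eval_fn(p, epoch)
                    entry = {"epoch": epoch, "loss": epoch_loss, **entry}
                    self.log_.append(entry)
                    if entry.get("converged"):
                        streak += 1
                        if self.convergence_patience and streak >= self.convergence_patience:
                            break
                    else:
                        streak = 0
        self.params_ = p
        self.n_epochs_ = epoch
        self.input_dim_ = X.shape[2]
        return self

    def forward_states(self, X) -> np.ndarray:
        """Hidden states for every timestep of every sequence: (n, T, hidden)."""
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        hs, _ = batch_forward(self.params_, X)
        return hs

    def predict(self, X) -> np.ndarray:
        """Hidden state at the final timestep of each sequence."""
        return self.forward_states(X)[:, -1, :]
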