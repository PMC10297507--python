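"""Gated recurrent unit classifiers built from scratch.

Two cell variants share one skeleton

    z_t = g(W_zx x_t + W_zh h_{t-1})                      (update gate)
    r_t = g(W_rx x_t + W_rh h_{t-1})                      (reset gate)
    h~_t = f(W_cx x_t + W_cr r_t + W_ch h_{t-1})          (candidate)
    h_t = (1 - z_t) * h_{t-1} + z_t * h~_t

The *standard* cell uses g = sigmoid, f = tanh.  The *modified* cell
replaces the gate activations with swish, f(x) = x·sigmoid(βx), and the
candidate activation with ReLU.  Note the candidate enters the reset
gate additively (a term W_cr r_t), not through the conventional
elementwise product r_t ⊙ (U h_{t-1}); a ``candidate_form="cho"``
switch restores the conventional coupling for comparison.

Swish is unbounded, so the modified cell's update gate can leave
[0, 1] and (1 − z) can go negative; the cell is implemented literally,
with an opt-in ``gate_clamp`` and global gradient-norm clipping (5.0)
as stability guards.  A useful consequence of swish(0) = 0: the
all-zero-weight modified cell is exactly the identity on its hidden
state.

The network is two stacked recurrent layers over the encoded
13-step record sequence, a 5-unit ReLU dense layer with dropout, and a
single sigmoid output unit.  Training is mini-batch Adam with a
per-epoch multiplicative learning-rate decay; gradients are exact
analytic backpropagation through time, verified against the
central-difference oracle in :func:`numerical_gradients`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .exceptions import (
    ConfigError,
    DimensionError,
    NumericError,
    TrainingError,
    ValidationError,
)

__all__ = [
    "ActivationConfig",
    "AdamState",
    "CellWeights",
    "GRUModel",
    "NetworkConfig",
    "TrainState",
    "adam_step",
    "backward",
    "forward",
    "loss_bce",
    "modified_cell_step",
    "numerical_gradients",
    "predict",
    "relu",
    "sigmoid",
    "standard_cell_step",
    "swish",
    "train",
]

EPS_PROB = 1e-12


# --------------------------------------------------------------------------
# activations
# --------------------------------------------------------------------------
def sigmoid(x):
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.empty_like(arr)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-arr[pos]))
    ex = np.exp(arr[~pos])
    out[~pos] = ex / (1.0 + ex)
    return float(out[0]) if scalar else out


def swish(x, beta: float = 1.0):
    """f(x) = x·sigmoid(βx); smooth, → x for large x, swish(0) = 0."""
    if beta <= 0:
        raise ConfigError("swish beta must be > 0")
    x = np.asarray(x, dtype=float)
    out = x * sigmoid(beta * x)
    return out if out.ndim else float(out)


def swish_grad(x, beta: float = 1.0):
    """d/dx swish = σ(βx) + βx·σ(βx)(1 − σ(βx))."""
    x = np.asarray(x, dtype=float)
    s = sigmoid(beta * x)
    return s + beta * x * s * (1.0 - s)


def relu(x):
    out = np.maximum(np.asarray(x, dtype=float), 0.0)
    return out if out.ndim else float(out)


def scalar_activations(kind: Literal["sigmoid", "tanh", "relu"], x):
    if kind == "sigmoid":
        return sigmoid(x)
    if kind == "tanh":
        out = np.tanh(np.asarray(x, dtype=float))
        return out if out.ndim else float(out)
    if kind == "relu":
        return relu(x)
    raise ConfigError(f"unknown activation kind {kind!r}")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ActivationConfig:
    swish_beta: float = 1.0
    gate_clamp: bool = False  # clamp swish gates to [0, 1]

    def __post_init__(self) -> None:
        if self.swish_beta <= 0:
            raise ConfigError("swish beta must be > 0")


@dataclass(frozen=True)
class NetworkConfig:
    """Layer plan and training hyperparameters.

    The architecture is fixed at four weighted layers — two recurrent
    hidden layers, a 5-unit dense layer, one output unit.  The training
    defaults (dropout 0.16, learning rate 0.018 with ×0.94 per-epoch
    decay, 765 epochs, batch 128, weights initialised uniformly in
    [0.1, 0.2]) are the published operating point of this model family;
    ``hidden_size`` is not published and defaults to 16.  ``lag`` is
    carried for config fidelity but has no role for fixed 13-step
    record sequences.
    """

    hidden_size: int = 16
    dense_units: int = 5
    dropout_rate: float = 0.16
    learning_rate: float = 0.018
    decay_rate: float = 0.94
    epochs: int = 765
    batch_size: int = 128
    init_low: float = 0.1
    init_high: float = 0.2
    lag: int = 1039  # unused for 13-step sequences
    seed: int = 0
    cell: Literal["standard", "modified"] = "modified"
    candidate_form: Literal["additive", "cho"] = "additive"
    activation: ActivationConfig = field(default_factory=ActivationConfig)
    init_mode: Literal["magnitude", "positive", "symmetric"] = "magnitude"
    grad_clip: float = 5.0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    max_restarts: int = 30

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout rate must lie in [0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigError("epochs must be >= 0 and batch size >= 1")
        if not self.init_low <= self.init_high:
            raise ConfigError("init bounds must be ordered")
        if self.hidden_size < 1 or self.dense_units < 1:
            raise ConfigError("layer sizes must be >= 1")


@dataclass
class CellWeights:
    """Per-gate input/hidden matrices of one recurrent layer.

    The update and reset gates each get an input matrix (hidden×input)
    and a hidden matrix (hidden×hidden); the candidate gets an input
    matrix ``W_cx``, a reset matrix ``W_cr`` (applied to r_t in the
    additive form) and a hidden matrix ``W_ch``.  No biases, matching
    the bare-matrix form of the cell equations.
    """

    W_zx: np.ndarray
    W_zh: np.ndarray
    W_rx: np.ndarray
    W_rh: np.ndarray
    W_cx: np.ndarray
    W_cr: np.ndarray
    W_ch: np.ndarray

    NAMES = ("W_zx", "W_zh", "W_rx", "W_rh", "W_cx", "W_cr", "W_ch")

    def __post_init__(self) -> None:
        h, i = self.W_zx.shape
        expect = {
            "W_zx": (h, i), "W_zh": (h, h), "W_rx": (h, i), "W_rh": (h, h),
            "W_cx": (h, i), "W_cr": (h, h), "W_ch": (h, h),
        }
        for name, shape in expect.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise DimensionError(f"{name}: expected shape {shape}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise NumericError(f"{name} contains non-finite entries")


def _as_batch(x: np.ndarray, width_name: str) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    if x.ndim != 2:
        raise DimensionError(f"{width_name} must be 1-D or 2-D")
    return x, False


def _cell_forward(
    x: np.ndarray,
    h_prev: np.ndarray,
    w: CellWeights,
    cell: str,
    act: ActivationConfig,
    candidate_form: str,
) -> tuple[np.ndarray, dict]:
    if x.shape[1] != w.W_zx.shape[1] or h_prev.shape[1] != w.W_zh.shape[1]:
        raise DimensionError(
            f"cell expects input width {w.W_zx.shape[1]} and hidden width "
            f"{w.W_zh.shape[1]}, got {x.shape[1]} and {h_prev.shape[1]}"
        )
    a_z = x @ w.W_zx.T + h_prev @ w.W_zh.T
    a_r = x @ w.W_rx.T + h_prev @ w.W_rh.T
    if cell == "standard":
        z_raw, r_raw = sigmoid(a_z), sigmoid(a_r)
    else:
        z_raw, r_raw = swish(a_z, act.swish_beta), swish(a_r, act.swish_beta)
    z = np.clip(z_raw, 0.0, 1.0) if (cell == "modified" and act.gate_clamp) else z_raw
    r = np.clip(r_raw, 0.0, 1.0) if (cell == "modified" and act.gate_clamp) else r_raw
    if candidate_form == "additive":
        a_c = x @ w.W_cx.T + r @ w.W_cr.T + h_prev @ w.W_ch.T
    else:  # conventional reset coupling r ⊙ h_{t-1}
        a_c = x @ w.W_cx.T + (r * h_prev) @ w.W_ch.T
    c = np.tanh(a_c) if cell == "standard" else relu(a_c)
    h = (1.0 - z) * h_prev + z * c
    if cell == "modified":
        for name, arr in (("update gate", z), ("reset gate", r), ("candidate", c)):
            if not np.all(np.isfinite(arr)):
                raise NumericError(f"non-finite values in the {name}")
    cache = {
        "x": x, "h_prev": h_prev, "a_z": a_z, "a_r": a_r, "z_raw": z_raw,
        "r_raw": r_raw, "z": z, "r": r, "a_c": a_c, "c": c, "h": h,
    }
    return h, cache


def standard_cell_step(x_t, h_prev, weights: CellWeights, cache: dict | None = None):
    """One step of the standard sigmoid/tanh cell."""
    xb, squeeze = _as_batch(x_t, "x_t")
    hb, _ = _as_batch(h_prev, "h_prev")
    h, c = _cell_forward(xb, hb, weights, "standard", ActivationConfig(), "additive")
    if cache is not None:
        cache.update(c)
    return h[0] if squeeze else h


def modified_cell_step(
    x_t, h_prev, weights: CellWeights, act: ActivationConfig | None = None,
    cache: dict | None = None,
):
    """One step of the swish-gated, ReLU-candidate cell."""
    act = act or ActivationConfig()
    xb, squeeze = _as_batch(x_t, "x_t")
    hb, _ = _as_batch(h_prev, "h_prev")
    h, c = _cell_forward(xb, hb, weights, "modified", act, "additive")
    if cache is not None:
        cache.update(c)
    return h[0] if squeeze else h


def _cell_backward(
    dh: np.ndarray,
    w: CellWeights,
    cache: dict,
    cell: str,
    act: ActivationConfig,
    candidate_form: str,
    grads: dict[str, np.ndarray],
    prefix: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of one cell step; returns (dx, dh_prev), accumulating grads."""
    x, h_prev = cache["x"], cache["h_prev"]
    z, r, c = cache["z"], cache["r"], cache["c"]
    dz = dh * (c - h_prev)
    dc = dh * z
    dh_prev = dh * (1.0 - z)

    if cell == "standard":
        dac = dc * (1.0 - c * c)
    else:
        dac = dc * (cache["a_c"] > 0)
    grads[prefix + "W_cx"] += dac.T @ x
    dx = dac @ w.W_cx
    if candidate_form == "additive":
        grads[prefix + "W_cr"] += dac.T @ r
        dr = dac @ w.W_cr
        grads[prefix + "W_ch"] += dac.T @ h_prev
        dh_prev = dh_prev + dac @ w.W_ch
    else:
        s = r * h_prev
        grads[prefix + "W_ch"] += dac.T @ s
        ds = dac @ w.W_ch
        dr = ds * h_prev
        dh_prev = dh_prev + ds * r

    if cell == "standard":
        dgz = z * (1.0 - z)
        dgr = r * (1.0 - r)
    else:
        dgz = swish_grad(cache["a_z"], act.swish_beta)
        dgr = swish_grad(cache["a_r"], act.swish_beta)
        if act.gate_clamp:
            dgz = dgz * ((cache["z_raw"] > 0) & (cache["z_raw"] < 1))
            dgr = dgr * ((cache["r_raw"] > 0) & (cache["r_raw"] < 1))
    daz = dz * dgz
    dar = dr * dgr
    grads[prefix + "W_zx"] += daz.T @ x
    grads[prefix + "W_zh"] += daz.T @ h_prev
    grads[prefix + "W_rx"] += dar.T @ x
    grads[prefix + "W_rh"] += dar.T @ h_prev
    dx = dx + daz @ w.W_zx + dar @ w.W_rx
    dh_prev = dh_prev + daz @ w.W_zh + dar @ w.W_rh
    return dx, dh_prev


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------
N_RECURRENT_LAYERS = 2


@dataclass
class GRUModel:
    """Parameters + configuration of the full four-layer network."""

    config: NetworkConfig
    input_width: int
    params: dict[str, np.ndarray]

    def layer_weights(self, layer: int) -> CellWeights:
        prefix = f"rnn{layer}."
        return CellWeights(**{n: self.params[prefix + n] for n in CellWeights.NAMES})

    def n_parameters(self) -> int:
        return sum(int(np.prod(v.shape)) for v in self.params.values())

    def copy(self) -> "GRUModel":
        return GRUModel(self.config, self.input_width, {k: v.copy() for k, v in self.params.items()})


def init_model(config: NetworkConfig, input_width: int, rng: np.random.Generator | None = None) -> GRUModel:
    """Weights with magnitudes drawn uniformly in [init_low, init_high].

    ``init_mode`` picks the sign convention for the stated magnitude
    range 0.1–0.2: ``magnitude`` (default) gives each weight a random
    sign, ``positive`` keeps all weights positive (the literal reading —
    but every hidden unit then starts nearly identical, and in practice
    the recurrent stack cannot break that symmetry; see the methods
    note), and ``symmetric`` ignores init_low and draws uniformly from
    ±init_high as a diagnostic baseline.
    """
    rng = rng or np.random.default_rng(config.seed)

    def draw(*shape):
        if config.init_mode == "symmetric":
            return rng.uniform(-config.init_high, config.init_high, size=shape)
        mag = rng.uniform(config.init_low, config.init_high, size=shape)
        if config.init_mode == "positive":
            return mag
        return mag * rng.choice([-1.0, 1.0], size=shape)

    h, d = config.hidden_size, config.dense_units
    params: dict[str, np.ndarray] = {}
    for layer in range(N_RECURRENT_LAYERS):
        i = input_width if layer == 0 else h
        for name in CellWeights.NAMES:
            cols = i if name.endswith("x") else h
            params[f"rnn{layer}.{name}"] = draw(h, cols)
    params["dense.W"] = draw(d, h)
    # biases are not part of the stated weight range; the dense bias
    # starts slightly positive so no ReLU unit is born dead, the output
    # bias at zero (an untrained network then scores sigma(0) = 0.5)
    params["dense.b"] = np.full(d, 0.1)
    params["out.W"] = draw(d)
    params["out.b"] = np.zeros(1)
    return GRUModel(config=config, input_width=input_width, params=params)


def forward(
    model: GRUModel,
    X: np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Probabilities in (0, 1) for a batch of encoded sequences.

    ``X`` has shape (batch, steps, width) — or (steps, width) for one
    record.  Inference mode is deterministic; train mode applies
    inverted dropout to the dense activations using ``rng``.
    """
    X = np.asarray(X, dtype=float)
    squeeze = X.ndim == 2
    if squeeze:
        X = X[None]
    if X.ndim != 3 or X.shape[2] != model.input_width:
        raise DimensionError(
            f"expected input shape (batch, steps, {model.input_width}), got {X.shape}"
        )
    cfg = model.config
    B, T, _ = X.shape
    caches: dict = {"layers": [], "X_shape": X.shape, "train_mode": train_mode}
    seq = X
    for layer in range(N_RECURRENT_LAYERS):
        w = model.layer_weights(layer)
        h = np.zeros((B, cfg.hidden_size))
        layer_caches = []
        outputs = np.empty((B, T, cfg.hidden_size))
        for t in range(T):
            h, cache = _cell_forward(
                seq[:, t, :], h, w, cfg.cell, cfg.activation, cfg.candidate_form
            )
            layer_caches.append(cache)
            outputs[:, t, :] = h
        caches["layers"].append(layer_caches)
        seq = outputs
    hT = seq[:, -1, :]
    d_pre = hT @ model.params["dense.W"].T + model.params["dense.b"]
    d_act = relu(d_pre)
    if train_mode and cfg.dropout_rate > 0.0:
        if rng is None:
            raise ValidationError("train-mode forward with dropout needs an rng")
        mask = (rng.random(d_act.shape) >= cfg.dropout_rate) / (1.0 - cfg.dropout_rate)
    else:
        mask = np.ones_like(d_act)
    d_drop = d_act * mask
    logit = d_drop @ model.params["out.W"] + model.params["out.b"][0]
    p = sigmoid(logit)
    caches.update(hT=hT, d_pre=d_pre, d_act=d_act, mask=mask, d_drop=d_drop, logit=logit, p=p)
    return (p[0] if squeeze else p), caches


def loss_bce(p, y):
    """Mean binary cross-entropy with probability clipping at 1e-12."""
    p = np.clip(np.asarray(p, dtype=float), EPS_PROB, 1.0 - EPS_PROB)
    y = np.asarray(y, dtype=float)
    if not np.all((y == 0) | (y == 1)):
        raise ValidationError("labels must be 0 or 1")
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def backward(model: GRUModel, caches: dict, y: np.ndarray) -> dict[str, np.ndarray]:
    """Exact gradients of the mean BCE loss for every parameter."""
    if "layers" not in caches:
        raise ValidationError("backward needs caches from a forward pass")
    cfg = model.config
    y = np.atleast_1d(np.asarray(y, dtype=float))
    p = np.atleast_1d(caches["p"])
    B, T, _ = caches["X_shape"]
    grads = {k: np.zeros_like(v) for k, v in model.params.items()}

    dlogit = (p - y) / B  # d mean-BCE / d logit through the sigmoid
    grads["out.W"] += caches["d_drop"].T @ dlogit
    grads["out.b"] += np.array([dlogit.sum()])
    dd_drop = np.outer(dlogit, model.params["out.W"])
    dd_act = dd_drop * caches["mask"]
    dd_pre = dd_act * (caches["d_pre"] > 0)
    grads["dense.W"] += dd_pre.T @ caches["hT"]
    grads["dense.b"] += dd_pre.sum(axis=0)
    dhT = dd_pre @ model.params["dense.W"]

    # BPTT: layer 2 receives gradient only at the last step; the dx it
    # emits per step is the gradient into layer 1's per-step output.
    dH = np.zeros((B, T, cfg.hidden_size))
    dH[:, -1, :] = dhT
    for layer in reversed(range(N_RECURRENT_LAYERS)):
        w = model.layer_weights(layer)
        prefix = f"rnn{layer}."
        layer_caches = caches["layers"][layer]
        in_width = model.input_width if layer == 0 else cfg.hidden_size
        dX = np.zeros((B, T, in_width))
        dh_carry = np.zeros((B, cfg.hidden_size))
        for t in reversed(range(T)):
            dh = dH[:, t, :] + dh_carry
            dx, dh_carry = _cell_backward(
                dh, w, layer_caches[t], cfg.cell, cfg.activation, cfg.candidate_form,
                grads, prefix,
            )
            dX[:, t, :] = dx
        dH = dX  # becomes the per-step injection for the layer below
    return grads


def numerical_gradients(
    model: GRUModel, X: np.ndarray, y: np.ndarray, eps: float = 1e-6
) -> dict[str, np.ndarray]:
    """Central-difference gradients, the package's verification oracle.

    Costs two forward passes per parameter — use tiny models only.
    Dropout must be off (the loss must be a deterministic function of
    the parameters).
    """
    if model.config.dropout_rate > 0.0:
        raise ValidationError("numerical gradients require dropout_rate = 0")
    grads = {}
    for key, value in model.params.items():
        g = np.zeros_like(value)
        flat = value.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_bce(forward(model, X)[0], y)
            flat[i] = orig - eps
            lm = loss_bce(forward(model, X)[0], y)
            flat[i] = orig
            gflat[i] = (lp - lm) / (2.0 * eps)
        grads[key] = g
    return grads


def gradient_check_error(model: GRUModel, X: np.ndarray, y: np.ndarray, eps: float = 1e-6) -> float:
    """Worst per-parameter relative disagreement of analytic vs numerical grads.

    Relative error is the norm ratio ||g_a − g_n|| / (||g_a|| + ||g_n||)
    per parameter tensor, which is robust to individual near-zero
    entries; the maximum over tensors is returned.
    """
    _, caches = forward(model, X, train_mode=True, rng=np.random.default_rng(0))
    analytic = backward(model, caches, y)
    numeric = numerical_gradients(model, X, y, eps=eps)
    worst = 0.0
    for key in analytic:
        num = float(np.linalg.norm(analytic[key] - numeric[key]))
        den = max(float(np.linalg.norm(analytic[key]) + np.linalg.norm(numeric[key])), 1e-12)
        worst = max(worst, num / den)
    return worst


# --------------------------------------------------------------------------
# optimisation
# --------------------------------------------------------------------------
@dataclass
class AdamState:
    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    step: int = 0

    @classmethod
    def for_model(cls, model: GRUModel) -> "AdamState":
        return cls(
            m={k: np.zeros_like(p) for k, p in model.params.items()},
            v={k: np.zeros_like(p) for k, p in model.params.items()},
        )


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = float(np.sqrt(sum(float(np.sum(g * g)) for g in grads.values())))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


def adam_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: AdamState,
    lr: float,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> AdamState:
    """One bias-corrected Adam update, in place on ``params``."""
    state.step += 1
    t = state.step
    for key, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise NumericError(f"non-finite gradient for {key}")
        state.m[key] = beta1 * state.m[key] + (1.0 - beta1) * g
        state.v[key] = beta2 * state.v[key] + (1.0 - beta2) * g * g
        mhat = state.m[key] / (1.0 - beta1**t)
        vhat = state.v[key] / (1.0 - beta2**t)
        params[key] -= lr * mhat / (np.sqrt(vhat) + eps)
    return state


@dataclass
class TrainState:
    """Optimiser state plus per-epoch history of a training run."""

    adam: AdamState
    loss_history: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)
    restarts: int = 0
    stalled: bool = False

    @property
    def epochs_run(self) -> int:
        return len(self.loss_history)


#: Batch std of the output probabilities below which the network is
#: considered collapsed (dead gates/ReLUs make the output exactly
#: constant; healthy runs sit orders of magnitude higher).
COLLAPSE_STD = 1e-8
#: First epoch at which the no-learning check may fire, the rolling
#: window it inspects, and the mean-BCE level some epoch in that window
#: must have beaten (ln 2 ≈ 0.693 is the constant-output loss on
#: balanced labels; any retained learning sits well below it).
STUCK_CHECK_EPOCH = 12
STUCK_WINDOW = 10
STUCK_LOSS = 0.67


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: NetworkConfig,
    epochs: int | None = None,
) -> tuple[GRUModel, TrainState]:
    """Fit a model on encoded sequences; reproducible from (data, config).

    Mini-batches are reshuffled each epoch with the run seed; the
    learning rate is ``learning_rate × decay_rate**epoch``; gradients
    are clipped to global norm ``grad_clip``.  ``epochs`` overrides the
    config (the full 765-epoch default schedule is rarely what a test
    wants).

    The swish/ReLU cell has an absorbing failure mode at this learning
    rate: a few aggressive early steps can close every gate and kill
    every ReLU candidate (or the dense ReLU layer), after which the
    output is constant across records and the upstream gradients are
    exactly zero — no amount of further training recovers.  ``train``
    therefore restarts from a fresh draw of the ongoing seeded RNG when
    it sees (a) a non-finite loss, (b) an output collapsed to a
    constant (batch std below ``COLLAPSE_STD``), or (c) no learning at
    all by ``STUCK_CHECK_EPOCH`` (mean BCE still at the
    constant-predictor level).  At most ``config.max_restarts``
    restarts are spent, so the run remains a deterministic function of
    (data, config); if they are exhausted, a non-finite loss raises
    :class:`TrainingError` naming the epoch, while a collapsed/stuck
    run finishes its epochs and is flagged ``TrainState.stalled``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 3 or X.shape[0] == 0:
        raise ValidationError("X must be a nonempty (n, steps, width) array")
    if X.shape[0] != y.shape[0]:
        raise DimensionError("X and y disagree on the number of records")
    n_epochs = config.epochs if epochs is None else epochs
    rng = np.random.default_rng(config.seed)
    model = init_model(config, X.shape[2], rng)
    state = TrainState(adam=AdamState.for_model(model))
    n = X.shape[0]
    epoch = 0
    while epoch < n_epochs:
        lr = config.learning_rate * config.decay_rate**epoch
        order = rng.permutation(n)
        epoch_losses = []
        failure: str | None = None
        out_std = np.inf
        try:
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                p, caches = forward(model, X[idx], train_mode=True, rng=rng)
                loss = loss_bce(p, y[idx])
                if not np.isfinite(loss):
                    failure = "loss is not finite"
                    break
                grads = backward(model, caches, y[idx])
                clip_gradients(grads, config.grad_clip)
                adam_step(
                    model.params, grads, state.adam, lr,
                    config.adam_beta1, config.adam_beta2, config.adam_eps,
                )
                epoch_losses.append(loss)
                out_std = float(np.std(p))
        except NumericError as exc:
            failure = str(exc)
        fatal = failure is not None  # non-finite state cannot keep training
        if not state.stalled:
            if failure is None and epoch > 0 and out_std < COLLAPSE_STD:
                failure = "network output collapsed to a constant"
            if failure is None and epoch + 1 >= STUCK_CHECK_EPOCH and epoch_losses:
                window = (state.loss_history + [float(np.mean(epoch_losses))])[-STUCK_WINDOW:]
                if min(window) > STUCK_LOSS:
                    failure = "no recent learning progress (loss stuck at chance)"
        if failure is not None:
            if state.restarts >= config.max_restarts:
                if fatal:
                    raise TrainingError(
                        f"training diverged at epoch {epoch} "
                        f"after {state.restarts} restarts: {failure}"
                    )
                state.stalled = True  # give up restarting, finish the run
            else:
                state.restarts += 1
                model = init_model(config, X.shape[2], rng)
                state.adam = AdamState.for_model(model)
                state.loss_history.clear()
                state.lr_history.clear()
                epoch = 0
                continue
        state.loss_history.append(float(np.mean(epoch_losses)))
        state.lr_history.append(lr)
        epoch += 1
    return model, state


def predict_proba(model: GRUModel, X: np.ndarray) -> np.ndarray:
    """Deterministic inference probabilities for encoded sequences."""
    p, _ = forward(model, X, train_mode=False)
    return np.atleast_1d(p)


def predict(
    model: GRUModel, X: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and probabilities; label 1 iff probability >= threshold."""
    p = predict_proba(model, X)
    return (p >= threshold).astype(int), p


# --------------------------------------------------------------------------
# checkpoints (text format: JSON header + nested weight lists)
# --------------------------------------------------------------------------
CHECKPOINT_VERSION = 1


def save_model(model: GRUModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "format_version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "input_width": model.input_width,
        "params": {k: v.tolist() for k, v in model.params.items()},
    }
    path.write_text(json.dumps(payload), encoding="utf-8")
    return path


def load_model(path: str | Path) -> GRUModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format_version") != CHECKPOINT_VERSION:
        raise ValidationError("unsupported checkpoint format version")
    cfg_dict = dict(payload["config"])
    cfg_dict["activation"] = ActivationConfig(**cfg_dict["activation"])
    config = NetworkConfig(**cfg_dict)
    params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
    return GRUModel(config=config, input_width=int(payload["input_width"]), params=params)
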