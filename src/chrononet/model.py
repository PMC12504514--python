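"""The recurrent attention network: LSTM encoder, per-step risk head,
temporal attention with an optional patient-context-adaptive query, and the
three multi-task output heads (AKI onset, recovery, dialysis).

Every operation accepts either plain ndarrays (values only) or autodiff
:class:`~chrononet._autodiff.Tensor` inputs (graph recorded), so the same
code path serves inference, training and gradient checking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

N_TASKS = 3  # AKI onset, recovery, dialysis


class UndefinedAttentionError(ValueError):
    """Attention over a fully padded sequence is undefined."""


@dataclass
class ModelConfig:
    d: int                      # input channels per step
    d_h: int = 64               # LSTM hidden size
    d_a: int = 32               # attention space size
    adaptive_attention: bool = False
    d_z: int = 0                # static-context dimension (adaptive query)
    seed: int = 0

    def to_dict(self):
        return {k: getattr(self, k) for k in
                ("d", "d_h", "d_a", "adaptive_attention", "d_z", "seed")}


@dataclass
class EncoderState:
    h: object
    c: object


class ChronoNetParams:
    """All trainable tensors, keyed by name.

    Gate matrices W_* are (d_h, d), recurrent U_* are (d_h, d_h); the
    attention scorer is W_h (d_a, d_h), b_h (d_a,) with query v (d_a, 1) or,
    in adaptive mode, W_z (d_a, d_z), b_z (d_a,) mapping the static context
    to a per-patient query.  The output head W_out (1, d_h) is shared by the
    per-step and the pooled risk; task heads are (3, d_h).  Initialization is
    uniform +-1/sqrt(fan_in) with the forget-gate bias at 1.0.
    """

    GATES = ("i", "f", "c", "o")

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, d_h, d_a = config.d, config.d_h, config.d_a

        def u(shape, fan_in):
            lim = 1.0 / np.sqrt(fan_in)
            return Tensor(rng.uniform(-lim, lim, shape), requires_grad=True)

        self.tensors = {}
        for g in self.GATES:
            self.tensors[f"W_{g}"] = u((d_h, d), d)
            self.tensors[f"U_{g}"] = u((d_h, d_h), d_h)
            bias = np.ones(d_h) if g == "f" else np.zeros(d_h)
            self.tensors[f"b_{g}"] = Tensor(bias, requires_grad=True)
        self.tensors["W_h"] = u((d_a, d_h), d_h)
        self.tensors["b_h"] = Tensor(np.zeros(d_a), requires_grad=True)
        if config.adaptive_attention:
            if config.d_z <= 0:
                raise ValueError("adaptive attention needs d_z > 0")
            self.tensors["W_z"] = u((d_a, config.d_z), config.d_z)
            self.tensors["b_z"] = Tensor(np.zeros(d_a), requires_grad=True)
        else:
            self.tensors["v"] = u((d_a, 1), d_a)
        self.tensors["W_out"] = u((1, d_h), d_h)
        self.tensors["b_out"] = Tensor(np.zeros(1), requires_grad=True)
        self.tensors["W_task"] = u((N_TASKS, d_h), d_h)
        self.tensors["b_task"] = Tensor(np.zeros(N_TASKS), requires_grad=True)
        self.tensors["log_sigma"] = Tensor(np.zeros(N_TASKS),
                                           requires_grad=True)

    def __getattr__(self, name):
        tensors = self.__dict__.get("tensors", {})
        if name in tensors:
            return tensors[name]
        raise AttributeError(name)

    def items(self):
        return self.tensors.items()

    def weight_matrices(self):
        """Tensors subject to L2 (matrices only; biases and log_sigma not)."""
        return [t for k, t in self.tensors.items()
                if k.startswith(("W_", "U_", "v"))]

    def zero_grad(self):
        for t in self.tensors.values():
            t.grad = None

    def snapshot(self) -> dict:
        return {k: t.value.copy() for k, t in self.tensors.items()}

    def load_snapshot(self, snap: dict) -> None:
        for k, v in snap.items():
            self.tensors[k].value = np.array(v, dtype=np.float64)


def save_checkpoint(params: ChronoNetParams, path) -> None:
    """Bit-exact checkpoint: named float64 arrays plus the model config."""
    np.savez(path, __config__=np.frombuffer(
        json.dumps(params.config.to_dict()).encode(), dtype=np.uint8),
        **{k: t.value for k, t in params.tensors.items()})


def load_checkpoint(path) -> ChronoNetParams:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        params = ChronoNetParams(cfg)
        params.load_snapshot({k: data[k] for k in data.files
                              if k != "__config__"})
    return params


# --------------------------------------------------------------------------
# forward operations
# --------------------------------------------------------------------------

def lstm_step(x_t, state: EncoderState, params: ChronoNetParams,
              step_index: int = None) -> EncoderState:
    """One LSTM cell update.

    i = sig(W_i x + U_i h + b_i);  f = sig(W_f x + U_f h + b_f);
    cand = tanh(W_c x + U_c h + b_c);  c' = f*c + i*cand;
    h' = sig(W_o x + U_o h + b_o) * tanh(c').
    """
    if not np.all(np.isfinite(ad.value_of(x_t))):
        where = f" at step {step_index}" if step_index is not None else ""
        raise FloatingPointError(f"non-finite model input{where}")
    h, c = state.h, state.c
    p = params.tensors

    def gate(g):
        return ad.tensor(x_t) @ p[f"W_{g}"].T + ad.tensor(h) @ p[f"U_{g}"].T \
            + p[f"b_{g}"]

    i = ad.sigmoid(gate("i"))
    f = ad.sigmoid(gate("f"))
    cand = ad.tanh(gate("c"))
    o = ad.sigmoid(gate("o"))
    c_new = f * c + i * cand
    h_new = o * ad.tanh(c_new)
    return EncoderState(h_new, c_new)


def encode_sequence(batch, params: ChronoNetParams):
    """Run the LSTM over a padded batch; returns hidden states (B, T, d_h).

    Padded steps carry the last real state forward (they are excluded from
    every head and loss via the pad-mask), so the entry at the final index is
    always the last *real* hidden state.
    """
    inputs, pad_mask = batch.inputs, batch.pad_mask
    B, T, _ = inputs.shape
    d_h = params.config.d_h
    state = EncoderState(np.zeros((B, d_h)), np.zeros((B, d_h)))
    hs = []
    for t in range(T):
        new = lstm_step(inputs[:, t, :], state, params, step_index=t + 1)
        m = pad_mask[:, t:t + 1].astype(float)
        state = EncoderState(m * new.h + (1.0 - m) * state.h,
                             m * new.c + (1.0 - m) * state.c)
        hs.append(state.h)
    return ad.stack(hs, axis=1)


def attention_weights(H, params: ChronoNetParams, pad_mask=None, z=None):
    """Softmax attention over real steps: e_t = v^T tanh(W_h h_t + b_h),
    with v = W_z z + b_z when a patient context ``z`` is supplied."""
    Hv = ad.value_of(H)
    B, T, _ = Hv.shape
    if pad_mask is None:
        pad_mask = np.ones((B, T), dtype=bool)
    if not pad_mask.any(axis=1).all():
        raise UndefinedAttentionError("a sequence has no real steps")
    u = ad.tanh(ad.tensor(H) @ params.W_h.T + params.b_h)  # (B, T, d_a)
    if params.config.adaptive_attention:
        if z is None:
            raise ValueError("adaptive attention requires a context vector z")
        v = ad.tensor(z) @ params.W_z.T + params.b_z       # (B, d_a)
        d_a = params.config.d_a
        e = ad.tsum(u * v.reshape(-1, 1, d_a), axis=2)     # (B, T)
    else:
        e = (u @ params.v).reshape(B, T)
    return ad.softmax_masked(e, pad_mask, axis=1)


def context_vector(H, alpha):
    """Convex combination of hidden states: c = sum_t alpha_t h_t."""
    B, T = ad.value_of(alpha).shape
    return ad.tsum(ad.tensor(alpha).reshape(B, T, 1) * ad.tensor(H), axis=1)


def step_risk(h, params: ChronoNetParams):
    """Per-step risk sig(W_out h + b_out); works on (d_h,), (B,d_h) or
    (B,T,d_h) input, returning the matching shape without the last axis."""
    logits = ad.tensor(h) @ params.W_out.T + params.b_out
    shape = ad.value_of(logits).shape[:-1]
    return ad.sigmoid(logits.reshape(*shape) if shape else logits)


def pooled_risk(c, params: ChronoNetParams):
    """Attention-pooled risk — the same affine head applied to the context."""
    return step_risk(c, params)


def multitask_forward(shared, params: ChronoNetParams):
    """Three independent sigmoid heads on the shared representation."""
    return ad.sigmoid(ad.tensor(shared) @ params.W_task.T + params.b_task)


def forward(batch, params: ChronoNetParams, mode: str = "sequence", z=None,
            multitask: bool = False) -> dict:
    """Full forward pass.

    sequence mode: per-step risks from every hidden state; the shared
    multi-task representation is the last real hidden state.
    pooled mode: attention over hidden states, one pooled risk per patient;
    the shared representation is the attention context.
    """
    if mode not in ("sequence", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    H = encode_sequence(batch, params)
    out = {"H": H}
    out["yhat_steps"] = step_risk(H, params)          # (B, T)
    h_last = H[:, -1, :]                              # last real state
    if mode == "pooled":
        alpha = attention_weights(H, params, batch.pad_mask, z=z)
        c = context_vector(H, alpha)
        out.update(alpha=alpha, context=c,
                   yhat_pooled=pooled_risk(c, params))
        shared = c
    else:
        shared = h_last
    out["h_last"] = h_last
    if multitask:
        out["task_probs"] = multitask_forward(shared, params)
    return out


# --------------------------------------------------------------------------
# gradient checking
# --------------------------------------------------------------------------

def gradient_check(loss_fn, params: ChronoNetParams,
                   eps: float = 1e-5) -> float:
    """Max relative error between analytic and central finite-difference
    gradients over every parameter entry.

    ``loss_fn()`` must rebuild the graph and return the scalar loss tensor.
    The relative error uses the guarded denominator |a| + |f| + 1e-8 so that
    entries whose true gradient magnitude is near the finite-difference
    noise floor do not dominate.
    """
    params.zero_grad()
    loss_fn().backward()
    analytic = {k: (t.grad.copy() if t.grad is not None
                    else np.zeros_like(t.value))
                for k, t in params.tensors.items()}
    numeric = finite_difference_gradients(
        lambda: float(ad.value_of(loss_fn())), params, eps=eps)
    worst = 0.0
    for k, a in analytic.items():
        f = numeric[k]
        rel = np.abs(a - f) / (np.abs(a) + np.abs(f) + 1e-8)
        worst = max(worst, float(rel.max()))
    return worst


def finite_difference_gradients(loss_fn, params: ChronoNetParams,
                                eps: float = 1e-6) -> dict:
    """Central finite differences of a scalar ``loss_fn()`` w.r.t. every
    parameter entry; the independent oracle for the analytic gradients."""
    grads = {}
    for name, t in params.tensors.items():
        g = np.zeros_like(t.value)
        it = np.nditer(t.value, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = t.value[idx]
            t.value[idx] = orig + eps
            lo_hi = loss_fn()
            t.value[idx] = orig - eps
            lo_lo = loss_fn()
            t.value[idx] = orig
            g[idx] = (lo_hi - lo_lo) / (2 * eps)
        grads[name] = g
    return grads
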