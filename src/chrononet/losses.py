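"""Composite training objectives: masked sequence cross-entropy, weighted and
focal variants, temporal smoothness, attention-entropy regularization, L2,
and the fixed- or uncertainty-weighted multi-task combination.

All loss functions are generic: given plain ndarrays they return floats,
given autodiff tensors they return a scalar tensor through which gradients
flow.  Probabilities are clipped to [eps, 1-eps] before any logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad

PROB_CLIP_EPS = 1e-7


@dataclass
class LossConfig:
    l2_lambda: float = 0.0
    smooth_gamma: float = 0.0
    entropy_beta: float = 0.0
    entropy_sign: str = "diversity"     # diversity | concentration
    focal_alpha: float = 1.0
    focal_gamma: float = 2.0
    class_weights: tuple = None          # (w_neg, w_pos) or None
    dynamic_temp: float = 2.0
    task_lambdas: tuple = (1.0, 1.0, 1.0)
    use_uncertainty: bool = False
    prob_clip_eps: float = PROB_CLIP_EPS

    def __post_init__(self):
        for name in ("l2_lambda", "smooth_gamma", "entropy_beta",
                     "focal_alpha", "focal_gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.entropy_sign not in ("diversity", "concentration"):
            raise ValueError("entropy_sign must be diversity|concentration")
        if self.class_weights is not None and \
                any(w <= 0 for w in self.class_weights):
            raise ValueError("class_weights must be strictly positive")


@dataclass
class LossBreakdown:
    """Per-term values of the composite objective; ``total`` is their sum in
    the fixed order data + l2 + smooth + entropy (exact identity)."""

    data_term: float = 0.0
    l2_term: float = 0.0
    smooth_term: float = 0.0
    entropy_term: float = 0.0
    task_terms: dict = field(default_factory=dict)
    total: float = 0.0


def _xlogy(x, y_clipped):
    return x * ad.log(y_clipped)


def bce_sequence(y, yhat, pad_mask=None, eps: float = PROB_CLIP_EPS,
                 instance_weights=None):
    """Binary cross-entropy summed over the real steps of each sequence and
    averaged over the batch.  ``y``/``yhat`` are (T,) or (B, T); padded
    positions (pad_mask false) contribute exactly zero.  Optional per-patient
    ``instance_weights`` multiply each patient's sequence loss."""
    yv = np.asarray(ad.value_of(y), dtype=float)
    if yv.shape != ad.value_of(yhat).shape:
        raise ValueError("y and yhat shapes disagree")
    yc = ad.clip(yhat, eps, 1.0 - eps)
    m = np.ones_like(yv) if pad_mask is None else \
        np.asarray(pad_mask, dtype=float)
    terms = (_xlogy(yv, yc) + _xlogy(1.0 - yv, 1.0 - yc)) * m
    per = -ad.tsum(terms, axis=-1)
    if yv.ndim == 1:
        return per
    if instance_weights is not None:
        per = per * np.asarray(instance_weights, dtype=float)
    return ad.tmean(per, axis=0)


def weighted_bce(y, yhat, weights, eps: float = PROB_CLIP_EPS):
    """Cost-sensitive instance-level BCE: each instance's two-term loss is
    multiplied by its weight w_i; mean over instances."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("instance weights must be strictly positive")
    yv = np.asarray(ad.value_of(y), dtype=float)
    yc = ad.clip(yhat, eps, 1.0 - eps)
    per = -(w * (_xlogy(yv, yc) + _xlogy(1.0 - yv, 1.0 - yc)))
    return ad.tmean(per)


def inverse_class_weights(class_counts):
    """Inverse-frequency class weights w_c = N / (2 N_c); satisfies the
    conservation identity sum_c N_c w_c = N for two classes."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("every class must be non-empty")
    return counts.sum() / (2.0 * counts)


def dynamic_weight_update(p_c: float, temp: float) -> float:
    """Difficulty-driven class weight w = sig(temp * (0.5 - p_c)):
    decreasing in the class accuracy p_c, equal to 0.5 at p_c = 0.5."""
    p = np.asarray(p_c, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("class accuracy must lie in [0, 1]")
    out = 1.0 / (1.0 + np.exp(-temp * (0.5 - p)))
    return float(out) if out.ndim == 0 else out


def combine_class_weights(static_w, dynamic_w):
    """Static (inverse-frequency) and dynamic (difficulty) weights combine
    multiplicatively and are renormalized to mean one."""
    w = np.asarray(static_w, dtype=float) * np.asarray(dynamic_w, dtype=float)
    return w / w.mean()


def focal_loss(y, yhat, alpha: float = 1.0, gamma: float = 2.0,
               symmetric: bool = True, eps: float = PROB_CLIP_EPS):
    """Focal loss, mean over instances.

    The positive-class term is -alpha (1-p)^gamma y log p; with ``symmetric``
    (default) the mirrored negative-class term -alpha p^gamma (1-y) log(1-p)
    is added so that negatives also carry gradient.  gamma = 0 with
    symmetric reduces to plain BCE scaled by alpha.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    yv = np.asarray(ad.value_of(y), dtype=float)
    yc = ad.clip(yhat, eps, 1.0 - eps)
    pos = (1.0 - yc) ** gamma * _xlogy(yv, yc)
    total = pos
    if symmetric:
        total = total + yc**gamma * _xlogy(1.0 - yv, 1.0 - yc)
    return ad.tmean(-alpha * total)


def smoothness_penalty(yhat, pad_mask=None, gamma: float = 1.0):
    """Temporal-consistency penalty gamma * sum_t (yhat_t - yhat_{t-1})^2
    over consecutive real steps; batch input is averaged over patients."""
    v = ad.value_of(yhat)
    if v.shape[-1] < 2:
        return 0.0 * ad.tsum(yhat) if isinstance(yhat, ad.Tensor) else 0.0
    if v.ndim == 1:
        d = ad.tensor(yhat)[1:] - ad.tensor(yhat)[:-1] \
            if isinstance(yhat, ad.Tensor) else yhat[1:] - yhat[:-1]
        m = np.ones(v.shape[-1] - 1) if pad_mask is None else \
            (np.asarray(pad_mask[1:], float) * np.asarray(pad_mask[:-1], float))
        return gamma * ad.tsum(d * d * m)
    yh = ad.tensor(yhat) if isinstance(yhat, ad.Tensor) else yhat
    d = yh[:, 1:] - yh[:, :-1]
    if pad_mask is None:
        m = np.ones((v.shape[0], v.shape[1] - 1))
    else:
        pm = np.asarray(pad_mask, dtype=float)
        m = pm[:, 1:] * pm[:, :-1]
    return ad.tmean(gamma * ad.tsum(d * d * m, axis=1), axis=0)


def attention_entropy(alpha):
    """Shannon entropy of the attention distribution, batch-averaged;
    0 * log 0 := 0 so fully padded positions are neutral."""
    av = ad.value_of(alpha)
    safe = ad.clip(alpha, 1e-300, 1.0)
    h = -ad.tsum(ad.tensor(alpha) * ad.log(safe), axis=-1) \
        if isinstance(alpha, ad.Tensor) else -np.sum(av * np.log(np.clip(av, 1e-300, 1.0)), axis=-1)
    if av.ndim == 1:
        return h
    return ad.tmean(h, axis=0)


def attention_entropy_term(alpha, beta: float, sign: str = "diversity"):
    """Entropy regularizer added to the total loss.

    ``diversity`` (default) contributes -beta * H, rewarding spread-out
    attention; ``concentration`` contributes +beta * H, penalizing it.
    """
    if sign not in ("diversity", "concentration"):
        raise ValueError("sign must be diversity|concentration")
    h = attention_entropy(alpha)
    return -beta * h if sign == "diversity" else beta * h


def l2_penalty(params, lam: float):
    """lam * ||theta||^2 over weight matrices (biases and the task
    log-uncertainties are exempt)."""
    if lam == 0.0:
        return 0.0
    acc = None
    for w in params.weight_matrices():
        s = ad.tsum(w * w)
        acc = s if acc is None else acc + s
    return lam * acc if acc is not None else 0.0


def total_loss(data_term, params=None, config: LossConfig = None,
               smooth_term=0.0, entropy_term=0.0):
    """Assemble the composite objective and its per-term breakdown.

    ``smooth_term``/``entropy_term`` arrive already scaled by their
    strengths; the L2 term is computed here from ``params`` and
    ``config.l2_lambda``.  Returns ``(total, LossBreakdown)`` where total is
    a tensor whenever any input is one.
    """
    config = config or LossConfig()
    l2 = l2_penalty(params, config.l2_lambda) if params is not None else 0.0
    total = data_term + l2 + smooth_term + entropy_term
    bd = LossBreakdown(
        data_term=float(ad.value_of(data_term)),
        l2_term=float(ad.value_of(l2)),
        smooth_term=float(ad.value_of(smooth_term)),
        entropy_term=float(ad.value_of(entropy_term)),
        total=float(ad.value_of(total)))
    return total, bd


def multitask_loss(task_losses, config: LossConfig = None, log_sigma=None):
    """Combined multi-task objective over K = 3 heads.

    Fixed mode: sum_k lambda_k L_k.  Uncertainty mode: each task is scaled
    by its learned homoscedastic precision, sum_k [L_k / (2 sigma_k^2) +
    log sigma_k] with sigma_k = exp(log_sigma_k) trainable.
    """
    config = config or LossConfig()
    if config.use_uncertainty:
        if log_sigma is None:
            raise ValueError("uncertainty mode needs log_sigma")
        total = None
        for k, lk in enumerate(task_losses):
            ls_k = log_sigma[k]
            term = lk * ad.exp(-2.0 * ls_k) * 0.5 + ls_k
            total = term if total is None else total + term
        return total
    total = None
    for lam, lk in zip(config.task_lambdas, task_losses):
        term = lam * lk
        total = term if total is None else total + term
    return total
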