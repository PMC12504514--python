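"""Training loop (plain SGD with stepwise learning-rate decay), data splits,
evaluation metrics, inference-time dynamic evaluation with an elastic
anchor, and the ablation harness.

Everything is deterministic given the config seed: splits, shuffling,
resampling and augmentation all derive from one ``numpy`` generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from . import _autodiff as ad
from .cohort import Cohort
from .imbalance import hybrid_resample
from .losses import (
    LossConfig,
    attention_entropy_term,
    bce_sequence,
    combine_class_weights,
    dynamic_weight_update,
    multitask_loss,
    smoothness_penalty,
    total_loss,
    weighted_bce,
)
from .model import (
    ChronoNetParams,
    ModelConfig,
    attention_weights,
    context_vector,
    encode_sequence,
    multitask_forward,
    pooled_risk,
    step_risk,
)
from .preprocess import (
    PreprocessConfig,
    augment,
    cohort_channel_medians,
    impute_cohort,
    normalize,
    pad_and_mask,
)


@dataclass
class TrainConfig:
    lr0: float = 0.001
    decay_factor: float = 10.0
    decay_every: int = 10
    batch_size: int = 32
    epochs: int = 50
    split: tuple = (0.8, 0.1, 0.1)      # (0.7, 0.15, 0.15) for small cohorts
    seed: int = 0
    mode: str = "sequence"              # sequence | pooled
    d_h: int = 64
    d_a: int = 32
    attention: bool = True              # pooled mode only; off = use h_T
    multitask: bool = False
    use_dynamic_weights: bool = False
    augment: bool = False
    threshold: float = 0.5

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.mode not in ("sequence", "pooled"):
            raise ValueError("mode must be sequence|pooled")


@dataclass
class MetricsReport:
    accuracy: float
    recall: float
    precision: float
    f1: float
    auc: float          # None when labels are single-class
    tp: int
    fp: int
    tn: int
    fn: int
    n: int


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """lr0 decayed by ``decay_factor`` every ``decay_every`` epochs."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.lr0 * config.decay_factor ** (
        -(epoch // config.decay_every))


def auc_rank(scores, labels):
    """AUROC via the Mann-Whitney rank statistic; ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def evaluate(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Threshold class metrics plus rank-statistic AUROC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n = len(labels)
    acc = (tp + tn) / n if n else float("nan")
    rec = tp / (tp + fn) if (tp + fn) else 0.0
    prec = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    return MetricsReport(acc, rec, prec, f1, auc_rank(scores, labels),
                         tp, fp, tn, fn, n)


def split_cohort(cohort: Cohort, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Disjoint patient-level train/validation/test index arrays."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cohort.n)
    n_train = int(round(fractions[0] * cohort.n))
    n_val = int(round(fractions[1] * cohort.n))
    return (perm[:n_train], perm[n_train:n_train + n_val],
            perm[n_train + n_val:])


def patient_scores(outputs, batch, mode: str) -> np.ndarray:
    """Per-patient risk score: the attention-pooled probability in pooled
    mode, the maximum per-step probability over real steps otherwise."""
    if mode == "pooled" and "yhat_pooled" in outputs:
        return ad.value_of(outputs["yhat_pooled"]).ravel()
    steps = ad.value_of(outputs["yhat_steps"])
    masked = np.where(batch.pad_mask, steps, -np.inf)
    return masked.max(axis=1)


def _patient_labels(batch) -> np.ndarray:
    return (np.where(batch.pad_mask, batch.labels, 0).max(axis=1) > 0).astype(int)


def _forward_pooled(batch, params, attention: bool, z=None):
    H = encode_sequence(batch, params)
    yhat_steps = step_risk(H, params)
    if attention:
        alpha = attention_weights(H, params, batch.pad_mask, z=z)
        c = context_vector(H, alpha)
        return {"H": H, "yhat_steps": yhat_steps, "alpha": alpha,
                "context": c, "yhat_pooled": pooled_risk(c, params),
                "h_last": H[:, -1, :]}
    h_last = H[:, -1, :]
    return {"H": H, "yhat_steps": yhat_steps, "h_last": h_last,
            "yhat_pooled": step_risk(h_last, params), "context": h_last}


def batch_objective(batch, params, train_cfg: TrainConfig,
                    loss_cfg: LossConfig, class_weights=None, z=None,
                    task_targets=None):
    """Forward pass plus composite loss for one padded batch.

    Returns ``(total, breakdown, outputs)``.  ``class_weights`` is an
    optional (w_neg, w_pos) pair mapped to per-patient instance weights by
    the patient-level label.
    """
    y_patient = _patient_labels(batch)
    inst_w = None
    if class_weights is not None:
        cw = np.asarray(class_weights, dtype=float)
        inst_w = cw[y_patient]
    if train_cfg.mode == "pooled":
        outputs = _forward_pooled(batch, params, train_cfg.attention, z=z)
        yhat = outputs["yhat_pooled"]
        if inst_w is not None:
            data = weighted_bce(y_patient, yhat, inst_w,
                                eps=loss_cfg.prob_clip_eps)
        else:
            data = bce_sequence(y_patient.astype(float).reshape(-1, 1),
                                yhat.reshape(-1, 1),
                                eps=loss_cfg.prob_clip_eps)
        entropy = 0.0
        if train_cfg.attention and loss_cfg.entropy_beta > 0:
            entropy = attention_entropy_term(
                outputs["alpha"], loss_cfg.entropy_beta,
                loss_cfg.entropy_sign)
    else:
        H = encode_sequence(batch, params)
        outputs = {"H": H, "yhat_steps": step_risk(H, params),
                   "h_last": H[:, -1, :]}
        data = bce_sequence(batch.labels, outputs["yhat_steps"],
                            batch.pad_mask, eps=loss_cfg.prob_clip_eps,
                            instance_weights=inst_w)
        entropy = 0.0
    smooth = 0.0
    if loss_cfg.smooth_gamma > 0:
        smooth = smoothness_penalty(outputs["yhat_steps"], batch.pad_mask,
                                    loss_cfg.smooth_gamma)
    total, bd = total_loss(data, params, loss_cfg, smooth, entropy)
    if train_cfg.multitask and task_targets is not None:
        shared = outputs.get("context", outputs["h_last"])
        probs = multitask_forward(shared, params)
        task_losses = []
        for k in range(task_targets.shape[1]):
            task_losses.append(bce_sequence(
                task_targets[:, k].astype(float).reshape(-1, 1),
                probs[:, k].reshape(-1, 1), eps=loss_cfg.prob_clip_eps))
        mt = multitask_loss(task_losses, loss_cfg,
                            log_sigma=params.log_sigma)
        bd.task_terms = {f"task_{k}": float(ad.value_of(l))
                         for k, l in enumerate(task_losses)}
        total = total + mt
        bd.total = float(ad.value_of(total))
    return total, bd, outputs


def _sgd_step(params: ChronoNetParams, lr: float) -> None:
    for t in params.tensors.values():
        if t.grad is not None:
            t.value = t.value - lr * t.grad


def prepare_splits(cohort: Cohort, train_cfg: TrainConfig,
                   pre_cfg: PreprocessConfig = None, plan=None):
    """Split, impute and normalize with training-split statistics only, and
    resample the training split if a plan is given."""
    pre_cfg = pre_cfg or PreprocessConfig()
    idx_tr, idx_va, idx_te = split_cohort(cohort, train_cfg.split,
                                          train_cfg.seed)
    train_c = cohort.subset(idx_tr)
    medians = cohort_channel_medians(train_c)
    train_c = impute_cohort(train_c, pre_cfg, medians)
    train_c, stats = normalize(train_c)
    val_c = normalize(impute_cohort(cohort.subset(idx_va), pre_cfg, medians),
                      stats)[0]
    test_c = normalize(impute_cohort(cohort.subset(idx_te), pre_cfg, medians),
                       stats)[0]
    resolved = None
    if plan is not None:
        train_c, resolved = hybrid_resample(train_c, plan)
    return train_c, val_c, test_c, stats, resolved


def _cohort_batch(cohort: Cohort, indices, T_max=None):
    sel = [cohort.series[i] for i in indices]
    T_max = T_max or max(s.T for s in sel)
    batch = pad_and_mask(sel, T_max)
    task = np.array([[cohort.profiles[i].outcome_aki,
                      cohort.profiles[i].outcome_recovery,
                      cohort.profiles[i].outcome_dialysis]
                     for i in indices], dtype=float)
    return batch, task


def train(cohort: Cohort, params: ChronoNetParams,
          train_cfg: TrainConfig = None, loss_cfg: LossConfig = None,
          plan=None, pre_cfg: PreprocessConfig = None):
    """Fit the network with plain SGD on the composite objective.

    The cohort is split by patient, imputed and normalized with
    training-split statistics, optionally resampled (training split only),
    then optimized for ``epochs`` epochs.  Per-epoch loss breakdowns and
    validation metrics are logged; the parameters giving the best validation
    AUROC are restored at the end.  Fully deterministic given the seed.

    Returns ``(params, logs)`` with logs a list of per-epoch dicts.
    """
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    train_c, val_c, _, _, _ = prepare_splits(cohort, train_cfg, pre_cfg, plan)
    rng = np.random.default_rng(train_cfg.seed + 1)

    logs = []
    best = {"auc": -np.inf, "snap": params.snapshot(), "epoch": -1}
    static_w = np.asarray(loss_cfg.class_weights, dtype=float) \
        if loss_cfg.class_weights is not None else None
    dyn_w = np.ones(2)
    last_snap = params.snapshot()

    for epoch in range(train_cfg.epochs):
        lr = lr_schedule(epoch, train_cfg)
        order = rng.permutation(train_c.n)
        epoch_bd, class_hits, class_tot = [], np.zeros(2), np.zeros(2)
        for start in range(0, train_c.n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            sel = [train_c.series[i] for i in idx]
            if train_cfg.augment:
                sel = [augment(s, pre_cfg, rng, train_c.channel_meta)
                       for s in sel]
            batch = pad_and_mask(sel, max(s.T for s in sel))
            task = np.array([[train_c.profiles[i].outcome_aki,
                              train_c.profiles[i].outcome_recovery,
                              train_c.profiles[i].outcome_dialysis]
                             for i in idx], dtype=float)
            cw = None
            if static_w is not None:
                cw = combine_class_weights(static_w, dyn_w) \
                    if train_cfg.use_dynamic_weights else static_w
            params.zero_grad()
            total, bd, outputs = batch_objective(
                batch, params, train_cfg, loss_cfg, class_weights=cw,
                task_targets=task if train_cfg.multitask else None)
            if not np.isfinite(ad.value_of(total)):
                params.load_snapshot(last_snap)
                logs.append({"epoch": epoch, "event": "diverged"})
                params.load_snapshot(best["snap"])
                return params, logs
            total.backward()
            _sgd_step(params, lr)
            epoch_bd.append(bd)
            y_p = _patient_labels(batch)
            s_p = patient_scores(outputs, batch, train_cfg.mode)
            hit = ((s_p >= train_cfg.threshold).astype(int) == y_p)
            for c in (0, 1):
                class_hits[c] += hit[y_p == c].sum()
                class_tot[c] += (y_p == c).sum()
        last_snap = params.snapshot()
        if train_cfg.use_dynamic_weights:
            acc = np.divide(class_hits, np.maximum(class_tot, 1))
            dyn_w = np.array([dynamic_weight_update(a, loss_cfg.dynamic_temp)
                              for a in acc])
        # validation
        val_scores, val_labels = predict_cohort(val_c, params, train_cfg)
        rep = evaluate(val_scores, val_labels, train_cfg.threshold)
        entry = {
            "epoch": epoch, "lr": lr,
            "loss_total": float(np.mean([b.total for b in epoch_bd])),
            "loss_data": float(np.mean([b.data_term for b in epoch_bd])),
            "loss_l2": float(np.mean([b.l2_term for b in epoch_bd])),
            "loss_smooth": float(np.mean([b.smooth_term for b in epoch_bd])),
            "loss_entropy": float(np.mean([b.entropy_term
                                           for b in epoch_bd])),
            "val_auc": rep.auc, "val_accuracy": rep.accuracy,
            "val_recall": rep.recall, "val_f1": rep.f1,
        }
        logs.append(entry)
        if rep.auc is not None and rep.auc > best["auc"]:
            best = {"auc": rep.auc, "snap": params.snapshot(),
                    "epoch": epoch}
    params.load_snapshot(best["snap"])
    return params, logs


def predict_cohort(cohort: Cohort, params, train_cfg: TrainConfig,
                   batch_size: int = 256):
    """Patient-level scores and labels for an (already preprocessed) cohort."""
    scores, labels = [], []
    for start in range(0, cohort.n, batch_size):
        idx = range(start, min(start + batch_size, cohort.n))
        batch, _ = _cohort_batch(cohort, list(idx))
        if train_cfg.mode == "pooled":
            outputs = _forward_pooled(batch, params, train_cfg.attention)
        else:
            H = encode_sequence(batch, params)
            outputs = {"yhat_steps": step_risk(H, params)}
        scores.append(patient_scores(outputs, batch, train_cfg.mode))
        labels.append(_patient_labels(batch))
    return np.concatenate(scores), np.concatenate(labels)


# --------------------------------------------------------------------------
# dynamic evaluation (inference-time adaptation with an elastic anchor)
# --------------------------------------------------------------------------

def dynamic_evaluate(params: ChronoNetParams, windows, eta: float,
                     elastic_lambda: float,
                     loss_cfg: LossConfig = None,
                     train_cfg: TrainConfig = None):
    """Online adaptation over a stream of windows.

    For each incoming window the current model first emits predictions, then
    (when the window carries observed labels) takes one gradient step on the
    masked sequence BCE combined with the elastic penalty
    (lambda/2)||theta - theta*||^2 anchored at the trained parameters.  The
    elastic part is applied as a proximal (implicit) update,
    theta <- (theta - eta g + eta lambda theta*) / (1 + eta lambda),
    so lambda -> inf pins theta at theta* exactly and lambda = 0 is a plain
    gradient step.  eta = 0 reproduces static inference.

    Returns ``(predictions, params)``; predictions is a list of per-window
    (B, T) arrays of per-step probabilities.
    """
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()
    anchor = params.snapshot()
    preds = []
    for batch in windows:
        H = encode_sequence(batch, params)
        yhat = step_risk(H, params)
        preds.append(ad.value_of(yhat).copy())
        if eta == 0.0 or batch.labels is None:
            continue
        params.zero_grad()
        data = bce_sequence(batch.labels, yhat, batch.pad_mask,
                            eps=loss_cfg.prob_clip_eps)
        data.backward()
        for name, t in params.tensors.items():
            g = t.grad if t.grad is not None else 0.0
            if np.isinf(elastic_lambda):
                t.value = anchor[name].copy()
            else:
                t.value = (t.value - eta * g
                           + eta * elastic_lambda * anchor[name]) \
                    / (1.0 + eta * elastic_lambda)
    return preds, params


# --------------------------------------------------------------------------
# ablations
# --------------------------------------------------------------------------

ABLATION_SWITCHES = ("no_sequence", "no_attention", "no_generalization")


def train_flat(cohort: Cohort, train_cfg: TrainConfig,
               loss_cfg: LossConfig = None, pre_cfg=None, seed=None):
    """Flattened single-layer predictor (logistic map on the concatenated
    padded sequence) — the no-sequence ablation reference."""
    loss_cfg = loss_cfg or LossConfig()
    train_c, val_c, _, _, _ = prepare_splits(cohort, train_cfg, pre_cfg)
    T_max = max(s.T for s in cohort.series)
    rng = np.random.default_rng(train_cfg.seed if seed is None else seed)
    D = T_max * cohort.d
    W = ad.Tensor(rng.uniform(-1, 1, (D, 1)) / np.sqrt(D), requires_grad=True)
    b = ad.Tensor(np.zeros(1), requires_grad=True)

    def flat_scores(c: Cohort):
        batch = pad_and_mask(c.series, T_max)
        X = batch.inputs.reshape(c.n, -1)
        y = _patient_labels(batch)
        return X, y

    Xtr, ytr = flat_scores(train_c)
    best, best_auc = (W.value.copy(), b.value.copy()), -np.inf
    for epoch in range(train_cfg.epochs):
        lr = lr_schedule(epoch, train_cfg)
        order = rng.permutation(len(ytr))
        for start in range(0, len(ytr), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            W.grad = b.grad = None
            logits = ad.tensor(Xtr[idx]) @ W + b
            prob = ad.sigmoid(logits.reshape(len(idx)))
            loss = bce_sequence(ytr[idx].astype(float).reshape(-1, 1),
                                prob.reshape(-1, 1),
                                eps=loss_cfg.prob_clip_eps)
            loss.backward()
            W.value = W.value - lr * W.grad
            b.value = b.value - lr * b.grad
        Xv, yv = flat_scores(val_c)
        sv = 1.0 / (1.0 + np.exp(-(Xv @ W.value + b.value.reshape(1, 1)))).ravel()
        auc = auc_rank(sv, yv)
        if auc is not None and auc > best_auc:
            best_auc, best = auc, (W.value.copy(), b.value.copy())
    W.value, b.value = best

    def predictor(c: Cohort):
        X, y = flat_scores(c)
        return 1.0 / (1.0 + np.exp(-(X @ W.value + b.value))).ravel(), y

    return predictor, best_auc


def fit_pooled_arrays(X, y, train_cfg: TrainConfig,
                      loss_cfg: LossConfig = None, model_seed: int = 0,
                      val_frac: float = 0.25):
    """Train the pooled (attention or final-state) model on raw arrays.

    ``X`` is (n, T, d) with no padding and ``y`` patient-level labels —
    the shape used by the planted mid-window benchmark.  Returns
    ``(params, val_auc)`` where the AUROC is computed on a held-out fraction
    at the best epoch.
    """
    from .preprocess import PaddedBatch

    loss_cfg = loss_cfg or LossConfig()
    n, T, d = X.shape
    rng = np.random.default_rng(train_cfg.seed)
    perm = rng.permutation(n)
    n_val = int(round(val_frac * n))
    va, tr = perm[:n_val], perm[n_val:]
    params = ChronoNetParams(ModelConfig(d=d, d_h=train_cfg.d_h,
                                         d_a=train_cfg.d_a, seed=model_seed))

    def make_batch(idx):
        lab = np.repeat(y[idx, None].astype(float), T, axis=1)
        return PaddedBatch(X[idx], np.ones((len(idx), T), dtype=bool), lab,
                           np.full(len(idx), T))

    cfg = replace(train_cfg, mode="pooled")
    best_auc, best_snap = -np.inf, params.snapshot()
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        order = rng.permutation(len(tr))
        for start in range(0, len(tr), cfg.batch_size):
            idx = tr[order[start:start + cfg.batch_size]]
            params.zero_grad()
            total, _, _ = batch_objective(make_batch(idx), params, cfg,
                                          loss_cfg)
            total.backward()
            _sgd_step(params, lr)
        vb = make_batch(va)
        outputs = _forward_pooled(vb, params, cfg.attention)
        auc = auc_rank(patient_scores(outputs, vb, "pooled"), y[va])
        if auc is not None and auc > best_auc:
            best_auc, best_snap = auc, params.snapshot()
    params.load_snapshot(best_snap)
    return params, best_auc


def ablate(cohort: Cohort, train_cfg: TrainConfig, loss_cfg: LossConfig,
           switches, plan=None, model_seed: int = 0):
    """Matched-seed component ablations on identical splits.

    ``no_sequence``: flattened single-layer predictor instead of the LSTM;
    ``no_attention``: pooled prediction from the final hidden state only;
    ``no_generalization``: imbalance handling, smoothness and entropy terms
    all disabled.  Returns {name: MetricsReport} on the validation split,
    including the unmodified ``baseline``.
    """
    for s in switches:
        if s not in ABLATION_SWITCHES:
            raise ValueError(f"unknown ablation switch {s!r}")
    results = {}

    def run(cfg, lcfg, use_plan):
        mcfg = ModelConfig(d=cohort.d, d_h=cfg.d_h, d_a=cfg.d_a,
                           seed=model_seed)
        params = ChronoNetParams(mcfg)
        params, _ = train(cohort, params, cfg, lcfg, plan=use_plan)
        _, val_c, _, _, _ = prepare_splits(cohort, cfg)
        scores, labels = predict_cohort(val_c, params, cfg)
        return evaluate(scores, labels, cfg.threshold)

    results["baseline"] = run(train_cfg, loss_cfg, plan)
    for s in switches:
        if s == "no_sequence":
            cfg = replace(train_cfg)
            predictor, _ = train_flat(cohort, cfg, loss_cfg)
            _, val_c, _, _, _ = prepare_splits(cohort, cfg)
            sc, yl = predictor(val_c)
            results[s] = evaluate(sc, yl, cfg.threshold)
        elif s == "no_attention":
            cfg = replace(train_cfg, mode="pooled", attention=False)
            results[s] = run(cfg, loss_cfg, plan)
        elif s == "no_generalization":
            cfg = replace(train_cfg)
            lcfg = replace(loss_cfg, smooth_gamma=0.0, entropy_beta=0.0,
                           class_weights=None)
            results[s] = run(cfg, lcfg, None)
    return results
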