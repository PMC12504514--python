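"""Imputation, normalization, padding/masking and train-time augmentation.

Short gaps are forward- then backward-filled (carry horizon capped at
``ffill_max_gap`` steps); persistent gaps fall back to the patient-level
median of observed values and then to the cohort-level median.  Categorical
gaps get a sentinel level.  The observed-mask always records the *original*
missingness.  Variable-length sequences are right-padded with an explicit
pad-mask so padded positions contribute nothing to any loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .cohort import ClinicalSeries, Cohort


@dataclass
class PreprocessConfig:
    ffill_max_gap: int = 3            # steps a value may be carried
    categorical_sentinel: float = -1  # missing-category code
    noise_sd_frac: float = 0.05       # augmentation noise, fraction of channel sd
    time_scale_range: tuple = (0.9, 1.1)
    mask_prob: float = 0.1            # per-channel drop prob, non-essential only
    normalize: bool = True

    def __post_init__(self):
        if self.ffill_max_gap < 1:
            raise ValueError("ffill_max_gap must be >= 1")
        if not 0.0 <= self.mask_prob <= 1.0:
            raise ValueError("mask_prob must lie in [0, 1]")


@dataclass
class PaddedBatch:
    """Right-padded (batch, T_max, d) inputs with a real-step mask."""

    inputs: np.ndarray
    pad_mask: np.ndarray   # (batch, T_max) bool, True = real step
    labels: np.ndarray     # (batch, T_max) per-step AKI labels
    lengths: np.ndarray

    def __post_init__(self):
        if self.inputs.shape[:2] != self.pad_mask.shape:
            raise ValueError("inputs and pad_mask shapes disagree")


class TruncationError(ValueError):
    """A sequence exceeds T_max; silent truncation is never performed."""


def _fill_channel_capped(x, obs, max_gap):
    """Forward- then backward-fill with a carry horizon of ``max_gap``."""
    x = x.copy()
    filled = obs.copy()
    # forward
    last, dist = None, 0
    for i in range(len(x)):
        if obs[i]:
            last, dist = x[i], 0
        elif last is not None:
            dist += 1
            if dist <= max_gap:
                x[i] = last
                filled[i] = True
    # backward (only into cells still unfilled)
    nxt, dist = None, 0
    for i in range(len(x) - 1, -1, -1):
        if obs[i]:
            nxt, dist = x[i], 0
        else:
            dist += 1
            if not filled[i] and nxt is not None and dist <= max_gap:
                x[i] = nxt
                filled[i] = True
    return x, filled


def cohort_channel_medians(cohort: Cohort) -> dict:
    """Cohort-level median of observed values, per channel."""
    med = {}
    for j, m in enumerate(cohort.channel_meta):
        vals = np.concatenate([s.values[s.observed_mask[:, j], j]
                               for s in cohort.series]) if cohort.n else np.array([])
        med[m.name] = float(np.median(vals)) if vals.size else np.nan
    return med


def impute_series(series: ClinicalSeries, config: PreprocessConfig,
                  channel_meta=None, cohort_medians: dict = None) -> ClinicalSeries:
    """Fill every gap; the observed-mask is left untouched.

    Continuous/binary channels: capped ffill/bfill, then patient median,
    then cohort median.  Categorical channels: sentinel level.
    """
    values = series.values.copy()
    kinds = {m.name: m.kind for m in (channel_meta or [])}
    for j, name in enumerate(series.channel_names):
        obs = series.observed_mask[:, j]
        if obs.all():
            continue
        kind = kinds.get(name, "continuous")
        if kind == "categorical":
            values[~obs, j] = config.categorical_sentinel
            continue
        x, filled = _fill_channel_capped(values[:, j], obs, config.ffill_max_gap)
        if not filled.all():
            if obs.any():
                x[~filled] = np.median(x[obs])
            elif cohort_medians and np.isfinite(cohort_medians.get(name, np.nan)):
                x[~filled] = cohort_medians[name]
            else:
                warnings.warn(f"channel {name!r}: no observed values anywhere; "
                              "filling with zero", stacklevel=2)
                x[~filled] = 0.0
        values[:, j] = x
    return replace(series, values=values)


def impute_cohort(cohort: Cohort, config: PreprocessConfig,
                  cohort_medians: dict = None) -> Cohort:
    meds = cohort_medians if cohort_medians is not None \
        else cohort_channel_medians(cohort)
    out = [impute_series(s, config, cohort.channel_meta, meds)
           for s in cohort.series]
    return Cohort(out, cohort.profiles, cohort.channel_meta)


def pad_and_mask(series_list, T_max: int) -> PaddedBatch:
    """Right-pad with zeros; unpadding via lengths recovers inputs exactly."""
    B = len(series_list)
    d = series_list[0].values.shape[1] if B else 0
    inputs = np.zeros((B, T_max, d))
    pad_mask = np.zeros((B, T_max), dtype=bool)
    labels = np.zeros((B, T_max))
    lengths = np.zeros(B, dtype=int)
    for i, s in enumerate(series_list):
        if s.T > T_max:
            raise TruncationError(
                f"patient {s.patient_id}: T={s.T} exceeds T_max={T_max}")
        inputs[i, :s.T] = s.values
        pad_mask[i, :s.T] = True
        labels[i, :s.T] = s.labels_aki
        lengths[i] = s.T
    return PaddedBatch(inputs, pad_mask, labels, lengths)


def augment(series: ClinicalSeries, config: PreprocessConfig, rng,
            channel_meta=None) -> ClinicalSeries:
    """Train-time augmentation: Gaussian jitter on continuous channels,
    elastic time scaling (length preserved via linear re-interpolation onto
    the hourly grid), and random masking of non-essential channels.  Labels
    are never touched.
    """
    values = series.values.copy()
    meta = {m.name: m for m in (channel_meta or [])}
    T = series.T
    lo, hi = config.time_scale_range
    factor = float(rng.uniform(lo, hi)) if (lo, hi) != (1.0, 1.0) else 1.0
    grid = np.arange(1, T + 1, dtype=float)
    for j, name in enumerate(series.channel_names):
        m = meta.get(name)
        kind = m.kind if m else "continuous"
        essential = m.essential if m else False
        col = values[:, j]
        if kind == "continuous":
            if factor != 1.0:
                # value'(t) = value(t / factor): a factor > 1 stretches the
                # trajectory, shrinking ramp slopes by 1/factor
                src = np.clip(grid / factor, 1.0, T)
                col = np.interp(src, grid, col)
            if config.noise_sd_frac > 0:
                sd = float(np.std(series.values[:, j]))
                col = col + rng.normal(0.0, config.noise_sd_frac * sd, size=T)
        if not essential and config.mask_prob > 0 and \
                rng.random() < config.mask_prob:
            if kind == "categorical":
                col = np.full(T, config.categorical_sentinel)
            else:
                col = np.full(T, float(np.median(series.values[:, j])))
        values[:, j] = col
    return replace(series, values=values)


def normalize(cohort: Cohort, stats: dict = None):
    """Z-score continuous channels; binary/categorical are untouched.

    With ``stats`` from the training split the same affine map is applied
    (validation/test must never contribute statistics).  Returns
    ``(cohort, stats)``.
    """
    if stats is None:
        stats = {}
        for j, m in enumerate(cohort.channel_meta):
            if m.kind != "continuous":
                continue
            vals = np.concatenate([s.values[:, j] for s in cohort.series])
            mu, sd = float(vals.mean()), float(vals.std())
            if sd == 0.0:
                warnings.warn(f"channel {m.name!r} has zero variance; "
                              "left unscaled", stacklevel=2)
            stats[m.name] = (mu, sd)
    out = []
    for s in cohort.series:
        values = s.values.copy()
        for j, m in enumerate(cohort.channel_meta):
            if m.name in stats:
                mu, sd = stats[m.name]
                if sd > 0:
                    values[:, j] = (values[:, j] - mu) / sd
        out.append(replace(s, values=values))
    return Cohort(out, cohort.profiles, cohort.channel_meta), stats
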