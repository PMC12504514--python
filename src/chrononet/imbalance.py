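"""Class-imbalance machinery: SMOTE interpolation, minority k-NN, random
undersampling, and the hybrid fixed-total resampling with exact before/after
bookkeeping (counts, prevalence to 1 decimal, majority:minority ratio to 2
decimals, counts rounded half-up).

SMOTE operates on flattened fixed-length sequence matrices with static
features appended, so interpolation happens in trajectory space and
preserves per-channel temporal shape; synthetic patients inherit the base
sample's per-step labels and outcomes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .cohort import Cohort
from .preprocess import pad_and_mask


class ResamplingPlanError(ValueError):
    """The requested target cannot be met (e.g. it would need a negative
    number of synthetic samples under a fixed total)."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ResamplingPlan:
    """Target and bookkeeping of one hybrid resampling run.

    ``target_kind`` is ``"prevalence"`` (positive fraction of the fixed
    total) or ``"ratio"`` (majority:minority quotient r in "1:r").
    """

    target_kind: str
    target_value: float
    fixed_total: bool = True
    k_neighbors: int = 5
    seed: int = 0
    n_total_before: int = None
    n_pos_before: int = None
    n_total_after: int = None
    n_pos_after: int = None

    def __post_init__(self):
        if self.target_kind not in ("prevalence", "ratio"):
            raise ValueError("target_kind must be prevalence|ratio")

    # -- printed-format bookkeeping ---------------------------------------
    @staticmethod
    def _prevalence_pct(n_pos, n_total):
        return _round_half_up(1000.0 * n_pos / n_total) / 10.0

    @staticmethod
    def _ratio(n_pos, n_total):
        return _round_half_up(100.0 * (n_total - n_pos) / n_pos) / 100.0

    @property
    def prevalence_before(self):
        return self._prevalence_pct(self.n_pos_before, self.n_total_before)

    @property
    def prevalence_after(self):
        return self._prevalence_pct(self.n_pos_after, self.n_total_after)

    @property
    def ratio_after(self):
        """Majority:minority quotient, 2 decimals (the 'r' of '1:r')."""
        return self._ratio(self.n_pos_after, self.n_total_after)

    @property
    def ratio_after_str(self):
        return f"1:{self.ratio_after:.2f}"

    def target_positive_count(self, n_total: int) -> int:
        if self.target_kind == "prevalence":
            return _round_half_up(self.target_value / 100.0 * n_total
                                  if self.target_value > 1 else
                                  self.target_value * n_total)
        return _round_half_up(n_total / (1.0 + self.target_value))

    def resolve(self, n_total: int, n_pos: int) -> "ResamplingPlan":
        """Fill the before/after count fields for a fixed-total run."""
        n_pos_after = self.target_positive_count(n_total)
        if n_pos_after > n_total:
            raise ResamplingPlanError("target exceeds the fixed total")
        plan = replace(self, n_total_before=n_total, n_pos_before=n_pos,
                       n_total_after=n_total, n_pos_after=n_pos_after)
        if n_pos_after < n_pos:
            raise ResamplingPlanError(
                "target needs a negative synthetic count "
                f"({n_pos_after} < {n_pos} positives)")
        if n_total - n_pos_after > n_total - n_pos:
            raise ResamplingPlanError("target needs negative undersampling")
        return plan

    def to_dict(self) -> dict:
        return {
            "target": {self.target_kind: self.target_value},
            "fixed_total": self.fixed_total,
            "k_neighbors": self.k_neighbors,
            "seed": self.seed,
            "before": {"positive": self.n_pos_before,
                       "total": self.n_total_before,
                       "prevalence_pct": self.prevalence_before},
            "after": {"positive": self.n_pos_after,
                      "total": self.n_total_after,
                      "prevalence_pct": self.prevalence_after,
                      "ratio": self.ratio_after_str},
        }


def smote_interpolate(x_i, x_neighbor, lam: float):
    """Synthetic sample on the segment between a minority point and one of
    its minority neighbors: x~ = x_i + lam (x_neighbor - x_i)."""
    x_i = np.asarray(x_i, dtype=float)
    x_neighbor = np.asarray(x_neighbor, dtype=float)
    if x_i.shape != x_neighbor.shape:
        raise ValueError("vectors must share dimension")
    return x_i + lam * (x_neighbor - x_i)


def minority_neighbors(X_minority, k: int = 5):
    """Indices of each minority point's k nearest minority neighbors
    (Euclidean, self excluded).  k is reduced with a warning when the class
    is too small."""
    X = np.asarray(X_minority, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two minority points")
    if k >= n:
        warnings.warn(f"k={k} >= minority size {n}; using k={n - 1}",
                      stacklevel=2)
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    idx = nn.kneighbors(X, return_distance=False)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        # drop self; with zero-distance duplicates self may not even appear,
        # leaving k+1 candidates — keep the nearest k either way
        out[i] = idx[i][idx[i] != i][:k]
    return out


def _flatten_cohort(cohort: Cohort, T_max: int):
    batch = pad_and_mask(cohort.series, T_max)
    flat = batch.inputs.reshape(cohort.n, -1)
    static = np.array([[p.age, s.weight_kg]
                       for s, p in zip(cohort.series, cohort.profiles)])
    return np.hstack([flat, static]), batch


def hybrid_resample(cohort: Cohort, plan: ResamplingPlan):
    """SMOTE oversampling of the minority class exactly offset by random
    undersampling of the majority, keeping the total fixed.

    Patients are classed by their AKI outcome flag.  Synthetic minority
    patients are interpolated on the flattened padded trajectory (plus age
    and weight), reshaped back to a series of the base patient's length, and
    inherit that patient's per-step labels, mask and outcomes.  Returns
    ``(resampled_cohort, resolved_plan)``.
    """
    labels = np.array([p.outcome_aki for p in cohort.profiles])
    n_pos = int(labels.sum())
    n_neg = cohort.n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ResamplingPlanError("both classes must be present")
    resolved = plan.resolve(cohort.n, n_pos)
    n_synthetic = resolved.n_pos_after - n_pos
    if n_synthetic == 0 and resolved.n_total_after == cohort.n:
        return cohort, resolved

    rng = np.random.default_rng(plan.seed)
    T_max = max(s.T for s in cohort.series)
    X, batch = _flatten_cohort(cohort, T_max)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)

    neighbors = minority_neighbors(X[pos_idx], plan.k_neighbors)
    k = neighbors.shape[1]
    new_series, new_profiles = [], []
    for m in range(n_synthetic):
        bi = int(rng.integers(len(pos_idx)))
        nb = int(neighbors[bi, rng.integers(k)])
        lam = float(rng.random())
        x_new = smote_interpolate(X[pos_idx[bi]], X[pos_idx[nb]], lam)
        base = cohort.series[pos_idx[bi]]
        base_p = cohort.profiles[pos_idx[bi]]
        values = x_new[:-2].reshape(T_max, cohort.d)[:base.T]
        new_series.append(replace(
            base,
            patient_id=f"{base.patient_id}_syn{m}",
            values=values,
            observed_mask=np.ones_like(base.observed_mask),
            labels_aki=base.labels_aki.copy(),
            weight_kg=float(x_new[-1])))
        new_profiles.append(replace(base_p,
                                    patient_id=f"{base_p.patient_id}_syn{m}",
                                    age=float(x_new[-2])))

    n_neg_after = resolved.n_total_after - resolved.n_pos_after
    keep_neg = rng.choice(neg_idx, size=n_neg_after, replace=False)
    keep = sorted(list(pos_idx) + list(keep_neg))
    out = Cohort([cohort.series[i] for i in keep] + new_series,
                 [cohort.profiles[i] for i in keep] + new_profiles,
                 cohort.channel_meta)
    return out, resolved
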