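"""Core data containers, KDIGO rule-based AKI labeling, and cohort filters.

A patient is represented as a :class:`ClinicalSeries` — an hourly grid of
multichannel observations with an explicit observed-mask — plus a
:class:`StaticProfile` of demographics, history flags and outcomes.  The KDIGO
consensus definition of acute kidney injury is applied per hourly step:

* serum creatinine rise >= 0.3 mg/dL within the prior 48 h, or
* serum creatinine >= 1.5x the 7-day baseline (rolling minimum), or
* urine output < 0.5 mL/kg/h sustained for more than 6 consecutive hours.

Only actually-measured values (observed-mask true) enter the rules; the
labeler therefore commutes with any later imputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CREATININE = "creatinine"
URINE_OUTPUT = "urine_output"

#: channels referenced by a KDIGO criterion; everything else is "non-essential"
ESSENTIAL_CHANNELS = (CREATININE, URINE_OUTPUT)


class MissingBaselineError(ValueError):
    """No observed serum creatinine — the KDIGO baseline is undefined."""


class InvalidProfileError(ValueError):
    """Patient-level metadata (e.g. weight) unusable for rule evaluation."""


@dataclass
class KDIGOThresholds:
    """KDIGO AKI criteria thresholds (defaults are the consensus values)."""

    delta_scr: float = 0.3       # mg/dL absolute rise
    delta_window: int = 48       # hours for the absolute-rise criterion
    ratio_scr: float = 1.5       # fold-change over baseline
    ratio_window: int = 168      # hours (7 days) for the baseline minimum
    urine_rate: float = 0.5      # mL/kg/h oliguria threshold
    urine_duration: int = 6      # hours; criterion needs strictly more

    def __post_init__(self):
        for name in ("delta_scr", "delta_window", "ratio_scr", "ratio_window",
                     "urine_rate", "urine_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ChannelMeta:
    name: str
    kind: str = "continuous"      # continuous | binary | categorical
    essential: bool = False


@dataclass
class ClinicalSeries:
    """One patient's hourly multichannel record.

    ``values`` is (T, d); ``observed_mask`` marks actually-measured cells;
    ``times`` is the strictly increasing hourly grid (1-based integers).
    """

    patient_id: str
    times: np.ndarray
    channel_names: list
    values: np.ndarray
    observed_mask: np.ndarray
    labels_aki: np.ndarray = None
    weight_kg: float = float("nan")

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.labels_aki is None:
            self.labels_aki = np.zeros(len(self.times), dtype=int)
        self.labels_aki = np.asarray(self.labels_aki, dtype=int)
        if self.values.shape != self.observed_mask.shape:
            raise ValueError("values and observed_mask must share shape")
        if self.values.shape[0] != len(self.times):
            raise ValueError("values and times length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) == 1):
            raise ValueError("times must be strictly increasing with unit spacing")

    @property
    def T(self) -> int:
        return len(self.times)

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_index(name)]

    def channel_mask(self, name: str) -> np.ndarray:
        return self.observed_mask[:, self.channel_index(name)]


@dataclass
class StaticProfile:
    patient_id: str
    age: float
    sex: str = "unknown"
    comorbidities: dict = field(default_factory=dict)
    esrd_history: bool = False
    dialysis_history: bool = False
    outcome_aki: int = 0
    outcome_recovery: int = 0
    outcome_dialysis: int = 0

    def __post_init__(self):
        if self.age < 0:
            raise InvalidProfileError("age must be non-negative")
        for f in ("outcome_aki", "outcome_recovery", "outcome_dialysis"):
            if getattr(self, f) not in (0, 1):
                raise InvalidProfileError(f"{f} must be 0 or 1")

    def static_vector(self) -> np.ndarray:
        """Numeric context vector (age, sex indicator, comorbidity flags)."""
        sex_ind = 1.0 if str(self.sex).lower() in ("f", "female") else 0.0
        com = [float(self.comorbidities[k]) for k in sorted(self.comorbidities)]
        return np.array([self.age, sex_ind] + com, dtype=float)


@dataclass
class Cohort:
    series: list
    profiles: list
    channel_meta: list

    def __post_init__(self):
        if len(self.series) != len(self.profiles):
            raise ValueError("series and profiles must align one-to-one")

    @property
    def n(self) -> int:
        return len(self.series)

    @property
    def d(self) -> int:
        return len(self.channel_meta)

    @property
    def channel_names(self) -> list:
        return [m.name for m in self.channel_meta]

    def subset(self, indices) -> "Cohort":
        return Cohort([self.series[i] for i in indices],
                      [self.profiles[i] for i in indices],
                      self.channel_meta)


# --------------------------------------------------------------------------
# KDIGO rule engine
# --------------------------------------------------------------------------

def compute_baseline_scr(series: ClinicalSeries, t: int,
                         thresholds: KDIGOThresholds = None) -> float:
    """Baseline creatinine at step ``t`` (1-based step index).

    The rolling minimum of observed creatinine over the prior 7 days
    (window ``(time_t - ratio_window, time_t]``); if no creatinine was
    observed inside that window, falls back to the earliest observed value.
    """
    thresholds = thresholds or KDIGOThresholds()
    scr = series.channel(CREATININE)
    mask = series.channel_mask(CREATININE)
    if not mask.any():
        raise MissingBaselineError(
            f"patient {series.patient_id}: no observed creatinine")
    time_t = series.times[t - 1]
    in_window = (series.times > time_t - thresholds.ratio_window) & \
                (series.times <= time_t) & mask
    if in_window.any():
        return float(scr[in_window].min())
    return float(scr[mask][0])


def urine_rate(series: ClinicalSeries, t: int) -> float:
    """Weight-normalized urine output (mL/kg/h) at step ``t`` (1-based)."""
    if not np.isfinite(series.weight_kg) or series.weight_kg <= 0:
        raise InvalidProfileError(
            f"patient {series.patient_id}: weight missing or nonpositive")
    return float(series.channel(URINE_OUTPUT)[t - 1] / series.weight_kg)


def label_aki_kdigo(series: ClinicalSeries,
                    thresholds: KDIGOThresholds = None,
                    absorbing: bool = False) -> np.ndarray:
    """Per-step binary AKI labels from the three KDIGO criteria.

    Creatinine comparisons are inclusive (>=); the oliguria comparison is
    strict (<) and must hold on a contiguous hourly run strictly longer than
    ``urine_duration`` ending at the labeled step.  With ``absorbing`` the
    label stays 1 from first onset onward; the default is the instantaneous
    per-step evaluation.
    """
    thresholds = thresholds or KDIGOThresholds()
    T = series.T
    scr = series.channel(CREATININE)
    scr_mask = series.channel_mask(CREATININE)
    if not scr_mask.any():
        raise MissingBaselineError(
            f"patient {series.patient_id}: no observed creatinine")
    urine_mask = series.channel_mask(URINE_OUTPUT)
    rates = np.full(T, np.nan)
    ok = urine_mask & (series.weight_kg > 0)
    if np.isfinite(series.weight_kg) and series.weight_kg > 0:
        rates[ok] = series.channel(URINE_OUTPUT)[ok] / series.weight_kg

    labels = np.zeros(T, dtype=int)
    oliguric_run = 0
    for i in range(T):
        t = i + 1
        time_t = series.times[i]
        fired = False
        if scr_mask[i]:
            win = (series.times > time_t - thresholds.delta_window) & \
                  (series.times <= time_t) & scr_mask
            if scr[i] - scr[win].min() >= thresholds.delta_scr:
                fired = True
            if not fired:
                base = compute_baseline_scr(series, t, thresholds)
                if scr[i] >= thresholds.ratio_scr * base:
                    fired = True
        # oliguria: contiguous run of observed sub-threshold rates ending here
        if np.isfinite(rates[i]) and rates[i] < thresholds.urine_rate:
            oliguric_run += 1
        else:
            oliguric_run = 0
        if oliguric_run > thresholds.urine_duration:
            fired = True
        labels[i] = int(fired)
    if absorbing and labels.any():
        labels[np.argmax(labels):] = 1
    return labels


# --------------------------------------------------------------------------
# Cohort inclusion / exclusion
# --------------------------------------------------------------------------

#: fixed order in which exclusion reasons are checked (first hit counts)
EXCLUSION_REASONS = ("age", "esrd", "dialysis_history", "missing_baseline",
                     "insufficient_steps", "insufficient_consecutive")

MIN_AGE = 18
MIN_STEPS = 6
MAX_STEPS = 48
MIN_CONSECUTIVE_HOURS = 12


def _longest_recorded_run(series: ClinicalSeries, upto_step: int) -> int:
    """Longest run of consecutive steps with any observation, up to a step."""
    rec = series.observed_mask[:upto_step].any(axis=1)
    best = cur = 0
    for r in rec:
        cur = cur + 1 if r else 0
        best = max(best, cur)
    return best


def _trim_to_window(series: ClinicalSeries, max_steps: int = MAX_STEPS):
    """Restrict to the observation window: the ``max_steps`` steps ending at
    first AKI onset for positives, at end of record for negatives."""
    if series.labels_aki.any():
        end = int(np.argmax(series.labels_aki)) + 1  # first onset step
    else:
        end = series.T
    start = max(0, end - max_steps)
    if start == 0 and end == series.T:
        return series
    return replace(
        series,
        times=np.arange(1, end - start + 1),
        values=series.values[start:end],
        observed_mask=series.observed_mask[start:end],
        labels_aki=series.labels_aki[start:end],
    )


def apply_cohort_filters(cohort: Cohort,
                         thresholds: KDIGOThresholds = None):
    """Inclusion/exclusion rules: adults, no ESRD or prior dialysis, baseline
    creatinine available, >= 6 recorded steps, >= 12 consecutive recorded
    hours before AKI onset (positives) or end of stay (negatives).

    Returns ``(filtered_cohort, report)`` where the report counts each
    exclusion reason (a patient is counted once, under the first failing
    rule in :data:`EXCLUSION_REASONS` order).
    """
    thresholds = thresholds or KDIGOThresholds()
    report = {r: 0 for r in EXCLUSION_REASONS}
    keep_series, keep_profiles = [], []
    for s, p in zip(cohort.series, cohort.profiles):
        reason = None
        if p.age < MIN_AGE:
            reason = "age"
        elif p.esrd_history:
            reason = "esrd"
        elif p.dialysis_history:
            reason = "dialysis_history"
        elif not s.channel_mask(CREATININE).any():
            reason = "missing_baseline"
        else:
            n_recorded = int(s.observed_mask.any(axis=1).sum())
            if n_recorded < MIN_STEPS:
                reason = "insufficient_steps"
            else:
                if s.labels_aki.any():
                    onset = int(np.argmax(s.labels_aki)) + 1
                else:
                    onset = s.T
                if _longest_recorded_run(s, onset) < MIN_CONSECUTIVE_HOURS:
                    reason = "insufficient_consecutive"
        if reason is None:
            keep_series.append(_trim_to_window(s))
            keep_profiles.append(p)
        else:
            report[reason] += 1
    report = {"n_input": cohort.n, "n_retained": len(keep_series),
              "excluded": report}
    return Cohort(keep_series, keep_profiles, cohort.channel_meta), report


# --------------------------------------------------------------------------
# Delimited-table interchange format
# --------------------------------------------------------------------------

def cohort_to_frames(cohort: Cohort):
    """Long observation table + one-row-per-patient static table."""
    rows = []
    for s in cohort.series:
        for i, t in enumerate(s.times):
            for j, name in enumerate(s.channel_names):
                if s.observed_mask[i, j]:
                    rows.append((s.patient_id, int(t), name, s.values[i, j]))
            rows.append((s.patient_id, int(t), "__label_aki__",
                         float(s.labels_aki[i])))
    long_df = pd.DataFrame(rows, columns=["patient_id", "hour", "variable",
                                          "value"])
    static_rows = []
    for s, p in zip(cohort.series, cohort.profiles):
        row = {"patient_id": p.patient_id, "age": p.age, "sex": p.sex,
               "weight_kg": s.weight_kg, "n_steps": s.T,
               "esrd_history": int(p.esrd_history),
               "dialysis_history": int(p.dialysis_history),
               "outcome_aki": p.outcome_aki,
               "outcome_recovery": p.outcome_recovery,
               "outcome_dialysis": p.outcome_dialysis}
        for k, v in p.comorbidities.items():
            row[f"cm_{k}"] = int(v)
        static_rows.append(row)
    return long_df, pd.DataFrame(static_rows)


def cohort_from_frames(long_df: pd.DataFrame, static_df: pd.DataFrame,
                       channel_meta: list) -> Cohort:
    names = [m.name for m in channel_meta]
    series, profiles = [], []
    static_df = static_df.set_index("patient_id")
    for pid, grp in long_df.groupby("patient_id", sort=True):
        T = int(grp["hour"].max())
        values = np.zeros((T, len(names)))
        mask = np.zeros((T, len(names)), dtype=bool)
        labels = np.zeros(T, dtype=int)
        for _, row in grp.iterrows():
            i = int(row["hour"]) - 1
            if row["variable"] == "__label_aki__":
                labels[i] = int(row["value"])
            elif row["variable"] in names:
                j = names.index(row["variable"])
                values[i, j] = row["value"]
                mask[i, j] = True
        meta = static_df.loc[pid]
        com = {c[3:]: int(meta[c]) for c in static_df.columns
               if c.startswith("cm_")}
        series.append(ClinicalSeries(str(pid), np.arange(1, T + 1), names,
                                     values, mask, labels,
                                     float(meta["weight_kg"])))
        profiles.append(StaticProfile(
            str(pid), float(meta["age"]), str(meta["sex"]), com,
            bool(meta["esrd_history"]), bool(meta["dialysis_history"]),
            int(meta["outcome_aki"]), int(meta["outcome_recovery"]),
            int(meta["outcome_dialysis"])))
    return Cohort(series, profiles, channel_meta)


def write_exclusion_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
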