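"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from chrononet.cohort import (
    CREATININE,
    URINE_OUTPUT,
    ChannelMeta,
    ClinicalSeries,
    KDIGOThresholds,
    StaticProfile,
)


def make_series(scr=None, urine=None, weight=70.0, T=None, patient_id="p0",
                scr_mask=None, urine_mask=None, extra=None, labels=None):
    """Build a two-channel (plus optional extras) hourly series by hand."""
    if T is None:
        T = len(scr) if scr is not None else len(urine)
    names = [CREATININE, URINE_OUTPUT]
    scr = np.full(T, 1.0) if scr is None else np.asarray(scr, dtype=float)
    urine = np.full(T, 70.0) if urine is None else np.asarray(urine, float)
    cols = [scr, urine]
    masks = [np.ones(T, bool) if scr_mask is None else np.asarray(scr_mask, bool),
             np.ones(T, bool) if urine_mask is None else np.asarray(urine_mask, bool)]
    if extra:
        for name, vals in extra.items():
            names.append(name)
            cols.append(np.asarray(vals, dtype=float))
            masks.append(np.ones(T, bool))
    return ClinicalSeries(patient_id, np.arange(1, T + 1), names,
                          np.column_stack(cols), np.column_stack(masks),
                          labels, weight)


def kdigo_oracle(series: ClinicalSeries,
                 thr: KDIGOThresholds = None) -> np.ndarray:
    """Exhaustive-enumeration KDIGO labeler (the independent oracle).

    Every (step, window-start) pair is enumerated explicitly; no incremental
    state is shared with the production labeler.
    """
    thr = thr or KDIGOThresholds()
    T = series.T
    scr = series.channel(CREATININE)
    scrm = series.channel_mask(CREATININE)
    urine = series.channel(URINE_OUTPUT)
    urm = series.channel_mask(URINE_OUTPUT)
    w = series.weight_kg
    y = np.zeros(T, dtype=int)
    for t in range(1, T + 1):
        fired = False
        tt = series.times[t - 1]
        if scrm[t - 1]:
            # (a) absolute rise within the delta window
            for s in range(1, t + 1):
                if series.times[s - 1] > tt - thr.delta_window and scrm[s - 1]:
                    if scr[t - 1] - scr[s - 1] >= thr.delta_scr:
                        fired = True
            # (b) fold change over the rolling 7-day baseline
            in_win = [scr[s - 1] for s in range(1, t + 1)
                      if scrm[s - 1] and series.times[s - 1] > tt - thr.ratio_window]
            if in_win:
                base = min(in_win)
            else:
                base = [scr[s - 1] for s in range(1, T + 1) if scrm[s - 1]][0]
            if scr[t - 1] >= thr.ratio_scr * base:
                fired = True
        # (c) oliguria run strictly longer than urine_duration ending at t
        run = 0
        for s in range(t, 0, -1):
            if urm[s - 1] and w > 0 and urine[s - 1] / w < thr.urine_rate:
                run += 1
            else:
                break
        if run > thr.urine_duration:
            fired = True
        y[t - 1] = int(fired)
    return y


def auc_bruteforce(scores, labels) -> float:
    """AUROC by explicit enumeration of all (positive, negative) pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return None
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def make_profile(pid="p0", age=50.0, **kw) -> StaticProfile:
    return StaticProfile(pid, age, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    from chrononet.simulate import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(n_patients=120, seed=42))


@pytest.fixture(scope="session")
def channel_meta_two():
    return [ChannelMeta(CREATININE, "continuous", essential=True),
            ChannelMeta(URINE_OUTPUT, "continuous", essential=True)]
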