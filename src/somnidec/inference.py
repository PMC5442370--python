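"""Permutation inference and the sliding-window accuracy time course.

Significance of decoding is assessed non-parametrically: condition labels
are re-drawn per subject (each subject's two nights randomly relabelled
face/house or house/face, preserving the paired design), the entire
two-step decoding pipeline is re-run on each relabelled cohort, and the
p-value is the fraction of null accuracies at or above the observed one.
With ``n_perm`` shuffles the smallest attainable p is ``1/n_perm``; when
no null value reaches the observed accuracy the result is reported as a
strict bound at that floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._rng import rng_for
from .decode import DecodeSettings, cross_validated_decode
from .preprocess import MIN_TRIALS, prepare_features
from .synthdata import SEGMENT_MIN, STAGE_GROUPS, CellFeatures, NightTrials


@dataclass
class NullDistribution:
    accuracies: np.ndarray
    observed: float
    p_value: float
    n_perm: int
    is_bound: bool                 # True when p is the strict floor 1/n_perm
    fingerprint: str


@dataclass
class TimeCourse:
    centres_min: np.ndarray        # window centre times from lights-off
    accuracy: np.ndarray           # NaN where the window failed inclusion
    n_subjects: np.ndarray
    stage: str
    width_min: float
    step_min: float


def min_attainable_p(n_perm: int) -> float:
    """Precision floor of a Monte-Carlo permutation p-value."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    return 1.0 / n_perm


def permute_labels(
    y: np.ndarray,
    subjects: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independently per subject, swap the two night labels with probability 1/2."""
    y = np.asarray(y, dtype=np.float64)
    out = y.copy()
    for s in np.unique(subjects):
        idx = np.flatnonzero(subjects == s)
        if idx.size != 2 or y[idx].sum() != 0.0:
            raise ValueError(f"subject {s} lacks a paired face/house night")
        if rng.random() < 0.5:
            out[idx] = -y[idx]
    return out


def permutation_test(
    cell: CellFeatures,
    settings: DecodeSettings,
    n_perm: int = 1001,
    seed: int = 0,
    enforce_min_subjects: bool = True,
) -> NullDistribution:
    """Label-permutation null for one analysis cell.

    The observed statistic and every null draw run the *identical* decoding
    configuration (same settings object, same fingerprint) so the null is
    exchangeable with the observed value under no-signal conditions.
    Identity relabellings are allowed draws (pure Monte-Carlo sampling of
    the per-subject swap group).
    """
    if n_perm < 19:
        warnings.warn(f"n_perm={n_perm} cannot reach alpha=0.05", stacklevel=2)
    observed = cross_validated_decode(
        cell, settings, seed=seed, enforce_min_subjects=enforce_min_subjects
    ).validation_accuracy
    rng = rng_for(seed, "perm", cell.stage, cell.segment)
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = permute_labels(cell.y, cell.subjects, rng)
        perm_cell = replace(cell, y=y_perm)
        null[i] = cross_validated_decode(
            perm_cell, settings, seed=seed, enforce_min_subjects=enforce_min_subjects
        ).validation_accuracy
    n_ge = int(np.sum(null >= observed - 1e-12))
    is_bound = n_ge == 0
    p = max(n_ge, 1) / n_perm
    return NullDistribution(
        accuracies=null, observed=float(observed), p_value=float(p),
        n_perm=n_perm, is_bound=is_bound, fingerprint=settings.fingerprint(),
    )


def holm_correct(p_values: np.ndarray) -> np.ndarray:
    """Step-down Holm adjustment over one family of p-values."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def sliding_window_timecourse(
    night_trials: list[NightTrials],
    stage: str,
    settings: DecodeSettings,
    width_min: float = 22.5,
    step_min: float = 4.5,
    night_duration_min: float | None = None,
    min_trials: int = max(1, MIN_TRIALS // 5),
    min_subjects: int = 11,
    seed: int = 0,
) -> TimeCourse:
    """Decode within a sliding window moved across the night.

    Trials are assigned to windows by onset; per window, each subject-night
    with at least ``min_trials`` trials of the stage group contributes one
    normalized+sharpened feature matrix, and the full two-step procedure
    runs on subjects with both nights present.  Windows failing inclusion
    are NaN (missing), not zero.
    """
    if width_min <= 0 or step_min <= 0:
        raise ValueError("width and step must be positive")
    members = set(STAGE_GROUPS.get(stage, (stage,)))
    if night_duration_min is None:
        night_duration_min = max(
            (nt.onsets.max() / 60.0 if nt.onsets.size else 0.0) for nt in night_trials
        )
    starts = np.arange(0.0, night_duration_min - width_min + 1e-9, step_min)
    centres = starts + width_min / 2.0

    acc = np.full(starts.size, np.nan)
    n_subj = np.zeros(starts.size, dtype=int)
    for w, start in enumerate(starts):
        feats, ys, subjs, nights = [], [], [], []
        for nt in night_trials:
            if nt.onsets.size == 0:
                continue
            sel = (
                np.isin(nt.stages, list(members))
                & (nt.onsets >= start * 60.0)
                & (nt.onsets < (start + width_min) * 60.0)
            )
            if int(sel.sum()) < min_trials:
                continue
            feats.append(nt.spectra[sel].mean(axis=0))
            ys.append(1.0 if nt.condition == "face" else -1.0)
            subjs.append(nt.subject)
            nights.append(nt.night)
        if not feats:
            continue
        subjs = np.array(subjs)
        paired = np.array([np.sum(subjs == s) == 2 for s in subjs])
        keep = np.flatnonzero(paired)
        uniq = np.unique(subjs[keep])
        n_subj[w] = uniq.size
        if uniq.size < max(min_subjects, settings.n_folds):
            continue
        X = np.stack([prepare_features(feats[i]) for i in keep])
        cell = CellFeatures(
            stage=stage, segment=w + 1, X=X,
            y=np.array([ys[i] for i in keep]),
            subjects=subjs[keep],
            nights=np.array([nights[i] for i in keep]),
            n_trials=np.full(keep.size, min_trials),
        )
        res = cross_validated_decode(cell, settings, seed=seed + w, enforce_min_subjects=False)
        acc[w] = res.validation_accuracy
    return TimeCourse(
        centres_min=centres, accuracy=acc, n_subjects=n_subj,
        stage=stage, width_min=width_min, step_min=step_min,
    )
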