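"""The two-step between-subject classifier.

Step one trains one linear SVM per group channel on that channel's 60
frequency bins, leave-one-subject-out within the training folds; each
channel's held-out accuracy becomes its weight.  Step two averages the
channels with those weights and trains the main linear SVM on the
resulting 60-dimensional vectors, evaluated on held-out subjects.  The
whole procedure is repeated over random subject-level 5-fold partitions;
both nights of a subject always share a fold, so train and validation
subject sets are disjoint in every evaluation.

Probability estimates come from Platt scaling fitted on training decision
values only; a night's "probability of correct class" is averaged over all
repetitions in which it sat in the validation fold.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from ._rng import rng_for
from ._svm import LinearSVM, platt_fit, platt_predict
from .synthdata import BANDS, FREQS, CellFeatures


@dataclass(frozen=True)
class DecodeSettings:
    """Everything that parametrizes one decoding run (shared with its null runs)."""

    n_reps: int = 20
    n_folds: int = 5
    cost: float = 1.0
    min_subjects: int = 11
    chance_subtract: bool = False

    def fingerprint(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


#: paper-scale repetition count, selected by the CLI ``--full`` flag
FULL_REPS = 280


@dataclass
class DecodingResult:
    stage: str
    segment: int
    validation_accuracy: float
    training_accuracy: float
    prob_correct: np.ndarray          # (n_nights,) mean P(true class) over reps
    subjects: np.ndarray
    nights: np.ndarray
    y: np.ndarray
    inner_weight_matrix: np.ndarray   # (n_groups, n_bins) mean |w| of channel SVMs
    outer_weights: np.ndarray         # (n_bins,) mean |w| of the main SVM
    n_subjects: int
    settings: DecodeSettings
    fingerprint: str = ""

    def __post_init__(self):
        if not self.fingerprint:
            self.fingerprint = self.settings.fingerprint()


def inner_channel_loop(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    cost: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-subject-out accuracy and mean |weights| per group channel.

    ``X`` is (n_nights, n_groups, n_bins); both nights of each subject are
    held out together.  Returns (accuracies (G,), mean absolute weight
    matrix (G, B)).
    """
    subj_u = np.unique(subjects)
    if subj_u.size < 3:
        raise ValueError("need at least 3 training subjects for the inner loop")
    n, G, B = X.shape
    acc = np.zeros(G)
    wabs = np.zeros((G, B))
    for g in range(G):
        Xg = np.ascontiguousarray(X[:, g, :])
        correct = 0
        total = 0
        n_fits = 0
        for s in subj_u:
            held = subjects == s
            y_tr = y[~held]
            if np.all(y_tr == y_tr[0]):
                raise RuntimeError("a class is absent from an inner training fold")
            m = LinearSVM(C=cost).fit(Xg[~held], y_tr)
            correct += int(np.sum(m.predict(Xg[held]) == y[held]))
            total += int(held.sum())
            wabs[g] += np.abs(m.coef_)
            n_fits += 1
        acc[g] = correct / total
        wabs[g] /= n_fits
    return acc, wabs


def weighted_channel_average(X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Accuracy-weighted average over group channels: (n, G, B) -> (n, B)."""
    w = np.asarray(weights, dtype=np.float64)
    if w.shape[0] != X.shape[-2]:
        raise ValueError("one weight per channel required")
    total = w.sum()
    if total <= 0:
        raise RuntimeError("channel weights sum to zero; cannot average")
    return np.tensordot(X, w, axes=([-2], [0])) / total


@dataclass
class MainModel:
    svm: LinearSVM
    platt: tuple[float, float]
    training_accuracy: float
    at_chance: bool = False

    def decision(self, Xw: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(Xw)

    def prob_face(self, Xw: np.ndarray) -> np.ndarray:
        return platt_predict(self.decision(Xw), *self.platt)


def train_main_classifier(Xw: np.ndarray, y: np.ndarray, cost: float = 1.0) -> MainModel:
    """Fit the main linear SVM on weighted channel averages, with calibration."""
    if np.all(y == y[0]):
        raise ValueError("both classes must be present")
    svm = LinearSVM(C=cost).fit(Xw, y)
    f = svm.decision_function(Xw)
    at_chance = bool(np.all(np.abs(f) < 1e-9))
    A, B = platt_fit(f, y)
    train_acc = float(np.mean(svm.predict(Xw) == y))
    return MainModel(svm=svm, platt=(A, B), training_accuracy=train_acc, at_chance=at_chance)


def _subject_folds(subjects_u: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random subject partition into k folds differing by at most one subject."""
    perm = rng.permutation(subjects_u)
    return [perm[i::k] for i in range(k)]


def cross_validated_decode(
    cell: CellFeatures,
    settings: DecodeSettings = DecodeSettings(),
    seed: int = 0,
    enforce_min_subjects: bool = True,
) -> DecodingResult:
    """Repeated subject-level k-fold cross-validation of the two-step classifier."""
    X, y, subjects = cell.X, cell.y, cell.subjects
    subj_u = np.unique(subjects)
    if enforce_min_subjects and subj_u.size < settings.min_subjects:
        raise ValueError(
            f"cell ({cell.stage}, {cell.segment}) has {subj_u.size} subjects "
            f"< min_subjects={settings.min_subjects}"
        )
    if subj_u.size < settings.n_folds:
        raise ValueError("fewer subjects than folds")
    rng = rng_for(seed, "cv", cell.stage, cell.segment)

    n = X.shape[0]
    val_correct = 0
    val_total = 0
    train_acc_sum = 0.0
    n_models = 0
    prob_sum = np.zeros(n)
    prob_cnt = np.zeros(n)
    inner_w = np.zeros(X.shape[1:])
    outer_w = np.zeros(X.shape[2])

    for _ in range(settings.n_reps):
        folds = _subject_folds(subj_u, settings.n_folds, rng)
        for fold_subjects in folds:
            val = np.isin(subjects, fold_subjects)
            if val.all() or not val.any():
                continue
            ch_acc, ch_w = inner_channel_loop(X[~val], y[~val], subjects[~val], cost=settings.cost)
            weights = ch_acc - 0.5 if settings.chance_subtract else ch_acc
            weights = np.clip(weights, 0.0, None)
            if weights.sum() <= 0:
                weights = np.ones_like(weights)
            model = train_main_classifier(
                weighted_channel_average(X[~val], weights), y[~val], cost=settings.cost
            )
            Xw_val = weighted_channel_average(X[val], weights)
            pred = model.svm.predict(Xw_val)
            val_correct += int(np.sum(pred == y[val]))
            val_total += int(val.sum())
            p_face = model.prob_face(Xw_val)
            p_correct = np.where(y[val] > 0, p_face, 1.0 - p_face)
            prob_sum[val] += p_correct
            prob_cnt[val] += 1.0
            train_acc_sum += model.training_accuracy
            inner_w += ch_w
            outer_w += np.abs(model.svm.coef_)
            n_models += 1

    return DecodingResult(
        stage=cell.stage,
        segment=cell.segment,
        validation_accuracy=val_correct / val_total,
        training_accuracy=train_acc_sum / n_models,
        prob_correct=np.divide(prob_sum, prob_cnt, out=np.full(n, np.nan), where=prob_cnt > 0),
        subjects=subjects.copy(),
        nights=cell.nights.copy(),
        y=y.copy(),
        inner_weight_matrix=inner_w / n_models,
        outer_weights=outer_w / n_models,
        n_subjects=subj_u.size,
        settings=settings,
    )


def feature_weight_maps(
    result: DecodingResult,
    bands: dict[str, tuple[float, float]] | None = None,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Frequency profile and band topographies from the inner weight matrix.

    Profile: mean |weight| over channels per frequency bin.  Topography:
    per named band, mean |weight| per channel over that band's bins
    (delta 0.5-3.5, theta 4-7.5, alpha 8-10.5, spindle 11-15.5,
    beta 16-30 Hz by default).
    """
    W = np.abs(result.inner_weight_matrix)
    f = FREQS if freqs is None else np.asarray(freqs)
    if W.shape[1] != f.size:
        raise ValueError("weight matrix and frequency grid disagree")
    bands = BANDS if bands is None else bands
    profile = W.mean(axis=0)
    topo = {}
    for name, (lo, hi) in bands.items():
        if lo < f[0] or hi > f[-1]:
            raise ValueError(f"band {name} outside {f[0]}-{f[-1]} Hz")
        m = (f >= lo - 1e-9) & (f <= hi + 1e-9)
        topo[name] = W[:, m].mean(axis=1)
    return profile, topo
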