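"""From raw recordings to normalized, sharpened spectral feature matrices.

The fixed preparation order is: cut 4-s trials -> artefact mask ->
Welch spectra (2-s Hamming windows, 95% overlap, 0.5-30 Hz in 0.5 Hz bins)
-> spatial average onto 32 group channels -> per-(stage, 90-min segment)
trial average -> per-channel min-max normalization -> spectral sharpening.
Each included subject-night then contributes exactly one
(groups x bins) feature matrix per analysis cell, regardless of how many
artefact-free trials it had, which keeps the between-subject classifier
unbiased by data quantity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .montage import Montage
from .synthdata import EPOCH_S, SEGMENT_MIN, STAGE_GROUPS, TRIAL_S, Hypnogram, Recording

logger = logging.getLogger(__name__)

#: inclusion thresholds quoted with the analysis: a subject-night enters a
#: cell only with >= 40 artefact-free trials (160 s of data); a cell is only
#: analysed with >= 11 qualifying subjects.
MIN_TRIALS = 40
MIN_SUBJECTS = 11


# ---------------------------------------------------------------------------
# trials

def epoch_and_label(
    recording: Recording | np.ndarray,
    hypnogram: Hypnogram,
    trial_s: float = TRIAL_S,
    segment_min: float = SEGMENT_MIN,
) -> pd.DataFrame:
    """Cut non-overlapping 4-s trials and label stage and 90-min segment.

    Trials are cut within each 30-s scoring epoch (7 whole trials fit, the
    2-s remainder is dropped), inherit that epoch's stage, and get the
    1-based segment of their onset counted from lights-off.  Trials beyond
    the last complete 90-min segment get segment -1 and are excluded from
    segment-based analyses.
    """
    sig = recording.signal if isinstance(recording, Recording) else np.asarray(recording)
    fs = recording.sampling_rate if isinstance(recording, Recording) else None
    n_samples = sig.shape[-1]
    per_epoch = int(hypnogram.epoch_s // trial_s)
    n_full_seg = int(hypnogram.duration_min // segment_min)
    rows = []
    trial = 0
    for i, stage in enumerate(hypnogram.stages):
        epoch_onset = i * hypnogram.epoch_s
        if fs is not None and (epoch_onset + hypnogram.epoch_s) * fs > n_samples + 1e-6:
            break
        for t in range(per_epoch):
            onset = epoch_onset + t * trial_s
            seg = int(onset // (segment_min * 60.0)) + 1
            rows.append({
                "trial": trial, "onset_s": onset, "stage": stage,
                "segment": seg if seg <= n_full_seg else -1,
            })
            trial += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# artefact detection

@dataclass
class ArtefactMask:
    trial_channel: np.ndarray      # (n_trials, n_channels) bool
    bad_channels: np.ndarray       # (n_channels,) bool
    trial_rejected: np.ndarray     # (n_trials,) bool


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale < 1e-12:
        scale = np.std(x) + 1e-12
    return (x - med) / scale


def detect_artefacts(
    recording: Recording,
    trials: pd.DataFrame,
    mad_k: float = 5.0,
    channel_bad_fraction: float = 0.2,
    trial_s: float = TRIAL_S,
) -> ArtefactMask:
    """Flag trials/channels with the three spectral-outlier criteria.

    Per (trial, channel) statistics: log overall power (disconnected
    electrodes), log maximal sample-to-sample amplitude change (jumps), and
    log 110-140 Hz power (muscle; skipped with a warning when the sampling
    rate cannot represent that band).  Values beyond ``mad_k`` robust
    standard deviations (median +/- k * 1.4826 MAD) are flagged; channels
    flagged in more than ``channel_bad_fraction`` of trials are marked bad
    as a whole.
    """
    fs = recording.sampling_rate
    sig = recording.signal
    spt = int(trial_s * fs)
    n_trials = len(trials)
    onsets = (trials["onset_s"].to_numpy() * fs).round().astype(int)
    seg = np.stack([sig[:, o: o + spt] for o in onsets], axis=0)  # (T, C, spt)
    seg = seg.astype(np.float64)

    log_power = np.log(np.var(seg, axis=2) + 1e-12)
    log_jump = np.log(np.max(np.abs(np.diff(seg, axis=2)), axis=2) + 1e-12)
    stats = [log_power, log_jump]
    two_sided = [True, False]
    if fs >= 280.0:
        spec = np.abs(np.fft.rfft(seg, axis=2)) ** 2
        f = np.fft.rfftfreq(spt, 1.0 / fs)
        band = (f >= 110.0) & (f <= 140.0)
        stats.append(np.log(spec[:, :, band].sum(axis=2) + 1e-12))
        two_sided.append(False)
    else:
        warnings.warn(
            f"sampling rate {fs} Hz cannot represent the 110-140 Hz muscle band; "
            "muscle criterion skipped", stacklevel=2,
        )

    mask = np.zeros_like(log_power, dtype=bool)
    for x, ts in zip(stats, two_sided):
        z = _robust_z(x.ravel()).reshape(x.shape)
        mask |= (np.abs(z) > mad_k) if ts else (z > mad_k)

    bad_channels = mask.mean(axis=0) > channel_bad_fraction
    trial_rejected = mask[:, ~bad_channels].any(axis=1) if (~bad_channels).any() else np.ones(n_trials, bool)
    if trial_rejected.all():
        raise RuntimeError(
            "artefact detection rejected every trial; check thresholds "
            f"(mad_k={mad_k}) and the recording"
        )
    logger.info(
        "artefact detection: %d/%d trials rejected, %d/%d channels bad",
        int(trial_rejected.sum()), n_trials, int(bad_channels.sum()), sig.shape[0],
    )
    return ArtefactMask(trial_channel=mask, bad_channels=bad_channels, trial_rejected=trial_rejected)


def interpolate_bad_channels(
    recording: Recording,
    bad_channels: np.ndarray,
    montage: Montage,
) -> tuple[Recording, list[int]]:
    """Replace bad channels by inverse-distance-weighted good neighbours.

    Neighbours are good electrodes within twice the grouping radius; a bad
    channel with fewer than three of them cannot be interpolated and is
    returned in the excluded list (its group simply loses a member).
    """
    from dataclasses import replace as _replace

    bad = np.asarray(bad_channels, dtype=bool)
    sig = recording.signal.copy()
    pos = montage.electrode_pos
    excluded: list[int] = []
    for c in np.flatnonzero(bad):
        d = np.linalg.norm(pos - pos[c], axis=1)
        nb = np.flatnonzero((d <= 2.0 * montage.radius) & ~bad & (d > 0))
        if nb.size < 3:
            excluded.append(int(c))
            logger.info("channel %d isolated; excluded instead of interpolated", c)
            continue
        w = 1.0 / (d[nb] + 1e-9)
        sig[c] = (w[:, None] * sig[nb]).sum(axis=0) / w.sum()
    return _replace(recording, signal=sig), excluded


# ---------------------------------------------------------------------------
# spectra

def welch_psd(
    x: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap: float = 0.95,
    fmax: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with Hamming windows; bins at 0.5 Hz up to ``fmax``.

    ``x`` may be (..., n_samples).  All full windows at the given overlap
    are averaged; the 0 Hz bin is discarded, leaving 60 bins for the
    default 2-s window and 30 Hz ceiling.
    """
    x = np.asarray(x)
    nperseg = int(round(window_s * fs))
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    if nperseg > x.shape[-1]:
        raise ValueError("window longer than the signal")
    noverlap = int(np.floor(overlap * nperseg))
    f, p = sps.welch(
        x, fs=fs, window="hamming", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", axis=-1,
    )
    keep = (f > 0) & (f <= fmax + 1e-9)
    return f[keep], p[..., keep]


def spatial_average(
    trial_psd: np.ndarray,
    montage: Montage,
    bad_channels: np.ndarray | None = None,
) -> np.ndarray:
    """Average electrode spectra onto group channels.

    ``trial_psd`` is (..., n_electrodes, n_bins); returns
    (..., n_groups, n_bins).  Bad electrodes are dropped from their groups;
    a group left without members becomes NaN (missing) so the subject-night
    can be excluded from cells that need it.
    """
    bad = np.zeros(montage.n_electrodes, bool) if bad_channels is None else np.asarray(bad_channels, bool)
    out = np.full(trial_psd.shape[:-2] + (montage.n_groups, trial_psd.shape[-1]), np.nan)
    for g, members in enumerate(montage.membership):
        good = members[~bad[members]]
        if good.size == 0:
            logger.info("group %s has no good member electrodes; marked missing", montage.group_names[g])
            continue
        out[..., g, :] = trial_psd[..., good, :].mean(axis=-2)
    return out


def aggregate_cell(
    group_spectra: np.ndarray,
    trials: pd.DataFrame,
    trial_rejected: np.ndarray,
    stage_group: str,
    segment: int,
    min_trials: int = MIN_TRIALS,
    stage_members: tuple[str, ...] | None = None,
) -> tuple[np.ndarray | None, int]:
    """Mean spectrum over artefact-free trials of one (stage, segment) cell.

    Returns ``(None, n)`` when fewer than ``min_trials`` clean trials are
    available (the subject-night is then excluded from this cell).
    """
    members = stage_members or STAGE_GROUPS[stage_group]
    sel = (
        trials["stage"].isin(members).to_numpy()
        & (trials["segment"].to_numpy() == segment)
        & ~np.asarray(trial_rejected)
    )
    n = int(sel.sum())
    if n < min_trials:
        logger.info("cell (%s, %d): %d < %d clean trials; excluded", stage_group, segment, n, min_trials)
        return None, n
    return group_spectra[sel].mean(axis=0), n


# ---------------------------------------------------------------------------
# normalization and sharpening

def normalize_channels(spectrum: np.ndarray) -> np.ndarray:
    """Min-max normalize each channel's spectrum to [0, 1] over its bins.

    A constant channel (max == min) maps to all zeros with a warning.
    """
    x = np.asarray(spectrum, dtype=np.float64)
    lo = x.min(axis=-1, keepdims=True)
    hi = x.max(axis=-1, keepdims=True)
    rng = hi - lo
    flat = rng[..., 0] < 1e-300
    if np.any(flat):
        warnings.warn("constant channel(s) normalized to all zeros", stacklevel=2)
    rng = np.where(rng == 0.0, 1.0, rng)
    return (x - lo) / rng


def sharpen_spectrum(spectrum: np.ndarray, half_width: int = 3) -> np.ndarray:
    """Subtract the mean of the six neighbouring bins (3 per side) from each bin.

    The moving-average baseline excludes the centre bin and is truncated at
    the spectrum edges; output values may be negative.  Removes the common
    baseline spectrum and accentuates narrow-band deviations.
    """
    x = np.asarray(spectrum, dtype=np.float64)
    if x.shape[-1] < 2 * half_width + 1:
        raise ValueError("spectrum too short for the sharpening window")
    kernel = np.ones(2 * half_width + 1)
    flat = x.reshape(-1, x.shape[-1])
    sums = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, flat)
    counts = np.convolve(np.ones(x.shape[-1]), kernel, mode="same")
    neigh_mean = (sums - flat) / (counts - 1.0)[None, :]
    return (flat - neigh_mean).reshape(x.shape)


def prepare_features(mean_spectrum: np.ndarray, half_width: int = 3) -> np.ndarray:
    """Canonical normalize-then-sharpen feature preparation."""
    return sharpen_spectrum(normalize_channels(mean_spectrum), half_width=half_width)


# ---------------------------------------------------------------------------
# whole-night driver

def process_night(
    recording: Recording,
    hypnogram: Hypnogram,
    montage: Montage,
    mad_k: float = 5.0,
    min_trials: int = MIN_TRIALS,
    sws_mode: str = "s3s4",
) -> dict[tuple[str, int], tuple[np.ndarray, int]]:
    """Full raw-signal chain for one night.

    Returns, per (stage-group, segment) cell, the *raw* (groups x bins)
    mean power matrix and the clean-trial count.  Normalization and
    sharpening are applied downstream (:func:`prepare_features`) so the
    store keeps physical units.
    """
    stage_groups = dict(STAGE_GROUPS)
    if sws_mode == "s4":
        stage_groups["SWS"] = ("S4",)
    trials = epoch_and_label(recording, hypnogram)
    mask = detect_artefacts(recording, trials, mad_k=mad_k)
    rec_i, excluded = interpolate_bad_channels(recording, mask.bad_channels, montage)
    still_bad = np.zeros(montage.n_electrodes, bool)
    still_bad[excluded] = True

    fs = recording.sampling_rate
    spt = int(TRIAL_S * fs)
    onsets = (trials["onset_s"].to_numpy() * fs).round().astype(int)
    seg = np.stack([rec_i.signal[:, o: o + spt] for o in onsets], axis=0).astype(np.float64)
    _, psd = welch_psd(seg, fs)
    group_psd = spatial_average(psd, montage, still_bad)

    n_full_seg = int(hypnogram.duration_min // SEGMENT_MIN)
    out = {}
    for sg, members in stage_groups.items():
        for segment in range(1, n_full_seg + 1):
            mean, n = aggregate_cell(
                group_psd, trials, mask.trial_rejected, sg, segment,
                min_trials=min_trials, stage_members=members,
            )
            if mean is not None:
                out[(sg, segment)] = (mean, n)
    return out
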