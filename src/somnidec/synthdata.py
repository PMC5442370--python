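"""Synthetic sleep-EEG cohorts with known ground truth.

The generator emulates the statistical structure the decoding analysis
assumes: two nights per subject (one per learned-material condition, face
vs house, counterbalanced), 90-min sleep cycles with stage-dependent power
spectra (delta-dominant deep NREM, a ~13 Hz spindle peak in S2/SWS, a ~6 Hz
theta bump in REM), a condition-specific multiplicative spectral signature
confined to configurable (channel-group x frequency-band) cells, stages and
90-min segments, artefact contamination of known location, and recognition
behaviour whose overnight change is linearly coupled to the realized
signature strength.

Two levels of realism are available:

* a full time-domain path (:func:`synthesize_recording`,
  :func:`inject_artefacts`) that emits spectrally shaped noise per 30-s
  epoch, for testing the raw-signal preprocessing chain; and
* a feature-level path (:func:`simulate_cells`,
  :func:`simulate_night_trials`) that draws per-trial Welch-like spectra
  directly around the stage templates.  The per-cell mean of ``n``
  independent Gamma(k)-noise trials is itself Gamma(nk)-distributed, so
  cell averages are drawn exactly in O(channels x bins) without
  materializing trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import rng_for
from .montage import GROUP_NAMES

STAGES: tuple[str, ...] = ("W", "S1", "S2", "S3", "S4", "REM", "MT")

#: canonical 0.5 Hz analysis grid, 0.5-30 Hz inclusive (60 bins)
FREQS: np.ndarray = np.round(np.arange(1, 61) * 0.5, 1)

#: frequency bands used for weight topographies and signature placement
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 3.5),
    "theta": (4.0, 7.5),
    "alpha": (8.0, 10.5),
    "spindle": (11.0, 15.5),
    "beta": (16.0, 30.0),
}

EPOCH_S = 30.0
TRIAL_S = 4.0
SEGMENT_MIN = 90.0

#: sleep stages pooled per analysis stage-group (SWS = S3 + S4)
STAGE_GROUPS: dict[str, tuple[str, ...]] = {
    "S2": ("S2",),
    "SWS": ("S3", "S4"),
    "REM": ("REM",),
}


def band_mask(band: str | tuple[float, float], freqs: np.ndarray = FREQS) -> np.ndarray:
    lo, hi = BANDS[band] if isinstance(band, str) else band
    if lo < freqs[0] or hi > freqs[-1]:
        raise ValueError(f"band {band} outside {freqs[0]}-{freqs[-1]} Hz")
    return (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of a simulated cohort.

    ``signature_amplitude`` scales the multiplicative condition signature:
    power in the signature cells is multiplied by ``1 + s*a`` with ``s=+1``
    for the face night and ``-1`` for the house night.  ``behaviour_link``
    is the slope (d-prime units per unit realized amplitude) coupling
    overnight consolidation to each night's realized signature strength.
    """

    n_subjects: int = 32
    sampling_rate: float = 250.0
    n_raw_channels: int = 128
    night_duration_min: float = 480.0
    n_groups: int = 32
    n_bins: int = 60
    signature_amplitude: float = 0.3
    signature_cells: tuple[tuple[str | int, str], ...] = (("CP4", "spindle"),)
    signature_segments: tuple[int, ...] = (2,)
    signature_stages: tuple[str, ...] = ("S2", "S3", "S4")
    signature_mode: str = "multiplicative"     # or "additive"
    artefact_rates: Mapping[str, float] = field(
        default_factory=lambda: {"disconnect": 0.01, "jump": 0.01, "muscle": 0.02}
    )
    trial_loss_rate: float = 0.05              # fraction of trials lost to artefacts
    behaviour_link: float = 1.0
    behaviour_noise_sd: float = 0.3
    behaviour_intercept: float = 0.0
    n_old: int = 100
    n_new: int = 50
    subject_band_sigma: float = 0.1            # log-normal per-band subject gain
    subject_amplitude_sigma: float = 0.3       # log-normal per-night amplitude jitter
    channel_gain_sigma: float = 0.05           # log-normal per-night per-group gain
    trial_noise_shape: float = 18.0            # Gamma shape of per-trial spectral noise
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.signature_amplitude < 0:
            raise ValueError("signature_amplitude must be >= 0")
        if not all(0.0 <= r <= 1.0 for r in self.artefact_rates.values()):
            raise ValueError("artefact rates must lie in [0, 1]")
        if not 0.0 <= self.trial_loss_rate <= 1.0:
            raise ValueError("trial_loss_rate must lie in [0, 1]")
        if not np.isfinite(self.behaviour_link):
            raise ValueError("behaviour_link must be finite")
        if self.signature_mode not in ("multiplicative", "additive"):
            raise ValueError("signature_mode must be multiplicative or additive")
        if self.night_duration_min <= 0:
            raise ValueError("night_duration_min must be positive")

    @property
    def freqs(self) -> np.ndarray:
        if self.n_bins == len(FREQS):
            return FREQS
        return np.linspace(FREQS[0], FREQS[-1], self.n_bins)

    @property
    def group_names(self) -> list[str]:
        return [GROUP_NAMES[i] if i < len(GROUP_NAMES) else f"G{i}" for i in range(self.n_groups)]

    @property
    def n_segments(self) -> int:
        return int(self.night_duration_min // SEGMENT_MIN)


@dataclass
class Hypnogram:
    """Per-30-s-epoch stage labels for one night, from lights-off."""

    stages: list[str]
    epoch_s: float = EPOCH_S

    def __post_init__(self):
        bad = sorted(set(self.stages) - set(STAGES))
        if bad:
            raise ValueError(f"unknown stage labels: {bad}")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration_min(self) -> float:
        return len(self.stages) * self.epoch_s / 60.0

    def segment_of_epoch(self, i: int) -> int:
        """1-based 90-min segment of epoch ``i``; -1 beyond the last full segment."""
        seg = int(i * self.epoch_s // (SEGMENT_MIN * 60.0)) + 1
        return seg if seg <= int(self.duration_min // SEGMENT_MIN) else -1


@dataclass
class Recording:
    """Multichannel time series for one subject-night (microvolts)."""

    signal: np.ndarray                 # (n_channels, n_samples), float32
    sampling_rate: float
    subject_id: int
    night_index: int
    condition: str                     # "face" | "house"
    montage_id: str = "synthetic"

    def __post_init__(self):
        if self.condition not in ("face", "house"):
            raise ValueError("condition must be face or house")


@dataclass
class ArtefactTruth:
    """Ground-truth locations of injected artefacts."""

    trial_channel: np.ndarray          # (n_trials, n_channels) bool
    bad_channels: np.ndarray           # (n_channels,) bool
    kinds: dict[str, list]             # per type, injected (trial, channel) pairs


# ---------------------------------------------------------------------------
# hypnograms

# per-cycle stage block template: (stage, minutes); deep sleep shrinks and REM
# grows across the night, as in healthy adult sleep architecture
def _cycle_template(cycle: int) -> list[tuple[str, float]]:
    w = 4.0 if cycle == 0 else 0.0
    s4 = max(3.0, 22.0 - 6.0 * cycle)
    s3 = max(3.0, 10.0 - 2.0 * cycle)
    rem = min(30.0, 9.0 + 5.0 * cycle)
    s2 = 90.0 - (w + 4.0 + s3 + s4 + 2.0 + rem)
    return [
        ("W", w),
        ("S1", 4.0),
        ("S2", s2 * 0.6),
        ("S3", s3),
        ("S4", s4),
        ("S3", 2.0),
        ("S2", s2 * 0.4),
        ("REM", rem),
    ]


def generate_hypnogram(duration_min: float, seed: int | np.random.Generator = 0) -> Hypnogram:
    """A hypnogram following a cyclic 90-min template with mild jitter.

    Every full 90-min segment contains S2, SWS (S3/S4) and REM epochs.
    """
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    n_epochs_total = duration_min * 60.0 / EPOCH_S
    if abs(n_epochs_total - round(n_epochs_total)) > 1e-9:
        raise ValueError("duration must be a multiple of 30 s")
    n_epochs_total = int(round(n_epochs_total))
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, "hypnogram")
    epochs_per_cycle = int(SEGMENT_MIN * 60 / EPOCH_S)   # 180

    stages: list[str] = []
    cycle = 0
    while len(stages) < n_epochs_total:
        blocks = _cycle_template(cycle)
        counts = []
        for stage, minutes in blocks:
            if minutes <= 0:
                counts.append(0)
                continue
            jit = float(rng.uniform(0.85, 1.15))
            counts.append(max(2, int(round(minutes * jit * 60 / EPOCH_S))))
        # force the cycle to exactly 180 epochs by adjusting the largest S2 block
        excess = sum(counts) - epochs_per_cycle
        s2_idx = max(
            (i for i, (s, _) in enumerate(blocks) if s == "S2"), key=lambda i: counts[i]
        )
        counts[s2_idx] = max(2, counts[s2_idx] - excess)
        excess = sum(counts) - epochs_per_cycle
        if excess != 0:  # still off (tiny cycles): trim/pad the final REM block
            counts[-1] = max(2, counts[-1] - excess)
            counts[-1] -= sum(counts) - epochs_per_cycle
        for (stage, _), c in zip(blocks, counts):
            stages.extend([stage] * c)
        cycle += 1
    return Hypnogram(stages=stages[:n_epochs_total])


# ---------------------------------------------------------------------------
# spectral templates

# stage -> (delta amp, theta amp, alpha amp, spindle amp); Gaussian peak
# heights in uV^2/Hz on top of the common 1/f background
_STAGE_PEAKS: dict[str, tuple[float, float, float, float]] = {
    "W":   (5.0,  0.0, 8.0, 0.0),
    "S1":  (10.0, 3.0, 1.0, 0.0),
    "S2":  (40.0, 2.0, 0.0, 10.0),
    "S3":  (120.0, 2.0, 0.0, 6.0),
    "S4":  (200.0, 2.0, 0.0, 4.0),
    "REM": (12.0, 6.0, 1.0, 0.0),
    "MT":  (30.0, 5.0, 5.0, 3.0),
}
_PEAK_FREQ = {"delta": 1.5, "theta": 6.0, "alpha": 10.0, "spindle": 13.0}
_PEAK_WIDTH = {"delta": 1.0, "theta": 1.5, "alpha": 1.2, "spindle": 1.2}


def stage_spectrum_template(
    stage: str,
    subject_offsets: Mapping[str, float] | None = None,
    freqs: np.ndarray = FREQS,
) -> np.ndarray:
    """Power spectral density template for a sleep stage (uV^2/Hz).

    1/f background plus stage-dependent Gaussian peaks; ``subject_offsets``
    maps band names to multiplicative gains modelling stable between-subject
    spectral differences.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    f = np.asarray(freqs, dtype=np.float64)
    psd = 60.0 / f**1.3
    d, t, a, s = _STAGE_PEAKS[stage]
    for amp, band in ((d, "delta"), (t, "theta"), (a, "alpha"), (s, "spindle")):
        if amp > 0:
            psd = psd + amp * np.exp(-0.5 * ((f - _PEAK_FREQ[band]) / _PEAK_WIDTH[band]) ** 2)
    if subject_offsets:
        for band, gain in subject_offsets.items():
            psd = np.where(band_mask(band, f), psd * gain, psd)
    return psd


def subject_band_offsets(rng: np.random.Generator, sigma: float) -> dict[str, float]:
    return {b: float(np.exp(rng.normal(0.0, sigma))) for b in BANDS}


def subject_group_band_gains(
    rng: np.random.Generator, sigma: float, n_groups: int
) -> dict[str, np.ndarray]:
    """Stable per-subject spectral gains, drawn per (channel group, band).

    Between-subject spectral differences in real EEG are regional, not
    global, so the log-normal band gains vary independently across the 32
    group channels; this is the between-subject variance the classifier
    must overcome.
    """
    return {b: np.exp(rng.normal(0.0, sigma, size=n_groups)) for b in BANDS}


# ---------------------------------------------------------------------------
# condition signature

def _resolve_group(g: str | int, group_names: Sequence[str]) -> int:
    if isinstance(g, (int, np.integer)):
        return int(g)
    return list(group_names).index(g)


def embed_condition_signature(
    spectra: Mapping[tuple[str, int], np.ndarray],
    config: SimConfig,
    condition: str,
    amplitude: float | None = None,
) -> dict[tuple[str, int], np.ndarray]:
    """Apply the condition-specific perturbation to per-(stage, segment) spectra.

    ``spectra`` maps ``(stage, segment)`` to a (n_groups, n_bins) power
    array.  Cells listed in ``config.signature_cells`` are scaled by
    ``1 + s*amplitude`` (``s``: +1 face, -1 house) in the configured stages
    and segments only; everything else is returned unchanged.
    """
    if condition not in ("face", "house"):
        raise ValueError("condition must be face or house")
    a = config.signature_amplitude if amplitude is None else float(amplitude)
    if a < 0:
        raise ValueError("amplitude must be >= 0")
    s = 1.0 if condition == "face" else -1.0
    freqs = config.freqs
    out: dict[tuple[str, int], np.ndarray] = {}
    for (stage, segment), arr in spectra.items():
        arr = np.array(arr, dtype=np.float64, copy=True)
        if a > 0 and stage in config.signature_stages and segment in config.signature_segments:
            for g, band in config.signature_cells:
                gi = _resolve_group(g, config.group_names)
                m = band_mask(band, freqs)
                if config.signature_mode == "multiplicative":
                    arr[gi, m] *= 1.0 + s * a
                else:
                    arr[gi, m] += s * a * float(np.median(arr[gi, m]))
        out[(stage, segment)] = arr
    return out


# ---------------------------------------------------------------------------
# time-domain synthesis

def _interp_psd(template: np.ndarray, tfreqs: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Extend a 0.5-30 Hz template to arbitrary FFT frequencies."""
    psd = np.interp(f, tfreqs, template, left=template[0], right=np.nan)
    hi = f > tfreqs[-1]
    if np.any(hi):  # continue the 1/f tail above the analysis ceiling
        psd[hi] = template[-1] * (tfreqs[-1] / f[hi]) ** 1.3
    psd[f == 0] = 0.0
    return psd


def synthesize_recording(
    hypnogram: Hypnogram,
    stage_spectra: Mapping[str, np.ndarray],
    config: SimConfig,
    seed: int | np.random.Generator = 0,
    freqs: np.ndarray | None = None,
    subject_id: int = 0,
    night_index: int = 0,
    condition: str = "face",
) -> Recording:
    """Emit spectrally shaped Gaussian noise following the hypnogram.

    ``stage_spectra`` maps each stage present in the hypnogram to a
    (n_channels, n_bins) PSD array (uV^2/Hz on the ``freqs`` grid).  Each
    30-s epoch is synthesized in the frequency domain with the exact
    expected periodogram and epochs are joined with a 0.5-s equal-power
    crossfade.
    """
    if len(hypnogram) == 0:
        raise ValueError("empty hypnogram")
    missing = sorted(set(hypnogram.stages) - set(stage_spectra))
    if missing:
        raise ValueError(f"no spectrum for stages {missing}")
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, "recording", subject_id, night_index)
    fs = config.sampling_rate
    tfreqs = config.freqs if freqs is None else np.asarray(freqs)
    n_ep = int(round(hypnogram.epoch_s * fs))
    n_fade = int(round(0.5 * fs))
    n_chan = next(iter(stage_spectra.values())).shape[0]
    n_total = len(hypnogram) * n_ep
    out = np.zeros((n_chan, n_total + n_fade), dtype=np.float32)

    n_seg = n_ep + n_fade
    f_fft = np.fft.rfftfreq(n_seg, d=1.0 / fs)
    # amplitude scaling: E[|X_k|^2] * 2 / (fs * n) = PSD  (one-sided)
    scale = {
        st: np.sqrt(
            np.stack([
                _interp_psd(np.asarray(row, dtype=np.float64), tfreqs, f_fft)
                for row in np.atleast_2d(spec)
            ]) * fs * n_seg / 2.0
        )
        for st, spec in stage_spectra.items()
    }
    ramp_up = np.sin(0.5 * np.pi * np.arange(n_fade) / n_fade) if n_fade else np.empty(0)
    for i, stage in enumerate(hypnogram.stages):
        re = rng.normal(size=(n_chan, f_fft.size))
        im = rng.normal(size=(n_chan, f_fft.size))
        spec = scale[stage] * (re + 1j * im) / np.sqrt(2.0)
        spec[:, 0] = 0.0
        spec[:, -1] = spec[:, -1].real * np.sqrt(2.0)
        x = np.fft.irfft(spec, n=n_seg, axis=1) * np.sqrt(1.0)
        if n_fade:
            w = np.ones(n_seg)
            w[:n_fade] = ramp_up
            w[-n_fade:] = np.sqrt(np.clip(1.0 - ramp_up**2, 0.0, 1.0))
            if i == 0:
                w[:n_fade] = 1.0
            x = x * w[None, :]
        out[:, i * n_ep: i * n_ep + n_seg] += x.astype(np.float32)
    return Recording(
        signal=out[:, :n_total],
        sampling_rate=fs,
        subject_id=subject_id,
        night_index=night_index,
        condition=condition,
    )


def raw_channel_spectra(
    config: SimConfig,
    group_spectra: Mapping[str, np.ndarray],
    group_of_electrode: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Expand per-group stage spectra to raw channels with per-channel gains."""
    n_chan = group_of_electrode.size
    gains = np.exp(rng.normal(0.0, config.channel_gain_sigma, size=n_chan))
    return {
        st: np.asarray(spec)[group_of_electrode, :] * gains[:, None]
        for st, spec in group_spectra.items()
    }


def trial_onsets(n_samples: int, fs: float, trial_s: float = TRIAL_S, epoch_s: float = EPOCH_S) -> np.ndarray:
    """Onset samples of the non-overlapping 4-s trials cut within 30-s epochs.

    The same grid the preprocessing stage uses (7 whole trials per epoch,
    remainder dropped), so injected-artefact truth masks align with
    detector output.
    """
    spe = int(round(epoch_s * fs))
    spt = int(round(trial_s * fs))
    per_epoch = int(epoch_s // trial_s)
    n_epochs = int(n_samples // spe)
    return np.array([e * spe + t * spt for e in range(n_epochs) for t in range(per_epoch)])


def inject_artefacts(
    recording: Recording,
    artefact_rates: Mapping[str, float],
    seed: int | np.random.Generator = 0,
    trial_s: float = TRIAL_S,
) -> tuple[Recording, ArtefactTruth]:
    """Contaminate a recording with the three artefact types the detector targets.

    Disconnections (flat or hugely noisy whole channels), step discontinuities
    in single trials, and 110-140 Hz muscle bursts (only representable when
    the sampling rate exceeds 280 Hz).  Returns the contaminated copy plus a
    ground-truth (trial, channel) mask.
    """
    if not all(0.0 <= r <= 1.0 for r in artefact_rates.values()):
        raise ValueError("rates must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, "artefacts")
    fs = recording.sampling_rate
    sig = recording.signal.astype(np.float64, copy=True)
    n_chan, n_samp = sig.shape
    onsets = trial_onsets(n_samp, fs, trial_s)
    n_trial = onsets.size
    spt = int(trial_s * fs)
    mask = np.zeros((n_trial, n_chan), dtype=bool)
    bad = np.zeros(n_chan, dtype=bool)
    kinds: dict[str, list] = {"disconnect": [], "jump": [], "muscle": []}
    ch_sd = np.std(sig, axis=1) + 1e-12

    for c in range(n_chan):
        if rng.random() < artefact_rates.get("disconnect", 0.0):
            if rng.random() < 0.5:
                sig[c] *= 1e-3                      # dangling, near-flat
            else:
                sig[c] += rng.normal(0.0, 25.0 * ch_sd[c], size=n_samp)
            bad[c] = True
            mask[:, c] = True
            kinds["disconnect"].append(c)

    for t, onset in enumerate(onsets):
        if rng.random() < artefact_rates.get("jump", 0.0):
            c = int(rng.integers(n_chan))
            pos = int(rng.integers(spt // 4, 3 * spt // 4))
            step = float(rng.choice([-1.0, 1.0])) * 10.0 * ch_sd[c]
            sig[c, onset + pos: onset + spt] += step
            mask[t, c] = True
            kinds["jump"].append((t, c))
        if rng.random() < artefact_rates.get("muscle", 0.0) and fs > 280.0:
            c = int(rng.integers(n_chan))
            burst = rng.normal(size=spt)
            f = np.fft.rfftfreq(spt, 1.0 / fs)
            bf = np.fft.rfft(burst)
            bf[(f < 110.0) | (f > 140.0)] = 0.0
            burst = np.fft.irfft(bf, n=spt)
            burst *= 6.0 * ch_sd[c] / (np.std(burst) + 1e-12)
            sig[c, onset: onset + spt] += burst
            mask[t, c] = True
            kinds["muscle"].append((t, c))

    rec = replace(recording, signal=sig.astype(np.float32))
    return rec, ArtefactTruth(trial_channel=mask, bad_channels=bad, kinds=kinds)


# ---------------------------------------------------------------------------
# behaviour

def generate_behaviour(
    config: SimConfig,
    realized_strengths: pd.DataFrame,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Recognition counts (pre/post) per subject-night.

    ``realized_strengths`` needs columns ``subject``, ``night``, ``strength``.
    Expected consolidation is ``intercept + behaviour_link * strength`` plus
    Gaussian noise; d-prime values are mapped to hit/false-alarm rates under
    an unbiased criterion and counts drawn binomially (which respects the
    0 <= hits <= n_old bounds by construction).
    """
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, "behaviour")
    rows = []
    for rec in realized_strengths.itertuples(index=False):
        d_pre = float(rng.normal(1.5, 0.3))
        delta = (config.behaviour_intercept
                 + config.behaviour_link * float(rec.strength)
                 + float(rng.normal(0.0, config.behaviour_noise_sd)))
        for session, d in (("pre", d_pre), ("post", d_pre + delta)):
            hr = float(np.clip(norm.cdf(d / 2.0), 0.02, 0.98))
            far = float(np.clip(norm.cdf(-d / 2.0), 0.02, 0.98))
            rows.append({
                "subject": rec.subject, "night": rec.night, "session": session,
                "n_old": config.n_old, "n_new": config.n_new,
                "hits": int(rng.binomial(config.n_old, hr)),
                "false_alarms": int(rng.binomial(config.n_new, far)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature-level cohort

@dataclass
class CellFeatures:
    """Per-night spectral features for one (stage-group, segment) analysis cell."""

    stage: str                     # "S2" | "SWS" | "REM"
    segment: int                   # 1-based 90-min segment
    X: np.ndarray                  # (n_nights, n_groups, n_bins) mean power
    y: np.ndarray                  # (n_nights,) +1 face / -1 house
    subjects: np.ndarray           # (n_nights,) subject ids
    nights: np.ndarray             # (n_nights,) night index within subject
    n_trials: np.ndarray           # (n_nights,) artefact-free trials averaged

    @property
    def n_nights(self) -> int:
        return self.X.shape[0]

    @property
    def n_subjects(self) -> int:
        return np.unique(self.subjects).size


@dataclass
class Cohort:
    """A simulated cohort at the feature level, with ground truth attached."""

    config: SimConfig
    cells: dict[tuple[str, int], CellFeatures]
    hypnograms: dict[tuple[int, int], Hypnogram]        # (subject, night)
    strengths: pd.DataFrame                             # subject, night, strength
    behaviour: pd.DataFrame
    conditions: dict[tuple[int, int], str]


def _night_conditions(config: SimConfig, subject: int) -> tuple[str, str]:
    """Counterbalanced condition order; exactly one face and one house night."""
    rng = rng_for(config.seed, "order", subject)
    return ("face", "house") if rng.random() < 0.5 else ("house", "face")


def _cell_trial_counts(hypno: Hypnogram, loss_rate: float, rng: np.random.Generator) -> dict[tuple[str, int], int]:
    """Artefact-free 4-s trials per (raw stage, segment)."""
    trials_per_epoch = int(EPOCH_S // TRIAL_S)
    counts: dict[tuple[str, int], int] = {}
    for i, st in enumerate(hypno.stages):
        seg = hypno.segment_of_epoch(i)
        if seg < 0:
            continue
        counts[(st, seg)] = counts.get((st, seg), 0) + trials_per_epoch
    if loss_rate > 0:
        counts = {k: int(v - rng.binomial(v, loss_rate)) for k, v in counts.items()}
    return counts


def _night_mean_spectra(
    config: SimConfig,
    offsets: Mapping[str, np.ndarray],
    condition: str,
    amplitude: float,
    rng: np.random.Generator,
) -> dict[tuple[str, int], np.ndarray]:
    """Noise-free expected (groups x bins) power per (raw stage, segment)."""
    freqs = config.freqs
    gmat = np.ones((config.n_groups, freqs.size))
    for band, g in offsets.items():
        m = band_mask(band, freqs)
        gmat[:, m] *= np.asarray(g).reshape(-1, 1)
    gains = np.exp(rng.normal(0.0, config.channel_gain_sigma, size=config.n_groups))
    gmat *= gains[:, None]
    base = {}
    for st in ("S2", "S3", "S4", "REM"):
        tmpl = stage_spectrum_template(st, None, freqs)
        base[st] = gmat * tmpl[None, :]
    spectra = {
        (st, seg): base[st]
        for st in base
        for seg in range(1, config.n_segments + 1)
    }
    return embed_condition_signature(spectra, config, condition, amplitude=amplitude)


def simulate_cells(config: SimConfig, sws_mode: str = "s3s4") -> Cohort:
    """Generate per-cell mean spectra for every subject-night.

    The mean over ``n`` trials of Gamma(k)-distributed multiplicative
    spectral noise is drawn exactly as Gamma(n*k)/(n*k), so no per-trial
    arrays are materialized.  Counterbalancing, subject band gains,
    per-night realized signature amplitudes and behaviour follow the
    config.
    """
    stage_groups = dict(STAGE_GROUPS)
    if sws_mode == "s4":
        stage_groups["SWS"] = ("S4",)
    elif sws_mode != "s3s4":
        raise ValueError("sws_mode must be 's3s4' or 's4'")

    acc: dict[tuple[str, int], dict[str, list]] = {
        (sg, seg): {"X": [], "y": [], "subj": [], "night": [], "nt": []}
        for sg in stage_groups for seg in range(1, config.n_segments + 1)
    }
    hypnos: dict[tuple[int, int], Hypnogram] = {}
    conditions: dict[tuple[int, int], str] = {}
    strength_rows = []
    k = config.trial_noise_shape

    for subject in range(config.n_subjects):
        offsets = subject_group_band_gains(
            rng_for(config.seed, "offsets", subject), config.subject_band_sigma, config.n_groups
        )
        order = _night_conditions(config, subject)
        for night, condition in enumerate(order):
            rng = rng_for(config.seed, "night", subject, night)
            hypno = generate_hypnogram(config.night_duration_min, rng)
            hypnos[(subject, night)] = hypno
            conditions[(subject, night)] = condition
            amplitude = min(
                config.signature_amplitude
                * float(np.exp(rng.normal(0.0, config.subject_amplitude_sigma))),
                0.95,  # keep the weaker condition's power positive
            )
            strength_rows.append({"subject": subject, "night": night, "strength": amplitude})
            mean_spectra = _night_mean_spectra(config, offsets, condition, amplitude, rng)
            counts = _cell_trial_counts(hypno, config.trial_loss_rate, rng)
            for sg, members in stage_groups.items():
                for seg in range(1, config.n_segments + 1):
                    n_tr = sum(counts.get((st, seg), 0) for st in members)
                    if n_tr == 0:
                        continue
                    # trial-count-weighted mean over member stages
                    mean = sum(
                        counts.get((st, seg), 0) * mean_spectra[(st, seg)] for st in members
                    ) / n_tr
                    noise = rng.gamma(n_tr * k, 1.0 / (n_tr * k), size=mean.shape)
                    a = acc[(sg, seg)]
                    a["X"].append(mean * noise)
                    a["y"].append(1.0 if condition == "face" else -1.0)
                    a["subj"].append(subject)
                    a["night"].append(night)
                    a["nt"].append(n_tr)

    cells = {
        key: CellFeatures(
            stage=key[0], segment=key[1],
            X=np.array(v["X"]), y=np.array(v["y"]),
            subjects=np.array(v["subj"]), nights=np.array(v["night"]),
            n_trials=np.array(v["nt"]),
        )
        for key, v in acc.items() if v["X"]
    }
    strengths = pd.DataFrame(strength_rows)
    behaviour = generate_behaviour(config, strengths, rng_for(config.seed, "behaviour"))
    return Cohort(
        config=config, cells=cells, hypnograms=hypnos,
        strengths=strengths, behaviour=behaviour, conditions=conditions,
    )


@dataclass
class NightTrials:
    """Per-trial group spectra for one night (for sliding-window analyses)."""

    subject: int
    night: int
    condition: str
    onsets: np.ndarray             # (n_trials,) seconds from lights-off
    stages: np.ndarray             # (n_trials,) raw stage labels
    spectra: np.ndarray            # (n_trials, n_groups, n_bins)


def simulate_night_trials(
    config: SimConfig,
    subject: int,
    night: int,
    stages: Iterable[str] = ("S2", "S3", "S4", "REM"),
) -> NightTrials:
    """Draw per-trial spectra for one night, restricted to ``stages``.

    Reuses the same derived streams as :func:`simulate_cells` for the
    hypnogram, condition order and realized amplitude, so trial-level and
    cell-level views of a cohort agree.
    """
    offsets = subject_group_band_gains(
        rng_for(config.seed, "offsets", subject), config.subject_band_sigma, config.n_groups
    )
    condition = _night_conditions(config, subject)[night]
    rng = rng_for(config.seed, "night", subject, night)
    hypno = generate_hypnogram(config.night_duration_min, rng)
    amplitude = min(
        config.signature_amplitude
        * float(np.exp(rng.normal(0.0, config.subject_amplitude_sigma))),
        0.95,  # keep the weaker condition's power positive
    )
    mean_spectra = _night_mean_spectra(config, offsets, condition, amplitude, rng)

    keep = set(stages)
    trials_per_epoch = int(EPOCH_S // TRIAL_S)
    onsets, labels, specs = [], [], []
    trng = rng_for(config.seed, "trials", subject, night)
    k = config.trial_noise_shape
    for i, st in enumerate(hypno.stages):
        if st not in keep:
            continue
        seg = hypno.segment_of_epoch(i)
        if seg < 0:
            continue
        mean = mean_spectra[(st, seg)]
        for t in range(trials_per_epoch):
            if trng.random() < config.trial_loss_rate:
                continue
            onsets.append(i * EPOCH_S + t * TRIAL_S)
            labels.append(st)
            specs.append(mean * trng.gamma(k, 1.0 / k, size=mean.shape))
    return NightTrials(
        subject=subject, night=night, condition=condition,
        onsets=np.array(onsets), stages=np.array(labels),
        spectra=np.array(specs) if specs else np.empty((0, config.n_groups, config.n_bins)),
    )
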