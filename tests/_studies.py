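"""Scaled-down validation studies shared by the acceptance test suite and
``scripts/acceptance.py``.

Each study regenerates its synthetic cohorts from scratch and runs the full
pipeline; study sizes are chosen to fit a single CPU in minutes (cohort
counts follow the property-based protocol: 200 null cohorts for type-I
calibration, 50 cohorts for behaviour-link recovery).
"""

from __future__ import annotations

import numpy as np

from somnidec.decode import DecodeSettings, cross_validated_decode, feature_weight_maps
from somnidec.inference import permutation_test, sliding_window_timecourse
from somnidec.pipeline import behaviour_statistics, included_cells, prepared
from somnidec.synthdata import SimConfig, simulate_cells, simulate_night_trials


def type_i_error_study(n_cohorts: int = 200, n_perm: int = 99, alpha: float = 0.05,
                       seed: int = 0) -> dict:
    """Empirical type-I error of the permutation test on null cohorts.

    Cohorts carry no condition information (signature amplitude 0, 24
    nights); decoding runs at one repetition per permutation on reduced
    feature dimensions, and each cohort's p-value comes from 99 label
    shuffles of the full two-step pipeline.
    """
    settings = DecodeSettings(n_reps=1)
    rejections = 0
    pvals = []
    for i in range(n_cohorts):
        cfg = SimConfig(n_subjects=12, n_groups=6, n_bins=12,
                        signature_amplitude=0.0, seed=seed * 1000 + i)
        cohort = simulate_cells(cfg)
        cell = prepared(included_cells(cohort.cells, 40, 11)[("S2", 2)])
        nd = permutation_test(cell, settings, n_perm=n_perm, seed=seed + i)
        pvals.append(nd.p_value)
        rejections += nd.p_value <= alpha
    return {
        "rejection_rate": rejections / n_cohorts,
        "mean_p": float(np.mean(pvals)),
        "n_cohorts": n_cohorts,
    }


def recovery_config(seed: int = 0) -> SimConfig:
    """The signal-recovery scenario: amplitude 0.3 confined to one channel
    group x spindle band x segment 2 x S2/SWS stages."""
    return SimConfig(
        n_subjects=20, n_groups=32, n_bins=60,
        signature_amplitude=0.3, signature_cells=(("CP4", "spindle"),),
        signature_stages=("S2", "S3", "S4"), signature_segments=(2,),
        subject_amplitude_sigma=0.3, seed=seed,
    )


def signal_recovery_study(seed: int = 0, n_perm: int = 99) -> dict:
    cfg = recovery_config(seed)
    cohort = simulate_cells(cfg)
    cells = included_cells(cohort.cells, 40, 11)
    cell = prepared(cells[("S2", 2)])

    res = cross_validated_decode(cell, DecodeSettings(n_reps=20), seed=seed)
    _, topo = feature_weight_maps(res)
    seeded = cfg.group_names.index("CP4")

    nd = permutation_test(cell, DecodeSettings(n_reps=2), n_perm=n_perm, seed=seed)

    night_trials = [simulate_night_trials(cfg, s, n, stages=("S2",))
                    for s in range(cfg.n_subjects) for n in (0, 1)]
    tc = sliding_window_timecourse(
        night_trials, "S2", DecodeSettings(n_reps=6),
        night_duration_min=cfg.night_duration_min,
        min_trials=8, min_subjects=11, seed=seed,
    )
    peak = float(tc.centres_min[np.nanargmax(tc.accuracy)])
    return {
        "validation_accuracy": res.validation_accuracy,
        "training_accuracy": res.training_accuracy,
        "permutation_p": nd.p_value,
        "permutation_bound": nd.is_bound,
        "timecourse_peak_min": peak,
        "peak_inside_segment2": bool(90.0 <= peak <= 180.0),
        "topography_argmax": int(np.argmax(topo["spindle"])),
        "topography_matches_seeded_group": bool(np.argmax(topo["spindle"]) == seeded),
    }


def behaviour_link_config(seed: int = 0) -> SimConfig:
    """Generous-signal scenario: behaviour coupled to SWS signature strength
    only (spatially distributed spindle signature in S3/S4, segments 2-4)."""
    return SimConfig(
        n_subjects=32, n_groups=8,
        signature_amplitude=0.45,
        signature_cells=((2, "spindle"), (5, "spindle"), (7, "spindle")),
        signature_stages=("S3", "S4"), signature_segments=(2, 3, 4),
        subject_amplitude_sigma=0.5,
        behaviour_link=3.0, behaviour_noise_sd=0.05,
        seed=seed,
    )


def behaviour_link_study(n_cohorts: int = 50, seed: int = 0) -> dict:
    """Recovery of the SWS-specific reprocessing-consolidation link.

    Per cohort (64 nights): decode the segment 2-4 cells of all three stage
    groups, correlate per-night strengths with overnight consolidation, and
    score (a) a positive significant SWS correlation and (b) null S2/REM
    correlations below |rho| = 0.2.
    """
    sws_hits = null_hits = joint_hits = 0
    sws_rhos = []
    for i in range(n_cohorts):
        cfg = behaviour_link_config(seed * 1000 + i)
        cohort = simulate_cells(cfg)
        cells = {k: v for k, v in included_cells(cohort.cells, 40, 11).items()
                 if k[1] in (2, 3, 4)}
        results = {k: cross_validated_decode(prepared(c), DecodeSettings(n_reps=12), seed=seed + i)
                   for k, c in cells.items()}
        stats = behaviour_statistics(cohort.behaviour, results)
        corr = stats["correlations"]
        sws_ok = corr["SWS"]["rho"] > 0 and corr["SWS"]["p"] < 0.05
        null_ok = abs(corr["S2"]["rho"]) < 0.2 and abs(corr["REM"]["rho"]) < 0.2
        sws_hits += sws_ok
        null_hits += null_ok
        joint_hits += sws_ok and null_ok
        sws_rhos.append(corr["SWS"]["rho"])
    return {
        "sws_detection_rate": sws_hits / n_cohorts,
        "null_stage_bound_rate": null_hits / n_cohorts,
        "joint_rate": joint_hits / n_cohorts,
        "mean_sws_rho": float(np.mean(sws_rhos)),
        "n_cohorts": n_cohorts,
    }
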