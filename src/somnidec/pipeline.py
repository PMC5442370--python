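"""End-to-end orchestration: simulate -> features -> decode -> inference -> behaviour.

Each stage writes its artefacts under the run's output directory; given a
fixed seed the whole bundle is byte-identical across reruns.  Inclusion
decisions (subject-nights below the trial minimum, cells below the subject
minimum) are logged at INFO because they gate every downstream statistic.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, inference, io, synthdata
from .config import RunConfig
from .decode import cross_validated_decode, feature_weight_maps
from .preprocess import prepare_features
from .synthdata import CellFeatures, Cohort

logger = logging.getLogger(__name__)


def included_cells(
    cohort_cells: dict[tuple[str, int], CellFeatures],
    min_trials: int,
    min_subjects: int,
) -> dict[tuple[str, int], CellFeatures]:
    """Apply the inclusion rules and return cells ready for decoding.

    A subject-night stays in a cell only with >= min_trials clean trials;
    a subject stays only with both nights included (paired design); a cell
    stays only with >= min_subjects subjects.
    """
    out = {}
    for key, cell in cohort_cells.items():
        keep = cell.n_trials >= min_trials
        subj = cell.subjects[keep]
        paired = np.array([np.sum(subj == s) == 2 for s in subj])
        idx = np.flatnonzero(keep)[paired]
        n_subj = np.unique(cell.subjects[idx]).size
        if n_subj < min_subjects:
            logger.info("cell %s: %d subjects < %d; excluded", key, n_subj, min_subjects)
            continue
        out[key] = CellFeatures(
            stage=cell.stage, segment=cell.segment,
            X=cell.X[idx], y=cell.y[idx],
            subjects=cell.subjects[idx], nights=cell.nights[idx],
            n_trials=cell.n_trials[idx],
        )
    return out


def prepared(cell: CellFeatures) -> CellFeatures:
    """Normalize + sharpen every night's matrix of a cell."""
    return dataclasses.replace(cell, X=np.stack([prepare_features(x) for x in cell.X]))


def run_pipeline(cfg: RunConfig, timecourse: bool = False) -> dict:
    """Execute the full analysis on a simulated cohort; returns the bundle."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fp = cfg.fingerprint()

    # --- simulate -----------------------------------------------------------
    cohort: Cohort = synthdata.simulate_cells(cfg.sim, sws_mode=cfg.sws_mode)
    io.write_behaviour(cohort.behaviour, out_dir / "behaviour.csv")
    for (s, n), hyp in list(cohort.hypnograms.items())[:2]:
        io.write_hypnogram(hyp, out_dir / f"hypnogram_s{s}_n{n}.tsv")
    io.write_json(
        {
            "fingerprint": fp,
            "signature_cells": [list(c) for c in cfg.sim.signature_cells],
            "signature_segments": list(cfg.sim.signature_segments),
            "signature_amplitude": cfg.sim.signature_amplitude,
            "strengths": cohort.strengths.to_dict(orient="list"),
        },
        out_dir / "truth.json",
    )

    # --- features + inclusion ----------------------------------------------
    cells = included_cells(cohort.cells, cfg.min_trials, cfg.min_subjects)
    io.write_feature_store(cells, out_dir / "features.h5", fingerprint=fp)
    ready = {key: prepared(cell) for key, cell in cells.items()}

    # --- decode -------------------------------------------------------------
    results = {}
    summary = {}
    for key, cell in ready.items():
        res = cross_validated_decode(cell, cfg.decode, seed=cfg.seed)
        results[key] = res
        profile, topo = feature_weight_maps(res) if cell.X.shape[2] == 60 else (None, None)
        summary[f"{key[0]}_{key[1]}"] = {
            "validation_accuracy": res.validation_accuracy,
            "training_accuracy": res.training_accuracy,
            "n_subjects": res.n_subjects,
        }
    io.write_json({"fingerprint": fp, "cells": summary}, out_dir / "decoding.json")

    # --- permutation inference ----------------------------------------------
    perm_settings = dataclasses.replace(cfg.decode, n_reps=cfg.perm_reps)
    nulls = {}
    for key, cell in ready.items():
        nulls[key] = inference.permutation_test(cell, perm_settings, n_perm=cfg.n_perm, seed=cfg.seed)
    keys = list(nulls)
    adjusted = inference.holm_correct(np.array([nulls[k].p_value for k in keys])) if keys else np.array([])
    io.write_json(
        {
            "fingerprint": fp,
            "cells": {
                f"{k[0]}_{k[1]}": {
                    "observed": nulls[k].observed,
                    "p": nulls[k].p_value,
                    "p_holm": float(adjusted[i]),
                    "bound": nulls[k].is_bound,
                    "n_perm": nulls[k].n_perm,
                }
                for i, k in enumerate(keys)
            },
        },
        out_dir / "inference.json",
    )

    # --- sliding-window time course ------------------------------------------
    timecourses = {}
    if timecourse:
        night_trials = [
            synthdata.simulate_night_trials(cfg.sim, s, n)
            for s in range(cfg.sim.n_subjects)
            for n in (0, 1)
        ]
        tc_settings = dataclasses.replace(cfg.decode, n_reps=cfg.perm_reps)
        rows = []
        for stage in cfg.timecourse_stages:
            tc = inference.sliding_window_timecourse(
                night_trials, stage, tc_settings,
                width_min=cfg.window_min, step_min=cfg.step_min,
                night_duration_min=cfg.sim.night_duration_min,
                min_trials=cfg.window_min_trials, min_subjects=cfg.min_subjects,
                seed=cfg.seed,
            )
            timecourses[stage] = tc
            for c, a, ns in zip(tc.centres_min, tc.accuracy, tc.n_subjects):
                rows.append({"centre_min": c, "stage": stage, "accuracy": a, "n_subjects": ns})
        pd.DataFrame(rows).to_csv(out_dir / "timecourse.tsv", sep="\t", index=False)

    # --- behaviour ------------------------------------------------------------
    stats_out = behaviour_statistics(cohort.behaviour, results)
    io.write_json({"fingerprint": fp, **stats_out}, out_dir / "behaviour_stats.json")

    return {
        "fingerprint": fp,
        "cells": cells,
        "decoding": results,
        "nulls": nulls,
        "timecourses": timecourses,
        "behaviour_stats": stats_out,
        "cohort": cohort,
    }


def stage_strengths(results: dict[tuple[str, int], "object"]) -> pd.DataFrame:
    """Per-night strength per stage group, averaged over that stage's cells."""
    frames = []
    for (stage, _seg), res in results.items():
        df = behavior.night_strengths(res)
        df["stage"] = stage
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["subject", "night", "stage", "strength"])
    allf = pd.concat(frames)
    return allf.groupby(["subject", "night", "stage"], as_index=False)["strength"].mean()


def behaviour_statistics(behaviour_df: pd.DataFrame, results: dict) -> dict:
    """Correlations/regressions between stage strengths and consolidation."""
    cons = behavior.consolidation_table(behaviour_df)
    strengths = stage_strengths(results)
    out: dict = {"correlations": {}, "n_nights": len(cons)}
    wide = strengths.pivot_table(index=["subject", "night"], columns="stage", values="strength")
    merged = cons.set_index(["subject", "night"]).join(wide).reset_index()

    for stage in [c for c in ("S2", "SWS", "REM") if c in merged.columns]:
        sub = merged.dropna(subset=[stage, "consolidation"])
        if len(sub) >= 5:
            rho, p = behavior.spearman(sub[stage], sub["consolidation"])
            out["correlations"][stage] = {"rho": rho, "p": p, "n": len(sub)}
    present = [c for c in ("S2", "SWS", "REM") if c in merged.columns]
    if len(present) >= 2:
        try:
            reg = behavior.reprocessing_regression(merged[present], merged["consolidation"])
            out["regression"] = {
                "beta": reg.beta, "p": reg.p_values,
                "variance_explained": reg.variance_explained, "n": reg.n,
            }
        except ValueError as e:
            out["regression"] = {"error": str(e)}
    if "SWS" in merged.columns and "REM" in merged.columns:
        sub = merged.dropna(subset=["SWS", "REM", "consolidation"])
        if len(sub) >= 4:
            inter = behavior.slope_interaction_test(
                sub["SWS"], sub["REM"], sub["consolidation"], groups=sub["subject"],
            )
            out["interaction"] = {
                "coef": inter.interaction_coef, "p": inter.interaction_p,
                "slope_sws": inter.slope_a, "slope_rem": inter.slope_b,
            }
    return out
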