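"""Plain-text and HDF5 input/output.

Hypnograms travel as two-column TSV (``onset_s<TAB>stage``, 30-s grid),
behaviour as CSV, spectral feature matrices and recordings as HDF5, and
result summaries as JSON carrying the configuration fingerprint.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthdata import EPOCH_S, STAGES, CellFeatures, Hypnogram

BEHAVIOUR_COLUMNS = ["subject", "night", "session", "n_old", "n_new", "hits", "false_alarms"]


def read_hypnogram(path) -> Hypnogram:
    """Parse an ``onset_s<TAB>stage`` TSV; errors name the offending line."""
    path = Path(path)
    stages: list[str] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("onset_s")]
    if not body:
        raise ValueError(f"{path}: empty hypnogram file")
    for expected, (lineno, ln) in enumerate(body):
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'onset_s<TAB>stage', got {ln!r}")
        onset_str, stage = parts
        try:
            onset = float(onset_str)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: bad onset {onset_str!r}") from None
        if stage not in STAGES:
            raise ValueError(f"{path}:{lineno}: unknown stage token {stage!r}")
        if abs(onset - expected * EPOCH_S) > 1e-6:
            raise ValueError(f"{path}:{lineno}: onset {onset} off the 30-s grid")
        stages.append(stage)
    return Hypnogram(stages=stages)


def write_hypnogram(hypno: Hypnogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("onset_s\tstage\n")
        for i, st in enumerate(hypno.stages):
            fh.write(f"{i * hypno.epoch_s:.1f}\t{st}\n")


def read_behaviour(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BEHAVIOUR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: behaviour CSV lacks columns {missing}")
    return df


def write_behaviour(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=BEHAVIOUR_COLUMNS)


# ---------------------------------------------------------------------------
# HDF5 feature store

def write_feature_store(cells: dict[tuple[str, int], CellFeatures], path, fingerprint: str = "") -> None:
    """Layout: ``/subject/<id>/night/<n>/cell/<stage>_<segment>`` raw matrices."""
    with h5py.File(path, "w") as f:
        f.attrs["fingerprint"] = fingerprint
        for (stage, segment), cell in cells.items():
            for i in range(cell.n_nights):
                grp = f.require_group(
                    f"subject/{cell.subjects[i]}/night/{cell.nights[i]}/cell"
                )
                ds = grp.create_dataset(f"{stage}_{segment}", data=cell.X[i])
                ds.attrs["condition"] = "face" if cell.y[i] > 0 else "house"
                ds.attrs["n_trials"] = int(cell.n_trials[i])
                ds.attrs["stage"] = stage
                ds.attrs["segment"] = segment


def read_feature_store(path) -> dict[tuple[str, int], CellFeatures]:
    acc: dict[tuple[str, int], dict[str, list]] = {}
    with h5py.File(path, "r") as f:
        for sid, subj in f["subject"].items():
            for nid, night in subj["night"].items():
                for name, ds in night["cell"].items():
                    stage, segment = ds.attrs["stage"], int(ds.attrs["segment"])
                    a = acc.setdefault((stage, segment), {"X": [], "y": [], "s": [], "n": [], "t": []})
                    a["X"].append(ds[()])
                    a["y"].append(1.0 if ds.attrs["condition"] == "face" else -1.0)
                    a["s"].append(int(sid))
                    a["n"].append(int(nid))
                    a["t"].append(int(ds.attrs["n_trials"]))
    out = {}
    for key, a in acc.items():
        order = np.lexsort((a["n"], a["s"]))
        out[key] = CellFeatures(
            stage=key[0], segment=key[1],
            X=np.array(a["X"])[order], y=np.array(a["y"])[order],
            subjects=np.array(a["s"])[order], nights=np.array(a["n"])[order],
            n_trials=np.array(a["t"])[order],
        )
    return out


def write_recordings(recordings: list, path) -> None:
    """Recordings container: ``/subject/<id>/night/<n>/signal`` (float32, uV)."""
    with h5py.File(path, "w") as f:
        for rec in recordings:
            grp = f.require_group(f"subject/{rec.subject_id}/night/{rec.night_index}")
            ds = grp.create_dataset("signal", data=rec.signal.astype(np.float32))
            ds.attrs["sampling_rate"] = rec.sampling_rate
            ds.attrs["condition"] = rec.condition
            ds.attrs["montage_id"] = rec.montage_id


def read_recordings(path) -> list:
    from .synthdata import Recording

    out = []
    with h5py.File(path, "r") as f:
        for sid, subj in f["subject"].items():
            for nid, night in subj["night"].items():
                ds = night["signal"]
                out.append(Recording(
                    signal=ds[()],
                    sampling_rate=float(ds.attrs["sampling_rate"]),
                    subject_id=int(sid), night_index=int(nid),
                    condition=str(ds.attrs["condition"]),
                    montage_id=str(ds.attrs["montage_id"]),
                ))
    return out


def write_json(obj: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.bool_):
            return bool(o)
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
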