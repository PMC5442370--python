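"""Run configuration: one object parametrizes every pipeline stage.

Every numeric output carries the configuration fingerprint (a hash of the
config plus the package version) so results are traceable to the exact
settings and seed that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .decode import FULL_REPS, DecodeSettings
from .synthdata import SimConfig


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    decode: DecodeSettings = field(default_factory=DecodeSettings)
    n_perm: int = 99
    perm_reps: int = 5                 # decoding repetitions inside each permutation
    window_min: float = 22.5
    step_min: float = 4.5
    window_min_trials: int = 8
    min_trials: int = 40
    min_subjects: int = 11
    sws_mode: str = "s3s4"
    timecourse_stages: tuple[str, ...] = ("S2",)
    seed: int = 0
    out_dir: str = "results"

    def apply_full_scale(self) -> "RunConfig":
        """Paper-scale repetitions and permutations (``--full``)."""
        return dataclasses.replace(
            self,
            decode=dataclasses.replace(self.decode, n_reps=FULL_REPS),
            n_perm=1001,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["artefact_rates"] = dict(d["sim"]["artefact_rates"])
        return d

    def fingerprint(self) -> str:
        """Hash of the scientific settings plus package version (paths excluded)."""
        from . import __version__

        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str) + __version__
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("signature_cells",):
            if key in sim_raw:
                sim_raw[key] = tuple(tuple(c) for c in sim_raw[key])
        for key in ("signature_segments", "signature_stages"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        dec_raw = raw.pop("decode", {})
        if "timecourse_stages" in raw:
            raw["timecourse_stages"] = tuple(raw["timecourse_stages"])
        return cls(sim=SimConfig(**sim_raw), decode=DecodeSettings(**dec_raw), **raw)
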