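"""Electrode montages and the 32-location spatial grouping.

High-density recordings are reduced to 32 "group channels" by averaging all
electrodes within a fixed radius (default 3 cm) of 32 evenly spread
extended 10-20 locations.  Positions come from the standard montages
shipped with :mod:`mne` (a 128-electrode layout for the dense cap, the
10-20 montage for the group centres, both on the template head of roughly
9.5 cm radius).  Groups may overlap; electrodes falling in no group are
simply never averaged into any group channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# 32 evenly spread extended 10-20 locations used as group centres.
GROUP_NAMES: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "O1", "Oz", "O2", "PO8",
)

DEFAULT_RADIUS_M = 0.03


@dataclass
class Montage:
    """Electrode layout plus the centre->member grouping."""

    electrode_names: list[str]
    electrode_pos: np.ndarray          # (n_electrodes, 3), metres
    group_names: list[str]
    group_pos: np.ndarray              # (n_groups, 3), metres
    radius: float = DEFAULT_RADIUS_M
    membership: list[np.ndarray] = field(default_factory=list)  # per group, electrode indices

    def __post_init__(self):
        if not self.membership:
            d = np.linalg.norm(
                self.electrode_pos[None, :, :] - self.group_pos[:, None, :], axis=2
            )
            self.membership = [np.flatnonzero(d[g] <= self.radius) for g in range(len(self.group_names))]

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_names)

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def group_of_electrode(self) -> np.ndarray:
        """Nearest group centre for every electrode (used by the simulator)."""
        d = np.linalg.norm(
            self.electrode_pos[None, :, :] - self.group_pos[:, None, :], axis=2
        )
        return np.argmin(d, axis=0)

    def group_index(self, name: str) -> int:
        return self.group_names.index(name)


def build_montage(radius: float = DEFAULT_RADIUS_M) -> Montage:
    """The standard montage: 128-electrode cap grouped onto 32 10-20 sites."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        dense = mne.channels.make_standard_montage("biosemi128").get_positions()["ch_pos"]
        sparse = mne.channels.make_standard_montage("standard_1020").get_positions()["ch_pos"]
    missing = [n for n in GROUP_NAMES if n not in sparse]
    if missing:
        raise RuntimeError(f"montage lacks group centres: {missing}")
    names = list(dense)
    return Montage(
        electrode_names=names,
        electrode_pos=np.array([dense[n] for n in names]),
        group_names=list(GROUP_NAMES),
        group_pos=np.array([sparse[n] for n in GROUP_NAMES]),
        radius=radius,
    )


def synthetic_montage(
    n_groups: int,
    electrodes_per_group: int = 4,
    radius: float = DEFAULT_RADIUS_M,
    seed: int = 0,
    head_radius: float = 0.095,
) -> Montage:
    """A reduced montage for small simulations and tests.

    Group centres are spread over the upper hemisphere of a spherical head
    (Fibonacci lattice); each centre gets ``electrodes_per_group`` member
    electrodes jittered inside the grouping radius.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    k = np.arange(n_groups)
    z = 0.15 + 0.85 * (k + 0.5) / n_groups          # keep off the head rim
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    centres = head_radius * np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    names = [GROUP_NAMES[i] if i < len(GROUP_NAMES) else f"G{i}" for i in range(n_groups)]
    epos, enames = [], []
    for g, c in enumerate(centres):
        for e in range(electrodes_per_group):
            jitter = rng.normal(scale=radius / 3.0, size=3)
            jitter = jitter / max(1.0, np.linalg.norm(jitter) / (0.9 * radius))
            p = c + jitter
            p = p / np.linalg.norm(p) * head_radius   # back onto the scalp
            epos.append(p)
            enames.append(f"{names[g]}_{e}")
    return Montage(
        electrode_names=enames,
        electrode_pos=np.array(epos),
        group_names=names,
        group_pos=centres,
        radius=radius,
    )
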