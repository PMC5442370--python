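import numpy as np
import pytest

from somnidec.decode import DecodeSettings, cross_validated_decode
from somnidec.pipeline import included_cells, prepared
from somnidec.synthdata import CellFeatures, SimConfig, simulate_cells


@pytest.fixture(scope="session")
def toy_cell():
    """6 subjects x 2 nights, 2 channels x 3 bins, partial signal on channel 0."""
    rng = np.random.default_rng(5)
    n_subj = 6
    X = rng.normal(size=(12, 2, 3)) * 0.5
    y = np.array([1.0, -1.0] * n_subj)
    X[y > 0, 0, :] += 0.4
    return CellFeatures(
        stage="S2", segment=2, X=X, y=y,
        subjects=np.repeat(np.arange(n_subj), 2),
        nights=np.tile([0, 1], n_subj),
        n_trials=np.full(12, 100),
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no condition information (signature amplitude 0)."""
    cfg = SimConfig(n_subjects=12, n_groups=8, n_bins=12, signature_amplitude=0.0, seed=42)
    return simulate_cells(cfg)


@pytest.fixture(scope="session")
def strong_cohort():
    """Cohort with a strong multi-group spindle signature in segment 2."""
    cfg = SimConfig(
        n_subjects=14, n_groups=8, signature_amplitude=0.8,
        signature_cells=((2, "spindle"), (5, "spindle"), (7, "spindle")),
        signature_stages=("S2", "S3", "S4"), signature_segments=(2,),
        subject_amplitude_sigma=0.0, seed=7,
    )
    return simulate_cells(cfg)


@pytest.fixture(scope="session")
def strong_decode(strong_cohort):
    cells = included_cells(strong_cohort.cells, 40, 11)
    cell = prepared(cells[("S2", 2)])
    return cross_validated_decode(cell, DecodeSettings(n_reps=10), seed=0), cell
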