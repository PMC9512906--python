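import numpy as np
import pandas as pd
import pytest

from urgetide.data import RaterTicTable, SubjectSeries
from urgetide.simulate import SimulationConfig


def make_rating_table(
    subject_id="S1",
    rater_id="R1",
    motor_intensity=None,
    vocal_intensity=None,
    n=None,
):
    """Build a valid rating table from intensity arrays (NaN = no tic)."""
    if motor_intensity is None:
        motor_intensity = np.full(n, np.nan)
    motor_intensity = np.asarray(motor_intensity, dtype=float)
    n = motor_intensity.size
    if vocal_intensity is None:
        vocal_intensity = np.full(n, np.nan)
    vocal_intensity = np.asarray(vocal_intensity, dtype=float)
    table = pd.DataFrame(
        {
            "interval": np.arange(n),
            "motor_present": np.isfinite(motor_intensity),
            "motor_intensity": motor_intensity,
            "vocal_present": np.isfinite(vocal_intensity),
            "vocal_intensity": vocal_intensity,
        }
    )
    return RaterTicTable(subject_id, rater_id, table)


def make_series(urge_z, tic, inst_z=None, subject_id="S1"):
    """Standardized SubjectSeries straight from analysis-ready arrays."""
    urge_z = np.asarray(urge_z, dtype=float)
    tic = np.asarray(tic, dtype=bool)
    inst = np.zeros_like(urge_z) if inst_z is None else np.asarray(inst_z, float)
    return SubjectSeries(
        subject_id=subject_id,
        times=np.arange(urge_z.size, dtype=float),
        urge=urge_z,
        tic=tic,
        tic_intensity=np.where(tic, 2.0, np.nan),
        inst_intensity=inst,
        urge_z=urge_z,
        inst_intensity_z=inst if inst_z is not None else None,
        standardized=True,
    )


@pytest.fixture
def small_config():
    """Short sessions, tiny cohort: fast but fully wired."""
    return SimulationConfig(duration_s=60.0, n_subjects=4, seed=123)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=42)
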