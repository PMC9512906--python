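"""In-memory containers for urge-monitor recordings and derived series.

A session consists of a continuous self-reported urge trace (0-100 slider,
sampled at a fixed rate) plus two independent raters' per-second tic codings
(motor presence/intensity on 1-8, vocal presence/intensity on 1-7).  The
analysis operates on a 1-s interval grid; intervals are 0-based and half-open,
``[t, t+1)`` seconds from recording start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MOTOR_SCALE = (1, 8)
VOCAL_SCALE = (1, 7)

RATING_COLUMNS = [
    "interval",
    "motor_present",
    "motor_intensity",
    "vocal_present",
    "vocal_intensity",
]


@dataclass
class UrgeTrace:
    """Continuous urge self-report: one session, one subject.

    Parameters
    ----------
    subject_id : str
        Subject label.
    rate_hz : float
        Sampling rate of the slider recording (samples per second).
    values : ndarray
        Urge intensities on the 0-100 scale, one per sample.
    start_offset_s : float
        Seconds of pre-roll already excluded upstream (informational).
    """

    subject_id: str
    rate_hz: float
    values: np.ndarray
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("urge trace must be one-dimensional")
        if self.values.size and (
            np.nanmin(self.values) < 0 or np.nanmax(self.values) > 100
        ):
            raise ValueError("urge values must lie in [0, 100]")
        if self.rate_hz < 1:
            raise ValueError("rate_hz must be >= 1")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.values.size) / self.rate_hz


@dataclass
class RaterTicTable:
    """One rater's per-1-s-interval motor/vocal tic codes.

    ``table`` holds columns ``interval`` (contiguous 0-based ints),
    ``motor_present`` (bool), ``motor_intensity`` (1-8, NaN where absent),
    ``vocal_present`` (bool, all-False with ``audio_present=False``) and
    ``vocal_intensity`` (1-7, NaN where absent).  Intensities must be present
    exactly where the corresponding presence flag is set.
    """

    subject_id: str
    rater_id: str
    table: pd.DataFrame
    audio_present: bool = True

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in RATING_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"rating table missing columns: {missing}")
        iv = t["interval"].to_numpy()
        if iv.size and not np.array_equal(iv, np.arange(iv[0], iv[0] + iv.size)):
            raise ValueError("interval indices must be contiguous")
        for mod, (lo, hi) in (("motor", MOTOR_SCALE), ("vocal", VOCAL_SCALE)):
            present = t[f"{mod}_present"].to_numpy(dtype=bool)
            inten = t[f"{mod}_intensity"].to_numpy(dtype=float)
            if np.any(present & ~np.isfinite(inten)):
                raise ValueError(f"{mod} intensity absent where {mod} tic present")
            if np.any(~present & np.isfinite(inten)):
                raise ValueError(f"{mod} intensity given without {mod} tic")
            obs = inten[np.isfinite(inten)]
            if obs.size and (obs.min() < lo or obs.max() > hi):
                raise ValueError(
                    f"{mod} intensity outside the {lo}-{hi} scale"
                )

    @property
    def n_intervals(self) -> int:
        return len(self.table)

    def presence(self) -> np.ndarray:
        """Any-tic (motor or vocal) presence per interval, as 0/1 floats."""
        t = self.table
        return (
            t["motor_present"].to_numpy(dtype=bool)
            | t["vocal_present"].to_numpy(dtype=bool)
        ).astype(float)

    def combined_intensity(self) -> np.ndarray:
        """Max of motor/vocal intensity per interval; 0 where no tic."""
        t = self.table
        m = t["motor_intensity"].to_numpy(dtype=float)
        v = t["vocal_intensity"].to_numpy(dtype=float)
        out = np.fmax(np.nan_to_num(m), np.nan_to_num(v))
        return out

    def without_vocal(self) -> "RaterTicTable":
        """Copy with vocal codes masked (as for sessions without audio)."""
        t = self.table.copy()
        t["vocal_present"] = False
        t["vocal_intensity"] = np.nan
        return RaterTicTable(self.subject_id, self.rater_id, t, audio_present=False)


@dataclass
class SubjectSeries:
    """Aligned per-interval series for one subject, ready for analysis.

    ``urge`` is the raw 0-100 interval urge; ``urge_z`` its per-subject
    z-score.  ``tic`` is the fused any-tic indicator, ``tic_intensity`` the
    fused combined intensity (NaN where no tic), ``inst_intensity`` the 11-s
    central moving average of intensity (0 substituted where no tic) and
    ``inst_intensity_z`` its z-score.  ``times`` gives each interval's start
    second.  ``degenerate_urge`` / ``degenerate_intensity`` flag zero-variance
    sequences that could not be standardized.
    """

    subject_id: str
    times: np.ndarray
    urge: np.ndarray
    tic: np.ndarray
    tic_intensity: np.ndarray
    inst_intensity: np.ndarray
    urge_z: np.ndarray | None = None
    inst_intensity_z: np.ndarray | None = None
    trim_s: float = 0.0
    standardized: bool = False
    degenerate_urge: bool = False
    degenerate_intensity: bool = False
    motor_only: bool = False
    true_gamma: float | None = None

    @property
    def n_intervals(self) -> int:
        return self.times.size

    def window(self, start_s: float, stop_s: float) -> "SubjectSeries":
        """Restrict to intervals whose start time lies in [start_s, stop_s)."""
        keep = (self.times >= start_s) & (self.times < stop_s)

        def cut(a):
            return None if a is None else a[keep]

        return replace(
            self,
            times=self.times[keep],
            urge=self.urge[keep],
            tic=self.tic[keep],
            tic_intensity=self.tic_intensity[keep],
            inst_intensity=self.inst_intensity[keep],
            urge_z=cut(self.urge_z),
            inst_intensity_z=cut(self.inst_intensity_z),
        )


@dataclass
class SubjectSummary:
    """Descriptive statistics of one subject's trimmed raw series."""

    subject_id: str
    mean_urge: float
    sd_urge: float
    tic_freq_pct: float
    mean_tic_intensity: float  # NaN when the subject had no tics

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "mean_urge": self.mean_urge,
            "sd_urge": self.sd_urge,
            "tic_freq_pct": self.tic_freq_pct,
            "mean_tic_intensity": self.mean_tic_intensity,
        }


CLINICAL_SCORE_COLUMNS = [
    "ygtss",
    "puts",
    "rush_total",
    "rush_tic_freq",
    "gtsqol",
    "conners_ia",
    "conners_hi",
]


@dataclass
class ClinicalScores:
    """One subject's clinical questionnaire / protocol scores."""

    subject_id: str
    ygtss: float = np.nan
    puts: float = np.nan
    rush_total: float = np.nan
    rush_tic_freq: float = np.nan
    gtsqol: float = np.nan
    conners_ia: float = np.nan
    conners_hi: float = np.nan
    age_group: str = "child_adolescent"

    def to_dict(self) -> dict:
        d = {"subject_id": self.subject_id, "age_group": self.age_group}
        for c in CLINICAL_SCORE_COLUMNS:
            d[c] = getattr(self, c)
        return d


@dataclass
class SubjectBundle:
    """One subject's raw inputs: trace, two rater tables, optional scores."""

    subject_id: str
    urge: UrgeTrace
    rater_a: RaterTicTable
    rater_b: RaterTicTable
    scores: ClinicalScores | None = None
    audio_present: bool = True


@dataclass
class GroundTruth:
    """Generative ground truth for one simulated subject."""

    subject_id: str
    gamma: float
    latent_urge: np.ndarray = field(default_factory=lambda: np.empty(0))
    tic: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    motor_intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    vocal_intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def tic_freq(self) -> float:
        return float(np.mean(self.tic)) if self.tic.size else np.nan
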