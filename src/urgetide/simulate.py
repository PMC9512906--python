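"""Synthetic urge-monitor cohorts with known urge-tic coupling.

The generator emulates the statistical structure of a 300-s urge-monitor
session: a bounded, slowly drifting continuous urge trace (Ornstein-Uhlenbeck
process sampled at 10 Hz, clipped to the 0-100 slider range), per-1-s-interval
tic occurrence whose log-odds depend on the standardized interval-mean urge,
ordinal tic intensities (motor 1-8, vocal 1-7), and two imperfect independent
raters.  Three causal regimes are supported:

``urge_drives_tic``
    tic_t ~ Bernoulli(logit^-1(alpha + gamma * z_t)) with z_t the standardized
    interval-mean urge; intensity increases with urge at slope ``delta``.
``tic_drives_urge``
    tics are a constant-rate Bernoulli process and each tic adds an asymmetric
    triangular bump (linear rise before, linear decay after) to the urge trace,
    encoding the increase-decrease pattern of urge around tic execution.
``none``
    no coupling (gamma forced to 0); used for null calibration.

Cohorts draw per-subject coupling slopes gamma_i ~ N(gamma, slope_sd^2), so
zero and negative couplings arise naturally, and can attach clinical-like
scores generated as noisy linear functions of each subject's true tic and urge
severity so that score-measure correlations are recoverable by construction.

Determinism: a single integer seed expands into per-subject substreams via
``numpy.random.SeedSequence(seed, spawn_key=(index,))``; cohorts are therefore
reproducible and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import (
    ClinicalScores,
    GroundTruth,
    RaterTicTable,
    SubjectBundle,
    UrgeTrace,
)

CouplingMode = Literal["urge_drives_tic", "tic_drives_urge", "none"]


@dataclass
class SimulationConfig:
    """Generative parameters for one session / cohort.

    Defaults mirror a typical pediatric GTS cohort: 300-s sessions at 10 Hz on
    a 0-100 scale; baseline tic log-odds ``alpha`` = logit(0.614) so ~61% of
    intervals contain a tic; OU mean 13 with stationary SD ~15 (mean urge 13.0,
    SD 14.9); mean coupling 0.44 with between-subject SD 0.3; intensity base
    2.2 (mean rated intensity 2.26); 6% of tics vocal; rater sensitivity 0.9
    and false-positive rate 0.02 per interval, which imply a between-rater
    presence correlation near the reported median of 0.71.
    """

    duration_s: float = 300.0
    urge_rate_hz: float = 10.0
    coupling_mode: CouplingMode = "urge_drives_tic"
    gamma: float = 0.44
    alpha: float = 0.46
    ou_mu: float = 13.0
    ou_tau: float = 20.0
    ou_sigma: float = 4.7
    kernel_rise_s: float = 3.0
    kernel_fall_s: float = 5.0
    kernel_amp: float = 10.0
    delta: float = 0.5
    intensity_base: float = 2.2
    intensity_jitter_sd: float = 0.8
    vocal_rate: float = 0.06
    vocal_base: float = 2.0
    n_subjects: int = 25
    slope_sd: float = 0.3
    rater_sensitivity: float = 0.9
    rater_fpr: float = 0.02
    intensity_sd: float = 0.5
    clinical_linkage: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.urge_rate_hz < 1:
            raise ValueError("urge_rate_hz must be >= 1")
        if self.ou_tau <= 0:
            raise ValueError("ou_tau must be positive")
        if not 0 <= self.ou_mu <= 100:
            raise ValueError("ou_mu must lie on the 0-100 urge scale")
        if self.kernel_rise_s < 0 or self.kernel_fall_s < 0:
            raise ValueError("kernel widths must be non-negative")
        if self.slope_sd < 0:
            raise ValueError("slope_sd must be non-negative")
        for name in ("rater_sensitivity", "rater_fpr", "vocal_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability")
        if self.coupling_mode not in ("urge_drives_tic", "tic_drives_urge", "none"):
            raise ValueError(f"unknown coupling_mode {self.coupling_mode!r}")

    @property
    def n_intervals(self) -> int:
        return int(round(self.duration_s))

    def subject_rng(self, index: int, stream: int = 0) -> np.random.Generator:
        """Deterministic, order-independent substream for one subject."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(index, stream))
        return np.random.Generator(np.random.PCG64(ss))

    def to_dict(self) -> dict:
        return asdict(self)


# Which latent measure each synthetic clinical score tracks, and the fraction
# of the configured linkage applied.  "tic_composite" is the equal-weight
# z-average of tic frequency and mean intensity.
CLINICAL_LINKS: dict[str, tuple[str, float]] = {
    "ygtss": ("tic_composite", 1.0),
    "rush_total": ("tic_composite", 1.0),
    "rush_tic_freq": ("tic_freq", 1.0),
    "puts": ("mean_urge", 1.0),
    "gtsqol": ("tic_composite", 0.5),
    "conners_ia": ("tic_composite", 0.5),
    "conners_hi": ("tic_composite", 0.5),
}

# Output location/scale and clipping bounds per synthetic score.
_SCORE_SCALES: dict[str, tuple[float, float, float, float]] = {
    "ygtss": (25.0, 8.0, 0.0, 50.0),
    "rush_total": (15.0, 5.0, 0.0, 40.0),
    "rush_tic_freq": (25.0, 12.0, 0.0, 120.0),
    "puts": (22.0, 5.0, 9.0, 36.0),
    "gtsqol": (30.0, 10.0, 0.0, 100.0),
    "conners_ia": (60.0, 10.0, 40.0, 90.0),
    "conners_hi": (60.0, 10.0, 40.0, 90.0),
}


def simulate_urge_ou(
    config: SimulationConfig,
    rng: np.random.Generator,
    start: float | None = None,
) -> UrgeTrace:
    """Euler-Maruyama simulation of the clipped OU urge trace.

    dX = (mu - X)/tau dt + sigma dW with dt = 1/urge_rate_hz; each step is
    clipped to [0, 100] after the noise is applied, so the process respects
    the slider bounds.  The trace starts at ``start`` (default: ``ou_mu``).
    """
    dt = 1.0 / config.urge_rate_hz
    n = int(round(config.duration_s * config.urge_rate_hz))
    x0 = config.ou_mu if start is None else float(start)
    noise = (rng.standard_normal(n) * (config.ou_sigma * np.sqrt(dt))).tolist()
    cur = min(max(x0, 0.0), 100.0)
    a = dt / config.ou_tau
    mu = config.ou_mu
    x = [0.0] * n
    for i in range(n):
        cur = cur + (mu - cur) * a + noise[i]
        cur = min(max(cur, 0.0), 100.0)
        x[i] = cur
    return UrgeTrace(
        subject_id="sim", rate_hz=config.urge_rate_hz, values=np.asarray(x)
    )


def _interval_means(values: np.ndarray, rate_hz: float) -> np.ndarray:
    per = int(round(rate_hz))
    n_iv = values.size // per
    return values[: n_iv * per].reshape(n_iv, per).mean(axis=1)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def _draw_intensities(
    z: np.ndarray,
    tic: np.ndarray,
    base: float,
    delta: float,
    jitter_sd: float,
    scale: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Ordinal intensities for tic intervals; NaN elsewhere."""
    lo, hi = scale
    out = np.full(z.size, np.nan)
    idx = np.flatnonzero(tic)
    raw = base + delta * z[idx] + rng.normal(0.0, jitter_sd, idx.size)
    out[idx] = np.clip(np.round(raw), lo, hi)
    return out


def simulate_tics_from_urge(
    urge: UrgeTrace,
    config: SimulationConfig,
    rng: np.random.Generator,
    gamma: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Draw per-interval tics with urge-coupled occurrence probability.

    Returns ``(tic, motor_intensity, vocal_intensity, truth)``; intensities
    are NaN where the corresponding tic/modality is absent.
    """
    if urge.values.size == 0:
        raise ValueError("empty urge trace")
    if config.coupling_mode == "tic_drives_urge":
        raise ValueError("use simulate_urge_from_tics for tic_drives_urge mode")
    g = config.gamma if gamma is None else gamma
    if config.coupling_mode == "none":
        g = 0.0
    iv_urge = _interval_means(urge.values, urge.rate_hz)
    z = _zscore(iv_urge)
    p = expit(config.alpha + g * z)
    tic = rng.random(z.size) < p
    motor = _draw_intensities(
        z, tic, config.intensity_base, config.delta,
        config.intensity_jitter_sd, (1, 8), rng,
    )
    vocal_tic = tic & (rng.random(z.size) < config.vocal_rate)
    vocal = _draw_intensities(
        z, vocal_tic, config.vocal_base, config.delta,
        config.intensity_jitter_sd, (1, 7), rng,
    )
    truth = GroundTruth(
        subject_id=urge.subject_id,
        gamma=g,
        latent_urge=urge.values.copy(),
        tic=tic,
        motor_intensity=motor,
        vocal_intensity=vocal,
    )
    return tic, motor, vocal, truth


def tic_kernel(
    times: np.ndarray,
    tic_times: np.ndarray,
    rise_s: float,
    fall_s: float,
) -> np.ndarray:
    """Unit-peak asymmetric triangular bump summed over tic times.

    Rises linearly from 0 over ``rise_s`` before each tic and decays linearly
    over ``fall_s`` after it.
    """
    out = np.zeros(times.size)
    for tt in tic_times:
        d = times - tt
        if rise_s > 0:
            pre = (d >= -rise_s) & (d < 0)
            out[pre] += 1.0 + d[pre] / rise_s
        if fall_s > 0:
            post = (d >= 0) & (d <= fall_s)
            out[post] += 1.0 - d[post] / fall_s
        else:
            out[d == 0] += 1.0
    return out


def simulate_urge_from_tics(
    config: SimulationConfig,
    rng: np.random.Generator,
    gamma: float | None = None,
) -> tuple[UrgeTrace, np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Reverse-causal regime: tics are primary, urge tracks them.

    Tics form a Bernoulli process at rate logit^-1(alpha) per 1-s interval;
    the urge trace is an OU process around ``ou_mu`` plus, for each tic, an
    asymmetric bump of peak ``|gamma| * kernel_amp`` urge units centred on the
    tic's interval midpoint, clipped to [0, 100].
    """
    if config.kernel_rise_s < 0 or config.kernel_fall_s < 0:
        raise ValueError("kernel widths must be non-negative")
    g = config.gamma if gamma is None else gamma
    n_iv = config.n_intervals
    tic = rng.random(n_iv) < expit(config.alpha)
    base = simulate_urge_ou(config, rng)
    tic_times = np.flatnonzero(tic) + 0.5
    bump = tic_kernel(
        base.times, tic_times, config.kernel_rise_s, config.kernel_fall_s
    )
    values = np.clip(base.values + abs(g) * config.kernel_amp * bump, 0.0, 100.0)
    urge = UrgeTrace(subject_id="sim", rate_hz=config.urge_rate_hz, values=values)
    z = np.zeros(n_iv)
    motor = _draw_intensities(
        z, tic, config.intensity_base, 0.0, config.intensity_jitter_sd, (1, 8), rng
    )
    vocal_tic = tic & (rng.random(n_iv) < config.vocal_rate)
    vocal = _draw_intensities(
        z, vocal_tic, config.vocal_base, 0.0, config.intensity_jitter_sd, (1, 7), rng
    )
    truth = GroundTruth(
        subject_id="sim",
        gamma=g,
        latent_urge=values.copy(),
        tic=tic,
        motor_intensity=motor,
        vocal_intensity=vocal,
    )
    return urge, tic, motor, vocal, truth


def _rate_one(
    tic: np.ndarray,
    motor: np.ndarray,
    vocal: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    subject_id: str,
    rater_id: str,
) -> RaterTicTable:
    n = tic.size
    motor_true = np.isfinite(motor)
    vocal_true = np.isfinite(vocal)

    def score_modality(true_present, true_int, scale):
        lo, hi = scale
        detected = true_present & (rng.random(n) < config.rater_sensitivity)
        false_pos = ~true_present & (rng.random(n) < config.rater_fpr)
        present = detected | false_pos
        inten = np.full(n, np.nan)
        if detected.any():
            noisy = true_int[detected] + rng.normal(
                0.0, config.intensity_sd, int(detected.sum())
            )
            inten[detected] = np.clip(np.round(noisy), lo, hi)
        if false_pos.any():
            # spurious codes sit near the scale minimum
            noisy = lo + np.abs(rng.normal(0.0, config.intensity_sd, int(false_pos.sum())))
            inten[false_pos] = np.clip(np.round(noisy), lo, hi)
        return present, inten

    mp, mi = score_modality(motor_true, motor, (1, 8))
    vp, vi = score_modality(vocal_true, vocal, (1, 7))
    table = pd.DataFrame(
        {
            "interval": np.arange(n),
            "motor_present": mp,
            "motor_intensity": mi,
            "vocal_present": vp,
            "vocal_intensity": vi,
        }
    )
    return RaterTicTable(subject_id, rater_id, table)


def apply_rater_model(
    tic: np.ndarray,
    motor_intensity: np.ndarray,
    vocal_intensity: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    subject_id: str = "sim",
) -> tuple[RaterTicTable, RaterTicTable]:
    """Two independent noisy raters observing the same true tic sequence.

    Each true tic (per modality) is scored with probability
    ``rater_sensitivity``; tic-free intervals are scored with probability
    ``rater_fpr`` (with a near-minimum intensity); scored intensities are the
    truth plus Normal(0, intensity_sd) noise, rounded and clipped to scale.
    """
    if not (tic.size == motor_intensity.size == vocal_intensity.size):
        raise ValueError("indicator and intensity sequences must align")
    a = _rate_one(tic, motor_intensity, vocal_intensity, config, rng, subject_id, "R1")
    b = _rate_one(tic, motor_intensity, vocal_intensity, config, rng, subject_id, "R2")
    return a, b


def simulate_subject(
    config: SimulationConfig,
    index: int = 0,
    gamma: float | None = None,
    subject_id: str | None = None,
) -> tuple[SubjectBundle, GroundTruth]:
    """One full synthetic session: trace + two rater tables + ground truth."""
    sid = subject_id if subject_id is not None else f"S{index + 1:03d}"
    rng = config.subject_rng(index)
    if config.coupling_mode == "tic_drives_urge":
        urge, tic, motor, vocal, truth = simulate_urge_from_tics(config, rng, gamma)
    else:
        urge = simulate_urge_ou(config, rng)
        tic, motor, vocal, truth = simulate_tics_from_urge(urge, config, rng, gamma)
    urge.subject_id = sid
    truth.subject_id = sid
    ra, rb = apply_rater_model(tic, motor, vocal, config, rng, sid)
    bundle = SubjectBundle(subject_id=sid, urge=urge, rater_a=ra, rater_b=rb)
    return bundle, truth


@dataclass
class SimulatedCohort:
    """Bundles, ground truth and config for a simulated cohort."""

    config: SimulationConfig
    bundles: list[SubjectBundle] = field(default_factory=list)
    truths: list[GroundTruth] = field(default_factory=list)

    @property
    def subject_ids(self) -> list[str]:
        return [b.subject_id for b in self.bundles]

    def true_gammas(self) -> np.ndarray:
        return np.array([t.gamma for t in self.truths])


def _true_measures(truth: GroundTruth, rate_hz: float) -> dict:
    combined = np.fmax(
        np.nan_to_num(truth.motor_intensity), np.nan_to_num(truth.vocal_intensity)
    )
    with_tic = combined[truth.tic]
    return {
        "tic_freq": float(np.mean(truth.tic)),
        "mean_intensity": float(np.mean(with_tic)) if with_tic.size else np.nan,
        "mean_urge": float(np.mean(truth.latent_urge)),
        "sd_urge": float(np.std(truth.latent_urge, ddof=1)),
    }


def simulate_clinical_scores(
    cohort: SimulatedCohort,
    age_group: str = "child_adolescent",
) -> list[ClinicalScores]:
    """Scores as noisy linear functions of each subject's true severity.

    Each score tracks one latent measure (see ``CLINICAL_LINKS``) with
    correlation ``clinical_linkage * weight`` before rescaling/clipping:
    score_z = rho * z(measure) + sqrt(1 - rho^2) * eps, eps ~ N(0, 1).
    """
    cfg = cohort.config
    rows = pd.DataFrame(
        [_true_measures(t, cfg.urge_rate_hz) for t in cohort.truths]
    )
    n = len(rows)
    z = {}
    for col in ("tic_freq", "mean_intensity", "mean_urge", "sd_urge"):
        v = rows[col].to_numpy(dtype=float)
        v = np.where(np.isfinite(v), v, np.nanmean(v) if np.isfinite(v).any() else 0.0)
        sd = np.std(v, ddof=1) if n > 1 else 0.0
        z[col] = (v - v.mean()) / sd if sd > 0 else np.zeros(n)
    z["tic_composite"] = (z["tic_freq"] + z["mean_intensity"]) / np.sqrt(2.0)
    sd_c = np.std(z["tic_composite"], ddof=1) if n > 1 else 0.0
    if sd_c > 0:
        z["tic_composite"] = z["tic_composite"] / sd_c

    out = []
    for i, t in enumerate(cohort.truths):
        rng = cfg.subject_rng(i, stream=1)
        vals = {}
        for score, (measure, weight) in CLINICAL_LINKS.items():
            rho = float(np.clip(cfg.clinical_linkage * weight, 0.0, 1.0))
            latent = rho * z[measure][i] + np.sqrt(1 - rho**2) * rng.standard_normal()
            loc, scale, lo, hi = _SCORE_SCALES[score]
            vals[score] = float(np.clip(loc + scale * latent, lo, hi))
        out.append(ClinicalScores(subject_id=t.subject_id, age_group=age_group, **vals))
    return out


def simulate_cohort(
    config: SimulationConfig,
    with_scores: bool = True,
    age_group: str = "child_adolescent",
) -> SimulatedCohort:
    """Cohort of ``n_subjects`` sessions with gamma_i ~ N(gamma, slope_sd^2)."""
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cohort = SimulatedCohort(config=config)
    for i in range(config.n_subjects):
        slope_rng = config.subject_rng(i, stream=2)
        gamma_i = config.gamma + config.slope_sd * slope_rng.standard_normal()
        if config.coupling_mode == "none":
            gamma_i = 0.0
        bundle, truth = simulate_subject(config, index=i, gamma=gamma_i)
        cohort.bundles.append(bundle)
        cohort.truths.append(truth)
    if with_scores:
        scores = simulate_clinical_scores(cohort, age_group=age_group)
        for b, s in zip(cohort.bundles, scores):
            b.scores = s
    return cohort
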