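"""From raw trace + rater tables to analysis-ready per-subject series.

Pipeline, in order: align the 10 Hz urge trace onto the 1-s interval grid
(within-interval mean by default), fuse the two raters per modality (presence
by disjunction, intensity averaged over the raters who scored one), combine
motor and vocal intensity by taking the maximum, smooth combined intensity
into an "instantaneous tic intensity" (11-s central moving average with 0
substituted in tic-free intervals), trim the first and last 10 s, and
z-standardize urge and instantaneous intensity per subject.
"""

from __future__ import annotations

import numpy as np

from .data import (
    RaterTicTable,
    SubjectBundle,
    SubjectSeries,
    SubjectSummary,
)

DEFAULT_TRIM_S = 10.0
DEFAULT_SMOOTH_WINDOW_S = 11


def align_urge(trace, method: str = "mean") -> np.ndarray:
    """Collapse an urge trace onto the 1-s interval grid.

    ``method="mean"`` (default) takes the arithmetic mean of the samples in
    each [t, t+1) interval; ``method="last"`` takes the final sample.
    """
    per = int(round(trace.rate_hz))
    if trace.values.size < per:
        raise ValueError("urge trace shorter than one interval")
    n_iv = trace.values.size // per
    blocks = trace.values[: n_iv * per].reshape(n_iv, per)
    if method == "mean":
        return blocks.mean(axis=1)
    if method == "last":
        return blocks[:, -1]
    raise ValueError(f"unknown alignment method {method!r}")


def _fuse_modality(a: RaterTicTable, b: RaterTicTable, mod: str):
    pa = a.table[f"{mod}_present"].to_numpy(dtype=bool)
    pb = b.table[f"{mod}_present"].to_numpy(dtype=bool)
    ia = a.table[f"{mod}_intensity"].to_numpy(dtype=float)
    ib = b.table[f"{mod}_intensity"].to_numpy(dtype=float)
    present = pa | pb
    with np.errstate(invalid="ignore"):
        stacked = np.vstack([ia, ib])
        count = np.isfinite(stacked).sum(axis=0)
        total = np.nansum(stacked, axis=0)
        intensity = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return present, intensity


def fuse_raters(a: RaterTicTable, b: RaterTicTable):
    """Fuse two raters per modality: presence OR, intensity mean of scorers.

    Returns ``(motor_present, motor_intensity, vocal_present,
    vocal_intensity)``; intensities are NaN where no rater scored a tic.
    """
    if a.subject_id != b.subject_id:
        raise ValueError("rater tables belong to different subjects")
    if a.n_intervals != b.n_intervals or not np.array_equal(
        a.table["interval"].to_numpy(), b.table["interval"].to_numpy()
    ):
        raise ValueError("rater tables have mismatched interval grids")
    mp, mi = _fuse_modality(a, b, "motor")
    vp, vi = _fuse_modality(a, b, "vocal")
    return mp, mi, vp, vi


def combine_modalities(
    motor_intensity: np.ndarray, vocal_intensity: np.ndarray
) -> np.ndarray:
    """Single combined intensity per interval: max of present modalities.

    NaN marks absence; where both modalities are absent the combined value is
    NaN.  Scale bounds are validated (motor 1-8, vocal 1-7).
    """
    m = np.asarray(motor_intensity, dtype=float)
    v = np.asarray(vocal_intensity, dtype=float)
    for arr, (lo, hi), name in ((m, (1, 8), "motor"), (v, (1, 7), "vocal")):
        obs = arr[np.isfinite(arr)]
        if obs.size and (obs.min() < lo or obs.max() > hi):
            raise ValueError(f"{name} intensity outside the {lo}-{hi} scale")
    out = np.fmax(m, v)  # fmax propagates a number over NaN
    return out


def instantaneous_intensity(
    tic_intensity: np.ndarray, window_s: int = DEFAULT_SMOOTH_WINDOW_S
) -> np.ndarray:
    """Central moving average of combined intensity (0 where no tic).

    Near the series edges the window truncates to the available intervals, so
    the output has the same length as the input.
    """
    x = np.nan_to_num(np.asarray(tic_intensity, dtype=float))
    half = window_s // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def build_subject_series(
    bundle: SubjectBundle,
    alignment: str = "mean",
    window_s: int = DEFAULT_SMOOTH_WINDOW_S,
    nonvocal_only: bool = False,
) -> SubjectSeries:
    """Aligned but untrimmed, unstandardized series from raw inputs."""
    ra, rb = bundle.rater_a, bundle.rater_b
    if not bundle.audio_present or nonvocal_only:
        ra, rb = ra.without_vocal(), rb.without_vocal()
    urge = align_urge(bundle.urge, method=alignment)
    mp, mi, vp, vi = fuse_raters(ra, rb)
    n = min(urge.size, mp.size)
    urge, mp, mi, vp, vi = urge[:n], mp[:n], mi[:n], vp[:n], vi[:n]
    combined = combine_modalities(mi, vi)
    tic = mp | vp
    inst = instantaneous_intensity(combined, window_s=window_s)
    return SubjectSeries(
        subject_id=bundle.subject_id,
        times=np.arange(n, dtype=float),
        urge=urge,
        tic=tic,
        tic_intensity=combined,
        inst_intensity=inst,
        motor_only=not bundle.audio_present or nonvocal_only,
    )


def trim_and_standardize(
    series: SubjectSeries,
    trim_s: float = DEFAULT_TRIM_S,
    standardize: bool = True,
) -> SubjectSeries:
    """Drop boundary intervals and z-standardize urge and intensity.

    ``trim_s`` seconds are removed from each end (10 by default: a 300-s
    session keeps 280 intervals).  With ``standardize``, urge and
    instantaneous intensity are each transformed to mean 0 / variance 1
    (ddof=1) over the retained intervals; a zero-variance sequence flags the
    subject degenerate instead of dividing by zero, and tic presence stays
    binary.
    """
    n_trim = int(round(trim_s))
    n = series.n_intervals
    if n <= 2 * n_trim:
        raise ValueError("series does not extend beyond the trimmed boundaries")
    sl = slice(n_trim, n - n_trim) if n_trim > 0 else slice(None)
    out = SubjectSeries(
        subject_id=series.subject_id,
        times=series.times[sl],
        urge=series.urge[sl],
        tic=series.tic[sl],
        tic_intensity=series.tic_intensity[sl],
        inst_intensity=series.inst_intensity[sl],
        trim_s=series.trim_s + trim_s,
        motor_only=series.motor_only,
        true_gamma=series.true_gamma,
    )
    if standardize:
        for attr, flag in (("urge", "degenerate_urge"),
                           ("inst_intensity", "degenerate_intensity")):
            x = getattr(out, attr)
            sd = np.std(x, ddof=1)
            if sd == 0 or not np.isfinite(sd):
                setattr(out, flag, True)
                setattr(out, attr + "_z", None)
            else:
                setattr(out, attr + "_z", (x - x.mean()) / sd)
        out.standardized = True
    return out


def preprocess_bundle(
    bundle: SubjectBundle,
    trim_s: float = DEFAULT_TRIM_S,
    window_s: int = DEFAULT_SMOOTH_WINDOW_S,
    alignment: str = "mean",
    standardize: bool = True,
    nonvocal_only: bool = False,
) -> SubjectSeries:
    """Full preprocessing: align, fuse, smooth, trim, standardize."""
    series = build_subject_series(
        bundle, alignment=alignment, window_s=window_s, nonvocal_only=nonvocal_only
    )
    return trim_and_standardize(series, trim_s=trim_s, standardize=standardize)


def subject_summary(series: SubjectSeries) -> SubjectSummary:
    """Descriptives on raw scales: mean/SD urge, tic %, mean intensity.

    Expects a trimmed series; mean tic intensity is computed exclusively over
    intervals containing a tic and is NaN for a tic-free subject.
    """
    tic = series.tic.astype(bool)
    with_tic = series.tic_intensity[tic]
    with_tic = with_tic[np.isfinite(with_tic)]
    return SubjectSummary(
        subject_id=series.subject_id,
        mean_urge=float(np.mean(series.urge)),
        sd_urge=float(np.std(series.urge, ddof=1)),
        tic_freq_pct=float(100.0 * np.mean(tic)),
        mean_tic_intensity=float(np.mean(with_tic)) if with_tic.size else float("nan"),
    )
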