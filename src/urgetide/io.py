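"""CSV formats, run configuration and the end-to-end pipeline driver.

All files are plain CSV (UTF-8, '.' decimal).  Per subject:

* ``<id>_urge.csv`` — columns ``time_s, urge`` (0-100 scale);
* ``<id>_rater1.csv`` / ``<id>_rater2.csv`` — columns ``interval,
  motor_present, motor_intensity, vocal_present, vocal_intensity`` (presence
  0/1; intensity empty where absent; motor 1-8, vocal 1-7);

plus a cohort-level ``clinical.csv`` (one row per subject) and a
``manifest.json`` listing subjects, sampling metadata and audio availability.
Every tabular output starts with a ``# config_hash=...`` comment so results
can be traced to the exact configuration; the package's readers skip ``#``
comment lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    analyze_cohort,
    classification_counts,
    fit_group_model,
    results_frame,
)
from .cohort import (
    clinical_correlations,
    compare_cohorts,
    interrater_reliability,
)
from .data import (
    CLINICAL_SCORE_COLUMNS,
    ClinicalScores,
    RaterTicTable,
    SubjectBundle,
    UrgeTrace,
)
from .preprocess import preprocess_bundle, subject_summary
from .simulate import SimulatedCohort, SimulationConfig, simulate_cohort

log = logging.getLogger("urgetide")


@dataclass
class RunConfig:
    """Analysis constants; the defaults reproduce the standard pipeline."""

    trim_s: float = 10.0
    smooth_window_s: int = 11
    alpha: float = 0.05
    group_window: tuple[float, float] = (50.0, 250.0)
    alignment: str = "mean"
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in cls.__dataclass_fields__ if k in raw}
        if "group_window" in known:
            known["group_window"] = tuple(known["group_window"])
        return cls(**known)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_window"] = list(self.group_window)
        return d


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


# ---------------------------------------------------------------------------
# Subject-level readers / writers
# ---------------------------------------------------------------------------


def write_urge_csv(trace: UrgeTrace, path, chash: str = "") -> None:
    df = pd.DataFrame({"time_s": trace.times, "urge": trace.values})
    _write_csv(df, Path(path), chash)


def read_urge_csv(path, subject_id: str, rate_hz: float | None = None) -> UrgeTrace:
    df = read_table(path)
    for col in ("time_s", "urge"):
        if col not in df.columns:
            raise ValueError(f"{path}: urge CSV must have column '{col}'")
    t = df["time_s"].to_numpy(dtype=float)
    if rate_hz is None:
        if t.size < 2:
            raise ValueError(f"{path}: cannot infer sampling rate")
        rate_hz = 1.0 / np.median(np.diff(t))
    values = df["urge"].to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError(f"{path}: non-numeric urge values")
    if values.min() < 0 or values.max() > 100:
        raise ValueError(f"{path}: urge values outside the 0-100 scale")
    return UrgeTrace(subject_id=subject_id, rate_hz=float(round(rate_hz)), values=values)


def write_rating_csv(table: RaterTicTable, path, chash: str = "") -> None:
    df = table.table.copy()
    df["motor_present"] = df["motor_present"].astype(int)
    df["vocal_present"] = df["vocal_present"].astype(int)
    _write_csv(df, Path(path), chash)


def read_rating_csv(path, subject_id: str, rater_id: str) -> RaterTicTable:
    df = read_table(path)
    needed = [
        "interval",
        "motor_present",
        "motor_intensity",
        "vocal_present",
        "vocal_intensity",
    ]
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"{path}: rating CSV must have column '{col}'")
    df = df[needed].copy()
    df["motor_present"] = df["motor_present"].astype(bool)
    df["vocal_present"] = df["vocal_present"].astype(bool)
    iv = df["interval"].to_numpy()
    if iv.size and not np.array_equal(iv, np.arange(iv[0], iv[0] + iv.size)):
        raise ValueError(f"{path}: interval indices must be contiguous")
    try:
        return RaterTicTable(subject_id, rater_id, df)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def read_clinical_csv(path) -> pd.DataFrame:
    df = read_table(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: clinical CSV must have a subject_id column")
    return df


# ---------------------------------------------------------------------------
# Cohort directories
# ---------------------------------------------------------------------------


def write_cohort(cohort: SimulatedCohort, out_dir, with_truth: bool = True) -> Path:
    """Serialize a simulated cohort into the analysis input layout."""
    out = Path(out_dir)
    subj_dir = out / "subjects"
    subj_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cohort.config.to_dict())
    manifest = {"config_hash": chash, "subjects": []}
    clin_rows = []
    for b in cohort.bundles:
        sid = b.subject_id
        write_urge_csv(b.urge, subj_dir / f"{sid}_urge.csv", chash)
        write_rating_csv(b.rater_a, subj_dir / f"{sid}_rater1.csv", chash)
        write_rating_csv(b.rater_b, subj_dir / f"{sid}_rater2.csv", chash)
        manifest["subjects"].append(
            {
                "id": sid,
                "urge": f"subjects/{sid}_urge.csv",
                "rater_a": f"subjects/{sid}_rater1.csv",
                "rater_b": f"subjects/{sid}_rater2.csv",
                "audio_present": bool(b.audio_present),
                "rate_hz": b.urge.rate_hz,
            }
        )
        if b.scores is not None:
            clin_rows.append(b.scores.to_dict())
    if clin_rows:
        _write_csv(pd.DataFrame(clin_rows), out / "clinical.csv", chash)
    manifest["simulation_config"] = cohort.config.to_dict()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    if with_truth:
        truth = pd.DataFrame(
            {
                "subject_id": [t.subject_id for t in cohort.truths],
                "gamma": [t.gamma for t in cohort.truths],
                "true_tic_freq": [t.tic_freq for t in cohort.truths],
            }
        )
        _write_csv(truth, out / "ground_truth.csv", chash)
    return out


def read_subject_bundle(
    urge_path,
    rater_a_path,
    rater_b_path,
    subject_id: str,
    audio_present: bool = True,
    rate_hz: float | None = None,
    scores: ClinicalScores | None = None,
) -> SubjectBundle:
    """Read and validate one subject's raw files into a bundle.

    With ``audio_present=False`` any populated vocal columns are dropped with
    a logged warning (the missing-audio flag takes precedence).
    """
    urge = read_urge_csv(urge_path, subject_id, rate_hz=rate_hz)
    ra = read_rating_csv(rater_a_path, subject_id, "R1")
    rb = read_rating_csv(rater_b_path, subject_id, "R2")
    if not audio_present:
        if ra.table["vocal_present"].any() or rb.table["vocal_present"].any():
            log.warning(
                "%s: vocal codes present but audio_present=false; dropping them",
                subject_id,
            )
        ra, rb = ra.without_vocal(), rb.without_vocal()
    return SubjectBundle(
        subject_id=subject_id,
        urge=urge,
        rater_a=ra,
        rater_b=rb,
        scores=scores,
        audio_present=audio_present,
    )


def read_cohort(cohort_dir) -> list[SubjectBundle]:
    """Load every subject listed in ``manifest.json`` under ``cohort_dir``."""
    root = Path(cohort_dir)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    clinical = None
    if (root / "clinical.csv").exists():
        clinical = read_clinical_csv(root / "clinical.csv").set_index("subject_id")
    bundles = []
    for entry in manifest["subjects"]:
        sid = entry["id"]
        scores = None
        if clinical is not None and sid in clinical.index:
            row = clinical.loc[sid]
            kwargs = {
                c: float(row[c]) for c in CLINICAL_SCORE_COLUMNS if c in row.index
            }
            scores = ClinicalScores(
                subject_id=sid,
                age_group=str(row.get("age_group", "child_adolescent")),
                **kwargs,
            )
        bundles.append(
            read_subject_bundle(
                root / entry["urge"],
                root / entry["rater_a"],
                root / entry["rater_b"],
                subject_id=sid,
                audio_present=bool(entry.get("audio_present", True)),
                rate_hz=entry.get("rate_hz"),
                scores=scores,
            )
        )
    return bundles


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineOutput:
    """Paths and in-memory results of one pipeline run."""

    out_dir: Path
    summaries: pd.DataFrame
    associations: pd.DataFrame
    classification: pd.DataFrame
    group_models: list = field(default_factory=list)
    reliability: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    comparison: pd.DataFrame | None = None


def cohort_measures(bundles, config: RunConfig, nonvocal_only: bool = False):
    """Per-subject series, summaries and association results for a cohort."""
    series, summaries, warn = [], [], []
    for b in bundles:
        s = preprocess_bundle(
            b,
            trim_s=config.trim_s,
            window_s=config.smooth_window_s,
            alignment=config.alignment,
            nonvocal_only=nonvocal_only,
        )
        if s.degenerate_urge:
            warn.append(f"{b.subject_id}: constant urge trace (degenerate)")
        series.append(s)
        summaries.append(subject_summary(s).to_dict())
    for w in warn:
        log.warning(w)
    results = analyze_cohort(series, alpha=config.alpha)
    summaries = pd.DataFrame(summaries)
    assoc = results_frame(results)
    measures = summaries.merge(
        assoc[["subject_id", "beta_logistic", "beta_linear", "r_intensity"]],
        on="subject_id",
    )
    return series, summaries, results, measures


def run_pipeline(
    bundles: list[SubjectBundle] | None = None,
    cohort_dir=None,
    config: RunConfig | None = None,
    out_dir=None,
    nonvocal_only: bool = False,
    compare_bundles: list[SubjectBundle] | None = None,
    compare_dir=None,
) -> PipelineOutput:
    """Full analysis: preprocess, associate, classify, group-fit, compare.

    Accepts either in-memory bundles or a cohort directory (and optionally a
    second cohort for the age-group comparison).  Writes all result tables
    under ``out_dir`` together with a provenance record; with
    ``nonvocal_only`` the vocal columns are masked and outputs are suffixed
    ``_nonvocal``.
    """
    config = config or RunConfig()
    if bundles is None:
        if cohort_dir is None:
            raise ValueError("either bundles or cohort_dir is required")
        bundles = read_cohort(cohort_dir)
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = "_nonvocal" if nonvocal_only else ""
    chash = config_hash(config.to_dict())

    log.info("preprocessing %d subjects", len(bundles))
    series, summaries, results, measures = cohort_measures(
        bundles, config, nonvocal_only=nonvocal_only
    )
    assoc = results_frame(results)
    counts = classification_counts(results).reset_index()
    _write_csv(summaries, out / f"summaries{suffix}.csv", chash)
    _write_csv(assoc, out / f"associations{suffix}.csv", chash)
    _write_csv(counts, out / f"classification{suffix}.csv", chash)

    log.info("fitting group models")
    group = []
    for family in ("logistic", "linear", "intensity"):
        window = None if family == "logistic" else config.group_window
        try:
            group.append(fit_group_model(series, family=family, window_s=window))
        except ValueError as e:
            log.warning("group model %s skipped: %s", family, e)
    group_df = pd.DataFrame([g.summary().iloc[0] for g in group])
    _write_csv(group_df, out / f"group_models{suffix}.csv", chash)
    with open(out / f"group_models{suffix}.json", "w") as fh:
        json.dump([g.to_dict() for g in group], fh, indent=2, default=str)

    rel_rows = []
    for b in bundles:
        rp, ri = interrater_reliability(b.rater_a, b.rater_b)
        rel_rows.append(
            {"subject_id": b.subject_id, "r_presence": rp, "r_intensity": ri}
        )
    reliability = pd.DataFrame(rel_rows)
    _write_csv(reliability, out / f"interrater{suffix}.csv", chash)

    correlations = None
    clin = [b.scores.to_dict() for b in bundles if b.scores is not None]
    if len(clin) >= 3:
        log.info("clinical correlations (%d subjects with scores)", len(clin))
        report = clinical_correlations(measures, pd.DataFrame(clin))
        correlations = report.table
        _write_csv(correlations, out / f"correlations{suffix}.csv", chash)

    comparison = None
    if compare_bundles is None and compare_dir is not None:
        compare_bundles = read_cohort(compare_dir)
    if compare_bundles is not None:
        log.info("comparing against second cohort (%d subjects)", len(compare_bundles))
        _, _, _, other_measures = cohort_measures(
            compare_bundles, config, nonvocal_only=nonvocal_only
        )
        comparison = compare_cohorts(measures, other_measures)
        _write_csv(comparison, out / f"comparison{suffix}.csv", chash)

    provenance = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "n_subjects": len(bundles),
        "nonvocal_only": nonvocal_only,
        "versions": _versions(),
    }
    with open(out / f"provenance{suffix}.json", "w") as fh:
        json.dump(provenance, fh, indent=2)

    return PipelineOutput(
        out_dir=out,
        summaries=summaries,
        associations=assoc,
        classification=counts,
        group_models=group,
        reliability=reliability,
        correlations=correlations,
        comparison=comparison,
    )


def _versions() -> dict:
    import scipy
    import statsmodels

    return {
        "urgetide": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def simulate_to_dir(sim_config: SimulationConfig, out_dir) -> Path:
    """Simulate a cohort and write it in the analysis input layout."""
    cohort = simulate_cohort(sim_config)
    return write_cohort(cohort, out_dir)
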