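"""Cohort-level statistics: reliability, clinical correlations, comparisons.

Inter-rater reliability is the Pearson correlation between the two raters'
per-interval presence indicators (0/1 treated as numeric, i.e. the phi
coefficient) and between their combined intensity series (0 where no tic).
Correlations between urge-monitor measures and clinical scores are corrected
per clinical score within measure families (tic: 2, urge: 2, urge-tic: 3)
with the Bonferroni-Holm step-down procedure.  Cohorts are compared measure
by measure with Welch t-tests (Satterthwaite df); the association measures
are additionally tested one-sided under the directional hypothesis
"adults > children".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import RaterTicTable

# measure families sharing one Holm correction per clinical score
MEASURE_FAMILIES: dict[str, list[str]] = {
    "tic": ["tic_freq_pct", "mean_tic_intensity"],
    "urge": ["mean_urge", "sd_urge"],
    "urge_tic": ["beta_logistic", "beta_linear", "r_intensity"],
}

ASSOCIATION_MEASURES = ["beta_logistic", "beta_linear", "r_intensity"]
COMPARISON_MEASURES = [
    "tic_freq_pct",
    "mean_tic_intensity",
    "mean_urge",
    "sd_urge",
] + ASSOCIATION_MEASURES


def interrater_reliability(
    a: RaterTicTable, b: RaterTicTable
) -> tuple[float, float]:
    """Pearson r between raters for tic presence and for tic intensity.

    Presence is the any-tic 0/1 indicator; intensity is the combined
    (max-of-modalities) score with 0 where the rater coded no tic.  A rater
    with a constant sequence makes that correlation degenerate (NaN).
    """
    if a.n_intervals != b.n_intervals:
        raise ValueError("rater tables have different lengths")

    def safe_r(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(stats.pearsonr(x, y)[0])

    r_presence = safe_r(a.presence(), b.presence())
    r_intensity = safe_r(a.combined_intensity(), b.combined_intensity())
    return r_presence, r_intensity


def holm_adjust(p_values, family_size: int | None = None) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment.

    Sorted ascending, the k-th smallest p is multiplied by (m - k + 1) with m
    the family size (default: the number of p-values), a cumulative maximum
    enforces monotonicity, values cap at 1 and the input order is restored.
    NaNs pass through untouched and do not count toward m by default.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    idx = np.flatnonzero(finite)
    if idx.size == 0:
        return out
    m = idx.size if family_size is None else int(family_size)
    if m < idx.size:
        raise ValueError("family_size smaller than the number of p-values")
    order = idx[np.argsort(p[idx], kind="stable")]
    adj = p[order] * (m - np.arange(order.size))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out[order] = adj
    return out


@dataclass
class CorrelationReport:
    """Tidy table of measure x score correlations with Holm adjustment."""

    table: pd.DataFrame  # columns: score, family, measure, r, p_raw, p_holm, n

    def to_matrix(self, value: str = "r") -> pd.DataFrame:
        return self.table.pivot(index="measure", columns="score", values=value)


def clinical_correlations(
    measures: pd.DataFrame,
    scores: pd.DataFrame,
    score_columns: list[str] | None = None,
    min_pairs: int = 3,
) -> CorrelationReport:
    """Pearson correlations of urge-monitor measures with clinical scores.

    ``measures`` must carry a ``subject_id`` column plus the family measures
    (tic_freq_pct, mean_tic_intensity, mean_urge, sd_urge, beta_logistic,
    beta_linear, r_intensity); ``scores`` a ``subject_id`` plus score columns.
    Missing data are handled pairwise-complete with the n reported per pair;
    pairs with fewer than ``min_pairs`` complete observations are skipped.
    Holm correction is applied per score within each measure family.
    """
    if score_columns is None:
        score_columns = [
            c for c in scores.columns if c not in ("subject_id", "age_group")
        ]
    merged = measures.merge(scores, on="subject_id", how="inner")
    rows = []
    for score in score_columns:
        for family, fam_measures in MEASURE_FAMILIES.items():
            fam_rows = []
            for meas in fam_measures:
                if meas not in merged.columns:
                    continue
                x = merged[meas].to_numpy(dtype=float)
                y = merged[score].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                n = int(ok.sum())
                if n < min_pairs or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                    fam_rows.append(
                        dict(score=score, family=family, measure=meas,
                             r=np.nan, p_raw=np.nan, n=n)
                    )
                    continue
                r, p = stats.pearsonr(x[ok], y[ok])
                fam_rows.append(
                    dict(score=score, family=family, measure=meas,
                         r=float(r), p_raw=float(p), n=n)
                )
            if not fam_rows:
                continue
            p_raw = [fr["p_raw"] for fr in fam_rows]
            p_adj = holm_adjust(p_raw, family_size=len(fam_measures))
            for fr, pa in zip(fam_rows, p_adj):
                fr["p_holm"] = float(pa) if np.isfinite(pa) else np.nan
                rows.append(fr)
    table = pd.DataFrame(
        rows, columns=["score", "family", "measure", "r", "p_raw", "p_holm", "n"]
    )
    return CorrelationReport(table=table)


def welch_compare(
    x_group, y_group, side: str = "two_sided"
) -> tuple[float, float, float]:
    """Welch two-sample t-test with Satterthwaite df.

    ``side`` is ``two_sided``, ``greater`` (mean(x) > mean(y)) or ``less``.
    Returns (t, df, p).  The statistic is computed on x - y.
    """
    x = np.asarray(x_group, dtype=float)
    y = np.asarray(y_group, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two finite values")
    alternative = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[
        side
    ]
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_cohorts(
    child: pd.DataFrame,
    adult: pd.DataFrame,
    measures: list[str] | None = None,
) -> pd.DataFrame:
    """Measure-wise Welch comparison of two cohorts' per-subject values.

    Two-sided tests for every measure; association measures additionally get
    the one-sided "adults > children" test.  Inputs are per-subject tables
    with one column per measure; the t statistic is child minus adult, so a
    negative t with a small one-sided p supports "adults > children".
    """
    if measures is None:
        measures = [m for m in COMPARISON_MEASURES if m in child.columns]
    if not len(child) or not len(adult):
        raise ValueError("both cohorts must be non-empty")
    rows = []
    for meas in measures:
        if meas not in child.columns or meas not in adult.columns:
            continue
        x = child[meas].to_numpy(dtype=float)
        y = adult[meas].to_numpy(dtype=float)
        t, df, p2 = welch_compare(x, y, side="two_sided")
        row = dict(
            measure=meas,
            t=t,
            df=df,
            p_two_sided=p2,
            n_child=int(np.isfinite(x).sum()),
            n_adult=int(np.isfinite(y).sum()),
        )
        if meas in ASSOCIATION_MEASURES:
            # adults > children  <=>  child - adult mean is negative
            _, _, p1 = welch_compare(x, y, side="less")
            row["p_adults_gt_children"] = p1
        else:
            row["p_adults_gt_children"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
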