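"""Urge-tic association measures: per-subject models and group mixed models.

Three complementary measures quantify how tic expression tracks the
continuously reported urge, each computed on per-subject z-standardized
series over the trimmed 1-s grid:

* logistic regression ``logit P(tic_t) = b0 + beta * z_urge_t`` — beta is the
  log-odds change in tic occurrence per SD of urge (odds ratio exp(beta));
* linear regression ``z_urge_t = b0 + beta * tic_t`` — beta equals the mean
  z-urge difference between tic and tic-free intervals;
* Pearson correlation between z-urge and z-instantaneous tic intensity.

Each measure is labelled positive / n.s. / negative at a two-sided alpha,
or degenerate (one-class response, constant series, complete separation).
The group-level counterparts are mixed-effects models with per-subject random
intercept and random slope (the maximal structure), tested by a df-1
likelihood-ratio test of the fixed slope; a singular or non-convergent fit
falls back to the random-intercept-only model, mirroring common practice.
Families with a z-standardized response are fitted on a restricted 50-250 s
window, where between-subject intercept variance survives standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import SubjectSeries
from .mixedlogit import MixedLogit

DEFAULT_ALPHA = 0.05
DEFAULT_STANDARDIZED_WINDOW = (50.0, 250.0)
_SEPARATION_BETA = 15.0

MEASURES = ("logistic", "linear", "intensity")
FAMILIES = ("logistic", "linear", "intensity")


def _label(coef: float, p: float, alpha: float) -> str:
    if not (np.isfinite(coef) and np.isfinite(p)):
        return "degenerate"
    if p < alpha:
        return "positive" if coef > 0 else "negative"
    return "ns"


def logistic_assoc(series: SubjectSeries) -> tuple[float, float]:
    """Per-subject logistic slope (log-odds per SD urge) and Wald p.

    Returns ``(nan, nan)`` for degenerate inputs: a single response class,
    a constant urge series, or complete separation (ML estimate unbounded).
    """
    if series.urge_z is None:
        return np.nan, np.nan
    y = series.tic.astype(float)
    if y.min() == y.max():
        return np.nan, np.nan
    X = sm.add_constant(series.urge_z)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        beta, p = fit.params[1], fit.pvalues[1]
    except Exception:
        return np.nan, np.nan
    if not np.isfinite(beta) or not np.isfinite(p) or abs(beta) > _SEPARATION_BETA:
        return np.nan, np.nan
    return float(beta), float(p)


def linear_assoc(series: SubjectSeries) -> tuple[float, float]:
    """OLS slope of z-urge on tic presence (= conditional-mean difference)."""
    if series.urge_z is None:
        return np.nan, np.nan
    y = series.urge_z
    x = series.tic.astype(float)
    if x.min() == x.max():
        return np.nan, np.nan
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def intensity_corr(series: SubjectSeries) -> tuple[float, float]:
    """Pearson r between z-urge and z-instantaneous tic intensity."""
    if series.urge_z is None or series.inst_intensity_z is None:
        return np.nan, np.nan
    r, p = stats.pearsonr(series.urge_z, series.inst_intensity_z)
    return float(r), float(p)


@dataclass
class AssociationResult:
    """Per-subject urge-tic association triplet with classification.

    The odds ratio is ``exp(beta_logistic)`` by construction.  ``labels``
    maps each measure to positive / ns / negative / degenerate.
    """

    subject_id: str
    beta_logistic: float
    p_logistic: float
    beta_linear: float
    p_linear: float
    r_intensity: float
    p_r: float
    alpha: float = DEFAULT_ALPHA
    labels: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta_logistic))

    def coefficient(self, measure: str) -> float:
        return {
            "logistic": self.beta_logistic,
            "linear": self.beta_linear,
            "intensity": self.r_intensity,
        }[measure]

    def pvalue(self, measure: str) -> float:
        return {
            "logistic": self.p_logistic,
            "linear": self.p_linear,
            "intensity": self.p_r,
        }[measure]

    def to_dict(self) -> dict:
        d = {
            "subject_id": self.subject_id,
            "beta_logistic": self.beta_logistic,
            "odds_ratio": self.odds_ratio,
            "p_logistic": self.p_logistic,
            "beta_linear": self.beta_linear,
            "p_linear": self.p_linear,
            "r_intensity": self.r_intensity,
            "p_r": self.p_r,
        }
        for m in MEASURES:
            d[f"label_{m}"] = self.labels.get(m, "degenerate")
        return d

    def summary(self) -> pd.DataFrame:
        rows = []
        for m in MEASURES:
            rows.append(
                {
                    "measure": m,
                    "coef": self.coefficient(m),
                    "p": self.pvalue(m),
                    "label": self.labels.get(m, "degenerate"),
                }
            )
        return pd.DataFrame(rows)


class UrgeTicModel:
    """Individual-level urge-tic association model for one subject.

    Built from a trimmed, standardized :class:`SubjectSeries`; ``fit()``
    returns an :class:`AssociationResult` carrying the three measures, their
    p-values and labels.
    """

    def __init__(self, series: SubjectSeries):
        if not series.standardized:
            raise ValueError("series must be trimmed and standardized first")
        self.series = series

    def fit(self, alpha: float = DEFAULT_ALPHA) -> AssociationResult:
        s = self.series
        bl, pl = logistic_assoc(s)
        bn, pn = linear_assoc(s)
        r, pr = intensity_corr(s)
        res = AssociationResult(
            subject_id=s.subject_id,
            beta_logistic=bl,
            p_logistic=pl,
            beta_linear=bn,
            p_linear=pn,
            r_intensity=r,
            p_r=pr,
            alpha=alpha,
        )
        res.labels = classify_subject(res, alpha=alpha)
        return res


def classify_subject(result: AssociationResult, alpha: float = DEFAULT_ALPHA) -> dict:
    """Label each measure: positive / negative iff p < alpha with that sign."""
    return {
        m: _label(result.coefficient(m), result.pvalue(m), alpha) for m in MEASURES
    }


def analyze_cohort(
    series_list: list[SubjectSeries], alpha: float = DEFAULT_ALPHA
) -> list[AssociationResult]:
    """Per-subject association results for a cohort."""
    return [UrgeTicModel(s).fit(alpha=alpha) for s in series_list]


def classification_counts(results: list[AssociationResult]) -> pd.DataFrame:
    """Counts of positive / ns / negative / degenerate per measure."""
    rows = []
    for m in MEASURES:
        labels = [r.labels.get(m, "degenerate") for r in results]
        rows.append(
            {
                "measure": m,
                "positive": labels.count("positive"),
                "ns": labels.count("ns"),
                "negative": labels.count("negative"),
                "degenerate": labels.count("degenerate"),
            }
        )
    return pd.DataFrame(rows).set_index("measure")


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


# ---------------------------------------------------------------------------
# Group-level mixed models
# ---------------------------------------------------------------------------


@dataclass
class GroupModelResult:
    """Fixed effect, LRT and random-effect diagnostics of a group fit."""

    family: str
    beta: float
    chi_sq: float
    p_value: float
    re_variances: np.ndarray
    singular_fallback: bool
    analysis_window: tuple[float, float] | None
    n_subjects: int
    converged: bool = True

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family": self.family,
                    "beta": self.beta,
                    "chi_sq(1)": self.chi_sq,
                    "p": self.p_value,
                    "re_var_intercept": self.re_variances[0]
                    if len(self.re_variances) > 0
                    else np.nan,
                    "re_var_slope": self.re_variances[1]
                    if len(self.re_variances) > 1
                    else np.nan,
                    "singular_fallback": self.singular_fallback,
                    "window_s": "full"
                    if self.analysis_window is None
                    else f"{self.analysis_window[0]:g}-{self.analysis_window[1]:g}",
                    "n_subjects": self.n_subjects,
                }
            ]
        )

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "beta": self.beta,
            "chi_sq": self.chi_sq,
            "p_value": self.p_value,
            "re_variances": [float(v) for v in np.atleast_1d(self.re_variances)],
            "singular_fallback": self.singular_fallback,
            "analysis_window": self.analysis_window,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
        }


def _family_data(series: SubjectSeries, family: str):
    """(response, predictor) arrays for one subject, or None if degenerate."""
    if family == "logistic":
        if series.urge_z is None:
            return None
        y = series.tic.astype(float)
        if y.min() == y.max():
            return None
        return y, series.urge_z
    if family == "linear":
        if series.urge_z is None:
            return None
        x = series.tic.astype(float)
        if x.min() == x.max():
            return None
        return series.urge_z, x
    if family == "intensity":
        if series.urge_z is None or series.inst_intensity_z is None:
            return None
        return series.inst_intensity_z, series.urge_z
    raise ValueError(f"unknown family {family!r}")


class GroupUrgeTicModel:
    """Group-level mixed model over a cohort of subject series.

    ``family`` selects the response/predictor pair: ``logistic`` (tic ~ urge,
    mixed logistic via Laplace ML), ``linear`` (z-urge ~ tic) or ``intensity``
    (z-instantaneous-intensity ~ z-urge), the latter two via linear mixed
    models (statsmodels MixedLM, ML for the likelihood-ratio test).
    ``window_s`` restricts the analysis to intervals whose start time falls in
    [start, stop); it defaults to the full trimmed range for the logistic
    family and to 50-250 s for the standardized-response families.
    """

    def __init__(
        self,
        series_list: list[SubjectSeries],
        family: str = "logistic",
        window_s: tuple[float, float] | None = "default",
    ):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        if window_s == "default":
            window_s = None if family == "logistic" else DEFAULT_STANDARDIZED_WINDOW
        self.window_s = window_s
        kept = []
        for s in series_list:
            sw = s if window_s is None else s.window(*window_s)
            if sw.n_intervals and _family_data(sw, family) is not None:
                kept.append(sw)
        if len(kept) < 2:
            raise ValueError(
                "group model needs at least two non-degenerate subjects"
            )
        self.series = kept

    def fit(self, lrt: bool = True) -> GroupModelResult:
        if self.family == "logistic":
            return self._fit_logistic(lrt)
        return self._fit_linear(lrt)

    # -- logistic family (own Laplace ML implementation) ------------------

    def _fit_logistic(self, lrt: bool) -> GroupModelResult:
        ys = [_family_data(s, "logistic")[0] for s in self.series]
        xs = [_family_data(s, "logistic")[1] for s in self.series]
        model = MixedLogit(ys, xs, random_slope=True)
        full = model.fit()
        fallback = full.is_singular or not full.converged
        if fallback:
            model = MixedLogit(ys, xs, random_slope=False)
            full = model.fit()
        chi_sq = p = np.nan
        if lrt:
            reduced = model.fit(fix_slope_zero=True)
            chi_sq = max(0.0, 2.0 * (full.llf - reduced.llf))
            p = float(stats.chi2.sf(chi_sq, df=1))
        return GroupModelResult(
            family="logistic",
            beta=full.beta1,
            chi_sq=chi_sq,
            p_value=p,
            re_variances=full.re_variances,
            singular_fallback=fallback,
            analysis_window=self.window_s,
            n_subjects=len(self.series),
            converged=full.converged,
        )

    # -- linear families (statsmodels MixedLM) ----------------------------

    def _fit_linear(self, lrt: bool) -> GroupModelResult:
        resp, pred, groups = [], [], []
        for i, s in enumerate(self.series):
            y, x = _family_data(s, self.family)
            resp.append(y)
            pred.append(x)
            groups.append(np.full(y.size, i))
        y = np.concatenate(resp)
        x = np.concatenate(pred)
        g = np.concatenate(groups)
        exog = sm.add_constant(x)

        def mixedlm_fit(exog_fe, exog_re, thorough=False):
            # lbfgs occasionally hits a singular Hessian or reports a bogus
            # infinite llf at a boundary fit; fall through to sturdier
            # optimizers (with thorough=True, keep the best finite fit)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = sm.MixedLM(y, exog_fe, groups=g, exog_re=exog_re)
                best, last_err = None, None
                for method in ("lbfgs", "bfgs", "powell"):
                    try:
                        f = m.fit(reml=False, method=method, maxiter=500)
                    except Exception as e:  # noqa: PERF203
                        last_err = e
                        continue
                    if not np.isfinite(f.llf):
                        continue
                    if best is None or f.llf > best.llf:
                        best = f
                    if not thorough and f.converged:
                        return f
                if best is None:
                    raise last_err if last_err else RuntimeError("MixedLM failed")
                return best

        exog_re_full = exog  # intercept + slope, unstructured covariance
        try:
            fit = mixedlm_fit(exog, exog_re_full)
            cov = np.asarray(fit.cov_re)
            var = np.diag(cov)
            corr = (
                cov[0, 1] / np.sqrt(var[0] * var[1])
                if cov.shape[0] > 1 and var.min() > 0
                else np.nan
            )
            singular = (
                np.any(var < 1e-6)
                or (np.isfinite(corr) and abs(corr) > 1 - 1e-3)
                or not fit.converged
            )
        except Exception:
            fit, singular = None, True
        fallback = bool(singular)
        if fallback:
            exog_re_used = np.ones((y.size, 1))
            fit = mixedlm_fit(exog, exog_re_used)
        else:
            exog_re_used = exog_re_full
        chi_sq = p = np.nan
        if lrt:
            reduced = mixedlm_fit(np.ones((y.size, 1)), exog_re_used)
            if 2.0 * (fit.llf - reduced.llf) < -1e-6:
                # full model must nest the reduced one; refit both thoroughly
                fit = mixedlm_fit(exog, exog_re_used, thorough=True)
                reduced = mixedlm_fit(
                    np.ones((y.size, 1)), exog_re_used, thorough=True
                )
            chi_sq = max(0.0, 2.0 * (fit.llf - reduced.llf))
            p = float(stats.chi2.sf(chi_sq, df=1))
        return GroupModelResult(
            family=self.family,
            beta=float(fit.fe_params[1]),
            chi_sq=chi_sq,
            p_value=p,
            re_variances=np.diag(np.atleast_2d(np.asarray(fit.cov_re))),
            singular_fallback=fallback,
            analysis_window=self.window_s,
            n_subjects=len(self.series),
            converged=bool(fit.converged),
        )


def fit_group_model(
    series_list: list[SubjectSeries],
    family: str = "logistic",
    window_s: tuple[float, float] | None = "default",
    lrt: bool = True,
) -> GroupModelResult:
    """Convenience wrapper: build and fit a :class:`GroupUrgeTicModel`."""
    return GroupUrgeTicModel(series_list, family=family, window_s=window_s).fit(
        lrt=lrt
    )
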