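"""Simulation experiments: calibration, recovery and power of the pipeline.

Each routine runs the full pipeline (simulate -> preprocess -> fit) under a
controlled causal regime and measures an operating characteristic of the
analysis: type-I error of the per-subject measures under no coupling,
bias of the individual and group-level logistic estimates under known
coupling, and power/calibration of the one-sided cohort comparison.  They are
deterministic given their seed and are what the acceptance script reports.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import analyze_cohort, fit_group_model, logistic_assoc
from .cohort import welch_compare
from .preprocess import preprocess_bundle
from .simulate import SimulationConfig, simulate_cohort, simulate_subject


def _cohort_series(config: SimulationConfig):
    cohort = simulate_cohort(config, with_scores=False)
    return [preprocess_bundle(b) for b in cohort.bundles], cohort


def null_calibration(
    n_subjects: int = 500, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Fraction of subjects flagged significant per measure with no coupling.

    Simulates ``n_subjects`` independent sessions under ``coupling_mode=none``
    (280 analyzed intervals each) and runs the three per-subject association
    tests at two-sided ``alpha``.  With a correctly calibrated test the
    significant fraction approaches ``alpha``.
    """
    config = SimulationConfig(
        coupling_mode="none", n_subjects=n_subjects, seed=seed
    )
    series, _ = _cohort_series(config)
    results = analyze_cohort(series, alpha=alpha)
    out = {"n_subjects": n_subjects, "alpha": alpha}
    for measure in ("logistic", "linear", "intensity"):
        labels = [r.labels[measure] for r in results]
        tested = sum(lab != "degenerate" for lab in labels)
        sig = sum(lab in ("positive", "negative") for lab in labels)
        out[f"significant_fraction_{measure}"] = sig / tested if tested else np.nan
        out[f"n_tested_{measure}"] = tested
    return out


def individual_recovery(
    n_intervals: int = 100_000, gamma: float = 0.44, seed: int = 0
) -> dict:
    """Bias of the per-subject logistic estimate at large n.

    One long session (``n_intervals`` 1-s intervals) with a fixed coupling
    slope; the full observation pipeline (two noisy raters, fusion, trimming,
    standardization) runs before the fit, so the reported bias includes the
    small attenuation from rater misclassification.
    """
    config = SimulationConfig(
        duration_s=float(n_intervals + 20),  # keep n_intervals after trimming
        gamma=gamma,
        slope_sd=0.0,
        seed=seed,
    )
    bundle, truth = simulate_subject(config, index=0)
    series = preprocess_bundle(bundle)
    beta, _ = logistic_assoc(series)
    return {
        "true_gamma": truth.gamma,
        "beta_hat": beta,
        "bias": beta - truth.gamma,
        "n_intervals": series.n_intervals,
    }


def group_recovery(
    n_replicates: int = 200,
    n_subjects: int = 25,
    gamma: float = 0.44,
    slope_sd: float = 0.3,
    seed: int = 0,
) -> dict:
    """Mean group-level mixed-logistic estimate over simulated cohorts.

    Each replicate simulates a cohort with gamma_i ~ N(gamma, slope_sd^2),
    fits the group mixed logistic model (with its singular-fit fallback) and
    records the fixed-effect slope.  Returns the replicate mean/SD of the
    estimate and the mean of the true per-cohort slope means.
    """
    betas, true_means, fallbacks = [], [], 0
    root = np.random.SeedSequence(seed)
    rep_seeds = root.generate_state(n_replicates) % (2**31)
    for rseed in rep_seeds:
        config = SimulationConfig(
            n_subjects=n_subjects,
            gamma=gamma,
            slope_sd=slope_sd,
            seed=int(rseed),
        )
        series, cohort = _cohort_series(config)
        res = fit_group_model(series, family="logistic", lrt=False)
        betas.append(res.beta)
        true_means.append(cohort.true_gammas().mean())
        fallbacks += res.singular_fallback
    betas = np.asarray(betas)
    return {
        "true_gamma": gamma,
        "mean_beta": float(betas.mean()),
        "sd_beta": float(betas.std(ddof=1)),
        "mean_true_cohort_gamma": float(np.mean(true_means)),
        "fallback_fraction": fallbacks / n_replicates,
        "n_replicates": n_replicates,
    }


def _cohort_logistic_betas(config: SimulationConfig) -> np.ndarray:
    series, _ = _cohort_series(config)
    betas = [logistic_assoc(s)[0] for s in series]
    return np.asarray([b for b in betas if np.isfinite(b)])


def directional_power(
    n_replicates: int = 200,
    child_gamma: float = 0.2,
    adult_gamma: float = 0.6,
    n_child: int = 25,
    n_adult: int = 21,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Power of the one-sided "adults > children" Welch comparison.

    Per replicate, a child and an adult cohort are simulated with the stated
    coupling strengths and cohort sizes, per-subject logistic slopes are
    computed, and the one-sided Welch test (child - adult, alternative
    "less") is applied.  Returns the rejection fraction.
    """
    root = np.random.SeedSequence(seed)
    rep_seeds = root.generate_state(2 * n_replicates) % (2**31)
    rejections = 0
    for i in range(n_replicates):
        child = _cohort_logistic_betas(
            SimulationConfig(
                n_subjects=n_child, gamma=child_gamma, seed=int(rep_seeds[2 * i])
            )
        )
        adult = _cohort_logistic_betas(
            SimulationConfig(
                n_subjects=n_adult, gamma=adult_gamma, seed=int(rep_seeds[2 * i + 1])
            )
        )
        _, _, p = welch_compare(child, adult, side="less")
        rejections += p < alpha
    return {
        "power": rejections / n_replicates,
        "n_replicates": n_replicates,
        "child_gamma": child_gamma,
        "adult_gamma": adult_gamma,
    }


def null_comparison_uniformity(
    n_replicates: int = 200,
    gamma: float = 0.44,
    n_child: int = 25,
    n_adult: int = 21,
    seed: int = 0,
) -> dict:
    """Two-sided comparison p-values under identical generators.

    Both cohorts are drawn from the same generator; the two-sided Welch
    p-value over replicates should be uniform, checked by a one-sample
    Kolmogorov-Smirnov test.
    """
    root = np.random.SeedSequence(seed)
    rep_seeds = root.generate_state(2 * n_replicates) % (2**31)
    pvals = []
    for i in range(n_replicates):
        child = _cohort_logistic_betas(
            SimulationConfig(
                n_subjects=n_child, gamma=gamma, seed=int(rep_seeds[2 * i])
            )
        )
        adult = _cohort_logistic_betas(
            SimulationConfig(
                n_subjects=n_adult, gamma=gamma, seed=int(rep_seeds[2 * i + 1])
            )
        )
        _, _, p = welch_compare(child, adult, side="two_sided")
        pvals.append(p)
    ks = stats.kstest(pvals, "uniform")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_replicates": n_replicates,
        "mean_p": float(np.mean(pvals)),
    }
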