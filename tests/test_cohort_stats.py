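"""Reliability, Holm correction, clinical correlations, Welch comparisons."""

import numpy as np
import pytest
import pandas as pd
from statsmodels.stats.multitest import multipletests

from conftest import make_rating_table
from urgetide.cohort import (
    clinical_correlations,
    compare_cohorts,
    holm_adjust,
    interrater_reliability,
    welch_compare,
)
from urgetide.preprocess import preprocess_bundle
from urgetide.simulate import SimulationConfig, simulate_cohort
from urgetide.io import cohort_measures, RunConfig


class TestInterraterReliability:
    def test_identical_tables_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        motor = np.where(rng.random(60) < 0.5, np.round(rng.uniform(1, 8, 60)), np.nan)
        a = make_rating_table(motor_intensity=motor)
        b = make_rating_table(motor_intensity=motor, rater_id="R2")
        rp, ri = interrater_reliability(a, b)
        assert rp == pytest.approx(1.0)
        assert ri == pytest.approx(1.0)

    def test_complementary_presence_is_minus_one(self):
        motor_a = np.array([2.0, np.nan] * 10)
        motor_b = np.array([np.nan, 2.0] * 10)
        a = make_rating_table(motor_intensity=motor_a)
        b = make_rating_table(motor_intensity=motor_b, rater_id="R2")
        rp, _ = interrater_reliability(a, b)
        assert rp == pytest.approx(-1.0)

    def test_constant_rater_is_degenerate(self):
        a = make_rating_table(motor_intensity=np.full(20, 3.0))
        b = make_rating_table(
            motor_intensity=np.where(np.arange(20) % 2 == 0, 3.0, np.nan),
            rater_id="R2",
        )
        rp, _ = interrater_reliability(a, b)
        assert np.isnan(rp)

    def test_matches_definitional_pearson_on_simulated_raters(self):
        from urgetide.simulate import apply_rater_model

        rng = np.random.default_rng(5)
        tic = rng.random(500) < 0.5
        motor = np.where(tic, np.clip(np.round(rng.normal(3, 1, 500)), 1, 8), np.nan)
        cfg = SimulationConfig(rater_sensitivity=0.8, rater_fpr=0.05)
        a, b = apply_rater_model(tic, motor, np.full(500, np.nan), cfg, rng)
        rp, ri = interrater_reliability(a, b)
        pa, pb = a.presence(), b.presence()
        expected = np.sum((pa - pa.mean()) * (pb - pb.mean())) / np.sqrt(
            np.sum((pa - pa.mean()) ** 2) * np.sum((pb - pb.mean()) ** 2)
        )
        assert rp == pytest.approx(expected, abs=1e-12)


class TestHolm:
    def test_two_pvalue_family_by_hand(self):
        assert np.allclose(holm_adjust([0.01, 0.04], 2), [0.02, 0.04])

    def test_single_pvalue_unchanged(self):
        assert holm_adjust([0.2], 1)[0] == pytest.approx(0.2)

    def test_ties_share_cumulative_maximum(self):
        assert np.allclose(holm_adjust([0.03, 0.03, 0.03], 3), [0.09, 0.09, 0.09])

    def test_dominates_raw_p_and_respects_order(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=7)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        perm = rng.permutation(7)
        assert np.allclose(holm_adjust(p[perm]), adj[perm])

    def test_agrees_with_statsmodels_when_family_equals_input(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=6)
        _, ref, _, _ = multipletests(p, method="holm")
        assert np.allclose(holm_adjust(p), ref)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            holm_adjust([0.5, 1.5])

    def test_family_larger_than_input_multiplies_up(self):
        # the family size m can exceed the number of computed p-values
        assert holm_adjust([0.02], family_size=3)[0] == pytest.approx(0.06)


class TestWelch:
    def test_identical_groups_give_zero_t_unit_p(self):
        t, _, p = welch_compare([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_pair_matches_hand_formulas(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 4, 6, 8])
        t, df, p = welch_compare(x, y)
        sx2, sy2 = x.var(ddof=1) / 4, y.var(ddof=1) / 4
        t_hand = (x.mean() - y.mean()) / np.sqrt(sx2 + sy2)
        df_hand = (sx2 + sy2) ** 2 / (sx2**2 / 3 + sy2**2 / 3)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == pytest.approx(df_hand, abs=1e-12)

    def test_one_sided_p_is_half_two_sided_with_matching_sign(self):
        rng = np.random.default_rng(6)
        x = rng.normal(1.0, 1.0, 12)
        y = rng.normal(0.0, 1.0, 15)
        t, _, p2 = welch_compare(x, y, side="two_sided")
        assert t > 0
        _, _, p1 = welch_compare(x, y, side="greater")
        assert p1 == pytest.approx(p2 / 2)

    def test_equal_variance_equal_n_matches_student(self):
        from scipy import stats

        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 20)
        y = x + 0.3  # equal sample variances: Satterthwaite df = 2n - 2
        _, _, p_welch = welch_compare(x, y)
        p_student = stats.ttest_ind(x, y, equal_var=True).pvalue
        assert p_welch == pytest.approx(p_student, abs=1e-6)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="two finite"):
            welch_compare([1.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def measured_cohort():
    cfg = SimulationConfig(n_subjects=25, seed=51)
    cohort = simulate_cohort(cfg)
    _, _, _, measures = cohort_measures(cohort.bundles, RunConfig())
    scores = pd.DataFrame([b.scores.to_dict() for b in cohort.bundles])
    return measures, scores


class TestClinicalCorrelations:
    def test_exact_linear_score_gives_unit_correlation(self, measured_cohort):
        measures, scores = measured_cohort
        scores = scores.copy()
        scores["ygtss"] = 2.0 * measures["tic_freq_pct"].to_numpy() + 5.0
        report = clinical_correlations(measures, scores)
        row = report.table.query("score == 'ygtss' and measure == 'tic_freq_pct'")
        assert row["r"].iloc[0] == pytest.approx(1.0)

    def test_linkage_recovered_within_tolerance(self):
        # generator-implied correlation oracle at n = 200
        cfg = SimulationConfig(
            duration_s=120.0, n_subjects=200, clinical_linkage=0.6, seed=52
        )
        cohort = simulate_cohort(cfg)
        _, _, _, measures = cohort_measures(
            cohort.bundles, RunConfig(trim_s=10.0)
        )
        scores = pd.DataFrame([b.scores.to_dict() for b in cohort.bundles])
        report = clinical_correlations(measures, scores)
        row = report.table.query("score == 'puts' and measure == 'mean_urge'")
        assert row["r"].iloc[0] == pytest.approx(0.6, abs=0.1)

    def test_permuted_scores_calibrate_raw_p(self, measured_cohort):
        measures, scores = measured_cohort
        rng = np.random.default_rng(53)
        hits, total = 0, 0
        for _ in range(300):
            perm = scores.copy()
            perm["puts"] = rng.permutation(perm["puts"].to_numpy())
            report = clinical_correlations(
                measures, perm, score_columns=["puts"]
            )
            p = report.table["p_raw"].to_numpy()
            ok = np.isfinite(p)
            hits += int((p[ok] < 0.05).sum())
            total += int(ok.sum())
        frac = hits / total
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / total) + 0.02

    def test_adjusted_p_dominates_raw_within_family(self, measured_cohort):
        measures, scores = measured_cohort
        report = clinical_correlations(measures, scores).table
        ok = np.isfinite(report["p_raw"]) & np.isfinite(report["p_holm"])
        assert np.all(
            report.loc[ok, "p_holm"] >= report.loc[ok, "p_raw"] - 1e-15
        )

    def test_too_few_pairs_skipped(self, measured_cohort):
        measures, scores = measured_cohort
        scores = scores.copy()
        scores.loc[2:, "gtsqol"] = np.nan
        report = clinical_correlations(measures, scores).table
        rows = report.query("score == 'gtsqol'")
        assert rows["r"].isna().all()


class TestCompareCohorts:
    def test_strong_coupling_difference_detected_one_sided(self):
        child_cfg = SimulationConfig(n_subjects=25, gamma=0.1, seed=61)
        adult_cfg = SimulationConfig(n_subjects=21, gamma=1.2, seed=62)
        child = simulate_cohort(child_cfg, with_scores=False)
        adult = simulate_cohort(adult_cfg, with_scores=False)
        _, _, _, cm = cohort_measures(child.bundles, RunConfig())
        _, _, _, am = cohort_measures(adult.bundles, RunConfig())
        table = compare_cohorts(cm, am).set_index("measure")
        assert table.loc["beta_logistic", "p_adults_gt_children"] < 0.05
        # non-association measures carry only the two-sided test
        assert np.isnan(table.loc["mean_urge", "p_adults_gt_children"])

    def test_masking_vocal_tics_has_bounded_effect(self):
        cfg = SimulationConfig(n_subjects=25, vocal_rate=0.05, seed=63)
        cohort = simulate_cohort(cfg, with_scores=False)
        _, _, full_res, fm = cohort_measures(cohort.bundles, RunConfig())
        _, _, nv_res, nm = cohort_measures(
            cohort.bundles, RunConfig(), nonvocal_only=True
        )
        b_full = fm["beta_logistic"].to_numpy()
        b_nv = nm["beta_logistic"].to_numpy()
        ok = np.isfinite(b_full) & np.isfinite(b_nv)
        assert np.max(np.abs(b_full[ok] - b_nv[ok])) < 0.5
        flips = np.mean(np.sign(b_full[ok]) != np.sign(b_nv[ok]))
        assert flips <= 0.05

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_cohorts(pd.DataFrame(), pd.DataFrame({"beta_logistic": [1.0]}))
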