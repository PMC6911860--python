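"""Statistics: transforms, regressions, mixed models, stratification."""

import numpy as np
import pandas as pd
import pytest

from wmh_bullseye import (CohortSpec, cohort_summary, fit_cross_sectional,
                          fit_longitudinal, generate_cohort_table,
                          log_volume, occupancy_percent, percent_excess,
                          residual_spearman, severity_group, severity_table)
from wmh_bullseye.stats import (RankDeficientDesign,
                                accrual_percent_per_year, round_half_up)


class TestTransforms:
    def test_log_volume_offset(self):
        assert log_volume(0.0, 1.0) == 0.0
        assert log_volume(np.e - 1, 1.0) == pytest.approx(1.0)
        v = np.linspace(0, 100, 50)
        assert np.all(np.diff(log_volume(v, 1.0)) > 0)
        with pytest.raises(ValueError):
            log_volume(-1.0)

    def test_percent_excess_identities(self):
        assert percent_excess(0.0) == 0.0
        assert percent_excess(np.log(2)) == pytest.approx(100.0)
        assert percent_excess(-np.log(2)) == pytest.approx(-50.0)
        pt, ci = percent_excess(0.0, (-np.log(2), np.log(2)))
        assert tuple(ci) == pytest.approx((-50.0, 100.0))

    def test_round_half_up_matches_reported_style(self):
        assert round_half_up(56.25, 1) == 56.3
        assert round_half_up(57.635, 1) == 57.6  # 117/203 = 57.635...
        assert round_half_up(0.0714285 * 100, 2) == 7.14


class TestCrossSectional:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        n = 80
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "wmh_mm3": rng.lognormal(6, 0.5, n),
            "group": rng.choice(["control", "symptomatic"], n),
            "age": rng.normal(50, 10, n),
            "tiv_mm3": rng.normal(1.4e6, 1e5, n)})
        res = fit_cross_sectional(df, covariates=("age", "tiv_mm3"),
                                  use_latest_visit=False)
        y = np.log(df.wmh_mm3 + 1)
        x = np.column_stack([np.ones(n),
                             (df.group == "symptomatic").astype(float),
                             df.age, df.tiv_mm3])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        got = [res.params["Intercept"],
               res.params["C(group, Treatment('control'))[T.symptomatic]"],
               res.params["age"], res.params["tiv_mm3"]]
        assert np.allclose(got, beta, atol=1e-8)

    def test_planted_group_effect_ci_coverage(self):
        covered = 0
        reps = 40
        for s in range(reps):
            cs = CohortSpec(
                n_per_group={"control": 150, "symptomatic": 150},
                group_excess={"control": 0.0,
                              "symptomatic": np.log(1.5)},
                visits_per_subject=1, random_intercept_sd=0.4,
                residual_sd=0.1, rng_seed=900 + s)
            tab = generate_cohort_table(cs)
            res = fit_cross_sectional(tab, outcome="log_wmh")
            term = "C(group, Treatment('control'))[T.symptomatic]"
            _, (lo, hi) = res.percent_excess[term]
            covered += lo <= 50.0 <= hi
        assert covered >= 0.9 * reps

    def test_null_effect_type_i_error(self):
        rej = 0
        reps = 120
        for s in range(reps):
            cs = CohortSpec(
                n_per_group={"control": 60, "symptomatic": 60},
                group_excess={"control": 0.0, "symptomatic": 0.0},
                visits_per_subject=1, random_intercept_sd=0.4,
                residual_sd=0.1, rng_seed=3000 + s)
            tab = generate_cohort_table(cs)
            res = fit_cross_sectional(tab, outcome="log_wmh")
            term = "C(group, Treatment('control'))[T.symptomatic]"
            rej += res.pvalues[term] < 0.05
        # binomial(120, 0.05): 3 sigma ~ 0.06
        assert abs(rej / reps - 0.05) < 0.06

    def test_duplicate_covariate_raises_rank_error(self):
        cs = CohortSpec(n_per_group={"control": 40}, visits_per_subject=1,
                        rng_seed=1)
        tab = generate_cohort_table(cs)
        tab["age_copy"] = tab["age"]
        with pytest.raises(RankDeficientDesign, match="age"):
            fit_cross_sectional(tab, outcome="log_wmh",
                                covariates=("age", "age_copy"))

    def test_shapiro_attached_and_sane(self):
        cs = CohortSpec(rng_seed=2, visits_per_subject=1)
        tab = generate_cohort_table(cs)
        res = fit_cross_sectional(tab, outcome="log_wmh")
        w, p = res.shapiro
        assert 0.9 < w <= 1.0


class TestLongitudinal:
    def test_planted_accrual_recovered_within_2se(self):
        cs = CohortSpec(n_per_group={"control": 100},
                        annual_accrual={"control": 0.05},
                        group_excess={"control": 0.0},
                        random_slope_sd=0.02, visits_per_subject=4,
                        rng_seed=5)
        tab = generate_cohort_table(cs)
        res = fit_longitudinal(tab, outcome="log_wmh", predictors=())
        slope = res.params["visit_time"]
        se = res.fitted.bse_fe["visit_time"]
        assert abs(slope - 0.05) <= 2 * se
        expected_pct = 100 * (np.exp(0.05) - 1)   # ~5.13 %/yr
        assert accrual_percent_per_year(res) == pytest.approx(
            expected_pct, abs=100 * (np.exp(2 * se) - 1))

    def test_random_slope_variance_recovered(self):
        cs = CohortSpec(n_per_group={"control": 200},
                        annual_accrual={"control": 0.05},
                        group_excess={"control": 0.0},
                        random_slope_sd=0.05, residual_sd=0.08,
                        visits_per_subject=4, rng_seed=6)
        tab = generate_cohort_table(cs)
        res = fit_longitudinal(tab, outcome="log_wmh", predictors=())
        cov_re = res.fitted.cov_re
        est_var = float(cov_re.loc["visit_time", "visit_time"])
        assert abs(est_var - 0.05 ** 2) <= 0.5 * 0.05 ** 2

    def test_subject_reordering_invariance(self):
        cs = CohortSpec(n_per_group={"control": 40, "symptomatic": 20},
                        visits_per_subject=3, rng_seed=7)
        tab = generate_cohort_table(cs)
        res1 = fit_longitudinal(tab, outcome="log_wmh")
        shuffled = tab.sample(frac=1.0, random_state=0)
        res2 = fit_longitudinal(shuffled, outcome="log_wmh")
        assert np.allclose(res1.params, res2.params, atol=1e-6)

    def test_single_visit_data_rejected(self):
        cs = CohortSpec(n_per_group={"control": 30}, visits_per_subject=1,
                        rng_seed=8)
        tab = generate_cohort_table(cs)
        with pytest.raises(ValueError):
            fit_longitudinal(tab, outcome="log_wmh")


class TestResidualSpearman:
    def test_planted_association_recovered(self):
        cs = CohortSpec(n_per_group={"control": 100},
                        cognition_loading=-1.0, visits_per_subject=1,
                        rng_seed=9)
        tab = generate_cohort_table(cs)
        rho, p = residual_spearman(tab, "log_wmh", "digit_span")
        assert rho < -0.5
        assert p < 0.001

    def test_independent_score_uncorrelated(self):
        hits = 0
        for s in range(20):
            cs = CohortSpec(n_per_group={"control": 100},
                            cognition_loading=0.0, visits_per_subject=1,
                            rng_seed=400 + s)
            tab = generate_cohort_table(cs)
            rho, _ = residual_spearman(tab, "log_wmh", "digit_span")
            hits += abs(rho) < 0.2
        # expected ~95% of replicates; 3-sigma binomial slack at 20 reps
        assert hits >= 16

    def test_constant_score_flagged(self):
        cs = CohortSpec(n_per_group={"control": 30}, visits_per_subject=1,
                        rng_seed=10)
        tab = generate_cohort_table(cs)
        tab["digit_span"] = 1.0
        with pytest.raises(ValueError):
            residual_spearman(tab, "log_wmh", "digit_span")

    def test_too_few_cases_rejected(self):
        cs = CohortSpec(n_per_group={"control": 4}, visits_per_subject=1,
                        rng_seed=11)
        tab = generate_cohort_table(cs)
        with pytest.raises(ValueError):
            residual_spearman(tab, "log_wmh", "digit_span")


class TestSeverityAndOccupancy:
    @pytest.mark.parametrize("volume,expected", [
        (644.8, "none/mild"), (1550.7, "moderate"), (6118.2, "severe"),
        (0.0, "none/mild"), (999.99, "none/mild"), (1000.0, "moderate"),
        (2499.9, "moderate"), (2500.0, "severe")])
    def test_stratification_bins(self, volume, expected):
        assert severity_group(volume) == expected

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            severity_group(-1.0)
        with pytest.raises(ValueError):
            occupancy_percent(-1.0, 1400)

    def test_threshold_occupancies_of_mean_tiv(self):
        assert occupancy_percent(1000.0, 1400.0) == 0.07
        assert occupancy_percent(2500.0, 1400.0) == 0.18

    def test_tiv_must_be_positive(self):
        with pytest.raises(ValueError):
            occupancy_percent(100.0, 0.0)


class TestCohortSummaries:
    def _study_counts_table(self):
        rows = []
        for group, n, n_f in (("control", 203, 117),
                              ("presymptomatic", 101, 65),
                              ("symptomatic", 32, 18)):
            for i in range(n):
                rows.append({"subject_id": f"{group}{i}", "group": group,
                             "sex": "F" if i < n_f else "M",
                             "age": 50.0, "visit_time": 0.0})
        return pd.DataFrame(rows)

    def test_percent_female_matches_study_ratios(self):
        summary = cohort_summary(self._study_counts_table())
        got = dict(zip(summary.group, summary.percent_female))
        assert got == {"control": 57.6, "presymptomatic": 64.4,
                       "symptomatic": 56.3}

    def test_all_female_group(self):
        df = pd.DataFrame({"subject_id": ["a", "b"], "group": ["control"] * 2,
                           "sex": ["F", "F"], "age": [50, 60],
                           "visit_time": [0.0, 0.0]})
        assert cohort_summary(df).percent_female.iloc[0] == 100.0

    def test_unknown_group_rejected(self):
        df = self._study_counts_table()
        df.loc[0, "group"] = "mystery"
        with pytest.raises(ValueError):
            cohort_summary(df)

    def test_severity_split_matches_abstract_arithmetic(self):
        # symptomatic carriers 8 / 12 / 12 of 32 -> 25.0 / 37.5 / 37.5 %
        rows = []
        vols = [500.0] * 8 + [1500.0] * 12 + [5000.0] * 12
        for i, v in enumerate(vols):
            rows.append({"subject_id": f"s{i}", "group": "symptomatic",
                         "sex": "F", "visit_time": 0.0, "wmh_mm3": v})
        st = severity_table(pd.DataFrame(rows))
        assert list(st.symptomatic_n) == [8, 12, 12]
        assert list(st.symptomatic_percent) == [25.0, 37.5, 37.5]


class TestMultipleComparisonFlag:
    def test_off_by_default_and_opt_in(self):
        from wmh_bullseye import adjust_pvalues
        p = np.array([0.01, 0.04, 0.2])
        assert np.array_equal(adjust_pvalues(p), p)
        bonf = adjust_pvalues(p, "bonferroni")
        assert np.allclose(bonf, np.minimum(p * 3, 1.0))
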