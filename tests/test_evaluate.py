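"""Evaluation: concordance, AUC, Cox/logistic fits, Fisher tests, strata."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from admetagrs.evaluate import (
    CoxResult,
    compare_models,
    cohort_summary,
    exclude_region,
    fisher_exact_2xk,
    fit_cox,
    fit_logistic_eval,
    harrell_c,
    roc_auc,
    stratify_by_e4,
)
from conftest import make_sumstats


def oracle_c(risk, time, event):
    """Exhaustive O(n^2) pair-count reference for Harrell's C."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


class TestHarrellC:
    def test_perfect_risk_ordering(self):
        t = np.arange(1.0, 11.0)
        assert harrell_c(-t, t, np.ones(10)) == 1.0

    def test_two_sample_toy_concordant(self):
        assert harrell_c([2.0, 1.0], [1.0, 2.0], [1, 1]) == 1.0

    def test_random_risk_is_null(self, rng):
        n = 2000
        c = harrell_c(rng.normal(size=n), rng.uniform(1, 10, size=n), np.ones(n))
        assert abs(c - 0.5) < 0.02

    def test_six_observation_censored_fixture(self):
        risk = np.array([2.0, 1.5, 1.5, 0.5, -1.0, 0.0])
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        assert harrell_c(risk, time, event) == oracle_c(risk, time, event)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_oracle_on_random_data(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(10, 50))
        risk = np.round(r.normal(size=n), 1)  # rounding induces risk ties
        time = r.integers(1, 20, size=n).astype(float)
        event = r.integers(0, 2, size=n)
        if not ((time[:, None] - time[None, :] < 0) & event[:, None].astype(bool)).any():
            event[np.argmin(time)] = 1
        assert harrell_c(risk, time, event) == pytest.approx(
            oracle_c(risk, time, event), abs=1e-12
        )

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            harrell_c([1.0, 2.0], [5.0, 5.0], [1, 1])


class TestAuc:
    def test_equals_rank_sum_oracle_exactly(self, rng):
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        s = rng.normal(size=10)
        u = stats.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").statistic
        assert roc_auc(y, s) == pytest.approx(u / 25.0, abs=1e-15)

    def test_null_score_near_half(self, rng):
        y = rng.integers(0, 2, size=4000)
        assert abs(roc_auc(y, rng.normal(size=4000)) - 0.5) < 0.03


def survival_pheno(n, rng, logh=0.0, censor=0.3):
    score = rng.standard_normal(n)
    t = rng.exponential(1.0 / np.exp(logh * score))
    cens = rng.uniform(size=n) < censor
    age = np.where(cens, t * rng.uniform(0.3, 1.0, size=n), t) + 0.01
    pheno = pd.DataFrame(
        {
            "age": age,
            "event": (~cens).astype(int),
            "status": (~cens).astype(int) | (rng.uniform(size=n) < 0.3),
            "sex": rng.integers(1, 3, size=n),
            "PC1": rng.normal(size=n),
        }
    )
    return score, pheno


class TestFitCox:
    def test_null_score_ci_covers_one(self, rng):
        """A score independent of onset: 95% CI covers HR=1 in about 95%
        of 200 replicates."""
        covered = 0
        for _ in range(200):
            score, pheno = survival_pheno(250, rng, logh=0.0)
            res = fit_cox(score, pheno, covariates=["sex", "PC1"])
            lo, hi = res.beta - 1.96 * res.se, res.beta + 1.96 * res.se
            covered += lo <= 0.0 <= hi
        assert abs(covered / 200 - 0.95) <= 0.04

    def test_log_hazard_recovery(self, rng):
        """Exponential onsets at true log-hazard 0.4/SD, 30% censoring:
        the mean estimate over 20 seeds lands within 0.4 +/- 0.05."""
        betas = []
        for _ in range(20):
            score, pheno = survival_pheno(5000, rng, logh=0.4, censor=0.3)
            betas.append(fit_cox(score, pheno, covariates=["sex", "PC1"]).beta)
        assert abs(np.mean(betas) - 0.4) < 0.05

    def test_hr_invariant_to_affine_rescaling(self, rng):
        score, pheno = survival_pheno(400, rng, logh=0.3)
        r1 = fit_cox(score, pheno, covariates=["sex"])
        r2 = fit_cox(score * 123.0 - 7.0, pheno, covariates=["sex"])
        assert r1.hr == pytest.approx(r2.hr, rel=1e-8)

    def test_reference_model_without_score(self, rng):
        _, pheno = survival_pheno(300, rng, logh=0.0)
        res = fit_cox(None, pheno, covariates=["sex", "PC1"])
        assert np.isnan(res.hr) and 0.0 <= res.c_index <= 1.0

    def test_breslow_ties_close_to_efron(self, rng):
        score, pheno = survival_pheno(300, rng, logh=0.4)
        pheno["age"] = np.ceil(pheno["age"] * 5) / 5  # induce ties
        r_e = fit_cox(score, pheno, covariates=["sex"])
        r_b = fit_cox(score, pheno, covariates=["sex"], ties="breslow")
        assert r_e.beta == pytest.approx(r_b.beta, abs=0.05)

    def test_no_events_rejected(self, rng):
        _, pheno = survival_pheno(50, rng)
        pheno["event"] = 0
        with pytest.raises(ValueError, match="events"):
            fit_cox(None, pheno, covariates=["sex"])


class TestFitLogistic:
    def test_null_score_auc_alone_near_half(self, rng):
        n = 3000
        y = rng.integers(0, 2, size=n)
        pheno = pd.DataFrame({"status": y})
        res = fit_logistic_eval(rng.normal(size=n), pheno, covariates=[])
        assert abs(res.auc - 0.5) < 0.03

    def test_auc_equals_rank_sum_on_fixture(self, rng):
        """With the score as only predictor, the model AUC equals the
        rank-sum AUC of the score itself (monotone link)."""
        y = np.array([0, 1, 0, 1, 1, 0, 0, 1, 1, 0])
        s = np.arange(10.0)
        pheno = pd.DataFrame({"status": y})
        res = fit_logistic_eval(s, pheno, covariates=[])
        assert res.auc == pytest.approx(roc_auc(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        pheno = pd.DataFrame({"status": np.ones(20, dtype=int)})
        with pytest.raises(ValueError, match="single"):
            fit_logistic_eval(np.random.default_rng(0).normal(size=20), pheno, covariates=[])

    def test_pseudo_r2_positive_for_informative_score(self, rng):
        n = 1000
        s = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-1.5 * s))).astype(int)
        pheno = pd.DataFrame({"status": y})
        res = fit_logistic_eval(s, pheno, covariates=[])
        assert 0.05 < res.pseudo_r2 < 1.0


class TestStratifyByE4:
    def test_genotype_partition(self):
        pheno = pd.DataFrame(
            {
                "e4_dosage": [1, 2, 1, 0, 0, np.nan],
                "e2_dosage": [0, 0, 1, 1, 0, 0],
                "label": ["e3e4", "e4e4", "e2e4", "e2e3", "e3e3", "?"],
            }
        )
        strata = stratify_by_e4(pheno)
        assert set(strata["carriers"]["label"]) == {"e3e4", "e4e4", "e2e4"}
        assert set(strata["non_carriers"]["label"]) == {"e2e3", "e3e3"}
        assert len(strata["missing"]) == 1
        assert sum(map(len, strata.values())) == len(pheno)


class TestExcludeRegion:
    def test_half_open_boundaries(self):
        ss = make_sumstats(
            [0.1, 0.1, 0.1], [0.5, 0.5, 0.5],
            chrom=[19, 19, 19], pos=[999_999, 1_000_000, 1_999_999],
        )
        out, n = exclude_region(ss, chrom=19, start=1_000_000, end=2_000_000)
        assert n == 2
        assert list(out.table["BP"]) == [999_999]

    def test_other_chromosome_untouched(self):
        ss = make_sumstats([0.1], [0.5], chrom=[18], pos=[1_500_000])
        out, n = exclude_region(ss, chrom=19, start=1_000_000, end=2_000_000)
        assert n == 0 and len(out) == 1


class TestFisherExact:
    @pytest.mark.parametrize(
        "table",
        [
            [[1, 0], [0, 1]],
            [[8, 1504], [1, 1661]],
            [[31, 1481], [50, 1612]],
            [[5, 805], [3, 1236]],
            [[3, 7], [9, 2]],
        ],
    )
    def test_2x2_matches_scipy(self, table):
        ours = fisher_exact_2xk(np.asarray(table))
        ref = stats.fisher_exact(table)[1]
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_minimal_table(self):
        assert fisher_exact_2xk([[1, 0], [0, 1]]) == 1.0

    def test_2x3_matches_enumeration_oracle(self):
        """Full conditional enumeration with multivariate-hypergeometric
        probabilities as the independent oracle."""
        table = np.array([[3, 5, 2], [6, 1, 4]])
        col = table.sum(axis=0)
        r1 = table[0].sum()
        rv = stats.multivariate_hypergeom(col.tolist(), r1)
        p_obs = rv.pmf(table[0])
        total = 0.0
        for x0 in range(col[0] + 1):
            for x1 in range(col[1] + 1):
                x2 = r1 - x0 - x1
                if 0 <= x2 <= col[2]:
                    p = rv.pmf([x0, x1, x2])
                    if p <= p_obs * (1 + 1e-7):
                        total += p
        assert fisher_exact_2xk(table) == pytest.approx(total, abs=1e-10)

    def test_monte_carlo_fallback_is_seeded_and_close(self):
        table = np.array([[40, 60, 55, 45], [60, 40, 45, 55]])
        p1 = fisher_exact_2xk(table, max_tables=10, seed=5)
        p2 = fisher_exact_2xk(table, max_tables=10, seed=5)
        assert p1 == p2
        exact = fisher_exact_2xk(table)
        assert p1 == pytest.approx(exact, abs=0.02)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2xk([[1, -1], [2, 3]])


class TestCohortSummary:
    def test_counts_and_fisher_against_direct_tables(self, rng):
        n = 500
        e2 = rng.choice([0, 1], size=n, p=[0.85, 0.15])
        e4 = np.where(e2 + rng.choice([0, 1, 2], size=n, p=[0.6, 0.3, 0.1]) + e2 > 2, 0,
                      rng.choice([0, 1, 2], size=n, p=[0.6, 0.3, 0.1]))
        e4 = np.minimum(e4, 2 - e2)
        pheno = pd.DataFrame(
            {
                "status": rng.integers(0, 2, size=n),
                "sex": rng.integers(1, 3, size=n),
                "e2_dosage": e2,
                "e4_dosage": e4,
            }
        )
        out = cohort_summary(pheno)
        assert set(out["characteristic"]) >= {"AD", "sex_male", "e3e3", "e3e4"}
        # genotype-class counts partition the cohort
        geno_rows = out[out["characteristic"].str.startswith("e")]
        assert geno_rows["all_n"].sum() == n
        # spot-check one row's Fisher p against scipy on the same 2x2
        row = out[out["characteristic"] == "e3e3"].iloc[0]
        n_ctrl = (pheno["status"] == 0).sum()
        n_case = (pheno["status"] == 1).sum()
        tab = [
            [row["control_n"], n_ctrl - row["control_n"]],
            [row["case_n"], n_case - row["case_n"]],
        ]
        assert row["p"] == pytest.approx(stats.fisher_exact(tab)[1], abs=1e-12)

    def test_empty_group_rejected(self):
        pheno = pd.DataFrame({"status": [1, 1], "sex": [1, 2]})
        with pytest.raises(ValueError, match="cases and controls"):
            cohort_summary(pheno)


class TestCompareModels:
    def test_identical_scores_identical_rows(self):
        res = CoxResult(beta=0.4, hr=1.49, se=0.05, p=1e-8, c_index=0.64, n=100, n_events=60)
        out = compare_models({"A": {"all": res}, "B": {"all": res}})
        a = out[out["model"] == "A"].drop(columns="model").reset_index(drop=True)
        b = out[out["model"] == "B"].drop(columns="model").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_stratum_noted(self):
        res = CoxResult(beta=0.4, hr=1.49, se=0.05, p=1e-8, c_index=0.64, n=100, n_events=60)
        out = compare_models({"A": {"all": res, "carriers": None}})
        note = out.loc[out["stratum"] == "carriers", "note"].iloc[0]
        assert "omitted" in note

    def test_grs_beats_reference_across_seeds(self, rng):
        """With real signal, the score model's C-index exceeds the
        reference model's in >= 18/20 seeds."""
        wins = 0
        for _ in range(20):
            score, pheno = survival_pheno(500, rng, logh=0.5)
            c_ref = fit_cox(None, pheno, covariates=["sex", "PC1"]).c_index
            c_grs = fit_cox(score, pheno, covariates=["sex", "PC1"]).c_index
            wins += c_grs > c_ref
        assert wins >= 18
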