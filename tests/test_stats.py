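"""Repeated-measures battery against independent oracles.

The sums-of-squares decomposition, sphericity estimates, pairwise tests and
contrasts are checked against brute-force computations written here (loops
over the raw data, no shared code path) and against pingouin.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from felicity import (EPOCH_LABELS, PowerSpec, achieved_power,
                      apriori_sample_size, cohens_f_from_eta,
                      mauchly_test, pairwise_bonferroni,
                      polynomial_contrasts, rm_anova, sphericity_epsilons)
from felicity.stats import LINEAR_COEF, QUADRATIC_COEF


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_rm_f(Y):
    """Brute-force within-subjects F via explicit sums of squares."""
    n, k = Y.shape
    grand = sum(Y[s][e] for s in range(n) for e in range(k)) / (n * k)
    ss_cond = n * sum((sum(Y[s][e] for s in range(n)) / n - grand) ** 2
                      for e in range(k))
    ss_subj = k * sum((sum(Y[s][e] for e in range(k)) / k - grand) ** 2
                      for s in range(n))
    ss_tot = sum((Y[s][e] - grand) ** 2 for s in range(n) for e in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    return (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))


def oracle_paired_p(a, b):
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    return 2 * sps.t.sf(abs(t), n - 1)


def oracle_contrast(Y, coef):
    scores = [sum(c * v for c, v in zip(coef, row)) for row in Y]
    n = len(scores)
    mean = sum(scores) / n
    var = sum((s - mean) ** 2 for s in scores) / (n - 1)
    t = mean / math.sqrt(var / n)
    return t ** 2


def _long(Y):
    rows = []
    for i, row in enumerate(Y):
        for lab, v in zip(EPOCH_LABELS, row):
            rows.append({"subject": f"s{i:02d}", "epoch": lab, "m": float(v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rmANOVA
# ---------------------------------------------------------------------------

class TestRmAnova:
    def test_f_matches_ss_oracle_on_toy_table(self, toy_table, toy_wide):
        b = rm_anova(toy_table, "score")
        assert b.F == pytest.approx(oracle_rm_f(toy_wide), rel=1e-12)
        assert b.df1 == 2 and b.df2 == 6

    def test_f_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            Y = rng.normal(0, 1, (8, 3)) + rng.normal(0, 2, (8, 1))
            b = rm_anova(_long(Y), "m")
            assert b.F == pytest.approx(oracle_rm_f(Y), rel=1e-10)
            assert 0 <= b.partial_eta_sq < 1

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        Y = rng.normal(0, 1, (12, 3)) + rng.normal(0, 1, (12, 1))
        tab = _long(Y)
        b = rm_anova(tab, "m")
        pg = pingouin.rm_anova(data=tab, dv="m", within="epoch",
                               subject="subject", correction=True)
        assert b.F == pytest.approx(float(pg["F"].iloc[0]), rel=1e-9)
        assert b.p_uncorrected == pytest.approx(float(pg["p_unc"].iloc[0]),
                                                rel=1e-9)
        assert b.epsilon_gg == pytest.approx(float(pg["eps"].iloc[0]), rel=1e-6)
        import scipy.stats as _sps
        p_gg = float(_sps.f.sf(b.F, 2 * b.epsilon_gg, 2 * 11 * b.epsilon_gg))
        assert p_gg == pytest.approx(float(pg["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_mauchly_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(13)
        Y = rng.normal(0, 1, (15, 3)) * np.array([1.0, 1.5, 3.0])
        W, p = mauchly_test(Y)
        spher = pingouin.sphericity(_long(Y), dv="m", within="epoch",
                                    subject="subject")
        assert W == pytest.approx(float(spher.W), rel=1e-9)
        assert p == pytest.approx(float(spher.pval), rel=1e-6)

    def test_identical_epoch_values_give_zero_f_degenerate(self):
        Y = np.array([[1.0, 1, 1], [2, 2, 2], [5, 5, 5], [3, 3, 3]])
        b = rm_anova(_long(Y), "m")
        assert b.F == 0.0 and b.degenerate

    def test_compound_symmetry_gives_unit_epsilon_and_w(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(0, 1, (20, 3))
        # recolour the sample so its covariance is exactly compound symmetric
        S = np.cov(Y, rowvar=False)
        cs = 0.5 * np.eye(3) + 0.5
        T = np.linalg.cholesky(cs) @ np.linalg.inv(np.linalg.cholesky(S))
        Y2 = (Y - Y.mean(axis=0)) @ T.T
        eps_gg, eps_hf = sphericity_epsilons(Y2)
        W, _ = mauchly_test(Y2)
        assert eps_gg == pytest.approx(1.0, abs=1e-10)
        assert eps_hf == 1.0
        assert W == pytest.approx(1.0, abs=1e-10)

    def test_epsilon_bounds_and_hf_ge_gg(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            Y = rng.normal(0, 1, (10, 3)) * rng.uniform(0.3, 3.0, 3)
            eps_gg, eps_hf = sphericity_epsilons(Y)
            assert 0.5 - 1e-12 <= eps_gg <= 1.0
            assert eps_gg <= eps_hf <= 1.0

    def test_corrected_df_shrink_by_epsilon(self):
        rng = np.random.default_rng(19)
        Y = rng.normal(0, 1, (10, 3)) * np.array([0.2, 1.0, 5.0])
        b = rm_anova(_long(Y), "m")
        if b.correction_used != "none":
            eps = b.epsilon_hf if b.correction_used == "HF" else b.epsilon_gg
            assert b.df1_corrected == pytest.approx(2 * eps)
            assert b.df2_corrected == pytest.approx(2 * 9 * eps)

    def test_k2_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(23)
        Y = rng.normal(0, 1, (12, 3)) + rng.normal(0, 1, (12, 1))
        tab = _long(Y)
        b = rm_anova(tab, "m", order=("relax", "stress"))
        t, _ = sps.ttest_rel(Y[:, 0], Y[:, 2])
        assert b.F == pytest.approx(t ** 2, rel=1e-9)

    def test_missing_cells_rejected(self, toy_table):
        broken = toy_table[~((toy_table.subject == "s1") &
                             (toy_table.epoch == "stress"))]
        with pytest.raises(ValueError, match="missing"):
            rm_anova(broken, "score")


# ---------------------------------------------------------------------------
# Pairwise and contrasts
# ---------------------------------------------------------------------------

class TestPairwise:
    def test_adjustment_is_capped_bonferroni(self):
        # p_adjusted = min(1, m * p_raw)
        rng = np.random.default_rng(29)
        Y = rng.normal(0, 1, (10, 3))
        res = pairwise_bonferroni(_long(Y), "m",
                                  pairs=(("relax", "happiness"),
                                         ("happiness", "stress"),
                                         ("relax", "stress")))
        for pw in res:
            assert pw.p_adjusted == pytest.approx(min(1.0, 3 * pw.p_raw))

    def test_matches_paired_difference_oracle(self, toy_table, toy_wide):
        res = pairwise_bonferroni(toy_table, "score",
                                  pairs=(("relax", "happiness"),
                                         ("happiness", "stress"),
                                         ("relax", "stress")))
        cols = {lab: toy_wide[:, i] for i, lab in enumerate(EPOCH_LABELS)}
        for pw in res:
            a, b = pw.pair
            expect = min(1.0, 3 * oracle_paired_p(cols[a], cols[b]))
            assert pw.p_adjusted == pytest.approx(expect, rel=1e-10)
            assert pw.mean_diff == pytest.approx(np.mean(cols[a] - cols[b]))

    def test_significance_implies_raw_below_alpha_over_m(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            Y = rng.normal(0, 1, (8, 3)) + np.array([0.0, 1.0, 1.0])
            for pw in pairwise_bonferroni(_long(Y), "m", alpha=0.05):
                if pw.significant:
                    assert pw.p_raw < 0.05 / 2

    def test_unknown_pair_rejected(self, toy_table):
        with pytest.raises(ValueError, match="unknown pair"):
            pairwise_bonferroni(toy_table, "score", pairs=(("relax", "bored"),))


class TestContrasts:
    def test_coefficients_orthonormal_and_sum_zero(self):
        assert abs(LINEAR_COEF.sum()) < 1e-12
        assert abs(QUADRATIC_COEF.sum()) < 1e-12
        assert abs(LINEAR_COEF @ QUADRATIC_COEF) < 1e-12

    def test_pure_linear_has_zero_quadratic(self):
        Y = np.array([[1.0, 2, 3]] * 4) + np.arange(4)[:, None]
        ct = polynomial_contrasts(_long(Y), "m")
        assert ct.quadratic_estimate == pytest.approx(0.0, abs=1e-12)
        assert ct.linear_estimate > 0

    def test_pure_quadratic_has_zero_linear(self):
        Y = np.array([[1.0, 3, 1]] * 4) + np.arange(4)[:, None]
        ct = polynomial_contrasts(_long(Y), "m")
        assert ct.linear_estimate == pytest.approx(0.0, abs=1e-12)
        assert ct.quadratic_estimate < 0  # middle epoch elevated

    def test_f_matches_per_subject_score_oracle(self, toy_table, toy_wide):
        ct = polynomial_contrasts(toy_table, "score")
        assert ct.linear_F == pytest.approx(
            oracle_contrast(toy_wide, LINEAR_COEF), rel=1e-10)
        assert ct.quadratic_F == pytest.approx(
            oracle_contrast(toy_wide, QUADRATIC_COEF), rel=1e-10)


# ---------------------------------------------------------------------------
# Effect size and power
# ---------------------------------------------------------------------------

class TestPower:
    def test_cohens_f_examples(self):
        assert cohens_f_from_eta(0.5) == pytest.approx(1.0)
        assert cohens_f_from_eta(0.0) == 0.0
        eta = 0.0625 / 1.0625
        assert cohens_f_from_eta(eta) == pytest.approx(0.25, rel=1e-12)
        with pytest.raises(ValueError):
            cohens_f_from_eta(1.0)

    def test_planning_table_reproduced(self):
        res = apriori_sample_size(PowerSpec(f=0.25, alpha=0.05,
                                            target_power=0.8, n_groups=1,
                                            k_measurements=3, rho=0.5,
                                            epsilon=1.0))
        assert res.N == 28
        assert res.lam == pytest.approx(10.5)
        assert (res.df1, res.df2) == (2.0, 54.0)
        assert res.F_crit == pytest.approx(3.168246, abs=1e-6)
        assert res.achieved_power == pytest.approx(0.8124546, abs=1e-7)

    def test_returned_n_is_minimal(self):
        spec = PowerSpec()
        res = apriori_sample_size(spec)
        assert achieved_power(spec, res.N - 1).achieved_power < spec.target_power

    def test_larger_effect_needs_fewer_subjects(self):
        assert apriori_sample_size(PowerSpec(f=0.4)).N < 28

    def test_power_monotone_in_n_f_rho(self):
        spec = PowerSpec()
        p = [achieved_power(spec, n).achieved_power for n in (27, 28, 29)]
        assert p[0] < p[1] < p[2]
        fvals = [achieved_power(PowerSpec(f=f), 28).achieved_power
                 for f in (0.15, 0.25, 0.4)]
        assert fvals[0] < fvals[1] < fvals[2]
        rvals = [achieved_power(PowerSpec(rho=r), 28).achieved_power
                 for r in (0.2, 0.5, 0.8)]
        assert rvals[0] < rvals[1] < rvals[2]

    def test_tiny_target_power_returns_minimal_feasible_n(self):
        res = apriori_sample_size(PowerSpec(target_power=1e-9))
        assert res.N == 2  # smallest N with positive denominator df

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            achieved_power(PowerSpec(), 1)

    def test_epsilon_scaled_lambda_option(self):
        res = achieved_power(PowerSpec(epsilon=0.8, lambda_uses_epsilon=True), 28)
        base = achieved_power(PowerSpec(epsilon=0.8), 28)
        assert res.lam == pytest.approx(base.lam * 0.8)
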