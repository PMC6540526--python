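"""Survival models, rank/enrichment tests, and measurement-panel clustering,
checked against closed forms and brute-force enumeration oracles."""

import math
import warnings
from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from repclonity import stats
from repclonity._errors import RepclonityError


def survival_frame(times, events, **extra):
    df = pd.DataFrame({"os_time": times, "os_event": events})
    for k, v in extra.items():
        df[k] = v
    df.index = [f"S{i}" for i in range(len(df))]
    return df


class TestCox:
    def test_two_group_exponential_recovers_rate_ratio(self):
        rng = np.random.default_rng(0)
        n = 2000
        group = rng.integers(0, 2, size=n)
        times = rng.exponential(1.0 / np.where(group == 1, 2.0, 1.0))
        clinical = survival_frame(times, np.ones(n, dtype=int))
        m = pd.Series(group.astype(float), index=clinical.index, name="grp")
        res = stats.fit_cox(m, clinical, zscore=False)
        assert 1.85 <= res.hazard_ratios["grp"] <= 2.15

    def test_independent_measurement_near_null(self):
        rng = np.random.default_rng(1)
        n = 1000
        clinical = survival_frame(rng.exponential(1.0, n), np.ones(n, dtype=int))
        m = pd.Series(rng.normal(size=n), index=clinical.index, name="x")
        res = stats.fit_cox(m, clinical)
        assert abs(res.coefs["x"]) < 0.15
        assert res.hazard_ratios["x"] == pytest.approx(
            math.exp(res.coefs["x"]), abs=1e-12)

    def test_constant_measurement_errors(self):
        clinical = survival_frame([1, 2, 3], [1, 1, 0])
        m = pd.Series([5.0, 5.0, 5.0], index=clinical.index, name="x")
        with pytest.raises(RepclonityError, match="constant"):
            stats.fit_cox(m, clinical)

    def test_no_events_errors(self):
        clinical = survival_frame([1, 2, 3], [0, 0, 0])
        m = pd.Series([1.0, 2.0, 3.0], index=clinical.index, name="x")
        with pytest.raises(RepclonityError, match="events"):
            stats.fit_cox(m, clinical)

    def test_covariate_encoding(self):
        rng = np.random.default_rng(2)
        n = 200
        clinical = survival_frame(
            rng.exponential(1.0, n), np.ones(n, dtype=int),
            age=rng.normal(60, 10, n),
            sex=rng.choice(["male", "female"], n),
            stage=rng.choice(["I", "II", "III"], n),
            tissue_site=rng.choice(["primary", "distant"], n))
        m = pd.Series(rng.normal(size=n), index=clinical.index, name="x")
        res = stats.fit_cox(m, clinical,
                            covariates=["tissue_site", "sex", "age", "stage"])
        # x + age + 1 sex dummy + 2 stage dummies + 1 site dummy
        assert len(res.terms) == 6
        assert "age" in res.terms


class TestNullLogLikelihood:
    def test_matches_risk_set_formula_without_ties(self):
        clinical = survival_frame([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1])
        res = stats.fit_cox_null(clinical)
        # risk sets at event times 1, 2, 4 are 4, 3, 1
        assert res.log_likelihood == pytest.approx(
            -(math.log(4) + math.log(3) + math.log(1)), abs=1e-12)

    def test_matches_heavily_penalized_fit(self):
        rng = np.random.default_rng(3)
        n = 120
        clinical = survival_frame(rng.exponential(1.0, n),
                                  rng.integers(0, 2, n) | 1)
        m = pd.Series(rng.normal(size=n), index=clinical.index, name="x")
        from lifelines import CoxPHFitter
        df = clinical.copy()
        df["x"] = m
        cph = CoxPHFitter(penalizer=1e6)
        cph.fit(df, duration_col="os_time", event_col="os_event")
        null = stats.fit_cox_null(clinical)
        assert cph.log_likelihood_ == pytest.approx(null.log_likelihood,
                                                    rel=1e-6)


class TestLikelihoodRatio:
    def _result(self, terms, ll, n=100, ev=60):
        s = pd.Series(np.zeros(len(terms)), index=terms)
        return stats.CoxResult(terms=list(terms), coefs=s, hazard_ratios=s,
                               standard_errors=s, wald_p=s, log_likelihood=ll,
                               n=n, n_events=ev)

    def test_identical_models_give_zero(self):
        full = self._result(["x"], -50.0)
        assert stats.likelihood_ratio_test(full, full).p_value == 1.0

    def test_chi_square_mapping_df1(self):
        full = self._result(["x", "y"], -50.0)
        reduced = self._result(["y"], -50.0 - 3.841 / 2)
        res = stats.likelihood_ratio_test(full, reduced)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.05, abs=1e-3)

    def test_non_nested_rejected(self):
        full = self._result(["x"], -50.0)
        other = self._result(["z"], -51.0)
        with pytest.raises(RepclonityError, match="nested"):
            stats.likelihood_ratio_test(full, other)

    def test_different_samples_rejected(self):
        full = self._result(["x", "y"], -50.0, n=100)
        reduced = self._result(["y"], -51.0, n=90, ev=55)
        with pytest.raises(RepclonityError, match="different samples"):
            stats.likelihood_ratio_test(full, reduced)

    def test_statistic_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(4)
        n = 300
        z = rng.normal(size=n)
        times = rng.exponential(np.exp(-0.4 * z))
        clinical = survival_frame(times, np.ones(n, dtype=int))
        m1 = pd.Series(z, index=clinical.index, name="x")
        m2 = pd.Series(5.0 * z + 3.0, index=clinical.index, name="x")
        null = stats.fit_cox_null(clinical)
        lrt1 = stats.likelihood_ratio_test(stats.fit_cox(m1, clinical), null)
        lrt2 = stats.likelihood_ratio_test(stats.fit_cox(m2, clinical), null)
        assert lrt1.statistic == pytest.approx(lrt2.statistic, rel=1e-8)

    def test_prognostic_measurement_power(self):
        rng = np.random.default_rng(5)
        hits = 0
        n = 800
        for _ in range(50):
            z = rng.normal(size=n)
            times = rng.exponential(np.exp(-math.log(1.5) * z))
            clinical = survival_frame(times, np.ones(n, dtype=int))
            m = pd.Series(z, index=clinical.index, name="x")
            lrt = stats.likelihood_ratio_test(
                stats.fit_cox(m, clinical), stats.fit_cox_null(clinical))
            hits += lrt.p_value < 0.05
        assert hits >= 40  # >= 80% power


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        clinical = survival_frame([5, 6, 7], [0, 0, 0],
                                  grp=["a", "a", "a"])
        curves = stats.km_curves(clinical, clinical["grp"])
        assert (curves["a"].to_numpy() == 1.0).all()

    def test_product_limit_arithmetic(self):
        clinical = survival_frame([1, 2], [1, 1], grp=["a", "a"])
        curve = stats.km_curves(clinical, clinical["grp"])["a"]
        assert curve.loc[1.0].item() == pytest.approx(0.5)
        assert curve.loc[2.0].item() == pytest.approx(0.0)

    def test_censoring_after_last_event_adds_no_step(self):
        clinical = survival_frame([1, 2, 9], [1, 1, 0], grp=["a", "a", "a"])
        curve = stats.km_curves(clinical, clinical["grp"])["a"]
        assert curve.loc[9.0].item() == pytest.approx(curve.loc[2.0].item())

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(1.0, 50).round(3)
        clinical = survival_frame(times, np.ones(50, dtype=int),
                                  grp=["a"] * 50)
        curve = stats.km_curves(clinical, clinical["grp"])["a"]
        for t in times:
            emp = (times > t).mean()
            assert curve.loc[t].item() == pytest.approx(emp, abs=1e-12)


def mann_whitney_enumeration(a, b, sided="two-sided"):
    """Exact p by enumerating all group-A rank assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    u_obs = sps.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic").statistic
    u_obs = min(u_obs, len(a) * len(b) - u_obs)
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        u = sum((x > y) for x in ga for y in gb)
        u = min(u, n_a * len(gb) - u)
        total += 1
        count += u <= u_obs + 1e-12
    return count / total


class TestMannWhitney:
    def test_disjoint_groups_exact_p(self):
        stat, p = stats.mann_whitney([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)  # 2/20 rankings

    def test_identical_groups_p_one(self):
        _, p = stats.mann_whitney([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_single_elements(self):
        _, p = stats.mann_whitney([1.0], [2.0])
        assert p == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(RepclonityError):
            stats.mann_whitney([], [1.0])

    def test_agrees_with_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.normal(size=4)
            b = rng.normal(size=5)
            _, p = stats.mann_whitney(a, b)
            assert p == pytest.approx(mann_whitney_enumeration(a, b), abs=1e-12)


class TestAnovaBH:
    def test_equal_values_give_zero_f(self):
        m = pd.DataFrame({"x": [1.0] * 6}, index=[f"S{i}" for i in range(6)])
        g = pd.Series(["a"] * 3 + ["b"] * 3, index=m.index)
        res = stats.anova_across_groups(m, g)
        assert res.loc["x", "F"] == 0.0 and res.loc["x", "p"] == 1.0

    def test_bh_step_up_arithmetic(self):
        q = stats.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_bh_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=30)
        q = stats.bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order_p = np.argsort(p)
        assert (np.diff(q[order_p]) >= -1e-15).all()

    def test_strong_shift_has_minimum_q(self):
        rng = np.random.default_rng(9)
        idx = [f"S{i}" for i in range(40)]
        g = pd.Series(["a"] * 20 + ["b"] * 20, index=idx)
        m = pd.DataFrame({
            "null1": rng.normal(size=40),
            "shifted": np.r_[rng.normal(size=20), rng.normal(10, 1, size=20)],
            "null2": rng.normal(size=40)}, index=idx)
        res = stats.anova_across_groups(m, g)
        assert res["q"].idxmin() == "shifted"


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.linspace(0, 3, 20)
        m = pd.DataFrame({"x": x, "expx": np.exp(x), "negx": -x})
        rho, _ = stats.spearman_matrix(m)
        assert rho.loc["x", "expx"] == pytest.approx(1.0)
        assert rho.loc["x", "negx"] == pytest.approx(-1.0)
        assert np.allclose(rho.to_numpy(), rho.to_numpy().T)
        assert np.allclose(np.diag(rho.to_numpy()), 1.0)

    def test_independent_pair_small_rho(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100)})
        rho, _ = stats.spearman_matrix(m)
        assert abs(rho.loc["a", "b"]) < 0.25

    def test_p_close_to_enumeration_at_n5(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        m = pd.DataFrame({"x": x, "y": y})
        rho, p = stats.spearman_matrix(m)
        r_obs = rho.loc["x", "y"]
        exact = np.mean([
            abs(sps.spearmanr(x, perm).statistic) >= abs(r_obs) - 1e-12
            for perm in permutations(y)])
        assert p.loc["x", "y"] == pytest.approx(exact, abs=0.06)

    def test_too_few_pairs_is_na_with_warning(self):
        m = pd.DataFrame({"a": [1.0, np.nan, 3.0, np.nan],
                          "b": [np.nan, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning):
            rho, _ = stats.spearman_matrix(m)
        assert np.isnan(rho.loc["a", "b"])


def fisher_enumeration(table, direction="greater"):
    """Hypergeometric tail by direct enumeration with math.comb."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = range(a, hi + 1) if direction == "greater" else range(lo, a + 1)
    return sum(math.comb(c1, k) * math.comb(n - c1, r1 - k) for k in ks) \
        / math.comb(n, r1)


class TestFisher:
    def test_perfect_enrichment(self):
        assert stats.fisher_one_sided([[3, 0], [0, 3]]) == pytest.approx(0.05)

    def test_balanced_table(self):
        assert stats.fisher_one_sided([[1, 1], [1, 1]]) == pytest.approx(5 / 6)

    def test_large_independent_table_not_significant(self):
        assert stats.fisher_one_sided([[50, 50], [50, 50]]) > 0.5

    def test_zero_margin_errors(self):
        with pytest.raises(RepclonityError, match="margin"):
            stats.fisher_one_sided([[0, 0], [1, 2]])

    def test_agrees_with_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t = rng.integers(1, 8, size=(2, 2))
            for direction in ("greater", "less"):
                assert stats.fisher_one_sided(t, direction) == pytest.approx(
                    fisher_enumeration(t.tolist(), direction), abs=1e-12)


class TestChiSquared:
    def test_outer_product_gives_zero(self):
        margins_r = np.array([0.3, 0.7])
        margins_c = np.array([0.2, 0.5, 0.3])
        table = 1000 * np.outer(margins_r, margins_c)
        stat, p = stats.chi_squared_enrichment(table)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_pearson_formula(self):
        stat, _ = stats.chi_squared_enrichment([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)

    def test_sparse_table_warns(self):
        with pytest.warns(UserWarning, match="expected count"):
            stats.chi_squared_enrichment([[2, 1], [1, 2]])

    def test_zero_table_errors(self):
        with pytest.raises(RepclonityError):
            stats.chi_squared_enrichment([[0, 0], [0, 0]])


class TestClusterMeasurements:
    def test_imputation_rules(self):
        m = pd.DataFrame({
            "IGHG_evenness": [0.5, np.nan, 0.2],
            "IGHG_total_count_norm": [np.nan, 10.0, 20.0],
            "IGHG_mean_v_identity": [90.0, np.nan, 96.0],
        }, index=["S1", "S2", "S3"])
        imputed = stats.impute_measurements(m)
        assert imputed.loc["S2", "IGHG_evenness"] == 1.0
        assert imputed.loc["S1", "IGHG_total_count_norm"] == 0.0
        assert imputed.loc["S2", "IGHG_mean_v_identity"] == 93.0  # median

    def test_rule_override(self):
        m = pd.DataFrame({"oddly_named": [1.0, np.nan]}, index=["a", "b"])
        imputed = stats.impute_measurements(m, rules={"oddly_named": "one"})
        assert imputed.loc["b", "oddly_named"] == 1.0

    def test_block_structure_recovered_at_k2(self):
        rng = np.random.default_rng(12)
        block_a = rng.normal(0.0, 0.1, size=(10, 4))
        block_b = rng.normal(8.0, 0.1, size=(10, 4))
        m = pd.DataFrame(np.vstack([block_a, block_b]),
                         index=[f"S{i}" for i in range(20)],
                         columns=list("wxyz"))
        result = stats.cluster_measurements(m, k=2)
        labels = result.sample_clusters
        assert labels.iloc[:10].nunique() == 1
        assert labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_scaling_unit_sd_then_median_center(self):
        rng = np.random.default_rng(13)
        m = pd.DataFrame({"a": rng.normal(5, 3, 30), "b": rng.normal(0, 1, 30)},
                         index=[f"S{i}" for i in range(30)])
        result = stats.cluster_measurements(m, k=2)
        assert result.scaled["a"].std(ddof=1) == pytest.approx(1.0)
        assert result.scaled["a"].median() == pytest.approx(0.0, abs=1e-12)

    def test_all_missing_measurement_dropped(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "dead": [np.nan] * 3,
                          "b": [3.0, 2.0, 1.0]})
        with pytest.warns(UserWarning, match="dead"):
            result = stats.cluster_measurements(m, k=2)
        assert "dead" not in result.scaled.columns
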