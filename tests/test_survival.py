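"""Eigen-genes, Cox fits, logrank, module scoring and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coexnet.containers import ExpressionMatrix, SurvivalTable, ValidationError
from coexnet.survival import (
    compute_eigengene,
    cox_univariate,
    logrank_median_split,
    logrank_test,
    module_score,
    rank_modules,
)

from conftest import logged_matrix, small_config, truth_hierarchy
from coexnet.simulate import simulate_cohort


def _em(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix([f"g{i:02d}" for i in range(values.shape[0])],
                            [f"s{j:02d}" for j in range(values.shape[1])],
                            values, "normalized")


def _surv(time, event):
    return SurvivalTable([f"s{i}" for i in range(len(time))],
                         np.asarray(time, float), np.asarray(event, int))


class TestEigenGene:
    def test_rank_one_module_recovers_shared_profile(self, rng):
        v = rng.normal(0, 1, 40)
        x = _em(np.vstack([2 * v + 1, -3 * v, 0.5 * v + 4, v]))
        eg = compute_eigengene(x, x.gene_ids, "m")
        prof = (v - v.mean()) / v.std()
        corr = np.corrcoef(eg.values, prof)[0, 1]
        assert abs(corr) > 0.9999
        assert eg.explained_variance_ratio > 0.999

    def test_sign_convention_positive_vs_mean_profile(self, rng):
        v = rng.normal(0, 1, (10, 50))
        x = _em(v)
        eg = compute_eigengene(x, x.gene_ids, "m")
        mean_profile = ((v - v.mean(1, keepdims=True)) / v.std(1, keepdims=True)).mean(0)
        assert np.dot(eg.values, mean_profile) >= 0

    def test_matches_covariance_eigendecomposition(self, rng):
        v = rng.normal(0, 1, (10, 50))
        x = _em(v)
        eg = compute_eigengene(x, x.gene_ids, "m")
        z = (v - v.mean(1, keepdims=True)) / v.std(1, keepdims=True)
        evals, evecs = np.linalg.eigh(z.T @ z)
        pc1 = evecs[:, -1]
        if np.dot(pc1, z.mean(0)) < 0:
            pc1 = -pc1
        assert np.abs(eg.values - pc1).max() < 1e-8

    def test_gene_order_invariance(self, rng):
        v = rng.normal(0, 1, (8, 30))
        x = _em(v)
        perm = rng.permutation(8)
        x2 = ExpressionMatrix([x.gene_ids[i] for i in perm], x.sample_ids,
                              v[perm], "normalized")
        e1 = compute_eigengene(x, x.gene_ids, "m")
        e2 = compute_eigengene(x2, x.gene_ids, "m")
        assert np.abs(e1.values - e2.values).max() < 1e-10

    def test_anticorrelated_halves(self, rng):
        v = rng.normal(0, 1, 40)
        x = _em(np.vstack([v, v, -v + 0.1 * rng.normal(0, 1, 40),
                           -v + 0.1 * rng.normal(0, 1, 40)]))
        eg = compute_eigengene(x, x.gene_ids, "m")
        assert eg.explained_variance_ratio < 1.0

    def test_too_few_genes(self, rng):
        x = _em(rng.normal(0, 1, (5, 20)))
        with pytest.raises(ValidationError):
            compute_eigengene(x, ["g00", "g01"], "m")


class TestCox:
    def test_zero_variance_covariate_rejected(self):
        s = _surv([1, 2, 3, 4], [1, 1, 1, 0])
        with pytest.raises(ValidationError, match="zero-variance"):
            cox_univariate(np.ones(4), s)

    def test_agreement_with_independent_implementation(self, rng):
        from lifelines import CoxPHFitter
        worst_beta = worst_p = 0.0
        for rep in range(50):
            n = int(rng.integers(40, 120))
            z = rng.standard_normal(n)
            beta = rng.uniform(-1, 1)
            t = rng.exponential(1 / (0.1 * np.exp(beta * z)))
            if rep % 3 == 0:
                t = np.ceil(t * 2) / 2 + 0.5  # induce ties
            c = rng.exponential(10, n)
            time = np.maximum(np.minimum(t, c), 1e-6)
            event = (t <= c).astype(int)
            if event.sum() < 3:
                continue
            s = _surv(time, event)
            res = cox_univariate(z, s)
            cph = CoxPHFitter()
            cph.fit(pd.DataFrame({"T": time, "E": event, "z": z}), "T", "E",
                    fit_options={"precision": 1e-9})
            worst_beta = max(worst_beta, abs(res.statistic - cph.params_["z"]))
            worst_p = max(worst_p, abs(res.p_value - cph.summary.loc["z", "p"]))
        assert worst_beta < 1e-4 and worst_p < 1e-4

    def test_null_p_uniform(self, rng):
        from scipy import stats
        ps = []
        for _ in range(400):
            n = 200
            z = rng.standard_normal(n)
            t = rng.exponential(10, n)
            c = rng.exponential(25, n)
            s = _surv(np.maximum(np.minimum(t, c), 1e-6), (t <= c).astype(int))
            ps.append(cox_univariate(z, s).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_beta_recovery(self, rng):
        betas = []
        for _ in range(50):
            n = 400
            z = rng.standard_normal(n)
            t = rng.exponential(1 / (0.1 * np.exp(0.8 * z)))
            c = rng.exponential(25, n)
            s = _surv(np.maximum(np.minimum(t, c), 1e-6), (t <= c).astype(int))
            betas.append(cox_univariate(z, s).statistic)
        betas = np.array(betas)
        assert abs(betas.mean() - 0.8) < 0.05
        assert np.mean(np.abs(betas - 0.8) < 0.15) > 0.8

    def test_monotone_likelihood_flagged(self):
        # covariate perfectly ordered with event times: monotone likelihood
        n = 12
        z = np.arange(n, dtype=float)
        time = np.arange(1, n + 1, dtype=float)
        s = _surv(time, np.ones(n))
        res = cox_univariate(-z, s)
        assert res.flagged and 0 < res.p_value <= 1


class TestLogrank:
    def test_identical_curves_give_zero_statistic(self):
        time = np.array([1, 2, 3, 4, 1, 2, 3, 4], float)
        event = np.ones(8, int)
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        stat, p = logrank_test(time, event, group)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_worked_o_minus_e_table(self):
        # times {1,2,3,4}, all events, group1 = {1,2}:
        # O1=2, E1=1/2+1/3, V=1/4+2/9 -> chi2=(7/6)^2/(17/36)=49/17
        stat, p = logrank_test(np.array([1, 2, 3, 4.]), np.ones(4, int),
                               np.array([1, 1, 0, 0]))
        assert stat == pytest.approx(49 / 17, abs=1e-12)

    def test_matches_independent_implementation(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank
        for rep in range(20):
            n = int(rng.integers(20, 60))
            time = np.maximum(rng.exponential(5, n), 1e-3)
            if rep % 2:
                time = np.ceil(time) + 1
            event = rng.integers(0, 2, n)
            group = rng.integers(0, 2, n)
            if event.sum() == 0 or len(set(group)) < 2:
                continue
            stat, p = logrank_test(time, event, group)
            ref = ll_logrank(time[group == 0], time[group == 1],
                             event[group == 0], event[group == 1])
            assert stat == pytest.approx(ref.test_statistic, abs=1e-10)
            assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_asymptotic_p_matches_permutation_oracle(self, rng):
        n = 60
        z = rng.standard_normal(n)
        t = rng.exponential(1 / (0.2 * np.exp(0.5 * z)))
        c = rng.exponential(8, n)
        time = np.maximum(np.minimum(t, c), 1e-6)
        event = (t <= c).astype(int)
        group = (z > np.median(z)).astype(int)
        stat_obs, p_asym = logrank_test(time, event, group)
        n_perm = 2000
        exceed = 0
        for _ in range(n_perm):
            stat, _ = logrank_test(time, event, rng.permutation(group))
            exceed += stat >= stat_obs
        p_perm = (exceed + 1) / (n_perm + 1)
        mc_sd = np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / n_perm)
        assert abs(p_perm - p_asym) < max(4 * mc_sd, 0.02)

    def test_median_split_ties_go_low(self):
        s = _surv([5, 6, 7, 8, 9], [1, 1, 1, 1, 1])
        z = np.array([1.0, 2.0, 2.0, 3.0, 4.0])  # median 2 -> low group size 3
        res = logrank_median_split(z, s)
        assert res.n_samples == 5 and 0 < res.p_value <= 1

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(np.array([1, 2.]), np.array([0, 0]), np.array([0, 1]))


class TestModuleScore:
    def test_printed_formula(self):
        assert module_score([0.01, 0.001]).ms == pytest.approx(5.0, abs=1e-12)

    def test_no_signal(self):
        assert module_score([1.0, 1.0, 1.0]).ms == 0.0

    def test_order_invariance(self, rng):
        ps = list(rng.uniform(1e-8, 1, 10))
        assert module_score(ps).ms == pytest.approx(module_score(ps[::-1]).ms)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            module_score([0.5, 0.0])
        with pytest.raises(ValidationError):
            module_score([1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=6),
           st.integers(0, 5), st.floats(0.01, 0.99))
    def test_monotone_decreasing_in_each_p(self, ps, idx, shrink):
        # lowering any single p-value strictly increases the score
        idx = idx % len(ps)
        base = module_score(ps).ms
        smaller = list(ps)
        smaller[idx] = ps[idx] * shrink
        assert module_score(smaller).ms > base


class TestRankModules:
    def test_planted_driver_module_ranks_first(self):
        hits = 0
        for seed in range(10):
            cohort = simulate_cohort(small_config(seed=seed))
            h = truth_hierarchy(cohort.truth)
            tab = rank_modules(h, logged_matrix(cohort), cohort.survival)
            hits += tab.iloc[0]["module_id"] == "P1_C1"
        assert hits >= 9

    def test_single_test_matches_p_ordering(self):
        cohort = simulate_cohort(small_config(seed=3))
        h = truth_hierarchy(cohort.truth)
        tab = rank_modules(h, logged_matrix(cohort), cohort.survival, tests=("cox",))
        ps = [float(s.split("=")[1]) for s in tab["p_values"]]
        assert ps == sorted(ps)

    def test_row_order_invariance(self):
        cohort = simulate_cohort(small_config(seed=4))
        h = truth_hierarchy(cohort.truth)
        surv = cohort.survival
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(surv))
        shuffled = SurvivalTable([surv.sample_ids[i] for i in perm],
                                 surv.time[perm], surv.event[perm])
        t1 = rank_modules(h, logged_matrix(cohort), surv)
        t2 = rank_modules(h, logged_matrix(cohort), shuffled)
        pd.testing.assert_frame_equal(t1, t2)
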