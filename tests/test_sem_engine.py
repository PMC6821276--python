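import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import graphsem as gs
from graphsem.sem_engine import RAMSpec, SemError, fit_indices
from tests.conftest import cfa_sim_spec


def path_graph(*edges, nodes=None, fixed=None):
    node_ids = nodes or sorted({v for e in edges for v in e})
    edge_dicts = []
    for k, (src, dst) in enumerate(edges):
        d = {"src": src, "dst": dst}
        if fixed is not None:
            d["fixed_value"] = fixed[k]
        edge_dicts.append(d)
    return gs.build_graph({"nodes": [{"id": n} for n in node_ids],
                           "edges": edge_dicts})


def continuous_cohort(name="T", **columns):
    n = len(next(iter(columns.values())))
    return gs.Cohort.from_columns(
        name, [f"s{i:04d}" for i in range(n)],
        {k: np.asarray(v, float) for k, v in columns.items()},
        [gs.Variable(k, "Clinical", "continuous") for k in columns],
    )


class TestCompile:
    def test_single_path_parameter_count(self, regression_cohort):
        g = path_graph(("X1", "Y"), nodes=["X1", "Y"])
        ram, data = gs.compile_graph(g, regression_cohort)
        a_free = [p for p in ram.free if p.matrix == "A"]
        s_free = [p for p in ram.free if p.matrix == "S"]
        assert len(a_free) == 1 and len(s_free) == 2
        assert ram.df() == 0
        assert len(data) == regression_cohort.n_samples

    def test_cfa_parameter_count(self, cfa_graph):
        coh, _ = gs.simulate_cohort(cfa_sim_spec(0, n_samples=50))
        # pure 3-indicator factor: 2 free loadings (first fixed to 1),
        # 3 residual variances, 1 factor variance
        g = gs.build_graph({
            "nodes": [{"id": "CellCycle", "kind": "latent"},
                      {"id": "CCNB1.RNA"}, {"id": "PCNA.RNA"}, {"id": "MKI67.RNA"}],
            "edges": [{"src": "CellCycle", "dst": d, "type": "loading"}
                      for d in ("CCNB1.RNA", "PCNA.RNA", "MKI67.RNA")]})
        ram, _ = gs.compile_graph(g, coh)
        assert len([p for p in ram.free if p.op == "=~"]) == 2
        assert len([p for p in ram.free if p.op == "~~"]) == 4
        assert ram.df() == 0

    def test_survival_only_model_flagged(self, tiny_cohort):
        g = path_graph(("TP53.Mut", "OS.Survival"), nodes=["TP53.Mut", "OS.Survival"])
        ram, _ = gs.compile_graph(g, tiny_cohort)
        # the mutation remains in the covariance part; survival is excluded
        assert ram.survival_nodes == ["OS.Survival"]
        assert "OS.Survival" not in ram.var_order


class TestImpliedCovariance:
    def test_no_paths_diagonal(self):
        ram = RAMSpec(["a", "b"], 2, np.zeros((2, 2)),
                      np.diag([2.0, 3.0]), [], [], [], {})
        assert np.allclose(gs.implied_covariance(ram, np.array([])),
                           np.diag([2.0, 3.0]))

    def test_single_path_symbolic(self):
        # y = b x with var(x)=phi, resid(y)=psi:
        # Sigma = [[phi, b phi], [b phi, b^2 phi + psi]]
        b, phi, psi = 0.7, 2.0, 0.5
        A = np.array([[0.0, 0.0], [b, 0.0]])
        S = np.diag([phi, psi])
        ram = RAMSpec(["x", "y"], 2, A, S, [], [], [], {})
        sigma = gs.implied_covariance(ram, np.array([]))
        expected = np.array([[phi, b * phi], [b * phi, b * b * phi + psi]])
        assert np.allclose(sigma, expected)

    def test_two_cycle_matches_series_oracle(self):
        a, b = 0.5, 0.4
        A = np.array([[0.0, b], [a, 0.0]])
        S = np.diag([1.0, 1.0])
        ram = RAMSpec(["x", "y"], 2, A, S, [], [], [], {})
        sigma = gs.implied_covariance(ram, np.array([]))
        B = sum(np.linalg.matrix_power(A, k) for k in range(200))
        assert np.allclose(sigma, B @ S @ B.T, atol=1e-8)


class TestDiscrepancy:
    def test_zero_at_saturation(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert gs.ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_bivariate_half_correlation(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert gs.ml_discrepancy(S, np.eye(2)) == pytest.approx(-np.log(0.75))

    def test_univariate_closed_form(self):
        assert gs.ml_discrepancy(np.array([[2.0]]), np.array([[1.0]])) == \
            pytest.approx(1.0 - np.log(2.0))

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nonnegative_everywhere(self, seed):
        rng = np.random.default_rng(seed)
        L1, L2 = rng.normal(size=(2, 3, 3))
        S = L1 @ L1.T + np.eye(3)
        Sig = L2 @ L2.T + np.eye(3)
        assert gs.ml_discrepancy(S, Sig) >= -1e-12


class TestFit:
    def test_just_identified_equals_least_squares(self, regression_cohort):
        g = path_graph(("X1", "Y"), ("X2", "Y"), nodes=["X1", "X2", "Y"])
        fit = gs.fit_graph(g, regression_cohort)
        X = np.column_stack([np.ones(regression_cohort.n_samples),
                             regression_cohort.values("X1"),
                             regression_cohort.values("X2")])
        y = regression_cohort.values("Y")
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.estimate("Y", "~", "X1").estimate == pytest.approx(beta[1], abs=1e-6)
        assert fit.estimate("Y", "~", "X2").estimate == pytest.approx(beta[2], abs=1e-6)
        assert fit.indices.chisq == pytest.approx(0.0, abs=1e-6)

    def test_z_close_to_classical_t(self, regression_cohort):
        import statsmodels.api as sm
        g = path_graph(("X1", "Y"), ("X2", "Y"), nodes=["X1", "X2", "Y"])
        fit = gs.fit_graph(g, regression_cohort)
        X = sm.add_constant(np.column_stack([regression_cohort.values("X1"),
                                             regression_cohort.values("X2")]))
        ols = sm.OLS(regression_cohort.values("Y"), X).fit()
        for name, tval in zip(("X1", "X2"), ols.tvalues[1:]):
            z = fit.estimate("Y", "~", name).z
            assert z == pytest.approx(tval, rel=0.02)

    def test_saturated_two_variable_model(self, regression_cohort):
        g = gs.build_graph({"nodes": [{"id": "X1"}, {"id": "X2"}], "edges": []})
        ram, data = gs.compile_graph(g, regression_cohort)
        fit = gs.fit_sem(ram, data)
        assert gs.ml_discrepancy(fit.sample_cov, fit.implied_cov) < 1e-10
        assert fit.indices.srmr < 1e-6

    def test_cfa_recovers_simulation_truth_within_3se(self, cfa_graph):
        coh, _ = gs.simulate_cohort(cfa_sim_spec(42))
        fit = gs.fit_graph(cfa_graph, coh)
        truth = {("CellCycle", "~", "TP53.Mut"): 0.8,
                 ("CellCycle", "=~", "PCNA.RNA"): 0.8,
                 ("CellCycle", "=~", "MKI67.RNA"): 0.6}
        for key, true_val in truth.items():
            est = fit.estimate(*key)
            assert abs(est.estimate - true_val) < 3 * est.se

    def test_nonidentified_model_rejected(self):
        # 2 observed, 1 free path + 2 variances + 1 covariance = 4 > 3 moments
        g = gs.build_graph({"nodes": [{"id": "X"}, {"id": "Y"}],
                            "edges": [{"src": "X", "dst": "Y"},
                                      {"src": "X", "dst": "Y", "type": "covariance"}]})
        rng = np.random.default_rng(0)
        coh = continuous_cohort(X=rng.normal(size=50), Y=rng.normal(size=50))
        with pytest.raises(SemError, match="identified"):
            gs.compile_graph(g, coh)

    def test_chisq_invariant_to_sample_order(self, regression_cohort):
        g = path_graph(("X1", "Y"), nodes=["X1", "Y"])
        ram, data = gs.compile_graph(g, regression_cohort)
        fit1 = gs.fit_sem(ram, data)
        rng = np.random.default_rng(1)
        shuffled = data.iloc[rng.permutation(len(data))]
        fit2 = gs.fit_sem(ram, shuffled)
        assert fit1.indices.chisq == pytest.approx(fit2.indices.chisq, abs=1e-8)
        assert fit1.indices.srmr == pytest.approx(fit2.indices.srmr, abs=1e-10)

    def test_srmr_invariant_to_rescaling(self):
        rng = np.random.default_rng(4)
        n = 300
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.4 * m + rng.normal(size=n)
        g = path_graph(("X", "M"), ("M", "Y"), nodes=["X", "M", "Y"])
        fit1 = gs.fit_graph(g, continuous_cohort(X=x, M=m, Y=y))
        fit2 = gs.fit_graph(g, continuous_cohort(X=10 * x, M=m, Y=0.1 * y))
        assert fit1.indices.srmr == pytest.approx(fit2.indices.srmr, abs=1e-6)


class TestFitIndices:
    def test_tli_arithmetic_identity(self):
        S = np.eye(2)
        tli, _, _, _ = fit_indices(10.0, 10, 100.0, 10, 101, S, S)
        assert tli == pytest.approx((10.0 - 1.0) / (10.0 - 1.0))

    def test_srmr_zero_at_saturation(self):
        S = np.array([[1.0, 0.4], [0.4, 2.0]])
        _, _, _, srmr = fit_indices(5.0, 1, 50.0, 1, 100, S, S)
        assert srmr == 0.0

    def test_rmsea_formula(self):
        S = np.eye(2)
        _, _, rmsea, _ = fit_indices(50.0, 10, 500.0, 45, 101, S, S)
        assert rmsea == pytest.approx(np.sqrt(40.0 / 1000.0))

    def test_saturated_df0_not_applicable(self):
        S = np.eye(2)
        tli, cfi, rmsea, _ = fit_indices(0.0, 0, 50.0, 1, 100, S, S)
        assert tli is None and rmsea is None and cfi == 1.0


class TestBaseline:
    def test_bivariate_closed_form(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        chisq, df = gs.baseline_chisq(S, 101)
        assert chisq == pytest.approx(-100 * np.log(0.75), abs=1e-3)
        assert df == 1

    def test_identity_correlation_zero(self):
        assert gs.baseline_chisq(np.diag([2.0, 5.0]), 50)[0] == pytest.approx(0.0)

    def test_matches_explicit_variances_only_fit(self, regression_cohort):
        g = gs.build_graph({"nodes": [{"id": v} for v in ("X1", "X2", "Y")],
                            "edges": [], "auto_covary_exogenous": False})
        ram, data = gs.compile_graph(g, regression_cohort)
        fit = gs.fit_sem(ram, data)
        chisq_b, _ = gs.baseline_chisq(fit.sample_cov, len(data))
        assert fit.indices.chisq == pytest.approx(chisq_b, abs=1e-6)


class TestEffects:
    def chain_ram(self):
        g = path_graph(("X", "M"), ("M", "Y"), ("X", "Y"),
                       nodes=["X", "M", "Y"], fixed=[0.5, 0.4, 0.1])
        coh = continuous_cohort(X=np.arange(5.0), M=np.arange(5.0) * 2,
                                Y=np.arange(5.0) * 3)
        ram, _ = gs.compile_graph(g, coh)
        return ram, np.array([p.start for p in ram.free])

    def test_mediation_chain_path_tracing(self):
        ram, theta = self.chain_ram()
        direct, indirect, total = gs.effect_decomposition(ram, theta, "X", "Y")
        assert (direct, indirect, total) == \
            (pytest.approx(0.1), pytest.approx(0.2), pytest.approx(0.3))

    def test_no_path_all_zero(self):
        ram, theta = self.chain_ram()
        assert gs.effect_decomposition(ram, theta, "Y", "X") == (0.0, 0.0, 0.0)

    def test_two_cycle_geometric_series(self):
        A = np.array([[0.0, 0.4], [0.5, 0.0]])
        ram = RAMSpec(["X", "Y"], 2, A, np.eye(2), [], [], [], {})
        direct, indirect, total = gs.effect_decomposition(ram, np.array([]), "X", "Y")
        assert total == pytest.approx(0.5 / (1 - 0.2))
        assert direct == pytest.approx(0.5)

    def test_unstable_cycle_rejected(self):
        A = np.array([[0.0, 1.1], [1.1, 0.0]])
        ram = RAMSpec(["X", "Y"], 2, A, np.eye(2), [], [], [], {})
        with pytest.raises(SemError, match="unstable"):
            gs.effect_decomposition(ram, np.array([]), "X", "Y")

    def test_direct_plus_indirect_equals_total(self):
        ram, theta = self.chain_ram()
        d, i, t = gs.effect_decomposition(ram, theta, "X", "Y")
        assert d + i == t


class TestFactorScores:
    def test_scores_have_mean_zero(self, cfa_graph):
        coh, _ = gs.simulate_cohort(cfa_sim_spec(3, n_samples=800))
        fit = gs.fit_graph(cfa_graph, coh)
        ram, data = gs.compile_graph(cfa_graph, coh)
        scores = gs.factor_scores(fit, data)
        assert abs(scores["CellCycle"].mean()) < 1e-10

    def test_symmetric_indicators_give_mean_proportional_scores(self):
        # with exactly equal loadings and residual variances the regression
        # scoring weights are symmetric, so the score is a multiple of the
        # per-sample indicator mean
        import pandas as pd
        from graphsem.sem_engine import FitResult, FreeParam
        A = np.zeros((4, 4))
        A[0:3, 3] = 0.8
        S = np.diag([0.25, 0.25, 0.25, 0.0])
        ram = RAMSpec(["I1", "I2", "I3", "F"], 3, A, S,
                      [FreeParam("S", 3, 3, "F", "~~", "F", 1.0)], ["F"], [], {})
        fit = FitResult([], None, None, np.eye(3), ram, np.array([1.0]))
        rng = np.random.default_rng(9)
        data = pd.DataFrame(rng.normal(size=(50, 3)), columns=["I1", "I2", "I3"])
        scores = gs.factor_scores(fit, data)["F"].to_numpy()
        means = data.to_numpy().mean(axis=1)
        means = means - means.mean()
        corr = np.corrcoef(scores, means)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-12)

    def test_single_perfect_indicator_degenerate_identity(self):
        # loading fixed to 1, zero residual variance: score == centered value
        A = np.array([[0.0, 1.0], [0.0, 0.0]])
        S_fixed = np.zeros((2, 2))
        from graphsem.sem_engine import FreeParam, FitResult
        ram = RAMSpec(["y", "F"], 1, A, S_fixed,
                      [FreeParam("S", 1, 1, "F", "~~", "F", 1.0)],
                      ["F"], [], {})
        theta = np.array([2.0])
        import pandas as pd
        y = pd.DataFrame({"y": [1.0, 2.0, 3.0, 6.0]})
        fit = FitResult([], None, None, np.array([[1.0]]), ram, theta)
        scores = gs.factor_scores(fit, y)["F"].to_numpy()
        assert np.allclose(scores, y["y"] - y["y"].mean())


class TestMultiCohort:
    def test_same_cohort_twice_identical_rows(self, regression_cohort):
        g = path_graph(("X1", "Y"), nodes=["X1", "Y"])
        table = gs.fit_multi_cohort(g, [regression_cohort, regression_cohort])
        a = table[table.index < len(table) // 2].reset_index(drop=True)
        b = table[table.index >= len(table) // 2].reset_index(drop=True)
        assert np.allclose(a["estimate"], b["estimate"])

    def test_missing_variable_cohort_skipped(self, regression_cohort, tiny_cohort):
        g = path_graph(("X1", "Y"), nodes=["X1", "Y"])
        with pytest.warns(UserWarning, match="lacks"):
            table = gs.fit_multi_cohort(g, [regression_cohort, tiny_cohort])
        assert set(table["cohort"]) == {"REG"}

    def test_z_monotone_in_effect_size(self):
        cohorts = []
        for name, beta in (("C0", 0.0), ("C3", 0.3), ("C6", 0.6)):
            spec = gs.SimSpec(
                n_samples=500, seed=21, name=name,
                structural={"X.RNA": {"parents": {}, "noise_sd": 1.0},
                            "Y.RNA": {"parents": {"X.RNA": beta}, "noise_sd": 1.0}})
            cohorts.append(gs.simulate_cohort(spec)[0])
        g = path_graph(("X.RNA", "Y.RNA"), nodes=["X.RNA", "Y.RNA"])
        table = gs.fit_multi_cohort(g, cohorts)
        zs = table[table["op"] == "~"].set_index("cohort")["z"]
        assert zs["C0"] < zs["C3"] < zs["C6"]
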