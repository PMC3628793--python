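import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pcpspath import (
    PathAnalysis,
    PathModel,
    ValidationError,
    build_path_model,
    effect_decomposition,
    group_preselect,
    ols_aic,
    path_coefficients,
    randomization_pvalues,
    residualize,
    select_subset,
)
from pcpspath.path import PathEdge


def _geo(rng, n=60):
    return pd.DataFrame({
        "latitude": rng.uniform(-50, 50, n),
        "longitude": rng.uniform(-120, -40, n),
        "area": np.exp(rng.normal(10, 1, n)),
    }, index=[f"s{i}" for i in range(n)])


class TestResidualize:
    def test_exact_linear_in_latitude_gives_zero(self, rng):
        geo = _geo(rng)
        y = pd.Series(2.0 * geo["latitude"] - 3, index=geo.index, name="y")
        r = residualize(y, geo)
        assert np.max(np.abs(r)) < 1e-10

    def test_orthogonal_variable_just_centered(self, rng):
        geo = _geo(rng)
        # build a variable exactly orthogonal to intercept + geography
        X = np.column_stack([np.ones(len(geo)), geo.to_numpy()])
        z = rng.normal(size=len(geo))
        z -= X @ np.linalg.lstsq(X, z, rcond=None)[0]
        y = pd.Series(z + 5.0, index=geo.index, name="y")
        r = residualize(y, geo)
        assert np.allclose(r, z, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        geo = _geo(rng)
        y = pd.Series(rng.normal(size=len(geo)), index=geo.index, name="y")
        X = np.column_stack([np.ones(len(geo)), geo.to_numpy()])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y.to_numpy()
        assert np.allclose(residualize(y, geo), y.to_numpy() - X @ beta, atol=1e-8)

    def test_residuals_orthogonal_to_geography(self, rng):
        geo = _geo(rng)
        y = pd.Series(rng.normal(size=len(geo)), index=geo.index, name="y")
        r = residualize(y, geo).to_numpy()
        for col in geo.columns:
            c = geo[col] - geo[col].mean()
            assert abs(np.corrcoef(r, c)[0, 1]) < 1e-8

    def test_collinear_geography_rejected(self, rng):
        geo = _geo(rng)
        geo["area"] = 2 * geo["latitude"]
        y = pd.Series(rng.normal(size=len(geo)), index=geo.index, name="y")
        with pytest.raises(ValidationError, match="collinear"):
            residualize(y, geo)


class TestOlsAic:
    def test_null_model_uses_total_sum_of_squares(self, rng):
        y = rng.normal(size=50)
        n = len(y)
        tss = ((y - y.mean()) ** 2).sum()
        assert ols_aic(y) == pytest.approx(n * np.log(tss / n) + 4)

    def test_matches_statsmodels_rss(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        y = rng.normal(size=50)
        X = rng.normal(size=(50, 3))
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        expected = 50 * np.log(fit.ssr / 50) + 2 * (3 + 2)
        assert ols_aic(y, X) == pytest.approx(expected, abs=1e-8)

    def test_perfect_fit_guard(self, rng):
        y = rng.normal(size=30)
        assert ols_aic(y, y[:, None]) == -np.inf

    def test_noise_predictor_usually_increases_aic(self):
        rng = np.random.default_rng(11)
        n, hits = 500, 0
        reps = 200
        for _ in range(reps):
            y = rng.normal(size=n)
            x = rng.normal(size=n)
            if ols_aic(y, x[:, None]) > ols_aic(y):
                hits += 1
        assert hits / reps >= 0.8

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValidationError):
            ols_aic(rng.normal(size=4), rng.normal(size=(4, 2)))


class TestSelectSubset:
    def _oracle(self, y, candidates):
        best = None
        for size in range(len(candidates.columns) + 1):
            for combo in itertools.combinations(sorted(candidates.columns), size):
                X = candidates[list(combo)].to_numpy() if combo else None
                aic = ols_aic(y, X)
                if best is None or aic < best[1] - 1e-9:
                    best = (combo, aic)
        return best[0]

    def test_two_candidate_case_equals_four_model_comparison(self, rng):
        y = rng.normal(size=40)
        C = pd.DataFrame(rng.normal(size=(40, 2)), columns=["x1", "x2"])
        assert select_subset(y, C).selected == self._oracle(y, C)

    def test_agrees_with_exhaustive_oracle_many_instances(self, rng):
        for _ in range(50):
            m = rng.integers(1, 5)
            n = 30
            C = pd.DataFrame(rng.normal(size=(n, m)),
                             columns=[f"x{j}" for j in range(m)])
            beta = rng.normal(size=m) * (rng.random(m) < 0.5)
            y = C.to_numpy() @ beta + rng.normal(size=n)
            assert select_subset(y, C).selected == self._oracle(y, C)

    def test_strong_signal_recovered(self):
        # the true driver is always kept; the exact singleton is the modal
        # outcome (each pure-noise variable enters with the classic ~16%
        # chance implied by the AIC penalty of 2)
        rng = np.random.default_rng(3)
        kept, exact = 0, 0
        reps = 200
        for _ in range(reps):
            n = 200
            C = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x1", "x2", "x3"])
            y = 2.0 * C["x1"].to_numpy() + rng.normal(size=n)
            sel = select_subset(y, C).selected
            kept += "x1" in sel
            exact += sel == ("x1",)
        assert kept / reps >= 0.99
        assert exact / reps >= 0.55

    def test_null_prefers_empty_model_most_often(self):
        rng = np.random.default_rng(4)
        empty = 0
        reps = 100
        counts = {}
        for _ in range(reps):
            C = pd.DataFrame(rng.normal(size=(150, 3)), columns=["x1", "x2", "x3"])
            sel = select_subset(rng.normal(size=150), C).selected
            counts[sel] = counts.get(sel, 0) + 1
            if sel == ():
                empty += 1
        assert counts[()] == max(counts.values())

    def test_candidate_bound(self, rng):
        C = pd.DataFrame(rng.normal(size=(40, 21)))
        C.columns = [f"x{j}" for j in range(21)]
        with pytest.raises(ValidationError, match="20"):
            select_subset(rng.normal(size=40), C)


class TestGroupPreselect:
    def test_driver_group_retains_driver(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 60
        for _ in range(reps):
            n = 150
            groups = {
                "anthromes": pd.DataFrame(
                    rng.normal(size=(n, 3)), columns=["villages", "croplands", "wild"]
                ),
                "climate": pd.DataFrame(rng.normal(size=(n, 2)), columns=["c1", "c2"]),
            }
            y = 1.5 * groups["anthromes"]["villages"].to_numpy() + rng.normal(size=n)
            retained = group_preselect(y, groups)
            if "villages" in retained["anthromes"]:
                hits += 1
        assert hits / reps >= 0.9

    def test_overlapping_groups_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        with pytest.raises(ValidationError, match="disjoint"):
            group_preselect(rng.normal(size=30), {"g1": df, "g2": df[["a"]]})

    def test_single_variable_group_is_two_model_comparison(self, rng):
        n = 100
        x = rng.normal(size=n)
        y = 2 * x + rng.normal(size=n) * 0.1
        retained = group_preselect(y, {"g": pd.DataFrame({"x": x})})
        assert retained["g"] == ("x",)


class TestBuildPathModel:
    RANKS = {"climate": 0, "villages": 1, "richness": 2, "threat": 3}

    def test_chain_recovered_at_strong_effects(self):
        rng = np.random.default_rng(6)
        hits = 0
        reps = 50
        for _ in range(reps):
            n = 200
            climate = rng.normal(size=n)
            villages = 1.5 * climate + rng.normal(size=n)
            richness = rng.normal(size=n)
            threat = 1.5 * villages + rng.normal(size=n)
            data = pd.DataFrame({
                "climate": climate, "villages": villages,
                "richness": richness, "threat": threat,
            })
            model = build_path_model(data, self.RANKS, "threat")
            edges = {(e.parent, e.child) for e in model.edges}
            if edges == {("villages", "threat"), ("climate", "villages")}:
                hits += 1
        assert hits / reps >= 0.8

    def test_independent_response_gives_empty_model(self):
        rng = np.random.default_rng(7)
        empties = 0
        reps = 40
        for _ in range(reps):
            n = 150
            data = pd.DataFrame(rng.normal(size=(n, 4)),
                                columns=["climate", "villages", "richness", "threat"])
            model = build_path_model(data, self.RANKS, "threat")
            if not model.edges:
                empties += 1
        # three noise candidates each enter with ~16% probability, so the
        # empty model is the modal outcome (~0.84^3 ~ 0.6 in expectation)
        assert empties / reps >= 0.4

    def test_rank_violation_rejected(self, rng):
        data = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "threat"])
        with pytest.raises(ValidationError):
            build_path_model(data, {"a": 3, "threat": 3}, "threat")

    def test_edges_respect_rank_order(self, small_world):
        from pcpspath import run_pipeline

        res = run_pipeline(
            small_world.W, small_world.phylogeny, small_world.attributes,
            small_world.threats, scenarios=("urgent",), n_perm=99, seed=0,
        )
        model = res.scenario_models["urgent"].model_
        for e in model.edges:
            assert model.ranks[e.parent] < model.ranks[e.child]
        assert nx.is_directed_acyclic_graph(model.graph())


class TestPathCoefficients:
    def test_single_parent_beta_is_pearson_r(self, rng):
        n = 80
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        data = pd.DataFrame({"x": x, "y": y})
        model = PathModel({"x": 0, "y": 1}, "y", [PathEdge("x", "y")])
        model = path_coefficients(model, data)
        assert model.edges[0].beta == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_orthogonal_parents_get_marginal_correlations(self, rng):
        n = 500
        x1 = rng.normal(size=n)
        x1 -= x1.mean()
        x2 = rng.normal(size=n)
        x2 -= x2.mean()
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)  # exactly orthogonal after centering
        y = x1 + 0.5 * x2 + rng.normal(size=n)
        data = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        model = PathModel({"x1": 0, "x2": 0, "y": 1}, "y",
                          [PathEdge("x1", "y"), PathEdge("x2", "y")])
        model = path_coefficients(model, data)
        for e in model.edges:
            r = np.corrcoef(data[e.parent], y)[0, 1]
            assert e.beta == pytest.approx(r, abs=1e-6)

    def test_matches_zscored_normal_equations(self, rng):
        n = 60
        X = rng.normal(size=(n, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + rng.normal(size=n)
        data = pd.DataFrame(np.column_stack([X, y]), columns=["a", "b", "c", "y"])
        model = PathModel({"a": 0, "b": 0, "c": 0, "y": 1}, "y",
                          [PathEdge(p, "y") for p in "abc"])
        model = path_coefficients(model, data)
        Z = (data - data.mean()) / data.std(ddof=1)
        Xz = Z[["a", "b", "c"]].to_numpy()
        expect = np.linalg.inv(Xz.T @ Xz) @ Xz.T @ Z["y"].to_numpy()
        got = [e.beta for e in model.edges]
        assert np.allclose(got, expect, atol=1e-10)


class TestRandomizationPvalues:
    def _one_edge(self, x, y):
        data = pd.DataFrame({"x": x, "y": y})
        model = PathModel({"x": 0, "y": 1}, "y", [PathEdge("x", "y")])
        return path_coefficients(model, data), data

    def test_perfect_relation_attains_minimum_p(self, rng):
        x = rng.normal(size=50)
        model, data = self._one_edge(x, 2 * x)
        model = randomization_pvalues(model, data, n_perm=199, seed=1)
        assert model.edges[0].p_value == pytest.approx(1 / 200)

    def test_identical_seeds_identical_pvalues(self, rng):
        x = rng.normal(size=60)
        y = 0.3 * x + rng.normal(size=60)
        model1, data = self._one_edge(x, y)
        p1 = randomization_pvalues(model1, data, 199, seed=5).edges[0].p_value
        model2, _ = self._one_edge(x, y)
        p2 = randomization_pvalues(model2, data, 199, seed=5).edges[0].p_value
        assert p1 == p2

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(8)
        n_data, n = 400, 100
        rejections = 0
        for _ in range(n_data):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            model, data = self._one_edge(x, y)
            model = randomization_pvalues(model, data, 199, seed=rng)
            if model.edges[0].p_value < 0.05:
                rejections += 1
        # binomial 99% envelope around the attainable level 9/200
        assert 0.02 <= rejections / n_data <= 0.08

    def test_too_few_permutations_rejected(self, rng):
        x = rng.normal(size=30)
        model, data = self._one_edge(x, x + rng.normal(size=30))
        with pytest.raises(ValidationError, match="99"):
            randomization_pvalues(model, data, n_perm=50)


class TestEffectDecomposition:
    def _model(self, edges, response="C"):
        nodes = sorted({n for e in edges for n in (e[0], e[1])})
        ranks = {}
        g = nx.DiGraph([(a, b) for a, b, _ in edges])
        for n in nx.topological_sort(g):
            ranks[n] = max([ranks[p] + 1 for p in g.predecessors(n)], default=0)
        model = PathModel(ranks, response,
                          [PathEdge(a, b, beta=w) for a, b, w in edges])
        return model

    def test_chain_indirect_is_product(self):
        model = self._model([("A", "B", 0.5), ("B", "C", 0.4)])
        eff = effect_decomposition(model).effects.set_index("variable")
        assert eff.loc["A", "direct"] == 0
        assert eff.loc["A", "indirect"] == pytest.approx(0.2)
        assert eff.loc["B", "total"] == pytest.approx(0.4)

    def test_direct_plus_indirect(self):
        model = self._model([("A", "C", 0.3), ("A", "B", 0.5), ("B", "C", 0.4)])
        eff = effect_decomposition(model).effects.set_index("variable")
        assert eff.loc["A", "total"] == pytest.approx(0.3 + 0.2)

    def test_matches_exhaustive_dfs_oracle(self, rng):
        nodes = list("ABCDEF")
        edges = []
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                if rng.random() < 0.5:
                    edges.append((a, b, float(rng.normal())))
        if not any(b == "F" for _, b, _ in edges):
            edges.append(("E", "F", 0.7))
        model = self._model(edges, response="F")
        eff = effect_decomposition(model).effects.set_index("variable")
        g = model.graph()
        for node in nodes[:-1]:
            total = 0.0
            for path in nx.all_simple_paths(g, node, "F"):
                prod = 1.0
                for a, b in zip(path[:-1], path[1:]):
                    prod *= g[a][b]["beta"]
                total += prod
            assert eff.loc[node, "total"] == pytest.approx(total, abs=1e-10)

    def test_disconnected_variable_has_zero_total(self):
        model = PathModel({"A": 0, "B": 0, "C": 1}, "C",
                          [PathEdge("A", "C", beta=0.5)])
        eff = effect_decomposition(model).effects.set_index("variable")
        assert eff.loc["B", "total"] == 0


class TestPathAnalysisEstimator:
    def test_sklearn_params_roundtrip(self):
        pa = PathAnalysis(n_perm=199, alpha=0.01)
        assert pa.get_params()["n_perm"] == 199
        pa.set_params(n_perm=299)
        assert pa.n_perm == 299

    def test_fit_produces_edges_and_effects(self, rng):
        n = 120
        climate = rng.normal(size=n)
        villages = 0.8 * climate + rng.normal(size=n)
        threat = 1.2 * villages + rng.normal(size=n)
        data = pd.DataFrame({"climate_1": climate, "villages": villages,
                             "richness": rng.normal(size=n), "threat": threat})
        ranks = {"climate_1": 0, "villages": 1, "richness": 2, "threat": 3}
        pa = PathAnalysis(n_perm=199, random_state=0).fit(
            data, ranks, "threat",
            groups={"climate": ["climate_1"], "anthromes": ["villages"]},
        )
        assert {"parent", "child", "beta", "p_value", "significant"} <= set(pa.edges_.columns)
        assert ("villages", "threat") in {
            (r.parent, r.child) for r in pa.edges_.itertuples()
        }
        dot = pa.model_.to_dot()
        assert "villages" in dot and "->" in dot
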