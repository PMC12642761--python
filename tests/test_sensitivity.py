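import numpy as np
import pytest

from adbc.model import AdbcParameters, AdbcState
from adbc.sensitivity import (
    LEVEL1_PARAMS,
    SobolProblem,
    level1_global,
    level2_regional,
    rank_regions,
    saltelli_sample,
    sobol_indices,
    SobolResult,
)
from adbc.synthetic import CohortSpec, generate_population_graph


def brute_force_s1(f, bounds, i, m=200):
    """Conditional-variance quadrature on a uniform grid: Var_Xi E[Y|Xi] / Var(Y)."""
    k = len(bounds)
    grids = [np.linspace(lo, hi, m) for lo, hi in bounds]
    mesh = np.meshgrid(*grids, indexing="ij")
    Y = f(np.stack([g.ravel() for g in mesh], axis=1)).reshape(mesh[0].shape)
    var_y = Y.var()
    cond = Y.mean(axis=tuple(j for j in range(k) if j != i))
    return cond.var() / var_y


class TestSobolOracles:
    def test_single_active_factor(self):
        prob = SobolProblem(names=["x1", "x2"], bounds=[(0, 1), (0, 1)], n_base=1024, seed=0)
        res = sobol_indices(prob, lambda x: x[0])
        assert res.S1[0] == pytest.approx(1.0, abs=0.02)
        assert res.S1[1] == pytest.approx(0.0, abs=0.02)
        assert res.ST[0] == pytest.approx(1.0, abs=0.02)
        assert res.ST[1] == pytest.approx(0.0, abs=0.02)

    def test_additive_model_closed_form(self):
        a, b = 2.0, 1.0
        prob = SobolProblem(names=["x1", "x2"], bounds=[(0, 1), (0, 1)], n_base=1024,
                            seed=1, second_order=True)
        res = sobol_indices(prob, lambda x: a * x[0] + b * x[1])
        expect = a ** 2 / (a ** 2 + b ** 2)
        assert res.S1[0] == pytest.approx(expect, abs=0.03)
        assert res.S1[1] == pytest.approx(1 - expect, abs=0.03)
        assert res.S2[0, 1] == pytest.approx(0.0, abs=0.03)
        # additive model: total and first-order indices coincide
        assert np.allclose(res.ST, res.S1, atol=0.03)

    def test_pure_interaction_model(self):
        prob = SobolProblem(names=["x1", "x2"], bounds=[(-1, 1), (-1, 1)], n_base=1024,
                            seed=2, second_order=True)
        res = sobol_indices(prob, lambda x: x[0] * x[1])
        assert res.S1 == pytest.approx([0.0, 0.0], abs=0.05)
        assert res.ST == pytest.approx([1.0, 1.0], abs=0.05)
        assert res.S2[0, 1] == pytest.approx(1.0, abs=0.05)

    def test_matches_brute_force_quadrature(self):
        bounds = [(0, 1), (0, 1), (0, 1)]

        def f_rows(X):
            return X[:, 0] + 2 * X[:, 1] * X[:, 2]

        prob = SobolProblem(names=list("abc"), bounds=bounds, n_base=2048, seed=3)
        res = sobol_indices(prob, lambda x: f_rows(x[None, :])[0])
        for i in range(3):
            oracle = brute_force_s1(f_rows, bounds, i, m=60)
            assert res.S1[i] == pytest.approx(oracle, abs=0.03)

    def test_matches_scipy_reference(self):
        from scipy.stats import sobol_indices as scipy_sobol
        from scipy.stats import uniform

        def f_vec(x):  # scipy passes (k, n)
            return x[0] + 0.5 * x[1] + x[0] * x[1]

        ref = scipy_sobol(func=f_vec, n=1024,
                          dists=[uniform(0, 1), uniform(0, 1)],
                          rng=np.random.default_rng(0))
        prob = SobolProblem(names=["x1", "x2"], bounds=[(0, 1), (0, 1)], n_base=1024, seed=4)
        res = sobol_indices(prob, lambda x: x[0] + 0.5 * x[1] + x[0] * x[1])
        assert np.allclose(res.S1, ref.first_order, atol=0.05)
        assert np.allclose(res.ST, ref.total_order, atol=0.05)

    def test_total_dominates_first_order(self):
        prob = SobolProblem(names=list("abc"), bounds=[(0, 1)] * 3, n_base=512, seed=5)
        res = sobol_indices(prob, lambda x: x[0] * x[1] + np.sin(3 * x[2]))
        assert np.all(res.ST - res.S1 >= -(res.ST_conf + res.S1_conf + 0.02))

    def test_zero_variance_flagged_as_zero(self, caplog):
        prob = SobolProblem(names=["x1"], bounds=[(0, 1)], n_base=64, seed=6)
        res = sobol_indices(prob, lambda x: 3.14)
        assert np.all(res.S1 == 0) and np.all(res.ST == 0)

    def test_non_finite_output_names_sample(self):
        prob = SobolProblem(names=["x1"], bounds=[(0, 1)], n_base=64, seed=7)
        with pytest.raises(ValueError, match="row"):
            sobol_indices(prob, lambda x: np.nan)

    def test_seed_reproducibility(self):
        prob = SobolProblem(names=["x1", "x2"], bounds=[(0, 1)] * 2, n_base=256, seed=8)
        f = lambda x: x[0] ** 2 + x[1]
        r1 = sobol_indices(prob, f)
        r2 = sobol_indices(prob, f)
        assert np.array_equal(r1.S1, r2.S1) and np.array_equal(r1.ST, r2.ST)

    def test_sample_size_must_be_power_of_two(self):
        with pytest.raises(ValueError):
            SobolProblem(names=["x"], bounds=[(0, 1)], n_base=1000)

    def test_saltelli_block_layout(self):
        prob = SobolProblem(names=["x", "y"], bounds=[(0, 1)] * 2, n_base=8, second_order=True)
        X = saltelli_sample(prob)
        assert X.shape == (8 * (2 * 2 + 2), 2)
        A, B, AB0 = X[:8], X[8:16], X[16:24]
        assert np.array_equal(AB0[:, 1], A[:, 1])  # column 1 kept from A
        assert np.array_equal(AB0[:, 0], B[:, 0])  # column 0 swapped from B


@pytest.fixture(scope="module")
def sens_graph():
    return generate_population_graph(CohortSpec(n_regions=8, seed=11))


@pytest.fixture(scope="module")
def quad_graph():
    return generate_population_graph(CohortSpec(n_regions=4, fc_density=1.0, seed=11))


BASE_RANGES = {
    "D_Abeta": (0.1, 0.1), "D_tau": (0.1, 0.1), "D_N": (0.1, 0.1),
    "lambda_CN": (0.04, 0.04), "lambda_C": (0.3, 0.3), "K_C": (1.1, 1.1),
    "lambda_Abeta": (0.15, 0.15), "lambda_tau": (0.25, 0.25), "lambda_N": (0.25, 0.25),
    "lambda_tauAbeta": (0.02, 0.02), "lambda_Ntau": (0.02, 0.02),
    "K_Abeta": (1.1, 1.1), "K_tau": (1.1, 1.1), "K_N": (1.1, 1.1),
}


class TestLevel1:
    def test_single_varying_parameter_takes_all_sensitivity(self, sens_graph):
        ranges = dict(BASE_RANGES)
        ranges["lambda_C"] = (0.1, 0.6)
        res = level1_global(ranges, sens_graph, ages=np.array([80.0, 100.0]),
                            n_base=128, seed=0)
        i = res["names"].index("lambda_C")
        assert res["ST"][i] == pytest.approx(1.0, abs=0.05)
        others = np.delete(np.arange(14), i)
        assert np.all(np.abs(res["ST"][others, :]) < 0.05)

    def test_collapsed_coupling_decouples_cascade(self, sens_graph):
        """With lambda_CN pinned at 0, C never sees the cascade: upstream
        parameters carry no sensitivity."""
        ranges = dict(BASE_RANGES)
        ranges["lambda_CN"] = (0.0, 0.0)
        ranges["lambda_C"] = (0.2, 0.5)
        ranges["lambda_Abeta"] = (0.05, 0.3)
        ranges["lambda_tau"] = (0.1, 0.4)
        res = level1_global(ranges, sens_graph, ages=np.array([90.0]), n_base=128, seed=1)
        for nm in ("lambda_Abeta", "lambda_tau", "D_Abeta", "K_tau"):
            i = res["names"].index(nm)
            assert abs(res["ST"][i, 0]) < 0.05

    def test_missing_range_rejected(self, sens_graph):
        with pytest.raises(ValueError, match="lambda_C"):
            level1_global({"D_Abeta": (0, 1)}, sens_graph, ages=np.array([80.0]))

    def test_constant_output_age_flagged(self, sens_graph):
        ranges = dict(BASE_RANGES)
        ranges["lambda_C"] = (0.1, 0.6)
        res = level1_global(ranges, sens_graph, ages=np.array([50.0, 90.0]),
                            n_base=64, seed=2)
        assert 50.0 in res["zero_variance_ages"]
        assert np.all(res["ST"][:, 0] == 0)


class TestLevel2:
    def _base(self, n):
        vals = {k: v[0] for k, v in BASE_RANGES.items()}
        return AdbcParameters.homogeneous(n, **vals)

    def test_structural_zero_for_pinned_lobe(self, quad_graph):
        n = 4
        lobe_map = {1: "frontal", 2: "frontal", 3: "temporal", 4: "temporal"}
        ranges = np.array([[0.05, 0.4]] * 2 + [[0.15, 0.15]] * 2)  # temporal pinned
        y0 = AdbcState.uniform(n, Abeta=0.1, tau=0.02, N=0.02, C=0.0)
        res = level2_regional("lambda_Abeta", ranges, lobe_map, self._base(n), quad_graph,
                              y0, stages=(80.0,), n_base=512, seed=0)
        stage = res["stages"][80.0]
        assert stage["lobe_S1"]["temporal"] == pytest.approx(0.0, abs=0.05)
        inter = stage["lobe_S2"].get(("frontal", "temporal"), 0.0)
        assert inter == pytest.approx(0.0, abs=0.05)

    def test_variance_bookkeeping_sums_to_one(self, quad_graph):
        n = 4
        lobe_map = {r: ("frontal" if r % 2 else "parietal") for r in range(1, 5)}
        ranges = np.tile([0.05, 0.4], (n, 1))
        y0 = AdbcState.uniform(n, Abeta=0.1, tau=0.02, N=0.02, C=0.0)
        res = level2_regional("lambda_Abeta", ranges, lobe_map, self._base(n), quad_graph,
                              y0, stages=(80.0,), n_base=512, seed=1)
        stage = res["stages"][80.0]
        total = sum(stage["lobe_S1"].values()) + sum(stage["lobe_S2"].values())
        assert total == pytest.approx(1.0, abs=0.1)

    def test_region_missing_from_lobe_map_rejected(self, sens_graph):
        with pytest.raises(ValueError, match="lobe map"):
            level2_regional("lambda_Abeta", np.tile([0.1, 0.2], (8, 1)), {1: "frontal"},
                            self._base(8), sens_graph,
                            AdbcState.uniform(8, Abeta=0.1, tau=0, N=0, C=0))

    def test_non_regional_parameter_rejected(self, sens_graph):
        with pytest.raises(ValueError):
            level2_regional("lambda_C", np.tile([0.1, 0.2], (8, 1)),
                            {r: "frontal" for r in range(1, 9)},
                            self._base(8), sens_graph,
                            AdbcState.uniform(8, Abeta=0.1, tau=0, N=0, C=0))


class TestRankRegions:
    def _result(self, S1, ST):
        k = len(S1)
        return SobolResult(names=[f"region_{i+1}" for i in range(k)],
                           S1=np.asarray(S1, float), ST=np.asarray(ST, float), S2=None,
                           S1_conf=np.zeros(k), ST_conf=np.zeros(k), n_base=0,
                           n_evals=0, var_y=1.0)

    def test_strict_ordering(self):
        res = self._result([0.1, 0.5, 0.3, 0.2], [0.2, 0.6, 0.4, 0.3])
        lobes = {1: "frontal", 2: "temporal", 3: "parietal", 4: "occipital"}
        out = rank_regions(res, lobes, k=3)
        assert [t["region"] for t in out["top"]] == [2, 3, 4]

    def test_tie_broken_by_total_index(self):
        res = self._result([0.4, 0.4, 0.1], [0.5, 0.7, 0.2])
        out = rank_regions(res, {1: "frontal", 2: "temporal", 3: "limbic"}, k=2)
        assert [t["region"] for t in out["top"]] == [2, 1]

    def test_lobe_counts_partition_k(self):
        res = self._result([0.4, 0.3, 0.2, 0.1], [0.4, 0.3, 0.2, 0.1])
        lobes = {1: "frontal", 2: "frontal", 3: "temporal", 4: "occipital"}
        out = rank_regions(res, lobes, k=4)
        assert sum(out["lobe_counts"].values()) == 4
        assert out["lobe_counts"]["frontal"] == 2

    def test_oversized_k_clipped(self):
        res = self._result([0.5, 0.5], [0.5, 0.5])
        out = rank_regions(res, {1: "frontal", 2: "temporal"}, k=10)
        assert len(out["top"]) == 2


def test_level1_parameter_set_is_the_fourteen(sens_graph):
    assert len(LEVEL1_PARAMS) == 14
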