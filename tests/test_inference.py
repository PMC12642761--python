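import numpy as np
import pytest

from adbc.data import LongitudinalRecord
from adbc.graph import LowRankPerturbation, check_weight_constraints
from adbc.inference import (
    FitConfig,
    fit_stage1_homogeneous,
    fit_stage2_regional,
    fit_stage3_initial_conditions,
    fit_stage4_fc,
    fit_subject,
    homotopy_schedule,
    homotopy_vs_vanilla,
    loss,
    split_train_test,
)
from adbc.model import AdbcParameters, AdbcState, simulate
from adbc.synthetic import CohortSpec, generate_population_graph


class TestHomotopySchedule:
    def test_default_path(self):
        assert homotopy_schedule(1000, 10, 4).tolist() == [1000.0, 100.0, 10.0, 1.0]

    def test_single_stage_degenerates_to_vanilla(self):
        assert homotopy_schedule(1000, 10, 1).tolist() == [1000.0]

    @pytest.mark.parametrize("kwargs", [dict(start=0), dict(decay=1.0), dict(n_stages=0)])
    def test_invalid_schedules_rejected(self, kwargs):
        base = dict(start=1000, decay=10, n_stages=4)
        base.update(kwargs)
        with pytest.raises(ValueError):
            homotopy_schedule(**base)


def _saturated_subject(pop, n):
    """Parameters whose solution sits exactly at capacity 1: zero loss reference."""
    params = AdbcParameters.homogeneous(
        n, D_Abeta=0.1, D_tau=0.1, D_N=0.1, lambda_CN=0.0, lambda_C=0.4, K_C=1.0,
        lambda_Abeta=0.3, lambda_tau=0.3, lambda_N=0.3, lambda_tauAbeta=0.0,
        lambda_Ntau=0.0, K_Abeta=1.0, K_tau=1.0, K_N=1.0)
    y0 = AdbcState.uniform(n, Abeta=1.0, tau=1.0, N=1.0, C=1.0)
    return params, y0


class TestLoss:
    def test_zero_at_perfect_saturated_fit(self, small_pop):
        n = small_pop.n
        params, y0 = _saturated_subject(small_pop, n)
        records = [LongitudinalRecord("s", 70.0, "Abeta", j + 1, 1.0) for j in range(n)]
        value = loss(params, y0, LowRankPerturbation.zero(n), records, small_pop)
        assert value == pytest.approx(0.0, abs=1e-8)

    def test_single_visit_double_prediction(self, small_pop):
        n = small_pop.n
        params, y0 = _saturated_subject(small_pop, n)
        # prediction is 1 everywhere; observations at 0.5 -> relative error 1, squared
        records = [LongitudinalRecord("s", 70.0, "Abeta", j + 1, 0.5) for j in range(n)]
        value = loss(params, y0, LowRankPerturbation.zero(n), records, small_pop, w=0.0)
        assert value == pytest.approx(1.0, abs=1e-6)

    def test_large_w_is_a_lower_bound_via_endpoint(self, small_pop):
        n = small_pop.n
        params, y0 = _saturated_subject(small_pop, n)
        y0_off = AdbcState.uniform(n, Abeta=0.5, tau=1.0, N=1.0, C=1.0)
        records = [LongitudinalRecord("s", 70.0, "Abeta", 1, 0.9)]
        value = loss(params, y0_off, LowRankPerturbation.zero(n), records, small_pop, w=1000.0)
        traj = simulate(params, y0_off, small_pop.as_graph(), t_eval=np.array([100.0]))
        endpoint = float(np.sum((traj.states[0].to_vector() - 1.0) ** 2))
        assert value >= 1000.0 * endpoint - 1e-6


class TestSplit:
    def test_last_visit_held_out_per_modality(self):
        records = [LongitudinalRecord("s", a, "Abeta", 1, 0.5) for a in (60.0, 70.0, 80.0)]
        records += [LongitudinalRecord("s", a, "C", None, 0.3) for a in (65.0, 75.0)]
        train, test = split_train_test(records)
        assert {r.age for r in test} == {80.0, 75.0}
        assert len(train) == 3

    def test_single_visit_modality_never_held_out(self):
        records = [LongitudinalRecord("s", 60.0, "Abeta", 1, 0.5)]
        train, test = split_train_test(records)
        assert test == [] and len(train) == 1


# capacities of exactly 1 so the end-stage saturation penalty vanishes at the
# truth and the oracle is unbiased
HOM_TRUTH = dict(D_Abeta=0.2, D_tau=0.2, D_N=0.2, lambda_CN=0.04, lambda_C=0.3, K_C=1.0,
                 lambda_Abeta=0.14, lambda_tau=0.3, lambda_N=0.3,
                 lambda_tauAbeta=0.01, lambda_Ntau=0.01,
                 K_Abeta=1.0, K_tau=1.0, K_N=1.0)


@pytest.fixture(scope="module")
def noiseless_subject(request):
    """Fully homogeneous truth (uniform baseline too), zero noise: the exact
    setting in which the homogenized stage should recover its scalars."""
    pop = generate_population_graph(CohortSpec(n_regions=8, seed=21))
    n = pop.n
    params = AdbcParameters.homogeneous(n, **HOM_TRUTH)
    y0 = AdbcState.uniform(n, Abeta=0.08, tau=0.0, N=0.0, C=0.0)
    ages = np.array([56.0, 63.0, 70.0, 77.0, 84.0, 92.0])
    traj = simulate(params, y0, pop.as_graph(), t_eval=ages)
    records = []
    for age, state in zip(ages, traj.states):
        for bio in ("Abeta", "tau", "N"):
            fld = getattr(state, bio)
            records += [LongitudinalRecord("hom", float(age), bio, j + 1, float(fld[j]))
                        for j in range(n)]
        records.append(LongitudinalRecord("hom", float(age), "C", None, float(state.C)))
    return pop, params, y0, records


class TestStage1:
    def test_recovers_homogeneous_logistic_parameters(self, noiseless_subject):
        pop, truth, _, records = noiseless_subject
        cfg = FitConfig(multistart=8, multistart_polish=2, seed=3, holdout_last_visit=False)
        s1 = fit_stage1_homogeneous(records, pop, cfg)
        e = s1.equations["Abeta"]
        assert abs(e["lam"] - HOM_TRUTH["lambda_Abeta"]) / HOM_TRUTH["lambda_Abeta"] < 0.05
        assert abs(e["K"] - HOM_TRUTH["K_Abeta"]) / HOM_TRUTH["K_Abeta"] < 0.02
        assert abs(e["y0"] - 0.08) < 0.02

    def test_bounds_respected(self, noiseless_subject):
        pop, _, _, records = noiseless_subject
        cfg = FitConfig(multistart=4, multistart_polish=1, seed=3)
        s1 = fit_stage1_homogeneous(records, pop, cfg)
        b = cfg.bounds
        for eq in ("Abeta", "tau", "N"):
            e = s1.equations[eq]
            assert b["lam"][0] <= e["lam"] <= b["lam"][1]
            assert b["K"][0] <= e["K"] <= b["K"][1]
            assert b["y0"][0] <= e["y0"] <= b["y0"][1]

    def test_inclusion_criterion_enforced(self, small_pop):
        records = [LongitudinalRecord("s", 60.0, "Abeta", 1, 0.5)]
        with pytest.raises(ValueError):
            fit_subject(records, small_pop)


@pytest.fixture(scope="module")
def staged(noiseless_subject):
    pop, _, _, records = noiseless_subject
    cfg = FitConfig(multistart=4, multistart_polish=2, maxiter_stage1=40,
                    maxiter_stage2=10, maxiter_stage3=10, maxiter_stage4=10, seed=7,
                    holdout_last_visit=False)
    s1 = fit_stage1_homogeneous(records, pop, cfg)
    s2 = fit_stage2_regional(records, s1, cfg)
    s3 = fit_stage3_initial_conditions(records, s2, cfg)
    return pop, records, s1, s2, s3, cfg


class TestStages234:
    def test_homogeneous_truth_keeps_deviations_sparse(self, staged):
        _, _, _, s2, s3, _ = staged
        assert s2.epsilon.l1() < 1e-3
        assert sum(np.abs(v).sum() for v in s3.epsilon.y0.values()) < 1e-3

    def test_stage2_data_fit_no_worse_than_stage1(self, staged, noiseless_subject):
        """eps = 0 is always feasible in stage 2, so the assembled stage-2
        model's pure data loss cannot meaningfully exceed the stage-1 model's."""
        pop, records, s1, s2, _, cfg = staged
        from adbc.inference import _assemble, _stage1_assemble
        from adbc.graph import LowRankPerturbation

        p1, y01 = _stage1_assemble(s1)
        p2, y02 = _assemble(s2)
        zero = LowRankPerturbation.zero(pop.n)
        l1 = loss(p1, y01, zero, records, pop, w=0.0)
        l2 = loss(p2, y02, zero, records, pop, w=0.0)
        assert l2 <= l1 + 0.05 * max(l1, 1.0)

    def test_stage4_near_zero_perturbation_for_population_truth(self, staged):
        pop, records, _, _, s3, cfg = staged
        pert = fit_stage4_fc(records, s3, pop, cfg)
        A0 = pop.adjacency
        from adbc.graph import patient_adjacency

        A1 = patient_adjacency(A0, pert)
        changed = np.abs(A1 - A0) > 0.01
        frac = changed[np.triu_indices(pop.n, 1)].mean()
        assert frac <= 0.05
        assert check_weight_constraints(A0, pert, tol=1e-6) == []


class TestFitSubject:
    def test_determinism(self, tiny_cohort, fast_fit_config):
        _, pop, subjects = tiny_cohort
        s = subjects[0]
        r1 = fit_subject(s.records, pop, fast_fit_config, stages=(1, 2))
        r2 = fit_subject(s.records, pop, fast_fit_config, stages=(1, 2))
        assert np.array_equal(r1.params.lambda_Abeta, r2.params.lambda_Abeta)
        assert r1.params.D_Abeta == r2.params.D_Abeta
        assert r1.train_accuracy == r2.train_accuracy

    def test_missing_downstream_modalities_are_skipped(self, small_pop, fast_fit_config):
        spec = CohortSpec(n_regions=8, noise_sigma=0.0, seed=22, missing_fraction={})
        from adbc.synthetic import generate_subject

        s = generate_subject(spec, small_pop, np.random.default_rng(5), "ab_only")
        ab_records = [r for r in s.records if r.biomarker == "Abeta"]
        res = fit_subject(ab_records, small_pop, fast_fit_config, stages=(1,))
        assert res.statuses["Abeta"] == "fitted"
        for eq in ("tau", "N", "C"):
            assert res.statuses[eq] == "skipped_no_data"
        assert "Abeta" in res.train_accuracy and "tau" not in res.train_accuracy

    def test_invalid_stage_prefix_rejected(self, tiny_cohort, fast_fit_config):
        _, pop, subjects = tiny_cohort
        with pytest.raises(ValueError):
            fit_subject(subjects[0].records, pop, fast_fit_config, stages=(2, 3))


def test_homotopy_no_worse_than_vanilla_on_equal_budget(tiny_cohort):
    """The homotopy path must not lose to single-weight training (same
    multistart candidates, same total iteration budget)."""
    _, pop, subjects = tiny_cohort
    cfg = FitConfig(multistart=6, multistart_polish=2, maxiter_stage1=30, seed=9)
    out = homotopy_vs_vanilla(subjects[0].records, pop, cfg, equation="Abeta")
    assert out["data_fit_homotopy"] <= out["data_fit_vanilla"] + 1e-9
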