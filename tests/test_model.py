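"""CSBN assembly, prediction under missing evidence, pipeline, I/O."""

import itertools

import numpy as np
import pytest

from csbn.bayesnet import CPT, DAG, DiscreteBN, StructureConstraints
from csbn.cox_core import CoxFit, fit_cox, predict_survival
from csbn.model import (
    CSBNModel,
    PipelineConfig,
    SurvivalCPD,
    build_csbn,
    load_model,
    posterior_covariate_given_outcome,
    predict_cohort,
    predict_survival_probability,
    save_model,
    survival_cpd_eval,
    train_from_cohort,
)

from conftest import make_survival_cohort, simulate_binary_cohort


def toy_cox(beta_by_col, baseline_times, H0, covariates=None):
    names = list(beta_by_col)
    covs = covariates or [n.split("=")[0] for n in names]
    encoding = {}
    for c in dict.fromkeys(covs):
        encoding[c] = [(n.split("=")[1], i) for i, n in enumerate(names)
                       if n.split("=")[0] == c]
    return CoxFit(
        covariates=list(dict.fromkeys(covs)),
        encoding=encoding,
        reference={c: "0" for c in dict.fromkeys(covs)},
        column_names=names,
        beta=np.array(list(beta_by_col.values()), dtype=float),
        se=np.ones(len(names)),
        loglik=0.0, n_events=1, N=1,
        baseline_times=np.asarray(baseline_times, dtype=float),
        H0=np.asarray(H0, dtype=float),
    )


def two_parent_model(p_x=0.4, p_y=0.5, s0_at_1=0.8):
    """Independent binary parents x, y feeding the survival node."""
    dag = DAG(("x", "y"), frozenset())
    cpts = {
        "x": CPT("x", (), ("0", "1"), (), np.array([[1 - p_x, p_x]])),
        "y": CPT("y", (), ("0", "1"), (), np.array([[1 - p_y, p_y]])),
    }
    bn = DiscreteBN(dag, cpts, {"x": ("0", "1"), "y": ("0", "1")})
    cox = toy_cox({"x=1": np.log(2.0), "y=1": -0.5},
                  [1.0], [-np.log(s0_at_1)])
    return build_csbn(bn, cox, ["x", "y"], horizon=1.0)


class TestSurvivalCPD:
    def test_reference_pattern(self):
        cox = toy_cox({"x=1": 0.7}, [1.0, 2.0], [0.1, 0.4])
        cpd = SurvivalCPD(("x",), cox)
        for t in (0.5, 1.5, 2.5):
            s0 = cox.baseline_survival(t)[0]
            assert survival_cpd_eval(cpd, {"x": "0"}, t) == pytest.approx(1 - s0)

    def test_power_identity_and_t_zero(self):
        cox = toy_cox({"x=1": np.log(2.0)}, [1.0], [-np.log(0.9)])
        cpd = SurvivalCPD(("x",), cox)
        assert survival_cpd_eval(cpd, {"x": "1"}, 2.0) == pytest.approx(0.19)
        for level in ("0", "1"):
            assert survival_cpd_eval(cpd, {"x": level}, 0.0) == 0.0

    def test_monotone_in_time(self):
        cox = toy_cox({"x=1": 0.4}, [1.0, 2.0, 3.0], [0.2, 0.5, 1.1])
        cpd = SurvivalCPD(("x",), cox)
        ts = np.linspace(0, 4, 25)
        vals = [survival_cpd_eval(cpd, {"x": "1"}, t) for t in ts]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_coherence_with_cox_prediction_is_exact(self, three_subject_cohort):
        fit = fit_cox(three_subject_cohort, ["x"])
        cpd = SurvivalCPD(("x",), fit)
        for level in ("0", "1"):
            for t in (0.5, 1.0, 2.0, 3.5):
                assert survival_cpd_eval(cpd, {"x": level}, t) == \
                    1 - predict_survival(fit, {"x": level}, t)


class TestBuild:
    def test_parent_count_and_acyclicity(self):
        model = two_parent_model()
        assert model.survival.parents == ("x", "y")
        assert model.bn.dag.topological_order()  # still a DAG

    def test_missing_predictor_raises(self):
        dag = DAG(("x",), frozenset())
        bn = DiscreteBN(dag, {"x": CPT("x", (), ("0", "1"), (),
                                       np.array([[0.5, 0.5]]))},
                        {"x": ("0", "1")})
        cox = toy_cox({"z=1": 0.2}, [1.0], [0.1])
        with pytest.raises(ValueError, match="not in network"):
            build_csbn(bn, cox, ["z"])


class TestPrediction:
    def test_full_evidence_matches_formula(self):
        model = two_parent_model()
        p, se = predict_survival_probability(model, {"x": "1", "y": "0"},
                                             t=1.0, samples=2000, seed=1)
        assert p == pytest.approx(0.8 ** 2.0, abs=3 * max(se, 1e-3))

    def test_one_unobserved_parent_is_two_term_mixture(self):
        model = two_parent_model(p_x=0.4)
        s_x0 = 0.8 ** np.exp(0.0 - 0.5)
        s_x1 = 0.8 ** np.exp(np.log(2.0) - 0.5)
        exact = 0.6 * s_x0 + 0.4 * s_x1
        p, se = predict_survival_probability(model, {"y": "1"}, t=1.0,
                                             samples=40_000, seed=2)
        assert abs(p - exact) < 3 * max(se, 1e-4)

    def test_no_evidence_matches_enumeration(self):
        model = two_parent_model()
        exact = 0.0
        for xi, yi in itertools.product((0, 1), (0, 1)):
            w = (0.6, 0.4)[xi] * (0.5, 0.5)[yi]
            lp = np.log(2.0) * xi - 0.5 * yi
            exact += w * 0.8 ** np.exp(lp)
        p, se = predict_survival_probability(model, {}, t=1.0,
                                             samples=40_000, seed=3)
        assert abs(p - exact) < 3 * max(se, 1e-4)

    def test_prediction_bounded_by_completion_extremes(self):
        model = two_parent_model()
        fulls = [predict_survival_probability(
            model, {"x": str(a), "y": "1"}, t=1.0, samples=500, seed=4)[0]
            for a in (0, 1)]
        p, _ = predict_survival_probability(model, {"y": "1"}, t=1.0,
                                            samples=20_000, seed=5)
        assert min(fulls) - 1e-3 <= p <= max(fulls) + 1e-3

    def test_highest_risk_completion_lowers_survival(self):
        model = two_parent_model()
        p_marg, _ = predict_survival_probability(model, {"y": "0"}, t=1.0,
                                                 samples=20_000, seed=6)
        p_risky, _ = predict_survival_probability(model, {"x": "1", "y": "0"},
                                                  t=1.0, samples=2000, seed=6)
        assert p_risky <= p_marg + 1e-3

    def test_survival_node_evidence_and_diagnostic_query(self):
        model = two_parent_model()
        assert predict_survival_probability(model, {"E": "0"}) == (1.0, 0.0)
        assert predict_survival_probability(model, {"E": "1"}) == (0.0, 0.0)
        # posterior over x given death: exact by Bayes on the 4-cell joint
        num = den = 0.0
        for xi, yi in itertools.product((0, 1), (0, 1)):
            w = (0.6, 0.4)[xi] * (0.5, 0.5)[yi]
            death = 1 - 0.8 ** np.exp(np.log(2.0) * xi - 0.5 * yi)
            den += w * death
            if xi == 1:
                num += w * death
        exact = num / den
        p, se = posterior_covariate_given_outcome(model, ("x", "1"),
                                                  outcome="1", t=1.0,
                                                  samples=60_000, seed=7)
        assert abs(p - exact) < 3 * max(se, 1e-3)

    def test_invalid_evidence_raises(self):
        model = two_parent_model()
        with pytest.raises(ValueError, match="unknown level"):
            predict_survival_probability(model, {"x": "7"})
        with pytest.raises(ValueError, match="unknown evidence node"):
            predict_survival_probability(model, {"nope": "1"})


def pipeline_cohort(n=800, seed=0):
    """Four strong predictors plus two noise covariates."""
    cohort, names, _ = simulate_binary_cohort(
        n, [1.2, -1.0, 1.0, 0.9, 0.0, 0.0], seed=seed)
    return cohort, names


SMALL_PIPELINE = PipelineConfig(bootstrap_B=5, cv_folds=5, n_lambda=25,
                                lw_samples=500, seed=11)


class TestTrainFromCohort:
    def test_recovers_strong_predictors_end_to_end(self):
        cohort, names = pipeline_cohort(n=3000, seed=1)
        model = train_from_cohort(cohort, SMALL_PIPELINE)
        assert {"x0", "x1", "x2", "x3"} <= set(model.survival.parents)
        assert set(model.survival.parents) <= set(names)
        assert model.provenance["selected"] == list(model.survival.parents)

    def test_fixed_seed_serializes_byte_identically(self, tmp_path):
        cohort, _ = pipeline_cohort(n=500, seed=2)
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        save_model(train_from_cohort(cohort, SMALL_PIPELINE), p1)
        save_model(train_from_cohort(cohort, SMALL_PIPELINE), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_events_raises(self):
        cohort = make_survival_cohort({"x": ("0", "1")},
                                      [{"x": "0"}, {"x": "1"}] * 3,
                                      np.arange(1, 7, dtype=float),
                                      np.zeros(6, dtype=int))
        with pytest.raises(ValueError, match="no events"):
            train_from_cohort(cohort, SMALL_PIPELINE)

    def test_constraints_respected_in_final_network(self):
        cohort, _ = pipeline_cohort(n=800, seed=3)
        cfg = PipelineConfig(bootstrap_B=3, cv_folds=5, n_lambda=20, seed=5,
                             constraints=StructureConstraints(
                                 blacklist=frozenset({("x0", "x1"), ("x1", "x0")})))
        model = train_from_cohort(cohort, cfg)
        assert ("x0", "x1") not in model.bn.dag.edges
        assert ("x1", "x0") not in model.bn.dag.edges


class TestSerialization:
    def test_round_trip_predictions_identical(self, tmp_path):
        model = two_parent_model()
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        rng = np.random.default_rng(9)
        for _ in range(100):
            evidence = {}
            if rng.random() < 0.7:
                evidence["x"] = str(rng.integers(0, 2))
            if rng.random() < 0.7:
                evidence["y"] = str(rng.integers(0, 2))
            seed = int(rng.integers(0, 1000))
            a = predict_survival_probability(model, evidence, t=1.0,
                                             samples=200, seed=seed)
            b = predict_survival_probability(loaded, evidence, t=1.0,
                                             samples=200, seed=seed)
            assert a == b

    def test_version_check(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format_version": 99}')
        with pytest.raises(ValueError, match="unsupported model format"):
            load_model(path)


def test_predict_cohort_reports_missing_counts():
    model = two_parent_model()
    cohort = make_survival_cohort(
        {"x": ("0", "1"), "y": ("0", "1")},
        [{"x": "1", "y": "0"}, {"x": None, "y": "1"}, {"x": None, "y": None}],
        [1.0, 1.0, 1.0], [1, 0, 1])
    out = predict_cohort(model, cohort, t=1.0, samples=300, seed=1)
    assert list(out["n_missing_predictors"]) == [0, 1, 2]
    assert out["mc_se"].iloc[0] == 0.0
    assert ((out["survival_prob"] >= 0) & (out["survival_prob"] <= 1)).all()
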