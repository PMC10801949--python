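"""Discrete BN structure learning, CPT estimation and inference."""

import itertools

import numpy as np
import pytest

from csbn.bayesnet import (
    CPT,
    DAG,
    ArcStrengths,
    DiscreteBN,
    StructureConstraints,
    average_model,
    bootstrap_arc_strengths,
    fit_parameters_mle,
    learn_structure_tabu,
    likelihood_weighting_query,
    score_dag,
)

from conftest import make_survival_cohort


def binary_cohort(columns: dict, times=None):
    n = len(next(iter(columns.values())))
    rows = [{k: str(int(v[i])) for k, v in columns.items()} for i in range(n)]
    return make_survival_cohort({k: ("0", "1") for k in columns}, rows,
                                times if times is not None else np.ones(n),
                                np.ones(n, dtype=int))


@pytest.fixture(scope="module")
def chain_bn():
    """A -> B -> C with known CPTs; small enough for exact enumeration."""
    dag = DAG(("A", "B", "C"), frozenset({("A", "B"), ("B", "C")}))
    cpts = {
        "A": CPT("A", (), ("0", "1"), (), np.array([[0.3, 0.7]])),
        "B": CPT("B", ("A",), ("0", "1"), (("0", "1"),),
                 np.array([[0.8, 0.2], [0.1, 0.9]])),
        "C": CPT("C", ("B",), ("0", "1"), (("0", "1"),),
                 np.array([[0.6, 0.4], [0.25, 0.75]])),
    }
    return DiscreteBN(dag, cpts, {n: ("0", "1") for n in "ABC"})


def enumerate_joint(bn):
    """Exhaustive joint distribution from the CPT product."""
    nodes = list(bn.dag.nodes)
    joint = {}
    for combo in itertools.product(*(range(len(bn.levels[n])) for n in nodes)):
        assign = dict(zip(nodes, combo))
        p = 1.0
        for n in nodes:
            cpt = bn.cpts[n]
            if cpt.parents:
                row = cpt.row_index(np.array([[assign[q] for q in cpt.parents]]))[0]
            else:
                row = 0
            p *= cpt.table[row, assign[n]]
        joint[combo] = p
    return nodes, joint


class TestStructureLearning:
    def test_dependent_pair_gets_an_arc_and_matches_exhaustive_score(self):
        rng = np.random.default_rng(1)
        a = rng.random(2000) < 0.4
        b = np.where(rng.random(2000) < 0.9, a, ~a)
        cohort = binary_cohort({"A": a, "B": b})
        learned = learn_structure_tabu(cohort)
        assert learned.edges in (frozenset({("A", "B")}), frozenset({("B", "A")}))
        # oracle: score all three two-node DAGs exhaustively
        candidates = [
            DAG(("A", "B"), frozenset()),
            DAG(("A", "B"), frozenset({("A", "B")})),
            DAG(("A", "B"), frozenset({("B", "A")})),
        ]
        scores = [score_dag(cohort, d) for d in candidates]
        assert score_dag(cohort, learned) == pytest.approx(max(scores))

    def test_independent_pair_stays_empty(self):
        rng = np.random.default_rng(2)
        cohort = binary_cohort({"A": rng.random(2000) < 0.5,
                                "B": rng.random(2000) < 0.5})
        assert learn_structure_tabu(cohort).edges == frozenset()

    def test_constraints_are_respected(self):
        rng = np.random.default_rng(3)
        a = rng.random(1500) < 0.4
        b = np.where(rng.random(1500) < 0.9, a, ~a)
        c = rng.random(1500) < 0.5
        cohort = binary_cohort({"A": a, "B": b, "C": c})
        cons = StructureConstraints(whitelist=frozenset({("A", "C")}),
                                    blacklist=frozenset({("A", "B"), ("B", "A")}))
        dag = learn_structure_tabu(cohort, cons)
        assert ("A", "C") in dag.edges
        assert ("A", "B") not in dag.edges and ("B", "A") not in dag.edges

    def test_single_node_gives_empty_dag(self):
        cohort = binary_cohort({"A": np.array([0, 1, 0, 1])})
        dag = learn_structure_tabu(cohort)
        assert dag.nodes == ("A",) and dag.edges == frozenset()

    def test_infeasible_whitelist_cycle_raises(self):
        cohort = binary_cohort({"A": np.array([0, 1, 0, 1]),
                                "B": np.array([1, 0, 1, 0])})
        cons = StructureConstraints(whitelist=frozenset({("A", "B"), ("B", "A")}))
        with pytest.raises(ValueError, match="infeasible|cycle"):
            learn_structure_tabu(cohort, cons)

    def test_score_decomposes_over_families(self):
        """Total BIC equals the sum of independent per-family scores
        computed by direct counting."""
        rng = np.random.default_rng(4)
        a = rng.random(500) < 0.3
        b = np.where(rng.random(500) < 0.8, a, ~a)
        cohort = binary_cohort({"A": a, "B": b})
        dag = DAG(("A", "B"), frozenset({("A", "B")}))

        def family_ll(child, parent):
            import pandas as pd
            df = cohort.df
            ll = 0.0
            if parent is None:
                counts = df[child].value_counts()
                ll = float((counts * np.log(counts / counts.sum())).sum())
                q = 1
            else:
                ll = 0.0
                q = 2
                for lev, sub in df.groupby(parent):
                    counts = sub[child].value_counts()
                    ll += float((counts * np.log(counts / counts.sum())).sum())
            return ll - 0.5 * np.log(len(df)) * (2 - 1) * q

        expected = family_ll("A", None) + family_ll("B", "A")
        assert score_dag(cohort, dag) == pytest.approx(expected)


class TestBootstrapAveraging:
    def test_single_resample_strengths_are_zero_or_one(self):
        rng = np.random.default_rng(5)
        a = rng.random(300) < 0.4
        b = np.where(rng.random(300) < 0.9, a, ~a)
        cohort = binary_cohort({"A": a, "B": b})
        st = bootstrap_arc_strengths(cohort, B=1, seed=0)
        assert all(v in (0.0, 1.0) for v in st.strength.values())

    def test_deterministic_copy_has_strength_one(self):
        rng = np.random.default_rng(6)
        a = rng.random(500) < 0.5
        cohort = binary_cohort({"A": a, "B": a})
        st = bootstrap_arc_strengths(cohort, B=10, seed=1)
        total = st.strength.get(("A", "B"), 0) + st.strength.get(("B", "A"), 0)
        assert total == pytest.approx(1.0)

    def test_independent_variables_have_weak_arcs(self):
        rng = np.random.default_rng(7)
        cohort = binary_cohort({"A": rng.random(2000) < 0.5,
                                "B": rng.random(2000) < 0.5,
                                "C": rng.random(2000) < 0.5})
        st = bootstrap_arc_strengths(cohort, B=10, seed=2)
        assert all(v < 0.5 for v in st.strength.values())

    def test_average_model_filter_and_boundary(self):
        st = ArcStrengths({("a", "b"): 0.9, ("b", "c"): 0.3}, B=10)
        assert average_model(st, 0.5).whitelist == frozenset({("a", "b")})
        st2 = ArcStrengths({("a", "b"): 1.0, ("b", "c"): 0.999}, B=1000)
        assert average_model(st2, 1.0).whitelist == frozenset({("a", "b")})

    def test_average_model_breaks_two_cycle_by_majority(self):
        st = ArcStrengths({("a", "b"): 0.9, ("b", "a"): 0.8}, B=10)
        assert average_model(st, 0.5).whitelist == frozenset({("a", "b")})
        assert st.direction_agreement("a", "b") == pytest.approx(0.9 / 1.7)

    def test_average_model_breaks_longer_cycles_dropping_weakest(self):
        st = ArcStrengths({("a", "b"): 0.9, ("b", "c"): 0.7, ("c", "a"): 0.6},
                          B=10)
        wl = average_model(st, 0.5).whitelist
        assert wl == frozenset({("a", "b"), ("b", "c")})


class TestParameters:
    def test_relative_frequency(self):
        a = np.array([1, 1, 1, 1, 0, 0])
        x = np.array([1, 1, 1, 0, 0, 1])
        cohort = binary_cohort({"A": a, "X": x})
        dag = DAG(("A", "X"), frozenset({("A", "X")}))
        bn = fit_parameters_mle(dag, cohort)
        assert bn.cpts["X"].table[1, 1] == pytest.approx(0.75)  # 3 of 4

    def test_unobserved_parent_config_uniform(self):
        a = np.array([0, 0, 0, 0])
        x = np.array([1, 0, 1, 0])
        cohort = make_survival_cohort(
            {"A": ("0", "1"), "X": ("0", "1")},
            [{"A": str(v), "X": str(w)} for v, w in zip(a, x)],
            np.ones(4), np.ones(4, dtype=int))
        dag = DAG(("A", "X"), frozenset({("A", "X")}))
        bn = fit_parameters_mle(dag, cohort)
        np.testing.assert_allclose(bn.cpts["X"].table[1], [0.5, 0.5])

    def test_recovery_within_003_at_n_10000(self, chain_bn):
        rng = np.random.default_rng(11)
        n = 10_000
        a = (rng.random(n) < 0.7).astype(int)
        pb = np.where(a == 1, 0.9, 0.2)
        b = (rng.random(n) < pb).astype(int)
        pc = np.where(b == 1, 0.75, 0.4)
        c = (rng.random(n) < pc).astype(int)
        cohort = binary_cohort({"A": a, "B": b, "C": c})
        bn = fit_parameters_mle(chain_bn.dag, cohort)
        for node in "ABC":
            np.testing.assert_allclose(bn.cpts[node].table,
                                       chain_bn.cpts[node].table, atol=0.03)


class TestLikelihoodWeighting:
    def test_parentless_marginal(self, chain_bn):
        p, se = likelihood_weighting_query(chain_bn, ("A", "0"), {},
                                           samples=20_000, seed=1)
        assert abs(p - 0.3) < 3 * max(se, 1e-4)

    def test_chain_query_matches_enumeration(self, chain_bn):
        nodes, joint = enumerate_joint(chain_bn)
        num = sum(p for combo, p in joint.items()
                  if combo[nodes.index("C")] == 1 and combo[nodes.index("A")] == 1)
        den = sum(p for combo, p in joint.items() if combo[nodes.index("A")] == 1)
        exact = num / den
        p, se = likelihood_weighting_query(chain_bn, ("C", "1"), {"A": "1"},
                                           samples=50_000, seed=2)
        assert abs(p - exact) < 3 * max(se, 1e-4)

    def test_query_on_evidence_node_is_degenerate(self, chain_bn):
        p1, se1 = likelihood_weighting_query(chain_bn, ("B", "1"), {"B": "1"},
                                             samples=100, seed=0)
        p0, _ = likelihood_weighting_query(chain_bn, ("B", "0"), {"B": "1"},
                                           samples=100, seed=0)
        assert (p1, p0) == (1.0, 0.0) and se1 == 0.0

    def test_zero_probability_evidence_raises(self):
        dag = DAG(("A", "B"), frozenset({("A", "B")}))
        cpts = {
            "A": CPT("A", (), ("0", "1"), (), np.array([[1.0, 0.0]])),
            "B": CPT("B", ("A",), ("0", "1"), (("0", "1"),),
                     np.array([[1.0, 0.0], [0.5, 0.5]])),
        }
        bn = DiscreteBN(dag, cpts, {"A": ("0", "1"), "B": ("0", "1")})
        with pytest.raises(ValueError, match="zero probability"):
            likelihood_weighting_query(bn, ("A", "0"), {"B": "1"},
                                       samples=2000, seed=3)

    def test_error_shrinks_with_sample_size(self, chain_bn):
        _, se_small = likelihood_weighting_query(chain_bn, ("C", "1"), {"A": "1"},
                                                 samples=1000, seed=4)
        _, se_big = likelihood_weighting_query(chain_bn, ("C", "1"), {"A": "1"},
                                               samples=16_000, seed=4)
        assert se_big < se_small / 2  # expect ~1/4 under root-n scaling

    def test_forward_joint_matches_cpt_product(self, chain_bn):
        """Factorized joint = empirical frequency of forward samples."""
        nodes, joint = enumerate_joint(chain_bn)
        assert sum(joint.values()) == pytest.approx(1.0)
        from csbn.bayesnet import _forward_samples
        rng = np.random.default_rng(5)
        assign, w = _forward_samples(chain_bn, {}, 40_000, rng)
        assert np.all(w == 1.0)
        sampled = np.stack([assign[n] for n in nodes], axis=1)
        for combo, p in joint.items():
            emp = np.mean(np.all(sampled == np.array(combo), axis=1))
            assert emp == pytest.approx(p, abs=0.01)


def test_cpt_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        CPT("A", (), ("0", "1"), (), np.array([[0.5, 0.4]]))
    with pytest.raises(ValueError, match="mismatch"):
        CPT("A", ("B",), ("0", "1"), (("0", "1"),), np.array([[0.5, 0.5]]))
    with pytest.raises(ValueError, match="cycle"):
        DAG(("A", "B"), frozenset({("A", "B"), ("B", "A")}))


def test_edge_list_csv_round_trip(tmp_path):
    from csbn.bayesnet import constraints_from_csv, dag_from_csv, dag_to_csv

    dag = DAG(("a", "b", "c"), frozenset({("a", "b"), ("b", "c")}))
    path = tmp_path / "edges.csv"
    dag_to_csv(dag, path)
    again = dag_from_csv(path, nodes=["a", "b", "c"])
    assert again == dag
    wl = tmp_path / "wl.csv"
    wl.write_text("from,to\nsmoking,COPD\n")
    cons = constraints_from_csv(whitelist_path=wl)
    assert cons.whitelist == frozenset({("smoking", "COPD")})
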