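import itertools
import math

import numpy as np
import pytest

from grnlearn import (
    DAGStructure,
    GeneratorConfig,
    bic_score,
    bn_loglik,
    d_separated,
    fit_local_params,
    generate_topology,
    hill_climb,
    implied_covariance,
    local_bic,
    sample_covariance,
    sample_expression,
    standardize,
)
from grnlearn.gbn import GBNModel
from conftest import make_expression, standardized_with_correlation
from oracles import all_dags, partial_correlation, random_gbn


class TestSampleCovariance:
    def test_standardized_diagonal_is_exactly_one(self, rng):
        X = standardize(make_expression(rng.normal(size=(30, 4))))
        s = sample_covariance(X)
        np.testing.assert_array_equal(np.diag(s), np.ones(4))

    def test_duplicate_columns_give_unit_offdiagonal(self, rng):
        col = rng.normal(size=20)
        X = standardize(make_expression(np.column_stack([col, col])))
        s = sample_covariance(X)
        assert s[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_two_sample_hand_computation(self):
        X = standardize(make_expression(np.array([[1.0, -1.0], [-1.0, 1.0]])))
        np.testing.assert_allclose(sample_covariance(X), [[1, -1], [-1, 1]], atol=1e-15)

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            sample_covariance(make_expression(np.array([[1.0, 2.0]])))


class TestFitLocalParams:
    def test_empty_structure_on_standardized_data(self, rng):
        n = 50
        X = standardize(make_expression(rng.normal(size=(n, 3))))
        structure = DAGStructure.from_edges(X.gene_ids, [])
        model = fit_local_params(structure, X)
        for g in X.gene_ids:
            assert model.beta[g] == {}
            assert model.mu[g] == pytest.approx(0.0, abs=1e-12)
            assert model.nu[g] == pytest.approx((n - 1) / n, abs=1e-12)

    def test_noiseless_regression_hits_variance_floor(self, rng):
        tf = rng.normal(size=40)
        X = make_expression(np.column_stack([tf, 2.0 * tf]), gene_ids=["tf1", "g1"])
        structure = DAGStructure.from_edges(["tf1", "g1"], [("tf1", "g1")])
        with pytest.warns(RuntimeWarning, match="clamped"):
            model = fit_local_params(structure, X)
        assert model.beta["g1"]["tf1"] == pytest.approx(2.0, abs=1e-9)
        assert model.nu["g1"] == pytest.approx(1e-12)

    def test_recovers_generating_coefficients(self):
        config = GeneratorConfig(n_tfs=2, n_targets=5, n_edges=8, n_decoy_tfs=0,
                                 n_decoy_targets=0, n_samples=100_000, seed=12)
        gold = generate_topology(config)
        X, truth = sample_expression(gold, config)
        fitted = fit_local_params(truth.structure, X)
        for node in gold.gene_ids:
            for parent, want in truth.beta[node].items():
                assert fitted.beta[node][parent] == pytest.approx(want, abs=0.02)

    def test_rank_deficient_design_raises(self, rng):
        col = rng.normal(size=30)
        X = make_expression(np.column_stack([col, col, rng.normal(size=30)]),
                            gene_ids=["a", "b", "c"])
        structure = DAGStructure.from_edges(["a", "b", "c"], [("a", "c"), ("b", "c")])
        with pytest.raises(np.linalg.LinAlgError):
            fit_local_params(structure, X)


class TestBicScore:
    def test_orphan_closed_form(self, rng):
        n = 100
        col = rng.normal(size=n)
        col = col - col.mean()
        col = col / np.sqrt(col @ col / n)  # MLE variance exactly 1
        X = make_expression(col[:, None], gene_ids=["g1"])
        want_loglik = -(n / 2) * (math.log(2 * math.pi) + 1)
        want = want_loglik - math.log(n)
        assert local_bic("g1", set(), X) == pytest.approx(want, abs=1e-9)
        assert want == pytest.approx(-146.4989, abs=1e-3)

    def test_uncorrelated_parent_costs_half_log_n(self, rng):
        n = 60
        raw = rng.normal(size=(n, 2))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)  # exactly orthogonal, mean ~0 after centering
        child = q[:, 0] - q[:, 0].mean()
        parent = q[:, 1] - q[:, 1].mean()
        parent -= (parent @ child) / (child @ child) * child
        X = make_expression(np.column_stack([child, parent]), gene_ids=["c", "p"])
        without = local_bic("c", set(), X)
        with_parent = local_bic("c", {"p"}, X)
        assert with_parent - without == pytest.approx(-0.5 * math.log(n), abs=1e-9)

    def test_decomposability(self, rng):
        X = standardize(make_expression(rng.normal(size=(40, 4))))
        structure = DAGStructure.from_edges(
            X.gene_ids, [("g1", "g2"), ("g1", "g3"), ("g2", "g3")]
        )
        total = sum(
            local_bic(n, structure.parent_sets[n], X) for n in structure.nodes
        )
        assert bic_score(structure, X) == pytest.approx(total, abs=1e-9)

    def test_empty_graph_closed_form(self, rng):
        n, p = 80, 3
        X = standardize(make_expression(rng.normal(size=(n, p))))
        var = (n - 1) / n
        want = p * (-(n / 2) * (math.log(2 * math.pi * var) + 1) - math.log(n))
        empty = DAGStructure.from_edges(X.gene_ids, [])
        assert bic_score(empty, X) == pytest.approx(want, abs=1e-8)

    def test_score_equivalence_within_markov_class(self, rng):
        """DAGs with the same skeleton and v-structures get equal BIC."""
        nodes = ["a", "b", "c", "d"]
        dags = all_dags(nodes)
        for _ in range(5):
            X = standardize(make_expression(rng.normal(size=(60, 4)), gene_ids=nodes))
            classes: dict = {}
            for edges in dags:
                skeleton = frozenset(frozenset(e) for e in edges)
                parents: dict = {n: set() for n in nodes}
                for p, c in edges:
                    parents[c].add(p)
                vstructs = frozenset(
                    (frozenset((p1, p2)), c)
                    for c in nodes
                    for p1, p2 in itertools.combinations(sorted(parents[c]), 2)
                    if frozenset((p1, p2)) not in skeleton
                )
                classes.setdefault((skeleton, vstructs), []).append(edges)
            checked = 0
            for members in classes.values():
                if len(members) < 2 or checked > 20:
                    continue
                scores = [
                    bic_score(DAGStructure.from_edges(nodes, e), X) for e in members[:3]
                ]
                assert max(scores) - min(scores) < 1e-8
                checked += 1


class TestHillClimb:
    def test_two_gene_edge_added_at_r_030(self, rng):
        X = standardized_with_correlation(0.3, 100, rng)
        model, trace = hill_climb(X)
        assert model.structure.n_edges == 1
        assert trace.converged

    def test_two_gene_no_edge_at_r_010(self, rng):
        X = standardized_with_correlation(0.1, 100, rng)
        model, trace = hill_climb(X)
        assert model.structure.n_edges == 0

    def test_delta_matches_closed_form(self, rng):
        n, r = 100, 0.3
        X = standardized_with_correlation(r, n, rng)
        model, trace = hill_climb(X)
        empty = DAGStructure.from_edges(X.gene_ids, [])
        delta = trace.rows[0].bic - bic_score(empty, X)
        want = -(n / 2) * math.log(1 - r * r) - 0.5 * math.log(n)
        assert delta == pytest.approx(want, abs=1e-8)

    def test_chain_skeleton_recovery(self):
        nodes = [f"v{i}" for i in range(10)]
        edges = [(nodes[i], nodes[i + 1]) for i in range(9)]
        structure = DAGStructure.from_edges(nodes, edges)
        model = GBNModel(
            structure=structure,
            beta={n: {p: 0.8 for p in structure.parent_sets[n]} for n in nodes},
            nu={n: 1.0 for n in nodes},
            mu={n: 0.0 for n in nodes},
        )
        rng = np.random.default_rng(77)
        sigma = implied_covariance(model)
        data = rng.multivariate_normal(np.zeros(10), sigma, size=2000)
        X = standardize(make_expression(data, gene_ids=nodes))
        fitted, _trace = hill_climb(X)
        skeleton = {frozenset(e) for e in fitted.structure.edges()}
        assert skeleton == {frozenset(e) for e in edges}

    def test_trace_bic_strictly_increasing_and_acyclic(self, rng):
        config = GeneratorConfig(n_tfs=3, n_targets=9, n_edges=14, n_decoy_tfs=0,
                                 n_decoy_targets=2, n_samples=300, seed=13)
        gold = generate_topology(config)
        X, _ = sample_expression(gold, config)
        X = standardize(X)
        _model, trace = hill_climb(X, checkpoints=[3, 6])
        bics = [r.bic for r in trace.rows]
        assert all(b2 > b1 for b1, b2 in zip(bics, bics[1:]))
        for row in trace.rows:
            trace.structure_at(row.iteration)  # DAGStructure validates acyclicity
        empty = DAGStructure.from_edges(X.gene_ids, [])
        assert bics[-1] >= bic_score(empty, X)

    def test_checkpoints_are_greedy_path_prefixes(self, rng):
        config = GeneratorConfig(n_tfs=2, n_targets=8, n_edges=10, n_decoy_tfs=0,
                                 n_decoy_targets=0, n_samples=400, seed=14)
        gold = generate_topology(config)
        X = standardize(sample_expression(gold, config)[0])
        _model, trace = hill_climb(X, checkpoints=[2, 5])
        assert set(trace.checkpoints) <= {2, 5}
        if 2 in trace.checkpoints and 5 in trace.checkpoints:
            e2 = trace.checkpoints[2].structure.edges()
            e5 = trace.checkpoints[5].structure.edges()
            assert e2 <= e5

    def test_matches_exhaustive_enumeration_on_three_genes(self, rng):
        nodes = ["a", "b", "c"]
        wins, total = 0, 12
        for _ in range(total):
            X = standardize(make_expression(rng.normal(size=(50, 3)), gene_ids=nodes))
            model, _ = hill_climb(X)
            hc_bic = bic_score(model.structure, X)
            best = max(
                bic_score(DAGStructure.from_edges(nodes, e), X) for e in all_dags(nodes)
            )
            assert hc_bic <= best + 1e-9
            wins += hc_bic >= best - 1e-9
        assert wins >= total - 1


class TestBnLoglik:
    def test_standard_normal_at_mode(self):
        structure = DAGStructure.from_edges(["g1"], [])
        model = GBNModel(structure=structure, beta={"g1": {}}, nu={"g1": 1.0}, mu={"g1": 0.0})
        X = make_expression(np.array([[0.0]]), gene_ids=["g1"])
        assert bn_loglik(model, X) == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_additive_over_identical_samples(self, rng):
        model = random_gbn(rng, 4)
        row = rng.normal(size=(1, 4))
        X1 = make_expression(row, gene_ids=model.structure.nodes)
        X5 = make_expression(np.repeat(row, 5, axis=0), gene_ids=model.structure.nodes)
        assert bn_loglik(model, X5) == pytest.approx(5 * bn_loglik(model, X1), rel=1e-12)

    def test_rejects_nonpositive_variance(self, rng):
        model = random_gbn(rng, 3)
        model.nu[model.structure.nodes[0]] = -1.0
        X = make_expression(rng.normal(size=(4, 3)), gene_ids=model.structure.nodes)
        with pytest.raises(ValueError):
            bn_loglik(model, X)


FIG6B = DAGStructure.from_edges(["X", "Y", "Z", "W"], [("X", "Z"), ("Y", "Z"), ("Z", "W")])


class TestDSeparation:
    @pytest.mark.parametrize(
        "x,y,S,separated",
        [
            ("X", "Y", {"Z"}, False),
            ("X", "W", set(), False),
            ("Y", "W", set(), False),
            ("X", "Y", set(), True),
            ("X", "W", {"Z"}, True),
            ("Y", "W", {"Z"}, True),
        ],
    )
    def test_collider_chain_statements(self, x, y, S, separated):
        assert d_separated(FIG6B, x, y, S) is separated

    def test_isolated_nodes_always_separated(self):
        structure = DAGStructure.from_edges(["a", "b", "c"], [])
        assert d_separated(structure, "a", "b", set())
        assert d_separated(structure, "a", "b", {"c"})

    def test_unknown_node_raises(self):
        with pytest.raises(KeyError):
            d_separated(FIG6B, "X", "nope", set())

    def test_dsep_implies_vanishing_partial_correlation(self, rng):
        for _ in range(30):
            model = random_gbn(rng, int(rng.integers(3, 9)))
            nodes = model.structure.nodes
            sigma = implied_covariance(model)
            idx = {n: i for i, n in enumerate(nodes)}
            x, y = rng.choice(nodes, size=2, replace=False)
            others = [n for n in nodes if n not in (x, y)]
            k = int(rng.integers(0, len(others) + 1))
            S = set(rng.choice(others, size=k, replace=False)) if k else set()
            if d_separated(model.structure, x, y, S):
                pc = partial_correlation(sigma, idx[x], idx[y], [idx[s] for s in S])
                assert abs(pc) < 1e-8
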