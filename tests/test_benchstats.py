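"""Benchmark statistics against brute-force oracles.

The hypergeometric tail is checked against exhaustive enumeration of all
draws, the KS statistic against a direct O(n*m) ECDF sweep, and the
set-based summaries against naive recomputation on random fixtures.
"""

import itertools

import numpy as np
import pytest

from gembench.benchstats import (confidence_enrichment,
                                 confusion_metrics, cross_validate,
                                 hypergeom_tail, jaccard_index,
                                 jaccard_matrix, ks_two_sample,
                                 overlap_counts, pathway_activity,
                                 resolution_power, ubiquity_counts)
from gembench.extractors import CoreSets
from gembench.network import ConfidenceMap, ReactionSet

from conftest import make_network


def enumerate_hypergeom_tail(N, K, n, k):
    """P(X >= k) by enumerating all C(N, n) draws."""
    population = [1] * K + [0] * (N - K)
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total if total else 1.0


def brute_force_ks(x, y):
    """sup |Fx - Fy| over all observed points, O(n*m)."""
    x, y = np.asarray(x), np.asarray(y)
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


class TestJaccard:
    @pytest.mark.parametrize("A, B, expected", [
        ({"a", "b"}, {"a", "b"}, 1.0),
        ({"a"}, {"b"}, 0.0),
        ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
        (set(), set(), 1.0),
        (set(), {"a"}, 0.0),
    ])
    def test_values(self, A, B, expected):
        assert jaccard_index(A, B) == expected

    def test_matrix_identical_models(self):
        J = jaccard_matrix({"m1": {"a"}, "m2": {"a"}, "m3": {"a"}})
        assert np.allclose(J.matrix, 1.0)

    def test_matrix_duplicate_pair_clusters_first(self):
        J = jaccard_matrix({"dup1": {"a", "b"}, "lone": {"x"},
                            "dup2": {"a", "b"}})
        order = [J.labels[i] for i in J.leaf_order]
        assert abs(order.index("dup1") - order.index("dup2")) == 1

    def test_matrix_symmetric_unit_diagonal_random(self):
        rng = np.random.default_rng(0)
        models = {f"m{i}": set(rng.choice(50, size=rng.integers(5, 30),
                                          replace=False).tolist())
                  for i in range(6)}
        J = jaccard_matrix(models)
        assert np.allclose(J.matrix, J.matrix.T)
        assert np.allclose(np.diag(J.matrix), 1.0)
        for i, li in enumerate(J.labels):
            for j, lj in enumerate(J.labels):
                assert J.matrix[i, j] == jaccard_index(models[li], models[lj])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            jaccard_matrix({"m": {"a"}})


class TestOverlapAndUbiquity:
    def test_identical_models_all_depth_two(self):
        table = overlap_counts({"m1": {"a", "b"}, "m2": {"a", "b"}})
        assert table.loc["m1", 2] == 2 and table.loc["m1", 1] == 0

    def test_disjoint_models_all_depth_one(self):
        table = overlap_counts({"m1": {"a"}, "m2": {"b"}})
        assert table.loc["m1", 1] == 1 and table.loc["m2", 1] == 1

    def test_row_sums_equal_model_sizes(self):
        rng = np.random.default_rng(1)
        models = {f"m{i}": set(rng.choice(30, size=rng.integers(3, 20),
                                          replace=False).tolist())
                  for i in range(5)}
        table = overlap_counts(models)
        for label, model in models.items():
            assert table.loc[label].sum() == len(model)

    def test_ubiquity_identical_single_bar(self):
        counts = ubiquity_counts({f"m{i}": {"a", "b"} for i in range(4)})
        assert counts[4] == 2 and counts.drop(4).sum() == 0

    def test_ubiquity_total_is_union_size(self):
        rng = np.random.default_rng(2)
        models = {f"m{i}": set(rng.choice(25, size=10, replace=False).tolist())
                  for i in range(4)}
        counts = ubiquity_counts(models)
        union = set().union(*models.values())
        assert counts.sum() == len(union)


class TestResolutionPower:
    def test_identical_runs_all_ones(self):
        runs = {"t1": [{"a", "b"}] * 3, "t2": [{"a", "b"}] * 3}
        M = resolution_power(runs)
        assert np.allclose(M.to_numpy(), 1.0)

    def test_disjoint_targets_zero_off_diagonal(self):
        runs = {"t1": [{"a"}, {"a"}], "t2": [{"b"}, {"b"}]}
        M = resolution_power(runs)
        assert M.loc["t1", "t2"] == 0.0 and M.loc["t1", "t1"] == 1.0

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(3)
        runs = {f"t{i}": [set(rng.choice(20, size=8, replace=False).tolist())
                          for _ in range(4)] for i in range(3)}
        M = resolution_power(runs)
        for ti in runs:
            A = runs[ti]
            within = [jaccard_index(A[a], A[b])
                      for a in range(4) for b in range(a + 1, 4)]
            assert M.loc[ti, ti] == pytest.approx(np.mean(within))
            for tj in runs:
                if ti == tj:
                    continue
                cross = [jaccard_index(a, b) for a in A for b in runs[tj]]
                assert M.loc[ti, tj] == pytest.approx(np.mean(cross))

    def test_single_run_diagonal_undefined(self):
        M = resolution_power({"t1": [{"a"}], "t2": [{"b"}, {"b"}]})
        assert np.isnan(M.loc["t1", "t1"])
        assert not np.isnan(M.loc["t2", "t2"])


class TestConfusion:
    def test_perfect_output(self):
        stats = confusion_metrics({"a", "b"}, {"a", "b"}, {"a", "b", "c"})
        assert stats.sensitivity == 1.0 and stats.fdr == 0.0

    def test_worked_arithmetic(self):
        target = set(range(12))
        output = set(range(4, 12)) | {100, 101}
        universe = set(range(12)) | {100, 101, 102}
        stats = confusion_metrics(output, target, universe)
        assert stats.TP == 8 and stats.FP == 2 and stats.FN == 4
        assert stats.sensitivity == pytest.approx(8 / 12)
        assert stats.fdr == pytest.approx(0.2)

    def test_empty_output_conventions(self):
        stats = confusion_metrics(set(), {"a"}, {"a", "b"})
        assert stats.sensitivity == 0.0
        assert stats.fdr == 0.0       # 0/0 defined as 0
        assert stats.specificity == 1.0

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics({"z"}, {"a"}, {"a"})


class TestHypergeometric:
    def test_k_zero_is_one(self):
        assert hypergeom_tail(10, 3, 4, 0) == 1.0

    def test_small_case_equals_exact_fraction(self):
        # N=10, K=3, n=4: P(X >= 2) enumerated over all C(10,4) draws
        assert hypergeom_tail(10, 3, 4, 2) == pytest.approx(
            enumerate_hypergeom_tail(10, 3, 4, 2), abs=1e-12)
        assert enumerate_hypergeom_tail(10, 3, 4, 2) == pytest.approx(1 / 3)

    def test_equals_enumeration_for_all_small_parameters(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_tail(N, K, n, k) == pytest.approx(
                            enumerate_hypergeom_tail(N, K, n, k), abs=1e-12)

    def test_monotone_decreasing_in_k(self):
        values = [hypergeom_tail(30, 12, 10, k) for k in range(11)]
        assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            hypergeom_tail(5, 6, 2, 1)
        with pytest.raises(ValueError):
            hypergeom_tail(10, 3, 4, 5)


class TestKS:
    def test_identical_samples(self):
        stat, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_fully_separated_supports(self):
        stat, _ = ks_two_sample([0, 1, 2], [10, 11, 12])
        assert stat == 1.0

    def test_matches_ecdf_oracle_on_random_samples(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=rng.integers(5, 40))
            y = rng.normal(loc=rng.uniform(-1, 1), size=rng.integers(5, 40))
            stat, _ = ks_two_sample(x, y)
            assert stat == pytest.approx(brute_force_ks(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestConfidenceEnrichment:
    @pytest.fixture
    def conf_net(self):
        return make_network(
            {"R1": {"A[c]": 1}, "R2": {"A[c]": -1, "B[c]": 1},
             "R3": {"B[c]": -1}},
            gpr=["g_hi", "g_hi and g_lo", ""])

    def test_all_high_genes(self, conf_net):
        conf = ConfidenceMap({"g_hi": "high", "g_lo": "high"})
        table = confidence_enrichment({"R1", "R2"}, conf_net, conf)
        assert table.loc["high", "fraction_of_gene_associated"] == 1.0

    def test_and_takes_worst_or_takes_best(self):
        net = make_network(
            {"R1": {"A[c]": 1}, "R2": {"A[c]": -1}},
            gpr=["g_hi and g_lo", "g_hi or g_lo"])
        conf = ConfidenceMap({"g_hi": "high", "g_lo": "low"})
        table = confidence_enrichment({"R1", "R2"}, net, conf)
        assert table.loc["low", "n_reactions"] == 1    # the complex
        assert table.loc["high", "n_reactions"] == 1   # the isozyme pair

    def test_empty_gpr_excluded_from_gene_associated(self, conf_net):
        conf = ConfidenceMap({"g_hi": "high", "g_lo": "low"})
        table = confidence_enrichment({"R1", "R3"}, conf_net, conf)
        assert table["n_reactions"].sum() == 1
        assert table.loc["high", "fraction_of_model"] == 0.5

    def test_missing_genes_count_not_detected(self, conf_net):
        table = confidence_enrichment({"R1"}, conf_net, ConfidenceMap({}))
        assert table.loc["not_detected", "n_reactions"] == 1

    def test_counts_sum_to_gene_associated(self, global_net):
        rng = np.random.default_rng(5)
        conf = ConfidenceMap({
            g: str(rng.choice(["high", "medium", "low", "not_detected"]))
            for g in global_net.gene_ids})
        model = set(map(str, rng.choice(global_net.reaction_ids, size=100,
                                        replace=False)))
        table = confidence_enrichment(model, global_net, conf)
        gene_assoc = sum(1 for r in model
                         if global_net.gpr[global_net.reaction_index(r)])
        assert table["n_reactions"].sum() == gene_assoc


class TestPathwayActivity:
    def test_full_model_all_ones(self, global_net):
        activity = pathway_activity(set(global_net.reaction_ids), global_net)
        assert np.allclose(activity.to_numpy(), 1.0)

    def test_empty_model_all_zero(self, global_net):
        activity = pathway_activity(set(), global_net)
        assert np.allclose(activity.to_numpy(), 0.0)

    def test_fractions_match_direct_counts(self, global_net):
        rng = np.random.default_rng(6)
        model = set(map(str, rng.choice(global_net.reaction_ids, size=120,
                                        replace=False)))
        activity = pathway_activity(model, global_net)
        for subsystem, fraction in activity.items():
            members = global_net.reactions_of_subsystem(subsystem)
            assert fraction == len(model & members) / len(members)
            assert 0.0 <= fraction <= 1.0


class TestCrossValidation:
    def _register(self, name, fn):
        import gembench.extractors as ex
        ex._REGISTRY[name] = fn

    def _drop(self, name):
        import gembench.extractors as ex
        ex._REGISTRY.pop(name, None)

    def test_whole_net_extractor_recovers_everything(self, chain_net):
        from gembench.extractors import ExtractionResult
        self._register("all_test", lambda net, cores, cfg, **p:
                       ExtractionResult(ReactionSet(net.reaction_ids), "all"))
        try:
            res = cross_validate("all_test", chain_net,
                                 CoreSets(active=ReactionSet(chain_net.reaction_ids)),
                                 holdout_fraction=0.34, reps=10, seed=0)
            assert (res.table.recovered == res.table.validation_size).all()
        finally:
            self._drop("all_test")

    def test_echo_extractor_recovers_nothing(self, chain_net):
        from gembench.extractors import ExtractionResult
        self._register("echo_test", lambda net, cores, cfg, **p:
                       ExtractionResult(cores.active, "echo"))
        try:
            res = cross_validate("echo_test", chain_net,
                                 CoreSets(active=ReactionSet(chain_net.reaction_ids)),
                                 holdout_fraction=0.34, reps=10, seed=0)
            assert (res.table.recovered == 0).all()
        finally:
            self._drop("echo_test")

    def test_recovered_never_exceeds_validation(self, global_net,
                                                small_targets):
        res = cross_validate("exclusive", global_net,
                             CoreSets(active=small_targets[0]),
                             holdout_fraction=0.2, reps=5, seed=1)
        assert (res.table.recovered <= res.table.validation_size).all()
        assert ((res.table.p_value >= 0) & (res.table.p_value <= 1)).all()

    def test_empty_core_rejected(self, chain_net):
        with pytest.raises(ValueError):
            cross_validate("exclusive", chain_net,
                           CoreSets(active=frozenset()))
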