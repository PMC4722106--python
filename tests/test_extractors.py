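"""Discretization and the reference extraction algorithms.

Expected sets for the non-trivial toys were derived by brute force:
enumerating all reaction subsets of the toy networks and checking, with
the per-reaction LP oracle, which subsets are flux-consistent supersets
of the core (see ``brute_force_minimal_consistent_supersets``).
"""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from gembench.consistency import reaction_is_consistent
from gembench.extractors import (CoreSets, DiscretizationConfig,
                                 ExtractionResult, InconsistentCoreError,
                                 discretize_gene_calls, discretize_profile,
                                 extract_absent_removal, extract_exclusive,
                                 extract_fastcore, extract_gimme,
                                 get_extractor, list_extractors,
                                 register_extractor, run_extractor)
from gembench.network import GeneScoreProfile, ReactionSet
from gembench.consistency import consistent_subnetwork

from conftest import make_network


def brute_force_minimal_consistent_supersets(net, core):
    """All minimal flux-consistent supersets of ``core``, by exhaustive
    enumeration — the independent oracle for the extraction toys."""
    others = [r for r in net.reaction_ids if r not in core]
    feasible = []
    for k in range(len(others) + 1):
        for extra in itertools.combinations(others, k):
            cand = set(core) | set(extra)
            sub = net.subnetwork(sorted(cand))
            if all(reaction_is_consistent(sub, r) for r in cand):
                feasible.append(frozenset(cand))
        if feasible:
            return feasible  # all of minimum cardinality
    return [frozenset()]


class TestDiscretization:
    def _profile(self, rows, n_samples=10):
        return GeneScoreProfile(pd.DataFrame(
            {f"s{j}": [r[j] for r in rows.values()] for j in range(n_samples)},
            index=list(rows)))

    def test_expressed_above_threshold_in_all_samples(self):
        net = make_network({"R1": {"A[c]": 1}}, gpr=["g1"])
        profile = self._profile({"g1": [5.1] * 10})
        cores = discretize_profile(net, profile)
        assert cores.active == {"R1"} and cores.inactive == frozenset()

    def test_unexpressed_below_zero(self):
        net = make_network({"R1": {"A[c]": 1}}, gpr=["g1"])
        cores = discretize_profile(net, self._profile({"g1": [-0.2] * 10}))
        assert cores.inactive == {"R1"} and cores.active == frozenset()

    def test_intermediate_scores_give_neither(self):
        net = make_network({"R1": {"A[c]": 1}}, gpr=["g1"])
        cores = discretize_profile(net, self._profile({"g1": [3.0] * 10}))
        assert cores.active == cores.inactive == frozenset()

    def test_sample_fraction_rule(self):
        # 9 of 10 samples above threshold meets the 90% rule; 8 does not
        calls = discretize_gene_calls(self._profile(
            {"g_hi9": [6.0] * 9 + [0.5], "g_hi8": [6.0] * 8 + [0.5] * 2}))
        assert calls == {"g_hi9": 1, "g_hi8": 0}

    def test_trinary_gpr_algebra(self):
        # complex of expressed+unexpressed genes scores min = -1; an
        # expressed isozyme rescues with max = +1
        net = make_network(
            {"R1": {"A[c]": 1}, "R2": {"A[c]": -1}},
            gpr=["g_on and g_off", "(g_on and g_off) or g_on"])
        profile = self._profile({"g_on": [6.0] * 10, "g_off": [-1.0] * 10})
        cores = discretize_profile(net, profile)
        assert cores.inactive == {"R1"}
        assert cores.active == {"R2"}

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DiscretizationConfig(expr_threshold=0, unexpr_threshold=5)
        with pytest.raises(ValueError):
            DiscretizationConfig(sample_fraction=0)


class TestFastcore:
    def test_minimal_superset_of_interior_core(self, chain_net):
        result = extract_fastcore(chain_net, {"R2"})
        oracles = brute_force_minimal_consistent_supersets(chain_net, {"R2"})
        assert oracles == [frozenset({"R1", "R2", "R3"})]
        assert result.reactions == oracles[0]

    def test_full_core_returns_whole_consistent_toy(self, chain_net):
        assert (extract_fastcore(chain_net, set(chain_net.reaction_ids)).reactions
                == set(chain_net.reaction_ids))

    def test_empty_core_empty_output(self, chain_net):
        assert extract_fastcore(chain_net, set()).reactions == frozenset()

    def test_two_path_core_picks_one_minimal_route(self, two_path_net):
        result = extract_fastcore(two_path_net, {"OUT"})
        assert result.reactions in brute_force_minimal_consistent_supersets(
            two_path_net, {"OUT"})

    def test_inconsistent_core_reaction_named(self, deadend_net):
        with pytest.raises(InconsistentCoreError, match="R4"):
            extract_fastcore(deadend_net, {"R4"})

    def test_output_contains_core_and_is_consistent(self, global_net,
                                                    small_targets):
        rng = np.random.default_rng(0)
        target = small_targets[0]
        core = ReactionSet(rng.choice(sorted(target),
                                      size=len(target) // 2, replace=False))
        result = extract_fastcore(global_net, core)
        assert core <= result.reactions
        induced = global_net.subnetwork(sorted(result.reactions))
        assert consistent_subnetwork(induced) == result.reactions

    def test_perfect_information_recovery(self, global_net, small_targets):
        """A flux-consistent target fed back as its own core is returned
        exactly (the complete-data convergence property)."""
        for target in small_targets:
            result = extract_fastcore(global_net, target)
            assert result.reactions == target


class TestExclusive:
    def test_no_inactive_reduces_to_fastcore(self, two_path_net):
        cores = CoreSets(active={"OUT"})
        a = extract_exclusive(two_path_net, cores)
        b = extract_fastcore(two_path_net, {"OUT"})
        assert a.reactions == b.reactions

    def test_blocked_path_forces_alternative(self, two_path_net):
        # inactive evidence kills P1; enumeration shows the only
        # consistent superset of OUT without P1 is the P2 route
        cores = CoreSets(active={"OUT"}, inactive={"P1"})
        result = extract_exclusive(two_path_net, cores)
        assert result.reactions == {"IN", "P2a", "P2b", "OUT"}

    def test_core_needing_inactive_dropped_with_warning(self, chain_net):
        cores = CoreSets(active={"R2", "R3"}, inactive={"R1"})
        with pytest.warns(UserWarning, match="dropped"), \
             pytest.raises(InconsistentCoreError):
            extract_exclusive(chain_net, cores)

    def test_partial_drop_keeps_survivors(self, two_path_net):
        extra = make_network({
            "IN": {"A[c]": 1}, "P1": {"A[c]": -1, "B[c]": 1},
            "OUT": {"B[c]": -1}, "D1": {"A[c]": -1, "D[c]": 1},
        })
        # D1's product is a dead end once OUT-side flux is the only sink;
        # with IN inactive the whole chain dies, but here only D1's core
        # membership is unsupportable
        cores = CoreSets(active={"P1", "D1"}, inactive=frozenset())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = extract_exclusive(extra, cores)
        assert "P1" in result.reactions
        assert "D1" not in result.reactions


class TestAbsentRemoval:
    def test_no_evidence_keeps_whole_consistent_net(self, deadend_net):
        cores = CoreSets(active=frozenset(), inactive=frozenset())
        assert (extract_absent_removal(deadend_net, cores).reactions
                == {"R1", "R2", "R3"})

    def test_broken_chain_collapses(self, chain_net):
        cores = CoreSets(active=frozenset(), inactive={"R1"})
        assert extract_absent_removal(chain_net, cores).reactions == frozenset()

    def test_removing_already_dead_reaction_changes_nothing(self, deadend_net):
        cores = CoreSets(active=frozenset(), inactive={"R4"})
        assert (extract_absent_removal(deadend_net, cores).reactions
                == {"R1", "R2", "R3"})

    def test_active_core_ignored(self, deadend_net):
        a = extract_absent_removal(deadend_net,
                                   CoreSets(active={"R2"}))
        b = extract_absent_removal(deadend_net, CoreSets(active=frozenset()))
        assert a.reactions == b.reactions

    def test_inclusive_at_least_as_large_as_exclusive(self, global_net,
                                                      small_targets):
        rng = np.random.default_rng(5)
        target = small_targets[1]
        core = ReactionSet(rng.choice(sorted(target),
                                      size=len(target) // 2, replace=False))
        cores = CoreSets(active=core)
        inclusive = extract_absent_removal(global_net, cores)
        exclusive = extract_fastcore(global_net, core)
        assert len(inclusive.reactions) >= len(exclusive.reactions)


class TestGimme:
    def test_all_above_cutoff_keeps_objective_subnetwork(self, two_path_net):
        scores = {r: 1.0 for r in two_path_net.reaction_ids}
        result = extract_gimme(two_path_net, scores, "OUT", score_cutoff=0.5)
        assert result.reactions == set(two_path_net.reaction_ids)

    def test_penalized_alternative_path_dropped(self, two_path_net):
        scores = {"IN": 1.0, "P1": 1.0, "P2a": 0.0, "P2b": 0.0, "OUT": 1.0}
        result = extract_gimme(two_path_net, scores, "OUT", score_cutoff=0.5)
        assert result.reactions == {"IN", "P1", "OUT"}

    def test_low_scores_kept_when_needed_for_objective(self, chain_net):
        scores = {"R1": 0.0, "R2": 0.0, "R3": 1.0}
        result = extract_gimme(chain_net, scores, "R3", score_cutoff=0.5)
        assert result.reactions == {"R1", "R2", "R3"}

    def test_blocked_objective_raises(self, deadend_net):
        scores = {r: 1.0 for r in deadend_net.reaction_ids}
        with pytest.raises(ValueError, match="cannot carry flux"):
            extract_gimme(deadend_net, scores, "R4", score_cutoff=0.5)

    def test_objective_flux_preserved_in_output(self, global_net):
        from gembench.synthgen import BIOMASS_ID
        from gembench._lp import solve_lp
        scores = {r: 0.0 for r in global_net.reaction_ids}
        result = extract_gimme(global_net, scores, BIOMASS_ID,
                               score_cutoff=0.5, objective_fraction=0.9)
        sub = global_net.subnetwork(sorted(result.reactions))
        jo = sub.reaction_index(BIOMASS_ID)
        c = np.zeros(sub.n_reactions)
        c[jo] = -1.0
        lb, ub = sub.capped_bounds()
        res = solve_lp(c, A_eq=sub.S, b_eq=np.zeros(sub.n_metabolites),
                       bounds=list(zip(lb, ub)))
        full_lb, full_ub = global_net.capped_bounds()
        c2 = np.zeros(global_net.n_reactions)
        c2[global_net.reaction_index(BIOMASS_ID)] = -1.0
        res_full = solve_lp(c2, A_eq=global_net.S,
                            b_eq=np.zeros(global_net.n_metabolites),
                            bounds=list(zip(full_lb, full_ub)))
        assert -res[1] >= 0.9 * (-res_full[1]) - 1e-6


class TestRegistry:
    def test_reference_extractors_registered(self):
        assert {"fastcore", "exclusive", "inclusive", "gimme"} <= set(
            list_extractors())

    def test_register_and_lookup(self):
        fn = lambda net, cores, cfg, **p: ExtractionResult(
            ReactionSet(), "noop")
        register_extractor("noop_test", fn)
        try:
            assert get_extractor("noop_test") is fn
            with pytest.raises(ValueError, match="already registered"):
                register_extractor("noop_test", fn)
        finally:
            import gembench.extractors as ex
            ex._REGISTRY.pop("noop_test", None)

    def test_contract_violation_detected(self, chain_net):
        bad = lambda net, cores, cfg, **p: ExtractionResult(
            ReactionSet({"NOT_A_REACTION"}), "bad")
        register_extractor("bad_test", bad)
        try:
            with pytest.raises(ValueError, match="contract"):
                run_extractor("bad_test", chain_net,
                              CoreSets(active=frozenset()))
        finally:
            import gembench.extractors as ex
            ex._REGISTRY.pop("bad_test", None)

    def test_unknown_extractor_lists_registered(self):
        with pytest.raises(KeyError, match="registered"):
            get_extractor("no_such_algorithm")
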