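"""Shared fixtures: toy networks with hand-checkable flux structure and a
session-scoped synthetic global network for protocol-level tests."""

import numpy as np
import pytest
import scipy.sparse as sp

from gembench.network import MetabolicNetwork
from gembench.synthgen import (BIOMASS_EXCHANGE_ID, BIOMASS_ID,
                               GlobalNetConfig, TargetSpec,
                               generate_global_network,
                               generate_target_models)


def make_network(reactions, reversible=(), bounds=1000.0, gpr=None,
                 subsystem=None):
    """Build a network from {rxn_id: {met: coef}} column specs."""
    rxn_ids = list(reactions)
    met_ids = []
    seen = set()
    for coeffs in reactions.values():
        for met in coeffs:
            if met not in seen:
                seen.add(met)
                met_ids.append(met)
    rows, cols, vals = [], [], []
    for j, coeffs in enumerate(reactions.values()):
        for met, coef in coeffs.items():
            rows.append(met_ids.index(met))
            cols.append(j)
            vals.append(float(coef))
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    lb = np.array([-bounds if r in reversible else 0.0 for r in rxn_ids])
    ub = np.full(len(rxn_ids), bounds)
    return MetabolicNetwork(
        metabolite_ids=met_ids, reaction_ids=rxn_ids, S=S, lb=lb, ub=ub,
        gpr=list(gpr) if gpr else [""] * len(rxn_ids),
        subsystem=list(subsystem) if subsystem else [""] * len(rxn_ids),
    )


@pytest.fixture
def chain_net():
    """R1: -> A; R2: A -> B; R3: B ->  (fully consistent linear chain)."""
    return make_network({
        "R1": {"A[c]": 1}, "R2": {"A[c]": -1, "B[c]": 1}, "R3": {"B[c]": -1},
    })


@pytest.fixture
def deadend_net():
    """Chain plus R4: A -> C where C has no consumer (R4 is blocked)."""
    return make_network({
        "R1": {"A[c]": 1}, "R2": {"A[c]": -1, "B[c]": 1},
        "R3": {"B[c]": -1}, "R4": {"A[c]": -1, "C[c]": 1},
    })


@pytest.fixture
def two_path_net():
    """Import A, two routes to B (direct P1, via C P2a+P2b), export B."""
    return make_network({
        "IN": {"A[c]": 1},
        "P1": {"A[c]": -1, "B[c]": 1},
        "P2a": {"A[c]": -1, "C[c]": 1},
        "P2b": {"C[c]": -1, "B[c]": 1},
        "OUT": {"B[c]": -1},
    })


def random_toy_network(rng, n_reactions=20, n_metabolites=10):
    """Small random network for oracle-equivalence sweeps; not guaranteed
    consistent — that is the point."""
    reactions = {}
    reversible = set()
    n_exchange = max(2, n_reactions // 5)
    mets = [f"m{i}[c]" for i in range(n_metabolites)]
    for j in range(n_reactions):
        rid = f"r{j}"
        if j < n_exchange:
            reactions[rid] = {str(rng.choice(mets)): -1.0}
            reversible.add(rid)
        else:
            k_sub = int(rng.integers(1, 3))
            k_prod = int(rng.integers(1, 3))
            chosen = rng.choice(mets, size=k_sub + k_prod, replace=False)
            coeffs = {str(m): -1.0 for m in chosen[:k_sub]}
            coeffs.update({str(m): 1.0 for m in chosen[k_sub:]})
            reactions[rid] = coeffs
            if rng.random() < 0.3:
                reversible.add(rid)
    return make_network(reactions, reversible=reversible)


@pytest.fixture(scope="session")
def global_net():
    return generate_global_network(GlobalNetConfig(seed=1))


@pytest.fixture(scope="session")
def small_targets(global_net):
    """Two mid-sized targets of the session network (fast to generate)."""
    n = global_net.n_reactions
    return generate_target_models(
        global_net,
        TargetSpec(sizes=(int(0.4 * n), int(0.65 * n)), tolerance=10, seed=2,
                   protected=(BIOMASS_ID, BIOMASS_EXCHANGE_ID)))
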