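"""Flux-consistency testing.

A reaction is *flux-consistent* if some steady-state flux distribution
(``S v = 0`` within bounds) pushes at least ``eps`` absolute flux through
it.  The module provides

* :func:`reaction_is_consistent` — the per-reaction two-LP oracle
  (maximize then minimize the reaction's flux), and
* :func:`consistent_subnetwork` — the full consistent set, computed with
  a FASTCC-style batched scheme whose result is contractually identical
  to running the oracle on every reaction.

The fast path has three exact stages.  First, dead-end elimination: a
metabolite that no remaining reaction can produce (or none can consume)
forces zero flux through all its reactions at steady state; iterated to
a fixpoint, this soundly marks a large share of inconsistent reactions
without any LP.  Second, batched positive certification: one LP
maximizes, over the still-undecided reactions, auxiliary variables
``t_i <= v_i`` with ``0 <= t_i <= eps`` — every reaction carrying
``>= eps`` flux in the optimum is consistent (reversible reactions get a
mirrored pass).  Third, whatever remains is settled by the per-reaction
oracle on the dead-end-free subnetwork, so negatives are never declared
heuristically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from ._lp import solve_lp
from .network import MetabolicNetwork, ReactionSet, DEFAULT_BOUND_CAP

__all__ = ["ConsistencyConfig", "reaction_is_consistent",
           "consistent_subnetwork", "consistent_fixpoint"]


@dataclass(frozen=True)
class ConsistencyConfig:
    """Numerical settings for consistency testing.

    ``eps`` is the minimum absolute flux a reaction must be able to
    carry (flux units; default 1e-4, the convention of the fast
    consistency-checking literature).  It must clear the solver's
    feasibility tolerance by a wide margin — at least 10x is enforced.
    """

    eps: float = 1e-4
    solver_tol: float = 1e-9
    bound_cap: float = DEFAULT_BOUND_CAP

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.eps < 10 * self.solver_tol:
            raise ValueError("eps must exceed solver tolerance by >= 10x")


def _bounds_list(net: MetabolicNetwork, cfg: ConsistencyConfig):
    lb, ub = net.capped_bounds(cfg.bound_cap)
    return lb, ub, list(zip(lb, ub))


def reaction_is_consistent(
    net: MetabolicNetwork, rxn: str, cfg: ConsistencyConfig = ConsistencyConfig()
) -> bool:
    """Two-LP oracle: can ``rxn`` carry ``>= eps`` flux in either direction?"""
    j = net.reaction_index(rxn)
    lb, ub, bounds = _bounds_list(net, cfg)
    b_eq = np.zeros(net.n_metabolites)
    c = np.zeros(net.n_reactions)

    c[j] = -1.0  # maximize v_j
    res = solve_lp(c, A_eq=net.S, b_eq=b_eq, bounds=bounds)
    if res is not None and -res[1] >= cfg.eps:
        return True
    if lb[j] < 0:
        c[j] = 1.0  # minimize v_j
        res = solve_lp(c, A_eq=net.S, b_eq=b_eq, bounds=bounds)
        if res is not None and res[1] <= -cfg.eps:
            return True
    return False


def _structurally_blocked(net: MetabolicNetwork, lb, ub) -> np.ndarray:
    """Exact dead-end elimination (see module docstring).  Returns the
    mask of provably blocked reactions — a sound subset of the LP
    oracle's negatives."""
    S = net.S.tocsr()
    # elementwise flux-contribution range of each (metabolite, reaction)
    lo = S.multiply(lb).tocsr()
    hi = S.multiply(ub).tocsr()
    prod_max = lo.maximum(hi)   # most this entry can add to the metabolite
    cons_min = lo.minimum(hi)   # most it can subtract
    can_prod = (prod_max > 0).tocsr()
    can_cons = (cons_min < 0).tocsr()
    incidence = (S != 0).tocsr()

    alive = np.ones(net.n_reactions, dtype=bool)
    while True:
        produce = (can_prod @ sp.diags(alive.astype(float))).sum(axis=1)
        consume = (can_cons @ sp.diags(alive.astype(float))).sum(axis=1)
        touched = (incidence @ sp.diags(alive.astype(float))).sum(axis=1)
        dead_mets = np.asarray(
            (touched > 0) & ((produce == 0) | (consume == 0))).ravel()
        if not dead_mets.any():
            return ~alive
        kill = np.asarray(incidence[dead_mets].sum(axis=0)).ravel() > 0
        kill &= alive
        if not kill.any():
            return ~alive
        alive &= ~kill


def _block_certify(net, cfg, block, forward, bounds):
    """One batched LP; returns flux vector or None if infeasible."""
    n = net.n_reactions
    k = len(block)
    # variables: v (n) then t (k); maximize sum(t)
    c = np.concatenate([np.zeros(n), -np.ones(k)])
    A_eq = sp.hstack([net.S, sp.csc_matrix((net.n_metabolites, k))])
    # t_i - s*v_i <= 0  (s = +1 forward, -1 backward)
    sign = 1.0 if forward else -1.0
    rows = np.arange(k)
    A_t = sp.csc_matrix((np.ones(k), (rows, n + rows)), shape=(k, n + k))
    A_v = sp.csc_matrix((-sign * np.ones(k), (rows, block)), shape=(k, n + k))
    res = solve_lp(c, A_eq=A_eq, b_eq=np.zeros(net.n_metabolites),
                   A_ub=A_t + A_v, b_ub=np.zeros(k),
                   bounds=bounds + [(0.0, cfg.eps)] * k)
    if res is None:
        return None
    return res[0][:n]


def consistent_subnetwork(
    net: MetabolicNetwork, cfg: ConsistencyConfig = ConsistencyConfig()
) -> ReactionSet:
    """The set of all flux-consistent reactions of ``net``.

    Equals ``{r : reaction_is_consistent(net, r, cfg)}`` exactly; the
    structural dead-end pass and the batching only accelerate the
    decision, they never change it.
    """
    if net.n_reactions == 0:
        return ReactionSet()
    lb_full, ub_full = net.capped_bounds(cfg.bound_cap)
    blocked = _structurally_blocked(net, lb_full, ub_full)
    if blocked.all():
        return ReactionSet()
    # blocked reactions carry zero flux in every feasible solution, so
    # consistency of the survivors is unchanged on the reduced network
    alive_ids = [r for r, b in zip(net.reaction_ids, blocked) if not b]
    sub = net.subnetwork(alive_ids) if blocked.any() else net

    n = sub.n_reactions
    lb, ub, bounds = _bounds_list(sub, cfg)
    rev = lb < 0
    undecided = np.ones(n, dtype=bool)
    consistent = np.zeros(n, dtype=bool)

    for forward in (True, False):
        while True:
            block = np.nonzero(undecided & (rev | forward))[0]
            if block.size == 0:
                break
            v = _block_certify(sub, cfg, block, forward, bounds)
            if v is None:
                break
            hit = np.abs(v) >= cfg.eps
            newly = hit & undecided
            if not newly.any():
                break
            consistent |= newly
            undecided &= ~newly

    # settle the rest one reaction at a time; each maximizing LP's flux
    # vector also certifies any other undecided reaction it pushes past
    # eps, so positives collapse quickly and only true negatives cost
    # their two LPs
    b_eq = np.zeros(sub.n_metabolites)
    for j in np.nonzero(undecided)[0]:
        if not undecided[j]:
            continue
        decided = False
        for sense in (-1.0, 1.0):
            if sense > 0 and not rev[j]:
                break
            c = np.zeros(n)
            c[j] = sense
            res = solve_lp(c, A_eq=sub.S, b_eq=b_eq, bounds=bounds)
            if res is None:
                break
            v = res[0]
            hit = (np.abs(v) >= cfg.eps) & undecided
            if hit.any():
                consistent |= hit
                undecided &= ~hit
            if abs(v[j]) >= cfg.eps:
                decided = True
                break
        if not decided:
            undecided[j] = False  # both directions proved below eps
    return ReactionSet(r for j, r in enumerate(sub.reaction_ids)
                       if consistent[j])


def consistent_fixpoint(
    net: MetabolicNetwork, cfg: ConsistencyConfig = ConsistencyConfig()
) -> ReactionSet:
    """Iterate :func:`consistent_subnetwork` on its own induced
    subnetwork until it stabilizes.

    Because "can carry >= eps flux" is judged against the surrounding
    network, a single pruning pass can leave reactions that were
    consistent only thanks to now-removed neighbours; iterating yields a
    *self-consistent* subnetwork — one that equals the consistent part
    of its own induced network.  This is the right notion for emitting
    standalone ground-truth models; it usually converges in one extra
    pass.
    """
    current = consistent_subnetwork(net, cfg)
    while True:
        if not current:
            return current
        sub = net.subnetwork(sorted(current))
        nxt = consistent_subnetwork(sub, cfg)
        if nxt == current:
            return current
        current = nxt
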