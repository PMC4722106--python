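"""Synthetic ground-truth generation for the benchmark.

Real benchmarking of extraction algorithms needs a global network whose
"true" context-specific subnetworks are known.  This module builds:

* random flux-consistent global networks with exchange reactions, GPR
  rules and subsystem labels (:func:`generate_global_network`);
* flux-consistent *target* submodels of prescribed sizes, obtained by
  random reaction removal followed by consistency pruning
  (:func:`generate_target_models`);
* partial present/absent evidence at a given information fraction
  (:func:`sample_partial_input`);
* z-score-like expression profiles in which genes of the target draw
  from an "expressed" normal distribution and all others from an
  "unexpressed" one (:func:`simulate_expression`);
* random subnetworks for the functionality-score size baseline
  (:func:`generate_random_subnetworks`).

Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .consistency import ConsistencyConfig, consistent_fixpoint
from .extractors import CoreSets
from .network import GeneScoreProfile, MetabolicNetwork, ReactionSet

__all__ = [
    "GlobalNetConfig", "TargetSpec", "ExpressionSimConfig",
    "generate_global_network", "generate_target_models",
    "sample_partial_input", "simulate_expression",
    "generate_random_subnetworks",
    "BIOMASS_ID", "BIOMASS_EXCHANGE_ID",
]

#: identifiers of the designated objective reaction and its boundary sink
BIOMASS_ID = "R_BIOMASS"
BIOMASS_EXCHANGE_ID = "EX_biomass"


@dataclass(frozen=True)
class GlobalNetConfig:
    """Shape parameters of a synthetic global network.

    ``n_reactions`` counts reactions generated *before* the final
    consistency pruning; the returned network keeps only the consistent
    part.  Defaults yield roughly 300 surviving reactions — large enough
    for the extraction benchmarks to be non-trivial, small enough that a
    full benchmark arm runs in minutes on one CPU.
    """

    n_metabolites: int = 120
    n_reactions: int = 330
    reversible_fraction: float = 0.3
    exchange_fraction: float = 0.15
    n_genes: int = 200
    mean_genes_per_reaction: float = 2.0
    isozyme_probability: float = 0.5
    gene_assoc_fraction: float = 0.85
    subsystem_count: int = 12
    seed: int = 0

    def __post_init__(self):
        for name in ("n_metabolites", "n_reactions", "n_genes",
                     "subsystem_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("reversible_fraction", "exchange_fraction",
                     "isozyme_probability", "gene_assoc_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class TargetSpec:
    """Request for target submodels of given sizes.

    ``tolerance`` is the accepted deviation (in reactions) from each
    requested size; ``max_removed`` caps how many reactions one attempt
    may delete; ``attempts`` bounds the retries per size.
    """

    sizes: Tuple[int, ...]
    tolerance: int = 10
    max_removed: Optional[int] = None
    attempts: int = 300
    seed: int = 0
    protected: Tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))
        object.__setattr__(self, "protected", tuple(self.protected))
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("sizes must be positive")


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Parameters of the two-population z-score simulation.

    Genes of the target draw per-sample scores from
    ``Normal(expressed_mean, expressed_sd)``; all other genes from
    ``Normal(unexpressed_mean, unexpressed_sd)``.  ``dropout_rate`` is
    the per-(gene, sample) probability that an expressed gene's value is
    replaced by an unexpressed draw, emulating probes lost in background.
    Defaults (8 +- 1.5 vs 0 +- 1) put the standard discretization
    thresholds (5 and 0) between the populations with realistic overlap.
    """

    expressed_mean: float = 8.0
    expressed_sd: float = 1.5
    unexpressed_mean: float = 0.0
    unexpressed_sd: float = 1.0
    n_samples: int = 10
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.expressed_sd <= 0 or self.unexpressed_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


# ---------------------------------------------------------------------
# global network
# ---------------------------------------------------------------------

def _random_gpr(rng, genes: Sequence[str], mean_genes: float,
                isozyme_p: float) -> str:
    k = 1 + rng.poisson(max(mean_genes - 1.0, 0.0))
    k = int(min(k, len(genes), 4))
    chosen = list(rng.choice(genes, size=k, replace=False))
    if k == 1:
        return chosen[0]
    if k >= 3 and rng.random() < 0.3:
        # mixed rule: a complex of two subunits with an isozyme alternative
        inner = f"({chosen[0]} and {chosen[1]})"
        rest = " or ".join(chosen[2:])
        return f"{inner} or {rest}"
    op = " or " if rng.random() < isozyme_p else " and "
    return op.join(chosen)


def generate_global_network(
    cfg: GlobalNetConfig = GlobalNetConfig(),
    consistency: ConsistencyConfig = ConsistencyConfig(),
) -> MetabolicNetwork:
    """Build a random flux-consistent global network.

    The raw network mixes internal conversions (1-2 substrates ->
    1-2 products), reversible boundary exchanges for a fraction of
    metabolites, and a designated biomass-like objective reaction
    (:data:`BIOMASS_ID`) consuming importable precursors and drained by
    its own exchange.  The returned network is the consistent part of
    the raw draw; an empty result raises with advice to raise
    ``exchange_fraction``.
    """
    rng = np.random.default_rng(cfg.seed)
    mets = [f"M{i:04d}[c]" for i in range(cfg.n_metabolites)]
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    subsystems = [f"SS{i:02d}" for i in range(cfg.subsystem_count)]

    n_exchange = int(round(cfg.exchange_fraction * cfg.n_reactions))
    n_internal = max(cfg.n_reactions - n_exchange - 2, 0)

    rxn_ids: List[str] = []
    lb: List[float] = []
    ub: List[float] = []
    gpr: List[str] = []
    subsystem: List[str] = []
    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []

    def add_column(coeffs):
        j = len(rxn_ids)
        for i, v in coeffs.items():
            rows.append(i)
            cols.append(j)
            vals.append(v)

    # boundary exchanges for a random subset of metabolites (reversible:
    # the environment may feed or drain them)
    exch_mets = rng.choice(cfg.n_metabolites, size=min(n_exchange, cfg.n_metabolites),
                           replace=False)
    for i in exch_mets:
        add_column({int(i): -1.0})
        rxn_ids.append(f"EX_M{i:04d}")
        lb.append(-1000.0)
        ub.append(1000.0)
        gpr.append("")
        subsystem.append("Exchange")

    # internal conversions
    for k in range(n_internal):
        n_sub = 1 + int(rng.random() < 0.4)
        n_prod = 1 + int(rng.random() < 0.4)
        chosen = rng.choice(cfg.n_metabolites, size=n_sub + n_prod, replace=False)
        coeffs = {}
        for i in chosen[:n_sub]:
            coeffs[int(i)] = -float(rng.choice([1.0, 1.0, 1.0, 2.0]))
        for i in chosen[n_sub:]:
            coeffs[int(i)] = float(rng.choice([1.0, 1.0, 1.0, 2.0]))
        add_column(coeffs)
        rxn_ids.append(f"R{k:04d}")
        reversible = rng.random() < cfg.reversible_fraction
        lb.append(-1000.0 if reversible else 0.0)
        ub.append(1000.0)
        gpr.append(_random_gpr(rng, genes, cfg.mean_genes_per_reaction,
                               cfg.isozyme_probability)
                   if rng.random() < cfg.gene_assoc_fraction else "")
        subsystem.append(str(rng.choice(subsystems)))

    # biomass-like objective: consumes importable precursors, drained by
    # its own exchange — consistent by construction
    mets.append("biomass[c]")
    n_prec = min(3, len(exch_mets))
    if n_prec:
        precursors = rng.choice(exch_mets, size=n_prec, replace=False)
        coeffs = {int(i): -1.0 for i in precursors}
        coeffs[cfg.n_metabolites] = 1.0
        add_column(coeffs)
        rxn_ids.append(BIOMASS_ID)
        lb.append(0.0)
        ub.append(1000.0)
        gpr.append("")
        subsystem.append("Biomass")
        add_column({cfg.n_metabolites: -1.0})
        rxn_ids.append(BIOMASS_EXCHANGE_ID)
        lb.append(0.0)
        ub.append(1000.0)
        gpr.append("")
        subsystem.append("Exchange")

    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(mets), len(rxn_ids)))
    # drop metabolites no reaction touches
    used = np.asarray((S != 0).sum(axis=1)).ravel() > 0
    raw = MetabolicNetwork(
        metabolite_ids=[m for m, u in zip(mets, used) if u],
        reaction_ids=rxn_ids, S=S[used, :],
        lb=np.array(lb), ub=np.array(ub), gpr=gpr, subsystem=subsystem,
    )
    consistent = consistent_fixpoint(raw, consistency)
    if not consistent:
        raise ValueError(
            "consistency pruning emptied the network; increase "
            "exchange_fraction or reversible_fraction")
    return raw.subnetwork(sorted(consistent))


# ---------------------------------------------------------------------
# target submodels
# ---------------------------------------------------------------------

def generate_target_models(
    net: MetabolicNetwork,
    spec: TargetSpec,
    consistency: ConsistencyConfig = ConsistencyConfig(),
) -> List[ReactionSet]:
    """Target submodels: for each requested size, repeatedly remove a
    random reaction subset and keep the consistent part of the remainder,
    until its size lands within ``spec.tolerance`` of the request.

    The number of removed reactions is adapted between attempts (stepping
    toward the requested size, with jitter) so that the attempt stream
    reaches each size band quickly; the first model within tolerance is
    accepted.  Reactions in ``spec.protected`` are never removed and must
    survive pruning.  Every returned target is flux-consistent by
    construction.
    """
    rng = np.random.default_rng(spec.seed)
    n = net.n_reactions
    max_removed = spec.max_removed if spec.max_removed is not None else n - 1
    protected = set(spec.protected)
    stray = protected - set(net.reaction_ids)
    if stray:
        raise ValueError(f"protected reactions not in network: {sorted(stray)}")
    removable = [r for r in net.reaction_ids if r not in protected]
    out: List[ReactionSet] = []
    achieved_log: List[int] = []
    for size in spec.sizes:
        if not 0 < size <= n:
            raise ValueError(f"requested size {size} outside (0, {n}]")
        k = int(np.clip(n - size, 1, max_removed))
        found = None
        for _ in range(spec.attempts):
            k = int(np.clip(k + rng.integers(-3, 4), 1, max_removed))
            drop = set(rng.choice(removable, size=min(k, len(removable)),
                                  replace=False))
            keep = [r for r in net.reaction_ids if r not in drop]
            sub = net.subnetwork(keep)
            target = consistent_fixpoint(sub, consistency)
            achieved = len(target)
            achieved_log.append(achieved)
            if abs(achieved - size) <= spec.tolerance and protected <= target:
                found = target
                break
            # removing more shrinks the consistent part: step toward the goal
            k = int(np.clip(k + 0.5 * (achieved - size), 1, max_removed))
        if found is None:
            raise RuntimeError(
                f"could not hit size {size} +- {spec.tolerance} in "
                f"{spec.attempts} attempts; achieved sizes ranged "
                f"{min(achieved_log)}..{max(achieved_log)}")
        out.append(found)
    return out


# ---------------------------------------------------------------------
# partial evidence
# ---------------------------------------------------------------------

def sample_partial_input(
    net: MetabolicNetwork,
    target: ReactionSet,
    fraction: float,
    seed: int,
) -> CoreSets:
    """Partial present/absent evidence at an information fraction.

    ``active`` is a uniform sample of ``floor(fraction * |target|)``
    target reactions; ``inactive`` a uniform sample of
    ``floor(fraction * |net \\ target|)`` non-target reactions.  A fixed
    seed yields the same sample, so the identical evidence can be fed to
    every algorithm under comparison.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    target = ReactionSet(target)
    stray = target - set(net.reaction_ids)
    if stray:
        raise ValueError(f"target reactions not in network: {sorted(stray)[:5]}")
    rng = np.random.default_rng(seed)
    inside = sorted(target)
    outside = sorted(set(net.reaction_ids) - target)
    n_act = int(np.floor(fraction * len(inside)))
    n_inact = int(np.floor(fraction * len(outside)))
    active = rng.choice(inside, size=n_act, replace=False) if n_act else []
    inactive = rng.choice(outside, size=n_inact, replace=False) if n_inact else []
    return CoreSets(active=ReactionSet(str(r) for r in active),
                    inactive=ReactionSet(str(r) for r in inactive))


# ---------------------------------------------------------------------
# expression profiles
# ---------------------------------------------------------------------

def simulate_expression(
    net: MetabolicNetwork,
    target: ReactionSet,
    cfg: ExpressionSimConfig = ExpressionSimConfig(),
) -> GeneScoreProfile:
    """Simulate a gene x sample z-score profile for a target context.

    Genes appearing in the GPR of at least one target reaction are
    "expressed"; all other network genes are "unexpressed".  Dropout
    replaces an expressed gene's sample value by an unexpressed draw.
    """
    target = ReactionSet(target)
    stray = target - set(net.reaction_ids)
    if stray:
        raise ValueError(f"target reactions not in network: {sorted(stray)[:5]}")
    expressed = set()
    for r in target:
        expressed |= net.genes_of(r)
    genes = list(net.gene_ids)
    if not genes:
        raise ValueError("network has no genes")
    rng = np.random.default_rng(cfg.seed)
    is_expr = np.array([g in expressed for g in genes])
    shape = (len(genes), cfg.n_samples)
    expr_draw = rng.normal(cfg.expressed_mean, cfg.expressed_sd, size=shape)
    unexpr_draw = rng.normal(cfg.unexpressed_mean, cfg.unexpressed_sd, size=shape)
    Z = np.where(is_expr[:, None], expr_draw, unexpr_draw)
    if cfg.dropout_rate > 0:
        dropped = (rng.random(size=shape) < cfg.dropout_rate) & is_expr[:, None]
        Z = np.where(dropped, unexpr_draw, Z)
    df = pd.DataFrame(Z, index=genes,
                      columns=[f"sample{j:02d}" for j in range(cfg.n_samples)])
    return GeneScoreProfile(df)


# ---------------------------------------------------------------------
# random subnetworks (functionality baseline)
# ---------------------------------------------------------------------

def generate_random_subnetworks(
    net: MetabolicNetwork,
    n: int,
    max_removed: int,
    seed: int,
    consistency: ConsistencyConfig = ConsistencyConfig(),
) -> List[ReactionSet]:
    """``n`` random flux-consistent subnetworks: each removes
    ``Uniform{0..max_removed}`` random reactions and keeps the consistent
    part of the remainder."""
    if not 0 <= max_removed < net.n_reactions:
        raise ValueError("max_removed must be in [0, n_reactions)")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        k = int(rng.integers(0, max_removed + 1))
        if k == 0:
            out.append(ReactionSet(net.reaction_ids))
            continue
        drop = set(rng.choice(net.reaction_ids, size=k, replace=False))
        keep = [r for r in net.reaction_ids if r not in drop]
        out.append(consistent_fixpoint(net.subnetwork(keep), consistency))
    return out
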