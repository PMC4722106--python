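"""Benchmark statistics: similarity, recovery, enrichment and validation.

Everything an extraction benchmark reports lives here:

* Jaccard similarity between reaction sets, pairwise matrices with
  hierarchical clustering, overlap/ubiquity histograms;
* resolution power — within- vs between-target mean Jaccard over
  repeated runs (diagonal ~ robustness, off-diagonal ~ inverse
  specificity);
* confusion metrics (sensitivity, specificity, FDR) against a known
  target network;
* left-out cross-validation with a hypergeometric enrichment score;
* two-sample Kolmogorov-Smirnov comparison of z-score distributions;
* proteomic confidence-category enrichment and per-pathway activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom, ks_2samp

from .consistency import ConsistencyConfig
from .extractors import CoreSets, run_extractor
from .gpr import NO_GENE, evaluate_gpr
from .network import ConfidenceMap, MetabolicNetwork, ReactionSet

__all__ = [
    "JaccardMatrix", "ConfusionStats", "CrossValResult",
    "jaccard_index", "jaccard_matrix", "overlap_counts",
    "resolution_power", "confusion_metrics", "hypergeom_tail",
    "cross_validate", "ks_two_sample", "confidence_enrichment",
    "ubiquity_counts", "pathway_activity",
]


# ---------------------------------------------------------------------
# Jaccard similarity & clustering
# ---------------------------------------------------------------------

def jaccard_index(A: Iterable[str], B: Iterable[str]) -> float:
    """|A n B| / |A u B|; two empty sets count as identical (1.0)."""
    A, B = set(A), set(B)
    union = A | B
    if not union:
        return 1.0
    return len(A & B) / len(union)


@dataclass
class JaccardMatrix:
    """Symmetric matrix of pairwise Jaccard indices with a clustering
    order of its rows (Euclidean distance on matrix rows)."""

    labels: List[str]
    matrix: np.ndarray
    leaf_order: List[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def jaccard_matrix(
    models: Mapping[str, Iterable[str]],
    linkage_method: str = "average",
) -> JaccardMatrix:
    """Pairwise Jaccard indices between labeled models, hierarchically
    clustered (Euclidean distance between matrix rows, configurable
    linkage)."""
    labels = list(models)
    if len(labels) < 2:
        raise ValueError("need at least two models")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate model labels")
    sets = [set(models[l]) for l in labels]
    K = len(sets)
    M = np.ones((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            M[i, j] = M[j, i] = jaccard_index(sets[i], sets[j])
    Z = linkage(M, method=linkage_method, metric="euclidean")
    return JaccardMatrix(labels, M, [int(i) for i in leaves_list(Z)])


def overlap_counts(models: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Per-model sharing-depth histogram.

    Entry ``(m, k)`` counts the reactions of model ``m`` found in exactly
    ``k`` of the K models (including ``m`` itself).  Row sums equal model
    sizes.
    """
    labels = list(models)
    if len(labels) < 2:
        raise ValueError("need at least two models")
    sets = {l: set(models[l]) for l in labels}
    union = set().union(*sets.values())
    depth = {r: sum(r in s for s in sets.values()) for r in union}
    K = len(labels)
    table = pd.DataFrame(0, index=labels, columns=range(1, K + 1))
    for l in labels:
        for r in sets[l]:
            table.loc[l, depth[r]] += 1
    return table


def ubiquity_counts(models: Mapping[str, Iterable[str]]) -> pd.Series:
    """Global histogram: number of reactions (over the union) present in
    exactly k of the K models."""
    labels = list(models)
    if len(labels) < 2:
        raise ValueError("need at least two models")
    sets = [set(models[l]) for l in labels]
    union = set().union(*sets)
    K = len(sets)
    counts = pd.Series(0, index=range(1, K + 1))
    for r in union:
        counts[sum(r in s for s in sets)] += 1
    return counts


def resolution_power(
    runs: Mapping[str, Sequence[Iterable[str]]],
) -> pd.DataFrame:
    """Within-/between-target mean Jaccard matrix over repeated runs.

    Entry ``(i, j)`` for ``i != j`` is the mean Jaccard over all cross
    pairs of runs for targets i and j; the diagonal is the mean over
    unordered within-target pairs (NaN if a target has fewer than two
    runs).  High diagonal = robust; low off-diagonal = able to resolve
    different targets.
    """
    labels = list(runs)
    sets = {l: [set(s) for s in runs[l]] for l in labels}
    for l in labels:
        if len(sets[l]) < 1:
            raise ValueError(f"target {l!r} has no runs")
    M = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, li in enumerate(labels):
        A = sets[li]
        if len(A) >= 2:
            vals = [jaccard_index(A[a], A[b])
                    for a in range(len(A)) for b in range(a + 1, len(A))]
            M.loc[li, li] = float(np.mean(vals))
        for lj in labels[i + 1:]:
            B = sets[lj]
            vals = [jaccard_index(a, b) for a in A for b in B]
            M.loc[li, lj] = M.loc[lj, li] = float(np.mean(vals))
    return M


# ---------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionStats:
    """Reaction-level confusion counts and derived fractions.

    ``sensitivity = TP/(TP+FN)``, ``specificity = TN/(TN+FP)``,
    ``FDR = FP/(TP+FP)`` with the 0/0 case (empty output) defined as 0.
    """

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 1.0

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP) if self.TN + self.FP else 1.0

    @property
    def fdr(self) -> float:
        return self.FP / (self.TP + self.FP) if self.TP + self.FP else 0.0


def confusion_metrics(
    output: Iterable[str],
    target: Iterable[str],
    universe: Iterable[str],
) -> ConfusionStats:
    """Compare an extracted model against its ground-truth target within
    a universe (the source network's reactions)."""
    output, target, universe = set(output), set(target), set(universe)
    if not output <= universe or not target <= universe:
        raise ValueError("output and target must be subsets of the universe")
    TP = len(output & target)
    FP = len(output - target)
    FN = len(target - output)
    TN = len(universe) - TP - FP - FN
    return ConfusionStats(TP, FP, FN, TN)


# ---------------------------------------------------------------------
# hypergeometric tail & cross-validation
# ---------------------------------------------------------------------

def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` population size, ``K`` successes in the population, ``n``
    draws, ``k`` observed successes.  Computed through scipy's
    log-space-stable survival function.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K, n <= N")
    if not 0 <= k <= min(K, n):
        raise ValueError("require 0 <= k <= min(K, n)")
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class CrossValResult:
    """Left-out cross-validation outcome.

    One row per repetition: validation-set size, number of validation
    reactions recovered in the output, output-model size, and the
    hypergeometric enrichment p-value.  Aggregates are means/SDs over
    repetitions.
    """

    table: pd.DataFrame  # columns: validation_size, recovered, model_size, p_value

    @property
    def mean_recovered_fraction(self) -> float:
        t = self.table
        return float((t.recovered / t.validation_size).mean())

    @property
    def mean_chance_fraction(self) -> float:
        """Mean expected-by-chance recovery fraction n*K/N / K = n/N."""
        return float((self.table.draws / self.table.population).mean())

    def summary(self) -> Dict[str, float]:
        t = self.table
        return {
            "reps": int(len(t)),
            "mean_validation_size": float(t.validation_size.mean()),
            "mean_recovered": float(t.recovered.mean()),
            "sd_recovered": float(t.recovered.std(ddof=1)) if len(t) > 1 else 0.0,
            "mean_recovered_fraction": self.mean_recovered_fraction,
            "mean_chance_fraction": self.mean_chance_fraction,
            "mean_model_size": float(t.model_size.mean()),
            "sd_model_size": float(t.model_size.std(ddof=1)) if len(t) > 1 else 0.0,
            "median_p_value": float(t.p_value.median()),
        }


def cross_validate(
    extractor: str,
    net: MetabolicNetwork,
    cores: CoreSets,
    holdout_fraction: float = 0.2,
    reps: int = 100,
    seed: int = 0,
    cfg: ConsistencyConfig = ConsistencyConfig(),
    **extractor_params,
) -> CrossValResult:
    """Left-out cross-validation of an extractor.

    Per repetition, ``floor(holdout_fraction * |active|)`` active core
    reactions move to a validation set; the extractor runs on the reduced
    evidence and the recovered validation reactions are counted.  The
    enrichment p-value uses a hypergeometric test with population =
    reactions outside the reduced core, successes = validation set,
    draws = non-core reactions the extractor added, observed = recovered.
    """
    if not cores.active:
        raise ValueError("cross-validation requires a nonempty active core")
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    active = sorted(cores.active)
    n_hold = int(np.floor(holdout_fraction * len(active)))
    if n_hold == 0:
        raise ValueError("active core too small for the holdout fraction")
    rows = []
    for _ in range(reps):
        validation = set(rng.choice(active, size=n_hold, replace=False))
        reduced = CoreSets(active=ReactionSet(set(active) - validation),
                           inactive=cores.inactive)
        result = run_extractor(extractor, net, reduced, cfg, **extractor_params)
        out = set(result.reactions)
        recovered = len(out & validation)
        population = set(net.reaction_ids) - reduced.active
        draws = out - reduced.active
        p = hypergeom_tail(len(population), len(validation),
                           len(draws), recovered)
        rows.append({
            "validation_size": n_hold,
            "recovered": recovered,
            "model_size": len(out),
            "population": len(population),
            "draws": len(draws),
            "p_value": p,
        })
    return CrossValResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------
# KS comparison
# ---------------------------------------------------------------------

def ks_two_sample(x: Sequence[float], y: Sequence[float]):
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    Returns ``(statistic, p_value)`` where the statistic is
    ``sup |F_x - F_y|`` over the empirical CDFs.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------
# confidence enrichment & pathway activity
# ---------------------------------------------------------------------

_CONF_ORD = {"not_detected": 0, "low": 1, "medium": 2, "high": 3}
_ORD_CONF = {v: k for k, v in _CONF_ORD.items()}


def confidence_enrichment(
    model: Iterable[str],
    net: MetabolicNetwork,
    conf: ConfidenceMap,
) -> pd.DataFrame:
    """Per-category counts and fractions of a model's reactions.

    A reaction's category combines its genes' categories through the GPR
    with OR = best (highest confidence) and AND = worst, on the ordinal
    scale high > medium > low > not_detected.  Genes absent from the map
    count as ``not_detected``.  Fractions are reported over the whole
    model and over its gene-associated reactions; reactions without
    genes are excluded from the latter denominator.
    """
    model = set(model)
    stray = model - set(net.reaction_ids)
    if stray:
        raise ValueError(f"model reactions not in network: {sorted(stray)[:5]}")
    ords = {g: _CONF_ORD[conf.get(g)] for g in net.gene_ids}
    counts = {c: 0 for c in _CONF_ORD}
    n_gene_assoc = 0
    for r in model:
        rule = net.gpr[net.reaction_index(r)]
        value = evaluate_gpr(rule, ords)
        if value is NO_GENE:
            continue
        n_gene_assoc += 1
        counts[_ORD_CONF[value]] += 1
    rows = []
    for cat in ("high", "medium", "low", "not_detected"):
        c = counts[cat]
        rows.append({
            "category": cat,
            "n_reactions": c,
            "fraction_of_model": c / len(model) if model else 0.0,
            "fraction_of_gene_associated": c / n_gene_assoc if n_gene_assoc else 0.0,
        })
    return pd.DataFrame(rows).set_index("category")


def pathway_activity(
    model: Iterable[str],
    net: MetabolicNetwork,
) -> pd.Series:
    """Fraction of each subsystem's reactions active in the model.

    Subsystems with no reactions in the network (empty labels included)
    are omitted.
    """
    model = set(model)
    totals: Dict[str, int] = {}
    hits: Dict[str, int] = {}
    for r, s in zip(net.reaction_ids, net.subsystem):
        if not s:
            continue
        totals[s] = totals.get(s, 0) + 1
        if r in model:
            hits[s] = hits.get(s, 0) + 1
    return pd.Series({s: hits.get(s, 0) / n for s, n in sorted(totals.items())},
                     dtype=float)
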