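"""Benchmark protocol drivers.

These functions wire the generator, the extractors and the statistics
into the two benchmark arms:

* :func:`run_recovery_benchmark` — the sensitivity/robustness protocol:
  for each target model and each information fraction, sample partial
  present/absent evidence, run every extractor on the *same* evidence,
  and score the outputs against the known target (confusion metrics) and
  against each other (Jaccard);
* :func:`run_resolution_analysis` — within- vs between-target mean
  Jaccard per extractor, from the recovery runs;
* :func:`run_crossval_benchmark` — left-out cross-validation per
  extractor on full-information evidence.

Each driver isolates extractor failures: a crashing algorithm is
reported in the run table (status column) without corrupting the other
algorithms' results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .benchstats import (CrossValResult, confusion_metrics, cross_validate,
                         resolution_power)
from .consistency import ConsistencyConfig
from .extractors import CoreSets, run_extractor
from .network import MetabolicNetwork, ReactionSet
from .synthgen import sample_partial_input

__all__ = ["RecoveryRuns", "run_recovery_benchmark",
           "run_resolution_analysis", "run_crossval_benchmark",
           "DEFAULT_FRACTIONS"]

#: the protocol's standard information fractions
DEFAULT_FRACTIONS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class RecoveryRuns:
    """Raw and aggregated results of the recovery protocol.

    ``table`` has one row per (target, fraction, repetition, extractor)
    with confusion metrics and sizes; ``outputs`` retains the extracted
    reaction sets keyed the same way, for similarity analyses.
    """

    table: pd.DataFrame
    outputs: Dict[Tuple[str, float, int, str], ReactionSet]

    def aggregate(self) -> pd.DataFrame:
        """Mean metrics per (extractor, fraction), over targets and reps."""
        ok = self.table[self.table.status == "ok"]
        return (ok.groupby(["extractor", "fraction"])
                  [["sensitivity", "specificity", "fdr", "jaccard_to_target",
                    "model_size"]]
                  .mean()
                  .reset_index())


def run_recovery_benchmark(
    net: MetabolicNetwork,
    targets: Mapping[str, Iterable[str]],
    extractors: Mapping[str, Dict],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    reps: int = 20,
    seed: int = 0,
    cfg: ConsistencyConfig = ConsistencyConfig(),
) -> RecoveryRuns:
    """Run the partial-information recovery protocol.

    ``targets`` maps labels to ground-truth reaction sets; ``extractors``
    maps registered extractor names to their extra keyword parameters.
    For every (target, fraction, repetition) one evidence sample is drawn
    and fed identically to all extractors.  Evidence seeds derive
    deterministically from ``seed``, so two runs with the same arguments
    are identical.
    """
    universe = ReactionSet(net.reaction_ids)
    rows = []
    outputs: Dict[Tuple[str, float, int, str], ReactionSet] = {}
    rng = np.random.default_rng(seed)
    for label, target in targets.items():
        target = ReactionSet(target)
        for fraction in fractions:
            for rep in range(reps):
                sample_seed = int(rng.integers(0, 2**31 - 1))
                cores = sample_partial_input(net, target, fraction, sample_seed)
                for name, params in extractors.items():
                    row = {"target": label, "fraction": fraction, "rep": rep,
                           "extractor": name, "status": "ok",
                           "sample_seed": sample_seed}
                    try:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            result = run_extractor(name, net, cores, cfg,
                                                   **params)
                    except Exception as exc:  # isolate per-extractor crashes
                        row.update(status=f"error: {exc}", model_size=0,
                                   sensitivity=np.nan, specificity=np.nan,
                                   fdr=np.nan, jaccard_to_target=np.nan)
                        rows.append(row)
                        continue
                    out = result.reactions
                    stats = confusion_metrics(out, target, universe)
                    inter = len(out & target)
                    union = len(out | target)
                    row.update(
                        model_size=len(out),
                        sensitivity=stats.sensitivity,
                        specificity=stats.specificity,
                        fdr=stats.fdr,
                        jaccard_to_target=(inter / union) if union else 1.0,
                        runtime_seconds=result.runtime_seconds,
                    )
                    rows.append(row)
                    outputs[(label, fraction, rep, name)] = out
    return RecoveryRuns(pd.DataFrame(rows), outputs)


def run_resolution_analysis(
    runs: RecoveryRuns,
    fraction: float,
) -> Dict[str, pd.DataFrame]:
    """Per-extractor within/between-target mean-Jaccard matrices at one
    information fraction (diagonal ~ robustness, off-diagonal ~ inverse
    resolution power)."""
    by_extractor: Dict[str, Dict[str, List[ReactionSet]]] = {}
    for (label, frac, rep, name), out in runs.outputs.items():
        if frac != fraction:
            continue
        by_extractor.setdefault(name, {}).setdefault(label, []).append(out)
    if not by_extractor:
        raise ValueError(f"no runs recorded at fraction {fraction}")
    return {name: resolution_power(per_target)
            for name, per_target in by_extractor.items()}


def run_crossval_benchmark(
    net: MetabolicNetwork,
    target: Iterable[str],
    extractors: Mapping[str, Dict],
    holdout_fraction: float = 0.2,
    reps: int = 100,
    seed: int = 0,
    cfg: ConsistencyConfig = ConsistencyConfig(),
) -> Dict[str, CrossValResult]:
    """Left-out cross-validation of each extractor on full-information
    evidence for one target (active = target, inactive = complement)."""
    target = ReactionSet(target)
    cores = CoreSets(active=target,
                     inactive=ReactionSet(set(net.reaction_ids) - target))
    out = {}
    for name, params in extractors.items():
        out[name] = cross_validate(name, net, cores, holdout_fraction, reps,
                                   seed, cfg, **params)
    return out
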