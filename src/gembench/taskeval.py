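"""Metabolic functionality (task) testing.

A *metabolic task* asks: given a set of importable and exportable
metabolites, can the network produce (or consume) stated objective
metabolites at steady state?  Instead of adding importer/exporter
reactions, the steady-state requirement is relaxed for the task
metabolites: with split fluxes ``v' = [v+; v-]`` (both nonnegative) and
doubled stoichiometry ``S' = [S, -S]``, the accumulation ``S' v'`` of
each metabolite is boxed between per-metabolite bounds ``bl <= S' v' <=
bu``:

* imported metabolites may be consumed (down to -10000),
* exported metabolites may accumulate (up to +10000),
* produced / consumed objective metabolites are pinned to exactly one
  unit of accumulation / depletion,
* all other metabolites stay balanced (0, 0).

All explicit exchange reactions are closed (``v+ - v- = 0``) so that
boundary traffic flows only through the task metabolites, and the LP
minimizes total flux ``sum(v+ + v-)``.  A task passes if the LP is
feasible with nonzero accumulation on every objective metabolite.

Two sign conventions are implemented for the objective rows (see
:func:`build_task_lp`): ``"accumulation"`` (default) pins produced
objectives at +1 and consumed at -1, the reading in which positive
``S v`` means net production; ``"literal"`` follows the historical
printed convention that assigns -1 to produced and +1 to consumed
objectives.  The two differ only by the sign of the objective rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import linregress, pearsonr

from ._lp import solve_lp
from .consistency import ConsistencyConfig
from .network import MetabolicNetwork, identify_exchange_reactions
from .synthgen import generate_random_subnetworks

__all__ = [
    "MetabolicTask", "TaskLP", "TaskResult", "TaskSuiteSummary",
    "read_tasks", "write_tasks", "build_task_lp", "run_task",
    "run_task_suite", "size_score_baseline", "generate_task_suite",
    "TASK_BOUND", "TASK_KINDS",
]

#: accumulation cap for imported/exported task metabolites (flux units)
TASK_BOUND = 10000.0

TASK_KINDS = ("network", "physiological")


@dataclass(frozen=True)
class MetabolicTask:
    """One functionality test.

    ``imported`` metabolites may be taken up, ``exported`` may be
    excreted; ``produced_objectives`` must accumulate and
    ``consumed_objectives`` must be depleted for the task to pass.
    ``kind`` groups tasks into network-level and physiological suites.
    """

    id: str
    kind: str
    imported: frozenset = frozenset()
    exported: frozenset = frozenset()
    produced_objectives: frozenset = frozenset()
    consumed_objectives: frozenset = frozenset()
    description: str = ""

    def __post_init__(self):
        for name in ("imported", "exported", "produced_objectives",
                     "consumed_objectives"):
            object.__setattr__(self, name, frozenset(getattr(self, name)))
        if self.kind not in TASK_KINDS:
            raise ValueError(f"unknown task kind {self.kind!r}; "
                             f"allowed: {TASK_KINDS}")
        overlap = self.produced_objectives & self.consumed_objectives
        if overlap:
            raise ValueError(
                f"task {self.id}: metabolites cannot be both produced and "
                f"consumed objectives: {sorted(overlap)}")

    @property
    def metabolites(self) -> frozenset:
        return (self.imported | self.exported
                | self.produced_objectives | self.consumed_objectives)


@dataclass
class TaskLP:
    """Assembled task LP: doubled stoichiometry and accumulation bounds."""

    S_prime: sp.csc_matrix      # [S, -S], metabolites x 2n
    bl: np.ndarray              # per-metabolite accumulation lower bound
    bu: np.ndarray              # per-metabolite accumulation upper bound
    vplus_ub: np.ndarray        # 0 <= v+ <= this
    vminus_ub: np.ndarray       # 0 <= v- <= this
    exchange_idx: np.ndarray    # columns whose net flux is pinned to zero


@dataclass
class TaskResult:
    """Outcome of one task on one network."""

    task_id: str
    status: str                 # "pass" | "fail" | "unresolvable"
    objective_value: Optional[float] = None
    accumulation: Dict[str, float] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return self.status == "pass"


# ---------------------------------------------------------------------
# task file I/O (TSV with comma-separated metabolite lists; JSON mirror)
# ---------------------------------------------------------------------

_TASK_COLUMNS = ["id", "kind", "imported", "exported", "produced",
                 "consumed", "description"]


def _split(cell: str) -> frozenset:
    cell = (cell or "").strip()
    return frozenset(x.strip() for x in cell.split(",") if x.strip())


def read_tasks(path) -> List[MetabolicTask]:
    """Read a task suite from TSV or JSON (by extension)."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            records = json.load(fh)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = set(_TASK_COLUMNS[:6]) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        records = df.to_dict("records")
    tasks, seen = [], set()
    for rec in records:
        tid = rec["id"]
        if tid in seen:
            raise ValueError(f"duplicate task id {tid!r}")
        seen.add(tid)
        tasks.append(MetabolicTask(
            id=tid, kind=rec["kind"],
            imported=_split(rec.get("imported", "")),
            exported=_split(rec.get("exported", "")),
            produced_objectives=_split(rec.get("produced", "")),
            consumed_objectives=_split(rec.get("consumed", "")),
            description=rec.get("description", ""),
        ))
    return tasks


def write_tasks(tasks: Sequence[MetabolicTask], path) -> None:
    path = str(path)
    records = [{
        "id": t.id, "kind": t.kind,
        "imported": ",".join(sorted(t.imported)),
        "exported": ",".join(sorted(t.exported)),
        "produced": ",".join(sorted(t.produced_objectives)),
        "consumed": ",".join(sorted(t.consumed_objectives)),
        "description": t.description,
    } for t in tasks]
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    else:
        pd.DataFrame(records, columns=_TASK_COLUMNS).to_csv(
            path, sep="\t", index=False)


# ---------------------------------------------------------------------
# LP construction & solving
# ---------------------------------------------------------------------

def build_task_lp(
    net: MetabolicNetwork,
    task: MetabolicTask,
    sign_mode: str = "accumulation",
    cap: float = TASK_BOUND,
) -> TaskLP:
    """Assemble the task LP for a network.

    Raises :class:`KeyError` if a task metabolite is missing from the
    network (callers wanting a soft failure use :func:`run_task`).
    """
    if sign_mode not in ("accumulation", "literal"):
        raise ValueError(f"unknown sign_mode {sign_mode!r}")
    m, n = net.S.shape
    bl = np.zeros(m)
    bu = np.zeros(m)
    for met in task.imported:
        bl[net.metabolite_index(met)] = -cap
    for met in task.exported:
        bu[net.metabolite_index(met)] = cap
    sign = 1.0 if sign_mode == "accumulation" else -1.0
    for met in task.produced_objectives:
        i = net.metabolite_index(met)
        bl[i] = bu[i] = sign * 1.0
    for met in task.consumed_objectives:
        i = net.metabolite_index(met)
        bl[i] = bu[i] = -sign * 1.0
    lb, ub = net.capped_bounds(cap)
    S = net.S.tocsc()
    exchange = identify_exchange_reactions(net)
    exchange_idx = np.array(sorted(net.reaction_index(r) for r in exchange),
                            dtype=int)
    return TaskLP(
        S_prime=sp.hstack([S, -S], format="csc"),
        bl=bl, bu=bu,
        vplus_ub=np.maximum(ub, 0.0),
        vminus_ub=np.maximum(-lb, 0.0),
        exchange_idx=exchange_idx,
    )


def run_task(
    net: MetabolicNetwork,
    task: MetabolicTask,
    sign_mode: str = "accumulation",
) -> TaskResult:
    """Evaluate one task on one network.

    Tasks naming metabolites absent from the network return status
    ``"unresolvable"`` (a subnetwork legitimately lacks metabolites);
    infeasible LPs return ``"fail"``.
    """
    missing = task.metabolites - set(net.metabolite_ids)
    if missing:
        return TaskResult(task.id, "unresolvable")
    lp = build_task_lp(net, task, sign_mode)
    m, n = net.S.shape
    n2 = 2 * n
    c = np.ones(n2)
    # bl <= S' v' <= bu   ->   S' v' <= bu  and  -S' v' <= -bl
    A_ub = sp.vstack([lp.S_prime, -lp.S_prime], format="csc")
    b_ub = np.concatenate([lp.bu, -lp.bl])
    A_eq = None
    b_eq = None
    k = len(lp.exchange_idx)
    if k:
        rows = np.arange(k)
        data = np.concatenate([np.ones(k), -np.ones(k)])
        rr = np.concatenate([rows, rows])
        cc = np.concatenate([lp.exchange_idx, lp.exchange_idx + n])
        A_eq = sp.csc_matrix((data, (rr, cc)), shape=(k, n2))
        b_eq = np.zeros(k)
    bounds = ([(0.0, u) for u in lp.vplus_ub]
              + [(0.0, u) for u in lp.vminus_ub])
    res = solve_lp(c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds)
    if res is None:
        return TaskResult(task.id, "fail")
    v, fun = res
    acc = lp.S_prime @ v
    accumulation = {met: float(acc[net.metabolite_index(met)])
                    for met in (task.produced_objectives
                                | task.consumed_objectives)}
    ok = all(abs(a) > 1e-9 for a in accumulation.values())
    return TaskResult(task.id, "pass" if ok else "fail",
                      objective_value=float(fun), accumulation=accumulation)


@dataclass
class TaskSuiteSummary:
    """Aggregated suite outcome with per-task detail."""

    results: List[TaskResult]
    counts_by_kind: pd.DataFrame  # index kind, columns pass/fail/unresolvable

    @property
    def n_passed(self) -> int:
        return int(sum(r.passed for r in self.results))

    @property
    def score(self) -> float:
        """Fraction of tasks passed."""
        return self.n_passed / len(self.results) if self.results else 0.0


def run_task_suite(
    net: MetabolicNetwork,
    tasks: Sequence[MetabolicTask],
    sign_mode: str = "accumulation",
) -> TaskSuiteSummary:
    """Evaluate a task suite; counts are broken down by task kind."""
    if not tasks:
        raise ValueError("task suite is empty")
    results = []
    for task in tasks:
        try:
            results.append(run_task(net, task, sign_mode))
        except Exception as exc:
            raise RuntimeError(f"task {task.id!r} failed to solve") from exc
    kinds = sorted({t.kind for t in tasks})
    table = pd.DataFrame(0, index=kinds,
                         columns=["pass", "fail", "unresolvable"])
    for task, result in zip(tasks, results):
        table.loc[task.kind, result.status] += 1
    return TaskSuiteSummary(results, table)


# ---------------------------------------------------------------------
# synthetic task suites and the size baseline
# ---------------------------------------------------------------------

def generate_task_suite(
    net: MetabolicNetwork,
    n_tasks: int = 40,
    seed: int = 0,
    max_imported: int = 3,
    max_attempts_factor: int = 50,
) -> List[MetabolicTask]:
    """Synthetic task suite: random import -> produce (or consume)
    functionality probes, each verified feasible on the full network.

    This stands in for curated physiological task collections, which are
    external data; half the accepted tasks are labeled ``network`` and
    half ``physiological`` (the labels only group reporting).
    """
    rng = np.random.default_rng(seed)
    mets = list(net.metabolite_ids)
    tasks: List[MetabolicTask] = []
    attempts = 0
    while len(tasks) < n_tasks:
        attempts += 1
        if attempts > max_attempts_factor * n_tasks:
            raise RuntimeError(
                f"could not assemble {n_tasks} feasible tasks "
                f"({len(tasks)} found in {attempts} attempts)")
        k = int(rng.integers(1, max_imported + 1))
        chosen = rng.choice(mets, size=k + 1, replace=False)
        imported = frozenset(str(x) for x in chosen[:k])
        objective = str(chosen[k])
        produce = bool(rng.random() < 0.5)
        kind = TASK_KINDS[len(tasks) % 2]
        task = MetabolicTask(
            id=f"T{len(tasks):03d}", kind=kind,
            imported=imported if produce else imported | {objective},
            exported=frozenset() if produce else frozenset(),
            produced_objectives=frozenset([objective]) if produce else frozenset(),
            consumed_objectives=frozenset() if produce else frozenset([objective]),
            description=("produce " if produce else "consume ") + objective,
        )
        if run_task(net, task).passed:
            tasks.append(task)
    return tasks


def size_score_baseline(
    net: MetabolicNetwork,
    tasks: Sequence[MetabolicTask],
    n_networks: int = 100,
    max_removed: int = 150,
    seed: int = 0,
    consistency: ConsistencyConfig = ConsistencyConfig(),
) -> Dict[str, object]:
    """Random-subnetwork functionality baseline.

    Generates random flux-consistent subnetworks, scores each with the
    task suite, and regresses tasks-passed on network size (ordinary
    least squares).  Returns the per-network ``(size, score)`` table, the
    regression slope/intercept/R^2, and the Pearson correlation; with
    zero size variance the fit fields are ``None``.
    """
    subnets = generate_random_subnetworks(net, n_networks, max_removed, seed,
                                          consistency)
    rows = []
    for i, reactions in enumerate(subnets):
        sub = net.subnetwork(sorted(reactions))
        summary = run_task_suite(sub, tasks)
        rows.append({"network": i, "size": len(reactions),
                     "passed": summary.n_passed})
    table = pd.DataFrame(rows)
    out: Dict[str, object] = {"table": table}
    if table["size"].nunique() < 2:
        out.update(slope=None, intercept=None, r_squared=None,
                   pearson_r=None, pearson_p=None)
        return out
    fit = linregress(table["size"], table["passed"])
    r, p = pearsonr(table["size"], table["passed"])
    out.update(slope=float(fit.slope), intercept=float(fit.intercept),
               r_squared=float(fit.rvalue ** 2),
               pearson_r=float(r), pearson_p=float(p))
    return out
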