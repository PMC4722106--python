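"""Metabolic network data model and file I/O.

The central container is :class:`MetabolicNetwork`: a stoichiometric
matrix ``S`` (metabolite x reaction, sparse), per-reaction flux bounds,
GPR rules and subsystem labels.  Two on-disk formats are supported:

* SBML Level 3 with the FBC extension (read/written through cobrapy);
* a plain-TSV "tabular" dialect with columns ``reaction_id``,
  ``equation``, ``lb``, ``ub``, ``gpr``, ``subsystem``, where the
  equation uses ``->`` for irreversible and ``<=>`` for reversible
  reactions, e.g. ``1 A[c] + 2 B[c] -> 1 C[c]``.  An empty side denotes a
  boundary (exchange) reaction.

Gene-level evidence is carried as a :class:`GeneScoreProfile`
(gene x sample table of Barcode-style z-scores) or a
:class:`ConfidenceMap` (gene -> proteomic confidence category).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gpr import NO_GENE, evaluate_gpr, gpr_genes

__all__ = [
    "MetabolicNetwork", "GeneScoreProfile", "ConfidenceMap", "ReactionSet",
    "NetworkValidationError", "read_model", "write_model",
    "identify_exchange_reactions", "map_scores_to_reactions",
    "read_gene_scores", "write_gene_scores", "read_confidence_map",
    "read_reaction_set", "write_reaction_set",
    "CONFIDENCE_LEVELS",
]

CONFIDENCE_LEVELS = ("high", "medium", "low", "not_detected")

#: default cap replacing infinite bounds, matching the task-LP flux cap
DEFAULT_BOUND_CAP = 10000.0


class NetworkValidationError(ValueError):
    """Raised when a network violates its structural invariants."""


# A reaction set is simply a frozenset/set of reaction identifiers; an
# optional provenance label travels alongside where useful.
ReactionSet = frozenset


@dataclass
class MetabolicNetwork:
    """A constraint-based metabolic network.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Ordered unique identifiers (metabolites carry a compartment
        suffix such as ``[c]``).
    S
        Stoichiometric matrix, shape ``(n_metabolites, n_reactions)``.
    lb, ub
        Per-reaction lower/upper flux bounds, ``lb <= ub`` elementwise.
    gpr
        Per-reaction GPR rule strings (may be empty).
    subsystem
        Per-reaction pathway labels (may be empty).
    """

    metabolite_ids: List[str]
    reaction_ids: List[str]
    S: sp.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    gpr: List[str]
    subsystem: List[str]
    gene_ids: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.S = sp.csc_matrix(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        m, n = self.S.shape
        if len(self.metabolite_ids) != m or len(self.reaction_ids) != n:
            raise NetworkValidationError(
                f"S is {m}x{n} but {len(self.metabolite_ids)} metabolites / "
                f"{len(self.reaction_ids)} reactions were given")
        for name, ids in (("reaction", self.reaction_ids),
                          ("metabolite", self.metabolite_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise NetworkValidationError(f"duplicate {name} ids: {dupes}")
        if self.lb.shape != (n,) or self.ub.shape != (n,):
            raise NetworkValidationError("lb/ub length must equal #reactions")
        if len(self.gpr) != n or len(self.subsystem) != n:
            raise NetworkValidationError("gpr/subsystem length must equal #reactions")
        bad = np.nonzero(self.lb > self.ub)[0]
        if bad.size:
            raise NetworkValidationError(
                f"lb > ub for reactions {[self.reaction_ids[i] for i in bad]}")
        referenced = set()
        for rule in self.gpr:
            referenced |= gpr_genes(rule)
        if not self.gene_ids:
            self.gene_ids = sorted(referenced)
        elif not referenced <= set(self.gene_ids):
            raise NetworkValidationError(
                f"GPR genes missing from gene_ids: {sorted(referenced - set(self.gene_ids))}")
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
        self._met_index = {m_: i for i, m_ in enumerate(self.metabolite_ids)}

    # -- basic queries -------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def reaction_index(self, rxn: str) -> int:
        try:
            return self._rxn_index[rxn]
        except KeyError:
            raise KeyError(f"reaction {rxn!r} not in network") from None

    def metabolite_index(self, met: str) -> int:
        try:
            return self._met_index[met]
        except KeyError:
            raise KeyError(f"metabolite {met!r} not in network") from None

    def reversible(self) -> np.ndarray:
        """Boolean mask: reaction can run backwards (lb < 0)."""
        return self.lb < 0

    def capped_bounds(self, cap: float = DEFAULT_BOUND_CAP):
        """Bounds with +-inf replaced by +-cap (keeps every LP bounded)."""
        lb = np.where(np.isneginf(self.lb), -cap, self.lb)
        ub = np.where(np.isposinf(self.ub), cap, self.ub)
        return lb, ub

    def genes_of(self, rxn: str) -> set:
        return gpr_genes(self.gpr[self.reaction_index(rxn)])

    # -- derived networks ----------------------------------------------

    def subnetwork(self, reactions: Iterable[str]) -> "MetabolicNetwork":
        """Induced subnetwork: keep the given reactions and every
        metabolite still touched by at least one of them."""
        keep = [self.reaction_index(r) for r in reactions]
        keep.sort()
        S = self.S[:, keep]
        used = np.asarray((S != 0).sum(axis=1)).ravel() > 0
        return MetabolicNetwork(
            metabolite_ids=[m for m, u in zip(self.metabolite_ids, used) if u],
            reaction_ids=[self.reaction_ids[i] for i in keep],
            S=S[used, :],
            lb=self.lb[keep], ub=self.ub[keep],
            gpr=[self.gpr[i] for i in keep],
            subsystem=[self.subsystem[i] for i in keep],
        )

    def reactions_of_subsystem(self, name: str) -> ReactionSet:
        return ReactionSet(r for r, s in zip(self.reaction_ids, self.subsystem)
                           if s == name)


# ---------------------------------------------------------------------
# evidence containers
# ---------------------------------------------------------------------

@dataclass
class GeneScoreProfile:
    """Gene x sample score table (z-score units).

    ``scores`` is a pandas DataFrame indexed by gene with one column per
    sample; all entries must be finite.
    """

    scores: pd.DataFrame

    def __post_init__(self):
        self.scores = self.scores.astype(float)
        if self.scores.empty:
            raise ValueError("empty gene score profile")
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("gene scores must be finite")
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate gene ids in profile")

    @property
    def genes(self) -> List[str]:
        return list(self.scores.index)

    @property
    def samples(self) -> List[str]:
        return list(self.scores.columns)

    def median_per_gene(self) -> pd.Series:
        return self.scores.median(axis=1)


@dataclass
class ConfidenceMap:
    """Gene -> proteomic confidence category."""

    categories: Dict[str, str]

    def __post_init__(self):
        bad = {g: c for g, c in self.categories.items()
               if c not in CONFIDENCE_LEVELS}
        if bad:
            raise ValueError(
                f"unknown confidence categories (allowed {CONFIDENCE_LEVELS}): {bad}")

    def get(self, gene: str) -> str:
        """Category for a gene; genes absent from the atlas count as
        ``not_detected``."""
        return self.categories.get(gene, "not_detected")


# ---------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------

_TAB_COLUMNS = ["reaction_id", "equation", "lb", "ub", "gpr", "subsystem"]
_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def _parse_side(side: str) -> List[tuple]:
    side = side.strip()
    if not side:
        return []
    terms = []
    for chunk in side.split(" + "):
        m = _TERM_RE.match(chunk.strip())
        if m is None:
            raise ValueError(f"cannot parse equation term {chunk!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        terms.append((m.group(2), coef))
    return terms


def _parse_equation(eq: str):
    for arrow, rev in (("<=>", True), ("->", False)):
        if arrow in eq:
            left, right = eq.split(arrow, 1)
            return _parse_side(left), _parse_side(right), rev
    raise ValueError(f"equation {eq!r} has no '->' or '<=>' arrow")


def _format_side(terms) -> str:
    return " + ".join(f"{coef:g} {met}" for met, coef in terms)


def _read_tabular(path) -> MetabolicNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_TAB_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("gpr", "subsystem"):
        if col not in df.columns:
            df[col] = ""
    rxn_ids, met_ids, met_pos = [], [], {}
    rows, cols, vals = [], [], []
    lb, ub = [], []
    for j, row in df.iterrows():
        rid = row["reaction_id"]
        if rid in rxn_ids:
            raise NetworkValidationError(
                f"{path}: duplicate reaction id {rid!r} (line {j + 2})")
        try:
            left, right, rev = _parse_equation(row["equation"])
        except ValueError as exc:
            raise ValueError(f"{path}: line {j + 2}: {exc}") from exc
        coeffs: Dict[str, float] = {}
        for met, coef in left:
            coeffs[met] = coeffs.get(met, 0.0) - coef
        for met, coef in right:
            coeffs[met] = coeffs.get(met, 0.0) + coef
        for met, coef in coeffs.items():
            if coef == 0.0:
                continue
            if met not in met_pos:
                met_pos[met] = len(met_ids)
                met_ids.append(met)
            rows.append(met_pos[met])
            cols.append(len(rxn_ids))
            vals.append(coef)
        rxn_ids.append(rid)
        lb.append(float(row["lb"]))
        ub.append(float(row["ub"]))
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    return MetabolicNetwork(
        metabolite_ids=met_ids, reaction_ids=rxn_ids, S=S,
        lb=np.array(lb), ub=np.array(ub),
        gpr=list(df["gpr"]), subsystem=list(df["subsystem"]),
    )


def _write_tabular(net: MetabolicNetwork, path) -> None:
    S = net.S.tocsc()
    records = []
    for j, rid in enumerate(net.reaction_ids):
        col = S.getcol(j).tocoo()
        left = [(net.metabolite_ids[i], -v) for i, v in zip(col.row, col.data) if v < 0]
        right = [(net.metabolite_ids[i], v) for i, v in zip(col.row, col.data) if v > 0]
        arrow = "<=>" if net.lb[j] < 0 else "->"
        eq = f"{_format_side(left)} {arrow} {_format_side(right)}".strip()
        records.append({
            "reaction_id": rid, "equation": eq,
            "lb": repr(float(net.lb[j])), "ub": repr(float(net.ub[j])),
            "gpr": net.gpr[j], "subsystem": net.subsystem[j],
        })
    pd.DataFrame(records, columns=_TAB_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------

def _from_cobra(model) -> MetabolicNetwork:
    met_ids = [m.id for m in model.metabolites]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    rxn_ids, lb, ub, gpr, subsystem = [], [], [], [], []
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions):
        rxn_ids.append(rxn.id)
        lb.append(rxn.lower_bound)
        ub.append(rxn.upper_bound)
        gpr.append(rxn.gene_reaction_rule or "")
        subsystem.append(rxn.subsystem or "")
        for met, coef in rxn.metabolites.items():
            rows.append(met_pos[met.id])
            cols.append(j)
            vals.append(float(coef))
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    return MetabolicNetwork(met_ids, rxn_ids, S, np.array(lb), np.array(ub),
                            gpr, subsystem)


def _to_cobra(net: MetabolicNetwork, model_id: str = "gembench"):
    import cobra

    model = cobra.Model(model_id)
    mets = {}
    for mid in net.metabolite_ids:
        compartment = mid[mid.rfind("[") + 1:-1] if mid.endswith("]") else "c"
        mets[mid] = cobra.Metabolite(mid, compartment=compartment)
    model.add_metabolites(list(mets.values()))
    rxns = []
    S = net.S.tocsc()
    for j, rid in enumerate(net.reaction_ids):
        rxn = cobra.Reaction(rid, lower_bound=float(net.lb[j]),
                             upper_bound=float(net.ub[j]))
        rxn.subsystem = net.subsystem[j]
        rxns.append(rxn)
    model.add_reactions(rxns)
    for j, rxn in enumerate(rxns):
        col = S.getcol(j).tocoo()
        rxn.add_metabolites({mets[net.metabolite_ids[i]]: float(v)
                             for i, v in zip(col.row, col.data)})
        rule = net.gpr[j]
        if rule:
            rxn.gene_reaction_rule = rule
    # subsystems persist through SBML as group memberships
    by_subsystem: Dict[str, list] = {}
    for rxn, label in zip(rxns, net.subsystem):
        if label:
            by_subsystem.setdefault(label, []).append(rxn)
    if by_subsystem:
        from cobra.core import Group

        model.add_groups([Group(f"group_{i}", name=label, members=members)
                          for i, (label, members)
                          in enumerate(sorted(by_subsystem.items()))])
    return model


def read_model(path, format: str = "tabular") -> MetabolicNetwork:
    """Read a metabolic network from ``path`` (``"sbml"`` or ``"tabular"``)."""
    if format == "tabular":
        return _read_tabular(path)
    if format == "sbml":
        import cobra.io

        return _from_cobra(cobra.io.read_sbml_model(str(path)))
    raise ValueError(f"unknown model format {format!r}")


def write_model(net: MetabolicNetwork, path, format: str = "tabular") -> None:
    """Write a metabolic network to ``path`` in the named format."""
    if format == "tabular":
        _write_tabular(net, path)
    elif format == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(_to_cobra(net), str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------
# exchange detection
# ---------------------------------------------------------------------

def identify_exchange_reactions(
    net: MetabolicNetwork,
    boundary_suffix: Optional[str] = None,
) -> ReactionSet:
    """Reactions that move mass across the system boundary.

    A reaction is an exchange if its stoichiometric column has a single
    nonzero entry (the standard genome-scale encoding), or — when
    ``boundary_suffix`` is given, e.g. ``"[e]"`` — if all its non-boundary
    entries vanish after dropping metabolites in the boundary compartment.
    Orphan reactions (all-zero column) are invalid.
    """
    S = net.S.tocsc()
    exchanges = []
    boundary = None
    if boundary_suffix is not None:
        boundary = np.array([m.endswith(boundary_suffix)
                             for m in net.metabolite_ids])
    for j, rid in enumerate(net.reaction_ids):
        col = S.getcol(j).tocoo()
        if col.nnz == 0:
            raise NetworkValidationError(
                f"orphan reaction {rid!r}: empty stoichiometric column")
        if col.nnz == 1:
            exchanges.append(rid)
        elif boundary is not None:
            internal = [v for i, v in zip(col.row, col.data) if not boundary[i]]
            if len(internal) <= 1 or all(v < 0 for v in internal) \
                    or all(v > 0 for v in internal):
                if len(internal) < col.nnz:
                    exchanges.append(rid)
    return ReactionSet(exchanges)


# ---------------------------------------------------------------------
# score mapping
# ---------------------------------------------------------------------

def map_scores_to_reactions(
    net: MetabolicNetwork,
    profile: GeneScoreProfile,
    reducer: str = "median-then-gpr",
) -> Dict[str, object]:
    """Map gene-level scores onto reactions through the GPR rules.

    ``reducer``:

    * ``"median-then-gpr"`` — take each gene's median across samples,
      then evaluate the GPR (AND=min, OR=max);
    * ``"gpr-per-sample"`` — evaluate the GPR per sample, then take the
      median across samples.

    Reactions without genes map to :data:`~gembench.gpr.NO_GENE`.
    """
    if reducer == "median-then-gpr":
        med = profile.median_per_gene().to_dict()
        return {r: evaluate_gpr(net.gpr[j], med)
                for j, r in enumerate(net.reaction_ids)}
    if reducer == "gpr-per-sample":
        out = {}
        per_sample = [profile.scores[c].to_dict() for c in profile.samples]
        for j, r in enumerate(net.reaction_ids):
            rule = net.gpr[j]
            vals = [evaluate_gpr(rule, s) for s in per_sample]
            out[r] = NO_GENE if vals[0] is NO_GENE else float(np.median(vals))
        return out
    raise ValueError(f"unknown reducer {reducer!r}")


# ---------------------------------------------------------------------
# small-format I/O
# ---------------------------------------------------------------------

def read_gene_scores(path) -> GeneScoreProfile:
    """Read a gene x sample TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return GeneScoreProfile(df)


def write_gene_scores(profile: GeneScoreProfile, path) -> None:
    profile.scores.to_csv(path, sep="\t", index_label="gene_id")


def read_confidence_map(path) -> ConfidenceMap:
    """Read a two-column TSV ``gene_id <tab> category``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ConfidenceMap(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def read_reaction_set(path) -> ReactionSet:
    """Read a one-ID-per-line reaction set file."""
    with open(path) as fh:
        return ReactionSet(line.strip() for line in fh if line.strip())


def write_reaction_set(reactions: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for rid in sorted(reactions):
            fh.write(rid + "\n")
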