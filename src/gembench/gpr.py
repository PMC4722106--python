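"""Gene-protein-reaction (GPR) rule parsing and evaluation.

A GPR rule is a boolean expression over gene identifiers, e.g.
``"(g1 and g2) or g3"``.  ``and`` encodes enzyme complexes (all subunits
required), ``or`` encodes isozymes (any one suffices).  When numeric
evidence (z-scores, trinary calls, confidence ordinals) is mapped from
genes to reactions, ``and`` aggregates by minimum and ``or`` by maximum —
the dominant convention in the field, and monotone: raising any gene's
score can never lower a reaction's score.

Gene identifiers may contain any characters except whitespace and
parentheses; the bare words ``and`` / ``or`` (case-insensitive) are
operators.  An empty rule means "no gene associated" and evaluates to the
distinct :data:`NO_GENE` marker, which is *not* the same as a score of 0
(a z-score of exactly 0 is meaningful evidence).
"""

from __future__ import annotations

from typing import Callable, Iterator, Mapping, Union

__all__ = ["NO_GENE", "GPRSyntaxError", "UnknownGeneError", "parse_gpr",
           "gpr_genes", "evaluate_gpr"]


class _NoGene:
    """Singleton marker for reactions with no gene association."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_GENE"


NO_GENE = _NoGene()


class GPRSyntaxError(ValueError):
    """Raised for malformed GPR rule strings."""


class UnknownGeneError(KeyError):
    """Raised when a rule references a gene missing from the score mapping."""

    def __init__(self, genes):
        self.genes = sorted(genes)
        super().__init__(f"genes not present in score mapping: {self.genes}")


# AST: ("gene", name) | ("and", [children]) | ("or", [children])
Node = tuple


def _tokenize(rule: str) -> Iterator[str]:
    token = []
    for ch in rule:
        if ch in "()" or ch.isspace():
            if token:
                yield "".join(token)
                token = []
            if ch in "()":
                yield ch
        else:
            token.append(ch)
    if token:
        yield "".join(token)


def parse_gpr(rule: str) -> Union[Node, None]:
    """Parse a GPR string into a nested AST; ``None`` for an empty rule.

    Grammar (standard precedence, ``and`` binds tighter than ``or``)::

        expr   := term ("or" term)*
        term   := factor ("and" factor)*
        factor := GENE | "(" expr ")"
    """
    tokens = list(_tokenize(rule))
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def advance():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr() -> Node:
        terms = [parse_term()]
        while peek() is not None and peek().lower() == "or":
            advance()
            terms.append(parse_term())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_term() -> Node:
        factors = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            advance()
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def parse_factor() -> Node:
        tok = peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of rule: {rule!r}")
        if tok == "(":
            advance()
            node = parse_expr()
            if peek() != ")":
                raise GPRSyntaxError(f"missing ')' in rule: {rule!r}")
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected {tok!r} in rule: {rule!r}")
        return ("gene", advance())

    node = parse_expr()
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens in rule: {rule!r}")
    return node


def gpr_genes(rule: str) -> set:
    """Set of gene identifiers referenced by a rule."""
    node = parse_gpr(rule)
    genes: set = set()

    def walk(n):
        if n[0] == "gene":
            genes.add(n[1])
        else:
            for child in n[1]:
                walk(child)

    if node is not None:
        walk(node)
    return genes


def evaluate_gpr(
    rule: str,
    scores: Mapping[str, float],
    and_reduce: Callable = min,
    or_reduce: Callable = max,
):
    """Evaluate a GPR rule against per-gene scores.

    Returns :data:`NO_GENE` for an empty rule.  Raises
    :class:`UnknownGeneError` if the rule references genes absent from
    ``scores``.
    """
    node = parse_gpr(rule)
    if node is None:
        return NO_GENE
    missing = gpr_genes(rule) - set(scores)
    if missing:
        raise UnknownGeneError(missing)

    def walk(n):
        kind = n[0]
        if kind == "gene":
            return scores[n[1]]
        reduce = and_reduce if kind == "and" else or_reduce
        return reduce(walk(child) for child in n[1])

    return walk(node)
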