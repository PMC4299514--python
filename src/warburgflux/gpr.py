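"""Gene-protein-reaction (GPR) rules.

A GPR rule is a boolean expression over gene identifiers in which ``or``
joins isoenzymes (either gene product suffices to catalyse the reaction)
and ``and`` joins subunits of a complex (all are required).  Rules are
parsed once into an expression tree that supports two queries:

* boolean evaluation under a set of deleted genes (knockout semantics);
* expression aggregation, mapping per-gene expression levels to a single
  per-reaction level with ``or`` -> sum and ``and`` -> min, applied
  recursively.  This is the usual additive-isoenzyme / limiting-subunit
  convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

__all__ = ["GeneRule", "parse_gpr", "GPRSyntaxError"]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class GPRSyntaxError(ValueError):
    """Raised when a gene-rule string cannot be parsed."""


@dataclass(frozen=True)
class _Node:
    op: str  # "gene" | "and" | "or"
    gene: Optional[str] = None
    children: tuple = ()

    def evaluate(self, deleted: frozenset) -> bool:
        if self.op == "gene":
            return self.gene not in deleted
        if self.op == "and":
            return all(c.evaluate(deleted) for c in self.children)
        return any(c.evaluate(deleted) for c in self.children)

    def aggregate(self, levels: Mapping[str, float]) -> Optional[float]:
        """OR = sum, AND = min over measured operands; None if nothing measured."""
        if self.op == "gene":
            return levels.get(self.gene)
        vals = [v for v in (c.aggregate(levels) for c in self.children) if v is not None]
        if not vals:
            return None
        return min(vals) if self.op == "and" else sum(vals)

    def genes(self) -> frozenset:
        if self.op == "gene":
            return frozenset([self.gene])
        out = frozenset()
        for c in self.children:
            out |= c.genes()
        return out


class GeneRule:
    """Parsed boolean gene rule.  An empty rule is always satisfied."""

    def __init__(self, text: str = ""):
        self.text = text.strip()
        self._root: Optional[_Node] = parse_gpr(self.text) if self.text else None

    @property
    def is_empty(self) -> bool:
        return self._root is None

    @property
    def genes(self) -> frozenset:
        return self._root.genes() if self._root else frozenset()

    def evaluate(self, deleted_genes: Iterable[str]) -> bool:
        """True if the reaction remains catalysable with *deleted_genes* absent."""
        if self._root is None:
            return True
        return self._root.evaluate(frozenset(deleted_genes))

    def aggregate_expression(self, levels: Mapping[str, float]) -> Optional[float]:
        """Per-reaction expression level, or None when no operand is measured."""
        if self._root is None:
            return None
        return self._root.aggregate(levels)

    def knockdown_sufficient(self, gene: str) -> bool:
        """True if deleting *gene* alone closes the reaction."""
        if self._root is None or gene not in self.genes:
            return False
        return not self.evaluate({gene})

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneRule({self.text!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneRule) and self.text == other.text

    def __hash__(self) -> int:
        return hash(self.text)


def parse_gpr(text: str) -> _Node:
    """Parse a rule string; precedence: ``and`` binds tighter than ``or``."""
    tokens = _TOKEN_RE.findall(text)
    if not tokens:
        raise GPRSyntaxError("empty gene rule")
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> _Node:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            advance()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else _Node("or", children=tuple(terms))

    def parse_and() -> _Node:
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            advance()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else _Node("and", children=tuple(terms))

    def parse_atom() -> _Node:
        tok = peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of rule: {text!r}")
        if tok == "(":
            advance()
            node = parse_or()
            if peek() != ")":
                raise GPRSyntaxError(f"unbalanced parentheses in {text!r}")
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in {text!r}")
        return _Node("gene", gene=advance())

    root = parse_or()
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens in {text!r}")
    return root
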