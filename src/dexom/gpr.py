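"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule is a boolean expression over gene identifiers using ``and``, ``or``
and parentheses (keywords case-insensitive), e.g. ``(g1 and g2) or g3``.  The
same tree is evaluated in two modes:

* boolean, for gene-knockout simulation (a leaf is true iff the gene is
  present), and
* ternary on the {-1, 0, +1} expression-class lattice, where ``and`` takes the
  minimum of its children (a complex needs all subunits) and ``or`` the maximum
  (isoenzymes rescue each other).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .exceptions import FormatError

__all__ = ["GprNode", "GprGene", "GprAnd", "GprOr", "parse_gpr", "gpr_to_string"]


class GprNode:
    """Base class for nodes of a GPR expression tree."""

    def genes(self) -> set[str]:
        raise NotImplementedError

    def evaluate_boolean(self, deleted: Iterable[str] = ()) -> bool:
        """Evaluate with the given genes knocked out; leaves are true otherwise."""
        raise NotImplementedError

    def evaluate_ternary(self, classes: Mapping[str, int], missing: int = 0) -> int:
        """Evaluate on the lowly/unclassified/highly lattice (-1/0/+1)."""
        raise NotImplementedError


@dataclass(frozen=True)
class GprGene(GprNode):
    gene: str

    def genes(self) -> set[str]:
        return {self.gene}

    def evaluate_boolean(self, deleted: Iterable[str] = ()) -> bool:
        return self.gene not in set(deleted)

    def evaluate_ternary(self, classes: Mapping[str, int], missing: int = 0) -> int:
        return int(classes.get(self.gene, missing))


@dataclass(frozen=True)
class GprAnd(GprNode):
    children: tuple[GprNode, ...] = field(default_factory=tuple)

    def genes(self) -> set[str]:
        return set().union(*(c.genes() for c in self.children))

    def evaluate_boolean(self, deleted: Iterable[str] = ()) -> bool:
        deleted = set(deleted)
        return all(c.evaluate_boolean(deleted) for c in self.children)

    def evaluate_ternary(self, classes: Mapping[str, int], missing: int = 0) -> int:
        return min(c.evaluate_ternary(classes, missing) for c in self.children)


@dataclass(frozen=True)
class GprOr(GprNode):
    children: tuple[GprNode, ...] = field(default_factory=tuple)

    def genes(self) -> set[str]:
        return set().union(*(c.genes() for c in self.children))

    def evaluate_boolean(self, deleted: Iterable[str] = ()) -> bool:
        deleted = set(deleted)
        return any(c.evaluate_boolean(deleted) for c in self.children)

    def evaluate_ternary(self, classes: Mapping[str, int], missing: int = 0) -> int:
        return max(c.evaluate_ternary(classes, missing) for c in self.children)


_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    # grammar: expr := term ('or' term)* ; term := factor ('and' factor)* ;
    #          factor := '(' expr ')' | GENE
    def __init__(self, tokens: list[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise FormatError(f"unexpected end of GPR rule: {self.source!r}")
        self.pos += 1
        return tok

    def expr(self) -> GprNode:
        terms = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else GprOr(tuple(terms))

    def term(self) -> GprNode:
        factors = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else GprAnd(tuple(factors))

    def factor(self) -> GprNode:
        tok = self.next()
        if tok == "(":
            node = self.expr()
            if self.next() != ")":
                raise FormatError(f"unbalanced parentheses in GPR rule: {self.source!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise FormatError(f"misplaced {tok!r} in GPR rule: {self.source!r}")
        return GprGene(tok)


def parse_gpr(text: str | None) -> GprNode | None:
    """Parse a GPR rule string; empty/blank rules parse to ``None``."""
    if text is None or not text.strip():
        return None
    parser = _Parser(_tokenize(text), text)
    node = parser.expr()
    if parser.peek() is not None:
        raise FormatError(f"trailing tokens in GPR rule: {text!r}")
    return node


def gpr_to_string(node: GprNode | None) -> str:
    if node is None:
        return ""
    if isinstance(node, GprGene):
        return node.gene
    sep = " and " if isinstance(node, GprAnd) else " or "
    parts = []
    for child in node.children:
        s = gpr_to_string(child)
        if not isinstance(child, GprGene):
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)
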