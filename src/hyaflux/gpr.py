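"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule links genes to a reaction's activity: ``AND`` joins subunits of an
enzyme complex (all genes required), ``OR`` joins isozymes (any gene
suffices).  An empty rule means no gene is known for the reaction, so no gene
knockout can ever disable it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["GprRule", "parse_gpr", "GprError"]


class GprError(ValueError):
    """Raised on a malformed GPR expression."""


# -- expression tree ---------------------------------------------------------


@dataclass(frozen=True)
class _Gene:
    name: str

    def evaluate(self, deleted: frozenset) -> bool:
        return self.name not in deleted

    def genes(self) -> set:
        return {self.name}

    def to_string(self) -> str:
        return self.name


@dataclass(frozen=True)
class _And:
    children: tuple

    def evaluate(self, deleted: frozenset) -> bool:
        return all(c.evaluate(deleted) for c in self.children)

    def genes(self) -> set:
        return set().union(*(c.genes() for c in self.children))

    def to_string(self) -> str:
        return " and ".join(
            f"({c.to_string()})" if isinstance(c, _Or) else c.to_string()
            for c in self.children
        )


@dataclass(frozen=True)
class _Or:
    children: tuple

    def evaluate(self, deleted: frozenset) -> bool:
        return any(c.evaluate(deleted) for c in self.children)

    def genes(self) -> set:
        return set().union(*(c.genes() for c in self.children))

    def to_string(self) -> str:
        return " or ".join(c.to_string() for c in self.children)


@dataclass(frozen=True)
class GprRule:
    """Boolean gene requirement of a reaction; ``GprRule()`` is the empty rule."""

    root: object = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def evaluate(self, deleted_genes: Iterable[str] = ()) -> bool:
        """Whether the reaction stays active with ``deleted_genes`` removed.

        An empty rule always evaluates to True: a reaction without known
        genes cannot be disabled by any knockout.
        """
        if self.root is None:
            return True
        return self.root.evaluate(frozenset(deleted_genes))

    @property
    def genes(self) -> set:
        return set() if self.root is None else self.root.genes()

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


# -- parser ------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-]+)")


def _tokenize(text: str) -> list:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise GprError(f"unexpected character in GPR at {text[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent over ``expr := term (or term)*; term := factor (and factor)*``."""

    def __init__(self, tokens: list):
        self.tokens = tokens
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise GprError(f"trailing tokens in GPR: {self.tokens[self.pos:]}")
        return node

    def expr(self):
        parts = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            parts.append(self.term())
        return parts[0] if len(parts) == 1 else _Or(tuple(parts))

    def term(self):
        parts = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            parts.append(self.factor())
        return parts[0] if len(parts) == 1 else _And(tuple(parts))

    def factor(self):
        tok = self.next()
        if tok is None:
            raise GprError("unexpected end of GPR expression")
        if tok == "(":
            node = self.expr()
            if self.next() != ")":
                raise GprError("unbalanced parenthesis in GPR")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprError(f"unexpected token {tok!r} in GPR")
        return _Gene(tok)


def parse_gpr(text: str | None) -> GprRule:
    """Parse an infix boolean GPR string such as ``"(g1 and g2) or g3"``."""
    if text is None or not text.strip():
        return GprRule()
    return GprRule(_Parser(_tokenize(text)).parse())
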