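"""Boolean conditions over multilevel literals.

Rule conditions are Boolean combinations of threshold literals.  The textual
dialect used in model files is::

    condition := term ('|' term)*
    term      := factor ('&' factor)*
    factor    := '!' factor | '(' condition ')' | literal
    literal   := NAME            # NAME >= 1
               | NAME ':' INT    # NAME >= INT
               | NAME '=' INT    # NAME == INT  (exact level)

so ``"PU1:2 & !MAFB"`` reads "PU1 at level 2 or above AND MAFB absent".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator


class ExpressionError(ValueError):
    """Raised for syntax errors or references that violate the network contract."""


class Expr:
    """Base class for condition AST nodes."""

    def evaluate(self, levels: dict[str, int]) -> bool:
        raise NotImplementedError

    def support(self) -> set[str]:
        """Names of the components the condition reads."""
        raise NotImplementedError

    def to_python(self, index: dict[str, int]) -> str:
        """Render as a python expression over an integer sequence ``x``."""
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({str(self)})"


@dataclass(frozen=True)
class Literal(Expr):
    name: str
    level: int = 1
    exact: bool = False

    def evaluate(self, levels):
        v = levels[self.name]
        return v == self.level if self.exact else v >= self.level

    def support(self):
        return {self.name}

    def to_python(self, index):
        op = "==" if self.exact else ">="
        return f"(x[{index[self.name]}] {op} {self.level})"

    def __str__(self):
        if self.exact:
            return f"{self.name}={self.level}"
        if self.level == 1:
            return self.name
        return f"{self.name}:{self.level}"


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr

    def evaluate(self, levels):
        return not self.operand.evaluate(levels)

    def support(self):
        return self.operand.support()

    def to_python(self, index):
        return f"(not {self.operand.to_python(index)})"

    def __str__(self):
        inner = str(self.operand)
        if isinstance(self.operand, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"


@dataclass(frozen=True)
class And(Expr):
    operands: tuple[Expr, ...]

    def evaluate(self, levels):
        return all(o.evaluate(levels) for o in self.operands)

    def support(self):
        return set().union(*(o.support() for o in self.operands))

    def to_python(self, index):
        return "(" + " and ".join(o.to_python(index) for o in self.operands) + ")"

    def __str__(self):
        parts = [f"({o})" if isinstance(o, Or) else str(o) for o in self.operands]
        return " & ".join(parts)


@dataclass(frozen=True)
class Or(Expr):
    operands: tuple[Expr, ...]

    def evaluate(self, levels):
        return any(o.evaluate(levels) for o in self.operands)

    def support(self):
        return set().union(*(o.support() for o in self.operands))

    def to_python(self, index):
        return "(" + " or ".join(o.to_python(index) for o in self.operands) + ")"

    def __str__(self):
        return " | ".join(str(o) for o in self.operands)


TRUE = And(())  # empty conjunction: constant truth, used for clamped components
FALSE = Or(())  # empty disjunction: constant falsehood


_TOKEN = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_.-]*|[0-9]+|[!&|():=])")


def _tokenize(text: str) -> Iterator[str]:
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise ExpressionError(f"unexpected character {text[pos]!r} in condition {text!r}")
        yield m.group(1)
        pos = m.end()


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ExpressionError(f"unexpected end of condition {self.text!r}")
        self.i += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.peek() is not None:
            raise ExpressionError(f"trailing token {self.peek()!r} in condition {self.text!r}")
        return expr

    def parse_or(self) -> Expr:
        terms = [self.parse_and()]
        while self.peek() == "|":
            self.next()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and(self) -> Expr:
        factors = [self.parse_factor()]
        while self.peek() == "&":
            self.next()
            factors.append(self.parse_factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_factor(self) -> Expr:
        tok = self.next()
        if tok == "!":
            return Not(self.parse_factor())
        if tok == "(":
            expr = self.parse_or()
            if self.next() != ")":
                raise ExpressionError(f"missing ')' in condition {self.text!r}")
            return expr
        if not re.match(r"^[A-Za-z_]", tok):
            raise ExpressionError(f"expected component name, got {tok!r} in {self.text!r}")
        name = tok
        if self.peek() in (":", "="):
            op = self.next()
            level_tok = self.next()
            if not level_tok.isdigit():
                raise ExpressionError(f"expected level after {op!r} in {self.text!r}")
            return Literal(name, int(level_tok), exact=(op == "="))
        return Literal(name)


def parse_condition(text: str) -> Expr:
    """Parse a condition string into an :class:`Expr`.

    The strings ``"1"``/``"true"`` and ``"0"``/``"false"`` denote the constant
    conditions (used for clamped components and constant rules).
    """
    stripped = text.strip()
    if stripped in ("1", "true", "TRUE", "True"):
        return TRUE
    if stripped in ("0", "false", "FALSE", "False"):
        return FALSE
    return _Parser(stripped).parse()
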