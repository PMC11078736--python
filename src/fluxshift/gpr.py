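"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule links a reaction to the genes whose products catalyse it:
``and`` denotes subunits of one enzyme complex, ``or`` denotes isozymes.
Rules are parsed into an explicit expression tree so they can be evaluated
numerically (fold-change propagation) or inspected (gene membership).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Mapping, Optional

__all__ = ["GprExpr", "GprGene", "GprNode", "GprParseError", "parse_gpr", "serialize_gpr"]


class GprExpr:
    """Base class for nodes of a GPR expression tree."""

    def genes(self) -> set[str]:
        return set(self._iter_genes())

    def _iter_genes(self) -> Iterator[str]:  # pragma: no cover - abstract
        raise NotImplementedError

    def evaluate(
        self,
        values: Mapping[str, float],
        and_agg: Callable[[list[float]], float] = min,
        or_agg: Callable[[list[float]], float] = max,
    ) -> Optional[float]:
        """Aggregate per-gene values through the rule.

        Complexes (``and``) take the scarcest subunit, isozymes (``or``) the
        strongest. Genes absent from *values* are unmeasured; a node whose
        children are all unmeasured is unmeasured (returns None).
        """
        raise NotImplementedError


@dataclass(frozen=True)
class GprGene(GprExpr):
    gene: str

    def _iter_genes(self) -> Iterator[str]:
        yield self.gene

    def evaluate(self, values, and_agg=min, or_agg=max):
        return values.get(self.gene)

    def __str__(self) -> str:
        return self.gene


@dataclass(frozen=True)
class GprNode(GprExpr):
    op: str  # "and" | "or"
    children: tuple[GprExpr, ...]

    def __post_init__(self) -> None:
        if self.op not in ("and", "or"):
            raise ValueError(f"unknown GPR operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("GPR operator node needs >= 2 children")

    def _iter_genes(self) -> Iterator[str]:
        for child in self.children:
            yield from child._iter_genes()

    def evaluate(self, values, and_agg=min, or_agg=max):
        vals = [v for v in (c.evaluate(values, and_agg, or_agg) for c in self.children) if v is not None]
        if not vals:
            return None
        return and_agg(vals) if self.op == "and" else or_agg(vals)

    def __str__(self) -> str:
        parts = [f"({c})" if isinstance(c, GprNode) else str(c) for c in self.children]
        return f" {self.op} ".join(parts)


class GprParseError(ValueError):
    """Malformed GPR string; carries the character position of the fault."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append(("paren", ch, i))
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in ("and", "or"):
            tokens.append(("op", low, i))
        else:
            tokens.append(("gene", word, i))
        i = j
    return tokens


def parse_gpr(text: Optional[str]) -> Optional[GprExpr]:
    """Parse a GPR string such as ``(g1 and g2) or g3``.

    ``and`` binds tighter than ``or``; keywords are case-insensitive; an
    empty or None string means the reaction has no gene association and
    parses to None. Same-operator chains are flattened into one n-ary node.
    """
    if text is None or not text.strip():
        return None
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def parse_or() -> GprExpr:
        nonlocal pos
        children = [parse_and()]
        while (tok := peek()) is not None and tok[:2] == ("op", "or"):
            pos += 1
            children.append(parse_and())
        if len(children) == 1:
            return children[0]
        flat: list[GprExpr] = []
        for c in children:
            flat.extend(c.children if isinstance(c, GprNode) and c.op == "or" else [c])
        return GprNode("or", tuple(flat))

    def parse_and() -> GprExpr:
        nonlocal pos
        children = [parse_atom()]
        while (tok := peek()) is not None and tok[:2] == ("op", "and"):
            pos += 1
            children.append(parse_atom())
        if len(children) == 1:
            return children[0]
        flat: list[GprExpr] = []
        for c in children:
            flat.extend(c.children if isinstance(c, GprNode) and c.op == "and" else [c])
        return GprNode("and", tuple(flat))

    def parse_atom() -> GprExpr:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GprParseError("unexpected end of expression", len(text))
        kind, value, at = tok
        if kind == "gene":
            pos += 1
            return GprGene(value)
        if (kind, value) == ("paren", "("):
            pos += 1
            inner = parse_or()
            closing = peek()
            if closing is None or closing[:2] != ("paren", ")"):
                raise GprParseError("unbalanced parenthesis", at)
            pos += 1
            return inner
        raise GprParseError(f"unexpected token {value!r}", at)

    expr = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing input {tokens[pos][1]!r}", tokens[pos][2])
    return expr


def serialize_gpr(expr: Optional[GprExpr]) -> str:
    """Canonical string form; inverse of :func:`parse_gpr`."""
    return "" if expr is None else str(expr)
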