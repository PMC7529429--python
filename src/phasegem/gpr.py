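"""Boolean gene-protein-reaction (GPR) rules.

A GPR links a reaction to the genes that support it: ``and`` joins the
subunits of an enzyme complex (all required), ``or`` joins isoenzymes (any
suffices).  An empty rule marks an orphan reaction, retained on physiological
evidence and treated as supported under every expression state.

Rules are stored as a small expression tree: a gene id string at the leaves
and ``("and", children)`` / ``("or", children)`` tuples at internal nodes.
"""

from __future__ import annotations

import re
from typing import FrozenSet, List, Optional, Set, Tuple, Union

__all__ = ["GPR", "GPRSyntaxError"]

Node = Union[str, Tuple[str, tuple]]


class GPRSyntaxError(ValueError):
    """Raised when a GPR rule string cannot be parsed."""


_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.:\-]+)")


def _tokenize(text: str) -> List[str]:
    tokens, pos, text = [], 0, text.strip()
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise GPRSyntaxError(f"unexpected character {text[pos]!r} in GPR {text!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser; ``and`` binds tighter than ``or``."""

    def __init__(self, tokens: List[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of GPR {self.source!r}")
        self.pos += 1
        return tok

    def parse(self) -> Node:
        node = self.parse_or()
        if self.peek() is not None:
            raise GPRSyntaxError(f"trailing tokens in GPR {self.source!r}")
        return node

    def parse_or(self) -> Node:
        children = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else ("or", tuple(children))

    def parse_and(self) -> Node:
        children = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            children.append(self.parse_atom())
        return children[0] if len(children) == 1 else ("and", tuple(children))

    def parse_atom(self) -> Node:
        tok = self.take()
        if tok == "(":
            node = self.parse_or()
            if self.take() != ")":
                raise GPRSyntaxError(f"unbalanced parentheses in GPR {self.source!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"misplaced token {tok!r} in GPR {self.source!r}")
        return tok


class GPR:
    """A Boolean gene association; immutable and hashable on its tree."""

    __slots__ = ("expr",)

    def __init__(self, expr: Optional[Node] = None):
        self.expr = expr

    # -- construction ----------------------------------------------------

    @classmethod
    def parse(cls, rule: Optional[str]) -> "GPR":
        """Parse a rule string like ``"g1 and (g2 or g3)"``; blank → empty GPR."""
        if rule is None or rule.strip() == "":
            return cls(None)
        return cls(_Parser(_tokenize(rule), rule).parse())

    @classmethod
    def single(cls, gene: str) -> "GPR":
        return cls(gene)

    @classmethod
    def any_of(cls, *genes: str) -> "GPR":
        return cls(genes[0] if len(genes) == 1 else ("or", tuple(genes)))

    @classmethod
    def all_of(cls, *genes: str) -> "GPR":
        return cls(genes[0] if len(genes) == 1 else ("and", tuple(genes)))

    # -- inspection ------------------------------------------------------

    @property
    def is_empty(self) -> bool:
        return self.expr is None

    @property
    def genes(self) -> FrozenSet[str]:
        out: Set[str] = set()

        def walk(node: Node) -> None:
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        if self.expr is not None:
            walk(self.expr)
        return frozenset(out)

    def evaluate(self, active_genes) -> bool:
        """Truth value when exactly the genes in ``active_genes`` are present.

        ``and`` is conjunction, ``or`` disjunction over leaf membership; the
        empty rule evaluates true (orphan reactions are always supported).
        """
        active = set(active_genes)

        def walk(node: Node) -> bool:
            if isinstance(node, str):
                return node in active
            op, children = node
            results = (walk(c) for c in children)
            return all(results) if op == "and" else any(results)

        return True if self.expr is None else walk(self.expr)

    def to_string(self) -> str:
        def walk(node: Node, parent_op: Optional[str]) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            joined = f" {op} ".join(walk(c, op) for c in children)
            needs_parens = parent_op is not None and parent_op != op
            return f"({joined})" if needs_parens else joined

        return "" if self.expr is None else walk(self.expr, None)

    # -- dunder ----------------------------------------------------------

    def __bool__(self) -> bool:
        return self.expr is not None

    def __eq__(self, other) -> bool:
        return isinstance(other, GPR) and self.expr == other.expr

    def __hash__(self) -> int:
        return hash(self.expr)

    def __repr__(self) -> str:
        return f"GPR({self.to_string()!r})"
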