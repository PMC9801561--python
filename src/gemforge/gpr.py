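"""Gene-protein-reaction (GPR) rules: parsing, evaluation, translation.

A GPR is a boolean expression over gene identifiers with AND / OR
connectives.  The empty rule is the convention for spontaneous or
gene-independent reactions and always evaluates to true.  Knockouts and
orthology-driven model reduction act on reactions exclusively through
these rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator


class GPRSyntaxError(ValueError):
    """Raised when a rule string cannot be parsed."""


# Expression nodes are plain nested tuples:
#   gene leaf          -> "gene_id"  (str)
#   conjunction        -> ("and", (child, child, ...))
#   disjunction        -> ("or", (child, child, ...))
#   unsatisfiable leaf -> FALSE (only produced by translation)
# The empty rule is represented by root = None.

FALSE = ("false", ())

Node = object  # str | tuple | None


@dataclass(frozen=True)
class GeneRule:
    """Boolean AND/OR expression tree over gene ids; no negation."""

    root: Node = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    @property
    def is_unsatisfiable(self) -> bool:
        return self.root == FALSE

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(_iter_genes(self.root))

    def evaluate(self, present: set[str] | frozenset[str]) -> bool:
        """Truth value given the set of present genes (empty rule -> True)."""
        return _eval(self.root, present)

    def to_string(self) -> str:
        return _unparse(self.root, top=True)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


EMPTY_RULE = GeneRule(None)
UNSATISFIABLE = GeneRule(FALSE)


def _iter_genes(node: Node) -> Iterator[str]:
    if node is None or node == FALSE:
        return
    if isinstance(node, str):
        yield node
        return
    for child in node[1]:
        yield from _iter_genes(child)


def _eval(node: Node, present) -> bool:
    if node is None:
        return True
    if isinstance(node, str):
        return node in present
    op, children = node
    if op == "false":
        return False
    if op == "and":
        return all(_eval(c, present) for c in children)
    return any(_eval(c, present) for c in children)


def _unparse(node: Node, top: bool = False) -> str:
    if node is None:
        return ""
    if isinstance(node, str):
        return node
    op, children = node
    if op == "false":
        return "<unsatisfiable>"
    sep = f" {op} "
    parts = []
    for c in children:
        s = _unparse(c)
        # parenthesise an OR child under an AND parent
        if op == "and" and isinstance(c, tuple) and c[0] == "or":
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)


_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent; 'and' binds tighter than 'or'."""

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse_expr(self) -> Node:
        children = [self.parse_term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            children.append(self.parse_term())
        return children[0] if len(children) == 1 else ("or", tuple(children))

    def parse_term(self) -> Node:
        children = [self.parse_factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            children.append(self.parse_factor())
        return children[0] if len(children) == 1 else ("and", tuple(children))

    def parse_factor(self) -> Node:
        tok = self.peek()
        if tok is None:
            raise GPRSyntaxError("unexpected end of rule: missing operand")
        if tok == "(":
            self.next()
            node = self.parse_expr()
            if self.peek() != ")":
                raise GPRSyntaxError("unbalanced parentheses in GPR rule")
            self.next()
            return node
        if tok == ")":
            raise GPRSyntaxError("unexpected ')' in GPR rule")
        if tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"missing operand before '{tok}'")
        return self.next()


def parse_gpr(text: str) -> GeneRule:
    """Parse a rule string; keywords are case-insensitive, ids opaque.

    '' (or whitespace) is the empty rule.  'and' binds tighter than 'or'
    when unparenthesised, so "g1 or g2 and g3" reads OR(g1, AND(g2, g3)).
    """
    tokens = _tokenize(text)
    if not tokens:
        return EMPTY_RULE
    parser = _Parser(tokens)
    node = parser.parse_expr()
    if parser.peek() is not None:
        raise GPRSyntaxError(f"trailing tokens in GPR rule near '{parser.peek()}'")
    return GeneRule(node)


def evaluate_gpr(rule: GeneRule, present: set[str] | frozenset[str]) -> bool:
    """Boolean value of a rule under a gene-presence assignment."""
    return rule.evaluate(present)


def _simplify(node: Node) -> Node:
    """Fold FALSE leaves: absorb under OR, propagate under AND."""
    if node is None or isinstance(node, str) or node == FALSE:
        return node
    op, children = node
    simplified = [_simplify(c) for c in children]
    if op == "and":
        if any(c == FALSE for c in simplified):
            return FALSE
        kept = simplified
    else:  # or
        kept = [c for c in simplified if c != FALSE]
        if not kept:
            return FALSE
    if len(kept) == 1:
        return kept[0]
    return (op, tuple(kept))


def translate_gpr(rule: GeneRule, ortholog_map: dict[str, str]) -> GeneRule:
    """Rewrite a rule onto target-strain gene ids through an ortholog map.

    Genes without an ortholog become FALSE and are boolean-simplified
    away; a rule whose every support vanishes collapses to the
    distinguished unsatisfiable rule.  The empty rule is preserved
    (spontaneous reactions carry no genetic requirement to translate).
    """

    def subst(node: Node) -> Node:
        if node is None:
            return None
        if isinstance(node, str):
            return ortholog_map.get(node, FALSE)
        if node == FALSE:
            return FALSE
        op, children = node
        return (op, tuple(subst(c) for c in children))

    return GeneRule(_simplify(subst(rule.root)))
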