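"""A small selection mini-language over :class:`~helixscope.model.Topology`.

Grammar (keywords are reserved words; everything is case-sensitive)::

    expr      := or_expr
    or_expr   := and_expr ( "or" and_expr )*
    and_expr  := unary ( "and" unary )*
    unary     := "not" unary | "(" expr ")" | primitive
    primitive := "name" WORD+ | "segid" WORD+
               | "resid" INT "to" INT | "resid" INT+

Examples: ``resid 57 to 82 and name CA``, ``segid MEMB and name P``,
``not (resid 57 to 82)``. Selection is deterministic and order-preserving:
the returned indices are the topology indices in increasing order. An
expression that matches nothing yields an empty Selection; downstream
operations decide whether that is an error.
"""

from __future__ import annotations

import re
from typing import List, Tuple

import numpy as np

from .errors import SelectionSyntaxError
from .model import Selection, Topology

__all__ = ["select"]

_KEYWORDS = {"name", "resid", "segid", "and", "or", "not", "to", "(", ")"}
_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expression: str) -> List[Tuple[str, int]]:
    tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]
    if not tokens:
        raise SelectionSyntaxError("empty selection expression", 0)
    return tokens


class _Parser:
    def __init__(self, topology: Topology, expression: str):
        self.top = topology
        self.expr = expression
        self.tokens = _tokenize(expression)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def error(self, message: str):
        position = (self.tokens[self.pos][1] if self.pos < len(self.tokens)
                    else len(self.expr))
        raise SelectionSyntaxError(message, position)

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            self.error(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            self.error("expected a term")
        if tok == "not":
            self.next()
            return ~self.unary()
        if tok == "(":
            self.next()
            mask = self.or_expr()
            if self.peek() != ")":
                self.error("expected ')'")
            self.next()
            return mask
        return self.primitive()

    def _values(self) -> List[str]:
        values = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            values.append(self.next()[0])
        if not values:
            self.error("expected one or more values")
        return values

    def primitive(self) -> np.ndarray:
        tok, _ = self.next()
        if tok == "name":
            wanted = set(self._values())
            return np.isin(self.top.atom_names, list(wanted))
        if tok == "segid":
            wanted = set(self._values())
            return np.isin(self.top.segment_ids, list(wanted))
        if tok == "resid":
            values = self._values()
            # range form: resid a to b — 'to' is a keyword so _values stops
            if self.peek() == "to":
                if len(values) != 1:
                    self.error("'resid a to b' takes exactly one lower bound")
                self.next()
                upper = self._values()
                if len(upper) != 1:
                    self.error("'resid a to b' takes exactly one upper bound")
                lo, hi = self._int(values[0]), self._int(upper[0])
                if hi < lo:
                    self.error(f"empty resid range {lo} to {hi}")
                return (self.top.residue_ids >= lo) & (self.top.residue_ids <= hi)
            ids = [self._int(v) for v in values]
            return np.isin(self.top.residue_ids, ids)
        self.pos -= 1
        self.error(f"unexpected token {tok!r}")

    def _int(self, value: str) -> int:
        try:
            return int(value)
        except ValueError:
            self.error(f"expected an integer residue id, got {value!r}")


def select(topology: Topology, expression: str) -> Selection:
    """Evaluate a selection expression against a topology."""
    mask = _Parser(topology, expression).parse()
    indices = tuple(int(i) for i in np.nonzero(mask)[0])
    return Selection(indices=indices, expression=expression)
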