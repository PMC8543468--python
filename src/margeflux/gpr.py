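"""Gene-protein-reaction (GPR) rule algebra.

A GPR rule is a boolean expression over gene identifiers in which ``or``
separates isozymes (independent enzymes able to catalyse the reaction)
and ``and`` groups the subunits of an enzyme complex.  Rules are
normalised to disjunctive normal form: a list of isozymes, each a
frozen set of gene ids.  ``and`` binds tighter than ``or`` when
parentheses are absent, matching the SBML-fbc convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass


class GPRParseError(ValueError):
    """Raised for malformed rule text; carries the offending token position."""


@dataclass(frozen=True)
class GPRRule:
    """DNF representation: disjunction (isozymes) of conjunctions (complexes)."""

    dnf: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.dnf:
            raise ValueError("GPR rule must have at least one isozyme")
        if any(not iso for iso in self.dnf):
            raise ValueError("GPR rule contains an empty isozyme")
        if len(set(self.dnf)) != len(self.dnf):
            raise ValueError("GPR rule contains duplicate isozymes")

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for iso in self.dnf:
            out |= iso
        return frozenset(out)

    def evaluate(self, active_genes: set[str] | frozenset[str]) -> bool:
        """Rule truth value when exactly `active_genes` are present."""
        return any(iso <= active_genes for iso in self.dnf)

    def to_string(self) -> str:
        terms = [" and ".join(sorted(iso)) for iso in self.dnf]
        if len(terms) == 1:
            return terms[0]
        return " or ".join(f"({t})" if " and " in t else t for t in terms)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def _absorb(isozymes: list[frozenset[str]]) -> tuple[frozenset[str], ...]:
    """Drop duplicate isozymes and any isozyme that is a superset of another."""
    uniq = sorted(set(isozymes), key=lambda s: (len(s), sorted(s)))
    kept: list[frozenset[str]] = []
    for iso in uniq:
        if not any(k < iso or k == iso for k in kept):
            kept.append(iso)
    return tuple(kept)


class _Parser:
    """Recursive descent over: expr := term ('or' term)*; term := factor ('and' factor)*."""

    def __init__(self, tokens: list[tuple[str, int]], text: str) -> None:
        self.tokens = tokens
        self.text = text
        self.i = 0

    def _peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _error(self, msg: str) -> GPRParseError:
        if self.i < len(self.tokens):
            tok, pos = self.tokens[self.i]
            return GPRParseError(f"{msg} at position {pos}: {tok!r}")
        return GPRParseError(f"{msg} at end of input")

    def parse(self) -> list[frozenset[str]]:
        dnf = self._expr()
        if self.i != len(self.tokens):
            raise self._error("unexpected token")
        return dnf

    def _expr(self) -> list[frozenset[str]]:
        dnf = self._term()
        while self._peek() is not None and self._peek().lower() == "or":
            self.i += 1
            dnf = dnf + self._term()
        return dnf

    def _term(self) -> list[frozenset[str]]:
        dnf = self._factor()
        while self._peek() is not None and self._peek().lower() == "and":
            self.i += 1
            rhs = self._factor()
            # distribute: (A1|A2) and (B1|B2) -> union pairs
            dnf = [a | b for a in dnf for b in rhs]
        return dnf

    def _factor(self) -> list[frozenset[str]]:
        tok = self._peek()
        if tok is None:
            raise self._error("expected gene id or '('")
        if tok == "(":
            self.i += 1
            inner = self._expr()
            if self._peek() != ")":
                raise self._error("expected ')'")
            self.i += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise self._error("expected gene id or '('")
        self.i += 1
        return [frozenset([tok])]


def parse_gpr(rule_text: str) -> GPRRule:
    """Parse a boolean GPR string into a minimal (absorbed) DNF rule.

    Raises
    ------
    GPRParseError
        If the expression is malformed; the message names the offending
        token position.
    """
    tokens = _tokenize(rule_text)
    if not tokens:
        raise GPRParseError("empty GPR expression")
    dnf = _Parser(tokens, rule_text).parse()
    return GPRRule(_absorb(dnf))
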