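"""Gene-protein-reaction (GPR) rules in disjunctive normal form.

A GPR rule gates a metabolic reaction on the activity of the genes that
encode its catalysing enzyme(s).  Rules are Boolean formulas over gene
identifiers; here they are normalised to DNF — an OR over AND-clauses —
so that a reaction fires whenever at least one clause has all of its
genes active (an AND-clause models an enzyme complex, alternative
clauses model isozymes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["GeneRule", "RuleError", "parse_gene_rule"]

#: Safety cap on the number of AND-clauses produced when distributing a
#: non-DNF formula into DNF.  Curated genome-scale models ship rules that
#: are already in DNF; the cap only guards against pathological inputs.
MAX_CLAUSES = 4096


class RuleError(ValueError):
    """Raised for unparseable or non-DNF-convertible rule strings."""


@dataclass(frozen=True)
class GeneRule:
    """A normalised DNF rule: OR over AND-clauses of gene ids.

    ``clauses`` is a sorted tuple of sorted gene-id tuples with duplicate
    clauses removed, so two semantically re-ordered renderings of the
    same rule compare (and hash) equal — the property rule-based
    reaction grouping relies on.
    """

    clauses: tuple[tuple[str, ...], ...]
    source_text: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.clauses:
            raise RuleError("a gene rule needs at least one clause")
        if any(len(c) == 0 for c in self.clauses):
            raise RuleError("empty AND-clause in gene rule")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for clause in self.clauses for g in clause)

    def evaluate(self, activity: Mapping[str, object]) -> bool:
        """DNF semantics: true iff some clause has every gene active.

        Genes absent from ``activity`` count as inactive.
        """
        return any(all(bool(activity.get(g, 0)) for g in clause) for clause in self.clauses)

    def render(self) -> str:
        """Canonical text rendering, parseable by :func:`parse_gene_rule`."""
        parts = [" and ".join(c) if len(c) == 1 else "(" + " and ".join(c) + ")" for c in self.clauses]
        return " or ".join(parts)

    @classmethod
    def from_clauses(cls, clauses: Iterable[Iterable[str]], source_text: str = "") -> "GeneRule":
        norm = sorted({tuple(sorted(set(c))) for c in clauses})
        return cls(clauses=tuple(norm), source_text=source_text)


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
    """Recursive-descent parser for ``and``/``or``/parenthesis formulas.

    Returns clause lists directly (DNF): ``or`` concatenates clause
    lists, ``and`` distributes (cartesian clause merge) under the
    MAX_CLAUSES cap.
    """

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise RuleError("unexpected end of rule")
        self.pos += 1
        return tok

    def parse_or(self) -> list[frozenset[str]]:
        clauses = self.parse_and()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            clauses = clauses + self.parse_and()
        return clauses

    def parse_and(self) -> list[frozenset[str]]:
        clauses = self.parse_atom()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            rhs = self.parse_atom()
            if len(clauses) * len(rhs) > MAX_CLAUSES:
                raise RuleError(
                    f"DNF expansion exceeds {MAX_CLAUSES} clauses; rule too entangled"
                )
            clauses = [a | b for a in clauses for b in rhs]
        return clauses

    def parse_atom(self) -> list[frozenset[str]]:
        tok = self.next()
        if tok == "(":
            inner = self.parse_or()
            if self.next() != ")":
                raise RuleError("unbalanced parenthesis in rule")
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise RuleError(f"unexpected token {tok!r} in rule")
        return [frozenset([tok])]


def parse_gene_rule(text: str) -> GeneRule:
    """Parse a Boolean GPR string into a normalised :class:`GeneRule`.

    Accepts ``and`` / ``or`` (case-insensitive) with parentheses.
    Formulas not already in DNF are distributed into DNF, capped at
    ``MAX_CLAUSES`` clauses.

    >>> parse_gene_rule("(G1 and G2) or G3").clauses
    (('G1', 'G2'), ('G3',))
    """
    if text is None or not str(text).strip():
        raise RuleError("empty gene rule")
    parser = _Parser(_tokenize(str(text)))
    clauses = parser.parse_or()
    if parser.peek() is not None:
        raise RuleError(f"trailing token {parser.peek()!r} in rule {text!r}")
    return GeneRule.from_clauses(clauses, source_text=str(text))
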