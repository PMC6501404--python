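"""Gene-protein-reaction boolean logic.

GPR rules tie genes to reactions: ``and`` joins subunits of an enzyme
complex (all required), ``or`` joins isozymes (any one suffices).  The same
tree answers two questions: is the reaction still catalysable after a set
of gene deletions, and what expression state does the reaction inherit from
its genes' states (AND = min, OR = max over child states).
"""

from __future__ import annotations

import re
import warnings
from typing import Mapping, NamedTuple

from .model import Gpr, MetabolicModel

__all__ = [
    "GprParseError",
    "parse_gpr_expression",
    "evaluate_deletion",
    "reactions_disabled_by",
    "reaction_expression_state",
    "GeneCountClassification",
    "classify_reactions_by_gene_count",
]


class GprParseError(ValueError):
    pass


_TOKEN_RE = re.compile(r"\(|\)|[A-Za-z0-9_.:\-]+")


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if text[pos : m.start()].strip():
            raise GprParseError(
                f"unexpected characters {text[pos:m.start()]!r} at position {pos}"
            )
        tokens.append(m.group())
        pos = m.end()
    if text[pos:].strip():
        raise GprParseError(f"unexpected characters {text[pos:]!r} at position {pos}")
    return tokens


def parse_gpr_expression(text: str) -> Gpr:
    """Parse a boolean expression like ``(g1 and g2) or g3``.

    ``and`` binds tighter than ``or``; both are case-insensitive.  N-ary
    chains are flattened into one node.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GprParseError("empty GPR expression")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Gpr:
        children = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            children.append(parse_and())
        return children[0] if len(children) == 1 else Gpr.or_(*children)

    def parse_and() -> Gpr:
        children = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            children.append(parse_atom())
        return children[0] if len(children) == 1 else Gpr.and_(*children)

    def parse_atom() -> Gpr:
        tok = peek()
        if tok is None:
            raise GprParseError("unexpected end of expression")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GprParseError("unbalanced parenthesis")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r}")
        return Gpr.gene_(take())

    node = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens {tokens[pos:]!r}")
    return node


def evaluate_deletion(rule: Gpr, deleted: set[str] | frozenset[str]) -> bool:
    """Is the reaction still functional after deleting ``deleted`` genes?

    AND: all children must remain functional; OR: any child suffices;
    a gene leaf is functional iff the gene is not deleted.
    """
    if rule.op == "gene":
        return rule.gene not in deleted
    if rule.op == "and":
        return all(evaluate_deletion(c, deleted) for c in rule.children)
    return any(evaluate_deletion(c, deleted) for c in rule.children)


def reactions_disabled_by(model: MetabolicModel, deleted: set[str]) -> list[str]:
    """Ids of reactions whose GPR evaluates non-functional under the deletion.

    Deleted ids not present in the model are ignored with a warning.
    """
    unknown = set(deleted) - set(model.genes)
    if unknown:
        warnings.warn(
            f"ignoring unknown gene ids in deletion set: {sorted(unknown)}",
            stacklevel=2,
        )
    disabled = []
    for rxn in model.reactions:
        if rxn.gpr is not None and not evaluate_deletion(rxn.gpr, deleted):
            disabled.append(rxn.id)
    return disabled


def reaction_expression_state(rule: Gpr, gene_states: Mapping[str, int]) -> int:
    """Map gene expression states in {-1, 0, 1} onto the reaction.

    AND takes the minimum of child states (a complex is as available as its
    scarcest subunit), OR the maximum (the best-expressed isozyme carries
    the reaction).  Genes missing from the map default to state 0.
    """
    if rule.op == "gene":
        return int(gene_states.get(rule.gene, 0))
    states = [reaction_expression_state(c, gene_states) for c in rule.children]
    return min(states) if rule.op == "and" else max(states)


class GeneCountClassification(NamedTuple):
    n_single_gene: int
    n_multi_gene: int
    n_no_gpr: int


def classify_reactions_by_gene_count(model: MetabolicModel) -> GeneCountClassification:
    """Tally reactions by the number of distinct genes in their GPR."""
    single = multi = none = 0
    for rxn in model.reactions:
        if rxn.gpr is None:
            none += 1
        elif len(rxn.gpr.genes()) == 1:
            single += 1
        else:
            multi += 1
    return GeneCountClassification(single, multi, none)
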