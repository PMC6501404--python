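"""Readers and writers for the four-file tabular model dialect.

A model on disk is four UTF-8 text files; ``#`` starts a comment line in
all of them.

``model.tsv``
    Header row ``id<TAB>equation<TAB>lb<TAB>ub<TAB>subsystem<TAB>name``,
    then one reaction per line.  The equation string uses ``-->`` for
    irreversible and ``<=>`` for reversible reactions, with terms like
    ``2 A_c + B_c``.  When the bound columns are empty, reversibility is
    inferred from the arrow: ``-->`` gives [0, 1000] and ``<=>`` gives
    [-1000, 1000].  A compact form ``Rid: equation`` (colon after the id,
    no further columns) is also accepted.  Metabolite compartments come
    from the id suffix: ``_c`` intracellular, ``_e`` extracellular, ``_b``
    boundary; metabolites are created on first use.

``biomass.txt``
    A single equation ``coef met + coef met + ... --> coef met + ...``
    with compartment-free metabolite names as conventionally printed for
    biomass compositions (e.g. ``45.7318 atp``); an omitted coefficient
    means 1 and scientific notation (``5.0E-5``) is accepted.  Ids may
    contain ``-`` (``pnto-r``) and may start with a digit (``5mthf``).

``gpr.tsv``
    Lines ``reaction-id<TAB>boolean expression`` with ``and``/``or`` and
    parentheses.

``exchange.tsv``
    Lines ``exchange-reaction-id<TAB>lb<TAB>ub`` overriding bounds of the
    listed reactions only.

``write_model`` emits all four files deterministically (reactions sorted
by id) so that identical models produce identical bytes.
"""

from __future__ import annotations

import re
from pathlib import Path

from .gpr import parse_gpr_expression
from .model import (
    DEFAULT_UPPER_BOUND,
    BiomassEquation,
    Compartment,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = [
    "ParseError",
    "parse_model_file",
    "parse_biomass_equation",
    "parse_gpr_file",
    "parse_exchange_file",
    "write_model",
    "read_model_dir",
    "write_model_dir",
    "models_equivalent",
]

MODEL_FILENAMES = {
    "model": "model.tsv",
    "biomass": "biomass.txt",
    "exchange": "exchange.tsv",
    "gpr": "gpr.tsv",
}


class ParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_ID_RE = re.compile(r"^[A-Za-z0-9_.:\-]+$")


def _iter_content_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line


def _parse_side(side: str, sign: float, stoich: dict[str, float], lineno: int) -> None:
    side = side.strip()
    if not side:
        return
    for term in re.split(r"\s+\+\s+", side):
        term = term.strip()
        if not term:
            continue
        parts = term.split()
        if len(parts) == 1:
            coef, mid = 1.0, parts[0]
        elif len(parts) == 2:
            if not _NUMBER_RE.match(parts[0]):
                raise ParseError(
                    f"expected a coefficient, got {parts[0]!r} in term {term!r}", lineno
                )
            coef, mid = float(parts[0]), parts[1]
        else:
            raise ParseError(f"malformed term {term!r}", lineno)
        if not _ID_RE.match(mid):
            raise ParseError(f"invalid metabolite id {mid!r}", lineno)
        stoich[mid] = stoich.get(mid, 0.0) + sign * coef


def _parse_equation(eq: str, lineno: int) -> tuple[dict[str, float], bool]:
    if "<=>" in eq:
        arrow, reversible = "<=>", True
    elif "-->" in eq:
        arrow, reversible = "-->", False
    else:
        raise ParseError(f"equation lacks an arrow (--> or <=>): {eq!r}", lineno)
    left, _, right = eq.partition(arrow)
    stoich: dict[str, float] = {}
    _parse_side(left, -1.0, stoich, lineno)
    _parse_side(right, +1.0, stoich, lineno)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ParseError(f"equation has empty stoichiometry: {eq!r}", lineno)
    return stoich, reversible


def parse_model_file(text: str, model_id: str = "model") -> MetabolicModel:
    """Parse the reaction table into a validated :class:`MetabolicModel`.

    Metabolites are created on first use with compartments inferred from
    their id suffix; an unknown suffix or a duplicate reaction id is a
    :class:`ParseError` naming the offending line.
    """
    model = MetabolicModel(id=model_id)
    for lineno, line in _iter_content_lines(text):
        fields = line.split("\t")
        first = fields[0].strip()
        if first.lower() == "id" and len(fields) > 1:
            continue  # header row
        if ":" in first and len(fields) == 1:
            rid, _, eq = first.partition(":")
            rid = rid.strip()
            fields = [rid, eq.strip()]
        if len(fields) < 2:
            raise ParseError(f"expected at least id and equation columns: {line!r}", lineno)
        rid = fields[0].strip()
        if rid in model.reaction_ids:
            raise ParseError(f"duplicate reaction id {rid!r}", lineno)
        stoich, reversible = _parse_equation(fields[1].strip(), lineno)
        lb_field = fields[2].strip() if len(fields) > 2 else ""
        ub_field = fields[3].strip() if len(fields) > 3 else ""
        lb = float(lb_field) if lb_field else (-DEFAULT_UPPER_BOUND if reversible else 0.0)
        ub = float(ub_field) if ub_field else DEFAULT_UPPER_BOUND
        subsystem = fields[4].strip() if len(fields) > 4 else ""
        name = fields[5].strip() if len(fields) > 5 else ""
        for mid in stoich:
            if mid not in model.metabolite_ids:
                try:
                    comp = Compartment.from_suffix(mid)
                except ValueError as exc:
                    raise ParseError(str(exc), lineno) from None
                model.add_metabolite(Metabolite(mid, comp))
        model.reactions.append(
            Reaction(rid, stoich, lb, ub, subsystem=subsystem, name=name)
        )
    if model.objective_reaction_id is None and "BIOMASS" in model.reaction_ids:
        model.objective_reaction_id = "BIOMASS"
    model.validate()
    return model


def parse_biomass_equation(text: str) -> BiomassEquation:
    """Parse a single biomass equation string into reactant/product maps."""
    body = " ".join(
        line for _, line in _iter_content_lines(text)
    ).strip() or text.strip()
    if "-->" not in body:
        raise ParseError("biomass equation lacks the --> arrow")
    left, _, right = body.partition("-->")
    eq = BiomassEquation()
    for side_text, coefs in ((left, eq.reactants), (right, eq.products)):
        pos = 0
        for term in side_text.split("+"):
            stripped = term.strip()
            pos += len(term) + 1
            if not stripped:
                continue
            parts = stripped.split()
            if len(parts) == 1:
                coef, mid = 1.0, parts[0]
            elif len(parts) == 2 and _NUMBER_RE.match(parts[0]):
                coef, mid = float(parts[0]), parts[1]
            else:
                raise ParseError(
                    f"token {stripped!r} near position {pos} is neither "
                    "'coefficient metabolite' nor a bare metabolite id"
                )
            if _NUMBER_RE.match(mid) or not _ID_RE.match(mid):
                raise ParseError(
                    f"token {mid!r} near position {pos} is not a metabolite id"
                )
            coefs[mid] = coefs.get(mid, 0.0) + coef
    eq.validate()
    return eq


def parse_gpr_file(text: str, model: MetabolicModel) -> MetabolicModel:
    """Attach GPR rules to a model's reactions (returns the same model).

    Any line naming a reaction absent from the model is collected and
    reported in a single error listing all unknown ids.
    """
    unknown: list[str] = []
    parsed: list[tuple[str, str, int]] = []
    for lineno, line in _iter_content_lines(text):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"expected 'reaction-id<TAB>expression': {line!r}", lineno)
        rid = fields[0].strip()
        if rid.lower() == "id":
            continue
        if rid not in model.reaction_ids:
            unknown.append(rid)
            continue
        parsed.append((rid, fields[1].strip(), lineno))
    if unknown:
        raise ParseError(f"unknown reaction ids in GPR file: {sorted(set(unknown))}")
    for rid, expr, lineno in parsed:
        try:
            model.get_reaction(rid).gpr = parse_gpr_expression(expr)
        except ValueError as exc:
            raise ParseError(f"bad GPR for {rid}: {exc}", lineno) from None
    return model


def parse_exchange_file(text: str, model: MetabolicModel) -> MetabolicModel:
    """Override bounds of the listed exchange reactions (in place)."""
    for lineno, line in _iter_content_lines(text):
        fields = line.split("\t")
        if fields[0].strip().lower() == "id":
            continue
        if len(fields) < 3:
            raise ParseError(f"expected 'id<TAB>lb<TAB>ub': {line!r}", lineno)
        rid = fields[0].strip()
        try:
            rxn = model.get_reaction(rid)
        except KeyError:
            raise ParseError(f"unknown reaction id {rid!r}", lineno) from None
        lb, ub = float(fields[1]), float(fields[2])
        if lb > ub:
            raise ParseError(f"{rid}: lower bound {lb} exceeds upper bound {ub}", lineno)
        rxn.lower_bound, rxn.upper_bound = lb, ub
    return model


def _format_coef(c: float) -> str:
    return repr(c) if c != int(c) else str(int(c))


def _format_equation(rxn: Reaction) -> str:
    lhs = sorted((m, -c) for m, c in rxn.stoichiometry.items() if c < 0)
    rhs = sorted((m, c) for m, c in rxn.stoichiometry.items() if c > 0)

    def fmt(side):
        return " + ".join(
            mid if coef == 1.0 else f"{_format_coef(coef)} {mid}" for mid, coef in side
        )

    arrow = "<=>" if rxn.reversible else "-->"
    return f"{fmt(lhs)} {arrow} {fmt(rhs)}".strip()


def write_model(model: MetabolicModel) -> dict[str, str]:
    """Serialise a model to the four dialect files.

    Returns ``{"model": ..., "gpr": ..., "exchange": ..., "biomass": ...}``;
    output is deterministic (sorted by reaction id).
    """
    rxns = sorted(model.reactions, key=lambda r: r.id)
    model_lines = ["id\tequation\tlb\tub\tsubsystem\tname"]
    for r in rxns:
        model_lines.append(
            "\t".join(
                [
                    r.id,
                    _format_equation(r),
                    repr(r.lower_bound),
                    repr(r.upper_bound),
                    r.subsystem,
                    r.name,
                ]
            )
        )
    gpr_lines = [
        f"{r.id}\t{r.gpr.to_string()}" for r in rxns if r.gpr is not None
    ]
    exch_lines = [
        f"{r.id}\t{r.lower_bound!r}\t{r.upper_bound!r}"
        for r in rxns
        if model.is_exchange(r)
    ]
    if model.objective_reaction_id is not None:
        biomass = _format_equation(model.get_reaction(model.objective_reaction_id))
    else:
        biomass = ""
    return {
        "model": "\n".join(model_lines) + "\n",
        "gpr": "\n".join(gpr_lines) + ("\n" if gpr_lines else ""),
        "exchange": "\n".join(exch_lines) + ("\n" if exch_lines else ""),
        "biomass": biomass + ("\n" if biomass else ""),
    }


def write_model_dir(model: MetabolicModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    texts = write_model(model)
    for key, fname in MODEL_FILENAMES.items():
        (directory / fname).write_text(texts[key], encoding="utf-8")


def read_model_dir(directory: str | Path, model_id: str | None = None) -> MetabolicModel:
    """Load a model from a directory holding the four dialect files.

    Only ``model.tsv`` is required; the other three are applied if present.
    """
    directory = Path(directory)
    model_path = directory / MODEL_FILENAMES["model"]
    model = parse_model_file(
        model_path.read_text(encoding="utf-8"), model_id=model_id or directory.name
    )
    gpr_path = directory / MODEL_FILENAMES["gpr"]
    if gpr_path.exists():
        parse_gpr_file(gpr_path.read_text(encoding="utf-8"), model)
    exch_path = directory / MODEL_FILENAMES["exchange"]
    if exch_path.exists():
        parse_exchange_file(exch_path.read_text(encoding="utf-8"), model)
    model.validate()
    return model


def models_equivalent(a: MetabolicModel, b: MetabolicModel) -> bool:
    """Component-wise equality ignoring ordering of reactions/metabolites."""
    if {m.id: m.compartment for m in a.metabolites} != {
        m.id: m.compartment for m in b.metabolites
    }:
        return False
    if a.objective_reaction_id != b.objective_reaction_id:
        return False
    ra, rb = a.reaction_ids, b.reaction_ids
    if set(ra) != set(rb):
        return False
    for rid, r1 in ra.items():
        r2 = rb[rid]
        if (
            r1.stoichiometry != r2.stoichiometry
            or r1.lower_bound != r2.lower_bound
            or r1.upper_bound != r2.upper_bound
            or r1.subsystem != r2.subsystem
            or r1.gpr != r2.gpr
        ):
            return False
    return True
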