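"""Core data structures for constraint-based metabolic models.

A model is a set of metabolites partitioned into three compartment classes
(intracellular, extracellular, boundary), a set of reactions with flux
bounds and signed stoichiometry, gene-protein-reaction (GPR) boolean rules,
and a biomass objective reaction.  The stoichiometric matrix ``S`` has one
row per *non-boundary* metabolite and one column per reaction; boundary
metabolites are the open ends of the system and are exempt from the
steady-state balance ``S v = 0``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "Compartment",
    "Metabolite",
    "Gpr",
    "Reaction",
    "MetabolicModel",
    "BiomassEquation",
    "MediumSpec",
    "ModelValidationError",
    "DEFAULT_UPPER_BOUND",
]

#: Magnitude used for unconstrained fluxes (mmol/gDW/h).  Matches the clamp
#: magnitude used when highly expressed reactions have their capacity opened.
DEFAULT_UPPER_BOUND = 1000.0


class ModelValidationError(ValueError):
    """A structural invariant of the model is violated."""


class Compartment(str, enum.Enum):
    INTRACELLULAR = "intracellular"
    EXTRACELLULAR = "extracellular"
    BOUNDARY = "boundary"

    @classmethod
    def from_suffix(cls, met_id: str) -> "Compartment":
        """Infer the compartment from the id suffix (_c / _e / _b)."""
        if met_id.endswith("_c"):
            return cls.INTRACELLULAR
        if met_id.endswith("_e"):
            return cls.EXTRACELLULAR
        if met_id.endswith("_b"):
            return cls.BOUNDARY
        raise ModelValidationError(
            f"metabolite id {met_id!r} has no recognised compartment suffix "
            "(_c intracellular, _e extracellular, _b boundary)"
        )


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: Compartment
    name: str = ""


@dataclass(frozen=True)
class Gpr:
    """Boolean gene-protein-reaction rule.

    ``op`` is one of ``"gene"``, ``"and"`` (enzyme complex: every subunit
    required) or ``"or"`` (isozymes: any one suffices).
    """

    op: str
    gene: str | None = None
    children: tuple["Gpr", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene or self.children:
                raise ValueError("gene node needs a gene id and no children")
        elif self.op in ("and", "or"):
            if self.gene is not None or len(self.children) < 1:
                raise ValueError(f"{self.op} node needs children and no gene id")
        else:
            raise ValueError(f"unknown GPR node op {self.op!r}")

    # -- constructors ------------------------------------------------------
    @staticmethod
    def gene_(gene_id: str) -> "Gpr":
        return Gpr("gene", gene=gene_id)

    @staticmethod
    def and_(*children: "Gpr") -> "Gpr":
        return Gpr("and", children=tuple(children))

    @staticmethod
    def or_(*children: "Gpr") -> "Gpr":
        return Gpr("or", children=tuple(children))

    # -- queries -----------------------------------------------------------
    def genes(self) -> frozenset[str]:
        """Set of distinct gene ids appearing as leaves."""
        if self.op == "gene":
            return frozenset((self.gene,))  # type: ignore[arg-type]
        out: frozenset[str] = frozenset()
        for child in self.children:
            out |= child.genes()
        return out

    def leaf_count(self) -> int:
        if self.op == "gene":
            return 1
        return sum(c.leaf_count() for c in self.children)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.op} "
        parts = []
        for child in self.children:
            s = child.to_string()
            if child.op != "gene" and child.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed)."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER_BOUND
    subsystem: str = ""
    name: str = ""
    gpr: Gpr | None = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            subsystem=self.subsystem,
            name=self.name,
            gpr=self.gpr,
        )


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_reaction_id: str | None = None
    id: str = "model"
    #: free-form annotations (e.g. planted ground truth from the generator)
    annotations: dict = field(default_factory=dict)

    # -- indexes -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def reaction_ids(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    @property
    def genes(self) -> list[str]:
        """Distinct GPR leaves, sorted.  The model's gene list is defined by
        the rules: a gene exists in the model iff some reaction cites it."""
        out: set[str] = set()
        for r in self.reactions:
            if r.gpr is not None:
                out |= r.gpr.genes()
        return sorted(out)

    def get_reaction(self, reaction_id: str) -> Reaction:
        try:
            return self.reaction_ids[reaction_id]
        except KeyError:
            raise KeyError(f"no reaction {reaction_id!r} in model {self.id!r}") from None

    # -- structure ---------------------------------------------------------
    def balanced_metabolites(self) -> list[Metabolite]:
        """Metabolites subject to steady-state balance (non-boundary)."""
        return [m for m in self.metabolites if m.compartment is not Compartment.BOUNDARY]

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Dense S over non-boundary metabolite rows; returns (S, row ids)."""
        rows = [m.id for m in self.balanced_metabolites()]
        index = {mid: i for i, mid in enumerate(rows)}
        S = np.zeros((len(rows), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                i = index.get(mid)
                if i is not None:
                    S[i, j] = coef
        return S, rows

    def is_exchange(self, reaction: Reaction) -> bool:
        """Exchange reactions move one species across the system boundary:
        either a single-metabolite open drain, or a two-metabolite reaction
        pairing one boundary metabolite with its non-boundary counterpart."""
        stoich = reaction.stoichiometry
        if len(stoich) == 1:
            return True
        if len(stoich) != 2:
            return False
        mets = self.metabolite_ids
        n_boundary = sum(
            1
            for mid in stoich
            if mid in mets and mets[mid].compartment is Compartment.BOUNDARY
        )
        return n_boundary == 1

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if self.is_exchange(r)]

    def exchange_for_metabolite(self, met_id: str) -> Reaction | None:
        """Find the exchange reaction consuming/producing ``met_id`` (the
        extracellular species; a bare id is tried with an ``_e`` suffix)."""
        candidates = (met_id, met_id + "_e")
        for rxn in self.exchange_reactions():
            if any(c in rxn.stoichiometry for c in candidates):
                return rxn
        return None

    def compartment_counts(self) -> dict[Compartment, int]:
        counts = {c: 0 for c in Compartment}
        for m in self.metabolites:
            counts[m.compartment] += 1
        return counts

    # -- mutation helpers --------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            objective_reaction_id=self.objective_reaction_id,
            id=self.id,
            annotations=dict(self.annotations),
        )

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolite_ids:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reaction_ids:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolite_ids:
                self.add_metabolite(Metabolite(mid, Compartment.from_suffix(mid)))
        self.reactions.append(rxn)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Raise ModelValidationError on any violated structural invariant."""
        seen_m: set[str] = set()
        for m in self.metabolites:
            if m.id in seen_m:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
        seen_r: set[str] = set()
        mets = self.metabolite_ids
        for r in self.reactions:
            if r.id in seen_r:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id!r} has empty stoichiometry")
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
            for mid in r.stoichiometry:
                if mid not in mets:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references unknown metabolite {mid!r}"
                    )
            if not self.is_exchange(r):
                for mid in r.stoichiometry:
                    if mets[mid].compartment is Compartment.BOUNDARY:
                        raise ModelValidationError(
                            f"non-exchange reaction {r.id!r} touches boundary "
                            f"metabolite {mid!r}"
                        )
        if self.objective_reaction_id is not None:
            if self.objective_reaction_id not in seen_r:
                raise ModelValidationError(
                    f"objective reaction {self.objective_reaction_id!r} not in model"
                )


@dataclass
class BiomassEquation:
    """The biomass pseudo-reaction: precursor demands and by-products.

    Both maps hold positive coefficients; reactants are consumed (growth
    precursors plus the growth-associated ATP demand) and products released
    (ADP, phosphate, protons, pyrophosphate and the Biomass token).
    """

    reactants: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for side, coefs in (("reactant", self.reactants), ("product", self.products)):
            for mid, c in coefs.items():
                if c <= 0:
                    raise ModelValidationError(
                        f"biomass {side} {mid!r} has non-positive coefficient {c}"
                    )

    def to_reaction(
        self,
        reaction_id: str = "BIOMASS",
        compartment_suffix: str = "_c",
        drop_tokens: frozenset[str] = frozenset({"Biomass"}),
    ) -> Reaction:
        """Embed as a model reaction; compartment-free metabolite names get
        ``compartment_suffix`` appended, and the bare Biomass product token is
        dropped (the reaction is the drain)."""
        stoich: dict[str, float] = {}
        for mid, c in self.reactants.items():
            stoich[mid + compartment_suffix] = stoich.get(mid + compartment_suffix, 0.0) - c
        for mid, c in self.products.items():
            if mid in drop_tokens:
                continue
            stoich[mid + compartment_suffix] = stoich.get(mid + compartment_suffix, 0.0) + c
        return Reaction(
            id=reaction_id,
            stoichiometry=stoich,
            lower_bound=0.0,
            upper_bound=DEFAULT_UPPER_BOUND,
            subsystem="Biomass",
            name="biomass objective",
        )


@dataclass
class MediumSpec:
    """A defined growth medium: maximal uptake rate per exchanged metabolite.

    ``components`` maps extracellular metabolite ids to their maximal uptake
    rates (mmol/gDW/h, non-negative); the carbon source is one of them with
    its own uptake bound (e.g. glucose at 10.53 for batch growth).
    """

    components: dict[str, float] = field(default_factory=dict)
    carbon_source: str | None = None

    def __post_init__(self) -> None:
        for mid, rate in self.components.items():
            if rate < 0:
                raise ModelValidationError(
                    f"medium component {mid!r} has negative uptake rate {rate}"
                )
        if self.carbon_source is not None and self.carbon_source not in self.components:
            raise ModelValidationError(
                f"carbon source {self.carbon_source!r} is not a medium component"
            )
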