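"""Single-gene-deletion essentiality scanning and vulnerable-subsystem rollups.

A gene is deleted in silico by evaluating every reaction's GPR rule with
the gene removed; reactions that lose catalysis are constrained to zero
flux, biomass is re-maximised by FBA, and the gene is called essential when
the knockout optimum falls below a numerical zero threshold.  Constraints
are restored before the next gene (the scan always operates on copies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import fba, gpr
from .model import MediumSpec, MetabolicModel

__all__ = [
    "GeneResult",
    "EssentialityReport",
    "single_gene_deletion",
    "essentiality_scan",
    "subsystem_vulnerability",
    "ZERO_GROWTH_TOL",
]

#: Absolute knockout-growth threshold below which a gene is called essential.
#: The biological criterion is literally "zero growth"; LP numerics require
#: a small tolerance.
ZERO_GROWTH_TOL = 1e-6


@dataclass
class GeneResult:
    gene: str
    z_wildtype: float
    z_knockout: float
    essential: bool
    disabled_reactions: list[str] = field(default_factory=list)

    @property
    def growth_ratio(self) -> float:
        return self.z_knockout / self.z_wildtype if self.z_wildtype else float("nan")


@dataclass
class EssentialityReport:
    z_wildtype: float
    results: dict[str, GeneResult]
    tolerance: float
    medium: MediumSpec | None = None

    @property
    def essential_genes(self) -> list[str]:
        return sorted(g for g, r in self.results.items() if r.essential)

    @property
    def n_essential(self) -> int:
        return len(self.essential_genes)

    @property
    def fraction_essential(self) -> float:
        return self.n_essential / len(self.results) if self.results else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": r.gene,
                "Z_wt": r.z_wildtype,
                "Z_ko": r.z_knockout,
                "ratio": r.growth_ratio,
                "essential": r.essential,
                "disabled_reactions": ";".join(r.disabled_reactions),
            }
            for r in self.results.values()
        ]
        return pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)


def _knockout_model(model: MetabolicModel, genes: set[str]) -> tuple[MetabolicModel, list[str]]:
    disabled = gpr.reactions_disabled_by(model, genes)
    ko = model.copy()
    for rid in disabled:
        rxn = ko.get_reaction(rid)
        rxn.lower_bound, rxn.upper_bound = 0.0, 0.0
    return ko, disabled


def single_gene_deletion(
    model: MetabolicModel, gene: str, objective_reaction_id: str | None = None
) -> float:
    """Maximal biomass flux after deleting one gene.

    Every reaction whose GPR evaluates non-functional without the gene is
    constrained to zero; the model itself is never mutated.
    """
    if gene not in model.genes:
        raise KeyError(f"gene {gene!r} not in model {model.id!r}")
    ko, _ = _knockout_model(model, {gene})
    sol = fba.solve_fba(ko, objective_reaction_id, minimize_total_flux=False)
    return sol.objective if sol.optimal else 0.0


def essentiality_scan(
    model: MetabolicModel,
    medium: MediumSpec | None = None,
    tolerance: float = ZERO_GROWTH_TOL,
    objective_reaction_id: str | None = None,
) -> EssentialityReport:
    """Scan every model gene with single deletions under the given medium.

    Genes are visited in sorted order (results are order-independent: each
    deletion starts from the same wild-type constraints).  Aborts with a
    diagnostic if the wild type itself does not grow, since essentiality
    calls would then be meaningless.
    """
    work = fba.apply_medium(model, medium) if medium is not None else model
    wt = fba.solve_fba(work, objective_reaction_id, minimize_total_flux=False)
    if not wt.optimal or wt.objective is None or wt.objective <= tolerance:
        raise RuntimeError(
            "wild-type FBA is not viable (status "
            f"{wt.status}, Z={wt.objective}); an essentiality scan under these "
            "constraints is meaningless"
        )
    z_wt = wt.objective

    results: dict[str, GeneResult] = {}
    for gene in sorted(work.genes):
        ko, disabled = _knockout_model(work, {gene})
        if not disabled:
            # the gene never disables a reaction (e.g. only in OR rules with
            # intact partners): trivially non-essential, no LP needed
            z_ko = z_wt
        else:
            sol = fba.solve_fba(ko, objective_reaction_id, minimize_total_flux=False)
            z_ko = sol.objective if sol.optimal else 0.0
        results[gene] = GeneResult(
            gene=gene,
            z_wildtype=z_wt,
            z_knockout=z_ko,
            essential=z_ko < tolerance,
            disabled_reactions=disabled,
        )
    return EssentialityReport(
        z_wildtype=z_wt, results=results, tolerance=tolerance, medium=medium
    )


def subsystem_vulnerability(
    report: EssentialityReport, model: MetabolicModel
) -> pd.DataFrame:
    """Per-subsystem essential-gene percentages ('vulnerable subsystems').

    A gene is linked to every subsystem containing a reaction that cites it;
    an essential gene counts toward every subsystem containing a reaction it
    disables.  Returns columns (subsystem, n_reactions, n_genes,
    n_essential, percentage), sorted by percentage descending.
    """
    essential = set(report.essential_genes)
    disabled_by_gene = {
        g: set(r.disabled_reactions) for g, r in report.results.items()
    }
    sub_reactions: dict[str, list] = {}
    for rxn in model.reactions:
        sub_reactions.setdefault(rxn.subsystem or "(unassigned)", []).append(rxn)

    rows = []
    for subsystem, rxns in sorted(sub_reactions.items()):
        genes_linked: set[str] = set()
        rids = {r.id for r in rxns}
        for r in rxns:
            if r.gpr is not None:
                genes_linked |= r.gpr.genes()
        if not genes_linked:
            continue
        n_ess = sum(
            1
            for g in genes_linked
            if g in essential and disabled_by_gene.get(g, set()) & rids
        )
        rows.append(
            {
                "subsystem": subsystem,
                "n_reactions": len(rxns),
                "n_genes": len(genes_linked),
                "n_essential": n_ess,
                "percentage": 100.0 * n_ess / len(genes_linked),
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(
            ["percentage", "subsystem"], ascending=[False, True]
        ).reset_index(drop=True)
    return frame
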