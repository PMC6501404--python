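"""Transcriptome-to-flux integration.

RNAseq expression levels (RPKM) are discretized per gene into three states
using two thresholds: state -1 (low/absent, g < gamma_low), state 0
(moderate), state 1 (high, g > gamma_high).  The thresholds sit on a
geometric grid of cutoffs with ratio 1.2; the defaults gamma_low = 3.00
(chosen to exclude roughly 10% of genes across conditions) and
gamma_high = 850.56 (= 1.2^37) follow the calibration used for the iSR929
study.  Gene states propagate to reactions through the GPR rules
(AND = min, OR = max) and constrain the flux space in one of two modes:

``clamp``
    literal bound surgery — a state -1 reaction is closed to zero flux and
    a state 1 reaction has its flux capacity opened to magnitude 1000;

``imat``
    an iMAT-style mixed-integer LP that maximises the number of highly
    expressed reactions carrying at least epsilon flux plus lowly expressed
    reactions carrying at most epsilon.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, milp

from . import gpr
from .fba import REPORTING_TOL, FluxSolution
from .model import DEFAULT_UPPER_BOUND, MetabolicModel

__all__ = [
    "ExpressionTable",
    "BinGrid",
    "DiscretizationThresholds",
    "build_bin_grid",
    "CutoffSelection",
    "select_lower_cutoff",
    "discretize_gene",
    "gene_states_for_condition",
    "reaction_states",
    "apply_expression_constraints",
    "ImatProblem",
    "ImatSolution",
    "ActiveReactionReport",
    "active_reaction_report",
    "FoldChange",
    "fold_change",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression table
# ---------------------------------------------------------------------------
@dataclass
class ExpressionTable:
    """RPKM values per gene (rows) per condition (columns)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] == 0:
            raise ValueError("expression table must have at least one condition")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.data.columns)

    def get(self, gene: str, condition: str) -> float:
        return float(self.data.at[gene, condition])

    @classmethod
    def from_tsv(cls, text_or_path) -> "ExpressionTable":
        frame = pd.read_csv(text_or_path, sep="\t", index_col=0, comment="#")
        return cls(frame.astype(float))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# bin grid and thresholds
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class BinGrid:
    base: float
    cutoffs: tuple[float, ...]


def build_bin_grid(base: float = 1.2, n: int = 58) -> BinGrid:
    """Geometric cutoff grid: cutoff_k = base**k for k = 0 .. n-1."""
    if base <= 1:
        raise ValueError(f"grid base must exceed 1, got {base}")
    if n < 2:
        raise ValueError(f"grid needs at least 2 cutoffs, got {n}")
    return BinGrid(base=base, cutoffs=tuple(float(base) ** k for k in range(n)))


@dataclass(frozen=True)
class DiscretizationThresholds:
    gamma_low: float = 3.00
    gamma_high: float = 850.56

    def __post_init__(self) -> None:
        if not 0 < self.gamma_low < self.gamma_high:
            raise ValueError(
                f"need 0 < gamma_low < gamma_high, got "
                f"({self.gamma_low}, {self.gamma_high})"
            )


class CutoffSelection(NamedTuple):
    gamma_low: float
    excluded_fraction: float


def select_lower_cutoff(
    table: ExpressionTable,
    conditions: Iterable[str] | None = None,
    target_excluded_fraction: float = 0.10,
    grid: BinGrid | None = None,
) -> CutoffSelection:
    """Smallest grid cutoff excluding at least the target fraction of genes.

    A gene is excluded at cutoff c when its RPKM is below c in *all* of the
    given conditions.  Returns the cutoff and the fraction it achieves.
    """
    if grid is None:
        grid = build_bin_grid()
    conds = list(conditions) if conditions is not None else table.conditions
    sub = table.data[conds]
    if sub.empty:
        raise ValueError("expression table has no genes")
    values = sub.to_numpy()
    n_genes = values.shape[0]
    for cutoff in grid.cutoffs:
        frac = float(((values < cutoff).all(axis=1)).sum()) / n_genes
        if frac >= target_excluded_fraction:
            return CutoffSelection(gamma_low=cutoff, excluded_fraction=frac)
    raise ValueError(
        f"no grid cutoff excludes {target_excluded_fraction:.0%} of genes "
        f"(max cutoff {grid.cutoffs[-1]:.2f})"
    )


def discretize_gene(g: float, thresholds: DiscretizationThresholds | None = None) -> int:
    """Discretize one RPKM value into {-1, 0, 1}.

    g = 0 (and anything below gamma_low) is low/absent (-1); values up to
    and including gamma_high are moderate (0); above gamma_high is high (1).
    """
    if thresholds is None:
        thresholds = DiscretizationThresholds()
    if g < 0:
        raise ValueError(f"RPKM must be non-negative, got {g}")
    if g < thresholds.gamma_low:
        return -1
    if g <= thresholds.gamma_high:
        return 0
    return 1


def gene_states_for_condition(
    table: ExpressionTable,
    condition: str,
    thresholds: DiscretizationThresholds | None = None,
) -> dict[str, int]:
    """Discretize a whole condition column into a gene-state map."""
    if condition not in table.conditions:
        raise KeyError(f"condition {condition!r} not in expression table")
    return {
        gene: discretize_gene(table.get(gene, condition), thresholds)
        for gene in table.genes
    }


def reaction_states(
    model: MetabolicModel, gene_states: Mapping[str, int]
) -> dict[str, int]:
    """Propagate gene states onto reactions via the GPR rules.

    Reactions without a GPR (spontaneous, exchanges) stay at state 0.
    """
    return {
        rxn.id: (
            gpr.reaction_expression_state(rxn.gpr, gene_states)
            if rxn.gpr is not None
            else 0
        )
        for rxn in model.reactions
    }


# ---------------------------------------------------------------------------
# constraint application
# ---------------------------------------------------------------------------
def apply_expression_constraints(
    model: MetabolicModel,
    gene_states: Mapping[str, int],
    mode: str = "clamp",
    epsilon: float = 1.0,
    clamp_magnitude: float = DEFAULT_UPPER_BOUND,
):
    """Constrain the flux space with discretized expression states.

    ``clamp`` returns a copy of the model in which state -1 reactions are
    closed ([0, 0]) and state 1 reactions have their capacity extended to
    magnitude ``clamp_magnitude`` (the upper bound; the lower bound too if
    the reaction is reversible).  State 0 reactions are untouched, as is the
    biomass reaction (a low state there only triggers a warning).

    ``imat`` returns an :class:`ImatProblem` whose MILP rewards state 1
    reactions carrying at least ``epsilon`` flux and state -1 reactions
    carrying at most ``epsilon``.
    """
    states = reaction_states(model, gene_states)
    if mode == "clamp":
        out = model.copy()
        for rxn in out.reactions:
            state = states[rxn.id]
            if state == 0:
                continue
            if rxn.id == out.objective_reaction_id:
                if state == -1:
                    warnings.warn(
                        f"biomass reaction {rxn.id!r} has expression state -1; "
                        "not clamping the objective",
                        stacklevel=2,
                    )
                continue
            if state == -1:
                rxn.lower_bound, rxn.upper_bound = 0.0, 0.0
            else:  # state == 1: open capacity, do not force flux
                was_reversible = rxn.reversible
                rxn.upper_bound = clamp_magnitude
                if was_reversible:
                    rxn.lower_bound = -clamp_magnitude
        out.annotations["expression_states"] = states
        return out
    if mode == "imat":
        return ImatProblem(model=model, states=states, epsilon=epsilon)
    raise ValueError(f"unknown integration mode {mode!r} (use 'clamp' or 'imat')")


@dataclass
class ImatSolution:
    status: str
    agreement: int
    fluxes: dict[str, float]
    indicators: dict[str, int]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class ImatProblem:
    """iMAT-style MILP over a model and reaction expression states.

    Binary indicators certify |v_i| >= epsilon for each state 1 reaction
    (split into a forward and a backward indicator) and |v_i| <= epsilon
    for each state -1 reaction; the objective maximises the number of
    satisfied indicators.  Variable ordering is fixed by reaction order, so
    the HiGHS solve is deterministic.
    """

    model: MetabolicModel
    states: dict[str, int]
    epsilon: float = 1.0

    @property
    def high_reactions(self) -> list[str]:
        return [r.id for r in self.model.reactions if self.states.get(r.id) == 1]

    @property
    def low_reactions(self) -> list[str]:
        return [r.id for r in self.model.reactions if self.states.get(r.id) == -1]

    def solve(self) -> ImatSolution:
        m = self.model
        n = len(m.reactions)
        rxn_index = {r.id: j for j, r in enumerate(m.reactions)}
        high = self.high_reactions
        low = self.low_reactions
        eps = self.epsilon
        # variables: v (n), then [yf, yb] per high reaction, then y0 per low
        n_high, n_low = len(high), len(low)
        n_var = n + 2 * n_high + n_low
        lb = np.empty(n_var)
        ub = np.empty(n_var)
        integrality = np.zeros(n_var)
        for j, r in enumerate(m.reactions):
            lb[j], ub[j] = r.lower_bound, r.upper_bound
        lb[n:], ub[n:] = 0.0, 1.0
        integrality[n:] = 1

        S, _ = m.stoichiometric_matrix()
        constraints = []
        if S.shape[0]:
            A = np.zeros((S.shape[0], n_var))
            A[:, :n] = S
            constraints.append(LinearConstraint(A, 0.0, 0.0))

        rows, lo, hi = [], [], []
        for k, rid in enumerate(high):
            j = rxn_index[rid]
            ljf, lyb = n + 2 * k, n + 2 * k + 1
            r = m.get_reaction(rid)
            # yf = 1  =>  v_j >= eps        (else v_j >= lb_j)
            row = np.zeros(n_var)
            row[j] = 1.0
            row[ljf] = -(eps - r.lower_bound)
            rows.append(row), lo.append(r.lower_bound), hi.append(np.inf)
            # yb = 1  =>  v_j <= -eps       (else v_j <= ub_j)
            row = np.zeros(n_var)
            row[j] = 1.0
            row[lyb] = eps + r.upper_bound
            rows.append(row), lo.append(-np.inf), hi.append(r.upper_bound)
            # at most one direction rewarded
            row = np.zeros(n_var)
            row[ljf], row[lyb] = 1.0, 1.0
            rows.append(row), lo.append(-np.inf), hi.append(1.0)
        for k, rid in enumerate(low):
            j = rxn_index[rid]
            jy = n + 2 * n_high + k
            r = m.get_reaction(rid)
            # y0 = 1  =>  v_j <= eps   and  v_j >= -eps
            row = np.zeros(n_var)
            row[j] = 1.0
            row[jy] = r.upper_bound - eps
            rows.append(row), lo.append(-np.inf), hi.append(r.upper_bound)
            row = np.zeros(n_var)
            row[j] = 1.0
            row[jy] = r.lower_bound + eps
            rows.append(row), lo.append(r.lower_bound), hi.append(np.inf)
        if rows:
            constraints.append(LinearConstraint(np.array(rows), np.array(lo), np.array(hi)))

        c = np.zeros(n_var)
        c[n:] = -1.0  # maximise indicator sum
        t0 = time.perf_counter()
        res = milp(
            c,
            constraints=constraints,
            bounds=Bounds(lb, ub),
            integrality=integrality,
        )
        logger.info(
            "iMAT MILP: status=%s agreement=%s wall=%.4fs",
            res.status,
            None if res.x is None else round(-res.fun),
            time.perf_counter() - t0,
        )
        if res.status != 0 or res.x is None:
            return ImatSolution(status="infeasible", agreement=0, fluxes={}, indicators={})
        fluxes = {r.id: float(res.x[j]) for j, r in enumerate(m.reactions)}
        indicators: dict[str, int] = {}
        for k, rid in enumerate(high):
            indicators[rid] = int(round(res.x[n + 2 * k] + res.x[n + 2 * k + 1]))
        for k, rid in enumerate(low):
            indicators[rid] = int(round(res.x[n + 2 * n_high + k]))
        return ImatSolution(
            status="optimal",
            agreement=int(round(-res.fun)),
            fluxes=fluxes,
            indicators=indicators,
        )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------
@dataclass
class ActiveReactionReport:
    """Active-reaction accounting in the style of a per-pathway summary table."""

    condition: str
    active: set[str]
    subsystem_counts: dict[str, int]
    total: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subsystem": s, "n_active": n}
            for s, n in sorted(self.subsystem_counts.items())
        ]
        rows.append({"subsystem": "Total", "n_active": self.total})
        return pd.DataFrame(rows)


def active_reaction_report(
    model: MetabolicModel,
    solution: FluxSolution,
    condition: str = "",
    tol: float = REPORTING_TOL,
    excluded_subsystems: frozenset[str] = frozenset({"Exchange", "Biomass"}),
) -> ActiveReactionReport:
    """Count reactions carrying flux (|v| > tol), grouped by subsystem.

    Exchange pseudo-reactions and the biomass drain are excluded so the
    total covers metabolic and transport reactions only.  Counts depend on
    which optimum the solution represents; pair with the flux-minimised
    FBA vector for reproducibility.
    """
    active: set[str] = set()
    counts: dict[str, int] = {}
    for rxn in model.reactions:
        if rxn.subsystem in excluded_subsystems:
            continue
        v = solution.fluxes.get(rxn.id, 0.0)
        if abs(v) > tol:
            active.add(rxn.id)
            label = rxn.subsystem or "(unassigned)"
            counts[label] = counts.get(label, 0) + 1
    return ActiveReactionReport(
        condition=condition,
        active=active,
        subsystem_counts=counts,
        total=len(active),
    )


class FoldChange(NamedTuple):
    value: float
    infinite: bool


def fold_change(
    table: ExpressionTable,
    gene: str,
    cond_num: str,
    cond_den: str,
    ndigits: int = 1,
) -> FoldChange:
    """Ratio of a gene's RPKM between two conditions, rounded for reporting.

    A zero denominator is reported as infinite with a flag rather than an
    exception.
    """
    num = table.get(gene, cond_num)
    den = table.get(gene, cond_den)
    if den == 0:
        return FoldChange(value=float("inf"), infinite=True)
    return FoldChange(value=round(num / den, ndigits), infinite=False)
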