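"""Linear programming core: FBA, FVA, media, measured-exchange constraints,
and gap detection.

Flux balance analysis maximises the flux Z through an objective reaction
(here: biomass) subject to steady-state mass balance ``S v = 0`` over all
non-boundary metabolites and per-reaction bounds ``a_i <= v_i <= b_i``.
The LPs are solved with the HiGHS solver via :func:`scipy.optimize.linprog`.

Because the optimum is usually degenerate (alternate optimal flux vectors
exist), the reported flux vector is post-processed by a secondary LP that
minimises total absolute flux at the fixed optimal Z.  This makes derived
quantities such as active-reaction counts reproducible.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import Compartment, MediumSpec, MetabolicModel, Reaction

__all__ = [
    "FluxSolution",
    "FVAResult",
    "MeasurementSet",
    "solve_fba",
    "solve_fva",
    "apply_medium",
    "constrain_measured_exchanges",
    "find_dead_end_metabolites",
    "find_blocked_reactions",
    "FEASIBILITY_TOL",
    "REPORTING_TOL",
]

logger = logging.getLogger(__name__)

#: Solver feasibility tolerance passed to HiGHS.
FEASIBILITY_TOL = 1e-9
#: Tolerance below which a flux is reported as zero.
REPORTING_TOL = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FluxSolution:
    status: str
    objective: float | None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    """Per-reaction flux ranges at a fixed fraction of the optimal objective."""

    objective: float
    objective_fraction: float
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)


#: reaction-id -> (measured flux, tolerance half-width)
MeasurementSet = dict[str, tuple[float, float]]


def _linprog(c, A_eq, b_eq, bounds):
    t0 = time.perf_counter()
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    logger.info(
        "LP solve: status=%s objective=%s wall=%.4fs",
        _STATUS.get(res.status, str(res.status)),
        None if res.x is None else -res.fun,
        time.perf_counter() - t0,
    )
    return res


def solve_fba(
    model: MetabolicModel,
    objective_reaction_id: str | None = None,
    minimize_total_flux: bool = True,
) -> FluxSolution:
    """Maximise flux through the objective reaction.

    When ``minimize_total_flux`` is true (the default), a second LP fixes
    the optimal Z and minimises the sum of absolute fluxes, selecting a
    parsimonious representative among the alternate optima.
    Biological infeasibility is reported as ``status="infeasible"``, never
    raised.
    """
    obj_id = objective_reaction_id or model.objective_reaction_id
    if obj_id is None:
        raise ValueError("no objective reaction specified")
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    if obj_id not in rxn_index:
        raise KeyError(f"objective reaction {obj_id!r} not in model")
    S, _ = model.stoichiometric_matrix()
    n = len(model.reactions)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    c = np.zeros(n)
    c[rxn_index[obj_id]] = -1.0  # linprog minimises

    res = _linprog(c, S, np.zeros(S.shape[0]), bounds)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(status=status, objective=None)
    z_star = float(res.x[rxn_index[obj_id]])
    v = res.x

    if minimize_total_flux:
        v2 = _minimize_total_flux(S, bounds, rxn_index[obj_id], z_star, n)
        if v2 is not None:
            v = v2
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    return FluxSolution(status="optimal", objective=z_star, fluxes=fluxes)


def _minimize_total_flux(S, bounds, obj_j, z_star, n):
    """Phase-two LP: min sum t, t >= |v|, S v = 0, v_obj = Z*."""
    m = S.shape[0]
    A_eq = np.zeros((m + 1, 2 * n))
    A_eq[:m, :n] = S
    A_eq[m, obj_j] = 1.0
    b_eq = np.zeros(m + 1)
    b_eq[m] = z_star
    # v - t <= 0 and -v - t <= 0
    A_ub = np.zeros((2 * n, 2 * n))
    A_ub[:n, :n] = np.eye(n)
    A_ub[:n, n:] = -np.eye(n)
    A_ub[n:, :n] = -np.eye(n)
    A_ub[n:, n:] = -np.eye(n)
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    all_bounds = list(bounds) + [(0.0, None)] * n
    t0 = time.perf_counter()
    res = linprog(
        c2,
        A_ub=A_ub,
        b_ub=np.zeros(2 * n),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=all_bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    logger.info(
        "flux-minimisation LP: status=%s total=%s wall=%.4fs",
        _STATUS.get(res.status, str(res.status)),
        res.fun,
        time.perf_counter() - t0,
    )
    if res.status != 0:
        return None
    return res.x[:n]


def solve_fva(
    model: MetabolicModel,
    objective_fraction: float = 1.0,
    reactions: list[str] | None = None,
    objective_reaction_id: str | None = None,
) -> FVAResult:
    """Flux variability analysis: per-reaction min/max flux with the
    objective held at ``objective_fraction`` times its optimum."""
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError(f"objective_fraction must be in [0, 1], got {objective_fraction}")
    obj_id = objective_reaction_id or model.objective_reaction_id
    sol = solve_fba(model, obj_id, minimize_total_flux=False)
    if not sol.optimal:
        raise RuntimeError(f"FBA optimum required for FVA; solver status {sol.status}")
    z_star = sol.objective

    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    S, _ = model.stoichiometric_matrix()
    n = len(model.reactions)
    # encode Z >= fraction * Z* as an extra row of A_ub
    A_ub = np.zeros((1, n))
    A_ub[0, rxn_index[obj_id]] = -1.0
    b_ub = np.array([-objective_fraction * z_star])
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    targets = reactions if reactions is not None else [r.id for r in model.reactions]

    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        j = rxn_index[rid]
        lo_hi = []
        for sense in (+1.0, -1.0):
            c = np.zeros(n)
            c[j] = sense
            res = linprog(
                c,
                A_ub=A_ub,
                b_ub=b_ub,
                A_eq=S,
                b_eq=np.zeros(S.shape[0]),
                bounds=bounds,
                method="highs",
                options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
            )
            if res.status != 0:
                raise RuntimeError(
                    f"FVA subproblem for {rid} returned status "
                    f"{_STATUS.get(res.status, res.status)}"
                )
            lo_hi.append(float(res.x[j]))
        vmin, vmax = min(lo_hi), max(lo_hi)
        ranges[rid] = (vmin, vmax)
    return FVAResult(objective=z_star, objective_fraction=objective_fraction, ranges=ranges)


def _uptake_direction(model: MetabolicModel, rxn: Reaction) -> int:
    """+1 if positive flux imports the exchanged species, -1 if it exports.

    Determined from the sign of the non-boundary metabolite's coefficient:
    with the convention ``X_e <=> X_b`` (coefficient of X_e negative),
    positive flux secretes and uptake is a negative flux.
    """
    mets = model.metabolite_ids
    for mid, coef in rxn.stoichiometry.items():
        if mets[mid].compartment is not Compartment.BOUNDARY:
            return +1 if coef > 0 else -1
    # pure boundary reaction: treat positive flux as export
    return -1


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy with uptake closed for every exchange not in the medium
    and opened to the stated rate for each component.

    Secretion bounds are untouched.  A component without a matching
    exchange reaction is an error naming the metabolite.
    """
    out = model.copy()
    for rxn in out.exchange_reactions():
        if _uptake_direction(out, rxn) < 0:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
        else:
            rxn.upper_bound = min(rxn.upper_bound, 0.0)
    for met_id, rate in medium.components.items():
        rxn = out.exchange_for_metabolite(met_id)
        if rxn is None:
            raise KeyError(
                f"medium component {met_id!r} has no exchange reaction in the model"
            )
        if _uptake_direction(out, rxn) < 0:
            rxn.lower_bound = -abs(rate)
        else:
            rxn.upper_bound = abs(rate)
    return out


def constrain_measured_exchanges(
    model: MetabolicModel, measurements: MeasurementSet
) -> MetabolicModel:
    """Return a copy with each measured reaction's bounds narrowed to the
    measurement window [m - tol, m + tol].

    An over-constrained window surfaces as infeasibility at solve time;
    it is never silently relaxed here.
    """
    out = model.copy()
    for rid, (value, tol) in measurements.items():
        if tol < 0:
            raise ValueError(f"negative tolerance for measurement {rid!r}")
        rxn = out.get_reaction(rid)
        rxn.lower_bound = value - tol
        rxn.upper_bound = value + tol
    return out


def find_dead_end_metabolites(model: MetabolicModel) -> list[str]:
    """Non-boundary metabolites that can only be produced or only consumed
    (taking reversibility into account) — the hallmark of a network gap."""
    producible: set[str] = set()
    consumable: set[str] = set()
    for rxn in model.reactions:
        fwd = rxn.upper_bound > 0
        bwd = rxn.lower_bound < 0
        for mid, coef in rxn.stoichiometry.items():
            if (coef > 0 and fwd) or (coef < 0 and bwd):
                producible.add(mid)
            if (coef < 0 and fwd) or (coef > 0 and bwd):
                consumable.add(mid)
    out = []
    for met in model.balanced_metabolites():
        if (met.id in producible) != (met.id in consumable):
            out.append(met.id)
    return sorted(out)


def find_blocked_reactions(
    model: MetabolicModel, open_exchanges: bool = True, tol: float = REPORTING_TOL
) -> list[str]:
    """Reactions that cannot carry flux under any steady state.

    With ``open_exchanges`` (default) every exchange is first opened to
    [-1000, 1000] so blockage reflects network structure, not the medium.
    Implemented as FVA at objective fraction 0: blocked iff the range is
    {0} within tolerance.
    """
    probe = model.copy()
    if open_exchanges:
        for rxn in probe.exchange_reactions():
            rxn.lower_bound, rxn.upper_bound = -1000.0, 1000.0
    S, _ = probe.stoichiometric_matrix()
    n = len(probe.reactions)
    bounds = [(r.lower_bound, r.upper_bound) for r in probe.reactions]
    blocked = []
    for j, rxn in enumerate(probe.reactions):
        extreme = []
        for sense in (+1.0, -1.0):
            c = np.zeros(n)
            c[j] = sense
            res = linprog(
                c,
                A_eq=S,
                b_eq=np.zeros(S.shape[0]),
                bounds=bounds,
                method="highs",
                options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
            )
            if res.status != 0:
                raise RuntimeError(f"blocked-reaction probe failed for {rxn.id}")
            extreme.append(abs(float(res.x[j])))
        if max(extreme) <= tol:
            blocked.append(rxn.id)
    return sorted(blocked)
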