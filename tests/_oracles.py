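"""Independent oracles used by the test suite.

These deliberately avoid the library's own solution paths: the LP optimum
is cross-checked by exhaustive vertex enumeration of the flux polytope,
GPR logic by Python boolean evaluation of the rule string, the iMAT MILP
by brute force over indicator assignments, and FBA/blocked-reaction calls
by cobrapy where a conversion is cheap.
"""

from __future__ import annotations

import itertools

import numpy as np

from seraflux.model import Gpr, MetabolicModel


def enumerate_vertices(S: np.ndarray, bounds: list[tuple[float, float]]):
    """All vertices of {v : S v = 0, lb <= v <= ub} for tiny networks.

    A vertex fixes at least n - rank(S) variables at a bound; the rest are
    solved from the balance equations.  Candidates failing the balance or
    the bounds are discarded.
    """
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank
    vertices = []
    for fixed in itertools.combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        choices = [(bounds[j][0], bounds[j][1]) for j in fixed]
        for vals in itertools.product(*choices):
            v = np.zeros(n)
            for j, val in zip(fixed, vals):
                v[j] = val
            if free:
                A = S[:, free]
                b = -S[:, list(fixed)] @ np.asarray(vals) if fixed else np.zeros(S.shape[0])
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[np.asarray(free, dtype=int)] = sol
            if S.size and np.max(np.abs(S @ v)) > 1e-7:
                continue
            if all(bounds[j][0] - 1e-8 <= v[j] <= bounds[j][1] + 1e-8 for j in range(n)):
                vertices.append(v)
    return vertices


def lp_optimum_by_enumeration(model: MetabolicModel, objective_id: str) -> float:
    S, _ = model.stoichiometric_matrix()
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    obj_j = [j for j, r in enumerate(model.reactions) if r.id == objective_id][0]
    vertices = enumerate_vertices(S, bounds)
    assert vertices, "flux polytope unexpectedly empty"
    return max(v[obj_j] for v in vertices)


def gpr_eval_oracle(rule: Gpr, deleted: set[str]) -> bool:
    """Evaluate functionality by Python `and`/`or` on the rule string."""
    env = {g: (g not in deleted) for g in rule.genes()}
    return bool(eval(rule.to_string(), {"__builtins__": {}}, env))


def gpr_state_oracle(rule: Gpr, states: dict[str, int]) -> int:
    """Exhaustive min/max recursion, written independently of the library."""
    if rule.op == "gene":
        return states.get(rule.gene, 0)
    vals = [gpr_state_oracle(c, states) for c in rule.children]
    return min(vals) if rule.op == "and" else max(vals)


def random_gpr_tree(rng: np.random.Generator, max_leaves: int = 8) -> Gpr:
    """Random flattened AND/OR tree over genes a0, a1, ... (<= max_leaves)."""
    n = int(rng.integers(2, max_leaves + 1))
    nodes: list[Gpr] = [Gpr.gene_(f"a{i}") for i in range(n)]
    while len(nodes) > 1:
        op = "and" if rng.random() < 0.5 else "or"
        k = int(rng.integers(2, min(4, len(nodes)) + 1))
        idx = sorted(rng.choice(len(nodes), size=k, replace=False))
        group = [nodes[i] for i in idx]
        rest = [nodes[i] for i in range(len(nodes)) if i not in set(idx)]
        # flatten same-op children so to_string round-trips structurally
        flat: list[Gpr] = []
        for g in group:
            if g.op == op:
                flat.extend(g.children)
            else:
                flat.append(g)
        nodes = rest + [Gpr(op, children=tuple(flat))]
    return nodes[0]


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (boundary metabolites dropped: cobra
    treats exchanges as open-ended)."""
    import cobra

    from seraflux.model import Compartment

    cm = cobra.Model(model.id)
    comp_code = {
        Compartment.INTRACELLULAR: "c",
        Compartment.EXTRACELLULAR: "e",
    }
    mets = {}
    for met in model.metabolites:
        if met.compartment is Compartment.BOUNDARY:
            continue
        mets[met.id] = cobra.Metabolite(met.id, compartment=comp_code[met.compartment])
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound, cr.upper_bound = rxn.lower_bound, rxn.upper_bound
        cm.add_reactions([cr])
        cr.add_metabolites(
            {mets[mid]: c for mid, c in rxn.stoichiometry.items() if mid in mets}
        )
    cm.objective = model.objective_reaction_id
    return cm


def imat_brute_force(problem) -> int:
    """Maximum iMAT agreement by enumerating indicator assignments.

    For every subset of satisfied indicators, impose the implied flux
    constraints and test LP feasibility directly.
    """
    from scipy.optimize import linprog

    m = problem.model
    S, _ = m.stoichiometric_matrix()
    rxn_index = {r.id: j for j, r in enumerate(m.reactions)}
    eps = problem.epsilon
    high, low = problem.high_reactions, problem.low_reactions
    best = 0
    # each high reaction: 0 = no reward, 1 = forward >= eps, 2 = backward <= -eps
    for h_assign in itertools.product((0, 1, 2), repeat=len(high)):
        for l_assign in itertools.product((0, 1), repeat=len(low)):
            score = sum(1 for a in h_assign if a) + sum(l_assign)
            if score <= best:
                continue
            bounds = [[r.lower_bound, r.upper_bound] for r in m.reactions]
            for rid, a in zip(high, h_assign):
                j = rxn_index[rid]
                if a == 1:
                    bounds[j][0] = max(bounds[j][0], eps)
                elif a == 2:
                    bounds[j][1] = min(bounds[j][1], -eps)
            for rid, a in zip(low, l_assign):
                j = rxn_index[rid]
                if a == 1:
                    bounds[j][0] = max(bounds[j][0], -eps)
                    bounds[j][1] = min(bounds[j][1], eps)
            if any(lo > hi for lo, hi in bounds):
                continue
            res = linprog(
                np.zeros(len(bounds)),
                A_eq=S,
                b_eq=np.zeros(S.shape[0]),
                bounds=bounds,
                method="highs",
            )
            if res.status == 0:
                best = score
    return best
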