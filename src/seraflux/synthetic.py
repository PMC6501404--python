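"""Synthetic models and expression tables with known ground truth.

Every pipeline stage (parsing, FBA/FVA, GPR logic, essentiality scanning,
expression integration) is exercised against generated fixtures whose
correct answers are known by construction:

* a fixed "core" toy model shaped like central carbon metabolism
  (glycolysis, pentose phosphate, TCA, fermentation outlets, a biomass
  drain) with a hand-computable optimum and a known essential-gene set;
* random networks (chain / diamond / random topologies) whose essential
  genes are recomputed at generation time by an independent brute-force
  deletion loop (string-eval GPR logic + a direct LP), and stored as
  ground truth;
* RPKM tables drawn from a heavy-tailed log-normal with planted exact
  zeros and planted high genes, calibrated so roughly 10% of genes fall
  below the lower cutoff of 3.00.

All randomness flows through :func:`numpy.random.default_rng` (PCG64) so
a fixed seed reproduces byte-identical model files on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .expression import ExpressionTable
from .model import Compartment, Gpr, MetabolicModel, Metabolite, Reaction

__all__ = [
    "SyntheticSpec",
    "make_toy_core_model",
    "make_random_model",
    "make_expression_table",
    "make_core_expression_profiles",
    "TOY_CORE_OPTIMUM",
    "TOY_CORE_OPTIMUM_NO_TCA",
]

#: Analytic biomass optimum of the core toy at glucose uptake 10.  Per unit
#: biomass the drain takes 1 pyruvate + 1 ribose-5P + 1 alanine + 1
#: oxaloacetate + 1 energy unit.  With the TCA loop (2 energy per pyruvate
#: turn) the pyruvate demand is 1 (drain) + 1 (alanine) + 1 (oxaloacetate
#: via carboxylation) + 0.5 (energy) = 3.5 Z; the ribose demand routes Z
#: glucose through the pentose branch and glycolysis supplies 2 pyruvate
#: per remaining glucose, so Z + 1.75 Z = 10 and Z = 40/11.
TOY_CORE_OPTIMUM = float(Fraction(40, 11))
#: With the TCA branch silenced the energy unit costs a full pyruvate
#: (acetate kinase route): demand 4 Z, so Z + 2 Z = 10 and Z = 10/3.
TOY_CORE_OPTIMUM_NO_TCA = float(Fraction(10, 3))


@dataclass
class SyntheticSpec:
    seed: int = 0
    n_reactions: int = 12
    topology: str = "random"  # chain | diamond | random
    #: log-normal parameters for the per-gene RPKM baseline; heavy-tailed,
    #: spanning 0 to well above 10^3 (~11% of mass above 850.56)
    rpkm_mu: float = 4.34
    rpkm_sigma: float = 2.0
    #: fraction of genes unexpressed (exactly zero) in every condition
    fraction_zero: float = 0.05
    #: total fraction of genes planted below the lower cutoff of 3.00 in all
    #: conditions (zeros included)
    target_low_fraction: float = 0.10
    #: per-condition multiplicative log-normal noise around the baseline;
    #: conditions are correlated through the shared baseline, as real RPKM
    #: tables are
    condition_sigma: float = 0.15
    conditions: tuple[str, ...] = ("glucose", "glcnac", "glycerol")

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_zero < 1:
            raise ValueError("fraction_zero must be in [0, 1)")


# ---------------------------------------------------------------------------
# fixed core toy
# ---------------------------------------------------------------------------
def make_toy_core_model(seed: int = 0) -> MetabolicModel:
    """Central-carbon-like toy model with known optimum and essentials.

    Glucose (uptake bound 10) enters by a PTS transporter, splits between
    glycolysis (2 pyruvate per hexose) and an oxidative pentose branch
    (ribose-5P + CO2), feeds a TCA loop producing 2 energy units per
    pyruvate, fermentation outlets (acetate — which also yields 1 energy —
    ethanol, lactate, formate, 2,3-butanediol), an alanine branch, and a
    biomass drain consuming pyruvate + ribose-5P + alanine + oxaloacetate
    + energy.

    Ground truth is stored under ``model.annotations``: the optimum 40/11,
    the essential genes {gALT, gGND, gPTS, gPYC, gZWF}, and the TCA /
    pentose branch reaction sets.  ``seed`` is accepted for interface
    symmetry; the topology is fixed.
    """
    del seed  # deterministic topology
    m = MetabolicModel(id="toy_core")

    def rxn(rid, stoich, lb, ub, subsystem, rule=None, name=""):
        m.add_reaction(
            Reaction(rid, stoich, lb, ub, subsystem=subsystem, name=name, gpr=rule)
        )

    G = Gpr.gene_
    # exchanges (X_e <=> X_b: negative flux = uptake)
    rxn("EX_glc", {"glc_e": -1, "glc_b": 1}, -10, 1000, "Exchange")
    rxn("EX_co2", {"co2_e": -1, "co2_b": 1}, 0, 1000, "Exchange")
    rxn("EX_ac", {"ac_e": -1, "ac_b": 1}, 0, 1000, "Exchange")
    rxn("EX_etoh", {"etoh_e": -1, "etoh_b": 1}, 0, 1000, "Exchange")
    rxn("EX_btd", {"btd_e": -1, "btd_b": 1}, 0, 1000, "Exchange")
    rxn("EX_lac", {"lac_e": -1, "lac_b": 1}, 0, 1000, "Exchange")
    rxn("EX_for", {"for_e": -1, "for_b": 1}, 0, 1000, "Exchange")
    # transport
    rxn("GLCpts", {"glc_e": -1, "g6p_c": 1}, 0, 1000, "Transportation", G("gPTS"))
    rxn("CO2t", {"co2_c": -1, "co2_e": 1}, -1000, 1000, "Transportation")
    # glycolysis
    rxn("PGI", {"g6p_c": -1, "f6p_c": 1}, -1000, 1000,
        "Glycolysis / Gluconeogenesis", G("gPGI"))
    rxn("PFK", {"f6p_c": -1, "pyr_c": 2}, 0, 1000,
        "Glycolysis / Gluconeogenesis", Gpr.or_(G("gPFK1"), G("gPFK2")))
    # pentose phosphate branch
    rxn("G6PDH", {"g6p_c": -1, "r5p_c": 1, "co2_c": 1}, 0, 1000,
        "Pentose phosphate pathway", Gpr.and_(G("gZWF"), G("gGND")))
    rxn("RPI", {"r5p_c": -1, "f6p_c": 1}, 0, 1000,
        "Pentose phosphate pathway", G("gRPI"))
    # TCA loop (oxaloacetate is catalytic; 2 energy units per pyruvate)
    rxn("PYC", {"pyr_c": -1, "co2_c": -1, "oaa_c": 1}, 0, 1000,
        "Pyruvate metabolism", G("gPYC"))
    rxn("CS", {"pyr_c": -1, "oaa_c": -1, "cit_c": 1}, 0, 1000,
        "Citrate cycle (TCA cycle)", G("gCS"))
    rxn("ICDH", {"cit_c": -1, "akg_c": 1, "co2_c": 1}, 0, 1000,
        "Citrate cycle (TCA cycle)", G("gICD"))
    rxn("AKGDH", {"akg_c": -1, "oaa_c": 1, "nrg_c": 2}, 0, 1000,
        "Citrate cycle (TCA cycle)", G("gSDH"))
    # fermentation outlets
    rxn("ACK", {"pyr_c": -1, "ac_e": 1, "nrg_c": 1}, 0, 1000,
        "Pyruvate metabolism", G("gACK"))
    rxn("ADH", {"pyr_c": -1, "etoh_e": 1}, 0, 1000,
        "Pyruvate metabolism", Gpr.or_(G("gADH1"), G("gADH2")))
    rxn("LDH", {"pyr_c": -1, "lac_e": 1}, 0, 1000, "Pyruvate metabolism", G("gLDH"))
    rxn("PFL", {"pyr_c": -1, "for_e": 1}, 0, 1000, "Pyruvate metabolism", G("gPFL"))
    rxn("BDH", {"pyr_c": -2, "btd_e": 1}, 0, 1000, "Butanoate metabolism", G("gBDH"))
    # amino acid branch
    rxn("ALT", {"pyr_c": -1, "ala_c": 1}, 0, 1000,
        "Alanine, aspartate and glutamate metabolism", G("gALT"))
    # energy dissipation (free sink, carries no flux at optimum)
    rxn("NRGD", {"nrg_c": -1}, 0, 1000, "Oxidative phosphorylation")
    # biomass drain (oxaloacetate demand keeps the carboxylation branch live)
    rxn("BIOMASS", {"pyr_c": -1, "r5p_c": -1, "ala_c": -1, "oaa_c": -1, "nrg_c": -1},
        0, 1000, "Biomass")
    m.objective_reaction_id = "BIOMASS"
    m.validate()
    m.annotations.update(
        {
            "optimum": TOY_CORE_OPTIMUM,
            "optimum_no_tca": TOY_CORE_OPTIMUM_NO_TCA,
            "essential_genes": ["gALT", "gGND", "gPTS", "gPYC", "gZWF"],
            "tca_reactions": ["CS", "ICDH", "AKGDH"],
            "ppp_reactions": ["G6PDH", "RPI"],
            "citrate_synthase_gene": "gCS",
            "carbon_uptake": 10.0,
        }
    )
    return m


# ---------------------------------------------------------------------------
# independent ground-truth oracle (kept apart from the scanned code paths)
# ---------------------------------------------------------------------------
def _oracle_rule_functional(rule: Gpr, deleted: set[str]) -> bool:
    """Evaluate a GPR by Python boolean eval of its string form."""
    expr = rule.to_string()
    env = {g: (g not in deleted) for g in rule.genes()}
    # gene ids are valid identifiers in generated models
    return bool(eval(expr, {"__builtins__": {}}, env))  # noqa: S307


def _oracle_max_growth(model: MetabolicModel, deleted: set[str]) -> float:
    S, _ = model.stoichiometric_matrix()
    n = len(model.reactions)
    bounds = []
    for r in model.reactions:
        if r.gpr is not None and not _oracle_rule_functional(r.gpr, deleted):
            bounds.append((0.0, 0.0))
        else:
            bounds.append((r.lower_bound, r.upper_bound))
    c = np.zeros(n)
    obj_j = [j for j, r in enumerate(model.reactions) if r.id == model.objective_reaction_id][0]
    c[obj_j] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status != 0:
        return 0.0
    return float(res.x[obj_j])


def _oracle_essentials(model: MetabolicModel, tol: float = 1e-6) -> list[str]:
    return sorted(
        g for g in model.genes if _oracle_max_growth(model, {g}) < tol
    )


# ---------------------------------------------------------------------------
# random models
# ---------------------------------------------------------------------------
def _chain_model(length: int, model_id: str) -> MetabolicModel:
    m = MetabolicModel(id=model_id)
    m.add_metabolite(Metabolite("s_b", Compartment.BOUNDARY))
    m.add_metabolite(Metabolite("s_e", Compartment.EXTRACELLULAR))
    m.add_reaction(Reaction("EX_s", {"s_e": -1, "s_b": 1}, -10, 1000, subsystem="Exchange"))
    m.add_reaction(
        Reaction("T_s", {"s_e": -1, "c1_c": 1}, 0, 1000,
                 subsystem="Transportation", gpr=Gpr.gene_("gT"))
    )
    for i in range(1, length + 1):
        m.add_reaction(
            Reaction(
                f"R{i}",
                {f"c{i}_c": -1, f"c{i + 1}_c": 1},
                0,
                1000,
                subsystem="Chain",
                gpr=Gpr.gene_(f"g{i}"),
            )
        )
    m.add_reaction(
        Reaction("BIOMASS", {f"c{length + 1}_c": -1}, 0, 1000, subsystem="Biomass")
    )
    m.objective_reaction_id = "BIOMASS"
    return m


def make_random_model(spec: SyntheticSpec, max_retries: int = 20) -> MetabolicModel:
    """Random feasible network with ground-truth essential genes.

    Topologies: ``chain`` (every gene on the sole path is essential),
    ``diamond`` (two equivalent branches; branch genes are non-essential),
    ``random`` (a chain backbone plus random shortcut and parallel
    reactions with single-gene, isozyme-OR, or complex-AND rules).  The
    essential set is recomputed at generation time by exhaustive deletion
    with an independent LP and stored under
    ``annotations["essential_genes"]``.
    """
    rng = np.random.default_rng(spec.seed)
    for attempt in range(max_retries):
        m = _build_topology(spec, rng)
        m.validate()
        if _oracle_max_growth(m, set()) > 1e-6:
            m.annotations["essential_genes"] = _oracle_essentials(m)
            m.annotations["topology"] = spec.topology
            m.annotations["seed"] = spec.seed
            return m
    raise RuntimeError(
        f"could not draw a feasible {spec.topology!r} model in {max_retries} tries"
    )


def _build_topology(spec: SyntheticSpec, rng: np.random.Generator) -> MetabolicModel:
    if spec.topology == "chain":
        length = max(1, spec.n_reactions - 3)
        return _chain_model(length, f"chain_{spec.seed}")
    if spec.topology == "diamond":
        m = MetabolicModel(id=f"diamond_{spec.seed}")
        m.add_metabolite(Metabolite("s_b", Compartment.BOUNDARY))
        m.add_metabolite(Metabolite("s_e", Compartment.EXTRACELLULAR))
        m.add_reaction(Reaction("EX_s", {"s_e": -1, "s_b": 1}, -10, 1000, subsystem="Exchange"))
        m.add_reaction(Reaction("T_s", {"s_e": -1, "u_c": 1}, 0, 1000,
                                subsystem="Transportation", gpr=Gpr.gene_("gT")))
        m.add_reaction(Reaction("RA1", {"u_c": -1, "a_c": 1}, 0, 1000,
                                subsystem="BranchA", gpr=Gpr.gene_("gA1")))
        m.add_reaction(Reaction("RA2", {"a_c": -1, "w_c": 1}, 0, 1000,
                                subsystem="BranchA", gpr=Gpr.gene_("gA2")))
        m.add_reaction(Reaction("RB1", {"u_c": -1, "b_c": 1}, 0, 1000,
                                subsystem="BranchB", gpr=Gpr.gene_("gB1")))
        m.add_reaction(Reaction("RB2", {"b_c": -1, "w_c": 1}, 0, 1000,
                                subsystem="BranchB", gpr=Gpr.gene_("gB2")))
        m.add_reaction(Reaction("BIOMASS", {"w_c": -1}, 0, 1000, subsystem="Biomass"))
        m.objective_reaction_id = "BIOMASS"
        return m
    if spec.topology != "random":
        raise ValueError(f"unknown topology {spec.topology!r}")

    backbone_len = max(3, spec.n_reactions // 2)
    m = _chain_model(backbone_len, f"random_{spec.seed}")
    n_extra = max(0, spec.n_reactions - (backbone_len + 3))
    gene_counter = backbone_len
    for k in range(n_extra):
        kind = rng.choice(["shortcut", "parallel"])
        gene_counter += 1
        kind_roll = rng.random()
        if kind_roll < 0.5:
            rule = Gpr.gene_(f"x{gene_counter}")
        elif kind_roll < 0.8:
            rule = Gpr.or_(Gpr.gene_(f"x{gene_counter}a"), Gpr.gene_(f"x{gene_counter}b"))
        else:
            rule = Gpr.and_(Gpr.gene_(f"x{gene_counter}a"), Gpr.gene_(f"x{gene_counter}b"))
        if kind == "parallel":
            i = int(rng.integers(1, backbone_len + 1))
            stoich = {f"c{i}_c": -1.0, f"c{i + 1}_c": 1.0}
        else:
            i, j = sorted(rng.choice(np.arange(1, backbone_len + 2), 2, replace=False))
            if i == j:
                continue
            stoich = {f"c{i}_c": -1.0, f"c{j}_c": 1.0}
        m.add_reaction(
            Reaction(f"E{k}", stoich, 0, 1000, subsystem="Extra", gpr=rule)
        )
    return m


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------
def make_expression_table(
    model: MetabolicModel | list[str],
    spec: SyntheticSpec,
    high_genes: dict[str, dict[str, float]] | None = None,
    low_genes: dict[str, dict[str, float]] | None = None,
) -> ExpressionTable:
    """Log-normal RPKM table over the model's genes, one column per condition.

    A ``fraction_zero`` share of genes is set to exactly zero per condition
    (unexpressed), and ``high_genes`` / ``low_genes`` plant per-condition
    values to drive known clamp outcomes, e.g.
    ``high_genes={"glcnac": {"gNAG": 967.2}}``.  ``model`` may also be a
    plain list of gene ids.
    """
    genes = model.genes if isinstance(model, MetabolicModel) else list(model)
    if not genes:
        raise ValueError("model has no genes to build an expression table for")
    n = len(genes)
    rng = np.random.default_rng(spec.seed)
    # shared per-gene baseline: a planted low decile (zeros plus uniform
    # values comfortably below 3.00) and a heavy-tailed bulk kept above the
    # lower cutoff, so "excluded across all conditions" hits the target
    n_low = int(round(spec.target_low_fraction * n))
    n_zero = min(n_low, int(round(spec.fraction_zero * n)))
    order = rng.permutation(n)
    zero_idx = order[:n_zero]
    dim_idx = order[n_zero:n_low]
    baseline = rng.lognormal(mean=spec.rpkm_mu, sigma=spec.rpkm_sigma, size=n)
    baseline = np.maximum(baseline, 4.0)
    baseline[dim_idx] = rng.uniform(0.5, 2.5, size=len(dim_idx))
    baseline[zero_idx] = 0.0
    columns = {}
    for k, cond in enumerate(spec.conditions):
        cond_rng = np.random.default_rng([spec.seed, k + 1])
        noise = cond_rng.lognormal(mean=0.0, sigma=spec.condition_sigma, size=n)
        noise[dim_idx] = cond_rng.uniform(0.85, 1.15, size=len(dim_idx))
        col = pd.Series(baseline * noise, index=genes)
        for gene, value in (high_genes or {}).get(cond, {}).items():
            col[gene] = value
        for gene, value in (low_genes or {}).get(cond, {}).items():
            col[gene] = value
        columns[cond] = col
    return ExpressionTable(pd.DataFrame(columns, index=genes))


def make_core_expression_profiles(seed: int = 0) -> ExpressionTable:
    """Condition profiles for the core toy mirroring the study's qualitative
    contrast: on the GlcNAc-like condition the citrate-synthase-analog gene
    is unexpressed (silencing the TCA branch) while the pentose branch genes
    are highly expressed; the glucose-like condition leaves every gene in
    the moderate band."""
    model = make_toy_core_model()
    spec = SyntheticSpec(seed=seed, conditions=("glucose", "glcnac", "glycerol"),
                         fraction_zero=0.0, rpkm_mu=3.5, rpkm_sigma=0.8)
    table = make_expression_table(
        model,
        spec,
        high_genes={"glcnac": {"gZWF": 1200.0, "gGND": 1100.0}},
        low_genes={"glcnac": {"gCS": 0.0}},
    )
    # keep the un-planted entries in the moderate band so clamp outcomes are
    # driven solely by the planted genes
    data = table.data.clip(lower=3.5, upper=800.0)
    for cond, planted in (("glcnac", {"gZWF": 1200.0, "gGND": 1100.0, "gCS": 0.0}),):
        for g, v in planted.items():
            data.at[g, cond] = v
    return ExpressionTable(data)
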