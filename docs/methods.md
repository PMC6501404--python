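# Methods

## Flux balance analysis

The steady-state flux space is `{v : S v = 0, a <= v <= b}` with one
balance row per non-boundary metabolite.  Boundary metabolites are the
open ends of the system: they terminate exchange reactions and carry no
balance row.  This matches the three-class metabolite accounting
(intracellular / extracellular / boundary) used by the model files.

LPs are solved with HiGHS through `scipy.optimize.linprog` at a primal
feasibility tolerance of 1e-9; fluxes below 1e-6 are reported as zero.
Both tolerances are module constants and can be overridden per call where
a function takes a `tol` argument.

**Degeneracy.** FBA optima are almost always degenerate.  All reported
flux vectors therefore come from a two-phase solve: phase one maximises
the objective `Z`, phase two fixes `Z` and minimises the total absolute
flux (each `|v_i|` bounded by an auxiliary variable).  This parsimonious
representative makes downstream counts — which reactions are "active"
under a condition — reproducible, at the cost of being one defensible
choice among the alternate optima.  Active-reaction counts derived from
any other optimum can legitimately differ; the reporting function
documents this and the per-subsystem table makes residuals visible rather
than hiding them in a total.

**FVA** minimises and maximises each flux with `Z >= fraction * Z*`; the
default fraction is 1.0 (ranges at the constrained optimum).  Infeasible
constraint sets are reported as a status, never silently relaxed: an
over-tight measurement window surfaces at solve time.

**Media.** A medium is a map from extracellular species to maximal uptake
rates.  Applying it closes the uptake direction of every exchange reaction
and reopens only the listed components.  The packaged minimal-medium
fixture contains water, ammonia, sulfate, phosphate, calcium, iron (token
`fe3`, kept as printed in the source description even though the prose
says "ferrous"), hydrogen sulfide, potassium, magnesium, pantothenate and
nicotinate D-ribonucleotide, plus one carbon source; the glucose uptake
default is the measured batch value 10.53 mmol/gDW/h.

**Gap detection** is limited to diagnosis: dead-end metabolites (only
produced or only consumed, reversibility considered) and blocked reactions
(FVA range {0} with all exchanges opened to ±1000).  Gap *filling* is out
of scope.

## Essentiality

A single-gene deletion evaluates every reaction's GPR with the gene
removed (AND = all subunits required, OR = any isozyme suffices), closes
the failed reactions to [0, 0] on a copy, and re-maximises biomass.  The
"zero growth" call uses an absolute threshold of 1e-6 on the knockout
optimum — the biological criterion is literally zero, but LP numerics
require a tolerance; the report also carries the knockout/wild-type ratio
so callers can apply their own.  On networks with integral yields the
calls are identical for thresholds anywhere in [1e-9, 1e-4].

Scans iterate genes in sorted order; each deletion starts from the same
wild-type constraint set, so results are order-independent and the model
is never left mutated.  A non-growing wild type aborts the scan with a
diagnostic rather than producing 100% "essential" calls.

For the vulnerable-subsystem rollup, a gene is linked to every subsystem
containing a reaction that cites it, and an essential gene counts toward
every subsystem containing a reaction it disables.  This multi-attribution
is a documented choice (recorded in the output metadata): genes guarding
reactions in several pathways inflate no single pathway, but percentages
across subsystems then need not average exactly to the global essential
fraction except when gene-to-subsystem assignment is a partition.

## Expression integration

Gene states are {-1, 0, 1} under two thresholds on the RPKM scale:
`g < γ_low` is low/absent (an unexpressed gene, g = 0, is always −1),
`γ_low <= g <= γ_high` moderate (boundary values inclusive to moderate),
`g > γ_high` high.  The one-threshold formulation (0 for `0 < g <= γ`,
1 above) is the special case with the lower threshold at zero; the
two-threshold form is what the condition-comparison procedure actually
uses, so it is the implementation.

The thresholds sit on a geometric grid `1.2^k, k = 0..57`.  `γ_low`
defaults to 3.00, the grid value selected so that roughly 10% of genes
fall below it in **all** conditions jointly (the selection routine
implements exactly this rule and reports the achieved fraction).
`γ_high` defaults to 850.56, which is grid point 1.2^37; no selection rule
for the upper threshold is implemented because none is defined — it is a
configurable default, not a computed quantity.

States reach reactions through the GPRs with AND = min and OR = max —
the standard isozyme/complex convention: a complex is only as available
as its scarcest subunit, and the best-expressed isozyme carries the
reaction.  Two constraint modes are exposed:

* **clamp** (default): state −1 reactions get bounds [0, 0]; state 1
  reactions get their flux capacity extended to magnitude 1000 (upper
  bound 1000, lower bound −1000 only if the reaction was reversible).
  "Constrained to 1000" is read as capacity extension, not forced flux —
  a bound can permit but never compel.  The biomass reaction is never
  clamped; a low state there only triggers a warning.
* **imat**: a mixed-integer LP in which binary indicators certify
  `|v_i| >= ε` for each high reaction (split into forward/backward
  indicators, at most one rewarded) and `|v_i| <= ε` for each low
  reaction, maximising total agreement.  ε defaults to 1.0 (configurable).
  The MILP is solved with HiGHS via `scipy.optimize.milp` with a fixed
  variable ordering, so solves are deterministic.

Active-reaction tables count reactions with `|v| > 1e-6` in the
flux-minimised optimum, grouped by subsystem label; exchange
pseudo-reactions and the biomass drain are excluded so the total covers
metabolic and transport reactions.

## Synthetic data

The generators exist so that every claim the pipeline makes can be tested
against an answer known by construction, without the published
genome-scale files.

**Core toy** (25 reactions, 18 genes): a central-carbon cartoon with a PTS
transporter, lumped glycolysis (2 pyruvate per hexose), an oxidative
pentose branch guarded by a two-subunit complex, a TCA loop with catalytic
oxaloacetate yielding 2 energy units per pyruvate, fermentation outlets
(acetate also yields 1 energy unit; ethanol, lactate, formate,
2,3-butanediol), an alanine branch, and a biomass drain consuming
pyruvate + ribose-5P + alanine + oxaloacetate + energy.  The optimum at
glucose uptake 10 is analytic: pyruvate demand 3.5 Z with the TCA route
(Z = 40/11) and 4 Z without it (Z = 10/3), so silencing the
citrate-synthase analog reroutes rather than kills.  The oxaloacetate
demand in biomass is deliberate: it keeps the anaplerotic carboxylation
unblocked (an earlier draft without it had a structurally blocked
reaction, caught by the package's own gap detector).  Subsystem labels use
standard pathway-category names so rollup outputs read like the
genome-scale tables.

**Random models**: chain (every path gene essential by the cut-vertex
argument), diamond (branch genes non-essential), and random (a chain
backbone plus shortcut/parallel reactions carrying single-gene, OR or AND
rules).  Feasibility is checked at generation; infeasible draws resample
up to a retry cap.  The planted essential set is recomputed at generation
time by an *independent* brute-force loop — GPR evaluation by Python
boolean `eval` of the rule string and a directly assembled LP — so the
scan under test shares no code path with its oracle.

**RPKM tables**: each gene gets a shared baseline across conditions — a
planted low decile (5% exact zeros plus values uniform in [0.5, 2.5]) and
a heavy-tailed log-normal bulk (μ = 4.34, σ = 2.0 on the log scale,
floored at 4.0) spanning 0 to well above 10³ — times mild per-condition
log-normal noise (σ = 0.15).  The shared baseline is what makes "excluded
in all conditions" come out at the planted 10%, as it does in real RPKM
tables where conditions are strongly correlated; the defaults put ≈11% of
genes above the 850.56 cutoff.  All draws use `numpy.random.default_rng`
(PCG64), so a fixed seed reproduces byte-identical files.

What the generators do **not** emulate: genome-scale topology statistics
(hub metabolites, cofactor coupling, compartment transport chains),
mass/charge balance, and the long right tail of GPR complexity.  Passing
tests on these fixtures therefore certify the algorithms — parsing,
LP/MILP construction, boolean logic, accounting — not numerical agreement
with any particular genome-scale reconstruction, which additionally
depends on the exact model content and on alternate-optimum handling.

## Problem sizes

The shipped analyses and tests use toys of 5–25 reactions, random panels
of up to 30 models (≈14 reactions each), and synthetic expression tables
of up to 5000 genes; these sizes make every oracle (vertex enumeration,
truth tables, brute-force MILP, exhaustive deletion) exact while keeping
the full suite fast on a single CPU.  The solvers themselves are generic:
nothing in the implementation assumes small models.

## Known limitations

* Active-reaction counts inherit the parsimonious-optimum convention;
  other tie-breaks (e.g. unclamped-by-state, all-optima intersection) are
  not implemented.
* No thermodynamic (loopless) constraints: spurious cycles are suppressed
  only by the flux-sum minimisation.
* The model dialect is the single source format; SBML/JSON interchange,
  reconstruction from annotation and mass balancing are non-goals.
* Fold-change reporting rounds to a configured number of decimals; ratios
  of printed-precision inputs can differ in the last digit from values
  quoted elsewhere.
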