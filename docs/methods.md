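# Methods

## Scope and model

glycodesign implements a three-stage pipeline for prospecting
substrate-to-product pathways in a KEGG-style reaction database:
stoichiometric design (mixed-integer linear programming), thermodynamic
screening (linear programming over log-concentrations), and protein-cost
estimation (convex minimization). The stages share one thermodynamic
convention: standard transformed Gibbs energies Δ_r G'° at pH 7, 25 °C,
ionic strength 0.1 M. Water activity is fixed at 1 and protons are absorbed
into the transformed energies, so H2O and H+ never enter reaction quotients
or concentration variables; protons are stripped from reaction
stoichiometries at load time and the proton term of the design reaction is
kept only for bookkeeping. Elemental balance is enforced exactly for C, N,
O, P and S; hydrogen may drift by the protons implied by this convention.
Reactions that fail the balance check or carry symbolic ("generic")
coefficients are dropped at load time with a logged reason.

## Directionality

Each reaction's attainable Δ_r G' range is evaluated with all substrates at
0.1 M and all products at 1 µM, and vice versa (stoichiometric coefficients
as exponents; H2O/H+ excluded, all other species — cofactors included — in
the quotient). A reaction is forward-only if the whole range is negative,
reverse-only if positive, reversible otherwise or when Δ_r G'° is
undefined. Because this rule leaves essentially every ATP-coupled kinase
reversible (the ATP/ADP terms alone span ±57 kJ/mol), a manual override
table is applied afterwards; the bundled overrides pin the five kinases of
the mini database (hexokinase, ATP-PFK, pyruvate kinase, KDG kinase,
triokinase) forward-only, mirroring how curated databases treat these
steps. The classification is antisymmetric under reaction reversal by
construction.

## minFlux design and loop elimination

The design MILP minimizes Σ|v_j| over internal reactions subject to
S·v = 0, exchange fluxes fixed to the design stoichiometry q (glucose −1,
pyruvate +2, n ATP, 2 redox equivalents, water +n), and directionality
bounds. Implementation choices:

- **Fluxes are integer-valued by default** (glucose basis 1); a continuous
  mode exists behind a flag, where activity indicators use an ε of 10⁻³.
- |v_j| is linearized as v_j = v_f − v_b with v_f ≤ M·a_j and
  v_b ≤ M·(1−a_j) for a direction binary a_j and big-M = 1000
  (configurable).
- **Loop law.** Exchange columns are absent by construction (the database
  holds only internal reactions); rows of the declared cofactors (ATP, ADP,
  AMP, NAD(P)(H), Pi, PPi, H2O, H+, CO2, CoA, GTP, GDP by default) are
  removed to give S_red, whose null space is computed **exactly** with
  rational arithmetic (sympy; each basis row scaled to integers). For each
  basis row l the constraint Σ_j N_lj·G_j = 0 is imposed on pseudo-energy
  variables G_j confined to 1 ≤ |G_j| ≤ M with sign opposite to the flux
  direction. This forbids net flux around any closed loop whose net
  conversion involves only cofactors (futile ATP cycles, redox generators,
  water splitting) as well as fully internal cycles, so the ATP demanded by
  the design reaction must be produced on the carbon backbone. A
  floating-point null space is not acceptable here: the constraint must
  annihilate loops exactly, which is why the basis is rational.
- **Redox "either" mode** adds one integer variable z ∈ [0, 2] splitting
  the two redox equivalents between the NADH and NADPH couples with
  matching oxidized-form consumption.
- **Exchanges** exist only for design-reaction metabolites (fixed to q) and
  for CO2 (free); every other metabolite is strictly balanced. Water is
  fixed to +n like any other design metabolite; oxygen balance makes this
  consistent.
- **Enumeration** appends, after each solution with active set A, the
  integer cut Σ_{j∈A} y_j ≤ |A|−1 over activity binaries y_j
  (|v_j| ≤ M·y_j, v_f+v_b ≥ y_j; integer fluxes make ε-thresholds
  unnecessary) and re-solves until infeasible or a solution cap. Total
  internal flux is capped (default 30) so the enumeration is exhaustive
  *under that cap*; as with any cut of this form, strict supersets of an
  already-found active set are excluded too. Solutions are returned in
  non-decreasing total-flux order and re-validated post hoc: mass balance,
  design stoichiometry, bounds, and an auxiliary LP that maximizes
  direction-aligned circulation within the active set while forcing zero
  non-cofactor exchange — its optimum is zero exactly when no cofactor-only
  subnetwork survives. The MILP/LP solver is HiGHS via scipy, which is
  deterministic, so enumeration results are reproducible run to run.

## MDF

For a pathway with reactions oriented along their fluxes, maximize B
subject to −(Δ_r G'°_j + RT·Σ_i S_ij x_i) ≥ B, ln(lo_i) ≤ x_i ≤ ln(hi_i),
and linear ratio windows on cofactor pairs. Feasibility means B > 0, with a
10⁻⁹ kJ/mol tolerance for LP round-off. An infeasible *LP* (contradictory
bounds or ratio windows, including windows violated by pinned
concentrations) raises a distinct error; a negative B is a result, not an
error. Note one sign convention trap: the driving force is −Δ_r G', so
"large positive MDF" = strongly driven pathway; this package follows that
standard convention throughout.

Named concentration presets: (i) all metabolites 1 µM–100 mM;
(v) 1 µM–10 mM; (vi) preset (i) plus ATP/ADP ≥ 1. Presets (ii)–(iv) are
templates for experimentally measured per-metabolite and cofactor-ratio
windows and deliberately ship without numbers — they raise until the user
supplies values. In screening studies these conditions are applied
*progressively*: each tightening layers on the previous one, so the
realistic version of the tight box (v) also carries the above-unity ATP/ADP
window of (iv). The acceptance tests use that cumulative screen when they
assert that the bundled 3–5 ATP designs lose feasibility while EMP and ED
survive; inside a plain (v) box alone the high-yield fixtures retain a
marginal B of 0.4–1.7 kJ/mol by pushing ATP/ADP to ~10⁻⁴, which is exactly
the regime the ratio window excludes.

The ATP/ADP robustness scan pins ATP and ADP to each of 400 pairs (20×20
log-uniform over [1 µM, 100 mM]²; the grid shape is a choice — only the
pair count is canonical) and re-solves MDF (optionally ECM) per cell.

## ECM

Per-reaction enzyme demand factorizes as
baseline × (v_j/v_glc) × (1/η_rev) × (1/η_sat) with
η_rev = 1 − exp(Δ_r G'_j/RT) (from the separable reversible
Michaelis–Menten rate law combined with the Haldane relationship) and the
common-modular saturation term
η_sat = Π_s(c/K)^m / (Π_s(1+c/K)^m + Π_p(1+c/K)^m − 1). A "power"
(substrate-only) variant is selectable for sensitivity checks. Parameters:

- uniform K_M = 10⁻⁴ M (a typical Michaelis constant; the single biggest
  source of quantitative drift in absolute costs, so it is configurable);
- baseline 20 µg protein/(mmol Glc/h) per unit relative flux; totals
  reported in mg protein/mmol glucose/h at a reference uptake of
  1 mmol/gDW/h;
- cofactors participate in η_sat and the concentration variables like any
  other metabolite unless pinned; H2O/H+ excluded.

The total cost is convex in x. Minimization runs SLSQP from the MDF
optimum plus random interior restarts (default 8; restart points are pulled
toward the MDF optimum until the linear constraints Δ_r G'_j ≤ −10⁻³ kJ/mol
hold), objective tolerance 10⁻⁸; outside the feasible cone the objective
returns a steep finite penalty so iterates are driven back inside. Because
the problem is convex, restarts agree to ~10⁻⁴ relative — this is verified
on every bundled pathway — and gradients are taken numerically (problem
dimension ≤ ~20). MDF-infeasible inputs return a distinguished
infinite-cost result rather than an exception. An MDF-feasible pathway with
B near zero gets a finite but exploding cost (the 1/η_rev factor), which is
the mechanism behind the cost-vs-MDF anticorrelation.

## Pareto analysis

The front is the set of per-yield minimum-cost vertices over feasible
points, ordered by yield; no cost-monotonicity in yield is assumed. Ties
at a per-yield minimum all count as front members. Distance to the front is
measured along the cost axis at fixed yield (mg protein/mmol Glc/h) —
Euclidean distance in the mixed-unit yield/cost plane would be
dimensionally meaningless. The cost CDF is the usual right-continuous
empirical distribution.

## The bundled fixtures (what they emulate, what they do not)

The mini database (31 reactions, 33 metabolites) contains canonical EMP
(2 ATP, total flux 15) and ED (1 ATP) glycolysis, semi-phosphorylative ED,
an ED-like variant with NAD-dependent G6P dehydrogenase and the
Rapoport–Luebering bypass, a non-phosphorylated-upper 2-ATP design, and
3/4/5-ATP designs built on GAPN, PPi-PFK with PEP
carboxytransphosphorylase, and a transaldolase + sedoheptulose-bisphosphate
cycle. Reaction and compound identifiers are reconstructions from standard
KEGG glycolysis entries.

Its thermodynamic table is **synthetic**: one set of transformed formation
energies, anchored so that glucose + 2 NAD(P)+ → 2 pyruvate + 2 NAD(P)H is
−133.6 kJ/mol, ATP synthesis +26.4 kJ/mol, and the 2-PG kinase R02664
−22 kJ/mol (the midpoint of its −79…+35 kJ/mol attainable range), with the
remaining steps at literature-typical glycolysis values. Deriving every
reaction energy from one formation table makes pathway energy sums
telescope exactly to −133.6 + n·26.4, as estimator-derived data would.
What this does *not* reproduce: component-contribution uncertainty, the
exact published per-reaction values, and therefore absolute protein costs
or the precise EMP/ED cost gap — those depend on the unknown K_M and
rate-law variant as well. Qualitative orderings (ED cheaper than EMP, cost
exploding as B → 0, high-yield designs requiring ATP/ADP < 1) are robust to
these choices; absolute numbers are not.

The seeded random-network generator plants a linear carbon chain with one
ATP-coupled step plus a configurable fraction of reactions arranged in
closed cofactor-only cycles (each netting ADP + Pi → ATP + H2O), with
ground-truth cycle membership returned. It emulates the loop hazard of a
real database, not its chemistry: metabolites are featureless CH2O units.

## Problem sizes and runtimes

The default test suite and the acceptance script run on the mini database:
per-yield enumeration capped at 12 solutions under a flux cap of 30
(43 routes across n = 1..5), 20×20 ATP/ADP grids, 25–100 random networks of
10 metabolites × 12 reactions, ECM with 4–8 restarts (50 in the convexity
check). Grid-search oracles in the tests use ≤ 4 free metabolites with six
refinement rounds. The suite takes ~2.5 minutes and the acceptance script
~40 seconds on one CPU.

## Known limitations

- No compartmentation, pH/ionic-strength transforms, or Δ_r G'°
  uncertainty propagation; energies are point values.
- The loop law excludes *all* directed internal cycles after cofactor
  removal, including hypothetical productive ones; this is the intended
  conservative behavior for pathway design.
- Integer-cut enumeration excludes strict supersets of found active sets
  and is exhaustive only under the flux cap.
- ECM assumes uniform kinetics; reported costs are lower bounds on real
  enzyme demand and comparable only within one parameterization.
- The semantics of exchange are glucose-to-pyruvate specific in
  `build_design`; arbitrary designs are expressible through `DesignSpec`
  but only glycolytic ones are exercised by the fixtures.
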