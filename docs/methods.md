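# Methods

## Model and assumptions

The search operates on a single-compartment stoichiometric network. A
pathway is a set of reactions that (i) balances every metabolite at steady
state while an injected net-conversion reaction runs at fixed rate −1, and
(ii) admits a single metabolite concentration vector under which every
member reaction is thermodynamically favourable. Condition (ii) is the
second law applied with transformed standard Gibbs energies: reaction *i*
is usable at log-concentrations *x* iff ΔrG′ᵢ = RT·(g⁰ᵢ + Sᵀᵢx) ≤ 0. Water
and protons are excluded from the concentration term (and from the
packaged network altogether), following the transformed-energy convention;
consequently only C, N and P are checked for elemental balance.

Equality (ΔrG′ = 0) is accepted by default; a strict mode can require
ΔrG′ ≤ −1e−6 RT. Temperature defaults to 298.15 K and enters only through
RT.

## MILP formulation

Variables: one continuous rate v ∈ [0, β] and one binary indicator z per
directed reaction, one continuous x = ln c per non-exempt metabolite.
Reversible reactions are split into forward/backward copies with negated
stoichiometry and g⁰; irreversible reactions get a single forward copy
(splitting them too would change the model's semantics; a
`split_irreversible` flag restores the literal two-way split). The
objective reaction is exempt from splitting, from the flux cap and from the
indicator count; its fixed rate −1 enters the mass-balance right-hand side.

Constraint families:

- mass balance `S v = 0` per metabolite (v_obj = −1 folded into the RHS);
- flux/indicator coupling `v ≤ β z` with β = 10 — the cap on any single
  reaction's rate relative to the unit objective rate;
- minimum active flux `v ≥ ε z` with ε = 1e−3. This constraint is an
  addition to the textbook formulation: with integer cuts in play, a solver
  could otherwise escape a cut by switching on indicators of zero-flux
  reactions, returning the same pathway dressed up as a new solution.
  Coupling both ways pins the indicator vector to the flux support. ε is
  three orders of magnitude below the unit pathway flux, so it excludes no
  pathway of practical interest;
- second law `−g⁰ᵢ − (Sᵀx)ᵢ + Mᵢ(1 − zᵢ) ≥ 0`, with a per-reaction big-M
  computed from the box corners (Mᵢ = max(0, g⁰ᵢ + Σⱼ Sⱼᵢ bⱼ + 1), bⱼ the
  most adverse bound per metabolite). Per-reaction constants with a 1 RT
  margin keep the LP relaxation tight while guaranteeing the constraint is
  vacuous when zᵢ = 0;
- direction exclusivity `z_fwd + z_bwd ≤ 1`. Thermodynamics already forbids
  both directions being strictly favourable; the explicit constraint removes
  the ΔrG′ = 0 degenerate case and tightens the MILP;
- the integer-cut pool (below).

Objective: minimise Σ z. The default backend is HiGHS through
`scipy.optimize.milp` (single-threaded, deterministic); the backend
interface is pluggable.

## Enumeration

The loop is solve → record → cut. A cut around an active set A is

    Σ_{i∈A} (1 − zᵢ) + Σ_{i∉A} zᵢ ≥ r + 1,

which excludes every indicator vector within Hamming distance r of A; with
the default radius r = 2 each subsequent solution differs from every
recorded one in at least 3 positions ("within a radius of 2" is read as
distance ≤ 2 eliminated; the radius is configurable, so the weaker reading
is available too). Enumeration stops at 10 solutions per ATP yield, on
infeasibility ("exhausted"), or on a time limit. The ATP-yield scan runs
independently per n ∈ {−2 … +2} by default, each with its own objective
injection and cut pool.

Every recorded solution is re-verified by raw arithmetic (mass-balance
residual, flux bounds, indicator coupling, per-reaction driving force at
the returned x). A failing solution triggers one re-solve with presolve
disabled, then a typed failure status. Solutions are exposed as sets;
tie-breaking among equal-cardinality optima is solver-dependent, and all
shipped analyses are order-insensitive up to cardinality.

## Post-processing

Net ATP per pyruvate is the flux-weighted sum of ATP stoichiometric
coefficients over active reactions (objective reaction excluded), computed
with exact rational arithmetic on denominator-limited fluxes; for any valid
solution it reproduces the injected n, which doubles as a cross-check. ATP
accounting is by ATP coefficient, not AMP-equivalents: PEP synthase
(ATP → AMP) counts −1 ATP, with adenylate kinase closing the AMP balance.

Strategy classification is marker-based: a label applies iff all its
committing-enzyme reactions are active in either direction (EMP: PGM, ENO,
PYK; ED: EDA; methylglyoxal: MGSA; serine shunt: SDAA plus co-required
SERA, SERC, SERB). Solutions may carry several labels — mixed solutions
are genuine (e.g. split flux between lower EMP and the methylglyoxal
bypass at n = 0) — and strategy counting counts atomic labels, not
combinations.

Route segments are shortest paths in the bipartite metabolite–reaction
digraph of a solution's active set, with currency metabolites (ATP/ADP/AMP,
Pi, NAD(P)(H), quinones, glutathione, glutamate/2-ketoglutarate, NH3, CoA)
removed so paths follow the main carbon skeleton. Glutathione is a cofactor
for path finding, but the glyoxalase steps it carries remain main-carbon
steps because they consume methylglyoxal itself. A segment can be anchored
through a waypoint (`via`): the serine-shunt segment is defined as
3PG → pyruvate via serine, so a solution that also runs lower EMP cannot
short-circuit the segment through enolase. Variant counting treats two
segments as distinct iff their reaction-id sets differ; cofactor-swapped
routes (quinone- vs NAD-linked lactate oxidation) therefore count as
distinct variants.

## Packaged network and generators

The central-carbon network (36 metabolites, 32 reactions) contains the
glycerol entry (GLPK, GLPD), lower EMP, the ED route reached
gluconeogenically from triose phosphates (FBA, FBPASE, PGI, ZWF lumped with
the lactonase, EDD, EDA), the methylglyoxal bypass with all three
methylglyoxal → pyruvate branches (glutathione/glyoxalase with the
spontaneous hemithioacetal step lumped into MGGSH; direct isomerase HCHA;
GLDA–ALDA–LLDD via L-lactate), the serine shunt (SERA, SERC, SERB, SDAA),
and closure reactions (GLUDY, THD, NDH, QOX, ADK, PPSA) so cofactors
balance without any ATP-synthesizing respiration — ATP bookkeeping is
purely substrate-level. Packaged ΔrG′° values are curated stand-ins chosen
for their feasibility class (SERA strongly endergonic at +30 kJ/mol, PYK
and SDAA strongly exergonic, quinone oxidations very exergonic); analyses
and tests rely on feasibility classes, not exact values, so re-deriving
them from a component-contribution estimator should not change any result
class. Concentration bounds default to 1 μM – 10 mM for every metabolite; a
physiological override table for central cofactors ships with the package
but is opt-in, and the packaged-network analyses use the plain box.

Random planted networks contain a linear source → sink chain (g⁰ uniform in
[−5, −1] RT, always feasible in the default box) plus random irreversible
distractor reactions; a draw is accepted only if exhaustive search confirms
the chain is the unique minimum-cardinality feasible route, so recovery
tests have a known ground truth. The parallel-routes generator builds
metabolite-disjoint chains (pairwise indicator distance 2·length) to
exercise the stopping rule. The brute-force oracle tests subsets in order
of increasing cardinality with two LPs per subset (restricted flux balance;
concentration feasibility) and is guarded to ≤ 20 directed reactions.

These generators emulate network *structure* only: there is no noise model
(the analysis is deterministic), no compartments or transport, no
gene–protein–reaction rules and no biomass reaction. Passing tests
demonstrate correct enumeration and accounting on networks of this kind;
they do not validate ΔrG′° values or concentration ranges against
measurements.

## Problem sizes and numerics

Shipped analyses scan the packaged network at ATP yields {−1, 0, +1}
(~40 MILP solves, seconds on one CPU), run the oracle comparison on 50
planted networks with ≤ 12 directed reactions each, and use 12 parallel
routes for the stopping-rule experiment. Flux-support and constraint checks
use a 1e−6 tolerance (verification at 1e−5 to absorb solver slack);
rational ATP accounting limits flux denominators to 1e6. Infeasibility is a
typed status, never an exception.

## Known limitations

- ΔrG′° values are inputs; no on-line estimation, pH/ionic-strength
  adjustment, or max–min driving force optimisation (feasibility only).
- The 15 central-metabolite physiological concentration ranges are
  literature-typical defaults, not organism-calibrated measurements.
- Genome-scale runs are supported through the SBML/BiGG readers but are
  hours-scale MILP work and are not exercised by the shipped analyses.
- Integer cuts enumerate *supports*; flux-variability within a support and
  elementary-flux-mode decompositions are out of scope.
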