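# Methods

## Model

`viadapp` analyses the long-term governability of a social-ecological system
(SES) by coupling three layers:

1. **A compartment model of the coupled infrastructure system** (module
   `cisf_core`).  One ecological resource compartment *R* — represented by
   the vector of ecosystem-service (ES) potentials it can deliver, each in
   [0, 1] — interacts with three social role compartments: exploitation *E*,
   conservation *C* and policy-making *P*, whose states are relative
   capacities of action in [0, 1].  Interactions are parameterised by
   dimensionless annual action-rate weights `u0a…u7h`: self-loops for natural
   growth/decay, bilinear exploitation/management terms with conservation-side
   regulation and monitoring, support/sanction terms between roles, and
   external-settings terms (`u7*`), of which `u7b ∈ [−1, 0]` carries climatic
   stress on the resource.  Two structural contracts are enforced: every
   weight lies in its admissible interval, and the incoming weights of each
   social compartment sum to one
   (*E*: `u0b+u1b+u2b+u6b+u7d`, *P*: `u0c+u2a+u3b+u7f`,
   *C*: `u0d+u3a+u4a+u6a+u7h`).  The role equations couple to the resource
   vector through its mean ES level; this scalar reduction is a modelling
   choice, made once, that keeps every bilinear term inside [0, 1].
   Integration is fixed-step explicit Euler with a one-year step (matching
   the annual framing of the land-cover dynamics below); after each step the
   state is clamped back to its ranges — dynamics first, clamp second.  Step
   size is configurable.

   The resource-growth condition is exposed in two variants because its
   closed form and the assembled dynamics disagree: the `printed` variant
   evaluates `u0a + (u1a·u5a′ + u4b)·C ≥ |u7b| + u1b·u5a` (the stress rate
   enters by magnitude on the loss side, consistent with its declared sign
   convention), while the `derived` variant takes the sign of the per-unit
   resource derivative of the full dynamics.  Neither is silently preferred;
   the dynamics are authoritative for simulation.

2. **Nested governance arrangements** (module `governance`).  Adaptation
   actions are identified by multi-tier codes — a first-tier attribute
   category (S, RS, RU, GS, A, I, O), a bounded second-tier index, optional
   trigger/target roles and an institutional level (OCA, KCA, CCA, MCA) with
   an arrangement transition — with a round-tripping text grammar
   (`U_C->E:A2`, `U_OCA:1->2_C->E:A2`).  A nested arrangement `CCAi|KCAj` is
   a role mask (constitutional eligibility), a link mask over the CIS action
   sets (collective coordination structure) and an operational specification
   fixing chosen intensities of free rates.  Concrete weights are derived by
   zeroing masked links and proportionally renormalizing each active
   compartment's incoming weights back to sum 1.  Design choices here:

   * proportional renormalization preserves the sum-to-1 contract without
     inventing new rates (the alternative — leaving deficits — would make
     arrangements incomparable);
   * an inactive compartment is inert (capacity pinned at 0); its incoming
     budget is collapsed onto its self-loop so the normalization contract
     stays checkable uniformly;
   * the settings→policy inflow (`u7e`, `u7f`) is treated as incident to the
     conservation role as well, because the policy equation drives those
     terms with the conservation capacity;
   * OCA intensities are *chosen absolute rates* (not multipliers) and may
     only target weights outside the sum groups — this is what makes weight
     derivation idempotent.

3. **Viability analysis** (module `viability`).  The satisfactory domain
   `K_R` is a box of ES levels: services above their floors, disservices
   below their caps.  The finite-horizon viability kernel — the set of
   states from which *some* sequence of arrangements keeps the trajectory in
   `K_R` at every annual step — is computed by backward induction on a
   regular grid: a node is viable at decision epoch *k* iff it is in `K_R`
   and some arrangement steers it (simulated annually over one decision
   interval, constraints checked at every sub-step) to a grid cell viable at
   epoch *k+1*.  Interval end-states are snapped to the nearest grid node;
   trajectories leaving the grid are non-viable and logged.  The per-node
   viable-arrangement sets form the regulation map.  Default resolution is
   21 points per dimension (configurable); because published kernels are
   resolution-sensitive, all kernel quantities are reported together with
   the grid used.  A configuration switch allows constraint checking at
   decision nodes only (faster, weaker).

## DAPP maps (module `dapp`)

A pathway assigns one arrangement per decision epoch: every 5 years over a
30-year horizon, i.e. 7 epochs.  The terminal epoch's arrangement labels the
end state but governs no interval; this convention is what makes the raw
pathway count `9^7 = 4,782,969` for nine arrangements rather than `9^6`.
Enumeration of viable pathways is exact and memoized on the deterministic
state reached at each epoch, so cost scales with distinct reachable states,
not raw pathway count.  Per-edge traversal counts (viable prefixes × viable
suffixes) shade the probability map; shading normalizes by the map-wide
maximum (per-map, not per-layer — flagged as a convention).

Pathway *security* is the time mean (configurable: minimum) over annual
steps of the mean normalized constraint margin; a margin is normalized by
the feasible width of its bound, so a maximally satisfied bound scores 1 and
a bound at its threshold scores 0.  A vacuous bound (floor 0 or cap 1)
cannot be violated and contributes full security.  The top-secured map keeps
the `⌈fraction·n⌉` most secured viable pathways, ties broken
lexicographically; per-ES optimal maps select the viable pathways maximizing
(services) or minimizing (disservices) the time-mean (configurable:
terminal) level of one ES, returning all co-optima.

## Synthetic hedgerow case (module `hedgerow_case`)

The fixture emulates a temperate agricultural landscape whose hedgerow
network delivers a bundle of ES.  It is a *synthetic emulation*, not a
reproduction of any empirical parameterization: all constants are design
constants documented in the source.

* **State.** Landscape fractions of five classes — tall/short ×
  species-rich/species-poor hedgerows (TR, TP, SR, SP) plus hedge-free land —
  on the 4-simplex.  The kernel grid lives on the four hedgerow coordinates.
* **Dynamics.** An annual row-stochastic transition operator composed of
  baseline ecological rates (growth, impoverishment, slow enrichment,
  dieback, attrition, colonization; 0.003–0.06 yr⁻¹), arrangement-specific
  management flows (planting 0.005–0.05, enrichment 0–0.08, trimming
  0.005–0.05, removal 0.001–0.02 yr⁻¹, and a maintenance factor damping
  natural decay by 5–60 %), and climate multipliers (×1.0/1.6/2.2 for stress
  levels 0/1/2) on decay out of tall and species-rich classes.  Climate also
  sets the external stress weight `u7b` (0/−0.15/−0.30).
* **Services.** Five services and two disservices.  All but aesthetics are
  convex-linear in the class proportions with coefficients in [0, 1] — hence
  automatically bounded on the simplex — weighting species-rich classes
  (pollinator resources, fruit production), tall classes (wood biomass,
  sunlight protection), management burden (maintenance costs) and tall
  species-poor hazard sources (environmental hazards).  Aesthetics is the
  Shannon diversity of the four hedgerow classes, renormalized over present
  hedgerows and divided by ln 4.  Seven ES is the shipped default; the count
  is configurable.
* **Contexts.** Two archetypes differ only in their satisfaction thresholds:
  the rural context is strictly tighter on every bound.  The 2020 initial
  composition (5 % TR, 15 % TP, 10 % SR, 40 % SP, 30 % none) satisfies both.
* **Arrangements.** Nine CCA|KCA combinations spanning exploitation-only
  (CCA1), exploitation+policy contracting (CCA2), exploitation+conservation
  (CCA3) and fully polycentric (CCA4) constitutions, with collective
  variants switching individual link sets.  Management intensity increases
  along the gradient; CCA4|KCA9 is the cost-minimizing variant.
* **Seeding.** The seed drives only a ±10 % jitter of the CIS action
  weights (sum groups are jittered then renormalized, so the contracts hold
  for every seed).  Landscape dynamics, ES coefficients and thresholds are
  fixed so the qualitative calibration does not drift with the seed.

**Calibration of the shipped defaults.** The constants were chosen so that
the case's stated qualitative properties hold: the 2020 state lies inside
both satisfactory domains; holding the traditional arrangement CCA1|KCA1
for the full 30 years is non-viable in both contexts at all three climate
levels (first violations between 2022 and 2039); higher climate levels
strictly inflate every decay rate out of TR/SR; and the rural constraint box
is a strict subset of the peri-urban one.  Under these defaults the
landscape-scale viability shares are high (79–100 % of the 9⁷ pathways,
decreasing with stress and tighter in the rural context) because every
non-traditional arrangement is restorative; the viability kernel then
coincides with `K_R` at the shipped resolution — from any satisfactory
composition some arrangement can hold the constraints.  The toy models used
in the test suite probe the regime where the kernel is a strict subset of
`K_R` and shrinks with the horizon.

**What the fixture does not emulate:** spatial structure, stochastic
transitions, estimation of rates from imagery or surveys, costs of
institutional transitions, and any published kernel or map panel.  Passing
tests therefore demonstrate correctness of the machinery and qualitative
behaviour of a plausible landscape, not empirical fidelity.

## Retrospective sensitivity (module `sensitivity`)

For each pathway the trajectory is re-simulated under two models with
management effort shifted by a perturbation (default 10 % of the decay
rates, clipped at range boundaries and logged) toward species-rich vs
species-poor classes (or tall vs short), uniformly across epochs.  The
reported ΔES per service is the difference in time-mean per-ES normalized
margin; distributions (exact sample medians and linear-interpolation
quartiles, fixed-width histogram bins) are reported for all pathways and the
viable subset.  The construction is antisymmetric under contrast reversal by
design.  A separate *swap* mode exchanges the per-class protection efforts;
because the shipped management profiles are richness-blind, a rich/poor
effort swap is structurally a no-op, so every ΔES — aesthetics in
particular, which is additionally invariant under any class relabelling by
the symmetry of the Shannon index — is identically zero.  Whether the
tall/short hazard pattern reverses at the highest stress level depends on
coefficients this synthetic case does not pin down; that question is left
exploratory.

## Numerical choices and degenerate inputs

* Exact floating-point state bytes key the enumeration memo (dynamics are
  deterministic; no grid snapping in forward enumeration).
* Nearest-node snapping uses half-cell tolerance at the grid boundary;
  beyond it a trajectory is non-viable.
* Ties in top-secured selection break lexicographically; co-optimal ES
  pathways are returned in full (tolerance 1e-12).
* Empty distributions are explicit empty markers, not NaN arrays; an
  arrangement whose masks leave an active compartment without incoming
  weight is a hard error; pathway stores that hit their cap raise rather
  than silently truncate.
* Normalization contracts are checked to 1e-9; simplex closure to 1e-9.

## Problem sizes used by the shipped analyses

The acceptance script enumerates all 9⁷ pathways exactly for the six
context × stress combinations (seconds each, thanks to memoization),
computes kernels at 13 grid points per dimension, and evaluates the
sensitivity medians on 100 seeded random pathways.  The test suite's oracle
comparisons run on 2-state toys with 3 arrangements and 3–4 epochs, where
exhaustive enumeration over every grid node and control sequence is cheap.

## Known limitations

* The compartment dynamics and the land-cover dynamics are linked through
  the arrangement layer (masks, intensities, `u7b`) but are not numerically
  coupled in the shipped case; role capacities are treated as
  arrangement-implied within each decision interval.
* Finite-horizon kernels only; no resilience (return-to-kernel) analysis.
* Kernel membership is resolution-dependent by construction; monotonicity
  properties are guaranteed, absolute occupancy numbers are not.
* Institutional transition costs are not modelled, so pathway feasibility is
  purely constraint-driven.
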