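# Methods

This note documents the modelling choices behind `camp`: the community
growth formulation, the decision thresholds, the synthetic fixtures, the
numerical conventions, and what the desk-scale tests do and do not show
about real genome-scale model collections.

## Community growth model

A two-species community couples the members through a shared
extracellular pool *[u]*.  Member exchange reactions become transfer
reactions member↔[u] that keep the member's own exchange bounds
(positive flux = secretion into the pool); one community exchange
`EX_<met>(u)` per pooled metabolite connects the pool to the
environment.  Nutrient conditions are applied to the community
exchanges only, so a bound of −1 mmol/gDW/h on glucose caps the *total*
community uptake, not each member's share.

Growth is the steady-state, abundance-scaled formulation: abundances
*X_k* ≥ 0 with Σ*X_k* = 1, fluxes *V_k* = *X_k*·(per-gram fluxes),
per-member mass balance *S_k·V_k* = 0, scaled capacity bounds
*lb·X_k* ≤ *V* ≤ *ub·X_k*, and a single shared growth rate through
*V_biomass,k* = *μ·X_k*.  The maximal *μ* is found by bisection on a
feasibility LP: at fixed *μ*, maximise Σ*X_k*; *μ* is feasible iff the
optimum reaches 1.  Because the system is homogeneous in (*V*, *X*)
apart from the absolute community-exchange bounds, any state with
Σ*X* ≥ 1 scales down to Σ*X* = 1, so the feasibility test is exact even
with the internal cap the solver places on *X* to keep the LP bounded.
Defaults: bisection tolerance 1e−6 h⁻¹, bracket [0, 50] h⁻¹ (growth
still feasible at the top of the bracket signals missing substrate caps
and raises a configuration error).

Flux variability, product maxima, uptake minimisation and the
parsimonious (minimum total member |flux|) solution are all solved over
the same feasible set with *μ* clamped.  `solve_steadycom` reports the
parsimonious flux vector by default: alternate optima are endemic in
flux analysis, and a deterministic representative makes single-solution
downstream analyses (cross-feeding, scan baselines) reproducible.
Quantities that matter quantitatively (product maxima, yields) are
always taken from flux-variability extremes or dedicated secondary
optimisations, never from an arbitrary vertex.

### Per-member growth in co-culture

The formulation gives all members one growth rate *μ*, but interaction
typing needs a per-member quantity that can move in either direction
relative to monoculture.  `camp` defines a member's co-culture growth
rate as *μ·X_k* — its biomass production per unit total community
biomass.  Two observations force this choice.  First, with identical
monoculture and community conditions, setting the partner's abundance
to zero embeds any monoculture solution in the community feasible set,
so the community *μ*\* can never fall below either monoculture rate:
had we compared *μ*\* itself with the monoculture rates, no member
could ever register a decrease and parasitism, amensalism and
competition would be unobservable by construction.  Second, *μ·X_k*
responds exactly the way the ecology intuitively should: a member
marginalised to low abundance registers a strong decrease even though
the community as a whole grows fast.  Viability uses the same quantity:
a pair is viable iff both members have *μ·X_k* ≥ 0.01 h⁻¹ (inclusive).

## Nutrient conditions and constants

Three named conditions cover the screen, all anaerobic with the ATP
maintenance reaction clamped (equal lower and upper bounds) at
0.36 mmol/gDW/h:

| condition | glucose | xylose |
|---|---|---|
| minimal | −1 | −1 |
| excess | −30 | −10 |
| community-specific | per-model half-max uptake | per-model half-max uptake |

Amino-acid exchanges in the medium get a lower bound of −1, other
essential components −1000 mmol/gDW/h; every exchange outside the
medium is closed for uptake.  The bundled default medium is a generic
VMH-style list (the 20 proteinogenic amino-acid exchanges plus common
inorganic components) authored in `camp.io`; the fixture medium is two
amino-acid exchanges (arginine, glutamate).

The community-specific condition needs a per-model uptake estimate:
each model's maximal growth is computed with the substrate as sole
carbon source under excess bounds, biomass is then fixed at half that
optimum and the uptake magnitude minimised by LP — the minimisation is
this package's interpretation, since "uptake at half-maximal growth"
does not pin down a unique flux.  For a pair community the [u] bound is
the sum of the two members' half-max uptakes; the monoculture
comparison uses each model's own value.

Decision constants, applied exactly as stated and centralised in
`camp.config.Thresholds`: ±10% growth change for interaction typing
(strict inequality: exactly ±10% counts as unchanged), 0.01 h⁻¹
viability (inclusive), 2 mmol/gDW/h cross-feeding flux (inclusive, on
community-scaled transfer fluxes), 10-fold observed/expected yield for
candidate producers (inclusive), and a 30-reaction shortlist limit for
double-deletion testing.

## Yields

Monoculture yield: biomass fixed at its FBA optimum, product flux
maximised, then — as a deterministic tie-break — substrate uptake
minimised at that product level; y = product max / uptake magnitude
(glucose + xylose).  Observed community yield MO_i: product FVA maximum
at *μ*\* divided by total community substrate uptake, with per-member
uptakes s₁, s₂ read from the substrate transfer fluxes of the
uptake-minimised solution at maximal product.  Expected yield is
computed literally as ME_i = s₁·y₁ᵢ + s₂·y₂ᵢ.  Note the dimensional
wrinkle: ME_i is a flux (uptake × yield) while MO_i is dimensionless;
the candidacy rule MO_i ≥ 10·ME_i is nevertheless applied to the
quantities as defined, because that is how the rule is stated;
`expected_yield(..., normalize=True)` divides by (s₁+s₂) for users who
want commensurable units.  Division guards: zero uptake with nonzero
product reports an infinite yield with a warning; zero/zero is 0.

## Robustness scenarios and ranking

Product- and growth-efficiency is probed by four re-solves per pair:
blocking each member's product (lactate) transfer entirely (both bounds
0 — no product cross-feeding), and designating each member in turn the
primary consumer while closing the partner's sugar *uptake* (transfer
lower bounds 0; secretion stays open).  A scenario passes if the
re-solved community keeps both members at ≥ 0.01 h⁻¹; a pair is
efficient iff all four pass — the stricter "each member in turn"
reading.  Efficient pairs are ranked by the unweighted mean of
min–max-normalised growth rate and observed yield (the aggregation
weight is this package's choice); ties break by raw yield, then pair
id.  A degenerate cohort (all equal, or a single record) normalises to
1.  The Jaccard metabolic distance between the members' reaction sets
is reported alongside.

## Knockout design

The community FSEOF adaptation: the baseline is the product's FVA
*minimum* at the wild-type optimum (the least product the community
must make while growing optimally); the ceiling is the best point on
the product-versus-growth frontier, probed on a small *μ* grid between
the viability floor and *μ*\* (the frontier can peak below *μ*\* when
product and growth compete for the same resources).  Ten enforced
levels span baseline→99% of the ceiling; at each level growth is
re-maximised and a parsimonious profile recorded with the product
pinned at the level.  Internal member reactions (never biomass, ATPM,
transfers or exchanges) whose |flux| is non-increasing across levels,
nonzero at the baseline and lower at the top are knockout candidates;
non-decreasing profiles are reported as amplification targets but not
deleted.  Profile comparisons use an absolute tolerance of 1e−4 — LP
round-off between levels is of order 1e−6–1e−5, so a tighter tolerance
mistakes solver noise for monotone change.

Deletions close the reaction (both bounds 0) in the tagged member copy;
every single deletion is evaluated, plus every unordered pair when the
shortlist has at most 30 reactions (≤ 435 doubles).  A mutant is scored
by re-solving growth and taking the product FVA maximum at the mutant
optimum; infeasible mutants are recorded as non-viable rather than
raised.  "Improved" requires strict product increase *and* viability of
both members.

## Synthetic fixtures

The generator provides the study conditions at desk scale; it is
first-class, tested code.

**Fermenter chassis** (redox-coupled): the homofermenter runs a lumped
EMP route (glucose → 2 pyruvate + 2 ATP + 2 NADH) whose only NADH sinks
are D-lactate dehydrogenase and biomass, so lactate secretion is tied
stoichiometrically to growth — at unit glucose uptake with growth off
the maximal lactate flux is exactly 2.  The heterofermenter runs the
phosphoketolase route (glucose → pentose at 1 NADH, xylose by kinase;
phosphoketolase splits the pentose into a C2 unit and G3P; lower
glycolysis yields 2 ATP + 2 NADH) with the mixed-acid branches: acetate
via phosphotransacetylase + acetate kinase (substrate-level ATP, finite
capacity 2 mmol/gDW/h), acetaldehyde/ethanol as NADH sinks, formate via
pyruvate formate-lyase, and an arginine-deiminase fallback.  The C2
unit is lumped at the acetyl-CoA node so that acetate strictly requires
the PTAr→ACKr chain; together with the capacity cap this reproduces the
qualitative engineering pattern end-to-end: the acetate-branch
reactions appear in the FSEOF shortlist and deleting either one
strictly raises the community's maximal lactate flux while both members
stay viable.  These stoichiometries are authored fixture choices, fixed
against those qualitative requirements.

**ATP-accounting chassis**: linear catabolic routes substrate → ATP
(+ carbon-balanced byproducts; CO₂ fills the balance) with biomass
built from ATP alone.  Community optima are then solvable by hand —
the optimum allocates each shared substrate to its most ATP-efficient
consumer, abundances follow as ATP shares — which makes it possible to
author pairs whose pipeline outcome realises any requested interaction
label with comfortable margins (e.g. competition from two generalists
with opposite substrate strengths; parasitism from an amino-acid
specialist that also eats the partner's obligate byproduct).
Generation is self-validating: the pair is run through the full
pipeline and construction fails loudly if the label does not round
trip.

All fixtures use VMH-style identifiers, carry exchanges for both sugars
even when one is catabolically disconnected (mirroring
sugar-restricted strains), and are carbon-balanced in their core
reactions (ATP/ADP, NAD/NADH and CoA are carbon-free carriers; biomass
and ATPM are drains) — with a closed medium they can neither grow nor
excrete product.  Panels are seeded and byte-reproducible down to the
SBML output.

What the fixtures do *not* emulate: realistic biomass compositions,
amino-acid biosynthesis, gene–protein–reaction associations,
thermodynamic or kinetic constraints, and the sheer degeneracy of
genome-scale networks.  Passing tests therefore demonstrate that the
algorithms are implemented correctly and behave as specified on
networks whose ground truth is known exactly — not that any particular
biological prediction about a real community is accurate.

## Numerical conventions

- Exchange sign convention: negative = uptake, positive = secretion,
  everywhere (monoculture exchanges, transfers, community exchanges).
- LP backend: GLPK through optlang.  Feasibility tolerance 1e−9 on the
  Σ*X* ≥ 1 test; growth bisection tolerance 1e−6 h⁻¹.
- FVA at exactly *μ*\* retries once at *μ*·(1−1e−6) before raising, to
  absorb marginal infeasibility at the bisection edge.
- Degenerate min–max normalisation (single record or all-equal cohort)
  maps to 1.0; ranking ties break by raw yield then lexicographic pair
  id, deletion ties by fewer deletions then lexicographic ids.
- Screens iterate pairs in sorted model-id order and write TSVs with a
  fixed float format, so identical configurations give byte-identical
  artifacts regardless of execution order.

## Problem sizes

The bundled test suite and the acceptance script run on generated
panels of 4–10 models (6–45 communities), three nutrient conditions and
toy networks of 15–35 reactions; brute-force oracles (μ-grid
feasibility scans at 1e−3 resolution, abundance-simplex subdivision for
flux extremes) are run on three representative communities.  These
sizes exercise every code path while keeping the whole suite in the
minutes range on a single core; the workflow itself scales to
collections the size of published GSMM screens (49 models, 1176
communities), where pair-level solves are independent and trivially
parallelisable.

## Known limitations

- Pairwise communities only; the data model does not preclude n > 2,
  but no larger-community operations are provided.
- Reaction-level deletions; gene-level (GPR-mediated) knockouts and
  bilevel strain-design formulations are out of scope.
- Cross-feeding is read from a single (parsimonious) optimal solution;
  alternate optima can change the reported set.  Records are
  deterministic but not exhaustive over the optimal face.
- The shared growth-rate assumption can impose "forced altruism": a
  member may be required to produce for the community before its own
  benefit, a known property of steady-state community formulations.
- Dynamic (time-course) community simulation and thermodynamic
  feasibility are not modelled.
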