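# Methods

`phaflux` reconstructs the metabolic states of PHA-cycle-engineered
*Pseudomonas putida* batch cultures from their measured physiology.  This
note documents the models and procedures the package implements, the
defaults it ships, and what its synthetic study conditions do and do not
establish about real data.

## The scientific setting

*P. putida* KT2440 grown on octanoate under nitrogen limitation stores
carbon as medium-chain-length polyhydroxyalkanoate (mcl-PHA).  Polymer
synthesis (polymerase PhaC), hydrolysis (depolymerase PhaZ) and
ATP-dependent reactivation of the released (R)-3-hydroxyalkanoates
((R)-HAs, via the acyl-CoA synthetase FadD) run simultaneously, forming a
turnover loop — the PHA cycle.  Engineering the PhaZ dose produces two
behavioural classes: accumulators (wild type, the *phaZ* knockout KT40Z,
low-dose strains) that reach ~70% polymer per cell dry weight, and
hydrolyzers (high-dose strains M2–M4) that store no polymer, secrete free
monomers, and respire more.  The package turns such measurements into
condition-specific constraint-based models and asks how carbon flux is
rerouted.

## Physiology-to-flux conversion

**Residual biomass.**  Total dry weight conflates cells and stored
polymer, so all growth-related quantities use residual biomass
`X = total · (1 − %CDW/100)` (g/L).

**Growth rate.**  μ is the least-squares slope of log10(X) versus time
over a phase window, converted to natural-log units.  The conversion
multiplies by ln(10) = 2.302585…; physiology papers conventionally print
this factor as 2.303.  Points with non-positive residual biomass are
excluded with a warning rather than failing the fit.  The fit window is
the phase's half-open interval [t_start, t_end), consistent with sample
assignment in phase segmentation.

**Specific rates.**  A concentration change Δm (g/L) over an interval Δt
becomes `(Δm/M) / (Δt · X̄)` in mmol gCDW⁻¹ h⁻¹, where M is the molar
mass (g/mmol) and X̄ the interval-mean residual biomass.  X̄ defaults to
the arithmetic mean of the interpolated endpoint values; a logarithmic
mean (exact for exponential growth) is available as a strategy option.
Octanoate is measured in mM, so its rate needs no molar mass.  Molar
masses default to the C8 repeat unit in the chain (142.20 g/mol,
dehydrated 3-hydroxyoctanoate) for PHA and free 3-hydroxyoctanoic acid
(160.21 g/mol) for (R)-HAs — octanoate feeds produce predominantly C8
monomers — and are overridable through `MonomerMassTable`.

**Phases.**  Batch growth is segmented at fixed clock boundaries,
default (5 h, 10 h): phase I [0, 5) early exponential (growth), phase II
[5, 10) late exponential (polymer/monomer production), phase III [10, 24]
stationary.  The last phase is closed on the right so the 24-h sample
belongs to it.

**Respirometry.**  MicroResp OD570 readings convert to %CO2 through the
rectangular hyperbola `y = A·x/(B + x)` with packaged calibration
A = 1.73, B = −0.13.  Because B < 0 the curve has a vertical asymptote at
x = 0.13; on its valid domain (x > 0.13) it is monotone *decreasing*
toward A — more CO2 acidifies the cresol-red dye and lowers the
absorbance — and readings at or left of the asymptote are rejected.

## Condition-specific models

For each strain × phase, the measured rates are imposed on the base
network as bound overrides: octanoate exchange in
[−uptake·(1+δ), −uptake·(1−δ)] (uptake is negative flux), the PHA sink,
the HA exchange and the biomass reaction each banded at (1±δ) around
their measured value.  The default relative band δ = 5% absorbs
measurement noise; exact clamping (δ = 0) frequently over-constrains real
models.  Banding growth on *both* sides (rather than only from below) is
what makes FBA "predictions" reproduce the observations the way a
contextualized model should, pins the near-zero stationary phase, and
leaves the sampler exactly the interior degrees of freedom — the
degeneracy the method is interested in.  Bounds are clipped to the base
reaction's thermodynamic direction: an irreversible reaction never
receives a negative lower bound.

FBA maximizes biomass flux subject to S·v = 0 and the bounds, solved with
HiGHS at a 1e-9 feasibility tolerance.  Growth maximization remains the
objective in all phases; in stationary phase the growth band pins the
optimum and sampling explores the residual space.  Because FBA optima are
degenerate, all claims about flux *distributions* are made through the
sampler, never from a single FBA vector.

Strain genotypes are expressed as knockouts of the base network before
contextualization: KT40Z lacks PHAZ; the whole-cluster deletion lacks
PHAP2C80, PHAZ and FADD1.

## Dynamic FBA

The batch curve is reconstructed by static-optimization dynamic FBA: at
each step the active phase's constraints are applied (tolerance 0 — the
deterministic reconstruction), uptake is additionally capped by the
remaining substrate, one FBA is solved, and the external state advances.
Within a step the flux vector is constant, so the biomass ODE integrates
exactly: `X ← X·e^{μΔt}`, and concentrations advance by
`v·M·X·(e^{μΔt} − 1)/μ` (→ `v·M·X·Δt` as μ→0).  This classic analytic
step was chosen over a plain Euler update because it is exact for
constant μ and conserves the network's linear invariants: on the
carbon-balanced core model the carbon audit closes to rounding error at
any step size, and the constant-growth trajectory matches `X₀e^{μt}` to
machine precision.  Default Δt = 0.01 h.

Substrate exhaustion is handled by first capping the uptake bound at the
available octanoate; if a production or growth floor then becomes
infeasible, the floors are relaxed to zero for that step (metabolism
winds down rather than erroring); persistent infeasibility raises with
the step index.  Phase switching is by clock time, not substrate level.

The carbon audit uses the model's own biomass carbon drain — exactly
40 mmol C per gCDW (≈ 0.48 gC/g) — plus 56.26 mmol C/g for PHA and
49.93 mmol C/g for free (R)-HA.

## Flux sampling and comparison

**ACHR.**  The flux polytope `{v : S·v = 0, lb ≤ v ≤ ub}` is sampled with
artificial-centering hit-and-run.  Warmup points are LP vertices obtained
by optimizing ±each coordinate (plus random dense objectives when more
are requested).  The walk is performed in reduced coordinates
`v = x₀ + N·y`, where N is an orthonormal null-space basis of S and x₀ a
warmup vertex re-projected onto the subspace; the steady-state constraint
therefore holds by construction and cannot drift.  Directions are
differences between a randomly chosen stored point and the running center
of all iterates; the step is uniform on the feasible chord.  A 1e-9 slack
in the chord bounds prevents deadlock when the walker touches several
facets of a narrow (tightly banded) polytope; it is an order of magnitude
below the 1e-8 bound tolerance every emitted point is checked against.
Defaults: 5,000 stored points, thinning 100, warmup 2·n_reactions (capped
at 400), single chain; sampling is bit-reproducible for a fixed seed and
configuration.

**Mixed fraction.**  The i-th point of the chain's first half is paired
with the i-th point of the second half; the fraction of pairs on strictly
opposite sides of the per-reaction overall median, averaged over
non-constant reactions, is the mixing diagnostic (0.5 = the halves are
interchangeable).  Constant reactions carry no information and are
excluded; an all-constant sample raises explicitly.  This is one concrete
definition of the diagnostic; it is tested against its own enumeration
oracle rather than assumed identical to any toolbox's variant.

**Medians and ratios.**  The per-reaction sample median is the most
probable flux.  Strain comparisons report the ratio of medians
(mutant/reference) and classify each reaction as increased (ratio > 1.2),
reduced (< 1/1.2 ≈ 0.83) or unaffected; the thresholds are symmetric on
the log scale and configurable, since no published arrow-coloring rule
exists.  A ratio with |reference median| < 1e-6 is undefined.

**Energy summaries.**  "ATP production" is the sum of positive median
ATP-producing contributions (stoichiometric coefficient × median flux)
over all reactions except the maintenance drain; respiration is the
magnitude of the median O2 exchange; CO2 production the median CO2
exchange.  Each is a named, documented report that users can swap.

## The core network

The packaged base model is a 61-reaction, 60-metabolite octanoate/PHA
core network — deliberately *not* the genome-scale iJN1411
reconstruction (2,087 metabolites × 2,826 reactions), which the loader
can also read in the community COBRA-JSON dialect.  It contains octanoate
uptake and activation, three β-oxidation rounds (C8→C6→C4→2 acetyl-CoA),
both (R)-HA-CoA supply routes — the R-specific enoyl-CoA hydratase
(RECOAH3, PhaJ) and the 3-oxoacyl reductase (RHACOAR80, FabG) whose
pairing with ECOAH3/HACD3i exchanges one NADH for one NADPH per monomer —
the PHA cycle (polymerase PHAP2C80, polymer sink, depolymerase PHAZ,
reactivation FADD1), TCA cycle with the canonical mnemonics
(CS, ACONTa/b, ICDHyr, AKGDH, SUCOAS, SUCDi, FUM, MDH), the glyoxylate
shunt (ICL, MALS), a gluconeogenic backbone (PPCK, ENO, PGM, PGK, GAPD,
ME1, PDH), lumped oxidative phosphorylation (P/O 2.5 for NADH, 1.5 for
FADH2), transhydrogenase, ATP maintenance, and a PHA-free biomass
reaction draining exactly 40 mmol C/gCDW.

Every interior reaction is elementally balanced (charged-species
formulas, BiGG conventions), verified by the packaged checker; exchange,
sink and biomass pseudo-reactions are exempt by definition.  PDH and ME1
give the glyoxylate shunt an oxidative role beyond anaplerosis, so its
feasible flux scales with carbon throughput — without them the shunt is
pinned by biomass demand alone and strain comparisons at the shunt are
structurally blind.  The ATP maintenance lower bound defaults to 0 so a
fully clamped (all-zero-rate) condition model remains feasible at zero
growth; users can raise the ATPM bound on a copy to enforce an NGAM
demand.  The biomass function is PHA-free by construction and polymer
accumulation is a separate sink on the polymerized repeat unit, so %CDW
accumulation is representable at steady state; which genome-scale biomass
function (polymer-inclusive or residual) a published analysis used is not
derivable from its text, and this choice is flagged to users here.

## Synthetic study conditions

The generator emulates the published 24-h endpoint physiology of eight
strains (wild type KT2440, depolymerase knockout KT40Z, whole-cluster
deletion, dose library M1–M4) grown on 15 mM octanoate:

* Residual biomass starts at 0.085 g/L and follows `X₀e^{μt}` capped at
  its final value (nitrogen limitation); each archetype's μ and endpoints
  are the published means (e.g. wild type: μ = 0.31 h⁻¹, 1.3 g/L total,
  71.7 %CDW PHA, 0.2 g/L (R)-HA).
* PHA, (R)-HA and CO2 accumulate toward their 24-h totals with per-phase
  allocation weights encoding the three-phase narrative: growth in phase
  I, polymer/monomer production in phase II, stationary phase III.  The
  knockout's CO2 is skewed toward phase I (its reported early-exponential
  oxidative elevation) and the hydrolyzers' toward phase III (their
  reported active stationary metabolism and ~3× endpoint CO2 fold).
* Octanoate is derived from carbon conservation — consumed carbon equals
  carbon appearing in biomass + PHA + HA + CO2 — and reaches zero at
  24 h, matching the observation that no octanoate remains.
* Sampling grid: half-hourly through the exponential phase (0–5 h),
  hourly to 10 h, then 12 and 24 h — the cadence of growth-curve
  monitoring.  Observations are means of three replicate draws with 5%
  CV multiplicative lognormal noise each, emulating the
  mean-of-triplicate values physiology tables report; the ±0.02 h⁻¹
  error band on μ is a replicate-mean band.
* The MicroResp channel is an endpoint (24 h) reading: the phase-III CO2
  evolution rate is scaled into the calibrated %CO2 range
  (2.6 %CO2 per mmol L⁻¹ h⁻¹) and inverted through the hyperbola.
* Viable-cell counts are generated for schema completeness but feed no
  downstream computation.

What passing on these conditions shows — and does not.  The generator's
trajectories are exactly log-linear in the exponential segment,
piecewise-linear in the product channels, and carbon-closed by
construction; real cultures have lag phases, curvature within phases,
replicate-correlated errors and imperfect carbon recovery.  Green tests
therefore certify the *machinery* — rate extraction, constraint
construction, solver correctness, integrator exactness, sampler
uniformity and the direction of constraint-driven flux rerouting at core
scale — not the quantitative genome-scale flux values, which depend on
iJN1411 and the full supplementary constraint tables.

## Numerical choices

* LP feasibility tolerance 1e-9 (FBA and warmup), reported in solution
  metadata.
* Sample feasibility invariants: |S·v| ≤ 1e-6, bounds ± 1e-8, asserted
  over every emitted set.
* Elemental-balance tolerance 1e-9 per element.
* Ties and degenerate inputs: a flat biomass series gives μ = 0; phases
  assign each sample once (half-open intervals, closed last); zero
  observed and predicted rates compare with zero relative error; an
  all-constant sample set makes the mixed fraction an explicit error, not
  a number.
* Seeds are explicit function arguments everywhere; no global RNG state.
  The pipeline derives per-condition seeds from the run seed and records
  them in the manifest, which suffices to reproduce every output
  byte-identically.

## Known limitations

* The core network is a curated desk-scale analogue; its flux ratios are
  direction-consistent with, but numerically smaller than, genome-scale
  results (e.g. TCA elevation ~1.3× here versus 1.8–2.2× reported at
  genome scale), because a 61-reaction network lacks the alternative
  routes that amplify rerouting.
* Exchange bounds for by-products other than the measured ones are left
  at model defaults; a `--close-secretions` style restriction is not
  applied because no significant extracellular by-products were reported.
* dFBA uses measured per-phase rates as driving constraints, not uptake
  kinetics; it reconstructs, it does not predict ab initio.
* SBML input is read-only and routed through cobrapy when available;
  JSON is canonical.
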