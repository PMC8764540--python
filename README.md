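# phaflux

Phase-resolved contextualization of constraint-based metabolic models from
the batch physiology of PHA-cycle-engineered *Pseudomonas putida*.

## The problem

*P. putida* KT2440 grown on octanoate under nitrogen limitation stores
carbon as medium-chain-length polyhydroxyalkanoate (mcl-PHA) while
simultaneously hydrolyzing it and re-activating the released
(R)-3-hydroxyalkanoate monomers — a turnover loop (the **PHA cycle**) that
couples carbon storage to central metabolism.  Strains engineered for
different depolymerase (PhaZ) doses range from polymer accumulators
(~70% of cell dry weight) to hydrolyzers that secrete free monomers and
respire the rest.  `phaflux` turns the measured physiology of such batch
cultures into quantitative flux pictures:

1. **Physiology → rates.** Growth rate from the log-linear slope of
   *residual* biomass (dry weight free of polymer), μ = ln(10) · slope of
   log₁₀X(t); uptake/production rates (Δm/M)/(Δt·X̄) in mmol gCDW⁻¹ h⁻¹;
   MicroResp respirometry through the calibration hyperbola
   %CO₂ = A·x/(B + x) with A = 1.73, B = −0.13.
2. **Condition-specific models.** The growth curve splits into three
   pseudo-steady states (phase I 0–5 h, II 5–10 h, III 10–24 h); each
   strain × phase becomes a flux balance analysis (FBA) problem
   max c·v s.t. S·v = 0, lb ≤ v ≤ ub with the measured rates imposed as
   exchange/sink bounds (±5% bands).
3. **Dynamic FBA.** The three steady states are stitched into the full
   batch curve by static-optimization dFBA with the analytic within-step
   update X ← X·e^{μΔt}; carbon closes exactly on the packaged network.
4. **Flux sampling.** Each condition model's flux polytope is sampled
   uniformly with an artificial-centering hit-and-run (ACHR) Markov
   chain; per-reaction medians are the most probable fluxes, the
   *mixed fraction* (≈0.5 when well mixed) diagnoses convergence, and
   mutant/wild-type median ratios classify reactions as
   increased / reduced / unaffected.

Everything runs on a packaged, hand-curated, fully element-balanced
61-reaction octanoate/PHA core network plus a synthetic-data generator
that reproduces the study conditions (eight strain archetypes, three-phase
structure, closed carbon bookkeeping), so the entire pipeline is testable
offline.  Genome-scale models such as iJN1411 load through the same
COBRA-JSON dialect.

Intended users: systems-biology practitioners contextualizing batch
physiology with constraint-based models, and method developers who need a
transparent, fully testable reference for the data-to-flux-to-sampling
chain.

## Worked example

```python
import phaflux as pf

arch = pf.builtin_archetypes()
tc   = pf.make_strain_timecourse(arch["KT2440"], seed=7)   # synthetic wild type
phases = pf.segment_phases(tc)                              # I, II, III

rates = pf.build_phase_rates(tc, phases[0])
print(f"phase I: mu={rates.growth_rate:.3f} /h, "
      f"octanoate uptake={rates.octanoate_uptake:.2f} mmol/gCDW/h")

model = pf.core_pha_model()
cm    = pf.apply_phase_constraints(model, rates, strain="KT2440")
sol   = pf.fba(cm)
print(f"FBA: {sol.status}, growth {sol.objective_value:.3f} /h")

samples = pf.achr_sample(cm, n_samples=5000, seed=1)
print(f"mixed fraction {pf.mixed_fraction(samples):.2f}, "
      f"median CS flux {pf.median_fluxes(samples)['CS']:.2f} mmol/gCDW/h")
```

prints (seed 7):

```
phase I: mu=0.311 /h, octanoate uptake=4.02 mmol/gCDW/h
FBA: optimal, growth 0.326 /h
mixed fraction 0.50, median CS flux 9.29 mmol/gCDW/h
```

The fitted growth rate recovers the wild-type 0.31 h⁻¹ within the noise
of this simulated replicate set, with a phase-I octanoate uptake around
4 mmol gCDW⁻¹ h⁻¹; the FBA optimum sits at the top of the
±5% growth band; a mixed fraction near 0.5 says the 5,000-point chain
covered the solution space evenly, and the citrate-synthase median is the
most probable TCA influx under those constraints.  Comparing against the
depolymerase knockout (`pf.compare_strains`) classifies CS, aconitase,
malate dehydrogenase and the glyoxylate-shunt reactions as *increased* in
the knockout — carbon that cannot leave as free monomers is burned.

A command-line interface mirrors the library
(`phaflux simulate-data | contextualize | fba | dfba | sample | compare |
run`); `phaflux run --config run.yaml` executes the full
strains × phases pipeline and writes condition models, validation tables,
sample sets, median-flux tables, comparison tables and a manifest with
seeds and diagnostics.

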