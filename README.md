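# sulfurflux

Desk-scale tooling for studying how gut-microbial **sulfur metabolism**
interacts with the host metabolome in Parkinson's disease (PD): personalized
community flux-balance models of toy strain panels, net maximal secretion
potentials for sulfur metabolites, longitudinal case/control metabolome
statistics (trajectory typing, pairwise interaction screening, medication
models), per-SD Cox incidence analysis, and a greedy case/control matching
optimizer — all driven by seeded synthetic-data generators so the entire
analysis chain can be exercised and validated end to end without access to
restricted cohort data.

It is intended for methodologists who want a reproducible, testable
re-implementation of this analysis style: every statistical routine can be
pointed at generated cohorts in which the true effect sizes are known, so
bias, test size, and power are measurable rather than assumed.

## The models at the core

**Community FBA.** Each subject's microbiome is a stoichiometric model built
from strain reconstructions joined through a shared lumen compartment `[lu]`.
Fluxes satisfy `S·v = 0, lb ≤ v ≤ ub`; diet exchanges `Diet_EX_met[d]` bound
uptake, fecal exchanges `EX_met[fe]` carry secretion, and a community biomass
reaction consumes each strain's biomass metabolite with stoichiometry equal
to its relative abundance, bounded to [0.4, 1] day⁻¹. The **net maximal
secretion potential** of a metabolite is `|v_fe + v_diet|` at the optimum of
`max v_fe` — the community's net capability to produce it (a pure
pass-through metabolite scores 0). Strain–lumen transporter capacity scales
with relative abundance, so potentials respond continuously to community
composition.

**Longitudinal mixed models.** Log metabolite concentrations over three
waves (BL, FU1, FU2) follow random-intercept models estimated by
exchangeable GEE (feasible GLS) with bias-reduced cluster-robust standard
errors. A 3-df Wald "global test" on (group, group×FU1, group×FU2) screens
for PD-specific trajectories, classified as type 1 (constant elevation),
type 2 (equal baseline, rising in PD), or type 3 (elevated baseline,
declining in PD). The pairwise screen adds each other metabolite and its
group interaction to the model; the interaction coefficient measures whether
PD rewires the metabolite–metabolite dependency. Benjamini–Hochberg FDR is
applied with the declared family size of each analysis.

**Incidence analysis.** Exposures are log-transformed, winsorised at ±5 SD
and standardized per batch; adjusted Cox proportional-hazards models (Efron
ties) report hazard ratios per SD, pooled across batches by inverse-variance
fixed-effect meta-analysis with Cochran's Q.

## Worked example

Run the full demonstration pipeline (5-strain panel with two sulfur-cycling
keystone archetypes, 59 microbiome subjects, a 60-subject 3-wave metabolome
with an embedded sphingomyelin-pair interaction of −0.53, and a 2000-subject
survival cohort with a true HR of 0.80):

```bash
sulfurflux run-all --seed 1 --out run1
```

The report (`run1/report.md`) from this exact invocation reads, in part:

```
- secretion tests: 8 metabolites, 7 significant at FDR 0.05
- variance explained (mucin-degrader -> methionine potential): R2 = 1.000, powers (1.0,)
- interaction screen: 42 ordered pairs, 2 discoveries
- levodopa-intake classification by 3-OMD: AUC = 1.00
- n = 2000, events = 134
- pooled HR per SD = 0.852 (0.720-1.007), Cochran Q = 0.434
```

Reading these numbers: the keystone-enriched PD communities secrete more
methionine and other sulfur species (7/8 group tests significant); the
mucin-degrading keystone's abundance explains essentially all variance in
the methionine secretion potential; the embedded sphingomyelin interaction
is the only discovery of the 42-pair screen (both orderings of the same
pair, estimate −0.69 ± 0.15 against a truth of −0.53); 3-O-methyldopa
separates levodopa takers from non-takers perfectly; and the Cox fit on one
2000-subject replicate estimates HR 0.85 against a generator truth of 0.80,
with no batch heterogeneity (Q = 0.43). Identical config and seed reproduce
identical bytes.

Individual stages are available as `sulfurflux
simulate|build|fba|screen|longitudinal|cox|match`.

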