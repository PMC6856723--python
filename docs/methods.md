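# Methods

This note records the modelling and statistical choices behind sulfurflux:
what each component assumes, which parameters matter, what the synthetic
cohorts do and do not emulate, and where the design was genuinely open.

## Community models and secretion potentials

A strain reconstruction is a small stoichiometric model (metabolites with
compartment tags and a sulfur flag; reactions with bounds in
mmol·person⁻¹·day⁻¹; one biomass reaction in day⁻¹). Exchange reactions are
written `met →` with coefficient −1: negative flux is uptake, positive is
secretion. Reversible reactions default to ±1000, irreversible to [0, 1000].

The community builder joins strains through one lumen compartment. Per
strain, internal reactions are copied with strain-prefixed identifiers, and
each strain exchange becomes a reversible strain↔lumen transporter. Every
lumen metabolite receives a diet exchange (`Diet_EX_met[d]`, bounds
`[−diet, 0]`) and a fecal exchange (`EX_met[fe]`, bounds `[0, 1000]`). The
community biomass reaction consumes each strain's biomass metabolite with a
coefficient equal to its relative abundance and is bounded to [0.4, 1]
day⁻¹ (fecal excretion between every third day and daily). Strains below the
0.1 coverage detection threshold are removed and survivors renormalized to
sum to one.

**Transporter capacity.** Transporter bounds are ±(100 × relative
abundance) mmol·person⁻¹·day⁻¹ by default. This is the desk-scale analogue
of biomass-flux coupling: a strain contributing 0.3% of the community cannot
carry an arbitrary share of community flux. Without it, secretion potentials
are pure diet-capacity numbers, identical across subjects, and the
downstream group tests and variance-explained analyses would be vacuous.
`abundance_capacity=None` restores unconstrained ±1000 transporters. No
other coupling constraints are applied; `build_community` exposes a
`coupling_hook` for callers who want to add rows.

**Net maximal secretion potential.** For each metabolite we solve one LP
maximising the fecal exchange, then a lexicographic second stage fixing that
optimum and minimising total absolute flux (split-variable formulation),
which makes the diet flux at the optimum — and hence the reported value —
deterministic under degenerate optima. The potential is `|v_fe + v_diet|`
with `v_diet ≤ 0` at uptake, i.e. maximal secretion minus the uptake
supporting it: net production capability. A metabolite the community merely
passes through (diet in = feces out) scores zero. An alternative reading
computes uptake in a separate minimisation LP; on the toy panels both
coincide because uptake at the secretion optimum is already minimal for the
producible metabolites. Tolerances: feasibility 1e−6, LP optimality 1e−7
(HiGHS via scipy).

## Synthetic strain panel

Two keystone archetypes anchor the sulfur pathways. The *mucin-degrader*
(modelled on *Akkermansia muciniphila*) carries the aspartate → aspartate
semialdehyde → homoserine → cystathionine → homocysteine → methionine chain
(EC 2.7.2.4, 1.1.1.3, 2.5.1.48, 4.4.1.8, 2.1.1.13), cysteine desulfhydrase
(EC 4.4.1.1), an assimilatory sulfite reductase (EC 1.8.2.2),
cysteinylglycine condensation, and asparagine synthesis. The
*taurine-respirer* (modelled on *Bilophila wadsworthia*) deconjugates
taurocholate (EC 3.5.1.24) and dissimilates taurine → sulfite → hydrogen
sulfide (EC 2.6.1.55, 1.8.7.1). Background strains ferment glucose to
acetate and carry no sulfur chemistry. The built-in toy diet supplies
glucose 20, aspartate 5, cysteine 2, glycine 5, sulfite 2 and taurocholate 1
mmol·person⁻¹·day⁻¹ — a carbon source plus exactly the precursors the
pathways transport. Panel generation self-checks that every strain grows
standalone on the diet (biomass flux > 0) and fails loudly otherwise.

## Abundance generator

Relative abundances are Dirichlet with base proportions of 0.3% per
keystone (anchored on the reported case/control means of 0.20%/0.34% for
the taurine-respiring species) and the remainder uniform over background
strains; in cases the keystone base proportions are multiplied by
`1 + keystone_shift` (default 0.7, matching 0.20% → 0.34%) before
renormalisation. The total Dirichlet concentration is 800, calibrated once
by Monte Carlo so that (a) the shift is detectable by the fractional
regression at the metagenomic cohort's sizes (31/28) in ≥ 80% of seeds and
(b) a Welch test at 200/200 detects it in ≥ 95% — which places the keystone
abundance coefficient of variation near 0.65, in the range of real taxon
abundances. Smaller concentrations make 0.3%-abundance taxa implausibly
over-dispersed (CV > 2) and the reported group difference undetectable at
the reported sample size, contradicting the observed p = 0.020.

The generator does not emulate phylogenetic covariance between taxa or
compositional zero-inflation; passing tests show the analysis stack is
correct under Dirichlet sampling, not that it is robust to those features.

## Longitudinal metabolome generator

Log concentrations follow
`y = μ + u_i + β_age·(age−65) + β_sex·sex + 0.05·wave + Δ·(template)·PD + ε`
with subject intercept `u_i ~ N(0, 0.3²)` and residual `ε ~ N(0, 0.3²)`
(no published variance components exist for this cohort; 0.3 on the log
scale is a typical metabolomics value and is a flagged calibration choice).
Trajectory templates on (group, group×FU1, group×FU2) are type 1 = (Δ,0,0),
type 2 = (0,Δ,2Δ), type 3 = (Δ,−Δ,−2Δ), Δ default 0.4 — fixed coefficient
encodings of the three verbally described PD trajectory shapes, chosen so
recovery is exactly testable.

An embedded pairwise interaction (A, B, β) generates
`A = … + (0.5 + β·PD)·B + ε`, so the fitted B×group coefficient has β as
its exact estimand. A pair's predictor may not be another pair's response
(this keeps every embedded β an exact conditional-model coefficient rather
than a marginal one).

Levodopa dosing starts at zero (drug-naive baseline); at follow-ups each
case takes levodopa with probability 0.8, with a 3-OMD fold-change drawn
log-uniformly from [10, 600] (the observed range separating treated from
drug-naive patients). The recorded dosage is `ln(fold)/0.614`, so the
intra-individual change-on-change slope of 3-OMD on dosage equals 0.614 by
construction and the taker/non-taker separation is at least tenfold,
guaranteeing AUC 1.0 under any monotone classifier.

## Estimation choices in the longitudinal suite

The random-intercept linear models are estimated as GEE with an
exchangeable working correlation — algebraically the feasible-GLS estimator
of the random-intercept model, which is what "generalized least squares
with heteroscedasticity-robust standard errors" denotes in the econometric
packages this analysis style comes from (REML would be the other natural
reading; GEE was chosen because it yields the cluster-robust sandwich
covariance natively). The sandwich is the **bias-reduced (Mancl–DeRouen)**
variant: with ~60 clusters the uncorrected robust covariance makes the 3-df
global Wald test anti-conservative (empirical size ≈ 8% at nominal 5%);
with the correction the size is ≈ 6% at 300 null simulations.

Outlier handling removes observations more than 4 SD from the metabolite's
full-sample mean before modelling; exclusion is idempotent on generated
data. Missing dosage drops the observation, never the subject. The
wave-dosage interaction is encoded as dosage × FU2-indicator: with a
drug-naive baseline the full categorical interaction is structurally
collinear (all baseline doses are zero).

Trajectory classification applies the global-test FDR gate first
(q < 0.05), then nominal α = 0.05 component rules: type 1 requires a
significant main effect (from the interaction-free refit) with both
interactions null; type 2 a null baseline contrast with both interactions
significantly positive; type 3 a significantly positive baseline contrast
with both interactions significantly negative.

UPDRS scales I/II/IV use proportional-odds ordered logit on pooled
observations with wave as a covariate (the exact random-effects structure
for ordinal scales is an open choice; pooled proportional odds is the
stated approximation, and its standard errors are model-based, not
cluster-robust). Scales III and the total score use the GEE linear model.
BH is applied with each analysis's declared family size, which may exceed
the number of tests actually run — skipped tests count as non-discoveries.

## Survival generator and Cox analysis

Event times are exponential with subject hazard
`λ0·exp(β_x·x + covariate effects)` (standard-normal exposure x; modest
fixed covariate log-hazards for age, sex, BMI, smoking, log CRP), censored
administratively at 23 years. `λ0` is calibrated by bisection on the
expected event count so the realized count lands near the target
(157 events among 10,034 subjects at the study scale). Exposure
preprocessing is ln → winsorise at mean ± 5 SD → standardize, per batch and
in that order. Cox models use lifelines with the Efron tie approximation;
batch estimates are pooled by inverse-variance fixed-effect meta-analysis
with Cochran's Q. The generator is proportional-hazards by construction, so
recovery tests measure estimator bias, not robustness to
non-proportionality.

## Matching optimizer

Candidates with hard exclusion flags (known causal risk variants) are
removed first. The greedy recursive elimination then removes, at each step,
the sample whose exclusion minimises the composite deviation score:
KS statistic for age + KS statistic for BMI + the fraction of selected
subjects carrying each soft flag (each component's theoretical optimum is
0; each enters with equal weight; the KS statistic rather than its p-value
is used because it is already scale-free on [0, 1]). Sex balance — equal
male counts across groups — is a hard constraint: removals that would make
it unattainable at the target sizes are never considered, which also forces
the final selection to be balanced. Ties break on the lowest subject id,
making runs deterministic. The greedy trace is usually non-increasing but
cannot be guaranteed to be (from a perfectly matched oversized pool, any
removal worsens the KS terms); the implementation records the trace and
warns rather than asserting. On 14-candidate pools the greedy score is
within 10% of the exhaustive optimum in the test fixtures; no global
optimality is claimed.

## Statistical primitives

* **Fractional regression**: quasi-likelihood GLM with logit link on
  fractional responses; the group coefficient is a log odds ratio. SEs and
  percentile CIs come from a nonparametric bootstrap resampling subjects
  (default 2000 replicates, seeded); p-values are normal approximations on
  the bootstrap SE. Degenerate (constant) responses return log-OR 0, p 1.
* **Secretion group tests**: linear regression of log potential on group
  with the same bootstrap machinery; zero potentials are offset by half the
  smallest positive value before the log (logged when it happens);
  all-zero metabolites are skipped.
* **Variance explained**: best fractional-polynomial fit of degree ≤ 2 with
  powers from {−2, −1, −0.5, 0 (log), 0.5, 1, 2, 3}, repeated powers
  contributing x^p and x^p·log x, selected by residual deviance; regressors
  with non-positive support are shifted positive first, as fractional-
  polynomial software does.
* **Fisher exact test**: two-sided p by explicit hypergeometric enumeration
  (sum of table probabilities ≤ the observed one, with a 1e−7 relative
  tolerance for floating-point ties), verified against the closed form.
* **BH FDR**: step-up with a declared family size m ≥ number of tests.

## Problem sizes

Defaults are desk-scale by choice: the demo pipeline uses a 5-strain panel,
59 microbiome subjects, a 60-subject × 3-wave metabolome and a
2000-subject survival cohort; the recovery protocols use 200 replicate
cohorts for longitudinal quantities and 100 replicates at the full
10,034-subject scale for the Cox analysis. At these sizes the full test
suite and the recovery script each complete in about one to two minutes on
a single CPU.

## Known limitations

* Toy reconstructions are not mass- or charge-balanced beyond the carbon
  and sulfur skeletons they model; they are designed for qualitative
  pathway topology and exact LP arithmetic, not biological flux values.
* The abundance-capacity constant (100) sets the scale of all secretion
  potentials; group-test effect sizes are therefore in "capacity units",
  and only their signs, orderings and test properties are meaningful.
* Ordinal UPDRS models ignore within-subject correlation.
* The interaction screen fits each ordered pair independently, as the
  original analysis does; embedded effects between trajectory-carrying
  metabolites are partially absorbed by the omitted group×wave terms, which
  is a property of the published model, not of this implementation.
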