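# Methods

This note documents the models implemented in `gutflux`, the
parameters that matter, the synthetic cohort the tests run on, and the
numerical and design choices that were genuinely open.

## Constraint-based core

A metabolic model is a stoichiometric matrix S with flux bounds; FBA
maximises an objective reaction subject to `S·v = 0` and the bounds,
FVA reports per-reaction flux ranges with the objective optionally
held at a fraction of its optimum, and a reaction is *blocked* at
tolerance ε if no feasible state gives it |flux| ≥ ε. All LPs run on
HiGHS via `scipy.optimize.linprog`, which is deterministic for a fixed
problem. Tolerances: primal/dual feasibility 1e-9, reporting 1e-6,
consistency ε = 1e-4 (community standards; nothing in the analysis is
sensitive to them at toy scale). Exchange reactions are written
`metabolite ↔ (outside)` with negative flux = uptake; diets act on
exchange lower bounds.

Because alternate optima are real (parallel pathways give degenerate
vertices), no analysis in this package compares raw interior fluxes
across runs; comparisons use objective values, exchange fluxes that
are unique by construction (see the synthetic models below), or FVA
envelopes.

SBML (Level 3 with flux bounds) goes through cobrapy; the package also
defines a small JSON dialect (`id`, `metabolites`, `reactions` with
explicit bounds and GPR strings, `genes`, `objective`) used for the
synthetic models. cobrapy additionally serves as the *independent
oracle* for FBA/FVA/blocked-reaction results in the test suite — the
implementation under test never calls it.

## Community models with coupling

Per sample, member models are merged with one compartment per member
plus a shared environment. Member exchange reactions become internal
member↔environment transfers (positive = secretion); one community
exchange per environmental metabolite connects to the diet/host side.
Each member's biomass reaction feeds a member-biomass metabolite that
a community biomass reaction consumes with stoichiometry equal to the
member's relative abundance aᵢ, so at any feasible point
`v_bio,i = aᵢ · v_community` exactly — growth proportions match the
observed composition by construction, not approximately. Coupling
rows `−c·v_bio,i − u ≤ v_j ≤ c·v_bio,i + u` with defaults c = 200 and
u = 0.01 mmol·gDW⁻¹·h⁻¹ are added for every non-biomass member
reaction; with v_bio,i = 0 they force |v_j| ≤ u. Members are screened
before assembly: each candidate is grown alone on the diet and removed
if its growth rate is strictly below 10⁻³ h⁻¹; the surviving
abundances are renormalised to sum to 1 (the renormalisation is a
package choice — the alternative of keeping the raw weights changes
only a global scale).

Exchange decomposition per metabolite m: host exchange is the
community exchange flux; microbial exchange is
`Σᵢ |v_int,i,m| − |v_host,m|`, algebraically `2·min(P, C)` with P/C
the summed member secretion/uptake. The absolute value of the overall
flux is used in the subtraction so the quantity is non-negative by
construction. Taxon contributions sum signed internal exchanges per
taxonomic rank, with unlabelled members pooled under "Other".

### Agent-based arena

The individual-based alternative stresses competition instead of
enforced proportionality. It is a deliberately minimal variant:
individuals are placed uniformly at random (seeded) in numbers
proportional to abundance; each step iterates individuals in seeded
random order; an individual's uptake bound per metabolite is its
cell's pool divided by (gDW · Δt); it solves its own FBA, updates the
pool, accumulates biomass, and splits into a 4-neighbour cell when its
biomass doubles; pools then diffuse at rate 0.5/step to the four
neighbours. Unit conversion: a concentration of 1 mM in a cell of
nominal volume 0.01 L is 0.01 mmol; with 10⁻³ gDW per individual and
Δt = 1 h the derived uptake bounds sit on the same mmol·gDW⁻¹·h⁻¹
scale as the models. Defaults: a 100×100
grid, 3 steps, and 1 mM chorismate/indole/salicylate supplements; the
synthetic pipeline runs a 20×20 arena with 40 individuals, which
preserves every qualitative contract at a fraction of the cost. The
simulation is bit-reproducible under a fixed seed. No fidelity to any
particular published agent framework's trajectories is claimed — the
movement/duplication physics of such frameworks is richer than needed
for the exchange summaries used here.

## Context-specific host models

Counts are converted to TPM (`(count/length) / Σ(count/length) × 1e6`).
Reaction expression evaluates the GPR tree with OR → sum (isozymes
add) and AND → min (complexes are limited by the scarcest subunit);
genes absent from the table score 0 (absent ≈ unexpressed, logged);
reactions without a GPR carry no expression evidence and are neither
core nor inactive — they remain available to FASTCORE as support
candidates. Thresholds: global lower/upper = pooled 10th/90th
percentiles of **all** reaction-expression values of the tissue
(reactions × samples pooled; the per-tissue pooling is one of two
defensible readings and is flagged as such), local = per-reaction 50th
percentile across samples. Below the lower bound (strict) → inactive;
above the upper bound (strict) → core; in between → core iff strictly
above the local threshold, else undetermined. Undetermined reactions
are retained as non-core candidates; only sub-lower-bound reactions
are removed. Percentiles use linear interpolation; the variant only
shifts boundary cases and is fixed for reproducibility.

Extraction removes the inactive set, restores consistency by pruning
blocked reactions, drops (with a logged warning) core reactions that
became unrealizable, and runs FASTCORE — the published two-LP
algorithm: LP7 maximises the number of core reactions carrying flux
≥ ε, LP10 minimises the L1 norm of the non-core support with the
found core flux forced (bounds scaled by 1e5 so support detection at
0.99·ε is safe), with the reversible-flip / singleton escalation loop
of the original method (flipping negates a reaction's stoichiometry
and mirrors its bounds). ε = 1e-4. The output provably contains the
realizable core and is flux-consistent; it is compact but not
guaranteed minimum-cardinality, which matches the method's own
contract — the tests report the size ratio against an exhaustive
minimal-subnetwork search on small instances.

The four layers per reaction × sample: rxnExpr (the GPR score), PA
(presence in the extracted subnetwork), FVA.range = max − min and
FVA.center = (max+min)/2 from FVA run on the context model at
fraction-of-optimum 0 (capability estimation; the context models have
no enforced objective). Absent reactions have range/center flagged
missing, not zero.

## Longitudinal statistics

Metadata preparation censors disease scores at 16 (harmonising HBI
with the Mayo scale's range) and imputes missing scores per patient
from the least-squares line of score against time (a single
observation is carried constant); patients with no observed score are
excluded.

Feature layers are filtered for near-zero variance (frequency ratio
> 95/5 **and** unique-value percentage < 10), z-scaled per feature,
and clustered with DBSCAN (eps = 0.1, minPts = 3) on the correlation
distance `d = 1 − sqrt(ρ²)`; each cluster is tested once through its
medoid (largest mean |ρ| to members) and members inherit the
representative's result. Because the distance uses |ρ|, a cluster can
contain anti-correlated features (a secretion flux and the uptake it
drives); inherited estimates, t-values and confidence bounds are
therefore flipped by the sign of the member's correlation with the
medoid — for z-scaled features the member is ±medoid up to noise, so
this is the coefficient it would have received itself. Only very
highly correlated features cluster at this eps, typically consecutive
reactions of one pathway.

The association model per feature is a REML linear mixed model with
the disease score as the dependent variable, the (scaled) feature as
predictor and a patient random intercept, so coefficients are
comparable across features and positive estimates mean higher activity
with higher inflammation. The Wald statistic is referred to a normal
distribution — statsmodels does not provide Satterthwaite degrees of
freedom, and at the cohort sizes used here the normal approximation is
accurate, as the calibration checks (type-I error within [0.03, 0.07]
at α = 0.05, CI coverage ≥ 90%, bias < 10% at 30 patients × 4 time
points) verify empirically. Optimiser fallback (lbfgs → bfgs → powell)
handles occasional singular Hessians; features whose fit still fails
are reported NA and stay in the BH denominator. The binary PA layer
enters the same linear model as a 0/1 predictor — consistent with
treating each layer identically — rather than a logistic variant.

Outcome models (response, remission) are logistic mixed models fitted
by variational Bayes (`BinomialBayesMixedGLM`), optionally controlling
for disease activity; the shrinkage priors of that estimator double as
the penalised fallback under separation. Samples from the
remission-defining week (14) are excluded when remission is the
outcome. Benjamini–Hochberg adjustment is applied per layer with NAs
passed through. Enrichment: upper-tail hypergeometric per annotation
set, and GSEA as a weighted (exponent 1) running-sum score with a
seeded permutation null over feature labels; metabolite-incidence
annotation (reactions containing a metabolite) gives hub-metabolite
enrichment, and a substrate/product × up/down tabulation summarises
how hubs are used. The across-tissue overlap test draws |A| and |B|
uniformly from the two universes and reports the add-one permutation
p-value. Taxon contribution uses flux ~ 0 + taxon with a patient
random intercept (taxa in < 5 samples pooled to "Other"), a
likelihood-ratio test for the taxonomy factor, and per-taxon tests
against zero.

## Metabolite networks

Nodes are metabolites of the significant reactions; each
substrate–product pair contributes an undirected edge (parallel edges
merge, pooling reaction ids); substrate–substrate pairs do not,
reversibility is ignored. Edge length is the natural log of the sum
of the endpoint degrees in the final simple graph — a hub penalty that
makes paths through currency metabolites expensive without deleting
them (the top hubs are themselves biologically informative); a
currency-exclusion hook exists but is off by default. A simple edge
always has degree sum ≥ 2, so lengths are positive. Distances are
exact Dijkstra; reported node sequences break ties lexicographically
so the pipeline is deterministic. "Closely connected" pairs fall below
the lower 5% percentile of all finite pairwise distances; category
pairs (Hub–Met, Hub–Mic, Mic–Met) are compared to all remaining pairs
with one-sided Welch t-tests (BH over the three classes), and the
reactions along selected paths are enriched hypergeometrically against
all reactions in the graph.

## Dietary intervention screen

Targets are metabolites with consistent association signs: significant
for at least one inflammation proxy, with every significant estimate
across simulation methods and proxies sharing one sign; any conflict
excludes the metabolite. Interventions set a dietary metabolite's
maximum uptake to zero (remove) or double it (double) — "concentration
doubled" maps to the uptake bound because the models are bound-, not
kinetics-based. Each community is re-simulated; before/after target
fluxes are compared with a two-sided paired Wilcoxon signed-rank test,
exact for ≤ 25 non-tied pairs and normal-with-continuity above, BH
over (intervention × target) cells. The fold change is
`mean(log2(after/before))` over communities with same-signed nonzero
pairs; zero-baseline and sign-flipping pairs are excluded from the
mean and counted separately. Classification (only for cells with
adjusted p < 0.05): direction_flip if most pairs change flux sign;
otherwise |FC| must exceed log2(1.05) ("exceeding 5%" read on the FC's
own scale), and the signed median change is compared with the target's
inflammation sign — a change opposing the association (e.g. more of a
negatively associated metabolite) is desired, reinforcing it is
undesired.

## Synthetic cohort

The generator defines the cohort conditions the tests run under:
20 patients × 4 time points (weeks 0/2/6/14), ~20% healthy, ~50%
responders (exponentially declining scores), the rest non-responders;
scores carry noise, occasionally exceed 16 before censoring and are
missing at ~10% so the censoring/imputation paths are exercised.
Abundances are logistic-normal with patient-level intercepts (temporal
autocorrelation) and a planted −0.18 logit/score-unit slope on the
butyrate producer. Six toy bacteria (8–14 reactions each) share one
metabolite namespace with the diet, the host model and the
metabolomics panel, so cross-layer identifier mapping is the identity;
a mapping hook mirrors the real-world need. Each template has a
*single* catabolic route, making every internal flux a fixed multiple
of the member's growth — community optima are vertex-unique and
exchange fluxes are comparable across runs. The diet keeps lactate
scarce; the generalist and the propionate producer both consume it,
so lactate supply limits community growth. Consequences used by the
tests: butyrate host exchange is proportional to the butyrate
producer's abundance (negative association with disease), and doubling
dietary lactate doubles community growth and butyrate output — the
planted "desired" intervention.

Host expression is negative-binomial (dispersion 0.1) with gene-level
patient intercepts (sd 0.3) and ±0.08 log-units per score unit planted
on the genes of one down- and one up-regulated subsystem out of eight;
two other subsystems are designated nulls. The host model is eight
5-reaction GPR chains (single-gene, OR, AND and nested rules) with
entry exchanges and terminal demands; because chains are linear, an
inactive reaction blocks its downstream core — deliberately exercising
the dropped-core warning path. Serum metabolomics is log-normal with
planted effects on butyrate and tryptophan (down) and cholate (up)
plus 15 null markers.

Recovery is judged per feature in its primary layer (microbial
exchanges in the host-exchange layer, host reactions in rxnExpr,
metabolites in metabolomics). Planted *nulls* for false-positive
accounting are host null-subsystem reactions and null serum
metabolites only: microbial null taxa are compositionally coupled to
the planted decline (their relative shares rise as the butyrate
producer falls), so their exchanges carry real, not spurious,
associations — a property of compositional data, not an artefact.

What the generator does not emulate: genome-scale model sizes,
sequencing error, compositional zero-inflation, batch effects,
nonlinear score trajectories, and measurement error in the diet. A
passing end-to-end run therefore demonstrates that the machinery is
correct and calibrated under its stated generative model, not that
effect sizes of this magnitude are detectable in real cohorts.

## Problem sizes and determinism

The default test/acceptance scales — 80 samples, 6-member communities,
a 56-reaction host model, 1000 null features for calibration, 40–100
random instances for the oracle comparisons — were chosen so the whole
suite completes in minutes on a single CPU while every contract is
exercised at meaningful sizes. All randomness flows from explicit
seeds (`numpy.random.default_rng`); the pipeline records a config hash
and per-output checksums so deterministic stages can be verified to
reproduce bit-identically.
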