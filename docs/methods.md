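# Methods

This note documents the models, estimators, and numerical choices behind
`fluxvar`, and what its synthetic experiments do and do not establish.

## Chemostat dFBA model

The community lives in a well-mixed vessel of volume V (default 0.00134 l, a
mouse-gut scale) with continuous dilution at rate D (default 0.0472 h⁻¹) and
constant nutrient inflow. Time advances in discrete steps of Δt = 0.25 h; the
default horizon is 576 steps (144 h), long enough for most runs to approach —
without fully reaching — a steady composition. A near-steady-state sentinel
(`SimulationTrace.near_steady_state`: no species moves by more than 0.01% of
the carrying capacity over the final 3 h) is computable on any trace.

Per step and species, uptake of metabolite *j* is bounded by the smaller of

* the Michaelis–Menten rate V·M/(Kₘ+M) with universal defaults
  Vmax = 20 mmol gDW⁻¹ h⁻¹ and Kₘ = 0.01 mM (no species- or
  metabolite-specific kinetics are modeled), and
* an allocation cap: the species may consume at most its biomass-proportional
  share of the current pool over the step. The cap is an *amount*, converted
  to a rate bound by inverting the step-growth integral
  bio·(e^{μΔt}−1)/μ at the species' previous-step growth rate (zero-growth
  limit on the first step).

Fluxes are then solved by a two-stage LP (HiGHS, single-threaded,
deterministic): maximize the biomass flux, then minimize Σ|v| (forward /
backward split variables) with growth pinned to within a relative
ε = 10⁻⁹ of the optimum. The parsimonious stage resolves degenerate
alternative optima and makes traces reproducible.

Updates use the discrete factors exactly as written in the update equations
(D·Δt, not e^{−DΔt}); exchange amounts are integrated over the
exponentially growing biomass, mFBA = v·bio·(e^{μΔt}−1)/μ, with a
third-order series below |μ| = 10⁻¹⁰ (computed via `expm1` to avoid
cancellation), and divided by V to convert mmol to mM. All per-step amounts
— exchanges, inflow, dilution outflow — are recorded, so the accounting
identity ΔM = Σₖ mⱼₖ + m_in Δt − M·D·Δt can be re-verified on any trace;
the test suite holds it to 10⁻⁹.

Because the solved growth rate of a step can exceed the previous-step rate
used to invert the allocation cap, a strict per-step no-overdraw guarantee is
not attainable under this convention; concentrations are clamped at zero with
the adjustment recorded (so the accounting identity stays exact) and a
warning counter exposed. In all shipped configurations the counter is zero,
and tests assert as much.

## Toy communities

`make_toy_community` stands in for curated genome-scale reconstructions.
Each species grows on 2–4 shared primary substrates (stoichiometric
coefficients from a seeded uniform grid, 1–4 per unit growth) and may secrete
up to two byproducts. A configurable fraction of environmental metabolites is
cross-fed: secreted as a growth byproduct of one species and convertible by
at least one *other* species into one of its own substrates via a
salvage-style conversion reaction. Making cross-fed inputs substitutive
rather than obligate guarantees every species grows autonomously in the
generated environment while still allowing cross-feeding to shape dynamics.
Inflow rates for primary substrates come from a seeded grid (1–5 mM h⁻¹);
initial concentrations are primed with one hour of inflow. Non-exchange
reaction bounds default to ±1000 mmol gDW⁻¹ h⁻¹.

These toys reproduce the *structure* of real communities (competition for
substrates, cross-feeding chains, emergent carrying capacity) but not their
scale: real gut reconstructions have hundreds of internal reactions,
species-specific transporter kinetics, and curated media. Passing tests
therefore validate the framework's identities and qualitative mechanisms,
not numerical agreement with any particular biological dataset.

## Variance decomposition

For per-step amounts m(t₁…t_N) and per-step dilution fraction d = D·Δt, the
dilution-corrected cumulative flux weights each amount by (1−d)^(N−1−k) —
the fraction surviving to the end of the run. The inflow series is
discounted identically, and the surviving share of the initial concentration
(itself derived from inflow priming) is folded into the environmental
column, so M = m_env + Σᵢ mᵢ\* holds exactly per sample (tested to 10⁻⁶,
achieved at ~10⁻¹⁵).

Contributions use the unbiased (n−1) covariance estimator throughout —
including inside Shapley marginals — so the conservation identity
Σcᵢ + c_env = var(M) and the equivalence cᵢ = cov(mᵢ, M) hold to machine
precision rather than approximately. Profiles require ≥ 3 samples;
zero-variance metabolites yield a NaN-relative sentinel. Key contributors
are species with cᵢ above 10% of the summed positive contributions (a
positive environmental term counts toward the denominator; the environment
itself is never flagged).

The Shapley estimator averages marginal variance changes over sampled
species orderings with the environmental column in the base set, switching
to exhaustive enumeration when n! does not exceed the requested ordering
count. With the environment in the base set, each marginal carries
2·cov(mᵢ, m_env) rather than the decomposition's single covariance, so exact
equivalence with the analytic cᵢ holds when the inflow is constant across
samples — the setting of the reference dataset — and equivalence tests use
constant-inflow tables.

## Evaluation pipeline

Variable metabolites are those with cross-sample variance strictly above the
25th percentile of all metabolite variances (numpy linear-interpolation
quantile; the strict inequality excludes zero-variance metabolites
regardless of the quartile). Spearman correlations use mid-ranked ties with
an exact n!-permutation p-value for n ≤ 9 and the t approximation otherwise.
Three significance policies are provided: raw p < α (default α = 0.01),
BH-adjusted ≤ q, and "matched FDR" — the raw cutoff translated into its
implied BH threshold over the evaluated family, which is the cutoff reused
for subgroup screens. Pairs with a constant series are reported as NA and
excluded from denominators, with the exclusion count carried in the metrics
report.

AUC uses the Mann–Whitney rank formulation on |rho| against the
key-contributor label, with a percentile bootstrap CI (default 500
resamples). Identity models are binomial GLMs with grouped indicators for
species and metabolite, compared by likelihood-ratio χ² tests in two strata
(false positives among non-contributors; false negatives among key
contributors); complete separation is detected and reported. Subgroup
consistency confirms a link only when it is significant with a consistent
sign in every subgroup of at least 4 samples, and also reports the relaxed
k-of-n tally. Environmental binning assigns each metabolite-dataset
instance to half-open bins of the environmental share of the positive
contribution total, with the constant-inflow dataset and inflow-absent
metabolites kept as separate categories.

## Experiments and problem sizes

The composition design fixes total initial biomass to the carrying capacity
and perturbs one species at a time to initial-abundance ratios
(2, 3, 4.5, 6, 9, 13) over the rest — 61 compositions for 10 species. The
carrying capacity can be estimated as the mean final total abundance over a
few low-inoculum runs (`estimate_carrying_capacity`), mirroring how such a
capacity is defined operationally. Inflow fluctuations draw each
metabolite's inflow independently from a normal with mean equal to the base
rate and standard deviation cv·mean, truncated at zero (inflow cannot be
negative) with a logged count; the built-in sweep enumerates cv ∈
{0.5%, 1%, 2%, 3%, 4%, 5%, 8%, 10%} plus the constant baseline.

Two desk-scale reference experiments keep the default test suite fast:

* the conservation benchmark — 4 species, 8 metabolites, 50% cross-feeding,
  13 compositions (ratios 2, 4.5, 13), 100 steps of 0.25 h;
* the mini fluctuation sweep — 6 species, 12 metabolites, 19 compositions,
  300 steps (75 h) at cv ∈ {0, 5%, 10%}, binned into thirds of
  environmental share. The longer horizon lets communities approach steady
  state so that inflow fluctuation becomes a substantial variance source and
  multiple environmental-share bins are populated; with shorter runs the
  composition-driven microbial variance swamps the inflow signal and the
  sweep collapses into a single bin.

The synthetic flux generator draws species/environment flux vectors from a
specified multivariate normal and constructs M as their sum, so analytic
contributions (row sums of the covariance) are exact ground truth; planted
motifs cover the sole producer (relative contribution exactly 1), the
compensating pair (negative contribution), and the masked producer (the
helper solves the two-parameter family m₂ = −(1−δ)m₁ + e for the δ and
noise variance that hit a requested contribution-to-variance ratio such as
71.7).

## Known limitations

* No spatial structure, pH/oxygen dynamics, regulation, or stochastic
  kinetics; species interact only through the shared metabolite pools.
* Universal Vmax/Kₘ and generated stoichiometries mean absolute fluxes are
  not calibrated to any organism.
* The amount-based allocation cap inverted at the previous step's growth
  rate is one of several defensible conventions (a pure rate cap is the
  obvious alternative); it is configurable in principle and its failure
  mode (overdraw clamping) is instrumented rather than hidden.
* Exact Spearman p-values are enumeration-based only up to n = 9; beyond
  that the t approximation is used, so tail p-values at small-to-moderate n
  are approximate.
* SBML input is not implemented; models are read from the documented JSON /
  TSV-triplet formats or generated.
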