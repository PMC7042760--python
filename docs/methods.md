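# Methods

This note documents the models and numerical choices behind `pollinet`:
what each stage computes, the defaults and why, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Sampling model and network assembly

The sampling unit is a timed transect walk; every recorded flower visit
is one event. One quantitative network is built per walk, so all species
in a matrix co-occurred in space and time, and morphospecies labels only
need to be consistent within a walk. Three pollinator groups enter
networks (bees, non-bee aculeate wasps, syrphid flies); all other
visitors are mapped to `other` and always excluded. Networks with fewer
than five total events (`min_interactions=5`, counted on the event total
m, not on distinct links) are dropped. Rows are plants ("lower level"),
columns pollinators ("higher level"), both sorted lexicographically, and
every downstream index is invariant to row/column permutation (tested).
Pooling walks into one joint network per site (`pool_site_networks`,
default minimum five walks) matches species by label within the site —
an approximation for morphospecies, which is why pooled networks are
used only as a sensitivity analysis, not as the primary unit.

## Specialization indices

**d′.** The observed use distribution of a focal species is compared
with partner availability (partner marginal totals / m) by KL
divergence. The upper reference is the closed form ln(m/A) — all events
on the least-available partner — rather than an integer-constrained
maximum; clamping keeps d′ ≤ 1 in the rare cases where the observed d
exceeds it. The lower reference d_min is the KL divergence of the *most
generalized integer allocation* of the species' A events: largest-
remainder rounding of the proportional allocation A·q, then single-unit
transfers while they lower the divergence. Because the objective is
separable and convex in the allocation, unit-step descent terminates at
the global integer optimum; the test suite verifies equality with
exhaustive enumeration over all allocations on every 2×2 and 2×3 matrix
with m ≤ 8.

**Community summaries.** The community mean of d′ is abundance-weighted
(weights = species event totals); an unweighted mean is also emitted
because both conventions exist in field practice, and the choice is a
reporting option rather than a model assumption. The coefficient of
variation uses the unweighted d′ values and population sd (denominator
n; switchable to sample sd); it is undefined (missing, never 0) for
singleton communities or zero means. Species mean d′ averages a species'
walk-level scores, requiring at least three occurrences by default.

**H₂′.** The two-dimensional entropy of a/m is standardized between the
extreme entropies achievable by integer matrices with the observed
marginals. The maximum-entropy table starts from largest-remainder
rounding of the independence expectations A_i·A_j/m with marginal
repair, polished by steepest-ascent 2×2 unit swaps (the swap moves
connect all tables with fixed marginals; the objective is concave, so
unit steps suffice). The minimum-entropy table is a vertex of the
transportation polytope: a greedy fill pairing the largest remaining
marginals, followed by vertex-hopping descent in which each candidate
2×2 swap is pushed to its full extent. Because concave minimization can
hide the optimum behind a worse vertex, on small matrices
(≤ 24 cells) the greedy fill is restarted from every possible first
placement and the most concentrated start is kept before polishing; on
all 2×2 and 2×3 matrices with m ≤ 8 the result provably equals the
enumeration optimum (tested), while for large matrices the single-start
heuristic is an approximation shared with standard implementations of
this index. Networks with fewer than two species on either level or
fewer than two events return a typed `NotComputable` result — never a
silent 0 — because the index is undefined there.

**WNODF and dependence asymmetry.** WNODF follows the
overlap-and-decreasing-fill rule for weighted matrices, with ties in
marginal totals scoring zero; it is validated against an independent
brute-force pairwise evaluator. Dependence asymmetry uses the signed,
max-normalized per-link form (pollinator dependence minus plant
dependence over the larger of the two, averaged over links), which spans
−1…1 with positive values meaning the higher trophic level depends more;
the variant is configurable in principle because more than one definition
circulates, and the implementation satisfies dep_asym(Aᵀ) = −dep_asym(A)
exactly.

## Null models and standardization

Absolute nestedness and robustness depend on network size, so both are
reported as z-scores against ensembles of random integer tables with
exactly the observed marginals. Sampling uses Patefield's algorithm
(via `scipy.stats.random_table`); 1×n tables are fully determined by
their marginals and short-circuited. The default ensemble size is 1,000
(configurable); the sampler itself is exchangeable through the
`sampler` argument. Per-network random streams are derived from
(study seed, network id), so results do not depend on processing order.
A zero null sd flags the ensemble as degenerate; z is 0 when the
observed value equals the null mean exactly (marginal-determined
metrics) and missing otherwise. Calibration: the z of a metric computed
on networks that are themselves null draws has mean ≈ 0 and sd ≈ 1
(tested at 200 replicates with ensembles of 200).

## Robustness

Species of one level are removed in random order, removed species' rows
are zeroed, and species of the other level with no events left go
secondarily extinct. The survivor curve is evaluated on normalized axes
including the endpoints (0,1) and (1,0) and integrated by the trapezoid
rule — stated explicitly because area conventions differ between
implementations; with this convention an identity matrix gives exactly
R = 1/2 and a fully connected network with p removed species gives
1 − 1/(2p). R averages 100 random removal orders by default (the Monte
Carlo SE is reported); only random orders are simulated, but the API
accepts explicit orders so trait-based scenarios remain possible.
Standardized robustness recomputes R on each null table with the same
number of orders.

## Land-use intensity

LUI is the mean of four z-scored site-level components: biomass
removal, agricultural inputs, vegetation-structure dissimilarity, and
the agricultural proportion of the surrounding landscape. The
dissimilarity component z-scores the raw structure variables across all
sites first and then takes the Euclidean distance to the mean vector of
*natural* sites in the same elevational band (bands are the habitat-zone
labels supplied in the metadata, not numeric bins), because raw
structure varies with elevation for natural reasons. Standardization is
z-scoring; min–max is available as an option since "standardized" admits
both readings. A missing component falls back to the mean of the
available ones (logged); a zero-variance component contributes 0.

## Gradient models

Walk-level metrics are regressed on site-level predictors with a random
site intercept (REML, `statsmodels` MixedLM; the optimizer result is
polished by a second conjugate-gradient fit and the higher restricted
likelihood kept, which recovers the closed-form ANOVA variance
components to ~1e-6 on balanced designs). Inference uses
containment-style denominator df: predictors constant within sites are
tested on the between-site stratum (G − 1 − p_between), within-site
predictors and the intercept on the within stratum (N − G − p_within);
with one between predictor this yields the familiar (N − G, G − 2)
pattern. t = estimate/SE everywhere; t-values, not df, are the primary
comparison across software. The variance share of a single fixed effect
is var(xβ)/(var(fixed) + var(random) + var(residual)) — the marginal-R²
decomposition in the Nakagawa & Schielzeth spirit, documented as an
approximation to semipartial R². Model comparison (elevation vs LUI)
refits both models by ML on identical complete cases and compares
AICc = AIC + 2k(k+1)/(n−k−1), reporting AICc(LUI) − AICc(elevation)
(negative → LUI better, |Δ| ≤ 2 → similar support). The intraspecific
model uses crossed species and site random intercepts (variance
components on a constant group); trait models use a genus random
intercept for the group contrast and nested order/family/genus terms for
trait slopes. The robustness-predictor model backward-eliminates the
least significant of {H₂′, standardized nestedness, MAT, LUI} while any
p > .05 and reports the elimination trace. Five sensitivity analyses
re-express the gradient result under site means (OLS), an elevation
cutoff, pooled networks, open habitats, and the AICc contest.

## Path analysis

All variables are z-transformed. Each endogenous node is fit on its
graph parents with a random site intercept (OLS fallback when grouping
is absent or constant). The d-separation basis set takes variables in a
deterministic lexicographic topological order and, for each non-adjacent
ordered pair, regresses the later variable on the earlier one plus the
later variable's parents — the later-as-response convention is fixed for
determinism. Fisher's C = −2 Σ ln p is χ² with 2k df under a compatible
structure (calibration verified by simulation: p_C uniform at n = 60).
Model score: AICc = C + 2K·n/(n − K − 1), with K the count of estimated
parameters across component models (fixed coefficients + intercepts +
random-effect and residual variances) and n the study-level number of
observations; exogenous-only marginals cancel across candidate
structures and are not counted. The exhaustive search fits every subset
of the optional edges (capped at 2¹²), sharing identical component
regressions through a cache, and ranks by AICc; AICc-based variable
preselection runs an all-subsets search within each hypothesis block and
then across the union of block winners.

## Synthetic-data generator

The generator emulates an elevational gradient study: 18 sites evenly
spaced over 993–4,390 m; MAT linear in elevation between 24.0 °C and
3.1 °C; mean annual precipitation peaking mid-slope; walks per site
uniform on 1–8 (the unbalanced design is deliberate, to stress the
mixed-model stage); log-normal flower abundance with a mild elevational
trend; plant and pollinator pools thinning log-linearly with elevation
(species occupy elevational windows, so species identity is shared
across neighboring sites); per-walk event counts negative-binomial with
mean tied to flower abundance and walk temperature; and a land-use index
constructed to hit the target elevation correlation (−0.57) exactly in
sample. The causal knob is Dirichlet-multinomial foraging: each
pollinator at a site draws a preference vector over local plants from a
Dirichlet with concentration α(MAT)·availability, α(MAT) = exp(a0 −
a1·MAT). The Dirichlet concentration maps directly onto d′/H₂′-style
specialization, which is why this family was chosen; a1 > 0 makes warm
sites more specialized, with defaults a0 = 3.0, a1 = 0.2 chosen so that
community mean d′ spans roughly 0.2–0.7 across the gradient, similar to
field ranges. All randomness flows from one seed through named
substreams, and output files are byte-identical across runs.

`GeneratorConfig.null()` defines the no-effect study used for type-I
calibration: it switches off a1 *and every other elevational dependence*
(richness decay, abundance trend, temperature–activity link). This is
deliberate: d′ carries a small finite-sampling bias that depends on
network size, so a generator in which event counts or richness trend
with elevation has a genuinely nonzero specialization–elevation slope
even at a1 = 0. With the fully flat null the elevation slope test
rejects at the nominal 5% rate (measured 5.0% over 400 studies).

What the generator does **not** emulate: phenology and seasonality,
spatially explicit foraging, observation-level misidentification,
pollinator-driven competition feedbacks, and trait–interaction matching
(traits are drawn per group but do not shape preferences). Passing
recovery tests therefore shows that the pipeline detects
Dirichlet-concentration-type specialization gradients under realistic
sampling noise and design imbalance — not that every process generating
field data is identifiable.

## Problem sizes in tests and the acceptance script

Enumeration oracles cover all 2×2 and 2×3 matrices with m ≤ 8 (≈1,900
matrices; larger shapes grow combinatorially without adding coverage of
the tie-breaking logic). Sampler calibration uses 20,000 draws; z
calibration 200 replicates × 200 nulls; Fisher's C calibration 500
simulated datasets at n = 60; parameter recovery 100 strong-effect and
200 null studies; mixed-model bias/coverage 200 balanced datasets of 60
observations in 15 sites. These sizes put Monte-Carlo error well inside
the asserted tolerances while keeping a full run in minutes.

## Known limitations

- d_max uses the closed form ln(m/A); the integer-constrained maximum
  can be slightly smaller, which the [0,1] clamp absorbs.
- H₂ extreme tables are exact on small matrices by construction and
  validated there; on large matrices they are heuristic, as in standard
  implementations of the index.
- Containment df are a deliberate convention; Satterthwaite-style df
  would differ, which is why cross-software comparisons should use
  t-values.
- The dependence-asymmetry literature contains more than one formula;
  the implemented variant is documented above and pinned by tests.
- No adaptive rewiring after partner loss in the robustness simulation;
  extinction order is random by default.
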