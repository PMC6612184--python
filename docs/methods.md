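# Methods

`traitscope` compares the functional-trait composition of microbial
communities — the motivating system is the human skin microbiome versus
bacteria at large — using culture-derived trait databases, abundance-based
species screening, and a suite of statistics chosen for the three trait
classes such databases contain. This note records the models, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
data do and do not establish.

## Trait databases and unknown values

A trait database is one row per validly described species with three trait
classes: binary traits (spore formation, pigment production, eleven enzyme
activities, gas production, nitrate reduction, per-substrate usage),
categorical traits with controlled vocabularies (oxygen use, motility, cell
shape, Gram stain, aggregation), and quantitative traits (GC content in %,
and min/maximum/optimum/range growth envelopes for temperature in °C, pH,
and NaCl in % w/v).

Culture descriptions are incomplete, so unknown values are first-class:
every proportion is k positives over n *known* values and every mean is over
known values only, with n reported alongside. Nothing is imputed. A cell
marked "v" records documented strain-to-strain variation; it contributes to
a per-record flag and is treated as unknown in denominators, since neither
state describes the species as a whole.

Categorical cells may carry several levels (a species that aggregates both
singly and in clumps). The default counting rule credits the species once
per level it exhibits, so level proportions of one trait need not sum to 1;
they do sum to 1 when every species carries a single level.

`range` cells are auto-derived as `max − min` only when empty; an explicit
conflicting value is kept and surfaced as a validation warning, because a
curated number may encode information (e.g. differing strain envelopes)
that silent recomputation would destroy.

## Screening

Species lists are built from a classification summary (per-sample relative
abundances in percent of reads at species rank). A species is *detected*
when its abundance strictly exceeds 0.001% of reads in at least one sample
and *abundant* above 0.1%, both read strictly per their "greater than"
definitions; ties at the boundary are excluded and noted in the set's
provenance. Site-restricted sets (dry / moist / sebaceous skin) apply the
same thresholds to that site's samples only. Abundances are used as given —
no renormalization after rank filtering — because screening is defined on
reported read fractions.

## Binary and categorical comparisons

Binary traits: prevalence per group with the binomial standard error
√(p(1−p)/n); an overall Pearson chi-square on the positive/negative by
group table (df = m−1, expected-count warning below 5); and pairwise
contrasts z = (p₁−p₂)/√(se₁²+se₂²) with two-sided normal p. A pooled-
variance variant exists because its z² equals the 2×2 chi-square statistic,
a relationship the tests verify. When both proportions sit on a common
boundary the contrast carries no information and p = 1 by convention,
flagged.

Categorical traits use a randomization test of equal level proportions:
group labels are permuted with the outcome multiset fixed (equivalent to
resampling without replacement), which is the exact null of "same level
composition, group sizes fixed". Per level the statistic is the spread
(max − min, the absolute difference for two groups) of the level proportion
across groups and p = (1 + #{spread* ≥ spread_obs})/(B+1), the add-one
permutation estimate; the default B = 10⁵. The overall p uses the maximum
spread over levels under the same permutations, so it needs no further
multiplicity correction but is conservative, as any joint max-statistic
test is; calibration checks therefore target the level-wise p. The fraction
of strictly less extreme resamples is reported alongside for transparency.
With pooled n ≤ ~12 an exact mode enumerates all label assignments instead.
The resample stream is canonicalized (groups and within-group rows sorted)
so a given seed yields the same p-values for any observation order.

No multiple-testing correction is applied across traits by default; an
optional Benjamini–Hochberg switch exists and is off unless requested.

## Quantitative comparisons

Quantitative traits are compared through the relative effect
p = P(X < Y) + ½P(X = Y), computed by midranks of the pooled sample
(placement formulation), which equals the brute-force count over all pairs
— a property the suite verifies exhaustively. The test of H₀: p = ½
studentizes with the Brunner–Munzel variance built from placement variances
and refers to a t distribution with Satterthwaite degrees of freedom. This
family is used because growth-envelope data are skewed, heteroscedastic and
tie-heavy; midranks handle ties throughout. Degenerate placement variance
(complete separation, or all values tied) cannot be studentized: the result
is flagged, with p = 1 when p̂ = ½ and otherwise the exhaustive-permutation
lower bound 2/C(n₁+n₂, n₁) — the t reference's minimum of 0 is not usable
as a convention.

All-pairs (Tukey-type) contrasts over ≥2 groups adjust jointly with the
single-step equicoordinate probability P(max|Z| ≥ |t|) under a multivariate
normal whose contrast correlation is estimated from the shared-group
placement-variance contributions (contrasts without a shared group are
treated as uncorrelated). The quantile is Monte-Carlo (20 000 draws,
seeded). If the correlation estimate is not positive definite, or any
contrast is degenerate, the adjustment falls back to Šidák and the results
are flagged. Two-group runs reduce to the plain Brunner–Munzel contrast
with p_adjusted = p_raw. Family-wise error under a three-group null is
verified by simulation.

## Naive and phylogenetically corrected regression

To ask whether a trait predicts membership (abundant vs rare, skin vs
world) beyond shared ancestry, membership is regressed on each trait
individually — never multivariately — both naively and with phylogenetic
correction, and each fit is screened against its intercept-only null with
a likelihood-ratio test (statistic 2Δℓ clipped at 0, chi-square reference,
df = number of slope parameters; categorical predictors are dummy-coded
against a configurable reference level).

The corrected model is a Bernoulli GLMM in the Ives–Garland tradition:
logit P(yᵢ=1) = xᵢ′β + uᵢ with u ~ N(0, σ²C(α)), where C(α) is the tip
correlation of a mean-reverting (Ornstein–Uhlenbeck) process evolving on
the tree *conditioned on the root state*. On a tree scaled to unit height,
with root-to-tip depths Tᵢ and root-to-MRCA depths sᵢⱼ,

    Cᵢⱼ = e^(−α(Tᵢ+Tⱼ−2sᵢⱼ)) (1 − e^(−2αsᵢⱼ))
          / √((1 − e^(−2αTᵢ))(1 − e^(−2αTⱼ))) .

α → 0 recovers the Brownian-motion correlation sᵢⱼ/√(TᵢTⱼ); α → ∞ and
σ² → 0 both recover independence. Conditioning on the root means tips with
no shared internal branches are exactly uncorrelated, so on a star tree the
model collapses to — and the implementation returns — the naive fit.

Estimation maximizes the Laplace-approximated marginal likelihood:
(β, u) by penalized IRLS with step-halving (tolerance 1e-8 on the
penalized objective, ≤200 iterations), (log σ², log α) by Nelder–Mead with
seeded random restarts, σ² ∈ (e⁻¹⁸, e⁶], α ∈ [e⁻⁶, e⁵]. The σ² → 0
boundary is the naive model, and a corrected fit is never reported with a
log-likelihood below the naive one. Separation (|β| > 12) and
non-convergence are flagged, never silent.

Two numerical facts shape the LRT here. First, Laplace likelihoods do not
preserve nesting exactly (the curvature term is evaluated at different
modes), so deficits up to 0.05 nats clip to a zero statistic while larger
ones raise as optimization failures. Second, independently optimized null
and full fits would give whichever model got luckier starts an advantage,
so the paired screening helper cross-warm-starts each model's signal
parameters at the other's optimum until the pair is consistent.

Simulations characterize the estimator honestly: under a null in which both
traits evolve on the tree (two-state Markov, no true association), the
naive LRT rejects at several times the nominal 5% while the corrected LRT
stays near nominal, and the corrected p exceeds the naive p in roughly
three quarters of replicates — the exceptions are diffuse cases with both
p-values far from significance, where approximation noise dominates. A
simulated β₁ = 1.5 effect on 200-tip trees has its sign recovered in
essentially all replicates.

Species names are matched to tree tips case-insensitively with underscores
and spaces equivalent; species absent from the tree are dropped and
counted, mirroring the practice of ignoring the handful of taxa a reference
ribosomal tree lacks. Branch lengths are scaled to unit tree height before
fitting so α is comparable across trees.

## Synthetic data

The generator defaults encode the study conditions the package is exercised
under: a skin-like cohort of 971 species against a 3 000-species world-like
cohort; binary prevalences at the reported contrasts (spore formation 3% vs
22.5%, catalase 47% vs 57%, oxidase 25% vs 47%, pigment 55% vs 68%, glucose
use 91%); categorical shifts (abundant skin taxa half as likely aerobic,
favoring facultative metabolism; clumps over chains); growth envelopes
centred on the reported means (pH maximum 7.97 vs 9.03, temperature optimum
≈33 vs ≈31 °C, NaCl minimum 1.09 vs 0.02%); GC 51.7% vs a chosen 55%; and
15% missingness per trait, completely at random (a phylum-clumped
missingness mode exists for robustness probes, off by default). The world
cohort size and world-side values the study does not print are single fixed
choices at realistic magnitudes, not tuned quantities.

Envelopes are generated coherently — minimum ~ N(μ_min, sd), width
truncated positive, optimum at a jittered interior point — so min <
optimum < max and range = max − min hold by construction. A consequence:
the sd of a generated maximum is ≈ sd·√2.

Phylogenies are pure-birth (Yule) trees with an exponential tail appended
to pendant edges (the waiting time to the next unobserved event), scaled to
unit height. Binary traits evolve along them under a two-state Markov
process from a stationary root draw; low rates produce the clade-clumped
patterns the corrected regression must handle. Abundance tables place a
designated fraction of taxa above the 0.1% screen by construction, keep
detected-but-rare taxa strictly between the two thresholds, and return the
truth lists, so screening can be checked exactly.

What passing on these data shows: correct arithmetic, calibrated tests at
nominal type-I error, power at the study's effect sizes, exact
screening/threshold semantics, and determinism. What it does not show:
robustness to curation error, taxonomy drift between database and tree,
non-random missingness, or compositional artifacts of read-fraction
abundances — real-data hazards outside the generator's scope.

## Problem sizes and runtime choices

Simulation-backed checks use sizes chosen to make their Monte-Carlo error
small relative to the asserted bands while keeping the suite quick: 1000
replicates for type-I bands at α = 0.05 (binomial se ≈ 0.7%), 2000 for the
Brunner–Munzel checks, 200 replicates on 200-tip trees for sign recovery,
100-tip trees for the inflation-correction study, and B = 999 within
permutation calibration replicates (the pipeline default stays at 10⁵).
The acceptance script mirrors these at the same or slightly reduced counts
and derives every stream from its `--seed`.

## Known limitations

- The corrected regression is an approximate-likelihood method; its LRT
  reference is asymptotic and conservative near the σ² = 0 boundary.
- The equicoordinate adjustment estimates contrast correlation from
  variance contributions only; with heavy ties it may fall back to Šidák.
- Name matching is exact after normalization; no synonym resolution.
- Multi-level categorical species have no single level to dummy-code and
  are dropped from regressions (counted); the randomization test handles
  them natively.
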