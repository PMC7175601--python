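# Methods

## The random-predator model and its fitting

Non-replacement predation trials deplete prey during the exposure, so the
per-trial expectation cannot use the instantaneous (disc-equation) form.
The model used throughout is

    Ne = N0 * (1 - exp(a * (Ne*h - T)))

solved on the principal Lambert-W branch,

    Ne = N0 - W(a*h*N0 * exp(-a*(T - N0*h))) / (a*h).

The W argument is always non-negative here, so there is no branch
ambiguity. Two numerical guards keep the evaluation exact in the limits:
when `a*h < 1e-12` the solver switches to the closed form
`N0*(1 - exp(-a*T))` (the handling-free limit, continuous in `h`), and when
the log of the W argument exceeds 700 (large `a`, `N0*h > T`), `W(e^L)` is
evaluated by Newton iteration on `w + log w = L` instead of exponentiating.
Returned values are clipped to `[0, N0]`; tests verify the implicit-equation
residual stays below 1e-9 everywhere and that `Ne` is monotone increasing in
`N0`, `a`, `T` and decreasing in `h`, with `Ne ≤ min(N0, 1 + T/h)`.

**Likelihood.** Counts of prey eaten out of `N0` offered are modelled as
`Binomial(N0, Ne(N0)/N0)`. This is the standard likelihood for
non-replacement count data and is exactly the noise model of the
"binomial" simulator, making the parameter-recovery tests a like-for-like
check. Optimization is over `(log a, log h)` (enforcing positivity and
improving conditioning), Nelder–Mead with tolerance 1e-8 from a 3×3 grid of
starts: `a` scaled 0.1/1/10 around an initial slope estimate from the
lowest density, `h` scaled 0.5/1/2 around the reciprocal of the largest
observed consumption. Standard errors come from the inverse observed
information (finite-difference Hessian), mapped to the natural scale by the
delta method. All-zero consumption has no finite MLE for `a` and raises;
fits pinned at the handling-time floor (1e-8 days) are flagged.

**FR type.** Second-order logistic regression of proportion eaten on
density and density², with a quasibinomial dispersion (Pearson X²/df)
inflating the standard errors. A significantly negative linear coefficient
calls type II; positive linear with significantly negative quadratic calls
type III; anything else is "I/indeterminate", including separation or
non-convergence. Normal-reference p-values are the default, with a
Student-t option exposed, since inference conventions for quasibinomial
coefficients differ between implementations.

**Bootstrap bands.** Nonparametric resampling of trials with replacement
*within each density stratum* (preserving the fixed-density design), refit
to each resample seeded from the full-data estimate, and a pointwise 95 %
percentile envelope of the refitted curves. Percentile rather than BCa
intervals are used; failed refits are dropped and counted, with a warning
above 10 %. Coverage is checked empirically in the test suite: bands from
199 resamples on simulated datasets (5 replicates per density — matching
the real design's replication — across the 1–80 egg density series) contain
the true curve at density 20 in ≥85 % of runs.

**Group comparison.** The indicator-variable parameterization writes the
comparison group's parameters as `a + Da`, `h + Dh`. With a full
interaction the joint MLE separates into the two group fits, so `Da` and
`Dh` equal the differences of the separate estimates exactly (asserted to
machine precision in tests) and their variances are the sums of the
group-wise observed-information variances. Wald z with two-sided normal
p-values.

## Electivity analysis

**Autogenic adjustment.** Food masses drift without a predator (decay,
leaching, water uptake), so true consumption in a treatment arena is the
raw mass loss plus the signed mean control change
`mean(remaining − offered)` for that food, floored at zero. At least one
control arena is required.

**Compositions.** Each individual's diet is the percentage of total
adjusted consumption per food; availability is the percentage of offered
mass (or an equal-availability option, reported side by side). Zeros are
replaced with 0.01 % and the non-zero entries rescaled proportionally so
the composition stays on the 100 % simplex — the replacement constant is a
published convention; the proportional renormalization is this package's
choice. Individuals with zero total consumption carry no compositional
information and are excluded with a warning.

**Wilks' Λ randomization test.** Per individual, the difference vector
`d_i = alr(use) − alr(avail)` uses additive log-ratios with the last food
alphabetically as reference (results are invariant to this choice; tested).
`Λ = det(W)/det(T)` with `W` the centred and `T` the uncentred
cross-product of the `d_i`. The null of random feeding is generated by
independent ±1 sign flips of each `d_i` — the exact null when use is
exchangeable with availability; the published analysis names randomization
without specifying its unit, and sign-flipping is adopted here as the exact
mechanism. Because the flips enter only through the flipped mean,
`Λ = 1 − n·d̄ᵀT⁻¹d̄` by the matrix determinant lemma, and the whole
randomization vectorizes. The p-value includes the observed statistic
(`p = (1 + #{Λ_rand ≤ Λ_obs})/(n_rand + 1)`), so `p ≥ 1/2000` at the
default n_rand = 1999. If every individual's use equals availability, Λ is
defined as 1 with p = 1.

**Ranking.** The pairwise statistic for foods (f, g) is the mean over
individuals of `log(use_f/use_g) − log(avail_f/avail_g)` (reference-free by
construction). Foods are ranked by the number of positive row entries, ties
broken by row sums and flagged. Pairwise significance uses per-individual
sign flips of the pairwise differences, two-sided. Significance letters are
the maximal cliques of the non-significance graph, lettered in rank order,
so foods share a letter iff they are not significantly different.

## Incidence GLMs

Incidence (whether a predator killed any prey) is fitted as a logit-link
binomial GLM on group, on the individual-level Bernoulli representation
with treatment coding. The group-term deviance is the null-minus-residual
deviance; for factor-only models it is identical under the grouped
representation (asserted against the closed-form grouped-binomial
likelihood ratio). Dispersion is Pearson X²/df on the individual level.
Wald contrasts are computed from the coefficient covariance and therefore
coding-invariant; for the saturated one-factor model they equal the
analytic log-odds-ratio statistic. Model simplification drops the least
significant droppable term (respecting marginality) while its deletion test
— chi-square for binomial, dispersion-scaled F for quasi models — is
non-significant. Clopper–Pearson intervals use exact beta quantiles;
Fisher's exact test sums hypergeometric probabilities not exceeding the
observed table's.

## Synthetic data: what it emulates and what it does not

The generators reproduce the designs the analyses assume, with defaults set
to the study conditions: carp-egg densities (1, 2, 3, 5, 8, 10, 15, 25, 35,
50, 80), carp-larva densities (1, 2, 3, 5, 8, 12, 25, 50), trout densities
(1, 3, 5, 8, 12, 16, 25, 35, 50); exposures of 1 day for carp and 2 days
for trout; autogenic drifts of −0.3 mg (eggs), −1.8 mg (leaf discs),
+1.7 mg (live plant) and −1.9 mg (isopods) per arena, with per-arena SDs
(1.2/1.2/0.9/2.0 mg) scaled from the reported between-arena variability;
offered masses near-equal at ~40 mg per food (fish at 38.1 mg = 10 eggs ×
3.81 mg); 9–15 individuals per group; total intake lognormal around ~15 mg
(keeping total consumption under ~30 % of offered mass, as in the real
arenas); and a carp-larva unit mass of 1.32 mg for count-to-mass
back-calculation.

Two FR noise modes are provided deliberately: "binomial" matches the
fitting likelihood exactly and underpins the parameter-recovery and
coverage checks; "mechanistic" is an independent event process (exponential
search waits at rate `a·N`, fixed handling intervals `h`) whose `h = 0`
limit has the known closed form — it probes the model from outside its own
likelihood. Handling intervals are fixed rather than exponential because
the depletion model's derivation treats `h` as a deterministic time cost.

Electivity allocation is Dirichlet around shares proportional to
weight × offered mass, concentration 5 by default — enough inter-individual
variation that single individuals can be dominated by one food, as observed
in real arenas. Features of real data *not* emulated: predator satiation
dynamics within electivity arenas, correlation between foods beyond the
simplex constraint, arena/block effects, and prey handling that damages but
does not remove mass. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generating processes, not
robustness to those unmodelled features.

One calibration caveat the simulator itself exposed: with food-specific
autogenic drift noise and control means estimated from finitely many
controls, the sign-flip null is only approximate (the shared estimation
error correlates individuals), inflating the type-I rate of the Λ test
above its nominal level. The calibration experiments in the test suite
therefore use drift-free controls and equal offered masses, where the null
is exact; analyses of real data with strong, noisy autogenic drift should
expect mildly anticonservative randomization p-values.

## Other design choices and limitations

- Prey-equivalents are rounded to the nearest whole prey with ties rounding
  up; dead-but-undamaged prey count toward neither consumption nor kills
  (background mortality).
- Body-part reconstruction pairs complementary parts (a head and a tail are
  one individual) and absorbs other parts into already-counted individuals
  where possible: `max(heads, tails) + max(0, other − max(heads, tails))`.
  Only the head/tail case is documented by the source design; the general
  minimizing matcher is this package's extension.
- Egg trials with damaged fractions warn rather than reject: eggs are
  normally consumed whole, but rare nibbling occurs.
- Reduced default replication (199 bootstraps/randomizations) keeps the
  demo pipeline fast; `--paper-scale` restores 1999. Test-suite problem
  sizes (20 recovery datasets, 100 coverage datasets at 199 resamples,
  500–1000 calibration simulations at n_rand = 199) were chosen as the
  smallest sizes at which the checked rates are statistically
  interpretable.
- No sigmoid (type III) FR fitting, no prey-replacement disc-equation
  fitting beyond the `h = 0` limit, and no multi-predator interference
  models.
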