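# predelect

Comparative predation analysis for laboratory feeding trials: functional
responses of predators on depleting prey, diet electivity among alternative
foods, and kill-incidence comparisons between predator groups.

The package was built around a concrete question in invasion ecology — does
an invasive amphipod (*Dikerogammarus villosus*, the "killer shrimp") exert a
stronger per-capita predatory impact on fish eggs and larvae than the native
amphipod it displaces (*Gammarus pulex*)? — but every stage is generic: it
applies to any non-replacement predation trial design with tabular records.

## What it computes

**Functional response (FR).** In an arena trial a predator is offered `N0`
prey for `T` days and eaten prey are not replaced, so prey density declines
during the trial. The expected number eaten follows the random-predator
model

    Ne = N0 * (1 - exp(a * (Ne*h - T)))

with attack coefficient `a` (day⁻¹) and handling time `h` (days·prey⁻¹).
The equation is implicit in `Ne`; its explicit form uses the Lambert W
function,

    Ne = N0 - W(a*h*N0 * exp(-a*(T - N0*h))) / (a*h),

and `1/(hT)` is the maximum feeding rate (prey·day⁻¹). The package
classifies FR type by second-order quasibinomial logistic regression of
proportion eaten on density, fits `(a, h)` by binomial maximum likelihood,
bootstraps 95 % confidence bands for the fitted curve (stratified by
density), and compares parameters between groups with indicator variables
(Wald z on `Da = a₂ − a₁`, `Dh = h₂ − h₁`).

**Electivity.** Four foods are offered simultaneously; consumed masses are
corrected for autogenic change measured in predator-free controls, expressed
as percentage diet compositions (zeros replaced with 0.01 %), and compared
with percentage availability on log-ratio scale. Departure from random
feeding is tested with Wilks' Λ against a sign-flip randomization null
(n = 1999), and foods are ranked by pairwise mean log-ratio differences with
randomization-based significance letters.

**Incidence.** Whether each predator killed any prey is analysed with a
logit-link binomial GLM on group, with Wald contrasts, Pearson-dispersion
quasi-likelihood checks, backward simplification to a minimum adequate
model, Clopper–Pearson intervals and Fisher's exact test.

A seeded synthetic-data module generates FR trials (binomial noise around
the model expectation, or an explicit search-and-handle event process),
electivity arenas with autogenic drift, and incidence tables, so the entire
pipeline runs and is testable with no external data.

## Worked example

Simulate a full three-group study and run every stage:

```sh
predelect reproduce --seed 7 --out demo_report
```

The Markdown report (`demo_report/report.md`) contains, among other tables:

```
| group           | a     | SE    | h     | SE    | 1/hT |
| G_pulex         | 1.208 | 0.190 | 0.129 | 0.011 | 7.8  |
| Dv_intermediate | 1.397 | 0.243 | 0.148 | 0.012 | 6.7  |
| Dv_large        | 1.674 | 0.203 | 0.080 | 0.006 | 12.5 |

- Dv_large vs Dv_intermediate: Dh = -0.069, z = -5.12, p < 0.001

events/totals: G_pulex 3/53, Dv_intermediate 10/52, Dv_large 41/54
group-term deviance = 70.19, dispersion = 1.02
```

Reading this: all three simulated groups share statistically
indistinguishable attack coefficients (`a` ≈ 1.2–1.7 day⁻¹), but the large
invader's handling time is roughly half that of the smaller amphipods
(0.080 vs 0.129–0.148 days·prey⁻¹), so its maximum feeding rate `1/hT` is
about 12.5 eggs·day⁻¹ versus 6.7–7.8 — a size-driven difference the
indicator-variable comparison flags as highly significant (z = −5.12 for
`Dh`). The electivity section ranks fish first (letter "a", not shared) for
both *D. villosus* groups but leaf first for *G. pulex*, and the incidence
GLM shows kill probability rising steeply with predator size.

The same stages are available on CSV inputs
(`predelect fit-fr --trials fr_trials.csv ...`,
`predelect electivity --trials electivity_trials.csv ...`,
`predelect incidence --events 3,12,40 --totals 53,52,54 ...`) and as plain
library functions (`fit_rogers`, `compare_fr`, `compositional_manova`,
`rank_electivity`, `fit_binomial_glm`, ...).

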