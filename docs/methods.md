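# Methods

## The model

`cradsim` simulates competitive microbial proliferation on a 3-D lattice
and analyses the resulting community structure through the cumulative
relative abundance distribution (CRAD): for each relative abundance `x`,
the fraction of species whose abundance is at least `x` — the survival
function of the abundance distribution across species, equivalent to the
rank-abundance curve with axes exchanged. Gut communities typically show
CRADs that are straight lines on log-log axes over the mid-abundance
range, i.e. power laws `S(x) ∝ x^(−β)`; the exponent β acts as a joint
index of richness and evenness (larger β ↔ richer, more even).

The lattice `(lx, ly, lz)` represents a growth front advancing away from
a nutrient surface (e.g. the mucus layer): the bottom layer `z = 0` is
seeded with `N(0)` founder species; every site of layer `z` is then
filled independently by either

* **copying** one of its nine lower-layer neighbours
  `(x±1, y±1, z−1)` (periodic in x and y), chosen with probability
  proportional to the growth weight of the species occupying it —
  probability `p`; or
* **immigration** of a brand-new species — probability `1 − p`.

Sites within a layer only ever read the completed layer below, so the
within-layer update order is irrelevant (verified against a sequential
reference implementation in the test suite). Only two layers are held in
memory; abundance tallies are streamed, so the default 40×40×2000 lattice
runs in ~0.1 s.

The copy step is a "rich get richer" amplifier: a species occupying more
sites of the lower layer is chosen more often, so small stochastic
differences in early growth are amplified into heavy-tailed abundance
distributions, with no species interactions and (by default) no growth
rate differences at all.

### Readout and sampling

Abundances are tallied over **all** `lx·ly·lz` sites (readout
`"whole"`); a top-layer-only readout is available behind
`readout="top"`. The whole-lattice convention is the package default
because it reproduces the regime-level sampled-richness values the model
is known for (~51 species at `p=1, N(0)=100`; ~189 at `p=0.999,
N(0)=200`; ~33 at `p=1, N(0)=40`; ~378 at `p=0.9975, N(0)=200`), whereas
the top layer at `p=1` is nearly fixated (richness ~3).

To emulate amplicon data, a profile is reduced to a 2,500-read
multinomial sample before any richness or β statistic is computed; 2,500
is the rarefaction depth used throughout (`rarefy` subsamples user
tables to the same depth, hypergeometrically).

### Key parameters

| parameter | default | meaning |
|---|---|---|
| `lx, ly, lz` | 40, 40, 2000 | lattice size; 2000 layers gives the straightest log-log CRADs at `p=1` |
| `p` | — | copy probability; `1−p` is the per-site immigration probability |
| `n_initial_species` | 200 | founder species N(0) |
| `init_mode` | `random_iid` | founder arrangement: i.i.d. uniform per site, or equal contiguous tiling |
| `growth_weights` | all 1.0 | per-species selection weights (e.g. 197 of 200 species at 0.5 for an antibiotic-like scenario) |
| `immigrant_weight` | 1.0 | weight given to every immigrant |
| `depth` | 2500 | reads per sample |

Regimes: `p=1` confines competition to the founders (infant-like, small
β ≈ 0.6); small immigration probabilities (`1−p` = 0.001–0.0025) feed
the mid-abundance ranks and raise β toward the adult-like ≈ 0.9 and
beyond.

## Exponent estimation

β is estimated by maximum likelihood from the relative abundances that
fall inside the window **[0.008, 0.40]** (0.8 %–40 %, endpoints
inclusive; at depth 2,500 this spans counts 20–1000, where a continuous
model is a standard approximation). Two conventions are implemented:

* `method="truncated"` (library default): exact MLE of the doubly
  truncated Pareto, density `f(x) = β x^(−β−1) / (L^(−β) − U^(−β))` on
  `[L, U]`, solved by Brent root-finding on the score with bracket
  `[1e-3, 50]`. Boundary-score cases return the bracket endpoint. This
  estimator is exactly self-consistent: i.i.d. draws from the truncated
  model refit to the generating β (mean error < 0.05 at n = 2,500).
* `method="untruncated"`: the closed form `β̂ = n / Σ ln(xᵢ/L)` — the
  classical continuous power-law MLE in which the upper bound only
  selects points. **Simulation ensembles use this convention** (it is
  the `FitOptions` default): on lattice-generated samples it gives mean
  β ≈ 0.66 for the `p=1, N(0)=100` regime, the documented ≈ 0.62
  behaviour, whereas the truncated form gives ≈ 0.34 on the same points.
  The window upper limit may be set above 1 to recover the untruncated
  limit of the truncated solver.

Exclusion rules: a sample with fewer than 2 window points is excluded
(`too_few_points`); a sample whose goodness-of-fit p-value is below 0.1
is excluded (`gof_reject`). Excluded replicates are dropped from
ensemble β means but counted and reported.

### Goodness of fit

`gof_pvalue` is a semi-parametric KS bootstrap: the observed KS distance
between the empirical and fitted window CDFs is compared with `n_boot`
synthetic datasets of the same window size drawn from the fitted
distribution and **refitted** before their KS distance is measured; p is
the fraction of bootstrap distances ≥ the observed one. Under the null
the p-value is approximately uniform (calibration is asserted in the
tests); a window-truncated log-normal with log-sd 0.3 is rejected with
p < 0.05 at n = 2,000. Default `n_boot=1000`; ensembles use 200, which
resolves the 0.1 threshold to ±0.02.

### Alternative families

Log-normal (μ, σ on the log scale) and stretched exponential
(survival ∝ `exp(−(x/λ)^c)`) are fitted by Nelder-Mead on the same
window-truncated likelihood, so log-likelihoods are directly comparable
with the power law's. A pure exponential (c fixed at 1) is also provided
as the natural one-parameter contrast to the one-parameter power law.
`compare_families` ranks families by AIC rather than raw log-likelihood:
measured on data generated from each family, the two-parameter families
beat the one-parameter power law on its own data more than half the time
by raw likelihood, while under AIC each generating family wins the
majority (40–50 of 50 datasets).

Optimiser failures are flagged (`converged=False`) rather than silently
returned; the stretched fit is started from three λ values and the best
optimum kept.

## Median CRADs

Curves from multiple samples are aggregated by splitting the pooled
abundance range into logarithmic bins (default 10 per decade) and taking
the median survival value per non-empty bin.

## Diversity theory

The ideal power-law community used for theory and fixtures is the Zipf
rank-abundance profile `x_i ∝ i^(−1/β)`, `i = 1..S` (default S = 200,
the adult-scale founder number), normalised to sum to 1 — the exact
deterministic inverse of a power-law CRAD, since the fraction of species
with abundance ≥ `x_i` is `i/S ∝ x_i^(−β)`. `theoretical_diversity`
Monte-Carlo-samples `depth`-read multinomials from this profile and
averages observed richness and Shannon index (`H = −Σ pᵢ ln pᵢ`, nats);
both are strictly increasing in β (asserted at 3 s.e. over
β ∈ [0.4, 1.4]), which is the qualitative content of the
richness/diversity-vs-β correlation. The closed-form route is left open
behind the same interface.

This profile was chosen over i.i.d. truncated-Pareto draws normalised to
1 after measuring both: normalisation plus multinomial noise at the
0.8 % window edge biases refitted exponents of the i.i.d. variant
upward by +0.1 or more, while the Zipf profile round-trips through
2,500-read sampling and the truncated MLE to within 0.04 at β = 0.9.

`generate_fixture_table` builds synthetic OTU tables from the same
profile (independent multinomial per sample), giving deterministic,
text-only test data with a known exponent.

Group comparisons use one-way fixed-effects ANOVA (`anova_beta`) and
Spearman rank correlation, with explicit handling of degenerate
zero-variance groups (F = 0, p = 1 when means agree; F = ∞, p = 0
flagged when they differ).

## What the generators do and do not emulate

Simulated communities and fixture tables reproduce the *distributional*
features the analysis stack consumes: heavy-tailed abundances, finite
read depth, rarefaction noise, window-limited fitting. They do not
emulate taxonomy, chimeras/sequencing error, compositional correlations
between samples, or temporal autocorrelation; passing tests therefore
validate the simulation and inference machinery, not any claim about a
particular real dataset.

## Known limitations and open points

* The initial-arrangement contrast (equal tiling → exponential-type
  CRAD vs random seeding → power-law-type) does **not** reproduce at the
  10×10×50 geometry as a sign difference of window log-likelihoods: at
  height 50 the whole-lattice tally is dominated by integrated
  neutral-drift fluctuations, whose totals are heavy-tailed regardless
  of the founders' arrangement, so the power law wins for both modes.
  The arrangement effect is real but transient: at heights ≤ 10 the
  equal tiling is more exponential-leaning than random seeding by ~9
  s.e. (asserted in the test suite). The exact spatial pattern behind
  the published "non-uniform" contrast is not recoverable.
* Immigrants inherit `immigrant_weight` (default 1.0); nothing is known
  about real immigrant growth rates.
* The mouse small-intestine regime is run at N(0) = 40 (which matches
  the ~33-species readout); N(0) = 200 gives ~60 and is not used.
* Ensemble problem sizes: 100 replicates for regime means, 50 for the
  immigration-monotonicity ordering, 200 bootstrap replicates for
  ensemble GoF tests — chosen so the full analysis reruns in about a
  minute while keeping Monte-Carlo error well inside the tolerances
  quoted above.
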