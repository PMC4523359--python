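# Methods

## Model

Counts N_i(j) of OTU j at site i are multinomial given the site's total
count and the composition **p**(X_i), a probability vector over an
unbounded set of taxa indexed by a continuous stressor covariate X (TPH,
mg/kg soil). The prior over compositions is stick-breaking: fractions
V_j ∈ (0,1) define weights p_j = V_j ∏_{l<j}(1 − V_l).

**Independent GEM.** One GEM(M) prior per site: V_j ~ Beta(1, M) i.i.d.
Given M the full conditionals are conjugate,
V_j | counts ~ Beta(1 + n_j, M + Σ_{l>j} n_l), so the per-site sampler is
Gibbs on the fractions with a Metropolis–Hastings step on log M under a
Gamma hyperprior. Sites share nothing; this is the non-dependent comparator
and can only be evaluated at observed covariate values.

**DepGEM.** Each stick index j carries a latent Gaussian process Z_j(·)
with zero mean and squared-exponential covariance
k(x, x′) = exp(−(x − x′)²/(2λ²)) over the covariate rescaled to [0, 1]
(division by the larger of the observed maximum and the prediction-grid
maximum). The stick fraction is the Gaussian copula transform

    V_j(X) = Q_{Beta(1,M)}(Φ(Z_j(X))) = 1 − (1 − Φ(Z_j(X)))^{1/M},

which enforces the Beta(1, M) marginal exactly at every X while the GP
correlation makes compositions vary smoothly in X. The GP variance is fixed
at 1: the copula makes the scale of Z unidentifiable from V, only
correlations matter. The bandwidth λ is, informally, the rescaled covariate
distance over which the community can change substantially.

Assumptions worth keeping in mind: a single continuous covariate; smooth
(GP-length-scale) community change in that covariate; multinomial sampling
(no overdispersion beyond what composition uncertainty induces); no attempt
to estimate the number of undetected taxa (the truncation tail absorbs
them).

## Sampler

One sweep updates:

1. **Stick rows Z_j** — under-relaxed autoregressive proposal
   Z′ = √(1−ε²) Z + ε η with η ~ N(0, K). The proposal is reversible with
   respect to the GP prior, so acceptance is the likelihood ratio alone.
   The multinomial log likelihood factorizes over stick rows as
   Σ_i [n_{ji} log V_{ji} + m_{ji} log(1 − V_{ji})] with m_{ji} the counts
   on sticks after j at site i, so all J rows are proposed and
   accepted/rejected independently in one vectorized step. ε is per-row and
   adapted only during burn-in toward 20–50% acceptance.
2. **Precision M** — random-walk MH on log M; Gamma(2, 0.1) hyperprior
   (mean 20, weakly informative on the scale of a few-hundred-OTU
   community). Changing M moves every V through the copula; the cached
   log(1 − Φ(Z)) makes this an O(J·I) recomputation.
3. **Bandwidth λ** — random-walk MH on log λ as a *whitened* move: the
   standardized field W = L⁻¹Z (L = chol K) is held fixed and the rows move
   with the kernel, Z′ = L′W. The GP prior density of the rows is invariant
   under this map, so the acceptance ratio is the likelihood ratio times
   the log-normal hyperprior ratio (centred on ¼ of the rescaled range,
   log-sd 1). A centred update (rows fixed, prior-density ratio) is valid
   MCMC but mixes pathologically here: conditioned on rows shaped by the
   current kernel it drives λ toward zero, after which sites decouple and
   grid predictions collapse to the prior. The whitened move lets λ and the
   rows travel together. Z is initialized flat (pooled shrunk stick
   fractions through the inverse copula, constant across sites), which is
   compatible with every bandwidth.

Proposal scales for M and λ adapt during burn-in only. A non-finite log
posterior aborts with a diagnostic; acceptance below 1% warns. Acceptance
rates, effective sample sizes (initial-positive-sequence estimator) and
lag-k autocorrelations for the M and λ traces are reported by
`fit_summary`.

**Prediction.** At each retained draw, compositions at the covariate grid
come from the GP conditional (kriging) mean of each row given its values at
the observed sites, then the copula transform and stick-breaking. No
conditional-noise draw is added: the posterior spread across draws carries
the uncertainty, and the conditional mean makes prediction at an observed
covariate reproduce the site fit exactly (grid points that coincide with an
observed site copy its column directly, avoiding round-off from the
factorization jitter). The cost is that between-site predictive bands
slightly understate the GP's local interpolation uncertainty; with ~20
sites over the range and the bandwidths the posterior selects, that
component is small against the posterior spread.

**Defaults.** 50,000 iterations, burn-in 10,000, thinning 5; truncation
J = retained OTUs + 25 spare sticks (prior mean residual tail
(M/(M+1))^J stays below 10⁻³ for the posterior-plausible M at the default
study size); prediction grid 0–25,000 mg/kg in steps of 625 (41 points);
kernel jitter 10⁻⁸. Tests and desk-scale examples use 5,000 / 1,000 / 2.

## Data preparation

* **Abundance filter**: an OTU is kept only when its total count over all
  sites is *strictly greater* than the threshold (default 10) — a literal
  reading of "exceeding". The filter is idempotent and never alters
  retained counts.
* **Jittering**: tied covariate values receive independent Gaussian noise
  (default sd 1 mg/kg, tiny against the 0–22,000 range) so each modelled
  site has a distinct covariate; zeros take the absolute value, and
  collisions are redrawn. Raw values are kept alongside: the baseline group
  (exact zeros) and all reporting use raw values, jittered values are used
  only for fitting. Refitting with a different jitter stream moves the
  diversity curve by less than the credible band (tested).
* **Reference genus lists** are case-folded and deduplicated; genus
  matching is exact string match after case-folding, and OTUs without a
  genus annotation are excluded from sensitivity/specificity.

## End points

* **Shannon curves** use the natural log (matching the digamma prior
  expectation ψ(M+1) − ψ(1), verified against a Monte-Carlo oracle), with
  0·log 0 = 0 and the residual tail excluded from the sum.
* **Δ classification** splits the grid at the median of the observed raw
  covariate by default. The 95% interval convention: entirely above zero →
  decreasing; below → increasing; containing zero → no classification. The
  raw-data classifier (no interval available) breaks exact ties toward
  increasing.
* **Bray–Curtis** is 1 − Σ min(u, v) with the truncation tail carried as
  one pseudo-category, so vectors stay compositional without renormalizing.
* **D0**, the dissimilarity between two uncontaminated communities, is not
  observable from a single baseline composition. Two estimators are
  provided: the default pairs distinct posterior draws of the
  zero-covariate composition (mean cross-draw Bray–Curtis, deterministic
  half-rotation pairing), capturing posterior variability at baseline; the
  alternative averages pairwise dissimilarities among the raw zero-TPH site
  compositions, capturing observed between-site variability (typically
  larger, since it includes sampling noise).
* **ECx** inverts the posterior-*mean* curve at D_x = D0 + (x/100)(1 − D0),
  taking the smallest crossing (conservative for non-monotone curves) with
  linear interpolation between grid points (`snap_to_grid` reports the
  first grid point at/above the crossing instead). Credible bounds invert
  the running-maximum envelope of the upper band curve (→ lower bound) and
  lower band curve (→ upper bound); envelopes only enlarge the interval, so
  the bounds are conservative. Bounds pinned at covariate 0 or at the grid
  maximum are flagged censored. Because a first-crossing time is monotone
  in its threshold, EC is nondecreasing in x by construction.

## Synthetic data

The generator emulates the study conditions the models are meant for: 22
sites of which 10 are uncontaminated (covariate exactly 0), positive
covariates up to 22,000 mg/kg with duplicated values among ~¼ of the sites
(so jittering is exercised), 450 candidate OTUs whose baseline weights come
from a truncated GEM(20) draw (a few hundred survive the abundance filter,
with heavy-tailed rank-abundance structure), multinomial counts at per-site
depths uniform on 2,000–10,000, and planted response groups: 20%
increasing, 20% decreasing, 60% unaffected.

Planted responses multiply the baseline weight by
exp(± effect_scale · s(X)) where s is a logistic curve affinely normalized
to run exactly 0 → 1 over [0, max], then renormalize per site. Two design
choices matter:

* the logistic *centre is drawn per response group*, not per OTU: with a
  shared centre the per-OTU proportion curves are provably monotone after
  renormalization, so planted labels are unambiguous ground truth (with
  per-OTU centres, a weakly-affected decreasing OTU can rise when a
  strongly-affected one collapses);
* group labels are assigned *stratified by abundance rank* (blocks of five
  OTUs in decreasing-weight order receive labels in the design proportions,
  shuffled within block). With fully random assignment the planted
  community turnover is a lottery over whether a dominant OTU draws a
  signal label (baseline-to-maximum Bray–Curtis ranged ~0.13–0.67 across
  seeds); stratification makes turnover a stable function of effect size.

Each OTU carries a synthetic one-genus-per-OTU label (`genus_k`) so the
reference-list path runs without real taxonomy; the clean reference list is
exactly the increasing group's genera, and `generate_reference_list` can
flip memberships at a configurable misannotation rate.

The strong-effect benchmark used in the end-to-end tests sets
effect_scale = 3 and depths 5,000–10,000, giving true baseline-to-maximum
turnover ≈ 0.66: EC50 then resolves inside the grid while EC75+ upper
bounds censor at the grid maximum — the qualitative regime a strong field
gradient produces.

What the generator does **not** emulate: sequencing error, chimeras or any
read-level process (counts are drawn at the OTU level); overdispersion
beyond multinomial; covariate measurement error beyond the modelled jitter;
real taxonomy (one genus per OTU, so genus-level aggregation is never
exercised); non-monotone per-OTU responses (subsidy–stress shapes). Passing
the recovery tests therefore shows the estimator works when its own
assumptions hold at field-realistic size and depth — not that those
assumptions hold for any particular field community.

## Problem sizes in tests

The acceptance-style checks run at desk scale, chosen to finish in minutes
while leaving clear margins: 10⁵ Monte-Carlo draws (truncation 2,000) for
the digamma oracle; 10⁵ draws for the copula KS checks; DepGEM recovery on
12 sites × 30 OTUs at depth 5,000 with 5,000 iterations (posterior mean
compositions land at mean L1 ≈ 0.06 from truth, against a 0.15 bar);
classification and robustness on the 22-site benchmark with 5,000-iteration
chains. The full-scale defaults (50,000 iterations, 392-OTU-scale tables)
run in well under an hour on one core thanks to the vectorized row updates.

## Known limitations

* Single covariate only; no categorical covariates.
* The exact-interpolation choice for kriging (see above).
* The M and bandwidth chains are global random-walk updates; for very large
  J their acceptance can drift outside the tuned range after burn-in.
* D0 estimators are heuristics for a quantity the model does not directly
  parameterize; ECx for small x is sensitive to that choice.
* The independent GEM fit cannot produce dissimilarity/ECx output (no
  prediction at covariate 0 after jittering); it is reported for diversity
  and classification comparison only.
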