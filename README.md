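# gemtox

Bayesian nonparametric community ecotoxicology: fit GEM and
covariate-dependent GEM (DepGEM) stick-breaking models to OTU count tables
observed along a contamination gradient, and derive whole-community toxicity
end points — posterior Shannon-diversity curves, per-OTU response
classification, Bray–Curtis dissimilarity curves, and ECx effective
concentrations with credible intervals.

Built for microbial ecologists and ecotoxicologists who have an OTU-by-site
count table (e.g. from 16S rRNA amplicon sequencing) plus a continuous
stressor measurement per site (here: total petroleum hydrocarbons, TPH, in
mg/kg soil) and want community-level dose–response estimates rather than
single-species toxicity tests.

## The model

Counts at site *i* are multinomial over OTUs *j* with probabilities
**p**(Xᵢ), the community composition at covariate Xᵢ. The prior on each
composition is the Griffiths–Engen–McCloskey (GEM) stick-breaking
distribution: fractions V_j ~ Beta(1, M) split a unit stick,

    p_j = V_j ∏_{l<j} (1 − V_l),

so the number of taxa is unbounded a priori. The precision M controls
evenness (prior expected Shannon index ψ(M+1) − ψ(1), increasing in M).

The dependent model (DepGEM) makes each stick fraction a smooth function of
the covariate by driving it with a latent Gaussian process Z_j(X)
(squared-exponential kernel, bandwidth = the covariate distance over which
the community can change substantially) through the Gaussian-copula link
V_j(X) = 1 − (1 − Φ(Z_j(X)))^{1/M}, which preserves the exact Beta(1, M)
marginals. Posterior sampling is Gibbs with Metropolis–Hastings steps
(prior-preserving under-relaxed proposals for the GP rows; log-scale
random-walk for M and the bandwidth, the latter as a whitened joint move).
Because the GP can be kriged, the fitted model predicts compositions at any
covariate value, not just observed ones — which is what makes interpolated
ECx estimation possible.

End points:

* **Diversity curve** — Shannon index H = −Σ p_j log p_j of each posterior
  draw along the covariate grid, with 95% credible bands.
* **Classification** — Δ_j = (average p_j at low covariate) − (average at
  high covariate), split at the median observed level. CI entirely above
  0 → decreasing with the contaminant; below 0 → increasing; containing
  0 → no classification. Compared against a reference list of genera
  expected to increase (sensitivity/specificity, plain and
  abundance-weighted).
* **ECx** — Bray–Curtis dissimilarity D(X) between the posterior composition
  at X and at X = 0; the x% effect threshold is D_x = D0 + (x/100)(1 − D0)
  where D0 is the baseline self-dissimilarity, and ECx is the smallest
  covariate where the mean curve reaches D_x. Credible bounds invert the
  running-maximum envelope of the band curves (conservative).

A synthetic-data module generates tables with this exact structure and known
planted truth (increasing / decreasing / unaffected OTU groups), so the
whole pipeline is testable end to end without field data.

## Worked example

```bash
gemtox simulate --out data --seed 1 --effect-scale 3.0
gemtox fit --table data/otu_table.tsv --metadata data/metadata.tsv \
           --out fit --seed 1 --iterations 5000 --burnin 1000 --thin 2
gemtox report --ensemble fit/ensemble --table data/otu_table.tsv \
              --metadata data/metadata.tsv \
              --reference data/reference_genera.txt --out report --seed 1
```

This simulates 22 sites (10 uncontaminated, TPH up to 22,000 mg/kg, tied
values jittered before fitting) with 450 candidate OTUs, filters to the 118
OTUs whose total abundance exceeds 10, fits DepGEM at desk scale, and writes
the result tables. `report/ecx.tsv` then contains (mg TPH/kg soil):

```
X      EC       min      max      censored_low  censored_high
5.0    2738     2581     2900     False         False
10.0   4209     4028     4411     False         False
20.0   6374     6229     6526     False         False
50.0   11965    11786    12160    False         False
75.0   25000    25000    25000    False         True
80.0   25000    25000    25000    False         True
```

i.e. a 5% community change at ~2,700 mg/kg, a 50% change at ~12,000 mg/kg,
and thresholds beyond 75% unreachable inside the modelled range (upper
bounds right-censored at the 25,000 mg/kg grid limit). The diversity curve
(`diversity_curve.tsv`) starts at H ≈ 3.65 at TPH 0, and the dissimilarity
curve reaches ≈ 0.65 at the top of the range with baseline D0 ≈ 0.018.
`confusion.tsv` reports sensitivity/specificity 1.0 here because the demo
reference list is the exact planted increasing group and the planted effect
is strong; pass `--misannotation-rate` to `simulate` for a noisy list.

`gemtox robustness` reruns fit+report with the abundance threshold at 12 and
at 8 and with 23% of sites dropped, and tabulates the EC50 movement against
the base run's credible interval.

The same pipeline runs on real data: a tab-separated OTU table
(`otu_id`, optional `genus`, one column per site; mothur-shared-style
orientation via `--transpose`), per-site metadata (`site_id`,
`tph_mg_per_kg`), and an optional genus list (one per line).

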