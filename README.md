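# vaxshare

Analysis pipeline for a factorial vignette survey on public support for
global COVID-19 vaccine sharing. The package contains everything needed to
generate a synthetic survey panel with the assumed statistical structure and
to run the full analysis on it (or on real data with the same schemas):

- **`vaxshare.design`** — the 2 × 2 × 5 factorial design (trade impact,
  mutation risk, international-deal level), the deal → (number of countries,
  total amount) mapping, and mean-centered design matrices with interactions
  up to three-way (14 slope terms).
- **`vaxshare.cohort`** — synthetic panel generator: respondent roster with
  official demographic marginals, two uniform vignette assignments per
  respondent, contribution outcomes from the structural model plus
  heterogeneity and Gaussian noise (censored at zero), a two-arm
  information-video experiment, and a three-category beneficiary
  prioritization item. Fully reproducible from one seed.
- **`vaxshare.regression`** — centered factorial regression with respondent
  fixed effects (within-demeaning, verified against an explicit
  dummy-variable fit), cluster-robust (default) or HC2-style standard
  errors, and an average-marginal-effects table for the four conditions.
- **`vaxshare.structural`** — the public-goods utility
  `u(y) = (α + β·E + δ·H)·log(S + y) − γ(y − κ·ȳ)² − y²`, closed-form
  optimal contributions, the Gaussian reporting likelihood, and multi-start
  maximum-likelihood estimation of (α, β, δ, γ, κ, σ) with Wald inference.
  Note: the likelihood is exactly flat along a one-dimensional rescaling
  ridge — only (α, β, δ)/(1+γ), γκ/(1+γ) and σ are point-identified — and
  the fit reports unbounded standard errors in the flat directions (see
  `structural.identified_combinations`).
- **`vaxshare.video`** — robust difference-in-means ATEs for the video
  experiment (attitudinal scale, donation as percent of the 50-point
  endowment) plus donation-distribution summaries.
- **`vaxshare.describe`** — empirical support CDFs by scenario grouping
  (high/low costs, high/low multilateralism, or a custom rule),
  median/mean summaries, prioritization shares, and the fair-share
  benchmark arithmetic.

## CLI

```sh
vaxshare simulate --n 2000 --seed 1 --out-dir scratch/sim
vaxshare fit-factorial --design scratch/sim/assignments.tsv \
    --responses scratch/sim/responses.tsv --outcome cash --se cluster
vaxshare fit-structural --data scratch/sim/responses.tsv \
    --design scratch/sim/assignments.tsv --starts 5 --seed 1
vaxshare ate --data scratch/sim/video.tsv --outcome donation
vaxshare report --responses scratch/sim/responses.tsv \
    --design scratch/sim/assignments.tsv \
    --priorities scratch/sim/priorities.tsv --out-dir scratch/report
```

All tables are UTF-8 TSV with documented headers (see `vaxshare/io.py`);
real data with the same column schemas drop straight into the same
commands.

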