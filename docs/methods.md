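# Methods

This note documents the models, defaults and numerical choices behind
`cnaprog`, what the synthetic cohorts do and do not emulate, and the design
decisions taken where several reasonable options existed.

## Purity correction and gene-level copy number

Observed segment log2 ratios are modeled as a two-population mixture of
diploid stroma and tumor at purity `p ∈ (0, 1]`:

    r_obs = log2((p · c_t + 2(1 − p)) / 2),

with `c_t` the tumor copy number. The inversion
`c_t = (2^(r_obs + 1) − 2(1 − p)) / p` is clamped at a floor of 0.02 tumor
copies before the log so that homozygous deletions in low-purity samples
stay finite; within the clamp-free region the map is strictly increasing in
`r_obs` and exact (the synthetic round trip recovers tumor ratios to
1e-12). Purity is an input — estimating it, and segmentation itself, are
out of scope; the package consumes already-segmented profiles.

Gene values are the corrected value of the covering segment, or, for genes
spanning breakpoints, the **lower weighted median** of their internal
segments: the smallest value whose cumulative weight reaches half the
total. Weights are base-pair overlaps by default because they are
reproducible from the inputs alone; `weight_by="markers"` switches to the
segment marker counts. The lower-median tie rule is a deterministic
convention, verified against a unit-atom brute-force oracle. Genes without
coverage in a sample are missing; genes missing in more than 10% of
samples are dropped with a logged count.

Internally all intervals are 0-based half-open; the SEG reader converts
from the 1-based inclusive dialect and BED input is taken as already
0-based half-open. Strand is stored but ignored: copy number is
strand-agnostic.

## Candidate filters

**Correlation filter.** Per gene, Pearson correlation r between gene CN
and its own expression over all samples carrying both, mapped to
`z = atanh(r)·sqrt(n − 3)` with a one-sided alternative r > 0 — a CNA that
does not move expression in the same direction is unlikely to be
functional. Significance is judged jointly by the two-groups model: the
marginal density f(z) is estimated by Lindsey's method (Poisson GLM of
histogram counts, 60 bins, degree-5 polynomial), the null is the
theoretical N(0,1) with null proportion `pi0 = min(1, f(0)/φ(0))`, and
`lfdr(z) = pi0·φ(z)/f(z)` clipped to [0, 1]. The reported q-value is the
tail-averaged lfdr (mean lfdr over genes with z at least as large), which
is monotone along the p-value ranking; genes with q < 0.2 pass.
Benjamini–Hochberg is available as `fdr_method="bh"`, and Spearman as the
correlation statistic, for sensitivity analyses.

**Prognostic filter.** A gene passes with external survival evidence from
either source: membership in a curated outcome gene list, or a two-sided
p < 0.05 from an unweighted Stouffer combination `z_meta = Σz_i/√k` of
per-study signed survival z-scores. The direction of association is not
constrained — either direction counts as outcome-related. Candidates are
the intersection of the two filters, ordered by gene id.

## Constrained Cox models

All survival models maximize the Efron-tie Cox partial likelihood. Stage
enters as monotone indicator increments (IA → 0,0,0; IB → 1,0,0;
IIA → 1,1,0; IIB → 1,1,1), so a patient's stage log-hazard is the
cumulative sum of per-stage increments and risk is monotone in stage by
construction. The coefficients of age, male sex and every stage increment
are bounded below by zero, encoding prior clinical knowledge of their
directions; gene coefficients are unconstrained.

The bounded problem is solved with L-BFGS-B from β = 0 on a centered,
unit-scaled design (the partial likelihood is location-invariant, so
centering is exact, and scaling only reparameterizes the box constraints).
The negative partial log-likelihood is convex, and every reported optimum
is certified by its KKT conditions: |gradient| < 1e-5 on free coordinates
and gradient ≤ 1e-5 on coordinates pinned at the bound. A masked
coefficient ending below 1e-7 is snapped to exactly 0 and flagged as an
active constraint. **AIC counts only free parameters**: a coefficient at
an active bound contributes no parameter, so AIC = 2q − 2·logPL with q the
number of coefficients off the bound. Per-gene significance is a 1-df
likelihood-ratio test of clinical+gene vs clinical-only (both with the
clinical constraints); LRT was preferred over Wald because Wald standard
errors are unreliable when clinical coefficients sit on the boundary.

Evaluation statistics: the log-rank test (two groups, hypergeometric
variance, 1-df chi-square, via lifelines); Harrell's c-index over usable
pairs (the shorter time has an event; tied scores count 1/2); and a paired
one-sided comparison of two risk scores by the leave-one-out jackknife
variance of the c-index difference, computed in O(n²) from per-pair
contributions. Zero jackknife variance with zero difference yields
p = 0.5; swapping the two models maps p to 1 − p.

## NetRank

Candidate genes are re-ranked by `r = (1−d)·s + d·Mᵀr`, where
`s ∝ −log10(p)` normalized to sum 1 (uniform fallback when every p = 1;
`1 − p` available as an alternative transform), and M is the row-normalized
weight matrix of the gene network: edges are |Pearson r| ≥ 0.5 between gene
CN vectors over the **unlabeled** samples — the mechanism by which samples
without outcomes inform gene selection. Damping d = 0.3 by default and
exposed as a first-class knob (d = 0 reproduces the p-value ranking
exactly). The fixed point is found by power iteration (L1 tolerance 1e-10,
cap 1,000 iterations — a contraction for d < 1) and is checked against a
dense linear solve in the tests. Isolated (dangling) nodes donate nothing
but still receive their (1−d)s share; classic uniform redistribution is
available by flag. The network is restricted to post-filter candidates,
which keeps the linear algebra at desk scale. Ties in the final ranking
break by gene id, making the ordering fully deterministic.

## AIC ensemble and risk scores

Candidate models are the nested prefixes of the NetRank ordering,
M_0 (clinical only) through M_k, k ≤ 15 by default and additionally capped
so events exceed the largest model's parameter count. Models within
ΔAIC ≤ 10 of the best are retained and weighted by
`w_i = exp(−Δ_i/2)/Σexp(−Δ_j/2)`. The ensemble risk score is the
weight-averaged linear predictor with every covariate centered at its
training mean (so member predictors are on a common location). The flat
reported signature is the set of genes whose member models carry
cumulative Akaike weight ≥ 0.5 — because the models are nested, this is a
prefix of the ranking and is deterministic and weight-faithful. Patients
are dichotomized at the **median training risk score** (strictly greater
→ high risk, so an even training cohort splits in half); validation
cohorts can instead be split at their own median via
`threshold_mode="cohort-median"`. The univariate validation Cox uses the
score standardized to unit variance, and both the per-SD hazard ratio and
the dichotomized high-vs-low hazard ratio are reported, since either scale
may be wanted. The clinical-only reference score is M_0's fit; the
genomic-only reference is an unconstrained Cox on the reported genes
fitted on the training cohort.

## Synthetic cohorts

The generator emulates the structure of a multi-dataset early-stage
lung-cancer series, with defaults chosen once as the package's standard
study conditions:

- 1,000 genes on 10 chromosomes (100 kb gene grid, 20 kb genes), 200
  labeled + 300 unlabeled samples.
- Tumor profiles: a breakpoint process between genes (~3 segments per
  chromosome); background segments altered with probability 0.3 by
  N(0, 0.35) log2 shifts. 100 planted-correlation genes, 8 of which are
  planted prognostic, receive a focal ±1.0 log2 shift in ~40% of tumors.
- Observed segments mix tumor and diploid stroma exactly per the admixture
  formula at purity ~ Uniform(0.4, 0.9), so the preprocessing round trip
  is assertable to 1e-12.
- Expression: `expr = 1.0·cn_true + N(0, 0.5²)` for planted-correlation
  genes; independent N(0,1) otherwise.
- Survival: Weibull baseline (shape 1.2, scale 81.4 months → ~60-month
  baseline median, a typical early-stage follow-up scale) under a Cox
  linear predictor with age log-HR 0.03/year, sex 0, stage increments
  (0.4, 0.2, 0.3), and gene effects |log-HR| 0.6 per unit log2 ratio with
  random signs. Censoring times are Uniform(0, c) with c calibrated by
  bisection to a 40% censoring rate. Clinical covariates: age ~ N(65, 8),
  sex ~ Bernoulli(0.6 male), stage ~ (IA .35, IB .35, IIA .15, IIB .15).
- External evidence surrogate: the curated list holds all planted
  prognostic genes plus 60 unrelated genes; the study table gives planted
  genes three studies of z ~ ±|N(3.5, 0.7)| (signed by the gene's true
  effect) and 150 random genes null z-scores.

Prognostic effects act through **true tumor** copy number, not the
observed mixed signal, so purity correction demonstrably matters to
recovery. `simulate_validation` draws an independent labeled cohort from
the same planted truth, emulating an external validation series (the test
bench uses n = 200).

What the generator does **not** emulate: platform-specific microarray
noise, GC waves, allele-specific signal, inter-dataset batch effects,
biological pathway structure in the gene network, or informative
censoring. Passing tests therefore demonstrate the correctness and
calibration of the machinery under the stated model, not performance on
any real cohort.

## Problem sizes and numerical conventions

The test bench runs the full pipeline at the default conditions over 50
seeds (20 for recovery medians) with 200-patient validation cohorts, and
the acceptance script over 20 seeds — sizes chosen so the whole bench
completes in minutes on one core while keeping Monte-Carlo error small
relative to the asserted margins. Key tolerances: optimizer ftol 1e-14 /
gtol 1e-9 (scaled space); KKT certification 1e-5; active-bound snap 1e-7;
NetRank L1 tolerance 1e-10; Akaike weights must sum to 1 within 1e-9 in a
serialized signature. All randomness flows through
`numpy.random.default_rng` seeds carried in the configs, and a re-run with
the same seed and config produces a byte-identical signature document.

## Known limitations

- The admixture inversion assumes a diploid stromal compartment and a
  single tumor clone; subclonal CNAs bias gene values toward diploid.
- The local-FDR fit needs a few hundred genes to estimate f(z) stably;
  for small panels use `fdr_method="bh"`.
- Nested-prefix candidate models never revisit a gene dropped by the
  ranking; a gene only predictive in combination with a lower-ranked gene
  can be missed.
- Harrell's jackknife comparison is asymptotically normal; with very few
  events or heavily tied scores the one-sided p is approximate.
- No proportional-hazards diagnostics, time-dependent covariates,
  competing risks, or stratified baselines.
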