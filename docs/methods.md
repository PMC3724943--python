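# Methods

## The model

`brvd` tests whether any rare variant in a genomic region is associated
with a binary trait, and identifies which ones drive the association,
in one Bayesian variable-selection framework.  For a subset
ξ ⊆ {1..P} of variants, disease status follows a logistic regression

    logit P(y_i = 1) = α + Z_i η + G_{i,ξ} β,

with the genotype matrix G coded additively in minor-allele copies and
Z an optional covariate matrix.  The two hypotheses are H0 (ξ empty —
covariates only) and H1 (ξ non-empty).  Priors:

* every regression coefficient (α, η and β alike) is N(0, σ²) — tying
  the intercept and covariate coefficients to the same prior variance
  keeps the computation simple and the prior covariance eigenvalues
  controlled;
* σ² has an inverse-gamma(a, b) prior truncated to [l, u].  The
  truncation bounds the prior covariance, which the posterior
  consistency theory for small-n-large-P generalized linear models
  requires.  Defaults a = 1, b = 1, l = 1e-4, u = 1e4: the interval is
  wide enough for any realistic rare-variant problem, and the IG(1,1)
  density already suppresses σ² below ~0.05 strongly, so the lower
  bound is rarely active;
* each variant enters ξ independently with probability p_j = 1 − γ_j,
  where γ_j = clamp(γL + (γU − γL)·MAF_j / 0.05, γL, γU).  Rarer
  variants get larger prior inclusion weight; γL ∈ (0,1) is the
  tunable sparsity hyperparameter (large γL discourages selection) and
  γU = 0.999 bounds p_j away from 0 and 1 for multiplicity control.
  The functional form is pluggable (`prior_inclusion_prob`);
* the model prior is truncated to |ξ| ≤ `max_model_size` (default 10).
  A bounded a-priori model size is part of the consistency conditions,
  matches the working assumption that one region harbors at most ~10
  independent causal rare variants, and — practically — keeps the
  sampler's energy ladder finite and traversable.  Raise it (with
  longer runs) for larger association sets;
* hypotheses carry prior weights λ0 = λ1 = 1/2.

The global evidence is the Bayes factor BF = Z(H1)/Z(H0), the ratio of
the hypotheses' marginal likelihoods, converted to the posterior
probability π(H1|D) = λ1·BF/(λ0 + λ1·BF) and interpreted on Jeffreys'
scale; H0 is rejected when π(H1|D) > 0.75 (the lower edge of the
"substantial" band, i.e. BF > 3 under equal priors).  γL is chosen by
maximizing the estimated BF over a grid (a type-II maximum-likelihood
prior choice).

## Bayes factor estimation by SAMC

Summing Z(H1) over 2^P models is infeasible, and plain MCMC visits too
few models to estimate a ratio of normalizing constants.  Stochastic
approximation Monte Carlo (SAMC) learns log-weights θ_i for a
partition of the joint (hypothesis, model, parameter) space such that
all subregions are visited with prescribed frequencies π_i; at
convergence θ_i → C + log(∫_{E_i} ψ) − log π_i for the unnormalized
posterior ψ, so subregion masses — and hence the evidence ratio — are
read off θ.  Two partitions are implemented, both with the whole H0
space as subregion 0:

* **by energy** — the H1 space cut into m−1 equal-width bands of the
  energy U(x) = −log ψ(x);
* **by model size** — subregion k holds the models with exactly k
  variants (m = `max_model_size` + 1 subregions).

The pipeline defaults to the size partition: adjacent subregions are a
single ADD/DELETE move apart, so the flat-histogram ladder is always
well connected, replicate chains agree within ~1 nat at a few tens of
thousands of iterations, and the estimates match both exhaustive
enumeration on discretized toys and long energy-partition reference
runs.  The energy partition remains available (and is what the
flat-histogram diagnostics below describe); at reduced run lengths it
can carry a slow transient — the chain discovers deep H1 basins
before θ equilibrates across the band ladder, which overstates the
evidence until a few hundred thousand iterations have passed.

Design choices that matter in practice:

* **Energy bracket.**  The band ladder must span everything the chain
  should traverse.  `build_partition` sets the lower edge from the
  null-model MLE energy plus the baseline H1 model-prior cost
  (−Σ log(1−p_j)) minus a score-test bound on the best achievable
  likelihood gain (half the sum of the top-`max_model_size` squared
  per-variant score statistics) — without that bound, strongly
  associated datasets collapse all well-fitting models into the bottom
  band and the chain cannot mix across them.  The upper edge is the
  mean + 2 SD of the energy over draws from the size-capped model
  prior with coefficients at a reference σ² (prior median) and α, η at
  the null MLE — the chain never dwells at prior-typical values of the
  shared coefficients, so randomizing those would push the bracket
  into regions of negligible mass.
* **Proposal mixture.**  ADD (0.25) / DELETE (0.25) / SWAP (0.15) /
  WALK (0.20, symmetric Gaussian steps on all coefficients) / SIGMA
  (0.10, log-scale walk on σ² with reflection into [l, u]) / JUMP
  (0.05, between H0 and size-1 models).  Trans-dimensional moves draw
  the new coefficient from its conditional prior N(0, σ²); all
  proposal-density ratios are computed exactly.  DELETE from a size-1
  model and JUMP to H0 are pooled so the reverse masses match.
* **Informed ADD.**  Candidate variants are proposed with weight
  1 + z_j², where z_j is the marginal score statistic against the
  intercept-only fit.  The weights are fixed for the run (an ordinary
  independence ingredient of the kernel, exactly accounted in the
  acceptance ratio) and concentrate proposals on plausibly associated
  variants; `informed_add=False` restores uniform proposals.
* **Gain factor and averaging.**  a_t = t0/max(t0, t) with default
  t0 = 5000 (large t0 spreads the chain over all subregions quickly).
  θ is recentred to θ_1 = 0 after every update (compactness), and the
  Bayes-factor estimator uses the post-burn-in trajectory average of θ
  (Polyak averaging), which on enumerable toys cuts the estimator
  error several-fold relative to the final iterate.
* **Desired distribution.**  Uniform by default.  The BF denominator
  rests entirely on the H0 subregion's θ, so the pipeline runs give H0
  a boosted desired frequency (π_1 = 0.2, remainder uniform); the
  estimator weights by π, so this is a variance choice, not a bias.
* **Convergence gating.**  At reduced run lengths the evidence
  estimate has a heavy right tail: a chain that fails to keep bridging
  H0 and H1 lets θ ratchet and can overstate the log-BF by tens of
  nats.  The γL-selection layer therefore runs replicate chains and
  escalates the run length (×2, ×4) whenever the replicates disagree
  about which side of the BF = 3 decision threshold the evidence falls
  on; the reported value is the median of the final batch.  A gross
  shortfall of the H0 subregion's realized visit share raises a
  warning (diagnostic only — strongly supported H1 data can be slow to
  equilibrate that share without the evidence call being in doubt).
* **Estimators.**  BF = (λ0/λ1)·Σ_{i≥2} π_i e^{θ_i} / (π_1 e^{θ_1}),
  restricted to visited subregions (empty-subregion renormalization).
  Marginal inclusion probabilities are importance-weighted averages of
  the inclusion indicators over post-burn-in H1 samples with weights
  e^{θ_{J(x_t)}} recorded at visit time, accumulated online with
  rescaling to avoid overflow.

On instances small enough to enumerate (n ≤ 30, P ≤ 3, coefficients on
a 5-point grid, σ² fixed), both estimators are checked against
exhaustive summation; the same machinery (partition, θ updates,
estimators) runs in both modes, only the within-model proposal changes.

### Operating range of γL

Under the clamp form of the inclusion weight, the prior inclusion mass
Σ_j p_j at a given γL scales with P, and three failure modes bound the
usable grid at panel scale (P ≈ 600, size cap 10).  At the sparse end
(γL ≥ 0.95), Σ_j p_j falls to a few tens or less; with so little
multiplicity averaging the null evidence does not concentrate —
converged null log-BFs sit within a few nats of the log 3 rejection
threshold (γL = 0.99 even crosses it), so any estimator noise causes
false rejections.  At the dense end (γL ≤ 0.8), the per-variant prior
inclusion cost (−log odds ≈ 1.7 nats at 0.8) drops below the
combinatorial entropy of boundary-size subsets, and the evidence
genuinely aggregates the best chance fits: converged null log-BFs of
+10 were observed — the prior itself is anti-conservative there.
Dense values also choke the H0 bridge (almost no in-band mass at the
size-1 states), destabilizing the estimator.  In between, γL ∈
[0.85, 0.9] gives per-variant costs ≥ 2 nats and prior mass 45–70:
converged null log-BFs of −12 to −46 across datasets, with wide
margins.  The pipeline studies therefore select γL over {0.85, 0.9}
at panel scale and {0.7, 0.9} for ~100-variant panels (small panels
do not reach the chance-aggregation regime).  The conventional grid
spans 0.4–0.99; with this package's clamp parameterization the
calibrated operating range is the narrower one above, and the
argmax on full-scale null data lands at 0.9.

## Causal-variant detection

The marginal inclusion probabilities q_j are transformed to probit
scores z_j = Φ⁻¹(clip(q_j, 1e-4, 1−1e-4)) and compared with an
empirical null fitted to the central bulk: mu0 is the median and s0
the IQR/1.349 (exact for a normal, affine-equivariant, robust to a
minority of signal scores).  Variants the sampler almost never
included pile up at the clip floor; when more than 10% of scores sit
there, the scale is additionally matched to the upper-quartile spread
(which the floor cannot contract and signal only inflates — the
conservative direction), with an absolute floor of 0.05.  The null
proportion pi0 is estimated by central matching and capped at 1.  The
selection rule takes the smallest threshold κ whose estimated FDR
pi0·P·S_null(κ)/#{z > κ} is below the requested level, made monotone
by step-up q-values, so a lower FDR level always selects a subset.
Panels with fewer than 20 variants skip the empirical null and fall
back to the median-probability-model rule (select iff q_j > 1/2).

Replicate chains: `n_runs` independent SAMC runs per γL are averaged
(log-BF mean; mip mean), the same device the full-scale analyses use
with five repeats.

## Divide-and-conquer pipeline

Large panels are split (by chromosome or fixed-size chunks), each
subset is tested and screened at a liberal FDR (default 0.25 — subsets
that miss causal variants recruit surrogates, so the screen must be
permissive), survivors are pooled, and the detector runs once more on
the pool.  The second-stage Bayes factor is selection-biased and is
flagged as such; global significance comes from a permutation p-value:
the phenotype is permuted, the whole screen-combine-test pipeline is
re-run per permutation, and p = (1 + #{BF_perm ≥ BF_obs})/(n_perm+1).
When the screened union is empty the statistic falls back to the
maximum subset-level Bayes factor — the same rule for observed and
permuted data, preserving exchangeability while avoiding mass ties.

## Synthetic data

The generator emulates a rare-variant resampling design without any
external download.  Per-site allele frequencies are drawn from a
truncated Beta(0.3, 30) capped at 5% (rare-skewed; most mass below
1%), haplotypes from a first-order Gaussian copula with latent AR(1)
correlation `ld_decay` (default 0.5, short-range LD), pooled into 2000
haplotypes over 1200 sites.  Each subject draws two haplotypes;
covariates are a Bernoulli(1/2) "sex" (coefficient 0.5) and a uniform
[20, 60] "age" (coefficient 0.02); under H1 the first 10 variants are
causal with log-odds ratios drawn once per dataset from N(0, 1.5²).
The intercept is tuned on a pilot batch so prevalence ≈ 50%, and cases
and controls are rejection-sampled to exactly 250/250.  Zero-MAF
columns and columns whose realized sample MAF exceeds the cap are
dropped and the first 600 survivors kept — so the number of surviving
causal variants is a random variable, usually 5–10 under strong
effects.

What the generator does **not** emulate: coalescent genealogy and
realistic long-range LD, population structure, genotyping error or
missingness, covariate-genotype confounding.  Passing tests on these
data show the method's statistical machinery is correct and calibrated
under the stated design; they do not by themselves establish
performance on real sequence data.

## Study scales used by the tests and the acceptance script

Chosen to keep a full run on one CPU in minutes while leaving the
study conditions (sample sizes, panel sizes, effect scales) intact:

* type-I error: 50 null datasets at full data scale (250/250 subjects,
  600 variants), sampler reduced to 30k iterations (7.5k burn-in),
  t0 = 1000, size partition, γL grid {0.85, 0.9}, two replicate
  chains per value; both covariate-adjusted and covariate-omitted
  fits on the same datasets.
* parameter recovery: 20 datasets, 5 causal among 100 variants,
  n = 500; causal effects 2.0 + U(0, 0.5) in magnitude with random
  signs (all |log-OR| ≥ 1.5), panel MAFs uniform on [3.2%, 4.2%]
  (carrier counts ~30-40 — at n = 500 a variant needs roughly that
  marginal information to be identifiable at all), independent sites
  (LD surrogates are genuinely associated, which strict truth labels
  would count as false positives); 60k iterations, three replicate
  chains per γL.
* oracle equivalence: n ≤ 30, P = 3, 5-point coefficient grid, 250k
  iterations.
* permutation calibration: 20 replicates × 99 permutations on 80 × 16
  null panels with a 2-chunk plan and 1.2k-iteration runs.

## Numerical details and edge cases

* Likelihood via a stable softplus; ψ ratios in log space throughout;
  importance-weight accumulators carry a running log-shift.
* Truncated-inverse-gamma normalizer via the regularized incomplete
  gamma function; the density integrates to 1 over [l, u] to 1e-8
  (quadrature-checked).
* Energies exactly at a band edge belong to the lower band; H1
  energies outside the bracket clip to the boundary bands.
* Inapplicable moves (ADD at the size cap, DELETE under H0, SWAP at
  k = 0 or k = P, JUMP from k ≥ 2) count as rejections.
* Missing genotypes are imputed as zero copies with a warning
  (conservative for rare alleles); multi-allelic VCF records are
  skipped and counted; sites whose coded-allele frequency exceeds 1/2
  are recoded to minor-allele counts.
* Ties in γL selection break toward the larger (sparser) value.
* Degenerate score sets (all equal) are flagged and select nothing.

## Known limitations

* The evidence estimate at a given run length degrades as the prior
  inclusion mass grows (dense-γL regime) — the γL operating-range
  rule above is a mitigation, not a removal, of this limit.
* The marginal-inclusion estimator effectively uses the samples of the
  lowest occupied energy bands; on multimodal posteriors single chains
  can lock onto one explanation, which is why replicate-chain
  averaging is the default in the studies.
* Interaction terms, continuous phenotypes and non-local priors are
  out of scope.
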