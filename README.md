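# brvd — Bayesian rare-variant detector

Rare variants (minor allele frequency below ~5%) carry much of the
heritability that single-marker association tests cannot see: with a
handful of carriers per variant, marginal tests are powerless, and
burden/kernel methods that pool a region can only say *whether* the
region is associated, not *which* variants drive it.  `brvd` addresses
both questions at once for case-control sequence data:

1. **Global association test** — is any variant in the region
   associated with the disease?  The model is a Bayesian
   variable-selection logistic regression: a subset ξ of variants
   enters the linear predictor, coefficients get Gaussian priors with
   a truncated inverse-gamma variance, and each variant's prior
   inclusion probability decreases with its MAF so that rare variants
   are favoured and multiplicity is controlled.  The test statistic is
   the Bayes factor BF = Z(H1)/Z(H0), a ratio of marginal likelihoods
   estimated consistently by stochastic approximation Monte Carlo
   (SAMC) — an adaptive flat-histogram sampler that learns log-weights
   for an energy-band partition of the joint (hypothesis, model,
   parameter) space.  BF converts to π(H1|D) = λ1·BF/(λ0 + λ1·BF) and
   is read on Jeffreys' scale; H0 is rejected when π(H1|D) > 0.75.
2. **Causal-variant detection** — which variants drive it?  The same
   run yields each variant's marginal inclusion probability by
   importance weighting; probit-transformed scores are compared with
   an empirical null fitted to their central bulk, and variants are
   selected by a local-FDR threshold at a user-chosen level.

A divide-and-conquer mode (`brvd.parallel`) handles panels too large
for one run — screen chromosome-sized subsets at a liberal FDR, pool
the survivors, re-run the detector, and assess global significance
with a permutation p-value that is immune to the selection bias.  A
self-contained generator (`brvd.simdata`) reproduces the kind of
rare-variant case-control data the method is designed for (haplotype
pool with a rare-skewed frequency spectrum and short-range LD, exact
case/control quotas, covariates, planted causal effects) and powers
the test-suite studies.  See `docs/methods.md` for the model, the
sampler design and the study scales.

## Worked example

Simulate a 500-subject panel of 100 rare variants (all MAF 3–4%) with
five planted causal variants of |log-odds ratio| ≥ 2 in columns 0–4,
then test and detect:

```python
import numpy as np
from brvd import (SimDesign, simulate_dataset, PriorConfig, SamcSettings,
                  global_test, detect_variants)

rng = np.random.default_rng(0)
beta = tuple(rng.choice([-1, 1], 5) * (2.0 + rng.uniform(0, 0.5, 5)))
design = SimDesign(h1=True, n_causal=5, beta_causal=beta, P_keep=100,
                   P_raw=260, pool_size=2000, ld_decay=0.0,
                   maf_spectrum=("uniform", 0.032, 0.042), seed=1)
data, truth = simulate_dataset(design)

settings = SamcSettings(iterations=60_000, burnin=15_000, t0=1000, m=61)
res = global_test(data, PriorConfig(), settings, grid=(0.7, 0.9), seed=2)
det = detect_variants(data, PriorConfig(), settings, fdr_level=0.05,
                      grid=(0.7, 0.9), seed=2, n_runs=2)
```

Output of this exact script (about a minute on one CPU):

```
selected gammaL = 0.7, log BF = 27.4, post_h1 = 1.000, grade = 5, reject = True
selected variants: [0, 1, 2, 3, 4]
top-10 by inclusion probability: [1, 3, 0, 4, 2, 52, 99, 9, 43, 44]
their mips: [1.0, 1.0, 1.0, 1.0, 0.99, 0.43, 0.39, 0.34, 0.31, 0.28]
```

Reading it: the evidence for association is decisive (grade 5, log
Bayes factor 27.4, posterior probability ≈ 1), the five planted
variants occupy the top five inclusion probabilities with a clear gap
to the best noise variant (0.99 vs 0.43), and the FDR-0.05 rule
selects exactly the five causal columns.

The same pipeline runs from the shell: `brvd simulate`, `brvd test`,
`brvd detect`, `brvd parallel` (with `--permute` for the unbiased
p-value), `brvd roc`; every run writes a JSON manifest with the
config, seed and versions, so results are reproducible from the
manifest alone.

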