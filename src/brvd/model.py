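"""The joint probability model targeted by the sampler.

The model is a Bayesian variable-selection logistic regression for
case-control data.  For a subset ``xi`` of variants, disease status
follows

    logit P(y_i = 1) = alpha + Z_i eta + G_{i,xi} beta,

with independent Gaussian N(0, sigma2) priors on all regression
coefficients (intercept, covariate and variant effects share one prior
variance), a truncated inverse-gamma prior on sigma2, and a model prior
that includes each variant independently with a probability that
decreases with its minor allele frequency — rarer variants are favoured
a priori, and the boundedness of the per-variant inclusion probability
controls the multiplicity when the number of variants is large.

The two hypotheses of the global association test are H0 (no variant in
the region has an effect, the model contains covariates only) and H1
(at least one variant is included).  ``log_psi`` evaluates the
unnormalized posterior over the joint (hypothesis, model, parameter)
space; its negative is the energy function used to partition the sample
space for the SAMC sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

from .data import Dataset

__all__ = [
    "PriorConfig",
    "ModelState",
    "log_likelihood",
    "trunc_invgamma_logpdf",
    "log_coefficient_prior",
    "prior_inclusion_prob",
    "log_model_prior",
    "log_psi",
    "energy",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the coefficient, variance and model priors.

    Attributes
    ----------
    a, b
        Shape and scale of the inverse-gamma prior on ``sigma2``.
    l, u
        Truncation interval of the variance prior, ``0 < l < u``.  The
        default span ``[1e-4, 1e4]`` is wide enough for rare-variant
        selection problems while keeping the prior covariance bounded
        (a requirement for posterior consistency).
    gammaL, gammaU
        Bounds of the MAF-dependent exclusion weight, both in (0, 1).
        ``gammaL`` is the tunable sparsity hyperparameter: a large value
        discourages variant selection.  It is normally chosen by
        maximizing the estimated Bayes factor over a grid.
    maf_cap
        MAF scale constant; the exclusion weight reaches ``gammaU`` at
        this frequency (default 0.05, the rare-variant cap).
    lambda0, lambda1
        Prior probabilities of H0 and H1 (must sum to 1).
    max_model_size
        Truncation of the model prior: subsets with more than this many
        variants get zero prior mass.  A bounded a-priori model size is
        required for posterior consistency in the small-n-large-P
        regime, and the bound keeps the sampler's energy ladder finite
        and traversable.  The default 10 encodes the working assumption
        that a single genomic region harbors at most ~10 independent
        causal rare variants; raise it (with longer runs) for larger
        association sets.
    sigma2_covariate_tied
        The intercept and covariate coefficients share the variant
        coefficients' prior variance.  Fixed true.
    standardize_covariates
        Optional z-scoring of the covariate matrix before fitting.
    """

    a: float = 1.0
    b: float = 1.0
    l: float = 1e-4
    u: float = 1e4
    gammaL: float = 0.9
    gammaU: float = 0.999
    maf_cap: float = 0.05
    lambda0: float = 0.5
    lambda1: float = 0.5
    max_model_size: int = 10
    sigma2_covariate_tied: bool = True
    standardize_covariates: bool = False

    def __post_init__(self):
        if not (0 < self.l < self.u):
            raise ValueError("variance truncation requires 0 < l < u")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("inverse-gamma parameters a, b must be positive")
        if not (0 < self.gammaL <= self.gammaU < 1):
            raise ValueError("need 0 < gammaL <= gammaU < 1")
        if not (0 < self.lambda0 < 1 and 0 < self.lambda1 < 1):
            raise ValueError("hypothesis priors must lie in (0, 1)")
        if self.max_model_size is not None and self.max_model_size < 1:
            raise ValueError("max_model_size must be at least 1")
        if abs(self.lambda0 + self.lambda1 - 1.0) > 1e-12:
            raise ValueError("lambda0 + lambda1 must equal 1")

    def with_gammaL(self, gammaL: float) -> "PriorConfig":
        return replace(self, gammaL=gammaL)


@dataclass
class ModelState:
    """One point of the joint (hypothesis, model, parameter) space."""

    h1: bool
    included: np.ndarray  # ordered variant indices; empty iff H0
    alpha: float
    eta: np.ndarray
    beta: np.ndarray
    sigma2: float

    def __post_init__(self):
        self.included = np.asarray(self.included, dtype=np.intp)
        self.eta = np.atleast_1d(np.asarray(self.eta, dtype=np.float64))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=np.float64))
        if self.h1 and len(self.included) == 0:
            raise ValueError("an H1 state must include at least one variant")
        if not self.h1 and len(self.included) > 0:
            raise ValueError("an H0 state cannot include variants")
        if len(self.beta) != len(self.included):
            raise ValueError("beta length must match the included set")

    @staticmethod
    def null(q: int = 0, alpha: float = 0.0, sigma2: float = 1.0,
             eta=None) -> "ModelState":
        if eta is None:
            eta = np.zeros(q)
        return ModelState(h1=False, included=np.empty(0, dtype=np.intp),
                          alpha=alpha, eta=eta, beta=np.empty(0),
                          sigma2=sigma2)


# ---------------------------------------------------------------------------
# likelihood


def linear_predictor(state: ModelState, data: Dataset) -> np.ndarray:
    lp = np.full(data.n, state.alpha)
    if data.q:
        lp += data.Z @ state.eta
    if len(state.included):
        if state.included.max() >= data.P or state.included.min() < 0:
            raise IndexError("included variant index out of range")
        lp += data.G[:, state.included] @ state.beta
    return lp


def log_likelihood(state: ModelState, data: Dataset) -> float:
    """Bernoulli log likelihood of the logistic model at ``state``.

    Evaluated as ``sum(y * lp) - sum(log(1 + exp(lp)))`` with a stable
    softplus, so it is finite for any finite coefficients.
    """
    lp = linear_predictor(state, data)
    return float(data.y @ lp - np.logaddexp(0.0, lp).sum())


def loglik_from_lp(y: np.ndarray, lp: np.ndarray) -> float:
    """Same likelihood given a precomputed linear predictor (sampler path)."""
    return float(y @ lp - np.logaddexp(0.0, lp).sum())


# ---------------------------------------------------------------------------
# priors


def _invgamma_lognorm(cfg: PriorConfig) -> float:
    # P(l <= sigma2 <= u) under untruncated InvGamma(a, b); the incomplete
    # gamma ratio gives the CDF: F(x) = Q(a, b/x).
    mass = special.gammaincc(cfg.a, cfg.b / cfg.u) - special.gammaincc(
        cfg.a, cfg.b / cfg.l
    )
    if mass <= 0:
        raise ValueError("variance truncation interval has no prior mass")
    return float(np.log(mass))


def trunc_invgamma_logpdf(sigma2: float, cfg: PriorConfig) -> float:
    """Log density of the truncated inverse-gamma variance prior.

    The InvGamma(a, b) density renormalized to integrate to one over the
    truncation interval ``[l, u]``; ``-inf`` outside it.
    """
    if sigma2 < cfg.l or sigma2 > cfg.u:
        return -np.inf
    logpdf = (
        cfg.a * np.log(cfg.b)
        - special.gammaln(cfg.a)
        - (cfg.a + 1.0) * np.log(sigma2)
        - cfg.b / sigma2
    )
    return float(logpdf - _invgamma_lognorm(cfg))


def _normal_logpdf_sum(x: np.ndarray, sigma2: float) -> float:
    x = np.atleast_1d(x)
    k = x.size
    return float(-0.5 * k * (_LOG_2PI + np.log(sigma2))
                 - 0.5 * np.dot(x, x) / sigma2)


def log_coefficient_prior(state: ModelState, cfg: PriorConfig) -> float:
    """Joint log prior of (alpha, eta, beta, sigma2).

    Independent N(0, sigma2) on every regression coefficient — the
    intercept and covariate coefficients are tied to the same prior
    variance as the variant effects — plus the truncated inverse-gamma
    log density of sigma2.  Returns ``-inf`` when sigma2 violates the
    truncation interval.
    """
    lv = trunc_invgamma_logpdf(state.sigma2, cfg)
    if lv == -np.inf:
        return -np.inf
    coefs = np.concatenate(([state.alpha], state.eta, state.beta))
    return _normal_logpdf_sum(coefs, state.sigma2) + lv


def prior_inclusion_prob(maf_j, cfg: PriorConfig):
    """Prior probability that a variant with the given MAF is included.

    Parameterized through a per-variant exclusion weight

        gamma_j = clamp(gammaL + (gammaU - gammaL) * maf_j / maf_cap,
                        gammaL, gammaU),

    with inclusion probability ``p_j = 1 - gamma_j``.  The result is
    non-increasing in MAF (rarer variants get larger prior weight) and
    non-increasing in ``gammaL`` (a large ``gammaL`` discourages
    selection); it lies in ``[1 - gammaU, 1 - gammaL]``.
    """
    maf_j = np.asarray(maf_j, dtype=np.float64)
    if (maf_j <= 0).any():
        raise ValueError("MAF must be strictly positive")
    g = np.clip(
        cfg.gammaL + (cfg.gammaU - cfg.gammaL) * maf_j / cfg.maf_cap,
        cfg.gammaL,
        cfg.gammaU,
    )
    p = 1.0 - g
    return float(p) if p.ndim == 0 else p


def log_model_prior(included, data: Dataset, cfg: PriorConfig) -> float:
    """Log prior probability of a variant subset under independent inclusion.

    ``sum_j e_j log p_j + (1 - e_j) log(1 - p_j)`` with ``p_j`` the
    MAF-dependent prior inclusion probability.  Normalizes over the full
    2^P model lattice when ``max_model_size >= P`` (the empty model's
    mass is carried by H0's prior weight instead, see ``log_psi``);
    larger subsets than ``max_model_size`` get ``-inf``.
    """
    included = np.asarray(included, dtype=np.intp)
    if len(included) and (included.max() >= data.P or included.min() < 0):
        raise IndexError("included variant index out of range")
    if (cfg.max_model_size is not None
            and len(included) > cfg.max_model_size):
        return -np.inf
    p = prior_inclusion_prob(data.maf, cfg)
    e = np.zeros(data.P, dtype=bool)
    e[included] = True
    return float(np.log(p[e]).sum() + np.log1p(-p[~e]).sum())


# ---------------------------------------------------------------------------
# unnormalized posterior / energy


def log_psi(state: ModelState, data: Dataset, cfg: PriorConfig) -> float:
    """Log of the unnormalized posterior over the joint sample space.

    Under H1: ``log lambda1 + log P(model) + log prior(coefs, sigma2)
    + log likelihood``.  Under H0 the model-prior term is absent and the
    hypothesis weight is ``lambda0``.  The energy function is
    ``U(x) = -log_psi(x)``.
    """
    lcp = log_coefficient_prior(state, cfg)
    if lcp == -np.inf:
        return -np.inf
    ll = log_likelihood(state, data)
    if state.h1:
        return float(np.log(cfg.lambda1)
                     + log_model_prior(state.included, data, cfg) + lcp + ll)
    return float(np.log(cfg.lambda0) + lcp + ll)


def energy(state: ModelState, data: Dataset, cfg: PriorConfig) -> float:
    """Energy ``U(x) = -log_psi(x)`` of a state."""
    return -log_psi(state, data, cfg)
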