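"""Independent brute-force oracles used to validate the samplers.

Everything here is deliberately naive: exhaustive enumeration over tiny
discrete state spaces, numeric quadrature, transition-matrix
eigenanalysis.  Nothing imports the sampler's own estimators.
"""

import itertools

import numpy as np
from scipy.special import logsumexp

from brvd.model import ModelState, log_psi


def enumerate_discrete_posterior(data, cfg, coef_grid, sigma2):
    """Exhaustive summation over (hypothesis, model, grid-coefficients).

    All coefficients (intercept and variant effects) live on
    ``coef_grid``; ``sigma2`` is fixed.  Returns ``(log_bf, mip)`` with
    ``log_bf = log Z1 - log Z0 - log(lambda1/lambda0)`` (the evidence
    ratio) and the exact marginal inclusion probabilities under the H1
    posterior.  Only valid for q = 0 (no covariates).
    """
    assert data.q == 0
    P = data.P
    grid = list(coef_grid)
    logs_h0 = [
        log_psi(ModelState.null(q=0, alpha=a, sigma2=sigma2), data, cfg)
        for a in grid
    ]
    z0 = logsumexp(logs_h0)
    vals, models = [], []
    for k in range(1, P + 1):
        for incl in itertools.combinations(range(P), k):
            incl_arr = np.asarray(incl, dtype=np.intp)
            for a in grid:
                for betas in itertools.product(grid, repeat=k):
                    st = ModelState(True, incl_arr, a, np.empty(0),
                                    np.asarray(betas), sigma2)
                    lp = log_psi(st, data, cfg)
                    if np.isfinite(lp):
                        vals.append(lp)
                        models.append(incl)
    vals = np.asarray(vals)
    z1 = logsumexp(vals)
    w = np.exp(vals - z1)
    mip = np.zeros(P)
    for wi, incl in zip(w, models):
        for j in incl:
            mip[j] += wi
    log_bf = float(np.log(cfg.lambda0 / cfg.lambda1) + z1 - z0)
    return log_bf, mip


def trunc_invgamma_mass(cfg, n_points=20001):
    """Numeric quadrature of the truncated inverse-gamma density."""
    from brvd.model import trunc_invgamma_logpdf

    # log-spaced grid handles the wide default interval
    x = np.logspace(np.log10(cfg.l), np.log10(cfg.u), n_points)
    y = np.exp([trunc_invgamma_logpdf(v, cfg) for v in x])
    return float(np.trapezoid(y, x))


def model_prior_total_mass(data, cfg):
    """Sum of the model prior over the full 2^P lattice (P small)."""
    from brvd.model import log_model_prior

    P = data.P
    total = 0.0
    for k in range(P + 1):
        for incl in itertools.combinations(range(P), k):
            lp = log_model_prior(np.asarray(incl, dtype=np.intp), data, cfg)
            if np.isfinite(lp):
                total += np.exp(lp)
    return total
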