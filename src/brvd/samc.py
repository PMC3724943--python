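"""Stochastic approximation Monte Carlo over the joint model space.

SAMC is an adaptive MCMC algorithm that learns a vector of log-weights
``theta``, one per subregion of a partition of the sample space, so that
all subregions are visited with prescribed frequencies.  Here the H0
parameter space is a single subregion and the H1 space is partitioned
into equally spaced energy bands; the converged ``theta`` then yields a
consistent estimator of the Bayes factor (a ratio of normalizing
constants), and the visited states, importance-weighted by
``exp(theta)``, yield consistent marginal inclusion probabilities.

One iteration: (a) a Metropolis-Hastings update targeting the
theta-weighted distribution ``psi(x) / exp(theta_{J(x)})``; (b) a
stochastic-approximation update ``theta_i += a_t (I(i = J(x)) - pi_i)``
with the decaying gain factor ``a_t = t0 / max(t0, t)``, followed by a
recentering that pins ``theta_1 = 0`` (theta is only identified up to an
additive constant).

The proposal is a mixture of model-space moves (ADD / DELETE / SWAP a
variant, JUMP between H0 and a size-1 model) and parameter moves (a
symmetric Gaussian random walk on the coefficients and a log-scale walk
on sigma2 reflected into its truncation interval).  Trans-dimensional
moves draw the new coefficient from its conditional prior N(0, sigma2).
A discrete coefficient-grid mode (``coef_grid`` + ``sigma2_fixed``)
replaces the parameter draws with uniform draws from a finite grid; on
that finite space the sampler can be checked against exhaustive
enumeration.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .data import Dataset
from .model import (
    ModelState,
    PriorConfig,
    linear_predictor,
    log_psi,
    loglik_from_lp,
    prior_inclusion_prob,
    trunc_invgamma_logpdf,
    _normal_logpdf_sum,
)

__all__ = [
    "Partition",
    "SamcSettings",
    "SamcRun",
    "EstimationError",
    "build_partition",
    "gain_factor",
    "propose",
    "mh_accept_ratio",
    "update_theta",
    "run_samc",
    "estimate_log_bayes_factor",
    "estimate_bayes_factor",
    "estimate_marginal_inclusion",
]

_LOG_2PI = np.log(2.0 * np.pi)


class EstimationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# partition


@dataclass(frozen=True)
class Partition:
    """Partition of the joint sample space.

    Subregion 0 (index ``0``) is always the entire H0 parameter space.

    ``kind="energy"`` (default): the H1 space is split into ``m - 1``
    equally spaced energy bands over ``[u_min, u_max]``; H1 energies
    below ``u_min`` map to the first band, above ``u_max`` to the last.

    ``kind="size"``: the H1 space is split by model size, subregion k
    holding the models with exactly k variants (``m - 1`` sizes).
    Adjacent subregions are one ADD/DELETE move apart, which makes the
    flat-histogram ladder extremely well connected when the model size
    is capped at a small value.
    """

    m: int
    u_min: float = 0.0
    u_max: float = 1.0
    desired_pi: np.ndarray = None
    kind: str = "energy"

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("partition needs m >= 2 subregions")
        if self.kind not in ("energy", "size"):
            raise ValueError(f"unknown partition kind {self.kind!r}")
        if self.kind == "energy" and not self.u_min < self.u_max:
            raise ValueError("u_min must be below u_max")
        pi = self.desired_pi
        if pi is None:
            pi = np.full(self.m, 1.0 / self.m)
        pi = np.asarray(pi, dtype=np.float64)
        if len(pi) != self.m or (pi <= 0).any():
            raise ValueError("desired_pi must be positive with length m")
        object.__setattr__(self, "desired_pi", pi / pi.sum())

    @property
    def band_width(self) -> float:
        return (self.u_max - self.u_min) / (self.m - 1)

    def region_index(self, energy: float, is_h1: bool,
                     size: int = None) -> int:
        """0-based subregion index of a state."""
        if not is_h1:
            return 0
        if self.kind == "size":
            if size is None:
                raise ValueError("size partition needs the model size")
            return min(max(int(size), 1), self.m - 1)
        band = int(np.ceil((energy - self.u_min) / self.band_width)) - 1
        return 1 + min(max(band, 0), self.m - 2)


def _null_mle(data: Dataset):
    """Intercept/covariate MLE of the covariates-only logistic model."""
    import statsmodels.api as sm

    X = np.column_stack([np.ones(data.n), data.Z])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(data.y, X).fit(disp=0, maxiter=200)
        coef = np.asarray(fit.params, dtype=float)
        if np.isfinite(coef).all():
            return coef[0], coef[1:]
    except Exception:
        pass
    ybar = float(np.clip(data.y.mean(), 1e-6, 1 - 1e-6))
    return float(np.log(ybar / (1 - ybar))), np.zeros(data.q)


def _sample_sigma2(cfg: PriorConfig, rng) -> float:
    """Inverse-CDF draw from the truncated inverse-gamma prior."""
    from scipy.stats import invgamma

    dist = invgamma(cfg.a, scale=cfg.b)
    lo, hi = dist.cdf(cfg.l), dist.cdf(cfg.u)
    return float(np.clip(dist.ppf(rng.uniform(lo, hi)), cfg.l, cfg.u))


def _prior_sigma2_median(cfg: PriorConfig) -> float:
    from scipy.stats import invgamma

    dist = invgamma(cfg.a, scale=cfg.b)
    lo, hi = dist.cdf(cfg.l), dist.cdf(cfg.u)
    return float(np.clip(dist.ppf(0.5 * (lo + hi)), cfg.l, cfg.u))


def _prior_energy_stats(data: Dataset, cfg: PriorConfig, n_draws: int = 64):
    """Mean/SD of the energy over draws from the (size-capped) H1 prior.

    Used to bracket the energy range: the flat-histogram ladder must
    reach the typical states of the model prior, otherwise the top band
    becomes a catch-all the sampler cannot traverse.  sigma2 is held at
    its prior median — the bracket tracks where the chain actually
    dwells, and extreme sigma2 draws would push the bracket into
    regions of negligible mass.
    """
    rng = np.random.default_rng(12345)  # partition is deterministic
    p = prior_inclusion_prob(data.maf, cfg)
    kmax = cfg.max_model_size or data.P
    sigma2 = _prior_sigma2_median(cfg)
    sd = np.sqrt(sigma2)
    a_hat, eta_hat = _null_mle(data)
    energies = np.empty(n_draws)
    for i in range(n_draws):
        incl = np.nonzero(rng.random(data.P) < p)[0]
        if len(incl) == 0:
            incl = np.array([int(rng.integers(data.P))])
        elif len(incl) > kmax:
            incl = rng.choice(incl, size=kmax, replace=False)
            incl.sort()
        # randomize the variant part only: the chain keeps the shared
        # intercept/covariate coefficients near their fitted values even
        # in high-energy states, so prior draws there would push the
        # bracket into regions of negligible within-band mass
        state = ModelState(
            True, incl, a_hat, eta_hat,
            rng.normal(0, sd, len(incl)), sigma2,
        )
        energies[i] = -log_psi(state, data, cfg)
    return float(energies.mean()), float(energies.std())


def build_partition(
    data: Dataset,
    cfg: PriorConfig,
    m: int = 51,
    u_min: float = None,
    u_max: float = None,
    pi0: float = None,
    kind: str = "energy",
) -> Partition:
    """Equally spaced energy partition bracketing the achievable range.

    By default ``u_min`` is the energy of the null model at its maximum
    likelihood fit, shifted by the baseline model-prior cost that every
    H1 state carries (``-sum_j log(1 - p_j)``), minus a score-test
    bound on the likelihood gain the best size-capped model could
    achieve (half the sum of the top squared per-variant score
    statistics) and a 10-nat margin — the band ladder must reach below
    the best-fitting H1 states, or they all collapse into the bottom
    band and the sampler cannot mix across strong models;
    ``u_max`` is the mean plus two standard deviations of the
    energy over draws from the size-capped H1 prior, so the band ladder
    spans everything from the best-fitting sparse models up to the
    prior-typical bulk.  Energies outside the bracket fall into the
    boundary bands.

    ``pi0`` optionally sets the desired sampling frequency of the H0
    subregion (the remaining mass is spread uniformly over the H1
    bands).  The Bayes-factor denominator rests entirely on the H0
    subregion's theta, so visiting it more often than 1/m sharpens the
    estimate; the estimator weights by the desired distribution, so
    this is a variance choice, not a bias.

    ``kind="size"`` ignores the energy bracket and partitions the H1
    space by model size into ``max_model_size`` subregions.
    """
    if kind == "size":
        kmax = cfg.max_model_size or min(data.P, 20)
        m = kmax + 1
        desired = None
        if pi0 is not None:
            if not (0 < pi0 < 1):
                raise ValueError("pi0 must lie in (0, 1)")
            desired = np.full(m, (1.0 - pi0) / (m - 1))
            desired[0] = pi0
        return Partition(m=m, kind="size", desired_pi=desired)
    if m < 2:
        raise ValueError("partition needs m >= 2 subregions")
    sigma2_ref = float(np.clip(1.0, cfg.l, cfg.u))
    if u_min is None:
        a_hat, eta_hat = _null_mle(data)
        mle_state = ModelState.null(q=data.q, alpha=a_hat, sigma2=sigma2_ref,
                                    eta=eta_hat)
        p = prior_inclusion_prob(data.maf, cfg)
        base_cost = -np.log1p(-p).sum()
        # score-test bound on the achievable likelihood gain of the
        # best model within the size cap
        lp = np.full(data.n, a_hat)
        if data.q:
            lp += data.Z @ eta_hat
        phat = 1.0 / (1.0 + np.exp(-lp))
        w = phat * (1.0 - phat)
        num = data.G.T @ (data.y - phat)
        den = np.sqrt((data.G * data.G).T @ w)
        z2 = np.where(den > 0, (num / np.maximum(den, 1e-12)) ** 2, 0.0)
        kmax = cfg.max_model_size or data.P
        gain = 0.5 * np.sort(z2)[::-1][:kmax].sum()
        u_min = -log_psi(mle_state, data, cfg) + base_cost - gain - 10.0
    if u_max is None:
        mu, sd = _prior_energy_stats(data, cfg)
        u_max = mu + 2.0 * sd
    if u_max <= u_min:
        u_max = u_min + 10.0
    desired = None
    if pi0 is not None:
        if not (0 < pi0 < 1):
            raise ValueError("pi0 must lie in (0, 1)")
        desired = np.full(m, (1.0 - pi0) / (m - 1))
        desired[0] = pi0
    return Partition(m=m, u_min=float(u_min), u_max=float(u_max),
                     desired_pi=desired)


def gain_factor(t: int, t0: int) -> float:
    """Decaying stochastic-approximation step size ``t0 / max(t0, t)``."""
    if t0 < 1:
        raise ValueError("t0 must be >= 1")
    return t0 / max(t0, t)


# ---------------------------------------------------------------------------
# settings & run record


@dataclass(frozen=True)
class SamcSettings:
    """Sampler configuration.

    ``iterations``/``burnin`` control run length; ``t0`` the gain-factor
    plateau; ``m`` the number of subregions when the partition is built
    automatically.  The move mixture and step sizes parameterize the
    proposal.  ``coef_grid``/``sigma2_fixed`` switch on the discrete
    coefficient-grid mode used for enumeration cross-checks.
    """

    iterations: int = 350_000
    burnin: int = 50_000
    t0: int = 5000
    m: int = 301
    p_add: float = 0.25
    p_delete: float = 0.25
    p_swap: float = 0.15
    p_walk: float = 0.20
    p_sigma: float = 0.10
    p_jump: float = 0.05
    walk_step: float = 0.2
    sigma_step: float = 0.2
    informed_add: bool = True
    coef_grid: tuple = None
    sigma2_fixed: float = None
    thin: int = 100

    def __post_init__(self):
        if self.iterations <= self.burnin or self.burnin < 0:
            raise ValueError("need iterations > burnin >= 0")
        if self.t0 < 1:
            raise ValueError("t0 must be >= 1")
        total = (self.p_add + self.p_delete + self.p_swap + self.p_walk
                 + self.p_sigma + self.p_jump)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("move probabilities must sum to 1")
        if (self.coef_grid is None) != (self.sigma2_fixed is None):
            raise ValueError("coef_grid and sigma2_fixed go together")

    @property
    def grid_mode(self) -> bool:
        return self.coef_grid is not None


@dataclass
class SamcRun:
    """Summary of one SAMC run (everything the estimators need)."""

    theta: np.ndarray
    visit_counts: np.ndarray
    post_visit_counts: np.ndarray
    t: int
    t0: int
    partition: Partition
    P: int
    lambda0: float
    lambda1: float
    # importance-weighted accumulators over post-burn-in H1 samples,
    # stored relative to `log_shift` to avoid overflow
    mip_num: np.ndarray = None
    mip_den: float = 0.0
    log_shift: float = -np.inf
    n_h1_samples: int = 0
    theta_mean: np.ndarray = None    # post-burn-in trajectory average
    accept_count: int = 0
    seed: int = 0
    theta_trace: list = field(default_factory=list)

    def h0_visit_fraction(self) -> float:
        """Realized post-burn-in visit share of the H0 subregion.

        The flat-histogram property says this should approach the
        desired frequency; a gross shortfall means the chain failed to
        bridge H0 and H1 and its Bayes-factor estimate is unreliable.
        """
        total = self.post_visit_counts.sum()
        if total == 0:
            return 0.0
        return float(self.post_visit_counts[0] / total)

    def save(self, path):
        """Write a JSON checkpoint of the run summary."""
        obj = {
            "theta": self.theta.tolist(),
            "visit_counts": self.visit_counts.tolist(),
            "post_visit_counts": self.post_visit_counts.tolist(),
            "t": self.t,
            "t0": self.t0,
            "partition": {
                "m": self.partition.m,
                "u_min": self.partition.u_min,
                "u_max": self.partition.u_max,
                "desired_pi": self.partition.desired_pi.tolist(),
            },
            "P": self.P,
            "lambda0": self.lambda0,
            "lambda1": self.lambda1,
            "mip_num": None if self.mip_num is None else self.mip_num.tolist(),
            "theta_mean": (None if self.theta_mean is None
                           else self.theta_mean.tolist()),
            "mip_den": self.mip_den,
            "log_shift": self.log_shift,
            "n_h1_samples": self.n_h1_samples,
            "accept_count": self.accept_count,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @staticmethod
    def load(path) -> "SamcRun":
        with open(path) as fh:
            obj = json.load(fh)
        part = Partition(
            m=obj["partition"]["m"],
            u_min=obj["partition"]["u_min"],
            u_max=obj["partition"]["u_max"],
            desired_pi=np.asarray(obj["partition"]["desired_pi"]),
        )
        return SamcRun(
            theta=np.asarray(obj["theta"]),
            visit_counts=np.asarray(obj["visit_counts"]),
            post_visit_counts=np.asarray(obj["post_visit_counts"]),
            t=obj["t"],
            t0=obj["t0"],
            partition=part,
            P=obj["P"],
            lambda0=obj["lambda0"],
            lambda1=obj["lambda1"],
            mip_num=None if obj["mip_num"] is None else np.asarray(obj["mip_num"]),
            theta_mean=(None if obj.get("theta_mean") is None
                        else np.asarray(obj["theta_mean"])),
            mip_den=obj["mip_den"],
            log_shift=obj["log_shift"],
            n_h1_samples=obj["n_h1_samples"],
            accept_count=obj["accept_count"],
            seed=obj["seed"],
        )


# ---------------------------------------------------------------------------
# proposal


def _normal_logpdf(x: float, sigma2: float) -> float:
    return -0.5 * (_LOG_2PI + np.log(sigma2)) - 0.5 * x * x / sigma2


class _Core:
    """Per-run caches: precomputed prior pieces and fast psi evaluation."""

    def __init__(self, data: Dataset, cfg: PriorConfig,
                 settings: SamcSettings):
        self.data = data
        self.cfg = cfg
        self.settings = settings
        self.y = data.y.astype(np.float64)
        self.G = data.G
        self.Z = data.Z
        p = prior_inclusion_prob(data.maf, cfg)
        self.log_p = np.log(p)
        self.log_1mp = np.log1p(-p)
        self.base_model_cost = self.log_1mp.sum()
        self.log_l0 = np.log(cfg.lambda0)
        self.log_l1 = np.log(cfg.lambda1)
        self.kmax = (cfg.max_model_size if cfg.max_model_size is not None
                     else data.P)
        # cached constants of the truncated inverse-gamma log density
        from .model import _invgamma_lognorm
        from scipy.special import gammaln
        self._ig_c1 = (cfg.a * np.log(cfg.b) - gammaln(cfg.a)
                       - _invgamma_lognorm(cfg))
        # informed ADD proposal: candidate variants drawn with weight
        # 1 + z_j^2 (marginal score statistic against the intercept-only
        # fit).  The weights are fixed for the whole run, so the move is
        # an ordinary independence ingredient of the MH kernel; the
        # proposal-ratio bookkeeping uses w_j exactly.
        if settings.informed_add and not settings.grid_mode:
            ybar = float(np.clip(self.y.mean(), 1e-6, 1 - 1e-6))
            resid = self.y - ybar
            w_var = ybar * (1 - ybar)
            num = self.G.T @ resid
            den = np.sqrt((self.G * self.G).sum(axis=0) * w_var)
            z2 = np.where(den > 0, (num / np.maximum(den, 1e-12)) ** 2, 0.0)
            w = 1.0 + z2
        else:
            w = np.ones(data.P)
        self.add_w = w / w.sum()
        self.log_add_w = np.log(self.add_w)
        self._add_cum = np.cumsum(self.add_w)

    # unnormalized posterior from cached linear predictor
    def logpsi(self, state: ModelState, lp: np.ndarray) -> float:
        cfg = self.cfg
        s2 = state.sigma2
        if s2 < cfg.l or s2 > cfg.u:
            return -np.inf
        lv = self._ig_c1 - (cfg.a + 1.0) * np.log(s2) - cfg.b / s2
        coefs = np.concatenate(([state.alpha], state.eta, state.beta))
        out = _normal_logpdf_sum(coefs, s2) + lv
        out += loglik_from_lp(self.y, lp)
        if state.h1:
            j = state.included
            if len(j) > self.kmax:
                return -np.inf
            out += (self.log_l1 + self.base_model_cost
                    + (self.log_p[j] - self.log_1mp[j]).sum())
        else:
            out += self.log_l0
        return float(out)

    def initial_state(self):
        sigma2 = (self.settings.sigma2_fixed
                  if self.settings.grid_mode
                  else float(np.clip(1.0, self.cfg.l, self.cfg.u)))
        state = ModelState.null(q=self.data.q, alpha=0.0, sigma2=sigma2)
        lp = linear_predictor(state, self.data)
        return state, lp

    # ----- individual moves -------------------------------------------
    def _draw_coef(self, rng, sigma2):
        """New-coefficient proposal: prior draw, or uniform grid draw."""
        if self.settings.grid_mode:
            grid = self.settings.coef_grid
            b = float(grid[rng.integers(len(grid))])
            return b, -np.log(len(grid))
        b = float(rng.normal(0.0, np.sqrt(sigma2)))
        return b, _normal_logpdf(b, sigma2)

    def _coef_logq(self, b, sigma2):
        if self.settings.grid_mode:
            return -np.log(len(self.settings.coef_grid))
        return _normal_logpdf(b, sigma2)

    def _draw_excluded(self, included, rng, P):
        """Weighted draw from the variants outside the model.

        Equivalent to drawing from ``add_w`` renormalized over the
        excluded set (rejection sampling against the included set).
        """
        for _ in range(200):
            j = int(np.searchsorted(self._add_cum, rng.random()))
            j = min(j, P - 1)
            if not (included == j).any():
                return j
        mask = np.ones(P, dtype=bool)
        mask[included] = False
        excl = np.nonzero(mask)[0]
        w = self.add_w[excl]
        return int(excl[rng.choice(len(excl), p=w / w.sum())])

    def propose(self, state: ModelState, lp: np.ndarray, rng):
        """One proposal.  Returns (cand, cand_lp, log_q_ratio) or None."""
        s = self.settings
        P = self.data.P
        k = len(state.included)
        u = rng.random()
        c_add = s.p_add
        c_del = c_add + s.p_delete
        c_swap = c_del + s.p_swap
        c_walk = c_swap + s.p_walk
        c_sigma = c_walk + s.p_sigma
        if u < c_add:
            move = "add"
        elif u < c_del:
            move = "delete"
        elif u < c_swap:
            move = "swap"
        elif u < c_walk:
            move = "walk"
        elif u < c_sigma:
            move = "sigma" if not s.grid_mode else "walk"
        else:
            move = "jump"

        p_to_h1 = s.p_add + s.p_jump       # pooled H0 -> size-1 mass
        p_to_h0 = s.p_delete + s.p_jump    # pooled size-1 -> H0 mass

        if move == "jump":
            if not state.h1:
                move = "add"
            elif k == 1:
                move = "delete"
            else:
                return None
        if move == "delete" and not state.h1:
            return None
        if move == "swap" and (k == 0 or k == P):
            return None
        if move == "add" and (k == P or k >= self.kmax):
            return None

        if move == "walk":
            if s.grid_mode:
                grid = np.asarray(s.coef_grid, dtype=float)
                ncoef = 1 + self.data.q + k
                which = int(rng.integers(ncoef))
                new = float(grid[rng.integers(len(grid))])
                cand = ModelState(state.h1, state.included.copy(),
                                  state.alpha, state.eta.copy(),
                                  state.beta.copy(), state.sigma2)
                if which == 0:
                    delta = new - cand.alpha
                    cand.alpha = new
                    cand_lp = lp + delta
                elif which <= self.data.q:
                    i = which - 1
                    delta = new - cand.eta[i]
                    cand.eta[i] = new
                    cand_lp = lp + delta * self.Z[:, i]
                else:
                    i = which - 1 - self.data.q
                    delta = new - cand.beta[i]
                    cand.beta[i] = new
                    cand_lp = lp + delta * self.G[:, state.included[i]]
                return cand, cand_lp, 0.0
            dalpha = rng.normal(0.0, s.walk_step)
            deta = rng.normal(0.0, s.walk_step, self.data.q)
            dbeta = rng.normal(0.0, s.walk_step, k)
            cand = ModelState(state.h1, state.included.copy(),
                              state.alpha + dalpha, state.eta + deta,
                              state.beta + dbeta, state.sigma2)
            cand_lp = lp + dalpha
            if self.data.q:
                cand_lp = cand_lp + self.Z @ deta
            if k:
                cand_lp = cand_lp + self.G[:, state.included] @ dbeta
            return cand, cand_lp, 0.0

        if move == "sigma":
            lo, hi = np.log(self.cfg.l), np.log(self.cfg.u)
            tau = np.log(state.sigma2) + rng.normal(0.0, s.sigma_step)
            # reflect into [lo, hi]
            span = hi - lo
            tau = (tau - lo) % (2 * span)
            tau = lo + (tau if tau <= span else 2 * span - tau)
            sigma2_new = float(np.exp(tau))
            cand = ModelState(state.h1, state.included.copy(), state.alpha,
                              state.eta.copy(), state.beta.copy(), sigma2_new)
            # log-scale walk Jacobian: q(old|new)/q(new|old) = s2'/s2
            return cand, lp, float(np.log(sigma2_new / state.sigma2))

        # mass of the add-proposal weights outside the current model
        w_ex = 1.0 - (self.add_w[state.included].sum() if k else 0.0)

        if move == "add":
            j = self._draw_excluded(state.included, rng, P)
            b, logq_b = self._draw_coef(rng, state.sigma2)
            cand = ModelState(True, np.append(state.included, j),
                              state.alpha, state.eta.copy(),
                              np.append(state.beta, b), state.sigma2)
            cand_lp = lp + b * self.G[:, j]
            logq_j = self.log_add_w[j] - np.log(max(w_ex, 1e-300))
            if k == 0:
                logq = np.log(p_to_h0) - (np.log(p_to_h1) + logq_j + logq_b)
            else:
                logq = (np.log(s.p_delete / (k + 1))
                        - (np.log(s.p_add) + logq_j + logq_b))
            return cand, cand_lp, float(logq)

        if move == "delete":
            i = int(rng.integers(k))
            j = int(state.included[i])
            b = float(state.beta[i])
            logq_b = self._coef_logq(b, state.sigma2)
            included = np.delete(state.included, i)
            beta = np.delete(state.beta, i)
            cand = ModelState(k > 1, included, state.alpha, state.eta.copy(),
                              beta, state.sigma2)
            cand_lp = lp - b * self.G[:, j]
            # reverse ADD draws j from the candidate's excluded mass
            logq_j = self.log_add_w[j] - np.log(w_ex + self.add_w[j])
            if k == 1:
                logq = (np.log(p_to_h1) + logq_j + logq_b) - np.log(p_to_h0)
            else:
                logq = (np.log(s.p_add) + logq_j + logq_b
                        - np.log(s.p_delete / k))
            return cand, cand_lp, float(logq)

        # swap
        i = int(rng.integers(k))
        j_out = int(state.included[i])
        j_in = self._draw_excluded(state.included, rng, P)
        b_out = float(state.beta[i])
        b_in, logq_in = self._draw_coef(rng, state.sigma2)
        included = state.included.copy()
        beta = state.beta.copy()
        included[i] = j_in
        beta[i] = b_in
        cand = ModelState(True, included, state.alpha, state.eta.copy(),
                          beta, state.sigma2)
        cand_lp = lp - b_out * self.G[:, j_out] + b_in * self.G[:, j_in]
        # forward draws j_in from the current excluded mass; the reverse
        # swap draws j_out from the candidate's excluded mass
        w_ex_rev = w_ex + self.add_w[j_out] - self.add_w[j_in]
        logq = ((self.log_add_w[j_out] - np.log(max(w_ex_rev, 1e-300)))
                + self._coef_logq(b_out, state.sigma2)
                - (self.log_add_w[j_in] - np.log(max(w_ex, 1e-300)))
                - logq_in)
        return cand, cand_lp, float(logq)


# ---------------------------------------------------------------------------
# public single-step operations (thin wrappers over the core)


def propose(state: ModelState, data: Dataset, cfg: PriorConfig,
            rng: np.random.Generator,
            settings: SamcSettings = None):
    """Draw one proposal from the mixture kernel.

    Returns ``(candidate, log_q_ratio)`` where ``log_q_ratio =
    log q(x | candidate) - log q(candidate | x)``, or ``(None, None)``
    when the selected move is inapplicable in the current state (the
    iteration then counts as a rejection).
    """
    if settings is None:
        settings = SamcSettings(iterations=2, burnin=1)
    core = _Core(data, cfg, settings)
    lp = linear_predictor(state, data)
    out = core.propose(state, lp, rng)
    if out is None:
        return None, None
    cand, _, logq = out
    return cand, logq


def mh_accept_ratio(x: ModelState, candidate: ModelState, theta: np.ndarray,
                    partition: Partition, log_q_ratio: float, data: Dataset,
                    cfg: PriorConfig) -> float:
    """Metropolis-Hastings ratio of the theta-weighted target."""
    lp_x = log_psi(x, data, cfg)
    lp_c = log_psi(candidate, data, cfg)
    if lp_c == -np.inf:
        return 0.0
    jx = partition.region_index(-lp_x, x.h1, len(x.included))
    jc = partition.region_index(-lp_c, candidate.h1,
                                len(candidate.included))
    logr = (theta[jx] - theta[jc]) + (lp_c - lp_x) + log_q_ratio
    return float(np.exp(min(logr, 0.0))) if logr < 0 else float(np.exp(
        min(logr, 700.0)))


def update_theta(run: SamcRun, visited_index: int,
                 partition: Partition = None) -> SamcRun:
    """One stochastic-approximation update of theta (in place).

    ``theta_i += a_{t+1} (I(i = visited) - pi_i)`` followed by the
    recentering ``theta -= theta_0`` that keeps the trajectory in a
    compact set; pairwise differences (hence acceptance decisions and
    estimators) are unaffected by the shift.
    """
    if partition is None:
        partition = run.partition
    if not 0 <= visited_index < partition.m:
        raise ValueError("visited_index out of range")
    a = gain_factor(run.t + 1, run.t0)
    run.theta -= a * partition.desired_pi
    run.theta[visited_index] += a
    run.theta -= run.theta[0]
    run.visit_counts[visited_index] += 1
    run.t += 1
    return run


# ---------------------------------------------------------------------------
# the full run


def run_samc(data: Dataset, cfg: PriorConfig, settings: SamcSettings,
             partition: Partition = None, seed: int = 0) -> SamcRun:
    """Execute a full SAMC run and collect estimator inputs.

    Deterministic given ``seed``.  Post-burn-in iterations accumulate
    the importance-weighted inclusion indicators (weights
    ``exp(theta_{J(x_t)})`` recorded at visit time, rescaled on the fly
    to avoid overflow) and the per-subregion visit counts used by the
    flat-histogram diagnostic.
    """
    rng = np.random.default_rng(seed)
    if partition is None:
        partition = build_partition(data, cfg, m=settings.m)
    core = _Core(data, cfg, settings)
    state, lp = core.initial_state()
    logpsi = core.logpsi(state, lp)
    idx = partition.region_index(-logpsi, state.h1, len(state.included))
    m = partition.m
    pi = partition.desired_pi
    theta = np.zeros(m)
    visit = np.zeros(m, dtype=np.int64)
    post_visit = np.zeros(m, dtype=np.int64)
    P = data.P
    mip_num = np.zeros(P)
    theta_sum = np.zeros(m)
    n_theta = 0
    mip_den = 0.0
    log_shift = -np.inf
    n_h1 = 0
    accepted = 0
    trace = []
    t0 = settings.t0
    burnin = settings.burnin

    for t in range(1, settings.iterations + 1):
        out = core.propose(state, lp, rng)
        if out is not None:
            cand, cand_lp, logq = out
            cand_logpsi = core.logpsi(cand, cand_lp)
            if cand_logpsi > -np.inf:
                cidx = partition.region_index(-cand_logpsi, cand.h1,
                                              len(cand.included))
                logr = (theta[idx] - theta[cidx]) + (cand_logpsi
                                                     - logpsi) + logq
                if logr >= 0 or np.log(rng.random()) < logr:
                    state, lp, logpsi, idx = cand, cand_lp, cand_logpsi, cidx
                    accepted += 1
        a = t0 / max(t0, t)
        theta -= a * pi
        theta[idx] += a
        theta -= theta[0]
        visit[idx] += 1
        if t > burnin:
            post_visit[idx] += 1
            theta_sum += theta
            n_theta += 1
            if state.h1:
                th = theta[idx]
                if th > log_shift + 500.0:
                    scale = np.exp(log_shift - th) if np.isfinite(
                        log_shift) else 0.0
                    mip_num *= scale
                    mip_den *= scale
                    log_shift = th
                elif not np.isfinite(log_shift):
                    log_shift = th
                w = np.exp(th - log_shift)
                mip_num[state.included] += w
                mip_den += w
                n_h1 += 1
        if settings.thin and t % settings.thin == 0:
            trace.append((t, idx, len(state.included)))

    if m > 2 and (visit[1:m - 1] == 0).any():
        warnings.warn(
            f"{int((visit[1:m - 1] == 0).sum())} interior subregions were "
            "never visited; estimators renormalize over visited subregions"
        )
    return SamcRun(
        theta=theta,
        visit_counts=visit,
        post_visit_counts=post_visit,
        t=settings.iterations,
        t0=t0,
        partition=partition,
        P=P,
        lambda0=cfg.lambda0,
        lambda1=cfg.lambda1,
        mip_num=mip_num,
        mip_den=mip_den,
        log_shift=log_shift,
        theta_mean=theta_sum / max(n_theta, 1),
        n_h1_samples=n_h1,
        accept_count=accepted,
        seed=seed,
        theta_trace=trace,
    )


# ---------------------------------------------------------------------------
# estimators


def estimate_log_bayes_factor(run: SamcRun, partition: Partition = None,
                              cfg: PriorConfig = None,
                              average_theta: bool = True) -> float:
    """log BF(H1 : H0) from the converged theta.

    ``BF = (lambda0 / lambda1) * sum_{i>=2} pi_i exp(theta_i) /
    (pi_1 exp(theta_1))``, restricted to visited subregions; the lambda
    factors cancel the hypothesis-prior weights embedded in psi, so the
    returned value is the evidence ratio Z(H1)/Z(H0).  By default theta
    is the post-burn-in trajectory average (Polyak averaging), which
    damps the stochastic-approximation noise of the final iterate.
    """
    if partition is None:
        partition = run.partition
    lambda0 = run.lambda0 if cfg is None else cfg.lambda0
    lambda1 = run.lambda1 if cfg is None else cfg.lambda1
    if run.visit_counts[0] == 0:
        raise EstimationError(
            "the H0 subregion was never visited; the Bayes factor "
            "denominator is unavailable (increase iterations or t0)"
        )
    theta = run.theta
    if average_theta and run.theta_mean is not None:
        theta = run.theta_mean
    visited = run.visit_counts[1:] > 0
    if not visited.any():
        return -np.inf
    log_pi = np.log(partition.desired_pi)
    log_num = logsumexp((log_pi[1:] + theta[1:])[visited])
    log_den = log_pi[0] + theta[0]
    return float(np.log(lambda0 / lambda1) + log_num - log_den)


def estimate_bayes_factor(run: SamcRun, partition: Partition = None,
                          cfg: PriorConfig = None) -> float:
    """Bayes factor BF(H1 : H0); may overflow to inf for decisive data."""
    return float(np.exp(min(estimate_log_bayes_factor(run, partition, cfg),
                            700.0)))


def estimate_marginal_inclusion(run: SamcRun, P: int = None) -> np.ndarray:
    """Importance-weighted marginal inclusion probabilities, in [0, 1]."""
    if P is None:
        P = run.P
    if run.mip_den <= 0 or run.n_h1_samples == 0:
        warnings.warn("no post-burn-in H1 samples; returning zeros")
        return np.zeros(P)
    return np.clip(run.mip_num[:P] / run.mip_den, 0.0, 1.0)
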