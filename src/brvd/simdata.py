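"""Synthetic case-control data and the power-study harness.

The generator emulates a rare-variant resampling design: a haplotype
pool whose per-site allele frequencies follow a rare-skewed spectrum
(all below a 5% cap) with short-range linkage disequilibrium, from
which each subject draws two haplotypes; disease status follows a
logistic model with two covariates (a binary "sex" and a uniform "age")
and, under H1, ten causal variants at the first positions.  Cases and
controls are rejection-sampled to exact quotas (default 250/250),
zero-MAF columns are dropped and the first 600 surviving variants are
kept — so the realized number of causal variants is itself random.

The harness side computes global and marginal ROC tables (dataset-level
and variant-level false/true positive rates as the evidence threshold
varies) and the empirical type-I error of the global test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .data import Dataset, compute_maf
from .model import PriorConfig
from .samc import SamcSettings

__all__ = [
    "SimDesign",
    "TruthRecord",
    "generate_haplotype_pool",
    "draw_causal_effects",
    "simulate_dataset",
    "roc_curves",
    "marginal_roc",
    "type1_error_study",
]


@dataclass(frozen=True)
class SimDesign:
    """Study design of the simulation.

    Defaults reproduce the empirical power-study conditions: 250 cases,
    250 controls, a rare-variant haplotype pool (all MAF < 5%), 600
    variants kept after zero-MAF removal, two covariates (binary with
    coefficient 0.5; uniform on [20, 60] with coefficient 0.02) and,
    under H1, 10 causal variants at the first positions with log-odds
    ratios drawn from N(0, 1.5^2).
    """

    n_cases: int = 250
    n_controls: int = 250
    pool_size: int = 2000
    P_raw: int = 1200
    P_keep: int = 600
    maf_cap: float = 0.05
    n_causal: int = 10
    beta_causal: tuple = None          # None => zero effects (H0)
    covariate_coefs: tuple = (0.5, 0.02)
    age_range: tuple = (20.0, 60.0)
    maf_spectrum: tuple = ("beta", 0.3, 30.0)
    ld_decay: float = 0.5
    h1: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.pool_size < 2 * (self.n_cases + self.n_controls):
            raise ValueError(
                "haplotype pool must hold at least two haplotypes per subject"
            )
        if self.P_keep > self.P_raw:
            raise ValueError("cannot keep more variants than generated")
        if self.h1 and self.beta_causal is not None:
            if len(self.beta_causal) != self.n_causal:
                raise ValueError("beta_causal length must equal n_causal")
        if not self.h1 and self.beta_causal is not None:
            raise ValueError("H0 designs carry no causal effects")

    def effects(self) -> np.ndarray:
        if not self.h1 or self.beta_causal is None:
            return np.zeros(self.n_causal)
        return np.asarray(self.beta_causal, dtype=float)


@dataclass
class TruthRecord:
    """Ground truth surviving the post-simulation filters."""

    causal_indices: np.ndarray       # column positions in the final dataset
    causal_original: np.ndarray      # positions in the raw pool
    realized_maf: np.ndarray         # per-kept-variant sample MAF
    realized_causal_count: int
    beta_causal: np.ndarray


def draw_causal_effects(rng: np.random.Generator, n_causal: int = 10,
                        scale: float = 1.5) -> np.ndarray:
    """Causal log-odds ratios: one draw from N(0, scale^2), signs kept."""
    return rng.normal(0.0, scale, n_causal)


def _spectrum_freqs(rng, P_raw, spectrum, cap):
    kind = spectrum[0]
    if kind == "beta":
        a, b = spectrum[1], spectrum[2]
        # truncated Beta(a, b) below the cap via inverse-CDF sampling
        u_cap = stats.beta.cdf(cap, a, b)
        u = rng.uniform(0.0, u_cap, P_raw)
        f = stats.beta.ppf(u, a, b)
        return np.clip(f, 1e-12, cap)
    if kind == "uniform":
        lo, hi = spectrum[1], min(spectrum[2], cap)
        return rng.uniform(lo, hi, P_raw)
    raise ValueError(f"unknown MAF spectrum {spectrum!r}")


def generate_haplotype_pool(pool_size: int, P_raw: int,
                            maf_spectrum=("beta", 0.3, 30.0),
                            ld_decay: float = 0.5, seed: int = 0,
                            maf_cap: float = 0.05):
    """Binary haplotype pool with a rare-skewed spectrum and AR(1) LD.

    Per-site target frequencies are drawn from the spectrum truncated
    below ``maf_cap``; haplotypes come from a first-order Gaussian
    copula whose latent AR(1) correlation ``ld_decay`` makes adjacent
    sites dependent with geometrically decaying correlation.  Columns
    whose realized pool frequency exceeds the cap (or is zero) are
    dropped, mirroring the removal of common variants from the pool
    before resampling.

    Returns ``(haplotypes, freqs)``; deterministic given ``seed``.
    """
    if pool_size < 2:
        raise ValueError("pool_size must be at least 2")
    if not (0 <= ld_decay < 1):
        raise ValueError("ld_decay must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    f = _spectrum_freqs(rng, P_raw, maf_spectrum, maf_cap)
    # latent AR(1) field, one row per haplotype
    z = np.empty((pool_size, P_raw))
    z[:, 0] = rng.standard_normal(pool_size)
    if P_raw > 1:
        innov = rng.standard_normal((pool_size, P_raw - 1))
        c = np.sqrt(1.0 - ld_decay**2)
        for j in range(1, P_raw):
            z[:, j] = ld_decay * z[:, j - 1] + c * innov[:, j - 1]
    thresh = stats.norm.ppf(f)
    H = (z < thresh).astype(np.uint8)
    pool_freq = H.mean(axis=0)
    keep = (pool_freq > 0) & (pool_freq <= maf_cap)
    if not keep.any():
        raise ValueError("spectrum parameters left no polymorphic rare site")
    return H[:, keep], pool_freq[keep]


def simulate_dataset(design: SimDesign):
    """Draw one case-control dataset from the design.

    Returns ``(Dataset, TruthRecord)``.  Raises when the case/control
    quotas cannot be filled within the draw budget.
    """
    rng = np.random.default_rng(design.seed)
    H, _ = generate_haplotype_pool(
        design.pool_size, design.P_raw, design.maf_spectrum,
        design.ld_decay, seed=design.seed, maf_cap=design.maf_cap,
    )
    P_pool = H.shape[1]
    beta = design.effects()
    n_causal = min(design.n_causal, P_pool)
    beta = beta[:n_causal]
    coef_sex, coef_age = design.covariate_coefs
    lo_age, hi_age = design.age_range

    # intercept tuned on a pilot batch so prevalence ~ 50%
    pilot = 4000
    idx = rng.integers(H.shape[0], size=(pilot, 2))
    Gp = (H[idx[:, 0]] + H[idx[:, 1]]).astype(float)
    sexp = rng.integers(0, 2, pilot)
    agep = rng.uniform(lo_age, hi_age, pilot)
    contrib = coef_sex * sexp + coef_age * agep
    if design.h1:
        contrib = contrib + Gp[:, :n_causal] @ beta
    alpha0 = -float(np.mean(contrib))

    n_need = design.n_cases + design.n_controls
    G_rows, Z_rows, y_rows = [], [], []
    got_cases = got_controls = 0
    max_batches = 200
    batch = max(1000, n_need)
    for _ in range(max_batches):
        if got_cases >= design.n_cases and got_controls >= design.n_controls:
            break
        i1 = rng.integers(H.shape[0], size=batch)
        i2 = rng.integers(H.shape[0], size=batch)
        G = (H[i1] + H[i2]).astype(float)
        sex = rng.integers(0, 2, batch)
        age = rng.uniform(lo_age, hi_age, batch)
        lp = alpha0 + coef_sex * sex + coef_age * age
        if design.h1:
            lp = lp + G[:, :n_causal] @ beta
        y = (rng.random(batch) < 1.0 / (1.0 + np.exp(-lp))).astype(np.int8)
        for take_y, need in ((1, design.n_cases - got_cases),
                             (0, design.n_controls - got_controls)):
            if need <= 0:
                continue
            sel = np.nonzero(y == take_y)[0][:need]
            if len(sel):
                G_rows.append(G[sel])
                Z_rows.append(np.column_stack([sex[sel], age[sel]]))
                y_rows.append(y[sel])
                if take_y:
                    got_cases += len(sel)
                else:
                    got_controls += len(sel)
    if got_cases < design.n_cases or got_controls < design.n_controls:
        raise RuntimeError(
            f"case/control quota unreachable: got {got_cases} cases / "
            f"{got_controls} controls after {max_batches} batches "
            f"(alpha0 = {alpha0:.2f})"
        )
    G = np.vstack(G_rows)
    Z = np.vstack(Z_rows)
    y = np.concatenate(y_rows)
    # shuffle subject order so cases/controls are interleaved
    perm = rng.permutation(n_need)
    G, Z, y = G[perm], Z[perm], y[perm]

    maf = compute_maf(G)
    ok = (maf > 0) & (maf <= design.maf_cap)
    kept = np.nonzero(ok)[0]
    if len(kept) < design.P_keep:
        raise RuntimeError(
            f"only {len(kept)} variants survive the zero-MAF/cap filter; "
            f"increase P_raw (currently {design.P_raw})"
        )
    kept = kept[:design.P_keep]
    Gk = G[:, kept]

    causal_pool = np.arange(n_causal)
    surv_mask = np.isin(kept, causal_pool)
    causal_new = np.nonzero(surv_mask)[0]
    causal_orig = kept[surv_mask]
    data = Dataset(
        y=y, G=Gk, Z=Z,
        variant_ids=[f"v{j}" for j in kept],
    )
    truth = TruthRecord(
        causal_indices=causal_new,
        causal_original=causal_orig,
        realized_maf=data.maf,
        realized_causal_count=int(design.h1) * len(causal_new),
        beta_causal=beta,
    )
    return data, truth


# ---------------------------------------------------------------------------
# ROC / type-I-error harness


def roc_curves(bfs, is_associated, thresholds=None):
    """Global ROC table: dataset-level FPR/TPR as the BF threshold varies.

    ``gFPR`` is the fraction of null datasets whose Bayes factor meets
    the threshold; ``gTPR`` the same fraction over associated datasets.
    """
    bfs = np.asarray(bfs, dtype=float)
    labels = np.asarray(is_associated, dtype=bool)
    if len(bfs) != len(labels):
        raise ValueError("one truth label per dataset result is required")
    if not labels.any() or labels.all():
        raise ValueError("need results from both null and associated datasets")
    if thresholds is None:
        thresholds = np.sort(np.unique(bfs))
    thresholds = np.asarray(thresholds, dtype=float)
    rows = []
    n_null = (~labels).sum()
    n_alt = labels.sum()
    for c in thresholds:
        det = bfs >= c
        rows.append((c, (det & ~labels).sum() / n_null,
                     (det & labels).sum() / n_alt))
    import pandas as pd

    return pd.DataFrame(rows, columns=["threshold", "gFPR", "gTPR"])


def marginal_roc(mip, is_causal, thresholds=None):
    """Variant-level ROC table from (averaged) inclusion probabilities."""
    mip = np.asarray(mip, dtype=float)
    labels = np.asarray(is_causal, dtype=bool)
    if mip.shape != labels.shape:
        raise ValueError("one truth label per variant is required")
    if thresholds is None:
        thresholds = np.sort(np.unique(mip))
    thresholds = np.asarray(thresholds, dtype=float)
    n_null = max((~labels).sum(), 1)
    n_alt = max(labels.sum(), 1)
    rows = []
    for c in thresholds:
        det = mip >= c
        rows.append((c, (det & ~labels).sum() / n_null,
                     (det & labels).sum() / n_alt))
    import pandas as pd

    return pd.DataFrame(rows, columns=["threshold", "mFPR", "mTPR"])


def type1_error_study(n_null_datasets: int, design: SimDesign,
                      cfg: PriorConfig, settings: SamcSettings,
                      grid, threshold: float = 0.75, seed: int = 0,
                      use_covariates: bool = True,
                      n_runs: int = 1) -> float:
    """Empirical type-I error of the global test over null datasets.

    Simulates ``n_null_datasets`` datasets under H0 from the design,
    runs the full per-dataset gammaL selection and reports the fraction
    with posterior probability of H1 above ``threshold``.  With
    ``use_covariates=False`` the covariate columns are omitted from the
    fitted model (they still act on the phenotype), probing robustness
    to covariate omission.
    """
    from .inference import global_test

    if n_null_datasets < 1:
        raise ValueError("need at least one null dataset")
    rejections = 0
    for r in range(n_null_datasets):
        d = replace(design, h1=False, beta_causal=None,
                    seed=int((seed * 1009 + r) % (2**31 - 1)))
        data, _ = simulate_dataset(d)
        if not use_covariates:
            data = data.without_covariates()
        res = global_test(data, cfg, settings, grid=grid,
                          seed=int((seed * 2003 + r) % (2**31 - 1)),
                          threshold=threshold, n_runs=n_runs)
        rejections += int(res.reject)
    return rejections / n_null_datasets
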