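"""Readers, writers and run configuration."""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, compute_maf

__all__ = [
    "GenotypeBlock",
    "RunConfig",
    "read_genotypes_vcf",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_covariates_tsv",
    "read_phenotype_tsv",
    "apply_rare_filter",
    "load_run_config",
]


@dataclass
class GenotypeBlock:
    """Genotype fragment as parsed from disk (pre-Dataset)."""

    G: np.ndarray
    variant_ids: list
    chrom: np.ndarray
    n_multiallelic_skipped: int = 0
    n_missing_imputed: int = 0
    n_monomorphic_dropped: int = 0


def read_genotypes_vcf(path) -> GenotypeBlock:
    """Additively coded genotypes from a VCF with GT fields.

    Coding refers to the minor allele in the analyzed sample (columns
    are flipped when the ALT frequency exceeds 0.5).  Multi-allelic
    sites are skipped, missing genotypes imputed as 0 copies
    (conservative for rare alleles) and monomorphic sites dropped; all
    three events are counted on the returned block.
    """
    from cyvcf2 import VCF

    cols, ids, chroms = [], [], []
    n_multi = n_missing = 0
    vcf = VCF(str(path))
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray([g[:2] for g in rec.genotypes], dtype=np.int16)
        missing = gt < 0
        n_missing += int(missing.sum())
        gt = np.where(missing, 0, gt)
        cols.append(gt.sum(axis=1).astype(np.float64))
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
    vcf.close()
    if n_missing:
        warnings.warn(f"{n_missing} missing genotype call(s) imputed as 0")
    if not cols:
        raise ValueError(f"no usable biallelic sites in {path}")
    G = np.column_stack(cols)
    freq = G.mean(axis=0) / 2.0
    flip = freq > 0.5
    G[:, flip] = 2.0 - G[:, flip]
    mono = compute_maf(G) == 0
    if mono.any():
        G = G[:, ~mono]
        ids = [v for v, m in zip(ids, mono) if not m]
        chroms = [c for c, m in zip(chroms, mono) if not m]
    return GenotypeBlock(
        G=G,
        variant_ids=ids,
        chrom=np.asarray(chroms),
        n_multiallelic_skipped=n_multi,
        n_missing_imputed=n_missing,
        n_monomorphic_dropped=int(mono.sum()),
    )


def read_matrix_tsv(path) -> GenotypeBlock:
    """Genotype matrix from TSV: header of variant ids, entries 0/1/2/NA."""
    df = pd.read_csv(path, sep="\t")
    vals = df.to_numpy(dtype=float)
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        warnings.warn(f"{n_missing} NA genotype(s) imputed as 0")
        vals = np.nan_to_num(vals, nan=0.0)
    bad = ~np.isin(vals, (0.0, 1.0, 2.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype entry {vals[r, c]!r} at row {r + 1}, "
            f"column {df.columns[c]!r}: entries must be 0, 1, 2 or NA"
        )
    return GenotypeBlock(
        G=vals,
        variant_ids=list(df.columns),
        chrom=None,
        n_missing_imputed=n_missing,
    )


def write_matrix_tsv(path, G, variant_ids):
    pd.DataFrame(np.asarray(G, dtype=int), columns=variant_ids).to_csv(
        path, sep="\t", index=False
    )


def read_covariates_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def read_phenotype_tsv(path) -> np.ndarray:
    y = pd.read_csv(path, sep="\t").to_numpy().ravel()
    return y.astype(int)


def apply_rare_filter(G, variant_ids, maf_cap: float = 0.05, chrom=None):
    """Drop common (MAF > cap) and monomorphic variants, preserving order.

    Returns ``(G, variant_ids, chrom, kept_indices)``.
    """
    maf = compute_maf(G)
    keep = (maf > 0) & (maf <= maf_cap)
    idx = np.nonzero(keep)[0]
    return (
        G[:, idx],
        [variant_ids[j] for j in idx],
        None if chrom is None else np.asarray(chrom)[idx],
        idx,
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML/JSON loadable).

    Groups the prior hyperparameters, sampler settings, gammaL grid and
    FDR levels; unknown keys in a config file are rejected.
    """

    # priors
    a: float = 1.0
    b: float = 1.0
    l: float = 1e-4
    u: float = 1e4
    gammaU: float = 0.999
    maf_cap: float = 0.05
    lambda0: float = 0.5
    lambda1: float = 0.5
    standardize_covariates: bool = False
    # sampler
    iterations: int = 350_000
    burnin: int = 50_000
    t0: int = 5000
    m: int = 301
    seed: int = 0
    # inference
    gammaL_grid: tuple = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99)
    fdr_level: float = 0.05
    reject_threshold: float = 0.75
    # parallel
    screen_fdr: float = 0.25
    chunk_size: int = None
    n_perm: int = 99

    def prior_config(self):
        from .model import PriorConfig

        return PriorConfig(
            a=self.a, b=self.b, l=self.l, u=self.u,
            gammaL=self.gammaL_grid[0], gammaU=self.gammaU,
            maf_cap=self.maf_cap, lambda0=self.lambda0,
            lambda1=self.lambda1,
            standardize_covariates=self.standardize_covariates,
        )

    def samc_settings(self):
        from .samc import SamcSettings

        return SamcSettings(iterations=self.iterations, burnin=self.burnin,
                            t0=self.t0, m=self.m)


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    import yaml

    with open(path) as fh:
        obj = yaml.safe_load(fh)
    if obj is None:
        obj = {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(obj) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "gammaL_grid" in obj:
        obj["gammaL_grid"] = tuple(obj["gammaL_grid"])
    cfg = RunConfig(**obj)
    cfg.prior_config()   # triggers hyperparameter validation
    if cfg.iterations <= cfg.burnin:
        raise ValueError("iterations must exceed burnin")
    return cfg


def write_manifest(path, config: RunConfig, seed: int, extra: dict = None):
    """JSON run manifest: config + seed + versions, for reproducibility."""
    import brvd

    obj = {
        "brvd_version": brvd.__version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config": dataclasses.asdict(config),
    }
    if extra:
        obj.update(extra)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
    return obj


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
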