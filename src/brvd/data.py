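"""Case-control dataset container.

A :class:`Dataset` couples a binary phenotype vector with an additively
coded genotype matrix (0/1/2 copies of the minor allele), an optional
covariate matrix and the per-variant minor allele frequencies computed
from the analyzed sample.  All downstream code (model, sampler,
inference) works on this container; readers in :mod:`brvd.io` are
responsible for producing it from VCF or TSV input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Dataset", "compute_maf"]


def compute_maf(G: np.ndarray) -> np.ndarray:
    """Minor allele frequency per column of an additively coded matrix.

    Assumes the coded allele is the minor allele; the result is simply
    the coded-allele frequency ``mean(G)/2``.
    """
    G = np.asarray(G)
    return G.mean(axis=0) / 2.0


@dataclass
class Dataset:
    """Subjects x variants case-control data.

    Parameters
    ----------
    y
        Length-``n`` vector of 0/1 disease status.
    G
        ``n x P`` matrix of minor-allele counts in ``{0, 1, 2}``.
    Z
        ``n x q`` covariate matrix; may have zero columns.
    maf
        Length-``P`` minor allele frequencies in ``(0, 0.5]``.  Computed
        from ``G`` when omitted.
    variant_ids
        Length-``P`` variant labels.
    chrom
        Optional length-``P`` chromosome labels (used by the parallel
        divide-and-conquer plan).
    """

    y: np.ndarray
    G: np.ndarray
    Z: np.ndarray = None
    maf: np.ndarray = None
    variant_ids: list = None
    chrom: np.ndarray = None

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("phenotype vector y must be binary 0/1")
        self.y = self.y.astype(np.int8)
        self.G = np.asarray(self.G)
        if not np.isin(self.G, (0, 1, 2)).all():
            raise ValueError("genotype matrix entries must lie in {0, 1, 2}")
        self.G = self.G.astype(np.float64)
        n, P = self.G.shape
        if len(self.y) != n:
            raise ValueError(f"y has length {len(self.y)} but G has {n} rows")
        if self.Z is None:
            self.Z = np.empty((n, 0))
        self.Z = np.asarray(self.Z, dtype=np.float64)
        if self.Z.ndim == 1:
            self.Z = self.Z[:, None]
        if self.Z.shape[0] != n:
            raise ValueError("covariate matrix row count does not match y")
        if self.maf is None:
            self.maf = compute_maf(self.G)
        self.maf = np.asarray(self.maf, dtype=np.float64)
        if len(self.maf) != P:
            raise ValueError("maf length does not match number of variants")
        if (self.maf <= 0).any():
            raise ValueError(
                "zero-MAF variants present; remove them before analysis "
                "(see brvd.io.apply_rare_filter)"
            )
        if (self.maf > 0.5).any():
            raise ValueError(
                "MAF > 0.5: genotype coding must refer to the minor allele"
            )
        if self.variant_ids is None:
            self.variant_ids = [f"v{j}" for j in range(P)]
        self.variant_ids = list(self.variant_ids)
        if len(self.variant_ids) != P:
            raise ValueError("variant_ids length does not match G")
        if self.chrom is not None:
            self.chrom = np.asarray(self.chrom)
            if len(self.chrom) != P:
                raise ValueError("chrom length does not match G")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def P(self) -> int:
        return self.G.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    # -- derived views --------------------------------------------------
    def subset(self, cols) -> "Dataset":
        """Dataset restricted to the given variant column indices."""
        cols = np.asarray(cols, dtype=int)
        return Dataset(
            y=self.y,
            G=self.G[:, cols],
            Z=self.Z,
            maf=self.maf[cols],
            variant_ids=[self.variant_ids[j] for j in cols],
            chrom=None if self.chrom is None else self.chrom[cols],
        )

    def without_covariates(self) -> "Dataset":
        """Same data with the covariate matrix dropped (q = 0)."""
        return Dataset(
            y=self.y,
            G=self.G,
            Z=np.empty((self.n, 0)),
            maf=self.maf,
            variant_ids=self.variant_ids,
            chrom=self.chrom,
        )

    def with_permuted_phenotype(self, rng: np.random.Generator) -> "Dataset":
        """Copy with the phenotype vector permuted (for permutation tests)."""
        perm = rng.permutation(self.n)
        return Dataset(
            y=self.y[perm],
            G=self.G,
            Z=self.Z,
            maf=self.maf,
            variant_ids=self.variant_ids,
            chrom=self.chrom,
        )

    @staticmethod
    def from_genotypes(
        G: np.ndarray,
        y: np.ndarray,
        Z: np.ndarray = None,
        variant_ids=None,
        chrom=None,
        orient_minor: bool = True,
    ) -> "Dataset":
        """Build a dataset, flipping columns coded on the major allele.

        Columns with coded-allele frequency above 0.5 are recoded as
        ``2 - G`` so the stored counts always refer to the minor allele
        in the analyzed sample.
        """
        G = np.asarray(G, dtype=np.float64).copy()
        if orient_minor:
            freq = G.mean(axis=0) / 2.0
            flip = freq > 0.5
            if flip.any():
                warnings.warn(
                    f"{int(flip.sum())} column(s) recoded to minor-allele counts"
                )
                G[:, flip] = 2.0 - G[:, flip]
        return Dataset(y=y, G=G, Z=Z, variant_ids=variant_ids, chrom=chrom)
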