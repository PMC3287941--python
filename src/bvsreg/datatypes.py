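"""In-memory containers for genotypes, phenotypes and simulation truth.

Genotypes are additive dosages of the alternate (or minor) allele, so every
entry is 0, 1 or 2 for hard calls; mean-imputed entries may be fractional.
Phenotype replicates follow the GAW17 layout: one fixed genotype matrix and
many independently re-simulated phenotype vectors over the same individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidDataError

__all__ = ["GenotypeMatrix", "PhenotypeSet", "TruthTable"]


@dataclass
class GenotypeMatrix:
    """n x p dosage matrix with per-SNP metadata.

    Parameters
    ----------
    X : ndarray of shape (n_individuals, n_snps)
        Dosage matrix; entries in [0, 2] (fractional after imputation).
    snp_ids : array of str
        Unique identifier per column.
    individual_ids : array of str
        Identifier per row.
    gene : array of str, optional
        Gene label per SNP (simulated data uses contiguous blocks).
    """

    X: np.ndarray
    snp_ids: np.ndarray
    individual_ids: np.ndarray
    gene: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.X.ndim != 2:
            raise InvalidDataError("genotype matrix must be 2-D")
        n, p = self.X.shape
        if len(self.snp_ids) != p:
            raise InvalidDataError(
                f"{len(self.snp_ids)} SNP ids for {p} genotype columns"
            )
        if len(self.individual_ids) != n:
            raise InvalidDataError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        if len(set(self.snp_ids)) != p:
            raise InvalidDataError("duplicate SNP ids")
        if self.gene is not None:
            self.gene = np.asarray(self.gene, dtype=object)
            if len(self.gene) != p:
                raise InvalidDataError("gene labels do not match SNP count")
        finite = np.isfinite(self.X)
        if finite.all() and ((self.X < 0) | (self.X > 2)).any():
            raise InvalidDataError("dosages outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.X.shape[0]

    @property
    def n_snps(self) -> int:
        return self.X.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per SNP (NaNs ignored)."""
        f = np.nanmean(self.X, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    @property
    def monomorphic(self) -> np.ndarray:
        """Mask of columns with no dosage variation."""
        with np.errstate(invalid="ignore"):
            return np.nanvar(self.X, axis=0) == 0.0


@dataclass
class PhenotypeSet:
    """One or more phenotype replicates over a shared set of individuals.

    ``Y`` has one column per replicate; GAW17-style designs re-draw the
    environmental noise per replicate over a fixed genotype matrix.
    """

    Y: np.ndarray
    individual_ids: np.ndarray
    replicate_names: np.ndarray | None = None
    realized_h2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.float64)
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.Y.shape[0] != len(self.individual_ids):
            raise InvalidDataError("phenotype rows do not match individual ids")
        if self.replicate_names is None:
            self.replicate_names = np.array(
                [f"replicate_{r + 1}" for r in range(self.Y.shape[1])], dtype=object
            )
        else:
            self.replicate_names = np.asarray(self.replicate_names, dtype=object)
            if len(self.replicate_names) != self.Y.shape[1]:
                raise InvalidDataError("replicate names do not match column count")

    @property
    def n_replicates(self) -> int:
        return self.Y.shape[1]

    def replicate(self, r: int) -> np.ndarray:
        return self.Y[:, r]


@dataclass
class TruthTable:
    """Known causal architecture of a simulated dataset.

    Effects are on the trait-per-dosage scale actually used to generate the
    phenotypes; an effect is 0 exactly when the SNP is not causal.
    """

    snp_id: np.ndarray
    gene: np.ndarray
    is_causal: np.ndarray
    effect: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.gene = np.asarray(self.gene, dtype=object)
        self.is_causal = np.asarray(self.is_causal, dtype=bool)
        self.effect = np.asarray(self.effect, dtype=np.float64)
        self.maf = np.asarray(self.maf, dtype=np.float64)
        lens = {len(a) for a in (self.snp_id, self.gene, self.is_causal, self.effect, self.maf)}
        if len(lens) != 1:
            raise InvalidDataError("truth table columns have unequal lengths")
        if len(set(self.snp_id)) != len(self.snp_id):
            raise InvalidDataError("duplicate SNP ids in truth table")
        if ((self.effect != 0) != self.is_causal).any():
            raise InvalidDataError("effect must be nonzero exactly for causal SNPs")

    @property
    def n_causal(self) -> int:
        return int(self.is_causal.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "gene": self.gene,
                "is_causal": self.is_causal.astype(int),
                "effect": self.effect,
                "maf": self.maf,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TruthTable":
        return cls(
            snp_id=df["snp_id"].to_numpy(dtype=object),
            gene=df["gene"].to_numpy(dtype=object),
            is_causal=df["is_causal"].to_numpy(dtype=bool),
            effect=df["effect"].to_numpy(dtype=float),
            maf=df["maf"].to_numpy(dtype=float),
        )
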