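"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based, inclusive everywhere (VCF convention). Genotypes are
alt-allele dosages in [0, 2]; methylation levels are beta-values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANNOTATION_FLAGS = ("gene", "island", "promoter", "enhancer", "dnase1")

VARIANT_COLUMNS = ("variant_id", "chrom", "pos", "ref", "alt")
CPG_COLUMNS = ("cpg_id", "chrom", "pos") + ANNOTATION_FLAGS


class InvariantError(ValueError):
    """An input violated a documented data invariant."""


@dataclass
class GenotypePanel:
    """Sample-by-variant alt-allele dosage matrix with variant metadata.

    Parameters
    ----------
    samples : list of str
        Sample identifiers, one per dosage row.
    variants : pandas.DataFrame
        One row per variant with columns ``variant_id, chrom, pos, ref, alt``;
        positions are 1-based and sorted within each chromosome.
    dosages : ndarray of shape (n_samples, n_variants)
        Alt-allele dosages in [0, 2].
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise InvariantError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(self.variants):
            bad = (self.dosages < 0) | (self.dosages > 2)
            if bad.any():
                j = int(np.where(bad.any(axis=0))[0][0])
                vid = self.variants["variant_id"].iloc[j]
                raise InvariantError(f"dosage outside [0, 2] for variant {vid!r}")
            ids = self.variants["variant_id"]
            if ids.duplicated().any():
                dup = ids[ids.duplicated()].iloc[0]
                raise InvariantError(f"duplicate variant id {dup!r}")
            for _, grp in self.variants.groupby("chrom", sort=False):
                if not grp["pos"].is_monotonic_increasing:
                    raise InvariantError("variant positions not sorted within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency from sample dosages."""
        p = self.dosages.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def take_variants(self, idx: np.ndarray) -> "GenotypePanel":
        """Sub-panel restricted to the variant (column) indices ``idx``."""
        idx = np.asarray(idx, dtype=int)
        return GenotypePanel(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx, dtype=int)
        return GenotypePanel(
            samples=[self.samples[i] for i in idx],
            variants=self.variants,
            dosages=self.dosages[idx, :],
        )


@dataclass
class MethylationMatrix:
    """Sample-by-CpG beta-value matrix with CpG coordinates and annotations.

    ``cpgs`` has columns ``cpg_id, chrom, pos`` plus boolean annotation flags
    ``gene, island, promoter, enhancer, dnase1``.
    """

    samples: list[str]
    cpgs: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.cpgs = self.cpgs.reset_index(drop=True)
        for flag in ANNOTATION_FLAGS:
            if flag not in self.cpgs.columns:
                self.cpgs[flag] = False
            self.cpgs[flag] = self.cpgs[flag].astype(bool)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.cpgs)):
            raise InvariantError(
                f"methylation matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.cpgs)} CpGs"
            )
        if len(self.cpgs):
            bad = (self.values < 0) | (self.values > 1)
            if bad.any():
                j = int(np.where(bad.any(axis=0))[0][0])
                cid = self.cpgs["cpg_id"].iloc[j]
                raise InvariantError(f"beta-value outside [0, 1] at CpG {cid!r}")
            ids = self.cpgs["cpg_id"]
            if ids.duplicated().any():
                dup = ids[ids.duplicated()].iloc[0]
                raise InvariantError(f"duplicate CpG id {dup!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpgs)

    def cpg_vector(self, cpg_id: str) -> np.ndarray:
        j = self.cpgs.index[self.cpgs["cpg_id"] == cpg_id]
        if len(j) == 0:
            raise KeyError(f"unknown CpG id {cpg_id!r}")
        return self.values[:, int(j[0])]

    def take_samples(self, idx: np.ndarray) -> "MethylationMatrix":
        idx = np.asarray(idx, dtype=int)
        return MethylationMatrix(
            samples=[self.samples[i] for i in idx],
            cpgs=self.cpgs,
            values=self.values[idx, :],
        )


@dataclass
class GwasSummaryStats:
    """Per-variant marginal association statistics from a GWAS.

    ``table`` has columns ``snp, chrom, pos, a1, a2, beta, se, p, n`` where
    ``a1`` is the effect allele whose dosage multiplies ``beta``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        if len(self.table):
            if (self.table["se"] <= 0).any():
                bad = self.table.loc[self.table["se"] <= 0, "snp"].iloc[0]
                raise InvariantError(f"non-positive SE for variant {bad!r}")
            ok = {"A", "C", "G", "T"}
            alleles = set(self.table["a1"]) | set(self.table["a2"])
            if not alleles <= ok:
                raise InvariantError(f"non-SNV alleles present: {sorted(alleles - ok)}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PredictionModel:
    """A per-CpG sparse SNP-weight model plus its training metadata.

    ``weights`` has columns ``variant_id, effect_allele, other_allele, weight``
    with weights on the original dosage scale (prediction = intercept +
    sum of weight * harmonised dosage).
    """

    cpg_id: str
    method: str  # 'ridge' | 'lasso' | 'enet'
    alpha: float  # L1/L2 mixing parameter
    lambda_: float  # selected penalty strength
    window: int  # cis window half-width in bp
    weights: pd.DataFrame
    intercept: float
    cv_mse: float
    n_folds: int

    def __post_init__(self) -> None:
        nz = (self.weights["weight"] != 0).sum()
        if nz < 1:
            raise InvariantError(
                f"model for CpG {self.cpg_id!r} has no non-zero SNP weights"
            )

    @property
    def n_snps(self) -> int:
        return int((self.weights["weight"] != 0).sum())


@dataclass
class WindowSweepResult:
    """Outcome of training one CpG across several candidate cis windows."""

    cpg_id: str
    windows: list[int]
    models: dict[int, PredictionModel | None] = field(default_factory=dict)
    test_r: dict[int, float] = field(default_factory=dict)

    def available_windows(self) -> list[int]:
        return [w for w in self.windows if self.models.get(w) is not None]


@dataclass
class HeritabilityEstimate:
    """REML variance-component estimate of cis-SNP heritability for one trait."""

    h2: float
    se: float
    sigma_g: float
    sigma_e: float
    loglik: float
    iterations: int
    converged: bool
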