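"""Synthetic cohort generator with a sparse cis-mQTL architecture.

Produces the three inputs the pipeline consumes — an LD-structured diploid
genotype panel, a matched beta-value methylation matrix driven by a handful of
cis causal SNPs at a target heritability, and marginal per-SNP GWAS summary
statistics for a quantitative phenotype driven by selected CpGs — together
with the generative ground truth, so that every downstream stage can be tested
for parameter recovery without access-controlled cohort data.

Layout: one synthetic chromosome ("chr1") with CpG sites every 500 kb, each
owning a region of variants within +/-250 kb of the CpG; regions tile the
chromosome so larger cis windows reach into neighbouring regions.

LD model: haplotypes follow a first-order Markov chain along each region.  The
alt-allele frequency is drawn once per region, so copying the previous allele
with probability ``ld_rho`` (else redrawing) makes the adjacent-haplotype
correlation exactly ``ld_rho``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypePanel, GwasSummaryStats, MethylationMatrix

logger = logging.getLogger(__name__)

CPG_SPACING = 500_000  # bp between consecutive CpG sites
REGION_HALF_WIDTH = 250_000  # variants lie within this distance of their CpG

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Defaults describe a post-QC cohort with a sparse cis architecture:
    moderately common variants (MAF 5-50%), realistic adjacent-SNP LD,
    two causal SNPs per heritable CpG at cis-h2 = 0.5, and a phenotype
    drawing 10% of its variance from five causal CpGs.
    """

    n_samples: int = 500
    n_variants_per_region: int = 50
    n_cpgs: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    k_causal: int = 2
    h2_cis: float = 0.5
    prop_heritable_cpgs: float = 0.8
    phenotype_causal_cpgs: int = 5
    phenotype_h2: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_variants_per_region", "n_cpgs", "k_causal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        for name in ("h2_cis", "prop_heritable_cpgs", "phenotype_h2"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.phenotype_causal_cpgs < 0:
            raise ValueError("phenotype_causal_cpgs must be non-negative")


@dataclass
class SyntheticTruth:
    """Generative ground truth retained for parameter-recovery tests."""

    # cpg_id -> list of (variant_id, per-dosage effect on the latent scale)
    cpg_effects: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    realised_h2: dict[str, float] = field(default_factory=dict)
    # cpg_id -> phenotype weight
    phenotype_cpgs: dict[str, float] = field(default_factory=dict)

    @property
    def heritable_cpgs(self) -> list[str]:
        return sorted(self.cpg_effects)


def cpg_position(region: int) -> int:
    """1-based position of the CpG owning region ``region`` (0-based)."""
    return CPG_SPACING // 2 + region * CPG_SPACING


def simulate_genotypes(config: SimulationConfig) -> GenotypePanel:
    """Draw an LD-structured diploid dosage panel on one synthetic chromosome.

    Haplotypes are sampled per region as a first-order Markov chain: the first
    variant is Bernoulli(f); each later variant copies its left neighbour with
    probability ``ld_rho`` and is redrawn Bernoulli(f) otherwise, f being the
    region's alt-allele frequency drawn uniformly from ``maf_range``.
    Dosage = sum of the two haplotype alleles, so values lie in {0, 1, 2}.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_variants_per_region
    n_hap = 2 * n

    rows = []
    hap_blocks = []
    for r in range(config.n_cpgs):
        centre = cpg_position(r)
        lo = max(1, centre - REGION_HALF_WIDTH)
        hi = centre + REGION_HALF_WIDTH
        positions = np.sort(
            rng.choice(np.arange(lo, hi + 1), size=m, replace=False)
        )
        f = rng.uniform(*config.maf_range)
        haps = np.empty((n_hap, m), dtype=np.int8)
        haps[:, 0] = rng.random(n_hap) < f
        for j in range(1, m):
            copy = rng.random(n_hap) < config.ld_rho
            fresh = rng.random(n_hap) < f
            haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
        hap_blocks.append(haps)
        for k, pos in enumerate(positions):
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(
                (f"var{r:04d}_{k:04d}", "chr1", int(pos), _BASES[ref], _BASES[alt])
            )

    haps = np.concatenate(hap_blocks, axis=1)
    dosages = (haps[0::2] + haps[1::2]).astype(float)
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    samples = [f"S{i:05d}" for i in range(n)]
    return GenotypePanel(samples=samples, variants=variants, dosages=dosages)


def _rescale_unit_interval(x: np.ndarray, lo: float = 0.05, hi: float = 0.95) -> np.ndarray:
    rng_ = x.max() - x.min()
    if rng_ == 0:
        return np.full_like(x, (lo + hi) / 2)
    return lo + (hi - lo) * (x - x.min()) / rng_


def simulate_methylation(
    panel: GenotypePanel, config: SimulationConfig
) -> tuple[MethylationMatrix, SyntheticTruth]:
    """Generate beta-values with a sparse cis genetic architecture.

    For each heritable CpG the latent trait is ``X @ beta + eps`` with the
    genetic part standardised to variance ``h2_cis`` and causal SNPs drawn
    from the CpG's own +/-250 kb region; non-heritable CpGs are pure noise.
    Latent values are mapped affinely per CpG into [0.05, 0.95] — Pearson R is
    affine-invariant, so model evaluation is unaffected by the rescaling.
    """
    if panel.n_variants == 0:
        raise ValueError("genotype panel has no variants")
    rng = np.random.default_rng(config.seed + 1)
    n = panel.n_samples
    n_her = int(round(config.prop_heritable_cpgs * config.n_cpgs))
    heritable = set(rng.choice(config.n_cpgs, size=n_her, replace=False).tolist())

    truth = SyntheticTruth()
    values = np.empty((n, config.n_cpgs))
    rows = []
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    for c in range(config.n_cpgs):
        cpg_id = f"cpg{c:04d}"
        p_c = cpg_position(c)
        rows.append((cpg_id, "chr1", p_c, False, False, False, False, False))
        if c in heritable and config.h2_cis > 0:
            cis = np.where((chrom == "chr1") & (np.abs(pos - p_c) <= REGION_HALF_WIDTH))[0]
            if len(cis) == 0:
                raise ValueError(f"CpG {cpg_id} has no variants in its cis region")
            k = min(config.k_causal, len(cis))
            causal = rng.choice(cis, size=k, replace=False)
            beta = rng.normal(size=k)
            g = panel.dosages[:, causal] @ beta
            sd = g.std()
            if sd == 0:  # monomorphic draw; fall back to noise
                latent = rng.normal(size=n)
                truth.realised_h2[cpg_id] = 0.0
                truth.cpg_effects[cpg_id] = []
            else:
                scale = np.sqrt(config.h2_cis) / sd
                g_std = (g - g.mean()) * scale
                eps = rng.normal(scale=np.sqrt(1 - config.h2_cis), size=n)
                latent = g_std + eps
                truth.realised_h2[cpg_id] = float(g_std.var() / latent.var())
                truth.cpg_effects[cpg_id] = [
                    (panel.variants["variant_id"].iloc[int(j)], float(b * scale))
                    for j, b in zip(causal, beta)
                ]
        else:
            latent = rng.normal(size=n)
            if c in heritable:  # h2_cis == 0: heritable set but no genetic part
                truth.realised_h2[cpg_id] = 0.0
                truth.cpg_effects[cpg_id] = []
        values[:, c] = _rescale_unit_interval(latent)

    cpgs = pd.DataFrame(
        rows,
        columns=["cpg_id", "chrom", "pos", "gene", "island", "promoter", "enhancer", "dnase1"],
    )
    meth = MethylationMatrix(samples=list(panel.samples), cpgs=cpgs, values=values)
    return meth, truth


def simulate_phenotype(
    meth: MethylationMatrix,
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Quantitative phenotype driven by ``phenotype_causal_cpgs`` CpGs.

    The methylation-driven signal is standardised to variance ``phenotype_h2``
    and completed with independent Gaussian noise of variance 1 - phenotype_h2.
    Causal CpGs are drawn from the heritable set and recorded in ``truth``.

    Weights are equal-magnitude with random signs and apply to per-CpG
    standardised methylation, so each causal CpG contributes an equal share
    ``phenotype_h2 / k`` of phenotype variance. This emulates the complex-trait
    regime (no single molecular feature dominates the trait) in which
    summary-statistic imputed-association tests are derived.
    """
    heritable = truth.heritable_cpgs
    k = config.phenotype_causal_cpgs
    if k > len(heritable):
        raise ValueError(
            f"phenotype_causal_cpgs={k} exceeds number of heritable CpGs ({len(heritable)})"
        )
    causal = [str(c) for c in rng.choice(heritable, size=k, replace=False)] if k else []
    w = rng.choice([-1.0, 1.0], size=len(causal))
    n = meth.n_samples
    noise = rng.normal(size=n)
    if causal and config.phenotype_h2 > 0:
        cols = [int(meth.cpgs.index[meth.cpgs["cpg_id"] == c][0]) for c in causal]
        M = meth.values[:, cols]
        M = (M - M.mean(axis=0)) / M.std(axis=0)
        signal = M @ w
        sd = signal.std()
        signal = (signal - signal.mean()) / (sd if sd > 0 else 1.0)
        y = np.sqrt(config.phenotype_h2) * signal + np.sqrt(1 - config.phenotype_h2) * noise
    else:
        y = noise
    truth.phenotype_cpgs = dict(zip(causal, (float(x) for x in w)))
    return y


def marginal_sumstats(
    panel: GenotypePanel, phenotype: np.ndarray, n_label: int | None = None
) -> GwasSummaryStats:
    """Marginal simple-regression summary statistics of a phenotype on dosages.

    Per variant: slope beta = Sxy/Sxx, its OLS standard error, and the
    two-sided t-test p-value on n-2 df. Monomorphic variants (Sxx = 0) are
    dropped with a log record since their SE is undefined.
    """
    from scipy import stats

    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    X = panel.dosages
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    poly = sxx > 0
    n_dropped = int((~poly).sum())
    if n_dropped:
        dropped = panel.variants.loc[~poly, "variant_id"].tolist()
        logger.info("dropping %d monomorphic variant(s): %s", n_dropped, dropped[:5])
    sxy = xc[:, poly].T @ yc
    syy = (yc**2).sum()
    beta = sxy / sxx[poly]
    rss = syy - beta * sxy
    se = np.sqrt(np.maximum(rss, 0) / ((n - 2) * sxx[poly]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    v = panel.variants.loc[poly].reset_index(drop=True)
    table = pd.DataFrame(
        {
            "snp": v["variant_id"],
            "chrom": v["chrom"],
            "pos": v["pos"],
            "a1": v["alt"],  # effect allele = alt allele
            "a2": v["ref"],
            "beta": beta,
            "se": se,
            "p": p,
            "n": n_label if n_label is not None else n,
        }
    )
    return GwasSummaryStats(table=table)


def simulate_gwas_sumstats(
    panel: GenotypePanel,
    meth: MethylationMatrix,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[GwasSummaryStats, np.ndarray]:
    """Simulate a phenotype from selected CpGs and return its marginal GWAS.

    Returns the summary table and the individual-level phenotype vector (the
    latter is what makes the summary-statistic association test verifiable
    against an individual-level regression oracle).
    """
    rng = np.random.default_rng(config.seed + 2)
    y = simulate_phenotype(meth, truth, config, rng)
    return marginal_sumstats(panel, y), y
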