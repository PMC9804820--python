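"""Summary-statistic association between predicted methylation and a trait.

Given a per-CpG SNP-weight model, per-SNP GWAS Z-scores and a reference
dosage covariance for the model's SNPs, the association statistic is

    Z_c = sum_l w_l * (sigma_l / sigma_c) * Z_l,
    sigma_l = sqrt(Sigma_ll),    sigma_c = sqrt(w' Sigma w),

the summary-statistic form of regressing the trait on individually predicted
methylation (the S-PrediXcan statistic applied to CpG models). SNPs missing
from the GWAS, or with irreconcilable alleles, are dropped and w / Sigma are
restricted to the observed subset; the usage fraction is reported. p-values
are two-sided normal, with Bonferroni family-wise control over the CpGs that
were actually testable (>= 1 overlapping SNP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GwasSummaryStats, PredictionModel
from .io import ModelDB

logger = logging.getLogger(__name__)


@dataclass
class MwasResult:
    cpg_id: str
    z: float
    p: float
    sigma_c: float
    n_model_snps: int
    n_snps_used: int

    @property
    def usage(self) -> float:
        return self.n_snps_used / self.n_model_snps if self.n_model_snps else 0.0


class UntestableCpG(Exception):
    """Raised when a CpG's statistic cannot be formed (with the reason)."""


def harmonize_alleles(
    weights: pd.DataFrame, sumstats: GwasSummaryStats
) -> pd.DataFrame:
    """Align model weights with GWAS Z-scores on a shared effect allele.

    ``weights`` columns: ``rsid`` (or ``variant_id``), ``effect_allele``,
    ``other_allele``, ``weight``. Matching GWAS rows with the same effect
    allele keep their Z; rows where effect and other allele are swapped get
    Z negated; unmatched allele pairs are dropped with a log record.

    Returns a frame with columns ``rsid, weight, z``.
    """
    w = weights.rename(columns={"variant_id": "rsid"})
    ss = sumstats.table.set_index("snp")
    rows = []
    for _, r in w.iterrows():
        if r["rsid"] not in ss.index:
            continue
        g = ss.loc[r["rsid"]]
        z = float(g["beta"] / g["se"])
        if g["a1"] == r["effect_allele"] and g["a2"] == r["other_allele"]:
            rows.append((r["rsid"], float(r["weight"]), z))
        elif g["a1"] == r["other_allele"] and g["a2"] == r["effect_allele"]:
            rows.append((r["rsid"], float(r["weight"]), -z))
        else:
            logger.info(
                "SNP %s: allele pair (%s,%s) vs GWAS (%s,%s) irreconcilable; dropped",
                r["rsid"], r["effect_allele"], r["other_allele"], g["a1"], g["a2"],
            )
    return pd.DataFrame(rows, columns=["rsid", "weight", "z"])


def mwas_zscore(
    weights: pd.DataFrame,
    sumstats: GwasSummaryStats,
    covariance: np.ndarray,
    cov_snps: list[str],
    cpg_id: str = "",
) -> MwasResult:
    """Association Z for one CpG from weights, GWAS Z-scores and covariance.

    ``covariance`` is the reference dosage covariance over ``cov_snps`` (the
    model's SNPs, superset of the harmonised ones); w and Sigma are restricted
    to the harmonised subset before forming the statistic.
    """
    n_model = len(weights)
    harm = harmonize_alleles(weights, sumstats)
    if len(harm) == 0:
        raise UntestableCpG(f"CpG {cpg_id!r}: no overlapping SNPs")
    order = {s: i for i, s in enumerate(cov_snps)}
    idx = [order[s] for s in harm["rsid"]]
    sig = np.asarray(covariance)[np.ix_(idx, idx)]
    w = harm["weight"].to_numpy()
    zl = harm["z"].to_numpy()
    var_c = float(w @ sig @ w)
    if var_c <= 0:
        raise UntestableCpG(
            f"CpG {cpg_id!r}: predicted methylation has zero variance in the reference"
        )
    sigma_c = np.sqrt(var_c)
    sigma_l = np.sqrt(np.diag(sig))
    z = float(np.sum(w * sigma_l * zl) / sigma_c)
    return MwasResult(
        cpg_id=cpg_id,
        z=z,
        p=float(2 * stats.norm.sf(abs(z))),
        sigma_c=sigma_c,
        n_model_snps=n_model,
        n_snps_used=len(harm),
    )


def mwas_zscore_model(
    model: PredictionModel, sumstats: GwasSummaryStats, covariance: np.ndarray
) -> MwasResult:
    """Convenience wrapper taking a :class:`PredictionModel` directly.

    ``covariance`` must be ordered like ``model.weights``.
    """
    w = model.weights.rename(columns={"variant_id": "rsid"})
    return mwas_zscore(
        w, sumstats, covariance, list(w["rsid"]), cpg_id=model.cpg_id
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test p-value threshold controlling the family-wise error at alpha."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


def run_mwas(
    model_db: ModelDB, sumstats: GwasSummaryStats, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Test every model in a DB against a GWAS.

    Returns (results, untestable, threshold): one results row per testable
    CpG with its Bonferroni significance call, a table of CpGs that could
    not be tested with the reason, and the per-test threshold. The number of
    tests is the number of *testable* CpGs, not the DB size.
    """
    results, skipped = [], []
    for cpg in model_db.cpgs:
        snps_df = model_db.model_snps(cpg)
        snps = list(snps_df["rsid"])
        cov = model_db.covariance_matrix(cpg, snps)
        try:
            res = mwas_zscore(snps_df, sumstats, cov, snps, cpg_id=cpg)
        except UntestableCpG as exc:
            skipped.append((cpg, str(exc)))
            continue
        results.append(
            (cpg, res.z, res.p, res.sigma_c, res.n_model_snps, res.n_snps_used, res.usage)
        )
    if not results:
        raise ValueError("no CpG in the model DB overlaps the summary statistics")
    out = pd.DataFrame(
        results,
        columns=["cpg", "zscore", "pvalue", "sigma_c", "n_model_snps", "n_snps_used", "usage"],
    )
    threshold = bonferroni_threshold(alpha, len(out))
    out["significant"] = out["pvalue"] < threshold
    untestable = pd.DataFrame(skipped, columns=["cpg", "reason"])
    return out, untestable, threshold


def nearby_significant_features(
    features_a: pd.DataFrame, features_b: pd.DataFrame, max_distance: int = 1_000_000
) -> pd.DataFrame:
    """Pairs of significant features from two scans within ``max_distance`` bp.

    Both frames need columns ``id, chrom, pos, significant``. Generic
    cross-scan intersection report (e.g. MWAS hits near TWAS hits).
    """
    a = features_a[features_a["significant"]]
    b = features_b[features_b["significant"]]
    rows = []
    for _, ra in a.iterrows():
        near = b[(b["chrom"] == ra["chrom"]) & (np.abs(b["pos"] - ra["pos"]) <= max_distance)]
        for _, rb in near.iterrows():
            rows.append((ra["id"], rb["id"], ra["chrom"], int(abs(rb["pos"] - ra["pos"]))))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "chrom", "distance"])
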