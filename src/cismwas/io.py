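"""Readers and writers for the pipeline's file formats.

Formats
-------
* genotypes: VCF v4.x (``DS`` dosage field when present, else ``GT`` allele
  count; multi-allelic records rejected) or a dosage TSV with variants as rows
  (columns ``variant_id chrom pos ref alt`` then one column per sample);
* methylation: TSV with CpGs as rows (id, coordinates, five boolean
  annotation flags, then per-sample beta-values);
* GWAS summary statistics: TSV with columns ``SNP CHR POS A1 A2 BETA SE P N``
  (A1 = effect allele);
* model database: a single-file SQLite database with ``weights`` and ``extra``
  tables in the PredictDB style, accompanied by a gzip TSV of within-model
  training-cohort dosage covariances (columns ``CPG RSID1 RSID2 VALUE``).

All coordinates are 1-based, inclusive. Readers enforce the container
invariants and fail loudly rather than coercing bad values.
"""

from __future__ import annotations

import gzip
import sqlite3
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ANNOTATION_FLAGS,
    GenotypePanel,
    GwasSummaryStats,
    InvariantError,
    MethylationMatrix,
    PredictionModel,
)

SUMSTATS_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "BETA", "SE", "P", "N"]


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes_tsv(panel: GenotypePanel, path: str | Path) -> None:
    df = panel.variants.copy()
    dos = pd.DataFrame(panel.dosages.T, columns=panel.samples)
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_genotypes_tsv(path: str | Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta_cols = ["variant_id", "chrom", "pos", "ref", "alt"]
    if list(df.columns[:5]) != meta_cols:
        raise InvariantError(
            f"dosage TSV must start with columns {meta_cols}, got {list(df.columns[:5])}"
        )
    samples = list(df.columns[5:])
    dosages = df[samples].to_numpy(dtype=float).T
    variants = df[meta_cols].copy()
    variants["chrom"] = variants["chrom"].astype(str)
    return GenotypePanel(samples=samples, variants=variants, dosages=dosages)


def write_genotypes_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Minimal VCF v4.2 writer carrying dosages in the FORMAT/DS field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for j, row in panel.variants.iterrows():
            ds = "\t".join(repr(float(d)) for d in panel.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tDS\t{ds}\n"
            )


def read_genotypes_vcf(path: str | Path) -> GenotypePanel:
    """Read a VCF via cyvcf2, taking dosage from DS when present, else GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise InvariantError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} not supported; "
                "split the record first"
            )
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dosage = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0=hom ref, 1=het, 2=hom alt (cyvcf2 gts012 off -> 3=unknown)
            gts = np.asarray(rec.genotypes, dtype=object)
            dosage = np.array(
                [float(int(g[0]) + int(g[1])) for g in gts], dtype=float
            )
        if ((dosage < 0) | (dosage > 2)).any():
            raise InvariantError(f"dosage outside [0, 2] for variant {vid!r}")
        rows.append((vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        cols.append(dosage)
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    dosages = np.column_stack(cols) if cols else np.zeros((len(samples), 0))
    return GenotypePanel(samples=samples, variants=variants, dosages=dosages)


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypePanel:
    """Dispatch on ``format`` ('vcf' or 'dosage_tsv'), guessing from the suffix."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz"} else "dosage_tsv"
    if format == "vcf":
        return read_genotypes_vcf(path)
    if format == "dosage_tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# methylation


def write_methylation(meth: MethylationMatrix, path: str | Path) -> None:
    df = meth.cpgs.copy()
    vals = pd.DataFrame(meth.values.T, columns=meth.samples)
    pd.concat([df, vals], axis=1).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_methylation(path: str | Path) -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta_cols = ["cpg_id", "chrom", "pos", *ANNOTATION_FLAGS]
    if list(df.columns[: len(meta_cols)]) != meta_cols:
        raise InvariantError(f"methylation TSV must start with columns {meta_cols}")
    samples = list(df.columns[len(meta_cols):])
    values = df[samples].to_numpy(dtype=float).T
    cpgs = df[meta_cols].copy()
    cpgs["chrom"] = cpgs["chrom"].astype(str)
    return MethylationMatrix(samples=samples, cpgs=cpgs, values=values)


# ---------------------------------------------------------------------------
# GWAS summary statistics


def write_sumstats(ss: GwasSummaryStats, path: str | Path) -> None:
    out = ss.table.rename(
        columns={
            "snp": "SNP", "chrom": "CHR", "pos": "POS", "a1": "A1", "a2": "A2",
            "beta": "BETA", "se": "SE", "p": "P", "n": "N",
        }
    )
    out[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_sumstats(path: str | Path) -> GwasSummaryStats:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(SUMSTATS_COLUMNS) - set(df.columns)
    if missing:
        raise InvariantError(f"sumstats file missing columns {sorted(missing)}")
    for col in ("BETA", "SE", "P"):
        if df[col].isna().any():
            # +2: one for the header line, one for 1-based numbering
            line = int(df.index[df[col].isna()][0]) + 2
            raise InvariantError(f"missing {col} value at line {line}")
    table = df.rename(
        columns={
            "SNP": "snp", "CHR": "chrom", "POS": "pos", "A1": "a1", "A2": "a2",
            "BETA": "beta", "SE": "se", "P": "p", "N": "n",
        }
    )
    table["chrom"] = table["chrom"].astype(str)
    return GwasSummaryStats(table=table)


# ---------------------------------------------------------------------------
# model database


@dataclass
class ModelDB:
    """Released model bundle: weights, per-model metadata, covariance blocks.

    ``weights``: columns ``cpg, rsid, effect_allele, other_allele, weight``.
    ``extra``: columns ``cpg, n_snps, window, alpha, lambda, cv_mse, test_R,
    validation_R`` (one row per model).
    ``covariances``: per-CpG DataFrame with columns ``rsid1, rsid2, value``
    covering every unordered pair of the model's variants, self-pairs
    (variances) included.
    """

    weights: pd.DataFrame
    extra: pd.DataFrame
    covariances: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        known = set(self.extra["cpg"])
        orphan = set(self.weights["cpg"]) - known
        if orphan:
            raise InvariantError(f"weights reference unknown CpG(s): {sorted(orphan)[:5]}")
        for cpg, grp in self.weights.groupby("cpg"):
            if (grp["weight"] == 0).all():
                raise InvariantError(f"model for CpG {cpg!r} has no non-zero weights")
            cov = self.covariances.get(cpg)
            if cov is None:
                raise InvariantError(f"no covariance block for CpG {cpg!r}")
            have = {frozenset((a, b)) for a, b in zip(cov["rsid1"], cov["rsid2"])}
            snps = list(grp["rsid"])
            for i, a in enumerate(snps):
                for b in snps[i:]:
                    if frozenset((a, b)) not in have:
                        raise InvariantError(
                            f"covariance block for CpG {cpg!r} missing pair ({a}, {b})"
                        )

    @property
    def cpgs(self) -> list[str]:
        return list(self.extra["cpg"])

    def model_snps(self, cpg: str) -> pd.DataFrame:
        return self.weights[self.weights["cpg"] == cpg].reset_index(drop=True)

    def covariance_matrix(self, cpg: str, snps: list[str]) -> np.ndarray:
        """Dense covariance matrix over ``snps`` in the given order."""
        cov = self.covariances[cpg]
        lut = {}
        for a, b, v in zip(cov["rsid1"], cov["rsid2"], cov["value"]):
            lut[(a, b)] = v
            lut[(b, a)] = v
        k = len(snps)
        out = np.empty((k, k))
        for i, a in enumerate(snps):
            for j, b in enumerate(snps):
                out[i, j] = lut[(a, b)]
        return out


def _cov_path(db_path: str | Path) -> Path:
    return Path(str(db_path) + ".covariance.txt.gz")


def models_to_db(
    models: list[PredictionModel],
    performance: dict[str, dict[str, float]],
    covariances: dict[str, pd.DataFrame],
) -> ModelDB:
    """Assemble a :class:`ModelDB` from fitted models and their metadata.

    ``performance`` maps cpg id to a dict with optional ``test_R`` and
    ``validation_R`` entries.
    """
    wrows, erows = [], []
    for m in models:
        nz = m.weights[m.weights["weight"] != 0]
        if len(nz) == 0:
            raise InvariantError(f"model for CpG {m.cpg_id!r} has no SNPs; refusing to write")
        for _, r in nz.iterrows():
            wrows.append((m.cpg_id, r["variant_id"], r["effect_allele"], r["other_allele"], r["weight"]))
        perf = performance.get(m.cpg_id, {})
        erows.append(
            (
                m.cpg_id, len(nz), m.window, m.alpha, m.lambda_, m.cv_mse,
                perf.get("test_R", np.nan), perf.get("validation_R", np.nan),
            )
        )
    weights = pd.DataFrame(
        wrows, columns=["cpg", "rsid", "effect_allele", "other_allele", "weight"]
    )
    extra = pd.DataFrame(
        erows,
        columns=["cpg", "n_snps", "window", "alpha", "lambda", "cv_mse", "test_R", "validation_R"],
    )
    return ModelDB(weights=weights, extra=extra, covariances=covariances)


def write_model_db(db: ModelDB, path: str | Path) -> None:
    """Write the SQLite model file and its gzip covariance companion."""
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        db.weights.to_sql("weights", con, index=False)
        db.extra.to_sql("extra", con, index=False)
        con.commit()
    finally:
        con.close()
    with gzip.open(_cov_path(path), "wt") as fh:
        fh.write("CPG\tRSID1\tRSID2\tVALUE\n")
        for cpg in db.extra["cpg"]:
            cov = db.covariances[cpg]
            for a, b, v in zip(cov["rsid1"], cov["rsid2"], cov["value"]):
                fh.write(f"{cpg}\t{a}\t{b}\t{v!r}\n")


def read_model_db(path: str | Path) -> ModelDB:
    path = Path(path)
    con = sqlite3.connect(path)
    try:
        weights = pd.read_sql("SELECT * FROM weights", con)
        extra = pd.read_sql("SELECT * FROM extra", con)
    finally:
        con.close()
    for col in ("alpha", "lambda", "cv_mse", "test_R", "validation_R"):
        extra[col] = extra[col].astype(float)  # sqlite NULLs read back as object
    cov = pd.read_csv(
        _cov_path(path), sep="\t", compression="gzip", float_precision="round_trip"
    )
    covariances = {
        str(cpg): grp.rename(
            columns={"RSID1": "rsid1", "RSID2": "rsid2", "VALUE": "value"}
        )[["rsid1", "rsid2", "value"]].reset_index(drop=True)
        for cpg, grp in cov.groupby("CPG", sort=False)
    }
    return ModelDB(weights=weights, extra=extra, covariances=covariances)


def dosage_covariance_block(panel: GenotypePanel, snps: list[str]) -> pd.DataFrame:
    """Training-cohort dosage covariance over ``snps`` in long format.

    Uses the unbiased (n-1) sample covariance; only the scale-free ratios
    sigma_l / sigma_c enter the association statistic, so the denominator
    convention cancels there.
    """
    idx = [int(panel.variants.index[panel.variants["variant_id"] == s][0]) for s in snps]
    X = panel.dosages[:, idx]
    C = np.cov(X, rowvar=False, ddof=1).reshape(len(snps), len(snps))
    rows = []
    for i, a in enumerate(snps):
        for j in range(i, len(snps)):
            rows.append((a, snps[j], float(C[i, j])))
    return pd.DataFrame(rows, columns=["rsid1", "rsid2", "value"])
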