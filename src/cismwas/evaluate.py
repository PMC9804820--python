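"""Sample splitting, model application and prediction-accuracy filtering.

Implements the staged evaluation design: split a cohort into training / test /
hold-out sets, apply trained SNP-weight models to a (possibly different)
genotype panel with allele harmonisation, score each model by the signed
Pearson correlation R between predicted and observed methylation, and retain
models with R >= 0.1 (>= 0.5 marking the well-predicted subset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypePanel, MethylationMatrix, PredictionModel

logger = logging.getLogger(__name__)

#: retention threshold on prediction accuracy R
DEFAULT_R_THRESHOLD = 0.1
#: threshold defining the well-predicted CpG subset
WELL_PREDICTED_R = 0.5

AMBIGUOUS_PAIRS = {frozenset("AT"), frozenset("CG")}


@dataclass
class SplitScheme:
    """Disjoint, exhaustive sample split with largest-remainder rounding."""

    fractions: tuple[float, ...]
    seed: int
    indices: tuple[np.ndarray, ...]

    @property
    def train(self) -> np.ndarray:
        return self.indices[0]

    @property
    def test(self) -> np.ndarray:
        return self.indices[1]

    @property
    def holdout(self) -> np.ndarray:
        return self.indices[2] if len(self.indices) > 2 else np.array([], dtype=int)


def split_samples(
    sample_ids: list[str], fractions: tuple[float, ...], seed: int
) -> SplitScheme:
    """Randomly partition samples into groups of the given fractions.

    Group sizes use largest-remainder rounding so they sum exactly to the
    cohort size; the assignment is a seeded permutation, hence reproducible.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(sample_ids)
    raw = np.array([f * n for f in fractions])
    sizes = np.floor(raw).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    for g in order[:remainder]:
        sizes[g] += 1
    perm = np.random.default_rng(seed).permutation(n)
    indices, start = [], 0
    for s in sizes:
        indices.append(np.sort(perm[start:start + s]))
        start += s
    return SplitScheme(fractions=fractions, seed=seed, indices=tuple(indices))


def predict_methylation(
    model: PredictionModel,
    panel: GenotypePanel,
    drop_ambiguous: bool = False,
) -> tuple[np.ndarray, float]:
    """Apply a SNP-weight model to a genotype panel.

    Harmonisation per SNP: when the panel's alt allele is the model's effect
    allele the dosage is used as-is; when ref and alt are swapped relative to
    the model, ``2 - dosage`` is used; any other allele pair is dropped.
    Model SNPs missing from the panel contribute 0 and reduce the usage
    fraction. Strand-ambiguous (A/T, C/G) SNPs are kept by default with a
    warning — synthetic panels have no strand issues; set ``drop_ambiguous``
    for real data.
    """
    lut = {v: j for j, v in enumerate(panel.variants["variant_id"])}
    pred = np.full(panel.n_samples, model.intercept, dtype=float)
    n_model = len(model.weights)
    used = 0
    for _, row in model.weights.iterrows():
        j = lut.get(row["variant_id"])
        if j is None:
            continue
        ref, alt = panel.variants["ref"].iloc[j], panel.variants["alt"].iloc[j]
        if frozenset((row["effect_allele"], row["other_allele"])) in AMBIGUOUS_PAIRS:
            if drop_ambiguous:
                logger.info("dropping strand-ambiguous SNP %s", row["variant_id"])
                continue
            logger.warning("strand-ambiguous SNP %s kept", row["variant_id"])
        if alt == row["effect_allele"] and ref == row["other_allele"]:
            dosage = panel.dosages[:, j]
        elif ref == row["effect_allele"] and alt == row["other_allele"]:
            dosage = 2.0 - panel.dosages[:, j]
        else:
            logger.info(
                "allele mismatch for SNP %s (model %s/%s vs panel %s/%s); dropped",
                row["variant_id"], row["effect_allele"], row["other_allele"], alt, ref,
            )
            continue
        pred += row["weight"] * dosage
        used += 1
    if used == 0:
        raise ValueError(f"model for CpG {model.cpg_id!r}: no overlapping SNPs in panel")
    return pred, used / n_model


def prediction_correlation(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Signed Pearson correlation R between predictions and observations.

    Returns nan (flagging the model, which then fails retention) when either
    vector is constant and the correlation is undefined.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or len(predicted) < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if predicted.std() == 0 or observed.std() == 0:
        logger.warning("constant vector: prediction accuracy undefined")
        return float("nan")
    return float(stats.pearsonr(predicted, observed)[0])


def filter_models(
    performance: pd.DataFrame, threshold: float = DEFAULT_R_THRESHOLD, column: str = "R"
) -> set[str]:
    """CpG ids whose signed R meets the retention threshold (inclusive).

    nan accuracies never pass; negative-R models are discarded naturally by
    the signed convention.
    """
    keep = performance[column] >= threshold
    return set(performance.loc[keep.fillna(False), "cpg"])


def evaluate_models(
    models: dict[str, PredictionModel],
    panel: GenotypePanel,
    meth: MethylationMatrix,
    stage: str = "internal_test",
    threshold: float = DEFAULT_R_THRESHOLD,
    sample_idx: np.ndarray | None = None,
    drop_ambiguous: bool = False,
) -> pd.DataFrame:
    """Score each model on a cohort; returns one row per model.

    Columns: cpg, stage, R, n_samples, usage, retained.
    """
    if sample_idx is not None:
        panel = panel.take_samples(sample_idx)
        meth = meth.take_samples(sample_idx)
    rows = []
    for cpg, model in models.items():
        try:
            pred, usage = predict_methylation(model, panel, drop_ambiguous=drop_ambiguous)
        except ValueError as exc:
            logger.warning("%s", exc)
            rows.append((cpg, stage, float("nan"), panel.n_samples, 0.0, False))
            continue
        r = prediction_correlation(pred, meth.cpg_vector(cpg))
        rows.append(
            (cpg, stage, r, panel.n_samples, usage, bool(r >= threshold) if np.isfinite(r) else False)
        )
    return pd.DataFrame(
        rows, columns=["cpg", "stage", "R", "n_samples", "usage", "retained"]
    )


def cross_cohort_validate(
    models: dict[str, PredictionModel],
    panel_b: GenotypePanel,
    meth_b: MethylationMatrix,
    threshold: float = DEFAULT_R_THRESHOLD,
    drop_ambiguous: bool = False,
) -> pd.DataFrame:
    """Validate cohort-A-trained models in an independent cohort B.

    Cohort B must not have contributed samples to training; applying models
    back to their own training cohort inflates R optimistically.
    """
    return evaluate_models(
        models, panel_b, meth_b, stage="cross_cohort",
        threshold=threshold, drop_ambiguous=drop_ambiguous,
    )
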