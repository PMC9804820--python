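"""Per-CpG penalised regression of methylation on cis SNP dosages.

The trainer regresses a CpG's beta-values on the dosages of all SNPs within a
cis window of the site, using ridge (mixing 0), elastic net (0.5) or lasso (1)
with the glmnet parameterisation of the objective

    (1/2n) * sum_i (y_i - b0 - x_i'b)^2 + lam * [(1-a)*||b||_2^2/2 + a*||b||_1].

The penalty ``lam`` is chosen by k-fold cross-validation over a geometric
path, with one twist that matters for sparse methods: any ``lam`` whose
full-data refit contains no SNPs (all weights exactly zero) is excluded
before the minimum-CV-MSE choice, and if every ``lam`` is excluded the CpG
gets no model at all. Window sizes are swept per CpG and the optimum is the
window with the highest held-out prediction accuracy R.

Genotype columns are standardised inside the fit; reported weights are mapped
back to the original dosage scale so they can be applied directly to dosages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_array, check_is_fitted, column_or_1d

from .datatypes import GenotypePanel, MethylationMatrix, PredictionModel, WindowSweepResult

logger = logging.getLogger(__name__)

#: candidate cis window half-widths, in bp
DEFAULT_WINDOWS = (250_000, 500_000, 1_000_000, 2_000_000, 3_000_000)

_METHOD_BY_RATIO = {0.0: "ridge", 0.5: "enet", 1.0: "lasso"}


class CisElasticNetCV(RegressorMixin, BaseEstimator):
    """Elastic net with CV penalty selection and the empty-model exclusion rule.

    Parameters
    ----------
    l1_ratio : float, default=0.5
        Mixing between the L2 (0 = ridge) and L1 (1 = lasso) penalties.
    n_lambdas : int, default=100
        Length of the geometric penalty path.
    lambda_min_ratio : float, default=1e-4
        Smallest path value as a fraction of the data-derived maximum
        ``max_j |x_j'y| / (n * max(l1_ratio, 0.001))``.
    lambdas : array-like or None
        Explicit penalty path overriding the automatic one (descending order
        is enforced internally).
    cv : int, default=10
        Number of cross-validation folds.
    random_state : int or None
        Seed for the fold assignment; folds are shared across the path.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Weights on the original dosage scale.
    intercept_ : float
    lambda_ : float
        Selected penalty (nan when no model survives the exclusion rule).
    cv_mse_ : float
        Cross-validated MSE at the selected penalty.
    null_model_ : bool
        True when every penalty produced an empty model (or the response was
        degenerate); ``coef_`` is all zeros and ``predict`` returns the mean.
    null_reason_ : str or None
    lambda_path_, cv_mse_path_, nonzero_path_ : ndarray
        The full path diagnostics (path order: decreasing penalty).
    """

    def __init__(
        self,
        l1_ratio: float = 0.5,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-4,
        lambdas=None,
        cv: int = 10,
        random_state: int | None = None,
        max_iter: int = 10_000,
        tol: float = 1e-4,
    ):
        self.l1_ratio = l1_ratio
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.lambdas = lambdas
        self.cv = cv
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    # -- internals ---------------------------------------------------------

    def _path(self, X: np.ndarray, y: np.ndarray, lams: np.ndarray) -> np.ndarray:
        """Coefficients along the penalty path for centred data (p, n_lams)."""
        _, coefs, _ = enet_path(
            X,
            y,
            l1_ratio=self.l1_ratio,
            alphas=lams,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        return coefs

    def _null_fit(self, y: np.ndarray, n_features: int, reason: str) -> "CisElasticNetCV":
        self.coef_ = np.zeros(n_features)
        self.intercept_ = float(np.mean(y)) if len(y) else 0.0
        self.lambda_ = np.nan
        self.cv_mse_ = np.nan
        self.null_model_ = True
        self.null_reason_ = reason
        return self

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = check_array(X, ensure_min_features=0)
        y = column_or_1d(y)
        if X.shape[0] != len(y):
            raise ValueError("X and y have mismatched numbers of rows")
        n, p = X.shape
        self.n_features_in_ = p
        if p == 0:
            return self._null_fit(y, p, "no candidate SNPs")
        if np.std(y) == 0:
            return self._null_fit(y, p, "constant response")
        if n <= self.cv:
            raise ValueError(f"need more than cv={self.cv} samples, got {n}")

        x_mean = X.mean(axis=0)
        x_scale = X.std(axis=0)
        x_scale_safe = np.where(x_scale > 0, x_scale, 1.0)
        Xs = (X - x_mean) / x_scale_safe
        Xs[:, x_scale == 0] = 0.0
        y_mean = float(y.mean())
        yc = y - y_mean
        self.x_mean_, self.x_scale_ = x_mean, x_scale_safe

        if self.lambdas is not None:
            lams = np.sort(np.asarray(self.lambdas, dtype=float))[::-1]
        else:
            lam_max = np.max(np.abs(Xs.T @ yc)) / (n * max(self.l1_ratio, 0.001))
            if lam_max <= 0:
                return self._null_fit(y, p, "response orthogonal to all SNPs")
            lams = np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambdas)
        self.lambda_path_ = lams

        # CV curve: folds fixed once, shared across the whole path
        folds = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        sq_err = np.zeros(len(lams))
        for tr, va in folds.split(Xs):
            xm = Xs[tr].mean(axis=0)
            ym = yc[tr].mean()
            coefs = self._path(Xs[tr] - xm, yc[tr] - ym, lams)
            pred = (Xs[va] - xm) @ coefs + ym
            sq_err += ((pred - yc[va][:, None]) ** 2).sum(axis=0)
        cv_mse = sq_err / n
        self.cv_mse_path_ = cv_mse

        # full-data refit along the path; empty-model penalties are excluded
        coefs_full = self._path(Xs, yc, lams)
        nonzero = (coefs_full != 0).sum(axis=0)
        self.nonzero_path_ = nonzero
        admissible = np.where(nonzero > 0)[0]
        if len(admissible) == 0:
            return self._null_fit(y, p, "all penalties gave empty models")
        best = admissible[int(np.argmin(cv_mse[admissible]))]

        coef_std = coefs_full[:, best]
        self.coef_ = coef_std / x_scale_safe
        self.intercept_ = y_mean - float(x_mean @ self.coef_)
        self.lambda_ = float(lams[best])
        self.cv_mse_ = float(cv_mse[best])
        self.null_model_ = False
        self.null_reason_ = None
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, ensure_min_features=0)
        return X @ self.coef_ + self.intercept_


def method_name(l1_ratio: float) -> str:
    return _METHOD_BY_RATIO.get(float(l1_ratio), "enet")


def extract_window(
    panel: GenotypePanel, cpg_chrom: str, cpg_pos: int, window: int
) -> np.ndarray:
    """Indices of panel variants within ``window`` bp of the CpG, inclusive."""
    if window <= 0:
        raise ValueError("window must be positive")
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    return np.where((chrom == cpg_chrom) & (np.abs(pos - cpg_pos) <= window))[0]


def fit_penalized(
    y: np.ndarray,
    X: np.ndarray,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int | None = None,
    variants: pd.DataFrame | None = None,
    cpg_id: str = "",
    window: int = 0,
    lambdas=None,
    pre_transform=None,
) -> PredictionModel | None:
    """Fit one CpG's penalised model; ``None`` when no model survives.

    ``variants`` supplies the id/allele metadata for the columns of ``X`` (a
    frame with ``variant_id, ref, alt``); when omitted, synthetic ids are
    used. The effect allele of every weight is the panel's alt allele.
    ``pre_transform`` optionally maps the response before fitting (e.g. an
    M-value transform or covariate residualisation); the default fits raw
    beta-values.
    """
    y = np.asarray(y, dtype=float)
    if pre_transform is not None:
        y = np.asarray(pre_transform(y), dtype=float)
    est = CisElasticNetCV(l1_ratio=alpha, cv=n_folds, random_state=seed, lambdas=lambdas)
    est.fit(np.asarray(X, dtype=float), y)
    if est.null_model_:
        logger.info("CpG %s: no model (%s)", cpg_id or "<anon>", est.null_reason_)
        return None
    if variants is None:
        variants = pd.DataFrame(
            {
                "variant_id": [f"x{j}" for j in range(est.n_features_in_)],
                "ref": "A",
                "alt": "G",
            }
        )
    nz = np.flatnonzero(est.coef_)
    weights = pd.DataFrame(
        {
            "variant_id": variants["variant_id"].to_numpy()[nz],
            "effect_allele": variants["alt"].to_numpy()[nz],
            "other_allele": variants["ref"].to_numpy()[nz],
            "weight": est.coef_[nz],
        }
    )
    return PredictionModel(
        cpg_id=cpg_id,
        method=method_name(alpha),
        alpha=float(alpha),
        lambda_=est.lambda_,
        window=int(window),
        weights=weights,
        intercept=est.intercept_,
        cv_mse=est.cv_mse_,
        n_folds=n_folds,
    )


def _test_r(model_coef_pred: np.ndarray, observed: np.ndarray) -> float:
    if np.std(model_coef_pred) == 0 or np.std(observed) == 0:
        return float("nan")
    return float(stats.pearsonr(model_coef_pred, observed)[0])


def sweep_windows(
    panel: GenotypePanel,
    meth: MethylationMatrix,
    cpg_id: str,
    windows=DEFAULT_WINDOWS,
    alpha: float = 0.5,
    train_idx: np.ndarray | None = None,
    test_idx: np.ndarray | None = None,
    seed: int | None = None,
    n_folds: int = 10,
) -> WindowSweepResult:
    """Train the CpG at every candidate window and score each on the test set."""
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test index sets overlap")
    row = meth.cpgs[meth.cpgs["cpg_id"] == cpg_id]
    if len(row) == 0:
        raise KeyError(f"unknown CpG id {cpg_id!r}")
    chrom, pos = row["chrom"].iloc[0], int(row["pos"].iloc[0])
    y = meth.cpg_vector(cpg_id)

    result = WindowSweepResult(cpg_id=cpg_id, windows=list(windows))
    for w in windows:
        idx = extract_window(panel, chrom, pos, w)
        if len(idx) == 0:
            logger.info("CpG %s window %d: no candidate SNPs", cpg_id, w)
            result.models[w] = None
            result.test_r[w] = float("nan")
            continue
        Xw = panel.dosages[:, idx]
        model = fit_penalized(
            y[train_idx],
            Xw[train_idx],
            alpha=alpha,
            n_folds=n_folds,
            seed=seed,
            variants=panel.variants.iloc[idx].reset_index(drop=True),
            cpg_id=cpg_id,
            window=w,
        )
        result.models[w] = model
        if model is None:
            result.test_r[w] = float("nan")
        else:
            cols = [
                int(panel.variants.index[panel.variants["variant_id"] == v][0])
                for v in model.weights["variant_id"]
            ]
            pred = model.intercept + panel.dosages[np.ix_(test_idx, cols)] @ model.weights[
                "weight"
            ].to_numpy()
            result.test_r[w] = _test_r(pred, y[test_idx])
    return result


def select_optimal_window(sweep: WindowSweepResult) -> tuple[int, float]:
    """Window with the maximum test R; ties resolve to the smallest window."""
    avail = [
        w for w in sweep.available_windows() if np.isfinite(sweep.test_r.get(w, np.nan))
    ]
    if not avail:
        raise ValueError(f"CpG {sweep.cpg_id!r}: no window produced a model")
    best = max(sorted(avail), key=lambda w: (sweep.test_r[w], -w))
    return best, sweep.test_r[best]


def train_models(
    panel: GenotypePanel,
    meth: MethylationMatrix,
    cpg_ids: list[str] | None = None,
    windows=DEFAULT_WINDOWS,
    alpha: float = 0.5,
    train_idx: np.ndarray | None = None,
    test_idx: np.ndarray | None = None,
    seed: int = 0,
    n_folds: int = 10,
) -> tuple[dict[str, PredictionModel], pd.DataFrame, dict[str, WindowSweepResult]]:
    """Window-swept training over many CpGs.

    Returns the per-CpG model at its optimal window, a performance table
    (cpg, optimal window, test R), and the raw sweeps. CpGs where every
    window fails are skipped with a log record.
    """
    if cpg_ids is None:
        cpg_ids = list(meth.cpgs["cpg_id"])
    models: dict[str, PredictionModel] = {}
    sweeps: dict[str, WindowSweepResult] = {}
    rows = []
    for i, cpg in enumerate(cpg_ids):
        sweep = sweep_windows(
            panel, meth, cpg,
            windows=windows, alpha=alpha,
            train_idx=train_idx, test_idx=test_idx,
            seed=seed + i, n_folds=n_folds,
        )
        sweeps[cpg] = sweep
        try:
            w_opt, r_opt = select_optimal_window(sweep)
        except ValueError:
            logger.info("CpG %s unmodellable at every window", cpg)
            continue
        models[cpg] = sweep.models[w_opt]
        rows.append((cpg, w_opt, r_opt))
    perf = pd.DataFrame(rows, columns=["cpg", "window", "test_R"])
    return models, perf, sweeps
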