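"""Window-local GRM construction and REML estimation of cis-heritability.

For each CpG the SNPs inside its optimal cis window form a genetic
relationship matrix (GRM)

    A_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

and the variance of methylation explained by those SNPs is estimated under
the linear mixed model  y = mu + g + e,  g ~ N(0, A sg2),  e ~ N(0, I se2)
by restricted maximum likelihood. Updates are average-information (AI) steps
with an EM fallback whenever an AI step would decrease the restricted
likelihood or leave the parameter space; variance components are kept
non-negative and the reported h2 = sg2 / (sg2 + se2) is restricted to [0, 1].

One eigendecomposition of A reduces every REML iteration to O(n) work, so
many response vectors can be fitted cheaply against the same GRM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import GenotypePanel, HeritabilityEstimate

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    """Genetic relationship matrix over ``m`` standardised SNPs."""

    matrix: np.ndarray
    m: int
    samples: list[str]

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, dtype=float)
        if A.shape[0] != A.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if not np.isfinite(A).all():
            raise ValueError("GRM contains non-finite entries")
        if self.m < 1:
            raise ValueError("GRM must be built from at least one SNP")
        self.matrix = A


def compute_grm(panel: GenotypePanel, variant_idx: np.ndarray | None = None) -> GRM:
    """Allele-frequency-standardised GRM from the given panel columns.

    Monomorphic variants (sample frequency 0 or 1) carry no information and
    are excluded with a log record; an all-monomorphic set is an error.
    """
    if variant_idx is None:
        variant_idx = np.arange(panel.n_variants)
    variant_idx = np.asarray(variant_idx, dtype=int)
    X = panel.dosages[:, variant_idx]
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        ids = panel.variants["variant_id"].to_numpy()[variant_idx[~poly]]
        logger.info("excluding %d monomorphic variant(s) from GRM: %s", n_mono, ids[:5])
    if not poly.any():
        raise ValueError("all variants monomorphic; cannot build GRM")
    Xp = X[:, poly]
    pp = p[poly]
    Z = (Xp - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    m = Z.shape[1]
    return GRM(matrix=(Z @ Z.T) / m, m=m, samples=list(panel.samples))


class _EigenLMM:
    """Single-GRM REML machinery in the eigenbasis of A (O(n) per iteration)."""

    def __init__(self, grm_matrix: np.ndarray, y: np.ndarray):
        d, U = np.linalg.eigh(grm_matrix)
        self.d = d
        self.yt = U.T @ y
        self.xt = U.T @ np.ones(len(y))
        self.n = len(y)

    def _pieces(self, sg: float, se: float):
        v = sg * self.d + se
        if (v <= 0).any():
            return None
        vinv = 1.0 / v
        xvx = float(np.sum(self.xt**2 * vinv))
        proj = float(np.sum(self.xt * self.yt * vinv)) / xvx
        py = self.yt * vinv - self.xt * vinv * proj
        return v, vinv, xvx, py

    def loglik(self, sg: float, se: float) -> float:
        pieces = self._pieces(sg, se)
        if pieces is None:
            return -np.inf
        v, vinv, xvx, py = pieces
        return -0.5 * (np.sum(np.log(v)) + np.log(xvx) + float(self.yt @ py))

    def _apply_p(self, z: np.ndarray, vinv: np.ndarray, xvx: float) -> np.ndarray:
        return z * vinv - self.xt * vinv * (float(np.sum(self.xt * z * vinv)) / xvx)

    def _tr_p(self, m_diag: np.ndarray, vinv: np.ndarray, xvx: float) -> float:
        return float(np.sum(m_diag * vinv) - np.sum(self.xt**2 * m_diag * vinv**2) / xvx)

    def score_and_ai(self, sg: float, se: float):
        v, vinv, xvx, py = self._pieces(sg, se)
        ug, ue = self.d * py, py
        ypdpy = float(py @ ug)
        ypipy = float(py @ ue)
        score = np.array(
            [
                -0.5 * (self._tr_p(self.d, vinv, xvx) - ypdpy),
                -0.5 * (self._tr_p(np.ones_like(self.d), vinv, xvx) - ypipy),
            ]
        )
        pug = self._apply_p(ug, vinv, xvx)
        pue = self._apply_p(ue, vinv, xvx)
        ai = 0.5 * np.array(
            [[float(ug @ pug), float(ug @ pue)], [float(ue @ pug), float(ue @ pue)]]
        )
        return score, ai, ypdpy, ypipy, vinv, xvx

    def em_step(self, sg: float, se: float) -> tuple[float, float]:
        _, _, ypdpy, ypipy, vinv, xvx = self.score_and_ai(sg, se)
        tr_pd = self._tr_p(self.d, vinv, xvx)
        tr_pi = self._tr_p(np.ones_like(self.d), vinv, xvx)
        sg_new = sg + sg**2 * (ypdpy - tr_pd) / self.n
        se_new = se + se**2 * (ypipy - tr_pi) / self.n
        return sg_new, se_new


def reml_h2(
    y: np.ndarray,
    grm: GRM | np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
    algorithm: str = "ai",
) -> HeritabilityEstimate:
    """REML cis-h2 of a response given a GRM.

    Parameters
    ----------
    y : array
        Response (e.g. one CpG's beta-values), sample order matching the GRM.
    grm : GRM or ndarray
    max_iter, tol : iteration cap and relative-change convergence tolerance
        on the variance components (GCTA-style defaults).
    algorithm : 'ai' (average information with EM fallback, default) or 'em'
        (pure EM, monotone in the restricted likelihood but slower).
    """
    A = grm.matrix if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != A.shape[0]:
        raise ValueError("response length does not match GRM order")
    vary = float(y.var(ddof=1))
    if vary == 0:
        raise ValueError("constant response: heritability undefined")
    lmm = _EigenLMM(A, y)
    floor = 1e-8 * vary

    sg = se = vary / 2.0
    ll = lmm.loglik(sg, se)
    if not np.isfinite(ll):
        raise ValueError("non-finite restricted likelihood at the starting point")
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        accepted = False
        if algorithm != "em" and it > 1:
            # AI step with step-halving; fall back to EM if no scale helps
            score, ai, *_ = lmm.score_and_ai(sg, se)
            try:
                step = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                step = None
            if step is not None:
                for t in range(8):
                    h = 0.5**t
                    sg_new = max(sg + h * step[0], floor)
                    se_new = max(se + h * step[1], floor)
                    ll_new = lmm.loglik(sg_new, se_new)
                    if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                        accepted = True
                        break
        if not accepted:
            sg_new, se_new = lmm.em_step(sg, se)
            sg_new = max(sg_new, floor)
            se_new = max(se_new, floor)
            ll_new = lmm.loglik(sg_new, se_new)
        delta = max(abs(sg_new - sg), abs(se_new - se))
        dll = ll_new - ll
        sg, se, ll = sg_new, se_new, ll_new
        if delta < tol * max(vary, 1e-12) and abs(dll) < 1e-6:
            converged = True
            break

    score, ai, *_ = lmm.score_and_ai(sg, se)
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(ai)
    total = sg + se
    h2 = min(max(sg / total, 0.0), 1.0)
    grad = np.array([se, -sg]) / total**2
    var_h2 = float(grad @ cov @ grad)
    se_h2 = float(np.sqrt(max(var_h2, 0.0)))
    sg_rep = 0.0 if sg <= floor else sg
    se_rep = 0.0 if se <= floor else se
    if sg_rep == 0.0:
        h2 = 0.0
    return HeritabilityEstimate(
        h2=h2, se=se_h2, sigma_g=sg_rep, sigma_e=se_rep,
        loglik=float(ll), iterations=it, converged=converged,
    )


class GremlReml:
    """Estimator-style wrapper: ``fit(A, y)`` stores the REML solution.

    Fitted attributes: ``h2_``, ``se_``, ``sigma_g_``, ``sigma_e_``,
    ``loglik_``, ``converged_``.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6, algorithm: str = "ai"):
        self.max_iter = max_iter
        self.tol = tol
        self.algorithm = algorithm

    def fit(self, A, y):
        est = reml_h2(y, A, max_iter=self.max_iter, tol=self.tol, algorithm=self.algorithm)
        self.h2_ = est.h2
        self.se_ = est.se
        self.sigma_g_ = est.sigma_g
        self.sigma_e_ = est.sigma_e
        self.loglik_ = est.loglik
        self.converged_ = est.converged
        self.estimate_ = est
        return self


def simulate_lmm_response(
    grm: GRM | np.ndarray, h2: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw y = g + e with var(g)/var(y) = h2 under the GRM's covariance.

    Used for parameter-recovery studies: the generative model is exactly the
    one REML fits, so nominal coverage of the 2-SE interval should hold.
    """
    A = grm.matrix if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
    n = A.shape[0]
    if h2 == 0:
        return rng.normal(size=n)
    d, U = np.linalg.eigh(A)
    d = np.clip(d, 0, None)
    g = U @ (np.sqrt(d) * rng.normal(size=n))
    return np.sqrt(h2) * g + np.sqrt(1 - h2) * rng.normal(size=n)
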