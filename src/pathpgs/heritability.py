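"""GRM construction, AI-REML variance components and the liability scale.

The model is y = Xb + sum_k g_k + e with g_k ~ N(0, sigma2_k A_k) for each
genetic relationship matrix A_k and e ~ N(0, sigma2_e I). Restricted maximum
likelihood is maximised by average-information updates with an EM fallback
step whenever an AI step leaves the feasible region. A binary phenotype is
analysed on the observed 0/1 scale and the variance fractions converted to
the liability scale with the prevalence-based threshold multiplier
K(1-K)/z(t)^2 (population-sample form; no case-control ascertainment
correction, appropriate when the cohort's own prevalence is used).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

log = logging.getLogger(__name__)

_VAR_FLOOR_FRACTION = 1e-6  # of phenotypic variance; boundary projection


class RemlError(RuntimeError):
    pass


@dataclass
class VarianceComponents:
    """REML variance decomposition with observed- and liability-scale h2."""

    names: list[str]
    variances: np.ndarray  # per component, residual last
    se: np.ndarray
    h2_observed: np.ndarray  # per GRM component: sigma2_k / sigma2_total
    h2_observed_se: np.ndarray
    prevalence: float | None = None
    h2_liability: np.ndarray | None = None
    h2_liability_se: np.ndarray | None = None
    converged: bool = False
    n_iter: int = 0
    loglik_trajectory: list[float] = field(default_factory=list)
    boundary: list[str] = field(default_factory=list)
    degenerate: bool = False

    @property
    def loglik(self) -> float:
        return self.loglik_trajectory[-1] if self.loglik_trajectory else np.nan

    @property
    def total_h2_observed(self) -> float:
        return float(self.h2_observed.sum())

    @property
    def total_h2_liability(self) -> float | None:
        return None if self.h2_liability is None else float(self.h2_liability.sum())


def build_grm(panel, snp_subset=None) -> np.ndarray:
    """Genetic relationship matrix A_jk = (1/m) sum_i w_ij w_ik with
    w_ij = (x_ij - 2 p_i) / sqrt(c_i), using sample allele frequencies.

    c_i = 2 p_i (1 - p_i) for diploid genotypes. For X-chromosome SNPs in an
    all-male panel (dosages {0, 2}) the scale is 4 p_i (1 - p_i), the
    full-dosage-compensation variant with unit expected diagonal, so the
    attributed variance is on the same footing as the autosomal component.
    Monomorphic SNPs (p in {0, 1}) are excluded and logged.
    """
    snps = list(panel.snp_ids if snp_subset is None else snp_subset)
    if not snps:
        raise ValueError("empty SNP subset")
    X = panel.dosage_of(snps)
    idx = panel.column_index(snps)
    chrom = panel.snp_meta["chr"].to_numpy()[idx]
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        log.info("build_grm: excluded %d monomorphic SNPs", int((~poly).sum()))
    X, p, chrom = X[:, poly], p[poly], chrom[poly]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic SNPs left for the GRM")
    all_male = bool(np.all(np.asarray(panel.sex) == 1))
    scale = 2.0 * p * (1.0 - p)
    is_x = chrom == "X"
    if all_male and is_x.any():
        scale = np.where(is_x, 4.0 * p * (1.0 - p), scale)
    W = (X - 2.0 * p) / np.sqrt(scale)
    A = W @ W.T / W.shape[1]
    return (A + A.T) / 2.0


def liability_transform(h2_observed: float | np.ndarray, prevalence: float) -> float | np.ndarray:
    """Observed-scale to liability-scale heritability, population sample:
    h2_liab = h2_obs * K(1-K) / z^2 with t = Phi^-1(1-K), z = phi(t)."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    return h2_observed * liability_multiplier(prevalence)


def liability_multiplier(prevalence: float) -> float:
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    t = stats.norm.ppf(1.0 - prevalence)
    z = stats.norm.pdf(t)
    return prevalence * (1.0 - prevalence) / (z * z)


def _design(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    keep = C.std(axis=0) > 0
    if not keep.all():
        log.warning("fit_aireml: dropping %d constant covariate columns", int((~keep).sum()))
        C = C[:, keep]
    return np.column_stack([np.ones(n), C])


def _he_start(y, X, grms, vp: float, floor: float) -> np.ndarray:
    """Haseman-Elston (method-of-moments) variance components: regress the
    cross-product matrix of OLS residuals on the GRMs and the identity."""
    K = len(grms)
    n = y.shape[0]
    Q, _ = np.linalg.qr(X)
    e = y - Q @ (Q.T @ y)
    S = np.outer(e, e)
    mats = [*grms, np.eye(n)]
    M = np.array([[float(np.sum(a * b)) for b in mats] for a in mats])
    rhs = np.array([float(np.sum(a * S)) for a in mats])
    try:
        est = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        return np.full(K + 1, vp / (K + 1))
    if not np.all(np.isfinite(est)) or np.linalg.cond(M) > 1e12:
        return np.full(K + 1, vp / (K + 1))
    return np.clip(est, max(floor, 0.01 * vp), vp)


def _dense_quantities(theta, y, X, mats):
    """REML loglik, gradient, AI matrix and EM ingredients for arbitrary
    (possibly >1) GRMs, via one explicit V inverse per iteration."""
    n, c = X.shape
    V = sum(t * A for t, A in zip(theta, mats))
    cf, info = linalg.lapack.dpotrf(V, lower=1)
    if info != 0:
        raise RemlError("V not positive definite")
    logdetV = 2.0 * np.log(np.diag(cf)).sum()
    vi, info = linalg.lapack.dpotri(cf, lower=1)
    if info != 0:
        raise RemlError("failed to invert V")
    Vi = vi + np.tril(vi, -1).T
    ViX = Vi @ X
    XtViX = X.T @ ViX
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise RemlError("X'V^-1X not positive definite")
    XtViX_inv = np.linalg.inv(XtViX)
    Viy = Vi @ y
    Py = Viy - ViX @ (XtViX_inv @ (ViX.T @ y))
    yPy = float(y @ Py)
    loglik = -0.5 * (logdetV + logdetX + yPy)

    K = len(mats)
    trPA = np.empty(K)
    APy = np.empty((n, K))
    for k, A in enumerate(mats):
        trVA = float(np.sum(Vi * A))  # tr(Vi A), both symmetric
        AViX = A @ ViX
        trPA[k] = trVA - float(np.sum(XtViX_inv * (ViX.T @ AViX)))
        APy[:, k] = A @ Py
    PAPy = Vi @ APy - ViX @ (XtViX_inv @ (ViX.T @ APy))
    grad = -0.5 * (trPA - (APy * Py[:, None]).sum(axis=0))
    AI = 0.5 * (APy.T @ PAPy)
    yPAPy = (APy * Py[:, None]).sum(axis=0)
    return loglik, grad, AI, trPA, yPAPy


def _eigen_quantities(theta, yt, Xt, lam):
    """Single-GRM fast path in the GRM eigenbasis: V is diagonal there."""
    n, c = Xt.shape
    d = theta[0] * lam + theta[1]
    di = 1.0 / d
    logdetV = float(np.log(d).sum())
    XtViX = Xt.T @ (di[:, None] * Xt)
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise RemlError("X'V^-1X not positive definite")
    XtViX_inv = np.linalg.inv(XtViX)
    Viy = di * yt
    Py = Viy - (di[:, None] * Xt) @ (XtViX_inv @ (Xt.T @ Viy))
    yPy = float(yt @ Py)
    loglik = -0.5 * (logdetV + logdetX + yPy)

    lam_mats = (lam, np.ones(n))
    trPA = np.empty(2)
    APy = np.empty((n, 2))
    for k, lk in enumerate(lam_mats):
        trVA = float((lk * di).sum())
        M = Xt * (lk * di)[:, None]
        trPA[k] = trVA - float(np.sum(XtViX_inv * (Xt.T @ (di[:, None] * M))))
        APy[:, k] = lk * Py
    PAPy = di[:, None] * APy - (di[:, None] * Xt) @ (XtViX_inv @ (Xt.T @ (di[:, None] * APy)))
    grad = -0.5 * (trPA - (APy * Py[:, None]).sum(axis=0))
    AI = 0.5 * (APy.T @ PAPy)
    yPAPy = (APy * Py[:, None]).sum(axis=0)
    return loglik, grad, AI, trPA, yPAPy


def fit_aireml(
    phenotype,
    covariates,
    grms: list[np.ndarray],
    prevalence: float | None = None,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> VarianceComponents:
    """Average-information REML for one or more GRMs plus residual.

    Starts from an equal split of the phenotypic variance; an AI step that
    leaves the feasible region falls back to an EM step; variances are
    projected onto [floor, +inf) and boundary hits reported. Convergence is
    declared at |delta log-lik| < ``tol``. Standard errors come from the
    inverse AI (information) matrix at the solution; a near-singular AI
    (e.g. a GRM indistinguishable from the identity) is reported via
    ``degenerate=True`` rather than silently.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")
    if not grms:
        raise ValueError("need at least one GRM")
    for A in grms:
        if A.shape != (n, n):
            raise ValueError("GRM dimensions do not match the phenotype")
    X = _design(n, covariates)
    K = len(grms)
    names = names or [f"grm{k + 1}" for k in range(K)]

    vp = float(np.var(y, ddof=1))
    floor = _VAR_FLOOR_FRACTION * vp
    # Haseman-Elston regression start (falls back to an equal split when the
    # HE system is ill-conditioned); a good start keeps AI steps feasible.
    theta = _he_start(y, X, grms, vp, floor)

    eigen_path = K == 1
    if eigen_path:
        lam, U = np.linalg.eigh(grms[0])
        lam = np.maximum(lam, 0.0)  # clip tiny negative eigenvalues of a PSD GRM
        yt, Xt = U.T @ y, U.T @ X
        quantities = lambda th: _eigen_quantities(th, yt, Xt, lam)
    else:
        mats = [*grms, np.eye(n)]
        quantities = lambda th: _dense_quantities(th, y, X, mats)

    trajectory: list[float] = []
    boundary: list[str] = []
    converged = False
    AI = np.eye(K + 1)
    it = 0
    prev_theta = theta.copy()
    for it in range(1, max_iter + 1):
        loglik, grad, AI, trPA, yPAPy = quantities(theta)
        if trajectory and loglik < trajectory[-1] - 1e-10:
            # AI step overshot: retreat to an EM step from the previous point
            theta = np.maximum(prev_theta + prev_theta**2 * (yPAPy_prev - trPA_prev) / n, floor)
            loglik, grad, AI, trPA, yPAPy = quantities(theta)
        trajectory.append(loglik)
        if len(trajectory) >= 2 and abs(trajectory[-1] - trajectory[-2]) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(AI, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(AI, grad, rcond=None)[0]
        prev_theta, trPA_prev, yPAPy_prev = theta.copy(), trPA, yPAPy
        theta = np.maximum(theta + step, floor)  # projected AI update
        boundary = [nm for nm, t in zip(names + ["residual"], theta) if t <= floor]
    else:
        log.warning("fit_aireml: no convergence after %d iterations", max_iter)

    try:
        AI_inv = np.linalg.inv(AI)
        degenerate = bool(np.linalg.cond(AI) > 1e10)
    except np.linalg.LinAlgError:
        AI_inv = np.linalg.pinv(AI)
        degenerate = True
    se = np.sqrt(np.maximum(np.diag(AI_inv), 0.0))

    total = theta.sum()
    h2 = theta[:K] / total
    # delta-method SE for the ratio sigma2_k / sigma2_total
    h2_se = np.empty(K)
    for k in range(K):
        grad_r = np.full(K + 1, -theta[k] / total**2)
        grad_r[k] += 1.0 / total
        h2_se[k] = np.sqrt(max(float(grad_r @ AI_inv @ grad_r), 0.0))

    vc = VarianceComponents(
        names=names + ["residual"],
        variances=theta.copy(),
        se=se,
        h2_observed=h2,
        h2_observed_se=h2_se,
        prevalence=prevalence,
        converged=converged,
        n_iter=it,
        loglik_trajectory=trajectory,
        boundary=boundary,
        degenerate=degenerate,
    )
    if prevalence is not None:
        mult = liability_multiplier(prevalence)
        vc.h2_liability = h2 * mult
        vc.h2_liability_se = h2_se * mult
    return vc


def reml_loglik(theta, phenotype, covariates, grms) -> float:
    """Restricted log-likelihood at a given variance parameter vector
    (components in GRM order, residual last). Used as an independent check
    of the AI-REML maximiser."""
    y = np.asarray(phenotype, dtype=float)
    X = _design(y.shape[0], covariates)
    mats = [*grms, np.eye(y.shape[0])]
    loglik, *_ = _dense_quantities(np.asarray(theta, float), y, X, mats)
    return loglik


def score_variance_explained(
    phenotype,
    covariates,
    grms: list[np.ndarray],
    score,
    prevalence: float | None = None,
) -> dict:
    """Decrease in GRM-attributed variance fraction when the polygenic score
    enters the fixed effects, on the observed and (if a prevalence is given)
    liability scales.

    Both fractions are expressed relative to the baseline (no-score) total
    phenotypic variance; projecting out the score shrinks the with-score
    model's own total, which would otherwise understate the decrease."""
    score = np.asarray(score, dtype=float)
    base = fit_aireml(phenotype, covariates, grms, prevalence=prevalence)
    if score.std() == 0:
        log.warning("score_variance_explained: constant score, decrease is zero")
        return {
            "observed": 0.0,
            "liability": 0.0 if prevalence is not None else None,
            "without_score": base,
            "with_score": base,
        }
    C = score[:, None] if covariates is None else np.column_stack([np.asarray(covariates, float), score])
    with_score = fit_aireml(phenotype, C, grms, prevalence=prevalence)
    K = len(grms)
    base_total_var = float(base.variances.sum())
    with_fraction = float(with_score.variances[:K].sum()) / base_total_var
    dec_obs = base.total_h2_observed - with_fraction
    out = {
        "observed": float(dec_obs),
        "liability": None,
        "without_score": base,
        "with_score": with_score,
    }
    if prevalence is not None:
        out["liability"] = float(dec_obs * liability_multiplier(prevalence))
    return out
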