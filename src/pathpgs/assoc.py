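"""Two-step per-SNP association, inverse-variance meta-analysis and genomic
control.

The discovery design mirrors large-biobank practice for a binary trait: a
fast vectorised linear (trend-test-equivalent) screen over all SNPs, then a
logistic refit of the SNPs passing an extraction threshold with the same
covariates. p-values are carried as natural-log values internally (column
``LOGP`` = ln p) so genome-wide signals survive floating-point underflow.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .panel import GenotypePanel

log = logging.getLogger(__name__)

#: extraction threshold at which screened SNPs advance to the logistic refit
SCREEN_REFIT_P = 1e-5

CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.454936...

STRAND_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class CollinearityError(ValueError):
    """Covariate or SNP columns are (near-)linearly dependent."""


def _check_covariates(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        return np.empty((n, 0))
    C = np.asarray(covariates, dtype=float)
    if C.shape[0] != n:
        raise ValueError("covariate rows do not align with the phenotype vector")
    names = list(covariates.columns) if isinstance(covariates, pd.DataFrame) else [
        f"c{i}" for i in range(C.shape[1])
    ]
    with_const = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(with_const)
    if rank < with_const.shape[1]:
        raise CollinearityError(f"collinear covariates among {names}")
    return C


def _logp_to_p(logp: np.ndarray) -> np.ndarray:
    return np.exp(np.maximum(logp, -745.0))  # underflow floor for the display column


def _assemble(meta: pd.DataFrame, beta, se, logp, n, cohort: str) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "SNP": meta["snp"].to_numpy(),
            "CHR": meta["chr"].to_numpy(),
            "BP": meta["pos"].to_numpy(),
            "A1": meta["a1"].to_numpy(),
            "A2": meta["a2"].to_numpy(),
            "BETA": beta,
            "SE": se,
            "P": _logp_to_p(np.asarray(logp)),
            "LOGP": logp,
            "N": n,
            "COHORT": cohort,
        }
    )
    return out


def run_screen(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    mac_min: int = 100,
    cohort: str = "discovery",
) -> pd.DataFrame:
    """Vectorised least-squares screen of phenotype on each SNP dosage plus
    covariates; equivalent to the Armitage trend test for a binary trait.

    SNPs with minor allele count below ``mac_min`` (default 100) or
    monomorphic SNPs are excluded (and logged).
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    if panel.n_individuals != n:
        raise ValueError("phenotype length does not match the panel")
    C = _check_covariates(covariates, n)

    X = panel.dosages
    mac = np.minimum(X.sum(axis=0), 2 * n - X.sum(axis=0))
    mono = X.std(axis=0) == 0
    keep = (mac >= mac_min) & ~mono
    dropped = int((~keep).sum())
    if dropped:
        log.info("run_screen: excluded %d SNPs (MAC < %d or monomorphic)", dropped, mac_min)

    # residualise phenotype and dosages on [1, C] once, then per-SNP OLS
    Q, _ = np.linalg.qr(np.column_stack([np.ones(n), C]))
    c = Q.shape[1]
    y_r = y - Q @ (Q.T @ y)
    G = X[:, keep]
    G_r = G - Q @ (Q.T @ G)
    gg = (G_r * G_r).sum(axis=0)
    gy = G_r.T @ y_r
    beta = gy / gg
    dof = n - c - 1
    rss = (y_r * y_r).sum() - beta * gy  # per-SNP residual sum of squares
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / gg)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf)
    logp = np.log(2.0) + stats.t.logsf(np.abs(tstat), dof)
    return _assemble(panel.snp_meta.iloc[keep.nonzero()[0]].reset_index(drop=True),
                     beta, se, logp, n, cohort)


def refit_logistic(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    snp_ids=None,
    cohort: str = "discovery",
    maxiter: int = 25,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-SNP additive logistic regression (IRLS) with Wald statistics.

    Separation and non-convergence are flagged in a ``FLAG`` column rather
    than silently dropped.
    """
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("refit_logistic requires a binary 0/1 phenotype")
    if y.min() == y.max():
        raise ValueError("phenotype has no variation (all cases or all controls)")
    n = y.shape[0]
    C = _check_covariates(covariates, n)
    if snp_ids is None:
        snp_ids = list(panel.snp_ids)
    cols = panel.column_index(snp_ids)

    rows = []
    base = np.column_stack([np.ones(n), C])
    for snp, j in zip(snp_ids, cols):
        x = panel.dosages[:, j]
        design = np.column_stack([base, x])
        flag = ""
        try:
            model = sm.GLM(y, design, family=sm.families.Binomial())
            res = model.fit(maxiter=maxiter, tol=tol)
            mu = res.fittedvalues
            if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
                flag = "separation"
            if not res.converged:
                flag = (flag + ";" if flag else "") + "nonconvergence"
            beta = res.params[-1]
            se = res.bse[-1]
            z = beta / se if se > 0 else np.inf
            logp = np.log(2.0) + stats.norm.logsf(abs(z))
        except Exception as exc:  # perfectly separated fits can raise
            beta, se, logp, flag = np.nan, np.nan, 0.0, f"failed:{type(exc).__name__}"
        rows.append((snp, beta, se, logp, flag))
    idx = panel.column_index(snp_ids)
    meta = panel.snp_meta.iloc[idx].reset_index(drop=True)
    out = _assemble(meta,
                    np.array([r[1] for r in rows]),
                    np.array([r[2] for r in rows]),
                    np.array([r[3] for r in rows]), n, cohort)
    out["FLAG"] = [r[4] for r in rows]
    return out


def two_step_scan(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    mac_min: int = 100,
    p_refit: float = SCREEN_REFIT_P,
    cohort: str = "discovery",
) -> pd.DataFrame:
    """Linear screen of every SNP, then logistic refit of SNPs with screen
    p below ``p_refit``; returns the screen table with refit columns
    substituted for the refitted SNPs."""
    screen = run_screen(panel, phenotype, covariates, mac_min=mac_min, cohort=cohort)
    selected = screen.loc[screen["P"] < p_refit, "SNP"].tolist()
    if not selected:
        return screen
    refit = refit_logistic(panel, phenotype, covariates, selected, cohort=cohort)
    merged = screen.set_index("SNP")
    refit_ok = refit[~refit["FLAG"].str.contains("failed", na=False)].set_index("SNP")
    merged.loc[refit_ok.index, ["BETA", "SE", "P", "LOGP"]] = refit_ok[
        ["BETA", "SE", "P", "LOGP"]
    ]
    return merged.reset_index()


def harmonise(stats_df: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Align effect alleles of ``stats_df`` with ``reference`` (keyed by SNP).

    A swapped (A1, A2) pair flips the sign of BETA; strand-ambiguous pairs
    (A/T, C/G) pass through with a warning; anything else is an error.
    """
    ref = reference.set_index("SNP")[["A1", "A2"]]
    out = stats_df.copy()
    mismatched = []
    for i, row in out.iterrows():
        if row["SNP"] not in ref.index:
            continue
        r = ref.loc[row["SNP"]]
        if (row["A1"], row["A2"]) == (r["A1"], r["A2"]):
            continue
        if (row["A1"], row["A2"]) in STRAND_AMBIGUOUS:
            # a swap cannot be told apart from a strand flip here
            log.warning("harmonise: strand-ambiguous SNP %s passed through", row["SNP"])
            continue
        if (row["A1"], row["A2"]) == (r["A2"], r["A1"]):
            out.loc[i, ["A1", "A2"]] = [r["A1"], r["A2"]]
            out.loc[i, "BETA"] = -row["BETA"]
            continue
        mismatched.append(row["SNP"])
    if mismatched:
        raise ValueError(f"allele mismatch not resolvable for SNPs: {mismatched}")
    return out


def meta_analyse(stats_list: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis across cohorts.

    beta = sum(w_i b_i) / sum(w_i), w_i = 1/se_i^2; se = sum(w_i)^(-1/2);
    two-sided normal p. Cohorts are harmonised to the first table's alleles.
    A single-cohort input is returned unchanged (identity).
    """
    if not stats_list:
        raise ValueError("need at least one cohort")
    if len(stats_list) == 1:
        return stats_list[0].copy()
    ref = stats_list[0]
    aligned = [ref] + [harmonise(df, ref) for df in stats_list[1:]]
    stacked = pd.concat(aligned, ignore_index=True)
    first = stacked.groupby("SNP", sort=False).first()

    def combine(grp: pd.DataFrame) -> pd.Series:
        w = 1.0 / grp["SE"] ** 2
        beta = float((w * grp["BETA"]).sum() / w.sum())
        se = float(w.sum() ** -0.5)
        z = beta / se
        logp = np.log(2.0) + stats.norm.logsf(abs(z))
        return pd.Series({"BETA": beta, "SE": se, "LOGP": logp, "N": grp["N"].sum()})

    meta = stacked.groupby("SNP", sort=False).apply(combine, include_groups=False)
    out = first[["CHR", "BP", "A1", "A2"]].join(meta).reset_index()
    out["P"] = _logp_to_p(out["LOGP"].to_numpy())
    out["COHORT"] = "meta"
    return out[["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "LOGP", "N", "COHORT"]]


def inflation_lambda(stats_df: pd.DataFrame) -> float:
    """Genomic-control inflation factor: median association chi-square over
    the null chi-square(1) median (0.4549...). Accepts a summary table (uses
    LOGP when available, else P) or a bare array of p-values."""
    if isinstance(stats_df, pd.DataFrame):
        if len(stats_df) == 0:
            raise ValueError("empty summary statistics")
        if "LOGP" in stats_df.columns:
            chi2 = stats.chi2.isf(np.exp(stats_df["LOGP"].to_numpy()), df=1)
        else:
            chi2 = stats.chi2.isf(stats_df["P"].to_numpy(), df=1)
    else:
        p = np.asarray(stats_df, dtype=float)
        if p.size == 0:
            raise ValueError("empty p-value vector")
        chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)
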