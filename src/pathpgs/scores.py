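"""Locus, overall and pathway-partitioned polygenic risk scores.

SNP weights come from one multivariable logistic regression over all
conditionally distinct SNPs jointly (plus covariates), not from the marginal
scan, so correlated signals at neighbouring SNPs are not double counted.
A locus score is the dosage-weighted sum over that locus's distinct SNPs;
the overall score is the sum of all locus scores; a pathway score is the sum
of the locus scores for the loci carrying the pathway's genes. Pathway
scores composed of identical locus sets are merged either for explicitly
named groups only, or for every identical group ("all-identical").

This partition is what exposes pathway-specific genetic correlations:
opposite-signed trait effects of two pathways cancel in the overall score
but remain visible in each pathway's own score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import CollinearityError
from .panel import GenotypePanel

log = logging.getLogger(__name__)


@dataclass
class PolygenicScoreSet:
    """Per-individual locus scores, the overall score and pathway scores."""

    locus_scores: pd.DataFrame  # individuals x locus columns ("locus<k>")
    weights: pd.Series  # SNP id -> joint beta
    locus_snps: dict[int, list[str]]  # locus id -> distinct SNPs in the score
    overall: pd.Series | None = None
    pathway_scores: pd.DataFrame | None = None
    pathway_loci: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def pathway_snp_count(self, pathway: str) -> int:
        return sum(len(self.locus_snps[l]) for l in self.pathway_loci[pathway])

    def validate(self, atol: float = 1e-9) -> None:
        if self.overall is not None:
            np.testing.assert_allclose(
                self.overall.to_numpy(), self.locus_scores.sum(axis=1).to_numpy(), atol=atol
            )
        if self.pathway_scores is not None:
            for name, loci in self.pathway_loci.items():
                expect = self.locus_scores[[f"locus{l}" for l in loci]].sum(axis=1)
                np.testing.assert_allclose(
                    self.pathway_scores[name].to_numpy(), expect.to_numpy(), atol=atol
                )


@dataclass
class TraitAssociationResult:
    score: str
    trait: str
    family: str
    effect: float
    se: float
    z: float
    p: float
    q: float | None = None


def reestimate_joint_betas(
    panel: GenotypePanel,
    phenotype,
    covariates,
    distinct_snps: list[str],
    maxiter: int = 50,
    tol: float = 1e-8,
) -> pd.Series:
    """Joint per-SNP log-odds from one logistic regression on all distinct
    SNPs simultaneously, with the covariates as nuisance terms."""
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    G = panel.dosage_of(distinct_snps)
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    design = np.column_stack([np.ones(n), C, G])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending SNP pair(s) via pairwise correlation
        corr = np.corrcoef(G.T)
        pairs = [
            (distinct_snps[i], distinct_snps[j])
            for i in range(len(distinct_snps))
            for j in range(i + 1, len(distinct_snps))
            if abs(corr[i, j]) > 0.999
        ]
        raise CollinearityError(f"collinear SNPs in joint model: {pairs or 'with covariates'}")
    res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=maxiter, tol=tol)
    mu = res.fittedvalues
    if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
        log.warning("reestimate_joint_betas: fitted probabilities at 0/1 (separation)")
    k = 1 + C.shape[1]
    return pd.Series(res.params[k:], index=distinct_snps, name="beta")


def compute_locus_scores(
    panel: GenotypePanel,
    weights: pd.Series,
    loci,
) -> PolygenicScoreSet:
    """Locus score per individual: sum over the locus's distinct SNPs of
    dosage x joint beta. Missing dosages are mean-imputed (logged)."""
    cols = {}
    locus_snps: dict[int, list[str]] = {}
    for locus in loci:
        snps = list(locus.distinct_snps)
        missing_w = [s for s in snps if s not in weights.index]
        if missing_w:
            raise KeyError(f"no weight for distinct SNPs {missing_w} of locus {locus.id}")
        G = panel.dosage_of(snps)
        if np.isnan(G).any():
            n_imputed = int(np.isnan(G).sum())
            col_means = np.nanmean(G, axis=0)
            G = np.where(np.isnan(G), col_means, G)
            log.info("compute_locus_scores: mean-imputed %d missing dosages", n_imputed)
        cols[f"locus{locus.id}"] = G @ weights.loc[snps].to_numpy()
        locus_snps[locus.id] = snps
    frame = pd.DataFrame(cols, index=pd.Index(panel.iids, name="iid"))
    return PolygenicScoreSet(locus_scores=frame, weights=weights, locus_snps=locus_snps)


def aggregate_scores(
    score_set: PolygenicScoreSet,
    pathway_table: dict[str, tuple[int, ...]] | pd.DataFrame,
    merge_rule: str = "explicit",
    explicit_merges: list[list[str]] | None = None,
) -> PolygenicScoreSet:
    """Add the overall score and named pathway scores to a locus score set.

    ``pathway_table`` maps pathway name -> member locus ids (or a DataFrame
    with columns ``pathway`` and ``loci``, the latter ";"-separated).
    ``merge_rule`` is "explicit" (merge only the groups in
    ``explicit_merges``, by name) or "all-identical" (merge every group of
    pathways with identical locus sets). Merged scores are named by
    concatenating the member names with " / ".
    """
    if isinstance(pathway_table, pd.DataFrame):
        mapping = {
            str(r["pathway"]): tuple(int(x) for x in str(r["loci"]).split(";"))
            for _, r in pathway_table.iterrows()
        }
    else:
        mapping = {k: tuple(v) for k, v in pathway_table.items()}
    known = set(score_set.locus_snps)
    for name, loci_ids in mapping.items():
        unknown = [l for l in loci_ids if l not in known]
        if unknown:
            raise KeyError(f"pathway {name!r} references unknown loci {unknown}")

    if merge_rule == "explicit":
        merged = _merge_named(mapping, explicit_merges or [])
    elif merge_rule == "all-identical":
        merged = _merge_identical(mapping)
    else:
        raise ValueError(f"unknown merge_rule {merge_rule!r}")

    frame = score_set.locus_scores
    pw_cols = {
        name: frame[[f"locus{l}" for l in loci_ids]].sum(axis=1)
        for name, loci_ids in merged.items()
    }
    score_set.overall = frame.sum(axis=1).rename("overall")
    score_set.pathway_scores = pd.DataFrame(pw_cols, index=frame.index)
    score_set.pathway_loci = merged
    return score_set


def _merge_named(mapping: dict[str, tuple[int, ...]], groups: list[list[str]]) -> dict[str, tuple[int, ...]]:
    out = dict(mapping)
    for group in groups:
        sets = {tuple(sorted(out[name])) for name in group}
        if len(sets) != 1:
            raise ValueError(f"cannot merge pathways with different locus sets: {group}")
        merged_name = " / ".join(group)
        loci_ids = out[group[0]]
        for name in group:
            del out[name]
        out[merged_name] = loci_ids
    return out


def _merge_identical(mapping: dict[str, tuple[int, ...]]) -> dict[str, tuple[int, ...]]:
    by_set: dict[tuple[int, ...], list[str]] = {}
    for name, loci_ids in mapping.items():
        by_set.setdefault(tuple(sorted(loci_ids)), []).append(name)
    out: dict[str, tuple[int, ...]] = {}
    for loci_ids, names in by_set.items():
        out[" / ".join(names)] = mapping[names[0]]
    return out


def associate_score_with_trait(
    score,
    trait,
    family: str,
    covariates=None,
    score_name: str = "score",
    trait_name: str = "trait",
) -> TraitAssociationResult:
    """Association of one score with one trait.

    family: "quantitative" -> linear regression; "binary" -> logistic;
    "parental-survival" -> Cox proportional hazards with ``trait`` a
    (time, status) two-column array/DataFrame.
    """
    s = np.asarray(score, dtype=float)
    n = s.shape[0]
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)

    if family == "parental-survival":
        tr = np.asarray(trait, dtype=float)
        if tr.ndim != 2 or tr.shape[1] != 2:
            raise ValueError("parental-survival requires (time, status) columns")
        if tr[:, 1].sum() == 0:
            raise ValueError("no events in survival trait")
        from lifelines import CoxPHFitter

        df = pd.DataFrame(C, columns=[f"c{i}" for i in range(C.shape[1])])
        df["score"] = s
        df["time"] = tr[:, 0]
        df["status"] = tr[:, 1]
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="status")
        eff = float(cph.params_["score"])
        se = float(cph.standard_errors_["score"])
    else:
        y = np.asarray(trait, dtype=float)
        if y.min() == y.max():
            raise ValueError("constant trait")
        design = np.column_stack([np.ones(n), C, s])
        if family == "binary":
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=50, tol=1e-8)
        elif family == "quantitative":
            res = sm.OLS(y, design).fit()
        else:
            raise ValueError(f"unknown trait family {family!r}")
        eff, se = float(res.params[-1]), float(res.bse[-1])

    z = eff / se if se > 0 else np.inf
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TraitAssociationResult(
        score=score_name, trait=trait_name, family=family, effect=eff, se=se, z=z, p=p
    )


def scan_scores_against_traits(
    scores: pd.DataFrame,
    traits: dict[str, tuple] ,
    covariates=None,
) -> pd.DataFrame:
    """All scores x all traits scan with Storey q-values over the whole scan.

    ``traits`` maps trait name -> (values, family).
    """
    results = []
    for trait_name, (values, family) in traits.items():
        for score_name in scores.columns:
            r = associate_score_with_trait(
                scores[score_name], values, family, covariates,
                score_name=score_name, trait_name=trait_name,
            )
            results.append(r)
    table = pd.DataFrame([r.__dict__ for r in results])
    table["q"] = storey_qvalues(table["p"].to_numpy())
    return table


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's null-proportion estimate via the cubic smoother over a lambda
    grid (0.05..0.95), falling back to the fixed lambda = 0.5 estimate for
    small m (< 100)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m < 100:
        pi0 = (p > 0.5).sum() / (m * 0.5)
        return float(min(max(pi0, 0.0), 1.0)) or 1.0 / m
    lambdas = np.arange(0.05, 0.96, 0.05) if lambdas is None else lambdas
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_lam, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    return min(max(pi0, 1.0 / m), 1.0)


def storey_qvalues(p, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: q_(i) = min_{j >= i} pi0 * m * p_(j) / j on the
    sorted scale, mapped back to the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
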