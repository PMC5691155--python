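"""Independent oracle implementations used only by the tests.

Each oracle re-derives an expected result by brute force or a closed form,
deliberately avoiding the package's own code paths.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def single_linkage_loci(positions: np.ndarray, gap: int) -> list[list[int]]:
    """Exhaustive pairwise single-linkage clustering of positions on one
    chromosome: indices i, j belong together iff a chain of points with
    consecutive gaps <= gap connects them."""
    order = np.argsort(positions)
    clusters: list[list[int]] = []
    current = [int(order[0])]
    for a, b in zip(order[:-1], order[1:]):
        if positions[b] - positions[a] > gap:
            clusters.append(current)
            current = [int(b)]
        else:
            current.append(int(b))
    clusters.append(current)
    return clusters


def ols_slope_se(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple-regression slope and SE via normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    beta = float(xc @ yc / (xc @ xc))
    resid = yc - beta * xc
    sigma2 = float(resid @ resid) / (n - 2)
    se = float(np.sqrt(sigma2 / (xc @ xc)))
    return beta, se


def newton_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
    """Plain Newton-Raphson maximum-likelihood logistic regression."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def inverse_variance_meta(betas, ses) -> tuple[float, float]:
    w = 1.0 / np.asarray(ses, float) ** 2
    beta = float(np.sum(w * np.asarray(betas, float)) / np.sum(w))
    return beta, float(np.sum(w) ** -0.5)


def grm_entry(X: np.ndarray, j: int, k: int) -> float:
    """Element-wise GRM formula on raw diploid dosages."""
    p = X.mean(axis=0) / 2.0
    terms = (X[j] - 2 * p) * (X[k] - 2 * p) / (2 * p * (1 - p))
    return float(terms.mean())


def reml_loglik_direct(theta, y, X, grms) -> float:
    """Restricted log-likelihood from its definition, straight numpy."""
    n = y.shape[0]
    V = theta[-1] * np.eye(n)
    for t, A in zip(theta[:-1], grms):
        V = V + t * A
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return float(-0.5 * (ldV + ldX + y @ P @ y))


def exhaustive_conditional_sets(G: np.ndarray, y: np.ndarray, p_gw: float) -> set[int]:
    """All-subsets conditional search on a tiny SNP set: the largest subset
    in which every SNP stays significant conditional on the others."""
    m = G.shape[1]
    n = G.shape[0]
    best: tuple[int, ...] = ()
    for size in range(1, m + 1):
        for subset in itertools.combinations(range(m), size):
            ok = True
            for j in subset:
                others = [k for k in subset if k != j]
                design = np.column_stack([np.ones(n)] + [G[:, k] for k in others])
                Q, _ = np.linalg.qr(design)
                y_r = y - Q @ (Q.T @ y)
                x_r = G[:, j] - Q @ (Q.T @ G[:, j])
                beta = x_r @ y_r / (x_r @ x_r)
                resid = y_r - beta * x_r
                dof = n - design.shape[1] - 1
                se = np.sqrt((resid @ resid) / dof / (x_r @ x_r))
                p = 2 * stats.t.sf(abs(beta / se), dof)
                if p >= p_gw:
                    ok = False
                    break
            if ok and size > len(best):
                best = subset
    return set(best)


def stepdown_qvalues(p: np.ndarray, pi0: float = 1.0) -> np.ndarray:
    """Brute-force q-values: for each sorted index take the minimum of
    pi0*m*p_j/j over all j at or after it."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        vals = [pi0 * m * p[order[j - 1]] / j for j in range(rank_i, m + 1)]
        q[idx] = min(min(vals), 1.0)
    return q


def gap_scan_regions(positions, pvals, p_seed, p_extend, gap) -> list[tuple[int, int]]:
    """Brute-force region scan: runs of extension SNPs split at gaps >= gap,
    kept only when a seed SNP is inside."""
    pts = sorted((pos, pv) for pos, pv in zip(positions, pvals) if pv < p_extend)
    regions, cur = [], []
    for pos, pv in pts:
        if cur and pos - cur[-1][0] >= gap:
            regions.append(cur)
            cur = []
        cur.append((pos, pv))
    if cur:
        regions.append(cur)
    out = []
    for reg in regions:
        if any(pv < p_seed for _, pv in reg):
            out.append((reg[0][0], reg[-1][0]))
    return out


def igraph_modularity(nx_graph, partition) -> float:
    """Weighted modularity computed by python-igraph on the same partition."""
    import igraph as ig

    nodes = list(nx_graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in nx_graph.edges]
    weights = [nx_graph[a][b].get("weight", 1) for a, b in nx_graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    membership = np.empty(len(nodes), dtype=int)
    for c, comm in enumerate(partition):
        for v in comm:
            membership[index[v]] = c
    return float(g.modularity(membership.tolist(), weights=weights))
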