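"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — enumeration, dense linear algebra,
hand-rolled Newton iterations — and shares no code path with the package.
"""

from __future__ import annotations

import itertools
from math import comb, log

import numpy as np


def brute_force_betweenness(n_nodes: int, edges: list[tuple[int, int]]
                            ) -> np.ndarray:
    """Betweenness by exhaustive simple-path enumeration (DFS), n_nodes <= ~8."""
    adj = {v: set() for v in range(n_nodes)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)

    def all_paths(s: int, t: int) -> list[tuple[int, ...]]:
        paths, stack = [], [(s, (s,))]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for u in adj[v]:
                if u not in path:
                    stack.append((u, path + (u,)))
        return paths

    bc = np.zeros(n_nodes)
    for s, t in itertools.combinations(range(n_nodes), 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for v in range(n_nodes):
            if v in (s, t):
                continue
            bc[v] += sum(v in p for p in sp) / len(sp)
    return bc


def pairwise_concordance_auc(scores, labels, positive) -> float:
    """AUC as the exhaustive count of concordant case/control pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == positive]
    controls = scores[labels != positive]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


def newton_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12,
                    max_iter: int = 200) -> np.ndarray:
    """Plain Newton-Raphson MLE of a logistic regression (intercept included
    by the caller in X)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = (X * W[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


def residual_partial_correlation(X: np.ndarray, i: int, j: int) -> float:
    """pcor(i, j | rest) as the correlation of least-squares residuals."""
    rest = [k for k in range(X.shape[1]) if k not in (i, j)]
    Z = np.column_stack([np.ones(X.shape[0]), X[:, rest]])
    ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
    rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
    return float(np.corrcoef(ri, rj)[0, 1])


def hypergeom_tail_enumeration(hits: int, n_background: int, class_size: int,
                               n_selected: int) -> float:
    """P(overlap >= hits) by summing the exact hypergeometric pmf."""
    total = comb(n_background, n_selected)
    p = 0.0
    for k in range(hits, min(class_size, n_selected) + 1):
        if n_selected - k > n_background - class_size:
            continue
        p += comb(class_size, k) * comb(n_background - class_size,
                                        n_selected - k) / total
    return p


def hwe_enumeration_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact HWE test by direct evaluation of the conditional distribution
    P(het = h | n, allele counts) = n! 2^h / (homr! h! homc!) / C(2n, rare)."""
    from math import lgamma, exp

    n = n_het + n_hom1 + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het

    def logpmf(h: int) -> float:
        homr = (rare - h) // 2
        homc = n - h - homr
        return (lgamma(n + 1) + h * log(2.0) - lgamma(homr + 1)
                - lgamma(h + 1) - lgamma(homc + 1)
                - (lgamma(2 * n + 1) - lgamma(rare + 1)
                   - lgamma(2 * n - rare + 1)))

    hs = [h for h in range(rare % 2, rare + 1, 2)
          if (rare - h) // 2 >= 0 and n - h - (rare - h) // 2 >= 0]
    pmf = {h: exp(logpmf(h)) for h in hs}
    total = sum(pmf.values())
    p_obs = pmf[n_het] / total
    return min(1.0, sum(v for v in pmf.values()
                        if v / total <= p_obs * (1 + 1e-12)) / total)


def mann_whitney_enumeration_p(x, y) -> float:
    """Two-sided Mann-Whitney p by enumerating all group labelings."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)

    def u_stat(group1_idx: tuple[int, ...]) -> float:
        g1 = [pooled[i] for i in group1_idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in group1_idx]
        u = 0.0
        for a in g1:
            for b in g2:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    observed = u_stat(tuple(range(n1)))
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(u_stat(idx) - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


def pls1_scores(X: np.ndarray, y_pm: np.ndarray) -> np.ndarray:
    """Predictive scores of a one-component PLS1 fit on centered data."""
    Xc = X - X.mean(axis=0)
    yc = y_pm - y_pm.mean()
    w = Xc.T @ yc
    w = w / np.linalg.norm(w)
    return Xc @ w
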