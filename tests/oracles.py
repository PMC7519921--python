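"""Independent reference implementations used as test oracles.

These are deliberately written in plain scalar/loop style, straight from the
textbook equations, and share no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def wc_components_brute(genotypes_per_pop: list[np.ndarray]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) a, b, c for one biallelic site.

    ``genotypes_per_pop`` holds one integer dosage array (0/1/2, missing
    entries removed beforehand) per population.  Scalar arithmetic only.
    """
    r = len(genotypes_per_pop)
    n = [len(g) for g in genotypes_per_pop]
    if any(ni == 0 for ni in n):
        raise ValueError("empty population")
    p = [sum(int(x) for x in g) / (2.0 * ni) for g, ni in zip(genotypes_per_pop, n)]
    h = [sum(1 for x in g if x == 1) / ni for g, ni in zip(genotypes_per_pop, n)]

    n_total = sum(n)
    n_bar = n_total / r
    n_c = (n_total - sum(ni * ni for ni in n) / n_total) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / n_total
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / n_total

    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1.0))
        * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def weighted_fst_brute(genotype_matrix: np.ndarray, pop_sizes: tuple[int, int],
                       missing: int = -1) -> float:
    """Ratio-of-sums Weir-Cockerham F_st over all defined sites of a matrix."""
    n1, _ = pop_sizes
    num = den = 0.0
    for row in genotype_matrix:
        groups = []
        for g in (row[:n1], row[n1:]):
            g = g[g != missing]
            if g.size == 0:
                break
            groups.append(g)
        else:
            a, b, c = wc_components_brute(groups)
            if a + b + c != 0.0:
                num += a
                den += a + b + c
    return num / den


def dense_pls_nipals(X: np.ndarray, y: np.ndarray, n_components: int,
                     scale: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Dense univariate-response PLS via power-method NIPALS.

    Columns centered (and unit-variance scaled); per component the weight is
    found by iterating w <- X^T y t / |..| to convergence (for univariate y
    this converges in one step but the loop form keeps the oracle generic);
    deflation is regression-mode on both X and y.  Returns (loadings, scores).
    """
    X = X.astype(float).copy()
    X -= X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X /= sd
    y = y.astype(float).copy()
    y -= y.mean()
    n, p = X.shape
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    for hcomp in range(n_components):
        u = y.copy()
        w = np.zeros(p)
        for _ in range(500):
            w_new = X.T @ u
            w_new /= np.linalg.norm(w_new)
            t = X @ w_new
            u = y * (y @ t) / (y @ y)
            if np.linalg.norm(w_new - w) < 1e-12:
                w = w_new
                break
            w = w_new
        # sign: largest-|entry| coordinate positive
        piv = int(np.argmax(np.abs(w)))
        if w[piv] < 0:
            w = -w
        t = X @ w
        X -= np.outer(t, t @ X) / (t @ t)
        y = y - t * (t @ y) / (t @ t)
        W[:, hcomp] = w
        T[:, hcomp] = t
    return W, T


def anova_oneway_brute(groups: list[np.ndarray]) -> tuple[float, float]:
    """Textbook one-way ANOVA arithmetic with p from scipy's F distribution."""
    from scipy.stats import f as f_dist

    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    k = len(groups)
    n = all_vals.size
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    F = msb / msw
    return F, float(f_dist.sf(F, k - 1, n - k))
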