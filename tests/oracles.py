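"""Independent brute-force reference implementations used only by tests.

Everything here is written scalar-style, straight from the defining
formulas, with no shared code paths with the package (which is vectorised
throughout). These functions are deliberately slow.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def informativeness_bruteforce(p_by_pop: list[float]) -> float:
    """Rosenberg informativeness for one biallelic SNP, term by term.

    ``p_by_pop`` holds the alternate-allele frequency in each of K
    populations; the reference-allele terms are included explicitly.
    """
    K = len(p_by_pop)
    total = 0.0
    for allele_freqs in (p_by_pop, [1.0 - p for p in p_by_pop]):
        p_mean = sum(allele_freqs) / K
        term = 0.0
        if p_mean > 0:
            term -= p_mean * math.log(p_mean)
        for p_i in allele_freqs:
            if p_i > 0:
                term += (p_i / K) * math.log(p_i)
        total += term
    return total


def wc_theta_bruteforce(genotype_lists: list[list[int]]) -> float:
    """Weir & Cockerham (1984) per-locus theta-hat from raw genotype lists.

    One list of {0,1,2} genotypes per population (missing already removed).
    Returns NaN when a + b + c = 0.
    """
    r = len(genotype_lists)
    n = [len(g) for g in genotype_lists]
    p = [sum(g) / (2 * len(g)) for g in genotype_lists]
    h = [sum(1 for x in g if x == 1) / len(g) for g in genotype_lists]

    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(ni * ni for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")


def binomial_loglik_bruteforce(genotypes: np.ndarray, freqs: np.ndarray) -> float:
    """Direct binomial log-likelihood: one frequency per SNP, K=1 case."""
    total = 0.0
    n, m = genotypes.shape
    for i in range(n):
        for l in range(m):
            g = genotypes[i, l]
            if g < 0:
                continue
            f = min(max(freqs[l], 1e-6), 1 - 1e-6)
            total += g * math.log(f) + (2 - g) * math.log(1 - f)
    return total


def best_alignment_bruteforce(q_ref: np.ndarray, q_test: np.ndarray) -> tuple[tuple[int, ...], float]:
    """Exhaustive search over all K! column permutations of q_test."""
    K = q_ref.shape[1]
    best_perm, best_cost = None, float("inf")
    for perm in itertools.permutations(range(K)):
        cost = float(((q_ref - q_test[:, list(perm)]) ** 2).sum())
        if cost < best_cost:
            best_perm, best_cost = perm, cost
    return best_perm, best_cost


def consensus_tally_bruteforce(universe: list[str], panels: list[list[str]], min_methods: int) -> set[str]:
    """Per-SNP membership count over panels, thresholded."""
    out = set()
    for sid in universe:
        count = sum(1 for panel in panels if sid in panel)
        if count >= min_methods:
            out.add(sid)
    return out


def pca_eigh_bruteforce(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PC coordinates, SNP loadings, eigenvalues via the SNP-SNP Gram route.

    Eigendecomposition of X^T X gives loadings directly; coordinates follow
    as X V. Returned sorted by decreasing eigenvalue.
    """
    gram = X.T @ X
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    loadings = eigvecs[:, order]
    coords = X @ loadings
    return coords, loadings, eigvals
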