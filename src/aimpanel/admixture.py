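"""Unsupervised admixture model: Q/P factorisation of genotype likelihood.

The model: individual i carries ancestry proportions q_i (a point on the
K-simplex) and cluster k has alternate-allele frequency p_kl at SNP l.
Genotypes are binomial, g_il ~ Bin(2, f_il) with f_il = sum_k q_ik p_kl.
Missing genotypes contribute nothing to the likelihood.

Fitting uses plain EM (the classic STRUCTURE/frappe updates). This reaches
the same stationary points as the quasi-Newton block relaxation of the
fast reference tool, just in more iterations — a deliberate trade of speed
for verifiability at desk scale: every accepted iteration provably does
not decrease the log-likelihood, which the test-suite asserts on every fit.

Label switching between independent fits is resolved by
:func:`align_components`, a minimum-squared-error assignment between the
columns of two Q matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genotype_io import MISSING, GenotypeMatrix, PMatrix, QMatrix


@dataclass
class AdmixtureFit:
    """Result of one admixture EM fit (the best of the seeded restarts)."""

    Q: QMatrix
    P: PMatrix
    K: int
    log_likelihood_trace: list[float]
    n_iterations: int
    seed: int
    converged: bool

    @property
    def log_likelihood(self) -> float:
        return self.log_likelihood_trace[-1]


@dataclass
class ComponentAlignment:
    """Column permutation mapping a test Q onto a reference Q."""

    permutation: tuple[int, ...]
    cost: float

    def __post_init__(self) -> None:
        if sorted(self.permutation) != list(range(len(self.permutation))):
            raise ValueError("alignment permutation must be a bijection of 0..K-1")

    def apply(self, Q: np.ndarray) -> np.ndarray:
        """Reorder the columns of ``Q`` to match the reference ordering."""
        return np.asarray(Q)[:, list(self.permutation)]


def _as_q_array(Q) -> np.ndarray:
    return Q.proportions if isinstance(Q, QMatrix) else np.asarray(Q, dtype=float)


def _as_p_array(P) -> np.ndarray:
    return P.frequencies if isinstance(P, PMatrix) else np.asarray(P, dtype=float)


def loglikelihood(G: GenotypeMatrix, Q, P, eps: float = 1e-6) -> float:
    """Binomial admixture log-likelihood of (Q, P) for the observed genotypes.

    ``sum over non-missing (i,l) of g ln f + (2-g) ln(1-f)`` with
    f = Q P^T clipped to [eps, 1-eps] so a discordant fixed frequency
    yields a very negative number rather than -inf or NaN.
    """
    q = _as_q_array(Q)
    p = _as_p_array(P)
    if q.shape[1] != p.shape[1]:
        raise ValueError("Q and P disagree on K")
    if q.shape[0] != G.n_individuals or p.shape[0] != G.n_snps:
        raise ValueError("Q/P dimensions do not match the genotype matrix")
    obs = G.genotypes != MISSING
    g = G.genotypes.astype(float)
    g[~obs] = 0.0
    f = np.clip(q @ p.T, eps, 1.0 - eps)
    ll = obs * (g * np.log(f) + (2.0 - g) * np.log1p(-f))
    return float(ll.sum())


def _em_run(
    g: np.ndarray,
    obs: np.ndarray,
    K: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    eps: float,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """One EM run from a random start; returns (Q, P, trace, converged)."""
    n, m = g.shape
    q = rng.dirichlet(np.ones(K), size=n)
    p = rng.uniform(0.05, 0.95, size=(m, K))

    calls_per_ind = np.maximum(2.0 * obs.sum(axis=1, keepdims=True), 1e-12)  # diploid alleles observed
    g_obs = np.where(obs, g, 0.0)
    two_minus_g = np.where(obs, 2.0 - g, 0.0)

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        f = np.clip(q @ p.T, eps, 1.0 - eps)
        ll = float((g_obs * np.log(f) + two_minus_g * np.log1p(-f)).sum())
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * (abs(trace[-2]) + 1.0):
            converged = True
            break

        # E-step responsibilities folded into multiplicative updates:
        #   R_il = g_il / f_il (alt-allele "pressure"), S_il analogous for ref.
        R = g_obs / f
        S = two_minus_g / (1.0 - f)
        # Q update: q_ik <- q_ik * sum_l [R p_lk + S (1-p_lk)] / (2 m_i)
        q = q * (R @ p + S @ (1.0 - p)) / calls_per_ind
        q /= q.sum(axis=1, keepdims=True)  # guard drift from clipping
        # P update: p_lk <- A_lk / (A_lk + B_lk), expected alt/ref counts.
        A = (R.T @ q) * p
        B = (S.T @ q) * (1.0 - p)
        p = A / np.maximum(A + B, 1e-300)
        p = np.clip(p, eps, 1.0 - eps)
    return q, p, trace, converged


def fit_admixture(
    G: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 3,
    eps: float = 1e-6,
) -> AdmixtureFit:
    """Maximum-likelihood admixture fit by EM with seeded random restarts.

    Runs ``n_restarts`` EM chains from independent Dirichlet(1) Q and
    Uniform(0.05, 0.95) P starts (all randomness derived from ``seed``)
    and keeps the chain with the best final log-likelihood. ``tol`` is a
    relative change threshold on the log-likelihood. Identical inputs and
    seed give a bit-identical fit.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > G.n_individuals:
        raise ValueError(f"K={K} exceeds the {G.n_individuals} individuals")
    obs = G.genotypes != MISSING
    g = G.genotypes.astype(float)

    if K == 1:
        # Closed form: Q is all ones; P is the pooled observed frequency.
        n_obs = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled = np.where(n_obs > 0, np.where(obs, g, 0.0).sum(axis=0) / (2 * n_obs), 0.5)
        Q = QMatrix(list(G.individual_ids), np.ones((G.n_individuals, 1)))
        P = PMatrix(list(G.snp_ids), pooled.reshape(-1, 1))
        ll = loglikelihood(G, Q, P, eps=eps)
        return AdmixtureFit(Q, P, 1, [ll], 1, seed, True)

    best: tuple | None = None
    for child_seed in np.random.SeedSequence(seed).spawn(n_restarts):
        rng = np.random.Generator(np.random.PCG64(child_seed))
        q, p, trace, converged = _em_run(g, obs, K, rng, tol, max_iter, eps)
        if best is None or trace[-1] > best[2][-1]:
            best = (q, p, trace, converged)
    q, p, trace, converged = best
    if not converged:
        warnings.warn(
            f"admixture EM did not converge in {max_iter} iterations "
            f"(last relative change above tol={tol})",
            RuntimeWarning,
        )
    return AdmixtureFit(
        Q=QMatrix(list(G.individual_ids), q),
        P=PMatrix(list(G.snp_ids), np.clip(p, 0.0, 1.0)),
        K=K,
        log_likelihood_trace=trace,
        n_iterations=len(trace),
        seed=seed,
        converged=converged,
    )


def align_components(Q_ref, Q_test) -> ComponentAlignment:
    """Resolve label switching between two Q matrices on the same individuals.

    Finds the permutation pi of the test columns minimising
    sum_k ||Q_ref[:, k] - Q_test[:, pi(k)]||^2 by optimal assignment.
    """
    qr = _as_q_array(Q_ref)
    qt = _as_q_array(Q_test)
    if qr.shape != qt.shape:
        raise ValueError(f"Q shape mismatch: {qr.shape} vs {qt.shape}")
    K = qr.shape[1]
    cost = np.empty((K, K))
    for a in range(K):
        cost[a] = ((qr[:, [a]] - qt) ** 2).sum(axis=0)
    rows, cols = linear_sum_assignment(cost)
    perm = tuple(int(cols[np.where(rows == k)[0][0]]) for k in range(K))
    return ComponentAlignment(permutation=perm, cost=float(cost[rows, cols].sum()))
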