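"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (direct
summation, explicit enumeration, textbook formulas) and never calls into the
package's own fitting/optimisation code paths.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def naive_binomial_loglik(beta0: float, beta, X, N) -> float:
    """Term-by-term log-likelihood: log C(2,N) + N log p + (2-N) log(1-p)."""
    total = 0.0
    for xi, ni in zip(np.atleast_2d(X), N):
        eta = beta0 + sum(b * x for b, x in zip(np.atleast_1d(beta), xi))
        p = 1.0 / (1.0 + math.exp(-eta))
        total += (
            math.log(math.comb(2, int(ni)))
            + ni * math.log(p)
            + (2 - ni) * math.log(1.0 - p)
        )
    return total


def _grid_loglik(B0, B, X, N):
    """Vectorised textbook log-likelihood over a flat parameter grid.

    B0: (G,) intercepts; B: (G, k) slopes; returns (G,) log-likelihoods.
    """
    eta = B0[:, None] + B @ X.T          # (G, n)
    # p = sigmoid(eta); use stable log p / log(1-p)
    logp = -np.logaddexp(0.0, -eta)
    log1mp = -np.logaddexp(0.0, eta)
    const = sum(math.log(math.comb(2, int(v))) for v in N)
    return (N[None, :] * logp + (2.0 - N[None, :]) * log1mp).sum(axis=1) + const


def grid_search_mle(X, N, lo: float = -4.0, hi: float = 4.0,
                    coarse: float = 0.2, fine: float = 0.005,
                    ) -> np.ndarray:
    """Two-stage exhaustive grid maximiser of the binomial log-likelihood.

    Stage 1 scans [lo, hi] at ``coarse`` spacing in every coordinate; stage 2
    rescans +-(coarse + fine) around the stage-1 argmax at ``fine`` spacing.
    Asserts the optimum is interior to the stage-1 box.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = np.asarray(N, dtype=float)
    k = X.shape[1]

    axes = [np.arange(lo, hi + coarse / 2, coarse)] * (k + 1)
    mesh = np.meshgrid(*axes, indexing="ij")
    flat = np.column_stack([m.ravel() for m in mesh])
    ll = _grid_loglik(flat[:, 0], flat[:, 1:], X, N)
    best = flat[np.argmax(ll)]
    assert np.all(np.abs(best) < hi - coarse), "grid optimum on the boundary"

    half = coarse + fine
    axes = [np.arange(b - half, b + half + fine / 2, fine) for b in best]
    mesh = np.meshgrid(*axes, indexing="ij")
    flat = np.column_stack([m.ravel() for m in mesh])
    ll = _grid_loglik(flat[:, 0], flat[:, 1:], X, N)
    return flat[np.argmax(ll)]


def grid_search_null_beta0(N, lo: float = -10.0, hi: float = 10.0,
                           step: float = 1e-4) -> float:
    """1-D grid maximiser of the intercept-only log-likelihood."""
    N = np.asarray(N, dtype=float)
    grid = np.arange(lo, hi + step / 2, step)
    ll = _grid_loglik(grid, np.zeros((grid.size, 0)), np.zeros((N.size, 0)), N)
    return float(grid[np.argmax(ll)])


def hwe_exact_enumeration(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact HWE p-value by full enumeration with rational arithmetic.

    Conditional probability of h heterozygotes given allele counts
    (n_a, n_b) in n individuals:
        P(h) = 2^h n! / (h! n_aa! n_bb!) * n_a! n_b! / (2n)!
    Feasible only for small totals (the oracle's use case).
    """
    n = n_hom_major + n_het + n_hom_minor
    n_minor = 2 * n_hom_minor + n_het
    probs = {}
    for h in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        num = (
            Fraction(2) ** h
            * math.factorial(n)
            * math.factorial(n_minor)
            * math.factorial(2 * n - n_minor)
        )
        den = (
            math.factorial(h)
            * math.factorial(hom_minor)
            * math.factorial(hom_major)
            * math.factorial(2 * n)
        )
        probs[h] = Fraction(num, den)
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def naive_bh(pvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Literal Benjamini-Hochberg step-up at rate 0.05.

    Returns (qvalues, reject) in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    M = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    q_sorted = np.empty(M)
    running = 1.0
    for i in range(M - 1, -1, -1):
        running = min(running, M * sorted_p[i] / (i + 1))
        q_sorted[i] = running
    # largest i with p_(i) <= i * alpha / M; reject all p-values up to it
    alpha = 0.05
    reject_sorted = np.zeros(M, dtype=bool)
    threshold_idx = -1
    for i in range(M):
        if sorted_p[i] <= (i + 1) * alpha / M:
            threshold_idx = i
    if threshold_idx >= 0:
        reject_sorted[: threshold_idx + 1] = True
    q = np.empty(M)
    reject = np.empty(M, dtype=bool)
    q[order] = q_sorted
    reject[order] = reject_sorted
    return q, reject


def ols_residuals_normal_equations(y: np.ndarray, covariates: np.ndarray,
                                   ) -> np.ndarray:
    """OLS residuals via explicitly solved normal equations (with intercept)."""
    A = np.column_stack([np.ones(len(y)), covariates])
    beta = np.linalg.inv(A.T @ A) @ (A.T @ y)
    return y - A @ beta
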