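"""Binomial reverse regression of minor-allele count on a phenotype vector.

The genotype at a biallelic SNP, coded as the number of copies of the minor
allele N in {0, 1, 2}, is modelled conditionally on a k-dimensional phenotype
vector X as

    N | X  ~  Binomial(2, p(X)),        logit p(X) = beta0 + sum_j beta_j X_j.

Association between the SNP and the multivariate phenotype is tested with the
likelihood-ratio statistic for H0: beta_1 = ... = beta_k = 0, which is
asymptotically chi-square with k degrees of freedom under the null.  Reversing
the regression (genotype as response) avoids specifying a joint distribution
for the phenotype vector, so the components of X may be correlated, skewed or
even binary without invalidating the test.

The public surface follows the statsmodels idiom: ``GenotypeBinomialModel``
holds the aligned data and link, ``fit``/``fit_null`` return
``GenotypeBinomialResults`` objects, and ``lr_test`` combines the two fits
into an ``LRTResult``.  Convenience functions (``binomial_loglik``,
``fit_null``, ``fit_full``, ``lrt_test``) wrap the same machinery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .exceptions import DegenerateDesignError, MonomorphicError

__all__ = [
    "PhenotypeVectorSet",
    "GenotypeCounts",
    "GenotypeBinomialModel",
    "GenotypeBinomialResults",
    "BinomialFit",
    "LRTResult",
    "binomial_loglik",
    "fit_null",
    "fit_full",
    "lrt_test",
]

#: coefficients larger than this in absolute value are treated as evidence of
#: (quasi-)complete separation; the fit is flagged non-converged.
SEPARATION_BOUND = 25.0

_LOG2 = math.log(2.0)


@dataclass
class PhenotypeVectorSet:
    """An n x k matrix of adjusted phenotype scores entering the model.

    Parameters
    ----------
    values : ndarray, shape (n, k)
        Complete (no missing entries) real-valued phenotype scores; any
        imputation and covariate adjustment happen upstream.
    individual_ids : sequence of str, optional
        Length-n identifiers; defaults to "ind0001", ...
    component_labels : sequence of str, optional
        Length-k names, e.g. ``["SBP_t1", ..., "SBP_t4"]`` or
        ``["SBP_PC1", "SBP_PC2"]``.
    """

    values: np.ndarray
    individual_ids: list[str] = field(default=None)  # type: ignore[assignment]
    component_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n, k = self.values.shape
        if k < 1:
            raise ValueError("phenotype matrix needs at least one column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                "phenotype matrix contains missing or non-finite entries; "
                "impute and adjust before association testing"
            )
        if n < k + 1:
            raise ValueError(
                f"need at least n >= k+1 observations to identify k={k} "
                f"phenotype coefficients plus an intercept; got n={n}"
            )
        if self.individual_ids is None:
            self.individual_ids = [f"ind{i + 1:04d}" for i in range(n)]
        else:
            self.individual_ids = [str(i) for i in self.individual_ids]
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match values")
        if self.component_labels is None:
            self.component_labels = [f"X{j + 1}" for j in range(k)]
        else:
            self.component_labels = [str(c) for c in self.component_labels]
        if len(self.component_labels) != k:
            raise ValueError("component_labels length does not match values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class GenotypeCounts:
    """Per-SNP vector of minor-allele counts with a missing mask.

    ``counts`` holds integers in {0, 1, 2}; entries flagged in
    ``missing_mask`` are ignored (their stored value is arbitrary).  The
    model itself is invariant to which allele is counted (flipping the coding
    flips coefficient signs and leaves the LRT unchanged), but QC recodes to
    the minor allele so that MAF filters read naturally.
    """

    counts: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]
    snp_id: str = "snp"
    chromosome: str = "0"
    position: int = 0

    def __post_init__(self) -> None:
        raw = np.asarray(self.counts)
        if self.missing_mask is None:
            if raw.dtype.kind == "f":
                self.missing_mask = ~np.isfinite(raw)
            else:
                self.missing_mask = np.zeros(raw.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != raw.shape:
            raise ValueError("missing_mask shape does not match counts")
        filled = np.where(self.missing_mask, 0, raw)
        self.counts = np.asarray(np.round(np.asarray(filled, dtype=float)), dtype=np.int64)
        observed = self.counts[~self.missing_mask]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("non-missing genotype counts must lie in {0, 1, 2}")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def n_nonmissing(self) -> int:
        return int((~self.missing_mask).sum())

    def observed(self) -> np.ndarray:
        """Counts restricted to non-missing individuals."""
        return self.counts[~self.missing_mask]


@dataclass
class GenotypeBinomialResults:
    """Fitted coefficients and log-likelihood of one binomial regression.

    ``loglik`` includes the log C(2, N_i) binomial constant, so it is a true
    log-probability; the constant is identical in null and full fits and
    cancels in the likelihood-ratio statistic.
    """

    params: np.ndarray          # (beta0, beta_1, ..., beta_k)
    loglik: float
    n_iter: int
    converged: bool
    n_used: int
    labels: list[str] = field(default_factory=list)

    @property
    def beta0(self) -> float:
        return float(self.params[0])

    @property
    def beta(self) -> np.ndarray:
        return self.params[1:]

    @property
    def k(self) -> int:
        return len(self.params) - 1

    def summary(self) -> str:
        lines = [
            "Binomial reverse regression (minor-allele count ~ phenotypes)",
            f"  observations: {self.n_used}    log-likelihood: {self.loglik:.4f}",
            f"  converged: {self.converged} ({self.n_iter} iterations)",
            f"  {'term':<12}{'coef':>12}",
            f"  {'intercept':<12}{self.beta0:>12.5f}",
        ]
        labels = self.labels or [f"X{j + 1}" for j in range(self.k)]
        for name, b in zip(labels, self.beta):
            lines.append(f"  {name:<12}{b:>12.5f}")
        return "\n".join(lines)


#: spec-facing alias — a fitted binomial regression.
BinomialFit = GenotypeBinomialResults


@dataclass
class LRTResult:
    """Likelihood-ratio test of H0: beta_1 = ... = beta_k = 0."""

    statistic: float
    df: int
    pvalue: float
    fit_full: GenotypeBinomialResults
    fit_null: GenotypeBinomialResults

    @property
    def converged(self) -> bool:
        return self.fit_full.converged and self.fit_null.converged

    def summary(self) -> str:
        p = "NA" if np.isnan(self.pvalue) else f"{self.pvalue:.4e}"
        return (
            f"LRT statistic = {self.statistic:.4f} on {self.df} df, "
            f"p = {p} (n = {self.fit_full.n_used})"
        )


def _log_binom_const(counts: np.ndarray) -> float:
    # log C(2, N) is log 2 for heterozygotes, 0 otherwise
    return _LOG2 * float(np.count_nonzero(counts == 1))


def _loglik_eta(eta: np.ndarray, counts: np.ndarray) -> float:
    # sum_i [N_i eta_i - 2 log(1 + exp(eta_i))]; logaddexp keeps |eta|~700 safe
    return float(np.dot(counts, eta) - 2.0 * np.logaddexp(0.0, eta).sum())


class GenotypeBinomialModel:
    """Binomial(2, logistic(beta0 + X beta)) model for a single SNP.

    Parameters
    ----------
    counts : GenotypeCounts or array-like
        Minor-allele counts; individuals with a missing genotype are dropped
        (per-SNP casewise deletion).
    phenotypes : PhenotypeVectorSet or array-like or None
        Phenotype matrix aligned on individuals with ``counts``.  ``None``
        specifies the intercept-only null model.
    drop_constant : bool
        If True, zero-variance phenotype columns are dropped with a warning
        and the test's degrees of freedom reduced accordingly; if False such
        columns raise :class:`DegenerateDesignError`.
    """

    def __init__(self, counts, phenotypes=None, *, drop_constant: bool = False):
        if not isinstance(counts, GenotypeCounts):
            counts = GenotypeCounts(np.asarray(counts))
        self.genotype = counts
        keep = ~counts.missing_mask
        self._N = counts.counts[keep].astype(float)
        self.n_used = int(keep.sum())
        if self.n_used == 0:
            raise ValueError("no non-missing genotypes to fit")

        self.dropped_components: list[str] = []
        if phenotypes is None:
            self._X = np.empty((self.n_used, 0))
            self.component_labels: list[str] = []
        else:
            if not isinstance(phenotypes, PhenotypeVectorSet):
                phenotypes = PhenotypeVectorSet(np.asarray(phenotypes, dtype=float))
            if phenotypes.n != counts.n:
                raise ValueError(
                    f"phenotype rows ({phenotypes.n}) do not match genotype "
                    f"length ({counts.n})"
                )
            X = phenotypes.values[keep]
            labels = list(phenotypes.component_labels)
            if drop_constant:
                varying = X.std(axis=0) > 0.0
                if not varying.all():
                    self.dropped_components = [
                        lab for lab, v in zip(labels, varying) if not v
                    ]
                    warnings.warn(
                        "dropping zero-variance phenotype component(s) "
                        f"{self.dropped_components}; degrees of freedom reduced",
                        stacklevel=2,
                    )
                    X = X[:, varying]
                    labels = [lab for lab, v in zip(labels, varying) if v]
            self._X = X
            self.component_labels = labels
        self.phenotypes = phenotypes

    # ------------------------------------------------------------------ #
    @property
    def k(self) -> int:
        """Number of phenotype components actually entering the fit."""
        return self._X.shape[1]

    @property
    def exog(self) -> np.ndarray:
        """Design matrix including the intercept column."""
        return np.column_stack([np.ones(self.n_used), self._X])

    def loglike(self, params) -> float:
        """Binomial log-likelihood (including the log C(2,N) constant)."""
        params = np.asarray(params, dtype=float)
        if params.shape != (self.k + 1,):
            raise ValueError(
                f"expected {self.k + 1} parameters (intercept + {self.k}), "
                f"got shape {params.shape}"
            )
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite coefficients")
        eta = self.exog @ params
        return _loglik_eta(eta, self._N) + _log_binom_const(self._N)

    def score(self, params) -> np.ndarray:
        """Gradient of the log-likelihood: A' (N - 2 p)."""
        eta = self.exog @ np.asarray(params, dtype=float)
        p = special.expit(eta)
        return self.exog.T @ (self._N - 2.0 * p)

    def hessian(self, params) -> np.ndarray:
        """Negative Fisher information: -A' diag(2 p (1-p)) A."""
        A = self.exog
        eta = A @ np.asarray(params, dtype=float)
        p = special.expit(eta)
        w = 2.0 * p * (1.0 - p)
        return -(A * w[:, None]).T @ A

    # ------------------------------------------------------------------ #
    def fit_null(self) -> GenotypeBinomialResults:
        """Closed-form intercept-only MLE: beta0 = logit(sum N / 2n)."""
        m = float(self._N.sum())
        n2 = 2.0 * self.n_used
        if m == 0.0 or m == n2:
            raise MonomorphicError(
                f"SNP {self.genotype.snp_id!r} is monomorphic in the analysed "
                f"sample (sum of counts = {int(m)} of {int(n2)} alleles)"
            )
        phat = m / n2
        beta0 = math.log(phat / (1.0 - phat))
        eta = np.full(self.n_used, beta0)
        ll = _loglik_eta(eta, self._N) + _log_binom_const(self._N)
        return GenotypeBinomialResults(
            params=np.array([beta0]),
            loglik=ll,
            n_iter=0,
            converged=True,
            n_used=self.n_used,
            labels=[],
        )

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> GenotypeBinomialResults:
        """Maximum-likelihood fit by Newton-Raphson with step-halving.

        Convergence is declared when the relative change in log-likelihood
        falls below ``tol``.  If any coefficient magnitude exceeds
        ``SEPARATION_BOUND`` (quasi-complete separation) or ``max_iter`` is
        exhausted, the result is returned with ``converged=False`` so the
        scan layer can record the SNP as untestable instead of aborting.
        """
        if self.k == 0:
            return self.fit_null()
        A = self.exog
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise DegenerateDesignError(
                "phenotype design matrix is rank deficient (constant or "
                "collinear columns)"
            )
        # start from the null intercept, slopes at zero
        m = float(self._N.sum())
        n2 = 2.0 * self.n_used
        phat = min(max(m / n2, 1e-10), 1.0 - 1e-10)
        params = np.zeros(self.k + 1)
        params[0] = math.log(phat / (1.0 - phat))
        const = _log_binom_const(self._N)
        ll = _loglik_eta(A @ params, self._N)

        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            eta = A @ params
            p = special.expit(eta)
            grad = A.T @ (self._N - 2.0 * p)
            w = 2.0 * p * (1.0 - p)
            info = (A * w[:, None]).T @ A
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise DegenerateDesignError(
                    "singular Fisher information matrix during Newton iteration"
                ) from exc
            # step-halving: never accept a decrease in log-likelihood
            new_params = params + step
            new_ll = _loglik_eta(A @ new_params, self._N)
            halvings = 0
            while new_ll < ll and halvings < 40:
                step *= 0.5
                new_params = params + step
                new_ll = _loglik_eta(A @ new_params, self._N)
                halvings += 1
            delta = new_ll - ll
            params, ll = new_params, new_ll
            if np.abs(params).max() > SEPARATION_BOUND:
                params = np.clip(params, -SEPARATION_BOUND, SEPARATION_BOUND)
                ll = _loglik_eta(A @ params, self._N)
                converged = False
                break
            if abs(delta) <= tol * (abs(ll) + 1.0):
                converged = True
                break
        if converged:
            # quasi-separation: fitted allele probabilities numerically 0 or 1
            pfit = special.expit(A @ params)
            if pfit.min() < 1e-7 or pfit.max() > 1.0 - 1e-7:
                converged = False
        return GenotypeBinomialResults(
            params=params,
            loglik=ll + const,
            n_iter=n_iter,
            converged=converged,
            n_used=self.n_used,
            labels=list(self.component_labels),
        )

    def lr_test(self, tol: float = 1e-8, max_iter: int = 100) -> LRTResult:
        """Likelihood-ratio test of association, chi-square(k) reference.

        A numerically slightly negative statistic (> -1e-8) is clipped to
        zero.  If either fit fails to converge the p-value is NaN; with
        ``drop_constant=True`` and all components constant (k = 0) the full
        model equals the null and the statistic is exactly 0 with p = 1.
        """
        null = self.fit_null()
        if self.k == 0:
            return LRTResult(0.0, 0, 1.0, null, null)
        full = self.fit(tol=tol, max_iter=max_iter)
        stat = 2.0 * (full.loglik - null.loglik)
        if stat < 0.0:
            if stat < -1e-8:
                raise RuntimeError(
                    f"full-model log-likelihood below null by {-stat / 2:.3e}; "
                    "optimizer failure"
                )
            stat = 0.0
        df = self.k
        if full.converged and null.converged:
            pvalue = float(stats.chi2.sf(stat, df))
        else:
            pvalue = float("nan")
        return LRTResult(stat, df, pvalue, full, null)


# ---------------------------------------------------------------------- #
# functional wrappers

def _aligned_model(X, N, drop_constant=False) -> GenotypeBinomialModel:
    if not isinstance(N, GenotypeCounts):
        N = GenotypeCounts(np.asarray(N))
    return GenotypeBinomialModel(N, X, drop_constant=drop_constant)


def binomial_loglik(beta0: float, beta, X, N) -> float:
    """Log-likelihood of the binomial reverse regression at given coefficients.

    Computes sum_i [N_i eta_i - 2 log(1 + e^{eta_i}) + log C(2, N_i)] with
    eta_i = beta0 + sum_j beta_j X_ij, stable for |eta| up to ~700.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    params = np.concatenate([[beta0], beta])
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite coefficients")
    if isinstance(X, PhenotypeVectorSet):
        Xv = X.values
    else:
        Xv = np.atleast_2d(np.asarray(X, dtype=float))
    if isinstance(N, GenotypeCounts):
        if N.missing_mask.any():
            raise ValueError("exclude missing-genotype rows before evaluation")
        Nv = N.counts.astype(float)
    else:
        Nv = np.atleast_1d(np.asarray(N, dtype=float))
    if Xv.shape != (Nv.shape[0], beta.shape[0]):
        raise ValueError(
            f"dimension mismatch: X is {Xv.shape}, N has {Nv.shape[0]} "
            f"entries, beta has {beta.shape[0]}"
        )
    eta = beta0 + Xv @ beta
    return _loglik_eta(eta, Nv) + _log_binom_const(Nv)


def fit_null(N) -> GenotypeBinomialResults:
    """Intercept-only MLE (closed form) for a genotype-count vector."""
    if not isinstance(N, GenotypeCounts):
        N = GenotypeCounts(np.asarray(N))
    return GenotypeBinomialModel(N, None).fit_null()


def fit_full(X, N, tol: float = 1e-8, max_iter: int = 100) -> GenotypeBinomialResults:
    """Full-model MLE of (beta0, beta) by Newton-Raphson."""
    return _aligned_model(X, N).fit(tol=tol, max_iter=max_iter)


def lrt_test(X, N) -> LRTResult:
    """Likelihood-ratio association test; drops zero-variance components."""
    return _aligned_model(X, N, drop_constant=True).lr_test()


# ---------------------------------------------------------------------- #
# lean array path used by the simulation study (no dataclass overhead)

def _lrt_arrays(X: np.ndarray, N: np.ndarray, tol: float = 1e-8,
                max_iter: int = 100) -> tuple[float, int, float, bool]:
    """(statistic, df, pvalue, converged) for float arrays X (n,k), N (n,).

    Raises MonomorphicError / DegenerateDesignError like the object path.
    Used in Monte-Carlo loops where constructing PhenotypeVectorSet /
    GenotypeCounts per replicate would dominate the runtime.
    """
    N = np.asarray(N, dtype=float)
    n = N.shape[0]
    m = float(N.sum())
    n2 = 2.0 * n
    if m == 0.0 or m == n2:
        raise MonomorphicError("monomorphic genotype vector")
    beta0 = math.log(m / (n2 - m))
    ll_null = _loglik_eta(np.full(n, beta0), N)

    A = np.column_stack([np.ones(n), X])
    params = np.zeros(A.shape[1])
    params[0] = beta0
    ll = ll_null
    converged = False
    for _ in range(max_iter):
        p = special.expit(A @ params)
        grad = A.T @ (N - 2.0 * p)
        w = 2.0 * p * (1.0 - p)
        info = (A * w[:, None]).T @ A
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise DegenerateDesignError("singular information matrix") from exc
        new_params = params + step
        new_ll = _loglik_eta(A @ new_params, N)
        halvings = 0
        while new_ll < ll and halvings < 40:
            step *= 0.5
            new_params = params + step
            new_ll = _loglik_eta(A @ new_params, N)
            halvings += 1
        delta = new_ll - ll
        params, ll = new_params, new_ll
        if np.abs(params).max() > SEPARATION_BOUND:
            converged = False
            break
        if abs(delta) <= tol * (abs(ll) + 1.0):
            converged = True
            break
    if converged:
        pfit = special.expit(A @ params)
        if pfit.min() < 1e-7 or pfit.max() > 1.0 - 1e-7:
            converged = False
    stat = max(2.0 * (ll - ll_null), 0.0)
    df = X.shape[1]
    pvalue = float(stats.chi2.sf(stat, df)) if converged else float("nan")
    return stat, df, pvalue, converged
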