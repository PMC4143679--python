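"""Longitudinal phenotype preprocessing.

Raw blood-pressure-style panels (n individuals x T time points x traits) are
turned into the adjusted phenotype vectors used by the association model:

1. natural-log transform of each trait to induce approximate normality;
2. EM estimation of a multivariate-normal model over the T time points of
   each trait, and conditional-mean imputation of missing entries
   (mu_Y + Sigma_YZ Sigma_ZZ^-1 (Z - mu_Z));
3. per-time-point ordinary-least-squares adjustment for age, smoking status
   and medication, keeping only individuals with complete covariates;
4. optional principal-component summarisation across time points.

The five phenotype-vector modes mirror the designs compared in the
association study: T1/T2 use all adjusted time points of one trait, T3/T4
their first principal components, and T5 concatenates the leading PCs of
both traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, InsufficientDataError
from .model import PhenotypeVectorSet

__all__ = [
    "LongitudinalPanel",
    "CovariatePanel",
    "MVNParams",
    "PhenotypeVectorSpec",
    "log_transform",
    "normality_diagnostic",
    "em_fit_mvn",
    "impute_missing",
    "impute_panel",
    "adjust_covariates",
    "pca_summarize",
    "build_phenotype_vector",
]

PHENOTYPE_MODES = ("T1", "T2", "T3", "T4", "T5")


@dataclass
class LongitudinalPanel:
    """n x T x traits array of longitudinal measurements with NaN missingness."""

    values: np.ndarray                      # (n, T, n_traits), NaN = missing
    individual_ids: list[str]
    time_labels: list[str]
    trait_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("panel values must be (n, T, n_traits)")
        n, T, p = self.values.shape
        if len(self.individual_ids) != n or len(self.time_labels) != T \
                or len(self.trait_labels) != p:
            raise ValueError("panel labels do not match value dimensions")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def trait_matrix(self, trait: str) -> np.ndarray:
        """The (n, T) matrix of one trait (a copy)."""
        j = self.trait_labels.index(trait)
        return self.values[:, :, j].copy()

    @classmethod
    def from_long_dataframe(cls, df: pd.DataFrame, id_col: str = "iid",
                            time_col: str = "timepoint",
                            trait_cols: list[str] | None = None) -> "LongitudinalPanel":
        """Build a panel from a long table with one row per (individual, time)."""
        if trait_cols is None:
            trait_cols = [c for c in df.columns if c not in (id_col, time_col)]
        ids = list(pd.unique(df[id_col].astype(str)))
        times = sorted(pd.unique(df[time_col]))
        n, T, p = len(ids), len(times), len(trait_cols)
        values = np.full((n, T, p), np.nan)
        id_ix = {v: i for i, v in enumerate(ids)}
        t_ix = {v: i for i, v in enumerate(times)}
        for _, row in df.iterrows():
            i = id_ix[str(row[id_col])]
            t = t_ix[row[time_col]]
            for j, c in enumerate(trait_cols):
                values[i, t, j] = row[c]
        return cls(values, ids, [str(t) for t in times], list(trait_cols))


@dataclass
class CovariatePanel:
    """Per-individual, per-time-point covariates: age, smoking, medication."""

    age: np.ndarray       # (n, T), NaN = missing
    smoking: np.ndarray   # (n, T), values in {0, 1} where observed
    medication: np.ndarray
    individual_ids: list[str]
    time_labels: list[str]

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.smoking = np.asarray(self.smoking, dtype=float)
        self.medication = np.asarray(self.medication, dtype=float)
        shape = self.age.shape
        if self.smoking.shape != shape or self.medication.shape != shape:
            raise ValueError("covariate arrays must share one (n, T) shape")
        for name, arr in (("smoking", self.smoking), ("medication", self.medication)):
            obs = arr[~np.isnan(arr)]
            if obs.size and not np.isin(obs, (0.0, 1.0)).all():
                raise ValueError(f"{name} must be binary (0/1) where observed")

    @property
    def complete_rows(self) -> np.ndarray:
        """Boolean mask of individuals with every covariate observed at every
        time point — the single analysis sample used downstream."""
        stacked = np.stack([self.age, self.smoking, self.medication], axis=-1)
        return ~np.isnan(stacked).any(axis=(1, 2))

    @classmethod
    def from_long_dataframe(cls, df: pd.DataFrame, id_col: str = "iid",
                            time_col: str = "timepoint") -> "CovariatePanel":
        ids = list(pd.unique(df[id_col].astype(str)))
        times = sorted(pd.unique(df[time_col]))
        n, T = len(ids), len(times)
        age = np.full((n, T), np.nan)
        smoke = np.full((n, T), np.nan)
        med = np.full((n, T), np.nan)
        id_ix = {v: i for i, v in enumerate(ids)}
        t_ix = {v: i for i, v in enumerate(times)}
        for _, row in df.iterrows():
            i, t = id_ix[str(row[id_col])], t_ix[row[time_col]]
            age[i, t] = row["age"]
            smoke[i, t] = row["smoke"]
            med[i, t] = row["med"]
        return cls(age, smoke, med, ids, [str(t) for t in times])


@dataclass
class MVNParams:
    """Multivariate-normal parameters fitted by EM on incomplete data."""

    mu: np.ndarray
    sigma: np.ndarray
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("sigma shape does not match mu")


@dataclass
class PhenotypeVectorSpec:
    """Which adjusted phenotype vector to test: T1..T5."""

    mode: str
    n_components: int = 2

    def __post_init__(self) -> None:
        if self.mode not in PHENOTYPE_MODES:
            raise ValueError(
                f"unknown phenotype-vector mode {self.mode!r}; "
                f"expected one of {PHENOTYPE_MODES}"
            )
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


# ---------------------------------------------------------------------- #

def log_transform(panel: LongitudinalPanel) -> LongitudinalPanel:
    """Natural-log transform of every observed entry; missingness unchanged.

    Raises :class:`DomainError` naming the offending individual/time point if
    any observed value is non-positive.
    """
    values = panel.values
    bad = (values <= 0) & ~np.isnan(values)
    if bad.any():
        i, t, j = map(int, np.argwhere(bad)[0])
        raise DomainError(
            f"non-positive value {values[i, t, j]!r} for individual "
            f"{panel.individual_ids[i]!r}, time {panel.time_labels[t]!r}, "
            f"trait {panel.trait_labels[j]!r}: cannot log-transform"
        )
    with np.errstate(invalid="ignore"):
        logged = np.log(values)
    return LongitudinalPanel(
        logged, list(panel.individual_ids), list(panel.time_labels),
        list(panel.trait_labels),
    )


def normality_diagnostic(values) -> float:
    """One-sample Kolmogorov-Smirnov p-value against a moment-matched normal.

    Advisory only (it motivates, but never gates, the log transform).  Uses
    the sample mean and ML standard deviation as the reference parameters.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 5:
        raise ValueError("need a 1-D sample of at least 5 observations")
    if np.isnan(x).any():
        raise ValueError("sample contains missing values")
    sd = x.std()
    if sd == 0:
        raise DomainError("constant sample: normality test undefined (zero variance)")
    return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


# ---------------------------------------------------------------------- #
# EM for a multivariate normal with arbitrarily missing entries

def _pattern_groups(mask: np.ndarray) -> dict[bytes, np.ndarray]:
    """Group row indices by missingness pattern (rows as bytes keys)."""
    keys = np.packbits(mask, axis=1).tobytes()
    width = np.packbits(mask, axis=1).shape[1]
    groups: dict[bytes, list[int]] = {}
    for i in range(mask.shape[0]):
        key = keys[i * width:(i + 1) * width]
        groups.setdefault(key, []).append(i)
    return {k: np.asarray(v) for k, v in groups.items()}


def _observed_loglik(X: np.ndarray, mask: np.ndarray, mu: np.ndarray,
                     sigma: np.ndarray) -> float:
    """Observed-data log-likelihood: sum of marginal normal densities of the
    observed sub-vectors."""
    ll = 0.0
    for idx in _pattern_groups(mask).values():
        obs = ~mask[idx[0]]
        if not obs.any():
            continue
        sub_mu = mu[obs]
        sub_sigma = sigma[np.ix_(obs, obs)]
        Z = X[np.ix_(idx, np.flatnonzero(obs))]
        ll += float(
            stats.multivariate_normal.logpdf(
                Z, mean=sub_mu, cov=sub_sigma, allow_singular=True
            ).sum()
        )
    return ll


def em_fit_mvn(X, tol: float = 1e-8, max_iter: int = 500) -> MVNParams:
    """Fit a multivariate normal to an incomplete (n, T) matrix by EM.

    Missing entries are NaN.  The E-step computes, for each row, the
    conditional mean AND conditional covariance of the missing block given
    the observed block; the M-step re-estimates mu and sigma from the
    completed sufficient statistics (the conditional covariance enters the
    second-moment update — omitting it would bias sigma downward).  Iteration
    stops when the relative change in the observed-data log-likelihood drops
    below ``tol``; this likelihood is non-decreasing by construction and the
    trace is returned for inspection.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D (n, T) matrix")
    n, T = X.shape
    mask = np.isnan(X)
    n_obs_col = (~mask).sum(axis=0)
    if (n_obs_col < 2).any():
        bad = int(np.flatnonzero(n_obs_col < 2)[0])
        raise InsufficientDataError(
            f"column {bad} observed for {int(n_obs_col[bad])} individuals; "
            "need at least 2 to estimate its variance"
        )
    if mask.all(axis=1).any():
        warnings.warn(
            "rows with no observed components contribute only the mean",
            stacklevel=2,
        )

    # init: column means; ML covariance of mean-filled data
    mu = np.nanmean(X, axis=0)
    filled = np.where(mask, mu, X)
    sigma = np.cov(filled, rowvar=False, bias=True)
    sigma = np.atleast_2d(sigma)
    if np.linalg.eigvalsh(sigma).min() < 1e-10:
        sigma = sigma + 1e-8 * np.eye(T)

    if not mask.any():
        ll = _observed_loglik(X, mask, mu, sigma)
        return MVNParams(mu, sigma, n_iter=1, loglik_trace=[ll])

    trace: list[float] = []
    groups = _pattern_groups(mask)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll = _observed_loglik(X, mask, mu, sigma)
        trace.append(ll)
        # E-step: completed rows and summed conditional covariances
        completed = np.where(mask, 0.0, X)
        cond_cov_sum = np.zeros((T, T))
        for idx in groups.values():
            miss = mask[idx[0]]
            if not miss.any():
                continue
            obs = ~miss
            mi = np.flatnonzero(miss)
            oi = np.flatnonzero(obs)
            if oi.size == 0:
                completed[np.ix_(idx, mi)] = mu[mi]
                cond_cov_sum[np.ix_(mi, mi)] += len(idx) * sigma[np.ix_(mi, mi)]
                continue
            S_oo = sigma[np.ix_(oi, oi)]
            S_mo = sigma[np.ix_(mi, oi)]
            try:
                B = np.linalg.solve(S_oo, S_mo.T).T
            except np.linalg.LinAlgError:
                B = S_mo @ np.linalg.pinv(S_oo)
            Z = X[np.ix_(idx, oi)]
            completed[np.ix_(idx, mi)] = mu[mi] + (Z - mu[oi]) @ B.T
            C = sigma[np.ix_(mi, mi)] - B @ S_mo.T
            cond_cov_sum[np.ix_(mi, mi)] += len(idx) * C
        # M-step
        mu_new = completed.mean(axis=0)
        centered = completed - mu_new
        sigma_new = (centered.T @ centered + cond_cov_sum) / n
        eig_min = np.linalg.eigvalsh(sigma_new).min()
        if eig_min < -1e-10:
            warnings.warn(
                "covariance update lost positive semi-definiteness; "
                "applying 1e-8 ridge repair",
                stacklevel=2,
            )
            sigma_new = sigma_new + 1e-8 * np.eye(T)
        mu, sigma = mu_new, sigma_new
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) <= tol * (abs(trace[-2]) + 1.0):
            break
    trace.append(_observed_loglik(X, mask, mu, sigma))
    return MVNParams(mu, sigma, n_iter=n_iter, loglik_trace=trace)


def impute_missing(X, params: MVNParams) -> np.ndarray:
    """Fill missing entries with their MVN conditional mean.

    Each row is partitioned into missing Y and observed Z; Y is replaced by
    mu_Y + Sigma_YZ Sigma_ZZ^-1 (Z - mu_Z).  Observed entries are untouched;
    fully missing rows are filled with mu.
    """
    X = np.asarray(X, dtype=float)
    T = X.shape[1]
    if params.mu.size != T:
        raise ValueError("params dimension does not match matrix width")
    mask = np.isnan(X)
    out = X.copy()
    if not mask.any():
        return out
    mu, sigma = params.mu, params.sigma
    for idx in _pattern_groups(mask).values():
        miss = mask[idx[0]]
        if not miss.any():
            continue
        mi = np.flatnonzero(miss)
        oi = np.flatnonzero(~miss)
        if oi.size == 0:
            out[np.ix_(idx, mi)] = mu[mi]
            continue
        S_oo = sigma[np.ix_(oi, oi)]
        S_mo = sigma[np.ix_(mi, oi)]
        if np.linalg.matrix_rank(S_oo) < S_oo.shape[0]:
            warnings.warn(
                "singular observed-block covariance; using pseudo-inverse",
                stacklevel=2,
            )
            B = S_mo @ np.linalg.pinv(S_oo)
        else:
            B = np.linalg.solve(S_oo, S_mo.T).T
        Z = X[np.ix_(idx, oi)]
        out[np.ix_(idx, mi)] = mu[mi] + (Z - mu[oi]) @ B.T
    return out


def impute_panel(panel: LongitudinalPanel, tol: float = 1e-8,
                 max_iter: int = 500, single_pass: bool = False,
                 ) -> tuple[LongitudinalPanel, dict[str, MVNParams]]:
    """EM-impute each trait of a log-scale panel independently.

    Each trait's T time points form one multivariate normal; traits are not
    jointly imputed.  ``single_pass=True`` skips EM iteration and performs one
    conditional-mean fill using available-case moment estimates.
    """
    values = panel.values.copy()
    params: dict[str, MVNParams] = {}
    for j, trait in enumerate(panel.trait_labels):
        Xj = panel.values[:, :, j]
        if single_pass:
            mu = np.nanmean(Xj, axis=0)
            dfj = pd.DataFrame(Xj)
            sigma = dfj.cov(min_periods=2).to_numpy() * (len(dfj) - 1) / len(dfj)
            sigma = np.where(np.isnan(sigma), 0.0, sigma)
            pj = MVNParams(mu, sigma, n_iter=0, loglik_trace=[])
        else:
            pj = em_fit_mvn(Xj, tol=tol, max_iter=max_iter)
        values[:, :, j] = impute_missing(Xj, pj)
        params[trait] = pj
    out = LongitudinalPanel(values, list(panel.individual_ids),
                            list(panel.time_labels), list(panel.trait_labels))
    return out, params


# ---------------------------------------------------------------------- #

def adjust_covariates(panel: LongitudinalPanel, covs: CovariatePanel,
                      ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Residualise each trait at each time point on age, smoking, medication.

    Individuals missing ANY covariate at ANY time point are dropped from the
    analysis entirely (the single analysis sample used downstream).  Returns
    ``(residuals, kept_index)`` where ``residuals[trait]`` is the (n', T)
    matrix of OLS residuals and ``kept_index`` indexes the retained rows of
    the input panel.

    Covariate columns that are constant within the kept sample (e.g. nobody
    on medication at one time point) are dropped from that regression with a
    warning rather than producing a singular design.
    """
    if covs.age.shape[0] != panel.n or covs.age.shape[1] != panel.n_timepoints:
        raise ValueError("covariate panel does not align with the phenotype panel")
    if panel.missing_mask.any():
        raise ValueError("phenotype panel still has missing values; impute first")
    kept = np.flatnonzero(covs.complete_rows)
    if kept.size == 0:
        raise InsufficientDataError("no individual has complete covariates")
    T = panel.n_timepoints
    residuals: dict[str, np.ndarray] = {}
    for j, trait in enumerate(panel.trait_labels):
        resid = np.empty((kept.size, T))
        for t in range(T):
            y = panel.values[kept, t, j]
            cols = {
                "age": covs.age[kept, t],
                "smoke": covs.smoking[kept, t],
                "med": covs.medication[kept, t],
            }
            design = [np.ones(kept.size)]
            for name, c in cols.items():
                if np.ptp(c) == 0.0:
                    warnings.warn(
                        f"covariate {name!r} is constant at time point "
                        f"{panel.time_labels[t]!r}; dropped from the regression",
                        stacklevel=2,
                    )
                else:
                    design.append(c)
            A = np.column_stack(design)
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid[:, t] = y - A @ coef
        residuals[trait] = resid
    return residuals, kept


def pca_summarize(residuals: np.ndarray, n_components: int,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores of an (n, T) residual matrix.

    Eigen-decomposition of the sample covariance of the column-centred
    matrix; components are ordered by decreasing eigenvalue and each loading
    vector is signed so its largest-magnitude entry is positive.  Returns
    ``(scores, variance_explained)`` where ``variance_explained`` covers all
    T components (fractions summing to 1).
    """
    R = np.asarray(residuals, dtype=float)
    n, T = R.shape
    if n_components > T:
        raise ValueError(f"n_components={n_components} exceeds {T} time points")
    if n <= T:
        raise ValueError("need more individuals than time points for PCA")
    centered = R - R.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # sign convention: dominant loading positive
    for c in range(T):
        peak = np.argmax(np.abs(eigvec[:, c]))
        if eigvec[peak, c] < 0:
            eigvec[:, c] = -eigvec[:, c]
    scores = centered @ eigvec[:, :n_components]
    variance_explained = eigval / eigval.sum()
    return scores, variance_explained


def build_phenotype_vector(sbp_resid: np.ndarray, dbp_resid: np.ndarray,
                           spec: PhenotypeVectorSpec,
                           individual_ids: list[str] | None = None,
                           trait_labels: tuple[str, str] = ("SBP", "DBP"),
                           ) -> PhenotypeVectorSet:
    """Assemble the phenotype vector X for one of the five study designs.

    T1/T2: all adjusted time points of the first/second trait (k = T);
    T3/T4: leading PC scores of the first/second trait (k = n_components);
    T5: concatenated leading PC scores of both traits (k = 2 n_components).
    """
    sbp = np.asarray(sbp_resid, dtype=float)
    dbp = np.asarray(dbp_resid, dtype=float)
    if sbp.shape != dbp.shape:
        raise ValueError("residual matrices must align on individuals and time points")
    T = sbp.shape[1]
    name_a, name_b = trait_labels
    if spec.mode == "T1":
        values, labels = sbp, [f"{name_a}_t{t + 1}" for t in range(T)]
    elif spec.mode == "T2":
        values, labels = dbp, [f"{name_b}_t{t + 1}" for t in range(T)]
    elif spec.mode == "T3":
        scores, _ = pca_summarize(sbp, spec.n_components)
        values = scores
        labels = [f"{name_a}_PC{c + 1}" for c in range(spec.n_components)]
    elif spec.mode == "T4":
        scores, _ = pca_summarize(dbp, spec.n_components)
        values = scores
        labels = [f"{name_b}_PC{c + 1}" for c in range(spec.n_components)]
    else:  # T5
        s_scores, _ = pca_summarize(sbp, spec.n_components)
        d_scores, _ = pca_summarize(dbp, spec.n_components)
        values = np.column_stack([s_scores, d_scores])
        labels = [f"{name_a}_PC{c + 1}" for c in range(spec.n_components)] + \
                 [f"{name_b}_PC{c + 1}" for c in range(spec.n_components)]
    return PhenotypeVectorSet(values, individual_ids, labels)
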