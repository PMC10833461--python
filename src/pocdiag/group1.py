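"""Group-1 diagnostics: distributional comparison between patients with and
without an observed value for a partially observed covariate (POC).

Three complementary views of the same question ("does missingness track
observed patient characteristics, as it would under MAR?"):

* :func:`asmd` — absolute standardized mean differences per covariate,
  with a median/min/max aggregate and a "Table 1"-style stratified
  descriptive table (0.1 is the conventional imbalance threshold);
* :func:`hotelling` — a two-sample Hotelling T² test on the vector of
  covariate means, F-transformed for the p-value;
* :func:`little_mcar` — Little's single global chi-square test of MCAR,
  built on EM estimates of a multivariate-normal mean and covariance.

Other POCs enter the comparison only through their missingness indicators
(their values would force case deletion); categorical covariates are
expanded to one-hot columns. The outcome is excluded by default and the
exposure included, both configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, Kind, RoleError

__all__ = [
    "AsmdResult",
    "HotellingResult",
    "LittleResult",
    "build_comparison_matrix",
    "asmd",
    "hotelling",
    "little_mcar",
    "EMConvergenceError",
]


class EMConvergenceError(RuntimeError):
    """EM failed to converge within the iteration budget."""


# ---------------------------------------------------------------------- #
# comparison design matrix
# ---------------------------------------------------------------------- #
def _encode_binary(s: pd.Series) -> pd.Series:
    """Deterministic 0/1 coding: larger of the two sorted values -> 1."""
    obs = sorted(pd.unique(s.dropna()))
    if len(obs) == 1:
        return (s == obs[0]).astype(float)
    return (s == obs[-1]).astype(float)


def build_comparison_matrix(
    table: CohortTable,
    poc: str,
    *,
    include_exposure: bool = True,
    include_outcome: bool = False,
    drop_first: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Numeric design matrix and missingness-stratum labels for one POC.

    Columns: exposure (optional), fully observed covariates (categoricals
    one-hot encoded; ``drop_first`` drops the reference level so the matrix
    stays full-rank for covariance-based tests), missingness indicators of
    the other POCs, and optionally the outcome column(s). Zero-variance
    columns are dropped with a warning.
    """
    if poc not in table.poc_cols:
        raise RoleError(f"{poc!r} is not a POC in this table")
    df = table.data
    cols: dict[str, pd.Series] = {}
    base: list[str] = []
    if include_exposure and table.exposure_col:
        base.append(table.exposure_col)
    base += table.covariate_cols
    if include_outcome:
        base += table.outcome_cols
    for col in base:
        kind = table.kinds[col]
        if kind == Kind.CATEGORICAL:
            dummies = pd.get_dummies(df[col], prefix=col)
            if drop_first and dummies.shape[1] > 1:
                dummies = dummies.iloc[:, 1:]
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
        elif kind == Kind.BINARY:
            cols[col] = _encode_binary(df[col])
        else:
            cols[col] = df[col].astype(float)
    for other in table.poc_cols:
        if other != poc:
            cols[f"{other}_missing"] = df[other].isna().astype(float)
    X = pd.DataFrame(cols, index=df.index)
    keep = X.std(ddof=0) > 0
    if not keep.all():
        dropped = list(X.columns[~keep])
        warnings.warn(
            f"dropping zero-variance comparison columns for {poc!r}: {dropped}",
            UserWarning,
            stacklevel=2,
        )
        X = X.loc[:, keep]
    labels = df[poc].isna().to_numpy(dtype=int)
    return X, labels


# ---------------------------------------------------------------------- #
# ASMD
# ---------------------------------------------------------------------- #
def _asmd_continuous(x1: np.ndarray, x0: np.ndarray) -> float:
    if len(x1) < 2 or len(x0) < 2:
        return np.nan
    s1, s0 = np.var(x1, ddof=1), np.var(x0, ddof=1)
    denom = np.sqrt((s1 + s0) / 2.0)
    if denom == 0:
        return 0.0 if np.mean(x1) == np.mean(x0) else np.inf
    return abs(np.mean(x1) - np.mean(x0)) / denom


def _asmd_binary(p1: float, p0: float) -> float:
    denom = np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2.0)
    if denom == 0:
        return 0.0 if p1 == p0 else np.inf
    return abs(p1 - p0) / denom


@dataclass
class AsmdResult:
    """Per-covariate ASMDs for one POC with a median/min/max aggregate."""

    poc: str
    per_covariate: pd.Series        # covariate -> summarized ASMD
    detail: pd.DataFrame            # covariate, level, stats per stratum, asmd
    aggregate: float
    asmd_min: float
    asmd_max: float
    method: str = "median"
    flagged: list[str] = field(default_factory=list)

    @property
    def table1(self) -> pd.DataFrame:
        """Stratified descriptive table (mean (SD) / n (%) by stratum)."""
        return self.detail

    def __str__(self) -> str:
        return (
            f"ASMD for {self.poc!r}: {self.method} {self.aggregate:.4f} "
            f"(min {self.asmd_min:.4f}, max {self.asmd_max:.4f})\n"
            + self.per_covariate.round(4).to_string()
        )


def asmd(
    table: CohortTable,
    poc: str,
    *,
    aggregate: str = "median",
    include_exposure: bool = True,
    include_outcome: bool = False,
) -> AsmdResult:
    """ASMDs of observed patient characteristics between patients with and
    without a value for ``poc``.

    Continuous: ``|m1-m0| / sqrt((s1^2+s0^2)/2)``. Binary (prevalences
    p1, p0): ``|p1-p0| / sqrt((p1(1-p1)+p0(1-p0))/2)``. Multi-level
    categoricals get one-vs-rest per-level ASMDs summarized by the level
    maximum. The aggregate is the median (or mean) across covariates with
    the min/max range.
    """
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    if poc not in table.poc_cols:
        raise RoleError(f"{poc!r} is not a POC in this table")
    df = table.data
    m = df[poc].isna()
    if m.all() or (~m).all():
        raise ValueError(f"both missingness strata must be non-empty for {poc!r}")

    base: list[tuple[str, Kind]] = []
    if include_exposure and table.exposure_col:
        base.append((table.exposure_col, Kind.BINARY))
    base += [(c, table.kinds[c]) for c in table.covariate_cols]
    if include_outcome:
        base += [(c, table.kinds[c]) for c in table.outcome_cols]
    indicator_cols = [f"{o}_missing" for o in table.poc_cols if o != poc]

    per_cov: dict[str, float] = {}
    rows: list[dict] = []
    flagged: list[str] = []
    n1, n0 = int(m.sum()), int((~m).sum())

    def _binary_row(name: str, level, x: pd.Series) -> float:
        p1 = float(x[m].mean())
        p0 = float(x[~m].mean())
        a = _asmd_binary(p1, p0)
        rows.append(
            {
                "covariate": name,
                "level": level,
                "missing_stat": f"{int(x[m].sum())} ({100 * p1:.1f}%)",
                "observed_stat": f"{int(x[~m].sum())} ({100 * p0:.1f}%)",
                "asmd": a,
            }
        )
        return a

    for name, kind in base:
        s = df[name]
        if kind == Kind.CONTINUOUS:
            x1 = s[m].to_numpy(dtype=float)
            x0 = s[~m].to_numpy(dtype=float)
            a = _asmd_continuous(x1, x0)
            if np.isnan(a):
                flagged.append(name)
            rows.append(
                {
                    "covariate": name,
                    "level": "",
                    "missing_stat": f"{np.mean(x1):.2f} ({np.std(x1, ddof=1):.2f})" if len(x1) > 1 else "n<2",
                    "observed_stat": f"{np.mean(x0):.2f} ({np.std(x0, ddof=1):.2f})" if len(x0) > 1 else "n<2",
                    "asmd": a,
                }
            )
            per_cov[name] = a
        elif kind == Kind.BINARY:
            per_cov[name] = _binary_row(name, "", _encode_binary(s))
        else:
            level_asmds = []
            for level in sorted(pd.unique(s.dropna())):
                level_asmds.append(_binary_row(name, level, (s == level).astype(float)))
            per_cov[name] = float(np.nanmax(level_asmds))
    for ind in indicator_cols:
        other = ind[: -len("_missing")]
        per_cov[ind] = _binary_row(ind, "", df[other].isna().astype(float))

    vals = pd.Series(per_cov, name="asmd")
    finite = vals.dropna()
    agg = float(finite.median() if aggregate == "median" else finite.mean())
    detail = pd.DataFrame(rows)
    detail.insert(1, "n_missing_stratum", n1)
    detail.insert(2, "n_observed_stratum", n0)
    return AsmdResult(
        poc=poc,
        per_covariate=vals,
        detail=detail,
        aggregate=agg,
        asmd_min=float(finite.min()),
        asmd_max=float(finite.max()),
        method=aggregate,
        flagged=flagged,
    )


# ---------------------------------------------------------------------- #
# Hotelling two-sample T^2
# ---------------------------------------------------------------------- #
@dataclass
class HotellingResult:
    poc: str
    t2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n_missing: int
    n_observed: int
    columns: list[str]

    def __str__(self) -> str:
        return (
            f"Hotelling T² for {self.poc!r}: T²={self.t2:.4f}, "
            f"F({self.df1},{self.df2})={self.f_stat:.4f}, p={self.p_value:.4g}"
        )


def hotelling(
    table: CohortTable,
    poc: str,
    *,
    include_exposure: bool = True,
    include_outcome: bool = False,
) -> HotellingResult:
    """Two-sample Hotelling T² comparing covariate mean vectors between the
    missing and observed strata of ``poc``.

    ``T² = (n0 n1 / (n0+n1)) d' S_pooled^{-1} d`` with
    ``F = (n0+n1-k-1) / (k (n0+n1-2)) T²`` on ``(k, n0+n1-k-1)`` degrees
    of freedom.
    """
    X, labels = build_comparison_matrix(
        table,
        poc,
        include_exposure=include_exposure,
        include_outcome=include_outcome,
        drop_first=True,
    )
    A = X.to_numpy(dtype=float)
    g1, g0 = A[labels == 1], A[labels == 0]
    n1, n0, k = len(g1), len(g0), A.shape[1]
    if min(n1, n0) == 0:
        raise ValueError(f"both missingness strata must be non-empty for {poc!r}")
    if n0 + n1 - 2 <= k:
        raise ValueError(
            f"too few patients ({n0 + n1}) for {k} comparison columns; reduce the covariate set"
        )
    d = g1.mean(axis=0) - g0.mean(axis=0)
    S1 = np.cov(g1, rowvar=False, ddof=1) if n1 > 1 else np.zeros((k, k))
    S0 = np.cov(g0, rowvar=False, ddof=1) if n0 > 1 else np.zeros((k, k))
    S = (np.atleast_2d(S1) * (n1 - 1) + np.atleast_2d(S0) * (n0 - 1)) / (n0 + n1 - 2)
    if np.linalg.cond(S) > 1e12:
        raise np.linalg.LinAlgError(
            f"pooled covariance for {poc!r} is singular; reduce or decorrelate the "
            "comparison covariates"
        )
    t2 = float(n0 * n1 / (n0 + n1) * d @ np.linalg.solve(S, d))
    df1, df2 = k, n0 + n1 - k - 1
    f_stat = t2 * df2 / (k * (n0 + n1 - 2))
    p = float(stats.f.sf(f_stat, df1, df2))
    return HotellingResult(
        poc=poc,
        t2=t2,
        f_stat=float(f_stat),
        df1=df1,
        df2=df2,
        p_value=p,
        n_missing=n1,
        n_observed=n0,
        columns=list(X.columns),
    )


# ---------------------------------------------------------------------- #
# Little's MCAR test
# ---------------------------------------------------------------------- #
@dataclass
class LittleResult:
    statistic: float
    df: int
    p_value: float
    n_patterns: int
    n_iter: int
    converged: bool
    applicable: bool
    variables: list[str]

    def __str__(self) -> str:
        if not self.applicable:
            return "Little's MCAR test: inapplicable (single missingness pattern, df=0)"
        return (
            f"Little's MCAR test: chi²={self.statistic:.4f}, df={self.df}, "
            f"p={self.p_value:.4g} ({self.n_patterns} patterns)"
        )


def _em_mvn(
    Y: np.ndarray, tol: float = 1e-6, max_iter: int = 500, ridge: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, int, bool, list[float]]:
    """ML mean and covariance of a multivariate normal with missing values.

    Classic EM over distinct missingness patterns: the E-step fills each
    pattern's missing block with its conditional expectation (plus the
    conditional covariance in the second moment), the M-step re-estimates
    mu and Sigma from the completed sufficient statistics. Convergence on
    the parameter sup-norm; a small ridge keeps Sigma positive definite.
    """
    n, p = Y.shape
    M = np.isnan(Y)
    keep = ~M.all(axis=1)
    Y, M = Y[keep], M[keep]
    n = len(Y)
    if n == 0:
        raise ValueError("no rows with any observed variable")

    pattern_rows: dict[tuple, np.ndarray] = {}
    keys = [tuple(row) for row in M]
    for i, key in enumerate(keys):
        pattern_rows.setdefault(key, []).append(i)
    pattern_rows = {k: np.asarray(v) for k, v in pattern_rows.items()}

    mu = np.nanmean(Y, axis=0)
    var = np.nanvar(Y, axis=0)
    Sigma = np.diag(np.maximum(var, ridge))
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sum_y = np.zeros(p)
        sum_yy = np.zeros((p, p))
        for key, rows in pattern_rows.items():
            mis = np.asarray(key)
            obs = ~mis
            Yo = Y[np.ix_(rows, np.flatnonzero(obs))]
            nj = len(rows)
            if not mis.any():
                sum_y += Yo.sum(axis=0)
                sum_yy += Yo.T @ Yo
                continue
            o = np.flatnonzero(obs)
            m_idx = np.flatnonzero(mis)
            Soo = Sigma[np.ix_(o, o)]
            Som = Sigma[np.ix_(o, m_idx)]
            B = np.linalg.solve(Soo, Som)                      # (|o|,|m|)
            resid = Yo - mu[o]
            Em = mu[m_idx] + resid @ B                          # (nj,|m|)
            Cmm = Sigma[np.ix_(m_idx, m_idx)] - Som.T @ B       # conditional cov
            full = np.zeros((nj, p))
            full[:, o] = Yo
            full[:, m_idx] = Em
            sum_y += full.sum(axis=0)
            sum_yy += full.T @ full
            sum_yy[np.ix_(m_idx, m_idx)] += nj * Cmm
        mu_new = sum_y / n
        Sigma_new = sum_yy / n - np.outer(mu_new, mu_new)
        Sigma_new[np.diag_indices(p)] += ridge
        delta = max(
            float(np.abs(mu_new - mu).max()), float(np.abs(Sigma_new - Sigma).max())
        )
        trace.append(delta)
        mu, Sigma = mu_new, Sigma_new
        if delta < tol:
            converged = True
            break
    return mu, Sigma, it, converged, trace


def little_mcar(
    table: CohortTable,
    pocs: Sequence[str] | None = None,
    *,
    include_covariates: bool = True,
    include_exposure: bool = False,
    tol: float = 1e-6,
    max_iter: int = 500,
    ridge: float = 1e-8,
) -> LittleResult:
    """Little's global chi-square test of MCAR across all POCs.

    The variable vector holds the POC values themselves plus the fully
    observed covariates (categoricals one-hot encoded without the
    reference level; multivariate normality is an approximation for the
    binary columns). With EM estimates (mu, Sigma), the statistic is

    ``d² = sum_j n_j (ybar_obs,j - mu_obs,j)' Sigma_obs,j^{-1} (ybar_obs,j - mu_obs,j)``

    over distinct missingness patterns j, with ``df = sum_j p_j - p``
    (p_j = number of observed variables in pattern j). Complete data form
    a single pattern with df = 0, flagged as inapplicable.
    """
    from .cohort import detect_pocs

    poc_list = detect_pocs(table, pocs)
    if not poc_list:
        raise ValueError("little_mcar needs at least one POC")
    df = table.data
    cols: dict[str, pd.Series] = {}
    for poc in poc_list:
        kind = table.kinds[poc]
        if kind == Kind.CATEGORICAL:
            obs_levels = sorted(pd.unique(df[poc].dropna()))
            for level in obs_levels[1:]:
                s = (df[poc] == level).astype(float)
                s[df[poc].isna()] = np.nan
                cols[f"{poc}_{level}"] = s
        else:
            if kind == Kind.BINARY:
                obs = sorted(pd.unique(df[poc].dropna()))
                s = (df[poc] == obs[-1]).astype(float) if len(obs) > 1 else df[poc] * 0.0
                s[df[poc].isna()] = np.nan
                cols[poc] = s
            else:
                cols[poc] = df[poc].astype(float)
    extra: list[str] = []
    if include_exposure and table.exposure_col:
        extra.append(table.exposure_col)
    if include_covariates:
        extra += table.covariate_cols
    for col in extra:
        kind = table.kinds[col]
        if kind == Kind.CATEGORICAL:
            dummies = pd.get_dummies(df[col], prefix=col)
            for c in dummies.columns[1:]:
                cols[c] = dummies[c].astype(float)
        elif kind == Kind.BINARY:
            cols[col] = _encode_binary(df[col])
        else:
            cols[col] = df[col].astype(float)
    X = pd.DataFrame(cols, index=df.index)
    keep = X.std(ddof=0) > 0
    X = X.loc[:, keep]
    Y = X.to_numpy(dtype=float)
    n, p = Y.shape

    M = np.isnan(Y)
    pattern_keys = sorted({tuple(row) for row in M})
    if len(pattern_keys) <= 1:
        return LittleResult(
            statistic=float("nan"), df=0, p_value=float("nan"), n_patterns=len(pattern_keys),
            n_iter=0, converged=True, applicable=False, variables=list(X.columns),
        )

    mu, Sigma, n_iter, converged, trace = _em_mvn(Y, tol=tol, max_iter=max_iter, ridge=ridge)
    if not converged:
        tail = ", ".join(f"{d:.3g}" for d in trace[-5:])
        raise EMConvergenceError(
            f"EM did not converge within {max_iter} iterations (last parameter "
            f"changes: {tail})"
        )

    d2 = 0.0
    df_sum = 0
    n_patterns = 0
    for key in pattern_keys:
        mis = np.asarray(key)
        obs = np.flatnonzero(~mis)
        if obs.size == 0:
            continue
        rows = np.flatnonzero((M == mis).all(axis=1))
        if rows.size == 0:
            continue
        n_patterns += 1
        ybar = Y[np.ix_(rows, obs)].mean(axis=0)
        diff = ybar - mu[obs]
        Soo = Sigma[np.ix_(obs, obs)]
        d2 += float(len(rows) * diff @ np.linalg.solve(Soo, diff))
        df_sum += obs.size
    dof = df_sum - p
    if dof <= 0:
        return LittleResult(
            statistic=float(d2), df=dof, p_value=float("nan"), n_patterns=n_patterns,
            n_iter=n_iter, converged=converged, applicable=False, variables=list(X.columns),
        )
    p_value = float(stats.chi2.sf(d2, dof))
    return LittleResult(
        statistic=float(d2), df=dof, p_value=p_value, n_patterns=n_patterns,
        n_iter=n_iter, converged=converged, applicable=True, variables=list(X.columns),
    )
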