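"""Group-3 diagnostic: is missingness associated with the outcome?

For each POC the missingness indicator enters an outcome model twice: a
univariate model (indicator only) and a fully adjusted model (indicator +
exposure + fully observed covariates + the other POCs' indicators, the
latter as indicators rather than values to avoid case deletion). The
signature across the two models separates mechanisms: no association in
either model is consistent with MCAR; a univariate association that
vanishes on adjustment with MAR; an association that persists after
adjustment with MNAR.

Supported outcome models: linear (continuous outcomes), GLM (default
binomial with logit link), and Cox proportional hazards (time-to-event,
Efron tie handling via lifelines). Coefficients are reported on the
coefficient scale — log hazard ratios for Cox, log odds for binomial —
with Wald 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable, Kind, RoleError
from .group1 import _encode_binary

__all__ = [
    "OutcomeModelSpec",
    "Estimate",
    "OutcomeAssociation",
    "outcome_association",
    "format_estimate",
]

_Z = 1.959963984540054  # normal 97.5% quantile


@dataclass
class OutcomeModelSpec:
    """Outcome model family and left-hand side.

    ``model`` in {"linear", "glm", "cox"}; ``lhs`` names the outcome
    column (or the (time, event) pair for Cox). Both default from the
    cohort's outcome roles.
    """

    model: str = "auto"
    glm_family: str = "binomial-logit"
    lhs: tuple[str, ...] | None = None

    def resolve(self, table: CohortTable) -> "OutcomeModelSpec":
        model = self.model
        if model == "auto":
            model = {"survival": "cox", "binary": "glm", "continuous": "linear"}.get(
                table.outcome_kind
            )
            if model is None:
                raise RoleError("cohort has no outcome columns; cannot fit outcome models")
        lhs = self.lhs
        if lhs is None:
            cols = table.outcome_cols
            if model == "cox":
                if table.outcome_kind != "survival":
                    raise RoleError("cox model requires a (time, event) outcome pair")
                lhs = tuple(cols[-2:])
            else:
                if not cols:
                    raise RoleError("no outcome column available")
                lhs = (cols[0],)
        if model == "cox" and len(lhs) != 2:
            raise RoleError("cox model needs lhs=(time, event)")
        if model in ("linear", "glm") and len(lhs) != 1:
            raise RoleError(f"{model} model needs a single outcome column")
        if model == "linear" and table.kinds.get(lhs[0]) == Kind.CATEGORICAL:
            raise RoleError("linear model requires a numeric outcome")
        return OutcomeModelSpec(model=model, glm_family=self.glm_family, lhs=tuple(lhs))


@dataclass
class Estimate:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class OutcomeAssociation:
    """Univariate and adjusted missingness-indicator coefficients for one POC."""

    poc: str
    model: str
    univariate: Estimate
    adjusted: Estimate
    adjusted_covariates: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        return (
            f"Outcome association for {self.poc!r} ({self.model}): "
            f"univariate {format_estimate(self.univariate)}, "
            f"adjusted {format_estimate(self.adjusted)}"
        )


def format_estimate(e: Estimate, digits: int = 2) -> str:
    """Render as e.g. ``-0.06 (-0.16 to 0.03)``."""
    f = f"{{:.{digits}f}}"
    return f"{f.format(e.beta)} ({f.format(e.ci_low)} to {f.format(e.ci_high)})"


def _adjustment_frame(table: CohortTable, poc: str, include_exposure: bool) -> pd.DataFrame:
    df = table.data
    cols: dict[str, pd.Series] = {}
    if include_exposure and table.exposure_col:
        cols[table.exposure_col] = df[table.exposure_col].astype(float)
    for col in table.covariate_cols:
        kind = table.kinds[col]
        if kind == Kind.CATEGORICAL:
            dummies = pd.get_dummies(df[col], prefix=col)
            for c in dummies.columns[1:]:
                cols[c] = dummies[c].astype(float)
        elif kind == Kind.BINARY:
            cols[col] = _encode_binary(df[col])
        else:
            cols[col] = df[col].astype(float)
    for other in table.poc_cols:
        if other != poc:
            cols[f"{other}_missing"] = df[other].isna().astype(float)
    X = pd.DataFrame(cols, index=df.index)
    return X.loc[:, X.std(ddof=0) > 0]


def _fit_cox(df: pd.DataFrame, time: str, event: str, term: str) -> Estimate:
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time, event_col=event)
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise RuntimeError(
            f"cox model failed to converge (covariates: {list(df.columns)}): {exc}"
        ) from exc
    beta = float(cph.params_[term])
    se = float(cph.standard_errors_[term])
    return Estimate(beta, se, beta - _Z * se, beta + _Z * se,
                    float(cph.summary.loc[term, "p"]))


def _fit_sm(y: pd.Series, X: pd.DataFrame, term: str, model: str, glm_family: str) -> Estimate:
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    try:
        if model == "linear":
            res = sm.OLS(y.astype(float), Xc).fit()
        else:
            if glm_family != "binomial-logit":
                raise ValueError(f"unsupported glm family {glm_family!r}")
            res = sm.GLM(y.astype(float), Xc, family=sm.families.Binomial()).fit()
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise RuntimeError(
            f"{model} model failed (covariates: {list(X.columns)}): {exc}"
        ) from exc
    beta = float(res.params[term])
    se = float(res.bse[term])
    return Estimate(beta, se, beta - _Z * se, beta + _Z * se, float(res.pvalues[term]))


def outcome_association(
    table: CohortTable,
    poc: str,
    spec: OutcomeModelSpec | None = None,
    *,
    include_exposure: bool = True,
) -> OutcomeAssociation:
    """Univariate and adjusted association between the POC's missingness
    indicator and the outcome, with Wald 95% CIs on the coefficient scale."""
    if poc not in table.poc_cols:
        raise RoleError(f"{poc!r} is not a POC in this table")
    spec = (spec or OutcomeModelSpec()).resolve(table)
    ind = pd.Series(table.indicator(poc), index=table.data.index, name=f"{poc}_missing")
    if ind.nunique() < 2:
        raise ValueError(f"missingness indicator for {poc!r} has a single class")
    adj = _adjustment_frame(table, poc, include_exposure)

    if spec.model == "cox":
        time, event = spec.lhs
        base = table.data[[time, event]].astype(float)
        uni_df = pd.concat([base, ind], axis=1)
        adj_df = pd.concat([base, ind, adj], axis=1)
        uni = _fit_cox(uni_df, time, event, ind.name)
        adjusted = _fit_cox(adj_df, time, event, ind.name)
    else:
        y = table.data[spec.lhs[0]]
        uni = _fit_sm(y, ind.to_frame(), ind.name, spec.model, spec.glm_family)
        adjusted = _fit_sm(
            y, pd.concat([ind, adj], axis=1), ind.name, spec.model, spec.glm_family
        )
    return OutcomeAssociation(
        poc=poc,
        model=spec.model,
        univariate=uni,
        adjusted=adjusted,
        adjusted_covariates=list(adj.columns),
    )
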