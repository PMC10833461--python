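"""Group-2 diagnostic: can missingness be predicted from observed data?

A random-forest classifier is trained on each POC's missingness indicator
with exposure, outcome (event flag and follow-up time separately for
survival outcomes), fully observed covariates, and the other POCs'
missingness indicators as predictors. A test-set AUC near 0.5 says the
missingness is unpredictable from observed data (consistent with MCAR or
MNAR); an AUC meaningfully above 0.5 points to MAR. AUCs above 0.9 are
flagged — when the top predictor is another POC's indicator, a monotone
missingness pattern is the likely cause and per-POC independent runs are
recommended.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .cohort import CohortTable, Kind, RoleError
from .group1 import _encode_binary

__all__ = ["RfResult", "rf_predict_missingness", "importance_barplot"]

INFLATED_AUC = 0.9


@dataclass
class RfResult:
    """Random-forest missingness-prediction result for one POC."""

    poc: str
    auc: float
    importances: pd.Series   # mean decrease in accuracy per predictor
    oob_error: float
    n_train: int
    n_test: int
    inflated: bool
    alert: str | None
    seed: int

    def __str__(self) -> str:
        head = f"RF missingness prediction for {self.poc!r}: AUC={self.auc:.3f} (OOB error {self.oob_error:.3f})"
        return head + (f"\n  ALERT: {self.alert}" if self.alert else "")


def _predictor_frame(table: CohortTable, poc: str) -> pd.DataFrame:
    df = table.data
    cols: dict[str, pd.Series] = {}
    if table.exposure_col:
        cols[table.exposure_col] = df[table.exposure_col].astype(float)
    for col in table.outcome_cols:  # follow-up time and event enter separately
        cols[col] = df[col].astype(float)
    for col in table.covariate_cols:
        kind = table.kinds[col]
        if kind == Kind.CATEGORICAL:
            dummies = pd.get_dummies(df[col], prefix=col)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
        elif kind == Kind.BINARY:
            cols[col] = _encode_binary(df[col])
        else:
            cols[col] = df[col].astype(float)
    for other in table.poc_cols:
        if other != poc:
            cols[f"{other}_missing"] = df[other].isna().astype(float)
    return pd.DataFrame(cols, index=df.index)


def rf_predict_missingness(
    table: CohortTable,
    poc: str,
    *,
    train_test_ratio: float = 0.7,
    ntree: int = 1000,
    n_cores: int = 1,
    seed: int = 0,
    importance_repeats: int = 10,
) -> RfResult:
    """Train a random forest on the POC's missingness indicator.

    A stratified ``train_test_ratio`` split; AUC from predicted class
    probabilities on the held-out split (midrank/trapezoidal tie
    convention); permutation importance ("mean decrease in accuracy",
    ``importance_repeats`` shuffles averaged per predictor, computed on
    the held-out split so that memorized noise scores near zero);
    out-of-bag error from the ensemble. Deterministic given ``seed``
    regardless of ``n_cores``.
    """
    if poc not in table.poc_cols:
        raise RoleError(f"{poc!r} is not a POC in this table")
    y = table.indicator(poc)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError(f"missingness indicator for {poc!r} has a single class")
    if counts.min() < 5:
        raise ValueError(
            f"need at least 5 cases per indicator class for {poc!r} (got {counts.min()})"
        )
    X = _predictor_frame(table, poc)
    rs = int(seed) % 2**31
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_test_ratio, stratify=y, random_state=rs
    )
    if min(np.bincount(y_te, minlength=2)) < 2:
        raise ValueError(
            f"fewer than 2 test cases per class for {poc!r}; use a larger dataset "
            "or a smaller train_test_ratio"
        )
    rf = RandomForestClassifier(
        n_estimators=ntree,
        max_features="sqrt",
        oob_score=True,
        n_jobs=n_cores,
        random_state=rs,
    )
    rf.fit(X_tr, y_tr)
    auc = float(roc_auc_score(y_te, rf.predict_proba(X_te)[:, 1]))
    if importance_repeats > 0:
        perm = permutation_importance(
            rf, X_te, y_te,
            scoring="accuracy", n_repeats=importance_repeats,
            random_state=rs, n_jobs=n_cores,
        )
        importances = pd.Series(perm.importances_mean, index=X.columns, name="mean_decrease_accuracy")
    else:
        importances = pd.Series(np.nan, index=X.columns, name="mean_decrease_accuracy")
    importances = importances.sort_values(ascending=False)
    oob_error = float(1.0 - rf.oob_score_)

    inflated = auc > INFLATED_AUC
    alert: str | None = None
    if inflated:
        if importances.notna().any():
            top = str(importances.index[0])
        else:  # fall back to impurity importances when permutation skipped
            top = str(X.columns[int(np.argmax(rf.feature_importances_))])
        alert = f"inflated AUC ({auc:.3f} > {INFLATED_AUC}); most important predictor: {top!r}"
        if top.endswith("_missing"):
            alert += (
                "; the top predictor is another POC's missingness indicator — a "
                "monotone missingness pattern is likely; rerun the diagnostics for "
                "each POC independently"
            )
    return RfResult(
        poc=poc,
        auc=auc,
        importances=importances,
        oob_error=oob_error,
        n_train=len(X_tr),
        n_test=len(X_te),
        inflated=inflated,
        alert=alert,
        seed=seed,
    )


def importance_barplot(result: RfResult, out: str | Path | None = None, ax=None):
    """Horizontal bar chart of the permutation variable importances."""
    import matplotlib

    if out is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    imp = result.importances.dropna().sort_values()
    ax.barh(imp.index, imp.to_numpy(), color="#4878b0")
    ax.set_xlabel("mean decrease in accuracy")
    ax.set_title(f"Predictors of missingness in {result.poc!r} (AUC {result.auc:.3f})")
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
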