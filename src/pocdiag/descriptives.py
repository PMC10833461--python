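"""Descriptive missingness summaries (counts, proportions, bar charts)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort import CohortTable, RoleError, detect_pocs

__all__ = ["MissingnessProfile", "missingness_summary", "missingness_barplot"]


@dataclass
class MissingnessProfile:
    """Per-POC missing counts and proportions, optionally stratified.

    ``table`` is tidy: one row per POC (per stratum level when stratified)
    with columns ``covariate``, optional ``stratum``, ``n_missing``,
    ``n_obs``, ``prop_missing``.
    """

    table: pd.DataFrame
    strata: str | None = None

    @property
    def pocs(self) -> list[str]:
        return list(dict.fromkeys(self.table["covariate"]))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    def __str__(self) -> str:
        out = self.table.copy()
        out["prop_missing"] = out["prop_missing"].map(lambda p: f"{p:.4f}")
        return out.to_string(index=False)


def missingness_summary(
    table: CohortTable,
    pocs: Sequence[str] | None = None,
    strata: str | None = None,
) -> MissingnessProfile:
    """Amount and proportion of missing observations per POC.

    When ``strata`` names a (fully observed) grouping column, counts and
    proportions are reported within each stratum level; the
    stratum-size-weighted mean of the proportions recovers the overall
    proportion.
    """
    poc_list = detect_pocs(table, pocs)
    df = table.data
    if strata is not None:
        if strata not in df.columns:
            raise RoleError(f"strata column {strata!r} not found")
        if df[strata].isna().any():
            raise RoleError(f"strata column {strata!r} has missing values")
    rows = []
    for poc in poc_list:
        miss = df[poc].isna()
        if strata is None:
            rows.append(
                {
                    "covariate": poc,
                    "n_missing": int(miss.sum()),
                    "n_obs": int((~miss).sum()),
                    "prop_missing": float(miss.mean()),
                }
            )
        else:
            for level, grp in miss.groupby(df[strata], sort=True):
                rows.append(
                    {
                        "covariate": poc,
                        "stratum": level,
                        "n_missing": int(grp.sum()),
                        "n_obs": int((~grp).sum()),
                        "prop_missing": float(grp.mean()),
                    }
                )
    return MissingnessProfile(table=pd.DataFrame(rows), strata=strata)


def missingness_barplot(
    profile: MissingnessProfile,
    out: str | Path | None = None,
    ax=None,
):
    """Bar chart of the missingness proportions (one bar per POC, grouped
    by stratum level when the profile is stratified). Returns the axes."""
    import matplotlib

    if out is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if profile.table.empty:
        raise ValueError("empty missingness profile; nothing to plot")

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    tab = profile.table
    if profile.strata is None:
        ax.bar(tab["covariate"], tab["prop_missing"], color="#4878b0")
    else:
        wide = tab.pivot(index="covariate", columns="stratum", values="prop_missing")
        wide = wide.loc[profile.pocs]
        k = wide.shape[1]
        width = 0.8 / k
        for j, level in enumerate(wide.columns):
            x = [i + (j - (k - 1) / 2) * width for i in range(len(wide))]
            ax.bar(x, wide[level], width=width, label=f"{profile.strata}={level}")
        ax.set_xticks(range(len(wide)))
        ax.set_xticklabels(wide.index)
        ax.legend()
    ax.set_ylabel("proportion missing")
    ax.set_xlabel("partially observed covariate")
    ax.set_ylim(0, 1)
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
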