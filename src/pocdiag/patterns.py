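"""Missing-data pattern structure: pattern-frequency matrix, upset-style
intersection counts, and monotone-pattern detection.

Convention note: pattern rows follow the ``md.pattern`` convention used
throughout the applied missing-data literature — **1 = observed, 0 =
missing** — which is the *inverse* of the missingness indicator returned
by :func:`pocdiag.cohort.missingness_indicator`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, detect_pocs

__all__ = ["PatternMatrix", "pattern_matrix", "intersection_counts", "is_monotone"]


@dataclass
class PatternMatrix:
    """Distinct missingness patterns over the POC columns.

    ``patterns``: one row per distinct pattern (1=observed, 0=missing),
    plus a ``count`` column, sorted by descending frequency with a
    deterministic lexicographic tie-break on the pattern bits.
    ``column_totals``: missing-cell count per POC.  ``monotone`` and
    ``monotone_order`` report whether some column ordering turns every
    pattern into an observed-prefix/missing-suffix staircase.
    """

    patterns: pd.DataFrame
    column_totals: pd.Series
    n_rows: int
    monotone: bool
    monotone_order: tuple[str, ...] | None

    @property
    def pocs(self) -> list[str]:
        return [c for c in self.patterns.columns if c != "count"]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.patterns.to_csv(path, index=False)
        return path


def _check_order(P: np.ndarray, order: Sequence[int]) -> bool:
    # monotone under `order` iff every pattern is non-increasing along it
    Q = P[:, list(order)]
    return bool(np.all(Q[:, :-1] >= Q[:, 1:]))


def _find_monotone_order(P: np.ndarray, names: Sequence[str]) -> tuple[bool, tuple[str, ...] | None]:
    k = P.shape[1]
    if k <= 8:
        # exhaustive permutation search; first hit wins
        for perm in itertools.permutations(range(k)):
            if _check_order(P, perm):
                return True, tuple(names[i] for i in perm)
        return False, None
    # larger sets: greedy order by ascending missingness, then verify
    miss = (P == 0).sum(axis=0)
    order = tuple(int(i) for i in np.argsort(miss, kind="stable"))
    if _check_order(P, order):
        return True, tuple(names[i] for i in order)
    return False, None


def pattern_matrix(table: CohortTable, pocs: Sequence[str] | None = None) -> PatternMatrix:
    """Frequency of each observed missing-data pattern over the POCs.

    Requires at least one POC. Pattern frequencies partition ``n_rows``;
    column totals equal the per-column missing counts.
    """
    poc_list = detect_pocs(table, pocs)
    if not poc_list:
        raise ValueError("pattern_matrix needs at least one POC")
    obs = (~table.data[poc_list].isna()).astype(int)
    counts = obs.value_counts(sort=False)
    rows = pd.DataFrame(
        [list(idx) if isinstance(idx, tuple) else [idx] for idx in counts.index],
        columns=poc_list,
    )
    rows["count"] = counts.to_numpy()
    # descending frequency; ties broken lexicographically on pattern bits
    rows = rows.sort_values(
        by=["count"] + poc_list, ascending=[False] + [True] * len(poc_list)
    ).reset_index(drop=True)
    totals = table.data[poc_list].isna().sum()
    mono, order = _find_monotone_order(rows[poc_list].to_numpy(), poc_list)
    return PatternMatrix(
        patterns=rows,
        column_totals=totals,
        n_rows=table.n,
        monotone=mono,
        monotone_order=order,
    )


def intersection_counts(
    table: CohortTable, pocs: Sequence[str] | None = None
) -> dict[frozenset, int]:
    """Upset-style counts: rows missing *exactly* each non-empty POC subset.

    The counts partition the rows that have at least one missing POC; they
    are a re-labelling of the pattern-matrix rows that contain a 0.
    """
    poc_list = detect_pocs(table, pocs)
    if not poc_list:
        raise ValueError("intersection_counts needs at least one POC")
    miss = table.data[poc_list].isna()
    out: dict[frozenset, int] = {}
    for pat, cnt in miss.value_counts(sort=False).items():
        bits = pat if isinstance(pat, tuple) else (pat,)
        subset = frozenset(p for p, m in zip(poc_list, bits) if m)
        if subset:
            out[subset] = out.get(subset, 0) + int(cnt)
    return out


def is_monotone(pm: PatternMatrix) -> tuple[bool, tuple[str, ...] | None]:
    """Whether some column permutation makes every pattern a staircase.

    Exhaustive permutation search for up to 8 POCs; above that, a greedy
    sort by missing count with verification.
    """
    return _find_monotone_order(pm.patterns[pm.pocs].to_numpy(), pm.pocs)
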