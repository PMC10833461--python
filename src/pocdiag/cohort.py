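"""Patient-level cohort data model with variable-role bookkeeping.

A :class:`CohortTable` wraps a rectangular pandas DataFrame in which one row
is one unique patient and each column plays a declared role: a binary
exposure, an outcome (continuous, binary, or a time/event pair), fully
observed covariates, or partially observed covariates (POCs).  Missing cells
are only permitted in POC columns; every diagnostic in this package
conditions on the exposure and outcome being complete.

Conventions
-----------
* Missing values are ``NaN`` in memory; on disk they are the empty string or
  a configurable sentinel (``"NA"`` by default).
* A column with at most two distinct non-missing values is *binary*; a
  numeric column with more is *continuous*; anything else is *categorical*.
  Both thresholds can be overridden per column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortError",
    "SchemaError",
    "RoleError",
    "FormatError",
    "Role",
    "Kind",
    "MissingnessMechanism",
    "CohortTable",
    "detect_pocs",
    "missingness_indicator",
    "load_cohort",
    "write_cohort",
    "DEFAULT_SENTINELS",
]

DEFAULT_SENTINELS: tuple[str, ...] = ("", "NA")


class CohortError(ValueError):
    """Base class for cohort validation problems."""


class SchemaError(CohortError):
    """Structural problem with the table (duplicate columns, bad header)."""


class RoleError(CohortError):
    """A column cannot play the role assigned to it."""


class FormatError(CohortError):
    """The on-disk file could not be parsed."""


class Role(str, Enum):
    EXPOSURE = "exposure"
    OUTCOME_CONTINUOUS = "outcome_continuous"
    OUTCOME_BINARY = "outcome_binary"
    OUTCOME_TIME = "outcome_time"
    OUTCOME_EVENT = "outcome_event"
    COVARIATE = "covariate"
    POC = "poc"
    EXCLUDED = "excluded"


class Kind(str, Enum):
    CONTINUOUS = "continuous"
    BINARY = "binary"
    CATEGORICAL = "categorical"


class MissingnessMechanism(str, Enum):
    """Closed vocabulary of missing-data mechanisms."""

    MCAR = "MCAR"
    MAR = "MAR"
    MNAR_VALUE = "MNAR_value"
    MNAR_UNMEASURED = "MNAR_unmeasured"
    INDETERMINATE = "indeterminate"


def infer_kind(values: pd.Series, binary_max_levels: int = 2) -> Kind:
    """Infer a column kind from its non-missing values.

    At most ``binary_max_levels`` distinct values -> binary; otherwise
    numeric -> continuous; otherwise categorical.
    """
    obs = values.dropna()
    if obs.nunique() <= binary_max_levels:
        return Kind.BINARY
    if pd.api.types.is_numeric_dtype(obs):
        return Kind.CONTINUOUS
    return Kind.CATEGORICAL


def _looks_like_identifier(values: pd.Series) -> bool:
    # all-unique object/integer columns are almost certainly identifiers
    obs = values.dropna()
    if len(obs) < 3 or obs.nunique() != len(obs):
        return False
    return obs.dtype == object or pd.api.types.is_integer_dtype(obs)


@dataclass
class CohortTable:
    """Validated patient-level table with role and kind assignments.

    Construct with :meth:`from_dataframe` (or :func:`load_cohort`) rather
    than directly; the constructor performs no validation.
    """

    data: pd.DataFrame
    roles: dict[str, Role]
    kinds: dict[str, Kind]

    # ------------------------------------------------------------------ #
    # construction
    # ------------------------------------------------------------------ #
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        exposure: str | None = None,
        outcome: str | None = None,
        time: str | None = None,
        event: str | None = None,
        covariates: Sequence[str] | None = None,
        pocs: Sequence[str] | None = None,
        exclude: Sequence[str] = (),
        kinds: Mapping[str, Kind | str] | None = None,
        binary_max_levels: int = 2,
    ) -> "CohortTable":
        """Validate a DataFrame and assign variable roles.

        ``pocs=None`` auto-detects every untagged column with at least one
        missing value. ``covariates=None`` takes all remaining fully
        observed columns.
        """
        if df.columns.duplicated().any():
            dupes = sorted(set(df.columns[df.columns.duplicated()]))
            raise SchemaError(f"duplicate column names: {dupes}")
        if len(df) < 2:
            raise CohortError("a cohort needs at least 2 rows")
        df = df.copy()

        def _need(col: str, what: str) -> None:
            if col not in df.columns:
                raise RoleError(f"{what} column {col!r} not found in table")

        roles: dict[str, Role] = {}
        for col in exclude:
            _need(col, "excluded")
            roles[col] = Role.EXCLUDED

        if (outcome is not None) and (time is not None or event is not None):
            raise RoleError("specify either a single outcome column or a time/event pair, not both")
        if (time is None) != (event is None):
            raise RoleError("time and event must be given together")

        kind_over = {k: Kind(v) for k, v in (kinds or {}).items()}

        def _kind(col: str) -> Kind:
            return kind_over.get(col, infer_kind(df[col], binary_max_levels))

        if exposure is not None:
            _need(exposure, "exposure")
            s = df[exposure]
            if s.isna().any():
                raise CohortError(
                    f"exposure column {exposure!r} has missing values; rows with missing "
                    "exposure/outcome must be resolved before diagnostics"
                )
            vals = set(pd.unique(s))
            if not vals <= {0, 1}:
                raise RoleError(f"exposure column {exposure!r} must be coded 0/1; found {sorted(map(str, vals))}")
            roles[exposure] = Role.EXPOSURE

        if outcome is not None:
            _need(outcome, "outcome")
            s = df[outcome]
            if s.isna().any():
                raise CohortError(f"outcome column {outcome!r} has missing values")
            k = _kind(outcome)
            if k == Kind.BINARY:
                if not set(pd.unique(s)) <= {0, 1}:
                    raise RoleError(f"binary outcome {outcome!r} must be coded 0/1")
                roles[outcome] = Role.OUTCOME_BINARY
            elif k == Kind.CONTINUOUS:
                roles[outcome] = Role.OUTCOME_CONTINUOUS
            else:
                raise RoleError(f"outcome column {outcome!r} is categorical; not supported")

        if time is not None and event is not None:
            _need(time, "time")
            _need(event, "event")
            t, e = df[time], df[event]
            if t.isna().any() or e.isna().any():
                raise CohortError("time/event outcome columns have missing values")
            if not pd.api.types.is_numeric_dtype(t) or (t <= 0).any():
                raise CohortError(f"follow-up time {time!r} must be numeric and > 0")
            if not set(pd.unique(e)) <= {0, 1}:
                raise RoleError(f"event column {event!r} must be coded 0/1")
            roles[time] = Role.OUTCOME_TIME
            roles[event] = Role.OUTCOME_EVENT

        if pocs is not None:
            for col in pocs:
                _need(col, "POC")
                if col in roles:
                    raise RoleError(f"column {col!r} already has role {roles[col].value}")
                if not df[col].isna().any():
                    raise RoleError(f"column {col!r} tagged as POC but is fully observed")
                roles[col] = Role.POC
        else:
            for col in df.columns:
                if col not in roles and df[col].isna().any():
                    roles[col] = Role.POC

        if covariates is not None:
            for col in covariates:
                _need(col, "covariate")
                if col in roles:
                    raise RoleError(f"column {col!r} already has role {roles[col].value}")
                roles[col] = Role.COVARIATE
        else:
            for col in df.columns:
                if col not in roles:
                    roles[col] = Role.COVARIATE

        for col in df.columns:
            if col not in roles:
                raise RoleError(f"column {col!r} has no role; tag it as covariate, poc, or excluded")
            if roles[col] == Role.COVARIATE and df[col].isna().any():
                raise RoleError(
                    f"covariate column {col!r} has missing values; tag it as a POC or exclude it"
                )

        for col in df.columns:
            if roles[col] in (Role.COVARIATE, Role.POC) and _looks_like_identifier(df[col]):
                warnings.warn(
                    f"column {col!r} looks like a patient identifier (all values unique); "
                    "identifier columns should be dropped or tagged 'excluded'",
                    UserWarning,
                    stacklevel=2,
                )

        kinds_out = {col: _kind(col) for col in df.columns}
        return cls(data=df, roles=roles, kinds=kinds_out)

    # ------------------------------------------------------------------ #
    # accessors
    # ------------------------------------------------------------------ #
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def _cols_with_role(self, role: Role) -> list[str]:
        return [c for c in self.data.columns if self.roles.get(c) == role]

    @property
    def exposure_col(self) -> str | None:
        cols = self._cols_with_role(Role.EXPOSURE)
        return cols[0] if cols else None

    @property
    def covariate_cols(self) -> list[str]:
        return self._cols_with_role(Role.COVARIATE)

    @property
    def poc_cols(self) -> list[str]:
        return self._cols_with_role(Role.POC)

    @property
    def outcome_kind(self) -> str:
        """One of ``'survival'``, ``'binary'``, ``'continuous'``, ``'none'``."""
        if self._cols_with_role(Role.OUTCOME_TIME):
            return "survival"
        if self._cols_with_role(Role.OUTCOME_BINARY):
            return "binary"
        if self._cols_with_role(Role.OUTCOME_CONTINUOUS):
            return "continuous"
        return "none"

    @property
    def outcome_cols(self) -> list[str]:
        """Outcome columns in role order (time before event for survival)."""
        return (
            self._cols_with_role(Role.OUTCOME_CONTINUOUS)
            + self._cols_with_role(Role.OUTCOME_BINARY)
            + self._cols_with_role(Role.OUTCOME_TIME)
            + self._cols_with_role(Role.OUTCOME_EVENT)
        )

    def indicator(self, poc: str) -> np.ndarray:
        """Missingness indicator: 1 where the POC value is missing."""
        return missingness_indicator(self, poc)

    def indicators(self, pocs: Sequence[str] | None = None) -> pd.DataFrame:
        pocs = list(pocs) if pocs is not None else self.poc_cols
        return pd.DataFrame(
            {p: self.data[p].isna().astype(int) for p in pocs}, index=self.data.index
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CohortTable(n={self.n}, exposure={self.exposure_col!r}, "
            f"outcome={self.outcome_kind}, covariates={len(self.covariate_cols)}, "
            f"pocs={self.poc_cols})"
        )


# ---------------------------------------------------------------------- #
# module-level operations
# ---------------------------------------------------------------------- #
def detect_pocs(
    table: CohortTable | pd.DataFrame, covar: Sequence[str] | None = None
) -> list[str]:
    """Return the POC set under investigation.

    With ``covar=None`` every column exhibiting at least one missing value
    is considered a POC; otherwise the explicit list is validated (each
    named column must exist and have at least one missing value).
    """
    df = table.data if isinstance(table, CohortTable) else table
    if covar is None:
        if isinstance(table, CohortTable):
            return table.poc_cols
        return [c for c in df.columns if df[c].isna().any()]
    out: list[str] = []
    for col in covar:
        if col not in df.columns:
            raise RoleError(f"column {col!r} not found in table")
        if not df[col].isna().any():
            raise RoleError(f"column {col!r} is fully observed and cannot be investigated as a POC")
        out.append(col)
    return out


def missingness_indicator(table: CohortTable | pd.DataFrame, poc: str) -> np.ndarray:
    """Binary vector: 1 = value missing, 0 = observed, length ``n_rows``."""
    df = table.data if isinstance(table, CohortTable) else table
    if poc not in df.columns:
        raise RoleError(f"column {poc!r} not found in table")
    return df[poc].isna().to_numpy(dtype=int)


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def load_cohort(
    path: str | Path,
    *,
    sep: str | None = None,
    sentinels: Iterable[str] = DEFAULT_SENTINELS,
    **roles,
) -> CohortTable:
    """Read a delimited patient-level file and validate it.

    Parameters
    ----------
    path
        CSV/TSV file with a header row. RFC-4180-style quoting is handled
        by the pandas reader.
    sep
        Field delimiter; inferred from the file extension when omitted.
    sentinels
        Strings encoding missing cells (default: empty string and ``"NA"``).
    **roles
        Forwarded to :meth:`CohortTable.from_dataframe` (``exposure=``,
        ``time=``, ``event=``, ``pocs=``, ...).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    delim = _infer_sep(path, sep)
    with open(path, "r", newline="") as fh:
        header_line = fh.readline()
    header = [h.strip().strip('"') for h in header_line.rstrip("\r\n").split(delim)]
    seen: set[str] = set()
    for h in header:
        if h in seen:
            raise SchemaError(f"duplicate column name in header: {h!r}")
        seen.add(h)
    try:
        df = pd.read_csv(
            path, sep=delim, na_values=list(sentinels), keep_default_na=False
        )
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    return CohortTable.from_dataframe(df, **roles)


def write_cohort(
    table: CohortTable, path: str | Path, *, sep: str | None = None, na_rep: str = ""
) -> Path:
    """Write the cohort back to a delimited file (missing cells -> ``na_rep``)."""
    path = Path(path)
    table.data.to_csv(path, sep=_infer_sep(path, sep), index=False, na_rep=na_rep)
    return path
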