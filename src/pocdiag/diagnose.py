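"""One-call missing-data diagnosis: model object, results, interpretation.

:class:`MissingnessDiagnostics` is the entry point of the package. It is
built from a :class:`~pocdiag.cohort.CohortTable` (or directly from a
DataFrame via :meth:`MissingnessDiagnostics.from_dataframe`) and its
:meth:`~MissingnessDiagnostics.fit` runs all three diagnostic groups for
every POC plus the global Little's MCAR test, returning a
:class:`DiagnosticsResults` whose :meth:`~DiagnosticsResults.summary`
prints the combined table (median ASMD with range, Hotelling p, RF AUC,
univariate and adjusted outcome coefficients, Little p footer) and whose
:meth:`~DiagnosticsResults.interpret` applies the mechanism-expectation
matrix to produce per-POC verdicts.

The verdict logic is deliberately advisory: MNAR-unmeasured is
unidentifiable from observed data and is never positively claimed, and
every report carries the caveat that no mechanism can be established with
certainty from observed data alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import json

import numpy as np
import pandas as pd

from .cohort import CohortTable, MissingnessMechanism, detect_pocs
from .descriptives import missingness_summary, missingness_barplot
from .group1 import AsmdResult, HotellingResult, LittleResult, asmd, hotelling, little_mcar
from .group2 import RfResult, rf_predict_missingness, importance_barplot
from .group3 import (
    Estimate,
    OutcomeAssociation,
    OutcomeModelSpec,
    format_estimate,
    outcome_association,
)

__all__ = [
    "Thresholds",
    "MechanismVerdict",
    "MissingnessDiagnostics",
    "DiagnosticsResults",
    "CAVEAT",
]

CAVEAT = (
    "The true mechanism behind missing data can never be established with "
    "certainty from the observed data alone; read these verdicts together "
    "with substantive knowledge of how each covariate is captured in care."
)


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for :meth:`DiagnosticsResults.interpret`.

    ``asmd`` — conventional 0.1 imbalance cut-off on the median ASMD;
    ``auc`` — operationalization of an AUC "meaningfully above 0.5";
    ``alpha`` — significance level for Hotelling's test.
    """

    asmd: float = 0.1
    auc: float = 0.55
    alpha: float = 0.05


@dataclass
class MechanismVerdict:
    poc: str
    label: MissingnessMechanism
    trace: list[str]
    caveat: str = CAVEAT

    def __str__(self) -> str:
        lines = "\n  ".join(self.trace)
        return f"{self.poc}: ~{self.label.value}\n  {lines}"


def _fmt_p(p: float) -> str:
    if np.isnan(p):
        return "NA"
    return "<.001" if p < 0.001 else f"{p:.3f}".lstrip("0") or ".000"


class MissingnessDiagnostics:
    """Structural missing-data investigation of a patient-level cohort.

    Parameters
    ----------
    cohort
        Validated cohort with exposure/outcome/covariate/POC roles.
    pocs
        POC subset to investigate; defaults to every column with at least
        one missing value.
    model, glm_family, lhs
        Outcome-model family for the Group-3 diagnostic (default inferred
        from the outcome roles: cox for time/event, glm-binomial for
        binary, linear for continuous).
    train_test_ratio, ntree, n_cores
        Random-forest settings for the Group-2 diagnostic.
    include_exposure
        Whether the exposure joins the Group-1 comparison set and the
        Group-3 adjustment set.
    asmd_aggregate
        "median" (default) or "mean" ASMD summary.
    """

    def __init__(
        self,
        cohort: CohortTable,
        *,
        pocs: Sequence[str] | None = None,
        model: str = "auto",
        glm_family: str = "binomial-logit",
        lhs: tuple[str, ...] | None = None,
        train_test_ratio: float = 0.7,
        ntree: int = 1000,
        n_cores: int = 1,
        include_exposure: bool = True,
        asmd_aggregate: str = "median",
    ) -> None:
        self.cohort = cohort
        self.pocs = detect_pocs(cohort, pocs)
        if not self.pocs:
            raise ValueError("no partially observed covariates to diagnose")
        self.spec = OutcomeModelSpec(model=model, glm_family=glm_family, lhs=lhs).resolve(cohort)
        self.train_test_ratio = train_test_ratio
        self.ntree = ntree
        self.n_cores = n_cores
        self.include_exposure = include_exposure
        self.asmd_aggregate = asmd_aggregate

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
        **kwargs,
    ) -> "MissingnessDiagnostics":
        cohort = CohortTable.from_dataframe(
            df,
            exposure=exposure,
            outcome=outcome,
            time=time,
            event=event,
            covariates=covariates,
            pocs=pocs,
            exclude=exclude,
        )
        return cls(cohort, **kwargs)

    def fit(self, seed: int = 0, importance_repeats: int = 10) -> "DiagnosticsResults":
        """Run every diagnostic; deterministic given ``seed``.

        A failure of one diagnostic for one POC is recorded as a flagged
        cell (NaN in the combined table) rather than aborting the run.
        """
        child_seeds = np.random.SeedSequence(seed).generate_state(len(self.pocs)) % 2**31
        asmd_res: dict[str, AsmdResult] = {}
        hot_res: dict[str, HotellingResult] = {}
        rf_res: dict[str, RfResult] = {}
        out_res: dict[str, OutcomeAssociation] = {}
        flags: dict[str, dict[str, str]] = {p: {} for p in self.pocs}

        for poc, s in zip(self.pocs, child_seeds):
            try:
                asmd_res[poc] = asmd(
                    self.cohort, poc,
                    aggregate=self.asmd_aggregate,
                    include_exposure=self.include_exposure,
                )
            except Exception as exc:  # per-cell graceful degradation
                flags[poc]["asmd"] = str(exc)
            try:
                hot_res[poc] = hotelling(
                    self.cohort, poc, include_exposure=self.include_exposure
                )
            except Exception as exc:
                flags[poc]["hotelling"] = str(exc)
            try:
                rf_res[poc] = rf_predict_missingness(
                    self.cohort, poc,
                    train_test_ratio=self.train_test_ratio,
                    ntree=self.ntree,
                    n_cores=self.n_cores,
                    seed=int(s),
                    importance_repeats=importance_repeats,
                )
            except Exception as exc:
                flags[poc]["rf"] = str(exc)
            try:
                out_res[poc] = outcome_association(
                    self.cohort, poc, self.spec, include_exposure=self.include_exposure
                )
            except Exception as exc:
                flags[poc]["outcome"] = str(exc)

        little: LittleResult | None = None
        little_error: str | None = None
        try:
            little = little_mcar(self.cohort, self.pocs)
        except Exception as exc:
            little_error = str(exc)

        rows = []
        for poc in self.pocs:
            a = asmd_res.get(poc)
            h = hot_res.get(poc)
            r = rf_res.get(poc)
            o = out_res.get(poc)
            rows.append(
                {
                    "covariate": poc,
                    "asmd_median": a.aggregate if a else np.nan,
                    "asmd_min": a.asmd_min if a else np.nan,
                    "asmd_max": a.asmd_max if a else np.nan,
                    "hotelling_p": h.p_value if h else np.nan,
                    "auc": r.auc if r else np.nan,
                    "beta_univariate": o.univariate.beta if o else np.nan,
                    "beta_univariate_low": o.univariate.ci_low if o else np.nan,
                    "beta_univariate_high": o.univariate.ci_high if o else np.nan,
                    "beta_adjusted": o.adjusted.beta if o else np.nan,
                    "beta_adjusted_low": o.adjusted.ci_low if o else np.nan,
                    "beta_adjusted_high": o.adjusted.ci_high if o else np.nan,
                }
            )
        frame = pd.DataFrame(rows).set_index("covariate")
        return DiagnosticsResults(
            model=self,
            frame_=frame,
            little_=little,
            little_error=little_error,
            asmd_=asmd_res,
            hotelling_=hot_res,
            rf_=rf_res,
            outcome_=out_res,
            flags=flags,
            seed=seed,
        )


@dataclass
class DiagnosticsResults:
    """Fitted three-group diagnostics for every POC.

    ``frame_`` holds the numeric combined table (one row per POC);
    the per-group result objects sit in ``asmd_``/``hotelling_``/``rf_``/
    ``outcome_`` keyed by POC, with the single global Little result in
    ``little_``. Failed cells are NaN with the error text in ``flags``.
    """

    model: MissingnessDiagnostics
    frame_: pd.DataFrame
    little_: LittleResult | None
    little_error: str | None
    asmd_: Mapping[str, AsmdResult]
    hotelling_: Mapping[str, HotellingResult]
    rf_: Mapping[str, RfResult]
    outcome_: Mapping[str, OutcomeAssociation]
    flags: Mapping[str, Mapping[str, str]]
    seed: int

    # ------------------------------------------------------------------ #
    @property
    def little_p(self) -> float:
        return self.little_.p_value if self.little_ is not None else float("nan")

    def to_frame(self, formatted: bool = False) -> pd.DataFrame:
        """Combined table; ``formatted=True`` renders display strings."""
        if not formatted:
            return self.frame_.copy()
        out = pd.DataFrame(index=self.frame_.index)
        f = self.frame_
        out["ASMD (min/max)"] = [
            f"{r.asmd_median:.3f} ({r.asmd_min:.3f}, {r.asmd_max:.3f})"
            if np.isfinite(r.asmd_median) else "failed"
            for r in f.itertuples()
        ]
        out["P Hotelling"] = [_fmt_p(p) if np.isfinite(p) else "failed" for p in f["hotelling_p"]]
        out["AUC"] = [f"{a:.3f}" if np.isfinite(a) else "failed" for a in f["auc"]]
        out["Beta univariate (95% CI)"] = [
            format_estimate(self.outcome_[p].univariate) if p in self.outcome_ else "failed"
            for p in f.index
        ]
        out["beta (95% CI)"] = [
            format_estimate(self.outcome_[p].adjusted) if p in self.outcome_ else "failed"
            for p in f.index
        ]
        return out

    # ------------------------------------------------------------------ #
    def interpret(self, thresholds: Thresholds | None = None) -> dict[str, MechanismVerdict]:
        """Apply the mechanism-expectation matrix to each POC.

        Rules (thresholds configurable): *imbalance* = median ASMD above
        the cut-off or Hotelling p below alpha; *predictable* = AUC at or
        above the AUC cut-off; *associations* = 95% CI excluding 0 in the
        univariate / adjusted outcome model. Then::

            no imbalance & not predictable & no association either model -> MCAR
            imbalance & predictable & univariate only                    -> MAR
            no imbalance & not predictable & adjusted association        -> MNAR_value
            anything else (or failed cells)                              -> indeterminate

        MNAR-unmeasured is never positively claimed: it is observationally
        indistinguishable from MCAR on these diagnostics.
        """
        thr = thresholds or Thresholds()
        verdicts: dict[str, MechanismVerdict] = {}
        for poc in self.frame_.index:
            row = self.frame_.loc[poc]
            fl = self.flags.get(poc, {})
            if fl:
                trace = [f"{grp} diagnostic failed: {msg}" for grp, msg in fl.items()]
                verdicts[poc] = MechanismVerdict(
                    poc, MissingnessMechanism.INDETERMINATE, trace
                )
                continue
            imbalance = bool(
                (row["asmd_median"] > thr.asmd) or (row["hotelling_p"] < thr.alpha)
            )
            predictable = bool(row["auc"] >= thr.auc)
            uni = not (row["beta_univariate_low"] <= 0.0 <= row["beta_univariate_high"])
            adj = not (row["beta_adjusted_low"] <= 0.0 <= row["beta_adjusted_high"])
            trace = [
                f"median ASMD {row['asmd_median']:.3f} {'>' if row['asmd_median'] > thr.asmd else '<='} {thr.asmd}"
                f" and Hotelling p {_fmt_p(row['hotelling_p'])} -> {'imbalance' if imbalance else 'no imbalance'}",
                f"AUC {row['auc']:.3f} {'>=' if predictable else '<'} {thr.auc} -> "
                f"{'predictable' if predictable else 'not predictable'}",
                f"univariate CI [{row['beta_univariate_low']:.3f}, {row['beta_univariate_high']:.3f}] "
                f"{'excludes' if uni else 'covers'} 0",
                f"adjusted CI [{row['beta_adjusted_low']:.3f}, {row['beta_adjusted_high']:.3f}] "
                f"{'excludes' if adj else 'covers'} 0",
            ]
            if not imbalance and not predictable and not uni and not adj:
                label = MissingnessMechanism.MCAR
                trace.append(
                    "note: an MNAR mechanism driven by unmeasured covariates would "
                    "look identical on these diagnostics"
                )
            elif imbalance and predictable and uni and not adj:
                label = MissingnessMechanism.MAR
            elif not imbalance and not predictable and adj:
                label = MissingnessMechanism.MNAR_VALUE
            else:
                label = MissingnessMechanism.INDETERMINATE
                trace.append("fired rules do not match a single mechanism signature")
            verdicts[poc] = MechanismVerdict(poc, label, trace)
        return verdicts

    # ------------------------------------------------------------------ #
    def summary(self, thresholds: Thresholds | None = None) -> str:
        """Human-readable combined report (Table-2-style layout)."""
        lines = [
            "Structural missing-data diagnostics",
            "=" * 72,
            f"n = {self.model.cohort.n} patients; outcome model: {self.model.spec.model}; "
            f"POCs: {', '.join(self.frame_.index)}",
            "",
            self.to_frame(formatted=True).to_string(),
            "",
        ]
        if self.little_ is not None:
            lines.append(str(self.little_))
        else:
            lines.append(f"Little's MCAR test failed: {self.little_error}")
        lines.append("")
        verdicts = self.interpret(thresholds)
        lines.append("Mechanism verdicts (advisory):")
        for poc, v in verdicts.items():
            lines.append(f"  {poc}: ~{v.label.value}")
        for poc, r in self.rf_.items():
            if r.alert:
                lines.append(f"  ALERT [{poc}]: {r.alert}")
        lines += ["", CAVEAT]
        return "\n".join(lines)

    # ------------------------------------------------------------------ #
    def _markdown_table(self, df: pd.DataFrame) -> str:
        cols = ["covariate"] + list(df.columns)
        head = "| " + " | ".join(cols) + " |"
        sep = "| " + " | ".join("---" for _ in cols) + " |"
        body = [
            "| " + " | ".join([str(idx)] + [str(v) for v in row]) + " |"
            for idx, row in zip(df.index, df.to_numpy())
        ]
        return "\n".join([head, sep] + body)

    def save_report(self, out_dir: str | Path, thresholds: Thresholds | None = None) -> list[Path]:
        """Write the combined table (CSV + markdown + HTML), a
        full-precision JSON companion, and the figure set. Returns the
        written paths."""
        out_dir = Path(out_dir)
        try:
            out_dir.mkdir(parents=True, exist_ok=True)
            probe = out_dir / ".write_probe"
            probe.write_text("")
            probe.unlink()
        except OSError as exc:
            raise OSError(f"cannot write report to {out_dir}: {exc}") from exc

        written: list[Path] = []
        fmt = self.to_frame(formatted=True)
        footer = (
            f"Global Little's MCAR test p: {_fmt_p(self.little_p)}"
            if self.little_ is not None
            else f"Little's MCAR test failed: {self.little_error}"
        )
        verdicts = self.interpret(thresholds)

        csv_path = out_dir / "report.csv"
        fmt.to_csv(csv_path)
        written.append(csv_path)

        md_path = out_dir / "report.md"
        md = [
            "# Structural missing-data diagnostics",
            "",
            self._markdown_table(fmt),
            "",
            footer,
            "",
            "## Mechanism verdicts (advisory)",
            "",
        ]
        for poc, v in verdicts.items():
            md.append(f"- **{poc}**: ~{v.label.value}")
            for t in v.trace:
                md.append(f"  - {t}")
        md += ["", f"> {CAVEAT}"]
        md_path.write_text("\n".join(md))
        written.append(md_path)

        html_path = out_dir / "report_table.html"
        html = (
            "<html><body><h1>Structural missing-data diagnostics</h1>"
            + fmt.to_html()
            + f"<p>{footer}</p><p><em>{CAVEAT}</em></p></body></html>"
        )
        html_path.write_text(html)
        written.append(html_path)

        # machine-readable full precision companion
        json_path = out_dir / "report.json"
        payload = {
            "seed": self.seed,
            "table": self.frame_.reset_index().to_dict(orient="records"),
            "little": None
            if self.little_ is None
            else {
                "statistic": self.little_.statistic,
                "df": self.little_.df,
                "p_value": self.little_.p_value,
                "n_patterns": self.little_.n_patterns,
            },
            "verdicts": {p: v.label.value for p, v in verdicts.items()},
            "flags": {p: dict(f) for p, f in self.flags.items() if f},
            "caveat": CAVEAT,
        }
        json_path.write_text(json.dumps(payload, indent=2, default=float))
        written.append(json_path)

        # figures: missingness bars + per-POC importance plots
        profile = missingness_summary(self.model.cohort, list(self.frame_.index))
        bar_path = out_dir / "missingness_bars.png"
        missingness_barplot(profile, out=bar_path)
        written.append(bar_path)
        for poc, r in self.rf_.items():
            if r.importances.notna().any():
                p_path = out_dir / f"importance_{poc}.png"
                importance_barplot(r, out=p_path)
                written.append(p_path)
        return written
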