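"""Orchestrated diagnosis: combined table, interpretation matrix, reports."""

import numpy as np
import pandas as pd
import pytest

from pocdiag import (
    MissingnessDiagnostics,
    MissingnessMechanism,
    Thresholds,
    simulate_cohort,
)
from pocdiag.diagnose import DiagnosticsResults, CAVEAT


@pytest.fixture(scope="module")
def fitted():
    cohort = simulate_cohort(n=1200, seed=77)
    model = MissingnessDiagnostics(cohort, ntree=200)
    return model.fit(seed=77, importance_repeats=1)


class TestFit:
    def test_table_structure(self, fitted):
        assert list(fitted.frame_.index) == ["ecog", "egfr", "pdl1"]
        assert fitted.little_ is not None and fitted.little_.applicable
        assert not fitted.frame_.isna().any().any()

    def test_rerun_identical(self):
        cohort = simulate_cohort(n=600, seed=5)
        kwargs = dict(ntree=100)
        r1 = MissingnessDiagnostics(cohort, **kwargs).fit(seed=9, importance_repeats=1)
        r2 = MissingnessDiagnostics(cohort, **kwargs).fit(seed=9, importance_repeats=1)
        pd.testing.assert_frame_equal(r1.frame_, r2.frame_)
        assert r1.little_.statistic == r2.little_.statistic

    def test_cells_equal_standalone_runs(self, fitted):
        """The orchestrator adds nothing numerically: each cell equals the
        single-function output run standalone with the same seed."""
        from pocdiag import asmd, hotelling, little_mcar, outcome_association, rf_predict_missingness

        cohort = fitted.model.cohort
        seeds = np.random.SeedSequence(77).generate_state(3) % 2**31
        for poc, s in zip(["ecog", "egfr", "pdl1"], seeds):
            row = fitted.frame_.loc[poc]
            assert row["asmd_median"] == asmd(cohort, poc).aggregate
            assert row["hotelling_p"] == hotelling(cohort, poc).p_value
            assert row["auc"] == rf_predict_missingness(
                cohort, poc, ntree=200, seed=int(s), importance_repeats=0
            ).auc
            assert row["beta_adjusted"] == outcome_association(cohort, poc).adjusted.beta
        assert fitted.little_.statistic == little_mcar(cohort, ["ecog", "egfr", "pdl1"]).statistic

    def test_graceful_per_cell_failure(self):
        """A cohort engineered to break Hotelling (collinear covariates)
        flags that cell but still fills the others."""
        rng = np.random.default_rng(3)
        n = 300
        a = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "a": a,
                "b": 2.0 * a,  # collinear -> singular pooled covariance
                "poc": np.where(rng.random(n) < 0.3, np.nan, rng.normal(size=n)),
                "y": rng.normal(size=n),
            }
        )
        model = MissingnessDiagnostics.from_dataframe(df, outcome="y", ntree=50)
        res = model.fit(seed=0, importance_repeats=0)
        assert "hotelling" in res.flags["poc"]
        assert np.isnan(res.frame_.loc["poc", "hotelling_p"])
        assert np.isfinite(res.frame_.loc["poc", "auc"])
        verdict = res.interpret()["poc"]
        assert verdict.label == MissingnessMechanism.INDETERMINATE


class TestInterpret:
    def _result_with(self, asmd_med, hot_p, auc, uni_ci, adj_ci):
        frame = pd.DataFrame(
            {
                "asmd_median": [asmd_med],
                "asmd_min": [0.0],
                "asmd_max": [asmd_med * 2],
                "hotelling_p": [hot_p],
                "auc": [auc],
                "beta_univariate": [np.mean(uni_ci)],
                "beta_univariate_low": [uni_ci[0]],
                "beta_univariate_high": [uni_ci[1]],
                "beta_adjusted": [np.mean(adj_ci)],
                "beta_adjusted_low": [adj_ci[0]],
                "beta_adjusted_high": [adj_ci[1]],
            },
            index=pd.Index(["poc"], name="covariate"),
        )
        return DiagnosticsResults(
            model=None, frame_=frame, little_=None, little_error=None,
            asmd_={}, hotelling_={}, rf_={}, outcome_={}, flags={"poc": {}}, seed=0,
        )

    def test_mcar_signature(self):
        res = self._result_with(0.03, 0.78, 0.51, (-0.1, 0.1), (-0.1, 0.1))
        assert res.interpret()["poc"].label == MissingnessMechanism.MCAR

    def test_mar_signature(self):
        res = self._result_with(0.24, 1e-4, 0.63, (0.04, 0.22), (-0.1, 0.09))
        assert res.interpret()["poc"].label == MissingnessMechanism.MAR

    def test_mnar_value_signature(self):
        res = self._result_with(0.06, 0.2, 0.52, (0.01, 0.23), (0.01, 0.22))
        assert res.interpret()["poc"].label == MissingnessMechanism.MNAR_VALUE

    def test_conflicting_rules_indeterminate(self):
        # imbalance + predictable but association persists after adjustment
        res = self._result_with(0.3, 1e-4, 0.65, (0.1, 0.3), (0.1, 0.3))
        v = res.interpret()["poc"]
        assert v.label == MissingnessMechanism.INDETERMINATE
        assert v.trace

    def test_thresholds_configurable(self):
        res = self._result_with(0.07, 0.5, 0.57, (-0.1, 0.1), (-0.1, 0.1))
        # default AUC cut-off 0.55: predictable without imbalance -> indeterminate
        assert res.interpret()["poc"].label == MissingnessMechanism.INDETERMINATE
        # raising the cut-off makes the same numbers read as MCAR
        assert res.interpret(Thresholds(auc=0.6))["poc"].label == MissingnessMechanism.MCAR

    def test_mnar_unmeasured_never_claimed(self, fitted):
        labels = {v.label for v in fitted.interpret().values()}
        assert MissingnessMechanism.MNAR_UNMEASURED not in labels

    def test_caveat_always_present(self, fitted):
        for v in fitted.interpret().values():
            assert v.caveat == CAVEAT
        assert CAVEAT in fitted.summary()


class TestReport:
    def test_report_files(self, fitted, tmp_path):
        written = fitted.save_report(tmp_path / "report")
        names = {p.name for p in written}
        assert {"report.csv", "report.md", "report_table.html", "report.json"} <= names
        figures = [p for p in written if p.suffix == ".png"]
        assert len(figures) >= 2

    def test_json_round_trips_full_precision(self, fitted, tmp_path):
        import json

        written = fitted.save_report(tmp_path / "r2")
        payload = json.loads([p for p in written if p.name == "report.json"][0].read_text())
        by_cov = {row["covariate"]: row for row in payload["table"]}
        for poc in fitted.frame_.index:
            assert by_cov[poc]["auc"] == fitted.frame_.loc[poc, "auc"]

    def test_summary_layout(self, fitted):
        s = fitted.summary()
        assert "ASMD (min/max)" in s
        assert "Little" in s
        assert "ecog" in s and "pdl1" in s
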