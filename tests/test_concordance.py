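import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import yaml

import ehrlink.synthetic as syn
from ehrlink.concordance import (
    COMPARISON_CHARACTERISTICS,
    PipelineConfig,
    cohort_comparison,
    missingness_report,
    overlap_from_counts,
    overlap_summary,
    run_pipeline,
    stratified_table,
)

DATA = Path(__file__).parent / "data"

# fixture-bundle study conditions: small cohort, inflated case rate so every
# stratum and characteristic is populated
FIXTURE_SEED = 20210821
FIXTURE_N = 400
FIXTURE_P_DEMENTIA = 0.30


def fixture_bundle():
    cfg = syn.default_config(seed=FIXTURE_SEED, n_patients=FIXTURE_N)
    cfg.p_dementia = FIXTURE_P_DEMENTIA
    return syn.generate(cfg)


def _fake_covariates(n_per_stratum=40):
    rng = np.random.default_rng(7)
    rows = []
    for stratum in ("BOTH", "SPECIALIST_ONLY", "PRIMARY_ONLY"):
        for i in range(n_per_stratum):
            rows.append(
                {
                    "patient_id": f"{stratum}-{i}",
                    "stratum": stratum,
                    "age_group": rng.choice(["65_74", "75_84", "85_PLUS"]),
                    "sex": rng.choice(["F", "M"]),
                    "ethnicity6": rng.choice(["WHITE_BRITISH", "BLACK", "MISSING"]),
                    "imd_q1": rng.choice([True, False]),
                    "smoking": rng.choice(["NEVER", "FORMER", "CURRENT", "MISSING"]),
                    "consult_count": int(rng.integers(0, 50)),
                    "consult_cat": rng.choice(["ABOVE_AVERAGE", "AVERAGE_OR_LESS", "NONE"]),
                    "care_home": bool(rng.random() < 0.2),
                    "charlson": 1,
                    "charlson_cat": rng.choice(["0", "1", "2_3"]),
                    "charlson_high": bool(rng.random() < 0.2),
                    "died_in_followup": bool(rng.random() < 0.3),
                    "full_followup": True,
                    "subtype": rng.choice(["ALZHEIMERS_MIXED", "VASCULAR", "UNSPECIFIED"]),
                    "medicated": bool(rng.random() < 0.3),
                }
            )
    return pd.DataFrame(rows)


class TestOverlap:
    def test_published_stratum_counts(self):
        ov = overlap_from_counts(n_both=2886, n_specialist_only=1380, n_primary_only=973)
        assert ov.n_union == 5239
        assert ov.n_primary == 3859 and ov.n_specialist == 4266
        assert round(ov.pct_both_of_union) == 55
        assert round(ov.pct_overlap_of_primary) == 75
        assert round(ov.pct_overlap_of_specialist) == 68

    def test_disjoint_sources(self):
        ov = overlap_from_counts(0, 10, 10)
        assert ov.pct_both_of_union == 0.0

    def test_identical_sources(self):
        ov = overlap_from_counts(10, 0, 0)
        assert ov.pct_both_of_union == 100.0
        assert ov.pct_overlap_of_primary == 100.0

    def test_empty_cohort(self):
        ov = overlap_summary(pd.DataFrame(columns=["stratum"]))
        assert ov.n_union == 0 and ov.pct_both_of_union is None


class TestStratifiedTable:
    def test_fixture_percentages(self):
        # 2x3 known counts -> 75/25, 25/75, 50/50
        rows = []
        for stratum, (a, b) in zip(
            ("BOTH", "SPECIALIST_ONLY", "PRIMARY_ONLY"), [(30, 10), (10, 30), (20, 20)]
        ):
            rows += [{"stratum": stratum, "sex": "F"}] * a + [{"stratum": stratum, "sex": "M"}] * b
        table = stratified_table(pd.DataFrame(rows), "sex")
        assert table.percentages.loc["BOTH", "F"] == pytest.approx(75.0)
        assert table.percentages.loc["SPECIALIST_ONLY", "F"] == pytest.approx(25.0)
        assert table.percentages.loc["PRIMARY_ONLY", "M"] == pytest.approx(50.0)
        assert table.chi2 is not None and table.chi2.df == 2

    def test_missing_category_excluded_from_denominator(self):
        cov = _fake_covariates()
        table = stratified_table(cov, "ethnicity6")
        assert "MISSING" in table.counts.columns
        assert "MISSING" not in table.percentages.columns
        # non-missing percentages sum to 100 per stratum
        assert np.allclose(table.percentages.sum(axis=1), 100.0)

    def test_empty_stratum_fatal(self):
        cov = _fake_covariates()
        cov = cov[cov["stratum"] != "PRIMARY_ONLY"]
        with pytest.raises(ValueError, match="PRIMARY_ONLY"):
            stratified_table(cov, "sex")

    def test_unknown_variable_fatal(self):
        with pytest.raises(ValueError, match="unknown table variable"):
            stratified_table(_fake_covariates(), "shoe_size")


class TestCohortComparison:
    def test_published_care_home_row(self):
        # feed the printed stratum-level tallies through the comparison path
        rows = []
        # care-home positives: specialist cohort 270, primary cohort 334, via
        # stratum splits both=231, spec-only=39, prim-only=103 (231+39=270, 231+103=334)
        for stratum, n, pos in [("BOTH", 2886, 231), ("SPECIALIST_ONLY", 1380, 39), ("PRIMARY_ONLY", 973, 103)]:
            for i in range(n):
                rows.append({"stratum": stratum, "care_home": i < pos, "full_followup": True})
        row = cohort_comparison(pd.DataFrame(rows), "care_home")
        assert (row.x1, row.n1, row.x2, row.n2) == (270, 4266, 334, 3859)
        assert round(row.result.pr, 2) == 0.73
        assert round(row.result.lo, 2) == 0.63 and round(row.result.hi, 2) == 0.85

    def test_identical_cohorts_give_unity(self):
        cov = _fake_covariates()
        cov = cov[cov["stratum"] == "BOTH"]
        cov = pd.concat(
            [cov, cov.assign(stratum="SPECIALIST_ONLY"), cov.assign(stratum="PRIMARY_ONLY")]
        )
        for name in COMPARISON_CHARACTERISTICS:
            row = cohort_comparison(cov, name)
            assert row.result.pr == pytest.approx((row.x1 / row.n1) / (row.x2 / row.n2))
            assert row.result.pr == pytest.approx(1.0, abs=1e-9)

    def test_stratum_tally_identity(self):
        cov = _fake_covariates()
        for name, (col, positive) in COMPARISON_CHARACTERISTICS.items():
            row = cohort_comparison(cov, name)
            df = cov if name != "medicated" else cov[cov["full_followup"]]
            pos = df[col] == positive
            both = int((pos & (df["stratum"] == "BOTH")).sum())
            sonly = int((pos & (df["stratum"] == "SPECIALIST_ONLY")).sum())
            ponly = int((pos & (df["stratum"] == "PRIMARY_ONLY")).sum())
            assert row.x1 == both + sonly
            assert row.x2 == both + ponly

    def test_unknown_characteristic_fatal(self):
        with pytest.raises(ValueError, match="valid"):
            cohort_comparison(_fake_covariates(), "hat_size")


class TestMissingness:
    def test_counts_and_formatting(self):
        cov = _fake_covariates()
        rep = missingness_report(cov).set_index("variable")
        n_eth = int((cov["ethnicity6"] == "MISSING").sum())
        assert rep.loc["ethnicity", "n_missing"] == n_eth
        assert rep.loc["ethnicity", "pct_missing"].endswith("%")

    def test_all_and_none_missing(self):
        cov = _fake_covariates()
        cov["smoking"] = "MISSING"
        cov["ethnicity6"] = "WHITE_BRITISH"
        rep = missingness_report(cov).set_index("variable")
        assert rep.loc["smoking", "pct_missing"] == "100%"
        assert rep.loc["ethnicity", "pct_missing"] == "0.0%"


class TestPipeline:
    def _write_inputs(self, tmp_path):
        bundle = fixture_bundle()
        paths = syn.write_bundle(bundle, tmp_path / "inputs")
        config = {
            "patients": str(paths["patients"]),
            "events": str(paths["events"]),
            "consultations": str(paths["consultations"]),
            "prescriptions": str(paths["prescriptions"]),
            "codelist": str(paths["codelist"]),
            "imd_lookup": str(paths["imd_lookup"]),
            "median_override": 23,
            "care_home_lookback": "unlimited",
        }
        cfg_path = tmp_path / "config.yaml"
        cfg_path.write_text(yaml.safe_dump(config))
        return cfg_path

    def test_missing_input_file_fatal_before_compute(self, tmp_path):
        cfg_path = self._write_inputs(tmp_path)
        cfg = PipelineConfig.from_yaml(cfg_path)
        cfg.events = str(tmp_path / "absent.csv")
        with pytest.raises(FileNotFoundError, match="events"):
            run_pipeline(cfg)

    def test_report_generation_is_pure(self, tmp_path):
        cfg_path = self._write_inputs(tmp_path)
        cfg = PipelineConfig.from_yaml(cfg_path)
        run_pipeline(cfg, out_dir=tmp_path / "out1")
        run_pipeline(cfg, out_dir=tmp_path / "out2")
        for f in sorted((tmp_path / "out1").iterdir()):
            a = f.read_bytes()
            b = (tmp_path / "out2" / f.name).read_bytes()
            assert a == b, f.name

    def test_outputs_match_golden_files(self, tmp_path):
        """Regression: fixture inputs reproduce the committed report files byte-for-byte."""
        cfg_path = self._write_inputs(tmp_path)
        cfg = PipelineConfig.from_yaml(cfg_path)
        out = tmp_path / "out"
        bundle = run_pipeline(cfg, out_dir=out)
        golden = DATA / "golden"
        produced = {p.name for p in out.iterdir() if p.name != "manifest.json"}
        expected = {p.name for p in golden.iterdir()}
        assert produced == expected
        for name in sorted(expected):
            assert (out / name).read_text() == (golden / name).read_text(), name
        # manifest records the decision switches (paths vary, so compare keys)
        assert bundle.manifest["care_home_lookback"] == "unlimited"
        assert bundle.manifest["consult_median"] == 23
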