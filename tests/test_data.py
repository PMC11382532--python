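"""Patient-level datasets: schema, I/O, synthesis and the analysis workflow."""

import math

import numpy as np
import pandas as pd
import pytest

from fillitup import (
    DesignSpec,
    ScenarioMeans,
    analyze_step,
    analyze_trial,
    generate_synthetic_dataset,
    read_dataset,
    stage_plan,
    write_dataset,
    z_ept,
    z_s1,
)
from fillitup.data import COLUMNS, DatasetFormatError, TrialDataset


@pytest.fixture()
def dataset(ataxia_spec, ataxia_plan):
    sc = ScenarioMeans(mu_e=0.275, mu_c=0.0, mu_h=0.05)
    return generate_synthetic_dataset(sc, ataxia_plan, 500, seed=123, stage=1)


@pytest.fixture()
def dataset2(ataxia_spec, ataxia_plan):
    sc = ScenarioMeans(mu_e=0.275, mu_c=0.0, mu_h=1.5)
    return generate_synthetic_dataset(sc, ataxia_plan, 500, seed=124, stage=2)


class TestSchemaAndIO:
    def test_generated_counts(self, dataset, ataxia_plan):
        counts = dataset.counts()
        assert counts[("H", "historical")] == 500
        assert counts[("E", "initial")] == ataxia_plan.n_e == 96
        assert counts[("C", "initial")] == 96
        assert len(dataset.frame) == 692
        assert dataset.frame["PatID"].is_unique

    def test_stage2_adds_further_records(self, dataset2, ataxia_plan):
        counts = dataset2.counts()
        assert counts[("E", "further")] == ataxia_plan.n_e2 == 68
        assert counts[("C", "further")] == 68
        assert len(dataset2.frame) == 692 + 136

    def test_roundtrip_identity(self, dataset, tmp_path):
        path = tmp_path / "fiudata.csv"
        write_dataset(dataset, path)
        back = read_dataset(path)
        pd.testing.assert_frame_equal(back.frame, dataset.frame)

    def test_same_seed_same_dataset(self, ataxia_plan):
        sc = ScenarioMeans(0.1, 0.0, 0.0)
        a = generate_synthetic_dataset(sc, ataxia_plan, 500, seed=7)
        b = generate_synthetic_dataset(sc, ataxia_plan, 500, seed=7)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_group_means_approach_scenario_means(self):
        from fillitup.design import StagePlan

        plan = StagePlan(n_e=20_000, n_c=20_000, n_e2=0, n_c2=0, gamma=1.0)
        sc = ScenarioMeans(0.3, -0.1, 0.2)
        ds = generate_synthetic_dataset(sc, plan, 20_000, seed=3)
        s = ds.summary()
        assert s.mean_e == pytest.approx(0.3, abs=0.03)
        assert s.mean_c == pytest.approx(-0.1, abs=0.03)
        assert s.mean_h == pytest.approx(0.2, abs=0.03)

    def test_case_insensitive_codes_canonicalized(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(
            "PatID,Group,Recruitment,Response\n"
            "1,h,HISTORICAL,0.1\n2,e,Initial,0.2\n3,c,initial,0.3\n"
        )
        ds = read_dataset(path)
        assert list(ds.frame["Group"]) == ["H", "E", "C"]
        assert list(ds.frame["Recruitment"]) == ["historical", "initial", "initial"]

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(DatasetFormatError):
            read_dataset(path)
        path.write_text("PatID,Group,Recruitment,Response\n")
        with pytest.raises(DatasetFormatError):
            read_dataset(path)

    @pytest.mark.parametrize("row, message", [
        ("4,X,initial,0.1", "unknown group"),
        ("4,E,sometime,0.1", "unknown recruitment"),
        ("4,H,initial,0.1", "must coincide"),
        ("4,E,initial,abc", "non-numeric"),
    ])
    def test_malformed_rows_reported_with_line_numbers(self, tmp_path, row, message):
        path = tmp_path / "bad.csv"
        path.write_text(
            "PatID,Group,Recruitment,Response\n"
            "1,H,historical,0.0\n2,E,initial,0.1\n3,C,initial,0.2\n" + row + "\n"
        )
        with pytest.raises(DatasetFormatError, match=message) as err:
            read_dataset(path)
        assert "5" in str(err.value)  # 1-based line number incl. header

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "PatID,Group,Recruitment,Response\n"
            "1,H,historical,0.0\n1,E,initial,0.1\n"
        )
        with pytest.raises(DatasetFormatError, match="duplicate"):
            read_dataset(path)

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "hdr.csv"
        path.write_text("id,arm,when,value\n1,H,historical,0.0\n")
        with pytest.raises(DatasetFormatError, match="header"):
            read_dataset(path)


class TestAnalysisWorkflow:
    def test_pretest_matches_direct_formula(self, dataset, ataxia_spec):
        result, report = analyze_step(dataset, ataxia_spec, "pretest")
        s = dataset.summary()
        direct = z_ept(s, ataxia_spec.margin, ataxia_spec.alpha_ept)
        assert result.statistic == pytest.approx(direct.statistic, rel=1e-12)
        assert "pre-test" in report.lower()

    def test_s1_matches_direct_formula_and_info_fraction(self, dataset, ataxia_spec):
        with pytest.warns(UserWarning):  # tight margin: pre-test rarely rejects
            result, report = analyze_step(dataset, ataxia_spec, "s1")
        s = dataset.summary()
        direct = z_s1(s, ataxia_spec.alpha_s1)
        assert result.statistic == pytest.approx(direct.statistic, rel=1e-12)
        # historical share of control information: 500 of 596 patients
        assert f"{100 * 500 / 596:.1f}" in report

    def test_s2_requires_further_records(self, dataset, ataxia_spec):
        with pytest.raises(DatasetFormatError, match="further"):
            analyze_step(dataset, ataxia_spec, "s2")

    def test_s2_on_full_dataset(self, dataset2, ataxia_spec):
        result, report = analyze_step(dataset2, ataxia_spec, "s2")
        s = dataset2.summary(stage=2)
        se = math.sqrt(1 / 164 + 1 / 164)
        assert result.statistic == pytest.approx(
            (s.mean_e_full - s.mean_c_full) / se, rel=1e-12
        )
        assert "100.0% randomized" in report

    def test_s1_after_failed_pretest_warns(self, dataset2, ataxia_spec):
        # mu_H = 1.5: the pre-test cannot establish equivalence
        with pytest.warns(UserWarning, match="pre-test did not reject"):
            analyze_step(dataset2, ataxia_spec, "s1")

    def test_workflow_equals_combined_decision_rule(self, ataxia_spec, ataxia_plan):
        """The dataset-level analysis reproduces the decision function on
        the individual test results, over a spread of generated trials."""
        from fillitup import fill_it_up_decision, z_s2

        for seed, mu_h in [(1, 0.0), (2, 0.0), (3, 1.0), (4, -0.4), (5, 0.1)]:
            sc = ScenarioMeans(0.275, 0.0, mu_h)
            ds = generate_synthetic_dataset(sc, ataxia_plan, 500, seed=seed, stage=2)
            res = analyze_trial(ds, ataxia_spec)
            s = ds.summary(stage=2)
            ept = z_ept(s, ataxia_spec.margin, ataxia_spec.alpha_ept)
            if ept.reject:
                expected = fill_it_up_decision(ept, s1=z_s1(s, 0.05))
                assert res["branch"] == "S1"
            else:
                expected = fill_it_up_decision(ept, s2=z_s2(s, 0.05))
                assert res["branch"] == "S2"
            assert res["decision"] == expected

    def test_repeated_analysis_reproduces_simulation_rates(
        self, ataxia_spec, ataxia_plan
    ):
        """Analyzing many generated datasets at a null scenario gives a
        rejection rate consistent with the vectorized Monte-Carlo engine."""
        from fillitup import SimulationConfig, monte_carlo_oc

        sc = ScenarioMeans(0.0, 0.0, 3 * ataxia_spec.margin)
        n_trials = 400
        rejections = sum(
            analyze_trial(
                generate_synthetic_dataset(sc, ataxia_plan, 500, seed=s, stage=2),
                ataxia_spec,
            )["decision"]
            for s in range(n_trials)
        )
        mc = monte_carlo_oc(SimulationConfig(scenario=sc, plan=ataxia_plan,
                                             spec=ataxia_spec, n_replicates=50_000,
                                             seed=0))
        se = math.sqrt(mc.reject_rate * (1 - mc.reject_rate) / n_trials)
        assert abs(rejections / n_trials - mc.reject_rate) <= 3 * se

    def test_missing_stratum_raises(self, ataxia_spec):
        frame = pd.DataFrame(
            [(1, "H", "historical", 0.0), (2, "E", "initial", 0.1)],
            columns=COLUMNS,
        )
        ds = TrialDataset(frame)
        with pytest.raises(DatasetFormatError, match="C/initial"):
            analyze_step(ds, ataxia_spec, "pretest")

    def test_nonfinite_response_rejected(self):
        frame = pd.DataFrame(
            [(1, "H", "historical", np.nan), (2, "E", "initial", 0.1),
             (3, "C", "initial", 0.2)],
            columns=COLUMNS,
        )
        with pytest.raises(DatasetFormatError, match="non-finite"):
            TrialDataset(frame)
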