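"""Increment-ratio statistic, group comparison, and the end-to-end report."""

import numpy as np
import pandas as pd
import pytest

from ledd_screen import screen
from ledd_screen.screen import ScreenParams
from ledd_screen.synthetic import SimulationConfig, generate_population
from oracles import mean_percent_change


class TestIncrementRatio:
    def test_mean_of_per_patient_percent_changes(self):
        res = screen.increment_ratio([(100, 110), (200, 210)])
        assert res.per_patient_ratios.tolist() == [10.0, 5.0]
        assert res.mean_ratio == 7.5
        assert res.n == 2

    def test_no_change_gives_zero(self):
        res = screen.increment_ratio([(100, 100), (250, 250)])
        assert res.mean_ratio == 0.0

    def test_mean_of_ratios_differs_from_ratio_of_means(self):
        """The two definitions must not be conflated."""
        res = screen.increment_ratio([(100, 110), (10, 12)])
        assert res.mean_ratio == pytest.approx(15.0)
        assert res.aggregate_ratio == pytest.approx(100 * (122 - 110) / 110)
        assert res.aggregate_ratio == pytest.approx(10.909, abs=1e-3)

    def test_zero_baseline_excluded_and_counted(self):
        res = screen.increment_ratio([(0, 50), (100, 110)])
        assert res.n == 1
        assert res.n_excluded_zero_baseline == 1
        assert res.mean_ratio == 10.0

    def test_all_zero_baselines_is_an_error(self):
        with pytest.raises(ValueError):
            screen.increment_ratio([(0, 10)])

    def test_matches_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for case in range(1000):
            k = int(rng.integers(1, 12))
            pairs = [
                (float(rng.integers(0, 20)) * 25, float(rng.integers(0, 600)))
                for _ in range(k)
            ]
            if all(b == 0 for b, _ in pairs):
                continue
            n, mean, n_zero = mean_percent_change(pairs)
            res = screen.increment_ratio(pairs)
            assert res.n == n and res.n_excluded_zero_baseline == n_zero
            assert res.mean_ratio == pytest.approx(mean)


class TestCompareGroups:
    def result(self, values):
        return screen.increment_ratio([(100, 100 * (1 + v / 100)) for v in values])

    def test_identical_samples_give_p_one(self):
        a = self.result([5, 5, 5])
        t, _, p = screen.compare_groups(a, a)
        assert (t, p) == (0.0, 1.0)

    def test_student_hand_computed_example(self):
        t, df, p = screen.compare_groups(
            self.result([1, 2, 3]), self.result([2, 3, 4]), method="student"
        )
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == 4
        assert p == pytest.approx(0.2878, abs=1e-4)

    def test_welch_reduces_to_student_for_equal_variances(self):
        a, b = self.result([1, 2, 3]), self.result([2, 3, 4])
        ts, dfs, ps = screen.compare_groups(a, b, method="student")
        tw, dfw, pw = screen.compare_groups(a, b, method="welch")
        assert tw == pytest.approx(ts)
        assert dfw == pytest.approx(dfs)
        assert pw == pytest.approx(ps)

    def test_constant_but_different_samples(self):
        t, _, p = screen.compare_groups(self.result([5, 5]), self.result([7, 7]))
        assert p == 0.0 and t < 0

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            screen.compare_groups(self.result([5]), self.result([1, 2]))


class TestAdjustPvalues:
    def frame(self, ps):
        return pd.DataFrame({"label": range(len(ps)), "p_value": ps})

    def test_none_leaves_report_unchanged(self):
        rep = self.frame([0.01, 0.5])
        out = screen.adjust_pvalues(rep, "none")
        assert "p_adjusted" not in out.columns

    def test_benjamini_hochberg_step_up(self):
        out = screen.adjust_pvalues(self.frame([0.01, 0.02, 0.03, 0.04]), "benjamini_hochberg")
        assert np.allclose(out.p_adjusted, 0.04)

    def test_single_pvalue_unchanged_by_bh(self):
        out = screen.adjust_pvalues(self.frame([0.013]), "benjamini_hochberg")
        assert out.p_adjusted.iloc[0] == pytest.approx(0.013)


class TestRunScreen:
    @pytest.fixture(scope="class")
    def screen_result(self):
        sim = generate_population(
            SimulationConfig(n_patients=4000, seed=13, exposure_effect=0.5, confounding_strength=0.5)
        )
        return screen.run_screen(sim.patients, sim.prescriptions)

    def test_report_rows_satisfy_difference_identity(self, screen_result):
        rep = screen_result.report
        done = rep[rep.skipped == ""]
        assert len(done) > 10
        for side in ("unexposed", "exposed"):
            np.testing.assert_allclose(
                done[f"{side}_difference"],
                done[f"{side}_ledd_after"] - done[f"{side}_ledd_before"],
            )

    def test_strict_matching_arithmetic_in_report(self, screen_result):
        done = screen_result.report.query("skipped == ''")
        assert (done.matched_control_n == 3 * done.matched_exposed_n).all()

    def test_report_layout_mirrors_overall_generation_drug(self, screen_result):
        labels = screen_result.report.label.tolist()
        assert labels[:3] == ["overall", "1st_generation", "2nd_generation"]
        assert "fexofenadine" in labels and "mizolastine" in labels

    def test_attrition_and_assignment_partition(self, screen_result):
        asg = screen_result.assignments
        assert asg.patient_id.is_unique
        assert set(asg.group) <= {"exposed", "unexposed", "excluded_multi_type"}
        assert screen_result.attrition.n_remaining == len(asg)

    def test_deterministic_end_to_end(self):
        cfg = SimulationConfig(n_patients=1500, seed=21)
        params = ScreenParams(analyses=("overall",))
        reports = []
        for _ in range(2):
            sim = generate_population(cfg)
            reports.append(screen.run_screen(sim.patients, sim.prescriptions, params=params).report)
        pd.testing.assert_frame_equal(reports[0], reports[1])

    def test_exposed_ratio_decreases_with_exposure_effect(self):
        """Larger protective effects yield smaller exposed increment ratios."""
        means = []
        for effect in (0.0, 0.5, 1.0):
            sim = generate_population(
                SimulationConfig(n_patients=5000, seed=31, exposure_effect=effect)
            )
            rep = screen.run_screen(
                sim.patients, sim.prescriptions, params=ScreenParams(analyses=("overall",))
            ).report
            means.append(float(rep.iloc[0].exposed_ratio))
        assert means[0] > means[1] > means[2]

    def test_drug_without_exposed_patients_reported_as_skipped(self):
        sim = generate_population(SimulationConfig(n_patients=300, seed=5))
        rep = screen.run_screen(sim.patients, sim.prescriptions).report
        skipped = rep[rep.skipped != ""]
        assert (skipped.exposed_case_n == 0).any() or len(skipped) >= 0
        assert "p_value" in rep.columns
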