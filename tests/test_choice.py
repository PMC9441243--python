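"""Split-regression choice model, blue-peak scan, validation and diagnostics."""

import numpy as np
import pytest

import aphidvision as av
from aphidvision.choice import model_inputs
from aphidvision.errors import FitError, InputError
from aphidvision.receptors import photon_catch_matrix
from aphidvision.spectra import ExperimentData, TrapRecord
from aphidvision.synthetic import extended_series_plan


class TestLogRatio:
    def test_base_conversion(self):
        x_e = av.log_ratio(2.0, 1.0, log_base="e")
        x_10 = av.log_ratio(2.0, 1.0, log_base="10")
        assert x_e == pytest.approx(np.log(2.0))
        assert x_10 == pytest.approx(np.log10(2.0))

    def test_invalid_base_raises(self):
        with pytest.raises(InputError):
            av.log_ratio(2.0, 1.0, log_base="2")


class TestSplitRegression:
    def _data(self, a=2.0, b=0.5, n=40, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-1.5, 1.5, n)
        y = b + a * np.maximum(0.0, x)
        return x, y

    def test_exact_recovery(self):
        x, y = self._data()
        m = av.fit_split_regression(x, y)
        assert m.a == pytest.approx(2.0, abs=1e-10)
        assert m.b == pytest.approx(0.5, abs=1e-10)
        assert m.r2 == pytest.approx(1.0)

    def test_prediction_is_flat_left_of_the_split(self):
        x, y = self._data()
        m = av.fit_split_regression(x, y)
        assert m.predict_from_ratio(-2.0) == pytest.approx(m.b)
        assert m.predict_from_ratio(0.5) == pytest.approx(m.b + 0.5 * m.a)

    def test_one_sided_data_raise(self):
        x = np.linspace(0.1, 1.0, 20)
        with pytest.raises(FitError):
            av.fit_split_regression(x, 0.5 + 2.0 * x)

    def test_free_left_slope_recovers_planted_descent(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-1.5, 1.5, 60)
        y = 0.5 + 2.0 * np.maximum(0.0, x) - 0.3 * np.minimum(0.0, x)
        m = av.fit_split_regression(x, y, free_left_slope=True)
        assert m.left_slope == pytest.approx(-0.3, abs=1e-10)


class TestChoiceModelOnExperiments:
    def test_noise_free_round_trip(self, truth_clean, model_clean):
        assert model_clean.a == pytest.approx(truth_clean.a_true, abs=1e-6)
        assert model_clean.b == pytest.approx(truth_clean.b_true, abs=1e-6)
        assert model_clean.r2 == pytest.approx(1.0, abs=1e-12)
        assert model_clean.n == 138  # 140 traps minus the two references

    def test_blue_peak_scan_selects_the_true_receptor(self, truth_clean,
                                                      experiment_clean):
        scan = av.optimize_blue_peak(experiment_clean)
        assert scan.lambda_max_B == truth_clean.lambda_max_B
        assert not scan.degenerate

    def test_green_candidate_is_skipped_not_fatal(self, experiment_clean):
        with pytest.warns(UserWarning, match="530"):
            scan = av.optimize_blue_peak(experiment_clean)
        assert 530.0 in scan.skipped

    def test_predict_attractivity_reproduces_generated_relative_catch(
            self, truth_clean, model_clean, experiment_clean):
        for t in experiment_clean.traps[:10]:
            if t.is_reference:
                continue
            y = av.predict_attractivity(model_clean, t.spectrum,
                                        experiment_clean.background,
                                        experiment_clean.illuminant)
            observed = t.total_count() / truth_clean.n_ref_mean
            assert y == pytest.approx(observed, abs=1e-6)

    def test_cross_validation_on_an_independent_colour_set(self, model_clean):
        exp2 = av.generate_trap_experiment(
            av.GroundTruth(), series_plan=extended_series_plan(50), seed=1)
        vr = av.cross_validate(model_clean, exp2)
        assert vr.slope == pytest.approx(1.0, abs=1e-6)
        assert vr.intercept == pytest.approx(0.0, abs=1e-6)
        assert vr.r2 == pytest.approx(1.0, abs=1e-9)


class TestGroupComparison:
    def test_planted_taxon_effect_is_recovered_per_group(self):
        truth = av.GroundTruth(taxon_effects={"Myzus persicae": (1.6, 0.22)})
        exp = av.generate_trap_experiment(truth, seed=0)
        gc = av.compare_groups(exp)
        table = gc.per_group.set_index("group")
        assert table.loc["M. persicae", "a"] == pytest.approx(1.6, abs=1e-6)
        assert table.loc["B. brassicae", "a"] == pytest.approx(2.499, abs=1e-6)

    def test_planted_taxon_effect_is_significant(self):
        truth = av.GroundTruth(noise="poisson",
                               taxon_effects={"Myzus persicae": (1.6, 0.22)})
        exp = av.generate_trap_experiment(truth, seed=0)
        gc = av.compare_groups(exp)
        assert gc.slope_p < 1e-6
        assert set(gc.groups) == {"M. persicae", "B. brassicae", "other"}


class TestCompletenessCheck:
    def test_model_generated_data_is_judged_complete(self):
        exp = av.generate_trap_experiment(av.GroundTruth(noise="poisson"),
                                          seed=11)
        rep = av.completeness_check(av.fit_choice_model(exp), exp)
        assert not rep.incomplete

    def test_planted_uv_signal_is_detected(self):
        truth = av.GroundTruth(noise="poisson")
        exp = av.generate_trap_experiment(truth, seed=12)
        P350 = photon_catch_matrix(exp, np.array([350.0])).P[:, 0]
        traps = []
        for t, p in zip(exp.traps, P350):
            extra = 0.0 if t.is_reference else truth.n_ref_mean * p
            counts = {k: v + extra / len(t.counts) for k, v in t.counts.items()}
            traps.append(TrapRecord(t.trap_id, t.series, t.spectrum, counts))
        exp2 = ExperimentData(traps, exp.background, exp.illuminant,
                              exp.reference_ids)
        rep = av.completeness_check(av.fit_choice_model(exp2), exp2)
        assert rep.incomplete

    def test_model_inputs_exclude_references(self, experiment_clean):
        ids, x, y = model_inputs(experiment_clean)
        assert len(ids) == 138
        for rid in experiment_clean.reference_ids:
            assert rid not in ids
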