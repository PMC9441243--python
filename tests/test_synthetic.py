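"""Synthetic trap-experiment and wheat-leaf generators."""

import numpy as np
import pytest

import aphidvision as av
from aphidvision.errors import InputError
from aphidvision.synthetic import (DEFAULT_TREATMENTS, chlorophyll_depth,
                                   default_series_plan, extended_series_plan,
                                   leaf_reflectance, make_paint_bases,
                                   mix_paints)


class TestPaints:
    def test_bases_are_valid_reflectances(self):
        for base in make_paint_bases(seed=0).values():
            base.reflectance.validate_reflectance(base.name)
            assert np.all(base.reflectance.value <= 1.0)

    def test_mixture_lies_between_constituents(self):
        bases = make_paint_bases(seed=1)
        mix = mix_paints({"yellow": 0.4, "black": 0.6}, bases)
        y = bases["yellow"].reflectance.value
        k = bases["black"].reflectance.value
        lo = np.minimum(y, np.maximum(k, 1e-4))
        hi = np.maximum(np.maximum(y, 1e-4), np.maximum(k, 1e-4))
        assert np.all(mix.value >= lo - 1e-12)
        assert np.all(mix.value <= hi + 1e-12)

    def test_weights_must_sum_to_one(self):
        bases = make_paint_bases(seed=0)
        with pytest.raises(InputError):
            mix_paints({"yellow": 0.5, "black": 0.4}, bases)

    def test_unknown_base_is_reported(self):
        bases = make_paint_bases(seed=0)
        with pytest.raises(InputError, match="magenta"):
            mix_paints({"magenta": 1.0}, bases)


class TestSeriesPlans:
    def test_default_plan_shape(self):
        plan = default_series_plan(70)
        assert len(plan) == 70
        assert sum(p.is_reference for p in plan) == 1
        assert sum(p.series == "yellow-black" for p in plan) == 10
        # the primary plan uses only the four 2007-style paints
        used = {name for p in plan for name in p.weights}
        assert used <= {"yellow", "blue", "white", "black"}

    def test_extended_plan_adds_hue_series(self):
        plan = extended_series_plan(70)
        assert len(plan) == 70
        series = {p.series for p in plan}
        assert {"green-black", "red-white", "uv-yellow"} <= series

    def test_too_small_budget_raises(self):
        with pytest.raises(InputError):
            default_series_plan(5)


class TestTrapGenerator:
    def test_replicate_structure(self, experiment_clean):
        assert len(experiment_clean.traps) == 140
        names = {t.trap_id.rsplit("-", 1)[0] for t in experiment_clean.traps}
        assert len(names) == 70
        assert len(experiment_clean.reference_ids) == 2

    def test_reference_traps_hit_the_nominal_mean(self, truth_clean,
                                                  experiment_clean):
        for rid in experiment_clean.reference_ids:
            assert experiment_clean.trap(rid).total_count() == pytest.approx(
                truth_clean.n_ref_mean)

    def test_noise_free_replicates_are_identical(self, experiment_clean):
        counts = experiment_clean.counts_total()
        by_name = {}
        for t, c in zip(experiment_clean.traps, counts):
            by_name.setdefault(t.trap_id.rsplit("-", 1)[0], []).append(c)
        for name, pair in by_name.items():
            assert pair[0] == pytest.approx(pair[1]), name

    def test_taxon_shares_respected_noise_free(self, truth_clean,
                                               experiment_clean):
        rid = experiment_clean.reference_ids[0]
        counts = experiment_clean.trap(rid).counts
        for taxon, share in truth_clean.taxon_shares.items():
            assert counts[taxon] == pytest.approx(share * truth_clean.n_ref_mean)

    def test_poisson_seeds_are_reproducible(self):
        truth = av.GroundTruth(noise="poisson")
        e1 = av.generate_trap_experiment(truth, seed=7)
        e2 = av.generate_trap_experiment(truth, seed=7)
        assert np.array_equal(e1.counts_total(), e2.counts_total())

    def test_invalid_taxon_shares_raise(self):
        with pytest.raises(InputError):
            av.GroundTruth(taxon_shares={"a": 0.5, "b": 0.2})

    def test_invalid_noise_mode_raises(self):
        with pytest.raises(InputError):
            av.GroundTruth(noise="gaussian")


class TestLeafGenerator:
    def test_campaign_shape(self, leaves_clean):
        assert len(leaves_clean) == len(DEFAULT_TREATMENTS) * 3 * 6
        plots = {l.plot_id for l in leaves_clean}
        assert len(plots) == len(DEFAULT_TREATMENTS) * 3

    def test_depth_monotone_in_mineral_n(self):
        depths = [chlorophyll_depth(n, "none") for n in (0, 60, 110, 160)]
        assert np.all(np.diff(depths) > 0)

    def test_green_peak_shrinks_with_depth(self):
        at550 = [leaf_reflectance(d).interp(np.array([550.0]))[0]
                 for d in (0.3, 0.6, 1.0)]
        assert np.all(np.diff(at550) < 0)

    def test_noise_free_leaves_identical_within_treatment(self, leaves_clean):
        by_treat = {}
        for l in leaves_clean:
            by_treat.setdefault((l.organic_level, l.mineral_n), []).append(l)
        for group in by_treat.values():
            ref = group[0].spectrum.value
            for l in group[1:]:
                assert np.allclose(l.spectrum.value, ref)
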