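"""Synthetic generator: trajectories, sampling, rendering, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vped.config import PORE_FEATURES, RenderConfig, HistologyNoise
from vped.ensembles import weibull_cdf
from vped.morphometry import polygon_area, pore_features
from vped.synthetic import (CohortNoise, TrajectoryTable,
                            build_hormone_reference, generate_cohort,
                            render_image, sample_features)


class TestTrajectoryTable:
    def test_deterministic_lookup(self, trajectories):
        p1 = trajectories.params(18, "pore_area")
        p2 = trajectories.params(18, "pore_area")
        assert (p1.b, p1.lam, p1.gamma) == (p2.b, p2.lam, p2.gamma)

    def test_unknown_feature_names_valid_ones(self, trajectories):
        with pytest.raises(KeyError, match="pore_area"):
            trajectories.params(18, "nope")

    def test_day_out_of_range(self, trajectories):
        with pytest.raises(ValueError):
            trajectories.params(5, "pore_area")

    def test_shape_parameter_regimes(self, trajectories):
        """Pore-area PDFs stay left-skewed; pore length develops an interior
        mode only in the merging window; vessel diameters always have one."""
        for day in trajectories.days:
            assert trajectories.params(day, "pore_area").gamma < 1.0
            assert trajectories.params(day, "bv_diameter").gamma > 1.0
            length_gamma = trajectories.params(day, "pore_length").gamma
            if 20 <= day <= 22:
                assert length_gamma > 1.0
            elif day <= 18 or day >= 24:
                assert length_gamma < 1.0

    def test_positive_scale_and_shape_everywhere(self, trajectories):
        for f in trajectories.features:
            for d in trajectories.days:
                p = trajectories.params(d, f)
                assert p.lam > 0 and p.gamma > 0 and p.b >= 0


class TestSampleFeatures:
    def test_empty_sample(self):
        assert len(sample_features(20, 0, seed=1)) == 0

    def test_row_counts_per_kind(self):
        t = sample_features(17, 25, seed=1)
        assert (t["kind"] == "pore").sum() == 25
        assert (t["kind"] == "vessel").sum() == 25

    def test_seed_reproducibility(self):
        a = sample_features(21, 100, seed=42)
        b = sample_features(21, 100, seed=42)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("feature,day", [("pore_area", 15),
                                             ("pore_length", 21),
                                             ("bv_diameter", 28)])
    def test_draws_match_analytic_cpdf(self, trajectories, feature, day):
        """Empirical cPDF of 5000 draws vs the closed-form Weibull cPDF."""
        t = sample_features(day, 5000, seed=7, table=trajectories)
        x = t.loc[t[feature].notna(), feature].to_numpy()
        params = trajectories.params(day, feature)
        res = stats.kstest(x, lambda v: weibull_cdf(v, params))
        assert res.statistic < 0.03
        assert res.pvalue > 0.01


class TestRenderImage:
    def test_empty_sample_pure_background(self):
        img, truth = render_image(sample_features(20, 0, seed=1), seed=2)
        assert truth.pore_polygons == []
        assert truth.vessel_centerlines == []
        cfg = RenderConfig()
        assert abs(img.mean() - cfg.background) < 0.01

    def test_single_circular_pore_area(self):
        fs = pd.DataFrame([{"kind": "pore", "pore_area": np.pi * 100.0,
                            "pore_length": 20.0, "pore_curvature": 0.1,
                            "pore_tortuosity": 1.0}])
        img, truth = render_image(fs, seed=3)
        assert len(truth.pore_polygons) == 1
        area = polygon_area(truth.pore_polygons[0])
        assert area == pytest.approx(np.pi * 100.0, rel=0.02)

    def test_count_conservation(self, benchmark_scene):
        _, truth = benchmark_scene
        assert len(truth.pore_polygons) == 50
        assert len(truth.vessel_centerlines) == 10

    def test_truth_in_image_extent(self, benchmark_scene):
        _, truth = benchmark_scene
        h, w = truth.image_spec.extent_um
        for poly in truth.pore_polygons:
            assert poly[:, 0].min() >= 0 and poly[:, 0].max() <= w
            assert poly[:, 1].min() >= 0 and poly[:, 1].max() <= h

    def test_overcrowding_rejected(self):
        fs = pd.DataFrame([{"kind": "pore", "pore_area": 3e5,
                            "pore_length": 100.0, "pore_curvature": 0.1,
                            "pore_tortuosity": 1.0}] * 2)
        with pytest.raises(ValueError, match="filling factor"):
            render_image(fs, seed=1)

    def test_render_measure_area_round_trip(self, benchmark_scene):
        """Measured truth areas track the sampled areas (<5% mean error)."""
        _, truth = benchmark_scene
        fs = sample_features(20, 50, seed=11)
        sampled = np.sort(fs.loc[fs["kind"] == "pore", "pore_area"])
        measured = np.sort(truth.features.loc[
            truth.features["kind"] == "pore", "pore_area"])
        big = sampled >= 20.0
        rel = np.abs(measured[big] - sampled[big]) / sampled[big]
        assert rel.mean() < 0.05

    def test_truth_json_round_trip(self, benchmark_scene):
        from vped.synthetic import SceneTruth
        _, truth = benchmark_scene
        again = SceneTruth.from_json(truth.to_json())
        assert len(again.pore_polygons) == len(truth.pore_polygons)
        np.testing.assert_allclose(again.pore_polygons[0],
                                   truth.pore_polygons[0])


class TestHormoneReference:
    def test_shape_and_positivity(self):
        ref = build_hormone_reference()
        assert set(ref.hormones) == {"E2", "P4", "LH", "FSH"}
        assert len(ref.days) == 30
        assert (ref.table["variance"] > 0).all()

    def test_lh_peak_at_ovulation_day(self):
        ref = build_hormone_reference()
        lh = [ref.mean(d, "LH") for d in range(1, 31)]
        assert int(np.argmax(lh)) + 1 == 16

    def test_luteal_progesterone_plateau(self):
        ref = build_hormone_reference()
        assert ref.mean(23, "P4") > 5 * ref.mean(10, "P4")


class TestGenerateCohort:
    def test_record_count(self):
        assert len(generate_cohort(37, seed=0)) == 37

    def test_zero_noise_histology_equals_truth(self):
        cohort = generate_cohort(10, seed=1, noise=CohortNoise.zero())
        for p in cohort.patients:
            assert p.histology_day == p.true_day

    def test_seed_determinism_byte_identical(self):
        a = generate_cohort(8, seed=5).to_frame().to_csv()
        b = generate_cohort(8, seed=5).to_frame().to_csv()
        assert a == b

    def test_days_within_supported_range(self):
        cohort = generate_cohort(20, seed=2)
        for p in cohort.patients:
            assert 15 <= p.true_day <= 28

    def test_explicit_day_assignment(self):
        cohort = generate_cohort(3, day_assignment=[16, 20, 24], seed=3)
        assert [p.true_day for p in cohort.patients] == [16, 20, 24]
        with pytest.raises(ValueError):
            generate_cohort(2, day_assignment=[10, 20], seed=3)

    def test_histology_noise_kernel_distribution(self):
        noise = CohortNoise(histology=HistologyNoise(p0=0.6, p1=0.15, p2=0.05))
        cohort = generate_cohort(400, day_assignment=[21] * 400, seed=9,
                                 noise=noise, elements_per_patient=1)
        offsets = np.array([p.histology_day - p.true_day
                            for p in cohort.patients])
        assert set(np.unique(offsets)).issubset({-2, -1, 0, 1, 2})
        assert abs((offsets == 0).mean() - 0.6) < 0.08
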