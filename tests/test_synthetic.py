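"""Synthetic generator: ground-truth consistency, determinism, calibration."""

import numpy as np
import pytest

from alveomorph.errors import FieldOfViewError
from alveomorph.geometry import measure_alveolus
from alveomorph.stats import regress_mq_on_score
from alveomorph.synthetic import (
    CohortSpec,
    ConditionParams,
    RenderSpec,
    ShapeSpec,
    amplitude_for_circularity,
    center_in_field,
    make_alveolus,
    make_cohort,
    make_injury_scores,
    render_image,
    sample_animal_means,
)

ZERO_SD = ConditionParams(30.0, 0.0, 0.0, 0.8, 0.0, 0.0)


class TestMakeAlveolus:
    def test_smooth_shape_hits_targets(self):
        _, rec = make_alveolus(ShapeSpec(target_thickness_pct=19.0, seed=1))
        assert rec.wall_thickness_pct == pytest.approx(19.0, abs=0.5)
        assert rec.circularity >= 0.999

    def test_thickness_exact_by_construction(self):
        for t in (5.0, 27.0, 50.0, 80.0):
            _, rec = make_alveolus(ShapeSpec(target_thickness_pct=t, seed=2))
            assert rec.wall_thickness_pct == pytest.approx(t, abs=1e-9)

    def test_determinism(self):
        spec = ShapeSpec(roughness_amplitudes=((2, 0.2), (5, 0.1)), seed=7)
        t1, _ = make_alveolus(spec)
        t2, _ = make_alveolus(spec)
        np.testing.assert_array_equal(t1.outer.vertices, t2.outer.vertices)
        np.testing.assert_array_equal(t1.inner.vertices, t2.inner.vertices)

    def test_roughness_lowers_circularity(self):
        _, rec = make_alveolus(
            ShapeSpec(roughness_amplitudes=((2, 0.3),), seed=3)
        )
        assert rec.circularity < 0.9

    def test_excessive_amplitudes_are_damped_not_fatal(self, caplog):
        spec = ShapeSpec(roughness_amplitudes=((2, 0.8), (3, 0.8)), seed=4)
        with caplog.at_level("WARNING"):
            trace, _ = make_alveolus(spec)
        trace.validate()  # still a simple, contained pair
        assert any("damping" in m for m in caplog.messages)

    def test_ground_truth_equals_remeasurement(self):
        trace, rec = make_alveolus(
            ShapeSpec(roughness_amplitudes=((2, 0.25), (6, 0.1)), seed=5)
        )
        again = measure_alveolus(trace)
        assert again.wall_thickness_pct == rec.wall_thickness_pct
        assert again.circularity == rec.circularity
        assert again.mq == rec.mq


class TestAmplitudeCalibration:
    @pytest.mark.parametrize("target", [0.95, 0.88, 0.6, 0.41, 0.25])
    def test_bisection_hits_target(self, target):
        from alveomorph.synthetic import _mix_circularity

        amp = amplitude_for_circularity(target)
        assert _mix_circularity(amp, {k: 0.0 for k in (2, 6, 12, 20)}) == pytest.approx(
            target, abs=2e-4
        )

    def test_out_of_range_target_clamps(self):
        assert amplitude_for_circularity(1.0) == 0.0
        assert amplitude_for_circularity(0.01) > 0.3  # clamps at the max amplitude


class TestMakeCohort:
    def test_counts_and_labels(self):
        traces, gt = make_cohort(CohortSpec(n_animals=5, n_alveoli=10, seed=0))
        assert len(traces) == 100
        assert gt["animal_id"].nunique() == 10
        assert set(gt["condition"]) == {"baseline", "injury"}

    def test_determinism(self):
        t1, g1 = make_cohort(CohortSpec(seed=11))
        t2, g2 = make_cohort(CohortSpec(seed=11))
        assert g1.equals(g2)
        np.testing.assert_array_equal(t1[3].outer.vertices, t2[3].outer.vertices)

    def test_ground_truth_matches_geometry_exactly(self):
        traces, gt = make_cohort(CohortSpec(n_animals=2, n_alveoli=5, seed=1))
        for trace, (_, row) in zip(traces, gt.iterrows()):
            rec = measure_alveolus(trace)
            assert rec.wall_thickness_pct == row["wall_thickness_pct"]
            assert rec.circularity == row["circularity"]
            assert rec.mq == row["mq"]

    def test_zero_sd_gives_constant_targets(self):
        spec = CohortSpec(
            n_animals=2, n_alveoli=3, baseline=ZERO_SD, injury=ZERO_SD, seed=2
        )
        _, gt = make_cohort(spec)
        assert np.allclose(gt["target_thickness_pct"], 30.0)
        assert np.allclose(gt["target_circularity"], 0.8)
        # realized thickness is exact; circularity within bisection tolerance
        assert np.allclose(gt["wall_thickness_pct"], 30.0)
        assert np.allclose(gt["circularity"], 0.8, atol=2e-4)

    def test_parameter_recovery_within_2_se(self):
        """Pooled cohorts (600 alveoli/condition) recover generator means
        within 2 SE of the grand mean — the generator is unbiased."""
        import pandas as pd

        spec = CohortSpec(n_animals=10, n_alveoli=10)
        gt = pd.concat(
            make_cohort(CohortSpec(n_animals=10, n_alveoli=10, seed=s))[1]
            for s in range(6)
        )
        n_animals, n_alv = 60, 600
        for condition, params in (("baseline", spec.baseline), ("injury", spec.injury)):
            sub = gt[gt["condition"] == condition]
            assert len(sub) == n_alv
            for col, mean, sd_a, sd_w in (
                (
                    "wall_thickness_pct",
                    params.thickness_mean,
                    params.thickness_sd_animal,
                    params.thickness_sd_alveolus,
                ),
                (
                    "circularity",
                    params.circularity_mean,
                    params.circularity_sd_animal,
                    params.circularity_sd_alveolus,
                ),
            ):
                # SE of the grand mean under the hierarchy: animals are the
                # independent unit.
                se = np.sqrt(sd_a**2 / n_animals + sd_w**2 / n_alv)
                assert abs(sub[col].mean() - mean) < 2 * se

    def test_sample_animal_means_matches_hierarchy(self, rng):
        params = CohortSpec().baseline
        draws = sample_animal_means(params, 4000, 10, rng, "thickness")
        expected_sd = np.sqrt(
            params.thickness_sd_animal**2 + params.thickness_sd_alveolus**2 / 10
        )
        assert draws.mean() == pytest.approx(params.thickness_mean, abs=0.05)
        assert draws.std(ddof=1) == pytest.approx(expected_sd, rel=0.05)


class TestRenderImage:
    def _small_spec(self, **kw):
        defaults = dict(width=256, height=256, noise_sd=0.0, blur_sd_um=0.0)
        defaults.update(kw)
        return RenderSpec(**defaults)

    def test_clean_render_wall_band_exact(self):
        spec = self._small_spec()
        trace, _ = make_alveolus(ShapeSpec(base_radius=15.0, seed=1))
        trace = center_in_field(trace, spec)
        img = render_image([trace], spec)
        h, w = img.shape
        # mid-wall pixel: walk right from the centre to radius ~ between
        # inner (sqrt(1-0.27)*15) and outer (15) borders
        px = spec.pixel_size
        mid_r_px = int(15.0 * (1 + np.sqrt(0.73)) / 2 / px)
        assert img[h // 2, w // 2 + mid_r_px] == int(spec.wall_intensity)
        assert img[h // 2, w // 2] == int(spec.background_intensity)  # lumen
        assert img[2, 2] == int(spec.background_intensity)

    def test_determinism_bit_identical(self):
        spec = self._small_spec(noise_sd=10.0, blur_sd_um=0.3)
        trace, _ = make_alveolus(ShapeSpec(base_radius=15.0, seed=2))
        trace = center_in_field(trace, spec)
        np.testing.assert_array_equal(
            render_image([trace], spec, seed=5), render_image([trace], spec, seed=5)
        )

    def test_wall_band_pixel_count_oracle(self):
        """Rasterized band area matches A_out - A_in within 2 %."""
        spec = RenderSpec(noise_sd=0.0, blur_sd_um=0.0)
        trace, rec = make_alveolus(
            ShapeSpec(base_radius=50.0, roughness_amplitudes=((2, 0.15),), seed=3)
        )
        trace = center_in_field(trace, spec)
        img = render_image([trace], spec)
        band_px = np.count_nonzero(img == int(spec.wall_intensity))
        band_area = band_px * spec.pixel_size**2
        assert band_area == pytest.approx(rec.area_outer - rec.area_inner, rel=0.02)

    def test_trace_outside_field_raises(self):
        spec = self._small_spec()
        trace, _ = make_alveolus(ShapeSpec(base_radius=15.0, seed=4))
        with pytest.raises(FieldOfViewError, match="synthetic-4"):
            render_image([trace], spec)  # centred at the origin -> out of field


class TestInjuryScores:
    def test_noiseless_grid_aligned_recovery(self):
        # slope/intercept chosen so noiseless scores land on the integer grid
        mq = np.array([1.0, 2.0, 3.0, 4.0])
        scores = make_injury_scores(mq, slope=-2.0, intercept=10.0, noise_sd=0.0)
        fit = regress_mq_on_score(mq, scores)
        assert fit.slope == pytest.approx(-2.0)
        assert fit.intercept == pytest.approx(10.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_determinism(self):
        mq = np.linspace(0.8, 3.5, 10)
        np.testing.assert_array_equal(
            make_injury_scores(mq, seed=9), make_injury_scores(mq, seed=9)
        )

    def test_small_noise_high_r_squared(self):
        """Monte-Carlo under the generator's own model: R^2 > 0.98."""
        rng = np.random.default_rng(0)
        r2 = []
        for i in range(20):
            mq = np.concatenate(
                [rng.normal(3.46, 0.17, 5), rng.normal(0.88, 0.18, 5)]
            )
            fit = regress_mq_on_score(mq, make_injury_scores(mq, seed=i))
            r2.append(fit.r_squared)
            assert fit.slope < 0
        assert np.median(r2) > 0.98

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            make_injury_scores([1.0, 2.0, 3.0], slope=1.0)
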