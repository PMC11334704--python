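"""Ground-truth consistency and statistical calibration of the generators."""

import numpy as np
import pytest
from matplotlib.path import Path as MplPath
from scipy import stats as sps

from octavd.image import PolygonROI
from octavd.register import SimilarityTransform
from octavd.stats import mann_whitney_u
from octavd.synthetic import (CohortSpec, GenerationError, GroupSpec,
                              ImageParams, METRICS, ParameterError,
                              generate_cohort, generate_longitudinal_deltas,
                              generate_longitudinal_pair,
                              generate_vessel_image, reference_cohort_spec,
                              reference_longitudinal_spec)


def _flat_group(name, n_patients, n_eyes, mean=30.0, sd=5.0, **kw):
    means = {(p, m): mean for p in ("SCP", "DCP") for m in METRICS}
    sds = {(p, m): sd for p in ("SCP", "DCP") for m in METRICS}
    return GroupSpec(name=name, n_patients=n_patients, n_eyes=n_eyes,
                     metric_means=means, metric_sds=sds, **kw)


class TestVesselImage:
    def test_same_seed_and_params_bit_identical(self, default_image):
        img, truth = default_image
        img2, truth2 = generate_vessel_image(ImageParams(), seed=7)
        np.testing.assert_array_equal(img.pixels, img2.pixels)
        np.testing.assert_array_equal(truth.mask.pixels, truth2.mask.pixels)
        np.testing.assert_array_equal(truth.faz_polygon.vertices,
                                      truth2.faz_polygon.vertices)

    def test_noiseless_image_is_two_level(self, noiseless_image):
        img, truth = noiseless_image
        levels = np.unique(img.pixels)
        assert len(levels) == 2
        # thresholding anywhere between the two levels recovers the mask
        mid = levels.mean()
        np.testing.assert_array_equal(img.pixels > mid, truth.mask.pixels)

    def test_true_whole_vd_equals_independent_pixel_count(self, default_image):
        _, truth = default_image
        count = sum(bool(v) for v in truth.mask.pixels.ravel())  # brute force
        assert truth.true_whole_vd == count / truth.mask.pixels.size

    def test_no_foreground_strictly_inside_faz(self, default_image):
        _, truth = default_image
        ys, xs = np.nonzero(truth.mask.pixels)
        path = MplPath(truth.faz_polygon.vertices)
        # negative radius shrinks the polygon: strictly-interior test
        inside = path.contains_points(np.column_stack([xs, ys]), radius=-1e-9)
        assert not inside.any()

    @pytest.mark.parametrize("bad", [
        dict(size=32), dict(target_density=0.0), dict(target_density=0.9),
        dict(faz_radius=100.0), dict(falloff=1.5),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ParameterError):
            generate_vessel_image(ImageParams(**bad), seed=0)

    def test_unreachable_density_raises_generation_error(self):
        # a handful of strokes cannot tile 70% of the frame
        with pytest.raises(GenerationError, match="target_density"):
            generate_vessel_image(ImageParams(size=64, faz_radius=15.9,
                                              target_density=0.7), seed=0,
                                  max_strokes=3)

    def test_achievable_density_tracks_target_with_faz_excluded(self):
        # the target refers to the final mask, after the FAZ is cleared
        _, truth = generate_vessel_image(ImageParams(size=64, faz_radius=15.9,
                                                     target_density=0.7),
                                         seed=0)
        assert truth.true_whole_vd >= 0.9 * 0.7


class TestCohort:
    def test_eye_counts_match_spec_exactly(self):
        cohort = generate_cohort(reference_cohort_spec(), seed=0)
        scp = cohort[cohort.plexus == "SCP"]
        assert (scp.group == "BCR").sum() == 53
        assert (scp.group == "control").sum() == 110
        assert scp[scp.group == "BCR"].patient_id.nunique() == 28
        assert scp[scp.group == "control"].patient_id.nunique() == 59
        assert cohort.groupby(["patient_id", "plexus"]).size().max() <= 2

    def test_sample_means_converge_to_spec_means(self):
        # law of large numbers: rho=0, no effects, 10^4 eyes per group
        g = _flat_group("big", 5000, 10000, mean=30.0, sd=5.0)
        cohort = generate_cohort(CohortSpec(groups=(g,), rho=0.0), seed=4)
        sub = cohort[cohort.plexus == "SCP"]
        se = 5.0 / np.sqrt(len(sub))
        for m in METRICS:
            assert abs(sub[m].mean() - 30.0) < 3 * se

    def test_within_patient_correlation_dominates_at_high_rho(self):
        g = _flat_group("c", 200, 400, mean=30.0, sd=5.0)
        cohort = generate_cohort(CohortSpec(groups=(g,), rho=0.99), seed=5)
        sub = cohort[cohort.plexus == "DCP"]
        diffs = sub.groupby("patient_id")["whole_vd"].agg(np.ptp)
        diffs = diffs[diffs > 0]  # two-eye patients
        assert diffs.abs().mean() < 0.25 * sub["whole_vd"].std()

    def test_invalid_rho_rejected(self):
        g = _flat_group("g", 5, 10)
        with pytest.raises(ParameterError):
            generate_cohort(CohortSpec(groups=(g,), rho=1.0), seed=0)

    def test_covariate_effects_recovered_in_large_sample(self):
        g = _flat_group("g", 4000, 8000, mean=30.0, sd=2.0,
                        age_mean=60, age_sd=10)
        spec = CohortSpec(groups=(g,), rho=0.0, covariate_effects={
            ("DCP", "whole_vd"): {"age": -0.31}})
        cohort = generate_cohort(spec, seed=6)
        sub = cohort[cohort.plexus == "DCP"]
        slope = np.polyfit(sub["age"], sub["whole_vd"], 1)[0]
        assert slope == pytest.approx(-0.31, abs=0.02)
        # centering preserves the configured mean
        assert sub["whole_vd"].mean() == pytest.approx(30.0, abs=0.15)

    def test_null_two_group_mann_whitney_type_i_error(self):
        # identical groups at study sample sizes: rejection rate at
        # alpha=0.05 should be nominal across replicates
        rej = 0
        n_rep = 500
        for seed in range(n_rep):
            a = _flat_group("BCR", 28, 53)
            b = _flat_group("control", 59, 110)
            cohort = generate_cohort(CohortSpec(groups=(a, b), rho=0.0),
                                     seed=seed)
            sub = cohort[cohort.plexus == "SCP"]
            p = mann_whitney_u(sub[sub.group == "BCR"].whole_vd,
                               sub[sub.group == "control"].whole_vd).p
            rej += p < 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_null_p_values_are_uniform(self):
        # KS calibration of the downstream test under the global null
        ps = []
        for seed in range(500):
            a = _flat_group("BCR", 28, 53)
            b = _flat_group("control", 59, 110)
            cohort = generate_cohort(CohortSpec(groups=(a, b), rho=0.0),
                                     seed=10_000 + seed)
            sub = cohort[cohort.plexus == "DCP"]
            ps.append(mann_whitney_u(sub[sub.group == "BCR"].faz_area_pct,
                                     sub[sub.group == "control"].faz_area_pct).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestLongitudinalPair:
    def test_identity_zero_noise_reproduces_baseline(self, noiseless_image):
        img, truth = noiseless_image
        pair = generate_longitudinal_pair(img, truth.faz_polygon,
                                          SimilarityTransform.identity())
        np.testing.assert_array_equal(pair.followup.pixels, img.pixels)

    def test_translation_overlap_arithmetic(self, noiseless_image):
        img, truth = noiseless_image
        tf = SimilarityTransform(1.0, 0.0, (10.0, 0.0))
        pair = generate_longitudinal_pair(img, truth.faz_polygon, tf)
        h, w = img.shape
        assert pair.valid.sum() == h * (w - 10)

    def test_faz_growth_squares_polygon_area(self, noiseless_image):
        img, truth = noiseless_image
        pair = generate_longitudinal_pair(img, truth.faz_polygon,
                                          SimilarityTransform.identity(),
                                          faz_growth=1.1)
        ratio = (pair.faz_followup.shoelace_area()
                 / pair.faz_baseline.shoelace_area())
        assert ratio == pytest.approx(1.21, abs=1e-9)

    def test_out_of_frame_transform_rejected(self, noiseless_image):
        img, truth = noiseless_image
        tf = SimilarityTransform(1.0, 0.0, (10 * img.width, 0.0))
        with pytest.raises(GenerationError):
            generate_longitudinal_pair(img, truth.faz_polygon, tf)


class TestLongitudinalDeltas:
    def test_shape_and_cluster_structure(self):
        d = generate_longitudinal_deltas(reference_longitudinal_spec(), seed=1)
        scp = d[d.plexus == "SCP"]
        assert len(scp) == 23
        assert scp.patient_id.nunique() == 16
        assert {"delta_whole_vd", "delta_faz_area_pct"} <= set(d.columns)

    def test_deterministic(self):
        d1 = generate_longitudinal_deltas(reference_longitudinal_spec(), seed=2)
        d2 = generate_longitudinal_deltas(reference_longitudinal_spec(), seed=2)
        assert d1.equals(d2)
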