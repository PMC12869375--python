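import numpy as np
import pytest

from fixsearch import (
    GLCMParams,
    PipelineConfig,
    default_bank,
    feature_correlation,
    gaze_overlap,
    run_pipeline_a,
    run_pipeline_b,
    run_thresholded,
)
from fixsearch.errors import InsufficientDataError, ParameterError


@pytest.fixture(scope="module")
def small_config():
    """Configuration scaled to the 320x320 session phantom (50 px target)."""
    return PipelineConfig(
        glcm=GLCMParams(G=64, window=64),
        bank=default_bank(50.0),
        target_radius_px=50.0,
        seed=7,
    )


@pytest.fixture(scope="module")
def results(small_phantom, small_config):
    image, center = small_phantom["image"], small_phantom["center"]
    return {
        "A": run_pipeline_a(image, small_config, center),
        "B": run_pipeline_b(image, small_config, center),
        "T": run_thresholded(image, small_config),
    }


def min_distance_to(locations, center):
    if len(locations) == 0:
        return np.inf
    return np.sqrt(((locations - np.asarray(center)) ** 2).sum(axis=1)).min()


class TestPipelineA:
    def test_final_candidate_lands_within_lesion_radius(self, results, small_phantom):
        d = min_distance_to(results["A"].final.locations, small_phantom["center"])
        assert d <= small_phantom["radius_px"]

    def test_final_is_screened_subset_of_watershed_candidates(self, results):
        initial = set(results["A"].intermediates["watershed_candidates"].candidates)
        assert set(results["A"].final.candidates) <= initial
        assert results["A"].final.provenance == "screened"

    def test_all_final_candidates_lie_on_mask(self, results):
        mask = results["A"].intermediates["mask"].values
        for c in results["A"].final.candidates:
            assert mask[c.location]

    def test_determinism(self, small_phantom, small_config):
        image, center = small_phantom["image"], small_phantom["center"]
        r1 = run_pipeline_a(image, small_config, center)
        r2 = run_pipeline_a(image, small_config, center)
        assert r1.final.candidates == r2.final.candidates
        np.testing.assert_array_equal(
            r1.intermediates["mask"].values, r2.intermediates["mask"].values
        )

    def test_oracle_mode_without_center_rejected(self, small_phantom, small_config):
        with pytest.raises(ParameterError):
            run_pipeline_a(small_phantom["image"], small_config)


class TestPipelineB:
    def test_final_candidate_lands_within_lesion_radius(self, results, small_phantom):
        d = min_distance_to(results["B"].final.locations, small_phantom["center"])
        assert d <= small_phantom["radius_px"]

    def test_final_is_subset_of_initial_regional_maxima(self, results):
        initial = results["B"].intermediates["initial_candidates"]
        initial_locs = {c.location for c in initial.candidates}
        assert {c.location for c in results["B"].final.candidates} <= initial_locs
        assert results["B"].final.provenance == "clustered"

    def test_candidates_carry_six_features(self, results):
        for c in results["B"].final.candidates:
            assert len(c.channel_values) == 4
            assert c.texture_values is not None

    def test_determinism(self, small_phantom, small_config):
        image, center = small_phantom["image"], small_phantom["center"]
        r1 = run_pipeline_b(image, small_config, center)
        r2 = run_pipeline_b(image, small_config, center)
        assert r1.final.candidates == r2.final.candidates


class TestThresholded:
    def test_zero_quantile_returns_all_initial_candidates(self, small_phantom, small_config):
        config = PipelineConfig.from_dict({**small_config.to_dict(), "threshold_quantile": 0.0})
        result = run_thresholded(small_phantom["image"], config)
        assert len(result.final) == len(result.intermediates["initial_candidates"])

    def test_quantile_count_arithmetic(self, results):
        initial = results["T"].intermediates["initial_candidates"]
        stats = np.array([c.max_channel_value for c in initial.candidates])
        cut = np.quantile(stats, 0.75)
        assert len(results["T"].final) == int((stats >= cut).sum())

    def test_survivors_dominate_rejected(self, results):
        final = set(results["T"].final.candidates)
        initial = set(results["T"].intermediates["initial_candidates"].candidates)
        rejected = initial - final
        if rejected and final:
            assert min(c.max_channel_value for c in final) >= max(
                c.max_channel_value for c in rejected
            )

    def test_hit_within_lesion_radius(self, results, small_phantom):
        d = min_distance_to(results["T"].final.locations, small_phantom["center"])
        assert d <= small_phantom["radius_px"]


class TestCrossMethodAgreement:
    def test_methods_share_a_candidate_region(self, results, small_config):
        """The three methods' final sets intersect within the dedupe radius."""
        radius = small_config.effective_dedupe_radius
        sets = [results[k].final.locations for k in ("A", "B", "T")]
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.sqrt(
                    ((sets[i][:, None, :] - sets[j][None, :, :]) ** 2).sum(axis=2)
                )
                assert d.min() <= radius


class TestFeatureCorrelation:
    def test_affine_dependence_gives_unit_correlation(self):
        x = np.linspace(1, 10, 50)
        responses = np.column_stack([2 * x + 1, 0.5 * x + 3])
        report = feature_correlation(x, responses)
        assert report.per_channel == pytest.approx((1.0, 1.0))
        assert report.vs_mean_over_channels == pytest.approx(1.0)

    def test_independent_noise_is_nearly_uncorrelated(self, rng):
        x = rng.normal(size=1000)
        responses = rng.normal(size=(1000, 4))
        report = feature_correlation(x, responses)
        assert all(abs(r) < 0.1 for r in report.per_channel)

    def test_matches_covariance_formula_oracle(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200) + 0.3 * x
        report = feature_correlation(x, np.abs(y)[:, None])
        ay = np.abs(y)
        oracle = ((x - x.mean()) * (ay - ay.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((ay - ay.mean()) ** 2).sum()
        )
        assert report.per_channel[0] == pytest.approx(oracle, abs=1e-12)

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            feature_correlation([1.0, 2.0], [[1.0], [2.0]])

    def test_positive_sign_against_low_frequency_channel(self, results):
        """GLCM mean tracks the magnitude of the coarsest Gabor channel."""
        cands = results["B"].intermediates["initial_candidates"].candidates
        glcm_means = np.array([c.texture_values[0] for c in cands])
        responses = np.array([c.channel_values for c in cands])
        report = feature_correlation(glcm_means, responses)
        assert report.per_channel[0] > 0


class TestGazeOverlap:
    def _set(self, locations):
        from fixsearch.candidates import Candidate, CandidateSet

        cands = tuple(
            Candidate(location=loc, channel_values=(1.0,), source_channel=0) for loc in locations
        )
        return CandidateSet(candidates=cands, image_shape=(100, 100), provenance="clustered")

    def test_gaze_on_candidates_gives_full_overlap(self):
        cs = self._set([(10, 10), (50, 50)])
        fraction, mean_dist = gaze_overlap(np.array([(10, 10), (50, 50)]), cs, radius=5)
        assert fraction == 1.0
        assert mean_dist == 0.0

    def test_distant_gaze_gives_zero_overlap(self):
        cs = self._set([(10, 10)])
        fraction, _ = gaze_overlap(np.array([(90.0, 90.0)]), cs, radius=5)
        assert fraction == 0.0

    def test_partial_overlap_counts_fraction(self):
        cs = self._set([(10, 10)])
        gaze = np.array([(12.0, 10.0), (80.0, 80.0)])
        fraction, _ = gaze_overlap(gaze, cs, radius=5)
        assert fraction == 0.5

    def test_empty_candidate_set_warns(self):
        cs = self._set([])
        with pytest.warns(UserWarning):
            fraction, mean_dist = gaze_overlap(np.array([(1.0, 1.0)]), cs, radius=5)
        assert fraction == 0.0
        assert np.isinf(mean_dist)
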