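import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import gaussian_kde, norm, ortho_group

import neurosep as ns


def _gaussian_samples(rng, means, n=200, sd=1.0):
    """2x2 condition samples with prescribed decoded-value means."""
    return {
        cond: rng.normal(mu, sd, size=n) for cond, mu in means.items()
    }


class TestBuildGrid:
    def test_span_is_twice_the_data_range(self):
        grid = ns.build_grid([0.0, 1.0, 2.0])
        assert grid.points[0] == pytest.approx(-1.0)
        assert grid.points[-1] == pytest.approx(3.0)
        assert grid.points.size == 1000
        assert grid.spacing == pytest.approx(4.0 / 999)

    def test_symmetric_data_gives_symmetric_grid(self):
        grid = ns.build_grid([-1.0, 1.0])
        assert grid.points[0] == pytest.approx(-2.0)
        assert grid.points[-1] == pytest.approx(2.0)

    def test_constant_samples_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ns.build_grid([1.0, 1.0, 1.0])


class TestEstimateDensity:
    def test_matches_reference_gaussian_kde(self):
        # Scott's-rule Gaussian KDE must agree with the scipy implementation
        rng = np.random.default_rng(0)
        samples = rng.standard_normal(200)
        grid = ns.build_grid(samples)
        ours = ns.estimate_density(samples, grid)
        reference = gaussian_kde(samples)(grid.points)
        np.testing.assert_allclose(ours.density, reference, atol=1e-12)

    def test_consistency_against_true_density(self):
        rng = np.random.default_rng(1)
        samples = rng.standard_normal(100_000)
        grid = ns.build_grid(samples)
        est = ns.estimate_density(samples, grid)
        assert np.abs(est.density - norm.pdf(grid.points)).max() <= 0.01

    def test_density_near_zero_far_outside_data(self):
        grid = ns.EvaluationGrid(points=np.linspace(100, 101, 50), spacing=1 / 49)
        est = ns.estimate_density([0.0, 1.0], grid)
        assert est.density.max() < 1e-12

    def test_mode_at_center_of_symmetric_sample(self):
        samples = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        grid = ns.build_grid(samples)
        est = ns.estimate_density(samples, grid)
        center = np.argmin(np.abs(grid.points))
        assert est.density[center] == est.density.max()

    def test_integrates_to_one_for_in_range_data(self):
        rng = np.random.default_rng(2)
        samples = rng.normal(0, 1, 500)
        grid = ns.build_grid(samples)
        est = ns.estimate_density(samples, grid)
        assert 0.9 <= est.density.sum() * grid.spacing <= 1.0 + 1e-9

    def test_zero_spread_rejected(self):
        grid = ns.EvaluationGrid(points=np.linspace(-1, 1, 10), spacing=2 / 9)
        with pytest.raises(ValueError, match="standard deviation"):
            ns.estimate_density([1.0, 1.0, 1.0], grid)


class TestL1Distance:
    def test_zero_for_identical_densities(self):
        rng = np.random.default_rng(3)
        samples = rng.standard_normal(50)
        grid = ns.build_grid(samples)
        p = ns.estimate_density(samples, grid)
        assert ns.l1_distance(p, p) == 0.0

    def test_matches_closed_form_for_unit_gaussians(self):
        # L1 between N(0,1) and N(1,1) is 2(2 Phi(1/2) - 1)
        rng = np.random.default_rng(4)
        n = 100_000
        a = rng.normal(0, 1, n)
        b = rng.normal(1, 1, n)
        grid = ns.build_grid(np.concatenate([a, b]))
        closed_form = 2 * (2 * norm.cdf(0.5) - 1)
        assert closed_form == pytest.approx(0.7659, abs=1e-4)
        observed = ns.l1_distance(
            ns.estimate_density(a, grid), ns.estimate_density(b, grid)
        )
        assert observed == pytest.approx(closed_form, abs=0.02)

    def test_disjoint_supports_approach_total_variation_bound(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.1, 20_000)
        b = rng.normal(100, 0.1, 20_000)
        grid = ns.build_grid(np.concatenate([a, b]))
        observed = ns.l1_distance(
            ns.estimate_density(a, grid), ns.estimate_density(b, grid)
        )
        assert observed == pytest.approx(2.0, abs=0.05)

    def test_grid_mismatch_rejected(self):
        p = ns.estimate_density([0.0, 1.0], ns.build_grid([0.0, 1.0]))
        q = ns.estimate_density([0.0, 2.0], ns.build_grid([0.0, 2.0]))
        with pytest.raises(ValueError, match="grid"):
            ns.l1_distance(p, q)


class TestDDSStatistic:
    def test_zero_when_irrelevant_levels_share_identical_samples(self):
        rng = np.random.default_rng(6)
        x1, x2 = rng.normal(0, 1, 30), rng.normal(2, 1, 30)
        samples = {(1, 1): x1, (1, 2): x1, (2, 1): x2, (2, 2): x2}
        assert ns.dds_statistic(samples) == 0.0

    def test_positive_under_separability_at_finite_n(self):
        rng = np.random.default_rng(7)
        samples = _gaussian_samples(rng, {(1, 1): 0, (1, 2): 0, (2, 1): 2, (2, 2): 2})
        assert ns.dds_statistic(samples) > 0

    def test_scaled_dds_matches_closed_form_l1(self):
        # one target level holds N(0,1) vs N(5,1): L1 = 2(2 Phi(5/2) - 1)
        rng = np.random.default_rng(8)
        n = 10_000
        samples = {
            (1, 1): rng.normal(0, 1, n),
            (1, 2): rng.normal(5, 1, n),
            (2, 1): rng.normal(0, 1, n),
            (2, 2): rng.normal(0, 1, n),
        }
        grid = ns.build_grid(np.concatenate(list(samples.values())))
        closed_form = 2 * (2 * norm.cdf(2.5) - 1)  # level-1 contribution
        observed = ns.dds_statistic(samples) * grid.spacing
        # level 2 contributes only estimation error
        assert observed == pytest.approx(closed_form, rel=0.10)

    def test_symmetric_in_irrelevant_levels(self):
        rng = np.random.default_rng(9)
        samples = _gaussian_samples(rng, {(1, 1): 0, (1, 2): 1, (2, 1): 2, (2, 2): 3})
        swapped = {(i, 3 - j): v for (i, j), v in samples.items()}
        assert ns.dds_statistic(samples) == pytest.approx(
            ns.dds_statistic(swapped), abs=1e-12
        )

    def test_requires_2x2_design(self):
        with pytest.raises(ValueError, match="2x2"):
            ns.dds_statistic({(1, 1): np.arange(3.0), (1, 2): np.arange(3.0)})


class TestStandardizeDDS:
    def test_observed_above_entire_edf_hits_upper_bound(self):
        rng = np.random.default_rng(10)
        # enormous separation across the irrelevant dimension
        samples = _gaussian_samples(
            rng, {(1, 1): 0, (1, 2): 50, (2, 1): 0, (2, 2): 50}, n=40, sd=0.5
        )
        result = ns.standardize_dds(samples, seed=0)
        assert result.standardized_proportion == 1.0
        assert result.standardized_percentile == 50.0

    def test_identical_condition_samples_hit_lower_bound(self):
        rng = np.random.default_rng(11)
        x1, x2 = rng.normal(0, 1, 40), rng.normal(2, 1, 40)
        samples = {(1, 1): x1, (1, 2): x1.copy(), (2, 1): x2, (2, 2): x2.copy()}
        result = ns.standardize_dds(samples, seed=0)
        assert result.standardized_proportion == 0.0
        assert result.standardized_percentile == -50.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(12)
        samples = _gaussian_samples(rng, {(1, 1): 0, (1, 2): 0, (2, 1): 1, (2, 2): 1})
        a = ns.standardize_dds(samples, seed=33)
        b = ns.standardize_dds(samples, seed=33)
        assert a.raw == b.raw
        np.testing.assert_array_equal(a.edf, b.edf)
        assert a.standardized_proportion == b.standardized_proportion

    def test_edf_has_requested_size(self):
        rng = np.random.default_rng(13)
        samples = _gaussian_samples(rng, {(1, 1): 0, (1, 2): 0, (2, 1): 1, (2, 2): 1})
        result = ns.standardize_dds(samples, n_shuffles=57, seed=1)
        assert result.edf.size == 57

    def test_per_condition_bandwidth_mode_agrees_on_raw_statistic(self):
        rng = np.random.default_rng(14)
        samples = _gaussian_samples(rng, {(1, 1): 0, (1, 2): 1, (2, 1): 0, (2, 2): 0})
        result = ns.standardize_dds(samples, seed=2, bandwidth="per-condition")
        # in this mode the observed value is exactly the public raw statistic
        assert result.raw == pytest.approx(ns.dds_statistic(samples), abs=1e-9)
        assert 0.0 <= result.standardized_proportion <= 1.0

    def test_bandwidth_modes_agree_on_strong_effects(self):
        rng = np.random.default_rng(15)
        samples = _gaussian_samples(
            rng, {(1, 1): 0, (1, 2): 4, (2, 1): 0, (2, 2): 0}, n=100
        )
        pooled = ns.standardize_dds(samples, seed=3, bandwidth="pooled")
        per_cond = ns.standardize_dds(samples, seed=3, bandwidth="per-condition")
        assert pooled.standardized_proportion > 0.95
        assert per_cond.standardized_proportion > 0.95

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(16)
        samples = _gaussian_samples(rng, {(1, 1): 0, (1, 2): 0, (2, 1): 1, (2, 2): 1})
        with pytest.raises(ValueError):
            ns.standardize_dds(samples, n_shuffles=0, seed=0)
        with pytest.raises(ValueError):
            ns.standardize_dds(samples, bandwidth="adaptive", seed=0)


class TestAccuracyTable:
    REGIONS = [[(-np.inf, 0.0)], [(0.0, np.inf)]]

    def test_gaussian_mass_in_half_line(self):
        dists = {
            (1, 1): ns.DecodingDistribution(-1.0, 1.0),
            (1, 2): ns.DecodingDistribution(-1.0, 1.0),
            (2, 1): ns.DecodingDistribution(1.0, 1.0),
            (2, 2): ns.DecodingDistribution(1.0, 1.0),
        }
        table = ns.accuracy_table(dists, self.REGIONS)
        assert table.values[1, 0] == pytest.approx(norm.cdf(1.0))  # 0.8413
        assert table.chance == pytest.approx(0.5)

    def test_point_mass_inside_region_gives_certainty(self):
        dists = {
            (1, 1): ns.DecodingDistribution(-3.0, 0.0),
            (1, 2): ns.DecodingDistribution(-3.0, 0.0),
            (2, 1): ns.DecodingDistribution(3.0, 0.0),
            (2, 2): ns.DecodingDistribution(3.0, 0.0),
        }
        table = ns.accuracy_table(dists, self.REGIONS)
        np.testing.assert_array_equal(table.values, np.ones((2, 2)))

    def test_separable_distributions_give_identical_columns(self):
        dists = {
            (1, 1): ns.DecodingDistribution(-0.7, 1.3),
            (1, 2): ns.DecodingDistribution(-0.7, 1.3),
            (2, 1): ns.DecodingDistribution(0.4, 0.8),
            (2, 2): ns.DecodingDistribution(0.4, 0.8),
        }
        table = ns.accuracy_table(dists, self.REGIONS)
        np.testing.assert_allclose(table.values[:, 0], table.values[:, 1])

    def test_overlapping_regions_rejected(self):
        dists = {(i, j): ns.DecodingDistribution(0.0, 1.0) for i in (1, 2) for j in (1, 2)}
        with pytest.raises(ValueError, match="overlap"):
            ns.accuracy_table(dists, [[(-np.inf, 1.0)], [(0.0, np.inf)]])

    def test_non_covering_regions_rejected(self):
        dists = {(i, j): ns.DecodingDistribution(0.0, 1.0) for i in (1, 2) for j in (1, 2)}
        with pytest.raises(ValueError):
            ns.accuracy_table(dists, [[(-np.inf, 0.0)], [(1.0, np.inf)]])


class TestInvarianceAndGeneralization:
    @pytest.mark.parametrize(
        "rows, expect_inv, expect_gen",
        [
            ([[0.9, 0.9], [0.9, 0.9]], True, True),
            ([[0.9, 0.6], [0.9, 0.9]], False, True),
            ([[0.9, 0.4], [0.9, 0.9]], False, False),
        ],
    )
    def test_verdict_triples(self, rows, expect_inv, expect_gen):
        table = ns.AccuracyTable(values=np.array(rows), chance=0.5)
        verdicts = ns.accuracy_invariance_and_generalization(table)
        assert verdicts["invariance"] is expect_inv
        assert verdicts["generalization"] is expect_gen

    @given(st.integers(0, 10_000))
    def test_invariance_always_implies_generalization(self, seed):
        """Randomized tables derived from Gaussian decoding distributions
        can never satisfy invariance while violating generalization."""
        rng = np.random.default_rng(seed)
        separable = rng.random() < 0.5
        dists = {}
        for i in (1, 2):
            mean = rng.normal(0, 2)
            var = rng.uniform(0.2, 3.0)
            for j in (1, 2):
                if separable or rng.random() < 0.3:
                    dists[(i, j)] = ns.DecodingDistribution(mean, var)
                else:
                    dists[(i, j)] = ns.DecodingDistribution(
                        rng.normal(0, 2), rng.uniform(0.2, 3.0)
                    )
        cut = rng.normal(0, 1)
        table = ns.accuracy_table(
            dists, [[(-np.inf, cut)], [(cut, np.inf)]]
        )
        verdicts = ns.accuracy_invariance_and_generalization(table)
        assert not (verdicts["invariance"] and not verdicts["generalization"])


class TestOrthogonalityIndex:
    def test_orthogonal_basis_vectors(self):
        result = ns.orthogonality_index([1, 0, 0], [0, 1, 0])
        assert result.cosine == pytest.approx(0.0)
        assert result.angle_deg == pytest.approx(90.0)

    def test_forty_five_degrees(self):
        result = ns.orthogonality_index([1, 0], [1, 1])
        assert result.cosine == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert result.angle_deg == pytest.approx(45.0)

    def test_cosine_and_pearson_differ_without_centering(self):
        result = ns.orthogonality_index([1, 2, 3], [3, 2, 1])
        assert result.cosine == pytest.approx(10 / 14)
        assert result.pearson_of_vectors == pytest.approx(-1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ns.orthogonality_index([0, 0], [1, 0])

    @given(st.integers(0, 500))
    def test_rotation_preserves_angle_general_linear_map_does_not(self, seed):
        rng = np.random.default_rng(seed)
        w_a, w_b = rng.standard_normal(4), rng.standard_normal(4)
        base = ns.orthogonality_index(w_a, w_b).cosine
        rotation = ortho_group.rvs(4, random_state=seed)
        rotated = ns.orthogonality_index(rotation @ w_a, rotation @ w_b).cosine
        assert rotated == pytest.approx(base, abs=1e-10)
        arbitrary = rng.standard_normal((4, 4)) + 0.1 * np.eye(4)
        mapped = ns.orthogonality_index(arbitrary @ w_a, arbitrary @ w_b).cosine
        # a generic non-orthogonal map moves the angle
        assert abs(mapped - base) > 1e-6


class TestPatternDifferenceTest:
    def test_equal_condition_means_give_zero_statistic(self):
        patterns = {
            (i, j): np.tile([1.0, -1.0], (10, 1)) for i in (1, 2) for j in (1, 2)
        }
        result = ns.pattern_difference_test(patterns, n_perm=50, seed=0)
        assert result.statistic == pytest.approx(0.0)

    def test_additive_design_has_no_interaction(self):
        patterns = {
            (1, 1): np.tile([1.0, 0.0], (10, 1)),
            (2, 1): np.tile([0.0, 0.0], (10, 1)),
            (1, 2): np.tile([1.0, 0.0], (10, 1)),
            (2, 2): np.tile([0.0, 0.0], (10, 1)),
        }
        result = ns.pattern_difference_test(patterns, n_perm=50, seed=0)
        np.testing.assert_allclose(result.interaction_vector, 0.0, atol=1e-12)

    def test_encoding_violation_recovered_through_mixing(self, separable_model):
        """Forward simulation: a tuning deviation delta behind full-rank
        mixing B yields an interaction norm near ||B delta|| and a small p."""
        rng = np.random.default_rng(20)
        delta = np.array([1.5, -0.5, 1.0, 0.8])
        violated = ns.apply_violation(
            separable_model, ns.TuningViolation(delta=delta, target_condition=(1, 1))
        )
        mixing = rng.standard_normal((6, 4))
        mm = ns.MeasurementModel(mixing=mixing, error_cov=0.25 * np.eye(6))
        n = 4000
        patterns = {}
        for k, cond in enumerate(violated.grid.conditions()):
            responses = ns.sample_responses(violated, cond, n, seed=100 + k)
            patterns[cond] = ns.measure(mm, responses, seed=200 + k)
        result = ns.pattern_difference_test(patterns, n_perm=200, seed=21)
        expected = float(np.linalg.norm(mixing @ delta))
        assert result.statistic == pytest.approx(expected, rel=0.1)
        assert result.permutation_p <= 0.01

    def test_permutation_p_within_unit_interval(self):
        rng = np.random.default_rng(22)
        patterns = {
            (i, j): rng.standard_normal((8, 3)) for i in (1, 2) for j in (1, 2)
        }
        result = ns.pattern_difference_test(patterns, n_perm=99, seed=1)
        assert 0.0 < result.permutation_p <= 1.0


def test_variance_explained_squares_the_correlation():
    assert ns.variance_explained(-0.5) == pytest.approx(25.0)
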