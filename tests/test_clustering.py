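import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdmclust.clustering import (
    FcmConfig,
    GaConfig,
    ThresholdChromosome,
    assign_roles,
    between_cluster_scatter_sdm,
    constraints_violated,
    fcm_cluster,
    fcm_memberships,
    fcm_seed_chromosome,
    fcs_objective,
    fitness,
    ga_optimize,
    lda_objective,
    objective_value,
    partition_by_thresholds,
    partition_from_labels,
    refine_morphology,
    within_cluster_scatter_sdm,
)
from sdmclust.imaging import BACKGROUND, CYTOPLASM, NUCLEUS


def make_partition(*clusters):
    """Partition from explicit per-cluster value lists (1-D pseudo image)."""
    values = np.concatenate([np.asarray(c, dtype=float) for c in clusters])
    labels = np.concatenate([np.full(len(c), j) for j, c in enumerate(clusters)])
    return partition_from_labels(values, labels, n_clusters=max(3, len(clusters)))


class TestPartition:
    def test_threshold_assignment_and_boundaries(self):
        L = np.array([[10.0, 50.0, 90.0, 40.0]])
        part = partition_by_thresholds(L, ThresholdChromosome(40.0, 70.0))
        # pixel exactly at t1 joins the mid cluster (half-open intervals)
        assert part.labels.tolist() == [[0, 1, 2, 1]]

    def test_uniform_image_leaves_outer_clusters_empty(self):
        part = partition_by_thresholds(np.full((4, 4), 50.0), ThresholdChromosome(40.0, 70.0))
        assert part.counts.tolist() == [0, 16, 0]
        assert np.isnan(part.centers[0]) and np.isnan(part.centers[2])

    def test_chromosome_ordering_enforced(self):
        with pytest.raises(ValueError):
            ThresholdChromosome(70.0, 40.0)


class TestSdmScatter:
    def test_within_is_max_squared_deviation(self):
        part = make_partition([1.0, 2.0, 3.0])
        assert within_cluster_scatter_sdm(part) == pytest.approx(1.0)

    def test_within_sums_over_clusters(self):
        part = make_partition([0.0, 1.0], [10.0, 11.0])
        assert within_cluster_scatter_sdm(part) == pytest.approx(0.5)

    def test_singleton_cluster_contributes_zero(self):
        part = make_partition([7.0])
        assert within_cluster_scatter_sdm(part) == 0.0

    def test_between_uses_nearest_member_to_other_centre(self):
        part = make_partition([0.0, 1.0], [10.0, 11.0])
        s_b, per_pair = between_cluster_scatter_sdm(part)
        # nearest member of {0,1} to centre 10.5 is 1 -> 9.5^2
        assert per_pair[0][2] == pytest.approx(90.25)

    def test_overlapping_clusters_zero_separation(self):
        part = make_partition([0.0, 10.0], [5.0, 15.0])
        # 5.0 in cluster 2 coincides with centre of cluster 1
        _, per_pair = between_cluster_scatter_sdm(part)
        assert per_pair[0][2] == pytest.approx(0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(2, 4), st.integers(0, 10_000))
    def test_perm_pair_count(self, R, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 100, size=40)
        labels = rng.integers(0, R, size=40)
        part = partition_from_labels(values, labels, n_clusters=R)
        if len(part.nonempty()) < 2:
            return
        _, per_pair = between_cluster_scatter_sdm(part)
        assert len(per_pair) == R * (R - 1) // 2

    def test_max_statistic_ignores_interior_members(self):
        # adding interior members symmetric about the centre leaves the
        # worst-case (max) scatter unchanged but grows the summed scatter
        base = make_partition([0.0, 10.0], [20.0, 30.0])
        augmented = make_partition([0.0, 4.0, 6.0, 10.0], [20.0, 30.0])
        assert within_cluster_scatter_sdm(base) == pytest.approx(
            within_cluster_scatter_sdm(augmented))
        s_w = lambda p: sum(float(np.sum((p.samples[j] - p.centers[j]) ** 2))
                            for j in p.nonempty())
        assert s_w(augmented) > s_w(base)

    def test_all_empty_rejected(self):
        part = partition_by_thresholds(np.full((3, 3), 50.0), ThresholdChromosome(60.0, 70.0))
        part.samples = [np.array([])] * 3
        part.labels = np.full((3, 3), -1)
        with pytest.raises(ValueError):
            within_cluster_scatter_sdm(part)


class TestBaselineObjectives:
    def test_lda_hand_computed_ratio(self):
        part = make_partition([0.0, 1.0], [10.0, 11.0])
        # S_W = 0.25*4 = 1.0; S_B = 2*(0.5-5.5)^2 + 2*(10.5-5.5)^2 = 100
        assert lda_objective(part) == pytest.approx(0.01, rel=1e-6)

    def test_lda_translation_invariance(self):
        a = make_partition([0.0, 1.0, 2.0], [10.0, 12.0])
        b = make_partition([30.0, 31.0, 32.0], [40.0, 42.0])
        assert lda_objective(a) == pytest.approx(lda_objective(b))

    def test_lda_single_cluster_guarded(self):
        part = make_partition([1.0, 2.0, 3.0])
        assert lda_objective(part) < 1e10  # eps guard, no division error

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_fcs_memberships_bounded(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 100, 50)
        centers = np.sort(rng.uniform(0, 100, 3))
        u = fcm_memberships(x, centers)
        assert (u >= 0).all() and (u <= 1 + 1e-12).all()
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("variant", ["FCS1", "FCS2"])
    def test_fcs_eta_zero_reduces_to_compactness(self, variant):
        part = make_partition([1.0, 4.0], [40.0, 44.0], [80.0, 90.0])
        with_sep = fcs_objective(part, variant=variant)
        compact = fcs_objective(part, variant=variant, eta=0.0)
        assert with_sep < compact  # separation term is positive
        other = fcs_objective(part, variant="FCS2" if variant == "FCS1" else "FCS1", eta=0.0)
        assert compact == pytest.approx(other)

    def test_fcs2_separation_positive_for_separated_clusters(self):
        part = make_partition([0.0, 1.0], [50.0, 51.0], [99.0, 100.0])
        assert fcs_objective(part, "FCS2", eta=0.0) > fcs_objective(part, "FCS2", eta=0.5)


class TestFitness:
    def test_ratio_formula(self):
        part = make_partition([10.0, 11.0], [50.0, 51.0], [90.0, 91.0])
        s_w = within_cluster_scatter_sdm(part)
        s_b, _ = between_cluster_scatter_sdm(part)
        assert fitness(part, GaConfig(), penalty=1000.0) == pytest.approx(s_w / (s_b + 1e-9))

    def test_small_nucleus_penalised(self):
        # nucleus area 5 < 10% of cytoplasm area 100
        part = make_partition([10.0] * 5, [50.0] * 100, [90.0] * 100)
        assert constraints_violated(part)
        assert fitness(part, GaConfig(), penalty=1e6) > 1e5

    def test_oversized_background_penalised(self):
        part = make_partition([10.0] * 20, [50.0] * 20, [90.0] * 60)
        assert constraints_violated(part)

    def test_balanced_partition_unpenalised(self):
        part = make_partition([10.0] * 30, [50.0] * 40, [90.0] * 30)
        assert not constraints_violated(part)


class TestFcm:
    def test_two_point_masses_recovered(self):
        # symmetric fixed point of the update equations: centres at the
        # masses, memberships saturating to 0/1
        L = np.array([[0.0, 0.0, 0.0], [100.0, 100.0, 100.0]])
        centers, u, part = fcm_cluster(L, FcmConfig(n_clusters=2, seed=1))
        assert centers[0] == pytest.approx(0.0, abs=1e-6)
        assert centers[1] == pytest.approx(100.0, abs=1e-6)
        assert u.max(axis=1).min() == pytest.approx(1.0, abs=1e-6)

    def test_pixel_at_centre_gets_full_membership(self):
        u = fcm_memberships(np.array([25.0]), np.array([25.0, 75.0]))
        assert u[0, 0] == pytest.approx(1.0)

    def test_memberships_row_normalised(self, noisy_cell):
        _, u, _ = fcm_cluster(noisy_cell.lab.L, FcmConfig(seed=0))
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            fcm_cluster(np.full((4, 4), 5.0), FcmConfig())

    def test_seed_thresholds_are_centre_midpoints(self, three_level_cell):
        chrom = fcm_seed_chromosome(three_level_cell.lab.L, FcmConfig(seed=0))
        assert 25.0 < chrom.t1 < 60.0
        assert 60.0 < chrom.t2 < 90.0


class TestGa:
    def test_three_level_image_recovered_exactly(self, three_level_cell):
        L = three_level_cell.lab.L
        chrom, part, _ = ga_optimize(L, GaConfig(seed=11))
        assert 25.0 < chrom.t1 < 60.0 and 60.0 < chrom.t2 < 90.0
        assert np.array_equal(assign_roles(part), three_level_cell.truth)

    def test_same_seed_identical_trace(self, noisy_cell):
        cfg = GaConfig(seed=5, max_generations=15, population_size=20)
        _, _, tr1 = ga_optimize(noisy_cell.lab.L, cfg)
        _, _, tr2 = ga_optimize(noisy_cell.lab.L, cfg)
        assert tr1 == tr2

    def test_best_fitness_monotone_non_increasing(self, noisy_cell):
        _, _, trace = ga_optimize(noisy_cell.lab.L,
                                  GaConfig(seed=2, max_generations=25, population_size=20))
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_matches_exhaustive_integer_search(self):
        """GA optimum is at least as good as brute force over all integer
        threshold pairs on a small image (independent oracle)."""
        rng = np.random.default_rng(0)
        L = rng.uniform(0, 100, size=(8, 8)).round(1)
        best = np.inf
        cfg = GaConfig()
        for t1 in range(100):
            for t2 in range(t1 + 1, 101):
                part = partition_by_thresholds(L, ThresholdChromosome(float(t1), float(t2)))
                best = min(best, fitness(part, cfg, penalty=1000.0))
        _, part, _ = ga_optimize(L, GaConfig(seed=1, penalty=1000.0))
        assert fitness(part, cfg, penalty=1000.0) <= best + 1e-9


class TestRoles:
    def test_centre_ordering(self):
        part = make_partition([15.0, 16.0], [55.0, 56.0], [92.0, 93.0])
        mask = assign_roles(part)
        assert mask[0] == NUCLEUS and mask[2] == CYTOPLASM and mask[4] == BACKGROUND

    def test_empty_middle_cluster(self):
        L = np.array([[10.0, 90.0, 10.0, 90.0]])
        part = partition_by_thresholds(L, ThresholdChromosome(40.0, 70.0))
        mask = assign_roles(part)
        assert set(np.unique(mask)) == {NUCLEUS, BACKGROUND}

    def test_tie_broken_by_size(self):
        part = make_partition([50.0], [50.0, 50.0], [90.0])
        mask = assign_roles(part)
        # equal centres: the larger of the tied clusters takes the brighter role
        assert mask[0] == NUCLEUS
        assert (mask[1:3] == CYTOPLASM).all()
        assert mask[3] == BACKGROUND


class TestMorphology:
    def test_small_hole_filled_into_nucleus(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[4:16, 4:16] = NUCLEUS
        mask[9:11, 9:11] = CYTOPLASM  # 4-px enclosed hole
        out = refine_morphology(mask)
        assert (out[9:11, 9:11] == NUCLEUS).all()
        assert (out == CYTOPLASM).sum() == 0

    def test_salt_speck_removed(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[2:28, 2:28] = CYTOPLASM
        mask[5:17, 5:17] = NUCLEUS
        mask[22, 22] = NUCLEUS  # isolated 1-px speck in the cytoplasm
        out = refine_morphology(mask)
        assert out[22, 22] == CYTOPLASM
        assert (out[5:17, 5:17] == NUCLEUS).all()

    def test_idempotent(self, noisy_cell):
        from sdmclust.clustering import segment
        mask, _, _ = segment(noisy_cell.lab.L, GaConfig(seed=1, max_generations=30,
                                                        population_size=20))
        once = refine_morphology(mask)
        assert np.array_equal(once, refine_morphology(once))

    def test_clean_mask_unchanged(self, three_level_cell):
        assert np.array_equal(refine_morphology(three_level_cell.truth),
                              three_level_cell.truth)

    def test_nucleus_survives_as_hole_of_cytoplasm_ring(self, three_level_cell):
        # the nucleus is the ring's one big enclosed cavity; it must not be
        # swallowed by hole filling
        out = refine_morphology(three_level_cell.truth)
        assert (out == NUCLEUS).sum() == (three_level_cell.truth == NUCLEUS).sum()
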