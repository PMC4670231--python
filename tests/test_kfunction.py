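"""Grayscale K-function: exact examples, oracle equivalence, invariances
and the CSR-reference / K-tilde contracts."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grayripley as gr
from grayripley.field import DomainError, GrayField, make_disc_kernel
from grayripley.kfunction import (
    EDGE_METHODS,
    CSRReference,
    KProfile,
    cornish_fisher_quantile,
    csr_reference,
    disc_area_in_mask,
    edge_correction_factor,
    k_profile,
    kmax_radius,
    ktilde,
    quantile_relative_error,
    ripley_k,
)
from grayripley.simulate import simulate_aggregates_only, simulate_csr

from conftest import disc_area_brute, k_double_sum, k_point_pattern, random_small_field


class TestDiscAreaAndCorrection:
    def test_interior_area_equals_kernel_size(self):
        f = GrayField(np.zeros((256, 256), int))
        assert disc_area_in_mask(f, (100, 100), make_disc_kernel(3)) == 29

    def test_corner_area_is_clipped(self):
        f = GrayField(np.zeros((256, 256), int))
        assert disc_area_in_mask(f, (0, 0), make_disc_kernel(3)) == 11

    def test_all_false_mask_has_zero_area(self):
        f = GrayField(np.zeros((8, 8), int), mask=np.zeros((8, 8), bool))
        assert disc_area_in_mask(f, (4, 4), make_disc_kernel(3)) == 0

    def test_off_lattice_pixel_rejected(self):
        f = GrayField(np.zeros((8, 8), int))
        with pytest.raises(ValueError):
            disc_area_in_mask(f, (8, 0), make_disc_kernel(1))

    @pytest.mark.parametrize("seed", range(5))
    def test_area_matches_brute_force_on_ragged_masks(self, seed):
        rng = np.random.default_rng(seed)
        field = random_small_field(rng)
        kernel = make_disc_kernel(2.5)
        for i, j in np.argwhere(field.mask)[:10]:
            assert disc_area_in_mask(field, (i, j), kernel) == disc_area_brute(
                field.mask, i, j, 2.5
            )

    def test_full_field_factor_values(self):
        f = GrayField(np.zeros((256, 256), int))
        k3 = make_disc_kernel(3)
        assert edge_correction_factor(f, (100, 100), k3, "full_field") == pytest.approx(
            9 * np.pi / 29
        )
        assert edge_correction_factor(f, (0, 0), k3, "full_field") == pytest.approx(
            9 * np.pi / 11
        )

    def test_border_methods_leave_interior_uncorrected(self):
        f = GrayField(np.zeros((256, 256), int))
        k3 = make_disc_kernel(3)
        assert edge_correction_factor(f, (100, 100), k3, "pixelated_border") == 1.0
        assert edge_correction_factor(f, (100, 100), k3, "ideal_border") == 1.0
        assert edge_correction_factor(f, (0, 0), k3, "pixelated_border") == pytest.approx(29 / 11)

    def test_mask_holes_create_borders(self):
        mask = np.ones((32, 32), bool)
        mask[10:20, 10:20] = False
        f = GrayField(np.zeros((32, 32), int), mask=mask)
        # pixel adjacent to the hole is a border pixel even though it is
        # far from the lattice edge
        assert edge_correction_factor(f, (9, 15), make_disc_kernel(3), "ideal_border") > 1.0

    def test_outside_study_region_is_a_domain_error(self):
        f = GrayField(np.zeros((8, 8), int), mask=np.zeros((8, 8), bool))
        with pytest.raises(DomainError):
            edge_correction_factor(f, (4, 4), make_disc_kernel(1), "full_field")


class TestRipleyK:
    def test_constant_field_with_covering_disc_gives_exact_circle_area(self):
        # every particle sees all n-1 others and c_x = pi r^2 / |Omega|
        field = GrayField(np.full((8, 8), 3))
        kernel = make_disc_kernel(20)
        assert ripley_k(field, kernel, "full_field") == pytest.approx(
            kernel.ideal_area, rel=1e-12
        )

    def test_fewer_than_two_particles_rejected(self):
        field = GrayField(np.zeros((8, 8), int))
        with pytest.raises(DomainError):
            ripley_k(field, make_disc_kernel(2), "full_field")

    def test_empty_mask_rejected(self):
        field = GrayField(np.ones((8, 8), int), mask=np.zeros((8, 8), bool))
        with pytest.raises(DomainError):
            ripley_k(field, make_disc_kernel(2), "full_field")

    def test_two_particle_hand_computed_value(self):
        # two unit pixels one step apart on a full 3x3 lattice, r=1: both
        # see each other; the corner pixel has A=3, the edge pixel A=4
        intensities = np.zeros((3, 3), int)
        intensities[0, 0] = intensities[0, 1] = 1
        field = GrayField(intensities)
        kernel = make_disc_kernel(1)
        expected = 9 / 2 * (np.pi / 3 + np.pi / 4)
        assert ripley_k(field, kernel, "full_field") == pytest.approx(expected, rel=1e-12)
        assert k_double_sum(field, 1, "full_field") == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), radius=st.sampled_from([1, 2, 2.5, 3]),
           method=st.sampled_from(EDGE_METHODS))
    def test_filter_path_equals_direct_double_sum(self, seed, radius, method):
        """The FFT evaluation must agree with the O(Np^2) double sum."""
        field = random_small_field(np.random.default_rng(seed))
        k_fast = ripley_k(field, make_disc_kernel(radius), method)
        k_slow = k_double_sum(field, radius, method)
        assert k_fast == pytest.approx(k_slow, rel=1e-9)

    @pytest.mark.parametrize("method", EDGE_METHODS)
    @pytest.mark.parametrize("seed", range(8))
    def test_binary_fields_reduce_to_point_pattern_k(self, seed, method):
        field = random_small_field(np.random.default_rng(100 + seed), binary=True)
        k_gray = ripley_k(field, make_disc_kernel(2.5), method)
        k_points = k_point_pattern(field, 2.5, method)
        assert k_gray == pytest.approx(k_points, rel=1e-9)

    @pytest.mark.parametrize("method", EDGE_METHODS)
    def test_geometric_invariance(self, method):
        rng = np.random.default_rng(7)
        intensities = rng.integers(0, 20, size=(24, 24))
        mask = rng.random((24, 24)) < 0.9
        base = ripley_k(GrayField(intensities, mask=mask), make_disc_kernel(3), method)
        for op in (np.rot90, np.transpose, np.fliplr):
            k_t = ripley_k(GrayField(op(intensities), mask=op(mask)),
                           make_disc_kernel(3), method)
            assert k_t == pytest.approx(base, rel=1e-9)

    def test_intensity_rescaling_changes_k(self):
        # K is not invariant under contrast changes; the library never
        # rescales silently, so callers must not either.
        rng = np.random.default_rng(3)
        intensities = rng.integers(0, 10, size=(32, 32))
        kernel = make_disc_kernel(3)
        k1 = ripley_k(GrayField(intensities), kernel, "full_field")
        k2 = ripley_k(GrayField(intensities * 2), kernel, "full_field")
        assert k1 != pytest.approx(k2, rel=1e-6)


@pytest.fixture(scope="module")
def small_ref():
    mask = np.ones((64, 64), bool)
    return csr_reference(mask, 4096, make_disc_kernel(4), "full_field",
                         replicates=300, seed=11)


class TestCSRReference:
    def test_deterministic_given_seed(self, small_ref):
        mask = np.ones((64, 64), bool)
        again = csr_reference(mask, 4096, make_disc_kernel(4), "full_field",
                              replicates=300, seed=11)
        assert dataclasses.asdict(again) == dataclasses.asdict(small_ref)

    def test_mean_k_near_circle_area_and_quantiles_bracket_zero(self, small_ref):
        se = np.sqrt(small_ref.var_k / small_ref.replicates)
        assert abs(small_ref.mean_k - make_disc_kernel(4).ideal_area) < 3 * se
        assert small_ref.q01_empirical < 0 < small_ref.q99_empirical
        assert small_ref.q01_cf < 0 < small_ref.q99_cf
        assert small_ref.var_k > 0

    def test_ktilde_is_standardized_on_held_out_replicates(self, small_ref):
        mask = np.ones((64, 64), bool)
        kernel = make_disc_kernel(4)
        values = []
        for i in range(150):
            f = simulate_csr((64, 64), n=4096, seed=50_000 + i)
            values.append(ktilde(f, kernel, "full_field", small_ref))
        values = np.asarray(values)
        assert abs(values.mean()) < 3 / np.sqrt(len(values))
        assert 0.7 < values.var(ddof=1) < 1.4
        inside = np.mean(
            (values >= small_ref.q01_empirical) & (values <= small_ref.q99_empirical)
        )
        assert inside > 0.9

    def test_clustered_field_exceeds_upper_quantile(self, small_ref):
        field, _ = simulate_aggregates_only((64, 64), n_clusters=1,
                                            cluster_radius=5, n_particles=4096,
                                            seed=3)
        value = ktilde(field, make_disc_kernel(4), "full_field", small_ref)
        assert value > 10 * small_ref.q99_empirical

    def test_reference_mismatch_is_rejected(self, small_ref):
        kernel = make_disc_kernel(4)
        wrong_n = simulate_csr((64, 64), n=4000, seed=1)
        with pytest.raises(ValueError):
            ktilde(wrong_n, kernel, "full_field", small_ref)
        # a relaxed count tolerance accepts the 2% mismatch
        assert np.isfinite(ktilde(wrong_n, kernel, "full_field", small_ref, n_rtol=0.05))
        right_n = simulate_csr((64, 64), n=4096, seed=1)
        with pytest.raises(ValueError):
            ktilde(right_n, make_disc_kernel(5), "full_field", small_ref)
        with pytest.raises(ValueError):
            ktilde(right_n, kernel, "ideal_border", small_ref)
        other_mask = np.ones((64, 64), bool)
        other_mask[0, 0] = False
        shifted = simulate_csr((64, 64), n=4096, mask=other_mask, seed=1)
        with pytest.raises(ValueError):
            ktilde(shifted, kernel, "full_field", small_ref)

    def test_too_many_particles_for_mask_rejected(self):
        with pytest.raises(DomainError):
            csr_reference(np.ones((2, 2), bool), 5000, make_disc_kernel(1),
                          "full_field", replicates=100, seed=0)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            csr_reference(np.ones((8, 8), bool), 10, make_disc_kernel(1),
                          "full_field", replicates=50, seed=0)


class TestCornishFisher:
    def test_zero_skew_reduces_to_normal_quantiles(self):
        assert cornish_fisher_quantile(0.99, 0.0) == pytest.approx(2.3263, abs=1e-4)
        assert cornish_fisher_quantile(0.01, 0.0) == pytest.approx(-2.3263, abs=1e-4)

    def test_positive_skew_stretches_the_upper_tail(self):
        assert cornish_fisher_quantile(0.99, 0.5) > cornish_fisher_quantile(0.99, 0.0)
        assert cornish_fisher_quantile(0.01, 0.5) > cornish_fisher_quantile(0.01, 0.0)

    def test_relative_error_of_identical_quantiles_is_zero(self):
        ref = CSRReference(
            mask_signature="x", n=10, radius=3.0, edge_method="full_field",
            replicates=100, seed=0, mean_k=28.0, var_k=1.0, skew_k=0.0,
            q01_empirical=-2.3, q99_empirical=2.3, q01_cf=-2.3, q99_cf=2.3,
        )
        assert quantile_relative_error(ref) == (0.0, 0.0)

    def test_degenerate_zero_quantile_rejected(self):
        ref = CSRReference(
            mask_signature="x", n=10, radius=3.0, edge_method="full_field",
            replicates=100, seed=0, mean_k=28.0, var_k=1.0, skew_k=0.0,
            q01_empirical=0.0, q99_empirical=2.3, q01_cf=-2.3, q99_cf=2.3,
        )
        with pytest.raises(DomainError):
            quantile_relative_error(ref)


class TestProfiles:
    def _profile(self, ktildes, radii):
        r = np.asarray(radii, dtype=float)
        return KProfile(radii=r, k_values=np.zeros(len(r)),
                        ktilde_values=np.asarray(ktildes, dtype=float),
                        n=10, omega_area=100, edge_method="full_field")

    def test_kmax_picks_the_interior_maximum(self):
        assert kmax_radius(self._profile([1, 3, 2], [2, 4, 6])) == 4

    def test_kmax_tie_breaks_to_smallest_radius(self):
        assert kmax_radius(self._profile([3, 3], [4, 6])) == 4

    def test_kmax_of_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            kmax_radius(self._profile([], []))

    def test_profile_matches_per_radius_calls(self):
        mask = np.ones((48, 48), bool)
        field = simulate_csr((48, 48), density=2.0, seed=5)
        radii = [2.0, 3.0, 4.0]
        refs = [csr_reference(mask, field.n, make_disc_kernel(r), "full_field",
                              replicates=100, seed=20 + i)
                for i, r in enumerate(radii)]
        prof = k_profile(field, radii, "full_field", refs)
        for i, (r, ref) in enumerate(zip(radii, refs)):
            kernel = make_disc_kernel(r)
            assert prof.k_values[i] == pytest.approx(ripley_k(field, kernel, "full_field"))
            assert prof.ktilde_values[i] == pytest.approx(
                ktilde(field, kernel, "full_field", ref)
            )

    def test_empty_radii_give_empty_profile(self):
        field = simulate_csr((16, 16), density=1.0, seed=0)
        prof = k_profile(field, [], "full_field", [])
        assert len(prof) == 0

    def test_radii_must_increase(self):
        field = simulate_csr((16, 16), density=1.0, seed=0)
        with pytest.raises(ValueError):
            k_profile(field, [3, 2], "full_field", [None, None])
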