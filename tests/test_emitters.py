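import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mnphotodose import (
    ArrayGeometry,
    EmitterDisk,
    SingularityError,
    annulus_integrand,
    array_intensity_bruteforce,
    compare_models,
    directed_intensity,
    disk_intensity,
    disk_intensity_bruteforce,
    disk_intensity_quadrature,
    point_source_intensity,
)

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestPointSource:
    def test_reference_distance_returns_reference_intensity(self):
        assert point_source_intensity(1.0, 1.0, 1.0) == 1.0

    def test_inverse_square_at_double_distance(self):
        assert point_source_intensity(2.0, 1.0, 2.0) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=50)
    @given(I0=positive, r0=positive, d=positive)
    def test_doubling_distance_quarters_intensity(self, I0, r0, d):
        near = point_source_intensity(I0, r0, d)
        far = point_source_intensity(I0, r0, 2 * d)
        assert far == pytest.approx(near / 4)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            point_source_intensity(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            point_source_intensity(1.0, 0.0, 1.0)


class TestAnnulusIntegrand:
    def test_vanishing_annulus_at_zero_radius(self, unit_disk):
        assert annulus_integrand(1.0, 0.0, unit_disk) == 0.0

    def test_direct_substitution_gives_pi(self, unit_disk):
        # 2π·1·1/(1+1) = π
        assert annulus_integrand(1.0, 1.0, unit_disk) == pytest.approx(math.pi)

    def test_nonpositive_rho_rejected(self, unit_disk):
        with pytest.raises(ValueError):
            annulus_integrand(0.0, 1.0, unit_disk)


class TestClosedForm:
    def test_pi_ln2_at_rho_equal_R(self, unit_disk):
        """At ρ = R the log term is ln 2, so I = π ln 2 exactly."""
        assert disk_intensity(1.0, unit_disk, attenuated=False) == pytest.approx(
            math.pi * math.log(2), rel=1e-15
        )

    @pytest.mark.parametrize("ratio", [0.1, 0.5, 1.0, 2.0, 10.0])
    def test_matches_adaptive_quadrature_of_the_integrand(self, ratio):
        disk = EmitterDisk(R=2.5, sigma=0.7, I0=3.0, r0=0.4, alpha=0.0)
        rho = ratio * disk.R
        closed = disk_intensity(rho, disk, attenuated=False)
        quad = disk_intensity_quadrature(rho, disk)
        assert closed == pytest.approx(quad, rel=1e-8)

    @settings(derandomize=True, max_examples=50)
    @given(rho=positive, R=positive, alpha=st.floats(0.0, 5.0))
    def test_attenuated_form_factorizes_as_global_exponential(self, rho, R, alpha):
        disk = EmitterDisk(R=R, alpha=alpha)
        plain = disk_intensity(rho, disk, attenuated=False)
        att = disk_intensity(rho, disk, attenuated=True)
        assert att == pytest.approx(plain * math.exp(-alpha * rho), rel=1e-12)

    def test_singularity_guard_raises_instead_of_returning_infinity(self, unit_disk):
        with pytest.raises(SingularityError):
            disk_intensity(1e-9, unit_disk)

    def test_small_source_limit_approaches_lumped_point_source(self):
        """For R ≪ ρ the disk acts as σπR² emitters lumped at the center."""
        rho = 1.0
        errs = []
        for ratio in (1e-1, 1e-2, 1e-3):
            disk = EmitterDisk(R=ratio * rho)
            lumped = disk.sigma * math.pi * disk.R**2 * point_source_intensity(
                disk.I0, disk.r0, rho
            )
            full = disk_intensity(rho, disk, attenuated=False)
            errs.append(abs(full - lumped) / lumped)
        assert errs[0] > errs[1] > errs[2]
        assert errs[1] < 1e-4

    def test_strictly_decreasing_in_rho_and_increasing_in_R(self, unit_disk):
        rhos = np.linspace(0.2, 5.0, 40)
        vals = disk_intensity(rhos, unit_disk, attenuated=False)
        assert np.all(np.diff(vals) < 0)
        Rs = np.linspace(0.5, 4.0, 20)
        by_R = [disk_intensity(1.0, EmitterDisk(R=R), attenuated=False) for R in Rs]
        assert np.all(np.diff(by_R) > 0)

    @settings(derandomize=True, max_examples=30)
    @given(scale=positive)
    def test_linear_in_density_and_in_I0_r0_squared(self, scale):
        base = EmitterDisk(R=1.0, sigma=1.0, I0=1.0, r0=1.0)
        ref = disk_intensity(0.7, base, attenuated=False)
        scaled_sigma = EmitterDisk(R=1.0, sigma=scale)
        assert disk_intensity(0.7, scaled_sigma, attenuated=False) == pytest.approx(
            scale * ref, rel=1e-12
        )
        scaled_I = EmitterDisk(R=1.0, I0=scale, r0=2.0)
        assert disk_intensity(0.7, scaled_I, attenuated=False) == pytest.approx(
            scale * 4.0 * ref, rel=1e-12
        )


class TestMonteCarloOracle:
    def test_agrees_with_closed_form_within_three_standard_errors(self, unit_disk):
        est = disk_intensity_bruteforce(1.0, unit_disk, n_emitters=10**5, seed=42)
        closed = disk_intensity(1.0, unit_disk, attenuated=False)
        assert abs(est.value - closed) <= 3 * est.stderr
        assert est.stderr < 0.01 * closed

    def test_single_emitter_near_center_reduces_to_point_source(self):
        # R → 0 pins the lone emitter at the disk center
        disk = EmitterDisk(R=1e-9, sigma=1.0)
        est = disk_intensity_bruteforce(2.0, disk, n_emitters=1, seed=0)
        expected = disk.sigma * math.pi * disk.R**2 * point_source_intensity(
            1.0, 1.0, 2.0
        )
        assert est.value == pytest.approx(expected, rel=1e-12)

    def test_deterministic_under_seed(self, unit_disk):
        a = disk_intensity_bruteforce(1.0, unit_disk, 1000, seed=5)
        b = disk_intensity_bruteforce(1.0, unit_disk, 1000, seed=5)
        assert a.value == b.value

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
    def test_per_emitter_attenuation_never_exceeds_global_factor(self, alpha, ratio):
        """Each path dᵢ ≥ ρ, so per-path attenuation removes more light."""
        rho = 1.0
        disk = EmitterDisk(R=ratio * rho, alpha=alpha)
        per = disk_intensity_bruteforce(
            rho, disk, 10**4, seed=7, per_emitter_attenuation=True
        )
        glob = disk_intensity(rho, disk, attenuated=True)
        assert per.value <= glob


class TestArrayOracle:
    def test_single_tip_equals_attenuated_point_source(self):
        geom = ArrayGeometry(n_rows=1, n_cols=1)
        d = 123.0
        got = array_intensity_bruteforce((0.0, 0.0, d), geom, I0=2.0, r0=5.0, alpha=0.01)
        want = point_source_intensity(2.0, 5.0, d) * math.exp(-0.01 * d)
        assert got == pytest.approx(want, rel=1e-12)

    def test_mirror_symmetric_off_axis_points_agree(self, geometry):
        a = array_intensity_bruteforce((500.0, 0.0, 800.0), geometry)
        b = array_intensity_bruteforce((-500.0, 0.0, 800.0), geometry)
        assert a == pytest.approx(b, rel=1e-12)

    def test_far_field_matches_continuum_disk_model(self, geometry):
        """On-axis far field: the 19×19 grid behaves as the equivalent disk."""
        sigma = 1.0 / geometry.pitch_um**2
        n_tips = geometry.n_rows * geometry.n_cols
        R_eq = math.sqrt(n_tips * geometry.pitch_um**2 / math.pi)
        rho = 10.0 * geometry.extent_x_um
        grid = array_intensity_bruteforce((0.0, 0.0, rho), geometry)
        disk = EmitterDisk(R=R_eq, sigma=sigma)
        cont = disk_intensity(rho, disk, attenuated=False)
        assert grid == pytest.approx(cont, rel=0.01)

    def test_coincident_point_raises(self, geometry):
        with pytest.raises(SingularityError):
            array_intensity_bruteforce((0.0, 0.0, 0.0), ArrayGeometry(n_rows=1, n_cols=1))


class TestDirectedBeam:
    def test_surface_value_and_lossless_medium(self):
        assert directed_intensity(0.0, I0=3.0, alpha=1.0) == 3.0
        z = np.linspace(0, 10, 5)
        assert np.allclose(directed_intensity(z, I0=3.0, alpha=0.0), 3.0)

    @settings(derandomize=True, max_examples=30)
    @given(z1=st.floats(0.0, 50.0), z2=st.floats(0.0, 50.0), alpha=st.floats(0.0, 2.0))
    def test_exponential_semigroup_composition(self, z1, z2, alpha):
        whole = directed_intensity(z1 + z2, alpha=alpha)
        step = directed_intensity(z1, alpha=alpha) * math.exp(-alpha * z2)
        assert whole == pytest.approx(step, rel=1e-9)

    def test_dispersion_variant_adds_inverse_square_spreading(self):
        got = directed_intensity(1.0, I0=4.0, alpha=0.0, r0=1.0, dispersion=True)
        assert got == pytest.approx(1.0)  # 4·(1/2)²

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            directed_intensity(-0.1)


class TestCompareModels:
    def test_point_like_disk_self_comparison_is_null(self):
        """R → 0 makes the disk a point source: identical to the dispersive
        beam, so the fractional attenuation difference vanishes. At R = 1e-3
        the residual deviation is O(R²/2) ≈ 5e-7."""
        disk = EmitterDisk(R=1e-3, alpha=0.5)
        res = compare_models(disk, np.linspace(1.0, 5.0, 20))
        assert abs(res.fractional_difference) < 1e-5
        assert np.allclose(
            res.disk_profile.intensities, res.beam_profile.intensities, atol=1e-5
        )

    def test_output_rows_match_depth_grid(self, unit_disk):
        depths = np.linspace(1.0, 3.0, 17)
        res = compare_models(unit_disk, depths)
        assert len(res.disk_profile.depths) == 17
        assert len(res.to_frame()) == 34

    def test_empty_depth_grid_rejected(self, unit_disk):
        with pytest.raises(ValueError):
            compare_models(unit_disk, [])

    @pytest.mark.parametrize("R_over_rho", [0.1, 0.5, 1.0, 3.0, 10.0])
    @pytest.mark.parametrize("alpha_rho", [0.1, 1.0, 3.0])
    def test_distributed_source_attenuates_more_slowly_than_directed_beam(
        self, R_over_rho, alpha_rho
    ):
        """Across the sweep, the normalized disk profile stays above the
        point-source beam profile at every depth: distributing emitters over
        a finite disk flattens the fall-off."""
        rho0 = 1.0
        disk = EmitterDisk(R=R_over_rho * rho0, alpha=alpha_rho / rho0)
        depths = np.linspace(rho0, 5 * rho0, 30)
        res = compare_models(disk, depths)
        assert np.all(
            res.disk_profile.intensities[1:] > res.beam_profile.intensities[1:]
        )
        assert res.attenuation_disk < res.attenuation_beam

    def test_pure_exponential_comparator_decays_slower_than_disk(self, unit_disk):
        """Without dispersion the beam keeps only Beer–Lambert decay, which
        the disk's decreasing log factor always undercuts."""
        disk = EmitterDisk(R=1.0, alpha=0.5)
        res = compare_models(disk, np.linspace(1.0, 5.0, 30), beam_dispersion=False)
        assert np.all(
            res.disk_profile.intensities[1:] < res.beam_profile.intensities[1:]
        )
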