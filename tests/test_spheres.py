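import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbsuggest.field import FieldModelConfig, sweep_transform_samples
from dbsuggest.lead_model import build_lead
from dbsuggest.spheres import (
    CurrentRadiusTransform,
    PlacementModel,
    Sphere,
    current_to_radius,
    fit_transform,
    overlap_at_current,
    place_vta,
    radius_to_current,
    sphere_overlap,
)
from dbsuggest.volumes import make_reference_grid

from conftest import montecarlo_sphere_overlap

DEFAULT = CurrentRadiusTransform()


class TestTransform:
    @pytest.mark.parametrize(
        "r,expected", [(0.0, 0.0), (1.0, 0.79), (2.0, 2.30)]
    )
    def test_printed_polynomial_values(self, r, expected):
        assert radius_to_current(DEFAULT, r) == pytest.approx(expected, abs=1e-12)

    def test_inverse_of_printed_value(self):
        assert current_to_radius(DEFAULT, 0.79) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=50.0))
    @settings(max_examples=200, derandomize=True)
    def test_exact_round_trip(self, r):
        assert radius_to_current(DEFAULT, current_to_radius(DEFAULT, r)) == pytest.approx(
            r, abs=1e-12
        )

    @given(st.floats(min_value=0.0, max_value=20.0), st.floats(min_value=0.001, max_value=20.0))
    @settings(max_examples=100, derandomize=True)
    def test_strictly_increasing(self, i, di):
        assert current_to_radius(DEFAULT, i + di) > current_to_radius(DEFAULT, i)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            radius_to_current(DEFAULT, -1.0)
        with pytest.raises(ValueError):
            current_to_radius(DEFAULT, -0.1)


class TestFitTransform:
    def test_noiseless_recovery_of_printed_coefficients(self):
        rr = np.arange(0.2, 5.0, 0.1)
        samples = [(0.43 * r + 0.36 * r**2, r) for r in rr]
        t, r2 = fit_transform(samples)
        assert t.a1 == pytest.approx(0.43, abs=1e-9)
        assert t.a2 == pytest.approx(0.36, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_field_standin_sweep_fits_well(self):
        lead = build_lead((0, 0, 0), (0, 0, 1))
        ref = make_reference_grid(lead.level_centers[0], 8.0, 0.25)
        samples = sweep_transform_samples(lead.contact("1"), ref, FieldModelConfig())
        t, r2 = fit_transform(samples)
        assert r2 >= 0.99
        assert t.a2 > 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_transform([(1.0, 1.0), (2.0, 1.5)])

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            fit_transform([(1.0, 2.0), (1.0, 2.0), (1.0, 2.0)])


class TestPlaceVta:
    def test_directional_center_drifts_along_segment(self, straight_lead):
        c = straight_lead.contact("2")  # directional, level 2
        t = CurrentRadiusTransform()
        i_for_r2 = radius_to_current(t, 2.0)
        sphere = place_vta(c, i_for_r2, t, PlacementModel(gamma=0.1))
        u = c.segment_direction
        assert np.allclose(sphere.center, c.p_e + 0.1 * u * 2.0, atol=1e-12)
        assert sphere.radius == pytest.approx(2.0)

    def test_omnidirectional_center_fixed_at_level_center(self, straight_lead):
        c = straight_lead.contact("1")
        for current in (0.5, 2.0, 8.0):
            assert np.allclose(place_vta(c, current).center, c.p_c)

    def test_ring_mode_center_fixed_at_level_center(self, straight_lead):
        ring = straight_lead.contact("ring2")
        assert np.allclose(place_vta(ring, 3.0).center, ring.p_c)

    def test_gamma_zero_keeps_center_at_surface(self, straight_lead):
        c = straight_lead.contact("5")
        sphere = place_vta(c, 4.0, DEFAULT, PlacementModel(gamma=0.0))
        assert np.allclose(sphere.center, c.p_e)


class TestSphereOverlap:
    def test_tangent_spheres_zero(self):
        assert sphere_overlap(2.0, 4.0, 2.0) == 0.0

    def test_containment_returns_inner_volume(self):
        assert sphere_overlap(2.0, 0.5, 3.0) == pytest.approx(4 / 3 * np.pi * 8)
        assert sphere_overlap(3.0, 0.5, 2.0) == pytest.approx(4 / 3 * np.pi * 8)

    def test_equal_sphere_lens_matches_independent_formula(self):
        # independent equal-sphere lens: pi (4R + d)(2R - d)^2 / 12
        R, d = 2.0, 2.0
        expected = math.pi * (4 * R + d) * (2 * R - d) ** 2 / 12.0
        assert sphere_overlap(R, d, R) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(80 * math.pi / 24)

    def test_concentric_equal_radii_no_division_by_zero(self):
        assert sphere_overlap(2.0, 0.0, 2.0) == pytest.approx(4 / 3 * np.pi * 8)

    def test_symmetry_in_radii(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            r1, r2 = rng.uniform(0.1, 4.0, 2)
            d = rng.uniform(0.0, r1 + r2 + 1.0)
            assert sphere_overlap(r1, d, r2) == pytest.approx(
                sphere_overlap(r2, d, r1), rel=1e-12
            )

    def test_continuity_at_case_boundaries(self):
        rng = np.random.default_rng(3)
        eps = 1e-9
        for _ in range(50):
            r1, r2 = rng.uniform(0.5, 4.0, 2)
            outer = r1 + r2
            inner = abs(r1 - r2)
            assert sphere_overlap(r1, outer - eps, r2) == pytest.approx(
                sphere_overlap(r1, outer + eps, r2), abs=1e-6
            )
            assert sphere_overlap(r1, max(inner - eps, 0), r2) == pytest.approx(
                sphere_overlap(r1, inner + eps, r2), abs=1e-6
            )

    def test_agrees_with_monte_carlo_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            r1, r2 = rng.uniform(0.3, 4.0, 2)
            d = rng.uniform(0.0, r1 + r2 + 0.3)
            analytic = sphere_overlap(r1, d, r2)
            mc = montecarlo_sphere_overlap(r1, d, r2, n=400_000, rng=rng)
            assert analytic == pytest.approx(mc, abs=max(0.5, 0.01 * max(analytic, mc)))

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            sphere_overlap(-1.0, 1.0, 1.0)


class TestOverlapAtCurrent:
    def test_zero_current_zero_overlap(self, straight_lead, sweetspot_sphere):
        c = straight_lead.contact("2")
        assert overlap_at_current(c, 0.0, sweetspot_sphere) == 0.0

    def test_far_contact_never_overlaps(self, straight_lead):
        far = Sphere(center=(100.0, 0.0, 0.0), radius=2.0)
        for c in straight_lead.contacts:
            for current in (1.0, 4.0, 8.0):
                assert overlap_at_current(c, current, far) == 0.0

    def test_plateau_at_sweetspot_volume(self, straight_lead):
        c = straight_lead.contact("1")
        ss = Sphere(center=c.p_c, radius=1.5)
        big = overlap_at_current(c, 30.0, ss)
        assert big == pytest.approx(ss.volume)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monotone_in_current_for_gamma_below_one(self, seed):
        rng = np.random.default_rng(seed)
        lead = build_lead(rng.normal(0, 3, 3), rng.normal(0, 1, 3) + [0, 0, 1.5],
                          roll_angle=float(rng.uniform(0, 360)))
        ss = Sphere(center=rng.normal(0, 3, 3) + [0, 0, 3.75],
                    radius=float(rng.uniform(0.5, 4.0)))
        pm = PlacementModel(gamma=float(rng.uniform(0.0, 0.99)))
        contact = lead.contacts[int(rng.integers(0, len(lead.contacts)))]
        currents = np.linspace(0.0, 10.0, 40)
        vals = [overlap_at_current(contact, i, ss, DEFAULT, pm) for i in currents]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))
        assert max(vals) <= ss.volume + 1e-9
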