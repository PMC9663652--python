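import numpy as np
import pytest

from dbsuggest.desired_overlap import DesiredOverlapModel
from dbsuggest.engines import IASEngine
from dbsuggest.lead_model import build_lead, transform_lead
from dbsuggest.spheres import Sphere, radius_to_current, CurrentRadiusTransform
from dbsuggest.suggest import (
    reconstruction_guided,
    shortlist_contacts,
    suggest_best_contact,
    suggest_best_level,
    threshold_continuous,
    threshold_grid_search,
)
from dbsuggest.volumes import make_reference_grid, rasterize_sphere

CONST_VD = DesiredOverlapModel()  # constant 33%


class TestGridSearch:
    def test_worked_example_interpolates_to_2_5(self):
        overlaps = {i: 20.0 * (i - 1) for i in range(1, 9)}  # 0,20,40,...
        s = threshold_grid_search(lambda i: overlaps[i], vd=30.0)
        # |20-30| ties |40-30|; tie resolves to the lower current (2 mA)
        assert s.initial_index == 1
        assert s.estimate == pytest.approx(2.5)
        assert s.reached

    def test_exact_hit_is_fixed_point(self):
        overlaps = {i: 20.0 * (i - 1) for i in range(1, 9)}
        s = threshold_grid_search(lambda i: overlaps[i], vd=40.0)
        assert s.estimate == 3.0

    def test_unattainable_target_not_reached(self):
        s = threshold_grid_search(lambda i: 5.0, vd=500.0)
        assert not s.reached and s.estimate is None

    def test_overestimate_at_first_node_interpolates_from_zero(self):
        s = threshold_grid_search(lambda i: 40.0 * i, vd=10.0)
        assert s.initial_index == 0
        assert s.estimate == pytest.approx(0.25)

    def test_flat_segment_degenerates_to_node(self):
        vals = {1: 0.0, 2: 20.0, 3: 20.0, 4: 20.0, 5: 90.0, 6: 95.0, 7: 96.0, 8: 97.0}
        s = threshold_grid_search(lambda i: vals[i], vd=25.0)
        assert s.reached
        assert s.estimate is not None

    def test_nonascending_grid_rejected(self):
        with pytest.raises(ValueError):
            threshold_grid_search(lambda i: i, vd=1.0, grid=[2.0, 1.0])


class TestContinuous:
    def test_matches_grid_search_on_linear_overlap_curve(self):
        f = lambda i: 12.0 * i
        for vd in (6.0, 30.0, 90.0):
            g = threshold_grid_search(f, vd)
            c = threshold_continuous(f, vd, i_max=8.0, tol=1e-6)
            assert c.estimate == pytest.approx(g.estimate, abs=1e-4)

    def test_unreachable_within_ceiling(self):
        c = threshold_continuous(lambda i: i, vd=20.0, i_max=8.0)
        assert not c.reached and c.estimate is None

    def test_overlap_at_estimate_hits_target(self, straight_lead, sweetspot_sphere):
        engine = IASEngine(sweetspot_sphere)
        contact = straight_lead.contact("2")
        vd = 0.33 * sweetspot_sphere.volume
        s = threshold_continuous(lambda i: engine.overlap(contact, i), vd)
        assert s.reached
        assert engine.overlap(contact, s.estimate) >= vd
        assert engine.overlap(contact, s.estimate - 0.05) < vd

    def test_containment_boundary(self, straight_lead):
        # contact at the sweet-spot center: full coverage needs r_VTA >= r_SS
        contact = straight_lead.contact("1")
        ss = Sphere(center=contact.p_c, radius=2.0)
        s = threshold_continuous(
            lambda i: IASEngine(ss).overlap(contact, i), vd=ss.volume * 0.999, i_max=8.0
        )
        expected = radius_to_current(CurrentRadiusTransform(), 2.0)
        assert s.estimate == pytest.approx(expected, abs=0.05)

    def test_monotone_in_target(self, straight_lead, sweetspot_sphere):
        engine = IASEngine(sweetspot_sphere)
        contact = straight_lead.contact("2")
        ests = []
        for frac in (0.05, 0.15, 0.30, 0.60):
            s = threshold_continuous(
                lambda i: engine.overlap(contact, i), frac * sweetspot_sphere.volume
            )
            ests.append(s.estimate)
        assert all(b >= a for a, b in zip(ests, ests[1:]))

    def test_cross_method_consistency_random_geometries(self):
        rng = np.random.default_rng(12)
        checked = 0
        for _ in range(200):
            lead = build_lead(rng.normal(0, 2, 3), [0, 0, 1.0],
                              roll_angle=float(rng.uniform(0, 360)))
            ss = Sphere(rng.normal(0, 2, 3) + [0, 0, 3.75], float(rng.uniform(1.5, 3.5)))
            engine = IASEngine(ss)
            contact = lead.contacts[int(rng.integers(0, 10))]
            vd = float(rng.uniform(0.1, 0.5)) * ss.volume
            f = lambda i: engine.overlap(contact, i)
            c = threshold_continuous(f, vd, i_max=8.0)
            g = threshold_grid_search(f, vd)
            if not (c.reached and g.reached and g.estimate >= 1.0):
                continue
            # compare only where the curve is locally near-linear between nodes
            lo, hi = int(np.floor(g.estimate)), int(np.ceil(g.estimate))
            if hi == lo:
                hi += 1
            mid = 0.5 * (lo + hi)
            lin = 0.5 * (f(lo) + f(hi))
            if abs(lin - f(mid)) > 0.02 * max(f(hi), 1e-9):
                continue
            checked += 1
            assert c.estimate == pytest.approx(g.estimate, abs=0.15)
        assert checked >= 50  # enough informative geometries

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            threshold_continuous(lambda i: i, vd=0.0)


class TestBestSite:
    def test_symmetric_sweetspot_ties_levels_2_and_3(self, straight_lead):
        # sweet spot centered between levels 2 and 3 on the lead axis
        ss = Sphere(center=(0.0, 0.0, 3.75), radius=2.5)
        res = suggest_best_level(straight_lead, IASEngine(ss), CONST_VD)
        assert res.best_level == {2, 3}

    def test_sweetspot_on_level2_selects_level2(self, straight_lead):
        ss = Sphere(center=(0.0, 0.0, 2.75), radius=2.5)
        res = suggest_best_level(straight_lead, IASEngine(ss), CONST_VD)
        assert res.best_level == {2}

    def test_far_sweetspot_yields_empty_best_set(self, straight_lead):
        ss = Sphere(center=(80.0, 0.0, 0.0), radius=2.5)
        res = suggest_best_level(straight_lead, IASEngine(ss), CONST_VD)
        assert res.best_level == frozenset()
        assert all(not s.reached for s in res.sites)

    def test_facing_segment_beats_opposite_segment(self, straight_lead):
        contact2 = straight_lead.contact("2")
        u = contact2.segment_direction
        ss = Sphere(center=contact2.p_c + 3.0 * u, radius=2.5)
        res = suggest_best_contact(straight_lead, IASEngine(ss), CONST_VD)
        est = {s.contact_id: s.estimate for s in res.sites if s.reached}
        # segments 3 and 4 face 120 degrees away on the same level
        assert est["2"] < est.get("3", np.inf)
        assert est["2"] < est.get("4", np.inf)
        assert res.best_contact == {"2"}

    def test_sweetspot_on_level1_selects_omni_contact_1(self, straight_lead):
        ss = Sphere(center=straight_lead.level_centers[0], radius=2.0)
        res = suggest_best_contact(straight_lead, IASEngine(ss), CONST_VD)
        assert res.best_contact == {"1"}

    def test_best_contact_invariant_under_rigid_rotation(self, straight_lead):
        ss_center = np.array([1.5, 0.5, 3.0])
        theta = np.radians(55.0)
        R = np.array(
            [
                [1, 0, 0],
                [0, np.cos(theta), -np.sin(theta)],
                [0, np.sin(theta), np.cos(theta)],
            ]
        )
        t = np.array([4.0, -1.0, 2.0])
        res0 = suggest_best_contact(
            straight_lead, IASEngine(Sphere(ss_center, 2.5)), CONST_VD
        )
        rotated = transform_lead(straight_lead, R, t)
        res1 = suggest_best_contact(
            rotated, IASEngine(Sphere(R @ ss_center + t, 2.5)), CONST_VD
        )
        assert res0.best_contact == res1.best_contact
        for s0, s1 in zip(res0.sites, res1.sites):
            if s0.reached:
                assert s1.estimate == pytest.approx(s0.estimate, abs=0.02)


class TestShortlistAndBaseline:
    def test_shortlist_picks_nearest_contacts(self, straight_lead):
        target = straight_lead.level_centers[0]
        ids = [c.contact_id for c in shortlist_contacts(straight_lead, target, k=3)]
        assert ids[0] == "1"
        assert len(ids) == 3

    def test_shortlist_k8_returns_all(self, straight_lead):
        assert len(shortlist_contacts(straight_lead, (0, 0, 0), k=8)) == 8

    def test_reconstruction_guided_level_and_contact(self, straight_lead):
        ref = make_reference_grid(straight_lead.level_centers[2], 3.0, 0.5)
        stn = rasterize_sphere(Sphere(straight_lead.level_centers[2], 2.0), ref)
        levels, contacts = reconstruction_guided(straight_lead, stn)
        assert levels == {3}
        # centroid on the axis: nearest contact is a level-3 site
        best = straight_lead.contact(next(iter(contacts)))
        assert best.level_index == 3

    def test_centroid_in_segment_wedge_selects_that_segment(self, straight_lead):
        c2 = straight_lead.contact("2")
        center = c2.p_e + 1.5 * c2.segment_direction
        ref = make_reference_grid(center, 1.5, 0.25)
        stn = rasterize_sphere(Sphere(center, 0.8), ref)
        _, contacts = reconstruction_guided(straight_lead, stn)
        assert contacts == {"2"}

    def test_empty_stn_mask_rejected(self, straight_lead):
        ref = make_reference_grid((0, 0, 0), 2.0, 0.5)
        with pytest.raises(ValueError):
            reconstruction_guided(straight_lead, ref)
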