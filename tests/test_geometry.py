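"""Geometry core: direction sampling, acceptance predicates, nucleolus sizing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ctsim import SpeciesConfig, Sphere
from ctsim.geometry import (
    DistanceWindows,
    centromere_candidate_ok,
    domain_candidate_ok,
    foreign_threshold,
    nucleolus_radius_bounds,
    own_threshold,
    random_offset,
    random_offsets,
)


def make_cfg(**overrides):
    kw = dict(
        chr_pair=1,
        l_arm_c=[(1, 1)],
        l_arm_d=[(2, 2)],
        min_rad_nu=5000.0,
        max_rad_nu=5000.0,
        min_vol_no=0.02,
        max_vol_no=0.05,
        rad_bead=250.0,
        eps_1=25.0,
        eps_2=50.0,
    )
    kw.update(overrides)
    return SpeciesConfig(**kw)


class _StubRng:
    """Returns scripted values for successive uniform() calls."""

    def __init__(self, values):
        self._values = list(values)

    def uniform(self, lo, hi, size=None):
        return self._values.pop(0)


class TestRandomOffset:
    @settings(deadline=None, max_examples=100)
    @given(
        origin=st.tuples(*[st.floats(-1e4, 1e4) for _ in range(3)]),
        step=st.floats(1.0, 5e3),
        seed=st.integers(0, 2**16),
    )
    def test_step_length_is_exact(self, origin, step, seed):
        rng = np.random.default_rng(seed)
        p = random_offset(np.array(origin), step, rng)
        assert np.linalg.norm(p - origin) == pytest.approx(step, rel=1e-12)

    def test_forced_zero_azimuth_points_along_z(self):
        # with phi forced to 0 the offset reduces to (0, 0, step)
        rng = _StubRng([math.pi / 3, 0.0])  # theta arbitrary, phi = 0
        p = random_offset(np.zeros(3), 500.0, rng)
        assert p == pytest.approx([0.0, 0.0, 500.0], abs=1e-12)

    def test_rejects_nonpositive_step(self):
        with pytest.raises(ValueError):
            random_offset(np.zeros(3), 0.0, np.random.default_rng(0))

    def test_azimuthal_symmetry_about_z(self):
        # the sampling convention is unusual, but the azimuth of the offset
        # around the z-axis must still be uniform
        rng = np.random.default_rng(1234)
        pts = random_offsets(np.zeros((100_000, 3)), 1.0, rng)
        azimuth = np.arctan2(pts[:, 1], pts[:, 0])
        counts, _ = np.histogram(azimuth, bins=36, range=(-np.pi, np.pi))
        _, p = stats.chisquare(counts)
        assert p > 1e-3

    def test_vectorised_matches_scalar_contract(self):
        rng = np.random.default_rng(7)
        origins = rng.uniform(-1000, 1000, size=(50, 3))
        out = random_offsets(origins, 500.0, rng)
        assert np.allclose(np.linalg.norm(out - origins, axis=1), 500.0)


class TestCentromerePredicate:
    def setup_method(self):
        self.cfg = make_cfg()
        self.nucleus = Sphere(np.zeros(3), 5000.0)
        # far-corner nucleolus that never interferes unless stated
        self.nucleolus = Sphere(np.array([2000.0, 2000.0, 0.0]), 300.0)

    def test_accept_just_inside_margin(self):
        p = np.array([4499.0, 0.0, 0.0])  # 4499 < 5000 - (250 + 5*50) = 4500
        assert centromere_candidate_ok(p, self.nucleus, self.nucleolus, [], self.cfg).ok

    def test_reject_on_boundary_is_strict(self):
        p = np.array([4500.0, 0.0, 0.0])
        verdict = centromere_candidate_ok(p, self.nucleus, self.nucleolus, [], self.cfg)
        assert (verdict.ok, verdict.code) == (False, "C1")

    def test_centromere_crowding_rejected_as_C3(self):
        first = np.array([0.0, 0.0, 0.0])
        second = np.array([550.0, 0.0, 0.0])  # 550 is not > 2*250 + 50
        ok1 = centromere_candidate_ok(first, self.nucleus, self.nucleolus, [], self.cfg)
        verdict = centromere_candidate_ok(second, self.nucleus, self.nucleolus, [first], self.cfg)
        assert ok1.ok
        assert (verdict.ok, verdict.code) == (False, "C3")
        # slightly farther apart is fine
        third = np.array([550.001, 0.0, 0.0])
        assert centromere_candidate_ok(third, self.nucleus, self.nucleolus, [first], self.cfg).ok

    def test_nucleolus_clearance_rejected_as_C2(self):
        p = self.nucleolus.centre + np.array([300.0 + 250.0 + 50.0, 0.0, 0.0])
        verdict = centromere_candidate_ok(p, self.nucleus, self.nucleolus, [], self.cfg)
        assert (verdict.ok, verdict.code) == (False, "C2")  # boundary: strict >


class TestDomainPredicate:
    def setup_method(self):
        self.cfg = make_cfg()
        self.nucleus = Sphere(np.zeros(3), 5000.0)
        self.nucleolus = Sphere(np.array([2000.0, 2000.0, 0.0]), 300.0)

    def check(self, p, own=(), foreign=(), precursor=None):
        return domain_candidate_ok(
            np.asarray(p, float),
            self.nucleus,
            self.nucleolus,
            np.array(own, float).reshape(-1, 3),
            np.array(foreign, float).reshape(-1, 3),
            self.cfg,
            precursor_index=precursor,
        )

    def test_own_bead_threshold_2rb_minus_2eps1(self):
        # threshold 2*250 - 2*25 = 450 nm
        own = [[0.0, 0.0, 0.0]]
        assert self.check([479.0, 0, 0], own=own).ok
        verdict = self.check([449.0, 0, 0], own=own)
        assert (verdict.ok, verdict.code) == (False, "C3'")

    def test_precursory_bead_exempt_from_own_collision(self):
        own = [[0.0, 0.0, 0.0]]
        assert self.check([100.0, 0, 0], own=own, precursor=0).ok

    def test_foreign_bead_threshold_2rb_plus_eps2(self):
        verdict = self.check([549.0, 0, 0], foreign=[[0.0, 0.0, 0.0]])
        assert (verdict.ok, verdict.code) == (False, "C5")
        assert self.check([550.0, 0, 0], foreign=[[0.0, 0.0, 0.0]]).ok

    def test_paper_literal_foreign_threshold(self):
        cfg = make_cfg(paper_literal=True)
        # literal threshold 2*250 - 2*50 = 400
        v = domain_candidate_ok(
            np.array([449.0, 0, 0]), self.nucleus, self.nucleolus,
            np.empty((0, 3)), np.zeros((1, 3)), cfg,
        )
        assert v.ok
        assert foreign_threshold(cfg) == 400.0

    def test_nucleus_containment_C1prime(self):
        verdict = self.check([4750.0, 0, 0])
        assert (verdict.ok, verdict.code) == (False, "C1'")
        assert self.check([4749.0, 0, 0]).ok

    def test_nucleolus_surface_boundary_is_strict(self):
        p = self.nucleolus.centre + np.array([300.0 + 250.0 + 50.0, 0.0, 0.0])
        verdict = self.check(p)
        assert (verdict.ok, verdict.code) == (False, "C2'")

    def test_too_far_from_own_chromosome_C4(self):
        own = [[-4000.0, 0.0, 0.0]]
        # candidate inside the nucleus but farther than R - 2*r_b - eps_1 from
        # every own bead
        verdict = self.check([4000.0, 1500.0, 0.0], own=own)
        assert (verdict.ok, verdict.code) == (False, "C4")


def brute_force_verdict(p, nucleus, nucleolus, own, foreign, cfg, precursor=None):
    """Independent scalar re-derivation of the acceptance rules."""
    dist = lambda a, b: math.dist(tuple(a), tuple(b))
    if dist(p, nucleus.centre) >= nucleus.radius - cfg.rad_bead:
        return (False, "C1'")
    if dist(p, nucleolus.centre) <= nucleolus.radius + cfg.rad_bead + cfg.eps_2:
        return (False, "C2'")
    own_d = [dist(p, q) for q in own]
    for i, d in enumerate(own_d):
        if i != precursor and d < own_threshold(cfg):
            return (False, "C3'")
    if own_d and min(own_d) > nucleus.radius - 2 * cfg.rad_bead - cfg.eps_1:
        return (False, "C4")
    for q in foreign:
        if dist(p, q) < foreign_threshold(cfg):
            return (False, "C5")
    return (True, None)


@settings(deadline=None, max_examples=30)
@given(seed=st.integers(0, 10_000), n_own=st.integers(0, 25), n_foreign=st.integers(0, 25))
def test_domain_predicate_agrees_with_brute_force(seed, n_own, n_foreign):
    """All-pairs scalar oracle reproduces the vectorised verdicts exactly."""
    rng = np.random.default_rng(seed)
    cfg = make_cfg()
    nucleus = Sphere(np.zeros(3), 5000.0)
    nucleolus = Sphere(rng.uniform(-2000, 2000, 3), float(rng.uniform(200, 800)))
    own = rng.uniform(-4800, 4800, (n_own, 3))
    foreign = rng.uniform(-4800, 4800, (n_foreign, 3))
    precursor = int(rng.integers(n_own)) if n_own else None
    for _ in range(20):
        p = rng.uniform(-5200, 5200, 3)
        got = domain_candidate_ok(p, nucleus, nucleolus, own, foreign, cfg, precursor)
        assert (got.ok, got.code) == brute_force_verdict(
            p, nucleus, nucleolus, own, foreign, cfg, precursor
        )


def test_acceptance_invariant_under_rotation():
    rng = np.random.default_rng(42)
    cfg = make_cfg()
    nucleus = Sphere(np.zeros(3), 5000.0)
    nucleolus = Sphere(np.array([1000.0, -500.0, 800.0]), 400.0)
    own = rng.uniform(-3000, 3000, (10, 3))
    foreign = rng.uniform(-3000, 3000, (10, 3))
    rot = stats.special_ortho_group.rvs(3, random_state=7)
    for _ in range(50):
        p = rng.uniform(-5200, 5200, 3)
        before = domain_candidate_ok(p, nucleus, nucleolus, own, foreign, cfg)
        after = domain_candidate_ok(
            rot @ p, nucleus, Sphere(rot @ nucleolus.centre, nucleolus.radius),
            own @ rot.T, foreign @ rot.T, cfg,
        )
        assert before.ok == after.ok


class TestNucleolusRadiusBounds:
    def test_cube_root_examples(self):
        assert nucleolus_radius_bounds(1000.0, 0.064, 0.216) == pytest.approx((400.0, 600.0))
        assert nucleolus_radius_bounds(2000.0, 0.001, 0.001) == pytest.approx((200.0, 200.0))

    def test_degenerate_interval(self):
        r_min, r_max = nucleolus_radius_bounds(1234.5, 0.05, 0.05)
        assert r_min == r_max

    @settings(deadline=None, max_examples=100)
    @given(
        R=st.floats(100.0, 2e4),
        v1=st.floats(1e-4, 0.5),
        v2=st.floats(1e-4, 0.5),
    )
    def test_volume_fraction_recovered(self, R, v1, v2):
        v_min, v_max = sorted((v1, v2))
        r_min, r_max = nucleolus_radius_bounds(R, v_min, v_max)
        assert (r_min / R) ** 3 == pytest.approx(v_min, rel=1e-9)
        assert (r_max / R) ** 3 == pytest.approx(v_max, rel=1e-9)

    def test_domain_violation(self):
        with pytest.raises(ValueError):
            nucleolus_radius_bounds(1000.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            nucleolus_radius_bounds(1000.0, 0.2, 1.5)


def test_distance_windows_from_config():
    cfg = make_cfg()
    w = DistanceWindows.from_config(5000.0, cfg)
    assert w.d1_min == 500.0
    assert w.d1_max == 5000.0 - 500.0 - 25.0
    assert w.d2_min == 550.0
    assert w.d2_max == 5000.0 - 250.0 - 250.0
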