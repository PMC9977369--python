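import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psdgold.geometry import (
    Pose,
    center_of_gravity,
    classify_particles,
    max_feret_diameter,
    normalize_pose,
    points_in_region,
    region_area,
    transform_record,
)
from psdgold.model import Region
from psdgold.reference import (
    brute_force_feret,
    monte_carlo_area,
    ray_casting_inside,
    triangulation_centroid,
)

from conftest import disc_region, make_record, ring_region, square_region


IRREGULAR_7GON = Region(outer=[
    [0, 0], [120, -30], [200, 40], [170, 150], [90, 180], [10, 140], [-40, 60],
])


class TestArea:
    def test_square(self):
        assert region_area(square_region(100.0)) == pytest.approx(0.01)

    def test_square_with_centered_hole(self):
        r = Region(outer=[[-150, -150], [150, -150], [150, 150], [-150, 150]],
                   holes=([[-50, -50], [50, -50], [50, 50], [-50, 50]],))
        assert region_area(r) == pytest.approx(0.08)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(42)
        mc, se = monte_carlo_area(IRREGULAR_7GON, rng, n=1_000_000)
        exact = region_area(IRREGULAR_7GON) * 1e6
        assert abs(exact - mc) / exact < 0.005


class TestCentroid:
    def test_square_symmetry(self):
        assert center_of_gravity(square_region(100.0)) == pytest.approx((0, 0))

    def test_annulus_center(self):
        r = Region(outer=[[-150, -150], [150, -150], [150, 150], [-150, 150]],
                   holes=([[-50, -50], [50, -50], [50, 50], [-50, 50]],))
        assert center_of_gravity(r) == pytest.approx((0, 0))

    def test_l_shaped_hexagon(self):
        r = Region(outer=[[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]])
        cx, cy = center_of_gravity(r)
        assert (cx, cy) == pytest.approx((5 / 6, 5 / 6))
        assert triangulation_centroid(r) == pytest.approx((5 / 6, 5 / 6))

    def test_matches_triangulation_oracle_with_holes(self):
        r = ring_region(100.0, 40.0)
        assert center_of_gravity(r) == pytest.approx(
            triangulation_centroid(r), abs=1e-9)


class TestFeret:
    def test_square_diagonal(self):
        d, pair = max_feret_diameter(square_region(100.0))
        assert d == pytest.approx(100 * np.sqrt(2))

    def test_thin_rectangle(self):
        r = Region(outer=[[0, 0], [500, 0], [500, 10], [0, 10]])
        d, _ = max_feret_diameter(r)
        assert d == pytest.approx(np.hypot(500, 10))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_polygon_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 50))
        radii = rng.uniform(50, 150, 50)
        pts = np.column_stack([radii * np.cos(ang), radii * np.sin(ang)])
        r = Region(outer=pts)
        d, (i, j) = max_feret_diameter(r)
        assert d == pytest.approx(brute_force_feret(pts), rel=1e-12)
        assert d == pytest.approx(np.hypot(*(pts[j] - pts[i])))


class TestNormalizePose:
    def test_already_normalized_gives_identity(self):
        # centered hexagon whose longest vertex pair lies on the x axis
        hexagon = Region(outer=[[150, 0], [50, 60], [-50, 60],
                                [-150, 0], [-50, -60], [50, -60]])
        rec = make_record(hexagon, [(10, 10)])
        normed, pose = normalize_pose(rec)
        assert pose.translation == pytest.approx((0, 0), abs=1e-9)
        assert pose.rotation == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(normed.region.outer, hexagon.outer,
                                   atol=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_invariance_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 30))
        radii = rng.uniform(60, 140, 30)
        pts = np.column_stack([radii * np.cos(ang), radii * np.sin(ang)])
        rec = make_record(Region(outer=pts),
                          [(0, 0), (20, 30), (-40, 10)])
        base, _ = normalize_pose(rec)
        moved = transform_record(
            rec, Pose(translation=(123.4, -56.7), rotation=rng.uniform(0, np.pi)))
        renormed, _ = normalize_pose(moved)
        # the canonical frame has a 180-degree ambiguity (no reflection used)
        direct = np.max(np.abs(renormed.region.outer - base.region.outer))
        flipped = np.max(np.abs(renormed.region.outer + base.region.outer))
        assert min(direct, flipped) < 1e-6

    def test_distances_and_area_preserved(self, square_record):
        normed, _ = normalize_pose(square_record)
        assert region_area(normed.region) == pytest.approx(
            region_area(square_record.region), rel=1e-9)
        c0 = center_of_gravity(square_record.region)
        for p0, p1 in zip(square_record.particles, normed.particles):
            d0 = np.hypot(p0.x - c0[0], p0.y - c0[1])
            d1 = np.hypot(p1.x, p1.y)
            assert d1 == pytest.approx(d0, rel=1e-9)

    def test_feret_pair_horizontal_after_normalization(self, square_record):
        normed, _ = normalize_pose(square_record)
        _, (i, j) = max_feret_diameter(normed.region)
        dy = normed.region.outer[j][1] - normed.region.outer[i][1]
        dx = normed.region.outer[j][0] - normed.region.outer[i][0]
        assert abs(dy) < 1e-6 * abs(dx)


class TestClassify:
    def test_centroid_of_convex_region_is_synaptic(self):
        rec = make_record(square_region(100.0), [(0.0, 0.0)])
        syn, extra = classify_particles(rec)
        assert len(syn) == 1 and not extra

    def test_point_in_hole_is_extrasynaptic(self, ring_record):
        syn, extra = classify_particles(ring_record)
        assert [p.x for p in syn] == [70.0]
        assert [p.x for p in extra] == [0.0]

    def test_boundary_point_counts_inside(self):
        rec = make_record(square_region(100.0), [(50.0, 0.0)])
        syn, _ = classify_particles(rec)
        assert len(syn) == 1

    def test_partition_is_exhaustive(self, square_record):
        syn, extra = classify_particles(square_record)
        assert len(syn) + len(extra) == len(square_record.particles)

    @pytest.mark.parametrize("region_factory", [
        lambda: ring_region(100.0, 40.0),
        lambda: square_region(120.0),
        lambda: disc_region(80.0, n=72),
    ])
    def test_matches_ray_casting_oracle(self, region_factory):
        region = region_factory()
        rng = np.random.default_rng(7)
        pts = rng.uniform(-130, 130, size=(1000, 2))
        assert np.array_equal(points_in_region(region, pts),
                              ray_casting_inside(region, pts))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(angle=st.floats(0, np.pi - 1e-9),
       tx=st.floats(-1000, 1000), ty=st.floats(-1000, 1000))
def test_area_and_centroid_rigid_invariance(angle, tx, ty):
    rec = make_record(square_region(100.0), [(10, 5)])
    moved = transform_record(rec, Pose(translation=(tx, ty), rotation=angle))
    assert region_area(moved.region) == pytest.approx(
        region_area(rec.region), rel=1e-9)
    c = center_of_gravity(moved.region)
    expected = Pose(translation=(tx, ty), rotation=angle).apply(
        np.array([[0.0, 0.0]]))[0]
    assert c == pytest.approx(tuple(expected), abs=1e-6)
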