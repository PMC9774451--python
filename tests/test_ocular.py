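"""Ocular-surface unwrapping, region partition and locality scoring."""

import numpy as np
import pytest

from ocustim import ocular
from ocustim.ocular import (ADJACENT, LOWER_REGIONS, RegionSpec,
                            classify_zone, direction_from_spherical,
                            eye_frame, extract_eye_surface,
                            interpolate_grid, locality_delta,
                            locality_report, partition_regions,
                            to_spherical, SurfaceSamples)
from ocustim.solver import FieldSolution

AZ = 24.0


class TestSphericalMap:
    def test_poles_and_equator(self):
        frame = eye_frame("right", AZ)
        center = np.zeros(3)
        lon, lat = to_spherical([frame.up], center, frame)
        assert np.isclose(lat[0], np.pi / 2)
        lon, lat = to_spherical([frame.temporal], center, frame)
        assert np.isclose(lat[0], 0.0) and np.isclose(lon[0], 0.0)
        lon, lat = to_spherical([frame.axis], center, frame)
        assert np.isclose(lon[0], np.pi / 2) and np.isclose(lat[0], 0.0)

    @pytest.mark.parametrize("eye", ["left", "right"])
    def test_round_trip_recovers_direction(self, eye, rng):
        frame = eye_frame(eye, AZ)
        d = rng.normal(size=(1000, 3))
        d /= np.linalg.norm(d, axis=1)[:, None]
        lon, lat = to_spherical(d, np.zeros(3), frame)
        assert np.all(lon >= -np.pi) and np.all(lon < np.pi)
        assert np.all(np.abs(lat) <= np.pi / 2)
        back = direction_from_spherical(lon, lat, frame)
        # chord length between unit vectors equals the angle to first order
        ang = np.linalg.norm(d - back, axis=1)
        assert ang.max() < 1e-9

    def test_center_point_rejected(self):
        frame = eye_frame("right", AZ)
        with pytest.raises(ValueError):
            to_spherical([[0.0, 0.0, 0.0]], np.zeros(3), frame)

    def test_mirror_eyes_share_band_semantics(self):
        """The temporal-most direction of either eye maps to longitude 0."""
        for eye in ("left", "right"):
            frame = eye_frame(eye, AZ)
            lon, _ = to_spherical([frame.temporal], np.zeros(3), frame)
            assert np.isclose(lon[0], 0.0)


class TestRegions:
    def test_three_equal_disjoint_contiguous_bands(self):
        regions = partition_regions("right")
        assert [r.name for r in regions] == list(LOWER_REGIONS)
        assert np.isclose(regions[0].lon_min, 0.0)
        for r in regions:
            assert np.isclose(r.lon_max - r.lon_min, np.pi / 3)
        for a, b in zip(regions, regions[1:]):
            assert np.isclose(a.lon_max, b.lon_min)
        assert np.isclose(regions[-1].lon_max, np.pi)

    def test_temporal_band_matches_stated_interval(self):
        temporal = partition_regions("right")[0]
        assert temporal.contains(0.5, -0.1)
        assert temporal.contains(0.0, 0.0)
        assert not temporal.contains(1.1, -0.1)

    def test_point_above_band_is_upper_not_lower(self):
        assert classify_zone(0.5, 0.3) == "upper_temporal"
        for region in partition_regions("right"):
            assert not region.contains(0.5, 0.3)

    def test_zone_partition_is_exhaustive_and_exclusive(self):
        lons = np.linspace(-np.pi, np.pi, 73, endpoint=False)
        lats = np.linspace(-np.pi / 2, np.pi / 2, 37)
        for lon in lons:
            for lat in lats:
                zone = classify_zone(lon, lat)
                lower_hits = [r.name for r in partition_regions("right")
                              if r.contains(lon, lat)]
                if zone in LOWER_REGIONS:
                    assert lower_hits == [zone]
                else:
                    assert lower_hits == []

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            RegionSpec(eye="right", name="temporal", lon_min=1.0,
                       lon_max=1.0)


def synthetic_samples(values_fn, n=2000, eye="right", seed=0):
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1)[:, None]
    frame = eye_frame(eye, AZ)
    lon, lat = to_spherical(d, np.zeros(3), frame)
    return SurfaceSamples(eye=eye, lon=lon, lat=lat,
                          value=values_fn(lon, lat))


class TestInterpolation:
    def test_constant_samples_give_constant_grid(self):
        samples = synthetic_samples(lambda lon, lat: np.full(len(lon), 2.5))
        grid = interpolate_grid(samples, resolution_deg=2.0)
        finite = grid.values[np.isfinite(grid.values)]
        assert finite.size > 0
        assert np.allclose(finite, 2.5)

    def test_interpolating_property_at_sample_points(self):
        samples = synthetic_samples(
            lambda lon, lat: np.cos(lon) + np.sin(2 * lat), n=500)
        grid = interpolate_grid(samples)
        recovered = grid(samples.lon, samples.lat)
        assert np.allclose(recovered, samples.value, rtol=0, atol=1e-9)

    def test_too_few_samples_rejected(self):
        s = SurfaceSamples(eye="right", lon=np.array([0.0, 1.0]),
                           lat=np.array([0.0, 0.1]),
                           value=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            interpolate_grid(s)


def brute_force_zone_max(grid, predicate):
    best = -np.inf
    for iy, lat in enumerate(grid.lat):
        for ix, lon in enumerate(grid.lon):
            v = grid.values[iy, ix]
            if np.isfinite(v) and predicate(lon, lat) and v > best:
                best = v
    return best


@pytest.fixture(scope="module")
def bump_grid():
    def bump(lon, lat):
        return np.exp(-((lon - 0.5) ** 2 + (lat + 0.3) ** 2) / 0.05)
    return interpolate_grid(synthetic_samples(bump, n=4000),
                            resolution_deg=2.0)


class TestLocalityReport:

    def test_bump_peak_located_and_deltas_match_grid_scan(self, bump_grid):
        temporal = partition_regions("right")[0]
        rep = locality_report(bump_grid, temporal)
        assert abs(rep.max_in.lon - 0.5) < 0.15
        assert abs(rep.max_in.lat + 0.3) < 0.15
        adj = brute_force_zone_max(
            bump_grid,
            lambda lon, lat: any(
                r.contains(lon, lat)
                for r in partition_regions("right")
                if r.name in ADJACENT["temporal"]))
        assert np.isclose(rep.delta_adjacent, rep.max_in.value - adj)
        up = brute_force_zone_max(
            bump_grid, lambda lon, lat: temporal.upper_contains(lon, lat))
        assert np.isclose(rep.delta_upper, rep.max_in.value - up)

    def test_uniform_field_has_zero_deltas(self):
        grid = interpolate_grid(
            synthetic_samples(lambda lon, lat: np.ones(len(lon))))
        for region in partition_regions("right"):
            rep = locality_report(grid, region)
            assert np.isclose(rep.delta_upper, 0.0)
            assert np.isclose(rep.delta_adjacent, 0.0)

    def test_rotation_invariance(self, rng):
        """Rotating the sample directions and the eye frame together leaves
        every report quantity unchanged."""
        frame = eye_frame("right", AZ)
        d = rng.normal(size=(3000, 3))
        d /= np.linalg.norm(d, axis=1)[:, None]

        def field(dirs):
            # fixed pattern defined in the frame's own coordinates
            lon, lat = to_spherical(dirs, np.zeros(3), frame)
            return np.exp(-((lon - 0.8) ** 2 + (lat + 0.2) ** 2) / 0.1)

        vals = field(d)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
        frame_rot = ocular.EyeFrame(axis=rot @ frame.axis,
                                    temporal=rot @ frame.temporal,
                                    up=rot @ frame.up)
        lon1, lat1 = to_spherical(d, np.zeros(3), frame)
        lon2, lat2 = to_spherical(d @ rot.T, np.zeros(3), frame_rot)
        s1 = SurfaceSamples("right", lon1, lat1, vals)
        s2 = SurfaceSamples("right", lon2, lat2, vals)
        region = partition_regions("right")[1]
        r1 = locality_report(interpolate_grid(s1, 2.0), region)
        r2 = locality_report(interpolate_grid(s2, 2.0), region)
        assert np.isclose(r1.max_in.value, r2.max_in.value, atol=1e-9)
        assert np.isclose(r1.delta_upper, r2.delta_upper, atol=1e-9)
        assert np.isclose(r1.delta_adjacent, r2.delta_adjacent, atol=1e-9)
        assert abs(r1.max_in.lon - r2.max_in.lon) < np.radians(2.5)

    def test_shrinking_region_never_increases_max(self, bump_grid):
        full = RegionSpec("right", "temporal", 0.0, np.pi / 3)
        prev = locality_report(bump_grid, full).max_in.value
        for width in (0.8, 0.6, 0.4):
            sub = RegionSpec("right", "temporal", 0.0, width * np.pi / 3)
            cur = locality_report(bump_grid, sub).max_in.value
            assert cur <= prev + 1e-12
            prev = cur

    def test_region_outside_grid_mask_rejected(self):
        # samples confined to the posterior hemisphere leave the anterior
        # regions unsampled
        rng = np.random.default_rng(1)
        lon = rng.uniform(-np.pi, -0.5, 300)
        lat = rng.uniform(-1.2, 1.2, 300)
        s = SurfaceSamples("right", lon, lat, np.ones(300))
        # no periodic padding rescue here: the anterior band is empty
        grid = interpolate_grid(s)
        region = partition_regions("right")[1]
        values = np.where(
            region.contains(*np.meshgrid(grid.lon, grid.lat)),
            grid.values, np.nan)
        if not np.isfinite(values).any():
            with pytest.raises(ValueError):
                locality_report(grid, region)


class TestLocalityDelta:
    def test_reported_montage_examples(self):
        assert locality_delta(2.16, 0.68) == pytest.approx(1.48, abs=1e-12)
        assert locality_delta(1.68, 1.04) == pytest.approx(0.64, abs=1e-12)

    def test_equal_maxima_give_zero(self, rng):
        for a in rng.uniform(0, 10, 20):
            assert locality_delta(a, a) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            locality_delta(-0.1, 1.0)
        with pytest.raises(ValueError):
            locality_delta(1.0, np.nan)


class TestEyeSurfaceExtraction:
    def test_one_sample_per_surface_triangle(self, coarse_phantom):
        n_faces = len(coarse_phantom.eye_surface_faces("right"))
        sol = FieldSolution(
            potential=np.zeros(len(coarse_phantom.nodes)),
            element_field=np.zeros((len(coarse_phantom.tets), 3)),
            element_field_magnitude=np.ones(len(coarse_phantom.tets)),
            drive={}, residual=0.0, n_nodes=len(coarse_phantom.nodes),
            n_elements=len(coarse_phantom.tets))
        samples = extract_eye_surface(coarse_phantom, sol, "right")
        assert len(samples) == n_faces
        assert np.all(samples.value == 1.0)       # uniform imposed field
        assert np.all(samples.value >= 0)

    def test_absent_eye_rejected(self, small_sphere):
        sol = FieldSolution(
            potential=np.zeros(len(small_sphere.nodes)),
            element_field=np.zeros((len(small_sphere.tets), 3)),
            element_field_magnitude=np.zeros(len(small_sphere.tets)),
            drive={}, residual=0.0, n_nodes=len(small_sphere.nodes),
            n_elements=len(small_sphere.tets))
        with pytest.raises(KeyError):
            extract_eye_surface(small_sphere, sol, "right")
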