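"""Ocular-surface locality evaluation.

The per-element field magnitude on an eyeball's surface is unwrapped into a
longitude/latitude map (one point per surface triangle, placed at the
triangle centroid), interpolated onto a regular grid, partitioned into the
temporal / central / nasal lower regions, and scored by the difference
between the in-region field maximum and the maxima in the overlying
("upper") and neighboring ("adjacent") zones.  A large positive delta means
the montage stimulates the intended sub-region without spilling into its
neighbors — the decision quantity for montage suitability.

Conventions
-----------
Latitude is 0 on the eye's horizontal meridian, positive upward, in
[-pi/2, pi/2].  Longitude is measured from the temporal-most horizontal
direction of each eye, increasing across the anterior hemisphere toward the
nose, so for either eye the anterior half is [0, pi] and the three lower
regions are equal 60-degree bands: temporal [0, pi/3], central
[pi/3, 2 pi/3], nasal [2 pi/3, pi] (1.047 is read as pi/3 exactly).  The
left eye's frame is the mirror image of the right eye's, which maps
left-eye regions onto right-eye regions under reflection.  The posterior
hemisphere carries negative longitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .phantom import TissuePhantom
from .solver import FieldSolution

__all__ = [
    "LOWER_REGIONS",
    "ADJACENT",
    "EyeFrame",
    "eye_frame",
    "to_spherical",
    "direction_from_spherical",
    "SurfaceSamples",
    "extract_eye_surface",
    "InterpolatedGrid",
    "interpolate_grid",
    "RegionSpec",
    "partition_regions",
    "classify_zone",
    "PeakInfo",
    "LocalityReport",
    "locality_report",
    "locality_delta",
]

LOWER_REGIONS = ("temporal", "central", "nasal")
#: Lower regions sharing a longitude boundary.
ADJACENT: Mapping[str, tuple] = {
    "temporal": ("central",),
    "central": ("temporal", "nasal"),
    "nasal": ("central",),
}
_BAND = np.pi / 3.0


@dataclass(frozen=True)
class EyeFrame:
    """Orthonormal frame of one eye: anterior axis, temporal horizontal
    direction (longitude origin) and the global up vector."""

    axis: np.ndarray
    temporal: np.ndarray
    up: np.ndarray


def eye_frame(eye: str, eye_azimuth_deg: float) -> EyeFrame:
    a = np.radians(eye_azimuth_deg)
    up = np.array([0.0, 1.0, 0.0])
    if eye == "right":
        axis = np.array([np.sin(a), 0.0, np.cos(a)])
        temporal = np.array([np.cos(a), 0.0, -np.sin(a)])
    elif eye == "left":
        axis = np.array([-np.sin(a), 0.0, np.cos(a)])
        temporal = np.array([-np.cos(a), 0.0, -np.sin(a)])
    else:
        raise ValueError(f"unknown eye {eye!r}")
    return EyeFrame(axis=axis, temporal=temporal, up=up)


def to_spherical(points, eye_center, frame: EyeFrame):
    """Longitude/latitude (radians) of points on a sphere around an eye.

    Longitude 0 at the temporal horizon, +pi/2 at the anterior pole of the
    equator; latitude positive above the horizontal meridian plane.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float)) - eye_center
    r = np.linalg.norm(p, axis=1)
    if np.any(r < 1e-12):
        raise ValueError("point coincides with the eye center")
    u = p / r[:, None]
    lat = np.arcsin(np.clip(u @ frame.up, -1.0, 1.0))
    lon = np.arctan2(u @ frame.axis, u @ frame.temporal)
    # keep the canonical half-open interval [-pi, pi)
    lon = np.where(lon >= np.pi, lon - 2 * np.pi, lon)
    return lon, lat


def direction_from_spherical(lon, lat, frame: EyeFrame) -> np.ndarray:
    """Inverse of :func:`to_spherical` (unit directions from eye center)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    horiz = (np.cos(lon)[..., None] * frame.temporal
             + np.sin(lon)[..., None] * frame.axis)
    return np.cos(lat)[..., None] * horiz + np.sin(lat)[..., None] * frame.up


@dataclass
class SurfaceSamples:
    """Per-triangle (longitude, latitude, |E|) samples of one eye surface."""

    eye: str
    lon: np.ndarray
    lat: np.ndarray
    value: np.ndarray     # V/m, >= 0

    def __len__(self):
        return len(self.lon)


def extract_eye_surface(phantom: TissuePhantom, solution: FieldSolution,
                        eye: str) -> SurfaceSamples:
    """One sample per eyeball surface triangle, at the triangle centroid.

    Each surface triangle inherits the field magnitude of its owning eyeball
    tetrahedron (element-constant P1 field).
    """
    faces = phantom.eye_surface_faces(eye)   # raises KeyError if eye absent
    cent = phantom.nodes[phantom.tri_nodes[faces]].mean(axis=1)
    frame = eye_frame(eye, phantom.provenance["config"]["eye_azimuth_deg"])
    lon, lat = to_spherical(cent, phantom.eye_centers[eye], frame)
    val = solution.element_field_magnitude[phantom.tri_tets[faces]]
    return SurfaceSamples(eye=eye, lon=lon, lat=lat, value=val)


@dataclass
class InterpolatedGrid:
    """Regular longitude/latitude grid of interpolated field magnitudes.

    ``values`` is NaN outside the convex hull of the samples (no
    extrapolation); the underlying interpolator is kept for point queries so
    the interpolating property (grid reproduces samples) can be checked.
    """

    lon: np.ndarray          # (n_lon,)
    lat: np.ndarray          # (n_lat,)
    values: np.ndarray       # (n_lat, n_lon), NaN where masked
    method: str
    interpolator: LinearNDInterpolator = field(repr=False)

    def __call__(self, lon, lat):
        return self.interpolator(np.column_stack(
            [np.atleast_1d(lon), np.atleast_1d(lat)]))


def interpolate_grid(samples: SurfaceSamples,
                     resolution_deg: float = 1.0) -> InterpolatedGrid:
    """Piecewise-linear scattered interpolation onto a regular grid.

    The scatter is triangulated in the (longitude, latitude) plane; samples
    are replicated at +/- 2 pi so the periodic seam interpolates cleanly.
    Raises ``ValueError`` for fewer than three or collinear samples.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to interpolate")
    lon = np.concatenate([samples.lon, samples.lon + 2 * np.pi,
                          samples.lon - 2 * np.pi])
    lat = np.tile(samples.lat, 3)
    val = np.tile(samples.value, 3)
    try:
        interp = LinearNDInterpolator(np.column_stack([lon, lat]), val)
    except QhullError as exc:
        raise ValueError(f"degenerate sample set: {exc}") from exc
    step = np.radians(resolution_deg)
    glon = np.arange(-np.pi, np.pi + step / 2, step)
    glat = np.arange(-np.pi / 2, np.pi / 2 + step / 2, step)
    gx, gy = np.meshgrid(glon, glat)
    vals = interp(np.column_stack([gx.ravel(), gy.ravel()]))
    return InterpolatedGrid(lon=glon, lat=glat,
                            values=vals.reshape(gx.shape),
                            method="linear", interpolator=interp)


@dataclass(frozen=True)
class RegionSpec:
    """A lower ocular region: a 60-degree longitude band with latitude <= 0."""

    eye: str
    name: str
    lon_min: float
    lon_max: float

    def __post_init__(self):
        if not self.lon_max > self.lon_min:
            raise ValueError("longitude interval must have positive width")

    def contains(self, lon, lat):
        return ((lon >= self.lon_min) & (lon < self.lon_max) & (lat <= 0))

    def upper_contains(self, lon, lat):
        return ((lon >= self.lon_min) & (lon < self.lon_max) & (lat > 0))


def partition_regions(eye: str) -> list[RegionSpec]:
    """The three lower anterior regions of one eye.

    Temporal is [0, pi/3] from the temporal edge of the anterior hemisphere,
    central and nasal follow; the bands are pairwise disjoint and contiguous
    and cover the anterior half with latitude <= 0.
    """
    if eye not in ("left", "right"):
        raise ValueError(f"unknown eye {eye!r}")
    return [RegionSpec(eye=eye, name=name, lon_min=i * _BAND,
                       lon_max=(i + 1) * _BAND)
            for i, name in enumerate(LOWER_REGIONS)]


def classify_zone(lon: float, lat: float) -> str:
    """Zone of a single (longitude, latitude) point.

    Returns one of ``temporal``/``central``/``nasal`` (lower anterior
    bands), ``upper_<band>`` for the overlying zones, or ``posterior``.
    Every point belongs to exactly one zone.
    """
    if not (0.0 <= lon < np.pi):
        return "posterior"
    band = LOWER_REGIONS[min(int(lon // _BAND), 2)]
    return band if lat <= 0 else f"upper_{band}"


@dataclass(frozen=True)
class PeakInfo:
    """A field maximum and the grid coordinates where it occurs."""

    value: float
    lon: float
    lat: float

    def to_dict(self):
        return {"value": self.value, "lon": self.lon, "lat": self.lat}


@dataclass
class LocalityReport:
    """Region-wise maxima and their differences for one drive.

    ``delta_upper``/``delta_adjacent`` are the in-region maximum minus the
    upper-zone / worst adjacent-region maximum; negative values mean the
    stimulation peaks outside the intended region.
    """

    eye: str
    region: str
    max_in: PeakInfo
    max_upper: PeakInfo
    max_adjacent: dict            # region name -> PeakInfo
    delta_upper: float
    delta_adjacent: float
    global_outside: PeakInfo

    def to_dict(self):
        return {
            "eye": self.eye, "region": self.region,
            "max_in": self.max_in.to_dict(),
            "max_upper": self.max_upper.to_dict(),
            "max_adjacent": {k: v.to_dict()
                             for k, v in self.max_adjacent.items()},
            "delta_upper": self.delta_upper,
            "delta_adjacent": self.delta_adjacent,
            "global_outside": self.global_outside.to_dict(),
        }


def _masked_peak(grid: InterpolatedGrid, mask: np.ndarray) -> PeakInfo | None:
    vals = np.where(mask, grid.values, np.nan)
    if not np.isfinite(vals).any():
        return None
    vmax = np.nanmax(vals)
    iy, ix = np.nonzero(vals == vmax)
    # tie-break: smallest longitude, then smallest latitude
    order = np.lexsort((grid.lat[iy], grid.lon[ix]))
    iy, ix = iy[order[0]], ix[order[0]]
    return PeakInfo(value=float(vmax), lon=float(grid.lon[ix]),
                    lat=float(grid.lat[iy]))


def locality_report(grid: InterpolatedGrid,
                    region: RegionSpec) -> LocalityReport:
    """Maxima over the target region and its upper/adjacent zones.

    Maxima are taken on the interpolated grid (mirroring how peaks are read
    off the unwrapped surface plots).  Raises ``ValueError`` if the region
    lies entirely outside the interpolation mask.
    """
    gx, gy = np.meshgrid(grid.lon, grid.lat)
    peak_in = _masked_peak(grid, region.contains(gx, gy))
    if peak_in is None:
        raise ValueError(
            f"region {region.name!r} lies outside the interpolated grid")
    peak_up = _masked_peak(grid, region.upper_contains(gx, gy))
    if peak_up is None:
        raise ValueError(f"upper zone of {region.name!r} is unsampled")
    adjacent = {}
    for other in partition_regions(region.eye):
        if other.name in ADJACENT[region.name]:
            pk = _masked_peak(grid, other.contains(gx, gy))
            if pk is None:
                raise ValueError(
                    f"adjacent region {other.name!r} is unsampled")
            adjacent[other.name] = pk
    outside = _masked_peak(grid, ~region.contains(gx, gy))
    return LocalityReport(
        eye=region.eye, region=region.name, max_in=peak_in,
        max_upper=peak_up, max_adjacent=adjacent,
        delta_upper=peak_in.value - peak_up.value,
        delta_adjacent=peak_in.value - max(p.value
                                           for p in adjacent.values()),
        global_outside=outside)


def locality_delta(max_in: float, max_out: float) -> float:
    """Difference between an in-region and an out-of-region field maximum.

    Both arguments are field magnitudes (V/m) and must be finite and
    non-negative; the result may be negative when the out-of-region maximum
    dominates.
    """
    if not (np.isfinite(max_in) and np.isfinite(max_out)):
        raise ValueError("field maxima must be finite")
    if max_in < 0 or max_out < 0:
        raise ValueError("field magnitudes cannot be negative")
    return float(max_in) - float(max_out)


def plot_ocular_map(grid: InterpolatedGrid, report: LocalityReport | None,
                    path: str, title: str = "") -> None:
    """Export the unwrapped surface as a 3D plot with the in-region maximum
    marked by a black circle and the outside maximum by a red star."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 5))
    ax = fig.add_subplot(projection="3d")
    gx, gy = np.meshgrid(grid.lon, grid.lat)
    z = np.where(np.isfinite(grid.values), grid.values, 0.0)
    ax.plot_surface(gx, gy, z, cmap="viridis", linewidth=0)
    if report is not None:
        ax.scatter([report.max_in.lon], [report.max_in.lat],
                   [report.max_in.value], c="k", marker="o", s=60)
        out = report.global_outside
        ax.scatter([out.lon], [out.lat], [out.value],
                   c="r", marker="*", s=120)
    ax.set_xlabel("longitude (rad)")
    ax.set_ylabel("latitude (rad)")
    ax.set_zlabel("|E| (V/m)")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
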