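"""Synthetic head/orbit phantom: labeled tetrahedral mesh plus electrode pads.

The phantom is a spherical head with a resistive skin layer, a bone shell
pierced by an anterior orbital aperture in front of each eye, two spherical
eyeballs embedded in the bone sockets just under the skin, and brain-like
tissue filling the interior.  It stands in for an MR-derived head mesh while
preserving the skin -> (aperture) -> eyeball current-path structure that
periocular montages exploit.

Meshes are mirror-symmetric about the midsagittal plane x = 0 by
construction: points are generated on the x >= 0 half-domain (including an
explicit triangulated plane), tetrahedralized with scipy's Delaunay, and the
x < 0 half is produced by reflecting the half-mesh.  This makes left/right
eye centers exact mirror images and lets anti-phase drives of mirror-image
electrode pairs null the potential on the plane to solver precision.

Coordinate frame (mm): +x right, +y superior, +z anterior; origin at the
head center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "TISSUES",
    "GeometryError",
    "PlacementError",
    "PhantomConfig",
    "TissuePhantom",
    "ElectrodePatch",
    "SITE_TABLE",
    "resolve_site",
    "mirror_site",
    "build_head_phantom",
    "build_sphere_phantom",
    "place_electrode",
    "patch_overlap",
]

#: Recognized tissue labels.  csf / white matter are optional layers and are
#: absent from the default phantom (the interior is gray-matter-like).
TISSUES = ("skin", "bone", "eyeball", "csf", "gray_matter", "white_matter")

_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))


class GeometryError(ValueError):
    """Infeasible phantom geometry or degenerate mesh."""


class PlacementError(ValueError):
    """Electrode footprint cannot be realized on the skin surface."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic head/orbit phantom.

    All lengths in mm.  ``fine_size`` controls the target element size within
    ``fine_radius`` of either eye center; ``coarse_size`` elsewhere.  The eye
    radius defaults to 12 mm (adult eye ~24 mm diameter); each eye sits on a
    horizontal axis rotated ``eye_azimuth_deg`` from the anterior (+z)
    direction and bulges ``eye_protrusion`` mm into the skin layer, leaving
    a thin lid-like resistive cover over the anterior cap (see
    ``eye_center``).
    """

    head_radius: float = 80.0
    skin_thickness: float = 5.0
    bone_thickness: float = 6.0
    eye_radius: float = 12.0
    eye_azimuth_deg: float = 24.0
    eye_protrusion: float = 2.0
    lid_offset: float = 1.4
    aperture_half_angle_deg: float = 20.0
    socket_thickness: float = 4.0
    socket_aperture_deg: float = 60.0
    fine_size: float = 3.0
    coarse_size: float = 8.0
    fine_radius: float = 40.0
    eye_surface_size: float = 1.7
    skin_surface_size: float = 5.0
    periocular_skin_size: float = 1.7
    periocular_angle_deg: float = 32.0
    jitter: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        for name in ("head_radius", "skin_thickness", "bone_thickness",
                     "eye_radius", "fine_size", "coarse_size", "fine_radius",
                     "eye_surface_size", "skin_surface_size"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        inner = self.head_radius - self.skin_thickness - self.bone_thickness
        if inner <= 2 * self.eye_radius:
            raise GeometryError("tissue shells leave no room for the brain")
        if not 0 <= self.eye_protrusion < self.skin_thickness - 1.0:
            raise GeometryError("eye_protrusion must leave at least 1 mm of "
                                "skin over the corneal pole")
        # the eye must stay clear of the midsagittal plane so the mesh can be
        # mirrored without the two eyes overlapping
        cx = (self.head_radius - self.skin_thickness - self.eye_radius) * \
            np.sin(np.radians(self.eye_azimuth_deg))
        if cx <= self.eye_radius + self.fine_size:
            raise GeometryError("eyes overlap the midsagittal plane; "
                                "increase eye_azimuth_deg")

    def eye_axis(self, eye: str) -> np.ndarray:
        """Unit vector from head center through the given eye center."""
        a = np.radians(self.eye_azimuth_deg)
        sign = {"right": 1.0, "left": -1.0}[eye]
        return np.array([sign * np.sin(a), 0.0, np.cos(a)])

    def eye_center(self, eye: str) -> np.ndarray:
        """The eye bulges ``eye_protrusion`` mm into the skin layer, leaving
        a thin lid-like cover of roughly constant thickness over the
        anterior cap."""
        d = (self.head_radius - self.skin_thickness - self.eye_radius
             + self.eye_protrusion)
        return d * self.eye_axis(eye)


@dataclass
class TissuePhantom:
    """Labeled tetrahedral head mesh with tissue-interface surface triangles.

    ``surface_triangles`` lists every face lying on a tissue interface or on
    the outer boundary, once per adjacent tetrahedron, so an eyeball-owned
    record carries the index of the eyeball element whose field value the
    ocular evaluation reads out.
    """

    nodes: np.ndarray                 # (N, 3) mm
    tets: np.ndarray                  # (M, 4) node indices, positive volume
    tet_labels: np.ndarray            # (M,) strings from TISSUES
    tri_nodes: np.ndarray             # (K, 3) node indices
    tri_labels: np.ndarray            # (K,) owning-tissue label
    tri_tets: np.ndarray              # (K,) owning tet index
    eye_centers: Mapping[str, np.ndarray] | None
    eye_radius: float | None
    plane_nodes: np.ndarray           # node indices on the midsagittal plane
    provenance: dict

    # -- derived quantities ------------------------------------------------
    def tet_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        d = x[:, 1:] - x[:, :1]
        return np.linalg.det(d) / 6.0

    def boundary_mask(self) -> np.ndarray:
        """Surface-triangle records lying on the outer mesh boundary."""
        return self.provenance["tri_boundary"]

    def skin_surface_faces(self) -> np.ndarray:
        """Indices into the surface-triangle arrays for the outer skin."""
        return np.nonzero(self.boundary_mask())[0]

    def skin_surface_nodes(self) -> np.ndarray:
        return np.unique(self.tri_nodes[self.skin_surface_faces()])

    def eye_surface_faces(self, eye: str) -> np.ndarray:
        """Eyeball-owned interface triangles belonging to one eye."""
        if self.eye_centers is None or eye not in self.eye_centers:
            raise KeyError(f"phantom has no eye {eye!r}")
        sel = np.nonzero(self.tri_labels == "eyeball")[0]
        cent = self.nodes[self.tri_nodes[sel]].mean(axis=1)
        near = np.linalg.norm(cent - self.eye_centers[eye], axis=1) \
            < 1.5 * self.eye_radius
        return sel[near]


@dataclass
class ElectrodePatch:
    """Square gel-pad electrode projected onto the skin surface.

    The pad is represented by the set of outer-surface nodes inside its
    footprint; during a solve those nodes are held equipotential (the
    infinite-gel-conductivity limit of a thin conductive pad).
    """

    center_spec: object
    center: np.ndarray               # (3,) mm, on the outer surface
    e1: np.ndarray                   # footprint tangent axes
    e2: np.ndarray
    edge_length: float               # mm
    gel_thickness: float             # mm (metadata)
    current_ma: float                # signed; + = anode
    nodes: np.ndarray                # skin-surface node indices
    faces: np.ndarray                # surface-triangle record indices
    area: float                      # summed face area, mm^2
    node_weights: np.ndarray         # area fractions, sum 1 (injection model)


# ---------------------------------------------------------------------------
# point generation helpers

def _fibonacci_sphere(n: int, rotate: np.ndarray | None = None) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = _GOLDEN * np.arange(n)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    if rotate is not None:
        pts = pts @ rotate.T
    return pts


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _shell_points(radius, spacing, local_size, rng, radial_jitter=0.2):
    """Graded Fibonacci points on a sphere, thinned to the local size."""
    n = max(16, int(np.ceil(4.0 * np.pi * radius ** 2 / spacing ** 2)))
    pts = _fibonacci_sphere(n, _random_rotation(rng))
    ls = local_size(pts * radius)
    keep = rng.random(n) < (spacing / ls) ** 2
    pts = pts[keep]
    ls = ls[keep]
    r = radius - rng.random(len(pts)) * radial_jitter * ls
    return pts * r[:, None]


def _volume_points(R, spacing, local_size, jitter, rng):
    ax = np.arange(-R, R + spacing, spacing)
    gx, gy, gz = np.meshgrid(ax[ax >= -spacing], ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) < R]
    ls = local_size(pts)
    keep = rng.random(len(pts)) < (spacing / ls) ** 3
    pts, ls = pts[keep], ls[keep]
    pts = pts + rng.uniform(-jitter, jitter, pts.shape) * ls[:, None]
    return pts, local_size(pts)


def _plane_ring(radius, spacing, rng):
    n = max(12, int(np.ceil(2 * np.pi * radius / spacing)))
    th = 2 * np.pi * (np.arange(n) + rng.random()) / n
    return np.column_stack([np.zeros(n), radius * np.cos(th),
                            radius * np.sin(th)])


def _plane_points(R, spacing, local_size, jitter, rng, ring_radii=()):
    """2D point set on the midsagittal disc, plus its rim circle and
    optional rings tracing the tissue-interface radii (so radial layering
    is as well resolved on the symmetry plane as off it)."""
    ax = np.arange(-R, R + spacing, spacing)
    gy, gz = np.meshgrid(ax, ax, indexing="ij")
    yz = np.column_stack([gy.ravel(), gz.ravel()])
    pts = np.column_stack([np.zeros(len(yz)), yz])
    ls = local_size(pts)
    keep = rng.random(len(pts)) < (spacing / ls) ** 2
    pts, ls = pts[keep], ls[keep]
    pts[:, 1:] += rng.uniform(-jitter, jitter, (len(pts), 2)) * ls[:, None]
    rad = np.linalg.norm(pts[:, 1:], axis=1)
    ok = rad < R - 0.6 * ls
    for r_ring in ring_radii:
        ok &= np.abs(rad - r_ring) > 0.5 * ls
    pts = pts[ok]
    rim_spacing = local_size(np.array([[0.0, 0.0, R]]))[0]
    rings = [_plane_ring(R, rim_spacing, rng)]
    for r_ring in ring_radii:
        rings.append(_plane_ring(r_ring, rim_spacing, rng))
    return np.vstack([pts] + rings)


# ---------------------------------------------------------------------------
# meshing

def _mirror_mesh(plane_pts, half_pts, tets_half):
    """Reflect the x>=0 half-mesh through x=0 and fuse on the shared plane."""
    n_plane = len(plane_pts)
    n_half = len(half_pts)
    nodes = np.vstack([plane_pts, half_pts, half_pts * [-1.0, 1.0, 1.0]])
    idx_map = np.concatenate([np.arange(n_plane),
                              n_plane + n_half + np.arange(n_half)])
    tets_mirror = idx_map[tets_half]
    tets = np.vstack([tets_half, tets_mirror])
    return nodes, tets


def _orient_positive(nodes, tets):
    x = nodes[tets]
    vol = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    return tets, np.abs(vol)


_FACE_LOCAL = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


def _interface_triangles(tets, labels_int):
    """Faces on label boundaries or the outer hull, one record per side."""
    m = len(tets)
    faces = tets[:, _FACE_LOCAL].reshape(-1, 3)
    faces_sorted = np.sort(faces, axis=1)
    owner = np.repeat(np.arange(m), 4)
    order = np.lexsort(faces_sorted.T)
    fs = faces_sorted[order]
    ow = owner[order]
    same = np.all(fs[1:] == fs[:-1], axis=1)
    # boundary faces appear once; interface faces twice with != labels
    first = np.concatenate([[True], ~same])
    start = np.nonzero(first)[0]
    count = np.diff(np.append(start, len(fs)))
    rec_nodes, rec_tets = [], []
    single = start[count == 1]
    rec_nodes.append(fs[single])
    rec_tets.append(ow[single])
    dbl = start[count == 2]
    a, b = ow[dbl], ow[dbl + 1]
    diff = labels_int[a] != labels_int[b]
    rec_nodes.append(fs[dbl][diff])
    rec_tets.append(a[diff])
    rec_nodes.append(fs[dbl][diff])
    rec_tets.append(b[diff])
    tri_nodes = np.vstack(rec_nodes)
    tri_tets = np.concatenate(rec_tets)
    boundary = np.zeros(len(tri_tets), dtype=bool)
    boundary[: len(single)] = True
    return tri_nodes, tri_tets, boundary


def _build_from_points(plane_pts, half_pts, label_fn, provenance,
                       eye_centers=None, eye_radius=None):
    pts_half = np.vstack([plane_pts, half_pts])
    tri = Delaunay(pts_half)
    tets_half = tri.simplices.astype(np.int64)
    # discard exactly degenerate slivers (coplanar quadruples)
    x = pts_half[tets_half]
    vol = np.abs(np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0)
    tets_half = tets_half[vol > 1e-9]
    nodes, tets = _mirror_mesh(plane_pts, half_pts, tets_half)
    tets, vols = _orient_positive(nodes, tets)
    if vols.min() <= 0:
        raise GeometryError("mesh contains a zero-volume tetrahedron")
    cent = nodes[tets].mean(axis=1)
    labels = label_fn(cent)
    codes, labels_int = np.unique(labels, return_inverse=True)
    tri_nodes, tri_tets, boundary = _interface_triangles(tets, labels_int)
    provenance = dict(provenance)
    provenance.update(n_nodes=len(nodes), n_tets=len(tets),
                      tri_boundary=boundary)
    return TissuePhantom(
        nodes=nodes, tets=tets, tet_labels=labels,
        tri_nodes=tri_nodes, tri_labels=labels[tri_tets], tri_tets=tri_tets,
        eye_centers=eye_centers, eye_radius=eye_radius,
        plane_nodes=np.arange(len(plane_pts)), provenance=provenance)


def build_head_phantom(config: PhantomConfig | None = None) -> TissuePhantom:
    """Generate the synthetic head/orbit phantom.

    Deterministic for a fixed ``config.seed``.  Raises
    :class:`GeometryError` for infeasible geometry.
    """
    cfg = config or PhantomConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    R = cfg.head_radius
    c_right = cfg.eye_center("right")
    c_left = cfg.eye_center("left")
    eye_centers = {"right": c_right, "left": c_left}

    def local_size(p):
        d = np.minimum(np.linalg.norm(p - c_right, axis=1),
                       np.linalg.norm(p - c_left, axis=1))
        return np.where(d < cfg.fine_radius, cfg.fine_size, cfg.coarse_size)

    # the mid-skin shell keeps the resistive skin layer two elements thick
    # everywhere, so pad contact impedance does not fluctuate with the
    # random interior sampling
    interface_radii = (R - 0.5 * cfg.skin_thickness,
                       R - cfg.skin_thickness,
                       R - cfg.skin_thickness - cfg.bone_thickness)
    plane_pts = _plane_points(R, cfg.fine_size, local_size, cfg.jitter, rng,
                              ring_radii=interface_radii)

    shells = []
    # the outer skin surface is sampled densely over each orbit so that the
    # pad-to-eye coupling (which the near-eye surface nodes mediate) varies
    # smoothly with pad position rather than with individual node capture
    cos_peri = np.cos(np.radians(cfg.periocular_angle_deg))
    ax_r, ax_l = cfg.eye_axis("right"), cfg.eye_axis("left")

    def outer_size(p):
        u = p / np.maximum(np.linalg.norm(p, axis=1)[:, None], 1e-12)
        peri = (u @ ax_r > cos_peri) | (u @ ax_l > cos_peri)
        base = np.minimum(local_size(p), cfg.skin_surface_size)
        return np.where(peri, cfg.periocular_skin_size, base)

    outer = _shell_points(R, cfg.periocular_skin_size, outer_size, rng,
                          radial_jitter=0.06)
    shells.append(outer)
    for i_if, r_if in enumerate(interface_radii):
        size_fn = outer_size if i_if == 0 else local_size
        base = cfg.periocular_skin_size if i_if == 0 else cfg.fine_size
        pts_if = _shell_points(r_if, base, size_fn, rng)
        # the protruding eyes pierce the concentric interfaces; keep the
        # interface point layers clear of the eye surfaces
        d_if = np.minimum(np.linalg.norm(pts_if - c_right, axis=1),
                          np.linalg.norm(pts_if - c_left, axis=1))
        shells.append(pts_if[d_if > cfg.eye_radius + cfg.lid_offset
                             + 0.5 * cfg.fine_size])
    # right eye surface (the left eye comes from mirroring)
    n_eye = max(32, int(np.ceil(4 * np.pi * cfg.eye_radius ** 2
                                / cfg.eye_surface_size ** 2)))
    eye_pts = _fibonacci_sphere(n_eye, _random_rotation(rng))
    eye_r = cfg.eye_radius - rng.random(n_eye) * 0.1 * cfg.eye_surface_size
    eye_pts = c_right + eye_pts * eye_r[:, None]
    shells.append(eye_pts)
    # lid layer: a conforming point shell just outside the eye guarantees at
    # least one resistive soft-tissue element layer between the skin surface
    # and the conductive eyeball (no spurious element-scale short circuits)
    lid_r = cfg.eye_radius + cfg.lid_offset
    n_lid = max(32, int(np.ceil(4 * np.pi * lid_r ** 2
                                / cfg.eye_surface_size ** 2)))
    lid_pts = _fibonacci_sphere(n_lid, _random_rotation(rng))
    lid_rr = lid_r - rng.random(n_lid) * 0.05 * cfg.eye_surface_size
    lid_pts = c_right + lid_pts * lid_rr[:, None]
    lid_pts = lid_pts[np.linalg.norm(lid_pts, axis=1) < R - 1.0]
    shells.append(lid_pts)

    vol_pts, vol_ls = _volume_points(R, cfg.fine_size, local_size,
                                     cfg.jitter, rng)
    # keep interior points clear of every explicit surface
    r = np.linalg.norm(vol_pts, axis=1)
    ok = r < R - 0.55 * vol_ls
    for r_if in interface_radii:
        ok &= np.abs(r - r_if) > 0.5 * vol_ls
    d_eye = np.minimum(np.linalg.norm(vol_pts - c_right, axis=1),
                       np.linalg.norm(vol_pts - c_left, axis=1))
    ok &= np.abs(d_eye - cfg.eye_radius) > 0.55 * cfg.eye_surface_size
    ok &= np.abs(d_eye - cfg.eye_radius - cfg.lid_offset) \
        > 0.55 * cfg.eye_surface_size
    vol_pts, vol_ls = vol_pts[ok], vol_ls[ok]

    half = np.vstack(shells + [vol_pts])
    half_ls = np.concatenate([
        outer_size(s) if i in (0, 1)
        else local_size(s) if i < 4
        else np.full(len(s), cfg.eye_surface_size) if i in (4, 5)
        else vol_ls
        for i, s in enumerate(shells + [vol_pts])])
    keep = half[:, 0] > 0.45 * half_ls
    half = half[keep]

    cos_ap = np.cos(np.radians(cfg.aperture_half_angle_deg))
    axes = {"right": cfg.eye_axis("right"), "left": cfg.eye_axis("left")}

    cos_sock = np.cos(np.radians(cfg.socket_aperture_deg))

    def label_fn(cent):
        lab = np.full(len(cent), "gray_matter", dtype=object)
        r = np.linalg.norm(cent, axis=1)
        in_bone = (r >= interface_radii[2]) & (r < interface_radii[1])
        lab[in_bone] = "bone"
        u = cent / np.maximum(r[:, None], 1e-12)
        in_ap = np.zeros(len(cent), dtype=bool)
        for ax in axes.values():
            in_ap |= u @ ax > cos_ap
        # orbital aperture: the bone shell in front of the orbit is replaced
        # by periocular soft tissue (eyelids, canthi), which shares the skin
        # conductivity; the conductive eyeball is then electrically isolated
        # and current enters it where a pad's footprint approaches closest
        lab[in_bone & in_ap] = "skin"
        lab[r >= interface_radii[1]] = "skin"
        # bone socket: a cup of thickness socket_thickness around each eye,
        # open over the anterior cap (socket_aperture_deg from the eye axis)
        for eye, c in (("right", c_right), ("left", c_left)):
            rel = cent - c
            d = np.linalg.norm(rel, axis=1)
            shellish = (d >= cfg.eye_radius) & \
                (d < cfg.eye_radius + cfg.socket_thickness)
            anterior = rel @ axes[eye] > cos_sock * np.maximum(d, 1e-12)
            lab[shellish & ~anterior] = "bone"
        for c in (c_right, c_left):
            lab[np.linalg.norm(cent - c, axis=1) < cfg.eye_radius] = "eyeball"
        return lab.astype("U12")

    prov = {"config": asdict(cfg), "seed": cfg.seed, "kind": "head"}
    return _build_from_points(plane_pts, half, label_fn, prov,
                              eye_centers=eye_centers,
                              eye_radius=cfg.eye_radius)


def build_sphere_phantom(radius: float = 50.0, target_size: float = 4.0,
                         seed: int = 0, tissue: str = "gray_matter",
                         refine_points=None, refine_radius: float = 0.0,
                         refine_factor: float = 0.5,
                         jitter: float = 0.25) -> TissuePhantom:
    """Homogeneous conducting sphere used for analytic-oracle validation.

    ``refine_points``/``refine_radius`` optionally grade the element size
    down to ``refine_factor * target_size`` within ``refine_radius`` of the
    given points (used to resolve the steep field around point contacts).
    """
    if radius <= 0 or target_size <= 0:
        raise GeometryError("radius and target_size must be positive")
    rng = np.random.default_rng(seed)
    refine = (np.atleast_2d(np.asarray(refine_points, dtype=float))
              if refine_points is not None else None)
    min_size = target_size * (refine_factor if refine is not None else 1.0)

    def local_size(p):
        ls = np.full(len(p), target_size)
        if refine is not None:
            d = np.min(np.linalg.norm(
                p[:, None, :] - refine[None, :, :], axis=2), axis=1)
            ls[d < refine_radius] = target_size * refine_factor
        return ls

    # near-zero radial jitter keeps the discrete boundary on the ideal
    # sphere (the analytic oracle's geometry) while still breaking the
    # co-sphericity degeneracy for the Delaunay triangulation
    plane_pts = _plane_points(radius, min_size, local_size, jitter, rng)
    outer = _shell_points(radius, min_size, local_size, rng,
                          radial_jitter=0.02)
    vol_pts, vol_ls = _volume_points(radius, min_size, local_size,
                                     jitter, rng)
    r = np.linalg.norm(vol_pts, axis=1)
    vol_pts = vol_pts[r < radius - 0.55 * vol_ls]
    half = np.vstack([outer, vol_pts])
    half = half[half[:, 0] > 0.45 * target_size]

    def label_fn(cent):
        return np.full(len(cent), tissue, dtype="U12")

    prov = {"config": {"radius": radius, "target_size": target_size},
            "seed": seed, "kind": "sphere"}
    return _build_from_points(plane_pts, half, label_fn, prov)


# ---------------------------------------------------------------------------
# electrode placement

#: Named skin sites as (azimuth_deg about +y from anterior +z toward +x,
#: elevation_deg above the horizontal plane).  Lower-orbit active sites sit
#: just below each eye; cheek sites are the return pads.  ``left_*`` sites
#: are exact mirrors of ``right_*``; ``nasal_lower`` lies on the midline.
SITE_TABLE: dict[str, tuple[float, float]] = {
    "right_temporal_lower": (40.0, -14.0),
    "right_central_lower": (26.0, -18.0),
    "right_temporal_lower_adjusted": (38.0, -20.0),
    "right_temporal_lower_crowded": (31.0, -16.0),
    "right_central_lower_crowded": (29.0, -16.0),
    "right_cheek_medial_low": (14.0, -52.0),
    "right_cheek_medial_low2": (10.0, -54.0),
    "right_cheek_lateral_low": (46.0, -52.0),
    "right_cheek_crossed_a": (13.0, -53.0),
    "right_cheek_crossed_b": (15.0, -52.0),
    "nasal_lower": (0.0, -22.0),
}
for _name, (_az, _el) in list(SITE_TABLE.items()):
    if _name.startswith("right_"):
        SITE_TABLE["left_" + _name[6:]] = (-_az, _el)


def mirror_site(name: str) -> str:
    """Mirror a named site about the midsagittal plane."""
    if name.startswith("right_"):
        return "left_" + name[6:]
    if name.startswith("left_"):
        return "right_" + name[5:]
    return name


def resolve_site(center_spec) -> np.ndarray:
    """Resolve a site name / (azimuth, elevation) pair / direction vector
    to a unit direction from the head center."""
    if isinstance(center_spec, str):
        try:
            az, el = SITE_TABLE[center_spec]
        except KeyError as exc:
            raise PlacementError(f"unknown skin site {center_spec!r}") from exc
    elif isinstance(center_spec, (tuple, list)) and len(center_spec) == 2:
        az, el = center_spec
    else:
        v = np.asarray(center_spec, dtype=float)
        if v.shape != (3,) or not np.linalg.norm(v) > 0:
            raise PlacementError(f"cannot interpret site {center_spec!r}")
        return v / np.linalg.norm(v)
    az, el = np.radians(az), np.radians(el)
    return np.array([np.sin(az) * np.cos(el), np.sin(el),
                     np.cos(az) * np.cos(el)])


def place_electrode(phantom: TissuePhantom, center_spec,
                    edge_length: float = 42.0, current_ma: float = 1.0,
                    gel_thickness: float = 2.0) -> ElectrodePatch:
    """Project a square pad footprint onto the outer skin surface.

    The footprint is the set of boundary faces whose centroid falls inside
    the ``edge_length`` square on the local tangent plane at the site; the
    patch node set is the union of their vertices.  Raises
    :class:`PlacementError` if the footprint is degenerate or captures no
    mesh nodes.
    """
    if edge_length <= 0:
        raise PlacementError("edge_length must be positive")
    d = resolve_site(center_spec)
    faces = phantom.skin_surface_faces()
    tri = phantom.tri_nodes[faces]
    cent = phantom.nodes[tri].mean(axis=1)
    # surface point nearest the ray from the head center
    radius = np.linalg.norm(phantom.nodes[np.unique(tri)], axis=1).max()
    center = d * radius
    up = np.array([0.0, 1.0, 0.0])
    e2 = up - (up @ d) * d
    n2 = np.linalg.norm(e2)
    if n2 < 1e-9:
        raise PlacementError("site at a pole; footprint frame undefined")
    e2 /= n2
    e1 = np.cross(e2, d)
    def in_square(pts):
        rel = pts - center
        return ((pts @ d > 0.3 * radius)
                & (np.abs(rel @ e1) <= edge_length / 2)
                & (np.abs(rel @ e2) <= edge_length / 2))

    inside = in_square(cent)
    if not inside.any():
        raise PlacementError(
            f"footprint at {center_spec!r} captured no skin faces "
            "(resolution too coarse or site off the surface)")
    sel = faces[inside]
    tri_in = phantom.tri_nodes[sel]
    v1 = phantom.nodes[tri_in[:, 1]] - phantom.nodes[tri_in[:, 0]]
    v2 = phantom.nodes[tri_in[:, 2]] - phantom.nodes[tri_in[:, 0]]
    areas = 0.5 * np.linalg.norm(np.cross(v1, v2), axis=1)
    # node membership is strictly geometric so that two non-touching
    # footprints can never share a node through a protruding face vertex
    cand = np.unique(tri_in)
    nodes = cand[in_square(phantom.nodes[cand])]
    if nodes.size == 0:
        raise PlacementError(
            f"footprint at {center_spec!r} captured no skin nodes")
    w = np.zeros(len(phantom.nodes))
    for k in range(3):
        np.add.at(w, tri_in[:, k], areas / 3.0)
    weights = w[nodes]
    weights /= weights.sum()
    return ElectrodePatch(center_spec=center_spec, center=center,
                          e1=e1, e2=e2, edge_length=float(edge_length),
                          gel_thickness=float(gel_thickness),
                          current_ma=float(current_ma), nodes=nodes,
                          faces=sel, area=float(areas.sum()),
                          node_weights=weights)


def patch_overlap(a: ElectrodePatch, b: ElectrodePatch) -> np.ndarray:
    """Node indices shared by two patches (empty when disjoint)."""
    return np.intersect1d(a.nodes, b.nodes)
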