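"""Software stand-in for the physical turntable-LiDAR platform.

Ray-casts range profiles of parametric scenes (calibration cube, planar
calibration target, maize seedling) under the scanner model of the real
device: a 2D profile scanner with a 70 degree aperture at 0.0833 degree
angular resolution, a 70-300 cm working range, distance-dependent Gaussian
range noise, and 100-repeat profile averaging.  The turntable steps the
specimen in 0.1 degree increments by default.

Conventions shared with :mod:`phenoscan.geometry`:

* lengths in cm, angles in degrees, disc surface at ``z = 0``;
* at turntable angle ``phi`` the scene is rotated by ``-phi`` about the
  vertical axis (equivalently, the specimen turns with the disc), so the
  reconstruction chain's final ``+phi`` rotation maps returns back into the
  specimen frame;
* the physical sensor tilt raises every beam's elevation by the tilt angle
  (the scan plane pivots about the horizontal axis perpendicular to the
  viewing direction), which is what the calibration-target procedure
  estimates.

Noise model: each returned range is the mean of ``repeat_count`` independent
draws ``N(true, sigma(d))`` where ``sigma`` is a cubic in the distance in
meters yielding cm (the platform's measured precision curve), inflated by
``1/cos(incidence)`` capped at 3x to reflect the qualitative degradation at
grazing incidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import trimesh

from .geometry import PlatformCalibration, PointCloud, Profile

__all__ = [
    "ScannerConfig",
    "TurntableConfig",
    "Scene",
    "LeafParams",
    "SeedlingParams",
    "noise_sigma",
    "build_cube",
    "build_target",
    "build_seedling",
    "random_seedling_params",
    "cast_profile",
    "simulate_scan",
    "point_mesh_distance",
]

#: coefficients of the platform precision cubic (d in meters -> sigma in cm)
DEFAULT_NOISE_COEFFS = (0.0639, 0.1139, 0.0473, 0.0589)


def noise_sigma(distance_m: float | np.ndarray, coeffs=DEFAULT_NOISE_COEFFS):
    """Single-shot range noise sigma in cm for a distance in meters.

    Evaluates the platform precision cubic ``a3 d^3 + a2 d^2 + a1 d + a0``.
    """
    d = np.asarray(distance_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    a3, a2, a1, a0 = coeffs
    out = ((a3 * d + a2) * d + a1) * d + a0
    return float(out) if np.isscalar(distance_m) else out


@dataclass
class ScannerConfig:
    """Scanner model parameters (defaults match the hardware data sheet)."""

    aperture_deg: float = 70.0
    angular_resolution_deg: float = 0.0833
    range_min_cm: float = 70.0
    range_max_cm: float = 300.0
    repeat_count: int = 100
    noise_coeffs: tuple = DEFAULT_NOISE_COEFFS
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.aperture_deg <= 0 or self.angular_resolution_deg <= 0:
            raise ValueError("aperture and resolution must be positive")
        if not self.range_min_cm < self.range_max_cm:
            raise ValueError("range_min must be below range_max")
        if self.repeat_count < 1:
            raise ValueError("repeat_count must be >= 1")

    def beam_angles(self) -> np.ndarray:
        """Symmetric sweep about the horizontal, strictly increasing."""
        half = self.aperture_deg / 2.0
        n = int(math.floor(half / self.angular_resolution_deg))
        return np.arange(-n, n + 1) * self.angular_resolution_deg


@dataclass
class TurntableConfig:
    """Turntable stepping: one profile per ``step_deg`` in [start, end)."""

    step_deg: float = 0.1
    start_deg: float = 0.0
    end_deg: float = 360.0

    def __post_init__(self) -> None:
        if not 0 < self.step_deg <= 360:
            raise ValueError("step must lie in (0, 360]")
        if not self.start_deg < self.end_deg <= self.start_deg + 360:
            raise ValueError("need start < end <= start + 360")

    def angles(self) -> np.ndarray:
        n = int(round((self.end_deg - self.start_deg) / self.step_deg))
        # guard against float drift past the open upper bound
        a = self.start_deg + np.arange(n) * self.step_deg
        return a[a < self.end_deg - 1e-9 + self.step_deg * 1e-6]


class Scene:
    """Labeled triangle-mesh scene placed on the turntable disc.

    ``parts`` is a sequence of ``(label, trimesh.Trimesh)``; every triangle
    carries its part's label.  ``reflectance`` maps labels to a [0, 1]
    albedo used by the synthetic intensity model (default 1.0).
    """

    def __init__(self, parts, reflectance: dict | None = None):
        self.parts = list(parts)
        self.reflectance = dict(reflectance or {})
        tris, labels = [], []
        for label, mesh in self.parts:
            t = mesh.triangles.view(np.ndarray)
            tris.append(t)
            labels.extend([label] * len(t))
        if tris:
            self._tris = np.concatenate(tris, axis=0)
        else:
            self._tris = np.zeros((0, 3, 3))
        self._labels = np.asarray(labels)
        e1 = self._tris[:, 1] - self._tris[:, 0]
        e2 = self._tris[:, 2] - self._tris[:, 0]
        n = np.cross(e1, e2)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        self._normals = n / norm
        verts = self._tris.reshape(-1, 3)
        if len(verts):
            lo, hi = verts.min(axis=0), verts.max(axis=0)
            self._center = (lo + hi) / 2.0
            self._radius = float(np.linalg.norm(verts - self._center, axis=1).max())
        else:
            self._center = np.zeros(3)
            self._radius = 0.0

    @property
    def triangles(self) -> np.ndarray:
        return self._tris

    @property
    def triangle_labels(self) -> np.ndarray:
        return self._labels

    @property
    def labels(self) -> list:
        return [label for label, _ in self.parts]

    def part_area(self, label: str) -> float:
        """One-sided surface area (cm^2) of all triangles with this label."""
        return float(sum(m.area for lb, m in self.parts if lb == label))

    def max_z(self) -> float:
        return float(self._tris[:, :, 2].max()) if len(self._tris) else 0.0


# ---------------------------------------------------------------------------
# Scene builders
# ---------------------------------------------------------------------------


def build_cube(edge_cm: float) -> Scene:
    """Axis-aligned calibration cube resting on the disc, centered on its axis."""
    if edge_cm <= 0:
        raise ValueError("edge must be positive")
    box = trimesh.creation.box(extents=(edge_cm, edge_cm, edge_cm))
    box.apply_translation([0.0, 0.0, edge_cm / 2.0])
    return Scene([("cube", box)])


def build_target(
    height_cm: float = 40.0,
    width_cm: float = 4.5,
    disc_radius_cm: float = 20.0,
    include_disc: bool = True,
) -> Scene:
    """Planar calibration target standing vertically through the disc center.

    The target is a 40 x 4.5 cm low-reflectance rectangle in the plane
    ``x = 0``.  The turntable disc surface (a circle at ``z = 0``) is part of
    the scene: during calibration it is in the scanner's view and its returns
    anchor the ``z = 0`` reference.
    """
    v = np.array(
        [
            [0.0, -width_cm / 2, 0.0],
            [0.0, width_cm / 2, 0.0],
            [0.0, width_cm / 2, height_cm],
            [0.0, -width_cm / 2, height_cm],
        ]
    )
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    target = trimesh.Trimesh(vertices=v, faces=faces, process=False)
    parts = [("target", target)]
    if include_disc:
        n = 48
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        rim = np.column_stack(
            [disc_radius_cm * np.cos(ang), disc_radius_cm * np.sin(ang), np.zeros(n)]
        )
        verts = np.vstack([[0.0, 0.0, 0.0], rim])
        faces = np.array([[0, 1 + i, 1 + (i + 1) % n] for i in range(n)])
        parts.append(("disc", trimesh.Trimesh(vertices=verts, faces=faces, process=False)))
    return Scene(parts, reflectance={"target": 0.3})


@dataclass
class LeafParams:
    """One maize leaf: a drooping ribbon leaving the stem."""

    attachment_frac: float  # fraction of stem height where the leaf emerges
    azimuth_deg: float  # horizontal direction of the leaf midrib
    length_cm: float  # arc length of the midrib
    max_width_cm: float  # blade width at its widest point
    droop: float = 0.08  # parabola curvature of the midrib, 1/cm
    elevation_deg: float = 55.0  # initial midrib elevation above horizontal


@dataclass
class SeedlingParams:
    """Parametric maize seedling (heights in the 10-40 cm range of the study)."""

    stem_height_cm: float = 20.0
    stem_radius_cm: float = 0.3
    n_leaves: int = 4
    leaves: list | None = None  # explicit LeafParams; generated from seed if None
    include_pot: bool = False
    pot_radius_cm: float = 6.0
    pot_height_cm: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 10.0 <= self.stem_height_cm <= 40.0:
            raise ValueError("stem height must lie in the 10-40 cm study range")
        if self.stem_radius_cm <= 0:
            raise ValueError("stem radius must be positive")
        if self.n_leaves < 0:
            raise ValueError("n_leaves must be >= 0")


def _default_leaves(params: SeedlingParams) -> list:
    """Deterministic alternate-ranked (distichous) leaf set for a seed."""
    rng = np.random.default_rng(params.rng_seed)
    leaves = []
    n = params.n_leaves
    for i in range(n):
        frac = 0.30 + 0.60 * (i + 1) / max(n, 1)
        # maize leaves alternate sides with some scatter
        azimuth = (180.0 * i + rng.uniform(-25, 25)) % 360.0
        rank = (i + 1) / max(n, 1)
        length = params.stem_height_cm * (0.55 + 0.45 * rank)
        width = float(rng.uniform(1.0, 2.2))
        droop = float(rng.uniform(0.05, 0.11))
        elev = float(rng.uniform(45.0, 62.0))
        leaves.append(LeafParams(min(frac, 0.95), azimuth, length, width, droop, elev))
    return leaves


def _tapered_stem(radius: float, z0: float, z1: float, sections: int = 24):
    """Tapered vertical cylinder (maize culm), open base, capped tip."""
    ang = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    ring = np.column_stack([np.cos(ang), np.sin(ang)])
    r_top = 0.6 * radius
    bottom = np.column_stack([radius * ring, np.full(sections, z0)])
    top = np.column_stack([r_top * ring, np.full(sections, z1)])
    verts = np.vstack([bottom, top, [[0.0, 0.0, z1]]])
    faces = []
    for i in range(sections):
        j = (i + 1) % sections
        faces.append([i, j, sections + i])
        faces.append([j, sections + j, sections + i])
        faces.append([sections + i, sections + j, 2 * sections])  # tip cap
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def _leaf_ribbon(leaf: LeafParams, stem_height: float, base_z: float, n_seg: int = 14):
    """Ribbon surface along a parabolic midrib, widest mid-blade."""
    z0 = base_z + leaf.attachment_frac * stem_height
    slope = math.tan(math.radians(leaf.elevation_deg))
    # midrib in the vertical plane: z(r) = z0 + slope*r - droop*r^2
    r_dense = np.linspace(0.0, 60.0, 2400)
    z_dense = z0 + slope * r_dense - leaf.droop * r_dense**2
    seg = np.hypot(np.diff(r_dense), np.diff(z_dense))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    r_end = np.interp(leaf.length_cm, arc, r_dense)
    u = np.linspace(0.0, 1.0, n_seg + 1)
    r = np.interp(u * min(leaf.length_cm, arc[-1]), arc, r_dense)
    z = z0 + slope * r - leaf.droop * r**2
    psi = math.radians(leaf.azimuth_deg)
    along = np.array([math.cos(psi), math.sin(psi), 0.0])
    across = np.array([-math.sin(psi), math.cos(psi), 0.0])
    center = r[:, None] * along + np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    # lanceolate width profile, kept slightly open at the ends
    w = leaf.max_width_cm * np.clip(np.sin(np.pi * np.clip(u, 0.03, 0.97)) ** 0.8, 0.05, None)
    left = center - (w / 2)[:, None] * across
    right = center + (w / 2)[:, None] * across
    verts = np.vstack([left, right])
    m = n_seg + 1
    faces = []
    for i in range(n_seg):
        faces.append([i, m + i, i + 1])
        faces.append([i + 1, m + i, m + i + 1])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def build_seedling(params: SeedlingParams) -> Scene:
    """Parametric maize seedling: tapered stem, drooping leaf ribbons, optional pot."""
    base_z = params.pot_height_cm if params.include_pot else 0.0
    parts = []
    if params.include_pot:
        pot = trimesh.creation.cylinder(
            radius=params.pot_radius_cm, height=params.pot_height_cm, sections=32
        )
        pot.apply_translation([0.0, 0.0, params.pot_height_cm / 2.0])
        parts.append(("pot", pot))
    stem = _tapered_stem(params.stem_radius_cm, base_z, base_z + params.stem_height_cm)
    parts.append(("stem", stem))
    leaves = params.leaves if params.leaves is not None else _default_leaves(params)
    if params.n_leaves and len(leaves) != params.n_leaves:
        raise ValueError("leaves list must match n_leaves")
    for leaf in leaves:
        parts.append(("leaf", _leaf_ribbon(leaf, params.stem_height_cm, base_z)))
    return Scene(parts, reflectance={"pot": 0.6})


def random_seedling_params(rng: np.random.Generator, include_pot: bool = False) -> SeedlingParams:
    """Draw a seedling from the study population (10-40 cm, 2-6 leaves)."""
    height = float(rng.uniform(10.0, 40.0))
    n_leaves = int(np.clip(round(height / 7.0) + rng.integers(-1, 2), 2, 6))
    return SeedlingParams(
        stem_height_cm=height,
        stem_radius_cm=float(rng.uniform(0.22, 0.42)),
        n_leaves=n_leaves,
        include_pot=include_pot,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Ray casting
# ---------------------------------------------------------------------------


def _ray_mesh_first_hit(origins, dirs, tris, eps=1e-12):
    """Nearest two-sided Moller-Trumbore intersection per ray.

    Returns (t, tri_index) with t = +inf where a ray misses everything.
    Vectorized over rays x triangles; fine for the small parametric scenes
    used here (tens to hundreds of triangles).
    """
    n_rays = len(origins)
    n_tris = len(tris)
    if n_rays == 0 or n_tris == 0:
        return np.full(n_rays, np.inf), np.full(n_rays, -1, dtype=int)
    v0 = tris[:, 0]
    e1 = tris[:, 1] - v0
    e2 = tris[:, 2] - v0
    # pvec: (R, T, 3)
    pvec = np.cross(dirs[:, None, :], e2[None, :, :])
    det = np.einsum("tj,rtj->rt", e1, pvec)
    inv_det = np.where(np.abs(det) > eps, 1.0 / np.where(det == 0, 1.0, det), 0.0)
    tvec = origins[:, None, :] - v0[None, :, :]
    u = np.einsum("rtj,rtj->rt", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1[None, :, :])
    v = np.einsum("rj,rtj->rt", dirs, qvec) * inv_det
    t = np.einsum("tj,rtj->rt", e2, qvec) * inv_det
    valid = (
        (np.abs(det) > eps)
        & (u >= -1e-9)
        & (v >= -1e-9)
        & (u + v <= 1.0 + 1e-9)
        & (t > 1e-9)
    )
    t = np.where(valid, t, np.inf)
    idx = np.argmin(t, axis=1)
    t_min = t[np.arange(n_rays), idx]
    idx = np.where(np.isfinite(t_min), idx, -1)
    return t_min, idx


def cast_profile(
    scene: Scene,
    scanner: ScannerConfig,
    calib: PlatformCalibration,
    disc_angle: float,
    rng: np.random.Generator | None = None,
    noiseless: bool = False,
):
    """Acquire one profile at the given turntable angle.

    Returns ``(profile, true_points)`` where ``profile`` carries the averaged
    noisy ranges plus per-return ground-truth part labels, and ``true_points``
    are the exact ray-surface hit points in the specimen frame (index-aligned
    with the profile's returns).
    """
    if rng is None:
        rng = np.random.default_rng(scanner.rng_seed)
    theta = scanner.beam_angles()
    alpha = np.radians(theta + calib.tilt_varphi)  # physical beam elevation
    phi = math.radians(disc_angle % 360.0)
    c, s = math.cos(phi), math.sin(phi)
    # lab-frame ray: origin (d, 0, h), direction (-cos a, 0, sin a);
    # the scene is rotated by -disc_angle, i.e. rays rotate by +disc_angle
    # into the specimen frame.
    origin = np.array([calib.d * c, calib.d * s, calib.h])
    dirs = np.column_stack(
        [-np.cos(alpha) * c, -np.cos(alpha) * s, np.sin(alpha)]
    )
    origins = np.broadcast_to(origin, dirs.shape).copy()

    # cheap prefilter: only beams whose ray passes near the scene bounding sphere
    oc = scene._center - origin
    along = dirs @ oc
    perp_sq = float(oc @ oc) - along**2
    margin = scene._radius + 1e-6
    cand = (along > 0) & (perp_sq <= margin**2)
    t = np.full(len(dirs), np.inf)
    tri_idx = np.full(len(dirs), -1, dtype=int)
    if cand.any():
        t_c, i_c = _ray_mesh_first_hit(origins[cand], dirs[cand], scene.triangles)
        t[cand] = t_c
        tri_idx[cand] = i_c

    hit = np.isfinite(t) & (t >= scanner.range_min_cm) & (t <= scanner.range_max_cm)
    t_hit = t[hit]
    theta_hit = theta[hit]
    dirs_hit = dirs[hit]
    tri_hit = tri_idx[hit]
    normals = scene._normals[tri_hit]
    cos_inc = np.abs(np.einsum("rj,rj->r", dirs_hit, normals))

    if noiseless:
        dist = t_hit
    else:
        sigma = noise_sigma(t_hit / 100.0, scanner.noise_coeffs)
        sigma = sigma * np.minimum(1.0 / np.maximum(cos_inc, 1e-6), 3.0)
        # mean of repeat_count independent draws
        dist = t_hit + rng.normal(size=len(t_hit)) * sigma / math.sqrt(
            scanner.repeat_count
        )

    labels = scene.triangle_labels[tri_hit]
    refl = np.array([scene.reflectance.get(lb, 1.0) for lb in labels])
    intensity = np.clip(refl * cos_inc * (70.0 / np.maximum(t_hit, 1e-9)) ** 2, 0.0, 1.0)
    profile = Profile(
        beam_angles_deg=theta_hit,
        distances_cm=dist,
        intensity=intensity,
        disc_angle_phi=disc_angle,
        repeat_count=scanner.repeat_count,
        labels=labels,
    )
    # origin/dirs were built in the specimen frame, so hit points are too
    true_points = origins[hit] + t_hit[:, None] * dirs_hit
    return profile, true_points


def simulate_scan(
    scene: Scene,
    scanner: ScannerConfig,
    turntable: TurntableConfig,
    calib: PlatformCalibration,
    noiseless: bool = False,
):
    """Full turntable scan: one profile per step plus the ground-truth cloud.

    The ground-truth cloud holds the exact ray-surface hit points in the
    specimen frame with true part labels, index-aligned with the
    concatenated noisy returns.
    """
    rng = np.random.default_rng(scanner.rng_seed)
    profiles, gt_pts, gt_labels, gt_inten = [], [], [], []
    for angle in turntable.angles():
        prof, pts = cast_profile(scene, scanner, calib, angle, rng, noiseless)
        profiles.append(prof)
        if len(prof):
            gt_pts.append(pts)
            gt_labels.append(prof.labels)
            gt_inten.append(prof.intensity)
    if gt_pts:
        gt_cloud = PointCloud(
            np.vstack(gt_pts),
            np.concatenate(gt_inten),
            np.concatenate(gt_labels),
            frame="disc",
        )
    else:
        gt_cloud = PointCloud(np.zeros((0, 3)), np.zeros(0), frame="disc")
    return profiles, gt_cloud


# ---------------------------------------------------------------------------
# Geometric oracle: exact point-to-mesh distance
# ---------------------------------------------------------------------------


def point_mesh_distance(points: np.ndarray, scene: Scene, chunk: int = 2000):
    """Unsigned distance from each point to the nearest scene triangle (cm)."""
    tris = scene.triangles
    points = np.atleast_2d(points)
    out = np.empty(len(points))
    for i in range(0, len(points), chunk):
        out[i : i + chunk] = _point_tri_min(points[i : i + chunk], tris)
    return out


def _point_tri_min(points, tris):
    """Min distance point->triangle, vectorized (P, T)."""
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    ab = b - a
    ac = c - a
    p = points[:, None, :]
    ap = p - a
    d1 = np.einsum("tj,ptj->pt", ab, ap)
    d2 = np.einsum("tj,ptj->pt", ac, ap)
    bp = p - b
    d3 = np.einsum("tj,ptj->pt", ab, bp)
    d4 = np.einsum("tj,ptj->pt", ac, bp)
    cp = p - c
    d5 = np.einsum("tj,ptj->pt", ab, cp)
    d6 = np.einsum("tj,ptj->pt", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    nearest = np.empty(points.shape[:1] + tris.shape[:1] + (3,))
    remaining = np.ones(nearest.shape[:2], dtype=bool)

    def _assign(cond, cand):
        nonlocal remaining
        take = cond & remaining
        nearest[take] = np.broadcast_to(cand, nearest.shape)[take]
        remaining &= ~cond

    def _safe_div(num, den):
        return np.where(np.abs(den) > 1e-30, num / np.where(den == 0, 1.0, den), 0.0)

    # Ericson's closest-point region walk, first matching region wins
    _assign((d1 <= 0) & (d2 <= 0), a)  # vertex A
    _assign((d3 >= 0) & (d4 <= d3), b)  # vertex B
    _assign((d6 >= 0) & (d5 <= d6), c)  # vertex C
    w = _safe_div(d1, d1 - d3)
    _assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + w[..., None] * ab)  # edge AB
    w = _safe_div(d2, d2 - d6)
    _assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w[..., None] * ac)  # edge AC
    w = _safe_div(d4 - d3, (d4 - d3) + (d5 - d6))
    _assign(
        (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w[..., None] * (c - b)
    )  # edge BC
    denom = va + vb + vc
    v = _safe_div(vb, denom)
    w = _safe_div(vc, denom)
    _assign(remaining.copy(), a + v[..., None] * ab + w[..., None] * ac)  # interior

    d = np.linalg.norm(p - nearest, axis=2)
    return d.min(axis=1)
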