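"""Accuracy and precision metrology of the scanning platform.

Accuracy is assessed by scanning a reference cube and comparing the twelve
measurable edge lengths against the known edge.  Edges are named after the
face they bound: ``U1-U4`` on the top face, ``D1-D4`` on the bottom face and
``L1-L4`` the vertical front edges; ``U1, U2, D1, D2`` run along X,
``U3, U4, D3, D4`` along Y, and ``L1-L4`` along Z.

Per edge, the individual error is the absolute relative deviation in percent

    indiv_error = |m - Ref| / Ref * 100,

per-axis errors are means over that axis's four edges, the platform accuracy
is the mean of the three per-axis means, and the absolute error of the whole
measurement set is the standard error of the mean,

    abs_error = sqrt( sum_i (m_i - mbar)^2 / (N (N - 1)) ).

Precision is characterised by repeating a fixed zero-incidence distance
measurement and fitting a third-degree polynomial sigma(d) to the observed
dispersion as a function of distance (d in meters, sigma in cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .geometry import PlatformCalibration, PointCloud
from .simulate import ScannerConfig, build_cube, cast_profile

__all__ = [
    "EDGE_AXES",
    "EdgeMeasurement",
    "ErrorReport",
    "PrecisionFit",
    "individual_error",
    "absolute_error",
    "error_report",
    "measure_cube_edges",
    "edge_lengths_from_corners",
    "fit_precision_polynomial",
    "dispersion_experiment",
]

#: edge id -> coordinate axis whose accuracy the edge probes
EDGE_AXES = {
    "U1": "X", "U2": "X", "D1": "X", "D2": "X",
    "U3": "Y", "U4": "Y", "D3": "Y", "D4": "Y",
    "L1": "Z", "L2": "Z", "L3": "Z", "L4": "Z",
}


@dataclass(frozen=True)
class EdgeMeasurement:
    """One named cube-edge length measurement."""

    edge_id: str
    ref_cm: float
    measured_cm: float

    def __post_init__(self) -> None:
        if self.edge_id not in EDGE_AXES:
            raise ValueError(f"unknown edge id {self.edge_id!r}")
        if self.ref_cm <= 0:
            raise ValueError("reference length must be positive")

    @property
    def axis(self) -> str:
        return EDGE_AXES[self.edge_id]


@dataclass
class ErrorReport:
    """Edge-wise, axis-wise and aggregate accuracy of a cube measurement."""

    individual_errors_pct: dict
    axis_mean_errors_pct: dict
    accuracy_pct: float
    mean_m_cm: float
    sum_sq_dev_cm2: float
    abs_error_cm: float

    def as_dict(self) -> dict:
        return {
            "individual_errors_pct": dict(self.individual_errors_pct),
            "axis_mean_errors_pct": dict(self.axis_mean_errors_pct),
            "accuracy_pct": self.accuracy_pct,
            "mean_m_cm": self.mean_m_cm,
            "sum_sq_dev_cm2": self.sum_sq_dev_cm2,
            "abs_error_cm": self.abs_error_cm,
        }


@dataclass
class PrecisionFit:
    """Cubic precision model sigma(d): coefficients in (d^3, d^2, d, 1) order."""

    coefficients: tuple
    rms_residual_cm: float

    def __call__(self, distance_m):
        return np.polyval(self.coefficients, distance_m)


def absolute_error(measurements) -> float:
    """Standard error of the mean of a measurement set:
    ``sqrt(sum (m - mbar)^2 / (N (N - 1)))``."""
    m = np.asarray(measurements, dtype=float)
    n = len(m)
    if n < 2:
        raise ValueError("need at least 2 measurements")
    return math.sqrt(((m - m.mean()) ** 2).sum() / (n * (n - 1)))


def individual_error(measured_cm: float, ref_cm: float) -> float:
    """Absolute relative measurement error in percent."""
    if ref_cm == 0:
        raise ZeroDivisionError("reference length must be nonzero")
    return abs(measured_cm - ref_cm) / ref_cm * 100.0


def error_report(edges: "list[EdgeMeasurement]") -> ErrorReport:
    """Aggregate the twelve edge measurements into the accuracy report."""
    ids = [e.edge_id for e in edges]
    if sorted(ids) != sorted(EDGE_AXES):
        missing = set(EDGE_AXES) - set(ids)
        dupes = {i for i in ids if ids.count(i) > 1}
        raise ValueError(
            f"need exactly one measurement per edge; missing={sorted(missing)} "
            f"duplicated={sorted(dupes)}"
        )
    indiv = {e.edge_id: individual_error(e.measured_cm, e.ref_cm) for e in edges}
    axis_means = {}
    for axis in ("X", "Y", "Z"):
        vals = [indiv[i] for i in EDGE_AXES if EDGE_AXES[i] == axis]
        axis_means[axis] = float(np.mean(vals))
    accuracy = float(np.mean(list(axis_means.values())))
    m = np.array([e.measured_cm for e in edges])
    mbar = float(m.mean())
    ss = float(((m - mbar) ** 2).sum())
    n = len(m)
    abs_error = math.sqrt(ss / (n * (n - 1)))
    return ErrorReport(indiv, axis_means, accuracy, mbar, ss, abs_error)


# ---------------------------------------------------------------------------
# Cube-edge measurement from a reconstructed scan
# ---------------------------------------------------------------------------


def edge_lengths_from_corners(top4: np.ndarray, bottom4: np.ndarray) -> dict:
    """Twelve named edge lengths from the 4 top and 4 bottom corner points.

    Corners must be index-aligned (bottom corner ``i`` below top corner ``i``)
    and ordered counter-clockwise around the vertical axis.  Horizontal edges
    are assigned to X or Y by their dominant direction.
    """
    top4 = np.asarray(top4, dtype=float)
    bottom4 = np.asarray(bottom4, dtype=float)
    if top4.shape != (4, 3) or bottom4.shape != (4, 3):
        raise ValueError("need exactly four top and four bottom corners")

    def _axis_of(vec):
        return "X" if abs(vec[0]) >= abs(vec[1]) else "Y"

    lengths = {}
    for ring, prefix in ((top4, "U"), (bottom4, "D")):
        by_axis = {"X": [], "Y": []}
        for i in range(4):
            vec = ring[(i + 1) % 4] - ring[i]
            by_axis[_axis_of(vec)].append(float(np.linalg.norm(vec)))
        if len(by_axis["X"]) != 2 or len(by_axis["Y"]) != 2:
            raise ValueError("horizontal edges do not split 2/2 between X and Y")
        lengths[f"{prefix}1"], lengths[f"{prefix}2"] = by_axis["X"]
        lengths[f"{prefix}3"], lengths[f"{prefix}4"] = by_axis["Y"]
    for i in range(4):
        lengths[f"L{i + 1}"] = float(np.linalg.norm(top4[i] - bottom4[i]))
    return lengths


def _local_normals(points: np.ndarray, k: int = 12) -> np.ndarray:
    """Unit normals from the smallest principal direction of k-NN patches."""
    nn = NearestNeighbors(n_neighbors=min(k, len(points))).fit(points)
    _, idx = nn.kneighbors(points)
    patches = points[idx]
    centered = patches - patches.mean(axis=1, keepdims=True)
    cov = np.einsum("pki,pkj->pij", centered, centered) / idx.shape[1]
    _, vecs = np.linalg.eigh(cov)
    return vecs[:, :, 0]


def _fit_plane(points: np.ndarray, trim: float = 2.5) -> tuple[np.ndarray, float]:
    """Total-least-squares plane (normal n, offset c with n.p = c), one
    trimmed refinement pass to shed edge-straddling points."""
    for _ in range(2):
        centroid = points.mean(axis=0)
        _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
        normal = vt[2]
        resid = (points - centroid) @ normal
        rms = float(np.sqrt(np.mean(resid**2)))
        keep = np.abs(resid) <= max(trim * rms, 1e-12)
        if keep.sum() < 3 or keep.all():
            break
        points = points[keep]
    return normal, float(normal @ centroid)


def _intersect_planes(planes) -> np.ndarray:
    """Point where three planes (n, c) meet."""
    n = np.array([p[0] for p in planes])
    c = np.array([p[1] for p in planes])
    return np.linalg.solve(n, c)


def measure_cube_edges(
    cloud: PointCloud, ref_cm: float, normal_k: int = 12
) -> "list[EdgeMeasurement]":
    """Measure the twelve edges of a scanned cube resting on the disc.

    The four side faces and the top face are segmented by clustering local
    normals: the cube's yaw is estimated from the fourfold symmetry of the
    side-face normal azimuths, side points are assigned to the nearest of the
    four side directions, and each face gets a trimmed total-least-squares
    plane.  Top corners come from intersecting two adjacent side planes with
    the top plane; bottom corners from the same side planes and the disc
    plane ``z = 0`` the cube rests on.
    """
    pts = cloud.points
    if len(pts) < 30:
        raise ValueError("cube not resolvable: too few points")
    normals = _local_normals(pts, k=normal_k)
    # orient outward (cube is convex) so opposite faces separate in azimuth
    outward = pts - pts.mean(axis=0)
    flip = np.einsum("pj,pj->p", normals, outward) < 0
    normals[flip] *= -1.0
    nz = np.abs(normals[:, 2])
    top_mask = (nz > 0.8) & (pts[:, 2] > pts[:, 2].max() - 0.25 * ref_cm)
    side_mask = nz < 0.3
    if top_mask.sum() < 10 or side_mask.sum() < 40:
        raise ValueError("cube not resolvable: faces not recoverable")

    # yaw from fourfold symmetry of side-normal azimuths
    az = np.arctan2(normals[side_mask, 1], normals[side_mask, 0])
    yaw = math.atan2(np.sin(4 * az).mean(), np.cos(4 * az).mean()) / 4.0
    side_planes = []
    for i in range(4):
        direction = yaw + i * math.pi / 2.0
        axis = np.array([math.cos(direction), math.sin(direction)])
        proj = normals[side_mask, :2] @ axis
        members = proj > math.cos(math.pi / 4.5)
        if members.sum() < 10:
            raise ValueError("cube not resolvable: a side face is missing")
        side_planes.append(_fit_plane(pts[side_mask][members]))
    top_plane = _fit_plane(pts[top_mask])
    disc_plane = (np.array([0.0, 0.0, 1.0]), 0.0)

    top_corners, bottom_corners = [], []
    for i in range(4):
        pair = (side_planes[i], side_planes[(i + 1) % 4])
        top_corners.append(_intersect_planes([*pair, top_plane]))
        bottom_corners.append(_intersect_planes([*pair, disc_plane]))
    lengths = edge_lengths_from_corners(np.array(top_corners), np.array(bottom_corners))
    return [EdgeMeasurement(eid, ref_cm, lengths[eid]) for eid in EDGE_AXES]


# ---------------------------------------------------------------------------
# Precision: dispersion experiment and polynomial fit
# ---------------------------------------------------------------------------


def fit_precision_polynomial(pairs) -> PrecisionFit:
    """Least-squares cubic through (distance m, sigma cm) pairs."""
    pairs = np.asarray(pairs, dtype=float)
    d, s = pairs[:, 0], pairs[:, 1]
    if len(np.unique(d)) < 4:
        raise ValueError("need at least 4 distinct distances for a cubic fit")
    coeffs = np.polyfit(d, s, deg=3)
    resid = s - np.polyval(coeffs, d)
    return PrecisionFit(tuple(coeffs), float(np.sqrt(np.mean(resid**2))))


def dispersion_experiment(
    scanner: ScannerConfig,
    distances_m,
    repetitions: int = 142,
    face_edge_cm: float = 20.0,
):
    """Observed dispersion of the zero-incidence distance measurement.

    For each distance, a flat face is placed square to the sensor and the
    horizontal-beam range is acquired ``repetitions`` times (each acquisition
    averaged over the scanner's ``repeat_count``); the sample standard
    deviation of those ranges is the platform dispersion at that distance.
    """
    if repetitions < 2:
        raise ValueError("need at least 2 repetitions")
    rng = np.random.default_rng(scanner.rng_seed)
    out = []
    for d_m in distances_m:
        d_cm = 100.0 * d_m
        # place the cube so its near face is exactly at the probed distance
        calib = PlatformCalibration(d=d_cm + face_edge_cm / 2.0, h=face_edge_cm / 2.0)
        scene = build_cube(face_edge_cm)
        ranges = []
        for _ in range(repetitions):
            prof, _ = cast_profile(scene, scanner, calib, 0.0, rng)
            if len(prof) == 0:
                continue
            j = int(np.argmin(np.abs(prof.beam_angles_deg)))
            ranges.append(prof.distances_cm[j])
        ranges = np.asarray(ranges)
        out.append((float(d_m), float(ranges.std(ddof=1)) if len(ranges) > 1 else 0.0))
    return out
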