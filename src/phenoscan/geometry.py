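"""Reference frames and the homogeneous-transform reconstruction chain.

A 2D profile scanner sweeps a laser beam vertically (beam angle ``theta``)
while the specimen sits on a turntable (disc angle ``phi``).  Each return is a
polar sample ``(s, theta)`` in the sensor's scan plane; the reconstruction
chain converts it to Cartesian coordinates in the turntable (disc) frame:

1. polar -> sensor-plane Cartesian: ``(-s cos(theta), 0, s sin(theta), 1)``;
2. sensor-tilt rotation by ``varphi``;
3. translation by ``(d, 0, h)`` aligning sensor and disc origins;
4. rotation about the vertical disc axis by the turntable angle ``phi``.

All lengths are centimeters and all angles are degrees at every interface.
The disc surface defines ``z = 0``; ``h`` is the signed sensor height above
it and ``d`` the horizontal distance from the sensor origin to the disc
center ``O``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PolarSample",
    "Profile",
    "PlatformCalibration",
    "PointCloud",
    "polar_to_sensor_plane",
    "sensor_plane_points",
    "tilt_transform",
    "sensor_to_disc_translation",
    "disc_rotation",
    "compose_chain",
    "reconstruct_profile",
    "reconstruct_scan",
    "calibrate_from_target",
    "CalibrationError",
    "steps_per_revolution",
    "turntable_resolution_deg",
]

#: Sentinel distance for a beam that produced no return.
NO_RETURN = float("nan")


class CalibrationError(ValueError):
    """Raised when the calibration-target scan cannot be interpreted."""


@dataclass(frozen=True)
class PolarSample:
    """One LiDAR return: range ``s`` (cm), beam angle ``theta`` (deg), intensity."""

    distance_s: float
    beam_angle_theta: float
    intensity: float = 0.0

    @property
    def is_return(self) -> bool:
        return math.isfinite(self.distance_s) and self.distance_s > 0

    @staticmethod
    def missed(beam_angle_theta: float) -> "PolarSample":
        """A missed beam (no return within the working range)."""
        return PolarSample(NO_RETURN, beam_angle_theta, 0.0)


@dataclass
class Profile:
    """One vertical sweep at a fixed turntable angle.

    Only valid returns are stored; missed beams are dropped at acquisition
    time and never zero-filled.  Arrays are index-aligned and ordered by
    strictly increasing beam angle.
    """

    beam_angles_deg: np.ndarray
    distances_cm: np.ndarray
    intensity: np.ndarray
    disc_angle_phi: float
    repeat_count: int = 1
    #: optional per-return ground-truth part label (simulator output)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beam_angles_deg = np.asarray(self.beam_angles_deg, dtype=float)
        self.distances_cm = np.asarray(self.distances_cm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (
            len(self.beam_angles_deg) == len(self.distances_cm) == len(self.intensity)
        ):
            raise ValueError("profile arrays must be index-aligned")
        if len(self.beam_angles_deg) > 1 and np.any(np.diff(self.beam_angles_deg) <= 0):
            raise ValueError("samples must be ordered by strictly increasing beam angle")
        self.disc_angle_phi = float(self.disc_angle_phi) % 360.0

    def __len__(self) -> int:
        return len(self.beam_angles_deg)

    @property
    def samples(self) -> list[PolarSample]:
        return [
            PolarSample(s, t, i)
            for s, t, i in zip(self.distances_cm, self.beam_angles_deg, self.intensity)
        ]


@dataclass
class PlatformCalibration:
    """Sensor-to-disc geometry: offsets ``d`` (cm), ``h`` (cm) and tilt (deg)."""

    d: float
    h: float
    tilt_varphi: float = 0.0
    target_fit_rms_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError(f"horizontal offset d must be positive, got {self.d}")
        if not -90.0 < self.tilt_varphi < 90.0:
            raise ValueError(f"tilt must lie in (-90, 90) deg, got {self.tilt_varphi}")


@dataclass
class PointCloud:
    """N x 3 Cartesian points (cm) with optional per-point intensity and labels."""

    points: np.ndarray
    intensity: np.ndarray | None = None
    labels: np.ndarray | None = None
    frame: str = "disc"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        for name in ("intensity", "labels"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if len(arr) != len(self.points):
                    raise ValueError(f"{name} must have one entry per point")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Sub-cloud of the points where ``mask`` holds, attributes carried along."""
        return PointCloud(
            self.points[mask],
            None if self.intensity is None else self.intensity[mask],
            None if self.labels is None else self.labels[mask],
            self.frame,
        )

    @staticmethod
    def concatenate(clouds: "list[PointCloud]", frame: str = "disc") -> "PointCloud":
        clouds = [c for c in clouds if len(c)]
        if not clouds:
            return PointCloud(np.zeros((0, 3)), np.zeros(0), frame=frame)
        pts = np.vstack([c.points for c in clouds])
        inten = (
            np.concatenate([c.intensity for c in clouds])
            if all(c.intensity is not None for c in clouds)
            else None
        )
        labels = (
            np.concatenate([c.labels for c in clouds])
            if all(c.labels is not None for c in clouds)
            else None
        )
        return PointCloud(pts, inten, labels, frame)


# ---------------------------------------------------------------------------
# The reconstruction chain
# ---------------------------------------------------------------------------


def polar_to_sensor_plane(sample: PolarSample) -> np.ndarray:
    """Sensor-plane homogeneous point ``(-s cos(theta), 0, s sin(theta), 1)``."""
    if not sample.is_return:
        raise ValueError("missed beam has no Cartesian image")
    t = math.radians(sample.beam_angle_theta)
    s = sample.distance_s
    return np.array([-s * math.cos(t), 0.0, s * math.sin(t), 1.0])


def sensor_plane_points(
    beam_angles_deg: np.ndarray, distances_cm: np.ndarray
) -> np.ndarray:
    """Vectorized polar -> sensor-plane conversion, returns (N, 4) points."""
    t = np.radians(np.asarray(beam_angles_deg, dtype=float))
    s = np.asarray(distances_cm, dtype=float)
    out = np.empty((len(s), 4))
    out[:, 0] = -s * np.cos(t)
    out[:, 1] = 0.0
    out[:, 2] = s * np.sin(t)
    out[:, 3] = 1.0
    return out


def tilt_transform(tilt_varphi: float) -> np.ndarray:
    """Sensor-tilt rotation of the reconstruction chain (4 x 4, degrees in)."""
    if not -90.0 < tilt_varphi < 90.0:
        raise ValueError("tilt must lie in (-90, 90) degrees")
    p = math.radians(tilt_varphi)
    c, s = math.cos(p), math.sin(p)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, -s, 0.0],
            [0.0, s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def sensor_to_disc_translation(calib: PlatformCalibration) -> np.ndarray:
    """Translation by ``(d, 0, h)`` aligning the sensor origin with the disc."""
    m = np.eye(4)
    m[0, 3] = calib.d
    m[2, 3] = calib.h
    return m


def disc_rotation(disc_angle_phi: float) -> np.ndarray:
    """Rotation about the vertical disc axis by the turntable angle (degrees)."""
    p = math.radians(disc_angle_phi % 360.0)
    c, s = math.cos(p), math.sin(p)
    return np.array(
        [
            [c, -s, 0.0, 0.0],
            [s, c, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def compose_chain(calib: PlatformCalibration, disc_angle_phi: float) -> np.ndarray:
    """Single matrix taking sensor-plane points to the disc frame."""
    return (
        disc_rotation(disc_angle_phi)
        @ sensor_to_disc_translation(calib)
        @ tilt_transform(calib.tilt_varphi)
    )


def reconstruct_profile(profile: Profile, calib: PlatformCalibration) -> PointCloud:
    """Reconstruct one profile into the disc frame.

    Applies the full chain to every valid sample; intensity (and, for
    simulator output, ground-truth labels) are carried through unchanged.
    An empty profile yields an empty cloud.
    """
    if len(profile) == 0:
        return PointCloud(np.zeros((0, 3)), np.zeros(0), frame="disc")
    pts = sensor_plane_points(profile.beam_angles_deg, profile.distances_cm)
    m = compose_chain(calib, profile.disc_angle_phi)
    out = pts @ m.T
    return PointCloud(out[:, :3], profile.intensity.copy(), profile.labels, "disc")


def reconstruct_scan(
    profiles: "list[Profile]", calib: PlatformCalibration
) -> PointCloud:
    """Concatenated reconstruction of a full turntable scan."""
    return PointCloud.concatenate(
        [reconstruct_profile(p, calib) for p in profiles], frame="disc"
    )


# ---------------------------------------------------------------------------
# Platform calibration from the planar-target scan
# ---------------------------------------------------------------------------


def _tls_line(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares line fit: (centroid, unit direction, rms residual).

    Orthogonal regression is the right model here because range noise acts
    along the beam, not along one coordinate axis.
    """
    centroid = xy.mean(axis=0)
    centered = xy - centroid
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    resid = centered @ vt[1]
    rms = float(np.sqrt(np.mean(resid**2))) if len(xy) > 2 else 0.0
    return centroid, direction, rms


def calibrate_from_target(
    target_profiles: "list[Profile]",
    max_fit_rms_cm: float = 0.5,
) -> PlatformCalibration:
    """Estimate (d, h, tilt) from a scan of the vertical planar target.

    The target stands on the disc through its center ``O``, so its trace in
    the sensor ``X'Z'`` plane is a straight line inclined by the sensor tilt.
    A total-least-squares line fit to the upper portion of the trace (which
    is guaranteed to be pure target: any turntable-surface returns sit at the
    very bottom) gives the tilt as the signed angle to the ``Z'`` axis and,
    after de-tilting, the horizontal offset ``d``.  The lowest de-tilted
    return anchors the disc surface at ``z = 0`` and hence gives ``h``:
    returns from the disc surface itself land exactly at ``z = -h``.
    """
    xs, zs = [], []
    for p in target_profiles:
        if len(p) == 0:
            continue
        pts = sensor_plane_points(p.beam_angles_deg, p.distances_cm)
        xs.append(pts[:, 0])
        zs.append(pts[:, 2])
    if not xs:
        raise CalibrationError("insufficient target returns")
    x = np.concatenate(xs)
    z = np.concatenate(zs)
    if len(x) < 2:
        raise CalibrationError("insufficient target returns")

    # Upper 60% of the vertical extent: pure target-face returns.
    z_lo, z_hi = z.min(), z.max()
    upper = z >= z_lo + 0.4 * (z_hi - z_lo)
    if upper.sum() < 2:
        upper = np.ones_like(z, dtype=bool)
    xy = np.column_stack([x[upper], z[upper]])
    centroid, direction, rms = _tls_line(xy)
    if direction[1] < 0:
        direction = -direction
    if rms > max_fit_rms_cm:
        raise CalibrationError(
            f"target not planar/vertical: line-fit rms {rms:.3f} cm "
            f"exceeds {max_fit_rms_cm} cm"
        )
    tilt = math.degrees(math.atan2(-direction[0], direction[1]))
    if abs(tilt) > 45.0:
        raise CalibrationError(
            "no vertical target line found (fitted trace is near-horizontal); "
            "is the target inside the sweep?"
        )

    # De-tilt all returns so the target face becomes the vertical line x = -d.
    p = math.radians(tilt)
    c, s = math.cos(p), math.sin(p)
    x_dt = x * c + z * s
    z_dt = -x * s + z * c
    cx_dt = centroid[0] * c + centroid[1] * s
    d = -float(cx_dt)
    if d <= 0:
        raise CalibrationError("target appears behind the sensor; bad scan")
    h = -float(z_dt.min())
    return PlatformCalibration(d=d, h=h, tilt_varphi=tilt, target_fit_rms_cm=rms)


# ---------------------------------------------------------------------------
# Turntable gear-train arithmetic
# ---------------------------------------------------------------------------


def steps_per_revolution(motor_steps_per_rev: int, worm_ratio: int = 36) -> int:
    """Steps for one full turntable revolution through the worm-gear train."""
    if motor_steps_per_rev <= 0 or worm_ratio <= 0:
        raise ValueError("steps and ratio must be positive")
    return int(motor_steps_per_rev) * int(worm_ratio)


def turntable_resolution_deg(motor_steps_per_rev: int, worm_ratio: int = 36) -> float:
    """Smallest commandable turntable increment in degrees."""
    return 360.0 / steps_per_revolution(motor_steps_per_rev, worm_ratio)
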