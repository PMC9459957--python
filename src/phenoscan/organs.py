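"""Stem/leaf organ classification of seedling point clouds.

Each point is described by geometric morphology features computed from its
spherical neighbourhood plus two global cues:

* eigenvalue shape features of the local covariance (eigenvalues
  ``l1 >= l2 >= l3``): linearity ``(l1-l2)/l1``, planarity ``(l2-l3)/l1``,
  sphericity ``l3/l1``;
* verticality of the surface normal (smallest eigenvector) and of the
  dominant direction (largest eigenvector) relative to the vertical axis;
* local point density;
* normalized height ``z / max(z)`` and horizontal (radial) distance to the
  estimated stem axis.

A Random Forest is trained on a 60/20/20 train/tune/validate split made by
whole plant (all points of one scan stay together), with growth stages
(shoot to third leaf vs. later) routed to separate models.  Predicted labels
are post-processed by an ascending virtual-ring filter: a ring of fixed
radius sweeps up the stem axis and any stem-labeled point falling outside it
is relabeled leaf (leaf labels are never turned into stem).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

from .geometry import PointCloud

__all__ = [
    "PointFeatures",
    "SplitSpec",
    "RingFilterParams",
    "LabeledScan",
    "extract_features",
    "split_dataset",
    "train_classifier",
    "classify",
    "ring_filter",
    "accuracy",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "linearity",
    "planarity",
    "sphericity",
    "normal_verticality",
    "axis_verticality",
    "density",
    "normalized_height",
    "radial_distance",
)

DEGENERATE_SENTINEL = 0.0


@dataclass
class PointFeatures:
    """Per-point feature matrix plus a flag for degenerate neighbourhoods."""

    values: np.ndarray  # (N, len(FEATURE_NAMES))
    degenerate: np.ndarray  # (N,) bool; features were set to a sentinel

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SplitSpec:
    """Plant-wise 60/20/20 split with stage routing by leaf count."""

    train_frac: float = 0.60
    tune_frac: float = 0.20
    validate_frac: float = 0.20
    early_max_leaves: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_frac + self.tune_frac + self.validate_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class RingFilterParams:
    """Ascending virtual-ring stem filter.

    ``radius`` is in the cloud's native units; the platform default of
    0.0015 is kept for compatibility with clouds expressed in meters and
    should be overridden to match the stem scale of cm clouds.
    """

    radius: float = 0.0015
    step_height: float = 0.5
    axis_xy: tuple | None = None  # estimated from basal stem points if None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ring radius must be positive")


@dataclass
class LabeledScan:
    """One scanned plant with per-point organ labels and stage metadata."""

    plant_id: str
    cloud: PointCloud
    labels: np.ndarray  # per-point {"stem", "leaf"}
    n_leaves: int = 0


def _stem_axis_estimate(points: np.ndarray, stem_mask: np.ndarray | None = None):
    """(x0, y0) of the stem axis: centroid of the basal 10% height slab."""
    z = points[:, 2]
    slab = z <= z.min() + 0.10 * max(z.max() - z.min(), 1e-9)
    if stem_mask is not None and (slab & stem_mask).sum() >= 3:
        slab = slab & stem_mask
    return points[slab, :2].mean(axis=0)


def extract_features(cloud: PointCloud, neighborhood_radius: float = 1.0) -> PointFeatures:
    """Geometric morphology descriptors for every point.

    Neighbourhoods with fewer than 3 points cannot support a covariance;
    their eigen-features are set to a sentinel and the point is flagged.
    """
    pts = cloud.points
    n = len(pts)
    if n < 10:
        raise ValueError("need at least 10 points to extract features")
    r = float(neighborhood_radius)
    nn = NearestNeighbors(radius=r).fit(pts)
    neighbor_lists = nn.radius_neighbors(pts, return_distance=False)

    # accumulate per-neighbourhood first and second moments with bincount,
    # then eigendecompose all 3x3 covariances in one batched call
    counts = np.array([len(idx) for idx in neighbor_lists])
    rows = np.repeat(np.arange(n), counts)
    cols = np.concatenate(neighbor_lists) if counts.sum() else np.zeros(0, dtype=int)
    neigh = pts[cols]
    s1 = np.stack([np.bincount(rows, weights=neigh[:, j], minlength=n)
                   for j in range(3)], axis=1)
    s2 = np.empty((n, 3, 3))
    for j in range(3):
        for k in range(j, 3):
            s2[:, j, k] = s2[:, k, j] = np.bincount(
                rows, weights=neigh[:, j] * neigh[:, k], minlength=n)
    safe_counts = np.maximum(counts, 1)[:, None]
    mean = s1 / safe_counts
    cov = s2 / safe_counts[..., None] - mean[:, :, None] * mean[:, None, :]
    cov = (cov + cov.transpose(0, 2, 1)) / 2.0

    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues, batched
    evals = np.maximum(evals, 0.0)
    l3, l2, l1 = evals[:, 0], evals[:, 1], evals[:, 2]
    degenerate = (counts < 3) | (l1 <= 1e-18)
    l1_safe = np.where(l1 > 0, l1, 1.0)

    values = np.full((n, len(FEATURE_NAMES)), DEGENERATE_SENTINEL)
    ok = ~degenerate
    values[ok, 0] = ((l1 - l2) / l1_safe)[ok]
    values[ok, 1] = ((l2 - l3) / l1_safe)[ok]
    values[ok, 2] = (l3 / l1_safe)[ok]
    values[ok, 3] = np.abs(evecs[:, 2, 0])[ok]  # smallest eigenvector vs z
    values[ok, 4] = np.abs(evecs[:, 2, 2])[ok]  # largest eigenvector vs z
    sphere_vol = 4.0 / 3.0 * np.pi * r**3
    values[ok, 5] = (counts / sphere_vol)[ok]

    z = pts[:, 2]
    axis = _stem_axis_estimate(pts)
    values[:, 6] = np.clip(z / max(z.max(), 1e-9), 0.0, 1.0)
    values[:, 7] = np.hypot(pts[:, 0] - axis[0], pts[:, 1] - axis[1])
    return PointFeatures(values, degenerate)


def split_dataset(scans: "list[LabeledScan]", spec: SplitSpec | None = None):
    """Deterministic plant-wise split into (train, tune, validate) per stage.

    Returns a dict ``{"early": (train, tune, validate), "late": (...)}``;
    a stage absent from the input maps to three empty lists.  Train size is
    the floor of its fraction; the remainder is balanced between tune and
    validate (validate gets the odd scan).
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.rng_seed)
    out = {}
    for stage in ("early", "late"):
        if stage == "early":
            members = [s for s in scans if s.n_leaves <= spec.early_max_leaves]
        else:
            members = [s for s in scans if s.n_leaves > spec.early_max_leaves]
        if not members:
            out[stage] = ([], [], [])
            continue
        if len(members) < 5:
            raise ValueError(f"need at least 5 scans in stage {stage!r}")
        order = rng.permutation(len(members))
        members = [members[i] for i in order]
        n = len(members)
        n_train = int(np.floor(spec.train_frac * n))
        rest = n - n_train
        n_tune = rest // 2
        out[stage] = (
            members[:n_train],
            members[n_train : n_train + n_tune],
            members[n_train + n_tune :],
        )
    return out


_LABELS = np.array(["stem", "leaf"])

DEFAULT_TUNING_GRID = tuple(
    {"n_estimators": t, "max_depth": d}
    for t in (50, 100, 200)
    for d in (8, 16, None)
)


def _scan_matrix(scans, neighborhood_radius):
    xs, ys = [], []
    for s in scans:
        feats = extract_features(s.cloud, neighborhood_radius)
        xs.append(feats.values)
        ys.append(np.asarray(s.labels))
    return np.vstack(xs), np.concatenate(ys)


def train_classifier(
    train: "list[LabeledScan]",
    tune: "list[LabeledScan]",
    neighborhood_radius: float = 1.0,
    tuning_grid=DEFAULT_TUNING_GRID,
    max_train_points: int = 40000,
    rng_seed: int = 0,
) -> RandomForestClassifier:
    """Random Forest with hyperparameters selected on the tune split."""
    x_train, y_train = _scan_matrix(train, neighborhood_radius)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both stem and leaf points")
    rng = np.random.default_rng(rng_seed)
    if len(x_train) > max_train_points:
        keep = rng.choice(len(x_train), size=max_train_points, replace=False)
        x_train, y_train = x_train[keep], y_train[keep]
    if tune:
        x_tune, y_tune = _scan_matrix(tune, neighborhood_radius)
    else:
        x_tune, y_tune = x_train, y_train
    best, best_acc = None, -1.0
    for params in tuning_grid:
        model = RandomForestClassifier(
            random_state=rng_seed, n_jobs=1, **params
        ).fit(x_train, y_train)
        acc = float((model.predict(x_tune) == y_tune).mean())
        if acc > best_acc:
            best, best_acc = model, acc
    best.tune_accuracy_ = best_acc
    best.neighborhood_radius_ = neighborhood_radius
    return best


def classify(
    model: RandomForestClassifier, cloud: PointCloud, neighborhood_radius: float | None = None
) -> np.ndarray:
    """Per-point {"stem", "leaf"} prediction for a cloud."""
    r = neighborhood_radius or getattr(model, "neighborhood_radius_", 1.0)
    feats = extract_features(cloud, r)
    return model.predict(feats.values)


def ring_filter(
    cloud: PointCloud,
    labels: np.ndarray,
    params: RingFilterParams,
) -> np.ndarray:
    """Ascending virtual-ring stem filter.

    A ring of the given radius rises along the estimated stem axis from the
    base to the top of the plant; stem-labeled points falling outside the
    ring at their height are relabeled leaf.  The axis estimate and the
    relabeling are iterated to a fixed point, which makes the filter
    idempotent; leaf labels are never changed back to stem.
    """
    labels = np.asarray(labels).copy()
    stem = labels == "stem"
    if not stem.any():
        warnings.warn("no stem-labeled points; ring filter left cloud unchanged",
                      stacklevel=2)
        return labels
    pts = cloud.points
    for _ in range(50):
        stem = labels == "stem"
        if not stem.any():
            break
        if params.axis_xy is not None:
            axis = np.asarray(params.axis_xy, dtype=float)
        else:
            axis = _stem_axis_estimate(pts, stem)
        radial = np.hypot(pts[:, 0] - axis[0], pts[:, 1] - axis[1])
        outside = stem & (radial > params.radius)
        if not outside.any():
            break
        labels[outside] = "leaf"
        if params.axis_xy is not None:
            break  # fixed axis: a single sweep already is a fixed point
    return labels


def accuracy(predicted, truth) -> float:
    """Percentage of matching labels."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have the same length")
    if len(predicted) == 0:
        raise ValueError("empty labelings have no accuracy")
    return float((predicted == truth).mean() * 100.0)
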