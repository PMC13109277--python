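"""Ion footprints on a virtual 4-pi spherical detector, and their comparison.

After an explosion the ions travel ballistically; the direction of each
ion's asymptotic velocity is binned on an equal-angle elevation x azimuth
grid (default 40 x 80), mimicking an idealized position-sensitive MCP
detector that records only the total ion count per solid angle.  Footprints
are compared with the Euclidean (L2) distance of their flattened count
maps, embedded in 2D (t-SNE, or PCA for a deterministic fallback), and
classified by seeded k-means with best-permutation label matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cei_dynamics import ExplosionResult

__all__ = [
    "SphericalDetectorSpec",
    "Footprint",
    "EmbeddingResult",
    "project",
    "l2_distance",
    "embed",
    "classify",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SphericalDetectorSpec:
    """Equal-angle binning: elevation in [-90, 90] deg, azimuth in [0, 360)."""

    n_elevation: int = 40
    n_azimuth: int = 80

    def __post_init__(self) -> None:
        if self.n_elevation < 1 or self.n_azimuth < 1:
            raise ValueError("bin counts must be >= 1")

    @property
    def elevation_centers_deg(self) -> np.ndarray:
        width = 180.0 / self.n_elevation
        return -90.0 + width * (np.arange(self.n_elevation) + 0.5)


@dataclass
class Footprint:
    """Ion counts per detector bin; the unit compared and classified."""

    counts: np.ndarray
    spec: SphericalDetectorSpec
    label: str = ""
    seed: int | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.spec.n_elevation, self.spec.n_azimuth):
            raise ValueError("counts shape does not match detector spec")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")

    @property
    def total_ions(self) -> int:
        return int(self.counts.sum())


@dataclass
class EmbeddingResult:
    """2D coordinates per footprint (arbitrary units)."""

    coordinates: np.ndarray
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("coordinates must be (n, 2)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite embedding coordinates")


def direction_footprint(
    velocities: np.ndarray,
    spec: SphericalDetectorSpec = SphericalDetectorSpec(),
    label: str = "",
    seed: int | None = None,
    n_excluded: int = 0,
) -> Footprint:
    """Bin velocity directions (one count each) on the spherical detector."""
    v = np.asarray(velocities, dtype=float)
    speed = np.linalg.norm(v, axis=1)
    elev = np.degrees(np.arcsin(np.clip(v[:, 2] / speed, -1.0, 1.0)))
    azim = np.degrees(np.arctan2(v[:, 1], v[:, 0])) % 360.0
    i = np.minimum((elev + 90.0) / (180.0 / spec.n_elevation), spec.n_elevation - 1e-9)
    j = np.minimum(azim / (360.0 / spec.n_azimuth), spec.n_azimuth - 1e-9)
    counts = np.zeros((spec.n_elevation, spec.n_azimuth), dtype=np.int64)
    np.add.at(counts, (i.astype(int), j.astype(int)), 1)
    return Footprint(counts, spec, label=label, seed=seed, n_excluded=n_excluded)


def project(
    result: ExplosionResult,
    spec: SphericalDetectorSpec = SphericalDetectorSpec(),
    min_charge: int = 1,
    label: str = "",
    seed: int | None = None,
) -> Footprint:
    """Project an explosion's asymptotic ion directions onto the detector.

    Only atoms with charge >= ``min_charge`` (default 1: neutrals are
    invisible to an ion detector) and nonzero speed contribute; ions with
    zero velocity are excluded and counted in ``n_excluded``.
    """
    if min_charge < 1:
        raise ValueError("min_charge must be >= 1")
    sys_ = result.system
    speed = np.linalg.norm(sys_.velocities, axis=1)
    charged = sys_.charges >= min_charge
    moving = speed > 0
    n_excluded = int(np.sum(charged & ~moving))
    if n_excluded:
        logger.warning("excluded %d zero-velocity ion(s) from footprint", n_excluded)
    sel = charged & moving
    return direction_footprint(
        sys_.velocities[sel], spec, label=label, seed=seed, n_excluded=n_excluded
    )


def l2_distance(a: Footprint, b: Footprint, normalize: bool = False) -> float:
    """Euclidean norm of the flattened count difference.

    In normalized mode each footprint is first divided by its total count.
    """
    if a.spec != b.spec:
        raise ValueError("footprints use different detector specs")
    x = a.counts.astype(float).ravel()
    y = b.counts.astype(float).ravel()
    if normalize:
        if a.total_ions == 0 or b.total_ions == 0:
            raise ValueError("cannot normalize an empty footprint")
        x = x / a.total_ions
        y = y / b.total_ions
    return float(np.linalg.norm(x - y))


def embed(
    footprints: list,
    method: str = "tsne",
    seed: int = 0,
    perplexity: float | None = None,
) -> EmbeddingResult:
    """Embed footprints in 2D: seeded t-SNE, or deterministic PCA.

    ``perplexity=None`` picks min(30, (n - 1) / 3 - eps) automatically; an
    explicit value must satisfy perplexity < (n - 1) / 3.
    """
    n = len(footprints)
    X = np.array([fp.counts.ravel() for fp in footprints], dtype=float)
    if method == "pca":
        from sklearn.decomposition import PCA

        if n < 1:
            raise ValueError("need at least one footprint")
        if n < 3 or np.allclose(X, X[0]):
            coords = np.zeros((n, 2))
        else:
            coords = PCA(n_components=2, svd_solver="full").fit_transform(X)
            # fix the sign convention so the result is reproducible
            for k in range(2):
                if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
                    coords[:, k] *= -1
        return EmbeddingResult(coords, "pca", seed)
    if method == "tsne":
        from sklearn.manifold import TSNE

        if n < 3:
            raise ValueError("t-SNE needs at least 3 footprints")
        limit = (n - 1) / 3.0
        if perplexity is None:
            perplexity = min(30.0, limit * 0.999)
        if not 0 < perplexity < limit:
            raise ValueError(f"perplexity must be in (0, {limit:.2f}) for {n} footprints")
        tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
        return EmbeddingResult(tsne.fit_transform(X), "tsne", seed)
    raise ValueError(f"unknown method {method!r}")


def classify(
    embedding: EmbeddingResult, true_labels: list, k: int, seed: int = 0
) -> float:
    """k-means accuracy on the 2D embedding, best label permutation.

    Returns the fraction of points whose cluster matches their true label
    under the assignment that maximizes agreement.
    """
    labels = np.asarray(true_labels)
    if k != len(set(labels.tolist())):
        raise ValueError("k must equal the number of distinct true labels")
    coords = embedding.coordinates
    if np.allclose(coords, coords[0]):
        logger.warning("degenerate embedding (all points identical); accuracy = 1/k")
        return 1.0 / k
    from sklearn.cluster import KMeans

    pred = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(coords)
    classes = {lab: idx for idx, lab in enumerate(sorted(set(labels.tolist())))}
    truth = np.array([classes[lab] for lab in labels])
    contingency = np.zeros((k, k))
    for p, tr in zip(pred, truth):
        contingency[p, tr] += 1
    rows, cols = linear_sum_assignment(-contingency)
    return float(contingency[rows, cols].sum() / len(labels))
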