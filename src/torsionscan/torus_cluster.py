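"""Clustering fragment conformations on the dihedral torus.

A fragment match of length k carries k (phi, psi) pairs; stacking them
gives one point in a 2k-dimensional angular space.  Because each coordinate
is periodic (−180° and +180° are the same angle) distances are computed on
the torus: per-coordinate differences are wrapped to at most 180° before
taking the Euclidean norm.  A density-based hierarchical method (HDBSCAN)
then finds however many conformational clusters the data supports — the
cluster count is never prespecified — and each cluster is summarised by its
medoid, the member with the lowest total distance to the rest of its
cluster.

With each residue restricted to at most three Ramachandran basins
(alpha-helical, beta-strand, left-handed-helical), a k-residue fragment can
occupy at most 3^k joint basin combinations; in practice far fewer are
populated, which is what makes the recovered clusters informative.

The per-residue view is also supported: the conditional distribution of a
target residue's (phi, psi) given its sequence context is estimated with a
wrapped-Gaussian kernel density on the torus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import HDBSCAN
from sklearn.utils.validation import check_is_fitted

from .fragment_index import FragmentMatch

__all__ = [
    "TorsionPointSet",
    "ClusterResult",
    "MixtureSpec",
    "MixtureComponent",
    "assemble_points",
    "torus_distance",
    "pairwise_torus_distances",
    "TorusHDBSCAN",
    "cluster_fragments",
    "cluster_medoids",
    "target_residue_index",
    "target_conditional_density",
    "max_basin_combinations",
    "DensityGrid",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Raised when too few points are available to cluster."""


def wrap_degrees(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (−180, 180], mapping −180 to +180."""
    wrapped = ((np.asarray(a, dtype=float) + 180.0) % 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.ndim(a) == 0:
        return float(wrapped)
    return wrapped


@dataclass
class TorsionPointSet:
    """M fragment conformations as rows of 2k angular coordinates
    (phi1, psi1, ..., phik, psik), degrees in (−180, 180]."""

    points: np.ndarray
    matches: list[FragmentMatch] = field(default_factory=list)
    n_excluded: int = 0

    @property
    def k(self) -> int:
        return self.points.shape[1] // 2 if self.points.size else 0

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ClusterResult:
    """Labels (−1 = noise), cluster count C, sizes and medoids."""

    labels: np.ndarray
    n_clusters: int
    medoid_indices: dict[int, int]
    sizes: dict[int, int]
    n_noise: int
    params: dict = field(default_factory=dict)


@dataclass
class MixtureComponent:
    center: np.ndarray       # 2k-vector, degrees
    kappa: float             # von Mises concentration
    weight: float


@dataclass
class MixtureSpec:
    """A mixture of independent-von-Mises components on the torus."""

    components: list[MixtureComponent]

    def __post_init__(self) -> None:
        w = np.array([c.weight for c in self.components], dtype=float)
        if np.any(w <= 0):
            raise ValueError("component weights must be positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")

    @property
    def dim(self) -> int:
        return len(np.atleast_1d(self.components[0].center))


def assemble_points(matches: Sequence[FragmentMatch]) -> TorsionPointSet:
    """Stack each match's k (phi, psi) pairs into one 2k-dimensional row.

    Matches with any undefined angle (segment termini) are excluded and
    counted in ``n_excluded``.
    """
    if matches:
        k = len(matches[0].kmer)
        if any(len(m.kmer) != k for m in matches):
            raise ValueError("all matches must share the same k")
    rows, kept, excluded = [], [], 0
    for m in matches:
        flat = [v for pair in m.angles for v in pair]
        if any(v is None for v in flat):
            excluded += 1
            continue
        rows.append(flat)
        kept.append(m)
    pts = np.array(rows, dtype=float) if rows else np.empty((0, 0))
    if pts.size:
        pts = wrap_degrees(pts)
    return TorsionPointSet(points=pts, matches=kept, n_excluded=excluded)


def torus_distance(u, v) -> float:
    """Euclidean norm of per-coordinate wrapped differences.

    Each coordinate difference is reduced to ``min(|du|, 360 − |du|)`` so
    that −180° and +180° coincide (e.g. −179° vs 179° differ by 2°).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    delta = np.abs(u - v)
    delta = np.minimum(delta, 360.0 - delta)
    return float(np.sqrt(np.sum(delta**2)))


def pairwise_torus_distances(points: np.ndarray) -> np.ndarray:
    """Full M x M torus distance matrix (vectorised)."""
    p = np.asarray(points, dtype=float)
    delta = np.abs(p[:, None, :] - p[None, :, :])
    delta = np.minimum(delta, 360.0 - delta)
    return np.sqrt(np.sum(delta**2, axis=-1))


class TorusHDBSCAN(ClusterMixin, BaseEstimator):
    """HDBSCAN on angular data under the torus metric.

    scikit-learn-style estimator: ``fit(X)`` takes an (M, 2k) array of
    angles in degrees, precomputes wrapped pairwise distances, runs HDBSCAN
    on them and selects per-cluster medoids.

    Parameters
    ----------
    min_cluster_size : int or None
        Smallest cluster; ``None`` uses ``max(5, ceil(0.025 * M))`` so the
        granularity scales with the match count.
    min_samples : int or None
        Density smoothing parameter; ``None`` mirrors ``min_cluster_size``.
    max_points : int or None
        Optional cap on M; larger inputs are subsampled with ``random_state``
        before the (M x M) distance matrix is formed.
    random_state : int
        Seed for the optional subsampling (HDBSCAN itself is deterministic).

    Attributes
    ----------
    labels_ : (M,) int array, −1 for noise
    n_clusters_ : int, noise excluded
    medoid_indices_ : dict cluster id -> row index into the fitted X
    sizes_ : dict cluster id -> member count
    """

    def __init__(
        self,
        min_cluster_size: Optional[int] = None,
        min_samples: Optional[int] = None,
        max_points: Optional[int] = None,
        random_state: int = 0,
    ):
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples
        self.max_points = max_points
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise InsufficientDataError("need a nonempty 2-D array of angles")
        m = X.shape[0]
        subsample = None
        if self.max_points is not None and m > self.max_points:
            rng = np.random.default_rng(self.random_state)
            subsample = np.sort(rng.choice(m, size=self.max_points, replace=False))
            X = X[subsample]
            m = X.shape[0]
        mcs = self.min_cluster_size or max(5, int(np.ceil(0.025 * m)))
        ms = self.min_samples or mcs
        if m < mcs:
            raise InsufficientDataError(
                f"insufficient data: {m} points < min_cluster_size {mcs}"
            )
        dist = pairwise_torus_distances(X)
        if np.allclose(dist, 0.0):
            # all points coincide on the torus: one cluster, no noise
            labels = np.zeros(m, dtype=int)
        else:
            labels = HDBSCAN(
                min_cluster_size=mcs,
                min_samples=ms,
                metric="precomputed",
                allow_single_cluster=True,
                copy=True,
            ).fit_predict(dist)
        self.labels_ = labels
        self.subsample_indices_ = subsample
        self.n_clusters_ = int(len(set(labels[labels >= 0])))
        self.sizes_ = {
            int(c): int(np.sum(labels == c)) for c in sorted(set(labels[labels >= 0]))
        }
        self.medoid_indices_ = _medoids_from_distances(dist, labels)
        self.fitted_params_ = {
            "min_cluster_size": mcs,
            "min_samples": ms,
            "max_points": self.max_points,
            "random_state": self.random_state,
        }
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _medoids_from_distances(dist: np.ndarray, labels: np.ndarray) -> dict[int, int]:
    medoids: dict[int, int] = {}
    for c in sorted(set(labels[labels >= 0])):
        members = np.flatnonzero(labels == c)
        totals = dist[np.ix_(members, members)].sum(axis=1)
        # argmin takes the first minimum, i.e. the lowest row index on ties
        medoids[int(c)] = int(members[int(np.argmin(totals))])
    return medoids


def cluster_fragments(
    points: TorsionPointSet,
    min_cluster_size: Optional[int] = None,
    min_samples: Optional[int] = None,
    max_points: Optional[int] = None,
    random_state: int = 0,
) -> ClusterResult:
    """Cluster a fragment point set (HDBSCAN, torus metric, medoids)."""
    est = TorusHDBSCAN(
        min_cluster_size=min_cluster_size,
        min_samples=min_samples,
        max_points=max_points,
        random_state=random_state,
    ).fit(points.points)
    return ClusterResult(
        labels=est.labels_,
        n_clusters=est.n_clusters_,
        medoid_indices=est.medoid_indices_,
        sizes=est.sizes_,
        n_noise=int(np.sum(est.labels_ == -1)),
        params=est.fitted_params_,
    )


def cluster_medoids(points: TorsionPointSet, result: ClusterResult) -> dict[int, int]:
    """Recompute medoids from a labelling: per cluster, the member with the
    lowest total torus distance to its co-members (ties to lowest index)."""
    dist = pairwise_torus_distances(points.points)
    return _medoids_from_distances(dist, result.labels)


def target_residue_index(k: int) -> int:
    """The residue whose conformation a k-mer query contextualises: the
    center for odd k, the first of the two central residues for even k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return (k - 1) // 2


def max_basin_combinations(k: int, basins_per_residue: int = 3) -> int:
    """Upper bound on joint conformational clusters for a k-mer when each
    residue occupies at most ``basins_per_residue`` Ramachandran basins."""
    if k < 1 or basins_per_residue < 1:
        raise ValueError("k and basins_per_residue must be >= 1")
    return basins_per_residue**k


@dataclass
class DensityGrid:
    """A KDE over the (phi, psi) torus on a regular grid.

    ``density[i, j]`` is the probability density at ``(phi_grid[i],
    psi_grid[j])``; cell areas sum the density to 1 over the torus.
    """

    phi_grid: np.ndarray
    psi_grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    @property
    def cell_area(self) -> float:
        return (360.0 / len(self.phi_grid)) ** 2

    def mode(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return float(self.phi_grid[i]), float(self.psi_grid[j])


def _circular_scott_bandwidth(samples: np.ndarray) -> float:
    """Scott's rule on wrapped deviations from the circular mean, per
    coordinate, averaged; floor keeps the kernel usable for tiny n."""
    n, d = samples.shape
    sds = []
    for j in range(d):
        rad = np.radians(samples[:, j])
        mean = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
        dev = np.abs(samples[:, j] - mean)
        dev = np.minimum(dev, 360.0 - dev)
        sds.append(np.sqrt(np.mean(dev**2)))
    sd = float(np.mean(sds))
    bw = sd * n ** (-1.0 / 6.0)   # Scott for 2-D
    return max(bw, 1.0)


def target_conditional_density(
    matches: Sequence[FragmentMatch],
    bandwidth: Optional[float] = None,
    grid_size: int = 72,
) -> DensityGrid:
    """Wrapped-Gaussian KDE of the target residue's (phi, psi) distribution
    conditioned on its sequence context (the matches' k-mer).

    The kernel is a Gaussian summed over ±360° image shifts in both
    coordinates, so mass wraps correctly across the ±180° seam; the grid
    density integrates to 1 over the torus.
    """
    if not matches:
        raise ValueError("no matches to estimate a density from")
    k = len(matches[0].kmer)
    if any(len(m.kmer) != k for m in matches):
        raise ValueError("all matches must share the same k")
    t = target_residue_index(k)
    samples = np.array(
        [m.angles[t] for m in matches if None not in m.angles[t]], dtype=float
    )
    if samples.size == 0:
        raise ValueError("no defined target-residue angle pairs")
    samples = wrap_degrees(samples)
    bw = bandwidth if bandwidth is not None else _circular_scott_bandwidth(samples)

    step = 360.0 / grid_size
    centers = -180.0 + step * (np.arange(grid_size) + 0.5)
    shifts = np.array([-360.0, 0.0, 360.0])

    def axis_kernel(grid: np.ndarray, vals: np.ndarray) -> np.ndarray:
        # (grid, n) matrix of wrapped 1-D Gaussian kernel values
        diff = grid[:, None, None] - (vals[None, :, None] + shifts[None, None, :])
        return np.exp(-0.5 * (diff / bw) ** 2).sum(axis=-1) / (bw * np.sqrt(2 * np.pi))

    kphi = axis_kernel(centers, samples[:, 0])
    kpsi = axis_kernel(centers, samples[:, 1])
    density = (kphi[:, None, :] * kpsi[None, :, :]).mean(axis=-1)
    # renormalise: truncation to +/-360 image shifts leaves <1e-9 mass out
    density /= density.sum() * step * step
    return DensityGrid(
        phi_grid=centers, psi_grid=centers, density=density, bandwidth=bw
    )
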