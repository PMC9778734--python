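"""RMSd superposition and the clustering protocols driving conformational bookkeeping.

Two clustering flavors are provided: greedy neighbor-counting (Gromos style)
under an RMSd cutoff with an occupancy-gated iterative seeding rule, and
k-means representatives in a supplied CV feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.cluster import KMeans

from .errors import GeometryError, ValidationError
from .series import CVSeries

__all__ = [
    "ConformationSet",
    "ClusterResult",
    "superpose",
    "rmsd_series",
    "gromos_cluster",
    "select_seed",
    "kmeans_representatives",
]


@dataclass
class ConformationSet:
    """Cartesian frames over a fixed atom selection."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray | None = None
    selection_label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValidationError("at least one frame required")
        if self.times is None:
            self.times = np.arange(self.coords.shape[0], dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape[0] != self.coords.shape[0]:
            raise ValidationError("one time per frame required")

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass
class ClusterResult:
    """Frame assignments with per-cluster centroids/representatives."""

    assignments: np.ndarray  # cluster id per frame, 0-based, discovery order
    centroids: list[int]  # frame index per cluster
    occupancies: np.ndarray  # percent of frames per cluster
    method: str
    parameter: float  # cutoff (Å) for gromos, k for kmeans

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.occupancies)) - 100.0) > 1e-9:
            raise ValidationError("occupancies must sum to 100%")
        for c, frame in enumerate(self.centroids):
            if self.assignments[frame] != c:
                raise ValidationError(f"centroid {frame} not member of cluster {c}")


def _checked_pair(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValidationError(f"shape mismatch {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValidationError("need >= 3 atoms with xyz coordinates")
    return mobile, reference


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Returns the transformed mobile frame and the minimal RMSd (Å).  The
    optimal proper rotation comes from the standard SVD/quaternion solution;
    reflections are never applied.  Degenerate (collinear) atom sets raise
    :class:`GeometryError`.
    """
    mobile, reference = _checked_pair(mobile, reference)
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    m0, r0 = mobile - mc, reference - rc
    if np.linalg.matrix_rank(m0, tol=1e-10) < 2 or np.linalg.matrix_rank(r0, tol=1e-10) < 2:
        raise GeometryError("degenerate atom set: collinear or coincident points")
    rot, rssd = Rotation.align_vectors(r0, m0)
    fitted = rot.apply(m0) + rc
    return fitted, float(rssd) / np.sqrt(mobile.shape[0])


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def rmsd_series(conformations: ConformationSet, reference: np.ndarray,
                fit: bool = True) -> np.ndarray:
    """Per-frame RMSd to a reference, optionally after superposition."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape != conformations.coords.shape[1:]:
        raise ValidationError("reference atom count differs from the set")
    out = np.empty(len(conformations))
    for i, frame in enumerate(conformations.coords):
        if fit:
            _, out[i] = superpose(frame, reference)
        else:
            out[i] = _rmsd(frame, reference)
    return out


def _pairwise_rmsd(conformations: ConformationSet, fit: bool) -> np.ndarray:
    n = len(conformations)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if fit:
                _, r = superpose(conformations.coords[j], conformations.coords[i])
            else:
                r = _rmsd(conformations.coords[j], conformations.coords[i])
            d[i, j] = d[j, i] = r
    return d


def gromos_cluster(conformations: ConformationSet, cutoff: float,
                   fit: bool = True) -> ClusterResult:
    """Greedy neighbor-counting clustering under an RMSd cutoff.

    Repeatedly promote the frame with the most unassigned neighbors within
    ``cutoff`` to centroid, assign it and its neighbors to a new cluster, and
    remove them.  Ties in neighbor count break toward the lower frame index,
    making the result deterministic.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    n = len(conformations)
    d = _pairwise_rmsd(conformations, fit)
    within = d <= cutoff

    assignments = np.full(n, -1, dtype=int)
    centroids: list[int] = []
    remaining = np.ones(n, dtype=bool)
    cluster = 0
    while np.any(remaining):
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        centroid = int(np.argmax(counts))  # argmax takes the first = lowest index on ties
        members = np.flatnonzero(within[centroid] & remaining)
        assignments[members] = cluster
        centroids.append(centroid)
        remaining[members] = False
        cluster += 1
    occupancies = np.array([
        100.0 * np.count_nonzero(assignments == c) / n for c in range(cluster)
    ])
    return ClusterResult(assignments=assignments, centroids=centroids,
                         occupancies=occupancies, method="gromos", parameter=cutoff)


def select_seed(result: ClusterResult, conformations: ConformationSet,
                start_frame: np.ndarray, occupancy_min: float = 10.0,
                fit: bool = True) -> int | None:
    """Seeding rule for iterative resampling rounds.

    Among clusters with occupancy strictly above ``occupancy_min`` percent,
    return the centroid frame index with the largest (fitted) RMSd to the
    starting structure; ``None`` when no cluster qualifies.
    """
    start_frame = np.asarray(start_frame, dtype=float)
    if start_frame.shape != conformations.coords.shape[1:]:
        raise ValidationError("start frame incompatible with the conformation set")
    best, best_rmsd = None, -1.0
    for c, centroid in enumerate(result.centroids):
        if result.occupancies[c] <= occupancy_min:
            continue
        frame = conformations.coords[centroid]
        r = superpose(frame, start_frame)[1] if fit else _rmsd(frame, start_frame)
        if r > best_rmsd:
            best, best_rmsd = centroid, r
    return best


def kmeans_representatives(samples, k: int, seed: int = 0) -> ClusterResult:
    """Lloyd k-means in CV feature space with nearest-to-mean representatives.

    ``samples`` is a CVSeries or an (n, k_features) array.  Initialisation is
    seeded k-means++, so a fixed seed gives identical results across runs.
    Clusters are relabelled by decreasing size; the representative of each
    cluster is the member sample closest to its mean.
    """
    if isinstance(samples, CVSeries):
        x = samples.values
    else:
        x = np.asarray(samples, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > x.shape[0]:
        raise ValidationError(f"k={k} exceeds {x.shape[0]} samples")

    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(x)
    raw = km.labels_
    sizes = np.array([np.count_nonzero(raw == c) for c in range(k)])
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    assignments = relabel[raw]

    centroids: list[int] = []
    for c in range(k):
        members = np.flatnonzero(assignments == c)
        center = km.cluster_centers_[order[c]]
        centroids.append(int(members[np.argmin(
            np.linalg.norm(x[members] - center, axis=1))]))
    occupancies = np.array([
        100.0 * np.count_nonzero(assignments == c) / x.shape[0] for c in range(k)
    ])
    return ClusterResult(assignments=assignments, centroids=centroids,
                         occupancies=occupancies, method="kmeans", parameter=float(k))
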