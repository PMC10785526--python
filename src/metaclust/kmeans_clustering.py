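"""K-means over feature vectors with automatic selection of k.

The variant implemented here initializes centers uniformly at random within
the global value range of the data, assigns each row to the center with the
smallest summed pointwise distance, recomputes centers as positionwise means,
and iterates until assignments stabilize.  k grows from 1 until the total
distance fails to improve by more than a relative threshold (default 20%),
at which point the previous k is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from metaclust.metagene_core import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.20
DEFAULT_K_MAX = 10
DEFAULT_RESTARTS = 5
DEFAULT_MAX_ITER = 300
DEFAULT_SEED = 1337


@dataclass
class ClusterModel:
    """A fitted k-means model: centers, assignments and the final objective."""

    k: int
    centers: np.ndarray
    assignments: np.ndarray
    total_distance: float
    n_iter: int = 0
    # objective after each assignment step; non-increasing in squared mode
    objective_history: list[float] = field(default_factory=list)

    def member_counts(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


@dataclass
class KSelectionTrace:
    """(k, D(k), relative improvement) for every k tried, k consecutive from 1."""

    entries: list[tuple[int, float, float | None]] = field(default_factory=list)

    def distances(self) -> list[float]:
        return [d for _, d, _ in self.entries]


def _pointwise_distances(rows: np.ndarray, centers: np.ndarray, distance: str) -> np.ndarray:
    diff = rows[:, None, :] - centers[None, :, :]
    if distance == "squared":
        return np.einsum("ikl,ikl->ik", diff, diff)
    if distance == "absolute":
        return np.abs(diff).sum(axis=2)
    raise ValueError(f"unknown distance mode {distance!r}")


def init_centers(matrix: FeatureMatrix, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw k centers with every value uniform in [global min, global max]."""
    if k < 1:
        raise ValueError("k must be >= 1")
    lo = float(matrix.rows.min())
    hi = float(matrix.rows.max())
    return rng.uniform(lo, hi, size=(k, matrix.L))


def assign(
    matrix: FeatureMatrix, centers: np.ndarray, *, distance: str = "squared"
) -> tuple[np.ndarray, float]:
    """Assign each row to its nearest center; ties break toward the lowest index.

    Returns (assignments, total_distance).
    """
    dists = _pointwise_distances(matrix.rows, centers, distance)
    assignments = np.argmin(dists, axis=1)
    total = float(dists[np.arange(matrix.n), assignments].sum())
    return assignments, total


def update_centers(
    matrix: FeatureMatrix,
    assignments: np.ndarray,
    k: int,
    rng: np.random.Generator,
    *,
    distance: str = "squared",
) -> np.ndarray:
    """Recompute each center as the positionwise mean of its member rows.

    An empty cluster is reseeded to the single row farthest from its
    currently assigned center (that row leaves its donor cluster, whose mean
    is recomputed); if no cluster can spare a row, the center falls back to
    random-in-range.
    """
    rows = matrix.rows
    work = np.asarray(assignments).copy()
    centers = np.zeros((k, rows.shape[1]))
    counts = np.bincount(work, minlength=k)
    for c in np.flatnonzero(counts):
        centers[c] = rows[work == c].mean(axis=0)
    for c in np.flatnonzero(counts == 0):
        donors = np.flatnonzero(counts[work] > 1)
        if donors.size == 0:
            centers[c] = init_centers(matrix, 1, rng)[0]
            continue
        own = _pointwise_distances(rows[donors], centers[work[donors]], distance)
        far = donors[int(np.argmax(np.diagonal(own)))]
        donor_cluster = work[far]
        centers[c] = rows[far]
        work[far] = c
        counts[donor_cluster] -= 1
        counts[c] += 1
        centers[donor_cluster] = rows[work == donor_cluster].mean(axis=0)
    return centers


def run_kmeans(
    matrix: FeatureMatrix,
    k: int,
    rng: np.random.Generator,
    max_iter: int = DEFAULT_MAX_ITER,
    *,
    distance: str = "squared",
    init: np.ndarray | None = None,
) -> ClusterModel:
    """Alternate assignment and center updates until assignments stabilize.

    Stops when two consecutive assignment steps agree or after max_iter
    iterations, returning the model with its recomputed total distance.
    """
    if not 1 <= k <= matrix.n:
        raise ValueError(f"k={k} must be in [1, n={matrix.n}]")
    centers = init_centers(matrix, k, rng) if init is None else np.array(init, dtype=float)
    prev: np.ndarray | None = None
    history: list[float] = []
    assignments = np.zeros(matrix.n, dtype=int)
    total = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        assignments, total = assign(matrix, centers, distance=distance)
        history.append(total)
        if prev is not None and np.array_equal(prev, assignments):
            converged = True
            break
        prev = assignments
        centers = update_centers(matrix, assignments, k, rng, distance=distance)
    if not converged:
        # sync assignments with the last center update
        assignments, total = assign(matrix, centers, distance=distance)
        history.append(total)
    return ClusterModel(
        k=k,
        centers=centers,
        assignments=assignments,
        total_distance=total,
        n_iter=n_iter,
        objective_history=history,
    )


def choose_k(distances: list[float], threshold: float = DEFAULT_THRESHOLD) -> int:
    """Apply the stopping rule to a D(1), D(2), ... sequence and return k.

    Stops at the first k >= 2 whose relative improvement
    (D(k-1) - D(k)) / D(k-1) is <= threshold, selecting k-1; a zero
    objective selects its own k immediately.  If the rule never fires the
    last k in the sequence is returned.
    """
    if not distances:
        raise ValueError("empty distance sequence")
    if distances[0] == 0.0:
        return 1
    for k, (d_prev, d_cur) in enumerate(zip(distances, distances[1:]), start=2):
        improvement = (d_prev - d_cur) / d_prev
        if improvement <= threshold:
            return k - 1
        if d_cur == 0.0:
            return k
    return len(distances)


def _best_of_restarts(
    matrix: FeatureMatrix,
    k: int,
    rng: np.random.Generator,
    restarts: int,
    max_iter: int,
    distance: str,
    warm_centers: np.ndarray | None,
) -> ClusterModel:
    best: ClusterModel | None = None
    for _ in range(restarts):
        model = run_kmeans(matrix, k, rng, max_iter, distance=distance)
        if best is None or model.total_distance < best.total_distance:
            best = model
    if warm_centers is not None:
        model = run_kmeans(matrix, k, rng, max_iter, distance=distance, init=warm_centers)
        if model.total_distance < best.total_distance:
            best = model
    return best


def _warm_start_centers(
    matrix: FeatureMatrix, model: ClusterModel, distance: str
) -> np.ndarray:
    """Previous best centers plus the row farthest from its assigned center."""
    own = _pointwise_distances(matrix.rows, model.centers, distance)
    per_row = own[np.arange(matrix.n), model.assignments]
    far = matrix.rows[int(np.argmax(per_row))]
    return np.vstack([model.centers, far[None, :]])


def select_k(
    matrix: FeatureMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    rng: np.random.Generator | None = None,
    k_max: int = DEFAULT_K_MAX,
    restarts: int = DEFAULT_RESTARTS,
    *,
    max_iter: int = DEFAULT_MAX_ITER,
    distance: str = "squared",
) -> tuple[ClusterModel, KSelectionTrace]:
    """Grow k from 1 until the total distance stops improving enough.

    For each k the best of `restarts` random initializations is kept,
    plus one warm start seeded from the previous best model (which makes
    D(k) non-increasing in k).  Stops at the first k >= 2 whose relative
    improvement is <= threshold, returning the k-1 model; a zero objective
    returns immediately; hitting k_max returns the k_max model with a
    warning.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if rng is None:
        rng = np.random.default_rng(DEFAULT_SEED)
    trace = KSelectionTrace()
    prev_model: ClusterModel | None = None
    k_cap = min(k_max, matrix.n)
    for k in range(1, k_cap + 1):
        warm = (
            _warm_start_centers(matrix, prev_model, distance)
            if prev_model is not None
            else None
        )
        model = _best_of_restarts(matrix, k, rng, restarts, max_iter, distance, warm)
        d = model.total_distance
        if k == 1:
            trace.entries.append((1, d, None))
            if d == 0.0:
                logger.info("D(1) = 0, all rows identical: selected k = 1")
                return model, trace
        else:
            improvement = (prev_model.total_distance - d) / prev_model.total_distance
            trace.entries.append((k, d, improvement))
            if improvement <= threshold:
                logger.info(
                    "k = %d improves by %.1f%% <= %.1f%%: selected k = %d",
                    k, 100 * improvement, 100 * threshold, k - 1,
                )
                return prev_model, trace
            if d == 0.0:
                logger.info("D(%d) = 0: selected k = %d", k, k)
                return model, trace
        prev_model = model
    logger.warning("k selection hit the cap k_max = %d without stopping", k_cap)
    return prev_model, trace
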