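"""Brain-state identification: L1 k-means over windowed FC and ranking of the
resulting states by their similarity to the structural connectome.

The windows from all conditions and sessions are pooled, each Fisher-z matrix
is vectorized to its strict upper triangle, and the pooled feature matrix is
clustered under the Manhattan (L1) metric with a component-wise median
centroid update (k-medians), the update consistent with the L1 objective.
Cluster centroids are then scored by the Pearson correlation of their upper
triangle with the structural weights, and states are relabeled 1..k in
ascending similarity: state k is the most structure-like (the anesthesia
signature), state 1 the least.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dynamic_fc import FCWindowStack
from .synthetic import StructuralConnectome

try:  # optional JIT for the L1 distance kernel; NumPy fallback below
    from numba import njit

    @njit(cache=False, fastmath=True)
    def _l1_dist_kernel(x, c, out):  # pragma: no cover - exercised via wrapper
        n, d = x.shape
        k = c.shape[0]
        for i in range(n):
            for j in range(k):
                s = 0.0
                for t in range(d):
                    s += abs(x[i, t] - c[j, t])
                out[i, j] = s

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _l1_distances(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Pairwise cityblock distances between rows of x and rows of c."""
    out = np.empty((x.shape[0], c.shape[0]), dtype=x.dtype)
    if _HAVE_NUMBA:
        _l1_dist_kernel(x, np.ascontiguousarray(c), out)
        return out
    for j in range(c.shape[0]):
        out[:, j] = np.abs(x - c[j]).sum(axis=1)
    return out

__all__ = [
    "KMeansModel",
    "BrainStateSet",
    "vectorize_fc",
    "devectorize_fc",
    "pool_stacks",
    "kmeans_l1",
    "structure_similarity",
    "rank_states",
]


@dataclass
class KMeansModel:
    """Fitted L1 k-means model.

    ``labels`` are 1-based raw cluster indices over the pooled window rows;
    ``inertia`` is the total L1 deviation of rows from their centroids.
    """

    centroids: np.ndarray  # k x d
    labels: np.ndarray  # 1-based
    inertia: float
    n_init: int
    max_iter: int
    tol: float
    seed: int | None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


@dataclass
class BrainStateSet:
    """Similarity-ranked brain states with per-session label sequences.

    ``state_matrices[i]`` is the centroid of state i+1; states are ordered by
    ascending structure-function similarity, so ``state_matrices[-1]`` (state
    k) is the most anatomy-like. ``label_sequences`` maps (condition,
    session_id) to the 1-based window-state sequence in original window order.
    """

    state_matrices: np.ndarray  # k x n_rois x n_rois
    similarity: np.ndarray  # ascending
    rank_order: np.ndarray  # raw cluster index (0-based) per ranked state
    label_sequences: dict[tuple[str, str], np.ndarray]

    @property
    def k(self) -> int:
        return self.state_matrices.shape[0]


# ---------------------------------------------------------------------------
# vectorization
# ---------------------------------------------------------------------------

def vectorize_fc(stack: FCWindowStack | np.ndarray) -> np.ndarray:
    """Strict upper triangle of each window matrix, row-major pair order."""
    z = stack.z if isinstance(stack, FCWindowStack) else np.asarray(stack)
    single = z.ndim == 2
    if single:
        z = z[None]
    n = z.shape[1]
    iu = np.triu_indices(n, k=1)
    x = z[:, iu[0], iu[1]]
    return x[0] if single else x


def devectorize_fc(x: np.ndarray, n_rois: int) -> np.ndarray:
    """Inverse of :func:`vectorize_fc`; rebuilds symmetric zero-diagonal matrices."""
    x = np.asarray(x)
    single = x.ndim == 1
    if single:
        x = x[None]
    iu = np.triu_indices(n_rois, k=1)
    out = np.zeros((x.shape[0], n_rois, n_rois))
    out[:, iu[0], iu[1]] = x
    out += out.transpose(0, 2, 1)
    return out[0] if single else out


def pool_stacks(stacks: list[FCWindowStack]) -> tuple[np.ndarray, list[tuple[str, str, int]]]:
    """Concatenate vectorized stacks; returns (X, [(condition, session, n_windows)])."""
    xs = [vectorize_fc(s) for s in stacks]
    index = [(s.condition, s.session_id, s.n_windows) for s in stacks]
    return np.vstack(xs), index


# ---------------------------------------------------------------------------
# L1 k-means (k-medians)
# ---------------------------------------------------------------------------

def _plusplus_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy k-means++-style seeding under the L1 metric.

    Each new seed is drawn from several candidates sampled with probability
    proportional to the current minimum distance; the candidate that most
    reduces the seeding potential is kept (the greedy variant is markedly
    more reliable when within-cluster spread dominates between-cluster
    separation, as it does for windowed-FC features).
    """
    n = x.shape[0]
    n_cand = 2 + int(np.log(k)) if k > 1 else 1
    centroids = np.empty((k, x.shape[1]), dtype=x.dtype)
    centroids[0] = x[rng.integers(n)]
    dmin = _l1_distances(x, centroids[:1]).ravel()
    for j in range(1, k):
        total = dmin.sum()
        if total <= 0:
            cands = rng.integers(n, size=n_cand)
        else:
            cands = rng.choice(n, size=n_cand, p=dmin / total)
        best_c, best_pot, best_d = None, np.inf, None
        for c in np.atleast_1d(cands):
            dc = _l1_distances(x, x[c : c + 1]).ravel()
            pot = np.minimum(dmin, dc).sum()
            if pot < best_pot:
                best_c, best_pot, best_d = c, pot, dc
        centroids[j] = x[best_c]
        dmin = np.minimum(dmin, best_d)
    return centroids


def _lloyd_l1(
    x: np.ndarray, centroids: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float]:
    k = centroids.shape[0]
    n = x.shape[0]
    prev_inertia = np.inf
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d = _l1_distances(x, centroids)
        labels = d.argmin(axis=1)
        # empty-cluster repair: seed with the point farthest from its centroid
        for j in range(k):
            if not (labels == j).any():
                far = d[np.arange(n), labels].argmax()
                centroids[j] = x[far]
                labels[far] = j
                d[:, j] = _l1_distances(x, centroids[j : j + 1]).ravel()
        inertia = d[np.arange(n), labels].sum(dtype=np.float64)
        if np.isfinite(prev_inertia):
            if inertia > prev_inertia * (1 + 1e-6) + 1e-8:
                raise AssertionError("L1 inertia increased across Lloyd iterations")
            if prev_inertia - inertia <= tol * max(prev_inertia, 1e-12):
                prev_inertia = inertia
                break
        prev_inertia = inertia
        for j in range(k):
            centroids[j] = np.median(x[labels == j], axis=0)
    # final consistent assignment
    d = _l1_distances(x, centroids)
    labels = d.argmin(axis=1)
    inertia = d[np.arange(n), labels].sum(dtype=np.float64)
    return centroids, labels, float(inertia)


def kmeans_l1(
    x: np.ndarray,
    k: int = 7,
    n_init: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
    init: str = "auto",
    n_components: int = 20,
) -> KMeansModel:
    """Cluster rows of ``x`` under the Manhattan metric (k-medians).

    Lloyd-style alternation of L1 nearest-centroid assignment and
    component-wise median centroid updates; empty clusters are reseeded with
    the point farthest from its assigned centroid, and the total L1 deviation
    is asserted nonincreasing across iterations. Deterministic given
    ``seed``.

    Initialization (``init``):

    * ``"++"`` — ``n_init`` restarts from greedy L1 k-means++ seedings with
      distinct sub-seeds, each refined by full-data Lloyd; best inertia kept.
    * ``"pca"`` — the restarts run in a low-rank PCA subspace (top
      ``n_components`` components) where the cluster structure of windowed-FC
      features is far better conditioned; the best subspace partition then
      seeds a single full-feature L1 Lloyd refinement via component-wise
      medians. For high-dimensional window stacks point-based seedings are
      swamped by estimation noise and systematically miss the deepest basin,
      which is why this is the default there.
    * ``"auto"`` — ``"pca"`` when the problem is high-dimensional (more than
      500 rows and more than 100 features), else ``"++"``.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("x must be a 2-D feature matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    if x.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {x.shape[0]}")
    if init not in ("auto", "++", "pca"):
        raise ValueError("init must be 'auto', '++' or 'pca'")
    if init == "auto":
        init = "pca" if (x.shape[0] > 500 and x.shape[1] > 100) else "++"

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    if init == "pca":
        from scipy.sparse.linalg import svds

        r = min(n_components, x.shape[1] - 1, x.shape[0] - 1)
        xc = x - x.mean(axis=0)
        # top right-singular vectors; fixed start vector keeps ARPACK deterministic
        _, _, vt = svds(xc, k=r, v0=np.ones(min(xc.shape)))
        proj = np.ascontiguousarray(xc @ vt.T)
        # many cheap subspace restarts; the subspace L1 inertia ranks basins
        # faithfully, so only the few best candidates need full refinement
        n_restarts = max(n_init, 60)
        candidates: list[tuple[float, np.ndarray]] = []
        for ss in np.random.SeedSequence(seed).spawn(n_restarts):
            rng = np.random.default_rng(ss)
            c0 = _plusplus_init(proj, k, rng)
            _, lab, inert = _lloyd_l1(proj, c0, max_iter, tol)
            candidates.append((inert, lab.copy()))
        candidates.sort(key=lambda t: t[0])
        gmed = np.median(x, axis=0)
        refined: set[bytes] = set()
        for inert_sub, lab_sub in candidates:
            key = lab_sub.tobytes()
            if key in refined:
                continue
            refined.add(key)
            centroids = np.stack(
                [
                    np.median(x[lab_sub == j], axis=0)
                    if (lab_sub == j).any()
                    else x[_l1_distances(x, gmed[None]).ravel().argmax()]
                    for j in range(k)
                ]
            )
            centroids, labels, inertia = _lloyd_l1(x, centroids, max_iter, tol)
            if best is None or inertia < best[0]:
                best = (inertia, centroids.copy(), labels.copy())
            if len(refined) >= 3:
                break
    else:
        for ss in np.random.SeedSequence(seed).spawn(n_init):
            rng = np.random.default_rng(ss)
            centroids = _plusplus_init(x, k, rng)
            centroids, labels, inertia = _lloyd_l1(x, centroids, max_iter, tol)
            if best is None or inertia < best[0]:
                best = (inertia, centroids.copy(), labels.copy())

    inertia, centroids, labels = best
    return KMeansModel(
        centroids=centroids,
        labels=labels + 1,
        inertia=float(inertia),
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# structure-function similarity and ranking
# ---------------------------------------------------------------------------

def structure_similarity(
    state_matrix: np.ndarray, sc: StructuralConnectome
) -> float:
    """Pearson correlation between a state's FC pattern and the structure.

    Both the state matrix and the structural weights are reduced to their
    strict upper triangles (structural zeros retained) before correlating.
    A constant state matrix yields similarity 0 with a warning.
    """
    state_matrix = np.asarray(state_matrix)
    if state_matrix.shape != sc.weights.shape:
        raise ValueError("state matrix and structural weights must share ROI order")
    iu = np.triu_indices(sc.n_rois, k=1)
    a = state_matrix[iu]
    b = sc.weights[iu]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant matrix in similarity; returning 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def rank_states(
    model: KMeansModel,
    sc: StructuralConnectome,
    stack_index: list[tuple[str, str, int]],
) -> BrainStateSet:
    """Relabel clusters 1..k by ascending structure-function similarity.

    ``stack_index`` is the (condition, session_id, n_windows) bookkeeping from
    :func:`pool_stacks`, in the row order the model was fitted on; the pooled
    label vector is split back into per-session sequences accordingly.

    Ties in similarity are broken by cluster size (larger cluster ranked
    lower, i.e. less structure-like), logged via a warning.
    """
    k = model.k
    matrices = devectorize_fc(model.centroids, sc.n_rois)
    sims = np.array([structure_similarity(m, sc) for m in matrices])
    sizes = np.bincount(model.labels - 1, minlength=k)
    if np.unique(sims).size < k:
        warnings.warn("tied similarities; breaking ties by cluster size", stacklevel=2)
    # ascending similarity; ties: larger cluster first
    order = np.lexsort((-sizes, sims))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    new_labels = relabel[model.labels - 1]

    total = sum(n for _, _, n in stack_index)
    if total != new_labels.size:
        raise ValueError("stack index does not match the fitted window count")
    sequences: dict[tuple[str, str], np.ndarray] = {}
    pos = 0
    for cond, sess, n in stack_index:
        sequences[(cond, sess)] = new_labels[pos : pos + n]
        pos += n

    return BrainStateSet(
        state_matrices=matrices[order],
        similarity=sims[order],
        rank_order=order,
        label_sequences=sequences,
    )
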