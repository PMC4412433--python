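"""Deterministic clustering backends over time-concentration curves.

Three reproducible algorithms, all on Euclidean distance and all yielding
exactly ``k`` clusters:

* ``hier`` — agglomerative hierarchical clustering (average linkage), tree
  cut at ``k`` (scipy);
* ``ncut`` — normalized-cut spectral clustering by recursive two-way cuts
  of a Gaussian similarity graph, splitting at each step the cluster whose
  best split has the smallest normalized-cut value;
* ``fastap`` — affinity propagation with similarity = negative squared
  Euclidean distance, the shared preference tuned by bisection until
  exactly ``k`` exemplars emerge.

Unlike k-means or fuzzy c-means, none of these depends on random
initialization: repeated runs on identical input give bit-identical
partitions, and input reordering changes labels only up to renaming.
Clusters are canonically relabeled by ascending smallest member index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .phantom import CurveSet

__all__ = [
    "ClusterConfig",
    "ClusterResult",
    "ClusteringError",
    "cluster_hier",
    "cluster_ncut",
    "cluster_fastap",
    "cluster_curves",
]


class ClusteringError(RuntimeError):
    pass


@dataclass(frozen=True)
class ClusterConfig:
    method: str = "ncut"
    k: int = 5
    ncut_sigma_percentile: float = 20.0  # similarity bandwidth rule
    hier_linkage: str = "average"
    ap_damping: float = 0.9
    ap_max_iter: int = 1000
    ap_conv_iter: int = 100
    seed: int = 0  # reserved; no backend currently draws random numbers

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.5 <= self.ap_damping < 1.0:
            raise ValueError("ap_damping must lie in [0.5, 1)")
        if self.method not in ("ncut", "hier", "fastap"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class ClusterResult:
    labels: np.ndarray       # per-curve cluster id in 0..k-1
    mean_curves: np.ndarray  # k x n_frames
    sizes: np.ndarray        # per-cluster member counts

    @property
    def k(self) -> int:
        return self.mean_curves.shape[0]

    def members(self, j: int) -> np.ndarray:
        return np.nonzero(self.labels == j)[0]


def _as_matrix(curves) -> np.ndarray:
    if isinstance(curves, CurveSet):
        return curves.values
    return np.atleast_2d(np.asarray(curves, dtype=float))


def _finalize(X: np.ndarray, raw_labels: np.ndarray, k: int) -> ClusterResult:
    """Canonical relabeling (ascending smallest member index) + means."""
    raw_labels = np.asarray(raw_labels)
    uniq = list(dict.fromkeys(raw_labels.tolist()))  # order of first occurrence
    if len(uniq) != k:
        raise ClusteringError(f"expected {k} clusters, got {len(uniq)}")
    remap = {u: j for j, u in enumerate(uniq)}
    labels = np.array([remap[u] for u in raw_labels.tolist()], dtype=int)
    means = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
    sizes = np.bincount(labels, minlength=k)
    if np.any(sizes == 0):
        raise ClusteringError("empty cluster")
    return ClusterResult(labels=labels, mean_curves=means, sizes=sizes)


def _check_n(X: np.ndarray, k: int) -> None:
    if X.shape[0] < k:
        raise ClusteringError(f"need at least k={k} curves, got {X.shape[0]}")


# ----------------------------------------------------------------- hier --

def cluster_hier(curves, cfg: ClusterConfig | None = None) -> ClusterResult:
    """Agglomerative hierarchy on Euclidean distances, cut at k clusters."""
    cfg = cfg or ClusterConfig(method="hier")
    X = _as_matrix(curves)
    _check_n(X, cfg.k)
    Z = hierarchy.linkage(X, method=cfg.hier_linkage, metric="euclidean")
    raw = hierarchy.cut_tree(Z, n_clusters=cfg.k).ravel()
    return _finalize(X, raw, cfg.k)


# ----------------------------------------------------------------- ncut --

def ncut_value(W: np.ndarray, mask: np.ndarray) -> float:
    """Normalized-cut value of the bipartition (mask, ~mask) of graph W."""
    d = W.sum(axis=1)
    cut = W[np.ix_(mask, ~mask)].sum()
    assoc_a, assoc_b = d[mask].sum(), d[~mask].sum()
    if assoc_a == 0 or assoc_b == 0:
        return np.inf
    return float(cut / assoc_a + cut / assoc_b)


def _best_bipartition(W: np.ndarray):
    """Best two-way normalized cut of (sub)graph W.

    The second-smallest eigenvector of the symmetric normalized Laplacian is
    swept over all threshold positions; cut and association terms are
    updated incrementally (O(n^2) total).  Returns (ncut value, boolean mask
    of side A) or (inf, None) if no split exists.
    """
    n = W.shape[0]
    if n < 2:
        return np.inf, None
    d = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    lsym = -(W * inv_sqrt[:, None]) * inv_sqrt[None, :]
    np.fill_diagonal(lsym, lsym.diagonal() + 1.0)
    vals, vecs = linalg.eigh(lsym, subset_by_index=(0, min(1, n - 1)))
    v = vecs[:, -1] * inv_sqrt
    # deterministic sign: first nonzero component positive
    nz = np.nonzero(v)[0]
    if nz.size and v[nz[0]] < 0:
        v = -v
    order = np.argsort(v, kind="stable")
    total = d.sum()
    cut = 0.0
    acc = np.zeros(n)          # acc[j] = sum of W[j, A] over current side A
    assoc_a = 0.0
    best = (np.inf, -1)
    for m in range(n - 1):
        u = order[m]
        cut += d[u] - W[u, u] - 2.0 * acc[u]
        acc += W[:, u]
        assoc_a += d[u]
        assoc_b = total - assoc_a
        if v[order[m + 1]] == v[u]:
            continue  # threshold must separate distinct eigenvector values
        if assoc_a <= 0 or assoc_b <= 0:
            continue
        val = cut / assoc_a + cut / assoc_b
        if val < best[0]:
            best = (val, m)
    if best[1] < 0:
        return np.inf, None
    mask = np.zeros(n, dtype=bool)
    mask[order[: best[1] + 1]] = True
    return best[0], mask


def cluster_ncut(curves, cfg: ClusterConfig | None = None) -> ClusterResult:
    """Recursive two-way normalized cuts until exactly k clusters exist.

    Similarity ``w_ij = exp(-d_ij^2 / sigma^2)`` with ``sigma`` the
    configured percentile of pairwise Euclidean distances.  At each step the
    cluster whose best split has the smallest normalized-cut value is split
    (ties: the cluster containing the lowest curve index).
    """
    cfg = cfg or ClusterConfig(method="ncut")
    X = _as_matrix(curves)
    _check_n(X, cfg.k)
    dists = pdist(X)
    sigma = float(np.percentile(dists, cfg.ncut_sigma_percentile))
    if sigma <= 0:
        raise ClusteringError("degenerate similarity: identical curves")
    W = np.exp(-(squareform(dists) / sigma) ** 2)
    np.fill_diagonal(W, 1.0)

    clusters: list[np.ndarray] = [np.arange(X.shape[0])]
    splits: list[tuple[float, np.ndarray | None]] = [
        _best_bipartition(W)]
    while len(clusters) < cfg.k:
        vals = [s[0] for s in splits]
        best = int(np.argmin(vals))  # argmin keeps the first (lowest-index) tie
        val, mask = splits[best]
        if not np.isfinite(val) or mask is None:
            raise ClusteringError(
                f"cannot reach k={cfg.k}: only {len(clusters)} separable clusters")
        idx = clusters[best]
        a, b = idx[mask], idx[~mask]
        clusters[best: best + 1] = [a, b]
        splits[best: best + 1] = [_best_bipartition(W[np.ix_(a, a)]),
                                  _best_bipartition(W[np.ix_(b, b)])]
    raw = np.empty(X.shape[0], dtype=int)
    for j, idx in enumerate(clusters):
        raw[idx] = j
    return _finalize(X, raw, cfg.k)


# --------------------------------------------------------------- fastap --

def _ap_exemplars(S: np.ndarray, preference: float, damping: float,
                  max_iter: int, conv_iter: int) -> np.ndarray:
    """Deterministic affinity propagation; returns exemplar indices."""
    n = S.shape[0]
    S = S.copy()
    np.fill_diagonal(S, preference)
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    last = None
    for _ in range(max_iter):
        # responsibilities
        AS = A + S
        first = AS.max(axis=1)
        am = AS.argmax(axis=1)
        AS[idx, am] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - first[:, None]
        Rnew[idx, am] = S[idx, am] - second
        R = damping * R + (1.0 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, R.diagonal())
        col = Rp.sum(axis=0)
        Anew = np.minimum(0.0, col[None, :] - Rp)
        np.fill_diagonal(Anew, col - Rp.diagonal())
        A = damping * A + (1.0 - damping) * Anew
        ex = np.nonzero(A.diagonal() + R.diagonal() > 0)[0]
        if last is not None and ex.size == last.size and np.array_equal(ex, last):
            stable += 1
            if stable >= conv_iter:
                break
        else:
            stable = 0
        last = ex
    return np.nonzero(A.diagonal() + R.diagonal() > 0)[0]


def cluster_fastap(curves, cfg: ClusterConfig | None = None) -> ClusterResult:
    """Affinity propagation with the shared preference bisected until exactly
    k exemplars result; points are assigned to their most similar exemplar."""
    cfg = cfg or ClusterConfig(method="fastap")
    X = _as_matrix(curves)
    _check_n(X, cfg.k)
    # exact duplicate rows make the message passing oscillate on ties; run
    # the search on unique rows and map duplicates to their representative
    U, inverse = np.unique(X, axis=0, return_inverse=True)
    n = U.shape[0]
    if n < cfg.k:
        raise ClusteringError(
            f"only {n} distinct curves; cannot form k={cfg.k} clusters")
    S = -squareform(pdist(U, metric="sqeuclidean"))

    def search(damping: float):
        def count(pref: float) -> tuple[int, np.ndarray]:
            ex = _ap_exemplars(S, pref, damping, cfg.ap_max_iter, cfg.ap_conv_iter)
            return ex.size, ex

        off = S[~np.eye(n, dtype=bool)]
        lo = 2.0 * float(off.min()) - 1.0   # very negative -> few exemplars
        hi = 0.0                            # self-similarity dominates -> n exemplars
        k_lo, ex = count(lo)
        for _ in range(30):
            if k_lo <= cfg.k:
                break
            lo *= 4.0
            k_lo, ex = count(lo)
        if k_lo == cfg.k:
            return ex, None
        k_hi, ex_hi = count(hi)
        if k_hi == cfg.k:
            return ex_hi, None
        if not (k_lo < cfg.k < k_hi):
            return None, (min(k_lo, k_hi), max(k_lo, k_hi))
        nearest = (k_lo, k_hi)
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            k_mid, ex_mid = count(mid)
            if k_mid == cfg.k:
                return ex_mid, None
            if k_mid < cfg.k:
                lo, nearest = mid, (max(k_mid, nearest[0]), nearest[1])
            else:
                hi, nearest = mid, (nearest[0], min(k_mid, nearest[1]))
        return None, nearest

    # the cluster count can jump past k at one damping level; retry on a
    # deterministic damping ladder before giving up
    ladder = [cfg.ap_damping] + [d for d in (0.95, 0.85, 0.8, 0.92, 0.88, 0.75)
                                 if abs(d - cfg.ap_damping) > 1e-9]
    nearest = None
    exemplars = None
    for damping in ladder:
        exemplars, nearest = search(damping)
        if exemplars is not None:
            break
    if exemplars is None:
        raise ClusteringError(
            f"preference bisection failed to reach k={cfg.k}; nearest "
            f"achievable cluster counts {nearest}")
    raw_u = exemplars[np.argmax(S[:, exemplars], axis=1)]
    raw_u[exemplars] = exemplars  # exemplars represent themselves
    return _finalize(X, raw_u[inverse], cfg.k)


_BACKENDS = {"hier": cluster_hier, "ncut": cluster_ncut, "fastap": cluster_fastap}


def cluster_curves(curves, cfg: ClusterConfig) -> ClusterResult:
    """Dispatch to the configured backend."""
    return _BACKENDS[cfg.method](curves, cfg)
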