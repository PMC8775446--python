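"""Population-geometry analysis with Laplacian eigenmaps.

Mean-filtered population activity vectors (one per time window) are
nodes of a k-nearest-neighbour similarity graph (Euclidean distance,
binary edges, OR-symmetrized).  The graph must be connected; if not, the
largest component is kept provided at most 5% of nodes are discarded.
The embedding solves the generalized eigenproblem L v = lambda D v with
L = D - A, dropping the constant zero-mode; reconstruction quality of
the physical track geometry is the residual variance
RV = 1 - rho^2(Dh, Dl), the squared Pearson correlation between
pairwise distances in physical space and in the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from sklearn.neighbors import kneighbors_graph

from .events import CalciumEvent, TraceMatrix
from .fields import SelectivityRecord
from .synthetic import Trajectory

__all__ = [
    "ActivityMatrix",
    "SimilarityGraph",
    "Embedding",
    "RVResult",
    "GraphDisconnectedError",
    "prepare_activity",
    "window_positions",
    "window_angles",
    "build_graph",
    "choose_k",
    "laplacian_eigenmaps",
    "pca_embed",
    "residual_variance",
    "sliding_rv",
    "unselectivity_curve",
    "cosine_similarity",
    "circular_correlation",
    "circular_rank_correlation",
]

MIN_EVENTS = 5
MAX_DISCARD_FRACTION = 0.05
K_CANDIDATES = (5, 10, 15, 20, 30)


class GraphDisconnectedError(RuntimeError):
    """Raised when the similarity graph cannot be repaired within the 5% rule."""


@dataclass
class ActivityMatrix:
    """Cells x windows mean-filtered activity."""

    values: np.ndarray  # (n_cells, n_windows)
    window_size: int  # frames per window
    fps: float
    cell_ids: np.ndarray
    window_times: np.ndarray  # window-centre times, seconds

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


@dataclass
class SimilarityGraph:
    adjacency: sp.csr_matrix  # binary, symmetric, zero diagonal; kept nodes only
    k: int
    kept_nodes: np.ndarray  # indices into the original window axis
    n_total: int

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def discarded_fraction(self) -> float:
        return 1.0 - self.n_nodes / self.n_total


@dataclass
class Embedding:
    coords: np.ndarray  # (n_kept, m)
    eigenvalues: np.ndarray  # ascending, length m+1 for LE (leading zero incl.)
    method: str  # "LE" | "PCA"
    kept_nodes: np.ndarray


@dataclass
class RVResult:
    rv: float
    n: int
    t_center: float | None = None


def prepare_activity(
    traces: TraceMatrix,
    events: list[CalciumEvent],
    w: int,
    min_events: int = MIN_EVENTS,
) -> ActivityMatrix:
    """Drop cells with fewer than ``min_events`` events, block-average frames.

    The mean filter is non-overlapping: Teff = floor(T / w) windows.
    """
    if w < 1:
        raise ValueError("window size w must be a positive integer")
    counts: dict[int, int] = {}
    for e in events:
        counts[e.cell_id] = counts.get(e.cell_id, 0) + 1
    keep = np.array(
        [i for i, cid in enumerate(traces.cell_ids) if counts.get(int(cid), 0) >= min_events],
        dtype=int,
    )
    if keep.size == 0:
        raise ValueError("no cell has enough events for the manifold stage")
    teff = traces.n_frames // w
    v = traces.values[keep, : teff * w]
    if w > 1:
        v = v.reshape(v.shape[0], teff, w).mean(axis=2)
    times = (np.arange(teff) + 0.5) * w / traces.fps
    return ActivityMatrix(
        values=v, window_size=w, fps=traces.fps,
        cell_ids=traces.cell_ids[keep], window_times=times,
    )


def window_positions(traj: Trajectory, w: int) -> np.ndarray:
    """Mean (x, y) of each non-overlapping w-frame window, (Teff, 2)."""
    teff = traj.t.size // w
    x = traj.x[: teff * w].reshape(teff, w).mean(axis=1)
    y = traj.y[: teff * w].reshape(teff, w).mean(axis=1)
    return np.column_stack([x, y])


def window_angles(traj: Trajectory, w: int) -> np.ndarray:
    """Circular mean angle of each window, radians in [0, 2pi)."""
    teff = traj.t.size // w
    th = traj.theta[: teff * w].reshape(teff, w)
    z = np.exp(1j * th).mean(axis=1)
    return np.mod(np.angle(z), 2.0 * np.pi)


def build_graph(
    X: ActivityMatrix | np.ndarray,
    k: int,
    max_discard: float = MAX_DISCARD_FRACTION,
) -> SimilarityGraph:
    """Exact-k Euclidean nearest-neighbour graph, OR-symmetrized.

    Symmetrization makes k a lower bound on node degree.  A disconnected
    graph is repaired by keeping the largest component when at most
    ``max_discard`` of the nodes are lost; otherwise the reduction is
    unsuccessful for this k and a :class:`GraphDisconnectedError` asks
    for a larger k.
    """
    pts = X.values.T if isinstance(X, ActivityMatrix) else np.asarray(X, dtype=float)
    n = pts.shape[0]
    if k < 1 or k >= n:
        raise ValueError("require 1 <= k < number of nodes")
    A = kneighbors_graph(pts, n_neighbors=k, mode="connectivity", include_self=False)
    A = A.maximum(A.T)  # logical OR
    n_comp, labels = connected_components(A, directed=False)
    if n_comp == 1:
        kept = np.arange(n)
    else:
        sizes = np.bincount(labels)
        largest = int(np.argmax(sizes))
        kept = np.flatnonzero(labels == largest)
        if 1.0 - kept.size / n > max_discard:
            raise GraphDisconnectedError(
                f"graph has {n_comp} components; keeping the largest would discard "
                f"{100 * (1 - kept.size / n):.1f}% of nodes (> {100 * max_discard:.0f}%); "
                "increase k"
            )
        A = A[kept][:, kept]
    A = sp.csr_matrix(A)
    A.setdiag(0)
    A.eliminate_zeros()
    return SimilarityGraph(adjacency=A, k=k, kept_nodes=kept, n_total=n)


def choose_k(
    X: ActivityMatrix | np.ndarray, candidates: tuple[int, ...] = K_CANDIDATES
) -> SimilarityGraph:
    """Smallest candidate k whose graph passes the connectivity rule."""
    err: Exception | None = None
    for k in candidates:
        try:
            return build_graph(X, k)
        except GraphDisconnectedError as e:
            err = e
    raise GraphDisconnectedError(
        f"no candidate k in {candidates} yields an acceptable graph"
    ) from err


def _generalized_spectrum_dense(A: np.ndarray, m: int):
    d = A.sum(axis=1)
    L = np.diag(d) - A
    vals, vecs = scipy.linalg.eigh(L, np.diag(d))
    return vals[: m + 1], vecs[:, : m + 1]


def laplacian_eigenmaps(
    G: SimilarityGraph, m: int = 2, dense_cutoff: int = 600, tol: float = 0.0
) -> Embedding:
    """Solve L v = lambda D v and embed on eigenvectors 1..m.

    Eigenvalues are sorted ascending; the single zero eigenvalue with its
    constant eigenvector is verified and dropped.  Small graphs use a
    dense symmetric solver; larger ones a shift-inverted sparse solver on
    the normalized Laplacian (v = D^{-1/2} u maps back to the generalized
    problem).  Eigenvector sign is fixed by making the largest-magnitude
    component positive.
    """
    n = G.n_nodes
    if m >= n:
        raise ValueError("m must be smaller than the number of nodes")
    A = G.adjacency
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise GraphDisconnectedError("graph has isolated nodes")
    if n <= dense_cutoff:
        vals, vecs = _generalized_spectrum_dense(A.toarray(), m)
    else:
        dinv_sqrt = 1.0 / np.sqrt(deg)
        Dhalf = sp.diags(dinv_sqrt)
        Lsym = sp.identity(n, format="csr") - Dhalf @ A @ Dhalf
        Lsym = (Lsym + Lsym.T) * 0.5
        v0 = np.random.default_rng(0).normal(size=n)  # deterministic Lanczos start
        vals, u = spla.eigsh(Lsym, k=m + 1, sigma=-1e-3, which="LM", tol=tol,
                             v0=v0)
        order = np.argsort(vals)
        vals = vals[order]
        vecs = (u[:, order] * dinv_sqrt[:, None])

    if abs(vals[0]) > 1e-8:
        raise RuntimeError(f"smallest eigenvalue {vals[0]:.2e} is not zero")
    if m + 1 > 1 and vals[1] <= 1e-8:
        raise GraphDisconnectedError(
            "multiple numerically zero eigenvalues: graph is not connected"
        )
    coords = vecs[:, 1 : m + 1].copy()
    for j in range(coords.shape[1]):
        col = coords[:, j]
        # normalize v^T D v = 1 and fix the arbitrary sign
        col /= np.sqrt(np.sum(deg * col**2))
        if col[np.argmax(np.abs(col))] < 0:
            col *= -1.0
    return Embedding(
        coords=coords, eigenvalues=np.asarray(vals), method="LE",
        kept_nodes=G.kept_nodes,
    )


def pca_embed(X: ActivityMatrix | np.ndarray, m: int = 2) -> Embedding:
    """Linear baseline: project windows onto the top-m principal components."""
    pts = X.values.T if isinstance(X, ActivityMatrix) else np.asarray(X, dtype=float)
    n, p = pts.shape
    if m > min(n, p):
        raise ValueError("m cannot exceed min(n_windows, n_cells)")
    centered = pts - pts.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    coords = u[:, :m] * s[:m]
    var = s**2 / (n - 1)
    return Embedding(
        coords=coords, eigenvalues=var[:m][::-1], method="PCA",
        kept_nodes=np.arange(n),
    )


def residual_variance(
    positions: np.ndarray, emb: Embedding | np.ndarray, t_center: float | None = None
) -> RVResult:
    """RV = 1 - rho^2 between pairwise physical and embedding distances.

    ``positions`` must already be restricted to the embedding's kept
    windows; rho is the Pearson correlation over strictly-upper-triangular
    distance entries.
    """
    coords = emb.coords if isinstance(emb, Embedding) else np.asarray(emb, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] != coords.shape[0]:
        raise ValueError("positions and embedding must have the same length")
    dh = pdist(positions)
    dl = pdist(coords)
    rho = pearsonr(dh, dl).statistic
    rv = float(1.0 - rho**2)
    return RVResult(rv=min(max(rv, 0.0), 1.0), n=positions.shape[0], t_center=t_center)


def sliding_rv(
    X: ActivityMatrix,
    positions: np.ndarray,
    k: int,
    m: int = 2,
    window_s: float = 250.0,
    stride_s: float = 25.0,
) -> list[RVResult]:
    """Full LE + RV recomputed on sliding time slices of the session.

    ``positions`` is the (Teff, 2) window-position array aligned with X.
    """
    t = X.window_times
    out: list[RVResult] = []
    start = t[0]
    step = X.window_size / X.fps
    t_end = t[-1] + step  # end of the last filtered window
    while start + window_s <= t_end + 1e-9:
        sel = np.flatnonzero((t >= start) & (t < start + window_s))
        if sel.size > k + m + 1:
            sub = X.values[:, sel]
            G = build_graph(sub.T, k)
            emb = laplacian_eigenmaps(G, m)
            pos = positions[sel][G.kept_nodes]
            res = residual_variance(pos, emb, t_center=float(start + window_s / 2))
            out.append(res)
        start += stride_s
    return out


def unselectivity_curve(
    records: list[SelectivityRecord],
    frame_times: np.ndarray,
    window_s: float = 250.0,
) -> np.ndarray:
    """1 - mean selectivity over fields, interpolated to frames and
    smoothed with a running-average filter of the given window length."""
    recs = [r for r in records if r.scored_idx.size > 0]
    if not recs:
        raise ValueError("need at least one scored place field")
    frame_times = np.asarray(frame_times, dtype=float)
    acc = np.zeros(frame_times.size)
    for r in recs:
        t_vis = np.array([r.epochs[i].t_enter for i in r.scored_idx])
        scores = r.raw_scores[r.scored_idx]
        acc += np.interp(frame_times, t_vis, scores)
    unsel = 1.0 - acc / len(recs)
    if frame_times.size > 1:
        dt = frame_times[1] - frame_times[0]
        size = max(1, int(round(window_s / dt)))
        kern = np.ones(size) / size
        unsel = np.convolve(np.pad(unsel, size // 2, mode="edge"), kern, mode="same")[
            size // 2 : size // 2 + frame_times.size
        ]
    return unsel


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size != v.size or u.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def circular_rank_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Circular correlation of the circular ranks of two angle series.

    Each series is replaced by uniform angles 2*pi*rank/n, which makes the
    coefficient invariant to any order-preserving (monotone circular)
    warping — it measures agreement of angular ORDER, not of the angles
    themselves.  Sign flips under reflection.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ra = 2.0 * np.pi * np.argsort(np.argsort(a)) / a.size
    rb = 2.0 * np.pi * np.argsort(np.argsort(b)) / b.size
    return circular_correlation(ra, rb)


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Circular correlation (Jammalamadaka-SarmaRao) between two angle series.

    Invariant to rotating either series; reflection flips the sign.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mu_a = np.angle(np.exp(1j * a).mean())
    mu_b = np.angle(np.exp(1j * b).mean())
    sa = np.sin(a - mu_a)
    sb = np.sin(b - mu_b)
    return float(np.sum(sa * sb) / np.sqrt(np.sum(sa**2) * np.sum(sb**2)))
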