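"""Nonlocal operator calculus: NL-means weight graphs, graph gradient and
divergence, the nonlocal TV norm, and the graph-dual projection denoiser.

Pixels become graph nodes; an edge ``(x, y)`` carries the patch-similarity
weight

    w(x, y) = exp(-d_a(x, y) / h(x)^2)

where ``d_a`` is the Gaussian-weighted squared distance between the
``(2r+1)^2`` patches around ``x`` and ``y`` (patches read through symmetric
boundary reflection), and ``h`` is the filter bandwidth — a scalar or a
per-pixel map tied to the local noise scale.  The self-weight is set to the
largest off-center weight (the standard NL-means convention), each pixel
keeps its ``max_neighbors`` strongest edges inside the search window, and
the kept edge set is symmetrized with ``w <- max(w(x,y), w(y,x))``.

With square-root weight splitting the graph gradient
``(grad_w u)(x,y) = (u(y) - u(x)) sqrt(w(x,y))`` and divergence
``(div_w v)(x) = sum_y (v(x,y) - v(y,x)) sqrt(w(x,y))`` are exact negative
adjoints, which is what the dual projection iteration requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numpy.lib.stride_tricks import sliding_window_view

from .degradation import as_image
from .tv import DenoiseInfo

__all__ = [
    "NLConfig",
    "WeightGraph",
    "NLVectorField",
    "compute_nl_weights",
    "lattice_graph",
    "nl_gradient",
    "nl_divergence",
    "nltv_norm",
    "nltv_objective",
    "nl_chambolle_denoise",
]


@dataclass(frozen=True)
class NLConfig:
    """Nonlocal weight-graph parameters.

    ``patch_radius`` r gives (2r+1)^2 comparison patches; ``search_radius``
    bounds the neighbor window; ``gauss_a`` is the std of the intra-patch
    Gaussian kernel G_a; ``h`` is the filter bandwidth (scalar, or a
    per-pixel array for the adaptive scheme); ``max_neighbors`` caps the
    kept edges per pixel so the solver stays O(N * m);
    ``weight_every`` recomputes the graph every n-th outer iteration.
    """

    patch_radius: int = 2
    search_radius: int = 5
    gauss_a: float = 1.0
    h: float | np.ndarray = 0.1
    max_neighbors: int = 10
    weight_every: int = 1

    def __post_init__(self):
        if self.patch_radius < 0:
            raise ValueError("patch_radius must be >= 0")
        if self.search_radius < max(1, self.patch_radius):
            raise ValueError("search_radius must be >= max(1, patch_radius)")
        if self.gauss_a <= 0:
            raise ValueError("gauss_a must be positive")
        if self.max_neighbors < 1:
            raise ValueError("max_neighbors must be >= 1")
        if self.weight_every < 1:
            raise ValueError("weight_every must be >= 1")


@dataclass
class WeightGraph:
    """Sparse symmetric nonnegative weight graph over image pixels.

    ``matrix`` is an N x N CSR matrix (N = height * width, row-major pixel
    order) with ``matrix[x, y] = w(x, y)``.
    """

    matrix: sp.csr_matrix
    shape: tuple[int, int]

    def __post_init__(self):
        n = self.shape[0] * self.shape[1]
        if self.matrix.shape != (n, n):
            raise ValueError("graph matrix size does not match image shape")

    @property
    def n_pixels(self) -> int:
        return self.shape[0] * self.shape[1]

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def to_edge_list(self) -> list[tuple[int, int, int, int, float]]:
        """Edges as (x_row, x_col, y_row, y_col, weight) tuples, for debugging."""
        coo = self.matrix.tocoo()
        w = self.shape[1]
        return [
            (int(r // w), int(r % w), int(c // w), int(c % w), float(v))
            for r, c, v in zip(coo.row, coo.col, coo.data)
        ]

    def save_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("x_row\tx_col\ty_row\ty_col\tweight\n")
            for edge in self.to_edge_list():
                fh.write("\t".join(str(v) for v in edge[:4]) + f"\t{edge[4]:.12g}\n")


@dataclass
class NLVectorField:
    """Edge function congruent with a :class:`WeightGraph`'s CSR adjacency."""

    graph: WeightGraph
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.graph.matrix.data.shape:
            raise ValueError("field data must align with the graph's stored edges")

    @classmethod
    def zeros(cls, graph: WeightGraph) -> "NLVectorField":
        return cls(graph, np.zeros_like(graph.matrix.data))

    def as_matrix(self) -> sp.csr_matrix:
        m = self.graph.matrix
        return sp.csr_matrix((self.data, m.indices.copy(), m.indptr.copy()), shape=m.shape)


def _gauss_patch_kernel(radius: int, sigma: float) -> np.ndarray:
    """Normalized (2r+1)^2 Gaussian patch kernel G_a."""
    if radius == 0:
        return np.ones((1, 1))
    ax = np.arange(-radius, radius + 1)
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    return g / g.sum()


def patch_distances(reference: np.ndarray, cfg: NLConfig) -> dict[tuple[int, int], np.ndarray]:
    """G_a-weighted squared patch distances for every search-window offset.

    Returns ``{(dy, dx): D}`` where ``D[i, j] = d_a(x, x + t)`` for pixel
    ``x = (i, j)`` and offset ``t = (dy, dx)``; entries whose neighbor falls
    outside the image are NaN.  Patches are read through symmetric
    reflection of the image boundary.
    """
    u = as_image(reference)
    H, W = u.shape
    r = cfg.patch_radius
    G = _gauss_patch_kernel(r, cfg.gauss_a)
    pad = np.pad(u, r, mode="symmetric")
    # patches[i, j] is the (2r+1)^2 patch centered at pixel (i, j), G_a-weighted
    patches = sliding_window_view(pad, (2 * r + 1, 2 * r + 1))
    q = (patches * np.sqrt(G)).reshape(H, W, -1)

    out: dict[tuple[int, int], np.ndarray] = {}
    R = cfg.search_radius
    for dy in range(-R, R + 1):
        for dx in range(-R, R + 1):
            if dy == 0 and dx == 0:
                continue
            D = np.full((H, W), np.nan)
            y0, y1 = max(0, -dy), min(H, H - dy)
            x0, x1 = max(0, -dx), min(W, W - dx)
            if y0 >= y1 or x0 >= x1:
                continue
            diff = q[y0:y1, x0:x1] - q[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
            D[y0:y1, x0:x1] = np.einsum("ijk,ijk->ij", diff, diff)
            out[(dy, dx)] = D
    return out


def compute_nl_weights(reference: np.ndarray, cfg: NLConfig) -> WeightGraph:
    """NL-means weight graph of a reference image.

    Raw weights ``exp(-d_a(x, y) / h(x)^2)`` use the bandwidth of the *row*
    pixel ``x``; after per-pixel top-``max_neighbors`` sparsification the
    graph is symmetrized by the elementwise maximum over the kept edge
    union, so ``w(x, y) = w(y, x)`` exactly.
    """
    u = as_image(reference)
    H, W = u.shape
    h = cfg.h
    if np.isscalar(h):
        hsq = np.full((H, W), float(h) ** 2)
        if h <= 0:
            raise ValueError("filter parameter h must be positive")
    else:
        h = np.asarray(h, dtype=float)
        if h.shape != u.shape:
            raise ValueError("per-pixel h must match the image shape")
        if np.any(h <= 0):
            raise ValueError("filter parameter h must be positive everywhere")
        hsq = h**2

    dists = patch_distances(u, cfg)
    offsets = list(dists.keys())
    n_off = len(offsets)
    # stack of raw weights per offset; NaN marks out-of-image neighbors
    Wstack = np.full((n_off, H, W), np.nan)
    for k, t in enumerate(offsets):
        Wstack[k] = np.exp(-dists[t] / hsq)

    # self-weight: max off-center weight per pixel
    self_w = np.nanmax(Wstack, axis=0)

    # per-pixel top-m among window weights (self always kept; it ties the max)
    m = min(cfg.max_neighbors, n_off)
    filled = np.where(np.isnan(Wstack), -np.inf, Wstack).reshape(n_off, H * W)
    keep_idx = np.argpartition(-filled, kth=m - 1, axis=0)[:m]

    rows_list, cols_list, vals_list = [], [], []
    pix = np.arange(H * W)
    iy, ix = np.divmod(pix, W)
    off_arr = np.array(offsets)
    for rank in range(m):
        k = keep_idx[rank]
        w = filled[k, pix]
        valid = np.isfinite(w) & (w > 0)
        dy = off_arr[k, 0]
        dx = off_arr[k, 1]
        ny, nx = iy + dy, ix + dx
        rows_list.append(pix[valid])
        cols_list.append((ny * W + nx)[valid])
        vals_list.append(w[valid])
    # diagonal self edges
    rows_list.append(pix)
    cols_list.append(pix)
    vals_list.append(np.where(np.isfinite(self_w.ravel()), self_w.ravel(), 1.0))

    rows = np.concatenate(rows_list)
    cols = np.concatenate(cols_list)
    vals = np.concatenate(vals_list)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(H * W, H * W))
    A = A.maximum(A.T)  # symmetrize over the union of kept edges
    A.sort_indices()
    return WeightGraph(matrix=A, shape=(H, W))


def lattice_graph(shape: tuple[int, int], weight: float = 1.0) -> WeightGraph:
    """4-nearest-neighbor lattice graph with constant edge weight.

    The degenerate graph on which nonlocal TV collapses to a local
    (symmetric-difference) lattice TV — used for consistency checks.
    """
    H, W = shape
    pix = np.arange(H * W).reshape(H, W)
    rows, cols = [], []
    for dy, dx in ((0, 1), (1, 0)):
        a = pix[: H - dy, : W - dx].ravel()
        b = pix[dy:, dx:].ravel()
        rows.extend([a, b])
        cols.extend([b, a])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    A = sp.csr_matrix(
        (np.full(rows.size, float(weight)), (rows, cols)), shape=(H * W, H * W)
    )
    A.sort_indices()
    return WeightGraph(matrix=A, shape=(H, W))


def _row_of_edges(graph: WeightGraph) -> np.ndarray:
    m = graph.matrix
    return np.repeat(np.arange(m.shape[0]), np.diff(m.indptr))


def nl_gradient(u: np.ndarray, W: WeightGraph) -> NLVectorField:
    """Graph gradient ``(u(y) - u(x)) sqrt(w(x, y))`` on every stored edge."""
    u = as_image(u)
    if u.shape != W.shape:
        raise ValueError("image shape does not match graph shape")
    uf = u.ravel()
    m = W.matrix
    rows = _row_of_edges(W)
    data = (uf[m.indices] - uf[rows]) * np.sqrt(m.data)
    return NLVectorField(W, data)


def nl_divergence(v: NLVectorField, W: WeightGraph | None = None) -> np.ndarray:
    """Graph divergence ``sum_y (v(x,y) - v(y,x)) sqrt(w(x,y))``.

    Exact negative adjoint of :func:`nl_gradient` for symmetric weights.
    """
    graph = v.graph if W is None else W
    if W is not None and v.graph is not W:
        if (v.graph.matrix.indptr != W.matrix.indptr).any() or (
            v.graph.matrix.indices != W.matrix.indices
        ).any():
            raise ValueError("field is not congruent with the given graph")
    m = graph.matrix
    weighted = v.data * np.sqrt(m.data)
    Vw = sp.csr_matrix((weighted, m.indices.copy(), m.indptr.copy()), shape=m.shape)
    out = np.asarray(Vw.sum(axis=1)).ravel() - np.asarray(Vw.sum(axis=0)).ravel()
    return out.reshape(graph.shape)


def _rowwise_norms(graph: WeightGraph, data: np.ndarray) -> np.ndarray:
    """Per-node Euclidean norm of an edge function over the node's edges."""
    m = graph.matrix
    sq = sp.csr_matrix((data**2, m.indices, m.indptr), shape=m.shape)
    return np.sqrt(np.asarray(sq.sum(axis=1)).ravel())


def nltv_norm(u: np.ndarray, W: WeightGraph) -> float:
    """Nonlocal TV: ``sum_x sqrt(sum_y w(x,y) (u(y) - u(x))^2)``."""
    g = nl_gradient(u, W)
    return float(_rowwise_norms(W, g.data).sum())


def nltv_objective(g: np.ndarray, f: np.ndarray, W: WeightGraph, reg_weight: float) -> float:
    """Graph ROF energy ``NLTV(g) + (reg_weight/2) ||g - f||^2``."""
    return nltv_norm(g, W) + 0.5 * reg_weight * float(np.sum((g - f) ** 2))


def nl_chambolle_denoise(
    f: np.ndarray,
    W: WeightGraph,
    reg_weight: float,
    tol: float = 1e-4,
    max_iter: int = 100,
    full_output: bool = False,
):
    """Nonlocal TV denoising by the graph analogue of Chambolle projection.

    Minimizes ``NLTV(g) + (reg_weight/2) ||g - f||^2`` with a dual variable
    on the edges, step size ``1 / (2 max_x sum_y w(x, y))``, rowwise
    renormalization, and output ``g = f - (1/reg_weight) div_w p``.
    """
    f = as_image(f)
    if reg_weight <= 0:
        raise ValueError(f"reg_weight must be positive, got {reg_weight}")
    if f.shape != W.shape:
        raise ValueError("image shape does not match graph shape")

    m = W.matrix
    rows = _row_of_edges(W)
    sqw = np.sqrt(m.data)
    max_rowsum = W.row_sums().max()
    if max_rowsum <= 0:
        return (f.copy(), DenoiseInfo(True, 0)) if full_output else f.copy()
    tau = 1.0 / (2.0 * max_rowsum)
    inv_w = 1.0 / reg_weight
    uf = f.ravel()

    def edge_grad(node_vals: np.ndarray) -> np.ndarray:
        return (node_vals[m.indices] - node_vals[rows]) * sqw

    def divergence(p: np.ndarray) -> np.ndarray:
        weighted = p * sqw
        Vw = sp.csr_matrix((weighted, m.indices, m.indptr), shape=m.shape)
        return np.asarray(Vw.sum(axis=1)).ravel() - np.asarray(Vw.sum(axis=0)).ravel()

    p = np.zeros_like(m.data)
    converged = False
    history: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        eta = edge_grad(divergence(p) - reg_weight * uf)
        norms = _rowwise_norms(W, eta)
        denom = 1.0 + tau * np.repeat(norms, np.diff(m.indptr))
        p_new = (p + tau * eta) / denom
        delta = np.abs(p_new - p).max(initial=0.0)
        p = p_new
        if full_output:
            g_it = (uf - inv_w * divergence(p)).reshape(f.shape)
            history.append(nltv_objective(g_it, f, W, reg_weight))
        if delta < tol:
            converged = True
            break

    g = (uf - inv_w * divergence(p)).reshape(f.shape)
    if full_output:
        return g, DenoiseInfo(converged=converged, iterations=it, energy_history=history)
    return g
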