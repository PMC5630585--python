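"""Radial-ray graph construction and star-shaped s-t min cut.

The segmenter samples the image along K radial rays distributed clockwise
around a user seed (a circular template), builds a directed graph whose
infinite-capacity intra-edges (outward -> inward along each ray) force the
cut to sever exactly one position per ray, and whose inter-edges between
adjacent rays (offset by the smoothness parameter ``delta_r``) bound how
fast the contour radius may change between neighboring rays. Terminal edges
carry the image evidence: per ray, the absolute deviation of each sampled
gray value from the mean gray around the seed is differenced between
radially adjacent nodes; the sign of that difference binds the node to the
source (negative) or the sink (non-negative) with the magnitude as
capacity, while the innermost node is bound to the source and the outermost
to the sink with their full deviations. The minimum s-t cut of this graph
is a globally optimal star-shaped contour around the seed.

Among co-optimal cuts the solver returns the *maximal* source set (the
outermost contour), obtained from residual reachability to the sink. On a
noiseless step profile every cut strictly inside the homogeneous lesion
costs zero, and only the outermost of these sits on the lesion boundary, so
this tie rule is what makes the cut track the edge rather than collapse
toward the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .image_io import PointPx, UltrasoundImage

__all__ = [
    "GraphParams",
    "RadialGraph",
    "CutResult",
    "default_max_radius",
    "sample_rays",
    "average_seed_gray",
    "terminal_weights",
    "build_graph",
    "solve_min_cut",
    "oracle_min_cut",
]

# ceiling for the fixed-point capacity scale; the actual scale shrinks so the
# scaled capacity total stays below 2^31 (the max-flow backend uses int32)
_MAX_CAP_SCALE = 1 << 20


def _cap_scale(total_cap: float) -> int:
    # headroom below 2^31 so the backend's internal int32 arithmetic on
    # capacities near the infinite-edge value cannot overflow
    return max(1, min(_MAX_CAP_SCALE, int(2**29 / max(1.0, total_cap))))


@dataclass(frozen=True)
class GraphParams:
    """Geometry and smoothness parameters of the radial graph template.

    ``n_rays`` (K) and ``n_nodes`` (N) control angular/radial resolution,
    ``max_radius`` (px) the outermost node distance from the seed,
    ``delta_r`` the maximum cut-index jump between adjacent rays, and
    ``avg_window`` the side of the square patch whose mean gray anchors the
    terminal weights.
    """

    n_rays: int = 60
    n_nodes: int = 40
    max_radius: float | None = None  # None -> derived from seed/image geometry
    delta_r: int = 2
    avg_window: int = 9
    avg_mode: str = "template"  # "template": mean over sampled template nodes;
    # "window": mean of the avg_window square around the seed

    def __post_init__(self) -> None:
        if self.avg_mode not in ("template", "window"):
            raise ValueError("avg_mode must be 'template' or 'window'")
        if self.n_rays < 3:
            raise ValueError("need at least 3 rays")
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes per ray")
        if self.max_radius is not None and self.max_radius < self.n_nodes:
            raise ValueError("max_radius must allow >= 1 px node spacing")
        if self.delta_r < 0:
            raise ValueError("delta_r must be >= 0")
        if self.avg_window < 1 or self.avg_window % 2 == 0:
            raise ValueError("avg_window must be odd and >= 1")


@dataclass
class RadialGraph:
    """Sampled node grid plus terminal attachments of the s-t graph.

    ``positions`` is (K, N, 2) in (x, y); ``grays`` the bilinearly sampled
    values; ``term_sink``/``term_cap`` give each node's terminal side and
    capacity; ``forced`` pins nodes with infinite-capacity terminal edges
    (0 none, +1 source, -1 sink) as used by helper seeds.
    """

    params: GraphParams
    seed: PointPx
    positions: np.ndarray
    grays: np.ndarray
    avg_gray: float = 0.0
    term_sink: np.ndarray | None = None  # (K,N) bool, True -> sink
    term_cap: np.ndarray | None = None  # (K,N) float >= 0
    forced: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.forced is None:
            K, N = self.shape
            self.forced = np.zeros((K, N), dtype=np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.positions.shape[0], self.positions.shape[1]

    @property
    def node_spacing(self) -> float:
        K, N = self.shape
        return float(self.params.max_radius) / N

    def copy(self) -> "RadialGraph":
        return RadialGraph(
            params=self.params,
            seed=self.seed,
            positions=self.positions,
            grays=self.grays,
            avg_gray=self.avg_gray,
            term_sink=None if self.term_sink is None else self.term_sink.copy(),
            term_cap=None if self.term_cap is None else self.term_cap.copy(),
            forced=self.forced.copy(),
        )


@dataclass(frozen=True)
class CutResult:
    """Per-ray cut indices (outermost foreground node) and min-cut value."""

    cut_index: np.ndarray
    flow_value: float

    def __post_init__(self) -> None:
        if self.flow_value < 0 or not np.isfinite(self.flow_value):
            raise ValueError("flow value must be finite and >= 0")


def default_max_radius(image: UltrasoundImage, seed: PointPx) -> float:
    """Default template radius: distance to the nearest border, capped at
    0.45 * min(height, width)."""
    border = min(seed.x, seed.y, image.width - 1 - seed.x, image.height - 1 - seed.y)
    return float(min(border, 0.45 * min(image.height, image.width)))


def ray_directions(n_rays: int) -> np.ndarray:
    """Unit direction (x, y) of each ray: angles 2*pi*k/K clockwise on
    screen starting from 'up' (0, -1)."""
    theta = 2.0 * np.pi * np.arange(n_rays) / n_rays
    return np.stack([np.sin(theta), -np.cos(theta)], axis=1)


def bilinear_sample(pixels: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at (x, y) positions; out-of-image positions
    clamp to the border pixel."""
    h, w = pixels.shape
    x = np.clip(np.asarray(xy)[..., 0], 0.0, w - 1.0)
    y = np.clip(np.asarray(xy)[..., 1], 0.0, h - 1.0)
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = x - x0
    fy = y - y0
    p = pixels.astype(float)
    return (
        p[y0, x0] * (1 - fx) * (1 - fy)
        + p[y0, x1] * fx * (1 - fy)
        + p[y1, x0] * (1 - fx) * fy
        + p[y1, x1] * fx * fy
    )


def _resolved(params: GraphParams, image: UltrasoundImage, seed: PointPx) -> GraphParams:
    if params.max_radius is not None:
        return params
    r = default_max_radius(image, seed)
    r = max(r, float(params.n_nodes))  # keep >= 1 px node spacing
    return GraphParams(
        params.n_rays, params.n_nodes, r, params.delta_r, params.avg_window, params.avg_mode
    )


def sample_rays(image: UltrasoundImage, seed: PointPx, params: GraphParams) -> RadialGraph:
    """Sample node positions and gray values on the radial template.

    Node (k, i) lies at radius (i+1) * max_radius / N from the seed along
    ray k; grays come from bilinear interpolation.
    """
    if not image.contains(seed):
        raise ValueError(f"seed {seed} outside image bounds {image.shape}")
    params = _resolved(params, image, seed)
    K, N = params.n_rays, params.n_nodes
    radii = (np.arange(1, N + 1) * params.max_radius / N)[None, :, None]
    dirs = ray_directions(K)[:, None, :]
    pos = np.array([seed.x, seed.y]) + radii * dirs  # (K, N, 2)
    grays = bilinear_sample(image.pixels, pos)
    return RadialGraph(params=params, seed=seed, positions=pos, grays=grays)


def average_seed_gray(image: UltrasoundImage, seed: PointPx, avg_window: int = 9) -> float:
    """Mean gray of the avg_window x avg_window square centered at the seed,
    clipped to the image bounds."""
    if not image.contains(seed):
        raise ValueError("seed outside image")
    half = avg_window // 2
    cx, cy = int(round(seed.x)), int(round(seed.y))
    x0, x1 = max(0, cx - half), min(image.width, cx + half + 1)
    y0, y1 = max(0, cy - half), min(image.height, cy + half + 1)
    return float(image.pixels[y0:y1, x0:x1].mean())


def terminal_weights(ray_grays: np.ndarray, m: float) -> tuple[np.ndarray, np.ndarray]:
    """Terminal side and capacity for the nodes of one or more rays.

    With a_i = |g_i - m|: node 0 -> source with a_0, node N-1 -> sink with
    a_{N-1}; interior node i carries |a_i - a_{i-1}| and goes to the source
    when the difference is negative, to the sink otherwise (tie -> sink).

    Accepts a single ray of shape (N,) or a stack (K, N); returns
    (sink_side bool array, capacity array) of the same shape.
    """
    g = np.atleast_2d(np.asarray(ray_grays, dtype=float))
    if g.shape[-1] < 2:
        raise ValueError("need at least 2 nodes per ray")
    a = np.abs(g - m)
    diff = np.diff(a, axis=-1)  # diff[..., i-1] = a_i - a_{i-1}
    sink = np.ones_like(a, dtype=bool)
    cap = np.empty_like(a)
    sink[..., 0] = False  # innermost node -> source
    cap[..., 0] = a[..., 0]
    sink[..., 1:-1] = diff[..., :-1] >= 0
    cap[..., 1:-1] = np.abs(diff[..., :-1])
    sink[..., -1] = True  # outermost node -> sink
    cap[..., -1] = a[..., -1]
    if np.asarray(ray_grays).ndim == 1:
        return sink[0], cap[0]
    return sink, cap


def build_graph(image: UltrasoundImage, seed: PointPx, params: GraphParams) -> RadialGraph:
    """Sample the template and attach terminal weights (full graph).

    The reference gray ``m`` is sampled on the fly around the seed. In the
    default ``template`` mode it is the mean over all sampled template
    nodes, so it mixes lesion and surrounding tissue and sits between the
    two gray levels at any lesion scale; the cut then settles where the ray
    profiles cross ``m``, i.e. on the lesion boundary. The ``window`` mode
    uses the plain avg_window square mean around the seed instead: with the
    seed deep inside a homogeneous lesion this makes the cut position
    within the lesion noise-driven, so it is mainly useful with helper
    seeds or for seeds placed near the transition zone.
    """
    graph = sample_rays(image, seed, params)
    if params.avg_mode == "template":
        graph.avg_gray = float(graph.grays.mean())
    else:
        graph.avg_gray = average_seed_gray(image, seed, params.avg_window)
    graph.term_sink, graph.term_cap = terminal_weights(graph.grays, graph.avg_gray)
    return graph


def _edge_arrays(graph: RadialGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """Sparse COO arrays of the full s-t graph with int64 capacities."""
    K, N = graph.shape
    dr = graph.params.delta_r
    scale = _cap_scale(float(graph.term_cap.sum()))
    cap = np.rint(graph.term_cap * scale).astype(np.int64)
    inf = int(cap.sum()) + 1
    src, snk = K * N, K * N + 1
    nid = np.arange(K * N).reshape(K, N)

    rows = [nid[:, 1:].ravel()]  # intra: (k,i) -> (k,i-1), infinite
    cols = [nid[:, :-1].ravel()]
    target = np.maximum(0, np.arange(N) - dr)
    for dk in (-1, 1):  # inter: (k,i) -> (k+-1, max(0, i-delta_r)), infinite
        rows.append(nid.ravel())
        cols.append(nid[(np.arange(K)[:, None] + dk) % K, target[None, :]].ravel())
    n_inf = sum(r.size for r in rows)

    sink_side = graph.term_sink.ravel()
    forced = graph.forced.ravel()
    tcap = cap.ravel().copy()
    tcap[forced != 0] = inf
    to_sink = np.where(forced != 0, forced == -1, sink_side)
    rows.append(np.where(to_sink, nid.ravel(), src))
    cols.append(np.where(to_sink, snk, nid.ravel()))

    data = np.concatenate([np.full(n_inf, inf, dtype=np.int64), tcap])
    return np.concatenate(rows), np.concatenate(cols), data, src, snk


def _cut_cost(graph: RadialGraph, cut_index: np.ndarray) -> float:
    """Exact capacity of the cut defined by per-ray indices (float weights)."""
    K, N = graph.shape
    idx = np.arange(N)[None, :]
    fg = idx <= np.asarray(cut_index)[:, None]
    severed = (fg & graph.term_sink) | (~fg & ~graph.term_sink)
    return float(graph.term_cap[severed].sum())


def solve_min_cut(graph: RadialGraph) -> CutResult:
    """Globally optimal star-shaped cut via max-flow/min-cut.

    Returns the outermost co-optimal contour: the foreground is the maximal
    source set, i.e. the complement of the nodes that can still reach the
    sink in the residual network.
    """
    if graph.term_cap is None:
        raise ValueError("graph has no terminal weights; call build_graph first")
    K, N = graph.shape
    rows, cols, data, src, snk = _edge_arrays(graph)
    n = K * N + 2
    G = sp.csr_matrix((data, (rows, cols)), shape=(n, n), dtype=np.int64)
    res = maximum_flow(G, src, snk)

    residual = G - res.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reach = breadth_first_order(residual.T, snk, directed=True, return_predecessors=False)
    to_sink = np.zeros(n, dtype=bool)
    to_sink[reach] = True
    fg = (~to_sink[: K * N]).reshape(K, N)

    cut_index = np.empty(K, dtype=int)
    for k in range(K):
        on = np.flatnonzero(fg[k])
        if on.size == 0 or on[-1] != on.size - 1:
            raise RuntimeError("cut is not a per-ray prefix; graph construction broken")
        cut_index[k] = on[-1]
    return CutResult(cut_index=cut_index, flow_value=_cut_cost(graph, cut_index))


def oracle_min_cut(graph: RadialGraph, max_nodes: int = 4096) -> CutResult:
    """Exact optimum by dynamic programming over per-ray cut indices.

    Independent of the max-flow path: enumerates the first ray's index to
    close the cycle and runs a DP along rays with the circular
    |c_k - c_{k+1}| <= delta_r transition. Ties prefer larger indices
    (outermost contour), matching the solver's tie rule. Intended for small
    instances only.
    """
    K, N = graph.shape
    if K * N > max_nodes:
        raise ValueError(f"instance too large for the DP oracle ({K * N} nodes)")
    dr = graph.params.delta_r

    # per-ray cost of cutting at index c: sink caps for i<=c plus source caps for i>c
    sink_cum = np.cumsum(np.where(graph.term_sink, graph.term_cap, 0.0), axis=1)
    src_tail = np.where(~graph.term_sink, graph.term_cap, 0.0)[:, ::-1].cumsum(axis=1)[:, ::-1]
    cost = sink_cum + np.concatenate([src_tail[:, 1:], np.zeros((K, 1))], axis=1)
    for k in range(K):
        f = graph.forced[k]
        pinned = np.flatnonzero(f)
        if pinned.size:  # helper pinning: only the forced prefix boundary is feasible
            feasible = np.full(N, np.inf)
            lo = max([i for i in pinned if f[i] == 1], default=0)
            hi = min([i for i in pinned if f[i] == -1], default=N)
            feasible[lo : max(lo + 1, hi)] = cost[k, lo : max(lo + 1, hi)]
            cost[k] = feasible

    best_flow = np.inf
    best_cut: np.ndarray | None = None
    offsets = np.arange(-dr, dr + 1)
    for c0 in range(N):
        dp = np.full(N, np.inf)
        dp[c0] = cost[0, c0]
        choice = np.zeros((K, N), dtype=int)
        for k in range(1, K):
            prev_idx = np.clip(np.arange(N)[:, None] + offsets[None, :], 0, N - 1)
            cand = dp[prev_idx]
            cand[np.abs(prev_idx - np.arange(N)[:, None]) > dr] = np.inf
            pick = cand.shape[1] - 1 - np.argmin(cand[:, ::-1], axis=1)  # tie -> larger prev
            dp = cand[np.arange(N), pick] + cost[k]
            choice[k] = prev_idx[np.arange(N), pick]
        dp[np.abs(np.arange(N) - c0) > dr] = np.inf  # close the cycle
        cN = int(np.flatnonzero(dp == dp.min())[-1]) if np.isfinite(dp.min()) else -1
        if cN < 0 or dp[cN] > best_flow or (dp[cN] == best_flow and best_cut is not None):
            continue
        cut = np.empty(K, dtype=int)
        cut[K - 1] = cN
        for k in range(K - 1, 0, -1):
            cut[k - 1] = choice[k, cut[k]]
        best_flow = float(dp[cN])
        best_cut = cut
    assert best_cut is not None
    return CutResult(cut_index=best_cut, flow_value=best_flow)


def dump_edges(graph: RadialGraph, path) -> None:
    """Debug dump of the graph as a node_id,node_id,capacity text file."""
    rows, cols, data, src, snk = _edge_arrays(graph)
    with open(path, "w") as fh:
        fh.write(f"# source={src} sink={snk}\n")
        for r, c, d in zip(rows, cols, data):
            fh.write(f"{r},{c},{d}\n")
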