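"""Seed + helper seeds -> closed contour and mask.

Emulates the interactive session as a batch-callable, pure API: the caller
places a seed inside the lesion (and may "drag" it by calling again with a
new position); helper seeds placed on the lesion border pin the cut locally
through infinite-capacity terminal edges, and the whole solution is
recomputed instantly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

from .image_io import BinaryMask, PointPx, UltrasoundImage
from .metrics import diameters
from .radial_graph import (
    CutResult,
    GraphParams,
    RadialGraph,
    build_graph,
    ray_directions,
    solve_min_cut,
)

__all__ = [
    "HelperSeed",
    "SegmentationResult",
    "segment",
    "resegment",
    "apply_helper_constraints",
    "cut_to_mask",
    "contour_from_cut",
]


@dataclass(frozen=True)
class HelperSeed:
    """A point placed on (or near) the intended lesion border."""

    position: PointPx


@dataclass
class SegmentationResult:
    contour: np.ndarray  # (K, 2) sub-pixel vertices, one per ray
    mask: BinaryMask
    cut: CutResult
    diameter_a: float  # mm
    diameter_b: float  # mm
    params: GraphParams
    seed: PointPx
    helpers: tuple[HelperSeed, ...] = ()
    satisfied: bool | None = None  # caller-set flag; does not alter computation
    flow_value: float = field(init=False)

    def __post_init__(self) -> None:
        self.flow_value = self.cut.flow_value


def helper_to_node(graph: RadialGraph, helper: HelperSeed) -> tuple[int, int]:
    """Map a helper seed to its nearest (ray, radial index) node."""
    K, N = graph.shape
    dx = helper.position.x - graph.seed.x
    dy = helper.position.y - graph.seed.y
    r = float(np.hypot(dx, dy))
    if r > graph.params.max_radius * (1.0 + 1e-9) + 1e-9:
        raise ValueError(
            f"helper at radius {r:.1f} px exceeds template max_radius "
            f"{graph.params.max_radius:.1f} px"
        )
    # clockwise angle from 'up', consistent with ray_directions
    theta = float(np.arctan2(dx, -dy)) % (2.0 * np.pi)
    k = int(round(theta / (2.0 * np.pi / K))) % K
    h = graph.node_spacing
    i = int(np.clip(round(r / h - 1.0), 0, N - 1))
    return k, i


def apply_helper_constraints(graph: RadialGraph, helpers: list[HelperSeed]) -> RadialGraph:
    """Pin the cut at each helper's nearest node via infinite terminal edges.

    On the helper's ray, nodes at or inside the helper index are forced to
    the source, nodes outside to the sink, so the cut on that ray lands
    exactly at the helper; neighboring rays adapt through the delta_r
    smoothness constraint. Two helpers landing on the same ray: the last
    one wins (with a warning).
    """
    out = graph.copy()
    seen: dict[int, int] = {}
    for helper in helpers:
        k, i = helper_to_node(out, helper)
        if k in seen and seen[k] != i:
            warnings.warn(
                f"multiple helpers map to ray {k}; keeping the last (index {i})",
                stacklevel=2,
            )
        seen[k] = i
        out.forced[k, :] = 0
        out.forced[k, : i + 1] = 1
        out.forced[k, i + 1 :] = -1
    return out


def contour_from_cut(graph: RadialGraph, cut: CutResult) -> np.ndarray:
    """Closed polygon with one vertex per ray.

    The vertex sits at the radial midpoint between the outermost foreground
    node and the first background node; when the cut reaches the last node
    the vertex is at max_radius.
    """
    K, N = graph.shape
    h = graph.node_spacing
    radii = np.where(cut.cut_index == N - 1, N * h, (cut.cut_index + 1.5) * h)
    dirs = ray_directions(K)
    return np.array([graph.seed.x, graph.seed.y]) + radii[:, None] * dirs


def cut_to_mask(contour: np.ndarray, shape: tuple[int, int], spacing: float = 1.0) -> BinaryMask:
    """Rasterize a simple closed polygon: a pixel is foreground iff its
    center lies inside (half-open boundary rule via a +1e-9 nudge)."""
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[0] < 3:
        raise ValueError("need a simple closed polygon with >= 3 vertices")
    poly = shapely.Polygon(contour)
    if not poly.is_valid or poly.area == 0:
        poly = shapely.make_valid(poly)
    h, w = shape
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    inside = shapely.contains_xy(poly, xs.ravel() + 1e-9, ys.ravel() + 1e-9)
    return BinaryMask(inside.reshape(h, w).astype(np.uint8), spacing=spacing)


def segment(
    image: UltrasoundImage,
    seed: PointPx,
    helpers: list[HelperSeed] | None = None,
    params: GraphParams | None = None,
) -> SegmentationResult:
    """Full pipeline: build the radial graph, apply helper constraints,
    solve the min cut, and convert to contour, mask and diameters."""
    helpers = list(helpers or [])
    params = params or GraphParams()
    for helper in helpers:
        if not image.contains(helper.position):
            raise ValueError(f"helper {helper.position} outside image")
    graph = build_graph(image, seed, params)
    if helpers:
        graph = apply_helper_constraints(graph, helpers)
    cut = solve_min_cut(graph)
    contour = contour_from_cut(graph, cut)
    mask = cut_to_mask(contour, image.shape, spacing=image.spacing)
    if mask.area_px() > 0:
        dpair = diameters(mask, image.spacing)
        d_a, d_b = dpair.a, dpair.b
    else:  # contour thinner than a pixel: report the polygon extent instead
        d_a = d_b = float(2.0 * graph.node_spacing * image.spacing)
    return SegmentationResult(
        contour=contour,
        mask=mask,
        cut=cut,
        diameter_a=d_a,
        diameter_b=d_b,
        params=graph.params,
        seed=seed,
        helpers=tuple(helpers),
    )


def resegment(
    image: UltrasoundImage,
    previous: SegmentationResult,
    new_seed: PointPx | None = None,
    added_helpers: list[HelperSeed] | None = None,
) -> SegmentationResult:
    """Re-run with a dragged seed and/or extra helpers; referentially
    transparent: equivalent to a fresh ``segment`` with the merged inputs."""
    seed = new_seed if new_seed is not None else previous.seed
    helpers = list(previous.helpers) + list(added_helpers or [])
    return segment(image, seed, helpers, previous.params)
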