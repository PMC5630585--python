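"""Agreement and size measures for segmentation masks.

Dice similarity score (DSC, %), symmetric Hausdorff distance (px), caliper
diameters a/b (mm), a two-way absolute-agreement single-measure intraclass
correlation coefficient for inter-operator variability, and a percentile
bootstrap CI of the median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import directed_hausdorff

from .image_io import BinaryMask

__all__ = [
    "AgreementScores",
    "DiameterPair",
    "dice",
    "hausdorff",
    "diameters",
    "icc_dsc",
    "bootstrap_median_ci",
]


@dataclass(frozen=True)
class AgreementScores:
    """Per-case agreement between two segmentations of the same image."""

    dsc: float  # percent, 0..100
    hd: float  # pixels
    d_a_diff: float = float("nan")  # mm
    d_b_diff: float = float("nan")  # mm

    def __post_init__(self) -> None:
        if not 0.0 <= self.dsc <= 100.0:
            raise ValueError("DSC must be in [0, 100] percent")
        if self.hd < 0:
            raise ValueError("Hausdorff distance must be >= 0")


@dataclass(frozen=True)
class DiameterPair:
    """Largest caliper diameter ``a`` and the largest extent perpendicular
    to it, ``b``, both in mm, with the pixel-coordinate endpoints."""

    a: float
    b: float
    a_endpoints: tuple[tuple[float, float], tuple[float, float]]
    b_endpoints: tuple[tuple[float, float], tuple[float, float]]


def _check_shapes(mask_a: BinaryMask, mask_b: BinaryMask) -> None:
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"shape mismatch: {mask_a.shape} vs {mask_b.shape}")


def dice(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Dice similarity score in percent: 100 * 2|A∩B| / (|A|+|B|).

    100% is perfect overlap; two empty masks are defined as 100%.
    """
    _check_shapes(mask_a, mask_b)
    a, b = mask_a.pixels.astype(bool), mask_b.pixels.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 100.0
    return 100.0 * 2.0 * int((a & b).sum()) / denom


def hausdorff(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Symmetric Hausdorff distance in pixels over foreground pixel centers
    (Euclidean metric): max over both directed distances."""
    _check_shapes(mask_a, mask_b)
    pa = np.argwhere(mask_a.pixels)
    pb = np.argwhere(mask_b.pixels)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("Hausdorff distance undefined for an empty mask")
    return float(max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0]))


def _max_caliper(points: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Max pairwise Euclidean distance between points, via the convex hull
    when possible (the diameter of a set is attained on its hull)."""
    if len(points) > 3:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # noqa: BLE001 - degenerate (collinear) sets
            pass
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(int(d2.argmax()), d2.shape)
    return float(np.sqrt(d2[i, j])), points[i], points[j]


def diameters(mask: BinaryMask, spacing: float | None = None, projection_b: bool = False) -> DiameterPair:
    """Caliper diameters of a mask: ``a`` is the largest distance across the
    foreground, ``b`` the largest extent measured perpendicular to ``a``.

    Pixels count as unit squares, so one pixel is added to the extreme
    center-to-center distances (a single-pixel mask has a = b = spacing).
    By default ``b`` is the longest foreground chord along the perpendicular
    direction; ``projection_b=True`` uses the projection width of the whole
    foreground onto that axis instead.
    """
    if spacing is None:
        spacing = mask.spacing
    pts = np.argwhere(mask.pixels)[:, ::-1].astype(float)  # (x, y)
    if len(pts) == 0:
        raise ValueError("diameters undefined for an empty mask")
    dist, p, q = _max_caliper(pts)
    a = (dist + 1.0) * spacing
    if dist == 0.0:
        u = np.array([1.0, 0.0])
        v = np.array([0.0, 1.0])
    else:
        u = (q - p) / dist
        v = np.array([-u[1], u[0]])  # perpendicular direction
    along = pts @ u
    perp = pts @ v

    def _seg(c: float, p_lo: float, p_hi: float):
        # endpoints on the axis through along-coordinate c, exactly along v
        return (tuple(c * u + p_lo * v), tuple(c * u + p_hi * v))

    if projection_b:
        p_lo, p_hi = float(perp.min()), float(perp.max())
        b = (p_hi - p_lo + 1.0) * spacing
        b_ends = _seg(float(along.mean()), p_lo, p_hi)
    else:
        bins = np.rint(along - along.min()).astype(int)
        b, b_ends = 0.0, _seg(float(along[0]), float(perp[0]), float(perp[0]))
        order = np.argsort(bins, kind="stable")
        bounds = np.searchsorted(bins[order], np.arange(bins.max() + 2))
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e <= s:
                continue
            sel = order[s:e]
            p_lo, p_hi = float(perp[sel].min()), float(perp[sel].max())
            chord = (p_hi - p_lo + 1.0) * spacing
            if chord > b:
                b, b_ends = chord, _seg(float(along[sel].mean()), p_lo, p_hi)
    # chord/projection extents never exceed the max caliper, so a >= b holds
    return DiameterPair(a=a, b=b, a_endpoints=(tuple(p), tuple(q)), b_endpoints=b_ends)


def icc_dsc(scores_rater1, scores_rater2) -> float:
    """Intraclass correlation coefficient ICC(2,1): two-way random effects,
    absolute agreement, single measurement, from the cases x raters table.

    Used to estimate inter-operator variability of per-case DSC values.
    """
    y1 = np.asarray(scores_rater1, dtype=float)
    y2 = np.asarray(scores_rater2, dtype=float)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise ValueError("need two equal-length 1-D score lists")
    n = len(y1)
    if n < 2:
        raise ValueError("need at least 2 paired cases")
    table = np.stack([y1, y2], axis=1)  # n cases x k raters
    k = 2
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((table - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0  # all scores identical
    return float((msr - mse) / denom)


def bootstrap_median_ci(
    values, n_boot: int = 2000, seed: int | np.random.Generator = 0, level: float = 0.95
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the median: (median, lo, hi)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value list")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    meds = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(meds, [alpha, 1.0 - alpha])
    return float(np.median(values)), float(lo), float(hi)
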