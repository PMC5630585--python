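"""Synthetic B-mode speckle phantoms with known ground truth.

Each phantom is a hypoechoic, star-shaped lesion embedded in brighter
speckled "liver" tissue, optionally surrounded by an echo-poor halo of
intermediate echogenicity. The speckle model is the standard multi-look
B-mode approximation: per look, an i.i.d. circular complex Gaussian field
is blurred coherently by a Gaussian point-spread function, its intensity
(magnitude squared) taken, and the L look intensities averaged; because the
PSF acts on the complex field, the per-pixel intensity stays exponential
and the L-look average keeps the theoretical coefficient of variation
1/sqrt(L). The averaged intensity is multiplied by the echogenicity map,
log-compressed and linearly mapped to 8-bit gray.

The suite sampler emulates the clinical material the method targets: lesion
maximal diameters follow a piecewise log-linear distribution through the
quantile anchors 6 / 14 / 20 / 27 / 115 mm (min / Q1 / median / Q3 / max),
and the on-screen zoom varies per case so lesions span roughly 30-250 px.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import BinaryMask, PointPx, UltrasoundImage
from .interactive_segmentation import cut_to_mask

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "multilook_speckle",
    "generate_phantom",
    "generate_suite",
    "DIAMETER_ANCHORS_MM",
]

# Quantile anchors of the clinical lesion-size distribution (mm):
# (cumulative probability, maximal diameter)
DIAMETER_ANCHORS_MM: tuple[tuple[float, float], ...] = (
    (0.0, 6.0),
    (0.25, 14.0),
    (0.5, 20.0),
    (0.75, 27.0),
    (1.0, 115.0),
)

# on-screen lesion span (px) at the smallest / largest lesion diameter
_PX_SPAN = (30.0, 250.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic lesion image.

    ``boundary_harmonics`` is a list of (amplitude fraction <= 0.25,
    integer frequency 2..6, phase) triples deforming the circular boundary:
    r(theta) = base_radius * (1 + sum amp * sin(freq*theta + phase)).
    ``lesion_gain`` < 1 makes the lesion hypoechoic; ``halo_gain`` sets the
    echogenicity of an optional echo-poor rim of ``halo_width`` px.
    """

    image_size: int = 256
    spacing: float = 1.0
    center: tuple[float, float] | None = None
    base_radius: float = 60.0
    boundary_harmonics: tuple[tuple[float, int, float], ...] = ()
    lesion_gain: float = 0.25
    halo_width: float = 0.0
    halo_gain: float = 0.7
    psf_sigma: float = 1.5
    speckle_looks: int = 24
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.lesion_gain < 1.0:
            raise ValueError("lesion_gain must be in (0,1): lesion is hypoechoic")
        if not 0.0 < self.halo_gain <= 1.0:
            raise ValueError("halo_gain must be in (0,1]")
        if self.halo_width < 0:
            raise ValueError("halo_width must be >= 0")
        if self.speckle_looks < 1:
            raise ValueError("speckle_looks must be >= 1")
        amp_sum = sum(a for a, _, _ in self.boundary_harmonics)
        if self.base_radius * (1.0 - amp_sum) <= 0:
            raise ValueError("boundary radius must stay positive at all angles")
        for a, f, _ in self.boundary_harmonics:
            if a < 0 or a > 0.25:
                raise ValueError("harmonic amplitude fraction must be in [0, 0.25]")
            if not 2 <= int(f) <= 6:
                raise ValueError("harmonic frequency must be an integer in 2..6")

    def radius_at(self, theta: np.ndarray) -> np.ndarray:
        r = np.ones_like(np.asarray(theta, dtype=float))
        for amp, freq, phase in self.boundary_harmonics:
            r = r + amp * np.sin(freq * np.asarray(theta) + phase)
        return self.base_radius * r

    @property
    def center_point(self) -> PointPx:
        if self.center is None:
            c = (self.image_size - 1) / 2.0
            return PointPx(c, c)
        return PointPx(*self.center)


@dataclass
class PhantomCase:
    """Generated phantom: image, pre-log intensity, and ground truth."""

    image: UltrasoundImage
    truth_mask: BinaryMask
    truth_contour: np.ndarray
    spec: PhantomSpec
    intensity: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def multilook_speckle(
    shape: tuple[int, int], looks: int, psf_sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """L-look intensity speckle field with unit mean.

    Each look blurs an i.i.d. complex Gaussian field coherently with the
    PSF before detection, so the marginal intensity stays exponential and
    the L-look average has coefficient of variation 1/sqrt(L).
    """
    acc = np.zeros(shape)
    for _ in range(looks):
        re = rng.standard_normal(shape)
        im = rng.standard_normal(shape)
        if psf_sigma > 0:
            # periodic boundaries keep the field exactly stationary, so the
            # spatial sample CV matches the ensemble 1/sqrt(L) law
            re = gaussian_filter(re, psf_sigma, mode="wrap")
            im = gaussian_filter(im, psf_sigma, mode="wrap")
        acc += re * re + im * im
    acc /= acc.mean()
    return acc


def _echogenicity_map(spec: PhantomSpec, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    c = spec.center_point
    ys, xs = np.mgrid[0:h, 0:w]
    dx, dy = xs - c.x, ys - c.y
    rr = np.hypot(dx, dy)
    theta = np.arctan2(dx, -dy) % (2 * np.pi)  # clockwise from 'up'
    r_lesion = spec.radius_at(theta)
    emap = np.ones(shape)
    if spec.halo_width > 0:
        emap[rr <= r_lesion + spec.halo_width] = spec.halo_gain
    emap[rr <= r_lesion] = spec.lesion_gain
    return emap


def truth_polygon(spec: PhantomSpec, n_vertices: int = 720, include_halo: bool = False) -> np.ndarray:
    """Ground-truth lesion boundary as a closed polygon (x, y vertices)."""
    theta = 2 * np.pi * np.arange(n_vertices) / n_vertices
    r = spec.radius_at(theta)
    if include_halo:
        r = r + spec.halo_width
    c = spec.center_point
    return np.stack([c.x + r * np.sin(theta), c.y - r * np.cos(theta)], axis=1)


def generate_phantom(spec: PhantomSpec, include_halo_in_truth: bool = False) -> PhantomCase:
    """Render one phantom deterministically from its spec.

    ``include_halo_in_truth`` widens the ground truth to the outer halo
    edge (the reading under which the echo-poor rim belongs to the lesion);
    by default the truth stops at the lesion proper.
    """
    shape = (spec.image_size, spec.image_size)
    rng = np.random.default_rng(spec.rng_seed)
    speckle = multilook_speckle(shape, spec.speckle_looks, spec.psf_sigma, rng)
    intensity = speckle * _echogenicity_map(spec, shape)
    # log compression: dynamic-range mapping of intensity to 8-bit display gray
    compressed = np.log1p(50.0 * intensity)
    gray = np.rint(255.0 * compressed / compressed.max()).astype(np.uint8)
    image = UltrasoundImage(
        gray, spacing=spec.spacing, source_id=f"phantom-{spec.rng_seed}"
    )
    contour = truth_polygon(spec, include_halo=include_halo_in_truth)
    mask = cut_to_mask(contour, shape, spacing=spec.spacing)
    return PhantomCase(
        image=image, truth_mask=mask, truth_contour=contour, spec=spec, intensity=intensity
    )


def sample_diameter_mm(u: np.ndarray) -> np.ndarray:
    """Map uniform(0,1) draws to lesion diameters (mm) by piecewise
    log-linear interpolation through the clinical quantile anchors."""
    ps = np.array([p for p, _ in DIAMETER_ANCHORS_MM])
    logd = np.log([d for _, d in DIAMETER_ANCHORS_MM])
    return np.exp(np.interp(u, ps, logd))


def _zoom_px(d_mm: float) -> float:
    """On-screen lesion span in px for a given diameter: log interpolation
    between the smallest and largest clinical zoom."""
    lo, hi = math.log(DIAMETER_ANCHORS_MM[0][1]), math.log(DIAMETER_ANCHORS_MM[-1][1])
    f = (math.log(d_mm) - lo) / (hi - lo)
    return _PX_SPAN[0] + f * (_PX_SPAN[1] - _PX_SPAN[0])


def spec_for_case(case_seed: int, rng: np.random.Generator) -> PhantomSpec:
    """Draw one phantom spec from the documented suite distribution."""
    d_mm = float(sample_diameter_mm(rng.uniform()))
    span_px = _zoom_px(d_mm)
    base_radius = span_px / 2.0
    image_size = max(64, int(math.ceil(span_px * 1.9)))
    n_harm = int(rng.integers(1, 3))
    harmonics = tuple(
        (float(rng.uniform(0.02, 0.12)), int(rng.integers(2, 7)), float(rng.uniform(0, 2 * np.pi)))
        for _ in range(n_harm)
    )
    has_halo = rng.uniform() < 0.3
    # off-center jitter keeps the lesion fully inside the field of view
    c0 = (image_size - 1) / 2.0
    jitter = 0.05 * image_size
    center = (c0 + float(rng.uniform(-jitter, jitter)), c0 + float(rng.uniform(-jitter, jitter)))
    return PhantomSpec(
        image_size=image_size,
        spacing=d_mm / span_px,
        center=center,
        base_radius=base_radius,
        boundary_harmonics=harmonics,
        lesion_gain=float(rng.uniform(0.10, 0.35)),
        halo_width=float(rng.uniform(2.0, 6.0)) if has_halo else 0.0,
        halo_gain=float(rng.uniform(0.55, 0.8)),
        psf_sigma=float(rng.uniform(1.0, 2.0)),
        speckle_looks=int(rng.integers(16, 33)),
        rng_seed=case_seed,
    )


def generate_suite(n_cases: int, master_seed: int, lazy: bool = False):
    """Deterministic list of phantom cases (or specs when ``lazy``).

    Per-case seeds and spec draws derive from ``master_seed`` alone, so the
    same master seed always reproduces the identical suite bit for bit.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(master_seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=n_cases)
    specs = [spec_for_case(int(s), rng) for s in case_seeds]
    if lazy:
        return specs
    return [generate_phantom(spec) for spec in specs]
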