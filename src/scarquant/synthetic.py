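"""Synthetic stained-section generator with exact ground truth.

Emulates scanned heart sections for each staining technique: a near-white
slide background, a tissue region in the stain's normal palette, an embedded
infarct region (compact blobs) or scattered fibrotic pixels (diffuse mode) in
the stain's infarct palette, per-pixel Gaussian noise, and optional bubble
artifacts. Palette anchors are the printed example values for each stain, so
a noise-free fixture sits strictly on the correct side of every default
threshold. Ground-truth masks are the exact painted regions before noise.

Stack generation samples a 3-D infarct geometry (spherical cap or cylinder)
at serial-section planes and returns the analytic volumes of the continuous
geometry, so the serial-section volume estimator can be validated against a
closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from scarquant.image_io import validate_rgb
from scarquant.mask_ops import ROI

BACKGROUND = (245, 245, 245)

#: Per-stain class palettes. The channels each stain's rule keys on anchor to
#: the printed example pixels (MTS R 41/251; TTC (133,136,134)/(187,69,61);
#: PSR (240,129,143)/(204,191,174); H&E G 174/99).
PALETTES = {
    "mts": {"normal": (251, 120, 120), "infarct": (41, 80, 200)},
    "ttc": {"normal": (187, 69, 61), "infarct": (133, 136, 134)},
    "psr": {"normal": (204, 191, 174), "infarct": (240, 129, 143)},
    "he": {"normal": (170, 99, 160), "infarct": (140, 174, 150), "speckle": (120, 185, 130)},
}
BUBBLE_COLOR = (210, 208, 211)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic section.

    The tissue region is an ellipse (or annulus, mimicking a ventricular
    cross-section) centered in the image; the infarct is a set of circular
    blobs, or — in diffuse mode — a Bernoulli sprinkle of single fibrotic
    pixels at ``diffuse_fraction`` of the tissue. ``noise_sd`` is the per
    channel Gaussian noise level (clipped to [0, 255]).
    """

    stain: str = "mts"
    height: int = 160
    width: int = 160
    tissue_shape: str = "ellipse"  # "ellipse" | "annulus"
    tissue_axes: tuple[float, float] | None = None  # semi-axes (rows, cols)
    annulus_inner_frac: float = 0.45
    blobs: tuple[tuple[float, float, float], ...] | None = None  # (row, col, radius)
    diffuse_fraction: float | None = None
    speckle_fraction: float = 0.01  # H&E only: sparse green in normal tissue
    speckle_guard: int = 8  # px kept speckle-free around the infarct border
    noise_sd: float = 8.0
    artifacts: tuple[tuple[int, int, int, int], ...] = ()  # bubble ROIs (t, l, b, r)
    palette: dict = field(default_factory=dict)
    seed: int = 0

    def resolved_palette(self) -> dict:
        pal = dict(PALETTES[self.stain])
        pal.update(self.palette)
        return pal


@dataclass(frozen=True)
class SectionFixture:
    """A generated section with its exact ground truth."""

    image: np.ndarray
    truth_infarct: np.ndarray
    truth_tissue: np.ndarray
    spec: FixtureSpec

    @property
    def infarct_pixels(self) -> int:
        return int(self.truth_infarct.sum())

    @property
    def tissue_pixels(self) -> int:
        return int(self.truth_tissue.sum())

    @property
    def truth_fraction_pct(self) -> float:
        return 100.0 * self.infarct_pixels / self.tissue_pixels


def _tissue_geometry(spec: FixtureSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = spec.tissue_axes or (0.4 * h, 0.4 * w)
    yy, xx = np.ogrid[:h, :w]
    rho2 = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    tissue = rho2 <= 1.0
    if spec.tissue_shape == "annulus":
        tissue &= rho2 >= spec.annulus_inner_frac**2
    elif spec.tissue_shape != "ellipse":
        raise ValueError(f"unknown tissue shape {spec.tissue_shape!r}")
    return tissue


def _blob_mask(spec: FixtureSpec, blobs) -> np.ndarray:
    h, w = spec.height, spec.width
    yy, xx = np.ogrid[:h, :w]
    mask = np.zeros((h, w), bool)
    for row, col, radius in blobs:
        mask |= (yy - row) ** 2 + (xx - col) ** 2 <= radius**2
    return mask


def make_section(spec: FixtureSpec) -> SectionFixture:
    """Render one section; deterministic for a given ``spec.seed``."""
    if spec.stain not in PALETTES:
        raise ValueError(f"unknown stain {spec.stain!r}")
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(spec.seed)
    pal = spec.resolved_palette()
    tissue = _tissue_geometry(spec)

    if spec.diffuse_fraction is not None:
        if not (0 <= spec.diffuse_fraction <= 1):
            raise ValueError("diffuse_fraction must be in [0, 1]")
        infarct = np.zeros_like(tissue)
        infarct[tissue] = rng.random(int(tissue.sum())) < spec.diffuse_fraction
    else:
        blobs = spec.blobs
        if blobs is None:
            h, w = spec.height, spec.width
            blobs = (((h - 1) / 2.0, (w - 1) / 2.0, 0.15 * min(h, w)),)
        infarct = _blob_mask(spec, blobs)
        if (infarct & ~tissue).any():
            raise ValueError("infarct blobs extend outside the tissue region")

    img = np.empty((spec.height, spec.width, 3), np.float64)
    img[:] = BACKGROUND
    img[tissue] = pal["normal"]
    img[infarct] = pal["infarct"]

    if spec.stain == "he" and spec.speckle_fraction > 0:
        # speckle models sparse green away from the scar; a guard band keeps
        # the painted truth unambiguous at the infarct border
        from scipy import ndimage

        forbidden = infarct
        if spec.speckle_guard > 0 and infarct.any():
            forbidden = ndimage.binary_dilation(infarct, iterations=spec.speckle_guard)
        normal = tissue & ~forbidden
        speckle = np.zeros_like(tissue)
        speckle[normal] = rng.random(int(normal.sum())) < spec.speckle_fraction
        img[speckle] = pal["speckle"]

    for t, l, b, r in spec.artifacts:
        ROI(t, l, b, r).check_within((spec.height, spec.width))
        img[t:b, l:r] = BUBBLE_COLOR
        infarct = infarct.copy()
        infarct[t:b, l:r] = False

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SectionFixture(image=validate_rgb(image), truth_infarct=infarct, truth_tissue=tissue, spec=spec)


@dataclass(frozen=True)
class StackFixture:
    """Serial-section fixture set plus the analytic volumes of its geometry."""

    sections: tuple[SectionFixture, ...]
    section_thickness: float  # h1, µm
    removed_thickness: float  # h2, µm
    pixel_size: float  # µm/pixel
    geometry: str
    analytic_infarct_volume_mm3: float
    analytic_tissue_volume_mm3: float


def make_stack(
    spec: FixtureSpec,
    n_sections: int = 80,
    geometry: str = "spherical-cap",
    section_thickness: float = 5.0,
    removed_thickness: float = 10.0,
    pixel_size: float = 5.0,
    cap_sphere_radius_um: float = 500.0,
    cap_height_um: float = 900.0,
    cylinder_radius_um: float = 300.0,
) -> StackFixture:
    """Sample a 3-D infarct geometry at serial-section planes.

    Sections of thickness h1 alternate with removed slabs of thickness h2;
    the infarct cross-section is evaluated at each section's mid-depth. The
    spherical cap (height h_c of a sphere of radius R, apex at depth 0) has
    analytic volume π·h_c²·(R − h_c/3); the cylinder's analytic volume is its
    painted cross-section extruded over the full stack depth, which the
    per-section volume sum reproduces exactly. The tissue is a constant
    ellipse, an extruded prism over the painted cross-section.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    if geometry not in ("spherical-cap", "cylinder"):
        raise ValueError(f"unknown geometry {geometry!r}")
    h1, h2 = section_thickness, removed_thickness
    pitch = h1 + h2
    depth_um = n_sections * pitch
    if geometry == "spherical-cap" and cap_height_um > depth_um:
        raise ValueError("cap height exceeds the sampled stack depth")
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_sections) % (2**31)

    sections = []
    for i in range(n_sections):
        z = i * pitch + h1 / 2.0  # mid-depth of the stained section
        if geometry == "cylinder":
            r_um = cylinder_radius_um
        else:
            z0 = cap_height_um - cap_sphere_radius_um  # sphere center depth
            inside = cap_sphere_radius_um**2 - (z - z0) ** 2
            r_um = math.sqrt(inside) if (inside > 0 and z <= cap_height_um) else 0.0
        r_px = r_um / pixel_size
        blobs = ((cy, cx, r_px),) if r_px > 0 else ()
        sections.append(make_section(replace(spec, blobs=blobs, seed=int(seeds[i]))))

    tissue_area_mm2 = sections[0].tissue_pixels * pixel_size**2 / 1e6
    analytic_tissue = tissue_area_mm2 * depth_um / 1e3
    if geometry == "cylinder":
        infarct_area_mm2 = sections[0].infarct_pixels * pixel_size**2 / 1e6
        analytic_infarct = infarct_area_mm2 * depth_um / 1e3
    else:
        hc, rr = cap_height_um, cap_sphere_radius_um
        analytic_infarct = math.pi * hc**2 * (rr - hc / 3.0) / 1e9
    return StackFixture(
        sections=tuple(sections),
        section_thickness=h1,
        removed_thickness=h2,
        pixel_size=pixel_size,
        geometry=geometry,
        analytic_infarct_volume_mm3=analytic_infarct,
        analytic_tissue_volume_mm3=analytic_tissue,
    )


def render_slide(spec: FixtureSpec, n_sections: int = 5, gap: int = 16):
    """Compose several sections vertically on one slide-scan canvas.

    Returns ``(slide_image, boundaries, fixtures)`` where the boundaries are
    equal-height bands each containing exactly one section, so splitting the
    slide recovers every section image bit-exactly.
    """
    from scarquant.image_io import SplitBoundary

    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_sections) % (2**31)
    fixtures = [make_section(replace(spec, seed=int(s))) for s in seeds]
    band = spec.height + gap
    total = n_sections * band + gap
    canvas = np.empty((total, spec.width, 3), np.uint8)
    canvas[:] = np.asarray(BACKGROUND, np.uint8)
    boundaries = []
    for i, fx in enumerate(fixtures):
        top = gap + i * band
        canvas[top : top + spec.height] = fx.image
        boundaries.append(SplitBoundary(i * band, (i + 1) * band if i < n_sections - 1 else total))
    return canvas, boundaries, fixtures
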