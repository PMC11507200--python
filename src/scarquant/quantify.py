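"""Infarct size, physical area and serial-section volume arithmetic.

From pixel counts and scan geometry:

* relative infarct size (%) = 100 · infarct pixels / tissue pixels,
* physical area (mm²) = Px² · pixel count, with Px in µm/pixel,
* serial-section volumes: each stained section of thickness h1 contributes
  V_si = A_si · h1, and the tissue removed between sections (thickness h2) is
  assumed to carry the same cross-section, contributing V_rsi = A_si · h2;
  totals are summed over sections and the relative infarct volume is
  100 · V_Ts / V_Tt.

Diffuse-fibrosis quantification reuses the Masson's-trichrome blue rule on a
whole section with no minimum-component filtering (diffuse fibrosis is sparse
by nature) and reports the fibrotic fraction of the tissue area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scarquant.classifiers import StainParams, classify_mts, tissue_mask
from scarquant.mask_ops import isolate

UM2_PER_MM2 = 1e6
UM_PER_MM = 1e3


class UndefinedMeasurementError(ValueError):
    """Raised when a ratio is requested over an empty tissue region."""


@dataclass(frozen=True)
class SectionMeasurement:
    """Pixel counts and pixel size for one stained section.

    infarct_pixels : ∑P_s, pixels classified infarct
    tissue_pixels : ∑P_t, pixels in the entire (tissue-masked) section
    pixel_size : Px, µm per pixel side (pixels are assumed square)
    """

    infarct_pixels: int
    tissue_pixels: int
    pixel_size: float

    def __post_init__(self) -> None:
        if self.infarct_pixels < 0 or self.tissue_pixels < 0:
            raise ValueError("pixel counts must be non-negative")
        if self.infarct_pixels > self.tissue_pixels:
            raise ValueError("infarct pixels cannot exceed tissue pixels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def infarct_area_mm2(self) -> float:
        return physical_area(self.infarct_pixels, self.pixel_size)

    @property
    def tissue_area_mm2(self) -> float:
        return physical_area(self.tissue_pixels, self.pixel_size)


def relative_infarct_pct(m: SectionMeasurement) -> float:
    """Relative infarct size: 100 · infarct pixels / tissue pixels (%)."""
    if m.tissue_pixels == 0:
        raise UndefinedMeasurementError("relative infarct size is undefined for an empty section")
    return 100.0 * m.infarct_pixels / m.tissue_pixels


def relative_volume_pct(infarct_volume: float, tissue_volume: float) -> float:
    """Relative infarct volume: 100 · V_Ts / V_Tt (%)."""
    if tissue_volume <= 0:
        raise UndefinedMeasurementError("relative volume is undefined for non-positive tissue volume")
    return 100.0 * infarct_volume / tissue_volume


def physical_area(pixels: int, pixel_size: float) -> float:
    """Area in mm² of ``pixels`` square pixels of side ``pixel_size`` µm."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if pixels < 0:
        raise ValueError("pixel count must be non-negative")
    return pixel_size * pixel_size * pixels / UM2_PER_MM2


@dataclass(frozen=True)
class VolumeStack:
    """Ordered serial sections (apex-to-base or base-to-apex) with thicknesses.

    section_thickness : h1, µm, thickness of each stained section
    removed_thickness : h2, µm, tissue discarded between consecutive sections
    """

    sections: tuple[SectionMeasurement, ...]
    section_thickness: float
    removed_thickness: float = 0.0

    def __init__(self, sections, section_thickness: float, removed_thickness: float = 0.0) -> None:
        object.__setattr__(self, "sections", tuple(sections))
        object.__setattr__(self, "section_thickness", float(section_thickness))
        object.__setattr__(self, "removed_thickness", float(removed_thickness))
        if not self.sections:
            raise ValueError("a volume stack needs at least one section")
        if self.section_thickness <= 0:
            raise ValueError("section_thickness (h1) must be > 0")
        if self.removed_thickness < 0:
            raise ValueError("removed_thickness (h2) must be >= 0")


def stack_volumes(stack: VolumeStack, gap_policy: str = "per-section") -> dict:
    """Total infarct and tissue volumes (mm³) and relative infarct volume (%).

    Per section i: V_si = A_si·h1 and V_rsi = A_si·h2 (areas from
    :func:`physical_area`, thicknesses in µm). Gap policy:

    ``"per-section"`` (default)
        every section carries one removed-tissue gap, V_total = Σ A_i·(h1+h2);
    ``"n-1"``
        removed tissue is attributed only between consecutive sections, so the
        last section contributes A_n·h1 only.
    """
    if gap_policy not in ("per-section", "n-1"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    h1 = stack.section_thickness / UM_PER_MM  # mm
    h2 = stack.removed_thickness / UM_PER_MM
    n = len(stack.sections)
    per_section = []
    v_ts = v_tt = 0.0
    for i, m in enumerate(stack.sections):
        gap = h2 if (gap_policy == "per-section" or i < n - 1) else 0.0
        v_si = m.infarct_area_mm2 * h1
        v_rsi = m.infarct_area_mm2 * gap
        v_ti = m.tissue_area_mm2 * h1
        v_rti = m.tissue_area_mm2 * gap
        v_ts += v_si + v_rsi
        v_tt += v_ti + v_rti
        per_section.append(
            {
                "index": i,
                "infarct_area_mm2": m.infarct_area_mm2,
                "tissue_area_mm2": m.tissue_area_mm2,
                "infarct_volume_mm3": v_si + v_rsi,
                "tissue_volume_mm3": v_ti + v_rti,
            }
        )
    return {
        "infarct_volume_mm3": v_ts,
        "tissue_volume_mm3": v_tt,
        "relative_volume_pct": relative_volume_pct(v_ts, v_tt),
        "gap_policy": gap_policy,
        "sections": per_section,
    }


@dataclass(frozen=True)
class FibrosisResult:
    """Outcome of diffuse-fibrosis analysis on one MTS section."""

    fibrosis_pct: float
    fibrotic_pixels: int
    tissue_pixels: int
    fibrosis_mask: np.ndarray = field(compare=False)
    isolated_image: np.ndarray = field(compare=False)


def fibrosis_analysis(image: np.ndarray, params: StainParams | None = None) -> FibrosisResult:
    """Quantify diffuse fibrosis in a Masson's-trichrome section.

    Applies the MTS blue rule per pixel with no minimum-component filtering
    (diffuse fibrosis is scattered single fibers, not a compact scar) and
    reports 100 · fibrotic pixels / tissue pixels together with the isolated
    fibrosis image (fibrotic pixels at original color on white).
    """
    params = params or StainParams.for_stain("mts")
    if params.stain != "mts":
        raise ValueError("fibrosis analysis is supported for MTS sections only")
    tissue = tissue_mask(image, params)
    tissue_pixels = int(tissue.sum())
    if tissue_pixels == 0:
        raise UndefinedMeasurementError("no tissue found; fibrosis fraction is undefined")
    mask = classify_mts(image, params, tissue=tissue)
    fibrotic = int(mask.sum())
    return FibrosisResult(
        fibrosis_pct=100.0 * fibrotic / tissue_pixels,
        fibrotic_pixels=fibrotic,
        tissue_pixels=tissue_pixels,
        fibrosis_mask=mask,
        isolated_image=isolate(image, mask),
    )


def fibrosis_pct(image: np.ndarray, params: StainParams | None = None) -> float:
    """Diffuse-fibrosis percentage of the tissue area (MTS sections)."""
    return fibrosis_analysis(image, params).fibrosis_pct
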