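"""Ground-truth tissue phantom: a coronal spinal-cord section with a focal
demyelinating lesion.

The phantom is parametric rather than anatomically traced: the cord
cross-section is an ellipse on a background, the ventral grey matter a
horizontal band inside it, and the lesion an ellipse (core) wrapped in a
ring (peri-lesion) placed in the dorsal white matter.  This keeps the
ground truth exact and regeneration trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BACKGROUND", "GREY_MATTER", "WHITE_MATTER", "PERI_LESION", "LESION_CORE",
    "REGION_NAMES", "REGION_CODES", "GeometryParams", "TissuePhantom",
    "InvalidGeometryError", "default_geometry", "build_phantom",
]

BACKGROUND = 0
GREY_MATTER = 1
WHITE_MATTER = 2
PERI_LESION = 3
LESION_CORE = 4

REGION_NAMES = {
    BACKGROUND: "background",
    GREY_MATTER: "grey_matter",
    WHITE_MATTER: "white_matter",
    PERI_LESION: "peri_lesion",
    LESION_CORE: "lesion_core",
}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}


class InvalidGeometryError(ValueError):
    """Lesion geometry that does not fit inside the tissue area."""


@dataclass(frozen=True)
class GeometryParams:
    """All lengths in pixels; centres as (row, col)."""

    tissue_center: tuple[float, float]
    tissue_axes: tuple[float, float]      # (row semi-axis, col semi-axis)
    grey_band_start: float                # rows >= this (inside tissue) are grey matter
    lesion_center: tuple[float, float]
    lesion_axes: tuple[float, float]      # core semi-axes; (0, 0) -> no lesion
    ring_thickness: float = 3.0           # peri-lesion ring width


@dataclass(frozen=True)
class TissuePhantom:
    labels: np.ndarray                    # (height, width) int8 region codes
    geometry: GeometryParams
    pixel_size_um: float = 10.0

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def region_mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def region_counts(self) -> dict:
        return {REGION_NAMES[c]: int((self.labels == c).sum()) for c in REGION_NAMES}


def default_geometry(width: int, height: int) -> GeometryParams:
    """Desk-scale default: cord ellipse covering ~60% of the raster, ventral
    grey band, dorsal lesion with a 3-px peri-lesion ring."""
    return GeometryParams(
        tissue_center=(height / 2.0, width / 2.0),
        tissue_axes=(height * 0.42, width * 0.46),
        grey_band_start=height * 0.70,
        lesion_center=(height * 0.33, width / 2.0),
        lesion_axes=(height * 0.105, width * 0.145),
        ring_thickness=max(2.0, height / 16.0),
    )


def _inside_ellipse(rr, cc, center, axes) -> np.ndarray:
    b, a = axes
    if b <= 0 or a <= 0:
        return np.zeros_like(rr, dtype=bool)
    return ((rr - center[0]) / b) ** 2 + ((cc - center[1]) / a) ** 2 <= 1.0


def build_phantom(width: int = 48, height: int = 48,
                  geometry: GeometryParams | None = None,
                  seed: int = 0, pixel_size_um: float = 10.0) -> TissuePhantom:
    """Build the label raster.  Deterministic given its arguments; ``seed``
    is accepted for interface symmetry with the simulator (the geometry
    itself is deterministic)."""
    if width < 16 or height < 16:
        raise ValueError("width and height must be >= 16 pixels")
    geo = geometry if geometry is not None else default_geometry(width, height)

    has_lesion = geo.lesion_axes[0] > 0 and geo.lesion_axes[1] > 0
    if has_lesion:
        ring_axes = (geo.lesion_axes[0] + geo.ring_thickness,
                     geo.lesion_axes[1] + geo.ring_thickness)
        # the outer ring ellipse must fit inside the tissue ellipse
        for dr, dc in ((ring_axes[0], 0), (-ring_axes[0], 0),
                       (0, ring_axes[1]), (0, -ring_axes[1])):
            r = geo.lesion_center[0] + dr
            c = geo.lesion_center[1] + dc
            v = (((r - geo.tissue_center[0]) / geo.tissue_axes[0]) ** 2
                 + ((c - geo.tissue_center[1]) / geo.tissue_axes[1]) ** 2)
            if v > 1.0:
                raise InvalidGeometryError(
                    f"lesion (with ring) extends outside the tissue ellipse at ({r:.1f}, {c:.1f})")

    rr, cc = np.mgrid[0:height, 0:width].astype(float)
    labels = np.full((height, width), BACKGROUND, dtype=np.int8)
    tissue = _inside_ellipse(rr, cc, geo.tissue_center, geo.tissue_axes)
    labels[tissue] = WHITE_MATTER
    labels[tissue & (rr >= geo.grey_band_start)] = GREY_MATTER
    if has_lesion:
        ring = _inside_ellipse(rr, cc, geo.lesion_center, ring_axes) & tissue
        core = _inside_ellipse(rr, cc, geo.lesion_center, geo.lesion_axes) & tissue
        labels[ring] = PERI_LESION
        labels[core] = LESION_CORE
    return TissuePhantom(labels=labels, geometry=geo, pixel_size_um=pixel_size_um)


def jitter_geometry(geo: GeometryParams, rng: np.random.Generator,
                    center_sd_px: float = 1.5, axis_rel_sd: float = 0.10) -> GeometryParams:
    """Lesion-to-lesion variability across sections: the lesion centre and
    axes are perturbed while the cord outline stays fixed."""
    dr, dc = rng.normal(0.0, center_sd_px, 2)
    fr, fc = np.exp(rng.normal(0.0, axis_rel_sd, 2))
    return replace(
        geo,
        lesion_center=(geo.lesion_center[0] + dr, geo.lesion_center[1] + dc),
        lesion_axes=(geo.lesion_axes[0] * fr, geo.lesion_axes[1] * fc),
    )
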