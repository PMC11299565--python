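"""Rendered glyphs that embed tabular clinical features into images.

Three prognostic features ride along with the brain content as visual
symbols, so a single-channel CNN sees both modalities at once:

* initial severity — a categorical shape (square=severe, triangle=moderate,
  cross=mild, ellipse=normal, star=unknown/unconscious);
* left-hemisphere lesion size — a filled regular pentagon whose radius is
  a linear map of the clipped value;
* recovery time — a pie slice of fixed geometry whose fill intensity is a
  linear map of the clipped value.

In stitched montages the glyphs occupy tiles surrendered by the four most
dorsal slices; in region images they occupy a dedicated panel strip below
the packed regions.  Rasterisation is 4× supersampled then box-averaged
(anti-aliased) and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from matplotlib.path import Path as MplPath

from .roi_image import ROIImage
from .stitch import StitchedImage, StitchLayout

__all__ = ["GlyphStyle", "NormalisationSpec", "HybridImage",
           "reserve_glyph_slots", "render_glyph", "embed_glyphs",
           "fit_normalisation"]

_SUPER = 4   # supersampling factor for anti-aliased rasterisation

DEFAULT_SHAPE_MAP = {"severe": "square", "moderate": "triangle",
                     "mild": "cross", "normal": "ellipse",
                     "unknown": "star"}


@dataclass(frozen=True)
class GlyphStyle:
    """Visual parameters for the three glyphs.

    Radii are fractions of the glyph slot's smaller dimension, so one style
    serves any slot size.  ``intensity_range`` maps recovery time into pie
    fill; its lower bound is kept above 0 so the symbol never vanishes.
    """

    severity_shape_map: dict = field(
        default_factory=lambda: dict(DEFAULT_SHAPE_MAP))
    pentagon_radius_range: tuple[float, float] = (0.12, 0.42)
    pie_radius: float = 0.40
    pie_angle_deg: float = 90.0
    intensity_range: tuple[float, float] = (0.2, 1.0)
    severity_radius: float = 0.35
    foreground: float = 1.0

    def __post_init__(self):
        r0, r1 = self.pentagon_radius_range
        i0, i1 = self.intensity_range
        if not (0 < r0 < r1):
            raise ValueError("need 0 < r_min < r_max")
        if not (0 <= i0 < i1 <= 1):
            raise ValueError("need 0 ≤ i_min < i_max ≤ 1")


@dataclass(frozen=True)
class NormalisationSpec:
    """Clip bounds and target channel for one continuous feature."""

    lower: float
    upper: float
    target: str        # "radius" or "intensity"

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("lower must be < upper")

    def unit(self, value: float) -> float:
        v = min(max(float(value), self.lower), self.upper)
        return (v - self.lower) / (self.upper - self.lower)


def fit_normalisation(values, target: str,
                      percentiles=(1.0, 99.0)) -> NormalisationSpec:
    """Clip bounds from training-split percentiles (lock box excluded)."""
    lo, hi = np.percentile(np.asarray(values, dtype=float), percentiles)
    if hi <= lo:
        hi = lo + 1.0
    return NormalisationSpec(float(lo), float(hi), target)


@dataclass(frozen=True)
class HybridImage:
    pixels: np.ndarray
    base_provenance: dict
    glyph_record: dict


def reserve_glyph_slots(layout: StitchLayout, n_slots: int = 4) -> StitchLayout:
    """Surrender the last ``n_slots`` tiles (the most dorsal slices) to glyphs.

    Under the frozen inferior→superior, row-major convention the last tiles
    hold the most dorsal selected slices, which are rarely lesioned; their
    slice indices are dropped and the tiles marked as glyph slots.
    """
    total = layout.grid[0] * layout.grid[1]
    if n_slots >= total:
        raise ValueError("cannot reserve every tile for glyphs")
    if n_slots == 0:
        return layout
    if layout.glyph_slots:
        raise ValueError("layout already has glyph slots")
    kept = layout.slice_indices[:len(layout.slice_indices) - n_slots]
    slots = tuple(range(total - n_slots, total))
    return replace(layout, slice_indices=kept, glyph_slots=slots)


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def _regular_polygon(n: int, radius: float, phase: float = -np.pi / 2):
    ang = phase + 2 * np.pi * np.arange(n) / n
    return np.stack([radius * np.cos(ang), radius * np.sin(ang)], axis=1)


def _star_vertices(radius: float, inner_frac: float = 0.45):
    ang = -np.pi / 2 + np.pi * np.arange(10) / 5
    r = np.where(np.arange(10) % 2 == 0, radius, inner_frac * radius)
    return np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)


def _shape_mask(shape_name: str, radius: float, xx: np.ndarray,
                yy: np.ndarray) -> np.ndarray:
    """Boolean membership of supersampled grid points in the symbol."""
    if shape_name == "square":
        s = radius / np.sqrt(2.0)
        return (np.abs(xx) <= s) & (np.abs(yy) <= s)
    if shape_name == "ellipse":
        return (xx / radius) ** 2 + (yy / (0.6 * radius)) ** 2 <= 1.0
    if shape_name == "cross":
        arm = 0.3 * radius
        return ((np.abs(xx) <= arm) & (np.abs(yy) <= radius)) | \
               ((np.abs(yy) <= arm) & (np.abs(xx) <= radius))
    if shape_name == "triangle":
        verts = _regular_polygon(3, radius)
    elif shape_name == "pentagon":
        verts = _regular_polygon(5, radius)
    elif shape_name == "star":
        verts = _star_vertices(radius)
    else:
        raise ValueError(f"unknown glyph shape {shape_name!r}")
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    return MplPath(verts).contains_points(pts).reshape(xx.shape)


def _supersampled_grid(patch_shape: tuple[int, int]):
    h, w = patch_shape
    ys = (np.arange(h * _SUPER) + 0.5) / _SUPER - h / 2
    xs = (np.arange(w * _SUPER) + 0.5) / _SUPER - w / 2
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return xx, yy


def _downsample(mask_or_vals: np.ndarray) -> np.ndarray:
    h, w = mask_or_vals.shape
    return mask_or_vals.reshape(h // _SUPER, _SUPER, w // _SUPER,
                                _SUPER).mean(axis=(1, 3))


def render_glyph(feature: str, value, style: GlyphStyle,
                 norm: NormalisationSpec | None,
                 patch_shape: tuple[int, int]) -> np.ndarray:
    """Rasterise one glyph onto a zero-background patch.

    ``feature`` ∈ {"initial_severity", "left_lesion_size", "recovery_time"}.
    Severity draws the mapped shape at fixed size and intensity; lesion
    size a pentagon with value-mapped radius; recovery time a fixed pie
    slice with value-mapped fill intensity.
    """
    h, w = patch_shape
    m = min(h, w)
    xx, yy = _supersampled_grid(patch_shape)

    if feature == "initial_severity":
        shape_map = style.severity_shape_map
        if value not in shape_map:
            raise ValueError(f"unknown severity category {value!r}")
        mask = _shape_mask(shape_map[value], style.severity_radius * m / 2,
                           xx, yy)
        return style.foreground * _downsample(mask.astype(np.float64))

    if feature == "left_lesion_size":
        if norm is None or norm.target != "radius":
            raise ValueError("lesion size needs a radius normalisation")
        if float(value) < 0:
            raise ValueError("lesion size must be ≥ 0")
        r0, r1 = style.pentagon_radius_range
        radius = (r0 + (r1 - r0) * norm.unit(value)) * m / 2
        mask = _shape_mask("pentagon", radius, xx, yy)
        return style.foreground * _downsample(mask.astype(np.float64))

    if feature == "recovery_time":
        if norm is None or norm.target != "intensity":
            raise ValueError("recovery time needs an intensity normalisation")
        if float(value) < 0:
            raise ValueError("recovery time must be ≥ 0")
        i0, i1 = style.intensity_range
        fill = i0 + (i1 - i0) * norm.unit(value)
        radius = style.pie_radius * m / 2
        theta = np.degrees(np.arctan2(-yy, xx)) % 360.0
        sector = (np.hypot(xx, yy) <= radius) & \
                 (theta >= 45.0) & (theta <= 45.0 + style.pie_angle_deg)
        return fill * _downsample(sector.astype(np.float64))

    raise ValueError(f"unknown feature {feature!r}")


# slot order is fixed and documented: severity, lesion size, recovery time
SLOT_ORDER = ("initial_severity", "left_lesion_size", "recovery_time")


def _glyph_boxes_for_base(base) -> list[tuple[int, int, int, int]]:
    """Three (row0, col0, h, w) glyph boxes for a stitched or ROI base."""
    if isinstance(base, StitchedImage):
        slots = base.layout.glyph_slots
        if len(slots) < 3:
            raise ValueError("stitched base needs ≥ 3 reserved glyph slots "
                             "(see reserve_glyph_slots)")
        return [base.layout.tile_box(t) for t in slots[:3]]
    if isinstance(base, ROIImage):
        reserved = int(base.provenance.get("reserved_bottom", 0))
        if reserved < 16:
            raise ValueError("ROI base needs a reserved bottom glyph panel "
                             "(compose with reserved_bottom ≥ 16)")
        h, w = base.pixels.shape
        r0 = h - reserved
        box_w = w // 3
        return [(r0, i * box_w, reserved, box_w) for i in range(3)]
    raise TypeError("base must be a StitchedImage or ROIImage")


def embed_glyphs(base, tabular, style: GlyphStyle,
                 norms: dict[str, NormalisationSpec]) -> HybridImage:
    """Draw the three tabular glyphs into the base image's glyph area.

    All pixels outside the three glyph boxes are bit-identical to the base.
    """
    boxes = _glyph_boxes_for_base(base)
    pixels = np.asarray(base.pixels, dtype=np.float64).copy()
    record = {"slots": [], "style": "default"}
    values = {"initial_severity": tabular.initial_severity,
              "left_lesion_size": tabular.left_lesion_size,
              "recovery_time": tabular.recovery_time}
    for feature, (r0, c0, h, w) in zip(SLOT_ORDER, boxes):
        patch = render_glyph(feature, values[feature], style,
                             norms.get(feature), (h, w))
        pixels[r0:r0 + h, c0:c0 + w] = patch
        record["slots"].append({"feature": feature, "box": [r0, c0, h, w],
                                "value": values[feature]})
    prov = getattr(base, "provenance", {})
    return HybridImage(pixels=np.clip(pixels, 0.0, 1.0),
                       base_provenance=dict(prov), glyph_record=record)
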