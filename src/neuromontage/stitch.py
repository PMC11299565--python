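"""2D stitched-montage construction from 3D normalised brain volumes.

A stitched image tiles a fixed, ordered subset of axial slices of one 3D
scan onto a single 2D canvas, so that a pixel location always corresponds
to the same brain location across subjects.  The standard layout is an 8×8
grid of 64 axial slices; for scans whose axial slices are 79×95 voxels the
canvas is exactly 632×760 pixels.  Before entering a CNN, canvases are
area-downsampled to 256×256.

Orientation convention (frozen, see docs/methods.md): the volume's third
axis runs inferior→superior; tiles are filled row-major from the top-left,
so the most dorsal selected slices occupy the last tiles of the grid —
those are the tiles later surrendered to glyph slots in hybrid images.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = ["StitchLayout", "StitchedImage", "default_layout", "stitch_volume",
           "preprocess_for_cnn", "canvas_index", "load_volume"]


@dataclass(frozen=True)
class StitchLayout:
    """Geometry of a slice montage.

    ``slice_indices`` index the volume's third (inferior→superior) axis in
    strictly increasing order; tile ``t`` of the row-major grid holds slice
    ``slice_indices[t]``.  ``glyph_slots`` are tile numbers reserved for
    rendered tabular symbols instead of brain content.
    """

    grid: tuple[int, int]
    tile_shape: tuple[int, int]
    slice_indices: tuple[int, ...]
    glyph_slots: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        rows, cols = self.grid
        if len(self.slice_indices) + len(self.glyph_slots) != rows * cols:
            raise ValueError("slice_indices + glyph_slots must fill the grid")
        idx = np.asarray(self.slice_indices)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("slice_indices must be strictly increasing")

    @property
    def n_slices(self) -> int:
        return len(self.slice_indices)

    @property
    def canvas_shape(self) -> tuple[int, int]:
        return (self.grid[0] * self.tile_shape[0],
                self.grid[1] * self.tile_shape[1])

    def content_tiles(self) -> list[int]:
        """Tile numbers that carry brain slices, in slice order."""
        slots = set(self.glyph_slots)
        return [t for t in range(self.grid[0] * self.grid[1])
                if t not in slots]

    def tile_box(self, tile: int) -> tuple[int, int, int, int]:
        """(row0, col0, height, width) of a tile on the canvas."""
        rows, cols = self.grid
        r, c = divmod(tile, cols)
        th, tw = self.tile_shape
        return r * th, c * tw, th, tw

    def to_json(self) -> str:
        return json.dumps({
            "grid": list(self.grid), "tile_shape": list(self.tile_shape),
            "slice_indices": list(self.slice_indices),
            "glyph_slots": list(self.glyph_slots)})

    @classmethod
    def from_json(cls, text: str) -> "StitchLayout":
        d = json.loads(text)
        return cls(grid=tuple(d["grid"]), tile_shape=tuple(d["tile_shape"]),
                   slice_indices=tuple(d["slice_indices"]),
                   glyph_slots=tuple(d.get("glyph_slots", [])))


@dataclass(frozen=True)
class StitchedImage:
    pixels: np.ndarray          # 2D float array in [0, 1]
    layout: StitchLayout
    provenance: dict

    def __post_init__(self):
        if self.pixels.shape != self.layout.canvas_shape:
            raise ValueError("pixels shape inconsistent with layout")


def default_layout(volume_shape: tuple[int, int, int], n_slices: int = 64,
                   grid: tuple[int, int] = (8, 8),
                   slice_indices: tuple[int, ...] | None = None
                   ) -> StitchLayout:
    """Standard montage layout: ``grid`` tiles of the volume's axial slices.

    Slices are picked evenly across the third-axis extent (the exact
    historical selection rule is not recoverable; pass ``slice_indices`` to
    reproduce a specific choice).  For 79×95 axial slices the 8×8 canvas is
    632×760.
    """
    x, y, z = volume_shape
    if n_slices != grid[0] * grid[1]:
        raise ValueError("n_slices must equal rows*cols of the grid")
    if slice_indices is None:
        if z < n_slices:
            raise ValueError(
                f"volume has {z} axial slices; {n_slices} requested")
        slice_indices = tuple(int(round(v))
                              for v in np.linspace(0, z - 1, n_slices))
    else:
        slice_indices = tuple(int(i) for i in slice_indices)
        if any(i < 0 or i >= z for i in slice_indices):
            raise ValueError("explicit slice index out of volume range")
    return StitchLayout(grid=grid, tile_shape=(x, y),
                        slice_indices=slice_indices)


def stitch_volume(volume: np.ndarray, layout: StitchLayout,
                  subject_id: str | None = None) -> StitchedImage:
    """Tile the selected axial slices onto one canvas, min-max normalised.

    Tile ``t`` (row-major) holds axial slice ``slice_indices`` entry ``t``
    among content tiles; glyph-slot tiles stay at background 0.  The whole
    volume is min-max scaled to [0, 1] before slicing so glyph intensities
    added later are comparable across subjects.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D")
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite intensities")
    vmin, vmax = volume.min(), volume.max()
    norm = (volume - vmin) / (vmax - vmin) if vmax > vmin \
        else np.zeros_like(volume)
    canvas = np.zeros(layout.canvas_shape)
    th, tw = layout.tile_shape
    for pos, tile in enumerate(layout.content_tiles()):
        z = layout.slice_indices[pos]
        sl = norm[:, :, z]
        if sl.shape != (th, tw):
            raise ValueError("axial slice shape does not match tile shape")
        r0, c0, _, _ = layout.tile_box(tile)
        canvas[r0:r0 + th, c0:c0 + tw] = sl
    prov = {"subject_id": subject_id,
            "volume_crc32": zlib.crc32(np.ascontiguousarray(volume).tobytes())}
    return StitchedImage(pixels=canvas, layout=layout, provenance=prov)


def canvas_index(layout: StitchLayout, slice_pos: int, ix: int, iy: int
                 ) -> tuple[int, int]:
    """Map (selected-slice position, in-slice voxel (ix, iy)) → canvas pixel."""
    tile = layout.content_tiles()[slice_pos]
    r0, c0, _, _ = layout.tile_box(tile)
    return r0 + ix, c0 + iy


def preprocess_for_cnn(image, side: int = 256) -> np.ndarray:
    """Area-interpolated resize of a montage to ``side``×``side`` in [0, 1].

    Accepts a stitched / ROI / hybrid image object (``.pixels``) or a bare
    2D array.  Area (box) averaging is used so constant regions survive and
    thin glyph strokes are averaged rather than dropped.
    """
    if side < 8:
        raise ValueError("side must be ≥ 8")
    pixels = getattr(image, "pixels", image)
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if pixels.shape == (side, side):
        return pixels.copy()
    h, w = pixels.shape
    if h % side == 0 and w % side == 0:
        # integer downscale factor: exact area average
        out = pixels.reshape(side, h // side, side, w // side).mean(
            axis=(1, 3))
        return np.clip(out, 0.0, 1.0)
    im = Image.fromarray(pixels.astype(np.float32), mode="F")
    out = im.resize((side, side), Image.Resampling.BOX)
    return np.clip(np.asarray(out, dtype=np.float64), 0.0, 1.0)


def load_volume(path) -> np.ndarray:
    """Read a NIfTI volume as a float array (nibabel)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64)
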