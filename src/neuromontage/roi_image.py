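"""Atlas-parcellated region images.

Instead of showing every axial slice, a region image packs only the
top-K most important anatomical regions — at native scan resolution — onto
one canvas.  K is chosen by cross-validation: for each candidate K and
learning rate the training protocol is run on images built from the top-K
regions of an importance ranking, and the K minimising the mean
class-weighted validation loss wins (never lock-box accuracy, which would
overfit the held-out test).

Two extraction paths exist for a region's 2D content:

* ``"native3d"`` (default): the axial slice on which the region has the
  greatest area, cropped to the region's bounding box in the original
  voxel grid — no resampling loss;
* ``"canvas"``: the region's footprint on the stitched montage canvas.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .stitch import StitchLayout

__all__ = ["RegionMaskSet", "ROIImage", "ROISweepResult", "project_atlas",
           "compose_roi_image", "extract_region_patches", "shelf_pack",
           "sweep_roi_count", "select_k_from_table"]


@dataclass(frozen=True)
class RegionMaskSet:
    """Per-region masks on the stitched canvas (a single label canvas)."""

    label_canvas: np.ndarray          # 2D int, 0 = background
    region_ids: tuple[int, ...]

    def mask(self, region_id: int) -> np.ndarray:
        if region_id not in self.region_ids:
            raise KeyError(f"region {region_id} not in mask set")
        return self.label_canvas == region_id

    def union_mask(self, region_ids=None) -> np.ndarray:
        ids = self.region_ids if region_ids is None else tuple(region_ids)
        return np.isin(self.label_canvas, ids)


@dataclass(frozen=True)
class ROIImage:
    pixels: np.ndarray                         # 2D float in [0, 1]
    region_ids: tuple[int, ...]                # importance order
    packing_boxes: dict                        # region id → (r0, c0, h, w)
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ROISweepResult:
    table: "object"        # DataFrame with columns K, learning_rate, val_loss
    selected_k: int


def project_atlas(atlas, layout: StitchLayout) -> RegionMaskSet:
    """Push the 3D atlas labels through the stitch layout onto the canvas.

    Every canvas pixel inside a content tile inherits the label of its
    source voxel; glyph-slot tiles and background stay 0.
    """
    label_volume = atlas.label_volume
    th, tw = layout.tile_shape
    if label_volume.shape[:2] != (th, tw):
        raise ValueError("atlas grid does not match layout tile shape")
    if max(layout.slice_indices) >= label_volume.shape[2]:
        raise ValueError("layout slice indices exceed atlas axial extent")
    canvas = np.zeros(layout.canvas_shape, dtype=np.int32)
    for pos, tile in enumerate(layout.content_tiles()):
        z = layout.slice_indices[pos]
        r0, c0, _, _ = layout.tile_box(tile)
        canvas[r0:r0 + th, c0:c0 + tw] = label_volume[:, :, z]
    present = tuple(int(v) for v in np.unique(canvas) if v != 0)
    return RegionMaskSet(label_canvas=canvas, region_ids=present)


def _crop_to_bbox(content: np.ndarray, mask: np.ndarray) -> np.ndarray:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    patch = np.where(mask, content, 0.0)[r0:r1 + 1, c0:c1 + 1]
    return patch


def extract_region_patches(source, masks_or_atlas, region_ids,
                           mode: str = "native3d") -> list[tuple[int, np.ndarray]]:
    """Cropped 2D content for each region, in the given order.

    ``mode="canvas"``: ``source`` is a 2D stitched canvas (or object with
    ``.pixels``) and ``masks_or_atlas`` a :class:`RegionMaskSet`.
    ``mode="native3d"``: ``source`` is the 3D volume and ``masks_or_atlas``
    the atlas; each region contributes its largest-area axial slice.
    """
    patches = []
    if mode == "canvas":
        canvas = np.asarray(getattr(source, "pixels", source), dtype=np.float64)
        for rid in region_ids:
            m = masks_or_atlas.mask(rid)
            if not m.any():
                raise ValueError(f"region {rid} has empty canvas footprint")
            patches.append((rid, _crop_to_bbox(canvas, m)))
    elif mode == "native3d":
        volume = np.asarray(source, dtype=np.float64)
        vmin, vmax = volume.min(), volume.max()
        norm = (volume - vmin) / (vmax - vmin) if vmax > vmin \
            else np.zeros_like(volume)
        labels = masks_or_atlas.label_volume
        for rid in region_ids:
            region3d = labels == rid
            if not region3d.any():
                raise ValueError(f"region {rid} empty in atlas")
            areas = region3d.sum(axis=(0, 1))
            z = int(areas.argmax())
            patches.append((rid, _crop_to_bbox(norm[:, :, z], region3d[:, :, z])))
    else:
        raise ValueError(f"unknown extraction mode {mode!r}")
    return patches


def shelf_pack(sizes: list[tuple[int, int]], canvas_shape: tuple[int, int],
               gutter: int = 2, reserved_bottom: int = 0
               ) -> list[tuple[int, int]]:
    """First-fit shelf packing, row-major, in the given order.

    Returns the (row0, col0) origin per item.  Raises if the items do not
    fit ``canvas_shape`` (less ``reserved_bottom`` rows).
    """
    max_r = canvas_shape[0] - reserved_bottom
    origins = []
    r = c = shelf_h = 0
    for h, w in sizes:
        if w > canvas_shape[1] or h > max_r:
            raise ValueError("region patch larger than canvas; "
                             "use a larger canvas")
        if c + w > canvas_shape[1]:          # new shelf
            r += shelf_h + gutter
            c = shelf_h = 0
        if r + h > max_r:
            raise ValueError("regions exceed canvas capacity; "
                             "use a larger canvas")
        origins.append((r, c))
        c += w + gutter
        shelf_h = max(shelf_h, h)
    return origins


def compose_roi_image(source, masks_or_atlas, region_ids,
                      canvas_shape: tuple[int, int], mode: str = "native3d",
                      gutter: int = 2, reserved_bottom: int = 0,
                      provenance: dict | None = None) -> ROIImage:
    """Pack the named regions' native-resolution crops onto a fresh canvas.

    Regions are placed by first-fit shelf packing in the order of
    ``region_ids`` (importance order); ``reserved_bottom`` rows can be kept
    free for a glyph panel in hybrid region images.
    """
    region_ids = tuple(int(r) for r in region_ids)
    if not region_ids:
        raise ValueError("region_ids must be nonempty")
    patches = extract_region_patches(source, masks_or_atlas, region_ids, mode)
    sizes = [p.shape for _, p in patches]
    origins = shelf_pack(sizes, canvas_shape, gutter, reserved_bottom)
    canvas = np.zeros(canvas_shape)
    boxes = {}
    for (rid, patch), (r0, c0) in zip(patches, origins):
        h, w = patch.shape
        canvas[r0:r0 + h, c0:c0 + w] = patch
        boxes[rid] = (int(r0), int(c0), int(h), int(w))
    prov = dict(provenance or {})
    prov["reserved_bottom"] = reserved_bottom
    return ROIImage(pixels=canvas, region_ids=region_ids,
                    packing_boxes=boxes, provenance=prov)


def content_hash(patch: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(patch).tobytes()).hexdigest()


def select_k_from_table(table) -> int:
    """argmin over K of (min over learning rates of mean validation loss)."""
    best = table.groupby("K")["val_loss"].min()
    return int(best.idxmin())


def sweep_roi_count(run_cell, importance_ranking,
                    k_range=range(3, 13),
                    learning_rates=(1e-4, 5e-4, 1e-5)) -> ROISweepResult:
    """Cross-validated choice of how many top regions to show.

    ``run_cell(top_k_region_ids, learning_rate)`` must run the training
    protocol on region images built from those regions and return the mean
    class-weighted validation loss across folds.  The returned table has
    one row per (K, learning rate) cell; ``selected_k`` minimises the
    per-K best loss.  Selection never touches lock-box metrics.
    """
    import pandas as pd

    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty K range")
    if len(importance_ranking) < max(k_range):
        raise ValueError("importance ranking shorter than max K")
    rows = []
    for k in k_range:
        top = tuple(importance_ranking[:k])
        for lr in learning_rates:
            rows.append({"K": k, "learning_rate": lr,
                         "val_loss": float(run_cell(top, lr))})
    table = pd.DataFrame(rows)
    return ROISweepResult(table=table, selected_k=select_k_from_table(table))
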