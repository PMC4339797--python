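"""Per-cell border polygons, 3D mask rasterization, and masking.

A cell region of interest (ROI) is a set of per-slice border polygons —
exactly the structure produced by tracing a cell outline slice by slice.
Stacking the filled polygons gives the cell's 3D binary mask; applying the
mask zeroes every voxel outside the cell border so downstream component
counting sees that cell only.

Conventions (fixed, stated once):

* Coordinates are 0-based; polygon vertices are ``(y, x)`` pixel coordinates
  in the slice plane; polygons are implicitly closed.
* A voxel belongs to the mask iff its integer-coordinate center lies inside
  (or exactly on the boundary of) that slice's polygon.
* z is handled strictly slice-by-slice — no interpolation between slices.

The interchange format is one JSON file per image:
``[{"cell_id": ..., "slices": {"<z>": [[y, x], ...], ...}}, ...]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon

from .image_io import ImageStack

__all__ = ["CellROI", "MaskVolume", "rasterize_roi", "apply_mask", "load_rois", "save_rois"]


@dataclass
class CellROI:
    """Border polygons for one cell, keyed by z-slice index."""

    cell_id: str
    slices: dict[int, np.ndarray]  # z -> (n_vertices, 2) array of (y, x)

    def __post_init__(self) -> None:
        self.cell_id = str(self.cell_id)
        clean: dict[int, np.ndarray] = {}
        for z, verts in self.slices.items():
            v = np.asarray(verts, dtype=np.float64)
            if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
                raise ValueError(
                    f"cell {self.cell_id} slice {z}: polygon needs ≥3 (y, x) vertices"
                )
            poly = Polygon(v[:, ::-1])  # shapely wants (x, y)
            if not poly.is_valid or poly.area == 0:
                raise ValueError(
                    f"cell {self.cell_id} slice {z}: degenerate or self-intersecting polygon"
                )
            clean[int(z)] = v
        self.slices = clean


@dataclass
class MaskVolume:
    """Rasterized 3D binary mask for one cell, shaped like its target stack."""

    mask: np.ndarray
    cell_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")


def _fill_polygon(verts_yx: np.ndarray, shape_yx: tuple[int, int]) -> np.ndarray:
    """Boolean (Y, X) raster of voxel centers covered by the polygon.

    Uses the covers predicate so points exactly on the border count as inside.
    Only the polygon's bounding box is tested.
    """
    ny, nx = shape_yx
    out = np.zeros((ny, nx), dtype=bool)
    poly = Polygon(verts_yx[:, ::-1])
    minx, miny, maxx, maxy = poly.bounds
    x0 = max(0, int(np.ceil(minx - 1e-9)))
    x1 = min(nx - 1, int(np.floor(maxx + 1e-9)))
    y0 = max(0, int(np.ceil(miny - 1e-9)))
    y1 = min(ny - 1, int(np.floor(maxy + 1e-9)))
    if x1 < x0 or y1 < y0:
        return out
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    pts = shapely.points(xs.ravel().astype(float), ys.ravel().astype(float))
    shapely.prepare(poly)
    inside = shapely.covers(poly, pts).reshape(ys.shape)
    out[y0 : y1 + 1, x0 : x1 + 1] = inside
    return out


def rasterize_roi(roi: CellROI, shape: tuple[int, int, int]) -> MaskVolume:
    """Rasterize a per-slice polygon ROI into a stack-shaped 3D boolean mask.

    Slices without a polygon are all-false; polygons (or parts) falling
    outside the frame are clipped.  Raises if any polygon slice index is
    outside the stack's z range.
    """
    nz, ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    for z, verts in roi.slices.items():
        if not (0 <= z < nz):
            raise ValueError(f"cell {roi.cell_id}: slice index {z} outside stack (Z={nz})")
        mask[z] = _fill_polygon(verts, (ny, nx))
    return MaskVolume(mask=mask, cell_id=roi.cell_id)


def apply_mask(stack: ImageStack, mask: MaskVolume) -> ImageStack:
    """Zero every voxel outside the cell border; inside voxels are untouched."""
    if mask.mask.shape != stack.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match stack shape {stack.shape}"
        )
    return stack.with_voxels(np.where(mask.mask, stack.voxels, 0.0))


def load_rois(path: str | Path) -> list[CellROI]:
    """Read a list of cell ROIs from the JSON interchange format."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI file not found: {path}")
    raw = json.loads(path.read_text())
    rois = []
    for entry in raw:
        slices = {int(z): np.asarray(v, dtype=float) for z, v in entry["slices"].items()}
        rois.append(CellROI(cell_id=entry["cell_id"], slices=slices))
    return rois


def save_rois(rois: list[CellROI], path: str | Path) -> Path:
    """Write cell ROIs to the JSON interchange format."""
    path = Path(path)
    payload = [
        {
            "cell_id": roi.cell_id,
            "slices": {str(z): np.asarray(v, dtype=float).tolist() for z, v in roi.slices.items()},
        }
        for roi in rois
    ]
    path.write_text(json.dumps(payload) + "\n")
    return path
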