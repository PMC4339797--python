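"""Image-stack container and TIFF + sidecar I/O.

All modules in this package operate on :class:`ImageStack`, a 3D voxel array
indexed ``(z, y, x)`` with physical voxel dimensions attached.  Stacks are
stored on disk as multi-page grayscale TIFF (one page per z-slice) plus a JSON
sidecar ``<file>.meta.json`` carrying voxel size, channel name and the
normalized flag.  Metadata lives in the sidecar rather than TIFF tags so that
round trips are bit-exact and dialect-free.

Intensities are held as floating point in memory regardless of the on-disk bit
depth; 8/16-bit TIFFs are promoted on read.  Normalized stacks (values in
``[0, 1]``) are written as 32-bit float pages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelSize", "ImageStack", "read_stack", "write_stack"]

#: Confocal voxel dimensions (µm) used as the package-wide default:
#: 0.04 µm laterally, 0.3 µm z-spacing.
DEFAULT_VOXEL_SIZE_UM = (0.04, 0.04, 0.3)


@dataclass(frozen=True)
class VoxelSize:
    """Physical voxel dimensions in µm along x, y and z."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"voxel size {name} must be finite and > 0, got {v!r}")

    @property
    def anisotropy(self) -> float:
        """Axial/lateral anisotropy ratio dz/dx."""
        return self.dz / self.dx

    @classmethod
    def default(cls) -> "VoxelSize":
        return cls(*DEFAULT_VOXEL_SIZE_UM)


@dataclass
class ImageStack:
    """A 3D grayscale image with physical voxel size.

    Parameters
    ----------
    voxels
        3D array indexed ``(z, y, x)``.  Raw images are non-negative; filtered
        (band-pass) intermediates may contain negative values until
        normalization.
    voxel_size
        Physical voxel dimensions.
    channel_name
        Free-text channel label (e.g. a dye or gene name).
    normalized
        True once intensities have been rescaled to ``[0, 1]``.
    """

    voxels: np.ndarray
    voxel_size: VoxelSize
    channel_name: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x), got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")
        if self.normalized:
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < 0 or hi > 1 + 1e-12:
                raise ValueError(
                    f"normalized stack must lie in [0, 1], got range [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def with_voxels(self, voxels: np.ndarray, *, normalized: bool | None = None) -> "ImageStack":
        """Copy of this stack with new voxel data (metadata preserved)."""
        return ImageStack(
            voxels=voxels,
            voxel_size=self.voxel_size,
            channel_name=self.channel_name,
            normalized=self.normalized if normalized is None else normalized,
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_stack(path: str | Path, voxel_size: VoxelSize | None = None) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    The voxel size is taken from the ``voxel_size`` argument if given,
    otherwise from the JSON sidecar ``<path>.meta.json``; if neither is
    available an error is raised.  Page count becomes the z-dimension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image stack not found: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent page shape in {path}: {sorted(shapes)}")
        data = tif.asarray()
    if data.ndim == 2:
        data = data[np.newaxis, :, :]
    if data.ndim != 3:
        raise ValueError(f"expected grayscale pages, got array of ndim {data.ndim}")

    channel_name = ""
    normalized = False
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        channel_name = meta.get("channel", "")
        normalized = bool(meta.get("normalized", False))
        if voxel_size is None:
            voxel_size = VoxelSize(meta["dx_um"], meta["dy_um"], meta["dz_um"])
    if voxel_size is None:
        raise ValueError(
            f"no voxel size: pass voxel_size= or provide sidecar {sidecar.name}"
        )
    return ImageStack(
        voxels=data.astype(np.float64),
        voxel_size=voxel_size,
        channel_name=channel_name,
        normalized=normalized,
    )


def write_stack(stack: ImageStack, path: str | Path) -> tuple[Path, Path]:
    """Write a stack as multi-page TIFF plus JSON metadata sidecar.

    Integer-valued data are written as uint16 (bit-exact round trip);
    anything else, including normalized stacks, as 32-bit float pages.
    Returns the TIFF path and the sidecar path.
    """
    path = Path(path)
    data = stack.voxels
    if not stack.normalized and np.array_equal(data, np.round(data)) and data.min() >= 0 and data.max() < 2**16:
        out = data.astype(np.uint16)
    else:
        out = data.astype(np.float32)
    tifffile.imwrite(str(path), out, photometric="minisblack")
    meta = {
        "dx_um": stack.voxel_size.dx,
        "dy_um": stack.voxel_size.dy,
        "dz_um": stack.voxel_size.dz,
        "channel": stack.channel_name,
        "normalized": stack.normalized,
    }
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=1) + "\n")
    return path, sidecar
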