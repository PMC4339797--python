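"""Shared fixtures: tiny deterministic stacks and rendering helpers."""

from __future__ import annotations

import numpy as np
import pytest

from smfish3d import ImageStack, VoxelSize


@pytest.fixture
def voxel_size() -> VoxelSize:
    return VoxelSize(0.04, 0.04, 0.3)


@pytest.fixture
def iso_voxel_size() -> VoxelSize:
    """Isotropic grid for tests where anisotropy is a distraction."""
    return VoxelSize(0.1, 0.1, 0.1)


def render_gaussian(
    shape: tuple[int, int, int],
    centers,
    amplitudes,
    sigma_vox: tuple[float, float, float],
) -> np.ndarray:
    """Sum of anisotropic 3D Gaussians on a zero background (direct evaluation)."""
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]].astype(float)
    out = np.zeros(shape)
    sz, sy, sx = sigma_vox
    for (cz, cy, cx), a in zip(centers, amplitudes):
        out += a * np.exp(
            -((zz - cz) ** 2) / (2 * sz**2)
            - ((yy - cy) ** 2) / (2 * sy**2)
            - ((xx - cx) ** 2) / (2 * sx**2)
        )
    return out


def spot_stack(
    voxel_size: VoxelSize,
    shape=(15, 41, 41),
    centers=((7, 20, 20),),
    amplitudes=(100.0,),
    sigma_um=(0.35, 0.1),
) -> ImageStack:
    """Stack of clean Gaussian dots with PSF sigma given in µm (z, xy)."""
    sig = (
        sigma_um[0] / voxel_size.dz,
        sigma_um[1] / voxel_size.dy,
        sigma_um[1] / voxel_size.dx,
    )
    return ImageStack(render_gaussian(shape, centers, amplitudes, sig), voxel_size)
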