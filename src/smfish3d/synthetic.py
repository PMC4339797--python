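"""Ground-truth-annotated synthetic smFISH stacks and transcript-count samples.

The generator emulates the imaging regime the rest of the package is built
for: diffraction-limited fluorescent dots (one per transcript) inside cell
borders, over autofluorescent background with shot and read noise, on an
anisotropic confocal voxel grid.  Every simulated stack comes with full
ground truth (spot positions, amplitudes, conglomerate flags, channel-B
presence, per-cell counts), so every downstream stage can be tested with no
external data.

Model components
----------------
* **Cells** — convex polygons (perturbed regular polygons) tiled without
  overlap on the XY plane, each replicated over a contiguous z-interval: a
  deliberate prism-shaped simplification of real cell geometry.
* **Spots** — separable anisotropic 3D Gaussians (the PSF model), peak
  amplitude jittered lognormally (±10%-scale) around the mean; a stated
  fraction are "conglomerates" with 2× amplitude (two unresolved
  transcripts).  Spot centers keep a minimum PSF-scaled pairwise separation
  (resolved single-molecule regime) and stay clear of cell borders.
* **Background** — a mean autofluorescence level with a fractional linear
  ramp across X.
* **Noise** — optional Poisson (shot) resampling of the expected photon
  image, plus additive Gaussian read noise (clipped at 0).
* **Two channels** — channel A renders every spot; channel B drops each spot
  independently with probability ``channel_dropout`` (probe/dye detection
  failure), with the realized presence recorded in the ground truth.

Randomness: one seed; named child generators spawned from it in a fixed
documented order (geometry, counts, placement, marks, channel_b, noise_a,
noise_b), so individual draws can be replayed exactly by tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .image_io import ImageStack, VoxelSize
from .roi import CellROI, rasterize_roi
from shapely.geometry import MultiPoint

__all__ = [
    "SimParams",
    "GroundTruth",
    "simulate_stack",
    "simulate_two_channel",
    "sample_cell_counts",
    "COUNT_FAMILIES",
]

#: Order in which child RNG streams are spawned from the seed.
RNG_STREAMS = ("geometry", "counts", "placement", "marks", "channel_b", "noise_a", "noise_b")

COUNT_FAMILIES = ("normal", "gamma", "logistic", "weibull", "poisson")


@dataclass(frozen=True)
class SimParams:
    """Synthetic-stack parameters; defaults define the package's standard
    simulated imaging conditions (see docs/methods.md for rationale)."""

    image_shape: tuple[int, int, int] = (24, 384, 384)
    voxel_size: VoxelSize = field(default_factory=VoxelSize.default)
    n_cells: int = 4
    #: fixed spots per cell (int) or ("family", {param: value}) distribution
    spots_per_cell: int | tuple[str, dict] = 50
    psf_sigma_xy: float = 0.1  # µm
    psf_sigma_z: float = 0.35  # µm
    spot_amplitude: float = 400.0  # mean peak photons
    amplitude_jitter_sd: float = 0.1  # lognormal sigma (≈ ±10%)
    conglomerate_fraction: float = 0.004
    background_level: float = 40.0  # mean autofluorescence photons
    background_gradient: float = 0.2  # fractional ramp across X
    read_noise_sd: float = 4.0
    shot_noise: bool = True
    channel_dropout: float = 0.2
    min_separation_sigma: float = 6.0  # PSF-scaled pairwise spacing floor
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conglomerate_fraction", "channel_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.psf_sigma_xy <= 0 or self.psf_sigma_z <= 0:
            raise ValueError("PSF sigmas must be > 0")
        if self.spot_amplitude <= 0:
            raise ValueError("spot_amplitude must be > 0")
        if len(self.image_shape) != 3 or any(s < 4 for s in self.image_shape):
            raise ValueError("image_shape must be (Z, Y, X), each ≥ 4")
        if self.n_cells < 0:
            raise ValueError("n_cells must be ≥ 0")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background_level and read_noise_sd must be ≥ 0")


@dataclass
class GroundTruth:
    """Everything the generator knows that a real experiment would not."""

    spots: pd.DataFrame  # cell_id, z, y, x (voxels), amplitude, conglomerate, in_channel_b
    cell_rois: list[CellROI]
    per_cell_counts: dict[str, int]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(RNG_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(RNG_STREAMS, children)}


def _cell_geometry(params: SimParams, rng: np.random.Generator) -> list[CellROI]:
    """Convex polygon per cell on a non-overlapping XY tile grid, extruded in z."""
    nz, ny, nx = params.image_shape
    n = params.n_cells
    if n == 0:
        return []
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    tile_y, tile_x = ny / nrows, nx / ncols
    base_r = 0.38 * min(tile_y, tile_x)
    if base_r < 3:
        raise ValueError(
            f"cannot fit {n} cells in a {ny}×{nx} frame: tiles too small for a polygon"
        )
    rois = []
    for i in range(n):
        row, col = divmod(i, ncols)
        cy = (row + 0.5) * tile_y
        cx = (col + 0.5) * tile_x
        angles = np.linspace(0, 2 * math.pi, 10, endpoint=False)
        angles = angles + rng.uniform(0, 2 * math.pi / 10)
        radii = base_r * rng.uniform(0.82, 1.0, size=angles.size)
        pts = np.column_stack([cy + radii * np.sin(angles), cx + radii * np.cos(angles)])
        hull = MultiPoint(pts[:, ::-1]).convex_hull  # shapely (x, y)
        verts_xy = np.asarray(hull.exterior.coords)[:-1]
        verts = verts_xy[:, ::-1]  # back to (y, x)
        z_lo = int(rng.integers(0, max(1, nz // 6)))
        z_hi = nz - 1 - int(rng.integers(0, max(1, nz // 6)))
        slices = {z: verts.copy() for z in range(z_lo, z_hi + 1)}
        rois.append(CellROI(cell_id=f"cell_{i + 1:02d}", slices=slices))
    return rois


def _resolve_counts(
    params: SimParams, n_cells: int, rng: np.random.Generator
) -> list[int]:
    spec = params.spots_per_cell
    if isinstance(spec, int):
        if spec < 0:
            raise ValueError("spots_per_cell must be ≥ 0")
        return [spec] * n_cells
    family, fam_params = spec
    seed = int(rng.integers(0, 2**31 - 1))
    return list(sample_cell_counts(family, fam_params, n_cells, seed))


def _place_spots(
    params: SimParams,
    rois: list[CellROI],
    counts: list[int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample spot centers inside eroded cell masks with a PSF-scaled
    minimum pairwise separation (rejection sampling)."""
    nz, ny, nx = params.image_shape
    vs = params.voxel_size
    sx = params.psf_sigma_xy / vs.dx
    sy = params.psf_sigma_xy / vs.dy
    sz = params.psf_sigma_z / vs.dz
    # physical-µm coordinates scaled by per-axis PSF sigma for the spacing test
    scale = np.array([params.psf_sigma_z, params.psf_sigma_xy, params.psf_sigma_xy])
    min_sep = params.min_separation_sigma

    rows = []
    for roi, count in zip(rois, counts):
        mask = rasterize_roi(roi, params.image_shape).mask
        # erode laterally by ~2 PSF sigma and axially by ~1 sigma so rendered
        # photons stay essentially inside the mask
        margin = (max(1, int(round(sz))), max(1, int(round(2 * sx))), max(1, int(round(2 * sy))))
        interior = ndi.binary_erosion(
            mask, structure=np.ones((2 * margin[0] + 1, 2 * margin[1] + 1, 2 * margin[2] + 1))
        )
        cand = np.argwhere(interior)
        if cand.shape[0] == 0 and count > 0:
            raise ValueError(f"cell {roi.cell_id} interior too small to place spots")
        accepted_scaled: list[np.ndarray] = []
        placed = 0
        attempts = 0
        max_attempts = 500 * max(count, 1)
        while placed < count:
            if attempts >= max_attempts:
                raise ValueError(
                    f"cell {roi.cell_id}: could not place {count} spots with "
                    f"min_separation_sigma={min_sep} (placed {placed})"
                )
            attempts += 1
            vz, vy, vx = cand[rng.integers(0, cand.shape[0])]
            jitter = rng.uniform(-0.5, 0.5, size=3)
            pos = np.array([vz, vy, vx], dtype=float) + jitter
            pos_um = pos * np.array([vs.dz, vs.dy, vs.dx])
            pos_scaled = pos_um / scale
            ok = True
            for prev in accepted_scaled:
                if np.linalg.norm(pos_scaled - prev) < min_sep:
                    ok = False
                    break
            if not ok:
                continue
            accepted_scaled.append(pos_scaled)
            rows.append((roi.cell_id, pos[0], pos[1], pos[2]))
            placed += 1
    return pd.DataFrame(rows, columns=["cell_id", "z", "y", "x"])


def _render(
    params: SimParams,
    spots: pd.DataFrame,
    amplitudes: np.ndarray,
    include: np.ndarray,
) -> np.ndarray:
    """Expected (noise-free) photon image: background + gradient + Gaussians."""
    nz, ny, nx = params.image_shape
    vs = params.voxel_size
    sz = params.psf_sigma_z / vs.dz
    sy = params.psf_sigma_xy / vs.dy
    sx = params.psf_sigma_xy / vs.dx
    xs = np.arange(nx, dtype=np.float64)
    ramp = 1.0 + params.background_gradient * (xs / max(nx - 1, 1) - 0.5)
    expected = np.broadcast_to(params.background_level * ramp, (nz, ny, nx)).copy()
    rz, ry, rx = (int(math.ceil(4 * s)) + 1 for s in (sz, sy, sx))
    for (z, y, x), amp, inc in zip(
        spots[["z", "y", "x"]].to_numpy(), amplitudes, include
    ):
        if not inc:
            continue
        z0, z1 = max(0, int(z) - rz), min(nz, int(z) + rz + 1)
        y0, y1 = max(0, int(y) - ry), min(ny, int(y) + ry + 1)
        x0, x1 = max(0, int(x) - rx), min(nx, int(x) + rx + 1)
        gz = np.exp(-((np.arange(z0, z1) - z) ** 2) / (2 * sz**2))
        gy = np.exp(-((np.arange(y0, y1) - y) ** 2) / (2 * sy**2))
        gx = np.exp(-((np.arange(x0, x1) - x) ** 2) / (2 * sx**2))
        expected[z0:z1, y0:y1, x0:x1] += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return expected


def _apply_noise(
    expected: np.ndarray, params: SimParams, rng: np.random.Generator
) -> np.ndarray:
    img = rng.poisson(expected).astype(np.float64) if params.shot_noise else expected.copy()
    if params.read_noise_sd > 0:
        img += rng.normal(0.0, params.read_noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def _simulate(params: SimParams, two_channel: bool):
    streams = _streams(params.seed)
    rois = _cell_geometry(params, streams["geometry"])
    counts = _resolve_counts(params, len(rois), streams["counts"])
    spots = _place_spots(params, rois, counts, streams["placement"])
    n = len(spots)

    marks = streams["marks"]
    conglomerate = marks.random(n) < params.conglomerate_fraction
    jitter = marks.lognormal(0.0, params.amplitude_jitter_sd, size=n)
    amplitudes = params.spot_amplitude * jitter * np.where(conglomerate, 2.0, 1.0)

    in_b = streams["channel_b"].random(n) < (1.0 - params.channel_dropout)

    gt_spots = spots.copy()
    gt_spots["amplitude"] = amplitudes
    gt_spots["conglomerate"] = conglomerate
    gt_spots["in_channel_b"] = in_b if two_channel else True
    per_cell = {
        roi.cell_id: int((gt_spots["cell_id"] == roi.cell_id).sum()) for roi in rois
    }
    truth = GroundTruth(spots=gt_spots, cell_rois=rois, per_cell_counts=per_cell)

    all_on = np.ones(n, dtype=bool)
    expected_a = _render(params, spots, amplitudes, all_on)
    stack_a = ImageStack(
        _apply_noise(expected_a, params, streams["noise_a"]),
        params.voxel_size,
        channel_name="A",
    )
    if not two_channel:
        return stack_a, truth
    expected_b = _render(params, spots, amplitudes, in_b)
    stack_b = ImageStack(
        _apply_noise(expected_b, params, streams["noise_b"]),
        params.voxel_size,
        channel_name="B",
    )
    return stack_a, stack_b, truth


def simulate_stack(params: SimParams) -> tuple[ImageStack, GroundTruth]:
    """Simulate one single-channel stack with complete ground truth.

    Identical parameters (including seed) give bit-identical output.
    """
    return _simulate(params, two_channel=False)


def simulate_two_channel(
    params: SimParams,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Simulate a double-labeling experiment: channel A carries every spot,
    channel B drops each spot independently with probability
    ``channel_dropout``; realized presence is recorded in the ground truth."""
    return _simulate(params, two_channel=True)


def sample_cell_counts(
    family: str, params: dict, n: int, seed: int
) -> np.ndarray:
    """Draw per-cell transcript counts from a named reference family.

    Families: normal(mean, sd), gamma(shape, rate), logistic(loc, scale),
    weibull(shape, scale), poisson(rate).  Continuous draws are rounded to the
    nearest integer and clipped at 0 — transcript counts are non-negative
    integers even when the generating family is continuous.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    rng = np.random.default_rng(seed)
    if family == "normal":
        if params["sd"] <= 0:
            raise ValueError("normal sd must be > 0")
        draws = rng.normal(params["mean"], params["sd"], size=n)
    elif family == "gamma":
        if params["shape"] <= 0 or params["rate"] <= 0:
            raise ValueError("gamma shape and rate must be > 0")
        draws = rng.gamma(params["shape"], 1.0 / params["rate"], size=n)
    elif family == "logistic":
        if params["scale"] <= 0:
            raise ValueError("logistic scale must be > 0")
        draws = rng.logistic(params["loc"], params["scale"], size=n)
    elif family == "weibull":
        if params["shape"] <= 0 or params["scale"] <= 0:
            raise ValueError("weibull shape and scale must be > 0")
        draws = params["scale"] * rng.weibull(params["shape"], size=n)
    elif family == "poisson":
        if params["rate"] <= 0:
            raise ValueError("poisson rate must be > 0")
        return rng.poisson(params["rate"], size=n).astype(np.int64)
    else:
        raise ValueError(f"unknown family {family!r}; choose from {COUNT_FAMILIES}")
    return np.clip(np.rint(draws), 0, None).astype(np.int64)
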