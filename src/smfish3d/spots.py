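"""Spot counting: component labeling, threshold sweep, plateau selection,
per-cell transcript counts, dot intensities, conglomerates, colocalization.

The counting principle: after band-pass filtering and normalization, a
transcript dot is a connected set of voxels above an intensity threshold.
Because the true threshold is unknown, the normalized image is binarized at a
uniform grid of thresholds (default 100: t = k/100 for k = 1..100) and the
connected-component count recorded at each.  Over a band of thresholds the
count is stable — noise components are gone, real dots not yet eroded — and
that plateau count is taken as the transcript number.  Selection is either
automatic (longest plateau, lowest-threshold tie-break) or manual (a supplied
threshold value).

Spot tables are pandas DataFrames with one row per detected dot:
``spot_id, cell_id, z_vox, y_vox, x_vox, z_um, y_um, x_um, voxel_count,
mean_intensity, conglomerate, threshold``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .image_io import ImageStack, VoxelSize
from .roi import CellROI, MaskVolume, apply_mask, rasterize_roi

__all__ = [
    "ThresholdSweep",
    "CellCountResult",
    "ColocResult",
    "SPOT_COLUMNS",
    "label_components",
    "threshold_sweep",
    "select_threshold",
    "count_per_cell",
    "measure_dot_intensities",
    "classify_conglomerates",
    "colocalize",
]

SPOT_COLUMNS = [
    "spot_id",
    "cell_id",
    "z_vox",
    "y_vox",
    "x_vox",
    "z_um",
    "y_um",
    "x_um",
    "voxel_count",
    "mean_intensity",
    "conglomerate",
    "threshold",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class ThresholdSweep:
    """Threshold → component-count curve plus the selected counting threshold."""

    thresholds: np.ndarray
    counts: np.ndarray
    selected_threshold: float | None = None
    selected_count: int | None = None
    selection_mode: str | None = None  # "plateau" | "manual"


@dataclass(frozen=True)
class CellCountResult:
    """Transcript count for one cell at its selected threshold."""

    cell_id: str
    transcript_count: int
    threshold: float | None
    embryo_id: str = ""


@dataclass(frozen=True)
class ColocResult:
    """Two-channel detection-efficiency result."""

    efficiency_ab: float  # fraction of A dots with a matched B dot
    efficiency_ba: float  # fraction of B dots with a matched A dot
    pairs: list[tuple[int, int, float]]  # (index in A, index in B, distance µm)
    radius_um: float


def label_components(binary: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Label maximal connected sets of true voxels in a 3D binary array.

    ``connectivity`` is the 3D voxel adjacency: 6 (faces), 18 (faces+edges) or
    26 (faces+edges+corners).  Returns a label array (0 = background, labels
    1..count) and the component count.
    """
    binary = np.asarray(binary)
    if binary.ndim != 3:
        raise ValueError("binary array must be 3D")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, count = ndimage.label(binary.astype(bool), structure=structure)
    return labels, int(count)


def threshold_sweep(
    filtered: ImageStack,
    mask: MaskVolume | None = None,
    n_thresholds: int = 100,
    connectivity: int = 26,
) -> ThresholdSweep:
    """Count components at a uniform grid of thresholds t_k = k/n, k = 1..n.

    The stack must be normalized to [0, 1]; the mask (if given) is applied
    before thresholding.  Binarization is strict: voxel > t_k.
    """
    if not filtered.normalized:
        raise ValueError("threshold_sweep expects a normalized stack")
    if n_thresholds < 1:
        raise ValueError("n_thresholds must be ≥ 1")
    data = apply_mask(filtered, mask).voxels if mask is not None else filtered.voxels
    thresholds = np.arange(1, n_thresholds + 1, dtype=np.float64) / n_thresholds
    counts = np.empty(n_thresholds, dtype=np.int64)
    for i, t in enumerate(thresholds):
        _, counts[i] = label_components(data > t, connectivity)
    return ThresholdSweep(thresholds=thresholds, counts=counts)


def _runs(counts: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of identical values as (start, length, value)."""
    runs = []
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[start]:
            runs.append((start, i - start, int(counts[start])))
            start = i
    return runs


def select_threshold(
    sweep: ThresholdSweep,
    mode: str = "plateau",
    manual_value: float | None = None,
    min_plateau: int = 3,
) -> ThresholdSweep:
    """Fill in the counting threshold on a computed sweep.

    ``plateau`` mode picks the *widest* run of consecutive thresholds with an
    identical nonzero count and returns the run's midpoint threshold.  Width
    is measured in log-threshold (log of the run's upper/lower threshold
    ratio): a threshold is a scale parameter and dot amplitudes spread
    multiplicatively, so a run high up the intensity range — e.g. the band
    where only the one or two brightest dots survive — must not outscore the
    true-count band merely because the grid is uniform on the linear scale.
    Ties go to the lower-threshold run.  Runs shorter than ``min_plateau``
    grid points do not qualify; if no run qualifies, the modal nonzero count
    is used and its first (lowest-threshold) run's midpoint is selected.  An
    all-zero sweep yields the explicit "no spots" outcome: count 0, no
    threshold.

    ``manual`` mode records ``manual_value`` (which must be on the grid) and
    the count at it.
    """
    counts = np.asarray(sweep.counts)
    thresholds = np.asarray(sweep.thresholds)
    if mode == "manual":
        if manual_value is None:
            raise ValueError("manual mode requires manual_value")
        idx = np.flatnonzero(np.isclose(thresholds, manual_value))
        if idx.size == 0:
            raise ValueError(f"manual threshold {manual_value} is not on the sweep grid")
        i = int(idx[0])
        return replace(
            sweep,
            selected_threshold=float(thresholds[i]),
            selected_count=int(counts[i]),
            selection_mode="manual",
        )
    if mode != "plateau":
        raise ValueError(f"unknown selection mode {mode!r}")

    if not np.any(counts > 0):
        return replace(sweep, selected_threshold=None, selected_count=0, selection_mode="plateau")

    runs = [(s, l, v) for s, l, v in _runs(counts) if v > 0]
    qualifying = [r for r in runs if r[1] >= min_plateau]
    if qualifying:
        # widest run in log-threshold; ties toward the lower threshold
        def log_width(r: tuple[int, int, int]) -> float:
            start, length, _ = r
            return float(np.log(thresholds[start + length - 1] / thresholds[start]))

        best = max(qualifying, key=lambda r: (log_width(r), -r[0]))
    else:
        values = [v for _, l, v in runs for _ in range(l)]
        modal = int(pd.Series(values).mode().iloc[0])
        best = next(r for r in runs if r[2] == modal)
    start, length, value = best
    mid = start + (length - 1) // 2
    return replace(
        sweep,
        selected_threshold=float(thresholds[mid]),
        selected_count=value,
        selection_mode="plateau",
    )


def _component_table(
    values: np.ndarray,
    labels: np.ndarray,
    count: int,
    voxel_size: VoxelSize,
    cell_id: str,
    threshold: float,
) -> pd.DataFrame:
    """Per-component centroid/size/intensity table from a labeled volume."""
    if count == 0:
        return pd.DataFrame(columns=SPOT_COLUMNS)
    index = np.arange(1, count + 1)
    # intensity-weighted centroids in voxel coordinates
    centroids = np.array(ndimage.center_of_mass(values, labels, index), dtype=float)
    sizes = ndimage.sum_labels(np.ones_like(labels, dtype=np.int64), labels, index)
    means = ndimage.mean(values, labels, index)
    df = pd.DataFrame(
        {
            "spot_id": index,
            "cell_id": cell_id,
            "z_vox": centroids[:, 0],
            "y_vox": centroids[:, 1],
            "x_vox": centroids[:, 2],
            "z_um": centroids[:, 0] * voxel_size.dz,
            "y_um": centroids[:, 1] * voxel_size.dy,
            "x_um": centroids[:, 2] * voxel_size.dx,
            "voxel_count": sizes.astype(np.int64),
            "mean_intensity": means,
            "conglomerate": False,
            "threshold": threshold,
        }
    )
    return df


def count_per_cell(
    filtered: ImageStack,
    rois: list[CellROI],
    mode: str = "plateau",
    manual_value: float | None = None,
    n_thresholds: int = 100,
    connectivity: int = 26,
    min_plateau: int = 3,
    embryo_id: str = "",
) -> tuple[list[CellCountResult], pd.DataFrame]:
    """Run mask → sweep → select → label for each cell of a normalized stack.

    Overlapping ROIs are reported with a warning; overlapped voxels are owned
    by the first cell in list order.  For each cell the sweep is run on the
    masked volume cropped to the mask bounding box (a pure speed measure; the
    counts are identical to sweeping the full masked volume).  Returns per-cell
    count results and the accumulated spot table.
    """
    if not filtered.normalized:
        raise ValueError("count_per_cell expects a normalized stack")
    shape = filtered.shape
    masks: list[MaskVolume] = []
    claimed = np.zeros(shape, dtype=bool)
    for roi in rois:
        mv = rasterize_roi(roi, shape)
        overlap = mv.mask & claimed
        if overlap.any():
            warnings.warn(
                f"ROI {roi.cell_id} overlaps a previous cell by {int(overlap.sum())} voxels; "
                "first-come ownership applied",
                stacklevel=2,
            )
            mv = MaskVolume(mask=mv.mask & ~claimed, cell_id=mv.cell_id)
        claimed |= mv.mask
        masks.append(mv)

    results: list[CellCountResult] = []
    tables: list[pd.DataFrame] = []
    vs = filtered.voxel_size
    for mv in masks:
        if not mv.mask.any():
            results.append(CellCountResult(mv.cell_id, 0, None, embryo_id))
            continue
        zs, ys, xs = np.nonzero(mv.mask)
        box = tuple(slice(a.min(), a.max() + 1) for a in (zs, ys, xs))
        sub_vals = np.where(mv.mask[box], filtered.voxels[box], 0.0)
        sub = ImageStack(sub_vals, vs, filtered.channel_name, normalized=True)
        sweep = threshold_sweep(sub, None, n_thresholds, connectivity)
        sweep = select_threshold(sweep, mode, manual_value, min_plateau)
        if sweep.selected_threshold is None:
            results.append(CellCountResult(mv.cell_id, 0, None, embryo_id))
            continue
        labels, count = label_components(sub_vals > sweep.selected_threshold, connectivity)
        df = _component_table(sub_vals, labels, count, vs, mv.cell_id, sweep.selected_threshold)
        # shift centroids from crop-local back to stack coordinates
        off = np.array([box[0].start, box[1].start, box[2].start], dtype=float)
        df[["z_vox", "y_vox", "x_vox"]] += off
        df["z_um"] = df["z_vox"] * vs.dz
        df["y_um"] = df["y_vox"] * vs.dy
        df["x_um"] = df["x_vox"] * vs.dx
        tables.append(df)
        results.append(CellCountResult(mv.cell_id, count, sweep.selected_threshold, embryo_id))

    if tables:
        spot_table = pd.concat(tables, ignore_index=True)
        spot_table["spot_id"] = np.arange(1, len(spot_table) + 1)
    else:
        spot_table = pd.DataFrame(columns=SPOT_COLUMNS)
    return results, spot_table


def measure_dot_intensities(
    filtered: ImageStack,
    fixed_threshold: float = 0.25,
    mask: MaskVolume | None = None,
    connectivity: int = 26,
) -> pd.DataFrame:
    """Dot intensity table at a fixed threshold applied to a normalized stack.

    Each dot's ``mean_intensity`` is the mean of its member voxels' normalized
    values — by construction ≥ the threshold that produced the component.
    """
    if not filtered.normalized:
        raise ValueError("measure_dot_intensities expects a normalized stack")
    data = apply_mask(filtered, mask).voxels if mask is not None else filtered.voxels
    labels, count = label_components(data > fixed_threshold, connectivity)
    cell_id = mask.cell_id if mask is not None else ""
    return _component_table(data, labels, count, filtered.voxel_size, cell_id, fixed_threshold)


def classify_conglomerates(
    spots: pd.DataFrame,
    bin_width: float = 0.05,
    fold: float = 2.0,
    tol: float = 0.15,
) -> tuple[pd.DataFrame, dict]:
    """Flag dots whose intensity is ~``fold``× the modal single-dot intensity.

    The modal intensity m is the center of the most populated ``bin_width``
    histogram bin on [0, 1].  A dot is a conglomerate (two unresolved
    transcripts) iff its mean intensity is ≥ fold·m·(1 − tol).  Returns the
    table with flags set and a summary: modal intensity, flagged count, and
    flagged percentage (one decimal).
    """
    if len(spots) == 0:
        raise ValueError("empty spot table")
    intensities = spots["mean_intensity"].to_numpy(dtype=float)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    hist, _ = np.histogram(intensities, bins=edges)
    modal_bin = int(np.argmax(hist))
    modal = edges[modal_bin] + bin_width / 2
    flagged = intensities >= fold * modal * (1.0 - tol)
    out = spots.copy()
    out["conglomerate"] = flagged
    pct = round(100.0 * flagged.sum() / len(spots), 1)
    summary = {
        "modal_intensity": float(modal),
        "n_spots": int(len(spots)),
        "n_conglomerates": int(flagged.sum()),
        "pct_conglomerates": float(pct),
    }
    return out, summary


def colocalize(
    spots_a: pd.DataFrame,
    spots_b: pd.DataFrame,
    radius_um: float,
) -> ColocResult:
    """Two-channel detection efficiency by one-to-one greedy spot matching.

    Candidate pairs are all (A, B) dot pairs with centroid distance ≤
    ``radius_um`` (µm coordinates, same voxel grid); they are accepted in
    ascending distance order, each dot matched at most once — i.e.
    mutual-nearest greedy matching.  Efficiency A→B is matched/|A| (the
    fraction of dots seen in one channel that the other channel also finds),
    and symmetrically B→A.
    """
    if len(spots_a) == 0:
        raise ValueError("no reference dots: channel A spot table is empty")
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    if len(spots_b) == 0:
        return ColocResult(0.0, float("nan"), [], radius_um)
    pa = spots_a[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
    pb = spots_b[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
    tree_b = cKDTree(pb)
    candidates: list[tuple[float, int, int]] = []
    for ia, neighbors in enumerate(cKDTree(pa).query_ball_tree(tree_b, radius_um)):
        for ib in neighbors:
            d = float(np.linalg.norm(pa[ia] - pb[ib]))
            candidates.append((d, ia, ib))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for d, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((ia, ib, d))
    return ColocResult(
        efficiency_ab=len(pairs) / len(spots_a),
        efficiency_ba=len(pairs) / len(spots_b),
        pairs=pairs,
        radius_um=radius_um,
    )
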