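"""Independent brute-force oracles used by the tests.

Each oracle recomputes a quantity by the most transparent method available
(graph search, dynamic programming, dense grid evaluation) and is kept free
of any code from the package implementation it checks.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def bfs_component_count(binary: np.ndarray, connectivity: int) -> int:
    """Connected components of true voxels by breadth-first search."""
    binary = np.asarray(binary, dtype=bool)
    if connectivity == 6:
        max_l1 = 1
    elif connectivity == 18:
        max_l1 = 2
    elif connectivity == 26:
        max_l1 = 3
    else:
        raise ValueError(connectivity)
    offsets = [
        d
        for d in product((-1, 0, 1), repeat=3)
        if d != (0, 0, 0) and sum(map(abs, d)) <= max_l1
    ]
    seen = np.zeros_like(binary, dtype=bool)
    count = 0
    shape = binary.shape
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        count += 1
        queue = deque([start])
        seen[start] = True
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nx < shape[2]
                    and binary[nz, ny, nx]
                    and not seen[nz, ny, nx]
                ):
                    seen[nz, ny, nx] = True
                    queue.append((nz, ny, nx))
    return count


def dp_max_tiling(seq_length: int, probe_length: int, min_gap: int) -> int:
    """Maximum probe packing by dynamic programming over start positions."""
    if probe_length > seq_length:
        return 0
    best = [0] * (seq_length + 1)
    for i in range(seq_length - probe_length, -1, -1):
        skip = best[i + 1]
        nxt = i + probe_length + min_gap
        take = 1 + (best[nxt] if nxt <= seq_length else 0)
        best[i] = max(skip, take)
    return best[0]


def point_in_polygon(y: float, x: float, verts_yx: np.ndarray) -> bool:
    """Even-odd crossing test with boundary points counted inside."""
    n = len(verts_yx)
    inside = False
    for i in range(n):
        y1, x1 = verts_yx[i]
        y2, x2 = verts_yx[(i + 1) % n]
        # on-segment check
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
        if (y1 > y) != (y2 > y):
            x_at = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_at:
                inside = not inside
    return inside


def ks_sup_distance(sample: np.ndarray, cdf, grid: np.ndarray) -> float:
    """Brute-force sup |F_n − F| for a continuous fitted CDF.

    Evaluates on a dense grid plus all sample points; at sample points the
    empirical CDF is taken from both sides (F is continuous there).
    """
    sample = np.sort(np.asarray(sample, dtype=float))
    n = sample.size
    pts = np.unique(np.concatenate([grid, sample]))
    F = cdf(pts)
    Fn_right = np.searchsorted(sample, pts, side="right") / n
    Fn_left = np.searchsorted(sample, pts, side="left") / n
    return float(
        max(np.max(np.abs(Fn_right - F)), np.max(np.abs(Fn_left - F)))
    )


def ks_sup_distance_steps(sample: np.ndarray, cdf, grid: np.ndarray) -> float:
    """Brute-force sup |F_n − F| when both CDFs are right-continuous steps.

    Right-side evaluation over a dense grid suffices provided the grid
    contains points strictly between consecutive atoms (where each function
    equals its left limit at the next atom).
    """
    sample = np.sort(np.asarray(sample, dtype=float))
    n = sample.size
    Fn = np.searchsorted(sample, grid, side="right") / n
    return float(np.max(np.abs(Fn - cdf(grid))))


def grid_search_loglik(x: np.ndarray, logpdf, grids: list[np.ndarray]):
    """Coarse exhaustive likelihood search; returns (best params, best loglik)."""
    best = (None, -np.inf)
    for theta in product(*grids):
        ll = float(np.sum(logpdf(x, *theta)))
        if ll > best[1]:
            best = (theta, ll)
    return best
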