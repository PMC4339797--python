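"""End-to-end pipeline driver: filter → mask → sweep → count → intensities.

``run_pipeline`` wires the stages together for one stack + one ROI file and
writes the standard output bundle:

* ``cell_counts.csv`` — embryo_id, cell_id, threshold, transcript_count
* ``spots.csv`` — one row per counted dot (plateau threshold)
* ``sweep.csv`` — threshold → component count curve per cell
* ``intensity_spots.csv`` — dots at the fixed intensity threshold, with
  conglomerate flags
* ``summary.json`` — conglomerate summary and run metadata
* ``run.log`` — every parameter and the seed

Every CSV begins with a commented provenance header (tool version, config
hash, seed); identical config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .filtering import FilterParams, NoSignalError, log_filter, normalize_filtered
from .image_io import read_stack
from .roi import load_rois, rasterize_roi
from .spots import (
    classify_conglomerates,
    count_per_cell,
    measure_dot_intensities,
    threshold_sweep,
)

logger = logging.getLogger("smfish3d")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline settings; defaults are the package's standard constants
    (100-threshold grid, fixed 0.25 intensity threshold, α = 0.05)."""

    stack_path: str = ""
    roi_path: str = ""
    out_dir: str = "."
    embryo_id: str = ""
    # filtering
    sigma_xy: float = 0.13
    sigma_z: float = 0.4
    kernel_truncation: float = 4.0
    # sweep / selection
    n_thresholds: int = 100
    connectivity: int = 26
    selection_mode: str = "plateau"
    manual_threshold: float | None = None
    min_plateau: int = 3
    # dot intensity / conglomerates
    fixed_threshold: float = 0.25
    conglomerate_bin_width: float = 0.05
    conglomerate_fold: float = 2.0
    conglomerate_tol: float = 0.15
    # colocalization
    coloc_radius_um: float = 0.39  # 3 × sigma_xy
    # statistics
    alpha: float = 0.05
    bootstrap: bool = False
    pooling: str = "pooled"
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the analysis parameters (file locations excluded, so the
        same analysis on the same data hashes identically anywhere)."""
        payload = dataclasses.asdict(self)
        for key in ("stack_path", "roi_path", "out_dir"):
            payload.pop(key)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _provenance(config: RunConfig) -> str:
    return (
        f"# smfish3d v{__version__}\n"
        f"# config_hash={config.config_hash()}\n"
        f"# seed={config.seed}\n"
    )


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full per-cell counting pipeline and write the output bundle.

    Stage errors are re-raised with the stage (and cell, where applicable)
    named.  Returns a dict of output paths plus the in-memory results.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("parameters: %s", json.dumps(dataclasses.asdict(config), sort_keys=True))

        try:
            stack = read_stack(config.stack_path)
        except Exception as err:
            raise RuntimeError(f"stage read_stack: {err}") from err
        try:
            rois = load_rois(config.roi_path)
        except Exception as err:
            raise RuntimeError(f"stage load_rois: {err}") from err

        fparams = FilterParams(config.sigma_xy, config.sigma_z, config.kernel_truncation)
        try:
            filtered = normalize_filtered(log_filter(stack, fparams))
        except NoSignalError:
            logger.warning("no positive filter response anywhere: reporting 0 spots")
            filtered = None
        except Exception as err:
            raise RuntimeError(f"stage filter: {err}") from err

        if filtered is None:
            counts_df = pd.DataFrame(
                {
                    "embryo_id": config.embryo_id,
                    "cell_id": [r.cell_id for r in rois],
                    "threshold": float("nan"),
                    "transcript_count": 0,
                }
            )
            _write_csv(counts_df, out_dir / "cell_counts.csv", config)
            return {"cell_counts": out_dir / "cell_counts.csv", "log": log_path}

        try:
            results, spot_table = count_per_cell(
                filtered,
                rois,
                mode=config.selection_mode,
                manual_value=config.manual_threshold,
                n_thresholds=config.n_thresholds,
                connectivity=config.connectivity,
                min_plateau=config.min_plateau,
                embryo_id=config.embryo_id,
            )
        except Exception as err:
            raise RuntimeError(f"stage count_per_cell: {err}") from err

        sweep_rows = []
        intensity_tables = []
        for roi in rois:
            try:
                mask = rasterize_roi(roi, filtered.shape)
                sweep = threshold_sweep(filtered, mask, config.n_thresholds, config.connectivity)
                for t, c in zip(sweep.thresholds, sweep.counts):
                    sweep_rows.append((config.embryo_id, roi.cell_id, t, c))
                intensity_tables.append(
                    measure_dot_intensities(
                        filtered, config.fixed_threshold, mask, config.connectivity
                    )
                )
            except Exception as err:
                raise RuntimeError(f"stage sweep/intensity, cell {roi.cell_id}: {err}") from err

        intensity_df = (
            pd.concat(intensity_tables, ignore_index=True)
            if intensity_tables
            else pd.DataFrame()
        )
        summary: dict = {"version": __version__, "seed": config.seed}
        if len(intensity_df):
            intensity_df, cong = classify_conglomerates(
                intensity_df,
                bin_width=config.conglomerate_bin_width,
                fold=config.conglomerate_fold,
                tol=config.conglomerate_tol,
            )
            summary["conglomerates"] = cong

        counts_df = pd.DataFrame(
            {
                "embryo_id": [r.embryo_id for r in results],
                "cell_id": [r.cell_id for r in results],
                "threshold": [r.threshold for r in results],
                "transcript_count": [r.transcript_count for r in results],
            }
        )
        sweep_df = pd.DataFrame(
            sweep_rows, columns=["embryo_id", "cell_id", "threshold", "count"]
        )

        paths = {
            "cell_counts": out_dir / "cell_counts.csv",
            "spots": out_dir / "spots.csv",
            "sweep": out_dir / "sweep.csv",
            "intensity_spots": out_dir / "intensity_spots.csv",
            "summary": out_dir / "summary.json",
            "log": log_path,
        }
        _write_csv(counts_df, paths["cell_counts"], config)
        _write_csv(spot_table, paths["spots"], config)
        _write_csv(sweep_df, paths["sweep"], config)
        _write_csv(intensity_df, paths["intensity_spots"], config)
        paths["summary"].write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
        logger.info(
            "counted %d cells, %d spots total",
            len(results),
            int(counts_df["transcript_count"].sum()),
        )
        return {**paths, "results": results, "spot_table": spot_table, "summary": summary}
    finally:
        logger.removeHandler(handler)
        handler.close()
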