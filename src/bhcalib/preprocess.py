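"""Motion QC, linear detrending, percent-change conversion, SD maps."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Bold4D, UNITS_PERCENT

__all__ = [
    "MotionTrace",
    "read_motion_trace",
    "motion_qc",
    "brain_mask",
    "detrend_linear",
    "to_percent_change",
    "sd_map",
]

MOTION_COLUMNS = ("x", "y", "z", "pitch", "roll", "yaw")


@dataclass
class MotionTrace:
    """Per-volume displacements (mm) and rotations; one row per volume."""

    displacements_mm: np.ndarray  # (n_volumes, 3): x, y, z
    rotations: np.ndarray         # (n_volumes, 3)

    def __post_init__(self) -> None:
        self.displacements_mm = np.atleast_2d(np.asarray(self.displacements_mm, float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, float))
        if self.displacements_mm.shape[1] != 3 or self.rotations.shape[1] != 3:
            raise ValueError("motion trace needs 3 displacement and 3 rotation columns")
        if len(self.displacements_mm) != len(self.rotations):
            raise ValueError("displacement and rotation row counts differ")
        if len(self.displacements_mm) == 0:
            raise ValueError("empty motion trace")

    @property
    def n_volumes(self) -> int:
        return len(self.displacements_mm)

    def mean_abs_displacement(self) -> np.ndarray:
        """Per-axis mean absolute displacement (the run summary)."""
        return np.abs(self.displacements_mm).mean(axis=0)


def read_motion_trace(path: str | Path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion TSV missing columns {missing}")
    return MotionTrace(
        displacements_mm=df[["x", "y", "z"]].to_numpy(),
        rotations=df[["pitch", "roll", "yaw"]].to_numpy(),
    )


def motion_qc(
    trace: MotionTrace,
    max_mm: float = 2.0,
    voxel_size_mm: tuple[float, float, float] | None = None,
) -> dict:
    """Pass/fail motion screen.

    Fails if any per-volume displacement exceeds ``max_mm`` or exceeds the
    smallest voxel dimension (one voxel-shift), whichever is stricter.
    Returns a JSON-serializable report listing offending volumes.
    """
    limit = max_mm
    if voxel_size_mm is not None:
        limit = min(limit, min(voxel_size_mm))
    over = np.abs(trace.displacements_mm) > limit
    bad_volumes = sorted(int(i) for i in np.unique(np.nonzero(over)[0]))
    report = {
        "decision": "fail" if bad_volumes else "pass",
        "limit_mm": float(limit),
        "max_abs_displacement_mm": float(np.abs(trace.displacements_mm).max()),
        "offending_volumes": bad_volumes,
        "mean_abs_displacement_mm": [float(v) for v in trace.mean_abs_displacement()],
    }
    return report


def write_qc_report(report: dict, path: str | Path) -> Path:
    Path(path).write_text(json.dumps(report, indent=2))
    return Path(path)


def brain_mask(run: Bold4D, frac_of_robust_max: float = 0.10) -> np.ndarray:
    """Voxels whose temporal mean exceeds a fraction of the robust (98th
    percentile) maximum of the mean image."""
    mean_img = run.data.mean(axis=-1)
    robust_max = np.percentile(mean_img, 98)
    return mean_img > frac_of_robust_max * robust_max


def detrend_linear(run: Bold4D) -> Bold4D:
    """Remove each voxel's least-squares line over time, keep its mean."""
    n_t = run.n_volumes
    if n_t < 3:
        raise ValueError(f"detrending needs >= 3 volumes, got {n_t}")
    t = run.time_axis_s
    tc = t - t.mean()
    flat = run.data.reshape(-1, n_t)
    slope = flat @ tc / (tc @ tc)
    out = flat - slope[:, None] * tc[None, :]
    meta = dict(run.meta)
    meta["detrended"] = True
    return run.copy_with(data=out.reshape(run.data.shape), meta=meta)


def to_percent_change(
    run: Bold4D,
    mask: np.ndarray | None = None,
    baseline: np.ndarray | float | None = None,
) -> Bold4D:
    """Convert to percent signal change: 100 * (v - mean) / mean.

    ``baseline`` overrides the per-voxel temporal mean (useful when the
    true rest level is known, e.g. for phantom data).  Voxels with
    near-zero mean inside the mask are masked out (set to NaN) with a
    warning.  Refuses input already in percent units.
    """
    if run.units == UNITS_PERCENT:
        raise ValueError("input is already in percent units")
    if mask is None:
        mask = brain_mask(run)
    mean_img = run.data.mean(axis=-1) if baseline is None else (
        np.broadcast_to(np.asarray(baseline, dtype=float), run.grid_shape).copy()
    )
    tiny = mean_img <= 1e-12 * max(np.abs(mean_img).max(), 1.0)
    bad = mask & tiny
    if bad.any():
        warnings.warn(f"{int(bad.sum())} masked voxels have near-zero mean; masked out")
    use = mask & ~tiny
    out = np.full(run.data.shape, np.nan)
    out[use] = 100.0 * (run.data[use] / mean_img[use, None] - 1.0)
    meta = dict(run.meta)
    meta["mask_voxels"] = int(use.sum())
    return run.copy_with(data=out, units=UNITS_PERCENT, meta=meta)


def sd_map(run: Bold4D) -> np.ndarray:
    """Per-voxel temporal standard deviation (ddof=1)."""
    if run.n_volumes < 2:
        raise ValueError("SD map needs >= 2 volumes")
    return run.data.std(axis=-1, ddof=1)
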