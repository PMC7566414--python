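"""Cross-correlation activation mapping with rest-derived thresholds and
Monte-Carlo cluster-extent correction."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .core import Bold4D, write_map
from .paradigm import ReferenceWaveform

__all__ = [
    "ActivationMap",
    "cross_correlation",
    "cc_map",
    "rest_null_threshold",
    "analytic_r_threshold",
    "cluster_threshold_mc",
    "apply_threshold",
]

#: 26-connectivity structuring element for 3D cluster labeling
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ActivationMap:
    statistic: np.ndarray            # cc or scaled amplitude; NaN outside mask
    threshold: float
    active: np.ndarray               # bool
    clusters: np.ndarray             # int labels, 0 = background
    min_cluster_size: int
    meta: dict = field(default_factory=dict)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def write(self, prefix: str | Path, voxel_size_mm=(2.5, 2.5, 3.0)) -> None:
        prefix = Path(prefix)
        write_map(self.statistic, voxel_size_mm, prefix.parent / (prefix.name + "_stat.nii"))
        write_map(self.active.astype(np.int16), voxel_size_mm,
                  prefix.parent / (prefix.name + "_mask.nii"))
        write_map(self.clusters.astype(np.int16), voxel_size_mm,
                  prefix.parent / (prefix.name + "_clusters.nii"))
        sidecar = dict(self.meta)
        sidecar.update(threshold=float(self.threshold),
                       min_cluster_size=int(self.min_cluster_size),
                       n_active=self.n_active)
        (prefix.parent / (prefix.name + ".json")).write_text(json.dumps(sidecar, indent=2))


def cross_correlation(t_series, r_series) -> float:
    """Pearson correlation between a voxel time course and a reference.

    Returns NaN for constant inputs (undefined correlation).
    """
    t = np.asarray(t_series, dtype=float)
    r = np.asarray(r_series, dtype=float)
    if t.shape != r.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {r.shape}")
    if t.size < 3:
        raise ValueError("need at least 3 samples")
    tc = t - t.mean()
    rc = r - r.mean()
    denom = np.sqrt(np.sum(tc ** 2) * np.sum(rc ** 2))
    if denom == 0:
        return float("nan")
    return float(np.sum(tc * rc) / denom)


def cc_map(run: Bold4D, reference: ReferenceWaveform | np.ndarray,
           mask: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel correlation with the reference; NaN outside the mask and
    for constant voxels."""
    ref = reference.values if isinstance(reference, ReferenceWaveform) else np.asarray(reference, float)
    if ref.size != run.n_volumes:
        raise ValueError(f"reference length {ref.size} != n_volumes {run.n_volumes}")
    if np.ptp(ref) == 0:
        raise ValueError("reference waveform is constant")
    if mask is None:
        mask = np.all(np.isfinite(run.data), axis=-1)
    flat = run.data[mask]
    tc = flat - flat.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    t_norm = np.sqrt(np.sum(tc ** 2, axis=1))
    denom = t_norm * np.sqrt(np.sum(rc ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(denom > 0, tc @ rc / np.where(denom > 0, denom, 1.0), np.nan)
    out = np.full(run.grid_shape, np.nan)
    out[mask] = cc
    return out


def rest_null_threshold(rest_cc_values: np.ndarray, k: float = 4.0) -> tuple[float, dict]:
    """Activation threshold = k x SD of the resting cc distribution."""
    vals = np.asarray(rest_cc_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 100:
        raise ValueError(f"need >= 100 rest cc values, got {vals.size}")
    sd = float(vals.std(ddof=1))
    summary = dict(n=int(vals.size), mean=float(vals.mean()), sd=sd, k=float(k))
    return k * sd, summary


def analytic_r_threshold(n: int, p_one_tailed: float) -> float:
    """Smallest |r| significant at a one-tailed p with df = n - 2.

    Uses r = t / sqrt(t^2 + df) with t the inverse Student-t quantile.
    """
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if not 0 < p_one_tailed < 0.5:
        raise ValueError(f"p must be in (0, 0.5), got {p_one_tailed}")
    df = n - 2
    t = stats.t.ppf(1.0 - p_one_tailed, df)
    return float(t / np.sqrt(t * t + df))


def cluster_threshold_mc(
    grid_shape: tuple[int, int, int],
    smoothness_fwhm_mm: float,
    voxel_size_mm=(2.5, 2.5, 3.0),
    voxel_p: float = 0.005,
    alpha: float = 0.05,
    n_sims: int = 5000,
    seed: int = 0,
) -> int:
    """Monte-Carlo minimum cluster size at cluster-wise ``alpha``.

    Simulates smooth Gaussian noise fields, thresholds two-tailed at
    ``voxel_p``, records the largest 26-connected cluster per simulation,
    and returns the (1 - alpha) quantile (rounded up, at least 1).
    """
    if n_sims < 100:
        raise ValueError(f"need n_sims >= 100, got {n_sims}")
    if any(s < 2 for s in grid_shape):
        raise ValueError(f"degenerate grid {grid_shape}")
    rng = np.random.default_rng(seed)
    sigma_vox = tuple(
        smoothness_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
        for v in voxel_size_mm
    )
    z_crit = stats.norm.ppf(1.0 - voxel_p / 2.0)
    max_sizes = np.zeros(n_sims)
    for s in range(n_sims):
        field_ = rng.standard_normal(grid_shape)
        if smoothness_fwhm_mm > 0:
            field_ = ndimage.gaussian_filter(field_, sigma_vox)
            field_ = (field_ - field_.mean()) / field_.std()
        supra = np.abs(field_) > z_crit
        if not supra.any():
            continue
        lab, n_lab = ndimage.label(supra, structure=STRUCT_26)
        if n_lab:
            max_sizes[s] = np.bincount(lab.ravel())[1:].max()
    return int(max(1, np.ceil(np.quantile(max_sizes, 1.0 - alpha))))


def apply_threshold(
    statistic: np.ndarray, threshold: float, min_cluster_size: int = 1,
    meta: dict | None = None,
) -> ActivationMap:
    """Two-sided threshold (|stat| > threshold) plus cluster-extent filter.

    Surviving clusters are labeled 1..K in descending size order, ties
    broken by the lexicographically smallest voxel coordinate.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    stat = np.asarray(statistic, dtype=float)
    with np.errstate(invalid="ignore"):
        active = np.abs(stat) > threshold
    active &= np.isfinite(stat)
    lab, n_lab = ndimage.label(active, structure=STRUCT_26)
    clusters = np.zeros_like(lab)
    if n_lab:
        sizes = np.bincount(lab.ravel())
        keep = [i for i in range(1, n_lab + 1) if sizes[i] >= min_cluster_size]
        # deterministic ordering: descending size, then seed-voxel coordinate
        def sort_key(i):
            seed_vox = tuple(np.argwhere(lab == i)[0])
            return (-sizes[i], seed_vox)
        keep.sort(key=sort_key)
        for new_id, old_id in enumerate(keep, start=1):
            clusters[lab == old_id] = new_id
        active = clusters > 0
    return ActivationMap(
        statistic=stat, threshold=float(threshold), active=active,
        clusters=clusters, min_cluster_size=int(min_cluster_size),
        meta=dict(meta or {}),
    )
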