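"""GLM beta estimation and breath-hold scaling of task activation.

Scaling divides each voxel's task beta (percent signal change, unit-peak
regressor) by its breath-hold response amplitude, canceling multiplicative
vascular gain so the scaled map tracks neural drive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .core import Bold4D, UNITS_PERCENT, write_map
from .gammafit import GammaParamMaps
from .paradigm import ReferenceWaveform
from .xcorr import ActivationMap

__all__ = [
    "BetaMap",
    "ScaledMap",
    "glm_beta",
    "bh_amplitude_map",
    "scale_map",
    "activation_compare",
    "bartlett_test",
    "distribution_report",
]


@dataclass
class BetaMap:
    """Per-voxel regressor coefficient (percent) and its standard error."""

    beta: np.ndarray
    se: np.ndarray
    design_label: str = ""
    units: str = "percent"
    meta: dict = field(default_factory=dict)


@dataclass
class ScaledMap:
    """Task beta / BH amplitude, valid only where the divisor clears a floor."""

    scaled: np.ndarray
    valid: np.ndarray
    floor_pct: float
    source: str
    meta: dict = field(default_factory=dict)

    def write(self, prefix: str | Path, voxel_size_mm=(2.5, 2.5, 3.0)) -> None:
        prefix = Path(prefix)
        write_map(self.scaled, voxel_size_mm, prefix.parent / (prefix.name + "_scaled.nii"))
        write_map(self.valid.astype(np.int16), voxel_size_mm,
                  prefix.parent / (prefix.name + "_valid.nii"))
        sidecar = dict(self.meta)
        sidecar.update(floor_pct=self.floor_pct, source=self.source,
                       n_valid=int(self.valid.sum()))
        (prefix.parent / (prefix.name + ".json")).write_text(json.dumps(sidecar, indent=2))


def glm_beta(
    run: Bold4D,
    regressor: ReferenceWaveform | np.ndarray,
    mask: np.ndarray | None = None,
    design_label: str = "",
) -> BetaMap:
    """Voxel-wise OLS with intercept + linear drift + regressor columns.

    With unit-peak regressors on percent-change data, the beta reads
    directly as the response amplitude in percent signal change.
    """
    reg = regressor.values if isinstance(regressor, ReferenceWaveform) else np.asarray(regressor, float)
    n_t = run.n_volumes
    if reg.size != n_t:
        raise ValueError(f"regressor length {reg.size} != n_volumes {n_t}")
    if run.units != UNITS_PERCENT:
        raise ValueError("glm_beta expects percent-change input")
    if mask is None:
        mask = np.all(np.isfinite(run.data), axis=-1)
    t = run.time_axis_s
    X = np.column_stack([np.ones(n_t), (t - t.mean()) / max(t.max(), 1.0), reg])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    Y = run.data[mask].T                          # (n_t, n_vox)
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = n_t - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se_vec = np.sqrt(sigma2 * xtx_inv[2, 2])
    beta = np.full(run.grid_shape, np.nan)
    se = np.full(run.grid_shape, np.nan)
    beta[mask] = coef[2]
    se[mask] = se_vec
    return BetaMap(beta=beta, se=se, design_label=design_label,
                   meta=dict(run.meta))


def bh_amplitude_map(
    gamma_maps: GammaParamMaps | None = None,
    bh_beta: BetaMap | None = None,
    source: str = "gamma_smax",
) -> tuple[np.ndarray, str]:
    """Breath-hold amplitude map from the gamma fits (default) or BH GLM."""
    if source == "gamma_smax":
        if gamma_maps is None:
            raise ValueError("gamma_smax source requested but no gamma maps given")
        return gamma_maps.smax, source
    if source == "glm_beta":
        if bh_beta is None:
            raise ValueError("glm_beta source requested but no BH beta map given")
        return bh_beta.beta, source
    raise ValueError(f"unknown amplitude source {source!r}")


def scale_map(
    task_beta: BetaMap | np.ndarray,
    bh_amplitude: np.ndarray,
    floor_pct: float | None = None,
    bh_se: np.ndarray | None = None,
    source: str = "gamma_smax",
) -> ScaledMap:
    """Divide task betas by BH amplitude where the amplitude clears a floor.

    Default floor = max(0.05, 2 x median BH amplitude SE) percent; voxels
    below the floor are invalid rather than clipped.  The sign of the task
    beta is preserved.
    """
    beta = task_beta.beta if isinstance(task_beta, BetaMap) else np.asarray(task_beta, float)
    amp = np.asarray(bh_amplitude, dtype=float)
    if beta.shape != amp.shape:
        raise ValueError(f"grid mismatch {beta.shape} vs {amp.shape}")
    if floor_pct is None:
        med_se = (float(np.nanmedian(bh_se)) if bh_se is not None
                  and np.isfinite(bh_se).any() else 0.0)
        floor_pct = max(0.05, 2.0 * med_se)
    with np.errstate(invalid="ignore"):
        valid = np.isfinite(beta) & np.isfinite(amp) & (amp >= floor_pct)
    scaled = np.full(beta.shape, np.nan)
    scaled[valid] = beta[valid] / amp[valid]
    return ScaledMap(scaled=scaled, valid=valid, floor_pct=float(floor_pct),
                     source=source)


def activation_compare(before: ActivationMap, after: ActivationMap,
                       roi_mask: np.ndarray) -> dict:
    """Before/after activation summary: ROI hit counts, amplitude SD,
    and cluster compactness (largest-cluster fraction)."""
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != before.active.shape or roi.shape != after.active.shape:
        raise ValueError("grid mismatch between maps and ROI")
    if not roi.any():
        raise ValueError("empty ROI")

    def summarize(m: ActivationMap) -> dict:
        act = m.active
        vals = m.statistic[act]
        n_act = int(act.sum())
        if m.clusters.max() > 0:
            largest = int((m.clusters == 1).sum())
            compact = largest / n_act if n_act else 0.0
        else:
            compact = 0.0
        return dict(
            n_active=n_act,
            n_in_roi=int((act & roi).sum()),
            n_out_roi=int((act & ~roi).sum()),
            amplitude_sd=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
            largest_cluster_fraction=float(compact),
        )

    return dict(before=summarize(before), after=summarize(after))


def bartlett_test(*groups) -> tuple[float, float]:
    """Bartlett's test of homogeneity of variance.

    T = [(N - k) ln s_p^2 - sum (n_i - 1) ln s_i^2] / C with the usual
    correction factor C; p-value from chi-square with k - 1 df.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    n = np.array([g.size for g in groups])
    if np.any(n < 2):
        raise ValueError("each group needs >= 2 values")
    s2 = np.array([g.var(ddof=1) for g in groups])
    if np.any(s2 <= 0):
        raise ValueError("non-positive group variance")
    N = n.sum()
    sp2 = np.sum((n - 1) * s2) / (N - k)
    T = (N - k) * np.log(sp2) - np.sum((n - 1) * np.log(s2))
    C = 1.0 + (np.sum(1.0 / (n - 1)) - 1.0 / (N - k)) / (3.0 * (k - 1))
    T /= C
    p = float(stats.chi2.sf(T, k - 1))
    return float(T), p


def distribution_report(values_before, values_after, n_bins: int = 30) -> dict:
    """Histograms, medians, variances, and Bartlett comparison of the
    amplitude distributions before and after scaling."""
    before = np.asarray(values_before, dtype=float)
    after = np.asarray(values_after, dtype=float)
    before = before[np.isfinite(before)]
    after = after[np.isfinite(after)]
    if before.size < 10 or after.size < 10:
        raise ValueError("need >= 10 values in each distribution")
    lo = min(before.min(), after.min())
    hi = max(before.max(), after.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    h_before, _ = np.histogram(before, bins=edges)
    h_after, _ = np.histogram(after, bins=edges)
    if before.var(ddof=1) > 0 and after.var(ddof=1) > 0:
        T, p = bartlett_test(before, after)
    else:
        T, p = 0.0, 1.0
    return dict(
        bin_edges=[float(e) for e in edges],
        hist_before=[int(c) for c in h_before],
        hist_after=[int(c) for c in h_after],
        median_before=float(np.median(before)),
        median_after=float(np.median(after)),
        var_before=float(before.var(ddof=1)),
        var_after=float(after.var(ddof=1)),
        bartlett_T=T,
        bartlett_df=1,
        bartlett_p=p,
    )
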