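"""Voxel-wise gamma-variate fitting of breath-hold responses.

The response template is ``S(t) = Q (t - t0)^r exp(-(t - t0)/b)`` for
``t > t0`` and 0 otherwise.  A breath-hold run is modeled as one such
response per hold epoch with shared (Q, t0, r, b), where t0 is the onset
delay relative to the hold onset, plus a constant baseline offset.

Fitting is multistart bounded nonlinear least squares: per repeat,
``n_starts`` random parameter draws are scored (with the amplitude and
baseline solved in closed form, since the model is linear in both), the
``n_keep`` lowest-RSS solutions are kept, and the final estimate is the
element-wise median of all kept solutions across repeats with the
amplitude re-projected onto the median-shape template.  Optional local
least-squares refinement serves high-precision (high-SNR) use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gamma as gamma_fn

from .core import Bold4D, UNITS_PERCENT, write_map, read_map
from .paradigm import BlockDesign

__all__ = [
    "FitBounds",
    "GammaParams",
    "GammaParamMaps",
    "gamma_variate",
    "derived_params",
    "fit_voxel",
    "fit_volume",
    "segment_tissue",
    "gm_wm_stats",
    "split_epochs",
    "epoch_reliability",
]

PARAM_NAMES = ("q", "t0", "r", "b")


@dataclass(frozen=True)
class FitBounds:
    """Box bounds for (Q, t0, r, b); t0 is seconds after hold onset.

    ``max_tmax_s`` additionally caps the time-to-peak t0 + r*b: peaks far
    past the hold onset are non-physiological, and templates peaking
    beyond the sampled window have unconstrained (exploding) amplitude.
    """

    q: tuple[float, float] = (0.0, 50.0)
    t0: tuple[float, float] = (0.0, 30.0)
    r: tuple[float, float] = (0.5, 8.0)
    b: tuple[float, float] = (0.5, 20.0)
    max_tmax_s: float = 45.0

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.q[0], self.t0[0], self.r[0], self.b[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.q[1], self.t0[1], self.r[1], self.b[1]])


@dataclass
class GammaParams:
    """One voxel's fitted parameters.  t0 is relative to hold onset."""

    q: float
    t0: float
    r: float
    b: float
    rss: float
    converged: bool
    baseline: float = 0.0
    best_rss: float = np.nan  # lowest RSS over all polished starts


@dataclass
class GammaParamMaps:
    """Per-voxel fits plus derived maps; NaN outside the fitted mask."""

    q: np.ndarray
    t0: np.ndarray
    r: np.ndarray
    b: np.ndarray
    rss: np.ndarray
    converged: np.ndarray
    smax: np.ndarray
    tmax: np.ndarray
    sarea: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    _MAP_ORDER = ("q", "t0", "r", "b", "rss", "smax", "tmax", "sarea")

    def param_maps(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self._MAP_ORDER}

    def write(self, prefix: str | Path, voxel_size_mm=(2.5, 2.5, 3.0)) -> Path:
        """Multi-volume NIfTI (parameter order in the JSON sidecar)."""
        prefix = Path(prefix)
        stack = np.stack(
            [getattr(self, n) for n in self._MAP_ORDER]
            + [self.converged.astype(float), self.mask.astype(float)],
            axis=-1,
        )
        nii = prefix.with_suffix(".nii")
        write_map(stack, voxel_size_mm, nii)
        sidecar = dict(self.meta)
        sidecar["volumes"] = list(self._MAP_ORDER) + ["converged", "mask"]
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return nii

    @classmethod
    def read(cls, prefix: str | Path) -> "GammaParamMaps":
        prefix = Path(prefix)
        stack = read_map(prefix.with_suffix(".nii"))
        meta = json.loads(prefix.with_suffix(".json").read_text())
        names = meta.pop("volumes")
        vols = {n: stack[..., i] for i, n in enumerate(names)}
        return cls(
            q=vols["q"], t0=vols["t0"], r=vols["r"], b=vols["b"], rss=vols["rss"],
            converged=vols["converged"] > 0.5, smax=vols["smax"], tmax=vols["tmax"],
            sarea=vols["sarea"], mask=vols["mask"] > 0.5, meta=meta,
        )


def gamma_variate(t, q: float, t0: float, r: float, b: float):
    """``Q (t-t0)^r exp(-(t-t0)/b)`` for t > t0, else 0."""
    t = np.asarray(t, dtype=float)
    dt = t - t0
    out = np.zeros_like(dt)
    pos = dt > 0
    out[pos] = q * dt[pos] ** r * np.exp(-dt[pos] / b)
    return out if out.ndim else float(out)


def derived_params(q: float, t0: float, r: float, b: float) -> tuple[float, float, float]:
    """Closed-form (Smax, Tmax, SArea) of the gamma-variate response."""
    tmax = t0 + r * b
    smax = q * (r * b) ** r * np.exp(-r)
    sarea = q * b ** (r + 1) * gamma_fn(r + 1)
    return float(smax), float(tmax), float(sarea)


def amplitude_to_q(amp: float, r: float, b: float) -> float:
    """Q that gives a peak response of ``amp``."""
    return amp / ((r * b) ** r * np.exp(-r))


def _epoch_model(t: np.ndarray, onsets: np.ndarray, params: np.ndarray) -> np.ndarray:
    q, t0, r, b = params
    out = np.zeros_like(t)
    for onset in onsets:
        out += gamma_variate(t, q, onset + t0, r, b)
    return out


def _model_with_baseline(t, onsets, params4, y):
    """Given shape params, the optimal constant baseline is analytic."""
    m = _epoch_model(t, onsets, params4)
    c = float(np.mean(y - m))
    return m + c, c


def _rss_of(t, onsets, params4, y) -> float:
    m, _ = _model_with_baseline(t, onsets, params4, y)
    return float(np.sum((y - m) ** 2))


def _model_jacobian(t: np.ndarray, onsets: np.ndarray, params: np.ndarray) -> np.ndarray:
    """d(model)/d(Q, t0, r, b), with the analytic-baseline column means
    removed (the baseline soaks up any constant component)."""
    q, t0, r, b = params
    J = np.zeros((t.size, 4))
    for onset in onsets:
        u = t - (onset + t0)
        pos = u > 0
        up = u[pos]
        core = up ** r * np.exp(-up / b)
        g = q * core
        J[pos, 0] += core
        J[pos, 1] += -g * (r / up - 1.0 / b)
        J[pos, 2] += g * np.log(up)
        J[pos, 3] += g * up / (b * b)
    return J - J.mean(axis=0, keepdims=True)


def fit_voxel(
    percent_series: np.ndarray,
    time_axis: np.ndarray,
    epoch_onsets,
    bounds: FitBounds | None = None,
    n_starts: int = 1000,
    n_keep: int = 5,
    n_repeats: int = 10,
    n_refine: int | None = 0,
    final_polish: bool = False,
    seed: int | np.random.Generator = 0,
) -> GammaParams:
    """Multistart gamma-variate fit of one percent-change voxel series.

    ``epoch_onsets`` are the hold-onset times (s) on ``time_axis``; all
    epochs share one parameter set.  ``n_refine`` limits how many of the
    ``n_starts`` draws per repeat are polished by least squares (None
    polishes all of them).  The reported estimate is the element-wise
    median of the kept solutions; at low SNR this ensemble median is a
    markedly better onset estimator than the single best-RSS solution,
    which slides along the t0/r/b trade-off ridge, so re-polishing the
    median (``final_polish``) is off by default.  Deterministic for a
    given seed.
    """
    y = np.asarray(percent_series, dtype=float)
    t = np.asarray(time_axis, dtype=float)
    onsets = np.atleast_1d(np.asarray(epoch_onsets, dtype=float))
    if y.shape != t.shape:
        raise ValueError("series and time axis must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in voxel series")
    if onsets.min() < t[0] or onsets.max() > t[-1]:
        raise ValueError("epoch window outside the sampled time axis")
    if n_starts < n_keep:
        raise ValueError(f"n_starts={n_starts} < n_keep={n_keep}")
    bounds = bounds or FitBounds()
    lo, hi = bounds.lower, bounds.upper
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def residuals(p):
        m, _ = _model_with_baseline(t, onsets, p, y)
        return m - y

    def jacobian(p):
        return _model_jacobian(t, onsets, p)

    yc = y - y.mean()

    def with_optimal_q(shape3: np.ndarray) -> np.ndarray:
        """Start point: drawn (t0, r, b) with the analytically optimal
        (clipped) amplitude — the model is linear in Q."""
        h = _template(t, onsets, *shape3)
        hc = h - h.mean()
        hh = float(hc @ hc)
        q = float(np.clip(yc @ hc / hh, lo[0], hi[0])) if hh > 0 else lo[0]
        return np.array([q, *shape3])

    kept: list[np.ndarray] = []
    kept_rss: list[float] = []
    best_rss = np.inf
    any_success = False
    for _ in range(n_repeats):
        draws3 = lo[1:] + rng.uniform(size=(n_starts, 3)) * (hi[1:] - lo[1:])
        ok3 = draws3[:, 0] + draws3[:, 1] * draws3[:, 2] <= bounds.max_tmax_s
        while ok3.sum() < max(n_keep, n_starts // 4):
            extra = lo[1:] + rng.uniform(size=(n_starts, 3)) * (hi[1:] - lo[1:])
            draws3 = np.vstack([draws3[ok3], extra])
            ok3 = draws3[:, 0] + draws3[:, 1] * draws3[:, 2] <= bounds.max_tmax_s
        draws3 = draws3[ok3][:n_starts]
        starts = np.stack([with_optimal_q(d3) for d3 in draws3])
        init_rss = np.array([_rss_of(t, onsets, p, y) for p in starts])
        order = np.argsort(init_rss, kind="stable")
        if n_refine == 0:  # pure screened multistart, no local optimization
            for i in order[:n_keep]:
                kept.append(starts[i])
                kept_rss.append(init_rss[i])
            best_rss = min(best_rss, float(init_rss[order[0]]))
            any_success = True
            continue
        refine_idx = order if n_refine is None else order[: max(n_refine, n_keep)]
        sols, rsss = [], []
        for i in refine_idx:
            try:
                res = least_squares(
                    residuals, starts[i], jac=jacobian, bounds=(lo, hi),
                    method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
                    max_nfev=100,
                )
            except Exception:
                continue
            any_success = any_success or res.success
            sols.append(res.x)
            rsss.append(_rss_of(t, onsets, res.x, y))
        if not sols:
            continue
        k_order = np.argsort(rsss, kind="stable")[:n_keep]
        for i in k_order:
            kept.append(sols[i])
            kept_rss.append(rsss[i])
        best_rss = min(best_rss, min(rsss))

    if not kept:
        return GammaParams(np.nan, np.nan, np.nan, np.nan, np.nan, False)

    median_p = np.median(np.stack(kept), axis=0)
    # medians of the coupled (Q, r, b) draws are mutually incoherent; fix
    # the amplitude by re-projecting the data onto the median-shape template
    h = _template(t, onsets, *median_p[1:])
    hc = h - h.mean()
    hh = float(hc @ hc)
    if hh > 0:
        median_p[0] = float(np.clip(yc @ hc / hh, lo[0], hi[0]))
    final, converged = median_p, any_success
    if final_polish:
        try:
            res = least_squares(
                residuals, np.clip(median_p, lo, hi), jac=jacobian, bounds=(lo, hi),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=200,
            )
            final = res.x
            converged = bool(res.success) or any_success
        except Exception:
            pass
        # the polished median can land in a worse local minimum than the
        # best individual solution; keep whichever fits better
        i_best = int(np.argmin(kept_rss))
        if _rss_of(t, onsets, kept[i_best], y) < _rss_of(t, onsets, final, y):
            final = kept[i_best]
    rss = _rss_of(t, onsets, final, y)
    _, baseline = _model_with_baseline(t, onsets, final, y)
    return GammaParams(
        q=float(final[0]), t0=float(final[1]), r=float(final[2]), b=float(final[3]),
        rss=rss, converged=converged, baseline=baseline,
        best_rss=float(min(best_rss, rss)),
    )


def _template(t: np.ndarray, onsets: np.ndarray, t0: float, r: float, b: float) -> np.ndarray:
    """Unit-Q multi-epoch gamma-variate template."""
    out = np.zeros_like(t)
    for onset in onsets:
        u = t - (onset + t0)
        pos = u > 0
        out[pos] += u[pos] ** r * np.exp(-u[pos] / b)
    return out


def fit_volume(
    run: Bold4D,
    design: BlockDesign,
    mask: np.ndarray | None = None,
    bounds: FitBounds | None = None,
    n_starts: int = 100,
    n_keep: int = 5,
    n_repeats: int = 5,
    polish: bool = False,
    seed: int = 0,
) -> GammaParamMaps:
    """Fit every masked voxel of a percent-change breath-hold run.

    Epochs are fitted jointly (shared parameters, per-epoch onsets from
    the design).  The multistart is vectorized across voxels: for each
    random (t0, r, b) draw the optimal amplitude and baseline are solved
    in closed form (the model is linear in both), the ``n_keep`` best
    candidates per voxel and repeat are kept, and the element-wise median
    of the kept solutions is polished by bounded least squares per voxel.
    Defaults are desk-scale; raise ``n_starts``/``n_repeats`` toward
    production settings as needed.  Per-voxel failures are recorded,
    never fatal for the volume.
    """
    if run.units != UNITS_PERCENT:
        raise ValueError(
            "fit_volume requires percent-change input; convert with "
            "preprocess.to_percent_change first"
        )
    if not design.epochs:
        raise ValueError("design has no hold epochs")
    if mask is None:
        mask = np.all(np.isfinite(run.data), axis=-1) & np.any(run.data != 0, axis=-1)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.grid_shape:
        raise ValueError("mask shape does not match run grid")
    bounds = bounds or FitBounds()
    onsets = design.onsets(design.conditions[0])
    t = run.time_axis_s
    rng = np.random.default_rng(seed)

    Y = run.data[mask]                                  # (n_vox, T)
    good = np.all(np.isfinite(Y), axis=1)
    yc = Y - Y.mean(axis=1, keepdims=True)
    n_vox = Y.shape[0]
    lo3 = np.array([bounds.t0[0], bounds.r[0], bounds.b[0]])
    hi3 = np.array([bounds.t0[1], bounds.r[1], bounds.b[1]])

    kept_params = []                                    # each (n_vox, 4)
    for _ in range(n_repeats):
        draws = lo3 + rng.uniform(size=(n_starts, 3)) * (hi3 - lo3)
        ok3 = draws[:, 0] + draws[:, 1] * draws[:, 2] <= bounds.max_tmax_s
        while ok3.sum() < max(n_keep, n_starts // 4):
            extra = lo3 + rng.uniform(size=(n_starts, 3)) * (hi3 - lo3)
            draws = np.vstack([draws[ok3], extra])
            ok3 = draws[:, 0] + draws[:, 1] * draws[:, 2] <= bounds.max_tmax_s
        draws = draws[ok3][:n_starts]
        H = np.stack([_template(t, onsets, *d) for d in draws])   # (S, T)
        Hc = H - H.mean(axis=1, keepdims=True)
        hh = np.sum(Hc * Hc, axis=1)                    # (S,)
        hh = np.where(hh > 0, hh, np.inf)
        proj = yc @ Hc.T                                # (n_vox, S)
        q = np.clip(proj / hh[None, :], bounds.q[0], bounds.q[1])
        rss = np.sum(yc * yc, axis=1)[:, None] - 2 * q * proj + q * q * hh[None, :]
        order = np.argsort(rss, axis=1, kind="stable")[:, :n_keep]  # (n_vox, keep)
        for col in range(order.shape[1]):
            sel = order[:, col]
            kept_params.append(np.column_stack([
                q[np.arange(n_vox), sel], draws[sel, 0], draws[sel, 1], draws[sel, 2],
            ]))
    median_p = np.median(np.stack(kept_params), axis=0)  # (n_vox, 4)
    # re-project amplitude onto each voxel's median-shape template (the
    # median of the coupled Q draws is incoherent with the median shape)
    for v in range(n_vox):
        h = _template(t, onsets, *median_p[v, 1:])
        hc = h - h.mean()
        hh = float(hc @ hc)
        if hh > 0:
            median_p[v, 0] = float(np.clip(yc[v] @ hc / hh, bounds.q[0], bounds.q[1]))

    lo4, hi4 = bounds.lower, bounds.upper
    shape = run.grid_shape
    maps = {n: np.full(shape, np.nan) for n in
            ("q", "t0", "r", "b", "rss", "smax", "tmax", "sarea")}
    converged = np.zeros(shape, dtype=bool)
    vox_idx = np.argwhere(mask)
    n_failed = 0
    for v in range(n_vox):
        i, j, k = vox_idx[v]
        if not good[v]:
            n_failed += 1
            continue
        y = Y[v]
        p0 = np.clip(median_p[v], lo4, hi4)
        if polish:
            try:
                res = least_squares(
                    lambda p: _model_with_baseline(t, onsets, p, y)[0] - y,
                    p0, jac=lambda p: _model_jacobian(t, onsets, p),
                    bounds=(lo4, hi4), method="trf",
                    xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=60,
                )
                p_fit, ok = res.x, True
            except Exception:
                p_fit, ok = p0, False
                n_failed += 1
        else:
            p_fit, ok = p0, True
        maps["q"][i, j, k] = p_fit[0]
        maps["t0"][i, j, k] = p_fit[1]
        maps["r"][i, j, k] = p_fit[2]
        maps["b"][i, j, k] = p_fit[3]
        maps["rss"][i, j, k] = _rss_of(t, onsets, p_fit, y)
        converged[i, j, k] = ok
        smax, tmax, sarea = derived_params(*p_fit)
        maps["smax"][i, j, k] = smax
        maps["tmax"][i, j, k] = tmax
        maps["sarea"][i, j, k] = sarea

    meta = dict(
        seed=seed, n_starts=n_starts, n_keep=n_keep, n_repeats=n_repeats,
        n_failed=int(n_failed), polish=bool(polish),
        bounds=dict(q=list(bounds.q), t0=list(bounds.t0), r=list(bounds.r),
                    b=list(bounds.b)),
        t0_reference="hold_onset",
        epoch_onsets_s=[float(o) for o in onsets],
    )
    return GammaParamMaps(
        q=maps["q"], t0=maps["t0"], r=maps["r"], b=maps["b"], rss=maps["rss"],
        converged=converged, smax=maps["smax"], tmax=maps["tmax"],
        sarea=maps["sarea"], mask=mask, meta=meta,
    )


def segment_tissue(maps: GammaParamMaps, vessel_percentile: float = 99.0) -> dict:
    """Classify fitted voxels into GM-like / WM-like / vessel-like.

    Otsu's threshold on the SArea map separates GM-like from WM-like;
    voxels above the ``vessel_percentile`` of SArea are vessel-like.
    """
    from skimage.filters import threshold_otsu

    fitted = maps.mask & maps.converged & np.isfinite(maps.sarea)
    if fitted.sum() == 0 or fitted.sum() < 0.5 * maps.mask.sum():
        raise ValueError("fewer than 50% of masked voxels converged")
    vals = maps.sarea[fitted]
    if np.ptp(vals) == 0:
        raise ValueError("degenerate (constant) SArea map")
    otsu = float(threshold_otsu(vals))
    vessel_cut = float(np.percentile(vals, vessel_percentile))
    labels = np.zeros(maps.mask.shape, dtype="U12")
    labels[fitted & (maps.sarea < otsu)] = "WM-like"
    labels[fitted & (maps.sarea >= otsu)] = "GM-like"
    labels[fitted & (maps.sarea > vessel_cut)] = "vessel-like"
    return dict(labels=labels, sarea_threshold=otsu, vessel_threshold=vessel_cut)


def gm_wm_stats(maps: GammaParamMaps, labels: np.ndarray) -> dict:
    """Per-class mean +/- SD of Smax, t0, SArea and the GM/WM SArea ratio."""
    out: dict = {"classes": {}}
    for cls in ("GM-like", "WM-like", "vessel-like"):
        sel = labels == cls
        if cls in ("GM-like", "WM-like") and sel.sum() == 0:
            raise ValueError(f"empty class {cls}")
        if sel.sum() == 0:
            continue
        out["classes"][cls] = {
            name: dict(mean=float(np.nanmean(arr[sel])), sd=float(np.nanstd(arr[sel], ddof=1))
                       if sel.sum() > 1 else 0.0)
            for name, arr in (("smax", maps.smax), ("t0", maps.t0), ("sarea", maps.sarea))
        }
    gm = out["classes"]["GM-like"]["sarea"]["mean"]
    wm = out["classes"]["WM-like"]["sarea"]["mean"]
    out["gm_wm_sarea_ratio"] = float(gm / wm) if wm != 0 else float("inf")
    return out


def split_epochs(run: Bold4D, design: BlockDesign) -> list[tuple[Bold4D, BlockDesign]]:
    """Break a 3-epoch run into three single-epoch sub-runs.

    Sub-run ``k`` spans [onset_k, onset_k + cycle) re-timed to start at 0,
    where the cycle is the onset-to-onset spacing; the initial rest
    lead-in is dropped.
    """
    cond = design.conditions[0] if design.epochs else None
    onsets = design.onsets(cond) if cond else np.array([])
    if len(onsets) != 3:
        raise ValueError(f"split_epochs requires exactly 3 epochs, got {len(onsets)}")
    durs = [d for c, o, d in design.epochs if c == cond]
    cycle_s = float(onsets[1] - onsets[0])
    if not np.isclose(onsets[2] - onsets[1], cycle_s):
        raise ValueError("epochs are not uniformly spaced")
    n_sub = int(round(cycle_s / design.tr_s))
    out = []
    for k, onset in enumerate(onsets):
        i0 = int(round(onset / design.tr_s))
        sub = run.copy_with(data=run.data[..., i0:i0 + n_sub])
        sub_design = BlockDesign(
            tr_s=design.tr_s, n_volumes=n_sub,
            epochs=((cond, 0.0, durs[k]),), lead_in_rest_s=0.0,
        )
        out.append((sub, sub_design))
    return out


def epoch_reliability(
    maps_list: list[GammaParamMaps],
    params: tuple[str, ...] = ("q", "t0", "r", "b", "smax", "sarea"),
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Across-voxel correlation of fit parameters between epoch pairs.

    For each parameter and each pair of epoch maps, the Pearson
    correlation over common converged voxels is computed, with a voxel
    bootstrap (``n_boot`` resamples) giving mean +/- SD and a 95% CI.
    """
    if len(maps_list) < 2:
        raise ValueError("need at least two epoch maps")
    common = maps_list[0].mask & maps_list[0].converged
    for m in maps_list[1:]:
        common = common & m.mask & m.converged
    for name in params:
        for m in maps_list:
            common = common & np.isfinite(getattr(m, name))
    n_common = int(common.sum())
    if n_common < 10:
        raise ValueError(f"only {n_common} common voxels (need >= 10)")

    rng = np.random.default_rng(seed)
    out: dict = {"n_voxels": n_common, "pairs": {}}
    pairs = [(a, b) for a in range(len(maps_list)) for b in range(a + 1, len(maps_list))]
    for a, b in pairs:
        key = f"{a + 1}-{b + 1}"
        out["pairs"][key] = {}
        for name in params:
            x = getattr(maps_list[a], name)[common]
            y = getattr(maps_list[b], name)[common]
            r = _pearson(x, y)
            idx = rng.integers(0, n_common, size=(n_boot, n_common))
            boot = np.array([_pearson(x[i], y[i]) for i in idx])
            boot = boot[np.isfinite(boot)]
            lo_ci, hi_ci = (np.percentile(boot, [2.5, 97.5])
                            if boot.size else (np.nan, np.nan))
            out["pairs"][key][name] = dict(
                r=float(r),
                boot_mean=float(np.mean(boot)) if boot.size else np.nan,
                boot_sd=float(np.std(boot, ddof=1)) if boot.size > 1 else 0.0,
                ci95=[float(lo_ci), float(hi_ci)],
            )
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)
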