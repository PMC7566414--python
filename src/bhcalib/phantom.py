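"""Synthetic 4D BOLD phantom with known vascular and neural ground truth.

The phantom is a brain-shaped ellipsoid with a white-matter core, a
gray-matter shell, one or more small high-amplitude vessel blobs, and an
optional tumor-margin blob with suppressed vascular gain.  Breath-hold
runs add a gamma-variate response per hold epoch whose peak percent
change per voxel is ``tissue amplitude x vascular gain``; task runs add
``neural amplitude x vascular gain`` times the unit-peak canonical
regressor.  Dividing task amplitude by breath-hold amplitude therefore
recovers neural amplitude up to the constant tissue factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Bold4D, UNITS_RAW, write_run, read_run  # noqa: F401 (re-export)
from .gammafit import amplitude_to_q, gamma_variate
from .paradigm import BlockDesign, task_regressor

__all__ = [
    "PhantomSpec",
    "TruthMaps",
    "make_labels",
    "make_truth",
    "simulate_bh_run",
    "simulate_task_run",
    "write_run",
    "read_run",
    "write_motion_trace",
]

LABELS = ("background", "GM", "WM", "vessel", "tumor-margin")


@dataclass
class PhantomSpec:
    """Generative parameters for the synthetic phantom."""

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 3.0)
    tr_s: float = 3.0
    baseline_intensity: float = 1000.0
    noise_sd_pct: float = 0.2
    drift_pct_per_run: float = 0.3
    tissue_bh_amp_pct: dict = field(default_factory=lambda: {
        "GM": 0.25, "WM": 0.06, "vessel": 1.2, "tumor-margin": 0.10,
    })
    tissue_t0_s: dict = field(default_factory=lambda: {
        "GM": 4.0, "WM": 7.0, "vessel": 2.0, "tumor-margin": 5.0,
    })
    # shared gamma-variate shape; r*b = 12 s puts the peak ~15-20 s after
    # hold onset once the tissue onset delay is added
    gamma_r: float = 3.0
    gamma_b: float = 4.0
    gain_sd_log: float = 0.5
    tumor_gain_factor: float = 0.4
    neural_amp_pct: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.noise_sd_pct < 0:
            raise ValueError("noise_sd_pct must be >= 0")
        if any(v < 0 for v in self.tissue_bh_amp_pct.values()):
            raise ValueError("tissue amplitudes must be >= 0")


@dataclass
class TruthMaps:
    """Ground truth the pipeline is expected to recover."""

    tissue_labels: np.ndarray       # str per voxel, one of LABELS
    neural_amp: np.ndarray          # percent, task drive before vascular gain
    vascular_gain: np.ndarray       # dimensionless multiplicative gain
    bh_amp_pct: np.ndarray          # tissue default x gain
    t0_s: np.ndarray                # onset delay after hold onset
    t0_run_start_s: np.ndarray | None = None  # same delays + first hold onset

    def __post_init__(self) -> None:
        if not set(np.unique(self.tissue_labels)) <= set(LABELS):
            raise ValueError("unknown tissue label in truth maps")


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semi):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_labels(grid_shape=(32, 32, 16), seed: int = 0) -> np.ndarray:
    """Deterministic tissue label volume: WM core, GM shell, vessel and
    tumor-margin blobs.  Requires at least 16 voxels per axis."""
    if any(s < 16 for s in grid_shape):
        raise ValueError(f"grid too small, need >= 16 per axis, got {grid_shape}")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in grid_shape)
    center = np.array(shape) / 2 - 0.5 + rng.uniform(-0.5, 0.5, size=3)
    outer = np.array(shape) * 0.44
    inner = outer * 0.62
    brain = _ellipsoid(shape, center, outer)
    wm = _ellipsoid(shape, center, inner)
    labels = np.full(shape, "background", dtype="U12")
    labels[brain] = "GM"
    labels[wm] = "WM"

    gm_idx = np.argwhere(labels == "GM")
    # vessel blobs: small spheres seeded in the GM shell
    for _ in range(2):
        c = gm_idx[rng.integers(len(gm_idx))]
        blob = _ellipsoid(shape, c, (1.6, 1.6, 1.2))
        labels[blob & (labels != "background")] = "vessel"
    # one tumor-margin blob in GM
    c = gm_idx[rng.integers(len(gm_idx))]
    blob = _ellipsoid(shape, c, (3.0, 3.0, 2.0))
    labels[blob & np.isin(labels, ("GM", "WM"))] = "tumor-margin"
    return labels


def make_truth(labels: np.ndarray, spec: PhantomSpec,
               task_blob_center=None, task_blob_radius: float = 4.0) -> TruthMaps:
    """Build per-voxel gain / amplitude truth maps from a label volume.

    Vascular gain is lognormal around 1 (suppressed inside the tumor
    margin); neural amplitude is ``spec.neural_amp_pct`` inside a
    spherical GM blob and 0 elsewhere.
    """
    rng = np.random.default_rng(spec.seed + 1)
    shape = labels.shape
    gain = np.ones(shape)
    in_brain = labels != "background"
    gain[in_brain] = np.exp(rng.normal(0.0, spec.gain_sd_log, size=int(in_brain.sum())))
    gain[labels == "tumor-margin"] *= spec.tumor_gain_factor
    gain[~in_brain] = 0.0

    bh_amp = np.zeros(shape)
    t0 = np.zeros(shape)
    for lab in LABELS[1:]:
        sel = labels == lab
        bh_amp[sel] = spec.tissue_bh_amp_pct.get(lab, 0.0) * gain[sel]
        t0[sel] = spec.tissue_t0_s.get(lab, 4.0)

    neural = np.zeros(shape)
    if task_blob_center is None:
        gm_idx = np.argwhere(labels == "GM")
        task_blob_center = gm_idx[len(gm_idx) // 3]
    blob = _ellipsoid(shape, task_blob_center, (task_blob_radius,) * 3)
    neural[blob & (labels == "GM")] = spec.neural_amp_pct
    return TruthMaps(
        tissue_labels=labels, neural_amp=neural, vascular_gain=gain,
        bh_amp_pct=bh_amp, t0_s=t0,
    )


def _noise_and_drift(spec: PhantomSpec, shape4d, rng) -> np.ndarray:
    """Additive fractional (of baseline) noise + centered linear drift."""
    n_t = shape4d[-1]
    frac = np.zeros(shape4d)
    if spec.drift_pct_per_run:
        ramp = np.linspace(-0.5, 0.5, n_t) * spec.drift_pct_per_run / 100.0
        frac += ramp
    if spec.noise_sd_pct:
        frac += rng.normal(0.0, spec.noise_sd_pct / 100.0, size=shape4d)
    return frac


def bh_response_pct(truth: TruthMaps, spec: PhantomSpec, design: BlockDesign) -> np.ndarray:
    """Noiseless breath-hold response in percent of baseline, (x,y,z,t)."""
    onsets = design.onsets(design.conditions[0])
    t = np.arange(design.n_volumes) * design.tr_s
    # unit-amplitude template per distinct t0 delay, scaled per voxel
    resp = np.zeros(truth.bh_amp_pct.shape + (design.n_volumes,))
    for delay in np.unique(truth.t0_s[truth.bh_amp_pct > 0]):
        q1 = amplitude_to_q(1.0, spec.gamma_r, spec.gamma_b)
        template = np.zeros_like(t)
        for onset in onsets:
            template += gamma_variate(t, q1, onset + delay, spec.gamma_r, spec.gamma_b)
        sel = (truth.t0_s == delay) & (truth.bh_amp_pct > 0)
        resp[sel] = truth.bh_amp_pct[sel, None] * template[None, :]
    return resp


def simulate_bh_run(
    labels: np.ndarray, spec: PhantomSpec, design: BlockDesign,
    truth: TruthMaps | None = None,
) -> tuple[Bold4D, TruthMaps]:
    """Simulate a breath-hold run; signal peaks ~15-20 s after hold onset."""
    if labels.shape != tuple(spec.grid_shape):
        raise ValueError(
            f"labels shape {labels.shape} != spec grid {tuple(spec.grid_shape)}"
        )
    if truth is None:
        truth = make_truth(labels, spec)
    truth.t0_run_start_s = truth.t0_s + float(design.onsets(design.conditions[0])[0])
    rng = np.random.default_rng(spec.seed + 11)
    resp = bh_response_pct(truth, spec, design)
    frac = _noise_and_drift(spec, resp.shape, rng)
    data = spec.baseline_intensity * (1.0 + resp / 100.0 + frac)
    data[labels == "background"] = spec.baseline_intensity * 0.02 * (
        1.0 + frac[labels == "background"]
    )
    run = Bold4D(data, tr_s=spec.tr_s, voxel_size_mm=spec.voxel_size_mm,
                 units=UNITS_RAW, meta=dict(seed=spec.seed, kind="breath_hold"))
    return run, truth


def simulate_task_run(
    labels: np.ndarray, spec: PhantomSpec, design: BlockDesign,
    truth: TruthMaps | None = None,
) -> tuple[Bold4D, TruthMaps]:
    """Simulate a task run: amplitude = neural_amp x vascular_gain (percent)."""
    if labels.shape != tuple(spec.grid_shape):
        raise ValueError(
            f"labels shape {labels.shape} != spec grid {tuple(spec.grid_shape)}"
        )
    if truth is None:
        truth = make_truth(labels, spec)
    rng = np.random.default_rng(spec.seed + 23)
    reg = task_regressor(design).values  # unit peak
    amp = truth.neural_amp * truth.vascular_gain  # percent
    resp = amp[..., None] * reg[None, None, None, :]
    frac = _noise_and_drift(spec, resp.shape, rng)
    data = spec.baseline_intensity * (1.0 + resp / 100.0 + frac)
    data[labels == "background"] = spec.baseline_intensity * 0.02 * (
        1.0 + frac[labels == "background"]
    )
    run = Bold4D(data, tr_s=spec.tr_s, voxel_size_mm=spec.voxel_size_mm,
                 units=UNITS_RAW, meta=dict(seed=spec.seed, kind="task"))
    return run, truth


def write_motion_trace(path: str | Path, n_volumes: int, seed: int = 0,
                       scale_mm: float = 0.05) -> Path:
    """Synthetic 6-column motion trace TSV (x, y, z, pitch, roll, yaw)."""
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.normal(0.0, scale_mm / 10.0, size=(n_volumes, 6)), axis=0)
    header = "x\ty\tz\tpitch\troll\tyaw"
    rows = ["\t".join(f"{v:.6f}" for v in row) for row in walk]
    Path(path).write_text(header + "\n" + "\n".join(rows) + "\n")
    return Path(path)
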