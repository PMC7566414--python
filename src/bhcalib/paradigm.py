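"""Block paradigms, reference waveforms, and GLM regressors.

The two designs used throughout the package are the breath-hold run
(30 s rest lead-in, then 3 x [16 s hold + 44 s recovery]) and the task
runs (30 s rest, then 3 x [30 s on + 30 s off]), both at TR = 3 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "BlockDesign",
    "ReferenceWaveform",
    "build_block_design",
    "bh_design",
    "task_design",
    "boxcar",
    "shift_waveform",
    "canonical_hrf",
    "convolve_regressor",
    "task_regressor",
    "bh_delayed_regressor",
    "design_to_yaml",
    "design_from_yaml",
    "waveform_to_tsv",
]

_EPS = 1e-9


@dataclass(frozen=True)
class BlockDesign:
    """On/off epochs of one or more conditions on a volume time grid."""

    tr_s: float
    n_volumes: int
    epochs: tuple[tuple[str, float, float], ...]  # (condition, onset_s, duration_s)
    lead_in_rest_s: float = 0.0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        total = self.n_volumes * self.tr_s
        for cond, onset, dur in self.epochs:
            if onset < 0:
                raise ValueError(f"epoch {cond!r} has negative onset {onset}")
            if onset + dur > total + _EPS:
                raise ValueError(
                    f"epoch {cond!r} ends at {onset + dur} s, past run end {total} s"
                )
        # non-overlap within a condition
        by_cond: dict[str, list[tuple[float, float]]] = {}
        for cond, onset, dur in self.epochs:
            by_cond.setdefault(cond, []).append((onset, dur))
        for cond, spans in by_cond.items():
            spans.sort()
            for (o1, d1), (o2, _) in zip(spans, spans[1:]):
                if o1 + d1 > o2 + _EPS:
                    raise ValueError(f"overlapping epochs in condition {cond!r}")

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for cond, _, _ in self.epochs:
            if cond not in seen:
                seen.append(cond)
        return tuple(seen)

    def onsets(self, condition: str) -> np.ndarray:
        """Epoch onsets (s) for one condition, sorted."""
        on = sorted(o for c, o, _ in self.epochs if c == condition)
        if not on:
            raise KeyError(f"condition {condition!r} not in design")
        return np.asarray(on, dtype=float)


@dataclass(frozen=True)
class ReferenceWaveform:
    """One dimensionless value per volume."""

    values: np.ndarray
    tr_s: float
    label: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("waveform values must be 1D")

    def __len__(self) -> int:
        return self.values.size


def _check_multiple(value: float, tr_s: float, name: str) -> None:
    if abs(value / tr_s - round(value / tr_s)) > 1e-6:
        raise ValueError(f"{name}={value} s is not a multiple of TR={tr_s} s")


def build_block_design(
    lead_in_rest_s: float,
    n_cycles: int,
    on_s: float,
    off_s: float,
    tr_s: float,
    condition: str = "task",
) -> BlockDesign:
    """Lead-in rest followed by ``n_cycles`` repetitions of [on, off].

    The lead-in and the cycle length (on + off) must be multiples of the
    TR so that epoch onsets and the run length are volume-aligned; the
    on-duration itself may be unaligned (e.g. a 16 s hold at TR 3 s), in
    which case the half-open boxcar rule decides volume membership.
    """
    if tr_s <= 0:
        raise ValueError(f"tr_s must be positive, got {tr_s}")
    if n_cycles < 0:
        raise ValueError(f"n_cycles must be >= 0, got {n_cycles}")
    for name, val in (("lead_in_rest_s", lead_in_rest_s), ("on_s", on_s), ("off_s", off_s)):
        if val <= 0 and not (name == "lead_in_rest_s" and val == 0):
            raise ValueError(f"{name} must be positive, got {val}")
    _check_multiple(lead_in_rest_s, tr_s, "lead_in_rest_s")
    if n_cycles:
        _check_multiple(on_s + off_s, tr_s, "cycle duration (on_s + off_s)")
    total_s = lead_in_rest_s + n_cycles * (on_s + off_s)
    n_volumes = int(round(total_s / tr_s))
    epochs = tuple(
        (condition, lead_in_rest_s + k * (on_s + off_s), on_s) for k in range(n_cycles)
    )
    return BlockDesign(
        tr_s=tr_s, n_volumes=n_volumes, epochs=epochs, lead_in_rest_s=lead_in_rest_s
    )


def bh_design(tr_s: float = 3.0) -> BlockDesign:
    """The breath-hold run: 30 s rest, then 3 x [16 s hold + 44 s recovery]."""
    return build_block_design(30.0, 3, 16.0, 44.0, tr_s, condition="breath_hold")


def task_design(tr_s: float = 3.0, condition: str = "task") -> BlockDesign:
    """A task run: 30 s rest, then 3 x [30 s on + 30 s off]."""
    return build_block_design(30.0, 3, 30.0, 30.0, tr_s, condition=condition)


def boxcar(design: BlockDesign, condition: str | None = None) -> ReferenceWaveform:
    """Binary ON/OFF waveform: 1 where the volume onset falls in [onset, onset+dur)."""
    if condition is None:
        conds = design.conditions
        if len(conds) > 1:
            raise ValueError(f"ambiguous condition, design has {conds}")
        condition = conds[0] if conds else "task"
    if design.epochs and condition not in design.conditions:
        raise KeyError(f"condition {condition!r} not in design {design.conditions}")
    t = np.arange(design.n_volumes) * design.tr_s
    values = np.zeros(design.n_volumes)
    for cond, onset, dur in design.epochs:
        if cond == condition:
            values[(t >= onset - _EPS) & (t < onset + dur - _EPS)] = 1.0
    return ReferenceWaveform(values, design.tr_s, label=f"boxcar:{condition}")


def shift_waveform(
    w: ReferenceWaveform, delay_s: float, tr_s: float | None = None
) -> ReferenceWaveform:
    """Delay a waveform by ``delay_s`` (zero-padded, length preserved).

    Delays that are not volume-aligned are rounded to the nearest volume;
    the realized delay is recorded in the output metadata.
    """
    tr = w.tr_s if tr_s is None else tr_s
    if delay_s < 0:
        raise ValueError(f"delay_s must be non-negative, got {delay_s}")
    n_shift = int(round(delay_s / tr))
    if n_shift >= len(w):
        raise ValueError(
            f"delay {delay_s} s (= {n_shift} volumes) >= run length {len(w)} volumes"
        )
    out = np.zeros_like(w.values)
    if n_shift:
        out[n_shift:] = w.values[: len(w) - n_shift]
    else:
        out[:] = w.values
    meta = dict(w.meta)
    meta["delay_requested_s"] = float(delay_s)
    meta["delay_realized_s"] = n_shift * tr
    return ReferenceWaveform(out, tr, label=f"{w.label}+{n_shift * tr:g}s", meta=meta)


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Double-gamma canonical HRF sampled at the TR, unit peak.

    Response gamma shape 6, undershoot shape 16, undershoot ratio 1/6,
    unit time scale; peaks near 5 s.
    """
    if tr_s <= 0:
        raise ValueError(f"tr_s must be positive, got {tr_s}")
    t = np.arange(0.0, duration_s + tr_s / 2, tr_s)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    peak = h.max()
    return h / peak if peak > 0 else h


def convolve_regressor(
    box: ReferenceWaveform, kernel: np.ndarray, normalize: bool = True
) -> ReferenceWaveform:
    """Causal convolution, truncated to run length; unit peak by default."""
    full = np.convolve(box.values, np.asarray(kernel, dtype=float))
    out = full[: len(box)]
    meta = dict(box.meta)
    if normalize:
        peak = np.abs(out).max()
        if peak > 0:
            out = out / peak
        meta["unit_peak"] = True
    return ReferenceWaveform(out, box.tr_s, label=f"{box.label}*hrf", meta=meta)


def task_regressor(design: BlockDesign, condition: str | None = None) -> ReferenceWaveform:
    """Boxcar convolved with the canonical HRF, rescaled to unit peak."""
    return convolve_regressor(boxcar(design, condition), canonical_hrf(design.tr_s))


def bh_delayed_regressor(
    design: BlockDesign, delay_s: float = 8.0, condition: str | None = None
) -> ReferenceWaveform:
    """Breath-hold GLM regressor: boxcar delayed ~8 s, then HRF-convolved.

    An 8 s delay is not volume-aligned at TR 3 s; the shift rounds to the
    nearest volume (9 s) and the realized delay is kept in the metadata.
    """
    box = boxcar(design, condition)
    shifted = shift_waveform(box, delay_s) if delay_s > 0 else box
    reg = convolve_regressor(shifted, canonical_hrf(design.tr_s))
    meta = dict(reg.meta)
    meta.update(shifted.meta)
    return ReferenceWaveform(reg.values, reg.tr_s, label="bh_delayed", meta=meta)


# ---------------------------------------------------------------------------
# serialization

def design_to_yaml(design: BlockDesign, path: str | Path, **extra) -> Path:
    """Serialize a cyclic design to a YAML config.

    Only designs built by :func:`build_block_design` (single condition,
    uniform cycles) round-trip through this format.
    """
    path = Path(path)
    conds = design.conditions
    if len(conds) > 1:
        raise ValueError("config format supports a single condition")
    if design.epochs:
        cond = conds[0]
        durs = {d for c, d_on, d in design.epochs if c == cond for d in (d,)}
        if len(durs) != 1:
            raise ValueError("config format requires uniform epoch durations")
        on_s = durs.pop()
        onsets = design.onsets(cond)
        cycle = (
            float(onsets[1] - onsets[0]) if len(onsets) > 1
            else design.duration_s - design.lead_in_rest_s
        )
        off_s = cycle - on_s
        payload = dict(
            tr_s=design.tr_s,
            lead_in_rest_s=design.lead_in_rest_s,
            cycles=len(onsets),
            on_s=float(on_s),
            off_s=float(off_s),
            condition=cond,
        )
    else:
        payload = dict(
            tr_s=design.tr_s,
            lead_in_rest_s=design.lead_in_rest_s,
            cycles=0,
            on_s=design.tr_s,
            off_s=design.tr_s,
            condition="task",
        )
    payload.update(extra)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def design_from_yaml(path: str | Path) -> BlockDesign:
    cfg = yaml.safe_load(Path(path).read_text())
    return build_block_design(
        lead_in_rest_s=float(cfg["lead_in_rest_s"]),
        n_cycles=int(cfg["cycles"]),
        on_s=float(cfg["on_s"]),
        off_s=float(cfg["off_s"]),
        tr_s=float(cfg["tr_s"]),
        condition=str(cfg.get("condition", "task")),
    )


def waveform_to_tsv(w: ReferenceWaveform, path: str | Path) -> Path:
    """Two-column TSV export: time_s, value."""
    path = Path(path)
    t = np.arange(len(w)) * w.tr_s
    lines = ["time_s\tvalue"] + [f"{ti:g}\t{vi:.10g}" for ti, vi in zip(t, w.values)]
    path.write_text("\n".join(lines) + "\n")
    return path
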