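"""Core containers for 4D BOLD runs and NIfTI round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: unit tags carried by :class:`Bold4D`; operations check these to refuse
#: running twice (e.g. percent-change conversion of percent data).
UNITS_RAW = "raw"
UNITS_PERCENT = "percent"


@dataclass
class Bold4D:
    """A voxel grid x time array with acquisition metadata.

    ``data`` is indexed ``(x, y, z, t)``.  ``units`` is either ``"raw"``
    (scanner intensity) or ``"percent"`` (percent signal change); several
    downstream stages require one or the other and reject the wrong tag.
    """

    data: np.ndarray
    tr_s: float
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 3.0)
    units: str = UNITS_RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"Bold4D requires a 4D array, got ndim={self.data.ndim}")
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        if self.units not in (UNITS_RAW, UNITS_PERCENT):
            raise ValueError(f"unknown units tag {self.units!r}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def time_axis_s(self) -> np.ndarray:
        """Volume acquisition-onset times in seconds."""
        return np.arange(self.n_volumes) * self.tr_s

    def copy_with(self, **kwargs) -> "Bold4D":
        out = replace(self, **kwargs)
        if "meta" not in kwargs:
            out.meta = dict(self.meta)
        return out


def write_run(run: Bold4D, path: str | Path) -> Path:
    """Write a run as NIfTI-1 (float32), with TR in pixdim[4]."""
    path = Path(path)
    affine = np.diag(list(run.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(run.data.astype(np.float32), affine)
    img.header.set_zooms(tuple(run.voxel_size_mm) + (run.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def read_run(path: str | Path) -> Bold4D:
    """Read a 4D NIfTI run written by :func:`write_run`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()
    tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return Bold4D(
        data=np.asarray(data, dtype=float),
        tr_s=tr_s,
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
    )


def write_map(volume: np.ndarray, voxel_size_mm, path: str | Path) -> Path:
    """Write a 3D (or stacked 4D) parameter map as NIfTI-1."""
    path = Path(path)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    nib.save(img, str(path))
    return path


def read_map(path: str | Path) -> np.ndarray:
    img = nib.load(str(Path(path)))
    return np.asarray(np.asanyarray(img.dataobj), dtype=float)
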