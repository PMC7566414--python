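"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["motion_summaries"]


def motion_summaries() -> pd.DataFrame:
    """Per-axis mean displacement summaries (mm) for 21 scan sessions.

    Columns: subject, x_displacement_mm, y_displacement_mm,
    z_displacement_mm.  Used to exercise the motion QC exclusion rule on
    realistic clinical-scale motion magnitudes.
    """
    with resources.files("bhcalib.data").joinpath("motion_summaries.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
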