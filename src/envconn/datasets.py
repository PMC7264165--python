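"""Bundled coordinate tables and TSV readers.

Two reference point sets ship with the package: the MNI coordinates of
the within-frequency (n = 14) and cross-frequency (n = 47) seed-based
envelope-correlation local maxima of the verbal language network
(seed in the left inferior frontal gyrus).  They serve as fixtures for
the spatial-clustering stage, which can be exercised without running the
full source-level pipeline.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_within_frequency_maxima",
    "load_cross_frequency_maxima",
    "read_points_tsv",
]

_COLUMNS = ["band_seed", "band_target", "x", "y", "z"]


def read_points_tsv(path) -> pd.DataFrame:
    """Read a maxima coordinate TSV (band_seed, band_target, x, y, z).

    Malformed numeric fields raise a ValueError naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("x", "y", "z"):
        for row, val in enumerate(df[col]):
            try:
                float(val)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: line {row + 2}: bad {col} value {val!r}"
                ) from None
        df[col] = df[col].astype(float)
    return df


def _load_bundled(name: str) -> pd.DataFrame:
    with resources.as_file(
        resources.files("envconn.data").joinpath(name)
    ) as path:
        return read_points_tsv(path)


def load_within_frequency_maxima() -> pd.DataFrame:
    """14 within-frequency language-network connectivity maxima (MNI mm)."""
    return _load_bundled("within_frequency_maxima.tsv")


def load_cross_frequency_maxima() -> pd.DataFrame:
    """47 cross-frequency language-network connectivity maxima (MNI mm)."""
    return _load_bundled("cross_frequency_maxima.tsv")


def points_array(df: pd.DataFrame) -> np.ndarray:
    return df[["x", "y", "z"]].to_numpy(dtype=float)
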