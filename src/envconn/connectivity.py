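"""Seed-based within- and cross-frequency envelope-correlation maps.

One generic routine produces all band-pair maps.  When seed and target
share a band, each target's band-limited series is first orthogonalized
against the seed's (static zero-lag regression) to remove spatial
leakage; when bands differ no correction is applied — brick-wall-filtered
signals in disjoint bands are already exactly orthogonal, so the
correction would be a no-op.  Map values are Pearson correlations of the
1-Hz slow envelopes over the boundary-trimmed record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .bands import FrequencyBand, get_band
from .simulate import SourceSpace
from .spectral import analytic_signal, slow_envelope, trim_boundaries

__all__ = [
    "SeedSpec",
    "ConnectivityMap",
    "resolve_seed",
    "orthogonalize_static",
    "seed_envelope_map",
]


class DegenerateSeedError(ValueError):
    pass


class SeedResolutionError(ValueError):
    pass


@dataclass(frozen=True)
class SeedSpec:
    """A seed location in MNI mm; resolves to its nearest grid source."""

    mni_xyz: tuple[float, float, float]
    label: str = "seed"


def resolve_seed(source_space: SourceSpace, seed: "SeedSpec | tuple") -> int:
    """Nearest grid source by Euclidean distance (ties: lowest index)."""
    xyz = np.asarray(
        seed.mni_xyz if isinstance(seed, SeedSpec) else seed, dtype=float
    )
    coords = source_space.coords
    lo = coords.min(axis=0) - source_space.spacing_mm
    hi = coords.max(axis=0) + source_space.spacing_mm
    if (xyz < lo).any() or (xyz > hi).any():
        raise SeedResolutionError(
            f"seed {tuple(xyz)} lies outside the source grid bounding box "
            f"[{lo}, {hi}]"
        )
    return int(np.argmin(((coords - xyz) ** 2).sum(axis=1)))


def orthogonalize_static(
    target_series: np.ndarray, seed_series: np.ndarray
) -> np.ndarray:
    """Remove the zero-lag least-squares projection of the seed from targets.

    y_perp = y - (<y, x> / <x, x>) x, applied along the last axis; the
    corrected targets have exactly zero zero-lag correlation with the
    seed.  Targets may be a single series or a stack (targets x time).
    """
    x = np.asarray(seed_series, dtype=float)
    y = np.asarray(target_series, dtype=float)
    denom = float(x @ x)
    if denom <= 0.0 or x.var() == 0.0:
        raise DegenerateSeedError("seed series has zero variance")
    beta = (y @ x) / denom
    return y - np.multiply.outer(beta, x) if y.ndim > 1 else y - beta * x


def _pearson_rows(seed_env: np.ndarray, target_envs: np.ndarray) -> np.ndarray:
    s = seed_env - seed_env.mean()
    t = target_envs - target_envs.mean(axis=-1, keepdims=True)
    s_norm = np.sqrt((s**2).sum())
    t_norm = np.sqrt((t**2).sum(axis=-1))
    denom = s_norm * t_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (t @ s) / denom
    return np.where(denom > 0, r, np.nan)


@dataclass
class ConnectivityMap:
    """Per-source seed-based envelope correlations for one band pair.

    For within-frequency maps the value at the seed source is undefined
    (NaN): orthogonalization annihilates the seed's own series.
    """

    r: np.ndarray
    seed_index: int
    band_seed: FrequencyBand
    band_target: FrequencyBand
    subject_id: str | None = None

    @property
    def is_within(self) -> bool:
        return self.band_seed == self.band_target


def seed_envelope_map(
    source_band_series: Mapping[str, np.ndarray],
    fs_hz: float,
    seed_index: int,
    band_seed: "FrequencyBand | str",
    band_target: "FrequencyBand | str",
    envelope_cutoff_hz: float = 1.0,
    trim_s: float = 1.0,
    subject_id: str | None = None,
) -> ConnectivityMap:
    """Seed-based envelope-correlation map for one (seed, target) band pair.

    ``source_band_series`` maps band names to (sources x time) real
    band-limited source series.  Within-frequency pairs are leakage
    corrected by static orthogonalization before the Hilbert transform;
    cross-frequency pairs are not.  Envelopes are slow (sub-1-Hz)
    envelopes and the correlation is computed on boundary-trimmed
    segments.
    """
    band_seed = get_band(band_seed)
    band_target = get_band(band_target)
    for b in (band_seed, band_target):
        if b.name not in source_band_series:
            raise KeyError(f"band {b.name!r} missing from the analytic store")

    seed_series = np.asarray(source_band_series[band_seed.name][seed_index], float)
    targets = np.asarray(source_band_series[band_target.name], float)

    within = band_seed == band_target
    if within:
        targets = orthogonalize_static(targets, seed_series)

    seed_env = slow_envelope(analytic_signal(seed_series), fs_hz, envelope_cutoff_hz)
    target_env = slow_envelope(analytic_signal(targets), fs_hz, envelope_cutoff_hz)
    seed_env = trim_boundaries(seed_env, fs_hz, trim_s)
    target_env = trim_boundaries(target_env, fs_hz, trim_s)

    r = _pearson_rows(seed_env, target_env)
    if within:
        r[seed_index] = np.nan
    return ConnectivityMap(
        r=r,
        seed_index=seed_index,
        band_seed=band_seed,
        band_target=band_target,
        subject_id=subject_id,
    )
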