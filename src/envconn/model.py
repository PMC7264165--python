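"""Group seed-based envelope-connectivity analysis as a model/results pair.

``SeedConnectivityModel`` holds the data (multi-subject sensor
recordings, an empty-room noise segment, a forward model) and the
analysis conditions (band set, seed location, family-wise alpha).
``fit()`` runs band-specific minimum-norm inversion, computes every
(seed-band, target-band) envelope-correlation map with leakage
correction on the diagonal pairs, and performs background-corrected
group inference; it returns a ``SeedConnectivityResults`` carrying the
t-maps, the effective spatial degrees of freedom, the corrected
threshold, and methods for local-maxima extraction, template
classification, spatial clustering, and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import CANONICAL_BANDS, FrequencyBand, get_band
from .connectivity import SeedSpec, resolve_seed, seed_envelope_map
from .inference import GroupTMap, background_correct, make_group_tmap
from .inverse import (
    ForwardModel,
    apply_inverse,
    effective_dof,
    estimate_noise_cov,
    make_inverse_operator,
    reduce_orientation,
)
from .peaks import (
    LocalMaximum,
    classify_template,
    filter_cortical,
    find_local_maxima,
    hemisphere_count,
)
from .clustering import ClusterSolution, cluster_points
from .simulate import SimulatedDataset, SubjectRecording
from .spectral import brickwall_bandpass, trim_boundaries

__all__ = ["SeedConnectivityModel", "SeedConnectivityResults"]

#: default seed: ventral pars triangularis of the left inferior frontal
#: gyrus (Broca's area), MNI mm
DEFAULT_SEED = SeedSpec(mni_xyz=(-43.0, 20.0, 4.0), label="F3tv")


class SeedConnectivityModel:
    """Seed-based within- and cross-frequency envelope-correlation model.

    Parameters
    ----------
    recordings
        Per-subject sensor recordings (sensors x time), all with the same
        sampling rate and sensor count.
    empty_room
        Sensor-noise-only segment used for band-specific noise covariance.
    forward
        Leadfield over the analysis source grid.
    seed
        Seed location in MNI mm; resolved to the nearest grid source.
    bands
        Frequency bands to analyze; every ordered (seed, target) pair is
        mapped, diagonal pairs with static-orthogonalization leakage
        correction, off-diagonal pairs without.
    alpha
        Family-wise error level for the Bonferroni-corrected voxel test.
    """

    def __init__(
        self,
        recordings: Sequence[SubjectRecording],
        empty_room: SubjectRecording,
        forward: ForwardModel,
        seed: SeedSpec = DEFAULT_SEED,
        bands: Sequence["FrequencyBand | str"] = CANONICAL_BANDS,
        alpha: float = 0.05,
        envelope_cutoff_hz: float = 1.0,
        trim_s: float = 1.0,
    ) -> None:
        if len(recordings) < 2:
            raise ValueError("need at least 2 subjects")
        fs = {rec.fs_hz for rec in recordings} | {empty_room.fs_hz}
        if len(fs) != 1:
            raise ValueError("all recordings must share one sampling rate")
        self.recordings = list(recordings)
        self.empty_room = empty_room
        self.forward = forward
        self.seed = seed
        self.bands = tuple(get_band(b) for b in bands)
        self.alpha = alpha
        self.envelope_cutoff_hz = envelope_cutoff_hz
        self.trim_s = trim_s
        self.fs_hz = float(fs.pop())
        self.seed_index = resolve_seed(forward.source_space, seed)

    @classmethod
    def from_simulation(
        cls,
        dataset: SimulatedDataset,
        seed: SeedSpec | None = None,
        bands: Sequence["FrequencyBand | str"] | None = None,
        **kwargs,
    ) -> "SeedConnectivityModel":
        if seed is None:
            # default to the grid source nearest the grid center unless told
            space = dataset.source_space
            center = space.coords.mean(axis=0)
            seed = SeedSpec(mni_xyz=tuple(center), label="grid-center")
        return cls(
            recordings=dataset.recordings,
            empty_room=dataset.empty_room,
            forward=dataset.forward,
            seed=seed,
            bands=bands if bands is not None else dataset.config.bands,
            **kwargs,
        )

    # -- fitting ----------------------------------------------------------

    def _invert_subject(
        self, rec: SubjectRecording, noise_covs: Mapping[str, object], snr: float
    ) -> dict[str, np.ndarray]:
        """Band-filter, trim, and invert one subject's sensor data."""
        series: dict[str, np.ndarray] = {}
        for band in self.bands:
            xb = brickwall_bandpass(rec.data, self.fs_hz, band)
            xb = trim_boundaries(xb, self.fs_hz, self.trim_s)
            xb_c = xb - xb.mean(axis=1, keepdims=True)
            data_cov = xb_c @ xb_c.T / xb.shape[1]
            inv_op = make_inverse_operator(
                self.forward, noise_covs[band.name], snr=snr, data_cov=data_cov
            )
            src = apply_inverse(inv_op, xb)
            if self.forward.n_orient == 3:
                n_src = self.forward.source_space.n_sources
                src = np.stack(
                    [
                        reduce_orientation(src[3 * i : 3 * i + 3])
                        for i in range(n_src)
                    ]
                )
            series[band.name] = src
        return series

    def fit(self, snr: float = 3.0, rho: int | None = None) -> "SeedConnectivityResults":
        """Run inversion, mapping and group inference for all band pairs.

        ``snr`` sets the minimum-norm regularization (lambda^2 = 1/snr^2);
        ``rho`` overrides the effective spatial degrees of freedom, which
        default to the forward-model rank.
        """
        if rho is None:
            rho = effective_dof(self.forward)
        noise_covs = {
            band.name: estimate_noise_cov(self.empty_room, band, self.trim_s)
            for band in self.bands
        }
        pairs = [(bs, bt) for bs in self.bands for bt in self.bands]
        n_src = self.forward.source_space.n_sources
        deviations = np.zeros((len(pairs), len(self.recordings), n_src))

        for s, rec in enumerate(self.recordings):
            series = self._invert_subject(rec, noise_covs, snr)
            for p, (bs, bt) in enumerate(pairs):
                cmap = seed_envelope_map(
                    series,
                    self.fs_hz,
                    self.seed_index,
                    bs,
                    bt,
                    envelope_cutoff_hz=self.envelope_cutoff_hz,
                    trim_s=self.trim_s,
                    subject_id=rec.subject_id,
                )
                deviations[p, s] = background_correct(cmap.r)

        tmaps = {
            (bs.name, bt.name): make_group_tmap(deviations[p], self.alpha, rho, bs, bt)
            for p, (bs, bt) in enumerate(pairs)
        }
        return SeedConnectivityResults(model=self, tmaps=tmaps, rho=rho)


@dataclass
class SeedConnectivityResults:
    """Fitted group t-maps and the derived network description."""

    model: SeedConnectivityModel
    tmaps: dict[tuple[str, str], GroupTMap]
    rho: int

    @property
    def df(self) -> int:
        return next(iter(self.tmaps.values())).df

    @property
    def t_threshold(self) -> float:
        return next(iter(self.tmaps.values())).t_threshold

    @property
    def alpha(self) -> float:
        return self.model.alpha

    # -- maxima -----------------------------------------------------------

    def local_maxima(
        self,
        band_seed: "FrequencyBand | str | None" = None,
        band_target: "FrequencyBand | str | None" = None,
        cortical_only: bool = True,
        template_mask=None,
    ) -> list[LocalMaximum]:
        """Supra-threshold local maxima, optionally for one band pair only."""
        space = self.model.forward.source_space
        out: list[LocalMaximum] = []
        for (bs_name, bt_name), tmap in self.tmaps.items():
            if band_seed is not None and get_band(band_seed).name != bs_name:
                continue
            if band_target is not None and get_band(band_target).name != bt_name:
                continue
            maxima = find_local_maxima(
                tmap.t,
                space,
                tmap.t_threshold,
                band_seed=tmap.band_seed,
                band_target=tmap.band_target,
            )
            if cortical_only:
                maxima = filter_cortical(maxima, space)
            if template_mask is not None:
                maxima = classify_template(maxima, template_mask)
            out.extend(maxima)
        return sorted(out, key=lambda m: -m.t_value)

    def maxima_table(self, template_mask=None, cortical_only: bool = True) -> pd.DataFrame:
        """All supra-threshold maxima as a tidy table (one row per maximum)."""
        rows = []
        for m in self.local_maxima(
            cortical_only=cortical_only, template_mask=template_mask
        ):
            rows.append(
                {
                    "band_seed": m.band_seed.name,
                    "band_target": m.band_target.name,
                    "x": m.mni_xyz[0],
                    "y": m.mni_xyz[1],
                    "z": m.mni_xyz[2],
                    "t": m.t_value,
                    "parcel": m.parcel_id,
                    "dist_mm": m.dist_to_template_mm,
                    "in_template": m.in_template,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "band_seed",
                "band_target",
                "x",
                "y",
                "z",
                "t",
                "parcel",
                "dist_mm",
                "in_template",
            ],
        )

    # -- clustering -------------------------------------------------------

    def _cluster(self, diagonal: bool, n_restarts: int, rng) -> ClusterSolution:
        maxima = [
            m
            for m in self.local_maxima()
            if (m.band_seed == m.band_target) == diagonal
        ]
        if len(maxima) < 3:
            raise ValueError(
                f"need at least 3 {'within' if diagonal else 'cross'}-frequency "
                f"maxima to cluster, found {len(maxima)}"
            )
        pts = np.array([m.mni_xyz for m in maxima])
        pairs = [(m.band_seed.name, m.band_target.name) for m in maxima]
        return cluster_points(pts, n_restarts=n_restarts, rng=rng, band_pairs=pairs)

    def cluster_within(self, n_restarts: int = 200, rng=0) -> ClusterSolution:
        """Spatial clustering of the within-frequency (diagonal-pair) maxima."""
        return self._cluster(True, n_restarts, rng)

    def cluster_cross(self, n_restarts: int = 200, rng=0) -> ClusterSolution:
        """Spatial clustering of the cross-frequency (off-diagonal) maxima."""
        return self._cluster(False, n_restarts, rng)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Seed-based envelope connectivity — group inference",
            "=" * 52,
            f"subjects: {len(self.model.recordings)}   df: {self.df}",
            f"sources: {self.model.forward.source_space.n_sources}   "
            f"sensors: {self.model.forward.leadfield.shape[0]}",
            f"seed: {self.model.seed.label} at {self.model.seed.mni_xyz} "
            f"(grid source {self.model.seed_index})",
            f"alpha (FWE): {self.alpha}   effective spatial DOF rho: {self.rho}",
            f"corrected voxel level alpha/rho: {self.alpha / self.rho:.3g}",
            f"one-tailed critical t: {self.t_threshold:.3f}",
            "",
            f"{'seed band':>12} {'target band':>12} {'supra voxels':>13} "
            f"{'max t':>8} {'flags':>6}",
        ]
        for (bs, bt), tmap in self.tmaps.items():
            with np.errstate(invalid="ignore"):
                n_supra = int(np.nansum(tmap.t >= tmap.t_threshold))
            finite = tmap.t[np.isfinite(tmap.t)]
            tmax = float(finite.max()) if finite.size else float("nan")
            lines.append(
                f"{bs:>12} {bt:>12} {n_supra:>13d} {tmax:>8.2f} "
                f"{int(tmap.quality_flags.sum()):>6d}"
            )
        return "\n".join(lines)
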