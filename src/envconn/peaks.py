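"""Local-maxima extraction from thresholded t-maps, cortical-parcel
filtering, and template-mask distance classification.

Local maxima (rather than whole supra-threshold clusters) are extracted
because a focal peak indicates genuine coupling rather than field
spread.  Maxima in parcel 0 (deep / non-cortical) are discarded, and the
remaining peaks are classified as in- or out-of-template by their
Euclidean distance to the nearest in-mask voxel center (strictly less
than 10 mm counts as inside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .bands import FrequencyBand
from .simulate import SourceSpace

__all__ = [
    "LocalMaximum",
    "HemisphereTally",
    "find_local_maxima",
    "filter_cortical",
    "template_distance",
    "classify_template",
    "hemisphere_count",
]

#: maxima closer than this (mm) to the template mask count as inside it
TEMPLATE_DISTANCE_MM = 10.0


@dataclass
class LocalMaximum:
    """A supra-threshold local maximum of a group t-map."""

    mni_xyz: tuple[float, float, float]
    t_value: float
    source_index: int
    parcel_id: int
    band_seed: FrequencyBand | None = None
    band_target: FrequencyBand | None = None
    dist_to_template_mm: float | None = None
    in_template: bool | None = None
    tie: bool = False  # centroid of an exact-tie plateau


def _neighbor_lists(source_space: SourceSpace) -> list[np.ndarray]:
    """26-connected neighbors: sources within sqrt(3) grid spacings."""
    tree = cKDTree(source_space.coords)
    radius = np.sqrt(3.0) * source_space.spacing_mm * 1.0001
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    nbrs: list[list[int]] = [[] for _ in range(source_space.n_sources)]
    for i, j in pairs:
        nbrs[i].append(j)
        nbrs[j].append(i)
    return [np.asarray(v, dtype=int) for v in nbrs]


def find_local_maxima(
    t_map: np.ndarray,
    source_space: SourceSpace,
    t_threshold: float,
    band_seed: FrequencyBand | None = None,
    band_target: FrequencyBand | None = None,
) -> list[LocalMaximum]:
    """All sources with t >= threshold strictly exceeding every neighbor.

    NaN sources (e.g. the masked seed) never qualify and compare as
    minus infinity for their neighbors.  An exact-tie supra-threshold
    plateau whose value exceeds all exterior neighbors is reported once,
    at its centroid, with ``tie=True``.  Results are sorted by
    descending t.
    """
    t = np.asarray(t_map, dtype=float)
    if t.shape != (source_space.n_sources,):
        raise ValueError("t_map length must match the source space")
    vals = np.where(np.isnan(t), -np.inf, t)
    nbrs = _neighbor_lists(source_space)
    with np.errstate(invalid="ignore"):
        supra = vals >= t_threshold

    maxima: list[LocalMaximum] = []
    in_plateau = np.zeros(len(vals), dtype=bool)
    for i in np.nonzero(supra)[0]:
        others = vals[nbrs[i]] if nbrs[i].size else np.array([])
        if others.size and others.max() > vals[i]:
            continue
        ties = nbrs[i][vals[nbrs[i]] == vals[i]] if nbrs[i].size else np.array([], int)
        if ties.size == 0:
            maxima.append(
                LocalMaximum(
                    mni_xyz=tuple(map(float, source_space.coords[i])),
                    t_value=float(t[i]),
                    source_index=int(i),
                    parcel_id=int(source_space.parcel_id[i]),
                    band_seed=band_seed,
                    band_target=band_target,
                )
            )
            continue
        if in_plateau[i]:
            continue
        # flood-fill the equal-valued plateau and check its exterior rim
        component = {int(i)}
        stack = [int(i)]
        while stack:
            j = stack.pop()
            for k in nbrs[j]:
                if vals[k] == vals[i] and int(k) not in component:
                    component.add(int(k))
                    stack.append(int(k))
        rim = {
            int(k)
            for j in component
            for k in nbrs[j]
            if int(k) not in component
        }
        if any(vals[k] > vals[i] for k in rim):
            continue
        members = np.array(sorted(component))
        in_plateau[members] = True
        centroid = source_space.coords[members].mean(axis=0)
        rep = members[
            np.argmin(((source_space.coords[members] - centroid) ** 2).sum(1))
        ]
        maxima.append(
            LocalMaximum(
                mni_xyz=tuple(map(float, centroid)),
                t_value=float(t[members[0]]),
                source_index=int(rep),
                parcel_id=int(source_space.parcel_id[rep]),
                band_seed=band_seed,
                band_target=band_target,
                tie=True,
            )
        )
    maxima.sort(key=lambda m: -m.t_value)
    return maxima


def filter_cortical(
    maxima: list[LocalMaximum], source_space: SourceSpace | None = None
) -> list[LocalMaximum]:
    """Discard maxima in parcel 0 (artifactual deep activity)."""
    return [m for m in maxima if m.parcel_id != 0]


def _mask_voxel_centers(mask) -> tuple[np.ndarray, np.ndarray]:
    """(in-mask voxel centers in mm, affine) from a NIfTI-like mask image."""
    data = np.asarray(mask.dataobj) if hasattr(mask, "dataobj") else np.asarray(
        mask.get_fdata()
    )
    affine = np.asarray(mask.affine)
    ijk = np.argwhere(data > 0)
    if ijk.size == 0:
        raise ValueError("template mask contains no in-mask voxel")
    centers = ijk @ affine[:3, :3].T + affine[:3, 3]
    return centers, affine


def template_distance(mni_xyz, mask) -> float:
    """Euclidean distance (mm) to the closest in-mask voxel center.

    A coordinate whose nearest-voxel rounding lands on an in-mask voxel
    has distance exactly 0.
    """
    xyz = np.asarray(mni_xyz, dtype=float)
    centers, affine = _mask_voxel_centers(mask)
    # nearest-voxel rounding convention: in-mask voxel -> distance 0
    inv = np.linalg.inv(affine)
    voxel = np.rint(xyz @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    data = np.asarray(mask.dataobj) if hasattr(mask, "dataobj") else np.asarray(
        mask.get_fdata()
    )
    if (voxel >= 0).all() and (voxel < data.shape).all() and data[tuple(voxel)] > 0:
        return 0.0
    return float(cKDTree(centers).query(xyz)[0])


def classify_template(
    maxima: list[LocalMaximum],
    mask,
    threshold_mm: float = TEMPLATE_DISTANCE_MM,
) -> list[LocalMaximum]:
    """Annotate each maximum with its mask distance and in-template flag.

    The inclusion rule is strict: ``in_template`` iff distance <
    ``threshold_mm``.
    """
    for m in maxima:
        d = template_distance(m.mni_xyz, mask)
        m.dist_to_template_mm = d
        m.in_template = d < threshold_mm
    return maxima


@dataclass(frozen=True)
class HemisphereTally:
    left: int
    right: int
    midline: int  # x == 0, counted as neither and flagged

    @property
    def flagged(self) -> bool:
        return self.midline > 0


def hemisphere_count(maxima) -> HemisphereTally:
    """Count maxima by hemisphere from the sign of MNI x (negative = left)."""
    xs = np.array(
        [m.mni_xyz[0] if isinstance(m, LocalMaximum) else m[0] for m in maxima],
        dtype=float,
    )
    return HemisphereTally(
        left=int((xs < 0).sum()),
        right=int((xs > 0).sum()),
        midline=int((xs == 0).sum()),
    )
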