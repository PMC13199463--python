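"""Binary-mask colocalization and morphology metrics.

Colocalization here is mask overlap, not intensity correlation: each marker
channel is thresholded to a binary mask and the percentage of double- or
triple-positive voxels is computed per image plane. The percentage needs a
denominator; three conventions are supported and every result records which
one was used:

* ``reference_marker`` (default): voxels of the first mask,
* ``union``: voxels in either mask (symmetric),
* ``total_pixels``: all voxels of the plane.

An empty denominator yields ``nan`` (flagged missing) rather than 0 or an
error, so blank planes do not masquerade as zero colocalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

__all__ = [
    "ColocResult",
    "FragmentationResult",
    "pairwise_coloc",
    "triple_coloc",
    "coloc_by_plane",
    "marker_area",
    "ratio_metric",
    "neurite_fragmentation",
]

DENOMINATOR_MODES = ("reference_marker", "union", "total_pixels")


@dataclass
class ColocResult:
    field_id: str
    markers: tuple[str, ...]
    denominator_mode: str
    per_plane_percent: list[float]
    percent: float  # per-plane values averaged to the field value
    marker_areas: dict[str, int]


@dataclass
class FragmentationResult:
    field_id: str
    th_area_um2: float
    n_fragments: int
    fragmentation_index: float  # fragments per µm² of TH-positive area


def _check_masks(*masks: np.ndarray) -> list[np.ndarray]:
    out = [np.asarray(m, dtype=bool) for m in masks]
    shapes = {m.shape for m in out}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {sorted(shapes)}")
    return out


def _percent(inter: np.ndarray, masks: list[np.ndarray], mode: str) -> float:
    if mode == "reference_marker":
        denom = masks[0].sum()
    elif mode == "union":
        denom = np.logical_or.reduce(masks).sum()
    elif mode == "total_pixels":
        denom = masks[0].size
    else:
        raise ValueError(f"unknown denominator mode {mode!r}")
    if denom == 0:
        return float("nan")
    return 100.0 * float(inter.sum()) / float(denom)


def pairwise_coloc(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    denominator_mode: str = "reference_marker",
) -> float:
    """Percent of double-positive voxels: ``100 × |A∩B| / denominator``."""
    a, b = _check_masks(mask_a, mask_b)
    return _percent(a & b, [a, b], denominator_mode)


def triple_coloc(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    mask_c: np.ndarray,
    denominator_mode: str = "reference_marker",
) -> float:
    """Percent of triple-positive voxels: ``100 × |A∩B∩C| / denominator``."""
    a, b, c = _check_masks(mask_a, mask_b, mask_c)
    return _percent(a & b & c, [a, b, c], denominator_mode)


def coloc_by_plane(
    masks: dict[str, np.ndarray],
    markers: tuple[str, ...],
    denominator_mode: str = "reference_marker",
    field_id: str = "",
) -> ColocResult:
    """Per-plane double/triple percentages, averaged to a per-field value.

    ``masks`` maps marker name to a ``(plane, row, col)`` boolean mask;
    ``markers`` selects 2 (pairwise) or 3 (triple) of them, the first being
    the reference. Planes with an empty denominator are skipped in the field
    average; if all planes are empty the field value is ``nan``.
    """
    stack = _check_masks(*(masks[m] for m in markers))
    fn = pairwise_coloc if len(markers) == 2 else triple_coloc
    per_plane = [
        fn(*(m[p] for m in stack), denominator_mode=denominator_mode)
        for p in range(stack[0].shape[0])
    ]
    finite = [v for v in per_plane if np.isfinite(v)]
    return ColocResult(
        field_id=field_id,
        markers=tuple(markers),
        denominator_mode=denominator_mode,
        per_plane_percent=per_plane,
        percent=float(np.mean(finite)) if finite else float("nan"),
        marker_areas={m: int(masks[m].sum()) for m in markers},
    )


def marker_area(
    mask: np.ndarray,
    voxel_area_um2: float,
    normalizer_mask: np.ndarray | None = None,
) -> float:
    """Mask area in µm², or the dimensionless fraction of a normalizer mask.

    With a ``normalizer_mask`` (e.g. a nuclei or cytoplasm mask) the result
    is ``area(mask) / area(normalizer)``; an empty normalizer flags the
    value missing (``nan``).
    """
    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum()) * voxel_area_um2
    if normalizer_mask is None:
        return area
    norm = float(np.asarray(normalizer_mask, dtype=bool).sum()) * voxel_area_um2
    if norm == 0:
        return float("nan")
    return area / norm


def ratio_metric(numerator: float, denominator: float) -> float:
    """Plain quotient; zero denominator flags the value missing (``nan``)."""
    if denominator == 0:
        return float("nan")
    return numerator / denominator


def neurite_fragmentation(
    th_mask: np.ndarray,
    voxel_area_um2: float,
    min_skeleton_voxels: int = 5,
    field_id: str = "",
) -> FragmentationResult:
    """Skeleton-fragment count of the TH-positive mask.

    The mask is skeletonized per plane; 8-connected skeleton components with
    at least ``min_skeleton_voxels`` voxels count as fragments, and the
    fragmentation index is fragments per µm² of TH area. This is an
    interpretation of "neurite fragmentation" as a concrete, reproducible
    readout: more gaps in the same arbor mean more (shorter) fragments.
    """
    th_mask = np.asarray(th_mask, dtype=bool)
    if th_mask.ndim == 2:
        th_mask = th_mask[None]
    area = float(th_mask.sum()) * voxel_area_um2
    n_fragments = 0
    struct = np.ones((3, 3), dtype=bool)
    for plane in th_mask:
        if not plane.any():
            continue
        skel = skeletonize(plane)
        labels, n = ndimage.label(skel, structure=struct)
        if n:
            sizes = ndimage.sum_labels(skel, labels, np.arange(1, n + 1))
            n_fragments += int((sizes >= min_skeleton_voxels).sum())
    index = n_fragments / area if n_fragments else 0.0
    return FragmentationResult(
        field_id=field_id,
        th_area_um2=area,
        n_fragments=n_fragments,
        fragmentation_index=index,
    )
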