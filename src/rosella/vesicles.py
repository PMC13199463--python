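"""Autolysosome detection, size classification and per-field metrics.

The tandem reporter (pHluorin + DsRed fused to LC3) distinguishes
autolysosomes from autophagosomes by lumen pH: the acidic autolysosome
quenches pHluorin, so autolysosomes appear as red-only vesicles
(DsRed+ / pHluorin−) while autophagosomes are dual-positive. This module
segments the red channel, discards dual-positive components, classifies the
remaining vesicles into small / medium / large voxel-count classes with
model-specific thresholds, and summarises each imaged field as densities per
cell area plus the single largest autolysosome area.

Size classes are half-open voxel-count intervals: ``small = [1, small_max)``,
``medium = [small_max, medium_max)``, ``large = [medium_max, inf)`` — i.e. a
count exactly at a boundary belongs to the larger class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu

from .io import ImageStack

__all__ = [
    "SizeClassScheme",
    "NEURONAL_SCHEME",
    "ORGANOID_SCHEME",
    "get_scheme",
    "VesicleRecord",
    "AutophagyMetrics",
    "threshold_channel",
    "detect_autolysosomes",
    "classify_vesicles",
    "classify_count",
    "compute_cell_area",
    "compute_metrics",
    "SIZE_CLASSES",
]

SIZE_CLASSES = ("small", "medium", "large")

#: default in-plane element area, µm² (chosen so 25 voxels ≈ 0.29 µm²)
DEFAULT_VOXEL_AREA_UM2 = 0.0116

#: in-plane 8-connectivity, planes kept independent
_STRUCTURE = np.zeros((3, 3, 3), dtype=bool)
_STRUCTURE[1] = True  # 8-connected within a plane, no cross-plane links


@dataclass(frozen=True)
class SizeClassScheme:
    """Model-specific small/medium/large voxel-count thresholds.

    ``small_max_voxels`` and ``medium_max_voxels`` are the half-open class
    boundaries; 2D neuronal cultures use (8, 25), midbrain organoids — whose
    vesicles image larger — use (25, 80).
    """

    name: str
    small_max_voxels: int
    medium_max_voxels: int
    voxel_area_um2: float = DEFAULT_VOXEL_AREA_UM2

    def __post_init__(self) -> None:
        if not 0 < self.small_max_voxels < self.medium_max_voxels:
            raise ValueError("need 0 < small_max_voxels < medium_max_voxels")
        if not self.voxel_area_um2 > 0:
            raise ValueError("voxel_area_um2 must be > 0")

    def classify(self, voxel_count: int) -> str:
        return classify_count(voxel_count, self)


NEURONAL_SCHEME = SizeClassScheme("neuronal", 8, 25)
ORGANOID_SCHEME = SizeClassScheme("organoid", 25, 80)

_SCHEMES = {"neuronal": NEURONAL_SCHEME, "organoid": ORGANOID_SCHEME}


def get_scheme(name: str, voxel_area_um2: float | None = None) -> SizeClassScheme:
    """Look up a named scheme, optionally overriding the reporting voxel area."""
    try:
        scheme = _SCHEMES[name]
    except KeyError:
        raise ValueError(f"unknown scheme {name!r}; choose from {sorted(_SCHEMES)}") from None
    if voxel_area_um2 is not None:
        scheme = replace(scheme, voxel_area_um2=voxel_area_um2)
    return scheme


@dataclass
class VesicleRecord:
    """One detected autolysosome."""

    vesicle_id: int
    field_id: str
    voxel_count: int
    area_um2: float
    centroid: tuple[float, float, float]  # (plane, row, col)
    channel_means: dict[str, float]
    size_class: str | None = None


@dataclass
class AutophagyMetrics:
    """Per-field summary of the autolysosome population."""

    field_id: str
    cell_area_um2: float
    total_autolysosome_area_per_cell_area: float
    autolysosome_count_per_cell_area: float  # 1/µm²
    count_per_cell_area_by_class: dict[str, float]
    max_autolysosome_area_um2: float
    n_vesicles: int


def classify_count(voxel_count: int, scheme: SizeClassScheme) -> str:
    """Three-branch size rule on in-plane voxel counts."""
    if voxel_count <= 0:
        raise ValueError(f"voxel_count must be positive, got {voxel_count}")
    if voxel_count < scheme.small_max_voxels:
        return "small"
    if voxel_count < scheme.medium_max_voxels:
        return "medium"
    return "large"


def threshold_channel(
    stack: ImageStack,
    channel: str,
    method: str = "otsu",
    threshold: float | None = None,
    quantile: float | None = None,
    robust_k: float = 3.0,
    smooth_sigma: float = 0.0,
) -> np.ndarray:
    """Binarise one channel into a marker mask.

    Parameters
    ----------
    method:
        ``'otsu'`` (default), ``'fixed'`` (requires ``threshold``),
        ``'quantile'`` (requires ``quantile`` in (0, 1)) or ``'robust'``
        (``median + robust_k × MAD/0.6745``: with a background-dominated
        channel the median estimates the background level and the scaled MAD
        the noise SD, so the threshold sits ``robust_k`` noise SDs above
        background; on noiseless data MAD is 0 and the mask is exact).
    smooth_sigma:
        Optional in-plane Gaussian pre-smoothing (pixels). 0 disables it.
        Smoothing suppresses isolated noise pixels but erodes objects only a
        few voxels across; reserve it for channels with large structures.

    A constant-intensity channel under Otsu yields an empty mask with a
    warning rather than an error, so a blank field does not abort a batch.
    """
    img = stack.channel(channel).astype(float)
    if smooth_sigma > 0:
        # per-plane smoothing; preserve_range keeps the documented levels
        img = np.stack(
            [gaussian(p, sigma=smooth_sigma, preserve_range=True) for p in img]
        )
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires threshold=")
        thr = float(threshold)
    elif method == "quantile":
        if quantile is None:
            raise ValueError("method='quantile' requires quantile=")
        thr = float(np.quantile(img, quantile))
    elif method == "robust":
        med = float(np.median(img))
        mad_sigma = float(np.median(np.abs(img - med))) / 0.6745
        thr = med + robust_k * mad_sigma
    elif method == "otsu":
        if np.ptp(img) == 0:
            warnings.warn(
                f"channel {channel!r} is constant; Otsu undefined, returning empty mask",
                stacklevel=2,
            )
            return np.zeros(img.shape, dtype=bool)
        thr = float(threshold_otsu(img))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return img > thr


def _label_per_plane(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected components within each plane; planes never linked."""
    return ndimage.label(mask, structure=_STRUCTURE)


def detect_autolysosomes(
    red_mask: np.ndarray,
    green_mask: np.ndarray,
    stack: ImageStack,
    min_voxels: int = 2,
    dual_positive_cutoff: float = 0.5,
    field_id: str = "",
) -> list[VesicleRecord]:
    """Find red-only vesicles: red components not substantially green.

    A red connected component (8-connectivity, per plane) is retained as an
    autolysosome iff the fraction of its voxels also inside ``green_mask`` is
    below ``dual_positive_cutoff`` and it has at least ``min_voxels`` voxels.
    The sub-50% default tolerates 1–2 voxel mask misregistration while still
    rejecting genuinely dual-positive autophagosomes.
    """
    red_mask = np.asarray(red_mask, dtype=bool)
    green_mask = np.asarray(green_mask, dtype=bool)
    if red_mask.shape != green_mask.shape:
        raise ValueError(
            f"mask shapes differ: {red_mask.shape} vs {green_mask.shape}"
        )
    if red_mask.shape != stack.data.shape[1:]:
        raise ValueError("masks must match the stack's (plane, row, col) shape")

    labels, n = _label_per_plane(red_mask)
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    green_overlap = ndimage.sum_labels(green_mask.astype(float), labels, idx)
    centroids = ndimage.center_of_mass(red_mask, labels, idx)

    records: list[VesicleRecord] = []
    vid = 0
    for i, lab in enumerate(idx):
        count = int(counts[i])
        if count < min_voxels:
            continue
        if green_overlap[i] / count >= dual_positive_cutoff:
            continue
        means = {
            name: float(ndimage.mean(stack.channel(name), labels, lab))
            for name in stack.channel_names
        }
        records.append(
            VesicleRecord(
                vesicle_id=vid,
                field_id=field_id,
                voxel_count=count,
                area_um2=count * stack.voxel_area_um2,
                centroid=tuple(float(c) for c in centroids[i]),
                channel_means=means,
            )
        )
        vid += 1
    return records


def classify_vesicles(
    records: list[VesicleRecord], scheme: SizeClassScheme
) -> list[VesicleRecord]:
    """Assign each record its size class (in place; returns the list)."""
    for rec in records:
        rec.size_class = classify_count(rec.voxel_count, scheme)
    return records


def compute_cell_area(
    stack: ImageStack,
    cytoplasm_channel: str,
    method: str = "otsu",
    threshold: float | None = None,
    mask: np.ndarray | None = None,
    smooth_sigma: float = 0.0,
) -> float:
    """Cell (cytoplasm) area in µm², the per-field normaliser.

    By default thresholds the diffuse reporter channel; an externally
    segmented ``mask`` may be supplied instead. Area sums mask voxels over
    all planes times the in-plane element area. An empty mask is a hard
    error: downstream densities would divide by zero, and a field with no
    detectable cells is an acquisition failure worth surfacing.
    """
    if mask is None:
        mask = threshold_channel(
            stack, cytoplasm_channel, method=method, threshold=threshold,
            smooth_sigma=smooth_sigma,
        )
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty cell mask: no cytoplasm detected in field")
    return n * stack.voxel_area_um2


def compute_metrics(
    records: list[VesicleRecord],
    cell_area_um2: float,
    scheme: SizeClassScheme,
    field_id: str = "",
) -> AutophagyMetrics:
    """Summarise one field: totals, per-class densities, max area."""
    if not cell_area_um2 > 0:
        raise ValueError("cell_area_um2 must be > 0")
    classify_vesicles(records, scheme)
    areas = np.array([r.area_um2 for r in records], dtype=float)
    by_class = {
        cls: sum(1 for r in records if r.size_class == cls) / cell_area_um2
        for cls in SIZE_CLASSES
    }
    return AutophagyMetrics(
        field_id=field_id or (records[0].field_id if records else ""),
        cell_area_um2=cell_area_um2,
        total_autolysosome_area_per_cell_area=float(areas.sum()) / cell_area_um2,
        autolysosome_count_per_cell_area=len(records) / cell_area_um2,
        count_per_cell_area_by_class=by_class,
        max_autolysosome_area_um2=float(areas.max()) if len(areas) else 0.0,
        n_vesicles=len(records),
    )


def records_to_frame(records: list[VesicleRecord]) -> pd.DataFrame:
    """Per-vesicle records as a long-format table (one row per vesicle)."""
    rows = []
    for r in records:
        rows.append(
            {
                "vesicle_id": r.vesicle_id,
                "field_id": r.field_id,
                "voxel_count": r.voxel_count,
                "area_um2": r.area_um2,
                "size_class": r.size_class,
                "plane": r.centroid[0],
                "row": r.centroid[1],
                "col": r.centroid[2],
                **{f"mean_{k}": v for k, v in r.channel_means.items()},
            }
        )
    return pd.DataFrame(rows)
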