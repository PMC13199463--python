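"""Synthetic data with exact ground truth for every pipeline stage.

Real inputs to this pipeline are live-cell reporter fields, immunostained
multi-marker stacks, 10-minute multi-electrode voltage recordings, and
per-field measurement tables. Each generator here emulates one of those,
returning both the rendered data and a ground-truth object so that every
downstream stage can be tested for exact recovery on noiseless renders and
for graceful degradation under noise.

Design notes:

* Vesicles are rendered as filled digital discs/ellipses grown pixel-by-pixel
  to an exact target voxel count, because boundary-exact size control is what
  the size-class tests need; real vesicle morphology is irrelevant for the
  counting statistics under test.
* Generators are bit-reproducible: all randomness flows from a single
  ``numpy.random.default_rng(seed)`` per call.
* Mosaic cultures (a fraction of cells carrying the reporter, default 55%)
  are emulated by rendering non-reporter cells with background-only reporter
  channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ElectrodeRecording, ImageStack
from .vesicles import DEFAULT_VOXEL_AREA_UM2, SizeClassScheme, get_scheme

__all__ = [
    "FieldSpec",
    "NoiseModel",
    "CohortSpec",
    "PlacementError",
    "VesicleGroundTruth",
    "ColocGroundTruth",
    "MeaGroundTruth",
    "CohortGroundTruth",
    "NeuriteGroundTruth",
    "generate_rosella_field",
    "generate_coloc_field",
    "generate_mea_recording",
    "generate_cohort",
    "generate_neurite_field",
]

REPORTER_STATES = ("red_only", "dual_positive")


class PlacementError(ValueError):
    """Raised when vesicles of some class cannot be placed without overlap."""


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition-noise model.

    ``gaussian``: additive, ``sigma_rel`` expressed relative to the
    vesicle-background contrast of each channel (``sigma_rel=0.2`` means the
    contrast is 5 noise SDs). ``poisson``: shot noise with ``gain`` expected
    counts per intensity unit. ``none``: noiseless render.
    """

    kind: str = "gaussian"
    sigma_rel: float = 0.2
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma_rel < 0 or self.gain <= 0:
            raise ValueError("sigma_rel must be >= 0 and gain > 0")


NO_NOISE = NoiseModel(kind="none")

#: per-channel (background, cytoplasm, vesicle) mean intensities.
#: DsRed carries no diffuse cytoplasmic term by default, so its histogram is
#: cleanly bimodal and Otsu recovers the vesicle mask exactly on noiseless
#: renders; pHluorin is diffuse (the reporter decorates the cytoskeleton).
#: The background emulates a camera offset and sits several noise SDs above
#: zero at the default noise level, so additive noise is not clipped.
DEFAULT_INTENSITY_LEVELS = {
    "pHluorin": (200.0, 280.0, 520.0),
    "DsRed": (200.0, 200.0, 520.0),
}


def _default_vesicle_counts() -> dict[tuple[str, str], int]:
    return {
        ("red_only", "small"): 8,
        ("red_only", "medium"): 8,
        ("red_only", "large"): 4,
        ("dual_positive", "small"): 3,
        ("dual_positive", "medium"): 3,
        ("dual_positive", "large"): 1,
    }


@dataclass
class FieldSpec:
    """Geometry, content and noise of one synthetic reporter field."""

    field_shape: tuple[int, int, int] = (3, 192, 192)  # planes, rows, cols
    voxel_area_um2: float = DEFAULT_VOXEL_AREA_UM2
    n_cells: int = 5
    reporter_fraction: float = 0.55
    vesicles_per_class: dict[tuple[str, str], int] = field(
        default_factory=_default_vesicle_counts
    )
    intensity_levels: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_LEVELS)
    )
    noise: NoiseModel = NO_NOISE
    scheme: str = "neuronal"
    large_max_voxels: int | None = None  # upper draw bound for 'large'; default 2x medium_max
    seed: int = 0

    def __post_init__(self) -> None:
        planes, rows, cols = self.field_shape
        if min(planes, rows, cols) <= 0:
            raise ValueError("field_shape entries must be positive")
        if not self.voxel_area_um2 > 0:
            raise ValueError("voxel_area_um2 must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0 <= self.reporter_fraction <= 1:
            raise ValueError("reporter_fraction must be in [0, 1]")
        for (state, cls), n in self.vesicles_per_class.items():
            if state not in REPORTER_STATES:
                raise ValueError(f"unknown reporter state {state!r}")
            if cls not in ("small", "medium", "large"):
                raise ValueError(f"unknown size class {cls!r}")
            if n < 0:
                raise ValueError("vesicle counts must be >= 0")
        for ch, levels in self.intensity_levels.items():
            if any(v < 0 for v in levels):
                raise ValueError(f"negative intensity level for channel {ch!r}")


@dataclass
class VesicleGroundTruth:
    """Truth for one rendered reporter field."""

    vesicles: pd.DataFrame  # vesicle_id, plane, row, col, voxel_count, reporter_state, size_class
    cell_mask: np.ndarray  # (plane, row, col) reporter-positive cytoplasm
    red_mask: np.ndarray  # all vesicle footprints (DsRed-bright)
    green_mask: np.ndarray  # dual-positive footprints (pHluorin-bright)
    suggested_thresholds: dict[str, float]  # documented ideal thresholds

    def class_counts(self, state: str | None = "red_only") -> dict[str, int]:
        tab = self.vesicles
        if state is not None:
            tab = tab[tab.reporter_state == state]
        return {
            cls: int((tab.size_class == cls).sum())
            for cls in ("small", "medium", "large")
        }


def _class_interval(cls: str, scheme: SizeClassScheme, large_max: int | None) -> tuple[int, int]:
    """Inclusive voxel-count draw interval for a size class.

    The lower bound is clamped to 2 voxels so noiseless renders survive the
    detector's single-voxel noise rejection.
    """
    if cls == "small":
        return 2, scheme.small_max_voxels - 1
    if cls == "medium":
        return scheme.small_max_voxels, scheme.medium_max_voxels - 1
    return scheme.medium_max_voxels, large_max or 2 * scheme.medium_max_voxels


def _blob_offsets(k: int, rng: np.random.Generator) -> np.ndarray:
    """Offsets of a connected (8-conn) blob of exactly k pixels.

    Pixels nearest the origin under a mildly anisotropic elliptic metric are
    taken first; any prefix of that ordering is 8-connected because every
    pixel has a neighbour strictly closer to the origin.
    """
    if k == 1:
        return np.zeros((1, 2), dtype=int)
    q = rng.uniform(1.0, 1.6)  # axis ratio; axis-aligned to keep connectivity
    if rng.random() < 0.5:
        ar, ac = q, 1.0 / q
    else:
        ar, ac = 1.0 / q, q
    r = int(np.ceil(np.sqrt(k))) + 3
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    dist = (dr * ar) ** 2 + (dc * ac) ** 2
    flat = np.argsort(dist, axis=None, kind="stable")[:k]
    offs = np.column_stack([dr.ravel()[flat], dc.ravel()[flat]])
    # verify connectivity; fall back to the isotropic disc if ever violated
    probe = np.zeros((2 * r + 1, 2 * r + 1), dtype=bool)
    probe[offs[:, 0] + r, offs[:, 1] + r] = True
    _, n = ndimage.label(probe, structure=np.ones((3, 3)))
    if n != 1:
        flat = np.argsort(dr**2 + dc**2, axis=None, kind="stable")[:k]
        offs = np.column_stack([dr.ravel()[flat], dc.ravel()[flat]])
    return offs


def _make_cell_mask(
    spec: FieldSpec, rng: np.random.Generator
) -> np.ndarray:
    """2D reporter-cell cytoplasm mask (replicated over planes by caller)."""
    _, rows, cols = spec.field_shape
    n_reporter = int(round(spec.reporter_fraction * spec.n_cells))
    mask = np.zeros((rows, cols), dtype=bool)
    rr, cc = np.mgrid[0:rows, 0:cols]
    for i in range(spec.n_cells):
        radius = rng.uniform(0.13, 0.19) * min(rows, cols)
        cy = rng.uniform(radius, rows - radius)
        cx = rng.uniform(radius, cols - radius)
        if i < n_reporter:  # reporter-positive cells only contribute signal
            mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
    return mask


def generate_rosella_field(spec: FieldSpec) -> tuple[ImageStack, VesicleGroundTruth]:
    """Render a two-channel reporter field with known vesicle content.

    Red-only vesicles (autolysosomes: the acidic lumen quenches pHluorin)
    are bright in DsRed and stay at cytoplasm level in pHluorin;
    dual-positive vesicles (autophagosomes) are bright in both channels.
    Vesicle footprints are mutually separated connected components whose
    voxel counts fall strictly inside the requested size-class interval.
    """
    rng = np.random.default_rng(spec.seed)
    planes, rows, cols = spec.field_shape
    scheme = get_scheme(spec.scheme, spec.voxel_area_um2)
    total_requested = sum(spec.vesicles_per_class.values())

    cell2d = _make_cell_mask(spec, rng)
    if total_requested > 0 and not cell2d.any():
        raise ValueError(
            "zero-area cell mask: no reporter-positive cells to host vesicles"
        )
    cell_mask = np.broadcast_to(cell2d, (planes, rows, cols)).copy()

    # --- place vesicles -------------------------------------------------
    # occupied_pad marks vesicle footprints dilated by 1 pixel so distinct
    # vesicles can never merge under 8-connectivity
    occupied_pad = np.zeros((planes, rows, cols), dtype=bool)
    red_mask = np.zeros((planes, rows, cols), dtype=bool)
    green_mask = np.zeros((planes, rows, cols), dtype=bool)
    cand_rows, cand_cols = np.nonzero(cell2d)
    records = []
    vid = 0
    for (state, cls), n_req in sorted(spec.vesicles_per_class.items()):
        lo, hi = _class_interval(cls, scheme, spec.large_max_voxels)
        for _ in range(n_req):
            k = int(rng.integers(lo, hi + 1))
            offs = _blob_offsets(k, rng)
            placed = False
            for _attempt in range(500):
                plane = int(rng.integers(planes))
                j = int(rng.integers(len(cand_rows)))
                r0, c0 = int(cand_rows[j]), int(cand_cols[j])
                rr = offs[:, 0] + r0
                cc = offs[:, 1] + c0
                if rr.min() < 0 or cc.min() < 0 or rr.max() >= rows or cc.max() >= cols:
                    continue
                if not cell2d[rr, cc].all():
                    continue
                if occupied_pad[plane, rr, cc].any():
                    continue
                red_mask[plane, rr, cc] = True
                if state == "dual_positive":
                    green_mask[plane, rr, cc] = True
                # pad the footprint by 2 px so distinct vesicles stay
                # separate even after mild pre-smoothing blurs their edges
                pr = np.clip(rr[:, None] + np.arange(-2, 3), 0, rows - 1)
                pc = np.clip(cc[:, None] + np.arange(-2, 3), 0, cols - 1)
                for dj in range(5):
                    for dk in range(5):
                        occupied_pad[plane, pr[:, dj], pc[:, dk]] = True
                records.append(
                    {
                        "vesicle_id": vid,
                        "plane": plane,
                        "row": float(rr.mean()),
                        "col": float(cc.mean()),
                        "voxel_count": k,
                        "reporter_state": state,
                        "size_class": cls,
                    }
                )
                vid += 1
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place a {state}/{cls} vesicle after 500 tries; "
                    f"the class is over-subscribed for this field size"
                )

    # --- render ----------------------------------------------------------
    channels = list(spec.intensity_levels)
    data = np.empty((len(channels), planes, rows, cols), dtype=np.float32)
    for ci, ch in enumerate(channels):
        bg, cyto, ves = spec.intensity_levels[ch]
        img = np.full((planes, rows, cols), bg, dtype=np.float32)
        if cyto > bg:
            img[cell_mask] = cyto
        bright = green_mask if ch == "pHluorin" else red_mask
        img[bright] = ves
        data[ci] = img

    data = _apply_noise(data, spec, channels, rng)
    stack = ImageStack(
        data=data,
        channel_names=channels,
        voxel_area_um2=spec.voxel_area_um2,
        source_id=f"synthetic:rosella:seed={spec.seed}",
    )
    ph_bg, ph_cyto, ph_ves = spec.intensity_levels.get("pHluorin", (8, 40, 180))
    red_bg, _, red_ves = spec.intensity_levels.get("DsRed", (8, 8, 180))
    truth = VesicleGroundTruth(
        vesicles=pd.DataFrame(
            records,
            columns=[
                "vesicle_id", "plane", "row", "col",
                "voxel_count", "reporter_state", "size_class",
            ],
        ),
        cell_mask=cell_mask,
        red_mask=red_mask,
        green_mask=green_mask,
        suggested_thresholds={
            "DsRed": (red_bg + red_ves) / 2,
            "pHluorin": (ph_cyto + ph_ves) / 2,
            "pHluorin_cell": (ph_bg + ph_cyto) / 2,
        },
    )
    return stack, truth


def _apply_noise(
    data: np.ndarray,
    spec: FieldSpec,
    channels: list[str],
    rng: np.random.Generator,
) -> np.ndarray:
    noise = spec.noise
    if noise.kind == "none":
        return data
    if noise.kind == "gaussian":
        for ci, ch in enumerate(channels):
            bg, _, ves = spec.intensity_levels[ch]
            sigma = noise.sigma_rel * (ves - bg)
            if sigma > 0:
                data[ci] += rng.normal(0.0, sigma, size=data[ci].shape).astype(
                    np.float32
                )
        return np.clip(data, 0.0, None)
    # poisson shot noise: expected counts = intensity * gain
    return (
        rng.poisson(np.clip(data, 0, None) * noise.gain).astype(np.float32)
        / noise.gain
    )


# ---------------------------------------------------------------------------
# colocalization fields


@dataclass
class ColocGroundTruth:
    masks: dict[str, np.ndarray]
    pair_fractions: dict[tuple[str, str], float]  # realized, reference = first marker
    triple_fraction: float | None
    threshold: float  # ideal intensity threshold recovering the masks


def generate_coloc_field(
    marker_names: Sequence[str],
    pair_fractions: dict[tuple[str, str], float],
    spec: FieldSpec | None = None,
    triple_fraction: float | None = None,
    mask_voxels: int = 4000,
) -> tuple[ImageStack, ColocGroundTruth]:
    """Construct marker masks with exact overlap fractions.

    All masks have ``mask_voxels`` voxels; overlap fractions are interpreted
    relative to the first (reference) marker and realized exactly up to one
    voxel of rounding. Intensities are painted at the vesicle level inside
    masks and background outside, so thresholding at the documented midpoint
    recovers the true masks.
    """
    spec = spec or FieldSpec(field_shape=(1, 100, 100))
    markers = list(marker_names)
    if len(markers) not in (2, 3):
        raise ValueError("generate_coloc_field supports 2 or 3 markers")
    ref = markers[0]
    n = int(mask_voxels)
    fracs = {}
    for other in markers[1:]:
        key = (ref, other)
        if key not in pair_fractions:
            raise ValueError(f"missing pair fraction for {key}")
        f = float(pair_fractions[key])
        if not 0 <= f <= 1:
            raise ValueError(f"pair fraction for {key} must be in [0, 1]")
        fracs[other] = f
    t = 0
    if len(markers) == 3:
        if triple_fraction is None:
            triple_fraction = 0.0
        if not 0 <= triple_fraction <= min(fracs.values()):
            raise ValueError(
                "triple fraction must satisfy 0 <= triple <= min(pairwise)"
            )
        t = int(round(triple_fraction * n))

    planes, rows, cols = spec.field_shape
    grid = rows * cols
    # sequential linear-index allocation of disjoint regions
    if len(markers) == 2:
        b = markers[1]
        ab = int(round(fracs[b] * n))
        sizes = {"AB": ab, "Ao": n - ab, "Bo": n - ab}
        comp = {ref: ["AB", "Ao"], b: ["AB", "Bo"]}
    else:
        b, c = markers[1], markers[2]
        ab = int(round(fracs[b] * n))
        ac = int(round(fracs[c] * n))
        sizes = {
            "T": t,
            "ABo": ab - t,
            "ACo": ac - t,
            "Ao": n - ab - (ac - t),
            "Bo": n - ab,
            "Co": n - ac,
        }
        if sizes["Ao"] < 0:
            raise ValueError(
                "infeasible fractions: pairwise overlaps exceed the reference mask"
            )
        comp = {
            ref: ["T", "ABo", "ACo", "Ao"],
            b: ["T", "ABo", "Bo"],
            c: ["T", "ACo", "Co"],
        }
    if sum(sizes.values()) > grid:
        raise ValueError(
            f"masks need {sum(sizes.values())} voxels but the field has {grid}"
        )
    start = 0
    region_idx = {}
    for name, size in sizes.items():
        region_idx[name] = np.arange(start, start + size)
        start += size

    bg, _, ves = next(iter((spec.intensity_levels or DEFAULT_INTENSITY_LEVELS).values()))
    masks = {}
    data = np.full((len(markers), planes, rows, cols), bg, dtype=np.float32)
    for mi, m in enumerate(markers):
        flat = np.zeros(grid, dtype=bool)
        for region in comp[m]:
            flat[region_idx[region]] = True
        mask = np.zeros((planes, rows, cols), dtype=bool)
        mask[0] = flat.reshape(rows, cols)
        masks[m] = mask
        data[mi][mask] = ves

    realized_pairs = {
        (ref, m): float((masks[ref] & masks[m]).sum() / masks[ref].sum())
        for m in markers[1:]
    }
    realized_triple = None
    if len(markers) == 3:
        realized_triple = float(
            (masks[ref] & masks[markers[1]] & masks[markers[2]]).sum()
            / masks[ref].sum()
        )
    stack = ImageStack(
        data=data,
        channel_names=markers,
        voxel_area_um2=spec.voxel_area_um2,
        source_id="synthetic:coloc",
    )
    truth = ColocGroundTruth(
        masks=masks,
        pair_fractions=realized_pairs,
        triple_fraction=realized_triple,
        threshold=(bg + ves) / 2,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# MEA recordings


@dataclass
class MeaGroundTruth:
    spike_times: dict[str, np.ndarray]  # electrode_id -> sorted peak times (s)
    bursts: dict[str, list[tuple[float, float, int]]]  # (start, end, n_spikes)
    fs: float
    duration_s: float


def _spike_template(fs: float, width_ms: float = 1.0) -> tuple[np.ndarray, int]:
    """Biphasic (one sine cycle) unit-amplitude template and its peak index."""
    w = max(int(round(fs * width_ms / 1000.0)), 4)
    t = np.arange(w)
    tpl = np.sin(2 * np.pi * t / w)
    tpl = tpl / np.abs(tpl).max()
    return tpl.astype(np.float32), int(np.argmax(np.abs(tpl)))


def _min_gap_times(
    n: int, lo: float, hi: float, gap: float, rng: np.random.Generator
) -> np.ndarray:
    """n sorted times in [lo, hi] with pairwise spacing >= gap."""
    if n == 0:
        return np.empty(0)
    span = (hi - lo) - (n - 1) * gap
    if span <= 0:
        raise ValueError(
            f"cannot fit {n} events with {gap}s spacing into {hi - lo:.3f}s"
        )
    base = np.sort(rng.uniform(0, span, n))
    return lo + base + np.arange(n) * gap


def generate_mea_recording(
    n_electrodes: int = 16,
    duration_s: float = 600.0,
    fs: float = 12500.0,
    spike_rate: float | Sequence[float] = 1.0,
    spike_amplitude_sd: float = 12.0,
    burst_spec: dict | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    well_id: str = "W01",
) -> tuple[list[ElectrodeRecording], MeaGroundTruth]:
    """Gaussian-noise traces with injected biphasic spikes.

    Spike peak amplitude is ``spike_amplitude_sd × noise_sd``; tonic spike
    counts are Poisson draws placed with a 2 ms minimum spacing so the
    detector's dead time can never merge two true spikes. ``burst_spec``
    (optional) adds clustered spikes:
    ``{"rate_per_min": r, "n_spikes": m, "intra_isi_ms": isi}``.
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be > 0")
    if fs <= 2 * 3000:
        raise ValueError("fs must exceed twice the 3 kHz filter band edge")
    if spike_amplitude_sd <= 0:
        raise ValueError("spike amplitude must be > 0")
    rates = np.broadcast_to(np.asarray(spike_rate, dtype=float), (n_electrodes,))
    rng = np.random.default_rng(seed)
    tpl, peak_off = _spike_template(fs)
    n_samples = int(round(duration_s * fs))
    amp = spike_amplitude_sd * noise_sd
    margin = (len(tpl) + 1) / fs

    recordings = []
    spike_truth: dict[str, np.ndarray] = {}
    burst_truth: dict[str, list[tuple[float, float, int]]] = {}
    for ei in range(n_electrodes):
        eid = f"electrode_{ei + 1:02d}"
        n_spk = int(rng.poisson(rates[ei] * duration_s))
        times = _min_gap_times(n_spk, margin, duration_s - margin, 0.002, rng)
        bursts: list[tuple[float, float, int]] = []
        if burst_spec:
            m = int(burst_spec["n_spikes"])
            isi = float(burst_spec["intra_isi_ms"]) / 1000.0
            if isi < 0.002:
                raise ValueError("intra-burst ISI must be >= the 2 ms refractory gap")
            burst_len = (m - 1) * isi
            n_b = int(rng.poisson(burst_spec["rate_per_min"] / 60.0 * duration_s))
            onsets = _min_gap_times(
                n_b, margin, duration_s - margin - burst_len, burst_len + 0.1, rng
            )
            burst_times = (onsets[:, None] + np.arange(m) * isi).ravel()
            # drop tonic spikes within 2 ms of any burst spike
            if len(burst_times) and len(times):
                d = np.min(np.abs(times[:, None] - burst_times[None, :]), axis=1)
                times = times[d >= 0.002]
            times = np.sort(np.concatenate([times, burst_times]))
            bursts = [(float(o), float(o + burst_len), m) for o in onsets]

        trace = rng.normal(0.0, noise_sd, n_samples).astype(np.float32)
        starts = np.round(times * fs).astype(int) - peak_off
        for s in starts:
            trace[s : s + len(tpl)] += amp * tpl
        peak_times = (starts + peak_off) / fs
        recordings.append(ElectrodeRecording(well_id, eid, fs, trace))
        spike_truth[eid] = peak_times
        burst_truth[eid] = bursts
    truth = MeaGroundTruth(
        spike_times=spike_truth, bursts=burst_truth, fs=fs, duration_s=duration_s
    )
    return recordings, truth


# ---------------------------------------------------------------------------
# cohort tables


@dataclass
class CohortSpec:
    """Design of a control-vs-PD measurement table.

    ``pd_effect`` is multiplicative (0.7 = 30% reduction in the PD group),
    per metric or scalar; ``dispersion`` is the coefficient of variation of
    the per-(experiment, timepoint) values around their group mean.
    """

    metric_baselines: dict[str, float] = field(
        default_factory=lambda: {"autolysosome_density": 1.0}
    )
    pd_effect: float | dict[str, float] = 0.7
    n_experiments: int = 3
    timepoints: tuple = (50, 70)
    dispersion: float = 0.1
    conditions: tuple = ("control", "PD")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experiments < 2:
            raise ValueError("n_experiments must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def effect_for(self, metric: str) -> float:
        if isinstance(self.pd_effect, dict):
            return float(self.pd_effect.get(metric, 1.0))
        return float(self.pd_effect)


@dataclass
class CohortGroundTruth:
    group_means: pd.DataFrame  # condition, metric, timepoint, true_mean


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, CohortGroundTruth]:
    """One value per (condition, experiment, timepoint, metric)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    means = []
    for metric, baseline in spec.metric_baselines.items():
        for tp in spec.timepoints:
            for cond in spec.conditions:
                mean = baseline * (spec.effect_for(metric) if cond != "control" else 1.0)
                means.append(
                    {"condition": cond, "metric": metric, "timepoint": tp,
                     "true_mean": mean}
                )
                for exp in range(1, spec.n_experiments + 1):
                    value = mean * (1.0 + spec.dispersion * rng.standard_normal())
                    rows.append(
                        {
                            "condition": cond,
                            "line_id": f"{cond}_line",
                            "experiment_id": f"exp{exp:02d}",
                            "timepoint": tp,
                            "metric": metric,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows), CohortGroundTruth(group_means=pd.DataFrame(means))


# ---------------------------------------------------------------------------
# neurite fields


@dataclass
class NeuriteGroundTruth:
    th_mask: np.ndarray
    n_fragments: int


def generate_neurite_field(
    n_branches: int,
    breaks_per_branch: int,
    spec: FieldSpec | None = None,
) -> tuple[ImageStack, NeuriteGroundTruth]:
    """Curvilinear TH-positive branches with a stated number of gaps.

    Each branch is a gently sinusoidal 2-pixel-thick curve in its own
    horizontal band; ``breaks_per_branch`` gaps cut it into
    ``breaks_per_branch + 1`` fragments, so the field contains
    ``n_branches × (breaks_per_branch + 1)`` disconnected fragments.
    """
    if n_branches < 0 or breaks_per_branch < 0:
        raise ValueError("counts must be >= 0")
    spec = spec or FieldSpec(field_shape=(1, 160, 160))
    rng = np.random.default_rng(spec.seed)
    planes, rows, cols = spec.field_shape
    mask2d = np.zeros((rows, cols), dtype=bool)
    margin = 6
    if n_branches > 0:
        band = rows // n_branches
        amp = min(5.0, band / 2 - 3)
        if amp < 1:
            raise ValueError(f"too many branches ({n_branches}) for {rows} rows")
        c = np.arange(margin, cols - margin)
        gap_w = 4
        for b in range(n_branches):
            center = b * band + band // 2
            phase = rng.uniform(0, 2 * np.pi)
            wav = rng.uniform(60, 120)
            r = np.round(center + amp * np.sin(2 * np.pi * c / wav + phase)).astype(int)
            keep = np.ones(len(c), dtype=bool)
            if breaks_per_branch > 0:
                # evenly spaced gaps with jitter, never at the ends
                seg = len(c) / (breaks_per_branch + 1)
                for k in range(1, breaks_per_branch + 1):
                    pos = int(k * seg + rng.integers(-3, 4))
                    keep[max(pos - gap_w, 1) : pos + gap_w] = False
            mask2d[r[keep], c[keep]] = True
            mask2d[r[keep] + 1, c[keep]] = True  # 2 px thickness

    mask = np.zeros((planes, rows, cols), dtype=bool)
    mask[0] = mask2d
    bg, _, ves = DEFAULT_INTENSITY_LEVELS["DsRed"]
    data = np.full((1, planes, rows, cols), bg, dtype=np.float32)
    data[0][mask] = ves
    stack = ImageStack(
        data=data,
        channel_names=["TH"],
        voxel_area_um2=spec.voxel_area_um2,
        source_id="synthetic:neurite",
    )
    n_fragments = n_branches * (breaks_per_branch + 1) if n_branches else 0
    return stack, NeuriteGroundTruth(th_mask=mask, n_fragments=n_fragments)
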