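"""Image and electrode-trace IO with explicit acquisition metadata.

Conventions used throughout the package (declared once, here):

* image axes are ``(channel, plane, row, col)``, 0-based, half-open ranges;
* a "voxel" is one in-plane image element — per-plane analysis counts
  in-plane elements, and ``voxel_area_um2`` is the area of one such element;
* metadata travels in a plain-text ``key=value`` sidecar next to each data
  file, because silently assumed voxel sizes are the classic way image
  quantification goes wrong.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "ElectrodeRecording",
    "read_image",
    "write_image",
    "read_recording",
    "write_recording",
    "read_sidecar",
    "write_sidecar",
]


@dataclass
class ImageStack:
    """Multi-channel, multi-plane intensity grid with voxel-size metadata.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_planes, n_rows, n_cols)`` with
        non-negative, finite intensities.
    channel_names:
        Ordered channel labels, e.g. ``["pHluorin", "DsRed"]``.
    voxel_area_um2:
        Area of one in-plane element in µm². Must be positive.
    source_id:
        Provenance string (file path, generator call, ...).
    """

    data: np.ndarray
    channel_names: list[str]
    voxel_area_um2: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"expected (channel, plane, row, col) data, got ndim={self.data.ndim}"
            )
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} channels in data but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.voxel_area_um2 > 0:
            raise ValueError("voxel_area_um2 must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a ``(plane, row, col)`` array."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]


@dataclass
class ElectrodeRecording:
    """One electrode's sampled voltage trace."""

    well_id: str
    electrode_id: str
    fs: float
    trace: np.ndarray
    duration_s: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("sampling rate must be > 0")
        self.trace = np.asarray(self.trace)
        if self.trace.ndim != 1:
            raise ValueError("trace must be 1-D")
        if not self.duration_s:
            self.duration_s = len(self.trace) / self.fs
        if abs(self.duration_s * self.fs - len(self.trace)) > 1.0:
            raise ValueError(
                f"duration {self.duration_s} s at {self.fs} Hz does not match "
                f"trace length {len(self.trace)}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.trace)


# ---------------------------------------------------------------------------
# key=value sidecar metadata


def write_sidecar(path: str, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"{key}={value}\n")


def read_sidecar(path: str) -> dict:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def _default_sidecar_path(path: str) -> str:
    return os.path.splitext(path)[0] + ".meta"


# ---------------------------------------------------------------------------
# images


def write_image(stack: ImageStack, path: str, metadata_path: str | None = None) -> None:
    """Write a stack as multi-page TIFF plus a key=value metadata sidecar.

    Pages are ordered channel-major: all planes of channel 0, then channel 1,
    etc. Lossless for integer data and for float32 traces (stored bit-exact).
    """
    c, z, y, x = stack.data.shape
    tifffile.imwrite(path, stack.data.reshape(c * z, y, x))
    write_sidecar(
        metadata_path or _default_sidecar_path(path),
        {
            "channels": ",".join(stack.channel_names),
            "n_planes": z,
            "voxel_area_um2": repr(float(stack.voxel_area_um2)),
            "source_id": stack.source_id,
        },
    )


def read_image(path: str, metadata_path: str | None = None) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_image`.

    The sidecar must declare ``channels`` and ``voxel_area_um2``; a missing
    voxel size is an error — it is never silently defaulted.
    """
    meta = read_sidecar(metadata_path or _default_sidecar_path(path))
    if "voxel_area_um2" not in meta:
        raise ValueError(f"metadata for {path} lacks voxel_area_um2")
    if "channels" not in meta:
        raise ValueError(f"metadata for {path} lacks channel names")
    channel_names = [c for c in meta["channels"].split(",") if c]
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    n_planes = int(meta.get("n_planes", n_pages // max(len(channel_names), 1)))
    if n_planes * len(channel_names) != n_pages:
        raise ValueError(
            f"{n_pages} TIFF pages incompatible with {len(channel_names)} "
            f"channels x {n_planes} planes"
        )
    data = pages.reshape(len(channel_names), n_planes, *pages.shape[1:])
    return ImageStack(
        data=data,
        channel_names=channel_names,
        voxel_area_um2=float(meta["voxel_area_um2"]),
        source_id=meta.get("source_id", path),
    )


# ---------------------------------------------------------------------------
# electrode recordings


def write_recording(
    recordings: list[ElectrodeRecording],
    path: str,
    metadata_path: str | None = None,
    fmt: str = "csv",
) -> None:
    """Write one well's electrode traces.

    ``fmt='csv'``: columns ``time_s, <electrode_id>...`` (readable, large);
    ``fmt='bin'``: raw little-endian float32, electrodes concatenated
    (compact). The sidecar carries fs, electrode ids and well id either way.
    """
    if not recordings:
        raise ValueError("no recordings to write")
    fs = recordings[0].fs
    n = recordings[0].n_samples
    if any(r.fs != fs or r.n_samples != n for r in recordings):
        raise ValueError("all electrodes of a well must share fs and length")
    meta = {
        "well_id": recordings[0].well_id,
        "fs": repr(float(fs)),
        "n_samples": n,
        "electrodes": ",".join(r.electrode_id for r in recordings),
        "format": fmt,
    }
    if fmt == "csv":
        frame = pd.DataFrame(
            {"time_s": np.arange(n) / fs}
            | {r.electrode_id: r.trace for r in recordings}
        )
        frame.to_csv(path, index=False)
    elif fmt == "bin":
        np.concatenate([r.trace.astype("<f4") for r in recordings]).tofile(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    write_sidecar(metadata_path or _default_sidecar_path(path), meta)


def read_recording(path: str, metadata_path: str | None = None) -> list[ElectrodeRecording]:
    """Read a well written by :func:`write_recording`; errors on missing fs."""
    meta = read_sidecar(metadata_path or _default_sidecar_path(path))
    if "fs" not in meta:
        raise ValueError(f"metadata for {path} lacks sampling rate (fs)")
    fs = float(meta["fs"])
    well_id = meta.get("well_id", "")
    electrode_ids = [e for e in meta.get("electrodes", "").split(",") if e]
    fmt = meta.get("format", "csv")
    if fmt == "csv":
        frame = pd.read_csv(path)
        if not electrode_ids:
            electrode_ids = [c for c in frame.columns if c != "time_s"]
        return [
            ElectrodeRecording(well_id, eid, fs, frame[eid].to_numpy())
            for eid in electrode_ids
        ]
    if fmt == "bin":
        if "n_samples" not in meta:
            raise ValueError(f"binary recording {path} lacks n_samples metadata")
        n = int(meta["n_samples"])
        flat = np.fromfile(path, dtype="<f4")
        if len(flat) != n * len(electrode_ids):
            raise ValueError(f"binary recording {path} has unexpected size")
        return [
            ElectrodeRecording(well_id, eid, fs, flat[i * n : (i + 1) * n])
            for i, eid in enumerate(electrode_ids)
        ]
    raise ValueError(f"unknown recording format {fmt!r}")
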