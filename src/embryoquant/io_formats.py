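"""Image, label and FRAP-trace containers with explicit physical units.

All volumes are indexed ``(channel, z, y, x)`` and carry a ``(z, y, x)``
voxel spacing in micrometres.  Physical coordinates place the origin at the
corner of voxel ``(0, 0, 0)``, so the centre of voxel ``(k, j, i)`` is at
``((k + 0.5) * dz, (j + 0.5) * dy, (i + 0.5) * dx)`` µm.  Every quantity
written to a result table is in µm / µm² / µm³ / seconds — voxel-unit
values never leave this layer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class MissingSpacingError(ValueError):
    """Raised when a volume has no resolvable voxel spacing and no override."""


@dataclass
class VolumeImage:
    """Multi-channel 3D intensity volume with anisotropic voxel spacing.

    Parameters
    ----------
    data
        Float or integer array of shape ``(n_channels, nz, ny, nx)``.
    voxel_spacing
        ``(dz, dy, dx)`` in µm, all strictly positive.
    channel_names
        One name per channel, e.g. ``["dapi", "actin", "lamin"]``.
    """

    data: np.ndarray
    voxel_spacing: tuple[float, float, float]
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (c, z, y, x) data, got ndim={self.data.ndim}")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be 3 positive floats, got {self.voxel_spacing}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.voxel_spacing))

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D array for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}") from None
        return self.data[idx]


@dataclass
class LabelVolume:
    """Integer-labelled 3D mask volume; background is label 0."""

    labels: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D labels, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_spacing))

    def ids(self) -> np.ndarray:
        """Sorted non-background label ids present in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class FrapTrace:
    """Raw photobleaching time series.

    ``bleach_index`` is the index of the first post-bleach frame; frames
    ``[0, bleach_index)`` are pre-bleach.  ``background`` may be a scalar or
    a per-frame array.
    """

    t: np.ndarray
    roi: np.ndarray
    reference: np.ndarray
    background: np.ndarray | float = 0.0
    bleach_index: int = 1

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.roi = np.asarray(self.roi, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if np.isscalar(self.background):
            self.background = float(self.background) * np.ones_like(self.t)
        else:
            self.background = np.asarray(self.background, dtype=float)
        n = len(self.t)
        if not (len(self.roi) == len(self.reference) == len(self.background) == n):
            raise ValueError("t, roi, reference, background must have equal length")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            bad = np.nonzero(dt <= 0)[0] + 1
            raise ValueError(f"time must be strictly increasing; offending rows {bad.tolist()}")
        if not 1 <= self.bleach_index < n:
            raise ValueError(f"bleach_index {self.bleach_index} outside (0, {n})")


# ---------------------------------------------------------------------------
# TIFF I/O


def write_volume(img: VolumeImage, path: str | Path) -> None:
    """Write a :class:`VolumeImage` as OME-TIFF with voxel-size metadata."""
    dz, dy, dx = img.voxel_spacing
    tifffile.imwrite(
        str(path),
        img.data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": img.channel_names},
        },
    )


def _spacing_from_ome(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    if not tf.is_ome or tf.ome_metadata is None:
        return None
    import xml.etree.ElementTree as ET

    root = ET.fromstring(tf.ome_metadata)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    px = root.find(".//ome:Pixels", ns)
    if px is None:
        return None
    try:
        return (
            float(px.attrib["PhysicalSizeZ"]),
            float(px.attrib["PhysicalSizeY"]),
            float(px.attrib["PhysicalSizeX"]),
        )
    except KeyError:
        return None


def _channel_names_from_ome(tf: tifffile.TiffFile, n: int) -> list[str]:
    if tf.is_ome and tf.ome_metadata is not None:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tf.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        names = [c.attrib.get("Name", "") for c in root.findall(".//ome:Channel", ns)]
        if len(names) == n and all(names):
            return names
    return [f"ch{i}" for i in range(n)]


def read_volume(
    path: str | Path,
    spacing_override: tuple[float, float, float] | None = None,
    channel_names: list[str] | None = None,
) -> VolumeImage:
    """Read a TIFF/OME-TIFF volume.

    Spacing is taken from OME metadata unless ``spacing_override`` is given;
    a file without resolvable spacing and no override raises
    :class:`MissingSpacingError` — there is no silent unit-less default.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        spacing = spacing_override or _spacing_from_ome(tf)
        if spacing is None:
            raise MissingSpacingError(
                f"{path}: no voxel-size metadata; pass spacing_override=(dz, dy, dx) in µm"
            )
        if data.ndim == 3:
            data = data[None]
        names = channel_names or _channel_names_from_ome(tf, data.shape[0])
    return VolumeImage(data=data, voxel_spacing=tuple(spacing), channel_names=names)


def write_labels(labels: LabelVolume, path: str | Path) -> None:
    """Write a label volume as 16-bit (or 32-bit when needed) OME-TIFF."""
    dtype = np.uint16 if labels.labels.max() < 2**16 else np.uint32
    img = VolumeImage(
        data=labels.labels.astype(dtype)[None],
        voxel_spacing=labels.voxel_spacing,
        channel_names=["labels"],
    )
    write_volume(img, path)


def read_labels(
    path: str | Path, spacing_override: tuple[float, float, float] | None = None
) -> LabelVolume:
    img = read_volume(path, spacing_override=spacing_override)
    return LabelVolume(labels=img.data[0].astype(np.int64), voxel_spacing=img.voxel_spacing)


# ---------------------------------------------------------------------------
# CSV / JSON I/O


def read_frap_csv(path: str | Path) -> FrapTrace:
    """Read a FRAP trace table with columns time, roi, reference[, background].

    A missing background column is treated as 0.  The bleach frame is taken
    from a ``bleach`` indicator column (first row with 1) when present, else
    detected as the largest single-frame drop in the roi signal.
    """
    df = pd.read_csv(path)
    required = {"time", "roi", "reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    background = df["background"].to_numpy() if "background" in df.columns else 0.0
    if "bleach" in df.columns:
        post = np.nonzero(df["bleach"].to_numpy() > 0)[0]
        if len(post) == 0:
            raise ValueError(f"{path}: bleach column present but no frame flagged")
        bleach_index = int(post[0])
    else:
        bleach_index = int(np.argmin(np.diff(df["roi"].to_numpy()))) + 1
    return FrapTrace(
        t=df["time"].to_numpy(),
        roi=df["roi"].to_numpy(),
        reference=df["reference"].to_numpy(),
        background=background,
        bleach_index=bleach_index,
    )


def write_frap_csv(trace: FrapTrace, path: str | Path) -> None:
    bleach = np.zeros(len(trace.t), dtype=int)
    bleach[trace.bleach_index :] = 1
    pd.DataFrame(
        {
            "time": trace.t,
            "roi": trace.roi,
            "reference": trace.reference,
            "background": trace.background,
            "bleach": bleach,
        }
    ).to_csv(path, index=False)


def write_records_csv(records: list[dict] | pd.DataFrame, path: str | Path) -> None:
    """Serialize per-object records, one row per object, stable column order."""
    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records
    df.to_csv(path, index=False)


def write_provenance(path: str | Path, **entries) -> None:
    """Dump run configuration / provenance (parameters, seed, version) as JSON."""

    def _default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(entries, indent=2, default=_default, sort_keys=True))
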