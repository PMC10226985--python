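"""Intensity-derived statistics: L:N ratio, DAPI-standardized intensities,
nuclear:cytoplasmic ratios and cytoplasmic meshwork density.

"Mean fluorescence intensity" is always the arithmetic mean of raw voxel
values inside a 3D mask.  No background subtraction is applied to
immunofluorescence-style quantities (background correction belongs to the
FRAP path only).  All ratio operations are pure functions of the multiset
of voxel intensities inside each mask, so they are invariant under voxel
enumeration order and under any shared gain applied to both masks.
"""

from __future__ import annotations

import numpy as np

from .io_formats import VolumeImage
from .segmentation import CompartmentMasks

__all__ = [
    "mean_intensity",
    "ln_ratio",
    "dapi_standardized_intensity",
    "nuclear_cytoplasmic_ratio",
    "cytoplasmic_mesh_density",
    "nucleus_record",
    "cell_intensity_record",
]


def mean_intensity(img: VolumeImage, channel: str, mask: np.ndarray) -> float:
    """Arithmetic mean of a channel over a non-empty voxel mask."""
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    return float(img.channel(channel)[mask].mean())


def ln_ratio(
    img: VolumeImage,
    channel: str,
    lamina_shell: np.ndarray,
    nucleoplasm: np.ndarray,
) -> float:
    """Lamina-to-nucleoplasm (L:N) intensity ratio of one nucleus.

    Mean intensity over the lamina shell divided by the mean over the
    nucleoplasm; the readout of lamina enrichment of a Lamin channel.
    """
    lam = mean_intensity(img, channel, lamina_shell)
    npl = mean_intensity(img, channel, nucleoplasm)
    if npl == 0:
        raise ZeroDivisionError("zero mean nucleoplasm intensity")
    return lam / npl


def dapi_standardized_intensity(
    img: VolumeImage,
    channel: str,
    mask: np.ndarray,
    dapi_channel: str = "dapi",
    dapi_mask: np.ndarray | None = None,
) -> float:
    """Mean channel intensity over ``mask``, standardized to the DNA stain.

    ``dapi_mask`` defaults to ``mask`` itself; for cytoplasmic ROIs pass the
    same cell's nucleus, since the DNA stain is nuclear.
    """
    dm = mask if dapi_mask is None else dapi_mask
    denom = mean_intensity(img, dapi_channel, dm)
    if denom == 0:
        raise ZeroDivisionError("zero mean DAPI intensity")
    return mean_intensity(img, channel, mask) / denom


def nuclear_cytoplasmic_ratio(
    img: VolumeImage,
    channel: str,
    nucleus_mask: np.ndarray,
    cytoplasm_mask: np.ndarray,
) -> float:
    """Mean nuclear over mean cytoplasmic intensity of a channel."""
    if np.any(np.asarray(nucleus_mask, bool) & np.asarray(cytoplasm_mask, bool)):
        raise ValueError("nucleus and cytoplasm masks overlap")
    nuc = mean_intensity(img, channel, nucleus_mask)
    cyt = mean_intensity(img, channel, cytoplasm_mask)
    if cyt == 0:
        raise ZeroDivisionError("zero mean cytoplasmic intensity")
    return nuc / cyt


def cytoplasmic_mesh_density(
    img: VolumeImage,
    actin_channel: str,
    masks: CompartmentMasks,
    dapi_channel: str = "dapi",
) -> float:
    """Cytoplasmic F-actin meshwork density proxy.

    DAPI-standardized mean actin intensity over the cytoplasm mask (cortex
    and nucleus excluded by construction; validated here).  This is an
    intensity-based density, not a skeletonized filament-length density.
    """
    if np.any(masks.cytoplasm & masks.cortex):
        raise ValueError("cytoplasm mask includes cortex voxels")
    if np.any(masks.cytoplasm & masks.nucleus):
        raise ValueError("cytoplasm mask includes nucleus voxels")
    return dapi_standardized_intensity(
        img, actin_channel, masks.cytoplasm, dapi_channel, dapi_mask=masks.nucleus
    )


def nucleus_record(
    img: VolumeImage,
    masks: CompartmentMasks,
    lamin_channel: str = "lamin",
    dapi_channel: str = "dapi",
) -> dict:
    """Per-nucleus intensity metrics (geometry metrics are added separately)."""
    lam = mean_intensity(img, lamin_channel, masks.lamina_shell)
    npl = mean_intensity(img, lamin_channel, masks.nucleoplasm)
    if npl == 0:
        raise ZeroDivisionError("zero mean nucleoplasm intensity")
    vox = float(np.prod(masks.voxel_spacing))
    return {
        "nucleus_id": masks.object_id,
        "ln_ratio": lam / npl,
        "lamina_mean": lam,
        "nucleoplasm_mean": npl,
        "nucleus_total": float(img.channel(lamin_channel)[masks.nucleus].sum()),
        "nucleus_volume_um3": float(masks.nucleus.sum()) * vox,
        "lamin_dapi_standardized": dapi_standardized_intensity(
            img, lamin_channel, masks.nucleus, dapi_channel
        ),
    }


def cell_intensity_record(
    img: VolumeImage,
    masks: CompartmentMasks,
    channels: list[str] | None = None,
    dapi_channel: str = "dapi",
) -> dict:
    """Per-cell, per-compartment DAPI-standardized intensities and N:C ratios.

    For cytoplasmic and cortical compartments the DAPI reference region is
    the cell's own nucleus.
    """
    channels = channels or [c for c in img.channel_names if c != dapi_channel]
    rec: dict = {"cell_id": masks.object_id}
    for ch in channels:
        rec[f"{ch}_nuclear_std"] = dapi_standardized_intensity(
            img, ch, masks.nucleus, dapi_channel
        )
        rec[f"{ch}_cytoplasm_std"] = dapi_standardized_intensity(
            img, ch, masks.cytoplasm, dapi_channel, dapi_mask=masks.nucleus
        )
        if np.any(masks.cortex):
            rec[f"{ch}_cortex_std"] = dapi_standardized_intensity(
                img, ch, masks.cortex, dapi_channel, dapi_mask=masks.nucleus
            )
        rec[f"{ch}_nc_ratio"] = nuclear_cytoplasmic_ratio(
            img, ch, masks.nucleus, masks.cytoplasm
        )
    rec["mesh_density"] = cytoplasmic_mesh_density(img, "actin", masks, dapi_channel) if (
        "actin" in img.channel_names
    ) else np.nan
    return rec
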