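"""Embryo phantoms and FRAP traces with known ground truth.

The phantom emulates a fixed, multi-channel confocal stack of a cleavage-stage
embryo: 2–32 blastomeres packed around a common centre, each with a nucleus
whose lamina shell has a prescribed intensity ratio to the nucleoplasm, a
membrane/F-actin channel with bright cell-cell and cell-medium interfaces plus
a cytoplasmic filament meshwork of prescribed mean density, and optional
inner cells that are fully enclosed by their neighbours.  Every structural
parameter that the analysis pipeline later estimates (L:N ratio, inner/outer
class, nuclear wrinkling amplitude, meshwork density, centroids) is recorded
in a ground-truth table, so parameter recovery can be scored exactly.

Cells are laid out as a power diagram (Laguerre tessellation) over the embryo
ball: voxel ``v`` belongs to cell ``i`` minimising ``|v - c_i|^2 - r_i^2``.
This partitions the embryo with no gaps, which is what guarantees that a
designated inner cell has no voxel face-adjacent to the outside medium.
Nuclear wrinkling is a real spherical-harmonic radial perturbation
``r(θ, φ) = R (1 + a · Ỹ_l^m(θ, φ))`` with ``Ỹ`` scaled to unit peak
amplitude, so an analytic surface is available for geometric oracles.

Noise follows the standard fluorescence model: scaled-Poisson shot noise
followed by additive Gaussian read noise, each independently switchable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import sph_harm_y

from .io_formats import FrapTrace, LabelVolume, VolumeImage

__all__ = [
    "PhantomSpec",
    "PhantomOutput",
    "PackingError",
    "generate_embryo_phantom",
    "generate_frap_trace",
    "wrinkled_sphere_cloud",
]


class PackingError(ValueError):
    """Cells cannot be packed without overlap at the requested radii."""

    def __init__(self, message: str, cell_ids: list[int]):
        super().__init__(f"{message} (offending cell ids: {cell_ids})")
        self.cell_ids = cell_ids


@dataclass
class PhantomSpec:
    """Parameters of a synthetic embryo volume.

    Defaults describe an 8-cell mouse embryo imaged on a confocal with
    0.5 µm lateral and 1.0 µm axial sampling: ~25 µm embryo radius, ~12 µm
    blastomeres, nuclei at 45% of the cell radius, a 1.2 µm-wide lamina
    signal, bright cortical interfaces and a dimmer cytoplasmic meshwork,
    with shot plus read noise giving a nucleoplasm SNR of roughly 20.
    """

    n_cells: int = 8
    embryo_radius: float = 25.0  # µm
    voxel_spacing: tuple[float, float, float] = (1.0, 0.5, 0.5)  # (z, y, x) µm
    cell_radius_mean: float = 12.0  # µm
    cell_radius_sd: float = 1.0  # µm
    nucleus_radius_fraction: float = 0.45
    true_ln_ratio_per_cell: list[float] | float = 2.0
    lamina_thickness: float = 1.2  # µm
    wrinkle_amplitude: float = 0.0  # relative radial amplitude
    wrinkle_order: int = 4  # spherical-harmonic degree l
    dapi_intensity: float = 100.0
    nucleoplasm_intensity: float = 100.0
    cortical_intensity: float = 200.0
    cytoplasmic_mesh_density: list[float] | float = 40.0  # per-cell mean actin intensity
    marker_nuclear_intensity: float | None = None
    marker_cytoplasmic_intensity: float | None = None
    noise_gaussian_sd: float = 5.0
    noise_poisson_scale: float = 2.0
    inner_cell_ids: frozenset[int] = field(default_factory=frozenset)
    margin: float = 3.0  # µm of medium around the embryo
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_cells <= 32 and self.n_cells != 1:
            raise ValueError("n_cells must be 1 (calibration) or in [2, 32]")
        if min(self.embryo_radius, self.cell_radius_mean) <= 0:
            raise ValueError("radii must be positive")
        if not 0 < self.nucleus_radius_fraction < 1:
            raise ValueError("nucleus_radius_fraction must be in (0, 1)")
        if self.lamina_thickness < 0 or self.wrinkle_amplitude < 0:
            raise ValueError("lamina_thickness and wrinkle_amplitude must be >= 0")
        self.inner_cell_ids = frozenset(int(i) for i in self.inner_cell_ids)
        bad = [i for i in self.inner_cell_ids if not 1 <= i <= self.n_cells]
        if bad:
            raise ValueError(f"inner_cell_ids outside 1..n_cells: {bad}")
        if len(self.inner_cell_ids) > 4:
            raise ValueError("at most 4 designated inner cells are supported")

    def ln_ratios(self) -> np.ndarray:
        r = self.true_ln_ratio_per_cell
        arr = np.full(self.n_cells, float(r)) if np.isscalar(r) else np.asarray(r, float)
        if len(arr) != self.n_cells:
            raise ValueError("true_ln_ratio_per_cell length must equal n_cells")
        if np.any(arr < 0):
            raise ValueError("L:N ratios must be >= 0")
        return arr

    def mesh_densities(self) -> np.ndarray:
        d = self.cytoplasmic_mesh_density
        arr = np.full(self.n_cells, float(d)) if np.isscalar(d) else np.asarray(d, float)
        if len(arr) != self.n_cells:
            raise ValueError("cytoplasmic_mesh_density length must equal n_cells")
        return arr


@dataclass
class PhantomOutput:
    """A phantom volume plus its ground truth."""

    image: VolumeImage
    truth_cells: LabelVolume
    truth_nuclei: LabelVolume
    truth_lamina: LabelVolume
    truth_nucleoplasm: LabelVolume
    truth_table: pd.DataFrame


# ---------------------------------------------------------------------------
# geometry helpers


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly spread unit vectors (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([z, r * np.sin(phi), r * np.cos(phi)], axis=1)  # (z, y, x)


_INNER_ARRANGEMENTS = {
    1: np.array([[0.0, 0.0, 0.0]]),
    2: np.array([[1.0, 0, 0], [-1.0, 0, 0]]),
    3: np.array([[0, 1.0, 0], [0, -0.5, np.sqrt(3) / 2], [0, -0.5, -np.sqrt(3) / 2]]),
    4: np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3),
}
_INNER_PAIR_FACTOR = {1: np.inf, 2: 2.0, 3: np.sqrt(3.0), 4: np.sqrt(8.0 / 3.0)}


def _harmonic_norm(l: int, m: int) -> float:
    """Peak |Re Y_l^m| over a dense angular grid, for unit-amplitude scaling."""
    theta = np.linspace(0, np.pi, 181)
    phi = np.linspace(0, 2 * np.pi, 361)
    th, ph = np.meshgrid(theta, phi, indexing="ij")
    vals = np.real(sph_harm_y(l, m, th, ph))
    return float(np.abs(vals).max())


def _wrinkle_field(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Unit-peak real spherical harmonic Ỹ_l^m(θ, φ)."""
    return np.real(sph_harm_y(l, m, theta, phi)) / _harmonic_norm(l, m)


def wrinkled_sphere_cloud(
    radius: float,
    amplitude: float,
    order: int,
    n_points: int = 2000,
    m: int | None = None,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int = 0,
) -> np.ndarray:
    """Sample points on the analytic wrinkled sphere r = R(1 + a·Ỹ_l^m).

    Uniform-area sampling of the underlying sphere directions; returns an
    ``(n, 3)`` array of ``(z, y, x)`` coordinates in µm.  This is the exact
    surface the phantom nuclei are carved from, used as a geometric oracle.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_points, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    theta = np.arccos(np.clip(v[:, 0], -1, 1))
    phi = np.arctan2(v[:, 1], v[:, 2])
    mm = min(2, order) if m is None else m
    r = radius * (1.0 + amplitude * _wrinkle_field(order, mm, theta, phi))
    return np.asarray(center) + v * r[:, None]


# ---------------------------------------------------------------------------
# phantom generation


def _place_seeds(spec: PhantomSpec, radii: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Seed positions (µm, embryo-centred) for each cell, inner cells central."""
    centers = np.zeros((spec.n_cells, 3))
    inner = sorted(spec.inner_cell_ids)
    outer = [i for i in range(1, spec.n_cells + 1) if i not in spec.inner_cell_ids]
    k = len(inner)
    if k:
        nuc_max = float(
            np.max(radii[[i - 1 for i in inner]])
            * spec.nucleus_radius_fraction
            * (1 + spec.wrinkle_amplitude)
        )
        if k == 1:
            rho = 0.0
        else:
            rho = (2 * nuc_max + 2.0) / _INNER_PAIR_FACTOR[k]
        dirs = _INNER_ARRANGEMENTS[k]
        for j, cid in enumerate(inner):
            centers[cid - 1] = rho * dirs[j]
    if outer:
        shell_r = max(spec.embryo_radius - spec.cell_radius_mean, 0.45 * spec.embryo_radius)
        dirs = _fibonacci_sphere(len(outer))
        # random rotation so different seeds give different embryos
        q = rng.normal(size=(3, 3))
        qr, _ = np.linalg.qr(q)
        dirs = dirs @ qr.T
        jitter = rng.normal(scale=0.5, size=(len(outer), 3))
        for j, cid in enumerate(outer):
            centers[cid - 1] = shell_r * dirs[j] + jitter[j]
    return centers


def generate_embryo_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Render a multi-channel embryo phantom with ground truth.

    The lamin channel of cell *i* is painted so that, before noise, the mean
    voxel value over the true lamina shell divided by the mean over the true
    nucleoplasm equals ``true_ln_ratio_per_cell[i]`` exactly.  Designated
    inner cells are verified to have no boundary voxel face-adjacent to the
    medium; nuclei are verified to lie inside their own cell's territory,
    otherwise :class:`PackingError` names the offending cells.
    """
    rng = np.random.default_rng(spec.seed)
    dz, dy, dx = spec.voxel_spacing
    extent = 2.0 * (spec.embryo_radius + spec.margin)
    shape = (
        int(np.ceil(extent / dz)),
        int(np.ceil(extent / dy)),
        int(np.ceil(extent / dx)),
    )
    center = np.array([shape[0] * dz, shape[1] * dy, shape[2] * dx]) / 2.0

    zc = (np.arange(shape[0]) + 0.5) * dz - center[0]
    yc = (np.arange(shape[1]) + 0.5) * dy - center[1]
    xc = (np.arange(shape[2]) + 0.5) * dx - center[2]
    Z = zc[:, None, None]
    Y = yc[None, :, None]
    X = xc[None, None, :]
    r2_embryo = Z**2 + Y**2 + X**2
    embryo = r2_embryo <= spec.embryo_radius**2

    if spec.n_cells == 1:
        radii = np.array([min(spec.cell_radius_mean, spec.embryo_radius)])
        seeds = np.zeros((1, 3))
    else:
        radii = np.clip(
            rng.normal(spec.cell_radius_mean, spec.cell_radius_sd, spec.n_cells),
            0.5 * spec.cell_radius_mean,
            1.5 * spec.cell_radius_mean,
        )
        seeds = _place_seeds(spec, radii, rng)

    # power diagram over the embryo ball
    labels = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf)
    for i in range(spec.n_cells):
        d2 = (Z - seeds[i, 0]) ** 2 + (Y - seeds[i, 1]) ** 2 + (X - seeds[i, 2]) ** 2
        power = d2 - radii[i] ** 2
        take = embryo & (power < best)
        labels[take] = i + 1
        best = np.where(take, power, best)

    empty = [i + 1 for i in range(spec.n_cells) if not np.any(labels == i + 1)]
    if empty:
        raise PackingError("cells received no voxels in the packing", empty)

    # nuclei, lamina and nucleoplasm label volumes
    ratios = spec.ln_ratios()
    nuclei = np.zeros(shape, dtype=np.int32)
    lamina = np.zeros(shape, dtype=np.int32)
    nucleoplasm = np.zeros(shape, dtype=np.int32)
    mm = min(2, spec.wrinkle_order)
    bad_fit: list[int] = []
    nuc_radii = radii * spec.nucleus_radius_fraction
    spacing_arr = np.array([dz, dy, dx])
    nuc_centers = np.zeros((spec.n_cells, 3))
    for i in range(spec.n_cells):
        R = nuc_radii[i]
        if spec.lamina_thickness >= R * (1 - spec.wrinkle_amplitude):
            raise ValueError(
                f"lamina_thickness {spec.lamina_thickness} leaves no nucleoplasm for cell {i + 1}"
            )
        # place the nucleus at the cell's incentre: the interior point with
        # maximal clearance from neighbouring cells and the medium
        cell_idx = np.argwhere(labels == i + 1)
        clo = cell_idx.min(axis=0)
        chi = cell_idx.max(axis=0) + 1
        ccrop = tuple(slice(int(a), int(b)) for a, b in zip(clo, chi))
        # pad with one background voxel so clearance is not overestimated at
        # the bounding-box border
        clearance = ndimage.distance_transform_edt(
            np.pad(labels[ccrop] == i + 1, 1), sampling=spacing_arr
        )
        peak = np.unravel_index(int(np.argmax(clearance)), clearance.shape)
        R_outer = R * (1.0 + spec.wrinkle_amplitude)
        if clearance[peak] <= R_outer:
            bad_fit.append(i + 1)
            continue
        nuc_centers[i] = (np.asarray(peak) - 1 + clo + 0.5) * spacing_arr - center

        # carve the nucleus on a crop around its centre
        halfwidth = R_outer + spacing_arr
        lo = np.maximum(((nuc_centers[i] + center - halfwidth) / spacing_arr).astype(int), 0)
        hi = np.minimum(
            np.ceil((nuc_centers[i] + center + halfwidth) / spacing_arr).astype(int), shape
        )
        crop = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        rel_z = zc[crop[0], None, None] - nuc_centers[i, 0]
        rel_y = yc[None, crop[1], None] - nuc_centers[i, 1]
        rel_x = xc[None, None, crop[2]] - nuc_centers[i, 2]
        rr = np.sqrt(rel_z**2 + rel_y**2 + rel_x**2)
        if spec.wrinkle_amplitude > 0:
            rr_safe = np.where(rr > 0, rr, 1.0)
            theta = np.arccos(np.clip(rel_z / rr_safe, -1, 1))
            phi = np.arctan2(rel_y, rel_x)
            surf = R * (
                1.0 + spec.wrinkle_amplitude * _wrinkle_field(spec.wrinkle_order, mm, theta, phi)
            )
        else:
            surf = R
        nuc = rr <= surf
        nucpl = rr <= surf - spec.lamina_thickness
        if not np.all(labels[crop][nuc] == i + 1):
            bad_fit.append(i + 1)
            continue
        nuclei[crop][nuc] = i + 1
        nucleoplasm[crop][nucpl] = i + 1
        lamina[crop][nuc & ~nucpl] = i + 1
    if bad_fit:
        raise PackingError("nucleus does not fit inside its cell territory", bad_fit)

    # verify the inner/outer ground truth is airtight: designated inner cells
    # never touch the medium, and every other cell does
    touching = _labels_touching_background(labels)
    bad_inner = sorted(set(spec.inner_cell_ids) & touching)
    if bad_inner:
        raise PackingError("designated inner cells touch the embryo surface", bad_inner)
    bad_outer = sorted(
        set(range(1, spec.n_cells + 1)) - set(spec.inner_cell_ids) - touching
    )
    if bad_outer:
        raise PackingError("undesignated cells ended up fully enclosed", bad_outer)

    # --- channels -----------------------------------------------------------
    fg = labels > 0
    dapi = np.where(nuclei > 0, spec.dapi_intensity, 0.0)

    lamin_ch = np.zeros(shape)
    for i in range(spec.n_cells):
        lamin_ch[nucleoplasm == i + 1] = spec.nucleoplasm_intensity
        lamin_ch[lamina == i + 1] = ratios[i] * spec.nucleoplasm_intensity

    # interfaces: voxels whose 6-neighbourhood crosses a label boundary
    # (one voxel deep on each side — a ±1 µm cytoplasm erosion must clear it)
    iface = _interface_voxels(labels)
    actin = np.where(iface, spec.cortical_intensity, 0.0)

    densities = spec.mesh_densities()
    mesh_region = fg & ~iface & (nuclei == 0)
    if np.any(densities > 0):
        tex = ndimage.gaussian_filter(rng.random(shape), sigma=1.0)
        for i in range(spec.n_cells):
            reg = mesh_region & (labels == i + 1)
            if densities[i] > 0 and np.any(reg):
                actin[reg] = tex[reg] * (densities[i] / tex[reg].mean())

    channels = [dapi, actin, lamin_ch]
    names = ["dapi", "actin", "lamin"]
    if spec.marker_nuclear_intensity is not None or spec.marker_cytoplasmic_intensity is not None:
        mn = spec.marker_nuclear_intensity or 0.0
        mc = spec.marker_cytoplasmic_intensity or 0.0
        marker = np.where(nuclei > 0, mn, np.where(fg, mc, 0.0))
        channels.append(marker)
        names.append("marker")

    data = np.stack(channels).astype(np.float64)
    if spec.noise_poisson_scale > 0:
        data = spec.noise_poisson_scale * rng.poisson(data / spec.noise_poisson_scale).astype(
            np.float64
        )
    if spec.noise_gaussian_sd > 0:
        data = data + rng.normal(0.0, spec.noise_gaussian_sd, size=data.shape)

    image = VolumeImage(data=data, voxel_spacing=spec.voxel_spacing, channel_names=names)

    # --- ground-truth table -------------------------------------------------
    rows = []
    vox = np.prod(spec.voxel_spacing)
    for i in range(spec.n_cells):
        cid = i + 1
        cm_cell = center + _centroid(labels == cid, spec.voxel_spacing)
        cm_nuc = center + _centroid(nuclei == cid, spec.voxel_spacing)
        rows.append(
            {
                "cell_id": cid,
                "true_ln_ratio": ratios[i],
                "true_position_class": "inner" if cid in spec.inner_cell_ids else "outer",
                "true_cell_centroid_z": cm_cell[0],
                "true_cell_centroid_y": cm_cell[1],
                "true_cell_centroid_x": cm_cell[2],
                "true_nucleus_centroid_z": cm_nuc[0],
                "true_nucleus_centroid_y": cm_nuc[1],
                "true_nucleus_centroid_x": cm_nuc[2],
                "true_cell_radius": radii[i],
                "true_nucleus_radius": nuc_radii[i],
                "true_wrinkle_amplitude": spec.wrinkle_amplitude,
                "true_mesh_density": densities[i],
                "true_nucleus_volume": float((nuclei == cid).sum()) * vox,
            }
        )
    truth = pd.DataFrame(rows)

    mk = lambda a: LabelVolume(labels=a, voxel_spacing=spec.voxel_spacing)
    return PhantomOutput(
        image=image,
        truth_cells=mk(labels),
        truth_nuclei=mk(nuclei),
        truth_lamina=mk(lamina),
        truth_nucleoplasm=mk(nucleoplasm),
        truth_table=truth,
    )


def _face_structure() -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1)


def _centroid(mask: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    idx = np.argwhere(mask)
    return (idx.mean(axis=0) + 0.5) * np.asarray(spacing) - np.asarray(
        [mask.shape[0], mask.shape[1], mask.shape[2]]
    ) * np.asarray(spacing) / 2.0


def _shift_pairs(a: np.ndarray):
    """Yield (core slice of a, face-neighbour slice) for all 6 directions."""
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(1, None)
        sl_b[ax] = slice(None, -1)
        yield tuple(sl_a), tuple(sl_b)
        yield tuple(sl_b), tuple(sl_a)


def _interface_voxels(labels: np.ndarray) -> np.ndarray:
    """Foreground voxels with a face neighbour of a different label (or outside)."""
    out = np.zeros(labels.shape, dtype=bool)
    fg = labels > 0
    for sa, sb in _shift_pairs(labels):
        out[sa] |= fg[sa] & (labels[sa] != labels[sb])
    # volume faces count as outside
    for ax in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[ax] = edge
            out[tuple(sl)] |= fg[tuple(sl)]
    return out


def _labels_touching_background(labels: np.ndarray) -> set[int]:
    """Labels with at least one voxel face-adjacent to background (label 0)."""
    touch: set[int] = set()
    for sa, sb in _shift_pairs(labels):
        sel = (labels[sa] > 0) & (labels[sb] == 0)
        if np.any(sel):
            touch.update(np.unique(labels[sa][sel]).tolist())
    for ax in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[ax] = edge
            face = labels[tuple(sl)]
            touch.update(np.unique(face[face > 0]).tolist())
    return touch


# ---------------------------------------------------------------------------
# FRAP trace generation


def generate_frap_trace(
    i_inf: float,
    tau: float,
    pre_bleach_level: float = 1000.0,
    n_pre: int = 5,
    n_post: int = 60,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    bleach_depth: float = 0.2,
    reference_decay: float = 0.0,
    background: float = 50.0,
    seed: int = 0,
) -> FrapTrace:
    """Synthesize a FRAP time series with known recovery parameters.

    The underlying noiseless normalized recovery is
    ``y(t) = i_inf * (1 - exp(-(t - t0)/tau))`` for post-bleach times; the
    raw trace injects a background offset, an immediate post-bleach residual
    signal of ``bleach_depth`` times the pre-bleach level, and a
    multiplicative per-frame photofade that also affects the non-bleached
    reference, so the analysis module's corrections are all exercised.

    ``noise_sd`` is additive Gaussian noise on the *normalized* intensity
    scale (it is scaled by the signal amplitude before being added to the
    raw roi and reference).
    """
    if not 0.0 <= i_inf <= 1.0:
        raise ValueError("i_inf must be in [0, 1]")
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    if n_pre < 2:
        raise ValueError("need at least 2 pre-bleach frames")
    if not 0.0 <= bleach_depth < 1.0:
        raise ValueError("bleach_depth must be in [0, 1)")

    rng = np.random.default_rng(seed)
    n = n_pre + n_post
    t = np.arange(n) * dt
    t0 = t[n_pre]

    s = np.ones(n)
    post = np.arange(n_pre, n)
    y = i_inf * (1.0 - np.exp(-(t[post] - t0) / tau))
    s[post] = bleach_depth + (1.0 - bleach_depth) * y

    fade = (1.0 - reference_decay) ** np.arange(n)
    roi = background + fade * s * pre_bleach_level
    reference = background + fade * pre_bleach_level
    if noise_sd > 0:
        roi = roi + rng.normal(0.0, noise_sd * pre_bleach_level, n)
        reference = reference + rng.normal(0.0, noise_sd * pre_bleach_level, n)

    return FrapTrace(t=t, roi=roi, reference=reference, background=background, bleach_index=n_pre)
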