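"""Shared fixtures: small phantoms and analytic voxel masks."""

from __future__ import annotations

import numpy as np
import pytest

from embryoquant import PhantomSpec, generate_embryo_phantom


def digital_ball(radius, spacing, extent=None, center=(0.0, 0.0, 0.0)):
    """Boolean mask of a ball sampled at voxel centres (analytic oracle input)."""
    extent = extent or radius + 2.0
    shape = [int(np.ceil(2 * extent / s)) for s in spacing]
    axes = [(np.arange(n) + 0.5) * s - extent for n, s in zip(shape, spacing)]
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    return (Z - center[0]) ** 2 + (Y - center[1]) ** 2 + (X - center[2]) ** 2 <= radius**2


def sphere_cloud(radius, n=5000, center=(0, 0, 0), seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.asarray(center) + radius * v


@pytest.fixture(scope="session")
def noiseless_single_cell():
    """One-cell phantom, no noise: exact-ratio calibration object."""
    spec = PhantomSpec(
        n_cells=1,
        embryo_radius=14.0,
        cell_radius_mean=12.0,
        true_ln_ratio_per_cell=[2.0],
        noise_gaussian_sd=0.0,
        noise_poisson_scale=0.0,
        marker_nuclear_intensity=200.0,
        marker_cytoplasmic_intensity=100.0,
    )
    return generate_embryo_phantom(spec)


@pytest.fixture(scope="session")
def default_embryo():
    """8-cell phantom at default (noisy) imaging conditions."""
    return generate_embryo_phantom(PhantomSpec(seed=3))
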