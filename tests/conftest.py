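"""Shared fixtures: small analytic fields and generated synthetic data."""

from __future__ import annotations

import numpy as np
import pytest

from morphaline import synthgen as gen
from morphaline.grids import FieldFrame, GridSpec, VelocityFrame, VelocitySequence
from morphaline.shape3d import TriMeshFrame


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(16, 16, 1.0, 1.0, periodic2=False, truncation_fraction=0.0)


@pytest.fixture
def periodic_grid() -> GridSpec:
    return GridSpec(32, 32, 1.0, 1.0, periodic2=True, truncation_fraction=0.0)


def rotation_field(grid: GridSpec, omega: float, time: float = 0.0) -> VelocityFrame:
    """Solid-body rotation about the grid centre, rate omega (1/min)."""
    x1, x2 = np.meshgrid(grid.x1_coords(), grid.x2_coords(), indexing="ij")
    c1 = 0.5 * (grid.n1 - 1) * grid.spacing1
    c2 = 0.5 * (grid.n2 - 1) * grid.spacing2
    return VelocityFrame(grid, -omega * (x2 - c2), omega * (x1 - c1), time)


def rotation_sequence(grid: GridSpec, omega: float, n_frames: int, dt: float = 1.0):
    return VelocitySequence(
        [rotation_field(grid, omega, k * dt) for k in range(n_frames)], dt
    )


def smooth_random_field(grid: GridSpec, seed: int, sigma: float = 2.0) -> VelocityFrame:
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    mode = ("nearest", "wrap") if grid.periodic2 else "nearest"
    v1 = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma, mode=mode)
    v2 = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma, mode=mode)
    return VelocityFrame(grid, v1, v2)


def icosphere(subdiv: int, radius: float = 1.0) -> TriMeshFrame:
    """Icosahedron subdivided ``subdiv`` times, projected to a sphere."""
    t = (1 + 5**0.5) / 2
    v = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(subdiv):
        verts = list(map(np.array, v))
        mid: dict = {}

        def midpoint(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in mid:
                verts.append(0.5 * (verts[a] + verts[b]))
                mid[key] = len(verts) - 1
            return mid[key]

        new_f = []
        for a, b, c in f:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_f += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        v = np.array(verts)
        f = np.array(new_f)
    v = v / np.linalg.norm(v, axis=1, keepdims=True) * radius
    return TriMeshFrame(v, f, 0.0)


@pytest.fixture(scope="session")
def stripe_video():
    """A 40-frame stripe video advected by a quadrupole flow (master clock)."""
    spec = GridSpec(32, 48, 1.0, 1.0, periodic2=True, truncation_fraction=0.0)
    mods = [gen.ModuleSpec("extension_quadrupole", 0.0, 40.0, envelope=2.0)]
    flow = gen.make_modular_flow(spec, mods, 1.0, 40, 0.0, seed=0)
    stripe = gen.make_stripe_pattern(
        spec, edge=lambda x2: 12 + 2 * np.sin(2 * np.pi * x2 / 48)
    )
    return gen.advect_scalar(stripe, flow)
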