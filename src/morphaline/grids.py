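"""Gridded scalar/vector fields on a cylindrical chart, and curve types.

Conventions
-----------
Arrays are indexed ``[i1, i2]`` with shape ``(n1, n2)``: axis 0 is the
longitudinal chart coordinate ``x1`` and axis 1 the circumferential
coordinate ``x2`` (optionally periodic).  Physical positions are
``x1 = i1 * spacing1``, ``x2 = i2 * spacing2`` (micrometres).  Times are
minutes throughout; frame ``k`` of a sequence sits at
``start_time + k * dt``.  Missing data is carried as an explicit boolean
``valid`` mask and propagated pairwise-complete through all statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import InvalidGridError, NoStripeError

__all__ = [
    "GridSpec",
    "FieldFrame",
    "FieldSequence",
    "VelocityFrame",
    "VelocitySequence",
    "StripeCurve",
    "SpeedCurve",
    "TimeSeries",
    "apply_grid_conventions",
    "vorticity",
    "rms_speed",
    "extract_stripe_boundary",
    "rasterize_curve",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the rectangular chart grid.

    Parameters
    ----------
    n1, n2 : int
        Node counts along ``x1`` (longitudinal) and ``x2`` (circumferential).
    spacing1, spacing2 : float
        Physical node spacing in micrometres.
    periodic2 : bool
        Whether ``x2`` wraps around (cylindrical chart).
    truncation_fraction : float
        Fraction of the ``x1`` range removed at *each* end by
        :func:`apply_grid_conventions` (pole regions where measurements
        are unreliable).
    """

    n1: int
    n2: int
    spacing1: float = 1.0
    spacing2: float = 1.0
    periodic2: bool = True
    truncation_fraction: float = 0.08

    def __post_init__(self) -> None:
        if self.n1 < 4 or self.n2 < 4:
            raise InvalidGridError(f"grid must be at least 4x4, got {self.n1}x{self.n2}")
        if self.spacing1 <= 0 or self.spacing2 <= 0:
            raise InvalidGridError("grid spacings must be positive")
        if not (0 <= self.truncation_fraction < 0.5):
            raise InvalidGridError(
                f"truncation_fraction must be in [0, 0.5), got {self.truncation_fraction}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n1, self.n2)

    @property
    def extent2(self) -> float:
        """Physical circumference of the periodic x2 axis (μm)."""
        return self.n2 * self.spacing2

    def x1_coords(self) -> np.ndarray:
        return np.arange(self.n1) * self.spacing1

    def x2_coords(self) -> np.ndarray:
        return np.arange(self.n2) * self.spacing2

    def truncation_columns(self) -> int:
        """Columns removed at each x1 end by the truncation convention."""
        return math.ceil(self.truncation_fraction * self.n1)


def _check_values(grid: GridSpec, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"{name} shape {values.shape} does not match grid {grid.shape}")
    return values


def _default_valid(grid: GridSpec, values: np.ndarray, valid) -> np.ndarray:
    if valid is None:
        valid = np.isfinite(values)
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != grid.shape:
        raise ValueError("valid mask shape does not match grid")
    return valid


@dataclass
class FieldFrame:
    """One scalar chart image at a single time."""

    grid: GridSpec
    values: np.ndarray
    time: float = 0.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _check_values(self.grid, self.values, "values")
        self.valid = _default_valid(self.grid, self.values, self.valid)

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=~self.valid)


@dataclass
class VelocityFrame:
    """One tangent velocity field (μm/min) at a single time."""

    grid: GridSpec
    v1: np.ndarray
    v2: np.ndarray
    time: float = 0.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.v1 = _check_values(self.grid, self.v1, "v1")
        self.v2 = _check_values(self.grid, self.v2, "v2")
        self.valid = _default_valid(
            self.grid, np.where(np.isfinite(self.v1) & np.isfinite(self.v2), 0.0, np.nan), self.valid
        )

    def speed(self) -> np.ndarray:
        return np.hypot(self.v1, self.v2)


def _check_sequence(frames, dt: float) -> None:
    if not frames:
        raise ValueError("sequence must contain at least one frame")
    if dt <= 0:
        raise ValueError("dt must be positive")
    grid = frames[0].grid
    for k, f in enumerate(frames):
        if f.grid != grid:
            raise ValueError("all frames must share one GridSpec")
        expected = frames[0].time + k * dt
        if abs(f.time - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError(f"frame {k} at t={f.time}, expected {expected} (uniform dt)")


@dataclass
class FieldSequence:
    """Time-ordered scalar frames with uniform interval ``dt`` (min)."""

    frames: list[FieldFrame]
    dt: float

    def __post_init__(self) -> None:
        _check_sequence(self.frames, self.dt)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[FieldFrame]:
        return iter(self.frames)

    def __getitem__(self, k: int) -> FieldFrame:
        return self.frames[k]

    @property
    def grid(self) -> GridSpec:
        return self.frames[0].grid

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass
class VelocitySequence:
    """Time-ordered velocity frames with uniform interval ``dt`` (min)."""

    frames: list[VelocityFrame]
    dt: float

    def __post_init__(self) -> None:
        _check_sequence(self.frames, self.dt)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[VelocityFrame]:
        return iter(self.frames)

    def __getitem__(self, k: int) -> VelocityFrame:
        return self.frames[k]

    @property
    def grid(self) -> GridSpec:
        return self.frames[0].grid

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass
class StripeCurve:
    """Ordered polyline in chart coordinates (μm)."""

    points: np.ndarray  # (n, 2) columns (x1, x2)
    closed2: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 3:
            raise ValueError("a StripeCurve needs at least 3 points")
        seg = np.diff(self.points, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ValueError("consecutive curve points must be distinct")


@dataclass
class TimeSeries:
    """A sampled scalar trace over time (minutes)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1D arrays")


@dataclass
class SpeedCurve(TimeSeries):
    """Per-frame r.m.s. surface speed (μm/min)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise ValueError("speeds must be nonnegative")

    @property
    def speeds(self) -> np.ndarray:
        return self.values


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _truncate_grid(spec: GridSpec) -> tuple[GridSpec, slice]:
    k = spec.truncation_columns()
    kept = spec.n1 - 2 * k
    if kept < 4:
        raise InvalidGridError(
            f"truncating {k} columns per end of n1={spec.n1} leaves {kept} (< 4) columns"
        )
    new = replace(spec, n1=kept)
    return new, slice(k, spec.n1 - k)


def apply_grid_conventions(seq, spec: GridSpec | None = None):
    """Remove the truncated ``x1`` margins from every frame of a sequence.

    ``ceil(truncation_fraction * n1)`` columns are dropped at each ``x1``
    end.  The ``x2`` axis is untouched: periodicity is honoured downstream
    by index wrapping, never by storing tiled copies.
    """
    if spec is None:
        spec = seq.grid
    if spec.truncation_fraction == 0:
        return seq
    new_spec, sl = _truncate_grid(spec)
    if isinstance(seq, FieldSequence):
        frames = [
            FieldFrame(new_spec, f.values[sl], f.time, f.valid[sl]) for f in seq
        ]
        return FieldSequence(frames, seq.dt)
    frames = [
        VelocityFrame(new_spec, f.v1[sl], f.v2[sl], f.time, f.valid[sl]) for f in seq
    ]
    return VelocitySequence(frames, seq.dt)


def _d_dx1(a: np.ndarray, h: float) -> np.ndarray:
    """Central difference along axis 0, one-sided at the edges."""
    out = np.empty_like(a)
    out[1:-1] = (a[2:] - a[:-2]) / (2 * h)
    out[0] = (a[1] - a[0]) / h
    out[-1] = (a[-1] - a[-2]) / h
    return out


def _d_dx2(a: np.ndarray, h: float, periodic: bool) -> np.ndarray:
    """Central difference along axis 1, wrapping when periodic."""
    if periodic:
        return (np.roll(a, -1, axis=1) - np.roll(a, 1, axis=1)) / (2 * h)
    out = np.empty_like(a)
    out[:, 1:-1] = (a[:, 2:] - a[:, :-2]) / (2 * h)
    out[:, 0] = (a[:, 1] - a[:, 0]) / h
    out[:, -1] = (a[:, -1] - a[:, -2]) / h
    return out


def vorticity(frame: VelocityFrame) -> FieldFrame:
    """Curl of the tangent velocity, ``ω = ∂₁v2 − ∂₂v1`` (1/min).

    Central differences; wraps in ``x2`` when the grid is periodic and is
    one-sided at ``x1`` edges.  A node whose stencil touches a masked
    neighbour is flagged missing.
    """
    g = frame.grid
    om = _d_dx1(frame.v2, g.spacing1) - _d_dx2(frame.v1, g.spacing2, g.periodic2)
    ok = frame.valid
    # stencil validity: node valid and all difference neighbours valid
    n1ok = np.ones_like(ok)
    n1ok[1:-1] = ok[2:] & ok[:-2]
    n1ok[0] = ok[1]
    n1ok[-1] = ok[-2]
    if g.periodic2:
        n2ok = np.roll(ok, -1, axis=1) & np.roll(ok, 1, axis=1)
    else:
        n2ok = np.ones_like(ok)
        n2ok[:, 1:-1] = ok[:, 2:] & ok[:, :-2]
        n2ok[:, 0] = ok[:, 1]
        n2ok[:, -1] = ok[:, -2]
    valid = ok & n1ok & n2ok
    om = np.where(valid, om, np.nan)
    return FieldFrame(g, om, frame.time, valid)


def rms_speed(seq: VelocitySequence) -> SpeedCurve:
    """Per-frame root-mean-square speed over unmasked nodes (μm/min)."""
    speeds = []
    for f in seq:
        if not f.valid.any():
            raise ValueError(f"frame at t={f.time}: all nodes masked")
        sq = f.v1[f.valid] ** 2 + f.v2[f.valid] ** 2
        speeds.append(math.sqrt(float(np.mean(sq))))
    return SpeedCurve(seq.times, np.array(speeds))


def extract_stripe_boundary(
    frame: FieldFrame,
    side: str = "anterior",
    smooth_sigma: float = 1.0,
) -> StripeCurve:
    """Extract one edge of the dominant bright stripe as a polyline.

    Pipeline: Gaussian smoothing (s.d. ``smooth_sigma`` grid units, wrapping
    in periodic x2) → Otsu threshold → largest connected component →
    per-x2-row subpixel edge by linear interpolation of the smoothed profile
    across the threshold.  ``side='anterior'`` returns the low-``x1`` edge,
    ``'posterior'`` the high-``x1`` edge.
    """
    if side not in ("anterior", "posterior"):
        raise ValueError("side must be 'anterior' or 'posterior'")
    g = frame.grid
    img = np.where(frame.valid, frame.values, 0.0)
    mode = ("nearest", "wrap") if g.periodic2 else ("nearest", "nearest")
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma, mode=mode)
    if np.ptp(img) == 0:
        raise NoStripeError("image is constant; no stripe present")
    thr = threshold_otsu(img)
    mask = img > thr
    if not mask.any():
        raise NoStripeError("no pixels above Otsu threshold")
    structure = np.ones((3, 3), dtype=bool)
    labels, nlab = ndimage.label(mask, structure=structure)
    if g.periodic2 and nlab > 1:
        # merge components split across the periodic seam
        for j in range(g.n1):
            a, b = labels[j, 0], labels[j, -1]
            if a and b and a != b:
                labels[labels == b] = a
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    if len(ids) == 0:
        raise NoStripeError("no connected component above threshold")
    comp = labels == ids[np.argmax(counts)]

    pts = []
    for j in range(g.n2):
        col = np.flatnonzero(comp[:, j])
        if col.size == 0:
            continue
        if side == "anterior":
            i = col[0]
            # subpixel: interpolate crossing between i-1 and i
            if i > 0 and img[i, j] != img[i - 1, j]:
                frac = (thr - img[i - 1, j]) / (img[i, j] - img[i - 1, j])
                x1 = (i - 1 + np.clip(frac, 0.0, 1.0)) * g.spacing1
            else:
                x1 = i * g.spacing1
        else:
            i = col[-1]
            if i < g.n1 - 1 and img[i, j] != img[i + 1, j]:
                frac = (thr - img[i + 1, j]) / (img[i, j] - img[i + 1, j])
                x1 = (i + 1 - np.clip(frac, 0.0, 1.0)) * g.spacing1
            else:
                x1 = i * g.spacing1
        pts.append((x1, j * g.spacing2))
    if len(pts) < 3:
        raise NoStripeError("stripe spans fewer than 3 x2 rows")
    return StripeCurve(np.asarray(pts), closed2=g.periodic2 and len(pts) == g.n2)


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from points p (m,2) to segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(p - a, axis=1)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


def rasterize_curve(curve: StripeCurve, spec: GridSpec, bandwidth: float) -> FieldFrame:
    """Gaussian band image of a polyline: ``exp(-d²/2σ²)`` with σ=bandwidth.

    Distance is from each grid node to the nearest curve segment, honouring
    x2 periodicity by evaluating the curve at ``x2``, ``x2 ± circumference``.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x1 = spec.x1_coords()
    x2 = spec.x2_coords()
    nodes = np.stack(np.meshgrid(x1, x2, indexing="ij"), axis=-1).reshape(-1, 2)
    pts = curve.points
    shifts = [0.0]
    if spec.periodic2:
        shifts += [-spec.extent2, spec.extent2]
    d = np.full(len(nodes), np.inf)
    segs = list(zip(pts[:-1], pts[1:]))
    if curve.closed2 and len(pts) > 2:
        segs.append((pts[-1], pts[0] + np.array([0.0, spec.extent2 if spec.periodic2 else 0.0])))
    for s in shifts:
        off = np.array([0.0, s])
        for a, b in segs:
            d = np.minimum(d, _point_segment_distance(nodes, a + off, b + off))
    img = np.exp(-0.5 * (d / bandwidth) ** 2).reshape(spec.n1, spec.n2)
    return FieldFrame(spec, img)
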