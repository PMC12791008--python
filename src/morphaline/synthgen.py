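"""Ground-truthed synthetic data for every pipeline stage.

Generates piecewise-stationary chart flows built from fixed spatial
patterns, scalar stripe patterns advected through those flows, monotone
time warps emulating variable developmental rates, temperature-proxy
ensembles differing by a global speed scale, static "fixed-sample" frames
drawn at hidden times, and constricting-tube mesh sequences under known
rigid motions.  Everything is deterministic given (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.transform import Rotation

from .grids import FieldFrame, FieldSequence, GridSpec, VelocityFrame, VelocitySequence
from .kinematics import _FlowInterpolator, _rk4_step
from .shape3d import MeshSequence, RigidTransform, TriMeshFrame

__all__ = [
    "ModuleSpec",
    "WarpSpec",
    "SyntheticEnsemble",
    "flow_pattern",
    "make_modular_flow",
    "make_stripe_pattern",
    "advect_scalar",
    "apply_time_warp",
    "synth_ensemble",
    "synth_fixed_samples",
    "make_tube_sequence",
]

DEFAULT_GRID = GridSpec(64, 128, 1.0, 1.0, periodic2=True, truncation_fraction=0.0)


# ---------------------------------------------------------------------------
# flow patterns and modular flows
# ---------------------------------------------------------------------------


def flow_pattern(pattern: str, spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """A fixed, smooth unit flow pattern on the chart grid.

    ``furrow_convergence``: circumferential convergence toward mid-x2 with
    longitudinal modulation (nonzero vorticity); ``extension_quadrupole``:
    flow from the stream function sin(2πx1/L1)·sin(2πx2/L2), whose vorticity
    has the four-vortex structure of axis elongation; ``rotation``:
    solid-body rotation about the chart centre.
    """
    x1 = spec.x1_coords()
    x2 = spec.x2_coords()
    l1 = spec.n1 * spec.spacing1
    l2 = spec.extent2
    xx1, xx2 = np.meshgrid(x1, x2, indexing="ij")
    if pattern == "furrow_convergence":
        v1 = np.zeros(spec.shape)
        v2 = -np.sin(2 * np.pi * (xx2 - 0.5 * l2) / l2) * (0.5 + 0.5 * np.cos(2 * np.pi * xx1 / l1))
    elif pattern == "extension_quadrupole":
        k1, k2 = 2 * np.pi / l1, 2 * np.pi / l2
        v1 = k2 * np.sin(k1 * xx1) * np.cos(k2 * xx2) / max(k1, k2)
        v2 = -k1 * np.cos(k1 * xx1) * np.sin(k2 * xx2) / max(k1, k2)
    elif pattern == "rotation":
        c1, c2 = 0.5 * (spec.n1 - 1) * spec.spacing1, 0.5 * (spec.n2 - 1) * spec.spacing2
        scale = max(l1, l2)
        v1 = -(xx2 - c2) / scale
        v2 = (xx1 - c1) / scale
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    rms = math.sqrt(float(np.mean(v1**2 + v2**2)))
    return v1 / rms, v2 / rms


@dataclass
class ModuleSpec:
    """One stationary flow module: a fixed pattern active on a time window."""

    pattern: str
    t_start: float
    t_end: float
    envelope: float | Callable[[float], float] = 1.0
    custom_field: tuple | None = None  # (v1, v2) arrays for pattern='custom'

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("t_start must precede t_end")
        if self.pattern == "custom" and self.custom_field is None:
            raise ValueError("custom pattern requires custom_field")

    def magnitude(self, t: float) -> float:
        if not (self.t_start <= t < self.t_end):
            return 0.0
        return self.envelope(t) if callable(self.envelope) else float(self.envelope)


def make_modular_flow(
    spec: GridSpec,
    modules: list[ModuleSpec],
    dt: float = 1.0,
    n_frames: int = 60,
    noise: float = 0.0,
    seed: int = 0,
    start_time: float = 0.0,
) -> VelocitySequence:
    """Piecewise-stationary flow: v(t) = Σ envelope_k(t) · P_k(x) (+ noise)."""
    windows = sorted((m.t_start, m.t_end) for m in modules)
    for (s0, e0), (s1, _) in zip(windows, windows[1:]):
        if s1 < e0:
            raise ValueError("module windows may not overlap")
    fields = []
    for m in modules:
        if m.pattern == "custom":
            fields.append(tuple(np.asarray(a, dtype=float) for a in m.custom_field))
        else:
            fields.append(flow_pattern(m.pattern, spec))
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n_frames):
        t = start_time + k * dt
        v1 = np.zeros(spec.shape)
        v2 = np.zeros(spec.shape)
        for m, (p1, p2) in zip(modules, fields):
            a = m.magnitude(t)
            if a:
                v1 = v1 + a * p1
                v2 = v2 + a * p2
        if noise > 0:
            v1 = v1 + noise * rng.standard_normal(spec.shape)
            v2 = v2 + noise * rng.standard_normal(spec.shape)
        frames.append(VelocityFrame(spec, v1, v2, t))
    return VelocitySequence(frames, dt)


# ---------------------------------------------------------------------------
# scalar stripe patterns and advection
# ---------------------------------------------------------------------------


def make_stripe_pattern(
    spec: GridSpec,
    edge: float | Callable[[np.ndarray], np.ndarray] = None,
    width: float = 4.0,
    amplitude: float = 1.0,
    profile: str = "gauss",
    edge_scale: float = 1.0,
) -> FieldFrame:
    """Bright stripe image with a known anterior boundary.

    ``edge`` gives the anterior (low-x1) boundary location in μm as a
    function of x2.  ``profile='gauss'``: Gaussian band of s.d. ``width/2``
    centred ``width`` posterior of the edge.  ``profile='box'``: smooth
    boxcar built from error functions whose half-maximum crossing lies
    exactly on ``edge`` (sharp ground truth for boundary-extraction tests).
    """
    from scipy.special import erf

    if edge is None:
        edge = 0.4 * spec.n1 * spec.spacing1
    x2 = spec.x2_coords()
    e = edge(x2) if callable(edge) else np.full(spec.n2, float(edge))
    x1 = spec.x1_coords()[:, None]
    if profile == "gauss":
        centre = e[None, :] + width
        img = amplitude * np.exp(-0.5 * ((x1 - centre) / (0.5 * width)) ** 2)
    elif profile == "box":
        img = 0.5 * amplitude * (
            erf((x1 - e[None, :]) / edge_scale)
            - erf((x1 - e[None, :] - width) / edge_scale)
        )
    else:
        raise ValueError("profile must be 'gauss' or 'box'")
    return FieldFrame(spec, img)


def _sample_scalar(frame: FieldFrame, pos: np.ndarray) -> np.ndarray:
    """Bilinear sample of a scalar frame at physical positions (x2 wrapped)."""
    g = frame.grid
    f1 = np.clip(pos[:, 0] / g.spacing1, 0.0, g.n1 - 1.0)
    f2 = pos[:, 1] / g.spacing2
    i0 = np.clip(np.floor(f1).astype(int), 0, g.n1 - 2)
    a1 = f1 - i0
    if g.periodic2:
        j0 = np.floor(f2).astype(int) % g.n2
        j1 = (j0 + 1) % g.n2
        a2 = f2 - np.floor(f2)
    else:
        f2 = np.clip(f2, 0.0, g.n2 - 1.0)
        j0 = np.clip(np.floor(f2).astype(int), 0, g.n2 - 2)
        j1 = j0 + 1
        a2 = f2 - j0
    vals = frame.values
    return (
        (1 - a1) * (1 - a2) * vals[i0, j0]
        + (1 - a1) * a2 * vals[i0, j1]
        + a1 * (1 - a2) * vals[i0 + 1, j0]
        + a1 * a2 * vals[i0 + 1, j1]
    )


def advect_scalar(
    init: FieldFrame,
    flow: VelocitySequence,
    dt_int: float = 1.0,
) -> FieldSequence:
    """Advect a scalar pattern through the flow (semi-Lagrangian).

    Frame k samples the initial pattern at the RK4-backtracked source
    position of each grid node, with bilinear interpolation; x2 wraps and
    backtracking clamps at the x1 edges.
    """
    g = init.grid
    ii, jj = np.meshgrid(np.arange(g.n1), np.arange(g.n2), indexing="ij")
    nodes = np.stack([ii.ravel() * g.spacing1, jj.ravel() * g.spacing2], axis=1).astype(float)
    fl = _FlowInterpolator(flow)
    x1_max = (g.n1 - 1) * g.spacing1
    times = flow.times
    frames = [FieldFrame(g, init.values.copy(), times[0])]
    for t in times[1:]:
        pos = nodes.copy()
        n_steps = max(1, int(round((t - times[0]) / dt_int)))
        h = (t - times[0]) / n_steps
        for s in range(n_steps):
            tau = t - s * h
            pos = _rk4_step(fl, tau, pos, -h)
            pos[:, 0] = np.clip(pos[:, 0], 0.0, x1_max)
            if g.periodic2:
                pos[:, 1] %= g.extent2
        vals = _sample_scalar(init, pos).reshape(g.shape)
        frames.append(FieldFrame(g, vals, t))
    return FieldSequence(frames, flow.dt)


# ---------------------------------------------------------------------------
# monotone time warps
# ---------------------------------------------------------------------------


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


@dataclass
class WarpSpec:
    """Monotone map g: true time → recorded time.

    g(t) = shift + rate·t + bump_amp·smoothstep((t − bump_center)/bump_width);
    monotonicity (g' > 0) is validated numerically on each domain of use.
    """

    shift: float = 0.0
    rate: float = 1.0
    bump_amp: float = 0.0
    bump_center: float = 0.0
    bump_width: float = 10.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.shift + self.rate * t + self.bump_amp * _smoothstep(
            (t - self.bump_center) / self.bump_width
        )

    def validate(self, t_min: float, t_max: float) -> None:
        tt = np.linspace(t_min, t_max, 2048)
        g = self(tt)
        if np.any(np.diff(g) <= 0):
            raise ValueError("warp is not strictly monotone on the requested domain")

    def inverse(self, tau, t_min: float, t_max: float):
        self.validate(t_min, t_max)
        tt = np.linspace(t_min, t_max, 4096)
        return np.interp(tau, self(tt), tt)


def apply_time_warp(seq, warp: WarpSpec, dt: float | None = None):
    """Resample a sequence as it would appear on a warped recording clock.

    The recorded frame at time τ shows the master sequence at g⁻¹(τ)
    (linear interpolation in time).  Recorded frame times run from
    g(t_first) in steps of ``dt`` (default: the master dt) up to g(t_last).
    """
    times = seq.times
    warp.validate(times[0], times[-1])
    dt = seq.dt if dt is None else dt
    tau0, tau1 = float(warp(times[0])), float(warp(times[-1]))
    n_out = int(math.floor((tau1 - tau0) / dt + 1e-9)) + 1
    taus = tau0 + dt * np.arange(n_out)
    src = warp.inverse(taus, times[0], times[-1])
    is_vel = isinstance(seq, VelocitySequence)
    frames = []
    for tau, u in zip(taus, src):
        k = int(np.clip(np.searchsorted(times, u, side="right") - 1, 0, len(times) - 2))
        a = np.clip((u - times[k]) / (times[k + 1] - times[k]), 0.0, 1.0)
        if is_vel:
            f0, f1 = seq[k], seq[k + 1]
            v1 = (1 - a) * f0.v1 + a * f1.v1
            v2 = (1 - a) * f0.v2 + a * f1.v2
            frames.append(VelocityFrame(seq.grid, v1, v2, tau, f0.valid & f1.valid))
        else:
            f0, f1 = seq[k], seq[k + 1]
            vals = (1 - a) * f0.values + a * f1.values
            frames.append(FieldFrame(seq.grid, vals, tau, f0.valid & f1.valid))
    return (VelocitySequence if is_vel else FieldSequence)(frames, dt)


# ---------------------------------------------------------------------------
# ensembles and fixed samples
# ---------------------------------------------------------------------------


@dataclass
class SyntheticEnsemble:
    """Generated members plus the full ground truth that produced them."""

    members: list
    truth: dict = field(default_factory=dict)


def _scale_velocity(seq: VelocitySequence, s: float) -> VelocitySequence:
    frames = [
        VelocityFrame(seq.grid, s * f.v1, s * f.v2, f.time, f.valid) for f in seq
    ]
    return VelocitySequence(frames, seq.dt)


def _add_noise(seq, sigma: float, rng) -> object:
    if sigma <= 0:
        return seq
    if isinstance(seq, VelocitySequence):
        frames = [
            VelocityFrame(
                seq.grid,
                f.v1 + sigma * rng.standard_normal(f.v1.shape),
                f.v2 + sigma * rng.standard_normal(f.v2.shape),
                f.time,
                f.valid,
            )
            for f in seq
        ]
        return VelocitySequence(frames, seq.dt)
    frames = [
        FieldFrame(seq.grid, f.values + sigma * rng.standard_normal(f.values.shape), f.time, f.valid)
        for f in seq
    ]
    return FieldSequence(frames, seq.dt)


def synth_ensemble(
    n: int,
    base,
    warps: list[WarpSpec] | None = None,
    speed_scales=None,
    noise: float = 0.0,
    seed: int = 0,
) -> SyntheticEnsemble:
    """Ensemble of independently warped, scaled, noised copies of a master.

    Each member e is ``s_e · base(g_e⁻¹(τ))`` plus seeded Gaussian noise.
    A temperature proxy uses warp rate 1/s_e together with speed scale s_e
    (hotter → faster clock and faster flow, identical net deformation).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    if warps is None:
        warps = [WarpSpec() for _ in range(n)]
    if speed_scales is None:
        speed_scales = [1.0] * n
    if len(warps) != n or len(speed_scales) != n:
        raise ValueError("warps and speed_scales must have length n")
    members = []
    for w, s in zip(warps, speed_scales):
        m = apply_time_warp(base, w)
        if isinstance(m, VelocitySequence) and s != 1.0:
            m = _scale_velocity(m, s)
        members.append(_add_noise(m, noise, rng))
    truth = {"warps": warps, "speed_scales": list(speed_scales), "noise": noise, "seed": seed}
    return SyntheticEnsemble(members, truth)


def synth_fixed_samples(
    seq: FieldSequence, times, noise: float = 0.0, seed: int = 0
) -> tuple[list[FieldFrame], np.ndarray]:
    """Static snapshots of a live sequence at hidden times, plus the truth."""
    rng = np.random.default_rng(seed)
    ts = seq.times
    times = np.asarray(times, dtype=float)
    if np.any(times < ts[0]) or np.any(times > ts[-1]):
        raise ValueError("sample times outside the sequence span")
    out = []
    for t in times:
        k = int(np.clip(np.searchsorted(ts, t, side="right") - 1, 0, len(ts) - 2))
        a = np.clip((t - ts[k]) / (ts[k + 1] - ts[k]), 0.0, 1.0)
        vals = (1 - a) * seq[k].values + a * seq[k + 1].values
        if noise > 0:
            vals = vals + noise * rng.standard_normal(vals.shape)
        out.append(FieldFrame(seq.grid, vals, float(t)))
    return out, times


# ---------------------------------------------------------------------------
# constricting tube meshes
# ---------------------------------------------------------------------------


def make_tube_sequence(
    n_frames: int = 10,
    dt: float = 1.0,
    n_z: int = 40,
    n_theta: int = 24,
    length: float = 100.0,
    radius0: float = 12.0,
    constrictions=((0.5, 8.0, 0.5),),
    rigid_motion: bool = False,
    seed: int = 0,
    progress=None,
) -> tuple[MeshSequence, list[RigidTransform]]:
    """Tube with Gaussian constrictions deepening over the sequence.

    ``constrictions`` are (z_fraction, width_um, final_depth_fraction)
    triples; the radius field is
    ``R(z, t_k) = R0 · (1 − Σ depth_i·progress_k·exp(−(z−z_i)²/2w²))`` with
    ``progress`` defaulting to a linear ramp 0 → 1 (pass a custom monotone
    array to emulate a time-warped recording).  Vertex indexing is
    consistent across frames (material correspondence); optional per-frame
    rigid motions are returned as ground truth.
    """
    z = np.linspace(0.0, length, n_z)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    rng = np.random.default_rng(seed)
    if progress is None:
        progress = np.linspace(0.0, 1.0, n_frames) if n_frames > 1 else np.zeros(1)
    progress = np.asarray(progress, dtype=float)
    if len(progress) != n_frames:
        raise ValueError("progress must have one value per frame")

    # deepest constriction must keep the radius positive
    final = np.ones(n_z)
    for zf, w, depth in constrictions:
        final -= depth * progress.max() * np.exp(-0.5 * ((z - zf * length) / w) ** 2)
    if final.min() <= 0:
        raise ValueError("constriction schedule drives the radius nonpositive")

    faces = []
    for i in range(n_z - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append((a, b, d))
            faces.append((a, d, c))
    faces = np.asarray(faces, dtype=int)

    frames, transforms = [], []
    for k in range(n_frames):
        t = k * dt
        shrink = np.ones(n_z)
        for zf, w, depth in constrictions:
            shrink -= depth * progress[k] * np.exp(-0.5 * ((z - zf * length) / w) ** 2)
        r = radius0 * shrink
        verts = np.empty((n_z * n_theta, 3))
        for i in range(n_z):
            verts[i * n_theta : (i + 1) * n_theta, 0] = r[i] * np.cos(theta)
            verts[i * n_theta : (i + 1) * n_theta, 1] = r[i] * np.sin(theta)
            verts[i * n_theta : (i + 1) * n_theta, 2] = z[i]
        if rigid_motion and k > 0:
            rot = Rotation.from_rotvec(rng.uniform(-0.3, 0.3, 3)).as_matrix()
            tr = RigidTransform(rot, rng.uniform(-5.0, 5.0, 3))
        else:
            tr = RigidTransform.identity()
        transforms.append(tr)
        frames.append(TriMeshFrame(tr.apply(verts), faces, t))
    return MeshSequence(frames), transforms
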