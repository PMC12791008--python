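"""Flow-derived observables: PIV, pathlines, autocorrelation, flow modules.

The PIV block matcher is deliberately minimal plumbing (normalized
cross-correlation with a parabolic subpixel peak); the scientific content
lives in the pathline integration (RK4, linear interpolation in space and
time), the velocity autocorrelation matrices and the stationary-module
segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import (
    FieldFrame,
    GridSpec,
    TimeSeries,
    VelocityFrame,
    VelocitySequence,
)
from .similarity import SimilarityMatrix, similarity_matrix

__all__ = [
    "PathlineSet",
    "DisplacementField",
    "ModuleSegmentation",
    "piv_estimate",
    "integrate_pathlines",
    "displacement_field",
    "autocorr_matrix",
    "segment_modules",
    "time_average_flow",
    "ensemble_average_flow",
    "corr_to_ensemble",
]

DEFAULT_DT_INT = 0.2  # min, integration step


@dataclass
class PathlineSet:
    """Material trajectories integrated through a velocity sequence.

    ``positions`` has shape (n_seeds, n_steps + 1, 2) in μm; ``escaped``
    marks seeds frozen after leaving the x1 domain.
    """

    seeds: np.ndarray
    positions: np.ndarray
    t_start: float
    t_end: float
    dt_int: float
    escaped: np.ndarray

    def __post_init__(self) -> None:
        n_steps = int(round((self.t_end - self.t_start) / self.dt_int))
        if self.positions.shape != (len(self.seeds), n_steps + 1, 2):
            raise ValueError("positions shape inconsistent with seeds and step count")
        if not np.isfinite(self.positions).all():
            raise ValueError("pathline positions must be finite")


@dataclass
class DisplacementField:
    """Per-seed net Euclidean displacement Δ = |x(t1) − x(t0)| (μm)."""

    delta: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.delta[self.valid] < 0):
            raise ValueError("displacements must be nonnegative")


@dataclass
class ModuleSegmentation:
    """Disjoint, ordered stationary-flow intervals on one timeline."""

    modules: list  # of (t_start, t_end, mean_corr, label)
    threshold: float

    def __post_init__(self) -> None:
        for k in range(1, len(self.modules)):
            if self.modules[k][0] < self.modules[k - 1][1]:
                raise ValueError("modules must be disjoint and ordered")
        for t0, t1, mc, _ in self.modules:
            if mc < self.threshold:
                raise ValueError("module mean correlation below threshold")


# ---------------------------------------------------------------------------
# minimal PIV
# ---------------------------------------------------------------------------


def _window_at(img: np.ndarray, i0: int, j0: int, win: int, periodic2: bool) -> np.ndarray | None:
    n1, n2 = img.shape
    if i0 < 0 or i0 + win > n1:
        return None
    if periodic2:
        cols = np.arange(j0, j0 + win) % n2
        return img[i0 : i0 + win][:, cols]
    if j0 < 0 or j0 + win > n2:
        return None
    return img[i0 : i0 + win, j0 : j0 + win]


def _parabolic_offset(cm: float, cc: float, cp: float) -> float:
    denom = cm - 2 * cc + cp
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))


def piv_estimate(
    a: FieldFrame, b: FieldFrame, window: int = 8, search: int = 4
) -> VelocityFrame:
    """Block-matching PIV between two frames (μm/min).

    Each non-overlapping ``window``×``window`` block of ``a`` is matched
    against ``b`` over integer shifts in ±``search``, maximizing the
    normalized cross-correlation, refined to subpixel precision with a
    3-point parabolic peak fit per axis.  Flat (zero-variance) blocks are
    masked.  x2 wraps when the grid is periodic.
    """
    if a.grid != b.grid:
        raise ValueError("frames must share a grid")
    if window < 8:
        raise ValueError("window must be at least 8 grid units")
    g = a.grid
    dt = b.time - a.time
    if dt <= 0:
        raise ValueError("frame b must be later than frame a")
    ia = np.where(a.valid, a.values, 0.0)
    ib = np.where(b.valid, b.values, 0.0)
    n1w, n2w = g.n1 // window, g.n2 // window
    if n1w < 4 or n2w < 4:
        raise ValueError("too few PIV windows; reduce window size")
    out_grid = GridSpec(
        n1w, n2w, g.spacing1 * window, g.spacing2 * window, g.periodic2, g.truncation_fraction
    )
    v1 = np.zeros((n1w, n2w))
    v2 = np.zeros((n1w, n2w))
    ok = np.zeros((n1w, n2w), dtype=bool)
    shifts = range(-search, search + 1)
    for wi in range(n1w):
        for wj in range(n2w):
            i0, j0 = wi * window, wj * window
            ref = _window_at(ia, i0, j0, window, g.periodic2)
            ref = ref - ref.mean()
            nref = np.sqrt((ref**2).sum())
            if nref == 0:
                continue
            ncc = np.full((2 * search + 1, 2 * search + 1), -np.inf)
            for du in shifts:
                for dv in shifts:
                    tgt = _window_at(ib, i0 + du, j0 + dv, window, g.periodic2)
                    if tgt is None:
                        continue
                    tgt = tgt - tgt.mean()
                    ntgt = np.sqrt((tgt**2).sum())
                    if ntgt == 0:
                        continue
                    ncc[du + search, dv + search] = float((ref * tgt).sum()) / (nref * ntgt)
            if not np.isfinite(ncc).any():
                continue
            pu, pv = np.unravel_index(np.argmax(ncc), ncc.shape)
            du, dv = pu - search, pv - search
            su = sv = 0.0
            # NCC of 1 is an exact match: the displacement is integral and
            # 3-point refinement would only add peak-asymmetry bias
            if ncc[pu, pv] < 1.0 - 1e-9:
                if 0 < pu < 2 * search and np.isfinite(ncc[pu - 1, pv]) and np.isfinite(ncc[pu + 1, pv]):
                    su = _parabolic_offset(ncc[pu - 1, pv], ncc[pu, pv], ncc[pu + 1, pv])
                if 0 < pv < 2 * search and np.isfinite(ncc[pu, pv - 1]) and np.isfinite(ncc[pu, pv + 1]):
                    sv = _parabolic_offset(ncc[pu, pv - 1], ncc[pu, pv], ncc[pu, pv + 1])
            v1[wi, wj] = (du + su) * g.spacing1 / dt
            v2[wi, wj] = (dv + sv) * g.spacing2 / dt
            ok[wi, wj] = True
    v1[~ok] = np.nan
    v2[~ok] = np.nan
    return VelocityFrame(out_grid, v1, v2, a.time, ok)


# ---------------------------------------------------------------------------
# pathline integration (RK4)
# ---------------------------------------------------------------------------


class _FlowInterpolator:
    """Bilinear-in-space, linear-in-time sampler of a VelocitySequence."""

    def __init__(self, seq: VelocitySequence):
        self.grid = seq.grid
        self.times = seq.times
        g = self.grid
        self.v1 = np.stack([np.where(f.valid, f.v1, 0.0) for f in seq])
        self.v2 = np.stack([np.where(f.valid, f.v2, 0.0) for f in seq])
        self.wt = np.stack([f.valid.astype(float) for f in seq])
        self.x1_max = (g.n1 - 1) * g.spacing1

    def _sample_frame(self, k: int, pos: np.ndarray) -> np.ndarray:
        g = self.grid
        f1 = pos[:, 0] / g.spacing1
        f2 = pos[:, 1] / g.spacing2
        i0 = np.clip(np.floor(f1).astype(int), 0, g.n1 - 2)
        a1 = np.clip(f1 - i0, 0.0, 1.0)
        if g.periodic2:
            j0 = np.floor(f2).astype(int) % g.n2
            j1 = (j0 + 1) % g.n2
            a2 = f2 - np.floor(f2)
        else:
            j0 = np.clip(np.floor(f2).astype(int), 0, g.n2 - 2)
            j1 = j0 + 1
            a2 = np.clip(f2 - j0, 0.0, 1.0)
        i1 = i0 + 1
        w00 = (1 - a1) * (1 - a2)
        w01 = (1 - a1) * a2
        w10 = a1 * (1 - a2)
        w11 = a1 * a2
        out = np.empty_like(pos)
        for comp, arr in ((0, self.v1[k]), (1, self.v2[k])):
            num = (
                w00 * arr[i0, j0] * self.wt[k][i0, j0]
                + w01 * arr[i0, j1] * self.wt[k][i0, j1]
                + w10 * arr[i1, j0] * self.wt[k][i1, j0]
                + w11 * arr[i1, j1] * self.wt[k][i1, j1]
            )
            den = (
                w00 * self.wt[k][i0, j0]
                + w01 * self.wt[k][i0, j1]
                + w10 * self.wt[k][i1, j0]
                + w11 * self.wt[k][i1, j1]
            )
            out[:, comp] = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
        return out

    def __call__(self, t: float, pos: np.ndarray) -> np.ndarray:
        ts = self.times
        if t <= ts[0]:
            return self._sample_frame(0, pos)
        if t >= ts[-1]:
            return self._sample_frame(len(ts) - 1, pos)
        k = int(np.searchsorted(ts, t, side="right") - 1)
        k = min(k, len(ts) - 2)
        a = (t - ts[k]) / (ts[k + 1] - ts[k])
        return (1 - a) * self._sample_frame(k, pos) + a * self._sample_frame(k + 1, pos)


def _rk4_step(fl, t: float, pos: np.ndarray, h: float) -> np.ndarray:
    k1 = fl(t, pos)
    k2 = fl(t + 0.5 * h, pos + 0.5 * h * k1)
    k3 = fl(t + 0.5 * h, pos + 0.5 * h * k2)
    k4 = fl(t + h, pos + h * k3)
    return pos + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def integrate_pathlines(
    seq: VelocitySequence,
    t_start: float,
    t_end: float,
    dt_int: float = DEFAULT_DT_INT,
    seeds: np.ndarray | None = None,
) -> PathlineSet:
    """Integrate material pathlines through the flow with RK4.

    Velocity is interpolated bilinearly in space and linearly in time;
    ``x2`` wraps on periodic grids; seeds leaving the ``x1`` domain are
    frozen in place and flagged as escaped.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    ts = seq.times
    if t_start < ts[0] - 1e-9 or t_end > ts[-1] + 1e-9:
        raise ValueError("integration window outside the sequence span")
    g = seq.grid
    if seeds is None:
        k0 = int(np.clip(np.searchsorted(ts, t_start, side="right") - 1, 0, len(ts) - 1))
        ii, jj = np.nonzero(seq[k0].valid)
        seeds = np.stack([ii * g.spacing1, jj * g.spacing2], axis=1).astype(float)
    else:
        seeds = np.asarray(seeds, dtype=float)
    n_steps = int(round((t_end - t_start) / dt_int))
    if abs(t_start + n_steps * dt_int - t_end) > 1e-6:
        raise ValueError("(t_end - t_start) must be an integer multiple of dt_int")
    fl = _FlowInterpolator(seq)
    pos = seeds.copy()
    escaped = np.zeros(len(seeds), dtype=bool)
    traj = np.empty((len(seeds), n_steps + 1, 2))
    traj[:, 0] = pos
    extent2 = g.extent2
    for s in range(n_steps):
        t = t_start + s * dt_int
        live = ~escaped
        if live.any():
            new = _rk4_step(fl, t, pos[live], dt_int)
            if g.periodic2:
                new[:, 1] %= extent2
            out = (new[:, 0] < 0) | (new[:, 0] > fl.x1_max)
            idx = np.flatnonzero(live)
            pos[idx[~out]] = new[~out]
            escaped[idx[out]] = True  # freeze at last inside position
        traj[:, s + 1] = pos
    return PathlineSet(seeds, traj, t_start, t_end, dt_int, escaped)


def displacement_field(p: PathlineSet) -> DisplacementField:
    """Net displacement Δ = sqrt((x1−x0)² + (y1−y0)²) per seed (μm)."""
    d = np.linalg.norm(p.positions[:, -1] - p.positions[:, 0], axis=1)
    return DisplacementField(d, ~p.escaped)


# ---------------------------------------------------------------------------
# autocorrelation and module segmentation
# ---------------------------------------------------------------------------


def autocorr_matrix(seq: VelocitySequence, measure="vorticity", **params) -> SimilarityMatrix:
    """Square symmetric frame-to-frame autocorrelation of one recording."""
    if len(seq) < 2:
        raise ValueError("need at least 2 frames")
    return similarity_matrix(seq, seq, measure, **params)


def segment_modules(
    m: SimilarityMatrix, threshold: float = 0.6, min_len: int = 3
) -> ModuleSegmentation:
    """Partition the diagonal into stationary-flow blocks.

    Dynamic program maximizing Σ (block mean correlation − threshold) ×
    block_area over disjoint diagonal blocks of length ≥ ``min_len``;
    frames between blocks are gaps.  The default threshold 0.6 sits at the
    pattern-decorrelation level e^{−1/2} ≈ 0.61.
    """
    v = m.values
    n = v.shape[0]
    if v.shape[0] != v.shape[1]:
        raise ValueError("segment_modules requires a square matrix")
    filled = np.where(np.isfinite(v), v, 0.0)
    cnt = np.isfinite(v).astype(float)
    ps = np.zeros((n + 1, n + 1))
    pc = np.zeros((n + 1, n + 1))
    ps[1:, 1:] = np.cumsum(np.cumsum(filled, 0), 1)
    pc[1:, 1:] = np.cumsum(np.cumsum(cnt, 0), 1)

    def block_mean(s, e):  # frames s..e-1, rectangle [s:e, s:e]
        tot = ps[e, e] - ps[s, e] - ps[e, s] + ps[s, s]
        num = pc[e, e] - pc[s, e] - pc[e, s] + pc[s, s]
        return tot / num if num > 0 else -np.inf

    best = np.zeros(n + 1)
    choice = np.full(n + 1, -1, dtype=int)  # -1: frame e-1 unassigned; else block start
    for e in range(1, n + 1):
        best[e] = best[e - 1]
        choice[e] = -1
        for s in range(0, e - min_len + 1):
            mu = block_mean(s, e)
            score = best[s] + (mu - threshold) * (e - s) ** 2
            if score > best[e] + 1e-12:
                best[e] = score
                choice[e] = s
    blocks = []
    e = n
    while e > 0:
        s = choice[e]
        if s < 0:
            e -= 1
        else:
            blocks.append((s, e))
            e = s
    blocks.reverse()
    times = m.times_a
    dt = float(np.median(np.diff(times))) if n > 1 else 1.0
    mods = []
    for k, (s, e) in enumerate(blocks):
        mods.append((float(times[s]), float(times[e - 1] + dt), block_mean(s, e), f"module_{k}"))
    return ModuleSegmentation(mods, threshold)


# ---------------------------------------------------------------------------
# flow averaging
# ---------------------------------------------------------------------------


def time_average_flow(seq: VelocitySequence, t_start=None, t_end=None) -> VelocityFrame:
    """Arithmetic time average of the flow over [t_start, t_end]."""
    ts = seq.times
    t_start = ts[0] if t_start is None else t_start
    t_end = ts[-1] if t_end is None else t_end
    keep = (ts >= t_start - 1e-9) & (ts <= t_end + 1e-9)
    if not keep.any():
        raise ValueError("no frames in the averaging window")
    frames = [f for f, k in zip(seq, keep) if k]
    w = np.sum([f.valid for f in frames], axis=0).astype(float)
    v1 = np.sum([np.where(f.valid, f.v1, 0.0) for f in frames], axis=0)
    v2 = np.sum([np.where(f.valid, f.v2, 0.0) for f in frames], axis=0)
    ok = w > 0
    v1 = np.where(ok, v1 / np.maximum(w, 1), np.nan)
    v2 = np.where(ok, v2 / np.maximum(w, 1), np.nan)
    return VelocityFrame(seq.grid, v1, v2, float(frames[0].time), ok)


def ensemble_average_flow(seqs: list) -> VelocitySequence:
    """Frame-wise arithmetic mean across rigidly aligned members."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 members for an ensemble average")
    n = min(len(s) for s in seqs)
    g = seqs[0].grid
    for s in seqs:
        if s.grid.shape != g.shape:
            raise ValueError("members must share a common grid")
        if abs(s.dt - seqs[0].dt) > 1e-9 or abs(s.times[0] - seqs[0].times[0]) > 1e-9:
            raise ValueError("members must be rigidly aligned to common frame times")
    frames = []
    for k in range(n):
        w = np.sum([s[k].valid for s in seqs], axis=0).astype(float)
        v1 = np.sum([np.where(s[k].valid, s[k].v1, 0.0) for s in seqs], axis=0)
        v2 = np.sum([np.where(s[k].valid, s[k].v2, 0.0) for s in seqs], axis=0)
        ok = w > 0
        v1 = np.where(ok, v1 / np.maximum(w, 1), np.nan)
        v2 = np.where(ok, v2 / np.maximum(w, 1), np.nan)
        frames.append(VelocityFrame(g, v1, v2, seqs[0][k].time, ok))
    return VelocitySequence(frames, seqs[0].dt)


def corr_to_ensemble(member, ensemble: VelocitySequence, measure="vorticity", **params) -> TimeSeries:
    """Correlation trace of one member's time-averaged flow to the ensemble.

    ``member`` may be a VelocityFrame (already averaged) or a
    VelocitySequence (time-averaged first).
    """
    from .similarity import _MEASURES

    frame = member if isinstance(member, VelocityFrame) else time_average_flow(member)
    fn = measure if callable(measure) else _MEASURES[measure]
    vals = []
    for f in ensemble:
        try:
            vals.append(fn(frame, f, **params))
        except Exception:
            vals.append(np.nan)
    return TimeSeries(ensemble.times, np.asarray(vals))
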