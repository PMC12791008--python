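"""Timeline registration: monotone warping, rigid offsets, consensus, timestamps.

A similarity matrix between two recordings is turned into a monotone
*correspondence curve* by a weighted shortest path that may only move
down/right (order preservation).  Multiple recordings are fused into a
consensus timeline; static samples are then placed on that timeline with a
1-σ uncertainty obtained from the curvature of a χ² profile.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    AmbiguousLandmarkError,
    BoundaryTimestampWarning,
    CannotFuseError,
    DegenerateOverlapError,
    NoPathError,
    TieWarning,
    UncertaintyUndefinedError,
)
from .grids import SpeedCurve
from .similarity import SimilarityMatrix

__all__ = [
    "CorrespondenceCurve",
    "LandmarkTime",
    "ConsensusTimeline",
    "Timestamp",
    "select_endpoints",
    "monotone_shortest_path",
    "pairwise_align",
    "rigid_offset",
    "onset_from_acceleration",
    "consensus_timeline",
    "timestamp_from_chi2",
    "timestamp_fixed",
]

_TIE_TOL = 1e-12


@dataclass
class CorrespondenceCurve:
    """Monotone map between two time axes: ``t_b = s(t_a)``.

    ``t_a`` is strictly increasing, ``t_b`` nondecreasing; the map is
    defined on the overlap of the two recordings only.
    """

    t_a: np.ndarray
    t_b: np.ndarray
    mean_similarity: float | None = None

    def __post_init__(self) -> None:
        self.t_a = np.asarray(self.t_a, dtype=float)
        self.t_b = np.asarray(self.t_b, dtype=float)
        if self.t_a.shape != self.t_b.shape or self.t_a.ndim != 1 or len(self.t_a) < 2:
            raise ValueError("need two equal-length 1D sample arrays (≥ 2 points)")
        if np.any(np.diff(self.t_a) <= 0):
            raise ValueError("t_a must be strictly increasing")
        if np.any(np.diff(self.t_b) < -1e-9):
            raise ValueError("t_b must be nondecreasing")

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.t_a[0]), float(self.t_a[-1])

    def __call__(self, t) -> np.ndarray:
        return np.interp(t, self.t_a, self.t_b)

    def inverse(self, t) -> np.ndarray:
        """Inverse map (pseudo-inverse across flat stretches)."""
        return np.interp(t, self.t_b, self.t_a)

    def compose(self, other: "CorrespondenceCurve") -> "CorrespondenceCurve":
        """Return the map t ↦ other(self(t)) on the composable overlap."""
        lo, hi = other.domain
        keep = (self.t_b >= lo - 1e-9) & (self.t_b <= hi + 1e-9)
        if keep.sum() < 2:
            raise CannotFuseError("maps have no composable overlap")
        ta = self.t_a[keep]
        tb = other(self.t_b[keep])
        sims = [s for s in (self.mean_similarity, other.mean_similarity) if s is not None]
        return CorrespondenceCurve(ta, np.maximum.accumulate(tb), float(np.mean(sims)) if sims else None)


@dataclass
class LandmarkTime:
    """A landmark event time used for rigid timeline alignment."""

    t0: float
    method: str  # vorticity_flip | max_acceleration | furrow_onset_manual


@dataclass
class ConsensusTimeline:
    """Per-member monotone maps (member time → consensus time)."""

    member_ids: list
    maps: dict  # id -> CorrespondenceCurve
    dt: float
    medoid_id: object = None

    def __post_init__(self) -> None:
        missing = [i for i in self.member_ids if i not in self.maps]
        if missing:
            raise ValueError(f"missing maps for members {missing}")


@dataclass
class Timestamp:
    """Placement of a static sample on a timeline, with 1-σ uncertainty."""

    t0: float
    sigma_t: float
    chi2_times: np.ndarray = field(default=None, repr=False)
    chi2_values: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.sigma_t > 0:
            raise ValueError("sigma_t must be positive")


# ---------------------------------------------------------------------------
# endpoint selection and monotone shortest path
# ---------------------------------------------------------------------------


def select_endpoints(m: SimilarityMatrix) -> tuple[tuple[int, int], tuple[int, int]]:
    """Pick start/end cells for the correspondence curve on the matrix edges.

    Start is the maximal cell on the top or left edge (ties broken toward
    (0, 0)); end is the maximal cell on the bottom or right edge (ties
    toward the last cell).  The start must be strictly up-left of the end.
    """
    v = m.values
    nr, nc = v.shape
    if nr < 2 or nc < 2:
        raise DegenerateOverlapError("matrix must be at least 2x2")

    start_cells = [(0, j) for j in range(nc)] + [(i, 0) for i in range(1, nr)]
    start_cells.sort(key=lambda rc: (rc[0] + rc[1], rc[0]))
    end_cells = [(nr - 1, j) for j in range(nc)] + [(i, nc - 1) for i in range(nr - 1)]
    end_cells.sort(key=lambda rc: (-(rc[0] + rc[1]), -rc[0]))

    def best(cells):
        vals = [v[r, c] for r, c in cells]
        finite = [x for x in vals if np.isfinite(x)]
        if not finite:
            raise DegenerateOverlapError("no finite similarity on the edge")
        top = max(finite)
        for (r, c), x in zip(cells, vals):
            if np.isfinite(x) and x >= top - _TIE_TOL:
                return (r, c)

    start = best(start_cells)
    end = best(end_cells)
    if not (start[0] < end[0] and start[1] < end[1]):
        raise DegenerateOverlapError(
            f"start {start} is not strictly up-left of end {end}: recordings do not overlap"
        )
    return start, end


def _fill_missing(v: np.ndarray) -> np.ndarray:
    """Replace NaN entries by the nearest finite entry (path search only)."""
    bad = ~np.isfinite(v)
    if not bad.any():
        return v
    if bad.all():
        raise NoPathError("similarity matrix has no finite entries")
    idx = ndimage.distance_transform_edt(bad, return_distances=False, return_indices=True)
    return v[tuple(idx)]


def _weights(v: np.ndarray) -> np.ndarray:
    """Similarity → traversal weight 1/(ρ − ρ_min + ε), ε = 0.05·range."""
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.ones_like(v)
    eps = 0.05 * (hi - lo)
    return 1.0 / (v - lo + eps)


_SQRT2 = float(np.sqrt(2.0))
# predecessor moves in preference order: diagonal first (ties bias toward
# unit developmental-rate ratio), then down, then right
_MOVES = ((1, 1, _SQRT2), (1, 0, 1.0), (0, 1, 1.0))


def monotone_shortest_path(
    m: SimilarityMatrix,
    start: tuple[int, int] | None = None,
    end: tuple[int, int] | None = None,
) -> CorrespondenceCurve:
    """Minimum-cost monotone lattice path through the similarity matrix.

    Moves are restricted to down, right and down-right, which makes the
    correspondence order preserving.  A step costs its Euclidean length
    times the mean of the two endpoint weights, where weight is the inverse
    of the (shifted-positive) similarity.  Missing entries are interpolated
    for the search only.
    """
    if start is None or end is None:
        s, e = select_endpoints(m)
        start = start or s
        end = end or e
    (r0, c0), (r1, c1) = start, end
    nr, nc = m.values.shape
    if not (0 <= r0 <= r1 < nr and 0 <= c0 <= c1 < nc):
        raise DegenerateOverlapError("endpoints outside matrix or out of order")
    if r1 == r0 or c1 == c0:
        raise DegenerateOverlapError("endpoints must differ in both row and column")

    w = _weights(_fill_missing(m.values))[r0 : r1 + 1, c0 : c1 + 1]
    if not np.isfinite(w).all():
        raise NoPathError("non-finite traversal weights")
    h, k = w.shape
    cost = np.full((h, k), np.inf)
    pred = np.full((h, k), -1, dtype=np.int8)
    cost[0, 0] = 0.0
    for i in range(h):
        for j in range(k):
            if i == 0 and j == 0:
                continue
            best_c, best_p = np.inf, -1
            for p, (di, dj, ln) in enumerate(_MOVES):
                pi, pj = i - di, j - dj
                if pi < 0 or pj < 0:
                    continue
                c = cost[pi, pj] + ln * 0.5 * (w[pi, pj] + w[i, j])
                if c < best_c - _TIE_TOL * max(1.0, abs(c)):
                    best_c, best_p = c, p
            cost[i, j] = best_c
            pred[i, j] = best_p
    if not np.isfinite(cost[-1, -1]):
        raise NoPathError("no finite-cost monotone path")

    cells = []
    i, j = h - 1, k - 1
    while True:
        cells.append((i + r0, j + c0))
        if i == 0 and j == 0:
            break
        di, dj, _ = _MOVES[pred[i, j]]
        i, j = i - di, j - dj
    cells.reverse()

    rows = sorted({r for r, _ in cells})
    ta, tb, sims = [], [], []
    for r in rows:
        js = [c for rr, c in cells if rr == r]
        ta.append(m.times_a[r])
        tb.append(float(np.mean(m.times_b[js])))
        sims.extend(m.values[r, c] for c in js)
    sims = [s for s in sims if np.isfinite(s)]
    mean_sim = float(np.mean(sims)) if sims else None
    return CorrespondenceCurve(np.asarray(ta), np.maximum.accumulate(tb), mean_sim)


def pairwise_align(m: SimilarityMatrix, override_endpoints=None) -> CorrespondenceCurve:
    """Endpoint selection followed by the monotone shortest path."""
    if override_endpoints is not None:
        r0, c0, r1, c1 = override_endpoints
        return monotone_shortest_path(m, (r0, c0), (r1, c1))
    return monotone_shortest_path(m)


# ---------------------------------------------------------------------------
# rigid landmarks
# ---------------------------------------------------------------------------


def rigid_offset(m_self: SimilarityMatrix, rel_tol: float = 1e-9) -> LandmarkTime:
    """Landmark time from the autocorrelation matrix of one recording.

    The landmark is ``t0 = argmax_x Σ_y ∂ₓM(x, y)``: the time at which the
    flow pattern flips (e.g. the vorticity sign change at the onset of axis
    elongation) produces the sharpest row-derivative of the matrix.
    """
    v = m_self.values
    if v.shape[0] != v.shape[1]:
        raise ValueError("rigid_offset requires a square autocorrelation matrix")
    d = np.nansum(v[1:] - v[:-1], axis=1)  # backward difference, indexed at x
    if not np.isfinite(d).any():
        raise AmbiguousLandmarkError("derivative profile is entirely missing")
    order = np.argsort(d)[::-1]
    top, second = d[order[0]], d[order[1]] if len(d) > 1 else -np.inf
    scale = max(1.0, float(np.nanmax(np.abs(d))))
    if not np.isfinite(top) or top - second <= rel_tol * scale:
        raise AmbiguousLandmarkError("landmark derivative maximum is not unique")
    return LandmarkTime(float(m_self.times_a[order[0] + 1]), "vorticity_flip")


def onset_from_acceleration(sc: SpeedCurve, smooth_sigma: float = 0.0) -> LandmarkTime:
    """Landmark at the maximum forward difference of the speed curve.

    Defines t = 0 at the onset of rapid flow (maximum acceleration).  The
    returned time is the midpoint of the maximizing frame interval; ties
    resolve to the earliest interval with a warning.
    """
    if len(sc.times) < 5:
        raise ValueError("need at least 5 frames")
    v = sc.values
    if smooth_sigma > 0:
        v = ndimage.gaussian_filter1d(v, smooth_sigma)
    d = np.diff(v)
    top = d.max()
    ties = np.flatnonzero(d >= top - 1e-12 * max(1.0, abs(top)))
    if len(ties) > 1:
        warnings.warn("acceleration maximum tied; using earliest interval", TieWarning)
    i = int(ties[0])
    t0 = 0.5 * (sc.times[i] + sc.times[i + 1])
    return LandmarkTime(float(t0), "max_acceleration")


# ---------------------------------------------------------------------------
# consensus timeline
# ---------------------------------------------------------------------------


def _curve_between(curves: dict, a, b) -> CorrespondenceCurve | None:
    if (a, b) in curves:
        return curves[(a, b)]
    if (b, a) in curves:
        c = curves[(b, a)]
        # invert: swap axes, enforcing strict monotonicity of the new t_a
        tb, ta = c.t_a, c.t_b
        keep = np.concatenate(([True], np.diff(tb) > 0))
        if keep.sum() < 2:
            return None
        return CorrespondenceCurve(tb[keep], ta[keep], c.mean_similarity)
    return None


def consensus_timeline(curves: dict, ids: list, dt: float | None = None) -> ConsensusTimeline:
    """Fuse pairwise correspondence curves into a single consensus timeline.

    The medoid member (largest mean similarity along its correspondence
    curves) seeds the consensus axis; every member is mapped into the
    medoid (composing through intermediates where no direct curve exists),
    and one refinement pass replaces the consensus with the pointwise
    average of all members' warped time axes, re-fit monotonically.
    """
    if not ids:
        raise ValueError("no member ids")
    # connectivity of the overlap graph
    adj = {i: set() for i in ids}
    for (a, b) in curves:
        if a in adj and b in adj:
            adj[a].add(b)
            adj[b].add(a)
    seen, queue = {ids[0]}, deque([ids[0]])
    while queue:
        for nb in adj[queue[0]]:
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
        queue.popleft()
    if seen != set(ids):
        raise CannotFuseError(f"overlap graph disconnected; unreachable members {set(ids) - seen}")

    # medoid: maximal mean similarity along its curves (overlap length fallback)
    def member_score(i):
        sims, spans = [], []
        for j in adj[i]:
            c = _curve_between(curves, i, j)
            if c is None:
                continue
            spans.append(c.domain[1] - c.domain[0])
            if c.mean_similarity is not None:
                sims.append(c.mean_similarity)
        if sims:
            return float(np.mean(sims))
        return float(np.mean(spans)) if spans else -np.inf

    medoid = max(ids, key=member_score)

    # map every member into the medoid, composing via BFS where needed
    to_medoid: dict = {}
    for i in ids:
        if i == medoid:
            continue
        direct = _curve_between(curves, i, medoid)
        if direct is not None:
            to_medoid[i] = direct
            continue
        # BFS path i -> medoid through available curves
        prev = {i: None}
        q = deque([i])
        while q and medoid not in prev:
            u = q.popleft()
            for nb in adj[u]:
                if nb not in prev:
                    prev[nb] = u
                    q.append(nb)
        if medoid not in prev:
            raise CannotFuseError(f"no correspondence chain from {i} to medoid {medoid}")
        chain = [medoid]
        while chain[-1] != i:
            chain.append(prev[chain[-1]])
        chain.reverse()  # i ... medoid
        cur = _curve_between(curves, chain[0], chain[1])
        for a, b in zip(chain[1:-1], chain[2:]):
            nxt = _curve_between(curves, a, b)
            if cur is None or nxt is None:
                raise CannotFuseError(f"broken correspondence chain at ({a}, {b})")
            cur = cur.compose(nxt)
        to_medoid[i] = cur

    # consensus support = medoid times covered by every member
    lo = max(c.t_b.min() for c in to_medoid.values()) if to_medoid else -np.inf
    hi = min(c.t_b.max() for c in to_medoid.values()) if to_medoid else np.inf
    all_tm = np.unique(np.concatenate([c.t_b for c in to_medoid.values()])) if to_medoid else None
    if all_tm is None:  # single member
        only = ids[0]
        grid = np.array([0.0, 1.0])
        return ConsensusTimeline([only], {only: CorrespondenceCurve(grid, grid)}, dt or 1.0, only)
    if dt is None:
        steps = np.diff(all_tm)
        dt = float(np.median(steps[steps > 0])) if np.any(steps > 0) else 1.0
    if hi - lo < dt:
        raise CannotFuseError("common overlap on the medoid axis is empty")
    grid = np.arange(lo, hi + 0.5 * dt, dt)

    # refinement: consensus coordinate = average of members' warped axes
    warped = [grid]  # medoid maps to itself
    for c in to_medoid.values():
        # s_{medoid -> i} evaluated on the grid, then back onto a common
        # scale via the member's own clock; averaging the images of the
        # medoid axis under all cross-member warps removes medoid
        # idiosyncrasy while preserving monotonicity
        s_m_to_i = np.interp(grid, c.t_b, c.t_a)
        warped.append(s_m_to_i)
    chat = np.maximum.accumulate(np.mean(warped, axis=0))

    maps: dict = {}
    cons_of_medoid = CorrespondenceCurve(grid, chat)
    maps[medoid] = cons_of_medoid
    for i, c in to_medoid.items():
        keep = (c.t_b >= lo - 1e-9) & (c.t_b <= hi + 1e-9)
        if keep.sum() < 2:
            raise CannotFuseError(f"member {i} does not cover the common overlap")
        ta = c.t_a[keep]
        tb = cons_of_medoid(c.t_b[keep])
        strict = np.concatenate(([True], np.diff(ta) > 0))
        maps[i] = CorrespondenceCurve(
            ta[strict], np.maximum.accumulate(tb[strict]), c.mean_similarity
        )
    return ConsensusTimeline(list(ids), maps, dt, medoid)


# ---------------------------------------------------------------------------
# timestamping with uncertainty
# ---------------------------------------------------------------------------


def timestamp_from_chi2(times, chi2, window: int = 5) -> Timestamp:
    """Timestamp from a χ²(t) profile: σ_t² = 2 / (∂²χ²/∂t²) at the minimum.

    A parabola is fit to χ² on ±``window`` frames around the discrete
    minimum; ``t0`` is the parabola vertex and ``sigma_t`` follows from the
    fitted curvature.
    """
    times = np.asarray(times, dtype=float)
    chi2 = np.asarray(chi2, dtype=float)
    if times.shape != chi2.shape or len(times) < 3:
        raise ValueError("need equal-length arrays with at least 3 samples")
    idx = int(np.nanargmin(chi2))
    if idx in (0, len(times) - 1):
        warnings.warn(
            "chi-squared minimum on the timeline boundary; timestamp unreliable",
            BoundaryTimestampWarning,
        )
    lo, hi = max(0, idx - window), min(len(times), idx + window + 1)
    tt, cc = times[lo:hi], chi2[lo:hi]
    ok = np.isfinite(cc)
    if ok.sum() < 3:
        raise UncertaintyUndefinedError("fewer than 3 finite chi-squared samples in window")
    a, b, c = np.polyfit(tt[ok] - times[idx], cc[ok], 2)
    if a <= 0:
        raise UncertaintyUndefinedError("non-convex parabola fit; curvature not positive")
    t0 = float(times[idx] - b / (2 * a))
    t0 = float(np.clip(t0, tt[0], tt[-1]))
    sigma = float(np.sqrt(1.0 / a))  # sigma^2 = 2 / (2a)
    return Timestamp(t0, sigma, times, chi2)


def timestamp_fixed(
    sample_feature,
    timeline_features,
    times=None,
    window: int = 5,
    normalize: bool = True,
    n_members: int | None = None,
) -> Timestamp:
    """Place a static sample on a timeline by χ² minimization.

    ``sample_feature`` and each entry of ``timeline_features`` are arrays
    (or FieldFrames) of a comparable morphological feature, e.g. rasterized
    stripe-boundary band images.  χ²(t) is the sum of squared residuals over
    jointly valid entries; when ``normalize`` is true it is expressed in
    units of the noise variance estimated from the best-matching frame, so
    that the curvature-based σ_t is calibrated.
    """
    if n_members is not None and n_members < 3:
        raise ValueError("a timeline requires a minimum of three live members")

    def as_arr(x):
        vals = getattr(x, "values", x)
        valid = getattr(x, "valid", None)
        return np.asarray(vals, dtype=float), valid

    s, s_valid = as_arr(sample_feature)
    tlist = [as_arr(f) for f in timeline_features]
    if times is None:
        times = [getattr(f, "time", k) for k, f in enumerate(timeline_features)]
    times = np.asarray(times, dtype=float)
    ssr = np.empty(len(tlist))
    npix = np.empty(len(tlist))
    for k, (f, f_valid) in enumerate(tlist):
        ok = np.isfinite(s) & np.isfinite(f)
        if s_valid is not None:
            ok &= s_valid
        if f_valid is not None:
            ok &= f_valid
        r = s[ok] - f[ok]
        ssr[k] = float(r @ r)
        npix[k] = ok.sum()
    if normalize:
        kmin = int(np.argmin(ssr))
        dof = max(npix[kmin] - 1.0, 1.0)
        sigma2 = max(ssr[kmin] / dof, 1e-300)
        chi2 = ssr / sigma2
    else:
        chi2 = ssr
    return timestamp_from_chi2(times, chi2, window)
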