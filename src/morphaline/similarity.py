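"""Frame-to-frame similarity measures and rectangular similarity matrices.

All measures return values in [−1, 1]; undefined comparisons (constant
inputs, no valid nodes) raise :class:`UndefinedCorrelationError` at the
frame level and are stored as NaN ("missing") inside matrices — never as a
silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedCorrelationError
from .grids import (
    FieldFrame,
    GridSpec,
    StripeCurve,
    VelocityFrame,
    rasterize_curve,
    vorticity,
)

__all__ = [
    "SimilarityMatrix",
    "pearson_image",
    "corr_vorticity",
    "corr_angle",
    "curve_similarity",
    "similarity_matrix",
]

DEFAULT_SPEED_FLOOR = 0.1  # μm/min


@dataclass
class SimilarityMatrix:
    """Pairwise frame-similarity values between two timelines.

    ``values[i, j]`` compares frame ``i`` of recording A (time
    ``times_a[i]``) with frame ``j`` of recording B.  Missing entries are
    NaN.
    """

    values: np.ndarray
    times_a: np.ndarray
    times_b: np.ndarray
    measure_id: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_a = np.asarray(self.times_a, dtype=float)
        self.times_b = np.asarray(self.times_b, dtype=float)
        if self.values.shape != (len(self.times_a), len(self.times_b)):
            raise ValueError("matrix shape must be (len(times_a), len(times_b))")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlation values must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = float(np.sqrt(a @ a))
    nb = float(np.sqrt(b @ b))
    if na == 0 or nb == 0:
        raise UndefinedCorrelationError("Pearson correlation of a constant field is undefined")
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))


def pearson_image(a: FieldFrame, b: FieldFrame) -> float:
    """Pearson correlation of two scalar frames over jointly valid nodes."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("frames must share a grid")
    ok = a.valid & b.valid
    if not ok.any():
        raise UndefinedCorrelationError("no jointly valid nodes")
    return _pearson(a.values[ok].ravel(), b.values[ok].ravel())


def corr_vorticity(u: VelocityFrame, w: VelocityFrame) -> float:
    """Pearson correlation of the two vorticity fields.

    Magnitude-invariant: rescaling either field by c > 0 leaves the value
    unchanged.
    """
    return pearson_image(vorticity(u), vorticity(w))


def corr_angle(u: VelocityFrame, w: VelocityFrame, floor: float = DEFAULT_SPEED_FLOOR) -> float:
    """Mean cosine of the angle between the two fields, node by node.

    Nodes where either speed is ≤ ``floor`` (μm/min) are excluded, so the
    measure is insensitive to noise-dominated near-zero vectors.
    """
    if u.grid.shape != w.grid.shape:
        raise ValueError("frames must share a grid")
    su, sw = u.speed(), w.speed()
    ok = u.valid & w.valid & (su > floor) & (sw > floor)
    if not ok.any():
        raise UndefinedCorrelationError("no node passes the speed floor")
    dot = u.v1[ok] * w.v1[ok] + u.v2[ok] * w.v2[ok]
    cos = dot / (su[ok] * sw[ok])
    return float(np.clip(np.mean(cos), -1.0, 1.0))


def curve_similarity(
    c1: StripeCurve, c2: StripeCurve, spec: GridSpec, bandwidth: float
) -> float:
    """Pearson correlation of the Gaussian-band rasterizations of two curves."""
    r1 = rasterize_curve(c1, spec, bandwidth)
    r2 = rasterize_curve(c2, spec, bandwidth)
    return pearson_image(r1, r2)


_MEASURES = {
    "pearson": pearson_image,
    "vorticity": corr_vorticity,
    "angle": corr_angle,
}


def similarity_matrix(seq_a, seq_b, measure="pearson", **measure_params) -> SimilarityMatrix:
    """Assemble the rectangular similarity matrix between two sequences.

    ``measure`` is a name from {'pearson', 'vorticity', 'angle'} or any
    callable ``f(frame_a, frame_b, **params) -> float``.  Undefined pairs
    are flagged missing (NaN).
    """
    if callable(measure):
        fn, mid = measure, getattr(measure, "__name__", "custom")
    else:
        try:
            fn, mid = _MEASURES[measure], measure
        except KeyError:
            raise ValueError(f"unknown measure {measure!r}") from None
    if len(seq_a) == 0 or len(seq_b) == 0:
        raise ValueError("sequences must be nonempty")
    same = seq_a is seq_b
    m = np.full((len(seq_a), len(seq_b)), np.nan)
    for i, fa in enumerate(seq_a):
        for j, fb in enumerate(seq_b):
            if same and j < i:
                m[i, j] = m[j, i]
                continue
            try:
                m[i, j] = fn(fa, fb, **measure_params)
            except UndefinedCorrelationError:
                pass
    return SimilarityMatrix(m, seq_a.times, seq_b.times, mid, dict(measure_params))
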