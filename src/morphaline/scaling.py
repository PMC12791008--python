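"""Temperature rescaling of kinematics and pattern-decorrelation timescales.

Speed curves from different temperature conditions are collapsed by
``v -> v / max(v)`` and ``t -> t * max(v)`` (rescaled speed is
dimensionless; rescaled time has distance units).  Displacement fields are
compared against in-condition variance (Welch t per seed, BH across seeds).
Mitotic-clock ratios and the pair-rule-pattern decorrelation timescales
t_obs / t_est round out the analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import FitError
from .grids import SpeedCurve
from .kinematics import DisplacementField

__all__ = [
    "DECORRELATION_THRESHOLD",
    "MitoticEventTable",
    "DecorrelationEstimate",
    "rescale_collapse",
    "curve_family_residual",
    "scaled_endpoint",
    "compare_displacements",
    "mitotic_ratio",
    "speed_ratio",
    "decorrelation_timescale_obs",
    "stripe_width",
    "decorrelation_timescale_est",
    "shift_fraction_c",
]

#: correlation level below which two pattern snapshots count as decorrelated
#: (a Gaussian at one s.d. relative to its peak, e^{-1/2} ≈ 0.61)
DECORRELATION_THRESHOLD = math.exp(-0.5)

MITOTIC_DOMAINS = (1, 2, 5, 6, 11)


@dataclass
class MitoticEventTable:
    """Onset times of mitotic events per domain and embryo side."""

    table: pd.DataFrame  # columns: domain, side, onset_min, condition

    def __post_init__(self) -> None:
        required = {"domain", "side", "onset_min"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"table needs columns {sorted(required)}")
        if not np.isfinite(self.table["onset_min"]).all():
            raise ValueError("onset times must be finite")

    @classmethod
    def from_csv(cls, path) -> "MitoticEventTable":
        return cls(pd.read_csv(path))

    def domain_time(self, domain: int) -> float:
        rows = self.table[self.table["domain"] == domain]
        if rows.empty:
            raise KeyError(f"no events recorded for domain {domain}")
        return float(rows["onset_min"].mean())


@dataclass
class DecorrelationEstimate:
    """Decorrelation timescale bundle: observed and estimated (minutes)."""

    t_obs: float | None
    t_est: float | None
    c: float
    w_est: float
    v_est: float
    threshold: float = DECORRELATION_THRESHOLD

    def __post_init__(self) -> None:
        for name in ("c", "w_est", "v_est"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# temperature collapse
# ---------------------------------------------------------------------------


def curve_family_residual(curves: list[SpeedCurve]) -> float:
    """R.m.s. pairwise difference between curves on their common support."""
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    lo = max(c.times.min() for c in curves)
    hi = min(c.times.max() for c in curves)
    if hi <= lo:
        raise ValueError("curves have no common support")
    grid = np.linspace(lo, hi, 200)
    vals = np.stack([np.interp(grid, c.times, c.values) for c in curves])
    diffs = []
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            diffs.append(np.mean((vals[i] - vals[j]) ** 2))
    return float(np.sqrt(np.mean(diffs)))


def rescale_collapse(curves: list[SpeedCurve]) -> tuple[list[SpeedCurve], float]:
    """Collapse speed curves by v → v/max(v), t → t·max(v).

    Curves must already be rigidly aligned to their own onset (t = 0).
    Returns the rescaled curves and the post-collapse residual (r.m.s.
    pairwise difference of the rescaled curves on their common support).
    """
    rescaled = []
    for c in curves:
        vmax = float(c.values.max())
        if vmax <= 0:
            raise ValueError("curve has max speed 0; cannot rescale")
        rescaled.append(SpeedCurve(c.times * vmax, c.values / vmax))
    return rescaled, curve_family_residual(rescaled)


def scaled_endpoint(t1_ref: float, vmax_ref: float, vmax_t: float) -> float:
    """Temperature-rescaled integration endpoint t1(T) = t1_ref · vmax_ref / vmax_T."""
    if t1_ref <= 0 or vmax_ref <= 0 or vmax_t <= 0:
        raise ValueError("all inputs must be positive")
    return t1_ref * vmax_ref / vmax_t


# ---------------------------------------------------------------------------
# displacement-field comparison across conditions
# ---------------------------------------------------------------------------


def compare_displacements(
    cond_a: list[DisplacementField],
    cond_b: list[DisplacementField],
    alpha: float = 0.05,
):
    """Test whether two conditions' displacement fields differ beyond
    in-condition variance.

    Per seed: Welch two-sample t-test between the replicate displacement
    values of the two conditions; Benjamini–Hochberg FDR across seeds.
    Returns (significant_mask, summary_fraction, pvalues); seeds with no
    jointly valid replicates are excluded from the summary.
    """
    if len(cond_a) < 3 or len(cond_b) < 3:
        raise ValueError("need at least 3 replicates per condition")
    da = np.stack([f.delta for f in cond_a])
    db = np.stack([f.delta for f in cond_b])
    va = np.stack([f.valid for f in cond_a]).all(axis=0)
    vb = np.stack([f.valid for f in cond_b]).all(axis=0)
    usable = va & vb
    n_seed = da.shape[1]
    pvals = np.full(n_seed, np.nan)
    for s in np.flatnonzero(usable):
        xa, xb = da[:, s], db[:, s]
        if np.ptp(xa) == 0 and np.ptp(xb) == 0:
            pvals[s] = 1.0 if xa[0] == xb[0] else 0.0
            continue
        pvals[s] = stats.ttest_ind(xa, xb, equal_var=False).pvalue
    ok = np.isfinite(pvals)
    sig = np.zeros(n_seed, dtype=bool)
    if ok.any():
        rej, _, _, _ = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")
        sig[np.flatnonzero(ok)] = rej
    frac = float(sig[ok].mean()) if ok.any() else 0.0
    return sig, frac, pvals


# ---------------------------------------------------------------------------
# mitotic-clock ratios
# ---------------------------------------------------------------------------


def mitotic_ratio(
    cold: MitoticEventTable,
    hot: MitoticEventTable,
    reference: str = "onset",
    domains=MITOTIC_DOMAINS,
):
    """Ratio of division-time differences between two conditions.

    ``reference='onset'``: per domain, the ratio of mean onset times (each
    measured from the condition's stated reference, e.g. the
    acceleration-based t = 0).  ``reference='pairwise'``: per domain pair,
    the ratio of inter-domain onset differences δt.  Returns
    (ratios, mean, sem); domains missing from either table are skipped with
    a warning.
    """
    if reference not in ("onset", "pairwise"):
        raise ValueError("reference must be 'onset' or 'pairwise'")
    usable = []
    for d in domains:
        try:
            usable.append((d, cold.domain_time(d), hot.domain_time(d)))
        except KeyError:
            warnings.warn(f"domain {d} missing from one condition; skipped")
    if reference == "onset":
        ratios = np.array([tc / th for _, tc, th in usable if th != 0])
    else:
        ratios = []
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                dc = usable[j][1] - usable[i][1]
                dh = usable[j][2] - usable[i][2]
                if dh != 0:
                    ratios.append(dc / dh)
        ratios = np.asarray(ratios)
    if ratios.size == 0:
        raise ValueError("no usable domain ratios")
    mean = float(ratios.mean())
    if ratios.size < 2:
        raise ValueError("no-sem: need at least 2 usable ratios for the s.e.m.")
    sem = float(ratios.std(ddof=1) / math.sqrt(ratios.size))
    return ratios, mean, sem


def speed_ratio(sc_num: SpeedCurve, sc_den: SpeedCurve) -> float:
    """Ratio of the two curves' maximum r.m.s. speeds."""
    num, den = float(sc_num.values.max()), float(sc_den.values.max())
    if den <= 0:
        raise ValueError("denominator curve has max speed 0")
    return num / den


def welch_ratio_test(sample_a, sample_b):
    """Welch t-test between two ratio samples (e.g. mitotic vs flow-speed)."""
    res = stats.ttest_ind(np.asarray(sample_a), np.asarray(sample_b), equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# pattern-decorrelation timescales
# ---------------------------------------------------------------------------


def _gauss1(x, a, mu, s):
    return a * np.exp(-((x - mu) ** 2) / (2 * s**2))


def _gauss2(x, a1, s1, a2, s2, mu):
    return _gauss1(x, a1, mu, s1) + _gauss1(x, a2, mu, s2)


def decorrelation_timescale_obs(lags, corr, min_sigma_ratio: float = 1.2):
    """Observed decorrelation timescale from a correlation-vs-lag curve.

    Fits a two-term sum of Gaussians (shared centre) and returns the
    smaller fitted s.d. with a 95% CI from the fit covariance.  Falls back
    to a single Gaussian (with a warning) when the two-term fit does not
    converge or is degenerate (s.d. ratio < ``min_sigma_ratio``).
    """
    x = np.asarray(lags, dtype=float)
    y = np.asarray(corr, dtype=float)
    if np.ptp(y) < 1e-12:
        raise FitError("flat correlation curve; no peak to fit")
    mu0 = float(x[np.argmax(y)])
    amp0 = float(y.max())
    span = float(np.ptp(x)) or 1.0
    try:
        p, cov = optimize.curve_fit(
            _gauss2,
            x,
            y,
            p0=[0.6 * amp0, 0.1 * span, 0.4 * amp0, 0.4 * span, mu0],
            maxfev=20000,
        )
        s1, s2 = abs(p[1]), abs(p[3])
        a1, a2 = abs(p[0]), abs(p[2])
        if min(a1, a2) < 0.05 * max(a1, a2) or min(s1, s2) < 1e-6 * span:
            raise RuntimeError("one component vanishes: effectively single-Gaussian")
        if max(s1, s2) / max(min(s1, s2), 1e-12) < min_sigma_ratio:
            raise RuntimeError("degenerate two-term fit")
        k = 1 if s1 <= s2 else 3
        t_obs = min(s1, s2)
        se = math.sqrt(abs(cov[k, k]))
        return float(t_obs), (float(t_obs - 1.96 * se), float(t_obs + 1.96 * se))
    except (RuntimeError, optimize.OptimizeWarning):
        warnings.warn("two-term Gaussian fit degenerate; falling back to single Gaussian")
    try:
        p, cov = optimize.curve_fit(
            _gauss1, x, y, p0=[amp0, mu0, 0.2 * span], maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError("Gaussian fit did not converge") from exc
    s = abs(float(p[2]))
    se = math.sqrt(abs(cov[2, 2]))
    return s, (s - 1.96 * se, s + 1.96 * se)


def stripe_width(positions, intensities) -> float:
    """Stripe width = twice the intensity-weighted positional s.d. (μm)."""
    x = np.asarray(positions, dtype=float)
    w = np.asarray(intensities, dtype=float)
    if np.any(w < 0):
        raise ValueError("intensities must be nonnegative")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("zero total intensity")
    mu = float((x * w).sum() / tot)
    var = float(((x - mu) ** 2 * w).sum() / tot)
    return 2.0 * math.sqrt(var)


def decorrelation_timescale_est(c: float, w_est: float, v_est: float) -> float:
    """Estimated decorrelation time t_est = c · w_est / v_est (minutes)."""
    if c <= 0 or w_est <= 0 or v_est <= 0:
        raise ValueError("all inputs must be positive")
    return c * w_est / v_est


def shift_fraction_c(
    threshold: float = DECORRELATION_THRESHOLD, measure: str = "pearson"
) -> float:
    """Shift fraction c = Δx/λ at which shifted cos² patterns hit a
    correlation threshold.

    For the Pearson measure the correlation of cos² with its shift is
    ``cos(2πc)`` in closed form; for the uncentered overlap it is
    ``(2 + cos(2πc)) / 3`` (reachable only for thresholds ≥ 1/3).
    """
    if measure == "pearson":
        if not (-1 < threshold < 1):
            raise ValueError("Pearson threshold must be in (-1, 1)")
        return float(np.arccos(threshold) / (2 * np.pi))
    if measure == "uncentered":
        arg = 3 * threshold - 2
        if not (-1 <= arg <= 1):
            raise ValueError("threshold unreachable by the uncentered overlap of cos²")
        return float(np.arccos(arg) / (2 * np.pi))
    raise ValueError("measure must be 'pearson' or 'uncentered'")
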