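"""Conformational-lock counting from residual-activity kinetics.

For a dimeric enzyme dissociating thermally through a chain of still-active
intermediate dimer forms, the minimal number of distinct active forms n is
estimated from the shape of the residual-activity-vs-time curve through the
empirical relations

    n = (0.13 + delta) / (0.13 - 0.05 * delta),      0 <= delta < 2.6
    delta = R - 1

where R is a dimensionless ratio read off the kinetic plot.  The literature
does not pin down R operationally; this module adopts the convention

    R = (total activity loss) / (activity loss of the first resolved step)

from a plateau decomposition of the curve.  Under it a single-step
(single-exponential) decay gives R = 1, hence delta = 0 and n = 1, the
simple two-state dissociation limit; a decay pausing at intermediate
plateaus gives R > 1.  The true number of intermediates m is only bounded
below by n and is not itself estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticCurve",
    "LockCountEstimate",
    "EstimateRConfig",
    "DomainError",
    "DELTA_MAX",
    "n_from_delta",
    "delta_from_R",
    "estimate_R",
    "lock_count",
]

DELTA_MAX = 0.13 / 0.05  # 2.6: the pole of the lock-count formula


class DomainError(ValueError):
    pass


@dataclass
class KineticCurve:
    """Residual activity (fraction of initial) versus time."""

    times: np.ndarray
    residual_activity: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.residual_activity = np.asarray(self.residual_activity, dtype=float)
        if self.times.shape != self.residual_activity.shape or self.times.size < 3:
            raise ValueError("times and activity must match with length >= 3")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        a = self.residual_activity
        if a.min() < -0.05 or a.max() > 1.05:
            raise ValueError("activity must lie in [0, 1.05] "
                             "(small experimental overshoot tolerated)")

    @classmethod
    def from_csv(cls, path) -> "KineticCurve":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "time" not in cols or "activity" not in cols:
            raise ValueError("kinetic CSV needs columns 'time' and 'activity'")
        return cls(df[cols["time"]].to_numpy(), df[cols["activity"]].to_numpy())


@dataclass
class LockCountEstimate:
    R: float
    delta: float
    n: float | None
    n_rounded: int | None
    valid: bool
    R_se: float | None = None
    n_ci: tuple[float, float] | None = None
    diagnostic: str = ""


@dataclass
class EstimateRConfig:
    smooth_frac: float = 0.04     # smoothing window as fraction of n points
    slope_frac: float = 0.10      # plateau when |slope| < slope_frac * max|slope|
    min_plateau_frac: float = 0.05  # minimum plateau duration, fraction of span
    min_step_frac: float = 0.05   # drop steps smaller than this fraction of range
    n_bootstrap: int = 199
    seed: int = 0


def n_from_delta(delta: float) -> float:
    """Minimal number of active dimer forms from the kinetic shape parameter.

    Strictly increasing on [0, 2.6) with n(0) = 1; diverges at delta = 2.6.
    """
    if delta < 0:
        raise DomainError(f"delta must be >= 0, got {delta}")
    if delta >= DELTA_MAX:
        raise DomainError(f"delta must be < {DELTA_MAX} (formula pole), got {delta}")
    return (0.13 + delta) / (0.13 - 0.05 * delta)


def delta_from_R(R: float) -> float:
    """delta = R - 1; R below 1 has no meaning in this scheme."""
    if R < 1:
        raise DomainError(f"R must be >= 1, got {R}")
    return R - 1.0


def _smooth(y: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return y
    k = np.ones(n) / n
    return np.convolve(y, k, mode="same") / np.convolve(np.ones_like(y), k, mode="same")


def _estimate_R_once(t: np.ndarray, a: np.ndarray, cfg: EstimateRConfig) -> float:
    n_smooth = max(1, int(round(cfg.smooth_frac * t.size)))
    s = _smooth(a, n_smooth)
    a0, a_end = float(s[0]), float(s[-1])
    rng = a0 - a_end
    slope = np.gradient(s, t)
    thresh = cfg.slope_frac * float(np.max(np.abs(slope)))
    plateau = np.abs(slope) < thresh
    min_len = cfg.min_plateau_frac * (t[-1] - t[0])
    levels: list[float] = []
    i = 0
    while i < t.size:
        if plateau[i]:
            j = i
            while j + 1 < t.size and plateau[j + 1]:
                j += 1
            if t[j] - t[i] >= min_len:
                # level at the flattest point of the run: for smooth staircase
                # decays this sits past the transition tails, so noiseless
                # curves give the exact plateau value
                k = i + int(np.argmin(np.abs(slope[i:j + 1])))
                levels.append(float(s[k]))
            i = j + 1
        else:
            i += 1
    # intermediate plateaus: clearly inside the (a_end, a0) range
    margin = cfg.min_step_frac * rng
    inter = [L for L in levels if a_end + margin < L < a0 - margin]
    # merge near-duplicates
    merged: list[float] = []
    for L in inter:
        if not merged or abs(L - merged[-1]) > margin:
            merged.append(L)
    if not merged:
        return 1.0
    first_level = merged[0]
    return rng / (a0 - first_level)


def estimate_R(curve: KineticCurve, config: EstimateRConfig | None = None) -> tuple[float, float]:
    """Estimate the kinetic ratio R with a bootstrap standard error.

    The curve is smoothed, plateaus are located where the local slope falls
    below ``slope_frac`` of the maximum decay slope for at least
    ``min_plateau_frac`` of the time span, and R = total loss over
    first-step loss; with no intermediate plateau the decay is single-step
    and R = 1.  The SE comes from residual resampling.
    """
    cfg = config or EstimateRConfig()
    t, a = curve.times, curve.residual_activity
    if a[-1] > a[0]:
        raise ValueError("activity increases over the curve; not a decay")
    if a[0] - a[-1] < 0.2:
        raise ValueError("activity dynamic range below 0.2; cannot resolve steps")
    R = _estimate_R_once(t, a, cfg)
    # residual bootstrap around the smoothed curve
    n_smooth = max(1, int(round(cfg.smooth_frac * t.size)))
    s = _smooth(a, n_smooth)
    resid = a - s
    rng_ = np.random.default_rng(cfg.seed)
    boots = []
    for _ in range(cfg.n_bootstrap):
        a_star = np.clip(s + rng_.choice(resid, size=resid.size, replace=True), -0.05, 1.05)
        try:
            boots.append(_estimate_R_once(t, a_star, cfg))
        except Exception:
            continue
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else 0.0
    return R, se


def lock_count(curve: KineticCurve, config: EstimateRConfig | None = None) -> LockCountEstimate:
    """Full chain: curve -> R -> delta -> n, with propagated uncertainty.

    ``n`` is reported both as the real-valued formula output and as an
    integer ceiling (``n_rounded``), since a count of forms is meant.
    ``valid`` is False when delta leaves the formula's domain [0, 2.6).
    """
    cfg = config or EstimateRConfig()
    R, se = estimate_R(curve, cfg)
    delta = delta_from_R(max(R, 1.0))
    if delta >= DELTA_MAX:
        return LockCountEstimate(R=R, delta=delta, n=None, n_rounded=None,
                                 valid=False, R_se=se,
                                 diagnostic=f"delta={delta:.3g} at/beyond the "
                                            f"formula pole {DELTA_MAX}")
    n = n_from_delta(delta)
    ci = None
    if se > 0:
        lo, hi = max(1.0, R - 1.96 * se), R + 1.96 * se
        try:
            n_lo = n_from_delta(delta_from_R(lo))
            n_hi = (n_from_delta(delta_from_R(hi))
                    if hi - 1 < DELTA_MAX else float("inf"))
            ci = (n_lo, n_hi)
        except DomainError:
            ci = None
    return LockCountEstimate(R=R, delta=delta, n=n, n_rounded=int(np.ceil(n)),
                             valid=True, R_se=se, n_ci=ci)
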