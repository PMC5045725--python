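"""Guinier fitting and the peak-forming transforms of the Guinier region.

The central identity: for I(q) = I0 exp(-q^2 Rg^2 / 3), the curve
q I(q) vs q^2 has its maximum at q^2 = 1.5 / Rg^2, and in dimensionless
coordinates (q Rg)^2 vs q Rg I(q)/I(0) the peak sits at
(1.5, sqrt(1.5) exp(-0.5) = 0.7428) for every size and scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .saxs_io import Annotation, ScatteringCurve

logger = logging.getLogger(__name__)

#: theoretical dimensionless peak position of an ideal Guinier scatterer
PEAK_X_THEORY = 1.5
PEAK_Y_THEORY = float(np.sqrt(1.5) * np.exp(-0.5))  # 0.74279...

GPA_VARIANTS = ("qiq_vs_q2", "ln_qiq_vs_q2", "qiq_vs_q", "dimensionless",
                "kratky_dimensionless")


class GuinierError(ValueError):
    """Raised when a Guinier fit is impossible on the given data."""


@dataclass(frozen=True)
class GuinierFit:
    """Result of the traditional ln I vs q^2 linear fit."""

    rg: float
    i0: float
    q2_window: Tuple[float, float]
    qrg_range: Tuple[float, float]
    r_squared: float
    n_points: int
    converged: bool = True


@dataclass(frozen=True)
class GPACurve:
    """A transformed scattering curve; meaning of (x, y) depends on variant."""

    x: np.ndarray
    y: np.ndarray
    variant: str
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if len(x) != len(y):
            raise ValueError("x and y must have equal length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if self.variant not in GPA_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class DimensionlessPeak:
    """A located peak mapped to dimensionless coordinates.

    ``dx`` and ``dy`` are offsets from the theoretical position
    (1.5, 0.7428).
    """

    x_prime: float
    y_prime: float
    dx: float = field(init=False)
    dy: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.x_prime > 0 and self.y_prime > 0):
            raise ValueError("dimensionless peak coordinates must be positive")
        object.__setattr__(self, "dx", self.x_prime - PEAK_X_THEORY)
        object.__setattr__(self, "dy", self.y_prime - PEAK_Y_THEORY)


@dataclass(frozen=True)
class LocalEstimateTrack:
    """Sliding-window Guinier estimates across the low-q region."""

    centers: np.ndarray          # window centres on the q^2 axis
    rg: np.ndarray               # per-window Rg (NaN where undefined)
    i0: np.ndarray
    trend: int                   # sign of the Theil-Sen slope of rg vs centre


def _fit_line(q2: np.ndarray, ln_i: np.ndarray,
              weights: Optional[np.ndarray]) -> Tuple[float, float, float]:
    """Weighted least squares of ln I on q^2; returns slope, intercept, R^2."""
    if weights is None:
        w = np.ones_like(q2)
    else:
        w = weights
    wsum = w.sum()
    xm = (w * q2).sum() / wsum
    ym = (w * ln_i).sum() / wsum
    sxx = (w * (q2 - xm) ** 2).sum()
    sxy = (w * (q2 - xm) * (ln_i - ym)).sum()
    if sxx <= 0:
        raise GuinierError("degenerate q window")
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = ln_i - (slope * q2 + intercept)
    sst = (w * (ln_i - ym) ** 2).sum()
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - (w * resid ** 2).sum() / sst)
    return slope, intercept, min(1.0, r2)


def guinier_fit(curve: ScatteringCurve, qrg_max: float = 1.3,
                qrg_min: float = 0.0, weighted: bool = False,
                max_iter: int = 10) -> GuinierFit:
    """Iteratively windowed Guinier fit.

    Starts from the lowest 20% of points, then refits restricted to
    ``qrg_min <= q Rg <= qrg_max`` until the point window is stable (at
    most ``max_iter`` refinements).  Non-convergence is reported through
    ``converged=False`` on the result, not as an error.

    Raises
    ------
    GuinierError
        For non-positive intensities in the window, a non-negative slope
        (Rg undefined), or a window that collapses below 5 points.
    """
    if not (qrg_max > qrg_min >= 0):
        raise ValueError("require qrg_max > qrg_min >= 0")
    q = curve.q
    n = len(q)
    n0 = max(5, int(np.ceil(0.2 * n)))
    idx = np.arange(n0)
    weights = None

    def _window_fit(sel: np.ndarray):
        qw = q[sel]
        iw = curve.intensity[sel]
        if np.any(iw <= 0):
            raise GuinierError("non-positive intensities in Guinier window")
        ln_i = np.log(iw)
        w = None
        if weighted and curve.sigma is not None:
            sig = curve.sigma[sel]
            if np.any(sig <= 0):
                raise GuinierError("non-positive sigma with --weighted")
            w = (iw / sig) ** 2  # delta-method weights for ln I
        slope, intercept, r2 = _fit_line(qw ** 2, ln_i, w)
        if slope >= 0:
            raise GuinierError("Rg undefined: non-negative Guinier slope")
        rg = float(np.sqrt(-3.0 * slope))
        i0 = float(np.exp(intercept))
        return rg, i0, r2

    converged = False
    rg = i0 = r2 = None
    for _ in range(max_iter):
        rg, i0, r2 = _window_fit(idx)
        qrg = q * rg
        new_idx = np.nonzero((qrg >= qrg_min) & (qrg <= qrg_max))[0]
        if len(new_idx) < 5:
            raise GuinierError("Guinier window collapsed below 5 points")
        if np.array_equal(new_idx, idx):
            converged = True
            break
        idx = new_idx
    else:  # pragma: no cover - loop always breaks or exhausts
        pass
    if not converged:
        rg, i0, r2 = _window_fit(idx)
        logger.warning("Guinier window unstable after %d iterations", max_iter)
    qw = q[idx]
    return GuinierFit(
        rg=rg, i0=i0,
        q2_window=(float(qw[0] ** 2), float(qw[-1] ** 2)),
        qrg_range=(float(qw[0] * rg), float(qw[-1] * rg)),
        r_squared=float(r2), n_points=len(idx), converged=converged,
    )


def gpa_transform(curve: ScatteringCurve, variant: str = "qiq_vs_q2") -> GPACurve:
    """Pointwise transform of a curve into one of the peak-forming plots.

    No resampling is performed; the input grid maps exactly.  For the
    logarithmic variant, points with q I(q) <= 0 are dropped (with a
    logged count).
    """
    q, inten = curve.q, curve.intensity
    qi = q * inten
    if variant == "qiq_vs_q2":
        return GPACurve(x=q ** 2, y=qi, variant=variant, label=curve.label)
    if variant == "qiq_vs_q":
        return GPACurve(x=q, y=qi, variant=variant, label=curve.label)
    if variant == "ln_qiq_vs_q2":
        keep = qi > 0
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("ln transform: dropped %d non-positive points", n_drop)
        if not np.any(keep):
            raise ValueError("no positive qI(q) points for ln transform")
        return GPACurve(x=q[keep] ** 2, y=np.log(qi[keep]), variant=variant,
                        label=curve.label)
    raise ValueError(f"unknown variant {variant!r}")


def dimensionless_gpa(curve: ScatteringCurve, ann: Annotation) -> GPACurve:
    """Scale to (q Rg)^2 vs q Rg I(q)/I(0) using the annotated (Rg, I0)."""
    x = (curve.q * ann.rg) ** 2
    y = curve.q * ann.rg * curve.intensity / ann.i0
    return GPACurve(x=x, y=y, variant="dimensionless", label=curve.label)


def dimensionless_kratky(curve: ScatteringCurve, ann: Annotation) -> GPACurve:
    """Dimensionless Kratky plot: (q Rg)^2 I(q)/I(0) vs q Rg.

    For an ideal Guinier scatterer the peak is at q Rg = sqrt(3) with
    height 3/e.
    """
    x = curve.q * ann.rg
    y = x ** 2 * curve.intensity / ann.i0
    return GPACurve(x=x, y=y, variant="kratky_dimensionless", label=curve.label)


def peak_to_dimensionless(peak_x: float, peak_y: float,
                          ann: Annotation) -> DimensionlessPeak:
    """Map a peak of the q I(q) vs q^2 plot into dimensionless coordinates.

    x' = x Rg^2 and y' = y Rg / I(0).
    """
    if not peak_x > 0:
        raise ValueError("peak_x must be positive")
    return DimensionlessPeak(x_prime=float(peak_x * ann.rg ** 2),
                             y_prime=float(peak_y * ann.rg / ann.i0))


def estimate_from_peak(peak_x: float, peak_y: float) -> Annotation:
    """Estimate (Rg, I0) from a located peak of the q I(q) vs q^2 plot.

    Rg = sqrt(1.5 / x) and I0 = y exp(0.5) / sqrt(x).  The estimate is
    biased for elongated scatterers, whose Guinier approximation breaks
    down before (q Rg)^2 = 1.5, and is less precise than a windowed
    Guinier fit for globular ones.
    """
    if not (peak_x > 0 and peak_y > 0):
        raise ValueError("peak coordinates must be positive")
    rg = float(np.sqrt(1.5 / peak_x))
    i0 = float(peak_y * np.exp(0.5) / np.sqrt(peak_x))
    return Annotation(rg=rg, i0=i0, source="guinier")


def local_guinier_track(curve: ScatteringCurve, window_pts: int = 9,
                        qrg_cap: float = 1.5) -> LocalEstimateTrack:
    """Sliding-window Guinier fits across the low-q region.

    Windows of ``window_pts`` points overlap by half a window; only
    windows whose upper edge satisfies q Rg_global <= qrg_cap are used,
    where Rg_global comes from a standard windowed fit.  Windows with a
    locally non-negative slope yield NaN.  The overall trend is the sign
    of the Theil-Sen slope of Rg against window centre.
    """
    if window_pts < 5:
        raise ValueError("window_pts must be >= 5")
    fit = guinier_fit(curve, qrg_max=qrg_cap)
    q = curve.q
    step = max(1, window_pts // 2)
    centers, rgs, i0s = [], [], []
    for start in range(0, len(q) - window_pts + 1, step):
        sel = slice(start, start + window_pts)
        if q[sel].max() * fit.rg > qrg_cap:
            break
        iw = curve.intensity[sel]
        if np.any(iw <= 0):
            continue
        slope, intercept, _ = _fit_line(q[sel] ** 2, np.log(iw), None)
        centers.append(float(np.mean(q[sel] ** 2)))
        if slope < 0:
            rgs.append(float(np.sqrt(-3 * slope)))
            i0s.append(float(np.exp(intercept)))
        else:
            rgs.append(np.nan)
            i0s.append(np.nan)
    centers = np.asarray(centers)
    rgs = np.asarray(rgs)
    i0s = np.asarray(i0s)
    valid = np.isfinite(rgs)
    if valid.sum() < 2:
        raise GuinierError("fewer than 2 valid sliding windows")
    if valid.sum() >= 3 and np.ptp(rgs[valid]) > 1e-9 * np.nanmean(rgs[valid]):
        slope = stats.theilslopes(rgs[valid], centers[valid])[0]
        trend = int(np.sign(slope))
    else:
        trend = 0
    return LocalEstimateTrack(centers=centers, rg=rgs, i0=i0s, trend=trend)
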