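"""Real-space statistics derived from pair-distribution functions.

Covers the moment-based (Rg, I0), the elongation ratio ER — the area
under P(r) after its maximum divided by the area before it — and the
size-normalised P'(r') vectors used for shape clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .saxs_io import Annotation, PairDistribution

#: sampling step of the normalised r' = r/Rg grid
R_PRIME_STEP = 0.25

#: negative P(r) mass above this fraction of the positive mass is an error
NEG_MASS_LIMIT = 0.01


@dataclass(frozen=True)
class ERResult:
    """Elongation ratio and the areas it is built from."""

    er: float
    r_largest: float
    area_before: float
    area_after: float


@dataclass(frozen=True)
class NormalizedPr:
    """P(r) sampled on an Rg-scaled grid (step 1/4) and scaled to unit sum."""

    r_prime: np.ndarray
    p_prime: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        rp = np.asarray(self.r_prime, dtype=float)
        pp = np.asarray(self.p_prime, dtype=float)
        object.__setattr__(self, "r_prime", rp)
        object.__setattr__(self, "p_prime", pp)
        if len(rp) != len(pp):
            raise ValueError("r_prime and p_prime must have equal length")
        if not np.allclose(np.diff(rp), R_PRIME_STEP):
            raise ValueError("r_prime must advance in steps of 1/4")
        if abs(pp.sum() - 1.0) > 1e-10:
            raise ValueError("p_prime must sum to one")

    def __len__(self) -> int:
        return len(self.r_prime)


def _clipped_p(pr: PairDistribution) -> np.ndarray:
    """Clip small negative truncation noise; reject corrupt inputs."""
    p = pr.p.copy()
    neg = -p[p < 0].sum()
    pos = p[p > 0].sum()
    if pos <= 0:
        raise ValueError("P(r) has no positive mass")
    if neg > NEG_MASS_LIMIT * pos:
        raise ValueError(
            f"negative P(r) mass ({neg / pos:.1%} of positive) exceeds limit")
    np.clip(p, 0.0, None, out=p)
    return p


def pr_moments(pr: PairDistribution) -> Annotation:
    """Moment estimates of Rg and I(0) from P(r).

    Rg^2 = int r^2 P dr / (2 int P dr); I0 = 4 pi int P dr (the common
    indirect-transform convention).  Trapezoidal quadrature on the native
    grid.
    """
    p = _clipped_p(pr)
    r = pr.r
    total = np.trapezoid(p, r)
    if total <= 0:
        raise ValueError("P(r) integrates to zero")
    rg = float(np.sqrt(np.trapezoid(r ** 2 * p, r) / (2.0 * total)))
    i0 = float(4.0 * np.pi * total)
    return Annotation(rg=rg, i0=i0, source="pr")


def elongation_ratio(pr: PairDistribution) -> ERResult:
    """Elongation ratio: area after the P(r) maximum over area before it.

    Around 1 for compact symmetric bodies and large for extended ones.
    Ties for the maximum resolve to the smallest r; a maximum at either
    end of the grid is degenerate and rejected.
    """
    p = _clipped_p(pr)
    r = pr.r
    imax = int(np.argmax(p))  # argmax returns first index on ties
    if imax == 0 or imax == len(p) - 1:
        raise ValueError("degenerate P(r): maximum at grid boundary")
    area_before = float(np.trapezoid(p[:imax + 1], r[:imax + 1]))
    area_after = float(np.trapezoid(p[imax:], r[imax:]))
    if area_before <= 0:
        raise ValueError("degenerate P(r): zero area before maximum")
    return ERResult(er=area_after / area_before, r_largest=float(r[imax]),
                    area_before=area_before, area_after=area_after)


def normalize_pr(pr: PairDistribution, ann: Annotation) -> NormalizedPr:
    """Resample P on the r' = r/Rg axis with step 1/4 and unit total.

    Linear interpolation; values beyond dmax are zero.  The grid runs
    from 0 to dmax/Rg rounded up to the next quarter step.
    """
    if not ann.rg > 0:
        raise ValueError("annotation Rg must be positive")
    p = _clipped_p(pr)
    n_steps = int(np.ceil(pr.dmax / ann.rg / R_PRIME_STEP))
    r_prime = np.arange(n_steps + 1) * R_PRIME_STEP
    sampled = np.interp(r_prime * ann.rg, pr.r, p, left=0.0, right=0.0)
    sampled[r_prime * ann.rg > pr.dmax] = 0.0
    if (sampled > 0).sum() < 4:
        raise ValueError("Rg too large: fewer than 4 nonzero samples")
    return NormalizedPr(r_prime=r_prime, p_prime=sampled / sampled.sum(),
                        label=pr.label)
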