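"""Synthetic scattering and pair-distance distributions for regular solids.

Provides orientationally averaged form-factor intensities for spheres,
ellipsoids (of revolution and triaxial), cylinders and rectangular
prisms, plus ideal Guinier scatterers, polydisperse sphere populations,
two-component mixtures and a non-physical low-q suppression emulator for
repulsion-like curves.  Every generated intensity satisfies I(0) = i0
exactly.  Pair distributions come from Monte Carlo sampling of point
pairs inside the solid (the solid sphere also has a closed form).

Analytic radii of gyration used as ground truth:

=================  =============================================
sphere             sqrt(3/5) R
ellipsoid a,a,va   sqrt((a^2 + a^2 + (va)^2) / 5)
triaxial a,b,c     sqrt((a^2 + b^2 + c^2) / 5)
cylinder r, L=2vr  sqrt(r^2/2 + L^2/12)
prism A,B,C        sqrt((A^2 + B^2 + C^2) / 12)
=================  =============================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import j1

from .saxs_io import PairDistribution, ScatteringCurve

KINDS = ("ideal_guinier", "sphere", "ellipsoid_rev", "triaxial_ellipsoid",
         "cylinder", "prism", "polydisperse_spheres", "mixture",
         "repulsion_emulated")

#: Gauss-Legendre order for orientation averages
QUAD_ORDER = 128

#: polydisperse radius law: Gaussian truncated at +/- 4 sigma, 41 nodes
POLY_TRUNC_SIGMA = 4.0
POLY_NODES = 41


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric description of a scatterer for the synthetic generator."""

    kind: str
    params: dict
    rg_true: float
    i0_true: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if not (self.rg_true > 0 and self.i0_true > 0):
            raise ValueError("rg_true and i0_true must be positive")


# ---------------------------------------------------------------- factories

def ideal_guinier(rg: float, i0: float = 1.0, label: str = "") -> ShapeSpec:
    return ShapeSpec("ideal_guinier", {"rg": rg, "i0": i0}, rg_true=rg,
                     i0_true=i0, label=label or f"ideal_rg{rg:g}")


def sphere(radius: float, i0: float = 1.0, label: str = "") -> ShapeSpec:
    return ShapeSpec("sphere", {"radius": radius}, rg_true=np.sqrt(0.6) * radius,
                     i0_true=i0, label=label or f"sphere_R{radius:g}")


def ellipsoid_rev(a: float, v: float, i0: float = 1.0, label: str = "") -> ShapeSpec:
    """Ellipsoid of revolution with semi-axes (a, a, v*a)."""
    rg = np.sqrt((2 * a ** 2 + (v * a) ** 2) / 5.0)
    return ShapeSpec("ellipsoid_rev", {"a": a, "v": v}, rg_true=rg, i0_true=i0,
                     label=label or f"ellipsoid_a{a:g}_v{v:g}")


def triaxial_ellipsoid(a: float, b: float, c: float, i0: float = 1.0,
                       label: str = "") -> ShapeSpec:
    rg = np.sqrt((a ** 2 + b ** 2 + c ** 2) / 5.0)
    return ShapeSpec("triaxial_ellipsoid", {"a": a, "b": b, "c": c},
                     rg_true=rg, i0_true=i0,
                     label=label or f"triaxial_{a:g}_{b:g}_{c:g}")


def cylinder(radius: float, v: float, i0: float = 1.0, label: str = "") -> ShapeSpec:
    """Cylinder of radius r and length 2*v*r."""
    length = 2.0 * v * radius
    rg = np.sqrt(radius ** 2 / 2.0 + length ** 2 / 12.0)
    return ShapeSpec("cylinder", {"radius": radius, "v": v}, rg_true=rg,
                     i0_true=i0, label=label or f"cylinder_r{radius:g}_v{v:g}")


def prism(a: float, b: float, c: float, i0: float = 1.0, label: str = "") -> ShapeSpec:
    """Rectangular prism with full edge lengths (a, b, c)."""
    rg = np.sqrt((a ** 2 + b ** 2 + c ** 2) / 12.0)
    return ShapeSpec("prism", {"a": a, "b": b, "c": c}, rg_true=rg, i0_true=i0,
                     label=label or f"prism_{a:g}_{b:g}_{c:g}")


def polydisperse_spheres(mean_radius: float, sigma_radius: float,
                         i0: float = 1.0, label: str = "") -> ShapeSpec:
    radii, weights = _poly_nodes(mean_radius, sigma_radius)
    vol2 = (radii ** 3) ** 2
    w = weights * vol2
    rg2_z = np.sum(w * 0.6 * radii ** 2) / np.sum(w)
    return ShapeSpec("polydisperse_spheres",
                     {"mean_radius": mean_radius, "sigma_radius": sigma_radius},
                     rg_true=float(np.sqrt(rg2_z)), i0_true=i0,
                     label=label or f"polysphere_R{mean_radius:g}")


def mixture(components: Sequence[ShapeSpec], weights: Sequence[float],
            i0: float = 1.0, label: str = "") -> ShapeSpec:
    """Two-or-more component mixture; weights are forward-intensity
    fractions and must sum to 1.  rg_true is the z-average:
    Rg^2 = sum w_k Rg_k^2."""
    weights = np.asarray(weights, dtype=float)
    if len(components) != len(weights) or len(components) < 2:
        raise ValueError("need >= 2 components with matching weights")
    if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights <= 0):
        raise ValueError("weights must be positive and sum to 1")
    rg2 = sum(w * c.rg_true ** 2 for w, c in zip(weights, components))
    return ShapeSpec("mixture",
                     {"components": tuple(components), "weights": tuple(weights)},
                     rg_true=float(np.sqrt(rg2)), i0_true=i0,
                     label=label or "mixture")


def repulsion_emulated(rg: float, i0: float = 1.0, amp: float = 0.2,
                       xi_factor: float = 0.7, label: str = "") -> ShapeSpec:
    """Ideal Guinier intensity multiplied by 1 - amp*exp(-q^2 xi^2),
    xi = xi_factor * rg.  Emulates the concave-downward Guinier region of
    repulsive interparticle interference; explicitly not a physical
    structure-factor model.  rg_true is the underlying particle Rg;
    i0_true is the actual (suppressed) forward intensity."""
    if not (0 < amp < 1):
        raise ValueError("amp must be in (0, 1)")
    return ShapeSpec("repulsion_emulated",
                     {"rg": rg, "i0": i0, "amp": amp, "xi": xi_factor * rg},
                     rg_true=rg, i0_true=i0 * (1.0 - amp),
                     label=label or f"repulsion_rg{rg:g}")


# ------------------------------------------------------------- form factors

def _sphere_amplitude(u: np.ndarray) -> np.ndarray:
    """3 (sin u - u cos u) / u^3, continuous at u = 0."""
    u = np.asarray(u, dtype=float)
    out = np.ones_like(u)
    m = np.abs(u) > 1e-6
    um = u[m]
    out[m] = 3.0 * (np.sin(um) - um * np.cos(um)) / um ** 3
    return out


def _poly_nodes(mean_r: float, sigma_r: float) -> Tuple[np.ndarray, np.ndarray]:
    lo = max(mean_r - POLY_TRUNC_SIGMA * sigma_r, 1e-6 * mean_r)
    hi = mean_r + POLY_TRUNC_SIGMA * sigma_r
    radii = np.linspace(lo, hi, POLY_NODES)
    weights = np.exp(-0.5 * ((radii - mean_r) / sigma_r) ** 2)
    return radii, weights / weights.sum()


_GL_X, _GL_W = np.polynomial.legendre.leggauss(QUAD_ORDER)
_GL_T = 0.5 * (_GL_X + 1.0)   # nodes mapped to [0, 1]
_GL_WT = 0.5 * _GL_W


def _normalized_intensity(spec: ShapeSpec, q: np.ndarray) -> np.ndarray:
    """I(q)/I(0) for a single-component spec."""
    kind, p = spec.kind, spec.params
    if kind == "ideal_guinier":
        return np.exp(-q ** 2 * p["rg"] ** 2 / 3.0)
    if kind == "sphere":
        return _sphere_amplitude(q * p["radius"]) ** 2
    if kind == "ellipsoid_rev":
        a, v = p["a"], p["v"]
        # effective radius along orientation t = cos(angle to symmetry axis)
        re = a * np.sqrt(1.0 + (v ** 2 - 1.0) * _GL_T ** 2)
        amp2 = _sphere_amplitude(np.outer(q, re)) ** 2
        return amp2 @ _GL_WT
    if kind == "triaxial_ellipsoid":
        a, b, c = p["a"], p["b"], p["c"]
        x = _GL_T[:, None]
        ycos = _GL_T[None, :]
        r2 = ((a ** 2 * np.cos(np.pi * x / 2) ** 2 +
               b ** 2 * np.sin(np.pi * x / 2) ** 2) * (1 - ycos ** 2) +
              c ** 2 * ycos ** 2)
        re = np.sqrt(r2).ravel()
        w2 = np.outer(_GL_WT, _GL_WT).ravel()
        amp2 = _sphere_amplitude(np.outer(q, re)) ** 2
        return amp2 @ w2
    if kind == "cylinder":
        radius, v = p["radius"], p["v"]
        length = 2.0 * v * radius
        ct = _GL_T
        st = np.sqrt(1.0 - ct ** 2)
        zr = np.outer(q, radius * st)
        zl = np.outer(q, length * ct / 2.0)
        safe = np.where(zr > 1e-8, zr, 1.0)
        bess = np.where(zr > 1e-8, 2.0 * j1(safe) / safe, 1.0)
        sinc = np.sinc(zl / np.pi)
        return (bess * sinc) ** 2 @ _GL_WT
    if kind == "prism":
        a, b, c = p["a"], p["b"], p["c"]
        ct, phi = np.meshgrid(_GL_T, (np.pi / 2.0) * _GL_T, indexing="ij")
        st = np.sqrt(1.0 - ct ** 2)
        nx = (st * np.cos(phi)).ravel()
        ny = (st * np.sin(phi)).ravel()
        nz = ct.ravel()
        w2 = np.outer(_GL_WT, _GL_WT).ravel()
        qa = np.outer(q, nx * a / 2.0)
        qb = np.outer(q, ny * b / 2.0)
        qc = np.outer(q, nz * c / 2.0)
        amp = np.sinc(qa / np.pi) * np.sinc(qb / np.pi) * np.sinc(qc / np.pi)
        return amp ** 2 @ w2
    if kind == "polydisperse_spheres":
        radii, weights = _poly_nodes(p["mean_radius"], p["sigma_radius"])
        w = weights * (radii ** 3) ** 2   # volume^2 weighting
        w = w / w.sum()
        amp2 = _sphere_amplitude(np.outer(q, radii)) ** 2
        return amp2 @ w
    if kind == "mixture":
        total = np.zeros_like(q)
        for comp, w in zip(p["components"], p["weights"]):
            total += w * _normalized_intensity(comp, q)
        return total
    if kind == "repulsion_emulated":
        base = np.exp(-q ** 2 * p["rg"] ** 2 / 3.0)
        suppressed = base * (1.0 - p["amp"] * np.exp(-q ** 2 * p["xi"] ** 2))
        return suppressed / (1.0 - p["amp"])   # so that value at q=0 is 1
    raise ValueError(f"unknown kind {kind!r}")  # pragma: no cover


def intensity(spec: ShapeSpec, q_grid: np.ndarray) -> ScatteringCurve:
    """Orientationally averaged intensity on a grid, with I(0) = i0_true."""
    q = np.asarray(q_grid, dtype=float)
    if np.any(np.diff(q) <= 0) or q[0] < 0:
        raise ValueError("q grid must be non-negative and strictly increasing")
    i_norm = _normalized_intensity(spec, q)
    return ScatteringCurve(q=q, intensity=spec.i0_true * i_norm,
                           label=spec.label)


# -------------------------------------------------------- pair distributions

def sphere_pr_analytic(radius: float, n_points: int = 5001,
                       label: str = "") -> PairDistribution:
    """Closed-form solid-sphere P(r) on [0, 2R]:
    p(r) proportional to r^2 (1 - 1.5 u + 0.5 u^3), u = r / 2R."""
    r = np.linspace(0.0, 2.0 * radius, n_points)
    u = r / (2.0 * radius)
    p = r ** 2 * (1.0 - 1.5 * u + 0.5 * u ** 3)
    return PairDistribution(r=r, p=p, label=label or f"sphere_R{radius:g}_pr")


def _bounding_box(spec: ShapeSpec) -> np.ndarray:
    p = spec.params
    if spec.kind == "sphere":
        rr = p["radius"]
        return np.array([rr, rr, rr])
    if spec.kind == "ellipsoid_rev":
        return np.array([p["a"], p["a"], p["a"] * p["v"]])
    if spec.kind == "triaxial_ellipsoid":
        return np.array([p["a"], p["b"], p["c"]])
    if spec.kind == "cylinder":
        return np.array([p["radius"], p["radius"], p["v"] * p["radius"]])
    if spec.kind == "prism":
        return np.array([p["a"] / 2, p["b"] / 2, p["c"] / 2])
    raise ValueError(f"pair_distribution not supported for kind {spec.kind!r}")


def _inside(spec: ShapeSpec, pts: np.ndarray) -> np.ndarray:
    p = spec.params
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    if spec.kind == "sphere":
        return x ** 2 + y ** 2 + z ** 2 <= p["radius"] ** 2
    if spec.kind == "ellipsoid_rev":
        a, c = p["a"], p["a"] * p["v"]
        return (x / a) ** 2 + (y / a) ** 2 + (z / c) ** 2 <= 1.0
    if spec.kind == "triaxial_ellipsoid":
        return ((x / p["a"]) ** 2 + (y / p["b"]) ** 2 + (z / p["c"]) ** 2) <= 1.0
    if spec.kind == "cylinder":
        return x ** 2 + y ** 2 <= p["radius"] ** 2  # |z| bounded by box
    if spec.kind == "prism":
        return np.ones(len(pts), dtype=bool)  # box IS the solid
    raise ValueError(f"unsupported kind {spec.kind!r}")  # pragma: no cover


def _sample_points(spec: ShapeSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n uniform points inside the solid."""
    half = _bounding_box(spec)
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(-half, half, size=(max(2 * (n - filled), 1024), 3))
        good = cand[_inside(spec, cand)]
        take = min(len(good), n - filled)
        out[filled:filled + take] = good[:take]
        filled += take
    return out


def pair_distribution(spec: ShapeSpec, n_samples: int = 200_000,
                      n_bins: int = 200, seed: int = 0,
                      analytic: bool = False) -> PairDistribution:
    """Monte Carlo pair-distance histogram for a single-component solid.

    Samples ``n_samples`` independent point pairs uniformly inside the
    body and bins their separations on [0, geometric dmax].  Deterministic
    for a fixed seed.  For spheres ``analytic=True`` returns the closed
    form instead.
    """
    if spec.kind == "sphere" and analytic:
        return sphere_pr_analytic(spec.params["radius"],
                                  label=spec.label + "_pr")
    if spec.kind in ("ideal_guinier", "polydisperse_spheres", "mixture",
                     "repulsion_emulated"):
        raise ValueError(
            f"pair_distribution requires a single geometric body, not {spec.kind!r}")
    if n_samples < 10_000:
        raise ValueError("n_samples must be >= 10000")
    rng = np.random.default_rng(seed)
    a = _sample_points(spec, n_samples, rng)
    b = _sample_points(spec, n_samples, rng)
    dist = np.linalg.norm(a - b, axis=1)
    dmax_geom = 2.0 * float(np.linalg.norm(_bounding_box(spec)))
    # tight dmax for the common bodies
    p = spec.params
    if spec.kind == "sphere":
        dmax_geom = 2.0 * p["radius"]
    elif spec.kind == "ellipsoid_rev":
        dmax_geom = 2.0 * max(p["a"], p["a"] * p["v"])
    elif spec.kind == "triaxial_ellipsoid":
        dmax_geom = 2.0 * max(p["a"], p["b"], p["c"])
    elif spec.kind == "cylinder":
        dmax_geom = float(np.hypot(2 * p["radius"], 2 * p["v"] * p["radius"]))
    elif spec.kind == "prism":
        dmax_geom = float(np.linalg.norm([p["a"], p["b"], p["c"]]))
    counts, edges = np.histogram(dist, bins=n_bins, range=(0.0, dmax_geom))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    pvals = counts / (n_samples * width)
    r = np.concatenate([[0.0], centers, [dmax_geom]])
    pv = np.concatenate([[0.0], pvals, [0.0]])
    return PairDistribution(r=r, p=pv, label=spec.label + "_pr")


# ------------------------------------------------------------------- noise

def add_noise(curve: ScatteringCurve, rel_sigma: float,
              seed: int = 0) -> ScatteringCurve:
    """Gaussian noise with sigma(q) = rel_sigma * sqrt(I(q) * I(0)).

    The geometric-mean scaling gives roughly constant relative error at
    low q and growing relative error at high q, mimicking counting
    statistics.  I(0) is taken as the first (lowest-q) intensity.
    """
    if rel_sigma < 0:
        raise ValueError("rel_sigma must be non-negative")
    i0 = float(curve.intensity[0])
    sig = rel_sigma * np.sqrt(np.abs(curve.intensity) * abs(i0))
    if rel_sigma == 0:
        return ScatteringCurve(q=curve.q, intensity=curve.intensity.copy(),
                               sigma=sig, label=curve.label)
    rng = np.random.default_rng(seed)
    noisy = curve.intensity + rng.normal(0.0, 1.0, len(curve)) * sig
    return ScatteringCurve(q=curve.q, intensity=noisy, sigma=sig,
                           label=curve.label)


def guinier_validity_limit(spec: ShapeSpec, tol: float = 0.05,
                           qrg_scan_max: float = 3.0,
                           n_scan: int = 3000) -> float:
    """Largest q Rg at which the intensity tracks the Guinier model.

    Scans from low q and returns the last q Rg before
    |I(q) / I_guinier(q) - 1| first exceeds ``tol``; returns the top of
    the scanned range if the approximation holds throughout.
    """
    rg = spec.rg_true
    q = np.linspace(1e-4, qrg_scan_max, n_scan) / rg
    i_model = _normalized_intensity(spec, q)
    i_guinier = np.exp(-q ** 2 * rg ** 2 / 3.0)
    dev = np.abs(i_model / i_guinier - 1.0)
    bad = dev > tol
    if not bad.any():
        return float(q[-1] * rg)
    first = int(np.argmax(bad))
    if first == 0:
        return 0.0
    return float(q[first - 1] * rg)
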