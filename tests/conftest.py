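import numpy as np
import pytest

from saxsgpa import synth
from saxsgpa.saxs_io import Annotation, PairDistribution, ScatteringCurve


def ideal_curve(rg=30.0, i0=1.0, n=400, qrg_span=(0.1, 2.5), label="ideal"):
    """Exact Guinier-model curve on a grid spanning qrg_span in qRg."""
    q = np.linspace(qrg_span[0] / rg, qrg_span[1] / rg, n)
    return ScatteringCurve(q=q, intensity=i0 * np.exp(-q ** 2 * rg ** 2 / 3.0),
                           label=label)


def body_curve(spec, n=400, qrg_span=(0.05, 4.0), noise=0.0, seed=0):
    """Form-factor curve for a ShapeSpec, grid scaled by its true Rg."""
    rg = spec.rg_true
    q = np.linspace(qrg_span[0] / rg, qrg_span[1] / rg, n)
    curve = synth.intensity(spec, q)
    if noise > 0:
        curve = synth.add_noise(curve, noise, seed=seed)
    return curve


@pytest.fixture
def ideal30():
    return ideal_curve(rg=30.0, i0=1.0)


@pytest.fixture
def ann30():
    return Annotation(rg=30.0, i0=1.0, source="external")


@pytest.fixture
def triangle_pr():
    """Piecewise-linear P(r): 0->1 on [0,1], 1->0 on [1,4]; ER = 3."""
    r = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0])
    p = np.array([0.0, 0.5, 1.0, 2.0 / 3.0, 1.0 / 3.0, 0.0])
    return PairDistribution(r=r, p=p, label="triangle")


@pytest.fixture
def symmetric_triangle_pr():
    """Symmetric triangle on [0, 2] peaked at 1; ER = 1 exactly."""
    r = np.linspace(0.0, 2.0, 41)
    p = np.where(r <= 1.0, r, 2.0 - r)
    return PairDistribution(r=r, p=p, label="sym_triangle")


@pytest.fixture
def sphere_pr():
    return synth.sphere_pr_analytic(30.0)
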