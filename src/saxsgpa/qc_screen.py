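"""End-to-end screening of scattering curves against the theoretical
Guinier peak position.

Each curve is transformed to q I(q) vs q^2, its peak located model-free,
mapped to dimensionless coordinates with the annotated (Rg, I0), and the
collection is screened with the Hampel identifier (k = 3): deviations
from the theoretical (1.5, 0.7428) larger than 3 sample MADs on either
axis flag a curve as an outlier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import peakfind, pr_metrics, transforms
from .saxs_io import Annotation, PairDistribution, ScatteringCurve
from .transforms import PEAK_X_THEORY, PEAK_Y_THEORY, DimensionlessPeak

logger = logging.getLogger(__name__)

CLASS_HINTS = ("ok", "elongated", "annotation_suspect", "problematic_guinier",
               "no_guinier_region")

#: MAD floor as a fraction of the theoretical coordinate, to avoid a
#: zero threshold on degenerate (e.g. all-identical synthetic) collections
MAD_FLOOR_FRAC = 0.01

ER_CUTOFF_DEFAULT = 5.0

#: relative tolerance when checking whether a curve's own Guinier refit
#: reconciles the observed peak (annotation_suspect vs problematic_guinier)
_RECONCILE_TOL = 0.15


@dataclass
class ScreenRecord:
    """Screening outcome for a single curve."""

    label: str
    rise_present: bool
    peak: Optional[DimensionlessPeak] = None
    peak_x_raw: float = np.nan          # q^2 at peak, instrument units
    peak_y_raw: float = np.nan          # smoothed q I(q) at peak
    er: Optional[float] = None
    ann_rg: float = np.nan
    ann_i0: float = np.nan
    refit_rg: float = np.nan            # curve's own Guinier refit
    refit_i0: float = np.nan
    est_rg: float = np.nan              # peak-based re-estimate
    est_i0: float = np.nan
    outlier_x: bool = False
    outlier_y: bool = False
    class_hint: str = "ok"

    @property
    def outlier(self) -> bool:
        return self.outlier_x or self.outlier_y


@dataclass(frozen=True)
class CollectionStats:
    """Robust location/spread of the dimensionless peaks in a collection."""

    median_x: float
    mad_x: float
    median_y: float
    mad_y: float
    n: int


def screen_curve(curve: ScatteringCurve, ann: Annotation,
                 pr: Optional[PairDistribution] = None) -> ScreenRecord:
    """Locate and dimensionalise the Guinier peak of one curve.

    Attaches the elongation ratio when a P(r) is supplied, a windowed
    Guinier refit of the curve itself, and the peak-based (Rg, I0)
    re-estimate — both used later to separate annotation errors from
    genuinely problematic Guinier regions.
    """
    gpa = transforms.gpa_transform(curve, "qiq_vs_q2")
    try:
        pk = peakfind.find_guinier_peak(gpa)
    except peakfind.PeakFindError as exc:
        logger.info("%s: peak finding failed (%s)", curve.label, exc)
        return ScreenRecord(label=curve.label, rise_present=False,
                            ann_rg=ann.rg, ann_i0=ann.i0,
                            class_hint="no_guinier_region")
    rec = ScreenRecord(label=curve.label, rise_present=pk.interior,
                       ann_rg=ann.rg, ann_i0=ann.i0)
    if not pk.interior:
        rec.class_hint = "no_guinier_region"
        return rec
    y_peak = pk.y_smooth if pk.y_smooth > 0 else pk.y_raw
    rec.peak_x_raw = pk.x
    rec.peak_y_raw = y_peak
    rec.peak = transforms.peak_to_dimensionless(pk.x, y_peak, ann)
    est = transforms.estimate_from_peak(pk.x, y_peak)
    rec.est_rg, rec.est_i0 = est.rg, est.i0
    try:
        refit = transforms.guinier_fit(curve)
        rec.refit_rg, rec.refit_i0 = refit.rg, refit.i0
    except transforms.GuinierError:
        pass
    if pr is not None:
        try:
            rec.er = pr_metrics.elongation_ratio(pr).er
        except ValueError as exc:
            logger.info("%s: ER unavailable (%s)", curve.label, exc)
    return rec


def hampel_flag(records: List[ScreenRecord],
                er_cutoff: float = ER_CUTOFF_DEFAULT
                ) -> Tuple[CollectionStats, List[ScreenRecord]]:
    """Flag outliers with the Hampel identifier (k = 3).

    The spread (MAD) comes from the sample; the deviation is measured
    from the THEORETICAL position (1.5, 0.7428).  A record is an outlier
    when it deviates by >= 3 MAD on either axis.  MADs are unscaled (no
    normal-consistency factor) and floored at 1% of the theoretical
    coordinate to avoid zero thresholds on degenerate collections.
    Records are updated in place and re-classified; the stats and the
    same list are returned.
    """
    live = [r for r in records if r.rise_present and r.peak is not None]
    if len(live) < 5:
        raise ValueError(f"need >= 5 screenable records, got {len(live)}")
    xs = np.array([r.peak.x_prime for r in live])
    ys = np.array([r.peak.y_prime for r in live])
    med_x, med_y = float(np.median(xs)), float(np.median(ys))
    mad_x = float(np.median(np.abs(xs - med_x)))
    mad_y = float(np.median(np.abs(ys - med_y)))
    stats = CollectionStats(median_x=med_x, mad_x=mad_x,
                            median_y=med_y, mad_y=mad_y, n=len(live))
    thr_x = 3.0 * max(mad_x, MAD_FLOOR_FRAC * abs(PEAK_X_THEORY))
    thr_y = 3.0 * max(mad_y, MAD_FLOOR_FRAC * abs(PEAK_Y_THEORY))
    for r in live:
        r.outlier_x = abs(r.peak.x_prime - PEAK_X_THEORY) >= thr_x
        r.outlier_y = abs(r.peak.y_prime - PEAK_Y_THEORY) >= thr_y
    for r in records:
        r.class_hint = classify(r, er_cutoff=er_cutoff,
                                x_limit=thr_x, y_limit=thr_y)
    return stats, records


def classify(record: ScreenRecord, er_cutoff: float = ER_CUTOFF_DEFAULT,
             x_limit: float = 3.0 * MAD_FLOOR_FRAC * PEAK_X_THEORY,
             y_limit: float = 3.0 * MAD_FLOOR_FRAC * PEAK_Y_THEORY) -> str:
    """Assign a heuristic class to a screened record.

    no_guinier_region   — the GPA rise / interior peak is absent;
    elongated           — outlier with ER above the cutoff (default 5);
    annotation_suspect  — outlier, but the curve's own Guinier refit
                          reconciles the peak (moves it back within
                          limits): the annotation, not the data, is off;
    problematic_guinier — outlier that the refit cannot reconcile
                          (polydispersity, interparticle interference,
                          bad low-q intensities);
    ok                  — everything else.

    The suspect/problematic split is a triage heuristic, not a rule
    stated by the theory; treat it as a hint.
    """
    if not record.rise_present or record.peak is None:
        return "no_guinier_region"
    if not record.outlier:
        return "ok"
    if record.er is not None and record.er > er_cutoff:
        return "elongated"
    if np.isfinite(record.refit_rg) and record.refit_rg > 0 \
            and np.isfinite(record.refit_i0) and record.refit_i0 > 0:
        x_ref = record.peak_x_raw * record.refit_rg ** 2
        y_ref = record.peak_y_raw * record.refit_rg / record.refit_i0
        reconciled = (abs(x_ref - PEAK_X_THEORY) <
                      max(x_limit, _RECONCILE_TOL * PEAK_X_THEORY)
                      and abs(y_ref - PEAK_Y_THEORY) <
                      max(y_limit, _RECONCILE_TOL * PEAK_Y_THEORY))
        if reconciled:
            return "annotation_suspect"
    return "problematic_guinier"


def screen_collection(items, er_cutoff: float = ER_CUTOFF_DEFAULT):
    """Screen (curve, annotation, optional P(r)) triples and Hampel-flag.

    ``items`` is an iterable of (ScatteringCurve, Annotation) or
    (ScatteringCurve, Annotation, PairDistribution) tuples.  Returns
    (CollectionStats, list of ScreenRecord).
    """
    records = []
    for item in items:
        curve, ann = item[0], item[1]
        pr = item[2] if len(item) > 2 else None
        records.append(screen_curve(curve, ann, pr))
    return hampel_flag(records, er_cutoff=er_cutoff)
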