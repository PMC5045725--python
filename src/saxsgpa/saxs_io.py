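"""Core data types and readers/writers for SAXS curves, P(r) files and reports.

Input formats are deliberately permissive: whitespace- or comma-delimited
ASCII with ``#`` comments and free-text header lines, covering common
beamline ``.dat`` exports.  Units are fixed at inverse angstroms for ``q``
and angstroms for ``r``.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: relative tolerance used to locate the support limit of P(r)
DMAX_RTOL = 1e-6

ANNOTATION_SOURCES = ("guinier", "pr", "external")

REPORT_SCHEMA_VERSION = "saxsgpa-screen-1"


class FileFormatError(ValueError):
    """Raised when an input file cannot be parsed into a valid object."""


@dataclass(frozen=True)
class ScatteringCurve:
    """A 1-D scattering curve I(q), optionally with uncertainties.

    Parameters
    ----------
    q : array-like
        Scattering-vector magnitudes in inverse angstroms, strictly
        increasing and non-negative.
    intensity : array-like
        Intensities, arbitrary units, finite, same length as ``q``.
    sigma : array-like, optional
        Per-point uncertainties, non-negative.
    label : str
        Free-text identifier.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if q.ndim != 1 or i.ndim != 1 or len(q) != len(i):
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if len(q) < 8:
            raise ValueError(f"need at least 8 points, got {len(q)}")
        if not np.all(np.isfinite(q)) or not np.all(np.isfinite(i)):
            raise ValueError("q and intensity must be finite")
        if q[0] < 0:
            raise ValueError("q must be non-negative")
        if np.any(np.diff(q) <= 0):
            raise ValueError("non-monotone q")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(s < 0) or not np.all(np.isfinite(s)):
                raise ValueError("sigma must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.q)


@dataclass(frozen=True)
class PairDistribution:
    """A pair-distribution function P(r) on a grid starting at r = 0.

    ``dmax`` is derived as the last r at which P rises above
    ``DMAX_RTOL * max(P)``; grids not starting at zero are extended with a
    (0, 0) anchor point so that P(0) = 0 holds by construction.
    """

    r: np.ndarray
    p: np.ndarray
    label: str = ""
    dmax: float = field(init=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if r.ndim != 1 or p.ndim != 1 or len(r) != len(p):
            raise ValueError("r and p must be 1-D arrays of equal length")
        if np.any(np.diff(r) <= 0):
            raise ValueError("r must be strictly increasing")
        if not np.all(np.isfinite(r)) or not np.all(np.isfinite(p)):
            raise ValueError("r and p must be finite")
        if r[0] < 0:
            raise ValueError("r must be non-negative")
        if r[0] > 0:
            r = np.concatenate([[0.0], r])
            p = np.concatenate([[0.0], p])
        if len(r) < 3:
            raise ValueError("P(r) needs at least 3 points")
        pmax = np.max(p)
        if pmax <= 0:
            raise ValueError("P(r) is identically non-positive")
        above = np.nonzero(p > DMAX_RTOL * pmax)[0]
        # support edge: one grid point past the last above-tolerance sample
        # (where P returns to zero), clipped to the end of the grid
        edge = min(above[-1] + 1, len(r) - 1)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "dmax", float(r[edge]))

    def __len__(self) -> int:
        return len(self.r)


@dataclass(frozen=True)
class Annotation:
    """Reference (Rg, I0) pair attached to a curve.

    ``source`` records where the values came from: a Guinier fit, P(r)
    integration, or an external deposition.
    """

    rg: float
    i0: float
    source: str = "external"

    def __post_init__(self) -> None:
        if not (self.rg > 0):
            raise ValueError("rg must be positive")
        if not (self.i0 > 0):
            raise ValueError("i0 must be positive")
        if self.source not in ANNOTATION_SOURCES:
            raise ValueError(f"source must be one of {ANNOTATION_SOURCES}")


@dataclass
class ScreenReport:
    """Per-curve screening records plus collection-level robust statistics."""

    records: list  # list[qc_screen.ScreenRecord]
    stats: Optional[object] = None  # qc_screen.CollectionStats

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("report must contain at least one record")


def _parse_numeric_rows(path: Path, min_cols: int, max_cols: int):
    """Parse whitespace/comma-delimited numeric rows, skipping comments and
    free-text headers. Returns (rows, n_dropped_nonfinite)."""
    rows = []
    ncols = None
    dropped = 0
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = [float(x) for x in parts]
            except ValueError:
                if not rows:
                    continue  # header line before data
                continue
            if not (min_cols <= len(vals) <= max_cols):
                continue
            if ncols is None:
                ncols = len(vals)
            if len(vals) != ncols:
                vals = vals[:ncols] if len(vals) > ncols else None
                if vals is None:
                    continue
            if not all(np.isfinite(v) for v in vals):
                dropped += 1
                continue
            rows.append(vals)
    if dropped:
        logger.info("dropped %d non-finite rows from %s", dropped, path)
    return rows, dropped


def read_curve(path, dialect: str = "auto") -> ScatteringCurve:
    """Read a 2- or 3-column ASCII scattering curve (q, I, optional sigma).

    Parameters
    ----------
    path : path-like
    dialect : {"auto", "plain3col"}
        ``plain3col`` requires exactly three columns; ``auto`` accepts two.

    Raises
    ------
    FileFormatError
        On unreadable files, fewer than 8 valid rows, or non-monotone q.
    """
    if dialect not in ("auto", "plain3col"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.is_file():
        raise FileFormatError(f"cannot read {path}")
    min_cols = 3 if dialect == "plain3col" else 2
    rows, _ = _parse_numeric_rows(path, min_cols=min_cols, max_cols=3)
    if len(rows) < 8:
        raise FileFormatError(f"{path}: fewer than 8 valid data rows")
    arr = np.asarray(rows, dtype=float)
    q, inten = arr[:, 0], arr[:, 1]
    sigma = arr[:, 2] if arr.shape[1] >= 3 else None
    if np.any(np.diff(q) <= 0):
        raise FileFormatError(f"{path}: non-monotone q")
    try:
        return ScatteringCurve(q=q, intensity=inten, sigma=sigma, label=path.stem)
    except ValueError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def read_pr(path) -> PairDistribution:
    """Read a 2-column ASCII pair-distribution function (r, P(r))."""
    path = Path(path)
    if not path.is_file():
        raise FileFormatError(f"cannot read {path}")
    rows, _ = _parse_numeric_rows(path, min_cols=2, max_cols=3)
    if len(rows) < 8:
        raise FileFormatError(f"{path}: fewer than 8 valid data rows")
    arr = np.asarray(rows, dtype=float)
    r, p = arr[:, 0], arr[:, 1]
    if np.any(np.diff(r) <= 0):
        raise FileFormatError(f"{path}: non-monotone r")
    if np.max(p) <= 0:
        raise FileFormatError(f"{path}: all-zero P(r)")
    return PairDistribution(r=r, p=p, label=path.stem)


def write_curve(curve: ScatteringCurve, path) -> None:
    """Write a curve as 2- or 3-column ASCII (round-trips with read_curve)."""
    cols = [curve.q, curve.intensity]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    header = "# q(1/A)  I(q)" + ("  sigma" if curve.sigma is not None else "")
    np.savetxt(path, np.column_stack(cols), fmt="%.9e", header=header, comments="")


def write_pr(pr: PairDistribution, path) -> None:
    """Write a P(r) as 2-column ASCII."""
    np.savetxt(path, np.column_stack([pr.r, pr.p]), fmt="%.9e",
               header="# r(A)  P(r)", comments="")


def _record_to_dict(rec) -> dict:
    d = {}
    for f in dataclasses.fields(rec):
        v = getattr(rec, f.name)
        if dataclasses.is_dataclass(v):
            for g in dataclasses.fields(v):
                d[f"{f.name}_{g.name}"] = getattr(v, g.name)
        elif v is None:
            d[f.name] = None
        else:
            d[f.name] = v
    return d


def write_report(report: ScreenReport, path, fmt: str = "json") -> None:
    """Write a screening report to JSON (versioned schema) or CSV."""
    if fmt not in ("json", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    if not report.records:
        raise ValueError("report must contain at least one record")
    rows = [_record_to_dict(r) for r in report.records]
    path = Path(path)
    if fmt == "json":
        payload = {"schema": REPORT_SCHEMA_VERSION, "records": rows}
        if report.stats is not None:
            payload["stats"] = _record_to_dict(report.stats)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=float)
    else:
        keys = sorted({k for row in rows for k in row})
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(rows)


def read_report(path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("schema") != REPORT_SCHEMA_VERSION:
        raise FileFormatError(f"unexpected report schema {payload.get('schema')!r}")
    return payload
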