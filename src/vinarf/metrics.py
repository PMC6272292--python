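"""Scoring-power metrics: RMSE, SD, Pearson Rp and Spearman Rs.

For measured affinities {y(n)} and predictions {p(n)} on a test set of N
complexes:

    RMSE = sqrt( mean (y - p)^2 )
    SD   = sqrt( sum (y - (a + b p))^2 / (N - 1) )
    Rp   = Pearson correlation of p and y
    Rs   = Pearson correlation of the rank vectors (average ranks on ties)

(a, b) is the least-squares fit of y on p, so SD is the residual spread about
the regression line — affine miscalibration of p inflates RMSE but not SD.
Lower RMSE/SD and higher Rp/Rs mean better scoring power.  The SD denominator
is N-1 by benchmark convention; ``sd_ddof=0`` switches to N.

All formulas are written out in plain numpy so the test suite can cross-check
them against scipy's independent implementations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["PredictionSet", "MetricsReport", "compute_metrics", "median_summary"]


@dataclass
class PredictionSet:
    """Paired prediction/measurement vectors for one evaluation."""

    p: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.p.shape != self.y.shape or self.p.ndim != 1:
            raise ValueError("p and y must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(self.p)) and np.all(np.isfinite(self.y))):
            raise ValueError("p and y must be finite")

    @property
    def n(self) -> int:
        return len(self.p)


@dataclass
class MetricsReport:
    """One evaluation's metrics; rp/rs are None when undefined (zero variance)."""

    rmse: float
    sd: float
    rp: float | None
    rs: float | None
    n: int
    a: float  # intercept of y-on-p fit
    b: float  # slope of y-on-p fit


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0.0 or sy == 0.0:
        return None
    return float((xc * yc).sum() / (sx * sy))


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """1-based ranks with ties sharing their average rank."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def compute_metrics(ps: PredictionSet, sd_ddof: int = 1) -> MetricsReport:
    """All four metrics plus the (a, b) calibration line for one set."""
    if ps.n < 2:
        raise ValueError("at least 2 paired observations are required")
    p, y = ps.p, ps.y
    n = ps.n

    rmse = float(np.sqrt(np.mean((y - p) ** 2)))

    # least squares y = a + b p; degenerate (constant p) -> b = 0, a = mean(y)
    var_p = np.var(p)
    if var_p == 0.0:
        b, a = 0.0, float(y.mean())
    else:
        b = float(np.cov(p, y, bias=True)[0, 1] / var_p)
        a = float(y.mean() - b * p.mean())
    resid = y - (a + b * p)
    sd = float(np.sqrt((resid**2).sum() / (n - sd_ddof)))

    rp = _pearson(p, y)
    if rp is None:
        logger.warning("zero-variance input: Pearson/Spearman undefined, reported as missing")
        rs = None
    else:
        rs = _pearson(_average_ranks(p), _average_ranks(y))
    return MetricsReport(rmse=rmse, sd=sd, rp=rp, rs=rs, n=n, a=a, b=b)


def median_summary(reports: list[MetricsReport]) -> MetricsReport:
    """Componentwise median across reports (one per RF seed, typically).

    Each metric's median is taken independently; missing rp/rs propagate as
    missing only if every report lacks them.
    """
    if not reports:
        raise ValueError("no reports to summarise")
    ns = {r.n for r in reports}
    if len(ns) > 1:
        raise ValueError(f"reports evaluate different set sizes: {sorted(ns)}")

    def med(name: str) -> float | None:
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        return float(np.median(vals)) if vals else None

    return MetricsReport(
        rmse=med("rmse"),
        sd=med("sd"),
        rp=med("rp"),
        rs=med("rs"),
        n=reports[0].n,
        a=med("a"),
        b=med("b"),
    )
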