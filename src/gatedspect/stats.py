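"""Quantitative comparison layer: activity ratio, Pearson r, Lin's CCC.

Lin's concordance correlation coefficient measures agreement between two
reads of the same quantity, penalizing both imperfect correlation and
systematic location/scale shifts:

    CCC = r · C_b = (σ_xy / σ_x σ_y) · 2σ_xσ_y / (σ_x² + σ_y² + (μ_x − μ_y)²)

with population (1/n) moments.  It is the reliability metric used to compare
dyssynchrony indices across activity-ratio levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import scipy.stats

from gatedspect.phase import PhaseAnalysisResult
from gatedspect.recon import GatedImageSeries

__all__ = ["CCCResult", "ARValue", "activity_ratio", "pearson_r", "ccc", "delta_params"]


@dataclass(frozen=True)
class CCCResult:
    """Lin's concordance coefficient with its full decomposition."""

    ccc: float
    r: float
    c_b: float
    sigma_x: float
    sigma_y: float
    sigma_xy: float
    mu_x: float
    mu_y: float


@dataclass(frozen=True)
class ARValue:
    """Per-bin total activity and the last-bin/first-five activity ratio."""

    bin_totals: tuple[float, ...]
    ar_pct: float


class DeltaParams(NamedTuple):
    d_bw: float
    d_std: float
    d_ent: float


def activity_ratio(series: GatedImageSeries | np.ndarray) -> ARValue:
    """Activity ratio: 100 × (last-bin total) / mean(first five bin totals).

    Accepts a gated image series or a vector of per-bin totals; needs at
    least 6 ECG bins.
    """
    if isinstance(series, GatedImageSeries):
        totals = series.bin_totals()
    else:
        totals = np.asarray(series, dtype=float)
    if totals.ndim != 1 or totals.size < 6:
        raise ValueError("activity ratio needs at least 6 ECG bins")
    if np.any(totals < 0):
        raise ValueError("bin totals must be non-negative")
    denom = totals[:5].mean()
    if denom <= 0:
        raise ZeroDivisionError("first five bins hold no activity")
    return ARValue(
        bin_totals=tuple(float(t) for t in totals),
        ar_pct=float(100.0 * totals[-1] / denom),
    )


def _check_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return x, y


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x, y = _check_pair(x, y)
    return float(scipy.stats.pearsonr(x, y).statistic)


def ccc(x, y, sample_moments: bool = False) -> CCCResult:
    """Lin's concordance correlation coefficient with decomposition.

    Uses population (1/n) moments by default (Lin's original estimator);
    ``sample_moments=True`` switches to n−1 denominators (the factor cancels
    in r but not in C_b).
    """
    x, y = _check_pair(x, y)
    ddof = 1 if sample_moments else 0
    mu_x, mu_y = float(x.mean()), float(y.mean())
    n = x.size
    sxy = float(np.sum((x - mu_x) * (y - mu_y)) / (n - ddof))
    sx = float(np.sqrt(np.sum((x - mu_x) ** 2) / (n - ddof)))
    sy = float(np.sqrt(np.sum((y - mu_y) ** 2) / (n - ddof)))
    r = sxy / (sx * sy)
    c_b = 2.0 * sx * sy / (sx**2 + sy**2 + (mu_x - mu_y) ** 2)
    return CCCResult(
        ccc=r * c_b, r=r, c_b=c_b,
        sigma_x=sx, sigma_y=sy, sigma_xy=sxy, mu_x=mu_x, mu_y=mu_y,
    )


def delta_params(
    osem: PhaseAnalysisResult, tosem: PhaseAnalysisResult
) -> DeltaParams:
    """Per-index differences (TOSEM − OSEM) of BW, StD and ENT."""
    return DeltaParams(
        d_bw=tosem.bw_deg - osem.bw_deg,
        d_std=tosem.std_deg - osem.std_deg,
        d_ent=tosem.ent_pct - osem.ent_pct,
    )
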