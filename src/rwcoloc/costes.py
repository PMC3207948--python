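"""Costes automated dual-threshold determination and the M1C/M2C coefficients.

The Costes procedure links the two channels' thresholds through the
regression line B = a*A + b fitted over all analyzed pixels, then lowers
the threshold pair from the top of the intensity range until the pixels
remaining below both thresholds are uncorrelated.  The Manders-style
coefficients evaluated at those thresholds are M1C/M2C.

Published descriptions leave several details open (inclusive vs strict
comparisons, scan granularity, the exact stopping test), and reference
implementations differ.  The convention here was fixed by requiring that
the 16-segment benchmark grid and its rotations reproduce the
above-threshold mask fractions reported for the reference ImageJ plugin:

* ordinary least squares of B on A (orthogonal regression available);
* candidate thresholds T scan the distinct grey levels of channel A,
  descending, with thr_a = T and thr_b = a*T + b;
* the below-threshold set is {pixels with A < thr_a and B < thr_b};
* by default the scan stops at the first level where the below-set
  Pearson correlation is *degenerate* (at least two pixels but a
  constant channel); below-sets of fewer than two pixels are skipped,
  and if no level triggers, the thresholds settle at the lowest grey
  level.  The classical stop at the first non-positive correlation is
  available as ``stop="nonpositive"``;
* if the whole-image correlation is negative (or undefined) the
  procedure does not converge: the mask is empty and both coefficients
  are 0.  An exactly-zero whole-image correlation still scans: the
  rotated benchmark grids have covariance exactly 0 yet a well-defined
  published threshold.

"Above threshold" is strict (>) on both channels, matching the Manders
convention used elsewhere in this package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .coefficients import ImageLike, _resolve_mask, as_channel

logger = logging.getLogger(__name__)

__all__ = ["CostesResult", "costes_auto_threshold", "costes_coefficients"]


@dataclass(frozen=True)
class CostesResult:
    """Outcome of the Costes automated-threshold procedure.

    ``slope``/``intercept`` describe the fitted line B = slope*A +
    intercept.  ``thr_a``/``thr_b`` are the selected thresholds (channel A
    carries the scanned level, channel B the regression image of it).
    ``mask_fraction`` is the fraction of analyzed pixels strictly above
    both thresholds.  When ``converged`` is False the mask is empty and
    ``m1c = m2c = 0``.
    """

    slope: float
    intercept: float
    thr_a: float
    thr_b: float
    mask_fraction: float
    m1c: float
    m2c: float
    converged: bool


def _pearson(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Centered correlation, or None when degenerate (the scan's stop signal)."""
    if x.size < 2:
        return None
    xc = x - x.mean()
    yc = y - y.mean()
    den = math.sqrt(float(np.dot(xc, xc)) * float(np.dot(yc, yc)))
    if den == 0.0:
        return None
    return float(np.dot(xc, yc) / den)


def _fit_line(x: np.ndarray, y: np.ndarray, regression: str) -> Tuple[float, float]:
    # one covariance matrix for everything: identical channels then get
    # slope exactly 1 and intercept exactly 0, with no last-ulp asymmetry
    c = np.cov(x, y, bias=True)
    sxx, syy, sxy = float(c[0, 0]), float(c[1, 1]), float(c[0, 1])
    if regression == "ols":
        if sxx == 0.0:
            raise ZeroDivisionError("constant channel A")
        a = sxy / sxx
    elif regression == "orthogonal":
        if sxy == 0.0:
            raise ZeroDivisionError("degenerate orthogonal regression")
        a = (syy - sxx + math.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    else:
        raise ValueError(f"unknown regression {regression!r}; use 'ols' or 'orthogonal'")
    return a, float(y.mean() - a * x.mean())


def costes_auto_threshold(
    a: ImageLike,
    b: ImageLike,
    mask: Optional[np.ndarray] = None,
    regression: str = "ols",
    stop: str = "degenerate",
) -> CostesResult:
    """Determine the linked per-channel thresholds (no coefficients yet).

    Returns a :class:`CostesResult` with ``m1c = m2c = 0``; use
    :func:`costes_coefficients` for the fully populated result.
    """
    ca, cb = as_channel(a), as_channel(b)
    if ca.shape != cb.shape:
        raise ValueError(f"channel shapes differ: {ca.shape} vs {cb.shape}")
    if stop not in ("degenerate", "nonpositive"):
        raise ValueError(f"unknown stop rule {stop!r}")
    m = _resolve_mask(ca.shape, mask)
    x = ca.pixels[m].astype(np.float64)
    y = cb.pixels[m].astype(np.float64)

    whole = _pearson(x, y)
    failed = CostesResult(
        slope=math.nan, intercept=math.nan,
        thr_a=float(ca.ceiling), thr_b=float(cb.ceiling),
        mask_fraction=0.0, m1c=0.0, m2c=0.0, converged=False,
    )
    if whole is None or whole < 0.0:
        logger.warning(
            "Costes thresholding failed: whole-image correlation is %s",
            "undefined" if whole is None else f"{whole:.3f} (negative)",
        )
        return failed
    try:
        slope, intercept = _fit_line(x, y, regression)
    except ZeroDivisionError:
        return failed

    levels = np.unique(ca.pixels[m])[::-1].astype(np.float64)  # descending
    thr_a = float(levels[-1])
    thr_b = slope * thr_a + intercept
    for t in levels:
        tb = slope * t + intercept
        below = (x < t) & (y < tb)
        if below.sum() < 2:
            continue
        p = _pearson(x[below], y[below])
        triggered = p is None if stop == "degenerate" else (p is None or p <= 0.0)
        if triggered:
            thr_a, thr_b = float(t), float(tb)
            break
    frac = float(np.mean((x > thr_a) & (y > thr_b)))
    return CostesResult(
        slope=slope, intercept=intercept,
        thr_a=thr_a, thr_b=thr_b,
        mask_fraction=frac, m1c=0.0, m2c=0.0, converged=True,
    )


def costes_coefficients(
    a: ImageLike,
    b: ImageLike,
    mask: Optional[np.ndarray] = None,
    regression: str = "ols",
    stop: str = "degenerate",
) -> CostesResult:
    """Costes thresholds plus the co-localization coefficients M1C/M2C.

    M1C = sum(A over pixels above both thresholds) / sum(A over pixels
    above channel A's threshold), and symmetrically for M2C — the same
    denominator convention as Manders M1/M2.
    """
    res = costes_auto_threshold(a, b, mask, regression=regression, stop=stop)
    if not res.converged:
        return res
    ca, cb = as_channel(a), as_channel(b)
    m = _resolve_mask(ca.shape, mask)
    af = ca.pixels.astype(np.float64)
    bf = cb.pixels.astype(np.float64)
    above_a = m & (af > res.thr_a)
    above_b = m & (bf > res.thr_b)
    co = above_a & above_b
    den_a = float(af[above_a].sum())
    den_b = float(bf[above_b].sum())
    m1c = float(af[co].sum()) / den_a if den_a else 0.0
    m2c = float(bf[co].sum()) / den_b if den_b else 0.0
    return replace(res, m1c=m1c, m2c=m2c)
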