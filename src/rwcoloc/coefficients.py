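"""Intensity-based co-localization coefficients for dual-channel images.

Implements the rank-weighted co-localization coefficients (RWC1/RWC2)
together with the classical measures they are usually compared against:
Pearson correlation (PC), the overlap coefficient r, the split overlap
coefficients k1/k2 and the Manders coefficients M1/M2.

The RWC coefficients combine co-occurrence and intensity correlation in a
single number.  Each channel is ranked by intensity (dense descending
ranks, rank 1 = brightest; equal grey levels share a rank) and every
co-occurring pixel is weighted by how close its two ranks are:

    W_i = (Rn' - D_i) / Rn'       D_i = |rank_A(i) - rank_B(i)|

where Rn is the larger of the two channels' rank counts and
Rn' = Rn + k*Rn for a sensitivity parameter k in [0, 1].  A pixel whose
relative intensity standing agrees perfectly in both channels gets weight
1; the largest possible rank disagreement gets weight 1/Rn' (about 0.5
at k = 1).  RWC1 is then the weighted fraction of channel A's
above-threshold signal that co-occurs with channel B:

    RWC1 = sum(A_i * W_i  over A_i > thrA and B_i > thrB)
           / sum(A_i over A_i > thrA)

and symmetrically for RWC2.  With all weights forced to 1 this reduces
exactly to Manders' M1/M2.  Ranks are always computed from the full
(masked) images before thresholding, so the weighting does not depend on
the threshold choice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelImage",
    "ThresholdPair",
    "RankMap",
    "WeightMap",
    "CoefficientReport",
    "as_channel",
    "dense_rank_transform",
    "rank_weight_map",
    "rwc_coefficients",
    "pearson_correlation",
    "overlap_coefficient_r",
    "overlap_k1_k2",
    "manders_m1_m2",
    "full_report",
]


@dataclass(frozen=True)
class ChannelImage:
    """A single fluorescence channel: 2-D non-negative integer intensities.

    Parameters
    ----------
    pixels
        2-D array of intensity counts.
    bit_depth
        8 or 16; the grey-level ceiling is ``2**bit_depth - 1``.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"channel image must be 2-D, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.size == 0:
            raise ValueError("channel image must contain at least one pixel")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(px == np.rint(px)):
                raise ValueError("intensities must be integers")
            px = px.astype(np.int64)
        if px.min() < 0 or px.max() > self.ceiling:
            raise ValueError(
                f"intensities must lie in [0, {self.ceiling}] for a "
                f"{self.bit_depth}-bit image"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def ceiling(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


ImageLike = Union[ChannelImage, np.ndarray]


def as_channel(img: ImageLike, bit_depth: Optional[int] = None) -> ChannelImage:
    """Coerce a bare array into a :class:`ChannelImage`.

    The bit depth is inferred from the dtype (uint16 -> 16, otherwise 8,
    widened to 16 if any value exceeds 255).
    """
    if isinstance(img, ChannelImage):
        return img
    arr = np.asarray(img)
    if bit_depth is None:
        if arr.dtype == np.uint16:
            bit_depth = 16
        elif arr.size and arr.max() > 255:
            bit_depth = 16
        else:
            bit_depth = 8
    return ChannelImage(arr, bit_depth)


@dataclass(frozen=True)
class ThresholdPair:
    """Manual per-channel thresholds; zero means no threshold."""

    thr_a: float = 0
    thr_b: float = 0

    def __iter__(self):
        return iter((self.thr_a, self.thr_b))


def _resolve_mask(shape: Tuple[int, int], mask: Optional[np.ndarray]) -> np.ndarray:
    if mask is None:
        return np.ones(shape, dtype=bool)
    m = np.asarray(mask).astype(bool)
    if m.shape != shape:
        raise ValueError(f"mask shape {m.shape} does not match image shape {shape}")
    if not m.any():
        raise ValueError("mask excludes every pixel; nothing to analyze")
    return m


def _check_pair(a: ChannelImage, b: ChannelImage) -> None:
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")


@dataclass(frozen=True)
class RankMap:
    """Dense descending intensity ranks of one channel.

    ``ranks`` holds positive integers for pixels inside the mask (1 = the
    brightest grey level present) and 0 for excluded pixels.  ``n_ranks``
    is the number of distinct grey levels inside the mask.
    """

    ranks: np.ndarray
    n_ranks: int
    mask: np.ndarray


def dense_rank_transform(img: ImageLike, mask: Optional[np.ndarray] = None) -> RankMap:
    """Rank pixels by intensity, brightest first, ties sharing one rank.

    Ranks of distinct grey levels are consecutive integers 1..n_ranks, so
    the transform is invariant under any strictly increasing remap of the
    intensities.  Pixels outside ``mask`` get rank 0 and are excluded from
    the grey-level count.
    """
    ch = as_channel(img)
    m = _resolve_mask(ch.shape, mask)
    values = ch.pixels[m]
    levels = np.unique(values)  # ascending distinct grey levels
    n_ranks = int(levels.size)
    ranks = np.zeros(ch.shape, dtype=np.int64)
    # descending dense rank: brightest level -> 1
    ranks[m] = n_ranks - np.searchsorted(levels, values)
    return RankMap(ranks=ranks, n_ranks=n_ranks, mask=m)


@dataclass(frozen=True)
class WeightMap:
    """Per-pixel rank-agreement weights in (0, 1].

    ``rn`` is the larger of the two channels' rank counts; ``k_sens``
    the sensitivity parameter that inflates it to ``rn * (1 + k_sens)``.
    Weights are defined only inside the shared mask (0 outside).
    """

    weights: np.ndarray
    rn: int
    k_sens: float
    mask: np.ndarray


def rank_weight_map(ra: RankMap, rb: RankMap, k_sens: float = 0.0) -> WeightMap:
    """Combine two rank maps into the RWC weight map.

    weight = (Rn' - D) / Rn' with Rn' = Rn + k_sens * Rn and
    D = |rank_A - rank_B| per pixel.
    """
    if not (0.0 <= k_sens <= 1.0):
        raise ValueError(f"k_sens must be in [0, 1], got {k_sens}")
    if ra.ranks.shape != rb.ranks.shape or not np.array_equal(ra.mask, rb.mask):
        raise ValueError("rank maps must cover identical pixel sets")
    rn = max(ra.n_ranks, rb.n_ranks)
    rn_eff = rn * (1.0 + k_sens)
    d = np.abs(ra.ranks.astype(np.float64) - rb.ranks)
    weights = np.where(ra.mask, (rn_eff - d) / rn_eff, 0.0)
    return WeightMap(weights=weights, rn=rn, k_sens=k_sens, mask=ra.mask)


def rwc_coefficients(
    a: ImageLike,
    b: ImageLike,
    thr: Union[ThresholdPair, Tuple[float, float]] = ThresholdPair(),
    k_sens: float = 0.0,
    mask: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Rank-weighted co-localization coefficients (RWC1, RWC2).

    Thresholds are strict (a pixel contributes when its intensity is
    strictly greater than its channel's threshold); ranks are computed on
    the full masked images regardless of the thresholds.  A coefficient
    whose denominator is zero is reported as 0 with a warning.
    """
    ca, cb = as_channel(a), as_channel(b)
    _check_pair(ca, cb)
    thr_a, thr_b = thr
    m = _resolve_mask(ca.shape, mask)
    wmap = rank_weight_map(
        dense_rank_transform(ca, m), dense_rank_transform(cb, m), k_sens
    )
    af = ca.pixels.astype(np.float64)
    bf = cb.pixels.astype(np.float64)
    above_a = m & (ca.pixels > thr_a)
    above_b = m & (cb.pixels > thr_b)
    co = above_a & above_b
    w = wmap.weights
    return (
        _safe_ratio(float(np.sum(af[co] * w[co])), float(af[above_a].sum()), "RWC1"),
        _safe_ratio(float(np.sum(bf[co] * w[co])), float(bf[above_b].sum()), "RWC2"),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0.0:
        logger.warning("%s denominator is zero (no above-threshold signal); returning 0", name)
        return 0.0
    return num / den


def pearson_correlation(
    a: ImageLike, b: ImageLike, mask: Optional[np.ndarray] = None
) -> float:
    """Pearson correlation of pixel intensities over the included pixels.

    Returns NaN (with a warning) when either channel is constant, so that
    "not computable" is never confused with "no co-localization".
    """
    ca, cb = as_channel(a), as_channel(b)
    _check_pair(ca, cb)
    m = _resolve_mask(ca.shape, mask)
    x = ca.pixels[m].astype(np.float64)
    y = cb.pixels[m].astype(np.float64)
    if x.size < 2:
        logger.warning("Pearson correlation undefined for fewer than 2 pixels")
        return math.nan
    x -= x.mean()
    y -= y.mean()
    den = math.sqrt(float(np.dot(x, x)) * float(np.dot(y, y)))
    if den == 0.0:
        logger.warning("Pearson correlation undefined: constant channel")
        return math.nan
    return float(np.clip(np.dot(x, y) / den, -1.0, 1.0))


def overlap_coefficient_r(
    a: ImageLike, b: ImageLike, mask: Optional[np.ndarray] = None
) -> float:
    """Uncentered overlap coefficient r = sum(AB) / sqrt(sum(A^2) sum(B^2))."""
    ca, cb = as_channel(a), as_channel(b)
    _check_pair(ca, cb)
    m = _resolve_mask(ca.shape, mask)
    x = ca.pixels[m].astype(np.float64)
    y = cb.pixels[m].astype(np.float64)
    den = math.sqrt(float(np.dot(x, x)) * float(np.dot(y, y)))
    if den == 0.0:
        logger.warning("overlap coefficient undefined: all-zero channel")
        return math.nan
    return float(np.dot(x, y) / den)


def overlap_k1_k2(
    a: ImageLike, b: ImageLike, mask: Optional[np.ndarray] = None
) -> Tuple[float, float]:
    """Split overlap coefficients k1 = sum(AB)/sum(A^2), k2 = sum(AB)/sum(B^2)."""
    ca, cb = as_channel(a), as_channel(b)
    _check_pair(ca, cb)
    m = _resolve_mask(ca.shape, mask)
    x = ca.pixels[m].astype(np.float64)
    y = cb.pixels[m].astype(np.float64)
    sab = float(np.dot(x, y))
    saa = float(np.dot(x, x))
    sbb = float(np.dot(y, y))
    k1 = sab / saa if saa else math.nan
    k2 = sab / sbb if sbb else math.nan
    if math.isnan(k1) or math.isnan(k2):
        logger.warning("overlap k1/k2 undefined: all-zero channel")
    return k1, k2


def manders_m1_m2(
    a: ImageLike,
    b: ImageLike,
    thr: Union[ThresholdPair, Tuple[float, float]] = ThresholdPair(),
    mask: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Manders coefficients M1, M2 with strict per-channel thresholds.

    M1 is the fraction of channel A's above-threshold signal located at
    pixels where channel B is also above threshold (and symmetrically for
    M2); equivalent to the RWC coefficients with all weights forced to 1.
    """
    ca, cb = as_channel(a), as_channel(b)
    _check_pair(ca, cb)
    thr_a, thr_b = thr
    m = _resolve_mask(ca.shape, mask)
    af = ca.pixels.astype(np.float64)
    bf = cb.pixels.astype(np.float64)
    above_a = m & (ca.pixels > thr_a)
    above_b = m & (cb.pixels > thr_b)
    co = above_a & above_b
    return (
        _safe_ratio(float(af[co].sum()), float(af[above_a].sum()), "M1"),
        _safe_ratio(float(bf[co].sum()), float(bf[above_b].sum()), "M2"),
    )


@dataclass(frozen=True)
class CoefficientReport:
    """All intensity-based coefficients for one channel pair."""

    pc: float
    r: float
    k1: float
    k2: float
    m1: float
    m2: float
    rwc1: float
    rwc2: float
    thresholds: ThresholdPair = field(default_factory=ThresholdPair)
    k_sens: float = 0.0

    def to_dict(self) -> dict:
        return {
            "pc": self.pc,
            "r": self.r,
            "k1": self.k1,
            "k2": self.k2,
            "m1": self.m1,
            "m2": self.m2,
            "rwc1": self.rwc1,
            "rwc2": self.rwc2,
            "thr_a": self.thresholds.thr_a,
            "thr_b": self.thresholds.thr_b,
            "k_sens": self.k_sens,
        }


def full_report(
    a: ImageLike,
    b: ImageLike,
    thr: Union[ThresholdPair, Tuple[float, float]] = ThresholdPair(),
    k_sens: float = 0.0,
    mask: Optional[np.ndarray] = None,
) -> CoefficientReport:
    """Compute every intensity-based coefficient in one pass.

    Undefined coefficients (constant or all-zero channels) are reported as
    NaN without aborting the others.
    """
    if not isinstance(thr, ThresholdPair):
        thr = ThresholdPair(*thr)
    rwc1, rwc2 = rwc_coefficients(a, b, thr, k_sens, mask)
    m1, m2 = manders_m1_m2(a, b, thr, mask)
    k1, k2 = overlap_k1_k2(a, b, mask)
    return CoefficientReport(
        pc=pearson_correlation(a, b, mask),
        r=overlap_coefficient_r(a, b, mask),
        k1=k1,
        k2=k2,
        m1=m1,
        m2=m2,
        rwc1=rwc1,
        rwc2=rwc2,
        thresholds=thr,
        k_sens=k_sens,
    )
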