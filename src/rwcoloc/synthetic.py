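"""Synthetic benchmark image pairs with known ground truth.

Two families are generated:

* **segment grids** — a 512x512 8-bit image of 4x4 square segments whose
  intensities rise row-major from 15 to 240 in steps of 15.  Channel B is
  the same image rotated clockwise by quarter turns, giving pairs with
  perfectly known intensity relations (the 180-degree rotation is the
  exact complement B = 255 - A, i.e. perfect anti-correlation).

* **spot pairs** — 256x256 8-bit images of pixel-sized objects.  Two
  disjoint foreground masks are drawn at a given density, a controlled
  fraction of channel A's foreground is copied into channel B's mask to
  set the co-occurrence level, and foreground intensities are drawn from
  a Gaussian with mean 128 and SD 128 (clamped to [1, ceiling] and
  rounded).  The intensity correlation at co-occurring pixels is then set
  by the copy-fraction mixing formula

      A_new = A_avg + (A_i - A_avg)(1 - Cf) + (B_i - B_avg) Cf

  which interpolates channel A's co-occurring intensities toward channel
  B's: Cf = 0 leaves A unchanged, Cf = 1 makes them a positive-affine
  image of B (correlation 1 before rounding).

Optional zero-mean Gaussian read noise (rounded, clamped to the grey
range) can be added to each channel independently, after the correlation
adjustment.  All randomness flows from the spec's integer seed, so an
identical spec regenerates bit-identical images.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .coefficients import ChannelImage, ImageLike, as_channel

__all__ = [
    "GridSpec",
    "SpotSpec",
    "SpotPair",
    "generate_grid_pair",
    "generate_spot_pair",
    "set_correlation",
    "add_gaussian_noise",
]


@dataclass(frozen=True)
class GridSpec:
    """Parameters of the segment-grid benchmark pair."""

    size: int = 512
    n_segments: int = 4  # per side
    base: int = 15
    step: int = 15
    rotation: int = 0  # clockwise quarter turns (0..3)
    bit_depth: int = 8

    def intensities(self) -> np.ndarray:
        k = np.arange(self.n_segments**2)
        return self.base + self.step * k


@dataclass(frozen=True)
class SpotSpec:
    """Parameters of the Gaussian spot-pair benchmark."""

    size: int = 256
    density: float = 0.10  # foreground fraction per channel
    co_occurrence: float = 1.0  # fraction f of FG1 copied onto FG2
    copy_fraction: float = 1.0  # Cf, sets correlation at co-occurring pixels
    intensity_mean: float = 128.0
    intensity_sd: float = 128.0
    noise_sd: float = 0.0
    seed: int = 0
    bit_depth: int = 8


@dataclass(frozen=True)
class SpotPair:
    """A generated spot pair plus its construction ground truth."""

    a: ChannelImage
    b: ChannelImage
    spec: SpotSpec
    fg1: np.ndarray  # boolean foreground mask of channel A
    fg2: np.ndarray  # boolean foreground mask of channel B
    coloc: np.ndarray  # boolean mask of co-occurring foreground pixels

    def __iter__(self):
        return iter((self.a, self.b))

    @property
    def n_coloc(self) -> int:
        return int(self.coloc.sum())

    def manifest(self) -> dict:
        return {
            "family": "spots",
            "spec": asdict(self.spec),
            "n_fg1": int(self.fg1.sum()),
            "n_fg2": int(self.fg2.sum()),
            "n_coloc": self.n_coloc,
        }


def generate_grid_pair(spec: GridSpec = GridSpec()) -> Tuple[ChannelImage, ChannelImage]:
    """Build the segment grid (channel A) and its rotation (channel B).

    Coordinates are (row, col) with row 0 at the top; rotations are
    clockwise, so one quarter turn sends the top-left segment to the
    top-right corner.
    """
    n = spec.n_segments
    if spec.size % n:
        raise ValueError(f"size {spec.size} not divisible by {n} segments per side")
    ceiling = (1 << spec.bit_depth) - 1
    top = spec.base + (n * n - 1) * spec.step
    if not (0 <= spec.base and top <= ceiling):
        raise ValueError(
            f"segment intensities {spec.base}..{top} exceed the "
            f"{spec.bit_depth}-bit grey range"
        )
    seg = spec.size // n
    tiles = spec.intensities().reshape(n, n)
    a = np.repeat(np.repeat(tiles, seg, axis=0), seg, axis=1)
    b = np.rot90(a, -(spec.rotation % 4))  # numpy rotates CCW; negate for CW
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    return (
        ChannelImage(a.astype(dtype), spec.bit_depth),
        ChannelImage(np.ascontiguousarray(b).astype(dtype), spec.bit_depth),
    )


def _draw_intensities(
    rng: np.random.Generator, n: int, mean: float, sd: float, ceiling: int
) -> np.ndarray:
    vals = np.rint(rng.normal(mean, sd, n))
    # clamp (not resample) so foreground stays strictly positive
    return np.clip(vals, 1, ceiling).astype(np.int64)


def generate_spot_pair(spec: SpotSpec = SpotSpec()) -> SpotPair:
    """Generate a spot pair with controlled co-occurrence and correlation.

    Exactly ``floor(co_occurrence * |FG1|)`` foreground pixels of channel
    A also carry channel-B foreground; both channels keep ``density`` of
    their pixels in the foreground.  Requires ``density <= 0.5`` so the
    initial masks can be disjoint.
    """
    if not (0.0 < spec.density <= 0.5):
        raise ValueError("density must be in (0, 0.5] so disjoint masks exist")
    for name in ("co_occurrence", "copy_fraction"):
        v = getattr(spec, name)
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    rng = np.random.default_rng(spec.seed)
    npx = spec.size * spec.size
    n_fg = int(round(spec.density * npx))
    ceiling = (1 << spec.bit_depth) - 1

    perm = rng.permutation(npx)
    fg1_idx = perm[:n_fg]
    fg2_initial = perm[n_fg : 2 * n_fg]  # disjoint from fg1 by construction
    n_co = int(math.floor(spec.co_occurrence * n_fg))
    copied = rng.permutation(fg1_idx)[:n_co]
    fg2_idx = np.concatenate([fg2_initial[n_co:], copied])

    flat_a = np.zeros(npx, dtype=np.int64)
    flat_b = np.zeros(npx, dtype=np.int64)
    flat_a[fg1_idx] = _draw_intensities(
        rng, n_fg, spec.intensity_mean, spec.intensity_sd, ceiling
    )
    flat_b[fg2_idx] = _draw_intensities(
        rng, n_fg, spec.intensity_mean, spec.intensity_sd, ceiling
    )

    shape = (spec.size, spec.size)
    fg1 = np.zeros(npx, dtype=bool)
    fg1[fg1_idx] = True
    fg2 = np.zeros(npx, dtype=bool)
    fg2[fg2_idx] = True
    coloc = fg1 & fg2

    a = ChannelImage(flat_a.reshape(shape), spec.bit_depth)
    b = ChannelImage(flat_b.reshape(shape), spec.bit_depth)
    if coloc.any() and spec.copy_fraction > 0.0:
        a = set_correlation(a, b, spec.copy_fraction, coloc.reshape(shape))
    if spec.noise_sd > 0.0:
        a = add_gaussian_noise(a, spec.noise_sd, rng)
        b = add_gaussian_noise(b, spec.noise_sd, rng)
    return SpotPair(
        a=a, b=b, spec=spec,
        fg1=fg1.reshape(shape), fg2=fg2.reshape(shape), coloc=coloc.reshape(shape),
    )


def set_correlation(
    a: ImageLike,
    b: ImageLike,
    cf: float,
    coloc_positions: Union[np.ndarray, Sequence[Tuple[int, int]]],
) -> ChannelImage:
    """Pull channel A's co-occurring intensities toward channel B's.

    Applies A_new = A_avg + (A_i - A_avg)(1 - Cf) + (B_i - B_avg) Cf at
    the given positions (a boolean mask or an (n, 2) index array), with
    the averages taken over those same positions; the result is rounded
    and clamped to [1, ceiling] so foreground pixels stay positive.
    """
    if not (0.0 <= cf <= 1.0):
        raise ValueError(f"copy fraction must be in [0, 1], got {cf}")
    ca, cb = as_channel(a), as_channel(b)
    if ca.shape != cb.shape:
        raise ValueError("channel shapes differ")
    pos = np.asarray(coloc_positions)
    if pos.dtype == bool:
        if pos.shape != ca.shape:
            raise ValueError("boolean position mask must match the image shape")
        sel = pos
    else:
        sel = np.zeros(ca.shape, dtype=bool)
        sel[pos[:, 0], pos[:, 1]] = True
    if not sel.any():
        raise ValueError("empty co-occurring position set")
    av = ca.pixels[sel].astype(np.float64)
    bv = cb.pixels[sel].astype(np.float64)
    new = av.mean() + (av - av.mean()) * (1.0 - cf) + (bv - bv.mean()) * cf
    out = ca.pixels.copy()
    out[sel] = np.clip(np.rint(new), 1, ca.ceiling).astype(out.dtype)
    return ChannelImage(out, ca.bit_depth)


def add_gaussian_noise(
    img: ImageLike,
    sd: float,
    rng: Optional[Union[int, np.random.Generator]] = None,
) -> ChannelImage:
    """Add independent zero-mean Gaussian noise per pixel, round, clamp.

    ``rng`` may be an integer seed or a Generator; ``sd = 0`` returns the
    image unchanged.
    """
    if sd < 0:
        raise ValueError("noise SD must be non-negative")
    ch = as_channel(img)
    if sd == 0:
        return ch
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    noisy = np.rint(ch.pixels.astype(np.float64) + gen.normal(0.0, sd, ch.shape))
    return ChannelImage(
        np.clip(noisy, 0, ch.ceiling).astype(ch.pixels.dtype), ch.bit_depth
    )
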