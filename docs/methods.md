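# Methods

This note records the models, conventions and design choices behind
`rwcoloc`, at the level of detail a maintainer or reviewer needs to
reproduce or challenge them.

## Rank-weighted co-localization

Both channels are ranked by intensity with **dense descending ranks**:
the brightest grey level present gets rank 1, the next distinct level
rank 2, and equal intensities share a rank. The number of ranks in a
channel therefore equals its number of distinct grey levels (at most
2^bit-depth), and the ranking — hence the weight map — is invariant
under any strictly increasing remap of one channel's intensities. This
is what makes the weighting robust to inter-channel differences in
illumination, gain, or fluorophore brightness.

Per pixel, `D = |rank_A - rank_B|` and the weight is
`W = (Rn' - D)/Rn'` with `Rn' = Rn(1 + k)`, where `Rn` is the larger of
the two rank counts. At `k = 0` weights span `[1/Rn, 1]`; at `k = 1`
they span roughly `[0.5, 1]`, reducing the penalty for rank
disagreement. `k = 0` is the default and is what all benchmark values
use.

Conventions that materially affect the numbers:

* **Ranks are computed on the full (masked) images, before
  thresholding.** Ranking only above-threshold pixels changes the
  180°-grid benchmark from 0.48 to ≈0.44; the full-image convention is
  the one that reproduces the published value.
* **Thresholds are strict** (`A > thr_A`), and the RWC/Manders
  denominators run over the pixels above *that channel's own*
  threshold, while numerators additionally require the partner channel
  above its threshold. A whole-image denominator would give 0.47 on the
  same benchmark.
* A coefficient whose denominator is empty is reported as 0 with a
  logged warning; undefined correlations (constant channel) are
  reported as NaN, never silently 0, so "not computable" stays
  distinguishable from "no co-localization".
* When a region of interest is supplied, ranks, grey-level counts and
  all sums are recomputed strictly inside it; excluded pixels do not
  exist for any purpose.

## Costes automated thresholding

The procedure fits `B = aA + b` by ordinary least squares over the
analyzed pixels (orthogonal regression is available as an option, since
reference implementations disagree), then scans candidate thresholds
downward over the distinct grey levels of channel A with
`thr_A = T, thr_B = aT + b`, examining at each step the pixels strictly
below both thresholds.

Published descriptions do not fix the comparison directions, the scan
granularity, or the exact stopping test, and different plugins behave
differently. The convention here was **calibrated once against the
16-segment grid quartet** (the identical pair and its 90°/180°/270°
rotations, whose above-threshold mask fractions are known) and then
frozen as a regression test:

* the scan stops at the first level whose below-threshold set is
  *degenerate* — at least two pixels but constant in either channel —
  rather than at the first non-positive below-threshold correlation
  (that classical rule is exposed as `stop="nonpositive"`);
* below-sets of fewer than two pixels are skipped; if no level triggers,
  the thresholds settle at the lowest grey level;
* a *negative or undefined* whole-image correlation aborts the procedure
  (`converged = False`, empty mask, `M1C = M2C = 0`). An exactly-zero
  whole-image correlation still scans: the rotated grid benchmarks have
  covariance exactly 0 yet well-defined published thresholds;
* "above threshold" is strict on both channels, and the M1C/M2C
  denominators use each channel's own above-threshold pixels (the same
  convention as Manders), which makes identical channels score exactly
  1.0 whenever the procedure converges.

This convention reproduces three of the four published grid mask
fractions (87.5%, 37.5%, 0%). The fourth (the 270° pair, published as
12.5%) is not reproducible by any member of the ~4600-combination
convention family we searched — that pair's regression is exactly
degenerate (slope 0, covariance 0), and the frozen convention yields
50% there. The discrepancy is asserted as a known-failing expectation in
the acceptance suite rather than papered over.

## Synthetic benchmarks

The generators' defaults *are* the benchmark conditions; they are not
tuning knobs.

**Segment grid** — 512×512, 8-bit, 4×4 segments of 128×128 px,
intensities 15, 30, …, 240 row-major. Channel B is channel A rotated
**clockwise** by 0–3 quarter turns; coordinates are (row, col), 0-based,
row 0 at top. The direction is fixed by the published asymmetry of the
90° pair (M1 ≈ 0.910, M2 ≈ 0.835 at 15% thresholds); a counter-clockwise
convention would swap them. The 180° pair satisfies `B = 255 − A`
exactly, giving Pearson −1.

**Spot pairs** — 256×256, 8-bit, pixel-sized objects. Two disjoint
foreground masks are drawn at density 0.10 per channel (the published
description does not state a density; 10% is a realistic puncta load
and is exposed as a parameter). A fraction `f` of channel A's
foreground positions is copied into channel B's mask — displacing
randomly chosen original positions so both channels keep exactly
`round(0.10·N)` foreground pixels and exactly `floor(f·|FG1|)` pixels
co-occur. Foreground intensities are drawn from a Gaussian with mean
128 and SD 128, rounded and **clamped to [1, 255]** (not resampled —
the heavy out-of-range mass of that distribution piles up at the ends;
clamping keeps foreground strictly positive and is the simplest
defensible choice). The intensity correlation at co-occurring pixels is
then set by the copy-fraction formula

    A_new = A_avg + (A_i − A_avg)(1 − Cf) + (B_i − B_avg) Cf

with averages over the co-occurring positions: `Cf = 0` is the
identity, `Cf = 1` makes the co-occurring intensities an exact affine
image of channel B (correlation 1 before integer rounding).

**Noise** — independent zero-mean Gaussian draws per pixel and channel,
rounded and clamped to the grey range, applied after the correlation
adjustment and before any thresholding. Identical specs (including the
seed) regenerate bit-identical images.

What the spot generator does *not* emulate: spatially extended objects,
optical blur and the microscope PSF, correlated (shot/read) noise,
background gradients, or chromatic misregistration. Passing benchmarks
therefore demonstrates correctness of the coefficients under the stated
statistical model, not robustness to every real-microscope artifact.

## Object-based analysis

Foreground is the strictly-above-threshold set; connected components
(8-connectivity by default, 4 available) smaller than `min_size` pixels
are discarded; centroids are unweighted pixel means. An object of one
channel co-localizes when its centroid, rounded half-up to the nearest
pixel, lies inside any object of the other channel — a parameter-free
reading of "centroid as reference point"; a centroid-distance mode with
an explicit radius is available but off by default. The published
per-image object counts come from microscopy data that cannot be
regenerated, so the tests assert the method's parameter-dependence
invariants (object count non-increasing in `min_size`, fractions in
[0, 1]) rather than numeric counts.

## Problem sizes and tolerances

The benchmark suite uses the full-size images (512×512 grids, 256×256
spot pairs). Noise-robustness values are averaged over 20 independent
realizations and compared at ±0.02, matching the two-decimal precision
of the reference table; deterministic grid values are compared at two
decimals or exactly where closed forms exist. Coefficient arithmetic is
floating point over exact integer sums; rounding to two decimals happens
only at reporting/comparison time. Small brute-force oracles (per-pixel
loop RWC, exhaustive Costes scan, flood-fill labeling) cross-check the
vectorized implementations on random images up to 8×8 / 16×16.

## Known limitations

* Strictly 2-D, single-frame: no z-stacks, time series, or volumetric
  coefficients (iterate externally per plane/frame).
* No significance testing of coefficients (e.g. scrambling-based
  P-values for Costes thresholds).
* The Costes scan convention is calibrated to one published benchmark
  family; other plugins will differ in edge cases, which is precisely
  why the convention is documented and switchable.
* RGB or multi-channel files are deliberately rejected rather than
  silently converted; split channels upstream.
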