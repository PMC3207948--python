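# rwcoloc

Quantitative co-localization analysis for dual-channel fluorescence
microscopy images, built around the **rank-weighted co-localization
coefficient (RWC)** — a measure that combines pixel *co-occurrence*
(do both markers occupy the same pixel?) with intensity *correlation*
(do their intensities agree?) in a single, threshold-tolerant number.

It is aimed at microscopists and image analysts who need reproducible
co-localization numbers for channel pairs (e.g. an organelle marker
versus a protein of interest), and at method developers who want the
classical coefficients, the RWC coefficients and the synthetic
benchmarks that characterize them in one place.

## The coefficients

For pixel intensities $A_i$, $B_i$, the package computes:

* **Pearson correlation** $PC$ — centered intensity correlation.
* **Overlap coefficient** $r = \sum_i A_i B_i / \sqrt{\sum_i A_i^2 \sum_i B_i^2}$
  and its split forms $k_1 = \sum A_i B_i / \sum A_i^2$,
  $k_2 = \sum A_i B_i / \sum B_i^2$.
* **Manders coefficients** $M_1, M_2$ — the fraction of each channel's
  above-threshold signal located where the other channel is also above
  threshold.
* **Costes automated-threshold coefficients** $M_1C, M_2C$ — Manders-style
  coefficients at thresholds linked by the regression $B = aA + b$ and
  lowered until the below-threshold pixels are uncorrelated.
* **Rank-weighted coefficients** $RWC_1, RWC_2$. Each channel is ranked
  by intensity (dense descending ranks, rank 1 = brightest, ties share a
  rank). With $D_i = |\mathrm{Rank}(A_i) - \mathrm{Rank}(B_i)|$ and $Rn$
  the larger rank count, every co-occurring pixel is weighted by
  $W_i = (Rn - D_i)/Rn$, and

  $$RWC_1 = \frac{\sum_i A_{i,\mathrm{coloc}} W_i}{\sum_i A_i}
  \quad \forall A_i > A_{Thr},$$

  where $A_{i,\mathrm{coloc}} = A_i$ if $B_i > B_{Thr}$, else 0 (and
  symmetrically for $RWC_2$). A sensitivity parameter $k \in [0,1]$
  inflates $Rn$ to $Rn' = Rn + kRn$, compressing the weights toward
  $[0.5, 1]$ at $k = 1$. Because ranking normalizes intensities, RWC
  gives meaningful values even with thresholds left at zero.

Object-based co-localization (thresholded connected components, minimum
object size, centroid containment) is included as the standard
segmentation-driven alternative.

## Worked example

Generate the 512×512 benchmark grid (16 square segments, intensities
15, 30, …, 240) paired with its 180° rotation — a pair in which every
pixel co-occurs but intensities are perfectly anti-correlated — and
analyze it at thresholds of 15% of each channel's maximum:

```python
from rwcoloc import (GridSpec, generate_grid_pair, full_report,
                     costes_coefficients, percent_threshold)

a, b = generate_grid_pair(GridSpec(rotation=2))        # 180 degrees
thr = (percent_threshold(a, 15), percent_threshold(b, 15))   # (36, 36)
rep = full_report(a, b, thr)
print(f"PC   = {rep.pc:.2f}")     # PC   = -1.00
print(f"M1   = {rep.m1:.2f}")     # M1   = 0.77
print(f"RWC1 = {rep.rwc1:.2f}")   # RWC1 = 0.48

res = costes_coefficients(a, b)
print(res.converged, res.m1c)     # False 0.0
```

Pearson reports perfect anti-correlation (−1.00) and the Costes
procedure discards the entire image, even though every pixel carries
signal in both channels. Manders reports 0.77 co-localization and is
blind to the intensity mismatch. RWC lands in between at 0.48: the
pixels do co-occur, but their relative intensities disagree, and the
rank weighting prices that in.

The same analyses run from the shell:

```bash
rwcoloc simulate grid --rotation 2 --out sim/
rwcoloc compute --channel-a sim/channel_a.tif --channel-b sim/channel_b.tif \
        --threshold-percent 15 --out report.json
```

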