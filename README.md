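# dapd — developmental normalization for plant phenotyping time series

High-throughput plant phenotyping (HTPP) systems image hundreds of
Arabidopsis plants daily and report traits such as leaf number and
projected rosette area against days after sowing (DAS). Germination is not
synchronous: genetically identical seeds sown at the same moment emerge a
few days apart, so at any calendar day the population mixes developmental
stages and trait dispersion inflates over the experiment. `dapd`
implements **D**igital **A**djustment of **P**lant **D**evelopment: each
plant's time series is shifted by a whole number of days so that plants
align at equal developmental stage (leaf number) rather than equal sowing
age. The package also provides the image pipeline that produces the
measurements — rosette segmentation from top-view pot crops and
marker-controlled-watershed leaf counting — plus an evaluation harness and
synthetic fixture generators with exact ground truth, so the whole system
is testable without external image datasets.

## The method

The measured leaf count decomposes as

```
Leaf_meas(t) = Leaf_number(t) + Leaf_occlusion(t) + ME(t)
```

(the real count, an occlusion deficit from overlapping leaves, and
measurement error). Each plant's early-stage trend is fitted as an
exponential

```
Leaf_trend(t) = a · exp(b · t)
```

by log-linear least squares on the days with 2–12 leaves; the population
reference is the arithmetic mean of the per-plant trends,
`mean_trend(t) = (1/N) Σ aᵢ·exp(bᵢ·t)`. For each plant, candidate integer
delays `k` are scored by the mean squared deviation

```
MSD(k) = (1/n) Σ_t ( Leaf_meas(t − k) − mean_trend(t) )²
```

over the `n` overlapping days; the minimizer `s` (ties break toward the
smallest `|k|`) shifts the leaf and area series, and a further whole-day
adjustment `Δt` (chosen by the same criterion on log area against the mean
area trend) compensates for leaf-expansion maturity differences:
`Area_shift(t) = Area_meas(t − s + Δt)`. Because averaging exponentials is
biased toward the most advanced plants, the mean trend is re-estimated
from the shifted series and the shifts re-selected for a few refinement
passes. Shifting only re-indexes days: no measured value is interpolated
or rescaled, and within-day (diurnal) area oscillations survive untouched.

Upstream of the normalization, the rosette is segmented from a pot crop by
a decision tree that routes the crop (based on foreground fraction, hue
and excess-green features of an Otsu mask on `2G − R − B`) to K-means
pixel clustering, hue-histogram analysis (Savitzky–Golay smoothed, with a
spatial-correlation cleanup), or a shape-assisted hue pipeline; the chosen
method runs under several random gamma corrections and the runs vote
pixel-wise. Leaves are counted by a watershed of the inverted distance
transform seeded at leaf markers, and a leaf fully hidden below younger
leaves lowers the count by exactly one — the occlusion term above.

## Worked example

```python
from dapd import PopulationSpec, generate_population, DevelopmentalNormalizer
from dapd.evaluate import dispersion_curves, dispersion_ratio

spec = PopulationSpec(n_plants=14, shift_dist=("balanced", -3, 3),
                      a_dist=(0.9, 0.0), b_dist=(0.085, 0.0), seed=5)
plants, true_shifts = generate_population(spec)

norm = DevelopmentalNormalizer().fit(plants)
normalized = norm.transform(plants)
print(norm.report().head(6).to_string(index=False))
```

```
plant_id  s  delta_t  min_msd flags
plant000  1        0 0.098495
plant001  0        0 0.093428
plant002  0        0 0.103641
plant003  2        0 0.088791
plant004  3        0 0.100607
plant005 -3        0 0.096251
```

Each plant's selected delay `s` is the negative of its germination offset
(the first six true offsets are `[-1, 0, 0, -2, -3, 3]`), `delta_t` is the
extra whole-day area adjustment, and `min_msd` the residual deviation from
the population mean leaf trend at the chosen delay. Aligning the
population collapses the area dispersion at the final day:

```python
raw = dispersion_curves(plants)
post = dispersion_curves(normalized)
print(dispersion_ratio(raw, post, 32))
```

prints a day-32 SD ratio of `44.9` for this noise-only population (the SD
falls from 485 mm² to 11 mm²); with realistic between-plant coefficient
variation the ratio is in the range 4–8.

The image side is just as direct:

```python
from dapd import RosetteSpec, generate_rosette_image, segment_rosette, count_leaves

rgb, truth = generate_rosette_image(
    RosetteSpec(n_leaves=8, overlap_fraction=0.2, background="soil"), seed=1)
mask = segment_rosette(rgb, seed=0)
print(count_leaves(mask).leaf_count)   # -> 8
```

A `dapd` command-line tool exposes every stage
(`dapd simulate | segment | count-leaves | normalize | evaluate | outliers`)
over PNG/CSV/YAML artifacts; see `dapd --help`.

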