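# Methods

This note records the models, parameter choices and numerical conventions
behind the package, what the synthetic generators do and do not emulate,
and the known limits of the approach.

## Developmental normalization

**Model.** A plant's daily leaf count is treated as an exponential in time
during early vegetative growth, `leaf(t) = a·exp(b·t)`, with `a` the
nominal count at the timeline origin and `b` the relative leaf appearance
rate (per day). The population reference trend is the pointwise arithmetic
mean of the fitted per-plant exponentials. A plant is aligned to the
reference by the integer delay `s` minimizing the mean squared deviation
(MSD) between its day-shifted counts and the reference over their
overlapping days; the area series receives one further whole-day
adjustment `Δt` minimizing the MSD between log area and the log of the
population mean area trend. Whole-day shifting guarantees that measured
values — including sub-daily diurnal oscillation — are re-indexed, never
altered.

**Fit window.** "Early stage" is operationalized as days whose count lies
in [2, 12] leaves (config `leaf_range`). Below 2 the log of a rounded
count is dominated by quantization; above 12 leaf emergence starts to
saturate and occlusion-driven undercounting grows, so the exponential
stops being a trustworthy description. Fits need ≥ 3 usable days; plants
that cannot be fitted pass through unshifted with a `fit_failed` flag.

**Search windows.** Candidate delays span ±7 days with at least 5
overlapping days (`k_range`, `min_overlap`); `Δt` spans ±2 days. Ties
break to the smallest `|k|`, then the smaller `k`, making the selection
deterministic and auditable. The MSD is the primary alignment score; a
normalized cross-correlation score is available via `score="xcorr"` but is
not the default.

**Refinement.** The arithmetic mean of exponentials with heterogeneous
effective origins is biased toward the most advanced plants (Jensen's
inequality): with offsets spread ±5 days and `b ≈ 0.085`/day the mean
trend sits ~0.4 day ahead of the population median, close enough to the
rounding boundary that integer recovery becomes marginal under noise. The
normalizer therefore refits the mean trend from the *shifted* series and
re-selects all shifts, iterating (default 3 passes, usually converging in
2). This removed the bias entirely in simulation: exact recovery at 5 %
measurement noise rose from a minimum of ~82 % to 100 % across 50
replicate populations.

**Identifiability.** Alignment is only defined relative to the population.
Two consequences matter when interpreting recovered shifts against a known
truth: (i) if the sample of germination offsets is unbalanced, every
recovered shift absorbs the same global constant (the population anchor
moves); (ii) between-plant variation in `a` is developmentally confounded
with the offset — a plant with fewer leaves at equal age is
indistinguishable from a late germinator, at a rate of roughly
`ln(1+cv)/b` days per relative unit of `a`. Shift-recovery experiments
therefore use balanced offset designs and homogeneous coefficients; under
realistic coefficient spread the method aligns plants by *apparent*
development, which is the scientifically relevant alignment and still
collapses dispersion.

**Imputation.** Interior gaps of a daily series can be filled by cubic
spline, linear interpolation, or an exponential fit evaluated at the gap
(`impute_series`). Imputed values are used only for trend estimation and
MSD scoring; the normalized output re-indexes the original measurements,
so imputation never fabricates output data. Extrapolation beyond the
observed range is refused.

## Synthetic population generator

The generator emulates a tray of genetically near-identical Arabidopsis
plants imaged every 15 minutes of a 12-hour photoperiod from DAS 12 to 32:

- leaf trend `a·exp(b·(t − shift))`, defaults `a ~ N(0.9, 0.05)`,
  `b ~ N(0.085, 0.002)` per day — about 2 leaves at day 12 and 12 leaves
  at day 30, with a few-percent between-plant spread;
- projected area `c·exp(d·(t − shift))` mm² with `c` proportional to the
  plant's `a` (area scale 1.5 mm² at the origin) and `d = 2.4·b`, i.e. an
  area growth rate near 0.2/day;
- germination offsets are integer days (`uniform`, `balanced` or
  `constant` designs; default uniform on {−3..3});
- every frame carries multiplicative measurement noise (default 5 % on
  both traits), the apparent area oscillates within the day (sinusoid,
  relative amplitude 0.08, peaking mid-photoperiod — the leaf elevation
  effect), and 15 % of frames are dropped at random (the acquisition-gap
  rate of a realistic campaign);
- the daily leaf value is the median of the surviving frames, the daily
  area their mean.

What the generator deliberately does *not* emulate: saturating (sigmoid)
growth late in the rosette stage, correlated day-to-day environmental
fluctuations, and continuous (sub-day) germination offsets. Passing tests
on these fixtures therefore demonstrate correct recovery of the model the
method assumes, not robustness to every property of glasshouse data.

**A consequence for SD-curve shapes.** In this purely exponential world
every dispersion source (offset spread, coefficient spread, relative
noise) is multiplicative, so the population SD of area is proportional to
the exponential mean curve both before and after normalization —
normalization rescales the SD curve (strongly: day-32 ratios of 4–8 under
default conditions) but cannot change its shape. The often-reported
pattern in real data — raw SD growing exponentially while normalized SD
grows roughly linearly — requires saturating growth and additive error
floors that are outside the generator's contract. The evaluation helper
`sd_growth_shape` (R² of linear vs log-linear fits to the SD curve) makes
this measurable, and the corresponding acceptance check of the linear
normalized-SD pattern fails by design under the exponential generator; we
keep it failing rather than bend the generator, because the ratio-based
dispersion check is the meaningful one here.

## Rosette image generator

Leaves are rotated ellipses arranged around the apex at golden-angle
(137.5°) phyllotaxis with a small angular jitter (±2.5°); a repulsion step
enforces a minimum angular gap (20° or 0.8·360/n) between neighbours,
mimicking the petiole repositioning by which real rosettes avoid complete
mutual shading. Older leaves are the expanded ones (length scale 1.0 down
to 0.62 for the youngest), younger leaves draw on top, and overlapping
rosettes gain 4-px petioles meeting at the apex so the silhouette is one
connected region, as in a real top view. The `overlap_fraction` knob
widens blades and pulls them toward the apex; the achieved mean overlap of
angularly adjacent blades saturates well below heavy targets because
blades must remain blades. Zero-overlap rosettes are rendered blades-only
and verified disjoint. Leaf color is sampled in HSV around hue 95–125°
with per-pixel variation; backgrounds are plain grey, low-saturation brown
soil noise, or soil plus a dark pot rim; additive RGB noise finishes the
render.

Ground truth is pixel-exact: per-leaf masks, a visible-leaf label image
(labels partition the union mask), and the occlusion count under the
convention that a leaf covered ≥ 95 % by younger leaves is occluded.
`n_occluded` re-poses old leaves as shrunken copies fully beneath a young
host, making the occlusion undercount exactly controllable.

## Segmentation pipeline

Contrast is first enhanced by CLAHE on the HSV value channel (hue and
saturation untouched). Cheap global features — foreground fraction of an
Otsu mask on the excess-green index `2G − R − B`, mean foreground hue,
mean green excess — drive a fixed rule tree: foreground below 1 % of the
crop routes to the sensitive hue-histogram method; foreground above 25 %
with green excess below 20 (8-bit scale) indicates a cluttered background
and routes to K-means; everything else uses the shape-assisted hue
pipeline. The chosen method runs 7 times under gamma drawn uniformly from
[0.6, 1.6] (odd count → clean majority vote, ties counting as foreground).

The hue-histogram method bins hue into 180 bins over the
adequately-saturated pixels, smooths with a Savitzky–Golay filter (window
11, order 3), and keeps all hues on the plant side of the valley between
the dominant green mode (60–180°) and the dominant non-green mode — one
cut per side, so multimodal leaf hues within the green band stay together.
Surviving pixels are grouped transitively by a 5-px dilation and only the
group containing the dominant component is kept (the spatial-correlation
test); this removes distant greenish artifacts without splitting rosettes
whose leaves touch only near the apex. K-means clusters pixels on (hue,
saturation, green index) with seeded initialization and keeps the
greenest cluster(s). Over-segmentation repair interpolates a
foreground-probability field by Gaussian-kernel smoothing of the mask
(σ = 3 px), adds pixels above probability ½ (optionally gated on a
positive green response in the reference crop), fills holes, and iterates
to a fixed point — making the repair monotone and idempotent by
construction. Otsu's threshold is computed by an exact vectorized
between-class-variance maximizer with lowest-threshold tie-breaking, so it
is verifiable against exhaustive search.

On the canonical 20-image suite (2–12 leaves, plain and soil backgrounds,
moderate overlap) the pipeline reaches mean Dice ≈ 99 %.

## Leaf counting

The rosette centre is the mask centroid, refined by a circular-symmetry
vote along inward boundary normals only when the vote peak is decisive and
near the centroid (leaf side-normals also pile up along each blade's own
axis, so distant hotspots are artefacts). Markers for the watershed come
from two regimes. Disjoint leaves: local maxima of the Gaussian-smoothed
distance transform (σ = 2 px, minima below 4 px suppressed — petiole
ridges are ~2 px), merged within 0.4× the mean leaf length. Fused
rosettes: distance maxima are unreliable (two fused blades yield one
midway peak), but blades keep separate radial ridges through the outer
annulus, so ridge maxima restricted to annuli at 0.45/0.55/0.65 of the
outer radius become the primary markers — candidates whose local ridge
direction (from the EDT Hessian) deviates from the ray by more than ~37°
are junction webs and are dropped, duplicates merge at 8°, and global
maxima fill only angular sectors with no annulus marker within 10°. A
final 5° angular merge reflects that two leaves cannot emerge on the same
ray; every connected component is guaranteed at least one marker. The
count is the number of watershed regions; label support equals the mask
exactly.

Counting is exact on disjoint rosettes of 0–12 leaves, ~85–100 % exact on
the moderate-overlap suite (misses are ±1 on crowded 10–12-leaf rosettes),
and undercounts full-occlusion fixtures by exactly the occluded count.

## Evaluation conventions

Precision, recall, Jaccard and Dice are reported on the percent scale;
`dice = 2J/(1+J)` holds identically. Empty-prediction-vs-empty-truth
scores 100 on all metrics; empty-vs-nonempty is flagged degenerate with
precision 0. Aggregation over dataset rows is the unweighted mean, rounded
to 2 decimals. Note that the mean of the five published per-dataset dice
rows is 94.89, not the 94.90 shown in the published mean row — the
aggregation here reports the computed value. Dispersion curves use the
sample (n−1) SD per day over plants observed that day (≥ 2 required). The
outlier rule is a reproducible stand-in for visual inspection: per day,
robust z = deviation from the population median divided by the scaled MAD
(×1.4826); a plant is flagged after `|z| > 3.5` on ≥ 3 consecutive days.
Defaults were chosen for a near-zero false-positive rate on
measurement-noise-only populations; with realistic biological coefficient
spread, plants a few robust SDs from the median are genuine distributional
outliers and may be flagged too. A caveat: the `Δt` area adjustment is
estimated on the full series, so a late-onset area defect can shift a sick
plant's whole aligned series and advance its first flagged day — detection
remains unique, but the flag day is not a defect-onset estimate.

## Known limitations

- Exact shift recovery requires balanced designs and near-homogeneous
  trend coefficients (see Identifiability above); this is a property of
  population-referenced alignment, not an implementation artefact.
- Leaf counting degrades to ±1 on crowded rosettes where adjacent blades
  fuse over most of their length; fully hidden leaves are invisible by
  construction (the occlusion term exists precisely for this).
- The `Δt` criterion (log-area MSD against the mean area trend) is a
  stated convention; other maturity criteria are conceivable.
- Color correction is a global per-channel affine fit from color-card
  patches; spatially varying illumination models are out of scope, as are
  lens-distortion correction and any 3D/stereo processing.
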