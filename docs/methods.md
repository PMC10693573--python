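# Methods

## The model

The luminal surface of the secretory-phase endometrium carries two kinds of
segmentable elements: gland outlets (pores) and superficial blood vessels.
Their per-specimen morphometry is treated as a statistical ensemble: each
feature (pore area, pore length, rim curvature, rim tortuosity, vessel
diameter, vessel segment length) contributes one empirical distribution per
specimen.  The cumulative distribution of every feature is modelled by the
three-parameter Weibull function `We(x) = 1 − exp(−((x − b)/λ)^γ)`:

* `b` (location, feature units) — the smallest observable value, set
  jointly by biology and the optical resolution limit; it is therefore
  **fixed per feature and magnification**, not fitted.  Joint maximum
  likelihood over `(b, λ, γ)` is notoriously unstable (the likelihood is
  unbounded as `b → x_min` for `γ < 1`), so fitting `b` is an explicit
  opt-in (`location_policy="min-offset"` or a fixed value).
* `λ` (scale, feature units, > 0) — the stretch of the distribution.
* `γ` (shape, > 0) — `γ < 1` piles the PDF against the resolution floor,
  `γ > 1` gives an interior mode that narrows as `γ` grows.

`(λ, γ)` are fitted by maximum likelihood on the shifted values
(`scipy.stats.weibull_min` with the location pinned to zero); if MLE fails
to converge, a least-squares fit of the model cPDF to the empirical cPDF is
used instead, and the chosen route is recorded in the fit diagnostics
together with the sup-distance between fitted and empirical cPDF.

## Distribution comparison and day inference

Two ensembles are compared with the two-sample Kolmogorov–Smirnov
statistic, computed exactly as the supremum of |cPDF₁ − cPDF₂| over the
union of the support points.  Weighted samples use the Kish effective size
`(Σw)²/Σw²`; the p-value is asymptotic (Kolmogorov distribution at
`√(n₁n₂/(n₁+n₂))·D`).  The implementation is cross-checked in the tests
against a brute-force enumeration oracle and against `scipy.stats.ks_2samp`
on unweighted data.

The per-day dictionary pools all specimens sharing a (histology-labelled)
day; pooling weights are element counts, so pooling is implemented as
concatenation of the element samples — a patient contributing more elements
counts proportionally more.  A specimen's score for day `d` is the
arithmetic mean of the KS p-values over the four pore features ("equal
weights"); a geometric-mean (Fisher-style) combination is available via
`combine="geometric"`, since the combining algebra is a genuinely open
choice.  Vessel features can be added to the feature set but are off by
default.  The raw profile is smoothed with a five-day top-hat window
(truncated and renormalised at the range edges, then normalised to sum 1)
and the argmax is the inferred day; exact plateau ties break to the
score-weighted centroid rounded to the nearest day, which is deterministic.
Day-level uncertainty comes from the day-vs-day confusion matrix of pooled
distributions, smoothed with a separable 3×3 binomial (Gaussian) kernel and
row-normalised; the ± error of a day is the contiguous half-width around
the diagonal where the relative probability stays ≥ 0.5.  A derivative
(Sobel) kernel cannot smooth, so a Gaussian kernel is the only sensible
reading of the smoothing step and is what is implemented.

The day grid is integer (whole days, no sub-day interpolation), default
range 15–28 of the standard 28-day calendar: histological dating — the
label source for the dictionary — is only reliable in the secretory phase,
and the proliferative phase has no per-day calibration here.

## Reference datings

* **Cycle renormalization.**  Day `d` of an `L`-day cycle maps to the
  28-day standard assuming a fixed 14-day luteal phase: ovulation at
  `O = L − 14`, `d' = 14·d/O` for `d ≤ O`, else `d' = 14 + (d − O)`,
  rounded to 2 decimals.  The formula is isolated in one function so an
  alternative convention can be swapped in.
* **Hormones.**  `χ²(d) = Σ_h (x_h − μ_{h,d})²/(σ_meas,h² + σ_ref,h,d²)`
  over a 30-day reference profile anchored at the LH peak; the argmin day
  converts to the standard calendar through the renormalization map, and
  the ± error covers reference days with `Δχ² ≤ 1` (the single-parameter
  confidence convention, recorded in the output).  Hormones with zero total
  variance at a day are excluded from that day's sum with a warning; if
  that leaves nothing anywhere, the panel is rejected.
* **Patient report.**  Day = days since the reported first menses day
  (inclusive), renormalized with the reported mean cycle length; the
  reported cycle-length variance propagates through the local slope of the
  renormalization map.
* **Histology.**  The consensus day passes through unchanged with its
  asymmetric error — histological dating is already calendar-normalised by
  its own criteria.
* **Ultrasound thickness** is carried in the records but never converted
  into a dating; it has no established per-day mapping.

Concordance between methods: Pearson R with a t-transform p-value, the
adjusted coefficient `R_adj = sign(R)·√(1 − (1−R²)(n−1)/(n−2))` (reported
alongside plain R so the adjustment is transparent), an OLS regression line
by default and an equal-variance Deming line as an errors-in-variables
opt-in, and a mean offset with an exact binomial sign test for systematic
bias.

## The synthetic generator

The generator exists so that every pipeline stage has ground truth.  It
emulates three layers:

1. **Feature ensembles.**  A per-day trajectory table assigns `(b, λ, γ)`
   to every feature; elements are drawn by inverse-transform sampling
   `x = b + λ(−ln U)^{1/γ}`.  No quantitative per-day parameter values are
   published for real tissue, so the default table is synthetic: smooth
   curves honouring the qualitative regimes (pore-area `γ < 1` on all
   secretory days; pore-length `γ > 1` only in the pore-merging window
   around days 20–22; vessel-diameter `γ > 1` throughout, dipping near day
   19) with scale ramps of roughly 7–11% per day.  The drift is deliberately
   large enough that neighbouring days are statistically distinguishable at
   a few hundred elements per specimen — that discriminability is the study
   condition the dating benchmarks assume, and the table is fully editable
   via YAML for other regimes.
2. **Images.**  Pores render as dark blobs whose rim is a radial Fourier
   perturbation (modes 3–7) of an ellipse; the perturbation amplitude is
   bisected numerically until the measured tortuosity (same
   resample–smooth–hull measure morphometry uses) matches the sampled
   target, and the polygon is rescaled so its shoelace area equals the
   sampled area exactly.  Sampled lengths are clamped to a maximum aspect
   ratio of 4 so that independently drawn (area, length) pairs cannot imply
   unrenderable slivers.  Vessels render as dark curvilinear bands of the
   sampled diameter along smooth random paths of the sampled segment
   length.  Elements are rejection-placed with a minimum clearance of 4 px
   so benchmark scenes are truly non-overlapping; a requested filling
   factor above the configured maximum raises.  The background is Gaussian
   texture; an optional Gaussian-blurred patch exercises the focus gate and
   is recorded in the in-focus mask.  Noise is Gaussian throughout — chosen
   for reproducibility, not realism.
3. **Cohorts.**  Per patient: a true standard day; a cycle length
   `N(28, 2.5²)` clipped to 25–35 days; a reported day (inverse
   renormalization of the true day into the own cycle plus integer
   reporting noise, default SD 1 day); a histology day (true day plus a
   discrete kernel, default P(0)=0.6, P(±1)=0.15, P(±2)=0.05 — the ±1-day
   scatter scale of consensus histology); a hormone panel (reference mean
   at the mapped 30-day reference day plus Gaussian noise at the tabulated
   SD); and either a direct feature table or rendered images with truth.

The shipped hormone reference is synthetic (the assay manufacturers'
tables are proprietary): smooth anchor-interpolated curves with the LH/FSH
surge at reference day 16, a luteal progesterone rise-plateau-fall and a
biphasic estradiol curve.  The curves are designed so the four-hormone
trajectory never nearly revisits itself and moves by about one tabulated
SD per day, which is what makes χ² dating well-posed on every day; the χ²
machinery itself accepts any CSV-shaped reference.

**What passing tests do not show:** the generator's elements are
independent draws with no spatial correlation, no staining or illumination
gradients, no specular artefacts, no out-of-plane tissue, and feature
values drawn independently per element (real pores have correlated
area/length/tortuosity).  Benchmarks passed on this material demonstrate
the correctness and internal consistency of the computational chain, not
clinical accuracy.

## Segmentation pipeline

No segmentation algorithm is prescribed for this problem, so a classical,
deterministic pipeline was chosen over a learned one:

* **Focus gating** — variance of the Laplacian response in a 31-px sliding
  window, thresholded at 5·10⁻⁴ (images normalised to [0, 1]), then
  border-safe morphological opening/closing.  Constant or fully blurred
  images yield an empty mask, not an error.
* **Pores** — threshold at 0.10 below the in-focus background median,
  small-structure opening, hole filling; each candidate region is then
  re-segmented at the half-contrast level between the background and its
  own core intensity (10th percentile), which removes the area bias the
  soft edge ramp would otherwise introduce.  Filters: area within
  [20, 5·10⁴] µm², solidity ≥ 0.75, max/min Feret ratio ≤ 6, and a core at
  least 0.35 below background (vessel lumina are darker than background but
  shallower than gland outlets).  Merged pore candidates are **not** split:
  coalescing outlets are treated as real biology, not as segmentation
  errors.  The optional quality score is the mean boundary gradient
  contrast, off by default.
* **Vessels** — multiscale Sato tubeness (σ ∈ {2, 4, 6} px) on the
  pore-masked image, thresholded at 0.15 of its maximum, skeletonised,
  split at branch points (pixels with ≥ 3 skeleton neighbours); per-point
  width is twice the Euclidean distance transform of the *intensity*
  half-contrast mask at the centreline (the tubeness support depends on the
  ridge threshold and systematically overestimates widths).  Segments
  shorter than 10 skeleton px, shallower than 0.10 below background, or
  with length below 2.5× their mean width (blob-shaped fragments) are
  discarded.
* **Collation** — detections of all images of a specimen concatenate into
  one ensemble, partitioned by magnification (2X and 4X have different
  resolution floors `b` and are never mixed); the analyzed area is the
  in-focus area.  Overlapping fields of view are *not* de-duplicated —
  images are treated as disjoint samples, a simplification worth noting
  for densely tiled acquisitions.

## Morphometry definitions

"Length", "rim curvature", "tortuosity" and "vessel density" have no
canonical definitions in this context; the choices here, each isolated
behind one function so alternatives can be substituted:

* length = maximum Feret (caliper) diameter — reads elongation directly;
* rim curvature = mean |κ| along the boundary after resampling to 128
  points equidistant in arc length and circular moving-average smoothing
  over 5% of the perimeter (suppresses pixelation noise and makes the
  number comparable across pore sizes; a circle of radius r gives 1/r);
* rim tortuosity = perimeter / convex-hull perimeter of that same smoothed
  resampled boundary — bounded below by 1 and reading "wiggles" directly;
* vessel density = total centreline length per area (mm/mm²) — robust to
  width errors; count- and area-based variants would react differently to
  branching.

All features are physical (µm-based) via the image pixel size, so
magnification sets share axes while remaining separate ensembles.

## Numerical choices and degenerate inputs

* Histogram axes are fixed per feature (default 24 bins spanning
  [b, 99th percentile of pooled data]) so per-day histograms are
  comparable; the KS path never uses histograms, only exact ECDFs.
* KS with `D = 0` returns `p = 1` exactly; all-zero day profiles raise an
  "unclassifiable" error rather than returning an arbitrary day.
* `fit_weibull` requires ≥ 20 observations, rejects degenerate
  (all-identical) samples and values at or below a fixed location.
* Windowing preserves normalisation (profile sums to 1) and cannot move a
  symmetric unimodal peak; edge windows renormalise by their actual size.
* Seeds: every stochastic routine takes a seed or Generator;
  per-patient streams come from `SeedSequence.spawn`, so cohorts are
  byte-identical under a fixed seed regardless of patient count order.

## Benchmark problem sizes

The shipped benchmarks use: 2000-draw samples (50 replicates) for
parameter recovery; 20 rendered scenes of 50 pores + 10 vessels for the
segmentation benchmark; dictionaries of 3×1000 elements per day and 100
fresh 300-element samples per day for day recovery; 200 noisy panels per
day for hormone dating; and a 40-patient imaged cohort (4 images × 50
pores each) with leave-one-out dictionaries for the end-to-end
correlation.  These sizes keep the whole suite desk-scale while leaving
the measured rates well clear of their thresholds; the reproduction script
uses slightly smaller replicate counts for the same quantities.

## Known limitations

* The default trajectory table and hormone profile are synthetic devices,
  not estimates of published tissue values; absolute numbers from them
  carry no clinical meaning.
* Dictionary labels default to histology days, whose own ±1–2-day noise
  propagates into the dictionary; the end-to-end benchmark against ground
  truth sidesteps this, clinical use would not.
* Across-image de-duplication of elements is not attempted.
* The proliferative phase is supported by configuration but has no
  calibrated trajectories; the window-of-implantation "pace" extrapolation
  sketched in the motivating literature is out of scope.
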