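# Methods

This note records the models, conventions and design choices behind
`ctmaster`, in the order the pipeline runs them.

## Size measurement from localizer radiographs

Patient size is the sum of the anterior–posterior and lateral widths
(AP+LAT, cm) measured on the two standard localizer views. Per detector row
the pipeline is: (1) Savitzky–Golay smoothing along the row (window 15 px,
polynomial order 2 — the window/order are configurable since no canonical
values exist; 15 px ≈ 1.5 cm at typical localizer spacing suppresses noise
without eroding the body edge); (2) saturation of the highest and lowest 5%
of the smoothed intensity distribution, computed per image (a per-row option
exists); (3) a threshold at 30% of the saturated maximum, which removes the
couch because couch attenuation is well below 30% of soft tissue; (4) width
= count of supra-threshold pixels × pixel spacing. Rows in the central 80%
of the z range are averaged. The width is a pixel *count*, not a span, so
internal sub-threshold gaps reduce it; the threshold is relative, making the
measurement invariant to global intensity scaling.

Degenerate inputs: an image whose saturated maximum is not positive raises
`NoPatientFoundError` (with a relative threshold an "everything below
threshold" state is otherwise unreachable); images narrower than the
smoothing window are rejected.

## Exam mA statistics and the exponential size model

Each exam is summarized by the 10th/50th/90th percentiles of its per-image
mA values (linear interpolation between order statistics — stated because
percentile definitions differ). Quartile-based whiskers flag far too many
points on thorax-to-pelvis anatomy, where lung-field and pelvis mA differ by
several fold; instead a point is an outlier when it lies more than
1.5 × (p90 − p10) outside the [p10, p90] band (configurable). Whiskers span
all non-outlier points and are widened to cover the percentile band itself
in near-constant distributions, keeping the summary's ordering invariants
unconditional.

Each percentile statistic is fitted against size as `a·e^(b·s)` by ordinary
least squares on `ln(stat) = ln(a) + b·s`. The log-linear form reproduces
the stated model class exactly, is convex, and is exact to machine precision
on noiseless exponential data; a nonlinear refinement was considered and
rejected as adding nothing at the noise levels of interest. Fits require at
least three distinct sizes.

Protocol limits per size class (small < 55 ≤ medium < 75 ≤ large, half-open
intervals so boundary sizes belong to the upper class): `ma_max` is the p90
curve at the class's upper bound, evaluated at 100 cm for the unbounded
large class; `ma_min` is the p10 curve at the lower bound. Both snap to the
nearest 5 mA station (the console granularity; rounding before floor
clamping reproduces the published 640/200/50/15 mA examples from the raw
scale arithmetic), then `ma_min` is clamped up to the institutional
minimum-current policy (30–50 mA depending on platform). An optional size
margin evaluates slightly beyond the class bounds, since scanner-reported mA
is a rotation average; its default is 0. Evaluation more than 25 cm outside
the fitted size support emits `ExtrapolationWarning`.

Rail events are images whose mA lies within 1 mA (configurable) of the
protocol's configured ceiling or floor; the per-exam ceiling/floor fractions
are the protocol-health surrogate.

## Customization rules and factors

Within-scanner (quality change) and cross-scanner (equal quality) scale
rules are given in the README. Conventions fixed here:

* **NI normalization.** Noise index values are stored at their quoted
  reference slice thickness and rescaled as NI ∝ 1/√thickness to a common
  thickness before entering the within-scanner rule. All stored NI values
  are pre-denoising; denoisers act only through F_D.
* **Pitch direction.** The numerator carries P_new, the denominator P_orig —
  equivalent to conserving effective mAs (mA·t/P) when quality, energy and
  geometry are unchanged. This direction is what reproduces the published
  lower-pitch worked value (458.8 mA).
* **F_kV direction.** Tabulated factors describe high→low kV moves; a
  low→high move uses the reciprocal, non-adjacent moves chain the
  intermediate stations, and an explicit override always wins (task-specific
  values, e.g. 0.8 for a 100→120 kV move where non-iodinated structures
  matter, are a clinical judgement and never auto-derived).
* **F_SS** is a pure pass-through multiplier (default 1) in both rules, for
  scanner pairs whose beam filtration or detector response differ; no
  formula is modeled for it.
* **Rounding.** Scaled limits snap to 5 mA stations *before* the floor
  clamp. Trade-off option tables keep unrounded mA so near-limit options can
  be judged to ±1 mA.
* **Feasibility** is evaluated at the protocol's `ma_max` against the
  target scanner's ceiling for the protocol's kV station, with margins
  reported as percentages. An infeasible customization is a recorded
  verdict, not an exception — rejected options are part of the trade-off
  analysis.
* **Option enumeration** defaults to the cross-scanner rule. In that mode a
  candidate's NI is metadata: when the kV changes, the NI shifts to
  compensate the contrast change at fixed CNR, and that same physics is
  already carried by F_kV, so applying an NI ratio on top would double-count
  it. This choice reproduces every mA cell of the published trade-off table,
  including the rows that are inconsistent with applying the NI-aware rule.
  Feasible options are ranked by scan duration; an optional maximum-duration
  constraint flags slower options infeasible rather than hiding them.

## QA comparison

Percent acceptance is good reads over all reads. Comparisons use the
two-tailed Fisher exact test with the minimum-likelihood two-sided rule (the
sum of hypergeometric probabilities of all tables with the observed margins
whose probability does not exceed the observed one — stated because
two-sided conventions differ). The summation runs in exact integer
arithmetic so probability ties are decided exactly; only the final ratio is
floating point. Significance defaults to p < 0.005. Because large samples
make negligible differences significant, the report also flags whether the
rate difference lies within a practical-equivalence margin (default 1
percentage point).

## Synthetic data: what it emulates and what it does not

The localizer phantom is a constant-width torso silhouette with a steep
elliptical intensity shoulder (full intensity except in a thin edge zone).
This makes the geometric extent — the generator's ground truth — the
quantity the 30%-threshold pipeline should recover; a physically
proportional chord-length projection would make "true width" depend on the
threshold itself and leave nothing exact to test against. The couch is a
band at 20% of body intensity (superimposed across the frontal view,
a posterior side band in the lateral view); its exclusion relies solely on
the 30% threshold, as in the clinical procedure. Not emulated: attenuation
line integrals, scatter, collimation shading, arms-down artifacts, or
vendor-specific localizer processing — passing size tests therefore
demonstrates the thresholding pipeline's correctness, not its robustness to
every clinical confounder.

Exam populations draw patient size from a truncated normal
(mean 62, SD 10, range 40–100 cm — the size axis adult abdominal demand
data spans), then per-image mA lognormally around the truth median curve
with within-exam spread matched to the truth p90/median ratio, an exam-level
multiplicative lognormal factor of cv 0.10, and 40 images per exam. Values
are optionally clipped to a protocol's mA range, which is how rail events
emerge for the largest patients. The generator reproduces the fitted
percentile structure of real populations but not AEC waveform shape,
z-correlation of mA along the patient, or kV-dependent demand.

DICOM fixtures are minimal but standard-conformant; per-image mA is written
both as the floating-point attribute (read back exactly) and the classic
integer one, and all UIDs derive deterministically from the record content
so generators are pure functions of their arguments including the seed.

## Numerical choices

* Station rounding: half-up to the step multiple (`floor(x/step + 0.5)`),
  deterministic across platforms.
* Fisher p-values are exact rationals evaluated as one float division;
  agreement with an independent float-pmf enumeration oracle is verified to
  1e-12 over every 2×2 table with total ≤ 60.
* Percentiles: numpy linear interpolation, verified against a sort-based
  oracle.
* Rail tolerance 1 mA: scanner-reported averages near a rail differ from it
  by less than a station but not exactly zero.

## Problem sizes in the test-suite

The stochastic checks run at the sizes the methodology is quoted at: 100
seeded populations of 200 exams × 40 images for fit recovery (median
relative error of b under 5%; observed ≈ 1.3%), phantom widths 20–45 cm in
2.5 cm steps for size recovery (tolerance 3 px; observed ≤ 2 px), and the
exhaustive Fisher sweep at total ≤ 60. The full suite runs in well under a
minute on one CPU.

## Known limitations

Vendor AEC internals are out of scope: the package treats the noise index
as the AEC parameter and assumes dose ∝ 1/NI²; platforms with differently
calibrated AEC (captured only as a free-text note on the scanner record)
cannot be derived analytically and need a measured F_SS. Dose metrics
(CTDIvol/SSDE) and model-observer detectability are not computed. Anode
heat capacity is modeled only as a static per-kV mA ceiling.
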