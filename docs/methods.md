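# Methods

`cannaspec` implements a hyperspectral-imaging pipeline for non-destructive
quality assessment of cannabis flowers during postharvest drying.  This note
documents the models and procedures, the parameters that matter, what the
synthetic benchmark does and does not emulate, and the design choices made
where the protocol was genuinely open.

## Pipeline overview

Reflectance cubes (nominally 682 × 1,540 px × 150 bands over 400–1,000 nm)
pass through six stages:

1. **Segmentation.** A normalized band difference,
   `NBD = (R_764.74 − R_684.69) / (R_764.74 + R_684.69)`, separates plant
   from background; pixels with NBD strictly greater than 0.3 form the
   region of interest (ROI).
2. **Patch extraction.** Non-overlapping 20 × 20 px patches covering
   strictly more than 70 % ROI pixels are placed greedily in raster order;
   each patch contributes its ROI-pixel mean spectrum to the feature table.
3. **Labeling.** Four categorical targets come from fixed intervals on
   drying and chemistry quantities: relative water content
   `RWC = 100 (w_t − w_0·DM) / w_t` with dry-matter ratio `DM = 0.21894`;
   the conversion ratios `C/TC = 100·CBD/(CBD+CBDA)` and
   `T/TT = 100·THC/(THC+THCA)`; and the chemotype ratio
   `C/T = totalCBD/totalTHC`.  Dryness bins at (0,10]/(10,40]/(40,100],
   CBDA conversion at (0,20]/(20,60]/(60,100], THCA conversion at
   (0,20]/(20,50]/(50,100], and C:T asymmetrically at (0,20) vs [20,100].
   All intervals are open at zero; a quantity of exactly 0 raises rather
   than being silently binned.
4. **Preprocessing.** Five chemometric pre-treatments: raw, Savitzky–Golay
   smoothing (window 5, polynomial order 3), SG first and second
   derivatives (same window/order, scaled by the 4.0025 nm band spacing),
   and multiplicative scatter correction (per-spectrum OLS fit
   `x ≈ a + b·ref`, corrected to `(x − a)/b`, reference = calibration-set
   mean).  MSC is the only stateful method; its reference is frozen on
   calibration data and reused everywhere downstream, including pixel maps.
5. **Model selection.** One global random 8:2 calibration/prediction split
   (prediction size = ⌈0.2·N⌉, shared by all four targets), then a
   5 preprocessing × 5 classifier grid — logistic regression (LR), RBF SVM,
   5-nearest-neighbours, 100-tree random forest, Gaussian naive Bayes —
   scored by 10-fold cross-validated accuracy with all stateful
   preprocessing refitted inside each training fold.  The arg-max cell wins;
   ties break in fixed method order (raw, sg, der1, der2, msc) then
   classifier order (LR, SVM, KNN, RF, GNB).  LR and SVM handle three-class
   targets one-vs-rest; LR's per-class probability is the sigmoid
   `P = 1/(1+e^{−(β₀+Σβᵢxᵢ)})` of the stored coefficients.
6. **Evaluation and mapping.** Metrics come from the confusion matrix via
   a one-vs-rest reduction: accuracy = trace/total, precision and recall
   macro-averaged, and the reported F1 is the harmonic mean of the macro
   precision and macro recall (this convention — not the macro average of
   per-class F1 — reproduces the published report rows from their printed
   precision/recall).  ROC curves sweep unique score thresholds per class;
   AUC is trapezoidal, summarized as the macro average.  Trained models
   applied per pixel yield class maps and class proportions; the drying
   endpoint fires when the target class strictly exceeds 80 % of plant
   pixels.

## Key defaults and their rationale

| parameter | default | why |
|---|---|---|
| NBD threshold | 0.3 (strict >) | stated protocol |
| patch size / coverage | 20 px / > 0.7 (strict) | stated protocol; coverage read as fraction of the 400 patch pixels |
| SG window / order | 5 / 3 | stated protocol |
| derivative flavour | SG derivative (finite differences behind `sg=False`) | standard chemometric reading; less noise-amplifying |
| MSC reference | calibration mean, frozen | leakage-free; protocol silent |
| split | global, unstratified, ⌈0.2·N⌉ test | a single shared split is the only way the four per-quality prediction columns can sum to the same 942 of 4,707 |
| LR | L2, C = 1.0, OvR, 5,000 iterations | era-standard toolkit defaults |
| SVM | RBF, C = 1 | toolkit default; kernel unstated in the protocol |
| KNN | k = 5, Euclidean, uniform | k stated; rest default |
| RF | 100 trees, unlimited depth, seeded | toolkit default |
| content thresholds | totalCBD ≥ 90, totalTHC ≥ 3 µg/mg (inclusive) | stated values; strictness unstated, inclusivity configurable |
| endpoint | > 80 % of plant pixels (strict) | stated rule |

No feature scaling is applied before the classifiers (not part of the
protocol); the wavelength grid is reconstructed as
`λ_k = 400.53 + 4.0025·k` nm, `k = 0..149`, which reproduces every named
band center to ≤ 0.03 nm — the instrument's true band list is not published,
so the grid is an explicit reconstruction.

## The synthetic benchmark

No raw images are publicly deposited, so all image-level claims are
exercised on a generator that reproduces the statistical structure the
analysis needs.  One integer seed determines everything.

**Geometry.** Flowers are unions of 4–6 rough-edged random ellipses
(semi-axes 25–50 px) on a 300 × 300 px stage, calibrated once so greedy
patch extraction yields 27–73 patches per image — the per-sample data-point
range reported for the real tray images (observed 31–63 over 20 seeds).

**Spectra.** A fresh-flower endmember (green bump, sharp red edge near
722 nm, NIR plateau ≈ 0.55) is deformed by a latent drying state
`d ∈ [0,1]` and the drying method.  Four wavelength regimes each carry a
method-specific gain at full drying — hot air: −0.20 below 552.61 nm,
+0.25 in 556.61–612.65 nm, +0.45 in the red regime, −0.38 in
720.71–884.81 nm; cool air: +0.02 / +1.0 / +0.9 / −0.30 — and a monotone
response curve in `d` (linear, √d, d², linear respectively).  This
reproduces the empirically observed orderings at every drying state:
hot-air lowers the blue-green bands, cool-air maximizes the green-yellow
and red bands, and the NIR falls under both methods with hot-air falling
further.  Two deliberate choices deserve emphasis: (a) per-regime response
curves make the drying trajectory *curved* in spectral space — a
linear-in-d deformation would put the classes on a straight line, an
unrealistic degenerate geometry in which no one-vs-rest hyperplane can
isolate a middle class; (b) the red-regime deformation tapers off below
the 684.69 nm NBD band, so segmentation margins are independent of drying
state (visible-band gains up to +1.0 correspond to the strong browning of
dried plant material).

**Noise model.** Four nuisance processes, each motivated by a failure mode
a specific pre-treatment addresses:

* *Multiplicative gain and additive offset* (Uniform[0.8, 1.2] and
  Uniform[−0.05, 0.05] marginals, smooth 30 px spatial fields) — the
  scatter MSC removes exactly; raw and SG suffer it, derivatives drop the
  offset but keep the gain.
* *Within-flower drying heterogeneity* — a smooth (15 px) perturbation of
  the per-pixel drying state (sd 0.045); drying never progresses uniformly
  across a flower, and this is what makes every grid cell imperfect.
* *Band-incoherent striping* (sd 0.014, 12 px spatial correlation,
  windowed off 670–780 nm so the NBD bands stay clean) — a push-broom
  sensor artifact that survives patch averaging and is precisely the noise
  derivative pre-treatments amplify; it is why second-derivative cells
  degrade while MSC cells do not.
* *Residual smooth spectral components and i.i.d. band noise* (small) —
  generic sensor/chemistry texture.

**Kinetics.** A single per-sample latent exposure `τ = t·J`
(`J ~ lognormal, sd 0.06`) drives every process, keeping weights,
chemistry, spectra and hence all four labels mutually consistent:
residual water `ρ = ε + (1−ε)e^{−r_w τ}` (hot 2.5/day reaching the ≈3.6 %
RWC plateau by day 2; cool 0.385/day reaching ≈12.7 % at day 9; both match
the reported drying curves); spectral state `d = 1 − e^{−r_s τ}` (hot
0.35, cool 0.25/day); conversions `c = c₀ + (1−c₀)(1−e^{−kτ})` with a 1 %
baseline at harvest (fresh flowers carry a small neutral-cannabinoid
fraction; an exactly-zero conversion would be unlabelable under the
open-at-zero intervals).  The CBDA rate k = 0.2/day reproduces the
reported ≈83 % conversion after 9 days of hot air; the cool-air rate
0.005/day keeps conversions below the reported 6 % ceiling.  The THC total
grows by a saturating factor (hot ×2.7 asymptote), pulling the CBD:THC
ratio from its ≈36:1 harvest value below 20:1 under hot air — without this
growth term the ratio would be constant and the lower C:T class could
never be populated.  A CBD-total growth term (the transient early-drying
peak) exists but is off by default.

**What the benchmark does not emulate:** real band-to-band spectral
covariance (unknown without deposited data), trichome-scale texture,
non-monotone THCA trajectories, tray geometry, and illumination gradients
beyond the smooth scatter fields.  Passing tests therefore demonstrate
that the pipeline's machinery is correct and that its comparative claims
(MSC-based selection, derivative degradation of LR) follow from the stated
noise structure — not that the same accuracies would be obtained on real
flowers.

## Problem sizes used in tests

The default benchmark is 2 methods × 5 days × 6 cubes at 300 × 300 px
(≈2,700 patch spectra); the model-selection stability check across seeds
uses 2 cubes per condition (≈950 spectra), and the end-to-end CLI check
uses 120 × 120 px cubes with smaller flowers.  These sizes were chosen as
the smallest at which every class comfortably supports 10-fold
cross-validation.

## Numerical choices and degenerate inputs

* Coverage is compared as `count/400 > 0.7` (division, not
  multiplication) so an exactly-70 % patch is rejected despite floating
  error; the NBD and endpoint comparisons are likewise strict.
* `nearest_band` breaks distance ties toward the lower band index and
  refuses targets outside the grid by more than half a band spacing.
* MSC with a fitted gain below 1e−12 passes the spectrum through with a
  warning; a constant reference raises.
* Negative RWC (weight below estimated dry mass) is reported with a
  warning, never clamped.
* Zero-denominator NBD pixels are flagged and can never enter the ROI.
* Classes smaller than the fold count abort cross-validation with an error
  naming the class; boundary-scan candidates that empty a class are
  recorded as skipped, not dropped silently.

## Known limitations

* The ENVI reader supports BSQ float pairs written by this package plus
  ordinary single-part headers; it is not a general ENVI implementation.
* Selection-grid runtimes grow quadratically with calibration size through
  the RBF SVM; at the default benchmark size a full 25-cell grid for one
  quality takes a few minutes on one core.
* The boundary sensitivity scan explores user-supplied candidate edge
  sets; it does not search the space of boundaries itself.
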