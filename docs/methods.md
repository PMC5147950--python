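# Methods

## The severity model

A turtle's external fibropapillomatosis burden is recorded as a count matrix
over 11 body regions (left/right eye, head, neck, left/right forelimb,
carapace, plastron, left/right hindlimb, inguinal region/tail) and 4 tumor
diameter classes. Diameter is the larger of a tumor's two axes. The class
intervals are read as A = (0, 1) cm, B = [1, 4] cm, C = (4, 10] cm,
D = (10, ∞) cm — the only gapless, non-overlapping reading of the
conventional "A (<1), B (1–4), C (>4–10), D (>10)" notation. A tumor of
exactly 1 cm is therefore class B and one of exactly 4 cm is class B; the
field protocol behind the original data may have resolved these boundaries
differently, which cannot be checked from published summaries alone.

Total tumor area (TTA, cm²) is the sum over tumors of the ellipse
cross-section π·0.5a·0.5b (major axis a, minor axis b). TTA is the best
available scalar burden measure but requires measuring every tumor; the
index exists to approximate it from counts alone.

The fibropapillomatosis index is the weighted count sum

    FPI = 0.1·N_A + 1·N_B + 20·N_C + 40·N_D

with N_X the turtle's total count in class X. The canonical weights come
from an OLS regression of measured TTA on the four marginals
(TTA = 0.031 + 0.056·N_A + 1.172·N_B + 22.161·N_C + 36.198·N_D, fitted on a
27-turtle subset), simplified to round field-usable values. The ordinal
score FPS_SWA thresholds FPI at 40 and 120 (mild / moderate / severe, with
40 → moderate and 120 → severe, following the defining inequalities).
FPS_HWI is an adapted version of the Hawaii-style count-rule score: mild
when N_C = N_D = 0 and N_A ≤ 5 and N_B ≤ 5; severe when N_D ≥ 1 or N_C ≥ 4;
moderate otherwise. The two membership rules are mutually exclusive (mild
requires N_C = N_D = 0) and the fallback makes the classification total.

Index comparisons against thresholds use an absolute tolerance of 1e-9 so
that decimal-exact boundary values (e.g. 400 class-A tumors, FPI exactly 40)
classify at the boundary regardless of binary floating-point representation.

## Calibration workflow

For a new region the construction is re-run on local data:

1. **Count regression.** OLS with intercept of measured TTA on
   (N_A, N_B, N_C, N_D); plain R² = 1 − SS_res/SS_tot is reported (the
   adjusted variant is not used). At least 6 observations are required. A
   size class that never varies in the sample is unidentifiable; its slope
   is reported as NaN with a warning rather than silently dropped or zeroed.
2. **Simplification.** Each slope is snapped to the nearest value in an
   ordered candidate set, default {0.1, 0.2, 0.5, 1, 2, 5, 10, 20, 40, 50,
   100}, ties resolving to the larger candidate; the intercept is dropped so
   a tumor-free turtle scores 0. The published weight for class A (0.1, from
   a slope of 0.056) is not the result of any uniform rounding rule; the
   default candidate set omits 0.05 so that the canonical weights are the
   fixed point of the procedure. This is a reconstruction of an
   under-documented step, made explicit and configurable. Negative slopes
   abort with an error — clamping them to zero would hide data problems.
   A simplified weight vector that decreases with size class is likewise
   rejected (a larger tumor must never count for less).
3. **Index regression.** Simple OLS of TTA on the simplified index. On the
   canonical system this gives TTA ≈ 0.16 + 1.11·FPI.
4. **Thresholds.** The original cutoffs were chosen by inspecting the
   TTA-vs-index scatter plot, which is not reproducible; here the fitted
   line is inverted at two TTA cutpoints, t = (cutpoint − intercept)/slope,
   rounded to a granularity (default: nearest 10). The shipped default
   cutpoints (44.56, 133.36 cm²) are the canonical line's values at index
   40 and 120, so the canonical thresholds are recovered as a special case.
   No uncertainty is propagated into the thresholds.

`FPICalibrator` runs the four steps as one scikit-learn estimator; its
`predict` is the calibrated index mapped through the index-regression line,
so its default `score` is the R² of the simplified-index TTA predictor.

## Agreement statistic

Two ordinal scorings of the same turtles are compared with weighted Cohen's
kappa over the fixed category order mild < moderate < severe:
κ = (P_o − P_e)/(1 − P_e), with P_o = Σ w_ij·p_ij over observed cell
proportions and P_e = Σ w_ij·p_i·q_j over the product of marginals. Weights
are w_ij = 1 − |i−j|/(k−1) (linear, the default for three ordered
categories) or 1 − (i−j)²/(k−1)² (quadratic, available by flag). The
weighting behind the originally published κ values is not recorded; linear
is the documented default pending the raw subjective-score data. κ is
stored as a fraction and printed as a percentage. The degenerate case where
both raters place all mass in one identical category has P_e = 1 and κ is
reported as undefined rather than raised. No confidence intervals or
multi-rater statistics are computed.

## Synthetic cohort generator

The generator emulates the reference study's data structure so the entire
toolkit is testable without the original raw data:

* **Counts.** Each of the 44 region × class cells draws independently from a
  negative binomial moment-matched to the published per-cell mean and SD
  (every published cell is overdispersed, SD > mean; a Poisson fallback
  covers configured cells that are not). Cells the published table marks
  with a dash are structural zeros and never generate tumors; the head/C
  cell, printed as mean 0.00 with SD 0.07, is treated as a structural zero
  as well. Turtles with zero tumors overall are redrawn, because the study
  cohort is defined as FP-positive (this conditioning is negligible at the
  default means, where an all-zero turtle is vanishingly rare, but matters
  for sparse custom configurations; the unconditioned sampler can be
  selected with `require_positive=False`).
* **Defaults.** 214 turtles; TTA on a 27-turtle random subset; subjective
  labels on a 52-turtle random subset — the reference cohort sizes.
* **TTA subset.** TTA = the canonical counts-based linear predictor +
  Gaussian noise (default SD 5 cm², a round value on the order of the
  canonical fit's residual scale), truncated at 0. With zero noise the
  calibration workflow must recover the generating coefficients exactly.
* **Subjective subset.** The label equals the turtle's FPS_SWA score with
  probability `subjective_agreement` (default 0.75, which places κ against
  FPS_SWA in the 0.5–0.75 band reported for expert panels in this system);
  disagreements move to an adjacent category only (moderate splits evenly
  between mild and severe), since expert panels essentially never confuse
  mild with severe.
* **What is not emulated.** No between-cell or between-region correlation is
  published, so cells are independent by default; an optional shared
  per-turtle gamma frailty multiplier (`frailty_shape`) induces positive
  correlation for robustness checks but any dependence structure is an
  invention. No capture-year, site or growth dynamics are simulated.
  Consequently, passing tests demonstrate correctness of the formulas,
  estimators and pipelines under the published marginal structure — not
  that the generator reproduces joint features of real cohorts. In
  particular, the synthetic subjective labels are derived from FPS_SWA, so
  synthetic agreement between FPS_HWI and the subjective label reflects the
  divergence between the two classifiers on synthetic count profiles, not
  an empirical expert-agreement level.

A separate reference fixture (`table1_reference_cohort`) reconstructs a
214-turtle cohort whose per-region totals equal the published totals
exactly, by spreading each region's total as evenly as possible across
turtles; only region-level aggregates of it are meaningful. The published
grand total of externally counted tumors (7464, the table total) is used
throughout; the abstract's 7466 includes oral/esophageal tumors found at
necropsy in three turtles, which were excluded from the statistical analyses
and are not representable in this data model.

## Descriptive conventions

Standard deviations are sample SDs (n − 1); the published table's SDs
cannot be re-verified without raw data, so the convention is documented
rather than fitted. A single-turtle cohort has undefined SDs, reported as 0
with a warning. Display rounding is two decimals for means/SDs and whole
percent for anatomical percentages; integer rounding means pooled
percentages sum to 100 ± 1 (the published "10% remaining areas" corresponds
to 819/7464 = 11% at whole-percent rounding; the forelimb, hindlimb and neck
shares — 45%, 34%, 10% — all verify exactly).

## Problem sizes and numerics

Test and acceptance runs use the reference sizes throughout (214 / 27 / 52),
with 200–500 seeded replicates for Monte-Carlo checks and n = 50,000 draws
for single-cell moment checks. OLS is delegated to statsmodels; an
independent normal-equations solve serves as an oracle in tests. Coefficient
recovery under noise is assessed per identifiable slope at ±3 standard
errors; replicates whose 27-turtle subset lacks variation in a class (about
6% of seeds lack any D tumor) contribute only their identifiable slopes.
Constant-response fits report R² = 0 by convention.

## Known limitations

* The boundary convention for tumors of exactly 1, 4 or 10 cm follows the
  interval notation and may not match the original field protocol.
* The candidate-set simplification reproduces the canonical weights by
  construction of the default set; it is a principled reconstruction, not
  the original authors' documented rule.
* The weighted-kappa scheme (linear vs quadratic) behind the originally
  published agreement values is unknown; both are implemented.
* Published-value reproduction that requires the study's raw supplementary
  spreadsheet (per-turtle TTA and expert labels) is supported (export it to
  `data/s1_raw.csv` in the wide cohort schema) but cannot run without that
  file.
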