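# Methods

This note documents the models, numerical choices and validation design of
`voccast`, in the order data flows through the package.

## Data model and interchange format

A GC-IMS sample is a dense matrix of non-negative intensities, rows indexed
by gas-chromatography retention time and columns by ion-mobility drift time,
with strictly increasing axes. Vendors ship proprietary binary containers;
`voccast` deliberately does not parse them and instead defines an open
interchange format — `<sample_id>.csv` (headerless matrix, 17 significant
digits so float64 round-trips bit-exactly) plus `<sample_id>.json` carrying
`sample_id`, both axes and free-form metadata. Axis units are metadata only:
every downstream operation works in index space, mirroring how crop windows
are chosen in practice (by visual inspection of the map, not in physical
units).

Clinical metadata travels as a CSV with columns
`patient_id,sample_id,seq_index,fcp,hbi,sccai,subtype`. FCP (fecal
calprotectin, mg/g) and the activity scores may be missing at load time —
cohorts from different centers record different variables — and are only
required when a label of the corresponding family is requested.

## Disease-activity states and transition groups

Biochemical state: ACTIVE iff FCP ≥ 250 mg/g, REMISSION iff FCP < 100 mg/g,
INDETERMINATE in the gap. Clinical state: for Crohn's disease ACTIVE iff
HBI ≥ 5, REMISSION iff HBI < 4, and HBI = 4 — which neither definition
covers — is INDETERMINATE; for UC/IBD-U ACTIVE iff SCCAI ≥ 3, REMISSION iff
SCCAI ≤ 2 (no gap). All cut-offs are configuration (`StateThresholds`) with
these defaults, because the surrounding literature uses FCP cut-offs
anywhere between 200 and 250 µg/g; mg/g and µg/g labels are treated as
synonymous and never converted.

Pairs are formed per patient from samples adjacent in collection order; a
middle sample may close one pair and open the next, so a sequence of FCP
values (300, 260, 80) yields B3 then B4. This maximizes usable pairs, which
matters when patients contribute up to eight samples. Pairs containing an
indeterminate or unlabellable sample are dropped and the exclusion reasons
are kept (logging + `pair_samples_detailed`), never raised: exclusions are a
reportable property of a cohort, not an error.

## Synthetic cohorts

The generator emulates the statistical structure the analysis relies on,
not instrument physics. A spectrum is

```
clip( baseline + RIP ridge + Σ shared peaks + s · Σ effect peaks + noise, 0 )
```

with `s = effect_multiplier` in group 1 and 1 otherwise. Peaks are
axis-aligned 2-D Gaussians; retention positions follow a truncated
exponential because most analytes are light and elute early; the
reactant-ion peak (RIP) is a full-height ridge at a fixed drift column with
nothing behind it, giving the crop stage something to cut. Noise is i.i.d.
homoscedastic Gaussian; "truncated at zero" is implemented as clipping the
composed matrix, which guarantees the non-negativity invariant. The group
effect is multiplicative on peak amplitude since concentration changes scale
peak height in IMS.

Defaults: 200 × 150 matrices (desk-scale; the real instrument produces
~11 million points per sample, and every algorithm here is shape-agnostic),
baseline 100, noise SD 10, shared amplitudes 100–600, effect amplitudes
120–250, peak sigmas 1.2–3 cells. Ground truth for an effect peak is the
elliptical 2σ footprint (Mahalanobis ≤ 2 in units of the peak sigmas);
ground-truth locations carry full-matrix row-major indices because
crop-relative feature indices depend on a window the generator does not
know.

`simulate_metadata` draws FCP uniformly from [0, 100) for remission and
[250, 1000] for active (HBI from {0..3} / {5..16}, SCCAI from {0..2} /
{3..12}), so the labeller maps generated pairs to the requested transition
code by construction — a closed loop the tests exercise for all eight codes.

What the generator does **not** emulate: peak tailing and dimer ions,
retention-index calibration, inter-batch drift, heteroscedastic detector
noise, and correlated biological variation between VOCs. Passing recovery
tests therefore show the *pipeline machinery* is sound, not that real
cohorts of this size would yield similar accuracy.

## Preprocessing

"Feature" means one cell of the cropped matrix (optionally mean-pooled over
`bin_size` × `bin_size` blocks, default 1), flattened row-major with an
explicit inverse map (`FeatureLocation`) so that selected features can be
replotted onto the original spectrum.

Numerical choices, each fixed for bit-reproducibility:

* Background model uses the **sample** SD (n−1 denominator); the threshold
  is exactly `mean + 2·sd` and the `BackgroundModel` constructor enforces
  the identity.
* Default background regions are the pre-RIP drift columns plus the last 10%
  of retention rows — chemical-free by construction and disjoint from the
  default crop window.
* Thresholding **zeroes** sub-threshold cells (rather than subtracting the
  threshold) and is applied **per sample** (robust to per-run baseline
  drift). Each feature-matrix row is therefore a pure function of its own
  spectrum, which makes row order irrelevant and the tests simple.
* The crop window is required configuration; `default_crop_window` provides
  a sensible choice for generated designs (80% of retention rows, drift
  columns safely past the RIP).

## Feature selection and classification

Within every training set, each feature gets a two-sided Wilcoxon rank-sum
p-value. Implementation: exact p from the enumerated Mann–Whitney U null
distribution (a counting DP, cached per group-size pair; float64 counts are
exact for these sizes) for tie-free columns when both groups have ≤ 25
samples; otherwise the tie-corrected, continuity-corrected normal
approximation, vectorised over all columns. Constant columns get p = 1.
The suite checks both regimes against scipy and against exhaustive
permutation enumeration.

Ranking order is p ascending, then **absolute group-mean difference
descending**, then feature index. The effect-size tie-break is the
volcano-plot convention and is load-bearing here: a strong group effect
pushes many cells to complete separation, where the rank statistic saturates
(U = n₁n₀) and p-values tie at the test's floor, so p alone cannot order
them — but the mean difference still points at peak cores rather than
background-threshold edge artifacts. The tie-break uses training rows only,
so leakage safety is unchanged.

The top `n_features` (default 100) feed two classifiers:

* **SVM** — StandardScaler (training statistics) + RBF-kernel SVC, C = 1,
  `gamma='scale'`; probabilities via cross-validated sigmoid (Platt)
  calibration, with the internal CV capped at the minority-class count.
* **Random Forest** — 500 trees, default feature subsampling, probabilities
  as vote fractions.

Hyperparameters are deliberately library defaults, pinned and documented;
no tuning is performed anywhere.

Resampling: stratified 10-fold CV is the default; a stratified 70/30
hold-out is also provided (`mode="holdout"`) since both designs appear in
practice, and every report names its mode. Folds are stratified because
minority transition groups can be as small as 7–8 samples. Fold assignment
is keyed by sample id (rows are sorted before splitting), making results
invariant to input row order, and `group_folds_by_patient` (default on,
when patient groups are supplied) keeps a patient's samples in one fold to
avoid twin-sample leakage. Out-of-fold probabilities are pooled, not
averaged per fold — with ≤ 1 case per fold, per-fold ROC curves do not
exist. Pooling has a documented cost at strong class imbalance: the
training prevalence of each fold is anticorrelated with its test
composition, which biases the pooled null AUC slightly below ½ (clearly
visible for Random-Forest vote fractions, mild for the calibrated SVM) and
inflates its between-cohort variance (null SD ≈ 0.165 vs 0.113 for
independent scores at n = (41, 8)). This is a property of the resampling
design, not a leak; the permutation test below accounts for it exactly.

`run_cv(..., leak_selection=True)` deliberately ranks features on the full
data before splitting. It exists only so the test suite can demonstrate the
value of fold-local selection: on pure-noise cohorts the leaky variant
averages AUC ≈ 0.98 while the correct pipeline stays at ≈ 0.50.

## Evaluation

* **AUC** is the Mann–Whitney concordance probability (ties ½).
* **95% CI** by DeLong's placement-variance method, truncated to [0, 1];
  degenerate variance collapses the interval to the point estimate with a
  warning. The implementation matches R's pROC to 10⁻⁶ (cross-checked in the
  suite). Being asymptotic, it undercovers slightly at very small case
  counts: measured 89.4% coverage over 500 binormal replicates at
  n = (41, 8). A seeded bootstrap is not provided; users needing
  small-sample intervals should prefer the permutation machinery below.
* **Optimum cut-off** maximizes Youden's J over the observed probability
  values; ties break toward higher sensitivity, then lower cut-off;
  predicted-positive means probability ≥ cut-off. PPV/NPV are NaN if no
  sample falls on the corresponding side. All metrics derive from one
  integer confusion matrix, and everything is rank-based, hence invariant
  under strictly monotone transforms of the probabilities.
* **Significance.** Two regimes, and the distinction matters:
  * *Hold-out predictions*: a plain two-sided Mann–Whitney test on the test
    probabilities (`comparison_pvalue`, exact where scipy can be). This is
    exactly valid — conditional on the single fitted model, test scores of
    the two classes are exchangeable under the null, so the MWU null
    distribution applies regardless of the model.
  * *Pooled cross-validated predictions*: the same MWU is **anticonservative**
    (measured type-I ≈ 0.20 at α = 0.05 under null conditions with
    n = (41, 8)). The cause is not calibration of the probability scale —
    Platt variants, class weighting, per-fold standardized decision values
    and even a fold-stratified van Elteren test all stay inflated — but
    cross-fold dependence: fold models share training samples, so chance
    clustering of the few cases inflates every fold's statistic at once,
    over-dispersing the pooled AUC (null SD ≈ 0.165 vs 0.113 for
    independent scores). The only reference distribution that honours the
    procedure is to permute labels and re-run the entire pipeline;
    `pipeline_permutation_pvalue` does exactly that, with Besag–Clifford
    sequential early stopping (stop at the 3rd exceedance; default budget
    199 permutations) so clearly-null comparisons cost only a handful of
    pipeline re-runs. Measured type-I: 0.05.

## Validation studies (`voccast.validation`)

Problem sizes were chosen to exercise the claims at desk scale:

* **Recovery** — 200 × 150 spectra, 40 + 40 samples, 5 planted effect peaks
  amplified 3×, 10 seeds: median out-of-fold SVM AUC and the fraction of the
  100 modally-selected features inside the 2σ ground-truth footprint.
* **Null calibration** — 50 × 40 spectra, 41 + 8 samples (the sizes of the
  remission→remission vs remission→exacerbation comparison), no effect:
  mean pooled AUC over 50 seeds, and the permutation-test rejection rate at
  α = 0.05 over 200 independent replicates.
* **Leakage sentinel** — the same 50 null cohorts run with fold-local vs
  whole-data selection.
* **Determinism** — the full simulate → preprocess → fit → report chain run
  twice with one seed must produce byte-identical CSV artifacts.

`scripts/acceptance.py` runs all four and writes the numbers as JSON;
`tests/test_acceptance.py` asserts the corresponding bands.

## Known limitations

* The synthetic generator's intensity scales are free parameters; recovery
  and null behaviour — not distributional match to any instrument — are the
  validation currency.
* The normal approximation for heavily tied rank-sum inputs drifts from the
  exact enumeration at n = 8 in the deep-null region (up to ~0.26 near
  p = 1); real training sets here are several times larger.
* Patient-level grouping is supported for CV but not for the hold-out split;
  the label-permutation test permutes at sample level and assumes one pair
  per patient in the compared groups.
* No multiple-testing correction is applied across comparisons, matching
  standard practice for pilot-scale reports; interpret families of p-values
  accordingly.
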