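# Methods

## The problem

After induction therapy, acute myeloid leukemia (AML) patients are
monitored for minimal residual disease (MRD): a small fraction of leukemic
blasts — often 10⁻⁴ to 10⁻² of nucleated cells — persisting in marrow.
Multiparameter flow cytometry detects MRD through a leukemia-associated
immunophenotype (LAIP), here aberrant CD7/CD117 co-expression with HLA-DR
on blasts, measured alongside CD45 and light scatter.  Conventional review
draws 2-D gates by hand and is analyst-dependent; `flowmrd` automates the
quantification with a per-patient supervised classifier and retains the
manual-gating path as a comparator.

## The per-patient model

For each patient a soft-margin binary SVM with RBF kernel
K(u, v) = exp(−γ‖u−v‖²) is trained on

* **class 1 (leukemic):** the patient's diagnosis blast population (the
  gated export of the dominant abnormal cluster at initial
  immunophenotyping), and
* **class 0 (normal):** pooled events from a panel of healthy-donor
  specimens (15 by default).

Feature channels default to the full panel (FSC, SSC, CD7, CD117, HLA-DR,
CD45).  Whether scatter channels belong in the feature space is genuinely
open; all-channels is the default because the manual comparator uses
scatter, and the channel subset is configurable per run.

MRD in a follow-up specimen is the percentage of its events the trained
model classifies as class 1.  No test labels are assumed; the reported
quantity is purely the predicted leukemic fraction.

### Subsampling

The pooled training set (~2×10⁵ events in the default study: 5×10⁴
diagnosis blasts plus 15 donor contributions of 10⁴ events) is reduced to
10⁴ events by stratified random sampling before tuning and training,
because SVM training cost grows superlinearly with training size.  Strata
are the source files (the diagnosis export and each donor file); this
preserves the leukemic:normal ratio and donor balance, the only structure
available before a model exists.  Per-stratum quotas are the exact
largest-remainder apportionment of 10⁴ by stratum size, so quotas are
deterministic and reproducible; within strata, draws are uniform without
replacement under a recorded seed.

### Scaling

Features are mapped channel-wise onto [−1, 1] by the affine transform
x′ = lo + (hi−lo)(x − min)/(max − min), with (min, max) fitted on the
training subsample and persisted in a range file.  The *same saved range*
is re-applied to every follow-up specimen, whose out-of-range values
extrapolate linearly — no clipping — keeping the transform affine and
invertible (round-trip error ≤ 1e-9 relative).  A degenerate channel
(min = max) maps to lo.  The [−1, 1] target follows the conventional
practice of SVM feature scaling tools.

### Parameter search

(C, γ) are tuned by exhaustive search over a log₂ lattice, by default
C = 2⁻⁵ … 2¹⁵ and γ = 2³ … 2⁻¹⁵ in steps of 2, which spans the full range
of optima one sees across patients (heavily regularized through nearly
hard-margin, wide through narrow kernels).  Each pair is scored by 5-fold
cross-validated accuracy; fold assignment is label-stratified (round-robin
within each shuffled class) and seeded, so every lattice point is compared
on identical splits and folds never lack leukemic events even at strong
class imbalance.  Ties are broken toward smaller C, then smaller γ: when
accuracies are equal the more regularized model is preferred for
generalization.  Pipeline-level studies use the same lattice thinned to
log₂ steps of 4 (`REDUCED_GRID`), which keeps every decade of the search
space at a quarter of the cost; module defaults remain the full grid.

Class weighting is deliberately not applied; the training-set composition
(dominant donor pool, minority blast class) is controlled upstream, and
the per-patient training ratio is part of the study design.

### Prediction determinism

The fitted classifier is reduced to support vectors, dual coefficients and
intercept; prediction evaluates the kernel expansion directly (chunked,
vectorized).  A model persisted to its versioned text file and reloaded
yields bit-identical predictions, and the embedded scaling range makes a
model file self-contained.

## Manual comparator and agreement statistics

The conventional analysis is reproduced as flat boolean-AND gating:
rectangles or simple polygons on channel pairs, boundary-inclusive so
events exactly on an edge resolve deterministically.  The gated fraction
is 100·|P1 ∧ P2 ∧ ... | / n.

Paired (manual %, automated %) results are compared with a two-tailed
paired Student t-test (sample SD, df = n−1), the Pearson product-moment
correlation, and Bland–Altman limits of agreement at bias ± 1.96·SD of the
paired differences.  The 1.96 normal quantile is used without a
small-sample t correction, matching the classic 95% limits; a difference
exactly on a limit counts as inside; a set of identical differences has no
t statistic and is reported as a degenerate-input error rather than a
fabricated p-value.

## The synthetic-data generator

Clinical list-mode files cannot ship with the package, so every study runs
on seeded synthetic specimens: mixtures of multivariate-Gaussian event
populations in linear intensity space (optionally correlated across
channels), truncated at zero intensity.  Population event counts are the
exact largest-remainder apportionment of n_events by the specified
fractions — ground-truth fractions carry no sampling noise, so any error a
test observes is attributable to the classifier or gates, not the
generator.  A follow-up specimen spikes the blast population at
round(fraction·n) events and records the realized fraction.

The default study emulates the clinical design: marrow-like specimens of
10⁵ events (normal background: a lymphocyte and a myeloid cluster), a
diagnosis blast export, 15 healthy donors, and spiked follow-ups.  The
blast cluster shares the lymphocyte scatter profile and is offset on the
three LAIP markers by a tunable number of pooled standard deviations
(`separation_sd`, spread 30 intensity units), plus a fixed 2-SD CD45-dim
shift — so a single knob moves the phenotype from cleanly aberrant
(6 SD) to heavily overlapping (0 SD).  Donor files contribute 10⁴ events
each to training so that the pooled training file lands at the ~2×10⁵
scale the subsampling stage is designed around.

What the generator does **not** model: doublets, debris, autofluorescence,
spectral spillover/compensation, acquisition drift, or heavy-tailed and
skewed intensity distributions.  Passing tests therefore demonstrate the
pipeline's correctness and its detection behaviour on compact,
well-defined populations; they do not certify performance on clinical
files, where population shapes and overlaps are less benign.

## Study designs used by the acceptance checks

* **Spike-in recovery** (`recovery_study`): 4 synthetic patients at 6-SD
  separation; for each, the full pipeline (assembly → 10⁴ subsample →
  scaling → reduced-grid search → training) and five follow-ups spiked at
  0.05%, 0.1%, 1%, 5% and 25% of 10⁵ events — 20 truth/estimate pairs.
  Spike levels bracket the 10⁻⁴ sensitivity regime of cytometric MRD.
* **Subsample adequacy** (`subsample_adequacy_study`): ten *independent*
  synthetic cases, each its own patient, training data, tuned model pair
  and one 10⁵-event follow-up.  Case separations cycle over 2.5–3.5 SD, a
  partially overlapping LAIP regime in which a 10⁴-event model and a
  2×10⁵-event model can genuinely disagree near the decision boundary; at
  6 SD the two models agree to the event and there is nothing to compare.
  Cases must be independent for the paired t-test to be valid: repeated
  follow-ups of one model pair share the same boundary geometry, are
  strongly correlated, and would overstate significance.  The full-set
  model reuses the (C, γ) tuned on the subsample — the comparison targets
  training-set size, not the tuning procedure, and grid search at 2×10⁵
  events is computationally out of proportion to what it would add.
* **CV plausibility**: the full default grid on a 2×10³-event stratified
  subsample of a separable (6-SD) patient; best CV accuracy is expected
  ≥ 98%, the regime individual-specific clinical models reportedly reach.

Problem sizes (10⁴-event training subsamples, 10⁵-event specimens, 4–10
cases per study) are the package's chosen defaults for these studies;
they keep each study in the minutes range on a single CPU while exercising
the same regime as the clinical workflow.

## Numerical and design choices

* FCS 3.0 only; 2.0/3.1 are rejected explicitly rather than coerced.  The
  writer stores $DATATYPE F, little-endian, single data segment — chosen
  so fixtures round-trip bit-exactly; the reader additionally accepts
  integer data in either byte order and decodes log-amplified integer
  channels to 10^(decades·x/range).
* Stored intensities are taken as-is; fluorescence compensation is neither
  computed nor applied (documented limitation).
* Channel identity is the $PnN short name (the standard's unique key);
  $PnS is display metadata; duplicate $PnN is an error.
* Largest-remainder ties are broken by position (earlier populations or
  strata first), making apportionment total and deterministic.
* Negative Gaussian draws are truncated at zero rather than resampled,
  preserving per-seed determinism; at the separations used the bias is
  negligible.
* Gate membership is boundary-inclusive everywhere (rectangle and
  polygon), so edge events cannot flip between runs or geometries.
* Two identical training points with opposite labels train without error
  (soft margin); one is necessarily misclassified.
* All randomness flows through recorded integer seeds
  (`numpy.random.default_rng` / `SeedSequence`); identical configuration
  and seeds reproduce every output byte-for-byte.

## Known limitations

* Gaussian populations understate the spread asymmetries and tails of real
  cytometry data; recovery tolerances established here are optimistic for
  clinical files.
* The pipeline assumes the diagnosis blast population is provided (gated
  upstream); it does not identify blasts automatically.
* Only binary leukemic/normal classification with an RBF kernel is
  supported — no probability outputs, alternative kernels, or multi-class
  phenotypes.
* Bland–Altman limits are the classic large-sample form, without
  confidence intervals on the limits or regression-based variants.
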