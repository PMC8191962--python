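# Methods

## Problem setting

Cardiac resynchronization therapy (CRT) is offered to heart-failure
patients with conduction delay, typically left bundle branch block
(LBBB), yet roughly a third of implanted patients do not remodel.
Speckle-tracking echocardiography yields, for each of the three standard
apical views (4-chamber, 3-chamber, 2-chamber), longitudinal strain time
series for six myocardial segments — percent shortening versus time from
QRS onset. This package implements (i) a fully automatic extraction of
158 scalar features from those 18 curves plus two clinical scalars, and
(ii) a multi-method feature-importance stage that asks which features,
and which views, carry information about CRT response (defined as a
strictly >15% decrease in LV end-systolic volume at follow-up).

Because no patient-level strain curves are publicly available, the
package ships a synthetic cohort generator that emulates LBBB segmental
mechanics with a controllable responder/non-responder effect structure,
so the whole pipeline is testable end to end.

## Feature extraction

All timings are referenced to QRS onset (`t = 0`); each curve is linearly
resampled to 500 Hz before any computation. Strain values in the ±5%
dead zone are ignored: only samples below −5% count as contraction, both
for integral accumulation and for deciding whether a segment has a
defined peak time.

Per segment (magnitude convention: contraction is reported positive):

* `P` — peak contraction, max(−strain), and `Tpeak` — time of the first
  global strain minimum, defined only when `P > 5%`.
* `Iavc` — integral of |strain| (masked) from QRS onset to aortic valve
  closure (AVC): cumulative shortening that ejects blood (%·s).
* `Ipeak` — same integral up to `Tpeak`: total deployed shortening.
* `E = Ipeak − Iavc` — efficiency marker; `E > 0` means qualifying
  shortening continued past AVC to a later peak, i.e. wasted work.

Per view: the AVC time; mean/std of `P` and `Tpeak`; the heterogeneity
and dyssynchrony markers `dP = max−min(P)` and `dTpeak = max−min(Tpeak)`;
and for each integral family the per-view mean/std, the two wall sums
(septal/lateral, inferior/anterior, anteroseptal/posterior) and their
difference (first wall minus second). 52 features per view, three views,
plus QRS duration and LVEF: 158 in total.

### Numerical choices

* **Integration.** The masked integral is computed exactly for the
  piecewise-linear 500 Hz interpolant: every sampling interval is split
  analytically at its crossing of the −5% threshold and at the upper
  integration limit. A per-sample masked trapezoid would carry a
  phase-dependent boundary error of up to ~5·h/2 ≈ 5×10⁻³ %·s per
  crossing at 500 Hz; the crossing-split rule removes it, and agreement
  with adaptive quadrature on closed-form pulses is below 10⁻³ %·s.
* **Mask convention.** We integrate the full |strain| over samples below
  −5%, not |strain|−5: the dead zone excludes samples from contributing,
  it is not an offset.
* **Peak ties.** `Tpeak` is the first global minimum (earliest
  mechanical event); deterministic.
* **Flat segments.** A segment that never exceeds the dead zone has no
  peak time: `Ipeak = 0`, `E = −Iavc`, and it is excluded from the
  `Tpeak` mean/std/`dTpeak` statistics (count logged). A view where all
  six segments are flat is flagged low-quality and the patient skipped.
  Downstream rankers require complete data; the pipeline median-imputes
  any resulting missing values before ranking.
* **Std convention.** Per-view stds use the sample convention (ddof 1).
* **Constant features.** The AVC times are constant across a synthetic
  cohort; univariate statistics on n identical floats produce ~10⁻¹⁶
  variance through mean round-off, so all rankers detect exactly
  constant columns (max == min) and score them zero. For the same
  reason the correlation-graph threshold comparison rounds |r| to 12
  decimals, so an exactly-0.5 correlation never draws an edge.

## Synthetic cohort generator

Curves are sums of raised-cosine lobes with closed-form extrema (so every
feature has an analytic oracle), plus white measurement noise (default
1%). Default export rate is 100 Hz — above the ≥60 frames/s acquisition
floor — so the 500 Hz upsampling step does real work.

Wall mechanics (cycle length 1 s, AVC ≈ 0.39–0.41 s per view):

* **Septal-type walls** (4ch septal, 3ch anteroseptal) follow the LBBB
  triple pattern: an early systolic lobe (peak ≈ −10% at 0.25 s) with a
  rebound-stretch lobe, then a deeper post-systolic lobe (≈ 0.58 s,
  after AVC). The global peak is therefore late and septal `E` is
  positive — part of the septal work is wasted, as expected in LBBB.
* **Lateral wall** (4ch): a single delayed lobe peaking after AVC
  (≈ 0.48 s, ≈ −12%).
* **Other walls** (2ch, 3ch posterior): single lobe near AVC.

Per-patient variability is independent Gaussian jitter on every lobe
parameter; one integer seed drives everything. Labels are drawn first
(responder count = round(0.64 × n), so n = 130 gives exactly 83/47) and
all parameters are conditioned on the label; end-systolic volume pairs
are drawn from label-conditional decrease fractions (responders 20–45%,
non-responders −8–10%) so the strict >15% rule reproduces the labels
exactly.

**Responder effects** (4-chamber view, where the septal–lateral LBBB
axis is imaged): the septal-efficiency effect deepens (+3%), delays
(+0.03 s) and broadens (+0.08 s) the post-systolic lobe — three
co-directional routes into the septal `E` features; the lateral effect
strengthens (+4%) and further delays (+0.05 s) the lateral peak, raising
the lateral cumulative-strain features. The broadening route is neutral
to both `P` (depth) and `Tpeak` (timing), which is what makes the wall
sum `E_4ch_S` the dominant group separator rather than the peak-based
aggregates; with only the septal effect enabled, the best-separating
feature is a septal `E` feature. The declared carriers of the planted
effects are `E_4ch_BS/MS/AS`, `E_4ch_S` and `Ipeak_4ch_L`.

What the generator does **not** emulate: beat-to-beat variability and
arrhythmia, drift and tracking artifacts of speckle tracking, inter-view
inconsistency of a real probe session, correlated (colored) measurement
noise, and any realistic covariance between clinical scalars and
mechanics (QRS/LVEF are drawn from group-conditional normals and carry
negligible signal). Passing recovery tests therefore demonstrates that
the pipeline detects the effects it is pointed at under clean, known
conditions — not that those effects are detectable at clinical
signal-to-noise.

## Importance stage

* **OOB forest.** 700 classification trees (gini, unlimited depth,
  inverse-class-frequency weights). Each tree gets a bootstrap resample
  and a random subspace of 10 features — the feature set varies per
  tree, so out-of-bag sensitivity can be attributed per feature.
  Importance of a feature is the decrease in that tree's out-of-bag
  accuracy when the feature's OOB column is permuted, averaged over the
  trees whose subspace included it (a feature used by no tree scores 0),
  then normalized so the maximum is 1. Permutation-based rather than
  split-impurity importance: the quantity of interest is sensitivity of
  the out-of-bag decision, and "gini" refers to the split criterion.
* **Five filter/wrapper rankers**: |point-biserial r| with the label;
  |Welch t|; ANOVA F (the K-Best criterion); recursive feature
  elimination of an L2 logistic classifier on z-scored features (one
  feature per round, ties eliminate the lexicographically greatest
  name); ReliefF with k = 10 neighbors on min-max-scaled features, all
  samples used.
* **CWF consensus**: features in the top-20 of at least three of the
  five rankers, ordered by the mean of their ranks within the top-20
  lists *where they appear* (the alternative — averaging over all five
  with a penalty rank for absences — is a known ambiguity; the
  where-they-appear convention is used throughout).
* **Correlation graph**: Pearson |r| among a feature subset; an edge
  requires |r| strictly above 0.5 and is drawn with thickness
  10·|r| − 5 (so |r| = 1 → 5 points).
* Ties everywhere break lexicographically by feature name; all
  stochastic steps derive their seeds from the single run seed through
  `numpy.random.SeedSequence`, so each stage is independently
  reproducible and every output file carries the seed and a config hash.

## Problem sizes used in the test and analysis runs

The analysis scripts and the recovery experiments use the full study
shape: n = 130 patients (83/47), 158 features, 700 trees. The recovery
experiment repeats this over 20 seeds and its permuted-label control
over 10 seeds. Unit tests use smaller cohorts (5–34 patients) and
forests (60–200 trees) chosen to exercise the same code paths quickly.

## Known limitations

* The published importance values of the clinical cohort depend on the
  130 real patients and are not reproducible from synthetic data; the
  package reproduces the *structural* published quantities (feature
  census, view census of the published top-20 lists, their overlap, the
  graph-drawing rule, cohort proportions) and validates the methods
  against oracles and planted-effect recovery instead.
* ReliefF is the canonical k-nearest hits/misses variant; other Relief
  flavors (RReliefF, SURF) are out of scope.
* The RFE estimator and the K-Best score are conventional defaults; the
  methods they stand in for are named but not parameterized in the
  clinical description.
* No predictive-performance evaluation (accuracy/AUC of response
  prediction) is included — feature importance only.
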