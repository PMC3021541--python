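# Methods

## The analysis

The pipeline predicts a per-subject behavioural quantity — the improvement
in total game score between two MRI sessions — from the spatial pattern of
time-averaged T2\*-weighted EPI signal inside an anatomical region of
interest.

1. **Per-volume normalization.** Every EPI volume is divided by its mean
   intensity inside a brain mask. This compensates slow scanner drift and
   gain differences between runs and subjects; the in-mask mean of every
   normalized volume is exactly 1, so the operation is idempotent.
   Normalization happens *before* temporal averaging; averaging first and
   normalizing afterwards is not equivalent (the per-volume gain factors
   would not cancel) and is deliberately not offered.
2. **Temporal averaging.** Normalized volumes from the selected
   acquisition blocks are averaged voxelwise. Under the default 13-block
   schedule (seven 46-second passive-watching blocks interleaved with six
   4-minute active blocks at TR = 2 s) the two game-play and two
   game-plus-oddball blocks contribute 480 volumes. Averaging suppresses
   stimulus-driven BOLD fluctuations and leaves the stable,
   subject-specific component of the signal.
3. **Feature extraction.** The in-ROI voxels of the averaged volume form
   the subject's feature vector, in C-order scan of the ROI, with no voxel
   selection and no further scaling.
4. **ε-SVR with leave-one-subject-out cross-validation.** A linear
   ε-insensitive support vector regression is trained on all subjects but
   one and predicts the held-out subject's improvement; pooling the 34
   held-out predictions and Pearson-correlating them with the measured
   improvements gives the accuracy measure. The correlation is computed
   once over the pooled predictions, not per fold.
5. **Statistics.** Significance of a single correlation uses the
   exact-under-normality t test (t = r√(n−2)/√(1−r²), df = n−2); a
   Fisher-z normal test is available by flag. Differences between
   correlations use the Fisher-z two-sample test, which assumes
   independent samples; when the two correlations share subjects the
   result carries an "independence assumed" note, since no
   dependent-correlation correction is applied. Second-order partial
   correlations residualize both variables on two covariates by ordinary
   least squares with intercept and correlate the residuals (df = n−4).

## The SVR solver

The dual problem, in the paired-multiplier variable β = α − α\*, is

  max −½ βᵀKβ + yᵀβ − ε‖β‖₁  s.t. Σβᵢ = 0, |βᵢ| ≤ C,  K = XXᵀ.

It is solved by pairwise (SMO-style) coordinate ascent. Each sample's KKT
state implies an admissible interval for the bias b; the pair chosen is
(arg max lower bound, arg min upper bound) — the maximal violating pair,
ties broken toward the lowest index — and the two coordinates are updated
by exactly minimizing the one-dimensional restriction, a convex piecewise
quadratic with kinks where a β crosses zero. Convergence is declared when
the maximal KKT violation (max lower − min upper bound, in target units)
falls below `kkt_tol` (default 1e-6). The bias is the mean of the KKT
values over free support vectors, or the midpoint of the admissible
interval when no free support vector exists. On random small instances the
solver matches a generic QP solver's optimal objective to ~1e-14 relative
and a reference SVR's predictions to ~1e-6; primal–dual gap and
complementary slackness are asserted in the test suite.

### Hyperparameters

Neither C nor ε is dictated by the scientific problem, so both are
explicit configuration with scale-aware defaults:

- `epsilon="auto"` = 0.1 · SD of the training targets. The tube then
  ignores the smallest 10 %-of-spread deviations regardless of score units.
- `C="auto"` uses the Cherkassky–Ma heuristic
  max(|ȳ + 3σ_y|, |ȳ − 3σ_y|) on the training targets. A fixed default
  such as C = 1 is meaningless here: the features are normalized
  intensities of order 1 with voxel-to-voxel variation of order 0.01,
  while the targets are game-score improvements of order 10³, so a
  unit-box dual cannot move predictions away from a constant and every
  fold would predict (approximately) its training centre. The heuristic
  keeps the box commensurate with the target scale.
- No per-feature standardization by default — the upstream normalization
  is global, not per-voxel — but fold-internal standardization is
  available via `SvrConfig(standardize=True)`.

## The synthetic cohort generator

Real data of this kind are not publicly deposited, so validation uses
simulated cohorts with known ground truth. Inside an ellipsoidal "brain"
on a 16 × 16 × 12 grid at EPI resolution (3.4375 × 3.4375 × 4 mm), subject
s's volume at timepoint t is

  v(s,t) = baseline + g·y_s·1_ROI + γ·y_s·W + η_s + ε_{s,t}

with baseline 100 intensity units; y_s ~ N(1500, 1000²) the true score
improvement (game points); W a fixed random voxel pattern confined to the
configured signal subregion, zero-sum and unit-RMS, so the pattern carries
no spatial-mean information; η_s ~ N(0, 1²) per-voxel subject-level
"anatomy", fixed over time; and ε_{s,t} ~ N(0, 5²) fresh per timepoint.
Two box ROIs ("dorsal striatum", left and right, 128 voxels each) sit
symmetrically in the brain; by default the pattern signal occupies the
whole left ROI and the right ROI is pure null. Scores decompose into four
sub-scores (control, velocity, speed, points) that sum exactly to the
session totals; ROI-volume and initial-score covariates are generated
independent of y_s so partial-correlation analyses have a known null.
Tissue partial-volume maps are produced by softmax over template class
logits (deep white-matter core, gray-matter shell, a small central CSF
compartment, an ambiguous WM/GM transition band) plus a smooth per-subject
random field, guaranteeing fractions in [0,1] summing to ≤ 1 and all four
consensus-label outcomes. Everything is deterministic given the config
seed.

### Effect-size defaults

No published effect size exists in intensity units, so the defaults were
calibrated once, and then frozen, to reproduce the *reported operating
point* of the motivating study: `signal_gain = 2.5e-4` intensity units per
score point puts the per-voxel pattern SD at a quarter of the
between-subject anatomical SD and yields a median LOSO pattern correlation
of ≈ 0.79 across seeds (the study reported 0.74–0.82 across striatal
ROIs); `global_gain = 6e-5` yields a spatial-mean correlation of ≈ 0.5
(reported: 0.47). The pattern correlation exceeded the spatial-mean
correlation in every seed examined.

### Problem sizes

The full-schedule cohort (34 subjects × 881 volumes) is used for the
single-cohort demonstrations and the acceptance script. Multi-seed suites
(parameter recovery, null calibration) use a scaled-down schedule — the
same 13-block structure with 3/16 volumes per passive/active block — with
the temporal noise SD lowered from 5 to 2 so that the noise SD of the
*time-averaged* volume matches the full schedule (5/√480 ≈ 2/√64); the
operating characteristics of the analysis are thereby preserved at a
fraction of the simulation cost (verified: median pattern r 0.788 vs
0.783, spatial-mean r 0.52).

## What the simulations do and do not show

The generator reproduces the statistical structure the analysis assumes —
a linear, time-stable multi-voxel signal plus Gaussian noise on a common
grid — and therefore supports parameter-recovery and calibration claims
about the *pipeline*. It does not emulate registration error, motion,
field inhomogeneity, hemodynamics, spatially correlated noise, or
non-linear brain–behaviour relationships; passing tests say nothing about
whether real T2\* patterns carry such signals.

## Known limitations

- **The pooled-LOSO correlation test is not calibrated under the null.**
  With no signal present, the held-out predictions are not independent of
  the measured scores: each fold's bias tracks its training fold's centre,
  which moves opposite to the held-out subject's score (driving the null
  correlation strongly negative for capacity-limited fits, mean r ≈ −0.6
  under the default configuration), and the predictions of different
  subjects are mutually correlated through their shared training subjects
  (overdispersing r by ~1.5× relative to the nominal 1/√(n−1) even when
  the mean is centred, for large-C fits). Across the C/ε regimes examined
  the two-tailed t test rejects a true null in far more than 5 % of
  simulated cohorts (≈ 87 % at the defaults; 13–24 % in the best large-C
  regimes). This is a property of correlating pooled cross-validated
  predictions with their targets, not of the solver; permutation testing
  would be the remedy but parametric testing is retained as the method
  under study. Significance values from `loso_predict` should therefore
  be read as descriptive, and the accompanying calibration test documents
  the failure rather than hiding it.
- Correlation comparisons between overlapping ROIs assume independent
  samples (flagged in the output); no dependent-correlation correction is
  applied.
- The coronal-split tie-break (smaller anterior count) and the
  median-split tie handling (alternate assignment by ascending subject id
  to the smaller group, good first on exact balance) are fixed
  conventions chosen for determinism where the procedure is otherwise
  underdetermined.
- Percentile ranks for the relative score improvement use the midpoint
  convention (rank − 0.5)/n, average ranks for ties; session-2 scores are
  mapped through a normal model with session-1 sample mean and SD
  (ddof = 1).
- `subsample_volume` requires integer voxel-size ratios (block averaging);
  fractional resampling is out of scope.
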