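# t2mvpa

Predicting individual learning success from multi-voxel patterns of
time-averaged T2\*-weighted MRI.

## The problem

People differ widely in how much they improve with training on complex
skills. Region-of-interest MRI studies have shown that the *pattern* of
time-averaged T2\*-weighted (EPI) signal in the dorsal striatum, recorded
before training, predicts a person's subsequent improvement in a complex
video game far better than the regional mean signal does. `t2mvpa`
implements that analysis pipeline as a tested, reusable Python package for
methodologists and neuroimaging researchers who want to study, validate, or
extend it:

- **Preprocessing** — each EPI volume is divided by its within-brain mean
  (drift compensation), the volumes from selected task blocks are averaged
  over time, and the in-ROI voxel intensities of the average become one
  feature vector per subject. Consensus tissue segmentation (label a voxel
  WM/GM/CSF only if the group-averaged partial volume exceeds 50 %),
  coronal anterior/posterior ROI splitting, and block-average resampling
  are included.
- **ε-support-vector regression** — the core estimator, written from the
  primal/dual formulation. For features x_i and targets y_i it solves

      min_{w,b,ξ,ξ*}  ½‖w‖² + C Σᵢ (ξᵢ + ξᵢ*)
      s.t.  y_i − w·x_i − b ≤ ε + ξᵢ,   w·x_i + b − y_i ≤ ε + ξᵢ*,  ξ, ξ* ≥ 0

  via the dual (box constraints 0 ≤ α, α\* ≤ C, equality Σ(αᵢ−αᵢ\*) = 0)
  with SMO-style pairwise ascent on the maximal KKT-violating pair, weights
  w = Σ(αᵢ−αᵢ\*)x_i and KKT-based bias recovery.
- **Leave-one-subject-out cross-validation (LOSO)** — each subject's score
  improvement is predicted by a model trained on all other subjects; the
  pooled Pearson correlation between predicted and measured improvement
  measures prediction accuracy.
- **Correlation statistics** — Fisher z transform (z = ½ ln((1+r)/(1−r))),
  t tests on correlations, Fisher-z comparison of two correlations,
  second-order partial correlations against covariates (ROI volume,
  initial score), median-split good/poor learner comparisons, R², and
  percentile-rank relative score improvement.
- **Synthetic cohorts** — the original study's raw data are not deposited,
  so the package ships a generator that simulates cohorts with the
  assumed statistical structure (a zero-sum voxel pattern and a weak
  global in-ROI shift, both proportional to each subject's true score
  improvement, plus subject-level anatomical variation and per-timepoint
  noise) with known ground truth for parameter-recovery testing.

## Worked example

```python
from t2mvpa import MVPAModel, spatial_mean_analysis, average_cohort
from t2mvpa.simulate import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=1))   # 34 subjects, 881 volumes each
res = MVPAModel.from_cohort(cohort, "dorsal_striatum_left").fit()
print(res.summary())
```

```
MVPA LOSO Prediction Results
==============================================
ROI:                      dorsal_striatum_left
Subjects:                                   34
Voxels (features):                         128
Training size per fold:                     33
Pearson r (pred, meas):                 0.8777
Fisher z:                               1.3658
R squared:                              0.7704
t statistic (df=n-2):                  10.3624
Two-tailed p:                         9.42e-12
==============================================
```

The model averaged the 480 game-play volumes of each subject's series,
extracted the 128 left-ROI voxels, and ran 34 leave-one-out SVR fits; the
predicted improvements correlate r = 0.88 with the simulated true ones,
i.e. the pattern explains 77 % of the between-subject variance in this
cohort. The spatial-mean baseline on the same data is much weaker:

```python
vols, n_used = average_cohort(cohort)            # n_used == 480
means, corr = spatial_mean_analysis(vols, cohort.masks["dorsal_striatum_left"],
                                    cohort.scores["score_improvement"])
print(f"spatial mean: r = {corr.r:.2f}, p = {corr.p:.3g}")
```

```
spatial mean: r = 0.29, p = 0.1
```

A command-line interface mirrors the library
(`t2mvpa simulate | preprocess | predict | report | run-all`), reading and
writing NIfTI volumes and tab-delimited tables with provenance headers.

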