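"""Leave-one-subject-out prediction and the surrounding group analyses.

The central object is :class:`MVPAModel`: a subjects x voxels feature
matrix (time-averaged, normalized in-ROI intensities) paired with a
per-subject behavioural target (score improvement).  Its :meth:`fit`
runs leave-one-subject-out cross-validation of a linear eps-SVR — each
subject is predicted by a model trained on all the others — and returns
an :class:`MVPAResults` carrying the pooled predicted-vs-measured
correlation, per-fold diagnostics and a summary table.

Also here: the spatial-mean baseline (one mean intensity per subject),
the median-split good/poor learner comparison, the good-minus-poor
difference pattern, and the ROI x score battery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as st
from .preprocess import (BrainVolume, FeatureMatrix, ROIMask,
                         extract_features, temporal_average)
from .svr import EpsilonSVR, SvrConfig

logger = logging.getLogger(__name__)

__all__ = [
    "CvPrediction", "GroupComparison", "DifferencePattern",
    "MVPAModel", "MVPAResults",
    "loso_predict", "spatial_mean_analysis", "median_split_compare",
    "difference_pattern", "run_roi_battery", "average_cohort",
]


@dataclass
class CvPrediction:
    """Per-subject LOSO predictions and the pooled correlation."""

    table: pd.DataFrame                    # subject_id, y_measured, y_predicted
    fold_sizes: list[int]
    correlation: st.CorrelationResult


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison of a quantity between good and poor learners."""

    mean_good: float
    mean_poor: float
    n_good: int
    n_poor: int
    t_stat: float
    df: float
    p: float
    good_idx: np.ndarray
    poor_idx: np.ndarray
    variant: str = "pooled"


@dataclass
class DifferencePattern:
    """Good-minus-poor mean pattern after per-subject mean subtraction."""

    data: np.ndarray
    roi_name: str


def loso_predict(features: FeatureMatrix | np.ndarray, scores,
                 svr_config: SvrConfig | None = None) -> CvPrediction:
    """Predict each subject's score from a model trained on the others.

    The Pearson correlation of predicted vs measured scores is computed
    once over the pooled predictions of all subjects, not per fold.
    """
    if isinstance(features, FeatureMatrix):
        X = features.values
        ids = features.subject_ids or [f"s{i:02d}" for i in range(X.shape[0])]
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        ids = [f"s{i:02d}" for i in range(X.shape[0])]
    y = np.asarray(scores, dtype=float).ravel()
    n = X.shape[0]
    if y.size != n:
        raise ValueError(f"{y.size} scores for {n} subjects")
    if n < 4:
        raise ValueError(f"LOSO needs at least 4 subjects, got {n}")
    cfg = svr_config or SvrConfig()
    preds = np.empty(n)
    fold_sizes = []
    for s in range(n):
        train = np.arange(n) != s
        try:
            res = EpsilonSVR(y[train], X[train], config=cfg).fit()
        except Exception as exc:
            raise RuntimeError(
                f"SVR fit failed in LOSO fold for subject {ids[s]!r}: {exc}"
            ) from exc
        preds[s] = res.predict(X[s:s + 1])[0]
        fold_sizes.append(int(train.sum()))
        logger.debug("fold %s: n_train=%d C=%.4g eps=%.4g iters=%d",
                     ids[s], fold_sizes[-1], res.C, res.epsilon, res.n_iter)
    corr = st.pearson_r(preds, y)
    table = pd.DataFrame(
        {"subject_id": ids, "y_measured": y, "y_predicted": preds})
    return CvPrediction(table, fold_sizes, corr)


def spatial_mean_analysis(volumes: Sequence[BrainVolume], roi: ROIMask,
                          scores) -> tuple[np.ndarray, st.CorrelationResult | None]:
    """Correlate per-subject mean in-ROI intensity with the scores.

    Returns the per-subject means and the correlation; the correlation is
    ``None`` when it is undefined (zero variance in the means).
    """
    y = np.asarray(scores, dtype=float).ravel()
    means = np.empty(len(volumes))
    for i, vol in enumerate(volumes):
        if vol.data.shape != roi.data.shape:
            raise ValueError(f"subject {i}: volume grid differs from ROI grid")
        means[i] = vol.data[roi.data].mean()
    if means.size != y.size:
        raise ValueError("scores and volumes differ in length")
    try:
        corr = st.pearson_r(means, y)
    except st.DegenerateDataError:
        corr = None
    return means, corr


def _median_split(scores, subject_ids=None) -> tuple[np.ndarray, np.ndarray]:
    """Indices of good (above-median) and poor (below-median) learners.

    For even n the median is the midpoint of the two central order
    statistics.  Subjects whose score equals the median exactly are
    assigned alternately (ascending subject id) to whichever group is
    currently smaller, good first on exact balance, so the groups stay
    as equal as possible.
    """
    y = np.asarray(scores, dtype=float).ravel()
    if y.size < 4:
        raise ValueError("median split needs at least 4 subjects")
    if np.ptp(y) == 0:
        raise ValueError("all scores equal; median split impossible")
    ids = (list(subject_ids) if subject_ids is not None
           else [f"s{i:02d}" for i in range(y.size)])
    med = float(np.median(y))
    good = list(np.flatnonzero(y > med))
    poor = list(np.flatnonzero(y < med))
    ties = sorted(np.flatnonzero(y == med), key=lambda i: ids[i])
    for i in ties:
        if len(good) <= len(poor):
            good.append(i)
        else:
            poor.append(i)
    return np.asarray(sorted(good), dtype=int), np.asarray(sorted(poor), dtype=int)


def median_split_compare(values, scores, subject_ids=None,
                         welch: bool = False) -> GroupComparison:
    """Two-sample t test of ``values`` between good and poor learners.

    Groups come from a median split of ``scores``; the default test is
    the classical pooled-variance t test (group sizes are equal by
    construction), Welch's variant by flag.
    """
    from scipy import stats as sps
    v = np.asarray(values, dtype=float).ravel()
    y = np.asarray(scores, dtype=float).ravel()
    if v.size != y.size:
        raise ValueError("values and scores differ in length")
    good, poor = _median_split(y, subject_ids)
    res = sps.ttest_ind(v[good], v[poor], equal_var=not welch)
    if welch:
        df = float(res.df)
    else:
        df = float(good.size + poor.size - 2)
    t_stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t_stat):  # identical values in both groups
        t_stat, p = 0.0, 1.0
    return GroupComparison(float(v[good].mean()), float(v[poor].mean()),
                           good.size, poor.size, t_stat, df, p,
                           good, poor, "welch" if welch else "pooled")


def difference_pattern(volumes: Sequence[BrainVolume], roi: ROIMask,
                       scores) -> DifferencePattern:
    """Good-minus-poor average in-ROI pattern, per-subject mean removed.

    Each subject's mean in-ROI intensity is subtracted from their in-ROI
    voxels; the centered patterns are averaged within the good and poor
    learner groups (median split of the scores) and subtracted.  The map
    is zero outside the ROI.
    """
    y = np.asarray(scores, dtype=float).ravel()
    good, poor = _median_split(y)
    if good.size < 2 or poor.size < 2:
        raise ValueError("need at least 2 subjects per group")
    pats = []
    for vol in volumes:
        p = vol.data[roi.data]
        pats.append(p - p.mean())
    pats = np.vstack(pats)
    diff = pats[good].mean(axis=0) - pats[poor].mean(axis=0)
    out = np.zeros(roi.data.shape)
    out[roi.data] = diff
    return DifferencePattern(out, roi.name)


def average_cohort(cohort, include_blocks=("SF", "SO")):
    """Per-subject normalized temporal averages of a synthetic cohort.

    Returns (volumes, n_volumes_used); the count is identical across
    subjects since they share the block schedule.
    """
    brain = cohort.masks["brain"]
    vols, n_used = [], None
    for series in cohort.subjects:
        vol, n = temporal_average(series, include_blocks, brain)
        vols.append(vol)
        n_used = n
    return vols, n_used


def run_roi_battery(volumes: Sequence[BrainVolume], rois: Mapping[str, ROIMask],
                    scores: pd.DataFrame, score_columns: Sequence[str],
                    svr_config: SvrConfig | None = None,
                    comparisons: Sequence[tuple[str, str]] = (),
                    subject_ids: Sequence[str] | None = None,
                    bonferroni: bool = False,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LOSO prediction for every (ROI, score column) pair.

    Returns a tidy results table (one row per ROI x score) and a
    comparison table with Fisher-z tests between the requested ROI pairs
    for every score column.  ``bonferroni`` optionally multiplies the
    battery p values by the number of rows (off by default).
    """
    ids = list(subject_ids) if subject_ids is not None else list(
        scores["subject_id"]) if "subject_id" in scores else None
    results = {}
    rows = []
    for roi_name, roi in rois.items():
        feats = extract_features(volumes, roi, ids)
        for col in score_columns:
            y = scores[col].to_numpy(dtype=float)
            cv = loso_predict(feats, y, svr_config)
            results[(roi_name, col)] = cv.correlation
            c = cv.correlation
            rows.append({"roi": roi_name, "score": col, "n": c.n, "r": c.r,
                         "z_fisher": c.z_fisher, "stat": c.stat, "df": c.df,
                         "p": c.p})
    table = pd.DataFrame(rows)
    if bonferroni:
        table["p_bonferroni"] = np.minimum(table["p"] * len(table), 1.0)
    comp_rows = []
    for roi_a, roi_b in comparisons:
        for col in score_columns:
            ca, cb = results[(roi_a, col)], results[(roi_b, col)]
            cmp_res = st.compare_correlations(ca.r, ca.n, cb.r, cb.n)
            comp_rows.append({
                "roi_a": roi_a, "roi_b": roi_b, "score": col,
                "r_a": ca.r, "r_b": cb.r, "z_stat": cmp_res.z_stat,
                "p": cmp_res.p, "note": cmp_res.note})
    comp = pd.DataFrame(comp_rows, columns=[
        "roi_a", "roi_b", "score", "r_a", "r_b", "z_stat", "p", "note"])
    return table, comp


class MVPAModel:
    """Multi-voxel pattern model: predict a score from in-ROI intensities.

    Parameters
    ----------
    endog : array_like, shape (n,)
        Per-subject target (score improvement).
    exog : FeatureMatrix or array, shape (n, k)
        Time-averaged normalized in-ROI intensities.
    svr_config : SvrConfig, optional
        Hyperparameters of the underlying linear eps-SVR.
    """

    def __init__(self, endog, exog, svr_config: SvrConfig | None = None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = exog
        self.svr_config = svr_config or SvrConfig()

    @classmethod
    def from_cohort(cls, cohort, roi_name: str,
                    score_column: str = "score_improvement",
                    include_blocks=("SF", "SO"),
                    svr_config: SvrConfig | None = None) -> "MVPAModel":
        vols, _ = average_cohort(cohort, include_blocks)
        feats = extract_features(vols, cohort.masks[roi_name],
                                 list(cohort.scores["subject_id"]))
        return cls(cohort.scores[score_column].to_numpy(), feats, svr_config)

    def fit(self) -> "MVPAResults":
        """Run the leave-one-subject-out cross-validation."""
        cv = loso_predict(self.exog, self.endog, self.svr_config)
        return MVPAResults(self, cv)


@dataclass
class MVPAResults:
    """LOSO results: per-subject predictions and the pooled correlation."""

    model: MVPAModel
    cv: CvPrediction

    @property
    def predictions(self) -> pd.DataFrame:
        return self.cv.table

    @property
    def correlation(self) -> st.CorrelationResult:
        return self.cv.correlation

    @property
    def r_squared(self) -> float:
        return st.r_squared(self.cv.correlation.r)

    def summary(self) -> str:
        c = self.cv.correlation
        roi = getattr(self.model.exog, "roi_name", "features")
        k = (self.model.exog.values.shape[1]
             if hasattr(self.model.exog, "values")
             else np.atleast_2d(self.model.exog).shape[1])
        lines = [
            "MVPA LOSO Prediction Results",
            "=" * 46,
            f"{'ROI:':<26}{roi:>20}",
            f"{'Subjects:':<26}{c.n:>20}",
            f"{'Voxels (features):':<26}{k:>20}",
            f"{'Training size per fold:':<26}{c.n - 1:>20}",
            f"{'Pearson r (pred, meas):':<26}{c.r:>20.4f}",
            f"{'Fisher z:':<26}{c.z_fisher:>20.4f}",
            f"{'R squared:':<26}{self.r_squared:>20.4f}",
            f"{'t statistic (df=n-2):':<26}{c.stat:>20.4f}",
            f"{'Two-tailed p:':<26}{c.p:>20.3g}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Scatter of predicted vs measured scores with the LS fit line."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        t = self.cv.table
        ax.scatter(t["y_measured"], t["y_predicted"], s=24)
        coef = np.polyfit(t["y_measured"], t["y_predicted"], 1)
        xs = np.linspace(t["y_measured"].min(), t["y_measured"].max(), 2)
        ax.plot(xs, np.polyval(coef, xs), "--", color="gray")
        c = self.cv.correlation
        ax.set_xlabel("measured score improvement")
        ax.set_ylabel("predicted score improvement")
        ax.set_title(f"LOSO prediction (r = {c.r:.2f}, p = {c.p:.2g})")
        return ax
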