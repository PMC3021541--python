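"""Correlation inference for brain-behaviour prediction studies.

Everything the prediction pipeline reports funnels through this module:
Pearson correlations with parametric significance, the Fisher z transform
used to compare correlations between regions, second-order partial
correlations that remove anatomical covariates, and the percentile-rank
relative score improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "CorrelationComparison",
    "PartialCorrResult",
    "pearson_r",
    "fisher_z",
    "fisher_z_inv",
    "compare_correlations",
    "partial_correlation",
    "r_squared",
    "percentile_ranks",
    "relative_improvement",
]


class DegenerateDataError(ValueError):
    """Raised when an input has no variance (or is otherwise collinear)."""


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson correlation with its significance test.

    Attributes
    ----------
    r : float
        Product-moment correlation coefficient.
    n : int
        Sample size.
    z_fisher : float
        Fisher-transformed coefficient, ``0.5 * log((1 + r) / (1 - r))``.
    stat : float
        Test statistic (t by default, standard normal for the Fisher-z test).
    df : float
        Degrees of freedom of the test (``n - 2`` for the t test; NaN for
        the normal Fisher-z test).
    p : float
        Two-tailed probability.
    method : str
        ``"t"`` or ``"fisher-z"``.
    """

    r: float
    n: int
    z_fisher: float
    stat: float
    df: float
    p: float
    method: str = "t"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"r = {self.r:.3f} (n = {self.n}, p = {self.p:.3g})"


@dataclass(frozen=True)
class CorrelationComparison:
    """Fisher-z test of the difference between two correlations."""

    r1: float
    n1: int
    r2: float
    n2: int
    z_stat: float
    p: float
    note: str = "independence assumed"


@dataclass(frozen=True)
class PartialCorrResult:
    """Partial correlation after residualizing on covariates."""

    r_partial: float
    order: int
    n: int
    stat: float
    df: float
    p: float


def _as_1d(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def pearson_r(x, y, method: str = "t") -> CorrelationResult:
    """Pearson correlation of ``x`` and ``y`` with a two-tailed test.

    The default significance test is the exact-under-normality t test,
    ``t = r * sqrt(n - 2) / sqrt(1 - r**2)`` with ``n - 2`` degrees of
    freedom.  ``method="fisher-z"`` instead refers ``z_fisher * sqrt(n - 3)``
    to the standard normal distribution.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    r = float(sps.pearsonr(xa, ya).statistic)
    r = float(np.clip(r, -1.0, 1.0))
    zf = fisher_z(r) if abs(r) < 1 else np.inf * np.sign(r)
    if method == "t":
        df = n - 2
        if abs(r) == 1.0:
            stat, p = np.inf * np.sign(r), 0.0
        else:
            stat = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
            p = 2.0 * sps.t.sf(abs(stat), df)
        return CorrelationResult(r, n, float(zf), float(stat), float(df), float(p), "t")
    if method == "fisher-z":
        if n < 4:
            raise ValueError("fisher-z test needs n >= 4")
        stat = zf * np.sqrt(n - 3)
        p = 2.0 * sps.norm.sf(abs(stat))
        return CorrelationResult(r, n, float(zf), float(stat), np.nan, float(p), "fisher-z")
    raise ValueError(f"unknown method {method!r}")


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform, ``0.5 * ln((1+r)/(1-r))``."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1, got {r}")
    return float(np.arctanh(r))


def fisher_z_inv(z: float) -> float:
    """Inverse of :func:`fisher_z` (the hyperbolic tangent)."""
    return float(np.tanh(z))


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Two-tailed Fisher-z test of ``r1 == r2`` from independent samples.

    ``Z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3))`` referred to the standard
    normal.  The samples are treated as independent even when the two
    correlations were computed on the same subjects; the result carries a
    note to that effect.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("comparison requires n >= 4 in both samples")
    z1, z2 = fisher_z(r1), fisher_z(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_stat = (z1 - z2) / se
    p = 2.0 * sps.norm.sf(abs(z_stat))
    return CorrelationComparison(float(r1), int(n1), float(r2), int(n2),
                                 float(z_stat), float(min(p, 1.0)))


def partial_correlation(y, x, covariates) -> PartialCorrResult:
    """Partial correlation of ``y`` and ``x`` given ``covariates``.

    Both variables are residualized on the covariates (ordinary least
    squares with an intercept) and the residuals are Pearson-correlated.
    Significance uses ``df = n - 2 - k`` where ``k`` is the number of
    covariates ("order"); order 0 reduces exactly to :func:`pearson_r`.
    """
    ya, xa = _as_1d(y, "y"), _as_1d(x, "x")
    covs = [_as_1d(c, "covariate") for c in covariates]
    n = ya.size
    if xa.size != n or any(c.size != n for c in covs):
        raise ValueError("all vectors must have equal length")
    k = len(covs)
    if n - 2 - k < 1:
        raise ValueError("too few samples for the requested order")
    if k == 0:
        base = pearson_r(xa, ya)
        return PartialCorrResult(base.r, 0, n, base.stat, base.df, base.p)
    design = np.column_stack([np.ones(n)] + covs)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateDataError("covariates are collinear")
    beta_y, *_ = np.linalg.lstsq(design, ya, rcond=None)
    beta_x, *_ = np.linalg.lstsq(design, xa, rcond=None)
    ry = ya - design @ beta_y
    rx = xa - design @ beta_x
    scale = max(np.std(xa), 1.0)
    if np.std(rx) < 1e-10 * scale or np.std(ry) < 1e-10 * max(np.std(ya), 1.0):
        raise DegenerateDataError(
            "a variable is collinear with the covariates (zero residual variance)")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        stat, p = np.inf * np.sign(r), 0.0
    else:
        stat = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        p = 2.0 * sps.t.sf(abs(stat), df)
    return PartialCorrResult(r, k, n, float(stat), float(df), float(p))


def r_squared(r: float) -> float:
    """Fraction of variance explained by a correlation of ``r``."""
    r = float(r)
    if abs(r) > 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    return r * r


def percentile_ranks(values) -> np.ndarray:
    """Within-sample percentile ranks, midpoint convention.

    ``(rank - 0.5) / n * 100`` with average ranks for ties, so the middle
    of an odd-sized sample sits at exactly 50 and the output depends on
    the values only through their ordering.
    """
    v = _as_1d(values, "values")
    ranks = sps.rankdata(v, method="average")
    return (ranks - 0.5) / v.size * 100.0


def relative_improvement(scores_s1, scores_s2) -> np.ndarray:
    """Percentile-rank relative score improvement between two sessions.

    Game scores can be negative, so a plain percent change is ill-defined.
    Session-1 scores are converted to within-sample percentile ranks
    ``R(t1)`` (midpoint convention, average rank for ties); session-2 scores
    are mapped through the session-1 normal model,
    ``R(t2) = 100 * Phi((s2 - mean1) / sd1)`` with the sample SD of the
    session-1 scores.  The relative improvement is
    ``(R(t2) - R(t1)) / R(t1)``.
    """
    s1 = _as_1d(scores_s1, "scores_s1")
    s2 = _as_1d(scores_s2, "scores_s2")
    if s1.size != s2.size:
        raise ValueError("sessions must have equal length")
    n = s1.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    sd1 = float(np.std(s1, ddof=1))
    if sd1 == 0:
        raise DegenerateDataError("session-1 scores have zero variance")
    r_t1 = percentile_ranks(s1)
    r_t2 = 100.0 * sps.norm.cdf((s2 - s1.mean()) / sd1)
    return (r_t2 - r_t1) / r_t1
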