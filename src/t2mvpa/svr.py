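r"""Linear epsilon-insensitive support vector regression.

The estimator solves the classical flatness-regularized regression problem

.. math::

    \min_{w, b, \xi, \xi^*} \tfrac12 \lVert w\rVert^2
        + C \sum_i (\xi_i + \xi_i^*)

subject to ``y_i - w.x_i - b <= eps + xi_i`` and
``w.x_i + b - y_i <= eps + xi_i*`` with nonnegative slacks: residuals inside
the eps-tube are free, larger deviations are penalized linearly at rate C.

The solver works on the dual.  Writing ``beta_i = alpha_i - alpha_i*`` for
the paired Lagrange multipliers (which can never both be nonzero), the dual
is the concave box-constrained problem

.. math::

    \max_\beta \; -\tfrac12 \beta^\top K \beta + y^\top \beta
        - \varepsilon \lVert\beta\rVert_1
    \quad \text{s.t.} \quad \sum_i \beta_i = 0, \; |\beta_i| \le C,

with ``K = X X^T`` the linear Gram matrix.  It is optimized by pairwise
(SMO-style) coordinate ascent on the maximal-KKT-violating pair, with the
one-dimensional subproblem solved exactly (it is a convex piecewise
quadratic with kinks where a ``beta`` crosses zero).  The weight vector is
recovered as ``w = sum_i beta_i x_i`` and the bias from the KKT conditions
of the free support vectors.

The public surface follows the Model/Results convention: build an
:class:`EpsilonSVR` from targets and features, call :meth:`~EpsilonSVR.fit`,
and read estimates off the returned :class:`EpsilonSVRResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SvrConfig", "EpsilonSVR", "EpsilonSVRResults", "SvrConvergenceError", "fit_svr"]


class SvrConvergenceError(RuntimeError):
    """Solver stopped before reaching the requested KKT tolerance."""

    def __init__(self, msg: str, violation: float):
        super().__init__(f"{msg} (achieved KKT violation {violation:.3g})")
        self.violation = violation


@dataclass(frozen=True)
class SvrConfig:
    """Hyperparameters and solver controls.

    Parameters
    ----------
    C : float or "auto"
        Trade-off between flatness of ``w`` and tolerance for deviations
        beyond ``epsilon``.  ``"auto"`` uses the Cherkassky–Ma heuristic
        ``max(|mean(y) + 3 sd(y)|, |mean(y) - 3 sd(y)|)`` on the training
        targets, which keeps the box constraint on a scale commensurate
        with the target variable.
    epsilon : float or "auto"
        Half-width of the insensitivity tube; ``"auto"`` uses
        ``0.1 * sd(y)`` of the training targets.
    kkt_tol : float
        Maximum admissible KKT violation, on the scale of the targets.
    max_iter : int
        Cap on pairwise updates.
    standardize : bool
        Optional fold-internal per-feature standardization (off by default;
        upstream intensity normalization is global, not per-voxel).
    """

    C: float | str = "auto"
    epsilon: float | str = "auto"
    kkt_tol: float = 1e-6
    max_iter: int = 100_000
    standardize: bool = False

    def __post_init__(self):
        if self.C != "auto" and not (float(self.C) > 0):
            raise ValueError(f"C must be positive, got {self.C}")
        if self.epsilon != "auto" and not (float(self.epsilon) >= 0):
            raise ValueError(f"epsilon must be nonnegative, got {self.epsilon}")
        if not (self.kkt_tol > 0):
            raise ValueError("kkt_tol must be positive")

    def resolve(self, y: np.ndarray) -> tuple[float, float]:
        """Concrete (C, epsilon) for a given training target vector."""
        sd = float(np.std(y, ddof=0))
        if self.C == "auto":
            m = float(np.mean(y))
            c = max(abs(m + 3 * sd), abs(m - 3 * sd))
            c = c if c > 0 else 1.0
        else:
            c = float(self.C)
        eps = 0.1 * sd if self.epsilon == "auto" else float(self.epsilon)
        return c, eps


def _pair_step(bi, bj, Ei, Ej, eta, C, eps):
    """Exact minimizer of the 1-D pair subproblem.

    phi(t) = eta/2 t^2 - (Ei - Ej) t + eps (|bi + t| + |bj - t|), with
    bi + t and bj - t confined to [-C, C].  Convex, so evaluating phi at
    the kinks, the box ends and the per-segment stationary points finds
    the global minimum.
    """
    t_lo = max(-C - bi, bj - C)
    t_hi = min(C - bi, bj + C)
    if t_hi <= t_lo:
        return 0.0
    # candidate knots inside the box
    cand = [t_lo, t_hi]
    for knot in (-bi, bj):
        if t_lo < knot < t_hi:
            cand.append(knot)
    cand.sort()
    g = Ei - Ej
    best_t, best_phi = 0.0, np.inf
    for a, b in zip(cand[:-1], cand[1:]):
        if b <= a:
            continue
        mid = 0.5 * (a + b)
        si = 1.0 if bi + mid > 0 else -1.0
        sj = 1.0 if bj - mid > 0 else -1.0
        pts = [a, b]
        if eta > 1e-300:
            t_star = (g - eps * (si - sj)) / eta
            if a < t_star < b:
                pts.append(t_star)
        for t in pts:
            phi = 0.5 * eta * t * t - g * t + eps * (abs(bi + t) + abs(bj - t))
            if phi < best_phi - 0.0:
                best_phi, best_t = phi, t
    return best_t


def _smo_solve(K, y, C, eps, tol, max_iter):
    """Pairwise dual ascent.  Returns (beta, n_iter, violation, converged)."""
    n = y.shape[0]
    beta = np.zeros(n)
    Kb = np.zeros(n)
    snap = 1e-12 * max(1.0, C)
    lo = np.empty(n)
    hi = np.empty(n)
    stall = 0
    it = 0
    viol = np.inf
    for it in range(1, max_iter + 1):
        E = y - Kb
        # feasible-bias interval [lo_k, hi_k] implied by each sample's KKT state
        upper = beta >= C - snap          # alpha at C      -> b <= E - eps
        lower = beta <= -C + snap         # alpha* at C     -> b >= E + eps
        pos = (beta > snap) & ~upper      # free alpha      -> b = E - eps
        neg = (beta < -snap) & ~lower     # free alpha*     -> b = E + eps
        zero = ~(upper | lower | pos | neg)
        lo[:] = -np.inf
        hi[:] = np.inf
        lo[pos] = E[pos] - eps
        hi[pos] = E[pos] - eps
        lo[neg] = E[neg] + eps
        hi[neg] = E[neg] + eps
        lo[zero] = E[zero] - eps
        hi[zero] = E[zero] + eps
        hi[upper] = E[upper] - eps
        lo[lower] = E[lower] + eps
        i = int(np.argmax(lo))
        j = int(np.argmin(hi))
        viol = lo[i] - hi[j]
        if viol <= tol:
            return beta, it - 1, max(viol, 0.0), True
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        t = _pair_step(beta[i], beta[j], E[i], E[j], max(eta, 0.0), C, eps)
        if abs(t) <= snap:
            stall += 1
            if stall >= 5:
                return beta, it, viol, False
            continue
        stall = 0
        beta[i] += t
        beta[j] -= t
        for b_idx in (i, j):
            if abs(beta[b_idx]) < snap:
                beta[b_idx] = 0.0
            elif abs(beta[b_idx] - C) < snap:
                beta[b_idx] = C
            elif abs(beta[b_idx] + C) < snap:
                beta[b_idx] = -C
        Kb += t * (K[:, i] - K[:, j])
    return beta, it, viol, False


def _recover_bias(E, beta, C, eps):
    """Bias from KKT: average over free support vectors, else the midpoint
    of the feasible interval."""
    snap = 1e-8 * max(1.0, C)
    free_pos = (beta > snap) & (beta < C - snap)
    free_neg = (beta < -snap) & (beta > -C + snap)
    vals = np.concatenate([E[free_pos] - eps, E[free_neg] + eps])
    if vals.size:
        return float(vals.mean())
    lo, hi = [], []
    for k in range(beta.size):
        b = beta[k]
        if b >= C - snap:
            hi.append(E[k] - eps)
        elif b <= -C + snap:
            lo.append(E[k] + eps)
        else:  # beta == 0
            lo.append(E[k] - eps)
            hi.append(E[k] + eps)
    lo_b = max(lo) if lo else None
    hi_b = min(hi) if hi else None
    if lo_b is None:
        return float(hi_b)
    if hi_b is None:
        return float(lo_b)
    return float(0.5 * (lo_b + hi_b))


class EpsilonSVR:
    """Linear eps-SVR model for targets ``endog`` and features ``exog``.

    Parameters
    ----------
    endog : array_like, shape (n,)
        Target values (here: score improvements).
    exog : array_like, shape (n, d)
        Feature rows (here: in-ROI voxel intensities).
    config : SvrConfig, optional
        Hyperparameters; keyword shortcuts ``C`` and ``epsilon`` override
        the config fields.
    """

    def __init__(self, endog, exog, config: SvrConfig | None = None,
                 C=None, epsilon=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError(
                f"endog has {self.endog.shape[0]} samples but exog has "
                f"{self.exog.shape[0]} rows")
        if self.endog.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if self.exog.shape[1] < 1:
            raise ValueError("need at least 1 feature")
        if not (np.all(np.isfinite(self.endog)) and np.all(np.isfinite(self.exog))):
            raise ValueError("non-finite values in input")
        cfg = config or SvrConfig()
        if C is not None or epsilon is not None:
            cfg = SvrConfig(C=C if C is not None else cfg.C,
                            epsilon=epsilon if epsilon is not None else cfg.epsilon,
                            kkt_tol=cfg.kkt_tol, max_iter=cfg.max_iter,
                            standardize=cfg.standardize)
        self.config = cfg

    def fit(self) -> "EpsilonSVRResults":
        y = self.endog
        X = self.exog
        cfg = self.config
        mu = sigma = None
        if cfg.standardize:
            mu = X.mean(axis=0)
            sigma = X.std(axis=0, ddof=0)
            sigma = np.where(sigma > 0, sigma, 1.0)
            X = (X - mu) / sigma
        C, eps = cfg.resolve(y)
        K = X @ X.T
        beta, n_iter, viol, ok = _smo_solve(K, y, C, eps, cfg.kkt_tol, cfg.max_iter)
        if not ok:
            raise SvrConvergenceError(
                f"SMO did not reach kkt_tol={cfg.kkt_tol} in {n_iter} updates", viol)
        E = y - K @ beta
        b = _recover_bias(E, beta, C, eps)
        w = beta @ X
        alpha = np.maximum(beta, 0.0)
        alpha_star = np.maximum(-beta, 0.0)
        resid = y - (X @ w + b)
        slack = np.maximum(resid - eps, 0.0)
        slack_star = np.maximum(-resid - eps, 0.0)
        dual = float(-0.5 * beta @ K @ beta + y @ beta - eps * np.abs(beta).sum())
        primal = float(0.5 * w @ w + C * (slack.sum() + slack_star.sum()))
        return EpsilonSVRResults(
            model=self, params=w, bias=float(b), alpha=alpha, alpha_star=alpha_star,
            C=C, epsilon=eps, slack=slack, slack_star=slack_star,
            dual_objective=dual, primal_objective=primal,
            n_iter=n_iter, kkt_violation=float(max(viol, 0.0)),
            _mu=mu, _sigma=sigma)


@dataclass
class EpsilonSVRResults:
    """Fitted eps-SVR: weights, bias, dual variables and diagnostics."""

    model: EpsilonSVR
    params: np.ndarray          # w, per-feature weights
    bias: float                 # b
    alpha: np.ndarray
    alpha_star: np.ndarray
    C: float
    epsilon: float
    slack: np.ndarray
    slack_star: np.ndarray
    dual_objective: float
    primal_objective: float
    n_iter: int
    kkt_violation: float
    _mu: np.ndarray | None = None
    _sigma: np.ndarray | None = None

    @property
    def beta(self) -> np.ndarray:
        return self.alpha - self.alpha_star

    @property
    def support_idx(self) -> np.ndarray:
        snap = 1e-8 * max(1.0, self.C)
        return np.flatnonzero(np.abs(self.beta) > snap)

    @property
    def duality_gap(self) -> float:
        return self.primal_objective - self.dual_objective

    def predict(self, X) -> np.ndarray:
        """Evaluate ``f(x) = w.x + b`` row-wise."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.params.shape[0]:
            raise ValueError(
                f"expected {self.params.shape[0]} features, got {X.shape[1]}")
        if self._mu is not None:
            X = (X - self._mu) / self._sigma
        return X @ self.params + self.bias

    def summary(self) -> str:
        n, d = self.model.exog.shape
        lines = [
            "Linear epsilon-SVR Results",
            "=" * 44,
            f"{'No. samples:':<24}{n:>20}",
            f"{'No. features:':<24}{d:>20}",
            f"{'C:':<24}{self.C:>20.6g}",
            f"{'epsilon:':<24}{self.epsilon:>20.6g}",
            f"{'Support vectors:':<24}{self.support_idx.size:>20}",
            f"{'Bias b:':<24}{self.bias:>20.6g}",
            f"{'||w||:':<24}{np.linalg.norm(self.params):>20.6g}",
            f"{'Dual objective:':<24}{self.dual_objective:>20.6g}",
            f"{'Primal objective:':<24}{self.primal_objective:>20.6g}",
            f"{'KKT violation:':<24}{self.kkt_violation:>20.3g}",
            f"{'Pair updates:':<24}{self.n_iter:>20}",
            "=" * 44,
        ]
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        """Serialize the fitted model.  Layout: ``{"w": [...], "b": float,
        "C": float, "epsilon": float, "support_idx": [...], "alpha": [...],
        "alpha_star": [...]}``."""
        payload = {
            "w": self.params.tolist(),
            "b": self.bias,
            "C": self.C,
            "epsilon": self.epsilon,
            "support_idx": self.support_idx.tolist(),
            "alpha": self.alpha.tolist(),
            "alpha_star": self.alpha_star.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def predictor_from_json(text_or_path):
        """Load a serialized model as a plain prediction function."""
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        payload = json.loads(text)
        w = np.asarray(payload["w"], dtype=float)
        b = float(payload["b"])

        def predict(X):
            X = np.atleast_2d(np.asarray(X, dtype=float))
            return X @ w + b

        return predict


def fit_svr(X, y, config: SvrConfig | None = None) -> EpsilonSVRResults:
    """Functional wrapper: fit a linear eps-SVR to ``(X, y)``."""
    return EpsilonSVR(y, X, config=config).fit()
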