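"""Weighted proportional-odds cumulative logistic regression.

The model for an ordinal outcome ``Y in 1..J`` with covariate row ``x_i``:

    logit P(Y_i <= j) = alpha_j - x_i' b,      j = 1..J-1,

with strictly increasing thresholds ``alpha_j`` and a single slope vector
``b`` shared across categories (proportional odds).  Estimation maximises
the weighted multinomial log-likelihood

    l(alpha, b) = sum_i w_i log P(Y_i = y_i | x_i)

by quasi-Newton (L-BFGS-B) with an analytic gradient.  Threshold
monotonicity is enforced by reparameterising alpha_1 freely and the
remaining thresholds through log-increments, so the optimisation is
smooth and unconstrained.

The observation weights are likelihood weights (sampling weights,
inverse-probability-of-treatment weights, or their product): point
estimates are invariant to rescaling all weights by a positive constant.
The reported covariance is the inverse observed information at the
optimum, which treats the weights as fixed; confidence intervals for
estimated (propensity-based) weights should come from
:func:`bootstrap_or_ci` instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

__all__ = [
    "CumulativeLogitModel",
    "CumulativeLogitResults",
    "EffectEstimate",
    "ConvergenceError",
    "recode_outcome",
    "bootstrap_or_ci",
]

_Z975 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)


class ConvergenceError(RuntimeError):
    """Raised when an operation requires a converged fit and has none."""


@dataclass
class EffectEstimate:
    """A treatment effect on the odds-ratio scale with a 95%-style CI."""

    term: str
    or_point: float
    ci_low: float
    ci_high: float
    ci_method: str  # "wald" or "bootstrap"
    n_failed: int = 0

    def __post_init__(self) -> None:
        if self.ci_method == "wald" and not (
            self.ci_low <= self.or_point <= self.ci_high
        ):
            raise ValueError("Wald CI must bracket the point estimate")


def _kish_ess(w: np.ndarray) -> float:
    return float(w.sum() ** 2 / (w**2).sum())


class CumulativeLogitModel:
    """Proportional-odds model for an ordinal outcome.

    Parameters
    ----------
    y : array-like
        Ordinal outcome labels; any sortable values with >= 2 observed
        levels.  Integer labels with unobserved intermediate levels are
        collapsed onto the observed ones with a warning.
    X : 2-d array or DataFrame, optional
        Covariate matrix (no intercept column; the thresholds play that
        role).  ``None`` fits the thresholds-only model.
    weights : array-like, optional
        Positive observation weights; default all ones.
    exog_names : sequence of str, optional
        Names for the columns of ``X`` when it is a bare array.
    """

    def __init__(self, y, X=None, weights=None, exog_names=None):
        y = np.asarray(y)
        if y.ndim != 1 or y.size == 0:
            raise ValueError("y must be a non-empty 1-d array")
        self.categories = np.unique(y)
        if self.categories.size < 2:
            raise ValueError("outcome must have at least 2 observed categories")
        if np.issubdtype(y.dtype, np.integer):
            full = np.arange(y.min(), y.max() + 1)
            if self.categories.size != full.size:
                warnings.warn(
                    "unobserved intermediate outcome categories collapsed "
                    "onto the observed levels",
                    UserWarning,
                    stacklevel=2,
                )
        self._y0 = np.searchsorted(self.categories, y)
        self.n_categories = int(self.categories.size)

        if X is None:
            self.exog = np.empty((y.size, 0))
            self.exog_names: list[str] = []
        elif isinstance(X, pd.DataFrame):
            self.exog = X.to_numpy(dtype=float)
            self.exog_names = [str(c) for c in X.columns]
        else:
            self.exog = np.asarray(X, dtype=float)
            if self.exog.ndim == 1:
                self.exog = self.exog[:, None]
            self.exog_names = (
                list(exog_names)
                if exog_names is not None
                else [f"x{k}" for k in range(self.exog.shape[1])]
            )
        if self.exog.shape[0] != y.size:
            raise ValueError("X and y length mismatch")
        if not np.isfinite(self.exog).all():
            raise ValueError("X contains non-finite values")

        if weights is None:
            self.weights = np.ones(y.size)
        else:
            self.weights = np.asarray(weights, dtype=float)
            if self.weights.shape != (y.size,):
                raise ValueError("weights length mismatch")
            if np.any(self.weights <= 0) or not np.isfinite(self.weights).all():
                raise ValueError("weights must be positive and finite")
        self.nobs = int(y.size)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str,
                       terms: Sequence[str] = (), weights=None):
        """Build the model from named columns of a DataFrame."""
        terms = list(terms)
        if isinstance(weights, str):
            weights = data[weights].to_numpy()
        X = data[terms] if terms else None
        return cls(data[outcome].to_numpy(), X, weights=weights)

    # -- likelihood machinery ------------------------------------------------

    def _unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        J = self.n_categories
        t, b = theta[: J - 1], theta[J - 1 :]
        alpha = np.empty(J - 1)
        alpha[0] = t[0]
        if J > 2:
            alpha[1:] = t[0] + np.cumsum(np.exp(t[1:]))
        return alpha, b

    def _nll_grad_direct(
        self, alpha: np.ndarray, b: np.ndarray
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """Weighted negative log-likelihood and its gradient in (alpha, b)."""
        y0, w = self._y0, self.weights
        J = self.n_categories
        eta = self.exog @ b if b.size else np.zeros(self.nobs)
        upper = y0 < J - 1
        lower = y0 > 0
        c_up = np.where(upper, expit(np.take(alpha, y0, mode="clip") - eta), 1.0)
        c_lo = np.where(
            lower, expit(np.take(alpha, np.maximum(y0 - 1, 0)) - eta), 0.0
        )
        p = np.clip(c_up - c_lo, 1e-300, None)
        nll = -float(np.dot(w, np.log(p)))

        g_up = np.where(upper, c_up * (1.0 - c_up), 0.0) / p
        g_lo = np.where(lower, c_lo * (1.0 - c_lo), 0.0) / p
        # d logL / d alpha_j
        d_alpha = np.bincount(y0, weights=w * g_up, minlength=J)[: J - 1]
        d_alpha -= np.bincount(
            np.maximum(y0 - 1, 0), weights=w * g_lo, minlength=J
        )[: J - 1]
        # d logL / d eta_i = -(g_up - g_lo)
        d_eta = w * (g_up - g_lo)
        d_b = self.exog.T @ d_eta if b.size else np.empty(0)
        return nll, -d_alpha, d_b

    def _objective(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        alpha, b = self._unpack(theta)
        nll, g_alpha, g_b = self._nll_grad_direct(alpha, b)
        J = self.n_categories
        g_t = np.empty(J - 1)
        g_t[0] = g_alpha.sum()
        if J > 2:
            # alpha_j depends on t_m (m>=1) via exp(t_m) for all j >= m
            rev_cum = np.cumsum(g_alpha[::-1])[::-1]
            g_t[1:] = np.exp(theta[1 : J - 1]) * rev_cum[1:]
        return nll, np.concatenate([g_t, g_b])

    def _start(self) -> np.ndarray:
        cum = np.cumsum(np.bincount(self._y0, weights=self.weights))
        cum = cum[:-1] / cum[-1]
        cum = np.clip(cum, 1e-6, 1 - 1e-6)
        alpha0 = logit(cum)
        J = self.n_categories
        t0 = np.empty(J - 1)
        t0[0] = alpha0[0]
        if J > 2:
            t0[1:] = np.log(np.maximum(np.diff(alpha0), 1e-6))
        return np.concatenate([t0, np.zeros(self.exog.shape[1])])

    def fit(self, maxiter: int = 500, gtol: float = 1e-7,
            track_history: bool = False,
            start_params: np.ndarray | None = None) -> "CumulativeLogitResults":
        """Maximise the weighted likelihood; returns a results object.

        ``start_params`` warm-starts the optimiser from a previous fit's
        ``params`` (thresholds followed by slopes, direct scale).
        """
        history: list[float] = []
        cb = None
        if track_history:
            def cb(theta):  # noqa: E731 - scipy callback signature
                history.append(-self._objective(theta)[0])
        n_params = self.n_categories - 1 + self.exog.shape[1]
        if start_params is not None and len(start_params) != n_params:
            start_params = None  # e.g. a resample lost an outcome category
        if start_params is not None:
            sp = np.asarray(start_params, dtype=float)
            J = self.n_categories
            t0 = np.empty(J - 1)
            t0[0] = sp[0]
            if J > 2:
                t0[1:] = np.log(np.maximum(np.diff(sp[: J - 1]), 1e-6))
            x0 = np.concatenate([t0, sp[J - 1 :]])
        else:
            x0 = self._start()
        res = optimize.minimize(
            self._objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
        )
        alpha, b = self._unpack(res.x)
        grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        converged = bool(res.success) and grad_norm < 1e-3 * (1 + abs(res.fun))
        return CumulativeLogitResults(
            model=self,
            thresholds=alpha,
            slope_values=b,
            llf=-float(res.fun),
            converged=converged,
            n_iter=int(res.nit),
            llf_history=history,
            message=str(res.message),
        )


class CumulativeLogitResults:
    """Fit results: thresholds, slopes, covariance, ORs, summary."""

    def __init__(self, model, thresholds, slope_values, llf, converged,
                 n_iter, llf_history, message=""):
        self.model = model
        self.thresholds = np.asarray(thresholds)
        self.slopes = pd.Series(np.asarray(slope_values), index=model.exog_names,
                                dtype=float)
        self.llf = llf
        self.converged = converged
        self.n_iter = n_iter
        self.llf_history = llf_history
        self.message = message
        self.n_effective = _kish_ess(model.weights)
        self._cov: pd.DataFrame | None = None

    @property
    def threshold_names(self) -> list[str]:
        c = self.model.categories
        return [f"alpha_{c[j]}" for j in range(self.model.n_categories - 1)]

    @property
    def param_names(self) -> list[str]:
        return self.threshold_names + list(self.model.exog_names)

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            np.concatenate([self.thresholds, self.slopes.to_numpy()]),
            index=self.param_names,
        )

    def cov_params(self) -> pd.DataFrame:
        """Inverse observed information in the (alpha, b) parameterisation.

        Hessian by central finite differences of the analytic gradient;
        the result is symmetrised.  Weights are treated as fixed.
        """
        if self._cov is None:
            theta = self.params.to_numpy()
            J = self.model.n_categories
            p = theta.size

            def grad(th):
                _, ga, gb = self.model._nll_grad_direct(th[: J - 1], th[J - 1 :])
                return np.concatenate([ga, gb])

            H = np.empty((p, p))
            for k in range(p):
                h = 1e-5 * (1.0 + abs(theta[k]))
                tp, tm = theta.copy(), theta.copy()
                tp[k] += h
                tm[k] -= h
                H[:, k] = (grad(tp) - grad(tm)) / (2 * h)
            H = (H + H.T) / 2
            cov = np.linalg.pinv(H)
            self._cov = pd.DataFrame(cov, index=self.param_names,
                                     columns=self.param_names)
        return self._cov

    @property
    def bse(self) -> pd.Series:
        var = np.clip(np.diag(self.cov_params().to_numpy()), 0, None)
        return pd.Series(np.sqrt(var), index=self.param_names)

    def wald_ci(self, term: str, level: float = 0.95) -> EffectEstimate:
        """Odds ratio exp(b) with a Wald CI on the log scale."""
        if not self.converged:
            raise ConvergenceError("Wald CI requires a converged fit")
        if term not in self.slopes.index:
            raise KeyError(f"unknown term {term!r}")
        from scipy.stats import norm

        b = float(self.slopes[term])
        se = float(self.bse[term])
        z = norm.ppf(0.5 + level / 2)
        return EffectEstimate(
            term=term,
            or_point=float(np.exp(b)),
            ci_low=float(np.exp(b - z * se)),
            ci_high=float(np.exp(b + z * se)),
            ci_method="wald",
        )

    def or_table(self, level: float = 0.95) -> pd.DataFrame:
        rows = [self.wald_ci(t, level) for t in self.slopes.index]
        return pd.DataFrame(
            {
                "term": [r.term for r in rows],
                "or": [r.or_point for r in rows],
                "ci_low": [r.ci_low for r in rows],
                "ci_high": [r.ci_high for r in rows],
                "ci_method": "wald",
            }
        )

    def summary(self) -> str:
        lines = [
            "Cumulative logit (proportional odds) regression",
            f"  n obs: {self.model.nobs}   effective n (Kish): "
            f"{self.n_effective:.1f}",
            f"  categories: {list(self.model.categories)}",
            f"  log-likelihood: {self.llf:.4f}   converged: {self.converged}"
            f"   iterations: {self.n_iter}",
            "",
        ]
        tab = pd.DataFrame({"coef": self.params, "std err": self.bse})
        if len(self.slopes):
            tab["OR"] = np.where(
                tab.index.isin(self.slopes.index), np.exp(tab["coef"]), np.nan
            )
        lines.append(tab.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


def recode_outcome(y7) -> np.ndarray:
    """Collapse a 7-point scale to 5 points: {1,2,3}->1, 4->2, ..., 7->5.

    The bottom three categories are merged (sparse low categories cause
    numerical instability in threshold estimation); the mapping is order
    preserving.
    """
    y7 = np.asarray(y7)
    if not np.issubdtype(y7.dtype, np.integer):
        raise ValueError("y7 must be integer-coded")
    if y7.size and (y7.min() < 1 or y7.max() > 7):
        raise ValueError("y7 values must lie in 1..7")
    return np.maximum(y7 - 2, 1)


def bootstrap_or_ci(
    data: pd.DataFrame,
    estimator: Callable[[pd.DataFrame, np.random.Generator], float],
    n_boot: int = 500,
    level: float = 0.95,
    seed: int | None = None,
    term: str = "treatment",
    max_failure_frac: float = 0.10,
) -> EffectEstimate:
    """Percentile bootstrap CI for an odds ratio from a full re-estimation
    recipe.

    ``estimator(df, rng)`` must re-run the entire pipeline (propensity fit,
    weight construction, outcome regression) on the resampled rows and
    return the treatment log-odds coefficient.  Rows are resampled
    uniformly with replacement; sampling weights travel with their rows.
    Replicates that raise are dropped and counted; more than
    ``max_failure_frac`` failures is an error.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    point = float(estimator(data, rng))
    n = len(data)
    betas = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            betas.append(float(estimator(sample, rng)))
        except Exception:
            n_failed += 1
    if n_failed > max_failure_frac * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap replicates failed"
        )
    ors = np.exp(betas)
    lo, hi = np.percentile(ors, [100 * (0.5 - level / 2),
                                 100 * (0.5 + level / 2)])
    return EffectEstimate(
        term=term,
        or_point=float(np.exp(point)),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_method="bootstrap",
        n_failed=n_failed,
    )
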