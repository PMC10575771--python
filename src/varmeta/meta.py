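"""Random-effects pooling, meta-regression, subgroup tests and FDR control.

Model
-----
Study effect sizes y_i with known sampling variances v_i follow the
normal-normal hierarchical model

    y_i = x_i' beta + u_i + e_i,   u_i ~ N(0, tau^2),  e_i ~ N(0, v_i),

with x_i = 1 for plain pooling or (1, m_i) for a single-moderator
meta-regression.  tau^2 is estimated by restricted maximum likelihood
(Fisher scoring with step halving, non-negativity by projection), the
DerSimonian-Laird moment estimator being available as a sensitivity option.
Given tau^2-hat, beta is the weighted least-squares estimate with weights
w_i = 1/(v_i + tau^2-hat) and plain Wald (normal) inference — no
Knapp-Hartung adjustment, so reported z and p mirror the usual
random-effects output of standard meta-analysis software.

Heterogeneity is summarised by I^2 = 100 tau^2 / (tau^2 + s^2) with the
typical within-study variance

    s^2 = (k - 1) sum(w0_i) / ( (sum w0_i)^2 - sum(w0_i^2) ),  w0_i = 1/v_i.

The restricted log-likelihood maximised for tau^2 (constants dropped) is

    l_R(tau^2) = -1/2 [ sum log(v_i + tau^2) + log det(X'WX) + r'Wr ],

with r the WLS residuals at the current weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Z975", "ConvergenceError", "RandomEffectsMeta", "RandomEffectsMetaResults",
    "PooledResult", "MetaRegressionResult", "WaldComparison",
    "reml_tau2", "dersimonian_laird_tau2", "i_squared", "pool_random_effects",
    "meta_regress", "compare_subgroups", "bh_fdr",
]

#: 97.5% normal quantile used for all 95% Wald intervals.
Z975 = 1.959964


class ConvergenceError(RuntimeError):
    """REML iteration failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list[tuple[int, float, float]]):
        super().__init__(message)
        self.trace = trace


def _restricted_ll(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    XtWX = X.T @ (X * w[:, None])
    beta = np.linalg.solve(XtWX, X.T @ (w * y))
    r = y - X @ beta
    sign, logdet = np.linalg.slogdet(XtWX)
    return -0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * r * r))


def dersimonian_laird_tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Moment estimator; used as the REML starting value and sensitivity option."""
    w = 1.0 / v
    XtWX = X.T @ (X * w[:, None])
    beta = np.linalg.solve(XtWX, X.T @ (w * y))
    r = y - X @ beta
    Q = float(np.sum(w * r * r))
    p = X.shape[1]
    # trace of the DL denominator: sum(w) - tr((X'WX)^-1 X'W^2X)
    XtW2X = X.T @ (X * (w ** 2)[:, None])
    c = float(np.sum(w) - np.trace(np.linalg.solve(XtWX, XtW2X)))
    if c <= 0:
        return 0.0
    return max(0.0, (Q - (len(y) - p)) / c)


def reml_tau2(y: Sequence[float], v: Sequence[float],
              X: np.ndarray | None = None, tol: float = 1e-10,
              maxiter: int = 200) -> float:
    """REML estimate of the between-study variance tau^2.

    Fisher scoring on tau^2 with step halving on the restricted
    log-likelihood; negative proposals are projected to zero.  Raises
    :class:`ConvergenceError` (with the iteration trace attached) if the
    update has not stabilised to ``tol`` within ``maxiter`` iterations.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if y.size < 2:
        raise ValueError("need at least two studies")
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    if X is None:
        X = np.ones((y.size, 1))
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    tau2 = dersimonian_laird_tau2(y, v, X)
    trace: list[tuple[int, float, float]] = []

    def score_info(t2: float) -> tuple[float, float]:
        w = 1.0 / (v + t2)
        XtWX = X.T @ (X * w[:, None])
        H = X @ np.linalg.solve(XtWX, X.T)        # hat-like matrix (k x k)
        P = np.diag(w) - (w[:, None] * H) * w[None, :]
        Py = P @ y
        U = -0.5 * np.trace(P) + 0.5 * float(Py @ Py)
        I = 0.5 * float(np.sum(P * P))
        return U, I

    # Safeguarded Newton (Fisher scoring) on the restricted score: keep a
    # sign-change bracket [lo, hi] and bisect it whenever the Newton step
    # leaves its central part, which defeats the slow zig-zag the plain
    # expected-information step can fall into.
    lo, hi = 0.0, np.inf
    for it in range(maxiter):
        U, I = score_info(tau2)
        trace.append((it, tau2, U))
        if I <= 0 or abs(U) < 1e-12:
            return tau2
        if U > 0:
            lo = max(lo, tau2)
        else:
            if tau2 == 0.0:                       # boundary maximum
                return 0.0
            hi = min(hi, tau2)
        prop = tau2 + U / I
        if np.isfinite(hi):
            width = hi - lo
            if not (lo + 0.2 * width < prop < hi - 0.2 * width):
                prop = 0.5 * (lo + hi)
        elif prop < 0.0:
            prop = 0.0
        if abs(prop - tau2) < tol * max(1.0, tau2):
            return prop
        tau2 = prop
    raise ConvergenceError(
        f"REML did not converge in {maxiter} iterations (last tau2={tau2:.3e})",
        trace)


def i_squared(tau2: float, v: Sequence[float]) -> float:
    """I^2 percent heterogeneity against the typical within-study variance."""
    v = np.asarray(v, float)
    w0 = 1.0 / v
    k = v.size
    s2 = (k - 1) * np.sum(w0) / (np.sum(w0) ** 2 - np.sum(w0 ** 2))
    return float(100.0 * tau2 / (tau2 + s2))


class RandomEffectsMeta:
    """Random-effects meta-analysis / meta-regression model.

    Parameters
    ----------
    endog : array of study effect sizes y_i
    variances : array of known sampling variances v_i
    exog : optional moderator matrix (without intercept; one is added)
    exog_names : names for the moderator columns
    """

    def __init__(self, endog, variances, exog=None, exog_names=None):
        self.endog = np.asarray(endog, float)
        self.variances = np.asarray(variances, float)
        if self.endog.size != self.variances.size:
            raise ValueError("endog and variances must have equal length")
        if self.endog.size < 2:
            raise ValueError("need at least two studies")
        if np.any(self.variances <= 0):
            raise ValueError("sampling variances must be positive")
        if exog is None:
            self.exog = np.ones((self.endog.size, 1))
            self.exog_names = ["intercept"]
        else:
            exog = np.atleast_2d(np.asarray(exog, float))
            if exog.shape[0] != self.endog.size:
                exog = exog.T
            for j in range(exog.shape[1]):
                if np.ptp(exog[:, j]) == 0:
                    raise ValueError("constant moderator")
            self.exog = np.column_stack([np.ones(self.endog.size), exog])
            names = list(exog_names or [f"x{j + 1}" for j in range(exog.shape[1])])
            self.exog_names = ["intercept"] + names
        self.k = self.endog.size

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, effect_col: str = "estimate",
                       var_col: str = "variance",
                       moderators: Sequence[str] | None = None) -> "RandomEffectsMeta":
        exog = df[list(moderators)].to_numpy() if moderators else None
        return cls(df[effect_col].to_numpy(), df[var_col].to_numpy(),
                   exog=exog, exog_names=list(moderators) if moderators else None)

    def fit(self, method: str = "reml", tol: float = 1e-10,
            maxiter: int = 200) -> "RandomEffectsMetaResults":
        y, v, X = self.endog, self.variances, self.exog
        if method == "reml":
            tau2 = reml_tau2(y, v, X, tol=tol, maxiter=maxiter)
        elif method == "dl":
            tau2 = dersimonian_laird_tau2(y, v, X)
        else:
            raise ValueError(f"unknown method {method!r}")
        w = 1.0 / (v + tau2)
        XtWX = X.T @ (X * w[:, None])
        cov = np.linalg.inv(XtWX)
        params = cov @ (X.T @ (w * y))
        bse = np.sqrt(np.diag(cov))
        return RandomEffectsMetaResults(self, params, bse, tau2, method)


@dataclass
class RandomEffectsMetaResults:
    """Estimates, uncertainties and heterogeneity diagnostics of a fit."""
    model: RandomEffectsMeta
    params: np.ndarray
    bse: np.ndarray
    tau2: float
    method: str

    def __post_init__(self):
        self.zvalues = self.params / self.bse
        self.pvalues = 2.0 * stats.norm.sf(np.abs(self.zvalues))
        self.k = self.model.k
        if self.model.exog.shape[1] == 1:
            self.i2 = i_squared(self.tau2, self.model.variances)
        else:
            self.i2 = None

    def conf_int(self, alpha: float = 0.05):
        if alpha != 0.05:
            z = stats.norm.ppf(1 - alpha / 2)
        else:
            z = Z975
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return np.column_stack([lo, hi])

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Random-effects meta-analysis"
            + ("" if self.model.exog.shape[1] == 1 else " (meta-regression)"),
            f"k = {self.k} studies, tau2 ({self.method.upper()}) = {self.tau2:.6f}"
            + (f", I2 = {self.i2:.1f}%" if self.i2 is not None else ""),
            f"{'term':<12} {'estimate':>10} {'se':>9} {'z':>8} {'p':>9} "
            f"{'[95% CI]':>21}",
        ]
        for j, name in enumerate(self.model.exog_names):
            lines.append(
                f"{name:<12} {self.params[j]:>10.4f} {self.bse[j]:>9.4f} "
                f"{self.zvalues[j]:>8.3f} {self.pvalues[j]:>9.4g} "
                f"[{ci[j, 0]:>8.4f}, {ci[j, 1]:>8.4f}]")
        return "\n".join(lines)


@dataclass
class PooledResult:
    measure: str
    region: str
    metabolite: str
    subset: str
    k: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    z_stat: float
    p_value: float
    tau2: float
    i2: float
    study_ids: tuple = field(default_factory=tuple)


@dataclass
class MetaRegressionResult:
    moderator: str
    k: int
    slope: float
    se: float
    z_stat: float
    p_value: float
    tau2_residual: float
    measure: str = ""
    region: str = ""
    metabolite: str = ""
    study_ids: tuple = field(default_factory=tuple)


@dataclass
class WaldComparison:
    estimate_a: float
    se_a: float
    estimate_b: float
    se_b: float
    z_stat: float = 0.0
    p_value: float = 1.0
    label: str = ""

    def __post_init__(self):
        se = math.sqrt(self.se_a ** 2 + self.se_b ** 2)
        self.z_stat = (self.estimate_a - self.estimate_b) / se
        self.p_value = float(2.0 * stats.norm.sf(abs(self.z_stat)))


def _as_arrays(effects) -> tuple[np.ndarray, np.ndarray, tuple]:
    if isinstance(effects, pd.DataFrame):
        ids = tuple(effects.get("cohort_id", effects.get("study_id",
                    pd.Series(range(len(effects))))).astype(str))
        return effects["estimate"].to_numpy(), effects["variance"].to_numpy(), ids
    y = np.array([e.estimate for e in effects], float)
    v = np.array([e.variance for e in effects], float)
    ids = tuple(e.cohort_id or e.study_id for e in effects)
    return y, v, ids


def pool_random_effects(effects, method: str = "reml", measure: str = "",
                        region: str = "", metabolite: str = "",
                        subset: str = "all") -> PooledResult:
    """Pool a homogeneous set of effect sizes under the random-effects model."""
    y, v, ids = _as_arrays(effects)
    if y.size < 2:
        raise ValueError("need at least two studies to pool")
    res = RandomEffectsMeta(y, v).fit(method=method)
    est, se = float(res.params[0]), float(res.bse[0])
    ci = res.conf_int()[0]
    return PooledResult(
        measure=measure, region=region, metabolite=metabolite, subset=subset,
        k=int(y.size), estimate=est, se=se, ci_low=float(ci[0]),
        ci_high=float(ci[1]), z_stat=float(res.zvalues[0]),
        p_value=float(res.pvalues[0]), tau2=float(res.tau2),
        i2=float(res.i2), study_ids=ids)


def meta_regress(effects, moderator: Sequence[float], name: str = "moderator",
                 method: str = "reml", min_k: int = 5) -> MetaRegressionResult:
    """Single-moderator mixed-effects meta-regression (slope with Wald inference)."""
    y, v, ids = _as_arrays(effects)
    m = np.asarray(moderator, float)
    if m.size != y.size:
        raise ValueError("moderator length mismatch")
    if y.size < min_k:
        raise ValueError(f"k={y.size} below minimum {min_k} for meta-regression")
    if np.ptp(m) == 0:
        raise ValueError("constant moderator")
    res = RandomEffectsMeta(y, v, exog=m, exog_names=[name]).fit(method=method)
    return MetaRegressionResult(
        moderator=name, k=int(y.size), slope=float(res.params[1]),
        se=float(res.bse[1]), z_stat=float(res.zvalues[1]),
        p_value=float(res.pvalues[1]), tau2_residual=float(res.tau2),
        study_ids=ids)


def compare_subgroups(a: PooledResult, b: PooledResult,
                      label: str = "") -> WaldComparison:
    """Wald z test of two pooled estimates from disjoint study subsets."""
    if a.study_ids and b.study_ids:
        overlap = set(a.study_ids) & set(b.study_ids)
        if overlap:
            raise ValueError(f"subgroups overlap: {sorted(overlap)}")
    return WaldComparison(a.estimate, a.se, b.estimate, b.se, label=label)


def bh_fdr(p_values: Sequence[float], q: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at rate ``q``.

    Ties and input order are preserved; an empty input yields an empty
    output.  Delegates to :func:`statsmodels.stats.multitest.multipletests`.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
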