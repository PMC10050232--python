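"""Survival estimators: Kaplan-Meier, logrank, Cox proportional hazards and
jackknife pseudo-observation regression.

Everything here is written against plain numpy arrays so that the Monte-Carlo
engine can run tens of thousands of fits cheaply.  The regression estimators
are exposed both as scikit-learn style classes (:class:`CoxPH`,
:class:`PseudoValueRegression`) and as thin module functions
(:func:`cox_fit`, :func:`glm_identity`).

Conventions
-----------
* KM convention for ties: a censoring recorded at an event time is ordered
  *after* the event, i.e. censored subjects at time ``u`` are counted in the
  risk set at ``u``.
* Cox ties use the Efron correction.
* Pseudo-observations are exact jackknife values
  ``theta_i = n * theta_hat - (n - 1) * theta_hat_minus_i`` of the pooled
  Kaplan-Meier functional, computed in O(n log n) with closed-form
  leave-one-out updates (with a brute-force fallback for degenerate corner
  cases).
* Robust (sandwich) variance for the identity-link pseudo-value regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator


class FitError(RuntimeError):
    """An estimator could not produce a finite fit (separation, no events,
    non-convergence).  The simulation engine records such replicates as
    non-estimable instead of crashing."""


@dataclass
class FitResult:
    """One contrast estimate with its test.

    ``estimate`` is on the natural scale of the estimand: a hazard ratio
    (ratio scale) for HR, a probability difference for SD, months for RMST,
    and NaN for the logrank test, which has no magnitude.  ``se`` is on the
    scale inference is done on (log scale for HR).
    """

    estimand: str  # "HR" | "SD" | "RMST" | "LR"
    estimate: float
    se: float
    statistic: float
    p_value: float
    contrast: Optional[str] = None
    coefficients: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "estimand": self.estimand,
            "contrast": self.contrast,
            "estimate": self.estimate,
            "se": self.se,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }
        row.update(self.extra)
        return row


def _check_surv(times, events):
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).ravel().astype(int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times <= 0):
        raise ValueError("observed times must be strictly positive")
    if not np.all((events == 0) | (events == 1)):
        raise ValueError("events must be 0/1")
    return times, events


def _risk_table(times, events):
    """Group sorted survival data by unique observed time.

    Returns (order, u, n_at_risk, d, first_index) where ``u`` are the unique
    times ascending, ``n_at_risk[k] = #{y_i >= u_k}`` and ``d[k]`` the number
    of events at ``u_k``.
    """
    order = np.argsort(times, kind="stable")
    ys = times[order]
    es = events[order]
    u, first, counts = np.unique(ys, return_index=True, return_counts=True)
    n_at_risk = times.shape[0] - first
    d = np.add.reduceat(es, first)
    return order, ys, es, u, first, counts, n_at_risk, d


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Product-limit (Kaplan-Meier) estimate as a right-continuous step
    function, dropping only at event times."""

    event_times: np.ndarray  # unique event times, ascending
    survival: np.ndarray  # S(u_k+) after each event time
    at_risk: np.ndarray  # risk-set size at each event time
    n_events: np.ndarray  # deaths at each event time
    n: int  # sample size
    max_time: float  # largest observed (event or censoring) time

    def survival_at(self, t):
        """Right-continuous step evaluation S(t); carries the last value (with
        a warning) beyond the observed support."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0):
            raise ValueError("t must be >= 0")
        if np.any(t_arr > self.max_time):
            warnings.warn(
                "evaluating the survival curve beyond the last observed time; "
                "carrying the last value",
                stacklevel=2,
            )
        idx = np.searchsorted(self.event_times, t_arr, side="right")
        s = np.concatenate([[1.0], self.survival])[idx]
        return float(s[0]) if np.isscalar(t) or np.ndim(t) == 0 else s

    def rmst(self, t):
        """Exact area under the step function on [0, t] (months)."""
        t = float(t)
        if not t > 0:
            raise ValueError("t must be > 0")
        if t > self.max_time:
            warnings.warn(
                "restricted mean beyond the last observed time; the curve's "
                "last value is carried",
                stacklevel=2,
            )
        bounds = np.concatenate([[0.0], np.minimum(self.event_times, t), [t]])
        heights = np.concatenate([[1.0], self.survival])
        widths = np.maximum(np.diff(bounds), 0.0)
        return float(np.sum(heights * widths))


def km_fit(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    All-censored input yields a flat curve at 1 with a warning.
    """
    times, events = _check_surv(times, events)
    if times.size == 0:
        raise ValueError("empty sample")
    _, _, _, u, _, _, n_at_risk, d = _risk_table(times, events)
    has_event = d > 0
    if not np.any(has_event):
        warnings.warn("all observations censored; survival curve is flat at 1", stacklevel=2)
    factors = 1.0 - d[has_event] / n_at_risk[has_event]
    surv = np.cumprod(factors)
    return SurvivalCurve(
        event_times=u[has_event],
        survival=surv,
        at_risk=n_at_risk[has_event],
        n_events=d[has_event],
        n=times.shape[0],
        max_time=float(u[-1]),
    )


def survival_at(curve: SurvivalCurve, t):
    """Evaluate a fitted curve at time ``t`` (right-continuous)."""
    return curve.survival_at(t)


def rmst(curve: SurvivalCurve, t):
    """Restricted mean survival time: integral of the curve on [0, t]."""
    return curve.rmst(t)


# ---------------------------------------------------------------------------
# Logrank
# ---------------------------------------------------------------------------


def logrank(times, events, group) -> FitResult:
    """Two-sample logrank test.

    ``group`` holds exactly two levels; the statistic is the usual
    (O - E)^2 / V chi-square on 1 df built from the hypergeometric mean and
    variance at each distinct event time.
    """
    times, events = _check_surv(times, events)
    group = np.asarray(group).ravel()
    levels = np.unique(group)
    if levels.shape[0] != 2:
        raise ValueError(f"logrank requires exactly two groups, got {levels.shape[0]}")
    if events.sum() == 0:
        raise ValueError("logrank requires at least one event")
    g1 = group == levels[1]

    event_times = np.unique(times[events == 1])
    sorted_all = np.sort(times)
    sorted_g1 = np.sort(times[g1])
    n_tot = times.shape[0] - np.searchsorted(sorted_all, event_times, side="left")
    n_1 = sorted_g1.shape[0] - np.searchsorted(sorted_g1, event_times, side="left")

    # deaths per event time, overall and in group 1
    idx = np.searchsorted(event_times, times)
    d_tot = np.bincount(idx[events == 1], minlength=event_times.shape[0])
    d_1 = np.bincount(idx[(events == 1) & g1], minlength=event_times.shape[0])

    frac1 = n_1 / n_tot
    o_minus_e = float(np.sum(d_1 - d_tot * frac1))
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = d_tot * frac1 * (1.0 - frac1) * (n_tot - d_tot) / np.maximum(n_tot - 1, 1)
    v_terms[n_tot <= 1] = 0.0
    v = float(np.sum(v_terms))
    if v <= 0:
        raise FitError("degenerate logrank variance (no between-group information)")
    statistic = o_minus_e**2 / v
    p = float(stats.chi2.sf(statistic, df=1))
    return FitResult(
        estimand="LR",
        estimate=float("nan"),
        se=float("nan"),
        statistic=float(statistic),
        p_value=p,
        coefficients={"o_minus_e": o_minus_e, "variance": v},
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------


def _cox_quantities(beta, Xs, es, first, d):
    """Efron partial log-likelihood, gradient and information at ``beta``
    for data sorted ascending in time."""
    n, p = Xs.shape
    eta = Xs @ beta
    eta -= eta.max()  # guard overflow; constant shifts cancel in ratios
    w = np.exp(eta)
    xw = Xs * w[:, None]
    xxw = Xs[:, :, None] * Xs[:, None, :] * w[:, None, None]

    # suffix (at-risk) sums evaluated at each unique-time group start
    sw = np.cumsum(w[::-1])[::-1]
    sxw = np.cumsum(xw[::-1], axis=0)[::-1]
    sxxw = np.cumsum(xxw[::-1], axis=0)[::-1]

    ev_groups = np.flatnonzero(d > 0)
    we = w * es
    xwe = Xs * we[:, None]
    xxwe = Xs[:, :, None] * Xs[:, None, :] * we[:, None, None]
    swd = np.add.reduceat(we, first)[ev_groups]
    sxwd = np.add.reduceat(xwe, first, axis=0)[ev_groups]
    sxxwd = np.add.reduceat(xxwe, first, axis=0)[ev_groups]
    dk = d[ev_groups]

    # expand Efron terms: one row per (event group, j), j = 0..d_k-1
    rep = np.repeat(np.arange(ev_groups.shape[0]), dk)
    j = np.concatenate([np.arange(k) for k in dk]) if dk.size else np.empty(0, dtype=int)
    frac = j / np.repeat(dk, dk)
    R = sw[first[ev_groups]][rep] - frac * swd[rep]
    V = sxw[first[ev_groups]][rep] - frac[:, None] * sxwd[rep]
    M = sxxw[first[ev_groups]][rep] - frac[:, None, None] * sxxwd[rep]

    if np.any(R <= 0):
        raise FitError("non-positive Efron risk sums; degenerate data")
    loglik = float(np.sum(eta[es == 1]) - np.sum(np.log(R)))
    VR = V / R[:, None]
    grad = Xs[es == 1].sum(axis=0) - VR.sum(axis=0)
    info = (M / R[:, None, None]).sum(axis=0) - np.einsum("dp,dq->pq", VR, VR)
    return loglik, grad, info


def _cox_newton(times, events, X, max_iter=50, tol=1e-10):
    times, events = _check_surv(times, events)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.shape[0]:
        X = X.T
    n, p = X.shape
    if events.sum() == 0:
        raise FitError("no events; Cox model is not estimable")
    order = np.argsort(times, kind="stable")
    ys, es, Xs = times[order], events[order], X[order]
    u, first, counts = np.unique(ys, return_index=True, return_counts=True)
    d = np.add.reduceat(es, first)

    beta = np.zeros(p)
    loglik, grad, info = _cox_quantities(beta, Xs, es, first, d)
    trace = [loglik]
    for it in range(max_iter):
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix: {exc}") from exc
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            if np.max(np.abs(cand)) > 50.0:
                raise FitError(
                    "coefficients diverging (|beta| > 50); likely complete "
                    "separation (a group with no events)"
                )
            new_ll, new_grad, new_info = _cox_quantities(cand, Xs, es, first, d)
            if new_ll >= loglik - 1e-12:
                break
            step /= 2.0
        else:
            raise FitError(f"step-halving failed; trace={trace}")
        converged = np.max(np.abs(step * delta)) < tol
        beta, loglik, grad, info = cand, new_ll, new_grad, new_info
        trace.append(loglik)
        if converged:
            break
    else:
        raise FitError(f"Newton iteration did not converge; log-likelihood trace={trace}")
    if np.max(np.abs(beta)) > 20.0:
        # |log HR| > 20 is far outside any plausible effect; the partial
        # likelihood is drifting to an infinite maximizer (complete separation)
        raise FitError(
            f"coefficient diverged to {beta} (complete separation: a compared "
            "group has no events)"
        )
    cov = np.linalg.inv(info)
    return beta, cov, loglik, len(trace) - 1


def cox_score_test(times, events, X):
    """Score test of beta = 0 in a Cox model.

    For a two-group comparison without ties this equals the logrank
    chi-square statistic exactly.
    """
    times, events = _check_surv(times, events)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.shape[0]:
        X = X.T
    order = np.argsort(times, kind="stable")
    ys, es, Xs = times[order], events[order], X[order]
    u, first, counts = np.unique(ys, return_index=True, return_counts=True)
    d = np.add.reduceat(es, first)
    _, grad, info = _cox_quantities(np.zeros(X.shape[1]), Xs, es, first, d)
    statistic = float(grad @ np.linalg.solve(info, grad))
    p = float(stats.chi2.sf(statistic, df=X.shape[1]))
    return statistic, p


class CoxPH(BaseEstimator):
    """Cox proportional-hazards regression (partial likelihood, Efron ties).

    scikit-learn style estimator: ``fit(X, y)`` where ``y`` is a structured
    array with fields ``event`` and ``time`` (scikit-survival convention) or
    a ``(times, events)`` tuple.

    Attributes (after fit)
    ----------------------
    coef_ : (p,) log hazard ratios
    cov_ : (p, p) inverse observed information
    se_ : (p,) Wald standard errors on the log scale
    hazard_ratios_ : exp(coef_)
    p_values_ : two-sided Wald p-values
    n_iter_ : Newton iterations used
    """

    def __init__(self, ties="efron", max_iter=50, tol=1e-10):
        self.ties = ties
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        if self.ties != "efron":
            raise ValueError("only the Efron tie correction is implemented")
        times, events = _unpack_y(y)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != times.shape[0]:
            X = X.T
        beta, cov, loglik, n_iter = _cox_newton(
            times, events, X, max_iter=self.max_iter, tol=self.tol
        )
        self.coef_ = beta
        self.cov_ = cov
        self.se_ = np.sqrt(np.diag(cov))
        self.hazard_ratios_ = np.exp(beta)
        z = beta / self.se_
        self.p_values_ = 2.0 * stats.norm.sf(np.abs(z))
        self.loglik_ = loglik
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Linear risk score X @ coef_ (log relative hazard)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef_


def _unpack_y(y):
    if isinstance(y, tuple):
        return _check_surv(*y)
    y = np.asarray(y)
    if y.dtype.names:
        names = y.dtype.names
        tname = "time" if "time" in names else names[1]
        ename = "event" if "event" in names else names[0]
        return _check_surv(y[tname], y[ename].astype(int))
    if y.ndim == 2 and y.shape[1] == 2:
        return _check_surv(y[:, 0], y[:, 1])
    raise ValueError("y must be (times, events), a structured array, or an (n, 2) array")


def survival_y(times, events):
    """Pack times/events into the structured-array convention of ``fit``."""
    times, events = _check_surv(times, events)
    y = np.empty(times.shape[0], dtype=[("event", bool), ("time", float)])
    y["event"] = events.astype(bool)
    y["time"] = times
    return y


_COX_MODEL_TARGET = {5: 0, 6: 2, 7: 0}
_COX_MODEL_NCOL = {5: 1, 6: 3, 7: 1}


def cox_fit(times, events, covariate_matrix, model) -> FitResult:
    """Fit one of the three canonical Cox models and report its target
    hazard ratio.

    ``model`` selects the column layout and the coefficient of interest:

    * 5 — single treatment indicator I(X = B); HR = exp(beta_0)
      (treatment effect within one subgroup when fit on that subgroup).
    * 6 — I(X = B), M, I(X = B) * M; the interaction HR exp(beta_2) is the
      differential treatment effect.
    * 7 — single arm indicator I(arm = biomarker-directed); HR = exp(beta_0)
      is the clinical utility on the hazard scale.

    The reported ``se`` is on the log-hazard scale and the test is a
    two-sided Wald test of the target coefficient.
    """
    if model not in _COX_MODEL_TARGET:
        raise ValueError(f"model must be one of {sorted(_COX_MODEL_TARGET)}")
    X = np.atleast_2d(np.asarray(covariate_matrix, dtype=float))
    if X.shape[0] != np.asarray(times).shape[0]:
        X = X.T
    if X.shape[1] != _COX_MODEL_NCOL[model]:
        raise ValueError(f"model {model} expects {_COX_MODEL_NCOL[model]} covariate column(s)")
    est = CoxPH().fit(X, (times, events))
    k = _COX_MODEL_TARGET[model]
    return FitResult(
        estimand="HR",
        estimate=float(est.hazard_ratios_[k]),
        se=float(est.se_[k]),
        statistic=float(est.coef_[k] / est.se_[k]),
        p_value=float(est.p_values_[k]),
        coefficients={f"beta_{i}": float(b) for i, b in enumerate(est.coef_)},
        extra={"hr_reciprocal": float(np.exp(-est.coef_[k])), "n_iter": est.n_iter_},
    )


# ---------------------------------------------------------------------------
# Pseudo-observations
# ---------------------------------------------------------------------------


@dataclass
class PseudoObservationSet:
    """Per-subject jackknife pseudo-values of a KM functional.

    ``values[i] = n * theta_hat - (n - 1) * theta_hat_minus_i`` where
    ``theta_hat`` is the pooled Kaplan-Meier estimate of the functional
    (survival probability past ``horizon``, or restricted mean up to it).
    """

    functional: str  # "survival" | "rmst"
    horizon: float
    values: np.ndarray
    theta_hat: float

    @property
    def n(self):
        return self.values.shape[0]


def _km_functional(times, events, t, functional):
    """Direct KM functional on a raw sample (used for leave-one-out
    fallbacks and in the full-sample estimate)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = km_fit(times, events)
        if functional == "survival":
            return curve.survival_at(t)
        return curve.rmst(t)


def _pseudo_arrays(times, events, t):
    """Shared prefix-log arrays for the closed-form leave-one-out KM.

    Groups observations by unique time; ``f_k`` is the full-sample KM factor
    at group k, ``h_k`` the factor when the risk set is reduced by one
    (a left-out subject with a time >= u_k).
    """
    n = times.shape[0]
    order, ys, es, u, first, counts, n_risk, d = _risk_table(times, events)
    with np.errstate(divide="ignore"):
        f = 1.0 - d / n_risk
        h = np.where(d == 0, 1.0, 1.0 - d / np.maximum(n_risk - 1, 1))
        h = np.maximum(h, 0.0)  # d == n_risk can only occur at the last group; unused there
        logF = np.concatenate([[0.0], np.cumsum(np.log(f))])
        logH = np.concatenate([[0.0], np.cumsum(np.log(h))])
    # 1-based group index of each (sorted) subject
    g = np.searchsorted(u, ys, side="left") + 1
    return order, ys, es, u, n_risk, d, f, h, logF, logH, g


def pseudo_observations(times, events, functional, t) -> PseudoObservationSet:
    """Exact jackknife pseudo-observations of the pooled KM functional.

    ``functional`` is ``"survival"`` (f(T) = I(T > t)) or ``"rmst"``
    (f(T) = min(T, t)).  With no censoring the pseudo-values reduce exactly
    to those transforms of the raw observations.
    """
    functional = {"survival": "survival", "survival_at_t": "survival", "rmst": "rmst", "rmst_at_t": "rmst"}.get(functional)
    if functional is None:
        raise ValueError("functional must be 'survival' or 'rmst'")
    times, events = _check_surv(times, events)
    n = times.shape[0]
    if n < 2:
        raise ValueError("pseudo-observations require at least 2 subjects")
    t = float(t)
    if not t > 0:
        raise ValueError("t must be > 0")
    if t > times.max():
        warnings.warn(
            "horizon beyond the last observed time; the KM curve's last value is carried",
            stacklevel=2,
        )

    order, ys, es, u, n_risk, d, f, h, logF, logH, g = _pseudo_arrays(times, events, t)
    K = u.shape[0]
    G = int(np.searchsorted(u, t, side="right"))  # groups with u_k <= t

    with np.errstate(invalid="ignore", over="ignore"):
        if functional == "survival":
            theta = float(np.exp(logF[G]))
            loo = np.empty(n)
            m = np.minimum(g, G)
            cens = es == 0
            loo[cens] = np.exp(logH[m[cens]] + logF[G] - logF[m[cens]])
            ev = ~cens
            ge, de, ne = g[ev], d[g[ev] - 1], n_risk[g[ev] - 1]
            hp = np.where(de - 1 == 0, 1.0, 1.0 - (de - 1) / np.maximum(ne - 1, 1))
            inside = ge <= G
            val = np.where(
                inside,
                np.where(hp == 0.0, 0.0, hp * np.exp(logH[ge - 1] + logF[G] - logF[np.minimum(ge, G + 0)])),
                np.exp(logH[np.minimum(ge, G)]),
            )
            # note logF[ge] only valid when inside; clip index to avoid OOB
            loo[ev] = val
        else:
            # segment k = 0..G covers [b_k, b_{k+1}) with b_0 = 0, b_k = u_k, b_{G+1} = t
            bounds = np.concatenate([[0.0], u[:G], [t]])
            seg_len = np.maximum(np.diff(bounds), 0.0)  # length G + 1
            expH = np.exp(logH[: G + 1])
            expF = np.exp(logF[: G + 1])
            PH = np.concatenate([[0.0], np.cumsum(expH * seg_len)])  # PH[k+1] = sum over segments 0..k
            QF = np.concatenate([[0.0], np.cumsum(expF * seg_len)])
            theta = float(QF[G + 1])

            loo = np.empty(n)
            m = np.minimum(g, G)
            cens = es == 0
            mc = m[cens]
            tail = np.where(
                g[cens] < G,
                np.exp(logH[mc] - logF[mc]) * (QF[G + 1] - QF[mc + 1]),
                0.0,
            )
            loo[cens] = PH[mc + 1] + tail
            ev = ~cens
            ge, de, ne = g[ev], d[g[ev] - 1], n_risk[g[ev] - 1]
            hp = np.where(de - 1 == 0, 1.0, 1.0 - (de - 1) / np.maximum(ne - 1, 1))
            inside = ge <= G
            gi = np.minimum(ge, G)  # clip for safe indexing; only used when inside
            coef = np.where(hp == 0.0, 0.0, hp * np.exp(logH[ge - 1] - logF[gi]))
            # pre-part for inside events covers segments 0..g-1 = PH[g]
            # (gi == ge whenever the inside branch is selected)
            loo[ev] = np.where(inside, PH[gi] + coef * (QF[G + 1] - QF[gi]), PH[gi + 1])

    values_sorted = n * theta - (n - 1) * loo

    # brute-force fallback for any degenerate closed-form entries
    bad = ~np.isfinite(values_sorted)
    if np.any(bad):
        idx_all = np.arange(n)
        for j in np.flatnonzero(bad):
            mask = idx_all != j
            loo_j = _km_functional(ys[mask], es[mask], t, functional)
            values_sorted[j] = n * theta - (n - 1) * loo_j

    values = np.empty(n)
    values[order] = values_sorted
    return PseudoObservationSet(functional=functional, horizon=t, values=values, theta_hat=theta)


# ---------------------------------------------------------------------------
# Identity-link pseudo-value regression (GEE with sandwich variance)
# ---------------------------------------------------------------------------


def _ols_sandwich(Z, y):
    n, p = Z.shape
    if np.linalg.matrix_rank(Z) < p:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(Z, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = sorted(piv[diag < diag.max() * 1e-10].tolist())
        raise FitError(f"design matrix is rank deficient; collinear column(s): {bad}")
    ztz_inv = np.linalg.inv(Z.T @ Z)
    beta = ztz_inv @ (Z.T @ y)
    resid = y - Z @ beta
    meat = (Z * resid[:, None] ** 2).T @ Z
    cov = ztz_inv @ meat @ ztz_inv
    return beta, cov


class PseudoValueRegression(BaseEstimator):
    """Identity-link regression of KM pseudo-observations on covariates.

    Computes pooled jackknife pseudo-values of the chosen functional at the
    horizon, then solves the identity-link estimating equations (ordinary
    least squares) with a robust sandwich variance — the standard
    Andersen/Klein generalized-estimating-equation treatment of
    pseudo-values, which are not independent given the pooled estimate.

    Parameters
    ----------
    functional : "survival" or "rmst"
        f(T) = I(T > t) gives survival-probability contrasts (SD);
        f(T) = min(T, t) gives restricted-mean contrasts (RMST).
    horizon : float
        Evaluation time t in months.
    add_intercept : bool
        Prepend an intercept column to X (default True).

    Attributes (after fit)
    ----------------------
    coef_, cov_, se_, p_values_ : regression estimates with sandwich SEs
    pseudo_values_ : the per-subject pseudo-observations
    theta_hat_ : pooled full-sample functional estimate
    """

    def __init__(self, functional="survival", horizon=36.0, add_intercept=True):
        self.functional = functional
        self.horizon = horizon
        self.add_intercept = add_intercept

    def fit(self, X, y, groups=None):
        """Fit on covariates ``X`` and survival outcome ``y``.

        ``groups``, if given, computes pseudo-values within each group
        separately instead of from the pooled sample (non-default option).
        """
        times, events = _unpack_y(y)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != times.shape[0]:
            X = X.T
        if groups is None:
            pseudo = pseudo_observations(times, events, self.functional, self.horizon)
            values = pseudo.values
            self.theta_hat_ = pseudo.theta_hat
        else:
            groups = np.asarray(groups)
            values = np.empty(times.shape[0])
            for lev in np.unique(groups):
                mask = groups == lev
                values[mask] = pseudo_observations(
                    times[mask], events[mask], self.functional, self.horizon
                ).values
            self.theta_hat_ = float(np.mean(values))
        Z = np.column_stack([np.ones(X.shape[0]), X]) if self.add_intercept else X
        beta, cov = _ols_sandwich(Z, values)
        self.coef_ = beta
        self.cov_ = cov
        self.se_ = np.sqrt(np.diag(cov))
        z = beta / self.se_
        self.p_values_ = 2.0 * stats.norm.sf(np.abs(z))
        self.pseudo_values_ = values
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = np.column_stack([np.ones(X.shape[0]), X]) if self.add_intercept else X
        return Z @ self.coef_


_GLM_MODEL_TARGET = {8: 1, 9: 3, 10: 1}
_GLM_MODEL_NCOL = {8: 2, 9: 4, 10: 2}


def glm_identity(pseudo: PseudoObservationSet, covariate_matrix, model) -> FitResult:
    """Identity-link regression of precomputed pseudo-values.

    ``covariate_matrix`` must include the intercept column.  ``model``
    selects the layout and target coefficient:

    * 8 — [1, I(X = B)]; beta_1 is the subgroup treatment effect.
    * 9 — [1, I(X = B), M, I(X = B) * M]; beta_3 is the differential effect.
    * 10 — [1, I(arm = directed)]; beta_1 is the clinical utility.

    Inference is a two-sided Wald test with the robust sandwich variance.
    """
    if model not in _GLM_MODEL_TARGET:
        raise ValueError(f"model must be one of {sorted(_GLM_MODEL_TARGET)}")
    Z = np.atleast_2d(np.asarray(covariate_matrix, dtype=float))
    if Z.shape[0] != pseudo.n:
        Z = Z.T
    if Z.shape[1] != _GLM_MODEL_NCOL[model]:
        raise ValueError(f"model {model} expects {_GLM_MODEL_NCOL[model]} design column(s)")
    beta, cov = _ols_sandwich(Z, pseudo.values)
    k = _GLM_MODEL_TARGET[model]
    se = float(np.sqrt(cov[k, k]))
    z = float(beta[k] / se)
    estimand = "SD" if pseudo.functional == "survival" else "RMST"
    return FitResult(
        estimand=estimand,
        estimate=float(beta[k]),
        se=se,
        statistic=z,
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        coefficients={f"beta_{i}": float(b) for i, b in enumerate(beta)},
    )
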