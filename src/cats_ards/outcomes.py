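"""Subtype-outcome inference.

PICU mortality is modeled with logistic regression (Wald inference);
probability of extubation alive by day 28 is modeled with Fine-Gray
subdistribution-hazard regression treating death as the competing risk.
Subjects still ventilated at day 28 are administratively censored. The
Fine-Gray fitter maximizes the weighted partial likelihood in which
subjects with a prior competing event remain in later risk sets carrying
inverse-probability-of-censoring weights G(t-)/G(T_i-) from the
Kaplan-Meier estimate of the censoring distribution; ties are handled with
the Breslow convention and variance with a sandwich estimator over
per-subject score residuals.

Event coding throughout: 0 = censored, 1 = event of interest (extubated
alive), 2 = competing event (death).

Kaplan-Meier curves and log-rank tests delegate to lifelines; the Cox
model (the no-competing-event limit of Fine-Gray) delegates to
statsmodels and doubles as an independent cross-check of the Fine-Gray
code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, pairwise_logrank_test
from statsmodels.duration.hazard_regression import PHReg

from .errors import ConvergenceError, DomainError, SeparationError

Z95 = 1.959963984540054  # standard-normal 97.5% quantile

ADJUSTMENT_PRESETS: dict[str, tuple[str, ...]] = {
    "unadjusted": (),
    "prism": ("prism_iii",),
    "immunocompromised": ("immunocompromised",),
    "prism_immunocompromised": ("prism_iii", "immunocompromised"),
    "prism_immunocompromised_anc": ("prism_iii", "immunocompromised", "anc"),
    "prism_immunocompromised_alc": ("prism_iii", "immunocompromised", "alc"),
}


@dataclass
class RegressionFit:
    """Coefficients with Wald inference on the exp scale."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    converged: bool
    n_iter: int
    estimate_label: str = "exp(coef)"

    @property
    def exp_coef(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coef - Z95 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coef + Z95 * self.se)

    @property
    def p_values(self) -> np.ndarray:
        from scipy.stats import norm

        z = self.coef / self.se
        return 2 * norm.sf(np.abs(z))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.names,
            "coef": self.coef,
            "se": self.se,
            self.estimate_label: self.exp_coef,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_values,
        })


class LogisticFit(RegressionFit):
    pass


class CoxFit(RegressionFit):
    pass


class FineGrayFit(RegressionFit):
    pass


def _check_design(X: np.ndarray, what: str):
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise DomainError(f"{what}: covariates must be finite")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DomainError(f"{what}: design matrix is rank deficient")
    return X


def fit_logistic(y, X, names=None, *, add_intercept: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald 95% CIs.

    ``y`` is a binary outcome vector; ``X`` the covariate matrix (an
    intercept column is prepended unless ``add_intercept=False``).
    Perfect separation raises :class:`SeparationError`.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + names
    X = _check_design(X, "logistic")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DomainError("logistic outcome must be binary 0/1")
    try:
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # statsmodels PerfectSeparation and kin
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    mu = res.fittedvalues
    if np.any(np.abs(res.params) > 30) or np.any((mu < 1e-10) | (mu > 1 - 1e-10)):
        raise SeparationError("perfect or quasi-perfect separation detected")
    if not res.converged:
        raise ConvergenceError("logistic IRLS did not converge")
    return LogisticFit(
        names=names, coef=np.asarray(res.params), se=np.asarray(res.bse),
        converged=True, n_iter=int(res.fit_history["iteration"]),
        estimate_label="odds_ratio",
    )


def fit_cox(times, events, X, names=None, *, ties: str = "breslow") -> CoxFit:
    """Cox proportional-hazards partial-likelihood fit (Breslow ties).

    ``events`` is a binary event indicator (1 = event, 0 = censored).
    Serves both as an exposed utility and as the independent reduction
    oracle for the Fine-Gray model when competing events are absent.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.shape[0]:
        X = X.T
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    X = _check_design(X, "cox")
    if events.sum() == 0:
        raise DomainError("no events observed")
    model = PHReg(times, X, status=events, ties=ties)
    res = model.fit(maxiter=200)
    return CoxFit(
        names=list(names), coef=np.asarray(res.params),
        se=np.asarray(res.bse), converged=True, n_iter=0,
        estimate_label="hazard_ratio",
    )


# ---------------------------------------------------------------------------
# Fine-Gray subdistribution-hazard regression


def _censoring_survival_left(times, events):
    """Kaplan-Meier estimate of the censoring survival G, evaluated
    left-continuously: returns a callable G(t-).

    Censoring (event == 0) is the "event" here; actual events of either
    cause are treated as censored observations of the censoring time.
    """
    times = np.asarray(times, dtype=float)
    cens = np.asarray(events) == 0
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    c_sorted = cens[order]
    uniq = np.unique(t_sorted[c_sorted])
    n = len(times)
    surv_vals = []
    g = 1.0
    for t in uniq:
        at_risk = np.sum(t_sorted >= t)
        d = np.sum(c_sorted & (t_sorted == t))
        g *= 1.0 - d / at_risk
        surv_vals.append(g)
    surv_vals = np.asarray(surv_vals)

    def g_minus(t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(uniq, t, side="left") - 1  # strictly before t
        out = np.where(idx >= 0, surv_vals[np.clip(idx, 0, None)], 1.0)
        return out

    return g_minus


def fit_fine_gray(times, events, X, names=None, *, event_of_interest: int = 1,
                  max_iter: int = 100, tol: float = 1e-8,
                  robust: bool = True) -> FineGrayFit:
    """Fine-Gray subdistribution-hazard regression.

    ``events`` uses the 0/1/2 coding above; any nonzero code other than
    ``event_of_interest`` is treated as competing. Returns subdistribution
    hazard ratios with sandwich (or model-based, ``robust=False``) Wald
    inference.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.shape[0]:
        X = X.T
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    X = _check_design(X, "fine-gray")
    if np.any(times <= 0):
        raise DomainError("event times must be positive")
    interest = events == event_of_interest
    competing = (events != 0) & ~interest
    if interest.sum() == 0:
        raise DomainError("no events of interest")

    g_minus = _censoring_survival_left(times, events)

    event_times = np.unique(times[interest])
    J = len(event_times)
    # weight matrix W[j, i]: subject i's IPCW weight in the risk set at t_j
    T_col = times[None, :]
    tj = event_times[:, None]
    in_risk_natural = T_col >= tj
    W = in_risk_natural.astype(float)
    if competing.any():
        g_tj = g_minus(event_times)[:, None]          # G(t_j-)
        g_ti = g_minus(times[competing])[None, :]     # G(T_i-)
        extended = (T_col[:, competing] < tj)
        W_comp = np.where(extended, g_tj / np.maximum(g_ti, 1e-300), 1.0)
        W[:, competing] = np.where(in_risk_natural[:, competing], 1.0, 0.0)
        W[:, competing] = np.where(extended, W_comp, W[:, competing])

    # per-event-time tallies (Breslow)
    d_j = np.array([np.sum(interest & (times == t)) for t in event_times])
    sum_x_events = np.vstack([X[interest & (times == t)].sum(axis=0)
                              for t in event_times])

    beta = np.zeros(p)
    trace = []
    for it in range(1, max_iter + 1):
        eta = X @ beta
        eta -= eta.max()  # guard overflow; cancels in ratios
        w_exp = W * np.exp(eta)[None, :]
        s0 = w_exp.sum(axis=1)                       # (J,)
        s1 = w_exp @ X                               # (J, p)
        xbar = s1 / s0[:, None]
        score = (sum_x_events - d_j[:, None] * xbar).sum(axis=0)
        # information: sum_j d_j * (S2/S0 - xbar xbar')
        s2 = np.einsum("ji,ik,il->jkl", w_exp, X, X)
        info = np.einsum("j,jkl->kl", d_j, s2 / s0[:, None, None]) \
            - np.einsum("j,jk,jl->kl", d_j, xbar, xbar)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix",
                                   trace=trace) from exc
        gnorm = float(np.max(np.abs(score)))
        trace.append({"iter": it, "grad_norm": gnorm, "beta": beta.copy()})
        if gnorm < tol:
            break
        # step-halving on the log-likelihood surrogate (gradient norm)
        beta = beta + step
    else:
        raise ConvergenceError(
            f"Fine-Gray did not converge in {max_iter} iterations "
            f"(grad norm {gnorm:.3g})", trace=trace)

    info_inv = np.linalg.inv(info)
    if robust:
        # per-subject score residuals
        eta = X @ beta
        eta -= eta.max()
        w_exp = W * np.exp(eta)[None, :]
        s0 = w_exp.sum(axis=1)
        xbar = (w_exp @ X) / s0[:, None]
        U = np.zeros((n, p))
        # event part
        for j, t in enumerate(event_times):
            idx = interest & (times == t)
            U[idx] += X[idx] - xbar[j]
        # risk-set part: -sum_j d_j * w_exp[j, i]/s0[j] * (x_i - xbar_j)
        frac = (d_j[:, None] * w_exp / s0[:, None])   # (J, n)
        U -= frac.sum(axis=0)[:, None] * X
        U += frac.T @ xbar
        meat = U.T @ U
        cov = info_inv @ meat @ info_inv
    else:
        cov = info_inv
    se = np.sqrt(np.diag(cov))
    return FineGrayFit(
        names=list(names), coef=beta, se=se, converged=True, n_iter=it,
        estimate_label="subdistribution_hazard_ratio",
    )


# ---------------------------------------------------------------------------
# nonparametric estimators


def km_estimate(times, event_observed):
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns ``(times, survival)`` arrays for the right-continuous step
    function, starting at S(0) = 1.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(event_observed, dtype=int))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(times, event_observed, groups, *, pairwise: bool = False):
    """Log-rank chi-square test across groups; optionally all unadjusted
    pairwise two-group tests as well.

    Returns ``(statistic, p_value)`` or ``(statistic, p_value, pairwise_df)``.
    """
    times = np.asarray(times, dtype=float)
    event_observed = np.asarray(event_observed, dtype=int)
    groups = np.asarray(groups)
    counts = pd.Series(groups).value_counts()
    if len(counts) < 2:
        raise DomainError("log-rank requires >= 2 groups")
    res = multivariate_logrank_test(times, groups, event_observed)
    if not pairwise:
        return float(res.test_statistic), float(res.p_value)
    pw = pairwise_logrank_test(times, groups, event_observed)
    table = pw.summary.reset_index()
    return float(res.test_statistic), float(res.p_value), table


def cumulative_incidence(times, events):
    """Aalen-Johansen cumulative incidence functions under competing risks.

    ``events`` uses integer cause codes with 0 = censored. Returns
    ``(jump_times, {cause: cif_array}, overall_survival_array)`` where, at
    every jump time, the cause-specific CIFs and the overall (any-event)
    Kaplan-Meier survival sum to 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    causes = sorted(c for c in np.unique(events) if c != 0)
    uniq = np.unique(times[events != 0]) if (events != 0).any() else np.array([])
    surv = 1.0
    cif = {c: [] for c in causes}
    surv_path = []
    totals = {c: 0.0 for c in causes}
    for t in uniq:
        at_risk = np.sum(times >= t)
        s_before = surv
        d_any = 0
        for c in causes:
            d_c = np.sum((times == t) & (events == c))
            totals[c] += s_before * d_c / at_risk
            d_any += d_c
        surv = s_before * (1.0 - d_any / at_risk)
        for c in causes:
            cif[c].append(totals[c])
        surv_path.append(surv)
    return uniq, {c: np.asarray(v) for c, v in cif.items()}, np.asarray(surv_path)


# ---------------------------------------------------------------------------
# subtype-outcome model presets


def subtype_design(labels, clinical: pd.DataFrame, adjust: str,
                   reference: int = 1):
    """Design matrix of subtype indicators (reference = subtype 1, the
    CATS-1 convention) plus a named adjustment set; returns (X, names)."""
    if adjust not in ADJUSTMENT_PRESETS:
        raise DomainError(
            f"unknown adjustment preset {adjust!r}; "
            f"choose from {sorted(ADJUSTMENT_PRESETS)}")
    labels = np.asarray(labels)
    levels = sorted(np.unique(labels))
    if reference not in levels:
        raise DomainError(f"reference subtype {reference} absent from labels")
    cols, names = [], []
    for lev in levels:
        if lev == reference:
            continue
        cols.append((labels == lev).astype(float))
        names.append(f"subtype_{lev}")
    for cov in ADJUSTMENT_PRESETS[adjust]:
        vals = clinical[cov].astype(float).to_numpy()
        cols.append(vals)
        names.append(cov)
    return np.column_stack(cols), names


def mortality_model(labels, clinical: pd.DataFrame, died,
                    adjust: str = "unadjusted") -> LogisticFit:
    """Logistic model of PICU mortality on subtype membership."""
    X, names = subtype_design(labels, clinical, adjust)
    return fit_logistic(np.asarray(died, dtype=float), X, names)


def extubation_model(labels, clinical: pd.DataFrame, times, events,
                     adjust: str = "unadjusted") -> FineGrayFit:
    """Fine-Gray model of extubation alive (death competing) on subtype."""
    X, names = subtype_design(labels, clinical, adjust)
    return fit_fine_gray(times, events, X, names, event_of_interest=1)
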