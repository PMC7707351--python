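"""Survival modelling of region dose summaries.

Implements the outcome-modelling arm of the analysis: elastic-net
penalized Cox regression for variable selection (equal ridge and lasso
weight), an unpenalized multivariable Cox model for effect estimates,
an octile analysis that re-fits the model within planned-dose strata to
locate a dose threshold, and a Kaplan–Meier / log-rank validation of a
dose cut-point.

Partial-likelihood fits go through lifelines; the penalized path is
fit with scikit-survival's Coxnet, with the penalty chosen by
cross-validated partial-likelihood deviance computed here (Breslow tie
handling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "CoxResult",
    "OctileAnalysis",
    "KMValidation",
    "breslow_partial_loglik",
    "elastic_net_select",
    "fit_cox",
    "octile_analysis",
    "km_validation",
]


@dataclass
class CoxResult:
    table: pd.DataFrame  # index: variable; columns: hr, ci_low, ci_high, p, coef
    log_likelihood: float
    n: int
    n_events: int

    def hr(self, variable: str) -> float:
        return float(self.table.loc[variable, "hr"])

    def p(self, variable: str) -> float:
        return float(self.table.loc[variable, "p"])


def breslow_partial_loglik(X: np.ndarray, beta: np.ndarray,
                           times: np.ndarray, events: np.ndarray) -> float:
    """Cox partial log-likelihood with Breslow tie handling.

    Used to score held-out folds on the penalty path; independent of
    the fitting libraries.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    eta = X @ beta
    order = np.argsort(-times, kind="stable")
    t_s, e_s, eta_s = times[order], events[order], eta[order]
    # risk-set sums: cumulative over descending time; tied times share the
    # risk set of everyone with t >= t_i, i.e. the last cumulative entry of
    # the tie block
    shift = eta_s.max()
    cum = np.cumsum(np.exp(eta_s - shift))
    log_risk = np.log(cum) + shift
    block_last = np.empty(len(t_s), dtype=int)
    j = len(t_s) - 1
    for i in range(len(t_s) - 1, -1, -1):
        if i < len(t_s) - 1 and t_s[i] != t_s[i + 1]:
            j = i
        block_last[i] = j
    return float(np.sum(eta_s[e_s] - log_risk[block_last][e_s]))


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=0)
    if np.any(sd.values == 0):
        bad = list(sd.index[sd.values == 0])
        raise ValueError(f"constant covariate(s): {bad}")
    return (X - X.mean()) / sd


def elastic_net_select(X: pd.DataFrame, times, events, mixing: float = 0.5,
                       cv_folds: int = 5, seed: int = 0,
                       alpha: float | None = None) -> list:
    """Select covariates via elastic-net penalized Cox regression.

    Covariates are standardized; a penalty path is fit at the given
    ridge/lasso mixing (0.5 = equal penalties) and the penalty chosen
    by minimum cross-validated partial-likelihood deviance. Returns the
    names of covariates with nonzero coefficients at the chosen
    penalty. ``alpha`` overrides the CV choice (0 means no penalty,
    i.e. all covariates retained).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if X.shape[1] < 2:
        raise ValueError("variable selection needs >= 2 covariates")
    if events.sum() < 10:
        raise ValueError(f"too few events for selection: {int(events.sum())}")
    Xs = _standardize(X.astype(float))
    y = Surv.from_arrays(event=events, time=times)

    if alpha is not None and alpha == 0.0:
        return list(X.columns)
    if alpha is not None:
        model = CoxnetSurvivalAnalysis(l1_ratio=mixing, alphas=[alpha])
        model.fit(Xs.values, y)
        coefs = model.coef_[:, 0]
        return [c for c, b in zip(X.columns, coefs) if b != 0.0]

    path = CoxnetSurvivalAnalysis(l1_ratio=mixing, alpha_min_ratio=0.01, n_alphas=50)
    path.fit(Xs.values, y)
    alphas = path.alphas_

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    dev = np.zeros((cv_folds, len(alphas)))
    for k, (tr, te) in enumerate(kf.split(Xs)):
        if events[te].sum() == 0 or events[tr].sum() == 0:
            raise ValueError("cross-validation fold without events; reduce cv_folds")
        m = CoxnetSurvivalAnalysis(l1_ratio=mixing, alphas=alphas)
        m.fit(Xs.values[tr], y[tr])
        for j in range(m.coef_.shape[1]):
            dev[k, j] = -2.0 * breslow_partial_loglik(
                Xs.values[te], m.coef_[:, j], times[te], events[te]
            )
        dev[k, m.coef_.shape[1]:] = dev[k, m.coef_.shape[1] - 1]
    best = int(np.argmin(dev.mean(axis=0)))
    coefs = path.coef_[:, min(best, path.coef_.shape[1] - 1)]
    return [c for c, b in zip(X.columns, coefs) if b != 0.0]


def fit_cox(X: pd.DataFrame, times, events, alpha_ci: float = 0.05) -> CoxResult:
    """Unpenalized multivariable Cox fit with Wald CIs and p-values."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if X.isnull().any().any():
        raise ValueError("covariate table contains missing values")
    sd = X.std(ddof=0)
    if np.any(sd.values == 0):
        raise ValueError(f"constant covariate(s): {list(sd.index[sd.values == 0])}")
    if events.sum() < X.shape[1]:
        raise ValueError(
            f"too few events ({int(events.sum())}) for {X.shape[1]} covariates"
        )
    df = X.astype(float).copy()
    df["_time"] = times
    df["_event"] = events
    cph = CoxPHFitter(alpha=alpha_ci)
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception:
        # near-separation: retry once with a whisper of ridge regularisation
        try:
            cph = CoxPHFitter(alpha=alpha_ci, penalizer=0.01, l1_ratio=0.0)
            cph.fit(df, duration_col="_time", event_col="_event")
        except Exception as exc:  # lifelines ConvergenceError and friends
            raise RuntimeError(
                f"Cox fit failed (n={len(df)}, events={int(events.sum())}, "
                f"covariates={list(X.columns)}): {exc}"
            ) from exc
    s = cph.summary
    table = pd.DataFrame(
        dict(
            coef=s["coef"],
            hr=s["exp(coef)"],
            ci_low=np.exp(s["coef lower 95%"]),
            ci_high=np.exp(s["coef upper 95%"]),
            p=s["p"],
        )
    )
    return CoxResult(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(events.sum()),
    )


@dataclass
class OctileSubset:
    label: str
    dose_low: float
    dose_high: float
    index: np.ndarray  # integer row positions of cohort members
    n: int
    n_events: int
    flagged: bool = False
    flag_reason: str = ""
    cox: CoxResult | None = None
    delta_p: float | None = None
    delta_hr: float | None = None


@dataclass
class OctileAnalysis:
    boundaries: np.ndarray  # 9 ascending Gy values
    subsets: list
    merge_lowest: int
    threshold_estimate: float | None


def octile_analysis(planned_region, table: pd.DataFrame, times, events,
                    delta_col: str = "mean_delta_region_gy",
                    adjust_cols: tuple = (), merge_lowest: int = 3,
                    min_size: int = 30, min_events: int = 10) -> OctileAnalysis:
    """Planned-dose-octile stratified Cox analysis of the Δdose effect.

    The cohort is split at the empirical octiles (k/8 quantiles, linear
    interpolation) of the planned region dose; the lowest
    ``merge_lowest`` octiles are merged to cover a dose range
    comparable to the others. Within each subset a multivariable Cox
    model of the Δdose term plus ``adjust_cols`` is fit; subsets below
    the size/event floor are flagged rather than dropped. The threshold
    estimate is the lower dose bound of the lowest subset in which the
    Δdose term reaches p < 0.05 (a conservative reading of where the
    dose–effect relation switches on).
    """
    planned = np.asarray(planned_region, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(planned)
    boundaries = np.quantile(planned, np.linspace(0, 1, 9))
    bins = np.searchsorted(boundaries[1:-1], planned, side="right")  # 0..7
    merged = np.where(bins < merge_lowest, 0, bins - merge_lowest + 1)
    n_groups = 8 - merge_lowest + 1

    subsets = []
    threshold = None
    for g in range(n_groups):
        members = np.flatnonzero(merged == g)
        if g == 0:
            lo, hi = boundaries[0], boundaries[merge_lowest]
            label = f"octiles 1-{merge_lowest}"
        else:
            lo, hi = boundaries[merge_lowest + g - 1], boundaries[merge_lowest + g]
            label = f"octile {merge_lowest + g}"
        sub = OctileSubset(
            label=label, dose_low=float(lo), dose_high=float(hi),
            index=members, n=len(members), n_events=int(events[members].sum()),
        )
        if sub.n < min_size or sub.n_events < min_events:
            sub.flagged = True
            sub.flag_reason = f"subset too small (n={sub.n}, events={sub.n_events})"
        else:
            cols = [delta_col] + [c for c in adjust_cols if c != delta_col]
            Xs = table.iloc[members][cols].astype(float)
            # covariates constant within a stratum carry no information there
            keep = [c for c in Xs.columns if Xs[c].std(ddof=0) > 0]
            if delta_col not in keep:
                sub.flagged = True
                sub.flag_reason = "Δdose constant within subset"
            else:
                try:
                    sub.cox = fit_cox(Xs[keep], times[members], events[members])
                    sub.delta_p = sub.cox.p(delta_col)
                    sub.delta_hr = sub.cox.hr(delta_col)
                except (RuntimeError, ValueError) as exc:
                    sub.flagged = True
                    sub.flag_reason = str(exc)
        subsets.append(sub)
        if threshold is None and sub.delta_p is not None and sub.delta_p < 0.05:
            threshold = sub.dose_low
    return OctileAnalysis(
        boundaries=boundaries, subsets=subsets,
        merge_lowest=merge_lowest, threshold_estimate=threshold,
    )


@dataclass
class KMValidation:
    cutpoint: float
    n_below: int
    n_above: int
    hr_below: float  # hazard ratio of the below-cutpoint group vs above
    ci_low: float
    ci_high: float
    logrank_p: float
    median_below: float | None = None
    median_above: float | None = None
    km_below: KaplanMeierFitter | None = field(default=None, repr=False)
    km_above: KaplanMeierFitter | None = field(default=None, repr=False)


def km_validation(planned_region, cutpoint: float, times, events) -> KMValidation:
    """Kaplan–Meier / log-rank comparison across a planned-dose cut-point.

    Groups patients by region dose below vs at-or-above ``cutpoint``,
    fits KM curves, tests with log-rank, and reports the univariable
    proportional-hazards HR of the below group relative to the above
    group (HR < 1 means lower region dose carries lower risk).
    """
    planned = np.asarray(planned_region, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    below = planned < cutpoint
    if below.all() or (~below).all():
        raise ValueError(
            f"cutpoint {cutpoint} Gy does not split the cohort "
            f"(dose range {planned.min():.2f}-{planned.max():.2f} Gy)"
        )
    km_b, km_a = KaplanMeierFitter(), KaplanMeierFitter()
    km_b.fit(times[below], events[below], label=f"< {cutpoint:g} Gy")
    km_a.fit(times[~below], events[~below], label=f">= {cutpoint:g} Gy")
    lr = logrank_test(times[below], times[~below], events[below], events[~below])
    cox = fit_cox(pd.DataFrame({"below_cutpoint": below.astype(float)}), times, events)
    return KMValidation(
        cutpoint=float(cutpoint),
        n_below=int(below.sum()),
        n_above=int((~below).sum()),
        hr_below=cox.hr("below_cutpoint"),
        ci_low=float(cox.table.loc["below_cutpoint", "ci_low"]),
        ci_high=float(cox.table.loc["below_cutpoint", "ci_high"]),
        logrank_p=float(lr.p_value),
        median_below=float(km_b.median_survival_time_),
        median_above=float(km_a.median_survival_time_),
        km_below=km_b,
        km_above=km_a,
    )
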