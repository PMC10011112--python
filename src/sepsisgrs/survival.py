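"""Survival machinery: Kaplan–Meier, log-rank, Cox, landmark windows.

Time origins follow the study design: a subject who develops sepsis is
followed from the sepsis diagnosis, a sepsis-free subject from recruitment.
Post-diagnosis time is split into short- (0–30 days], mid- (31 days–2 years]
and long-term (>2 years) windows; each window is analysed as a landmark:
only subjects event-free, alive and still under follow-up at the window
start enter its risk set, contributing time from the window start to the
first of event, death, end of follow-up or window end.  Death from any cause
censors.

Kaplan–Meier and the k-group log-rank statistic are computed directly from
risk-set bookkeeping; Cox proportional-hazards fits delegate to lifelines
(Efron tie handling), and the contract is the returned (HR, 95% CI, p)
per covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WindowSpec",
    "WindowResult",
    "DEFAULT_WINDOWS",
    "km_estimate",
    "logrank_test",
    "logrank_o_minus_e",
    "cox_fit",
    "landmark_window_analysis",
    "grs_trend_test",
    "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 365.25

#: CI bounds beyond this are displayed as ">999" and flagged unstable.
UNSTABLE_HR_BOUND = 999.0


@dataclass(frozen=True)
class WindowSpec:
    """Half-open follow-up window (start_day, end_day] in days from origin."""

    name: str
    start_day: float
    end_day: float | None  # None = open-ended

    @property
    def start_years(self) -> float:
        return self.start_day / DAYS_PER_YEAR

    @property
    def end_years(self) -> float:
        return np.inf if self.end_day is None else self.end_day / DAYS_PER_YEAR


DEFAULT_WINDOWS = (
    WindowSpec("short", 0, 30),
    WindowSpec("mid", 30, 730),
    WindowSpec("long", 730, None),
)


@dataclass(frozen=True)
class WindowResult:
    window: WindowSpec
    n_at_risk: dict
    n_events: dict
    rate: dict
    hr: float
    ci95: tuple[float, float]
    p: float
    flag: str  # ok | unstable | inestimable


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event time with columns ``time n_at_risk
    n_events survival``.  Ties are handled by counting every subject with
    time >= t in the risk set at t: events at t are processed before
    censorings at the same instant.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("km_estimate needs at least one record")
    if (t < 0).any():
        raise ValueError("negative survival times")

    event_times = np.unique(t[e])
    rows = []
    surv = 1.0
    for et in event_times:
        n_risk = int((t >= et).sum())
        d = int(((t == et) & e).sum())
        surv *= 1.0 - d / n_risk
        rows.append({"time": et, "n_at_risk": n_risk, "n_events": d, "survival": surv})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_o_minus_e(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Observed and expected event counts plus covariance over shared risk sets.

    Returns ``(observed, expected, covariance, group_labels)`` with one entry
    per group in sorted label order.  Hypergeometric variance at each event
    time; the covariance matrix is singular (rows sum to zero) by design.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = sorted(pd.unique(g).tolist())
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank needs at least two groups")
    for lab in labels:
        if (g == lab).sum() == 0:  # pragma: no cover - unique() precludes
            raise ValueError(f"group {lab!r} has no subjects")

    gi = np.searchsorted(np.array(labels, dtype=object), g)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in np.unique(t[e]):
        at_risk = t >= et
        n = at_risk.sum()
        nj = np.bincount(gi[at_risk], minlength=k).astype(float)
        died = (t == et) & e
        d = died.sum()
        dj = np.bincount(gi[died], minlength=k).astype(float)
        O += dj
        E += d * nj / n
        if n > 1:
            c = d * (n - d) / (n - 1.0)
            p = nj / n
            V += c * (np.diag(p) - np.outer(p, p))
    return O, E, V, labels


def logrank_test(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence,
) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi2, df, p)."""
    O, E, V, labels = logrank_o_minus_e(times, events, groups)
    k = len(labels)
    u = (O - E)[: k - 1]
    Vr = V[: k - 1, : k - 1]
    chi2 = float(u @ np.linalg.pinv(Vr) @ u) if Vr.size else 0.0
    chi2 = max(chi2, 0.0)
    df = k - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties via lifelines).

    Returns one row per covariate: ``covariate hr ci_low ci_high p flag``.
    Non-convergence or a monotone likelihood yields a single row flagged
    ``inestimable`` instead of raising; CI bounds beyond 999 flag
    ``unstable``.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cols = [duration_col, event_col, *covariates]
    df = records[cols].copy()
    df[event_col] = df[event_col].astype(int)
    # constant covariates carry no information and break the fit
    usable = [c for c in covariates if df[c].nunique() > 1]
    if not usable or df[event_col].sum() == 0:
        return _inestimable_frame(covariates)

    # standardize internally for Newton stability; back-transform after
    sds = df[usable].std(ddof=1).replace(0.0, 1.0)
    means = df[usable].mean()
    dfz = df[[duration_col, event_col]].copy()
    for c in usable:
        dfz[c] = (df[c] - means[c]) / sds[c]

    # damp the Newton step progressively if the default diverges (rare
    # binary exposures with large effects can overshoot on the first step)
    attempts = (
        {"precision": 1e-9},
        {"precision": 1e-9, "step_size": 0.25, "max_steps": 500},
        {"precision": 1e-9, "step_size": 0.1, "max_steps": 2000},
    )
    cph = None
    for fit_options in attempts:
        candidate = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                candidate.fit(
                    dfz,
                    duration_col=duration_col,
                    event_col=event_col,
                    fit_options=fit_options,
                )
            cph = candidate
            break
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            continue
    if cph is None:
        return _inestimable_frame(covariates)

    summ = cph.summary
    z975 = stats.norm.ppf(0.975)
    rows = []
    for c in covariates:
        if c not in summ.index:
            rows.append(_inestimable_row(c))
            continue
        coef = float(summ.loc[c, "coef"]) / sds[c]
        se = float(summ.loc[c, "se(coef)"]) / sds[c]
        with np.errstate(over="ignore"):
            hr = float(np.exp(coef))
            lo = float(np.exp(coef - z975 * se))
            hi = float(np.exp(coef + z975 * se))
        flag = "unstable" if (hi > UNSTABLE_HR_BOUND or lo > UNSTABLE_HR_BOUND) else "ok"
        rows.append(
            {
                "covariate": c,
                "hr": hr,
                "ci_low": lo,
                "ci_high": hi,
                "p": float(summ.loc[c, "p"]),
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def _inestimable_row(c: str) -> dict:
    return {
        "covariate": c,
        "hr": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "p": np.nan,
        "flag": "inestimable",
    }


def _inestimable_frame(covariates: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame([_inestimable_row(c) for c in covariates])


def _prepare_covariates(records: pd.DataFrame, covariates: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
    """Expand categoricals (e.g. race) to dummies; drop single-level ones."""
    out = records.copy()
    final: list[str] = []
    for c in covariates:
        col = out[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                continue  # e.g. race in a White-only analysis
            for lev in levels[1:]:
                name = f"{c}_{lev}"
                out[name] = (col.astype(str) == lev).astype(float)
                final.append(name)
        else:
            final.append(c)
    return out, final


def landmark_window_analysis(
    records: pd.DataFrame,
    windows: Sequence[WindowSpec] = DEFAULT_WINDOWS,
    group_col: str = "group",
    covariates: Sequence[str] = (),
) -> list[WindowResult]:
    """Per-window landmark comparison of two (or more) groups.

    ``records`` has one row per subject with ``time`` (years from the
    subject's own origin to first event or censoring), ``event``, the group
    column, and covariates.  For each window, subjects still at risk at the
    window start re-enter at time zero; the hazard ratio is the group_col
    coefficient from a covariate-adjusted Cox fit on the window's records.
    """
    results = []
    for w in windows:
        s, e = w.start_years, w.end_years
        sub = records[records["time"] > s].copy()
        sub["time"] = np.minimum(sub["time"], e) - s
        sub["event"] = sub["event"] & (records.loc[sub.index, "time"] <= e)

        n_at_risk = sub.groupby(group_col).size().to_dict()
        n_events = sub.groupby(group_col)["event"].sum().astype(int).to_dict()
        rate = {g: n_events.get(g, 0) / n for g, n in n_at_risk.items()}

        if sub.empty or sub["event"].sum() == 0 or sub[group_col].nunique() < 2:
            results.append(
                WindowResult(w, n_at_risk, n_events, rate, np.nan, (np.nan, np.nan), np.nan, "inestimable")
            )
            continue
        sub2, covs = _prepare_covariates(sub, covariates)
        sub2["_group"] = pd.factorize(sub2[group_col], sort=True)[0].astype(float)
        fit = cox_fit(sub2, ["_group", *covs])
        row = fit[fit["covariate"] == "_group"].iloc[0]
        results.append(
            WindowResult(
                window=w,
                n_at_risk=n_at_risk,
                n_events=n_events,
                rate=rate,
                hr=row["hr"],
                ci95=(row["ci_low"], row["ci_high"]),
                p=row["p"],
                flag=row["flag"],
            )
        )
    return results


def grs_trend_test(
    times: Sequence[float],
    events: Sequence[bool],
    ordered_groups: Sequence,
    levels: Sequence = ("low", "intermediate", "high"),
) -> pd.DataFrame:
    """Ordered-group trend tests across GRS risk groups.

    Two routes, both reported: (a) the log-rank test for trend with scores
    0, 1, 2, ... over the ordered levels; (b) a Cox Wald test treating the
    ordinal score as a continuous covariate.  Returns a two-row DataFrame
    ``method statistic p``.
    """
    g = pd.Categorical(ordered_groups, categories=list(levels), ordered=True)
    if g.isna().any():
        raise ValueError("group labels outside the declared levels")
    present = [lev for lev in levels if (g == lev).sum() > 0]
    if len(present) < 2:
        raise ValueError("trend test needs at least two non-empty groups")
    scores = {lev: i for i, lev in enumerate(levels)}
    s_arr = np.array([scores[x] for x in np.asarray(g)], dtype=float)

    O, E, V, labels = logrank_o_minus_e(times, events, np.asarray(g))
    w = np.array([scores[lab] for lab in labels], dtype=float)
    u = float(w @ (O - E))
    var = float(w @ V @ w)
    z = u / np.sqrt(var) if var > 0 else 0.0
    p_lr = 2 * stats.norm.sf(abs(z))

    df = pd.DataFrame(
        {"time": np.asarray(times, dtype=float), "event": np.asarray(events, bool), "score": s_arr}
    )
    fit = cox_fit(df, ["score"])
    row = fit.iloc[0]
    if row["flag"] == "inestimable":
        z_cox, p_cox = np.nan, np.nan
    else:
        z_cox = np.log(row["hr"]) / ((np.log(row["ci_high"]) - np.log(row["ci_low"])) / (2 * 1.959964))
        p_cox = row["p"]

    return pd.DataFrame(
        {
            "method": ["logrank_trend", "cox_ordinal"],
            "statistic": [z, z_cox],
            "p": [p_lr, p_cox],
        }
    )
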