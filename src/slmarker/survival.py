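"""Constrained survival screen over single and paired IHC markers.

Given patient-level over/under stain calls and a clinical table (overall
survival in months, death indicator, stage and other covariates), the screen
runs, per candidate marker: a two-group log-rank test, a univariate Cox
proportional-hazards model on the binary risk indicator, and a
stage-adjusted Cox model (stage III–IV vs I–II). Follow-up is
administratively censored at a fixed horizon (default 120 months, i.e.
10-year overall survival). Markers whose risk group or its complement holds
fewer than ``min_subset`` patients are skipped rather than fitted.

Model fitting is delegated to lifelines (Efron tie handling); this module
adds the screening logic, the guard rails, stepwise/AIC covariate entry and
two-marker combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines import statistics as lls
from lifelines.exceptions import ConvergenceError

from .ihc import MarkerDefinition, marker_membership

STAGE_LATE = ("III", "IV")


# ---------------------------------------------------------------------------
# containers


@dataclass
class KMEstimate:
    """Product-limit survival estimate."""

    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    n_groups: tuple[int, int]


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``params`` is indexed by covariate with columns coef, se, hr, ci_low,
    ci_high, p (Wald); ``lr_chi2`` is the likelihood-ratio statistic of the
    model against the null (or supplied nested) model.
    """

    params: pd.DataFrame
    lr_chi2: float
    lr_df: int
    lr_p: float
    n: int
    n_events: int
    log_likelihood: float
    aic: float
    converged: bool = True

    def hr(self, covariate: str) -> float:
        return float(self.params.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.params.loc[covariate]
        return float(row["ci_low"]), float(row["ci_high"])

    def p(self, covariate: str) -> float:
        return float(self.params.loc[covariate, "p"])


@dataclass
class ScreenResult:
    """Outcome of screening one marker."""

    marker: MarkerDefinition
    n: int = 0
    n_risk: int = 0
    status: str = "tested"  # tested | skipped_small_subset | not_converged
    logrank: LogRankResult | None = None
    univariate: CoxFit | None = None
    adjusted: CoxFit | None = None
    label: str | None = None
    notes: list[str] = field(default_factory=list)

    def display_label(self) -> str:
        return self.label if self.label is not None else self.marker.label()


# ---------------------------------------------------------------------------
# core estimators


def _check_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    return t


def km_estimate(times, events) -> KMEstimate:
    """Kaplan–Meier product-limit estimate.

    At tied times deaths precede censorings (the standard convention), so a
    death and a censoring at the same time both leave the at-risk set but
    only the death enters the product.
    """
    t = _check_times(times)
    e = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    times_out = table.index.to_numpy(dtype=float)
    return KMEstimate(
        event_times=times_out,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        survival=surv.reindex(table.index).to_numpy(dtype=float),
    )


def logrank_test(times, events, group) -> LogRankResult:
    """Two-group log-rank test (1 df, two-sided)."""
    t = _check_times(times)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group, dtype=int)
    n0, n1 = int(np.sum(g == 0)), int(np.sum(g == 1))
    if n0 == 0 or n1 == 0:
        raise ValueError("log-rank test requires two non-empty groups")
    res = lls.logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
    return LogRankResult(float(res.test_statistic), float(res.p_value), (n0, n1))


def administrative_censor(df: pd.DataFrame, horizon: float, time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
    """Truncate follow-up at ``horizon``: later events become censorings."""
    out = df.copy()
    late = out[time_col] > horizon
    out.loc[late, event_col] = 0
    out.loc[late, time_col] = horizon
    return out


def encode_stage(stage: pd.Series) -> pd.Series:
    """Binary late-stage indicator: 1 for stage III–IV, 0 for I–II."""
    def _one(v):
        if pd.isna(v):
            return np.nan
        s = str(v).strip().upper()
        if s in STAGE_LATE:
            return 1.0
        if s in ("I", "II"):
            return 0.0
        raise ValueError(f"unknown stage value {v!r}")

    return stage.map(_one)


def cox_fit(
    df: pd.DataFrame,
    covariates: Sequence[str],
    time_col: str = "time",
    event_col: str = "event",
    reduced_covariates: Sequence[str] | None = None,
) -> CoxFit:
    """Cox proportional-hazards fit with Efron tie handling.

    ``lr_chi2`` is 2(ℓ_full − ℓ_reduced); by default the reduced model is the
    null (no covariates). Constant covariates are rejected; monotone partial
    likelihood (complete separation) yields a result flagged
    ``converged=False`` rather than an exception.
    """
    covariates = list(covariates)
    data = df[[time_col, event_col, *covariates]].dropna().copy()
    _check_times(data[time_col].to_numpy())
    n = len(data)
    n_events = int(data[event_col].sum())
    if n_events < 1:
        raise ValueError("need at least one event to fit a Cox model")
    for c in covariates:
        if data[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")

    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(data, duration_col=time_col, event_col=event_col,
                    fit_options={"precision": 1e-12, "r_precision": 1e-18})
        for w in caught:
            msg = str(w.message).lower()
            if "convergence" in msg or "separation" in msg or "collinear" in msg:
                converged = False
    except ConvergenceError as err:
        nanrow = {c: np.nan for c in ("coef", "se", "hr", "ci_low", "ci_high", "p")}
        params = pd.DataFrame([nanrow] * len(covariates), index=covariates)
        return CoxFit(params, np.nan, len(covariates), np.nan, n, n_events,
                      np.nan, np.nan, converged=False)

    summ = cph.summary
    params = pd.DataFrame(
        {
            "coef": summ["coef"],
            "se": summ["se(coef)"],
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    ll_full = float(cph.log_likelihood_)
    if reduced_covariates is None:
        lr = cph.log_likelihood_ratio_test()
        lr_chi2, lr_df, lr_p = float(lr.test_statistic), int(lr.degrees_freedom), float(lr.p_value)
    else:
        reduced = cox_fit(df, reduced_covariates, time_col, event_col) if reduced_covariates else None
        if reduced is None:
            raise ValueError("reduced_covariates must be non-empty or None")
        from scipy import stats as sps

        lr_df = len(covariates) - len(reduced_covariates)
        lr_chi2 = 2.0 * (ll_full - reduced.log_likelihood)
        lr_p = float(sps.chi2.sf(lr_chi2, lr_df))
    return CoxFit(
        params=params,
        lr_chi2=lr_chi2,
        lr_df=lr_df,
        lr_p=lr_p,
        n=n,
        n_events=n_events,
        log_likelihood=ll_full,
        aic=float(cph.AIC_partial_),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# the screen


def _marker_frame(
    marker: MarkerDefinition,
    calls: pd.DataFrame,
    survival: pd.DataFrame,
    horizon: float,
) -> pd.DataFrame:
    """Join a marker's risk indicator onto the clinical table and censor."""
    ind = marker_membership(calls, marker).rename("marker")
    df = survival.set_index("patient_id") if "patient_id" in survival.columns else survival
    joined = df.join(ind, how="inner").dropna(subset=["time", "event"])
    return administrative_censor(joined, horizon)


def screen_markers(
    markers: Sequence[MarkerDefinition],
    calls: pd.DataFrame,
    survival: pd.DataFrame,
    min_subset: int = 5,
    horizon_months: float = 120.0,
    adjust: str | None = "stage",
) -> list[ScreenResult]:
    """Screen every marker with log-rank + univariate + adjusted Cox.

    A marker is skipped (``status='skipped_small_subset'``) when its risk
    group, or the complement, holds fewer than ``min_subset`` patients; the
    symmetric guard prevents degenerate fits on either side. Tested results
    are sorted by univariate Wald p.
    """
    results = []
    for marker in markers:
        res = ScreenResult(marker=marker)
        df = _marker_frame(marker, calls, survival, horizon_months)
        res.n = len(df)
        res.n_risk = int(df["marker"].sum())
        if res.n_risk < min_subset or res.n - res.n_risk < min_subset:
            res.status = "skipped_small_subset"
            results.append(res)
            continue
        try:
            res.logrank = logrank_test(df["time"], df["event"], df["marker"])
            res.univariate = cox_fit(df, ["marker"])
            if adjust == "stage":
                adj = df.assign(stage_late=encode_stage(df["stage"]))
                res.adjusted = cox_fit(adj, ["marker", "stage_late"])
            if (res.univariate is not None and not res.univariate.converged) or (
                res.adjusted is not None and not res.adjusted.converged
            ):
                res.status = "not_converged"
        except ValueError as err:
            res.status = "not_converged"
            res.notes.append(str(err))
        results.append(res)

    def _key(r: ScreenResult):
        if r.status == "tested" and r.univariate is not None:
            return (0, r.univariate.p("marker"))
        return (1, np.inf)

    return sorted(results, key=_key)


def screen_to_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Tabulate screen results (one row per marker), with a BH-adjusted
    p column emitted for reference but not used for selection."""
    rows = []
    for r in results:
        row = {
            "marker": r.display_label(),
            "n": r.n,
            "n_risk": r.n_risk,
            "status": r.status,
            "logrank_chi2": np.nan,
            "logrank_p": np.nan,
            "hr": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
            "lr_chi2": np.nan,
            "hr_adj": np.nan,
            "ci_low_adj": np.nan,
            "ci_high_adj": np.nan,
            "p_adj": np.nan,
            "lr_chi2_adj": np.nan,
        }
        if r.logrank is not None:
            row["logrank_chi2"] = r.logrank.chi_square
            row["logrank_p"] = r.logrank.p_value
        if r.univariate is not None:
            row.update(
                hr=r.univariate.hr("marker"),
                ci_low=r.univariate.ci("marker")[0],
                ci_high=r.univariate.ci("marker")[1],
                p=r.univariate.p("marker"),
                lr_chi2=r.univariate.lr_chi2,
            )
        if r.adjusted is not None:
            row.update(
                hr_adj=r.adjusted.hr("marker"),
                ci_low_adj=r.adjusted.ci("marker")[0],
                ci_high_adj=r.adjusted.ci("marker")[1],
                p_adj=r.adjusted.p("marker"),
                lr_chi2_adj=r.adjusted.lr_chi2,
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    tested = frame["p"].notna()
    if tested.any():
        from .qvalue import storey_qvalues

        frame.loc[tested, "p_bh"] = storey_qvalues(frame.loc[tested, "p"].to_numpy(), pi0=1.0)
    else:
        frame["p_bh"] = np.nan
    return frame


def stepwise_aic(
    df: pd.DataFrame,
    base_covariates: Sequence[str],
    candidates: Sequence[str],
    time_col: str = "time",
    event_col: str = "event",
) -> tuple[CoxFit, list[str]]:
    """Forward-backward stepwise selection minimizing partial-likelihood AIC.

    Base covariates (the marker and the adjustment factor) are never
    dropped; candidates (e.g. age, alcohol use) enter or leave while each
    move lowers AIC. Returns the final fit and a human-readable trace.
    """
    base = list(base_covariates)
    cand = list(candidates)
    data = df[[time_col, event_col, *base, *cand]].dropna()
    included: list[str] = []
    current = cox_fit(data, base, time_col, event_col)
    trace = [f"start AIC={current.aic:.3f} with {base}"]
    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, str, str]] = []
        for c in cand:
            if c in included:
                continue
            try:
                fit = cox_fit(data, base + included + [c], time_col, event_col)
            except ValueError:
                continue
            moves.append((fit.aic, "add", c))
        for c in included:
            cov = base + [x for x in included if x != c]
            fit = cox_fit(data, cov, time_col, event_col)
            moves.append((fit.aic, "drop", c))
        if not moves:
            break
        best_aic, action, var = min(moves, key=lambda m: m[0])
        if best_aic < current.aic - 1e-9:
            if action == "add":
                included.append(var)
            else:
                included.remove(var)
            current = cox_fit(data, base + included, time_col, event_col)
            trace.append(f"{action} {var}: AIC={current.aic:.3f}")
            improved = True
    trace.append(f"final covariates: {base + included}")
    return current, trace


def combine_markers(
    marker_a: MarkerDefinition,
    marker_b: MarkerDefinition,
    calls: pd.DataFrame,
    survival: pd.DataFrame,
    min_subset: int = 5,
    horizon_months: float = 120.0,
    combine_protective: str = "complement",
) -> ScreenResult:
    """Stage-adjusted Cox fit on the intersection of two markers' risk subsets.

    A protective marker (orientation='protective') contributes the
    COMPLEMENT of its pattern subset as its risk side, unless
    ``combine_protective='as-is'``. Combining a marker with itself returns
    the marker's own indicator (idempotent).
    """
    if combine_protective not in ("complement", "as-is"):
        raise ValueError("combine_protective must be 'complement' or 'as-is'")
    inds = []
    for m in (marker_a, marker_b):
        ind = marker_membership(calls, m)
        if m.orientation == "protective" and combine_protective == "complement":
            ind = 1 - ind
        inds.append(ind)
    joint = (inds[0] * inds[1]).rename("marker")

    res = ScreenResult(marker=marker_a, label=f"[{marker_a.label()}] x [{marker_b.label()}]")

    df = survival.set_index("patient_id") if "patient_id" in survival.columns else survival
    joined = df.join(joint, how="inner").dropna(subset=["time", "event"])
    joined = administrative_censor(joined, horizon_months)
    res.n = len(joined)
    res.n_risk = int(joined["marker"].sum())
    if res.n_risk < min_subset or res.n - res.n_risk < min_subset:
        res.status = "skipped_small_subset"
        return res
    res.logrank = logrank_test(joined["time"], joined["event"], joined["marker"])
    res.univariate = cox_fit(joined, ["marker"])
    adj = joined.assign(stage_late=encode_stage(joined["stage"]))
    res.adjusted = cox_fit(adj, ["marker", "stage_late"])
    if not (res.univariate.converged and res.adjusted.converged):
        res.status = "not_converged"
    return res
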