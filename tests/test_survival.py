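"""Tests for the survival engine against hand and numeric oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import slmarker as sl
from slmarker.ihc import OVER, UNDER
from slmarker.survival import administrative_censor, encode_stage

from conftest import make_survival_frame


# ---------------------------------------------------------------------------
# Kaplan–Meier


def test_km_no_events_stays_at_one():
    est = sl.km_estimate([3.0, 5.0, 8.0], [0, 0, 0])
    assert np.all(est.survival == 1.0)
    assert est.survival_at(100.0) == 1.0


def test_km_hand_product_limit():
    # n=4, deaths at 1 and 2: S(1) = 3/4, S(2) = 3/4 * (2/3) = 1/2
    est = sl.km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0])
    assert est.survival_at(1.0) == pytest.approx(0.75)
    assert est.survival_at(2.0) == pytest.approx(0.5)


def test_km_deaths_precede_censorings_at_ties():
    # death and censoring both at t=1 with n=2: the death sees 2 at risk
    est = sl.km_estimate([1.0, 1.0], [1, 0])
    assert est.survival_at(1.0) == pytest.approx(0.5)


def test_km_rejects_nonpositive_times():
    with pytest.raises(ValueError):
        sl.km_estimate([0.0, 1.0], [1, 1])


def test_km_complements_ecdf_without_censoring():
    rng = np.random.default_rng(0)
    t = rng.exponential(10, size=50)
    est = sl.km_estimate(t, np.ones(50, dtype=int))
    last = np.max(t)
    assert est.survival_at(last) == pytest.approx(0.0, abs=1e-12)
    mid = np.median(t)
    assert est.survival_at(mid) == pytest.approx(1 - np.mean(t <= mid), abs=1e-12)


# ---------------------------------------------------------------------------
# log-rank


def _hand_logrank(times, events, group):
    """Independent oracle: O−E and hypergeometric variance accumulated over
    the 2×2 risk table at each distinct death time."""
    times, events, group = map(np.asarray, (times, events, group))
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n - d) * n1 * (n - n1) / (n**2 * (n - 1))
    return o_minus_e**2 / var


def test_logrank_identical_groups_is_null():
    t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    e = [1, 1, 0, 1, 1, 0]
    g = [0, 0, 0, 1, 1, 1]
    res = sl.logrank_test(t, e, g)
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_matches_hand_risk_tables():
    # group A deaths at 1, 2; group B deaths at 3, 4; no censoring
    t = [1.0, 2.0, 3.0, 4.0]
    e = [1, 1, 1, 1]
    g = [0, 0, 1, 1]
    res = sl.logrank_test(t, e, g)
    assert res.chi_square == pytest.approx(_hand_logrank(t, e, g), abs=1e-10)

    rng = np.random.default_rng(1)
    t = rng.exponential(10, 40)
    e = (rng.random(40) < 0.7).astype(int)
    g = (rng.random(40) < 0.5).astype(int)
    res = sl.logrank_test(t, e, g)
    assert res.chi_square == pytest.approx(_hand_logrank(t, e, g), abs=1e-6)


def test_logrank_invariant_to_patient_order():
    rng = np.random.default_rng(2)
    t = rng.exponential(10, 30)
    e = (rng.random(30) < 0.8).astype(int)
    g = (rng.random(30) < 0.4).astype(int)
    perm = rng.permutation(30)
    assert sl.logrank_test(t, e, g).chi_square == pytest.approx(
        sl.logrank_test(t[perm], e[perm], g[perm]).chi_square, abs=1e-12
    )
    with pytest.raises(ValueError):
        sl.logrank_test(t, e, np.zeros(30, dtype=int))


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _neg_log_partial_likelihood(beta, times, events, x):
    """Hand-written Cox partial likelihood for untied data."""
    ll = 0.0
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return -ll


def test_cox_matches_numeric_partial_likelihood_optimum():
    # interleaved covariate: the partial likelihood has a finite maximizer
    # (a risk group that dies strictly first is separated, beta -> infinity)
    times = np.array([1.0, 2.0, 3.0, 4.0])
    events = np.array([1, 1, 1, 1])
    x = np.array([1.0, 0.0, 1.0, 0.0])
    df = pd.DataFrame({"time": times, "event": events, "x": x})
    fit = sl.cox_fit(df, ["x"])
    oracle = minimize_scalar(
        _neg_log_partial_likelihood, bounds=(-5, 5), args=(times, events, x), method="bounded",
        options={"xatol": 1e-10},
    )
    assert fit.params.loc["x", "coef"] == pytest.approx(oracle.x, abs=1e-6)
    # and the model log-likelihood agrees with the hand-written one
    assert fit.log_likelihood == pytest.approx(
        -_neg_log_partial_likelihood(oracle.x, times, events, x), abs=1e-6
    )


def test_cox_ci_brackets_hr_and_lr_positive():
    rng = np.random.default_rng(3)
    df = make_survival_frame(rng, n=150, hr=2.5)
    fit = sl.cox_fit(df, ["x"])
    lo, hi = fit.ci("x")
    assert lo < fit.hr("x") < hi
    assert fit.hr("x") > 0
    assert fit.lr_chi2 >= 0
    assert fit.n == 150 and fit.n_events == int(df["event"].sum())


def test_cox_null_covariate_ci_coverage():
    rng = np.random.default_rng(4)
    covered = 0
    n_sim = 100
    for _ in range(n_sim):
        df = make_survival_frame(rng, n=80, hr=1.0)
        fit = sl.cox_fit(df, ["x"])
        lo, hi = fit.ci("x")
        covered += lo <= 1.0 <= hi
    assert covered / n_sim >= 0.90


def test_cox_duplication_near_invariance_under_efron():
    rng = np.random.default_rng(5)
    df = make_survival_frame(rng, n=60, hr=2.0)
    fit1 = sl.cox_fit(df, ["x"])
    fit2 = sl.cox_fit(pd.concat([df, df], ignore_index=True), ["x"])
    assert fit2.hr("x") == pytest.approx(fit1.hr("x"), rel=0.02)


def test_cox_guard_rails():
    df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 0], "x": [1.0, 1.0]})
    with pytest.raises(ValueError, match="constant"):
        sl.cox_fit(df, ["x"])
    df2 = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [1.0, 0.0]})
    with pytest.raises(ValueError, match="event"):
        sl.cox_fit(df2, ["x"])


def test_cox_flags_complete_separation():
    # risk group dies first, all of it, before any other death: monotone likelihood
    df = pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
            "event": [1, 1, 1, 1, 1, 1],
            "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        }
    )
    fit = sl.cox_fit(df, ["x"])
    assert not fit.converged


def test_lr_chi2_against_nested_model():
    rng = np.random.default_rng(6)
    df = make_survival_frame(rng, n=100, hr=3.0)
    df["z"] = rng.normal(size=100)
    full = sl.cox_fit(df, ["x", "z"], reduced_covariates=["z"])
    fx = sl.cox_fit(df, ["x", "z"])
    fz = sl.cox_fit(df, ["z"])
    assert full.lr_chi2 == pytest.approx(2 * (fx.log_likelihood - fz.log_likelihood), abs=1e-8)
    assert full.lr_df == 1


# ---------------------------------------------------------------------------
# screen mechanics


def _cohort(rng, n=60, risk=None):
    patients = [f"P{i}" for i in range(n)]
    if risk is None:
        risk = rng.random(n) < 0.3
    calls = pd.DataFrame(
        {
            "A": np.where(risk, UNDER, OVER),
            "B": np.where(risk, UNDER, rng.choice([OVER, UNDER], size=n)),
        },
        index=pd.Index(patients, name="patient_id"),
    )
    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "time": rng.exponential(40, n),
            "event": (rng.random(n) < 0.7).astype(int),
            "stage": rng.choice(["I", "II", "III", "IV"], n),
        }
    )
    return calls, clinical


def test_screen_skips_small_subsets():
    rng = np.random.default_rng(7)
    risk = np.zeros(60, dtype=bool)
    risk[:3] = True  # 3 patients in the risk group < min_subset 5
    calls, clinical = _cohort(rng, 60, risk)
    marker = sl.MarkerDefinition(("A", "B"), ("↓", "↓"))
    res = sl.screen_markers([marker], calls, clinical)[0]
    assert res.status == "skipped_small_subset"
    assert res.univariate is None


def test_screen_empty_risk_group_never_crashes():
    rng = np.random.default_rng(8)
    calls, clinical = _cohort(rng, 40, np.zeros(40, dtype=bool))
    marker = sl.MarkerDefinition(("A", "B"), ("↓", "↓"))
    res = sl.screen_markers([marker], calls, clinical)[0]
    assert res.status == "skipped_small_subset"
    assert res.n_risk == 0


def test_screen_sorts_tested_by_univariate_p():
    rng = np.random.default_rng(9)
    calls, clinical = _cohort(rng, 120)
    markers = [
        sl.MarkerDefinition(("A",), ("↓",)),
        sl.MarkerDefinition(("A", "B"), ("↓", "↓")),
        sl.MarkerDefinition(("B",), ("↑",)),
    ]
    results = sl.screen_markers(markers, calls, clinical)
    ps = [r.univariate.p("marker") for r in results if r.status == "tested"]
    assert ps == sorted(ps)


def test_administrative_censoring_never_adds_events():
    rng = np.random.default_rng(10)
    df = make_survival_frame(rng, n=200, censor=0.0)
    out = administrative_censor(df, 120.0)
    assert out["event"].sum() <= df["event"].sum()
    assert (out["time"] <= 120.0).all()
    late = df["time"] > 120.0
    assert (out.loc[late, "event"] == 0).all()


def test_stage_adjustment_matches_univariate_when_independent():
    rng = np.random.default_rng(11)
    diffs = []
    for _ in range(30):
        df = make_survival_frame(rng, n=200, hr=2.0)
        df["stage_late"] = (rng.random(200) < 0.4).astype(float)  # independent of x and outcome
        uni = sl.cox_fit(df, ["x"])
        adj = sl.cox_fit(df, ["x", "stage_late"])
        diffs.append(np.log(adj.hr("x")) - np.log(uni.hr("x")))
    assert abs(np.mean(diffs)) < 0.05


def test_encode_stage():
    s = pd.Series(["I", "II", "III", "IV", None])
    out = encode_stage(s)
    assert list(out[:4]) == [0.0, 0.0, 1.0, 1.0]
    assert np.isnan(out.iloc[4])
    with pytest.raises(ValueError):
        encode_stage(pd.Series(["V"]))


# ---------------------------------------------------------------------------
# stepwise AIC


def _stepwise_frame(rng, n=100, null_candidates=("c1",)):
    df = make_survival_frame(rng, n=n, hr=2.5)
    df["stage_late"] = (rng.random(n) < 0.4).astype(float)
    for c in null_candidates:
        df[c] = (rng.random(n) < 0.5).astype(float)
    return df


def test_stepwise_no_candidates_returns_base():
    rng = np.random.default_rng(12)
    df = _stepwise_frame(rng)
    fit, trace = sl.stepwise_aic(df, ["x", "stage_late"], [])
    assert set(fit.params.index) == {"x", "stage_late"}


def test_stepwise_duplicate_candidate_enters_at_most_once():
    rng = np.random.default_rng(13)
    df = make_survival_frame(rng, n=120, hr=2.0)
    strong = (rng.random(120) < 0.5).astype(float)
    df["time"] *= np.exp(-0.8 * strong)  # make the candidate genuinely prognostic
    df["c_dup1"] = strong
    df["c_dup2"] = strong
    fit, _ = sl.stepwise_aic(df, ["x"], ["c_dup1", "c_dup2"])
    entered = [c for c in ("c_dup1", "c_dup2") if c in fit.params.index]
    assert len(entered) == 1


def test_stepwise_null_candidates_rarely_enter():
    """A candidate independent of outcome enters only when its chance LR χ²
    exceeds 2 (the AIC entry bar), i.e. with probability ≈ P(χ²₁ > 2) ≈ 0.16;
    the base model should therefore survive most replicates."""
    rng = np.random.default_rng(14)
    kept = 0
    n_rep = 40
    for _ in range(n_rep):
        df = _stepwise_frame(rng, n=80)
        fit, _ = sl.stepwise_aic(df, ["x", "stage_late"], ["c1"])
        kept += set(fit.params.index) == {"x", "stage_late"}
    assert kept / n_rep >= 0.65


# ---------------------------------------------------------------------------
# combinations


def test_combine_and_with_complement():
    patients = [f"P{i}" for i in range(4)]
    calls = pd.DataFrame(
        {
            "A": [UNDER, OVER, UNDER, OVER],
            "B": [UNDER, UNDER, UNDER, OVER],
            "C": [OVER, OVER, UNDER, UNDER],
            "D": [OVER, OVER, UNDER, UNDER],
        },
        index=pd.Index(patients, name="patient_id"),
    )
    ma = sl.MarkerDefinition(("A", "B"), ("↓", "↓"))  # membership 1,0,1,0
    mb = sl.MarkerDefinition(("C", "D"), ("↑", "↑"), orientation="protective")  # 1,1,0,0
    clinical = pd.DataFrame(
        {"patient_id": patients, "time": [5.0, 6.0, 7.0, 8.0], "event": [1, 1, 1, 0],
         "stage": ["I", "II", "III", "IV"]}
    )
    res = sl.combine_markers(ma, mb, calls, clinical, min_subset=1)
    # complement of mb is (0,0,1,1); AND with (1,0,1,0) -> (0,0,1,0)
    assert res.n_risk == 1

    res_asis = sl.combine_markers(ma, mb, calls, clinical, min_subset=1, combine_protective="as-is")
    # as-is: (1,1,0,0) AND (1,0,1,0) -> (1,0,0,0)
    assert res_asis.n_risk == 1
    assert res_asis.status in ("tested", "not_converged", "skipped_small_subset")


def test_combine_marker_with_itself_is_idempotent():
    rng = np.random.default_rng(15)
    calls, clinical = _cohort(rng, 80)
    m = sl.MarkerDefinition(("A", "B"), ("↓", "↓"))
    alone = sl.screen_markers([m], calls, clinical)[0]
    joint = sl.combine_markers(m, m, calls, clinical)
    assert joint.n_risk == alone.n_risk
    if alone.status == "tested" and joint.status == "tested":
        assert joint.univariate.hr("marker") == pytest.approx(alone.univariate.hr("marker"))


def test_combine_skips_tiny_joint_subset():
    rng = np.random.default_rng(16)
    calls, clinical = _cohort(rng, 40, np.zeros(40, dtype=bool))
    ma = sl.MarkerDefinition(("A", "B"), ("↓", "↓"))
    mb = sl.MarkerDefinition(("B",), ("↓",))
    res = sl.combine_markers(ma, mb, calls, clinical)
    assert res.status == "skipped_small_subset"


def test_planted_interaction_joint_hr_exceeds_singles():
    """When only the joint subset carries excess hazard, the combined
    indicator's HR should beat both single-marker HRs in most replicates."""
    rng = np.random.default_rng(17)
    wins = 0
    n_rep = 40
    for _ in range(n_rep):
        n = 160
        a = rng.random(n) < 0.5
        b = rng.random(n) < 0.5
        joint = a & b
        t = rng.exponential(1.0 / (0.02 * np.exp(np.log(5.0) * joint)))
        clinical = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "time": np.maximum(t, 1e-3),
                "event": np.ones(n, dtype=int),
                "stage": rng.choice(["I", "II", "III", "IV"], n),
            }
        )
        calls = pd.DataFrame(
            {"A": np.where(a, UNDER, OVER), "B": np.where(b, UNDER, OVER)},
            index=pd.Index(clinical["patient_id"], name="patient_id"),
        )
        ma = sl.MarkerDefinition(("A",), ("↓",))
        mb = sl.MarkerDefinition(("B",), ("↓",))
        res = sl.combine_markers(ma, mb, calls, clinical)
        singles = sl.screen_markers([ma, mb], calls, clinical, adjust=None)
        hrs = [r.univariate.hr("marker") for r in singles if r.status == "tested"]
        if res.status == "tested" and len(hrs) == 2:
            wins += res.univariate.hr("marker") > max(hrs)
    assert wins / n_rep >= 0.8
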