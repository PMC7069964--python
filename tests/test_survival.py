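"""Five-year labels, KM product-limit oracle, log-rank, and the Breslow
Cox solver against closed-form, grid-search and lifelines references."""
import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from prognet import survival as surv


def _surv_df(times, events):
    return pd.DataFrame({"time_months": times, "event": events},
                        index=[f"s{i}" for i in range(len(times))])


@pytest.mark.parametrize("time, event, dead, usable", [
    (72.0, 1, False, True),   # death after 5 years counts as alive
    (30.0, 1, True, True),
    (40.0, 0, False, False),  # censored early: unlabeled
    (61.0, 0, False, True),
])
def test_five_year_label_rules(time, event, dead, usable):
    lab = surv.five_year_label(_surv_df([time], [event]))
    assert lab.dead[0] == dead
    assert lab.usable[0] == usable


def test_negative_time_errors():
    with pytest.raises(ValueError):
        surv.five_year_label(_surv_df([-1.0], [1]))


def km_oracle(times, events):
    """Hand product-limit estimator (events before censorings at ties)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1.0 - d / n_at_risk
        out.append((t, s, n_at_risk, d))
    return out


def test_km_toy_curve():
    km = surv.km_estimate([2, 4, 5, 7], [1, 1, 0, 1])
    assert km.times.tolist() == [2, 4, 7]
    assert km.survival == pytest.approx([0.75, 0.50, 0.0])
    assert km.at_risk.tolist() == [4, 3, 1]


def test_km_no_events_is_flat():
    km = surv.km_estimate([5, 10, 20], [0, 0, 0])
    assert km.times.size == 0


def test_km_equals_empirical_survivor_without_censoring():
    times = [3.0, 8.0, 15.0, 30.0]
    km = surv.km_estimate(times, [1, 1, 1, 1])
    assert km.survival == pytest.approx([0.75, 0.5, 0.25, 0.0])


def test_km_matches_hand_oracle_with_ties(rng):
    for _ in range(25):
        n = int(rng.integers(3, 20))
        times = rng.integers(1, 8, n).astype(float)  # forces ties
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            continue
        km = surv.km_estimate(times, events, truncate_months=100)
        oracle = km_oracle(times, events)
        assert km.times.tolist() == [t for t, *_ in oracle]
        assert km.survival == pytest.approx([s for _, s, *_ in oracle])
        assert km.at_risk.tolist() == [n for *_, n, _ in oracle]


def test_km_truncation_at_horizon():
    km = surv.km_estimate([10, 50, 70, 90], [1, 1, 1, 1])
    assert km.times.max() <= 60.0


def test_logrank_identical_groups_null():
    t = [2.0, 5.0, 9.0]
    e = [1, 1, 0]
    res = surv.logrank(t, e, t, e)
    assert res.statistic == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0)
    with pytest.raises(ValueError):
        surv.logrank([], [], t, e)


def test_logrank_detects_strong_separation(rng):
    n = 300
    ta = rng.exponential(10.0, n)
    tb = rng.exponential(30.0, n)
    res = surv.logrank(ta, np.ones(n), tb, np.ones(n))
    assert res.p_value < 1e-6


# --- Cox ----------------------------------------------------------------

def grid_search_log_hr(x, times, events, lo=-3, hi=3, steps=20001):
    """Independent oracle: dense grid on the Breslow partial likelihood."""
    terms = surv._breslow_score_terms(np.asarray(x, int),
                                      np.asarray(times, float),
                                      np.asarray(events, int))
    s_total = sum(s for _, s, _, _ in terms)
    betas = np.linspace(lo, hi, steps)
    ll = np.zeros_like(betas)
    for d, _s, n1, n0 in terms:
        ll -= d * np.log(n1 * np.exp(betas) + n0)
    ll += s_total * betas
    return float(betas[np.argmax(ll)])


def test_cox_toy_closed_form_root():
    # A = {1, 3} events coded 1; B = {2, 4} events coded 0:
    # score equation reduces to u^2 - u - 4 = 0, u = e^beta
    res = surv.cox_univariate([1, 1, 0, 0], [1, 3, 2, 4], [1, 1, 1, 1])
    expected = (1 + np.sqrt(17)) / 2
    assert res.hr == pytest.approx(expected, abs=1e-6)
    assert res.ci_low < res.hr < res.ci_high
    grid = grid_search_log_hr([1, 1, 0, 0], [1, 3, 2, 4], [1, 1, 1, 1])
    assert res.log_hr == pytest.approx(grid, abs=1e-3)


def test_cox_identical_groups_unit_hr():
    t = [1.0, 2.0, 3.0, 4.0] * 2
    e = [1, 1, 1, 0] * 2
    x = [1, 1, 1, 1, 0, 0, 0, 0]
    res = surv.cox_univariate(x, t, e)
    assert res.hr == pytest.approx(1.0, abs=1e-6)


def test_cox_agrees_with_grid_oracle_and_lifelines(rng):
    n = 120
    x = rng.integers(0, 2, n)
    times = rng.exponential(20.0 / (1.0 + x), n)  # true HR 2 for x=1
    events = (rng.random(n) > 0.2).astype(int)
    res = surv.cox_univariate(x, times, events)
    assert res.log_hr == pytest.approx(
        grid_search_log_hr(x, times, events), abs=1e-3)
    df = pd.DataFrame({"x": x, "t": times, "e": events})
    lifelines_beta = float(CoxPHFitter().fit(df, "t", "e").params_["x"])
    # continuous times -> no ties -> Breslow == Efron
    assert res.log_hr == pytest.approx(lifelines_beta, abs=1e-5)


def test_cox_monotone_likelihood_flagged():
    res = surv.cox_univariate([1, 1, 0, 0], [1, 2, 10, 12], [1, 1, 0, 0])
    assert res.monotone
    assert np.isinf(res.hr) or res.hr == 0.0


def test_cox_input_validation():
    with pytest.raises(ValueError):
        surv.cox_univariate([0, 1, 2], [1, 2, 3], [1, 1, 1])
    with pytest.raises(ValueError):
        surv.cox_univariate([0, 1], [1.0, 2.0], [0, 0])


# --- risk-group stratification -------------------------------------------

def test_risk_group_survival_on_planted_signal(small_bundle):
    g = small_bundle.truth.planted_prognostic_genes[0]
    v = small_bundle.expression.loc[g]
    scores = (v - v.min()) / (v.max() - v.min())
    rg = surv.risk_group_survival(scores.to_numpy(), 0.5,
                                  small_bundle.survival)
    assert not rg.degenerate
    assert rg.cox.hr > 1.0
    assert rg.logrank.p_value < 0.01
    assert rg.n_high + rg.n_low == len(small_bundle.sample_ids)


def test_risk_group_degenerate_warns(small_bundle):
    scores = np.zeros(len(small_bundle.sample_ids))
    with pytest.warns(UserWarning, match="degenerate"):
        rg = surv.risk_group_survival(scores, 0.5, small_bundle.survival)
    assert rg.degenerate


def test_risk_group_alignment_checked(small_bundle):
    with pytest.raises(ValueError):
        surv.risk_group_survival(np.zeros(3), 0.5, small_bundle.survival)
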