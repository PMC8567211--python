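import numpy as np
import pandas as pd
import pytest

from hehrisk import _coxfast
from hehrisk.survival import concordance, cox_fit, km_fit, logrank, rate_at


def test_km_product_limit_hand_example():
    curve = km_fit([1, 2, 3], [1, 0, 1])
    s = dict(zip(curve.event_times, curve.survival))
    assert s[1.0] == pytest.approx(2 / 3)
    assert s[3.0] == pytest.approx(0.0)


def test_km_all_censored_is_flat_one():
    curve = km_fit([1, 2, 3], [0, 0, 0])
    assert np.allclose(curve.survival, 1.0)


def test_km_no_censoring_equals_empirical_survival():
    rng = np.random.default_rng(0)
    t = rng.exponential(5, 200)
    curve = km_fit(t, np.ones_like(t))
    for ti, si in zip(curve.event_times[1:], curve.survival[1:]):
        assert si == pytest.approx((t > ti).mean(), abs=1e-12)


def test_km_input_validation():
    with pytest.raises(ValueError):
        km_fit([1, 2], [1])
    with pytest.raises(ValueError):
        km_fit([], [])


def test_rate_at_failure_complement_and_carry_forward():
    curve = km_fit([1, 2, 3, 4], [1, 0, 1, 0])
    s, _ = rate_at(curve, 3.5)
    f, _ = rate_at(curve, 3.5, as_failure=True)
    assert f == pytest.approx(1 - s)
    with pytest.warns(UserWarning):
        s_beyond, _ = rate_at(curve, 100)
    assert s_beyond == pytest.approx(curve.survival[-1])
    with pytest.warns(UserWarning):
        s_before, _ = rate_at(curve, 0.5)
    assert s_before == 1.0


def test_logrank_identical_groups_and_relabel_invariance():
    t = np.arange(1, 21, dtype=float)
    e = np.tile([1, 0], 10)
    chi2, p = logrank([(t, e), (t, e)])
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)
    g1 = (t[:10], e[:10])
    g2 = (t[10:], e[10:])
    assert logrank([g1, g2])[0] == pytest.approx(logrank([g2, g1])[0])


def test_logrank_single_event_hand_computation():
    # one event at t=1 with both groups at risk: O-E = 0.5, Var = 0.25
    chi2, _ = logrank([([1.0], [1]), ([2.0], [0])])
    assert chi2 == pytest.approx(1.0)


def test_logrank_empty_group_errors():
    with pytest.raises(ValueError):
        logrank([([1.0], [1]), ([], [])])


def _grid_partial_likelihood_beta(times, events, x):
    """Brute-force oracle: maximise the (untied) Cox partial likelihood
    over a fine beta grid."""
    order = np.argsort(times)
    t, e, xv = np.asarray(times)[order], np.asarray(events)[order], np.asarray(x)[order]

    def loglik(b):
        eta = b * xv
        ll = 0.0
        for i in np.flatnonzero(e):
            ll += eta[i] - np.log(np.exp(eta[t >= t[i]]).sum())
        return ll

    grid = np.arange(-4, 4, 1e-4)
    return grid[np.argmax([loglik(b) for b in grid])]


def test_cox_fit_matches_grid_oracle_on_toy_data():
    times = [1, 2, 3, 4, 5, 6]
    events = [1, 1, 1, 1, 1, 1]
    x = [1, 1, 0, 1, 0, 0]
    res = cox_fit(times, events, pd.DataFrame({"x": x}))["x"]
    beta_grid = _grid_partial_likelihood_beta(times, events, x)
    assert res.coef == pytest.approx(beta_grid, abs=1e-4)
    assert res.hr > 0 and res.ci95[0] <= res.hr <= res.ci95[1]


def test_cox_constant_covariate_errors():
    with pytest.raises(ValueError, match="constant"):
        cox_fit([1, 2, 3], [1, 1, 0], pd.DataFrame({"x": [1, 1, 1]}))


def test_cox_parameter_recovery_binary_hr():
    rng = np.random.default_rng(3)
    n = 2000
    x = rng.binomial(1, 0.5, n)
    lam = 0.05 * np.exp(np.log(2.5) * x)
    t_true = rng.exponential(1 / lam)
    c = rng.uniform(5, 15, n)
    t = np.minimum(t_true, c)
    e = (t_true <= c).astype(int)
    res = cox_fit(t, e, pd.DataFrame({"x": x}))["x"]
    assert res.ci95[0] <= 2.5 <= res.ci95[1]
    assert res.hr == pytest.approx(2.5, rel=0.15)


def test_fast_cox_agrees_with_lifelines_including_ties():
    rng = np.random.default_rng(1)
    n = 400
    X = np.column_stack([rng.binomial(1, 0.4, n), rng.normal(size=n)])
    lam = 0.1 * np.exp(X @ np.array([0.7, -0.3]))
    t = np.ceil(rng.exponential(1 / lam))  # yearly resolution -> many ties
    c = rng.uniform(5, 20, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    fit = _coxfast.fit(X, time, event)
    df = pd.DataFrame(X, columns=["a", "b"])
    res = cox_fit(time, event, df)
    assert fit.beta[0] == pytest.approx(res["a"].coef, abs=1e-5)
    assert fit.beta[1] == pytest.approx(res["b"].coef, abs=1e-5)
    assert fit.loglik == pytest.approx(res["a"].log_partial_likelihood, abs=1e-6)


def test_fast_cox_null_loglik_matches_beta_zero():
    rng = np.random.default_rng(2)
    t = rng.exponential(5, 100)
    e = rng.binomial(1, 0.7, 100)
    x = rng.normal(size=(100, 1))
    ll0 = _coxfast.null_loglik(t, e)
    llb, _, _ = _coxfast._loglik_grad_hess(*_coxfast._prepare(x, t, e), np.zeros(1))
    assert ll0 == pytest.approx(llb)


def _concordance_bruteforce(risk, times, events):
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if events[i] and (times[i] < times[j]):
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def test_concordance_perfect_random_and_bruteforce():
    t = np.array([5.0, 3.0, 9.0, 1.0, 7.0])
    e = np.array([1, 1, 0, 1, 1])
    risk = -t  # perfectly anti-ordered with survival time
    assert concordance(risk, t, e) == pytest.approx(1.0)

    risk2 = np.array([0.3, 0.9, 0.1, 0.5, 0.4])
    assert concordance(risk2, t, e) == pytest.approx(
        _concordance_bruteforce(risk2, t, e)
    )

    rng = np.random.default_rng(0)
    n = 4000
    tt = rng.exponential(5, n)
    assert concordance(rng.normal(size=n), tt, np.ones(n)) == pytest.approx(0.5, abs=0.02)


def test_concordance_antisymmetry_and_errors():
    rng = np.random.default_rng(5)
    t = rng.exponential(3, 50)
    e = rng.binomial(1, 0.8, 50)
    risk = rng.normal(size=50)
    assert concordance(-risk, t, e) == pytest.approx(1 - concordance(risk, t, e))
    with pytest.raises(ValueError):
        concordance(risk, t, np.zeros(50))
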