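"""Landmark construction and the three calibration fits, against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize, minimize_scalar

from revivalpred import (
    Cohort,
    CohortConfig,
    build_landmark,
    calibration_table,
    cox_calibration,
    exp_calibration,
    generate_cohort,
    km_marginal,
    km_simple_calibration,
    reports_frame,
    simple_calibration,
    standard_prediction_engine,
)

from conftest import make_subject


def _cohort_of(entries):
    subs = [
        make_subject(sid=f"C{i}", observed_time=t, event=e, times=(), values=())
        for i, (t, e) in enumerate(entries)
    ]
    return Cohort(subjects=subs, config=CohortConfig(n_subjects=len(entries)))


def test_build_landmark_exposure_and_events():
    cohort = _cohort_of([(3.0, True), (10.0, True), (2.5, False), (1.0, True)])
    preds = {s.id: 0.3 for s in cohort}
    rows = build_landmark(cohort, preds, t_lm=2.0, t_hor=4.0)
    assert len(rows) == 3  # the t=1 death is not at risk
    by_id = rows.set_index("id")
    assert by_id.loc["C0", "exposure"] == pytest.approx(1.0)
    assert bool(by_id.loc["C0", "event"])
    assert by_id.loc["C1", "exposure"] == pytest.approx(2.0)  # administrative
    assert not bool(by_id.loc["C1", "event"])
    assert by_id.loc["C2", "exposure"] == pytest.approx(0.5)
    assert not bool(by_id.loc["C2", "event"])
    with pytest.raises(KeyError):
        build_landmark(cohort, {}, 2.0, 4.0)


def _rows(h, exposure, event):
    return pd.DataFrame({"id": range(len(h)), "H_pred": h,
                         "exposure": exposure, "event": event})


def test_simple_calibration_hand_value():
    """10 deaths over 30.49 exposure years at reference rate 0.164 -> c = 2."""
    rows = _rows([0.3] * 12, [30.49 / 12] * 12, [True] * 10 + [False] * 2)
    c, se = simple_calibration(rows, 0.164)
    assert c == pytest.approx(10 / (0.164 * 30.49), abs=1e-12)
    assert c == pytest.approx(2.00, abs=0.01)
    assert se == pytest.approx(c / np.sqrt(10))
    assert se == pytest.approx(0.632, abs=0.01)


def test_simple_calibration_properties():
    rows = _rows([0.3] * 5, [2.0] * 5, [True, False, False, False, False])
    # deaths exactly lambda_ref * exposure -> c = 1
    c, _ = simple_calibration(rows, 1.0 / 10.0)
    assert c == pytest.approx(1.0)
    doubled = rows.assign(exposure=rows["exposure"] * 2)
    c2, _ = simple_calibration(doubled, 1.0 / 10.0)
    assert c2 == pytest.approx(c / 2)
    none = rows.assign(event=False)
    c0, se0 = simple_calibration(none, 0.164)
    assert c0 == 0.0 and np.isinf(se0)


def test_simple_calibration_is_the_mle():
    """Matches brute-force maximization of the exponential likelihood in c."""
    rng = np.random.default_rng(0)
    rows = _rows(
        rng.uniform(0.1, 1, 30), rng.uniform(0.2, 2, 30), rng.random(30) < 0.4
    )
    lam = 0.164
    d = rows["event"].sum()
    E = rows["exposure"].sum()

    def nll(c):
        return -(d * np.log(c * lam) - c * lam * E)

    res = minimize_scalar(nll, bounds=(1e-4, 50), method="bounded")
    c, _ = simple_calibration(rows, lam)
    assert c == pytest.approx(res.x, abs=1e-4)


def test_exp_calibration_two_group_closed_form():
    """Rates 0.1 and 0.2 at H=0.2 and 0.4 give beta=1, alpha=ln(0.5)."""
    h = [0.2] * 20 + [0.4] * 40
    expo = [1.0] * 60
    ev = [True] * 2 + [False] * 18 + [True] * 8 + [False] * 32
    a, a_se, b, b_se, z = exp_calibration(_rows(h, expo, ev))
    assert b == pytest.approx(1.0, abs=1e-6)
    assert a == pytest.approx(np.log(0.5), abs=1e-6)
    assert a == pytest.approx(-0.693, abs=1e-3)
    assert a_se > 0 and b_se > 0
    assert z == pytest.approx(b / b_se)


def test_exp_calibration_rate_scale_equivariance():
    rng = np.random.default_rng(1)
    rows = _rows(
        rng.uniform(0.1, 1, 80), rng.uniform(0.2, 2, 80), rng.random(80) < 0.4
    )
    a1, _, b1, _, _ = exp_calibration(rows)
    k = 3.0  # scaling every rate by k == dividing exposures by k
    a2, _, b2, _, _ = exp_calibration(rows.assign(exposure=rows["exposure"] / k))
    assert b2 == pytest.approx(b1, abs=1e-8)
    assert a2 == pytest.approx(a1 + np.log(k), abs=1e-8)


def test_exp_calibration_matches_brute_force_oracle():
    """Direct 2-D maximization of the censored-exponential likelihood."""
    h = np.array([0.15] * 10 + [0.35] * 10 + [0.6] * 10)
    rng = np.random.default_rng(2)
    expo = rng.uniform(0.3, 2.0, 30)
    ev = np.array([True] * 3 + [False] * 7 + [True] * 5 + [False] * 5
                  + [True] * 6 + [False] * 4)
    rows = _rows(h, expo, ev)

    def nll(theta):
        a, b = theta
        lograte = a + b * np.log(h)
        return -np.sum(ev * lograte - expo * np.exp(lograte))

    res = minimize(nll, [0.0, 1.0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12})
    a, _, b, _, _ = exp_calibration(rows)
    assert a == pytest.approx(res.x[0], abs=1e-6)
    assert b == pytest.approx(res.x[1], abs=1e-6)


def test_exp_calibration_constant_H_rejected():
    rows = _rows([0.3] * 10, [1.0] * 10, [True] * 3 + [False] * 7)
    with pytest.raises(ValueError, match="constant|identifiable"):
        exp_calibration(rows)
    with pytest.raises(ValueError, match="identifiable"):
        cox_calibration(rows)


def test_cox_calibration_matches_partial_likelihood_oracle():
    """4-row instance vs brute-force maximization of the partial likelihood."""
    rows = _rows([0.2, 0.5, 0.8, 1.2], [1.0, 2.0, 1.5, 0.7],
                 [True, False, True, True])
    x = np.log(rows["H_pred"].to_numpy())
    t = rows["exposure"].to_numpy()
    d = rows["event"].to_numpy()

    def neg_pl(beta):
        ll = 0.0
        for i in np.where(d)[0]:
            risk = t >= t[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    res = minimize_scalar(neg_pl, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    beta, se, z = cox_calibration(rows)
    assert beta == pytest.approx(res.x, abs=1e-6)
    assert se > 0 and z == pytest.approx(beta / se)


def test_perfect_calibration_reference_under_constant_hazards():
    """With heterogeneous constant window hazards and H = rate * window,
    the fit converges to the perfect-calibration reference (1, ln 0.5)."""
    rng = np.random.default_rng(5400)
    n = 100_000
    lam = 0.164 * np.exp(rng.normal(0, 0.4, n))
    T = rng.exponential(1 / lam)
    rows = _rows(2 * lam, np.minimum(T, 2.0), T <= 2.0)
    a, _, b, _, _ = exp_calibration(rows)
    assert b == pytest.approx(1.0, abs=0.05)
    assert a == pytest.approx(np.log(0.5), abs=0.05)


def test_exp_and_cox_slopes_agree_on_simulated_landmarks(default_params):
    """The two calibration slopes are near-identical on a large landmark set."""
    cohort = generate_cohort(CohortConfig(n_subjects=600, seed=31))
    engine = standard_prediction_engine(default_params)
    preds = {s.id: engine(s, 2.0, 4.0) for s in cohort.at_risk(2.0)}
    rows = build_landmark(cohort, preds, 2.0, 4.0)
    _, _, b_exp, _, _ = exp_calibration(rows)
    b_cox, _, _ = cox_calibration(rows)
    assert b_cox == pytest.approx(b_exp, abs=0.25)


def test_calibration_table_shape_and_km_reference(small_cohort):
    engine = standard_prediction_engine(small_cohort.config.revival)
    reports = calibration_table(
        small_cohort, engine, [1.0, 2.0, 3.0], 2.0,
        lambda_ref=small_cohort.config.lambda0,
    )
    assert len(reports) == 3
    frame = reports_frame(reports)
    assert (frame["n"] >= frame["deaths"]).all()
    assert (frame["hpred_sd"] > 0).all()
    # KM-referenced simple calibration on the same data sits near 1
    km = km_marginal(small_cohort, 9.0)
    preds = {s.id: engine(s, 2.0, 4.0) for s in small_cohort.at_risk(2.0)}
    rows = build_landmark(small_cohort, preds, 2.0, 4.0)
    c, se = km_simple_calibration(rows, km, 2.0)
    assert c == pytest.approx(1.0, abs=3 * se)


def test_calibration_table_records_failures():
    cohort = _cohort_of([(3.0, True), (4.0, False), (5.0, True)])

    def engine(subject, t_lm, t_hor):
        return 0.3  # constant predictions: slope not identifiable

    reports = calibration_table(cohort, engine, [2.0], 2.0, lambda_ref=0.164)
    assert len(reports) == 1
    assert reports[0].error is not None
    assert np.isnan(reports[0].beta_hat)
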