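"""Cox fits and interaction metrics: oracles, identities, CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

import chcv
from chcv.survival import (
    CoxInteraction, CoxResult, NotReportableError, compute_ap,
    compute_classical_si, compute_mult_ratio, compute_reri, fit_cox,
    interaction_ci, interaction_term, run_interaction_analysis,
)
from tests.conftest import null_interaction_config, truth_analysis_table


# ----------------------------------------------------------------------
# interaction arithmetic
# ----------------------------------------------------------------------
def test_reri_examples():
    # published worked example (time to CV death adjusted HRs)
    assert compute_reri(1.090, 1.073, 1.148) == pytest.approx(-0.131, abs=5e-4)
    assert compute_reri(1, 1, 1) == 0
    assert compute_reri(2.0, 1.5, 1.3) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        compute_reri(-1.0, 1.0, 1.0)


def test_ap_examples():
    assert compute_ap(-0.131, 1.090) == pytest.approx(-0.120, abs=5e-4)
    assert compute_ap(0.0, 3.7) == 0
    assert compute_ap(0.2, 2.0) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        compute_ap(0.1, 0.0)


def test_mult_ratio_examples():
    assert compute_mult_ratio(1.090, 1.073, 1.148) == pytest.approx(0.885,
                                                                    abs=5e-4)
    assert compute_mult_ratio(1, 1, 1) == 1


def test_classical_si_examples():
    assert compute_classical_si(1, 1, 1) is None  # 0/0
    assert compute_classical_si(3, 2, 2) == pytest.approx(1.0)
    assert compute_classical_si(2.0, 1.5, 1.3) == pytest.approx(1.25)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(h11=st.floats(0.1, 5), h10=st.floats(0.1, 5), h01=st.floats(0.1, 5))
def test_metric_identities(h11, h10, h01):
    reri = compute_reri(h11, h10, h01)
    assert reri == h11 - h10 - h01 + 1.0
    assert compute_ap(reri, h11) == reri / h11
    assert compute_mult_ratio(h11, h10, h01) == h11 / (h10 * h01)
    si = compute_classical_si(h11, h10, h01)
    denom = (h10 - 1) + (h01 - 1)
    if denom != 0:
        assert si == (h11 - 1) / denom


# ----------------------------------------------------------------------
# Cox oracle equivalence
# ----------------------------------------------------------------------
TINY = pd.DataFrame({
    "time_any_death": [1.2, 2.5, 3.1, 4.0, 4.6, 5.9, 7.3, 8.8],
    "event_any_death": [1, 1, 0, 1, 1, 0, 1, 0],
    "x1": [1, 0, 1, 0, 1, 0, 0, 1],
    "x2": [0.5, -0.2, 0.1, 0.9, -1.1, 0.3, 0.0, 0.7],
})


def _neg_partial_loglik(beta, df):
    t = df["time_any_death"].to_numpy()
    d = df["event_any_death"].to_numpy()
    X = df[["x1", "x2"]].to_numpy()
    eta = X @ beta
    ll = 0.0
    for i in np.where(d == 1)[0]:
        risk = t >= t[i]
        ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return -ll


def test_cox_matches_partial_likelihood_oracle():
    res = fit_cox(TINY, "any_death", exposure=["x1", "x2"], covariates=None,
                  min_events=1)
    opt = minimize(_neg_partial_loglik, np.zeros(2), args=(TINY,),
                   method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14,
                            "maxiter": 20_000})
    assert np.allclose(res.beta, opt.x, atol=1e-6)


def test_cox_null_exposure_covers_one():
    covered = 0
    reps = 30
    for r in range(reps):
        rng = np.random.default_rng(2000 + r)
        n = 1500
        x = rng.binomial(1, 0.3, n)
        t = rng.exponential(10, n)
        df = pd.DataFrame({"time_any_death": np.minimum(t, 8.0),
                           "event_any_death": (t <= 8.0).astype(int),
                           "x1": x})
        res = fit_cox(df, "any_death", exposure=["x1"], covariates=None)
        row = res.summary.iloc[0]
        covered += row["ci_low"] <= 1.0 <= row["ci_high"]
    assert covered / reps >= 0.85


def test_mult_ratio_equals_exp_interaction_coefficient(small_table):
    # exact reparameterization: h11/(h10*h01) == exp(b11 - b10 - b01)
    res = fit_cox(small_table, "incident_cvd", exposure="ch4",
                  covariates=["age_baseline", "sex"])
    h11, h10, h01 = np.exp([res.beta_of(t) for t in res.exposure_terms])
    ratio = compute_mult_ratio(h11, h10, h01)
    term = interaction_term(res)
    assert ratio == pytest.approx(term["hr"], rel=1e-10)


def test_zero_event_category_not_reportable(small_table):
    broken = small_table.copy()
    cell = broken["exposure4"] == "both"
    broken.loc[cell, "event_cv_death"] = 0
    with pytest.raises(NotReportableError, match="ch_both"):
        fit_cox(broken, "cv_death", exposure="ch4",
                covariates=["age_baseline"])
    report = run_interaction_analysis(broken, ["cv_death"],
                                      covariates=["age_baseline"])
    entry = report["endpoints"]["cv_death"]
    assert entry["not_reportable"] and "ch_both" in entry["reason"]


def test_too_few_events_rejected():
    df = TINY.copy()
    with pytest.raises(ValueError, match="events"):
        fit_cox(df, "any_death", exposure=["x1"], covariates=None,
                min_events=50)


# ----------------------------------------------------------------------
# interaction CIs
# ----------------------------------------------------------------------
def _null_cox():
    terms = ["ch_both", "ch_chip_only", "ch_mca_only"]
    beta = np.zeros(3)
    vcov = np.diag([0.04, 0.01, 0.01])
    summary = pd.DataFrame({"term": terms, "beta": beta,
                            "se": np.sqrt(np.diag(vcov)),
                            "hr": np.exp(beta)})
    return CoxResult(terms=terms, beta=beta, vcov=vcov, summary=summary,
                     n=100, n_events=50, exposure_terms=terms)


def test_delta_reri_ci_symmetric_at_null():
    lo, hi = interaction_ci(_null_cox(), "reri")
    assert lo == pytest.approx(-hi)
    assert lo < 0 < hi


def test_delta_mult_ratio_ci_contains_point():
    cox = _null_cox()
    lo, hi = interaction_ci(cox, "mult_ratio")
    assert lo < 1.0 < hi


def test_bootstrap_and_delta_agree_on_well_powered_cohort():
    cfg = null_interaction_config(77, n=6000, endpoint_rate=0.05)
    b = chcv.generate_cohort(cfg)
    table = truth_analysis_table(b)

    def refit(sample):
        return fit_cox(sample, "any_death", exposure="ch4",
                       covariates=["age_baseline"])

    cox = refit(table)
    d_lo, d_hi = interaction_ci(cox, "reri", method="delta")
    b_lo, b_hi = interaction_ci(cox, "reri", method="bootstrap", data=table,
                                refit=refit, n_boot=200, seed=3)
    assert (d_hi - d_lo) == pytest.approx(b_hi - b_lo, rel=0.15)
    assert d_lo < 0 < d_hi and b_lo < 0 < b_hi


def test_interaction_estimator_sex_restriction(small_table):
    model = CoxInteraction(endpoint="incident_cvd", pair="chip_x_loy",
                           covariates=["age_baseline", "sex"]).fit(small_table)
    assert model.n_input_ == (small_table["sex"] == "M").sum()
    assert "sex_M" not in model.cox_.terms
    m = model.metrics_
    assert m.reri == pytest.approx(m.h11 - m.h10 - m.h01 + 1)
    assert "reri" in m.ci


def test_report_structure(small_table):
    report = run_interaction_analysis(small_table, ["incident_cvd"],
                                      covariates=["age_baseline", "sex"])
    entry = report["endpoints"]["incident_cvd"]
    assert not entry["not_reportable"]
    assert set(entry["hr"]) == {"ch_both", "chip_only", "any_mca_only"}
    assert entry["metrics"]["mult_ratio"] == pytest.approx(
        entry["interaction_term"]["hr"], rel=1e-10)
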