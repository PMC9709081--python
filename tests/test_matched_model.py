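"""Conditional-logit likelihood, fitting, and curve extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stillburden import cohort_builder as cb
from stillburden import matched_model as mm
from stillburden import synthetic_data as sd
from stillburden.erf import AGE_GROUPS

from conftest import enumerate_conditional_loglik, make_sets, small_config


def test_symmetric_two_member_set_gives_log_half():
    sets = make_sets([(0, True, 10.0), (0, False, 20.0)])
    ll = mm.conditional_loglik(sets, np.zeros(2))
    assert ll == pytest.approx(np.log(0.5), abs=1e-12)


@given(st.floats(min_value=-30, max_value=30))
@settings(deadline=None, max_examples=25)
def test_per_set_constant_shift_leaves_likelihood_unchanged(shift):
    # this invariance is exactly how the mother intercept cancels
    sets = make_sets(
        [(0, True, 1.0), (0, False, 2.0), (0, False, 3.0),
         (1, False, 1.0), (1, True, 5.0)]
    )
    eta = np.array([0.3, -1.2, 0.8, 2.0, -0.5])
    base = mm.conditional_loglik(sets, eta)
    shifted = eta + np.array([shift, shift, shift, 0.0, 0.0])
    assert mm.conditional_loglik(sets, shifted) == pytest.approx(base, abs=1e-9)


def test_likelihood_matches_bruteforce_enumeration_oracle():
    rng = np.random.default_rng(42)
    rows, eta, eta_by_set, case_pos = [], [], [], []
    for s in range(5):
        size = int(rng.integers(2, 7))
        cpos = int(rng.integers(size))
        etas = list(rng.normal(0, 2, size))
        for j in range(size):
            rows.append((s, j == cpos, 30.0 + j))
            eta.append(etas[j])
        eta_by_set.append(etas)
        case_pos.append(cpos)
    ll = mm.conditional_loglik(make_sets(rows), np.array(eta))
    assert ll == pytest.approx(
        enumerate_conditional_loglik(eta_by_set, case_pos), abs=1e-10
    )


def test_likelihood_rejects_bad_sets():
    no_case = make_sets([(0, False, 1.0), (0, False, 2.0)])
    with pytest.raises(ValueError, match="exactly one case"):
        mm.conditional_loglik(no_case, np.zeros(2))
    ok = make_sets([(0, True, 1.0), (0, False, 2.0)])
    with pytest.raises(ValueError, match="non-finite"):
        mm.conditional_loglik(ok, np.array([np.nan, 0.0]))


def test_fit_agrees_with_statsmodels_conditional_logit(stillbirth_sets):
    sm = pytest.importorskip("statsmodels.api")
    from statsmodels.discrete.conditional_models import ConditionalLogit

    spec = mm.ModelSpec(
        age_spline_df=None,
        temperature_spline_df=None,
        month_spline_df=None,
        parity=True,
        nightlight=True,
    )
    model = mm.fit(stillbirth_sets, spec)
    tab = stillbirth_sets.table
    X = tab[["pm25", "multiparous", "nightlight"]].to_numpy(dtype=float)
    ref = ConditionalLogit(
        tab["is_case"].astype(int).to_numpy(), X, groups=tab["set_id"].to_numpy()
    ).fit(disp=False)
    np.testing.assert_allclose(
        model.params.to_numpy(), ref.params, atol=1e-5, rtol=1e-4
    )
    assert model.loglik == pytest.approx(ref.llf, abs=1e-5)
    np.testing.assert_allclose(
        np.sqrt(np.diag(model.cov.to_numpy())), ref.bse, rtol=1e-3
    )


def test_fit_reaches_same_optimum_from_any_start(stillbirth_sets):
    spec = mm.ModelSpec()
    m0 = mm.fit(stillbirth_sets, spec)
    rng = np.random.default_rng(1)
    m1 = mm.fit(
        stillbirth_sets, spec, start=rng.normal(0, 0.05, len(m0.params))
    )
    np.testing.assert_allclose(
        m0.params.to_numpy(), m1.params.to_numpy(), atol=1e-6
    )


def test_or_per_10_inverts_the_coefficient():
    fake = mm.FittedModel(
        params=pd.Series([np.log(1.11) / 10.0], index=["pm25"]),
        cov=pd.DataFrame([[1e-6]], index=["pm25"], columns=["pm25"]),
        loglik=-1.0, n_sets=100, n_members=300, converged=True,
        n_iter=3, grad_norm=0.0, spec=mm.ModelSpec(),
        design=mm.DesignInfo(
            columns=["pm25"], exposure_cols={"linear": [0]},
            exposure_knots=None, exposure_range=(0.0, 100.0),
        ),
    )
    assert mm.or_per_10(fake)["or"] == pytest.approx(1.11)

    fake.params.iloc[0] = 0.010436
    fake.cov.iloc[0, 0] = 0.002128**2
    res = mm.or_per_10(fake)
    assert res["or"] == pytest.approx(1.110, abs=5e-4)
    assert res["ci_lo"] == pytest.approx(1.065, abs=5e-4)
    assert res["ci_hi"] == pytest.approx(1.157, abs=5e-4)

    fake.params.iloc[0] = 0.0
    res = mm.or_per_10(fake)
    assert res["or"] == pytest.approx(1.0)
    assert res["ci_lo"] * res["ci_hi"] == pytest.approx(1.0)  # log-symmetric


def test_or_per_10_requires_linear_term(stillbirth_sets):
    model = mm.fit(stillbirth_sets, mm.ModelSpec(exposure_term="spline_all_ages"))
    with pytest.raises(ValueError, match="linear"):
        mm.or_per_10(model)
    with pytest.raises(ValueError, match="spline"):
        mm.extract_erf(
            mm.fit(stillbirth_sets, mm.ModelSpec()), "all_ages"
        )


def test_nested_exposure_terms_never_lose_likelihood(stillbirth_sets):
    # exact nestings: linear is in every spline span; the all-ages spline
    # is in the span of the age-specific interaction basis
    ll_linear = mm.fit(stillbirth_sets, mm.ModelSpec()).loglik
    for df in (2, 3, 4):
        ll_spline = mm.fit(
            stillbirth_sets,
            mm.ModelSpec(exposure_term="spline_all_ages", spline_df=df),
        ).loglik
        assert ll_spline >= ll_linear - 1e-8
    ll_all = mm.fit(
        stillbirth_sets, mm.ModelSpec(exposure_term="spline_all_ages")
    ).loglik
    ll_age = mm.fit(
        stillbirth_sets, mm.ModelSpec(exposure_term="spline_age_specific")
    ).loglik
    assert ll_age >= ll_all - 1e-8


def test_within_set_constant_covariate_is_dropped():
    # every pregnancy of a mother in the same year -> nightlight (an
    # annual value) is constant within set and inestimable
    rows = []
    rng = np.random.default_rng(0)
    for m in range(60):
        year = 2004 + m % 5
        order = [cb.STILLBIRTH, cb.LIVEBIRTH] if m % 2 else [cb.LIVEBIRTH, cb.STILLBIRTH]
        for j, outcome in enumerate(order):
            rows.append(
                {
                    "mother_id": m,
                    "country_id": 0,
                    "location_id": 0,
                    "conception_year": year,
                    "conception_month": 1 + (m % 3) + 2 * j,
                    "gestation_months": 7 if outcome == cb.STILLBIRTH else 9,
                    "outcome": outcome,
                    "maternal_age_years": 20.0 + rng.uniform(0, 15),
                    "parity": "nulliparous" if j == 0 else "multiparous",
                }
            )
    records = pd.DataFrame(rows)
    months = pd.DataFrame(
        [
            {
                "location_id": 0,
                "year": y,
                "month": mth,
                "pm25": 30 + 10 * np.sin(mth) + y % 3,
                "temperature": 20.0 + mth / 3,
                "nightlight": 5.0 + (y - 2004),
            }
            for y in range(2004, 2011)
            for mth in range(1, 13)
        ]
    )
    sets = cb.build_matched_sets(records, months, cb.STILLBIRTH)
    spec = mm.ModelSpec(age_spline_df=None, temperature_spline_df=None,
                        month_spline_df=None, min_sets=10)
    model = mm.fit(sets, spec)
    assert "nightlight" in model.design.dropped
    assert "nightlight" not in model.params.index


def test_null_effect_z_scores_have_nominal_size():
    truth = 0.0
    n_reject = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = small_config(seed=300 + seed, true_erf=sd.TrueERF(or_per_10=1.0))
        env = sd.simulate_environment(cfg)
        rec = sd.simulate_pregnancy_histories(cfg, env)
        sets = cb.build_matched_sets(rec, env, "stillbirth")
        res = mm.or_per_10(mm.fit(sets, mm.ModelSpec()))
        n_reject += abs((res["beta"] - truth) / res["se"]) > 1.96
    assert n_reject <= 4  # 5% nominal; binomial slack at n=20


def test_spline_curve_anchors_and_covers_log_linear_truth():
    # data generated from a log-linear truth: the fitted spline's own
    # pointwise 95% band should cover the true line at exposure deciles.
    # Wald bands are asymptotic, so this runs at full study scale.
    hits = total = 0
    for seed in range(6):
        cfg = sd.SimConfig(seed=500 + seed)
        env = sd.simulate_environment(cfg)
        rec = sd.simulate_pregnancy_histories(cfg, env)
        sets = cb.build_matched_sets(rec, env, "stillbirth")
        model = mm.fit(sets, mm.ModelSpec(exposure_term="spline_all_ages"))
        c0 = 10.0
        curve = mm.extract_erf(model, "all_ages", reference_c0=c0)
        f0, lo0, hi0 = curve.evaluate_ci([c0])
        assert f0[0] == 0.0 and lo0[0] == 0.0 and hi0[0] == 0.0
        deciles = np.quantile(sets.table["pm25"], np.linspace(0.1, 0.9, 9))
        truth = np.log(cfg.true_erf.or_per_10) / 10.0 * (deciles - c0)
        _, lo, hi = curve.evaluate_ci(deciles)
        hits += int(((truth >= lo) & (truth <= hi)).sum())
        total += len(deciles)
    assert hits / total >= 0.9


def test_age_modified_simulation_orders_extracted_curves():
    wins = 0
    n_seeds = 5
    for seed in range(n_seeds):
        cfg = small_config(
            n_mothers=4000,
            seed=700 + seed,
            true_erf=sd.TrueERF(
                or_per_10=1.15,
                age_modifiers={"<20": 1.0, "20-29": 1.0, "30-34": 1.2, ">34": 2.0},
            ),
        )
        env = sd.simulate_environment(cfg)
        rec = sd.simulate_pregnancy_histories(cfg, env)
        sets = cb.build_matched_sets(rec, env, "stillbirth")
        model = mm.fit(
            sets, mm.ModelSpec(exposure_term="spline_age_specific")
        )
        eset = mm.extract_erf_set(model, reference_c0=10.0)
        c90 = float(np.quantile(sets.table["pm25"], 0.9))
        old = eset[">34"].evaluate([c90])[0]
        young = eset["<20"].evaluate([c90])[0]
        wins += old > young
    assert wins >= 3  # ordering holds in most seeds

    with pytest.raises(KeyError):
        mm.extract_erf(model, "35-44")


def test_fit_refuses_too_few_sets():
    sets = make_sets([(0, True, 1.0), (0, False, 2.0)])
    with pytest.raises(ValueError, match="at least"):
        mm.fit(sets, mm.ModelSpec())
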