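"""Weighted exposure, attributable burden, scenarios, uncertainty, trends."""

import numpy as np
import pandas as pd
import pytest

from stillburden import burden as bd
from stillburden import population_at_risk as par
from stillburden.erf import AGE_GROUPS, ERF

Z = 1.959963984540054


def _pop(weights, countries=None):
    """Population table with all pregnancies in the 20-29 group."""
    countries = countries or [0] * len(weights)
    df = pd.DataFrame(
        {"pixel_id": range(len(weights)), "country_id": countries}
    )
    for g in AGE_GROUPS:
        df[g] = 0.0
    df["20-29"] = np.asarray(weights, dtype=float)
    return df


def _conc(values):
    return pd.Series(
        np.asarray(values, dtype=float),
        index=pd.Index(range(len(values)), name="pixel_id"),
    )


def test_weighted_exposure_hand_values():
    pop = _pop([1.0, 3.0])
    assert bd.weighted_exposure(_conc([10, 20]), pop, level="domain") == (
        pytest.approx(17.5)
    )
    assert bd.weighted_exposure(_conc([33, 33]), pop, level="domain") == (
        pytest.approx(33.0)
    )
    equal = _pop([2.0, 2.0])
    assert bd.weighted_exposure(_conc([10, 20]), equal, level="domain") == (
        pytest.approx(15.0)
    )
    with pytest.raises(ValueError, match="weight"):
        bd.weighted_exposure(_conc([10, 20]), _pop([0.0, 0.0]), level="domain")


def test_attributable_fraction_closed_form_single_pixel():
    curve = ERF.log_linear(1.15)
    _, af_country, af_domain = bd.attributable_fraction(
        _conc([20.0]), "custom:10", curve, _pop([100.0])
    )
    expected = 1.0 - 1.0 / 1.15
    assert af_domain == pytest.approx(expected, abs=1e-12)
    assert af_country.loc[0] == pytest.approx(expected, abs=1e-12)


def test_country_af_is_weighted_mean_of_pixel_afs():
    curve = ERF.log_linear(1.15)
    beta = np.log(1.15) / 10.0
    # invert AF -> concentration so pixel AFs are exactly 0.1 and 0.3
    c = [10.0 - np.log(1.0 - af) / beta for af in (0.1, 0.3)]
    af_pixel, af_country, _ = bd.attributable_fraction(
        _conc(c), 10.0, curve, _pop([1.0, 1.0])
    )
    np.testing.assert_allclose(af_pixel["20-29"], [0.1, 0.3], atol=1e-12)
    assert af_country.loc[0] == pytest.approx(0.2, abs=1e-12)


def test_af_zero_when_concentration_below_reference():
    curve = ERF.log_linear(1.2)
    _, af_country, af_domain = bd.attributable_fraction(
        _conc([5.0, 9.9]), "IT4", curve, _pop([1.0, 1.0])
    )
    assert af_domain == 0.0
    assert af_country.loc[0] == 0.0


def test_af_bounds_and_convex_hull_property():
    curve = ERF.log_linear(1.4)
    conc = _conc([12.0, 40.0, 90.0])
    af_pixel, af_country, af_domain = bd.attributable_fraction(
        conc, "IT4", curve, _pop([1.0, 5.0, 2.0])
    )
    pix = af_pixel["20-29"].to_numpy()
    assert 0.0 <= af_domain < 1.0
    assert pix.min() <= af_country.loc[0] <= pix.max()


def test_uniform_country_equals_single_pixel_closed_form():
    curve = ERF.log_linear(1.11)
    beta = np.log(1.11) / 10.0
    conc = _conc([47.0] * 6)
    _, af_country, _ = bd.attributable_fraction(
        conc, "IT4", curve, _pop(np.linspace(1, 6, 6))
    )
    assert af_country.loc[0] == pytest.approx(
        1.0 - np.exp(-beta * 37.0), abs=1e-12
    )


def test_reference_level_monotonicity_on_fixture_grid(risk_inputs):
    ages = par.AgeStructure(risk_inputs["fertility"])
    pop = par.disaggregate(
        risk_inputs["pregnancies"], risk_inputs["female_population"], ages
    )
    conc = (
        risk_inputs["pm25"]
        .query("year == 2015")
        .set_index("pixel_id")["value"]
    )
    curve = ERF.log_linear(1.11)
    afs = []
    for level in ("AQG", "IT4", "IT3", "IT2", "IT1"):
        _, _, af_domain = bd.attributable_fraction(conc, level, curve, pop)
        afs.append(af_domain)
    assert all(a >= b - 1e-15 for a, b in zip(afs, afs[1:]))


def test_attributable_number_identity():
    af = pd.Series({0: 0.397})
    n = pd.Series({0: 2_090_000.0})
    an = bd.attributable_number(af, n)
    assert an.loc[0] == pytest.approx(0.397 * 2_090_000.0)
    assert bd.attributable_number(pd.Series({0: 0.0}), n).loc[0] == 0.0
    assert bd.attributable_number(
        pd.Series({0: 0.5}), pd.Series({0: 1000.0})
    ).loc[0] == pytest.approx(500.0)
    with pytest.raises(ValueError, match="missing"):
        bd.attributable_number(pd.Series({7: 0.1}), n)


def test_exceedance_share_counts_strictly_above():
    pop = _pop([1.0, 1.0])
    assert bd.exceedance_share(_conc([6.0, 8.0]), pop, 5.0) == 1.0
    assert bd.exceedance_share(_conc([4.0, 6.0]), pop, 5.0) == 0.5
    assert bd.exceedance_share(_conc([4.0, 6.0]), pop, 99.0) == 0.0
    assert bd.exceedance_share(_conc([5.0, 5.0]), pop, 5.0) == 0.0


def test_scenario_capping_limits():
    curve = ERF.log_linear(1.2)
    pop = _pop([1.0, 2.0, 3.0])
    conc = _conc([8.0, 30.0, 55.0])
    n = pd.Series({0: 1000.0})
    at_ref = bd.scenario_cap(conc, 10.0, 10.0, curve, pop, n)
    assert at_ref["an_counterfactual"] == pytest.approx(0.0, abs=1e-12)
    assert at_ref["an_avoided"] == pytest.approx(
        at_ref["an_baseline"], abs=1e-12
    )
    noop = bd.scenario_cap(conc, 100.0, 10.0, curve, pop, n)
    assert noop["an_avoided"] == pytest.approx(0.0, abs=1e-12)
    # tighter caps avoid at least as much burden
    it3 = bd.scenario_cap(conc, "IT3", 10.0, curve, pop, n)
    it1 = bd.scenario_cap(conc, "IT1", 10.0, curve, pop, n)
    assert it3["an_avoided"] >= it1["an_avoided"]


def test_reference_level_parsing_and_who_constants():
    assert bd.WHO_LEVELS == {
        "AQG": 5.0, "IT4": 10.0, "IT3": 15.0, "IT2": 25.0, "IT1": 35.0
    }
    assert bd.ReferenceLevel.parse("IT4").c0 == 10.0
    assert bd.ReferenceLevel.parse("custom:12.5").c0 == 12.5
    assert bd.ReferenceLevel.parse(7).c0 == 7.0
    with pytest.raises(ValueError, match="IT4"):
        bd.ReferenceLevel.parse("IT9")


def _n_table(point, lo=None, hi=None):
    return pd.DataFrame(
        {
            "country_id": [0],
            "n": [point],
            "n_lo": [lo if lo is not None else point],
            "n_hi": [hi if hi is not None else point],
        }
    )


def test_mc_interval_degenerates_with_no_uncertainty():
    curve = ERF.log_linear(1.15)
    curve.cov = np.array([[0.0]])
    res = bd.mc_confidence(
        _conc([30.0]), _pop([10.0]), curve, _n_table(500.0),
        "IT4", n_draws=200, seed=3,
    )
    dom = res[res["country_id"] == "domain"].iloc[0]
    assert dom["af_lo"] == pytest.approx(dom["af_hi"], abs=1e-12)
    assert dom["an_lo"] == pytest.approx(dom["an_hi"], abs=1e-9)
    assert dom["af"] == pytest.approx(dom["af_lo"], abs=1e-12)


def test_mc_interval_matches_closed_form_for_log_linear():
    # single uniform pixel: AF is monotone in beta, so MC percentiles of
    # AF must match the transformed beta percentiles
    curve = ERF.log_linear(1.15, ci=(1.07, 1.25))
    delta = 25.0
    res = bd.mc_confidence(
        _conc([10.0 + delta]), _pop([10.0]), curve,
        _n_table(1000.0), "IT4", n_draws=10_000, seed=11,
    )
    beta, se = curve.coef[0], np.sqrt(curve.cov[0, 0])
    lo = 1.0 - np.exp(-(beta - Z * se) * delta)
    hi = 1.0 - np.exp(-(beta + Z * se) * delta)
    dom = res[res["country_id"] == "domain"].iloc[0]
    assert dom["af_lo"] == pytest.approx(lo, abs=0.005)
    assert dom["af_hi"] == pytest.approx(hi, abs=0.005)


def test_mc_is_deterministic_under_seed():
    curve = ERF.log_linear(1.15, ci=(1.07, 1.25))
    kwargs = dict(n_draws=300, seed=21)
    a = bd.mc_confidence(
        _conc([40.0]), _pop([5.0]), curve,
        _n_table(100.0, 80.0, 125.0), "IT4", **kwargs,
    )
    b = bd.mc_confidence(
        _conc([40.0]), _pop([5.0]), curve,
        _n_table(100.0, 80.0, 125.0), "IT4", **kwargs,
    )
    pd.testing.assert_frame_equal(a, b)


def test_annual_rate_methods():
    years = pd.Series(
        {2000: 2.83, 2009: 2.37}
    )
    assert bd.annual_rate(years, 2000, 2009) == pytest.approx(1.95, abs=0.005)
    const = pd.Series({y: 4.0 for y in range(2000, 2010)})
    assert bd.annual_rate(const, 2000, 2009) == pytest.approx(0.0, abs=1e-12)
    assert bd.annual_rate(const, 2000, 2009, "loglinear") == pytest.approx(
        0.0, abs=1e-9
    )
    geom = pd.Series({2000 + i: 5.0 * 0.98**i for i in range(10)})
    assert bd.annual_rate(geom, 2000, 2009) == pytest.approx(2.0, abs=1e-9)
    assert bd.annual_rate(geom, 2000, 2009, "loglinear") == pytest.approx(
        2.0, abs=1e-9
    )
    with pytest.raises(ValueError, match="positive"):
        bd.annual_rate(pd.Series({2000: 1.0, 2009: 0.0}), 2000, 2009)
    with pytest.raises(ValueError, match="exceed"):
        bd.annual_rate(geom, 2009, 2000)
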