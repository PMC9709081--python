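"""Synthetic DHS-like pregnancy histories and gridded risk-assessment inputs.

Real inputs for this kind of analysis are access-restricted survey microdata
and large raster stacks.  This module generates structurally equivalent
tables with a *known* data-generating process so that every downstream
stage — matched-set construction, conditional-logit fitting, curve
extraction, burden attribution — can be tested for parameter recovery.

The outcome mechanism is the same fixed-effect logit that the estimator
assumes: each mother carries a latent intercept (genetics, place, anything
time-invariant), and each of her pregnancies becomes a loss with
probability ``logistic(theta_i + f(x) + z*gamma + baseline)`` where ``x``
is the gestation-adjusted PM2.5 over her loss-length window.  Conditioning
within mother removes ``theta_i`` exactly, so the fitted exposure
coefficient should recover the configured truth.

Defaults emulate the analysis sample of a multi-country survey-based
self-matched design: mothers with several pregnancies, a substantial share
of losses (the design samples mothers *with* a loss), strong seasonal and
month-to-month PM2.5 variation, and wide between-country concentration
differences.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort_builder import classify_outcome
from .erf import AGE_GROUPS

__all__ = [
    "TrueERF",
    "SimConfig",
    "simulate_environment",
    "simulate_pregnancy_histories",
    "simulate_risk_inputs",
    "loss_probability",
]


# ----------------------------------------------------------------------
@dataclass
class TrueERF:
    """Ground-truth exposure-response used by the generator.

    ``log_linear``: log-odds contribution ``ln(or_per_10)/10 * x``.
    ``sublinear``: ``a * ln(1 + x/s)`` with ``shape_params = (a, s)`` —
    concave in concentration, the curvature the fitted splines should find.
    ``age_modifiers`` scale the log-odds contribution per maternal-age
    group, emulating effect modification by age.
    """

    form: str = "log_linear"
    or_per_10: float = 1.11
    shape_params: tuple[float, float] = (0.25, 30.0)
    age_modifiers: dict = field(
        default_factory=lambda: {g: 1.0 for g in AGE_GROUPS}
    )

    def __post_init__(self) -> None:
        if self.form not in ("log_linear", "sublinear"):
            raise ValueError(f"unknown TrueERF form {self.form!r}")
        if self.or_per_10 <= 0:
            raise ValueError("or_per_10 must be positive")

    def log_odds(self, x, age_group=None):
        """Log-odds contribution at concentration ``x`` (0 at x=0)."""
        x = np.asarray(x, dtype=float)
        if self.form == "log_linear":
            f = np.log(self.or_per_10) / 10.0 * x
        else:
            a, s = self.shape_params
            f = a * np.log1p(x / s)
        if age_group is not None:
            mods = np.asarray(
                [self.age_modifiers.get(g, 1.0) for g in np.atleast_1d(age_group)]
            )
            f = f * (mods if f.shape == mods.shape else mods.reshape(f.shape))
        return f


def _default_covariate_effects() -> dict:
    # log-odds per unit of each longitudinal covariate
    return {
        "maternal_age": 0.01,  # per year
        "parity": 0.10,  # multiparous vs nulliparous
        "temperature": -0.01,  # per degree C (window mean)
        "month_sin": 0.15,  # seasonality via sin(2*pi*month/12)
        "nightlight": 0.002,  # per digit-number
    }


def _default_gestation_probs() -> dict:
    # Month of loss for a mother's loss pregnancies.  Survey gestational
    # length is in whole months 2-9; weight toward >=7 months so that the
    # primary (stillbirth) analysis retains most mothers, while all four
    # outcome classes still occur.
    return {2: 0.03, 3: 0.03, 4: 0.04, 5: 0.06, 6: 0.09, 7: 0.25, 8: 0.25, 9: 0.25}


@dataclass
class SimConfig:
    """All knobs of the generator; one seed fixes every draw."""

    n_mothers: int = 10_000
    n_countries: int = 8
    n_locations: int = 40
    years: tuple[int, int] = (1998, 2016)
    true_erf: TrueERF = field(default_factory=TrueERF)
    seasonal_amplitude: float = 15.0  # ug/m3
    country_trend_sd: float = 0.0  # log-odds per year
    country_slope_sd: float = 0.0  # log-odds per ug/m3
    baseline_stillbirth_logodds: float = -1.2
    covariate_effects: dict = field(default_factory=_default_covariate_effects)
    seed: int = 0

    # environment texture
    pm25_noise_sd: float = 14.0  # monthly AR(1) innovation scale, ug/m3
    pm25_ar1: float = 0.4
    pm25_country_mean_range: tuple[float, float] = (12.0, 75.0)
    country_pm25_means: list | None = None  # overrides the range draw
    location_sd: float = 4.0

    # pregnancy-history texture
    mother_intercept_sd: float = 0.75
    gestation_probs: dict = field(default_factory=_default_gestation_probs)
    pregnancies_geom_p: float = 0.30  # extra pregnancies ~ 1 + Geom(p)
    max_pregnancies: int = 8
    min_conception_gap_months: int = 10

    # gridded risk-assessment inputs
    assess_years: tuple[int, int] = (2000, 2019)
    n_pixels: int = 250
    total_pregnancies: float = 1_000_000.0
    stillbirth_rate: float = 0.02  # stillbirths per pregnancy, base year
    stillbirth_ci_sigma: float = 0.05  # log-scale half-width/1.96 of N CI

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_mothers < 1:
            raise ValueError("n_mothers must be >= 1")
        if self.years[1] < self.years[0]:
            raise ValueError("empty year range")
        if self.n_locations < self.n_countries:
            raise ValueError("need at least one location per country")
        probs = np.array(list(self.gestation_probs.values()), dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("gestation_probs must sum to 1")
        if any(m < 2 or m > 9 for m in self.gestation_probs):
            raise ValueError("gestation_probs keys must be months 2-9")
        if not 0 < self.pregnancies_geom_p <= 1:
            raise ValueError("pregnancies_geom_p must be in (0, 1]")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_erf"] = dataclasses.asdict(self.true_erf)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "true_erf" in d and isinstance(d["true_erf"], dict):
            te = dict(d["true_erf"])
            if "shape_params" in te:
                te["shape_params"] = tuple(te["shape_params"])
            if "gestation_probs" in d:
                d["gestation_probs"] = {
                    int(k): v for k, v in d["gestation_probs"].items()
                }
            d["true_erf"] = TrueERF(**te)
        for key in ("years", "assess_years", "pm25_country_mean_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- shared derived quantities ------------------------------------
    @property
    def n_months(self) -> int:
        return (self.years[1] - self.years[0] + 1) * 12

    def location_country(self) -> np.ndarray:
        """Round-robin assignment of locations to countries."""
        return np.arange(self.n_locations) % self.n_countries

    def country_params(self) -> pd.DataFrame:
        """Country-level environment parameters (own seed stream)."""
        rng = np.random.default_rng([self.seed, 0])
        n = self.n_countries
        if self.country_pm25_means is not None:
            pm = np.asarray(self.country_pm25_means, dtype=float)
            if len(pm) != n:
                raise ValueError("country_pm25_means length != n_countries")
        else:
            lo, hi = self.pm25_country_mean_range
            pm = rng.uniform(lo, hi, n)
        return pd.DataFrame(
            {
                "country_id": np.arange(n),
                "pm25_mean": pm,
                "temp_mean": rng.uniform(16.0, 30.0, n),
                "season_phase": rng.uniform(0.0, 12.0, n),
                "pm25_trend": rng.uniform(-0.015, 0.0, n),
                "trend_effect": rng.normal(0.0, self.country_trend_sd, n),
                "slope_effect": rng.normal(0.0, self.country_slope_sd, n),
            }
        )


# ----------------------------------------------------------------------
def simulate_environment(config: SimConfig) -> pd.DataFrame:
    """Monthly PM2.5, temperature and nightlight series per location.

    PM2.5 is country mean + location offset + sinusoidal season + AR(1)
    monthly noise, truncated at zero.  Nightlight is an annual
    location-level value (constant within a year), emulating a satellite
    development indicator.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    cp = config.country_params()
    loc_country = config.location_country()
    T = config.n_months
    y0 = config.years[0]
    n_years = T // 12

    months = np.arange(T)
    month_of_year = months % 12 + 1

    loc_offset = rng.normal(0.0, config.location_sd, config.n_locations)
    frames = []
    for loc in range(config.n_locations):
        c = loc_country[loc]
        phase = cp.season_phase[c]
        season = config.seasonal_amplitude * np.sin(
            2.0 * np.pi * (month_of_year - phase) / 12.0
        )
        # stationary AR(1): marginal sd == pm25_noise_sd
        rho = config.pm25_ar1
        innov_sd = config.pm25_noise_sd * np.sqrt(max(1.0 - rho**2, 0.0))
        e = np.empty(T)
        e[0] = rng.normal(0.0, config.pm25_noise_sd)
        shocks = rng.normal(0.0, innov_sd, T - 1) if T > 1 else np.empty(0)
        for t in range(1, T):
            e[t] = rho * e[t - 1] + shocks[t - 1]
        pm25 = np.clip(cp.pm25_mean[c] + loc_offset[loc] + season + e, 0.0, None)

        temp = (
            cp.temp_mean[c]
            + 4.0 * np.sin(2.0 * np.pi * (month_of_year - phase - 1.0) / 12.0)
            + rng.normal(0.0, 1.2, T)
        )
        ntl_base = rng.lognormal(mean=1.5, sigma=1.2)
        ntl_year = ntl_base * (1.02 ** np.arange(n_years))
        ntl = np.repeat(ntl_year, 12)

        frames.append(
            pd.DataFrame(
                {
                    "location_id": loc,
                    "year": y0 + months // 12,
                    "month": month_of_year,
                    "pm25": pm25,
                    "temperature": temp,
                    "nightlight": ntl,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _pivot_environment(config_years, env: pd.DataFrame):
    """(locations x months) arrays for pm25/temperature, and annual ntl.

    Raises with the missing location-months named if the series has gaps.
    """
    y0, y1 = config_years
    T = (y1 - y0 + 1) * 12
    env = env.copy()
    env["t"] = (env["year"] - y0) * 12 + (env["month"] - 1)
    locs = np.sort(env["location_id"].unique())
    arrays = {}
    for var in ("pm25", "temperature", "nightlight"):
        wide = env.pivot_table(
            index="location_id", columns="t", values=var, aggfunc="first"
        ).reindex(index=locs, columns=np.arange(T))
        if wide.isna().any().any():
            missing = np.argwhere(wide.isna().to_numpy())[:10]
            desc = ", ".join(
                f"(location {locs[i]}, {y0 + t // 12}-{t % 12 + 1:02d})"
                for i, t in missing
            )
            raise ValueError(
                f"environment series has gaps in {var}; first missing "
                f"location-months: {desc}"
            )
        arrays[var] = wide.to_numpy()
    loc_index = {loc: i for i, loc in enumerate(locs)}
    return arrays, loc_index, T


def loss_probability(
    config: SimConfig,
    x,
    maternal_age,
    multiparous,
    temperature,
    month,
    nightlight,
    theta,
    age_group=None,
    country_trend_effect=0.0,
    country_slope_effect=0.0,
    year_centered=0.0,
):
    """Per-pregnancy loss probability under the generating logit model.

    Exposed so tests can verify mechanism-level contracts (e.g. strict
    monotonicity in the mother intercept ``theta``).
    """
    eff = config.covariate_effects
    eta = (
        config.baseline_stillbirth_logodds
        + np.asarray(theta, dtype=float)
        + config.true_erf.log_odds(x, age_group)
        + eff.get("maternal_age", 0.0) * np.asarray(maternal_age, dtype=float)
        + eff.get("parity", 0.0) * np.asarray(multiparous, dtype=float)
        + eff.get("temperature", 0.0) * np.asarray(temperature, dtype=float)
        + eff.get("month_sin", 0.0)
        * np.sin(2.0 * np.pi * np.asarray(month, dtype=float) / 12.0)
        + eff.get("nightlight", 0.0) * np.asarray(nightlight, dtype=float)
        + np.asarray(country_trend_effect) * np.asarray(year_centered)
        + np.asarray(country_slope_effect) * np.asarray(x, dtype=float)
    )
    return 1.0 / (1.0 + np.exp(-eta))


def _age_group_of(ages: np.ndarray) -> np.ndarray:
    grp = np.full(len(ages), AGE_GROUPS[1], dtype=object)
    grp[ages < 20] = AGE_GROUPS[0]
    grp[(ages >= 30) & (ages < 35)] = AGE_GROUPS[2]
    grp[ages >= 35] = AGE_GROUPS[3]
    return grp


def simulate_pregnancy_histories(
    config: SimConfig, environment: pd.DataFrame
) -> pd.DataFrame:
    """Per-pregnancy records with outcomes drawn from the fixed-effect logit.

    Each mother gets >= 2 pregnancies, a Normal(0, sigma^2) latent
    intercept, and one loss gestational length G in months 2-9; *every*
    pregnancy's exposure is the mean PM2.5 over G months from its own
    conception (the gestation-adjusted definition the matched design
    reconstructs), so the generated data are exactly the estimator's
    assumed model.  Losses get ``gestation_months = G`` and are classed by
    G; the rest are livebirths at 9 months.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    arrays, loc_index, T = _pivot_environment(config.years, environment)
    cp = config.country_params()
    loc_country = config.location_country()
    y0 = config.years[0]

    M = config.n_mothers
    # mothers -> locations, sizes, intercepts, loss lengths
    mloc = rng.integers(0, config.n_locations, M)
    extra = np.minimum(
        rng.geometric(config.pregnancies_geom_p, M) - 1,
        config.max_pregnancies - 2,
    )
    n_preg = 2 + extra
    theta = rng.normal(0.0, config.mother_intercept_sd, M)
    g_months = np.array(sorted(config.gestation_probs), dtype=int)
    g_probs = np.array([config.gestation_probs[m] for m in g_months])
    G = rng.choice(g_months, size=M, p=g_probs)
    age0 = rng.uniform(15.0, 32.0, M)

    # flat per-pregnancy rows, in conception order within mother
    N = int(n_preg.sum())
    mrow = np.repeat(np.arange(M), n_preg)
    u = rng.random(N)
    order = np.lexsort((u, mrow))
    u = u[order]
    starts = np.concatenate(([0], np.cumsum(n_preg)))[:-1]
    j = np.arange(N) - np.repeat(starts, n_preg)

    gap = config.min_conception_gap_months
    # conceptions in [0, T-9] with a minimum spacing, uniform otherwise
    L = T - 9 - (n_preg - 1) * gap
    if np.any(L <= 0):
        raise ValueError(
            "year range too short for the configured pregnancy counts"
        )
    conc_t = (u * np.repeat(L, n_preg)).astype(int) + j * gap

    loc_rep = mloc[mrow]
    country_rep = loc_country[loc_rep]
    G_rep = G[mrow]
    theta_rep = theta[mrow]
    age = np.minimum(age0[mrow] + (conc_t - conc_t[starts][mrow]) / 12.0, 49.0)
    multiparous = (j > 0).astype(float)
    month = conc_t % 12 + 1
    year = y0 + conc_t // 12

    # window means via cumulative sums over the month axis
    cs_pm = np.concatenate(
        [np.zeros((arrays["pm25"].shape[0], 1)), np.cumsum(arrays["pm25"], axis=1)],
        axis=1,
    )
    cs_tm = np.concatenate(
        [
            np.zeros((arrays["temperature"].shape[0], 1)),
            np.cumsum(arrays["temperature"], axis=1),
        ],
        axis=1,
    )
    li = np.array([loc_index[l] for l in loc_rep])
    x = (cs_pm[li, conc_t + G_rep] - cs_pm[li, conc_t]) / G_rep
    temp = (cs_tm[li, conc_t + G_rep] - cs_tm[li, conc_t]) / G_rep
    ntl = arrays["nightlight"][li, conc_t - (conc_t % 12)]

    groups = _age_group_of(age)
    p = loss_probability(
        config,
        x,
        age,
        multiparous,
        temp,
        month,
        ntl,
        theta_rep,
        age_group=groups,
        country_trend_effect=cp.trend_effect.to_numpy()[country_rep],
        country_slope_effect=cp.slope_effect.to_numpy()[country_rep],
        year_centered=year - (config.years[0] + config.years[1]) / 2.0,
    )
    loss = rng.random(N) < p

    gestation = np.where(loss, G_rep, 9)
    outcome = np.array(
        [classify_outcome(g, bool(t)) for g, t in zip(gestation, loss)],
        dtype=object,
    )

    return pd.DataFrame(
        {
            "mother_id": mrow,
            "country_id": country_rep,
            "location_id": loc_rep,
            "conception_year": year,
            "conception_month": month,
            "gestation_months": gestation,
            "outcome": outcome,
            "maternal_age_years": age,
            "parity": np.where(multiparous > 0, "multiparous", "nulliparous"),
        }
    )


# ----------------------------------------------------------------------
_BANDS = tuple(range(10, 55, 5))  # 5-year band start ages, 10-54
_BAND_POP_SHARE = np.array(
    [0.13, 0.13, 0.13, 0.12, 0.11, 0.11, 0.10, 0.09, 0.08]
)
_BAND_FERTILITY = np.array(
    [0.010, 0.080, 0.180, 0.170, 0.100, 0.050, 0.020, 0.005, 0.001]
)


def simulate_risk_inputs(config: SimConfig) -> dict:
    """Gridded PM2.5, female population, pregnancies, and country tables.

    Returns a dict of tidy tables sharing one pixel index and one
    pixel->country map:

    - ``pm25``: pixel_id, country_id, year, value (annual mean ug/m3)
    - ``female_population``: pixel_id, country_id, band, value (women)
    - ``pregnancies``: pixel_id, country_id, value (pregnancies, one
      reference year; the grand total equals ``config.total_pregnancies``)
    - ``fertility``: country_id, band, rate (births per woman-year)
    - ``stillbirths``: country_id, year, n, n_lo, n_hi (95% CI)
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    cp = config.country_params()
    S = config.n_pixels
    pixel_country = (np.arange(S) * config.n_countries) // S
    years = np.arange(config.assess_years[0], config.assess_years[1] + 1)
    ref_year = 2015

    # annual PM2.5 per pixel-year: country mean * trend + pixel texture
    pix_offset = rng.normal(0.0, 8.0, S)
    base = cp.pm25_mean.to_numpy()[pixel_country] + pix_offset
    trend = cp.pm25_trend.to_numpy()[pixel_country]
    noise = rng.normal(0.0, 2.0, (S, len(years)))
    conc = np.clip(
        base[:, None] * (1.0 + trend[:, None]) ** (years[None, :] - ref_year)
        + noise,
        0.0,
        None,
    )
    pm25 = pd.DataFrame(
        {
            "pixel_id": np.repeat(np.arange(S), len(years)),
            "country_id": np.repeat(pixel_country, len(years)),
            "year": np.tile(years, S),
            "value": conc.ravel(),
        }
    )

    # female population by 5-year band
    pop_total = rng.lognormal(mean=7.0, sigma=0.8, size=S)
    band_noise = rng.uniform(0.8, 1.2, (S, len(_BANDS)))
    W = pop_total[:, None] * _BAND_POP_SHARE[None, :] * band_noise
    female_population = pd.DataFrame(
        {
            "pixel_id": np.repeat(np.arange(S), len(_BANDS)),
            "country_id": np.repeat(pixel_country, len(_BANDS)),
            "band": np.tile(_BANDS, S),
            "value": W.ravel(),
        }
    )

    # country fertility schedules
    country_factor = rng.uniform(0.7, 1.4, config.n_countries)
    fertility = pd.DataFrame(
        {
            "country_id": np.repeat(np.arange(config.n_countries), len(_BANDS)),
            "band": np.tile(_BANDS, config.n_countries),
            "rate": (
                country_factor[:, None] * _BAND_FERTILITY[None, :]
            ).ravel(),
        }
    )

    # total pregnancies allocated by expected-birth shares, exact total
    R_pix = (country_factor[pixel_country, None] * _BAND_FERTILITY[None, :])
    expected_births = (W * R_pix).sum(axis=1)
    shares = expected_births * rng.uniform(0.7, 1.3, S)
    P = shares / shares.sum() * config.total_pregnancies
    P[-1] += config.total_pregnancies - P.sum()
    pregnancies = pd.DataFrame(
        {"pixel_id": np.arange(S), "country_id": pixel_country, "value": P}
    )

    # country-year stillbirth totals with lognormal-style 95% CI
    country_preg = pregnancies.groupby("country_id")["value"].sum()
    z = 1.959963984540054
    rows = []
    for c in range(config.n_countries):
        n_ref = country_preg.loc[c] * config.stillbirth_rate
        for y in years:
            n = n_ref * 0.98 ** (y - years[0])
            rows.append(
                {
                    "country_id": c,
                    "year": int(y),
                    "n": n,
                    "n_lo": n * np.exp(-z * config.stillbirth_ci_sigma),
                    "n_hi": n * np.exp(z * config.stillbirth_ci_sigma),
                }
            )
    stillbirths = pd.DataFrame(rows)

    return {
        "pm25": pm25,
        "female_population": female_population,
        "pregnancies": pregnancies,
        "fertility": fertility,
        "stillbirths": stillbirths,
    }
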