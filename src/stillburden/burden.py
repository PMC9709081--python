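"""Pregnancy-weighted exposure, attributable burden, scenarios and trends.

The attribution model is the standard counterfactual one: at pixel *s*,
age group *k* and year *y*, the fraction of stillbirths attributable to
PM2.5 above a reference level C0 is

    AF_{s,k,y} = 1 - 1 / exp(f_k(max(C_{s,y} - C0, 0)))

with ``f_k`` an (age-specific) exposure-response curve anchored at zero
excess.  Country attributable fractions are pregnancy-weighted means over
pixels and age groups; attributable numbers multiply by the country
stillbirth total, AN = AF * N.  Reference levels are the WHO air quality
guideline and interim targets.

Uncertainty is propagated by Monte Carlo over the two inputs whose
uncertainty the assessment carries: the curve coefficients (sampled from
their estimation covariance, jointly across age groups when the curves
come from one fit) and the baseline stillbirth totals (lognormal, solved
from the reported 95% CI).  Exposure-field uncertainty is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .erf import AGE_GROUPS, ERF, ERFSet

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054

#: WHO 2021 long-term PM2.5 guideline and interim targets, ug/m3.
WHO_LEVELS = {"AQG": 5.0, "IT4": 10.0, "IT3": 15.0, "IT2": 25.0, "IT1": 35.0}


@dataclass(frozen=True)
class ReferenceLevel:
    """A named counterfactual concentration of minimum risk."""

    name: str
    c0: float

    @classmethod
    def parse(cls, spec) -> "ReferenceLevel":
        """Accept "IT4", "custom:12.5", a number, or a ReferenceLevel."""
        if isinstance(spec, ReferenceLevel):
            return spec
        if isinstance(spec, (int, float)):
            return cls("custom", float(spec))
        s = str(spec)
        if s in WHO_LEVELS:
            return cls(s, WHO_LEVELS[s])
        if s.startswith("custom:"):
            return cls("custom", float(s.split(":", 1)[1]))
        raise ValueError(
            f"unknown reference level {spec!r}; use one of "
            f"{sorted(WHO_LEVELS)} or 'custom:<ug/m3>'"
        )


def _as_group_frame(population: pd.DataFrame) -> pd.DataFrame:
    missing = [g for g in AGE_GROUPS if g not in population.columns]
    if missing:
        raise ValueError(f"population table lacks age-group columns {missing}")
    return population


def _aligned_concentration(
    concentration: pd.Series | pd.DataFrame, population: pd.DataFrame
) -> np.ndarray:
    """Concentration values aligned to the population pixel order."""
    if isinstance(concentration, pd.DataFrame):
        concentration = concentration.set_index("pixel_id")["value"]
    conc = concentration.reindex(population["pixel_id"]).to_numpy(dtype=float)
    if np.any(np.isnan(conc)):
        raise ValueError("concentration missing for some population pixels")
    if np.any(conc < 0):
        raise ValueError("negative concentration")
    return conc


def weighted_exposure(
    concentration,
    population: pd.DataFrame,
    by_age: bool = False,
    level: str = "country",
) -> pd.DataFrame | pd.Series:
    """Pregnancy-weighted mean PM2.5.

    Weights are the age-group pregnancy counts (summed over groups unless
    ``by_age``); ``level`` is "country" or "domain".
    """
    pop = _as_group_frame(population)
    conc = _aligned_concentration(concentration, pop)
    groups = list(AGE_GROUPS)
    W = pop[groups].to_numpy(dtype=float)

    def wmean(c, w):
        tot = w.sum()
        if tot <= 0:
            raise ValueError("zero total pregnancy weight")
        return float((c * w).sum() / tot)

    if level == "domain":
        if by_age:
            return pd.Series(
                {g: wmean(conc, W[:, i]) for i, g in enumerate(groups)}
            )
        return wmean(conc, W.sum(axis=1))
    if level != "country":
        raise ValueError(f"unknown level {level!r}")
    rows = {}
    for c, idx in pop.groupby("country_id").indices.items():
        if by_age:
            rows[c] = {
                g: wmean(conc[idx], W[idx, i]) for i, g in enumerate(groups)
            }
        else:
            rows[c] = wmean(conc[idx], W[idx].sum(axis=1))
    out = pd.Series(rows, name="exposure") if not by_age else pd.DataFrame(
        rows
    ).T
    out.index.name = "country_id"
    return out


def _curve_lookup(erfs) -> dict:
    """Normalize the ERF argument to {age_group: ERF}."""
    if isinstance(erfs, ERF):
        return {g: erfs for g in AGE_GROUPS}
    if isinstance(erfs, ERFSet):
        return {g: erfs[g] for g in AGE_GROUPS}
    missing = [g for g in AGE_GROUPS if g not in erfs]
    if missing:
        raise ValueError(f"missing exposure-response curve for {missing}")
    return dict(erfs)


def attributable_fraction(
    concentration,
    c0,
    erfs,
    population: pd.DataFrame,
    clamp_negative: bool = False,
    coef_draws: dict | None = None,
):
    """Pixel, country and domain attributable fractions.

    ``erfs`` may be a single ERF (applied to every age group), a dict
    ``{age_group: ERF}``, or an :class:`ERFSet`.  Spline curves can dip
    below zero at some excess concentrations; the resulting negative
    (protective) pixel AFs are reported as computed unless
    ``clamp_negative``, and counted either way.

    With ``coef_draws`` (mapping group -> (n_draws, k) coefficient draws)
    the computation is vectorized over Monte Carlo draws and returns
    (af_country (n_draws x countries), af_domain (n_draws,)).
    """
    ref = ReferenceLevel.parse(c0)
    pop = _as_group_frame(population)
    conc = _aligned_concentration(concentration, pop)
    curves = _curve_lookup(erfs)
    W = pop[list(AGE_GROUPS)].to_numpy(dtype=float)
    country = pop["country_id"].to_numpy()

    if coef_draws is not None:
        n_draws = next(iter(coef_draws.values())).shape[0]
        num_c = {}
        num_dom = np.zeros(n_draws)
        den_dom = 0.0
        cidx, cinv = np.unique(country, return_inverse=True)
        num_mat = np.zeros((n_draws, len(cidx)))
        den_vec = np.zeros(len(cidx))
        for i, g in enumerate(AGE_GROUPS):
            f = curves[g].evaluate_draws(conc, coef_draws[g], c0=ref.c0)
            af = 1.0 - np.exp(-f)
            if clamp_negative:
                af = np.clip(af, 0.0, None)
            wa = af * W[:, i][None, :]
            for j in range(len(cidx)):
                num_mat[:, j] += wa[:, cinv == j].sum(axis=1)
            den_vec += np.bincount(cinv, weights=W[:, i], minlength=len(cidx))
        af_country = pd.DataFrame(
            num_mat / den_vec[None, :], columns=cidx
        )
        af_domain = num_mat.sum(axis=1) / den_vec.sum()
        return af_country, af_domain

    af_pixel = pd.DataFrame(
        {"pixel_id": pop["pixel_id"], "country_id": country}
    )
    n_negative = 0
    for g in AGE_GROUPS:
        f = curves[g].evaluate(conc, c0=ref.c0)
        af = 1.0 - np.exp(-f)
        n_negative += int((af < 0).sum())
        if clamp_negative:
            af = np.clip(af, 0.0, None)
        af_pixel[g] = af
    if n_negative:
        logger.info(
            "%d pixel-by-age AF values are negative (curve below zero); "
            "%s",
            n_negative,
            "clamped to zero" if clamp_negative else "reported as computed",
        )

    A = af_pixel[list(AGE_GROUPS)].to_numpy()
    num = (A * W).sum(axis=1)
    den = W.sum(axis=1)
    af_country = (
        pd.DataFrame({"country_id": country, "num": num, "den": den})
        .groupby("country_id")
        .sum()
    )
    result_country = af_country["num"] / af_country["den"]
    result_country.name = "af"
    af_domain = float(num.sum() / den.sum())
    return af_pixel, result_country, af_domain


def attributable_number(af_country: pd.Series, n_country: pd.Series) -> pd.Series:
    """AN = AF x N per country (unrounded)."""
    n = n_country.reindex(af_country.index)
    if n.isna().any():
        raise ValueError(
            f"stillbirth totals missing for countries "
            f"{list(af_country.index[n.isna()])}"
        )
    if (n < 0).any():
        raise ValueError("negative stillbirth totals")
    out = af_country * n
    out.name = "an"
    return out


def exceedance_share(
    concentration, population: pd.DataFrame, threshold: float
) -> float:
    """Pregnancy-weighted share of pixels with PM2.5 strictly above threshold."""
    pop = _as_group_frame(population)
    conc = _aligned_concentration(concentration, pop)
    w = pop[list(AGE_GROUPS)].to_numpy(dtype=float).sum(axis=1)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("zero total pregnancy weight")
    return float(w[conc > threshold].sum() / tot)


def scenario_cap(
    concentration,
    target,
    c0,
    erfs,
    population: pd.DataFrame,
    n_country: pd.Series,
) -> dict:
    """Counterfactual where concentrations are capped at a WHO target.

    The counterfactual field is ``C' = min(C, target)``; avoided
    stillbirths are baseline AN minus counterfactual AN (summed over the
    domain).  Capping at or below the reference level removes all excess,
    so avoided equals the baseline burden.
    """
    tgt = ReferenceLevel.parse(target)
    pop = _as_group_frame(population)
    conc = _aligned_concentration(concentration, pop)
    capped = pd.Series(
        np.minimum(conc, tgt.c0), index=pd.Index(pop["pixel_id"])
    )

    _, af_c_base, _ = attributable_fraction(concentration, c0, erfs, pop)
    _, af_c_cf, _ = attributable_fraction(capped, c0, erfs, pop)
    an_base = attributable_number(af_c_base, n_country)
    an_cf = attributable_number(af_c_cf, n_country)
    return {
        "target": tgt,
        "counterfactual_concentration": capped,
        "an_baseline": float(an_base.sum()),
        "an_counterfactual": float(an_cf.sum()),
        "an_avoided": float(an_base.sum() - an_cf.sum()),
        "an_country_baseline": an_base,
        "an_country_counterfactual": an_cf,
    }


# ----------------------------------------------------------------------
def _sample_n(n_table: pd.DataFrame, n_draws: int, rng) -> pd.DataFrame:
    """Lognormal draws of country stillbirth totals from point + 95% CI.

    mu = ln(point); sigma solved from the log-scale CI half width.  A
    degenerate CI (lo == hi == point) yields the point value in every
    draw.
    """
    draws = {}
    for _, row in n_table.iterrows():
        point, lo, hi = row["n"], row["n_lo"], row["n_hi"]
        if not (lo <= point <= hi):
            raise ValueError(
                f"stillbirth CI does not contain the point value for "
                f"country {row['country_id']}"
            )
        sigma = (np.log(hi) - np.log(lo)) / (2.0 * _Z95) if hi > lo else 0.0
        draws[row["country_id"]] = point * np.exp(
            rng.normal(0.0, sigma, n_draws) if sigma > 0 else np.zeros(n_draws)
        )
    return pd.DataFrame(draws)


def mc_confidence(
    concentration,
    population: pd.DataFrame,
    erfs,
    n_table: pd.DataFrame,
    c0,
    n_draws: int = 1000,
    seed: int = 0,
    clamp_negative: bool = False,
) -> pd.DataFrame:
    """Monte Carlo percentile CIs for country and domain AF and AN.

    Per draw: sample curve coefficients (jointly across age groups when
    ``erfs`` is an :class:`ERFSet`; independently across groups when a
    plain dict of unrelated curves is given) and country stillbirth
    totals, recompute AF and AN, then take 2.5th/97.5th percentiles.
    Curve draws and baseline draws are independent.  Deterministic for a
    fixed seed.

    ``n_table`` needs columns country_id, n, n_lo, n_hi for the assessed
    year.
    """
    if n_draws < 100:
        logger.warning(
            "n_draws=%d is small; percentile CIs will be noisy", n_draws
        )
    rng = np.random.default_rng(seed)
    ref = ReferenceLevel.parse(c0)
    curves = _curve_lookup(erfs)

    # point estimates
    _, af_country, af_domain = attributable_fraction(
        concentration, ref, curves, population, clamp_negative=clamp_negative
    )
    n_point = n_table.set_index("country_id")["n"]
    an_country = attributable_number(af_country, n_point)

    # curve coefficient draws
    if isinstance(erfs, ERFSet):
        coef_draws = erfs.sample(n_draws, seed=rng)
    else:
        coef_draws = {
            g: curves[g].sample(n_draws, seed=rng) for g in AGE_GROUPS
        }
    af_c_draws, af_d_draws = attributable_fraction(
        concentration,
        ref,
        curves,
        population,
        clamp_negative=clamp_negative,
        coef_draws=coef_draws,
    )
    n_draws_tab = _sample_n(n_table, n_draws, rng)
    common = [c for c in af_c_draws.columns if c in n_draws_tab.columns]
    an_c_draws = af_c_draws[common] * n_draws_tab[common].to_numpy()
    an_d_draws = an_c_draws.sum(axis=1)

    lo, hi = 2.5, 97.5
    rows = []
    for c in common:
        rows.append(
            {
                "country_id": c,
                "af": float(af_country.loc[c]),
                "af_lo": float(np.percentile(af_c_draws[c], lo)),
                "af_hi": float(np.percentile(af_c_draws[c], hi)),
                "an": float(an_country.loc[c]),
                "an_lo": float(np.percentile(an_c_draws[c], lo)),
                "an_hi": float(np.percentile(an_c_draws[c], hi)),
            }
        )
    rows.append(
        {
            "country_id": "domain",
            "af": af_domain,
            "af_lo": float(np.percentile(af_d_draws, lo)),
            "af_hi": float(np.percentile(af_d_draws, hi)),
            "an": float(an_country.sum()),
            "an_lo": float(np.percentile(an_d_draws, lo)),
            "an_hi": float(np.percentile(an_d_draws, hi)),
        }
    )
    out = pd.DataFrame(rows)
    out.attrs.update(
        {"n_mc_draws": n_draws, "seed": seed, "reference_level": ref.name}
    )
    return out


def annual_rate(
    values: pd.Series, y_start: int, y_end: int, method: str = "endpoint"
) -> float:
    """Average annual percent decline of a yearly series.

    ``endpoint``: ``100 * (1 - (V_end / V_start)^(1/(y_end - y_start)))``,
    the geometric rate implied by the two endpoints.  ``loglinear``:
    ``100 * (1 - exp(slope))`` from regressing log(V) on year over the
    window — less sensitive to endpoint noise.  Positive return values
    are declines.
    """
    if y_end <= y_start:
        raise ValueError("y_end must exceed y_start")
    window = values.loc[y_start:y_end]
    if (window <= 0).any():
        raise ValueError("annual_rate requires positive values")
    if method == "endpoint":
        ratio = float(values.loc[y_end] / values.loc[y_start])
        return 100.0 * (1.0 - ratio ** (1.0 / (y_end - y_start)))
    if method == "loglinear":
        yrs = window.index.to_numpy(dtype=float)
        slope = np.polyfit(yrs, np.log(window.to_numpy(dtype=float)), 1)[0]
        return 100.0 * (1.0 - np.exp(slope))
    raise ValueError(f"unknown method {method!r}")
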