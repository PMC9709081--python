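"""Disaggregate gridded pregnancies into age-specific populations at risk.

Stillbirth risk assessment must weight exposure by *pregnancies*, not
total population, and the exposure-response curves are age-specific — so
the gridded total pregnancy count per pixel has to be split by maternal
age.  The split uses expected births: within a pixel the share of
pregnancies at age band k is proportional to (women in band k) x
(country fertility rate of band k),

    P_{s,k} = [W_{s,k} R_{i,k} / sum_k W_{s,k} R_{i,k}] * P_s,

which conserves the pixel total by construction.  Five-year bands are
split first, then summed into the four analysis age groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .erf import AGE_GROUPS

logger = logging.getLogger(__name__)


def default_band_to_group() -> dict:
    """5-year band start age -> analysis age group."""
    mapping = {}
    for band in range(10, 55, 5):
        if band < 20:
            mapping[band] = AGE_GROUPS[0]
        elif band < 30:
            mapping[band] = AGE_GROUPS[1]
        elif band < 35:
            mapping[band] = AGE_GROUPS[2]
        else:
            mapping[band] = AGE_GROUPS[3]
    return mapping


@dataclass
class AgeStructure:
    """Country fertility schedules plus the band-to-group aggregation map.

    ``fertility``: columns (country_id, band, rate), rate in births per
    woman-year, nonnegative.  Every band must map to exactly one group.
    """

    fertility: pd.DataFrame
    band_to_group: dict = field(default_factory=default_band_to_group)

    def __post_init__(self) -> None:
        if (self.fertility["rate"] < 0).any():
            raise ValueError("negative fertility rate")
        bands = set(self.fertility["band"].unique())
        unmapped = bands - set(self.band_to_group)
        if unmapped:
            raise ValueError(f"bands without an age-group mapping: {unmapped}")


def disaggregate(
    pregnancies: pd.DataFrame,
    female_population: pd.DataFrame,
    ages: AgeStructure,
) -> pd.DataFrame:
    """Age-group pregnancy counts per pixel.

    Parameters
    ----------
    pregnancies : DataFrame with (pixel_id, country_id, value) — total
        pregnancies per pixel.
    female_population : DataFrame with (pixel_id, band, value) — women of
        reproductive age per 5-year band.
    ages : AgeStructure

    Returns a DataFrame with pixel_id, country_id and one column per
    analysis age group; rows sum to the pixel total to 1e-9 relative.
    """
    P = pregnancies.set_index("pixel_id")
    W = female_population.pivot_table(
        index="pixel_id", columns="band", values="value", aggfunc="sum"
    ).reindex(P.index)
    if W.isna().any().any():
        missing = list(W.index[W.isna().any(axis=1)][:5])
        raise ValueError(f"female population missing for pixels {missing}")
    R = ages.fertility.pivot_table(
        index="country_id", columns="band", values="rate", aggfunc="first"
    ).reindex(columns=W.columns)
    R_pix = R.loc[P["country_id"].to_numpy()].to_numpy()

    births = W.to_numpy() * R_pix
    denom = births.sum(axis=1)
    p_total = P["value"].to_numpy(dtype=float)
    bad = (denom <= 0) & (p_total > 0)
    if bad.any():
        raise ValueError(
            "zero expected births but positive pregnancies at pixels "
            f"{list(P.index[bad][:10])}; cannot disaggregate"
        )
    idle = (denom <= 0) & (p_total <= 0)
    if idle.any():
        logger.info(
            "%d pixels have neither pregnancies nor expected births; "
            "they contribute zero",
            int(idle.sum()),
        )
    shares = np.divide(
        births,
        denom[:, None],
        out=np.zeros_like(births),
        where=denom[:, None] > 0,
    )
    band_P = shares * p_total[:, None]

    out = pd.DataFrame(
        {"pixel_id": P.index, "country_id": P["country_id"].to_numpy()}
    )
    for g in AGE_GROUPS:
        cols = [
            j
            for j, band in enumerate(W.columns)
            if ages.band_to_group[band] == g
        ]
        out[g] = band_P[:, cols].sum(axis=1)

    total = out[list(AGE_GROUPS)].sum(axis=1).to_numpy()
    scale = np.maximum(np.abs(p_total), 1.0)
    if np.max(np.abs(total - p_total) / scale) > 1e-9:
        raise AssertionError("pixel-level conservation violated")
    return out.reset_index(drop=True)


def group_population(
    population: pd.DataFrame, level: str = "country"
) -> pd.DataFrame:
    """Age-group totals at pixel or country level (sums conserve totals)."""
    if level == "pixel":
        return population.copy()
    if level == "country":
        return (
            population.groupby("country_id")[list(AGE_GROUPS)]
            .sum()
            .reset_index()
        )
    if level == "domain":
        return population[list(AGE_GROUPS)].sum().to_frame().T
    raise ValueError(f"unknown level {level!r}")
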