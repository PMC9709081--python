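"""Build self-matched case-control sets from pregnancy records.

The design compares pregnancies *within* a mother: her loss pregnancy (the
case) against her livebirth pregnancies (the controls).  Anything constant
within a mother — genetics, residence, climate zone — cancels in the
conditional likelihood downstream, so only longitudinal covariates are
assembled here.

Exposure is the *gestation-adjusted* mean: every member of a matched set
is assigned the mean PM2.5 over a hazard time window (HTW) of identical
length, starting at that member's own conception month, with the length
set by the case's gestational month.  Equal window lengths are the
matching rule; without them longer gestations would mechanically average
over more months.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LIVEBIRTH = "livebirth"
STILLBIRTH = "stillbirth"
EARLY_STILLBIRTH = "early_stillbirth"
MISCARRIAGE = "miscarriage"
PREGNANCY_LOSS = "pregnancy_loss"
LOSS_CLASSES = (STILLBIRTH, EARLY_STILLBIRTH, MISCARRIAGE)
TARGET_OUTCOMES = LOSS_CLASSES + (PREGNANCY_LOSS,)

RECORD_COLUMNS = [
    "mother_id",
    "country_id",
    "location_id",
    "conception_year",
    "conception_month",
    "gestation_months",
    "outcome",
    "maternal_age_years",
    "parity",
]


def classify_outcome(gestation_months: int, terminated_early: bool) -> str:
    """Outcome class from gestational length and early-termination status.

    Terminated pregnancies partition into stillbirth (>= 7 months), early
    stillbirth (5-6 months) and miscarriage (< 5 months); survey data give
    gestation in whole months, so the clinical >= 28 weeks threshold maps
    to >= 7 months.  Non-terminated pregnancies are livebirths.
    """
    g = int(gestation_months)
    if g < 1 or g > 10:
        raise ValueError(f"gestation_months out of range [1, 10]: {g}")
    if not terminated_early:
        return LIVEBIRTH
    if g >= 7:
        return STILLBIRTH
    if g >= 5:
        return EARLY_STILLBIRTH
    return MISCARRIAGE


@dataclass
class SelectionLog:
    """Bookkeeping from eligibility filtering and set construction."""

    n_mothers_in: int = 0
    n_sets: int = 0
    n_no_case: int = 0
    n_no_control: int = 0
    n_earlier_losses_dropped: int = 0
    n_sets_dropped_missing_env: int = 0
    n_controls_shorter_gestation: int = 0
    n_sets_no_exposure_variation: int = 0


def _is_target(outcome: pd.Series, target_outcome: str) -> pd.Series:
    if target_outcome == PREGNANCY_LOSS:
        return outcome.isin(LOSS_CLASSES)
    if target_outcome not in LOSS_CLASSES:
        raise ValueError(
            f"unknown target outcome {target_outcome!r}; "
            f"expected one of {TARGET_OUTCOMES}"
        )
    return outcome == target_outcome


def select_eligible(
    records: pd.DataFrame, target_outcome: str = STILLBIRTH
) -> tuple[pd.DataFrame, SelectionLog]:
    """Keep, per mother, the most recent target-class loss and all livebirths.

    Restricting to the most recent loss limits recall bias in
    retrospective histories.  Mothers without a target-class loss, or
    without any livebirth control, are dropped and counted.

    Returns the eligible rows with a ``role`` column ("case"/"control")
    and a :class:`SelectionLog`.
    """
    log = SelectionLog(n_mothers_in=records["mother_id"].nunique())
    df = records.copy()
    df["_t"] = df["conception_year"] * 12 + df["conception_month"]
    is_case_class = _is_target(df["outcome"], target_outcome)
    is_control = df["outcome"] == LIVEBIRTH

    cases = df[is_case_class]
    # most recent target loss per mother
    latest = cases.sort_values("_t").groupby("mother_id").tail(1)
    log.n_earlier_losses_dropped = len(cases) - len(latest)

    controls = df[is_control]
    mothers_with_case = set(latest["mother_id"])
    mothers_with_control = set(controls["mother_id"])
    eligible = mothers_with_case & mothers_with_control
    log.n_no_case = log.n_mothers_in - len(mothers_with_case)
    log.n_no_control = len(mothers_with_case - mothers_with_control)
    log.n_sets = len(eligible)

    case_rows = latest[latest["mother_id"].isin(eligible)].assign(role="case")
    ctrl_rows = controls[controls["mother_id"].isin(eligible)].assign(
        role="control"
    )
    out = (
        pd.concat([case_rows, ctrl_rows])
        .sort_values(["mother_id", "_t"], kind="stable")
        .drop(columns="_t")
        .reset_index(drop=True)
    )
    logger.info(
        "eligibility (%s): %d mothers in, %d sets; dropped %d without a "
        "case, %d without a control; %d earlier losses not used",
        target_outcome,
        log.n_mothers_in,
        log.n_sets,
        log.n_no_case,
        log.n_no_control,
        log.n_earlier_losses_dropped,
    )
    return out, log


def gestation_adjusted_exposure(
    record,
    htw_months: int,
    series: pd.DataFrame,
    variable: str = "pm25",
) -> float:
    """Mean of ``variable`` over the hazard time window of one record.

    The window is the ``htw_months`` consecutive calendar months starting
    at the record's own conception month.  ``series`` is a long monthly
    table (location_id, year, month, <variable>); missing months raise.
    """
    if htw_months < 1:
        raise ValueError("htw_months must be >= 1")
    t0 = int(record["conception_year"]) * 12 + int(record["conception_month"]) - 1
    sub = series[series["location_id"] == record["location_id"]]
    t = sub["year"].to_numpy() * 12 + sub["month"].to_numpy() - 1
    values = pd.Series(sub[variable].to_numpy(), index=t)
    window = np.arange(t0, t0 + htw_months)
    missing = [tt for tt in window if tt not in values.index]
    if missing:
        desc = ", ".join(f"{tt // 12}-{tt % 12 + 1:02d}" for tt in missing)
        raise ValueError(
            f"environment missing months for location "
            f"{record['location_id']}: {desc}"
        )
    return float(values.loc[window].mean())


@dataclass
class MatchedSets:
    """Flat table of matched sets, one row per member.

    Columns: set_id, mother_id, is_case, htw_months, pm25 (gestation-
    adjusted), maternal_age, multiparous, temperature (window mean),
    month, year, nightlight, country_id.  Rows are sorted by set_id; the
    order of members within a set carries no meaning.
    """

    table: pd.DataFrame
    target_outcome: str = STILLBIRTH
    log: SelectionLog = field(default_factory=SelectionLog)

    def __post_init__(self) -> None:
        self.table = self.table.sort_values(
            "set_id", kind="stable"
        ).reset_index(drop=True)

    @property
    def n_sets(self) -> int:
        return self.table["set_id"].nunique()

    @property
    def set_starts(self) -> np.ndarray:
        """Row offsets of each set in the (sorted) table."""
        sid = self.table["set_id"].to_numpy()
        return np.flatnonzero(np.r_[True, sid[1:] != sid[:-1]])

    def validate(self) -> None:
        counts = self.table.groupby("set_id")["is_case"].agg(["sum", "count"])
        bad = counts[counts["sum"] != 1]
        if len(bad):
            raise ValueError(
                f"sets without exactly one case: {list(bad.index[:5])}"
            )
        if (counts["count"] < 2).any():
            raise ValueError("sets with no controls present")
        htw = self.table.groupby("set_id")["htw_months"].nunique()
        if (htw != 1).any():
            raise ValueError("window length differs within a set")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, target_outcome: str = STILLBIRTH) -> "MatchedSets":
        return cls(pd.read_csv(path), target_outcome=target_outcome)


def build_matched_sets(
    records: pd.DataFrame,
    environment: pd.DataFrame,
    target_outcome: str = STILLBIRTH,
) -> MatchedSets:
    """Assemble matched sets with gestation-adjusted exposures.

    Applies eligibility selection, computes each member's window-mean
    PM2.5 and temperature over the case-length HTW starting at the
    member's own conception, attaches longitudinal covariates, and drops
    (with a count) any set containing a member whose window is not fully
    covered by the environment series.

    Sets whose exposure does not vary across members are retained — they
    still inform the covariate coefficients — but counted.
    """
    from .synthetic_data import _pivot_environment  # shared pivot/validation

    selected, log = select_eligible(records, target_outcome)
    if selected.empty:
        raise ValueError(
            "no eligible matched sets; check the target outcome and that "
            "mothers have both a loss and a livebirth"
        )

    years = (int(environment["year"].min()), int(environment["year"].max()))
    arrays, loc_index, T = _pivot_environment(years, environment)

    df = selected.copy()
    case_len = (
        df[df["role"] == "case"]
        .set_index("mother_id")["gestation_months"]
        .astype(int)
    )
    df["htw_months"] = df["mother_id"].map(case_len).to_numpy()
    df["_t0"] = (df["conception_year"] - years[0]) * 12 + (
        df["conception_month"] - 1
    )

    # members whose window runs off the environment axis -> drop the set
    off_axis = (df["_t0"] < 0) | (df["_t0"] + df["htw_months"] > T)
    unknown_loc = ~df["location_id"].isin(loc_index)
    bad_mothers = set(df.loc[off_axis | unknown_loc, "mother_id"])
    if bad_mothers:
        log.n_sets_dropped_missing_env = len(bad_mothers)
        log.n_sets -= len(bad_mothers)
        logger.warning(
            "dropped %d sets with exposure windows outside the "
            "environment series",
            len(bad_mothers),
        )
        df = df[~df["mother_id"].isin(bad_mothers)]
    if df.empty:
        raise ValueError("all sets dropped: environment does not cover them")

    li = df["location_id"].map(loc_index).to_numpy()
    t0 = df["_t0"].to_numpy()
    h = df["htw_months"].to_numpy()
    cs_pm = np.concatenate(
        [np.zeros((len(loc_index), 1)), np.cumsum(arrays["pm25"], axis=1)], axis=1
    )
    cs_tm = np.concatenate(
        [np.zeros((len(loc_index), 1)), np.cumsum(arrays["temperature"], axis=1)],
        axis=1,
    )
    pm = (cs_pm[li, t0 + h] - cs_pm[li, t0]) / h
    tm = (cs_tm[li, t0 + h] - cs_tm[li, t0]) / h
    ntl = arrays["nightlight"][li, t0 - (t0 % 12)]

    # controls with own gestation shorter than the case window, flagged
    log.n_controls_shorter_gestation = int(
        ((df["role"] == "control") & (df["gestation_months"] < h)).sum()
    )

    set_ids = pd.factorize(df["mother_id"], sort=True)[0]
    table = pd.DataFrame(
        {
            "set_id": set_ids,
            "mother_id": df["mother_id"].to_numpy(),
            "is_case": (df["role"] == "case").to_numpy(),
            "htw_months": h,
            "pm25": pm,
            "maternal_age": df["maternal_age_years"].to_numpy(),
            "multiparous": (df["parity"] == "multiparous").astype(int).to_numpy(),
            "temperature": tm,
            "month": df["conception_month"].to_numpy(),
            "year": df["conception_year"].to_numpy(),
            "nightlight": ntl,
            "country_id": df["country_id"].to_numpy(),
        }
    )
    novar = table.groupby("set_id")["pm25"].nunique()
    log.n_sets_no_exposure_variation = int((novar == 1).sum())

    sets = MatchedSets(table, target_outcome=target_outcome, log=log)
    sets.validate()
    return sets
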