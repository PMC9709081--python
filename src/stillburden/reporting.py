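"""Human-readable summaries: cohort tables, rankings, scenarios, trends.

Tables follow the conventions of epidemiological descriptive reporting:
counts with percentages to one decimal per categorical block, so every
printed percentage recomputes from its own printed counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .burden import annual_rate
from .cohort_builder import MatchedSets
from .erf import AGE_GROUPS
from .matched_model import assign_age_group

DEFAULT_NIGHTLIGHT_CUTS = (4.0, 20.5)  # digit-number tertile boundaries


def share_percent(part: float, total: float, decimals: int = 2) -> float:
    """Percentage part/total, rounded to the requested printed precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * part / total, decimals)


def _block(labels: pd.Series, order=None) -> pd.DataFrame:
    counts = labels.value_counts()
    if order is not None:
        counts = counts.reindex(order, fill_value=0)
    total = counts.sum()
    return pd.DataFrame(
        {
            "count": counts,
            "percent": (100.0 * counts / total).round(1),
        }
    )


def population_summary(
    sets: MatchedSets,
    nightlight_cuts: tuple[float, float] = DEFAULT_NIGHTLIGHT_CUTS,
) -> pd.DataFrame:
    """Population-characteristics table for one analysis cohort.

    Blocks: case/control split, number of matched controls per set,
    maternal age group, nightlight tertile, parity.  Each block's
    percentages sum to 100 up to rounding.
    """
    t = sets.table
    blocks = {}

    blocks["pregnancy_loss"] = _block(
        pd.Series(np.where(t["is_case"], "case", "control")),
        order=["control", "case"],
    )

    ctrl = (
        t.groupby("set_id")["is_case"].agg(lambda s: int((~s).sum())).clip(upper=5)
    )
    labels = ctrl.astype(str).replace("5", "5+")
    blocks["n_matched_controls"] = _block(labels, order=[str(i) for i in range(1, 5)] + ["5+"])

    groups = assign_age_group(t["maternal_age"].to_numpy())
    blocks["maternal_age_group"] = _block(pd.Series(groups), order=list(AGE_GROUPS))

    lo, hi = nightlight_cuts
    ntl = pd.cut(
        t["nightlight"],
        bins=[-np.inf, lo, hi, np.inf],
        labels=[f"low (<= {lo})", f"middle ({lo}-{hi})", f"high (> {hi})"],
    )
    blocks["nightlight_tertile"] = _block(ntl.astype(str), order=list(ntl.cat.categories.astype(str)))

    blocks["parity"] = _block(
        pd.Series(
            np.where(t["multiparous"] == 1, "multiparous", "nulliparous")
        ),
        order=["nulliparous", "multiparous"],
    )

    frames = []
    for name, blk in blocks.items():
        blk = blk.reset_index(names="level")
        blk.insert(0, "variable", name)
        frames.append(blk)
    return pd.concat(frames, ignore_index=True)


def country_ranking(
    results: pd.DataFrame, by: str = "an", ascending: bool = False
) -> pd.DataFrame:
    """Country table sorted by attributable number (or fraction)."""
    if results.empty:
        raise ValueError("empty burden results")
    tab = results[results["country_id"] != "domain"].copy()
    return tab.sort_values(by, ascending=ascending).reset_index(drop=True)


def scenario_table(scenarios: list[dict]) -> pd.DataFrame:
    """Flat table of counterfactual capping scenarios (for bar charts)."""
    if not scenarios:
        raise ValueError("no scenarios given")
    return pd.DataFrame(
        [
            {
                "target": s["target"].name,
                "target_c0": s["target"].c0,
                "an_baseline": s["an_baseline"],
                "an_counterfactual": s["an_counterfactual"],
                "an_avoided": s["an_avoided"],
            }
            for s in scenarios
        ]
    )


def trend_summary(
    values: pd.Series, windows: list[tuple[int, int]], method: str = "endpoint"
) -> pd.DataFrame:
    """Annual percent rates of change over the requested year windows."""
    rows = []
    for y0, y1 in windows:
        rows.append(
            {
                "y_start": y0,
                "y_end": y1,
                "v_start": float(values.loc[y0]),
                "v_end": float(values.loc[y1]),
                "annual_decline_pct": annual_rate(values, y0, y1, method=method),
                "method": method,
            }
        )
    return pd.DataFrame(rows)


def plot_scenarios(table: pd.DataFrame, path) -> None:
    """Bar chart of remaining stillbirth burden under each WHO target."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(table["target"], table["an_counterfactual"], color="#737fa3",
           label="remaining attributable stillbirths")
    ax.bar(table["target"], table["an_avoided"],
           bottom=table["an_counterfactual"], color="#c7d0e8", label="avoided")
    ax.set_ylabel("attributable stillbirths")
    ax.set_xlabel("PM2.5 cap (WHO target)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
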