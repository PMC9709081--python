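"""Conditional logistic regression for self-matched pregnancy sets.

The model is a fixed-effect logit: the log odds of loss for pregnancy *t*
of mother *i* is ``x_{i,t} beta + z_{i,t} gamma + theta_i``.  The mother
intercept ``theta_i`` is never estimated — conditioning on "exactly one
case per matched set" gives a likelihood in which any within-set constant
cancels:

    log L = sum_sets [ eta_case - log sum_members exp(eta_member) ]

which is the softmax probability that the case is the member it actually
is.  This cancellation is exact, not an approximation, and is the reason
the design needs no model for between-mother differences.

The exposure term can be linear (reported as an odds ratio per
10 ug/m3), a natural-spline curve shared across ages, or four
age-group-specific spline curves fitted jointly with shared covariate
coefficients.  Country heterogeneity terms (country-specific calendar
trends and country-specific exposure slopes) are available as
ridge-penalized interaction columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr

from ._splines import natural_spline_basis, spline_knots
from .cohort_builder import MatchedSets
from .erf import AGE_GROUPS, ALL_AGES, ERF, ERFSet

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054

EXPOSURE_TERMS = ("linear", "spline_all_ages", "spline_age_specific")


@dataclass
class ModelSpec:
    """What goes into the linear predictor.

    ``spline_df`` controls the exposure curve flexibility; covariate
    spline degrees of freedom follow the standard adjustment set for this
    design (3-DF maternal age, 3-DF window-mean temperature, 4-DF
    conception-month seasonality, parity, nightlight).  Any covariate can
    be switched off by setting its field to ``None``/``False``.
    """

    exposure_term: str = "linear"
    spline_df: int = 3
    age_spline_df: int | None = 3
    parity: bool = True
    temperature_spline_df: int | None = 3
    month_spline_df: int | None = 4
    nightlight: bool = True
    country_year_trend: bool = False
    country_pm25_slope: bool = False
    ridge_penalty: float = 1.0
    age_group_bounds: tuple[float, float, float] = (20.0, 30.0, 35.0)
    min_sets: int = 30

    def __post_init__(self) -> None:
        if self.exposure_term not in EXPOSURE_TERMS:
            raise ValueError(
                f"exposure_term must be one of {EXPOSURE_TERMS}, "
                f"got {self.exposure_term!r}"
            )
        if self.spline_df < 2:
            raise ValueError("spline_df must be >= 2")


def assign_age_group(ages, bounds=(20.0, 30.0, 35.0)) -> np.ndarray:
    """Map maternal ages to the four analysis groups."""
    ages = np.asarray(ages, dtype=float)
    grp = np.full(ages.shape, AGE_GROUPS[1], dtype=object)
    grp[ages < bounds[0]] = AGE_GROUPS[0]
    grp[(ages >= bounds[1]) & (ages < bounds[2])] = AGE_GROUPS[2]
    grp[ages >= bounds[2]] = AGE_GROUPS[3]
    return grp


@dataclass
class DesignInfo:
    """Metadata needed to interpret fitted coefficients."""

    columns: list
    exposure_cols: dict  # group (or "all_ages"/"linear") -> column indices
    exposure_knots: np.ndarray | None
    exposure_range: tuple[float, float]
    penalized: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dropped: list = field(default_factory=list)


def build_design(sets: MatchedSets, spec: ModelSpec):
    """Design matrix (one row per set member) plus interpretation metadata.

    Columns that are constant within every set are inestimable under
    conditioning and are dropped with a log message; remaining collinear
    columns raise, named.
    """
    t = sets.table
    pm = t["pm25"].to_numpy(dtype=float)
    cols: list[np.ndarray] = []
    names: list[str] = []
    penal: list[bool] = []
    exposure_cols: dict = {}
    knots = None

    def add(mat, base_names, penalized=False):
        mat = np.atleast_2d(mat.T).T if mat.ndim == 1 else mat
        start = len(names)
        for j, nm in enumerate(base_names):
            cols.append(mat[:, j])
            names.append(nm)
            penal.append(penalized)
        return list(range(start, len(names)))

    # exposure term(s) first
    if spec.exposure_term == "linear":
        exposure_cols["linear"] = add(pm[:, None], ["pm25"])
    else:
        knots = spline_knots(pm, spec.spline_df)
        basis = natural_spline_basis(pm, knots)
        if spec.exposure_term == "spline_all_ages":
            exposure_cols[ALL_AGES] = add(
                basis, [f"pm25_s{j + 1}" for j in range(basis.shape[1])]
            )
        else:
            groups = assign_age_group(
                t["maternal_age"].to_numpy(), spec.age_group_bounds
            )
            for g in AGE_GROUPS:
                ind = (groups == g).astype(float)
                exposure_cols[g] = add(
                    basis * ind[:, None],
                    [f"pm25[{g}]_s{j + 1}" for j in range(basis.shape[1])],
                )

    # longitudinal covariates
    if spec.age_spline_df:
        age = t["maternal_age"].to_numpy(dtype=float)
        b = natural_spline_basis(age, spline_knots(age, spec.age_spline_df))
        add(b, [f"age_s{j + 1}" for j in range(b.shape[1])])
    if spec.parity:
        add(t["multiparous"].to_numpy(dtype=float)[:, None], ["multiparous"])
    if spec.temperature_spline_df:
        tmp = t["temperature"].to_numpy(dtype=float)
        b = natural_spline_basis(
            tmp, spline_knots(tmp, spec.temperature_spline_df)
        )
        add(b, [f"temp_s{j + 1}" for j in range(b.shape[1])])
    if spec.month_spline_df:
        mo = t["month"].to_numpy(dtype=float)
        b = natural_spline_basis(mo, spline_knots(mo, spec.month_spline_df))
        add(b, [f"month_s{j + 1}" for j in range(b.shape[1])])
    if spec.nightlight:
        add(t["nightlight"].to_numpy(dtype=float)[:, None], ["nightlight"])

    # country heterogeneity terms (ridge-penalized)
    if spec.country_year_trend or spec.country_pm25_slope:
        yr = t["year"].to_numpy(dtype=float)
        yr = yr - yr.mean()
        for c in np.unique(t["country_id"].to_numpy()):
            ind = (t["country_id"].to_numpy() == c).astype(float)
            if spec.country_year_trend:
                add((ind * yr)[:, None], [f"trend[c{c}]"], penalized=True)
            if spec.country_pm25_slope:
                add((ind * pm)[:, None], [f"pm25[c{c}]"], penalized=True)

    X = np.column_stack(cols)
    penal = np.array(penal)

    # drop columns constant within every set (inestimable)
    sid = t["set_id"].to_numpy()
    order = np.argsort(sid, kind="stable")
    starts = np.flatnonzero(np.r_[True, sid[order][1:] != sid[order][:-1]])
    Xs = X[order]
    ptp = np.maximum.reduceat(Xs, starts, axis=0) - np.minimum.reduceat(
        Xs, starts, axis=0
    )
    constant = ptp.max(axis=0) < 1e-12
    dropped = [n for n, c in zip(names, constant) if c]
    if dropped:
        logger.info(
            "dropping within-set-constant columns (inestimable under "
            "conditioning): %s",
            dropped,
        )
        keep = ~constant
        X = X[:, keep]
        remap = np.cumsum(keep) - 1
        exposure_cols = {
            g: [int(remap[i]) for i in idx if keep[i]]
            for g, idx in exposure_cols.items()
        }
        names = [n for n, k in zip(names, keep) if k]
        penal = penal[keep]

    # rank check on the within-set-centered matrix
    Xs = X[order]
    counts = np.diff(np.r_[starts, len(sid)])
    means = np.add.reduceat(Xs, starts, axis=0) / counts[:, None]
    Xc = Xs - np.repeat(means, counts, axis=0)
    if X.shape[1]:
        _, r, piv = qr(Xc, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(Xc.shape) * np.finfo(float).eps
        deficient = piv[diag < tol]
        if len(deficient):
            raise ValueError(
                "design matrix rank-deficient after within-set centering; "
                f"collinear columns: {[names[i] for i in deficient]}"
            )

    info = DesignInfo(
        columns=names,
        exposure_cols=exposure_cols,
        exposure_knots=knots,
        exposure_range=(float(pm.min()), float(pm.max())),
        penalized=penal,
        dropped=dropped,
    )
    return X, info


# ----------------------------------------------------------------------
def _set_structure(sets: MatchedSets):
    t = sets.table
    sid = t["set_id"].to_numpy()
    if np.any(sid[1:] < sid[:-1]):
        raise ValueError("MatchedSets table must be sorted by set_id")
    starts = np.flatnonzero(np.r_[True, sid[1:] != sid[:-1]])
    counts = np.diff(np.r_[starts, len(sid)])
    is_case = t["is_case"].to_numpy(dtype=bool)
    ncase = np.add.reduceat(is_case.astype(int), starts)
    if np.any(ncase != 1):
        bad = np.unique(sid[np.repeat(ncase != 1, counts)])[:5]
        raise ValueError(f"sets without exactly one case: {list(bad)}")
    return starts, counts, is_case


def conditional_loglik(sets: MatchedSets, eta: np.ndarray) -> float:
    """Conditional log-likelihood for given member linear predictors.

    ``sum_sets [eta_case - log sum_members exp(eta_member)]``, computed
    with per-set max subtraction so large predictors cannot overflow.
    Adding any constant to all members of a set leaves the value
    unchanged — this invariance is exactly how the mother intercept
    drops out.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        sid = sets.table["set_id"].to_numpy()
        bad = np.unique(sid[~np.isfinite(eta)])[:5]
        raise ValueError(f"non-finite linear predictor in sets {list(bad)}")
    starts, counts, is_case = _set_structure(sets)
    return _cloglik(eta, starts, counts, is_case)


def _cloglik(eta, starts, counts, is_case) -> float:
    m = np.maximum.reduceat(eta, starts)
    z = np.exp(eta - np.repeat(m, counts))
    lse = m + np.log(np.add.reduceat(z, starts))
    return float(eta[is_case].sum() - lse.sum())


def _softmax(eta, starts, counts):
    m = np.maximum.reduceat(eta, starts)
    z = np.exp(eta - np.repeat(m, counts))
    return z / np.repeat(np.add.reduceat(z, starts), counts)


@dataclass
class FittedModel:
    """A fitted conditional-logit model."""

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_sets: int
    n_members: int
    converged: bool
    n_iter: int
    grad_norm: float
    spec: ModelSpec
    design: DesignInfo

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "z": self.params / se,
                "ci_lo": self.params - _Z95 * se,
                "ci_hi": self.params + _Z95 * se,
            }
        )


def fit(
    sets: MatchedSets,
    spec: ModelSpec | None = None,
    start: np.ndarray | None = None,
    max_iter: int = 100,
    gtol: float = 1e-6,
) -> FittedModel:
    """Maximize the conditional likelihood by Newton-Raphson.

    The analytic gradient is ``X'(y - p)`` and the observed information
    ``X' diag(p) X - M'M`` with ``M`` the matrix of within-set
    probability-weighted column means; the unpenalized likelihood is
    concave, so Newton with step-halving converges from any start.  The
    coefficient covariance is the inverse observed information at the
    optimum.  Heterogeneity columns carry a ridge penalty.
    """
    spec = spec or ModelSpec()
    starts, counts, is_case = _set_structure(sets)
    n_sets = len(starts)
    if n_sets < spec.min_sets:
        raise ValueError(
            f"only {n_sets} matched sets; at least {spec.min_sets} required"
        )
    X, info = build_design(sets, spec)
    k = X.shape[1]
    lam = np.where(info.penalized, spec.ridge_penalty, 0.0) if k else np.zeros(0)
    y = is_case.astype(float)
    row_set = np.searchsorted(starts, np.arange(len(y)), side="right") - 1

    beta = np.zeros(k) if start is None else np.asarray(start, dtype=float).copy()

    def penalized_ll(b):
        return _cloglik(X @ b, starts, counts, is_case) - 0.5 * float(
            (lam * b**2).sum()
        )

    ll = penalized_ll(beta)
    converged = False
    it = 0
    gnorm = np.inf
    for it in range(1, max_iter + 1):
        p = _softmax(X @ beta, starts, counts)
        g = X.T @ (y - p) - lam * beta
        gnorm = float(np.max(np.abs(g))) if k else 0.0
        if gnorm < gtol:
            converged = True
            break
        mu = np.zeros((n_sets, k))
        np.add.at(mu, row_set, p[:, None] * X)
        H = X.T @ (p[:, None] * X) - mu.T @ mu + np.diag(lam)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step-halving keeps the ascent monotone
        alpha = 1.0
        for _ in range(30):
            new = penalized_ll(beta + alpha * step)
            if new >= ll - 1e-12:
                break
            alpha *= 0.5
        beta = beta + alpha * step
        ll = penalized_ll(beta)
    if not converged:
        raise RuntimeError(
            f"conditional-logit fit did not converge in {max_iter} "
            f"iterations (gradient inf-norm {gnorm:.3g})"
        )

    p = _softmax(X @ beta, starts, counts)
    mu = np.zeros((n_sets, k))
    np.add.at(mu, row_set, p[:, None] * X)
    H = X.T @ (p[:, None] * X) - mu.T @ mu + np.diag(lam)
    cov = np.linalg.inv(H)

    return FittedModel(
        params=pd.Series(beta, index=info.columns),
        cov=pd.DataFrame(cov, index=info.columns, columns=info.columns),
        loglik=_cloglik(X @ beta, starts, counts, is_case),
        n_sets=n_sets,
        n_members=len(y),
        converged=converged,
        n_iter=it,
        grad_norm=gnorm,
        spec=spec,
        design=info,
    )


# ----------------------------------------------------------------------
def or_per_10(model: FittedModel) -> dict:
    """Odds ratio of stillbirth per 10 ug/m3, with 95% CI.

    ``OR = exp(10 beta)``; only defined for the linear exposure term.
    """
    if model.spec.exposure_term != "linear":
        raise ValueError(
            "or_per_10 requires a linear exposure term; for spline models "
            "extract the curve instead"
        )
    (idx,) = model.design.exposure_cols["linear"]
    beta = float(model.params.iloc[idx])
    se = float(np.sqrt(model.cov.to_numpy()[idx, idx]))
    return {
        "or": float(np.exp(10.0 * beta)),
        "ci_lo": float(np.exp(10.0 * (beta - _Z95 * se))),
        "ci_hi": float(np.exp(10.0 * (beta + _Z95 * se))),
        "beta": beta,
        "se": se,
    }


def extract_erf(
    model: FittedModel,
    age_group: str = ALL_AGES,
    reference_c0: float = 0.0,
) -> ERF:
    """The fitted exposure-response curve, anchored at ``reference_c0``.

    Returns a spline ERF whose value and pointwise CI are exactly zero at
    the reference.  Evaluation outside the observed exposure range is
    flagged by the ERF as extrapolation (the curve continues linearly
    there, a property of the natural-spline basis).
    """
    if model.spec.exposure_term == "linear":
        raise ValueError(
            "extract_erf requires a spline exposure term; use or_per_10 "
            "for the linear model"
        )
    if age_group not in model.design.exposure_cols:
        raise KeyError(
            f"no curve for age group {age_group!r}; available: "
            f"{sorted(model.design.exposure_cols)}"
        )
    idx = model.design.exposure_cols[age_group]
    coef = model.params.to_numpy()[idx]
    cov = model.cov.to_numpy()[np.ix_(idx, idx)]
    return ERF(
        form="spline",
        reference_c0=reference_c0,
        coef=coef,
        cov=cov,
        knots=model.design.exposure_knots,
        age_group=age_group,
        exposure_range=model.design.exposure_range,
    )


def extract_erf_set(model: FittedModel, reference_c0: float = 0.0) -> ERFSet:
    """All four age-specific curves with their joint covariance.

    Because the curves come from a single interaction model, Monte Carlo
    draws through the returned set preserve the cross-curve correlation
    of the coefficient estimates.
    """
    if model.spec.exposure_term != "spline_age_specific":
        raise ValueError("extract_erf_set requires spline_age_specific")
    curves = {g: extract_erf(model, g, reference_c0) for g in AGE_GROUPS}
    idx = np.concatenate(
        [model.design.exposure_cols[g] for g in AGE_GROUPS]
    ).astype(int)
    joint = model.cov.to_numpy()[np.ix_(idx, idx)]
    return ERFSet(groups=AGE_GROUPS, curves=curves, joint_cov=joint)
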