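"""Exposure-response functions (ERFs) for PM2.5 and stillbirth.

An ERF is a curve ``f(delta)`` giving the log relative odds of stillbirth
at excess concentration ``delta = max(C - C0, 0)`` above a reference level
``C0`` of minimum risk.  Two forms are supported:

* ``log_linear`` — ``f(delta) = beta * delta`` with ``beta`` in log-odds per
  ug/m3; this is the form of the meta-analytic pooled estimates, which are
  reported as odds ratios per 10 ug/m3.
* ``spline`` — a natural cubic spline in concentration, anchored so that
  ``f(0) = 0`` at the reference; this is the form produced by the
  conditional-logit spline fits and captures sublinear curvature.

Every ERF carries a coefficient covariance so that Monte Carlo uncertainty
propagation can re-draw whole curves.  Curves are anchored by construction:
the curve (and every sampled draw of it) is exactly zero at the reference
concentration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from ._splines import natural_spline_basis

AGE_GROUPS = ("<20", "20-29", "30-34", ">34")
ALL_AGES = "all_ages"

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ERF:
    """One exposure-response curve with coefficient uncertainty.

    Parameters
    ----------
    form : {"log_linear", "spline"}
    reference_c0 : float
        Reference concentration of minimum risk (ug/m3); the curve value
        is 0 at and below this concentration.
    coef : ndarray
        ``log_linear``: length-1 array holding beta (log-odds per ug/m3).
        ``spline``: coefficients of the natural-spline basis evaluated on
        the concentration scale.
    cov : ndarray
        Covariance of ``coef``; required for :meth:`sample`.
    knots : ndarray or None
        Spline knots on the concentration scale (``spline`` form only).
    age_group : str
        One of ``AGE_GROUPS`` or ``"all_ages"``.
    exposure_range : tuple of float
        Concentration support the curve was fitted on; evaluation outside
        it is flagged as extrapolation.
    """

    form: str
    reference_c0: float
    coef: np.ndarray
    cov: np.ndarray | None = None
    knots: np.ndarray | None = None
    age_group: str = ALL_AGES
    exposure_range: tuple[float, float] = (0.0, np.inf)
    name: str = ""

    def __post_init__(self) -> None:
        if self.form not in ("log_linear", "spline"):
            raise ValueError(f"unknown ERF form {self.form!r}")
        self.coef = np.atleast_1d(np.asarray(self.coef, dtype=float))
        if self.cov is not None:
            self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.form == "spline":
            if self.knots is None:
                raise ValueError("spline ERF requires knots")
            self.knots = np.asarray(self.knots, dtype=float)
            if len(self.coef) != len(self.knots) - 1:
                raise ValueError(
                    f"spline ERF with {len(self.knots)} knots needs "
                    f"{len(self.knots) - 1} coefficients, got {len(self.coef)}"
                )

    # ------------------------------------------------------------------
    @classmethod
    def log_linear(
        cls,
        or_per_10: float,
        ci: tuple[float, float] | None = None,
        reference_c0: float = 0.0,
        age_group: str = ALL_AGES,
        name: str = "",
    ) -> "ERF":
        """Build a log-linear ERF from an odds ratio per 10 ug/m3.

        ``beta = ln(OR)/10``; if a 95% CI is given, the standard error is
        back-solved from the log-scale half width.
        """
        if or_per_10 <= 0:
            raise ValueError("odds ratio must be positive")
        beta = np.log(or_per_10) / 10.0
        cov = None
        if ci is not None:
            lo, hi = ci
            se = (np.log(hi) - np.log(lo)) / (2.0 * _Z95) / 10.0
            cov = np.array([[se**2]])
        return cls(
            form="log_linear",
            reference_c0=reference_c0,
            coef=np.array([beta]),
            cov=cov,
            age_group=age_group,
            name=name,
        )

    # ------------------------------------------------------------------
    def _curve_basis(self, conc: np.ndarray, c0: float) -> np.ndarray:
        """Difference basis B(max(C, c0)) - B(c0); one row per value."""
        conc = np.clip(np.asarray(conc, dtype=float), c0, None)
        if self.form == "log_linear":
            return (conc - c0)[:, None]
        b = natural_spline_basis(conc, self.knots)
        b0 = natural_spline_basis(np.array([c0]), self.knots)
        return b - b0

    def evaluate(
        self,
        concentration,
        c0: float | None = None,
        return_extrapolation: bool = False,
    ):
        """Log relative odds ``f(max(C - C0, 0))`` at the given concentrations.

        Parameters
        ----------
        concentration : array-like
            Ambient PM2.5 concentrations, ug/m3, nonnegative.
        c0 : float, optional
            Reference level; defaults to the ERF's own ``reference_c0``.
        return_extrapolation : bool
            Also return a boolean mask marking values evaluated outside
            the fitted exposure range (extrapolation is unreliable at
            both tails and must be surfaced, not silently accepted).
        """
        conc = np.atleast_1d(np.asarray(concentration, dtype=float))
        if np.any(conc < 0):
            raise ValueError("negative concentration")
        if c0 is None:
            c0 = self.reference_c0
        if c0 < 0:
            raise ValueError("negative reference concentration")
        f = self._curve_basis(conc, c0) @ self.coef
        if return_extrapolation:
            lo, hi = self.exposure_range
            extrap = (conc > hi) | ((conc > c0) & (conc < lo))
            return f, extrap
        return f

    def evaluate_ci(self, concentration, c0: float | None = None):
        """Pointwise delta-method 95% CI for the curve: (f, lo, hi)."""
        if self.cov is None:
            raise ValueError("ERF has no covariance")
        conc = np.atleast_1d(np.asarray(concentration, dtype=float))
        if c0 is None:
            c0 = self.reference_c0
        b = self._curve_basis(conc, c0)
        f = b @ self.coef
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", b, self.cov, b), 0.0))
        return f, f - _Z95 * se, f + _Z95 * se

    # ------------------------------------------------------------------
    def sample(self, n_draws: int, seed=None) -> np.ndarray:
        """Draw coefficient vectors from N(coef, cov); shape (n_draws, k).

        Draws are on the coefficient scale, so each draw is a smooth curve
        and is anchored at the reference by the same difference-basis
        construction as the point curve.
        """
        if self.cov is None:
            raise ValueError("ERF has no covariance; cannot sample")
        rng = np.random.default_rng(seed) if not isinstance(
            seed, np.random.Generator
        ) else seed
        if not np.any(self.cov):
            return np.tile(self.coef, (n_draws, 1))
        return rng.multivariate_normal(
            self.coef, self.cov, size=n_draws, method="svd"
        )

    def evaluate_draws(
        self, concentration, draws: np.ndarray, c0: float | None = None
    ) -> np.ndarray:
        """Evaluate many sampled curves at once; shape (n_draws, n_conc)."""
        conc = np.atleast_1d(np.asarray(concentration, dtype=float))
        if np.any(conc < 0):
            raise ValueError("negative concentration")
        if c0 is None:
            c0 = self.reference_c0
        return draws @ self._curve_basis(conc, c0).T

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "reference_c0": float(self.reference_c0),
            "coefficients": self.coef.tolist(),
            "covariance": None if self.cov is None else self.cov.tolist(),
            "knots": None if self.knots is None else self.knots.tolist(),
            "age_group": self.age_group,
            "exposure_range": [float(v) for v in self.exposure_range],
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ERF":
        return cls(
            form=d["form"],
            reference_c0=d["reference_c0"],
            coef=np.asarray(d["coefficients"], dtype=float),
            cov=None if d.get("covariance") is None
            else np.asarray(d["covariance"], dtype=float),
            knots=None if d.get("knots") is None
            else np.asarray(d["knots"], dtype=float),
            age_group=d.get("age_group", ALL_AGES),
            exposure_range=tuple(d.get("exposure_range", (0.0, np.inf))),
            name=d.get("name", ""),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ERF":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ERFSet:
    """Age-specific curves from one joint fit, with joint covariance.

    The four maternal-age curves come out of a single interaction model,
    so their coefficients share one covariance matrix; Monte Carlo draws
    sample all four curves jointly, preserving cross-curve correlation.
    """

    groups: tuple[str, ...]
    curves: dict = field(default_factory=dict)  # group -> ERF
    joint_cov: np.ndarray | None = None  # (G*k, G*k), block order = groups

    def __getitem__(self, group: str) -> ERF:
        return self.curves[group]

    def sample(self, n_draws: int, seed=None) -> dict:
        """Jointly sampled coefficient draws, {group: (n_draws, k)}."""
        rng = np.random.default_rng(seed) if not isinstance(
            seed, np.random.Generator
        ) else seed
        k = len(self.curves[self.groups[0]].coef)
        mean = np.concatenate([self.curves[g].coef for g in self.groups])
        if self.joint_cov is None or not np.any(self.joint_cov):
            flat = np.tile(mean, (n_draws, 1))
        else:
            flat = rng.multivariate_normal(
                mean, self.joint_cov, size=n_draws, method="svd"
            )
        return {
            g: flat[:, i * k : (i + 1) * k] for i, g in enumerate(self.groups)
        }

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "curves": {g: self.curves[g].to_dict() for g in self.groups},
            "joint_covariance": None if self.joint_cov is None
            else self.joint_cov.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ERFSet":
        return cls(
            groups=tuple(d["groups"]),
            curves={g: ERF.from_dict(c) for g, c in d["curves"].items()},
            joint_cov=None if d.get("joint_covariance") is None
            else np.asarray(d["joint_covariance"], dtype=float),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ERFSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ----------------------------------------------------------------------
def available_presets() -> dict:
    """The bundled meta-analytic log-linear presets, as raw metadata."""
    text = (
        resources.files("stillburden.data")
        .joinpath("meta_analysis_presets.json")
        .read_text()
    )
    return json.loads(text)


def preset(name: str) -> ERF:
    """A bundled log-linear ERF from a published meta-analysis.

    ``zhang2021`` — pooled OR 1.103 (95% CI 1.074, 1.131) per 10 ug/m3;
    ``xie2021`` — pooled OR 1.15 (95% CI 1.07, 1.25) per 10 ug/m3.
    """
    presets = available_presets()
    if name not in presets:
        raise KeyError(
            f"unknown ERF preset {name!r}; available: {sorted(presets)}"
        )
    p = presets[name]
    return ERF.log_linear(
        p["or_per_10"], ci=(p["ci_lo"], p["ci_hi"]), name=name
    )
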