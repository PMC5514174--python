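"""Repeated-measures covariate models for accuracy and signal detection.

Binary outcomes (detection / localization / joint DL accuracy on the
manipulated-image trials) are fitted with generalized estimating equations
clustered by subject — a marginal logistic model with a working correlation
structure (exchangeable by default) and robust sandwich standard errors.
Subject-level d' and c get the analogous linear GEE.  Response times enter
as octile levels: the data are split into eight equal groups, level 1 the
slowest and level 8 the fastest, used as a numeric predictor.

The modelling surface is statsmodels-style: build a
:class:`RepeatedMeasuresGEE` from a trial table, call :meth:`fit`, get a
:class:`RepeatedMeasuresResults` carrying B, odds ratios, robust 95% CIs,
p values and a ``summary()`` table.  ``fit_repeated_binary`` /
``fit_repeated_linear`` are the corresponding convenience constructors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .observer import COVARIATE_LEVELS

__all__ = [
    "RTLevels",
    "rt_octiles",
    "RepeatedMeasuresGEE",
    "RepeatedMeasuresResults",
    "fit_repeated_binary",
    "fit_repeated_linear",
    "FitError",
]

_SEPARATION_BOUND = 15.0  # |B| beyond this on a logit scale flags separation


class FitError(RuntimeError):
    """Estimating-equations fit failed to produce finite estimates."""


@dataclass(frozen=True)
class RTLevels:
    """Octile levels per observation (1 = slowest, 8 = fastest)."""

    levels: np.ndarray
    boundaries: np.ndarray  # 7 cut values, slow -> fast

    def __post_init__(self) -> None:
        if self.levels.min() < 1 or self.levels.max() > 8:
            raise ValueError("levels must lie in 1..8")


def rt_octiles(rts) -> RTLevels:
    """Split response times into eight equal-sized groups by rank.

    Groups differ in size by at most one; ties keep their input order
    (stable ranking).  The slowest observations get level 1.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.ndim != 1 or len(rts) < 8:
        raise ValueError("need a flat array of at least 8 response times")
    order = np.argsort(-rts, kind="stable")
    levels = np.empty(len(rts), dtype=int)
    chunks = np.array_split(order, 8)
    for lvl, idx in enumerate(chunks, start=1):
        levels[idx] = lvl
    boundaries = np.array([rts[chunk[-1]] for chunk in chunks[:-1]])
    return RTLevels(levels=levels, boundaries=boundaries)


def _nonref_level(covariate: str) -> str:
    return COVARIATE_LEVELS[covariate][1]


def _design_matrix(
    data: pd.DataFrame,
    predictors: tuple[str, ...],
    reference_overrides: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Intercept + numeric passthrough / reference-coded binary factors.

    Factors follow the descending category-order convention (reference =
    first listed level, e.g. male / low belief); ``reference_overrides``
    flips the coding of a factor.
    """
    reference_overrides = reference_overrides or {}
    X = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    for pred in predictors:
        if pred in COVARIATE_LEVELS:
            ref = reference_overrides.get(pred, COVARIATE_LEVELS[pred][0])
            levels = COVARIATE_LEVELS[pred]
            if ref not in levels:
                raise ValueError(f"{ref!r} is not a level of {pred!r}")
            coded = [lv for lv in levels if lv != ref][0]
            X[f"{pred}_{coded}"] = (data[pred] == coded).astype(float)
        else:
            X[pred] = data[pred].astype(float)
    return X


@dataclass
class RepeatedMeasuresResults:
    """Estimates from a subject-clustered estimating-equations fit."""

    coefficients: pd.DataFrame  # B, OR (binary), se, ci_lo, ci_hi, p, unstable
    outcome: str
    family: str
    working_correlation: str
    n_subjects: int
    n_obs: int

    def summary(self) -> str:
        lines = [
            f"Repeated-measures GEE ({self.family}, "
            f"{self.working_correlation} working correlation)",
            f"outcome: {self.outcome}   subjects: {self.n_subjects}   "
            f"observations: {self.n_obs}",
            "",
            self.coefficients.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)


class RepeatedMeasuresGEE:
    """Marginal regression with subject clusters and robust errors.

    Parameters
    ----------
    data : DataFrame with the outcome, predictors and a cluster column.
    outcome : name of a 0/1 (binomial) or real-valued (gaussian) column.
    predictors : mix of numeric column names and the binary factor names
        ``gender``, ``belief``, ``interest``, ``frequency``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        predictors: tuple[str, ...],
        groups: str = "subject_id",
        family: str = "binomial",
        working_correlation: str = "exchangeable",
        reference_overrides: dict[str, str] | None = None,
    ) -> None:
        if family not in ("binomial", "gaussian"):
            raise ValueError(f"unsupported family {family!r}")
        if working_correlation not in ("exchangeable", "independence"):
            raise ValueError(f"unsupported working correlation {working_correlation!r}")
        self.data = data.dropna(subset=[outcome]).copy()
        self.outcome = outcome
        self.predictors = tuple(predictors)
        self.groups = groups
        self.family = family
        self.working_correlation = working_correlation
        self.reference_overrides = reference_overrides

    def fit(self, maxiter: int = 100) -> RepeatedMeasuresResults:
        X = _design_matrix(self.data, self.predictors, self.reference_overrides)
        y = self.data[self.outcome].astype(float)
        fam = sm.families.Binomial() if self.family == "binomial" else sm.families.Gaussian()
        cov = (
            sm.cov_struct.Exchangeable()
            if self.working_correlation == "exchangeable"
            else sm.cov_struct.Independence()
        )
        model = sm.GEE(y, X, groups=self.data[self.groups], family=fam, cov_struct=cov)
        res = model.fit(maxiter=maxiter)
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)  # robust (sandwich) by default
        if not (np.isfinite(params).all() and np.isfinite(bse).all()):
            raise FitError(
                f"non-finite estimates for outcome {self.outcome!r}; "
                f"params={params}, se={bse}"
            )
        ci_lo, ci_hi = params - 1.96 * bse, params + 1.96 * bse
        pvals = np.asarray(res.pvalues)
        table = pd.DataFrame(
            {
                "B": params,
                "se": bse,
                "ci_lo": ci_lo,
                "ci_hi": ci_hi,
                "p": pvals,
                "unstable": np.abs(params) > _SEPARATION_BOUND,
            },
            index=X.columns,
        )
        if self.family == "binomial":
            table.insert(1, "OR", np.exp(params))
            table.insert(2, "or_ci_lo", np.exp(ci_lo))
            table.insert(3, "or_ci_hi", np.exp(ci_hi))
        return RepeatedMeasuresResults(
            coefficients=table,
            outcome=self.outcome,
            family=self.family,
            working_correlation=self.working_correlation,
            n_subjects=self.data[self.groups].nunique(),
            n_obs=len(self.data),
        )


_BINARY_OUTCOMES = {
    "detect_accuracy": "detect_correct",
    "locate_accuracy": "locate_correct",
    "dl_accuracy": "dl_correct",
}


def fit_repeated_binary(
    trials: pd.DataFrame,
    outcome: str = "detect_accuracy",
    predictors: tuple[str, ...] | None = None,
    working_correlation: str = "exchangeable",
    reference_overrides: dict[str, str] | None = None,
) -> RepeatedMeasuresResults:
    """GEE binary logistic model on the manipulated-image trials.

    ``locate_accuracy`` drops trials without a localization response (in
    the detect-first design those are the "no" trials, replicating the
    exclusion of missing location data); ``dl_accuracy`` is the joint
    detect-and-locate success and requires the locate-always design.
    RT octiles are computed on the rows entering the model.
    """
    if outcome not in _BINARY_OUTCOMES:
        raise ValueError(f"unknown binary outcome {outcome!r}")
    data = trials[trials["is_manipulated"]].copy()
    if outcome == "dl_accuracy":
        if data["locate_region"].isna().any():
            raise ValueError("dl_accuracy requires a location response on every trial")
        data["dl_correct"] = (
            data["detect_correct"].astype(bool) & (data["locate_correct"] > 0.5)
        ).astype(float)
    elif outcome == "locate_accuracy":
        data = data.dropna(subset=["locate_correct"])
    data[_BINARY_OUTCOMES[outcome]] = data[_BINARY_OUTCOMES[outcome]].astype(float)

    if len(data) >= 8:
        data["rt_level_detect"] = rt_octiles(data["rt_detect"].to_numpy()).levels
        if data["rt_locate"].notna().all():
            data["rt_level_locate"] = rt_octiles(data["rt_locate"].to_numpy()).levels
    if predictors is None:
        factors = ("belief", "gender", "interest", "frequency")
        if outcome == "detect_accuracy":
            predictors = ("rt_level_detect",) + factors
        elif outcome == "locate_accuracy":
            rt = ("rt_level_locate",) if "rt_level_locate" in data else ()
            predictors = rt + factors
        else:
            predictors = ("rt_level_detect", "rt_level_locate") + factors
    return RepeatedMeasuresGEE(
        data,
        outcome=_BINARY_OUTCOMES[outcome],
        predictors=predictors,
        family="binomial",
        working_correlation=working_correlation,
        reference_overrides=reference_overrides,
    ).fit()


def fit_repeated_linear(
    subject_stats: pd.DataFrame,
    outcome: str = "d_prime",
    predictors: tuple[str, ...] = ("belief", "gender", "interest", "frequency"),
    working_correlation: str = "independence",
    reference_overrides: dict[str, str] | None = None,
) -> RepeatedMeasuresResults:
    """Linear GEE for subject-level signal-detection estimates.

    ``subject_stats`` carries one row per subject (``d_prime``, ``c`` plus
    the covariates); with one observation per cluster the GEE reduces to a
    linear model with heteroskedasticity-robust errors.
    """
    if outcome not in ("d_prime", "c"):
        raise ValueError("linear outcomes are 'd_prime' and 'c'")
    return RepeatedMeasuresGEE(
        subject_stats,
        outcome=outcome,
        predictors=predictors,
        family="gaussian",
        working_correlation=working_correlation,
        reference_overrides=reference_overrides,
    ).fit()
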