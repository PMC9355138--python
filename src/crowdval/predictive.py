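"""Regression battery: crowd scores predicting behaviors, experiences, traits.

Each of the ten crowd scores (two instruments x five crowds) predicts each of
eleven outcomes — seven dichotomous behaviors via logistic regression
(reported as adjusted odds ratios per score point) and four continuous
scores via linear regression (unstandardized B per score point).  Every
model controls for age in years, gender (reference: female), and
race/ethnicity (reference: non-Hispanic white); region is not a control.

By default each crowd score is entered in its own model; a joint mode
entering all five scores of an instrument together is available but is
unstable under the instruments' ipsative score structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from crowdval.crowds import BEHAVIORS, CROWDS, TRAIT_OUTCOMES

GENDER_LEVELS = ("female", "male", "another identity")
RACE_LEVELS = ("NH white", "Hispanic", "NH Black", "NH API", "NH other/multiracial")

BINARY_OUTCOMES = tuple(f"current_use_{b}" for b in BEHAVIORS[:-1]) + ("sad_hopeless",)
CONTINUOUS_OUTCOMES = TRAIT_OUTCOMES


class RegressionError(RuntimeError):
    """Estimation failure for one outcome-predictor pair."""


class DegenerateOutcomeError(RegressionError):
    """Binary outcome with a single observed class."""


@dataclass(frozen=True)
class RegressionSpec:
    """One model: an outcome, a predictor score column, fixed covariates."""

    outcome: str
    family: str                      # "binary" or "continuous"
    predictor: str                   # scored-table column, e.g. vmls_score_country
    extra_predictors: tuple[str, ...] = ()   # additional score columns (joint mode)

    def __post_init__(self):
        if self.family not in ("binary", "continuous"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class RegressionEstimate:
    coefficient: float
    se: float
    p: float
    n: int
    aor: float | None = None         # exp(coefficient), binary outcomes only


def _design(table: pd.DataFrame, spec: RegressionSpec) -> tuple[pd.Series, pd.DataFrame]:
    cols = [spec.outcome, spec.predictor, *spec.extra_predictors,
            "age", "gender", "race_ethnicity"]
    data = table[cols].dropna()
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X[spec.predictor] = data[spec.predictor].astype(float)
    for extra in spec.extra_predictors:
        X[extra] = data[extra].astype(float)
    X["age"] = data["age"].astype(float)
    for level in GENDER_LEVELS[1:]:
        X[f"gender[{level}]"] = (data["gender"] == level).astype(float)
    for level in RACE_LEVELS[1:]:
        X[f"race[{level}]"] = (data["race_ethnicity"] == level).astype(float)
    # drop constant dummy columns (empty cells) so the design stays full rank
    keep = [c for c in X.columns
            if c == "const" or X[c].nunique() > 1]
    dropped_predictor = spec.predictor not in keep
    X = X[keep]
    if dropped_predictor:
        raise RegressionError(
            f"{spec.outcome} ~ {spec.predictor}: predictor has zero variance")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise RegressionError(
            f"{spec.outcome} ~ {spec.predictor}: design matrix rank-deficient "
            f"(rank {rank} < {X.shape[1]}); columns: {list(X.columns)}")
    return data[spec.outcome], X


def fit_logistic(spec: RegressionSpec, table: pd.DataFrame) -> RegressionEstimate:
    """Maximum-likelihood logistic fit; returns the AOR per score point."""
    y, X = _design(table, spec)
    y = y.astype(float)
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise RegressionError(f"{spec.outcome}: outcome is not binary 0/1")
    if len(classes) < 2:
        raise DegenerateOutcomeError(
            f"{spec.outcome} ~ {spec.predictor}: outcome has a single class")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as exc:  # separation, singular information matrix, ...
        raise RegressionError(
            f"{spec.outcome} ~ {spec.predictor}: {exc}") from exc
    if not getattr(res, "converged", True):
        raise RegressionError(
            f"{spec.outcome} ~ {spec.predictor}: IRLS did not converge")
    if not np.all(np.isfinite(res.bse)):
        raise RegressionError(
            f"{spec.outcome} ~ {spec.predictor}: non-finite standard errors "
            "(quasi-separation)")
    coef = float(res.params[spec.predictor])
    return RegressionEstimate(
        coefficient=coef,
        se=float(res.bse[spec.predictor]),
        p=float(res.pvalues[spec.predictor]),
        n=int(res.nobs),
        aor=float(np.exp(coef)),
    )


def fit_linear(spec: RegressionSpec, table: pd.DataFrame) -> RegressionEstimate:
    """Ordinary least squares; returns unstandardized B per score point."""
    y, X = _design(table, spec)
    res = sm.OLS(y.astype(float), X).fit()
    return RegressionEstimate(
        coefficient=float(res.params[spec.predictor]),
        se=float(res.bse[spec.predictor]),
        p=float(res.pvalues[spec.predictor]),
        n=int(res.nobs),
        aor=None,
    )


def _score_col(instrument: str, crowd: str) -> str:
    prefix = "ibase" if instrument == "IBASE" else "vmls"
    return f"{prefix}_score_{crowd.lower().replace(' ', '_')}"


def run_prediction_battery(scored_table: pd.DataFrame,
                           mode: str = "separate") -> pd.DataFrame:
    """All 110 models: 2 instruments x 5 crowds x 11 outcomes.

    Per-cell estimation failures are recorded in the ``error`` column
    without aborting the battery.  ``mode='joint'`` enters all five crowd
    scores of an instrument simultaneously.
    """
    if mode not in ("separate", "joint"):
        raise ValueError(f"unknown mode {mode!r}")
    outcomes = ([(o, "binary") for o in BINARY_OUTCOMES]
                + [(o, "continuous") for o in CONTINUOUS_OUTCOMES])
    rows = []
    for instrument in ("IBASE", "VMLS"):
        for crowd in CROWDS:
            predictor = _score_col(instrument, crowd)
            extras = (tuple(_score_col(instrument, c) for c in CROWDS if c != crowd)
                      if mode == "joint" else ())
            for outcome, family in outcomes:
                spec = RegressionSpec(outcome=outcome, family=family,
                                      predictor=predictor, extra_predictors=extras)
                row = {"instrument": instrument, "crowd": crowd,
                       "outcome": outcome, "family": family,
                       "coefficient": np.nan, "se": np.nan, "p": np.nan,
                       "aor": np.nan, "n": 0, "error": ""}
                try:
                    est = (fit_logistic(spec, scored_table) if family == "binary"
                           else fit_linear(spec, scored_table))
                    row.update(coefficient=est.coefficient, se=est.se, p=est.p,
                               n=est.n, aor=est.aor if est.aor is not None else np.nan)
                except RegressionError as exc:
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)


def battery_wide(battery: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long battery into the published layout: outcome rows,
    instrument-by-crowd columns, AOR for binary outcomes and B otherwise."""
    df = battery.copy()
    df["value"] = np.where(df["family"] == "binary", df["aor"], df["coefficient"])
    df.loc[df["error"] != "", "value"] = np.nan
    wide = df.pivot_table(index="outcome", columns=["crowd", "instrument"],
                          values="value", sort=False)
    order = [o for o in list(BINARY_OUTCOMES) + list(CONTINUOUS_OUTCOMES)
             if o in wide.index]
    return wide.loc[order]
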