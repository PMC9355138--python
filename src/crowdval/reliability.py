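"""McDonald's omega from a one-factor model fit to item-level data.

The fit runs on the sample correlation matrix (items standardized), by
unweighted least squares on the off-diagonal residuals by default, with
maximum likelihood available.  With unit item variances the uniquenesses are
``theta_i = 1 - lambda_i**2``; negative values (Heywood cases) are clamped to
zero and flagged.  Omega is ``(sum lambda)^2 / ((sum lambda)^2 + sum theta)``.

Item definitions for the two instruments (neither instrument prescribes
one; both are configurable through the extraction helpers):

* ranked-choice crowd subscale: the 7 per-question point contributions to
  that crowd (values in {0, 0.5 or 1, 2});
* photo-grid crowd subscale: one signed selection indicator per photo of
  that crowd (+1 best-fit, -1 least-fit, 0 unselected).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from crowdval.crowds import CROWDS, N_BEST, N_LEAST, N_VMLS_QUESTIONS, rank2_weight


class EstimationError(RuntimeError):
    """Raised when the one-factor fit fails to converge or is infeasible."""


@dataclass(frozen=True)
class ItemMatrix:
    """Item-level contributions for one crowd subscale of one instrument."""

    values: np.ndarray  # (n_respondents, k_items)
    item_labels: tuple[str, ...]
    crowd: str
    instrument: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] < 2:
            raise ValueError("item matrix needs >= 2 item columns")
        if v.shape[1] != len(self.item_labels):
            raise ValueError("item_labels length must match column count")
        if not np.all(np.isfinite(v)):
            raise ValueError("item matrix contains missing or non-finite cells")
        object.__setattr__(self, "values", v)

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FactorFit:
    loadings: np.ndarray
    uniquenesses: np.ndarray
    heywood: bool
    method: str
    n_iter: int


def _correlation(values: np.ndarray) -> np.ndarray:
    sds = values.std(axis=0, ddof=1)
    constant = np.flatnonzero(sds == 0)
    if constant.size:
        raise EstimationError(
            f"items {constant.tolist()} are constant; correlation undefined")
    return np.corrcoef(values, rowvar=False)


def fit_one_factor(items: ItemMatrix, method: str = "uls",
                   max_iter: int = 500) -> FactorFit:
    """Fit a single-factor model to the items' correlation matrix.

    Returns standardized loadings and uniquenesses; loadings are sign-fixed
    so their sum is non-negative.  Two-item matrices use the equal-loading
    constraint (the unconstrained model would be under-identified).
    """
    if method not in ("uls", "ml"):
        raise ValueError(f"unknown method {method!r}")
    R = _correlation(items.values)
    k = items.k

    if k == 2:
        r12 = R[0, 1]
        s = np.sqrt(abs(r12))
        lam = np.array([s, s]) if r12 >= 0 else np.array([s, -s])
        theta = 1.0 - lam**2
        return FactorFit(lam, np.maximum(theta, 0.0), bool(np.any(theta < 0)),
                         method, 0)

    mask = ~np.eye(k, dtype=bool)

    def uls_obj(lam: np.ndarray) -> float:
        # full-matrix ULS with uniquenesses profiled out at theta >= 0:
        # off-diagonal residuals plus the clamped diagonal residual
        resid = (R - np.outer(lam, lam))[mask]
        diag_pen = np.maximum(lam**2 - 1.0, 0.0)
        return 0.5 * float(resid @ resid) + 0.5 * float(diag_pen @ diag_pen)

    def ml_obj(lam: np.ndarray) -> float:
        theta = np.maximum(1.0 - lam**2, 1e-6)
        sigma = np.outer(lam, lam) + np.diag(theta)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf
        return float(logdet + np.trace(np.linalg.solve(sigma, R)))

    obj = uls_obj if method == "uls" else ml_obj
    # start from the top eigenpair, scaled by the eigenvalue *excess* over 1
    # (for an equal-loading model the top eigenvalue is 1 + (k-1) lambda^2,
    # so pure-noise data starts near zero instead of near the unit vector)
    w, v = np.linalg.eigh(R)
    scale = np.sqrt(max(w[-1] - 1.0, 0.0) / (k - 1)) * np.sqrt(k)
    start = np.clip(v[:, -1] * scale, -0.99, 0.99)
    if start.sum() < 0:
        start = -start
    bounds = [(-0.999, 0.999)] * k if method == "ml" else [(-2.0, 2.0)] * k
    res = optimize.minimize(obj, start, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": max_iter})
    if not res.success and "MAXITER" in str(res.message).upper():
        raise EstimationError(
            f"one-factor fit did not converge in {res.nit} iterations")
    lam = res.x
    if lam.sum() < 0:
        lam = -lam
    theta = 1.0 - lam**2
    heywood = bool(np.any(theta < -1e-10))
    return FactorFit(lam, np.maximum(theta, 0.0), heywood, method, int(res.nit))


@dataclass(frozen=True)
class OmegaResult:
    omega: float
    heywood: bool
    fit: FactorFit


def mcdonalds_omega(items: ItemMatrix, method: str = "uls") -> OmegaResult:
    """Composite reliability of the subscale's unit-weighted total score."""
    fit = fit_one_factor(items, method=method)
    s = fit.loadings.sum()
    denom = s**2 + fit.uniquenesses.sum()
    omega = float(s**2 / denom) if denom > 0 else 0.0
    return OmegaResult(omega=omega, heywood=fit.heywood, fit=fit)


# ---------------------------------------------------------------------------
# item extraction from a cohort table
# ---------------------------------------------------------------------------


def vmls_item_matrix(table: pd.DataFrame, crowd: str) -> ItemMatrix:
    """Per-question point contributions to ``crowd`` (7 items)."""
    if crowd not in CROWDS:
        raise ValueError(f"unknown crowd {crowd!r}")
    w = rank2_weight(crowd)
    cols = []
    labels = []
    for q in range(1, N_VMLS_QUESTIONS + 1):
        r1 = table[f"vmls_q{q}_rank1"].to_numpy()
        r2 = table[f"vmls_q{q}_rank2"].to_numpy()
        cols.append(2.0 * (r1 == crowd) + w * (r2 == crowd))
        labels.append(f"q{q}")
    return ItemMatrix(np.column_stack(cols), tuple(labels), crowd, "VMLS")


def ibase_item_matrix(table: pd.DataFrame, crowd: str,
                      grids: Sequence[Mapping[str, str]]) -> ItemMatrix:
    """Signed selection indicator per photo of ``crowd`` across all grids."""
    if crowd not in CROWDS:
        raise ValueError(f"unknown crowd {crowd!r}")
    cols = []
    labels = []
    for g, grid in enumerate(grids, start=1):
        best = np.column_stack([table[f"ibase_g{g}_best_{j}"].to_numpy()
                                for j in range(1, N_BEST + 1)])
        least = np.column_stack([table[f"ibase_g{g}_least_{j}"].to_numpy()
                                 for j in range(1, N_LEAST + 1)])
        for pid, c in grid.items():
            if c != crowd:
                continue
            col = ((best == pid).any(axis=1).astype(float)
                   - (least == pid).any(axis=1).astype(float))
            cols.append(col)
            labels.append(pid)
    if len(cols) < 2:
        raise EstimationError(f"crowd {crowd!r} has fewer than 2 photos in the grids")
    return ItemMatrix(np.column_stack(cols), tuple(labels), crowd, "IBASE")


def reliability_table(table: pd.DataFrame,
                      grids: Sequence[Mapping[str, str]],
                      method: str = "uls") -> pd.DataFrame:
    """Omega for every (instrument, crowd) subscale — the MTMM diagonal.

    Subscales whose fit fails (constant items in a degenerate cohort,
    non-convergence) get ``omega = NaN`` with the error recorded, so one bad
    cell does not abort the table.
    """
    rows = []
    for instrument in ("IBASE", "VMLS"):
        for crowd in CROWDS:
            try:
                items = (ibase_item_matrix(table, crowd, grids)
                         if instrument == "IBASE" else vmls_item_matrix(table, crowd))
                result = mcdonalds_omega(items, method=method)
                rows.append({"instrument": instrument, "crowd": crowd,
                             "k_items": items.k, "omega": result.omega,
                             "heywood_flag": result.heywood, "error": ""})
            except (EstimationError, ValueError) as exc:
                rows.append({"instrument": instrument, "crowd": crowd,
                             "k_items": np.nan, "omega": np.nan,
                             "heywood_flag": False, "error": str(exc)})
    return pd.DataFrame(rows)
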