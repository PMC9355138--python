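"""Multi-trait multi-method matrix construction and validity decision rules.

Ten measures — five crowd scores from each of two instruments — yield a
10x10 correlation matrix whose diagonal carries each measure's reliability
(omega) rather than 1.  Convergent validity for a crowd requires the
monotrait-heteromethod correlation (same crowd, different instruments) to be
positive and significant.  Every other cell satisfies discriminant validity
unless it is significant, positive, and at least as large as either of the
convergent coefficients for the two crowds it involves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from crowdval.crowds import CROWDS

METHODS = ("IBASE", "VMLS")

#: Printed significance markers mapped to the p-value upper bound they imply.
SIG_MARKER_P = {"***": 0.001, "**": 0.01, "*": 0.05, "": 1.0}


class UndefinedCorrelationError(ValueError):
    """A correlation was requested for a zero-variance vector."""


def pearson_with_p(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-test p-value.

    ``p`` comes from ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equal-length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _labels() -> tuple[tuple[str, str], ...]:
    return tuple((m, c) for m in METHODS for c in CROWDS)


@dataclass
class MtmmMatrix:
    """10x10 trait-by-method correlation matrix with a reliability diagonal.

    ``labels`` orders measures photo-grid x 5 crowds, then ranked-choice x 5;
    ``correlations`` holds NaN on the diagonal, where ``reliabilities``
    (omega, possibly NaN when unavailable) applies instead.
    """

    correlations: np.ndarray
    p_values: np.ndarray
    reliabilities: np.ndarray
    labels: tuple[tuple[str, str], ...] = field(default_factory=_labels)

    def __post_init__(self):
        self.correlations = np.asarray(self.correlations, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.reliabilities = np.asarray(self.reliabilities, dtype=float)
        k = len(self.labels)
        if self.correlations.shape != (k, k) or self.p_values.shape != (k, k):
            raise ValueError(f"matrices must be {k}x{k}")
        if self.reliabilities.shape != (k,):
            raise ValueError(f"need {k} reliabilities")
        off = ~np.eye(k, dtype=bool)
        if not np.allclose(self.correlations[off], self.correlations.T[off],
                           equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(self.correlations[off])) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")

    def index(self, method: str, crowd: str) -> int:
        return self.labels.index((method, crowd))

    def cell(self, a: tuple[str, str], b: tuple[str, str]) -> tuple[float, float]:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.correlations[i, j]), float(self.p_values[i, j])

    def monotrait_heteromethod(self) -> dict[str, tuple[float, float]]:
        """The five convergent cells: crowd -> (r, p)."""
        return {c: self.cell((METHODS[0], c), (METHODS[1], c)) for c in CROWDS}

    def to_dataframe(self, kind: str = "r") -> pd.DataFrame:
        """Render as a labeled table; ``kind='r'`` puts omega on the diagonal."""
        names = [f"{m}:{c}" for m, c in self.labels]
        if kind == "r":
            m = self.correlations.copy()
            np.fill_diagonal(m, self.reliabilities)
        elif kind == "p":
            m = self.p_values
        else:
            raise ValueError("kind must be 'r' or 'p'")
        return pd.DataFrame(m, index=names, columns=names)


def build_mtmm(scored_table: pd.DataFrame,
               reliabilities: Mapping[tuple[str, str], float]) -> MtmmMatrix:
    """Correlate all ten crowd-score columns of a scored cohort table.

    ``reliabilities`` maps (instrument, crowd) to omega for the diagonal.
    Requires at least 3 respondents with complete scores.
    """
    def colname(method: str, crowd: str) -> str:
        prefix = "ibase" if method == "IBASE" else "vmls"
        return f"{prefix}_score_{crowd.lower().replace(' ', '_')}"

    labels = _labels()
    cols = [colname(m, c) for m, c in labels]
    data = scored_table[cols].dropna()
    if len(data) < 3:
        raise ValueError(f"need >= 3 complete respondents, have {len(data)}")
    k = len(labels)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij = pearson_with_p(data[cols[i]], data[cols[j]])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rel = np.array([reliabilities.get(lab, np.nan) for lab in labels])
    return MtmmMatrix(correlations=r, p_values=p, reliabilities=rel, labels=labels)


# ---------------------------------------------------------------------------
# validity evaluation
# ---------------------------------------------------------------------------


@dataclass
class ValidityReport:
    """Outcome of the convergent/discriminant decision rules."""

    alpha: float
    convergent: dict[str, dict]           # crowd -> {r, p, passed}
    discriminant_violations: list[dict]   # cells failing the discriminant rule

    @property
    def all_convergent(self) -> bool:
        return all(v["passed"] for v in self.convergent.values())

    @property
    def n_convergent_passes(self) -> int:
        return sum(v["passed"] for v in self.convergent.values())

    @property
    def discriminant_ok(self) -> bool:
        return not self.discriminant_violations

    def to_json(self) -> str:
        return json.dumps({
            "alpha": self.alpha,
            "convergent": self.convergent,
            "discriminant_violations": self.discriminant_violations,
            "all_convergent": self.all_convergent,
            "discriminant_ok": self.discriminant_ok,
        }, indent=2)

    def to_text(self) -> str:
        lines = [f"Validity evaluation (alpha = {self.alpha:g})", ""]
        lines.append("Convergent cells (same crowd, both instruments):")
        for crowd, v in self.convergent.items():
            status = "PASS" if v["passed"] else "FAIL"
            lines.append(f"  {crowd:<12} r = {v['r']:+.2f}  p = {v['p']:.3g}  {status}")
        lines.append("")
        if self.discriminant_violations:
            lines.append("Discriminant violations:")
            for v in self.discriminant_violations:
                lines.append(
                    f"  {v['cell'][0]} x {v['cell'][1]}: r = {v['r']:+.2f} "
                    f"is not weaker than convergent r for {', '.join(v['fails_against'])}")
        else:
            lines.append("No discriminant violations.")
        return "\n".join(lines)


def evaluate_validity(matrix: MtmmMatrix, alpha: float = 0.05) -> ValidityReport:
    """Apply the convergent and discriminant decision rules to a matrix.

    A non-convergent cell violates discriminant validity when it is
    significant, positive, and >= either convergent coefficient of the two
    crowds it involves (i.e., it must be strictly weaker than both).
    Negative or non-significant cells always satisfy the rule.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if np.isnan(matrix.correlations[~np.eye(len(matrix.labels), dtype=bool)]).any():
        raise ValueError("matrix has missing off-diagonal cells")

    conv_cells = matrix.monotrait_heteromethod()
    convergent = {
        crowd: {"r": r, "p": p, "passed": bool(r > 0 and p < alpha)}
        for crowd, (r, p) in conv_cells.items()
    }

    violations = []
    labels = matrix.labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            (mi, ci), (mj, cj) = labels[i], labels[j]
            if ci == cj and mi != mj:
                continue  # the convergent cell itself
            r = matrix.correlations[i, j]
            p = matrix.p_values[i, j]
            if not (p < alpha and r > 0):
                continue
            fails = [c for c in {ci, cj} if r >= conv_cells[c][0]]
            if fails:
                violations.append({
                    "cell": [f"{mi}:{ci}", f"{mj}:{cj}"],
                    "r": float(r),
                    "p": float(p),
                    "fails_against": sorted(fails),
                    "convergent_r": {c: conv_cells[c][0] for c in (ci, cj)},
                })
    return ValidityReport(alpha=alpha, convergent=convergent,
                          discriminant_violations=violations)


# ---------------------------------------------------------------------------
# published-matrix fixture
# ---------------------------------------------------------------------------


def _parse_fixture(text: str) -> MtmmMatrix:
    labels = _labels()
    short = {}
    for m in METHODS:
        for c in CROWDS:
            tag = f"{c[0]}{'1' if m == 'IBASE' else '2'}"
            short[tag] = (m, c)
    k = len(labels)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    rel = np.full(k, np.nan)
    for line in text.strip().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        parts = [s.strip() for s in line.split(",")]
        kind = parts[0]
        if kind == "kind":
            continue  # header
        if kind == "omega":
            tag, value = parts[1], float(parts[2])
            rel[labels.index(short[tag])] = value
        elif kind == "r":
            tag_a, tag_b, value, sig = parts[1], parts[2], float(parts[3]), parts[4]
            i, j = labels.index(short[tag_a]), labels.index(short[tag_b])
            r[i, j] = r[j, i] = value
            p[i, j] = p[j, i] = SIG_MARKER_P[sig]
        else:
            raise ValueError(f"unknown fixture row kind {kind!r}")
    return MtmmMatrix(correlations=r, p_values=p, reliabilities=rel, labels=labels)


def load_published_matrix() -> MtmmMatrix:
    """The validation study's printed 10x10 matrix, packaged as a fixture.

    Significance markers are mapped to p-value upper bounds
    (``***`` -> 0.001, ``**`` -> 0.01, ``*`` -> 0.05, none -> 1.0), which is
    sufficient for the alpha = 0.05 decision rules.
    """
    text = resources.files("crowdval.data").joinpath("mtmm_published.csv").read_text()
    return _parse_fixture(text)


def published_fixture_text() -> str:
    """Raw text of the packaged published-matrix fixture."""
    return resources.files("crowdval.data").joinpath("mtmm_published.csv").read_text()
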