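"""Scoring rules for both peer-crowd instruments and the auxiliary scales.

Ranked-choice instrument: each of 7 questions contributes 2 points to the
rank-1 crowd and 1 point to the rank-2 crowd — except Alternative and
Mainstream, whose rank-2 selections earn 0.5 points (desirability-bias
counterweight).  Per-crowd scores span 0-14 in 0.5 steps and are never
rounded.

Photo-grid instrument: +2 points per best-fit photo, -2 per least-fit photo
of a crowd, over 2 grids x (3 best + 3 least); per-crowd scores span -12..12.

Auxiliary scales: ACE count 0-9; Brief Resilience Scale mean 1-5 after
reverse-coding items 2, 4, 6; abbreviated social-prioritization index mean
rescaled to 0-10; Brief Sensation Seeking Scale mean 1-5.  Past-30-day use
frequencies are dichotomized to any-use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from crowdval.crowds import (
    CROWDS,
    TIED,
    IBASE_POINTS_PER_PHOTO,
    N_BEST,
    N_LEAST,
    N_VMLS_QUESTIONS,
    rank2_weight,
)

BRS_REVERSED_ITEMS = (2, 4, 6)  # 1-based, published scale convention


class ValidationError(ValueError):
    """Raised when instrument responses fail structural validation."""


@dataclass(frozen=True)
class CrowdScoreSet:
    """One instrument's five crowd scores for a single respondent."""

    instrument: str  # "VMLS" or "IBASE"
    scores: dict[str, float]

    def __post_init__(self):
        if set(self.scores) != set(CROWDS):
            raise ValidationError(f"scores must cover exactly the crowds {CROWDS}")

    def as_array(self) -> np.ndarray:
        return np.array([self.scores[c] for c in CROWDS], dtype=float)


@dataclass(frozen=True)
class CrowdAssignment:
    """Single-crowd assignment: the unique argmax crowd, or tied."""

    label: str

    @property
    def is_tied(self) -> bool:
        return self.label == TIED


@dataclass(frozen=True)
class ScaleScores:
    """Auxiliary scale scores for one respondent."""

    ace: int
    brs: float
    spi: float
    bsss: float
    current_use: dict[str, int] = field(default_factory=dict)
    sad_hopeless: int = 0


def _check_crowd(crowd: str, where: str) -> None:
    if crowd not in CROWDS:
        raise ValidationError(f"{where}: unknown crowd {crowd!r}")


def score_vmls(vmls_choices: Sequence[tuple[str, str]],
               n_questions: int = N_VMLS_QUESTIONS) -> CrowdScoreSet:
    """Score the ranked-choice instrument from (rank1, rank2) crowd pairs.

    Parameters
    ----------
    vmls_choices
        One (rank1_crowd, rank2_crowd) pair per question.
    n_questions
        Expected number of questions (7 for the full instrument; smaller
        values support exhaustive-enumeration testing).
    """
    if len(vmls_choices) != n_questions:
        raise ValidationError(
            f"expected {n_questions} questions, got {len(vmls_choices)}")
    scores = {c: 0.0 for c in CROWDS}
    for q, pair in enumerate(vmls_choices, start=1):
        if len(pair) != 2:
            raise ValidationError(f"question {q}: need a (rank1, rank2) pair")
        rank1, rank2 = pair
        _check_crowd(rank1, f"question {q} rank 1")
        _check_crowd(rank2, f"question {q} rank 2")
        if rank1 == rank2:
            raise ValidationError(
                f"question {q}: rank 1 and rank 2 both map to {rank1!r}")
        scores[rank1] += 2.0
        scores[rank2] += rank2_weight(rank2)
    return CrowdScoreSet(instrument="VMLS", scores=scores)


def score_ibase(ibase_selections: Sequence[Mapping[str, Sequence[str]]],
                photo_crowd_map: Mapping[str, str],
                points_per_photo: float = IBASE_POINTS_PER_PHOTO) -> CrowdScoreSet:
    """Score the photo-grid instrument from per-grid best/least selections.

    ``ibase_selections`` holds one ``{"best": [...], "least": [...]}`` mapping
    of photo ids per grid; ``photo_crowd_map`` maps every photo id to its
    crowd.  Best-fit photos earn ``+points_per_photo`` for their crowd,
    least-fit photos ``-points_per_photo``.
    """
    scores = {c: 0.0 for c in CROWDS}
    for g, grid_sel in enumerate(ibase_selections, start=1):
        best = list(grid_sel["best"])
        least = list(grid_sel["least"])
        if len(best) != N_BEST or len(set(best)) != N_BEST:
            raise ValidationError(f"grid {g}: need {N_BEST} distinct best-fit photos")
        if len(least) != N_LEAST or len(set(least)) != N_LEAST:
            raise ValidationError(f"grid {g}: need {N_LEAST} distinct least-fit photos")
        overlap = set(best) & set(least)
        if overlap:
            raise ValidationError(
                f"grid {g}: best and least selections overlap: {sorted(overlap)}")
        for pid in best + least:
            if pid not in photo_crowd_map:
                raise ValidationError(f"grid {g}: unknown photo id {pid!r}")
        for pid in best:
            scores[photo_crowd_map[pid]] += points_per_photo
        for pid in least:
            scores[photo_crowd_map[pid]] -= points_per_photo
    return CrowdScoreSet(instrument="IBASE", scores=scores)


def assign_primary_crowd(score_set: CrowdScoreSet) -> CrowdAssignment:
    """Assign the unique highest-scoring crowd, or the tied label."""
    arr = score_set.as_array()
    top = arr.max()
    winners = [c for c, v in zip(CROWDS, arr) if v == top]
    return CrowdAssignment(label=winners[0] if len(winners) == 1 else TIED)


def score_ace(ace_items: Sequence[int]) -> int:
    """Count of adverse experiences endorsed (9 binary items, score 0-9)."""
    if len(ace_items) != 9:
        raise ValidationError(f"expected 9 ACE items, got {len(ace_items)}")
    for i, v in enumerate(ace_items, start=1):
        if v not in (0, 1):
            raise ValidationError(f"ACE item {i}: value {v!r} is not binary")
    return int(sum(ace_items))


def score_brs(brs_items: Sequence[float],
              reversed_items: Sequence[int] = BRS_REVERSED_ITEMS) -> float:
    """Resilience score 1-5: item mean after reverse-coding items 2, 4, 6."""
    if len(brs_items) != 6:
        raise ValidationError(f"expected 6 resilience items, got {len(brs_items)}")
    vals = []
    for i, v in enumerate(brs_items, start=1):
        if not 1 <= v <= 5:
            raise ValidationError(f"resilience item {i}: {v!r} outside 1-5")
        vals.append(6 - v if i in reversed_items else v)
    return float(np.mean(vals))


def score_spi(spi_items: Sequence[float],
              item_range: tuple[float, float] = (1, 5)) -> float:
    """Social-prioritization score: item mean linearly rescaled to 0-10."""
    if len(spi_items) != 8:
        raise ValidationError(f"expected 8 items, got {len(spi_items)}")
    lo, hi = item_range
    for i, v in enumerate(spi_items, start=1):
        if not lo <= v <= hi:
            raise ValidationError(f"item {i}: {v!r} outside {lo}-{hi}")
    return float((np.mean(spi_items) - lo) / (hi - lo) * 10.0)


def score_bsss(bsss_items: Sequence[float]) -> float:
    """Sensation-seeking score 1-5: plain item mean."""
    if len(bsss_items) != 8:
        raise ValidationError(f"expected 8 items, got {len(bsss_items)}")
    for i, v in enumerate(bsss_items, start=1):
        if not 1 <= v <= 5:
            raise ValidationError(f"item {i}: {v!r} outside 1-5")
    return float(np.mean(bsss_items))


def dichotomize_behavior(use_days: int) -> int:
    """Any past-30-day use (1) vs none (0)."""
    if not 0 <= use_days <= 30:
        raise ValidationError(f"use days {use_days!r} outside 0-30")
    return int(use_days >= 1)


# ---------------------------------------------------------------------------
# vectorized table scoring
# ---------------------------------------------------------------------------


def _slug(crowd: str) -> str:
    return crowd.lower().replace(" ", "_")


def score_table(table: pd.DataFrame,
                grids: Sequence[Mapping[str, str]],
                spi_item_range: tuple[float, float] = (1, 5)) -> pd.DataFrame:
    """Append all derived score columns to a raw cohort table.

    Adds, per crowd, ``vmls_score_*`` and ``ibase_score_*``; the two
    ``*_assignment`` columns; the four scale scores; and the seven
    dichotomous behavior columns.  Agrees exactly with the per-respondent
    scoring functions (tested by equivalence on random cohorts).
    """
    out = table.copy()
    n = len(out)

    vmls = np.zeros((n, len(CROWDS)))
    for q in range(1, N_VMLS_QUESTIONS + 1):
        r1 = out[f"vmls_q{q}_rank1"].to_numpy()
        r2 = out[f"vmls_q{q}_rank2"].to_numpy()
        for k, c in enumerate(CROWDS):
            vmls[:, k] += 2.0 * (r1 == c) + rank2_weight(c) * (r2 == c)
    for k, c in enumerate(CROWDS):
        out[f"vmls_score_{_slug(c)}"] = vmls[:, k]

    photo_map: dict[str, str] = {}
    for grid in grids:
        photo_map.update(grid)
    ibase = np.zeros((n, len(CROWDS)))
    for g in range(1, len(grids) + 1):
        for j in range(1, N_BEST + 1):
            crowd_col = out[f"ibase_g{g}_best_{j}"].map(photo_map).to_numpy()
            for k, c in enumerate(CROWDS):
                ibase[:, k] += IBASE_POINTS_PER_PHOTO * (crowd_col == c)
        for j in range(1, N_LEAST + 1):
            crowd_col = out[f"ibase_g{g}_least_{j}"].map(photo_map).to_numpy()
            for k, c in enumerate(CROWDS):
                ibase[:, k] -= IBASE_POINTS_PER_PHOTO * (crowd_col == c)
    for k, c in enumerate(CROWDS):
        out[f"ibase_score_{_slug(c)}"] = ibase[:, k]

    crowd_arr = np.array(CROWDS, dtype=object)
    for name, mat in (("vmls", vmls), ("ibase", ibase)):
        top = mat.max(axis=1)
        ties = (mat == top[:, None]).sum(axis=1) > 1
        labels = crowd_arr[mat.argmax(axis=1)]
        labels[ties] = TIED
        out[f"{name}_assignment"] = labels

    out["ace_score"] = sum(out[f"ace_{i}"] for i in range(1, 10))

    brs_cols = []
    for i in range(1, 7):
        v = out[f"brs_{i}"]
        brs_cols.append(6 - v if i in BRS_REVERSED_ITEMS else v)
    out["brs_score"] = pd.concat(brs_cols, axis=1).mean(axis=1)

    lo, hi = spi_item_range
    spi_mean = pd.concat([out[f"spi_{i}"] for i in range(1, 9)], axis=1).mean(axis=1)
    out["spi_score"] = (spi_mean - lo) / (hi - lo) * 10.0

    out["bsss_score"] = pd.concat([out[f"bsss_{i}"] for i in range(1, 9)],
                                  axis=1).mean(axis=1)

    from crowdval.crowds import SUBSTANCES
    for sub in SUBSTANCES:
        out[f"current_use_{sub}"] = (out[f"use_days_{sub}"] >= 1).astype(np.int64)

    return out


def score_columns() -> list[str]:
    """Names of all columns :func:`score_table` appends, in order."""
    from crowdval.crowds import SUBSTANCES
    cols = [f"vmls_score_{_slug(c)}" for c in CROWDS]
    cols += [f"ibase_score_{_slug(c)}" for c in CROWDS]
    cols += ["vmls_assignment", "ibase_assignment"]
    cols += ["ace_score", "brs_score", "spi_score", "bsss_score"]
    cols += [f"current_use_{s}" for s in SUBSTANCES]
    return cols
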