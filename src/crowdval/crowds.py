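"""Shared vocabulary: the five peer crowds and instrument-wide constants."""

from __future__ import annotations

#: Canonical crowd order used everywhere (scores, matrices, config arrays).
CROWDS: tuple[str, ...] = ("Alternative", "Country", "Hip Hop", "Mainstream", "Popular")

#: Assignment label when no unique highest score exists.
TIED = "Tied"

#: Crowds whose rank-2 selections earn half a point instead of a full point
#: (a desirability-bias counterweight built into the ranked-choice scoring).
HALF_POINT_RANK2: frozenset[str] = frozenset({"Alternative", "Mainstream"})

#: Number of ranked-choice questions in the mindset instrument.
N_VMLS_QUESTIONS = 7

#: Photo-grid instrument layout: grids per administration, selections per grid.
N_GRIDS = 2
N_BEST = 3
N_LEAST = 3

#: Points per photo selection (+ for best-fit, - for least-fit).  With
#: 2 grids x (3 best + 3 least), +/-2 per selection spans the documented
#: -12..12 range.
IBASE_POINTS_PER_PHOTO = 2.0

CROWD_INDEX = {c: i for i, c in enumerate(CROWDS)}

#: Six substances with past-30-day use-frequency items, in reporting order.
SUBSTANCES: tuple[str, ...] = (
    "cigarettes",
    "lcc",
    "smokeless",
    "vape",
    "alcohol",
    "marijuana",
)

#: Dichotomous outcomes of the prediction battery: current use of the six
#: substances plus the sad/hopeless indicator.
BEHAVIORS: tuple[str, ...] = SUBSTANCES + ("sad_hopeless",)

#: Continuous outcomes of the prediction battery.
TRAIT_OUTCOMES: tuple[str, ...] = ("ace_score", "brs_score", "spi_score", "bsss_score")


def rank2_weight(crowd: str) -> float:
    """Rank-2 point weight for ``crowd`` in the ranked-choice instrument."""
    return 0.5 if crowd in HALF_POINT_RANK2 else 1.0
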