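import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdval.cohort import CohortConfig, default_grids, generate_cohort
from crowdval.crowds import CROWDS, TIED
from crowdval.instruments import (
    CrowdScoreSet,
    ValidationError,
    assign_primary_crowd,
    dichotomize_behavior,
    score_ace,
    score_bsss,
    score_brs,
    score_ibase,
    score_spi,
    score_table,
    score_vmls,
)

A, C, H, M, P = CROWDS

ORDERED_PAIRS = [(a, b) for a in CROWDS for b in CROWDS if a != b]
pair_strategy = st.sampled_from(ORDERED_PAIRS)
choices_strategy = st.lists(pair_strategy, min_size=7, max_size=7)


def enumerate_vmls_scores(choices):
    """Independent scoring oracle: count-based, no shared code path."""
    rank1_counts = Counter(r1 for r1, _ in choices)
    rank2_counts = Counter(r2 for _, r2 in choices)
    return {
        crowd: 2 * rank1_counts[crowd]
        + (0.5 if crowd in (A, M) else 1) * rank2_counts[crowd]
        for crowd in CROWDS
    }


class TestScoreVmls:
    def test_maximum_score(self):
        s = score_vmls([(H, C)] * 7)
        assert s.scores[H] == 14
        assert s.scores[C] == 7
        assert all(s.scores[c] == 0 for c in (A, M, P))

    def test_half_point_rule(self):
        s = score_vmls([(P, A)] * 7)
        assert s.scores[A] == 3.5
        assert s.scores[P] == 14

    def test_mixed_ranks_hand_enumeration(self):
        # 4 x (Country #1, Mainstream #2) + 3 x (Mainstream #1, Country #2)
        choices = [(C, M)] * 4 + [(M, C)] * 3
        s = score_vmls(choices)
        assert s.scores[C] == 4 * 2 + 3 * 1       # 11
        assert s.scores[M] == 3 * 2 + 4 * 0.5     # 8
        assert all(s.scores[c] == 0 for c in (A, H, P))

    def test_wrong_question_count(self):
        with pytest.raises(ValidationError, match="expected 7"):
            score_vmls([(H, C)] * 6)

    def test_duplicate_rank_names_question(self):
        choices = [(H, C)] * 3 + [(P, P)] + [(H, C)] * 3
        with pytest.raises(ValidationError, match="question 4"):
            score_vmls(choices)

    def test_unknown_crowd_names_question(self):
        with pytest.raises(ValidationError, match="question 1"):
            score_vmls([("Jocks", C)] + [(H, C)] * 6)

    def test_exhaustive_two_question_oracle(self):
        # every (rank1, rank2) pattern over 2 questions: 20 x 20 = 400 cases
        for q1, q2 in itertools.product(ORDERED_PAIRS, repeat=2):
            got = score_vmls([q1, q2], n_questions=2).scores
            assert got == enumerate_vmls_scores([q1, q2])

    @given(choices_strategy)
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence_and_bounds(self, choices):
        scores = score_vmls(choices).scores
        assert scores == enumerate_vmls_scores(choices)
        assert all(0 <= v <= 14 for v in scores.values())
        # per-respondent total = 14 rank-1 points + sum of rank-2 weights
        expected_total = 14 + sum(0.5 if r2 in (A, M) else 1 for _, r2 in choices)
        assert sum(scores.values()) == expected_total
        assert 17.5 <= expected_total <= 21


class TestScoreIbase:
    def setup_method(self):
        self.grids = default_grids(photos_per_crowd=3)
        self.map = {p: c for grid in self.grids for p, c in grid.items()}

    def _sel(self, best_by_grid, least_by_grid):
        return [{"best": b, "least": l} for b, l in zip(best_by_grid, least_by_grid)]

    def test_maximum_score(self):
        sel = self._sel(
            [[f"g1_hip_hop_{i}" for i in (1, 2, 3)], [f"g2_hip_hop_{i}" for i in (1, 2, 3)]],
            [[f"g1_country_{i}" for i in (1, 2, 3)], [f"g2_popular_{i}" for i in (1, 2, 3)]],
        )
        s = score_ibase(sel, self.map)
        assert s.scores[H] == 12
        assert s.scores[C] == -6 and s.scores[P] == -6

    def test_minimum_score(self):
        sel = self._sel(
            [[f"g1_country_{i}" for i in (1, 2, 3)], [f"g2_popular_{i}" for i in (1, 2, 3)]],
            [[f"g1_mainstream_{i}" for i in (1, 2, 3)], [f"g2_mainstream_{i}" for i in (1, 2, 3)]],
        )
        assert score_ibase(sel, self.map).scores[M] == -12

    def test_unselected_crowd_scores_zero(self):
        sel = self._sel(
            [[f"g1_country_{i}" for i in (1, 2, 3)], [f"g2_country_{i}" for i in (1, 2, 3)]],
            [[f"g1_popular_{i}" for i in (1, 2, 3)], [f"g2_popular_{i}" for i in (1, 2, 3)]],
        )
        s = score_ibase(sel, self.map)
        assert s.scores[A] == 0 and s.scores[H] == 0 and s.scores[M] == 0

    def test_scores_sum_to_zero(self):
        # equal +/- point magnitudes, one crowd per photo -> zero-sum
        sel = self._sel(
            [["g1_country_1", "g1_hip_hop_1", "g1_popular_2"],
             ["g2_mainstream_1", "g2_mainstream_2", "g2_alternative_3"]],
            [["g1_alternative_1", "g1_alternative_2", "g1_mainstream_3"],
             ["g2_country_2", "g2_hip_hop_3", "g2_popular_1"]],
        )
        assert sum(score_ibase(sel, self.map).scores.values()) == 0

    def test_unknown_photo_rejected(self):
        sel = self._sel(
            [["nope", "g1_hip_hop_1", "g1_popular_2"], ["g2_country_1", "g2_country_2", "g2_country_3"]],
            [["g1_alternative_1", "g1_alternative_2", "g1_mainstream_3"],
             ["g2_popular_1", "g2_popular_2", "g2_popular_3"]],
        )
        with pytest.raises(ValidationError, match="unknown photo id"):
            score_ibase(sel, self.map)

    def test_overlapping_best_least_rejected(self):
        sel = self._sel(
            [["g1_country_1", "g1_hip_hop_1", "g1_popular_2"],
             ["g2_country_1", "g2_country_2", "g2_country_3"]],
            [["g1_country_1", "g1_alternative_2", "g1_mainstream_3"],
             ["g2_popular_1", "g2_popular_2", "g2_popular_3"]],
        )
        with pytest.raises(ValidationError, match="overlap"):
            score_ibase(sel, self.map)


class TestAssignment:
    def test_unique_max(self):
        s = CrowdScoreSet("VMLS", dict(zip(CROWDS, [14, 0, 0, 0, 0])))
        assert assign_primary_crowd(s).label == A

    def test_two_way_tie(self):
        s = CrowdScoreSet("VMLS", dict(zip(CROWDS, [7, 7, 0, 0, 0])))
        assert assign_primary_crowd(s).label == TIED

    def test_all_zero_is_tied(self):
        s = CrowdScoreSet("IBASE", dict.fromkeys(CROWDS, 0))
        a = assign_primary_crowd(s)
        assert a.label == TIED and a.is_tied

    @given(st.lists(st.integers(-12, 12), min_size=5, max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_argmax_property(self, values):
        s = CrowdScoreSet("IBASE", dict(zip(CROWDS, values)))
        label = assign_primary_crowd(s).label
        top = max(values)
        if values.count(top) == 1:
            assert label == CROWDS[values.index(top)]
        else:
            assert label == TIED


class TestAuxScales:
    def test_ace(self):
        assert score_ace([0] * 9) == 0
        assert score_ace([1] * 9) == 9
        assert score_ace([1, 1, 0, 1, 0, 0, 0, 0, 1]) == 4
        with pytest.raises(ValidationError):
            score_ace([1] * 8)
        with pytest.raises(ValidationError, match="item 3"):
            score_ace([0, 0, 2, 0, 0, 0, 0, 0, 0])

    def test_brs_reverse_coding(self):
        assert score_brs([5, 1, 5, 1, 5, 1]) == 5.0
        assert score_brs([1, 5, 1, 5, 1, 5]) == 1.0
        assert score_brs([3, 3, 3, 3, 3, 3]) == 3.0

    def test_brs_range_check(self):
        with pytest.raises(ValidationError, match="item 2"):
            score_brs([3, 6, 3, 3, 3, 3])

    def test_spi_rescaling(self):
        assert score_spi([5] * 8) == 10.0
        assert score_spi([1] * 8) == 0.0
        assert score_spi([3] * 8) == 5.0

    def test_bsss(self):
        assert score_bsss([5] * 8) == 5.0
        assert score_bsss([1] * 8) == 1.0
        assert score_bsss([1, 2, 3, 4, 5, 5, 4, 3]) == 3.375

    def test_dichotomize(self):
        assert dichotomize_behavior(0) == 0
        assert dichotomize_behavior(1) == 1
        assert dichotomize_behavior(30) == 1
        with pytest.raises(ValidationError):
            dichotomize_behavior(-1)
        with pytest.raises(ValidationError):
            dichotomize_behavior(31)


class TestScoreTable:
    def test_matches_per_respondent_scoring(self, scored_cohort):
        cfg, scored = scored_cohort
        photo_map = {p: c for grid in cfg.grids for p, c in grid.items()}
        sample = scored.sample(n=50, random_state=0)
        for _, row in sample.iterrows():
            choices = [(row[f"vmls_q{q}_rank1"], row[f"vmls_q{q}_rank2"])
                       for q in range(1, 8)]
            vs = score_vmls(choices).scores
            sel = [{"best": [row[f"ibase_g{g}_best_{j}"] for j in (1, 2, 3)],
                    "least": [row[f"ibase_g{g}_least_{j}"] for j in (1, 2, 3)]}
                   for g in (1, 2)]
            ibs = score_ibase(sel, photo_map).scores
            for crowd in CROWDS:
                slug = crowd.lower().replace(" ", "_")
                assert row[f"vmls_score_{slug}"] == vs[crowd]
                assert row[f"ibase_score_{slug}"] == ibs[crowd]
            assert row["ace_score"] == score_ace([row[f"ace_{i}"] for i in range(1, 10)])
            assert row["brs_score"] == pytest.approx(
                score_brs([row[f"brs_{i}"] for i in range(1, 7)]))
            assert row["spi_score"] == pytest.approx(
                score_spi([row[f"spi_{i}"] for i in range(1, 9)]))
            assert row["bsss_score"] == pytest.approx(
                score_bsss([row[f"bsss_{i}"] for i in range(1, 9)]))

    def test_score_bounds(self, scored_cohort):
        _, scored = scored_cohort
        for crowd in CROWDS:
            slug = crowd.lower().replace(" ", "_")
            v = scored[f"vmls_score_{slug}"]
            assert v.between(0, 14).all()
            assert ((v * 2) == (v * 2).round()).all()  # 0.5 granularity
            ib = scored[f"ibase_score_{slug}"]
            assert ib.between(-12, 12).all()
        assert scored["ace_score"].between(0, 9).all()
        assert scored["brs_score"].between(1, 5).all()
        assert scored["spi_score"].between(0, 10).all()
        assert scored["bsss_score"].between(1, 5).all()

    def test_ibase_scores_sum_to_zero(self, scored_cohort):
        _, scored = scored_cohort
        total = sum(scored[f"ibase_score_{c.lower().replace(' ', '_')}"]
                    for c in CROWDS)
        assert (total == 0).all()
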