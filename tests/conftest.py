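import numpy as np
import pytest

from crowdval.cohort import CohortConfig, default_grids, generate_cohort
from crowdval.crowds import CROWDS
from crowdval.instruments import score_table


def uniform_config(n: int, seed: int, **overrides) -> CohortConfig:
    """Fully exchangeable config: chance-level fidelity, uniform affinities
    (including the least-fit diagonal), equal prevalences, no outcome effects."""
    uniform = np.full((5, 5), 0.2)
    offdiag = np.full((5, 5), 0.25)
    np.fill_diagonal(offdiag, 0.0)
    base = dict(
        n_respondents=n,
        seed=seed,
        crowd_prevalences={c: 0.2 for c in CROWDS},
        vmls_rank1_fidelity=0.2,
        vmls_affinity=offdiag,
        ibase_best_fidelity=0.2,
        ibase_least_affinity=uniform,
        behavior_crowd_logodds=np.zeros((5, 7)),
        trait_means={"brs": np.full(5, 3.0), "spi": np.full(5, 3.4),
                     "bsss": np.full(5, 3.3)},
        ace_prob=np.full(5, 0.3),
    )
    base.update(overrides)
    return CohortConfig(**base)


def high_fidelity_config(n: int, seed: int, fidelity: float = 0.8,
                         **overrides) -> CohortConfig:
    base = dict(n_respondents=n, seed=seed,
                vmls_rank1_fidelity=fidelity, ibase_best_fidelity=fidelity)
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    cfg = CohortConfig(n_respondents=800, seed=42)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    cfg, table = default_cohort
    return cfg, score_table(table, cfg.grids)


@pytest.fixture(scope="session")
def big_scored_cohort():
    """High-fidelity cohort for recovery-style tests, scored once."""
    cfg = high_fidelity_config(20_000, seed=7)
    table = generate_cohort(cfg)
    return cfg, score_table(table, cfg.grids)


@pytest.fixture()
def grids():
    return default_grids()
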