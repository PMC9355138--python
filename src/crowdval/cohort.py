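"""Synthetic respondent cohorts with a known latent peer-crowd structure.

Every respondent is assigned a latent crowd; instrument responses are then
drawn from a fidelity/affinity model, and behaviors, experiences, and traits
are drawn with crowd-specific effects.  The latent crowd is carried in the
output table (column ``latent_crowd``) strictly as a ground-truth oracle for
recovery tests — downstream analysis stages never read it.

Response model
--------------
* Ranked-choice instrument: per question, the rank-1 option matches the
  latent crowd with probability ``vmls_rank1_fidelity`` (otherwise uniform
  over the other four); the rank-2 option is drawn from the latent crowd's
  row of ``vmls_affinity`` restricted to options other than rank 1.
* Photo-grid instrument: per grid, three best-fit photos are drawn without
  replacement with per-photo weights calibrated so the first pick is an
  own-crowd photo with probability ``ibase_best_fidelity``; three least-fit
  photos are then drawn from the remainder with crowd weights from the
  latent crowd's row of ``ibase_least_affinity``.
* Dichotomous behaviors follow logistic(base + crowd effect); positive users
  get a uniform 1-30 day count.  Trait scales are built from a per-respondent
  latent target drawn at the crowd's mean/SD plus per-item rounding noise.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from crowdval.crowds import (
    CROWDS,
    CROWD_INDEX,
    BEHAVIORS,
    SUBSTANCES,
    N_BEST,
    N_LEAST,
    N_VMLS_QUESTIONS,
)

N_CROWDS = len(CROWDS)
N_ACE_ITEMS = 9
N_BRS_ITEMS = 6
N_SPI_ITEMS = 8
N_BSSS_ITEMS = 8
BRS_REVERSED = (2, 4, 6)  # 1-based item positions stored reverse-keyed

GENDERS = ("female", "male", "another identity")
RACE_ETHNICITIES = ("NH white", "Hispanic", "NH Black", "NH API", "NH other/multiracial")
REGIONS = ("North", "Central", "Southeast", "Southwest")
AGES = (13, 14, 15, 16, 17, 18)


class ConfigurationError(ValueError):
    """Raised when a :class:`CohortConfig` field fails validation."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


def _crowd_slug(crowd: str) -> str:
    return crowd.lower().replace(" ", "_")


def default_grids(photos_per_crowd: int = 2, n_grids: int = 2) -> list[dict[str, str]]:
    """Photo grids with ``photos_per_crowd`` photos per crowd per grid."""
    grids = []
    for g in range(1, n_grids + 1):
        grid = {}
        for crowd in CROWDS:
            for k in range(1, photos_per_crowd + 1):
                grid[f"g{g}_{_crowd_slug(crowd)}_{k}"] = crowd
        grids.append(grid)
    return grids


def _uniform_offdiag(diag_zero: bool = True) -> np.ndarray:
    m = np.full((N_CROWDS, N_CROWDS), 1.0 / (N_CROWDS - 1))
    np.fill_diagonal(m, 0.0)
    return m


def _default_prevalences() -> dict[str, float]:
    # Observed single-crowd assignment shares, renormalized over the five
    # crowds (ties excluded): 30.4 / 10.6 / 14.6 / 18.6 / 18.9 percent.
    raw = {"Alternative": 0.304, "Country": 0.106, "Hip Hop": 0.146,
           "Mainstream": 0.186, "Popular": 0.189}
    total = sum(raw.values())
    return {c: v / total for c, v in raw.items()}


def _default_behavior_base() -> dict[str, float]:
    # Intercepts chosen so marginal prevalences land near the observed
    # sample: ~8% cigarettes, ~5% LCC, ~2% smokeless, ~19% vape,
    # ~29% alcohol, ~20% marijuana, ~57% sad/hopeless.
    return {
        "cigarettes": -2.5,
        "lcc": -3.0,
        "smokeless": -3.7,
        "vape": -1.5,
        "alcohol": -0.9,
        "marijuana": -1.4,
        "sad_hopeless": 0.3,
    }


def _default_behavior_effects() -> np.ndarray:
    # Crowd-by-behavior log-odds shifts following the reported sign pattern:
    # rows Alternative, Country, Hip Hop, Mainstream, Popular; columns
    # cigarettes, lcc, smokeless, vape, alcohol, marijuana, sad_hopeless.
    return np.array(
        [
            [0.0, 0.0, -0.5, 0.0, 0.0, 0.5, 0.6],
            [0.5, 0.4, 0.9, 0.0, 0.0, 0.0, -0.5],
            [0.3, 0.6, 0.0, 0.5, 0.4, 0.5, 0.0],
            [-0.8, -0.8, -0.8, -0.7, -0.5, -0.8, -0.3],
            [0.0, 0.0, -0.4, 0.4, 0.5, 0.0, -0.4],
        ]
    )


def _default_trait_means() -> dict[str, np.ndarray]:
    return {
        "brs": np.array([2.75, 3.10, 3.10, 3.10, 3.20]),
        "spi": np.array([3.00, 3.40, 3.90, 2.70, 4.50]),
        "bsss": np.array([3.50, 3.10, 3.40, 3.00, 3.60]),
    }


def _default_trait_sds() -> dict[str, np.ndarray]:
    return {
        "brs": np.full(N_CROWDS, 0.75),
        "spi": np.full(N_CROWDS, 2.0),
        "bsss": np.full(N_CROWDS, 0.70),
    }


def _default_demographics() -> dict[str, dict]:
    return {
        "age": {13: 0.064, 14: 0.064, 15: 0.064, 16: 0.270, 17: 0.270, 18: 0.268},
        "gender": {"female": 0.573, "male": 0.353, "another identity": 0.074},
        "race_ethnicity": {
            "NH white": 0.544,
            "Hispanic": 0.112,
            "NH Black": 0.162,
            "NH API": 0.083,
            "NH other/multiracial": 0.099,
        },
        "region": {"North": 0.321, "Central": 0.270, "Southeast": 0.212, "Southwest": 0.197},
    }


@dataclass
class CohortConfig:
    """All generative parameters for a synthetic cohort.

    Defaults emulate the validation study's sample margins and effect signs;
    fidelity defaults are illustrative (chosen to yield convergent
    correlations in the 0.2-0.6 range), not estimates.
    """

    n_respondents: int = 1113
    crowd_prevalences: dict[str, float] = field(default_factory=_default_prevalences)
    vmls_rank1_fidelity: float = 0.65
    vmls_affinity: np.ndarray = field(default_factory=_uniform_offdiag)
    ibase_best_fidelity: float = 0.65
    ibase_least_affinity: np.ndarray = field(default_factory=_uniform_offdiag)
    grids: list[dict[str, str]] = field(default_factory=default_grids)
    behavior_base_logodds: dict[str, float] = field(default_factory=_default_behavior_base)
    behavior_crowd_logodds: np.ndarray = field(default_factory=_default_behavior_effects)
    trait_means: dict[str, np.ndarray] = field(default_factory=_default_trait_means)
    trait_sds: dict[str, np.ndarray] = field(default_factory=_default_trait_sds)
    ace_prob: np.ndarray = field(
        default_factory=lambda: np.array([0.40, 0.28, 0.40, 0.22, 0.26])
    )
    item_noise_sd: float = 0.7
    demographic_marginals: dict[str, dict] = field(default_factory=_default_demographics)
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first invalid field."""
        if not isinstance(self.n_respondents, (int, np.integer)) or self.n_respondents <= 0:
            raise ConfigurationError("n_respondents", "must be a positive integer")

        prev = self.crowd_prevalences
        if set(prev) != set(CROWDS):
            raise ConfigurationError("crowd_prevalences", f"keys must be exactly {CROWDS}")
        vals = np.array([prev[c] for c in CROWDS], dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ConfigurationError("crowd_prevalences", "probabilities must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ConfigurationError("crowd_prevalences", f"must sum to 1, got {vals.sum()!r}")

        for name in ("vmls_rank1_fidelity", "ibase_best_fidelity", "item_noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0 or (name != "item_noise_sd" and v > 1):
                raise ConfigurationError(name, "must be a probability in [0, 1]"
                                         if name != "item_noise_sd" else "must be >= 0")

        self._check_stochastic("vmls_affinity", self.vmls_affinity, zero_diag=True)
        self._check_stochastic("ibase_least_affinity", self.ibase_least_affinity, zero_diag=False)

        if len(self.grids) < 1:
            raise ConfigurationError("grids", "at least one grid required")
        for g, grid in enumerate(self.grids, start=1):
            if len(grid) < N_BEST + N_LEAST:
                raise ConfigurationError(
                    "grids", f"grid {g} has {len(grid)} photos; need >= {N_BEST + N_LEAST}"
                )
            crowds_present = set(grid.values())
            if not crowds_present <= set(CROWDS):
                raise ConfigurationError("grids", f"grid {g} maps photos to unknown crowds")
            if crowds_present != set(CROWDS):
                raise ConfigurationError("grids", f"grid {g} must include >=1 photo per crowd")

        if set(self.behavior_base_logodds) != set(BEHAVIORS):
            raise ConfigurationError("behavior_base_logodds", f"keys must be {BEHAVIORS}")
        eff = np.asarray(self.behavior_crowd_logodds, dtype=float)
        if eff.shape != (N_CROWDS, len(BEHAVIORS)):
            raise ConfigurationError(
                "behavior_crowd_logodds", f"shape must be {(N_CROWDS, len(BEHAVIORS))}"
            )

        for name, table in (("trait_means", self.trait_means), ("trait_sds", self.trait_sds)):
            if set(table) != {"brs", "spi", "bsss"}:
                raise ConfigurationError(name, "keys must be {'brs', 'spi', 'bsss'}")
            for k, arr in table.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (N_CROWDS,):
                    raise ConfigurationError(name, f"{k} must have one value per crowd")
                if name == "trait_sds" and np.any(arr < 0):
                    raise ConfigurationError(name, f"{k} SDs must be non-negative")

        ace = np.asarray(self.ace_prob, dtype=float)
        if ace.shape not in ((N_CROWDS,), (N_CROWDS, N_ACE_ITEMS)):
            raise ConfigurationError("ace_prob", f"shape must be ({N_CROWDS},) or "
                                     f"({N_CROWDS}, {N_ACE_ITEMS})")
        if np.any(ace < 0) or np.any(ace > 1):
            raise ConfigurationError("ace_prob", "probabilities must lie in [0, 1]")

        demo = self.demographic_marginals
        expected = {"age": AGES, "gender": GENDERS, "race_ethnicity": RACE_ETHNICITIES,
                    "region": REGIONS}
        for key, cats in expected.items():
            if key not in demo:
                raise ConfigurationError("demographic_marginals", f"missing {key!r}")
            dist = demo[key]
            if set(dist) != set(cats):
                raise ConfigurationError("demographic_marginals",
                                         f"{key} categories must be {cats}")
            p = np.array([dist[c] for c in cats], dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError("demographic_marginals",
                                         f"{key} probabilities must be >=0 and sum to 1")

    @staticmethod
    def _check_stochastic(name: str, m: np.ndarray, zero_diag: bool) -> None:
        m = np.asarray(m, dtype=float)
        if m.shape != (N_CROWDS, N_CROWDS):
            raise ConfigurationError(name, f"shape must be {(N_CROWDS, N_CROWDS)}")
        if np.any(m < 0) or np.any(m > 1):
            raise ConfigurationError(name, "entries must lie in [0, 1]")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError(name, "rows must sum to 1")
        if zero_diag and np.any(np.diag(m) != 0):
            raise ConfigurationError(name, "diagonal must be exactly 0")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in list(d.items()):
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        d["trait_means"] = {k: np.asarray(v).tolist() for k, v in d["trait_means"].items()}
        d["trait_sds"] = {k: np.asarray(v).tolist() for k, v in d["trait_sds"].items()}
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        kwargs = dict(d)
        for k in ("vmls_affinity", "ibase_least_affinity", "behavior_crowd_logodds", "ace_prob"):
            if k in kwargs:
                kwargs[k] = np.asarray(kwargs[k], dtype=float)
        for k in ("trait_means", "trait_sds"):
            if k in kwargs:
                kwargs[k] = {t: np.asarray(v, dtype=float) for t, v in kwargs[k].items()}
        if "demographic_marginals" in kwargs and "age" in kwargs["demographic_marginals"]:
            age = kwargs["demographic_marginals"]["age"]
            kwargs["demographic_marginals"]["age"] = {int(a): p for a, p in age.items()}
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# vectorized samplers (shared by generate_cohort and the per-respondent ops)
# ---------------------------------------------------------------------------


def _categorical(rng: np.random.Generator, probs: np.ndarray, n: int) -> np.ndarray:
    """Draw n categorical indices; probs is (k,) or (n, k) row-stochastic."""
    probs = np.atleast_2d(probs)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(n)
    if cum.shape[0] == 1:
        return np.searchsorted(cum[0], u, side="right").clip(0, probs.shape[1] - 1)
    return (cum < u[:, None]).sum(axis=1).clip(0, probs.shape[1] - 1)


def _sample_vmls(latent: np.ndarray, config: CohortConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Return (rank1, rank2) crowd-index arrays of shape (n, 7)."""
    n = latent.shape[0]
    fid = config.vmls_rank1_fidelity
    affinity = np.asarray(config.vmls_affinity, dtype=float)
    rank1 = np.empty((n, N_VMLS_QUESTIONS), dtype=np.int64)
    rank2 = np.empty((n, N_VMLS_QUESTIONS), dtype=np.int64)
    for q in range(N_VMLS_QUESTIONS):
        match = rng.random(n) < fid
        # uniform over the four non-latent crowds
        offset = rng.integers(1, N_CROWDS, size=n)
        miss = (latent + offset) % N_CROWDS
        r1 = np.where(match, latent, miss)
        w = affinity[latent].copy()
        w[np.arange(n), r1] = 0.0
        rowsum = w.sum(axis=1, keepdims=True)
        degenerate = rowsum[:, 0] <= 0
        if degenerate.any():
            u = np.ones((int(degenerate.sum()), N_CROWDS))
            u[np.arange(u.shape[0]), r1[degenerate]] = 0.0
            w[degenerate] = u
            rowsum = w.sum(axis=1, keepdims=True)
        r2 = _categorical(rng, w / rowsum, n)
        rank1[:, q] = r1
        rank2[:, q] = r2
    return rank1, rank2


def _gumbel_topk(rng: np.random.Generator, weights: np.ndarray, k: int) -> np.ndarray:
    """Top-k weighted sampling without replacement, rowwise, via Gumbel keys.

    Zero-weight items are only drawn once all positive-weight items are
    exhausted (then uniformly among themselves).
    """
    g = rng.gumbel(size=weights.shape)
    with np.errstate(divide="ignore"):
        keys = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)), -1e12) + g
    order = np.argsort(-keys, axis=1)
    return order[:, :k]


def _sample_ibase(latent: np.ndarray, config: CohortConfig,
                  rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per grid, return (best, least) photo-index arrays of shape (n, 3)."""
    n = latent.shape[0]
    fid = config.ibase_best_fidelity
    least_aff = np.asarray(config.ibase_least_affinity, dtype=float)
    out = []
    for grid in config.grids:
        photo_ids = list(grid)
        photo_crowds = np.array([CROWD_INDEX[grid[p]] for p in photo_ids])
        n_photos = len(photo_ids)
        counts = np.bincount(photo_crowds, minlength=N_CROWDS).astype(float)

        own = photo_crowds[None, :] == latent[:, None]           # (n, n_photos)
        n_own = counts[latent][:, None]
        n_other = float(n_photos) - n_own
        w_best = np.where(own, fid / n_own, (1.0 - fid) / n_other)
        best = _gumbel_topk(rng, w_best, N_BEST)

        # least-fit: crowd weight from the affinity row, spread over that
        # crowd's photos; best-picked photos removed from the pool
        w_least = least_aff[latent][:, photo_crowds] / counts[photo_crowds][None, :]
        np.put_along_axis(w_least, best, 0.0, axis=1)
        least = _gumbel_topk(rng, w_least, N_LEAST)
        out.append((best, least))
    return out


def _round_items(target: np.ndarray, n_items: int, lo: int, hi: int,
                 noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Integer items centered on a per-respondent target value."""
    noise = rng.normal(0.0, noise_sd, size=(target.shape[0], n_items))
    return np.clip(np.rint(target[:, None] + noise), lo, hi).astype(np.int64)


def _sample_outcomes(latent: np.ndarray, config: CohortConfig,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    from scipy.special import expit

    n = latent.shape[0]
    out: dict[str, np.ndarray] = {}

    base = np.array([config.behavior_base_logodds[b] for b in BEHAVIORS])
    eff = np.asarray(config.behavior_crowd_logodds, dtype=float)
    p = expit(base[None, :] + eff[latent])                       # (n, 7)
    positive = rng.random((n, len(BEHAVIORS))) < p
    for j, sub in enumerate(SUBSTANCES):
        days = np.where(positive[:, j], rng.integers(1, 31, size=n), 0)
        out[f"use_days_{sub}"] = days.astype(np.int64)
    out["sad_hopeless"] = positive[:, len(SUBSTANCES)].astype(np.int64)

    ace = np.asarray(config.ace_prob, dtype=float)
    if ace.ndim == 1:
        ace = np.repeat(ace[:, None], N_ACE_ITEMS, axis=1)
    ace_draws = (rng.random((n, N_ACE_ITEMS)) < ace[latent]).astype(np.int64)
    for i in range(N_ACE_ITEMS):
        out[f"ace_{i + 1}"] = ace_draws[:, i]

    means, sds = config.trait_means, config.trait_sds

    brs_t = np.clip(rng.normal(np.asarray(means["brs"])[latent],
                               np.asarray(sds["brs"])[latent]), 1, 5)
    brs_items = _round_items(brs_t, N_BRS_ITEMS, 1, 5, config.item_noise_sd, rng)
    for i in range(N_BRS_ITEMS):
        v = brs_items[:, i]
        out[f"brs_{i + 1}"] = (6 - v) if (i + 1) in BRS_REVERSED else v

    spi_t = np.clip(rng.normal(np.asarray(means["spi"])[latent],
                               np.asarray(sds["spi"])[latent]), 0, 10)
    spi_item_target = 1.0 + spi_t * 0.4                          # map 0-10 onto 1-5 items
    spi_items = _round_items(spi_item_target, N_SPI_ITEMS, 1, 5, config.item_noise_sd, rng)
    for i in range(N_SPI_ITEMS):
        out[f"spi_{i + 1}"] = spi_items[:, i]

    bsss_t = np.clip(rng.normal(np.asarray(means["bsss"])[latent],
                                np.asarray(sds["bsss"])[latent]), 1, 5)
    bsss_items = _round_items(bsss_t, N_BSSS_ITEMS, 1, 5, config.item_noise_sd, rng)
    for i in range(N_BSSS_ITEMS):
        out[f"bsss_{i + 1}"] = bsss_items[:, i]

    demo = config.demographic_marginals
    for key, cats in (("age", AGES), ("gender", GENDERS),
                      ("race_ethnicity", RACE_ETHNICITIES), ("region", REGIONS)):
        probs = np.array([demo[key][c] for c in cats], dtype=float)
        idx = _categorical(rng, probs, n)
        values = np.array(cats, dtype=object)[idx]
        out[key] = values.astype(np.int64) if key == "age" else values
    return out


# ---------------------------------------------------------------------------
# public per-respondent samplers
# ---------------------------------------------------------------------------


def sample_vmls_response(latent_crowd: str, config: CohortConfig,
                         rng: np.random.Generator) -> list[tuple[str, str]]:
    """Draw one respondent's seven (rank1, rank2) crowd choices."""
    if latent_crowd not in CROWD_INDEX:
        raise ValueError(f"unknown crowd {latent_crowd!r}")
    latent = np.array([CROWD_INDEX[latent_crowd]])
    r1, r2 = _sample_vmls(latent, config, rng)
    return [(CROWDS[r1[0, q]], CROWDS[r2[0, q]]) for q in range(N_VMLS_QUESTIONS)]


def sample_ibase_response(latent_crowd: str, config: CohortConfig,
                          rng: np.random.Generator) -> list[dict[str, list[str]]]:
    """Draw one respondent's per-grid best/least photo-id selections."""
    if latent_crowd not in CROWD_INDEX:
        raise ValueError(f"unknown crowd {latent_crowd!r}")
    latent = np.array([CROWD_INDEX[latent_crowd]])
    picks = _sample_ibase(latent, config, rng)
    result = []
    for grid, (best, least) in zip(config.grids, picks):
        ids = list(grid)
        result.append({"best": [ids[j] for j in best[0]],
                       "least": [ids[j] for j in least[0]]})
    return result


def sample_outcomes(latent_crowd: str, config: CohortConfig,
                    rng: np.random.Generator) -> dict:
    """Draw one respondent's scale items, use days, indicator, demographics."""
    if latent_crowd not in CROWD_INDEX:
        raise ValueError(f"unknown crowd {latent_crowd!r}")
    latent = np.array([CROWD_INDEX[latent_crowd]])
    cols = _sample_outcomes(latent, config, rng)
    return {k: (v[0] if isinstance(v[0], str) else v[0].item() if hasattr(v[0], "item") else v[0])
            for k, v in cols.items()}


# ---------------------------------------------------------------------------
# cohort generation and I/O
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a full cohort table, one row per respondent.

    The table carries raw responses only (plus the oracle ``latent_crowd``
    column); scoring is a separate stage.  Identical config (including seed)
    yields an identical table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents

    prev = np.array([config.crowd_prevalences[c] for c in CROWDS])
    latent = _categorical(rng, prev, n)

    cols: dict[str, object] = {
        "respondent_id": np.arange(1, n + 1),
        "latent_crowd": np.array(CROWDS, dtype=object)[latent],
    }

    r1, r2 = _sample_vmls(latent, config, rng)
    crowd_arr = np.array(CROWDS, dtype=object)
    for q in range(N_VMLS_QUESTIONS):
        cols[f"vmls_q{q + 1}_rank1"] = crowd_arr[r1[:, q]]
        cols[f"vmls_q{q + 1}_rank2"] = crowd_arr[r2[:, q]]

    for g, (grid, (best, least)) in enumerate(
            zip(config.grids, _sample_ibase(latent, config, rng)), start=1):
        ids = np.array(list(grid), dtype=object)
        for j in range(N_BEST):
            cols[f"ibase_g{g}_best_{j + 1}"] = ids[best[:, j]]
        for j in range(N_LEAST):
            cols[f"ibase_g{g}_least_{j + 1}"] = ids[least[:, j]]

    cols.update(_sample_outcomes(latent, config, rng))
    return pd.DataFrame(cols)


def cohort_to_csv(table: pd.DataFrame) -> str:
    buf = io.StringIO()
    table.to_csv(buf, index=False)
    return buf.getvalue()


def save_cohort(table: pd.DataFrame, config: CohortConfig, path: str | Path) -> None:
    """Write the cohort CSV plus its generating config as YAML alongside."""
    path = Path(path)
    path.write_text(cohort_to_csv(table))
    path.with_suffix(".config.yaml").write_text(config.to_yaml())
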