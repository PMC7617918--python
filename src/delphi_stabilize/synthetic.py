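"""Synthetic multistakeholder Delphi rating generator with known ground truth.

Ratings come from a discretized latent-opinion model (graded-response
flavour with equally spaced thresholds): participant i in stakeholder
group g rates item j through

    z_ij = mu_j + gamma_g(i) + u_i + e_ij,      u_i ~ N(0, sigma_u^2),
                                                e_ij ~ N(0, sigma_e^2),

and the latent value is cut into k ordered categories by k - 1 equally
spaced thresholds spanning a fixed window mu_0 +/- 4 * s_total (so k only
controls granularity, never the effective scale of the noise).  Item
locations mu_j are N(mu_0, tau^2) except for a controllable fraction of
*knife-edge* items whose location is placed so the latent population
median sits exactly on a category threshold — these are the items whose
subsample medians flip between adjacent categories and hence drive
replicability below 100%.

A configurable share of participants is made incomplete (a few cells
blanked, emulating skipped or "unsure" answers) so the completeness
filter has something to do, and every random choice is recorded in a
:class:`SyntheticTruth` for ground-truth cross-checks in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import LikertScale, RatingsMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate",
    "scenario_presets",
    "discretize",
    "latent_window",
]

#: default stakeholder mix: label -> (proportion, latent location shift).
#: The shared positive shift emulates consensus panels, where candidate
#: items are pre-screened and most stakeholders rate them favourably;
#: the spread between shifts carries the between-group disagreement.
DEFAULT_GROUP_MIX = {
    "clinician": (0.55, 4.6),
    "researcher": (0.30, 5.0),
    "patient": (0.15, 4.0),
}

_GENDERS = ("man", "woman")
_ROLES = (
    "Epidemiologist",
    "Trial Investigator",
    "Statistician",
    "Trial Methodologist",
    "Clinician/Health and allied health professional",
)
_COUNTRIES = (
    "United Kingdom", "Germany", "Italy", "Netherlands", "Spain", "Sweden",
    "United States", "Canada", "Australia", "Brazil", "India", "China",
    "South Africa", "Kenya", "Ethiopia", "Japan",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of the latent-opinion ordinal model.

    All scale parameters are on the latent (continuous) axis.  The
    defaults give a mid-scale survey with mild stakeholder disagreement;
    :func:`scenario_presets` tunes them to the shapes of real panels.
    """

    n_participants: int = 200
    n_items: int = 22
    k: int = 9
    group_mix: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MIX)
    )
    item_loc_mean: float = 0.0     # mu_0, centre of the latent window
    item_loc_sd: float = 1.0       # tau, spread of item locations
    participant_sd: float = 0.8    # sigma_u, rater leniency/severity
    residual_sd: float = 1.0       # sigma_e, item-by-rater noise
    knife_edge_fraction: float = 0.15
    incomplete_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_items < 1:
            raise ValueError("need >=1 participant and >=1 item")
        if self.k < 3:
            raise ValueError("k must be >= 3")
        props = [p for p, _ in self.group_mix.values()]
        if not props or abs(sum(props) - 1.0) > 1e-9 or any(p < 0 for p in props):
            raise ValueError("group proportions must be nonnegative and sum to 1")
        for sd in (self.item_loc_sd, self.participant_sd, self.residual_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        for frac in (self.knife_edge_fraction, self.incomplete_rate):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def total_sd(self) -> float:
        return float(
            np.sqrt(self.item_loc_sd**2 + self.participant_sd**2 + self.residual_sd**2)
        )


@dataclass
class SyntheticTruth:
    """Everything the generator decided, for ground-truth cross-checks."""

    item_locations: np.ndarray          # mu_j
    knife_edge_items: list[str]
    group_labels: pd.Series             # participant_id -> stakeholder group
    group_shifts: dict[str, float]      # gamma_g
    participant_effects: np.ndarray     # u_i
    incomplete_ids: list[str]           # participants given missing cells
    thresholds: np.ndarray              # latent cut points
    noise_free_medians: np.ndarray      # per-item median of discretize(mu_j + gamma_g)
    seed: int


def latent_window(cfg: SyntheticConfig) -> tuple[float, float]:
    """The fixed latent interval mapped onto the k categories."""
    half = 4.0 * cfg.total_sd
    return cfg.item_loc_mean - half, cfg.item_loc_mean + half


def _thresholds(cfg: SyntheticConfig) -> np.ndarray:
    lo, hi = latent_window(cfg)
    return np.linspace(lo, hi, cfg.k + 1)[1:-1]


def discretize(z: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Latent values -> integer categories 1..k (k-1 thresholds)."""
    return np.searchsorted(thresholds, z, side="right") + 1


def generate(
    cfg: SyntheticConfig,
) -> tuple[RatingsMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw one synthetic Delphi round-1 dataset.

    Returns the ratings matrix (with missing cells where participants
    were made incomplete), a participant-metadata table covering every
    field the subgroup analysis uses, and the ground truth.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    N, J, k = cfg.n_participants, cfg.n_items, cfg.k
    thresholds = _thresholds(cfg)

    labels = list(cfg.group_mix)
    props = np.array([cfg.group_mix[g][0] for g in labels])
    shifts = {g: cfg.group_mix[g][1] for g in labels}
    group_idx = rng.choice(len(labels), size=N, p=props)
    gamma = np.array([shifts[labels[g]] for g in group_idx])
    mean_shift = float(props @ np.array([shifts[g] for g in labels]))

    # item locations: ordinary items around mu_0; knife-edge items placed so
    # the latent population median (= mu_j + mean shift, noise symmetric)
    # sits exactly on a threshold
    mu = rng.normal(cfg.item_loc_mean, cfg.item_loc_sd, size=J)
    n_knife = int(round(cfg.knife_edge_fraction * J))
    knife_pos = rng.choice(J, size=n_knife, replace=False) if n_knife else np.array([], dtype=int)
    if n_knife:
        interior = thresholds[1:-1] if len(thresholds) > 2 else thresholds
        mu[knife_pos] = rng.choice(interior, size=n_knife) - mean_shift

    u = rng.normal(0.0, cfg.participant_sd, size=N)
    eps = rng.normal(0.0, cfg.residual_sd, size=(N, J))
    z = mu[None, :] + gamma[:, None] + u[:, None] + eps
    ratings = discretize(z, thresholds).astype(float)

    participant_ids = [f"p{i+1:04d}" for i in range(N)]
    item_ids = [f"item{j+1:03d}" for j in range(J)]

    # structured missingness: a few blanked cells per incomplete participant
    n_incomplete = int(round(cfg.incomplete_rate * N))
    incomplete_rows = (
        rng.choice(N, size=n_incomplete, replace=False) if n_incomplete else np.array([], dtype=int)
    )
    for i in incomplete_rows:
        n_holes = int(rng.integers(1, min(3, J) + 1))
        holes = rng.choice(J, size=n_holes, replace=False)
        ratings[i, holes] = np.nan

    frame = pd.DataFrame(
        ratings, index=pd.Index(participant_ids, name="participant_id"), columns=item_ids
    )
    rm = RatingsMatrix(frame, LikertScale(k))

    group_series = pd.Series(
        [labels[g] for g in group_idx], index=participant_ids, name="stakeholder_group"
    )
    meta = _draw_metadata(rng, participant_ids, group_series)

    noise_free = discretize(mu[None, :] + gamma[:, None], thresholds)
    truth = SyntheticTruth(
        item_locations=mu,
        knife_edge_items=[item_ids[j] for j in sorted(knife_pos.tolist())],
        group_labels=group_series,
        group_shifts=shifts,
        participant_effects=u,
        incomplete_ids=[participant_ids[i] for i in sorted(incomplete_rows.tolist())],
        thresholds=thresholds,
        noise_free_medians=np.median(noise_free, axis=0),
        seed=cfg.seed,
    )
    return rm, meta, truth


def _draw_metadata(
    rng: np.random.Generator, participant_ids: list[str], groups: pd.Series
) -> pd.DataFrame:
    """Demographics for the built-in grouping specs; independent of ratings."""
    from .subgroups import load_income_table, load_region_table

    N = len(participant_ids)
    countries = rng.choice(_COUNTRIES, size=N)
    region_lut = dict(
        zip(load_region_table()["country"], load_region_table()["region"])
    )
    income_lut = dict(
        zip(load_income_table()["country"], load_income_table()["income_group"])
    )
    role = np.where(
        groups.to_numpy() == "patient",
        "Patient and public partner",
        rng.choice(_ROLES, size=N),
    )
    ptype = np.where(
        groups.to_numpy() == "patient",
        "patient and carer",
        "clinician/health care professional",
    )
    return pd.DataFrame(
        {
            "participant_id": participant_ids,
            "gender": rng.choice(_GENDERS, size=N),
            "age_years": rng.integers(25, 76, size=N),
            "role_raw": role,
            "years_experience": rng.integers(1, 41, size=N),
            "country": countries,
            "region": [region_lut[c] for c in countries],
            "income_group": [income_lut[c] for c in countries],
            "participant_type": ptype,
            "stakeholder_group": groups.to_numpy(),
        }
    )


def scenario_presets() -> dict[str, SyntheticConfig]:
    """Named configurations emulating the shapes of real multistakeholder panels.

    * ``surrogate-like`` — 175 raters, 22 items, 9-point scale
    * ``spi-like``       — 333 raters, 77 items, 10-point scale
    * ``cosb-like``      — 553 raters, 88 items, 9-point scale

    Dispersion (item spread, rater and residual noise, knife-edge share)
    is fixed so each preset's small-sample (n = 20) replicability falls in
    the moderate 60-80% band, rising toward but not reaching 100% at
    n = 500 — the qualitative regime real panels show.
    """
    common = dict(
        item_loc_mean=0.0,
        item_loc_sd=2.0,
        participant_sd=0.8,
        residual_sd=1.6,
        knife_edge_fraction=0.20,
        incomplete_rate=0.05,
    )
    return {
        "surrogate-like": SyntheticConfig(
            n_participants=175, n_items=22, k=9, seed=175, **common
        ),
        "spi-like": SyntheticConfig(
            n_participants=333, n_items=77, k=10, seed=333, **common
        ),
        "cosb-like": SyntheticConfig(
            n_participants=553, n_items=88, k=9, seed=553, **common
        ),
    }
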