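"""Synthetic replicated-SCED cohorts with the structure the analysis assumes.

The study's raw daily data are not public, so this module generates
datasets carrying the features the downstream analysis must handle:
bounded ordinal daily scores, A/B/C phase structure on a fixed-length
course, lag-1 serial dependence, a *delayed, gradual* treatment effect,
between-participant variability through randomized baseline lengths, and
missing-completely-at-random daily responses.

Mechanism: a latent continuous process ``x_t = mu_t + e_t`` where ``e_t``
is stationary AR(1) noise and the mean path ``mu_t`` sits at
``baseline_level`` through phase A and the first ``onset_delay_days`` of
phase B, then declines linearly by ``effect_size`` over ``ramp_days``
and stays at the post level.  Observed scores are the latent values
rounded and clipped to the outcome bounds; each day's response is
missing with probability ``missing_rate``.  Impact and value-based
action are derived from the same latent process scaled to 0-9 (value
action mirrored, since more action is better), keeping the three
outcomes coherent within a participant.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .daily import DailyResponse, DailySeries, OUTCOME_BOUNDS
from .design import (
    ConfigurationError,
    DesignSpace,
    PhaseDesign,
    allocate_strata,
    draw_design,
)

__all__ = [
    "GeneratorConfig",
    "CohortParticipant",
    "SyntheticCohort",
    "simulate_series",
    "simulate_participant",
    "simulate_cohort",
    "cohort_to_responses",
    "write_design_sidecar",
    "read_design_sidecar",
]

ANXIETY_MAX = OUTCOME_BOUNDS["anxiety"][1]
ITEM_MAX = OUTCOME_BOUNDS["impact"][1]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic daily-outcome process (anxiety 0-27 scale).

    Defaults emulate the qualitative study conditions: a moderate
    baseline anxiety level with considerable day-to-day variability,
    an effect that begins only weeks into treatment (exposure work starts
    mid-program) and accrues gradually, and the observed 23.7% missing
    daily responses.
    """

    baseline_level: float = 12.0
    effect_size: float = 9.0
    onset_delay_days: int = 21
    ramp_days: int = 28
    ar_coefficient: float = 0.5
    noise_sd: float = 3.0
    missing_rate: float = 0.237
    effect_shape: str = "ramp"  # "ramp" | "step"

    def __post_init__(self) -> None:
        if not (0 <= self.baseline_level <= ANXIETY_MAX):
            raise ConfigurationError(
                f"baseline_level {self.baseline_level} outside [0, {ANXIETY_MAX}]"
            )
        if not (0 <= self.ar_coefficient < 1):
            raise ConfigurationError(
                f"ar_coefficient {self.ar_coefficient} outside [0, 1)"
            )
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError(
                f"missing_rate {self.missing_rate} outside [0, 1)"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.onset_delay_days < 0 or self.ramp_days < 0:
            raise ConfigurationError("onset_delay_days and ramp_days must be >= 0")
        if self.effect_shape not in ("ramp", "step"):
            raise ConfigurationError(
                f"effect_shape must be 'ramp' or 'step', got {self.effect_shape!r}"
            )


def mean_path(config: GeneratorConfig, design: PhaseDesign) -> np.ndarray:
    """Deterministic latent mean per day (length ``design.total_days``)."""
    if config.onset_delay_days + config.ramp_days > design.treatment_days + design.followup_days:
        raise ConfigurationError(
            "onset_delay_days + ramp_days exceeds the post-baseline course "
            f"({config.onset_delay_days}+{config.ramp_days} > "
            f"{design.treatment_days + design.followup_days})"
        )
    t = np.arange(1, design.total_days + 1)
    # days elapsed since treatment entry (day of B onset = 1)
    since_entry = t - design.baseline_days
    mu = np.full(design.total_days, config.baseline_level, dtype=float)
    active = since_entry > config.onset_delay_days
    if config.effect_shape == "step" or config.ramp_days == 0:
        mu[active] -= config.effect_size
    else:
        progress = (since_entry - config.onset_delay_days) / config.ramp_days
        mu -= config.effect_size * np.clip(progress, 0.0, 1.0) * active
    return mu


def _latent(
    config: GeneratorConfig, design: PhaseDesign, rng: np.random.Generator
) -> np.ndarray:
    """Latent process: mean path plus stationary AR(1) noise."""
    n = design.total_days
    mu = mean_path(config, design)
    e = np.zeros(n)
    if config.noise_sd > 0:
        phi = config.ar_coefficient
        innov = rng.normal(0.0, config.noise_sd, size=n)
        e[0] = rng.normal(0.0, config.noise_sd / np.sqrt(1 - phi**2)) if phi > 0 else innov[0]
        for i in range(1, n):
            e[i] = phi * e[i - 1] + innov[i]
    return mu + e


def _observe(
    latent: np.ndarray, bounds: tuple[int, int], missing: np.ndarray
) -> np.ndarray:
    lo, hi = bounds
    if lo >= hi:
        raise ConfigurationError(f"inverted outcome bounds ({lo}, {hi})")
    obs = np.clip(np.round(latent), lo, hi).astype(float)
    obs[missing] = np.nan
    return obs


def simulate_series(
    config: GeneratorConfig,
    design: PhaseDesign,
    bounds: tuple[int, int] = (0, 27),
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
    outcome_name: str = "anxiety",
) -> DailySeries:
    """Simulate one outcome series (round-then-clip of the latent process)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent = _latent(config, design, rng)
    missing = rng.random(design.total_days) < config.missing_rate
    # latent is on the anxiety scale; rescale if other bounds requested
    scale = (bounds[1] - bounds[0]) / ANXIETY_MAX
    values = _observe(bounds[0] + latent * scale, bounds, missing)
    return DailySeries(participant_id, design, outcome_name, values)


@dataclass(frozen=True)
class CohortParticipant:
    participant_id: str
    design: PhaseDesign
    series: dict[str, DailySeries]
    config: GeneratorConfig


@dataclass(frozen=True)
class SyntheticCohort:
    participants: list[CohortParticipant]
    master_seed: int
    space: DesignSpace = field(default_factory=DesignSpace)

    def designs(self) -> dict[str, PhaseDesign]:
        return {p.participant_id: p.design for p in self.participants}


def simulate_participant(
    participant_id: str,
    config: GeneratorConfig,
    design: PhaseDesign,
    rng: np.random.Generator,
) -> CohortParticipant:
    """All three daily outcomes for one participant from a shared latent process.

    A missing day (unanswered text message) drops all three outcomes at
    once, matching how the daily items are delivered together.
    """
    latent = _latent(config, design, rng)
    missing = rng.random(design.total_days) < config.missing_rate
    anx = _observe(latent, OUTCOME_BOUNDS["anxiety"], missing)
    impact = _observe(latent * ITEM_MAX / ANXIETY_MAX, OUTCOME_BOUNDS["impact"], missing)
    value = _observe(ITEM_MAX - latent * ITEM_MAX / ANXIETY_MAX,
                     OUTCOME_BOUNDS["value_action"], missing)
    series = {
        "anxiety": DailySeries(participant_id, design, "anxiety", anx),
        "impact": DailySeries(participant_id, design, "impact", impact),
        "value_action": DailySeries(participant_id, design, "value_action", value),
    }
    return CohortParticipant(participant_id, design, series, config)


def simulate_cohort(
    n_participants: int,
    space: DesignSpace | None = None,
    configs: GeneratorConfig | list[GeneratorConfig] | None = None,
    master_seed: int = 0,
) -> SyntheticCohort:
    """Simulate a replicated cohort with stratified randomized designs.

    Baseline strata are allocated cyclically in enrollment order; each
    participant gets a child random stream derived deterministically from
    ``master_seed``.
    """
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    space = space or DesignSpace()
    if configs is None:
        configs = GeneratorConfig()
    if isinstance(configs, GeneratorConfig):
        configs = [configs] * n_participants
    if len(configs) != n_participants:
        raise ConfigurationError(
            f"got {len(configs)} configs for {n_participants} participants"
        )
    strata = allocate_strata(n_participants, n_strata=len(space.strata))
    children = np.random.SeedSequence(master_seed).spawn(n_participants)
    participants = []
    for i, (stratum, child, config) in enumerate(zip(strata, children, configs)):
        rng = np.random.default_rng(child)
        design = draw_design(space, stratum, rng)
        pid = f"P{i + 1}"
        participants.append(simulate_participant(pid, config, design, rng))
    return SyntheticCohort(participants, master_seed, space)


def cohort_to_responses(cohort: SyntheticCohort) -> list[DailyResponse]:
    """Express a cohort as raw daily item responses (1-10 scale).

    The anxiety sum is decomposed into three items as evenly as possible;
    item 4 carries impact and item 5 value-based action.  Missing days
    produce no response row.  Scoring the result reproduces the cohort's
    scored values exactly.
    """
    responses = []
    for p in cohort.participants:
        anx = p.series["anxiety"].values
        imp = p.series["impact"].values
        val = p.series["value_action"].values
        for day in range(1, p.design.total_days + 1):
            a, im, va = anx[day - 1], imp[day - 1], val[day - 1]
            if np.isnan(a) and np.isnan(im) and np.isnan(va):
                continue
            items: list[int | None] = [None] * 5
            if not np.isnan(a):
                s = int(a)
                q, r = divmod(s, 3)
                coded = [q + 1] * r + [q] * (3 - r)
                items[:3] = [c + 1 for c in coded]  # back to raw 1-10
            if not np.isnan(im):
                items[3] = int(im) + 1
            if not np.isnan(va):
                items[4] = int(va) + 1
            responses.append(
                DailyResponse(p.participant_id, day, tuple(items), same_day=True)
            )
    return responses


def write_design_sidecar(cohort: SyntheticCohort, path: str | Path) -> None:
    """Record designs, configs and the master seed alongside the daily CSV."""
    payload = {
        "master_seed": cohort.master_seed,
        "space": asdict(cohort.space),
        "participants": {
            p.participant_id: {
                "design": asdict(p.design),
                "config": asdict(p.config),
            }
            for p in cohort.participants
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_design_sidecar(path: str | Path) -> tuple[dict[str, PhaseDesign], dict]:
    """Read the sidecar; returns (designs by participant, full metadata)."""
    payload = json.loads(Path(path).read_text())
    designs = {
        pid: PhaseDesign(**info["design"])
        for pid, info in payload["participants"].items()
    }
    return designs, payload
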