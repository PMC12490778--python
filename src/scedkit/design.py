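"""Randomized phase designs for single-case experiments.

A single-case phase design partitions a fixed-length measurement course
into a baseline phase (A), a treatment phase (B) and a follow-up phase
(C).  Randomizing the baseline length — and hence the treatment start
point — is what licenses the exact randomization test in
:mod:`scedkit.inference`: every admissible baseline length that could
have been drawn defines one scenario of the null distribution.

The default design space mirrors a 96-day course with a fixed 56-day
treatment phase and baseline lengths of 7–26 days stratified into
7–11, 12–19 and 20–26 days, giving 20 admissible designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhaseDesign",
    "DesignSpace",
    "ConfigurationError",
    "enumerate_designs",
    "draw_design",
    "phase_of",
    "allocate_strata",
]

log = logging.getLogger(__name__)

PHASES = ("A", "B", "C")


class ConfigurationError(ValueError):
    """Raised when a design space or generator configuration is invalid."""


@dataclass(frozen=True)
class PhaseDesign:
    """One participant's A/B/C partition of the measurement course.

    Parameters
    ----------
    baseline_days
        Length of the baseline phase A, in days.
    treatment_days
        Length of the treatment phase B, in days.
    followup_days
        Length of the follow-up phase C, in days.
    """

    baseline_days: int
    treatment_days: int
    followup_days: int

    def __post_init__(self) -> None:
        for name in ("baseline_days", "treatment_days", "followup_days"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")

    @property
    def total_days(self) -> int:
        return self.baseline_days + self.treatment_days + self.followup_days

    @property
    def treatment_start_day(self) -> int:
        """1-based index of the first day of phase B."""
        return self.baseline_days + 1

    def phase_days(self, phase: str) -> range:
        """1-based day indices belonging to ``phase``."""
        if phase == "A":
            return range(1, self.baseline_days + 1)
        if phase == "B":
            return range(self.baseline_days + 1, self.baseline_days + self.treatment_days + 1)
        if phase == "C":
            return range(self.baseline_days + self.treatment_days + 1, self.total_days + 1)
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")


@dataclass(frozen=True)
class DesignSpace:
    """The set of admissible phase designs the randomization could produce.

    Defaults encode a 96-day course with a 56-day treatment phase,
    baseline lengths 7–26 days and three baseline strata.
    """

    total_days: int = 96
    treatment_days: int = 56
    baseline_min: int = 7
    baseline_max: int = 26
    strata: tuple[tuple[int, int], ...] = field(default=((7, 11), (12, 19), (20, 26)))

    def __post_init__(self) -> None:
        if self.baseline_min > self.baseline_max:
            raise ConfigurationError(
                f"empty baseline range [{self.baseline_min}, {self.baseline_max}]"
            )
        if self.baseline_min < 1:
            raise ConfigurationError("baseline_min must be >= 1")
        if self.total_days - self.treatment_days - self.baseline_max < 1:
            raise ConfigurationError(
                "treatment too long: no room for at least one follow-up day "
                f"(total {self.total_days}, treatment {self.treatment_days}, "
                f"baseline_max {self.baseline_max})"
            )
        # strata must tile [baseline_min, baseline_max] in order, no gaps
        covered = []
        for lo, hi in self.strata:
            if lo > hi:
                raise ConfigurationError(f"stratum ({lo}, {hi}) is empty")
            covered.extend(range(lo, hi + 1))
        if covered != list(range(self.baseline_min, self.baseline_max + 1)):
            raise ConfigurationError(
                "strata must be disjoint, ordered and cover the baseline range "
                f"[{self.baseline_min}, {self.baseline_max}]; got {self.strata}"
            )

    @property
    def n_designs(self) -> int:
        return self.baseline_max - self.baseline_min + 1

    def design_for_baseline(self, baseline_days: int) -> PhaseDesign:
        if not (self.baseline_min <= baseline_days <= self.baseline_max):
            raise ConfigurationError(
                f"baseline_days {baseline_days} outside "
                f"[{self.baseline_min}, {self.baseline_max}]"
            )
        return PhaseDesign(
            baseline_days=baseline_days,
            treatment_days=self.treatment_days,
            followup_days=self.total_days - self.treatment_days - baseline_days,
        )

    def stratum_of(self, baseline_days: int) -> int:
        for i, (lo, hi) in enumerate(self.strata):
            if lo <= baseline_days <= hi:
                return i
        raise ConfigurationError(f"baseline_days {baseline_days} in no stratum")


def enumerate_designs(space: DesignSpace) -> list[PhaseDesign]:
    """All admissible phase designs, ascending by baseline length.

    With the default space this yields 20 designs (baselines 7..26),
    each totalling 96 days.
    """
    return [
        space.design_for_baseline(b)
        for b in range(space.baseline_min, space.baseline_max + 1)
    ]


def draw_design(
    space: DesignSpace,
    stratum_index: int,
    seed: int | np.random.Generator,
) -> PhaseDesign:
    """Uniform random draw of a design from one baseline stratum.

    ``seed`` may be an integer or an existing :class:`numpy.random.Generator`
    (so that cohort simulation can pass a shared stream).
    """
    if not (0 <= stratum_index < len(space.strata)):
        raise ConfigurationError(
            f"stratum_index {stratum_index} out of range 0..{len(space.strata) - 1}"
        )
    lo, hi = space.strata[stratum_index]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    baseline = int(rng.integers(lo, hi + 1))
    return space.design_for_baseline(baseline)


def phase_of(day_index: int, design: PhaseDesign) -> str:
    """Phase label ('A', 'B' or 'C') of a 1-based day index."""
    if not (1 <= day_index <= design.total_days):
        raise IndexError(
            f"day_index {day_index} outside 1..{design.total_days}"
        )
    if day_index <= design.baseline_days:
        return "A"
    if day_index <= design.baseline_days + design.treatment_days:
        return "B"
    return "C"


def allocate_strata(n_participants: int, n_strata: int = 3) -> list[int]:
    """Cyclic stratum allocation in enrollment order.

    Aims for an equal number of participants per stratum; when
    ``n_participants`` is not divisible by ``n_strata`` exact equality is
    impossible and a warning is logged.
    """
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    if n_participants % n_strata != 0:
        log.warning(
            "n_participants=%d is not divisible by %d strata; "
            "allocation is unequal by one", n_participants, n_strata,
        )
    return [i % n_strata for i in range(n_participants)]
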