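import numpy as np
import pytest

from scedkit import DailySeries, DesignSpace, PhaseDesign


@pytest.fixture
def space():
    """The default 96-day design space (20 admissible baselines)."""
    return DesignSpace()


@pytest.fixture
def small_space():
    """A tiny design space for brute-force oracles: 12 days, 5-day treatment,
    baselines 3-6 (4 admissible designs)."""
    return DesignSpace(total_days=12, treatment_days=5, baseline_min=3,
                       baseline_max=6, strata=((3, 4), (5, 6)))


def make_series(values, design, outcome="anxiety", pid="T"):
    vals = np.asarray(values, dtype=float)
    return DailySeries(pid, design, outcome, vals)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def design_756():
    return PhaseDesign(baseline_days=7, treatment_days=56, followup_days=33)
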