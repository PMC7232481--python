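import numpy as np
import pytest

from digesterkit import breakpoints as bp
from digesterkit.gas import FeedingSchedule, segment_cycles
from digesterkit.synthetic import SimConfig, simulate


@pytest.fixture(scope="session")
def study_bundle():
    """One full-scale default simulation (4 reactors, 350 days, seed 1)."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def study_trends(study_bundle):
    """Breakpoint trend and alarm day per reactor of the default run."""
    sim = study_bundle.config
    out = {}
    for rid, run in study_bundle.runs.items():
        schedule = FeedingSchedule(
            feed_times=np.arange(sim.horizon_days) * 1440.0,
            reactor_volume_l=sim.volume_l,
            hrt_days=sim.hrt_days,
            olr=sim.olr,
        )
        cycles = segment_cycles(run.gas, schedule)
        trend = bp.breakpoint_series(cycles)
        out[rid] = {
            "cycles": cycles,
            "trend": trend,
            "alarm": bp.detect_drift(trend),
        }
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
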