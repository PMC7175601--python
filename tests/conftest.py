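import numpy as np
import pytest

from predelect import FRSimConfig, FRTrial, simulate_fr_binomial

# Attack coefficient / handling time of the fastest-feeding predator group
# on carp eggs over a 1-day exposure: used throughout as the reference
# simulation condition.
EGG_A, EGG_H, EGG_T = 1.710, 0.081, 1.0


@pytest.fixture(scope="session")
def egg_trials():
    """One simulated carp-egg FR experiment, 20 replicates per density."""
    cfg = FRSimConfig(a=EGG_A, h=EGG_H, t_days=EGG_T, replicates_per_density=20, seed=42)
    return simulate_fr_binomial(cfg)


def make_trial(n0, consumed, trial_id="t0", t_days=1.0, **kw):
    """Minimal FR trial with a given number of whole prey eaten."""
    return FRTrial(
        trial_id=trial_id,
        group=kw.pop("group", "g"),
        prey=kw.pop("prey", "carp_larva"),
        n0=n0,
        t_days=t_days,
        whole_remaining=n0 - consumed,
        **kw,
    )


def trials_from_counts(density_counts, t_days=1.0):
    """Build a trial list from {density: [consumed, ...]} mappings."""
    trials = []
    i = 0
    for n0, counts in density_counts.items():
        for c in counts:
            trials.append(make_trial(n0, c, trial_id=f"t{i}", t_days=t_days))
            i += 1
    return trials
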