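import numpy as np
import pytest

from lungeforge.io import RunConfig
from lungeforge.synthetic import default_profile, simulate_cohort, simulate_deployment

SPECIES = ("minke", "humpback", "fin", "blue")


@pytest.fixture(scope="session")
def deployments():
    """One default-noise deployment per species (expensive; shared)."""
    return {sp: simulate_deployment(default_profile(sp), n_dives=3, seed=7)
            for sp in SPECIES}


@pytest.fixture(scope="session")
def detected(deployments):
    from lungeforge.kinematics import detect_lunges
    return {sp: detect_lunges(dep.trace) for sp, dep in deployments.items()}


@pytest.fixture(scope="session")
def cohort_bundle():
    """Small analyzed multi-species cohort (shared across tests)."""
    from lungeforge.pipeline import analyze_cohort
    cohort = simulate_cohort(n_individuals=3, seed=11, n_dives=2)
    return analyze_cohort(cohort, RunConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def match_truth(events, truth_event, window=2.0):
    """The detected lunge closest in T_MO to an injected one, or None."""
    cands = [e for e in events if abs(e.T_MO - truth_event.T_MO) < window]
    if not cands:
        return None
    return min(cands, key=lambda e: abs(e.T_MO - truth_event.T_MO))
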