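import numpy as np
import pytest

from orplan.instance import Instance, Patient
from orplan.pipeline import SolveConfig, full_pipeline


def make_tiny() -> Instance:
    """Three patients, two 12-slot days, one OR: the hand-checkable
    reference instance (nominal optimum 19 by enumeration)."""
    patients = [
        Patient("P1", 8, 30, 28, (1, 2), (1,)),
        Patient("P2", 10, 360, 0, (1, 2), (1,)),
        Patient("P3", 8, 180, 100, (1, 2), (1,)),
    ]
    return Instance(
        horizon_days=2, num_ors=1, capacity=np.full((2, 1), 12),
        patients=patients, rs_days=(1,), emergency_classes=(4, 8),
        delta_noshow=1, delta_max=1,
    )


@pytest.fixture(scope="session")
def tiny_instance() -> Instance:
    return make_tiny()


@pytest.fixture(scope="session")
def tiny_bundle(tiny_instance):
    return full_pipeline(tiny_instance, SolveConfig(strategy="heuristic",
                                                    mode="fix", time_limit=60))


@pytest.fixture(scope="session")
def tiny_bundle_faithful(tiny_instance):
    return full_pipeline(tiny_instance, SolveConfig(strategy="heuristic",
                                                    mode="faithful", time_limit=60))


def random_tiny_instance(seed: int) -> Instance:
    """Random instances inside the oracle guard rails."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 7))
    D = int(rng.integers(1, 3))
    J = int(rng.integers(1, 3))
    T = int(rng.integers(8, 16))
    patients = []
    for k in range(n):
        li = int(rng.choice([30, 60, 90, 180, 360]))
        patients.append(Patient(
            id=f"P{k + 1}",
            duration_slots=int(rng.integers(2, max(3, T // 2))),
            deadline_days=li,
            waited_days=int(rng.integers(0, li)),
            compatible_days=tuple(d for d in range(1, D + 1) if rng.random() > 0.15),
            compatible_ors=tuple(j for j in range(1, J + 1) if rng.random() > 0.15),
        ))
    return Instance(
        horizon_days=D, num_ors=J, capacity=np.full((D, J), T),
        patients=patients, rs_days=(1,),
        emergency_classes=(2, max(2, T // 2)),
        delta_noshow=min(1, D - 1) or 1, delta_max=max(1, D - 1),
    ) if D >= 2 else Instance(
        horizon_days=2, num_ors=J, capacity=np.full((2, J), T),
        patients=[Patient(p.id, p.duration_slots, p.deadline_days, p.waited_days,
                          (1, 2), p.compatible_ors) for p in patients],
        rs_days=(1,), emergency_classes=(2, max(2, T // 2)),
        delta_noshow=1, delta_max=1,
    )
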