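import numpy as np
import pytest

from orplan.backend import HighsBackend
from orplan.instance import Instance, Patient, PenaltyTable
from orplan.model import build_nominal_model
from orplan.oracle import (
    OracleSizeError,
    brute_force_nominal,
    exhaustive_rs_check,
)
from orplan.pipeline import SolveConfig, full_pipeline

from conftest import random_tiny_instance


class TestBruteForceNominal:
    def test_tiny_unique_argmin(self, tiny_instance):
        res = brute_force_nominal(tiny_instance)
        assert res.objective == pytest.approx(19.0)
        assert res.objective_exact == 19
        assert len(res.argmins) == 1
        assert res.argmins[0] == {"P1": (1, 1), "P2": None, "P3": (2, 1)}
        # capacity pruning cuts whole branches of the 3^3 assignment tree
        assert 0 < res.states <= 27

    def test_single_patient(self):
        p = Patient("A", 4, 30, 5, (1,), (1,))
        inst = Instance(horizon_days=2, num_ors=1, capacity=np.full((2, 1), 12),
                        patients=[p], rs_days=(1,), emergency_classes=(4,),
                        delta_noshow=1, delta_max=1)
        pen = PenaltyTable.from_instance(inst)
        res = brute_force_nominal(inst, pen)
        assert res.objective == pytest.approx(pen.p[0, 0])

    def test_all_incompatible(self):
        patients = [Patient(f"P{k}", 4, 30, 0, (), ()) for k in range(3)]
        inst = Instance(horizon_days=2, num_ors=1, capacity=np.full((2, 1), 12),
                        patients=patients, rs_days=(1,), emergency_classes=(4,),
                        delta_noshow=1, delta_max=1)
        pen = PenaltyTable.from_instance(inst)
        res = brute_force_nominal(inst, pen)
        assert res.objective == pytest.approx(pen.q.sum())

    def test_guard_rails(self):
        patients = [Patient(f"P{k}", 2, 360, 0, (1, 2), (1,)) for k in range(8)]
        inst = Instance(horizon_days=2, num_ors=1, capacity=np.full((2, 1), 24),
                        patients=patients, rs_days=(1,), emergency_classes=(4,),
                        delta_noshow=1, delta_max=1)
        with pytest.raises(OracleSizeError):
            brute_force_nominal(inst)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_milp_on_random_tiny(self, seed):
        inst = random_tiny_instance(seed)
        oracle = brute_force_nominal(inst)
        h = build_nominal_model(inst)
        res = HighsBackend().solve(h.model)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(oracle.objective, abs=1e-6)


class TestExhaustiveRsCheck:
    def test_tiny_bundle_feasible_and_conditionally_optimal(self, tiny_instance, tiny_bundle):
        ok, cert = exhaustive_rs_check(tiny_bundle, tiny_instance)
        assert ok, cert
        for entry in cert["emergency"].values():
            assert entry["plan_feasible"]
            assert entry["plan_penalty"] <= entry["min_penalty"] + 1e-9

    def test_guard_rails(self, tiny_bundle):
        patients = [Patient(f"P{k}", 2, 360, 0, (1, 2), (1,)) for k in range(8)]
        inst = Instance(horizon_days=2, num_ors=1, capacity=np.full((2, 1), 24),
                        patients=patients, rs_days=(1,), emergency_classes=(4,),
                        delta_noshow=1, delta_max=1)
        with pytest.raises(OracleSizeError):
            exhaustive_rs_check(tiny_bundle, inst)

    def test_full_capacity_emergency_displaces_everyone(self):
        # gamma = T and Omega = 0: zero elective capacity remains on the
        # struck OR, so every backup plan moves all its day-1 patients
        p1 = Patient("A", 4, 90, 10, (1, 2), (1,))
        p2 = Patient("B", 4, 360, 0, (1, 2), (1,))
        inst = Instance(horizon_days=2, num_ors=1, capacity=np.full((2, 1), 12),
                        patients=[p1, p2], rs_days=(1,), emergency_classes=(12,),
                        delta_noshow=1, delta_max=1, overtime_slots=0)
        bundle = full_pipeline(inst, SolveConfig(mode="fix", time_limit=60))
        ok, cert = exhaustive_rs_check(bundle, inst)
        assert ok, cert
        for (h, g, l), plan in bundle.emergency_plans.items():
            occ = min(12, 12 - h)
            for pid, d, j in plan.assignments:
                if d == g:
                    # whatever remains on day g must fit in 12 - occ slots
                    assert occ + 4 <= 12 or d != g

    def test_noshow_without_substitute_candidates(self):
        # the only patient is compatible with day 1 alone: no substitute can
        # exist, the model is infeasible without the dummy escape
        p = Patient("A", 4, 90, 10, (1,), (1,))
        inst = Instance(horizon_days=2, num_ors=1, capacity=np.full((2, 1), 12),
                        patients=[p], rs_days=(1,), emergency_classes=(4,),
                        delta_noshow=1, delta_max=1)
        from orplan.pipeline import PipelineStepError
        with pytest.raises(PipelineStepError):
            full_pipeline(inst, SolveConfig(mode="fix", time_limit=30))
        bundle = full_pipeline(inst, SolveConfig(mode="fix", time_limit=30,
                                                 allow_dummy_substitute=True))
        assert bundle.substitutes[(1, 1)] is None
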