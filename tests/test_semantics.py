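import numpy as np
import pytest

from orplan.instance import Instance, Patient, PenaltyTable
from orplan.semantics import (
    EmergencyPlan,
    NominalEntry,
    NoShowPlan,
    ScheduleStructureError,
    SolutionBundle,
    apply_emergency,
    apply_noshow,
    decode_schedule,
    evaluate_objective,
    validate_bundle,
)


def bare_instance(durations, T=24, D=2, J=1, **kw):
    patients = [Patient(f"P{k + 1}", t, 360, 0,
                        tuple(range(1, D + 1)), tuple(range(1, J + 1)))
                for k, t in enumerate(durations)]
    defaults = dict(rs_days=(1,), emergency_classes=(4,), delta_noshow=1, delta_max=1)
    defaults.update(kw)
    return Instance(horizon_days=D, num_ors=J, capacity=np.full((D, J), T),
                    patients=patients, **defaults)


def empty_bundle(nominal, **kw):
    defaults = dict(substitutes={}, emergency_plans={}, noshow_plans={},
                    metrics={"noshow_mode": "fixed_delay"})
    defaults.update(kw)
    return SolutionBundle(nominal=nominal, **defaults)


class TestDecode:
    def test_cumulative_starts(self):
        inst = bare_instance([8, 6])
        bundle = empty_bundle([
            NominalEntry("P1", 1, 1, position=1, start_slot=1),
            NominalEntry("P2", 1, 1, position=2, start_slot=9),
        ])
        decoded = decode_schedule(bundle, inst)
        day = decoded[(1, 1)]
        assert day.sequence == [("P1", 1, 8), ("P2", 9, 6)]
        assert day.completion == 15

    def test_empty_or(self):
        inst = bare_instance([8])
        bundle = empty_bundle([NominalEntry("P1", 2, 1)])
        decoded = decode_schedule(bundle, inst)
        assert decoded[(1, 1)].sequence == []
        assert decoded[(1, 1)].completion == 0
        assert not decoded[(1, 1)].busy(5)
        assert decoded[(1, 1)].availability(5) == 5

    def test_duplicate_position_rejected(self):
        inst = bare_instance([4, 4])
        bundle = empty_bundle([
            NominalEntry("P1", 1, 1, position=1, start_slot=1),
            NominalEntry("P2", 1, 1, position=1, start_slot=5),
        ])
        with pytest.raises(ScheduleStructureError, match=r"\(10\)"):
            decode_schedule(bundle, inst)

    def test_position_gap_rejected(self):
        inst = bare_instance([4, 4])
        bundle = empty_bundle([
            NominalEntry("P1", 1, 1, position=1, start_slot=1),
            NominalEntry("P2", 1, 1, position=3, start_slot=5),
        ])
        with pytest.raises(ScheduleStructureError, match=r"\(9\)"):
            decode_schedule(bundle, inst)

    def test_wrong_start_slot_rejected(self):
        inst = bare_instance([8, 6])
        bundle = empty_bundle([
            NominalEntry("P1", 1, 1, position=1, start_slot=1),
            NominalEntry("P2", 1, 1, position=2, start_slot=10),
        ])
        with pytest.raises(ScheduleStructureError, match=r"\(11\)"):
            decode_schedule(bundle, inst)

    def test_busy_and_operating(self):
        inst = bare_instance([8, 6])
        bundle = empty_bundle([
            NominalEntry("P1", 1, 1, position=1, start_slot=1),
            NominalEntry("P2", 1, 1, position=2, start_slot=9),
        ])
        day = decode_schedule(bundle, inst)[(1, 1)]
        assert day.operating(0) == "P1"  # moment 0 belongs to the first surgery
        assert day.operating(8) == "P1"
        assert day.operating(9) == "P2"
        assert day.availability(9) == 15
        assert day.operating(15) is None


class TestValidator:
    def test_capacity_violation(self):
        inst = bare_instance([10, 10, 5])
        bundle = empty_bundle([
            NominalEntry("P1", 1, 1, position=1, start_slot=1),
            NominalEntry("P2", 1, 1, position=2, start_slot=11),
            NominalEntry("P3", 1, 1, position=3, start_slot=21),
        ])
        rep = validate_bundle(bundle, inst)
        hits = [v for v in rep.violations if v.equation == "6"]
        assert len(hits) == 1
        assert hits[0].block == "A"
        assert hits[0].slack == -1  # 25 > 24

    def test_anticipating_noshow_plan_flagged(self):
        inst = bare_instance([4, 4], D=3, delta_noshow=2, delta_max=2)
        nominal = [
            NominalEntry("P1", 1, 1, position=1, start_slot=1),
            NominalEntry("P2", 2, 1),
        ]
        # P2 anticipated to day 1 although not the summoned substitute
        plan = NoShowPlan(assignments=[("P1", 3, 1), ("P2", 1, 1)])
        bundle = empty_bundle(nominal, noshow_plans={("P1", 1): plan},
                              substitutes={(1, 1): None},
                              metrics={"noshow_mode": "fixed_delay",
                                       "allow_dummy_substitute": True})
        rep = validate_bundle(bundle, inst)
        assert any(v.block == "H" and v.equation == "47" for v in rep.violations)

    def test_pipeline_bundle_clean(self, tiny_instance, tiny_bundle):
        rep = validate_bundle(tiny_bundle, tiny_instance)
        assert rep.ok, rep.table()

    def test_report_roundtrip(self):
        inst = bare_instance([10, 10, 5])
        bundle = empty_bundle([
            NominalEntry("P1", 1, 1, position=1, start_slot=1),
            NominalEntry("P2", 1, 1, position=2, start_slot=11),
            NominalEntry("P3", 1, 1, position=3, start_slot=21),
        ])
        rep = validate_bundle(bundle, inst)
        assert not rep.ok
        assert rep.counts().get("A") == 1
        assert "6" in rep.to_json()
        assert "Block A" in rep.table()


class TestEvaluateObjective:
    def test_tiny_nominal(self, tiny_instance, tiny_bundle):
        assert evaluate_objective(tiny_bundle, tiny_instance, "nominal") == pytest.approx(19.0)

    def test_all_unscheduled(self, tiny_instance):
        bundle = empty_bundle([])
        pen = PenaltyTable.from_instance(tiny_instance)
        value = evaluate_objective(bundle, tiny_instance, "nominal")
        assert value == pytest.approx(pen.q.sum())

    def test_identical_plans_average_to_nominal(self, tiny_instance):
        nominal = [NominalEntry("P1", 1, 1, position=1, start_slot=1),
                   NominalEntry("P3", 2, 1)]
        plans = {
            (h, 1, 0): EmergencyPlan(or_assigned=1,
                                     assignments=[("P1", 1, 1), ("P3", 2, 1)])
            for h in range(12)
        }
        bundle = empty_bundle(nominal, emergency_plans=plans)
        nominal_value = evaluate_objective(bundle, tiny_instance, "nominal")
        assert evaluate_objective(bundle, tiny_instance, "emergency") == \
            pytest.approx(nominal_value)

    def test_matches_solver_on_pipeline_bundle(self, tiny_instance, tiny_bundle):
        steps = {r["step"]: r for r in tiny_bundle.metrics["steps"]}
        o54 = evaluate_objective(tiny_bundle, tiny_instance, "emergency")
        o56 = evaluate_objective(tiny_bundle, tiny_instance, "noshow")
        assert o54 == pytest.approx(steps["step7_emergency"]["objective"],
                                    rel=1e-6, abs=1e-6)
        assert o56 == pytest.approx(steps["step9_noshow"]["objective"],
                                    rel=1e-6, abs=1e-6)

    def test_missing_plans_raise(self, tiny_instance):
        bundle = empty_bundle([])
        with pytest.raises(RuntimeError):
            evaluate_objective(bundle, tiny_instance, "emergency")


class TestApplyEmergency:
    def test_first_available_or_chosen(self, tiny_instance, tiny_bundle):
        for scenario in tiny_bundle.emergency_plans:
            out = apply_emergency(tiny_bundle, scenario, tiny_instance)
            avail = out["availability"]
            assert avail[out["chosen_or"]] == min(avail.values())

    def test_no_displacement_when_or_finished(self, tiny_instance, tiny_bundle):
        decoded = decode_schedule(tiny_bundle, tiny_instance)
        for (h, g, l), _ in tiny_bundle.emergency_plans.items():
            if all(h >= d.completion for (gg, j), d in decoded.items() if gg == g):
                out = apply_emergency(tiny_bundle, (h, g, l), tiny_instance)
                assert out["displaced"] == []

    def test_capacity_bound_with_long_emergency(self):
        # T=24, gamma=16, omega=4, h=7: elective day-g load <= 12 on the hit OR
        inst = bare_instance([4, 4, 4, 6], T=24, D=3,
                             emergency_classes=(16,), delta_noshow=2, delta_max=2)
        from orplan.pipeline import SolveConfig, full_pipeline
        bundle = full_pipeline(inst, SolveConfig(mode="fix", time_limit=60))
        out = apply_emergency(bundle, (7, 1, 0), inst)
        jstar = out["chosen_or"]
        occ = min(16, 24 - 7)
        assert out["day_g_load"][jstar] <= out["day_g_bound"][jstar]
        assert out["day_g_load"][jstar] - occ <= 24 - 16 + 4

    def test_displaced_reappear_within_delta(self, tiny_instance, tiny_bundle):
        for scenario in tiny_bundle.emergency_plans:
            out = apply_emergency(tiny_bundle, scenario, tiny_instance)
            for pid in out["displaced"]:
                assert pid in out["reappearance"] or pid in out["dropped"]
                if pid in out["reappearance"]:
                    g = scenario[1]
                    assert g <= out["reappearance"][pid] < g + tiny_instance.delta_max + 1

    def test_unknown_scenario(self, tiny_instance, tiny_bundle):
        with pytest.raises(KeyError):
            apply_emergency(tiny_bundle, (99, 1, 0), tiny_instance)


class TestApplyNoshow:
    def test_substitute_swap_and_fixed_delay(self, tiny_instance, tiny_bundle):
        scenario = ("P1", 1)  # P1 is nominally on day 1
        out = apply_noshow(tiny_bundle, scenario, tiny_instance)
        assert out["substitute"] == "P3"  # the only day-2 patient
        assert out["substitute_moved_to"] == (1, 1)
        assert out["noshow_reassigned_to"][0] == 1 + tiny_instance.delta_noshow
        for j, load in out["day_g_load"].items():
            assert load <= out["day_g_bound"][j]

    def test_substitute_appears_once(self, tiny_instance, tiny_bundle):
        plan = tiny_bundle.noshow_plans[("P1", 1)]
        counts = {}
        for pid, d, j in plan.assignments:
            counts[pid] = counts.get(pid, 0) + 1
        assert all(v == 1 for v in counts.values())

    def test_not_scheduled_patient_rejected(self, tiny_instance, tiny_bundle):
        with pytest.raises(ValueError):
            apply_noshow(tiny_bundle, ("P3", 1), tiny_instance)  # P3 is on day 2
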