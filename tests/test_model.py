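import numpy as np
import pytest

from orplan.backend import HighsBackend
from orplan.instance import Instance, Patient, PenaltyTable
from orplan.model import (
    attach_auxiliary_block,
    build_complete_model,
    build_nominal_model,
    enumerate_scenarios,
    extract_solution,
    set_objective,
)


def solve(handle, **kw):
    return HighsBackend().solve(handle.model, **kw)


def flat_instance(durations, T=24, D=2, J=1, gammas=(4, 8), deadlines=None):
    deadlines = deadlines or [360] * len(durations)
    patients = [Patient(f"P{k + 1}", t, li, 0,
                        tuple(range(1, D + 1)), tuple(range(1, J + 1)))
                for k, (t, li) in enumerate(zip(durations, deadlines))]
    return Instance(horizon_days=D, num_ors=J, capacity=np.full((D, J), T),
                    patients=patients, rs_days=(1,), emergency_classes=gammas,
                    delta_noshow=1, delta_max=1)


class TestNominalModel:
    def test_variable_and_constraint_counts(self):
        inst = flat_instance([2, 2, 2])
        h = build_nominal_model(inst)
        assert h.model.blocks["x"].size == 3 * 2 * 1
        fams = h.model.families
        assert fams["4"]["count"] == 3
        assert fams["5"]["count"] == 6
        assert fams["6"]["count"] == 2
        assert h.model.nrows == 11

    def test_tiny_optimum(self, tiny_instance):
        h = build_nominal_model(tiny_instance)
        res = solve(h)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(19.0)
        x = np.rint(h.model.block_values("x", res.x)).astype(int)
        assert x[0, 0, 0] == 1  # P1 day 1
        assert x[2, 1, 0] == 1  # P3 day 2
        assert x[1].sum() == 0  # P2 unscheduled

    def test_all_incompatible_pays_all_exclusions(self):
        patients = [Patient(f"P{k}", 4, 360, 0, (), ()) for k in range(3)]
        inst = Instance(horizon_days=2, num_ors=1, capacity=np.full((2, 1), 12),
                        patients=patients, rs_days=(1,), emergency_classes=(4,),
                        delta_noshow=1, delta_max=1)
        pen = PenaltyTable.from_instance(inst)
        h = build_nominal_model(inst, pen)
        res = solve(h)
        assert res.objective == pytest.approx(pen.q.sum())

    def test_empty_waiting_list(self):
        inst = flat_instance([2])
        inst.patients = []
        with pytest.raises(ValueError):
            build_nominal_model(inst)

    def test_lp_relaxation_sandwich(self, tiny_instance):
        pen = PenaltyTable.from_instance(tiny_instance)
        h = build_nominal_model(tiny_instance, pen)
        lp = HighsBackend().solve(h.model, relax=True)
        ip = HighsBackend().solve(h.model)
        feasible_value = pen.q.sum()  # schedule nobody
        assert lp.objective <= ip.objective + 1e-9
        assert ip.objective <= feasible_value + 1e-9


class TestScenarios:
    def test_standard_counts(self):
        inst = flat_instance([2, 2], T=24, gammas=(4, 8, 16))
        scen = enumerate_scenarios(inst)
        assert len(scen.emergencies) == 24 * 1 * 3

    def test_tiny_counts(self, tiny_instance):
        scen = enumerate_scenarios(tiny_instance)
        assert len(scen.emergencies) == 12 * 1 * 2 == 24
        assert len(scen.noshows) <= tiny_instance.n_patients

    def test_xbar_size(self, tiny_instance):
        h = build_complete_model(tiny_instance)
        assert h.model.blocks["xbar"].size == 24 * 3 * 2 * 1 == 144

    def test_empty_emergency_classes(self):
        inst = flat_instance([2, 2], gammas=())
        scen = enumerate_scenarios(inst)
        assert scen.emergencies == ()
        h = build_complete_model(inst, scen)
        assert "xbar" not in h.model.blocks

    def test_duplicate_rejection(self):
        from orplan.model import ScenarioSet
        with pytest.raises(ValueError):
            ScenarioSet(emergencies=((0, 1, 0), (0, 1, 0)), noshows=())


class TestCompleteModel:
    def test_registry_audit_all_families(self, tiny_instance):
        h = build_complete_model(tiny_instance)
        fams = h.model.families
        expected = {str(k) for k in range(4, 50)}
        mode_absent = {"42"} if h.noshow_mode == "fixed_delay" else {"41"}
        missing = expected - set(fams) - mode_absent
        assert not missing, f"missing families: {sorted(missing)}"
        assert ("41" in fams) != ("42" in fams)
        # compatibility families are realized as variable bounds
        for fam in ("5", "34", "39", "44"):
            assert fams[fam]["kind"] == "bounds"
        assert fams["26"]["kind"] == "alias" and fams["26"]["target"] == "11"

    def test_window_mode_uses_42(self, tiny_instance):
        h = build_complete_model(tiny_instance, noshow_mode="window")
        assert "42" in h.model.families and "41" not in h.model.families

    def test_eq36_capacity_reduction(self):
        # T=24, gamma=16, omega=4: at h=7 the emergency occupies min(16, 17)=16
        inst = flat_instance([2, 2], T=24, gammas=(16,))
        inst2 = Instance(horizon_days=2, num_ors=1, capacity=np.full((2, 1), 24),
                         patients=inst.patients, rs_days=(1,), emergency_classes=(16,),
                         delta_noshow=1, delta_max=1, overtime_slots=4)
        h = build_complete_model(inst2)
        rows36 = h.model.rows_of("36")
        # one row per (scenario h, OR); single OR and single class here
        cols, vals, lb, ub = h.model.row(rows36[7])
        eta_col = h.model.col("eta", 7, 0, 0)
        coef = dict(zip(cols, vals))[eta_col]
        assert coef == 16.0
        assert ub == 24 + 4
        # at h=9 the emergency is truncated by the end of the day
        cols, vals, _, _ = h.model.row(rows36[9])
        assert dict(zip(cols, vals))[h.model.col("eta", 9, 0, 0)] == 15.0

    def test_complete_optimum_equals_nominal_when_capacity_is_loose(self):
        # with the dummy-substitute escape the only coupling left is capacity,
        # and with enough slack robustness costs nothing; without it the
        # model must keep a real substitute on the following day and pays
        # exactly that premium
        inst = flat_instance([2, 2], T=24, D=2, J=1, gammas=(4, 8))
        hn = build_nominal_model(inst)
        nominal = solve(hn).objective
        hc = build_complete_model(inst, allow_dummy_substitute=True)
        res = solve(hc, time_limit=60)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(nominal)
        hc2 = build_complete_model(inst)
        res2 = solve(hc2, time_limit=60)
        assert res2.objective == pytest.approx(nominal + 1.0)  # one patient pushed to day 2

    def test_complete_objective_at_least_nominal(self, tiny_instance):
        hn = build_nominal_model(tiny_instance)
        nominal = solve(hn).objective
        hc = build_complete_model(tiny_instance)
        res = solve(hc, time_limit=60)
        assert res.objective >= nominal - 1e-9

    def test_unscheduled_patient_has_zero_start(self, tiny_instance):
        hc = build_complete_model(tiny_instance)
        res = solve(hc, time_limit=60)
        sol = extract_solution(hc, res.x)
        unscheduled = [i for i in range(3) if sol["x"][i].sum() == 0]
        for i in unscheduled:
            assert sol["xi"][i].max() == pytest.approx(0.0)


class TestAuxiliaryBlocks:
    def _solved_complete(self, tiny_instance):
        h = build_complete_model(tiny_instance)
        res = solve(h, time_limit=60)
        return h, extract_solution(h, res.x)

    def test_block_i_zero_difference_attainable(self, tiny_instance):
        h, sol = self._solved_complete(tiny_instance)
        attach_auxiliary_block(h, "i", sol["x"])
        set_objective(h, "difference")
        res = solve(h, time_limit=60)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(0.0)

    def test_block_i_twice_fails(self, tiny_instance):
        h, sol = self._solved_complete(tiny_instance)
        attach_auxiliary_block(h, "i", sol["x"])
        with pytest.raises(RuntimeError):
            attach_auxiliary_block(h, "i", sol["x"])

    def test_block_ii_pins_admission(self, tiny_instance):
        h, sol = self._solved_complete(tiny_instance)
        assert sol["x"][0, 0, 0] == 1  # P1 on day 1
        attach_auxiliary_block(h, "ii", sol["x"])
        # try hard to move P1 off day 1: make day 1 expensive for P1
        set_objective(h, "nominal")
        c = h.model.obj.copy()
        c[h.model.col("x", 0, 0, 0)] += 1e4
        h.model.set_objective(c, h.model.obj_const, "3-perturbed")
        res = solve(h, time_limit=60)
        x = np.rint(h.model.block_values("x", res.x)).astype(int)
        assert x[0, 0, :].sum() == 1  # still admitted on day 1

    def test_block_iii_pins_start_slot(self, tiny_instance):
        h, sol = self._solved_complete(tiny_instance)
        attach_auxiliary_block(h, "iii", sol["y"])
        set_objective(h, "nominal")
        res = solve(h, time_limit=60)
        sol2 = extract_solution(h, res.x)
        # the pinned patient keeps position and start slot
        i, w, j0, s = np.argwhere(sol["y"] > 0)[0]
        assert sol2["y"][i, w, j0, s] == 1
        assert sol2["xi"][i, w, j0] == pytest.approx(sol["xi"][i, w, j0])

    def test_block_iii_without_reference_fails(self, tiny_instance):
        h = build_complete_model(tiny_instance)
        with pytest.raises(RuntimeError):
            attach_auxiliary_block(h, "iii", None)

    def test_objective_53_requires_block_i(self, tiny_instance):
        h = build_complete_model(tiny_instance)
        with pytest.raises(RuntimeError):
            set_objective(h, "difference")

    def test_objective_switch_keeps_constraints(self, tiny_instance):
        h = build_complete_model(tiny_instance)
        nrows = h.model.nrows
        set_objective(h, "emergency")
        set_objective(h, "noshow")
        set_objective(h, "nominal")
        assert h.model.nrows == nrows

    def test_objective_54_equals_nominal_when_plans_keep_everyone(self, tiny_instance):
        # scenario-average of identical terms: fix xbar copies to the nominal
        # assignment and evaluate
        h = build_complete_model(tiny_instance)
        res = solve(h, time_limit=60)
        sol = extract_solution(h, res.x)
        set_objective(h, "emergency")
        E = len(h.scenarios.emergencies)
        pen = h.penalties
        value = 0.0
        for e in range(E):
            sched = sol["xbar"][e].sum(axis=2)
            value += float((pen.p * sched).sum() + (pen.q * (1 - sched.sum(axis=1))).sum())
        c = h.model.obj
        manual = float(c @ res.x) + h.model.obj_const
        assert manual == pytest.approx(value / E)
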