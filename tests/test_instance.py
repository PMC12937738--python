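import json
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orplan.instance import (
    Instance,
    Patient,
    PenaltyTable,
    assignment_penalty,
    default_compatibility,
    exclusion_penalty,
    max_positions,
    read_waiting_list_csv,
    urgency_coefficient,
)


class TestUrgencyCoefficient:
    def test_year_deadline(self):
        assert urgency_coefficient(360) == 1

    def test_month_deadline(self):
        assert urgency_coefficient(30) == 12

    def test_exact_rational(self):
        u = urgency_coefficient(7)
        assert u == Fraction(360, 7)
        assert u != pytest.approx(51.43)
        assert u * 7 == 360  # exactness, not truncation

    @pytest.mark.parametrize("bad", [0, -3, 2.5])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            urgency_coefficient(bad)


class TestAssignmentPenalty:
    def test_no_tardiness_unit_urgency(self):
        assert assignment_penalty(0, 360, 1, 1) == 1

    def test_tardy_urgent_patient(self):
        # (5 + max(28 + 5 - 30, 0)) * 12
        assert assignment_penalty(28, 30, 12, 5) == 96

    def test_long_wait_but_within_deadline(self):
        assert assignment_penalty(100, 180, 2, 2) == 4

    def test_day_outside_horizon(self):
        with pytest.raises(ValueError):
            assignment_penalty(0, 30, 12, 15, horizon_days=14)
        with pytest.raises(ValueError):
            assignment_penalty(0, 30, 12, 0)

    def test_tardiness_only_weighting(self):
        # d + max(m + d - l, 0) * u
        assert assignment_penalty(28, 30, 12, 5, weighting="tardiness_only") == 5 + 3 * 12


class TestExclusionPenalty:
    def test_unit_urgency(self):
        assert exclusion_penalty(0, 360, 1, 2) == 3

    def test_tardy(self):
        # (28 + 2 + 1 + max(31 - 30, 0)) * 12
        assert exclusion_penalty(28, 30, 12, 2) == 384

    @given(m=st.integers(0, 400), li=st.sampled_from([30, 60, 90, 180, 360]),
           D=st.integers(1, 28), d=st.integers(1, 28))
    @settings(max_examples=60, deadline=None)
    def test_exclusion_dominates_assignment(self, m, li, D, d):
        if d > D:
            d = D
        u = urgency_coefficient(li)
        q = exclusion_penalty(m, li, u, D)
        p = assignment_penalty(m, li, u, d)
        assert q > p


class TestPenaltyMonotonicity:
    @given(m=st.integers(0, 300), li=st.sampled_from([30, 60, 90, 180, 360]),
           d=st.integers(1, 27))
    @settings(max_examples=60, deadline=None)
    def test_nondecreasing_in_day(self, m, li, d):
        u = urgency_coefficient(li)
        assert assignment_penalty(m, li, u, d + 1) >= assignment_penalty(m, li, u, d)

    def test_strictly_increasing_in_tardy_regime(self):
        u = urgency_coefficient(30)
        p1 = assignment_penalty(29, 30, u, 1)
        p2 = assignment_penalty(29, 30, u, 2)
        assert p2 > p1


class TestMaxPositions:
    def _inst(self, T, durations):
        patients = [
            Patient(f"P{k}", t, 360, 0, (1,), (1,)) for k, t in enumerate(durations)
        ]
        return Instance(horizon_days=2, num_ors=1, capacity=np.full((2, 1), T),
                        patients=patients, rs_days=(1,), emergency_classes=(1,),
                        delta_noshow=1, delta_max=1)

    def test_even_division(self):
        assert max_positions(self._inst(24, [2, 4, 8])) == 12

    def test_floor(self):
        assert max_positions(self._inst(24, [5, 7])) == 4

    def test_single_position(self):
        assert max_positions(self._inst(12, [12])) == 1

    def test_empty_waiting_list(self):
        inst = self._inst(12, [4])
        inst.patients = []
        with pytest.raises(ValueError):
            max_positions(inst)

    def test_definitional_bound(self, tiny_instance):
        S = max_positions(tiny_instance)
        tmin = int(tiny_instance.duration_array()[tiny_instance.compat_array()].min())
        assert S * tmin <= int(tiny_instance.capacity.max())


class TestWeekendMask:
    def test_14_days(self):
        working = default_compatibility(14)
        blocked = sorted(set(range(1, 15)) - set(working))
        assert blocked == [6, 7, 12, 14]

    def test_short_horizon_has_no_weekend(self):
        assert default_compatibility(5) == [1, 2, 3, 4, 5]

    def test_28_days(self):
        blocked = sorted(set(range(1, 29)) - set(default_compatibility(28)))
        assert blocked == [6, 7, 12, 14, 18, 21, 24, 28]


class TestPenaltyTable:
    def test_invariants_full_scan(self, tiny_instance):
        pen = PenaltyTable.from_instance(tiny_instance)
        pen.check()  # q > p, monotone

    def test_tiny_values(self, tiny_instance):
        pen = PenaltyTable.from_instance(tiny_instance)
        assert pen.p[0, 0] == 12 and pen.p[0, 1] == 24
        assert pen.q[0] == 384
        assert pen.p[1, 0] == 1 and pen.q[1] == 3
        assert pen.p[2, 1] == 4 and pen.q[2] == 206

    def test_rational_float_agreement(self, tiny_instance):
        pen = PenaltyTable.from_instance(tiny_instance)
        for i in range(tiny_instance.n_patients):
            assert abs(pen.q[i] - float(pen.q_exact[i])) < 1e-9
            for d in range(tiny_instance.horizon_days):
                assert abs(pen.p[i, d] - float(pen.p_exact[i][d])) < 1e-9


class TestInstanceIO:
    def test_json_round_trip(self, tiny_instance, tmp_path):
        path = tmp_path / "inst.json"
        tiny_instance.to_json(path)
        again = Instance.from_json(path)
        assert again.to_dict() == tiny_instance.to_dict()

    def test_field_names(self, tiny_instance):
        data = tiny_instance.to_dict()
        for key in ("horizon_days", "num_ors", "rs_days", "slot_minutes", "capacity",
                    "overtime_slots", "delta_max", "delta_noshow",
                    "emergency_classes", "epsilon", "patients"):
            assert key in data
        for key in ("id", "duration_slots", "deadline_days", "waited_days",
                    "compatible_days", "compatible_ors"):
            assert key in data["patients"][0]

    def test_csv_reader(self, tmp_path):
        path = tmp_path / "list.csv"
        path.write_text("id,duration_slots,deadline_days,waited_days\n"
                        "A,4,30,2\nB,8,360,100\n")
        patients = read_waiting_list_csv(path, horizon_days=14, num_ors=2)
        assert [p.id for p in patients] == ["A", "B"]
        assert patients[0].compatible_days == tuple(default_compatibility(14))
        assert patients[1].compatible_ors == (1, 2)

    def test_invalid_instances(self):
        with pytest.raises(ValueError):
            Patient("X", 0, 30, 0, (1,), (1,))  # zero duration
        with pytest.raises(ValueError):
            Patient("X", 1, 0, 0, (1,), (1,))  # zero deadline
        with pytest.raises(ValueError):
            Patient("X", 1, 30, -1, (1,), (1,))  # negative wait
        good = Patient("X", 4, 30, 0, (1, 2), (1,))
        with pytest.raises(ValueError):  # rs_days not a prefix
            Instance(horizon_days=3, num_ors=1, capacity=np.full((3, 1), 12),
                     patients=[good], rs_days=(2,), emergency_classes=(4,),
                     delta_noshow=1, delta_max=2)
        with pytest.raises(ValueError):  # delta_noshow > delta_max
            Instance(horizon_days=3, num_ors=1, capacity=np.full((3, 1), 12),
                     patients=[good], rs_days=(1,), emergency_classes=(4,),
                     delta_noshow=2, delta_max=1)
        with pytest.raises(ValueError):  # emergency class exceeds capacity
            Instance(horizon_days=3, num_ors=1, capacity=np.full((3, 1), 12),
                     patients=[good], rs_days=(1,), emergency_classes=(13,),
                     delta_noshow=1, delta_max=2)
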