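"""Exhaustive reference solver for tiny instances.

Ground truth for the nominal optimum (full enumeration of patient ->
{unscheduled} | (day, OR) maps) and for per-scenario backup-plan
feasibility/optimality, independent of any MILP machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .instance import Instance, PenaltyTable
from .semantics import SolutionBundle, decode_schedule

__all__ = ["OracleResult", "OracleSizeError", "brute_force_nominal", "exhaustive_rs_check"]

MAX_PATIENTS = 7
MAX_DAYS = 3
MAX_ORS = 2
MAX_STATES = 10 ** 6


class OracleSizeError(ValueError):
    """Instance exceeds the oracle guard rails."""


@dataclass
class OracleResult:
    objective: float
    objective_exact: Fraction
    argmins: list[dict[str, tuple[int, int] | None]]
    states: int


def _guard(instance: Instance) -> None:
    if instance.n_patients > MAX_PATIENTS:
        raise OracleSizeError(f"too many patients ({instance.n_patients} > {MAX_PATIENTS})")
    if instance.horizon_days > MAX_DAYS:
        raise OracleSizeError(f"horizon too long ({instance.horizon_days} > {MAX_DAYS})")
    if instance.num_ors > MAX_ORS:
        raise OracleSizeError(f"too many ORs ({instance.num_ors} > {MAX_ORS})")


def brute_force_nominal(instance: Instance,
                        penalties: PenaltyTable | None = None,
                        weighting: str = "full") -> OracleResult:
    """Exact minimum of the assignment-penalty objective by enumeration."""
    _guard(instance)
    pen = penalties or PenaltyTable.from_instance(instance, weighting)
    a = instance.compat_array()
    t = instance.duration_array()
    n, D, J = instance.n_patients, instance.horizon_days, instance.num_ors
    choices = []
    for i in range(n):
        opts: list[tuple[tuple[int, int] | None, Fraction]] = [(None, pen.q_exact[i])]
        for d0 in range(D):
            for j0 in range(J):
                if a[i, d0, j0]:
                    opts.append(((d0 + 1, j0 + 1), pen.p_exact[i][d0]))
        choices.append(opts)
    space = 1
    for opts in choices:
        space *= len(opts)
    if space > MAX_STATES:
        raise OracleSizeError(f"search space too large ({space} > {MAX_STATES})")

    cap0 = {(d0, j0): int(instance.capacity[d0, j0]) for d0 in range(D) for j0 in range(J)}
    best: list[Fraction] = [None]
    argmins: list[dict] = []
    assign: list = [None] * n
    states = 0

    def rec(i: int, cap: dict, cost: Fraction):
        nonlocal states
        if i == n:
            states += 1
            if best[0] is None or cost < best[0]:
                best[0] = cost
                argmins.clear()
            if cost == best[0]:
                argmins.append({
                    instance.patients[k].id: assign[k] for k in range(n)
                })
            return
        for slot, pcost in choices[i]:
            if slot is None:
                assign[i] = None
                rec(i + 1, cap, cost + pcost)
            else:
                d0, j0 = slot[0] - 1, slot[1] - 1
                ti = int(t[i, d0, j0])
                if cap[(d0, j0)] >= ti:
                    cap[(d0, j0)] -= ti
                    assign[i] = slot
                    rec(i + 1, cap, cost + pcost)
                    cap[(d0, j0)] += ti
        assign[i] = None

    rec(0, dict(cap0), Fraction(0))
    return OracleResult(objective=float(best[0]), objective_exact=best[0],
                        argmins=argmins, states=states)


def _scenario_penalty(assignments: dict, instance: Instance, pen: PenaltyTable) -> Fraction:
    total = Fraction(0)
    for i, pat in enumerate(instance.patients):
        slot = assignments.get(pat.id)
        if slot is None:
            total += pen.q_exact[i]
        else:
            total += pen.p_exact[i][slot[0] - 1]
    return total


def _enumerate_emergency_plans(instance: Instance, bundle: SolutionBundle,
                               scenario: tuple[int, int, int]):
    """Yield every feasible reschedule map for one emergency scenario,
    given the bundle's nominal schedule."""
    h, g, l = scenario
    inst = instance
    a = inst.compat_array()
    t = inst.duration_array()
    decoded = decode_schedule(bundle, inst)
    where = {e.patient: (e.day, e.orid) for e in bundle.nominal}
    starts = {pid: s for (gg, j), day in decoded.items() for pid, s, ti in day.sequence}
    avail = {j: decoded[(g, j)].availability(h) for j in inst.ors}
    amin = min(avail.values())
    eta_choices = [j for j in inst.ors if avail[j] <= amin]
    n, D = inst.n_patients, inst.horizon_days
    gam = inst.emergency_classes[l]
    Dlt = inst.delta_max

    opts = []
    ids = []
    for i, pat in enumerate(inst.patients):
        pid = pat.id
        if pid not in where:
            continue  # (31): never enters a reschedule
        dstar, jstar = where[pid]
        if dstar == g and starts[pid] <= h:
            o = [(g, jstar)]  # pinned: started at or before h
        elif dstar == g:
            # displaceable: must stay inside the emergency window, may not vanish
            o = [(d, j) for d in range(g, min(D, g + Dlt - 1) + 1)
                 for j in inst.ors if a[i, d - 1, j - 1]]
        else:
            o = [None] + [(d, j) for d in range(dstar, D + 1)
                          for j in inst.ors if a[i, d - 1, j - 1]]
        ids.append(pid)
        opts.append(o)

    def capacity_ok(assign: dict, eta: int) -> bool:
        for j in inst.ors:
            j0 = j - 1
            for d in range(g, D + 1):
                load = sum(t[inst.patient_index(pid), d - 1, j0]
                           for pid, slot in assign.items()
                           if slot is not None and slot == (d, j))
                cap = int(inst.capacity[d - 1, j0])
                if d == g:
                    occ = min(gam, cap - h) if j == eta else 0
                    if load + occ > cap + inst.overtime_slots:
                        return False
                elif load > cap:
                    return False
        return True

    def rec(k: int, cur: dict):
        if k == len(ids):
            for eta in eta_choices:
                if capacity_ok(cur, eta):
                    yield dict(cur), eta
            return
        for slot in opts[k]:
            cur[ids[k]] = slot
            yield from rec(k + 1, cur)
        del cur[ids[k]]

    yield from rec(0, {})


def _enumerate_noshow_plans(instance: Instance, bundle: SolutionBundle,
                            scenario: tuple[str, int], noshow_mode: str):
    """Yield every feasible reschedule map for one no-show scenario, given
    the bundle's nominal schedule and substitute designation."""
    bpid, g = scenario
    inst = instance
    a = inst.compat_array()
    t = inst.duration_array()
    where = {e.patient: (e.day, e.orid) for e in bundle.nominal}
    n, D = inst.n_patients, inst.horizon_days
    b_on_g = where.get(bpid, (None, None))[0] == g
    summoned = bundle.substitutes.get((g, where[bpid][1])) if b_on_g else None

    opts = []
    ids = []
    for i, pat in enumerate(inst.patients):
        pid = pat.id
        if pid not in where:
            continue  # (48)
        dstar, jstar = where[pid]
        if b_on_g and pid == bpid:
            if noshow_mode == "fixed_delay":
                dr = g + inst.delta_noshow
                o = [(dr, j) for j in inst.ors if a[i, dr - 1, j - 1]]
            else:
                o = [(d, j) for d in range(dstar, min(D, g + inst.delta_max - 1) + 1)
                     for j in inst.ors if a[i, d - 1, j - 1]]
        elif b_on_g and pid == summoned:
            # summoned substitute: forced onto the vacated OR on day g (40)
            o = [(g, where[bpid][1])]
        elif dstar == g:
            o = [(g, jstar)]  # (49)
        else:
            dmin = dstar if pid != summoned else 1
            o = [None] + [(d, j) for d in range(dmin, D + 1)
                          for j in inst.ors if a[i, d - 1, j - 1]]
        ids.append(pid)
        opts.append(o)

    def capacity_ok(assign: dict) -> bool:
        for j in inst.ors:
            j0 = j - 1
            for d in range(g, D + 1):
                load = sum(t[inst.patient_index(pid), d - 1, j0]
                           for pid, slot in assign.items()
                           if slot is not None and slot == (d, j))
                cap = int(inst.capacity[d - 1, j0])
                lim = cap + inst.overtime_slots if d == g else cap
                if load > lim:
                    return False
        return True

    def rec(k: int, cur: dict):
        if k == len(ids):
            if capacity_ok(cur):
                yield dict(cur)
            return
        for slot in opts[k]:
            cur[ids[k]] = slot
            yield from rec(k + 1, cur)
        del cur[ids[k]]

    yield from rec(0, {})


def exhaustive_rs_check(bundle: SolutionBundle, instance: Instance,
                        penalties: PenaltyTable | None = None,
                        check_optimality: bool | None = None) -> tuple[bool, dict]:
    """Confirm by enumeration that every backup plan in the bundle is
    feasible and (when the optimizing steps reported optimality) that no
    feasible plan with strictly smaller scenario penalty exists.

    Returns ``(ok, certificate)`` with per-scenario minima and the bundle's
    own penalties.
    """
    _guard(instance)
    pen = penalties or PenaltyTable.from_instance(instance)
    cert: dict = {"emergency": {}, "noshow": {}}
    ok = True
    steps = {r["step"]: r for r in bundle.metrics.get("steps", [])}
    if check_optimality is None:
        check_optimality = True
    opt7 = check_optimality and steps.get("step7_emergency", {}).get("status") == "optimal"
    opt9 = check_optimality and steps.get("step9_noshow", {}).get("status") == "optimal"

    for scenario, plan in bundle.emergency_plans.items():
        plan_map = {pid: (d, j) for pid, d, j in plan.assignments}
        feasible = []
        found = False
        for cand, eta in _enumerate_emergency_plans(instance, bundle, scenario):
            cand_clean = {pid: slot for pid, slot in cand.items() if slot is not None}
            feasible.append(_scenario_penalty(cand_clean, instance, pen))
            if cand_clean == plan_map and eta == plan.or_assigned:
                found = True
        best = min(feasible) if feasible else None
        mine = _scenario_penalty(plan_map, instance, pen)
        cert["emergency"][scenario] = {
            "feasible_count": len(feasible),
            "plan_feasible": found,
            "plan_penalty": float(mine),
            "min_penalty": float(best) if best is not None else None,
        }
        if not found:
            ok = False
        if opt7 and best is not None and mine > best:
            ok = False

    mode = bundle.metrics.get("noshow_mode", "fixed_delay")
    for scenario, plan in bundle.noshow_plans.items():
        plan_map = {pid: (d, j) for pid, d, j in plan.assignments}
        feasible = []
        found = False
        for cand in _enumerate_noshow_plans(instance, bundle, scenario, mode):
            cand_clean = {pid: slot for pid, slot in cand.items() if slot is not None}
            feasible.append(_scenario_penalty(cand_clean, instance, pen))
            if cand_clean == plan_map:
                found = True
        best = min(feasible) if feasible else None
        mine = _scenario_penalty(plan_map, instance, pen)
        cert["noshow"][scenario] = {
            "feasible_count": len(feasible),
            "plan_feasible": found,
            "plan_penalty": float(mine),
            "min_penalty": float(best) if best is not None else None,
        }
        if not found:
            ok = False
        if opt9 and best is not None and mine > best:
            ok = False
    return ok, cert
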