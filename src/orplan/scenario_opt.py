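"""Per-scenario backup-plan optimization for a *fixed* nominal schedule.

Once the assignment x and the within-day ordering are frozen, the
reschedule copy of each disruption scenario is an independent small MILP;
solving them one by one is two orders of magnitude faster than handing the
monolith to the solver and yields exactly the conditional optimum of the
scenario-averaged objectives given that nominal schedule.

Used by the pipeline's restricted ("fix"/"auto") modes; the faithful mode
still solves the monolithic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backend import HighsBackend, MilpModel, INF
from .instance import Instance, PenaltyTable

__all__ = [
    "NominalView",
    "ScenarioPlan",
    "best_emergency_plan",
    "best_noshow_plan",
    "choose_substitutes",
    "UnrecoverableError",
]


class UnrecoverableError(RuntimeError):
    """A scenario admits no feasible backup plan for this nominal schedule."""

    def __init__(self, scenario, message):
        super().__init__(f"scenario {scenario}: {message}")
        self.scenario = scenario


@dataclass
class NominalView:
    """Derived, read-only view of a fixed nominal schedule."""

    instance: Instance
    x: np.ndarray  # (n, D, J) 0/1
    starts: dict[int, int]  # patient index -> 1-based start slot (backup days)
    where: dict[int, tuple[int, int]]  # patient index -> (day, or)
    sequences: dict[tuple[int, int], list[tuple[int, int, int]]]  # (g,j) -> [(i, start, dur)]

    @classmethod
    def build(cls, instance: Instance, x: np.ndarray, y: np.ndarray) -> "NominalView":
        t = instance.duration_array()
        W = list(instance.rs_days)
        where = {}
        n, D, J = x.shape
        for i in range(n):
            pos = np.argwhere(x[i] > 0)
            if pos.size:
                where[i] = (int(pos[0][0]) + 1, int(pos[0][1]) + 1)
        sequences = {}
        starts = {}
        for w, g in enumerate(W):
            for j0 in range(J):
                order = []
                for i in range(n):
                    srow = np.nonzero(y[i, w, j0, :])[0]
                    if srow.size:
                        order.append((int(srow[0]), i))
                order.sort()
                seq = []
                cursor = 1
                for _, i in order:
                    ti = int(t[i, g - 1, j0])
                    seq.append((i, cursor, ti))
                    starts[i] = cursor
                    cursor += ti
                sequences[(g, j0 + 1)] = seq
        return cls(instance=instance, x=x, starts=starts, where=where, sequences=sequences)

    def availability(self, g: int, j: int, h: int) -> int:
        hh = max(h, 1)
        for i, s, ti in self.sequences[(g, j)]:
            if s <= hh <= s + ti - 1:
                return s + ti
        return h

    def pinned(self, g: int, j: int, h: int) -> list[tuple[int, int]]:
        """(patient, duration) pairs that started at or before h on (g, j)."""
        return [(i, ti) for i, s, ti in self.sequences[(g, j)] if s <= h]

    def day_load(self, g: int, j: int) -> int:
        return sum(ti for _, _, ti in self.sequences[(g, j)])

    def loads(self) -> dict[tuple[int, int], int]:
        """Total scheduled slots per (day, OR) over the whole horizon."""
        t = self.instance.duration_array()
        out = {(d, j): 0 for d in self.instance.days for j in self.instance.ors}
        for i, (d, j) in self.where.items():
            out[(d, j)] += int(t[i, d - 1, j - 1])
        return out


@dataclass
class ScenarioPlan:
    status: str
    penalty: float
    assignments: list[tuple[int, int, int]]  # (patient index, day, or)
    eta: int | None = None  # chosen OR (emergencies)


def _solve_small(m: MilpModel, cols_of: dict) -> tuple[str, dict | None, float | None]:
    res = HighsBackend().solve(m, time_limit=30)
    if not res.has_solution:
        return res.status, None, None
    chosen = {}
    for i, slots in cols_of.items():
        for (d, j), c in slots.items():
            if res.x[c] > 0.5:
                chosen[i] = (d, j)
    return res.status, chosen, res.objective


def best_emergency_plan(instance: Instance, pen: PenaltyTable, view: NominalView,
                        scenario: tuple[int, int, int],
                        cache: dict | None = None) -> ScenarioPlan:
    """Minimum-penalty reschedule for an emergency triple (h, g, l).

    ``cache`` may be shared across scenarios of the same nominal schedule:
    triples with the same pinned set, struck OR and residual occupancy
    induce the identical subproblem.
    """
    h, g, l = scenario
    inst = instance
    a = inst.compat_array()
    t = inst.duration_array()
    D, J = inst.horizon_days, inst.num_ors
    gam = inst.emergency_classes[l]
    Dlt = inst.delta_max
    g0 = g - 1
    avail = {j: view.availability(g, j, h) for j in inst.ors}
    amin = min(avail.values())
    eta_ties = [j for j in inst.ors if avail[j] <= amin]
    # shortcut: keeping the whole nominal schedule is optimal whenever the
    # emergency itself fits in the chosen OR with overtime, because every
    # patient already sits on their cheapest admissible day (penalties are
    # nondecreasing in the day and anticipation is banned)
    for eta in eta_ties:
        occ = min(gam, int(inst.capacity[g0, eta - 1]) - h)
        if view.day_load(g, eta) + occ <= int(inst.capacity[g0, eta - 1]) + inst.overtime_slots:
            assignments = sorted((i, d, j) for i, (d, j) in view.where.items())
            return ScenarioPlan("optimal", _nominal_penalty(pen, view), assignments, eta=eta)
    # slot layout and forced part are eta-independent
    const = float(pen.q.sum())
    pinned_load = {j: 0 for j in inst.ors}
    forced: list[tuple[int, int, int]] = []
    spec: list[tuple[int, bool, list[tuple[int, int]]]] = []  # (i, must, slots)
    for i, (dstar, jstar) in view.where.items():
        if dstar == g and view.starts[i] <= h:
            forced.append((i, g, jstar))
            pinned_load[jstar] += int(t[i, g0, jstar - 1])
            const += pen.p[i, g0] - pen.q[i]
            continue
        if dstar == g:
            slots = [(d, j) for d in range(g, min(D, g + Dlt - 1) + 1)
                     for j in inst.ors if a[i, d - 1, j - 1]]
            if not slots:
                raise UnrecoverableError(scenario, "impacted patient has no reschedule slot")
            spec.append((i, True, slots))
        else:
            slots = [(d, j) for d in range(dstar, D + 1)
                     for j in inst.ors if a[i, d - 1, j - 1]]
            if slots:
                spec.append((i, False, slots))
    key = None
    if cache is not None:
        occs = tuple(min(gam, int(inst.capacity[g0, j - 1]) - h) for j in eta_ties)
        key = (g, l, tuple(eta_ties), tuple(sorted(forced)), occs)
        hit = cache.get(key)
        if hit is not None:
            if hit == "infeasible":
                raise UnrecoverableError(scenario, "no feasible emergency reschedule")
            return ScenarioPlan(hit.status, hit.penalty, list(hit.assignments), eta=hit.eta)
    best: ScenarioPlan | None = None
    for eta in eta_ties:
        m = MilpModel(f"em_{h}_{g}_{l}_{eta}")
        nz = sum(len(s) for _, _, s in spec)
        zb = m.add_block("z", (max(nz, 1),), "binary")
        cols_of: dict[int, dict] = {}
        c = np.zeros(m.ncols)
        k = 0
        feasible = True
        for i, must, slots in spec:
            cmap = {}
            for (d, j) in slots:
                cmap[(d, j)] = k
                c[k] = pen.p[i, d - 1] - pen.q[i]
                k += 1
            cols_of[i] = cmap
            cols = list(cmap.values())
            m.add_row(cols, [1.0] * len(cols), 1.0 if must else -INF, 1.0, "assign")
        for j in inst.ors:
            j0 = j - 1
            for d in range(g, D + 1):
                cols = [cmap[(d, j)] for cmap in cols_of.values() if (d, j) in cmap]
                vals = [float(t[i, d - 1, j0]) for i, cmap in cols_of.items()
                        if (d, j) in cmap]
                cap = float(inst.capacity[d - 1, j0])
                if d == g:
                    occ = min(gam, inst.capacity[g0, j0] - h) if j == eta else 0
                    rhs = cap + inst.overtime_slots - occ - pinned_load[j]
                else:
                    rhs = cap
                if rhs < 0:
                    feasible = False
                    break
                if cols:
                    m.add_row(cols, vals, -INF, rhs, "cap")
            if not feasible:
                break
        if not feasible:
            continue
        m.set_objective(c, const)
        status, chosen, obj = _solve_small(m, cols_of)
        if chosen is None:
            continue
        assignments = list(forced) + [(i, d, j) for i, (d, j) in chosen.items()]
        plan = ScenarioPlan(status, float(obj), sorted(assignments), eta=eta)
        if best is None or plan.penalty < best.penalty - 1e-9:
            best = plan
    if best is None:
        if cache is not None:
            cache[key] = "infeasible"
        raise UnrecoverableError(scenario, "no feasible emergency reschedule")
    if cache is not None:
        cache[key] = best
    return best


def _nominal_penalty(pen: PenaltyTable, view: NominalView) -> float:
    total = float(pen.q.sum())
    for i, (d, _) in view.where.items():
        total += pen.p[i, d - 1] - pen.q[i]
    return total


def best_noshow_plan(instance: Instance, pen: PenaltyTable, view: NominalView,
                     scenario: tuple[int, int], substitute: int | None,
                     noshow_mode: str = "fixed_delay") -> ScenarioPlan:
    """Minimum-penalty reschedule for a no-show pair (b, g), given the
    substitute designated for b's OR (or None for the dummy option)."""
    b, g = scenario
    inst = instance
    a = inst.compat_array()
    t = inst.duration_array()
    D, J = inst.horizon_days, inst.num_ors
    g0 = g - 1
    if view.where.get(b, (None, None))[0] != g:
        # vacuous scenario: keeping the nominal schedule is optimal
        assignments = sorted((i, d, j) for i, (d, j) in view.where.items())
        return ScenarioPlan("optimal", _nominal_penalty(pen, view), assignments)
    jb = view.where[b][1]
    # shortcut (fixed-delay mode): swap the substitute in, move the no-show
    # exactly delta_noshow days later, keep everybody else — optimal whenever
    # it fits, because every other patient stays on their cheapest day
    if noshow_mode == "fixed_delay":
        loads = view.loads()
        cap_g = int(inst.capacity[g0, jb - 1])
        swap_load = loads[(g, jb)] - int(t[b, g0, jb - 1])
        if substitute is not None:
            swap_load += int(t[substitute, g0, jb - 1])
        if swap_load <= cap_g + inst.overtime_slots:
            dr = g + inst.delta_noshow
            for j in inst.ors:
                if a[b, dr - 1, j - 1] and loads[(dr, j)] + int(t[b, dr - 1, j - 1]) \
                        <= int(inst.capacity[dr - 1, j - 1]):
                    assignments = []
                    for i, (d, jj) in view.where.items():
                        if i == b:
                            assignments.append((i, dr, j))
                        elif i == substitute:
                            assignments.append((i, g, jb))
                        else:
                            assignments.append((i, d, jj))
                    penalty = _nominal_penalty(pen, view) \
                        + float(pen.p[b, dr - 1] - pen.p[b, g0])
                    if substitute is not None:
                        penalty += float(pen.p[substitute, g0] - pen.p[substitute, g])
                    return ScenarioPlan("optimal", penalty, sorted(assignments))
    const = float(pen.q.sum())
    forced: list[tuple[int, int, int]] = []
    day_load = {j: 0 for j in inst.ors}
    spec: list[tuple[int, bool, list[tuple[int, int]]]] = []
    for i, (dstar, jstar) in view.where.items():
        if i == b:
            if noshow_mode == "fixed_delay":
                dr = g + inst.delta_noshow
                slots = [(dr, j) for j in inst.ors if a[i, dr - 1, j - 1]]
            else:
                slots = [(d, j) for d in range(g, min(D, g + inst.delta_max - 1) + 1)
                         for j in inst.ors if a[i, d - 1, j - 1]]
            if not slots:
                return ScenarioPlan("infeasible", float("inf"), [])
            spec.append((i, True, slots))
        elif i == substitute:
            forced.append((i, g, jb))
            day_load[jb] += int(t[i, g0, jb - 1])
            const += pen.p[i, g0] - pen.q[i]
        elif dstar == g:
            forced.append((i, g, jstar))
            day_load[jstar] += int(t[i, g0, jstar - 1])
            const += pen.p[i, g0] - pen.q[i]
        else:
            slots = [(d, j) for d in range(dstar, D + 1)
                     for j in inst.ors if a[i, d - 1, j - 1]]
            if slots:
                spec.append((i, False, slots))
    m = MilpModel(f"ns_{b}_{g}")
    nz = sum(len(s) for _, _, s in spec)
    m.add_block("z", (max(nz, 1),), "binary")
    cols_of: dict[int, dict] = {}
    c = np.zeros(m.ncols)
    k = 0
    for i, must, slots in spec:
        cmap = {}
        for (d, j) in slots:
            cmap[(d, j)] = k
            c[k] = pen.p[i, d - 1] - pen.q[i]
            k += 1
        cols_of[i] = cmap
        cols = list(cmap.values())
        m.add_row(cols, [1.0] * len(cols), 1.0 if must else -INF, 1.0, "assign")
    for j in inst.ors:
        j0 = j - 1
        for d in range(g, D + 1):
            cols = [cmap[(d, j)] for cmap in cols_of.values() if (d, j) in cmap]
            vals = [float(t[i, d - 1, j0]) for i, cmap in cols_of.items()
                    if (d, j) in cmap]
            cap = float(inst.capacity[d - 1, j0])
            rhs = (cap + inst.overtime_slots - day_load[j]) if d == g else cap
            if rhs < 0:
                return ScenarioPlan("infeasible", float("inf"), [])
            if cols:
                m.add_row(cols, vals, -INF, rhs, "cap")
    m.set_objective(c, const)
    status, chosen, obj = _solve_small(m, cols_of)
    if chosen is None:
        return ScenarioPlan("infeasible", float("inf"), [])
    assignments = list(forced) + [(i, d, j) for i, (d, j) in chosen.items()]
    return ScenarioPlan(status, float(obj), sorted(assignments))


MAX_SUBSTITUTE_CANDIDATES = 8


def choose_substitutes(instance: Instance, pen: PenaltyTable, view: NominalView,
                       noshow_mode: str = "fixed_delay",
                       allow_dummy: bool = False):
    """Pick one distinct substitute per (backup day, OR) minimizing the
    total no-show penalty, and return the resulting per-scenario plans.

    Candidates are patients nominally scheduled the day after, compatible
    with the OR they would cover; at most ``MAX_SUBSTITUTE_CANDIDATES`` per
    OR (shortest surgeries first) are scored exactly.
    """
    inst = instance
    a = inst.compat_array()
    t = inst.duration_array()
    theta: dict[tuple[int, int], int | None] = {}
    plans: dict[tuple[int, int], ScenarioPlan] = {}
    truncated = False
    for g in inst.rs_days:
        g0 = g - 1
        cand: dict[int, list[int]] = {}
        for j in inst.ors:
            cs = [i for i, (d, _) in view.where.items()
                  if d == g + 1 and a[i, g0, j - 1]]
            cs.sort(key=lambda i: (int(t[i, g0, j - 1]), i))
            if len(cs) > MAX_SUBSTITUTE_CANDIDATES:
                truncated = True
                cs = cs[:MAX_SUBSTITUTE_CANDIDATES]
            if not cs and not allow_dummy:
                raise UnrecoverableError(
                    ("substitute", g, j),
                    "no eligible substitute on the following day")
            cand[j] = cs
        noshows_on = {j: [i for i, (d, jj) in view.where.items()
                          if d == g and jj == j] for j in inst.ors}
        # exact score of each (OR, candidate) pair
        score: dict[int, dict[int | None, tuple[float, dict]]] = {}
        for j in inst.ors:
            score[j] = {}
            options: list[int | None] = list(cand[j]) or [None]
            for c in options:
                total = 0.0
                per_b = {}
                feasible = True
                for b in noshows_on[j]:
                    plan = best_noshow_plan(inst, pen, view, (b, g), c, noshow_mode)
                    if plan.status == "infeasible":
                        feasible = False
                        break
                    total += plan.penalty
                    per_b[b] = plan
                if feasible:
                    score[j][c] = (total, per_b)
        # distinct assignment of candidates to ORs (tiny: brute force)
        ors = list(inst.ors)
        best_combo = None
        best_val = float("inf")
        def combos(k, used, acc, val):
            nonlocal best_combo, best_val
            if val >= best_val:
                return
            if k == len(ors):
                best_combo, best_val = dict(acc), val
                return
            j = ors[k]
            for c, (v, _) in score[j].items():
                if c is not None and c in used:
                    continue
                acc[j] = c
                combos(k + 1, used | ({c} if c is not None else set()), acc, val + v)
                del acc[j]
        combos(0, frozenset(), {}, 0.0)
        if best_combo is None:
            raise UnrecoverableError(("substitute", g), "no feasible substitute assignment")
        for j in inst.ors:
            c = best_combo[j]
            theta[(g, j)] = c
            for b, plan in score[j][c][1].items():
                plans[(b, g)] = plan
        # vacuous scenarios for patients not scheduled on g
        for i in range(inst.n_patients):
            if view.where.get(i, (None, None))[0] != g and a[i, g0, :].any():
                plans[(i, g)] = best_noshow_plan(inst, pen, view, (i, g), None, noshow_mode)
    return theta, plans, truncated
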