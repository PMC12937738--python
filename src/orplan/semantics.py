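"""Decode solver output into schedules and re-verify every constraint block
by direct arithmetic — no solver is ever consulted here.

Canonical OR-state semantics (used for validation and for applying plans):

* a patient with start slot ``s`` and duration ``t`` occupies slots
  ``s .. s+t-1``; the OR's completion ``C`` is the end slot of its last
  patient plus one (an empty OR has ``C = 0``);
* at moment ``h`` the OR is *busy* iff some patient has
  ``start <= max(h, 1) <= start + t - 1`` (moment 0 is attributed to the
  first surgery, which starts at slot 1);
* the availability at ``h`` is the end-plus-one slot of the patient
  operating at ``h``, or ``h`` itself when the OR is idle;
* a day-g patient can be displaced by an emergency at ``h`` only if their
  start slot strictly exceeds ``h``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .instance import Instance, PenaltyTable

__all__ = [
    "NominalEntry",
    "EmergencyPlan",
    "NoShowPlan",
    "SolutionBundle",
    "DecodedDay",
    "Violation",
    "ViolationReport",
    "ScheduleStructureError",
    "decode_schedule",
    "validate_bundle",
    "evaluate_objective",
    "apply_emergency",
    "apply_noshow",
]

TOL = 1e-6


class ScheduleStructureError(ValueError):
    """Raised when a bundle's ordering data is structurally broken."""


@dataclass
class NominalEntry:
    patient: str
    day: int
    orid: int
    position: int | None = None  # 1-based, only on backup-plan days
    start_slot: int | None = None  # 1-based


@dataclass
class EmergencyPlan:
    or_assigned: int
    impacted: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    assignments: list[tuple[str, int, int]] = field(default_factory=list)  # (pid, day, or)


@dataclass
class NoShowPlan:
    assignments: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class DecodedDay:
    day: int
    orid: int
    sequence: list[tuple[str, int, int]]  # (pid, start_slot, duration) in order
    completion: int  # first free slot (end of last surgery); 0 when empty

    def busy(self, h: int) -> bool:
        hh = max(h, 1)
        return any(s <= hh <= s + t - 1 for _, s, t in self.sequence)

    def operating(self, h: int) -> str | None:
        hh = max(h, 1)
        for pid, s, t in self.sequence:
            if s <= hh <= s + t - 1:
                return pid
        return None

    def availability(self, h: int) -> int:
        hh = max(h, 1)
        for pid, s, t in self.sequence:
            if s <= hh <= s + t - 1:
                return s + t
        return h


@dataclass
class SolutionBundle:
    """NS + all backup plans + run metadata, JSON round-trippable."""

    nominal: list[NominalEntry]
    substitutes: dict[tuple[int, int], str | None]  # (g, j) -> patient id
    emergency_plans: dict[tuple[int, int, int], EmergencyPlan]  # (h, g, l)
    noshow_plans: dict[tuple[str, int], NoShowPlan]  # (patient id, g)
    pinned_day_admissions: dict[int, list[str]] = field(default_factory=dict)
    ordering_reference: list[NominalEntry] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    # -- array views ----------------------------------------------------

    def x_array(self, instance: Instance) -> np.ndarray:
        x = np.zeros((instance.n_patients, instance.horizon_days, instance.num_ors), dtype=int)
        for e in self.nominal:
            x[instance.patient_index(e.patient), e.day - 1, e.orid - 1] = 1
        return x

    def plan_x_array(self, instance: Instance, assignments) -> np.ndarray:
        x = np.zeros((instance.n_patients, instance.horizon_days, instance.num_ors), dtype=int)
        for pid, d, j in assignments:
            x[instance.patient_index(pid), d - 1, j - 1] = 1
        return x

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "conventions": "days 1-based; ORs 1-based; moments h 0-based; start slots 1-based",
            "nominal": [
                {"patient": e.patient, "day": e.day, "or": e.orid,
                 "position": e.position, "start_slot": e.start_slot}
                for e in self.nominal
            ],
            "substitutes": [
                {"day": g, "or": j, "patient": pid}
                for (g, j), pid in sorted(self.substitutes.items())
            ],
            "emergency_plans": {
                f"{h},{g},{l}": {
                    "or": p.or_assigned,
                    "impacted": list(p.impacted),
                    "dropped": list(p.dropped),
                    "assignments": [
                        {"patient": pid, "day": d, "or": j} for pid, d, j in p.assignments
                    ],
                }
                for (h, g, l), p in sorted(self.emergency_plans.items())
            },
            "noshow_plans": {
                f"{b},{g}": {
                    "assignments": [
                        {"patient": pid, "day": d, "or": j} for pid, d, j in p.assignments
                    ],
                }
                for (b, g), p in sorted(self.noshow_plans.items())
            },
            "pinned_day_admissions": {str(g): ids for g, ids in self.pinned_day_admissions.items()},
            "ordering_reference": [
                {"patient": e.patient, "day": e.day, "or": e.orid, "position": e.position}
                for e in self.ordering_reference
            ],
            "metrics": self.metrics,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "SolutionBundle":
        nominal = [
            NominalEntry(e["patient"], int(e["day"]), int(e["or"]),
                         e.get("position"), e.get("start_slot"))
            for e in data["nominal"]
        ]
        subs = {
            (int(s["day"]), int(s["or"])): s["patient"] for s in data.get("substitutes", [])
        }
        eplans = {}
        for key, p in data.get("emergency_plans", {}).items():
            h, g, l = (int(v) for v in key.split(","))
            eplans[(h, g, l)] = EmergencyPlan(
                or_assigned=int(p["or"]),
                impacted=list(p.get("impacted", [])),
                dropped=list(p.get("dropped", [])),
                assignments=[(a["patient"], int(a["day"]), int(a["or"]))
                             for a in p["assignments"]],
            )
        nplans = {}
        for key, p in data.get("noshow_plans", {}).items():
            b, g = key.rsplit(",", 1)
            nplans[(b, int(g))] = NoShowPlan(
                assignments=[(a["patient"], int(a["day"]), int(a["or"]))
                             for a in p["assignments"]],
            )
        return cls(
            nominal=nominal,
            substitutes=subs,
            emergency_plans=eplans,
            noshow_plans=nplans,
            pinned_day_admissions={int(g): ids for g, ids in
                                   data.get("pinned_day_admissions", {}).items()},
            ordering_reference=[
                NominalEntry(e["patient"], int(e["day"]), int(e["or"]), e.get("position"))
                for e in data.get("ordering_reference", [])
            ],
            metrics=data.get("metrics", {}),
        )

    @classmethod
    def from_json(cls, path) -> "SolutionBundle":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def decode_schedule(bundle: SolutionBundle, instance: Instance) -> dict[tuple[int, int], DecodedDay]:
    """Rebuild per-(day, OR) sequences on backup-plan days from positions,
    recomputing start slots cumulatively; stored start slots must agree."""
    out: dict[tuple[int, int], DecodedDay] = {}
    t = instance.duration_array()
    for g in instance.rs_days:
        for j in instance.ors:
            entries = [e for e in bundle.nominal if e.day == g and e.orid == j]
            positions = [e.position for e in entries]
            if any(p is None for p in positions):
                raise ScheduleStructureError(
                    f"missing position on day {g} OR {j} (ordering families (8)-(10))")
            if len(set(positions)) != len(positions):
                raise ScheduleStructureError(
                    f"duplicated position on day {g} OR {j} (family (10))")
            if sorted(positions) != list(range(1, len(positions) + 1)):
                raise ScheduleStructureError(
                    f"position gap on day {g} OR {j} (family (9))")
            entries.sort(key=lambda e: e.position)
            seq = []
            cursor = 1
            for e in entries:
                ti = int(t[instance.patient_index(e.patient), g - 1, j - 1])
                if e.start_slot is not None and e.start_slot != cursor:
                    raise ScheduleStructureError(
                        f"start slot of {e.patient} on day {g} OR {j} is "
                        f"{e.start_slot}, ordering implies {cursor} (family (11))")
                seq.append((e.patient, cursor, ti))
                cursor += ti
            out[(g, j)] = DecodedDay(day=g, orid=j,
                                     sequence=seq,
                                     completion=cursor if seq else 0)
    return out


@dataclass
class Violation:
    block: str
    equation: str
    index: tuple
    lhs: float
    rhs: float

    @property
    def slack(self) -> float:
        return self.rhs - self.lhs

    def __str__(self):
        return (f"[Block {self.block}] eq ({self.equation}) at {self.index}: "
                f"lhs={self.lhs:g} rhs={self.rhs:g} slack={self.slack:g}")


@dataclass
class ViolationReport:
    violations: list[Violation] = field(default_factory=list)

    def add(self, block, equation, index, lhs, rhs):
        self.violations.append(Violation(block, equation, tuple(index), float(lhs), float(rhs)))

    @property
    def ok(self) -> bool:
        return not self.violations

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.violations:
            out[v.block] = out.get(v.block, 0) + 1
        return out

    def to_json(self) -> str:
        return json.dumps(
            {"ok": self.ok, "counts": self.counts(),
             "violations": [asdict(v) for v in self.violations]},
            indent=2)

    def table(self) -> str:
        if self.ok:
            return "no violations"
        return "\n".join(str(v) for v in self.violations)


def _nominal_days(bundle: SolutionBundle, instance: Instance) -> dict[str, tuple[int, int]]:
    return {e.patient: (e.day, e.orid) for e in bundle.nominal}


def validate_bundle(bundle: SolutionBundle, instance: Instance,
                    penalties: PenaltyTable | None = None) -> ViolationReport:
    """Re-evaluate every constraint family on the bundle by arithmetic."""
    rep = ViolationReport()
    inst = instance
    n, D, J = inst.n_patients, inst.horizon_days, inst.num_ors
    a = inst.compat_array()
    t = inst.duration_array()
    T = inst.capacity
    Om = inst.overtime_slots
    Dlt = inst.delta_max
    gam = inst.emergency_classes
    x = bundle.x_array(inst)
    where = _nominal_days(bundle, inst)

    # ---- Block A ------------------------------------------------------
    for i in range(n):
        tot = int(x[i].sum())
        if tot > 1:
            rep.add("A", "4", (i,), tot, 1)
        for d0 in range(D):
            for j0 in range(J):
                if x[i, d0, j0] > a[i, d0, j0]:
                    rep.add("A", "5", (i, d0 + 1, j0 + 1), x[i, d0, j0], a[i, d0, j0])
    for d0 in range(D):
        for j0 in range(J):
            load = int((t[:, d0, j0] * x[:, d0, j0]).sum())
            if load > T[d0, j0]:
                rep.add("A", "6", (d0 + 1, j0 + 1), load, T[d0, j0])

    # ---- Block B: decode (raises on structural breakage) --------------
    try:
        decoded = decode_schedule(bundle, inst)
    except ScheduleStructureError as exc:
        rep.add("B", "9/10/11", ("structure",), 1, 0)
        return rep
    starts: dict[str, int] = {}
    for (g, j), day in decoded.items():
        for pid, s, ti in day.sequence:
            starts[pid] = s
            if s > T[g - 1, j - 1] + 1 - ti:
                rep.add("B", "15", (pid, g, j), s, T[g - 1, j - 1] + 1 - ti)

    # ---- Blocks C-F per emergency scenario ----------------------------
    for (h, g, l), plan in bundle.emergency_plans.items():
        g0 = g - 1
        avail = {j: decoded[(g, j)].availability(h) for j in inst.ors}
        jstar = plan.or_assigned
        if avail[jstar] > min(avail.values()) + TOL:
            rep.add("D", "25", (h, g, l), avail[jstar], min(avail.values()))
        rsx = bundle.plan_x_array(inst, plan.assignments)
        impacted = set(plan.impacted)
        dropped = set(plan.dropped)
        # (27): impacted only if nominal start strictly after h
        for pid in impacted:
            if where.get(pid, (None, None))[0] != g or starts.get(pid, 0) <= h:
                rep.add("E", "27", (h, g, l, pid), 1, 0)
        for i, pat in enumerate(inst.patients):
            pid = pat.id
            tot = int(rsx[i].sum())
            if tot > 1:
                rep.add("F", "33", (h, g, l, pid), tot, 1)
            bad = rsx[i] > a[i]
            if bad.any():
                rep.add("F", "34", (h, g, l, pid), int(bad.sum()), 0)
            sched = pid in where
            if not sched and tot > 0:
                rep.add("F", "31", (h, g, l, pid), tot, 0)
            if sched:
                dstar = where[pid][0]
                if rsx[i, : dstar - 1, :].sum() > 0:
                    rep.add("F", "30", (h, g, l, pid), 1, 0)
                # (28): impacted must be rescheduled before g + delta
                if pid in impacted and rsx[i, : min(D, g + Dlt - 1), :].sum() < 1:
                    rep.add("E", "28", (h, g, l, pid), 0, 1)
                # (29): reappear within the window unless flagged dropped
                lo, hi = dstar - 1, min(dstar - 1 + Dlt, D - 1)
                if rsx[i, lo:hi + 1, :].sum() < 1 and pid not in dropped:
                    rep.add("E", "29", (h, g, l, pid), 0, 1)
                # (32): non-impacted day-g patients keep their assignment
                if dstar == g and pid not in impacted:
                    j0 = where[pid][1] - 1
                    if rsx[i, g0, j0] < 1:
                        rep.add("F", "32", (h, g, l, pid), 0, 1)
        for j in inst.ors:
            j0 = j - 1
            for d0 in range(g, D):
                load = int((t[:, d0, j0] * rsx[:, d0, j0]).sum())
                if load > T[d0, j0]:
                    rep.add("F", "35", (h, g, l, d0 + 1, j), load, T[d0, j0])
            occ = min(gam[l], T[g0, j0] - h) if j == jstar else 0
            load = int((t[:, g0, j0] * rsx[:, g0, j0]).sum()) + occ
            if load > T[g0, j0] + Om:
                rep.add("F", "36", (h, g, l, j), load, T[g0, j0] + Om)

    # ---- Blocks G-H ----------------------------------------------------
    for g in inst.rs_days:
        g0 = g - 1
        seen: dict[str, int] = {}
        for j in inst.ors:
            pid = bundle.substitutes.get((g, j))
            if pid is None:
                # a missing substitute is only legal through the dummy option
                if not bundle.metrics.get("allow_dummy_substitute", False):
                    rep.add("G", "37", (g, j), 0, 1)
                continue
            seen[pid] = seen.get(pid, 0) + 1
            i = inst.patient_index(pid)
            if where.get(pid, (None, None))[0] != g + 1:
                rep.add("G", "38", (g, j, pid), 0, 1)
            if not a[i, g0, j - 1]:
                rep.add("G", "39", (g, j, pid), 1, 0)
        for pid, cnt in seen.items():
            if cnt > 1:
                rep.add("G", "38", (g, pid), cnt, 1)

    for (bpid, g), plan in bundle.noshow_plans.items():
        g0 = g - 1
        rsx = bundle.plan_x_array(inst, plan.assignments)
        bidx = inst.patient_index(bpid)
        b_on_g = where.get(bpid, (None, None))[0] == g
        subs = {j: bundle.substitutes.get((g, j)) for j in inst.ors}
        # only the substitute actually summoned by this scenario may anticipate
        summoned = subs.get(where[bpid][1]) if b_on_g else None
        if b_on_g:
            jb = where[bpid][1]
            spid = subs.get(jb)
            if spid is not None:
                si = inst.patient_index(spid)
                if rsx[si, g0, jb - 1] < 1:
                    rep.add("G", "40", (bpid, g, spid, jb), 0, 1)
            dr = g0 + inst.delta_noshow
            mode = bundle.metrics.get("noshow_mode", "fixed_delay")
            if mode == "fixed_delay":
                if rsx[bidx, dr, :].sum() < 1:
                    rep.add("G", "41", (bpid, g), 0, 1)
            else:
                if rsx[bidx, : min(D, g + Dlt - 1), :].sum() < 1:
                    rep.add("G", "42", (bpid, g), 0, 1)
        for i, pat in enumerate(inst.patients):
            pid = pat.id
            tot = int(rsx[i].sum())
            if tot > 1:
                rep.add("H", "43", (bpid, g, pid), tot, 1)
            if (rsx[i] > a[i]).any():
                rep.add("H", "44", (bpid, g, pid), 1, 0)
            sched = pid in where
            if not sched and tot > 0:
                rep.add("H", "48", (bpid, g, pid), tot, 0)
            if sched:
                dstar = where[pid][0]
                # (47) anticipation ban; the summoned substitute is exempt
                if pid != summoned and rsx[i, : dstar - 1, :].sum() > 0:
                    rep.add("H", "47", (bpid, g, pid), 1, 0)
                if dstar == g and pid != bpid:
                    j0 = where[pid][1] - 1
                    if rsx[i, g0, j0] < 1:
                        rep.add("H", "49", (bpid, g, pid), 0, 1)
        for j in inst.ors:
            j0 = j - 1
            for d0 in range(g, D):
                load = int((t[:, d0, j0] * rsx[:, d0, j0]).sum())
                if load > T[d0, j0]:
                    rep.add("H", "45", (bpid, g, d0 + 1, j), load, T[d0, j0])
            load = int((t[:, g0, j0] * rsx[:, g0, j0]).sum())
            if load > T[g0, j0] + Om:
                rep.add("H", "46", (bpid, g, j), load, T[g0, j0] + Om)

    # ---- auxiliary blocks ii / iii ------------------------------------
    for g, ids in bundle.pinned_day_admissions.items():
        for pid in ids:
            if where.get(pid, (None, None))[0] != g:
                rep.add("ii", "50", (g, pid), 0, 1)
    ref_pos = {(e.patient, e.day, e.orid): e.position for e in bundle.ordering_reference}
    cur_pos = {(e.patient, e.day, e.orid): e.position for e in bundle.nominal}
    for key, pos in ref_pos.items():
        if pos is not None and cur_pos.get(key) != pos:
            rep.add("iii", "55", key, 0, 1)
    return rep


def evaluate_objective(bundle: SolutionBundle, instance: Instance, kind: str,
                       penalties: PenaltyTable | None = None,
                       weighting: str = "full") -> float:
    """Recompute an objective value from the bundle by direct arithmetic."""
    pen = penalties or PenaltyTable.from_instance(instance, weighting)

    def penalty_of(assignments) -> float:
        assigned = {}
        for pid, d, j in assignments:
            assigned[pid] = d
        total = 0.0
        for i, pat in enumerate(instance.patients):
            if pat.id in assigned:
                total += pen.p[i, assigned[pat.id] - 1]
            else:
                total += pen.q[i]
        return total

    if kind in ("nominal", "3"):
        return penalty_of([(e.patient, e.day, e.orid) for e in bundle.nominal])
    if kind in ("emergency", "54"):
        if not bundle.emergency_plans:
            raise RuntimeError("bundle has no emergency plans")
        vals = [penalty_of(p.assignments) for p in bundle.emergency_plans.values()]
        return float(np.sum(vals)) / len(vals)
    if kind in ("noshow", "56"):
        if not bundle.noshow_plans:
            raise RuntimeError("bundle has no no-show plans")
        norm = bundle.metrics.get("noshow_norm") or (
            instance.n_patients / instance.horizon_days)
        vals = [penalty_of(p.assignments) for p in bundle.noshow_plans.values()]
        return float(np.sum(vals)) / norm
    raise ValueError(f"unknown objective kind {kind!r}")


def apply_emergency(bundle: SolutionBundle, scenario: tuple[int, int, int],
                    instance: Instance) -> dict:
    """Deploy one emergency backup plan and report the applied outcome."""
    if scenario not in bundle.emergency_plans:
        raise KeyError(f"no emergency plan for scenario {scenario}")
    h, g, l = scenario
    plan = bundle.emergency_plans[scenario]
    decoded = decode_schedule(bundle, instance)
    t = instance.duration_array()
    where = _nominal_days(bundle, instance)
    gam = instance.emergency_classes[l]
    g0 = g - 1
    day_load = {}
    bound = {}
    for j in instance.ors:
        j0 = j - 1
        load = sum(
            t[instance.patient_index(pid), g0, jj - 1]
            for pid, d, jj in plan.assignments if d == g and jj == j
        )
        occ = min(gam, instance.capacity[g0, j0] - h) if j == plan.or_assigned else 0
        day_load[j] = int(load) + occ
        bound[j] = int(instance.capacity[g0, j0]) + instance.overtime_slots
    unchanged = []
    for (pid, (d, j)) in where.items():
        if d == g and pid not in plan.impacted:
            unchanged.append(pid)
    reassigned = {pid: (d, j) for pid, d, j in plan.assignments}
    reappearance = {}
    for pid in plan.impacted:
        if pid in reassigned:
            reappearance[pid] = reassigned[pid][0]
    return {
        "scenario": scenario,
        "chosen_or": plan.or_assigned,
        "availability": {j: decoded[(g, j)].availability(h) for j in instance.ors},
        "displaced": sorted(plan.impacted),
        "dropped": sorted(plan.dropped),
        "unchanged": sorted(unchanged),
        "day_g_load": day_load,
        "day_g_bound": bound,
        "reappearance": reappearance,
        "assignments": list(plan.assignments),
    }


def apply_noshow(bundle: SolutionBundle, scenario: tuple[str, int],
                 instance: Instance) -> dict:
    """Deploy one no-show backup plan and report the applied outcome."""
    bpid, g = scenario
    where = _nominal_days(bundle, instance)
    if where.get(bpid, (None, None))[0] != g:
        raise ValueError(f"patient {bpid} is not nominally scheduled on day {g}")
    if scenario not in bundle.noshow_plans:
        raise KeyError(f"no no-show plan for scenario {scenario}")
    plan = bundle.noshow_plans[scenario]
    t = instance.duration_array()
    g0 = g - 1
    jb = where[bpid][1]
    substitute = bundle.substitutes.get((g, jb))
    reassigned = {pid: (d, j) for pid, d, j in plan.assignments}
    day_load = {}
    for j in instance.ors:
        load = sum(
            t[instance.patient_index(pid), g0, jj - 1]
            for pid, d, jj in plan.assignments if d == g and jj == j
        )
        day_load[j] = int(load)
    return {
        "scenario": scenario,
        "substitute": substitute,
        "substitute_moved_to": reassigned.get(substitute) if substitute else None,
        "noshow_reassigned_to": reassigned.get(bpid),
        "day_g_load": day_load,
        "day_g_bound": {
            j: int(instance.capacity[g0, j - 1]) + instance.overtime_slots
            for j in instance.ors
        },
        "assignments": list(plan.assignments),
    }
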