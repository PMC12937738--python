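"""Sequential solution procedure: nominal solve, warm-start or heuristic
completion, then emergency- and no-show-plan optimization.

The solver backend cannot accept incumbent hints, so the warm start is
realized as a fixing ladder (documented deviation):

1. check whether the nominal schedule is *recoverable*: with the
   assignment and a canonical shortest-first ordering held fixed, every
   scenario's backup plan is an independent small MILP, solved one by one;
2. if not, solve the monolithic complete model with the assignment fixed
   (ordering free), then with only backup-day admissions pinned (the
   hint-free fallback) — ``mode="auto"`` only;
3. if everything fails, descend a repair ladder that evicts ever-longer
   surgeries from the backup day until the re-solved nominal schedule
   becomes recoverable (the empty backup day always is).

``mode`` selects the route: ``"faithful"`` always solves the monolithic
model at every step (use at small scale), ``"fix"`` uses only the
decomposed route plus the repair ladder, ``"auto"`` (default) inserts the
monolithic attempts between the two.

In the decomposed route the backup-plan optimization of steps 7 and 9 is
exact *conditionally on the fixed nominal schedule*: each scenario copy is
solved to optimality, which is equivalent to the monolithic solve with the
assignment and ordering pinned.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np

from .backend import HighsBackend, SolveResult
from .instance import Instance, PenaltyTable
from .model import (
    ModelHandle,
    ScenarioSet,
    attach_auxiliary_block,
    build_complete_model,
    build_nominal_model,
    enumerate_scenarios,
    extract_solution,
    set_objective,
)
from .scenario_opt import (
    NominalView,
    ScenarioPlan,
    UnrecoverableError,
    best_emergency_plan,
    choose_substitutes,
)
from .semantics import EmergencyPlan, NominalEntry, NoShowPlan, SolutionBundle

__all__ = [
    "SolveConfig",
    "PipelineStepError",
    "solve_nominal",
    "run_warm_start",
    "run_heuristic",
    "optimize_backup_plans",
    "full_pipeline",
]


@dataclass(frozen=True)
class SolveConfig:
    strategy: str = "heuristic"  # "heuristic" | "warm_start"
    time_limit: float = 900.0  # per-step wall limit, seconds
    mip_gap: float | None = None
    seed: int = 0
    noshow_mode: str = "fixed_delay"  # "fixed_delay" | "window"
    resched_window: str = "assignment"  # "assignment" | "rs_day"
    penalty_weighting: str = "full"
    mode: str = "auto"  # "auto" | "fix" | "faithful"
    allow_dummy_substitute: bool = False

    def __post_init__(self):
        if self.time_limit <= 0:
            raise ValueError("time limit must be positive")
        if self.mip_gap is not None and self.mip_gap < 0:
            raise ValueError("gap must be nonnegative")
        if self.strategy not in ("heuristic", "warm_start"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.mode not in ("auto", "fix", "faithful"):
            raise ValueError(f"unknown mode {self.mode!r}")


class PipelineStepError(RuntimeError):
    def __init__(self, step: str, message: str):
        super().__init__(f"{step}: {message}")
        self.step = step


def _record(step: str, res: SolveResult, note: str = "") -> dict:
    return {
        "step": step,
        "status": res.status,
        "objective": res.objective,
        "bound": res.bound,
        "gap": res.gap,
        "runtime": round(res.runtime, 3),
        "note": note,
    }


def _plain_record(step: str, status: str, objective=None, bound=None,
                  gap=None, runtime=0.0, note="") -> dict:
    return {"step": step, "status": status, "objective": objective,
            "bound": bound, "gap": gap, "runtime": runtime, "note": note}


def _solve(handle: ModelHandle, cfg: SolveConfig, time_limit=None) -> SolveResult:
    backend = HighsBackend(seed=cfg.seed)
    return backend.solve(handle.model, time_limit=time_limit or cfg.time_limit,
                         mip_gap=cfg.mip_gap)


@contextmanager
def _fixed(handle: ModelHandle, **blocks: np.ndarray):
    """Temporarily clamp whole variable blocks to reference values."""
    m = handle.model
    names = list(m.blocks)
    saved = {}
    for name, vals in blocks.items():
        if vals is None:
            continue
        k = names.index(name)
        saved[k] = (m._lb[k].copy(), m._ub[k].copy())
        flat = np.asarray(vals, dtype=float).ravel()
        m._lb[k][:] = flat
        m._ub[k][:] = flat
    try:
        yield
    finally:
        for k, (lb0, ub0) in saved.items():
            m._lb[k][:] = lb0
            m._ub[k][:] = ub0


def canonical_ordering(instance: Instance, xs: np.ndarray, n_positions: int) -> np.ndarray:
    """Shortest-first within-day ordering as a full y-block assignment.

    Short surgeries first keep the OR's availability breakpoints early,
    which empirically makes emergency recovery easiest.
    """
    t = instance.duration_array()
    W = list(instance.rs_days)
    y = np.zeros((instance.n_patients, len(W), instance.num_ors, n_positions), dtype=int)
    for w, g in enumerate(W):
        for j0 in range(instance.num_ors):
            here = [(int(t[i, g - 1, j0]), i) for i in range(instance.n_patients)
                    if xs[i, g - 1, j0]]
            here.sort()
            for pos, (_, i) in enumerate(here):
                y[i, w, j0, pos] = 1
    return y


def _penalty_of_x(pen: PenaltyTable, xs: np.ndarray) -> float:
    sched = xs.sum(axis=2)  # (n, D)
    return float((pen.p * sched).sum() + (pen.q * (1 - sched.sum(axis=1))).sum())


def solve_nominal(instance: Instance, config: SolveConfig,
                  penalties: PenaltyTable | None = None,
                  forbid_day_g: list[int] | None = None):
    """Step 1: nominal assignment problem; returns (x*, record)."""
    pen = penalties or PenaltyTable.from_instance(instance, config.penalty_weighting)
    handle = build_nominal_model(instance, pen)
    if forbid_day_g:
        m = handle.model
        k = list(m.blocks).index("x")
        ub = m._ub[k].reshape(instance.n_patients, instance.horizon_days, instance.num_ors)
        for i in forbid_day_g:
            for g in instance.rs_days:
                ub[i, g - 1, :] = 0.0
    res = _solve(handle, config)
    if not res.has_solution:
        raise PipelineStepError("step1", f"nominal solve failed: {res.status}")
    xs = np.rint(handle.model.block_values("x", res.x)).astype(int)
    return xs, _record("step1_nominal", res)


# ---------------------------------------------------------------------------
# monolithic route (faithful mode; also reachable as an auto-mode rung)
# ---------------------------------------------------------------------------

def run_warm_start(handle: ModelHandle, x_star: np.ndarray, cfg: SolveConfig):
    """Steps 3-4 on the monolithic model: complete solve with backup-day
    admissions pinned to the nominal solution (the hint-free fallback),
    then re-pinning on the solution found."""
    records = []
    attach_auxiliary_block(handle, "ii", x_star)
    set_objective(handle, "nominal")
    res = _solve(handle, cfg)
    if not res.has_solution:
        records.append(_record("step3_warm_start", res, "block-ii monolith"))
        raise PipelineStepError("step3", f"no incumbent within limit ({res.status})")
    x6 = np.rint(handle.model.block_values("x", res.x)).astype(int)
    records.append(_record("step3_warm_start", res, "block-ii monolith"))
    attach_auxiliary_block(handle, "ii", x6)  # step 4
    return x6, res, records


def run_heuristic(handle: ModelHandle, x_star: np.ndarray, cfg: SolveConfig):
    """Steps 5-6 on the monolithic model: minimize the day-wise difference
    from the nominal solution, then re-optimize penalties with backup-day
    admissions pinned."""
    records = []
    attach_auxiliary_block(handle, "i", x_star)
    set_objective(handle, "difference")
    res5 = _solve(handle, cfg)
    if not res5.has_solution:
        raise PipelineStepError("step5", f"no incumbent within limit ({res5.status})")
    x5 = np.rint(handle.model.block_values("x", res5.x)).astype(int)
    records.append(_record("step5_difference", res5, "monolith"))
    attach_auxiliary_block(handle, "ii", x5)
    set_objective(handle, "nominal")
    res6 = _solve(handle, cfg)
    if not res6.has_solution:
        raise PipelineStepError("step6", f"no incumbent within limit ({res6.status})")
    x6 = np.rint(handle.model.block_values("x", res6.x)).astype(int)
    records.append(_record("step6_penalties", res6, "monolith with block ii"))
    attach_auxiliary_block(handle, "ii", x6)
    return x6, res6, records


def optimize_backup_plans(handle: ModelHandle, x6: np.ndarray, cfg: SolveConfig):
    """Steps 7-9 on the monolithic model: optimize emergency plans, pin the
    ordering (block iii), optimize no-show plans with the assignment held
    at the step-7 solution so the plan families stay consistent."""
    records = []
    set_objective(handle, "emergency")
    res7 = _solve(handle, cfg)
    if not res7.has_solution:
        raise PipelineStepError("step7", f"emergency optimization failed ({res7.status})")
    records.append(_record("step7_emergency", res7))
    sol7 = extract_solution(handle, res7.x)
    attach_auxiliary_block(handle, "iii", sol7["y"])  # step 8
    set_objective(handle, "noshow")
    with _fixed(handle, x=sol7["x"]):
        res9 = _solve(handle, cfg)
    if not res9.has_solution:
        raise PipelineStepError("step9", f"no-show optimization failed ({res9.status})")
    records.append(_record("step9_noshow", res9, "assignment fixed to step-7 solution"))
    sol9 = extract_solution(handle, res9.x)
    return sol7, sol9, records


# ---------------------------------------------------------------------------
# decomposed route (fix / auto modes)
# ---------------------------------------------------------------------------

def _try_decompose(instance: Instance, pen: PenaltyTable, scen: ScenarioSet,
                   cfg: SolveConfig, x: np.ndarray, y: np.ndarray):
    """All per-scenario backup plans for a fixed nominal schedule, or raise
    :class:`UnrecoverableError`."""
    view = NominalView.build(instance, x, y)
    eplans: dict[tuple[int, int, int], ScenarioPlan] = {}
    # longest emergency classes are the binding ones: check them first so
    # unrecoverable schedules are rejected quickly
    order = sorted(scen.emergencies,
                   key=lambda s: -instance.emergency_classes[s[2]])
    cache: dict = {}
    for s in order:
        eplans[s] = best_emergency_plan(instance, pen, view, s, cache=cache)
    theta, nplans, truncated = choose_substitutes(
        instance, pen, view, cfg.noshow_mode, cfg.allow_dummy_substitute)
    return view, eplans, theta, nplans, truncated


def _repair_ladder(instance: Instance, pen: PenaltyTable, scen: ScenarioSet,
                   cfg: SolveConfig, records: list):
    """Forbid ever-shorter surgeries from the backup day(s) and re-solve
    the nominal problem until a recoverable schedule appears; the empty
    backup day always is recoverable, so the ladder terminates."""
    from dataclasses import replace
    t = instance.duration_array()
    n = instance.n_patients
    durations = sorted({int(t[i, g - 1, :].max())
                        for g in instance.rs_days for i in range(n)}, reverse=True)
    thresholds = durations[1:] + [0]
    npos = _n_positions(instance)
    # rung candidates only need to be near-optimal: relax the gap
    rung_cfg = replace(cfg, mip_gap=max(cfg.mip_gap or 0.0, 0.01),
                       time_limit=min(cfg.time_limit, 30.0))
    for thr in thresholds:
        if thr == 0:
            banned = list(range(n))
        else:
            banned = [i for i in range(n)
                      if any(t[i, g - 1, :].max() >= thr for g in instance.rs_days)]
        xk, _ = solve_nominal(instance, rung_cfg, pen, forbid_day_g=banned)
        yk = canonical_ordering(instance, xk, npos)
        try:
            dec = _try_decompose(instance, pen, scen, cfg, xk, yk)
        except UnrecoverableError:
            continue
        records.append(_plain_record(
            "step5_repair", "optimal", objective=None,
            note=f"backup-day surgeries of >= {thr} slots evicted"))
        return xk, yk, dec
    raise PipelineStepError("step5", "repair ladder exhausted")


def _n_positions(instance: Instance) -> int:
    from .instance import max_positions
    return max_positions(instance)


def _fast_complete(instance: Instance, pen: PenaltyTable, scen: ScenarioSet,
                   cfg: SolveConfig, x_star: np.ndarray, records: list):
    """Warm-start / heuristic ladder of the decomposed route.  Returns
    (x6, y6, decomposition)."""
    npos = _n_positions(instance)
    ycan = canonical_ordering(instance, x_star, npos)
    try:
        dec = _try_decompose(instance, pen, scen, cfg, x_star, ycan)
        note = "nominal schedule recoverable under canonical ordering; no monolithic solve needed"
        if cfg.strategy == "warm_start":
            records.append(_plain_record("step3_warm_start", "optimal",
                                         objective=_penalty_of_x(pen, x_star), note=note))
        else:
            records.append(_plain_record("step5_difference", "optimal",
                                         objective=0.0, note=note))
            records.append(_plain_record("step6_penalties", "reused_step5",
                                         objective=_penalty_of_x(pen, x_star),
                                         note="restricted: assignment fixed"))
        return x_star, ycan, dec
    except UnrecoverableError as exc:
        records.append(_plain_record(
            "step3_warm_start" if cfg.strategy == "warm_start" else "step5_difference",
            "unrecoverable", note=f"nominal schedule not recoverable: {exc}"))

    if cfg.mode == "auto":
        handle = build_complete_model(
            instance, scen, pen, noshow_mode=cfg.noshow_mode,
            resched_window=cfg.resched_window,
            allow_dummy_substitute=cfg.allow_dummy_substitute,
            weighting=cfg.penalty_weighting)
        # rung 2: assignment fixed, ordering free
        set_objective(handle, "nominal")
        with _fixed(handle, x=x_star):
            res = _solve(handle, cfg)
        if res.has_solution:
            y6 = extract_solution(handle, res.x)["y"]
            records.append(_record("step3_warm_start" if cfg.strategy == "warm_start"
                                   else "step5_difference", res,
                                   "monolith, assignment fixed, ordering free"))
            dec = _try_decompose(instance, pen, scen, cfg, x_star, y6)
            return x_star, y6, dec
        # rung 3: free monolith under the strategy's objective
        if cfg.strategy == "warm_start":
            attach_auxiliary_block(handle, "ii", x_star)
            set_objective(handle, "nominal")
        else:
            attach_auxiliary_block(handle, "i", x_star)
            set_objective(handle, "difference")
        res = _solve(handle, cfg)
        if res.has_solution:
            sol = extract_solution(handle, res.x)
            records.append(_record("step3_warm_start" if cfg.strategy == "warm_start"
                                   else "step5_difference", res, "free monolith"))
            dec = _try_decompose(instance, pen, scen, cfg, sol["x"], sol["y"])
            return sol["x"], sol["y"], dec

    xk, yk, dec = _repair_ladder(instance, pen, scen, cfg, records)
    return xk, yk, dec


def _impacted_dropped(instance: Instance, view: NominalView, g: int,
                      plan: ScenarioPlan):
    rs_of = {i: (d, j) for i, d, j in plan.assignments}
    impacted, dropped = [], []
    for i, (dstar, jstar) in view.where.items():
        got = rs_of.get(i)
        if dstar == g and got != (g, jstar):
            impacted.append(i)
        if got is None or not (dstar <= got[0] <= dstar + instance.delta_max):
            dropped.append(i)
    return impacted, dropped


def _bundle_from_plans(instance: Instance, pen: PenaltyTable, scen: ScenarioSet,
                       cfg: SolveConfig, x6, y6, dec, records) -> SolutionBundle:
    view, eplans, theta, nplans, truncated = dec
    inst = instance
    pid = [p.id for p in inst.patients]
    W = list(inst.rs_days)
    nominal = []
    n, D, J = x6.shape
    for i in range(n):
        for d0 in range(D):
            for j0 in range(J):
                if x6[i, d0, j0]:
                    pos = start = None
                    if (d0 + 1) in W:
                        w = W.index(d0 + 1)
                        srow = np.nonzero(y6[i, w, j0, :])[0]
                        if srow.size:
                            pos = int(srow[0]) + 1
                        start = view.starts.get(i)
                    nominal.append(NominalEntry(pid[i], d0 + 1, j0 + 1, pos, start))
    subs = {(g, j): (pid[c] if c is not None else None) for (g, j), c in theta.items()}
    emergency_plans = {}
    e_pen = []
    e_opt = True
    for s, plan in eplans.items():
        h, g, l = s
        imp, drop = _impacted_dropped(inst, view, g, plan)
        emergency_plans[s] = EmergencyPlan(
            or_assigned=plan.eta,
            impacted=sorted(pid[i] for i in imp),
            dropped=sorted(pid[i] for i in drop),
            assignments=[(pid[i], d, j) for i, d, j in plan.assignments],
        )
        e_pen.append(plan.penalty)
        e_opt &= plan.status == "optimal"
    of54 = float(np.mean(e_pen)) if e_pen else None
    records.append(_plain_record(
        "step7_emergency", "optimal" if e_opt else "feasible", objective=of54,
        bound=of54 if e_opt else None, gap=0.0 if e_opt else None,
        note="decomposed per-scenario optimization, nominal schedule fixed"))
    noshow_plans = {}
    n_pen = []
    n_opt = not truncated
    for (b, g), plan in nplans.items():
        noshow_plans[(pid[b], g)] = NoShowPlan(
            assignments=[(pid[i], d, j) for i, d, j in plan.assignments])
        n_pen.append(plan.penalty)
        n_opt &= plan.status == "optimal"
    norm = inst.n_patients / inst.horizon_days
    of56 = float(np.sum(n_pen)) / norm if n_pen else None
    records.append(_plain_record(
        "step9_noshow", "optimal" if n_opt else "feasible", objective=of56,
        bound=of56 if n_opt else None, gap=0.0 if n_opt else None,
        note="decomposed per-scenario optimization, substitutes chosen by exact scoring"
             + (" (candidate pool truncated)" if truncated else "")))
    pinned = {g: [pid[i] for i in range(n) if x6[i, g - 1, :].sum() > 0] for g in W}
    ordering_reference = [e for e in nominal if e.position is not None]
    ordering_reference = [NominalEntry(e.patient, e.day, e.orid, e.position)
                          for e in ordering_reference]
    of_nominal = records[0]["objective"]
    metrics = _metrics(records, cfg, inst, of_nominal)
    # objective (3) of the complete solution, recomputed arithmetically
    metrics["of_complete"] = _penalty_of_x(pen, x6)
    return SolutionBundle(nominal=nominal, substitutes=subs,
                          emergency_plans=emergency_plans, noshow_plans=noshow_plans,
                          pinned_day_admissions=pinned,
                          ordering_reference=ordering_reference, metrics=metrics)


def _metrics(records, cfg, inst, of_nominal) -> dict:
    lb_nominal = records[0].get("bound")
    metrics = {
        "steps": records,
        "strategy": cfg.strategy,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "noshow_mode": cfg.noshow_mode,
        "resched_window": cfg.resched_window,
        "allow_dummy_substitute": cfg.allow_dummy_substitute,
        "noshow_norm": inst.n_patients / inst.horizon_days,
        "of_nominal": of_nominal,
        "lb_nominal": lb_nominal if lb_nominal is not None else of_nominal,
        # the nominal optimum is a valid lower bound of the complete problem
        # (complete-feasible assignments form a subset of the nominal ones)
        "lb_complete": of_nominal,
    }
    for r in records:
        if r["step"].startswith(("step3", "step6")):
            if (r["status"] in ("optimal", "feasible", "reused_step5")
                    and r["objective"] is not None):
                metrics["of_complete"] = r["objective"]
    return metrics


def _bundle_from_arrays(handle: ModelHandle, sol7: dict, sol9: dict,
                        records: list, cfg: SolveConfig, of_nominal: float) -> SolutionBundle:
    """Assemble a bundle from raw monolithic-solution arrays (faithful mode)."""
    inst = handle.instance
    scen = handle.scenarios
    n, D, J = inst.n_patients, inst.horizon_days, inst.num_ors
    W = list(inst.rs_days)
    pid = [p.id for p in inst.patients]
    x = sol9["x"]
    y = sol9["y"]
    xi = sol9["xi"]
    nominal = []
    for i in range(n):
        for d0 in range(D):
            for j0 in range(J):
                if x[i, d0, j0]:
                    pos = start = None
                    if (d0 + 1) in W:
                        w = W.index(d0 + 1)
                        srow = np.nonzero(y[i, w, j0, :])[0]
                        if srow.size:
                            pos = int(srow[0]) + 1
                        start = int(round(xi[i, w, j0]))
                    nominal.append(NominalEntry(pid[i], d0 + 1, j0 + 1, pos, start))
    theta = sol9["theta"]
    subs: dict[tuple[int, int], str | None] = {}
    for w, g in enumerate(W):
        for j0 in range(J):
            who = np.nonzero(theta[:, w, j0])[0]
            subs[(g, j0 + 1)] = pid[int(who[0])] if who.size else None
    where = {i: (d0 + 1, j0 + 1) for i in range(n)
             for d0 in range(D) for j0 in range(J) if x[i, d0, j0]}
    eplans = {}
    xbar = sol7.get("xbar")
    eta = sol7["eta"]
    for e, (h, g, l) in enumerate(scen.emergencies):
        w = W.index(g)
        assignments = []
        rs_of = {}
        for i in range(n):
            pos = np.argwhere(xbar[e, i] > 0)
            if pos.size:
                d0, j0 = int(pos[0][0]), int(pos[0][1])
                assignments.append((pid[i], d0 + 1, j0 + 1))
                rs_of[i] = (d0 + 1, j0 + 1)
        impacted, dropped = [], []
        for i, (dstar, jstar) in where.items():
            got = rs_of.get(i)
            if dstar == g and got != (g, jstar):
                impacted.append(pid[i])
            if got is None or not (dstar <= got[0] <= dstar + inst.delta_max):
                dropped.append(pid[i])
        eplans[(h, g, l)] = EmergencyPlan(
            or_assigned=int(np.argmax(eta[h, w, :])) + 1,
            impacted=sorted(impacted), dropped=sorted(dropped),
            assignments=assignments)
    nplans = {}
    xhat = sol9.get("xhat")
    for sb, (b, g) in enumerate(scen.noshows):
        assignments = []
        for i in range(n):
            pos = np.argwhere(xhat[sb, i] > 0)
            if pos.size:
                assignments.append((pid[i], int(pos[0][0]) + 1, int(pos[0][1]) + 1))
        nplans[(pid[b], g)] = NoShowPlan(assignments=assignments)
    pinned = {}
    if handle.x_star is not None:
        for g in W:
            pinned[g] = [pid[i] for i in range(n) if handle.x_star[i, g - 1, :].sum() > 0]
    ordering_reference = []
    if handle.y_star is not None:
        ys = handle.y_star
        for i in range(n):
            for w, g in enumerate(W):
                for j0 in range(J):
                    srow = np.nonzero(ys[i, w, j0, :])[0]
                    if srow.size:
                        ordering_reference.append(
                            NominalEntry(pid[i], g, j0 + 1, int(srow[0]) + 1))
    metrics = _metrics(records, cfg, inst, of_nominal)
    return SolutionBundle(nominal=nominal, substitutes=subs, emergency_plans=eplans,
                          noshow_plans=nplans, pinned_day_admissions=pinned,
                          ordering_reference=ordering_reference, metrics=metrics)


def full_pipeline(instance: Instance, config: SolveConfig | None = None,
                  scenarios: ScenarioSet | None = None) -> SolutionBundle:
    """Run the whole procedure and return a bundle ready for validation."""
    cfg = config or SolveConfig()
    pen = PenaltyTable.from_instance(instance, cfg.penalty_weighting)
    x_star, rec1 = solve_nominal(instance, cfg, pen)
    records = [rec1]
    of_nominal = rec1["objective"]
    scen = scenarios or enumerate_scenarios(instance)

    if cfg.mode != "faithful":
        try:
            x6, y6, dec = _fast_complete(instance, pen, scen, cfg, x_star, records)
        except PipelineStepError:
            raise
        bundle = _bundle_from_plans(instance, pen, scen, cfg, x6, y6, dec, records)
        bundle.metrics["strategy_used"] = cfg.strategy
        return bundle

    # ---- faithful (monolithic) route ----------------------------------
    def fresh_handle():
        return build_complete_model(
            instance, scen, pen,
            noshow_mode=cfg.noshow_mode, resched_window=cfg.resched_window,
            allow_dummy_substitute=cfg.allow_dummy_substitute,
            weighting=cfg.penalty_weighting)

    handle = fresh_handle()
    strategy_used = cfg.strategy
    if cfg.strategy == "warm_start":
        try:
            x6, res_c, recs = run_warm_start(handle, x_star, cfg)
            records += recs
        except PipelineStepError as exc:
            records.append(_plain_record("step3_warm_start", "failed",
                                         note=f"fell back to heuristic: {exc}"))
            handle = fresh_handle()  # the failed warm start pinned admissions
            x6, res_c, recs = run_heuristic(handle, x_star, cfg)
            records += recs
            strategy_used = "heuristic (warm-start fallback)"
    else:
        x6, res_c, recs = run_heuristic(handle, x_star, cfg)
        records += recs
    sol7, sol9, recs = optimize_backup_plans(handle, x6, cfg)
    records += recs
    bundle = _bundle_from_arrays(handle, sol7, sol9, records, cfg, of_nominal)
    bundle.metrics["strategy_used"] = strategy_used
    return bundle
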