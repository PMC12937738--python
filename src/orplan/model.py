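"""Integer-programming formulation of the nominal + backup scheduling problem.

The complete model couples the nominal assignment (x), within-day ordering
(y, nu, xi) and OR-state bookkeeping (C, rho, lam, Xi) with one reschedule
copy per enumerated disruption scenario: ``xbar`` per emergency triple
(h, g, l) and ``xhat`` per no-show pair (b, g), plus the emergency
assignment (eta), impact flags (chi), drop flags (mu) and the substitute
designation (theta).

Constraint families are registered under string ids "4" .. "49" (plus the
auxiliary ids "50", "51", "52", "55") so that the registry can be audited;
families that reduce to variable bounds (compatibility masks) are recorded
with kind ``"bounds"``.

Two printed ambiguities are resolved here and documented:

* the anticipation ban on no-show reschedules exempts the designated
  substitute (who moves one day *earlier* by design) — without the
  exemption the substitute constraints would be mutually contradictory;
* OR-state variables at moment 0 and on empty ORs are pinned to their
  canonical values (first patient operating at h=0; availability equal to
  h when the OR is idle) so that "first available OR" has a well-defined
  arithmetic meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backend import INF, MilpModel
from .instance import Instance, PenaltyTable, max_positions

__all__ = [
    "ScenarioSet",
    "ModelHandle",
    "enumerate_scenarios",
    "build_nominal_model",
    "build_complete_model",
    "attach_auxiliary_block",
    "set_objective",
    "extract_solution",
]

OBJECTIVE_IDS = {"nominal": "3", "difference": "53", "emergency": "54", "noshow": "56"}


@dataclass(frozen=True)
class ScenarioSet:
    """Enumerated disruption scenarios.

    ``emergencies`` holds triples ``(h, g, l)`` — moment (0-based), day
    (1-based, in the backup-plan prefix) and emergency length-class index
    (0-based into ``instance.emergency_classes``).  ``noshows`` holds pairs
    ``(b, g)`` with ``b`` a 0-based patient index.
    """

    emergencies: tuple[tuple[int, int, int], ...]
    noshows: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(set(self.emergencies)) != len(self.emergencies):
            raise ValueError("duplicate emergency scenarios")
        if len(set(self.noshows)) != len(self.noshows):
            raise ValueError("duplicate no-show scenarios")


def enumerate_scenarios(instance: Instance, nominal_x: np.ndarray | None = None) -> ScenarioSet:
    """All emergency triples (h, g, l) and no-show pairs (b, g).

    No-show pairs are kept for every patient with some compatibility on a
    backup day g; the restriction to *nominally scheduled* patients is
    enforced inside the model (through x factors), not by pruning here.
    """
    a = instance.compat_array()
    em = tuple(
        (h, g, l)
        for g in instance.rs_days
        for h in range(instance.n_slots)
        for l in range(len(instance.emergency_classes))
    )
    ns = tuple(
        (b, g)
        for g in instance.rs_days
        for b in range(instance.n_patients)
        if a[b, g - 1, :].any()
    )
    return ScenarioSet(emergencies=em, noshows=ns)


@dataclass
class ModelHandle:
    """A built model plus the index bookkeeping needed to read it back."""

    model: MilpModel
    instance: Instance
    penalties: PenaltyTable
    scenarios: ScenarioSet | None = None
    n_positions: int = 1
    noshow_mode: str = "fixed_delay"
    resched_window: str = "assignment"
    noshow_norm: float | None = None
    attached_blocks: set = field(default_factory=set)
    x_star: np.ndarray | None = None
    y_star: np.ndarray | None = None
    kind: str = "complete"

    @property
    def objective_id(self):
        return self.model.objective_id


def _obj_nominal(model: MilpModel, inst: Instance, pen: PenaltyTable) -> tuple[np.ndarray, float]:
    c = model.objective_template()
    n, D, J = inst.n_patients, inst.horizon_days, inst.num_ors
    blk = model.blocks["x"]
    coeff = (pen.p[:, :, None] - pen.q[:, None, None]) * np.ones((n, D, J))
    c[blk.offset:blk.offset + blk.size] = coeff.ravel()
    return c, float(pen.q.sum())


def build_nominal_model(
    instance: Instance,
    penalties: PenaltyTable | None = None,
    weighting: str = "full",
) -> ModelHandle:
    """Assignment-only model: x variables, families (4)-(6), objective (3)."""
    if instance.n_patients == 0:
        raise ValueError("empty waiting list")
    pen = penalties or PenaltyTable.from_instance(instance, weighting)
    n, D, J = instance.n_patients, instance.horizon_days, instance.num_ors
    a = instance.compat_array()
    t = instance.duration_array()
    T = instance.capacity
    m = MilpModel("nominal")
    xb = m.add_block("x", (n, D, J), "binary")
    for i in range(n):
        cols = [xb.offset + (i * D + d0) * J + j0
                for d0 in range(D) for j0 in range(J) if a[i, d0, j0]]
        if cols:
            m.add_row(cols, [1.0] * len(cols), -INF, 1.0, "4")
        else:
            m.add_row([xb.offset + i * D * J], [1.0], -INF, 1.0, "4")
    for i in range(n):
        for d0 in range(D):
            for j0 in range(J):
                m.add_row([xb.offset + (i * D + d0) * J + j0], [1.0],
                          -INF, float(a[i, d0, j0]), "5")
    for d0 in range(D):
        for j0 in range(J):
            cols = [xb.offset + (i * D + d0) * J + j0 for i in range(n) if a[i, d0, j0]]
            vals = [float(t[i, d0, j0]) for i in range(n) if a[i, d0, j0]]
            if cols:
                m.add_row(cols, vals, -INF, float(T[d0, j0]), "6")
    c, const = _obj_nominal(m, instance, pen)
    m.set_objective(c, const, "3")
    return ModelHandle(model=m, instance=instance, penalties=pen, kind="nominal")


def build_complete_model(
    instance: Instance,
    scenarios: ScenarioSet | None = None,
    penalties: PenaltyTable | None = None,
    *,
    noshow_mode: str = "fixed_delay",
    resched_window: str = "assignment",
    allow_dummy_substitute: bool = False,
    weighting: str = "full",
) -> ModelHandle:
    """Full model with all variable families and constraint blocks A-H."""
    if instance.n_patients == 0:
        raise ValueError("empty waiting list")
    if noshow_mode not in ("fixed_delay", "window"):
        raise ValueError(f"unknown noshow_mode {noshow_mode!r}")
    if resched_window not in ("assignment", "rs_day"):
        raise ValueError(f"unknown resched_window {resched_window!r}")
    scen = scenarios or enumerate_scenarios(instance)
    pen = penalties or PenaltyTable.from_instance(instance, weighting)
    inst = instance
    n, D, J = inst.n_patients, inst.horizon_days, inst.num_ors
    W = list(inst.rs_days)
    Wn = len(W)
    Hn = inst.n_slots
    gamma = inst.emergency_classes
    if noshow_mode == "fixed_delay":
        for g in W:
            if g + inst.delta_noshow > D:
                raise ValueError("fixed-delay no-show day beyond horizon")
    a = inst.compat_array()
    t = inst.duration_array()
    T = inst.capacity
    M = float(inst.big_m)
    Om = inst.overtime_slots
    Dlt = inst.delta_max
    S = max_positions(inst)
    E = len(scen.emergencies)
    B = len(scen.noshows)

    m = MilpModel("complete")
    # (7): the position-count formula, realized by max_positions
    m.families["7"] = {"kind": "definition", "count": S}
    # pre-register every row family so that index sets that happen to be
    # empty (single OR, single position, ...) still show up in audits
    row_families = ["4", "6", "8", "9", "10", "11", "12", "13", "14", "15",
                    "16", "17", "18", "19", "20", "21", "22", "23", "24", "25",
                    "27", "28", "29", "30", "31", "32", "33", "35", "36",
                    "37", "38", "40", "43", "45", "46", "47", "48", "49",
                    "41" if noshow_mode == "fixed_delay" else "42"]
    for fam in row_families:
        m.families.setdefault(fam, {"kind": "rows", "count": 0})
    xb = m.add_block("x", (n, D, J), "binary")
    yb = m.add_block("y", (n, Wn, J, S), "binary")
    nub = m.add_block("nu", (n, n, Wn, J), "binary")
    xib = m.add_block("xi", (n, Wn, J), "continuous")
    Cb = m.add_block("C", (Wn, J), "continuous")
    rob = m.add_block("rho", (Hn, Wn, J), "binary")
    lab = m.add_block("lam", (n, Wn, J, Hn), "binary")
    Xib = m.add_block("Xi", (Hn, Wn, J), "continuous")
    etb = m.add_block("eta", (Hn, Wn, J), "binary")
    chb = m.add_block("chi", (Hn, Wn, n), "binary")
    xbb = m.add_block("xbar", (E, n, D, J), "binary") if E else None
    mub = m.add_block("mu", (E, n), "binary") if E else None
    thb = m.add_block("theta", (n, Wn, J), "binary")
    dmb = m.add_block("theta_dummy", (Wn, J), "binary") if allow_dummy_substitute else None
    xhb = m.add_block("xhat", (B, n, D, J), "binary") if B else None
    # sub_w[sb, i, j] = theta[i, g, j] * x[b, g, j]: "patient i is summoned as
    # the substitute in scenario (b, g)"; linearized product, used to exempt
    # the summoned substitute from the anticipation ban (47)
    swb = m.add_block("sub_w", (B, n, J), "continuous", lb=0.0, ub=1.0) if B else None

    flat_a = a.ravel()
    # (5)/(34)/(44) as upper bounds; (39) restricts theta to compatible (g, j)
    m.set_bounds("x", ub=flat_a.astype(float))
    m.register_bounds_family("5", n * D * J)
    if xbb is not None:
        m.set_bounds("xbar", ub=np.tile(flat_a.astype(float), E))
        m.register_bounds_family("34", E * n * D * J)
    if xhb is not None:
        m.set_bounds("xhat", ub=np.tile(flat_a.astype(float), B))
        m.register_bounds_family("44", B * n * D * J)
    th_ub = np.ones((n, Wn, J))
    for w, g in enumerate(W):
        th_ub[:, w, :] = a[:, g - 1, :]
    m.set_bounds("theta", ub=th_ub.ravel())
    m.register_bounds_family("39", n * Wn * J)

    def cx(i, d0, j0):
        return xb.offset + (i * D + d0) * J + j0

    # ---- Block A -----------------------------------------------------
    for i in range(n):
        cols = [cx(i, d0, j0) for d0 in range(D) for j0 in range(J) if a[i, d0, j0]]
        m.add_row(cols or [cx(i, 0, 0)], [1.0] * max(len(cols), 1), -INF, 1.0, "4")
    for d0 in range(D):
        for j0 in range(J):
            cols = [cx(i, d0, j0) for i in range(n) if a[i, d0, j0]]
            if cols:
                vals = [float(t[i, d0, j0]) for i in range(n) if a[i, d0, j0]]
                m.add_row(cols, vals, -INF, float(T[d0, j0]), "6")

    # ---- Block B: ordering on backup days ----------------------------
    for w, g in enumerate(W):
        g0 = g - 1
        for j0 in range(J):
            for i in range(n):
                ycols = [yb.offset + ((i * Wn + w) * J + j0) * S + s for s in range(S)]
                m.add_row(ycols + [cx(i, g0, j0)], [1.0] * S + [-1.0], 0.0, 0.0, "8")
            for s in range(S - 1):
                cols = [yb.offset + ((i * Wn + w) * J + j0) * S + s + 1 for i in range(n)]
                cols += [yb.offset + ((i * Wn + w) * J + j0) * S + s for i in range(n)]
                m.add_row(cols, [1.0] * n + [-1.0] * n, -INF, 0.0, "9")
            for s in range(S):
                cols = [yb.offset + ((i * Wn + w) * J + j0) * S + s for i in range(n)]
                m.add_row(cols, [1.0] * n, -INF, 1.0, "10")
            for i in range(n):
                cols = [xib.offset + (i * Wn + w) * J + j0]
                vals = [1.0]
                for r in range(n):
                    if r != i:
                        cols.append(nub.offset + ((i * n + r) * Wn + w) * J + j0)
                        vals.append(-float(t[r, g0, j0]))
                cols.append(cx(i, g0, j0))
                vals.append(-1.0)
                m.add_row(cols, vals, 0.0, 0.0, "11")
            for i in range(n):
                for r in range(n):
                    if r == i:
                        continue
                    nu_ir = nub.offset + ((i * n + r) * Wn + w) * J + j0
                    for s in range(1, S):
                        cols = [yb.offset + ((i * Wn + w) * J + j0) * S + s]
                        vals = [1.0]
                        for s2 in range(s):
                            cols.append(yb.offset + ((r * Wn + w) * J + j0) * S + s2)
                            vals.append(1.0)
                        cols.append(nu_ir)
                        vals.append(-1.0)
                        m.add_row(cols, vals, -INF, 1.0, "12")
                    m.add_row([nu_ir, cx(r, g0, j0)], [1.0, -1.0], -INF, 0.0, "13")
                    if r > i:
                        nu_ri = nub.offset + ((r * n + i) * Wn + w) * J + j0
                        m.add_row([nu_ir, nu_ri], [1.0, 1.0], -INF, 1.0, "14")
            for i in range(n):
                cap = float(T[g0, j0] + 1 - t[i, g0, j0])
                m.add_row([xib.offset + (i * Wn + w) * J + j0, cx(i, g0, j0)],
                          [1.0, -cap], -INF, 0.0, "15")

    # ---- Block C: OR state -------------------------------------------
    for w, g in enumerate(W):
        g0 = g - 1
        for j0 in range(J):
            ccol = Cb.offset + w * J + j0
            for i in range(n):
                m.add_row([ccol, xib.offset + (i * Wn + w) * J + j0, cx(i, g0, j0)],
                          [1.0, -1.0, -float(t[i, g0, j0])], 0.0, INF, "16")
            for h in range(Hn):
                rcol = rob.offset + (h * Wn + w) * J + j0
                m.add_row([ccol, rcol], [-1.0, -M], -INF, -float(h), "17")
                m.add_row([ccol, rcol], [1.0, 1.0 + M], -INF, float(h) + M + 1.0, "18")
                lcols = [lab.offset + ((i * Wn + w) * J + j0) * Hn + h for i in range(n)]
                m.add_row(lcols + [rcol], [1.0] * n + [1.0], 1.0, 1.0, "19")
                xcol = Xib.offset + (h * Wn + w) * J + j0
                # canonical availability when the OR is idle at h
                m.add_row([xcol, rcol], [1.0, -float(h)], 0.0, INF, "rho_link")
                m.add_row([xcol, rcol], [1.0, M], -INF, float(h) + M, "rho_link")
                hh = float(max(h, 1))
                for i in range(n):
                    lc = lab.offset + ((i * Wn + w) * J + j0) * Hn + h
                    xic = xib.offset + (i * Wn + w) * J + j0
                    ti = float(t[i, g0, j0])
                    # end >= h+1 (not the printed h) so that lam picks the
                    # patient canonically operating at h, never the one whose
                    # surgery ends exactly as slot h begins
                    m.add_row([xic, cx(i, g0, j0), lc], [1.0, ti, -(hh + 1.0)], 0.0, INF, "20")
                    m.add_row([xic, lc], [1.0, M - hh], -INF, M, "21")
                    m.add_row([xcol, xic, cx(i, g0, j0), lc],
                              [1.0, -1.0, -ti, -M], -M, INF, "22")
                    m.add_row([xcol, xic, cx(i, g0, j0), lc],
                              [1.0, -1.0, -ti, M], -INF, M, "23")

    # ---- Block D: emergency-to-OR assignment -------------------------
    for w, g in enumerate(W):
        for h in range(Hn):
            cols = [etb.offset + (h * Wn + w) * J + j0 for j0 in range(J)]
            m.add_row(cols, [1.0] * J, 1.0, 1.0, "24")
            for j0 in range(J):
                for k0 in range(J):
                    if k0 == j0:
                        continue
                    m.add_row(
                        [Xib.offset + (h * Wn + w) * J + j0,
                         Xib.offset + (h * Wn + w) * J + k0,
                         etb.offset + (h * Wn + w) * J + j0],
                        [1.0, -1.0, M], -INF, M, "25")

    # ---- Block E: emergency impact ----------------------------------
    m.register_alias_family("26", "11")
    eps = inst.epsilon
    for w, g in enumerate(W):
        for h in range(Hn):
            for i in range(n):
                cols = [xib.offset + (i * Wn + w) * J + j0 for j0 in range(J)]
                cols.append(chb.offset + (h * Wn + w) * n + i)
                m.add_row(cols, [1.0] * J + [-(h + eps)], 0.0, INF, "27")
    wofg = {g: w for w, g in enumerate(W)}
    for e, (h, g, l) in enumerate(scen.emergencies):
        w = wofg[g]
        g0 = g - 1
        ebase = xbb.offset + e * n * D * J

        def cxb(i, d0, j0, _b=ebase):
            return _b + (i * D + d0) * J + j0

        dmax = min(D, g + Dlt - 1)  # d < g + Delta
        for i in range(n):
            cols = [cxb(i, d0, j0) for d0 in range(dmax) for j0 in range(J) if a[i, d0, j0]]
            cols.append(chb.offset + (h * Wn + w) * n + i)
            m.add_row(cols, [1.0] * (len(cols) - 1) + [-1.0], 0.0, INF, "28")
        for i in range(n):
            for d0 in range(D):
                xcols = [cx(i, d0, j0) for j0 in range(J) if a[i, d0, j0]]
                if not xcols:
                    continue
                if resched_window == "assignment":
                    ks = range(d0, min(d0 + Dlt, D - 1) + 1)
                else:
                    ks = range(g0, min(g0 + Dlt, D - 1) + 1)
                bcols = [cxb(i, k0, j0) for k0 in ks for j0 in range(J) if a[i, k0, j0]]
                cols = bcols + xcols + [mub.offset + e * n + i]
                vals = [1.0] * len(bcols) + [-1.0] * len(xcols) + [1.0]
                m.add_row(cols, vals, 0.0, INF, "29")
                kcols = [cxb(i, k0, j0) for k0 in range(d0) for j0 in range(J) if a[i, k0, j0]]
                m.add_row(xcols + kcols, [1.0] * (len(xcols) + len(kcols)), -INF, 1.0, "30")
            allb = [cxb(i, d0, j0) for d0 in range(D) for j0 in range(J) if a[i, d0, j0]]
            allx = [cx(i, d0, j0) for d0 in range(D) for j0 in range(J) if a[i, d0, j0]]
            if allb:
                m.add_row(allb + allx, [1.0] * len(allb) + [-1.0] * len(allx), -INF, 0.0, "31")
                m.add_row(allb, [1.0] * len(allb), -INF, 1.0, "33")
            for j0 in range(J):
                if a[i, g0, j0]:
                    m.add_row([cxb(i, g0, j0), cx(i, g0, j0), chb.offset + (h * Wn + w) * n + i],
                              [1.0, -1.0, 1.0], 0.0, INF, "32")
        for j0 in range(J):
            for d0 in range(g, D):
                cols = [cxb(i, d0, j0) for i in range(n) if a[i, d0, j0]]
                if cols:
                    vals = [float(t[i, d0, j0]) for i in range(n) if a[i, d0, j0]]
                    m.add_row(cols, vals, -INF, float(T[d0, j0]), "35")
            cols = [cxb(i, g0, j0) for i in range(n) if a[i, g0, j0]]
            vals = [float(t[i, g0, j0]) for i in range(n) if a[i, g0, j0]]
            occ = float(min(gamma[l], T[g0, j0] - h))
            cols.append(etb.offset + (h * Wn + w) * J + j0)
            vals.append(occ)
            m.add_row(cols, vals, -INF, float(T[g0, j0] + Om), "36")

    # ---- Block G: substitutes ---------------------------------------
    for w, g in enumerate(W):
        g0 = g - 1
        for j0 in range(J):
            cols = [thb.offset + (i * Wn + w) * J + j0 for i in range(n)]
            if dmb is not None:
                cols.append(dmb.offset + w * J + j0)
            m.add_row(cols, [1.0] * len(cols), 1.0, 1.0, "37")
        for i in range(n):
            tcols = [thb.offset + (i * Wn + w) * J + j0 for j0 in range(J)]
            xcols = [cx(i, g0 + 1, k0) for k0 in range(J) if a[i, g0 + 1, k0]]
            m.add_row(tcols + xcols, [1.0] * J + [-1.0] * len(xcols), -INF, 0.0, "38")

    for sb, (b, g) in enumerate(scen.noshows):
        w = wofg[g]
        g0 = g - 1
        hbase = xhb.offset + sb * n * D * J

        def cxh(i, d0, j0, _b=hbase):
            return _b + (i * D + d0) * J + j0

        for i in range(n):
            for j0 in range(J):
                wcol = swb.offset + (sb * n + i) * J + j0
                m.add_row([wcol, thb.offset + (i * Wn + w) * J + j0],
                          [1.0, -1.0], -INF, 0.0, "sub_w")
                m.add_row([wcol, cx(b, g0, j0)], [1.0, -1.0], -INF, 0.0, "sub_w")
                if a[i, g0, j0] and a[b, g0, j0]:
                    m.add_row([cxh(i, g0, j0), thb.offset + (i * Wn + w) * J + j0,
                               cx(b, g0, j0)], [1.0, -1.0, -1.0], -1.0, INF, "40")
        xbcols = [cx(b, g0, j0) for j0 in range(J) if a[b, g0, j0]]
        if noshow_mode == "fixed_delay":
            d0r = g0 + inst.delta_noshow
            rcols = [cxh(b, d0r, j0) for j0 in range(J) if a[b, d0r, j0]]
            m.add_row(rcols + xbcols, [1.0] * len(rcols) + [-1.0] * len(xbcols),
                      0.0, INF, "41")
        else:
            dmax = min(D, g + Dlt - 1)
            rcols = [cxh(b, d0, j0) for d0 in range(dmax) for j0 in range(J) if a[b, d0, j0]]
            m.add_row(rcols + xbcols, [1.0] * len(rcols) + [-1.0] * len(xbcols),
                      0.0, INF, "42")
        # ---- Block H ------------------------------------------------
        for i in range(n):
            alle = [cxh(i, d0, j0) for d0 in range(D) for j0 in range(J) if a[i, d0, j0]]
            allx = [cx(i, d0, j0) for d0 in range(D) for j0 in range(J) if a[i, d0, j0]]
            if alle:
                m.add_row(alle, [1.0] * len(alle), -INF, 1.0, "43")
                m.add_row(alle + allx, [1.0] * len(alle) + [-1.0] * len(allx), -INF, 0.0, "48")
            wcols = [swb.offset + (sb * n + i) * J + j0 for j0 in range(J)]
            for d0 in range(D):
                xcols = [cx(i, d0, j0) for j0 in range(J) if a[i, d0, j0]]
                if not xcols:
                    continue
                kcols = [cxh(i, k0, j0) for k0 in range(d0) for j0 in range(J) if a[i, k0, j0]]
                cols = xcols + kcols + wcols
                vals = [1.0] * (len(xcols) + len(kcols)) + [-1.0] * J
                m.add_row(cols, vals, -INF, 1.0, "47")
            if i != b:
                for j0 in range(J):
                    if a[i, g0, j0]:
                        m.add_row([cxh(i, g0, j0), cx(i, g0, j0)], [1.0, -1.0], 0.0, INF, "49")
        for j0 in range(J):
            for d0 in range(g, D):
                cols = [cxh(i, d0, j0) for i in range(n) if a[i, d0, j0]]
                if cols:
                    vals = [float(t[i, d0, j0]) for i in range(n) if a[i, d0, j0]]
                    m.add_row(cols, vals, -INF, float(T[d0, j0]), "45")
            cols = [cxh(i, g0, j0) for i in range(n) if a[i, g0, j0]]
            vals = [float(t[i, g0, j0]) for i in range(n) if a[i, g0, j0]]
            if cols:
                m.add_row(cols, vals, -INF, float(T[g0, j0] + Om), "46")

    c, const = _obj_nominal(m, inst, pen)
    m.set_objective(c, const, "3")
    return ModelHandle(
        model=m, instance=inst, penalties=pen, scenarios=scen,
        n_positions=S, noshow_mode=noshow_mode, resched_window=resched_window,
        kind="complete",
    )


def attach_auxiliary_block(handle: ModelHandle, block_id: str, reference: np.ndarray) -> ModelHandle:
    """Attach heuristic block "i" (difference variables), "ii" (pin day-g
    admissions to a stored x*) or "iii" (pin ordering to a stored y*).

    Block ii may be re-attached with an updated reference; i and iii may
    not.
    """
    m = handle.model
    inst = handle.instance
    n, D, J = inst.n_patients, inst.horizon_days, inst.num_ors
    W = list(inst.rs_days)
    Wn = len(W)
    xb = m.blocks["x"]

    def cx(i, d0, j0):
        return xb.offset + (i * D + d0) * J + j0

    if block_id == "i":
        if "i" in handle.attached_blocks:
            raise RuntimeError("block i already attached")
        xs = np.asarray(reference).reshape(n, D, J)
        db = m.add_block("xdiff", (n, D), "binary")
        star = xs.sum(axis=2)
        for i in range(n):
            for d0 in range(D):
                cols = [cx(i, d0, j0) for j0 in range(J)]
                dcol = db.offset + i * D + d0
                m.add_row(cols + [dcol], [1.0] * J + [-1.0], -INF, float(star[i, d0]), "51")
                m.add_row(cols + [dcol], [-1.0] * J + [-1.0], -INF, -float(star[i, d0]), "52")
        handle.attached_blocks.add("i")
        handle.x_star = xs
    elif block_id == "ii":
        if reference is None:
            raise RuntimeError("block ii needs a stored reference solution")
        xs = np.asarray(reference).reshape(n, D, J)
        for g in W:
            g0 = g - 1
            for i in range(n):
                rhs = float(xs[i, g0, :].sum())
                cols = [cx(i, g0, j0) for j0 in range(J)]
                m.add_row(cols, [1.0] * J, rhs, INF, "50")
        handle.attached_blocks.add("ii")
        handle.x_star = xs
    elif block_id == "iii":
        if "iii" in handle.attached_blocks:
            raise RuntimeError("block iii already attached")
        if reference is None:
            raise RuntimeError("block iii needs a stored ordering reference")
        yb = m.blocks["y"]
        ys = np.asarray(reference).reshape(yb.shape)
        ones = np.argwhere(ys > 0.5)
        for idx in ones:
            m.add_row([yb.offset + int(np.ravel_multi_index(tuple(idx), yb.shape))],
                      [1.0], 1.0, INF, "55")
        if "55" not in m.families:
            m.families["55"] = {"kind": "rows", "count": 0}
        handle.attached_blocks.add("iii")
        handle.y_star = ys
    else:
        raise ValueError(f"unknown auxiliary block {block_id!r}")
    return handle


def set_objective(handle: ModelHandle, kind: str) -> ModelHandle:
    """Switch the active objective; constraints are never dropped."""
    if kind in OBJECTIVE_IDS:
        oid = OBJECTIVE_IDS[kind]
    elif kind in OBJECTIVE_IDS.values():
        oid = kind
    else:
        raise ValueError(f"unknown objective {kind!r}")
    m = handle.model
    inst = handle.instance
    pen = handle.penalties
    n, D, J = inst.n_patients, inst.horizon_days, inst.num_ors
    pq = (pen.p[:, :, None] - pen.q[:, None, None]) * np.ones((n, D, J))
    if oid == "3":
        c, const = _obj_nominal(m, inst, pen)
        m.set_objective(c, const, "3")
        return handle
    if oid == "53":
        if "xdiff" not in m.blocks:
            raise RuntimeError("objective (53) requires block i")
        c = m.objective_template()
        blk = m.blocks["xdiff"]
        c[blk.offset:blk.offset + blk.size] = 1.0
        m.set_objective(c, 0.0, "53")
        return handle
    scen = handle.scenarios
    if scen is None:
        raise RuntimeError("scenario objectives require a complete model")
    c = m.objective_template()
    if oid == "54":
        if "xbar" not in m.blocks:
            raise RuntimeError("no emergency scenarios in model")
        E = len(scen.emergencies)
        N = float(E)
        blk = m.blocks["xbar"]
        c[blk.offset:blk.offset + blk.size] = np.tile(pq.ravel(), E) / N
        m.set_objective(c, float(pen.q.sum()), "54")
        return handle
    # oid == "56"
    if "xhat" not in m.blocks:
        raise RuntimeError("no no-show scenarios in model")
    B = len(scen.noshows)
    norm = handle.noshow_norm if handle.noshow_norm is not None else n / D
    blk = m.blocks["xhat"]
    c[blk.offset:blk.offset + blk.size] = np.tile(pq.ravel(), B) / norm
    m.set_objective(c, float(B * pen.q.sum()) / norm, "56")
    return handle


def extract_solution(handle: ModelHandle, xvec: np.ndarray) -> dict[str, np.ndarray]:
    """Read the raw solver vector back into named, shaped, rounded arrays."""
    out = {}
    for name, blk in handle.model.blocks.items():
        vals = handle.model.block_values(name, xvec)
        if blk.kind != "continuous":
            vals = np.rint(vals).astype(int)
        out[name] = vals
    return out
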