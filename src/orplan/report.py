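"""Human-readable renderings and benchmark-style CSV reports."""

from __future__ import annotations

import csv
import string

from .instance import Instance
from .semantics import SolutionBundle

__all__ = ["gantt_text", "results_csv_rows", "write_results_csv", "RESULT_COLUMNS"]

_SYMBOLS = string.digits + string.ascii_uppercase + string.ascii_lowercase


def _day_row(entries, instance: Instance, day: int, orid: int, width: int) -> str:
    """One OR-day as `width` one-character slot cells."""
    t = instance.duration_array()
    cells = ["."] * width
    order = sorted(entries, key=lambda e: e[1])
    for k, (pid, start) in enumerate(order):
        ti = int(t[instance.patient_index(pid), day - 1, orid - 1])
        sym = _SYMBOLS[k % len(_SYMBOLS)]
        for s in range(start - 1, min(start - 1 + ti, width)):
            cells[s] = sym
    return "".join(cells)


def gantt_text(bundle: SolutionBundle, instance: Instance,
               plan: tuple | None = None) -> str:
    """Textual Gantt: one row per (day, OR), one character per 15-min slot.

    Without ``plan`` the nominal schedule is drawn (row width = the OR's
    capacity).  With ``plan`` (an emergency triple or no-show pair) the
    corresponding backup schedule is drawn with the overtime extension.
    """
    lines = [
        "# slots are %d minutes; days 1-based; '.' = idle" % instance.slot_minutes,
    ]
    if plan is None:
        assignments = [(e.patient, e.day, e.orid) for e in bundle.nominal]
        extra = 0
        starts = {e.patient: e.start_slot for e in bundle.nominal}
        lines[0] += " ; nominal schedule"
    else:
        if len(plan) == 3:
            p = bundle.emergency_plans[tuple(plan)]
        else:
            p = bundle.noshow_plans[tuple(plan)]
        assignments = list(p.assignments)
        extra = instance.overtime_slots
        starts = {}
        lines[0] += f" ; backup schedule for scenario {tuple(plan)}"
    t = instance.duration_array()
    for d in instance.days:
        for j in instance.ors:
            here = [(pid, dd, jj) for pid, dd, jj in assignments if dd == d and jj == j]
            width = int(instance.capacity[d - 1, j - 1]) + extra
            seq = []
            cursor = 1
            for pid, _, _ in sorted(
                    here, key=lambda e: starts.get(e[0]) or instance.patient_index(e[0])):
                s = starts.get(pid)
                if s is None:
                    s = cursor
                cursor = s + int(t[instance.patient_index(pid), d - 1, j - 1])
                seq.append((pid, s))
            row = _day_row(seq, instance, d, j, width)
            legend = " ".join(f"{_SYMBOLS[k % len(_SYMBOLS)]}={pid}"
                              for k, (pid, _) in enumerate(sorted(seq, key=lambda e: e[1])))
            lines.append(f"day {d:>2} OR {j}: {row}  {legend}")
    return "\n".join(lines) + "\n"


RESULT_COLUMNS = ["ID", "|D|", "|J|", "OF", "LB_WS", "OF_WS", "OF_Heu",
                  "OF_WS-OF", "OF_Heu-OF", "gap_WS", "gap_Heu"]


def _of_complete(bundle: SolutionBundle) -> float | None:
    return bundle.metrics.get("of_complete")


def results_csv_rows(runs: list[dict]) -> list[dict]:
    """Fold per-run summaries into benchmark-table rows.

    ``runs`` entries: {"id", "horizon", "ors", "strategy", "bundle"}; the
    warm-start and heuristic runs of the same id are merged into one row.
    """
    by_key: dict[tuple, dict] = {}
    for run in runs:
        key = (run["id"], run["horizon"], run["ors"])
        row = by_key.setdefault(key, {
            "ID": run["id"], "|D|": run["horizon"], "|J|": run["ors"],
            "OF": None, "LB_WS": None, "OF_WS": None, "OF_Heu": None,
        })
        b: SolutionBundle = run["bundle"]
        row["OF"] = b.metrics.get("of_nominal")
        ofc = _of_complete(b)
        if run["strategy"] == "warm_start":
            row["OF_WS"] = ofc
            row["LB_WS"] = b.metrics.get("lb_complete")
        else:
            row["OF_Heu"] = ofc
            if row["LB_WS"] is None:
                row["LB_WS"] = b.metrics.get("lb_complete")
    out = []
    for key in sorted(by_key):
        row = by_key[key]
        of, lb = row["OF"], row["LB_WS"]
        for tag, src in (("WS", "OF_WS"), ("Heu", "OF_Heu")):
            val = row[src]
            row[f"OF_{tag}-OF"] = None if (val is None or of is None) else round(val - of, 6)
            row[f"gap_{tag}"] = (None if (val is None or not lb)
                                 else round((val - lb) / lb, 6))
        out.append(row)
    return out


def write_results_csv(rows: list[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=RESULT_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: ("" if row.get(k) is None else row[k]) for k in RESULT_COLUMNS})
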