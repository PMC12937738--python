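"""Waiting-list instances and the penalty machinery shared by every solver layer.

Conventions used throughout the package (also stated in every exported file):

* days are 1-based (``d = 1 .. horizon_days``);
* operating rooms are 1-based (``j = 1 .. num_ors``);
* within-day *moments* ``h`` are 0-based slot indices (``h = 0 .. n_slots-1``);
* surgery *start slots* are 1-based: the first patient of an OR starts at
  slot 1 and a patient of duration ``t`` starting at ``s`` occupies slots
  ``s .. s+t-1``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np

__all__ = [
    "Patient",
    "Instance",
    "PenaltyTable",
    "urgency_coefficient",
    "assignment_penalty",
    "exclusion_penalty",
    "max_positions",
    "default_compatibility",
    "read_waiting_list_csv",
]

URGENCY_NUMERATOR = 360
DEFAULT_SLOT_MINUTES = 15


def urgency_coefficient(deadline_days: int) -> Fraction:
    """Priority weight of a patient with clinical deadline ``deadline_days``.

    Returns the exact rational ``360 / deadline_days`` (never a truncated
    float), so that downstream penalty arithmetic stays exact.
    """
    if not isinstance(deadline_days, (int, np.integer)) or deadline_days <= 0:
        raise ValueError(f"deadline must be a positive integer, got {deadline_days!r}")
    return Fraction(URGENCY_NUMERATOR, int(deadline_days))


def _tardiness(waited_days: int, deadline_days: int, day: int) -> int:
    return max(waited_days + day - deadline_days, 0)


def assignment_penalty(
    waited_days: int,
    deadline_days: int,
    urgency,
    day: int,
    *,
    horizon_days: int | None = None,
    weighting: str = "full",
) -> Fraction:
    """Penalty for admitting a patient on ``day`` (1-based).

    ``weighting="full"`` multiplies the whole ``day + tardiness`` expression
    by the urgency coefficient; ``"tardiness_only"`` weights only the
    tardiness excess.
    """
    if day < 1 or (horizon_days is not None and day > horizon_days):
        raise ValueError(f"day {day} outside planning horizon")
    u = Fraction(urgency)
    tard = _tardiness(waited_days, deadline_days, day)
    if weighting == "full":
        return (day + tard) * u
    if weighting == "tardiness_only":
        return day + tard * u
    raise ValueError(f"unknown weighting {weighting!r}")


def exclusion_penalty(
    waited_days: int,
    deadline_days: int,
    urgency,
    horizon_days: int,
    *,
    weighting: str = "full",
) -> Fraction:
    """Penalty for leaving a patient off the plan entirely.

    The excluded patient is charged as if admitted one day past the horizon,
    on top of the days already spent waiting.
    """
    if horizon_days < 1:
        raise ValueError("horizon must contain at least one day")
    u = Fraction(urgency)
    base = waited_days + horizon_days + 1
    tard = max(base - deadline_days, 0)
    if weighting == "full":
        return (base + tard) * u
    if weighting == "tardiness_only":
        return base + tard * u
    raise ValueError(f"unknown weighting {weighting!r}")


def default_compatibility(horizon_days: int) -> list[int]:
    """Working days of a 1-based horizon: weekends block every day whose index
    is a multiple of 6 or of 7."""
    if horizon_days < 1:
        raise ValueError("horizon must be positive")
    return [d for d in range(1, horizon_days + 1) if d % 6 != 0 and d % 7 != 0]


@dataclass(frozen=True)
class Patient:
    """One waiting-list entry.

    ``duration_slots`` is the surgical time in whole slots, replicated over
    every compatible (day, OR) unless ``duration_overrides`` supplies a
    specific value for a pair.
    """

    id: str
    duration_slots: int
    deadline_days: int
    waited_days: int
    compatible_days: tuple[int, ...]
    compatible_ors: tuple[int, ...]
    duration_overrides: Mapping[tuple[int, int], int] | None = None

    def __post_init__(self):
        if self.duration_slots < 1:
            raise ValueError(f"patient {self.id}: duration must be >= 1 slot")
        if self.deadline_days < 1:
            raise ValueError(f"patient {self.id}: deadline must be positive")
        if self.waited_days < 0:
            raise ValueError(f"patient {self.id}: waited days must be >= 0")
        object.__setattr__(self, "compatible_days", tuple(sorted(set(self.compatible_days))))
        object.__setattr__(self, "compatible_ors", tuple(sorted(set(self.compatible_ors))))
        if self.duration_overrides:
            for (d, j), t in self.duration_overrides.items():
                if t < 1:
                    raise ValueError(f"patient {self.id}: override duration on ({d},{j}) must be >= 1")

    @property
    def urgency(self) -> Fraction:
        return urgency_coefficient(self.deadline_days)

    def duration(self, day: int, orid: int) -> int:
        if self.duration_overrides:
            return int(self.duration_overrides.get((day, orid), self.duration_slots))
        return self.duration_slots

    def is_compatible(self, day: int, orid: int) -> bool:
        return day in self.compatible_days and orid in self.compatible_ors


@dataclass
class Instance:
    """A full scheduling instance: calendar, capacities, disruption
    parameters and the waiting list."""

    horizon_days: int
    num_ors: int
    capacity: np.ndarray  # (horizon_days, num_ors) slots
    patients: list[Patient]
    rs_days: tuple[int, ...] = (1,)
    slot_minutes: int = DEFAULT_SLOT_MINUTES
    overtime_slots: int = 4
    delta_max: int = 7
    delta_noshow: int = 2
    emergency_classes: tuple[int, ...] = (4, 8, 16)
    epsilon: float = 0.5
    big_m: int | None = None

    def __post_init__(self):
        self.capacity = np.asarray(self.capacity, dtype=int)
        if self.capacity.shape != (self.horizon_days, self.num_ors):
            raise ValueError(
                f"capacity shape {self.capacity.shape} != ({self.horizon_days}, {self.num_ors})"
            )
        if (self.capacity < 1).any():
            raise ValueError("every (day, OR) capacity must be >= 1 slot")
        self.rs_days = tuple(self.rs_days)
        if self.rs_days != tuple(range(1, len(self.rs_days) + 1)):
            raise ValueError("rs_days must be a non-empty 1-based prefix of the horizon")
        maxT = int(self.capacity.max())
        for g in self.emergency_classes:
            if g < 1 or g > maxT:
                raise ValueError("emergency class lengths must lie in [1, max capacity]")
        if self.delta_noshow > self.delta_max:
            raise ValueError("delta_noshow must not exceed delta_max")
        for g in self.rs_days:
            if g + self.delta_noshow > self.horizon_days:
                raise ValueError("no-show reschedule day would fall beyond the horizon")
            if g + 1 > self.horizon_days:
                raise ValueError("substitute day g+1 would fall beyond the horizon")
        if not (0 < self.epsilon < 1):
            raise ValueError("epsilon must lie in (0, 1)")
        if self.big_m is None:
            self.big_m = max(self.n_slots, maxT + self.overtime_slots) + 1
        elif self.big_m < max(self.n_slots, maxT + self.overtime_slots + 1):
            raise ValueError("big_m too small for the horizon")

    # -- derived views -------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def days(self) -> range:
        return range(1, self.horizon_days + 1)

    @property
    def ors(self) -> range:
        return range(1, self.num_ors + 1)

    @property
    def n_slots(self) -> int:
        """Size of the within-day moment discretisation (|H|): moments run
        0 .. n_slots-1."""
        return int(self.capacity.max())

    def compat_array(self) -> np.ndarray:
        """Boolean (n_patients, horizon_days, num_ors) compatibility mask."""
        a = np.zeros((self.n_patients, self.horizon_days, self.num_ors), dtype=bool)
        for i, p in enumerate(self.patients):
            di = [d - 1 for d in p.compatible_days if 1 <= d <= self.horizon_days]
            ji = [j - 1 for j in p.compatible_ors if 1 <= j <= self.num_ors]
            if di and ji:
                a[np.ix_([i], di, ji)] = True
        return a

    def duration_array(self) -> np.ndarray:
        """Integer (n_patients, horizon_days, num_ors) surgical durations."""
        t = np.empty((self.n_patients, self.horizon_days, self.num_ors), dtype=int)
        for i, p in enumerate(self.patients):
            t[i, :, :] = p.duration_slots
            if p.duration_overrides:
                for (d, j), v in p.duration_overrides.items():
                    if 1 <= d <= self.horizon_days and 1 <= j <= self.num_ors:
                        t[i, d - 1, j - 1] = v
        return t

    def patient_index(self, pid: str) -> int:
        for i, p in enumerate(self.patients):
            if p.id == pid:
                return i
        raise KeyError(pid)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "horizon_days": self.horizon_days,
            "num_ors": self.num_ors,
            "rs_days": list(self.rs_days),
            "slot_minutes": self.slot_minutes,
            "capacity": self.capacity.tolist(),
            "overtime_slots": self.overtime_slots,
            "delta_max": self.delta_max,
            "delta_noshow": self.delta_noshow,
            "emergency_classes": list(self.emergency_classes),
            "epsilon": self.epsilon,
            "patients": [
                {
                    "id": p.id,
                    "duration_slots": p.duration_slots,
                    "deadline_days": p.deadline_days,
                    "waited_days": p.waited_days,
                    "compatible_days": list(p.compatible_days),
                    "compatible_ors": list(p.compatible_ors),
                }
                for p in self.patients
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "Instance":
        patients = [
            Patient(
                id=str(p["id"]),
                duration_slots=int(p["duration_slots"]),
                deadline_days=int(p["deadline_days"]),
                waited_days=int(p["waited_days"]),
                compatible_days=tuple(p["compatible_days"]),
                compatible_ors=tuple(p["compatible_ors"]),
            )
            for p in data["patients"]
        ]
        return cls(
            horizon_days=int(data["horizon_days"]),
            num_ors=int(data["num_ors"]),
            capacity=np.asarray(data["capacity"], dtype=int),
            patients=patients,
            rs_days=tuple(data.get("rs_days", (1,))),
            slot_minutes=int(data.get("slot_minutes", DEFAULT_SLOT_MINUTES)),
            overtime_slots=int(data.get("overtime_slots", 4)),
            delta_max=int(data.get("delta_max", 7)),
            delta_noshow=int(data.get("delta_noshow", 2)),
            emergency_classes=tuple(data.get("emergency_classes", (4, 8, 16))),
            epsilon=float(data.get("epsilon", 0.5)),
            big_m=data.get("big_m"),
        )

    @classmethod
    def from_json(cls, path) -> "Instance":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def max_positions(instance: Instance) -> int:
    """Number of within-day sequence positions to reserve:
    ``floor(max capacity / min duration)``, at least 1."""
    if not instance.patients:
        raise ValueError("instance has no patients")
    a = instance.compat_array()
    t = instance.duration_array()
    if a.any():
        tmin = int(t[a].min())
    else:
        tmin = int(t.min())
    return max(int(instance.capacity.max()) // tmin, 1)


@dataclass
class PenaltyTable:
    """Per-(patient, day) admission penalties and per-patient exclusion
    penalties, kept as exact fractions with a float view for the solvers."""

    p: np.ndarray  # (n_patients, horizon_days) float
    q: np.ndarray  # (n_patients,) float
    p_exact: list[list[Fraction]]
    q_exact: list[Fraction]
    weighting: str = "full"

    @classmethod
    def from_instance(cls, instance: Instance, weighting: str = "full") -> "PenaltyTable":
        n, D = instance.n_patients, instance.horizon_days
        p_exact = []
        q_exact = []
        for pat in instance.patients:
            u = pat.urgency
            row = [
                assignment_penalty(pat.waited_days, pat.deadline_days, u, d, weighting=weighting)
                for d in range(1, D + 1)
            ]
            p_exact.append(row)
            q_exact.append(
                exclusion_penalty(pat.waited_days, pat.deadline_days, u, D, weighting=weighting)
            )
        p = np.array([[float(v) for v in row] for row in p_exact])
        q = np.array([float(v) for v in q_exact])
        return cls(p=p, q=q, p_exact=p_exact, q_exact=q_exact, weighting=weighting)

    def check(self) -> None:
        """Assert the structural penalty invariants by full scan."""
        n, D = self.p.shape
        for i in range(n):
            for d in range(D):
                if not self.q_exact[i] > self.p_exact[i][d]:
                    raise AssertionError(f"q[{i}] <= p[{i},{d + 1}]")
                if d > 0 and not self.p_exact[i][d] >= self.p_exact[i][d - 1]:
                    raise AssertionError(f"p[{i}] not monotone at day {d + 1}")


def read_waiting_list_csv(path, horizon_days: int, num_ors: int) -> list[Patient]:
    """Read a waiting list with columns id,duration_slots,deadline_days,
    waited_days; compatibility defaults to all ORs on working (non-weekend)
    days."""
    days = tuple(default_compatibility(horizon_days))
    ors = tuple(range(1, num_ors + 1))
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Patient(
                    id=str(row["id"]),
                    duration_slots=int(row["duration_slots"]),
                    deadline_days=int(row["deadline_days"]),
                    waited_days=int(row["waited_days"]),
                    compatible_days=days,
                    compatible_ors=ors,
                )
            )
    return out
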