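"""Reproducible synthetic waiting-list instances.

Instances follow the benchmark design: 6-hour OR days split into 24
fifteen-minute slots, weekends blocked (days divisible by 6 or 7), one
hour of recovery overtime, emergencies of 1 h / 2 h / 4 h, no-shows
rescheduled exactly two days later and emergency-displaced patients within
a week.  Patients belong to five urgency classes and to one of four
surgical-length mixes (A short-skewed, B long-skewed, C uniform,
D bimodal); the case-study mix skews toward the most urgent classes.
The published histograms behind the mixes are not numerically tabulated,
so the distributions below are documented defaults and fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .instance import Instance, Patient, default_compatibility

__all__ = ["GeneratorConfig", "generate_instance", "case_study_instance", "MIXES"]

# duration (slots) -> probability
MIXES: dict[str, dict[int, float]] = {
    "A": {2: 0.35, 3: 0.25, 4: 0.20, 6: 0.12, 8: 0.08},
    "B": {4: 0.08, 6: 0.12, 8: 0.20, 12: 0.30, 16: 0.30},
    "C": {2: 1 / 6, 4: 1 / 6, 6: 1 / 6, 8: 1 / 6, 10: 1 / 6, 12: 1 / 6},
    "D": {2: 0.30, 4: 0.20, 12: 0.20, 16: 0.30},
    "case_study": {2: 0.30, 3: 0.20, 4: 0.20, 6: 0.15, 8: 0.15},
}

# five urgency classes, most urgent first; deadlines in days
DEADLINE_CLASSES: tuple[int, ...] = (30, 60, 90, 180, 360)
URGENCY_DIST: tuple[float, ...] = (0.08, 0.12, 0.20, 0.30, 0.30)
CASE_STUDY_URGENCY_DIST: tuple[float, ...] = (0.28, 0.24, 0.20, 0.16, 0.12)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic instance draw."""

    n_patients: int = 40
    horizon_days: int = 14
    num_ors: int = 2
    mix: str = "A"
    seed: int = 0
    capacity_slots: int = 24
    overtime_slots: int = 4
    delta_max: int = 7
    delta_noshow: int = 2
    emergency_classes: tuple[int, ...] = (4, 8, 16)
    rs_days: tuple[int, ...] = (1,)
    slot_minutes: int = 15
    deadline_classes: tuple[int, ...] = DEADLINE_CLASSES
    urgency_dist: tuple[float, ...] = URGENCY_DIST
    duration_dist: tuple[tuple[int, float], ...] | None = None
    waited_fraction: float = 0.8  # m_i ~ U{0 .. ceil(f * l_i)}

    def resolved_duration_dist(self) -> tuple[tuple[int, float], ...]:
        if self.duration_dist is not None:
            return self.duration_dist
        if self.mix not in MIXES:
            raise ValueError(f"unknown mix {self.mix!r}")
        return tuple(sorted(MIXES[self.mix].items()))

    def validate(self) -> None:
        if self.n_patients < 1 or self.horizon_days < 1 or self.num_ors < 1:
            raise ValueError("dimensions must be positive")
        dd = self.resolved_duration_dist()
        probs = [p for _, p in dd]
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("duration distribution must be a probability vector")
        if abs(sum(self.urgency_dist) - 1.0) > 1e-9:
            raise ValueError("urgency distribution must sum to 1")
        if len(self.urgency_dist) != len(self.deadline_classes):
            raise ValueError("urgency distribution / deadline classes length mismatch")
        if any(d < 1 or d > self.capacity_slots for d, _ in dd):
            raise ValueError("duration support must fit within the daily capacity")


def generate_instance(config: GeneratorConfig) -> Instance:
    """Draw one instance; byte-identical output for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    dd = config.resolved_duration_dist()
    dur_vals = np.array([d for d, _ in dd])
    dur_p = np.array([p for _, p in dd], dtype=float)
    dur_p = dur_p / dur_p.sum()
    urg_p = np.asarray(config.urgency_dist, dtype=float)
    urg_p = urg_p / urg_p.sum()
    days = tuple(default_compatibility(config.horizon_days))
    ors = tuple(range(1, config.num_ors + 1))
    width = len(str(config.n_patients))
    patients = []
    for k in range(config.n_patients):
        t = int(rng.choice(dur_vals, p=dur_p))
        cls = int(rng.choice(len(config.deadline_classes), p=urg_p))
        li = int(config.deadline_classes[cls])
        mi = int(rng.integers(0, int(np.ceil(config.waited_fraction * li)) + 1))
        patients.append(
            Patient(
                id=f"P{k + 1:0{width}d}",
                duration_slots=t,
                deadline_days=li,
                waited_days=mi,
                compatible_days=days,
                compatible_ors=ors,
            )
        )
    capacity = np.full((config.horizon_days, config.num_ors), config.capacity_slots, dtype=int)
    return Instance(
        horizon_days=config.horizon_days,
        num_ors=config.num_ors,
        capacity=capacity,
        patients=patients,
        rs_days=config.rs_days,
        slot_minutes=config.slot_minutes,
        overtime_slots=config.overtime_slots,
        delta_max=config.delta_max,
        delta_noshow=config.delta_noshow,
        emergency_classes=config.emergency_classes,
    )


def case_study_instance(
    seed: int = 0, horizon_days: int = 14, num_ors: int = 2
) -> Instance:
    """The 54-patient realistic configuration: same calendar defaults, a
    day-hospital duration mix and an urgency distribution skewed toward the
    most urgent classes."""
    cfg = GeneratorConfig(
        n_patients=54,
        horizon_days=horizon_days,
        num_ors=num_ors,
        mix="case_study",
        seed=seed,
        urgency_dist=CASE_STUDY_URGENCY_DIST,
    )
    return generate_instance(cfg)
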