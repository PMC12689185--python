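"""Exercise-dose quantification in METs·min/week.

A weekly exercise dose is the product of activity intensity (METs), session
duration (minutes) and weekly frequency.  Sessions are decomposed into
warm-up, main and cool-down phases, each contributing ``mets × minutes`` to
the session energy; combined-training (CT) sessions additionally split the
main phase into aerobic and resistance components weighted by their own METs
and durations.  Progressive protocols (dose escalating over the intervention)
are reduced to a single equivalent prescription by a weeks-weighted average
of METs, session minutes and frequency before the dose is computed.

Doses convert back to equivalent weekly minutes at a given intensity by
``round_half_up(dose / mets)``; intensity bands follow the Compendium
convention (light 1.6–2.9, moderate 3.0–5.9, vigorous ≥6.0 METs) and BMI
categories follow the Chinese WS/T 428-2013 cuts (normal 18.5–23.9,
overweight 24.0–27.9, obesity ≥28.0 kg/m²).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "Phase",
    "Component",
    "PeriodBlock",
    "Prescription",
    "session_energy",
    "combined_session_energy",
    "weekly_dose",
    "progressive_average",
    "dose_to_minutes",
    "classify_intensity",
    "classify_bmi",
    "DEFAULT_ANCILLARY_METS",
]

PHASE_ROLES = ("warmup", "main", "cooldown")

#: Default intensity assumed for warm-up/cool-down phases when a protocol
#: reports their duration but not their METs (mid light-intensity band).
DEFAULT_ANCILLARY_METS = 2.5


@dataclass(frozen=True)
class Phase:
    """One session phase: role, intensity (METs) and duration (minutes)."""

    role: str
    mets: float
    minutes: float

    def __post_init__(self) -> None:
        if self.role not in PHASE_ROLES:
            raise ValueError(f"unknown phase role {self.role!r}")
        if self.mets <= 0:
            raise ValueError("phase METs must be positive")
        if self.minutes < 0:
            raise ValueError("phase minutes must be non-negative")


@dataclass(frozen=True)
class Component:
    """Sub-modality block inside a CT main phase (e.g. AT or RT)."""

    sub_modality: str
    mets: float
    minutes: float


@dataclass(frozen=True)
class PeriodBlock:
    """One period of a progressive protocol."""

    weeks: float
    phases: tuple[Phase, ...]
    sessions_per_week: float


@dataclass
class Prescription:
    """Phase-structured exercise prescription for one trial arm."""

    phases: list[Phase] = field(default_factory=list)
    sessions_per_week: float = 0.0
    schedule: list[PeriodBlock] | None = None
    components: list[Component] | None = None

    def validate(self) -> None:
        if self.sessions_per_week < 0:
            raise ValueError("sessions_per_week must be non-negative")
        if self.schedule is not None and not self.schedule:
            raise ValueError("schedule present but empty")


def session_energy(phases) -> float:
    """Energy of one session, METs·min, summed over phases.

    Warm-up and cool-down count on the same footing as the main phase.
    """
    total = 0.0
    for ph in phases:
        if ph.minutes < 0:
            raise ValueError("negative phase minutes")
        total += ph.mets * ph.minutes
    return total


def combined_session_energy(components) -> float:
    """CT session energy: sum of mets×minutes over sub-modality components."""
    comps = list(components)
    if len(comps) < 2:
        warnings.warn(
            "CT prescription with fewer than 2 components is degenerate",
            stacklevel=2,
        )
    return sum(c.mets * c.minutes for c in comps)


def progressive_average(schedule) -> Prescription:
    """Collapse a progressive schedule into one equivalent prescription.

    Each period is summarised by its total session minutes, its
    minutes-weighted mean METs and its frequency; these three scalars are then
    averaged across periods weighted by period length in weeks.
    """
    periods = list(schedule)
    total_weeks = sum(p.weeks for p in periods)
    if total_weeks <= 0:
        raise ValueError("schedule has zero total weeks")
    mins = mets = freq = 0.0
    for p in periods:
        m = sum(ph.minutes for ph in p.phases)
        e = session_energy(p.phases)
        w = p.weeks / total_weeks
        mins += w * m
        mets += w * (e / m if m > 0 else 0.0)
        freq += w * p.sessions_per_week
    return Prescription(
        phases=[Phase("main", mets, mins)] if mets > 0 else [],
        sessions_per_week=freq,
    )


def weekly_dose(prescription: Prescription) -> float:
    """Weekly dose in METs·min/week for one prescription.

    ``session_energy × sessions_per_week``; frequency counts every weekly
    session including multiple sessions on the same day.  Progressive
    schedules are averaged first; CT components replace the main phase.
    """
    p = prescription
    p.validate()
    if p.schedule:
        p = progressive_average(p.schedule)
    if prescription.components:
        ancillary = [ph for ph in prescription.phases if ph.role != "main"]
        energy = combined_session_energy(prescription.components) + session_energy(ancillary)
        spw = prescription.sessions_per_week
    else:
        energy = session_energy(p.phases)
        spw = p.sessions_per_week
    return energy * spw


def dose_to_minutes(dose: float, mets: float) -> int:
    """Equivalent weekly minutes at a fixed intensity, rounded half up.

    Examples: 850 METs·min/week at 7 METs → 121 min; at 5.9 → 144;
    550 at 6.0 → 92.
    """
    if mets <= 0:
        raise ValueError("METs must be positive")
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if mets < 1.6:
        warnings.warn(
            f"intensity {mets} METs is below the light-activity threshold (1.6)",
            stacklevel=2,
        )
    return int(math.floor(dose / mets + 0.5))


def classify_intensity(mets: float) -> str:
    """Compendium intensity band: light/moderate/vigorous (closed bands)."""
    if mets <= 0:
        raise ValueError("METs must be positive")
    if mets < 1.6:
        return "below_light"
    if mets < 3.0:
        return "light"
    if mets < 6.0:
        return "moderate"
    return "vigorous"


def classify_bmi(bmi: float) -> str:
    """Chinese WS/T 428-2013 BMI category."""
    if bmi < 14:
        raise ValueError("BMI below plausible range")
    if bmi < 18.5:
        return "underweight"
    if bmi < 24.0:
        return "normal"
    if bmi < 28.0:
        return "overweight"
    return "obesity"
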