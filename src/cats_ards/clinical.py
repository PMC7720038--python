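"""Deterministic clinical scores and ventilation outcome variables.

Conventions for the ventilation course: only invasive ventilation counts,
day 0 is ARDS onset, and liberation from the ventilator must last more than
24 h to end an episode — an extubation gap of <= 1 day merges the adjacent
intervals, while re-intubation after a gap of > 1 day adds further days to
the total. Ventilator-free days (VFDs) are computed against a fixed 28-day
horizon: survivors receive 28 minus total ventilator days (partial days
rounded up), and PICU nonsurvivors or subjects ventilated >= 28 days
receive 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dataio import EventRecord
from .errors import DomainError

#: liberation threshold: a gap of exactly 24 h does NOT count as liberation
LIBERATION_GAP_DAYS = 1.0

#: vasopressor-score weights, in canonical drug order
VASOPRESSOR_WEIGHTS = {
    "dopamine": 1.0,        # ug/kg/min
    "dobutamine": 1.0,      # ug/kg/min
    "epinephrine": 100.0,   # ug/kg/min
    "norepinephrine": 100.0,
    "phenylephrine": 100.0,
    "milrinone": 10.0,
    "vasopressin": 10000.0,  # U/kg/min
}


@dataclass(frozen=True)
class GasExchange:
    """One arterial blood-gas observation with ventilator settings."""

    map_cmH2O: float  # mean airway pressure
    fio2: float       # inspired oxygen fraction, (0, 1]
    pao2: float       # arterial oxygen tension, mmHg


@dataclass(frozen=True)
class VasoactiveDoses:
    """Infusion rates; absent drug means 0."""

    dopamine: float = 0.0
    dobutamine: float = 0.0
    epinephrine: float = 0.0
    norepinephrine: float = 0.0
    phenylephrine: float = 0.0
    milrinone: float = 0.0
    vasopressin: float = 0.0


def oxygenation_index(g: GasExchange) -> float:
    """OI = (mean airway pressure x FiO2 x 100) / PaO2; higher is worse."""
    if g.pao2 <= 0:
        raise DomainError(f"pao2 must be positive, got {g.pao2}")
    return g.map_cmH2O * g.fio2 * 100.0 / g.pao2


def pf_ratio(pao2: float, fio2: float) -> float:
    """PaO2/FiO2 ratio in mmHg; lower is worse."""
    if fio2 <= 0:
        raise DomainError(f"fio2 must be positive, got {fio2}")
    return pao2 / fio2


def vasopressor_score(d: VasoactiveDoses) -> float:
    """Weighted sum of vasoactive infusion rates quantifying hemodynamic
    support (dopamine and dobutamine x1, catecholamine pressors x100,
    milrinone x10, vasopressin x10,000)."""
    total = 0.0
    for drug, weight in VASOPRESSOR_WEIGHTS.items():
        dose = getattr(d, drug)
        if dose < 0:
            raise DomainError(f"negative {drug} dose: {dose}")
        total += weight * dose
    return total


def _merged_intervals(record: EventRecord) -> list[tuple[float, float]]:
    """Merge ventilation intervals separated by gaps <= 24 h (liberation
    not achieved); longer gaps leave separate counted episodes."""
    merged: list[list[float]] = []
    for a, b in record.intervals:  # EventRecord sorts and checks overlap
        if merged and a - merged[-1][1] <= LIBERATION_GAP_DAYS:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def ventilator_days(record: EventRecord) -> float:
    """Total invasive ventilator days after applying the liberation rule."""
    return sum(b - a for a, b in _merged_intervals(record))


def vfd28(record: EventRecord, *, round_up_partial_days: bool = True) -> int:
    """Ventilator-free days at the 28-day horizon.

    PICU nonsurvivors get 0, as do survivors ventilated >= 28 days.
    Partial ventilator days are rounded up before subtraction by default
    (integer VFDs), configurable via ``round_up_partial_days``.
    """
    if not record.picu_survivor:
        return 0
    days = ventilator_days(record)
    if days >= 28.0:
        return 0
    if round_up_partial_days:
        days = math.ceil(days - 1e-9)
    return max(0, int(28 - days))


def classify_immunocompromised(
    *,
    oncologic: bool = False,
    immunologic: bool = False,
    rheumatologic: bool = False,
    transplant: bool = False,
    active_therapy: bool = False,
    congenital: bool = False,
) -> bool:
    """Immunocompromised designation: an immunocompromising diagnosis
    (oncologic / immunologic / rheumatologic / transplant) together with
    active immunosuppressive therapy, or a congenital immunodeficiency."""
    diagnosis = oncologic or immunologic or rheumatologic or transplant
    return (diagnosis and active_therapy) or congenital


def first_liberation_time(record: EventRecord) -> tuple[float, int]:
    """Competing-risk observation for the extubation analysis.

    Returns ``(time, event)`` with event 1 = extubated alive (first
    sustained liberation, > 24 h off the ventilator, and alive at that
    time), 2 = died on the ventilator by day 28, 0 = administratively
    censored at day 28 while ventilated.
    """
    horizon = record.followup_day
    merged = _merged_intervals(record)
    end = merged[0][1] if merged else 0.0
    death = record.death_day
    if death is not None and death <= end:
        return (min(death, horizon), 2)
    if end >= horizon:
        return (horizon, 0)
    return (end, 1)
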