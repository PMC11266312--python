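"""Core domain types: participants, beat-level observations, strata.

All pressures are mmHg, volumes mL, heart rate beats/min, height metres,
weight kg, body surface area m². Derived quantities (pulse pressure, BSA,
BMI) are computed at construction and never stored inconsistently.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class ValidationError(ValueError):
    """An input record violates a physiological/type invariant."""


class Posture(str, enum.Enum):
    SUPINE = "supine"
    HUT60 = "hut60"


class Condition(str, enum.Enum):
    THERMONEUTRAL = "thermoneutral"
    HOT = "hot"


_POSTURE_ALIASES = {
    "supine": Posture.SUPINE,
    "hut60": Posture.HUT60,
    "hut": Posture.HUT60,
    "hut 60": Posture.HUT60,
    "head-up tilt": Posture.HUT60,
}

_CONDITION_ALIASES = {
    "thermoneutral": Condition.THERMONEUTRAL,
    "neutral": Condition.THERMONEUTRAL,
    "hot": Condition.HOT,
    "heatwave": Condition.HOT,
}


def parse_posture(label: str) -> Posture:
    try:
        return _POSTURE_ALIASES[str(label).strip().lower()]
    except KeyError:
        raise ValidationError(f"unknown posture label: {label!r}") from None


def parse_condition(label: str) -> Condition:
    try:
        return _CONDITION_ALIASES[str(label).strip().lower()]
    except KeyError:
        raise ValidationError(f"unknown condition label: {label!r}") from None


def derive_pulse_pressure(sap: float, dap: float) -> float:
    """Pulse pressure PP = SAP − DAP (mmHg); requires SAP > DAP > 0."""
    if not (dap > 0):
        raise ValidationError(f"diastolic pressure must be positive, got {dap}")
    if not (sap > dap):
        raise ValidationError(
            f"systolic pressure must exceed diastolic (sap={sap}, dap={dap})"
        )
    return sap - dap


def derive_bsa(height_m: float, weight_kg: float, method: str = "dubois") -> float:
    """Body surface area (m²) from height (m) and weight (kg).

    Methods: ``dubois`` (0.007184·H_cm^0.725·W^0.425, the default) or
    ``mosteller`` (sqrt(H_cm·W/3600)).
    """
    if not (1.0 < height_m < 2.5):
        raise ValidationError(f"height {height_m} m outside plausible range (1.0, 2.5)")
    if not (30 < weight_kg < 250):
        raise ValidationError(f"weight {weight_kg} kg outside plausible range (30, 250)")
    h_cm = height_m * 100.0
    if method == "dubois":
        return 0.007184 * h_cm**0.725 * weight_kg**0.425
    if method == "mosteller":
        return math.sqrt(h_cm * weight_kg / 3600.0)
    raise ValidationError(f"unknown BSA method: {method!r} (use 'dubois' or 'mosteller')")


def compute_cardiac_output(sv_ml: float, hr_bpm: float) -> float:
    """Cardiac output CO = SV·HR / 1000 (L/min)."""
    if sv_ml <= 0 or hr_bpm <= 0:
        raise ValidationError(
            f"stroke volume and heart rate must be positive (sv={sv_ml}, hr={hr_bpm})"
        )
    return sv_ml * hr_bpm / 1000.0


def compute_cardiac_index(co_l_min: float, bsa_m2: float) -> float:
    """Cardiac index = CO / BSA (L/min/m²)."""
    if co_l_min <= 0 or bsa_m2 <= 0:
        raise ValidationError(
            f"cardiac output and BSA must be positive (co={co_l_min}, bsa={bsa_m2})"
        )
    return co_l_min / bsa_m2


@dataclass(frozen=True)
class SubjectProfile:
    """One participant's anthropometry with derived BSA and BMI."""

    subject_id: str
    age: float          # years
    height: float       # metres
    weight: float       # kg
    bsa_method: str = "dubois"
    bsa: float = field(init=False)
    bmi: float = field(init=False)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValidationError(f"subject {self.subject_id}: age must be positive")
        bsa = derive_bsa(self.height, self.weight, self.bsa_method)
        object.__setattr__(self, "bsa", bsa)
        object.__setattr__(self, "bmi", self.weight / self.height**2)


@dataclass(frozen=True)
class HemodynamicObservation:
    """One beat (or test-average) record of pressures, HR and measured SV."""

    subject_id: str
    day_index: int
    posture: Posture
    condition: Condition
    sap: float          # mmHg
    dap: float          # mmHg
    hr: float | None    # beats/min; None when the record carries no HR
    sv_measured: float  # mL
    pp: float = field(init=False)

    def __post_init__(self) -> None:
        pp = derive_pulse_pressure(self.sap, self.dap)  # raises if invalid
        object.__setattr__(self, "pp", pp)
        if not (1 <= self.day_index <= 9):
            raise ValidationError(
                f"subject {self.subject_id}: day_index {self.day_index} outside 1–9"
            )
        if self.hr is not None and not (20 < self.hr < 250):
            raise ValidationError(
                f"subject {self.subject_id}: heart rate {self.hr} outside (20, 250)"
            )
        if self.sv_measured <= 0:
            raise ValidationError(
                f"subject {self.subject_id}: measured SV must be positive"
            )


@dataclass(frozen=True)
class Stratum:
    """One analysis cell: a posture filter crossed with a condition filter.

    ``both`` on either axis pools the levels; the 3×3 grid gives the nine
    analysis cells (both/supine/hut60 × both/thermoneutral/hot).
    """

    posture: str = "both"     # supine | hut60 | both
    condition: str = "both"   # thermoneutral | hot | both

    def __post_init__(self) -> None:
        if self.posture not in ("supine", "hut60", "both"):
            raise ValidationError(f"bad posture filter: {self.posture!r}")
        if self.condition not in ("thermoneutral", "hot", "both"):
            raise ValidationError(f"bad condition filter: {self.condition!r}")

    @property
    def label(self) -> str:
        return f"{self.posture}|{self.condition}"


ALL_STRATA: tuple[Stratum, ...] = tuple(
    Stratum(p, c)
    for p in ("both", "supine", "hut60")
    for c in ("both", "thermoneutral", "hot")
)
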