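"""Registry of the 22 published stroke-volume prediction formulae.

Each entry stores the equation string as printed in its source alongside a
structured interpretation (functional form + parameters) that the predictor
evaluates. Four functional families are supported:

* ``pressure_linear`` — SV = s·(a + b·PP − c·(DAP + k·PP) − d·age) + o,
  the Starr/Jackson/Bridwell family (mmHg, years → mL);
* ``power_anthro`` — SV = coef·x^exp on weight, BSA or height;
* ``linear_anthro`` — SV = slope·x + intercept on weight or height;
* ``lu_co`` — a cardiac-output regression (L/min) on age and weight,
  converted to SV as 1000·CO/HR;
* ``remington_table`` — SV = (VF(SAP) − VF(DAP))·BSA with VF a user-supplied
  monotone pressure → volume-factor table.

Applicability constraints (the de Simone formulae were derived in a
normal-weight population, BMI ≤ 25.25 kg/m²) are evaluated per subject and
produce flagged, skipped predictions rather than numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

from .types import (
    HemodynamicObservation,
    SubjectProfile,
    ValidationError,
)

__all__ = [
    "FormulaSpec",
    "FormulaRegistry",
    "PredictionRecord",
    "VolumeFactorTable",
    "load_registry",
    "predict_sv",
    "predict_all",
    "predict_vector",
]

_INPUTS_BY_FORM = {
    "pressure_linear": frozenset({"pp", "dap", "age"}),
    "lu_co": frozenset({"age", "weight", "hr"}),
    "remington_table": frozenset({"sap", "dap", "bsa"}),
}

_ANTHRO_INPUT_KEYS = {"weight": "weight", "bsa": "bsa", "height_m": "height", "height_cm": "height"}


class MissingInputError(ValidationError):
    """A formula requires an input absent from the record (e.g. HR)."""


@dataclass(frozen=True)
class FormulaSpec:
    """One registry entry: interpretation plus the printed source string."""

    formula_id: str
    label: str
    source_text: str                  # equation exactly as printed
    form: str
    params: Mapping[str, float | str | bool]
    applicability: tuple[Mapping[str, float | str], ...] = ()
    required_inputs: frozenset[str] = dc_field(init=False)

    def __post_init__(self) -> None:
        if self.form in _INPUTS_BY_FORM:
            req = _INPUTS_BY_FORM[self.form]
            if self.form == "pressure_linear" and self.params.get("uses_sap"):
                req = frozenset({"sap", "dap", "age"})
        elif self.form in ("power_anthro", "linear_anthro"):
            req = frozenset({_ANTHRO_INPUT_KEYS[str(self.params["input"])]})
        else:
            raise ValidationError(f"{self.formula_id}: unknown form {self.form!r}")
        object.__setattr__(self, "required_inputs", req)

    def check_applicability(self, subject: SubjectProfile) -> str:
        """Return a skip reason, or '' when all constraints hold."""
        for rule in self.applicability:
            value = getattr(subject, str(rule["var"]))
            if "max" in rule and value > float(rule["max"]):
                return (
                    f"{rule['var']}={value:.2f} exceeds the {rule['max']} "
                    f"limit for {self.formula_id}"
                )
            if "min" in rule and value < float(rule["min"]):
                return (
                    f"{rule['var']}={value:.2f} below the {rule['min']} "
                    f"limit for {self.formula_id}"
                )
        return ""


@dataclass(frozen=True)
class PredictionRecord:
    """Outcome of applying one formula to one observation."""

    subject_id: str
    formula_id: str
    sv_predicted: float | None
    applicable: bool
    skip_reason: str = ""


class VolumeFactorTable:
    """Monotone pressure (mmHg) → volume-factor lookup, linearly interpolated."""

    def __init__(self, pressures: Sequence[float], factors: Sequence[float]):
        p = np.asarray(pressures, dtype=float)
        f = np.asarray(factors, dtype=float)
        if p.size < 2 or p.size != f.size:
            raise ValidationError("volume-factor table needs ≥2 aligned nodes")
        if not (np.all(np.diff(p) > 0) and np.all(np.diff(f) > 0)):
            raise ValidationError("volume-factor table must be strictly increasing")
        self._p, self._f = p, f

    def __call__(self, pressure: float | np.ndarray) -> float | np.ndarray:
        return np.interp(pressure, self._p, self._f)


class FormulaRegistry:
    """Ordered collection of :class:`FormulaSpec`, keyed by formula id."""

    def __init__(self, specs: Sequence[FormulaSpec], version: int = 1):
        self.version = version
        self._specs = list(specs)
        self._by_id = {s.formula_id: s for s in self._specs}
        if len(self._by_id) != len(self._specs):
            raise ValidationError("duplicate formula ids in registry")

    def __len__(self) -> int:
        return len(self._specs)

    def __iter__(self) -> Iterator[FormulaSpec]:
        return iter(self._specs)

    def __contains__(self, formula_id: str) -> bool:
        return formula_id in self._by_id

    def __getitem__(self, formula_id: str) -> FormulaSpec:
        try:
            return self._by_id[formula_id]
        except KeyError:
            raise KeyError(f"formula {formula_id!r} not in registry") from None

    @property
    def formula_ids(self) -> list[str]:
        return [s.formula_id for s in self._specs]


def load_registry(path: str | None = None) -> FormulaRegistry:
    """Load the registry from YAML (the packaged 22-entry file by default)."""
    if path is None:
        text = (
            resources.files("pulsesv").joinpath("data/formulae.yaml").read_text("utf-8")
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    specs = [
        FormulaSpec(
            formula_id=entry["id"],
            label=entry["label"],
            source_text=entry["equation"],
            form=entry["form"],
            params=dict(entry.get("params", {})),
            applicability=tuple(entry.get("applicability", ())),
        )
        for entry in doc["formulae"]
    ]
    return FormulaRegistry(specs, version=int(doc.get("version", 1)))


# ---------------------------------------------------------------------------
# evaluation of a single formula


def _eval_pressure_linear(params: Mapping, pp, dap, age):
    a = float(params["a"])
    b = float(params["b"])
    c = float(params["c"])
    d = float(params["d"])
    k = float(params.get("k", 0.0))
    scale = float(params.get("scale", 1.0))
    offset = float(params.get("offset", 0.0))
    if params.get("uses_sap"):
        # b multiplies SAP = PP + DAP rather than PP
        core = a + b * (pp + dap) - c * dap - d * age
    else:
        core = a + b * pp - c * (dap + k * pp) - d * age
    return scale * core + offset


def _eval_scalar(
    spec: FormulaSpec,
    subject: SubjectProfile,
    obs: HemodynamicObservation,
    remington_table: VolumeFactorTable | None,
) -> float:
    p = spec.params
    if spec.form == "pressure_linear":
        return float(_eval_pressure_linear(p, obs.pp, obs.dap, subject.age))
    if spec.form == "power_anthro":
        x = _anthro_value(subject, str(p["input"]))
        return float(p["coef"]) * x ** float(p["exponent"])
    if spec.form == "linear_anthro":
        x = _anthro_value(subject, str(p["input"]))
        return float(p["slope"]) * x + float(p["intercept"])
    if spec.form == "lu_co":
        if obs.hr is None:
            raise MissingInputError(
                f"{spec.formula_id} requires heart rate, absent from record"
            )
        co = (
            float(p["a0"])
            + float(p["orphan"])
            - float(p["age_coef"]) * subject.age
            + float(p["weight_coef"]) * subject.weight
        )
        return 1000.0 * co / obs.hr
    if spec.form == "remington_table":
        if remington_table is None:
            raise MissingInputError(
                f"{spec.formula_id} requires a volume-factor table; none supplied"
            )
        return float(
            (remington_table(obs.sap) - remington_table(obs.dap)) * subject.bsa
        )
    raise ValidationError(f"unknown form {spec.form!r}")


def _anthro_value(subject: SubjectProfile, key: str) -> float:
    if key == "weight":
        return subject.weight
    if key == "bsa":
        return subject.bsa
    if key == "height_m":
        return subject.height
    if key == "height_cm":
        return subject.height * 100.0
    raise ValidationError(f"unknown anthropometric input {key!r}")


def predict_sv(
    formula: str | FormulaSpec,
    subject: SubjectProfile,
    obs: HemodynamicObservation,
    registry: FormulaRegistry | None = None,
    remington_table: VolumeFactorTable | None = None,
) -> PredictionRecord:
    """Apply one formula to one observation.

    Returns a :class:`PredictionRecord`; applicability-constraint failures
    yield ``applicable=False`` with the reason, while missing required
    inputs raise :class:`MissingInputError`.
    """
    if isinstance(formula, FormulaSpec):
        spec = formula
    else:
        spec = (registry or load_registry())[formula]
    reason = spec.check_applicability(subject)
    if reason:
        return PredictionRecord(obs.subject_id, spec.formula_id, None, False, reason)
    sv = _eval_scalar(spec, subject, obs, remington_table)
    if not math.isfinite(sv):
        raise ValidationError(f"{spec.formula_id}: non-finite prediction")
    return PredictionRecord(obs.subject_id, spec.formula_id, sv, True)


def predict_all(
    subject: SubjectProfile,
    obs: HemodynamicObservation,
    registry: FormulaRegistry | None = None,
    remington_table: VolumeFactorTable | None = None,
) -> list[PredictionRecord]:
    """Apply every registry formula to one observation, in registry order.

    Per-formula failures (missing HR, absent Remington table) become skip
    records; the batch never aborts.
    """
    registry = registry or load_registry()
    records = []
    for spec in registry:
        try:
            records.append(predict_sv(spec, subject, obs, remington_table=remington_table))
        except MissingInputError as exc:
            records.append(
                PredictionRecord(obs.subject_id, spec.formula_id, None, False, str(exc))
            )
    return records


def predict_vector(
    spec: FormulaSpec,
    frame,
    remington_table: VolumeFactorTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised prediction over a merged observation/anthropometry frame.

    ``frame`` must carry columns ``pp, sap, dap, hr, age, weight, height, bsa,
    bmi`` (the observation frame joined with subject profiles; see
    :func:`pulsesv.io.attach_subjects`). Returns ``(sv_predicted, applicable)``
    where inapplicable rows hold NaN.
    """
    n = len(frame)
    applicable = np.ones(n, dtype=bool)
    for rule in spec.applicability:
        value = frame[str(rule["var"])].to_numpy(dtype=float)
        if "max" in rule:
            applicable &= value <= float(rule["max"])
        if "min" in rule:
            applicable &= value >= float(rule["min"])
    p = spec.params
    if spec.form == "pressure_linear":
        sv = _eval_pressure_linear(
            p,
            frame["pp"].to_numpy(dtype=float),
            frame["dap"].to_numpy(dtype=float),
            frame["age"].to_numpy(dtype=float),
        )
    elif spec.form == "power_anthro":
        sv = float(p["coef"]) * _anthro_column(frame, str(p["input"])) ** float(p["exponent"])
    elif spec.form == "linear_anthro":
        sv = float(p["slope"]) * _anthro_column(frame, str(p["input"])) + float(p["intercept"])
    elif spec.form == "lu_co":
        hr = frame["hr"].to_numpy(dtype=float)
        co = (
            float(p["a0"])
            + float(p["orphan"])
            - float(p["age_coef"]) * frame["age"].to_numpy(dtype=float)
            + float(p["weight_coef"]) * frame["weight"].to_numpy(dtype=float)
        )
        sv = 1000.0 * co / hr
        applicable &= np.isfinite(hr)
    elif spec.form == "remington_table":
        if remington_table is None:
            raise MissingInputError(
                f"{spec.formula_id} requires a volume-factor table; none supplied"
            )
        sv = (
            remington_table(frame["sap"].to_numpy(dtype=float))
            - remington_table(frame["dap"].to_numpy(dtype=float))
        ) * frame["bsa"].to_numpy(dtype=float)
    else:
        raise ValidationError(f"unknown form {spec.form!r}")
    sv = np.asarray(sv, dtype=float)
    sv = np.where(applicable, sv, np.nan)
    return sv, applicable


def _anthro_column(frame, key: str) -> np.ndarray:
    if key == "height_m":
        return frame["height"].to_numpy(dtype=float)
    if key == "height_cm":
        return frame["height"].to_numpy(dtype=float) * 100.0
    return frame[key].to_numpy(dtype=float)
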