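"""Fuzzy-inference triage of heart-disease risk.

Three vitals drive the preliminary risk call: resting blood pressure
(mm Hg), the resting ECG code (0 normal, 1 ST-T abnormality, 2 definite
ventricular hypertrophy), and the maximum achieved heart rate (bpm).
Blood pressure and heart rate are fuzzified through trapezoidal
low/normal/high membership functions; the ECG code is an ordinal
3-level code, so it maps crisply — code 0 to low risk, 1 to normal,
2 to high.  The rule base is deliberately simple: a patient is HIGH
risk as soon as any variable's high-membership reaches the decision
threshold (default 0.5); otherwise NORMAL if the strongest
normal-membership is at least the strongest low-membership, else LOW.
Ties resolve in the order high > normal > low.

Triage partitions a cohort: high-risk records are routed onward to the
prediction model and each produces exactly one notification event (a
structured log entry standing in for a gateway alert); every record's
state is stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .exceptions import ConfigError, ValidationError
from .ioformats import PatientRecord

__all__ = [
    "FISConfig",
    "FuzzyVariable",
    "HealthRiskState",
    "MembershipFunction",
    "RiskAssessment",
    "TriageResult",
    "assess_risk",
    "default_fis_config",
    "membership",
    "triage",
]

HealthRiskState = Literal["low", "normal", "high"]
STATES: tuple[HealthRiskState, ...] = ("low", "normal", "high")


@dataclass(frozen=True)
class MembershipFunction:
    """Trapezoid (a, b, c, d): 0 outside [a, d], 1 on [b, c], linear between."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ConfigError(f"trapezoid breakpoints must be ordered, got {self}")

    def __call__(self, x: float) -> float:
        return membership(x, self)


def membership(x: float, mf: MembershipFunction) -> float:
    """Piecewise-linear trapezoid evaluation, continuous in x, in [0, 1]."""
    if x < mf.a or x > mf.d:
        return 0.0
    if mf.b <= x <= mf.c:
        return 1.0
    if x < mf.b:  # rising edge; a == b handled above by the plateau branch
        return (x - mf.a) / (mf.b - mf.a)
    return (mf.d - x) / (mf.d - mf.c)


@dataclass(frozen=True)
class FuzzyVariable:
    """A named input with a universe and low/normal/high trapezoids."""

    name: str
    universe: tuple[float, float]
    low: MembershipFunction
    normal: MembershipFunction
    high: MembershipFunction

    def degrees(self, x: float) -> dict[str, float]:
        return {"low": membership(x, self.low), "normal": membership(x, self.normal),
                "high": membership(x, self.high)}

    def clip(self, x: float) -> tuple[float, bool]:
        lo, hi = self.universe
        clipped = min(max(x, lo), hi)
        return clipped, clipped != x


@dataclass(frozen=True)
class FISConfig:
    """Membership breakpoints, decision threshold and strictness.

    The default breakpoints are anchored to the schema ranges and
    conventional clinical bands (hypertension above ~140 mm Hg; a
    maximal heart rate below ~110 bpm is a poor chronotropic response);
    they are configuration, not dogma — override per deployment.
    """

    blood_pressure: FuzzyVariable = field(
        default_factory=lambda: FuzzyVariable(
            "blood_pressure",
            (94.0, 200.0),
            low=MembershipFunction(94, 94, 100, 110),
            normal=MembershipFunction(100, 110, 140, 150),
            high=MembershipFunction(140, 150, 200, 200),
        )
    )
    max_heart_rate: FuzzyVariable = field(
        default_factory=lambda: FuzzyVariable(
            "max_heart_rate",
            (71.0, 202.0),
            low=MembershipFunction(71, 71, 90, 110),
            normal=MembershipFunction(100, 120, 160, 180),
            high=MembershipFunction(160, 180, 202, 202),
        )
    )
    #: Crisp risk label per ECG code: 0 = normal trace -> low risk.
    ecg_map: tuple[HealthRiskState, ...] = ("low", "normal", "high")
    threshold: float = 0.5
    strict: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ConfigError("decision threshold must lie in (0, 1]")
        if len(self.ecg_map) != 3 or any(s not in STATES for s in self.ecg_map):
            raise ConfigError("ecg_map must assign a state to each code 0/1/2")


def default_fis_config() -> FISConfig:
    return FISConfig()


@dataclass(frozen=True)
class RiskAssessment:
    """Per-variable membership degrees and the overall risk state."""

    uid: int
    degrees: dict[str, dict[str, float]]  # variable -> {low, normal, high}
    state: HealthRiskState
    clipped: tuple[str, ...] = ()  # variables whose input left the universe


def _ecg_degrees(ecg: float, config: FISConfig) -> dict[str, float]:
    code = int(ecg)
    if code not in (0, 1, 2):
        if config.strict:
            raise ValidationError(f"ECG code must be 0, 1 or 2, got {ecg!r}")
        code = min(max(code, 0), 2)
    out = {s: 0.0 for s in STATES}
    out[config.ecg_map[code]] = 1.0
    return out


def assess_risk(
    bp: float, ecg: float, hr: float, config: FISConfig | None = None, uid: int = 0
) -> RiskAssessment:
    """Fuzzify the three inputs and resolve the overall risk state.

    Inputs outside a variable's universe are clipped (noted in
    ``clipped``); out-of-range ECG codes raise in strict mode.
    """
    config = config or FISConfig()
    clipped: list[str] = []
    degrees: dict[str, dict[str, float]] = {}
    for var, value in ((config.blood_pressure, bp), (config.max_heart_rate, hr)):
        x, was_clipped = var.clip(value)
        if was_clipped:
            clipped.append(var.name)
        degrees[var.name] = var.degrees(x)
    degrees["ecg"] = _ecg_degrees(ecg, config)

    max_high = max(d["high"] for d in degrees.values())
    max_normal = max(d["normal"] for d in degrees.values())
    max_low = max(d["low"] for d in degrees.values())
    if max_high >= config.threshold:
        state: HealthRiskState = "high"
    elif max_normal >= max_low:
        state = "normal"
    else:
        state = "low"
    return RiskAssessment(uid=uid, degrees=degrees, state=state, clipped=tuple(clipped))


@dataclass(frozen=True)
class TriageEvent:
    """One notification for a high-risk patient (seq keeps log order stable)."""

    seq: int
    uid: int
    state: HealthRiskState
    message: str


@dataclass
class TriageResult:
    """High-risk routing plus the stored state of every record."""

    routed: list[PatientRecord]
    stored: list[tuple[int, HealthRiskState]]
    events: list[TriageEvent]
    assessments: list[RiskAssessment]

    @property
    def routed_uids(self) -> list[int]:
        return [r.uid for r in self.routed]


def triage(records: Sequence[PatientRecord], config: FISConfig | None = None) -> TriageResult:
    """Assess every record; route high-risk ones and log one event each.

    The routed set and the non-high remainder partition the input:
    ``len(routed) + (len(stored) - len(routed)) == len(records)``, and
    record order (hence log order) follows input order deterministically.
    Records missing one of the three vitals cannot be fuzzified and
    raise in strict mode; in lenient mode they are assessed with the
    variable's universe midpoint.
    """
    config = config or FISConfig()
    routed: list[PatientRecord] = []
    stored: list[tuple[int, HealthRiskState]] = []
    events: list[TriageEvent] = []
    assessments: list[RiskAssessment] = []
    for record in records:
        values = {}
        for var, name in (
            (config.blood_pressure, "trestbps"),
            (None, "restecg"),
            (config.max_heart_rate, "thalach"),
        ):
            value = record.get(name)
            if value is None:
                if config.strict:
                    raise ValidationError(f"record uid={record.uid}: {name} missing")
                if var is None:
                    value = 0.0
                else:
                    value = (var.universe[0] + var.universe[1]) / 2.0
            values[name] = value
        assessment = assess_risk(
            values["trestbps"], values["restecg"], values["thalach"], config, uid=record.uid
        )
        assessments.append(assessment)
        stored.append((record.uid, assessment.state))
        if assessment.state == "high":
            routed.append(record)
            events.append(
                TriageEvent(
                    seq=len(events),
                    uid=record.uid,
                    state="high",
                    message=f"high-risk patient uid={record.uid}: notify gateway",
                )
            )
    return TriageResult(routed=routed, stored=stored, events=events, assessments=assessments)
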