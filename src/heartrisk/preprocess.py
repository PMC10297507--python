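"""Vital-stream smoothing and record encoding.

Two jobs live here.  First, a scalar Kalman filter for noisy wearable
vital streams (blood pressure, heart rate, ...): the state model is a
random walk (state transition 1, observation 1), the minimal standard
choice when nothing more is known about the signal's dynamics.  Second,
the :class:`Encoder` that turns a cleaned clinical record into the
numeric input the recurrent network consumes: numerics min-max scaled to
[0, 1] against the schema ranges, categoricals one-hot, emitted as a
13-step sequence (one attribute per time step, schema order) of
fixed-width vectors.  Feeding one attribute per step makes the
recurrence genuinely carry information between attributes; a
``single_step`` mode that presents all features at once is available
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Literal, Sequence

import numpy as np

from .exceptions import ConfigError, FittingError, ValidationError
from .ioformats import ATTRIBUTES, SCHEMA, SCHEMA_BY_NAME, AttributeSchema, PatientRecord

__all__ = [
    "Encoder",
    "KalmanParams",
    "encode",
    "encode_flat",
    "fit_encoder",
    "flat_feature_names",
    "kalman_smooth",
    "schema_encoder",
]

OTHER_LEVEL = "other"


@dataclass(frozen=True)
class KalmanParams:
    """Scalar random-walk filter parameters.

    ``process_variance`` (Q) is how much the true level is allowed to
    drift per step; ``measurement_variance`` (R) is the sensor noise
    power.  Small Q/R ratios smooth hard, large ratios track fast.
    """

    process_variance: float = 1e-3
    measurement_variance: float = 1.0
    initial_estimate: float | None = None  # None: first observation
    initial_variance: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.process_variance) or self.process_variance < 0:
            raise ConfigError("process variance Q must be finite and >= 0")
        if not np.isfinite(self.measurement_variance) or self.measurement_variance <= 0:
            raise ConfigError("measurement variance R must be finite and > 0")
        if self.initial_variance <= 0:
            raise ConfigError("initial variance must be > 0")


def kalman_smooth(
    series: Sequence[float], params: KalmanParams, return_variance: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Per-step posterior estimates of a scalar random-walk Kalman filter.

    Predict: x̂⁻ = x̂, P⁻ = P + Q.  Update with observation z:
    K = P⁻ / (P⁻ + R), x̂ = x̂⁻ + K (z − x̂⁻), P = (1 − K) P⁻.

    With ``return_variance`` the per-step posterior variance P is
    returned as well (always positive; non-increasing when Q = 0).
    """
    z = np.asarray(series, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise ValidationError("series must be a nonempty 1-D sequence")
    estimate = z[0] if params.initial_estimate is None else params.initial_estimate
    variance = params.initial_variance
    q, r = params.process_variance, params.measurement_variance
    out = np.empty_like(z)
    variances = np.empty_like(z)
    for t, obs in enumerate(z):
        variance = variance + q
        gain = variance / (variance + r)
        estimate = estimate + gain * (obs - estimate)
        variance = (1.0 - gain) * variance
        out[t] = estimate
        variances[t] = variance
    if return_variance:
        return out, variances
    return out


def default_measurement_variance(series: Sequence[float]) -> float:
    """R defaulted to the series' sample variance (floored away from 0)."""
    z = np.asarray(series, dtype=float)
    var = float(np.var(z, ddof=1)) if z.size > 1 else 1.0
    return max(var, 1e-8)


@dataclass
class Encoder:
    """Fitted per-attribute scaling, one-hot maps and imputation values.

    ``numeric_bounds`` maps a numeric attribute to its (lo, hi) scaling
    anchors — the schema ranges by default, so encodings are stable
    across folds.  ``categorical_levels`` maps a categorical attribute
    to its canonical level order; unknown levels go to a trailing
    "other" slot in lenient mode and raise in strict mode.
    """

    numeric_bounds: dict[str, tuple[float, float]]
    categorical_levels: dict[str, tuple[int, ...]]
    impute: dict[str, float]
    sequence_mode: Literal["per_attribute", "single_step"] = "per_attribute"
    strict: bool = False

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.numeric_bounds.items():
            if not lo < hi:
                raise ConfigError(f"{name}: scaling bounds must satisfy lo < hi")
        covered = set(self.numeric_bounds) | set(self.categorical_levels)
        missing = set(ATTRIBUTES) - covered
        if missing:
            raise ConfigError(f"encoder does not cover attributes: {sorted(missing)}")

    # -- geometry ---------------------------------------------------------
    @property
    def step_width(self) -> int:
        """Fixed width of one sequence step (widest one-hot incl. 'other')."""
        return max(len(levels) + 1 for levels in self.categorical_levels.values())

    @property
    def flat_dim(self) -> int:
        """Width of the canonical flat encoding (no 'other' slots)."""
        return sum(
            1 if a in self.numeric_bounds else len(self.categorical_levels[a])
            for a in ATTRIBUTES
        )

    @property
    def sequence_shape(self) -> tuple[int, int]:
        if self.sequence_mode == "per_attribute":
            return (len(ATTRIBUTES), self.step_width)
        return (1, self.flat_dim)

    # -- encoding ---------------------------------------------------------
    def _numeric_scaled(self, name: str, value: float) -> float:
        lo, hi = self.numeric_bounds[name]
        return (float(value) - lo) / (hi - lo)

    def _onehot(self, name: str, value: float, with_other: bool) -> np.ndarray:
        levels = self.categorical_levels[name]
        width = len(levels) + (1 if with_other else 0)
        vec = np.zeros(width)
        try:
            vec[levels.index(int(value))] = 1.0
        except ValueError:
            if self.strict:
                raise ValidationError(f"{name}: unknown level {value!r} in strict mode") from None
            if with_other:
                vec[-1] = 1.0
        return vec

    def _value(self, record: PatientRecord, name: str) -> float:
        value = record.get(name)
        if value is None:
            value = self.impute.get(name)
            if value is None:
                raise ValidationError(f"{name}: missing with no imputation value fitted")
        return value

    def encode_flat(self, record: PatientRecord) -> np.ndarray:
        """Canonical flat vector: scaled numerics + canonical one-hots."""
        parts = []
        for name in ATTRIBUTES:
            value = self._value(record, name)
            if name in self.numeric_bounds:
                parts.append(np.array([self._numeric_scaled(name, value)]))
            else:
                parts.append(self._onehot(name, value, with_other=False))
        return np.concatenate(parts)

    def encode(self, record: PatientRecord) -> np.ndarray:
        """Sequence input for the network, shape :attr:`sequence_shape`."""
        if self.sequence_mode == "single_step":
            return self.encode_flat(record)[None, :]
        width = self.step_width
        steps = np.zeros((len(ATTRIBUTES), width))
        for t, name in enumerate(ATTRIBUTES):
            value = self._value(record, name)
            if name in self.numeric_bounds:
                steps[t, 0] = self._numeric_scaled(name, value)
            else:
                onehot = self._onehot(name, value, with_other=True)
                steps[t, : onehot.size] = onehot
        return steps

    def encode_batch(self, records: Sequence[PatientRecord]) -> np.ndarray:
        return np.stack([self.encode(r) for r in records])

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "numeric_bounds": {k: list(v) for k, v in self.numeric_bounds.items()},
            "categorical_levels": {k: list(v) for k, v in self.categorical_levels.items()},
            "impute": dict(self.impute),
            "sequence_mode": self.sequence_mode,
            "strict": self.strict,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Encoder":
        return cls(
            numeric_bounds={k: (float(v[0]), float(v[1])) for k, v in data["numeric_bounds"].items()},
            categorical_levels={
                k: tuple(int(x) for x in v) for k, v in data["categorical_levels"].items()
            },
            impute={k: float(v) for k, v in data["impute"].items()},
            sequence_mode=data.get("sequence_mode", "per_attribute"),
            strict=bool(data.get("strict", False)),
        )


def flat_feature_names(schema: Sequence[AttributeSchema] = SCHEMA) -> list[str]:
    """Names of the canonical flat features, e.g. ``cp=2`` for one-hot slots."""
    names: list[str] = []
    for attr in schema:
        if attr.kind == "numeric":
            names.append(attr.name)
        else:
            names.extend(f"{attr.name}={level}" for level in attr.levels)
    return names


def schema_encoder(
    sequence_mode: Literal["per_attribute", "single_step"] = "per_attribute",
) -> Encoder:
    """Encoder anchored purely to the schema ranges (no data needed)."""
    numeric = {s.name: (float(s.lo), float(s.hi)) for s in SCHEMA if s.kind == "numeric"}
    categorical = {s.name: s.levels for s in SCHEMA if s.kind == "categorical"}
    impute = {s.name: (s.lo + s.hi) / 2 if s.kind == "numeric" else float(s.levels[0]) for s in SCHEMA}
    return Encoder(numeric, categorical, impute, sequence_mode=sequence_mode)


def fit_encoder(
    records: Sequence[PatientRecord],
    schema: Sequence[AttributeSchema] = SCHEMA,
    sequence_mode: Literal["per_attribute", "single_step"] = "per_attribute",
    strict: bool = False,
) -> Encoder:
    """Fit scaling bounds and imputation values from training records only.

    Numeric bounds default to the schema ranges and are widened (never
    narrowed) to the data extremes so lenient out-of-range values still
    land in [0, 1].  Imputation is the median (numeric) / mode
    (categorical) of the values present in ``records`` — pass the
    training fold only, so no test-fold statistic leaks in.
    """
    if not records:
        raise FittingError("cannot fit an encoder from zero records")
    numeric: dict[str, tuple[float, float]] = {}
    categorical: dict[str, tuple[int, ...]] = {}
    impute: dict[str, float] = {}
    for attr in schema:
        present = [r.get(attr.name) for r in records if r.get(attr.name) is not None]
        if not present:
            raise FittingError(f"{attr.name}: missing in every record, cannot fit")
        if attr.kind == "numeric":
            lo = min(float(attr.lo), min(present)) if not strict else float(attr.lo)
            hi = max(float(attr.hi), max(present)) if not strict else float(attr.hi)
            numeric[attr.name] = (lo, hi)
            impute[attr.name] = float(median(present))
        else:
            categorical[attr.name] = attr.levels
            counts: dict[int, int] = {}
            for v in present:
                counts[int(v)] = counts.get(int(v), 0) + 1
            # mode; ties broken by smallest level for determinism
            impute[attr.name] = float(min(sorted(counts), key=lambda k: (-counts[k], k)))
    return Encoder(numeric, categorical, impute, sequence_mode=sequence_mode, strict=strict)


# Convenience functional forms mirroring the module surface.
def encode(record: PatientRecord, encoder: Encoder) -> np.ndarray:
    return encoder.encode(record)


def encode_flat(record: PatientRecord, encoder: Encoder) -> np.ndarray:
    return encoder.encode_flat(record)
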