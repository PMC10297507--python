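"""Seeded synthetic cohorts, vital streams, and defect injection.

Real heart-disease tables of this shape exist but are small (a few
hundred rows); published work on this pipeline scaled them up with a
commercial mock-data generator whose distributions and label mechanism
are unpublished.  This module is the package's stand-in: attribute
values are drawn uniformly within the schema ranges (the neutral choice
when the true marginals are unknown), and — unlike a mock-data tool —
labels carry a *controllable* signal so that classifier recovery is
verifiable.  The label model is a latent-variable logistic regression
on the canonical flat encoding:

    y = 1  iff  w·x + b + s·ε > 0,   ε ~ standard logistic

so ``noise_scale`` s = 1 gives P(y=1) = σ(w·x + b) exactly, and s = 0
makes the label a deterministic threshold function of the score.

Everything here is a pure function of its configuration: the same seed
reproduces the same cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import ConfigError
from .ioformats import ATTRIBUTES, SCHEMA, PatientRecord, write_records
from .preprocess import flat_feature_names, schema_encoder

__all__ = [
    "Cohort",
    "CohortConfig",
    "DefectRecord",
    "SignalSpec",
    "VitalStreamSpec",
    "corrupt_records",
    "default_signal",
    "generate_cohort",
    "generate_vital_stream",
    "separable_signal",
    "write_vital_stream",
]

FLAT_FEATURES: tuple[str, ...] = tuple(flat_feature_names())


@dataclass(frozen=True)
class CohortConfig:
    """Size, seed, class balance, and defect rates of a synthetic cohort."""

    n_records: int
    seed: int = 0
    positive_fraction: float | None = 0.5
    missing_rate: float = 0.0
    duplicate_rate: float = 0.0
    outlier_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ConfigError("n_records must be >= 1")
        if self.positive_fraction is not None and not 0.0 <= self.positive_fraction <= 1.0:
            raise ConfigError("positive_fraction must lie in [0, 1]")
        for name in ("missing_rate", "duplicate_rate", "outlier_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ConfigError(f"{name} must lie in [0, 1)")


@dataclass(frozen=True)
class SignalSpec:
    """Latent logistic label model on the canonical flat features."""

    coefficients: tuple[float, ...]
    intercept: float = 0.0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(arr)) or not np.isfinite(self.intercept):
            raise ConfigError("signal coefficients and intercept must be finite")
        if self.noise_scale < 0:
            raise ConfigError("noise_scale must be >= 0")


@dataclass(frozen=True)
class VitalStreamSpec:
    """A drifting vital level observed through additive Gaussian noise."""

    length: int
    true_level: float = 120.0
    drift_per_step: float = 0.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ConfigError("stream length must be >= 2")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not np.isfinite(self.true_level) or not np.isfinite(self.drift_per_step):
            raise ConfigError("true_level and drift_per_step must be finite")


@dataclass(frozen=True)
class DefectRecord:
    """One injected defect, for cross-checking downstream cleaning."""

    kind: str  # "duplicate" | "missing" | "outlier"
    uid: int
    attribute: str | None = None
    detail: str = ""


@dataclass
class Cohort:
    """Generated records plus the resolved label signal behind them."""

    records: list[PatientRecord]
    labels: np.ndarray
    signal: SignalSpec  # with the calibrated intercept actually used
    features: np.ndarray  # canonical flat encoding, shape (n, flat_dim)
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.records)


def default_signal(noise_scale: float = 1.0) -> SignalSpec:
    """A clinically-plausible multi-attribute signal.

    Risk rises with age, resting blood pressure, cholesterol, ST
    depression, fluoroscopy vessel count, asymptomatic chest pain,
    exercise-induced angina and defect thal codes, and falls with a
    higher achieved heart rate — directions consistent with how these
    attributes behave in real cohorts.  Magnitudes give a moderately
    hard, learnable problem at ``noise_scale`` 1.
    """
    weights = {
        "age": 1.5,
        "trestbps": 1.5,
        "chol": 1.0,
        "thalach": -2.5,
        "oldpeak": 2.0,
        "ca": 2.0,
        "sex=1": 0.5,
        "cp=4": 1.5,
        "exang=1": 1.0,
        "slope=2": 0.5,
        "thal=6": 1.0,
        "thal=7": 1.5,
    }
    coeffs = tuple(weights.get(name, 0.0) for name in FLAT_FEATURES)
    return SignalSpec(coefficients=coeffs, noise_scale=noise_scale)


def separable_signal(attribute: str = "thalach", weight: float = -50.0) -> SignalSpec:
    """A strong single-attribute signal with no label noise.

    With ``noise_scale`` 0 the label is a deterministic threshold
    function of the one weighted feature — the ground truth used by the
    classifier-recovery tests.
    """
    if attribute not in FLAT_FEATURES:
        raise ConfigError(f"unknown flat feature {attribute!r}")
    coeffs = tuple(weight if name == attribute else 0.0 for name in FLAT_FEATURES)
    return SignalSpec(coefficients=coeffs, noise_scale=0.0)


def _draw_attributes(n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Uniform draws within the schema ranges / over the schema levels."""
    cols: dict[str, np.ndarray] = {}
    for attr in SCHEMA:
        if attr.kind == "categorical":
            cols[attr.name] = rng.choice(np.array(attr.levels), size=n).astype(float)
        elif attr.name == "oldpeak":
            cols[attr.name] = np.round(rng.uniform(attr.lo, attr.hi, size=n), 1)
        else:  # integer-valued numerics (age, trestbps, chol, thalach, ca)
            cols[attr.name] = rng.integers(int(attr.lo), int(attr.hi) + 1, size=n).astype(float)
    return cols


def _flat_matrix(cols: dict[str, np.ndarray], n: int) -> np.ndarray:
    """Vectorised canonical flat encoding; matches Encoder.encode_flat."""
    parts: list[np.ndarray] = []
    for attr in SCHEMA:
        values = cols[attr.name]
        if attr.kind == "numeric":
            parts.append(((values - attr.lo) / (attr.hi - attr.lo))[:, None])
        else:
            onehot = np.zeros((n, len(attr.levels)))
            for j, level in enumerate(attr.levels):
                onehot[:, j] = values == level
            parts.append(onehot)
    return np.concatenate(parts, axis=1)


def generate_cohort(config: CohortConfig, signal: SignalSpec | None = None) -> Cohort:
    """Generate ``config.n_records`` schema-valid labelled records.

    Attributes are uniform within their schema ranges; the label comes
    from the latent logistic model in ``signal`` (:func:`default_signal`
    when omitted).  When ``config.positive_fraction`` is set, the
    intercept is re-calibrated to the empirical quantile of the latent
    scores so the cohort hits that class balance; the calibrated
    intercept is reported back in ``Cohort.signal``.

    Corruption (duplicates / missing / outliers) is *not* applied here —
    see :func:`corrupt_records` — so every returned record satisfies the
    schema and labels are never computed from corrupted values.
    """
    signal = signal if signal is not None else default_signal()
    expected = len(FLAT_FEATURES)
    if len(signal.coefficients) != expected:
        raise ConfigError(
            f"signal has {len(signal.coefficients)} coefficients, "
            f"encoded feature dimension is {expected}"
        )
    n = config.n_records
    rng = np.random.default_rng(config.seed)
    cols = _draw_attributes(n, rng)
    features = _flat_matrix(cols, n)
    score = features @ np.asarray(signal.coefficients)
    noise = signal.noise_scale * rng.logistic(0.0, 1.0, size=n)
    latent = score + noise
    if config.positive_fraction is None:
        intercept = signal.intercept
    elif config.positive_fraction == 0.0:
        intercept = -np.max(latent) - 1.0
    elif config.positive_fraction == 1.0:
        intercept = -np.min(latent) + 1.0
    else:
        intercept = -float(np.quantile(latent, 1.0 - config.positive_fraction))
    labels = (latent + intercept > 0).astype(int)
    records = [
        PatientRecord(
            **{name: float(cols[name][i]) for name in ATTRIBUTES},
            raw_target=int(labels[i]),
            uid=i + 1,
        )
        for i in range(n)
    ]
    resolved = replace(signal, intercept=float(intercept))
    return Cohort(records=records, labels=labels, signal=resolved, features=features, config=config)


def generate_vital_stream(spec: VitalStreamSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (noisy, truth) series of length ``spec.length``.

    Truth is a linear drift from ``true_level``; the noisy series adds
    i.i.d. Gaussian noise with standard deviation ``noise_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.length, dtype=float)
    truth = spec.true_level + spec.drift_per_step * t
    noisy = truth + rng.normal(0.0, spec.noise_sd, size=spec.length) if spec.noise_sd > 0 else truth.copy()
    return noisy, truth


def write_vital_stream(series: Sequence[float], path: str | Path) -> Path:
    """Write a stream as two comma-separated columns (time index, value)."""
    path = Path(path)
    lines = ["t,value"] + [f"{t},{float(v)!r}" for t, v in enumerate(np.asarray(series, dtype=float))]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_vital_stream(path: str | Path) -> np.ndarray:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    values = [float(line.split(",")[1]) for line in lines[1:] if line.strip()]
    return np.asarray(values)


NUMERIC_ATTRS = tuple(s.name for s in SCHEMA if s.kind == "numeric")


def corrupt_records(
    records: Sequence[PatientRecord], config: CohortConfig
) -> tuple[list[PatientRecord], list[DefectRecord]]:
    """Inject missing cells, out-of-range outliers and exact duplicates.

    Defect counts are binomial draws from the seeded RNG: missing cells
    ~ Binomial(n·13, missing_rate) over attribute cells, outliers ~
    Binomial(n, outlier_rate) records, duplicates ~ Binomial(n,
    duplicate_rate) rows appended at the end with fresh uids.  Missing
    and outlier damage is applied *before* duplication, so each injected
    duplicate is an exact 14-field copy of its (possibly damaged) source
    and cleaning can be cross-checked against the returned manifest.
    Labels are never touched.
    """
    rng = np.random.default_rng([config.seed, 0xC0])
    out = [replace(r) for r in records]
    n = len(out)
    manifest: list[DefectRecord] = []
    if n == 0:
        return out, manifest

    n_missing = rng.binomial(n * len(ATTRIBUTES), config.missing_rate)
    if n_missing:
        cells = rng.choice(n * len(ATTRIBUTES), size=n_missing, replace=False)
        for cell in sorted(cells):
            i, j = divmod(int(cell), len(ATTRIBUTES))
            name = ATTRIBUTES[j]
            setattr(out[i], name, None)
            manifest.append(DefectRecord("missing", out[i].uid, name))

    n_outliers = rng.binomial(n, config.outlier_rate)
    if n_outliers:
        rows = rng.choice(n, size=n_outliers, replace=False)
        for i in sorted(rows):
            name = NUMERIC_ATTRS[int(rng.integers(len(NUMERIC_ATTRS)))]
            schema = next(s for s in SCHEMA if s.name == name)
            bad = schema.hi * 2.0 + 100.0
            setattr(out[int(i)], name, bad)
            manifest.append(DefectRecord("outlier", out[int(i)].uid, name, detail=f"set to {bad}"))

    n_dup = rng.binomial(n, config.duplicate_rate)
    if n_dup:
        sources = rng.choice(n, size=n_dup, replace=False)
        next_uid = max(r.uid for r in out) + 1
        for k, i in enumerate(sorted(sources)):
            dup = replace(out[int(i)], uid=next_uid + k)
            out.append(dup)
            manifest.append(DefectRecord("duplicate", dup.uid, detail=f"copy of uid {out[int(i)].uid}"))

    return out, manifest


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort in the UCI comma-separated dialect."""
    return write_records(cohort.records, path)
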