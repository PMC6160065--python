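"""The 14 3CCD imaging variables and the 17-predictor model input.

Seven raw indices are computed from ROI channel means: R, G, B, R-B, R-G,
(R-B)/G and (R-B)/(R^2+B^2). The last two are brightness normalizations:
(R-B)/G cancels a uniform per-image gain exactly, while (R-B)/(R^2+B^2)
magnifies relative differences when overall intensity drops.

Two normalization stages precede and follow the index computation:

1. hospital (cohort) normalization — each image's channel means are divided
   by its hospital's average R, G, B, removing camera-gain and lighting
   differences between operating rooms; the 7 raw indices are computed from
   these hospital-normalized channels;
2. variable normalization — each raw index is divided by the pooled mean of
   that index over the fit population, giving the 7 "normalized" variables.
   The two difference indices are structurally mean-free after stage 1 (the
   channel means cancel exactly), so their divisor falls back to the pooled
   mean magnitude; every normalized variable then has a well-defined O(1)
   scale, and downstream rank tests and autoscaled models are unaffected by
   the choice of (positive) divisor.

The model input appends wound surface area (cm^2), days post-injury and
patient age to the 14 imaging variables, in a fixed canonical order.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .images import ImageRecord

__all__ = [
    "RAW_INDEX_NAMES",
    "NORM_INDEX_NAMES",
    "MODEL_PREDICTORS",
    "ChannelMeans",
    "FeatureVector",
    "NormalizationReference",
    "UnknownCohortError",
    "NormalizationError",
    "IncompleteRecordError",
    "compute_raw_indices",
    "fit_normalizer",
    "normalize_channels",
    "normalize_features",
    "assemble_model_input",
]

RAW_INDEX_NAMES = (
    "r",
    "g",
    "b",
    "r_minus_b",
    "r_minus_g",
    "rb_over_g",
    "rb_over_r2b2",
)
NORM_INDEX_NAMES = tuple(f"{n}_norm" for n in RAW_INDEX_NAMES)
COVARIATE_NAMES = ("wound_area_cm2", "days_post_injury", "age")

#: canonical predictor order of the 17-variable model input
MODEL_PREDICTORS = RAW_INDEX_NAMES + NORM_INDEX_NAMES + COVARIATE_NAMES


class UnknownCohortError(KeyError):
    """A hospital label with no entry in the normalization reference."""


class NormalizationError(ValueError):
    """A variable's overall mean is zero or non-finite."""


class IncompleteRecordError(ValueError):
    """A record is missing clinical covariates required by the model."""


@dataclass(frozen=True)
class ChannelMeans:
    r: float
    g: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=float)


@dataclass(frozen=True)
class FeatureVector:
    """The 7 raw and 7 normalized imaging variables of one image."""

    raw: dict
    normalized: dict

    def __post_init__(self) -> None:
        if tuple(self.raw) != RAW_INDEX_NAMES or tuple(self.normalized) != NORM_INDEX_NAMES:
            raise ValueError("feature dictionaries must use the canonical index names")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.raw[n] for n in RAW_INDEX_NAMES]
            + [self.normalized[n] for n in NORM_INDEX_NAMES],
            dtype=float,
        )


def compute_raw_indices(m: ChannelMeans) -> dict:
    """The 7 raw indices from one image's channel means.

    A zero denominator yields NaN for that index (the record is retained;
    the value is treated as missing downstream), never +/-inf.
    """
    r, g, b = float(m.r), float(m.g), float(m.b)
    if not all(math.isfinite(v) for v in (r, g, b)):
        raise ValueError("channel means must be finite")
    out = {
        "r": r,
        "g": g,
        "b": b,
        "r_minus_b": r - b,
        "r_minus_g": r - g,
        "rb_over_g": (r - b) / g if g != 0.0 else math.nan,
        "rb_over_r2b2": (r - b) / (r * r + b * b) if (r * r + b * b) != 0.0 else math.nan,
    }
    return out


@dataclass(frozen=True)
class NormalizationReference:
    """Per-hospital channel means plus pooled per-variable means.

    Fit on a reference population (all data, or the training split only when
    leakage-free evaluation is wanted) and then applied record by record.
    """

    hospital_channel_means: dict  # hospital -> (r, g, b)
    variable_means: dict          # raw index name -> pooled mean
    fit_population: str = ""

    def __post_init__(self) -> None:
        for h, ch in self.hospital_channel_means.items():
            arr = np.asarray(ch, dtype=float)
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"hospital {h!r}: channel means must be finite and > 0")
        for name in RAW_INDEX_NAMES:
            if name not in self.variable_means:
                raise ValueError(f"missing overall mean for variable {name!r}")

    def to_json(self, path) -> None:
        payload = {
            "hospital_channel_means": {
                h: list(map(float, ch)) for h, ch in self.hospital_channel_means.items()
            },
            "variable_means": {k: float(v) for k, v in self.variable_means.items()},
            "fit_population": self.fit_population,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "NormalizationReference":
        d = json.loads(Path(path).read_text())
        return cls(
            hospital_channel_means={h: tuple(v) for h, v in d["hospital_channel_means"].items()},
            variable_means=d["variable_means"],
            fit_population=d.get("fit_population", ""),
        )


def fit_normalizer(records, fit_population: str = "") -> NormalizationReference:
    """Fit hospital channel means and pooled variable means.

    ``records`` is an iterable of ``(hospital, ChannelMeans)`` (or
    ``(hospital, (r, g, b))``). Hospital channel means are simple means over
    that hospital's images; variable means are pooled over all records after
    hospital channel normalization, ignoring missing (NaN) index values.
    """
    by_hospital: dict[str, list[np.ndarray]] = {}
    parsed: list[tuple[str, np.ndarray]] = []
    for hospital, ch in records:
        arr = ch.as_array() if isinstance(ch, ChannelMeans) else np.asarray(ch, dtype=float)
        by_hospital.setdefault(hospital, []).append(arr)
        parsed.append((hospital, arr))
    if not parsed:
        raise ValueError("cannot fit a normalizer on zero records")
    hospital_means = {h: tuple(np.mean(v, axis=0)) for h, v in by_hospital.items()}

    var_values: dict[str, list[float]] = {n: [] for n in RAW_INDEX_NAMES}
    for hospital, arr in parsed:
        scaled = arr / np.asarray(hospital_means[hospital])
        raw = compute_raw_indices(ChannelMeans(*scaled))
        for n, v in raw.items():
            if math.isfinite(v):
                var_values[n].append(v)
    variable_means = {}
    for n, vals in var_values.items():
        if not vals:
            raise NormalizationError(f"no finite values to average for variable {n!r}")
        mean = float(np.mean(vals))
        mean_abs = float(np.mean(np.abs(vals)))
        # The difference indices are structurally mean-free after hospital
        # channel normalization (the channel means cancel exactly), so their
        # pooled mean is zero up to rounding and cannot serve as a divisor;
        # fall back to the pooled mean magnitude, which is scale-appropriate.
        if mean_abs > 0 and abs(mean) < 1e-6 * mean_abs:
            mean = mean_abs
        variable_means[n] = mean
    return NormalizationReference(hospital_means, variable_means, fit_population)


def normalize_channels(hospital: str, m: ChannelMeans, ref: NormalizationReference) -> ChannelMeans:
    """Divide channel means by the hospital's reference channel means."""
    if hospital not in ref.hospital_channel_means:
        raise UnknownCohortError(
            f"hospital {hospital!r} has no entry in the normalization reference"
        )
    scaled = m.as_array() / np.asarray(ref.hospital_channel_means[hospital])
    return ChannelMeans(*scaled)


def normalize_features(raw: dict, ref: NormalizationReference) -> FeatureVector:
    """Divide each raw index by its pooled overall mean (14 values total)."""
    normalized = {}
    for n in RAW_INDEX_NAMES:
        vbar = ref.variable_means[n]
        if not math.isfinite(vbar) or vbar == 0.0:
            raise NormalizationError(f"overall mean of variable {n!r} is zero or non-finite")
        normalized[f"{n}_norm"] = raw[n] / vbar
    return FeatureVector(raw={n: raw[n] for n in RAW_INDEX_NAMES}, normalized=normalized)


def extract_features(
    hospital: str, m: ChannelMeans, ref: NormalizationReference
) -> FeatureVector:
    """Hospital-normalize channels, compute raw indices, variable-normalize."""
    scaled = normalize_channels(hospital, m, ref)
    return normalize_features(compute_raw_indices(scaled), ref)


def assemble_model_input(fv: FeatureVector, rec: ImageRecord) -> np.ndarray:
    """The 17-predictor vector in canonical order:
    7 raw indices, 7 normalized indices, wound area, days post-injury, age."""
    missing = [
        name
        for name in COVARIATE_NAMES
        if getattr(rec, name) is None or not math.isfinite(float(getattr(rec, name)))
    ]
    if missing:
        raise IncompleteRecordError(
            f"record {rec.image_id!r} is missing covariates: {', '.join(missing)}"
        )
    covs = np.array([float(getattr(rec, name)) for name in COVARIATE_NAMES])
    return np.concatenate([fv.as_array(), covs])
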