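"""Synthetic wound cohorts: photographs, ROI masks, and clinical metadata.

The generator is a first-class, testable model of the data the analysis
assumes, not a fixture dump. Wound-bed color follows a single-layer
Beer-Lambert reflectance model driven by tissue oxygen saturation (StO2):
each channel's intensity is

    I_c = gain_c * L_c * exp(-(sto2*eps_HbO2(c) + (1-sto2)*eps_Hb(c))
                             * c_Hb * path) + noise

where eps are effective hemoglobin extinction coefficients at the camera's
R/G/B band centers (~610, 540, 460 nm), L_c is the illumination weight and
gain_c a per-hospital camera gain. Deoxyhemoglobin absorbs more than
oxyhemoglobin in the red band, so R (and R-B) rises with StO2. A broadband
absorber representing devitalized tissue scales with (1 - StO2), darkening
every channel of failing wounds — the pattern the brightness-sensitive
index (R-B)/(R^2+B^2) reacts to.

Cohorts are sampled hierarchically (patients -> wounds -> debridements) with
two hospitals of different camera gains, wound-level outcomes at a
configurable dehiscence proportion, StO2 trajectories drifting across
debridements, clinical covariates, and optional glare/blur/blood artifacts
for quality-control testing.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import RGBImage, ROIMask, ImageRecord

__all__ = [
    "OpticalParams",
    "HospitalSpec",
    "ClassSpec",
    "CohortConfig",
    "SyntheticObservation",
    "SyntheticCohort",
    "render_wound_image",
    "sample_cohort",
    "inject_artifacts",
    "default_config",
    "null_config",
    "delayed_confound_config",
]


@dataclass(frozen=True)
class OpticalParams:
    """Effective optics of the wound-bed reflectance model.

    Extinction coefficients are molar extinction values at the band centers
    scaled by 1e-4 (so that with c_hb*path of order 0.1 the exponents stay in
    a photographically sensible range); only their ordering — deoxy > oxy in
    the red band — is contractual, not spectroscopic accuracy.
    """

    wavelengths_nm: tuple = (610.0, 540.0, 460.0)
    eps_oxy: tuple = (0.10, 5.00, 2.00)    # HbO2, per channel (R, G, B)
    eps_deoxy: tuple = (0.30, 5.30, 2.30)  # Hb
    path_length: float = 0.25
    hb_conc_scale: float = 1.0
    #: broadband absorbance of devitalized tissue, scaled by (1 - sto2):
    #: poorly oxygenated beds are darker in every channel, which is what the
    #: brightness-sensitive index (R-B)/(R^2+B^2) responds to
    devitalized_absorbance: float = 2.2
    illumination: tuple = (0.80, 0.92, 0.88)

    def __post_init__(self) -> None:
        if min(self.eps_oxy) <= 0 or min(self.eps_deoxy) <= 0:
            raise ValueError("extinction coefficients must be positive")
        if self.eps_deoxy[0] <= self.eps_oxy[0]:
            raise ValueError(
                "deoxyhemoglobin must absorb more than oxyhemoglobin in the red "
                "band (this ordering drives the R-B vs oxygenation direction)"
            )

    def wound_intensity(self, sto2: float, gain=(1.0, 1.0, 1.0)) -> np.ndarray:
        """Noise-free channel intensities of wound-bed tissue at one StO2."""
        eo = np.asarray(self.eps_oxy)
        ed = np.asarray(self.eps_deoxy)
        mu = (sto2 * eo + (1.0 - sto2) * ed) * self.hb_conc_scale
        mu = mu + self.devitalized_absorbance * (1.0 - sto2)
        refl = np.asarray(self.illumination) * np.exp(-mu * self.path_length)
        return np.asarray(gain) * refl


@dataclass(frozen=True)
class HospitalSpec:
    name: str
    gain: tuple = (1.0, 1.0, 1.0)
    weight: float = 1.0  # sampling weight for patient assignment


@dataclass(frozen=True)
class ClassSpec:
    """Per-outcome StO2 distribution and its debridement-to-debridement drift."""

    sto2_mean: float
    sto2_sd: float
    sto2_drift: float  # added per debridement index step


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the structure of a two-hospital traumatic-wound study:
    ~20% of wounds dehisce, delayed-healing wounds close after more than 21
    days post-injury, several debridements are photographed per wound, and
    the two hospitals differ in camera gain.
    """

    n_patients: int = 30
    wounds_per_patient_mean: float = 1.8
    debridements_per_wound_mean: float = 5.5
    max_wounds_per_patient: int = 4
    max_debridements: int = 10
    class_proportions: dict = field(
        default_factory=lambda: {"healed": 0.55, "delayed": 0.25, "dehisced": 0.20}
    )
    class_specs: dict = field(
        default_factory=lambda: {
            "healed": ClassSpec(0.72, 0.06, +0.015),
            "delayed": ClassSpec(0.58, 0.06, +0.006),
            "dehisced": ClassSpec(0.45, 0.06, -0.015),
        }
    )
    hospitals: tuple = (
        HospitalSpec("EmoryGrady", gain=(1.0, 1.0, 1.0), weight=0.7),
        HospitalSpec("WRNMMC", gain=(0.82, 0.88, 0.78), weight=0.3),
    )
    #: closure day ranges (days post-injury) per class; delayed must exceed 21
    closure_days: dict = field(
        default_factory=lambda: {
            "healed": (10, 21),
            "delayed": (25, 45),
            "dehisced": (10, 24),
        }
    )
    wound_area_mean_cm2: float = 230.0
    wound_area_sd_cm2: float = 120.0
    age_mean: float = 34.0
    age_sd: float = 12.0
    artifact_rates: dict = field(
        default_factory=lambda: {"glare": 0.02, "blur": 0.02, "blood": 0.02}
    )
    artifact_severity: float = 0.6
    image_size: tuple = (128, 128)
    noise_sd: float = 0.012
    optics: OpticalParams = field(default_factory=OpticalParams)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("class proportions must sum to 1")
        for k, v in self.artifact_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"artifact rate {k} must lie in [0, 1]")
        if not self.closure_days["delayed"][0] > 21:
            raise ValueError("delayed-healing closure must occur after day 21")


@dataclass(frozen=True)
class SyntheticObservation:
    image: RGBImage
    roi: ROIMask
    record: ImageRecord
    true_sto2: float
    artifact: str = "none"


@dataclass(frozen=True)
class SyntheticCohort:
    observations: list
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.observations)

    def metadata(self) -> pd.DataFrame:
        rows = []
        for obs in self.observations:
            r = obs.record
            rows.append(
                {
                    "image_id": r.image_id,
                    "patient_id": r.patient_id,
                    "wound_id": r.wound_id,
                    "debridement_index": r.debridement_index,
                    "hospital": r.hospital,
                    "wound_area_cm2": r.wound_area_cm2,
                    "days_post_injury": r.days_post_injury,
                    "age": r.age,
                    "outcome": r.outcome,
                    "true_sto2": obs.true_sto2,
                    "artifact": obs.artifact,
                }
            )
        return pd.DataFrame(rows)


def _child_seed(seed: int, *parts) -> int:
    """Stable per-entity seed below 2^31, derived by hashing identifiers."""
    h = hashlib.sha256(("/".join(map(str, (seed,) + parts))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def render_wound_image(
    sto2: float,
    optics: OpticalParams | None = None,
    gain=(1.0, 1.0, 1.0),
    noise_sd: float = 0.012,
    seed: int = 0,
    size: tuple = (128, 128),
) -> tuple[RGBImage, ROIMask]:
    """Render one wound photograph and its elliptical wound-bed ROI.

    The wound bed follows the Beer-Lambert model at the given StO2 with a
    smooth multiplicative texture; the background is textured skin tone.
    Per-pixel Gaussian noise (sd ``noise_sd``) is added after the gain and
    the result clipped to [0, 1]. Deterministic given the seed.
    """
    if not 0.0 <= sto2 <= 1.0:
        raise ValueError("sto2 must lie in [0, 1]")
    if min(gain) <= 0:
        raise ValueError("gains must be positive")
    optics = optics or OpticalParams()
    rng = np.random.default_rng(seed)
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]

    # jittered elliptical wound bed centered in the frame
    cy = h / 2 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2 + rng.uniform(-0.05, 0.05) * w
    ay = rng.uniform(0.22, 0.32) * h
    ax = rng.uniform(0.22, 0.32) * w
    roi = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    wound_rgb = optics.wound_intensity(sto2, gain=(1.0, 1.0, 1.0))
    skin_rgb = np.array([0.82, 0.62, 0.52]) * np.asarray(optics.illumination)

    texture = 1.0 + 0.10 * _smooth_noise(rng, (h, w), sigma=3.0)
    img = np.empty((h, w, 3))
    for c in range(3):
        base = np.where(roi, wound_rgb[c], skin_rgb[c])
        img[:, :, c] = gain[c] * base * texture
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return RGBImage(img), ROIMask(roi, source="synthetic-ellipse")


def inject_artifacts(
    image: RGBImage,
    kind: str,
    severity: float,
    seed: int = 0,
    roi: ROIMask | None = None,
) -> RGBImage:
    """Degrade an image with one artifact type at the given severity.

    glare: saturated specular blobs covering about ``severity`` of the ROI
    (whole frame if no ROI); blur: Gaussian blur with sigma = 8*severity px;
    blood: red-dominant overlay patches. severity=0 returns the image as is.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    if kind not in ("glare", "blur", "blood"):
        raise ValueError(f"unknown artifact kind {kind!r}")
    if severity == 0.0:
        return image
    rng = np.random.default_rng(seed)
    px = image.pixels.copy()
    h, w = px.shape[:2]
    region = roi.mask if roi is not None else np.ones((h, w), dtype=bool)

    if kind == "blur":
        sigma = 8.0 * severity
        for c in range(3):
            px[:, :, c] = ndimage.gaussian_filter(px[:, :, c], sigma)
        return RGBImage(np.clip(px, 0.0, 1.0))

    # blobby coverage mask of ~severity of the region, via thresholded
    # smooth noise (threshold at the (1-severity) quantile within the region)
    field_ = _smooth_noise(rng, (h, w), sigma=4.0)
    cutoff = np.quantile(field_[region], 1.0 - severity)
    blobs = region & (field_ >= cutoff)
    if kind == "glare":
        px[blobs] = 1.0
    else:  # blood
        px[blobs, 0] = np.clip(px[blobs, 0] + 0.45, 0.0, 1.0)
        px[blobs, 1] *= 0.35
        px[blobs, 2] *= 0.35
    return RGBImage(np.clip(px, 0.0, 1.0))


def _assign_classes(n: int, proportions: dict, rng: np.random.Generator) -> list:
    """Exact class counts by largest-remainder rounding, shuffled."""
    names = sorted(proportions)
    quotas = {c: proportions[c] * n for c in names}
    counts = {c: int(math.floor(quotas[c])) for c in names}
    short = n - sum(counts.values())
    remainders = sorted(names, key=lambda c: quotas[c] - counts[c], reverse=True)
    for c in remainders[:short]:
        counts[c] += 1
    if any(v < 0 for v in counts.values()):
        raise ValueError("infeasible class proportions for this cohort size")
    labels = [c for c in names for _ in range(counts[c])]
    rng.shuffle(labels)
    return labels


def sample_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Sample a full cohort: patients, wounds, debridements, and images.

    Outcomes are assigned at the wound level with exact largest-remainder
    proportions. Each wound gets an StO2 trajectory (class base + drift per
    debridement + noise), closure timing consistent with its class (delayed
    wounds close after day 21), and per-image artifacts at the configured
    rates. Deterministic given ``config.seed``.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)

    hospitals = list(cfg.hospitals)
    weights = np.array([h.weight for h in hospitals], dtype=float)
    weights /= weights.sum()

    # patients and their wound counts
    patients = []
    for i in range(cfg.n_patients):
        hosp = hospitals[rng.choice(len(hospitals), p=weights)]
        n_wounds = 1 + rng.poisson(cfg.wounds_per_patient_mean - 1.0)
        n_wounds = int(min(n_wounds, cfg.max_wounds_per_patient))
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 18, 80))
        patients.append((f"P{i:03d}", hosp, n_wounds, age))

    n_wounds_total = sum(p[2] for p in patients)
    outcomes = _assign_classes(n_wounds_total, cfg.class_proportions, rng)

    observations = []
    widx = 0
    for patient_id, hosp, n_wounds, age in patients:
        for j in range(n_wounds):
            outcome = outcomes[widx]
            wound_id = f"W{widx:03d}"
            widx += 1
            spec = cfg.class_specs[outcome]
            base_sto2 = rng.normal(spec.sto2_mean, spec.sto2_sd)
            area = float(max(rng.normal(cfg.wound_area_mean_cm2, cfg.wound_area_sd_cm2), 75.0))
            n_deb = 2 + rng.poisson(max(cfg.debridements_per_wound_mean - 2.0, 0.0))
            n_deb = int(min(n_deb, cfg.max_debridements))
            lo, hi = cfg.closure_days[outcome]
            closure_day = float(rng.uniform(lo, hi))
            # debridement days spread from ~day 2 up to closure
            days = np.sort(rng.uniform(2.0, closure_day, size=n_deb))
            for d in range(n_deb):
                sto2 = float(np.clip(
                    base_sto2 + spec.sto2_drift * d + rng.normal(0.0, 0.02),
                    0.02, 0.98,
                ))
                img_seed = _child_seed(cfg.seed, patient_id, wound_id, d)
                image, roi = render_wound_image(
                    sto2, cfg.optics, gain=hosp.gain, noise_sd=cfg.noise_sd,
                    seed=img_seed, size=cfg.image_size,
                )
                artifact = "none"
                for kind, rate in sorted(cfg.artifact_rates.items()):
                    if rng.uniform() < rate:
                        image = inject_artifacts(
                            image, kind, cfg.artifact_severity,
                            seed=img_seed + 1, roi=roi,
                        )
                        artifact = kind
                        break
                record = ImageRecord(
                    image_id=f"{wound_id}D{d + 1}",
                    patient_id=patient_id,
                    wound_id=wound_id,
                    debridement_index=d + 1,
                    hospital=hosp.name,
                    wound_area_cm2=round(area, 1),
                    days_post_injury=round(float(days[d]), 1),
                    age=round(age, 1),
                    outcome=outcome,
                )
                observations.append(
                    SyntheticObservation(image=image, roi=roi, record=record,
                                         true_sto2=sto2, artifact=artifact)
                )
    return SyntheticCohort(observations=observations, config=cfg)


# ---------------------------------------------------------------------------
# Named study conditions
# ---------------------------------------------------------------------------

def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default two-hospital cohort (~300 images, medium StO2 separation)."""
    return replace(CohortConfig(), seed=seed, **overrides)


def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """No-signal condition: identical StO2 and covariate distributions across
    classes, so labels are independent of everything measurable."""
    flat = ClassSpec(0.60, 0.06, 0.0)
    return replace(
        CohortConfig(),
        class_specs={"healed": flat, "delayed": flat, "dehisced": flat},
        closure_days={"healed": (10, 40), "delayed": (22, 40), "dehisced": (10, 40)},
        seed=seed,
        **overrides,
    )


def delayed_confound_config(seed: int = 0, **overrides) -> CohortConfig:
    """The regime the sequential two-stage classifier is built for: delayed
    wounds share the low-StO2 spectral range of dehisced wounds but close
    late, and dehisced wounds sit *between* healed and delayed along every
    linear direction of (spectra, days), so no single linear discriminant
    can isolate them while two sequential cuts can."""
    return replace(
        CohortConfig(),
        class_proportions={"healed": 0.45, "delayed": 0.35, "dehisced": 0.20},
        class_specs={
            "healed": ClassSpec(0.74, 0.05, +0.01),
            "delayed": ClassSpec(0.40, 0.05, +0.005),
            "dehisced": ClassSpec(0.57, 0.05, -0.01),
        },
        closure_days={"healed": (10, 20), "delayed": (25, 45), "dehisced": (16, 32)},
        seed=seed,
        **overrides,
    )
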