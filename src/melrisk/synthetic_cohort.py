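"""Synthetic co-registered multimodal phantom cohorts.

Generates fully synthetic patients — five co-registered volumes (PET_CT, CT,
PET_MR, MR_VIBE, ADC), textured ellipsoidal lesions, organ reference
landmarks (liver, spleen, L1–L4 vertebrae) — together with outcomes whose
distribution is tied to a latent per-patient "aggressiveness" a in [0, 1]:

* lesion texture heterogeneity grows with a (the PET lesion signal is
  ``SULmax * (1 - h(a) * T(x))`` with T a seeded multi-octave noise field),
* overall survival is exponential with hazard ``h0 * exp(beta * a)`` and
  administrative censoring,
* treatment response is Bernoulli with probability ``sigmoid(g0 - g1 * a)``,
* the between-lesion spread of lesion ADC grows with a, planting the
  "intraindividual range of ADCmean" marker.

The phantom makes no claim of anatomical realism: organ landmarks are uptake
spheres at fixed fractional grid positions so that the spleen–liver and
bone-marrow–liver reference ratios are computable by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging_io import (
    LesionMask,
    ORGAN_REGIONS,
    PatientRecord,
    Volume,
    ValidationError,
    save_cohort_table,
    save_mask,
    save_volume,
    CohortTable,
)
from .survival_stats import assign_risk


@dataclass
class SimConfig:
    """Parameters of the phantom cohort generator.

    Defaults follow the study conditions where the source cohort states them
    (injected dose 316 +/- 13 MBq, 19/37 female, age 62 +/- 13 y, responder
    fraction ~0.38, observation horizon 1800 days, MR grid spacing) and
    otherwise desk-scale choices documented in the methods note.
    """

    n_patients: int = 37
    shape: tuple[int, int, int] = (96, 96, 160)
    spacing: tuple[float, float, float] = (1.7, 1.7, 3.0)
    # lesions
    lesion_count_poisson_mean: float = 4.0  # per patient, plus one guaranteed
    lesion_diameter_range_mm: tuple[float, float] = (6.0, 40.0)
    sul_max_range: tuple[float, float] = (2.0, 12.0)
    heterogeneity_base: float = 0.15
    heterogeneity_effect: float = 0.65  # texture contrast h(a) = base + effect*a
    adc_patient_mean: float = 1050.0  # 1e-6 mm^2/s
    adc_patient_sd: float = 180.0
    adc_spread_base: float = 40.0  # between-lesion ADC sd at a=0
    adc_spread_effect: float = 330.0  # added sd at a=1
    adc_artifact_prob: float = 0.05
    brain_prob: float = 0.05
    # organs
    liver_uptake: float = 2.0
    spleen_uptake: float = 1.8
    vertebra_uptake: float = 1.5
    background_sul: float = 0.7
    render_organs: bool = True  # organ reference spheres (needed for SLR/BLR)
    # outcome model
    baseline_hazard: float = 1.0 / 900.0  # per day
    aggressiveness_log_hr: float = 1.5  # beta
    response_intercept: float = 1.0  # g0
    response_slope: float = 3.0  # g1
    censor_horizon_days: int = 1800
    # demographics (height m, weight kg, dose MBq)
    height_mean: float = 1.72
    height_sd: float = 0.09
    weight_mean: float = 78.0
    weight_sd: float = 14.0
    dose_mean: float = 316.0
    dose_sd: float = 13.0
    age_mean: float = 62.0
    age_sd: float = 13.0
    female_prob: float = 19.0 / 37.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("need at least 2 patients")
        if min(self.lesion_diameter_range_mm) <= 0 or min(self.sul_max_range) <= 0:
            raise ValidationError("ranges must be positive")
        if self.heterogeneity_base + self.heterogeneity_effect > 1.0 + 1e-9:
            raise ValidationError("heterogeneity must keep 1 - h*T nonnegative")
        if not 0 <= self.female_prob <= 1:
            raise ValidationError("female_prob must be a probability")


@dataclass
class Landmarks:
    liver_center: tuple[int, int, int]
    spleen_center: tuple[int, int, int]
    vertebra_centers: list[tuple[int, int, int]]
    vertebra_excluded: list[bool]


@dataclass
class LesionInfo:
    """Planted ground truth per lesion (for recoverability tests)."""

    lesion_id: str
    center: tuple[int, int, int]
    diameter_mm: float
    sul_max: float
    adc_mean: float
    organ_region: str
    adc_artifact: bool


@dataclass
class PatientCase:
    record: PatientRecord
    volumes: dict[str, Volume]
    lesions: list[LesionMask]
    landmarks: Landmarks
    latent_aggressiveness: float
    lesion_info: list[LesionInfo] = field(default_factory=list)
    n_lesions_found: int = 0

    @property
    def risk(self) -> str:
        return assign_risk(self.record.os_days, self.record.response)


# ---------------------------------------------------------------------------
# texture


def multi_octave_noise(
    shape: tuple[int, int, int], rng: np.random.Generator, octaves: int = 3
) -> np.ndarray:
    """Seeded multi-scale noise field normalised to [0, 1].

    Sum of ``octaves`` Gaussian-smoothed uniform-noise fields at dyadic
    smoothing scales — a controllable stand-in for intralesional texture.
    """
    acc = np.zeros(shape, dtype=np.float32)
    for o in range(octaves):
        sigma = 2.0 ** (octaves - 1 - o)
        layer = ndimage.gaussian_filter(
            rng.random(shape).astype(np.float32), sigma=sigma
        )
        acc += layer / (o + 1)
    lo, hi = acc.min(), acc.max()
    if hi - lo < 1e-12:
        return np.zeros(shape, dtype=np.float32)
    return (acc - lo) / (hi - lo)


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center: tuple[int, int, int],
    diameter_mm: float,
    z_ratio: float = 0.8,
) -> np.ndarray:
    """Axis-aligned ellipsoid with in-plane diameter ``diameter_mm`` and a
    shorter head–foot axis (z_ratio * diameter)."""
    semi = np.array(
        [diameter_mm / 2.0, diameter_mm / 2.0, z_ratio * diameter_mm / 2.0]
    )
    idx = np.indices(shape, dtype=np.float32)
    mm = [(idx[d] - center[d]) * spacing[d] for d in range(3)]
    r2 = sum((mm[d] / semi[d]) ** 2 for d in range(3))
    return r2 <= 1.0


# ---------------------------------------------------------------------------
# simulation


def _default_landmarks(config: SimConfig) -> Landmarks:
    nx, ny, nz = config.shape
    liver = (int(nx * 0.30), int(ny * 0.40), int(nz * 0.55))
    spleen = (int(nx * 0.72), int(ny * 0.42), int(nz * 0.57))
    verts = [
        (int(nx * 0.5), int(ny * 0.70), int(nz * (0.50 - 0.06 * i)))
        for i in range(4)
    ]
    return Landmarks(liver, spleen, verts, [False] * 4)


def _sample_outcome(
    a: float, config: SimConfig, rng: np.random.Generator
) -> tuple[int, bool, str]:
    hazard = config.baseline_hazard * math.exp(config.aggressiveness_log_hr * a)
    t = rng.exponential(1.0 / hazard)
    os_days = max(1, int(round(t)))
    died = os_days <= config.censor_horizon_days
    if not died:
        os_days = config.censor_horizon_days
    p_resp = 1.0 / (
        1.0 + math.exp(-(config.response_intercept - config.response_slope * a))
    )
    if rng.random() < p_resp:
        response = rng.choice(["CR", "PR", "SD"], p=[0.3, 0.55, 0.15])
    else:
        response = "PD"
    return os_days, died, str(response)


_LESION_REGIONS = [r for r in ORGAN_REGIONS if r != "brain"]
_LESION_REGION_P = np.array(
    [0.26, 0.26, 0.10, 0.10, 0.02, 0.18, 0.02, 0.06]
)  # lymph nodes, soft tissue, bone, liver, spleen, lung, pleura, other viscera


def _sample_lesion_geometry(
    config: SimConfig, rng: np.random.Generator, landmarks: Landmarks
) -> tuple[tuple[int, int, int], float]:
    """Random lesion centre away from organ landmarks; bounded retries."""
    lo, hi = config.lesion_diameter_range_mm
    d = float(rng.uniform(lo, hi))
    shape = np.array(config.shape)
    spacing = np.array(config.spacing)
    margin = np.ceil((d / 2.0) / spacing).astype(int) + 1
    keepout = [np.array(landmarks.liver_center), np.array(landmarks.spleen_center)]
    keepout += [np.array(v) for v in landmarks.vertebra_centers]
    for _ in range(200):
        c = np.array(
            [int(rng.integers(margin[i], shape[i] - margin[i])) for i in range(3)]
        )
        dists = [
            np.linalg.norm((c - k) * spacing) for k in keepout
        ]
        if min(dists) > d / 2.0 + 14.0:  # clear of 2 cm organ VOIs
            return tuple(int(x) for x in c), d
    raise ValidationError("could not place lesion inside the volume")


def render_volumes(
    case_skeleton: dict, config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, Volume], list[LesionMask]]:
    """Render the five co-registered modality volumes for one patient.

    PET lesion voxels are ``SULmax * (1 - h * T(x))`` with T in [0, 1]; CT
    lesions are soft-tissue dense, VIBE lesions hyperintense, ADC lesion
    voxels are drawn around the lesion's ADC mean.  Organ landmarks receive
    configurable uptake so SLR/BLR are computable.
    """
    shape, spacing = config.shape, config.spacing
    landmarks: Landmarks = case_skeleton["landmarks"]
    lesion_infos: list[LesionInfo] = case_skeleton["lesion_info"]
    h = case_skeleton["heterogeneity"]

    smooth = ndimage.gaussian_filter(rng.random(shape).astype(np.float32), 4.0)
    smooth = (smooth - smooth.mean()) / max(smooth.std(), 1e-6)

    pet = np.full(shape, config.background_sul, dtype=np.float32) + 0.05 * smooth
    ct = np.full(shape, 40.0, dtype=np.float32) + 8.0 * smooth
    vibe = np.full(shape, 200.0, dtype=np.float32) + 25.0 * smooth
    adc = np.full(shape, 1500.0, dtype=np.float32) + 60.0 * smooth

    # organ reference regions
    if config.render_organs:
        for center, uptake, diameter in (
            (landmarks.liver_center, config.liver_uptake, 55.0),
            (landmarks.spleen_center, config.spleen_uptake, 45.0),
        ):
            organ = _ellipsoid_mask(shape, spacing, center, diameter, z_ratio=1.0)
            pet[organ] = uptake
            ct[organ] = 55.0
        for center in landmarks.vertebra_centers:
            organ = _ellipsoid_mask(shape, spacing, center, 26.0, z_ratio=0.9)
            pet[organ] = config.vertebra_uptake
            ct[organ] = 300.0

    masks: list[LesionMask] = []
    for info in lesion_infos:
        les = _ellipsoid_mask(shape, spacing, info.center, info.diameter_mm)
        if not les.any():
            raise ValidationError("lesion rendered empty")
        texture = multi_octave_noise(shape, rng)
        tex = texture[les]
        span = tex.max() - tex.min()
        # rescale to [0, 1] within the lesion so the hottest voxel hits SULmax
        tex = (tex - tex.min()) / span if span > 1e-9 else np.zeros_like(tex)
        pet[les] = info.sul_max * (1.0 - h * tex)
        ct[les] = 60.0 + 6.0 * smooth[les]
        vibe[les] = 420.0 + 120.0 * (1.0 - h * tex)
        adc[les] = info.adc_mean + 40.0 * (tex - 0.5)
        masks.append(
            LesionMask(
                values=les,
                spacing=spacing,
                lesion_id=info.lesion_id,
                organ_region=info.organ_region,
                adc_artifact=info.adc_artifact,
            )
        )

    pet_mr = pet
    pet_ct = pet * (1.0 + 0.02 * smooth)  # slightly different noise realisation
    volumes = {
        "PET_CT": Volume(pet_ct, spacing, "PET_CT"),
        "CT": Volume(ct, spacing, "CT"),
        "PET_MR": Volume(pet_mr, spacing, "PET_MR"),
        "MR_VIBE": Volume(vibe, spacing, "MR_VIBE"),
        "ADC": Volume(np.clip(adc, 0, None), spacing, "ADC"),
    }
    return volumes, masks


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    """Independent, reproducible random stream per (cohort seed, patient)."""
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _sample_patient_skeleton(
    config: SimConfig, pid: str, rng: np.random.Generator
) -> dict:
    """Draw everything about one patient except the voxel data."""
    a = float(rng.uniform())
    os_days, died, response = _sample_outcome(a, config, rng)
    sex = "f" if rng.random() < config.female_prob else "m"
    record = PatientRecord(
        patient_id=pid,
        sex=sex,
        age=float(np.clip(rng.normal(config.age_mean, config.age_sd), 18, 95)),
        response=response,
        os_days=os_days,
        died=died,
        height=float(np.clip(rng.normal(config.height_mean, config.height_sd), 1.4, 2.1)),
        weight=float(np.clip(rng.normal(config.weight_mean, config.weight_sd), 40, 140)),
        dose_mbq=float(rng.normal(config.dose_mean, config.dose_sd)),
        risk=assign_risk(os_days, response),
    )
    landmarks = _default_landmarks(config)
    n_lesions = 1 + int(rng.poisson(config.lesion_count_poisson_mean))
    adc_patient = float(rng.normal(config.adc_patient_mean, config.adc_patient_sd))
    adc_spread = config.adc_spread_base + config.adc_spread_effect * a
    infos: list[LesionInfo] = []
    for k in range(n_lesions):
        center, d = _sample_lesion_geometry(config, rng, landmarks)
        region = (
            "brain"
            if rng.random() < config.brain_prob
            else str(rng.choice(_LESION_REGIONS, p=_LESION_REGION_P))
        )
        infos.append(
            LesionInfo(
                lesion_id=f"{pid}_lesion{k + 1}",
                center=center,
                diameter_mm=d,
                sul_max=float(rng.uniform(*config.sul_max_range)),
                adc_mean=float(max(200.0, rng.normal(adc_patient, adc_spread))),
                organ_region=region,
                adc_artifact=bool(rng.random() < config.adc_artifact_prob),
            )
        )
    return {
        "record": record,
        "latent": a,
        "landmarks": landmarks,
        "lesion_info": infos,
        "heterogeneity": config.heterogeneity_base + config.heterogeneity_effect * a,
        "n_lesions": n_lesions,
    }


def _render_case(
    skeleton: dict, config: SimConfig, rng: np.random.Generator
) -> PatientCase:
    volumes, masks = render_volumes(skeleton, config, rng)
    return PatientCase(
        record=skeleton["record"],
        volumes=volumes,
        lesions=masks,
        landmarks=skeleton["landmarks"],
        latent_aggressiveness=skeleton["latent"],
        lesion_info=skeleton["lesion_info"],
        n_lesions_found=skeleton["n_lesions"],
    )


def simulate_cohort(config: SimConfig) -> list[PatientCase]:
    """Simulate a reproducible phantom cohort.

    A latent aggressiveness ``a ~ Uniform(0, 1)`` per patient drives lesion
    texture heterogeneity, overall survival and response; the risk label is
    derived afterwards from the OS/response rule.  Each patient draws from
    an independent child stream of the cohort seed, so individual patients
    are reproducible without simulating the whole cohort.
    """
    cases: list[PatientCase] = []
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        skeleton = _sample_patient_skeleton(config, f"sim{i + 1:03d}", rng)
        cases.append(_render_case(skeleton, config, rng))
    return cases


def simulate_outcomes_only(config: SimConfig) -> tuple[np.ndarray, CohortTable]:
    """Outcome-level simulation without volume rendering.

    Returns ``(latent aggressiveness, cohort table)``; used for statistical
    calibration at large n, where rendering volumes would be wasteful.
    """
    records, lat = [], []
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        skeleton = _sample_patient_skeleton(config, f"sim{i + 1:03d}", rng)
        records.append(skeleton["record"])
        lat.append(skeleton["latent"])
    return np.asarray(lat), CohortTable(records)


def simulate_balanced_cohort(
    config: SimConfig,
    n_per_class: int,
    latent_ranges: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> list[PatientCase]:
    """Simulate until ``n_per_class`` low- and high-risk patients are found.

    Used for small planted-signal experiments where class balance matters
    more than the marginal class frequency.  ``latent_ranges`` optionally
    restricts the accepted latent aggressiveness per class
    ``((low_min, low_max), (high_min, high_max))`` so that the planted image
    signal is well separated between the classes rather than straddling the
    outcome boundary.
    """
    low: list[PatientCase] = []
    high: list[PatientCase] = []

    def accept(skeleton: dict, cls: int) -> bool:
        if latent_ranges is None:
            return True
        lo, hi = latent_ranges[cls]
        return lo <= skeleton["latent"] <= hi

    # screen candidate patients on their (cheap) skeletons; render volumes
    # only for accepted ones
    index = 0
    max_candidates = 100_000
    while (len(low) < n_per_class or len(high) < n_per_class) and index < max_candidates:
        rng = _patient_rng(config.seed, index)
        skeleton = _sample_patient_skeleton(config, f"sim{index + 1:03d}", rng)
        risk = skeleton["record"].risk
        if risk == "low" and len(low) < n_per_class and accept(skeleton, 0):
            low.append(_render_case(skeleton, config, rng))
        elif risk == "high" and len(high) < n_per_class and accept(skeleton, 1):
            high.append(_render_case(skeleton, config, rng))
        index += 1
    if len(low) < n_per_class or len(high) < n_per_class:
        raise ValidationError("balanced cohort sampling did not converge")
    cases = low + high
    for i, case in enumerate(cases):
        # re-key ids so the combined cohort has unique ids
        new_id = f"bal{i + 1:03d}"
        case.record = PatientRecord(**{**case.record.__dict__, "patient_id": new_id})
    return cases


# ---------------------------------------------------------------------------
# export


def export_case(case: PatientCase, directory: str | Path) -> Path:
    """Write one patient's volumes and masks under ``patients/<id>/``."""
    pdir = Path(directory) / "patients" / case.record.patient_id
    pdir.mkdir(parents=True, exist_ok=True)
    for modality, vol in case.volumes.items():
        save_volume(vol, pdir / f"{modality}.nii.gz")
    for k, mask in enumerate(case.lesions, start=1):
        save_mask(mask, pdir / f"lesion_{k}.nii.gz")
    return pdir


def export_cohort(cases: list[PatientCase], directory: str | Path) -> Path:
    """Write the full cohort: ``cohort.csv`` plus per-patient NIfTI files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for case in cases:
        export_case(case, directory)
    table = CohortTable([c.record for c in cases])
    save_cohort_table(table, directory / "cohort.csv")
    return directory
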