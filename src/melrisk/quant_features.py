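"""Handcrafted quantitative imaging features for whole-body FDG-PET hybrid imaging.

Implements the per-lesion and per-patient biomarkers used for melanoma risk
screening: SUL conversion (lean-body-mass normalised uptake), SULpeak (mean
SUL in a 1 cm^3 sphere placed to maximise the mean, the EANM convention),
metabolic tumor volume inside the 42% isocontour of the lesion maximum, total
lesion glycolysis, axial lesion diameters with the sub-centimetre rule, mean
ADC over an eroded largest-diameter slice, organ-involvement bookkeeping, and
the spleen–liver (SLR) and bone-marrow–liver (BLR) reference ratios.

Lesions with a longest axial diameter under 10 mm are recorded with a nominal
diameter of 5 mm and no functional parameters (partial-volume effects make
SUL/ADC unreliable at that scale); for brain lesions only the diameter is
kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import LesionMask, ValidationError, Volume

#: radius (mm) of a 1 cm^3 sphere, used for SULpeak
PEAK_SPHERE_RADIUS_MM = (3.0 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)

#: isocontour fraction defining the metabolic tumor volume
MTV_FRACTION = 0.42

#: maximum number of lesions recorded per patient
MAX_LESIONS = 200

#: spleen/liver ratio cutoffs swept when classifying SLR (high-to-low, step 0.05)
SLR_CUTOFFS = (1.1, 1.05, 1.0, 0.95, 0.9)


@dataclass
class LesionFeatures:
    """Per-lesion quantitative features; ``None`` marks a suppressed value."""

    lesion_id: str
    organ_region: str
    dm_mm: float
    sub_cm: bool = False
    sul_peak: float | None = None
    sul_max: float | None = None
    adc_mean: float | None = None
    mtv_ml: float | None = None
    tlg: float | None = None
    functional_suppressed: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass
class PatientFeatures:
    """Per-patient aggregates over all recorded lesions."""

    n_lesions: int
    tmtv_ml: float
    tlg_total: float
    organ_regions: frozenset[str]
    n_organ_regions: int
    dm_mean: float
    dm_min: float
    dm_max: float
    dm_range: float
    sul_peak_mean: float | None
    sul_peak_min: float | None
    sul_peak_max: float | None
    sul_peak_range: float | None
    adc_mean_mean: float | None
    adc_mean_min: float | None
    adc_mean_max: float | None
    adc_mean_range: float | None
    slr: float | None = None
    blr: float | None = None


# ---------------------------------------------------------------------------
# SUL conversion


def compute_lbm(sex: str, weight_kg: float, height_m: float) -> float:
    """Lean body mass (kg), Janmahasatian sex-specific formula.

    LBM = 9270 W / (6680 + 216 BMI) for males and
    LBM = 9270 W / (8780 + 244 BMI) for females, with BMI = W / H^2.
    """
    if weight_kg <= 0 or height_m <= 0:
        raise ValidationError("weight and height must be positive")
    bmi = weight_kg / height_m**2
    if sex == "m":
        return 9270.0 * weight_kg / (6680.0 + 216.0 * bmi)
    if sex == "f":
        return 9270.0 * weight_kg / (8780.0 + 244.0 * bmi)
    raise ValidationError(f"sex must be 'm' or 'f', got {sex!r}")


def to_sul(activity: Volume, dose_mbq: float, lbm_kg: float) -> Volume:
    """Convert an activity-concentration volume (Bq/mL) to SUL.

    SUL(v) = C(v) / (injected dose / lean body mass); with the dose in MBq and
    LBM in kg the normaliser is dose*1e6 Bq / (lbm*1e3 mL) assuming unit tissue
    density.
    """
    if dose_mbq <= 0:
        raise ValidationError("dose must be positive")
    if lbm_kg <= 0:
        raise ValidationError("lean body mass must be positive")
    norm = dose_mbq * 1e6 / (lbm_kg * 1e3)  # Bq per mL at uniform distribution
    from dataclasses import replace

    return replace(
        activity,
        values=(activity.values / norm).astype(np.float32),
        units="SUL",
    )


# ---------------------------------------------------------------------------
# sphere helpers


def _sphere_offsets(spacing: Sequence[float], radius_mm: float) -> np.ndarray:
    """(n, 3) voxel-index offsets whose centres lie within radius_mm."""
    r = [int(math.ceil(radius_mm / s)) for s in spacing]
    grids = np.meshgrid(*[np.arange(-n, n + 1) for n in r], indexing="ij")
    offs = np.stack([g.ravel() for g in grids], axis=1)
    d2 = ((offs * np.asarray(spacing)) ** 2).sum(axis=1)
    return offs[d2 <= radius_mm**2]


def sphere_voi_mean(
    volume: Volume, center_idx: Sequence[int], diameter_mm: float
) -> float:
    """Mean voxel value inside a spherical VOI centred on a voxel index."""
    offs = _sphere_offsets(volume.spacing, diameter_mm / 2.0)
    idx = np.asarray(center_idx, dtype=int) + offs
    shape = np.asarray(volume.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    if not ok.any():
        raise ValidationError("VOI entirely outside the volume")
    sel = idx[ok]
    return float(volume.values[sel[:, 0], sel[:, 1], sel[:, 2]].mean())


# ---------------------------------------------------------------------------
# SULpeak


def sul_peak(pet: Volume, mask: LesionMask) -> tuple[float, bool]:
    """Peak SUL: max over candidate centres inside the mask of the mean SUL in
    a 1 cm^3 sphere (clipped to the volume).

    Returns ``(value, fallback)``; ``fallback`` is true when the mask is
    smaller than the sphere support, in which case the plain mask mean is
    reported.
    """
    if pet.values.shape != mask.shape:
        raise ValidationError("PET volume and mask shapes differ")
    offs = _sphere_offsets(pet.spacing, PEAK_SPHERE_RADIUS_MM)
    centers = mask.indices()
    if len(centers) < len(offs) // 2:
        # mask substantially smaller than the 1 cm^3 sphere: fall back
        vals = pet.values[mask.values]
        return float(vals.mean()), True
    shape = np.asarray(pet.shape)
    best = -np.inf
    vol = pet.values
    for c in centers:
        idx = c + offs
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        sel = idx[ok]
        m = vol[sel[:, 0], sel[:, 1], sel[:, 2]].mean()
        if m > best:
            best = m
    return float(best), False


# ---------------------------------------------------------------------------
# MTV / TLG


def mtv_isocontour(
    pet: Volume, mask: LesionMask, fraction: float = MTV_FRACTION
) -> tuple[float, np.ndarray, bool]:
    """Metabolic tumor volume inside the ``fraction`` isocontour of the lesion
    maximum.

    The submask consists of mask voxels with SUL >= fraction * (max SUL within
    the mask) that are 26-connected to the maximum voxel.  Returns
    ``(mtv_ml, submask, degenerate)``.
    """
    if pet.values.shape != mask.shape:
        raise ValidationError("PET volume and mask shapes differ")
    vals = np.where(mask.values, pet.values, -np.inf)
    vmax = vals.max()
    if not np.isfinite(vmax) or vmax <= 0:
        return 0.0, np.zeros(mask.shape, dtype=bool), True
    thresh = fraction * vmax
    above = mask.values & (pet.values >= thresh)
    labels, _ = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    max_idx = np.unravel_index(int(np.argmax(vals)), mask.shape)
    submask = labels == labels[max_idx]
    mtv_ml = float(submask.sum()) * float(np.prod(pet.spacing)) / 1000.0
    return mtv_ml, submask, False


def tlg(pet: Volume, mtv_ml: float, mtv_submask: np.ndarray) -> tuple[float, bool]:
    """Total lesion glycolysis = MTV (mL) x mean SUL inside the MTV submask."""
    if not mtv_submask.any():
        return 0.0, True
    return float(mtv_ml) * float(pet.values[mtv_submask].mean()), False


# ---------------------------------------------------------------------------
# diameters


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance among 2D points (mm)."""
    if len(points) == 1:
        return 0.0
    if len(points) > 3:
        try:
            from scipy.spatial import ConvexHull

            hull = ConvexHull(points, qhull_options="QJ")
            points = points[hull.vertices]
        except Exception:
            pass  # degenerate (collinear) point sets: brute force below
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def lesion_diameter_axial(mask: LesionMask) -> float:
    """Longest lesion diameter (mm) in the axial (xy) plane.

    The maximum over z-slices of the largest pairwise in-plane distance
    between mask voxel centres, plus one in-plane voxel size so that a single
    voxel reports the extent of one voxel rather than zero.
    """
    sx, sy, _ = mask.spacing
    best = 0.0
    for z in range(mask.shape[2]):
        sl = mask.values[:, :, z]
        if not sl.any():
            continue
        pts = np.argwhere(sl).astype(float) * np.array([sx, sy])
        best = max(best, _max_pairwise_distance(pts))
    return best + max(sx, sy)


def apply_small_lesion_rule(dm_mm: float, organ_region: str) -> dict:
    """Recording rules for small and brain lesions.

    Sub-centimetre lesions (dm < 10 mm) are recorded with a nominal 5 mm
    diameter and all functional parameters suppressed; brain lesions keep only
    the diameter.
    """
    if dm_mm <= 0:
        raise ValidationError("diameter must be positive")
    sub_cm = dm_mm < 10.0
    suppressed = sub_cm or organ_region == "brain"
    return {
        "dm_mm": 5.0 if sub_cm else float(dm_mm),
        "sub_cm": sub_cm,
        "functional_suppressed": suppressed,
    }


# ---------------------------------------------------------------------------
# ADC


def adc_mean_roi(
    adc: Volume, mask: LesionMask, artifact_flag: bool = False, erosion: int = 1
) -> tuple[float | None, bool]:
    """Mean ADC over the largest-diameter axial slice of the lesion after
    in-plane erosion (a proxy for a free-hand ROI avoiding organ borders).

    Returns ``(value, flagged)``; ``value`` is ``None`` when the ADC map is
    unusable due to artifacts.  If erosion empties the slice the un-eroded
    slice is used and flagged.
    """
    if artifact_flag or mask.adc_artifact:
        return None, True
    sx, sy, _ = mask.spacing
    best_z, best_d = 0, -1.0
    for z in range(mask.shape[2]):
        sl = mask.values[:, :, z]
        if not sl.any():
            continue
        pts = np.argwhere(sl).astype(float) * np.array([sx, sy])
        d = _max_pairwise_distance(pts)
        if d > best_d:
            best_d, best_z = d, z
    sl = mask.values[:, :, best_z]
    flagged = False
    if erosion > 0:
        eroded = ndimage.binary_erosion(sl, iterations=erosion)
        if eroded.any():
            sl = eroded
        else:
            flagged = True
    return float(adc.values[:, :, best_z][sl].mean()), flagged


# ---------------------------------------------------------------------------
# lesion-level driver


def extract_lesion_features(
    pet: Volume,
    adc: Volume | None,
    mask: LesionMask,
    diameter_mask: LesionMask | None = None,
) -> LesionFeatures:
    """Full per-lesion feature extraction.

    Diameters are measured on ``diameter_mask`` when given (lung lesions are
    measured on CT, others on the post-contrast VIBE grid); functional
    parameters always come from the PET/ADC volumes on the common grid.
    """
    dmask = diameter_mask if diameter_mask is not None else mask
    raw_dm = lesion_diameter_axial(dmask)
    rule = apply_small_lesion_rule(raw_dm, mask.organ_region)
    feat = LesionFeatures(
        lesion_id=mask.lesion_id,
        organ_region=mask.organ_region,
        dm_mm=rule["dm_mm"],
        sub_cm=rule["sub_cm"],
        functional_suppressed=rule["functional_suppressed"],
    )
    if rule["functional_suppressed"]:
        return feat
    peak, fb = sul_peak(pet, mask)
    feat.sul_peak = peak
    if fb:
        feat.flags.append("sul_peak_fallback")
    feat.sul_max = float(pet.values[mask.values].max())
    mtv_ml, submask, degen = mtv_isocontour(pet, mask)
    feat.mtv_ml = mtv_ml
    if degen:
        feat.flags.append("mtv_degenerate")
    value, empty = tlg(pet, mtv_ml, submask)
    feat.tlg = value
    if empty:
        feat.flags.append("tlg_empty_submask")
    if adc is not None:
        adc_val, flagged = adc_mean_roi(adc, mask)
        feat.adc_mean = adc_val
        if flagged and adc_val is not None:
            feat.flags.append("adc_erosion_fallback")
    return feat


# ---------------------------------------------------------------------------
# patient aggregates


def _agg(values: list[float]) -> tuple[float, float, float, float] | None:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.min()), float(arr.max()), float(arr.max() - arr.min())


def patient_feature_summary(
    lesions: Sequence[LesionFeatures], n_found: int | None = None
) -> PatientFeatures:
    """Aggregate lesion features to the patient level.

    ``n_found`` is the number of lesions identified on the scan (capped at
    200); when omitted it defaults to the number of feature records.
    """
    if not lesions:
        raise ValidationError("patient has no lesions")
    if all(l.dm_mm is None for l in lesions):
        raise ValidationError("no lesion with a defined diameter")
    n = n_found if n_found is not None else len(lesions)
    n_lesions = min(int(n), MAX_LESIONS)
    mtvs = [l.mtv_ml for l in lesions if l.mtv_ml is not None]
    tlgs = [l.tlg for l in lesions if l.tlg is not None]
    dm = _agg([l.dm_mm for l in lesions if l.dm_mm is not None])
    sul = _agg([l.sul_peak for l in lesions if l.sul_peak is not None])
    adc = _agg([l.adc_mean for l in lesions if l.adc_mean is not None])
    regions = frozenset(l.organ_region for l in lesions)
    return PatientFeatures(
        n_lesions=n_lesions,
        tmtv_ml=float(sum(mtvs)),
        tlg_total=float(sum(tlgs)),
        organ_regions=regions,
        n_organ_regions=len(regions),
        dm_mean=dm[0],
        dm_min=dm[1],
        dm_max=dm[2],
        dm_range=dm[3],
        sul_peak_mean=sul[0] if sul else None,
        sul_peak_min=sul[1] if sul else None,
        sul_peak_max=sul[2] if sul else None,
        sul_peak_range=sul[3] if sul else None,
        adc_mean_mean=adc[0] if adc else None,
        adc_mean_min=adc[1] if adc else None,
        adc_mean_max=adc[2] if adc else None,
        adc_mean_range=adc[3] if adc else None,
    )


# ---------------------------------------------------------------------------
# organ reference ratios


def slr(
    pet: Volume,
    liver_center: Sequence[int],
    spleen_center: Sequence[int],
    cutoffs: Sequence[float] = SLR_CUTOFFS,
) -> tuple[float, dict[float, bool]]:
    """Spleen–liver ratio of mean SUL in 2 cm spherical VOIs, with the
    classification at each cutoff of the descending sweep."""
    liver = sphere_voi_mean(pet, liver_center, 20.0)
    spleen = sphere_voi_mean(pet, spleen_center, 20.0)
    if liver <= 0:
        raise ValidationError("liver VOI mean is non-positive")
    ratio = spleen / liver
    return float(ratio), {float(c): bool(ratio > c) for c in cutoffs}


def blr(
    pet: Volume,
    vertebra_centers: Sequence[Sequence[int]],
    exclusion_flags: Sequence[bool],
    liver_center: Sequence[int],
) -> float | None:
    """Bone-marrow–liver ratio: mean SUL over up to four 1.5 cm vertebral VOIs
    (L1–L4, excluding degenerate vertebrae) divided by the liver VOI mean.

    Returns ``None`` when every vertebra is excluded.
    """
    if len(vertebra_centers) != len(exclusion_flags):
        raise ValidationError("vertebra centers and exclusion flags differ in length")
    eligible = [
        c for c, excl in zip(vertebra_centers, exclusion_flags) if not excl
    ]
    if not eligible:
        return None
    liver = sphere_voi_mean(pet, liver_center, 20.0)
    if liver <= 0:
        raise ValidationError("liver VOI mean is non-positive")
    marrow = float(np.mean([sphere_voi_mean(pet, c, 15.0) for c in eligible]))
    return marrow / liver


# ---------------------------------------------------------------------------
# target lesion


def select_target_lesion(
    lesions: Sequence[LesionFeatures], tie_tolerance: float = 0.05
) -> str:
    """Pick the target lesion: highest SULpeak, ties (within a relative
    tolerance) broken by the largest diameter; brain lesions are excluded."""
    eligible = [
        l
        for l in lesions
        if l.organ_region != "brain" and l.sul_peak is not None
    ]
    if not eligible:
        raise ValidationError("no eligible lesion with a defined SULpeak")
    best_peak = max(l.sul_peak for l in eligible)
    contenders = [
        l for l in eligible if l.sul_peak >= best_peak * (1.0 - tie_tolerance)
    ]
    winner = max(contenders, key=lambda l: (l.dm_mm, l.sul_peak))
    return winner.lesion_id


def lesion_features_frame(lesions: Sequence[LesionFeatures]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "lesion_id": l.lesion_id,
                "organ_region": l.organ_region,
                "dm_mm": l.dm_mm,
                "sub_cm": l.sub_cm,
                "sul_peak": l.sul_peak,
                "adc_mean": l.adc_mean,
                "mtv_ml": l.mtv_ml,
                "tlg": l.tlg,
            }
            for l in lesions
        ]
    )
    for col in ("dm_mm", "sul_peak", "adc_mean", "mtv_ml", "tlg"):
        df[col] = pd.to_numeric(df[col])
    return df


def patient_features_frame(rows: dict[str, PatientFeatures]) -> pd.DataFrame:
    out = []
    for pid, f in rows.items():
        rec = {
            "patient_id": pid,
            "n_lesions": f.n_lesions,
            "tmtv_ml": f.tmtv_ml,
            "tlg_total": f.tlg_total,
            "n_organ_regions": f.n_organ_regions,
            "dm_mean": f.dm_mean,
            "dm_min": f.dm_min,
            "dm_max": f.dm_max,
            "dm_range": f.dm_range,
            "sul_peak_mean": f.sul_peak_mean,
            "sul_peak_min": f.sul_peak_min,
            "sul_peak_max": f.sul_peak_max,
            "sul_peak_range": f.sul_peak_range,
            "adc_mean_mean": f.adc_mean_mean,
            "adc_mean_min": f.adc_mean_min,
            "adc_mean_max": f.adc_mean_max,
            "adc_mean_range": f.adc_mean_range,
            "slr": f.slr,
            "blr": f.blr,
        }
        for region in f.organ_regions:
            rec[f"region_{region.replace(' ', '_')}"] = 1
        out.append(rec)
    df = pd.DataFrame(out)
    region_cols = [c for c in df.columns if c.startswith("region_")]
    df[region_cols] = df[region_cols].fillna(0).astype(int)
    return df
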