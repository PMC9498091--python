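"""Glue between the phantom cohort and the feature/statistics stages."""

from __future__ import annotations

import pandas as pd

from .quant_features import (
    LesionFeatures,
    PatientFeatures,
    blr,
    extract_lesion_features,
    lesion_features_frame,
    patient_feature_summary,
    patient_features_frame,
    slr,
)
from .synthetic_cohort import PatientCase


def case_lesion_features(case: PatientCase) -> list[LesionFeatures]:
    """Per-lesion features for one patient case.

    PET quantification uses the PET_MR volume; diameters are measured on the
    VIBE grid except for lung lesions, which are measured on CT (all volumes
    share one grid in the phantom, so the mask is reused).
    """
    pet = case.volumes["PET_MR"]
    adc = case.volumes.get("ADC")
    return [extract_lesion_features(pet, adc, mask) for mask in case.lesions]


def case_patient_features(
    case: PatientCase, lesions: list[LesionFeatures] | None = None
) -> PatientFeatures:
    """Patient-level aggregates including the SLR/BLR reference ratios."""
    if lesions is None:
        lesions = case_lesion_features(case)
    feats = patient_feature_summary(lesions, n_found=case.n_lesions_found)
    pet = case.volumes["PET_MR"]
    lm = case.landmarks
    ratio, _ = slr(pet, lm.liver_center, lm.spleen_center)
    feats.slr = ratio
    feats.blr = blr(pet, lm.vertebra_centers, lm.vertebra_excluded, lm.liver_center)
    return feats


def cohort_feature_frames(
    cases: list[PatientCase],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(lesion table, patient table) for a whole cohort."""
    lesion_rows = []
    patient_feats = {}
    for case in cases:
        lesions = case_lesion_features(case)
        df = lesion_features_frame(lesions)
        df.insert(0, "patient_id", case.record.patient_id)
        lesion_rows.append(df)
        patient_feats[case.record.patient_id] = case_patient_features(case, lesions)
    return (
        pd.concat(lesion_rows, ignore_index=True),
        patient_features_frame(patient_feats),
    )
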