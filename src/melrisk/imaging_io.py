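"""Data model and file I/O for co-registered hybrid-imaging volumes and cohort tables.

All volumes live on a regular 3D grid indexed ``(x, y, z)`` with 0-based voxel
indices; the physical coordinate of voxel ``(i, j, k)`` is
``origin + index * spacing`` (mm).  Axial slices are the xy-plane, the z axis
runs head–foot.  NIfTI is the single on-disk volume format; cohort tables are
plain CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

MODALITIES = ("PET_CT", "CT", "PET_MR", "MR_VIBE", "ADC")

#: physical units per modality; PET volumes are stored as SUL (lean-body-mass
#: normalised uptake), ADC maps in 1e-6 mm^2/s.
MODALITY_UNITS = {
    "PET_CT": "SUL",
    "PET_MR": "SUL",
    "CT": "HU",
    "MR_VIBE": "arbitrary",
    "ADC": "1e-6 mm^2/s",
}

ORGAN_REGIONS = (
    "lymph nodes",
    "soft tissue",
    "bone",
    "liver",
    "spleen",
    "lung",
    "pleura",
    "brain",
    "other viscera",
)

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")

#: free-text response labels as they appear in clinical tables -> category
RESPONSE_NORMALIZATION = {
    "complete response": "CR",
    "partial response": "PR",
    "stable disease": "SD",
    "progress": "PD",
    "progressive disease": "PD",
    "cr": "CR",
    "pr": "PR",
    "sd": "SD",
    "pd": "PD",
}

COHORT_COLUMNS = [
    "patient_id",
    "sex",
    "age",
    "height",
    "weight",
    "dose_mbq",
    "response",
    "os_days",
    "died",
    "risk",
]


class FormatError(ValueError):
    """Raised for structurally invalid files (wrong dimensionality, schema)."""


class ValidationError(ValueError):
    """Raised when domain invariants are violated."""


def normalize_response(raw: str) -> str:
    """Map a free-text response label onto {CR, PR, SD, PD}.

    Labels such as "progress (iRECIST, stable disease)" — a clinical-progress
    call overriding an iRECIST stable-disease read — normalise to PD: the
    clinical decision governs the response category.
    """
    s = str(raw).strip().lower()
    if s in RESPONSE_NORMALIZATION:
        return RESPONSE_NORMALIZATION[s]
    # clinical override annotations, e.g. "progress (iRECIST, stable disease)"
    for key in ("progress", "progressive"):
        if s.startswith(key):
            return "PD"
    raise ValidationError(f"unrecognised response label: {raw!r}")


@dataclass(frozen=True)
class Volume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    values : (nx, ny, nz) float array
    spacing : (sx, sy, sz) voxel size in mm, strictly positive
    modality : one of :data:`MODALITIES`
    units : physical units of the voxel values
    origin : physical coordinate (mm) of voxel (0, 0, 0)
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    modality: str
    units: str = ""
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise FormatError(f"volume must be 3D, got {v.ndim}D")
        if not np.all(np.isfinite(v)):
            raise ValidationError("volume contains non-finite values")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        if not self.units:
            object.__setattr__(self, "units", MODALITY_UNITS[self.modality])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion mask aligned to a reference volume grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    lesion_id: str
    organ_region: str
    adc_artifact: bool = False
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values).astype(bool)
        if v.ndim != 3:
            raise FormatError(f"mask must be 3D, got {v.ndim}D")
        if not v.any():
            raise ValidationError(f"lesion mask {self.lesion_id!r} is empty")
        if self.organ_region not in ORGAN_REGIONS:
            raise ValidationError(f"unknown organ region {self.organ_region!r}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("mask spacing must be positive")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def indices(self) -> np.ndarray:
        """(n, 3) voxel indices inside the mask."""
        return np.argwhere(self.values)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str
    age: float
    response: str
    os_days: int
    died: bool
    height: float | None = None  # m
    weight: float | None = None  # kg
    dose_mbq: float | None = None
    risk: str | None = None  # printed label, kept for fixture validation
    agent: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("m", "f"):
            raise ValidationError(f"sex must be 'm' or 'f', got {self.sex!r}")
        if self.response not in RESPONSE_CATEGORIES:
            raise ValidationError(f"response must be one of {RESPONSE_CATEGORIES}")
        if self.os_days <= 0:
            raise ValidationError("os_days must be positive")
        if self.height is not None and self.height <= 0:
            raise ValidationError("height must be positive")
        if self.weight is not None and self.weight <= 0:
            raise ValidationError("weight must be positive")
        if self.risk is not None and self.risk not in ("low", "high"):
            raise ValidationError(f"risk must be 'low'/'high', got {self.risk!r}")


@dataclass
class CohortTable:
    """Ordered collection of patient records with unique ids."""

    records: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate patient_ids in cohort table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def by_id(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "sex": r.sex,
                    "age": r.age,
                    "height": r.height,
                    "weight": r.weight,
                    "dose_mbq": r.dose_mbq,
                    "response": r.response,
                    "os_days": r.os_days,
                    "died": int(r.died),
                    "risk": r.risk,
                }
                for r in self.records
            ]
        )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(v: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI; spacing goes to the header affine/zooms."""
    img = nib.Nifti1Image(np.asarray(v.values, dtype=np.float32), _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def load_volume(path: str | Path, modality: str) -> Volume:
    """Read a NIfTI file as a :class:`Volume` of the given modality."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several I/O error types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return Volume(
        values=np.asarray(data, dtype=np.float32),
        spacing=tuple(float(z) for z in zooms),
        modality=modality,
        origin=origin,
    )


def save_mask(mask: LesionMask, path: str | Path) -> None:
    """Write a lesion mask as an 8-bit integer NIfTI."""
    img = nib.Nifti1Image(
        mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def load_mask(
    path: str | Path,
    lesion_id: str,
    organ_region: str,
    adc_artifact: bool = False,
) -> LesionMask:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return LesionMask(
        values=data > 0,
        spacing=tuple(float(z) for z in zooms),
        lesion_id=lesion_id,
        organ_region=organ_region,
        adc_artifact=adc_artifact,
        origin=origin,
    )


# ---------------------------------------------------------------------------
# Cohort tables


def _parse_record(row: pd.Series) -> PatientRecord:
    def opt_float(key: str) -> float | None:
        val = row.get(key)
        if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
            return None
        return float(val)

    died_raw = row["died"]
    if isinstance(died_raw, str):
        died = died_raw.strip().lower() in ("1", "true", "yes", "died")
    else:
        died = bool(int(died_raw))
    risk = row.get("risk")
    if risk is not None and (not isinstance(risk, str) or risk.strip() == ""):
        risk = None
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        sex=str(row["sex"]).strip(),
        age=float(row["age"]),
        response=normalize_response(row["response"]),
        os_days=int(row["os_days"]),
        died=died,
        height=opt_float("height"),
        weight=opt_float("weight"),
        dose_mbq=opt_float("dose_mbq"),
        risk=risk.strip().lower() if isinstance(risk, str) else None,
        agent=str(row["agent"]) if "agent" in row and isinstance(row.get("agent"), str) else None,
    )


def load_cohort_table(path: str | Path) -> CohortTable:
    """Load a cohort CSV (one row per patient) into a :class:`CohortTable`."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty cohort file") from exc
    required = {"patient_id", "sex", "age", "response", "os_days", "died"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    return CohortTable([_parse_record(row) for _, row in df.iterrows()])


def save_cohort_table(table: CohortTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def table1_fixture() -> CohortTable:
    """The embedded 37-patient melanoma cohort (sex, age, agent, response,
    OS days, death marker, printed risk label).

    Heights, weights and injected doses were not published per patient and are
    left empty; synthetic cohorts fill them in.
    """
    with resources.files("melrisk.data").joinpath("table1.csv").open("rb") as fh:
        df = pd.read_csv(fh)
    return CohortTable([_parse_record(row) for _, row in df.iterrows()])


# ---------------------------------------------------------------------------
# Resampling


def resample_to_grid(
    v: Volume | LesionMask, target_spacing: Sequence[float]
) -> Volume | LesionMask:
    """Resample a volume to a new voxel spacing, preserving physical extent.

    Scalar volumes are interpolated trilinearly; masks nearest-neighbour.  The
    output grid covers the same physical extent to within one voxel.
    """
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise ValidationError(f"target spacing must be positive, got {target}")
    src = np.asarray(v.values, dtype=np.float32)
    old_spacing = v.spacing
    if target == tuple(old_spacing):
        return v
    new_shape = tuple(
        max(1, int(round(n * old_spacing[d] / target[d])))
        for d, n in enumerate(src.shape)
    )
    # sample at the physical location of each new voxel centre
    coords = np.meshgrid(
        *[
            (np.arange(n) * target[d]) / old_spacing[d]
            for d, n in enumerate(new_shape)
        ],
        indexing="ij",
    )
    order = 0 if isinstance(v, LesionMask) else 1
    out = ndimage.map_coordinates(
        src, np.stack(coords), order=order, mode="nearest"
    )
    if isinstance(v, LesionMask):
        return LesionMask(
            values=out > 0.5,
            spacing=target,
            lesion_id=v.lesion_id,
            organ_region=v.organ_region,
            adc_artifact=v.adc_artifact,
            origin=v.origin,
        )
    return replace(v, values=out.astype(np.float32), spacing=target)
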