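"""Training, leave-one-patient-out cross-validation and evaluation metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ..imaging_io import ValidationError
from ..quant_features import LesionFeatures, lesion_diameter_axial
from . import nn
from .model import ModelConfig, MultistreamModel
from .patches import (
    MODALITY_PAIRS,
    SUBSET_PAIRS,
    lesion_fov_crop,
    normalize_modality,
    sample_patch_positions,
    slice_patch,
    tile_patch_positions,
)

logger = logging.getLogger(__name__)

#: reference constants for standardising the anthropometric inputs
#: (height m, weight kg, lesion diameter mm) — fixed so folds share a scale
ANTHRO_REFERENCE = ((1.72, 0.09), (78.0, 14.0), (30.0, 20.0))

PATCH = 32


class LeakageError(RuntimeError):
    """Raised when train and evaluation patient sets overlap."""


@dataclass
class SampleSet:
    """A batch-ready collection of slice-triple samples."""

    pet: np.ndarray  # (M, 3, 32, 32)
    anat: np.ndarray  # (M, 3, 32, 32)
    anthro: np.ndarray  # (M, 3)
    labels: np.ndarray  # (M,) int — 1 = low risk
    patient_ids: np.ndarray  # (M,) str
    pair_tags: np.ndarray  # (M,) str
    lesion_ids: np.ndarray  # (M,) str

    def __len__(self) -> int:
        return len(self.labels)

    def lesion_keys(self) -> set[tuple[str, str]]:
        return set(zip(self.patient_ids.tolist(), self.lesion_ids.tolist()))

    @staticmethod
    def concatenate(sets: Sequence["SampleSet"]) -> "SampleSet":
        sets = [s for s in sets if len(s)]
        return SampleSet(
            pet=np.concatenate([s.pet for s in sets]),
            anat=np.concatenate([s.anat for s in sets]),
            anthro=np.concatenate([s.anthro for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            patient_ids=np.concatenate([s.patient_ids for s in sets]),
            pair_tags=np.concatenate([s.pair_tags for s in sets]),
            lesion_ids=np.concatenate([s.lesion_ids for s in sets]),
        )


def standardize_anthro(height_m: float, weight_kg: float, dm_mm: float) -> np.ndarray:
    vals = (height_m, weight_kg, dm_mm)
    return np.array(
        [(v - m) / s for v, (m, s) in zip(vals, ANTHRO_REFERENCE)],
        dtype=np.float32,
    )


def _lesion_center_mm(mask) -> tuple[float, float, float]:
    idx = mask.indices().mean(axis=0)
    return tuple(
        float(mask.origin[d] + idx[d] * mask.spacing[d]) for d in range(3)
    )


@dataclass
class LesionBlocks:
    """Cached, normalised lesion field-of-view blocks for one lesion."""

    patient_id: str
    lesion_id: str
    blocks: dict[str, np.ndarray]
    pairs: list[str]
    anthro: np.ndarray
    label: int

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.blocks.values())).shape


def prepare_lesion_blocks(case, lesion_id: str, config: ModelConfig) -> LesionBlocks:
    """Crop and normalise the lesion FOV once; patch sampling reuses it.

    The PET_MR+ADC pair is dropped for lesions with an ADC artifact.
    """
    mask = next(m for m in case.lesions if m.lesion_id == lesion_id)
    pairs = [
        tag
        for tag in SUBSET_PAIRS[config.modality_subset]
        if not (tag == "PET_MR+ADC" and mask.adc_artifact)
    ]
    if not pairs:
        raise ValidationError("no usable modality pairs for this lesion")
    needed = sorted({m for tag in pairs for m in MODALITY_PAIRS[tag]})
    center = _lesion_center_mm(mask)
    blocks = lesion_fov_crop(
        {m: case.volumes[m] for m in needed},
        center,
        extent_mm=config.fov_extent_mm,
        working_spacing_mm=config.working_spacing_mm,
    )
    blocks = {m: normalize_modality(b, m) for m, b in blocks.items()}
    dm = lesion_diameter_axial(mask)
    rec = case.record
    anthro = standardize_anthro(
        rec.height if rec.height is not None else ANTHRO_REFERENCE[0][0],
        rec.weight if rec.weight is not None else ANTHRO_REFERENCE[1][0],
        dm,
    )
    return LesionBlocks(
        patient_id=case.record.patient_id,
        lesion_id=lesion_id,
        blocks=blocks,
        pairs=pairs,
        anthro=anthro,
        label=1 if case.risk == "low" else 0,
    )


def samples_from_blocks(
    lb: LesionBlocks, positions: np.ndarray, config: ModelConfig
) -> SampleSet:
    """Slice 32^3 patches at the given positions into slice-triple samples.

    ``config.slice_offsets`` selects explicit triple indices; otherwise
    ``config.slice_stride`` keeps every k-th triple of each patch (centred,
    so that the retained slices cover the middle of the patch).
    """
    if config.slice_offsets is not None:
        sl = list(config.slice_offsets)
    else:
        stride = max(1, config.slice_stride)
        offset = (PATCH % stride) // 2 + (stride // 2 if stride > 1 else 0)
        sl = slice(offset, None, stride)
    pet_parts, anat_parts, tags = [], [], []
    for tag in lb.pairs:
        pet_mod, anat_mod = MODALITY_PAIRS[tag]
        for i, j, k in positions:
            p3 = lb.blocks[pet_mod][i : i + PATCH, j : j + PATCH, k : k + PATCH]
            a3 = lb.blocks[anat_mod][i : i + PATCH, j : j + PATCH, k : k + PATCH]
            pet_parts.append(slice_patch(p3)[sl])
            anat_parts.append(slice_patch(a3)[sl])
            tags.extend([tag] * pet_parts[-1].shape[0])
    pet = np.concatenate(pet_parts)
    anat = np.concatenate(anat_parts)
    m = len(pet)
    return SampleSet(
        pet=pet,
        anat=anat,
        anthro=np.tile(lb.anthro, (m, 1)),
        labels=np.full(m, lb.label, dtype=int),
        patient_ids=np.full(m, lb.patient_id, dtype=object),
        pair_tags=np.asarray(tags, dtype=object),
        lesion_ids=np.full(m, lb.lesion_id, dtype=object),
    )


def build_lesion_samples(
    case,
    lesion_id: str,
    config: ModelConfig,
    seed: int,
    positions: np.ndarray | None = None,
) -> SampleSet:
    """Assemble slice-triple samples for one lesion of one patient.

    When ``positions`` is None, ``config.patches_per_patient`` random 32^3
    patch positions are drawn with the given seed; otherwise the supplied
    (deterministic) positions are used.  One sample is one co-indexed
    (axial, coronal, sagittal) slice triple of one modality pair.
    """
    lb = prepare_lesion_blocks(case, lesion_id, config)
    if positions is None:
        positions = sample_patch_positions(lb.shape, config.patches_per_patient, seed)
    return samples_from_blocks(lb, positions, config)


def _eval_positions(shape: tuple[int, int, int], config: ModelConfig) -> np.ndarray:
    pos = tile_patch_positions(shape, config.eval_tile_stride)
    if len(pos) > config.max_eval_patches:
        step = len(pos) / config.max_eval_patches
        pos = pos[(np.arange(config.max_eval_patches) * step).astype(int)]
    return pos


def build_eval_samples(case, lesion_id: str, config: ModelConfig) -> SampleSet:
    """Deterministically tiled samples (stride ``config.eval_tile_stride``)
    for a validation or test lesion, capped at ``config.max_eval_patches``."""
    lb = prepare_lesion_blocks(case, lesion_id, config)
    return samples_from_blocks(lb, _eval_positions(lb.shape, config), config)


# ---------------------------------------------------------------------------
# lesion selection


def select_validation_lesion(
    lesions: Sequence[LesionFeatures],
) -> tuple[str, bool]:
    """Validation lesion: second-highest SULpeak with diameter >= 10 mm.

    Lesions are ranked by SULpeak; the top lesion is the training target and
    is skipped; the next lesion with a diameter of at least 10 mm is chosen.
    Returns ``(lesion_id, fallback)`` — when no second lesion qualifies the
    highest-uptake lesion itself is reused, flagged.
    """
    eligible = [l for l in lesions if l.sul_peak is not None]
    if not eligible:
        raise ValidationError("no lesion with a defined SULpeak")
    ranked = sorted(eligible, key=lambda l: -l.sul_peak)
    for cand in ranked[1:]:
        if cand.dm_mm >= 10.0:
            return cand.lesion_id, False
    return ranked[0].lesion_id, True


# ---------------------------------------------------------------------------
# training


def train(
    model: MultistreamModel,
    train_samples: SampleSet,
    val_samples: SampleSet | None,
    config: ModelConfig,
) -> dict:
    """Minimise categorical cross-entropy with Adam; returns the history.

    Validation lesions come from the training patients (their
    second-highest-uptake lesions), so disjointness is enforced at the
    (patient, lesion) level: no lesion may appear in both sets.

    After the last epoch the batch-norm running statistics are recalibrated
    with one exact pass over the training samples ("precise BN"): with few
    optimisation steps the momentum-averaged statistics lag the final
    weights, which otherwise distorts inference-mode predictions.
    """
    if val_samples is not None and len(val_samples):
        overlap = train_samples.lesion_keys() & val_samples.lesion_keys()
        if overlap:
            raise LeakageError(f"lesions in both train and val: {sorted(overlap)}")
    rng = np.random.default_rng(config.seed + 17)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    n = len(train_samples)
    if val_samples is not None and config.max_val_samples == 0:
        val_samples = None
    if val_samples is not None and len(val_samples) > config.max_val_samples > 0:
        keep = (
            np.arange(config.max_val_samples)
            * (len(val_samples) / config.max_val_samples)
        ).astype(int)
        val_samples = SampleSet(
            pet=val_samples.pet[keep],
            anat=val_samples.anat[keep],
            anthro=val_samples.anthro[keep],
            labels=val_samples.labels[keep],
            patient_ids=val_samples.patient_ids[keep],
            pair_tags=val_samples.pair_tags[keep],
            lesion_ids=val_samples.lesion_ids[keep],
        )
    class_weights = None
    if config.class_balanced_loss:
        # inverse class frequency: leaving one patient out otherwise biases
        # the training prior against the held-out patient's class
        counts = np.bincount(train_samples.labels, minlength=2).astype(float)
        counts[counts == 0] = 1.0
        class_weights = len(train_samples.labels) / (2.0 * counts)
    history: dict = {"train_loss": [], "val_loss": []}
    steps_per_epoch = max(1, sum(
        1 for s in range(0, n, config.batch_size)
        if min(config.batch_size, n - s) >= 2
    ))
    total_steps = steps_per_epoch * config.epochs
    avg_from = (
        int(total_steps * (1.0 - config.weight_average_tail))
        if config.weight_average_tail > 0
        else total_steps + 1
    )
    avg_weights = None
    avg_count = 0
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs at least 2 samples
            x_pet = train_samples.pet[idx]
            x_anat = train_samples.anat[idx]
            if config.augment_flips:
                # random in-plane flips, applied jointly to the co-registered
                # pair so the sample stays geometrically consistent
                codes = rng.integers(0, 4, size=len(idx))
                x_pet, x_anat = x_pet.copy(), x_anat.copy()
                for code, axis in ((1, -1), (2, -2)):
                    m = (codes & code).astype(bool)
                    x_pet[m] = np.flip(x_pet[m], axis=axis)
                    x_anat[m] = np.flip(x_anat[m], axis=axis)
            logits = model.forward(
                x_pet,
                x_anat,
                train_samples.anthro[idx],
                train=True,
            )
            batch_labels = train_samples.labels[idx]
            loss, dlogits = nn.softmax_cross_entropy(
                logits,
                batch_labels,
                weights=None if class_weights is None else class_weights[batch_labels],
            )
            model.backward(dlogits)
            if config.cosine_lr_decay:
                opt.lr = config.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * step / max(1, total_steps))
                )
            opt.step()
            step += 1
            if step >= avg_from:
                if avg_weights is None:
                    avg_weights = [w.astype(np.float64) for w, _ in opt.params]
                else:
                    for acc, (w, _) in zip(avg_weights, opt.params):
                        acc += w
                avg_count += 1
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if val_samples is not None and len(val_samples):
            logits = []
            for i in range(0, len(val_samples), 64):
                logits.append(
                    model.forward(
                        val_samples.pet[i : i + 64],
                        val_samples.anat[i : i + 64],
                        val_samples.anthro[i : i + 64],
                        train=False,
                    )
                )
            vloss, _ = nn.softmax_cross_entropy(
                np.concatenate(logits), val_samples.labels
            )
            history["val_loss"].append(float(vloss))

    if avg_weights is not None and avg_count > 0:
        # tail weight averaging: replace weights with the mean over the
        # final steps before recalibrating batch norm
        for acc, (w, _) in zip(avg_weights, opt.params):
            w[...] = (acc / avg_count).astype(np.float32)

    # precise-BN pass: exact running statistics under the final weights,
    # with dropout disabled
    bn_layers = [m for m in model.modules() if isinstance(m, nn.BatchNorm)]
    drop_layers = [
        d
        for d in _dropout_layers(model)
    ]
    saved_rates = [d.rate for d in drop_layers]
    for d in drop_layers:
        d.rate = 0.0
    for bn in bn_layers:
        bn.begin_recalibration()
    order = np.arange(n)
    for start in range(0, n, max(config.batch_size, 2)):
        idx = order[start : start + max(config.batch_size, 2)]
        if len(idx) < 2:
            continue
        model.forward(
            train_samples.pet[idx],
            train_samples.anat[idx],
            train_samples.anthro[idx],
            train=True,
        )
    for bn in bn_layers:
        bn.finish_recalibration()
    for d, r in zip(drop_layers, saved_rates):
        d.rate = r
    return history


def _dropout_layers(model: MultistreamModel):
    out = []
    for branch in (model.pet_branch, model.anat_branch):
        for blk in branch.blocks:
            out.append(blk.drop)
    return out


def predict_patient(
    model: MultistreamModel, samples: SampleSet
) -> tuple[float, str]:
    """Mean softmax probability of low risk over all patch samples and
    modality pairs; threshold 0.5, ties resolved to high risk."""
    if not len(samples):
        raise ValidationError("no samples for patient prediction")
    probs = model.predict_proba(samples.pet, samples.anat, samples.anthro)
    p_low = float(probs[:, 1].mean())
    return p_low, ("low" if p_low > 0.5 else "high")


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ConfusionMetrics:
    """Confusion counts and rates; the positive class is low risk."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    accuracy: float | None


def confusion_metrics(
    predictions: Sequence[str], labels: Sequence[str]
) -> ConfusionMetrics:
    if len(predictions) != len(labels):
        raise ValidationError("prediction/label length mismatch")
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    tp = int(((pred == "low") & (lab == "low")).sum())
    tn = int(((pred == "high") & (lab == "high")).sum())
    fp = int(((pred == "low") & (lab == "high")).sum())
    fn = int(((pred == "high") & (lab == "low")).sum())

    def rate(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return ConfusionMetrics(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        sensitivity=rate(tp, tp + fn),
        specificity=rate(tn, tn + fp),
        ppv=rate(tp, tp + fp),
        accuracy=rate(tp + tn, tp + tn + fp + fn),
    )


# ---------------------------------------------------------------------------
# leave-one-patient-out cross-validation


def _case_target_and_validation(case, lesion_features) -> tuple[str, str]:
    from ..quant_features import select_target_lesion

    target = select_target_lesion(lesion_features)
    val, _ = select_validation_lesion(
        [l for l in lesion_features if l.lesion_id != target] or lesion_features
    ) if len(lesion_features) > 1 else (target, True)
    return target, val


def loocv(
    cases: Sequence,
    config: ModelConfig,
    label_override: dict[str, str] | None = None,
    checkpoint_dir: str | None = None,
) -> tuple[pd.DataFrame, ConfusionMetrics]:
    """n-fold leave-one-patient-out cross-validation.

    Each fold trains a fresh seeded model on every other patient's target
    lesion (``config.patches_per_patient`` seeded random patches each,
    validation loss monitored on the second-highest-uptake lesions of the
    training patients) and tests on the held-out patient's target lesion.
    ``label_override`` substitutes risk labels (used for permutation nulls).
    Returns the per-patient prediction table and pooled confusion metrics.
    """
    from ..pipeline import case_lesion_features

    if len(cases) < 3:
        raise ValidationError("cohort too small for cross-validation")
    ids = [c.record.patient_id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate patient ids")

    def case_label(case) -> str:
        if label_override is not None:
            return label_override[case.record.patient_id]
        return case.risk

    # feature extraction once per patient
    lesions = {c.record.patient_id: case_lesion_features(c) for c in cases}
    targets: dict[str, tuple[str, str]] = {}
    for c in cases:
        feats = [l for l in lesions[c.record.patient_id] if l.sul_peak is not None]
        if not feats:
            raise ValidationError(
                f"patient {c.record.patient_id} has no lesion with functional parameters"
            )
        from ..quant_features import select_target_lesion

        target = select_target_lesion(feats)
        rest = [l for l in feats if l.lesion_id != target]
        if rest:
            val_id, _ = select_validation_lesion(rest)
        else:
            val_id = target
        targets[c.record.patient_id] = (target, val_id)

    # FOV blocks and tiled evaluation samples are deterministic per lesion:
    # prepare them once and reuse across folds
    case_by_id = {c.record.patient_id: c for c in cases}
    target_blocks: dict[str, LesionBlocks] = {}
    val_eval: dict[str, SampleSet | None] = {}
    test_eval: dict[str, SampleSet] = {}
    for c in cases:
        pid = c.record.patient_id
        tgt, val_id = targets[pid]
        lb = prepare_lesion_blocks(c, tgt, config)
        target_blocks[pid] = lb
        test_eval[pid] = samples_from_blocks(lb, _eval_positions(lb.shape, config), config)
        if val_id != tgt:
            vb = prepare_lesion_blocks(c, val_id, config)
            val_eval[pid] = samples_from_blocks(vb, _eval_positions(vb.shape, config), config)
        else:
            val_eval[pid] = None
    if label_override is not None:
        for pid in case_by_id:
            lab = 1 if case_label(case_by_id[pid]) == "low" else 0
            target_blocks[pid].label = lab
            test_eval[pid].labels[:] = lab
            if val_eval[pid] is not None:
                val_eval[pid].labels[:] = lab

    rows = []
    master = np.random.default_rng(config.seed)
    fold_seeds = master.integers(0, 2**31 - 1, size=len(cases))
    for fold, held_out in enumerate(cases):
        hid = held_out.record.patient_id
        train_cases = [c for c in cases if c.record.patient_id != hid]
        fold_cfg = replace(config, seed=int(fold_seeds[fold]))
        patch_rng = np.random.default_rng(fold_cfg.seed + 1)
        train_sets, val_sets = [], []
        for c in train_cases:
            pid = c.record.patient_id
            lb = target_blocks[pid]
            positions = sample_patch_positions(
                lb.shape, config.patches_per_patient,
                int(patch_rng.integers(0, 2**31 - 1)),
            )
            train_sets.append(samples_from_blocks(lb, positions, fold_cfg))
            if val_eval[pid] is not None:
                val_sets.append(val_eval[pid])
        train_samples = SampleSet.concatenate(train_sets)
        val_samples = SampleSet.concatenate(val_sets) if val_sets else None
        if hid in set(train_samples.patient_ids):
            raise LeakageError(f"fold {fold}: held-out patches leaked into training")
        model = MultistreamModel(fold_cfg)
        train(model, train_samples, val_samples, fold_cfg)
        if checkpoint_dir is not None:
            from pathlib import Path

            from .model import save_checkpoint

            ckpt = Path(checkpoint_dir)
            ckpt.mkdir(parents=True, exist_ok=True)
            save_checkpoint(model, ckpt / f"fold_{fold:02d}.npz")
        p_low, pred = predict_patient(model, test_eval[hid])
        if config.calibrate_threshold:
            # place the decision threshold midway between the class-mean
            # patient-level probabilities of the training patients (their own
            # target lesions; the held-out patient is not involved)
            low_p, high_p = [], []
            for c in train_cases:
                pid = c.record.patient_id
                p_train, _ = predict_patient(model, test_eval[pid])
                (low_p if case_label(c) == "low" else high_p).append(p_train)
            if low_p and high_p:
                threshold = (float(np.mean(low_p)) + float(np.mean(high_p))) / 2.0
                pred = "low" if p_low > threshold else "high"
        rows.append(
            {
                "patient_id": hid,
                "fold": fold,
                "prob_low": p_low,
                "predicted": pred,
                "label": case_label(held_out),
            }
        )
        logger.info("fold %d: patient %s p(low)=%.3f -> %s", fold, hid, p_low, pred)
    preds = pd.DataFrame(rows)
    metrics = confusion_metrics(preds["predicted"], preds["label"])
    return preds, metrics


def modality_ablation(
    cases: Sequence, config: ModelConfig
) -> dict[str, ConfusionMetrics]:
    """Re-run LOOCV per modality subset (both, PET_CT+CT, PET_MR+MR)."""
    out = {}
    for subset in ("both", "PET_CT+CT", "PET_MR+MR"):
        _, metrics = loocv(cases, replace(config, modality_subset=subset))
        out[subset] = metrics
    return out
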