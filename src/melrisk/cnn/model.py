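"""The multistream risk-classification network.

Two branches — one for the PET streams, one for the anatomical (CT / VIBE /
ADC) streams — each consisting of three parallel per-orientation feature
extractors (two sequential squeeze-and-excitation blocks on 32x32 2D slices),
whose feature maps are concatenated and processed by three wide residual
blocks with an increasing channel schedule, then globally average-pooled.
The pooled branch features are concatenated with three standardised
anthropometric scalars (height, weight, target-lesion diameter) and fed to a
three-layer dense head with a binary softmax (low vs. high risk).

Working in 2D on co-indexed axial/coronal/sagittal slice triples keeps the
parameter count near 1.8 million under the frozen default configuration while
still aggregating 3D context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..imaging_io import ValidationError
from . import nn


@dataclass
class ModelConfig:
    """Network and training configuration.

    The default channel schedule is frozen: extractor channels 8 (SE
    attention reduction 2), wide-residual widths (48, 96, 192) and dense head
    (128, 32, 2), which instantiates ~1.8 M trainable parameters.
    """

    extractor_channels: int = 8
    se_reduction: int = 2
    widths: tuple[int, int, int] = (48, 96, 192)
    dense: tuple[int, int, int] = (128, 32, 2)
    dropout: float = 0.1
    learning_rate: float = 5e-4
    batch_size: int = 32
    epochs: int = 150
    seed: int = 0
    modality_subset: str = "both"  # both | PET_CT+CT | PET_MR+MR
    # sampling geometry
    patches_per_patient: int = 384
    fov_extent_mm: tuple[float, float, float] = (132.0, 160.0, 250.0)
    working_spacing_mm: float = 2.0
    slice_stride: int = 1  # keep every k-th slice triple of a 3D patch
    slice_offsets: tuple[int, ...] | None = None  # explicit triple indices (overrides stride)
    eval_tile_stride: int = 16  # deterministic tiling for validation/test
    max_eval_patches: int = 64  # cap on tiled evaluation patches per lesion
    max_val_samples: int = 256  # cap on per-epoch validation-loss samples (0 = skip)
    cosine_lr_decay: bool = False  # decay lr to ~0 over the training run
    weight_average_tail: float = 0.0  # fraction of final steps averaged (Polyak)
    augment_flips: bool = False  # random in-plane flips of each training sample
    class_balanced_loss: bool = False  # weight the loss by inverse class frequency
    calibrate_threshold: bool = False  # per-fold decision threshold from train patients

    def __post_init__(self) -> None:
        if not (self.widths[0] < self.widths[1] < self.widths[2]):
            raise ValidationError(
                f"wide-residual channel schedule must be strictly increasing, got {self.widths}"
            )
        if self.dense[-1] != 2:
            raise ValidationError("final dense layer must have width 2")
        if self.modality_subset not in ("both", "PET_CT+CT", "PET_MR+MR"):
            raise ValidationError(f"unknown modality subset {self.modality_subset!r}")
        if self.extractor_channels < 2:
            raise ValidationError("extractor needs at least 2 channels")


class SEBlock:
    """Two 3x3 convolutions (BN + ReLU) gated by channel attention.

    The attention path global-average-pools the convolutional output, passes
    it through a two-layer bottleneck (ReLU, then sigmoid) and rescales the
    channels.
    """

    def __init__(self, cin: int, ch: int, reduction: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(cin, ch, rng)
        self.bn1 = nn.BatchNorm(ch)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(ch, ch, rng)
        self.bn2 = nn.BatchNorm(ch)
        self.relu2 = nn.ReLU()
        hidden = max(1, ch // reduction)
        self.fc1 = nn.Dense(ch, hidden, rng)
        self.att_relu = nn.ReLU()
        self.fc2 = nn.Dense(hidden, ch, rng)
        self.att_sig = nn.Sigmoid()
        self.gap = nn.GlobalAvgPool2d()

    def modules(self):
        return [self.conv1, self.bn1, self.conv2, self.bn2, self.fc1, self.fc2]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x), train))
        h = self.relu2.forward(self.bn2.forward(self.conv2.forward(h), train))
        s = self.att_sig.forward(
            self.fc2.forward(self.att_relu.forward(self.fc1.forward(self.gap.forward(h))))
        )
        self._h, self._s = h, s
        return h * s[:, None, None, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, s = self._h, self._s
        dh = dout * s[:, None, None, :]
        ds = (dout * h).sum(axis=(1, 2))
        dgap = self.fc1.backward(
            self.att_relu.backward(self.fc2.backward(self.att_sig.backward(ds)))
        )
        dh = dh + self.gap.backward(dgap)
        dh = self.conv2.backward(self.bn2.backward(self.relu2.backward(dh)))
        return self.conv1.backward(self.bn1.backward(self.relu1.backward(dh)))


class Extractor:
    """Per-orientation feature extractor: two sequential SE blocks."""

    def __init__(self, ch: int, reduction: int, rng: np.random.Generator):
        self.se1 = SEBlock(1, ch, reduction, rng)
        self.se2 = SEBlock(ch, ch, reduction, rng)

    def modules(self):
        return self.se1.modules() + self.se2.modules()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.se2.forward(self.se1.forward(x, train), train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.se1.backward(self.se2.backward(dout))


class WideResBlock:
    """conv-BN-ReLU-dropout-conv main path plus a 3x3 convolutional residual
    path; the merged maps pass through BN + ReLU."""

    def __init__(self, cin: int, cout: int, p_drop: float, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(cin, cout, rng)
        self.bn1 = nn.BatchNorm(cout)
        self.relu1 = nn.ReLU()
        self.drop = nn.Dropout(p_drop, rng)
        self.conv2 = nn.Conv2d(cout, cout, rng)
        self.conv_res = nn.Conv2d(cin, cout, rng)
        self.bn_merge = nn.BatchNorm(cout)
        self.relu_merge = nn.ReLU()

    def modules(self):
        return [self.conv1, self.bn1, self.conv2, self.conv_res, self.bn_merge]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        a = self.relu1.forward(self.bn1.forward(self.conv1.forward(x), train))
        a = self.conv2.forward(self.drop.forward(a, train))
        r = self.conv_res.forward(x)
        return self.relu_merge.forward(self.bn_merge.forward(a + r, train))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dm = self.bn_merge.backward(self.relu_merge.backward(dout))
        dx = self.conv_res.backward(dm)
        da = self.drop.backward(self.conv2.backward(dm))
        dx += self.conv1.backward(self.bn1.backward(self.relu1.backward(da)))
        return dx


class Branch:
    """One modality branch: 3 orientation extractors -> concat -> 3 wide
    residual blocks -> global average pooling."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        ch = config.extractor_channels
        self.extractors = [
            Extractor(ch, config.se_reduction, rng) for _ in range(3)
        ]
        cin = 3 * ch
        self.blocks = []
        for cout in config.widths:
            self.blocks.append(WideResBlock(cin, cout, config.dropout, rng))
            cin = cout
        self.gap = nn.GlobalAvgPool2d()

    def modules(self):
        mods = []
        for e in self.extractors:
            mods += e.modules()
        for b in self.blocks:
            mods += b.modules()
        return mods

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # x: (N, 3, H, W) — one 1-channel image per orientation
        feats = [
            e.forward(np.ascontiguousarray(x[:, i])[..., None], train)
            for i, e in enumerate(self.extractors)
        ]
        h = np.concatenate(feats, axis=-1)
        self._split = [f.shape[-1] for f in feats]
        for b in self.blocks:
            h = b.forward(h, train)
        return self.gap.forward(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.gap.backward(dout)
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        dxs = []
        start = 0
        for e, width in zip(self.extractors, self._split):
            dxs.append(e.backward(dh[..., start : start + width]))
            start += width
        return np.stack([d[..., 0] for d in dxs], axis=1)


class MultistreamModel:
    """Full two-branch network with anthropometric fusion head."""

    N_ANTHRO = 3  # height, weight, target-lesion diameter (standardised)

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.pet_branch = Branch(config, rng)
        self.anat_branch = Branch(config, rng)
        feat_dim = 2 * config.widths[-1] + self.N_ANTHRO
        d1, d2, d3 = config.dense
        self.dense1 = nn.Dense(feat_dim, d1, rng)
        self.relu1 = nn.ReLU()
        self.dense2 = nn.Dense(d1, d2, rng)
        self.relu2 = nn.ReLU()
        self.dense3 = nn.Dense(d2, d3, rng)
        self.dropout_rng = rng

    def modules(self):
        return (
            self.pet_branch.modules()
            + self.anat_branch.modules()
            + [self.dense1, self.dense2, self.dense3]
        )

    def params(self):
        out = []
        for m in self.modules():
            out += m.params()
        return out

    def parameter_count(self) -> int:
        """Total number of trainable parameters (weights, biases, BN scales)."""
        return int(sum(w.size for w, _ in self.params()))

    def forward(
        self,
        x_pet: np.ndarray,
        x_anat: np.ndarray,
        anthro: np.ndarray,
        train: bool = False,
    ) -> np.ndarray:
        """Logits (N, 2); class index 1 is the low-risk class."""
        f_pet = self.pet_branch.forward(x_pet.astype(np.float32), train)
        f_anat = self.anat_branch.forward(x_anat.astype(np.float32), train)
        fused = np.concatenate([f_pet, f_anat, anthro.astype(np.float32)], axis=1)
        self._dims = (f_pet.shape[1], f_anat.shape[1])
        h = self.relu1.forward(self.dense1.forward(fused))
        h = self.relu2.forward(self.dense2.forward(h))
        return self.dense3.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.dense2.backward(self.relu2.backward(self.dense3.backward(dlogits)))
        dfused = self.dense1.backward(self.relu1.backward(dh))
        p, a = self._dims
        self.pet_branch.backward(dfused[:, :p])
        self.anat_branch.backward(dfused[:, p : p + a])

    def predict_proba(
        self, x_pet: np.ndarray, x_anat: np.ndarray, anthro: np.ndarray,
        batch_size: int = 64,
    ) -> np.ndarray:
        """Softmax probabilities in inference mode, batched."""
        out = []
        for i in range(0, len(x_pet), batch_size):
            logits = self.forward(
                x_pet[i : i + batch_size],
                x_anat[i : i + batch_size],
                anthro[i : i + batch_size],
                train=False,
            )
            out.append(nn.softmax(logits))
        return np.concatenate(out, axis=0)


def _state_arrays(model: "MultistreamModel") -> list[np.ndarray]:
    arrays = [w for w, _ in model.params()]
    for m in model.modules():
        if isinstance(m, nn.BatchNorm):
            arrays += [m.running_mean, m.running_var]
    return arrays


def save_checkpoint(model: "MultistreamModel", path) -> None:
    """Serialise all weights and batch-norm running statistics."""
    arrays = _state_arrays(model)
    np.savez_compressed(path, **{f"a{i}": a for i, a in enumerate(arrays)})


def load_checkpoint(model: "MultistreamModel", path) -> None:
    data = np.load(path)
    arrays = _state_arrays(model)
    if len(data.files) != len(arrays):
        raise ValidationError("checkpoint does not match the model configuration")
    for i, a in enumerate(arrays):
        a[...] = data[f"a{i}"]


def build_model(config: ModelConfig) -> tuple[MultistreamModel, int]:
    """Instantiate the network and report its trainable-parameter count."""
    model = MultistreamModel(config)
    return model, model.parameter_count()
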