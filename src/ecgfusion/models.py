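"""The four classifier architectures and their fusion variants.

Each architecture is a backbone mapping a 128x128x3 scalogram image to an
embedding, followed by either a plain linear 4-way classifier (pure-image
variant) or a fusion head that concatenates the embedding with the
handcrafted feature vector and passes it through two fully connected layers
(256 then 64 units, ReLU, dropout 0.3) before the 4-way softmax.

Backbones:

* ``simple_cnn`` — three conv layers, kernels 5/3/3, max-pool 2 after each,
  dropout 0.3, fully connected 128-unit embedding. The stated 5x1/3x1
  kernel notation is resolved as square kernels in image mode; the literal
  1-D kernels are kept behind ``input_mode="sequence"``.
* ``resnet18`` — the standard 18-layer residual topology (initial 7x7/2
  conv, four stages of two basic blocks at 64/128/256/512 channels, global
  average pooling) with dropout 0.5 before the classifier. No pretrained
  weights.
* ``cnn_transformer`` — two conv blocks (64, 128 filters, kernel 3) with
  pooling down to an 8x8 token grid, projected to model dim 256 and encoded
  by 4 transformer layers (8 heads, feed-forward 512, dropout 0.2);
  mean-pooled tokens form the embedding.
* ``vit`` — patch size 16 (64 patches + class token = 65 tokens), 12
  encoder layers, 12 heads, hidden 768, feed-forward 3072, dropout 0.1,
  layer normalization before the head; the class token is the embedding.

Weight initialization is Kaiming-uniform from a seeded generator, so every
build is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .ecg_io import ValidationError
from .nn import Tensor

ARCHITECTURES = ("simple_cnn", "resnet18", "cnn_transformer", "vit")

N_CLASSES = 4

#: Per-architecture hyperparameters.
DEFAULT_HYPERS: dict[str, dict] = {
    "simple_cnn": {"kernels": (5, 3, 3), "filters": (8, 16, 32), "pool": 2,
                   "dropout": 0.3, "fc": 128},
    "resnet18": {"stages": (64, 128, 256, 512), "blocks_per_stage": 2,
                 "dropout": 0.5},
    "cnn_transformer": {"conv_filters": (64, 128), "kernel": 3,
                        "encoder_layers": 4, "heads": 8, "hidden": 256,
                        "ff": 512, "dropout": 0.2},
    "vit": {"patch": 16, "layers": 12, "heads": 12, "hidden": 768,
            "ff": 3072, "dropout": 0.1},
}


@dataclass
class ModelConfig:
    """Architecture + fusion settings.

    ``hyper`` starts from the architecture's specified values
    (:data:`DEFAULT_HYPERS`) and explicit entries override them.
    """

    arch: str = "simple_cnn"
    fusion: bool = False
    handcrafted_dim: int = 509
    image_size: tuple[int, int, int] = (128, 128, 3)
    n_classes: int = N_CLASSES
    seed: int = 0
    input_mode: str = "image"  # "sequence" enables the literal 1-D kernels
    hyper: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arch not in ARCHITECTURES:
            raise ValidationError(f"unknown architecture {self.arch!r}")
        if self.n_classes != N_CLASSES:
            raise ValidationError(f"this task has {N_CLASSES} classes")
        merged = dict(DEFAULT_HYPERS[self.arch])
        merged.update(self.hyper)
        self.hyper = merged
        if self.arch == "vit":
            p = self.hyper["patch"]
            h, w, _ = self.image_size
            if h % p or w % p:
                raise ValidationError(
                    f"image size {h}x{w} not divisible by ViT patch size {p}"
                )


# ---------------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------------

class SimpleCNNBackbone(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        hp = cfg.hyper
        seq = cfg.input_mode == "sequence"
        c_in = 1 if seq else cfg.image_size[2]
        kernels = [(k, 1) if seq else k for k in hp["kernels"]]
        pool = (hp["pool"], 1) if seq else hp["pool"]
        filters = hp["filters"]
        self.conv1 = nn.Conv2d(c_in, filters[0], kernels[0], rng)
        self.conv2 = nn.Conv2d(filters[0], filters[1], kernels[1], rng)
        self.conv3 = nn.Conv2d(filters[1], filters[2], kernels[2], rng)
        self.pool = nn.MaxPool2d(pool)
        self.drop = nn.Dropout(hp["dropout"], rng)
        if seq:
            h = hp.get("seq_len", 8527)
            wdim = 1
        else:
            h, wdim = cfg.image_size[:2]
        for k in hp["kernels"]:
            h = (h - k + 1) // hp["pool"]
            if not seq:
                wdim = (wdim - k + 1) // hp["pool"]
        flat = filters[2] * h * wdim
        self.fc = nn.Linear(flat, hp["fc"], rng)
        self.embed_dim = hp["fc"]
        object.__setattr__(self, "cam_layer", self.conv3)

    def forward(self, x: Tensor) -> Tensor:
        x = self.pool(self.conv1(x).relu())
        x = self.pool(self.conv2(x).relu())
        x = self.pool(self.conv3(x).relu())
        n = x.shape[0]
        return self.drop(self.fc(x.reshape(n, -1)).relu())


class BasicBlock(nn.Module):
    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.down_conv = nn.Conv2d(c_in, c_out, 1, rng, stride=stride, bias=False)
            self.down_bn = nn.BatchNorm2d(c_out)
        else:
            self.down_conv = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        identity = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + identity).relu()


class ResNet18Backbone(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        hp = cfg.hyper
        stages = hp["stages"]
        self.stem_conv = nn.Conv2d(cfg.image_size[2], stages[0], 7, rng,
                                   stride=2, padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(stages[0])
        self.stem_pool = nn.MaxPool2d(3, stride=2, padding=1)
        blocks = []
        c_in = stages[0]
        for si, c_out in enumerate(stages):
            for bi in range(hp["blocks_per_stage"]):
                stride = 2 if (si > 0 and bi == 0) else 1
                blocks.append(BasicBlock(c_in, c_out, stride, rng))
                c_in = c_out
        self.blocks = nn.Sequential(*blocks)
        self.drop = nn.Dropout(hp["dropout"], rng)
        self.embed_dim = stages[-1]
        object.__setattr__(self, "cam_layer", blocks[-1].conv2)

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem_pool(self.stem_bn(self.stem_conv(x)).relu())
        x = self.blocks(x)
        x = x.mean(axis=(2, 3))  # global average pooling
        return self.drop(x)


class CNNTransformerBackbone(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        hp = cfg.hyper
        f1, f2 = hp["conv_filters"]
        k = hp["kernel"]
        self.conv1 = nn.Conv2d(cfg.image_size[2], f1, k, rng, padding=k // 2)
        self.conv2 = nn.Conv2d(f1, f2, k, rng, padding=k // 2)
        self.pool = nn.MaxPool2d(4)  # 128 -> 32 -> 8: an 8x8 = 64-token grid
        self.proj = nn.Linear(f2, hp["hidden"], rng)
        side = cfg.image_size[0] // 16
        self.pos = Tensor(
            (0.02 * rng.standard_normal((1, side * side, hp["hidden"]))).astype(np.float32),
            requires_grad=True,
        )
        self.encoders = nn.Sequential(*[
            nn.TransformerEncoderLayer(hp["hidden"], hp["heads"], hp["ff"], rng,
                                       hp["dropout"])
            for _ in range(hp["encoder_layers"])
        ])
        self.embed_dim = hp["hidden"]
        object.__setattr__(self, "cam_layer", self.conv2)

    def forward(self, x: Tensor) -> Tensor:
        x = self.pool(self.conv1(x).relu())
        x = self.pool(self.conv2(x).relu())
        n, c, h, w = x.shape
        tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)  # (n, 64, c)
        tokens = self.proj(tokens) + self.pos
        tokens = self.encoders(tokens)
        return tokens.mean(axis=1)


class ViTBackbone(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        hp = cfg.hyper
        p, d = hp["patch"], hp["hidden"]
        self.patch_embed = nn.Conv2d(cfg.image_size[2], d, p, rng, stride=p)
        side = cfg.image_size[0] // p
        n_tok = side * side + 1
        self.cls = Tensor(np.zeros((1, 1, d), dtype=np.float32), requires_grad=True)
        self.pos = Tensor((0.02 * rng.standard_normal((1, n_tok, d))).astype(np.float32),
                          requires_grad=True)
        self.drop = nn.Dropout(hp["dropout"], rng)
        self.encoders = nn.Sequential(*[
            nn.TransformerEncoderLayer(d, hp["heads"], hp["ff"], rng, hp["dropout"])
            for _ in range(hp["layers"])
        ])
        self.norm = nn.LayerNorm(d)
        self.embed_dim = d
        self.n_tokens = n_tok
        object.__setattr__(self, "cam_layer", self.patch_embed)

    def forward(self, x: Tensor) -> Tensor:
        x = self.patch_embed(x)                     # (n, d, s, s)
        n, d, h, w = x.shape
        tokens = x.reshape(n, d, h * w).transpose(0, 2, 1)
        cls = self.cls + Tensor(np.zeros((n, 1, d), dtype=np.float32))
        tokens = nn.concat([cls, tokens], axis=1) + self.pos
        tokens = self.encoders(self.drop(tokens))
        return self.norm(tokens)[:, 0]


_BACKBONES = {
    "simple_cnn": SimpleCNNBackbone,
    "resnet18": ResNet18Backbone,
    "cnn_transformer": CNNTransformerBackbone,
    "vit": ViTBackbone,
}


# ---------------------------------------------------------------------------
# Heads and the full model
# ---------------------------------------------------------------------------

class FusionHead(nn.Module):
    """Two FC layers (256, 64) with ReLU and dropout 0.3, then the classifier."""

    def __init__(self, in_dim: int, n_classes: int, rng: np.random.Generator,
                 hidden=(256, 64), dropout: float = 0.3):
        super().__init__()
        self.fc1 = nn.Linear(in_dim, hidden[0], rng)
        self.drop = nn.Dropout(dropout, rng)
        self.fc2 = nn.Linear(hidden[0], hidden[1], rng)
        self.out = nn.Linear(hidden[1], n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.drop(self.fc1(x).relu())
        x = self.fc2(x).relu()
        return self.out(x)


class EcgClassifier(nn.Module):
    """Backbone + (fusion) head producing 4-class logits/probabilities."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.backbone = _BACKBONES[config.arch](config, rng)
        if config.fusion:
            self.head = FusionHead(self.backbone.embed_dim + config.handcrafted_dim,
                                   config.n_classes, rng)
        else:
            self.head = nn.Linear(self.backbone.embed_dim, config.n_classes, rng)

    # -- plumbing -------------------------------------------------------
    def _image_tensor(self, images: np.ndarray) -> Tensor:
        images = np.asarray(images, dtype=np.float32)
        if self.config.input_mode == "sequence":
            if images.ndim == 1:
                images = images[None]
            n = images.shape[0]
            return Tensor(images.reshape(n, 1, -1, 1))
        if images.ndim == 3:
            images = images[None]
        return Tensor(images.transpose(0, 3, 1, 2))  # NHWC -> NCHW

    def embed(self, images: np.ndarray) -> Tensor:
        return self.backbone(self._image_tensor(images))

    def head_logits(self, embedding: Tensor, handcrafted: np.ndarray | None) -> Tensor:
        if self.config.fusion:
            if handcrafted is None:
                raise ValidationError("fusion model requires a handcrafted input")
            hc = np.atleast_2d(np.asarray(handcrafted, dtype=np.float32))
            if hc.shape[1] != self.config.handcrafted_dim:
                raise ValidationError(
                    f"handcrafted dim {hc.shape[1]} != configured "
                    f"{self.config.handcrafted_dim}"
                )
            joint = nn.concat([embedding, Tensor(hc)], axis=1)
            return self.head(joint)
        return self.head(embedding)

    def forward(self, images: np.ndarray, handcrafted: np.ndarray | None = None) -> Tensor:
        return self.head_logits(self.embed(images), handcrafted)

    def predict_proba(self, images: np.ndarray,
                      handcrafted: np.ndarray | None = None) -> np.ndarray:
        """Class probabilities (rows sum to 1); deterministic in eval mode."""
        with nn.no_grad():
            logits = self.forward(images, handcrafted)
            return nn.softmax(logits, axis=-1).data.astype(np.float64)

    # -- two-stage training support --------------------------------------
    def freeze_backbone(self) -> None:
        for p in self.backbone.parameters():
            p.requires_grad = False

    def unfreeze_backbone(self) -> None:
        for p in self.backbone.parameters():
            p.requires_grad = True

    def backbone_checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in self.backbone.parameters()))


def build_model(config: ModelConfig) -> EcgClassifier:
    """Construct a classifier from its config (deterministic given seed)."""
    return EcgClassifier(config)


def count_parameters(model: nn.Module, trainable_only: bool = True) -> int:
    """Total (trainable) parameter count."""
    return int(sum(
        p.data.size for p in model.parameters()
        if p.requires_grad or not trainable_only
    ))


def architecture_summary(model: EcgClassifier) -> str:
    lines = [f"arch={model.config.arch} fusion={model.config.fusion} "
             f"embed_dim={model.backbone.embed_dim}"]
    for name, p in model.named_parameters():
        lines.append(f"  {name:50s} {str(p.data.shape):20s} {p.data.size}")
    lines.append(f"total trainable parameters: {count_parameters(model)}")
    return "\n".join(lines)


def save_checkpoint(model: EcgClassifier, path) -> None:
    """Write weights plus the embedded ModelConfig (JSON) to one NPZ file."""
    import json
    from dataclasses import asdict

    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> EcgClassifier:
    """Rebuild a classifier from a checkpoint written by :func:`save_checkpoint`."""
    import json

    archive = np.load(path)
    cfg_dict = json.loads(archive["config_json"].tobytes().decode())
    cfg_dict["image_size"] = tuple(cfg_dict["image_size"])
    model = EcgClassifier(ModelConfig(**cfg_dict))
    state = {k[len("param/"):]: archive[k] for k in archive.files
             if k.startswith("param/")}
    model.load_state_dict(state)
    return model
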