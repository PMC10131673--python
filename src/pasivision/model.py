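"""The per-region severity network.

Mirrors how a dermatologist scores one body region from several
photographs:

1.  Each image is encoded by a small convolutional network whose stages
    carry squeeze-and-excitation (SE) channel gating.  A parallel 1x1
    convolution branch emits a single-channel attention map, squashed by
    a sigmoid to [0, 1], trained against lesion-box heatmap masks so the
    network looks where the lesions are.
2.  The attention map gates the visual feature map (elementwise product)
    and global average pooling turns each image into a feature vector.
3.  Multi-view fusion aggregates the N per-image vectors into one
    region-level vector via elementwise maximum and mean (concatenated;
    either half can be ablated away).
4.  A learned region-identity embedding is added (one shared network
    serves all four body regions), and two output heads produce, per
    subscore, a regression scalar and classification logits (7 labels
    for the area band, 5 for erythema / induration / desquamation).

Training couples the heads with a cross-teacher term: the regression
output is pulled toward the softmax-expected label of the classifier,
and the classifier is trained on the rounded regression output as a
pseudo-label — each head teaching the other, with stop-gradients on the
teacher side.  At prediction time the regression output is the final
answer: clamped to the legal range and rounded half away from zero.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .core import Region, RegionAssessment, round_half_away
from .preprocess import ace_normalize, crop_resize

__all__ = [
    "ModelConfig",
    "EncoderFeatures",
    "RegionOutputs",
    "LossBundle",
    "SeverityNet",
    "CheckpointError",
    "attention_gate",
    "fuse_multiview",
    "smooth_l1",
    "cross_teacher_loss",
    "predict_region",
]

METRICS = ("area", "erythema", "induration", "desquamation")
METRIC_LABELS = {"area": 7, "erythema": 5, "induration": 5, "desquamation": 5}
METRIC_MAX = {"area": 6, "erythema": 4, "induration": 4, "desquamation": 4}
REGION_INDEX = {r: i for i, r in enumerate(Region)}

#: Stage channel plans.  "small_se" is the desk-scale default; "deep_se"
#: follows the EfficientNet-B0 stage silhouette (widths per stride-2
#: stage, SE in every stage) without its depth multipliers.
BACKBONES = {
    "small_se": (16, 32, 48),
    "deep_se": (16, 24, 40, 80, 112),
}


class CheckpointError(RuntimeError):
    pass


@dataclass
class ModelConfig:
    backbone: str = "small_se"
    image_size: tuple[int, int] = (64, 80)
    se_reduction: int = 4
    fusion: str = "max_mean"  # max_mean | max | mean
    header_mode: str = "both_cross"  # regression | classification | both | both_cross
    hidden: int = 64
    shared_across_regions: bool = True
    ace: bool = False  # apply ACE color normalization before encoding
    ace_slope: float = 5.0

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.fusion not in ("max_mean", "max", "mean"):
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if self.header_mode not in ("regression", "classification", "both", "both_cross"):
            raise ValueError(f"unknown header_mode {self.header_mode!r}")
        self.image_size = tuple(self.image_size)  # type: ignore[assignment]

    @property
    def channels(self) -> tuple[int, ...]:
        return BACKBONES[self.backbone]

    @property
    def feature_dim(self) -> int:
        c = self.channels[-1]
        return 2 * c if self.fusion == "max_mean" else c


@dataclass
class EncoderFeatures:
    """Per-image encoder output: visual map (C,h,w) + attention (1,h,w)."""

    visual_map: np.ndarray
    attention_map: np.ndarray

    def __post_init__(self) -> None:
        if self.visual_map.shape[1:] != self.attention_map.shape[1:]:
            raise ValueError("visual and attention grids must match")


@dataclass
class RegionOutputs:
    """Raw model outputs for one region sample."""

    regression: dict[str, float]
    class_logits: dict[str, np.ndarray]
    attention_maps: list[np.ndarray]

    def to_assessment(self, region: Region) -> RegionAssessment:
        vals = {}
        for m in METRICS:
            clamped = min(max(self.regression[m], 0.0), float(METRIC_MAX[m]))
            vals[m] = int(round_half_away(clamped, 0))
        return RegionAssessment(
            region=region,
            area_band=vals["area"],
            erythema=vals["erythema"],
            induration=vals["induration"],
            desquamation=vals["desquamation"],
        )


@dataclass
class LossBundle:
    l_reg: float
    l_cls: float
    l_attn: float
    l_cross: float
    total: float
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# functional pieces (documented, framework-free forms)
# ---------------------------------------------------------------------------

def attention_gate(features: EncoderFeatures) -> np.ndarray:
    """Suppress off-lesion features: visual ⊙ attention, then global
    average pooling over the spatial grid -> length-C vector."""
    gated = features.visual_map * features.attention_map
    return gated.mean(axis=(1, 2))


def fuse_multiview(vectors: Sequence[np.ndarray], mode: str = "max_mean") -> np.ndarray:
    """Aggregate N image-level vectors into one region-level vector.

    ``max_mean`` concatenates the elementwise maximum and mean (length
    2C); ``max`` / ``mean`` keep a single aggregate (length C).  Symmetric
    in the input order.
    """
    if len(vectors) == 0:
        raise ValueError("fuse_multiview needs at least one vector")
    stack = np.stack(vectors)
    if mode == "max":
        return stack.max(axis=0)
    if mode == "mean":
        return stack.mean(axis=0)
    if mode == "max_mean":
        return np.concatenate([stack.max(axis=0), stack.mean(axis=0)])
    raise ValueError(f"unknown fusion mode {mode!r}")


def smooth_l1(pred: float, target: float) -> float:
    """0.5 d^2 for |d| < 1, |d| - 0.5 beyond (d = pred - target)."""
    d = float(pred) - float(target)
    return 0.5 * d * d if abs(d) < 1.0 else abs(d) - 0.5


def cross_teacher_loss(regression: float, class_logits: np.ndarray) -> float:
    """Mutual-revision loss between the two output heads for one metric.

    The classifier teaches the regressor through its softmax-expected
    label mu = sum_k k p_k; the regressor teaches the classifier through
    the pseudo-label clamp(round(regression), 0, K-1).  (In training each
    teacher side sits behind a stop-gradient.)
    """
    logits = np.asarray(class_logits, dtype=float)
    k = logits.shape[-1]
    z = logits - logits.max()
    p = np.exp(z) / np.exp(z).sum()
    mu = float((np.arange(k) * p).sum())
    label = int(min(max(round_half_away(float(regression), 0), 0), k - 1))
    ce = -float(np.log(max(p[label], 1e-300)))
    return smooth_l1(regression, mu) + ce


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class SeverityNet:
    """Attention-gated multi-view SE-CNN with dual output heads."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self.params: dict[str, nn.Tensor] = {}
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x90DE1]))
        chans = config.channels
        cin = 3
        for i, cout in enumerate(chans):
            self._add(f"conv{i}.w", nn.he_init(rng, (cout, cin, 3, 3), cin * 9))
            self._add(f"conv{i}.b", np.zeros(cout))
            r = max(2, cout // config.se_reduction)
            self._add(f"se{i}.w1", nn.he_init(rng, (cout, r), cout))
            self._add(f"se{i}.b1", np.zeros(r))
            self._add(f"se{i}.w2", nn.he_init(rng, (r, cout), r))
            self._add(f"se{i}.b2", np.zeros(cout))
            cin = cout
        c = chans[-1]
        self._add("attn.w", nn.he_init(rng, (1, c, 1, 1), c))
        self._add("attn.b", np.zeros(1))
        f = config.feature_dim
        self._add("region_embed", 0.01 * rng.standard_normal((len(Region), f)))
        self._add("trunk.w", nn.he_init(rng, (f, config.hidden), f))
        self._add("trunk.b", np.zeros(config.hidden))
        self._add("reg.w", nn.he_init(rng, (config.hidden, 4), config.hidden))
        self._add("reg.b", np.array([2.0, 1.5, 1.5, 1.5]))
        for m in METRICS:
            k = METRIC_LABELS[m]
            self._add(f"cls.{m}.w", nn.he_init(rng, (config.hidden, k), config.hidden))
            self._add(f"cls.{m}.b", np.zeros(k))

    def _add(self, name: str, data: np.ndarray) -> None:
        self.params[name] = nn.Parameter(data)

    # -- forward pieces -----------------------------------------------

    def _se(self, x: nn.Tensor, i: int) -> nn.Tensor:
        pooled = nn.mean(x, axis=(2, 3))  # (B, C)
        h = nn.relu(nn.add(nn.matmul(pooled, self.params[f"se{i}.w1"]),
                           self.params[f"se{i}.b1"]))
        s = nn.sigmoid(nn.add(nn.matmul(h, self.params[f"se{i}.w2"]),
                              self.params[f"se{i}.b2"]))
        b, c = s.shape
        return nn.mul(x, nn.reshape(s, (b, c, 1, 1)))

    def encode_t(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor]:
        """x: (B,3,H,W) -> (visual (B,C,h,w), attn_logits, attn in [0,1])."""
        h = x
        for i in range(len(self.config.channels)):
            h = nn.relu(nn.conv2d(h, self.params[f"conv{i}.w"],
                                  self.params[f"conv{i}.b"], stride=2, pad=1))
            h = self._se(h, i)
        attn_logits = nn.conv2d(h, self.params["attn.w"], self.params["attn.b"])
        return h, attn_logits, nn.sigmoid(attn_logits)

    def encode(self, image: np.ndarray) -> EncoderFeatures:
        """Encode one preprocessed image (3,H,W) or (H,W,3) float in [0,1]."""
        x = self._to_chw(image)
        if x.shape[1:] != (3, *self.config.image_size):
            raise ValueError(
                f"image shape {x.shape[1:]} does not match configured "
                f"size (3, {self.config.image_size[0]}, {self.config.image_size[1]})"
            )
        visual, _, attn = self.encode_t(nn.Tensor(x))
        return EncoderFeatures(visual_map=visual.data[0], attention_map=attn.data[0])

    @staticmethod
    def _to_chw(image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 3 and img.shape[2] == 3:
            img = img.transpose(2, 0, 1)
        return img[None] if img.ndim == 3 else img

    def _fuse_t(self, vecs: nn.Tensor, b: int, n: int) -> nn.Tensor:
        """vecs (B*N, C) -> fused (B, feature_dim)."""
        c = vecs.shape[1]
        grouped = nn.reshape(vecs, (b, n, c))
        mode = self.config.fusion
        if mode == "max":
            return nn.reduce_max(grouped, axis=1)
        if mode == "mean":
            return nn.mean(grouped, axis=1)
        return nn.concat([nn.reduce_max(grouped, axis=1), nn.mean(grouped, axis=1)], axis=1)

    def forward(
        self, images: np.ndarray, region_idx: np.ndarray
    ) -> dict[str, nn.Tensor]:
        """Full forward pass.

        images: (B, N, 3, H, W) float in [-0.5, 0.5]; region_idx: (B,) ints.
        Returns tensors: reg (B,4), cls.<metric> (B,K), attn_logits and
        attn ((B*N,1,h,w)).
        """
        b, n = images.shape[:2]
        flat = nn.Tensor(images.reshape(b * n, *images.shape[2:]))
        visual, attn_logits, attn = self.encode_t(flat)
        gated = nn.mean(nn.mul(visual, attn), axis=(2, 3))  # (B*N, C)
        fused = self._fuse_t(gated, b, n)
        fused = nn.add(fused, nn.embedding(self.params["region_embed"], region_idx)) \
            if self.config.shared_across_regions else fused
        h = nn.relu(nn.add(nn.matmul(fused, self.params["trunk.w"]), self.params["trunk.b"]))
        out: dict[str, nn.Tensor] = {
            "reg": nn.add(nn.matmul(h, self.params["reg.w"]), self.params["reg.b"]),
            "attn_logits": attn_logits,
            "attn": attn,
        }
        for m in METRICS:
            out[f"cls.{m}"] = nn.add(
                nn.matmul(h, self.params[f"cls.{m}.w"]), self.params[f"cls.{m}.b"]
            )
        return out

    # -- losses ---------------------------------------------------------

    def compute_losses(
        self,
        outputs: dict[str, nn.Tensor],
        target_subscores: np.ndarray,  # (B, 4) ints in metric order
        heatmaps: np.ndarray | None = None,  # (B*N, 1, h, w)
        heatmap_valid: np.ndarray | None = None,  # (B*N,) 0/1
        loss_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    ) -> tuple[nn.Tensor, LossBundle]:
        """Assemble the weighted training loss for the configured heads."""
        mode = self.config.header_mode
        w_reg, w_cls, w_attn, w_cross = loss_weights
        zero = nn.Tensor(0.0)
        reg = outputs["reg"]
        b = reg.shape[0]

        l_reg = nn.smooth_l1_loss(reg, target_subscores.astype(float)) \
            if mode != "classification" else zero

        if mode != "regression":
            cls_terms = [
                nn.softmax_cross_entropy(outputs[f"cls.{m}"], target_subscores[:, j])
                for j, m in enumerate(METRICS)
            ]
            l_cls = nn.mul(_sum_tensors(cls_terms), nn.Tensor(1.0 / len(cls_terms)))
        else:
            l_cls = zero

        if heatmaps is not None:
            valid = None if heatmap_valid is None else heatmap_valid.reshape(-1, 1, 1, 1)
            l_attn = nn.bce_with_logits(outputs["attn_logits"], heatmaps, valid)
        else:
            l_attn = zero

        if mode == "both_cross":
            cross_terms = []
            for j, m in enumerate(METRICS):
                k = METRIC_LABELS[m]
                logits = outputs[f"cls.{m}"]
                # classifier -> regressor: match the detached expected label
                z = logits.data - logits.data.max(axis=1, keepdims=True)
                p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
                mu = (p * np.arange(k)).sum(axis=1)
                reg_m = nn.reshape(reg, (b, 4))
                reg_col = _column(reg_m, j)
                cross_terms.append(nn.smooth_l1_loss(reg_col, mu))
                # regressor -> classifier: detached rounded pseudo-labels
                pseudo = np.clip(
                    np.array([round_half_away(v, 0) for v in reg.data[:, j]]),
                    0, k - 1,
                ).astype(int)
                cross_terms.append(nn.softmax_cross_entropy(logits, pseudo))
            l_cross = nn.mul(_sum_tensors(cross_terms), nn.Tensor(0.5 / len(METRICS)))
        else:
            l_cross = zero

        total = _sum_tensors([
            nn.mul(l_reg, nn.Tensor(w_reg)),
            nn.mul(l_cls, nn.Tensor(w_cls)),
            nn.mul(l_attn, nn.Tensor(w_attn)),
            nn.mul(l_cross, nn.Tensor(w_cross)),
        ])
        bundle = LossBundle(
            l_reg=float(l_reg.data),
            l_cls=float(l_cls.data),
            l_attn=float(l_attn.data),
            l_cross=float(l_cross.data),
            total=float(total.data),
            weights=loss_weights,
        )
        return total, bundle

    # -- prediction ------------------------------------------------------

    def preprocess_image(self, image: np.ndarray, mode: str = "eval_center",
                         seed: int | None = None) -> np.ndarray:
        """uint8 HxWx3 -> float (3,H,W) in [-0.5, 0.5] at the model size."""
        img = np.asarray(image)
        if self.config.ace:
            img = ace_normalize(img, slope=self.config.ace_slope)
        img = crop_resize(img, mode, target=self.config.image_size, seed=seed)
        return (img.astype(np.float64) / 255.0 - 0.5).transpose(2, 0, 1)

    def predict_region_outputs(
        self, images: Sequence[np.ndarray], region: Region
    ) -> RegionOutputs:
        if len(images) == 0:
            raise ValueError("predict needs at least one image")
        pre = np.stack([self.preprocess_image(im) for im in images])
        out = self.forward(pre[None], np.array([REGION_INDEX[Region(region)]]))
        return RegionOutputs(
            regression={m: float(out["reg"].data[0, j]) for j, m in enumerate(METRICS)},
            class_logits={m: out[f"cls.{m}"].data[0].copy() for m in METRICS},
            attention_maps=[a[0] for a in out["attn"].data],
        )

    # -- checkpointing ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = json.dumps({"config": asdict(self.config), "seed": self.seed,
                           "format_version": 1})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **{k: p.data for k, p in self.params.items()})

    @classmethod
    def load(cls, path: str | Path) -> "SeverityNet":
        path = Path(path)
        if not path.exists():
            raise CheckpointError(
                f"checkpoint {path} not found; train a model first — "
                "predictions from random weights are refused"
            )
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg = meta["config"]
            cfg["image_size"] = tuple(cfg["image_size"])
            net = cls(ModelConfig(**cfg), seed=meta["seed"])
            for k in net.params:
                net.params[k].data = z[k].copy()
        return net


def _sum_tensors(ts: list[nn.Tensor]) -> nn.Tensor:
    acc = ts[0]
    for t in ts[1:]:
        acc = nn.add(acc, t)
    return acc


def _column(t: nn.Tensor, j: int) -> nn.Tensor:
    """Select column j of a (B, K) tensor as (B,)."""
    k = t.shape[1]
    sel = np.zeros((k, 1))
    sel[j, 0] = 1.0
    return nn.reshape(nn.matmul(t, nn.Tensor(sel)), (t.shape[0],))


def predict_region(
    images: Sequence[np.ndarray],
    net: SeverityNet | str | Path,
    region: Region = Region.TRUNK,
) -> tuple[RegionOutputs, RegionAssessment]:
    """Run the full pipeline on one region's images.

    ``net`` may be a trained :class:`SeverityNet` or a checkpoint path
    (missing checkpoints raise :class:`CheckpointError`).  The reported
    integer subscores are the clamped, half-away-from-zero-rounded
    regression outputs; the classification logits ride along for
    diagnostics.
    """
    if not isinstance(net, SeverityNet):
        net = SeverityNet.load(net)
    outputs = net.predict_region_outputs(images, region)
    return outputs, outputs.to_assessment(Region(region))
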