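"""Seeded training loop and the ablation harness.

Training optimizes the four-component loss (regression smooth-L1,
classification cross-entropy, attention binary cross-entropy against the
box heatmaps, and the cross-teacher term) with an adaptive-moment
optimizer over region samples drawn from a manifest.  Geometry follows
the train/eval asymmetry: seeded random cropping during training,
deterministic full-frame resize for validation and prediction.  The
whole loop is deterministic given the config seed (single process,
fixed thread count).

The ablation harness retrains the same cohort under controlled config
variants — number of input images per region (1-4), fusion strategy
(only max / only mean / max + mean) and output-head arrangement (only
regression / only classification / both / both with cross-teacher) — and
tabulates per-subscore accuracy and total-PASI MAE per arm.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import nn
from .core import Region, RegionAssessment, VisitAssessment
from .evaluate import mae, subscore_accuracy
from .model import (
    METRIC_LABELS,
    METRICS,
    REGION_INDEX,
    ModelConfig,
    SeverityNet,
)
from .preprocess import (
    ace_normalize,
    apply_window_resize,
    boxes_to_heatmap,
    random_crop_window,
    transform_boxes,
)
from .synth import RegionSample, group_manifest, load_manifest

__all__ = [
    "TrainConfig",
    "TrainResult",
    "train",
    "run_ablation",
    "predict_visits",
    "constant_predictor_mae",
    "TABLE_FUSION_GRID",
    "TABLE_HEADER_GRID",
]

logger = logging.getLogger(__name__)

ABLATION_COLUMNS = [
    "arm",
    "area_acc",
    "erythema_acc",
    "desquamation_acc",
    "induration_acc",
    "pasi_mae",
]

#: The fusion-strategy and output-head ablation grids, as config overrides.
TABLE_FUSION_GRID = [
    ("only_max", {"fusion": "max"}),
    ("only_mean", {"fusion": "mean"}),
    ("max_mean", {"fusion": "max_mean"}),
]
TABLE_HEADER_GRID = [
    ("only_regression", {"header_mode": "regression"}),
    ("only_classification", {"header_mode": "classification"}),
    ("regression_classification", {"header_mode": "both"}),
    ("regression_classification_cross_teacher", {"header_mode": "both_cross"}),
]


class TrainError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    n_images_per_region: int = 3  # ablation arms use 1-4
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    loss_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    seed: int = 0
    random_crop: bool = True

    def __post_init__(self) -> None:
        if self.n_images_per_region not in (1, 2, 3, 4):
            raise ValueError(
                f"n_images_per_region must be 1..4, got {self.n_images_per_region}"
            )
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if isinstance(self.model, dict):
            self.model = ModelConfig(**self.model)
        self.loss_weights = tuple(self.loss_weights)  # type: ignore[assignment]

    def as_dict(self) -> dict:
        d = asdict(self)
        d["model"]["image_size"] = list(self.model.image_size)
        d["loss_weights"] = list(self.loss_weights)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


@dataclass
class TrainResult:
    net: SeverityNet
    history: pd.DataFrame
    checkpoint_path: Path | None
    best_val_mae: float | None


# ---------------------------------------------------------------------------
# data handling
# ---------------------------------------------------------------------------

class _Dataset:
    """Region samples with cached decoded images."""

    def __init__(self, samples: Sequence[RegionSample], config: TrainConfig):
        self.samples = list(samples)
        self.config = config
        self._cache: dict[str, np.ndarray] = {}
        mc = config.model
        # attention-grid size after the stride-2 stages (k3, pad 1)
        h, w = mc.image_size
        for _ in mc.channels:
            h = (h + 2 - 3) // 2 + 1
            w = (w + 2 - 3) // 2 + 1
        self.map_size = (h, w)

    def raw_image(self, path: str) -> np.ndarray:
        if path not in self._cache:
            try:
                img = np.asarray(Image.open(path).convert("RGB"))
            except OSError as exc:
                raise TrainError(f"cannot read image {path}: {exc}") from exc
            if self.config.model.ace:
                img = ace_normalize(img, slope=self.config.model.ace_slope)
            self._cache[path] = img
        return self._cache[path]

    def select_views(self, sample: RegionSample, seed: int) -> list[int]:
        """Seeded subsample when a region has more images than needed."""
        n = self.config.n_images_per_region
        k = len(sample.image_paths)
        if k <= n:
            return list(range(k))
        rng = np.random.default_rng(seed)
        return sorted(rng.choice(k, size=n, replace=False).tolist())

    def training_batch(
        self, samples: Sequence[RegionSample], epoch: int, base_index: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Preprocess a batch with per-(epoch, sample, view) crop seeds."""
        cfg = self.config
        target = cfg.model.image_size
        imgs, heats, regions, targets = [], [], [], []
        for si, s in enumerate(samples):
            sseed = int(
                np.random.SeedSequence(
                    [cfg.seed, 0xBA7C, epoch, base_index + si]
                ).generate_state(1)[0] % (2**31)
            )
            views = self.select_views(s, sseed)
            per_view = []
            for vi in views:
                raw = self.raw_image(s.image_paths[vi])
                if cfg.random_crop:
                    window = random_crop_window(raw.shape[:2], seed=sseed + vi + 1)
                    img = apply_window_resize(raw, window, target)
                    boxes = transform_boxes(s.boxes[vi], window, target)
                else:
                    window = None
                    img = apply_window_resize(raw, (0, 0, *raw.shape[:2]), target)
                    boxes = transform_boxes(s.boxes[vi], (0, 0, *raw.shape[:2]), target)
                per_view.append((img.astype(np.float64) / 255.0 - 0.5).transpose(2, 0, 1))
                heats.append(boxes_to_heatmap(boxes, target, self.map_size).values[None])
            imgs.append(np.stack(per_view))
            regions.append(REGION_INDEX[s.region])
            a = s.assessment
            targets.append([a.area_band, a.erythema, a.induration, a.desquamation])
        return (
            np.stack(imgs),
            np.stack(heats),
            np.array(regions),
            np.array(targets),
        )


def _resolve_samples(
    manifest: str | Path | pd.DataFrame, root: str | Path | None
) -> tuple[list[RegionSample], Path]:
    if isinstance(manifest, (str, Path)):
        mpath = Path(manifest)
        df = load_manifest(mpath)
        root = Path(root) if root is not None else mpath.parent
    else:
        df = manifest
        root = Path(root) if root is not None else Path(".")
    return group_manifest(df, root=root), root


# ---------------------------------------------------------------------------
# prediction over a manifest
# ---------------------------------------------------------------------------

def predict_visits(
    net: SeverityNet,
    samples: Iterable[RegionSample],
    n_images_per_region: int = 4,
    seed: int = 0,
) -> tuple[list[VisitAssessment], list[VisitAssessment], dict]:
    """Predict every visit in ``samples``; returns (predicted, truth, sidecar).

    The sidecar maps "patient/visit/region" to raw regression values and
    classification logits for diagnostics.
    """
    groups: dict[tuple[str, str], list[RegionSample]] = {}
    for s in samples:
        groups.setdefault((s.patient_id, s.visit_id), []).append(s)
    cls_mode = net.config.header_mode == "classification"
    predicted, truth = [], []
    sidecar: dict[str, dict] = {}
    for (pid, vid), group in sorted(groups.items()):
        pred_regions = []
        true_regions = []
        for s in sorted(group, key=lambda s: REGION_INDEX[s.region]):
            k = len(s.image_paths)
            take = min(k, n_images_per_region)
            if take < k:
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, REGION_INDEX[s.region]])
                )
                idx = sorted(rng.choice(k, size=take, replace=False).tolist())
            else:
                idx = list(range(k))
            images = [np.asarray(Image.open(s.image_paths[i]).convert("RGB")) for i in idx]
            out = net.predict_region_outputs(images, s.region)
            if cls_mode:
                labels = {m: int(np.argmax(out.class_logits[m])) for m in METRICS}
                assessment = RegionAssessment(
                    region=s.region,
                    area_band=labels["area"],
                    erythema=labels["erythema"],
                    induration=labels["induration"],
                    desquamation=labels["desquamation"],
                )
            else:
                assessment = out.to_assessment(s.region)
            pred_regions.append(assessment)
            true_regions.append(s.assessment)
            sidecar[f"{pid}/{vid}/{s.region.value}"] = {
                "regression": out.regression,
                "class_logits": {m: out.class_logits[m].tolist() for m in METRICS},
            }
        predicted.append(VisitAssessment(pid, vid, pred_regions))
        truth.append(VisitAssessment(pid, vid, true_regions))
    return predicted, truth, sidecar


def constant_predictor_mae(train_pasi: Sequence[float], eval_pasi: Sequence[float]) -> float:
    """MAE of the baseline that always predicts the training-set mean."""
    c = float(np.mean(train_pasi))
    return mae([c] * len(list(eval_pasi)), list(eval_pasi))


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

_HISTORY_COMPONENTS = {
    "regression": ("l_reg", "l_attn"),
    "classification": ("l_cls", "l_attn"),
    "both": ("l_reg", "l_cls", "l_attn"),
    "both_cross": ("l_reg", "l_cls", "l_attn", "l_cross"),
}


def train(
    manifest: str | Path | pd.DataFrame,
    config: TrainConfig,
    out_dir: str | Path | None = None,
    root: str | Path | None = None,
) -> TrainResult:
    """Optimize the severity network on a manifest's train split.

    Records per-epoch loss components (those active under the configured
    header mode) and validation total-PASI MAE; the best-validation
    parameters are retained and, when ``out_dir`` is given, written to
    ``checkpoint.npz`` alongside ``history.csv``.
    """
    samples, _ = _resolve_samples(manifest, root)
    train_samples = [s for s in samples if s.split == "train"]
    val_samples = [s for s in samples if s.split == "val"]
    if not train_samples:
        raise TrainError("manifest has no rows with split == 'train'")
    ds = _Dataset(train_samples, config)

    net = SeverityNet(config.model, seed=config.seed)
    opt = nn.Adam(net.params, lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x0D0]))

    components = _HISTORY_COMPONENTS[config.model.header_mode]
    rows = []
    best_val = None
    best_params = None
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(train_samples))
        # bucket by view count so each batch stacks rectangularly
        buckets: dict[int, list[int]] = {}
        for i in order:
            s = train_samples[i]
            nviews = min(len(s.image_paths), config.n_images_per_region)
            buckets.setdefault(nviews, []).append(i)
        sums = {c: 0.0 for c in components}
        total_sum, n_batches = 0.0, 0
        t0 = time.time()
        for nviews in sorted(buckets):
            idxs = buckets[nviews]
            for b0 in range(0, len(idxs), config.batch_size):
                batch = [train_samples[i] for i in idxs[b0 : b0 + config.batch_size]]
                imgs, heats, regions, targets = ds.training_batch(batch, epoch, b0)
                out = net.forward(imgs, regions)
                loss, bundle = net.compute_losses(
                    out, targets, heats, loss_weights=config.loss_weights
                )
                if not np.isfinite(loss.data):
                    raise TrainError(
                        f"non-finite loss at epoch {epoch}: {bundle}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                for c in components:
                    sums[c] += getattr(bundle, c)
                total_sum += bundle.total
                n_batches += 1
        row = {"epoch": epoch, "train_total": total_sum / n_batches}
        row.update({c: sums[c] / n_batches for c in components})
        if val_samples:
            pred, truth, _ = predict_visits(
                net, val_samples, config.n_images_per_region, seed=config.seed
            )
            val_mae = mae([v.pasi for v in pred], [v.pasi for v in truth])
            row["val_mae"] = val_mae
            if best_val is None or val_mae < best_val:
                best_val = val_mae
                best_params = {k: p.data.copy() for k, p in net.params.items()}
        logger.info(
            "epoch %d: train %.4f%s (%.1fs)",
            epoch,
            row["train_total"],
            f", val MAE {row['val_mae']:.3f}" if "val_mae" in row else "",
            time.time() - t0,
        )
        rows.append(row)

    if best_params is not None:
        for k, p in net.params.items():
            p.data = best_params[k]

    history = pd.DataFrame(rows)
    ckpt_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt_path = out_dir / "checkpoint.npz"
        net.save(ckpt_path)
        history.to_csv(out_dir / "history.csv", index=False)
    return TrainResult(net=net, history=history, checkpoint_path=ckpt_path,
                       best_val_mae=best_val)


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

def run_ablation(
    manifest: str | Path | pd.DataFrame,
    grid: Sequence[tuple[str, dict]],
    base_config: TrainConfig,
    out_path: str | Path | None = None,
    root: str | Path | None = None,
    eval_split: str = "val",
) -> pd.DataFrame:
    """Train and evaluate each config arm on the same cohort and seed.

    ``grid`` entries are (arm_name, overrides) where overrides may touch
    ``TrainConfig`` fields or ``ModelConfig`` fields (fusion,
    header_mode, ...).  All arms share the base seed, hence identical
    data ordering; the table mirrors the ablation layout: one row per
    arm with the four subscore accuracies and the total-PASI MAE.
    """
    samples, _ = _resolve_samples(manifest, root)
    eval_samples = [s for s in samples if s.split == eval_split]
    if not eval_samples:
        raise TrainError(f"no samples in eval split {eval_split!r}")

    rows = []
    for arm, overrides in grid:
        cfg = _apply_overrides(base_config, overrides)
        result = train(manifest, cfg, root=root)
        pred, truth, _ = predict_visits(
            result.net, eval_samples, cfg.n_images_per_region, seed=cfg.seed
        )
        accs = {}
        for m in METRICS:
            attr = "area_band" if m == "area" else m
            p_lab = [getattr(a, attr) for v in pred for a in v.regions]
            t_lab = [getattr(a, attr) for v in truth for a in v.regions]
            accs[m] = subscore_accuracy(p_lab, t_lab, METRIC_LABELS[m])
        rows.append(
            {
                "arm": arm,
                "area_acc": accs["area"],
                "erythema_acc": accs["erythema"],
                "desquamation_acc": accs["desquamation"],
                "induration_acc": accs["induration"],
                "pasi_mae": mae([v.pasi for v in pred], [v.pasi for v in truth]),
            }
        )
    table = pd.DataFrame(rows, columns=ABLATION_COLUMNS)
    if out_path is not None:
        table.to_csv(out_path, index=False)
    return table


def _apply_overrides(base: TrainConfig, overrides: dict) -> TrainConfig:
    model_fields = set(ModelConfig.__dataclass_fields__)
    train_fields = set(TrainConfig.__dataclass_fields__)
    m_over = {k: v for k, v in overrides.items() if k in model_fields}
    t_over = {k: v for k, v in overrides.items() if k in train_fields and k != "model"}
    unknown = set(overrides) - model_fields - train_fields
    if unknown:
        raise ValueError(f"unknown override fields {sorted(unknown)}")
    cfg = replace(base, **t_over)
    cfg.model = replace(base.model, **m_over)
    return cfg
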