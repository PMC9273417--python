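"""End-to-end pipeline: simulate → correct → train → predict → evaluate → count.

Mirrors the overall segmentation model: the blood-smear image is first
preprocessed with the adaptive retinex correction, then segmented per pixel
by the encoder-decoder network; predictions are scored with the four
segmentation metrics and leukocytes are counted by connected components.
Every run can write its resolved configuration next to its outputs so any
artifact can be reproduced from the directory alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as wio
from .adaptive import adaptive_retinex_correct
from .counting import binarize, count_components
from .metrics import MetricReport, evaluate_pairs
from .net import NetworkSpec, TrainSchedule, build_network, train, predict
from .retinex import RetinexParams, SurroundScaleSet
from .synthetic import SmearConfig, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    retinex: RetinexParams = field(default_factory=RetinexParams)
    network: NetworkSpec = field(default_factory=lambda: NetworkSpec.tiny())
    schedule: TrainSchedule = field(default_factory=TrainSchedule)
    smear: SmearConfig = field(default_factory=SmearConfig)
    n_images: int = 80
    split: float = 0.5
    apply_correction: bool = True
    iou_threshold: float = 0.8
    seed: int = 0

    def resolved(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            return obj
        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}


def _correct_set(samples, params: RetinexParams):
    out = []
    for img, mask, meta in samples:
        out.append((adaptive_retinex_correct(img, params).to_unit(), mask, meta))
    return out


def run_pipeline(config: PipelineConfig | None = None, out_dir=None):
    """Run the full pipeline on synthetic data and return the metric report.

    Stages: generate a seeded synthetic dataset; optionally apply the
    adaptive retinex correction to every image; train the network on the
    training split; predict on the held-out split; evaluate Dice/MIoU/MPA/
    accuracy-at-IoU; count leukocytes per predicted mask.  With ``out_dir``
    set, all intermediates (corrected images, predicted masks, loss curve,
    metric report, component counts, resolved config) are written there.

    Returns ``(report, artifacts)`` where ``artifacts`` carries the trained
    model, loss curve, predictions and counts.
    """
    if config is None:
        config = PipelineConfig()
    smear = dataclasses.replace(config.smear, seed=config.seed)
    schedule = dataclasses.replace(config.schedule, seed=config.seed)

    train_set, test_set, manifest = generate_dataset(
        config.n_images, smear, split=config.split)
    if config.apply_correction:
        train_set = _correct_set(train_set, config.retinex)
        test_set = _correct_set(test_set, config.retinex)

    model = build_network(config.network, seed=config.seed)
    model, curve = train(model, train_set, test_set, schedule)

    pairs, counts, pred_masks = [], [], []
    for img, mask, _ in test_set:
        _, pred_mask = predict(model, img)
        pairs.append((pred_mask, mask.astype(np.int64)))
        pred_masks.append(pred_mask)
        counts.append(count_components(binarize(pred_mask)).count)

    report = evaluate_pairs(pairs, iou_threshold=config.iou_threshold)
    artifacts = {
        "model": model,
        "loss_curve": curve,
        "manifest": manifest,
        "pred_masks": pred_masks,
        "counts": counts,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, ((img, mask, _), pred_mask) in enumerate(zip(test_set, pred_masks)):
            wio.write_image(img.to_byte(), out_dir / f"test_{i:03d}.png")
            wio.write_mask(mask, out_dir / f"test_{i:03d}_truth.png")
            wio.write_mask(pred_mask, out_dir / f"test_{i:03d}_pred.png")
        curve.to_csv(out_dir / "loss_curve.csv")
        (out_dir / "report.json").write_text(json.dumps(report.as_dict(), indent=1))
        (out_dir / "counts.json").write_text(json.dumps(counts))
        wio.write_sidecar(config.resolved(), out_dir / "run_config.json")

    return report, artifacts
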