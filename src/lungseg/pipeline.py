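"""End-to-end run driver: generate -> split -> train -> evaluate -> report.

A run is described by a YAML config with three blocks (``phantom``,
``model``, ``train``) plus top-level keys ``n_samples``, ``method`` and
``seed``. Every resolved setting and derived seed is persisted into the run
directory so a report can be re-created exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .io import render_overlay, save_mask_png
from .network import ModelConfig, assemble_model, predict_mask, save_weights
from .phantom import PhantomConfig, generate_dataset, write_dataset
from .training import TrainConfig, build_variant, evaluate, split_dataset, train
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "default_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"[stage:{stage}] {cause}")
        self.stage = stage


def default_config() -> dict:
    """Desk-scale demo configuration (tiny encoder, 64-px phantoms)."""
    return {
        "seed": 0,
        "n_samples": 60,
        "method": 5,
        "n_overlays": 4,
        "write_pngs": False,
        "phantom": {"image_size": 64},
        "model": {"encoder": "tiny_test", "input_size": 64, "dropout_rate": 0.1},
        "train": {"max_epochs": 40, "batch_size": 8},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the full pipeline and write reports into ``out_dir``.

    ``config`` is a dict or a path to a YAML file; omitted keys take the
    demo defaults. Returns the run directory. Raises :class:`PipelineError`
    tagged with the failing stage.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merge(default_config(), config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    def stage(name, fn):
        try:
            logger.info("pipeline stage: %s", name)
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-tagged and re-raised
            raise PipelineError(name, exc) from exc

    phantom_cfg = stage(
        "configure", lambda: PhantomConfig(**cfg["phantom"], seed=seed).validate()
    )
    model_cfg = stage(
        "configure",
        lambda: build_variant(int(cfg["method"]), ModelConfig(**cfg["model"])),
    )
    train_cfg = stage("configure", lambda: TrainConfig(**cfg["train"], seed=seed).validate())

    samples = stage(
        "generate", lambda: generate_dataset(int(cfg["n_samples"]), phantom_cfg, seed=seed)
    )
    if cfg.get("write_pngs"):
        stage("generate", lambda: write_dataset(samples, out_dir / "data"))
    tr, va, te = stage("split", lambda: split_dataset(samples, train_cfg))

    net = stage("train", lambda: assemble_model(model_cfg, seed=seed))
    net, history = stage("train", lambda: train(net, tr, va, train_cfg))
    result = stage("evaluate", lambda: evaluate(net, te, repair_enabled=True))

    def report():
        resolved = dict(
            cfg,
            phantom=phantom_cfg.__dict__ | {"lung_eccentricity_range": list(phantom_cfg.lung_eccentricity_range)},
            model=model_cfg.to_dict(),
            train=train_cfg.__dict__,
            split_sizes={"train": len(tr), "val": len(va), "test": len(te)},
            lungseg_version=__version__,
        )
        with open(out_dir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(resolved, fh, sort_keys=False)
        history.to_csv(out_dir / "history.csv", index=False)
        result.raw.to_csv(out_dir / "report_raw.csv")
        result.raw.to_json(out_dir / "report_raw.json")
        result.repaired.to_csv(out_dir / "report_repaired.csv")
        result.repaired.to_json(out_dir / "report_repaired.json")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(
                {
                    "method": int(cfg["method"]),
                    "raw": result.raw.aggregate,
                    "repaired": result.repaired.aggregate,
                },
                fh,
                indent=2,
            )
        save_weights(net, out_dir / "weights.npz")
        overlay_dir = out_dir / "overlays"
        overlay_dir.mkdir(exist_ok=True)
        for s in te[: int(cfg.get("n_overlays", 0))]:
            pred = predict_mask(net, s.image)
            Image.fromarray(render_overlay(s.image, s.mask, pred)).save(
                overlay_dir / f"{s.sample_id}.png"
            )
            save_mask_png(pred, overlay_dir / f"{s.sample_id}.pred.png")
        return out_dir

    return stage("report", report)
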