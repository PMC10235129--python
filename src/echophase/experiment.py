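"""End-to-end experiments driven by a single config object.

``run_experiment`` wires the stages together — simulate, preprocess,
optionally crop, train, evaluate — and writes every artifact needed to
reproduce the run (frames, manifest, tracings, config snapshot, history,
metrics, weights, log) into one output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.model_selection import train_test_split

from .cropping import compute_midpoints
from .errors import ConfigError
from .network import (LossConfig, ModelConfig, build_model,
                      layer_average_abs_weights, save_model)
from .preprocess import AugmentConfig
from .synthetic import (Phase, SyntheticConfig, generate_dataset,
                        write_frames, write_manifest, write_tracings)
from .train_eval import TrainConfig, evaluate, prepare_arrays, train

__all__ = ["ExperimentConfig", "run_experiment"]

log = logging.getLogger("echophase")


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, nestable from a YAML mapping."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_videos: int = 50
    crop_enabled: bool = False
    half_width: int | str = "full"
    test_fraction: float = 0.25
    output_dir: str = "echophase_run"
    seed: int = 0

    REQUIRED_SECTIONS = ("synthetic", "model", "loss", "train")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ExperimentConfig":
        """Build from a nested mapping (parsed YAML). The synthetic, model,
        loss and train sections must be present (possibly empty mappings)."""
        missing = [s for s in cls.REQUIRED_SECTIONS if s not in mapping]
        if missing:
            raise ConfigError(f"config missing sections: {missing}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sub = {
            "synthetic": SyntheticConfig, "augment": AugmentConfig,
            "model": ModelConfig, "loss": LossConfig, "train": TrainConfig,
        }
        kwargs = {}
        for key, value in mapping.items():
            if key in sub:
                value = dict(value or {})
                for tup_key in ("input_shape", "conv_filters", "kernel",
                                "pool", "nonesed_area_range"):
                    if tup_key in value and isinstance(value[tup_key], list):
                        value[tup_key] = tuple(value[tup_key])
                kwargs[key] = sub[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict):
            raise ConfigError(f"{path} does not contain a mapping")
        return cls.from_mapping(mapping)

    def to_mapping(self) -> dict:
        return dataclasses.asdict(self)


def _setup_logging(logfile: Path) -> logging.Handler:
    handler = logging.FileHandler(logfile)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        stderr = logging.StreamHandler(sys.stderr)
        stderr.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(stderr)
    log.setLevel(logging.INFO)
    return handler


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run simulate -> preprocess -> (crop) -> train -> evaluate.

    Writes frames/, manifest.csv, tracings.csv, config.yaml, history.csv,
    metrics.json, weights.npz, weight_summary.json and run.log to
    ``cfg.output_dir`` and returns a report dict. Outputs are fully
    determined by the config and its seeds.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out / "run.log")
    try:
        log.info("experiment seed=%d n_videos=%d crop=%s",
                 cfg.seed, cfg.n_videos, cfg.crop_enabled)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_mapping(), fh, sort_keys=False)

        rng = np.random.default_rng(cfg.seed)
        records, manifest = generate_dataset(cfg.synthetic, cfg.n_videos, rng)
        if cfg.model.n_classes == 2:
            keep = {Phase.ES, Phase.ED}
            records = [r for r in records if r.label in keep]
            manifest = manifest[manifest.label.isin({p.value for p in keep})]
            manifest = manifest.reset_index(drop=True)
        write_frames(records, out / "frames")
        write_manifest(manifest, out / "manifest.csv")
        write_tracings(records, out / "tracings.csv")
        log.info("simulated %d frames", len(records))

        labels = np.array([r.label.value for r in records])
        idx_tr, idx_te = train_test_split(
            np.arange(len(records)), test_size=cfg.test_fraction,
            random_state=cfg.seed, stratify=labels)
        rec_tr = [records[i] for i in idx_tr]
        rec_te = [records[i] for i in idx_te]

        mids = None
        if cfg.crop_enabled:
            mids = compute_midpoints([r.tracing for r in rec_tr],
                                     image_height=cfg.synthetic.image_height)
            log.info("crop midpoints M1=%s M2=%s", mids.M1, mids.M2)
            with open(out / "midpoints.json", "w") as fh:
                json.dump({"M1": list(mids.M1), "M2": list(mids.M2),
                           "n_frames_averaged": mids.n_frames_averaged}, fh)

        h, w = cfg.model.input_shape[:2]
        x_tr, y_tr = prepare_arrays(rec_tr, height=h, width=w, mids=mids,
                                    half_width=cfg.half_width)
        x_te, y_te = prepare_arrays(rec_te, height=h, width=w, mids=mids,
                                    half_width=cfg.half_width)

        model = build_model(cfg.model, seed=cfg.seed)
        history = train(model, (x_tr, y_tr), cfg.loss, cfg.train)
        history.to_csv(out / "history.csv", index=False)
        metrics = evaluate(model, (x_te, y_te), cfg.loss)
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics.as_dict(), fh, indent=2)
        save_model(model, out / "weights.npz")
        with open(out / "weight_summary.json", "w") as fh:
            json.dump(layer_average_abs_weights(model), fh, indent=2)
        log.info("test metrics: %s", metrics.as_dict())
        return {"metrics": metrics.as_dict(),
                "history": history,
                "n_frames": len(records),
                "output_dir": str(out)}
    finally:
        log.removeHandler(handler)
        handler.close()
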