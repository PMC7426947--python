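"""End-to-end pipeline wiring: generate -> train -> evaluate -> explain.

``run_benchmark`` reproduces the three-way model comparison design on the
synthetic benchmark: one dataset per replicate seed, baseline / M1 / M2
trained with shared component seeds, all evaluated on the identical test
split at the 2/3/7-class hierarchy levels, and a comparison table with
models as rows and level-by-metric columns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import evaluate_split, write_report
from .manifest import DatasetManifest, validate_manifest
from .models import EncoderConfig, ClassifierConfig
from .seeding import derive_seed
from .synth import PhantomSpec, benchmark_split_profile, generate_dataset
from .train import TrainConfig, TRAINERS

REGIMES = ("baseline", "m1", "m2")


@dataclass
class RunConfig:
    out_dir: str = "benchmark_out"
    seed: int = 0
    n_replicates: int = 3
    image_size: int = 64
    n_per_class_train: int = 100
    n_val: int = 100
    n_test: int = 200
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-4
    lam: float = 0.5
    loss: str = "cross-entropy"
    levels: tuple = (2, 3, 7)
    spec: PhantomSpec = field(default_factory=PhantomSpec)
    keep_artifacts: bool = False

    def train_config(self, regime: str, seed: int) -> TrainConfig:
        return TrainConfig(regime=regime, epochs=self.epochs,
                           batch_size=self.batch_size,
                           learning_rate=self.learning_rate,
                           lam=self.lam, loss=self.loss, seed=seed)


def config_hash(cfg) -> str:
    blob = json.dumps(asdict(cfg) if not isinstance(cfg, dict) else cfg,
                      sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_benchmark(cfg: RunConfig) -> dict:
    """Train and evaluate all three regimes; returns the full result dict
    and writes ``benchmark.json`` + ``comparison_table.tsv`` under
    ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = PhantomSpec(image_size=cfg.image_size,
                       noise_sd=cfg.spec.noise_sd,
                       confounder_prob=cfg.spec.confounder_prob)
    enc_cfg = EncoderConfig(input_size=cfg.image_size)
    cls_cfg = ClassifierConfig()
    profile = benchmark_split_profile(cfg.n_per_class_train, cfg.n_val,
                                      cfg.n_test)
    replicates = []
    for r in range(cfg.n_replicates):
        rep_seed = derive_seed(cfg.seed, f"replicate:{r}")
        data_dir = out / f"rep{r}" / "data"
        man = generate_dataset(profile, spec,
                               derive_seed(rep_seed, "data"), data_dir)
        rep = {"replicate": r, "seed": rep_seed, "models": {}}
        for regime in REGIMES:
            tcfg = cfg.train_config(regime, derive_seed(rep_seed, "train"))
            model, log = TRAINERS[regime](man, tcfg, enc_cfg=enc_cfg,
                                          cls_cfg=cls_cfg)
            result = evaluate_split(model, man, "test", cfg.levels)
            rep["models"][regime] = result
            if cfg.keep_artifacts:
                mdir = out / f"rep{r}" / regime
                mdir.mkdir(parents=True, exist_ok=True)
                model.save(mdir / "checkpoint.npz")
                log.save(mdir / "train_log.jsonl")
                write_report(result, mdir)
        replicates.append(rep)
    # averaged comparison table: rows = models, columns = level x metric
    rows = []
    for regime in REGIMES:
        row = {"model": regime}
        for level in cfg.levels:
            for metric in ("accuracy", "avg_f1"):
                vals = [rep["models"][regime]["levels"][str(level)][metric]
                        for rep in replicates]
                row[f"{level}class_{metric}"] = float(np.mean(vals))
        rows.append(row)
    table = pd.DataFrame(rows)
    result = {"config": asdict(cfg), "config_hash": config_hash(cfg),
              "seed": cfg.seed, "replicates": replicates,
              "table": rows}
    with open(out / "benchmark.json", "w") as fh:
        json.dump(result, fh, indent=1, default=str)
    table.to_csv(out / "comparison_table.tsv", sep="\t", index=False)
    return result


def load_train_config(path, **overrides) -> TrainConfig:
    """TrainConfig from a YAML file mirroring its fields; CLI flags
    override YAML values."""
    data = {}
    if path:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return TrainConfig(**data)


def validate(path) -> list[str]:
    man = DatasetManifest.load(path)
    return validate_manifest(man)
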