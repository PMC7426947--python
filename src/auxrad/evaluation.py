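"""Checkpoint evaluation against a manifest split: confusion matrices and
printed metrics at each hierarchy level, one-vs-rest AUC on softmax
scores, and latent-code export for external visualization (e.g. t-SNE)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as mx
from .manifest import DatasetManifest
from .models import SharedLatentModel, CLASS_NAMES, prepare_images
from .synth import load_split


def predict_split(model: SharedLatentModel, man: DatasetManifest,
                  split: str = "test", batch: int = 64):
    images, labels, _ = load_split(man, split)
    probs = []
    for i in range(0, len(images), batch):
        probs.append(model.predict_proba(images[i:i + batch]))
    return labels, np.concatenate(probs)


def evaluate_split(model: SharedLatentModel, man: DatasetManifest,
                   split: str = "test", levels=(2, 3, 7)) -> dict:
    """Metrics at the requested hierarchy levels plus per-class AUC (7-way)."""
    labels, probs = predict_split(model, man, split)
    preds = probs.argmax(axis=1)
    cm7 = mx.confusion_matrix(labels, preds, 7)
    out = {"split": split, "n": int(len(labels)), "levels": {}}
    for level in levels:
        cm = mx.collapse_cm(cm7, level)
        rep = mx.metrics(cm)
        out["levels"][str(level)] = {
            "accuracy": rep.accuracy, "avg_f1": rep.avg_f1,
            "precision": rep.precision, "recall": rep.recall, "f1": rep.f1,
            "confusion_matrix": cm.tolist(),
            "class_names": list(rep.class_names),
            "undefined": [[c, m] for c, m in rep.undefined],
        }
    out["auc_one_vs_rest"] = {CLASS_NAMES[c]: v for c, v in
                              mx.one_vs_rest_auc(labels, probs).items()}
    return out


def export_latents(model: SharedLatentModel, man: DatasetManifest,
                   split: str = "test", batch: int = 64) -> pd.DataFrame:
    """One row per sample: id, label, and the latent code values."""
    sub = man.split(split)
    images, labels, _ = load_split(man, split)
    zs = []
    for i in range(0, len(images), batch):
        zs.append(model.encode(prepare_images(images[i:i + batch],
                                              model.enc_cfg)))
    Z = np.concatenate(zs)
    df = pd.DataFrame(Z, columns=[f"z{i:02d}" for i in range(Z.shape[1])])
    df.insert(0, "label", [CLASS_NAMES[l] for l in labels])
    df.insert(0, "id", sub["id"].tolist())
    return df


def write_report(result: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "metrics.json", "w") as fh:
        json.dump(result, fh, indent=1)
    lines = []
    for level, rep in result["levels"].items():
        lines.append(f"== {level}-class ==")
        lines.append(mx.format_cm(np.array(rep["confusion_matrix"]),
                                  rep["class_names"]))
        lines.append(f"accuracy={rep['accuracy']:.4f}  "
                     f"avg_f1={rep['avg_f1']:.4f}")
        lines.append("")
    (out / "confusion_matrices.txt").write_text("\n".join(lines))
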