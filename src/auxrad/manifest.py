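"""Dataset manifests: the single source of truth for every pipeline stage.

A manifest is a delimited text file (TSV) with columns
``id, image, label, report, split`` plus a JSON metadata sidecar carrying
the generator seed and configuration.  Reports are attached to training
records only -- validation and test images are deliberately unpaired,
matching the protocol where auxiliary text exists only at training time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .models import CLASS_NAMES

COLUMNS = ["id", "image", "label", "report", "split"]
SPLITS = ("train", "val", "test")


@dataclass
class DatasetManifest:
    records: pd.DataFrame          # columns = COLUMNS
    root: Path = Path(".")
    meta: dict = field(default_factory=dict)

    def split(self, name: str) -> pd.DataFrame:
        return self.records[self.records["split"] == name]

    def counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for s in SPLITS:
            sub = self.split(s)
            out[s] = sub["label"].value_counts().to_dict()
        return out

    def save(self, path) -> None:
        path = Path(path)
        self.records[COLUMNS].to_csv(path, sep="\t", index=False)
        with open(path.with_suffix(".meta.json"), "w") as fh:
            json.dump(self.meta, fh, indent=1)

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        meta_path = path.with_suffix(".meta.json")
        meta = {}
        if meta_path.exists():
            with open(meta_path) as fh:
                meta = json.load(fh)
        return cls(df, root=path.parent, meta=meta)


def validate_manifest(man: DatasetManifest, check_files: bool = True
                      ) -> list[str]:
    """Protocol diagnostics; empty list means a well-formed manifest.

    Checks: known labels (C-types are invalid by design), disjoint splits
    covering all records, reports present only on training records, and
    referenced file existence.
    """
    problems: list[str] = []
    df = man.records
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        problems += [f"{i}: duplicate record id" for i in dups]
    for _, row in df.iterrows():
        rid = row["id"]
        if row["label"] not in CLASS_NAMES:
            problems.append(f"{rid}: invalid label {row['label']!r}")
        if row["split"] not in SPLITS:
            problems.append(f"{rid}: invalid split {row['split']!r}")
        if row["split"] in ("val", "test") and row["report"]:
            problems.append(f"{rid}: pairing violation -- {row['split']} "
                            "record carries a report")
        if check_files:
            img = man.root / row["image"]
            if not img.exists():
                problems.append(f"{rid}: missing image file {row['image']}")
            if row["report"]:
                rep = man.root / row["report"]
                if not rep.exists():
                    problems.append(f"{rid}: missing report file {row['report']}")
    return problems
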