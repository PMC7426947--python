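"""Synthetic paired radiograph-phantom and report generator.

Real pelvic radiographs with paired reports are protected patient data,
so this module emulates the *structure* of such a dataset: a stylized
pelvis with two femur contours rendered onto a noisy background, fracture
motifs drawn in the AO/OTA-designated anatomical region (A subtypes in
the trochanteric region, B subtypes in the femoral neck), class-consistent
template reports with a small constrained lexicon, severe class imbalance,
and strong non-fracture edge confounders on a fraction of normal images
(mimicking abdominal-fat overlap edges that distract image-only models).

Ground-truth fracture masks, which no real dataset provides, are emitted
so saliency maps can be scored against the true lesion support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.draw import disk, line

from .manifest import COLUMNS, DatasetManifest
from .models import CLASS_NAMES
from .seeding import derive_seed

FRACTURE_CLASSES = ("A1", "A2", "A3", "B1", "B2", "B3")


@dataclass
class PhantomSpec:
    image_size: int = 128
    jitter_pos: float = 0.02       # anatomy translation, fraction of size
    jitter_rot: float = 4.0        # global rotation range, degrees
    noise_sd: float = 0.10         # additive Gaussian noise, gray-levels in [0,1]
    confounder_prob: float = 0.3   # fraction of normals given strong edges

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        for p in (self.confounder_prob,):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticSample:
    image: np.ndarray              # (H, W) float32 in [0, 1]
    label: str
    fracture_mask: np.ndarray      # (H, W) bool; empty iff label == normal
    seed: int
    side: str = "left"
    report: str | None = None


def _thick_line(img, mask, r0, c0, r1, c1, value, width, accumulate=None):
    """Draw an anti-alias-free thick segment by stamping unit disks."""
    rr, cc = line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
    for r, c in zip(rr, cc):
        dd, cc2 = disk((r, c), width, shape=img.shape)
        img[dd, cc2] = value
        if accumulate is not None:
            accumulate[dd, cc2] = True


def _anatomy_points(s: int, side: str, jitter):
    """Key landmarks in pixel coords for one femur (left/right of image).

    The femoral neck spans roughly a quarter of the image so that the
    positional distinctions between neck-fracture subtypes are several
    pixels even at the 64-px benchmark size -- a phantom whose label
    cannot be read off the image would make every benchmark vacuous."""
    sign = -1 if side == "left" else 1
    jx, jy = jitter
    head = np.array([0.38 * s + jy, (0.5 + sign * 0.20) * s + jx])
    troch = np.array([0.58 * s + jy, (0.5 + sign * 0.38) * s + jx])
    shaft_end = np.array([0.95 * s + jy, (0.5 + sign * 0.33) * s + jx])
    return head, troch, shaft_end


def fracture_region(label: str, spec: PhantomSpec, side: str,
                    jitter=(0.0, 0.0)) -> np.ndarray:
    """Bounding polygon (rows, cols) of the designated anatomical region:
    trochanteric for A subtypes, femoral neck for B subtypes."""
    s = spec.image_size
    head, troch, _ = _anatomy_points(s, side, jitter)
    if label.startswith("A"):
        c = troch
        half = 0.14 * s
    elif label.startswith("B"):
        c = (head + troch) / 2.0
        half = 0.16 * s
    else:
        raise ValueError(f"no fracture region for label {label!r}")
    return np.array([[c[0] - half, c[1] - half], [c[0] - half, c[1] + half],
                     [c[0] + half, c[1] + half], [c[0] + half, c[1] - half]])


def render_phantom(label: str, spec: PhantomSpec, seed: int
                   ) -> SyntheticSample:
    """Render one stylized pelvis radiograph; deterministic under seed."""
    if label not in CLASS_NAMES:
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)
    s = spec.image_size
    img = np.full((s, s), 0.25, dtype=np.float64)
    mask = np.zeros((s, s), dtype=bool)
    jitter = rng.uniform(-spec.jitter_pos * s, spec.jitter_pos * s, size=2)
    side = "left" if rng.random() < 0.5 else "right"
    bone = 0.72
    # pelvic ring: bright ellipse annulus
    yy, xx = np.mgrid[0:s, 0:s]
    cy, cx = 0.32 * s + jitter[1], 0.5 * s + jitter[0]
    d = ((yy - cy) / (0.22 * s)) ** 2 + ((xx - cx) / (0.40 * s)) ** 2
    img[(d > 0.72) & (d < 1.0)] = 0.55
    w_neck = max(2, round(s / 26))
    w_shaft = max(3, round(s / 22))
    for sd in ("left", "right"):
        head, troch, shaft_end = _anatomy_points(s, sd, jitter)
        rr, cc = disk(head, 0.075 * s, shape=img.shape)
        img[rr, cc] = bone
        _thick_line(img, None, *head, *troch, bone, w_neck)
        _thick_line(img, None, *troch, *shaft_end, bone, w_shaft)
        rr, cc = disk(troch, 0.055 * s, shape=img.shape)
        img[rr, cc] = bone
    if label != "normal":
        _draw_fracture(img, mask, label, spec, side, jitter, rng)
    if label == "normal" and rng.random() < spec.confounder_prob:
        _draw_confounder(img, spec, rng)
    img = ndimage.gaussian_filter(img, sigma=s / 128.0)
    img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return SyntheticSample(img.astype(np.float32), label, mask, seed, side)


def _draw_fracture(img, mask, label, spec, side, jitter, rng):
    """Dark lucent fracture lines with subtype-specific geometry."""
    s = spec.image_size
    head, troch, _ = _anatomy_points(s, side, jitter)
    dark = 0.12
    w = max(1, round(s / 56))
    jit = lambda: rng.uniform(-0.012 * s, 0.012 * s)
    if label.startswith("A"):
        c = troch + np.array([jit(), jit()])
        L = 0.12 * s
        sign = -1 if side == "left" else 1
        if label == "A1":          # single oblique line
            d = np.array([1.0, sign * 1.0]) / np.sqrt(2)
            _thick_line(img, None, *(c - L * d), *(c + L * d), dark, w, mask)
        elif label == "A2":        # multifragmentary: main line + branches
            d = np.array([1.0, sign * 1.0]) / np.sqrt(2)
            _thick_line(img, None, *(c - L * d), *(c + L * d), dark, w, mask)
            for ang in (0.7, -0.9):
                d2 = np.array([np.cos(ang) * d[0] - np.sin(ang) * d[1],
                               np.sin(ang) * d[0] + np.cos(ang) * d[1]])
                _thick_line(img, None, *c, *(c + L * d2), dark, w, mask)
        else:                      # A3: reverse oblique (opposite slope)
            d = np.array([1.0, -sign * 1.0]) / np.sqrt(2)
            _thick_line(img, None, *(c - L * d), *(c + L * d), dark, w, mask)
    else:
        axis = troch - head
        axis = axis / np.linalg.norm(axis)
        perp = np.array([-axis[1], axis[0]])
        L = 0.09 * s
        if label == "B1":          # subcapital: just distal to the head
            c = head + 0.15 * (troch - head)
        elif label == "B2":        # transcervical: mid-neck
            c = head + 0.5 * (troch - head)
        else:                      # B3: displaced at the neck base
            c = head + 0.85 * (troch - head)
        c = c + np.array([jit(), jit()])
        _thick_line(img, None, *(c - L * perp), *(c + L * perp), dark, w, mask)
        if label == "B3":
            off = 0.05 * s * axis
            _thick_line(img, None, *(c - 0.8 * L * perp + off),
                        *(c + 0.8 * L * perp + off), dark, w, mask)


def _draw_confounder(img, spec, rng):
    """Strong non-fracture edge, e.g. an abdominal-fat overlap arc."""
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s]
    cy = rng.uniform(-0.4, -0.1) * s
    cx = rng.uniform(0.3, 0.7) * s
    r = rng.uniform(0.55, 0.8) * s
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    band = np.abs(d - r) < max(1.5, s / 80)
    img[band] = np.clip(img[band] + 0.35, 0, 1)


# -- reports -----------------------------------------------------------------

# Per-class report templates.  Each class keeps at least one distinctive
# keyword (KEYWORDS) present in every variant and absent from all other
# classes, so report class content is recoverable by keyword matching.
TEMPLATES: dict[str, list[str]] = {
    "normal": [
        "no acute fracture of either femur . hip joints and pelvic ring are intact",
        "both hips appear intact . no evidence of acute fracture or dislocation",
        "unremarkable study . femoral contours intact with no fracture",
    ],
    "A1": [
        "simple pertrochanteric fracture of the {side} femur with a single fracture line through the intertrochanteric region",
        "single oblique fracture line in the {side} intertrochanteric region consistent with a simple pertrochanteric fracture",
    ],
    "A2": [
        "comminuted multifragmentary pertrochanteric fracture of the {side} femur involving the intertrochanteric region",
        "multifragmentary fracture of the {side} trochanteric region with comminuted fragments",
    ],
    "A3": [
        "reverse oblique intertrochanteric fracture of the {side} proximal femur",
        "intertrochanteric fracture of the {side} femur with reverse obliquity pattern",
    ],
    "B1": [
        "subcapital fracture of the {side} femoral neck with minimal displacement",
        "minimally displaced subcapital fracture of the {side} femoral neck",
    ],
    "B2": [
        "transcervical fracture through the midportion of the {side} femoral neck",
        "fracture of the {side} femoral neck in its transcervical midportion",
    ],
    "B3": [
        "severely displaced subcapital fracture of the {side} femoral neck",
        "subcapital fracture of the {side} femoral neck with severe displacement",
    ],
}

KEYWORDS: dict[str, tuple[str, ...]] = {
    "normal": ("intact",),
    "A1": ("single",),
    "A2": ("multifragmentary",),
    "A3": ("reverse",),
    "B1": ("minimal", "minimally"),
    "B2": ("transcervical",),
    "B3": ("severe", "severely"),
}

_PREFIXES = ["", "impression : ", "findings : "]


def generate_report(label: str, seed: int, side: str | None = None,
                    templates: dict[str, list[str]] | None = None) -> str:
    """Class-consistent report from templates with light phrasing jitter."""
    templates = templates if templates is not None else TEMPLATES
    if label not in templates:
        raise KeyError(f"no report template for label {label!r}")
    rng = np.random.default_rng(seed)
    if side is None:
        side = "left" if rng.random() < 0.5 else "right"
    body = templates[label][rng.integers(len(templates[label]))]
    text = _PREFIXES[rng.integers(len(_PREFIXES))] + body.format(side=side)
    return text


def keyword_classify(report: str, keywords: dict = KEYWORDS) -> str | None:
    """Recover the class of a clean template report by keyword matching."""
    toks = set(report.lower().split())
    for label, keys in keywords.items():
        if label == "normal":
            continue
        if toks & set(keys):
            return label
    if toks & set(keywords["normal"]):
        return "normal"
    return None


# -- dataset assembly --------------------------------------------------------

def clinical_split_profile() -> dict[str, dict[str, int]]:
    """Per-split class counts of the emulated clinical protocol: 239 fracture /
    220 normal paired training cases, 59/41 validation, 112/115 test, with
    B3 extremely rare (5 cases in total) and 376 normals overall."""
    return {
        "train": {"normal": 220, "A1": 60, "A2": 55, "A3": 50,
                  "B1": 40, "B2": 30, "B3": 4},
        "val": {"normal": 41, "A1": 15, "A2": 14, "A3": 12,
                "B1": 10, "B2": 8, "B3": 0},
        "test": {"normal": 115, "A1": 28, "A2": 26, "A3": 24,
                 "B1": 18, "B2": 15, "B3": 1},
    }


def benchmark_split_profile(n_per_class_train: int = 100,
                            n_val: int = 100, n_test: int = 200
                            ) -> dict[str, dict[str, int]]:
    """Balanced desk-scale benchmark: ~700 paired training images,
    100 validation and 200 test images."""
    prof = {"train": {c: n_per_class_train for c in CLASS_NAMES}}
    for split, n in (("val", n_val), ("test", n_test)):
        base = n // 7
        extra = n - base * 7
        prof[split] = {c: base + (1 if i < extra else 0)
                       for i, c in enumerate(CLASS_NAMES)}
    return prof


def generate_dataset(split_counts: dict[str, dict[str, int]],
                     spec: PhantomSpec, seed: int, out_dir,
                     write_masks: bool = True) -> DatasetManifest:
    """Render images and reports, write them plus the manifest under
    ``out_dir``.  Training records are paired with reports; validation and
    test records never are."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(exist_ok=True)
    if write_masks:
        (out / "masks").mkdir(exist_ok=True)
    rows = []
    for split, counts in split_counts.items():
        for label, n in counts.items():
            if n < 0:
                raise ValueError("counts must be >= 0")
            for i in range(n):
                sid = f"{split}_{label}_{i:04d}"
                s_seed = derive_seed(seed, f"sample:{sid}")
                sample = render_phantom(label, spec, s_seed)
                img_rel = f"images/{sid}.png"
                Image.fromarray(
                    (sample.image * 255).round().astype(np.uint8)
                ).save(out / img_rel)
                if write_masks:
                    Image.fromarray(
                        sample.fracture_mask.astype(np.uint8) * 255
                    ).save(out / "masks" / f"{sid}.png")
                rep_rel = ""
                if split == "train":
                    rep = generate_report(label, derive_seed(seed, f"report:{sid}"),
                                          side=sample.side)
                    rep_rel = f"reports/{sid}.txt"
                    (out / rep_rel).write_text(rep, encoding="utf-8")
                rows.append({"id": sid, "image": img_rel, "label": label,
                             "report": rep_rel, "split": split})
    df = pd.DataFrame(rows, columns=COLUMNS)
    meta = {"seed": seed, "spec": asdict(spec), "split_counts": split_counts}
    man = DatasetManifest(df, root=out, meta=meta)
    man.save(out / "manifest.tsv")
    return man


# -- augmentation ------------------------------------------------------------

@dataclass
class AugmentationPolicy:
    rotation_range: tuple = (-10, 10)     # degrees, step 1
    scale_range: tuple = (90, 110)        # percent, step 1
    translation_range: tuple = (-10, 10)  # pixels per axis, step 1
    expansion_factor: int = 4
    exempt_classes: frozenset = frozenset({"normal"})


def _check_grid(value, lo, hi, name):
    if value != int(round(value)) or not lo <= value <= hi:
        raise ValueError(f"{name}={value} off the policy grid [{lo}, {hi}] step 1")
    return int(value)


def apply_transform(image: np.ndarray, rotation_deg, scale_pct, tx, ty,
                    policy: AugmentationPolicy = AugmentationPolicy()
                    ) -> np.ndarray:
    """Rotate and scale about the image center, then translate; bilinear
    interpolation, zero fill.  Parameters must lie on the policy grids."""
    rot = _check_grid(rotation_deg, *policy.rotation_range, "rotation")
    sc = _check_grid(scale_pct, *policy.scale_range, "scale")
    tx = _check_grid(tx, *policy.translation_range, "tx")
    ty = _check_grid(ty, *policy.translation_range, "ty")
    if rot == 0 and sc == 100 and tx == 0 and ty == 0:
        return image.copy()
    th = np.deg2rad(rot)
    s = sc / 100.0
    # output pixel -> input pixel: inverse of translate . scale . rotate
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    Minv = R.T / s
    center = (np.array(image.shape) - 1) / 2.0
    shift = np.array([ty, tx], dtype=float)
    # input = Minv @ (output - center - shift) + center
    offset = center - Minv @ (center + shift)
    return ndimage.affine_transform(
        image.astype(np.float64), Minv, offset=offset, order=1, mode="constant",
        cval=0.0).astype(image.dtype)


def augment_dataset(man: DatasetManifest, policy: AugmentationPolicy,
                    seed: int, out_dir=None) -> DatasetManifest:
    """Expand non-exempt training classes to ``expansion_factor`` times
    their original count (1 original + factor-1 transformed copies) with
    grid-sampled parameters.  Validation/test splits are untouched."""
    if policy.expansion_factor < 1:
        raise ValueError("expansion_factor must be >= 1")
    if not len(man.split("train")):
        raise ValueError("manifest has no training split")
    out = Path(out_dir) if out_dir is not None else man.root
    (out / "images_aug").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(derive_seed(seed, "augment"))
    rows = [dict(r) for _, r in man.records.iterrows()]
    new_rows = []
    for row in rows:
        new_rows.append(row)
        if row["split"] != "train" or row["label"] in policy.exempt_classes:
            continue
        img = np.asarray(Image.open(man.root / row["image"]), dtype=np.float32) / 255.0
        for k in range(policy.expansion_factor - 1):
            rot = int(rng.integers(policy.rotation_range[0],
                                   policy.rotation_range[1] + 1))
            sc = int(rng.integers(policy.scale_range[0],
                                  policy.scale_range[1] + 1))
            tx = int(rng.integers(policy.translation_range[0],
                                  policy.translation_range[1] + 1))
            ty = int(rng.integers(policy.translation_range[0],
                                  policy.translation_range[1] + 1))
            timg = apply_transform(img, rot, sc, tx, ty, policy)
            aid = f"{row['id']}_aug{k + 1}"
            rel = f"images_aug/{aid}.png"
            Image.fromarray((np.clip(timg, 0, 1) * 255).round().astype(np.uint8)
                            ).save(out / rel)
            new_rows.append({"id": aid, "image": rel, "label": row["label"],
                             "report": row["report"], "split": "train",
                             "_aug_params": (rot, sc, tx, ty)})
    params = {r["id"]: r.pop("_aug_params") for r in new_rows if "_aug_params" in r}
    df = pd.DataFrame(new_rows, columns=COLUMNS)
    meta = dict(man.meta)
    meta["augmentation"] = {"policy": {
        "rotation_range": list(policy.rotation_range),
        "scale_range": list(policy.scale_range),
        "translation_range": list(policy.translation_range),
        "expansion_factor": policy.expansion_factor,
        "exempt_classes": sorted(policy.exempt_classes)},
        "seed": seed,
        "params": {k: list(v) for k, v in params.items()}}
    aug = DatasetManifest(df, root=out, meta=meta)
    aug.save(out / "manifest_aug.tsv")
    return aug


def load_split(man: DatasetManifest, split: str):
    """Load a split's images (N,1,H,W float32 in [0,1]), integer labels,
    and report texts (None where unpaired)."""
    sub = man.split(split)
    images, labels, reports = [], [], []
    for _, row in sub.iterrows():
        img = np.asarray(Image.open(man.root / row["image"]), dtype=np.float32) / 255.0
        images.append(img[None])
        labels.append(CLASS_NAMES.index(row["label"]))
        if row["report"]:
            reports.append((man.root / row["report"]).read_text(encoding="utf-8"))
        else:
            reports.append(None)
    return np.stack(images), np.asarray(labels, dtype=np.int64), reports
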