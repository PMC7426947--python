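"""Shared-latent encoder / decoder / classifier models.

The architecture couples three components through a single latent code z:

* an image **encoder** (configurable CNN backbone) mapping a grayscale
  radiograph to a 64-D latent vector,
* a bidirectional-LSTM **decoder** that, conditioned on z through learned
  projections of its initial hidden (and optionally cell) states,
  reconstructs the paired radiology report under teacher forcing, and
* a two-layer **classifier** producing AO/OTA class logits from z.

At inference only the encoder + classifier path is used; the decoder (and
hence the report text) exists only at training time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.transform import resize as _resize

from . import nn
from .seeding import rng_for

CLASS_NAMES = ("normal", "A1", "A2", "A3", "B1", "B2", "B3")


@dataclass
class EncoderConfig:
    input_size: int = 128
    backbone: str = "small-cnn"          # small-cnn | inception-like
    latent_dim: int = 64
    dropout: float = 0.5
    channels: tuple = (8, 16, 32, 64)    # small-cnn block widths
    head: str = "flatten"                # flatten | gap
    dtype: str = "float32"

    def __post_init__(self):
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.backbone not in ("small-cnn", "inception-like"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.head not in ("flatten", "gap"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.input_size % 16:
            raise ValueError("input_size must be divisible by 16")


@dataclass
class DecoderConfig:
    steps: int = 40                      # max report length in tokens
    embed_dim: int = 128
    hidden: int = 128                    # units per LSTM direction
    vocab_size: int = 0                  # set from the fitted vocabulary
    dropout: float = 0.5
    condition_cell: bool = True          # project z into c0 as well as h0
    train_embeddings: bool = True

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


@dataclass
class ClassifierConfig:
    hidden: int = 32
    classes: int = 7


def _dt(cfg: EncoderConfig):
    return np.float64 if cfg.dtype == "float64" else np.float32


def build_encoder(cfg: EncoderConfig, seed: int) -> nn.Sequential:
    """CNN backbone -> spatial head -> dense projection to z.

    ``small-cnn``: stride-2 stem conv then three conv/pool blocks.  The
    default head flattens the final feature maps before the latent
    projection: fracture subtypes differ chiefly in *where* the lucent
    line sits (trochanteric vs neck, position along the neck), and a
    global average pool would discard exactly that information.  Dropout
    (rate 0.5 by default) is applied at the head, before the latent
    projection, following standard practice for Inception-style
    classifiers.  ``inception-like``: stem plus two mixed multi-kernel
    blocks in the Inception spirit (not layer-exact).
    """
    rng = rng_for(seed, "encoder.init")
    dt = _dt(cfg)
    layers, names = [], []
    if cfg.backbone == "small-cnn":
        c_prev = 1
        spatial = cfg.input_size // 2
        for i, c in enumerate(cfg.channels, start=1):
            stride = 2 if i == 1 else 1
            layers.append(nn.Conv2d(c_prev, c, rng, k=3, stride=stride, dtype=dt))
            names.append(f"conv{i}")
            layers.append(nn.ReLU()); names.append(f"relu{i}")
            if i < len(cfg.channels):
                layers.append(nn.MaxPool2d(2)); names.append(f"pool{i}")
                spatial //= 2
            c_prev = c
        feat = cfg.channels[-1]
    else:
        layers += [nn.Conv2d(1, 16, rng, k=3, stride=2, dtype=dt), nn.ReLU(),
                   nn.MaxPool2d(2)]
        names += ["stem", "relu_stem", "pool_stem"]
        layers += [nn.ConcatConv(16, [8, 16, 8], [1, 3, 5], rng, dtype=dt),
                   nn.ReLU(), nn.MaxPool2d(2)]
        names += ["mixed1", "relu_mixed1", "pool_mixed1"]
        layers += [nn.ConcatConv(32, [16, 32, 16], [1, 3, 5], rng, dtype=dt),
                   nn.ReLU(), nn.MaxPool2d(2)]
        names += ["mixed2", "relu_mixed2", "pool_mixed2"]
        feat = 64
        spatial = cfg.input_size // 16
    if cfg.head == "gap":
        layers += [nn.GlobalAvgPool()]
        names += ["gap"]
        feat_in = feat
    else:
        layers += [nn.Flatten()]
        names += ["flatten"]
        feat_in = feat * spatial * spatial
    layers += [nn.Dropout(cfg.dropout, rng_for(seed, "encoder.drop_head")),
               nn.Dense(feat_in, cfg.latent_dim, rng, dtype=dt)]
    names += ["drop_head", "latent"]
    return nn.Sequential(layers, names)


def build_classifier(cfg: ClassifierConfig, latent_dim: int, seed: int,
                     dtype=np.float32) -> nn.Sequential:
    rng = rng_for(seed, "classifier.init")
    return nn.Sequential(
        [nn.Dense(latent_dim, cfg.hidden, rng, dtype=dtype), nn.ReLU(),
         nn.Dense(cfg.hidden, cfg.classes, rng, dtype=dtype)],
        ["fc1", "relu", "fc2"])


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class BiLSTMDecoder:
    """Teacher-forced bidirectional LSTM over report tokens.

    z conditions both directions through learned projections to the
    initial hidden state (and, by default, the initial cell state).  At
    each step the two directions' hidden states are concatenated and
    projected to a distribution over the vocabulary.  Because the decoder
    is bidirectional the objective is report *restoration* under teacher
    forcing, not free generation.
    """

    def __init__(self, cfg: DecoderConfig, latent_dim: int, seed: int,
                 embeddings: np.ndarray | None = None, dtype=np.float32):
        if cfg.vocab_size < 2:
            raise ValueError("decoder vocab_size must be set (>= 2)")
        self.cfg = cfg
        self.latent_dim = latent_dim
        rng = rng_for(seed, "decoder.init")
        V, D, H = cfg.vocab_size, cfg.embed_dim, cfg.hidden
        def init(*shape, fan):
            return (rng.standard_normal(shape) / np.sqrt(fan)).astype(dtype)
        self.params: dict[str, np.ndarray] = {}
        p = self.params
        if embeddings is not None:
            if embeddings.shape != (V, D):
                raise ValueError(f"embeddings must be {(V, D)}, got {embeddings.shape}")
            p["E"] = embeddings.astype(dtype).copy()
        else:
            p["E"] = init(V, D, fan=D)
        for d in ("f", "b"):
            p[f"Wx_{d}"] = init(D, 4 * H, fan=D)
            p[f"Wh_{d}"] = init(H, 4 * H, fan=H)
            p[f"b_{d}"] = np.zeros(4 * H, dtype=dtype)
            p[f"Wzh_{d}"] = init(latent_dim, H, fan=latent_dim)
            p[f"bzh_{d}"] = np.zeros(H, dtype=dtype)
            if cfg.condition_cell:
                p[f"Wzc_{d}"] = init(latent_dim, H, fan=latent_dim)
                p[f"bzc_{d}"] = np.zeros(H, dtype=dtype)
        p["Wo"] = init(2 * H, V, fan=2 * H)
        p["bo"] = np.zeros(V, dtype=dtype)
        # forget-gate bias 1: standard LSTM trainability aid
        for d in ("f", "b"):
            p[f"b_{d}"][H:2 * H] = 1.0
        self.grads: dict[str, np.ndarray] = {}
        self._drop_in = nn.Dropout(cfg.dropout, rng_for(seed, "decoder.drop_in"))
        self._drop_out = nn.Dropout(cfg.dropout, rng_for(seed, "decoder.drop_out"))
        self._cache = None

    def _run_dir(self, X, z, d, train):
        """One direction; X is already time-ordered for this direction."""
        p = self.params
        B, T, D = X.shape
        H = self.cfg.hidden
        h = z @ p[f"Wzh_{d}"] + p[f"bzh_{d}"]
        if self.cfg.condition_cell:
            c = z @ p[f"Wzc_{d}"] + p[f"bzc_{d}"]
        else:
            c = np.zeros_like(h)
        h0, c0 = h, c
        steps = []
        hs = np.empty((B, T, H), dtype=X.dtype)
        for t in range(T):
            x = X[:, t]
            a = x @ p[f"Wx_{d}"] + h @ p[f"Wh_{d}"] + p[f"b_{d}"]
            i = _sigmoid(a[:, :H]); f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H]); o = _sigmoid(a[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            steps.append((x, h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        return hs, steps, h0, c0

    def _back_dir(self, dH, steps, d):
        p, g_ = self.params, self.grads
        B, T, H = dH.shape
        D = self.cfg.embed_dim
        for nm in (f"Wx_{d}", f"Wh_{d}", f"b_{d}"):
            g_.setdefault(nm, np.zeros_like(p[nm]))
        dX = np.empty((B, T, D), dtype=dH.dtype)
        dh_next = np.zeros((B, H), dtype=dH.dtype)
        dc_next = np.zeros((B, H), dtype=dH.dtype)
        for t in reversed(range(T)):
            x, h_prev, c_prev, i, f, g, o, tc = steps[t]
            dh = dH[:, t] + dh_next
            dc = dc_next + dh * o * (1 - tc * tc)
            do = dh * tc
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            da = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            g_[f"Wx_{d}"] += x.T @ da
            g_[f"Wh_{d}"] += h_prev.T @ da
            g_[f"b_{d}"] += da.sum(axis=0)
            dX[:, t] = da @ p[f"Wx_{d}"].T
            dh_next = da @ p[f"Wh_{d}"].T
        return dX, dh_next, dc_next

    def forward(self, z: np.ndarray, ids: np.ndarray, train: bool = False
                ) -> np.ndarray:
        """Per-step vocabulary distributions, shape (B, steps, V)."""
        p = self.params
        B, T = ids.shape
        if T != self.cfg.steps:
            raise ValueError(f"teacher sequence length {T} != steps {self.cfg.steps}")
        if z.shape[1] != self.latent_dim:
            raise ValueError("latent dim mismatch")
        X = p["E"][ids]
        X = self._drop_in.forward(X, train)
        hs_f, steps_f, *_ = self._run_dir(X, z, "f", train)
        Xr = X[:, ::-1]
        hs_br, steps_b, *_ = self._run_dir(Xr, z, "b", train)
        hs_b = hs_br[:, ::-1]
        Hcat = np.concatenate([hs_f, hs_b], axis=2)
        Hcat = self._drop_out.forward(Hcat, train)
        logits = Hcat @ p["Wo"] + p["bo"]
        probs = nn.softmax(logits, axis=-1)
        self._cache = (z, ids, X, steps_f, steps_b, Hcat, probs)
        return probs

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backprop from d(loss)/d(logits); returns d(loss)/dz."""
        p, g_ = self.params, self.grads
        z, ids, X, steps_f, steps_b, Hcat, _ = self._cache
        B, T, V = dlogits.shape
        H = self.cfg.hidden
        g_["Wo"] = np.einsum("btk,btv->kv", Hcat, dlogits)
        g_["bo"] = dlogits.sum(axis=(0, 1))
        dHcat = dlogits @ p["Wo"].T
        dHcat = self._drop_out.backward(dHcat)
        dhf = dHcat[:, :, :H]
        dhb = dHcat[:, :, H:][:, ::-1]
        dXf, dh0_f, dc0_f = self._back_dir(np.ascontiguousarray(dhf), steps_f, "f")
        dXbr, dh0_b, dc0_b = self._back_dir(np.ascontiguousarray(dhb), steps_b, "b")
        dX = dXf + dXbr[:, ::-1]
        dX = self._drop_in.backward(dX)
        dz = np.zeros_like(z)
        for d, dh0, dc0 in (("f", dh0_f, dc0_f), ("b", dh0_b, dc0_b)):
            g_[f"Wzh_{d}"] = z.T @ dh0
            g_[f"bzh_{d}"] = dh0.sum(axis=0)
            dz += dh0 @ p[f"Wzh_{d}"].T
            if self.cfg.condition_cell:
                g_[f"Wzc_{d}"] = z.T @ dc0
                g_[f"bzc_{d}"] = dc0.sum(axis=0)
                dz += dc0 @ p[f"Wzc_{d}"].T
        if self.cfg.train_embeddings:
            dE = np.zeros_like(p["E"])
            np.add.at(dE, ids, dX)
            g_["E"] = dE
        return dz


class SharedLatentModel:
    """Container wiring encoder, optional decoder, and classifier."""

    def __init__(self, enc_cfg: EncoderConfig, cls_cfg: ClassifierConfig,
                 dec_cfg: DecoderConfig | None, seed: int,
                 embeddings: np.ndarray | None = None):
        self.enc_cfg, self.cls_cfg, self.dec_cfg = enc_cfg, cls_cfg, dec_cfg
        self.seed = seed
        dt = _dt(enc_cfg)
        self.encoder = build_encoder(enc_cfg, seed)
        self.classifier = build_classifier(cls_cfg, enc_cfg.latent_dim, seed, dt)
        self.decoder = (BiLSTMDecoder(dec_cfg, enc_cfg.latent_dim, seed,
                                      embeddings, dt)
                        if dec_cfg is not None else None)

    # -- forward passes ---------------------------------------------------
    def encode(self, images: np.ndarray, train: bool = False,
               capture: bool = False) -> np.ndarray:
        if images.ndim != 4 or images.shape[1] != 1:
            raise ValueError("images must be (N, 1, H, W)")
        if images.shape[2] != self.enc_cfg.input_size:
            raise ValueError(
                f"images must be {self.enc_cfg.input_size}px, got {images.shape[2]}")
        z = self.encoder.forward(images, train=train, capture=capture)
        if not np.all(np.isfinite(z)):
            raise FloatingPointError("non-finite latent code")
        return z

    def classify(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        return self.classifier.forward(z, train=train)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities from images alone; text is never consulted."""
        z = self.encode(prepare_images(images, self.enc_cfg), train=False)
        return nn.softmax(self.classify(z), axis=-1)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "encoder": asdict(self.enc_cfg),
            "classifier": asdict(self.cls_cfg),
            "decoder": asdict(self.dec_cfg) if self.dec_cfg else None,
            "seed": self.seed,
        }
        arrays = {"__meta__": np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)}
        for key, layer, pname in self.encoder.parameters():
            arrays[f"encoder.{key}"] = layer.params[pname]
        for key, layer, pname in self.classifier.parameters():
            arrays[f"classifier.{key}"] = layer.params[pname]
        if self.decoder is not None:
            for k, v in self.decoder.params.items():
                arrays[f"decoder.{k}"] = v
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SharedLatentModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            enc_cfg = EncoderConfig(**{k: tuple(v) if k == "channels" else v
                                       for k, v in meta["encoder"].items()})
            cls_cfg = ClassifierConfig(**meta["classifier"])
            dec_cfg = (DecoderConfig(**meta["decoder"])
                       if meta["decoder"] else None)
            model = cls(enc_cfg, cls_cfg, dec_cfg, meta["seed"])
            for key, layer, pname in model.encoder.parameters():
                layer.params[pname] = data[f"encoder.{key}"]
            for key, layer, pname in model.classifier.parameters():
                layer.params[pname] = data[f"classifier.{key}"]
            if model.decoder is not None:
                for k in model.decoder.params:
                    model.decoder.params[k] = data[f"decoder.{k}"]
        return model


def prepare_images(images: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    """Resize to the encoder's input size and normalize intensities to [0,1]."""
    if images.ndim == 2:
        images = images[None]
    if images.ndim == 3:
        images = images[:, None]
    images = images.astype(_dt(cfg))
    if images.max() > 1.0:
        images = images / 255.0
    s = cfg.input_size
    if images.shape[2] != s or images.shape[3] != s:
        out = np.empty((images.shape[0], 1, s, s), dtype=images.dtype)
        for i in range(images.shape[0]):
            out[i, 0] = _resize(images[i, 0], (s, s), order=1,
                                anti_aliasing=True, preserve_range=True)
        images = out
    return images


def predict(image: np.ndarray, model: SharedLatentModel) -> np.ndarray:
    """7-class probability vector for a single image (softmax of logits)."""
    return model.predict_proba(image[None] if image.ndim == 2 else image)[0]
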