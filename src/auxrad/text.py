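"""Report corpus handling: tokenization, frequency-truncated vocabulary,
padded one-hot encoding, and co-occurrence-based (GloVe) word embeddings.

Radiology reports are short constrained-language sentences; the corpus
cap of 300 most-frequent words (out of the full lexicon) and the 40-token
maximum sequence length mirror the text pipeline this package implements.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

PAD, START, END, UNK = "<pad>", "<s>", "</s>", "<unk>"
SPECIALS = (PAD, START, END, UNK)

_PUNCT = re.compile(r"^\W+|\W+$", flags=re.UNICODE)


class EmptyReportError(ValueError):
    pass


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace, strip flanking punctuation.

    Alphanumeric class codes like ``a1`` survive intact.  Tokens that are
    pure punctuation vanish.  Raises on empty / whitespace-only input.
    """
    if not text or not text.strip():
        raise EmptyReportError("report text is empty")
    toks = []
    for raw in text.lower().split():
        t = _PUNCT.sub("", raw)
        if t:
            toks.append(t)
    if not toks:
        raise EmptyReportError("report contains no word tokens")
    return toks


@dataclass
class Vocabulary:
    token_to_id: dict[str, int]
    frequencies: dict[str, int]
    specials: tuple = SPECIALS

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, self.unk_id)

    @property
    def id_to_token(self) -> list[str]:
        inv = [""] * self.size
        for t, i in self.token_to_id.items():
            inv[i] = t
        return inv

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"tokens": [
                {"token": t, "id": i, "frequency": self.frequencies.get(t, 0)}
                for t, i in sorted(self.token_to_id.items(), key=lambda kv: kv[1])
            ]}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Vocabulary":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        t2i = {e["token"]: e["id"] for e in data["tokens"]}
        freq = {e["token"]: e["frequency"] for e in data["tokens"]
                if e["token"] not in SPECIALS}
        return cls(t2i, freq)


def build_vocabulary(corpus: list[list[str]], max_size: int = 300
                     ) -> Vocabulary:
    """Keep the ``max_size`` most frequent tokens plus the four specials.

    Frequency ties break lexicographically, which together with counting
    makes the vocabulary invariant to corpus order.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    freq: dict[str, int] = {}
    for toks in corpus:
        for t in toks:
            freq[t] = freq.get(t, 0) + 1
    kept = sorted(freq, key=lambda t: (-freq[t], t))[:max_size]
    token_to_id = {s: i for i, s in enumerate(SPECIALS)}
    for t in sorted(kept, key=lambda t: (-freq[t], t)):
        token_to_id[t] = len(token_to_id)
    return Vocabulary(token_to_id, {t: freq[t] for t in kept})


@dataclass
class TokenizedReport:
    tokens: list[str]
    ids: list[int]

    @property
    def length(self) -> int:
        return len(self.ids)


def tokenize_report(text: str, vocab: Vocabulary, max_len: int = 40
                    ) -> TokenizedReport:
    toks = tokenize(text)
    if len(toks) > max_len:
        warnings.warn(f"report of {len(toks)} tokens truncated to {max_len}")
        toks = toks[:max_len]
    return TokenizedReport(toks, [vocab.id_of(t) for t in toks])


@dataclass
class OneHotSequence:
    matrix: np.ndarray      # (max_len, V) binary
    mask: np.ndarray        # (max_len,) binary; 1 = real token


def encode_one_hot(report: TokenizedReport, vocab: Vocabulary,
                   max_len: int = 40) -> OneHotSequence:
    """Row i is the one-hot of token i; rows beyond the report length are
    PAD one-hots with mask 0.  Every row sums to exactly 1."""
    if report.length > max_len:
        raise ValueError("report longer than max_len; tokenize_report truncates")
    mat = np.zeros((max_len, vocab.size), dtype=np.int8)
    mask = np.zeros(max_len, dtype=np.int8)
    for i, tid in enumerate(report.ids):
        mat[i, tid] = 1
        mask[i] = 1
    mat[report.length:, vocab.pad_id] = 1
    return OneHotSequence(mat, mask)


def pad_ids(report: TokenizedReport, vocab: Vocabulary, max_len: int = 40
            ) -> np.ndarray:
    out = np.full(max_len, vocab.pad_id, dtype=np.int64)
    out[:report.length] = report.ids
    return out


@dataclass
class CooccurrenceMatrix:
    counts: np.ndarray      # (V, V) nonnegative reals
    window: int
    weighting: str = "uniform"   # uniform | inverse-distance


def build_cooccurrence(corpus: list[list[str]], vocab: Vocabulary,
                       window: int = 5, weighting: str = "uniform"
                       ) -> CooccurrenceMatrix:
    """Symmetric-window co-occurrence counts over in-vocabulary tokens.

    OOV tokens are dropped before pairing.  ``inverse-distance`` weights a
    pair at distance d by 1/d (the GloVe convention); the diagonal is zero
    since a token never co-occurs with itself at distance 0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if weighting not in ("uniform", "inverse-distance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    V = vocab.size
    counts = np.zeros((V, V), dtype=float)
    special_ids = {vocab.token_to_id[s] for s in vocab.specials}
    for toks in corpus:
        ids = [vocab.token_to_id[t] for t in toks if t in vocab.token_to_id
               and vocab.token_to_id[t] not in special_ids]
        for i, a in enumerate(ids):
            for d in range(1, window + 1):
                j = i + d
                if j >= len(ids):
                    break
                b = ids[j]
                w = 1.0 if weighting == "uniform" else 1.0 / d
                counts[a, b] += w
                counts[b, a] += w
    return CooccurrenceMatrix(counts, window, weighting)


@dataclass
class EmbeddingMatrix:
    vectors: np.ndarray     # (V, d)
    seed: int
    trained_on: str = ""    # corpus fingerprint

    def save(self, path_prefix) -> None:
        np.save(f"{path_prefix}.npy", self.vectors)
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump({"d": int(self.vectors.shape[1]),
                       "V": int(self.vectors.shape[0]),
                       "seed": self.seed,
                       "trained_on": self.trained_on}, fh)


def glove_objective(cooc: CooccurrenceMatrix, w, wt, b, bt,
                    x_max: float = 100.0, power: float = 0.75) -> float:
    """Weighted least squares on log-counts over nonzero cells."""
    X = cooc.counts
    ii, jj = np.nonzero(X)
    x = X[ii, jj]
    f = np.minimum((x / x_max) ** power, 1.0)
    err = (w[ii] * wt[jj]).sum(axis=1) + b[ii] + bt[jj] - np.log(x)
    return float((f * err * err).sum())


def fit_glove(cooc: CooccurrenceMatrix, d: int = 128, epochs: int = 100,
              seed: int = 0, lr: float = 0.05, x_max: float = 100.0,
              power: float = 0.75) -> EmbeddingMatrix:
    """Full-batch gradient descent on the GloVe weighted-least-squares
    objective; the final embedding is the sum of word and context vectors.

    With a sufficiently small step the objective is non-increasing; the
    fitter halves the step whenever a step would increase it, so the
    recorded objective trace is monotone within tolerance.
    """
    X = cooc.counts
    ii, jj = np.nonzero(X)
    if len(ii) == 0:
        raise ValueError("co-occurrence matrix has no positive entries")
    V = X.shape[0]
    rng = np.random.default_rng(seed)
    w = (rng.random((V, d)) - 0.5) / d
    wt = (rng.random((V, d)) - 0.5) / d
    b = np.zeros(V)
    bt = np.zeros(V)
    x = X[ii, jj]
    f = np.minimum((x / x_max) ** power, 1.0)
    logx = np.log(x)
    prev = glove_objective(cooc, w, wt, b, bt, x_max, power)
    objective_trace = [prev]
    for _ in range(epochs):
        err = (w[ii] * wt[jj]).sum(axis=1) + b[ii] + bt[jj] - logx
        fe = f * err
        gw = np.zeros_like(w); gwt = np.zeros_like(wt)
        gb = np.zeros_like(b); gbt = np.zeros_like(bt)
        np.add.at(gw, ii, 2 * fe[:, None] * wt[jj])
        np.add.at(gwt, jj, 2 * fe[:, None] * w[ii])
        np.add.at(gb, ii, 2 * fe)
        np.add.at(gbt, jj, 2 * fe)
        step = lr
        while True:
            w2, wt2 = w - step * gw, wt - step * gwt
            b2, bt2 = b - step * gb, bt - step * gbt
            val = glove_objective(cooc, w2, wt2, b2, bt2, x_max, power)
            if val <= prev + 1e-8 or step < 1e-12:
                break
            step /= 2.0
        w, wt, b, bt, prev = w2, wt2, b2, bt2, val
        objective_trace.append(prev)
    vectors = w + wt
    if not np.all(np.isfinite(vectors)):
        raise FloatingPointError("non-finite embedding")
    emb = EmbeddingMatrix(vectors.astype(np.float64), seed)
    emb.objective_trace = objective_trace
    return emb


def load_corpus(path) -> list[list[str]]:
    """One report per line in a UTF-8 text file."""
    corpus = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                corpus.append(tokenize(line))
    return corpus
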