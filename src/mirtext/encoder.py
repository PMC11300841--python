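"""A compact trainable text encoder with the two contracts the pipeline needs.

The tagging and relation modules are encoder-agnostic: they require only
(a) a subword tokenizer mapping each word to >= 1 subtokens and (b) an
encoder mapping a subtoken id sequence to one vector per subtoken plus a
pooled sentence vector. This module provides a small, fully deterministic
implementation of that contract in numpy:

* :class:`WordpieceTokenizer` — greedy longest-match wordpiece over a vocab
  built from a training corpus (whole words above a frequency cutoff,
  character fallback with ``##`` continuation pieces). Placeholder tokens
  such as ``@MIRNA$`` are registered as atomic, never split.
* :class:`TinyEncoder` — token embeddings followed by two tanh layers; each
  layer mixes every position with the sequence mean, so the final states are
  contextual and the pooled representation (CLS position or mean) sees the
  whole sentence. Trained by plain backpropagation with Adam.

The encoder is desk-scale by design: a few thousand parameters, minutes on
one CPU, exactly reproducible for a fixed seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

PAD, UNK, CLS = "[PAD]", "[UNK]", "[CLS]"

_PRETOKEN_RE = re.compile(r"\w+(?:[-/]\w+)*|[^\w\s]")


def pretokenize(text: str) -> list[str]:
    """Split text into words (hyphen/slash compounds kept whole) and punctuation."""
    return _PRETOKEN_RE.findall(text)


@dataclass
class WordpieceTokenizer:
    vocab: dict[str, int]
    atomic: frozenset[str] = frozenset()
    lowercase: bool = True

    @classmethod
    def train(cls, texts: list[str], vocab_size: int = 512,
              atomic_tokens: tuple[str, ...] = (),
              lowercase: bool = True) -> "WordpieceTokenizer":
        """Build a vocab: specials + atomic tokens + chars + frequent words."""
        counts: dict[str, int] = {}
        chars: set[str] = set()
        for text in texts:
            for word in pretokenize(text):
                if lowercase:
                    word = word.lower()
                counts[word] = counts.get(word, 0) + 1
                chars.update(word)
        vocab: dict[str, int] = {}
        for token in (PAD, UNK, CLS, *atomic_tokens):
            vocab.setdefault(token, len(vocab))
        for ch in sorted(chars):
            for piece in (ch, "##" + ch):
                vocab.setdefault(piece, len(vocab))
        by_freq = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        for word, _n in by_freq:
            if len(vocab) >= vocab_size:
                break
            vocab.setdefault(word, len(vocab))
        return cls(vocab=vocab, atomic=frozenset(atomic_tokens),
                   lowercase=lowercase)

    def split_word(self, word: str) -> list[str]:
        """Greedy longest-match wordpiece split of one word."""
        if word in self.atomic:
            return [word]
        if self.lowercase:
            word = word.lower()
        if word in self.vocab:
            return [word]
        pieces: list[str] = []
        pos = 0
        while pos < len(word):
            prefix = "##" if pieces else ""
            end = len(word)
            while end > pos:
                piece = prefix + word[pos:end]
                if piece in self.vocab:
                    pieces.append(piece)
                    break
                end -= 1
            else:
                pieces.append(UNK)
                end = pos + 1
            pos = end
        return pieces

    def encode_words(self, words: list[str]) -> tuple[list[int], list[int]]:
        """Subtoken ids (with a leading CLS) and the word index per subtoken.

        The word index of the CLS position is -1. Every word produces at
        least one subtoken.
        """
        ids = [self.vocab[CLS]]
        word_index = [-1]
        for w_i, word in enumerate(words):
            for piece in self.split_word(word):
                ids.append(self.vocab.get(piece, self.vocab[UNK]))
                word_index.append(w_i)
        return ids, word_index

    def encode_text(self, text: str) -> list[int]:
        ids, _ = self.encode_words(pretokenize(text))
        return ids

    def __len__(self) -> int:
        return len(self.vocab)


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------

@dataclass
class EncoderConfig:
    vocab_size: int
    width: int = 32
    n_layers: int = 2
    max_length: int = 64
    pooling: str = "cls"  # "cls" or "mean"
    seed: int = 0


class TinyEncoder:
    """Embeddings + ``n_layers`` mean-context tanh layers.

    Layer l: ``H_out = tanh(H W_s + 1 (m W_c) + b)`` where ``m`` is the mean
    of ``H`` over positions. The mean term makes every output state, and in
    particular the CLS position, contextual.
    """

    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.width
        scale = 1.0 / np.sqrt(d)
        self.embeddings = rng.normal(0.0, 0.5, size=(config.vocab_size, d))
        self.layers = [
            {
                "W_s": rng.normal(0.0, scale, size=(d, d)),
                "W_c": rng.normal(0.0, scale, size=(d, d)),
                "b": np.zeros(d),
            }
            for _ in range(config.n_layers)
        ]

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        params = {"embeddings": self.embeddings}
        for i, layer in enumerate(self.layers):
            for key, value in layer.items():
                params[f"layer{i}.{key}"] = value
        return params

    # -- forward / backward -------------------------------------------------
    def forward(self, ids: list[int]) -> tuple[np.ndarray, dict]:
        """Per-subtoken states (n, d) and a cache for backward()."""
        ids = list(ids[: self.config.max_length])
        H = self.embeddings[ids]
        cache: dict = {"ids": ids, "inputs": [], "outputs": []}
        for layer in self.layers:
            cache["inputs"].append(H)
            m = H.mean(axis=0)
            H = np.tanh(H @ layer["W_s"] + m @ layer["W_c"] + layer["b"])
            cache["outputs"].append(H)
        return H, cache

    def pooled(self, states: np.ndarray) -> np.ndarray:
        if self.config.pooling == "mean":
            return states.mean(axis=0)
        return states[0]

    def pooled_grad(self, states: np.ndarray, d_pooled: np.ndarray) -> np.ndarray:
        dH = np.zeros_like(states)
        if self.config.pooling == "mean":
            dH += d_pooled / states.shape[0]
        else:
            dH[0] = d_pooled
        return dH

    def backward(self, cache: dict, dH: np.ndarray,
                 grads: dict[str, np.ndarray]) -> None:
        """Accumulate parameter gradients given d(loss)/d(final states)."""
        n = dH.shape[0]
        for i in reversed(range(len(self.layers))):
            layer = self.layers[i]
            H_in, H_out = cache["inputs"][i], cache["outputs"][i]
            dA = dH * (1.0 - H_out ** 2)
            col = dA.sum(axis=0)
            grads[f"layer{i}.W_s"] += H_in.T @ dA
            grads[f"layer{i}.W_c"] += np.outer(H_in.mean(axis=0), col)
            grads[f"layer{i}.b"] += col
            dH = dA @ layer["W_s"].T + np.outer(
                np.ones(n) / n, col @ layer["W_c"].T)
        np.add.at(grads["embeddings"], cache["ids"], dH)


class AdamOptimizer:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, param in self.params.items():
            g = grads[key]
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            m_hat = self.m[key] / (1 - self.beta1 ** self.t)
            v_hat = self.v[key] / (1 - self.beta2 ** self.t)
            param -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# Heads
# ---------------------------------------------------------------------------

@dataclass
class LinearHead:
    """A single linear layer mapping a d-vector to ``n_out`` logits.

    Heads are zero-initialized: an untrained classifier is exactly
    uninformative (all logits zero, every score tied), and the first
    optimizer step breaks the symmetry through the loss gradient.
    """

    W: np.ndarray
    b: np.ndarray
    name: str = "head"

    @classmethod
    def create(cls, width: int, n_out: int,
               rng: np.random.Generator | None = None,
               name: str = "head") -> "LinearHead":
        return cls(W=np.zeros((width, n_out)), b=np.zeros(n_out), name=name)

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def logits(self, states: np.ndarray) -> np.ndarray:
        return states @ self.W + self.b

    def backward(self, states: np.ndarray, d_logits: np.ndarray,
                 grads: dict[str, np.ndarray]) -> np.ndarray:
        if d_logits.ndim == 1:
            grads[f"{self.name}.W"] += np.outer(states, d_logits)
            grads[f"{self.name}.b"] += d_logits
            return d_logits @ self.W.T
        grads[f"{self.name}.W"] += states.T @ d_logits
        grads[f"{self.name}.b"] += d_logits.sum(axis=0)
        return d_logits @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    exp = np.exp(shifted)
    return exp / exp.sum(axis=-1, keepdims=True)


def softmax_xent_grad(logits: np.ndarray, target: int | np.ndarray
                      ) -> tuple[float, np.ndarray]:
    """Cross-entropy loss and d(loss)/d(logits) for integer targets."""
    probs = softmax(logits)
    if logits.ndim == 1:
        loss = -float(np.log(probs[target] + 1e-12))
        d = probs.copy()
        d[target] -= 1.0
        return loss, d
    rows = np.arange(logits.shape[0])
    loss = -float(np.log(probs[rows, target] + 1e-12).sum())
    d = probs.copy()
    d[rows, target] -= 1.0
    return loss, d


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))
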