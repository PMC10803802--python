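"""Backbone-agnostic DRG classification.

The classifier contract follows the causal-LM convention: a backbone maps a
token sequence to one embedding per token, a linear head is applied to the
*last* token's embedding, and the resulting raw logits feed either

* a single-label objective — categorical cross-entropy over all C DRG codes; or
* a two-label objective — one joint logit vector of size B+5 whose first B
  dimensions score the base DRG and last 5 dimensions score the CC/MCC label,
  trained with loss  CE_base + lambda * CE_cc  (lambda = 1/2 by default).

At inference the two-label head takes independent argmaxes over its two slices
and the catalog mapping rule converts the (base, CC/MCC) pair into a final
DRG code.

Large pretrained backbones plug in behind the :class:`Backbone` protocol; the
module ships two deterministic numpy reference backbones for desk-scale work:
a linear bag-of-tokens scorer (whose running-sum "embedding" makes the last
token embedding equal the whole-sequence sum) and a tiny causal self-attention
encoder exercising true last-token semantics and the low-rank adapter
contract  W0 + (alpha/r) * B A  with frozen W0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Protocol, Sequence

import numpy as np

from .catalog import CcMccLabel, DrgCatalog, DrgCode, LabelSpace, infer_drg
from .corpus import HashingTokenizer, TokenSequence


# ---------------------------------------------------------------------------
# Numerics
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax; rows sum to 1."""
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, target: int) -> float:
    """-log softmax(logits)[target], computed via the log-sum-exp trick."""
    logits = np.asarray(logits, dtype=float)
    if not 0 <= target < logits.shape[-1]:
        raise IndexError(f"target {target} out of range for {logits.shape[-1]} classes")
    m = np.max(logits)
    lse = m + np.log(np.sum(np.exp(logits - m)))
    return float(lse - logits[target])


def single_label_loss(logits: np.ndarray, target: int) -> float:
    """Categorical cross-entropy over the full DRG label space."""
    return cross_entropy(logits, target)


def two_label_loss(
    logits: np.ndarray,
    base_target: int,
    cc_target: int,
    n_base: int,
    lam: float = 0.5,
) -> float:
    """CE over the first ``n_base`` dims plus ``lam`` times CE over the last 5."""
    logits = np.asarray(logits, dtype=float)
    if logits.shape[-1] != n_base + len(CcMccLabel):
        raise ValueError("joint logit vector has wrong dimension")
    return cross_entropy(logits[:n_base], base_target) + lam * cross_entropy(
        logits[n_base:], cc_target
    )


# ---------------------------------------------------------------------------
# Backbone contract and reference backbones
# ---------------------------------------------------------------------------


class Backbone(Protocol):
    """What a classification backbone must provide.

    ``embed`` returns one width-d embedding per token; the head is a linear
    map applied (by :func:`logits_last_token`) to the final position only.
    Implementations must be deterministic given fixed parameters and input.
    """

    tokenizer: HashingTokenizer

    def embed(self, ids: Sequence[int]) -> np.ndarray: ...  # (T, d)

    @property
    def head_weight(self) -> np.ndarray: ...  # (d, n_labels)

    @property
    def head_bias(self) -> np.ndarray: ...  # (n_labels,)


def logits_last_token(backbone: Backbone, tokens: TokenSequence | Sequence[int]) -> np.ndarray:
    """Apply the head to the final token position's embedding only."""
    ids = tokens.ids if isinstance(tokens, TokenSequence) else tuple(tokens)
    if len(ids) == 0:
        raise ValueError("cannot score an empty token sequence")
    emb = backbone.embed(ids)
    return emb[-1] @ backbone.head_weight + backbone.head_bias


class LinearBagBackbone:
    """Linear bag-of-tokens scorer.

    Each token's "embedding" at position i is the running sum of one-hot token
    vectors up to i (width d = vocabulary size), so the last-token embedding
    is the token-count vector of the whole sequence and the model is a
    multinomial logistic regression over token counts — convex, fast, and a
    faithful instance of the last-token-head contract.
    """

    def __init__(
        self,
        n_labels: int,
        vocab_size: int = 2**15,
        seed: int = 0,
        init_scale: float = 0.0,
    ) -> None:
        # Zero head init is the natural start for a convex model; a nonzero
        # init_scale gives the seeded random head some tests rely on.
        rng = np.random.default_rng(seed)
        self.tokenizer = HashingTokenizer(vocab_size)
        self.vocab_size = vocab_size
        self.n_labels = n_labels
        self.params: dict[str, np.ndarray] = {
            "head_W": rng.normal(0.0, init_scale, size=(vocab_size, n_labels))
            if init_scale
            else np.zeros((vocab_size, n_labels)),
            "head_b": np.zeros(n_labels),
        }

    @property
    def head_weight(self) -> np.ndarray:
        return self.params["head_W"]

    @property
    def head_bias(self) -> np.ndarray:
        return self.params["head_b"]

    def embed(self, ids: Sequence[int]) -> np.ndarray:
        onehots = np.zeros((len(ids), self.vocab_size))
        for i, t in enumerate(ids):
            onehots[i, t] = 1.0
        return np.cumsum(onehots, axis=0)

    # -- training interface --------------------------------------------------

    def counts(self, ids: Sequence[int]) -> np.ndarray:
        return np.bincount(np.asarray(ids), minlength=self.vocab_size).astype(float)

    def forward(self, ids: Sequence[int]) -> tuple[np.ndarray, dict]:
        x = self.counts(ids)
        logits = x @ self.params["head_W"] + self.params["head_b"]
        return logits, {"x": x}

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        return {
            "head_W": np.outer(cache["x"], dlogits),
            "head_b": dlogits,
        }

    @property
    def trainable(self) -> dict[str, np.ndarray]:
        return self.params


class TinyAttentionBackbone:
    """A 1-layer causal self-attention encoder (width <= 64) for reference use.

    Forward pass: token + positional embeddings, a single masked softmax
    attention block with a residual connection, then the linear head on the
    last position.  It exists to exercise genuine last-token semantics and the
    low-rank adapter contract on real attention weights; gradient training is
    provided by the linear reference backbone instead.
    """

    ATTENTION_WEIGHTS = ("Wq", "Wk", "Wv", "Wo")

    def __init__(
        self,
        n_labels: int,
        vocab_size: int = 512,
        d: int = 32,
        max_len: int = 64,
        seed: int = 0,
    ) -> None:
        if d > 64:
            raise ValueError("reference encoder width capped at 64")
        rng = np.random.default_rng(seed)
        self.tokenizer = HashingTokenizer(vocab_size)
        self.d = d
        self.max_len = max_len
        self.n_labels = n_labels
        s = 1.0 / np.sqrt(d)
        self.params: dict[str, np.ndarray] = {
            "E": rng.normal(0, s, size=(vocab_size, d)),
            "P": rng.normal(0, s, size=(max_len, d)),
            "Wq": rng.normal(0, s, size=(d, d)),
            "Wk": rng.normal(0, s, size=(d, d)),
            "Wv": rng.normal(0, s, size=(d, d)),
            "Wo": rng.normal(0, s, size=(d, d)),
            "head_W": rng.normal(0, s, size=(d, n_labels)),
            "head_b": np.zeros(n_labels),
        }
        # name -> (B, A, scale); populated by apply_adapters
        self.lora: dict[str, tuple[np.ndarray, np.ndarray, float]] = {}

    @property
    def head_weight(self) -> np.ndarray:
        return self.params["head_W"]

    @property
    def head_bias(self) -> np.ndarray:
        return self.params["head_b"]

    def effective_weight(self, name: str) -> np.ndarray:
        w = self.params[name]
        if name in self.lora:
            B, A, scale = self.lora[name]
            return w + scale * (B @ A)
        return w

    def embed(self, ids: Sequence[int]) -> np.ndarray:
        ids = np.asarray(ids)
        if len(ids) > self.max_len:
            raise ValueError(f"sequence longer than max_len={self.max_len}")
        X = self.params["E"][ids] + self.params["P"][: len(ids)]
        Q = X @ self.effective_weight("Wq")
        K = X @ self.effective_weight("Wk")
        V = X @ self.effective_weight("Wv")
        scores = Q @ K.T / np.sqrt(self.d)
        mask = np.tril(np.ones((len(ids), len(ids)), dtype=bool))
        scores = np.where(mask, scores, -np.inf)
        attn = softmax(scores, axis=-1)
        return X + (attn @ V) @ self.effective_weight("Wo")


# ---------------------------------------------------------------------------
# Low-rank adapters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdapterSpec:
    """Low-rank adapter configuration: W0 + (alpha/r) * B A with frozen W0."""

    r: int = 8
    alpha: float = 16.0
    dropout: float = 0.05  # training-time regularizer; inert at inference

    @property
    def scale(self) -> float:
        return self.alpha / self.r


def apply_adapters(
    backbone: TinyAttentionBackbone, spec: AdapterSpec, seed: int = 0
) -> TinyAttentionBackbone:
    """Attach rank-r adapters to every attention weight of the encoder.

    B is zero-initialized and A Gaussian, so the adapted model's forward pass
    equals the base model's exactly at initialization; base weights stay
    frozen and only (B, A) are trainable.
    """
    d = backbone.d
    if spec.r > d:
        raise ValueError(f"adapter rank {spec.r} exceeds weight dimension {d}")
    rng = np.random.default_rng(seed)
    adapted = TinyAttentionBackbone(
        backbone.n_labels,
        vocab_size=backbone.params["E"].shape[0],
        d=d,
        max_len=backbone.max_len,
    )
    adapted.params = backbone.params  # shared, frozen base weights
    adapted.tokenizer = backbone.tokenizer
    adapted.lora = {
        name: (
            np.zeros((d, spec.r)),
            rng.normal(0, 0.02, size=(spec.r, d)),
            spec.scale,
        )
        for name in TinyAttentionBackbone.ATTENTION_WEIGHTS
    }
    return adapted


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Prediction:
    """Ranked label indices with their softmax probabilities."""

    indices: tuple[int, ...]
    probabilities: tuple[float, ...]


def rank_logits(logits: np.ndarray, k: int | None = None) -> Prediction:
    """Rank all labels by descending logit; ties broken by ascending index.

    Probabilities are softmax over the *full* label space, then restricted to
    the top-k entries of the ranking.
    """
    logits = np.asarray(logits, dtype=float)
    n = logits.shape[-1]
    k = n if k is None else min(k, n)
    order = np.lexsort((np.arange(n), -logits))
    probs = softmax(logits)
    top = order[:k]
    return Prediction(tuple(int(i) for i in top), tuple(float(probs[i]) for i in top))


def predict_single(logits: np.ndarray, k: int = 10) -> Prediction:
    """Top-k DRG prediction from a full-label logit vector."""
    return rank_logits(logits, k)


def predict_two(
    logits: np.ndarray, catalog: DrgCatalog, space: LabelSpace
) -> tuple[int, CcMccLabel, DrgCode]:
    """Dual argmax over the joint (base | CC/MCC) logit vector, then the
    catalog mapping rule.  np.argmax ties resolve to the lowest index."""
    logits = np.asarray(logits, dtype=float)
    n_base = space.n_base
    base_idx = int(np.argmax(logits[:n_base]))
    cc = CcMccLabel(int(np.argmax(logits[n_base : n_base + space.n_cc])))
    final = infer_drg(base_idx, cc, catalog, space)
    return base_idx, cc, final


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Optimization defaults for fine-tuning.

    The learning rate, weight decay, epoch count and batch size are the
    standard sequence-classification fine-tuning recipe; ``lam`` weights the
    CC/MCC term of the two-label loss.  The default rate suits large
    pretrained backbones — the convex linear reference backbone trains with a
    much larger rate, passed explicitly.
    """

    learning_rate: float = 2e-5
    weight_decay: float = 0.01
    epochs: int = 3
    batch_size: int = 4
    lam: float = 0.5
    max_tokens: int = 512
    seed: int = 0


class AdamW:
    """Adam with decoupled weight decay over a dict of parameter arrays."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float,
        weight_decay: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            p = self.params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)


def _loss_and_grad_single(logits: np.ndarray, target: int) -> tuple[float, np.ndarray]:
    p = softmax(logits)
    loss = cross_entropy(logits, target)
    d = p.copy()
    d[target] -= 1.0
    return loss, d


def _loss_and_grad_two(
    logits: np.ndarray, base_t: int, cc_t: int, n_base: int, lam: float
) -> tuple[float, np.ndarray]:
    loss = two_label_loss(logits, base_t, cc_t, n_base, lam)
    d = np.empty_like(logits)
    pb = softmax(logits[:n_base])
    pc = softmax(logits[n_base:])
    pb[base_t] -= 1.0
    pc[cc_t] -= 1.0
    d[:n_base] = pb
    d[n_base:] = lam * pc
    return loss, d


@dataclass
class FittedModel:
    backbone: LinearBagBackbone
    mode: str  # "single" | "two"
    config: TrainConfig
    loss_trace: list[float] = field(default_factory=list)  # per-epoch mean loss

    def score(self, texts: Iterable[str]) -> np.ndarray:
        """Logit matrix (n_records, n_labels) for a batch of section texts."""
        rows = []
        for text in texts:
            ids = self.backbone.tokenizer.tokenize(text)[: self.config.max_tokens]
            logits, _ = self.backbone.forward(ids)
            rows.append(logits)
        return np.asarray(rows)


def train(
    backbone: LinearBagBackbone,
    texts: Sequence[str],
    targets: Sequence[int] | Sequence[tuple[int, int]],
    config: TrainConfig,
    mode: str = "single",
    n_base: int | None = None,
) -> FittedModel:
    """Mini-batch AdamW training of a reference backbone.

    ``targets`` are DRG indices in single-label mode, or (base_index,
    cc_index) pairs in two-label mode (``n_base`` required).  Deterministic
    given ``config.seed``; records the per-epoch mean loss.
    """
    if len(texts) == 0:
        raise ValueError("empty training set")
    if mode not in {"single", "two"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "two" and n_base is None:
        raise ValueError("two-label mode requires n_base")

    token_ids = [
        backbone.tokenizer.tokenize(t)[: config.max_tokens] for t in texts
    ]
    rng = np.random.default_rng(config.seed)
    opt = AdamW(backbone.trainable, config.learning_rate, config.weight_decay)
    n = len(texts)
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            grads: dict[str, np.ndarray] | None = None
            for i in batch:
                logits, cache = backbone.forward(token_ids[i])
                if mode == "single":
                    loss, dlogits = _loss_and_grad_single(logits, int(targets[i]))
                else:
                    bt, ct = targets[i]
                    loss, dlogits = _loss_and_grad_two(
                        logits, int(bt), int(ct), int(n_base), config.lam
                    )
                epoch_loss += loss
                g = backbone.backward(cache, dlogits)
                if grads is None:
                    grads = g
                else:
                    for k in grads:
                        grads[k] += g[k]
            assert grads is not None
            for k in grads:
                grads[k] /= len(batch)
            opt.step(grads)
        trace.append(epoch_loss / n)
    return FittedModel(backbone, mode, config, trace)
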