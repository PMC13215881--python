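"""Scaling family of masked-LM transformer encoders and desk-scale pretraining.

The family is parameterized by depth alone: hidden size is 64 per layer
(width-to-depth aspect ratio 64), one attention head per 64 hidden
dimensions, and a feed-forward size of 4x the hidden size.  The published
members — 8, 10, 12, 16 and 18 layers — come out at 38, 65, 104, 228 and
316 million parameters under the tied-embedding counting convention
implemented here (vocabulary 20,275, input size 4,096).

Pretraining uses the masked-gene objective: 15% of the gene tokens of each
rank value encoding are selected; of those, 80% are replaced by the mask
token, 10% by a random gene and 10% left unchanged, and the model must
recover the original gene id at each selected position.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import IGNORE_LABEL, AdamW, cosine_warmup_lr
from .tokenize import TokenVocabulary, TokenizedDataset

__all__ = [
    "EncoderSpec",
    "MaskingConfig",
    "TrainConfig",
    "EncoderModel",
    "build_spec",
    "count_parameters",
    "apply_masking",
    "pad_batch",
    "iterate_batches",
    "pretrain",
    "evaluate_loss",
    "estimate_flops",
    "IGNORE_LABEL",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture hyperparameters; derived fields follow the family rules."""

    layers: int
    vocab_size: int
    max_positions: int
    dropout: float = 0.02
    attn_dropout: float = 0.02
    init_std: float = 0.02
    ln_eps: float = 1e-12

    @property
    def hidden_size(self) -> int:
        return 64 * self.layers

    @property
    def heads(self) -> int:
        return self.hidden_size // 64

    @property
    def ff_size(self) -> int:
        return 4 * self.hidden_size

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EncoderSpec":
        return cls(**json.loads(text))


def build_spec(layers: int, vocab_size: int = 20_275, max_positions: int = 4_096) -> EncoderSpec:
    if layers < 1:
        raise ValueError("layers must be >= 1")
    return EncoderSpec(layers=layers, vocab_size=vocab_size, max_positions=max_positions)


def count_parameters(spec: EncoderSpec) -> int:
    """Exact trainable-parameter count of the tied-embedding masked-LM encoder."""
    return _nn.count_parameters_from_shapes(spec)


@dataclass(frozen=True)
class MaskingConfig:
    """Masked-gene selection: rate and BERT-style replacement scheme."""

    mask_prob: float = 0.15
    mask_fraction: float = 0.8
    random_fraction: float = 0.1
    keep_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.mask_prob < 1.0:
            raise ValueError("mask_prob must lie strictly between 0 and 1")
        if abs(self.mask_fraction + self.random_fraction + self.keep_fraction - 1.0) > 1e-9:
            raise ValueError("replacement fractions must sum to 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (published defaults, desk-scale batch/epochs)."""

    max_lr: float = 2e-4
    warmup_ratio: float = 0.007
    weight_decay: float = 0.044
    batch_size: int = 32
    epochs: float = 1.0
    seed: int = 0


def pad_batch(tokens: list[np.ndarray], pad_id: int = TokenVocabulary.PAD):
    """Stack variable-length sequences into (B, T_max) ids + lengths."""
    lengths = np.array([len(t) for t in tokens], dtype=np.int64)
    T = int(lengths.max())
    ids = np.full((len(tokens), T), pad_id, dtype=np.int64)
    for i, t in enumerate(tokens):
        ids[i, : len(t)] = t
    return ids, lengths


def apply_masking(
    ids: np.ndarray,
    lengths: np.ndarray,
    config: MaskingConfig,
    rng: np.random.Generator,
    n_special: int = TokenVocabulary.N_SPECIAL,
    vocab_size: int | None = None,
):
    """Select gene tokens i.i.d. with probability ``mask_prob`` and corrupt them.

    CLS/EOS/pad are never selected.  Returns (masked_ids, labels) where
    labels hold the original token at selected positions and IGNORE_LABEL
    elsewhere.  A short cell may receive zero masks in a given draw.
    """
    config.validate()
    B, T = ids.shape
    is_gene = ids >= n_special
    sel = (rng.random((B, T)) < config.mask_prob) & is_gene
    labels = np.where(sel, ids, IGNORE_LABEL)
    masked = ids.copy()
    u = rng.random((B, T))
    to_mask = sel & (u < config.mask_fraction)
    to_rand = sel & (u >= config.mask_fraction) & (u < config.mask_fraction + config.random_fraction)
    masked[to_mask] = TokenVocabulary.MASK
    if vocab_size is None:
        vocab_size = int(ids.max()) + 1
    n_rand = int(to_rand.sum())
    if n_rand:
        masked[to_rand] = rng.integers(n_special, vocab_size, size=n_rand)
    return masked, labels


class EncoderModel:
    """A (possibly quantized, possibly adapter-equipped) numpy encoder.

    ``forward_hidden`` returns all layer outputs; layer tags ``"last"`` and
    ``"second_to_last"`` index into that list.  With dropout disabled (the
    default at inference) forward passes are deterministic.
    """

    def __init__(self, spec: EncoderSpec, params: dict | None = None, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.params = params if params is not None else _nn.init_params(spec, rng)
        self.adapters: dict = {}
        self.qweights: dict = {}  # weight name -> QuantizedTensor-like (has .dequantize())
        self.frozen_base: bool = False

    # -- inference ---------------------------------------------------------
    def forward_hidden(self, ids, lengths, train=False, rng=None):
        hs, cache = _nn.forward(
            self.params, self.spec, ids, lengths, train=train, rng=rng,
            adapters=self.adapters or None, qweights=self.qweights or None,
        )
        self._cache = cache
        return hs

    def hidden_at(self, hidden_states, layer_tag: str):
        if layer_tag == "last":
            return hidden_states[-1]
        if layer_tag == "second_to_last":
            if self.spec.layers < 2:
                raise ValueError("second-to-last layer undefined for a 1-layer encoder")
            return hidden_states[-2]
        raise ValueError(f"unknown layer tag {layer_tag!r}")

    def logits(self, ids, lengths):
        hs = self.forward_hidden(ids, lengths)
        out, _ = _nn.mlm_logits(self.params, self.spec, hs[-1])
        return out

    # -- training ----------------------------------------------------------
    def loss_and_grads(self, ids, lengths, labels, train=True, rng=None):
        hs, cache = _nn.forward(
            self.params, self.spec, ids, lengths, train=train, rng=rng,
            adapters=self.adapters or None, qweights=self.qweights or None,
        )
        loss, aux = _nn.mlm_loss(self.params, self.spec, hs, labels)
        grads, lora_grads = _nn.mlm_backward(
            self.params, self.spec, cache, aux,
            adapters=self.adapters or None, qweights=self.qweights or None,
        )
        return loss, grads, lora_grads

    def eval_loss(self, ids, lengths, labels):
        hs, _ = _nn.forward(
            self.params, self.spec, ids, lengths, train=False,
            adapters=self.adapters or None, qweights=self.qweights or None,
        )
        loss, aux = _nn.mlm_loss(self.params, self.spec, hs, labels)
        return loss, aux["n"]

    # -- bookkeeping -------------------------------------------------------
    def num_parameters(self) -> int:
        return count_parameters(self.spec)

    def weight_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name]).tobytes())
        return h.hexdigest()[:16]

    def copy(self) -> "EncoderModel":
        m = EncoderModel(self.spec, params={k: v.copy() for k, v in self.params.items()})
        m.adapters = {
            k: {kk: (vv.copy() if isinstance(vv, np.ndarray) else vv) for kk, vv in v.items()}
            for k, v in self.adapters.items()
        }
        m.qweights = dict(self.qweights)
        m.frozen_base = self.frozen_base
        return m

    # -- persistence -------------------------------------------------------
    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "spec.json").write_text(self.spec.to_json())
        np.savez(outdir / "weights.npz", **self.params)

    @classmethod
    def load(cls, indir: str | Path) -> "EncoderModel":
        indir = Path(indir)
        spec = EncoderSpec.from_json((indir / "spec.json").read_text())
        with np.load(indir / "weights.npz") as z:
            params = {k: z[k] for k in z.files}
        return cls(spec, params=params)


def iterate_batches(dataset: TokenizedDataset, batch_size: int, rng=None, shuffle=False):
    idx = np.arange(len(dataset))
    if shuffle:
        rng.shuffle(idx)
    for start in range(0, len(idx), batch_size):
        chunk = idx[start : start + batch_size]
        yield chunk, pad_batch([dataset.tokens[i] for i in chunk])


def pretrain(
    dataset: TokenizedDataset,
    spec: EncoderSpec,
    masking: MaskingConfig | None = None,
    train_config: TrainConfig | None = None,
    model: EncoderModel | None = None,
) -> tuple[EncoderModel, list[dict]]:
    """Masked-gene pretraining; returns the model and a per-step loss trace."""
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    masking = masking or MaskingConfig()
    cfg = train_config or TrainConfig()
    model = model or EncoderModel(spec, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    mask_rng = np.random.default_rng(masking.seed)
    drop_rng = np.random.default_rng(cfg.seed + 2)

    steps_per_epoch = int(np.ceil(len(dataset) / cfg.batch_size))
    total_steps = max(1, int(round(cfg.epochs * steps_per_epoch)))
    opt = AdamW(model.params, lr=cfg.max_lr, weight_decay=cfg.weight_decay)
    trace: list[dict] = []
    step = 0
    while step < total_steps:
        for _, (ids, lengths) in iterate_batches(dataset, cfg.batch_size, rng, shuffle=True):
            if step >= total_steps:
                break
            masked, labels = apply_masking(
                ids, lengths, masking, mask_rng, vocab_size=spec.vocab_size
            )
            if (labels != IGNORE_LABEL).sum() == 0:
                continue
            loss, grads, _ = model.loss_and_grads(masked, lengths, labels, train=True, rng=drop_rng)
            lr = cosine_warmup_lr(step, total_steps, cfg.max_lr, cfg.warmup_ratio)
            opt.step(model.params, grads, lr=lr)
            trace.append({"step": step, "loss": float(loss), "lr": float(lr)})
            step += 1
    return model, trace


def evaluate_loss(
    model: EncoderModel,
    dataset: TokenizedDataset,
    masking: MaskingConfig | None = None,
    seed: int = 0,
    batch_size: int = 32,
) -> float:
    """Mean masked cross-entropy per token over a held-out set (fixed mask seed)."""
    if len(dataset) == 0:
        raise ValueError("empty held-out dataset")
    masking = masking or MaskingConfig()
    mask_rng = np.random.default_rng(seed)
    tot, n_tot = 0.0, 0
    for _, (ids, lengths) in iterate_batches(dataset, batch_size):
        masked, labels = apply_masking(
            ids, lengths, masking, mask_rng, vocab_size=model.spec.vocab_size
        )
        if (labels != IGNORE_LABEL).sum() == 0:
            continue
        loss, n = model.eval_loss(masked, lengths, labels)
        tot += loss * n
        n_tot += n
    if n_tot == 0:
        raise ValueError("no masked positions drawn over the held-out set")
    return tot / n_tot


def estimate_flops(spec: EncoderSpec, tokens_processed: int | float) -> float:
    """Training-compute estimate under the 6 * N * T convention."""
    if tokens_processed < 0:
        raise ValueError("tokens_processed must be nonnegative")
    return 6.0 * count_parameters(spec) * float(tokens_processed)
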