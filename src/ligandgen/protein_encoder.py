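"""Protein sequence embedding via masked-token Transformer pretraining.

A BERT-style encoder over the 22-letter amino-acid alphabet: random
positions are replaced by ``[MASK]`` and predicted from context with a
cross-entropy loss on the masked positions only. After pretraining, a
sequence is embedded by mean-pooling the final hidden states over non-pad
positions and projecting to a fixed feature dimension.

The full-scale configuration is 12 layers x 512 hidden x 8 heads with a
756-dimensional output feature; tests and the bundled pipeline use a small
configuration of the same shape. The output feature dimension is an
explicit learned projection of the pooled hidden state — hidden size and
feature size are independent knobs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, Embedding, Linear, Module, Tensor,
                 TransformerEncoderLayer, cross_entropy_logits, no_grad)
from .nn.tensor import backward as backward_
from .vocab import ProteinVocabulary


@dataclass
class ProteinEncoderConfig:
    n_layers: int = 12
    hidden_size: int = 512
    n_heads: int = 8
    feature_dim: int = 756
    ff_mult: int = 4
    mask_rate: float = 0.15
    max_len: int = 512
    lr: float = 1e-3
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.hidden_size % self.n_heads:
            raise ValueError("hidden_size must be divisible by n_heads")
        if not 0.0 < self.mask_rate < 1.0:
            raise ValueError("mask_rate must be in (0, 1)")

    @classmethod
    def test_scale(cls, **kw) -> "ProteinEncoderConfig":
        defaults = dict(n_layers=2, hidden_size=64, n_heads=2,
                        feature_dim=32, max_len=128)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class ProteinEmbedding:
    vector: np.ndarray
    source_id: str = ""


def mask_tokens(token_ids: list[int], mask_rate: float, seed: int,
                vocab: ProteinVocabulary | None = None) -> tuple[list[int], list[int]]:
    """Replace ceil(rate * n_maskable) residue positions with [MASK].

    Control tokens are never masked; at least one position is always masked
    so the loss is defined.
    """
    vocab = vocab or ProteinVocabulary()
    if not token_ids:
        raise ValueError("empty token list")
    n_control = len(vocab.control)
    maskable = [i for i, t in enumerate(token_ids) if t >= n_control]
    if not maskable:
        raise ValueError("no maskable positions")
    k = max(1, math.ceil(mask_rate * len(maskable)))
    k = min(k, len(maskable))
    rng = np.random.default_rng(seed)
    positions = sorted(rng.choice(len(maskable), size=k, replace=False))
    positions = [maskable[i] for i in positions]
    masked = list(token_ids)
    for p in positions:
        masked[p] = vocab.mask_id
    return masked, positions


class ProteinEncoder(Module):
    """Transformer encoder + masked-LM head + pooled feature projection."""

    def __init__(self, config: ProteinEncoderConfig,
                 vocab: ProteinVocabulary | None = None):
        self.config = config
        self.vocab = vocab or ProteinVocabulary()
        rng = np.random.default_rng(config.seed)
        D = config.hidden_size
        self.tok_emb = Embedding(len(self.vocab), D, rng)
        self.pos_emb = Embedding(config.max_len, D, rng)
        self.layers = [TransformerEncoderLayer(D, config.n_heads,
                                               config.ff_mult * D, rng)
                       for _ in range(config.n_layers)]
        # head over predictable classes: 22 residues + unknown; small init
        # keeps the untrained model near-uniform (loss ~ ln 23) while still
        # passing gradient to the encoder from the first step
        self.lm_head = Linear(D, self.vocab.n_predictable, rng, gain=0.1)
        self.feature_proj = Linear(D, config.feature_dim, rng)

    # class index of a predictable vocab id (unk and residues follow pad, mask)
    def _to_class(self, ids: np.ndarray) -> np.ndarray:
        return ids - self.vocab.unk_id

    def hidden_states(self, ids: np.ndarray, pad_mask: np.ndarray) -> Tensor:
        """ids, pad_mask: (B, T) -> final hidden states (B, T, D)."""
        T = ids.shape[1]
        if T > self.config.max_len:
            raise ValueError("sequence longer than max_len after batching")
        x = self.tok_emb(ids) + self.pos_emb(np.arange(T)[None, :].repeat(ids.shape[0], 0))
        for layer in self.layers:
            x = layer(x, pad_mask)
        return x

    def masked_lm_loss(self, batch_ids: np.ndarray, pad_mask: np.ndarray,
                       targets: np.ndarray, loss_mask: np.ndarray) -> Tensor:
        """Cross-entropy over masked positions only."""
        h = self.hidden_states(batch_ids, pad_mask)
        logits = self.lm_head(h)
        return cross_entropy_logits(logits, self._to_class(targets), loss_mask)

    def embed(self, sequence: str, source_id: str = "") -> ProteinEmbedding:
        """Mean-pool final hidden states over real positions, then project."""
        ids = self.vocab.encode(sequence)
        if len(ids) > self.config.max_len:
            import warnings
            warnings.warn(f"sequence truncated to max_len={self.config.max_len}")
            ids = ids[:self.config.max_len]
        arr = np.asarray(ids)[None, :]
        pad = np.ones_like(arr)
        with no_grad():
            h = self.hidden_states(arr, pad)
            pooled = h.mean(axis=1)
            feat = self.feature_proj(pooled)
        return ProteinEmbedding(vector=feat.data[0].copy(), source_id=source_id)


def _pad_batch(seqs_ids: list[list[int]], pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    T = max(len(s) for s in seqs_ids)
    ids = np.full((len(seqs_ids), T), pad_id, dtype=np.int64)
    mask = np.zeros((len(seqs_ids), T), dtype=np.int64)
    for i, s in enumerate(seqs_ids):
        ids[i, :len(s)] = s
        mask[i, :len(s)] = 1
    return ids, mask


def pretrain_masked_lm(corpus: list[str], config: ProteinEncoderConfig,
                       steps: int) -> tuple[ProteinEncoder, list[float]]:
    """Masked-token pretraining; returns the encoder and the loss trace."""
    if not corpus:
        raise ValueError("empty pretraining corpus")
    model = ProteinEncoder(config)
    vocab = model.vocab
    encoded = [vocab.encode(s[:config.max_len]) for s in corpus]
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    trace: list[float] = []
    params = model.parameters()
    for step in range(steps):
        take = rng.choice(len(encoded), size=min(config.batch_size, len(encoded)),
                          replace=False)
        batch = [encoded[i] for i in take]
        masked_batch = []
        positions = []
        for j, seq in enumerate(batch):
            m, pos = mask_tokens(seq, config.mask_rate,
                                 int(rng.integers(0, 2 ** 31)), vocab)
            masked_batch.append(m)
            positions.append(pos)
        ids, pad = _pad_batch(masked_batch, vocab.pad_id)
        tgt, _ = _pad_batch(batch, vocab.pad_id)
        loss_mask = np.zeros_like(ids)
        for j, pos in enumerate(positions):
            loss_mask[j, pos] = 1
        tgt = np.where(loss_mask > 0, tgt, len(vocab.control))  # dummy residue id at unmasked
        loss = model.masked_lm_loss(ids, pad, tgt, loss_mask)
        backward_(loss, params)
        opt.step()
        opt.zero_grad()
        trace.append(loss.item())
    return model, trace


def masked_accuracy(model: ProteinEncoder, sequences: list[str], seed: int = 0) -> float:
    """Fraction of masked positions recovered exactly on held-out sequences."""
    vocab = model.vocab
    rng = np.random.default_rng(seed)
    n_ok = n_tot = 0
    for s in sequences:
        ids = vocab.encode(s[:model.config.max_len])
        m, pos = mask_tokens(ids, model.config.mask_rate,
                             int(rng.integers(0, 2 ** 31)), vocab)
        arr = np.asarray(m)[None, :]
        pad = np.ones_like(arr)
        with no_grad():
            logits = model.lm_head(model.hidden_states(arr, pad))
        pred_class = logits.data[0].argmax(axis=-1)
        for p in pos:
            n_tot += 1
            if pred_class[p] == ids[p] - 2:
                n_ok += 1
    return n_ok / max(n_tot, 1)
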