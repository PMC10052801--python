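"""SMILES sequence autoencoder: BiLSTM encoder, LSTM decoder.

One-hot token sequences pass through a 2-layer bidirectional LSTM encoder;
the final-step outputs of both directions of the top layer are concatenated
and projected to the latent vector. A 4-layer LSTM decoder, initialised
from the latent through learned per-layer state maps, is trained with
teacher forcing under a softmax cross-entropy. At generation time the
decoder runs autoregressively (greedy or temperature-controlled
multinomial) and its parameters can be frozen so that adversarial training
upstream cannot disturb the latent-to-SMILES map.

The full-scale model uses 512 LSTM units per encoder layer (half per
direction) and a 512-dimensional latent; the test-scale model keeps the
same topology at small width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Adam, Linear, LSTMLayer, Module, Tensor, concat, stack,
                 cross_entropy_logits, no_grad, DTYPE)
from .nn.tensor import backward as backward_
from .vocab import SmilesVocabulary


@dataclass
class AutoencoderConfig:
    latent_dim: int = 512
    encoder_units: int = 512      # per layer, split across the two directions
    decoder_units: int = 512
    encoder_layers: int = 2       # bidirectional
    decoder_layers: int = 4
    max_smiles_len: int = 128     # includes start/end positions
    decode_mode: str = "multinomial"
    temperature: float = 1.0
    lr: float = 3e-3
    batch_size: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.encoder_units % 2:
            raise ValueError("encoder_units must be even (two directions)")
        if self.decode_mode not in ("greedy", "multinomial"):
            raise ValueError("decode_mode must be 'greedy' or 'multinomial'")

    @classmethod
    def test_scale(cls, **kw) -> "AutoencoderConfig":
        defaults = dict(latent_dim=48, encoder_units=128, decoder_units=64,
                        max_smiles_len=16)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class MolecularLatent:
    vector: np.ndarray


def encode_one_hot(tokens: list[str], vocab: SmilesVocabulary,
                   max_len: int) -> np.ndarray:
    """(max_len, V) one-hot with start/end framing and pad tail."""
    if len(tokens) > max_len - 2:
        raise ValueError(f"token sequence too long for max_len={max_len}")
    V = len(vocab)
    ids = [vocab.sos_id] + [vocab.token_id(t) for t in tokens] + [vocab.eos_id]
    ids += [vocab.pad_id] * (max_len - len(ids))
    mat = np.zeros((max_len, V), dtype=DTYPE)
    mat[np.arange(max_len), ids] = 1.0
    return mat


class SmilesAutoencoder(Module):
    def __init__(self, config: AutoencoderConfig,
                 vocab: SmilesVocabulary | None = None):
        self.config = config
        self.vocab = vocab or SmilesVocabulary()
        rng = np.random.default_rng(config.seed)
        V = len(self.vocab)
        H = config.encoder_units // 2
        D = config.decoder_units
        L = config.latent_dim
        self.enc_fwd = [LSTMLayer(V if i == 0 else 2 * H, H, rng)
                        for i in range(config.encoder_layers)]
        self.enc_bwd = [LSTMLayer(V if i == 0 else 2 * H, H, rng)
                        for i in range(config.encoder_layers)]
        self.to_latent = Linear(2 * H, L, rng)
        self.dec_layers = [LSTMLayer(V if i == 0 else D, D, rng)
                           for i in range(config.decoder_layers)]
        # latent initialises hidden and cell state of every decoder layer
        self.latent_to_state = [
            (Linear(L, D, rng), Linear(L, D, rng))
            for _ in range(config.decoder_layers)]
        self.out_head = Linear(D, V, rng)

    # -- encoding ----------------------------------------------------------

    def _encode_batch(self, onehots: np.ndarray) -> Tensor:
        """(B, T, V) one-hot array -> (B, latent) Tensor (graph-recorded)."""
        B, T, V = onehots.shape
        xs = [Tensor(np.ascontiguousarray(onehots[:, t, :])) for t in range(T)]
        h = xs
        for lf, lb in zip(self.enc_fwd, self.enc_bwd):
            f = lf(h)
            b = lb(h, reverse=True)
            h = [concat([ft, bt], axis=-1) for ft, bt in zip(f, b)]
        # final step of each direction: last for forward, first for backward
        fwd_last = f[-1]
        bwd_first = b[0]
        return self.to_latent(concat([fwd_last, bwd_first], axis=-1))

    def encode(self, smiles: str) -> MolecularLatent:
        tokens = self.vocab.tokenize(smiles)
        oh = encode_one_hot(tokens, self.vocab, self.config.max_smiles_len)
        with no_grad():
            z = self._encode_batch(oh[None])
        return MolecularLatent(vector=z.data[0].copy())

    def encode_many(self, smiles: list[str]) -> np.ndarray:
        ohs = np.stack([
            encode_one_hot(self.vocab.tokenize(s), self.vocab,
                           self.config.max_smiles_len) for s in smiles])
        with no_grad():
            z = self._encode_batch(ohs)
        return z.data.copy()

    # -- decoding ----------------------------------------------------------

    def _init_states(self, latent: Tensor) -> list[tuple[Tensor, Tensor]]:
        # linear maps: squashing the initial states slows convergence badly
        return [(wh(latent), wc(latent)) for wh, wc in self.latent_to_state]

    def _decoder_logits(self, latent: Tensor, onehots: np.ndarray) -> Tensor:
        """Teacher-forced logits: input rows 0..T-2 predict rows 1..T-1."""
        B, T, V = onehots.shape
        states = self._init_states(latent)
        xs = [Tensor(np.ascontiguousarray(onehots[:, t, :])) for t in range(T - 1)]
        seq = xs
        for li, layer in enumerate(self.dec_layers):
            h0, c0 = states[li]
            seq = layer(seq, h0=h0, c0=c0)
        out = stack(seq, axis=1)  # (B, T-1, D)
        D = self.config.decoder_units
        logits = (out.reshape((B * (T - 1), D)) @ self.out_head.weight
                  + self.out_head.bias)
        return logits.reshape((B, T - 1, len(self.vocab)))

    def teacher_forced_loss(self, onehots: np.ndarray) -> Tensor:
        """Mean cross-entropy over real (non-pad) target positions."""
        latent = self._encode_batch(onehots)
        logits = self._decoder_logits(latent, onehots)
        targets = onehots.argmax(axis=-1)[:, 1:]
        mask = (targets != self.vocab.pad_id).astype(np.int64)
        return cross_entropy_logits(logits, targets, mask)

    def decode(self, latent: MolecularLatent | np.ndarray,
               mode: str | None = None, temperature: float | None = None,
               seed: int = 0) -> str:
        return self.decode_many(
            np.asarray(latent.vector if isinstance(latent, MolecularLatent)
                       else latent)[None], mode, temperature, seed)[0]

    def decode_many(self, latents: np.ndarray, mode: str | None = None,
                    temperature: float | None = None, seed: int = 0) -> list[str]:
        """Autoregressive generation from latent vectors.

        Greedy mode is deterministic; multinomial samples from the softmax
        at ``temperature`` (temperature -> 0 recovers greedy).
        """
        mode = mode or self.config.decode_mode
        temperature = self.config.temperature if temperature is None else temperature
        if temperature < 1e-6:
            mode = "greedy"
        rng = np.random.default_rng(seed)
        B = latents.shape[0]
        V = len(self.vocab)
        with no_grad():
            states = self._init_states(Tensor(latents.astype(DTYPE)))
            states = [(h, c) for h, c in states]
            tok = np.full(B, self.vocab.sos_id)
            done = np.zeros(B, dtype=bool)
            seqs: list[list[int]] = [[] for _ in range(B)]
            for _ in range(self.config.max_smiles_len - 1):
                x = np.zeros((B, V), dtype=DTYPE)
                x[np.arange(B), tok] = 1.0
                inp = Tensor(x)
                new_states = []
                for li, layer in enumerate(self.dec_layers):
                    h, c = states[li]
                    h, c = layer.step(layer.project_input(inp), h, c)
                    new_states.append((h, c))
                    inp = h
                states = new_states
                logits = self.out_head(inp).data.copy()
                # never emit control tokens other than end-of-sequence
                for bad in (self.vocab.pad_id, self.vocab.sos_id,
                            self.vocab.token_id("<unk>")):
                    logits[:, bad] = -np.inf
                if mode == "greedy":
                    tok = logits.argmax(axis=-1)
                else:
                    scaled = logits / temperature
                    scaled -= scaled.max(axis=-1, keepdims=True)
                    p = np.exp(scaled)
                    p /= p.sum(axis=-1, keepdims=True)
                    cum = p.cumsum(axis=-1)
                    u = rng.random((B, 1))
                    tok = (cum < u).sum(axis=-1).clip(max=V - 1)
                for b in range(B):
                    if not done[b]:
                        if tok[b] == self.vocab.eos_id:
                            done[b] = True
                        elif tok[b] not in (self.vocab.pad_id, self.vocab.sos_id):
                            seqs[b].append(int(tok[b]))
                if done.all():
                    break
        toks = self.vocab.all_tokens
        return ["".join(toks[i] for i in s) for s in seqs]

    # -- freezing ----------------------------------------------------------

    def decoder_modules(self) -> list[Module]:
        return [*self.dec_layers, *[m for pair in self.latent_to_state for m in pair],
                self.out_head]

    def decoder_parameters(self) -> list[Tensor]:
        out = []
        for m in self.decoder_modules():
            out.extend(m.parameters(trainable_only=False))
        return out

    def freeze_decoder(self) -> "FrozenDecoder":
        for p in self.decoder_parameters():
            p.requires_grad = False
        return FrozenDecoder(self)


class FrozenDecoder:
    """Immutable handle on a trained decoder; checksummed for audit."""

    def __init__(self, ae: SmilesAutoencoder):
        self._ae = ae
        self.checksum = self.current_checksum()

    def current_checksum(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for p in self._ae.decoder_parameters():
            h.update(np.ascontiguousarray(p.data, dtype=np.float64).tobytes())
        return h.hexdigest()

    @property
    def latent_dim(self) -> int:
        return self._ae.config.latent_dim

    def decode_many(self, latents: np.ndarray, mode: str | None = None,
                    temperature: float | None = None, seed: int = 0) -> list[str]:
        return self._ae.decode_many(latents, mode, temperature, seed)


def reconstruction_rate(ae: SmilesAutoencoder, smiles: list[str]) -> float:
    """Fraction of strings reproduced exactly by greedy decode(encode(s))."""
    if not smiles:
        return float("nan")
    lat = ae.encode_many(smiles)
    recon = ae.decode_many(lat, mode="greedy")
    return float(np.mean([r == s for r, s in zip(recon, smiles)]))


def train_autoencoder(smiles: list[str], config: AutoencoderConfig,
                      epochs: int, holdout_fraction: float = 0.1,
                      target_holdout_recon: float | None = None,
                      eval_every: int = 10,
                      ) -> tuple[SmilesAutoencoder, dict]:
    """Teacher-forced training with a held-out exact-reconstruction report.

    Stops early once the held-out reconstruction rate reaches
    ``target_holdout_recon`` (checked every ``eval_every`` epochs).
    """
    if len(smiles) < 2:
        raise ValueError("need at least two training strings")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(smiles))
    n_hold = max(1, int(round(holdout_fraction * len(smiles))))
    hold = [smiles[i] for i in order[:n_hold]]
    train = [smiles[i] for i in order[n_hold:]]

    ae = SmilesAutoencoder(config)
    onehots = np.stack([
        encode_one_hot(ae.vocab.tokenize(s), ae.vocab, config.max_smiles_len)
        for s in train])
    params = ae.parameters()
    opt = Adam(params, lr=config.lr)
    trace: list[float] = []
    history: list[tuple[int, float]] = []
    B = config.batch_size
    # step-down schedule: fine lr late in training is what turns low
    # token loss into exact-string reconstruction
    milestones = {int(epochs * 0.5): config.lr / 3,
                  int(epochs * 0.83): config.lr / 7.5}
    for epoch in range(epochs):
        if epoch in milestones:
            opt.lr = milestones[epoch]
        perm = rng.permutation(len(train))
        for i in range(0, len(train), B):
            batch = onehots[perm[i:i + B]]
            loss = ae.teacher_forced_loss(batch)
            backward_(loss, params)
            opt.step()
            opt.zero_grad()
            trace.append(loss.item())
        if target_holdout_recon is not None and (epoch + 1) % eval_every == 0:
            r = reconstruction_rate(ae, hold)
            history.append((epoch + 1, r))
            if r >= target_holdout_recon:
                break
    report = {
        "n_train": len(train), "n_holdout": len(hold),
        "holdout_reconstruction": reconstruction_rate(ae, hold),
        "train_reconstruction": reconstruction_rate(ae, train[:200]),
        "loss_trace": trace, "recon_history": history,
        "epochs_run": epoch + 1,
    }
    return ae, report
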