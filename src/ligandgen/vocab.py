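"""Token vocabularies for SMILES strings and protein sequences.

The chemistry vocabulary is the 29-token SMILES set used to screen the
training corpus: aromatic/aliphatic C, N, S, O, plus F, Cl, Br, the [nH]
group, ring-closure digits 1-9, bond symbols, charges and brackets. The
protein vocabulary is the 22-letter amino-acid alphabet (including the
ambiguity code B and selenocysteine U); the unknown residue ``X`` is
deliberately absent — sequences containing it are filtered out upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SMILES_TOKENS: tuple[str, ...] = (
    "C", "c", "N", "n", "S", "s", "O", "o", "F", "Cl", "[nH]", "Br",
    "1", "2", "3", "4", "5", "6", "7", "8", "9",
    "#", "=", "+", "-", "(", ")", "[", "]",
)

AMINO_ACIDS: tuple[str, ...] = (
    "K", "I", "F", "W", "Y", "H", "A", "T", "B", "G", "V",
    "E", "P", "L", "N", "Q", "S", "U", "D", "R", "C", "M",
)

PAD, SOS, EOS, UNK, MASK = "<pad>", "<sos>", "<eos>", "<unk>", "[MASK]"


class TokenizationError(ValueError):
    """Raised when a string cannot be tokenized under a vocabulary."""


@dataclass(frozen=True)
class SmilesVocabulary:
    """Greedy longest-match tokenizer over the 29-token SMILES alphabet."""

    tokens: tuple[str, ...] = SMILES_TOKENS
    control: tuple[str, ...] = (PAD, SOS, EOS, UNK)
    _by_length: tuple[str, ...] = field(init=False, repr=False)

    def __post_init__(self):
        # multi-character tokens must win over their single-char prefixes
        object.__setattr__(
            self, "_by_length",
            tuple(sorted(self.tokens, key=len, reverse=True)))

    # ids: control tokens first, chemistry tokens after
    @property
    def all_tokens(self) -> tuple[str, ...]:
        return self.control + self.tokens

    def __len__(self) -> int:
        return len(self.all_tokens)

    def token_id(self, token: str) -> int:
        return self.all_tokens.index(token)

    @property
    def pad_id(self) -> int:
        return self.control.index(PAD)

    @property
    def sos_id(self) -> int:
        return self.control.index(SOS)

    @property
    def eos_id(self) -> int:
        return self.control.index(EOS)

    def tokenize(self, smiles: str) -> list[str]:
        """Greedy longest-match, left to right. Raises on unknown symbols."""
        out: list[str] = []
        i = 0
        n = len(smiles)
        while i < n:
            for tok in self._by_length:
                if smiles.startswith(tok, i):
                    out.append(tok)
                    i += len(tok)
                    break
            else:
                raise TokenizationError(
                    f"no vocabulary token matches {smiles[i:]!r} in {smiles!r}")
        return out

    def try_tokenize(self, smiles: str) -> list[str] | None:
        try:
            return self.tokenize(smiles)
        except TokenizationError:
            return None

    def encode(self, smiles: str) -> list[int]:
        ids = [self.token_id(t) for t in self.tokenize(smiles)]
        return ids

    def decode(self, ids: list[int]) -> str:
        toks = self.all_tokens
        out = []
        for i in ids:
            t = toks[i]
            if t == EOS:
                break
            if t in (PAD, SOS, UNK):
                continue
            out.append(t)
        return "".join(out)


def dp_tokenize(smiles: str, tokens: tuple[str, ...] = SMILES_TOKENS) -> list[list[str]]:
    """All tokenizations by dynamic programming (reference oracle for tests).

    Returns every way to segment ``smiles`` into vocabulary tokens; empty
    list if none exists.
    """
    n = len(smiles)
    table: list[list[list[str]]] = [[] for _ in range(n + 1)]
    table[0] = [[]]
    for i in range(n):
        if not table[i]:
            continue
        for tok in tokens:
            if smiles.startswith(tok, i):
                for seg in table[i]:
                    table[i + len(tok)].append(seg + [tok])
    return table[n]


@dataclass(frozen=True)
class ProteinVocabulary:
    """The 22-letter amino-acid alphabet plus control tokens."""

    tokens: tuple[str, ...] = AMINO_ACIDS
    control: tuple[str, ...] = (PAD, MASK, UNK)

    @property
    def all_tokens(self) -> tuple[str, ...]:
        return self.control + self.tokens

    def __len__(self) -> int:
        return len(self.all_tokens)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def mask_id(self) -> int:
        return 1

    @property
    def unk_id(self) -> int:
        return 2

    @property
    def n_predictable(self) -> int:
        """Classes the masked-token head predicts: residues + unknown."""
        return len(self.tokens) + 1

    def accepts(self, sequence: str) -> bool:
        """True iff every character is a vocabulary residue (no X, nonempty)."""
        return len(sequence) > 0 and all(ch in self.tokens for ch in sequence)

    def encode(self, sequence: str) -> list[int]:
        if not self.accepts(sequence):
            raise TokenizationError(f"sequence contains non-vocabulary residues: {sequence!r}")
        base = len(self.control)
        return [base + self.tokens.index(ch) for ch in sequence]
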