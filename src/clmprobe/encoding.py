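"""Tokenization and numerical encoding of compounds and protein sequences.

SMILES strings are tokenized with the published chemistry-NLP regular
expression (bracket atoms, two-letter halogens, ring-closure digits etc. as
single tokens); protein sequences are tokenized per residue over the 20-letter
IUPAC alphabet. Both channels share a vocabulary object with ``[start]``,
``[end]`` and ``[pad]`` special tokens at fixed indices.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

SMILES_TOKEN_PATTERN = (
    r"(\[[^\]]+]|Br?|Cl?|N|O|S|P|F|I|b|c|n|o|s|p|\(|\)|\.|=|#|-|\+|\\|\/|:"
    r"|~|@|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)
_SMILES_RE = re.compile(SMILES_TOKEN_PATTERN)

IUPAC_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_AMINO_ACIDS = "BZXUO"

PAD, START, END = "[pad]", "[start]", "[end]"


class TokenizationError(ValueError):
    """A string contains characters not consumed by the token pattern."""

    def __init__(self, text: str, position: int):
        self.position = position
        super().__init__(
            f"cannot tokenize {text!r}: unconsumed character "
            f"{text[position]!r} at position {position}"
        )


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; lossless (``''.join`` round-trips).

    Raises :class:`TokenizationError` at the first character the pattern
    does not consume.
    """
    tokens: list[str] = []
    pos = 0
    for match in _SMILES_RE.finditer(smiles):
        if match.start() != pos:
            raise TokenizationError(smiles, pos)
        tokens.append(match.group())
        pos = match.end()
    if pos != len(smiles):
        raise TokenizationError(smiles, pos)
    return tokens


def tokenize_protein(residues: str, permissive: bool = False) -> list[str]:
    """Per-residue tokens over the IUPAC alphabet.

    With ``permissive=True`` the extended codes B, Z, X, U, O are mapped to
    the ambiguity code X instead of raising.
    """
    tokens = []
    for i, ch in enumerate(residues):
        if ch in IUPAC_AMINO_ACIDS:
            tokens.append(ch)
        elif permissive and ch in EXTENDED_AMINO_ACIDS:
            tokens.append("X")
        else:
            raise TokenizationError(residues, i)
    return tokens


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token set with [pad]/[start]/[end] specials at indices 0/1/2.

    The vocabulary is corpus-derived and frozen: strings containing tokens
    outside the vocabulary raise a ``KeyError`` rather than mapping to an
    unknown token.
    """

    tokens: tuple[str, ...]
    max_length: int
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.tokens[:3] != (PAD, START, END):
            raise ValueError("vocabulary must start with [pad], [start], [end]")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        object.__setattr__(
            self, "index", {t: i for i, t in enumerate(self.tokens)}
        )

    @property
    def size(self) -> int:
        return len(self.tokens)

    pad_id, start_id, end_id = 0, 1, 2

    @classmethod
    def from_token_lists(
        cls, token_lists: Iterable[Sequence[str]], extra_length: int = 0
    ) -> "TokenVocabulary":
        """Build a vocabulary from tokenized corpus items.

        ``max_length`` is the longest item plus 2 (room for [start]/[end])
        plus ``extra_length`` slack.
        """
        seen: dict[str, None] = {}
        longest = 0
        for toks in token_lists:
            longest = max(longest, len(toks))
            for t in toks:
                seen.setdefault(t, None)
        if longest == 0:
            raise ValueError("empty corpus")
        content = tuple(sorted(seen))
        return cls((PAD, START, END) + content, longest + 2 + extra_length)

    def encode(self, tokens: Sequence[str], pad_to: int | None = None) -> np.ndarray:
        """[start] + tokens + [end], padded with [pad] to ``pad_to``."""
        length = self.max_length if pad_to is None else pad_to
        if len(tokens) + 2 > length:
            raise ValueError(
                f"item of {len(tokens)} tokens exceeds max length {length}"
            )
        ids = np.full(length, self.pad_id, dtype=np.int64)
        ids[0] = self.start_id
        for i, t in enumerate(tokens):
            ids[i + 1] = self.index[t]
        ids[len(tokens) + 1] = self.end_id
        return ids

    def decode(self, ids: Sequence[int]) -> list[str]:
        """Content tokens between [start] and the first [end]/[pad]."""
        out = []
        for i in ids:
            if i == self.start_id:
                continue
            if i in (self.end_id, self.pad_id):
                break
            out.append(self.tokens[i])
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"tokens": list(self.tokens), "max_length": self.max_length})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TokenVocabulary":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["tokens"]), d["max_length"])


def encode_protein(
    residues: str,
    vocab: TokenVocabulary,
    permissive: bool = False,
    pad_to: int | None = None,
) -> np.ndarray:
    """Residue string to padded index array (invertible up to padding)."""
    return vocab.encode(tokenize_protein(residues, permissive=permissive), pad_to)


def encode_smiles(
    smiles: str, vocab: TokenVocabulary, pad_to: int | None = None
) -> np.ndarray:
    return vocab.encode(tokenize_smiles(smiles), pad_to)


def positional_encoding(positions: int | np.ndarray, dimension: int) -> np.ndarray:
    """Sinusoidal positional encoding at geometrically spaced frequencies.

    Entry ``2i`` is ``sin(pos / 10000**(2i/d))`` and entry ``2i+1`` the
    matching cosine, as in the original transformer. ``positions`` may be a
    scalar (returns a vector) or an array of positions (returns a matrix).
    """
    if dimension % 2 != 0:
        raise ValueError("model dimension must be even")
    pos = np.atleast_1d(np.asarray(positions, dtype=np.float64))
    i = np.arange(0, dimension, 2, dtype=np.float64)
    angles = pos[:, None] / np.power(10000.0, i / dimension)[None, :]
    enc = np.empty((pos.shape[0], dimension))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles)
    if np.isscalar(positions) or np.asarray(positions).ndim == 0:
        return enc[0]
    return enc
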