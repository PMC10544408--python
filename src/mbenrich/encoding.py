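"""Binary feature encodings of sequences.

Three flat schemes feed the linear models:

* ``is`` — independent sites: one one-hot block of size ``|A|`` per position.
* ``neighbor`` — IS features plus one ``|A|^2`` one-hot block per adjacent
  position pair.
* ``pairwise`` — IS features plus one ``|A|^2`` block for every unordered
  position pair ``i < j`` in lexicographic order.

Neural models consume the IS features, either flat (fully-connected) or as
an ``L x |A|`` one-hot matrix (convolutional; supports variable ``L``).

Feature layout is fixed and position-major: all IS blocks in sequence order,
then pair blocks in their documented order; within a pair block the active
index is ``a_i * |A| + a_j``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .alphabets import resolve_alphabet, seq_to_indices, seqs_to_index_matrix

SCHEMES = ("is", "neighbor", "pairwise", "onehot-matrix")


@dataclass
class SequenceEncoding:
    """A single encoded sequence (mostly useful for inspection/debugging)."""

    vector: np.ndarray
    scheme: str
    alphabet_size: int
    length: int


def feature_dim(scheme: str, length: int, alphabet_size: int) -> int:
    """Dimensionality of a flat encoding scheme for the given length."""
    L, A = length, alphabet_size
    if scheme == "is":
        return L * A
    if scheme == "neighbor":
        return L * A + (L - 1) * A * A
    if scheme == "pairwise":
        return L * A + (L * (L - 1) // 2) * A * A
    raise ValueError(f"unknown flat scheme {scheme!r}")


def encode_batch(seqs, scheme: str, alphabet: str = "protein") -> np.ndarray:
    """Encode equal-length sequences into a (n, D) float32 matrix."""
    letters = resolve_alphabet(alphabet)
    A = len(letters)
    idx = seqs_to_index_matrix(list(seqs), alphabet)
    n, L = idx.shape
    is_dim = L * A
    if scheme == "is":
        out = np.zeros((n, is_dim), dtype=np.float32)
        flat = np.arange(L) * A + idx
        out[np.arange(n)[:, None], flat] = 1.0
        return out
    if scheme in ("neighbor", "pairwise"):
        pairs = (
            [(t, t + 1) for t in range(L - 1)]
            if scheme == "neighbor"
            else list(combinations(range(L), 2))
        )
        D = is_dim + len(pairs) * A * A
        out = np.zeros((n, D), dtype=np.float32)
        flat = np.arange(L) * A + idx
        out[np.arange(n)[:, None], flat] = 1.0
        for b, (i, j) in enumerate(pairs):
            col = is_dim + b * A * A + idx[:, i] * A + idx[:, j]
            out[np.arange(n), col] = 1.0
        return out
    raise ValueError(f"unknown flat scheme {scheme!r}")


def encode_is(seq: str, alphabet: str = "protein") -> SequenceEncoding:
    """Independent-site one-hot vector of length ``L * |A|``."""
    letters = resolve_alphabet(alphabet)
    return SequenceEncoding(
        vector=encode_batch([seq], "is", alphabet)[0],
        scheme="is",
        alphabet_size=len(letters),
        length=len(seq),
    )


def encode_neighbor(seq: str, alphabet: str = "protein") -> SequenceEncoding:
    """IS features plus adjacent-pair interaction one-hots."""
    letters = resolve_alphabet(alphabet)
    return SequenceEncoding(
        vector=encode_batch([seq], "neighbor", alphabet)[0],
        scheme="neighbor",
        alphabet_size=len(letters),
        length=len(seq),
    )


def encode_pairwise(seq: str, alphabet: str = "protein") -> SequenceEncoding:
    """IS features plus all-pair interaction one-hots."""
    letters = resolve_alphabet(alphabet)
    return SequenceEncoding(
        vector=encode_batch([seq], "pairwise", alphabet)[0],
        scheme="pairwise",
        alphabet_size=len(letters),
        length=len(seq),
    )


def encode_onehot_matrix(seq: str, alphabet: str = "protein") -> np.ndarray:
    """One-hot matrix (L, |A|): the IS vector reshaped; used by CNNs."""
    letters = resolve_alphabet(alphabet)
    A = len(letters)
    idx = seq_to_indices(seq, alphabet)
    out = np.zeros((len(seq), A), dtype=np.float32)
    out[np.arange(len(seq)), idx] = 1.0
    return out
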