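"""Sequence alphabets and translation helpers.

Modeling is done at the amino-acid level; the simulator constructs libraries
in nucleotide space and translates codon-aligned sequences before encoding.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

#: Canonical residue orders. Feature layouts depend on these orders, so they
#: are fixed: position-major blocks, residues in the order given here.
DNA = "ACGT"
PROTEIN = "ACDEFGHIKLMNPQRSTVWY"

ALPHABETS = {"dna": DNA, "protein": PROTEIN}

# Fixed back-translation table: one codon per amino acid (alphabetically
# first among its codons) so amino-acid-level constructions can be emitted
# as nucleotide reads deterministically.
_BACK_TRANSLATION = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC",
    "G": "GGA", "H": "CAC", "I": "ATA", "K": "AAA", "L": "CTA",
    "M": "ATG", "N": "AAC", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "AGC", "T": "ACA", "V": "GTA", "W": "TGG", "Y": "TAC",
}


def resolve_alphabet(alphabet: str) -> str:
    """Return the residue string for an alphabet name or literal residues."""
    if alphabet in ALPHABETS:
        return ALPHABETS[alphabet]
    return alphabet


def seq_to_indices(seq: str, alphabet: str) -> np.ndarray:
    """Map a sequence to integer residue indices, validating every residue."""
    letters = resolve_alphabet(alphabet)
    lut = np.full(128, -1, dtype=np.int64)
    for i, a in enumerate(letters):
        lut[ord(a)] = i
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    idx = lut[arr]
    if (idx < 0).any():
        pos = int(np.argmax(idx < 0))
        raise ValueError(
            f"residue {seq[pos]!r} at position {pos} is not in alphabet {letters!r}"
        )
    return idx


def seqs_to_index_matrix(seqs, alphabet: str) -> np.ndarray:
    """Index matrix (n, L) for equal-length sequences."""
    if not seqs:
        raise ValueError("empty sequence list")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have equal length")
    letters = resolve_alphabet(alphabet)
    lut = np.full(128, -1, dtype=np.int64)
    for i, a in enumerate(letters):
        lut[ord(a)] = i
    buf = np.frombuffer("".join(s.upper() for s in seqs).encode("ascii"), dtype=np.uint8)
    idx = lut[buf].reshape(len(seqs), L)
    if (idx < 0).any():
        r, c = np.argwhere(idx < 0)[0]
        raise ValueError(
            f"residue {seqs[r][c]!r} at position {c} of sequence {r} "
            f"is not in alphabet {letters!r}"
        )
    return idx


def translate(nt_seq: str) -> str:
    """Translate a codon-aligned nucleotide sequence to amino acids."""
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"length {len(nt_seq)} is not codon-aligned")
    return str(Seq(nt_seq).translate())


def back_translate(aa_seq: str) -> str:
    """Deterministically emit one nucleotide sequence encoding ``aa_seq``."""
    try:
        return "".join(_BACK_TRANSLATION[a] for a in aa_seq)
    except KeyError as e:
        raise ValueError(f"cannot back-translate residue {e.args[0]!r}") from None
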