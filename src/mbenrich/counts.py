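"""Count-based log-enrichment (cLE) estimation.

Reads labeled by condition are aggregated into a table of unique sequences
with per-condition counts. For a pair of conditions (denominator A,
numerator B) the cLE estimate for sequence ``i`` is the log-ratio of read
frequencies::

    log e_i = log[(n_i^B / N^B) / (n_i^A / N^A)]

with an optional pseudocount added to every raw count to stabilize the
estimate for sequences observed in only one condition. The asymptotic
variance of ``log e_i`` is::

    sigma_i^2 = (1/n_i^B)(1 - n_i^B/N^B) + (1/n_i^A)(1 - n_i^A/N^A)

and the weighted-regression weight is ``w_i = 1 / (2 sigma_i^2)``.

When a pseudocount ``c`` is applied, totals are recomputed from the adjusted
counts (``N + c * M'`` for ``M'`` unique sequences) so frequencies remain
normalized, and — by default — the variance formula is evaluated on the same
adjusted counts so that zero-count sequences receive finite weights.

All logarithms are natural.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alphabets import resolve_alphabet


class ZeroCountError(ValueError):
    """Raised when cLE would divide by zero (pseudocount 0, zero count)."""


class ZeroVarianceError(ValueError):
    """Raised when a sequence owns an entire library (sigma^2 = 0)."""


@dataclass
class ReadDataset:
    """Raw reads with categorical condition labels.

    ``records`` is a sequence of ``(read_sequence, condition_label)`` pairs;
    labels are integers in ``{0..k}`` with 0 conventionally the reference
    (pre-selection) condition.
    """

    records: list
    alphabet: str = "dna"
    k: int | None = None

    def __post_init__(self):
        if not self.records:
            raise ValueError("empty read dataset")
        letters = set(resolve_alphabet(self.alphabet))
        max_label = 0
        for seq, label in self.records:
            if not seq:
                raise ValueError("empty read sequence")
            if label < 0:
                raise ValueError(f"negative condition label {label}")
            bad = set(seq.upper()) - letters
            if bad:
                raise ValueError(
                    f"read contains residues {sorted(bad)} outside the "
                    f"{self.alphabet} alphabet (mixed alphabets?)"
                )
            max_label = max(max_label, label)
        if self.k is None:
            self.k = max_label
        elif max_label > self.k:
            raise ValueError(f"label {max_label} exceeds declared k={self.k}")

    @property
    def n_conditions(self) -> int:
        return self.k + 1


@dataclass
class CountTable:
    """Unique sequences with per-condition read counts.

    ``counts`` has shape ``(M', k+1)``; ``totals[j]`` is the column sum
    ``N^j``. Row order is deterministic (first appearance in the source).
    """

    sequences: list
    counts: np.ndarray
    alphabet: str = "dna"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.sequences):
            raise ValueError("counts must be (n_sequences, n_conditions)")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("every sequence needs a positive count somewhere")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("sequences must be unique")

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_conditions(self) -> int:
        return self.counts.shape[1]

    def __len__(self) -> int:
        return len(self.sequences)

    def expand_reads(self) -> ReadDataset:
        """Inverse of :func:`aggregate_reads`: reproduce the read multiset."""
        records = []
        for i, seq in enumerate(self.sequences):
            for j in range(self.n_conditions):
                records.extend([(seq, j)] * int(self.counts[i, j]))
        return ReadDataset(records, alphabet=self.alphabet, k=self.n_conditions - 1)


@dataclass
class EnrichmentEstimate:
    """Per-sequence cLE estimates with asymptotic variances and weights."""

    sequences: list
    log_e: np.ndarray
    sigma2: np.ndarray | None
    weight: np.ndarray | None
    pseudocount: float
    condition_pair: tuple  # (denominator j, numerator j')


def aggregate_reads(dataset: ReadDataset) -> CountTable:
    """Tally reads into a :class:`CountTable` in first-appearance order."""
    order: dict = {}
    rows: list = []
    k1 = dataset.n_conditions
    for seq, label in dataset.records:
        seq = seq.upper()
        i = order.get(seq)
        if i is None:
            i = len(order)
            order[seq] = i
            rows.append(np.zeros(k1, dtype=np.int64))
        rows[i][label] += 1
    return CountTable(list(order), np.vstack(rows), alphabet=dataset.alphabet)


def _adjusted(table: CountTable, denominator: int, numerator: int, pseudocount: float):
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    C = table.n_conditions
    for j in (denominator, numerator):
        if not 0 <= j < C:
            raise ValueError(f"condition {j} not in table (0..{C - 1})")
    if denominator == numerator:
        raise ValueError("numerator and denominator conditions must differ")
    nA = table.counts[:, denominator].astype(float)
    nB = table.counts[:, numerator].astype(float)
    if pseudocount == 0:
        for name, n in (("denominator", nA), ("numerator", nB)):
            if (n == 0).any():
                i = int(np.argmax(n == 0))
                raise ZeroCountError(
                    f"sequence {table.sequences[i]!r} has zero {name} count; "
                    "use a positive pseudocount"
                )
    nA += pseudocount
    nB += pseudocount
    return nA, nB, nA.sum(), nB.sum()


def compute_cle(
    table: CountTable,
    denominator: int = 0,
    numerator: int = 1,
    pseudocount: float = 1.0,
) -> EnrichmentEstimate:
    """cLE estimates ``log e_i`` for one condition pair (natural log)."""
    nA, nB, NA, NB = _adjusted(table, denominator, numerator, pseudocount)
    log_e = np.log(nB / NB) - np.log(nA / NA)
    return EnrichmentEstimate(
        sequences=table.sequences,
        log_e=log_e,
        sigma2=None,
        weight=None,
        pseudocount=pseudocount,
        condition_pair=(denominator, numerator),
    )


def compute_variance_weights(
    table: CountTable,
    denominator: int = 0,
    numerator: int = 1,
    pseudocount: float = 1.0,
    cap_weights: bool = False,
) -> EnrichmentEstimate:
    """Asymptotic variances ``sigma_i^2`` and weights ``w_i = 1/(2 sigma_i^2)``.

    Variances are evaluated on pseudocount-adjusted counts so zero-count
    sequences get finite weights. ``sigma2 == 0`` (a sequence owning an
    entire library) raises :class:`ZeroVarianceError` unless ``cap_weights``
    is set, in which case that sequence gets the largest finite weight in the
    table.
    """
    nA, nB, NA, NB = _adjusted(table, denominator, numerator, pseudocount)
    sigma2 = (1.0 / nB) * (1.0 - nB / NB) + (1.0 / nA) * (1.0 - nA / NA)
    est = compute_cle(table, denominator, numerator, pseudocount)
    with np.errstate(divide="ignore"):
        weight = 1.0 / (2.0 * sigma2)
    zero = sigma2 <= 0
    if zero.any():
        if not cap_weights:
            i = int(np.argmax(zero))
            raise ZeroVarianceError(
                f"sequence {table.sequences[i]!r} has zero asymptotic variance "
                "(single-sequence library); pass cap_weights=True to cap"
            )
        finite = weight[~zero]
        cap = finite.max() if finite.size else 1.0
        warnings.warn("capping infinite weights for zero-variance sequences")
        weight = np.where(zero, cap, weight)
    est.sigma2 = sigma2
    est.weight = weight
    return est
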