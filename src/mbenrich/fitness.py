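"""Simulated epistatic ground-truth fitness functions.

A fitness function over amino-acid sequences of length ``L_a`` is a linear
function of one-hot features of position subsets::

    F_T(x) = sum_{J in E_T} beta_J . phi(x[J])

where ``E_T`` contains every singleton site plus ``T`` randomly drawn
higher-order index sets. For each higher-order term, the order R is drawn
as round(N(3, 1/2)) — a bell-shaped distribution over epistasis orders
centered at 3 (variance 1/2) — clamped to [2, L_a], and R positions are
sampled without replacement. Coefficients are Gaussian with per-component
variance ``2^{-|J|}``, so higher-order terms contribute smaller effects.

Because phi is one-hot, each term selects exactly one coefficient per
sequence; evaluation is a table lookup per term. Dense coefficient arrays
are stored for orders <= 3; larger orders draw coefficients lazily from a
counter-based generator keyed by (term seed, subsequence index), which is
exactly reproducible and avoids materializing |A|^R-sized arrays.

The default number of epistatic terms scales linearly with length:
``T = 260 L_a / 13 = 20 L_a``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .alphabets import PROTEIN, resolve_alphabet, seqs_to_index_matrix

DENSE_MAX_ORDER = 3


def default_T(L_a: int) -> int:
    """Default epistasis hyper-parameter, ``T = 260 L_a / 13``."""
    if L_a < 1:
        raise ValueError(f"sequence length must be positive, got {L_a}")
    return 260 * L_a // 13


def sample_epistatic_terms(L_a: int, T: int, rng: np.random.Generator,
                           distinct: bool = False) -> list[tuple[int, ...]]:
    """All singleton sites plus ``T`` random higher-order index sets.

    Positions are 0-based and sorted within each term. By default the ``T``
    draws are with replacement across terms (duplicate index sets allowed;
    their coefficient vectors are drawn independently and effectively sum);
    ``distinct=True`` redraws until all higher-order terms are distinct.
    """
    if T < 0:
        raise ValueError("T must be non-negative")
    if T > 0 and L_a < 2:
        raise ValueError("higher-order terms need L_a >= 2")
    terms: list[tuple[int, ...]] = [(i,) for i in range(L_a)]
    seen: set[tuple[int, ...]] = set()
    while len(terms) < L_a + T:
        R = int(np.clip(np.rint(rng.normal(3.0, np.sqrt(0.5))), 2, L_a))
        J = tuple(sorted(rng.choice(L_a, size=R, replace=False).tolist()))
        if distinct:
            if J in seen:
                continue
            seen.add(J)
        terms.append(J)
    return terms


def sample_coefficients(terms, alphabet: str, rng: np.random.Generator):
    """Per-term coefficients, N(0, 2^-|J|) per one-hot component.

    Returns ``(dense, seeds)`` lists aligned with ``terms``: dense arrays of
    size ``|A|^|J|`` for small orders, or an integer stream seed for lazily
    materialized coefficients of large orders.
    """
    A = len(resolve_alphabet(alphabet))
    dense, seeds = [], []
    for J in terms:
        sd = 2.0 ** (-len(J) / 2.0)
        if len(J) <= DENSE_MAX_ORDER:
            dense.append(rng.normal(0.0, sd, size=A ** len(J)))
            seeds.append(None)
        else:
            dense.append(None)
            seeds.append(int(rng.integers(0, 2 ** 31 - 1)))
    return dense, seeds


@dataclass
class FitnessFunction:
    """An epistatic fitness landscape F_T over fixed-length sequences."""

    L_a: int
    terms: list
    coefficients: list
    term_seeds: list
    alphabet: str = "protein"
    seed: int | None = None
    T: int | None = None

    def __post_init__(self):
        for J in self.terms:
            if len(set(J)) != len(J):
                raise ValueError(f"repeated position in term {J}")
            if any(not 0 <= p < self.L_a for p in J):
                raise ValueError(f"term {J} outside sequence of length {self.L_a}")
        singles = {J[0] for J in self.terms if len(J) == 1}
        if singles != set(range(self.L_a)):
            raise ValueError("all singleton sites must be present")

    # -- evaluation -------------------------------------------------------
    def evaluate(self, seqs) -> np.ndarray:
        """Vectorized F_T over a list of sequences (or one sequence)."""
        single = isinstance(seqs, str)
        seq_list = [seqs] if single else list(seqs)
        for s in seq_list:
            if len(s) != self.L_a:
                raise ValueError(f"sequence length {len(s)} != L_a={self.L_a}")
        codes = seqs_to_index_matrix(seq_list, self.alphabet)
        A = len(resolve_alphabet(self.alphabet))
        out = np.zeros(len(seq_list))
        for J, coef, tseed in zip(self.terms, self.coefficients, self.term_seeds):
            idx = np.zeros(len(seq_list), dtype=np.int64)
            for p in J:
                idx = idx * A + codes[:, p]
            if coef is not None:
                out += np.asarray(coef)[idx]
            else:
                sd = 2.0 ** (-len(J) / 2.0)
                uniq, inv = np.unique(idx, return_inverse=True)
                vals = np.array([
                    np.random.default_rng([tseed, int(u)]).normal(0.0, sd)
                    for u in uniq])
                out += vals[inv]
        return out[0] if single else out

    __call__ = evaluate

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(dict(
            L_a=self.L_a, alphabet=self.alphabet, seed=self.seed, T=self.T,
            terms=[list(J) for J in self.terms],
            coefficients=[None if c is None else list(np.asarray(c))
                          for c in self.coefficients],
            term_seeds=self.term_seeds,
        ))

    @classmethod
    def from_json(cls, text: str) -> "FitnessFunction":
        d = json.loads(text)
        return cls(L_a=d["L_a"], alphabet=d["alphabet"], seed=d["seed"], T=d["T"],
                   terms=[tuple(J) for J in d["terms"]],
                   coefficients=[None if c is None else np.asarray(c)
                                 for c in d["coefficients"]],
                   term_seeds=d["term_seeds"])


def simulate_fitness(L_a: int, T: int | None = None, seed: int = 0,
                     alphabet: str = "protein",
                     distinct_terms: bool = False) -> FitnessFunction:
    """Draw a complete fitness function (terms + coefficients) from a seed."""
    if T is None:
        T = default_T(L_a)
    rng = np.random.default_rng(seed)
    terms = sample_epistatic_terms(L_a, T, rng, distinct=distinct_terms)
    dense, seeds = sample_coefficients(terms, alphabet, rng)
    return FitnessFunction(L_a=L_a, terms=terms, coefficients=dense,
                           term_seeds=seeds, alphabet=alphabet, seed=seed, T=T)
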