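"""Selection-experiment simulator: libraries, selection, sequencing reads.

Three library constructions are supported, mirroring common experimental
designs:

* **NNK insertion** — every codon drawn from the NNK degenerate codon
  (first two positions uniform over ACGT, third uniform over G/T; 32
  equiprobable codons), accumulated until a target number of unique
  sequences is reached. Draws whose translation contains a stop codon are
  rejected and redrawn (rejections are counted on the library).
* **Random mutagenesis** — each position of a reference mutated
  independently at a per-site rate (substitution to a uniformly random
  different residue), again accumulated to a target unique count.
  Mutations are applied at the amino-acid level on the translated
  reference and back-translated with a fixed codon table for read emission.
* **Recombination** — parents are cut into equally sized contiguous blocks
  (remainder distributed to the leading blocks) and chimeras concatenate
  one parent's segment per block, either exhaustively or sampled with
  multiplicities.

Selection and sequencing then proceed in four steps: (1) a pre-selection
distribution is drawn from Dirichlet(c_1..c_M'), modeling PCR-style
perturbation of the library proportions and providing replicates; (2) the
post-selection distribution rescales it by exp(F_T) and renormalizes, so
log(p_post/p_pre) - F_T is a constant across sequences; (3) read counts
are multinomial draws of the requested depths; (4) short-read mode clips
each read to a contiguous window (default 100 codons = 300 nt) at a
uniformly random codon-aligned start, and substitution errors may be added
to each position independently.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .alphabets import DNA, PROTEIN, back_translate, translate
from .counts import CountTable
from .fitness import FitnessFunction

_NNK_THIRD = "GT"


# --------------------------------------------------------------------------
# library constructions
# --------------------------------------------------------------------------

@dataclass
class Library:
    """Unique (nucleotide) library sequences with true sampling counts."""

    sequences: list
    counts: np.ndarray
    construction: str
    seed: int | None = None
    n_rejected: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 1).any():
            raise ValueError("library counts must be >= 1")
        if len(self.sequences) != len(self.counts):
            raise ValueError("sequences/counts length mismatch")
        lens = {len(s) for s in self.sequences}
        if len(lens) > 1:
            raise ValueError("library sequences must share one length")

    def __len__(self) -> int:
        return len(self.sequences)

    def translated(self) -> list:
        return [translate(s) for s in self.sequences]


def _accumulate_unique(draw_chunk, target_unique: int, max_draws: int = 10 ** 9):
    """Draw chunks of sequences until ``target_unique`` distinct ones exist.

    Returns (ordered unique sequences, counts) where each count is the
    number of times the sequence was drawn before (and including) the draw
    that completed the target.
    """
    counts: Counter = Counter()
    order: list = []
    drawn = 0
    while len(order) < target_unique:
        if drawn > max_draws:
            raise RuntimeError("unique-sequence target unreachable in max_draws")
        chunk = draw_chunk()
        drawn += len(chunk)
        for s in chunk:
            if s not in counts:
                order.append(s)
            counts[s] += 1
            if len(order) == target_unique:
                break
    return order, np.array([counts[s] for s in order], dtype=np.int64)


def nnk_library(n_codons: int, target_unique: int, rng: np.random.Generator,
                chunk: int = 20000, reject_stops: bool = True) -> Library:
    """NNK-diversified insertion library of ``n_codons`` codons."""
    if n_codons < 1 or target_unique < 1:
        raise ValueError("n_codons and target_unique must be positive")
    if target_unique > 32 ** n_codons:
        raise ValueError(
            f"target_unique={target_unique} exceeds the {32 ** n_codons} "
            "NNK-reachable sequences")
    rejected = 0

    def draw():
        nonlocal rejected
        n12 = rng.integers(0, 4, size=(chunk, n_codons, 2))
        n3 = rng.integers(0, 2, size=(chunk, n_codons, 1))
        codes = np.concatenate([n12, np.where(n3 == 0, 2, 3)], axis=2)
        flat = codes.reshape(chunk, -1)
        seqs = ["".join(DNA[c] for c in row) for row in flat]
        if reject_stops:
            kept = [s for s in seqs if "*" not in translate(s)]
            rejected += len(seqs) - len(kept)
            return kept
        return seqs

    seqs, counts = _accumulate_unique(draw, target_unique)
    return Library(seqs, counts, "nnk", n_rejected=rejected)


def mutagenesis_library(reference: str, per_site_rate: float, target_unique: int,
                        rng: np.random.Generator, chunk: int = 20000,
                        level: str = "protein") -> Library:
    """Random mutagenesis of a reference at a per-site substitution rate.

    ``reference`` is an amino-acid sequence when ``level='protein'`` (the
    default; fitness acts on amino acids) or a codon-aligned nucleotide
    sequence when ``level='dna'``.
    """
    if not 0 < per_site_rate < 1:
        raise ValueError("per_site_rate must be in (0, 1)")
    letters = PROTEIN if level == "protein" else DNA
    A = len(letters)
    lut = {a: i for i, a in enumerate(letters)}
    ref_codes = np.array([lut[a] for a in reference.upper()], dtype=np.int64)
    L = len(ref_codes)

    def draw():
        mask = rng.random((chunk, L)) < per_site_rate
        # uniform over the A-1 residues different from the reference
        offs = rng.integers(1, A, size=(chunk, L))
        muts = (ref_codes[None, :] + offs) % A
        codes = np.where(mask, muts, ref_codes[None, :])
        return ["".join(letters[c] for c in row) for row in codes]

    seqs, counts = _accumulate_unique(draw, target_unique)
    if level == "protein":
        seqs = [back_translate(s) for s in seqs]
    return Library(seqs, counts, "mutagenesis")


def recombination_library(parents, n_blocks: int,
                          rng: np.random.Generator | None = None,
                          target_unique: int | None = None,
                          codon_aligned: bool = True) -> Library:
    """Chimeric library recombining aligned parents over contiguous blocks.

    Blocks are equally sized contiguous segments (remainder distributed to
    the leading blocks). With ``codon_aligned`` (default) crossovers snap
    to codon boundaries so chimeric junctions never create novel codons —
    stop-free parents then guarantee stop-free chimeras. With
    ``target_unique`` unset the library is the exhaustive set of distinct
    chimeras (counts reflect how many parent-block choices map to each);
    otherwise chimeras are sampled uniformly over block choices until
    ``target_unique`` distinct sequences are seen.
    """
    parents = list(parents)
    if len(parents) < 2:
        raise ValueError("need at least two parents")
    L = len(parents[0])
    if any(len(p) != L for p in parents):
        raise ValueError("parents must have equal lengths")
    unit = 3 if codon_aligned else 1
    if codon_aligned and L % 3 != 0:
        raise ValueError("codon-aligned recombination needs length % 3 == 0")
    n_units = L // unit
    if not 2 <= n_blocks <= n_units:
        raise ValueError("n_blocks must be in [2, number of crossover units]")
    base, rem = divmod(n_units, n_blocks)
    sizes = [base + 1 if b < rem else base for b in range(n_blocks)]
    bounds = np.concatenate([[0], np.cumsum(sizes)]) * unit
    segments = [[p[bounds[b]:bounds[b + 1]] for p in parents]
                for b in range(n_blocks)]

    if target_unique is None:
        from itertools import product
        counter: Counter = Counter()
        order = []
        for choice in product(range(len(parents)), repeat=n_blocks):
            s = "".join(segments[b][c] for b, c in enumerate(choice))
            if s not in counter:
                order.append(s)
            counter[s] += 1
        return Library(order, np.array([counter[s] for s in order]),
                       "recombination")

    if rng is None:
        raise ValueError("sampled construction requires an rng")

    def draw(chunk=20000):
        picks = rng.integers(0, len(parents), size=(chunk, n_blocks))
        return ["".join(segments[b][c] for b, c in enumerate(row))
                for row in picks]

    seqs, counts = _accumulate_unique(draw, target_unique)
    return Library(seqs, counts, "recombination")


def random_parents(n_parents: int, n_codons: int, rng: np.random.Generator,
                   diversity: float = 0.5) -> list:
    """Synthetic aligned parent sequences for recombination studies.

    Generates one random codon-aligned ancestor (stop-free) and derives the
    parents by substituting each amino acid with probability ``diversity``.
    A stand-in for real serotype panels, which are external data.
    """
    aa = PROTEIN
    anc = rng.integers(0, len(aa), size=n_codons)
    parents = []
    for _ in range(n_parents):
        mask = rng.random(n_codons) < diversity
        offs = rng.integers(1, len(aa), size=n_codons)
        codes = np.where(mask, (anc + offs) % len(aa), anc)
        parents.append(back_translate("".join(aa[c] for c in codes)))
    return parents


# --------------------------------------------------------------------------
# selection
# --------------------------------------------------------------------------

@dataclass
class SelectionDistributions:
    """Pre-/post-selection library distributions and their fitness values."""

    library: Library
    p_pre: np.ndarray
    p_post: np.ndarray
    fitness_values: np.ndarray

    def __post_init__(self):
        for v in (self.p_pre, self.p_post):
            if (v < 0).any() or abs(v.sum() - 1.0) > 1e-12:
                raise ValueError("distributions must be normalized and non-negative")


def simulate_selection(library: Library, fitness: FitnessFunction,
                       rng: np.random.Generator) -> SelectionDistributions:
    """Dirichlet-perturbed pre distribution; fitness-rescaled post.

    ``p_pre ~ Dirichlet(c)``; ``p_post_i = exp(F(x_i)) p_pre_i / Z`` with
    ``Z = sum_i exp(F(x_i)) p_pre_i`` (computed max-shifted, so large
    fitness values cannot overflow). Re-running with a fresh rng draws a
    replicate over the same unique sequences.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    p_pre = rng.dirichlet(library.counts.astype(float))
    F = fitness.evaluate(library.translated())
    shifted = np.exp(F - F.max())
    unnorm = shifted * p_pre
    p_post = unnorm / unnorm.sum()
    return SelectionDistributions(library, p_pre, p_post, F)


@dataclass
class SelectivityDistributions:
    """Pre plus one post-selection distribution per fitness (pos, neg)."""

    library: Library
    p_pre: np.ndarray
    p_posts: list
    fitness_values: list  # one array per fitness, aligned with p_posts


def simulate_selectivity(library: Library, fitnesses,
                         rng: np.random.Generator) -> SelectivityDistributions:
    """Selection of one library under several fitness functions.

    Shares a single Dirichlet-perturbed pre-selection distribution and
    applies each fitness independently, as in a positive/negative
    selectivity experiment (condition 0 = pre, condition j = selection
    under ``fitnesses[j-1]``).
    """
    if len(library) == 0:
        raise ValueError("empty library")
    p_pre = rng.dirichlet(library.counts.astype(float))
    aa = library.translated()
    p_posts, values = [], []
    for fitness in fitnesses:
        F = fitness.evaluate(aa)
        unnorm = np.exp(F - F.max()) * p_pre
        p_posts.append(unnorm / unnorm.sum())
        values.append(F)
    return SelectivityDistributions(library, p_pre, p_posts, values)


# --------------------------------------------------------------------------
# sequencing reads
# --------------------------------------------------------------------------

@dataclass
class SimulatedReadSet:
    """Reads per condition, grouped by their source library sequence.

    ``by_source[j]`` maps a library-sequence index to a Counter of read
    strings drawn from it in condition ``j`` (condition 0 is
    pre-selection). Keeping the source allows sequence-level
    cross-validation to exclude every read of a held-out sequence, even
    truncated ones. ``library_counts`` holds the per-library-sequence
    multinomial draws (n_i^pre, n_i^post) before any truncation.
    """

    by_source: list
    library_counts: np.ndarray  # (M', n_conditions)
    read_mode: str
    window_codons: int | None
    error_rate: float = 0.0

    @property
    def n_conditions(self) -> int:
        return len(self.by_source)

    @property
    def totals(self) -> np.ndarray:
        return np.array([sum(sum(c.values()) for c in cond.values())
                         for cond in self.by_source])

    def condition_counts(self, condition: int) -> Counter:
        """Unique read -> count for one condition (sources merged)."""
        agg: Counter = Counter()
        for c in self.by_source[condition].values():
            agg.update(c)
        return agg

    def to_count_table(self, translate_aa: bool = True,
                       sources=None) -> CountTable:
        """Aggregate reads into a CountTable (translated by default).

        ``sources`` optionally restricts to reads originating from the
        given library-sequence indices. Reads whose translation contains a
        stop codon (possible only after substitution errors) are dropped
        from the translated table.
        """
        allowed = None if sources is None else set(int(i) for i in sources)
        agg: dict = {}
        k1 = self.n_conditions
        for j, cond in enumerate(self.by_source):
            for src, cc in cond.items():
                if allowed is not None and src not in allowed:
                    continue
                for s, n in cc.items():
                    key = translate(s) if translate_aa else s
                    if "*" in key:
                        continue
                    row = agg.setdefault(key, np.zeros(k1, dtype=np.int64))
                    row[j] += n
        seqs = list(agg)
        return CountTable(seqs, np.vstack([agg[s] for s in seqs]),
                          alphabet="protein" if translate_aa else "dna")

    def reads(self, condition: int):
        """Expand one condition's reads to a list of strings."""
        out = []
        for s, n in sorted(self.condition_counts(condition).items()):
            out.extend([s] * n)
        return out


def _truncate(seq: str, n_reads: int, window_codons: int,
              rng: np.random.Generator) -> Counter:
    n_cod = len(seq) // 3
    if window_codons >= n_cod:
        return Counter({seq: n_reads})
    starts = rng.integers(0, n_cod - window_codons + 1, size=n_reads)
    out: Counter = Counter()
    for st in starts:
        out[seq[3 * st: 3 * (st + window_codons)]] += 1
    return out


def sample_condition_reads(library: Library, distributions, depths,
                           read_mode: str = "full", window_codons: int = 100,
                           rng: np.random.Generator | None = None,
                           error_rate: float = 0.0) -> SimulatedReadSet:
    """Multinomial sequencing of one distribution per condition.

    ``distributions[j]`` is the library distribution for condition ``j``
    (condition 0 conventionally pre-selection) and ``depths[j]`` its read
    depth. ``read_mode``: ``full`` emits whole library sequences;
    ``short`` clips each read to ``window_codons`` codons at a uniform
    codon-aligned start (sequences shorter than the window are emitted
    whole); ``hybrid`` expects each depth as a ``(n_full, n_short)`` pair
    and mixes both. Substitution errors are applied independently per
    position at ``error_rate`` after truncation.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if read_mode not in ("full", "short", "hybrid"):
        raise ValueError(f"unknown read_mode {read_mode!r}")
    if len(distributions) != len(depths) or len(distributions) < 2:
        raise ValueError("need one depth per condition and >= 2 conditions")

    def one_condition(p, N):
        if read_mode == "hybrid":
            n_full, n_short = N
            parts = [("full", int(n_full)), ("short", int(n_short))]
        else:
            parts = [(read_mode, int(N))]
        by_src: dict = {}
        lib_counts = np.zeros(len(library), dtype=np.int64)
        for mode, n in parts:
            if n < 1:
                raise ValueError("read depths must be >= 1")
            counts = rng.multinomial(n, p)
            lib_counts += counts
            for i in np.nonzero(counts)[0]:
                seq, c = library.sequences[i], int(counts[i])
                dest = by_src.setdefault(int(i), Counter())
                if mode == "short":
                    dest.update(_truncate(seq, c, window_codons, rng))
                else:
                    dest[seq] += c
        return by_src, lib_counts

    cols = [one_condition(np.asarray(p), N)
            for p, N in zip(distributions, depths)]
    readset = SimulatedReadSet(
        by_source=[c[0] for c in cols],
        library_counts=np.column_stack([c[1] for c in cols]),
        read_mode=read_mode,
        window_codons=window_codons if read_mode != "full" else None,
        error_rate=0.0,
    )
    if error_rate > 0:
        readset = apply_substitution_errors(readset, error_rate, rng)
    return readset


def sample_reads(dist: SelectionDistributions, N_pre, N_post,
                 read_mode: str = "full", window_codons: int = 100,
                 rng: np.random.Generator | None = None,
                 error_rate: float = 0.0) -> SimulatedReadSet:
    """Two-condition (pre/post) wrapper around
    :func:`sample_condition_reads`."""
    return sample_condition_reads(dist.library, [dist.p_pre, dist.p_post],
                                  [N_pre, N_post], read_mode=read_mode,
                                  window_codons=window_codons, rng=rng,
                                  error_rate=error_rate)


def add_substitution_errors(reads, rate: float, alphabet: str,
                            rng: np.random.Generator) -> list:
    """Independently substitute each position with probability ``rate``.

    Takes and returns a list of read strings; lengths are always
    preserved (substitution-only error model).
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return list(reads)
    letters = DNA if alphabet in ("dna", DNA) else alphabet
    A = len(letters)
    lut = {a: i for i, a in enumerate(letters)}
    out = []
    by_len: dict = {}
    for i, s in enumerate(reads):
        by_len.setdefault(len(s), []).append(i)
        out.append(s)
    for L, idxs in by_len.items():
        codes = np.array([[lut[c] for c in out[i]] for i in idxs], dtype=np.int64)
        mask = rng.random(codes.shape) < rate
        offs = rng.integers(1, A, size=codes.shape)
        codes = np.where(mask, (codes + offs) % A, codes)
        for r, i in enumerate(idxs):
            out[i] = "".join(letters[c] for c in codes[r])
    return out


def apply_substitution_errors(readset: SimulatedReadSet, rate: float,
                              rng: np.random.Generator) -> SimulatedReadSet:
    """Expand, corrupt, and re-aggregate reads, source by source."""
    new_by_source = []
    for cond in readset.by_source:
        new_cond = {}
        for src in sorted(cond):
            expanded = []
            for s, n in sorted(cond[src].items()):
                expanded.extend([s] * n)
            corrupted = add_substitution_errors(expanded, rate, "dna", rng)
            new_cond[src] = Counter(corrupted)
        new_by_source.append(new_cond)
    return SimulatedReadSet(new_by_source, readset.library_counts,
                            readset.read_mode, readset.window_codons,
                            error_rate=rate)
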