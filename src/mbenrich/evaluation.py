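"""Evaluation protocol: sequence-level CV, focused rank metrics, tests.

Cross-validation is performed at the level of unique sequences so that a
held-out sequence's reads never reach the training data. Accuracy against
ground truth uses Spearman correlation, optionally *focused* on the
fraction of test sequences with the highest (or lowest) ground-truth
values. Selectivity experiments rank sequences by the difference between
predicted positive- and negative-selection fitness and compare the chosen
set against a theoretical optimum in the (positive, negative) fitness
plane. Significance machinery: Williams' t for two dependent correlations
sharing a variable, McNemar's test for paired accuracy indicators, and the
paired t-test across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar


@dataclass
class FoldAssignment:
    """Random k-way partition of unique sequences."""

    sequences: list
    fold: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.fold != fold)[0]


def make_folds(unique_sequences, k: int = 3, seed: int = 0) -> FoldAssignment:
    """Near-equal random partition, deterministic under ``seed``."""
    seqs = list(unique_sequences)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(seqs) < k:
        raise ValueError(f"need at least {k} sequences for {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(seqs))
    fold = np.zeros(len(seqs), dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, k)):
        fold[chunk] = f
    return FoldAssignment(seqs, fold, k, seed)


def generalized_spearman(pred, truth, fraction: float = 1.0,
                         tail: str = "top") -> float:
    """Spearman correlation focused on one tail of the ground truth.

    Restricts to the ``ceil(fraction * n)`` sequences with the highest
    (``tail='top'``) or lowest (``tail='bottom'``) ground-truth value; ties
    in the truth are broken by stable (input-order) sort. ``fraction=1``
    reduces to the standard Spearman correlation with average ranks.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length vectors")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if tail not in ("top", "bottom"):
        raise ValueError("tail must be 'top' or 'bottom'")
    n = len(truth)
    m = int(np.ceil(fraction * n))
    order = np.argsort(-truth if tail == "top" else truth, kind="stable")
    sel = order[:m]
    if m < 3:
        raise ValueError("selected subset too small for a correlation")
    if np.unique(truth[sel]).size < 2 or np.unique(pred[sel]).size < 2:
        raise ValueError("correlation undefined on a constant subset")
    rho = stats.spearmanr(pred[sel], truth[sel]).statistic
    return float(rho)


@dataclass
class SelectivityReport:
    """Top predicted-selectivity sequences vs. the theoretical optimum."""

    selected_indices: np.ndarray
    selected_fitness: np.ndarray  # (top_k, 2) true (positive, negative)
    mean_point: np.ndarray
    optimum: np.ndarray
    distance: float


def selectivity_analysis(pred_pos, pred_neg, truth_pos, truth_neg,
                         top_k: int = 10) -> SelectivityReport:
    """Rank by predicted selectivity (pos - neg); score the chosen set.

    The theoretical optimum has the maximum true positive fitness and
    minimum true negative fitness in the dataset; the report's distance is
    Euclidean from the mean selected point to that optimum. Rank ties are
    broken by input order (stable sort).
    """
    arrays = [np.asarray(a, dtype=float)
              for a in (pred_pos, pred_neg, truth_pos, truth_neg)]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all four vectors must be aligned")
    pp, pn, tp, tn = arrays
    sel = np.argsort(-(pp - pn), kind="stable")[:top_k]
    pts = np.column_stack([tp[sel], tn[sel]])
    mean_point = pts.mean(axis=0)
    optimum = np.array([tp.max(), tn.min()])
    return SelectivityReport(sel, pts, mean_point, optimum,
                             float(np.linalg.norm(mean_point - optimum)))


def top_fraction_identification_accuracy(pred_sel, truth_sel,
                                         fraction: float = 0.01) -> np.ndarray:
    """Hit indicators for identifying the truly most selective fraction.

    Returns, for each sequence in the true top fraction (by true
    selectivity), whether it also lands in the predicted top fraction.
    The paired indicator vectors of two methods feed :func:`mcnemar_test`.
    """
    pred_sel = np.asarray(pred_sel, dtype=float)
    truth_sel = np.asarray(truth_sel, dtype=float)
    n = len(truth_sel)
    m = int(np.ceil(fraction * n))
    if m < 1 or n < 1 / fraction:
        raise ValueError("not enough sequences for the requested fraction")
    true_top = np.argsort(-truth_sel, kind="stable")[:m]
    pred_top = set(np.argsort(-pred_sel, kind="stable")[:m].tolist())
    return np.array([1 if i in pred_top else 0 for i in true_top])


def williams_t_test(r_1g: float, r_2g: float, r_12: float, n: int):
    """Williams' test for two dependent correlations sharing one variable.

    Compares ``corr(X1, G)`` with ``corr(X2, G)`` given ``corr(X1, X2)``
    over ``n`` samples (Steiger's T2 form); returns ``(t, two-sided p)``
    with ``n - 3`` degrees of freedom.
    """
    for r in (r_1g, r_2g, r_12):
        if not -1 <= r <= 1:
            raise ValueError("correlations must be in [-1, 1]")
    if n < 4:
        raise ValueError("need n >= 4")
    detR = 1 - r_1g ** 2 - r_2g ** 2 - r_12 ** 2 + 2 * r_1g * r_2g * r_12
    rbar = (r_1g + r_2g) / 2
    denom = 2 * ((n - 1) / (n - 3)) * detR + rbar ** 2 * (1 - r_12) ** 3
    if denom <= 0:
        raise ValueError("degenerate correlation matrix")
    t = (r_1g - r_2g) * np.sqrt((n - 1) * (1 + r_12) / denom)
    p = 2 * stats.t.sf(abs(t), df=n - 3)
    return float(t), float(p)


def mcnemar_test(b: int, c: int, exact_threshold: int = 25):
    """McNemar's test from the two discordant counts.

    Exact binomial for ``b + c < exact_threshold``, chi-squared with
    continuity correction otherwise. ``b = c = 0`` returns p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b == 0 and c == 0:
        import warnings
        warnings.warn("no discordant pairs; test is uninformative")
        return 0.0, 1.0
    exact = (b + c) < exact_threshold
    table = [[0, b], [c, 0]]
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def paired_t_test(metric_pairs):
    """Paired t-test on per-dataset metric pairs [(m1, m2), ...]."""
    pairs = np.asarray(metric_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need >= 2 (m1, m2) pairs")
    diffs = pairs[:, 0] - pairs[:, 1]
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(pairs[:, 0], pairs[:, 1])
    return float(res.statistic), float(res.pvalue)
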